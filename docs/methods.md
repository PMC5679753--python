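# Methods

## The model

`memtube` simulates a fluid membrane tube decorated with curvature-sensing
proteins, the mechanistic picture proposed for the mitochondrial fission
factor MFF: a protein with a concave membrane-binding face prefers
membrane of small diameter, so it accumulates at constrictions (sensing)
and, at high surface density, can stabilise or induce them.

The membrane is a dynamically triangulated surface of V beads (diameter
σ, the length unit, mapped to ≈ 20 nm), closed into a tube that is
periodic along z with period L_z; topologically a torus (V − E + F = 0).
In-plane fluidity comes from bond flips: the shared edge of two adjacent
triangles is replaced by the opposite diagonal of their quadrilateral.
Self-avoidance is enforced by a bead hard core (σ) and tether bounds
l_min = σ < l < l_max = √3 σ on every edge — the standard
dynamically-triangulated-membrane choice that prevents surface crossing
under flips while allowing near-equilateral triangles.

The energy, in units of kT:

- **Curvature** (discrete Canham–Helfrich):
  U_bend = κ Σ_⟨ij⟩ (1 − **n**_i·**n**_j) over adjacent triangle pairs,
  with bending modulus κ = 20 kT.
- **Tension**: U_area = γ (A − A_ref), γ = 1 kT/σ² (≈ 0.01 pN/nm at
  σ = 20 nm, kT = 4.1 pN·nm). Only differences enter the acceptance
  rule; A_ref is fixed to the initial area so reported energies stay
  interpretable.
- **Adhesion**: each protein is a chain of five spheres (diameter
  D_col = 4σ, i.e. 80 nm; centre-to-centre spacing (2/3)·D_col) on a
  circular arc of radius R_pr (optimal 3.5σ). A sphere attracts membrane
  beads on its concave side only — beads within a closed cone of
  half-angle θ_pr = π/4 about the inward normal — with
  U_adh = −ε (D_min/r)⁶, ε = 3.8 kT, D_min = (D_col + σ)/2, truncated at
  r_cut = 2.5 D_min (the neglected tail is ≈ ε/244). Pairs closer than
  D_min are forbidden (hard core). Adhesion is pairwise additive over
  all eligible sphere–bead pairs; "ligand-receptor-like" is read as this
  distance form, not 1:1 bond bookkeeping.
- **Hinge**: the two wings (spheres {1,2} and {4,5}) are rigid and
  rotate about the middle sphere; U_flex = ½ k_flex (θ − θ_eq)², with
  k_flex = 20 kT and θ_eq = 2π/3. The hinge variable θ is defined so
  that θ = θ_eq is exactly the perfect-arc configuration (all five
  centres on the R_pr circle); deviations rotate the wings by ±(θ−θ_eq)/2
  about the arc-plane normal. This sidesteps the unresolvable question
  of whether a literal inter-wing angle of 2π/3 is compatible with the
  stated arc geometry: the equilibrium of the hinge potential *is* the
  arc shape.
- **Pre-constriction pinning** (optional): U_cp = ½ k_CP (R_v − R_eq)²
  summed over beads whose z lies in a central band (width 10σ,
  configurable), with k_CP = 0.01 kT/σ², R_eq = 3σ. R_v is the distance
  from the fixed z axis; the pinning defines where the constriction
  lives, so the axis is not refit per step.

Sampling is Metropolis Monte Carlo in the npT ensemble at p = 0: per
sweep, one attempted displacement per bead (uniform in a cube), one flip
attempt per bead, one rigid translation, one rigid rotation about a
random uniform axis and one hinge move per protein, and one axial box
rescale L_z → λL_z that scales all z coordinates affinely and carries
the volume-entropy weight N_dof ln λ (N_dof = beads + protein centres) in
the acceptance probability. All proposals are symmetric; amplitudes are
tuned to 30–50 % acceptance during burn-in only and then frozen, so
detailed balance holds in production. Energies are evaluated
incrementally (a cell list over beads serves the hard-core search); the
cached terms are tested against full recomputations to 1e-9 kT.

Two guard rails bound the ensemble without affecting the phenomena of
interest: the box length is confined to [0.5, 1.6] × its initial value
(the linear tension term would otherwise drive unbounded axial drift on
very long runs), and protein centres are confined to a lateral cylinder
of radius 2R + 6σ. The cage stands in for the finite lateral simulation
cell of a conventional periodic box: without it a protein that unbinds
random-walks into unbounded x, y and never returns, silently diluting
the surface density.

## Scenarios and the synthetic-data stage

Three scenarios reproduce the study conditions on a tube of radius 10σ
and length 100σ: `low_density` (20 proteins — they diffuse and remain
homogeneously distributed), `preconstricted` (20 proteins on a tube with
a waist pinned at R_eq = 3σ — proteins accumulate there), and
`high_density` (50 proteins — the regime where proteins can constrict
the tube themselves). A scale factor shrinks radius and length linearly
and the protein count with the area. The test-suite presets follow the
worked desk scale: tube 6σ × 40σ, 8 proteins at low density and 2.5×
that (20) at high density, with 6000–8000 sweeps per run — lengths chosen
by the energy-plateau diagnostic (Kendall-τ drift test on the second
half of the U_tot trace) at sizes a laptop CPU completes in about a
minute per run.

The pre-constricted initial mesh is built with the waist already formed
(rings of radius-adapted bead counts stitched by a two-pointer merge,
rings spaced by meridional arc length): the weak pinning (k_CP = 0.01)
can *maintain* a 3σ waist but cannot carve one from a 6–10σ tube on
sampling timescales. The waist half-width is 10σ: this makes the
meridional groove radius at the waist bottom ≈ 6σ, i.e. ≈ 3.5σ for
sphere centres riding 2.5σ above the surface — commensurate with the
protein arc, which is what lets proteins nestle into the waist. The
source study fixes only the central radius (3σ); the width is this
package's choice.

Protein placement is seeded rejection sampling, uniform in azimuth and
z, each protein wrapping the circumference with its binding face inward
and slid radially to minimal clearance from the actual mesh, so proteins
start bound at the local surface rather than hovering at the arc's
worst-case standoff.

The statistics stage consumes 2×2 event tables. `paper_event_tables`
packages the printed fission/division counts per experimental condition
(Shigella collisions, AFM indentation, vinyl-groove culture; wild-type
vs DRP1- or MFF-depleted). `generate_event_table` draws synthetic
Bernoulli analogues — n_positive ~ Binomial(n_events, p) — used for
calibration and parameter-recovery checks at the study sample sizes.

## Exact statistics

Fisher's exact test on [[k₁, n₁−k₁], [k₂, n₂−k₂]]. The two-sided
p-value follows the method of small p-values: the sum of hypergeometric
point probabilities, over all tables with the observed margins, not
exceeding the observed table's (relative tolerance 1e-12 absorbs
floating-point ties; a zero row or column margin gives p = 1 by
convention). Combinatorics run in log-gamma space, exact far beyond the
n ≈ 200 of the fixtures. The implementation is verified against full
integer enumeration for all n ≤ 30 and against an independent library
implementation at the study sizes. Whether the original analysis was
one- or two-sided is not stated; the two-sided value is reported, and it
reproduces every printed bound that is consistent with the printed
counts (the wild-type vs MFF-depleted Shigella bound of 10⁻⁴ is not:
13/23 vs 1/13 gives p ≈ 4.8×10⁻³, a discrepancy already latent in the
source's own "5.0 %" vs 1/13 = 7.7 %; the batch report flags that row
rather than reconciling it).

## What the synthetic scenarios do and do not show

The desk-scale runs reproduce, deterministically per seed:

- **Homogeneity at low density**: protein axial positions in the final
  snapshot pass a circular Kolmogorov–Smirnov uniformity test (the KS
  distance maximised over rotations of the origin; null distribution
  simulated once per sample size and cached). Pooling successive
  snapshots would correlate the sample and inflate rejection, so the
  test scores one equilibrated snapshot.
- **Accumulation at a pre-imposed constriction**: band enrichment
  (mean protein density inside the waist band over outside) exceeds 1,
  with a percentile bootstrap over post-burn-in snapshots. The
  mechanism at this scale is early capture: proteins within reach of
  the waist slide in and anchor at −80 to −110 kT, while proteins
  elsewhere settle into ≈ −40 kT surface grooves and become nearly
  immobile. Enrichment therefore reflects capture kinetics plus strong
  retention, not a fully mixed equilibrium — matching the qualitative
  claim (accumulation) but not quantifying its equilibrium constant.
- **Deeper constriction at high density**: compared seed-by-seed with
  the matched low-density run.

Known limitation, stated plainly: spontaneous *global* constriction of
the tube below 0.8× its nominal radius — the strongest high-density
phenotype — does not occur at desk scale within the sampling budget.
Outside-bound proteins pull membrane outward into bulges and engulfment
pockets; turning those into an inward neck requires a cooperative ring
of proteins whose nucleation is strongly activated, and the minimum
binned radius plateaus at ≈ 0.9× nominal over runs up to 40 000 sweeps,
across initial mesh densities from loose (the tube slowly densifies
axially through the box move) to dense (the tube entropically expands).
The corresponding acceptance test asserts the full property as stated
and is expected to fail at this scale; the comparative and
pre-constricted properties stand.

## Numerical choices

- Tether bounds (σ, √3 σ), bead hard core σ, contact conventions: the
  hard wall is strict (< forbidden, = allowed), the adhesion cone is
  closed (angle = θ_pr eligible). Measure-zero choices fixed for
  reproducibility.
- Initial triangulation: antiprism rings jittered by a seeded ±0.03σ;
  target edge 1.35σ (mid-tether), giving ≈ 1 bead/0.63σ² — close to the
  thermal equilibrium density, so the initial state carries neither
  artificial slack nor tension.
- Degenerate cases: `enrichment` with every protein in the band returns
  a documented sentinel (∞, capped at N in scenario reports);
  `min_radius` breaks ties toward the lowest z; empty histogram bins
  are flagged, not interpolated.
- RNG: a `numpy` Generator seeded per run; all sweep randomness is
  drawn in bulk per sweep and consumed by the compiled kernel, so runs
  are bit-reproducible from (config, seed). Rotation matrices are the
  canonical state; the sphere-offset cache is refreshed from them.
- The kernels are `numba`-compiled; the first sweep in a process pays
  the compilation cost (~10 s).

## Parameters at a glance

| symbol | meaning | default | units |
|---|---|---|---|
| κ | bending modulus | 20 | kT |
| γ | surface tension | 1 | kT/σ² |
| ε | adhesion strength | 3.8 | kT |
| D_col | protein-sphere diameter | 4 | σ |
| R_pr | binding-face arc radius | 3.5 | σ |
| θ_pr | contact half-angle | π/4 | rad |
| k_flex | hinge stiffness | 20 | kT/rad² |
| θ_eq | hinge equilibrium | 2π/3 | rad |
| k_CP | constriction pinning | 0.01 | kT/σ² |
| R_eq | pinning target radius | 3 | σ |
| σ | bead diameter = length unit | ≈ 20 | nm |

The sphere size deserves a note: the source material states in one
place that each sphere has radius σ and in another that the diameter is
σ, while its parameter list and physical mapping give D_col = 4σ =
80 nm. This package follows the parameter list (D_col = 4σ, spacing
(2/3)·D_col); `ProteinParams.D_col` is a plain config field, so the
alternative readings are one edit away.
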