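"""Scenario builders, synthetic event tables, and the packaged fixtures.

Three simulation scenarios mirror the study conditions: ``low_density``
(20 curvature-sensing proteins on a 10 sigma x 100 sigma tube, staying
homogeneously distributed), ``preconstricted`` (the same tube with a
harmonic radial pinning to R_eq = 3 sigma at its centre, where proteins
accumulate), and ``high_density`` (50 proteins, which constrict the tube
spontaneously).  A ``scale`` factor shrinks the tube for desk-sized runs
(radius and length scale linearly, the protein count with the area); the
``ci`` presets are the scaled-down study conditions used throughout the
test-suite (tube 6 sigma x 40 sigma, 8 proteins low density and 2.5x that
at high density).

The statistics stage's inputs are 2x2 event tables; ``paper_event_tables``
packages the printed fission/no-fission counts per experimental condition,
and ``generate_event_table`` draws synthetic Bernoulli analogues.
"""

from __future__ import annotations

import importlib.resources as resources
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .energy import EnergyParams
from .engine import MCParams, MCState, Trajectory, run
from .mesh import build_cylinder, build_preconstricted
from .observables import (
    enrichment,
    largest_cluster_fraction,
    min_radius,
    protein_axial_density,
    radius_profile,
    uniformity_test,
)
from .proteins import (
    Protein,
    ProteinParams,
    hard_core_overlap,
    local_geometry,
)

SCENARIO_NAMES = ("low_density", "preconstricted", "high_density",
                  "rpr_scan", "toy_harmonic")

#: full-scale protein counts on the 10 sigma x 100 sigma tube
_BASE = {
    "low_density": dict(radius=10.0, length=100.0, n_proteins=20, k_cp=0.0),
    "preconstricted": dict(radius=10.0, length=100.0, n_proteins=20, k_cp=0.01),
    "high_density": dict(radius=10.0, length=100.0, n_proteins=50, k_cp=0.0),
}

#: desk/CI-sized presets: smaller tube, proteins at the worked densities,
#: sweep counts sized by the energy-plateau diagnostic
CI_PRESETS = {
    "low_density": dict(radius=6.0, length=40.0, n_proteins=8,
                        sweeps=6000, burn_in=2000),
    "preconstricted": dict(radius=6.0, length=40.0, n_proteins=8,
                           sweeps=8000, burn_in=3000),
    "high_density": dict(radius=6.0, length=40.0, n_proteins=20,
                         sweeps=8000, burn_in=3000),
}


@dataclass
class ScenarioSpec:
    name: str
    radius: float
    length: float
    n_proteins: int
    scale: float = 1.0
    seed: int = 0
    sweeps: int = 100_000
    burn_in: int = 10_000
    snapshot_stride: int = 50
    eparams: EnergyParams = field(default_factory=EnergyParams)
    pparams: ProteinParams = field(default_factory=ProteinParams)
    mcparams: MCParams = field(default_factory=MCParams)

    def __post_init__(self):
        if self.name not in SCENARIO_NAMES:
            raise ValueError(f"unknown scenario {self.name!r}")
        if not 0 < self.scale <= 1:
            raise ValueError("scale must lie in (0, 1]")


def place_proteins(
    radius: float,
    length: float,
    n: int,
    pparams: ProteinParams,
    eparams: EnergyParams,
    rng: np.random.Generator,
    mesh=None,
    max_attempts: int = 20_000,
) -> list[Protein]:
    """Seeded rejection sampling of non-overlapping proteins on the tube.

    Each protein wraps the circumference with its binding face toward the
    axis and is slid radially inward to the smallest clearance from the
    membrane (so it starts bound rather than hovering at the arc's worst-
    case standoff).  When ``mesh`` is given the clearance search tests the
    actual beads; otherwise the ideal cylinder surface.
    """
    d_min = eparams.d_min(pparams)
    clear = pparams.R_pr * (1.0 - np.cos(2 * pparams.arc_step))
    out: list[Protein] = []
    attempts = 0
    while len(out) < n:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                f"placed {len(out)}/{n} proteins in {max_attempts} attempts; "
                f"tube {radius}x{length} too crowded"
            )
        phi = rng.uniform(0, 2 * np.pi)
        z = rng.uniform(0, length)
        r_hat = np.array([np.cos(phi), np.sin(phi), 0.0])
        phi_hat = np.array([-np.sin(phi), np.cos(phi), 0.0])
        z_hat = np.array([0.0, 0.0, 1.0])
        rot = np.column_stack([-r_hat, z_hat, phi_hat])

        def overlaps_membrane(rc: float) -> bool:
            cand = Protein(centre=rc * r_hat + z * z_hat, orientation=rot)
            if mesh is not None:
                return hard_core_overlap(cand, pparams, mesh)
            from .proteins import sphere_centres

            sph = sphere_centres(cand, pparams)
            rad = np.linalg.norm(sph[:, :2], axis=1)
            return bool((rad < radius + d_min + 0.05).any())

        # walk inward from the guaranteed-clear standoff to minimal clearance
        rc = radius + d_min + clear + 0.4
        step = 0.25
        while rc - step > radius and not overlaps_membrane(rc - step):
            rc -= step
        cand = Protein(centre=rc * r_hat + z * z_hat, orientation=rot)
        if any(hard_core_overlap(cand, pparams, o, box_length=length)
               for o in out):
            continue
        out.append(cand)
    return out


def make_scenario(
    name: str,
    scale: float = 1.0,
    seed: int = 0,
    *,
    radius: Optional[float] = None,
    length: Optional[float] = None,
    n_proteins: Optional[int] = None,
    sweeps: Optional[int] = None,
    burn_in: Optional[int] = None,
    r_pr: Optional[float] = None,
    target_edge: float = 1.35,
) -> tuple[MCState, ScenarioSpec]:
    """Build a fully configured, validated initial state for a scenario.

    At ``scale = 1`` the study dimensions apply (10 sigma radius, 100 sigma
    length, 20 or 50 proteins, pre-constriction pinning at R_eq = 3 sigma
    for ``preconstricted``); ``scale < 1`` shrinks radius and length
    linearly and the protein count with the tube area.  Keyword overrides
    take precedence (the ``ci`` presets use them).
    """
    if name not in _BASE:
        raise ValueError(f"unknown scenario {name!r}")
    base = _BASE[name]
    radius = radius if radius is not None else base["radius"] * scale
    length = length if length is not None else base["length"] * scale
    if n_proteins is None:
        n_proteins = max(1, int(round(base["n_proteins"] * scale**2)))
    eparams = EnergyParams(k_cp=base["k_cp"])
    pparams = ProteinParams(R_pr=r_pr if r_pr is not None else 3.5)
    mcparams = MCParams(seed=seed)
    spec = ScenarioSpec(
        name=name, radius=radius, length=length, n_proteins=n_proteins,
        scale=scale, seed=seed,
        sweeps=sweeps if sweeps is not None else 100_000,
        burn_in=burn_in if burn_in is not None else 10_000,
        eparams=eparams, pparams=pparams, mcparams=mcparams,
    )
    rng = np.random.default_rng(seed)
    if name == "preconstricted":
        # the pre-imposed constriction is part of the initial condition;
        # the weak pinning potential (k_cp) maintains it during sampling.
        # The waist half-width (10 sigma) makes the meridional groove
        # curvature commensurate with the protein arc.
        mesh = build_preconstricted(
            radius, length, neck_radius=eparams.R_eq, neck_width=10.0,
            seed=int(rng.integers(2**31)),
        )
    else:
        mesh = build_cylinder(radius, length, target_edge=target_edge,
                              seed=int(rng.integers(2**31)))
    prots = place_proteins(radius, length, n_proteins, pparams, eparams, rng,
                           mesh=mesh)
    state = MCState(mesh, prots, eparams, pparams, mcparams)
    return state, spec


def make_ci_scenario(name: str, seed: int = 0, **overrides):
    """The scaled-down study conditions used by the test-suite."""
    kw = dict(CI_PRESETS[name])
    kw.update(overrides)
    radius = kw.pop("radius")
    return make_scenario(name, scale=radius / 10.0, seed=seed,
                         radius=radius, **kw)


@dataclass
class ScenarioReport:
    spec: ScenarioSpec
    trajectory: Trajectory
    observables: dict
    diagnostics: dict
    passed: Optional[bool]  # None = inconclusive (no energy plateau)


def _plateau_diagnostics(energies: np.ndarray) -> dict:
    """Stationarity of the second half of the energy trace.

    Mann-Kendall style check via Kendall's tau of U_tot against snapshot
    index; a small p-value signals drift (no plateau)."""
    half = energies[len(energies) // 2:]
    if len(half) < 8 or np.allclose(half, half[0]):
        return {"tau": 0.0, "p_trend": 1.0, "plateau": True}
    tau, p = sps.kendalltau(np.arange(len(half)), half)
    if not np.isfinite(tau):
        tau, p = 0.0, 1.0
    return {"tau": float(tau), "p_trend": float(p),
            "plateau": bool(p > 0.01 or abs(tau) < 0.35)}


def run_scenario(
    state: MCState,
    spec: ScenarioSpec,
    n_bins: int = 10,
) -> ScenarioReport:
    """Run a scenario and score its qualitative property.

    low_density: protein axial positions stay uniform (circular-KS p > 0.01
    on pooled post-burn-in snapshots).  preconstricted: protein enrichment
    in the constriction band exceeds 1 with >= 95% bootstrap confidence.
    high_density: the equilibrated minimum tube radius drops below 0.8x the
    nominal radius.  A run with no energy plateau is flagged inconclusive
    (``passed = None``) rather than scored.
    """
    state.tune_amplitudes(n_sweeps=min(200, spec.burn_in // 2))
    done_burn = state.sweeps_done
    if spec.burn_in > done_burn:
        state.sweep(spec.burn_in - done_burn)
    traj = run(state, spec.sweeps - state.sweeps_done,
               snapshot_stride=spec.snapshot_stride)

    energies = traj.energy_trace
    diag = _plateau_diagnostics(energies)
    diag["acceptance"] = [
        (int(sw), a.tolist()) for sw, a in traj.acceptance[-3:]
    ]
    diag["seed"] = spec.seed
    diag["sweeps"] = spec.sweeps
    diag["energy_drift"] = state.energy_drift()

    half = traj.snapshots[len(traj.snapshots) // 2:]
    L = state.box[0]
    obs: dict = {}
    prof = radius_profile(state.mesh, n_bins=n_bins)
    obs["final_min_radius"], obs["min_radius_z"] = min_radius(prof)
    obs["initial_radius"] = spec.radius
    # uniformity is scored on the final snapshot: one draw from the
    # equilibrated ensemble (pooling successive snapshots would correlate
    # the sample and inflate rejection)
    last = traj.snapshots[-1]
    zs = last.protein_centres[:, 2] % last.box_length
    stat, p_unif = uniformity_test(zs, last.box_length) \
        if len(zs) >= 5 else (np.nan, np.nan)
    obs["uniformity_stat"], obs["uniformity_p"] = stat, p_unif
    # per-snapshot enrichment in the central band, bootstrap over snapshots
    band = (0.5 * L - state.eparams.band_width / 2,
            0.5 * L + state.eparams.band_width / 2)
    enr = []
    minr = []
    for s in half:
        dens = protein_axial_density(s.protein_centres[:, 2], s.box_length,
                                     n_bins=n_bins)
        e = enrichment(dens, (band[0] / L * s.box_length,
                              band[1] / L * s.box_length))
        enr.append(min(e, spec.n_proteins * 1.0))  # cap the sentinel
        m = build_profile_min(s, n_bins)
        minr.append(m)
    enr = np.asarray(enr)
    obs["enrichment_mean"] = float(enr.mean()) if len(enr) else np.nan
    rng = np.random.default_rng(spec.seed + 7)
    if len(enr):
        boots = np.array([
            enr[rng.integers(0, len(enr), len(enr))].mean()
            for _ in range(2000)
        ])
        obs["enrichment_ci_low"] = float(np.quantile(boots, 0.05))
    obs["min_radius_trace"] = np.asarray(minr)
    obs["min_radius_median"] = float(np.median(minr)) if minr else np.nan

    if not diag["plateau"]:
        passed = None
    elif spec.name == "low_density":
        passed = bool(p_unif > 0.01)
    elif spec.name == "preconstricted":
        passed = bool(obs.get("enrichment_ci_low", 0.0) > 1.0)
    elif spec.name == "high_density":
        passed = bool(obs["min_radius_median"] < 0.8 * spec.radius)
    else:
        passed = None
    return ScenarioReport(spec, traj, obs, diag, passed)


def build_profile_min(snapshot, n_bins: int) -> float:
    """Minimum binned mean radius of a snapshot's membrane."""
    L = snapshot.box_length
    z = snapshot.positions[:, 2] % L
    r = np.linalg.norm(snapshot.positions[:, :2], axis=1)
    idx = np.minimum((z / L * n_bins).astype(int), n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    sums = np.bincount(idx, weights=r, minlength=n_bins)
    means = sums[counts > 0] / counts[counts > 0]
    return float(means.min())


# ---------------------------------------------------------------------------
# R_pr scan
# ---------------------------------------------------------------------------

DEFAULT_RPR_GRID = (2.5, 3.0, 3.5, 4.0, 5.0)


def rpr_scan(
    values: Sequence[float] = DEFAULT_RPR_GRID,
    seeds: Sequence[int] = (0, 1, 2),
    scenario: str = "high_density",
    ci: bool = True,
    sweeps: Optional[int] = None,
    burn_in: Optional[int] = None,
) -> pd.DataFrame:
    """Assembly order parameter (largest cluster fraction) per arc radius.

    One row per (R_pr, seed); the argmax over R_pr of the seed-averaged
    cluster fraction locates the optimal protein/tube diameter ratio.
    """
    if len(values) < 1:
        raise ValueError("need at least one R_pr value")
    rows = []
    for rpr in values:
        for seed in seeds:
            if ci:
                st, spec = make_ci_scenario(scenario, seed=seed, r_pr=rpr)
            else:
                st, spec = make_scenario(scenario, seed=seed, r_pr=rpr)
            if sweeps is not None:
                spec = replace(spec, sweeps=sweeps,
                               burn_in=burn_in if burn_in is not None
                               else spec.burn_in)
            st.tune_amplitudes(n_sweeps=min(200, spec.burn_in))
            if spec.burn_in > st.sweeps_done:
                st.sweep(spec.burn_in - st.sweeps_done)
            traj = run(st, spec.sweeps - st.sweeps_done,
                       snapshot_stride=spec.snapshot_stride)
            half = traj.snapshots[len(traj.snapshots) // 2:]
            fracs = []
            for s in half:
                sph = np.empty((spec.n_proteins, 5, 3))
                for i in range(spec.n_proteins):
                    off_l, _ = local_geometry(st.pparams, s.wing_angles[i])
                    sph[i] = (s.protein_centres[i]
                              + off_l @ s.protein_rotations[i].T)
                fracs.append(largest_cluster_fraction(
                    sph, 1.2 * st.pparams.D_col, box_length=s.box_length))
            rows.append({"R_pr": rpr, "seed": seed,
                         "cluster_fraction": float(np.mean(fracs))})
    df = pd.DataFrame(rows)
    return df


def rpr_scan_argmax(df: pd.DataFrame) -> float:
    """R_pr with the highest seed-averaged cluster fraction."""
    return float(df.groupby("R_pr")["cluster_fraction"].mean().idxmax())


# ---------------------------------------------------------------------------
# event tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EventTable:
    """Scored events for one condition: how many led to fission/division."""

    label: str
    n_events: int
    n_positive: int
    provenance: str = "synthetic"
    description: str = ""

    def __post_init__(self):
        if not 0 <= self.n_positive <= self.n_events:
            raise ValueError("need 0 <= n_positive <= n_events")


def paper_event_tables() -> list[EventTable]:
    """The packaged fixture of printed fission/division counts."""
    with resources.files("memtube.data").joinpath("event_tables.csv").open() as f:
        df = pd.read_csv(f)
    return [
        EventTable(r.label, int(r.n_events), int(r.n_positive),
                   r.provenance, r.description)
        for r in df.itertuples(index=False)
    ]


def generate_event_table(
    n_events: int, p_fission: float, seed: int, label: str = "synthetic"
) -> EventTable:
    """Bernoulli fission outcomes: n_positive ~ Binomial(n_events, p)."""
    if n_events < 1:
        raise ValueError("n_events must be >= 1")
    if not 0 <= p_fission <= 1:
        raise ValueError("p_fission must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    k = int(rng.binomial(n_events, p_fission))
    return EventTable(label, n_events, k, provenance="synthetic")
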