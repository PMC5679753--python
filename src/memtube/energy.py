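"""Energy terms of the membrane-protein model, in units of kT and sigma.

Total energy:

    U_tot = U_bend + U_area + U_adh + U_flex (+ U_cp when constriction pinning
            is enabled)

with the discrete curvature (Canham-Helfrich) energy
``U_bend = kappa * sum_<ij> (1 - n_i . n_j)`` over adjacent triangle pairs,
a linear tension term ``U_area = gamma * (A - A_ref)``, a short-ranged
concave-side adhesion ``U_adh = -eps * (D_min / r)^6`` between protein spheres
and membrane beads, a harmonic hinge ``U_flex = 1/2 k_flex (theta-theta_eq)^2``
per protein, and an optional harmonic radial pinning
``U_cp = 1/2 k_cp (R_v - R_eq)^2`` over beads in a central axial band.

These are straightforward vectorised numpy implementations; they define the
model and serve as the reference against which the incremental Monte Carlo
kernels are tested.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np

from .mesh import TriMesh, surface_area
from .proteins import Protein, ProteinParams, local_geometry


@dataclass
class EnergyParams:
    """Hamiltonian parameters in simulation units (kT = 1, lengths in sigma).

    Defaults are the biologically-mapped values: kappa = 20 kT, gamma = 1
    kT/sigma^2, eps = 3.8 kT, k_flex = 20 kT, theta_eq = 2*pi/3, k_cp = 0.01
    kT/sigma^2 with R_eq = 3 sigma; sigma corresponds to roughly 20 nm.
    """

    kappa: float = 20.0
    gamma: float = 1.0
    eps: float = 3.8
    k_flex: float = 20.0
    theta_eq: float = 2 * np.pi / 3
    k_cp: float = 0.0  # 0.01 when the pre-constriction potential is enabled
    R_eq: float = 3.0
    band_width: float = 10.0  # axial width of the constriction band
    r_cut_factor: float = 2.5  # adhesion cutoff in units of D_min
    A_ref: Optional[float] = None  # reference area; defaults to initial area
    sigma_nm: float = 20.0
    kT_pN_nm: float = 4.1

    def __post_init__(self):
        for name in ("kappa", "gamma", "eps", "k_flex", "k_cp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0 < self.theta_eq < np.pi:
            raise ValueError("theta_eq must lie in (0, pi)")

    def d_min(self, protein: ProteinParams, bead_diameter: float = 1.0) -> float:
        """Sphere-bead contact distance (sum of the two radii)."""
        return 0.5 * (protein.D_col + bead_diameter)

    def r_cut(self, protein: ProteinParams, bead_diameter: float = 1.0) -> float:
        return self.r_cut_factor * self.d_min(protein, bead_diameter)

    def surface_tension_pN_per_nm(self) -> float:
        """gamma converted to physical units (the model's own cross-check)."""
        return self.gamma * self.kT_pN_nm / self.sigma_nm**2


def bending_energy(mesh: TriMesh, kappa: float) -> float:
    """kappa * sum over adjacent triangle pairs of (1 - n_i . n_j).

    Boundary edges of open test patches (single incident triangle) carry no
    dihedral and are skipped; the closed tube has none.
    """
    normals = mesh.triangle_normals()
    interior = (mesh.edge_tri >= 0).all(axis=1)
    n1 = normals[mesh.edge_tri[interior, 0]]
    n2 = normals[mesh.edge_tri[interior, 1]]
    return float(kappa * np.sum(1.0 - np.einsum("ij,ij->i", n1, n2)))


def area_energy(mesh: TriMesh, gamma: float, A_ref: float) -> float:
    """gamma * (A - A_ref); only differences enter the Metropolis rule."""
    return float(gamma * (surface_area(mesh) - A_ref))


def _sphere_arrays(
    proteins: Sequence[Protein], params: ProteinParams
) -> Tuple[np.ndarray, np.ndarray]:
    """World-frame sphere centres and binding directions, stacked (N*5, 3)."""
    cs, bs = [], []
    for p in proteins:
        off, bdir = local_geometry(params, p.wing_angle)
        cs.append(p.centre[None, :] + off @ p.orientation.T)
        bs.append(bdir @ p.orientation.T)
    if not cs:
        return np.zeros((0, 3)), np.zeros((0, 3))
    return np.concatenate(cs), np.concatenate(bs)


def adhesion_energy(
    proteins: Sequence[Protein],
    mesh: TriMesh,
    eps: float,
    protein_params: ProteinParams,
    r_cut: float,
    bead_diameter: float = 1.0,
) -> float:
    """Sum of -eps*(D_min/r)^6 over eligible sphere-bead pairs within r_cut.

    A pair is eligible when the bead lies inside the closed binding cone of
    half-angle theta_pr around the sphere's concave-side normal.  A pair
    closer than D_min is an invalid (hard-core) configuration and raises.
    """
    centres, bdirs = _sphere_arrays(proteins, protein_params)
    if centres.shape[0] == 0:
        return 0.0
    dmin = 0.5 * (protein_params.D_col + bead_diameter)
    d = mesh.minimum_image(mesh.positions[None, :, :] - centres[:, None, :])
    r = np.linalg.norm(d, axis=2)
    if (r < dmin - 1e-12).any():
        raise ValueError("sphere-bead pair inside hard core; invalid state")
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = np.einsum("svj,sj->sv", d, bdirs) / r
    mask = (r <= r_cut) & (cosang >= np.cos(protein_params.theta_pr) - 1e-12)
    return float(-eps * np.sum((dmin / r[mask]) ** 6))


def flex_energy(p: Protein, k_flex: float, theta_eq: float) -> float:
    """Harmonic hinge energy 1/2 k_flex (theta - theta_eq)^2."""
    if not 0 < p.wing_angle <= np.pi:
        raise ValueError("wing angle must lie in (0, pi]")
    return float(0.5 * k_flex * (p.wing_angle - theta_eq) ** 2)


def constriction_energy(
    mesh: TriMesh,
    k_cp: float,
    R_eq: float,
    band: Optional[Tuple[float, float]] = None,
) -> float:
    """1/2 k_cp (R_v - R_eq)^2 summed over beads in the axial band.

    ``band`` is an (z_lo, z_hi) window in [0, L); by default a central window
    of the configured width.  The radial distance is measured from the fixed
    z axis, which also defines where the pinning acts.
    """
    if k_cp == 0.0:
        return 0.0
    L = mesh.box_length
    if band is None:
        band = (L / 2 - 5.0, L / 2 + 5.0)
    z = mesh.positions[:, 2] % L
    lo, hi = band[0] % L, band[1] % L
    inside = (z >= lo) & (z <= hi) if lo <= hi else (z >= lo) | (z <= hi)
    R_v = np.linalg.norm(mesh.positions[inside, :2], axis=1)
    return float(0.5 * k_cp * np.sum((R_v - R_eq) ** 2))


def total_energy(
    mesh: TriMesh,
    proteins: Sequence[Protein],
    eparams: EnergyParams,
    protein_params: ProteinParams,
    band: Optional[Tuple[float, float]] = None,
) -> dict:
    """All enabled terms and their sum, as a breakdown dict (keys in kT)."""
    A_ref = eparams.A_ref if eparams.A_ref is not None else surface_area(mesh)
    terms = {
        "U_bend": bending_energy(mesh, eparams.kappa),
        "U_area": area_energy(mesh, eparams.gamma, A_ref),
        "U_adh": adhesion_energy(
            proteins, mesh, eparams.eps, protein_params,
            eparams.r_cut(protein_params),
        ),
        "U_flex": float(
            sum(flex_energy(p, eparams.k_flex, eparams.theta_eq) for p in proteins)
        ),
        "U_cp": constriction_energy(mesh, eparams.k_cp, eparams.R_eq, band),
    }
    terms["U_tot"] = float(sum(terms.values()))
    return terms
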