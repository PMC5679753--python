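"""Arc-shaped, five-sphere curvature-sensing protein.

The protein is a linear chain of five spheres whose centres sit on a circular
arc of radius ``R_pr``; the concave (inner) side of the arc is the membrane-
binding face.  The two wings (spheres {0,1} and {3,4}) are rigid and hinge
about the middle sphere; a single hinge angle theta parametrises the opening
between them, with the perfect-arc configuration at ``theta_eq``.  A binding
cone of half-angle ``theta_pr`` around each sphere's inward normal restricts
adhesion to the concave side.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

N_SPHERES = 5
MIDDLE = 2


@dataclass
class ProteinParams:
    """Geometry of the model protein, lengths in sigma.

    R_pr : arc radius of the binding face (optimum near 3.5).
    D_col : diameter of each sphere (4 sigma, i.e. 80 nm at sigma = 20 nm).
    spacing : centre-to-centre distance along the chain, (2/3) * D_col.
    theta_pr : protein-membrane contact half-angle (pi/4).
    theta_eq : hinge angle of the perfect-arc reference configuration.
    """

    R_pr: float = 3.5
    D_col: float = 4.0
    theta_pr: float = np.pi / 4
    theta_eq: float = 2 * np.pi / 3

    @property
    def spacing(self) -> float:
        return self.D_col * 2.0 / 3.0

    @property
    def arc_step(self) -> float:
        """Angular step between adjacent sphere centres on the arc (chord)."""
        x = self.spacing / (2.0 * self.R_pr)
        if x >= 1.0:
            raise ValueError("spacing exceeds arc diameter; R_pr too small")
        return 2.0 * np.arcsin(x)

    def __post_init__(self):
        if self.R_pr <= 0:
            raise ValueError("R_pr must be positive")
        if not 0 < self.theta_pr < np.pi / 2:
            raise ValueError("theta_pr must lie in (0, pi/2)")


@dataclass
class Protein:
    """A rigid-wing protein: middle-sphere position, orientation, hinge angle.

    ``orientation`` is a rotation matrix mapping the local frame to the world
    frame.  Local frame: x points from the middle sphere toward the arc
    centre (the binding direction of the middle sphere), y is the hinge axis
    (normal of the arc plane), z is the arc tangent at the middle sphere.
    """

    centre: np.ndarray
    orientation: np.ndarray = field(default_factory=lambda: np.eye(3))
    wing_angle: float = 2 * np.pi / 3

    def __post_init__(self):
        self.centre = np.asarray(self.centre, dtype=np.float64)
        self.orientation = np.asarray(self.orientation, dtype=np.float64)


def _rot_y(angle: float) -> np.ndarray:
    c, s = np.cos(angle), np.sin(angle)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def local_geometry(params: ProteinParams, wing_angle: float):
    """Sphere-centre offsets and binding directions in the protein frame.

    At ``wing_angle == theta_eq`` the five centres lie exactly on a circle of
    radius R_pr through the origin with its centre at +x * R_pr.  Deviations
    delta = wing_angle - theta_eq rotate each wing rigidly by +-delta/2 about
    the hinge axis (y) through the middle sphere; positive delta opens the
    wings (flattens the arc).
    """
    R, alpha = params.R_pr, params.arc_step
    idx = np.arange(N_SPHERES) - MIDDLE  # -2..2
    ang = idx * alpha
    off = np.stack(
        [R * (1.0 - np.cos(ang)), np.zeros_like(ang), -R * np.sin(ang)], axis=1
    )
    bdir = np.stack([np.cos(ang), np.zeros_like(ang), np.sin(ang)], axis=1)
    delta = wing_angle - params.theta_eq
    if delta != 0.0:
        # wing at -z (spheres 0,1) rotates by -delta/2, wing at +z by +delta/2
        rl = _rot_y(+delta / 2.0)
        rr = _rot_y(-delta / 2.0)
        off[:MIDDLE] = off[:MIDDLE] @ rl.T
        bdir[:MIDDLE] = bdir[:MIDDLE] @ rl.T
        off[MIDDLE + 1 :] = off[MIDDLE + 1 :] @ rr.T
        bdir[MIDDLE + 1 :] = bdir[MIDDLE + 1 :] @ rr.T
    return off, bdir


def sphere_centres(p: Protein, params: ProteinParams) -> np.ndarray:
    """World-frame centres of the five spheres, middle sphere at p.centre."""
    off, _ = local_geometry(params, p.wing_angle)
    return p.centre[None, :] + off @ p.orientation.T


def binding_direction(p: Protein, params: ProteinParams, i: int) -> np.ndarray:
    """Unit vector from sphere ``i`` toward the concave side of the arc."""
    if not 0 <= i < N_SPHERES:
        raise IndexError(f"sphere index {i} out of range")
    _, bdir = local_geometry(params, p.wing_angle)
    return p.orientation @ bdir[i]


def adhesion_eligible(
    p: Protein, params: ProteinParams, i: int, bead: np.ndarray
) -> bool:
    """True iff ``bead`` lies inside the closed binding cone of sphere ``i``."""
    centres = sphere_centres(p, params)
    d = np.asarray(bead, dtype=np.float64) - centres[i]
    r = np.linalg.norm(d)
    if r < 1e-12:
        raise ValueError("bead coincides with sphere centre; angle undefined")
    return float(np.dot(d / r, binding_direction(p, params, i))) >= np.cos(
        params.theta_pr
    ) - 1e-12


def hard_core_overlap(
    p: Protein,
    params: ProteinParams,
    other,
    bead_diameter: float = 1.0,
    box_length: float | None = None,
) -> bool:
    """Excluded-volume test against another protein or a membrane mesh.

    Sphere-sphere pairs of different proteins overlap below D_col; a sphere
    and a membrane bead overlap strictly below D_min = (D_col + sigma) / 2
    (contact at exactly D_min is allowed).  ``box_length``, when given,
    applies the minimum-image convention along z for protein-protein tests.
    """
    c1 = sphere_centres(p, params)
    if isinstance(other, Protein):
        c2 = sphere_centres(other, params)
        dv = c1[:, None, :] - c2[None, :, :]
        if box_length is not None:
            dv[..., 2] -= box_length * np.round(dv[..., 2] / box_length)
        d = np.linalg.norm(dv, axis=2)
        return bool((d < params.D_col).any())
    mesh = other
    dmin = 0.5 * (params.D_col + bead_diameter)
    d = mesh.minimum_image(mesh.positions[None, :, :] - c1[:, None, :])
    return bool((np.linalg.norm(d, axis=2) < dmin).any())
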