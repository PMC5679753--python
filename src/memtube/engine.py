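"""Metropolis Monte Carlo driver for the membrane-protein system.

Sampling is plain Metropolis with symmetric proposals in the npT ensemble at
p = 0: per sweep, one attempted displacement per membrane bead, one edge-flip
attempt per bead, one translation + one rigid rotation + one hinge move per
protein, and one axial box rescale.  The box move rescales L_z and all z
coordinates affinely and carries the volume-entropy weight N_dof * ln(lambda)
in the acceptance rule (no pV term at p = 0).

The hot loop lives in ``_kernels``; this module owns state packing, seeding,
amplitude tuning and trajectory capture.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from . import _kernels as K
from .energy import EnergyParams
from .mesh import L_MAX, L_MIN, SIGMA_HC, TriMesh, validate
from .proteins import Protein, ProteinParams, local_geometry

MOVE_KINDS = ("vertex", "flip", "protein_translate", "protein_rotate", "wing", "box")


@dataclass
class MCParams:
    """Move amplitudes, mix, and run bookkeeping.  kT = 1, p = 0 (fixed)."""

    max_vertex_disp: float = 0.12
    max_protein_disp: float = 0.4
    max_rotation: float = 0.25
    max_wing: float = 0.1
    max_box_frac: float = 0.01
    flips_per_vertex: float = 1.0
    box_moves_per_sweep: int = 1
    n_sweeps: int = 1000
    snapshot_stride: int = 50
    seed: int = 0
    kT: float = 1.0
    pressure: float = 0.0
    box_min_frac: float = 0.5  # guard walls on L_z relative to the initial box
    box_max_frac: float = 1.6

    def __post_init__(self):
        if self.pressure != 0.0:
            raise ValueError("only p = 0 is supported")
        for name in ("max_vertex_disp", "max_protein_disp", "max_rotation",
                     "max_wing", "max_box_frac"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def metropolis_accept(delta_u, log_weight: float, rng: np.random.Generator,
                      kT: float = 1.0) -> bool:
    """Accept with probability min(1, exp(-dU/kT + log_weight)).

    ``delta_u`` may be None or +inf as a rejection signal (hard-core
    overlap): always rejected.
    """
    if delta_u is None or not np.isfinite(delta_u):
        return False
    x = -delta_u / kT + log_weight
    if x >= 0.0:
        return True
    return bool(rng.random() < np.exp(x))


def propose_move(state: "MCState", kind: str, rng: np.random.Generator):
    """Describe one symmetric trial move; returns (proposal dict, log_weight).

    Pure description (nothing is mutated): used to verify proposal symmetry
    and the box-move volume weight.  The sweep kernel draws the same
    proposal families internally.
    """
    if kind not in MOVE_KINDS:
        raise ValueError(f"unknown move kind {kind!r}")
    m = state.mcparams
    if kind == "vertex":
        v = int(rng.integers(state.mesh.n_vertices))
        disp = rng.uniform(-m.max_vertex_disp, m.max_vertex_disp, 3)
        return {"kind": kind, "vertex": v, "displacement": disp}, 0.0
    if kind == "flip":
        return {"kind": kind, "edge": int(rng.integers(state.mesh.n_edges))}, 0.0
    if kind == "protein_translate":
        i = int(rng.integers(max(1, state.pc.shape[0])))
        disp = rng.uniform(-m.max_protein_disp, m.max_protein_disp, 3)
        return {"kind": kind, "protein": i, "displacement": disp}, 0.0
    if kind == "protein_rotate":
        i = int(rng.integers(max(1, state.pc.shape[0])))
        z = rng.uniform(-1.0, 1.0)
        phi = rng.uniform(0.0, 2 * np.pi)
        s = np.sqrt(max(0.0, 1.0 - z * z))
        axis = np.array([s * np.cos(phi), s * np.sin(phi), z])
        angle = rng.uniform(-m.max_rotation, m.max_rotation)
        return {"kind": kind, "protein": i, "axis": axis, "angle": angle}, 0.0
    if kind == "wing":
        i = int(rng.integers(max(1, state.pc.shape[0])))
        return {"kind": kind, "protein": i,
                "delta": rng.uniform(-m.max_wing, m.max_wing)}, 0.0
    lam = 1.0 + m.max_box_frac * rng.uniform(-1.0, 1.0)
    n_dof = state.mesh.n_vertices + state.pc.shape[0]
    return {"kind": kind, "lambda": lam}, n_dof * np.log(lam)


class MCState:
    """Mesh + proteins + parameters + RNG + cached energy terms.

    The cached accumulator (U_bend, area, U_adh, U_flex, U_cp) is updated
    incrementally by the kernels; ``energy_drift`` measures its deviation
    from a full recompute.
    """

    def __init__(
        self,
        mesh: TriMesh,
        proteins: Sequence[Protein],
        eparams: EnergyParams,
        pparams: ProteinParams,
        mcparams: Optional[MCParams] = None,
        check: bool = True,
    ):
        self.mesh = mesh
        self.eparams = eparams
        self.pparams = pparams
        self.mcparams = mcparams or MCParams()
        self.rng = np.random.default_rng(self.mcparams.seed)
        if abs(eparams.theta_eq - pparams.theta_eq) > 1e-12:
            raise ValueError(
                "hinge equilibrium angle differs between EnergyParams and "
                "ProteinParams; they parametrise the same reference shape"
            )
        self.box = np.array([mesh.box_length], dtype=np.float64)
        self.L0 = float(mesh.box_length)
        self.sweeps_done = 0

        NP = len(proteins)
        self.pc = np.zeros((NP, 3))
        self.rot = np.zeros((NP, 3, 3))
        self.theta = np.zeros(NP)
        self.off = np.zeros((NP, 5, 3))
        self.bdir = np.zeros((NP, 5, 3))
        for i, p in enumerate(proteins):
            self.pc[i] = p.centre
            self.pc[i, 2] %= self.box[0]
            self.rot[i] = p.orientation
            self.theta[i] = p.wing_angle
        self._refresh_sphere_cache()

        half = eparams.band_width / 2.0
        self.band_frac = ((0.5 * self.L0 - half) / self.L0,
                          (0.5 * self.L0 + half) / self.L0)
        self.ep = self._pack_energy_params()
        self.mp = self._pack_move_params()
        self._init_cells()
        self.A_ref = (eparams.A_ref if eparams.A_ref is not None
                      else K.full_area(self.mesh.positions, self.mesh.triangles,
                                       self.box[0]))
        self.en = self._fresh_energy()
        if check:
            report = validate(mesh)
            if report:
                raise ValueError("invalid initial mesh: " + report[0])
            if not self._constraints_ok():
                raise ValueError("initial state has hard-core overlaps")

    # -- packing ----------------------------------------------------------

    def _pack_energy_params(self) -> np.ndarray:
        e, p = self.eparams, self.pparams
        return np.array([
            e.kappa, e.gamma, e.eps, np.cos(p.theta_pr), e.k_flex, e.theta_eq,
            e.k_cp, e.R_eq, self.band_frac[0], self.band_frac[1],
            e.r_cut(p), e.d_min(p), p.D_col, L_MIN, L_MAX, SIGMA_HC,
            p.R_pr, p.arc_step,
        ])

    def _pack_move_params(self) -> np.ndarray:
        m = self.mcparams
        cage = 2.0 * self.mesh.nominal_radius + 6.0
        return np.array([
            m.max_vertex_disp, m.max_protein_disp, m.max_rotation, m.max_wing,
            m.max_box_frac, m.box_min_frac * self.L0, m.box_max_frac * self.L0,
            cage,
        ])

    def _refresh_sphere_cache(self) -> None:
        for i in range(self.pc.shape[0]):
            off_l, bdir_l = local_geometry(self.pparams, self.theta[i])
            self.off[i] = off_l @ self.rot[i].T
            self.bdir[i] = bdir_l @ self.rot[i].T

    def _init_cells(self) -> None:
        R = self.mesh.nominal_radius
        W = 2.0 * R + 8.0
        cs = 1.0
        ncx = int(np.ceil(2 * W / cs))
        ncz_max = max(3, int(self.mcparams.box_max_frac * self.L0) + 1)
        ncz = max(3, int(self.box[0]))
        self.gf = np.array([-W, -W, cs, self.box[0] / ncz])
        self.gi = np.array([ncx, ncx, ncz], dtype=np.int64)
        V = self.mesh.n_vertices
        self.head = np.full(ncx * ncx * ncz_max, -1, dtype=np.int64)
        self.nxt = np.full(V, -1, dtype=np.int64)
        self.prv = np.full(V, -1, dtype=np.int64)
        self.bead_cell = np.full(V, -1, dtype=np.int64)
        K.build_cells(self.mesh.positions, self.box[0], self.gf, self.gi,
                      self.head, self.nxt, self.prv, self.bead_cell)

    # -- energies ---------------------------------------------------------

    def _fresh_energy(self) -> np.ndarray:
        m = self.mesh
        e = self.ep
        u_adh, ok = K.full_adhesion(m.positions, self.box[0], self.pc, self.off,
                                    self.bdir, e[2], e[3], e[10], e[11])
        if not ok:
            raise ValueError("sphere-bead hard-core overlap in state")
        u_flex = float(np.sum(0.5 * e[4] * (self.theta - e[5]) ** 2))
        return np.array([
            e[0] * K.full_bend(m.positions, m.triangles, m.edge_tri, self.box[0]),
            K.full_area(m.positions, m.triangles, self.box[0]),
            u_adh,
            u_flex,
            K.full_cp(m.positions, self.box[0], e[6], e[7], e[8], e[9]),
        ])

    def energy_breakdown(self) -> dict:
        en = self.en
        terms = {
            "U_bend": float(en[0]),
            "U_area": float(self.eparams.gamma * (en[1] - self.A_ref)),
            "U_adh": float(en[2]),
            "U_flex": float(en[3]),
            "U_cp": float(en[4]),
        }
        terms["U_tot"] = float(sum(terms.values()))
        return terms

    def total_energy(self) -> float:
        return self.energy_breakdown()["U_tot"]

    def energy_drift(self) -> float:
        """Max absolute deviation of the cached terms from a full recompute."""
        fresh = self._fresh_energy()
        return float(np.max(np.abs(fresh - self.en)))

    def _constraints_ok(self) -> bool:
        m = self.mesh
        if not K.check_tethers(m.positions, m.edges, self.box[0], L_MIN, L_MAX):
            return False
        if not K._cells_ok(m.positions, self.box[0], self.gf, self.gi,
                           self.head, self.nxt, self.bead_cell, SIGMA_HC):
            return False
        if not K.check_sphere_sphere(self.pc, self.off, self.pparams.D_col,
                                     self.box[0]):
            return False
        _, ok = K.full_adhesion(m.positions, self.box[0], self.pc, self.off,
                                self.bdir, self.ep[2], self.ep[3],
                                self.ep[10], self.ep[11])
        return bool(ok)

    # -- protein views ----------------------------------------------------

    @property
    def proteins(self) -> list[Protein]:
        return [
            Protein(centre=self.pc[i].copy(), orientation=self.rot[i].copy(),
                    wing_angle=float(self.theta[i]))
            for i in range(self.pc.shape[0])
        ]

    @property
    def sphere_positions(self) -> np.ndarray:
        """World positions of all protein spheres, shape (N, 5, 3)."""
        return self.pc[:, None, :] + self.off

    # -- moves ------------------------------------------------------------

    def _sweep_schedule(self):
        V = self.mesh.n_vertices
        NP = self.pc.shape[0]
        nf = int(round(V * self.mcparams.flips_per_vertex))
        counts = [V, nf, NP, NP, NP, self.mcparams.box_moves_per_sweep]
        kinds = np.repeat(np.arange(6), counts)
        self.rng.shuffle(kinds)
        M = kinds.shape[0]
        targets = np.zeros(M, dtype=np.int64)
        for k, n_items in ((0, V), (1, self.mesh.n_edges), (2, NP), (3, NP),
                           (4, NP)):
            sel = kinds == k
            if n_items > 0:
                targets[sel] = self.rng.integers(0, n_items, int(sel.sum()))
        u = self.rng.random((M, 4))
        return kinds.astype(np.int64), targets, u

    def sweep(self, n: int = 1) -> np.ndarray:
        """Run n sweeps; returns (6, 2) [attempts, accepts] per move kind."""
        acc = np.zeros((6, 2), dtype=np.int64)
        m = self.mesh
        for _ in range(n):
            kinds, targets, u = self._sweep_schedule()
            K.run_moves(
                m.positions, m.triangles, m.tri_edges, m.edges, m.edge_tri,
                m.v_tri, m.v_tri_n, self.box,
                self.pc, self.rot, self.theta, self.off, self.bdir,
                self.ep, self.mp,
                self.head, self.nxt, self.prv, self.bead_cell, self.gf, self.gi,
                kinds, targets, u,
                self.en, acc,
            )
            self.sweeps_done += 1
        m.box_length = float(self.box[0])
        return acc

    def tune_amplitudes(self, n_sweeps: int = 50, block: int = 10,
                        target: tuple[float, float] = (0.3, 0.5)) -> None:
        """Adjust move amplitudes toward 30-50% acceptance, then freeze.

        Tuning happens only during burn-in; production sweeps use frozen
        amplitudes so detailed balance is untouched.
        """
        caps = {0: (0.01, 0.49), 2: (0.02, 2.0), 3: (0.01, 1.5),
                4: (0.01, 1.0)}
        for _ in range(max(1, n_sweeps // block)):
            acc = self.sweep(block)
            for kind, slot in ((0, 0), (2, 1), (3, 2), (4, 3)):
                if acc[kind, 0] == 0:
                    continue
                frac = acc[kind, 1] / acc[kind, 0]
                lo, hi = caps[kind]
                if frac < target[0]:
                    self.mp[slot] = max(lo, self.mp[slot] * 0.8)
                elif frac > target[1]:
                    self.mp[slot] = min(hi, self.mp[slot] * 1.25)

    def resync_orientations(self) -> None:
        """Re-orthonormalise rotation matrices (kills float drift) and
        rebuild the sphere cache from the canonical (pc, rot, theta)."""
        for i in range(self.rot.shape[0]):
            u, _, vt = np.linalg.svd(self.rot[i])
            self.rot[i] = u @ vt
        self._refresh_sphere_cache()


@dataclass
class Snapshot:
    sweep: int
    positions: np.ndarray
    triangles: np.ndarray
    box_length: float
    protein_centres: np.ndarray
    protein_rotations: np.ndarray
    wing_angles: np.ndarray
    energies: dict


@dataclass
class Trajectory:
    """Snapshots plus provenance; reproducible from (config, seed)."""

    snapshots: list = field(default_factory=list)
    acceptance: list = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    @property
    def energy_trace(self) -> np.ndarray:
        return np.array([s.energies["U_tot"] for s in self.snapshots])

    def checksum(self) -> str:
        import hashlib

        h = hashlib.sha256()
        for s in self.snapshots:
            h.update(np.ascontiguousarray(s.positions).tobytes())
            h.update(np.ascontiguousarray(s.protein_centres).tobytes())
        return h.hexdigest()


def run(
    state: MCState,
    n_sweeps: int,
    callbacks: Sequence[Callable[[MCState, int], None]] = (),
    snapshot_stride: Optional[int] = None,
) -> Trajectory:
    """Run sweeps, capturing snapshots at the configured stride.

    An exception mid-run still leaves a valid truncated trajectory attached
    to the error (``err.trajectory``).
    """
    stride = snapshot_stride or state.mcparams.snapshot_stride
    traj = Trajectory(provenance={
        "seed": state.mcparams.seed,
        "n_sweeps": n_sweeps,
        "stride": stride,
        "eparams": vars(state.eparams).copy(),
        "pparams": {"R_pr": state.pparams.R_pr, "D_col": state.pparams.D_col,
                    "theta_pr": state.pparams.theta_pr,
                    "theta_eq": state.pparams.theta_eq},
    })

    def snap():
        m = state.mesh
        traj.snapshots.append(Snapshot(
            sweep=state.sweeps_done,
            positions=m.positions.copy(),
            triangles=m.triangles.copy(),
            box_length=float(state.box[0]),
            protein_centres=state.pc.copy(),
            protein_rotations=state.rot.copy(),
            wing_angles=state.theta.copy(),
            energies=state.energy_breakdown(),
        ))

    snap()
    try:
        done = 0
        while done < n_sweeps:
            block = min(stride, n_sweeps - done)
            acc = state.sweep(block)
            done += block
            traj.acceptance.append((state.sweeps_done, acc))
            snap()
            for cb in callbacks:
                cb(state, state.sweeps_done)
    except BaseException as err:  # truncated runs stay usable
        err.trajectory = traj
        raise
    return traj


def harmonic_toy_samples(k: float = 1.0, n_steps: int = 100_000,
                         amp: float = 1.5, seed: int = 0) -> np.ndarray:
    """Metropolis samples of a single bead in U = 1/2 k x^2 (closed form:
    Var[x] = kT/k). Validates the acceptance rule against the Boltzmann
    distribution."""
    rng = np.random.default_rng(seed)
    x = 0.0
    out = np.empty(n_steps)
    steps = rng.uniform(-amp, amp, n_steps)
    us = rng.random(n_steps)
    for i in range(n_steps):
        xn = x + steps[i]
        du = 0.5 * k * (xn * xn - x * x)
        if du <= 0 or us[i] < np.exp(-du):
            x = xn
        out[i] = x
    return out
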