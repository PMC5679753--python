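"""Triangulated membrane tube: construction, geometry, edge flips, validation.

The membrane is a closed triangulated surface of "beads" (vertices) wrapped
into a tube that is periodic along the z axis, so topologically it is a torus
(V - E + F = 0).  In-plane fluidity is modelled by bond (edge) flips; membrane
self-avoidance by a bead hard core of diameter ``sigma`` together with tether
bounds ``l_min < l < l_max`` on every edge.  All lengths are in units of the
bead diameter sigma.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

# Tether bounds and bead hard core, in units of the bead diameter sigma.
# Standard fluid-membrane choice: prevents the surface from crossing itself
# under flips while leaving room for near-equilateral triangles.
L_MIN = 1.0
L_MAX = float(np.sqrt(3.0))
SIGMA_HC = 1.0

MAX_DEGREE = 20  # capacity of the per-vertex incident-triangle table


@dataclass
class TriMesh:
    """Oriented triangle mesh of a periodic membrane tube.

    positions : (V, 3) float array, z is the periodic axis with period
        ``box_length``; x, y unbounded.
    triangles : (F, 3) int array, counter-clockwise seen from outside.
    Derived connectivity (edges, edge->triangle, triangle->edge, vertex->
    triangle) is built once and kept consistent by ``flip_edge``.
    """

    positions: np.ndarray
    triangles: np.ndarray
    box_length: float
    nominal_radius: float
    edges: np.ndarray = field(default=None, repr=False)          # (E, 2)
    edge_tri: np.ndarray = field(default=None, repr=False)       # (E, 2)
    tri_edges: np.ndarray = field(default=None, repr=False)      # (F, 3)
    v_tri: np.ndarray = field(default=None, repr=False)          # (V, MAX_DEGREE)
    v_tri_n: np.ndarray = field(default=None, repr=False)        # (V,)

    def __post_init__(self):
        self.positions = np.ascontiguousarray(self.positions, dtype=np.float64)
        self.triangles = np.ascontiguousarray(self.triangles, dtype=np.int64)
        if self.edges is None:
            self._build_connectivity()

    # -- connectivity -----------------------------------------------------

    def _build_connectivity(self) -> None:
        tris = self.triangles
        edge_ids: dict[tuple[int, int], int] = {}
        edges: list[tuple[int, int]] = []
        edge_tri: list[list[int]] = []
        tri_edges = np.empty_like(tris)
        for t, (a, b, c) in enumerate(tris):
            for k, (u, v) in enumerate(((a, b), (b, c), (c, a))):
                key = (min(u, v), max(u, v))
                if key not in edge_ids:
                    edge_ids[key] = len(edges)
                    edges.append(key)
                    edge_tri.append([-1, -1])
                e = edge_ids[key]
                tri_edges[t, k] = e
                slot = 0 if edge_tri[e][0] < 0 else 1
                if edge_tri[e][slot] >= 0:
                    raise ValueError(f"edge {key} shared by >2 triangles")
                edge_tri[e][slot] = t
        self.edges = np.asarray(edges, dtype=np.int64)
        self.edge_tri = np.asarray(edge_tri, dtype=np.int64)
        self.tri_edges = np.ascontiguousarray(tri_edges, dtype=np.int64)
        V = self.positions.shape[0]
        self.v_tri = np.full((V, MAX_DEGREE), -1, dtype=np.int64)
        self.v_tri_n = np.zeros(V, dtype=np.int64)
        for t, tri in enumerate(tris):
            for v in tri:
                n = self.v_tri_n[v]
                if n >= MAX_DEGREE:
                    raise ValueError(f"vertex {v} exceeds max degree {MAX_DEGREE}")
                self.v_tri[v, n] = t
                self.v_tri_n[v] += 1

    # -- basic counts -----------------------------------------------------

    @property
    def n_vertices(self) -> int:
        return self.positions.shape[0]

    @property
    def n_edges(self) -> int:
        return self.edges.shape[0]

    @property
    def n_triangles(self) -> int:
        return self.triangles.shape[0]

    def euler_characteristic(self) -> int:
        return self.n_vertices - self.n_edges + self.n_triangles

    # -- geometry helpers -------------------------------------------------

    def minimum_image(self, d: np.ndarray) -> np.ndarray:
        """Apply the minimum-image convention along z to displacement(s) d."""
        d = np.array(d, dtype=np.float64, copy=True)
        L = self.box_length
        d[..., 2] -= L * np.round(d[..., 2] / L)
        return d

    def triangle_vectors(self) -> tuple[np.ndarray, np.ndarray]:
        """Edge displacement vectors (p1-p0, p2-p0) per triangle, min-image."""
        p = self.positions
        t = self.triangles
        d1 = self.minimum_image(p[t[:, 1]] - p[t[:, 0]])
        d2 = self.minimum_image(p[t[:, 2]] - p[t[:, 0]])
        return d1, d2

    def triangle_normals(self) -> np.ndarray:
        """Outward unit normals of all triangles."""
        d1, d2 = self.triangle_vectors()
        n = np.cross(d1, d2)
        norms = np.linalg.norm(n, axis=1)
        if np.any(norms < 1e-12):
            raise ValueError("degenerate (zero-area) triangle")
        return n / norms[:, None]

    def edge_lengths(self) -> np.ndarray:
        p = self.positions
        d = self.minimum_image(p[self.edges[:, 1]] - p[self.edges[:, 0]])
        return np.linalg.norm(d, axis=1)

    def copy(self) -> "TriMesh":
        return TriMesh(
            positions=self.positions.copy(),
            triangles=self.triangles.copy(),
            box_length=self.box_length,
            nominal_radius=self.nominal_radius,
            edges=self.edges.copy(),
            edge_tri=self.edge_tri.copy(),
            tri_edges=self.tri_edges.copy(),
            v_tri=self.v_tri.copy(),
            v_tri_n=self.v_tri_n.copy(),
        )


def triangle_normal(mesh: TriMesh, t: int) -> np.ndarray:
    """Outward unit normal of triangle ``t`` (CCW winding seen from outside)."""
    if not 0 <= t < mesh.n_triangles:
        raise IndexError(f"triangle id {t} out of range")
    a, b, c = mesh.triangles[t]
    p = mesh.positions
    d1 = mesh.minimum_image(p[b] - p[a])
    d2 = mesh.minimum_image(p[c] - p[a])
    n = np.cross(d1, d2)
    norm = np.linalg.norm(n)
    if norm < 1e-12:
        raise ValueError(f"degenerate triangle {t}")
    return n / norm


def surface_area(mesh: TriMesh) -> float:
    """Total membrane area: sum of triangle areas with periodic wrap."""
    d1, d2 = mesh.triangle_vectors()
    return float(0.5 * np.linalg.norm(np.cross(d1, d2), axis=1).sum())


def build_cylinder(
    radius: float,
    length: float,
    target_edge: float = 1.35,
    seed: int = 0,
    jitter: float = 0.03,
) -> TriMesh:
    """Build a triangulated tube of given radius and axial period.

    Rings of equal vertex count with alternating half-step azimuthal offset
    (antiprism tiling) give a reproducible, near-equilateral triangulation.
    A small seeded jitter breaks the perfect symmetry.  Raises if the
    requested discretisation cannot satisfy the tether bounds.
    """
    if radius <= 0 or length <= 0:
        raise ValueError("radius and length must be positive")
    if not (L_MIN < target_edge < L_MAX):
        raise ValueError(f"target_edge must lie in ({L_MIN}, {L_MAX:.4f})")
    n_theta = int(round(2.0 * np.pi * radius / target_edge))
    if n_theta < 3:
        raise ValueError("fewer than 3 vertices per ring; increase radius")
    # near-equilateral ring spacing; the ring count must be even so that the
    # alternating offset closes across the periodic boundary
    n_z = int(round(length / (target_edge * np.sqrt(3.0) / 2.0)))
    n_z += n_z % 2
    if n_z < 4:
        raise ValueError("tube too short for a periodic triangulation")
    dz = length / n_z

    rng = np.random.default_rng(seed)
    V = n_theta * n_z
    pos = np.empty((V, 3))
    for k in range(n_z):
        off = 0.5 * (k % 2)
        phi = 2.0 * np.pi * (np.arange(n_theta) + off) / n_theta
        i0 = k * n_theta
        pos[i0 : i0 + n_theta, 0] = radius * np.cos(phi)
        pos[i0 : i0 + n_theta, 1] = radius * np.sin(phi)
        pos[i0 : i0 + n_theta, 2] = k * dz
    if jitter > 0:
        pos += rng.uniform(-jitter, jitter, size=pos.shape)
        pos[:, 2] %= length

    tris = []
    for k in range(n_z):
        k1 = (k + 1) % n_z
        for j in range(n_theta):
            j1 = (j + 1) % n_theta
            a = k * n_theta + j
            b = k * n_theta + j1
            c = k1 * n_theta + j
            d = k1 * n_theta + j1
            if k % 2 == 0:
                # next ring offset by +half step: apex above midpoint of (a,b)
                tris.append((a, b, c))
                tris.append((c, b, d))
            else:
                tris.append((a, b, d))
                tris.append((a, d, c))
    mesh = TriMesh(
        positions=pos,
        triangles=np.asarray(tris, dtype=np.int64),
        box_length=float(length),
        nominal_radius=float(radius),
    )
    report = validate(mesh)
    if report:
        raise ValueError(
            "generated cylinder violates mesh invariants: " + "; ".join(report[:5])
        )
    return mesh


def build_tube_with_profile(
    radius_fn,
    length: float,
    target_edge: float = 1.35,
    seed: int = 0,
    jitter: float = 0.02,
    nominal_radius: Optional[float] = None,
) -> TriMesh:
    """Build a periodic tube whose radius varies along z.

    ``radius_fn(z)`` gives the ring radius at axial position z; each ring
    carries round(2*pi*R/target_edge) beads so the bead density stays
    uniform through waists.  Consecutive rings are stitched by a two-pointer
    merge over ring angles (the standard triangulation between two convex
    polygon rings), which the edge-flip moves then relax.  Used for
    pre-constricted initial states and constructed test fixtures.
    """
    if length <= 0:
        raise ValueError("length must be positive")
    if not (L_MIN < target_edge < L_MAX):
        raise ValueError(f"target_edge must lie in ({L_MIN}, {L_MAX:.4f})")
    rng = np.random.default_rng(seed)
    # place rings at equal meridional arc length, so sloped waist regions
    # get proportionally more rings and no edge outgrows the tether bound
    zf = np.linspace(0.0, length, 4001)
    Rf = np.array([float(radius_fn(z)) for z in zf])
    dRdz = np.gradient(Rf, zf)
    ds = np.sqrt(1.0 + dRdz**2)
    s = np.concatenate([[0.0], np.cumsum(0.5 * (ds[1:] + ds[:-1])
                                         * np.diff(zf))])
    n_z = int(round(s[-1] / (target_edge * np.sqrt(3.0) / 2.0)))
    if n_z < 4:
        raise ValueError("tube too short for a periodic triangulation")
    ring_z = np.interp(np.arange(n_z) * s[-1] / n_z, s, zf)

    ring_start: list[int] = []
    ring_sizes: list[int] = []
    ring_angles: list[np.ndarray] = []
    pos_chunks = []
    offset = 0.0
    count = 0
    for k in range(n_z):
        z = float(ring_z[k])
        R = float(radius_fn(z))
        if R <= 0:
            raise ValueError(f"radius_fn({z}) = {R} not positive")
        n_k = max(3, int(round(2.0 * np.pi * R / target_edge)))
        phi = (2.0 * np.pi * np.arange(n_k) / n_k + offset) % (2.0 * np.pi)
        order = np.argsort(phi)
        phi = phi[order]
        chunk = np.column_stack([
            R * np.cos(phi), R * np.sin(phi), np.full(n_k, z)
        ])
        ring_start.append(count)
        ring_sizes.append(n_k)
        ring_angles.append(phi)
        pos_chunks.append(chunk)
        count += n_k
        offset += np.pi / n_k  # stagger successive rings by half a step

    pos = np.vstack(pos_chunks)
    if jitter > 0:
        pos += rng.uniform(-jitter, jitter, size=pos.shape)
        pos[:, 2] %= length

    tris: list[tuple[int, int, int]] = []
    for k in range(n_z):
        k1 = (k + 1) % n_z
        nb, nt = ring_sizes[k], ring_sizes[k1]
        ab, at = ring_angles[k], ring_angles[k1]
        sb, st_ = ring_start[k], ring_start[k1]
        j0 = int(np.argmin((at - ab[0]) % (2.0 * np.pi)))
        # unwrapped angular ladders starting at the bottom ring's vertex 0
        A = np.empty(nb + 1)
        A[:nb] = (ab - ab[0]) % (2.0 * np.pi)
        A[0] = 0.0
        A[nb] = 2.0 * np.pi
        T = np.empty(nt + 1)
        for j in range(nt):
            T[j] = (at[(j0 + j) % nt] - ab[0]) % (2.0 * np.pi)
        T[1:nt] = np.maximum.accumulate(T[1:nt])
        T[nt] = T[0] + 2.0 * np.pi
        i = j = 0
        while i < nb or j < nt:
            bi = sb + i % nb
            bi1 = sb + (i + 1) % nb
            tj = st_ + (j0 + j) % nt
            tj1 = st_ + (j0 + j + 1) % nt
            adv_bottom = i < nb and (j >= nt or A[i + 1] <= T[j + 1])
            if adv_bottom:
                tris.append((bi, bi1, tj))
                i += 1
            else:
                tris.append((tj, bi, tj1))
                j += 1

    mesh = TriMesh(
        positions=pos,
        triangles=np.asarray(tris, dtype=np.int64),
        box_length=float(length),
        nominal_radius=float(nominal_radius if nominal_radius is not None
                             else radius_fn(0.0)),
    )
    report = validate(mesh)
    if report:
        raise ValueError(
            "profiled tube violates mesh invariants: " + "; ".join(report[:5])
        )
    return mesh


def build_preconstricted(
    radius: float,
    length: float,
    neck_radius: float = 3.0,
    neck_width: float = 8.0,
    target_edge: float = 1.25,
    seed: int = 0,
) -> TriMesh:
    """Tube with a smooth cosine waist of radius ``neck_radius`` at L/2.

    ``neck_width`` is the half-width of the waist region; outside
    |z - L/2| > neck_width the tube has the nominal radius.  A few nearby
    edge targets and jitter seeds are tried because the stitched rings can
    land marginally outside the tether bounds for unlucky combinations.
    """
    mid = length / 2.0

    def profile(z: float) -> float:
        d = abs(z - mid)
        if d >= neck_width:
            return radius
        return neck_radius + (radius - neck_radius) * 0.5 * (
            1.0 - np.cos(np.pi * d / neck_width)
        )

    last_err: Exception | None = None
    for te in (target_edge, target_edge - 0.03, target_edge + 0.03,
               target_edge - 0.06):
        for s in (seed, seed + 9973):
            try:
                return build_tube_with_profile(profile, length, te, s,
                                               nominal_radius=radius)
            except ValueError as err:
                last_err = err
    raise ValueError(f"could not build a valid pre-constricted tube: {last_err}")


def flip_edge(mesh: TriMesh, e: int, in_place: bool = False) -> Optional[TriMesh]:
    """Replace the shared edge of two triangles by the opposite diagonal.

    Returns the flipped mesh, or ``None`` as a rejection signal when the flip
    is infeasible (duplicate edge, tether violation, or a vertex degree that
    would fall below 3).  V, E, F and all vertex positions are unchanged.
    """
    if not 0 <= e < mesh.n_edges:
        raise IndexError(f"edge id {e} out of range")
    t1, t2 = mesh.edge_tri[e]
    u, v = mesh.edges[e]
    tri1 = mesh.triangles[t1]
    tri2 = mesh.triangles[t2]
    # orient: a->b traversed by t1, b->a by t2
    for k in range(3):
        if tri1[k] == u and tri1[(k + 1) % 3] == v:
            a, b = u, v
            break
        if tri1[k] == v and tri1[(k + 1) % 3] == u:
            a, b = v, u
            break
    else:  # pragma: no cover - connectivity corruption
        raise RuntimeError("edge not found in its incident triangle")
    c = int([x for x in tri1 if x != a and x != b][0])
    d = int([x for x in tri2 if x != a and x != b][0])
    if c == d:
        return None
    # duplicate edge: c and d already share a triangle
    for t in mesh.v_tri[c, : mesh.v_tri_n[c]]:
        if d in mesh.triangles[t]:
            return None
    # degree of a and b must stay >= 3
    if mesh.v_tri_n[a] <= 3 or mesh.v_tri_n[b] <= 3:
        return None
    # tether bound on the new diagonal
    lcd = np.linalg.norm(mesh.minimum_image(mesh.positions[d] - mesh.positions[c]))
    if not (L_MIN < lcd < L_MAX):
        return None

    out = mesh if in_place else mesh.copy()
    # locate the four boundary edges
    def _edge_between(t, x, y):
        for k in range(3):
            p, q = out.triangles[t][k], out.triangles[t][(k + 1) % 3]
            if (p == x and q == y) or (p == y and q == x):
                return out.tri_edges[t][k]
        raise RuntimeError("boundary edge not found")

    e_ca = _edge_between(t1, c, a)
    e_bc = _edge_between(t1, b, c)
    e_ad = _edge_between(t2, a, d)
    e_db = _edge_between(t2, d, b)

    out.triangles[t1] = (c, a, d)
    out.tri_edges[t1] = (e_ca, e_ad, e)
    out.triangles[t2] = (d, b, c)
    out.tri_edges[t2] = (e_db, e_bc, e)
    out.edges[e] = (min(c, d), max(c, d))
    # boundary edges change triangle incidence: e_ad t2->t1, e_bc t1->t2
    for eid, old, new in ((e_ad, t2, t1), (e_bc, t1, t2)):
        s = 0 if out.edge_tri[eid, 0] == old else 1
        out.edge_tri[eid, s] = new
    # vertex->triangle tables: a loses t2, b loses t1, c gains t2, d gains t1
    for vtx, lost in ((a, t2), (b, t1)):
        n = out.v_tri_n[vtx]
        row = out.v_tri[vtx]
        for k in range(n):
            if row[k] == lost:
                row[k] = row[n - 1]
                row[n - 1] = -1
                break
        out.v_tri_n[vtx] = n - 1
    for vtx, gained in ((c, t2), (d, t1)):
        n = out.v_tri_n[vtx]
        if n >= MAX_DEGREE:
            raise RuntimeError(f"vertex {vtx} exceeds max degree")
        out.v_tri[vtx, n] = gained
        out.v_tri_n[vtx] = n + 1
    return out


def validate(mesh: TriMesh) -> list[str]:
    """Check every mesh invariant; return a list of violations (empty = valid)."""
    report: list[str] = []
    V, E, F = mesh.n_vertices, mesh.n_edges, mesh.n_triangles
    if V - E + F != 0:
        report.append(f"Euler characteristic V-E+F = {V - E + F}, expected 0 (torus)")
    # each edge shared by exactly two triangles
    bad = np.where((mesh.edge_tri < 0).any(axis=1))[0]
    for e in bad[:10]:
        report.append(f"edge {e} not shared by exactly 2 triangles")
    # orientation consistency: every directed edge appears exactly once
    directed = set()
    for tri in mesh.triangles:
        for k in range(3):
            de = (int(tri[k]), int(tri[(k + 1) % 3]))
            if de in directed:
                report.append(f"directed edge {de} duplicated (orientation)")
            directed.add(de)
    for u, v in directed:
        if (v, u) not in directed:
            report.append(f"directed edge {(u, v)} lacks its opposite (orientation)")
            break
    # tether bounds
    ls = mesh.edge_lengths()
    for e in np.where((ls <= L_MIN) | (ls >= L_MAX))[0][:10]:
        report.append(
            f"edge {e} length {ls[e]:.4f} outside tether bounds "
            f"({L_MIN}, {L_MAX:.4f})"
        )
    # vertex degree >= 3
    for v in np.where(mesh.v_tri_n < 3)[0][:10]:
        report.append(f"vertex {v} has degree {mesh.v_tri_n[v]} < 3")
    # bead hard core between non-bonded beads (cell-binned to stay O(V))
    bonded = {tuple(sorted(e)) for e in mesh.edges.tolist()}
    p = mesh.positions
    L = mesh.box_length
    nzc = max(1, int(L // SIGMA_HC))  # z cell width = L/nzc >= hard core
    wz = L / nzc
    cell = {}
    for i in range(V):
        key = (int(np.floor(p[i, 0] / SIGMA_HC)), int(np.floor(p[i, 1] / SIGMA_HC)),
               min(int((p[i, 2] % L) / wz), nzc - 1))
        cell.setdefault(key, []).append(i)
    reported = 0
    for (cx, cy, cz), members in cell.items():
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dzc in (-1, 0, 1):
                    other = cell.get((cx + dx, cy + dy, (cz + dzc) % nzc))
                    if not other:
                        continue
                    for i in members:
                        for j in other:
                            if j <= i or (i, j) in bonded:
                                continue
                            d = mesh.minimum_image(p[j] - p[i])
                            if np.dot(d, d) < SIGMA_HC**2 and reported < 10:
                                report.append(
                                    f"beads {i},{j} closer than hard core"
                                )
                                reported += 1
    return report
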