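"""2D finite-element forward problem and sensitivity Jacobian.

The tank is modelled as a unit disk Omega with an isotropic, real-valued
conductivity field sigma (quasi-static regime: magnetic and capacitive
effects neglected).  The governing equation is the conservation law

    div( sigma grad u ) = 0  in Omega,

with current I injected at the boundary node of electrode a and withdrawn
at electrode b (point-electrode model) and zero current elsewhere.  The
pure Neumann problem fixes the potential only up to a constant; solutions
are reported with zero mean over all nodes, which cancels in the
differential measurements v = phi(m) - phi(n).

Discretization uses linear (P1) triangular elements on a structured disk
mesh built from concentric rings: ring i of R carries L*i equally spaced
nodes, which makes every triangle area identical up to curvature effects
(area coefficient of variation < 2%), places a boundary node exactly at
every electrode angle, and leaves the mesh invariant under rotation by
2*pi/L -- so the rotational symmetry of the ideal tank is inherited by
the discrete model to solver precision.

The measurement sensitivity to per-element conductivity is computed by the
adjoint method: with u_d the drive field of (a, b) and u_m the field of a
unit current driven through the sensing pair (m, n),

    d v / d sigma_e = - integral_e grad u_d . grad u_m dA,

which for P1 elements is a single constant-gradient dot product per
element.  For a homogeneous disk the boundary potential has the closed
form (2D point-source logarithmic kernel)

    u(theta) = (I / (pi sigma)) [ ln 2|sin((theta - theta_b)/2)|
                                 - ln 2|sin((theta - theta_a)/2)| ] + const,

used as the mesh-convergence oracle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .configs import ConfigSet, ElectrodeRing, Quadruple

__all__ = [
    "TriMesh",
    "ConductivityField",
    "ForwardSolution",
    "Jacobian",
    "build_disk_mesh",
    "ForwardSolver",
    "solve_forward",
    "assemble_measurements",
    "compute_jacobian",
    "disk_boundary_potential",
    "analytic_measurements",
]

DEFAULT_CURRENT = 1e-4  # 100 uA drive, the device's rated excitation current
DEFAULT_BACKGROUND = 1.0  # arbitrary background conductivity sigma0 in S/m


@dataclass(frozen=True)
class TriMesh:
    """P1 triangulation of the disk with ring electrodes on the boundary."""

    node_coords: np.ndarray  # (n_nodes, 2)
    triangles: np.ndarray  # (n_elements, 3), positively oriented
    electrode_nodes: np.ndarray  # (L,) node index of each electrode, e1 first
    boundary_nodes: np.ndarray  # node indices on the outer ring
    radius: float = 1.0

    def __post_init__(self) -> None:
        if np.any(self.signed_areas() <= 0):
            raise ValueError("triangles must be positively oriented")

    @property
    def n_nodes(self) -> int:
        return self.node_coords.shape[0]

    @property
    def n_elements(self) -> int:
        return self.triangles.shape[0]

    @property
    def L(self) -> int:
        return self.electrode_nodes.size

    def signed_areas(self) -> np.ndarray:
        a, b, c = (self.node_coords[self.triangles[:, k]] for k in range(3))
        return 0.5 * ((b[:, 0] - a[:, 0]) * (c[:, 1] - a[:, 1]) - (c[:, 0] - a[:, 0]) * (b[:, 1] - a[:, 1]))

    def areas(self) -> np.ndarray:
        return self.signed_areas()

    def centroids(self) -> np.ndarray:
        return self.node_coords[self.triangles].mean(axis=1)

    def p1_gradients(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-element gradients of the three P1 basis functions.

        Returns (gx, gy), each (n_elements, 3); the gradient of the field
        u on element e is (sum_k gx[e,k] u[tri[e,k]], sum_k gy[e,k] ...).
        """
        a, b, c = (self.node_coords[self.triangles[:, k]] for k in range(3))
        det = 2.0 * self.signed_areas()
        gx = np.stack([b[:, 1] - c[:, 1], c[:, 1] - a[:, 1], a[:, 1] - b[:, 1]], axis=1) / det[:, None]
        gy = np.stack([c[:, 0] - b[:, 0], a[:, 0] - c[:, 0], b[:, 0] - a[:, 0]], axis=1) / det[:, None]
        return gx, gy

    def vertex_incidence(self) -> sp.csr_matrix:
        """Sparse (n_nodes x n_elements) 0/1 matrix: node k touches element e."""
        ne = self.n_elements
        rows = self.triangles.ravel()
        cols = np.repeat(np.arange(ne), 3)
        return sp.csr_matrix(
            (np.ones(rows.size), (rows, cols)), shape=(self.n_nodes, ne)
        )

    def element_adjacency(self) -> sp.csr_matrix:
        """Sparse symmetric adjacency of elements sharing an edge."""
        edges = {}
        pairs_r, pairs_c = [], []
        for e, tri in enumerate(self.triangles):
            for k in range(3):
                key = tuple(sorted((tri[k], tri[(k + 1) % 3])))
                if key in edges:
                    pairs_r.append(edges[key])
                    pairs_c.append(e)
                else:
                    edges[key] = e
        r = np.array(pairs_r + pairs_c, dtype=np.int64)
        c = np.array(pairs_c + pairs_r, dtype=np.int64)
        ne = self.n_elements
        return sp.csr_matrix((np.ones(r.size), (r, c)), shape=(ne, ne))


@dataclass(frozen=True)
class ConductivityField:
    """Per-element conductivity sigma in S/m (all values > 0)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if np.any(v <= 0) or not np.all(np.isfinite(v)):
            raise ValueError("conductivity values must be positive and finite")
        object.__setattr__(self, "values", v)

    @classmethod
    def homogeneous(cls, mesh: TriMesh, sigma: float = DEFAULT_BACKGROUND) -> "ConductivityField":
        return cls(np.full(mesh.n_elements, float(sigma)))


@dataclass
class ForwardSolution:
    """Potentials for one excitation pair under a given conductivity."""

    node_potentials: np.ndarray
    electrode_potentials: np.ndarray
    injected_current: float
    quadruple: Quadruple | None = None

    @property
    def measurement(self) -> float:
        """Differential sensing value phi(m) - phi(n) of the quadruple."""
        if self.quadruple is None:
            raise ValueError("no quadruple attached to this solution")
        return float(
            self.electrode_potentials[self.quadruple.m - 1]
            - self.electrode_potentials[self.quadruple.n - 1]
        )


@dataclass
class Jacobian:
    """Sensitivity matrix J[r, e] = d v_r / d sigma_e at the background."""

    matrix: np.ndarray  # (n_configs, n_elements)
    configs: ConfigSet
    background: ConductivityField
    current: float

    def __post_init__(self) -> None:
        if self.matrix.shape[0] != len(self.configs):
            raise ValueError("Jacobian row count must match the configuration set")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("Jacobian contains non-finite entries")


def build_disk_mesh(
    radius: float = 1.0,
    target_elements: int = 12_000,
    ring: ElectrodeRing | None = None,
) -> TriMesh:
    """Structured quasi-uniform triangulation of the disk.

    Concentric ring i (of R rings) at radius i*R_disk/R carries L*i nodes,
    plus a center node, giving exactly L*R^2 elements with R chosen as the
    smallest ring count reaching ``target_elements``.  Every electrode
    angle coincides with an outer-ring node, and the construction is fully
    deterministic.
    """
    if ring is None:
        ring = ElectrodeRing(L=16, radius=radius)
    L = ring.L
    if L < 8:
        raise ValueError("need at least 8 electrodes")
    if target_elements < 64:
        raise ValueError("target_elements must be >= 64")
    R = max(2, int(np.ceil(np.sqrt(target_elements / L))))

    nodes = [(0.0, 0.0)]
    ring_start = [0] * (R + 1)
    for i in range(1, R + 1):
        ring_start[i] = len(nodes)
        n_i = L * i
        th = 2.0 * np.pi * np.arange(n_i) / n_i
        r = radius * i / R
        nodes.extend(zip(r * np.cos(th), r * np.sin(th)))
    coords = np.array(nodes)

    tris: list[tuple[int, int, int]] = []
    s1 = ring_start[1]
    for k in range(L):
        tris.append((0, s1 + k, s1 + (k + 1) % L))
    for i in range(2, R + 1):
        ni, no = L * (i - 1), L * i
        si, so = ring_start[i - 1], ring_start[i]
        ai = 2.0 * np.pi * np.arange(ni + 1) / ni
        ao = 2.0 * np.pi * np.arange(no + 1) / no
        p = q = 0
        # merge the two angular sequences into a triangle strip; ties
        # advance the outer ring first (deterministic, rotation-periodic)
        while p < ni or q < no:
            if p >= ni or (q < no and ao[q + 1] <= ai[p + 1] + 1e-15):
                tris.append((so + q % no, so + (q + 1) % no, si + p % ni))
                q += 1
            else:
                tris.append((si + (p + 1) % ni, si + p % ni, so + q % no))
                p += 1
    triangles = np.array(tris, dtype=np.int64)
    a, b, c = (coords[triangles[:, k]] for k in range(3))
    det = (b[:, 0] - a[:, 0]) * (c[:, 1] - a[:, 1]) - (c[:, 0] - a[:, 0]) * (b[:, 1] - a[:, 1])
    flip = det < 0
    triangles[flip] = triangles[flip][:, [0, 2, 1]]

    so = ring_start[R]
    electrode_nodes = so + np.arange(L) * R
    boundary_nodes = so + np.arange(L * R)
    return TriMesh(
        node_coords=coords,
        triangles=triangles,
        electrode_nodes=electrode_nodes,
        boundary_nodes=boundary_nodes,
        radius=radius,
    )


class ForwardSolver:
    """Assembled and factorized forward operator for one (mesh, sigma).

    The stiffness matrix K[i,j] = sum_e sigma_e integral_e grad phi_i .
    grad phi_j dA is factorized once (sparse LU with one interior node
    grounded to remove the Neumann null space) and reused across all
    excitation right-hand sides; results are re-referenced to zero mean.
    """

    def __init__(self, mesh: TriMesh, sigma: ConductivityField):
        if sigma.values.size != mesh.n_elements:
            raise ValueError("conductivity length must equal the element count")
        self.mesh = mesh
        self.sigma = sigma
        area = mesh.areas()
        gx, gy = mesh.p1_gradients()
        self._area, self._gx, self._gy = area, gx, gy
        w = sigma.values * area
        rows, cols, vals = [], [], []
        for i in range(3):
            for j in range(3):
                rows.append(mesh.triangles[:, i])
                cols.append(mesh.triangles[:, j])
                vals.append(w * (gx[:, i] * gx[:, j] + gy[:, i] * gy[:, j]))
        K = sp.coo_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(mesh.n_nodes, mesh.n_nodes),
        ).tocsr()
        self.stiffness = K
        # ground the center node (node 0, never an electrode) to make the
        # system nonsingular; the zero-mean reference is applied afterwards
        Kg = K.tolil()
        Kg[0, :] = 0.0
        Kg[:, 0] = 0.0
        Kg[0, 0] = 1.0
        try:
            self._lu = spla.factorized(Kg.tocsc())
        except RuntimeError as exc:  # pragma: no cover - singular mesh
            raise RuntimeError(f"forward system could not be factorized: {exc}") from exc
        self._pair_cache: dict[tuple[int, int, float], np.ndarray] = {}

    def rhs_for_pair(self, a: int, b: int, current: float) -> np.ndarray:
        """Nodal current vector: +I at electrode a, -I at b (1-based)."""
        rhs = np.zeros(self.mesh.n_nodes)
        rhs[self.mesh.electrode_nodes[a - 1]] = current
        rhs[self.mesh.electrode_nodes[b - 1]] = -current
        return rhs

    def solve_pair(self, a: int, b: int, current: float = DEFAULT_CURRENT) -> np.ndarray:
        """Zero-mean nodal potentials for current driven from a to b."""
        key = (a, b, current)
        if key not in self._pair_cache:
            u = self._lu(self.rhs_for_pair(a, b, current))
            self._pair_cache[key] = u - u.mean()
        return self._pair_cache[key]

    def solve(self, q: Quadruple, current: float = DEFAULT_CURRENT) -> ForwardSolution:
        q.validate(self.mesh.L)
        u = self.solve_pair(q.a, q.b, current)
        return ForwardSolution(
            node_potentials=u,
            electrode_potentials=u[self.mesh.electrode_nodes],
            injected_current=current,
            quadruple=q,
        )

    def measure(self, cfg: ConfigSet, current: float = DEFAULT_CURRENT) -> np.ndarray:
        """Differential measurement vector over ``cfg``, one scalar per row."""
        en = self.mesh.electrode_nodes
        out = np.empty(len(cfg))
        for r, q in enumerate(cfg):
            u = self.solve_pair(q.a, q.b, current)
            out[r] = u[en[q.m - 1]] - u[en[q.n - 1]]
        return out


def solve_forward(
    mesh: TriMesh,
    sigma: ConductivityField,
    q: Quadruple,
    current: float = DEFAULT_CURRENT,
) -> ForwardSolution:
    """One-shot forward solve for a single quadruple."""
    return ForwardSolver(mesh, sigma).solve(q, current)


def assemble_measurements(
    mesh: TriMesh,
    sigma: ConductivityField,
    cfg: ConfigSet,
    current: float = DEFAULT_CURRENT,
) -> np.ndarray:
    """Measurement vector v (length N) over ``cfg``, sharing one
    factorization and per-pair solves across quadruples."""
    return ForwardSolver(mesh, sigma).measure(cfg, current)


def compute_jacobian(
    mesh: TriMesh,
    sigma0: ConductivityField,
    cfg: ConfigSet,
    current: float = DEFAULT_CURRENT,
) -> Jacobian:
    """Adjoint sensitivity J[r, e] = d v_r / d sigma_e at sigma0.

    Needs one forward solve per distinct drive pair (at the drive current)
    and one per distinct sensing pair (at unit current); each row is then
    the elementwise product of the two constant P1 gradients integrated
    over every element.
    """
    solver = ForwardSolver(mesh, sigma0)
    area = mesh.areas()
    gx, gy = mesh.p1_gradients()
    tri = mesh.triangles

    def elem_grad(u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        un = u[tri]
        return (gx * un).sum(axis=1), (gy * un).sum(axis=1)

    drive: dict[tuple[int, int], tuple[np.ndarray, np.ndarray]] = {}
    meas: dict[tuple[int, int], tuple[np.ndarray, np.ndarray]] = {}
    J = np.empty((len(cfg), mesh.n_elements))
    for r, q in enumerate(cfg):
        dk, mk = (q.a, q.b), (q.m, q.n)
        if dk not in drive:
            drive[dk] = elem_grad(solver.solve_pair(q.a, q.b, current))
        if mk not in meas:
            meas[mk] = elem_grad(solver.solve_pair(q.m, q.n, 1.0))
        (dx, dy), (mx, my) = drive[dk], meas[mk]
        J[r] = -area * (dx * mx + dy * my)
    return Jacobian(matrix=J, configs=cfg, background=sigma0, current=current)


def disk_boundary_potential(
    theta,
    theta_a: float,
    theta_b: float,
    sigma: float = DEFAULT_BACKGROUND,
    current: float = DEFAULT_CURRENT,
):
    """Analytic boundary potential of the homogeneous disk.

    Point current ``current`` enters at boundary angle theta_a and leaves
    at theta_b; the boundary trace (up to an additive constant, and
    independent of the disk radius) is

        u(theta) = (I/(pi sigma)) [ ln 2|sin((theta-theta_b)/2)|
                                   - ln 2|sin((theta-theta_a)/2)| ].
    """
    th = np.asarray(theta, dtype=float)
    val = (current / (np.pi * sigma)) * (
        np.log(2.0 * np.abs(np.sin((th - theta_b) / 2.0)))
        - np.log(2.0 * np.abs(np.sin((th - theta_a) / 2.0)))
    )
    return float(val) if np.isscalar(theta) else val


def analytic_measurements(
    cfg: ConfigSet,
    ring: ElectrodeRing | None = None,
    sigma: float = DEFAULT_BACKGROUND,
    current: float = DEFAULT_CURRENT,
) -> np.ndarray:
    """Closed-form homogeneous-disk measurement vector over ``cfg``."""
    if ring is None:
        ring = ElectrodeRing(L=cfg.L)
    out = np.empty(len(cfg))
    for r, q in enumerate(cfg):
        ta, tb = ring.angle_of(q.a), ring.angle_of(q.b)
        out[r] = disk_boundary_potential(
            ring.angle_of(q.m), ta, tb, sigma, current
        ) - disk_boundary_potential(ring.angle_of(q.n), ta, tb, sigma, current)
    return out
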