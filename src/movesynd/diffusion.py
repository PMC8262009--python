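"""Finite-element discretization of the heterogeneous-space diffusion model.

The movement model is a diffusion with habitat-specific diffusion rate D^h
(m^2/day), habitat preference k^h (unitless, forest k^1 = 1), and a constant
mortality rate m (1/day).  Habitat preference acts through the transformed
variable u = p / k, which is continuous across habitat edges while the
probability density p itself jumps by the preference ratio, so that the
stationary density is proportional to k^h.  Weak form, for P1 test
functions phi:

    d/dt  int k u phi  =  - int D k grad(u) . grad(phi)  -  m int k u phi

with a reflecting (zero-flux) outer boundary.  Mass is lumped, which makes
the spatial generator of the probability mass vector

    dw/dt = G w,      G = -K M^{-1},

a proper continuous-time Markov chain generator on mesh vertices whenever
the stiffness matrix K has nonpositive off-diagonals (guaranteed on the
right-triangle meshes produced by the grid mesher).  Mortality is spatially
constant, so it factors out of the dynamics exactly: live mass decays by
exp(-m t) regardless of the spatial discretization.

Time propagation offers three methods:

``exact``
    dense eigendecomposition of the symmetrized generator; this *is* the
    CTMC transition kernel, so the track simulator and the likelihood agree
    exactly.  Default for the mesh sizes used here.
``implicit``
    lumped-mass backward Euler substeps; unconditionally stable and
    positivity-preserving, for large sparse meshes.
``cn``
    Crank-Nicolson substeps, second order, for accuracy checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from scipy.sparse.linalg import splu

from .landscape import FOREST, MATRIX, OPEN, Mesh

HABITATS = (FOREST, MATRIX, OPEN)


class MeshOperatorError(ValueError):
    """Raised for meshes unusable by the FE scheme (degenerate, disconnected)."""


@dataclass
class DiffusionParams:
    """Movement parameters of one individual on the natural scale.

    ``D`` maps habitat class -> diffusion rate (m^2/day), ``k`` maps habitat
    class -> preference (k[forest] must be exactly 1), ``m`` is the
    mortality rate (1/day; here dominated by transmitter battery death).
    """

    D: dict[int, float]
    k: dict[int, float]
    m: float = 0.0

    def __post_init__(self):
        for h in HABITATS:
            if self.D.get(h, 0.0) <= 0:
                raise ValueError(f"D[{h}] must be positive")
            if self.k.get(h, 0.0) <= 0:
                raise ValueError(f"k[{h}] must be positive")
        if self.k[FOREST] != 1.0:
            raise ValueError("k[forest] is the reference habitat and must equal 1")
        if self.m < 0:
            raise ValueError("mortality must be nonnegative")


# ---------------------------------------------------------------------------
# assembly


@dataclass
class UnitOperators:
    """Per-habitat unit stiffness matrices and lumped area vectors.

    ``K[h]`` is the P1 stiffness assembled over triangles of habitat h with
    unit coefficient; ``a[h]`` the lumped (area/3 per corner) mass vector.
    Parameter-dependent operators are linear combinations of these, so the
    expensive assembly is done once per mesh.
    """

    K: dict[int, sp.csr_matrix]
    a: dict[int, np.ndarray]
    n: int
    K_dense: np.ndarray | None = None
    a_dense: np.ndarray | None = None

    @classmethod
    def from_mesh(cls, mesh: Mesh) -> "UnitOperators":
        n = mesh.n_vertices
        rows: dict[int, list] = {h: [] for h in HABITATS}
        cols: dict[int, list] = {h: [] for h in HABITATS}
        vals: dict[int, list] = {h: [] for h in HABITATS}
        a = {h: np.zeros(n) for h in HABITATS}
        verts, tris = mesh.vertices, mesh.triangles
        for t in range(mesh.n_triangles):
            i, j, k = tris[t]
            h = int(mesh.habitat[t])
            area = mesh.areas[t]
            if area <= 0:
                raise MeshOperatorError(f"triangle {t} has nonpositive area")
            p = verts[[i, j, k]]
            # P1 gradient vectors: grad(phi_a) = rot(edge opposite a) / (2A)
            b = np.array([p[1, 1] - p[2, 1], p[2, 1] - p[0, 1], p[0, 1] - p[1, 1]])
            c = np.array([p[2, 0] - p[1, 0], p[0, 0] - p[2, 0], p[1, 0] - p[0, 0]])
            ke = (np.outer(b, b) + np.outer(c, c)) / (4.0 * area)
            idx = (i, j, k)
            for aa in range(3):
                a[h][idx[aa]] += area / 3.0
                for bb in range(3):
                    rows[h].append(idx[aa])
                    cols[h].append(idx[bb])
                    vals[h].append(ke[aa, bb])
        K = {
            h: sp.csr_matrix((vals[h], (rows[h], cols[h])), shape=(n, n))
            for h in HABITATS
        }
        ops = cls(K=K, a=a, n=n)
        if n <= 2500:  # dense fast path for the propagator
            ops.K_dense = np.stack([K[h].toarray() for h in HABITATS])
            ops.a_dense = np.stack([a[h] for h in HABITATS])
        return ops


_unit_cache: dict[int, tuple] = {}


def unit_operators(mesh: Mesh) -> UnitOperators:
    """Memoized per-mesh unit operators (keyed on object identity)."""
    key = id(mesh)
    hit = _unit_cache.get(key)
    if hit is not None and hit[0] is mesh:
        return hit[1]
    ops = UnitOperators.from_mesh(mesh)
    _unit_cache.clear()  # keep a single entry; meshes are long-lived per run
    _unit_cache[key] = (mesh, ops)
    return ops


def assemble_operators(mesh: Mesh, params: DiffusionParams):
    """Lumped mass vector M (diagonal) and stiffness K for given parameters.

    M_vv = sum_h k^h a^h_v ;  K = sum_h D^h k^h K^h.  The stiffness has zero
    row sums (reflecting boundary) and, on right-triangle meshes,
    nonpositive off-diagonals.
    """
    ops = unit_operators(mesh)
    M = np.zeros(ops.n)
    K = None
    for h in HABITATS:
        M += params.k[h] * ops.a[h]
        term = (params.D[h] * params.k[h]) * ops.K[h]
        K = term if K is None else K + term
    return M, K.tocsr()


def generator_rates(mesh: Mesh, params: DiffusionParams):
    """CTMC jump rates on mesh vertices: rate(v -> u) = max(-K_uv, 0)/M_vv.

    Returns ``(rates, M)`` where ``rates`` is a CSC matrix with column v
    holding the outflow rates of vertex v.  Negative off-diagonal stiffness
    entries (obtuse triangles) are clipped to zero; the grid mesher never
    produces them, but the guard keeps the generator a valid Q-matrix.
    """
    M, K = assemble_operators(mesh, params)
    R = (-K).tocsc(copy=True)
    R.setdiag(0.0)
    R.data = np.maximum(R.data, 0.0)
    R.eliminate_zeros()
    R = R @ sp.diags(1.0 / M)
    return R.tocsc(), M


# ---------------------------------------------------------------------------
# density fields


@dataclass
class DensityField:
    """Probability mass per mesh vertex (the live-individual distribution).

    ``mass[v]`` is the probability of being in the lumped control volume of
    vertex v; the transformed FE variable is u = mass / M with M the lumped
    k-weighted mass vector.  Total mass is at most 1; the deficit is the
    dead (battery-expired) probability tracked separately by the filter.
    """

    mesh: Mesh
    mass: np.ndarray

    def __post_init__(self):
        self.mass = np.asarray(self.mass, dtype=float)
        if self.mass.shape != (self.mesh.n_vertices,):
            raise ValueError("mass vector does not match mesh size")
        if not np.all(np.isfinite(self.mass)):
            raise FloatingPointError("non-finite density values")
        if np.any(self.mass < -1e-12):
            raise ValueError("negative density mass")
        if self.mass.sum() > 1 + 1e-9:
            raise ValueError("total probability mass exceeds 1")

    @property
    def total_mass(self) -> float:
        return float(self.mass.sum())

    @classmethod
    def point_mass(cls, mesh: Mesh, x: float, y: float, smooth: bool = True) -> "DensityField":
        """Unit mass at the vertex nearest (x, y), smoothed over its one-ring.

        Smoothing puts half the mass on the centre vertex and spreads the
        rest evenly over its neighbours, avoiding mesh-scale artefacts of a
        pure delta start.
        """
        v = mesh.nearest_vertex(x, y)
        w = np.zeros(mesh.n_vertices)
        if smooth:
            ring = sorted(mesh.vertex_rings()[v])
            w[v] = 0.5
            w[ring] = 0.5 / len(ring)
        else:
            w[v] = 1.0
        return cls(mesh, w)

    def mean_squared_displacement(self, origin) -> float:
        """Mass-weighted mean squared distance from ``origin`` (m^2)."""
        d2 = ((self.mesh.vertices - np.asarray(origin)) ** 2).sum(axis=1)
        return float((self.mass * d2).sum() / self.mass.sum())


# ---------------------------------------------------------------------------
# propagation


class Propagator:
    """Reusable time-propagation operator for one parameter set.

    ``step(w)`` advances a mass vector by ``step_days`` and applies the exact
    mortality factor exp(-m * step_days).  With ``method='exact'`` the dense
    kernel equals the CTMC transition matrix exp(G t); ``transition_matrix``
    then exposes the row-stochastic form used by the batch track sampler.
    """

    DENSE_LIMIT = 2500

    def __init__(
        self,
        mesh: Mesh,
        params: DiffusionParams,
        step_days: float = 0.5,
        method: str = "exact",
        substeps: int = 8,
    ):
        if step_days <= 0:
            raise ValueError("step_days must be positive")
        if substeps < 1:
            raise ValueError("substeps must be >= 1")
        self.mesh = mesh
        self.params = params
        self.step_days = float(step_days)
        self.method = method
        self.substeps = int(substeps)
        self.survival = float(np.exp(-params.m * step_days))
        n = mesh.n_vertices
        ops = unit_operators(mesh)
        if method == "exact" and ops.K_dense is not None:
            kvec = np.array([params.k[h] for h in HABITATS])
            dk = np.array([params.D[h] * params.k[h] for h in HABITATS])
            M = kvec @ ops.a_dense
            K = np.tensordot(dk, ops.K_dense, axes=1)
        else:
            M, K = assemble_operators(mesh, params)
        self._M = M
        if method == "exact":
            if n > self.DENSE_LIMIT:
                raise MeshOperatorError(
                    f"exact propagator is dense; mesh has {n} > {self.DENSE_LIMIT} vertices"
                )
            Kd = K if isinstance(K, np.ndarray) else K.toarray()
            s = 1.0 / np.sqrt(M)
            sym = -(Kd * s[:, None] * s[None, :])
            sym = 0.5 * (sym + sym.T)
            lam, V = np.linalg.eigh(sym)
            lam = np.minimum(lam, 0.0)  # generator spectrum is nonpositive
            core = (V * np.exp(lam * self.step_days)) @ V.T
            P = core * (np.sqrt(M)[:, None] * s[None, :])
            P = np.maximum(P, 0.0)
            P /= P.sum(axis=0, keepdims=True)  # restore exact column-stochasticity
            self._P = P
        elif method in ("implicit", "cn"):
            dt = self.step_days / self.substeps
            A = sp.diags(M) + dt * (K if method == "implicit" else 0.5 * K)
            self._lu = splu(A.tocsc())
            self._B = sp.diags(M) - 0.5 * dt * K if method == "cn" else None
        else:
            raise ValueError(f"unknown propagation method {method!r}")

    def step_live(self, w: np.ndarray) -> np.ndarray:
        """Advance mass by one step, without the mortality factor."""
        if self.method == "exact":
            return self._P @ w
        M = self._M
        u = w / M
        for _ in range(self.substeps):
            rhs = M * u if self._B is None else self._B @ u
            u = self._lu.solve(rhs)
        return M * u

    def step(self, w: np.ndarray) -> np.ndarray:
        return self.survival * self.step_live(w)

    def transition_matrix(self) -> np.ndarray:
        """Row-stochastic transition matrix (source vertex = row); exact only."""
        if self.method != "exact":
            raise ValueError("transition_matrix requires method='exact'")
        return self._P.T.copy()


def propagate(
    density: DensityField,
    duration: float,
    params: DiffusionParams,
    substeps: int = 8,
    method: str = "implicit",
) -> DensityField:
    """Advance a density by ``duration`` days.

    ``substeps`` are per call (the propagator splits the full duration).
    Total mass decays by exactly exp(-m * duration); with m = 0 it is
    conserved to solver accuracy.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if not np.all(np.isfinite(density.mass)):
        raise FloatingPointError("non-finite density values")
    prop = Propagator(density.mesh, params, step_days=duration, method=method, substeps=substeps)
    return DensityField(density.mesh, prop.step(density.mass))


def equilibrium_density(mesh: Mesh, params: DiffusionParams) -> DensityField:
    """Stationary density (m = 0): u constant, p proportional to k^h.

    Computed in closed form from the lumped k-weighted mass vector; requires
    a connected mesh (otherwise the stationary law is not unique).
    """
    if params.m != 0:
        raise ValueError("equilibrium is defined for m = 0")
    M, K = assemble_operators(mesh, params)
    ncomp, labels = connected_components(csgraph=(K != 0), directed=False)
    if ncomp > 1:
        sizes = np.bincount(labels)
        raise MeshOperatorError(
            f"mesh is disconnected: {ncomp} components with sizes {sizes.tolist()}"
        )
    return DensityField(mesh, M / M.sum())


def write_operator_coo(matrix, path) -> None:
    """Serialize a sparse operator as text coordinate triplets (row col value)."""
    coo = sp.coo_matrix(matrix)
    with open(path, "w") as fh:
        fh.write(f"{coo.shape[0]} {coo.shape[1]} {coo.nnz}\n")
        for r, c, v in zip(coo.row, coo.col, coo.data):
            fh.write(f"{r} {c} {v:.17g}\n")


def read_operator_coo(path):
    with open(path) as fh:
        nr, nc, nnz = (int(s) for s in fh.readline().split())
        rows, cols, vals = [], [], []
        for _ in range(nnz):
            r, c, v = fh.readline().split()
            rows.append(int(r))
            cols.append(int(c))
            vals.append(float(v))
    return sp.csr_matrix((vals, (rows, cols)), shape=(nr, nc))


def write_density_csv(field: DensityField, path) -> None:
    """Nodal mass vector with coordinates, for debugging."""
    import pandas as pd

    pd.DataFrame(
        {
            "vertex": np.arange(field.mesh.n_vertices),
            "x": field.mesh.vertices[:, 0],
            "y": field.mesh.vertices[:, 1],
            "mass": field.mass,
        }
    ).to_csv(path, index=False)


def habitat_mass(field: DensityField, params: DiffusionParams) -> dict[int, float]:
    """Split total mass by habitat, attributing vertex mass via lumped areas."""
    ops = unit_operators(field.mesh)
    M = np.zeros(ops.n)
    for h in HABITATS:
        M += params.k[h] * ops.a[h]
    out = {}
    for h in HABITATS:
        share = params.k[h] * ops.a[h] / M
        out[h] = float((field.mass * share).sum())
    return out
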