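"""FE diffusion engine: conservation, decay, equilibrium, free-space limit."""

import numpy as np
import pytest
from scipy.linalg import expm
from shapely.geometry import box

from movesynd.diffusion import (
    DensityField,
    DiffusionParams,
    MeshOperatorError,
    Propagator,
    assemble_operators,
    equilibrium_density,
    habitat_mass,
    propagate,
    unit_operators,
)
from movesynd.landscape import FOREST, MATRIX, OPEN, HabitatPolygonSet, Mesh, build_mesh
from movesynd.synthetic import make_landscape


def params(D=1.0, k2=1.0, k3=1.0, m=0.0, D2=None, D3=None):
    return DiffusionParams(
        D={FOREST: D, MATRIX: D2 or D, OPEN: D3 or D},
        k={FOREST: 1.0, MATRIX: k2, OPEN: k3},
        m=m,
    )


class TestAssembly:
    def test_stiffness_rows_sum_to_zero(self, forest_mesh):
        _, K = assemble_operators(forest_mesh, params(D=1.0))
        assert np.abs(K @ np.ones(forest_mesh.n_vertices)).max() < 1e-10

    def test_two_triangle_hand_assembly(self):
        verts = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])
        tris = np.array([[0, 1, 2], [0, 2, 3]])
        mesh = Mesh(verts, tris, np.array([FOREST, FOREST]), np.array([0.5, 0.5]))
        D = 3.0
        _, K = assemble_operators(mesh, params(D=D))
        # P1 stiffness of a unit right triangle (right angle at the middle
        # vertex): 0.5*[[1,-1,0],[-1,2,-1],[0,-1,1]]; assembled over both.
        expected = D * 0.5 * np.array(
            [
                [2.0, -1.0, 0.0, -1.0],
                [-1.0, 2.0, -1.0, 0.0],
                [0.0, -1.0, 2.0, -1.0],
                [-1.0, 0.0, -1.0, 2.0],
            ]
        )
        assert np.allclose(K.toarray(), expected, atol=1e-12)

    def test_preference_gauge_invariance(self, bipartite_mesh):
        """Scaling every habitat preference by a constant leaves the
        propagated probability mass unchanged (only u = p/k rescales)."""
        ops = unit_operators(bipartite_mesh)
        rng = np.random.default_rng(0)
        w0 = rng.uniform(size=bipartite_mesh.n_vertices)
        w0 /= w0.sum()
        out = []
        for c in (1.0, 7.3):
            k = {FOREST: c, MATRIX: c, OPEN: 5.0 * c}
            M = sum(k[h] * ops.a[h] for h in (FOREST, MATRIX, OPEN))
            K = sum(2e5 * k[h] * ops.K[h].toarray() for h in (FOREST, MATRIX, OPEN))
            P = expm(-K / M * 0.5)  # mass-coordinate generator G = -K M^-1
            out.append(P @ w0)
        assert np.allclose(out[0], out[1], atol=1e-10)

    def test_degenerate_triangle_rejected(self):
        verts = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]])
        with pytest.raises(Exception):
            Mesh(verts, np.array([[0, 1, 2]]), np.array([FOREST]), np.array([0.0]))


class TestPropagation:
    @pytest.mark.parametrize("method,substeps", [("implicit", 100), ("exact", 1), ("cn", 16)])
    def test_mass_conservation(self, bipartite_mesh, method, substeps):
        field = DensityField.point_mass(bipartite_mesh, 400, 900)
        out = propagate(field, 10.0, params(D=1e5, k3=4.0), substeps=substeps, method=method)
        assert out.total_mass == pytest.approx(1.0, abs=1e-8)

    @pytest.mark.parametrize("method", ["implicit", "exact"])
    def test_mortality_decay_exact(self, bipartite_mesh, method):
        field = DensityField.point_mass(bipartite_mesh, 1000, 1000)
        out = propagate(field, 1.0, params(D=1e5, m=0.15), substeps=16, method=method)
        assert out.total_mass == pytest.approx(np.exp(-0.15), abs=1e-6)

    def test_free_space_msd(self):
        """Mean squared displacement 4 D t for forest diffusion at the
        population-mean rate, on a refined homogeneous mesh."""
        D = 337_419.65
        habitat = HabitatPolygonSet([(box(0, 0, 4000, 4000), FOREST)], (0, 0, 4000, 4000))
        mesh = build_mesh(habitat, 5000.0)  # 100 m pitch
        field = DensityField.point_mass(mesh, 2000, 2000, smooth=True)
        out = propagate(field, 0.5, params(D=D), method="exact")
        msd = out.mean_squared_displacement((2000, 2000))
        assert msd == pytest.approx(4 * D * 0.5, rel=0.05)

    def test_msd_error_shrinks_under_refinement(self):
        D = 337_419.65
        habitat = HabitatPolygonSet([(box(0, 0, 6000, 6000), FOREST)], (0, 0, 6000, 6000))
        errors = []
        for max_area in (45000.0, 11250.0):  # 300 m and 150 m pitch
            mesh = build_mesh(habitat, max_area)
            field = DensityField.point_mass(mesh, 3000, 3000, smooth=True)
            out = propagate(field, 0.5, params(D=D), method="exact")
            msd = out.mean_squared_displacement((3000, 3000))
            errors.append(abs(msd - 4 * D * 0.5) / (4 * D * 0.5))
        assert errors[1] <= 0.6 * errors[0] + 1e-4

    def test_positivity_on_random_fixtures(self):
        rng = np.random.default_rng(42)
        for trial in range(20):
            land = make_landscape(trial, extent=1000.0, cell=250.0)
            mesh = build_mesh(land, 31250.0)
            p = params(
                D=float(np.exp(rng.uniform(9, 13))),
                k2=float(np.exp(rng.uniform(-2, 2))),
                k3=float(np.exp(rng.uniform(-2, 2))),
            )
            w0 = rng.uniform(size=mesh.n_vertices)
            w0 /= w0.sum()
            out = propagate(DensityField(mesh, w0), 0.5, p, substeps=8, method="implicit")
            assert out.mass.min() >= -1e-12

    def test_non_finite_input_rejected(self, forest_mesh):
        field = DensityField.point_mass(forest_mesh, 0, 0)
        field.mass = field.mass.copy()
        field.mass[0] = np.nan  # corrupt after construction
        with pytest.raises(FloatingPointError):
            propagate(field, 1.0, params())


class TestSerialization:
    def test_operator_coo_roundtrip(self, forest_mesh, tmp_path):
        from movesynd.diffusion import read_operator_coo, write_operator_coo

        _, K = assemble_operators(forest_mesh, params(D=2.0))
        write_operator_coo(K, tmp_path / "K.coo")
        back = read_operator_coo(tmp_path / "K.coo")
        assert (K != back).nnz == 0

    def test_density_csv(self, forest_mesh, tmp_path):
        from movesynd.diffusion import write_density_csv
        import pandas as pd

        field = DensityField.point_mass(forest_mesh, 500, 500)
        write_density_csv(field, tmp_path / "d.csv")
        df = pd.read_csv(tmp_path / "d.csv")
        assert len(df) == forest_mesh.n_vertices
        assert df["mass"].sum() == pytest.approx(1.0)


class TestEquilibrium:
    def test_uniform_when_k_is_one(self, forest_mesh):
        eq = equilibrium_density(forest_mesh, params())
        density = eq.mass / (eq.mass.sum())
        # per-vertex mass proportional to lumped area -> uniform areal density
        M, _ = assemble_operators(forest_mesh, params())
        assert np.allclose(density, M / M.sum(), atol=1e-12)

    def test_two_habitat_mass_ratio_closed_form(self, bipartite_mesh):
        p = params(D=1e5, k3=10.0)
        eq = equilibrium_density(bipartite_mesh, p)
        masses = habitat_mass(eq, p)
        assert masses[OPEN] / masses[FOREST] == pytest.approx(10.0, rel=1e-9)

    def test_open_preference_ratio_via_long_propagation(self, bipartite_mesh):
        """Open:forest equilibrium density ratio equals k3 = 101.17."""
        k3 = 101.17
        p = params(D=3e5, k3=k3)
        start = DensityField.point_mass(bipartite_mesh, 500, 1000)
        prop = Propagator(bipartite_mesh, p, step_days=50.0, method="exact")
        w = prop.step(start.mass)
        field = DensityField(bipartite_mesh, w)
        masses = habitat_mass(field, p)
        assert masses[OPEN] / masses[FOREST] == pytest.approx(k3, rel=0.02)
        closed = habitat_mass(equilibrium_density(bipartite_mesh, p), p)
        assert closed[OPEN] / closed[FOREST] == pytest.approx(k3, rel=1e-9)

    def test_disconnected_mesh_rejected(self):
        verts = np.array(
            [[0, 0], [1, 0], [0, 1], [10, 10], [11, 10], [10, 11]], dtype=float
        )
        tris = np.array([[0, 1, 2], [3, 4, 5]])
        mesh = Mesh(verts, tris, np.array([FOREST, FOREST]), np.array([0.5, 0.5]))
        with pytest.raises(MeshOperatorError, match="disconnected"):
            equilibrium_density(mesh, params())
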