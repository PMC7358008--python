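import numpy as np
import pytest
from scipy.stats import spearmanr

import lungatlas as la
from lungatlas.trajectory import PotentialField


class TestPseudotime:
    def test_one_dimensional_gradient_recovered(self):
        rng = np.random.default_rng(0)
        t = np.sort(rng.uniform(0, 1, 120))
        coords = np.column_stack([10 * t, rng.normal(0, 0.1, 120)])
        pt = la.compute_pseudotime(coords, root_cell=0)
        rho = spearmanr(pt.pseudotime, t).statistic
        assert rho >= 0.9
        assert pt.pseudotime[0] == 0.0

    def test_root_at_far_end_reverses_ordering(self):
        rng = np.random.default_rng(1)
        t = np.sort(rng.uniform(0, 1, 120))
        coords = np.column_stack([10 * t, rng.normal(0, 0.1, 120)])
        fwd = la.compute_pseudotime(coords, root_cell=0)
        rev = la.compute_pseudotime(coords, root_cell=119)
        assert spearmanr(fwd.pseudotime, rev.pseudotime).statistic <= -0.9

    def test_singleton_subset(self):
        coords = np.zeros((5, 2))
        pt = la.compute_pseudotime(coords, root_cell=3, subset=np.array([3]))
        assert pt.pseudotime.tolist() == [0.0]

    def test_root_outside_subset_is_error(self):
        with pytest.raises(ValueError, match="root"):
            la.compute_pseudotime(np.zeros((5, 2)), root_cell=0,
                                  subset=np.array([1, 2]))

    def test_values_scaled_to_unit_interval(self):
        rng = np.random.default_rng(2)
        coords = rng.normal(size=(50, 3))
        pt = la.compute_pseudotime(coords, root_cell=0)
        assert pt.pseudotime.min() == 0.0
        assert pt.pseudotime.max() == 1.0


class TestPotentialInterpolation:
    def test_constant_pseudotime_gives_constant_potential(self):
        rng = np.random.default_rng(3)
        emb = rng.uniform(-5, 5, size=(100, 2))
        f = la.interpolate_potential(emb, np.full(100, 0.5), nx=20, ny=20)
        vals = f.potential[f.populated]
        assert np.allclose(vals, 0.5)

    def test_exact_node_hit_takes_cell_value(self):
        emb = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        pt = np.array([0.7, 0.2, 0.4])
        # nx=ny=2 puts grid nodes exactly on the corner cells
        f = la.interpolate_potential(emb, pt, nx=2, ny=2, radius_factor=0.4)
        assert f.potential[0, 0] == 0.7

    def test_unpopulated_regions_masked(self):
        emb = np.array([[0, 0], [0.1, 0.1], [10, 10]], dtype=float)
        f = la.interpolate_potential(emb, np.array([0.0, 0.1, 1.0]), nx=30, ny=30)
        assert f.populated.sum() < f.populated.size
        assert np.isnan(f.potential[~f.populated]).all()

    def test_radial_field_monotone_along_rays(self):
        rng = np.random.default_rng(4)
        emb = rng.uniform(-1, 1, size=(800, 2))
        pt = np.linalg.norm(emb, axis=1)
        f = la.interpolate_potential(emb, pt, nx=21, ny=21)
        mid = 10  # node column/row closest to the center
        for line in (f.potential[mid, mid:], f.potential[mid, mid::-1],
                     f.potential[mid:, mid], f.potential[mid::-1, mid]):
            vals = line[~np.isnan(line)]
            assert (np.diff(vals) > -0.05).all()

    def test_degenerate_bounding_box_is_error(self):
        emb = np.tile([[1.0, 2.0]], (5, 1))
        with pytest.raises(ValueError, match="bounding box"):
            la.interpolate_potential(emb, np.zeros(5))


def full_field(potential):
    potential = np.asarray(potential, float)
    nx, ny = potential.shape
    return PotentialField(
        xs=np.arange(nx, dtype=float),
        ys=np.arange(ny, dtype=float),
        populated=np.ones((nx, ny), bool),
        potential=potential,
    )


class TestLocalMaxima:
    def test_single_gaussian_peak_yields_one_maximum(self):
        x = np.linspace(-2, 2, 25)
        gx, gy = np.meshgrid(x, x, indexing="ij")
        pot = np.exp(-(gx**2 + gy**2))
        maxima = la.find_local_maxima(full_field(pot))
        assert len(maxima) == 1
        assert maxima[0][:2] == (12, 12)

    def test_constant_potential_has_no_maxima(self):
        assert la.find_local_maxima(full_field(np.ones((10, 10)))) == []

    def test_two_disjoint_patches_have_two_maxima(self):
        pot = np.full((20, 20), np.nan)
        pop = np.zeros((20, 20), bool)
        for ci in (4, 15):
            for i in range(ci - 2, ci + 3):
                for j in range(ci - 2, ci + 3):
                    pop[i, j] = True
                    pot[i, j] = 1.0 - 0.1 * (abs(i - ci) + abs(j - ci))
        f = PotentialField(
            xs=np.arange(20.0), ys=np.arange(20.0), populated=pop, potential=pot
        )
        maxima = la.find_local_maxima(f)
        assert len(maxima) == 2
        assert {(m[0], m[1]) for m in maxima} == {(4, 4), (15, 15)}

    def test_plateau_counted_once(self):
        pot = np.zeros((7, 7))
        pot[2:5, 2:5] = 1.0  # 3x3 plateau above a flat floor
        maxima = la.find_local_maxima(full_field(pot))
        assert len(maxima) == 1
        assert maxima[0][:2] == (2, 2)  # lowest row-major plateau node


class TestGradientField:
    def test_linear_ramp_exact_at_interior(self):
        nx, ny = 12, 9
        gx = np.arange(nx, dtype=float)[:, None] * np.ones((1, ny))
        f = full_field(3.0 * gx)
        grad = la.gradient_field(f)
        interior = grad[1:-1, 1:-1]
        assert np.allclose(interior[..., 0], 3.0, atol=1e-12)
        assert np.allclose(interior[..., 1], 0.0, atol=1e-12)

    def test_constant_potential_zero_vectors(self):
        f = full_field(np.full((8, 8), 0.3))
        grad = la.gradient_field(f)
        assert np.allclose(grad, 0.0)

    def test_radial_field_points_outward(self):
        n = 21
        x = np.linspace(-1, 1, n)
        gx, gy = np.meshgrid(x, x, indexing="ij")
        f = full_field(np.sqrt(gx**2 + gy**2))
        grad = la.gradient_field(f)
        ok = total = 0
        for i in range(1, n - 1):
            for j in range(1, n - 1):
                r = np.array([gx[i, j], gy[i, j]])
                if np.linalg.norm(r) < 1e-9:
                    continue
                total += 1
                ok += np.dot(grad[i, j], r) > 0
        assert ok / total >= 0.95

    def test_no_arrow_exits_a_maximum_uphill(self):
        x = np.linspace(-2, 2, 15)
        gx, gy = np.meshgrid(x, x, indexing="ij")
        f = full_field(np.exp(-(gx**2 + gy**2)))
        maxima = la.find_local_maxima(f)
        grad = la.gradient_field(f)
        (i, j, _), = maxima
        assert np.linalg.norm(grad[i, j]) < 1e-6


class TestTrajectoryAnalysis:
    def test_latent_time_recovery_on_default_atlas(
        self, pipeline_result, truth_labels, default_atlas
    ):
        _, truth = default_atlas
        ann = pipeline_result.annotations
        grad_clusters = [cl for cl, n in ann.items() if n == "Mac II"]
        early = truth.gradient_genes[:15]
        pt, subset, coords = la.trajectory_analysis(
            pipeline_result, grad_clusters, early_markers=early
        )
        lt = truth_labels["latent_time"].to_numpy()[subset]
        keep = ~np.isnan(lt)
        rho = spearmanr(pt.pseudotime[keep], lt[keep]).statistic
        assert abs(rho) >= 0.9
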