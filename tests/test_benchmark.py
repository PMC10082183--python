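"""Pseudo-spot construction, evaluation metrics, fixture generation."""

import numpy as np
import pytest
from scipy.spatial.distance import jensenshannon

from spotdecon import benchmark as bench
from spotdecon.datasets import ProportionMatrix, SCReference


def make_pm(props, spots=None, types=None):
    props = np.asarray(props, dtype=float)
    spots = spots or [f"s{i}" for i in range(props.shape[0])]
    types = types or [f"t{j}" for j in range(props.shape[1])]
    return ProportionMatrix(proportions=props, spot_ids=spots, cell_types=types)


def toy_reference(rng, K=3, cells_per_type=10, n_genes=30):
    counts = rng.poisson(5, size=(K * cells_per_type, n_genes)).astype(float) + 1
    labels = [f"t{j}" for j in range(K) for _ in range(cells_per_type)]
    return SCReference(
        counts=counts,
        cell_ids=[f"c{i}" for i in range(K * cells_per_type)],
        gene_ids=[f"g{i}" for i in range(n_genes)],
        labels=labels,
    )


class TestBenchmarkProportions:
    def test_single_method_is_identity(self, rng):
        pm = make_pm(rng.dirichlet(np.ones(4), size=6))
        out = bench.build_benchmark_proportions([pm], n_rare=2)
        assert np.allclose(out.proportions, pm.proportions)

    def test_no_rare_types_is_renormalized_mean(self, rng):
        a = make_pm(rng.dirichlet(np.ones(3), size=5))
        b = make_pm(rng.dirichlet(np.ones(3), size=5))
        out = bench.build_benchmark_proportions([a, b], n_rare=0)
        mean = (a.proportions + b.proportions) / 2
        assert np.allclose(out.proportions, mean / mean.sum(1, keepdims=True))

    def test_rare_type_takes_minimum(self):
        # type t2 has the smallest mean -> min rule applies before renorm
        a = make_pm([[0.6, 0.3, 0.1], [0.5, 0.4, 0.1]])
        b = make_pm([[0.4, 0.3, 0.3], [0.3, 0.4, 0.3]])
        out = bench.build_benchmark_proportions([a, b], n_rare=1)
        raw = np.column_stack([
            (a.proportions[:, 0] + b.proportions[:, 0]) / 2,
            (a.proportions[:, 1] + b.proportions[:, 1]) / 2,
            np.minimum(a.proportions[:, 2], b.proportions[:, 2]),
        ])
        assert np.allclose(out.proportions, raw / raw.sum(1, keepdims=True))

    def test_rows_sum_to_one(self, rng):
        pms = [make_pm(rng.dirichlet(np.ones(5), size=8)) for _ in range(4)]
        out = bench.build_benchmark_proportions(pms)
        assert np.allclose(out.proportions.sum(axis=1), 1.0, atol=1e-12)

    def test_mismatched_types_error(self, rng):
        a = make_pm(rng.dirichlet(np.ones(3), size=4))
        b = make_pm(rng.dirichlet(np.ones(3), size=4), types=["x", "y", "z"])
        with pytest.raises(ValueError, match="universes"):
            bench.build_benchmark_proportions([a, b])


class TestPseudoSpotSampling:
    def test_ceiling_and_scale_factor(self, rng):
        # U=2400, p=0.5 -> n=1.2, n*=2, per-cell scale 0.6
        ref = toy_reference(rng).rescaled(1000.0)
        vec, _, cells = bench.sample_pseudo_spot(
            ref, 2400.0, np.array([0.5, 0.5, 0.0]), np.random.default_rng(0)
        )
        assert len(cells) == 4  # 2 per type with p=0.5
        assert vec.sum() == pytest.approx(2400.0, rel=1e-9)

    def test_single_pure_cell_spot(self, rng):
        ref = toy_reference(rng).rescaled(1000.0)
        vec, _, cells = bench.sample_pseudo_spot(
            ref, 1000.0, np.array([1.0, 0.0, 0.0]), np.random.default_rng(0)
        )
        assert len(cells) == 1
        assert vec.sum() == pytest.approx(1000.0, rel=1e-12)

    def test_umi_conservation_identity(self, rng):
        # pre-rounding spot total equals U_i for every spot and seed
        ref = toy_reference(rng)
        truth = make_pm(rng.dirichlet(np.ones(3), size=25))
        umis = rng.uniform(500, 5000, size=25)
        pseudo = bench.build_pseudo_srt(
            bench.BenchmarkSpec(umi_totals=umis, proportions=truth, seed=4), ref
        )
        totals = pseudo.counts_unrounded.sum(axis=1)
        assert np.allclose(totals, umis, rtol=1e-6)

    def test_zero_proportion_contributes_no_cells(self, rng):
        ref = toy_reference(rng).rescaled(1000.0)
        _, _, cells = bench.sample_pseudo_spot(
            ref, 3000.0, np.array([1.0, 0.0, 0.0]), np.random.default_rng(0)
        )
        t0_ids = set(ref.cell_ids[i] for i in np.flatnonzero(ref.label_indices() == 0))
        assert set(cells) <= t0_ids

    def test_positive_proportion_without_cells_errors(self, rng):
        ref = toy_reference(rng, K=2).rescaled(1000.0)
        with pytest.raises(ValueError, match="no reference cells"):
            bench.sample_pseudo_spot(
                ref, 1000.0, np.array([0.5, 0.2, 0.3]),
                np.random.default_rng(0),
            )
        # build_pseudo_srt propagates the same failure
        truth = make_pm(np.full((4, 3), 1 / 3))
        with pytest.raises(ValueError, match="no reference cells"):
            bench.build_pseudo_srt(
                bench.BenchmarkSpec(umi_totals=np.full(4, 1000.0),
                                    proportions=truth, seed=0),
                ref,
            )

    def test_seeded_determinism_and_rounding(self, rng):
        ref = toy_reference(rng)
        truth = make_pm(rng.dirichlet(np.ones(3), size=10))
        spec = bench.BenchmarkSpec(
            umi_totals=np.full(10, 2400.0), proportions=truth, seed=11
        )
        p1 = bench.build_pseudo_srt(spec, ref)
        p2 = bench.build_pseudo_srt(spec, ref)
        assert np.array_equal(p1.counts, p2.counts)
        assert p1.provenance == p2.provenance
        # half-to-even rounding
        assert np.array_equal(p1.counts, np.rint(p1.counts_unrounded))
        # rounded totals stay within the number of sampled cells of U_i
        K = 3
        n_sampled = np.array([len(c) for c in p1.provenance])
        dev = np.abs(p1.counts.sum(axis=1) - 2400.0)
        assert np.all(dev <= np.maximum(n_sampled, K) * ref.counts.shape[1] * 0.5)


class TestMetrics:
    def test_mse_zero_when_equal(self, rng):
        pm = make_pm(rng.dirichlet(np.ones(3), size=6))
        assert all(v == 0 for v in bench.mse_per_celltype(pm, pm).values())

    def test_mse_constant_error(self):
        truth = make_pm([[0.5, 0.5], [0.5, 0.5]])
        est = make_pm([[0.6, 0.4], [0.6, 0.4]])
        mse = bench.mse_per_celltype(est, truth)
        assert mse["t0"] == pytest.approx(0.01)

    def test_mse_hand_arithmetic(self):
        truth = make_pm([[0.5, 0.5], [0.5, 0.5]])
        est = make_pm([[0.6, 0.4], [0.8, 0.2]])
        assert bench.mse_per_celltype(est, truth)["t0"] == pytest.approx(0.05)

    def test_jsd_identical_rows_zero(self, rng):
        pm = make_pm(rng.dirichlet(np.ones(4), size=5))
        assert np.allclose(bench.jsd_per_spot(pm, pm), 0.0, atol=1e-12)

    def test_jsd_disjoint_point_masses_is_one(self):
        a = make_pm([[1.0, 0.0]])
        b = make_pm([[0.0, 1.0]])
        assert bench.jsd_per_spot(a, b)[0] == pytest.approx(1.0, abs=1e-12)

    def test_jsd_symmetry(self, rng):
        a = make_pm(rng.dirichlet(np.ones(5), size=20))
        b = make_pm(rng.dirichlet(np.ones(5), size=20))
        assert np.allclose(bench.jsd_per_spot(a, b), bench.jsd_per_spot(b, a),
                           atol=1e-12)

    def test_jsd_matches_brute_force_and_scipy(self, rng):
        """Dual oracle: explicit sums with explicit M, and scipy's
        jensenshannon (squared, base 2), on 1000 random pairs."""
        X = rng.dirichlet(np.ones(6), size=1000)
        Y = rng.dirichlet(np.ones(6), size=1000)
        ours = bench.jsd_per_spot(make_pm(X), make_pm(Y))

        def brute(x, y):
            m = 0.5 * (x + y)
            total = 0.0
            for xi, yi, mi in zip(x, y, m):
                if xi > 0:
                    total += 0.5 * xi * np.log2(xi / mi)
                if yi > 0:
                    total += 0.5 * yi * np.log2(yi / mi)
            return total

        expect = np.array([brute(x, y) for x, y in zip(X, Y)])
        assert np.allclose(ours, expect, atol=1e-12)
        scipy_jsd = jensenshannon(X, Y, base=2, axis=1) ** 2
        assert np.allclose(ours, scipy_jsd, atol=1e-9)

    def test_jsd_in_unit_interval(self, rng):
        a = make_pm(rng.dirichlet(np.full(4, 0.3), size=50))
        b = make_pm(rng.dirichlet(np.full(4, 0.3), size=50))
        vals = bench.jsd_per_spot(a, b)
        assert np.all((vals >= 0) & (vals <= 1.0 + 1e-12))


class TestFixtureGenerator:
    def test_shapes_and_row_sums(self, mini_fixture):
        ref, srt, truth = mini_fixture
        assert srt.counts.shape == (49, ref.counts.shape[1])
        assert np.allclose(truth.proportions.sum(axis=1), 1.0)
        assert srt.image is not None and srt.image.shape[2] == 3
        assert ref.n_types == 3

    def test_same_seed_identical_outputs(self):
        kw = dict(K=2, genes_per_type=20, n_background_genes=10,
                  n_cells=30, n_spots=16, grid=(4, 4), seed=5)
        r1, s1, t1 = bench.generate_synthetic_fixture(**kw)
        r2, s2, t2 = bench.generate_synthetic_fixture(**kw)
        assert np.array_equal(r1.counts, r2.counts)
        assert np.array_equal(s1.counts, s2.counts)
        assert np.array_equal(s1.image, s2.image)
        assert np.array_equal(t1.proportions, t2.proportions)

    def test_marker_blocks_carry_signal(self, mini_fixture):
        ref, _, _ = mini_fixture
        idx = ref.label_indices()
        markers0 = ref.counts[:, :40]
        mean_in = markers0[idx == 0].mean()
        mean_out = markers0[idx != 0].mean()
        assert mean_in > 3 * mean_out

    def test_unit_fold_change_removes_signal(self):
        ref, _, _ = bench.generate_synthetic_fixture(
            K=2, genes_per_type=30, n_background_genes=10, n_cells=60,
            n_spots=16, grid=(4, 4), fold_change=1.0, seed=2,
        )
        idx = ref.label_indices()
        markers0 = ref.counts[:, :30]
        ratio = markers0[idx == 0].mean() / markers0[idx != 0].mean()
        assert 0.8 < ratio < 1.25
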