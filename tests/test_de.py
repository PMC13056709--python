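import numpy as np
import pytest
import scipy.sparse as sp
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from txfidelity import (
    CountMatrix,
    DEConfig,
    SimConfig,
    ValidationError,
    bh_adjust,
    estimate_dispersion,
    exact_nb_test,
    filter_low_expression,
    generate_experiment,
    log2_fold_change,
    run_de,
    size_factors,
)
from txfidelity.de import exact_nb_test_batch

from conftest import make_counts


def brute_force_conditional_p(sum_a, sum_b, n_a, n_b, phi):
    """Independent oracle: enumerate P(a | T) from scipy pmfs directly."""
    total = sum_a + sum_b
    if total == 0:
        return 1.0
    mu = total / (n_a + n_b)
    a = np.arange(total + 1)

    def pmf(k, mass):
        mean = mass * mu
        if phi == 0:
            return scipy.stats.poisson.pmf(k, mean)
        r = mass / phi
        return scipy.stats.nbinom.pmf(k, r, r / (r + mean))

    weights = pmf(a, n_a) * pmf(total - a, n_b)
    weights = weights / weights.sum()
    obs = weights[sum_a]
    return float(weights[weights <= obs * (1 + 1e-12)].sum())


def reference_bh(p):
    """Independent step-up: sort ascending, q_i = min_{j>=i} p_j * n / j."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p)
    q_sorted = np.minimum.accumulate((p[order] * n / np.arange(1, n + 1))[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(q_sorted, 1.0)
    return out


class TestSizeFactors:
    def test_equal_depths_give_unit_factors(self):
        cm = make_counts([[500, 500, 500], [500, 500, 500]])
        assert np.allclose(size_factors(cm), 1.0)

    def test_median_scaling(self):
        cm = make_counts([[100, 200, 400]])
        assert size_factors(cm).tolist() == [0.5, 1.0, 2.0]

    def test_global_scaling_leaves_factors_unchanged(self):
        rng = np.random.default_rng(0)
        dense = rng.integers(0, 30, size=(20, 9))
        assert np.allclose(size_factors(make_counts(dense)), size_factors(make_counts(dense * 3)))

    def test_zero_depth_cells_marked_unusable(self):
        cm = make_counts([[4, 0], [4, 0]])
        factors = size_factors(cm)
        assert np.isnan(factors[1]) and factors[0] == 1.0

    def test_all_zero_matrix_is_an_error(self):
        with pytest.raises(ValidationError):
            size_factors(make_counts([[0, 0]]))


class TestFilterLowExpression:
    def test_boundary_mean(self):
        dense = np.zeros((2, 100), dtype=int)
        dense[0, :99] = 1  # mean 0.99 -> dropped
        dense[1, :] = 1  # mean 1.00 -> kept
        mask = filter_low_expression(make_counts(dense))
        assert mask.tolist() == [False, True]

    def test_matches_dense_row_means(self):
        rng = np.random.default_rng(1)
        dense = rng.poisson(1.0, size=(50, 40))
        mask = filter_low_expression(make_counts(dense))
        assert np.array_equal(mask, dense.mean(axis=1) >= 1.0)


class TestEstimateDispersion:
    def _groups(self, n):
        half = n // 2
        return np.arange(n) < half, np.arange(n) >= half

    def test_constant_gene_has_zero_dispersion(self):
        dense = np.full((5, 20), 7)
        cm = make_counts(dense)
        phi = estimate_dispersion(cm, self._groups(20), shrinkage_weight=0)
        assert np.allclose(phi, 0.0)

    def test_poisson_data_near_zero(self):
        rng = np.random.default_rng(2)
        dense = rng.poisson(5.0, size=(500, 400))
        phi = estimate_dispersion(make_counts(dense), self._groups(400))
        assert np.median(phi) <= 0.05

    def test_nb_dispersion_recovered(self):
        rng = np.random.default_rng(3)
        r = 1 / 0.5
        mean = 5.0
        dense = rng.negative_binomial(r, r / (r + mean), size=(2000, 300))
        phi = estimate_dispersion(make_counts(dense), self._groups(300))
        assert 0.35 <= phi.mean() <= 0.65

    def test_group_mean_differences_do_not_inflate_dispersion(self):
        rng = np.random.default_rng(4)
        ga = rng.poisson(2.0, size=(500, 150))
        gb = rng.poisson(8.0, size=(500, 150))
        cm = make_counts(np.hstack([ga, gb]))
        phi = estimate_dispersion(cm, self._groups(300))
        assert np.median(phi) <= 0.1

    def test_tiny_group_is_an_error(self):
        cm = make_counts([[1, 2, 3]])
        with pytest.raises(ValidationError, match=">= 2 cells"):
            estimate_dispersion(cm, (np.array([True, False, False]), np.array([False, True, True])))


class TestExactNBTest:
    def test_phi_zero_equal_masses_is_exact_binomial(self):
        assert abs(exact_nb_test(8, 2, 5.0, 5.0, 0.0) - 112 / 1024) < 1e-12

    def test_equal_sums_equal_masses_give_p_one(self):
        assert exact_nb_test(5, 5, 3.0, 3.0, 0.5) == 1.0

    def test_label_symmetry(self):
        for phi in (0.0, 0.3, 1.0):
            assert np.isclose(
                exact_nb_test(9, 3, 2.0, 4.0, phi), exact_nb_test(3, 9, 4.0, 2.0, phi), atol=1e-12
            )

    def test_zero_total_returns_one(self):
        assert exact_nb_test(0, 0, 1.0, 1.0, 0.5) == 1.0

    @pytest.mark.parametrize("phi", [0.0, 0.5])
    def test_matches_brute_force_enumeration(self, phi):
        for total in range(1, 13):
            for sum_a in range(total + 1):
                expected = brute_force_conditional_p(sum_a, total - sum_a, 6.0, 6.0, phi)
                got = exact_nb_test(sum_a, total - sum_a, 6.0, 6.0, phi)
                assert abs(got - expected) < 1e-9, (total, sum_a, phi)

    def test_unequal_masses_match_brute_force(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            n_a, n_b = rng.uniform(1, 20, 2)
            sum_a, sum_b = rng.integers(0, 40, 2)
            phi = rng.choice([0.0, 0.2, 1.0])
            expected = brute_force_conditional_p(int(sum_a), int(sum_b), n_a, n_b, phi)
            assert abs(exact_nb_test(int(sum_a), int(sum_b), n_a, n_b, phi) - expected) < 1e-9

    def test_batch_agrees_with_scalar(self):
        rng = np.random.default_rng(6)
        sums_a = rng.integers(0, 3000, 150)
        sums_b = rng.integers(0, 3000, 150)
        phi = np.concatenate([np.zeros(50), rng.uniform(0, 1.5, 100)])
        batch = exact_nb_test_batch(sums_a, sums_b, 37.5, 61.0, phi)
        scalar = np.array(
            [exact_nb_test(a, b, 37.5, 61.0, f) for a, b, f in zip(sums_a, sums_b, phi)]
        )
        assert np.abs(batch - scalar).max() < 1e-9


class TestFoldChangeAndBH:
    def test_log2fc_examples(self):
        assert log2_fold_change(3.0, 1.0, 1.0) == 1.0
        assert log2_fold_change(5.0, 5.0, 1.0) == 0.0
        assert log2_fold_change(0.0, 0.0, 1.0) == 0.0

    def test_bh_singleton_identity(self):
        assert bh_adjust([0.03]).tolist() == [0.03]

    def test_bh_known_vector(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04])

    def test_bh_rejects_out_of_range(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.5, 0.0])

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        st.lists(st.floats(min_value=1e-12, max_value=1.0, allow_nan=False), min_size=1, max_size=60)
    )
    def test_bh_bounds_property(self, p):
        q = bh_adjust(p)
        assert np.all(q >= np.asarray(p) - 1e-15)
        assert np.all(q <= 1.0)


@pytest.fixture(scope="module")
def marker_experiment():
    cfg = SimConfig(
        n_genes=600, n_cells_day0=800, n_cells_day14=10,
        n_markers_per_type=30, marker_fold=8.0, drift_sd=0.0, seed=21,
    )
    day0, _, truth = generate_experiment(cfg)
    return day0, truth


class TestRunDE:
    def test_marker_genes_called_significant(self, marker_experiment):
        day0, truth = marker_experiment
        k = truth.type_names[0]
        target = day0.cell_ids[truth.cell_labels_day0 == k]
        baseline = day0.cell_ids[truth.cell_labels_day0 != k]
        table = run_de(day0, target, baseline).set_index("gene_id")
        markers = [g for g in truth.markers_of(k) if g in table.index]
        hits = table.loc[markers]
        assert ((hits["significant"]) & (hits["log2fc"] > 0)).mean() >= 0.90

    def test_swapping_groups_negates_log2fc_and_keeps_p(self, marker_experiment):
        day0, truth = marker_experiment
        sub = day0.subset_cells(day0.cell_ids[:120])
        a = sub.cell_ids[:50]
        b = sub.cell_ids[50:]
        fwd = run_de(sub, a, b)
        rev = run_de(sub, b, a)
        assert np.allclose(fwd["log2fc"], -rev["log2fc"])
        assert np.allclose(fwd["p_raw"], rev["p_raw"], atol=1e-10)

    def test_invariant_to_cell_order(self, marker_experiment):
        day0, _ = marker_experiment
        rng = np.random.default_rng(8)
        sub = day0.subset_cells(day0.cell_ids[:100])
        a, b = list(sub.cell_ids[:40]), list(sub.cell_ids[40:])
        t1 = run_de(sub, a, b)
        shuffled = sub.subset_cells(rng.permutation(sub.cell_ids))
        t2 = run_de(shuffled, list(rng.permutation(a)), list(rng.permutation(b)))
        assert np.allclose(t1["p_raw"], t2["p_raw"], atol=1e-9)
        assert np.allclose(t1["log2fc"], t2["log2fc"], atol=1e-12)

    def test_overlapping_groups_rejected(self, marker_experiment):
        day0, _ = marker_experiment
        with pytest.raises(ValidationError, match="overlap"):
            run_de(day0, day0.cell_ids[:10], day0.cell_ids[5:20])

    def test_null_p_values_do_not_exceed_uniform(self):
        """Discrete exact tests are conservative: empirical CDF <= uniform + slack."""
        cfg = SimConfig(
            n_genes=1000, n_cells_day0=400, n_cells_day14=10,
            n_markers_per_type=0, cell_types=[("only", 1.0, 1.0)], seed=31,
        )
        day0, _, _ = generate_experiment(cfg)
        table = run_de(day0, day0.cell_ids[:200], day0.cell_ids[200:])
        p = np.sort(table["p_raw"].to_numpy())
        ecdf = np.arange(1, len(p) + 1) / len(p)
        slack = 3 * np.sqrt(0.25 / len(p))  # ~3 sigma binomial envelope
        assert np.all(ecdf - p <= slack + 0.01)
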