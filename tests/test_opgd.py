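import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rseikit.errors import DegenerateLayerError
from rseikit.opgd import (SampleTable, classify_interaction, discretize,
                          factor_detector, interaction_q,
                          optimal_discretization, q_statistic, run_opgd,
                          sample_grid)

from conftest import make_grid


def q_weighted_oracle(y, strata):
    """Independent oracle: 1 - sum(N_h sigma_h^2) / (N sigma^2),
    population variances."""
    y = np.asarray(y, dtype=float)
    strata = np.asarray(strata)
    total = y.size * y.var()
    acc = 0.0
    for s in np.unique(strata):
        grp = y[strata == s]
        acc += grp.size * grp.var()
    return 1.0 - acc / total


def jenks_brute_force(x, k):
    """Exhaustive enumeration of contiguous partitions of sorted x."""
    xs = np.sort(x)
    n = xs.size
    best_ssw, best_splits = np.inf, None
    for splits in itertools.combinations(range(1, n), k - 1):
        ssw = 0.0
        bounds = (0,) + splits + (n,)
        for a, b in zip(bounds[:-1], bounds[1:]):
            grp = xs[a:b]
            ssw += ((grp - grp.mean()) ** 2).sum()
        if ssw < best_ssw - 1e-12:
            best_ssw, best_splits = ssw, splits
    return best_ssw, xs[list(best_splits)]


def labels_ssw(x, labels):
    ssw = 0.0
    for s in np.unique(labels):
        grp = x[labels == s]
        ssw += ((grp - grp.mean()) ** 2).sum()
    return ssw


class TestQStatistic:
    def test_perfect_stratification(self):
        assert q_statistic([1, 1, 3, 3], ["A", "A", "B", "B"]) == \
            pytest.approx(1.0, abs=1e-12)

    def test_equal_stratum_means(self):
        assert q_statistic([1, 3, 1, 3], ["A", "A", "B", "B"]) == \
            pytest.approx(0.0, abs=1e-12)

    def test_hand_sum_of_squares(self):
        assert q_statistic([1, 2, 3, 6], ["A", "A", "B", "B"]) == \
            pytest.approx(9 / 14, abs=1e-12)

    def test_ss_form_equals_weighted_variance_form(self, rng):
        for _ in range(100):
            n = rng.integers(10, 60)
            y = rng.normal(size=n)
            strata = rng.integers(0, 5, size=n)
            assert q_statistic(y, strata) == pytest.approx(
                q_weighted_oracle(y, strata), abs=1e-12)

    def test_zero_variance_raises(self):
        with pytest.raises(DegenerateLayerError):
            q_statistic([2.0, 2.0, 2.0], [0, 1, 1])

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(a=st.floats(0.1, 10), b=st.floats(-5, 5),
           seed=st.integers(0, 1000))
    def test_affine_invariance(self, a, b, seed):
        rng = np.random.default_rng(seed)
        y = rng.normal(size=30)
        strata = rng.integers(0, 4, size=30)
        if np.var(y) == 0:
            return
        assert q_statistic(a * y + b, strata) == pytest.approx(
            q_statistic(y, strata), abs=1e-9)


class TestDiscretize:
    def test_equal_interval_breaks(self):
        d = discretize(np.linspace(0, 10, 101), "equal_interval", 5)
        np.testing.assert_allclose(d.breaks, [2, 4, 6, 8], atol=1e-12)

    def test_quantile_equal_frequency(self):
        d = discretize(np.arange(1.0, 11.0), "quantile", 2)
        counts = np.bincount(d.labels)
        np.testing.assert_array_equal(counts, [5, 5])

    def test_natural_breaks_two_clusters(self):
        x = np.array([1.0, 2, 3, 10, 11, 12])
        d = discretize(x, "natural_breaks", 2)
        assert 3 < d.breaks[0] <= 10
        assert labels_ssw(x, d.labels) == pytest.approx(4.0, abs=1e-12)

    def test_jenks_matches_enumeration(self, rng):
        for _ in range(60):
            n = int(rng.integers(6, 13))
            k = int(rng.integers(2, 5))
            x = np.round(rng.uniform(0, 100, n), 3)
            if np.unique(x).size < k:
                continue
            d = discretize(x, "natural_breaks", k)
            ssw_ref, _ = jenks_brute_force(x, k)
            assert labels_ssw(x, d.labels) == pytest.approx(ssw_ref,
                                                            abs=1e-9)

    def test_geometric_breaks_monotone(self):
        d = discretize(np.linspace(0, 1, 50), "geometric", 5)
        assert np.all(np.diff(d.breaks) > 0)
        # geometric spacing: successive gaps double with g = 2
        gaps = np.diff(np.concatenate([[0.0], d.breaks]))
        np.testing.assert_allclose(gaps[1:] / gaps[:-1], 2.0, rtol=1e-9)

    def test_std_dev_breaks_centred_on_mean(self, rng):
        x = rng.normal(10, 2, 500)
        d = discretize(x, "std_dev", 4)
        # step factor 0.5 centred on the mean: half-sd spacing for k = 4
        mean, sd = x.mean(), x.std()
        np.testing.assert_allclose(
            d.breaks, [mean - 0.5 * sd, mean, mean + 0.5 * sd], atol=1e-9)

    def test_reduced_k_warning(self):
        with pytest.warns(UserWarning, match="distinct"):
            d = discretize(np.array([1.0, 1, 2, 2, 3, 3]),
                           "equal_interval", 5)
        assert d.k <= 3

    def test_nonfinite_inputs_labelled_invalid(self):
        d = discretize(np.array([1.0, np.nan, 3.0, 2.0]),
                       "equal_interval", 2)
        assert d.labels[1] == -1


class TestOptimalDiscretization:
    def test_three_cluster_recovery(self, rng):
        centers = np.array([0.0, 10.0, 20.0])
        x = np.concatenate([c + rng.normal(0, 0.5, 50) for c in centers])
        y = np.concatenate([m + rng.normal(0, 0.3, 50)
                            for m in (1.0, 5.0, 9.0)])
        best = optimal_discretization(y, x, methods=("natural_breaks",),
                                      k_range=(2, 3))
        assert best.k == 3
        assert best.q > 0.9
        assert len(best.scan) == 2
        assert best.q == pytest.approx(best.scan["q"].max())

    def test_independent_factor_low_q(self, rng):
        y = rng.normal(size=1000)
        x = rng.normal(size=1000)
        best = optimal_discretization(y, x)
        assert best.q < 0.05

    def test_single_combination_returned(self, rng):
        y = rng.normal(size=50)
        x = rng.uniform(0, 1, 50)
        best = optimal_discretization(y, x, methods=("quantile",),
                                      k_range=(4,))
        assert best.method == "quantile" and best.k == 4


class TestFactorDetector:
    def make_sample(self, rng, n=300):
        y = rng.normal(size=n)
        return y

    def test_self_explanation_upper_bound(self, rng):
        y = rng.normal(size=400)
        sample = SampleTable(y=y, factors={"self": y.copy()})
        table = factor_detector(sample, k_range=(10,),
                                methods=("quantile",), n_perm=99, seed=1)
        row = table.iloc[0]
        assert row["q"] > 0.9
        assert row["p_value"] == pytest.approx(1 / 100)

    def test_noise_factor_not_significant(self, rng):
        hits = 0
        for rep in range(10):
            y = rng.normal(size=200)
            x = rng.normal(size=200)
            sample = SampleTable(y=y, factors={"noise": x})
            table = factor_detector(sample, k_range=(5,),
                                    methods=("quantile",), n_perm=99,
                                    seed=rep)
            if table.iloc[0]["p_value"] > 0.05:
                hits += 1
        assert hits >= 9

    def test_categorical_perfect_strata(self):
        y = np.array([1.0, 1, 1, 5, 5, 5, 9, 9, 9])
        codes = np.array([0.0, 0, 0, 1, 1, 1, 2, 2, 2])
        sample = SampleTable(y=y, factors={"lucc": codes},
                             categorical={"lucc"})
        table = factor_detector(sample, n_perm=49, seed=0)
        assert table.iloc[0]["q"] == pytest.approx(1.0, abs=1e-12)
        assert table.iloc[0]["method"] == "categorical"

    def test_single_value_factor_reported_missing(self, rng):
        y = rng.normal(size=50)
        sample = SampleTable(y=y, factors={"flat": np.ones(50)})
        table = factor_detector(sample, n_perm=9, seed=0)
        assert np.isnan(table.iloc[0]["q"])


class TestInteraction:
    def test_duplicate_factor_is_boundary_bifactor(self, rng):
        y = rng.normal(size=100)
        labels = rng.integers(0, 4, 100)
        q = q_statistic(y, labels)
        q_ij = interaction_q(y, labels, labels)
        assert q_ij == pytest.approx(q, abs=1e-12)
        assert classify_interaction(q, q, q_ij) == "bi-factor enhance"

    def test_xor_construction_nonlinear_enhance(self):
        # y determined only by the pair: crossed means cancel marginally
        a = np.repeat([0, 0, 1, 1], 25)
        b = np.tile(np.repeat([0, 1], 25), 2)
        y = np.where(a == b, 1.0, -1.0)
        q_a = q_statistic(y, a)
        q_b = q_statistic(y, b)
        q_ab = interaction_q(y, a, b)
        assert q_a == pytest.approx(0.0, abs=1e-12)
        assert q_b == pytest.approx(0.0, abs=1e-12)
        assert q_ab == pytest.approx(1.0, abs=1e-12)
        assert classify_interaction(q_a, q_b, q_ab) == "nonlinear enhance"

    def test_refinement_never_below_marginals(self, rng):
        for _ in range(200):
            n = int(rng.integers(20, 80))
            y = rng.normal(size=n)
            la = rng.integers(0, 4, n)
            lb = rng.integers(0, 3, n)
            q_ab = interaction_q(y, la, lb)
            assert q_ab >= q_statistic(y, la) - 1e-12
            assert q_ab >= q_statistic(y, lb) - 1e-12

    def test_independent_category(self):
        assert classify_interaction(0.3, 0.2, 0.5) == "independent"
        assert classify_interaction(0.3, 0.2, 0.45) == "bi-factor enhance"
        assert classify_interaction(0.3, 0.2, 0.1) == "nonlinear weaken"
        assert classify_interaction(0.3, 0.2, 0.25) == "single-factor weaken"
        assert classify_interaction(0.3, 0.2, 0.6) == "nonlinear enhance"


class TestSampleGrid:
    def test_spacing_counts(self, rng):
        g = make_grid(rng.uniform(0, 1, (4, 4)))
        f = make_grid(rng.uniform(0, 1, (4, 4)))
        assert sample_grid(g, {"f": f}, spacing=2).n == 4
        assert sample_grid(g, {"f": f}, spacing=1).n == 16

    def test_checkerboard_mask_halves_samples(self):
        vals = np.ones((6, 6))
        mask = (np.indices((6, 6)).sum(axis=0) % 2).astype(bool)
        g = make_grid(vals, mask=mask)
        f = make_grid(vals)
        assert sample_grid(g, {"f": f}, spacing=1).n == 18

    def test_masked_factor_cells_become_nan(self):
        g = make_grid(np.ones((2, 2)))
        fmask = np.array([[True, False], [False, False]])
        f = make_grid(np.ones((2, 2)), mask=fmask)
        table = sample_grid(g, {"f": f}, spacing=1)
        assert np.isnan(table.factors["f"][0])

    def test_no_valid_samples_raises(self):
        g = make_grid(np.full((3, 3), np.nan))
        with pytest.raises(DegenerateLayerError):
            sample_grid(g, {}, spacing=1)


class TestRunOpgd:
    def test_ranking_and_interaction_table(self, rng):
        n = 400
        strong = rng.integers(0, 4, n).astype(float)
        y = strong * 2.0 + rng.normal(0, 0.5, n)
        weak = rng.normal(size=n)
        sample = SampleTable(y=y, factors={"strong": strong, "weak": weak},
                             categorical={"strong"})
        res = run_opgd(sample, k_range=(5, 6), n_perm=49, seed=0)
        assert res.factor_q.iloc[0]["factor"] == "strong"
        assert len(res.interaction_q) == 1
        row = res.interaction_q.iloc[0]
        assert row["q_ij"] >= max(row["q_i"], row["q_j"]) - 1e-12
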