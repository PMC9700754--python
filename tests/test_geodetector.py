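import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rseikit.geodetector import (
    Stratification,
    classify_interaction,
    discretize,
    ecological_detect,
    factor_q,
    factor_q_value,
    grid_sample,
    interaction_detect,
    jenks_breaks,
    q_significance,
    risk_detect,
)
from rseikit.raster_core import Grid, RasterStack

from conftest import make_grid


def strat(labels) -> Stratification:
    return Stratification(np.asarray(labels, dtype=np.int64))


def jenks_ssw(values, breaks) -> float:
    """Within-class SS induced by a break list (classes = contiguous bins)."""
    values = np.sort(np.asarray(values, dtype=np.float64))
    labels = np.searchsorted(np.asarray(breaks), values, side="left")
    return sum(values[labels == c].var() * (labels == c).sum()
               for c in np.unique(labels))


def exhaustive_jenks_ssw(values, k) -> float:
    """Brute-force optimum over all contiguous k-partitions of sorted values."""
    x = np.sort(np.asarray(values, dtype=np.float64))
    n = x.size
    best = np.inf
    for cuts in itertools.combinations(range(1, n), k - 1):
        bounds = (0, *cuts, n)
        ssw = sum(x[a:b].var() * (b - a) for a, b in zip(bounds, bounds[1:]))
        best = min(best, ssw)
    return best


class TestGridSample:
    def _layers(self, shape=(10, 10), cell=500.0, origin_y=5000.0):
        rng = np.random.default_rng(0)
        resp = Grid(rng.uniform(0.2, 0.8, shape), origin_y=origin_y, cell_size=cell)
        cov = Grid(rng.normal(size=shape), origin_y=origin_y, cell_size=cell)
        return resp, RasterStack([cov], ["cov"])

    def test_spacing_equal_to_cell_gives_one_row_per_pixel(self):
        resp, covs = self._layers()
        assert len(grid_sample(resp, covs, 500.0)) == 100

    def test_1000m_spacing_on_10x10_500m_grid_gives_25_points(self):
        resp, covs = self._layers()
        assert len(grid_sample(resp, covs, 1000.0)) == 25

    def test_nodata_rows_dropped(self):
        resp, covs = self._layers()
        vals = covs[0].values.copy()
        # kill 3 lattice points of the 1000 m lattice (cells 1,1 / 1,3 / 3,5)
        vals[1, 1] = vals[1, 3] = vals[3, 5] = np.nan
        covs = RasterStack([covs[0].with_values(vals)], ["cov"])
        assert len(grid_sample(resp, covs, 1000.0)) == 22

    def test_abnormal_response_dropped(self):
        resp, covs = self._layers()
        vals = resp.values.copy()
        vals[1, 1] = 1.7  # outside [0, 1]
        resp = resp.with_values(vals)
        assert len(grid_sample(resp, covs, 1000.0)) == 24

    def test_all_rows_invalid_rejected(self):
        resp, covs = self._layers()
        bad = resp.with_values(np.full(resp.shape, np.nan))
        with pytest.raises(ValueError):
            grid_sample(bad, covs, 1000.0)


class TestJenks:
    def test_two_cluster_split(self):
        assert jenks_breaks([1, 2, 3, 10, 11, 12], 2) == [3.0]

    def test_k1_no_breaks(self):
        assert jenks_breaks([1, 5, 9], 1) == []

    def test_k_equals_distinct_gives_zero_ssw(self):
        vals = [1.0, 4.0, 9.0, 16.0]
        breaks = jenks_breaks(vals, 4)
        assert jenks_ssw(vals, breaks) == pytest.approx(0.0)

    def test_k_exceeding_distinct_rejected(self):
        with pytest.raises(ValueError):
            jenks_breaks([1, 1, 2], 3)

    def test_matches_exhaustive_search(self, rng):
        for trial in range(60):
            n = int(rng.integers(4, 13))
            k = int(rng.integers(2, 5))
            vals = rng.uniform(0, 100, n)
            if np.unique(vals).size < k:
                continue
            breaks = jenks_breaks(vals, k)
            assert jenks_ssw(vals, breaks) == pytest.approx(
                exhaustive_jenks_ssw(vals, k), abs=1e-8)

    def test_subsampled_path_still_orders_classes(self, rng):
        vals = rng.normal(size=500)
        breaks = jenks_breaks(vals, 4, max_n=100)
        assert breaks == sorted(breaks) and len(breaks) == 3


class TestDiscretize:
    def test_categorical_passthrough(self):
        codes = [5, 12, 12, 13, 5]
        s = discretize(codes, categorical=True)
        np.testing.assert_array_equal(s.labels, codes)
        assert s.L == 3

    def test_equal_ramp_gives_equal_classes(self):
        s = discretize(np.arange(1, 111, dtype=float), k=11)
        _, counts = np.unique(s.labels, return_counts=True)
        assert s.L == 11
        assert np.all(counts == 10)

    def test_constant_column_rejected(self):
        with pytest.raises(ValueError):
            discretize(np.full(20, 3.3), k=2)


class TestFactorQ:
    def test_fully_explanatory_strata(self):
        res = factor_q([2, 2, 2, 7, 7, 7], strat([1, 1, 1, 2, 2, 2]), reps=99)
        assert res.q == 1.0

    def test_uninformative_strata(self):
        res = factor_q([1, 3, 1, 3], strat([1, 1, 2, 2]), reps=99)
        assert res.q == 0.0

    def test_hand_oracle(self):
        res = factor_q([1, 2, 3, 4, 5, 6], strat([1, 1, 1, 2, 2, 2]), reps=99)
        # SSW = 4 (population variances), SST = 17.5
        assert res.q == pytest.approx(0.7714, abs=5e-5)
        assert res.q == pytest.approx(1 - res.ssw / res.sst)

    def test_constant_response_rejected(self):
        with pytest.raises(ValueError):
            factor_q([2.0, 2.0, 2.0, 2.0], strat([1, 1, 2, 2]), reps=9)

    @given(st.integers(0, 2 ** 31), st.floats(0.1, 10), st.floats(-5, 5))
    @settings(max_examples=30, deadline=None)
    def test_q_invariant_to_affine_response_transform(self, seed, a, b):
        rng = np.random.default_rng(seed)
        y = rng.normal(size=50)
        labels = rng.integers(1, 5, size=50)
        q1 = factor_q_value(y, strat(labels))
        q2 = factor_q_value(a * y + b, strat(labels))
        assert q2 == pytest.approx(q1, abs=1e-9)
        assert 0.0 <= q1 <= 1.0

    def test_refining_a_stratum_never_decreases_q(self, rng):
        y = rng.normal(size=120)
        labels = rng.integers(1, 5, size=120)
        q_coarse = factor_q_value(y, strat(labels))
        refined = labels.copy()
        half = (np.arange(120) % 2 == 0) & (labels == 1)
        refined[half] = 99
        assert factor_q_value(y, strat(refined)) >= q_coarse - 1e-12


class TestQSignificance:
    def test_perfect_strata_minimal_p(self):
        # n large enough that no random relabelling reproduces q = 1
        y = np.repeat([2.0, 7.0], 30)
        s = strat(np.repeat([1, 2], 30))
        p = q_significance(1.0, 60, 2, y, s, reps=199, seed=0)
        assert p == pytest.approx(1 / 200)

    def test_seed_reproducibility(self, rng):
        y = rng.normal(size=40)
        s = strat(rng.integers(1, 4, size=40))
        q = factor_q_value(y, s)
        p1 = q_significance(q, 40, s.L, y, s, reps=99, seed=5)
        p2 = q_significance(q, 40, s.L, y, s, reps=99, seed=5)
        assert p1 == p2

    def test_noncentral_f_detects_strong_effect(self, rng):
        y = np.concatenate([rng.normal(0, 0.2, 100), rng.normal(2, 0.2, 100)])
        s = strat(np.repeat([1, 2], 100))
        q = factor_q_value(y, s)
        p = q_significance(q, 200, 2, y, s, method="noncentral-F")
        assert p < 0.01

    def test_invalid_reps_rejected(self, rng):
        y = rng.normal(size=10)
        s = strat(rng.integers(1, 3, size=10))
        with pytest.raises(ValueError):
            q_significance(0.5, 10, 2, y, s, reps=0)


class TestInteraction:
    @pytest.mark.parametrize("q1, q2, q12, expected", [
        (0.2, 0.3, 0.6, "non-linear enhancement"),
        (0.2, 0.3, 0.45, "two-factor enhancement"),
        (0.2, 0.3, 0.5, "independent"),
        (0.2, 0.3, 0.25, "single-factor non-linear reduction"),
        (0.2, 0.3, 0.1, "non-linear reduction"),
    ])
    def test_decision_table(self, q1, q2, q12, expected):
        assert classify_interaction(q1, q2, q12) == expected

    def test_typing_is_total_and_exclusive_on_lattice(self):
        grid = np.linspace(0, 1, 50)
        types = set()
        for q1 in grid:
            for q2 in grid:
                for q12 in grid[::7]:
                    types.add(classify_interaction(q1, q2, q12))
        assert types <= {
            "non-linear reduction", "single-factor non-linear reduction",
            "two-factor enhancement", "independent", "non-linear enhancement"}

    def test_overlay_with_itself_returns_q1(self, rng):
        y = rng.normal(size=60)
        s = strat(rng.integers(1, 4, size=60))
        res = interaction_detect(y, s, s)
        assert res.q12 == pytest.approx(res.q1, abs=1e-12)
        assert res.type == "single-factor non-linear reduction"

    def test_true_refinement_dominates_both_factors(self, rng):
        y = rng.normal(size=200)
        a = strat(rng.integers(1, 4, size=200))
        b = strat(rng.integers(1, 4, size=200))
        res = interaction_detect(y, a, b)
        assert res.q12 >= res.q1 - 1e-12
        assert res.q12 >= res.q2 - 1e-12


class TestRiskDetect:
    def test_identical_groups_not_significant(self):
        res = risk_detect(np.array([1.0, 2, 3, 1, 2, 3]), strat([1, 1, 1, 2, 2, 2]))
        assert res.t[0, 1] == pytest.approx(0.0)
        assert not res.significant[0, 1]

    def test_hand_welch_value(self):
        res = risk_detect(np.array([0.5, 0.7, 0.2, 0.4]), strat([1, 1, 2, 2]))
        assert res.t[0, 1] == pytest.approx(0.3 / np.sqrt(0.02), abs=1e-9)

    def test_best_stratum_is_argmax_mean(self, rng):
        y = np.concatenate([rng.normal(0, 1, 50), rng.normal(5, 1, 50),
                            rng.normal(-2, 1, 50)])
        res = risk_detect(y, strat(np.repeat([10, 20, 30], 50)))
        assert res.best_stratum == 20

    def test_small_stratum_reports_mean_but_skips_tests(self):
        res = risk_detect(np.array([1.0, 2, 3, 9]), strat([1, 1, 1, 2]))
        assert res.means[1] == pytest.approx(9.0)
        assert np.isnan(res.t[0, 1])

    def test_t_matrix_symmetric_in_magnitude(self, rng):
        y = rng.normal(size=90)
        res = risk_detect(y, strat(rng.integers(1, 4, size=90)))
        finite = np.isfinite(res.t)
        np.testing.assert_allclose(np.abs(res.t[finite]),
                                   np.abs(res.t.T[finite.T]))


class TestEcologicalDetect:
    def test_same_stratification_f_is_one(self, rng):
        y = rng.normal(size=40)
        s = strat(rng.integers(1, 4, size=40))
        res = ecological_detect(y, s, s)
        assert res.F == pytest.approx(1.0)
        assert not res.significant

    def test_hand_value(self):
        res = ecological_detect([1, 2, 3, 4], strat([1, 1, 2, 2]), strat([1, 2, 1, 2]))
        assert res.F == pytest.approx(0.25)

    def test_reciprocity_under_exchange(self, rng):
        y = rng.normal(size=60)
        a = strat(rng.integers(1, 4, size=60))
        b = strat(rng.integers(1, 6, size=60))
        fwd = ecological_detect(y, a, b)
        rev = ecological_detect(y, b, a)
        assert rev.F == pytest.approx(1.0 / fwd.F)
        assert fwd.significant == rev.significant

    def test_zero_ssw_denominator_rejected(self):
        y = [1.0, 1.0, 2.0, 2.0]
        perfect = strat([1, 1, 2, 2])  # SSW = 0
        with pytest.raises(ValueError):
            ecological_detect(y, strat([1, 2, 1, 2]), perfect)
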