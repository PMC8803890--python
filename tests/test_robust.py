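"""Bootstrap windows, dimension selection, and the robust decision."""

import numpy as np
import pytest

from rccm import (
    LogisticMapParams,
    RCCMConfig,
    TimeSeries,
    ccm_curve,
    coupled_logistic_map,
    median_delta_curve,
    plan_windows,
    rccm_decide,
    select_dimension,
    split_train_test,
)
from rccm.embedding import EmbeddingConfig
from rccm.errors import InsufficientDataError


class TestPlanWindows:
    def test_eleven_years_ten_runs_gives_nine_year_windows(self):
        """506 samples at 46/year, 10 runs -> 10 windows of 414 samples
        whose start offsets span the 2 years of slack."""
        plan = plan_windows(506, 46, n_runs=10, min_valid_run=400)
        assert plan.n_runs == 10
        assert len(plan.windows) == 10
        assert all(e - s == 414 for s, e in plan.windows)
        starts = [s for s, _ in plan.windows]
        assert starts[0] == 0 and starts[-1] == 92
        assert starts == sorted(set(starts))

    def test_windows_are_whole_years(self):
        plan = plan_windows(506, 46, n_runs=10, min_valid_run=400)
        assert plan.window_length % 46 == 0

    def test_degenerate_single_run(self):
        plan = plan_windows(414, 46, n_runs=1, min_valid_run=414)
        assert plan.windows == [(0, 414)]

    def test_too_short_names_deficit(self):
        with pytest.raises(InsufficientDataError, match="short by"):
            plan_windows(300, 46, n_runs=10, min_valid_run=400)

    def test_cannot_fit_distinct_windows(self):
        with pytest.raises(InsufficientDataError, match="distinct"):
            plan_windows(414, 46, n_runs=10, min_valid_run=400)


class TestSplitTrainTest:
    @pytest.mark.parametrize(
        "length,train,test",
        [(414, 138, 276), (3, 1, 2), (300, 100, 200)],
    )
    def test_first_third_trains(self, length, train, test):
        (t0, t1), (s0, s1) = split_train_test((0, length))
        assert (t1 - t0, s1 - s0) == (train, test)
        assert t1 == s0


class TestMedianDeltaCurve:
    def test_single_run_is_plain_differences(self):
        np.testing.assert_allclose(
            median_delta_curve([[0.2, 0.5, 0.6]]), [0.3, 0.1]
        )

    def test_elementwise_median_across_runs(self):
        skills = [[0.0, 0.3, 0.4], [0.0, 0.1, 0.1], [0.0, 0.2, 0.4]]
        np.testing.assert_allclose(median_delta_curve(skills), [0.2, 0.1])

    def test_constant_skills_give_zero_curve(self):
        np.testing.assert_allclose(
            median_delta_curve([[0.5, 0.5, 0.5]]), [0.0, 0.0]
        )

    def test_single_library_size_flagged_empty(self):
        assert median_delta_curve([[0.5]]).size == 0


class TestSelectDimension:
    def test_forced_single_dimension(self, logistic_pair):
        x, y = logistic_pair
        plan = plan_windows(len(x), 50, 10, 400)
        dim, med = select_dimension(x, y, plan, [4], seed=0)
        assert dim == 4 and set(med) == {4}

    def test_logistic_system_selects_low_dimension(self):
        """The coupled logistic map is 2-D; selection should land in
        {2, 3} for the large majority of seeds."""
        cfg = RCCMConfig()
        hits = 0
        n = 12
        for s in range(n):
            x, y = coupled_logistic_map(
                LogisticMapParams(beta_yx=0.1, n_samples=506, seed=500 + s)
            )
            plan = plan_windows(506, 46, 10, 400)
            dim, _ = select_dimension(x, y, plan, range(1, 9), cfg, seed=s)
            hits += dim in (2, 3)
        assert hits >= 0.8 * n

    def test_white_noise_tie_breaks_to_smallest(self):
        rng = np.random.default_rng(8)
        x = TimeSeries(rng.normal(size=506))
        y = TimeSeries(rng.normal(size=506))
        plan = plan_windows(506, 46, 10, 400)
        dim, med = select_dimension(x, y, plan, range(1, 5), seed=0)
        assert max(abs(v) for v in med.values()) < 0.25
        assert dim in (1, 2, 3, 4)


@pytest.fixture(scope="module")
def decided():
    cfg = RCCMConfig(dim_min=1, dim_max=5)
    x, y = coupled_logistic_map(
        LogisticMapParams(beta_yx=0.3, r_y=3.5, n_samples=506, seed=6)
    )
    fwd = rccm_decide(x, y, cfg, seed=0)
    bwd = rccm_decide(y, x, cfg, seed=0)
    return fwd, bwd


class TestRccmDecide:
    def test_true_direction_convergent_with_causal_lag(self, decided):
        fwd, _ = decided
        assert fwd.convergent
        assert fwd.robust_skill > 0.8
        assert fwd.optimal_lag <= 0

    def test_false_direction_weaker_or_rejected(self, decided):
        fwd, bwd = decided
        assert (bwd.robust_skill < fwd.robust_skill) or (bwd.optimal_lag > 0)

    def test_identical_copies_are_instantaneous_and_strong(self):
        x, _ = coupled_logistic_map(
            LogisticMapParams(beta_yx=0.0, n_samples=506, seed=3)
        )
        y = TimeSeries(x.values.copy(), name="Y")
        # dimension 1: identical copies are a 1-D deterministic system,
        # and extra coordinates make adjacent lags degenerate
        dec = rccm_decide(x, y, RCCMConfig(), seed=0, dimension=1)
        assert dec.convergent
        assert dec.robust_skill > 0.99
        assert dec.optimal_lag == 0
        assert dec.acceptance.instantaneous

    def test_determinism_same_seed_same_decision(self):
        cfg = RCCMConfig(dim_min=2, dim_max=3)
        x, y = coupled_logistic_map(
            LogisticMapParams(beta_yx=0.2, r_y=3.5, n_samples=506, seed=10)
        )
        a = rccm_decide(x, y, cfg, seed=4)
        b = rccm_decide(x, y, cfg, seed=4)
        assert a.to_dict() == b.to_dict()
        np.testing.assert_array_equal(a.per_run_skills, b.per_run_skills)
        np.testing.assert_array_equal(a.median_lag_skills, b.median_lag_skills)

    def test_robust_skill_within_per_run_range(self, decided):
        """Median aggregation: rho-tilde is bounded by the per-run
        terminal skills at the optimal lag."""
        fwd, _ = decided
        col = int(np.flatnonzero(fwd.lags == fwd.optimal_lag)[0])
        per_run = fwd.per_run_lag_skills[:, col]
        assert np.nanmin(per_run) - 1e-12 <= fwd.robust_skill <= np.nanmax(per_run) + 1e-12

    def test_run_failure_policy_requires_half_surviving(self):
        x, y = coupled_logistic_map(
            LogisticMapParams(beta_yx=0.2, r_y=3.5, n_samples=506, seed=2)
        )
        # invalidate most of the series: windows fail the 400-sample rule
        mask = np.ones(506, dtype=bool)
        mask[100:400] = False
        xm = TimeSeries(x.values, mask=mask, name="X")
        with pytest.raises(InsufficientDataError, match="window"):
            rccm_decide(xm, y, RCCMConfig(), seed=0, dimension=2)

    def test_bootstrap_skill_more_stable_than_single_run(self):
        """Perturbing 10% of samples with sigma = 0.05 observation noise
        moves the bootstrapped median skill less than the single-run
        terminal skill, in median over seeds."""
        cfg = RCCMConfig()
        e2 = EmbeddingConfig(2, 1, 0)
        d_robust, d_plain = [], []
        for s in range(10):
            x, y = coupled_logistic_map(
                LogisticMapParams(beta_yx=0.15, r_y=3.5, n_samples=506, seed=700 + s)
            )
            rng = np.random.default_rng(s)
            idx = rng.choice(506, size=50, replace=False)
            yv = y.values.copy()
            yv[idx] += rng.normal(0, 0.05, idx.size)
            yn = TimeSeries(yv, name="Y")

            r0 = rccm_decide(x, y, cfg, seed=s, dimension=2).robust_skill
            r1 = rccm_decide(x, yn, cfg, seed=s, dimension=2).robust_skill
            c0 = ccm_curve(x, y, e2, rng=s, n_resamples=1, train_length=168).terminal_skill
            c1 = ccm_curve(x, yn, e2, rng=s, n_resamples=1, train_length=168).terminal_skill
            d_robust.append(abs(r1 - r0))
            d_plain.append(abs(c1 - c0))
        assert np.median(d_robust) <= np.median(d_plain)
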