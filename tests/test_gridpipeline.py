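"""Map products, stratified summaries, and pixel-wise orchestration."""

import numpy as np
import pytest

from rccm import (
    DominanceMap,
    RCCMConfig,
    dominance_map,
    regime_labels,
    run_pair,
    skill_difference_map,
    stratified_summary,
    synthetic_datacube,
)
from rccm.errors import ConfigError
from rccm.gridpipeline import FINAL_CODES, SKIP_CODE

SMALL_CFG = RCCMConfig(dim_min=1, dim_max=4)


class TestDominanceMap:
    def test_paper_threshold_examples(self):
        s1 = np.array([[0.95, 0.95, 0.50]])
        s2 = np.array([[0.30, 0.95, 0.50]])
        dom = dominance_map(s1, s2)
        assert dom.labels.tolist() == [
            [
                DominanceMap.LABELS["driver1"],
                DominanceMap.LABELS["joint"],
                DominanceMap.LABELS["none"],
            ]
        ]
        assert (dom.high, dom.low) == (0.9, 0.4)

    def test_driver2_symmetric(self):
        dom = dominance_map(np.array([[0.2]]), np.array([[0.95]]))
        assert dom.labels[0, 0] == DominanceMap.LABELS["driver2"]

    def test_missing_skill_propagates_as_masked(self):
        dom = dominance_map(np.array([[np.nan]]), np.array([[0.95]]))
        assert dom.labels[0, 0] == DominanceMap.LABELS["masked"]

    def test_inverted_thresholds_rejected(self):
        with pytest.raises(ConfigError):
            dominance_map(np.zeros((1, 1)), np.zeros((1, 1)), high=0.3, low=0.5)


class TestSkillDifferenceMap:
    def test_identical_grids_give_zero(self):
        s = np.random.default_rng(0).uniform(0, 1, (3, 3))
        np.testing.assert_array_equal(skill_difference_map(s, s), np.zeros((3, 3)))

    def test_swapping_arguments_negates(self):
        rng = np.random.default_rng(1)
        a, b = rng.uniform(0, 1, (2, 4)), rng.uniform(0, 1, (2, 4))
        np.testing.assert_allclose(
            skill_difference_map(a, b), -skill_difference_map(b, a)
        )

    def test_nan_propagates(self):
        a = np.array([[np.nan, 0.5]])
        b = np.array([[0.2, 0.1]])
        out = skill_difference_map(a, b)
        assert np.isnan(out[0, 0]) and out[0, 1] == pytest.approx(0.4)


class TestStratifiedSummary:
    def test_single_stratum_equals_global(self):
        v = np.random.default_rng(2).uniform(0, 1, 50)
        df, hists = stratified_summary(v, np.zeros(50, dtype=int))
        assert df.loc[0, "count"] == 50
        assert df.loc[0, "median"] == pytest.approx(np.median(v))
        assert hists[0][0].sum() == 50

    def test_constant_stratum_collapses_quartiles(self):
        v = np.concatenate([np.full(10, 0.7), np.random.uniform(0, 1, 10)])
        s = np.concatenate([np.zeros(10, int), np.ones(10, int)])
        df, _ = stratified_summary(v, s)
        assert df.loc[0, "median"] == df.loc[0, "q1"] == df.loc[0, "q3"] == 0.7

    def test_empty_stratum_reported_with_zero_count(self):
        v = np.array([np.nan, np.nan, 0.5])
        s = np.array([0, 0, 1])
        df, _ = stratified_summary(v, s)
        assert df.loc[0, "count"] == 0 and np.isnan(df.loc[0, "median"])

    def test_planted_coupling_orders_strata_medians(self):
        rng = np.random.default_rng(3)
        weak = rng.normal(0.3, 0.02, 30)
        strong = rng.normal(0.9, 0.02, 30)
        v = np.concatenate([weak, strong])
        s = np.repeat([0, 1], 30)
        df, _ = stratified_summary(v, s)
        assert df.loc[0, "median"] < df.loc[1, "median"]


class TestRunPair:
    def test_all_masked_input_skips_every_pixel(self):
        cube = synthetic_datacube((2, 2), n_years=11, samples_per_year=46, seed=0)
        res = run_pair(cube, "A", "B", SMALL_CFG, seed=0, mask=np.ones((2, 2), bool))
        assert all(p.skipped and p.reason == "masked" for p in res.pixels)
        assert (res.maps["final_ab"].values == SKIP_CODE).all()

    def test_every_pixel_accounted_for(self):
        cube = synthetic_datacube(
            (2, 2), n_years=11, samples_per_year=46,
            regime_layout="independent", seed=1,
        )
        mask = np.array([[True, False], [False, False]])
        res = run_pair(cube, "A", "B", SMALL_CFG, seed=0, mask=mask)
        assert len(res.pixels) == 4
        assert res.n_skipped == 1

    def test_short_series_pixels_skip_not_error(self):
        cube = synthetic_datacube((1, 2), n_years=2, samples_per_year=46, seed=2)
        res = run_pair(cube, "A", "B", SMALL_CFG, seed=0)
        assert all(p.skipped for p in res.pixels)
        assert all(p.reason == "insufficient_data" for p in res.pixels)

    def test_absent_variable_is_config_error(self):
        cube = synthetic_datacube((1, 1), n_years=2, samples_per_year=10, seed=0)
        with pytest.raises(ConfigError, match="not present"):
            run_pair(cube, "A", "Q", SMALL_CFG)

    def test_null_cube_detects_no_links(self):
        """Independent pixels: nothing passes the 0.8 skill threshold."""
        cube = synthetic_datacube(
            (2, 2), n_years=11, samples_per_year=46,
            regime_layout="independent", seed=3,
        )
        res = run_pair(cube, "A", "B", SMALL_CFG, seed=0)
        labels = regime_labels(res)
        assert (labels == 0).all()

    def test_pixel_independence(self):
        """A pixel's decision is identical run alone or in a grid."""
        cube = synthetic_datacube(
            (1, 2), n_years=11, samples_per_year=46,
            regime_layout="a_drives_b", seed=4,
        )
        full = run_pair(cube, "A", "B", SMALL_CFG, seed=9)
        alone = run_pair(
            cube, "A", "B", SMALL_CFG, seed=9,
            mask=np.array([[False, True]]),
        )
        assert (
            full.maps["skill_ab"].values[0, 0]
            == alone.maps["skill_ab"].values[0, 0]
        )
        assert (
            full.maps["final_ab"].values[0, 0]
            == alone.maps["final_ab"].values[0, 0]
        )

    def test_directed_regime_recovered(self):
        cube = synthetic_datacube(
            (1, 2), n_years=11, samples_per_year=46,
            regime_layout="a_drives_b", seed=5,
        )
        res = run_pair(cube, "A", "B", SMALL_CFG, seed=0)
        labels = regime_labels(res)
        assert (labels == 1).all()
        assert (res.maps["final_ab"].values == FINAL_CODES["kept"]).all()
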