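"""Tests for region-wise statistics and asymmetry recovery."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import binom

import centrotrace as ct
from centrotrace.errors import ParameterError
from centrotrace.stats import (
    InferenceConfig,
    compare_regions,
    count_by_colour,
    colour_proportions,
    estimate_asymmetry,
    fate_counts_from_cohort,
    fate_percentages,
    region_count_ratio,
    stars,
)


def six_punctum_table():
    rows = [
        (0, "VENT", "ORANGE"),
        (0, "VENT", "ORANGE"),
        (0, "VENT", "GREEN"),
        (0, "NONVENT", "GREEN"),
        (0, "NONVENT", "GREEN"),
        (0, "NONVENT", "GREEN"),
    ]
    return pd.DataFrame(rows, columns=["unit_id", "region", "colour"])


class TestCounts:
    def test_hand_built_tallies(self):
        counts, extras = count_by_colour(six_punctum_table())
        wide = counts.set_index(["region", "colour"])["count"]
        assert wide["VENT", "ORANGE"] == 2
        assert wide["VENT", "GREEN"] == 1
        assert wide["NONVENT", "GREEN"] == 3
        assert wide["VENT", "YELLOW"] == 0
        assert counts["count"].sum() == 6

    def test_zero_puncta_all_zero(self):
        empty = six_punctum_table().iloc[0:0]
        counts, _ = count_by_colour(empty)
        assert counts.empty or (counts["count"] == 0).all()

    def test_shuffle_invariance(self):
        t = six_punctum_table()
        a, _ = count_by_colour(t)
        b, _ = count_by_colour(t.sample(frac=1.0, random_state=3).reset_index(drop=True))
        assert a.equals(b)

    def test_missing_labels_listed(self):
        t = six_punctum_table()
        t.loc[2, "colour"] = None
        with pytest.raises(ParameterError, match="rows \\[2\\]"):
            count_by_colour(t)

    def test_unrecombined_and_excluded_reported_separately(self):
        t = six_punctum_table()
        t.loc[len(t)] = (0, "EXCLUDED", "GREEN")
        t.loc[len(t)] = (0, "VENT", "UNRECOMBINED")
        counts, extras = count_by_colour(t)
        assert counts["count"].sum() == 6
        assert extras.loc[0, "excluded"] == 1
        assert extras.loc[0, "unrecombined"] == 1


class TestProportions:
    def test_vent_proportions(self):
        counts, _ = count_by_colour(six_punctum_table())
        props = colour_proportions(counts)
        vent = props[props["region"] == "VENT"].set_index("colour")["proportion"]
        assert vent["ORANGE"] == pytest.approx(2 / 3)
        assert vent["YELLOW"] == 0.0
        assert vent["GREEN"] == pytest.approx(1 / 3)

    def test_each_region_sums_to_one(self):
        counts, _ = count_by_colour(six_punctum_table())
        props = colour_proportions(counts)
        sums = props.groupby(["unit_id", "region"])["proportion"].sum()
        assert np.allclose(sums, 1.0)

    def test_region_count_ratio_example(self):
        counts, _ = count_by_colour(six_punctum_table())
        ratio = region_count_ratio(counts)
        assert ratio["GREEN"] == pytest.approx(1 / 3)


class TestCompareRegions:
    def test_identical_groups(self):
        r = compare_regions([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (r.t, r.p, r.stars) == (0.0, 1.0, "ns")

    def test_large_shift_is_three_stars(self):
        r = compare_regions([1.0, 2.0, 3.0], [11.0, 12.0, 13.0])
        assert r.p < 0.001 and r.stars == "***"

    def test_closed_form_worked_example(self):
        """Pooled t for A=(1,2,3,4), B=(2,4,6,8): means 2.5 and 5, pooled
        variance 25/6, hence t = -2.5 / sqrt(25/6 * 1/2) = -sqrt(3)."""
        r = compare_regions([1.0, 2.0, 3.0, 4.0], [2.0, 4.0, 6.0, 8.0])
        assert r.t == pytest.approx(-np.sqrt(3.0), abs=1e-10)
        from scipy import stats as sps

        assert r.p == pytest.approx(2 * sps.t.sf(np.sqrt(3.0), 6), abs=1e-12)

    def test_zero_variance_unequal_means(self):
        r = compare_regions([1.0, 1.0], [2.0, 2.0])
        assert r.p == 0.0
        assert not np.isfinite(r.t)

    def test_small_groups_rejected(self):
        with pytest.raises(ParameterError):
            compare_regions([1.0], [1.0, 2.0])

    def test_star_thresholds(self):
        assert stars(0.2) == "ns"
        assert stars(0.04) == "*"
        assert stars(0.004) == "**"
        assert stars(0.0004) == "***"

    def test_welch_flag(self):
        r = compare_regions([1.0, 2.0, 3.0], [10.0, 20.0, 30.0, 40.0], equal_var=False)
        assert r.p < 0.1


class TestFates:
    def test_percentages_example(self):
        fates = pd.DataFrame(
            [{"unit_id": 0, "n_targeted": 10, "n_sox2": 7, "n_ctip2": 2, "n_undefined": 1}]
        )
        out = fate_percentages(fates)
        assert out.loc[0, "pct_sox2"] == 70.0
        assert out.loc[0, "pct_ctip2"] == 20.0

    def test_percentages_bounded(self):
        cfg = ct.SimConfig(n_units=4, n_lineages_per_unit=8, n_div=3, q_diff=0.3, seed=1)
        out = fate_percentages(fate_counts_from_cohort(ct.simulate_cohort(cfg)))
        assert (out["pct_sox2"] <= 100).all()
        assert ((out["pct_sox2"] + out["pct_ctip2"]) <= 100 + 1e-9).all()

    def test_zero_targeted_excluded(self):
        fates = pd.DataFrame(
            [
                {"unit_id": 0, "n_targeted": 0, "n_sox2": 0, "n_ctip2": 0, "n_undefined": 0},
                {"unit_id": 1, "n_targeted": 4, "n_sox2": 2, "n_ctip2": 1, "n_undefined": 1},
            ]
        )
        with pytest.warns(UserWarning):
            out = fate_percentages(fates)
        assert list(out["unit_id"]) == [1]

    def test_randomised_inheritance_with_coupling_lowers_sox2(self):
        """Ninein-knockdown-like condition (random inheritance plus fate
        coupling) yields fewer self-renewing SOX2 cells than wild-type."""
        wt = ct.SimConfig(p_asym=0.9, q_diff=0.0, n_units=8, seed=2)
        kd = ct.SimConfig(p_asym=0.5, q_diff=0.3, n_units=8, seed=2)
        pct = {
            name: fate_percentages(fate_counts_from_cohort(ct.simulate_cohort(cfg)))[
                "pct_sox2"
            ].mean()
            for name, cfg in (("wt", wt), ("kd", kd))
        }
        assert pct["kd"] < pct["wt"]


class TestEstimateAsymmetry:
    def study_classified(self, p_asym, n_units=10, n_div=1, tau=0.0, f_rec=1.0, seed=0):
        sim = ct.SimConfig(
            p_asym=p_asym, tau=tau, n_div=n_div, f_rec=f_rec, n_units=n_units,
            n_lineages_per_unit=12, seed=seed,
        )
        res = ct.run_study(ct.StudyConfig(sim=sim))
        return res.classified[~res.classified["colour"].isna()]

    @pytest.mark.parametrize("truth", [0.0, 1.0])
    def test_moment_estimator_exact_at_extremes(self, truth):
        classified = self.study_classified(truth, n_units=4)
        est = estimate_asymmetry(classified, InferenceConfig(n_div=1, tau=0.0, n_boot=50))
        assert est.p_hat == truth
        assert est.method == "moment"

    def test_moment_estimator_binomial_interval_at_half(self):
        """500 single-division lineages at p=0.5: the oldest-class VENT share
        sits inside the central 99% binomial interval."""
        sim = ct.SimConfig(p_asym=0.5, tau=0.0, n_div=1, f_rec=1.0, n_units=50,
                           n_lineages_per_unit=10, seed=21)
        res = ct.run_study(ct.StudyConfig(sim=sim))
        classified = res.classified[~res.classified["colour"].isna()]
        est = estimate_asymmetry(classified, InferenceConfig(n_div=1, tau=0.0, n_boot=50))
        n_orange = int((classified["colour"] == "ORANGE").sum())
        lo, hi = binom.ppf([0.005, 0.995], n_orange, 0.5) / n_orange
        assert lo <= est.p_hat <= hi

    def test_grid_estimator_recovers_strong_asymmetry(self):
        classified = self.study_classified(
            0.9, n_units=30, n_div=6, tau=0.05, f_rec=0.4, seed=5
        )
        est = estimate_asymmetry(
            classified, InferenceConfig(n_div=6, tau=0.05, ref_units=200, n_boot=50, seed=5)
        )
        assert est.method == "grid-l2"
        assert abs(est.p_hat - 0.9) < 0.05
        assert est.ci_low <= est.p_hat <= est.ci_high

    def test_no_recombined_is_an_error(self):
        classified = pd.DataFrame(columns=["unit_id", "region", "colour"])
        with pytest.raises(ParameterError):
            estimate_asymmetry(classified, InferenceConfig())
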