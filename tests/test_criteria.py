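"""MetS component flags: presets, percentile references, classification logic."""

import itertools

import numpy as np
import pandas as pd
import pytest

from cmets.criteria import (
    CriteriaConfig,
    EmpiricalPercentiles,
    MetSClassifier,
    fit_empirical_percentiles,
    flag_components,
    interpolated_percentile,
    preset,
    secondary_flags,
)
from cmets.derived import add_derived_measures


class TestPresets:
    def test_methods_text_thresholds(self):
        c = preset("methods_text")
        assert (c.tg_cmp, c.tg_threshold) == (">=", 150.0)
        assert (c.hdl_cmp, c.hdl_threshold) == ("<=", 40.0)
        assert (c.fbg_cmp, c.fbg_threshold) == (">=", 100.0)
        assert c.abdominal_rule == "whtr_gt_0.5"
        assert c.bp_percentile == 90.0 and c.mets_min_components == 3

    def test_table_footnote_thresholds(self):
        c = preset("table_footnote")
        assert (c.tg_cmp, c.tg_threshold) == (">", 100.0)
        assert (c.hdl_cmp, c.hdl_threshold) == ("<", 40.0)
        assert c.abdominal_rule == "wc_gt_90th_pct"
        # adolescent-boys HDL override
        assert c.hdl_threshold_for("male", "15-18") == 45.0
        assert c.hdl_threshold_for("female", "15-18") == 40.0
        assert c.hdl_threshold_for("male", "7-10") == 40.0

    def test_unknown_preset(self):
        with pytest.raises(ValueError, match="unknown preset"):
            preset("nonsense")

    def test_yaml_round_trip(self, tmp_path):
        c = preset("table_footnote")
        path = tmp_path / "criteria.yaml"
        c.to_yaml(path)
        back = CriteriaConfig.from_yaml(path)
        assert back == c


class TestInterpolatedPercentile:
    def test_linear_interpolation_on_1_to_100(self):
        assert interpolated_percentile(np.arange(1, 101), 90) == pytest.approx(90.1)

    def test_constant_sample(self):
        assert interpolated_percentile([5, 5, 5], 90) == 5

    def test_level_100_is_max(self):
        assert interpolated_percentile([1, 2, 3], 100) == 3

    def test_rejects_empty_and_bad_level(self):
        with pytest.raises(ValueError):
            interpolated_percentile([], 90)
        with pytest.raises(ValueError):
            interpolated_percentile([1, 2], 150)


def _reference_cohort(n_per_sex=30, seed=0):
    rng = np.random.default_rng(seed)
    n = 2 * n_per_sex
    return pd.DataFrame(
        {
            "id": np.arange(n),
            "age": rng.uniform(8.0, 9.0, n),
            "sex": ["male"] * n_per_sex + ["female"] * n_per_sex,
            "weight": rng.uniform(25, 35, n),
            "height": rng.uniform(120, 140, n),
            "wc": rng.uniform(50, 70, n),
            "sbp": rng.uniform(85, 105, n),
            "dbp": rng.uniform(55, 65, n),
            "fbg": rng.uniform(85, 95, n),
            "tg": rng.uniform(60, 120, n),
            "tc": rng.uniform(130, 170, n),
            "hdl": rng.uniform(42, 55, n),
            "ldl": rng.uniform(70, 100, n),
        }
    )


class TestFlagLogic:
    @pytest.mark.parametrize(
        "preset_name,tg,expected",
        [
            ("methods_text", 150.0, True),   # inclusive at the cutoff
            ("methods_text", 149.9, False),
            ("table_footnote", 150.0, True),
            ("table_footnote", 100.0, False),  # strict > at the cutoff
            ("table_footnote", 100.1, True),
        ],
    )
    def test_tg_comparators(self, preset_name, tg, expected):
        cohort = _reference_cohort()
        clf = MetSClassifier(criteria=preset_name).fit(cohort)
        subject = cohort.iloc[0].to_dict()
        subject["tg"] = tg
        flags = flag_components(subject, clf.criteria_, clf.reference_)
        assert flags.high_tg is expected

    def test_all_32_flag_combinations_brute_force(self):
        """n_components always equals the flag count; MetS iff count >= 3."""
        cohort = _reference_cohort()
        clf = MetSClassifier(criteria="methods_text").fit(cohort)
        ref = clf.reference_
        sbp90, dbp90 = (v[0] for v in ref.bp_p90(["male"], [8.5], [130.0]))
        for combo in itertools.product([False, True], repeat=5):
            want_tg, want_hdl, want_fbg, want_abd, want_bp = combo
            subject = dict(
                age=8.5, sex="male", weight=30.0, height=130.0,
                wc=70.0 if want_abd else 55.0,          # WHtR 0.538 vs 0.423
                sbp=sbp90 + 10.0 if want_bp else min(sbp90 - 1.0, 100.0),
                dbp=56.0,                                # below any dbp90 here
                fbg=110.0 if want_fbg else 90.0,
                tg=160.0 if want_tg else 100.0,
                tc=150.0, hdl=35.0 if want_hdl else 50.0, ldl=90.0,
            )
            assert dbp90 > 56.0  # guard: BP flag controlled via SBP only
            flags = flag_components(subject, clf.criteria_, clf.reference_)
            got = (flags.high_tg, flags.low_hdl, flags.high_fbg,
                   flags.abdominal_obesity, flags.elevated_bp)
            assert got == combo
            assert flags.n_components == sum(combo)
            assert flags.mets is (sum(combo) >= 3)

    def test_raising_threshold_never_increases_count(self, classified50k, cohort50k):
        base = classified50k["high_tg"].sum()
        stricter = preset("table_footnote")
        stricter.tg_threshold = 150.0
        clf = MetSClassifier(criteria=stricter).fit(cohort50k)
        assert clf.transform(cohort50k)["high_tg"].sum() <= base

    def test_elevated_bp_is_or_of_the_two_pressures(self, classified50k):
        df = classified50k
        expected = df["elevated_sbp"] | df["elevated_dbp"]
        assert df["elevated_bp"].equals(expected)

    def test_missing_measurements_are_excluded_and_counted(self):
        cohort = _reference_cohort(n_per_sex=40)
        cohort.loc[cohort.index[:5], "tg"] = np.nan
        clf = MetSClassifier().fit(cohort)
        out = clf.transform(cohort)
        assert clf.n_excluded_ == 5
        assert out["mets"].isna().sum() == 5
        assert out["n_components"].isna().sum() == 5


class TestEmpiricalReference:
    def test_flagged_fraction_bounded_by_level(self, footnote_classifier, cohort50k):
        """Strict '>' above an empirical 90th percentile flags <= 10% + 1/n per bin."""
        ref = footnote_classifier.reference_
        age_year = np.floor(cohort50k["age"]).astype(int)
        for s in ("male", "female"):
            sel = cohort50k["sex"] == s
            bins = age_year[sel].map(ref.age_bin_map_[s])
            for b, grp in cohort50k[sel].groupby(bins):
                frac = (grp["wc"] > ref.wc_p90_[(s, b)]).mean()
                assert frac <= 0.10 + 1.0 / len(grp)

    def test_small_age_bins_are_merged(self):
        parts = []
        for s in ("male", "female"):
            a = _reference_cohort(n_per_sex=30, seed=1)
            a = a[a["sex"] == s].copy()
            a["age"] = 8.5
            b = a.iloc[:8].copy()
            b["age"] = 7.2  # only 8 subjects aged 7: below min_bin
            parts += [a, b]
        cohort = pd.concat(parts, ignore_index=True)
        ref = fit_empirical_percentiles(cohort, min_bin=20)
        for s in ("male", "female"):
            assert ref.age_bin_map_[s][7] == ref.age_bin_map_[s][8]

    def test_too_few_subjects_even_after_merging(self):
        tiny = _reference_cohort(n_per_sex=8)
        with pytest.raises(ValueError, match="too few"):
            fit_empirical_percentiles(tiny, min_bin=20)

    def test_external_bp_table(self, tmp_path):
        cohort = _reference_cohort()
        rows = []
        for s in ("male", "female"):
            for band in ("0-33.3", "33.3-66.7", "66.7-100"):
                rows.append(
                    {"sex": s, "age_year": 8, "height_percentile_band": band,
                     "sbp_p90": 60.0, "dbp_p90": 30.0}
                )
        path = tmp_path / "bp.csv"
        pd.DataFrame(rows).to_csv(path, index=False)
        clf = MetSClassifier(percentile_mode="external", external_bp=str(path))
        out = clf.fit(cohort).transform(cohort)
        assert out["elevated_bp"].all()  # thresholds far below every reading

    def test_external_bp_table_must_cover_cohort(self, tmp_path):
        cohort = _reference_cohort()
        path = tmp_path / "bp.csv"
        pd.DataFrame(
            [{"sex": "male", "age_year": 15, "height_percentile_band": "0-100",
              "sbp_p90": 110.0, "dbp_p90": 70.0}]
        ).to_csv(path, index=False)
        clf = MetSClassifier(percentile_mode="external", external_bp=str(path))
        with pytest.raises(ValueError, match="no row"):
            clf.fit(cohort).transform(cohort)


class TestSecondaryFlags:
    def test_lipid_boundaries_are_strict(self):
        cohort = _reference_cohort()
        ref = fit_empirical_percentiles(cohort)
        probe = cohort.iloc[:4].copy()
        probe["ldl"] = [110.0, 110.1, 90.0, 90.0]
        probe["tc"] = [150.0, 150.0, 200.0, 200.1]
        out = secondary_flags(probe, ref)
        assert list(out["high_ldl"]) == [False, True, False, False]
        assert list(out["high_tc"]) == [False, False, False, True]

    def test_bmi_percentile_bands(self):
        cohort = _reference_cohort(n_per_sex=50, seed=3)
        ref = fit_empirical_percentiles(cohort)
        p85, p95 = ref.bmi_p85_p95(["male"], [8.5])
        probe = cohort.iloc[:3].copy()
        probe["sex"] = "male"
        probe["age"] = 8.5
        # place BMI via weight at fixed height
        probe["height"] = 100.0
        probe["weight"] = [p95[0] + 1.0, (p85[0] + p95[0]) / 2, p85[0] - 1.0]
        out = secondary_flags(probe.drop(columns=["bmi"], errors="ignore"), ref)
        assert list(out["obese"]) == [True, False, False]
        assert list(out["overweight"]) == [False, True, False]

    def test_overweight_and_obese_mutually_exclusive(self, classified50k, footnote_classifier):
        out = secondary_flags(classified50k, footnote_classifier.reference_)
        both = (out["overweight"] & out["obese"]).fillna(False)
        assert not both.any()
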