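"""Benefit-risk statistics: utility ranges, ARI, MAR, uncertainty, subgroups,
sensitivity."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import hemodce as h


class TestRanges:
    def test_published_coefficients_give_known_ranges(self, aset, params):
        ranges = h.attribute_ranges(params.mean, aset)
        assert ranges["annual_bleeds"] == pytest.approx(3.64)
        assert ranges["inhibitor_risk"] == pytest.approx(0.79 * 4)
        assert ranges["dosing_freq"] == pytest.approx(1.58)
        assert ranges["dosing_mode"] == pytest.approx(1.35)

    def test_flat_attribute_has_zero_range(self, aset, params):
        coefs = dict(params.mean)
        coefs["dosing_freq[1]"] = coefs["dosing_freq[2]"] = 0.0
        assert h.attribute_ranges(coefs, aset)["dosing_freq"] == 0.0

    def test_negation_leaves_ranges_unchanged(self, aset, params):
        base = h.attribute_ranges(params.mean, aset)
        neg = h.attribute_ranges({c: -v for c, v in params.mean.items()}, aset)
        for a in base:
            assert neg[a] == pytest.approx(base[a])

    def test_missing_coefficient_rejected(self, aset, params):
        coefs = dict(params.mean); coefs.pop("inhibitor_risk")
        with pytest.raises(KeyError):
            h.attribute_ranges(coefs, aset)


class TestRelativeImportance:
    def test_published_scores(self, aset, params):
        ari, raw, shares = h.relative_importance(params.mean, aset)
        assert ari == {"annual_bleeds": 100, "inhibitor_risk": 87,
                       "dosing_freq": 43, "dosing_mode": 37}
        assert sum(shares.values()) == pytest.approx(1.0)
        assert max(raw.values()) == pytest.approx(100.0)

    def test_equal_ranges_both_score_100(self):
        aset = h.AttributeSet((
            h.Attribute(name="a", coding="categorical", levels=(0, 1), reference=0),
            h.Attribute(name="b", coding="categorical", levels=(0, 1), reference=0),
        ))
        ari, _, _ = h.relative_importance({"a[1]": 2.0, "b[1]": -2.0}, aset)
        assert ari == {"a": 100, "b": 100}

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(st.floats(min_value=0.01, max_value=100.0))
    def test_scale_invariance(self, scale):
        aset = h.hemophilia_attributes()
        mean = h.study_parameters().mean
        base_ari, base_raw, base_shares = h.relative_importance(mean, aset)
        scaled = {c: scale * v for c, v in mean.items()}
        ari, raw, shares = h.relative_importance(scaled, aset)
        assert ari == base_ari
        for a in raw:
            assert raw[a] == pytest.approx(base_raw[a], rel=1e-9)
            assert shares[a] == pytest.approx(base_shares[a], rel=1e-9)

    def test_ordering_matches_raw_ranges(self, aset, params):
        ranges = h.attribute_ranges(params.mean, aset)
        _, raw, _ = h.relative_importance(params.mean, aset)
        assert sorted(ranges, key=ranges.get) == sorted(raw, key=raw.get)

    def test_all_zero_ranges_rejected(self, aset, params):
        with pytest.raises(ValueError):
            h.relative_importance({c: 0.0 for c in params.mean}, aset)


class TestMAR:
    def test_published_values(self, aset, params):
        rep = h.tradeoff_report(params.mean, aset, h.standard_changes())
        assert list(rep.mars.values()) == [4.6, 2.3, 2.0, 1.5, 1.7, 0.9]

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(st.floats(min_value=0.01, max_value=100.0))
    def test_scale_invariance(self, scale):
        aset = h.hemophilia_attributes()
        mean = h.study_parameters().mean
        change = h.AttributeChange("annual_bleeds", 12, 0)
        base = h.mar(mean, aset, change)
        scaled = h.mar({c: scale * v for c, v in mean.items()}, aset, change)
        assert scaled == pytest.approx(base, rel=1e-9)

    def test_error_cases(self, aset, params):
        with pytest.raises(ValueError, match="differ"):
            h.AttributeChange("dosing_freq", 3, 3)
        with pytest.raises(ValueError, match="risk attribute itself"):
            h.mar(params.mean, aset, h.AttributeChange("inhibitor_risk", 0.0, 4.0))
        zero_risk = dict(params.mean); zero_risk["inhibitor_risk"] = 0.0
        with pytest.raises(ValueError, match="zero risk"):
            h.mar(zero_risk, aset, h.AttributeChange("annual_bleeds", 12, 0))

    def test_utility_neutral_change_gives_zero(self, aset, params):
        coefs = dict(params.mean)
        coefs["dosing_freq[1]"] = coefs["dosing_freq[2]"] = 1.0
        assert h.mar(coefs, aset, h.AttributeChange("dosing_freq", 2, 1)) == 0.0


@pytest.fixture(scope="module")
def mnl_result(small_dataset):
    return h.fit_mnl(small_dataset)


class TestMARUncertainty:
    def test_zero_covariance_collapses_to_point(self, aset, mnl_result):
        change = h.AttributeChange("annual_bleeds", 12, 0)
        point = h.mar(mnl_result, aset, change)

        class Frozen:
            params = mnl_result.params
            def cov_params(self):
                z = mnl_result.cov_params()
                return z * 0.0

        lo, hi = h.mar_uncertainty(Frozen(), aset, change, n_sim=200, seed=1)
        assert lo == pytest.approx(point) and hi == pytest.approx(point)

    def test_interval_contains_point_estimate(self, aset, mnl_result):
        change = h.AttributeChange("annual_bleeds", 12, 0)
        point = h.mar(mnl_result, aset, change)
        lo, hi = h.mar_uncertainty(mnl_result, aset, change, n_sim=10000, seed=2)
        assert lo <= point <= hi

    def test_wider_covariance_never_narrows_interval(self, aset, mnl_result):
        change = h.AttributeChange("annual_bleeds", 12, 6)
        lo1, hi1 = h.mar_uncertainty(mnl_result, aset, change, n_sim=10000, seed=3)

        class Inflated:
            params = mnl_result.params
            def cov_params(self):
                return mnl_result.cov_params() * 4.0

        lo2, hi2 = h.mar_uncertainty(Inflated(), aset, change, n_sim=10000, seed=3)
        assert hi2 - lo2 >= hi1 - lo1

    def test_deterministic_under_seed(self, aset, mnl_result):
        change = h.AttributeChange("dosing_mode", "drip", "push")
        a = h.mar_uncertainty(mnl_result, aset, change, n_sim=500, seed=4)
        assert a == h.mar_uncertainty(mnl_result, aset, change, n_sim=500, seed=4)


class TestReport:
    def test_report_rounding_and_raw_values(self, aset, params):
        rep = h.tradeoff_report(params.mean, aset, h.standard_changes())
        label = "annual_bleeds: 12 -> 0"
        assert rep.mars[label] == 4.6
        assert rep.mars_raw[label] == pytest.approx(3.64 / 0.79)
        assert rep.ari_raw["inhibitor_risk"] == pytest.approx(100 * 3.16 / 3.64)

    def test_json_and_frame_outputs(self, tmp_path, aset, params):
        rep = h.tradeoff_report(params.mean, aset, h.standard_changes())
        path = tmp_path / "report.json"
        rep.write_json(path)
        import json

        loaded = json.loads(path.read_text())
        assert loaded["ari"]["annual_bleeds"] == 100
        frame = rep.to_frame()
        assert set(frame.columns) == {"range", "ari", "share"}

    def test_mar_plot_written(self, tmp_path, aset, params):
        rep = h.tradeoff_report(params.mean, aset, h.standard_changes())
        out = tmp_path / "mar.png"
        from hemodce.tradeoff import plot_mar

        plot_mar(rep, out)
        assert out.stat().st_size > 0


class TestSubgroups:
    def test_single_group_reproduces_overall_report(self, study_design, params):
        ds = h.simulate_study(80, params, design=study_design, seed=151)
        ds.covariates["location"] = "rural"
        spec = h.ModelSpec(attribute_set=ds.attribute_set, asc=True,
                           random_columns=("ASC", "annual_bleeds[0]",
                                           "inhibitor_risk",
                                           "dosing_mode[subcutaneous]"))
        res = h.MixedLogit(ds, spec).fit(n_draws=100, seed=5, gtol=1e-5)
        groups = h.subgroup_compare(ds, res, "location")
        assert list(groups) == ["rural"]
        indiv = res.individual_params()
        pooled = h.tradeoff_report(
            indiv.drop(columns="respondent_id").mean().to_dict(),
            ds.attribute_set)
        assert groups["rural"].ari == pooled.ari

    def test_planted_rural_mode_preference_flips_ordering(self, study_design,
                                                          params):
        """Rural respondents weight dosing mode up and urban respondents weight
        dosing frequency up; the per-group ARI orderings must flip
        accordingly."""
        n = 400
        cov = h.generate_covariates(n, h.study_covariate_proportions(), seed=161)
        betas = h.sample_individual_betas(params.with_sd_zero(), n, seed=162)
        rural = (cov["location"] == "rural").to_numpy()
        for c in ("dosing_mode[push]", "dosing_mode[subcutaneous]"):
            betas.loc[rural, c] *= 4.0
        for c in ("dosing_freq[1]", "dosing_freq[2]"):
            betas.loc[~rural, c] *= 4.0
        ds = h.simulate_choices(study_design, betas, seed=163)
        ds.covariates = cov
        spec = h.ModelSpec(
            attribute_set=ds.attribute_set, asc=True,
            random_columns=("ASC", "dosing_mode[push]", "dosing_mode[subcutaneous]",
                            "dosing_freq[1]", "dosing_freq[2]"),
        )
        res = h.MixedLogit(ds, spec).fit(n_draws=100, seed=6, gtol=1e-5)
        groups = h.subgroup_compare(ds, res, "location")
        assert groups["rural"].ari_raw["dosing_mode"] > \
            groups["rural"].ari_raw["dosing_freq"]
        assert groups["urban"].ari_raw["dosing_mode"] < \
            groups["urban"].ari_raw["dosing_freq"]
        # refitting per group recovers the same orderings more sharply
        refit = h.subgroup_compare(ds, res, "location", mode="refit",
                                   n_draws=60, seed=7, gtol=1e-4)
        assert refit["rural"].ari_raw["dosing_mode"] > \
            refit["rural"].ari_raw["dosing_freq"]
        assert refit["urban"].ari_raw["dosing_mode"] < \
            refit["urban"].ari_raw["dosing_freq"]

    def test_refit_mode_minimum_group_size(self, study_design, params):
        ds = h.simulate_study(40, params, design=study_design, seed=171)
        spec = h.ModelSpec(attribute_set=ds.attribute_set, asc=True,
                           random_columns=("ASC",))
        res = h.MixedLogit(ds, spec).fit(n_draws=50, seed=7, gtol=1e-4)
        with pytest.raises(ValueError, match="respondents"):
            h.subgroup_compare(ds, res, "treatment_type", mode="refit",
                               min_group_size=30)


class TestSensitivity:
    def test_identical_datasets_warn_and_match(self, small_dataset):
        spec = h.ModelSpec(attribute_set=small_dataset.attribute_set, asc=True)
        with pytest.warns(UserWarning, match="identical"):
            rep = h.sensitivity_analysis(small_dataset, small_dataset, spec,
                                         model="mnl")
        assert (rep.table["coef_all"] == rep.table["coef_filtered"]).all()
        assert rep.table["sign_agrees"].all()
        assert not rep.any_significant

    def test_random_removal_changes_nothing_significant(self, study_design,
                                                        params):
        ds = h.simulate_study(200, params, design=study_design, seed=181)
        rng = np.random.default_rng(182)
        keep = rng.choice(ds.respondent_ids, size=180, replace=False)
        spec = h.ModelSpec(attribute_set=ds.attribute_set, asc=True,
                           random_columns=("ASC", "annual_bleeds[0]"))
        rep = h.sensitivity_analysis(ds, ds.subset(keep), spec,
                                     n_draws=50, seed=8, gtol=1e-4)
        assert set(rep.table.index) >= set(params.mean)  # covers every coefficient
        assert not rep.any_significant

    def test_non_subset_rejected(self, study_design, params):
        a = h.simulate_study(30, params, design=study_design, seed=191)
        b = h.simulate_study(30, params, design=study_design, seed=192)
        spec = h.ModelSpec(attribute_set=a.attribute_set, asc=True)
        with pytest.raises(ValueError, match="subset"):
            h.sensitivity_analysis(a, b, spec, model="mnl")
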