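"""Conditional logit, mixed logit SMLE, draws, LR tests, selection,
individual-level coefficients."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import hemodce as h
from hemodce.models import ModelSpec, build_model_matrix

from conftest import make_manual_dataset


def full_spec(aset, params):
    return ModelSpec(attribute_set=aset, asc=True,
                     random_columns=tuple(params.columns))


class TestModelMatrix:
    def test_study_layout_has_seven_attribute_columns_plus_asc(self, small_dataset):
        md = build_model_matrix(small_dataset,
                                ModelSpec(attribute_set=small_dataset.attribute_set))
        assert len(md.columns) == 8 and md.columns[-1] == "ASC"
        assert md.X.shape[1:] == (3, 8)

    def test_reference_profile_encodes_to_zero_row(self, aset):
        profile = h.Profile({"annual_bleeds": 12, "inhibitor_risk": 0.0,
                             "dosing_freq": 3, "dosing_mode": "drip"})
        assert not aset.encode_profile_array(profile).any()

    def test_risk_enters_in_percentage_points(self, aset):
        profile = h.Profile({"annual_bleeds": 12, "inhibitor_risk": 4.0,
                             "dosing_freq": 3, "dosing_mode": "drip"})
        row = aset.encode_profile(profile)
        assert row["inhibitor_risk"] == 4.0

    def test_repeat_tasks_excluded_by_default(self, small_dataset):
        md = build_model_matrix(small_dataset,
                                ModelSpec(attribute_set=small_dataset.attribute_set))
        md_rep = build_model_matrix(
            small_dataset,
            ModelSpec(attribute_set=small_dataset.attribute_set, include_repeats=True),
        )
        assert md.n_obs == 9 * small_dataset.n_respondents
        assert md_rep.n_obs == 10 * small_dataset.n_respondents


class TestConditionalLogit:
    def test_initial_loglik_is_uniform_choice(self, small_dataset):
        model = h.ConditionalLogit(small_dataset)
        n_sit = model.data.n_obs
        assert model.loglike(np.zeros(8)) == pytest.approx(n_sit * np.log(1 / 3))

    def test_parameter_recovery_homogeneous(self, study_design, params):
        """Data from the homogeneous logit at the published means: every
        coefficient recovered within 3 estimated SEs."""
        homo = params.with_sd_zero()
        ds = h.simulate_study(1500, homo, design=study_design, seed=71)
        res = h.fit_mnl(ds)
        assert res.converged
        for col in params.columns:
            assert abs(res.params[col] - homo.mean[col]) <= 3 * res.bse[col], col

    def test_concavity_multistart_agreement(self, small_dataset):
        model = h.ConditionalLogit(small_dataset)
        rng = np.random.default_rng(8)
        sols = [model.fit(start=rng.uniform(-1.5, 1.5, 8)).params.to_numpy()
                for _ in range(5)]
        for s in sols[1:]:
            assert np.allclose(s, sols[0], atol=1e-6)

    def test_grid_search_oracle_tiny_dataset(self, binary_attribute_set):
        """Two respondents, two tasks, one column: the fitted optimum matches
        an exhaustive coarse-lattice search done here by direct computation."""
        fast, slow = {"speed": "fast"}, {"speed": "slow"}
        rows = [
            (1, 1, 1, slow, 0), (1, 1, 2, fast, 1),
            (1, 2, 1, slow, 1), (1, 2, 2, fast, 0),
            (2, 1, 1, slow, 0), (2, 1, 2, fast, 1),
            (2, 2, 1, slow, 0), (2, 2, 2, fast, 1),
        ]
        ds = make_manual_dataset(binary_attribute_set, rows)
        res = h.fit_mnl(ds, ModelSpec(attribute_set=binary_attribute_set, asc=False))

        xs = [(0.0, 1.0)] * 4  # per task: (x_slow, x_fast)
        chosen = [1, 0, 1, 1]  # chosen x per task
        def ll(b):
            return sum(c * b - np.log(np.exp(b * x[0]) + np.exp(b * x[1]))
                       for c, x in zip(chosen, xs))
        grid = np.arange(-3, 3.0001, 0.05)
        best = grid[np.argmax([ll(b) for b in grid])]
        est = res.params["speed[fast]"]
        assert abs(est - best) <= 0.05
        assert res.llf >= max(ll(b) for b in grid) - 1e-9
        assert est == pytest.approx(np.log(3), abs=1e-6)  # closed form: 3 of 4 chose fast

    def test_cluster_robust_covariance_available(self, small_dataset):
        plain = h.fit_mnl(small_dataset)
        robust = h.fit_mnl(small_dataset, cov_type="cluster")
        assert plain.params.equals(robust.params)
        assert not np.allclose(plain.bse, robust.bse)
        assert (robust.bse > 0).all()

    def test_aic_bic_identities(self, small_dataset):
        res = h.fit_mnl(small_dataset)
        k, ll, n = res.df_model, res.llf, res.n_obs
        assert res.aic == pytest.approx(2 * k - 2 * ll)
        assert res.bic == pytest.approx(k * np.log(n) - 2 * ll)


class TestDraws:
    def test_halton_matches_radical_inverse_oracle(self):
        def radical_inverse(n, base):
            f, r = 1.0, 0.0
            while n > 0:
                f /= base
                r += f * (n % base)
                n //= base
            return r

        draws = h.make_draws(2, 4, 2, draw_type="halton")
        for i in range(8):
            resp, r = divmod(i, 4)
            for d, base in enumerate((2, 3)):
                expected = stats.norm.ppf(radical_inverse(10 + i, base))
                assert draws[resp, r, d] == pytest.approx(expected, abs=1e-12)

    def test_halton_normal_moments(self):
        z = h.make_draws(1, 100000, 1, draw_type="halton")[0, :, 0]
        assert abs(z.mean()) < 0.01
        assert abs(z.std() - 1.0) < 0.01

    def test_pseudo_random_reproducible(self):
        a = h.make_draws(3, 10, 2, draw_type="pseudo_random", seed=5)
        b = h.make_draws(3, 10, 2, draw_type="pseudo_random", seed=5)
        assert np.array_equal(a, b)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            h.make_draws(0, 10, 1)
        with pytest.raises(ValueError):
            h.DrawConfig(schedule=(500, 50))
        with pytest.raises(ValueError):
            h.DrawConfig(tolerance=0.0)


@pytest.fixture(scope="module")
def mixl_model(small_dataset, params):
    return h.MixedLogit(small_dataset, full_spec(small_dataset.attribute_set,
                                                 params))


class TestMixedLogit:
    def test_sll_invariant_to_sd_sign_flip(self, mixl_model, params):
        """With a sign-symmetric (antithetic) draw set, flipping any SD's sign
        only permutes the draws, so the simulated likelihood is unchanged —
        which is why |SD| is the reported quantity."""
        half = h.make_draws(mixl_model.data.n_respondents, 25,
                            len(params.columns), "pseudo_random", seed=9)
        asc_dim = list(mixl_model.spec.random_columns).index("ASC")
        mirrored = half.copy()
        mirrored[:, :, asc_dim] *= -1
        draws = np.concatenate([half, mirrored], axis=1)
        mean = [params.mean[c] for c in mixl_model.data.columns]
        sds = {c: params.sd[c] for c in params.columns}
        base = mixl_model.simulated_loglike(mean, sds, draws)
        flipped = dict(sds); flipped["ASC"] = -flipped["ASC"]
        assert mixl_model.simulated_loglike(mean, flipped, draws) == \
            pytest.approx(base, abs=1e-9)

    def test_sll_invariant_to_respondent_permutation(self, small_dataset, params):
        """Relabeling respondents (and permuting their draw blocks with them)
        leaves the simulated likelihood unchanged."""
        spec = full_spec(small_dataset.attribute_set, params)
        m1 = h.MixedLogit(small_dataset, spec)
        rng = np.random.default_rng(10)
        old_ids = np.sort(small_dataset.respondent_ids)
        new_of_old = dict(zip(old_ids, rng.permutation(old_ids)))
        ds2 = small_dataset.copy()
        ds2.data["respondent_id"] = ds2.data["respondent_id"].map(new_of_old)
        m2 = h.MixedLogit(ds2, spec)

        D = len(params.columns)
        draws = h.make_draws(m1.data.n_respondents, 30, D, "pseudo_random", seed=11)
        # m2 sorts by new id; give each relabeled respondent their old draws
        pos_new = {rid: i for i, rid in enumerate(m2.data.resp_ids)}
        draws2 = np.empty_like(draws)
        for i, old in enumerate(m1.data.resp_ids):
            draws2[pos_new[new_of_old[old]]] = draws[i]
        mean = [params.mean[c] for c in m1.data.columns]
        sds = {c: params.sd[c] for c in params.columns}
        assert m2.simulated_loglike(mean, sds, draws2) == \
            pytest.approx(m1.simulated_loglike(mean, sds, draws), abs=1e-8)

    def test_single_draw_inflates_fit_and_warns(self, small_dataset, params):
        mnl = h.fit_mnl(small_dataset)
        res = h.MixedLogit(small_dataset,
                           full_spec(small_dataset.attribute_set, params)).fit(
            n_draws=1, draw_type="pseudo_random", seed=12, gtol=1e-4)
        assert res.llf >= mnl.llf - 1e-6
        assert "low_draw_warning" in res.diagnostics

    def test_fit_schedule_records_trace(self, study_design, params):
        ds = h.simulate_study(80, params, design=study_design, seed=81)
        spec = ModelSpec(attribute_set=ds.attribute_set, asc=True,
                         random_columns=("ASC", "dosing_mode[subcutaneous]"))
        cfg = h.DrawConfig(schedule=(30, 60, 90), tolerance=0.05)
        res = h.MixedLogit(ds, spec).fit_schedule(cfg, gtol=1e-5)
        assert len(res.schedule_trace) >= 2
        assert res.schedule_trace[0]["max_rel_change"] is None
        assert all(t["max_rel_change"] is not None for t in res.schedule_trace[1:])
        if res.stable_at is not None:
            assert res.schedule_trace[-1]["max_rel_change"] < cfg.tolerance


class TestLRTest:
    def test_identical_models_give_zero_statistic(self, small_dataset):
        res = h.fit_mnl(small_dataset)
        t = h.lr_test(res, res)
        assert t.statistic == 0.0 and t.pvalue == 1.0 and t.df == 0

    def test_df_equals_parameter_difference(self, small_dataset):
        aset = small_dataset.attribute_set
        full = h.fit_mnl(small_dataset, ModelSpec(attribute_set=aset, asc=True))
        reduced = h.fit_mnl(small_dataset, ModelSpec(
            attribute_set=aset, asc=True,
            keep_columns=tuple(c for c in aset.design_columns
                               if c != "dosing_mode[push]")))
        t = h.lr_test(full, reduced)
        assert t.df == 1
        assert t.statistic >= 0

    def test_mismatched_data_rejected(self, study_design, params):
        a = h.simulate_study(30, params, design=study_design, seed=91)
        b = h.simulate_study(30, params, design=study_design, seed=92)
        with pytest.raises(ValueError, match="different data"):
            h.lr_test(h.fit_mnl(a), h.fit_mnl(b))


class TestInteractionSelection:
    @staticmethod
    def _dataset_with_asc_education_effect(study_design, params, seed, effect=1.5,
                                           n=300):
        rng = np.random.default_rng(seed)
        cov = h.generate_covariates(n, h.study_covariate_proportions(),
                                    seed=int(rng.integers(2**31)))
        betas = h.sample_individual_betas(params.with_sd_zero(), n,
                                          seed=int(rng.integers(2**31)))
        high = (cov["education"] == "high_school_or_above").to_numpy()
        betas.loc[high, "ASC"] += effect
        ds = h.simulate_choices(study_design, betas, seed=int(rng.integers(2**31)))
        ds.covariates = cov
        return ds

    def test_alpha_one_retains_every_term(self, study_design, params):
        ds = self._dataset_with_asc_education_effect(study_design, params, 101)
        sel = h.backward_select_interactions(ds, ["education"], alpha=1.0)
        assert len(sel.selected) == 8  # 7 attribute columns + ASC
        assert sel.trace == []

    def test_planted_asc_education_interaction_retained(self, study_design, params):
        hits, clean = 0, 0
        for i in range(3):
            ds = self._dataset_with_asc_education_effect(study_design, params,
                                                         110 + i)
            sel = h.backward_select_interactions(ds, ["education"], alpha=0.05)
            if ("education", "ASC") in sel.selected:
                hits += 1
            clean += len([t for t in sel.selected if t != ("education", "ASC")])
        assert hits >= 2
        assert clean <= 3  # spurious retentions stay near the test level

    def test_null_drops_almost_everything(self, study_design, params):
        ds = h.simulate_study(300, params.with_sd_zero(), design=study_design,
                              seed=121)
        sel = h.backward_select_interactions(ds, ["location"], alpha=0.05)
        assert len(sel.selected) <= 2
        assert len(sel.trace) + len(sel.selected) == 8


class TestIndividualBetas:
    def test_zero_sd_returns_population_means(self, small_dataset, params):
        spec = full_spec(small_dataset.attribute_set, params)
        model = h.MixedLogit(small_dataset, spec)
        out = h.posterior_individual_betas(
            model, params.mean, {c: 0.0 for c in params.columns}, n_draws=20)
        for c in params.columns:
            assert np.allclose(out[c], params.mean[c])

    def test_population_average_of_conditional_means(self, study_design, params):
        """Law of total expectation: conditional means average back to the
        population mean (up to sampling and simulation error)."""
        n = 500
        ds = h.simulate_study(n, params, design=study_design, seed=131)
        model = h.MixedLogit(ds, full_spec(ds.attribute_set, params))
        out = h.posterior_individual_betas(model, params.mean, params.sd,
                                           n_draws=200, seed=131)
        for c in ("ASC", "annual_bleeds[0]", "inhibitor_risk",
                  "dosing_mode[subcutaneous]"):
            tol = 4 * params.sd[c] / np.sqrt(n) + 0.05
            assert abs(out[c].mean() - params.mean[c]) <= tol, c

    def test_risk_minimizer_has_more_negative_risk_coefficient(
            self, study_design, params):
        ds = h.simulate_study(60, params, design=study_design, seed=141,
                              dominant_spec={"inhibitor_risk": 1})
        rid = ds.provenance["contamination"]["dominant"]["inhibitor_risk"][0]
        model = h.MixedLogit(ds, full_spec(ds.attribute_set, params))
        out = h.posterior_individual_betas(model, params.mean, params.sd,
                                           n_draws=300, seed=141)
        val = out.set_index("respondent_id").loc[rid, "inhibitor_risk"]
        assert val < params.mean["inhibitor_risk"]
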