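import numpy as np
import pytest

import poachmort as pm
from poachmort.fit import numerical_np, real_estimates
from poachmort.structures import ModelStructure, ParameterIndex


class TestAicc:
    def test_zero_parameters_is_deviance(self):
        assert pm.compute_aicc(100.0, 0, 50) == pytest.approx(100.0)

    def test_large_sample_limit_is_aic(self):
        assert pm.compute_aicc(100.0, 5, 10**9) == pytest.approx(110.0, abs=1e-3)

    def test_selected_male_model_row(self):
        # deviance, identifiable-parameter count and effective sample size
        # of the best male model reproduce its published AICc
        assert pm.compute_aicc(533.24, 13, 140) == pytest.approx(562.12, abs=0.02)

    def test_selected_female_model_row(self):
        assert pm.compute_aicc(836.96, 21, 357) == pytest.approx(881.72, abs=0.02)

    def test_small_sample_guard(self):
        with pytest.raises(ValueError):
            pm.compute_aicc(100.0, 10, 11)


def test_effective_sample_size_counts_nonzero_codes():
    hs = [
        pm.EncounterHistory(id="a", sex="F", age_at_marking=2, events=[2, 0, 2, 8]),
        pm.EncounterHistory(id="b", sex="M", age_at_marking=1, events=[0, 1, 1, 0]),
    ]
    assert pm.effective_sample_size(hs) == 5


class TestWaldInterval:
    def test_zero_se_collapses(self):
        assert pm.wald_interval(0.5, 0.0) == (0.5, 0.5)

    def test_published_recovery_interval(self):
        # female recovery 0.47 with link-scale SE ~0.29 prints (0.33, 0.61)
        lo, hi = pm.wald_interval(0.47, 0.29)
        assert lo == pytest.approx(0.33, abs=0.01)
        assert hi == pytest.approx(0.61, abs=0.01)

    def test_probability_interval_stays_in_unit_range(self):
        lo, hi = pm.wald_interval(0.95, 2.0)
        assert 0 < lo < hi < 1

    def test_identity_link_is_symmetric(self):
        lo, hi = pm.wald_interval(1.0, 0.5, link="identity")
        assert lo == pytest.approx(1 - 1.959964 * 0.5, abs=1e-5)
        assert hi == pytest.approx(1 + 1.959964 * 0.5, abs=1e-5)


class TestNumericalNp:
    def test_full_rank_toy(self):
        H = np.diag([1.0, 2.0])
        assert numerical_np(H) == 2

    def test_flat_direction_dropped(self):
        H = np.diag([1.0, 1e-9])
        assert numerical_np(H) == 1

    def test_confounded_model_without_recoveries(self, presets):
        # no deaths in the data: recovery and cause-determination carry no
        # information, so the numerical rank falls below the nominal count
        params, structures = presets
        import dataclasses
        p = dataclasses.replace(params["F"], m=np.zeros_like(params["F"].m))
        data = pm.simulate_histories(pm.scaled_design(150), {"M": params["M"], "F": p}, seed=11)
        fit = pm.fit_model(data.by_sex("F"), structures["F"], n_starts=0, seed=0)
        assert fit.np_ < fit.n_nominal


class TestFitModel:
    def test_degenerate_data_hits_boundaries(self):
        # everyone observed at every occasion and nobody dies: resighting
        # pegs at 1 and mortality at 0
        T = 6
        hs = [
            pm.EncounterHistory(id=f"i{k}", sex="F", age_at_marking=2,
                                events=[2] * T)
            for k in range(25)
        ]
        stc = ModelStructure(sex="F", ages="1+", mortality="interactive",
                             resight="constant", recovery="constant",
                             initial_state="conditioned")
        fit = pm.fit_model(hs, stc, n_starts=1, seed=0)
        assert fit.estimate("resight", ".")["estimate"] > 0.999
        assert fit.estimate("poach_mortality", "1+")["estimate"] < 1e-4
        assert fit.estimate("survival", "1+")["estimate"] > 0.999
        assert fit.estimate("resight", ".")["boundary"]

    def test_refit_from_optimum_is_idempotent(self, presets, big_dataset):
        _, structures = presets
        hs = big_dataset.by_sex("M")[:400]
        fit = pm.fit_model(hs, structures["M"], n_starts=0, seed=0, compute_se=False)
        again = pm.fit_model(hs, structures["M"], n_starts=0, seed=1,
                             start=fit.theta, compute_se=False)
        assert again.deviance == pytest.approx(fit.deviance, abs=1e-4)

    def test_nested_models_deviance_monotonicity(self, presets, big_dataset):
        """A larger model never fits worse than one nested inside it."""
        params, _ = presets
        hs = big_dataset.by_sex("M")[:400]
        add = ModelStructure(sex="M", ages="1:3,4:7,8+", mortality="additive",
                             resight="by_mark", recovery="constant")
        inter = ModelStructure(sex="M", ages="1:3,4:7,8+", mortality="interactive",
                               resight="by_mark", recovery="constant")
        fit_add = pm.fit_model(hs, add, n_starts=0, seed=0, compute_se=False)
        start = ParameterIndex(inter, 11).deflate(fit_add.params)
        fit_int = pm.fit_model(hs, inter, n_starts=0, seed=0, start=start,
                               compute_se=False)
        assert fit_int.deviance <= fit_add.deviance + 1e-6

    def test_estimates_recover_generating_values_at_large_n(self, presets, big_dataset):
        params, structures = presets
        fit = pm.fit_model(big_dataset.by_sex("F"), structures["F"], n_starts=0, seed=0)
        truth = params["F"]
        for a, lab in enumerate(truth.partition.labels):
            est = fit.estimate("poach_mortality", lab)["estimate"]
            assert est == pytest.approx(truth.m[a, 0], abs=0.04)
        assert fit.estimate("recovery", ".")["estimate"] == pytest.approx(0.47, abs=0.08)

    def test_boundary_rows_have_no_interval(self, presets, big_dataset):
        # true female GPS signal loss in the deployment year is 0
        _, structures = presets
        fit = pm.fit_model(big_dataset.by_sex("F"), structures["F"], n_starts=0, seed=0)
        row = fit.estimate("gps_signal_loss", "yr1")
        assert row["boundary"] and not np.isfinite(row["lo"])
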