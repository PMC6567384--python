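import dataclasses

import numpy as np
import pandas as pd
import pytest

import poachmort as pm
from poachmort.simulate import Cohort, StudyDesign


class TestDesign:
    def test_default_design_matches_study_counts(self):
        d = pm.default_design()
        assert d.n_occasions == 11
        assert d.total("M") == 56 and d.total("F") == 85
        marks = {}
        for c in d.cohorts:
            marks[(c.sex, c.mark)] = marks.get((c.sex, c.mark), 0) + c.n
        assert marks[("M", "gps")] == 13 and marks[("F", "gps")] == 16
        assert marks[("M", "collar")] == 22 and marks[("F", "collar")] == 67
        assert marks[("M", "tags")] == 21 and marks[("F", "tags")] == 2
        assert all(c.occasion < 10 for c in d.cohorts)  # last occasion: no entry

    def test_scaled_design_preserves_totals(self):
        d = pm.scaled_design(500)
        assert d.total("M") == 500 and d.total("F") == 500


class TestPresets:
    def test_male_old_age_poaching(self):
        p, _ = pm.study_preset("M")
        assert p.m[2, 0] == pytest.approx(0.255)
        assert p.phi[1] == pytest.approx(0.902)

    def test_female_dropoff_at_zero(self):
        p, _ = pm.study_preset("F")
        assert p.dropoff == 0.0

    def test_probabilities_complement(self):
        for sex in "MF":
            p, _ = pm.study_preset(sex)
            np.testing.assert_allclose(p.phi + p.m[:, 0] + p.m[:, 1], 1.0, atol=1e-12)
            assert p.is_valid()


class TestSimulate:
    def test_deterministic_under_seed(self, presets):
        params, _ = presets
        d = pm.scaled_design(60)
        a = pm.simulate_histories(d, params, seed=5)
        b = pm.simulate_histories(d, params, seed=5)
        assert a.histories == b.histories
        pd.testing.assert_frame_equal(a.truth, b.truth)
        c = pm.simulate_histories(d, params, seed=6)
        assert a.histories != c.histories

    def test_histories_are_valid(self, study_dataset):
        for h in study_dataset.histories:
            assert pm.validate_history(h) == []

    def test_events_consistent_with_truth(self, study_dataset):
        truth = study_dataset.truth.set_index("id")
        for h in study_dataset.histories:
            row = truth.loc[h.id]
            dead_codes = [e for e in h.events if e >= 5]
            if row.recovered:
                assert len(dead_codes) == 1
                code = dead_codes[0]
                if row.determined:
                    want = {"poached": (5, 6), "other": (7, 8)}[row.cause]
                else:
                    want = (9, 10)
                assert code in want
                # GPS-coded recoveries only for deaths with a working collar
                if code in (5, 7, 9):
                    assert row.path[row.death_occasion - h.marking_occasion] in "46"
            else:
                assert dead_codes == []

    def test_forced_death(self, presets):
        params, _ = presets
        p = dataclasses.replace(params["F"], m=np.tile([0.5, 0.5], (3, 1)))
        d = StudyDesign(4, (Cohort("F", 0, "collar", 40),))
        data = pm.simulate_histories(d, {"F": p}, seed=1)
        for h in data.histories:
            assert h.events[2:].sum() == 0  # dead (or silent) after first interval
            assert all(e in (0, 6, 8, 10) for e in h.events[1:])

    def test_forced_detection(self, presets):
        params, _ = presets
        p = dataclasses.replace(
            params["F"],
            m=np.zeros((3, 2)),
            resight=np.ones_like(params["F"].resight),
        )
        d = StudyDesign(5, (Cohort("F", 0, "collar", 30),))
        data = pm.simulate_histories(d, {"F": p}, seed=2)
        for h in data.histories:
            assert list(h.events) == [2, 2, 2, 2, 2]

    def test_one_step_event_frequencies_match_emission_row(self, presets):
        """Monte-Carlo one-step frequencies against the analytic matrix row."""
        params, _ = presets
        p = params["M"]
        d = StudyDesign(2, (Cohort("M", 0, "collar", 10000),))
        data = pm.simulate_histories(d, {"M": p}, seed=9)
        ev = np.array([h.events[1] for h in data.histories])
        # analytic one-step law from state A_COLLAR, marginalized over the
        # age-at-marking distribution (age class governs the mortality draw)
        from poachmort.hmm import A_COLLAR
        from poachmort.simulate import AGE_VALUES, AGE_WEIGHTS
        B = pm.build_event_matrix(p, 1)
        law = np.zeros(11)
        for age, w in zip(AGE_VALUES, AGE_WEIGHTS):
            T = pm.build_transition(p, p.partition.class_of(int(age)), 1)
            law += w * (T[A_COLLAR] @ B)
        n = len(ev)
        for code in range(11):
            freq = np.mean(ev == code)
            se = np.sqrt(law[code] * (1 - law[code]) / n)
            assert abs(freq - law[code]) <= 3 * se + 1e-9, f"code {code}"

    def test_poached_recovery_rate_converges(self, presets):
        params, _ = presets
        p = params["M"]
        d = StudyDesign(2, (Cohort("M", 0, "tags", 20000),))
        data = pm.simulate_histories(d, {"M": p}, seed=12)
        # expected determined-poached fraction in one step, class 0
        expect = p.m[0, 0] * p.recovery[1] * p.delta
        got = np.mean([h.events[1] == 6 for h in data.histories])
        se = np.sqrt(expect * (1 - expect) / 20000)
        assert abs(got - expect) <= 3 * se


class TestRecoveryExperiment:
    def test_zero_replicates_empty_report(self, presets):
        params, structures = presets
        rep = pm.recovery_experiment(pm.scaled_design(50), params, structures, 0, seed=1)
        assert rep.empty

    def test_small_experiment_reports_all_mortality_rows(self, presets):
        params, structures = presets
        rep = pm.recovery_experiment(pm.scaled_design(250), params, structures, 2, seed=3)
        assert set(rep["name"]) == {"survival", "poach_mortality", "other_mortality"}
        assert len(rep) == 18  # 2 sexes x 3 classes x 3 quantities
        assert (rep["n_failed"] == 0).all()
        # point estimates at n=250 are noisy but must sit in the unit range
        assert rep["mean_estimate"].between(0, 1).all()
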