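import numpy as np
import pytest
from hypothesis import given, strategies as st

import poachmort as pm
from poachmort.hmm import (
    A_GPS, A_GPS_OFF, A_COLLAR, A_TAGS, DEAD,
    ND_POACH_MARK, ND_OTHER_MARK,
    MultieventLikelihood,
)
from poachmort.structures import AgePartition, ModelStructure, ParameterSet

from oracles import brute_force_history_loglik, random_parameter_set


def make_params(m=(0.1, 0.1), lam=(0.0, 0.3), dropoff=0.1, p=(0.6, 0.4),
                r=0.5, delta=0.8, r_gps=1.0, T=5, ages="1+"):
    part = AgePartition.parse(ages)
    A = part.n_classes
    return ParameterSet(
        partition=part,
        m=np.tile(m, (A, 1)),
        lam=np.asarray(lam),
        dropoff=dropoff,
        resight=np.tile(p, (T, 1)),
        recovery=np.full(T, r),
        delta=delta,
        r_gps=r_gps,
    )


class TestMarkKernel:
    def test_no_loss_no_dropoff_is_identity(self):
        K = pm.build_mark_kernel(make_params(lam=(0, 0), dropoff=0), 2)
        np.testing.assert_allclose(K, np.eye(4))

    def test_female_second_year_signal_loss(self):
        # published female estimates: signal loss 0.39 in year 2+, no drop-off
        K = pm.build_mark_kernel(make_params(lam=(0.0, 0.39), dropoff=0.0), 2)
        np.testing.assert_allclose(K[A_GPS], [0.61, 0.39, 0, 0])

    def test_male_loss_and_dropoff(self):
        K = pm.build_mark_kernel(make_params(lam=(0.0, 0.27), dropoff=0.15), 2)
        assert K[A_GPS, A_TAGS] == pytest.approx(0.15)
        assert K[A_GPS, A_GPS_OFF] == pytest.approx(0.27 * 0.85)

    def test_first_year_uses_first_class(self):
        K = pm.build_mark_kernel(make_params(lam=(0.05, 0.5), dropoff=0.0), 1)
        assert K[A_GPS, A_GPS_OFF] == pytest.approx(0.05)


class TestTransition:
    def test_old_male_tag_row_matches_published_breakdown(self):
        # averaged male 8+ estimates: survival 0.541, poaching 0.255,
        # other-cause mortality by complement 0.204
        p = make_params(m=(0.255, 0.204))
        T = pm.build_transition(p, 0, 2)
        assert T[A_TAGS, A_TAGS] == pytest.approx(0.541)
        assert T[A_TAGS, ND_POACH_MARK] == pytest.approx(0.255)
        assert T[A_TAGS, ND_OTHER_MARK] == pytest.approx(0.204)

    def test_zero_mortality_keeps_alive_block(self):
        p = make_params(m=(0.0, 0.0))
        T = pm.build_transition(p, 0, 2)
        assert T[:4, 4:].sum() == 0.0
        np.testing.assert_allclose(T[:4, :4].sum(axis=1), 1.0)

    def test_newly_dead_absorbs(self):
        T = pm.build_transition(make_params(), 0, 1)
        np.testing.assert_allclose(T[4:, DEAD], 1.0)

    @given(st.integers(0, 2**31 - 1))
    def test_rows_sum_to_one(self, seed):
        rng = np.random.default_rng(seed)
        params, _, _ = random_parameter_set(rng)
        for a in range(params.partition.n_classes):
            for dep in (1, 2):
                T = pm.build_transition(params, a, dep)
                np.testing.assert_allclose(T.sum(axis=1), 1.0, atol=1e-12)


class TestEventMatrix:
    def test_working_gps_is_certain(self):
        B = pm.build_event_matrix(make_params(), 2)
        assert B[A_GPS, 1] == 1.0

    def test_dead_tagged_row_splits_by_determination(self):
        B = pm.build_event_matrix(make_params(r=0.5, delta=0.8), 2)
        assert B[ND_POACH_MARK, 6] == pytest.approx(0.40)
        assert B[ND_POACH_MARK, 10] == pytest.approx(0.10)
        assert B[ND_POACH_MARK, 0] == pytest.approx(0.50)

    @given(st.integers(0, 2**31 - 1))
    def test_rows_sum_to_one(self, seed):
        rng = np.random.default_rng(seed)
        params, _, _ = random_parameter_set(rng)
        for t in range(params.n_occasions):
            B = pm.build_event_matrix(params, t)
            np.testing.assert_allclose(B.sum(axis=1), 1.0, atol=1e-12)


class TestHistoryLoglik:
    def test_release_only_contributes_zero(self):
        assert pm.history_loglik([2], 3, make_params(T=1)) == 0.0

    def test_perfect_gps_chain(self):
        p = make_params(m=(0, 0), lam=(0, 0), dropoff=0)
        assert pm.history_loglik([1, 1, 1], 2, p) == pytest.approx(0.0)

    def test_impossible_history_is_minus_inf(self):
        # a tag-only animal can never emit a collar code
        p = make_params()
        assert pm.history_loglik([3, 2, 0], 2, p) == -np.inf

    @pytest.mark.parametrize(
        "events, age",
        [
            ([1, 1, 5, 0], 2),
            ([2, 0, 2, 8], 1),
            ([3, 3, 0, 0], 9),
            ([1, 4, 0, 10], 3),
            ([0, 2, 0, 2], 5),
            ([0, 0, 3, 0], 2),
            ([1, 9], 4),
        ],
    )
    def test_forward_equals_enumeration(self, events, age):
        rng = np.random.default_rng(sum(events) * 101 + age)
        for _ in range(20):
            params, _, _ = random_parameter_set(rng, n_occasions=len(events),
                                                ages="1,2:7,8+")
            got = pm.history_loglik(events, age, params)
            want = brute_force_history_loglik(events, age, params)
            assert got == pytest.approx(want, abs=1e-10)

    @given(st.integers(0, 2**31 - 1))
    def test_event_alphabet_is_complete(self, seed):
        """Total probability over all two-step event sequences is one."""
        rng = np.random.default_rng(seed)
        params, _, _ = random_parameter_set(rng, n_occasions=3)
        for release in (1, 2, 3):
            total = 0.0
            for e1 in range(11):
                for e2 in range(11):
                    ll = pm.history_loglik([release, e1, e2], 2, params,
                                           marking_occasion=0)
                    if np.isfinite(ll):
                        total += np.exp(ll)
            assert total == pytest.approx(1.0, abs=1e-10)


class TestDatasetLoglik:
    def _two_identical(self):
        e = np.array([2, 0, 2, 8, 0])
        return [
            pm.EncounterHistory(id="a", sex="F", age_at_marking=2, events=e),
            pm.EncounterHistory(id="b", sex="F", age_at_marking=2, events=e.copy()),
        ]

    def test_two_identical_histories_double_the_contribution(self):
        hs = self._two_identical()
        stc = ModelStructure(sex="F", ages="1,2:7,8+", mortality="interactive",
                             resight="constant", recovery="constant")
        lik = MultieventLikelihood(hs, stc)
        theta = np.random.default_rng(0).normal(size=lik.index.n_params)
        per = lik.loglik_per_individual(theta)
        assert per[0] == pytest.approx(per[1])
        ll, dev = pm.dataset_loglik(hs, theta, stc)
        assert ll == pytest.approx(2 * per[0])
        assert dev == pytest.approx(-2 * ll)

    def test_relabeling_invariance(self, study_dataset):
        hs = list(study_dataset.histories)
        stc = ModelStructure(sex="F", ages="1,2:7,8+", mortality="interactive",
                             resight="by_mark", recovery="constant")
        females = [x for x in hs if x.sex == "F"]
        theta = np.random.default_rng(1).normal(
            size=MultieventLikelihood(females, stc).index.n_params)
        ll1, _ = pm.dataset_loglik(females, theta, stc)
        ll2, _ = pm.dataset_loglik(females[::-1], theta, stc)
        assert ll1 == pytest.approx(ll2, rel=1e-12)

    def test_impossible_history_names_offender(self):
        hs = self._two_identical()
        hs[1] = pm.EncounterHistory(id="bad", sex="F", age_at_marking=2,
                                    events=[3, 2, 0, 0, 0])
        stc = ModelStructure(sex="F", ages="1+", mortality="interactive",
                             resight="constant", recovery="constant")
        theta = np.zeros(MultieventLikelihood(hs, stc).index.n_params)
        with pytest.raises(ValueError, match="bad"):
            pm.dataset_loglik(hs, theta, stc)
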