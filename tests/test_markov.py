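"""Cohort recursion: mortality arithmetic, conservation, oracle equivalence."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import tdtcost as t
from tdtcost.markov import CohortTrace, LifeTable, STATE_COLUMNS
from tdtcost.params import ENDOCRINE_COMPLICATIONS, MortalityInputs

from conftest import assert_trace_close, enumerate_cohort_paths

STRATA_COLUMNS = [f"{c}_{s}" for c in ENDOCRINE_COMPLICATIONS
                  for s in ("y1", "y2p")]


def toy_params(entry=2, horizon=4):
    p = t.default_parameters()
    p.entry_age, p.horizon_age = entry, horizon
    return p


def flat_life_table(q, lo=0, hi=80):
    return LifeTable({a: q for a in range(lo, hi + 1)})


class TestDeathProbability:
    def test_relative_risk_scales_background(self):
        lt = flat_life_table(0.002)
        p = t.annual_death_prob(30, "no_cardiac", lt, MortalityInputs(3.9, 0.0062))
        assert p == pytest.approx(0.0078)

    def test_cardiac_state_combines_competing_risks(self):
        lt = flat_life_table(0.002)
        p = t.annual_death_prob(30, "cardiac", lt, MortalityInputs(3.9, 0.0062))
        assert p == pytest.approx(1 - 0.9922 * 0.9938)

    def test_identity_when_rr_one_and_no_excess(self):
        lt = flat_life_table(0.013)
        for state in ("no_cardiac", "cardiac"):
            assert t.annual_death_prob(
                20, state, lt, MortalityInputs(1.0, 0.0)
            ) == pytest.approx(0.013, abs=1e-15)

    def test_scaled_probability_capped_at_one(self):
        lt = flat_life_table(0.5)
        assert t.annual_death_prob(20, "no_cardiac", lt,
                                   MortalityInputs(3.9, 0.0)) == 1.0

    def test_uncovered_age_rejected(self):
        lt = flat_life_table(0.01, lo=2, hi=10)
        with pytest.raises(ValueError, match="not covered"):
            t.annual_death_prob(11, "no_cardiac", lt, MortalityInputs())


class TestCohortRecursion:
    def test_immortal_cohort_conserves_everyone(self):
        params = toy_params(2, 58)
        lt = flat_life_table(0.0)
        trans = t.make_transitions(0.0, {c: 0.0 for c in
                                         ENDOCRINE_COMPLICATIONS})
        trace = t.run_cohort(params, lt, trans)
        assert np.allclose(trace.frame["alive"], 1.0)
        assert t.life_expectancy(trace) == pytest.approx(57.0)

    def test_occupancies_conserved_and_alive_monotone(self, base_params,
                                                      life_table, transitions):
        trace = t.run_cohort(base_params, life_table, transitions)
        total = trace.frame[list(STATE_COLUMNS)].sum(axis=1)
        assert np.allclose(total, 1.0, atol=1e-12)
        alive = trace.frame["alive"].to_numpy()
        assert (np.diff(alive) <= 1e-15).all()

    def test_no_onset_keeps_cardiac_empty(self, base_params, life_table):
        trans = t.make_transitions(0.0)
        trace = t.run_cohort(base_params, life_table, trans)
        assert (trace.frame[["cardiac_y1", "cardiac_y2p"]] == 0.0).all().all()

    def test_matches_path_enumeration_oracle(self):
        params = toy_params(2, 4)
        q = {2: 0.1, 3: 0.1}
        lt = LifeTable(q | {4: 0.1})
        trans = t.make_transitions(0.2, {c: 0.0 for c in
                                         ENDOCRINE_COMPLICATIONS},
                                   entry_age=2, horizon_age=4,
                                   mortality=MortalityInputs(1.0, 0.0062))
        trace = t.run_cohort(params, lt, trans)
        oracle = enumerate_cohort_paths(
            [2, 3, 4], {2: 0.1, 3: 0.1}, 1.0, 0.0062,
            {2: 0.2, 3: 0.2})
        for age in (2, 3, 4):
            for col in STATE_COLUMNS:
                assert trace.frame.loc[age, col] == pytest.approx(
                    oracle[age][col], abs=1e-14), (age, col)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(q=st.floats(0, 0.3), onset=st.floats(0, 0.3),
           endo=st.floats(0, 0.3))
    def test_conservation_under_random_rates(self, q, onset, endo):
        params = toy_params(2, 10)
        lt = flat_life_table(q, 0, 20)
        trans = t.make_transitions(onset,
                                   {c: endo for c in ENDOCRINE_COMPLICATIONS},
                                   entry_age=2, horizon_age=10)
        trace = t.run_cohort(params, lt, trans)
        total = trace.frame[list(STATE_COLUMNS)].sum(axis=1)
        assert np.allclose(total, 1.0, atol=1e-12)

    def test_year1_stratum_equals_onset_inflow(self, base_params, life_table):
        trans = t.make_transitions(0.02, {"hypogonadism": 0.03})
        trace = t.run_cohort(base_params, life_table, trans)
        frame = trace.frame
        for age in list(base_params.ages)[1:]:
            free_prev = (1 - frame.loc[age - 1, "hypogonadism_y1"]
                         - frame.loc[age - 1, "hypogonadism_y2p"])
            assert frame.loc[age, "hypogonadism_y1"] == pytest.approx(
                free_prev * 0.03, abs=1e-12)

    def test_invalid_onset_probability_names_age(self, base_params, life_table):
        trans = t.make_transitions(0.0)
        trans.cardiac_onset = {a: (1.5 if a == 30 else 0.0)
                               for a in range(2, 59)}
        with pytest.raises(ValueError, match="age 30"):
            t.run_cohort(base_params, life_table, trans)

    def test_uncovered_life_table_rejected(self, base_params, transitions):
        lt = flat_life_table(0.01, lo=2, hi=30)
        with pytest.raises(ValueError, match="cover"):
            t.run_cohort(base_params, lt, transitions)


class TestLifeExpectancy:
    def test_sum_of_alive_probabilities(self):
        frame = pd.DataFrame({"alive": [1.0, 0.5, 0.0]},
                             index=pd.Index([2, 3, 4], name="age"))
        trace = CohortTrace(frame)
        assert t.life_expectancy(trace) == pytest.approx(1.5)
        assert t.life_expectancy(trace, as_attained_age=True) == pytest.approx(3.5)

    def test_increasing_relative_risk_never_raises_life_expectancy(
            self, base_params, life_table):
        les = []
        for rr in (1.0, 2.0, 3.9, 6.0):
            trans = t.make_transitions(
                mortality=MortalityInputs(rr, 0.0062))
            trace = t.run_cohort(base_params, life_table, trans)
            les.append(t.life_expectancy(trace))
        assert all(a >= b for a, b in zip(les, les[1:]))


class TestMicrosimulation:
    def test_zero_probabilities_match_cohort_exactly(self, base_params):
        lt = flat_life_table(0.0)
        trans = t.make_transitions(0.0, {c: 0.0 for c in
                                         ENDOCRINE_COMPLICATIONS})
        cohort = t.run_cohort(base_params, lt, trans)
        micro = t.microsimulate(base_params, lt, trans, 500, seed=1)
        cols = list(STATE_COLUMNS) + ["alive"] + STRATA_COLUMNS
        assert np.allclose(micro.frame[cols], cohort.frame[cols])

    def test_same_seed_reproduces_output(self, base_params, life_table,
                                         transitions):
        a = t.microsimulate(base_params, life_table, transitions, 2000, seed=3)
        b = t.microsimulate(base_params, life_table, transitions, 2000, seed=3)
        assert a.frame.equals(b.frame)

    def test_occupancies_within_three_se_of_cohort(self, base_params,
                                                   life_table, transitions,
                                                   base_trace):
        n = 30_000
        micro = t.microsimulate(base_params, life_table, transitions, n,
                                seed=11)
        assert_trace_close(base_trace, micro,
                           list(STATE_COLUMNS) + ["alive"], n, z=3.0)
        # tunnel strata add ~450 more comparisons; allow for multiplicity
        assert_trace_close(base_trace, micro, STRATA_COLUMNS, n, z=4.0)

    def test_needs_at_least_one_individual(self, base_params, life_table,
                                           transitions):
        with pytest.raises(ValueError):
            t.microsimulate(base_params, life_table, transitions, 0, seed=0)
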