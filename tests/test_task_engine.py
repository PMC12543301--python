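"""Task engine: designs, adaptive feedback, contingency reversal."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from looprl import task_engine as te


@pytest.fixture(scope="module")
def designs():
    return te.make_design(seed=1, n_participants=8)


class TestDesign:
    def test_sign_split_per_ability(self, designs):
        for d in designs:
            for (s, a, b), plan in d.plans.items():
                expected = 14 if b == "High" else 6
                assert plan.n_positive == expected
                assert len(plan.modifiers) == 20
                assert all(m != 0 for m in plan.modifiers)

    def test_categories_counterbalanced(self, designs):
        from collections import Counter

        c = Counter((cell, d.assignment[cell]) for d in designs for cell in te.CELLS)
        # 8 participants x 4 cells, each category serves each cell twice
        assert set(c.values()) == {2}

    def test_category_cell_mapping_flips_ability_at_t2(self, designs):
        d = designs[0]
        for agent in te.AGENTS:
            c1 = d.condition("T1", agent, "High").category
            assert d.condition("T2", agent, "Low").category == c1

    def test_reproducible_from_seed(self):
        a = te.make_design(seed=5, n_participants=3)
        b = te.make_design(seed=5, n_participants=3)
        assert [x.to_json_dict() for x in a] == [y.to_json_dict() for y in b]
        c = te.make_design(seed=6, n_participants=3)
        assert [x.to_json_dict() for x in a] != [z.to_json_dict() for z in c]

    def test_design_round_trips_through_json(self, designs):
        d = designs[2]
        d2 = te.ParticipantDesign.from_json_dict(d.to_json_dict())
        assert d2.assignment == d.assignment
        assert d2.plans == d.plans


class TestReversal:
    def test_sign_pattern_flips_to_opposite_ability(self, designs):
        for d in designs:
            for agent in te.AGENTS:
                high_t1 = d.plans[("T1", agent, "High")]
                # the category continues at T2 under the "Low" label
                low_t2 = d.plans[("T2", agent, "Low")]
                assert low_t2.n_positive == 6
                assert low_t2.modifiers == tuple(-m for m in high_t1.modifiers)

    def test_magnitude_multiset_preserved(self, designs):
        for d in designs:
            for agent in te.AGENTS:
                for b1, b2 in (("High", "Low"), ("Low", "High")):
                    assert (d.plans[("T1", agent, b1)].abs_multiset
                            == d.plans[("T2", agent, b2)].abs_multiset)

    def test_double_reversal_is_identity(self, designs):
        plan = designs[0].plans[("T1", "Self", "High")]
        assert te.reverse_contingencies(te.reverse_contingencies(plan)) == plan


class TestReferenceBelief:
    def test_empty_history_is_midpoint(self):
        assert te.reference_belief([]) == 50.0

    @pytest.mark.parametrize("history,expected", [
        ([60, 70, 80, 90, 100], 80.0),
        ([10, 60, 70, 80, 90, 100], 80.0),   # only the last five count
        ([42], 42.0),
    ])
    def test_trailing_mean(self, history, expected):
        assert te.reference_belief(history) == expected

    def test_out_of_range_rating_rejected(self):
        with pytest.raises(ValueError):
            te.reference_belief([50, 101])

    @given(st.lists(st.floats(0, 100), min_size=1, max_size=12))
    def test_always_within_scale(self, history):
        assert 0 <= te.reference_belief(history) <= 100


class TestFeedback:
    @pytest.mark.parametrize("ref,mod,expected", [
        (50, 20, 70.0),
        (95, 20, 100.0),     # clipped to the top of the scale
        (80, -15, 65.0),
    ])
    def test_compute_feedback(self, ref, mod, expected):
        assert te.compute_feedback(ref, mod) == expected

    def test_incentive_peaks_at_six_cents_for_exact_expectation(self):
        assert te.trial_incentive(70.0, 70.0) == 6.0
        assert te.trial_incentive(0.0, 100.0) == 0.0
        assert te.trial_incentive(60.0, 70.0) == pytest.approx(5.4)


def _constant_plan_design(modifier):
    d = te.make_design(seed=0, n_participants=1)[0]
    plans = {k: te.FeedbackPlan((modifier,) * 20) for k in d.plans}
    return te.ParticipantDesign(0, d.assignment, plans)


class TestRunSession:
    def test_constant_agent_fixed_point(self):
        # a constant-50 rater keeps the trailing mean at 50, so FB = 50 + mod
        d = _constant_plan_design(10.0)
        recs = te.run_session(lambda cond, h: 50.0, d, "T1")
        assert len(recs) == 80
        assert all(r.feedback == 60.0 and r.pe == 10.0 for r in recs)

    def test_first_trial_pe_equals_modifier(self):
        d = _constant_plan_design(-10.0)
        recs = te.run_session(lambda cond, h: 50.0, d, "T1")
        first = [r for r in recs if r.trial == 1]
        assert all(r.pe == -10.0 for r in first)

    def test_echo_agent_matches_bruteforce_trajectory(self):
        # oracle: replay the trailing-mean + modifier rule with plain lists
        d = te.make_design(seed=4, n_participants=1)[0]
        recs = te.run_session(
            lambda cond, h: 50.0 if not h else h[-1][1], d, "T1")
        for agent, ability in te.CELLS:
            plan = d.plans[("T1", agent, ability)].modifiers
            ratings, fbs = [], []
            for t in range(20):
                exp = 50.0 if not fbs else fbs[-1]
                ref = 50.0 if not ratings else float(np.mean(ratings[-5:]))
                fb = float(np.clip(ref + plan[t], 0, 100))
                ratings.append(exp)
                fbs.append(fb)
            got = [r for r in recs if r.agent == agent and r.ability == ability]
            assert [r.expectation for r in got] == ratings
            assert [r.feedback for r in got] == fbs

    def test_out_of_range_agent_rating_rejected(self):
        d = _constant_plan_design(5.0)
        with pytest.raises(ValueError):
            te.run_session(lambda cond, h: 120.0, d, "T1")

    def test_reference_tracking_agent_gets_exact_plan_pes(self):
        # rating the reference belief makes every PE equal its modifier,
        # so sign proportions and |PE| multisets follow the plan exactly
        d = te.make_design(seed=2, n_participants=1)[0]
        by_cat = {}
        for session in te.SESSIONS:
            recs = te.run_session(
                lambda cond, h: te.reference_belief([x[0] for x in h]) if h else 50.0,
                d, session)
            for r in recs:
                by_cat.setdefault((r.category, session), []).append(r.pe)
            for agent, ability in te.CELLS:
                cell = [r for r in recs if r.agent == agent and r.ability == ability]
                pos = sum(r.pe > 0 for r in cell)
                assert pos == (14 if ability == "High" else 6)
                assert all(-100 <= r.pe <= 100 and 0 <= r.feedback <= 100
                           for r in cell)
        for cat in te.CATEGORIES:
            t1 = sorted(abs(p) for p in by_cat[(cat, "T1")])
            t2 = sorted(abs(p) for p in by_cat[(cat, "T2")])
            assert t1 == t2   # magnitude preservation across the reversal

    def test_records_frame_schema(self):
        d = _constant_plan_design(5.0)
        df = te.records_to_frame(te.run_session(lambda c, h: 50.0, d, "T1"))
        assert tuple(df.columns) == te.TRIAL_COLUMNS
        assert len(df) == 80
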