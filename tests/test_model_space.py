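"""Model space: the delta-rule update, discounting curve, likelihood, nesting."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from looprl import task_engine as te
from looprl.model_space import (
    DEFAULT_SIGMA_ND, CellData, MODELS, cells_from_frame, congruency,
    delta_update, get_model, nd_weight, pointwise_loglik, predict_cell,
    simulate_trajectory, truncnorm_logpdf, update_expectation,
)


class TestNdWeight:
    def test_peak_and_symmetry(self):
        assert nd_weight(50, 17) == 1.0
        assert nd_weight(0, 17) == nd_weight(100, 17)
        assert nd_weight(67, 17) == pytest.approx(math.exp(-0.5))

    def test_monotone_decay_from_midpoint(self):
        grid = nd_weight(np.arange(50, 101), 17)
        assert np.all(np.diff(grid) < 0)

    def test_invalid_scale_rejected(self):
        with pytest.raises(ValueError):
            nd_weight(50, 0)


class TestCongruency:
    @pytest.mark.parametrize("ability,sign,expected", [
        ("High", +1, "congruent"),
        ("Low", +1, "incongruent"),
        ("High", -1, "incongruent"),
        ("Low", -1, "congruent"),
    ])
    def test_mapping(self, ability, sign, expected):
        assert congruency(ability, sign) == expected


class TestModelRegistry:
    @pytest.mark.parametrize("mid,n_alpha,n_params", [
        ("M1", 2, 11), ("M2", 4, 13), ("M3", 4, 13), ("M4", 4, 13),
        ("M5", 8, 17), ("M6", 8, 17), ("M7", 8, 19), ("M8", 8, 17),
        ("M9", 0, 9),
    ])
    def test_parameter_counts(self, mid, n_alpha, n_params):
        spec = get_model(mid)
        assert spec.n_alpha == n_alpha
        assert spec.n_params == n_params

    def test_unknown_model_rejected(self):
        with pytest.raises(KeyError):
            get_model("M10")

    def test_pack_unpack_round_trip(self):
        spec = get_model("M7")
        vals = {n: i + 0.01 for i, n in enumerate(spec.param_names)}
        theta = spec.pack(**vals)
        assert spec.unpack(theta) == pytest.approx(vals)


class TestUpdate:
    def test_plain_delta_rule(self):
        assert delta_update(50.0, 70.0, 0.5) == 60.0

    def test_full_discounting_cancels_update(self):
        # w*ND = 1 at the midpoint of the scale means no learning there
        assert delta_update(40.0, 50.0, 0.8, w=1.0) == 40.0

    def test_extended_model_scalar_example(self):
        nd = math.exp(-((90.0 - 50.0) ** 2) / (2 * 17.0**2))
        expected = 40.0 + 0.8 * 50.0 * (1.0 - 0.5 * nd)
        assert delta_update(40.0, 90.0, 0.8, w=0.5, sigma_nd=17.0) == pytest.approx(expected)

    def test_model_aware_update_selects_valence_alpha(self):
        spec = get_model("M3")
        theta = spec.pack(**{
            "alpha_Self_PE+": 0.5, "alpha_Self_PE-": 0.1,
            "alpha_Other_PE+": 0.2, "alpha_Other_PE-": 0.2,
            **{f"sv_{s}_{a}_{b}": 50.0 for s in te.SESSIONS
               for a in te.AGENTS for b in te.ABILITIES},
            "sigma": 8.0})
        up = update_expectation(spec, theta, 50.0, "T1", "Self", "High", 70.0)
        down = update_expectation(spec, theta, 50.0, "T1", "Self", "High", 40.0)
        assert up == 60.0          # positive PE uses alpha 0.5
        assert down == 49.0        # negative PE uses alpha 0.1
        assert update_expectation(spec, theta, 50.0, "T1", "Self", "High", 50.0) == 50.0

    @given(exp=st.floats(0, 100), fb=st.floats(0, 100),
           alpha=st.floats(0, 1), w=st.floats(0, 1))
    def test_update_never_overshoots(self, exp, fb, alpha, w):
        out = delta_update(exp, fb, alpha, w)
        assert min(exp, fb) - 1e-9 <= out <= max(exp, fb) + 1e-9


def _theta(spec, alpha_map, sv=50.0, sigma=8.0, w=0.0):
    vals = {}
    for n in spec.param_names:
        if n.startswith("alpha"):
            vals[n] = alpha_map(n)
        elif n.startswith("w_"):
            vals[n] = w
        elif n.startswith(("sv_", "mean_")):
            vals[n] = sv
        else:
            vals[n] = sigma
    return spec.pack(**vals)


@pytest.fixture(scope="module")
def cell_fixture():
    fb = np.array([62.0, 71.0, 40.0, 85.0, 55.0])
    obs = np.array([50.0, 58.0, 66.0, 52.0, 70.0])
    return CellData("T1", "Self", "High", fb, obs)


class TestNesting:
    def test_nesting_chain_trajectories_identical(self, cell_fixture):
        """M7(w=0, alpha_T2=alpha_T1) == M6(alpha_T1=alpha_T2) == M3(==valence) == M1."""
        rates = {"Self": {"+": 0.45, "-": 0.45}, "Other": {"+": 0.2, "-": 0.2}}

        def amap(name):
            agent = "Self" if "Self" in name else "Other"
            return rates[agent]["+" if name.endswith("PE+") else "-"] \
                if "PE" in name else rates[agent]["+"]

        preds = {}
        for mid in ("M1", "M3", "M6", "M7"):
            spec = get_model(mid)
            preds[mid] = predict_cell(spec, _theta(spec, amap), cell_fixture)
        for mid in ("M3", "M6", "M7"):
            np.testing.assert_array_equal(preds["M1"], preds[mid])

    def test_valence_split_breaks_equality(self, cell_fixture):
        def amap(name):
            return 0.5 if name.endswith("PE+") else 0.1

        m3 = predict_cell(get_model("M3"), _theta(get_model("M3"), amap), cell_fixture)
        m1 = predict_cell(get_model("M1"), _theta(get_model("M1"), lambda n: 0.5),
                          cell_fixture)
        assert not np.array_equal(m3, m1)


class TestPointwiseLoglik:
    def test_matches_scalar_bruteforce(self, cell_fixture):
        spec = get_model("M7")
        theta = _theta(spec, lambda n: 0.4 if n.endswith("PE+") else 0.25,
                       sv=45.0, sigma=9.0, w=0.3)
        got = pointwise_loglik(spec, theta, [cell_fixture])[0]
        # independent scalar replay of the recursion and truncated density
        exp = 45.0
        expected = []
        for fb, obs in zip(cell_fixture.feedback, cell_fixture.observed):
            a, b = (0 - exp) / 9.0, (100 - exp) / 9.0
            expected.append(stats.truncnorm.logpdf(obs, a, b, loc=exp, scale=9.0))
            pe = fb - exp
            alpha = 0.4 if pe >= 0 else 0.25
            nd = math.exp(-((fb - 50) ** 2) / (2 * 17.0**2))
            exp = exp + alpha * pe * (1 - 0.3 * nd)
        np.testing.assert_allclose(got, expected, rtol=1e-10)

    def test_peak_density_when_observation_matches_prediction(self):
        spec = get_model("M9")
        cell = CellData("T1", "Self", "High",
                        np.array([60.0] * 4), np.array([50.0] * 4))
        theta = _theta(spec, lambda n: 0.0, sv=50.0, sigma=10.0)
        ll = pointwise_loglik(spec, theta, [cell])[0]
        peak = truncnorm_logpdf(50.0, 50.0, 10.0)
        np.testing.assert_allclose(ll, peak)
        theta2 = _theta(spec, lambda n: 0.0, sv=50.0, sigma=20.0)
        assert pointwise_loglik(spec, theta2, [cell]).sum() < ll.sum()

    def test_mean_model_invariant_to_trial_order(self, rng):
        spec = get_model("M9")
        fb = rng.uniform(0, 100, 8)
        obs = rng.uniform(0, 100, 8)
        theta = _theta(spec, lambda n: 0.0, sv=42.0, sigma=7.0)
        a = pointwise_loglik(spec, theta, [CellData("T1", "Self", "High", fb, obs)])
        perm = rng.permutation(8)
        b = pointwise_loglik(spec, theta,
                             [CellData("T1", "Self", "High", fb[perm], obs[perm])])
        assert a.sum() == pytest.approx(b.sum())

    def test_sigma_must_be_positive(self, cell_fixture):
        spec = get_model("M1")
        theta = _theta(spec, lambda n: 0.3, sigma=0.0)
        with pytest.raises(ValueError):
            pointwise_loglik(spec, theta, [cell_fixture])


class TestSimulateTrajectory:
    def test_zero_learning_rate_stays_at_sv(self):
        spec = get_model("M6")
        theta = _theta(spec, lambda n: 0.0, sv=37.0, sigma=5.0)
        d = te.make_design(seed=0, n_participants=1)[0]
        recs = simulate_trajectory(spec, theta, d, "T1", noise=False)
        assert all(r.expectation == 37.0 for r in recs)

    def test_full_updating_tracks_feedback(self):
        spec = get_model("M6")
        theta = _theta(spec, lambda n: 1.0, sv=50.0, sigma=5.0)
        d = te.make_design(seed=0, n_participants=1)[0]
        recs = simulate_trajectory(spec, theta, d, "T1", noise=False)
        for agent, ability in te.CELLS:
            cell = [r for r in recs if r.agent == agent and r.ability == ability]
            for prev, nxt in zip(cell, cell[1:]):
                assert nxt.expectation == pytest.approx(prev.feedback)

    def test_m7_with_zero_w_reproduces_m6(self):
        d = te.make_design(seed=3, n_participants=1)[0]

        def amap(name):
            return 0.35 if "Self" in name else 0.2

        m6 = get_model("M6")
        m7 = get_model("M7")
        r6 = simulate_trajectory(m6, _theta(m6, amap, sv=55.0), d, "T1", noise=False)
        r7 = simulate_trajectory(m7, _theta(m7, amap, sv=55.0, w=0.0), d, "T1",
                                 noise=False)
        assert [(r.expectation, r.feedback) for r in r6] \
            == [(r.expectation, r.feedback) for r in r7]

    def test_cells_from_frame_canonical_order(self, small_cohort):
        tr = small_cohort.trials[small_cohort.trials.participant == 0]
        cells = cells_from_frame(tr)
        assert len(cells) == 8
        assert [c.session for c in cells[:4]] == ["T1"] * 4
        assert all(len(c.feedback) == 20 for c in cells)
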