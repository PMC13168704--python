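"""Decision variables, stop probabilities, likelihoods, stopping laws."""

import math

import numpy as np
import pytest

from beadtask import models as dm
from beadtask.task_math import Condition
from beadtask.trials import PrevSummary, Trial

from conftest import random_params

COND_HL = Condition("high", "low")
STIM = "DDCDCDDDCCDDDCDCDDCD"


class TestDecayedCI:
    @pytest.mark.parametrize(
        "prefix,alpha,expected",
        [
            (["dog", "dog", "cat"], 1.0, 1.0),  # plain count difference
            (["dog", "cat", "cat"], 0.0, -1.0),  # only the last draw survives
            (["dog", "dog"], 0.5, 1.5),
        ],
    )
    def test_examples(self, prefix, alpha, expected):
        assert dm.decayed_ci(prefix, alpha) == pytest.approx(expected)

    def test_alpha_domain(self):
        with pytest.raises(ValueError):
            dm.decayed_ci("DD", 1.5)

    def test_limit_reductions(self, rng):
        # alpha=1 -> raw dog-cat difference; alpha=0 -> +-1 last sample
        for _ in range(20):
            signs = rng.choice([1, -1], size=rng.integers(1, 21))
            stim = "".join("D" if s > 0 else "C" for s in signs)
            assert dm.decayed_ci(stim, 1.0) == pytest.approx(signs.sum())
            assert dm.decayed_ci(stim, 0.0) == pytest.approx(signs[-1])


class TestDecayedCIProperties:
    from hypothesis import given, settings, strategies as st

    @given(
        signs=st.lists(st.sampled_from([1, -1]), min_size=1, max_size=20),
        alpha=st.floats(0.0, 1.0),
    )
    @settings(derandomize=True, max_examples=60)
    def test_geometric_bound_and_exact_limits(self, signs, alpha):
        """|CI| never exceeds the geometric series bound, and the alpha
        limits reduce to the raw count difference / the last draw."""
        stim = "".join("D" if s > 0 else "C" for s in signs)
        ci = dm.decayed_ci(stim, alpha)
        bound = sum(alpha**k for k in range(len(signs)))
        assert abs(ci) <= bound + 1e-9
        if alpha == 1.0:
            assert ci == pytest.approx(sum(signs))
        if alpha == 0.0:
            assert ci == pytest.approx(signs[-1])


class TestBuildDVs:
    def test_decision_point_zero(self):
        dvs = dm.build_dvs(COND_HL, "", PrevSummary())
        assert dvs.draws_j == 0 and dvs.cumu_cost == 0
        assert dvs.abs_cumu_info == 0 and dvs.total_log_evidence == 0

    def test_cumulative_cost(self):
        dvs = dm.build_dvs(COND_HL, "DDC")
        assert dvs.cumu_cost == pytest.approx(12.0)  # 3 draws x 4 credits

    def test_total_log_evidence(self):
        cond = Condition("zero", "high")
        dvs = dm.build_dvs(cond, "DD", alpha=1.0)
        assert dvs.total_log_evidence == pytest.approx(2 * math.log(4))

    def test_previous_trial_carryover(self):
        dvs = dm.build_dvs(COND_HL, "D", PrevSummary(7, -1))
        assert dvs.last_draw == 7 and dvs.last_correct == -1


class TestStopProb:
    def test_zero_coefficients_give_half(self):
        m = dm.get_model("cost_only")
        dvs = dm.build_dvs(COND_HL, "DD")
        assert dm.stop_prob(m, dm.param_template(m), dvs) == pytest.approx(0.5)

    def test_logistic_identity(self):
        m = dm.get_model("cost_only")
        params = dm.param_template(m)
        params["beta_0"] = math.log(3)
        dvs = dm.build_dvs(Condition("zero", "low"), "")
        assert dm.stop_prob(m, params, dvs) == pytest.approx(0.75)

    def test_two_stage_arithmetic(self):
        # p = p1 + (1-p1) * p_sec * p2 with p1=0.2, p_sec=0.5, p2=0.4
        from scipy.special import logit

        m = dm.get_model("cost_ccond_evidence")
        params = dm.param_template(m)
        params["beta_0"] = float(logit(0.2))
        params["beta_0_s2"] = float(logit(0.4))
        params.update(p_sec_zero=0.5, p_sec_low=0.5, p_sec_high=0.5)
        dvs = dm.build_dvs(Condition("zero", "low"), "")
        assert dm.stop_prob(m, params, dvs, Condition("zero", "low")) == pytest.approx(0.36)

    def test_second_thought_zero_reduces_to_stage_one(self, rng):
        m = dm.get_model("evidence_econd_cost")
        params = random_params(m, rng)
        params.update(p_sec_low_evid=0.0, p_sec_high_evid=0.0)
        p1_only = dict(params)
        dvs = dm.build_dvs(COND_HL, "DCD", alpha=params["alpha_decay"])
        from scipy.special import expit

        x1 = params["beta_0"] + sum(
            params[dm._STAGE_PARAM[d]] * dvs.value(d) for d in m.stage1_dvs
        )
        assert dm.stop_prob(m, p1_only, dvs, COND_HL) == pytest.approx(float(expit(x1)))

    def test_independent_hazards_identity(self, rng):
        # p_sec = 1 with identical stage predictors: p = 1 - (1-p1)(1-p2)
        m = dm.get_model("cost_ccond_evidence")
        params = random_params(m, rng)
        params.update(p_sec_zero=1.0, p_sec_low=1.0, p_sec_high=1.0)
        dvs = dm.build_dvs(COND_HL, "DD", alpha=params["alpha_decay"])
        p = dm.stop_prob(m, params, dvs, COND_HL)
        from scipy.special import expit

        x1 = params["beta_0"] + sum(
            params[dm._STAGE_PARAM[d]] * dvs.value(d) for d in m.stage1_dvs
        )
        x2 = params["beta_0_s2"] + sum(
            params["s2_" + dm._STAGE_PARAM[d]] * dvs.value(d) for d in m.stage2_dvs
        )
        p1, p2 = float(expit(x1)), float(expit(x2))
        assert p == pytest.approx(1 - (1 - p1) * (1 - p2))

    def test_missing_condition_rejected(self, rng):
        m = dm.get_model("cost_ccond_evidence")
        dvs = dm.build_dvs(COND_HL, "")
        with pytest.raises(ValueError):
            dm.stop_prob(m, random_params(m, rng), dvs)


class TestTrialHazards:
    @pytest.mark.parametrize("name", sorted(dm.MODELS), ids=str)
    def test_matches_pointwise_stop_prob(self, name, rng):
        """Vectorized hazards equal the per-decision-point construction."""
        m = dm.get_model(name)
        params = random_params(m, rng)
        prev = PrevSummary(5, 1)
        h = dm.trial_hazards(m, params, COND_HL, STIM, prev)
        alpha = params.get("alpha_decay", 1.0)
        expected = [
            dm.stop_prob(m, params, dm.build_dvs(COND_HL, STIM[:j], prev, alpha), COND_HL)
            for j in range(20)
        ]
        assert h == pytest.approx(expected, abs=1e-12)


def _make_trial(n, cond=COND_HL, stim=STIM):
    correct = True
    return Trial(cond, "left", stim, n, "left", correct, 100.0 - cond.c * n)


class TestTrialLoglik:
    def test_constant_half_hazard(self):
        m = dm.get_model("cost_only")
        ll = dm.trial_loglik(m, dm.param_template(m), _make_trial(2))
        assert ll == pytest.approx(math.log(0.125))

    def test_stop_at_zero(self):
        from scipy.special import logit

        m = dm.get_model("cost_only")
        params = dm.param_template(m)
        params["beta_0"] = float(logit(0.9))
        assert dm.trial_loglik(m, params, _make_trial(0)) == pytest.approx(math.log(0.9))

    def test_forced_stop_certain_continuation(self):
        m = dm.get_model("cost_only")
        params = dm.param_template(m)
        params["beta_0"] = -60.0  # hazard numerically zero
        assert dm.trial_loglik(m, params, _make_trial(20)) == pytest.approx(0.0, abs=1e-12)

    def test_loglik_decreases_when_stop_becomes_unlikely(self):
        # pushing the intercept down makes the observed stop less likely
        m = dm.get_model("cost_only")
        params = dm.param_template(m)
        lls = []
        for b0 in (0.0, -1.0, -2.0):
            p = dict(params, beta_0=b0)
            lls.append(dm.trial_loglik(m, p, _make_trial(1)))
        assert lls[0] > lls[1] > lls[2]


class TestStoppingDistribution:
    def test_point_masses(self):
        m = dm.get_model("cost_only")
        params = dm.param_template(m)
        params["beta_0"] = 60.0
        d = dm.stopping_distribution(m, params, STIM, COND_HL)
        assert d[0] == pytest.approx(1.0)
        params["beta_0"] = -60.0
        d = dm.stopping_distribution(m, params, STIM, COND_HL)
        assert d[20] == pytest.approx(1.0)

    @pytest.mark.parametrize("name", sorted(dm.MODELS), ids=str)
    def test_normalizes(self, name, rng):
        m = dm.get_model(name)
        for _ in range(50):
            d = dm.stopping_distribution(m, random_params(m, rng), STIM, COND_HL, PrevSummary(3, -1))
            assert d.sum() == pytest.approx(1.0, abs=1e-12)
            assert np.all(d >= 0)


class TestDatasetLoglik:
    def test_empty_dataset(self):
        import pandas as pd

        m = dm.get_model("cost_only")
        total, pw = dm.dataset_loglik(m, {}, pd.DataFrame())
        assert total == 0.0 and len(pw) == 0

    def test_single_trial_matches_trial_loglik(self, rng):
        import pandas as pd

        m = dm.get_model("cost_evidence")
        params = random_params(m, rng)
        trial = _make_trial(4)
        df = pd.DataFrame(
            [
                {
                    "participant_id": "a",
                    "cost_level": "high",
                    "evidence_level": "low",
                    "trial_index": 0,
                    "n_samples": 4,
                    "stimuli": STIM,
                    "correct": 1,
                }
            ]
        )
        total, pw = dm.dataset_loglik(m, {"a": params}, df)
        assert total == pytest.approx(dm.trial_loglik(m, params, trial))
        assert pw[0] == pytest.approx(total)

    def test_true_parameters_dominate_perturbed_ones(self):
        """Across replicate cohorts the generating parameters yield a
        higher likelihood than a +-2 shift of one coefficient in the
        vast majority of replicates."""
        import pandas as pd

        from beadtask.simulate import GroupLevel, make_cohort

        m = dm.get_model("cost_only")
        gl = GroupLevel(
            m,
            {"beta_0": -4.0, "beta_L0": 1.0, "beta_H0": 2.0,
             "beta_draw": 0.3, "beta_cumu_cost": 0.03},
            {k: 0.0 for k in m.param_names},
        )
        true_params = {k: gl.means[k] for k in m.param_names}
        wins = 0
        n_rep = 100
        for rep in range(n_rep):
            co = make_cohort(gl, 2, seed=rep, trials_per_miniblock=2)
            shifted = dict(true_params)
            shifted["beta_draw"] += 2.0 if rep % 2 else -2.0
            pb_true = {c: true_params for c in co.child_ids}
            pb_shift = {c: shifted for c in co.child_ids}
            ll_true, _ = dm.dataset_loglik(m, pb_true, co.data)
            ll_shift, _ = dm.dataset_loglik(m, pb_shift, co.data)
            wins += ll_true > ll_shift
        assert wins >= 0.95 * n_rep

    def test_sequential_trials_match_chained_prevsummary(self, nt_cohort, rng):
        """Stacked likelihood agrees with per-trial evaluation that threads
        the previous trial's summary by hand (dual-route check)."""
        m = dm.get_model("cost_evidence")
        df = nt_cohort.data
        child = df["participant_id"].iloc[0]
        sub = df[df["participant_id"] == child].sort_values("trial_index")
        params = random_params(m, rng)
        total, pw = dm.dataset_loglik(m, {child: params}, sub)
        prev = PrevSummary()
        manual = 0.0
        for _, row in sub.iterrows():
            cond = Condition(row["cost_level"], row["evidence_level"])
            tr = Trial(
                cond, "left", row["stimuli"], int(row["n_samples"]),
                row["choice"], bool(row["correct"]), float(row["credits"]),
            )
            manual += dm.trial_loglik(m, params, tr, prev)
            prev = PrevSummary(int(row["n_samples"]), 1 if row["correct"] else -1)
        assert total == pytest.approx(manual, rel=1e-10)
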