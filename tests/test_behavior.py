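"""Behavioral summaries, mixed-model contrasts, parameter correlations."""

import numpy as np
import pandas as pd
import pytest

from beadtask import task_math
from beadtask.behavior import (
    correlate_params_behavior,
    fit_group_contrasts,
    summarize_children,
)
from beadtask.simulate import default_group_level, make_cohort


def _fixture_trials(ns, cost="high", evid="low", pid="kid", correct=1):
    c = {"zero": 0, "low": 1, "high": 4}[cost]
    return pd.DataFrame(
        {
            "participant_id": pid,
            "group": "g",
            "cost_level": cost,
            "evidence_level": evid,
            "n_samples": ns,
            "correct": correct,
            "credits": [100.0 * correct - c * n for n in ns],
        }
    )


class TestSummaries:
    def test_constant_samples_zero_variation(self):
        s = summarize_children(_fixture_trials([5, 5, 5]))
        assert s["sampling_variation"].iloc[0] == 0.0

    def test_all_correct_zero_cost_credits(self):
        s = summarize_children(_fixture_trials([3, 7], cost="zero"))
        assert s["mean_credits"].iloc[0] == 100.0

    def test_mean_signed_deviation_fixture(self):
        # optimal n at q=0.6, c=4 is 1; deviations of (1,3,5,7) average 3
        s = summarize_children(_fixture_trials([1, 3, 5, 7]))
        assert s["mean_signed_deviation"].iloc[0] == pytest.approx(3.0)

    def test_single_trial_cell_flagged(self):
        s = summarize_children(_fixture_trials([4]))
        assert not s["variation_defined"].iloc[0]
        assert np.isnan(s["sampling_variation"].iloc[0])

    def test_unknown_condition_label(self):
        bad = _fixture_trials([3]).assign(cost_level="medium")
        with pytest.raises(ValueError, match="unknown condition"):
            summarize_children(bad)

    def test_efficiency_single_source_of_truth(self, nt_cohort):
        """Per-trial efficiency equals task_math.efficiency exactly."""
        df = nt_cohort.data
        s = summarize_children(df)
        row = s.iloc[0]
        sub = df[
            (df.participant_id == row.participant_id)
            & (df.cost_level == row.cost_level)
            & (df.evidence_level == row.evidence_level)
        ]
        cond = task_math.Condition(row.cost_level, row.evidence_level)
        manual = np.mean([task_math.efficiency(n, cond.q, cond.c) for n in sub.n_samples])
        assert row.mean_efficiency == pytest.approx(manual)

    def test_forced_zero_sampling_composition(self):
        """An agent that never samples scores coin-flip accuracy and the
        n=0 efficiency of each condition."""
        from beadtask.models import get_model, param_template
        from beadtask.simulate import GroupLevel, make_cohort

        m = get_model("cost_only")
        means = {k: 0.0 for k in m.param_names}
        means["beta_0"] = 60.0
        gl = GroupLevel(m, means, {k: 0.0 for k in m.param_names})
        co = make_cohort(gl, 4, seed=3, trials_per_miniblock=16)
        s = summarize_children(co.data)
        assert (s["mean_samples"] == 0).all()
        assert abs(s["accuracy"].mean() - 0.5) < 0.1
        for _, row in s.iterrows():
            cond = task_math.Condition(row.cost_level, row.evidence_level)
            assert row.mean_efficiency == pytest.approx(
                task_math.efficiency(0, cond.q, cond.c)
            )


class TestGroupContrasts:
    def _two_group_summary(self, seed_a=1, seed_b=2, profile_b="NT", n=8):
        a = make_cohort(default_group_level("NT"), n, seed=seed_a, group="NT")
        b = make_cohort(default_group_level(profile_b), n, seed=seed_b, group=profile_b if profile_b != "NT" else "NT2")
        return summarize_children(pd.concat([a.data, b.data], ignore_index=True))

    def test_zero_outcome_gives_zero_contrasts(self):
        s = self._two_group_summary()
        s["zeros"] = 0.0
        ct = fit_group_contrasts(s, "zeros")
        assert (ct.contrasts["estimate"] == 0).all()

    def test_exchangeable_groups_mostly_null(self):
        """Same generating process in both groups: the overall contrast
        should rarely reach significance."""
        import warnings

        nonsig = 0
        reps = 8
        for r in range(reps):
            s = self._two_group_summary(seed_a=100 + r, seed_b=200 + r)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ct = fit_group_contrasts(s, "mean_samples", seed=r)
            p = ct.contrasts.loc[ct.contrasts.effect.str.contains("overall"), "p_adj"].iloc[0]
            nonsig += p > 0.05
        assert nonsig >= reps - 2

    def test_asd_like_group_shows_higher_variation(self):
        """ASD-like generator produces greater sampling variation, the
        direction reported for autistic children."""
        import warnings

        s = self._two_group_summary(seed_a=11, seed_b=12, profile_b="ASD", n=12)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ct = fit_group_contrasts(s.dropna(subset=["sampling_variation"]), "sampling_variation")
        row = ct.contrasts[ct.contrasts.effect.str.contains("overall")].iloc[0]
        # groups sort alphabetically: estimate is NT - ASD
        assert row["estimate"] < 0

    def test_needs_two_groups(self):
        a = make_cohort(default_group_level("NT"), 4, seed=1, group="NT")
        s = summarize_children(a.data)
        with pytest.raises(ValueError, match="two groups"):
            fit_group_contrasts(s, "mean_samples")

    def test_adjusted_p_not_below_raw(self):
        s = self._two_group_summary(seed_a=5, seed_b=6)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ct = fit_group_contrasts(s, "mean_efficiency")
        assert (ct.contrasts["p_adj"] >= ct.contrasts["p_raw"] - 1e-12).all()
        assert ((ct.contrasts["ci_low"] <= ct.contrasts["estimate"])
                & (ct.contrasts["estimate"] <= ct.contrasts["ci_high"])).all()


class TestCorrelations:
    def _frames(self, x, y):
        pid = [f"k{i}" for i in range(len(x))]
        params = pd.DataFrame({"beta_draw": x}, index=pid)
        summaries = pd.DataFrame(
            {"participant_id": pid, "mean_efficiency": y}
        )
        return params, summaries

    def test_monotone_pair(self):
        x = np.arange(10.0)
        params, summaries = self._frames(x, x**3)
        out = correlate_params_behavior(params, summaries, [("beta_draw", "mean_efficiency")])
        assert out["rho"].iloc[0] == pytest.approx(1.0)

    def test_antimonotone_pair(self):
        x = np.arange(10.0)
        params, summaries = self._frames(x, -x)
        out = correlate_params_behavior(params, summaries, [("beta_draw", "mean_efficiency")])
        assert out["rho"].iloc[0] == pytest.approx(-1.0)

    def test_too_few_pairs(self):
        params, summaries = self._frames([1, 2, 3], [1, 2, 3])
        with pytest.raises(ValueError, match="fewer than 4"):
            correlate_params_behavior(params, summaries, [("beta_draw", "mean_efficiency")])

    def test_fdr_nominal_level(self, rng):
        """Independent null pairs: the realized false-discovery proportion
        stays near the 5% target on average."""
        fdp = []
        for _ in range(300):
            x = rng.standard_normal((30, 20))
            y = rng.standard_normal(30)
            from scipy import stats as st

            p = np.array([st.spearmanr(x[:, j], y).pvalue for j in range(20)])
            from statsmodels.stats.multitest import fdrcorrection

            rejected, _ = fdrcorrection(p, alpha=0.05)
            fdp.append(rejected.any())
        # under the global null, any rejection is a false discovery;
        # BH controls this family-wise at ~alpha
        assert np.mean(fdp) <= 0.08
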