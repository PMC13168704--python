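"""Simulation-based calibration in both directions.

On the conjugate normal-mean toy the analytic posterior is exactly
calibrated, so ranks of the true parameter within posterior draws are
uniform and the chi-square uniformity test passes; deliberately halving
the posterior SD concentrates ranks at the extremes and the test
rejects.  The same rank machinery drives SBC of the hierarchical
stopping-model pipeline (see beadtask.calibration.run_sbc).
"""

from beadtask import run_sbc_toy, uniformity_check

for inflation, label in ((1.0, "calibrated posterior"), (0.5, "posterior SD halved")):
    res = run_sbc_toy(N=300, D=400, posterior_sd_inflation=inflation, seed=11)
    check = uniformity_check(res.ranks["mu"].to_numpy(), res.D)
    print(f"{label}: chi-square {check.statistic:.1f}, p = {check.p_value:.4f}, "
          f"{'PASS' if check.passed else 'REJECT'}")
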