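"""Behavioral outcome pipeline.

Per-child condition summaries (sample counts, credits, accuracy,
efficiency, signed deviation from the optimal sample size, inter-trial
sampling variation), mixed-model group contrasts of those outcomes, and
FDR-corrected rank correlations between model parameters and behavior.

Mixed models are deliberately delegated to statsmodels' ``MixedLM``;
this module owns the outcome construction, the contrast specification,
and the multiplicity-adjustment policy.  Degrees of freedom use the
between-subject approximation (children minus groups) rather than a
Satterthwaite correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
from scipy import stats

from . import task_math
from .task_math import ALL_CONDITIONS, COST_LEVELS, EVIDENCE_LEVELS

# efficiency / deviation lookups: 21 sample counts x 6 conditions
_EFF = {
    (cond.cost_level, cond.evidence_level): np.array(
        [task_math.efficiency(n, cond.q, cond.c) for n in range(21)]
    )
    for cond in ALL_CONDITIONS
}
_OPT = {
    (cond.cost_level, cond.evidence_level): task_math.optimal_n(cond.q, cond.c)
    for cond in ALL_CONDITIONS
}


def summarize_children(dataset: pd.DataFrame) -> pd.DataFrame:
    """Per child x condition behavioral summary.

    ``sampling_variation`` is the inter-trial standard deviation of the
    sample count (ddof=1); cells with fewer than two trials are returned
    with NaN variation and flagged in ``variation_defined``.
    """
    required = {"participant_id", "cost_level", "evidence_level", "n_samples", "correct", "credits"}
    missing = required - set(dataset.columns)
    if missing:
        raise ValueError(f"dataset missing columns: {sorted(missing)}")
    bad_cost = set(dataset["cost_level"]) - set(COST_LEVELS)
    bad_evid = set(dataset["evidence_level"]) - set(EVIDENCE_LEVELS)
    if bad_cost or bad_evid:
        raise ValueError(f"unknown condition labels: {sorted(bad_cost | bad_evid)}")

    df = dataset.copy()
    key = list(zip(df["cost_level"], df["evidence_level"]))
    n = df["n_samples"].to_numpy(dtype=int)
    df["efficiency"] = [_EFF[k][v] for k, v in zip(key, n)]
    df["signed_deviation"] = [v - _OPT[k] for k, v in zip(key, n)]

    group_cols = ["participant_id", "cost_level", "evidence_level"]
    if "group" in df.columns:
        group_cols.insert(1, "group")
    out = (
        df.groupby(group_cols, sort=False)
        .agg(
            n_trials=("n_samples", "size"),
            mean_samples=("n_samples", "mean"),
            mean_credits=("credits", "mean"),
            accuracy=("correct", "mean"),
            mean_efficiency=("efficiency", "mean"),
            mean_signed_deviation=("signed_deviation", "mean"),
            sampling_variation=("n_samples", lambda x: x.std(ddof=1)),
        )
        .reset_index()
    )
    out["variation_defined"] = out["n_trials"] >= 2
    return out


# ---------------------------------------------------------------------------
# group contrasts


@dataclass
class ContrastTable:
    """Marginal means and multiplicity-adjusted group contrasts."""

    outcome: str
    emmeans: pd.DataFrame  # group x cost x evidence estimated marginal means
    contrasts: pd.DataFrame  # effect, estimate, se, stat, df, p_raw, p_adj, d, CI
    converged: bool
    random_structure: str


def _emm_design(groups, costs=tuple(COST_LEVELS), evids=tuple(EVIDENCE_LEVELS)):
    return pd.DataFrame(
        [{"group": g, "cost_level": c, "evidence_level": e} for g, c, e in product(groups, costs, evids)]
    )


def fit_group_contrasts(
    summaries: pd.DataFrame,
    outcome: str,
    n_mc: int = 100_000,
    seed: int = 0,
) -> ContrastTable:
    """Mixed-model group contrasts for one behavioral outcome.

    Fits ``outcome ~ group * cost * evidence`` with a per-participant
    random intercept (the parsimonious simplification of the maximal
    within-participant structure; richer structures that fail to
    converge are reduced automatically by ``MixedLM``).  Contrasts are
    the overall group difference and the per-condition-level group
    differences; p-values get a single-step max-|z| adjustment from the
    joint normal distribution of the contrast estimates.
    """
    import statsmodels.formula.api as smf

    df = summaries.dropna(subset=[outcome]).copy()
    groups = sorted(df["group"].unique())
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for g in groups:
        if df.loc[df["group"] == g, "participant_id"].nunique() < 2:
            raise ValueError("need at least two children per group")

    if df[outcome].abs().max() == 0:
        # degenerate outcome: all contrasts are exactly zero
        emm = _emm_design(groups)
        emm["emmean"] = 0.0
        contrasts = pd.DataFrame(
            [{"effect": "group overall", "estimate": 0.0, "se": 0.0, "stat": 0.0,
              "df": np.nan, "p_raw": 1.0, "p_adj": 1.0, "d": 0.0,
              "ci_low": 0.0, "ci_high": 0.0}]
        )
        return ContrastTable(outcome, emm, contrasts, True, "degenerate")

    formula = f"{outcome} ~ C(group) * C(cost_level) * C(evidence_level)"
    model = smf.mixedlm(formula, data=df, groups=df["participant_id"])
    structure = "random intercept | participant"
    fit = None
    for method in ("lbfgs", "cg", "powell"):
        try:
            fit = model.fit(reml=True, method=method)
            break
        except (np.linalg.LinAlgError, ValueError):
            continue
    if fit is None:
        # singular random-effect structure: simplify to a fixed-effects
        # model with cluster-robust (by participant) covariance
        structure = "none (simplified after singular random-effect fit)"
        model = smf.ols(formula, data=df)
        fit = model.fit(cov_type="cluster", cov_kwds={"groups": df["participant_id"]})
    fe = fit.fe_params if hasattr(fit, "fe_params") else fit.params
    cov = fit.cov_params().loc[fe.index, fe.index].to_numpy()

    # design rows for the 2 x 3 x 2 marginal-mean grid
    import patsy

    grid = _emm_design(groups)
    X = patsy.dmatrix(model.data.design_info, grid, return_type="dataframe").to_numpy()
    grid["emmean"] = X @ fe.to_numpy()

    # contrast matrix: rows of (difference of design-row averages)
    rows, labels = [], []
    g0, g1 = groups[0], groups[1]
    m0 = (grid["group"] == g0).to_numpy()
    m1 = (grid["group"] == g1).to_numpy()
    rows.append(X[m1].mean(axis=0) - X[m0].mean(axis=0))
    labels.append(f"group {g1}-{g0} overall")
    for c in COST_LEVELS:
        sel = (grid["cost_level"] == c).to_numpy()
        rows.append(X[m1 & sel].mean(axis=0) - X[m0 & sel].mean(axis=0))
        labels.append(f"group {g1}-{g0} | cost {c}")
    for e in EVIDENCE_LEVELS:
        sel = (grid["evidence_level"] == e).to_numpy()
        rows.append(X[m1 & sel].mean(axis=0) - X[m0 & sel].mean(axis=0))
        labels.append(f"group {g1}-{g0} | evidence {e}")
    C = np.vstack(rows)

    est = C @ fe.to_numpy()
    vc = C @ cov @ C.T
    se = np.sqrt(np.maximum(np.diag(vc), 1e-300))
    z = est / se
    dfree = df["participant_id"].nunique() - len(groups)
    p_raw = 2 * stats.t.sf(np.abs(z), dfree)

    # single-step adjustment: reference distribution of max |z| under H0
    rng = np.random.default_rng(seed)
    corr = vc / np.outer(se, se)
    # contrasts are linearly dependent (the overall row averages the
    # per-level rows), so factor via eigendecomposition with clipping
    evals, evecs = np.linalg.eigh((corr + corr.T) / 2)
    L = evecs * np.sqrt(np.clip(evals, 0.0, None))
    draws = np.abs(L @ rng.standard_normal((len(se), n_mc))).max(axis=0)
    p_adj = np.array([(draws >= abs(zi)).mean() for zi in z])
    p_adj = np.maximum(p_adj, p_raw)

    # standardized effect size: contrast / total outcome SD
    if hasattr(fit, "cov_re") and fit.cov_re.size:
        sd_tot = float(np.sqrt(fit.cov_re.iloc[0, 0] + fit.scale))
    else:
        sd_tot = float(df[outcome].std())
    d = est / sd_tot
    tcrit = stats.t.ppf(0.975, dfree)
    contrasts = pd.DataFrame(
        {
            "effect": labels,
            "estimate": est,
            "se": se,
            "stat": z,
            "df": dfree,
            "p_raw": p_raw,
            "p_adj": p_adj,
            "d": d,
            "ci_low": est - tcrit * se,
            "ci_high": est + tcrit * se,
        }
    )
    return ContrastTable(outcome, grid, contrasts, bool(getattr(fit, "converged", True)), structure)


# ---------------------------------------------------------------------------
# parameter-behavior correlations


def correlate_params_behavior(
    child_params: pd.DataFrame,
    summaries: pd.DataFrame,
    pairs: list[tuple[str, str]],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Spearman correlations between per-child parameter estimates and
    per-child behavioral metrics, with Benjamini-Hochberg FDR adjustment.

    ``child_params`` is indexed by participant_id with one column per
    parameter; ``summaries`` is averaged over conditions per child
    before correlating.
    """
    from statsmodels.stats.multitest import fdrcorrection

    per_child = summaries.groupby("participant_id").mean(numeric_only=True)
    merged = child_params.join(per_child, how="inner")
    results = []
    for x, y in pairs:
        sub = merged[[x, y]].dropna()
        if len(sub) < 4:
            raise ValueError(f"fewer than 4 complete pairs for ({x}, {y})")
        rho, p = stats.spearmanr(sub[x], sub[y])
        results.append({"parameter": x, "metric": y, "rho": rho, "p_raw": p, "n": len(sub)})
    out = pd.DataFrame(results)
    rejected, p_adj = fdrcorrection(out["p_raw"].to_numpy(), alpha=alpha)
    out["p_adj"] = p_adj
    out["significant"] = rejected
    return out
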