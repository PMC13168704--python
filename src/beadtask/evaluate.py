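"""Model comparison and posterior predictive checking.

Out-of-sample fit is estimated with PSIS-LOO (Pareto-smoothed
importance-sampling leave-one-out cross-validation) on the per-trial
pointwise log-likelihood matrix, and models are weighted with
pseudo-Bayesian model averaging regularized by the Bayesian bootstrap
(pseudo-BMA+).  Comparison is always within one group of children.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp, softmax

PARETO_K_THRESHOLD = 0.7


@dataclass
class LooResult:
    elpd: float
    se: float
    elpd_pointwise: np.ndarray  # (T,)
    pareto_k: np.ndarray  # (T,)

    @property
    def n_bad_k(self) -> int:
        return int((self.pareto_k > PARETO_K_THRESHOLD).sum())


def psis_loo(pointwise_loglik: np.ndarray) -> LooResult:
    """PSIS-LOO expected log predictive density from a (draws, trials)
    log-likelihood matrix.

    Importance weights for leaving out trial i are proportional to
    1/p(y_i | draw); their tail is stabilized by Pareto smoothing
    (delegated to arviz), and the Pareto shape k flags trials whose
    weights are too heavy-tailed to trust (k > 0.7).
    """
    import arviz as az

    ll = np.asarray(pointwise_loglik, dtype=float)
    if ll.ndim != 2 or ll.shape[0] < 2:
        raise ValueError("need a (draws >= 2, trials) log-likelihood matrix")
    if not np.all(np.isfinite(ll)):
        raise ValueError("non-finite log-likelihood entries")
    S, T = ll.shape
    lw, k = az.psislw(-ll.T)  # (T, S) normalized smoothed log-weights
    lw = np.asarray(lw)
    elpd_i = logsumexp(lw + ll.T, axis=1)
    se = float(np.sqrt(T * np.var(elpd_i)))
    return LooResult(float(elpd_i.sum()), se, elpd_i, np.asarray(k))


def pseudo_bma_plus(
    elpd_pointwise: dict[str, np.ndarray],
    n_bootstrap: int = 1000,
    rng: np.random.Generator | None = None,
) -> dict[str, float]:
    """Pseudo-BMA+ model weights from pointwise ELPD vectors.

    Each Bayesian-bootstrap replicate reweights trials with a flat
    Dirichlet draw, recomputes each model's total ELPD, and converts the
    totals to weights with a softmax; the reported weight is the average
    over replicates (it regularizes away overconfidence from a few
    influential trials).
    """
    if len(elpd_pointwise) < 2:
        raise ValueError("need at least two models")
    names = list(elpd_pointwise)
    lengths = {len(v) for v in elpd_pointwise.values()}
    if len(lengths) != 1:
        raise ValueError("pointwise ELPD vectors are misaligned across models")
    T = lengths.pop()
    E = np.stack([np.asarray(elpd_pointwise[n], dtype=float) for n in names])  # (M, T)
    rng = rng or np.random.default_rng()
    w_dir = rng.dirichlet(np.ones(T), size=n_bootstrap)  # (B, T)
    z = T * (w_dir @ E.T)  # (B, M)
    weights = softmax(z, axis=1).mean(axis=0)
    weights = weights / weights.sum()
    return dict(zip(names, weights))


@dataclass
class ComparisonTable:
    """Within-group model comparison, best model first."""

    table: pd.DataFrame  # model, elpd_loo, se_elpd, delta_elpd, weight, n_bad_pareto_k

    @property
    def best(self) -> str:
        return str(self.table.iloc[0]["model"])


def compare_models(
    pointwise_by_model: dict[str, np.ndarray],
    n_bootstrap: int = 1000,
    seed: int | None = 0,
) -> ComparisonTable:
    """Rank models by PSIS-LOO ELPD and attach pseudo-BMA+ weights.

    ``pointwise_by_model`` maps model name to its (draws, trials)
    log-likelihood matrix on the *same* dataset.
    """
    trials = {name: m.shape[1] for name, m in pointwise_by_model.items()}
    if len(set(trials.values())) != 1:
        raise ValueError(f"models evaluated on different datasets: {trials}")
    loos = {name: psis_loo(m) for name, m in pointwise_by_model.items()}
    if len(loos) > 1:
        weights = pseudo_bma_plus(
            {n: r.elpd_pointwise for n, r in loos.items()},
            n_bootstrap=n_bootstrap,
            rng=np.random.default_rng(seed),
        )
    else:
        weights = {next(iter(loos)): 1.0}
    best = max(loos, key=lambda n: loos[n].elpd)
    rows = []
    for name, r in loos.items():
        diff = r.elpd_pointwise - loos[best].elpd_pointwise
        # paired SE of the ELPD difference against the best model
        delta_se = float(np.sqrt(len(diff) * np.var(diff))) if name != best else 0.0
        rows.append(
            {
                "model": name,
                "elpd_loo": r.elpd,
                "se_elpd": r.se,
                "delta_elpd": r.elpd - loos[best].elpd,
                "delta_se": delta_se,
                "weight": weights[name],
                "n_bad_pareto_k": r.n_bad_k,
            }
        )
    table = pd.DataFrame(rows).sort_values("elpd_loo", ascending=False, ignore_index=True)
    return ComparisonTable(table)


def posterior_predictive(
    posterior,
    dataset: pd.DataFrame,
    max_draws: int = 200,
    carryover_across_blocks: bool = True,
) -> pd.DataFrame:
    """Predicted sample-number distributions against observed histograms.

    For each retained posterior draw the analytic stopping distribution
    of every trial is computed from the *full* pregenerated stimulus
    sequence (including animals the child never saw), then averaged over
    draws and trials within each cost x evidence condition.  Returns a
    long table with columns ``cost_level, evidence_level, n,
    p_predicted, p_observed``.
    """
    from .fitting import GroupPosterior  # noqa: F401 (documents expected type)
    from .likelihood import StackedData, hazards_full
    from .models import get_model

    if "stimuli" not in dataset.columns or dataset["stimuli"].map(len).min() < 20:
        raise ValueError("posterior predictive needs full 20-symbol stimulus sequences")
    model = get_model(posterior.model_name)
    sd = StackedData.from_frame(dataset, carryover_across_blocks=carryover_across_blocks)
    if sd.child_ids != posterior.child_ids:
        raise ValueError("dataset children do not match the posterior")
    chains, draws = posterior.child.shape[:2]
    total = chains * draws
    take = np.linspace(0, total - 1, min(max_draws, total)).astype(int)
    flat_child = posterior.child.reshape(total, sd.n_children, len(posterior.param_names))

    pred = np.zeros((sd.n_trials, 21))
    for s in take:
        h = hazards_full(sd, model, flat_child[s])
        surv = np.cumprod(1.0 - h, axis=1)
        dist = np.empty((sd.n_trials, 21))
        dist[:, 0] = h[:, 0]
        dist[:, 1:20] = h[:, 1:] * surv[:, :-1]
        dist[:, 20] = surv[:, -1]
        pred += dist
    pred /= len(take)

    rows = []
    for cost_code, cost in enumerate(("zero", "low", "high")):
        for evid_code, evid in enumerate(("low", "high")):
            mask = (sd.cost_code == cost_code) & (sd.evid_code == evid_code)
            if not mask.any():
                continue
            p_pred = pred[mask].mean(axis=0)
            obs = np.bincount(sd.n_samples[mask], minlength=21) / mask.sum()
            for n in range(21):
                rows.append(
                    {
                        "cost_level": cost,
                        "evidence_level": evid,
                        "n": n,
                        "p_predicted": p_pred[n],
                        "p_observed": obs[n],
                    }
                )
    return pd.DataFrame(rows)
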