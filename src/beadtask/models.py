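"""The six logistic stopping-rule models.

Each decision point ``j`` within a trial (``j = 0..19``; a forced stop
occurs at ``j = 20``) carries a vector of decision variables (DVs).
One-stage models pass a linear combination of DVs through a logistic
function to obtain the per-decision stop probability (hazard).
Two-stage models combine a first-stage hazard, a "second-thought"
probability conditioned on the cost or the evidence condition, and a
second-stage hazard built from the complementary DV family:

    p = p1 + (1 - p1) * p_sec * p2

Evidence accumulates within a trial as decayed cumulative information
(CI): CI_0 = 0 and CI_j = alpha * CI_{j-1} +- 1 (+1 dog, -1 cat), so
``alpha = 1`` recovers the raw count difference and ``alpha = 0`` keeps
only the most recent draw.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .task_math import Condition
from .trials import PrevSummary, Trial, encode_stimuli

# ---------------------------------------------------------------------------
# decision variables

#: DV names in canonical order; 'intercept' is implicit per stage
COST_DVS = ("cost_low", "cost_high", "draws", "cumu_cost")
EVIDENCE_DVS = ("unit_evid", "abs_cumu_info", "total_log_evid", "last_draw", "last_correct")


@dataclass(frozen=True)
class DecisionVariables:
    """DV values at one decision point (trial i, decision j)."""

    cost_low_dummy: float
    cost_high_dummy: float
    draws_j: int
    cumu_cost: float
    unit_log_evidence: float
    abs_cumu_info: float
    total_log_evidence: float
    last_draw: float
    last_correct: float

    def value(self, name: str) -> float:
        return {
            "cost_low": self.cost_low_dummy,
            "cost_high": self.cost_high_dummy,
            "draws": float(self.draws_j),
            "cumu_cost": self.cumu_cost,
            "unit_evid": self.unit_log_evidence,
            "abs_cumu_info": self.abs_cumu_info,
            "total_log_evid": self.total_log_evidence,
            "last_draw": self.last_draw,
            "last_correct": self.last_correct,
        }[name]


def decayed_ci(stimuli_prefix, alpha: float) -> float:
    """Decayed cumulative information after the given stimulus prefix.

    CI_0 = 0; CI_j = alpha*CI_{j-1} + 1 after a dog, - 1 after a cat.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("decay parameter must lie in [0, 1]")
    ci = 0.0
    for s in encode_stimuli(stimuli_prefix):
        ci = alpha * ci + float(s)
    return ci


def ci_path(signs: np.ndarray, alpha) -> np.ndarray:
    """CI at j = 0..len(signs) for one sign sequence (vector form)."""
    out = np.zeros(len(signs) + 1)
    for j in range(1, len(signs) + 1):
        out[j] = alpha * out[j - 1] + signs[j - 1]
    return out


def unit_log_evidence(q: float) -> float:
    """Log likelihood ratio carried by a single draw: ln(q / (1-q))."""
    return math.log(q / (1.0 - q))


def build_dvs(
    condition: Condition,
    stimuli_prefix,
    prev: PrevSummary = PrevSummary(),
    alpha: float = 1.0,
) -> DecisionVariables:
    """DVs at the decision point reached after seeing ``stimuli_prefix``."""
    signs = encode_stimuli(stimuli_prefix)
    j = len(signs)
    if j > condition.max_samples:
        raise ValueError("prefix longer than the sample cap")
    ule = unit_log_evidence(condition.q)
    absci = abs(decayed_ci(signs, alpha)) if j else 0.0
    return DecisionVariables(
        cost_low_dummy=1.0 if condition.cost_level == "low" else 0.0,
        cost_high_dummy=1.0 if condition.cost_level == "high" else 0.0,
        draws_j=j,
        cumu_cost=condition.c * j,
        unit_log_evidence=ule,
        abs_cumu_info=absci,
        total_log_evidence=ule * absci,
        last_draw=float(prev.last_draw),
        last_correct=float(prev.last_correct),
    )


# ---------------------------------------------------------------------------
# model registry

_STAGE_PARAM = {
    "cost_low": "beta_L0",
    "cost_high": "beta_H0",
    "draws": "beta_draw",
    "cumu_cost": "beta_cumu_cost",
    "unit_evid": "beta_unit_evid",
    "abs_cumu_info": "beta_abs_cumu_info",
    "total_log_evid": "beta_total_log_evid",
    "last_draw": "beta_last_draw",
    "last_correct": "beta_last_correct",
}

SEC_PARAMS = {
    "none": (),
    "cost": ("p_sec_zero", "p_sec_low", "p_sec_high"),
    "evidence": ("p_sec_low_evid", "p_sec_high_evid"),
}


@dataclass(frozen=True)
class ModelSpec:
    """One of the six stopping models: DV sets per stage and conditioning."""

    name: str
    stage1_dvs: tuple
    stage2_dvs: tuple = ()
    conditioning: str = "none"  # selects p_sec: none | cost | evidence

    @property
    def two_stage(self) -> bool:
        return bool(self.stage2_dvs)

    @property
    def uses_decay(self) -> bool:
        evid = ("abs_cumu_info", "total_log_evid")
        return any(d in evid for d in self.stage1_dvs + self.stage2_dvs)

    @property
    def stage1_params(self) -> tuple:
        return ("beta_0",) + tuple(_STAGE_PARAM[d] for d in self.stage1_dvs)

    @property
    def stage2_params(self) -> tuple:
        if not self.two_stage:
            return ()
        return ("beta_0_s2",) + tuple("s2_" + _STAGE_PARAM[d] for d in self.stage2_dvs)

    @property
    def sec_params(self) -> tuple:
        return SEC_PARAMS[self.conditioning]

    @property
    def param_names(self) -> tuple:
        names = self.stage1_params + self.stage2_params + self.sec_params
        if self.uses_decay:
            names = names + ("alpha_decay",)
        return names

    def validate_params(self, params: dict) -> None:
        missing = set(self.param_names) - set(params)
        if missing:
            raise ValueError(f"missing parameters for {self.name}: {sorted(missing)}")
        if self.uses_decay and not 0.0 <= params["alpha_decay"] <= 1.0:
            raise ValueError("alpha_decay outside [0, 1]")
        for p in self.sec_params:
            if not 0.0 <= params[p] <= 1.0:
                raise ValueError(f"{p} outside [0, 1]")


MODELS: dict[str, ModelSpec] = {
    m.name: m
    for m in (
        ModelSpec("cost_only", COST_DVS),
        ModelSpec("cost_evidence", COST_DVS + EVIDENCE_DVS),
        ModelSpec("cost_ccond_evidence", COST_DVS, EVIDENCE_DVS, "cost"),
        ModelSpec("cost_econd_evidence", COST_DVS, EVIDENCE_DVS, "evidence"),
        ModelSpec("evidence_ccond_cost", EVIDENCE_DVS, COST_DVS, "cost"),
        ModelSpec("evidence_econd_cost", EVIDENCE_DVS, COST_DVS, "evidence"),
    )
}

#: human-readable aliases matching the published model names
MODEL_ALIASES = {
    "cost_only": "Cost only",
    "cost_evidence": "Cost + Evidence",
    "cost_ccond_evidence": "Cost ->(C-cond) Evidence",
    "cost_econd_evidence": "Cost ->(E-cond) Evidence",
    "evidence_ccond_cost": "Evidence ->(C-cond) Cost",
    "evidence_econd_cost": "Evidence ->(E-cond) Cost",
}


def get_model(name: str) -> ModelSpec:
    try:
        return MODELS[name]
    except KeyError:
        raise ValueError(f"unknown model {name!r}; known: {sorted(MODELS)}") from None


def param_template(model: ModelSpec) -> dict:
    """All-zero coefficient set (p_sec = 0.5, alpha_decay = 1)."""
    out = {name: 0.0 for name in model.param_names}
    for p in model.sec_params:
        out[p] = 0.5
    if model.uses_decay:
        out["alpha_decay"] = 1.0
    return out


def _sec_prob(model: ModelSpec, params: dict, condition: Condition) -> float:
    if model.conditioning == "cost":
        return params[{"zero": "p_sec_zero", "low": "p_sec_low", "high": "p_sec_high"}[condition.cost_level]]
    if model.conditioning == "evidence":
        return params[{"low": "p_sec_low_evid", "high": "p_sec_high_evid"}[condition.evidence_level]]
    raise ValueError("one-stage model has no second-thought probability")


def _stage_x(dvs: DecisionVariables, dv_names, params: dict, prefix: str, intercept: str) -> float:
    x = params[intercept]
    for d in dv_names:
        x += params[prefix + _STAGE_PARAM[d]] * dvs.value(d)
    return x


def stop_prob(model: ModelSpec, params: dict, dvs: DecisionVariables, condition: Condition | None = None) -> float:
    """Probability of stopping at one decision point.

    For two-stage models ``condition`` selects the second-thought
    probability and must be provided.
    """
    model.validate_params(params)
    p1 = float(expit(_stage_x(dvs, model.stage1_dvs, params, "", "beta_0")))
    if not model.two_stage:
        return p1
    if condition is None:
        raise ValueError("two-stage models need the condition to select p_sec")
    p2 = float(expit(_stage_x(dvs, model.stage2_dvs, params, "s2_", "beta_0_s2")))
    psec = _sec_prob(model, params, condition)
    return p1 + (1.0 - p1) * psec * p2


def trial_hazards(
    model: ModelSpec,
    params: dict,
    condition: Condition,
    stimuli,
    prev: PrevSummary = PrevSummary(),
    j_max: int = 20,
) -> np.ndarray:
    """Stop probabilities at decision points j = 0..min(j_max, 19).

    The hazard at decision point ``j`` conditions on the first ``j``
    stimuli; decision point 20 is a forced stop and has no hazard.
    """
    model.validate_params(params)
    signs = encode_stimuli(stimuli)
    alpha = params.get("alpha_decay", 1.0)
    n_points = min(j_max, condition.max_samples - 1) + 1
    ci = ci_path(signs[: n_points - 1], alpha) if model.uses_decay else np.zeros(n_points)
    ule = unit_log_evidence(condition.q)
    j = np.arange(n_points, dtype=float)
    absci = np.abs(ci)
    dv_rows = {
        "cost_low": 1.0 if condition.cost_level == "low" else 0.0,
        "cost_high": 1.0 if condition.cost_level == "high" else 0.0,
        "draws": j,
        "cumu_cost": condition.c * j,
        "unit_evid": ule,
        "abs_cumu_info": absci,
        "total_log_evid": ule * absci,
        "last_draw": float(prev.last_draw),
        "last_correct": float(prev.last_correct),
    }

    def stage_x(dv_names, prefix, intercept):
        x = np.full(n_points, params[intercept])
        for d in dv_names:
            x = x + params[prefix + _STAGE_PARAM[d]] * np.asarray(dv_rows[d])
        return x

    p1 = expit(stage_x(model.stage1_dvs, "", "beta_0"))
    if not model.two_stage:
        return p1
    p2 = expit(stage_x(model.stage2_dvs, "s2_", "beta_0_s2"))
    psec = _sec_prob(model, params, condition)
    return p1 + (1.0 - p1) * psec * p2


def trial_loglik(
    model: ModelSpec,
    params: dict,
    trial: Trial,
    prev: PrevSummary = PrevSummary(),
) -> float:
    """Log-likelihood of the observed stopping time of one trial.

    A voluntary stop at ``n < 20`` contributes the hazard at ``n`` and
    continuation factors before it; the forced stop at 20 contributes
    continuation factors only.
    """
    n = trial.n_samples
    cap = trial.condition.max_samples
    hazards = trial_hazards(model, params, trial.condition, trial.stimuli, prev, j_max=min(n, cap - 1))
    if not np.all(np.isfinite(hazards)):
        raise FloatingPointError("non-finite stop probabilities")
    with np.errstate(divide="ignore"):
        if n < cap:
            ll = np.log1p(-hazards[:n]).sum() + np.log(hazards[n])
        else:
            ll = np.log1p(-hazards[:cap]).sum()
    return float(ll)


def stopping_distribution(
    model: ModelSpec,
    params: dict,
    stimuli,
    condition: Condition,
    prev: PrevSummary = PrevSummary(),
) -> np.ndarray:
    """Analytic P(N = n) over n = 0..20 for one full stimulus sequence."""
    h = trial_hazards(model, params, condition, stimuli, prev)
    cap = condition.max_samples
    surv = np.concatenate(([1.0], np.cumprod(1.0 - h)))
    out = np.empty(cap + 1)
    out[:cap] = h * surv[:cap]
    out[cap] = surv[cap]
    return out


def dataset_loglik(model: ModelSpec, params_by_child: dict, dataset) -> tuple[float, np.ndarray]:
    """Total and per-trial log-likelihood of a trial table.

    ``dataset`` is the canonical trial DataFrame (see :mod:`beadtask.io`);
    ``params_by_child`` maps participant_id to a parameter dict.  Trials
    must be consecutive (experiment order) within each participant.
    """
    from .likelihood import StackedData  # deferred: avoids import cycle

    if len(dataset) == 0:
        return 0.0, np.zeros(0)
    stacked = StackedData.from_frame(dataset)
    theta = np.empty((stacked.n_children, len(model.param_names)))
    for ci, child in enumerate(stacked.child_ids):
        p = params_by_child[child]
        model.validate_params(p)
        theta[ci] = [p[name] for name in model.param_names]
    total, pointwise, _ = stacked.loglik(model, theta, want_grad=False)
    return float(total), pointwise
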