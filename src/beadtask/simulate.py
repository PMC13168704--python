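"""Synthetic-cohort generator.

Emulates the study design — six mini-blocks crossing three sampling
costs (0/1/4 credits) with two evidence strengths (q = 0.6/0.8), 16
trials per mini-block (96 trials; 8 per mini-block gives the 48-trial
short form) — and agents whose stopping decisions follow any of the six
logistic stopping models.  Stimulus sequences are i.i.d. Bernoulli(q)
draws of the predominant animal, pregenerated to the full length of 20
so that unseen draws are available for posterior predictive checks.
Judgments follow the majority of the seen animals with a fair-coin tie
break, the correctness model underlying the optimality mathematics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import models as dm
from .task_math import COST_LEVELS, EVIDENCE_LEVELS, Condition
from .trials import PrevSummary, Trial, decode_stimuli

# ---------------------------------------------------------------------------
# design


@dataclass(frozen=True)
class Design:
    """Ordered mini-blocks of the experiment."""

    blocks: tuple  # six (cost_level, evidence_level) pairs
    trials_per_miniblock: int = 16
    block_order_seed: int | None = None

    def __post_init__(self) -> None:
        if self.trials_per_miniblock < 1:
            raise ValueError("trials_per_miniblock must be >= 1")
        if sorted(self.blocks) != sorted(
            (c, e) for c in COST_LEVELS for e in EVIDENCE_LEVELS
        ):
            raise ValueError("design must contain each of the six conditions exactly once")

    @property
    def n_trials(self) -> int:
        return 6 * self.trials_per_miniblock

    def trial_conditions(self):
        """(block_index, Condition) per trial, in experiment order."""
        for b, (cost, evid) in enumerate(self.blocks):
            cond = Condition(cost, evid)
            for _ in range(self.trials_per_miniblock):
                yield b, cond


def make_design(trials_per_miniblock: int = 16, seed: int | None = None) -> Design:
    """Randomized block order: cost blocks permuted, evidence mini-blocks
    shuffled within each cost block."""
    rng = np.random.default_rng(seed)
    costs = list(COST_LEVELS)
    rng.shuffle(costs)
    blocks = []
    for cost in costs:
        evids = list(EVIDENCE_LEVELS)
        rng.shuffle(evids)
        blocks.extend((cost, e) for e in evids)
    return Design(tuple(blocks), trials_per_miniblock, seed)


def gen_stimuli(q: float, true_island: str, rng: np.random.Generator) -> str:
    """Twenty i.i.d. draws; each equals the predominant animal w.p. ``q``.

    The left island is dog-predominant, the right cat-predominant.
    """
    if not 0.0 < q <= 1.0:
        raise ValueError("q must lie in (0, 1]")
    predominant = 1 if true_island == "left" else -1
    signs = np.where(rng.random(20) < q, predominant, -predominant)
    return decode_stimuli(signs)


# ---------------------------------------------------------------------------
# agents


def simulate_agent(
    params: dict,
    model: dm.ModelSpec,
    design: Design,
    rng: np.random.Generator,
    carryover_across_blocks: bool = True,
) -> list[Trial]:
    """Simulate one child's full session under a stopping model.

    At each decision point j = 0..19 the agent stops with the model's
    hazard; at j = 20 stopping is forced.  The judgment follows the
    majority of the seen animals (ties: fair coin).
    """
    model.validate_params(params)
    trials: list[Trial] = []
    prev = PrevSummary()
    prev_block = None
    for block, cond in design.trial_conditions():
        if not carryover_across_blocks and block != prev_block:
            prev = PrevSummary()
        prev_block = block
        true_island = "left" if rng.random() < 0.5 else "right"
        stimuli = gen_stimuli(cond.q, true_island, rng)
        hazards = dm.trial_hazards(model, params, cond, stimuli, prev)
        stops = rng.random(len(hazards)) < hazards
        n = int(np.argmax(stops)) if stops.any() else cond.max_samples
        evidence = sum(1 if s == "D" else -1 for s in stimuli[:n])
        if evidence > 0:
            choice = "left"
        elif evidence < 0:
            choice = "right"
        else:
            choice = "left" if rng.random() < 0.5 else "right"
        correct = choice == true_island
        credits = 100.0 * correct - cond.c * n
        trials.append(Trial(cond, true_island, stimuli, n, choice, correct, credits))
        prev = PrevSummary(last_draw=n, last_correct=1 if correct else -1)
    return trials


def trials_to_frame(trials: list[Trial], participant_id, group: str, design: Design) -> pd.DataFrame:
    """Canonical trial table (one row per trial) for one participant."""
    rows = []
    for idx, ((block, _), tr) in enumerate(zip(design.trial_conditions(), trials)):
        rows.append(
            {
                "participant_id": participant_id,
                "group": group,
                "block_index": block,
                "cost_level": tr.condition.cost_level,
                "evidence_level": tr.condition.evidence_level,
                "trial_index": idx,
                "n_samples": tr.n_samples,
                "stimuli": tr.stimuli,
                "choice": tr.choice,
                "correct": int(tr.correct),
                "credits": tr.credits,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# cohorts


@dataclass
class GroupLevel:
    """Group-level normal distributions on the unconstrained scale.

    ``means``/``sds`` map parameter names to the location and spread of
    the population distribution; alpha_decay and p_sec entries are on
    the log-odds scale and mapped through a logistic transform per
    child, matching the hierarchical model.
    """

    model: dm.ModelSpec
    means: dict
    sds: dict

    def __post_init__(self) -> None:
        missing = set(self.model.param_names) - set(self.means)
        if missing:
            raise ValueError(f"group means missing {sorted(missing)}")
        if any(self.sds.get(k, 0.0) < 0 for k in self.model.param_names):
            raise ValueError("group SDs must be >= 0")

    def draw_child(self, rng: np.random.Generator) -> dict:
        out = {}
        for name in self.model.param_names:
            v = self.means[name] + self.sds.get(name, 0.0) * rng.standard_normal()
            out[name] = _constrain(name, v)
        return out


def _constrain(name: str, v: float) -> float:
    from scipy.special import expit

    if name == "alpha_decay" or name.startswith("p_sec"):
        return float(expit(v))
    return float(v)


@dataclass
class Cohort:
    """A simulated group: trial table plus generating truth for replay."""

    data: pd.DataFrame
    group_level: GroupLevel
    child_params: dict  # participant_id -> constrained parameter dict
    designs: dict  # participant_id -> Design
    seed: int | None = None

    @property
    def child_ids(self) -> list:
        return list(self.child_params)


def make_cohort(
    group_level: GroupLevel,
    n_children: int,
    seed: int | None = None,
    group: str = "synthetic",
    trials_per_miniblock: int = 16,
    short_form_ids: tuple = (),
    counterbalance: bool = True,
) -> Cohort:
    """Simulate a cohort of children with parameters drawn from the group.

    ``short_form_ids`` lists participant indices given the 48-trial short
    form (8 trials per mini-block).  With ``counterbalance`` each child
    receives their own block order.
    """
    if n_children < 1:
        raise ValueError("need at least one child")
    rng = np.random.default_rng(seed)
    frames, child_params, designs = [], {}, {}
    for i in range(n_children):
        pid = f"{group}_{i:03d}"
        tpm = 8 if i in short_form_ids else trials_per_miniblock
        dseed = int(rng.integers(2**31 - 1)) if counterbalance else 0
        design = make_design(tpm, dseed)
        params = group_level.draw_child(rng)
        trials = simulate_agent(params, group_level.model, design, rng)
        frames.append(trials_to_frame(trials, pid, group, design))
        child_params[pid] = params
        designs[pid] = design
    return Cohort(pd.concat(frames, ignore_index=True), group_level, child_params, designs, seed)


def replay_stimuli(
    params: dict,
    model: dm.ModelSpec,
    sequences: pd.DataFrame,
    rng: np.random.Generator,
    participant_id: str = "sweep",
    carryover_across_blocks: bool = True,
) -> pd.DataFrame:
    """Simulate stopping choices on predetermined stimulus sequences.

    Mirrors the study's own simulations, which replayed the exact
    stimulus sequences participants saw rather than fresh draws.
    """
    model.validate_params(params)
    prev = PrevSummary()
    prev_block = None
    out = []
    for idx, rec in enumerate(sequences.to_dict("records")):
        cond = Condition(rec["cost_level"], rec["evidence_level"])
        block = rec.get("block_index", 0)
        if not carryover_across_blocks and block != prev_block:
            prev = PrevSummary()
        prev_block = block
        stimuli = rec["stimuli"]
        island = rec.get("true_island", "left")
        hazards = dm.trial_hazards(model, params, cond, stimuli, prev)
        stops = rng.random(len(hazards)) < hazards
        n = int(np.argmax(stops)) if stops.any() else cond.max_samples
        evidence = sum(1 if s == "D" else -1 for s in stimuli[:n])
        if evidence > 0:
            choice = "left"
        elif evidence < 0:
            choice = "right"
        else:
            choice = "left" if rng.random() < 0.5 else "right"
        correct = choice == island
        out.append(
            {
                "participant_id": participant_id,
                "group": participant_id,
                "block_index": block,
                "cost_level": cond.cost_level,
                "evidence_level": cond.evidence_level,
                "trial_index": idx,
                "n_samples": n,
                "stimuli": stimuli,
                "choice": choice,
                "correct": int(correct),
                "credits": 100.0 * correct - cond.c * n,
            }
        )
        prev = PrevSummary(last_draw=n, last_correct=1 if correct else -1)
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# parameter sweeps


def sweep_parameter(
    base_params: dict,
    model: dm.ModelSpec,
    name: str,
    grid,
    sequences: pd.DataFrame | None = None,
    n_trials_per_condition: int = 200,
    seed: int | None = None,
) -> pd.DataFrame:
    """Behavioral metrics as one parameter moves along a grid.

    For each grid value the base parameter set is modified at ``name``
    only and an agent is simulated on a *fixed* stimulus set, so metric
    changes along the grid reflect the parameter alone.  ``sequences``
    may supply the stimulus table (canonical trial-frame columns
    ``block_index``, ``cost_level``, ``evidence_level``, ``stimuli``,
    ``true_island``); otherwise one is generated from ``seed``.
    Reported per condition: mean samples, mean efficiency, and the
    inter-trial SD of samples.
    """
    from .behavior import summarize_children

    if name not in base_params:
        raise ValueError(f"unknown parameter {name!r} for model {model.name}")
    if sequences is None:
        rng = np.random.default_rng(seed)
        design = Design(make_design(16, seed).blocks, n_trials_per_condition, seed)
        recs = []
        for block, cond in design.trial_conditions():
            island = "left" if rng.random() < 0.5 else "right"
            recs.append(
                {
                    "block_index": block,
                    "cost_level": cond.cost_level,
                    "evidence_level": cond.evidence_level,
                    "true_island": island,
                    "stimuli": gen_stimuli(cond.q, island, rng),
                }
            )
        sequences = pd.DataFrame(recs)
    rows = []
    for value in grid:
        params = dict(base_params)
        params[name] = float(value)
        model.validate_params(params)
        rng = np.random.default_rng(seed)  # identical choice noise across grid values
        df = replay_stimuli(params, model, sequences, rng)
        summary = summarize_children(df)
        for _, r in summary.iterrows():
            rows.append(
                {
                    "parameter": name,
                    "value": float(value),
                    "cost_level": r["cost_level"],
                    "evidence_level": r["evidence_level"],
                    "mean_samples": r["mean_samples"],
                    "mean_efficiency": r["mean_efficiency"],
                    "sampling_variation": r["sampling_variation"],
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# study-condition presets

#: Group-level parameters of the winning cost-plus-evidence model chosen
#: to emulate neurotypical-like behavior (moderate sampling that adapts
#: to cost, near-uniform evidence weighting, negative last-trial
#: carryover stabilizing sample counts across trials).
NT_LIKE = {
    "means": {
        "beta_0": -5.2,
        "beta_L0": 1.2,
        "beta_H0": 2.2,
        "beta_draw": 0.28,
        "beta_cumu_cost": 0.035,
        "beta_unit_evid": 0.4,
        "beta_abs_cumu_info": 0.22,
        "beta_total_log_evid": 0.12,
        "beta_last_draw": -0.05,
        "beta_last_correct": 0.1,
        "alpha_decay": 2.2,  # log-odds; expit ~ 0.90
    },
    "sds": {
        "beta_0": 0.8,
        "beta_L0": 0.4,
        "beta_H0": 0.4,
        "beta_draw": 0.08,
        "beta_cumu_cost": 0.015,
        "beta_unit_evid": 0.3,
        "beta_abs_cumu_info": 0.1,
        "beta_total_log_evid": 0.08,
        "beta_last_draw": 0.04,
        "beta_last_correct": 0.1,
        "alpha_decay": 0.7,
    },
}

#: ASD-like preset: lower baseline stopping tendency, stronger nominal
#: cost-condition offsets, weaker within-trial dynamic sensitivity,
#: last-trial influence near zero, faster evidence decay.
ASD_LIKE = {
    "means": {
        "beta_0": -6.0,
        "beta_L0": 1.8,
        "beta_H0": 3.0,
        "beta_draw": 0.18,
        "beta_cumu_cost": 0.015,
        "beta_unit_evid": 0.3,
        "beta_abs_cumu_info": 0.10,
        "beta_total_log_evid": 0.06,
        "beta_last_draw": -0.01,
        "beta_last_correct": 0.1,
        "alpha_decay": 0.4,  # log-odds; expit ~ 0.60
    },
    "sds": NT_LIKE["sds"],
}


def default_group_level(profile: str = "NT", model_name: str = "cost_evidence") -> GroupLevel:
    """Study-condition presets for the cost-plus-evidence model."""
    preset = {"NT": NT_LIKE, "ASD": ASD_LIKE}[profile]
    model = dm.get_model(model_name)
    means = {k: v for k, v in preset["means"].items() if k in model.param_names}
    sds = {k: v for k, v in preset["sds"].items() if k in model.param_names}
    missing = set(model.param_names) - set(means)
    if missing:
        raise ValueError(f"preset lacks parameters for {model_name}: {sorted(missing)}")
    return GroupLevel(model, means, sds)
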