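"""Vectorized stopping-model likelihoods and analytic gradients.

The hierarchical sampler evaluates the joint likelihood of a whole
group (every decision point of every trial of every child) thousands of
times, so trials are flattened once into per-decision-point rows and the
log-likelihood and its gradient with respect to each child's parameters
are computed with array operations.  Gradients are returned on the
*constrained* scale (betas raw, alpha_decay and p_sec in [0, 1]); the
fitting layer applies the chain rule for its unconstrained transforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .models import ModelSpec
from .task_math import COST_LEVELS, EVIDENCE_LEVELS
from .trials import encode_stimuli

_COST_CODE = {"zero": 0, "low": 1, "high": 2}
_EVID_CODE = {"low": 0, "high": 1}
_TINY = 1e-300


def _ci_kernel_py(a: np.ndarray, signs: np.ndarray, want_grad: bool):
    T = len(a)
    ci = np.zeros((T, 20))
    dci = np.zeros((T, 20)) if want_grad else None
    for j in range(1, 20):
        if want_grad:
            dci[:, j] = ci[:, j - 1] + a * dci[:, j - 1]
        ci[:, j] = a * ci[:, j - 1] + signs[:, j - 1]
    return ci, dci


try:  # compiled CI recursion; the numpy fallback is semantically identical
    from numba import njit

    @njit(cache=True, fastmath=False)
    def _ci_kernel_nb(a, signs):  # pragma: no cover - thin compiled kernel
        T = a.shape[0]
        ci = np.zeros((T, 20))
        dci = np.zeros((T, 20))
        for t in range(T):
            at = a[t]
            for j in range(1, 20):
                dci[t, j] = ci[t, j - 1] + at * dci[t, j - 1]
                ci[t, j] = at * ci[t, j - 1] + signs[t, j - 1]
        return ci, dci

    def _ci_kernel(a, signs, want_grad):
        ci, dci = _ci_kernel_nb(a, signs)
        return ci, (dci if want_grad else None)

except ImportError:  # pragma: no cover
    _ci_kernel = _ci_kernel_py


@dataclass
class StackedData:
    """One group's trials flattened to decision-point rows.

    Rows are ordered child-major then trial-major, so per-child and
    per-trial sums reduce to ``np.add.reduceat`` over precomputed
    boundaries.
    """

    child_ids: list
    trial_child: np.ndarray  # (T,) child index per trial
    signs: np.ndarray  # (T, 20) float, +1 dog / -1 cat
    n_samples: np.ndarray  # (T,)
    cost_code: np.ndarray  # (T,) 0 zero / 1 low / 2 high
    evid_code: np.ndarray  # (T,) 0 low / 1 high
    unit_cost: np.ndarray  # (T,)
    unit_evid: np.ndarray  # (T,) ln(q/(1-q))
    last_draw: np.ndarray  # (T,)
    last_correct: np.ndarray  # (T,) +1/-1/0
    row_trial: np.ndarray  # (R,)
    row_j: np.ndarray  # (R,)
    row_stop: np.ndarray  # (R,) bool
    trial_starts: np.ndarray  # (T,)
    child_starts: np.ndarray  # (C,)
    static_dv: dict = field(default_factory=dict)  # name -> (R,) array

    @property
    def n_children(self) -> int:
        return len(self.child_ids)

    @property
    def n_trials(self) -> int:
        return len(self.n_samples)

    # -- construction -------------------------------------------------

    @classmethod
    def from_frame(
        cls,
        df: pd.DataFrame,
        carryover_across_blocks: bool = True,
        standardize_dvs: bool = False,
    ) -> "StackedData":
        required = {"participant_id", "cost_level", "evidence_level", "n_samples", "stimuli", "correct"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"trial table missing columns: {sorted(missing)}")
        df = df.copy()
        if "trial_index" in df.columns:
            df = df.sort_values(["participant_id", "trial_index"], kind="stable")
        else:
            df = df.sort_values(["participant_id"], kind="stable")

        child_ids = list(dict.fromkeys(df["participant_id"]))
        child_index = {c: i for i, c in enumerate(child_ids)}
        T = len(df)
        trial_child = df["participant_id"].map(child_index).to_numpy()
        n = df["n_samples"].to_numpy(dtype=int)
        if n.min() < 0 or n.max() > 20:
            raise ValueError("n_samples outside [0, 20]")
        signs = np.stack([encode_stimuli(s).astype(float) for s in df["stimuli"]])
        if signs.shape[1] != 20:
            raise ValueError("stimulus sequences must have length 20")
        cost_code = df["cost_level"].map(_COST_CODE).to_numpy()
        evid_code = df["evidence_level"].map(_EVID_CODE).to_numpy()
        if np.isnan(cost_code.astype(float)).any() or np.isnan(evid_code.astype(float)).any():
            raise ValueError("unknown cost or evidence level label")
        unit_cost = df["cost_level"].map(COST_LEVELS).to_numpy(dtype=float)
        q = df["evidence_level"].map(EVIDENCE_LEVELS).to_numpy(dtype=float)
        unit_evid = np.log(q / (1 - q))

        # previous-trial summaries, computed in experiment order per child
        block = df["block_index"].to_numpy() if "block_index" in df.columns else np.zeros(T, dtype=int)
        correct = df["correct"].to_numpy(dtype=float)
        last_draw = np.zeros(T)
        last_correct = np.zeros(T)
        for t in range(1, T):
            same_child = trial_child[t] == trial_child[t - 1]
            same_scope = carryover_across_blocks or block[t] == block[t - 1]
            if same_child and same_scope:
                last_draw[t] = n[t - 1]
                last_correct[t] = 1.0 if correct[t - 1] else -1.0

        rows_per_trial = np.where(n < 20, n + 1, 20)
        row_trial = np.repeat(np.arange(T), rows_per_trial)
        row_j = np.concatenate([np.arange(r) for r in rows_per_trial])
        row_stop = np.zeros(len(row_trial), dtype=bool)
        ends = np.cumsum(rows_per_trial)
        row_stop[ends[n < 20] - 1] = True
        trial_starts = np.concatenate(([0], ends[:-1]))
        child_trial_starts = np.searchsorted(trial_child, np.arange(len(child_ids)))
        child_starts = trial_starts[child_trial_starts]

        sd = cls(
            child_ids, trial_child, signs, n, cost_code, evid_code,
            unit_cost, unit_evid, last_draw, last_correct,
            row_trial, row_j, row_stop, trial_starts, child_starts,
        )
        sd._build_static(standardize_dvs)
        return sd

    def _build_static(self, standardize: bool) -> None:
        rt, rj = self.row_trial, self.row_j
        dv = {
            "cost_low": (self.cost_code[rt] == 1).astype(float),
            "cost_high": (self.cost_code[rt] == 2).astype(float),
            "draws": rj.astype(float),
            "cumu_cost": self.unit_cost[rt] * rj,
            "unit_evid": self.unit_evid[rt],
            "last_draw": self.last_draw[rt],
            "last_correct": self.last_correct[rt],
        }
        if standardize:
            for name in ("draws", "cumu_cost", "unit_evid", "last_draw"):
                v = dv[name]
                s = v.std()
                dv[name] = (v - v.mean()) / (s if s > 0 else 1.0)
        self.static_dv = dv
        self.row_child = self.trial_child[rt]
        self.row_unit_evid = dv["unit_evid"]
        self.row_cost_code = self.cost_code[rt]
        self.row_evid_code = self.evid_code[rt]

    # -- likelihood ---------------------------------------------------

    def _ci(self, alpha_child: np.ndarray, want_grad: bool):
        """Decayed CI (and d/d alpha) at columns j = 0..19 per trial."""
        a = alpha_child[self.trial_child]
        return _ci_kernel(a, self.signs, want_grad)

    def _stage_terms(self, model: ModelSpec, stage: int):
        """(param column, DV name) pairs for one stage; intercept name '1'."""
        cols = {name: i for i, name in enumerate(model.param_names)}
        if stage == 1:
            names, prefix, icpt = model.stage1_dvs, "beta_", "beta_0"
        else:
            names, prefix, icpt = model.stage2_dvs, "s2_beta_", "beta_0_s2"
        from .models import _STAGE_PARAM

        pairs = [(cols[icpt], "1")]
        for d in names:
            pname = _STAGE_PARAM[d] if stage == 1 else "s2_" + _STAGE_PARAM[d]
            pairs.append((cols[pname], d))
        return pairs

    def _stage_cache(self, model: ModelSpec, stage: int):
        """Dense (rows x stage-columns) DV matrix with static columns
        prefilled; dynamic (decay-dependent) columns are rewritten per
        evaluation.  Cached per model/stage."""
        if not hasattr(self, "_dense_cache"):
            self._dense_cache = {}
        key = (model.name, stage)
        if key in self._dense_cache:
            return self._dense_cache[key]
        pairs = self._stage_terms(model, stage)
        R = len(self.row_j)
        D = np.empty((R, len(pairs)))
        theta_cols = np.array([c for c, _ in pairs])
        dyn = {}
        for i, (_, name) in enumerate(pairs):
            if name == "1":
                D[:, i] = 1.0
            elif name == "abs_cumu_info":
                dyn["abs"] = i
            elif name == "total_log_evid":
                dyn["tot"] = i
            else:
                D[:, i] = self.static_dv[name]
        self._dense_cache[key] = (D, theta_cols, dyn)
        return self._dense_cache[key]

    def _stop_sign(self):
        if not hasattr(self, "_stop_sign_arr"):
            self._stop_sign_arr = np.where(self.row_stop, 1.0, -1.0)
        return self._stop_sign_arr

    def _child_slices(self):
        if not hasattr(self, "_slices"):
            bounds = np.append(self.child_starts, len(self.row_j))
            self._slices = [(int(bounds[i]), int(bounds[i + 1])) for i in range(self.n_children)]
        return self._slices

    def _stage_x_fast(self, D, theta_cols, dyn, theta, absci):
        if "abs" in dyn:
            D[:, dyn["abs"]] = absci
        if "tot" in dyn:
            D[:, dyn["tot"]] = self.row_unit_evid * absci
        th = theta[:, theta_cols]
        x = np.empty(len(self.row_j))
        for c, (s, e) in enumerate(self._child_slices()):
            x[s:e] = D[s:e] @ th[c]
        return x

    def _grad_stage_fast(self, G, D, theta_cols, w):
        for c, (s, e) in enumerate(self._child_slices()):
            G[c, theta_cols] += D[s:e].T @ w[s:e]




    def loglik(self, model: ModelSpec, theta: np.ndarray, want_grad: bool = True):
        """Joint log-likelihood of the group.

        Parameters
        ----------
        theta : (n_children, n_params) constrained child parameters in
            ``model.param_names`` order.

        Returns
        -------
        total : float
        pointwise : (n_trials,) per-trial log-likelihoods
        grad : (n_children, n_params) or None
        """
        names = model.param_names
        if theta.shape != (self.n_children, len(names)):
            raise ValueError("theta has wrong shape for model/group")
        cols = {name: i for i, name in enumerate(names)}
        stop = self.row_stop
        G = np.zeros((self.n_children, len(names))) if want_grad else None

        absci = dabs = None
        if model.uses_decay:
            alpha = theta[:, cols["alpha_decay"]]
            if np.any((alpha < 0) | (alpha > 1)):
                raise ValueError("alpha_decay outside [0, 1]")
            ci, dci = self._ci(alpha, want_grad)
            ci_rows = ci[self.row_trial, self.row_j]
            absci = np.abs(ci_rows)
            if want_grad:
                dabs = np.sign(ci_rows) * dci[self.row_trial, self.row_j]

        def dx_dalpha(D, theta_cols, dyn):
            # d(stage X)/d alpha through the decayed-|CI| columns, per row
            out = np.zeros(len(self.row_j))
            rc = self.row_child
            if "abs" in dyn:
                out += theta[rc, theta_cols[dyn["abs"]]] * dabs
            if "tot" in dyn:
                out += theta[rc, theta_cols[dyn["tot"]]] * self.row_unit_evid * dabs
            return out

        def grad_scalar(col, w):
            G[:, col] += np.add.reduceat(w, self.child_starts)

        c1 = self._stage_cache(model, 1)
        x1 = self._stage_x_fast(c1[0], c1[1], c1[2], theta, absci)

        if not model.two_stage:
            stop_sign = self._stop_sign()
            ll_row = -np.logaddexp(0.0, -stop_sign * x1)
            if want_grad:
                # on stop rows exp(ll) = p, on continue rows exp(ll) = 1 - p,
                # so d ll/d x = stop_sign * (1 - exp(ll)) in both cases
                dll_dx1 = stop_sign * (1.0 - np.exp(ll_row))
                self._grad_stage_fast(G, c1[0], c1[1], dll_dx1)
                if model.uses_decay:
                    grad_scalar(cols["alpha_decay"], dll_dx1 * dx_dalpha(*c1))
        else:
            c2 = self._stage_cache(model, 2)
            x2 = self._stage_x_fast(c2[0], c2[1], c2[2], theta, absci)
            p1, p2 = _expit(x1), _expit(x2)
            if model.conditioning == "cost":
                sec_names = ("p_sec_zero", "p_sec_low", "p_sec_high")
                sec_idx = self.row_cost_code
            else:
                sec_names = ("p_sec_low_evid", "p_sec_high_evid")
                sec_idx = self.row_evid_code
            sec_cols = np.array([cols[nm] for nm in sec_names])
            sec_mat = theta[:, sec_cols]  # (C, n_sec)
            if np.any((sec_mat < 0) | (sec_mat > 1)):
                raise ValueError("p_sec outside [0, 1]")
            s = sec_mat[self.row_child, sec_idx]
            u = s * p2
            p = np.clip(p1 + (1.0 - p1) * u, _TINY, 1.0)
            log_1mp = -np.logaddexp(0.0, x1) + np.log1p(-u)
            with np.errstate(divide="ignore"):
                ll_row = np.where(stop, np.log(p), log_1mp)
            if want_grad:
                one_m_u = np.maximum(1.0 - u, 1e-12)
                d1 = p1 * (1.0 - p1)
                d2 = p2 * (1.0 - p2)
                dll_dx1 = np.where(stop, (1.0 - u) * d1 / p, -p1)
                dll_dx2 = np.where(stop, (1.0 - p1) * s * d2 / p, -s * d2 / one_m_u)
                dll_ds = np.where(stop, (1.0 - p1) * p2 / p, -p2 / one_m_u)
                self._grad_stage_fast(G, c1[0], c1[1], dll_dx1)
                self._grad_stage_fast(G, c2[0], c2[1], dll_dx2)
                for k, col in enumerate(sec_cols):
                    grad_scalar(col, np.where(sec_idx == k, dll_ds, 0.0))
                if model.uses_decay:
                    evid = c1 if "abs_cumu_info" in model.stage1_dvs else c2
                    dll_dx_e = dll_dx1 if evid is c1 else dll_dx2
                    grad_scalar(cols["alpha_decay"], dll_dx_e * dx_dalpha(*evid))

        pointwise = np.add.reduceat(ll_row, self.trial_starts)
        total = float(ll_row.sum())
        return total, pointwise, G


def _full_grid(sd: StackedData):
    """Row indices covering every decision point j = 0..19 of every trial."""
    T = sd.n_trials
    row_trial = np.repeat(np.arange(T), 20)
    row_j = np.tile(np.arange(20), T)
    dv = {
        "cost_low": (sd.cost_code[row_trial] == 1).astype(float),
        "cost_high": (sd.cost_code[row_trial] == 2).astype(float),
        "draws": row_j.astype(float),
        "cumu_cost": sd.unit_cost[row_trial] * row_j,
        "unit_evid": sd.unit_evid[row_trial],
        "last_draw": sd.last_draw[row_trial],
        "last_correct": sd.last_correct[row_trial],
    }
    return row_trial, row_j, dv


def hazards_full(sd: StackedData, model: ModelSpec, theta: np.ndarray) -> np.ndarray:
    """(T, 20) stop probabilities at every decision point of every trial.

    Unlike :meth:`StackedData.loglik` this ignores the observed stopping
    times; it is the analytic ingredient of posterior predictive checks,
    which require the full pregenerated stimulus sequences.
    """
    cache = getattr(sd, "_full_grid_cache", None)
    if cache is None:
        cache = _full_grid(sd)
        sd._full_grid_cache = cache
    row_trial, row_j, dv = cache
    cols = {name: i for i, name in enumerate(model.param_names)}
    rc = sd.trial_child[row_trial]

    absci = None
    if model.uses_decay:
        alpha = theta[:, cols["alpha_decay"]]
        ci, _ = sd._ci(alpha, want_grad=False)
        absci = np.abs(ci[row_trial, row_j])

    def stage_x(stage):
        pairs = sd._stage_terms(model, stage)
        x = np.zeros(len(row_j))
        for col, name in pairs:
            b = theta[rc, col]
            if name == "1":
                x += b
            elif name == "abs_cumu_info":
                x += b * absci
            elif name == "total_log_evid":
                x += b * dv["unit_evid"] * absci
            else:
                x += b * dv[name]
        return x

    p1 = _expit(stage_x(1))
    if model.two_stage:
        p2 = _expit(stage_x(2))
        if model.conditioning == "cost":
            sec_cols = [cols[n] for n in ("p_sec_zero", "p_sec_low", "p_sec_high")]
            sec_idx = sd.cost_code[row_trial]
        else:
            sec_cols = [cols[n] for n in ("p_sec_low_evid", "p_sec_high_evid")]
            sec_idx = sd.evid_code[row_trial]
        s = theta[:, sec_cols][rc, sec_idx]
        p1 = p1 + (1.0 - p1) * s * p2
    return p1.reshape(sd.n_trials, 20)


from scipy.special import expit as _expit  # noqa: E402
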