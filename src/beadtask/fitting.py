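"""Hierarchical Bayesian estimation of the stopping models.

Each group (autistic-like / neurotypical-like) is fitted separately.
Every child-level parameter is drawn from a group-level normal
distribution on an unconstrained scale — identity for the logistic
coefficients, log-odds for ``alpha_decay`` and the second-thought
probabilities — with the group mean and SD estimated from the data.
Sampling uses the non-centered parameterization (standard-normal child
latents scaled by the group SD) and the in-package HMC sampler; split
R-hat and effective sample sizes come from arviz.

Default priors: group means ~ Normal(0, 2) on the unconstrained scale,
group SDs ~ half-Normal(1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from . import hmc
from .likelihood import StackedData
from .models import ModelSpec, get_model


def _is_constrained(name: str) -> bool:
    return name == "alpha_decay" or name.startswith("p_sec")


@dataclass(frozen=True)
class PriorSpec:
    """Group-level priors on the unconstrained scale."""

    mean_loc: float = 0.0
    mean_scale: float = 2.0
    sd_scale: float = 1.0
    overrides: dict = field(default_factory=dict)  # name -> (loc, scale, sd_scale)

    def for_param(self, name: str) -> tuple[float, float, float]:
        return self.overrides.get(name, (self.mean_loc, self.mean_scale, self.sd_scale))


@dataclass(frozen=True)
class MCMCSettings:
    chains: int = 2
    warmup: int = 1000
    draws: int = 1000

    @property
    def retained_draws(self) -> int:
        return self.chains * self.draws


#: full preset reproduces the study's sampler configuration
#: (4 chains x 5000 warm-up x 10,000 sampling = 40,000 retained draws)
PRESETS = {
    "full": MCMCSettings(4, 5000, 10000),
    "desk": MCMCSettings(2, 1000, 1000),
    "smoke": MCMCSettings(2, 150, 150),
}


class HierarchicalModel:
    """Joint posterior over group means, group SDs and child latents.

    Flat vector layout: ``[mu (K), tau (K), z (C*K)]`` with
    ``sigma = exp(tau)``; child unconstrained parameter
    ``u = mu + sigma * z`` (non-centered) or ``u`` sampled directly
    (centered, for cross-checks).
    """

    def __init__(
        self,
        model: ModelSpec,
        stacked: StackedData,
        priors: PriorSpec = PriorSpec(),
        parameterization: str = "noncentered",
    ):
        if parameterization not in ("noncentered", "centered"):
            raise ValueError("parameterization must be noncentered or centered")
        self.model = model
        self.stacked = stacked
        self.priors = priors
        self.parameterization = parameterization
        self.names = model.param_names
        self.K = len(self.names)
        self.C = stacked.n_children
        if self.C < 2:
            raise ValueError("hierarchical fit needs at least two children")
        self.dim = 2 * self.K + self.C * self.K
        self.prior_loc = np.array([priors.for_param(n)[0] for n in self.names])
        self.prior_scale = np.array([priors.for_param(n)[1] for n in self.names])
        self.prior_sd_scale = np.array([priors.for_param(n)[2] for n in self.names])
        self.constrained_mask = np.array([_is_constrained(n) for n in self.names])

    # -- vector packing ------------------------------------------------

    def unpack(self, x: np.ndarray):
        K, C = self.K, self.C
        mu = x[:K]
        tau = x[K : 2 * K]
        z = x[2 * K :].reshape(C, K)
        return mu, tau, z

    def child_unconstrained(self, x: np.ndarray) -> np.ndarray:
        mu, tau, z = self.unpack(x)
        if self.parameterization == "noncentered":
            return mu[None, :] + np.exp(tau)[None, :] * z
        return z  # centered: latents are the child parameters themselves

    def child_constrained(self, x: np.ndarray) -> np.ndarray:
        u = self.child_unconstrained(x)
        theta = u.copy()
        theta[:, self.constrained_mask] = expit(u[:, self.constrained_mask])
        return theta

    # -- joint density -------------------------------------------------

    def logp_and_grad(self, x: np.ndarray):
        mu, tau, z = self.unpack(x)
        sigma = np.exp(tau)
        u = mu[None, :] + sigma[None, :] * z if self.parameterization == "noncentered" else z
        theta = u.copy()
        cmask = self.constrained_mask
        theta[:, cmask] = expit(u[:, cmask])

        ll, _, g_theta = self.stacked.loglik(self.model, theta, want_grad=True)
        # chain rule through the logistic transform for constrained params
        g_u = g_theta
        g_u[:, cmask] = g_theta[:, cmask] * theta[:, cmask] * (1.0 - theta[:, cmask])

        lp = ll
        grad = np.empty_like(x)
        K = self.K
        if self.parameterization == "noncentered":
            # priors: mu ~ N(loc, scale); sigma ~ halfN(sd_scale) via tau; z ~ N(0,1)
            lp += float(
                -0.5 * np.sum(((mu - self.prior_loc) / self.prior_scale) ** 2)
                - 0.5 * np.sum((sigma / self.prior_sd_scale) ** 2)
                + np.sum(tau)
                - 0.5 * np.sum(z * z)
            )
            grad[:K] = g_u.sum(axis=0) - (mu - self.prior_loc) / self.prior_scale**2
            grad[K : 2 * K] = (
                sigma * (g_u * z).sum(axis=0) - sigma**2 / self.prior_sd_scale**2 + 1.0
            )
            grad[2 * K :] = (g_u * sigma[None, :] - z).ravel()
        else:
            dev = (z - mu[None, :]) / sigma[None, :]
            lp += float(
                -0.5 * np.sum(((mu - self.prior_loc) / self.prior_scale) ** 2)
                - 0.5 * np.sum((sigma / self.prior_sd_scale) ** 2)
                + np.sum(tau)
                - 0.5 * np.sum(dev * dev)
                - self.C * np.sum(tau)
            )
            grad[:K] = dev.sum(axis=0) / sigma - (mu - self.prior_loc) / self.prior_scale**2
            grad[K : 2 * K] = (
                np.sum(dev * dev, axis=0) - sigma**2 / self.prior_sd_scale**2 + 1.0 - self.C
            )
            grad[2 * K :] = (g_u - dev / sigma[None, :]).ravel()
        return lp, grad

    def initial_point(self, rng: np.random.Generator) -> np.ndarray:
        x = np.zeros(self.dim)
        x[: self.K] = self.prior_loc + 0.1 * rng.standard_normal(self.K)
        x[self.K : 2 * self.K] = -1.0 + 0.1 * rng.standard_normal(self.K)
        if self.parameterization == "centered":
            z0 = np.tile(x[: self.K], (self.C, 1))
            x[2 * self.K :] = (z0 + 0.05 * rng.standard_normal((self.C, self.K))).ravel()
        else:
            x[2 * self.K :] = 0.1 * rng.standard_normal(self.C * self.K)
        return x


@dataclass
class GroupPosterior:
    """Posterior draws for one group, with diagnostics.

    Group means are stored on the unconstrained scale in ``mu``
    (transform through a logistic map for ``alpha_decay``/``p_sec``);
    ``child`` holds constrained child-level parameters.
    """

    model_name: str
    param_names: tuple
    child_ids: list
    mu: np.ndarray  # (chains, draws, K) unconstrained group means
    sigma: np.ndarray  # (chains, draws, K) group SDs
    child: np.ndarray  # (chains, draws, C, K) constrained child params
    divergences: int
    total_transitions: int
    accept_rate: float
    settings: MCMCSettings
    seed: int | None = None

    @property
    def retained_draws(self) -> int:
        return self.mu.shape[0] * self.mu.shape[1]

    def to_inferencedata(self):
        import arviz as az

        data = {}
        for k, name in enumerate(self.param_names):
            data[f"mu_{name}"] = self.mu[:, :, k]
            data[f"sigma_{name}"] = self.sigma[:, :, k]
        data["child"] = self.child
        return az.from_dict(
            posterior=data,
            coords={"child_id": self.child_ids, "param": list(self.param_names)},
            dims={"child": ["child_id", "param"]},
        )

    def child_means(self) -> pd.DataFrame:
        """Posterior-mean child-level parameters (constrained scale)."""
        m = self.child.mean(axis=(0, 1))
        return pd.DataFrame(m, index=self.child_ids, columns=list(self.param_names))

    def group_mean_draws(self, parameter: str, constrained: bool = True) -> np.ndarray:
        k = list(self.param_names).index(parameter)
        draws = self.mu[:, :, k]
        if constrained and _is_constrained(parameter):
            draws = expit(draws)
        return draws


def fit_hierarchical(
    model: ModelSpec | str,
    dataset: pd.DataFrame,
    priors: PriorSpec = PriorSpec(),
    settings: MCMCSettings | str = "desk",
    seed: int | None = 0,
    parameterization: str = "noncentered",
    carryover_across_blocks: bool = True,
) -> GroupPosterior:
    """Fit one stopping model to one group's trial table.

    Returns draws for group means/SDs and per-child parameters.
    Non-convergence (R-hat >= 1.01 or a systematic divergence rate)
    is reported through :func:`diagnostics_report`, and a warning is
    emitted here; the draws are still returned for inspection.
    """
    if isinstance(model, str):
        model = get_model(model)
    if isinstance(settings, str):
        settings = PRESETS[settings]
    if settings.chains < 1 or settings.warmup < 1 or settings.draws < 1:
        raise ValueError("MCMC settings must be positive")
    stacked = StackedData.from_frame(dataset, carryover_across_blocks=carryover_across_blocks)
    if (np.bincount(stacked.trial_child) < 1).any():
        raise ValueError("every child needs at least one trial")
    hier = HierarchicalModel(model, stacked, priors, parameterization)

    K, C = hier.K, hier.C
    mu = np.empty((settings.chains, settings.draws, K))
    sigma = np.empty_like(mu)
    child = np.empty((settings.chains, settings.draws, C, K))
    n_div = 0
    acc = []
    ss = np.random.SeedSequence(seed)
    for ch, child_seed in enumerate(ss.spawn(settings.chains)):
        rng = np.random.default_rng(child_seed)
        res = hmc.sample_chain(
            hier.logp_and_grad,
            hier.initial_point(rng),
            settings.warmup,
            settings.draws,
            rng,
        )
        n_div += res.divergences
        acc.append(res.accept_rate)
        for d in range(settings.draws):
            x = res.draws[d]
            m, tau, _ = hier.unpack(x)
            mu[ch, d] = m
            sigma[ch, d] = np.exp(tau)
            child[ch, d] = hier.child_constrained(x)

    post = GroupPosterior(
        model.name, model.param_names, stacked.child_ids,
        mu, sigma, child, n_div,
        settings.chains * settings.draws, float(np.mean(acc)), settings, seed,
    )
    report = diagnostics_report(post)
    if not report.attrs["pass"]:
        warnings.warn(
            f"fit of {model.name}: convergence diagnostics failed "
            f"(max R-hat {report['rhat'].max():.3f}, {n_div} divergences)",
            RuntimeWarning,
            stacklevel=2,
        )
    return post


def diagnostics_report(posterior: GroupPosterior) -> pd.DataFrame:
    """Split R-hat, bulk ESS and divergence counts per parameter.

    The boolean pass flag (``.attrs['pass']``) requires every R-hat
    below 1.01 and a divergence rate under 1% of post-warmup
    transitions.
    """
    import arviz as az

    if posterior.retained_draws == 0:
        raise ValueError("empty posterior")
    rows = []
    for label_prefix, arr in (("mu", posterior.mu), ("sigma", posterior.sigma)):
        ds = az.convert_to_dataset(arr)
        rh = np.asarray(az.rhat(ds)["x"].values).ravel()
        es = np.asarray(az.ess(ds)["x"].values).ravel()
        for k, name in enumerate(posterior.param_names):
            rows.append({"parameter": f"{label_prefix}_{name}", "rhat": rh[k], "ess_bulk": es[k]})
    child_flat = posterior.child.reshape(posterior.child.shape[:2] + (-1,))
    ds = az.convert_to_dataset(child_flat)
    child_rhat = np.asarray(az.rhat(ds)["x"].values).ravel()
    child_ess = np.asarray(az.ess(ds)["x"].values).ravel()
    ci = 0
    for cid in posterior.child_ids:
        for name in posterior.param_names:
            rows.append({"parameter": f"child[{cid}].{name}", "rhat": child_rhat[ci], "ess_bulk": child_ess[ci]})
            ci += 1
    out = pd.DataFrame(rows)
    out["divergences"] = posterior.divergences
    div_rate = posterior.divergences / max(1, posterior.total_transitions)
    out.attrs["pass"] = bool((out["rhat"] < 1.01).all() and div_rate < 0.01)
    out.attrs["divergence_rate"] = div_rate
    return out


def extract_group_summary(posterior: GroupPosterior, parameter: str, which: str = "mean") -> dict:
    """Posterior median and 95% HDI of a group-level quantity.

    ``which='mean'`` summarizes the group-level mean (logistic-
    transformed for constrained parameters); ``which='sd'`` the group
    SD on the unconstrained scale.
    """
    import arviz as az

    if parameter not in posterior.param_names:
        raise ValueError(f"unknown parameter {parameter!r}")
    k = list(posterior.param_names).index(parameter)
    if which == "mean":
        draws = posterior.group_mean_draws(parameter)
    elif which == "sd":
        draws = posterior.sigma[:, :, k]
    else:
        raise ValueError("which must be 'mean' or 'sd'")
    flat = draws.reshape(-1)
    if np.allclose(flat, flat[0]):
        return {"median": float(flat[0]), "hdi_low": float(flat[0]), "hdi_high": float(flat[0])}
    lo, hi = az.hdi(flat, hdi_prob=0.95)
    return {"median": float(np.median(flat)), "hdi_low": float(lo), "hdi_high": float(hi)}


def pointwise_loglik(
    posterior: GroupPosterior,
    dataset: pd.DataFrame,
    max_draws: int = 1000,
    carryover_across_blocks: bool = True,
) -> np.ndarray:
    """(draws, trials) pointwise log-likelihood matrix for LOO.

    Posterior draws are thinned evenly to at most ``max_draws``.
    """
    model = get_model(posterior.model_name)
    stacked = StackedData.from_frame(dataset, carryover_across_blocks=carryover_across_blocks)
    if stacked.child_ids != posterior.child_ids:
        raise ValueError("dataset children do not match the posterior")
    chains, draws = posterior.child.shape[:2]
    total = chains * draws
    take = np.linspace(0, total - 1, min(max_draws, total)).astype(int)
    flat_child = posterior.child.reshape(total, stacked.n_children, len(posterior.param_names))
    out = np.empty((len(take), stacked.n_trials))
    for i, s in enumerate(take):
        _, pw, _ = stacked.loglik(model, flat_child[s], want_grad=False)
        out[i] = pw
    return out
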