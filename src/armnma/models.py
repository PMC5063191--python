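"""Likelihood, priors and random-effects densities for the six parameterizations.

All six models share the observation model: arm-level event counts are
binomial, ``r_i ~ Bin(p_i, n_i)``, with a logit link ``p_i = expit(eta_i)``.
They differ in how the linear predictor ``eta_i`` is built from trial
baselines ``mu``, basic treatment effects ``d`` (log odds ratios versus the
network reference, with ``d[1] = 0``) and, for random-effects models, latent
effects ``delta``:

``contrast_fe``
    eta = mu_j for the trial's base treatment, mu_j + (d_k - d_b) otherwise.
``contrast_re``
    As above with the fixed contrast replaced by a trial-level random
    contrast effect; within a multi-arm trial the contrast effects are
    jointly multivariate normal with variance sigma^2 and covariance
    sigma^2/2, realized here through conditional univariate normals.
``arm_fe``
    eta = mu_{s[i]} + d_{t[i]} for every arm; mu is the trial's predicted
    log odds on the *network reference* treatment.
``arm_fe_baseshift``
    eta = mu'_{s[i]} + d_{t[i]} - d_{b[i]}; mu' = mu + d_b is the trial's
    log odds on its own base treatment.
``arm_re``
    eta = mu_{s[i]} + delta_i with one independent random effect per arm,
    delta_i ~ N(d_{t[i]}, sigma^2/2).  Contrasts of two such arm effects
    reproduce the contrast-level variance sigma^2 and, within multi-arm
    trials, the covariance sigma^2/2, with no explicit multivariate normal.
``arm_re_tx``
    As ``arm_re`` with a treatment-specific scale, delta_i ~
    N(d_{t[i]}, sigma_{t[i]}^2 / 2).

Priors are deliberately vague: mu, d ~ N(0, 100^2) and each random-effect
SD uniform on (0, 5).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.special import expit, gammaln

from .data import NmaDataset

__all__ = [
    "PARAMETERIZATIONS",
    "FIXED_EFFECT_PARAMETERIZATIONS",
    "RANDOM_EFFECT_PARAMETERIZATIONS",
    "ModelSpec",
    "ParameterState",
    "inverse_logit",
    "linear_predictor",
    "log_likelihood",
    "log_binomial_coefficients",
    "deviance",
    "log_random_effects_density",
    "log_prior",
    "log_posterior",
    "contrast_re_trial_logpdf",
]

PARAMETERIZATIONS = (
    "contrast_fe",
    "contrast_re",
    "arm_fe",
    "arm_fe_baseshift",
    "arm_re",
    "arm_re_tx",
)
FIXED_EFFECT_PARAMETERIZATIONS = ("contrast_fe", "arm_fe", "arm_fe_baseshift")
RANDOM_EFFECT_PARAMETERIZATIONS = ("contrast_re", "arm_re", "arm_re_tx")


@dataclass(frozen=True)
class ModelSpec:
    """Which parameterization to fit, plus prior hyperparameters.

    Parameters
    ----------
    parameterization
        One of :data:`PARAMETERIZATIONS`.
    prior_sd_mu, prior_sd_d
        Normal prior standard deviations for trial baselines and basic
        effects (default 100, i.e. variance 10^4).
    prior_sigma_upper
        Upper bound of the uniform prior on each random-effect SD.
    """

    parameterization: str
    prior_sd_mu: float = 100.0
    prior_sd_d: float = 100.0
    prior_sigma_upper: float = 5.0

    def __post_init__(self) -> None:
        if self.parameterization not in PARAMETERIZATIONS:
            raise ValueError(
                f"unknown parameterization {self.parameterization!r}; "
                f"choose from {PARAMETERIZATIONS}"
            )
        for name in ("prior_sd_mu", "prior_sd_d", "prior_sigma_upper"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")

    @property
    def is_random_effects(self) -> bool:
        return self.parameterization in RANDOM_EFFECT_PARAMETERIZATIONS

    @property
    def is_arm_based(self) -> bool:
        return self.parameterization.startswith("arm")

    def n_sigma(self, data: NmaDataset) -> int:
        if self.parameterization == "arm_re_tx":
            return data.n_treatments
        return 1 if self.is_random_effects else 0

    def n_delta(self, data: NmaDataset) -> int:
        if self.parameterization == "contrast_re":
            return data.n_arms - data.n_trials
        if self.parameterization in ("arm_re", "arm_re_tx"):
            return data.n_arms
        return 0

    def to_dict(self) -> dict:
        return {
            "parameterization": self.parameterization,
            "prior_sd_mu": self.prior_sd_mu,
            "prior_sd_d": self.prior_sd_d,
            "prior_sigma_upper": self.prior_sigma_upper,
        }

    @classmethod
    def from_dict(cls, payload: Mapping) -> "ModelSpec":
        return cls(**dict(payload))


@dataclass
class ParameterState:
    """One point in parameter space.

    ``mu`` has one entry per trial, ``d`` one per treatment with ``d[0]``
    (the network reference) pinned to zero.  ``delta`` holds the random
    effects in canonical arm order: for arm-based random-effects models one
    value per arm; for ``contrast_re`` one value per non-base arm.  ``sigma``
    is a length-1 array (common SD) or length-K array (per-treatment SDs);
    empty for fixed-effects models.
    """

    mu: np.ndarray
    d: np.ndarray
    delta: np.ndarray = field(default_factory=lambda: np.empty(0))
    sigma: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        self.d = np.asarray(self.d, dtype=float)
        self.delta = np.asarray(self.delta, dtype=float)
        self.sigma = np.atleast_1d(np.asarray(self.sigma, dtype=float))
        if self.sigma.size == 0:
            self.sigma = np.empty(0)
        if self.d.size and self.d[0] != 0.0:
            raise ValueError("d[0] (reference treatment effect) must be 0")

    def copy(self) -> "ParameterState":
        return ParameterState(
            self.mu.copy(), self.d.copy(), self.delta.copy(), self.sigma.copy()
        )


def _check_dimensions(state: ParameterState, data: NmaDataset, spec: ModelSpec) -> None:
    if state.mu.shape != (data.n_trials,):
        raise ValueError(
            f"mu has shape {state.mu.shape}, expected ({data.n_trials},)"
        )
    if state.d.shape != (data.n_treatments,):
        raise ValueError(
            f"d has shape {state.d.shape}, expected ({data.n_treatments},)"
        )
    if state.delta.shape != (spec.n_delta(data),):
        raise ValueError(
            f"delta has shape {state.delta.shape}, expected ({spec.n_delta(data)},)"
        )
    if state.sigma.shape != (spec.n_sigma(data),):
        raise ValueError(
            f"sigma has shape {state.sigma.shape}, expected ({spec.n_sigma(data)},)"
        )


def inverse_logit(eta):
    """Numerically stable inverse logit, ``exp(eta) / (1 + exp(eta))``."""
    return expit(eta)


def nonbase_arm_positions(data: NmaDataset) -> np.ndarray:
    """Canonical positions of arms whose treatment is not the trial base."""
    return np.flatnonzero(data.treatment_index != data.arm_base_treatment)


def linear_predictor(
    state: ParameterState, data: NmaDataset, spec: ModelSpec
) -> np.ndarray:
    """Per-arm log odds ``eta_i`` under the selected parameterization."""
    _check_dimensions(state, data, spec)
    s = data.study_index
    t = data.treatment_index
    b = data.arm_base_treatment
    p = spec.parameterization
    if p == "contrast_fe":
        eta = state.mu[s].copy()
        nonbase = t != b
        eta[nonbase] += state.d[t[nonbase]] - state.d[b[nonbase]]
        return eta
    if p == "contrast_re":
        eta = state.mu[s].copy()
        eta[nonbase_arm_positions(data)] += state.delta
        return eta
    if p == "arm_fe":
        return state.mu[s] + state.d[t]
    if p == "arm_fe_baseshift":
        return state.mu[s] + state.d[t] - state.d[b]
    # arm_re / arm_re_tx
    return state.mu[s] + state.delta


def log_binomial_coefficients(data: NmaDataset) -> float:
    """Sum of ``log C(n_i, r_i)`` over arms (constant in the parameters)."""
    r = data.events
    n = data.sizes
    return float(np.sum(gammaln(n + 1) - gammaln(r + 1) - gammaln(n - r + 1)))


def _log1pexp(eta: np.ndarray) -> np.ndarray:
    # log(1 + exp(eta)) without overflow for large |eta|
    return np.where(eta > 0, eta + np.log1p(np.exp(-np.abs(eta))), np.log1p(np.exp(eta)))


def log_likelihood(state: ParameterState, data: NmaDataset, spec: ModelSpec) -> float:
    """Full binomial log likelihood, including the binomial coefficients.

    The coefficients cancel in Metropolis ratios but are kept here so that
    ``-2 * log_likelihood`` matches the conventional deviance reported
    alongside DIC.
    """
    eta = linear_predictor(state, data, spec)
    core = float(np.sum(data.events * eta - data.sizes * _log1pexp(eta)))
    return core + log_binomial_coefficients(data)


def deviance(state: ParameterState, data: NmaDataset, spec: ModelSpec) -> float:
    """Model deviance, ``-2 log L``."""
    return -2.0 * log_likelihood(state, data, spec)


def contrast_re_trial_logpdf(
    deltas: np.ndarray, means: np.ndarray, sigma: float
) -> float:
    """Joint log density of one trial's contrast random effects.

    A trial with L contrasts (ordered by ascending treatment index) has
    jointly normal contrast effects with mean vector ``means``, common
    variance ``sigma^2`` and all covariances ``sigma^2 / 2``.  The joint
    density factorizes into conditional univariate normals: the l-th effect
    given its predecessors is normal with mean
    ``means[l] + mean of preceding residuals`` / ... precisely
    ``means[l] + (1/l) * sum_{m<l} (delta_m - means_m)`` and variance
    ``sigma^2 * (l + 1) / (2 l)``.
    """
    deltas = np.asarray(deltas, dtype=float)
    means = np.asarray(means, dtype=float)
    if deltas.shape != means.shape:
        raise ValueError("deltas and means must have matching shapes")
    if sigma <= 0:
        return -math.inf
    s2 = sigma * sigma
    lp = 0.0
    resid_sum = 0.0
    for l0, (x, m) in enumerate(zip(deltas, means)):
        l = l0 + 1
        var = s2 * (l + 1) / (2.0 * l)
        diff = x - m - resid_sum / l
        lp += -0.5 * math.log(2.0 * math.pi * var) - diff * diff / (2.0 * var)
        resid_sum += x - m
    return lp


def log_random_effects_density(
    state: ParameterState, data: NmaDataset, spec: ModelSpec
) -> float:
    """Log density of the latent random effects given ``d`` and ``sigma``."""
    if not spec.is_random_effects:
        raise ValueError(
            f"{spec.parameterization!r} is a fixed-effects parameterization "
            "and has no random-effects density"
        )
    _check_dimensions(state, data, spec)
    t = data.treatment_index
    if spec.parameterization == "contrast_re":
        sigma = float(state.sigma[0])
        if sigma <= 0:
            return -math.inf
        nonbase = nonbase_arm_positions(data)
        lp = 0.0
        pos_of_arm = {int(a): idx for idx, a in enumerate(nonbase)}
        for j in range(data.n_trials):
            arms = [int(i) for i in data.trial_arms(j) if int(i) in pos_of_arm]
            if not arms:
                continue
            idx = [pos_of_arm[i] for i in arms]
            means = state.d[t[arms]] - state.d[data.trial_base_treatment[j]]
            lp += contrast_re_trial_logpdf(state.delta[idx], means, sigma)
        return lp
    # arm_re / arm_re_tx: independent N(d_t, sigma_t^2 / 2) per arm
    if spec.parameterization == "arm_re":
        sig = np.full(data.n_arms, float(state.sigma[0]))
    else:
        sig = state.sigma[t]
    if np.any(sig <= 0):
        return -math.inf
    var = sig * sig / 2.0
    resid = state.delta - state.d[t]
    return float(np.sum(-0.5 * np.log(2.0 * math.pi * var) - resid * resid / (2.0 * var)))


def log_prior(state: ParameterState, spec: ModelSpec) -> float:
    """Log prior: normal on ``mu`` and free ``d``; uniform on each sigma."""
    lp = 0.0
    sd_mu = spec.prior_sd_mu
    lp += float(
        np.sum(-0.5 * math.log(2.0 * math.pi * sd_mu * sd_mu) - state.mu**2 / (2.0 * sd_mu * sd_mu))
    )
    free_d = state.d[1:]
    sd_d = spec.prior_sd_d
    lp += float(
        np.sum(-0.5 * math.log(2.0 * math.pi * sd_d * sd_d) - free_d**2 / (2.0 * sd_d * sd_d))
    )
    for sig in np.atleast_1d(state.sigma):
        if not 0.0 < sig < spec.prior_sigma_upper:
            return -math.inf
        lp += -math.log(spec.prior_sigma_upper)
    return lp


def log_posterior(state: ParameterState, data: NmaDataset, spec: ModelSpec) -> float:
    """Unnormalized log posterior; ``-inf`` for out-of-support states."""
    lp = log_prior(state, spec)
    if lp == -math.inf:
        return -math.inf
    if spec.is_random_effects:
        lre = log_random_effects_density(state, data, spec)
        if lre == -math.inf:
            return -math.inf
        lp += lre
    return lp + log_likelihood(state, data, spec)
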