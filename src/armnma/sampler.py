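"""Bespoke adaptive Metropolis-within-Gibbs sampler for the NMA models.

Each iteration ("sweep") updates every scalar parameter in turn with a
Gaussian random-walk Metropolis step: each trial baseline ``mu_j``, each free
basic effect ``d_k`` (k >= 2), each random effect ``delta``, and each
random-effect SD ``sigma`` (proposed on the log scale with the Jacobian
correction; proposals outside the uniform prior's support are rejected).
Step sizes are adapted toward a target acceptance rate by Robbins-Monro
scaling during burn-in only, so retained draws target the exact posterior.

In addition to the scalar updates, each sweep includes "group shift" moves —
Metropolis proposals along fixed linear combinations of parameters that the
posterior correlates strongly:

* ``d_k`` shifted jointly with the random effects (or baselines) tied to
  treatment ``k``, leaving the random-effects density (or the treatment-k
  arms' likelihood) unchanged;
* ``mu_j`` shifted jointly with trial ``j``'s random effects, leaving the
  likelihood (or all but the base arm's likelihood) unchanged.

These are ordinary scalar Metropolis updates of a reparameterized coordinate
and leave the invariant distribution untouched; they exist purely to cut
autocorrelation along the ``mu``-``d``-``delta`` ridge.

Reproducibility: one independent PCG64 stream per chain is spawned from the
master seed, so the same ``SamplerSettings`` always yield bit-identical
draws, and adding chains never reshuffles the draws of existing ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import models
from .data import NmaDataset
from .models import ModelSpec, ParameterState

__all__ = [
    "SamplerSettings",
    "PosteriorDraws",
    "run_mcmc",
    "default_initial_values",
    "n_free_parameters",
]

# Move kinds (internal)
(
    _MU,
    _D_LIK,
    _D_ARMRE,
    _D_CTRRE,
    _DELTA_ARM,
    _DELTA_CTR,
    _SIG_ARM,
    _SIG_CTR,
    _SIG_TX,
    _SHD_ARM,
    _SHD_CTR,
    _SHD_FE,
    _SHMU_ARM,
    _SHMU_CTR,
    _GLOBAL_ARM,
    _REROUTE_ARM,
) = range(16)

_REFRESH_EVERY = 500  # full cache rebuild cadence (guards float drift)


@dataclass
class SamplerSettings:
    """MCMC run configuration.

    Defaults mirror a conventional three-chain WinBUGS-style run: 20 000
    burn-in sweeps followed by 20 000 retained sweeps per chain, no thinning.
    """

    n_chains: int = 3
    n_burnin: int = 20_000
    n_sample: int = 20_000
    seed: int = 0
    adapt_interval: int = 50
    target_acceptance: float = 0.44
    mix_repeats: int = 8
    initial_values: Sequence[ParameterState] | None = None

    def __post_init__(self) -> None:
        if self.mix_repeats < 1:
            raise ValueError("mix_repeats must be >= 1")
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")
        if self.n_burnin < 0:
            raise ValueError("n_burnin must be >= 0")
        if self.n_sample < 1:
            raise ValueError("n_sample must be >= 1")
        if self.adapt_interval < 1:
            raise ValueError("adapt_interval must be >= 1")
        if not 0.0 < self.target_acceptance < 1.0:
            raise ValueError("target_acceptance must lie in (0, 1)")

    def to_dict(self) -> dict:
        return {
            "n_chains": self.n_chains,
            "n_burnin": self.n_burnin,
            "n_sample": self.n_sample,
            "seed": self.seed,
            "adapt_interval": self.adapt_interval,
            "target_acceptance": self.target_acceptance,
            "mix_repeats": self.mix_repeats,
        }


def n_free_parameters(data: NmaDataset, spec: ModelSpec) -> int:
    """Number of sampled scalars: J baselines + (K-1) effects + deltas + sigmas."""
    return (
        data.n_trials
        + (data.n_treatments - 1)
        + spec.n_delta(data)
        + spec.n_sigma(data)
    )


def default_initial_values(
    spec: ModelSpec, data: NmaDataset, n_chains: int
) -> list[ParameterState]:
    """Dispersed deterministic starting states.

    Chain 1 starts at zero (``sigma`` at the midpoint of its support); later
    chains offset ``mu`` and the free ``d`` by +1/-1 (then +2/-2, ...) and
    place ``sigma`` near the edges of its support.  Random effects start at
    their conditional means so every state has a finite log posterior.
    """
    if n_chains < 1:
        raise ValueError("n_chains must be >= 1")
    upper = spec.prior_sigma_upper
    offsets = [0.0, 1.0, -1.0, 2.0, -2.0, 0.5, -0.5]
    sigma_fracs = [0.5, 0.1, 0.8, 0.3, 0.6, 0.2, 0.7]
    states = []
    for c in range(n_chains):
        off = offsets[c % len(offsets)]
        mu = np.full(data.n_trials, off)
        d = np.full(data.n_treatments, off)
        d[0] = 0.0
        sig_val = upper * sigma_fracs[c % len(sigma_fracs)]
        sigma = np.full(spec.n_sigma(data), sig_val)
        if spec.parameterization in ("arm_re", "arm_re_tx"):
            delta = d[data.treatment_index]
        elif spec.parameterization == "contrast_re":
            nonbase = models.nonbase_arm_positions(data)
            delta = (
                d[data.treatment_index[nonbase]]
                - d[data.arm_base_treatment[nonbase]]
            )
        else:
            delta = np.empty(0)
        states.append(ParameterState(mu=mu, d=d, delta=delta, sigma=sigma))
    return states


class PosteriorDraws:
    """Retained posterior draws from all chains, plus per-draw deviance.

    ``draws`` has shape ``(n_chains, n_sample, n_parameters)`` in the order
    of ``param_names``.  ``p_mean`` holds the posterior mean of each arm's
    event probability (the plug-in point for the DIC's Dhat).
    """

    def __init__(
        self,
        param_names: tuple[str, ...],
        draws: np.ndarray,
        deviance_draws: np.ndarray,
        p_mean: np.ndarray,
        data: NmaDataset,
        spec: ModelSpec,
        settings: SamplerSettings,
        acceptance_rates: dict[str, float],
        final_states: list[ParameterState],
        final_log_posteriors: list[float],
    ):
        self.param_names = param_names
        self.draws = draws
        self.deviance_draws = deviance_draws
        self.p_mean = p_mean
        self.data = data
        self.spec = spec
        self.settings = settings
        self.acceptance_rates = acceptance_rates
        self.final_states = final_states
        self.final_log_posteriors = final_log_posteriors
        self._index = {name: i for i, name in enumerate(param_names)}

    @property
    def n_chains(self) -> int:
        return self.draws.shape[0]

    @property
    def n_sample(self) -> int:
        return self.draws.shape[1]

    def extract(self, name: str) -> np.ndarray:
        """Draws of one parameter, shape ``(n_chains, n_sample)``."""
        if name == "deviance":
            return self.deviance_draws
        if name not in self._index:
            raise KeyError(f"unknown parameter {name!r}")
        return self.draws[:, :, self._index[name]]

    def to_frame(self) -> pd.DataFrame:
        """Long-format draws: chain, iteration, parameter, value."""
        chains, iters, params = [], [], []
        frames = []
        for c in range(self.n_chains):
            frame = pd.DataFrame(self.draws[c], columns=list(self.param_names))
            frame["deviance"] = self.deviance_draws[c]
            frame.insert(0, "iteration", np.arange(1, self.n_sample + 1))
            frame.insert(0, "chain", c + 1)
            frames.append(frame)
        wide = pd.concat(frames, ignore_index=True)
        return wide.melt(
            id_vars=["chain", "iteration"], var_name="parameter", value_name="value"
        )

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def _l1pe(x: float) -> float:
    """Scalar log(1 + exp(x)) without overflow."""
    if x > 0.0:
        return x + math.log1p(math.exp(-x))
    return math.log1p(math.exp(x))


class _Engine:
    """Precomputed index structures and the per-chain sweep loop."""

    def __init__(self, data: NmaDataset, spec: ModelSpec):
        self.data = data
        self.spec = spec
        p = spec.parameterization
        J, K, I = data.n_trials, data.n_treatments, data.n_arms

        self.r = [int(x) for x in data.events]
        self.n = [int(x) for x in data.sizes]
        self.s_of = [int(x) for x in data.study_index]
        self.t_of = [int(x) for x in data.treatment_index]
        self.base_of_trial = [int(x) for x in data.trial_base_treatment]
        self.base_of = [self.base_of_trial[j] for j in self.s_of]
        self.trial_arms = [
            [int(i) for i in data.trial_arms(j)] for j in range(J)
        ]
        # canonical order sorts arms within trial by treatment index, so the
        # first arm of each trial is the base arm
        self.base_arm_of_trial = [arms[0] for arms in self.trial_arms]
        self.nonbase_of_trial = [arms[1:] for arms in self.trial_arms]

        self.n_delta = spec.n_delta(data)
        self.n_sigma = spec.n_sigma(data)
        self.delta_pos = [-1] * I
        if p in ("arm_re", "arm_re_tx"):
            for i in range(I):
                self.delta_pos[i] = i
            self.delta_arm = list(range(I))
        elif p == "contrast_re":
            self.delta_arm = []
            for j in range(J):
                for i in self.nonbase_of_trial[j]:
                    self.delta_pos[i] = len(self.delta_arm)
                    self.delta_arm.append(i)
        else:
            self.delta_arm = []
        # sigma index per arm (arm-based RE models)
        if p == "arm_re_tx":
            self.sig_index_of_arm = list(self.t_of)
        else:
            self.sig_index_of_arm = [0] * I

        self.arms_with_t = [
            [i for i in range(I) if self.t_of[i] == k] for k in range(K)
        ]

        labels = data.coding.labels
        studies = data.studies
        names: list[str] = [f"mu[{s}]" for s in studies]
        names += [f"d[{labels[k]}]" for k in range(1, K)]
        for i in self.delta_arm:
            names.append(f"delta[{studies[self.s_of[i]]}:{labels[self.t_of[i]]}]")
        if self.n_sigma == 1:
            names.append("sigma")
        elif self.n_sigma == K:
            names += [f"sigma[{labels[k]}]" for k in range(K)]
        self.param_names = tuple(names)
        self.n_params = len(names)

        self._build_moves()

    # ------------------------------------------------------------ move table
    def _build_moves(self) -> None:
        p = self.spec.parameterization
        J = self.data.n_trials
        K = self.data.n_treatments
        labels = self.data.coding.labels
        studies = self.data.studies
        kinds: list[int] = []
        payloads: list[tuple] = []
        names: list[str] = []
        scalar: list[bool] = []
        init_step: list[float] = []
        repeatable: list[bool] = []

        def add(kind, payload, name, is_scalar, step=0.5, repeat=False):
            kinds.append(kind)
            payloads.append(payload)
            names.append(name)
            scalar.append(is_scalar)
            init_step.append(step)
            repeatable.append(repeat)

        for j in range(J):
            add(_MU, (j, tuple(self.trial_arms[j])), f"mu[{studies[j]}]", True)

        for k in range(1, K):
            name = f"d[{labels[k]}]"
            if p in models.FIXED_EFFECT_PARAMETERIZATIONS:
                add(_D_LIK, (k, self._d_arm_coefs(k)), name, True)
            elif p in ("arm_re", "arm_re_tx"):
                add(_D_ARMRE, (k, tuple(self.arms_with_t[k])), name, True, repeat=True)
            else:
                trials = tuple(
                    j
                    for j in range(J)
                    if self.nonbase_of_trial[j]
                    and (
                        self.base_of_trial[j] == k
                        or any(self.t_of[i] == k for i in self.nonbase_of_trial[j])
                    )
                )
                add(_D_CTRRE, (k, trials), name, True, repeat=True)

        for pos, i in enumerate(self.delta_arm):
            name = f"delta[{studies[self.s_of[i]]}:{labels[self.t_of[i]]}]"
            if p in ("arm_re", "arm_re_tx"):
                add(_DELTA_ARM, (i, pos), name, True)
            else:
                add(_DELTA_CTR, (i, pos, self.s_of[i]), name, True)

        if p == "arm_re":
            add(_SIG_ARM, (), "sigma", True, repeat=True)
        elif p == "contrast_re":
            add(_SIG_CTR, (), "sigma", True, repeat=True)
        elif p == "arm_re_tx":
            for k in range(K):
                add(
                    _SIG_TX,
                    (k, tuple(self.arms_with_t[k])),
                    f"sigma[{labels[k]}]",
                    True,
                    repeat=True,
                )

        # group-shift moves (mixing only; invariant distribution unchanged)
        if p in ("arm_re", "arm_re_tx"):
            for k in range(1, K):
                add(
                    _SHD_ARM,
                    (k, tuple(self.arms_with_t[k])),
                    f"shift_d[{labels[k]}]",
                    False,
                    0.25,
                    repeat=True,
                )
            for j in range(J):
                add(
                    _SHMU_ARM,
                    (j, tuple(self.trial_arms[j])),
                    f"shift_mu[{studies[j]}]",
                    False,
                    0.25,
                    repeat=True,
                )
            # likelihood-invariant translation of the overall level:
            # all mu up, all delta down, all free d down; only the
            # reference-treatment arms' random-effect terms gate it
            add(
                _GLOBAL_ARM,
                (tuple(self.arms_with_t[0]),),
                "shift_level",
                False,
                0.25,
                repeat=True,
            )
            # likelihood-invariant reroute of d_k against the co-arms of the
            # trials containing treatment k: moves d_k relative to the rest
            # of the network, gated only by the co-arms' RE terms
            for k in range(1, K):
                trials_k = tuple(
                    j
                    for j in range(J)
                    if any(self.t_of[i] == k for i in self.trial_arms[j])
                )
                co_arms = tuple(
                    i
                    for j in trials_k
                    for i in self.trial_arms[j]
                    if self.t_of[i] != k
                )
                add(
                    _REROUTE_ARM,
                    (k, tuple(self.arms_with_t[k]), trials_k, co_arms),
                    f"reroute_d[{labels[k]}]",
                    False,
                    0.25,
                    repeat=True,
                )
        elif p == "contrast_re":
            for k in range(1, K):
                coefs = []
                for j in range(self.data.n_trials):
                    for i in self.nonbase_of_trial[j]:
                        if self.t_of[i] == k:
                            coefs.append((i, 1.0))
                        elif self.base_of_trial[j] == k:
                            coefs.append((i, -1.0))
                add(
                    _SHD_CTR,
                    (k, tuple(coefs)),
                    f"shift_d[{labels[k]}]",
                    False,
                    0.25,
                    repeat=True,
                )
            for j in range(J):
                add(
                    _SHMU_CTR,
                    (j, self.base_arm_of_trial[j], tuple(self.nonbase_of_trial[j])),
                    f"shift_mu[{studies[j]}]",
                    False,
                    0.25,
                    repeat=True,
                )
        else:
            # FE: shift d_k together with the baselines of trials containing
            # treatment k, keeping the treatment-k arms' linear predictor fixed
            for k in range(1, K):
                arm_coefs, mu_coefs = self._fe_shift_structure(k)
                if mu_coefs:
                    add(
                        _SHD_FE,
                        (k, arm_coefs, mu_coefs),
                        f"shift_d[{labels[k]}]",
                        False,
                        0.25,
                    )

        self.move_kinds = kinds
        self.move_payloads = payloads
        self.move_names = names
        self.move_scalar = scalar
        self.move_init_step = init_step
        self.move_repeatable = repeatable
        self.n_moves = len(kinds)

    def _d_coef(self, i: int, k: int) -> float:
        """Coefficient of d_k in arm i's linear predictor (FE models)."""
        p = self.spec.parameterization
        c = 0.0
        if p == "arm_fe":
            if self.t_of[i] == k:
                c = 1.0
        elif p == "arm_fe_baseshift":
            if self.t_of[i] == k:
                c += 1.0
            if self.base_of[i] == k:
                c -= 1.0
        else:  # contrast_fe
            if self.t_of[i] != self.base_of[i]:
                if self.t_of[i] == k:
                    c += 1.0
                if self.base_of[i] == k:
                    c -= 1.0
        return c

    def _d_arm_coefs(self, k: int) -> tuple:
        return tuple(
            (i, self._d_coef(i, k))
            for i in range(self.data.n_arms)
            if self._d_coef(i, k) != 0.0
        )

    def _fe_shift_structure(self, k: int) -> tuple[tuple, tuple]:
        """Net arm coefficients for the FE d_k/mu group-shift move."""
        mu_coefs = []
        c_of_trial = {}
        for j in range(self.data.n_trials):
            treats = {self.t_of[i] for i in self.trial_arms[j]}
            if k not in treats:
                continue
            p = self.spec.parameterization
            if p == "arm_fe":
                c = -1.0
            elif p == "arm_fe_baseshift":
                c = 0.0 if self.base_of_trial[j] == k else -1.0
            else:  # contrast_fe
                c = 1.0 if self.base_of_trial[j] == k else -1.0
            if c != 0.0:
                mu_coefs.append((j, c))
                c_of_trial[j] = c
        arm_coefs = []
        for i in range(self.data.n_arms):
            c = self._d_coef(i, k) + c_of_trial.get(self.s_of[i], 0.0)
            if c != 0.0:
                arm_coefs.append((i, c))
        return tuple(arm_coefs), tuple(mu_coefs)

    # --------------------------------------------------------- state helpers
    def state_to_lists(self, state: ParameterState):
        models._check_dimensions(state, self.data, self.spec)
        mu = [float(x) for x in state.mu]
        d = [float(x) for x in state.d]
        delta = [float(x) for x in state.delta]
        sigma = [float(x) for x in state.sigma]
        return mu, d, delta, sigma

    def lists_to_state(self, mu, d, delta, sigma) -> ParameterState:
        return ParameterState(
            mu=np.array(mu), d=np.array(d), delta=np.array(delta), sigma=np.array(sigma)
        )

    # ------------------------------------------------------------ cache math
    def _arm_eta(self, i: int, mu, d, delta) -> float:
        p = self.spec.parameterization
        eta = mu[self.s_of[i]]
        if p == "contrast_fe":
            if self.t_of[i] != self.base_of[i]:
                eta += d[self.t_of[i]] - d[self.base_of[i]]
        elif p == "contrast_re":
            if self.delta_pos[i] >= 0:
                eta += delta[self.delta_pos[i]]
        elif p == "arm_fe":
            eta += d[self.t_of[i]]
        elif p == "arm_fe_baseshift":
            eta += d[self.t_of[i]] - d[self.base_of[i]]
        else:
            eta += delta[self.delta_pos[i]]
        return eta

    def _re_arm_term(self, i: int, d, delta, sigma) -> float:
        sig = sigma[self.sig_index_of_arm[i]]
        resid = delta[self.delta_pos[i]] - d[self.t_of[i]]
        # variance sigma^2/2: logpdf = -0.5*log(pi*sigma^2) - resid^2/sigma^2
        return -0.5 * math.log(math.pi * sig * sig) - resid * resid / (sig * sig)

    def _re_trial_term(self, j: int, d, delta, sigma0: float) -> float:
        lp = 0.0
        rsum = 0.0
        s2 = sigma0 * sigma0
        base = self.base_of_trial[j]
        for l0, i in enumerate(self.nonbase_of_trial[j]):
            x = delta[self.delta_pos[i]]
            m = d[self.t_of[i]] - d[base]
            l = l0 + 1
            var = s2 * (l + 1) / (2.0 * l)
            diff = x - m - rsum / l
            lp += -0.5 * math.log(2.0 * math.pi * var) - diff * diff / (2.0 * var)
            rsum += x - m
        return lp

    # ---------------------------------------------------------------- runner
    def run_chain(
        self,
        init: ParameterState,
        rng: np.random.Generator,
        settings: SamplerSettings,
    ):
        spec = self.spec
        p = spec.parameterization
        is_re = spec.is_random_effects
        arm_re_like = p in ("arm_re", "arm_re_tx")
        r, n = self.r, self.n
        s_of, t_of = self.s_of, self.t_of
        I = self.data.n_arms
        J = self.data.n_trials
        delta_pos = self.delta_pos

        mu, d, delta, sigma = self.state_to_lists(init)
        logsig = [math.log(x) for x in sigma]
        sig_upper = spec.prior_sigma_upper
        inv2v_mu = 1.0 / (2.0 * spec.prior_sd_mu**2)
        inv2v_d = 1.0 / (2.0 * spec.prior_sd_d**2)

        eta = [0.0] * I
        ll = [0.0] * I
        re_arm = [0.0] * I
        re_trial = [0.0] * J

        def refresh():
            for i in range(I):
                e = self._arm_eta(i, mu, d, delta)
                eta[i] = e
                ll[i] = r[i] * e - n[i] * _l1pe(e)
            if arm_re_like:
                for i in range(I):
                    re_arm[i] = self._re_arm_term(i, d, delta, sigma)
            elif p == "contrast_re":
                for j in range(J):
                    re_trial[j] = self._re_trial_term(j, d, delta, sigma[0])

        refresh()

        kinds = self.move_kinds
        payloads = self.move_payloads
        M = self.n_moves
        # sweep schedule: every move once, then extra passes over the cheap
        # reparameterized moves (d, sigma, shifts) that dominate mixing
        schedule = list(range(M))
        if settings.mix_repeats > 1:
            extra = [m for m in range(M) if self.move_repeatable[m]]
            for _ in range(settings.mix_repeats - 1):
                schedule.extend(extra)
        T = len(schedule)
        sched_count = [0] * M
        for m in schedule:
            sched_count[m] += 1
        steps = list(self.move_init_step)
        log_steps = [math.log(s) for s in steps]
        acc_batch = [0] * M
        acc_post = [0] * M
        target = settings.target_acceptance
        adapt_interval = settings.adapt_interval
        n_burnin = settings.n_burnin
        n_total = n_burnin + settings.n_sample
        batch_no = 0

        draws = np.empty((settings.n_sample, self.n_params))
        dev_draws = np.empty(settings.n_sample)
        p_sum = [0.0] * I
        log_coeff = models.log_binomial_coefficients(self.data)

        for sweep in range(n_total):
            if sweep % _REFRESH_EVERY == 0:
                refresh()
            zs = rng.standard_normal(T)
            us = rng.random(T)
            for pos_t in range(T):
                m = schedule[pos_t]
                kind = kinds[m]
                eps = steps[m] * zs[pos_t]
                u = us[pos_t]
                pay = payloads[m]
                accept = False

                if kind == _MU:
                    j, arms = pay
                    old = mu[j]
                    new = old + eps
                    dlp = inv2v_mu * (old * old - new * new)
                    new_etas = []
                    new_lls = []
                    for i in arms:
                        e = eta[i] + eps
                        nl = r[i] * e - n[i] * _l1pe(e)
                        new_etas.append(e)
                        new_lls.append(nl)
                        dlp += nl - ll[i]
                    if dlp >= 0.0 or u < math.exp(dlp):
                        mu[j] = new
                        for idx, i in enumerate(arms):
                            eta[i] = new_etas[idx]
                            ll[i] = new_lls[idx]
                        accept = True

                elif kind == _D_LIK:
                    k, arm_coefs = pay
                    old = d[k]
                    new = old + eps
                    dlp = inv2v_d * (old * old - new * new)
                    new_etas = []
                    new_lls = []
                    for i, c in arm_coefs:
                        e = eta[i] + c * eps
                        nl = r[i] * e - n[i] * _l1pe(e)
                        new_etas.append(e)
                        new_lls.append(nl)
                        dlp += nl - ll[i]
                    if dlp >= 0.0 or u < math.exp(dlp):
                        d[k] = new
                        for idx, (i, _) in enumerate(arm_coefs):
                            eta[i] = new_etas[idx]
                            ll[i] = new_lls[idx]
                        accept = True

                elif kind == _D_ARMRE:
                    k, arms = pay
                    old = d[k]
                    new = old + eps
                    dlp = inv2v_d * (old * old - new * new)
                    new_terms = []
                    for i in arms:
                        sig = sigma[self.sig_index_of_arm[i]]
                        resid = delta[delta_pos[i]] - new
                        term = (
                            -0.5 * math.log(math.pi * sig * sig)
                            - resid * resid / (sig * sig)
                        )
                        new_terms.append(term)
                        dlp += term - re_arm[i]
                    if dlp >= 0.0 or u < math.exp(dlp):
                        d[k] = new
                        for idx, i in enumerate(arms):
                            re_arm[i] = new_terms[idx]
                        accept = True

                elif kind == _D_CTRRE:
                    k, trials = pay
                    old = d[k]
                    new = old + eps
                    dlp = inv2v_d * (old * old - new * new)
                    d[k] = new
                    new_terms = []
                    for j in trials:
                        term = self._re_trial_term(j, d, delta, sigma[0])
                        new_terms.append(term)
                        dlp += term - re_trial[j]
                    if dlp >= 0.0 or u < math.exp(dlp):
                        for idx, j in enumerate(trials):
                            re_trial[j] = new_terms[idx]
                        accept = True
                    else:
                        d[k] = old

                elif kind == _DELTA_ARM:
                    i, pos = pay
                    old = delta[pos]
                    new = old + eps
                    e = eta[i] + eps
                    nl = r[i] * e - n[i] * _l1pe(e)
                    sig = sigma[self.sig_index_of_arm[i]]
                    resid = new - d[t_of[i]]
                    term = (
                        -0.5 * math.log(math.pi * sig * sig)
                        - resid * resid / (sig * sig)
                    )
                    dlp = nl - ll[i] + term - re_arm[i]
                    if dlp >= 0.0 or u < math.exp(dlp):
                        delta[pos] = new
                        eta[i] = e
                        ll[i] = nl
                        re_arm[i] = term
                        accept = True

                elif kind == _DELTA_CTR:
                    i, pos, j = pay
                    old = delta[pos]
                    new = old + eps
                    e = eta[i] + eps
                    nl = r[i] * e - n[i] * _l1pe(e)
                    delta[pos] = new
                    term = self._re_trial_term(j, d, delta, sigma[0])
                    dlp = nl - ll[i] + term - re_trial[j]
                    if dlp >= 0.0 or u < math.exp(dlp):
                        eta[i] = e
                        ll[i] = nl
                        re_trial[j] = term
                        accept = True
                    else:
                        delta[pos] = old

                elif kind == _SIG_ARM or kind == _SIG_CTR:
                    old_ls = logsig[0]
                    new_ls = old_ls + eps
                    new_sig = math.exp(new_ls)
                    if new_sig < sig_upper:
                        dlp = new_ls - old_ls  # Jacobian of the log transform
                        if kind == _SIG_ARM:
                            new_terms = []
                            for i in range(I):
                                resid = delta[delta_pos[i]] - d[t_of[i]]
                                term = (
                                    -0.5 * math.log(math.pi * new_sig * new_sig)
                                    - resid * resid / (new_sig * new_sig)
                                )
                                new_terms.append(term)
                                dlp += term - re_arm[i]
                        else:
                            new_terms = []
                            for j in range(J):
                                term = self._re_trial_term(j, d, delta, new_sig)
                                new_terms.append(term)
                                dlp += term - re_trial[j]
                        if dlp >= 0.0 or u < math.exp(dlp):
                            logsig[0] = new_ls
                            sigma[0] = new_sig
                            if kind == _SIG_ARM:
                                for i in range(I):
                                    re_arm[i] = new_terms[i]
                            else:
                                for j in range(J):
                                    re_trial[j] = new_terms[j]
                            accept = True

                elif kind == _SIG_TX:
                    k, arms = pay
                    old_ls = logsig[k]
                    new_ls = old_ls + eps
                    new_sig = math.exp(new_ls)
                    if new_sig < sig_upper:
                        dlp = new_ls - old_ls
                        new_terms = []
                        for i in arms:
                            resid = delta[delta_pos[i]] - d[t_of[i]]
                            term = (
                                -0.5 * math.log(math.pi * new_sig * new_sig)
                                - resid * resid / (new_sig * new_sig)
                            )
                            new_terms.append(term)
                            dlp += term - re_arm[i]
                        if dlp >= 0.0 or u < math.exp(dlp):
                            logsig[k] = new_ls
                            sigma[k] = new_sig
                            for idx, i in enumerate(arms):
                                re_arm[i] = new_terms[idx]
                            accept = True

                elif kind == _SHD_ARM:
                    # d_k and its arm effects move together: RE density fixed
                    k, arms = pay
                    old = d[k]
                    new = old + eps
                    dlp = inv2v_d * (old * old - new * new)
                    new_etas = []
                    new_lls = []
                    for i in arms:
                        e = eta[i] + eps
                        nl = r[i] * e - n[i] * _l1pe(e)
                        new_etas.append(e)
                        new_lls.append(nl)
                        dlp += nl - ll[i]
                    if dlp >= 0.0 or u < math.exp(dlp):
                        d[k] = new
                        for idx, i in enumerate(arms):
                            delta[delta_pos[i]] += eps
                            eta[i] = new_etas[idx]
                            ll[i] = new_lls[idx]
                        accept = True

                elif kind == _SHD_CTR:
                    k, coefs = pay
                    old = d[k]
                    new = old + eps
                    dlp = inv2v_d * (old * old - new * new)
                    new_etas = []
                    new_lls = []
                    for i, c in coefs:
                        e = eta[i] + c * eps
                        nl = r[i] * e - n[i] * _l1pe(e)
                        new_etas.append(e)
                        new_lls.append(nl)
                        dlp += nl - ll[i]
                    if dlp >= 0.0 or u < math.exp(dlp):
                        d[k] = new
                        for idx, (i, c) in enumerate(coefs):
                            delta[delta_pos[i]] += c * eps
                            eta[i] = new_etas[idx]
                            ll[i] = new_lls[idx]
                        accept = True

                elif kind == _SHD_FE:
                    k, arm_coefs, mu_coefs = pay
                    old = d[k]
                    new = old + eps
                    dlp = inv2v_d * (old * old - new * new)
                    for j, c in mu_coefs:
                        om = mu[j]
                        nm = om + c * eps
                        dlp += inv2v_mu * (om * om - nm * nm)
                    new_etas = []
                    new_lls = []
                    for i, c in arm_coefs:
                        e = eta[i] + c * eps
                        nl = r[i] * e - n[i] * _l1pe(e)
                        new_etas.append(e)
                        new_lls.append(nl)
                        dlp += nl - ll[i]
                    if dlp >= 0.0 or u < math.exp(dlp):
                        d[k] = new
                        for j, c in mu_coefs:
                            mu[j] += c * eps
                        for idx, (i, _) in enumerate(arm_coefs):
                            eta[i] = new_etas[idx]
                            ll[i] = new_lls[idx]
                        accept = True

                elif kind == _SHMU_ARM:
                    # mu_j up, its arm effects down: likelihood fixed
                    j, arms = pay
                    old = mu[j]
                    new = old + eps
                    dlp = inv2v_mu * (old * old - new * new)
                    new_terms = []
                    for i in arms:
                        sig = sigma[self.sig_index_of_arm[i]]
                        resid = delta[delta_pos[i]] - eps - d[t_of[i]]
                        term = (
                            -0.5 * math.log(math.pi * sig * sig)
                            - resid * resid / (sig * sig)
                        )
                        new_terms.append(term)
                        dlp += term - re_arm[i]
                    if dlp >= 0.0 or u < math.exp(dlp):
                        mu[j] = new
                        for idx, i in enumerate(arms):
                            delta[delta_pos[i]] -= eps
                            re_arm[i] = new_terms[idx]
                        accept = True

                elif kind == _GLOBAL_ARM:
                    # translate the overall level: eta (hence the likelihood)
                    # is invariant; only reference-arm RE terms and the vague
                    # priors gate the move
                    ref_arms = pay[0]
                    dlp = 0.0
                    for j in range(J):
                        om = mu[j]
                        nm = om + eps
                        dlp += inv2v_mu * (om * om - nm * nm)
                    for k in range(1, len(d)):
                        od = d[k]
                        nd = od - eps
                        dlp += inv2v_d * (od * od - nd * nd)
                    new_terms = []
                    for i in ref_arms:
                        sig = sigma[self.sig_index_of_arm[i]]
                        resid = delta[delta_pos[i]] - eps  # d[reference] == 0
                        term = (
                            -0.5 * math.log(math.pi * sig * sig)
                            - resid * resid / (sig * sig)
                        )
                        new_terms.append(term)
                        dlp += term - re_arm[i]
                    if dlp >= 0.0 or u < math.exp(dlp):
                        for j in range(J):
                            mu[j] += eps
                        for k in range(1, len(d)):
                            d[k] -= eps
                        for pos in range(len(delta)):
                            delta[pos] -= eps
                        for idx, i in enumerate(ref_arms):
                            re_arm[i] = new_terms[idx]
                        accept = True

                elif kind == _REROUTE_ARM:
                    # d_k, its arm effects and the containing trials' levels
                    # move together; eta is invariant, only the co-arms'
                    # RE terms and the vague priors gate the move
                    k, t_arms, trials_k, co_arms = pay
                    old = d[k]
                    new = old + eps
                    dlp = inv2v_d * (old * old - new * new)
                    for j in trials_k:
                        om = mu[j]
                        nm = om - eps
                        dlp += inv2v_mu * (om * om - nm * nm)
                    new_terms = []
                    for i in co_arms:
                        sig = sigma[self.sig_index_of_arm[i]]
                        resid = delta[delta_pos[i]] + eps - d[t_of[i]]
                        term = (
                            -0.5 * math.log(math.pi * sig * sig)
                            - resid * resid / (sig * sig)
                        )
                        new_terms.append(term)
                        dlp += term - re_arm[i]
                    if dlp >= 0.0 or u < math.exp(dlp):
                        d[k] = new
                        for i in t_arms:
                            delta[delta_pos[i]] += eps
                        for j in trials_k:
                            mu[j] -= eps
                        for idx, i in enumerate(co_arms):
                            delta[delta_pos[i]] += eps
                            re_arm[i] = new_terms[idx]
                        accept = True

                else:  # _SHMU_CTR
                    j, base_arm, nonbase = pay
                    old = mu[j]
                    new = old + eps
                    dlp = inv2v_mu * (old * old - new * new)
                    e = eta[base_arm] + eps
                    nl = r[base_arm] * e - n[base_arm] * _l1pe(e)
                    dlp += nl - ll[base_arm]
                    for i in nonbase:
                        delta[delta_pos[i]] -= eps
                    term = self._re_trial_term(j, d, delta, sigma[0])
                    dlp += term - re_trial[j]
                    if dlp >= 0.0 or u < math.exp(dlp):
                        mu[j] = new
                        eta[base_arm] = e
                        ll[base_arm] = nl
                        re_trial[j] = term
                        accept = True
                    else:
                        for i in nonbase:
                            delta[delta_pos[i]] += eps

                if accept:
                    acc_batch[m] += 1
                    if sweep >= n_burnin:
                        acc_post[m] += 1

            # Robbins-Monro step-size adaptation, burn-in only
            if sweep < n_burnin and (sweep + 1) % adapt_interval == 0:
                batch_no += 1
                gamma = min(0.5, 3.0 / math.sqrt(batch_no))
                for m in range(M):
                    rate = acc_batch[m] / (adapt_interval * sched_count[m])
                    log_steps[m] += gamma * (rate - target)
                    steps[m] = math.exp(log_steps[m])
                    acc_batch[m] = 0
            elif (sweep + 1) % adapt_interval == 0:
                for m in range(M):
                    acc_batch[m] = 0

            if sweep >= n_burnin:
                it = sweep - n_burnin
                draws[it] = mu + d[1:] + delta + sigma
                tot_ll = log_coeff
                for i in range(I):
                    tot_ll += ll[i]
                    p_sum[i] += 1.0 / (1.0 + math.exp(-eta[i]))
                dev_draws[it] = -2.0 * tot_ll

        refresh()
        final = self.lists_to_state(mu, d, delta, sigma)
        final_lp = self._cached_log_posterior(
            mu, d, delta, sigma, ll, re_arm, re_trial, log_coeff, inv2v_mu, inv2v_d
        )
        acc_rates_post = [
            acc_post[m] / (settings.n_sample * sched_count[m]) for m in range(M)
        ]
        return draws, dev_draws, np.array(p_sum), acc_rates_post, final, final_lp

    def _cached_log_posterior(
        self, mu, d, delta, sigma, ll, re_arm, re_trial, log_coeff, inv2v_mu, inv2v_d
    ) -> float:
        """Log posterior assembled from the incremental caches (bug guard)."""
        spec = self.spec
        lp = log_coeff + sum(ll)
        sd_mu, sd_d = spec.prior_sd_mu, spec.prior_sd_d
        for x in mu:
            lp += -0.5 * math.log(2 * math.pi * sd_mu * sd_mu) - x * x * inv2v_mu
        for x in d[1:]:
            lp += -0.5 * math.log(2 * math.pi * sd_d * sd_d) - x * x * inv2v_d
        for s in sigma:
            if not 0.0 < s < spec.prior_sigma_upper:
                return -math.inf
            lp += -math.log(spec.prior_sigma_upper)
        if spec.parameterization in ("arm_re", "arm_re_tx"):
            lp += sum(re_arm)
        elif spec.parameterization == "contrast_re":
            lp += sum(re_trial)
        return lp


def run_mcmc(
    data: NmaDataset, spec: ModelSpec, settings: SamplerSettings
) -> PosteriorDraws:
    """Run the adaptive Metropolis-within-Gibbs sampler.

    Returns retained post-burn-in draws for every parameter in every chain,
    together with the per-draw deviance and the posterior-mean arm
    probabilities used for DIC.  Fully reproducible given ``settings.seed``.
    """
    engine = _Engine(data, spec)
    if settings.initial_values is not None:
        inits = list(settings.initial_values)
        if len(inits) != settings.n_chains:
            raise ValueError(
                f"got {len(inits)} initial states for {settings.n_chains} chains"
            )
    else:
        inits = default_initial_values(spec, data, settings.n_chains)
    for c, state in enumerate(inits):
        lp = models.log_posterior(state, data, spec)
        if not math.isfinite(lp):
            raise ValueError(
                f"initial state for chain {c + 1} has non-finite log posterior ({lp})"
            )

    children = np.random.SeedSequence(settings.seed).spawn(settings.n_chains)
    all_draws = np.empty((settings.n_chains, settings.n_sample, engine.n_params))
    all_dev = np.empty((settings.n_chains, settings.n_sample))
    p_sum = np.zeros(data.n_arms)
    acc = np.zeros(engine.n_moves)
    finals: list[ParameterState] = []
    final_lps: list[float] = []
    for c in range(settings.n_chains):
        rng = np.random.Generator(np.random.PCG64(children[c]))
        draws, dev, psum, rates, final, final_lp = engine.run_chain(
            inits[c], rng, settings
        )
        if not np.all(np.isfinite(dev)):
            raise RuntimeError("non-finite deviance encountered (sampler bug guard)")
        all_draws[c] = draws
        all_dev[c] = dev
        p_sum += psum
        acc += np.asarray(rates)
        finals.append(final)
        final_lps.append(final_lp)

    acc_rates = {
        name: float(acc[m] / settings.n_chains)
        for m, name in enumerate(engine.move_names)
    }
    # expose which moves are plain scalar updates (for diagnostics)
    scalar_moves = {
        name for m, name in enumerate(engine.move_names) if engine.move_scalar[m]
    }
    p_mean = p_sum / (settings.n_chains * settings.n_sample)
    result = PosteriorDraws(
        param_names=engine.param_names,
        draws=all_draws,
        deviance_draws=all_dev,
        p_mean=p_mean,
        data=data,
        spec=spec,
        settings=settings,
        acceptance_rates=acc_rates,
        final_states=finals,
        final_log_posteriors=final_lps,
    )
    result.scalar_move_names = scalar_moves
    return result
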