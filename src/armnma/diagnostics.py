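"""Posterior summaries, convergence diagnostics and model-fit statistics.

Summaries pool post-burn-in draws across chains.  Convergence is reported as
the split-chain Gelman-Rubin statistic (each chain halved, between/within
variance ratio).  Model fit uses the deviance information criterion with the
plug-in deviance evaluated at the posterior mean of each arm's event
probability — the direct parents of the data — which is the convention of
WinBUGS-style DIC for these models and makes DIC values comparable across
the arm- and contrast-based parameterizations.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .sampler import PosteriorDraws

__all__ = [
    "ParameterSummary",
    "PosteriorSummary",
    "split_rhat",
    "mcse_mean",
    "summarize",
    "baseline_heterogeneity",
    "compare_summaries",
]


@dataclass(frozen=True)
class ParameterSummary:
    mean: float
    sd: float
    q2_5: float
    median: float
    q97_5: float
    rhat: float
    mcse: float


@dataclass(frozen=True)
class PosteriorSummary:
    """Per-parameter summaries plus deviance-based fit statistics.

    ``dbar`` is the posterior mean deviance, ``dhat`` the plug-in deviance at
    the posterior-mean arm probabilities, ``p_d = dbar - dhat`` the effective
    number of parameters and ``dic = dbar + p_d``.
    """

    parameters: Mapping[str, ParameterSummary]
    dbar: float
    dhat: float
    p_d: float
    dic: float
    parameterization: str
    n_chains: int
    n_sample: int

    @property
    def dic_identity_gap(self) -> float:
        """|(dbar + p_d) - (dhat + 2 p_d)|; zero up to rounding by construction."""
        return abs((self.dbar + self.p_d) - (self.dhat + 2.0 * self.p_d))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, ps in self.parameters.items():
            rows.append(
                {
                    "parameter": name,
                    "mean": ps.mean,
                    "sd": ps.sd,
                    "q2.5": ps.q2_5,
                    "median": ps.median,
                    "q97.5": ps.q97_5,
                    "rhat": ps.rhat,
                    "mcse": ps.mcse,
                }
            )
        rows.append({"parameter": "Dbar", "mean": self.dbar})
        rows.append({"parameter": "pD", "mean": self.p_d})
        rows.append({"parameter": "DIC", "mean": self.dic})
        return pd.DataFrame(rows)

    def to_json_dict(self) -> dict:
        return {
            "parameterization": self.parameterization,
            "n_chains": self.n_chains,
            "n_sample": self.n_sample,
            "parameters": {
                name: {
                    "mean": ps.mean,
                    "sd": ps.sd,
                    "q2.5": ps.q2_5,
                    "median": ps.median,
                    "q97.5": ps.q97_5,
                    "rhat": ps.rhat,
                    "mcse": ps.mcse,
                }
                for name, ps in self.parameters.items()
            },
            "Dbar": self.dbar,
            "Dhat": self.dhat,
            "pD": self.p_d,
            "DIC": self.dic,
        }

    def write(self, csv_path: str | Path | None = None, json_path: str | Path | None = None) -> None:
        if csv_path is not None:
            self.to_frame().to_csv(csv_path, index=False)
        if json_path is not None:
            Path(json_path).write_text(json.dumps(self.to_json_dict(), indent=2))


def split_rhat(chains: np.ndarray) -> float:
    """Split-chain Gelman-Rubin statistic for draws of shape (chains, iters).

    Each chain is split in half; the statistic is
    ``sqrt(((n-1)/n * W + B/n) / W)`` over the 2C half-chains.  Degenerate
    (zero-variance) draws report exactly 1.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2:
        raise ValueError("expected draws of shape (n_chains, n_iterations)")
    c, n = chains.shape
    if c < 2:
        raise ValueError("Rhat requires at least 2 chains")
    half = n // 2
    if half < 2:
        raise ValueError("Rhat requires at least 4 draws per chain")
    parts = np.concatenate([chains[:, :half], chains[:, half : 2 * half]], axis=0)
    if np.ptp(parts) == 0.0:
        return 1.0
    w = float(np.mean(np.var(parts, axis=1, ddof=1)))
    b = half * float(np.var(np.mean(parts, axis=1), ddof=1))
    if w == 0.0:
        return math.inf
    var_hat = (half - 1) / half * w + b / half
    return math.sqrt(var_hat / w)


def mcse_mean(chains: np.ndarray, n_batches: int = 20) -> float:
    """Monte-Carlo standard error of the posterior mean by batch means."""
    chains = np.asarray(chains, dtype=float)
    c, n = chains.shape
    batch = max(n // n_batches, 1)
    usable = (n // batch) * batch
    means = chains[:, :usable].reshape(c, -1, batch).mean(axis=2)  # (c, nb)
    nb = means.shape[1]
    if nb < 2:
        return float("nan")
    var_bm = float(np.var(means, ddof=1)) * batch  # est. of var * IACT
    return math.sqrt(var_bm / (c * usable))


def _plugin_deviance(draws: PosteriorDraws) -> float:
    r = draws.data.events
    n = draws.data.sizes
    p = np.clip(draws.p_mean, 1e-300, 1 - 1e-16)
    log_coeff = gammaln(n + 1) - gammaln(r + 1) - gammaln(n - r + 1)
    ll = np.sum(log_coeff + r * np.log(p) + (n - r) * np.log1p(-p))
    return float(-2.0 * ll)


def summarize(
    draws: PosteriorDraws, monitored: Sequence[str] | None = None
) -> PosteriorSummary:
    """Summarize monitored parameters (default: all, plus the deviance)."""
    if draws.n_chains < 2:
        raise ValueError("summaries require at least 2 chains (for Rhat)")
    if monitored is None:
        monitored = list(draws.param_names) + ["deviance"]
    parameters: dict[str, ParameterSummary] = {}
    for name in monitored:
        x = draws.extract(name)  # raises KeyError for unknown names
        pooled = x.reshape(-1)
        q = np.percentile(pooled, [2.5, 50.0, 97.5], method="linear")
        parameters[name] = ParameterSummary(
            mean=float(np.mean(pooled)),
            sd=float(np.std(pooled, ddof=1)),
            q2_5=float(q[0]),
            median=float(q[1]),
            q97_5=float(q[2]),
            rhat=split_rhat(x),
            mcse=mcse_mean(x),
        )
    dbar = float(np.mean(draws.deviance_draws))
    dhat = _plugin_deviance(draws)
    p_d = dbar - dhat
    return PosteriorSummary(
        parameters=parameters,
        dbar=dbar,
        dhat=dhat,
        p_d=p_d,
        dic=dbar + p_d,
        parameterization=draws.spec.parameterization,
        n_chains=draws.n_chains,
        n_sample=draws.n_sample,
    )


def baseline_heterogeneity(summary: PosteriorSummary) -> dict:
    """Spread of the trial-baseline posterior means (arm-based fits only).

    Under the plain arm-based parameterizations every ``mu`` is the trial's
    predicted log odds on the network reference treatment, so their spread
    across trials is a descriptive signal of heterogeneity in reference
    treatment risk.  Under the base-shift and contrast parameterizations the
    baselines refer to each trial's own base treatment and are not
    comparable across trials, so this refuses to compute.
    """
    if summary.parameterization not in ("arm_fe", "arm_re", "arm_re_tx"):
        raise ValueError(
            "baseline heterogeneity is only meaningful for the plain arm-based "
            "parameterizations (arm_fe, arm_re, arm_re_tx): under "
            f"{summary.parameterization!r} the trial baselines refer to each "
            "trial's own base treatment and are not comparable across trials"
        )
    means = np.array(
        [ps.mean for name, ps in summary.parameters.items() if name.startswith("mu[")]
    )
    if means.size == 0:
        raise ValueError("no mu[...] parameters in this summary; monitor the baselines")
    return {
        "n_trials": int(means.size),
        "sd": float(np.std(means, ddof=1)) if means.size > 1 else 0.0,
        "range": float(np.ptp(means)),
        "min": float(means.min()),
        "max": float(means.max()),
    }


def compare_summaries(
    a: PosteriorSummary, b: PosteriorSummary, prefix: str = "d["
) -> dict:
    """Max absolute differences in posterior mean and SD over shared effects.

    By default compares the basic treatment effects (parameters named
    ``d[...]``), the quantities that are directly comparable across
    parameterizations.
    """
    shared = [
        name
        for name in a.parameters
        if name.startswith(prefix) and name in b.parameters
    ]
    if not shared:
        raise ValueError(
            f"no shared parameters with prefix {prefix!r} between the two fits"
        )
    dmean = {n: abs(a.parameters[n].mean - b.parameters[n].mean) for n in shared}
    dsd = {n: abs(a.parameters[n].sd - b.parameters[n].sd) for n in shared}
    return {
        "parameters": shared,
        "max_abs_mean_diff": max(dmean.values()),
        "max_abs_sd_diff": max(dsd.values()),
        "mean_diffs": dmean,
        "sd_diffs": dsd,
    }
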