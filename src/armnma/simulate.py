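"""Synthetic NMA datasets with known ground truth.

The generator draws data under the arm-based data-generating process: each
trial gets a baseline ``mu_j ~ N(mu_mean, mu_sd^2)`` (the trial's log odds
on the network reference treatment); each arm gets a response ``eta_i =
mu_{s[i]} + delta_i`` where, depending on the effects mode, ``delta_i`` is
the fixed effect ``d_{t[i]}`` or an independent draw from
``N(d_{t[i]}, sigma^2/2)`` (common variance) or ``N(d_{t[i]},
sigma_{t[i]}^2/2)`` (treatment-specific variances); and events are binomial,
``r_i ~ Bin(expit(eta_i), n_i)``.  Contrasts of two arm effects then carry
variance ``sigma^2`` and, within a multi-arm trial, pairwise covariance
``sigma^2/2`` — exactly the contrast-level random-effects structure the
models assume.

Defaults place event rates in a realistic 15-50% band (``mu ~ N(-1,
0.5^2)``) with 100-400 subjects per arm, so the binomial information is
non-degenerate without being overwhelming.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .data import ArmRecord, NmaDataset, TreatmentCoding

__all__ = [
    "TrialDesign",
    "GeneratorSpec",
    "GroundTruth",
    "generate",
    "make_benchmark_suite",
]

EFFECT_MODES = ("fixed", "random_common", "random_by_treatment")


@dataclass(frozen=True)
class TrialDesign:
    """Treatments (1-based indices, 1 = reference) and optional per-arm sizes."""

    treatments: tuple[int, ...]
    sizes: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "treatments", tuple(int(t) for t in self.treatments))
        if self.sizes is not None:
            object.__setattr__(self, "sizes", tuple(int(x) for x in self.sizes))
        if len(self.treatments) < 2:
            raise ValueError("every trial needs at least 2 arms")
        if len(set(self.treatments)) != len(self.treatments):
            raise ValueError("a trial cannot contain the same treatment twice")
        if self.sizes is not None and len(self.sizes) != len(self.treatments):
            raise ValueError("sizes must match the number of arms")


@dataclass(frozen=True)
class GeneratorSpec:
    """Data-generating configuration with known ground truth.

    ``d`` is the vector of true basic effects (log odds ratios versus the
    reference; ``d[0]`` must be 0).  ``effects`` selects fixed effects, a
    common random-effect SD ``sigma``, or per-treatment SDs ``sigma`` (a
    length-K tuple).
    """

    n_treatments: int
    trials: tuple[TrialDesign, ...]
    d: tuple[float, ...]
    mu_mean: float = -1.0
    mu_sd: float = 0.5
    effects: str = "fixed"
    sigma: float | tuple[float, ...] = 0.0
    size_range: tuple[int, int] = (100, 400)
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "trials", tuple(self.trials))
        object.__setattr__(self, "d", tuple(float(x) for x in self.d))
        if self.effects not in EFFECT_MODES:
            raise ValueError(f"effects must be one of {EFFECT_MODES}")
        if len(self.d) != self.n_treatments:
            raise ValueError("d must have one entry per treatment")
        if self.d[0] != 0.0:
            raise ValueError("d[0] (reference) must be 0")
        for trial in self.trials:
            for t in trial.treatments:
                if not 1 <= t <= self.n_treatments:
                    raise ValueError(f"treatment index {t} out of range")
        if self.effects == "random_by_treatment":
            sig = tuple(float(x) for x in np.atleast_1d(self.sigma))
            if len(sig) != self.n_treatments:
                raise ValueError("random_by_treatment needs one sigma per treatment")
            object.__setattr__(self, "sigma", sig)
            if any(x < 0 for x in sig):
                raise ValueError("sigma must be >= 0")
        else:
            if float(np.atleast_1d(self.sigma)[0]) < 0:
                raise ValueError("sigma must be >= 0")
        if self.mu_sd < 0:
            raise ValueError("mu_sd must be >= 0")


@dataclass(frozen=True)
class GroundTruth:
    """Latent truths behind a generated dataset (canonical arm order)."""

    d: tuple[float, ...]
    mu: tuple[float, ...]
    delta: tuple[float, ...]
    sigma: tuple[float, ...]
    effects: str

    def to_json_dict(self) -> dict:
        return {
            "effects": self.effects,
            "d": list(self.d),
            "mu": list(self.mu),
            "delta": list(self.delta),
            "sigma": list(self.sigma),
        }

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_json_dict(), indent=2))


def _treatment_label(t: int) -> str:
    return f"T{t}"


def generate(spec: GeneratorSpec) -> tuple[NmaDataset, GroundTruth]:
    """Draw one synthetic dataset; deterministic given ``spec.seed``.

    Trials are labelled ``trial01, trial02, ...`` in design order; treatments
    ``T1..TK`` with ``T1`` the reference.  Returns the validated dataset and
    all latent truths in the dataset's canonical arm order.
    """
    rng = np.random.default_rng(spec.seed)
    K = spec.n_treatments
    d = np.asarray(spec.d)
    if spec.effects == "random_by_treatment":
        sigma_by_t = np.asarray(spec.sigma, dtype=float)
    else:
        sigma_by_t = np.full(K, float(np.atleast_1d(spec.sigma)[0]))

    arms: list[ArmRecord] = []
    mus: list[float] = []
    # generate in canonical order (treatments ascending within trial) so the
    # returned truths line up with NmaDataset's arm order
    deltas: list[float] = []
    width = max(2, len(str(len(spec.trials))))
    for j, trial in enumerate(spec.trials):
        study = f"trial{j + 1:0{width}d}"
        mu_j = rng.normal(spec.mu_mean, spec.mu_sd)
        mus.append(mu_j)
        order = np.argsort(trial.treatments)
        for pos in order:
            t = trial.treatments[pos]  # 1-based
            if trial.sizes is not None:
                size = trial.sizes[pos]
            else:
                size = int(rng.integers(spec.size_range[0], spec.size_range[1] + 1))
            if spec.effects == "fixed":
                delta = float(d[t - 1])
            else:
                delta = float(
                    rng.normal(d[t - 1], sigma_by_t[t - 1] / np.sqrt(2.0))
                )
            deltas.append(delta)
            eta = mu_j + delta
            p = 1.0 / (1.0 + np.exp(-eta))
            r = int(rng.binomial(size, p))
            arms.append(
                ArmRecord(study=study, treatment=_treatment_label(t), events=r, size=size)
            )

    labels = tuple(_treatment_label(t + 1) for t in range(K))
    present = {a.treatment for a in arms}
    coding = TreatmentCoding(tuple(lab for lab in labels if lab in present))
    data = NmaDataset(arms, coding)
    truth = GroundTruth(
        d=tuple(float(x) for x in d),
        mu=tuple(mus),
        delta=tuple(deltas),
        sigma=tuple(float(x) for x in sigma_by_t),
        effects=spec.effects,
    )
    return data, truth


def make_benchmark_suite(seed: int = 0) -> dict[str, GeneratorSpec]:
    """Canonical synthetic test networks.

    ``two_trial_chain``
        Two 2-arm trials, A-B and B-C: four data points and (under arm-based
        fixed effects) four free parameters — the minimal just-identified
        chain network.
    ``smoking_like``
        A 24-trial, 4-treatment network shaped like the smoking-cessation
        evidence network, including exactly one 3-arm trial.
    ``indirect_reference``
        A 22-trial variant in which treatment 4 is never directly compared
        with the reference, so all paths to it are indirect.
    """
    chain = GeneratorSpec(
        n_treatments=3,
        trials=(
            TrialDesign((1, 2), (200, 200)),
            TrialDesign((2, 3), (200, 200)),
        ),
        d=(0.0, 0.3, 0.6),
        effects="fixed",
        seed=seed,
    )

    smoking_like_trials = (
        [TrialDesign((1, 3, 4))]
        + [TrialDesign((1, 3)) for _ in range(16)]
        + [TrialDesign((1, 2)) for _ in range(3)]
        + [TrialDesign((2, 4))]
        + [TrialDesign((3, 4)) for _ in range(2)]
        + [TrialDesign((1, 4))]
    )
    smoking_like = GeneratorSpec(
        n_treatments=4,
        trials=tuple(smoking_like_trials),
        d=(0.0, 0.25, 0.75, 1.0),
        mu_mean=-2.0,
        mu_sd=0.6,
        effects="random_common",
        sigma=0.5,
        seed=seed + 1,
    )

    indirect_trials = (
        [TrialDesign((2, 3, 4))]
        + [TrialDesign((1, 3)) for _ in range(15)]
        + [TrialDesign((1, 2)) for _ in range(3)]
        + [TrialDesign((2, 4))]
        + [TrialDesign((3, 4)) for _ in range(2)]
    )
    indirect = GeneratorSpec(
        n_treatments=4,
        trials=tuple(indirect_trials),
        d=(0.0, 0.25, 0.75, 1.0),
        mu_mean=-2.0,
        mu_sd=0.6,
        effects="random_common",
        sigma=0.5,
        seed=seed + 2,
    )
    return {
        "two_trial_chain": chain,
        "smoking_like": smoking_like,
        "indirect_reference": indirect,
    }
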