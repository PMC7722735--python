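"""Bayesian cue-combination rule and task condition parameters.

The task asks an observer to estimate the horizontal position of a hidden
target ("the coin") on a unit screen.  Two sources of information are
available on every trial:

* a *prior*: the coin is drawn from a Gaussian centred on the screen
  centre (0.5) whose variance is fixed within a block (small ``p`` or
  large ``P``), and
* a *likelihood*: a cloud of dots drawn iid around the coin, whose spread
  is small (``l``) or large (``L``) and varies trial to trial.

The normative observer combines the two by reliability weighting

    x_est = (1 - w) * mu_prior + w * mu_sensory,
    w     = var_prior / (var_prior + var_sensory),

where ``w`` is the *sensory weight*: the relative reliance on current
sensory evidence.  Everything else in the package (simulation, weight
estimation, observer models) is built on these two functions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

__all__ = [
    "CONDITIONS",
    "ConditionParams",
    "BayesEstimate",
    "effective_sensory_variance",
    "bayes_weight",
    "bayes_estimate",
    "optimal_condition_weights",
]

#: condition codes: first letter = prior variance, second = dot spread;
#: lowercase small, uppercase large.
CONDITIONS: tuple[str, ...] = ("pl", "pL", "Pl", "PL")

SensoryMode = Literal["centroid", "raw"]


@dataclass(frozen=True)
class ConditionParams:
    """Experimentally imposed task parameters, in unit screen coordinates.

    Defaults are the study design values: the coin prior is centred at
    0.5 with sd 0.025 (small) or 0.085 (large); each trial shows 5 dots
    with sd 0.06 (small) or 0.15 (large) around the coin.
    """

    prior_mean: float = 0.5
    prior_var_small: float = 0.025**2
    prior_var_large: float = 0.085**2
    dot_var_small: float = 0.06**2
    dot_var_large: float = 0.15**2
    dots_per_trial: int = 5
    conditions: tuple[str, ...] = field(default=CONDITIONS)

    def __post_init__(self) -> None:
        for name in ("prior_var_small", "prior_var_large", "dot_var_small", "dot_var_large"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)!r}")
        if self.prior_var_small >= self.prior_var_large:
            raise ValueError("prior_var_small must be < prior_var_large")
        if self.dot_var_small >= self.dot_var_large:
            raise ValueError("dot_var_small must be < dot_var_large")
        if self.dots_per_trial < 1:
            raise ValueError("dots_per_trial must be >= 1")

    def prior_var(self, level: str) -> float:
        """Prior variance for a prior level code ('p' small, 'P' large)."""
        if level == "p":
            return self.prior_var_small
        if level == "P":
            return self.prior_var_large
        raise ValueError(f"unknown prior level {level!r}")

    def dot_var(self, level: str) -> float:
        """Dot-spread variance for a likelihood level code ('l' small, 'L' large)."""
        if level == "l":
            return self.dot_var_small
        if level == "L":
            return self.dot_var_large
        raise ValueError(f"unknown likelihood level {level!r}")

    def sensory_var(self, level: str, mode: SensoryMode = "centroid") -> float:
        """Effective sensory variance for a likelihood level."""
        return effective_sensory_variance(self.dot_var(level), self.dots_per_trial, mode)


@dataclass(frozen=True)
class BayesEstimate:
    """Reliability-weighted combination of prior and sensory means."""

    estimate: float
    sensory_weight: float

    @property
    def prior_weight(self) -> float:
        return 1.0 - self.sensory_weight


def effective_sensory_variance(dot_var: float, n_dots: int, mode: SensoryMode = "centroid") -> float:
    """Variance of the observer's sensory estimate of the coin.

    In ``centroid`` mode the best sensory estimate is the mean of the
    ``n_dots`` dots, with variance ``dot_var / n_dots``; ``raw`` mode
    returns the single-dot spread unchanged.
    """
    if dot_var <= 0:
        raise ValueError(f"dot_var must be > 0, got {dot_var!r}")
    if n_dots < 1:
        raise ValueError(f"n_dots must be >= 1, got {n_dots!r}")
    if mode == "centroid":
        return dot_var / n_dots
    if mode == "raw":
        return dot_var
    raise ValueError(f"unknown sensory mode {mode!r}")


def bayes_weight(prior_var, sensory_var):
    """Optimal weight on sensory information, var_prior / (var_prior + var_sensory).

    Accepts scalars or numpy arrays (broadcast).  Strictly increasing in
    the prior variance and strictly decreasing in the sensory variance;
    always in (0, 1).
    """
    prior_var = np.asarray(prior_var, dtype=float)
    sensory_var = np.asarray(sensory_var, dtype=float)
    if np.any(prior_var <= 0) or np.any(sensory_var <= 0):
        raise ValueError("variances must be > 0")
    w = prior_var / (prior_var + sensory_var)
    return float(w) if w.ndim == 0 else w


def bayes_estimate(
    prior_mean: float, prior_var: float, sensory_mean: float, sensory_var: float
) -> BayesEstimate:
    """Posterior-mean estimate of the target position.

    Returns the reliability-weighted average of the prior mean and the
    sensory mean; the estimate always lies between the two means.
    """
    w = bayes_weight(prior_var, sensory_var)
    return BayesEstimate(estimate=(1.0 - w) * prior_mean + w * sensory_mean, sensory_weight=w)


def optimal_condition_weights(
    params: ConditionParams | None = None, mode: SensoryMode = "centroid"
) -> dict[str, float]:
    """Bayes-optimal sensory weight per condition (pl, pL, Pl, PL)."""
    params = params or ConditionParams()
    return {
        cond: bayes_weight(params.prior_var(cond[0]), params.sensory_var(cond[1], mode))
        for cond in params.conditions
    }
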