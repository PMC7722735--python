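"""Synthetic sessions and observers for the coin-estimation task.

Generates task sessions that follow the study design — 4 blocks of 150
trials, prior variance constant within a block (each prior level used in
two blocks), 75 trials of each dot-spread level per block in a seeded
pseudo-random order — and simulates responses from configurable observer
strategies, so that every downstream estimator can be tested against a
known ground truth.

Coin positions are drawn from the prior without truncation (with the
design variances, excursions outside the unit screen are negligible);
simulated responses are clipped to [0, 1] as a screen constraint.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
import yaml

from .task_model import ConditionParams, SensoryMode, bayes_weight, effective_sensory_variance

__all__ = [
    "Trial",
    "SessionData",
    "ObserverSpec",
    "StressEffect",
    "generate_session",
    "simulate_observer",
    "simulate_cohort",
    "score_trial",
    "score_session",
    "session_frame",
    "cohort_frame",
    "as_cohort_frame",
    "write_cohort_csv",
    "read_cohort_csv",
    "load_config",
    "condition_params_from_config",
]

#: default single-axis tolerance for the cosmetic hit/score column; the
#: net and coin widths are a display choice, not an analysis quantity.
DEFAULT_HIT_TOLERANCE = 0.015

GeneratorId = Literal["bayes", "senses_only", "prior_mean_only", "previous_coin"]


@dataclass
class Trial:
    """One task trial (positions in unit screen coordinates, x-axis only)."""

    block_index: int
    trial_index: int
    prior_level: str
    likelihood_level: str
    coin_x: float
    dot_xs: tuple[float, ...]
    centroid_x: float
    response_x: float | None = None
    hit: bool | None = None

    @property
    def condition(self) -> str:
        return self.prior_level + self.likelihood_level


@dataclass
class SessionData:
    """Ordered trials of one participant plus the design that produced them."""

    participant_id: str
    group: str
    trials: list[Trial]
    params: ConditionParams
    block_order: tuple[str, ...]
    trials_per_block: int
    seed: int | None = None

    def __len__(self) -> int:
        return len(self.trials)

    @property
    def has_responses(self) -> bool:
        return all(t.response_x is not None for t in self.trials)


@dataclass(frozen=True)
class ObserverSpec:
    """Generating strategy for simulated responses.

    ``subjective_prior_vars`` maps prior level ('p'/'P') to the variance
    the observer *believes* the prior has; setting them to the imposed
    task values yields the normative observer.  ``weight_shift`` and
    ``likelihood_var_multiplier`` are hooks for group (stress) effects on
    the generating parameters.
    """

    model_id: GeneratorId = "bayes"
    subjective_prior_vars: dict[str, float] = field(
        default_factory=lambda: {"p": 0.025**2, "P": 0.085**2}
    )
    sensory_mode: SensoryMode = "centroid"
    response_noise_sd: float = 0.05
    lapse_rate: float = 0.0
    weight_shift: float = 0.0
    likelihood_var_multiplier: float = 1.0

    def __post_init__(self) -> None:
        if self.model_id not in ("bayes", "senses_only", "prior_mean_only", "previous_coin"):
            raise ValueError(f"unknown observer model_id {self.model_id!r}")
        if self.response_noise_sd < 0:
            raise ValueError("response_noise_sd must be >= 0")
        if not 0.0 <= self.lapse_rate <= 1.0:
            raise ValueError("lapse_rate must be in [0, 1]")
        if any(v <= 0 for v in self.subjective_prior_vars.values()):
            raise ValueError("subjective prior variances must be > 0")
        if self.likelihood_var_multiplier <= 0:
            raise ValueError("likelihood_var_multiplier must be > 0")


@dataclass(frozen=True)
class StressEffect:
    """A named shift of the stressed group's generating parameters.

    parameter:
        ``sensory_weight`` — additive shift of the generating sensory
        weight (clipped to [0, 1] at generation time);
        ``prior_var`` — multiplier on both subjective prior variances;
        ``likelihood_var`` — multiplier on the effective sensory variance.
    """

    parameter: Literal["sensory_weight", "prior_var", "likelihood_var"]
    value: float

    def apply(self, spec: ObserverSpec) -> ObserverSpec:
        if self.parameter == "sensory_weight":
            return replace(spec, weight_shift=spec.weight_shift + self.value)
        if self.parameter == "prior_var":
            if self.value <= 0:
                raise ValueError("prior_var multiplier must be > 0")
            new_vars = {k: v * self.value for k, v in spec.subjective_prior_vars.items()}
            return replace(spec, subjective_prior_vars=new_vars)
        if self.parameter == "likelihood_var":
            if self.value <= 0:
                raise ValueError("likelihood_var multiplier must be > 0")
            return replace(
                spec,
                likelihood_var_multiplier=spec.likelihood_var_multiplier * self.value,
            )
        raise ValueError(f"unknown stress-effect parameter {self.parameter!r}")


def generate_session(
    params: ConditionParams | None = None,
    *,
    seed: int,
    block_order: Sequence[str] | None = None,
    trials_per_block: int = 150,
    n_blocks: int = 4,
    participant_id: str = "p01",
    group: str = "control",
) -> SessionData:
    """Generate one session of coin/dot stimuli (no responses).

    The coin on each trial is Gaussian around the prior mean with the
    block's prior variance; dots are iid Gaussian around the coin with
    the trial's dot variance.  Likelihood levels within a block are a
    seeded permutation of an equal split, so each (block, likelihood)
    cell holds ``trials_per_block / 2`` trials.  The same seed always
    reproduces the identical session.
    """
    params = params or ConditionParams()
    if trials_per_block % 2 != 0:
        raise ValueError("trials_per_block must be even to balance the two likelihood levels")
    rng = np.random.default_rng(seed)
    if block_order is None:
        # each prior level twice, in any order (drawn before the stimuli
        # so stimulus draws stay aligned across explicit/implicit orders)
        levels = ["p"] * (n_blocks // 2) + ["P"] * (n_blocks - n_blocks // 2)
        block_order = tuple(str(b) for b in rng.permutation(levels))
    else:
        block_order = tuple(block_order)
        if len(block_order) != n_blocks:
            raise ValueError("block_order length must equal n_blocks")
        if any(b not in ("p", "P") for b in block_order):
            raise ValueError("block_order entries must be 'p' or 'P'")

    half = trials_per_block // 2
    trials: list[Trial] = []
    t_index = 1
    for b_index, prior_level in enumerate(block_order, start=1):
        prior_sd = np.sqrt(params.prior_var(prior_level))
        labels = rng.permutation(np.array(["l"] * half + ["L"] * half))
        coins = rng.normal(params.prior_mean, prior_sd, size=trials_per_block)
        dot_sds = np.array([np.sqrt(params.dot_var(lab)) for lab in labels])
        dots = rng.normal(
            coins[:, None], dot_sds[:, None], size=(trials_per_block, params.dots_per_trial)
        )
        centroids = dots.mean(axis=1)
        for i in range(trials_per_block):
            trials.append(
                Trial(
                    block_index=b_index,
                    trial_index=t_index,
                    prior_level=prior_level,
                    likelihood_level=str(labels[i]),
                    coin_x=float(coins[i]),
                    dot_xs=tuple(float(x) for x in dots[i]),
                    centroid_x=float(centroids[i]),
                )
            )
            t_index += 1
    return SessionData(
        participant_id=participant_id,
        group=group,
        trials=trials,
        params=params,
        block_order=block_order,
        trials_per_block=trials_per_block,
        seed=seed,
    )


def _noiseless_predictions(session: SessionData, spec: ObserverSpec) -> np.ndarray:
    """Deterministic part of the observer's response, per trial."""
    params = session.params
    n = len(session.trials)
    centroids = np.array([t.centroid_x for t in session.trials])
    if spec.model_id == "senses_only":
        return centroids
    if spec.model_id == "prior_mean_only":
        return np.full(n, params.prior_mean)
    if spec.model_id == "previous_coin":
        coins = np.array([t.coin_x for t in session.trials])
        preds = np.empty(n)
        preds[0] = params.prior_mean  # no feedback yet: the told prior mean
        preds[1:] = coins[:-1]
        return preds
    # bayes: reliability weighting with subjective prior variances
    prior_vars = np.array([spec.subjective_prior_vars[t.prior_level] for t in session.trials])
    sens_vars = np.array(
        [
            effective_sensory_variance(
                params.dot_var(t.likelihood_level), params.dots_per_trial, spec.sensory_mode
            )
            for t in session.trials
        ]
    )
    sens_vars = sens_vars * spec.likelihood_var_multiplier
    w = np.clip(bayes_weight(prior_vars, sens_vars) + spec.weight_shift, 0.0, 1.0)
    return (1.0 - w) * params.prior_mean + w * centroids


def simulate_observer(session: SessionData, spec: ObserverSpec, *, seed: int) -> SessionData:
    """Fill in responses from an observer strategy.

    response = strategy prediction + Gaussian motor noise, replaced by a
    uniform draw on [0, 1] on lapse trials, then clipped to the screen.
    Returns a new SessionData; the input session is not modified.
    """
    if session.has_responses and len(session.trials) > 0:
        raise ValueError("session already has responses")
    rng = np.random.default_rng(seed)
    preds = _noiseless_predictions(session, spec)
    responses = preds + rng.normal(0.0, spec.response_noise_sd, size=len(preds))
    if spec.lapse_rate > 0:
        lapse = rng.random(len(preds)) < spec.lapse_rate
        responses[lapse] = rng.random(int(lapse.sum()))
    responses = np.clip(responses, 0.0, 1.0)
    new_trials = [replace(t, response_x=float(r)) for t, r in zip(session.trials, responses)]
    return replace(session, trials=new_trials)


def simulate_cohort(
    n_control: int = 31,
    n_stressed: int = 29,
    base_spec: ObserverSpec | None = None,
    stress_effect: StressEffect | None = None,
    *,
    seed: int,
    params: ConditionParams | None = None,
    trials_per_block: int = 150,
    n_blocks: int = 4,
    prior_var_sd_log: float = 0.0,
    hit_tolerance: float = DEFAULT_HIT_TOLERANCE,
) -> list[SessionData]:
    """Simulate a two-group cohort with a known (possibly null) group effect.

    Stressed participants' generating parameters are shifted by
    ``stress_effect``; with ``prior_var_sd_log > 0`` each participant's
    subjective prior variances are additionally scaled by independent
    lognormal factors exp(N(0, sd^2)) to mimic individual variation.
    All randomness derives from the master seed.
    """
    if n_control < 1 or n_stressed < 1:
        raise ValueError("group sizes must be >= 1")
    base_spec = base_spec or ObserverSpec()
    params = params or ConditionParams()
    master = np.random.default_rng(seed)
    sessions: list[SessionData] = []
    groups = [("control", i + 1) for i in range(n_control)] + [
        ("stressed", i + 1) for i in range(n_stressed)
    ]
    for group, idx in groups:
        spec = base_spec
        if group == "stressed" and stress_effect is not None:
            spec = stress_effect.apply(spec)
        if prior_var_sd_log > 0:
            factors = np.exp(master.normal(0.0, prior_var_sd_log, size=2))
            new_vars = {
                "p": spec.subjective_prior_vars["p"] * float(factors[0]),
                "P": spec.subjective_prior_vars["P"] * float(factors[1]),
            }
            spec = replace(spec, subjective_prior_vars=new_vars)
        stim_seed, resp_seed = (int(s) for s in master.integers(0, 2**31 - 1, size=2))
        pid = f"{'c' if group == 'control' else 's'}{idx:02d}"
        session = generate_session(
            params,
            seed=stim_seed,
            trials_per_block=trials_per_block,
            n_blocks=n_blocks,
            participant_id=pid,
            group=group,
        )
        session = simulate_observer(session, spec, seed=resp_seed)
        sessions.append(score_session(session, tolerance=hit_tolerance))
    return sessions


def score_trial(response_x: float, coin_x: float, tolerance: float = DEFAULT_HIT_TOLERANCE) -> bool:
    """Whether the placed net covers the coin (boundary inclusive)."""
    if tolerance <= 0:
        raise ValueError("tolerance must be > 0")
    # epsilon guard keeps the boundary inclusive under float round-off
    return bool(abs(response_x - coin_x) <= tolerance + 1e-12)


def score_session(session: SessionData, tolerance: float = DEFAULT_HIT_TOLERANCE) -> SessionData:
    """Fill the hit column for every responded trial."""
    new_trials = [
        replace(t, hit=score_trial(t.response_x, t.coin_x, tolerance))
        if t.response_x is not None
        else t
        for t in session.trials
    ]
    return replace(session, trials=new_trials)


# ---------------------------------------------------------------------------
# tabular interchange

def session_frame(session: SessionData) -> pd.DataFrame:
    """One row per trial; dot columns named dot1..dotK."""
    k = session.params.dots_per_trial
    rows = {
        "participant_id": session.participant_id,
        "group": session.group,
        "block": [t.block_index for t in session.trials],
        "trial": [t.trial_index for t in session.trials],
        "prior_level": [t.prior_level for t in session.trials],
        "likelihood_level": [t.likelihood_level for t in session.trials],
        "coin_x": [t.coin_x for t in session.trials],
    }
    frame = pd.DataFrame(rows)
    dots = np.array([t.dot_xs for t in session.trials])
    for j in range(k):
        frame[f"dot{j + 1}"] = dots[:, j]
    frame["centroid_x"] = [t.centroid_x for t in session.trials]
    frame["response_x"] = [t.response_x for t in session.trials]
    frame["hit"] = [t.hit for t in session.trials]
    return frame


def cohort_frame(sessions: Iterable[SessionData]) -> pd.DataFrame:
    return pd.concat([session_frame(s) for s in sessions], ignore_index=True)


def as_cohort_frame(cohort) -> pd.DataFrame:
    """Normalise a cohort argument (frame, session, or list of sessions)."""
    if isinstance(cohort, pd.DataFrame):
        return cohort
    if isinstance(cohort, SessionData):
        return session_frame(cohort)
    return cohort_frame(cohort)


def write_cohort_csv(cohort, path) -> None:
    as_cohort_frame(cohort).to_csv(path, index=False)


def read_cohort_csv(path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    required = {
        "participant_id",
        "group",
        "block",
        "trial",
        "prior_level",
        "likelihood_level",
        "coin_x",
        "centroid_x",
        "response_x",
    }
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"cohort CSV missing columns: {sorted(missing)}")
    return frame


# ---------------------------------------------------------------------------
# configuration

def load_config(path) -> dict:
    """Load a YAML/JSON config mirroring ConditionParams + cohort settings."""
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config must be a mapping")
    return cfg


def condition_params_from_config(cfg: dict) -> ConditionParams:
    fields = {
        k: cfg[k]
        for k in (
            "prior_mean",
            "prior_var_small",
            "prior_var_large",
            "dot_var_small",
            "dot_var_large",
            "dots_per_trial",
        )
        if k in cfg
    }
    return ConditionParams(**fields)
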