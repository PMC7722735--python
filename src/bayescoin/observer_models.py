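"""The ten candidate observer models and their fitting machinery.

Models 1–3 are heuristics (centroid only, prior mean only, previous
coin); models 4–7 are reliability-weighting observers differing in where
their prior variances come from (imposed task values, learned trial by
trial from feedback, fitted globally, fitted per participant); models
8–10 add a group (stress) dummy to the globally fitted observer, acting
on the sensory weight, the prior variance, or the likelihood variance.

All prediction functions operate on a tidy cohort frame (one row per
trial; see `synthetic_data.session_frame`) and return an array aligned
with it.  Fitting minimises the sum of squared response errors — the
maximum-likelihood criterion under a single Gaussian response-noise
variance — with a bounded quasi-Newton search on log-variances and
seeded multistarts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy import optimize

from .synthetic_data import as_cohort_frame
from .task_model import ConditionParams, SensoryMode, effective_sensory_variance

__all__ = [
    "MODEL_NAMES",
    "ModelSpec",
    "FittedModel",
    "model_k_free",
    "predict_m1_senses",
    "predict_m2_prior_mean",
    "predict_m3_previous_coin",
    "predict_m4_bayes_task_params",
    "predict_m5_bayes_learned_prior",
    "predict_m6_two_priors_global",
    "predict_m7_two_priors_per_participant",
    "predict_m8_stress_on_slope",
    "predict_m9_stress_on_prior_var",
    "predict_m10_stress_on_likelihood_var",
    "fit_model",
    "predict_fitted",
]

MODEL_NAMES: dict[int, str] = {
    1: "senses_only",
    2: "prior_mean_only",
    3: "previous_coin",
    4: "bayes_task_params",
    5: "bayes_learned_prior",
    6: "bayes_two_priors_global",
    7: "bayes_two_priors_per_participant",
    8: "bayes_stress_on_slope",
    9: "bayes_stress_on_prior_var",
    10: "bayes_stress_on_likelihood_var",
}

#: search bounds for fitted prior variances (screen-coordinate units²)
VAR_BOUNDS = (1e-6, 1.0)
#: additive sensory-weight dummy bounds (model 8)
SLOPE_BETA_BOUNDS = (-1.0, 1.0)
#: log-multiplicative variance dummy bounds (models 9, 10)
LOG_BETA_BOUNDS = (-5.0, 5.0)
#: variance floor for the trial-by-trial learner (model 5)
LEARNED_VAR_FLOOR = 1e-6


@dataclass(frozen=True)
class ModelSpec:
    model_id: int
    name: str
    fit_level: str  # "none", "cohort", or "participant"
    k_free_per_unit: int  # free parameters per cohort (or per participant for model 7)


MODEL_SPECS: dict[int, ModelSpec] = {
    1: ModelSpec(1, MODEL_NAMES[1], "none", 0),
    2: ModelSpec(2, MODEL_NAMES[2], "none", 0),
    3: ModelSpec(3, MODEL_NAMES[3], "none", 0),
    4: ModelSpec(4, MODEL_NAMES[4], "none", 0),
    5: ModelSpec(5, MODEL_NAMES[5], "none", 0),
    6: ModelSpec(6, MODEL_NAMES[6], "cohort", 2),
    7: ModelSpec(7, MODEL_NAMES[7], "participant", 2),
    8: ModelSpec(8, MODEL_NAMES[8], "cohort", 3),
    9: ModelSpec(9, MODEL_NAMES[9], "cohort", 3),
    10: ModelSpec(10, MODEL_NAMES[10], "cohort", 3),
}


def model_k_free(model_id: int, n_participants: int) -> int:
    """Cohort-level free-parameter count (2 per participant for model 7)."""
    spec = MODEL_SPECS[model_id]
    if spec.fit_level == "participant":
        return spec.k_free_per_unit * n_participants
    return spec.k_free_per_unit


# ---------------------------------------------------------------------------
# shared trial arrays

@dataclass
class _TrialArrays:
    centroid: np.ndarray
    coin: np.ndarray
    response: np.ndarray | None
    sensory_var: np.ndarray  # effective, per trial
    prior_is_large: np.ndarray  # bool
    stressed: np.ndarray  # bool
    pid: np.ndarray  # participant labels
    block: np.ndarray
    trial: np.ndarray
    prior_mean: float


def _arrays(frame: pd.DataFrame, params: ConditionParams, mode: SensoryMode) -> _TrialArrays:
    sv = {
        lev: effective_sensory_variance(params.dot_var(lev), params.dots_per_trial, mode)
        for lev in ("l", "L")
    }
    lik = frame["likelihood_level"].to_numpy(dtype=str)
    resp = None
    if "response_x" in frame.columns and frame["response_x"].notna().all():
        resp = frame["response_x"].to_numpy(dtype=float)
    return _TrialArrays(
        centroid=frame["centroid_x"].to_numpy(dtype=float),
        coin=frame["coin_x"].to_numpy(dtype=float),
        response=resp,
        sensory_var=np.where(lik == "L", sv["L"], sv["l"]),
        prior_is_large=(frame["prior_level"].to_numpy(dtype=str) == "P"),
        stressed=(frame["group"].to_numpy(dtype=str) == "stressed"),
        pid=frame["participant_id"].to_numpy(),
        block=frame["block"].to_numpy(),
        trial=frame["trial"].to_numpy(),
        prior_mean=params.prior_mean,
    )


def _bayes_pred(
    arr: _TrialArrays,
    v_p: float | np.ndarray,
    v_P: float | np.ndarray,
    *,
    beta_slope: float = 0.0,
    beta_prior: float = 0.0,
    beta_lik: float = 0.0,
) -> np.ndarray:
    pv = np.where(arr.prior_is_large, v_P, v_p)
    if beta_prior != 0.0:
        pv = pv * np.exp(beta_prior * arr.stressed)
    s2 = arr.sensory_var
    if beta_lik != 0.0:
        s2 = s2 * np.exp(beta_lik * arr.stressed)
    w = pv / (pv + s2)
    if beta_slope != 0.0:
        w = np.clip(w + beta_slope * arr.stressed, 0.0, 1.0)
    return (1.0 - w) * arr.prior_mean + w * arr.centroid


def _n_clamped(arr: _TrialArrays, v_p, v_P, beta_slope: float) -> int:
    pv = np.where(arr.prior_is_large, v_P, v_p)
    w = pv / (pv + arr.sensory_var) + beta_slope * arr.stressed
    return int(((w < 0) | (w > 1)).sum())


# ---------------------------------------------------------------------------
# prediction functions (spec order)

def predict_m1_senses(frame, params: ConditionParams | None = None) -> np.ndarray:
    """Centroid of the dot cloud; no reliance on prior information."""
    frame = as_cohort_frame(frame)
    return frame["centroid_x"].to_numpy(dtype=float)


def predict_m2_prior_mean(frame, params: ConditionParams | None = None) -> np.ndarray:
    """Always the prior mean (0.5); no reliance on current evidence."""
    frame = as_cohort_frame(frame)
    params = params or ConditionParams()
    return np.full(len(frame), params.prior_mean)


def predict_m3_previous_coin(frame, params: ConditionParams | None = None) -> np.ndarray:
    """The revealed coin position of the previous trial (per participant).

    On a participant's first trial there is no feedback yet, so the
    prediction falls back to the told prior mean.
    """
    frame = as_cohort_frame(frame)
    params = params or ConditionParams()
    preds = np.empty(len(frame))
    frame = frame.reset_index(drop=True)
    for _, idx in frame.groupby("participant_id", sort=False).groups.items():
        order = frame.loc[idx].sort_values("trial").index.to_numpy()
        coins = frame.loc[order, "coin_x"].to_numpy(dtype=float)
        p = np.empty(len(order))
        p[0] = params.prior_mean
        p[1:] = coins[:-1]
        preds[order] = p
    return preds


def predict_m4_bayes_task_params(
    frame, params: ConditionParams | None = None, mode: SensoryMode = "centroid"
) -> np.ndarray:
    """Reliability weighting with the experimentally imposed variances."""
    frame = as_cohort_frame(frame)
    params = params or ConditionParams()
    arr = _arrays(frame, params, mode)
    return _bayes_pred(arr, params.prior_var_small, params.prior_var_large)


def predict_m5_bayes_learned_prior(
    frame,
    params: ConditionParams | None = None,
    mode: SensoryMode = "centroid",
    init_var: float | None = None,
    var_floor: float = LEARNED_VAR_FLOOR,
) -> np.ndarray:
    """Reliability weighting with the prior variance learned from feedback.

    Within each block the prior-variance estimate before trial t is the
    mean squared deviation of the previously revealed coins from the
    (known) prior mean; it starts at ``init_var`` (default: the large
    imposed variance, an agnostic start) and resets at block boundaries,
    where the prior changes.  A small floor keeps weights defined when
    the first coins land exactly on the mean.
    """
    frame = as_cohort_frame(frame)
    params = params or ConditionParams()
    if init_var is None:
        init_var = params.prior_var_large
    arr = _arrays(frame, params, mode)
    preds = np.empty(len(frame))
    frame = frame.reset_index(drop=True)
    for _, idx in frame.groupby(["participant_id", "block"], sort=False).groups.items():
        order = frame.loc[idx].sort_values("trial").index.to_numpy()
        coins = frame.loc[order, "coin_x"].to_numpy(dtype=float)
        sq = (coins - params.prior_mean) ** 2
        v_hat = np.empty(len(order))
        v_hat[0] = init_var
        counts = np.arange(1, len(order))
        v_hat[1:] = np.cumsum(sq)[:-1] / counts
        v_hat = np.maximum(v_hat, var_floor)
        s2 = arr.sensory_var[order]
        w = v_hat / (v_hat + s2)
        preds[order] = (1.0 - w) * params.prior_mean + w * frame.loc[order, "centroid_x"].to_numpy(
            dtype=float
        )
    return preds


def predict_m6_two_priors_global(
    frame,
    v_p: float,
    v_P: float,
    params: ConditionParams | None = None,
    mode: SensoryMode = "centroid",
) -> np.ndarray:
    """Reliability weighting with two fitted prior variances shared cohort-wide."""
    frame = as_cohort_frame(frame)
    params = params or ConditionParams()
    return _bayes_pred(_arrays(frame, params, mode), v_p, v_P)


def predict_m7_two_priors_per_participant(
    frame,
    participant_vars: dict[str, tuple[float, float]],
    params: ConditionParams | None = None,
    mode: SensoryMode = "centroid",
) -> np.ndarray:
    """As model 6 but with (v_p, v_P) specific to each participant."""
    frame = as_cohort_frame(frame)
    params = params or ConditionParams()
    arr = _arrays(frame, params, mode)
    v_p = np.array([participant_vars[p][0] for p in arr.pid])
    v_P = np.array([participant_vars[p][1] for p in arr.pid])
    return _bayes_pred(arr, v_p, v_P)


def predict_m8_stress_on_slope(
    frame,
    v_p: float,
    v_P: float,
    beta: float,
    params: ConditionParams | None = None,
    mode: SensoryMode = "centroid",
) -> np.ndarray:
    """Model 6 plus an additive stress dummy on the sensory weight (clamped to [0, 1])."""
    frame = as_cohort_frame(frame)
    params = params or ConditionParams()
    return _bayes_pred(_arrays(frame, params, mode), v_p, v_P, beta_slope=beta)


def predict_m9_stress_on_prior_var(
    frame,
    v_p: float,
    v_P: float,
    beta: float,
    params: ConditionParams | None = None,
    mode: SensoryMode = "centroid",
) -> np.ndarray:
    """Model 6 with the stressed group's prior variances scaled by exp(beta)."""
    frame = as_cohort_frame(frame)
    params = params or ConditionParams()
    return _bayes_pred(_arrays(frame, params, mode), v_p, v_P, beta_prior=beta)


def predict_m10_stress_on_likelihood_var(
    frame,
    v_p: float,
    v_P: float,
    beta: float,
    params: ConditionParams | None = None,
    mode: SensoryMode = "centroid",
) -> np.ndarray:
    """Model 6 with the stressed group's likelihood variances scaled by exp(beta)."""
    frame = as_cohort_frame(frame)
    params = params or ConditionParams()
    return _bayes_pred(_arrays(frame, params, mode), v_p, v_P, beta_lik=beta)


# ---------------------------------------------------------------------------
# fitting

@dataclass
class FittedModel:
    """A fitted (or parameter-free) model plus its in-sample predictions."""

    model_id: int
    name: str
    params: dict
    k_free: int
    predictions: np.ndarray
    sse: float
    n_obs: int
    seed: int | None = None
    diagnostics: dict = field(default_factory=dict)
    condition_params: ConditionParams = field(default_factory=ConditionParams)
    mode: SensoryMode = "centroid"

    def to_json(self) -> str:
        payload = {
            "model_id": self.model_id,
            "name": self.name,
            "params": self.params,
            "k_free": self.k_free,
            "sse": self.sse,
            "n_obs": self.n_obs,
            "seed": self.seed,
            "diagnostics": self.diagnostics,
        }
        return json.dumps(payload, indent=2, default=float)


def _multistart_minimize(
    objective: Callable[[np.ndarray], float],
    starts: list[np.ndarray],
    bounds: list[tuple[float, float]],
) -> tuple[np.ndarray, float, dict]:
    """Bounded quasi-Newton from several starts; ties resolved by lowest
    objective, then lowest parameter norm."""
    best = None
    n_converged = 0
    for x0 in starts:
        res = optimize.minimize(
            objective, x0, method="L-BFGS-B", bounds=bounds, options={"ftol": 1e-9, "gtol": 1e-10}
        )
        n_converged += bool(res.success)
        key = (res.fun, float(np.linalg.norm(res.x)))
        if best is None or key < best[0]:
            best = (key, res)
    res = best[1]
    return res.x, float(res.fun), {"n_starts": len(starts), "n_converged": n_converged}


def _var_starts(rng: np.random.Generator, params: ConditionParams, n_extra: int) -> list[np.ndarray]:
    lo, hi = np.log(VAR_BOUNDS[0]), np.log(VAR_BOUNDS[1])
    starts = [np.log([params.prior_var_small, params.prior_var_large])]
    for _ in range(n_extra):
        starts.append(rng.uniform(lo, hi, size=2))
    return starts


def fit_model(
    model_id: int,
    frame,
    params: ConditionParams | None = None,
    mode: SensoryMode = "centroid",
    *,
    seed: int = 0,
    n_starts: int = 5,
) -> FittedModel:
    """Fit one of the ten models to a cohort frame with responses.

    Parameter-free models (1–5) are evaluated directly.  Models 6 and
    8–10 share their parameters cohort-wide; model 7 is fitted
    independently per participant (its squared-error objective is
    separable).  The objective is the summed squared response error.
    """
    frame = as_cohort_frame(frame)
    params = params or ConditionParams()
    if model_id not in MODEL_SPECS:
        raise ValueError(f"unknown model id {model_id!r}")
    if frame["response_x"].isna().any():
        raise ValueError("frame has trials without responses")
    arr = _arrays(frame, params, mode)
    y = arr.response
    rng = np.random.default_rng(seed)
    n_participants = frame["participant_id"].nunique()
    spec = MODEL_SPECS[model_id]
    diagnostics: dict = {}

    if spec.fit_level == "none":
        pred_fn = {
            1: predict_m1_senses,
            2: predict_m2_prior_mean,
            3: predict_m3_previous_coin,
            4: lambda f, p: predict_m4_bayes_task_params(f, p, mode),
            5: lambda f, p: predict_m5_bayes_learned_prior(f, p, mode),
        }[model_id]
        preds = pred_fn(frame, params)
        fitted: dict = {}
    elif model_id == 6:
        def obj(theta):
            return float(np.sum((y - _bayes_pred(arr, *np.exp(theta))) ** 2))

        bounds = [(np.log(VAR_BOUNDS[0]), np.log(VAR_BOUNDS[1]))] * 2
        x, _, diagnostics = _multistart_minimize(obj, _var_starts(rng, params, n_starts - 1), bounds)
        v_p, v_P = np.exp(x)
        fitted = {"v_p": float(v_p), "v_P": float(v_P)}
        preds = _bayes_pred(arr, v_p, v_P)
    elif model_id == 7:
        fitted_vars: dict[str, tuple[float, float]] = {}
        preds = np.empty(len(frame))
        bounds = [(np.log(VAR_BOUNDS[0]), np.log(VAR_BOUNDS[1]))] * 2
        conv_total = 0
        for pid in pd.unique(arr.pid):
            mask = arr.pid == pid
            sub = _TrialArrays(
                centroid=arr.centroid[mask],
                coin=arr.coin[mask],
                response=y[mask],
                sensory_var=arr.sensory_var[mask],
                prior_is_large=arr.prior_is_large[mask],
                stressed=arr.stressed[mask],
                pid=arr.pid[mask],
                block=arr.block[mask],
                trial=arr.trial[mask],
                prior_mean=arr.prior_mean,
            )
            ysub = y[mask]

            def obj(theta, _s=sub, _y=ysub):
                return float(np.sum((_y - _bayes_pred(_s, *np.exp(theta))) ** 2))

            x, _, diag = _multistart_minimize(obj, _var_starts(rng, params, n_starts - 1), bounds)
            v = np.exp(x)
            fitted_vars[pid] = (float(v[0]), float(v[1]))
            preds[mask] = _bayes_pred(sub, v[0], v[1])
            conv_total += diag["n_converged"]
        fitted = {"participant_vars": fitted_vars}
        diagnostics = {"n_starts": n_starts, "n_converged": conv_total}
    else:  # models 8, 9, 10: two shared variances plus a stress dummy
        which = {8: "beta_slope", 9: "beta_prior", 10: "beta_lik"}[model_id]
        beta_bounds = SLOPE_BETA_BOUNDS if model_id == 8 else LOG_BETA_BOUNDS

        def obj(theta):
            v = np.exp(theta[:2])
            return float(np.sum((y - _bayes_pred(arr, v[0], v[1], **{which: theta[2]})) ** 2))

        starts = [
            np.append(s, rng.uniform(*beta_bounds) if i else 0.0)
            for i, s in enumerate(_var_starts(rng, params, n_starts - 1))
        ]
        bounds = [(np.log(VAR_BOUNDS[0]), np.log(VAR_BOUNDS[1]))] * 2 + [beta_bounds]
        x, _, diagnostics = _multistart_minimize(obj, starts, bounds)
        v_p, v_P = np.exp(x[:2])
        beta = float(x[2])
        fitted = {"v_p": float(v_p), "v_P": float(v_P), "beta": beta}
        preds = _bayes_pred(arr, v_p, v_P, **{which: beta})
        if model_id == 8:
            diagnostics["clamp_events"] = _n_clamped(arr, v_p, v_P, beta)

    sse = float(np.sum((y - preds) ** 2))
    return FittedModel(
        model_id=model_id,
        name=spec.name,
        params=fitted,
        k_free=model_k_free(model_id, n_participants),
        predictions=preds,
        sse=sse,
        n_obs=len(frame),
        seed=seed,
        diagnostics=diagnostics,
        condition_params=params,
        mode=mode,
    )


def predict_fitted(fit: FittedModel, frame) -> np.ndarray:
    """Predictions of a fitted model on a (possibly different) cohort frame."""
    frame = as_cohort_frame(frame)
    params, mode = fit.condition_params, fit.mode
    mid = fit.model_id
    if mid == 1:
        return predict_m1_senses(frame, params)
    if mid == 2:
        return predict_m2_prior_mean(frame, params)
    if mid == 3:
        return predict_m3_previous_coin(frame, params)
    if mid == 4:
        return predict_m4_bayes_task_params(frame, params, mode)
    if mid == 5:
        return predict_m5_bayes_learned_prior(frame, params, mode)
    if mid == 6:
        return predict_m6_two_priors_global(frame, fit.params["v_p"], fit.params["v_P"], params, mode)
    if mid == 7:
        return predict_m7_two_priors_per_participant(
            frame, fit.params["participant_vars"], params, mode
        )
    if mid == 8:
        return predict_m8_stress_on_slope(
            frame, fit.params["v_p"], fit.params["v_P"], fit.params["beta"], params, mode
        )
    if mid == 9:
        return predict_m9_stress_on_prior_var(
            frame, fit.params["v_p"], fit.params["v_P"], fit.params["beta"], params, mode
        )
    if mid == 10:
        return predict_m10_stress_on_likelihood_var(
            frame, fit.params["v_p"], fit.params["v_P"], fit.params["beta"], params, mode
        )
    raise ValueError(f"unknown model id {mid!r}")
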