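"""Model scoring and comparison: Gaussian likelihoods, BIC/AIC, and
odd/even cross-validated prediction error.

Goodness of fit is scored two ways, mirroring the analysis design:

* full-data Gaussian log-likelihood with a single pooled residual
  variance, penalised by BIC/AIC with an effective parameter count of
  k_free + 1 (the residual variance counts as a parameter, so the
  parameter-free heuristics carry one effective parameter and
  BIC - AIC = (k_free + 1)(ln n - 2) for every model);
* cross-validation: parameters are fitted on a participant's
  odd-numbered trials (1-based session order) and the root mean squared
  prediction error is measured on the even-numbered trials.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .group_stats import rank_sum_test, signed_rank_test
from .observer_models import MODEL_SPECS, FittedModel, fit_model, predict_fitted
from .synthetic_data import as_cohort_frame
from .task_model import ConditionParams, SensoryMode

__all__ = [
    "ModelFitResult",
    "ComparisonTable",
    "gaussian_loglik",
    "information_criteria",
    "odd_even_cv",
    "fit_and_score",
    "compare_models",
]


def gaussian_loglik(predictions, responses) -> tuple[float, float]:
    """Maximised Gaussian log-likelihood of residuals and the ML variance.

    With sigma2 profiled out, logL = -n/2 (ln(2 pi sigma2_ML) + 1) where
    sigma2_ML is the mean squared residual.  Perfect predictions make
    the likelihood degenerate; +inf is returned for the caller to flag.
    """
    predictions = np.asarray(predictions, dtype=float)
    responses = np.asarray(responses, dtype=float)
    if predictions.shape != responses.shape:
        raise ValueError("predictions and responses must be aligned")
    n = len(responses)
    if n < 2:
        raise ValueError("need >= 2 observations")
    sigma2 = float(np.mean((responses - predictions) ** 2))
    if sigma2 == 0.0:
        return math.inf, 0.0
    return float(-n / 2.0 * (math.log(2.0 * math.pi * sigma2) + 1.0)), sigma2


def information_criteria(log_likelihood: float, k_free: int, n_obs: int) -> tuple[float, float]:
    """(BIC, AIC) with k_eff = k_free + 1 for the fitted residual variance."""
    if n_obs < 2:
        raise ValueError("n_obs must be >= 2")
    k_eff = k_free + 1
    aic = 2.0 * k_eff - 2.0 * log_likelihood
    bic = k_eff * math.log(n_obs) - 2.0 * log_likelihood
    return bic, aic


def _cv_masks(frame: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    trial = frame["trial"].to_numpy()
    odd = trial % 2 == 1
    return odd, ~odd


def odd_even_cv(
    model_id: int,
    frame,
    params: ConditionParams | None = None,
    mode: SensoryMode = "centroid",
    *,
    seed: int = 0,
    n_starts: int = 5,
) -> pd.Series:
    """Per-participant cross-validated rMSE for one model.

    Parameters are fitted on the odd trials only (parameter-free models
    skip fitting); predictions for the even trials are computed from the
    full session so that history-dependent models (previous coin,
    learned prior) see the true trial sequence.
    """
    frame = as_cohort_frame(frame).reset_index(drop=True)
    odd, even = _cv_masks(frame)
    if odd.sum() < 2 or even.sum() < 2:
        raise ValueError("need >= 2 odd and >= 2 even trials for odd/even CV")
    spec = MODEL_SPECS[model_id]
    fit_frame = frame if spec.fit_level == "none" else frame[odd]
    fit = fit_model(model_id, fit_frame, params, mode, seed=seed, n_starts=n_starts)
    preds = predict_fitted(fit, frame)
    resid2 = (frame["response_x"].to_numpy(dtype=float) - preds) ** 2
    out = (
        pd.DataFrame(
            {"participant_id": frame["participant_id"], "sq": resid2, "even": even}
        )
        .query("even")
        .groupby("participant_id", sort=False)["sq"]
        .mean()
        .pow(0.5)
    )
    out.name = f"cv_rmse_m{model_id}"
    return out


@dataclass
class ModelFitResult:
    model_id: int
    name: str
    params: dict
    log_likelihood: float
    sigma2: float
    k_free: int
    k_eff: int
    n_obs: int
    bic: float
    aic: float
    cv_rmse: pd.Series  # per participant
    pooled_cv_rmse: float
    fit: FittedModel


def fit_and_score(
    model_id: int,
    frame,
    params: ConditionParams | None = None,
    mode: SensoryMode = "centroid",
    *,
    seed: int = 0,
    n_starts: int = 5,
) -> ModelFitResult:
    """Full-data fit (for BIC/AIC) plus odd/even cross-validation."""
    frame = as_cohort_frame(frame).reset_index(drop=True)
    fit = fit_model(model_id, frame, params, mode, seed=seed, n_starts=n_starts)
    y = frame["response_x"].to_numpy(dtype=float)
    logl, sigma2 = gaussian_loglik(fit.predictions, y)
    bic, aic = information_criteria(logl, fit.k_free, fit.n_obs)
    cv = odd_even_cv(model_id, frame, params, mode, seed=seed, n_starts=n_starts)
    return ModelFitResult(
        model_id=model_id,
        name=fit.name,
        params=fit.params,
        log_likelihood=logl,
        sigma2=sigma2,
        k_free=fit.k_free,
        k_eff=fit.k_free + 1,
        n_obs=fit.n_obs,
        bic=bic,
        aic=aic,
        cv_rmse=cv,
        pooled_cv_rmse=float(cv.mean()),
        fit=fit,
    )


@dataclass
class ComparisonTable:
    """All fitted models side by side, with the group-level CV tests."""

    table: pd.DataFrame  # one row per model: k_free, BIC, AIC, mean cv-rMSE
    cv_rmse: pd.DataFrame  # participants x models
    groups: pd.Series  # group label per participant
    best_model_id: int
    within_group_tests: pd.DataFrame  # signed-rank vs best, per group & model
    between_group_tests: pd.DataFrame  # rank-sum control vs stressed, per model
    results: dict[int, ModelFitResult] = field(default_factory=dict)

    def group_delta_table(self) -> pd.DataFrame:
        """Fig-4-style summary: mean (and sem) cv-rMSE difference to the
        best model, per group and model."""
        best = self.cv_rmse[self.best_model_id]
        rows = []
        for g in self.groups.unique():
            mask = self.groups == g
            for mid in self.cv_rmse.columns:
                delta = self.cv_rmse.loc[mask, mid] - best[mask]
                rows.append(
                    {
                        "group": g,
                        "model_id": mid,
                        "mean_delta_cv_rmse": float(delta.mean()),
                        "sem_delta_cv_rmse": float(delta.sem()) if len(delta) > 1 else math.nan,
                    }
                )
        return pd.DataFrame(rows)


def compare_models(
    frame,
    model_ids: tuple[int, ...] = tuple(range(1, 11)),
    params: ConditionParams | None = None,
    mode: SensoryMode = "centroid",
    *,
    seed: int = 0,
    n_starts: int = 5,
) -> ComparisonTable:
    """Fit and score a set of models on one cohort.

    The best model is flagged by lowest BIC (ties broken by lower
    k_eff).  Within each group, every model's per-participant cv-rMSE is
    compared with the best model's by Wilcoxon signed-rank; between
    groups each model's cv-rMSE is compared by Wilcoxon rank-sum.
    """
    frame = as_cohort_frame(frame).reset_index(drop=True)
    results: dict[int, ModelFitResult] = {}
    for mid in model_ids:
        results[mid] = fit_and_score(mid, frame, params, mode, seed=seed, n_starts=n_starts)

    cv = pd.DataFrame({mid: r.cv_rmse for mid, r in results.items()})
    groups = frame.groupby("participant_id", sort=False)["group"].first().loc[cv.index]

    ranked = sorted(results.values(), key=lambda r: (r.bic, r.k_eff))
    best_id = ranked[0].model_id

    table = pd.DataFrame(
        [
            {
                "model_id": r.model_id,
                "name": r.name,
                "k_free": r.k_free,
                "log_likelihood": r.log_likelihood,
                "BIC": r.bic,
                "AIC": r.aic,
                "mean_cv_rmse": r.pooled_cv_rmse,
                "best": r.model_id == best_id,
            }
            for r in results.values()
        ]
    )

    within_rows = []
    for g in groups.unique():
        mask = groups == g
        best_vals = cv.loc[mask, best_id]
        for mid in model_ids:
            if mid == best_id:
                continue
            res = signed_rank_test(cv.loc[mask, mid].to_numpy(), best_vals.to_numpy())
            within_rows.append(
                {
                    "group": g,
                    "model_id": mid,
                    "statistic": res.statistic,
                    "p": res.p_value,
                    "mean_delta": float((cv.loc[mask, mid] - best_vals).mean()),
                }
            )
    between_rows = []
    glabels = list(groups.unique())
    if len(glabels) == 2:
        m0, m1 = (groups == glabels[0]), (groups == glabels[1])
        for mid in model_ids:
            res = rank_sum_test(cv.loc[m0, mid].to_numpy(), cv.loc[m1, mid].to_numpy())
            between_rows.append(
                {"model_id": mid, "W": res.statistic, "p": res.p_value, "d": res.effect_size}
            )

    return ComparisonTable(
        table=table,
        cv_rmse=cv,
        groups=groups,
        best_model_id=best_id,
        within_group_tests=pd.DataFrame(within_rows),
        between_group_tests=pd.DataFrame(between_rows),
        results=results,
    )
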