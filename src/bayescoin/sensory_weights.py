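"""Per-participant sensory weights and uncertainty sensitivity.

The *sensory weight* is the slope of an ordinary least-squares
regression of the participant's response on the dot-cloud centroid: 1
means pure reliance on current sensory evidence, 0 pure reliance on the
prior (the weight on the prior is 1 − slope).  Condition-wise weights
over the four prior × likelihood cells yield two sensitivity indices:

* prior sensitivity      = mean(w_Pl, w_PL) − mean(w_pl, w_pL)
* likelihood sensitivity = mean(w_pl, w_Pl) − mean(w_pL, w_PL)

both expected positive for an observer that re-weights with reliability.
Estimated slopes are deliberately not clipped to [0, 1]: bounds hold for
the generating weight, not for its noisy estimate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic_data import as_cohort_frame
from .task_model import CONDITIONS

__all__ = [
    "WeightEstimate",
    "SensitivityIndices",
    "estimate_sensory_weight",
    "condition_weights",
    "sensitivity_indices",
    "cohort_weight_table",
]


class DegenerateDesignError(ValueError):
    """Raised when the regression design carries no information (e.g. constant centroids)."""


@dataclass(frozen=True)
class WeightEstimate:
    slope: float
    intercept: float
    n_trials: int
    condition: str = "all"


@dataclass(frozen=True)
class SensitivityIndices:
    prior_sensitivity: float
    likelihood_sensitivity: float


def estimate_sensory_weight(trials: pd.DataFrame, condition: str = "all") -> WeightEstimate:
    """OLS slope/intercept of response_x on centroid_x over the given trials."""
    frame = as_cohort_frame(trials)
    if frame["response_x"].isna().any():
        raise ValueError("trials without responses; simulate or load responses first")
    if len(frame) < 3:
        raise ValueError(f"need >= 3 trials for a weight estimate, got {len(frame)}")
    x = frame["centroid_x"].to_numpy(dtype=float)
    y = frame["response_x"].to_numpy(dtype=float)
    if np.ptp(x) == 0 or np.var(x) == 0:
        raise DegenerateDesignError("centroids are constant; slope is undefined")
    fit = stats.linregress(x, y)
    return WeightEstimate(
        slope=float(fit.slope), intercept=float(fit.intercept), n_trials=len(frame), condition=condition
    )


def condition_weights(session) -> dict[str, WeightEstimate]:
    """Sensory weight separately for each of the four conditions."""
    frame = as_cohort_frame(session)
    cond = frame["prior_level"].astype(str) + frame["likelihood_level"].astype(str)
    missing = [c for c in CONDITIONS if (cond == c).sum() < 3]
    if missing:
        raise ValueError(f"conditions with < 3 trials: {missing}")
    return {c: estimate_sensory_weight(frame[cond == c], condition=c) for c in CONDITIONS}


def sensitivity_indices(weights: dict[str, WeightEstimate]) -> SensitivityIndices:
    """Condition-mean weight differences quantifying uncertainty sensitivity."""
    w = {c: weights[c].slope for c in CONDITIONS}
    return SensitivityIndices(
        prior_sensitivity=(w["Pl"] + w["PL"]) / 2 - (w["pl"] + w["pL"]) / 2,
        likelihood_sensitivity=(w["pl"] + w["Pl"]) / 2 - (w["pL"] + w["PL"]) / 2,
    )


def cohort_weight_table(cohort, first_n: int = 50) -> pd.DataFrame:
    """One row per participant with every derived weight quantity.

    Columns: general weight, the four condition weights, prior/likelihood
    sensitivity, mean hit rate, and the general weight over the first
    ``first_n`` trials in session order (early-learning check).
    """
    frame = as_cohort_frame(cohort)
    rows = []
    for pid, sub in frame.groupby("participant_id", sort=False):
        sub = sub.sort_values("trial")
        try:
            general = estimate_sensory_weight(sub)
            per_cond = condition_weights(sub)
            sens = sensitivity_indices(per_cond)
            early = estimate_sensory_weight(sub.head(first_n))
        except ValueError as err:
            raise ValueError(f"participant {pid!r}: {err}") from err
        hits = sub["hit"].dropna()
        rows.append(
            {
                "participant_id": pid,
                "group": sub["group"].iloc[0],
                "weight_general": general.slope,
                **{f"weight_{c}": per_cond[c].slope for c in CONDITIONS},
                "prior_sensitivity": sens.prior_sensitivity,
                "likelihood_sensitivity": sens.likelihood_sensitivity,
                "hit_rate": float(hits.astype(bool).mean()) if len(hits) else np.nan,
                f"weight_first{first_n}": early.slope,
            }
        )
    return pd.DataFrame(rows)
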