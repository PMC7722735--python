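# bayescoin

Bayesian cue-combination analysis for the "coin in the lake" sensorimotor
estimation task, built for studies that ask whether an experimental
manipulation (for example acute stress) changes how people weight prior
knowledge against current sensory evidence.

## The task and the model

On every trial a coin is thrown into a lake, hidden from view. Its
horizontal position is drawn from a Gaussian **prior** centred on the
screen centre (μ_P = 0.5 in unit screen coordinates) whose standard
deviation is fixed within a block — small (σ_p = 0.025) or large
(σ_P = 0.085). The only evidence is a splash: five dots drawn iid around
the coin with small (σ_l = 0.06) or large (σ_l = 0.15) spread, varying
trial to trial. A session has 4 blocks × 150 trials, with 75 trials of
each dot-spread level per block and feedback (the true coin position)
after every response.

A normative observer combines prior and likelihood by reliability
weighting:

    x_est = (1 − w) μ_P + w μ_L,      w = σ²_P / (σ²_P + σ²_L),

where μ_L is the dot-cloud centroid and σ²_L the effective sensory
variance (the centroid variance σ²_dots / 5 by default). The slope of a
per-participant regression of responses on centroids — the **sensory
weight** — estimates w; 1 − w is the reliance on the prior.

The package provides:

- `task_model` — the combination rule and the imposed task parameters;
- `synthetic_data` — seeded session/cohort simulation with configurable
  observer strategies, group effects, and participant heterogeneity;
- `sensory_weights` — general, condition-wise (pl, pL, Pl, PL) and
  early-trial weights plus prior/likelihood sensitivity indices;
- `observer_models` — ten candidate models: three heuristics (centroid
  only, prior mean only, previous coin), the normative observer with
  imposed / trial-by-trial learned / globally fitted / per-participant
  fitted prior variances, and three variants adding a group (stress)
  dummy on the sensory weight, prior variance, or likelihood variance;
- `model_comparison` — pooled Gaussian likelihoods, BIC/AIC
  (k_eff = k_free + 1 for the residual variance), and odd/even
  cross-validated rMSE with within- and between-group tests;
- `group_stats` — Wilcoxon rank-sum/signed-rank (exact enumeration for
  small samples), Cohen's d, the 2 × 2 × group split-plot ANOVA, a
  two-stage group-effect check, and noncentral-t power analysis.

## Worked example

```python
import bayescoin as bc
from bayescoin.sensory_weights import cohort_weight_table
from bayescoin.group_stats import rank_sum_test
from bayescoin.model_comparison import compare_models

sessions = bc.simulate_cohort(8, 8, bc.ObserverSpec(response_noise_sd=0.05),
                              seed=42, prior_var_sd_log=0.4)
frame = bc.cohort_frame(sessions)
table = cohort_weight_table(frame)
print(table[["participant_id", "group", "weight_general",
             "weight_Pl", "weight_pL", "prior_sensitivity"]].head(3).round(3))
```

```
participant_id   group  weight_general  weight_Pl  weight_pL  prior_sensitivity
           c01 control           0.558      0.928      0.135              0.434
           c02 control           0.447      0.730      0.100              0.195
           c03 control           0.613      0.826      0.046              0.425
```

Weights are highest when the prior is uncertain and the dots are tight
(`Pl`) and lowest in the opposite cell (`pL`), exactly the reliability
ordering the combination rule predicts (0.909 vs 0.122 for a normative
observer). The groups here were generated identically, and the group
comparison correctly finds nothing:

```python
ctrl = table[table.group == "control"]["weight_general"]
strs = table[table.group == "stressed"]["weight_general"]
res = rank_sum_test(ctrl, strs)
# group means 0.610 vs 0.631, W=65, p=0.798

comp = compare_models(frame, seed=0, n_starts=3)
comp.table[["model_id", "name", "k_free", "BIC", "mean_cv_rmse", "best"]]
```

The model table ranks the normative observer with the imposed task
variances best (BIC −30023, cv-rMSE 0.0505 ≈ the generating motor
noise), the heuristics far behind (centroid-only cv-rMSE 0.063,
prior-mean-only 0.074, previous-coin 0.098) — as it should, because
this cohort was generated by near-normative observers.

A thin CLI wraps the same functions:

```sh
bayescoin simulate --seed 7 -o cohort.csv
bayescoin weights cohort.csv -o table.csv
bayescoin compare cohort.csv --models 1-10 -o models.csv
bayescoin power --n1 31 --n2 29 --d 0.5        # -> 0.4775
bayescoin stats table.csv
```

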