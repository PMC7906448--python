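"""Random-intercept mixed-model forecasting of body weight.

Model: weight_it = b0 + bL*length_it + bW*width_it + bH*height_it
                   + a_i + e_it,
with a_i ~ N(0, sigma2_animal) per animal and e_it ~ N(0, sigma2_resid).
Volume is never included as a covariate — it is the product of the other
three and would induce near-collinearity.

Forecasting follows a move-forward time-series cross-validation: fit on
a contiguous 14-day window, predict every animal's weight on a single
later day (horizon 1-4), then slide the window forward one day.  Two
prediction modes:

* LMM1 — fixed effects only (x'beta; random effect set to 0);
* LMM2 — fixed effects plus the animal's predicted intercept (BLUP)
  from the training window.

Accuracy per slide is the squared Pearson correlation between observed
and forecast weights across animals (an alternative 1 - SSE/SST
definition is available), and the mean absolute error in kg.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

from pigmorph.types import CVScenario, ForecastResult, LMMFit

logger = logging.getLogger(__name__)

FIXED_EFFECTS = ["length_px", "width_px", "height_m"]


def fit_random_intercept(train: pd.DataFrame) -> LMMFit:
    """REML fit of the random-intercept model on a training window.

    ``train`` needs columns (pig_id, day, length_px, width_px, height_m,
    weight_kg) with at least two animals observed on at least two days
    each.  Returns the fixed effects, both variance components, and the
    per-animal BLUPs.
    """
    if train["pig_id"].nunique() < 2:
        raise ValueError("need at least 2 animals to separate the variance components")
    counts = train.groupby("pig_id").size()
    if (counts < 2).any():
        raise ValueError("every training animal needs >= 2 observations")
    for col in FIXED_EFFECTS:
        if train[col].nunique() <= 1:
            raise ValueError(f"descriptor {col!r} is constant in the training window")

    model = smf.mixedlm(
        "weight_kg ~ length_px + width_px + height_m", train, groups=train["pig_id"]
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = model.fit(reml=True)
    if not result.converged:
        logger.warning("mixed model did not converge on a %d-row window", len(train))

    beta = np.array(
        [
            result.fe_params["Intercept"],
            result.fe_params["length_px"],
            result.fe_params["width_px"],
            result.fe_params["height_m"],
        ]
    )
    beta_se = np.array(
        [result.bse[k] for k in ("Intercept", "length_px", "width_px", "height_m")]
    )
    sigma2_animal = float(np.squeeze(result.cov_re.values))
    sigma2_resid = float(result.scale)
    effects = {pig: float(np.squeeze(re.values)) for pig, re in result.random_effects.items()}
    keys = set(train[["pig_id", "day"]].itertuples(index=False, name=None))
    return LMMFit(
        beta=beta,
        sigma2_animal=max(0.0, sigma2_animal),
        sigma2_resid=sigma2_resid,
        animal_effects=effects,
        training_keys=keys,
        converged=bool(result.converged),
        beta_se=beta_se,
    )


def predict(fit: LMMFit, test: pd.DataFrame, mode: str = "LMM2") -> np.ndarray:
    """Predict test-row weights (kg).

    LMM1 uses the fixed effects only; LMM2 adds each animal's training
    BLUP.  An animal unseen in training falls back to a zero effect
    under LMM2, with a warning.
    """
    mode = mode.upper()
    if mode not in ("LMM1", "LMM2"):
        raise ValueError(f"mode must be LMM1 or LMM2, got {mode!r}")
    X = test[FIXED_EFFECTS].to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("missing descriptor values in test rows")
    yhat = fit.beta[0] + X @ fit.beta[1:]
    if mode == "LMM2":
        effects = np.empty(len(test))
        for j, pig in enumerate(test["pig_id"]):
            if pig in fit.animal_effects:
                effects[j] = fit.animal_effects[pig]
            else:
                logger.warning("animal %s unseen in training; using zero effect", pig)
                effects[j] = 0.0
        yhat = yhat + effects
    return yhat


def make_scenarios(
    days, window: int = 14, horizons=(1, 2, 3, 4)
) -> list[CVScenario]:
    """Enumerate sliding-window scenarios over the observed days.

    For each horizon h, a slide starting at day s requires the full
    window s..s+window-1 and the test day s+window-1+h to be present.
    """
    days = sorted(set(int(d) for d in days))
    present = set(days)
    scenarios = []
    for h in sorted(set(int(x) for x in horizons)):
        if h < 1:
            raise ValueError("horizons must be >= 1")
        starts = [
            s
            for s in days
            if all(s + k in present for k in range(window)) and (s + window - 1 + h) in present
        ]
        if not starts:
            raise ValueError(
                f"no valid slide for horizon {h}: need {window} consecutive days "
                f"plus the test day within {days[0]}..{days[-1]}"
            )
        scenarios.append(CVScenario(window_days=window, horizon=h, slide_starts=starts))
    return scenarios


def prediction_r2(
    observed, predicted, definition: str = "squared_correlation"
) -> float:
    """Out-of-sample coefficient of determination.

    Default: squared Pearson correlation between observed and forecast
    values (always in [0, 1]).  ``definition="one_minus_sse_sst"`` gives
    the alternative 1 - SSE/SST, which can be negative for poor
    forecasts.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.size < 2:
        raise ValueError("need two equal-length vectors with >= 2 entries")
    if np.ptp(obs) == 0:
        raise ValueError("observed values are constant; R2 undefined")
    if definition == "squared_correlation":
        if np.ptp(pred) == 0:
            return 0.0
        r = np.corrcoef(obs, pred)[0, 1]
        return float(r * r)
    if definition == "one_minus_sse_sst":
        sse = float(np.sum((obs - pred) ** 2))
        sst = float(np.sum((obs - obs.mean()) ** 2))
        return 1.0 - sse / sst
    raise ValueError(f"unknown R2 definition {definition!r}")


def mae(observed, predicted) -> float:
    """Mean absolute error in kg."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.size == 0:
        raise ValueError("need two equal-length nonempty vectors")
    return float(np.mean(np.abs(obs - pred)))


def run_cv(
    table: pd.DataFrame,
    scenarios: list[CVScenario] | None = None,
    modes=("LMM1", "LMM2"),
    r2_definition: str = "squared_correlation",
) -> list[ForecastResult]:
    """Sliding-window cross-validation over all (scenario, mode) pairs.

    For every slide, the model is fit on the window days and every
    animal with a recorded test-day weight is forecast; animals missing
    that day simply shrink the slide's test set.  Slides whose fit fails
    are skipped with a warning.
    """
    if scenarios is None:
        scenarios = make_scenarios(table["day"].unique())
    results = []
    for sc in scenarios:
        fits: dict[int, LMMFit] = {}
        for start in sc.slide_starts:
            window_days = range(start, start + sc.window_days)
            train = table[table["day"].isin(window_days)]
            try:
                fits[start] = fit_random_intercept(train)
            except Exception as exc:  # noqa: BLE001 - per-slide isolation
                logger.warning("slide at day %d skipped: %s", start, exc)
        for mode in modes:
            per_slide = []
            for start in sc.slide_starts:
                fit = fits.get(start)
                if fit is None:
                    continue
                test_day = start + sc.window_days - 1 + sc.horizon
                test = table[table["day"] == test_day].dropna(subset=["weight_kg"])
                if len(test) < 2:
                    logger.warning(
                        "slide at day %d: fewer than 2 test animals on day %d",
                        start,
                        test_day,
                    )
                    continue
                yhat = predict(fit, test, mode=mode)
                obs = test["weight_kg"].to_numpy()
                per_slide.append(
                    (
                        start,
                        prediction_r2(obs, yhat, r2_definition),
                        mae(obs, yhat),
                        len(test),
                    )
                )
            results.append(ForecastResult(model=mode, horizon=sc.horizon, per_slide=per_slide))
    return results


def results_frame(results: list[ForecastResult]) -> pd.DataFrame:
    """Flatten forecast results to one row per (model, horizon, slide)."""
    rows = [
        (r.model, r.horizon, s[0], s[1], s[2], s[3])
        for r in results
        for s in r.per_slide
    ]
    return pd.DataFrame(
        rows, columns=["model", "horizon", "start_day", "r2", "mae_kg", "n_test"]
    )
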