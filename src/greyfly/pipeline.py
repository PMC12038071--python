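"""Forecasting pipeline: metrics, rolling mechanism, tuning, comparison.

The evaluation protocol mirrors standard rolling-origin one-step-ahead
practice for grey models on annual data:

* hyperparameters (background coefficient alpha, power exponent gamma,
  fractional order r) are tuned by the firefly algorithm against the
  in-sample fitted MAPE on the training window;
* over a hold-out block the model is refitted each year on the trailing
  window of observed values and emits a one-step-ahead forecast (the window
  advances by appending the realized actual);
* beyond the data the window advances by appending the model's own
  predictions.

All aggregation is done at full precision; rounding happens only when a
report is rendered.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .firefly import FireflyConfig, OptimizationResult, optimize
from .grey import (
    GAMMA_ONE_TOL,
    GreyHyperparams,
    GreyModelError,
    ModelKind,
    fit_grey_model,
    predict_restored,
)
from .series import AnnualSeries, SeriesSplit

__all__ = [
    "EvaluationReport",
    "RollingConfig",
    "TunedModelSpec",
    "LINEAR_BASELINE",
    "absolute_percentage_error",
    "mean_absolute_percentage_error",
    "training_fit_mape",
    "rolling_forecast",
    "tune_hyperparameters",
    "default_bounds",
    "evaluate_models",
    "forecast_future",
    "linear_trend_baseline",
    "reports_to_table",
]

#: model-kind token for the ordinary-least-squares trend baseline
LINEAR_BASELINE = "LINEAR"


# ---------------------------------------------------------------------------
# error metrics


def absolute_percentage_error(actual: float, fitted: float) -> float:
    """APE in percent: 100 * |fitted - actual| / actual (actual > 0)."""
    if actual <= 0:
        raise ValueError(f"APE needs a positive actual value, got {actual}")
    return 100.0 * abs(fitted - actual) / actual


def mean_absolute_percentage_error(actuals, fitted) -> float:
    """Mean APE in percent, averaged at full precision."""
    a = np.asarray(actuals, dtype=np.float64)
    f = np.asarray(fitted, dtype=np.float64)
    if a.shape != f.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {f.shape}")
    if a.size == 0:
        raise ValueError("MAPE of an empty window is undefined")
    if np.any(a <= 0):
        raise ValueError("MAPE needs strictly positive actuals")
    return float(np.mean(np.abs(f - a) / a) * 100.0)


# ---------------------------------------------------------------------------
# configuration / result containers


@dataclass(frozen=True)
class RollingConfig:
    """Rolling-mechanism settings.

    window_length
        Trailing observations refitted at each origin; ``None`` means the
        full training history at the first origin (and stays fixed). Must
        be >= 4.
    refit_each_step
        If False, fit once at the first origin and extrapolate the single
        model over the whole horizon.
    feed
        What the window absorbs as the origin advances: realized
        ``"actuals"`` (hold-out evaluation) or the model's own
        ``"predictions"`` (future extrapolation).
    """

    window_length: int | None = None
    refit_each_step: bool = True
    feed: str = "actuals"

    def __post_init__(self) -> None:
        if self.window_length is not None and self.window_length < 4:
            raise ValueError("window_length must be >= 4")
        if self.feed not in ("actuals", "predictions"):
            raise ValueError(f"feed must be 'actuals' or 'predictions', got {self.feed!r}")


@dataclass(frozen=True)
class TunedModelSpec:
    """A model family plus the hyperparameters it will be run with."""

    kind: ModelKind | str
    hyper: GreyHyperparams | None = None
    train_mape: float = float("nan")
    label: str | None = None
    tuner: OptimizationResult | None = field(default=None, repr=False, compare=False)

    @property
    def name(self) -> str:
        return self.label if self.label is not None else str(getattr(self.kind, "value", self.kind))


@dataclass(frozen=True)
class EvaluationReport:
    """Per-period APEs and their full-precision mean for one model/window."""

    model_name: str
    window_label: str
    per_period: tuple[tuple[int, float, float, float], ...]  # (year, actual, fitted, ape%)

    @property
    def mape(self) -> float:
        return float(np.mean([row[3] for row in self.per_period]))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.per_period, columns=["year", "actual", "fitted", "ape_pct"]
        )


def _make_report(model_name, window_label, years, actuals, fitted) -> EvaluationReport:
    rows = tuple(
        (int(y), float(a), float(f), absolute_percentage_error(a, f))
        for y, a, f in zip(years, actuals, fitted)
    )
    return EvaluationReport(model_name, window_label, rows)


# ---------------------------------------------------------------------------
# rolling mechanism


def _coerce_kind(kind) -> ModelKind | str:
    if isinstance(kind, str) and kind.upper() == LINEAR_BASELINE:
        return LINEAR_BASELINE
    return ModelKind(kind)


def rolling_forecast(
    history: AnnualSeries,
    spec: TunedModelSpec,
    config: RollingConfig,
    horizon: int,
    future_actuals: AnnualSeries | None = None,
) -> np.ndarray:
    """One-step-ahead forecasts for ``horizon`` periods beyond ``history``.

    At each origin the model is refitted (fixed hyperparameters) on the
    trailing ``window_length`` observations of the current history and the
    restored prediction at k = window_length + 1 is emitted. The history then
    grows by the realized actual (``feed="actuals"``, requires
    ``future_actuals``) or by the prediction itself. Fully deterministic.
    """
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    kind = _coerce_kind(spec.kind)
    if kind == LINEAR_BASELINE:
        years = history.years[-1] + history.step * np.arange(1, horizon + 1)
        return linear_trend_baseline(history, years)
    length = config.window_length or history.n
    if length > history.n:
        raise ValueError(
            f"window_length {length} exceeds available history n={history.n}"
        )
    if config.feed == "actuals":
        if future_actuals is None or future_actuals.n < horizon:
            raise ValueError(
                "feed='actuals' needs future_actuals covering the horizon"
            )
    hyper = spec.hyper or GreyHyperparams()

    values = list(history.values)
    preds = np.empty(horizon)
    if not config.refit_each_step:
        model = fit_grey_model(np.array(values[-length:]), kind, hyper)
        preds[:] = predict_restored(model, length + np.arange(1, horizon + 1))
        return preds
    for step in range(horizon):
        window = np.array(values[-length:])
        model = fit_grey_model(window, kind, hyper)
        preds[step] = predict_restored(model, [length + 1])[0]
        if config.feed == "actuals":
            values.append(float(future_actuals.values[step]))
        else:
            values.append(float(preds[step]))
    return preds


# ---------------------------------------------------------------------------
# hyperparameter tuning


def default_bounds(kind) -> tuple[tuple[float, float], ...]:
    """Search box per model family: alpha in [0,1]; gamma in [-2,2] (the
    degenerate gamma = 1 handled by rejection); r in (0, 1]."""
    kind = ModelKind(kind)
    if kind == ModelKind.GM:
        return ((0.0, 1.0),)
    if kind == ModelKind.NGBM:
        return ((0.0, 1.0), (-2.0, 2.0))
    return ((0.0, 1.0), (1e-6, 1.0))  # FGM


def _hyper_from_vector(kind: ModelKind, x) -> GreyHyperparams:
    if kind == ModelKind.GM:
        return GreyHyperparams(alpha_bg=float(x[0]))
    if kind == ModelKind.NGBM:
        return GreyHyperparams(alpha_bg=float(x[0]), gamma_power=float(x[1]))
    return GreyHyperparams(alpha_bg=float(x[0]), frac_order=float(x[1]))


def _classical_default_vector(kind: ModelKind) -> np.ndarray:
    # the untuned textbook settings: midpoint background, GM exponent/order
    if kind == ModelKind.GM:
        return np.array([0.5])
    if kind == ModelKind.NGBM:
        return np.array([0.5, 0.0])
    return np.array([0.5, 1.0])  # FGM


def training_fit_mape(train: AnnualSeries, kind, hyper: GreyHyperparams) -> float:
    """In-sample fitted MAPE over k = 2..n of the training window (percent).

    This is the tuning fitness: fit once on the whole window, restore the
    fitted values, and average the APEs of the non-initial points (the k = 1
    fitted value reproduces the data exactly by construction).
    """
    kind = ModelKind(kind)
    model = fit_grey_model(train, kind, hyper)
    fitted = predict_restored(model, np.arange(2, train.n + 1))
    return mean_absolute_percentage_error(train.values[1:], fitted)


def tune_hyperparameters(
    train: AnnualSeries,
    kind,
    fa_config: FireflyConfig | None = None,
    rolling: RollingConfig | None = None,
    bounds: tuple[tuple[float, float], ...] | None = None,
    seed: int = 0,
) -> TunedModelSpec:
    """Firefly search for the hyperparameters minimizing the training fitness.

    Decision variables: GM -> alpha; NGBM -> (alpha, gamma); FGM -> (alpha, r).
    Candidates where the fit fails (degenerate gamma, singular system, domain
    error) score +inf and are thereby rejected. The swarm is warm-started
    with the classical default (alpha = 0.5, gamma = 0 / r = 1), so by
    elitism the tuned fitness never exceeds the untuned one. ``rolling`` is
    accepted for signature symmetry with the evaluation stage but the fitness
    is the single-fit in-sample MAPE.
    """
    kind = ModelKind(kind)
    if train.n < 4:
        raise GreyModelError(f"tuning needs a training window of n >= 4, got {train.n}")
    box = bounds or default_bounds(kind)
    if fa_config is None:
        fa_config = FireflyConfig(bounds=box, seed=seed)
    elif fa_config.bounds != tuple((float(a), float(b)) for a, b in box):
        fa_config = replace(fa_config, bounds=box)

    def fitness(x) -> float:
        if kind == ModelKind.NGBM and abs(float(x[1]) - 1.0) <= GAMMA_ONE_TOL:
            return math.inf
        try:
            hyper = _hyper_from_vector(kind, x)
            return training_fit_mape(train, kind, hyper)
        except GreyModelError:
            return math.inf

    result = optimize(
        fitness, fa_config, initial_positions=[_classical_default_vector(kind)]
    )
    hyper = _hyper_from_vector(kind, result.best_position)
    return TunedModelSpec(
        kind=kind,
        hyper=hyper,
        train_mape=result.best_value,
        label=f"FA-{kind.value}",
        tuner=result,
    )


# ---------------------------------------------------------------------------
# model comparison and extrapolation


def linear_trend_baseline(train: AnnualSeries, predict_years) -> np.ndarray:
    """OLS of value on time index, fitted on the training window only.

    Extrapolated values advance by a constant slope per year step.
    """
    if train.n < 2:
        raise ValueError("linear baseline needs at least 2 training points")
    idx = (train.years - train.years[0]) / train.step
    exog = sm.add_constant(idx.astype(float))
    fit = sm.OLS(train.values, exog).fit()
    years = np.asarray(predict_years, dtype=np.float64)
    new_idx = (years - train.years[0]) / train.step
    return np.asarray(fit.predict(sm.add_constant(new_idx, has_constant="add")))


def evaluate_models(
    split: SeriesSplit,
    specs: list[TunedModelSpec],
    rolling: RollingConfig | None = None,
) -> list[EvaluationReport]:
    """Score each model on the split's test and validation blocks.

    Grey models roll one step ahead with actuals fed back (refit each year on
    the trailing window); the linear baseline is fitted once on the training
    block and extrapolated. Returns one report per model per non-empty
    hold-out window.
    """
    if split.train is None:
        raise ValueError("split has no training part")
    rolling = rolling or RollingConfig(window_length=split.train.n, feed="actuals")
    if rolling.feed != "actuals":
        raise ValueError("hold-out evaluation requires feed='actuals'")
    reports: list[EvaluationReport] = []
    windows: list[tuple[str, AnnualSeries, AnnualSeries]] = []
    if split.test is not None:
        windows.append(("test", split.train, split.test))
    if split.validation is not None:
        hist = split.train if split.test is None else split.train.concat(split.test)
        windows.append(("validation", hist, split.validation))
    for spec in specs:
        for label, history, block in windows:
            kind = _coerce_kind(spec.kind)
            if kind == LINEAR_BASELINE:
                fitted = linear_trend_baseline(split.train, block.years)
            else:
                fitted = rolling_forecast(
                    history, spec, rolling, horizon=block.n, future_actuals=block
                )
            reports.append(
                _make_report(spec.name, label, block.years, block.values, fitted)
            )
    return reports


def forecast_future(
    series: AnnualSeries,
    spec: TunedModelSpec,
    rolling: RollingConfig | None = None,
    horizon: int = 3,
) -> list[tuple[int, float]]:
    """Extrapolate ``horizon`` periods beyond the observed series.

    The window advances on the model's own predictions; years continue the
    input spacing.
    """
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    rolling = rolling or RollingConfig()
    rolling = replace(rolling, feed="predictions")
    preds = rolling_forecast(series, spec, rolling, horizon=horizon)
    years = series.years[-1] + series.step * np.arange(1, horizon + 1)
    return [(int(y), float(v)) for y, v in zip(years, preds)]


# ---------------------------------------------------------------------------
# report rendering


def reports_to_table(reports: list[EvaluationReport], window_label: str) -> pd.DataFrame:
    """Wide comparison table for one window: year, actual, then one
    fitted/error(%) column pair per model, with a final MAPE(%) footer row."""
    subset = [r for r in reports if r.window_label == window_label]
    if not subset:
        raise ValueError(f"no reports for window {window_label!r}")
    base = subset[0].to_frame()[["year", "actual"]]
    out = base.copy()
    for rep in subset:
        frame = rep.to_frame()
        out[f"{rep.model_name}_fitted"] = frame["fitted"].round(2)
        out[f"{rep.model_name}_error_pct"] = frame["ape_pct"].round(2)
    footer = {"year": f"MAPE(%) {window_label}", "actual": np.nan}
    for rep in subset:
        footer[f"{rep.model_name}_fitted"] = np.nan
        footer[f"{rep.model_name}_error_pct"] = round(rep.mape, 2)
    out = pd.concat([out, pd.DataFrame([footer])], ignore_index=True)
    return out
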