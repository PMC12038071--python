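"""Grey-model core: accumulation operators, least squares, time response.

Implements the family of first-order single-variable grey models on a raw
positive sequence x(0)(1..n):

* **GM(1,1)** — classical grey model. The 1-AGO (cumulative sum) series
  y(1) is assumed to follow dy/dt + b1*y = b2.
* **NGBM(1,1)** — nonlinear grey Bernoulli model. The accumulated series
  follows the Bernoulli ODE dy/dt + b1*y = b2*y**g with power exponent
  g != 1; g = 0 recovers GM(1,1) exactly.
* **FGM(1,1)** — fractional grey model: GM(1,1) fitted after r-order
  fractional accumulation (0 < r <= 1); r = 1 recovers GM(1,1).

Both coefficients are estimated by least squares on the discretized grey
differential equation, with the background value z(k) a convex combination
of consecutive accumulated values controlled by ``alpha_bg`` (0.5 is the
classical midpoint rule).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np

__all__ = [
    "ModelKind",
    "AccumulatedSeries",
    "GreyHyperparams",
    "GreyCoefficients",
    "LsqSystem",
    "FittedGreyModel",
    "GreyModelError",
    "GreyDomainError",
    "ago",
    "iago",
    "fractional_ago",
    "fractional_iago",
    "background_sequence",
    "build_lsq_system",
    "estimate_coefficients",
    "time_response",
    "fit_grey_model",
    "predict_restored",
]

GAMMA_ONE_TOL = 1e-6  # exclusion band around the degenerate exponent g = 1
COND_LIMIT = 1e12  # normal-matrix condition number treated as singular


class GreyModelError(ValueError):
    """Invalid input or configuration for a grey-model operation."""


class GreyDomainError(GreyModelError):
    """A real-valued power would have a negative base (complex result)."""


class ModelKind(str, Enum):
    GM = "GM"
    NGBM = "NGBM"
    FGM = "FGM"


@dataclass(frozen=True)
class AccumulatedSeries:
    """An r-order accumulated sequence (order 1 = classical cumulative sum)."""

    values: np.ndarray
    order: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=np.float64))

    @property
    def n(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class GreyHyperparams:
    """Tunable grey-model hyperparameters.

    alpha_bg
        Background-value mixing coefficient in [0, 1]; z(k) =
        alpha_bg*y(k) + (1-alpha_bg)*y(k-1). 0.5 is the classical rule.
    gamma_power
        Bernoulli power exponent (NGBM only); must stay outside a 1e-6
        band around 1, where the ODE degenerates. 0 reduces to GM(1,1).
    frac_order
        Fractional accumulation order r in (0, 1] (FGM only); 1 reduces
        to the classical AGO.
    """

    alpha_bg: float = 0.5
    gamma_power: float = 0.0
    frac_order: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha_bg <= 1.0:
            raise GreyModelError(f"alpha_bg={self.alpha_bg} outside [0, 1]")
        if abs(self.gamma_power - 1.0) <= GAMMA_ONE_TOL:
            raise GreyModelError(
                f"gamma_power={self.gamma_power} within {GAMMA_ONE_TOL} of the "
                "degenerate value 1"
            )
        if not 0.0 < self.frac_order <= 1.0:
            raise GreyModelError(f"frac_order={self.frac_order} outside (0, 1]")


@dataclass(frozen=True)
class GreyCoefficients:
    """Least-squares coefficients of the grey differential equation.

    beta1 is the development coefficient, beta2 the grey input; c_const is
    the integration constant of the whitening ODE solution (NaN until the
    initial condition is known).
    """

    beta1: float
    beta2: float
    c_const: float = float("nan")


@dataclass(frozen=True)
class LsqSystem:
    """Stacked discrete grey equations Y = Z beta for k = 2..n."""

    y_vec: np.ndarray  # grey derivatives, raw[k], k = 2..n
    z_mat: np.ndarray  # rows (-z(k), z(k)**gamma)
    z_bg: np.ndarray = field(repr=False, default=None)  # background values z(k)
    gamma_power: float = 0.0

    @property
    def n_rows(self) -> int:
        return len(self.y_vec)


@dataclass(frozen=True)
class FittedGreyModel:
    """A grey model fitted on one window; prediction is index-based (k >= 1)."""

    kind: ModelKind
    hyper: GreyHyperparams
    coeffs: GreyCoefficients
    initial_value: float
    window_length: int


# ---------------------------------------------------------------------------
# accumulation operators


def ago(series) -> AccumulatedSeries:
    """First-order accumulated generating operation (cumulative sum)."""
    x = np.asarray(series, dtype=np.float64)
    if len(x) == 0:
        raise GreyModelError("cannot accumulate an empty series")
    return AccumulatedSeries(np.cumsum(x), order=1.0)


def iago(accumulated) -> np.ndarray:
    """Inverse AGO: first differences keeping the first entry."""
    y = _acc_values(accumulated, expect_order=1.0)
    return np.diff(y, prepend=0.0)


def _frac_weights(order: float, m: int) -> np.ndarray:
    # generalized binomial weights w_j = C(j + order - 1, j) via the stable
    # recurrence w_j = w_{j-1} * (j - 1 + order) / j; valid for any real order
    w = np.empty(m)
    w[0] = 1.0
    for j in range(1, m):
        w[j] = w[j - 1] * (j - 1 + order) / j
    return w


def fractional_ago(series, r: float) -> AccumulatedSeries:
    """r-order fractional accumulation, x(r)(k) = sum_i C(k-i+r-1, k-i) x(0)(i).

    r = 1 reduces exactly to :func:`ago`.
    """
    if not 0.0 < r <= 1.0:
        raise GreyModelError(f"fractional order r={r} outside (0, 1]")
    x = np.asarray(series, dtype=np.float64)
    if len(x) == 0:
        raise GreyModelError("cannot accumulate an empty series")
    w = _frac_weights(r, len(x))
    return AccumulatedSeries(np.convolve(x, w)[: len(x)], order=float(r))


def fractional_iago(accumulated, r: float) -> np.ndarray:
    """Inverse of r-order accumulation, implemented as (-r)-order accumulation.

    Exact inverse up to floating point: the weight sequences of orders r and
    -r are convolution inverses of each other.
    """
    if not 0.0 < r <= 1.0:
        raise GreyModelError(f"fractional order r={r} outside (0, 1]")
    y = _acc_values(accumulated)
    w = _frac_weights(-r, len(y))
    return np.convolve(y, w)[: len(y)]


def _acc_values(accumulated, expect_order: float | None = None) -> np.ndarray:
    if isinstance(accumulated, AccumulatedSeries):
        if expect_order is not None and accumulated.order != expect_order:
            raise GreyModelError(
                f"expected accumulation order {expect_order}, got {accumulated.order}"
            )
        return accumulated.values
    return np.asarray(accumulated, dtype=np.float64)


# ---------------------------------------------------------------------------
# least-squares estimation


def background_sequence(accumulated, alpha_bg: float) -> np.ndarray:
    """Background values z(k) = a*y(k) + (1-a)*y(k-1), k = 2..n.

    ``alpha_bg`` = 0.5 is the classical midpoint background; 0 and 1 pick the
    trailing and leading accumulated value respectively.
    """
    if not 0.0 <= alpha_bg <= 1.0:
        raise GreyModelError(f"alpha_bg={alpha_bg} outside [0, 1]")
    y = _acc_values(accumulated)
    if len(y) < 2:
        raise GreyModelError("background sequence needs n >= 2")
    return alpha_bg * y[1:] + (1.0 - alpha_bg) * y[:-1]


def build_lsq_system(raw, z_bg, gamma_power: float) -> LsqSystem:
    """Stack the discrete grey equations into matrix form Y = Z beta.

    Row k-1 reads x(0)(k) = -b1*z(k)*(-1 sign folded into Z) + b2*z(k)**g.
    With g = 0 the second column is all ones (the GM(1,1) design).
    """
    x = np.asarray(raw, dtype=np.float64)
    z = np.asarray(z_bg, dtype=np.float64)
    if len(z) != len(x) - 1:
        raise GreyModelError(
            f"background length {len(z)} != n-1 = {len(x) - 1}"
        )
    if gamma_power != int(gamma_power) and np.any(z <= 0):
        bad = int(np.flatnonzero(z <= 0)[0]) + 2  # z index starts at k=2
        raise GreyDomainError(
            f"background value z({bad}) <= 0 with non-integer exponent "
            f"{gamma_power}: real power undefined"
        )
    z_mat = np.column_stack([-z, np.power(z, gamma_power)])
    return LsqSystem(y_vec=x[1:], z_mat=z_mat, z_bg=z, gamma_power=gamma_power)


def estimate_coefficients(system: LsqSystem, method: str = "closed_form") -> GreyCoefficients:
    """Least-squares solution of Y = Z beta.

    Two algebraically equivalent routes are exposed and cross-checked in the
    test suite: ``closed_form`` evaluates the explicit 2x2 normal-equation
    ratios in terms of the background values, ``lstsq`` solves the stacked
    system with :func:`numpy.linalg.lstsq`.
    """
    if system.n_rows < 2:
        raise GreyModelError("need at least 2 equations (window n >= 3)")
    ztz = system.z_mat.T @ system.z_mat
    if np.linalg.cond(ztz) > COND_LIMIT:
        raise GreyModelError(
            f"normal matrix condition number {np.linalg.cond(ztz):.2e} exceeds "
            f"{COND_LIMIT:.0e}; the window cannot identify (beta1, beta2)"
        )
    if method == "lstsq":
        beta, *_ = np.linalg.lstsq(system.z_mat, system.y_vec, rcond=None)
        return GreyCoefficients(beta1=float(beta[0]), beta2=float(beta[1]))
    if method != "closed_form":
        raise GreyModelError(f"unknown method {method!r}")
    z = system.z_bg
    y = system.y_vec
    g = system.gamma_power
    zg = np.power(z, g)
    s_zg1 = float(np.sum(z * zg))  # sum z**(g+1)
    s_z2g = float(np.sum(zg * zg))  # sum z**(2g)
    s_z2 = float(np.sum(z * z))
    s_yzg = float(np.sum(y * zg))
    s_yz = float(np.sum(y * z))
    den = s_z2g * s_z2 - s_zg1**2
    beta1 = (s_zg1 * s_yzg - s_z2g * s_yz) / den
    beta2 = (s_z2 * s_yzg - s_zg1 * s_yz) / den
    return GreyCoefficients(beta1=beta1, beta2=beta2)


# ---------------------------------------------------------------------------
# time response


def _integration_constant(y1: float, beta1: float, beta2: float, g: float) -> float:
    # C such that y(1)(t) = [C exp(-(1-g) b1 t) + b2/b1]**(1/(1-g)) passes
    # through y(1)(1) = y1 at t = 1
    return (y1 ** (1.0 - g) - beta2 / beta1) * np.exp((1.0 - g) * beta1)


def time_response(model: FittedGreyModel, k) -> np.ndarray | float:
    """Accumulated-domain prediction yhat(1)(k) from the whitening-ODE solution.

    yhat(1)(k) = {[y(1)**(1-g) - b2/b1] exp(-(1-g) b1 (k-1)) + b2/b1}**(1/(1-g))

    k = 1 returns the window's initial value exactly. For GM (g = 0) this is
    the familiar (y1 - b2/b1) exp(-b1 (k-1)) + b2/b1.
    """
    karr = np.atleast_1d(np.asarray(k, dtype=np.float64))
    if np.any(karr < 1):
        raise GreyModelError(f"prediction index k must be >= 1, got {k}")
    b1, b2 = model.coeffs.beta1, model.coeffs.beta2
    if b1 == 0.0:
        raise GreyModelError("beta1 = 0: degenerate whitening ODE")
    g = model.hyper.gamma_power
    y1 = model.initial_value
    omg = 1.0 - g
    base = (y1**omg - b2 / b1) * np.exp(-omg * b1 * (karr - 1.0)) + b2 / b1
    expo = 1.0 / omg
    if expo != int(expo) and np.any(base <= 0):
        bad = karr[base <= 0][0]
        raise GreyDomainError(
            f"time response undefined at k={bad:g}: bracket {base[base <= 0][0]:.4g}"
            f" <= 0 under fractional exponent 1/(1-gamma)={expo:.4g}"
        )
    out = np.power(base, expo)
    return out if np.ndim(k) else float(out[0])


def _coerce_hyper(kind: ModelKind, hyper: GreyHyperparams) -> GreyHyperparams:
    # each model family pins the hyperparameters it does not use
    if kind == ModelKind.GM:
        return replace(hyper, gamma_power=0.0, frac_order=1.0)
    if kind == ModelKind.NGBM:
        return replace(hyper, frac_order=1.0)
    return replace(hyper, gamma_power=0.0)  # FGM


def fit_grey_model(window, kind: ModelKind | str, hyper: GreyHyperparams) -> FittedGreyModel:
    """Fit a grey model on one window of at least 4 observations.

    ``window`` is an :class:`~greyfly.series.AnnualSeries` or a plain positive
    array. GM pins gamma_power = 0 and r = 1; NGBM pins r = 1; FGM pins
    gamma_power = 0 and fits GM(1,1) machinery on the r-order accumulated
    series. Deterministic: identical window and hyperparameters give
    identical coefficients.
    """
    kind = ModelKind(kind)
    values = np.asarray(getattr(window, "values", window), dtype=np.float64)
    if len(values) < 4:
        raise GreyModelError(
            f"grey models need a fitting window of n >= 4, got {len(values)}"
        )
    if np.any(values <= 0):
        raise GreyModelError("fitting window must be strictly positive")
    hyper = _coerce_hyper(kind, hyper)
    if kind == ModelKind.FGM:
        acc = fractional_ago(values, hyper.frac_order)
        raw_fit = iago(AccumulatedSeries(acc.values, order=1.0))
    else:
        acc = ago(values)
        raw_fit = values
    z = background_sequence(acc, hyper.alpha_bg)
    system = build_lsq_system(raw_fit, z, hyper.gamma_power)
    coeffs = estimate_coefficients(system)
    y1 = float(raw_fit[0])  # equals values[0] for every kind
    c_const = _integration_constant(
        y1, coeffs.beta1, coeffs.beta2, hyper.gamma_power
    )
    return FittedGreyModel(
        kind=kind,
        hyper=hyper,
        coeffs=GreyCoefficients(coeffs.beta1, coeffs.beta2, c_const=float(c_const)),
        initial_value=y1,
        window_length=len(values),
    )


def predict_restored(model: FittedGreyModel, k_range) -> np.ndarray:
    """Raw-scale predictions xhat(0)(k) for the requested 1-based indices.

    The time response is evaluated on 1..max(k), differenced back to the raw
    scale (fractionally for FGM), and indexed. xhat(0)(1) reproduces the
    window's first raw value exactly.
    """
    ks = np.atleast_1d(np.asarray(k_range, dtype=np.int64))
    if np.any(ks < 1):
        raise GreyModelError(f"prediction indices must be >= 1, got {k_range}")
    kmax = int(ks.max())
    yhat = np.atleast_1d(time_response(model, np.arange(1, kmax + 1)))
    if model.kind == ModelKind.FGM and model.hyper.frac_order != 1.0:
        # yhat is the r-order accumulated prediction; undo the r-AGO directly
        restored = fractional_iago(
            AccumulatedSeries(yhat, order=model.hyper.frac_order),
            model.hyper.frac_order,
        )
    else:
        restored = np.diff(yhat, prepend=0.0)
    return restored[ks - 1]
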