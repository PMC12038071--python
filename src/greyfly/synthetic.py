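"""Synthetic data: grey-model-consistent series and optimizer benchmarks.

The generator runs a grey time-response function forward from chosen
coefficients and restores it to the raw scale, producing the near-exponential
positive trajectories grey models are designed for (annual waste tonnage,
energy consumption and the like). Optional noise is multiplicative
log-normal — each value is scaled by exp(eps), eps ~ N(0, noise_sd) — which
preserves the strict positivity the grey machinery requires. noise_sd = 0
yields an exact model trajectory, so refitting at the true hyperparameters
must reproduce it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grey import (
    FittedGreyModel,
    GreyCoefficients,
    GreyHyperparams,
    ModelKind,
    _integration_constant,
    predict_restored,
)
from .series import AnnualSeries

__all__ = ["GeneratorSpec", "generate_grey_series", "benchmark_objective"]

DEFAULT_N = 12  # a typical annual training-window length
DEFAULT_START_YEAR = 2004


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters of a synthetic grey trajectory.

    A negative ``beta1`` gives a growing series; ``gamma_power`` bends the
    trajectory away from the pure exponential (0 = GM). ``noise_sd`` is the
    standard deviation of the multiplicative log-noise (relative scale).
    """

    kind: ModelKind | str = ModelKind.NGBM
    beta1: float = -0.08
    beta2: float = 1.0
    gamma_power: float = 0.0
    initial_value: float = 1.0
    n: int = DEFAULT_N
    noise_sd: float = 0.0
    seed: int = 0
    start_year: int = DEFAULT_START_YEAR

    def __post_init__(self) -> None:
        object.__setattr__(self, "kind", ModelKind(self.kind))
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.initial_value <= 0:
            raise ValueError("initial_value must be > 0")


def generate_grey_series(spec: GeneratorSpec) -> AnnualSeries:
    """Run the grey time response forward and restore to the raw scale.

    Raises if the chosen coefficients produce non-positive or non-finite
    restored values (the trajectory would leave the grey-model domain).
    Deterministic for a fixed seed.
    """
    gamma = spec.gamma_power if spec.kind == ModelKind.NGBM else 0.0
    hyper = GreyHyperparams(alpha_bg=0.5, gamma_power=gamma)
    c = _integration_constant(spec.initial_value, spec.beta1, spec.beta2, gamma)
    model = FittedGreyModel(
        kind=spec.kind,
        hyper=hyper,
        coeffs=GreyCoefficients(spec.beta1, spec.beta2, c_const=float(c)),
        initial_value=spec.initial_value,
        window_length=spec.n,
    )
    values = predict_restored(model, np.arange(1, spec.n + 1))
    if not np.all(np.isfinite(values)) or np.any(values <= 0):
        raise ValueError(
            f"generator parameters {spec} produce non-positive or non-finite "
            "values; choose beta1 < 0 (growth) or a shorter n"
        )
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        values = values * np.exp(rng.normal(0.0, spec.noise_sd, spec.n))
    years = spec.start_year + np.arange(spec.n)
    return AnnualSeries(years, values)


def benchmark_objective(name: str, d: int):
    """Standard analytic test function with its known optimum.

    Returns ``(objective, optimum_position, optimum_value)`` for ``sphere``
    (sum of squares, minimum 0 at the origin) or ``rosenbrock`` (minimum 0
    at the all-ones point).
    """
    if d < 1:
        raise ValueError("dimension must be >= 1")
    if name == "sphere":

        def sphere(x):
            x = np.asarray(x, dtype=np.float64)
            return float(np.sum(x * x))

        return sphere, np.zeros(d), 0.0
    if name == "rosenbrock":
        if d < 2:
            raise ValueError("rosenbrock needs d >= 2")

        def rosenbrock(x):
            x = np.asarray(x, dtype=np.float64)
            return float(
                np.sum(100.0 * (x[1:] - x[:-1] ** 2) ** 2 + (1.0 - x[:-1]) ** 2)
            )

        return rosenbrock, np.ones(d), 0.0
    raise ValueError(f"unknown benchmark objective {name!r}")
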