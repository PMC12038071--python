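"""Univariate annual series: container, CSV I/O, chronological splitting, fixtures.

Grey models operate on short, strictly positive, equally spaced sequences.
:class:`AnnualSeries` enforces positivity and even spacing at construction;
the minimum length for *fitting* (n >= 4) is enforced where fitting happens,
so that short hold-out blocks (e.g. a 3-year validation window) remain
representable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AnnualSeries",
    "SeriesSplit",
    "SeriesError",
    "read_series_csv",
    "write_series_csv",
    "split_series",
    "istanbul_fixture",
    "istanbul_reported_fits",
]

#: Minimum window length a grey model can be fitted on.
MIN_FIT_LENGTH = 4


class SeriesError(ValueError):
    """Raised when a series violates the container invariants."""


@dataclass(frozen=True)
class AnnualSeries:
    """An ordered, strictly positive, equally spaced univariate series.

    Parameters
    ----------
    years
        Strictly increasing integers with a constant step (calendar years or
        abstract indices). Years are metadata only: all model mathematics is
        index-based (k = 1..n).
    values
        Strictly positive observations (e.g. tonnes of waste per year).
    """

    years: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        years = np.asarray(self.years, dtype=np.int64)
        values = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "years", years)
        object.__setattr__(self, "values", values)
        if years.ndim != 1 or values.ndim != 1:
            raise SeriesError("years and values must be one-dimensional")
        if len(years) != len(values):
            raise SeriesError(
                f"length mismatch: {len(years)} years vs {len(values)} values"
            )
        if len(years) == 0:
            raise SeriesError("series is empty")
        if not np.all(np.isfinite(values)):
            bad = int(np.flatnonzero(~np.isfinite(values))[0])
            raise SeriesError(f"non-finite value at position {bad + 1}")
        if np.any(values <= 0):
            bad = int(np.flatnonzero(values <= 0)[0])
            raise SeriesError(
                f"non-positive value {values[bad]} at year {years[bad]} "
                f"(row {bad + 1}); grey models require strictly positive data"
            )
        if len(years) > 1:
            steps = np.diff(years)
            if np.any(steps <= 0):
                bad = int(np.flatnonzero(steps <= 0)[0])
                raise SeriesError(
                    f"years not strictly increasing at row {bad + 2} "
                    f"({years[bad]} -> {years[bad + 1]})"
                )
            if len(set(steps.tolist())) > 1:
                raise SeriesError(
                    f"unevenly spaced years: steps {sorted(set(steps.tolist()))}"
                )

    @property
    def n(self) -> int:
        return len(self.values)

    @property
    def step(self) -> int:
        """Spacing between consecutive years (1 for a length-1 series)."""
        return int(self.years[1] - self.years[0]) if self.n > 1 else 1

    def slice(self, start: int, stop: int) -> "AnnualSeries":
        """Contiguous positional sub-series (start inclusive, stop exclusive)."""
        if not (0 <= start < stop <= self.n):
            raise SeriesError(f"invalid slice [{start}:{stop}] of n={self.n}")
        return AnnualSeries(self.years[start:stop], self.values[start:stop])

    def tail(self, length: int) -> "AnnualSeries":
        return self.slice(self.n - length, self.n)

    def concat(self, other: "AnnualSeries") -> "AnnualSeries":
        return AnnualSeries(
            np.concatenate([self.years, other.years]),
            np.concatenate([self.values, other.values]),
        )

    def value_at(self, year: int) -> float:
        idx = np.flatnonzero(self.years == year)
        if len(idx) == 0:
            raise SeriesError(f"year {year} not in series")
        return float(self.values[idx[0]])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"year": self.years, "value": self.values})


@dataclass(frozen=True)
class SeriesSplit:
    """Contiguous chronological train/test/validation partition."""

    train: AnnualSeries | None
    test: AnnualSeries | None
    validation: AnnualSeries | None
    fractions: tuple[float, float, float] = field(default=(0.6, 0.25, 0.15))

    @property
    def parts(self) -> tuple[AnnualSeries | None, ...]:
        return (self.train, self.test, self.validation)


def read_series_csv(
    path, year_col: str = "year", value_col: str = "value"
) -> AnnualSeries:
    """Read a two-column ``year,value`` CSV into a validated :class:`AnnualSeries`.

    The file must have a header row, comma separators, decimal points and at
    least :data:`MIN_FIT_LENGTH` rows. Rows are sorted by year before
    validation, so file order does not matter.
    """
    try:
        frame = pd.read_csv(path)
    except FileNotFoundError:
        raise SeriesError(f"input file not found: {path}") from None
    for col in (year_col, value_col):
        if col not in frame.columns:
            raise SeriesError(
                f"missing column {col!r} in {path} (found {list(frame.columns)})"
            )
    years = pd.to_numeric(frame[year_col], errors="coerce")
    values = pd.to_numeric(frame[value_col], errors="coerce")
    for name, col in ((year_col, years), (value_col, values)):
        if col.isna().any():
            row = int(col.index[col.isna()][0]) + 2  # 1-based + header line
            raise SeriesError(f"non-numeric {name!r} cell at line {row} of {path}")
    if len(frame) < MIN_FIT_LENGTH:
        raise SeriesError(
            f"{path} has {len(frame)} rows; at least {MIN_FIT_LENGTH} observations "
            "are required"
        )
    order = np.argsort(years.to_numpy())
    y = years.to_numpy()[order]
    if np.any(np.diff(y) == 0):
        dup = int(y[np.flatnonzero(np.diff(y) == 0)[0]])
        raise SeriesError(f"duplicate year {dup} in {path}")
    return AnnualSeries(y, values.to_numpy()[order])


def write_series_csv(series: AnnualSeries, path) -> None:
    """Write the standard ``year,value`` CSV (full float precision)."""
    series.to_frame().to_csv(path, index=False)


def split_series(
    series: AnnualSeries,
    fractions: tuple[float, float, float] = (0.6, 0.25, 0.15),
) -> SeriesSplit:
    """Partition a series chronologically into train/test/validation blocks.

    Sizes are ``round(f1*n)``, ``round(f2*n)`` (half-up) and the remainder,
    which reproduces a 12/5/3 split of 20 annual observations under the
    conventional 60/25/15 scheme. The three parts concatenate back to the
    input exactly.
    """
    f = tuple(float(x) for x in fractions)
    if len(f) != 3:
        raise SeriesError(f"expected 3 fractions, got {len(f)}")
    if any(x < 0 for x in f):
        raise SeriesError(f"negative fraction in {f}")
    if abs(sum(f) - 1.0) > 1e-9:
        raise SeriesError(f"fractions {f} sum to {sum(f)!r}, not 1")
    n = series.n
    n_train = int(np.floor(f[0] * n + 0.5))
    n_test = int(np.floor(f[1] * n + 0.5))
    n_test = min(n_test, n - n_train)
    n_val = n - n_train - n_test
    if 0 < n_train < MIN_FIT_LENGTH:
        warnings.warn(
            f"training part has n={n_train} < {MIN_FIT_LENGTH}; grey models "
            "cannot be fitted on it",
            stacklevel=2,
        )
    bounds = np.cumsum([0, n_train, n_test, n_val])
    parts = [
        series.slice(int(a), int(b)) if b > a else None
        for a, b in zip(bounds[:-1], bounds[1:])
    ]
    return SeriesSplit(parts[0], parts[1], parts[2], fractions=f)


# Istanbul medical waste, tonnes per year. The 2004-2015 history was published
# only as a figure; the printed record starts in 2016, so that is what ships.
_ISTANBUL_YEARS = (2016, 2017, 2018, 2019, 2020, 2021, 2022, 2023)
_ISTANBUL_TONNES = (
    24712.81,
    27068.74,
    28171.81,
    29065.25,
    32143.85,
    34565.10,
    36322.21,
    37648.01,
)


def istanbul_fixture() -> AnnualSeries:
    """The printed Istanbul medical-waste record, 2016-2023 (tonnes)."""
    return AnnualSeries(np.array(_ISTANBUL_YEARS), np.array(_ISTANBUL_TONNES))


# Published model comparison for the Istanbul record: fitted values of each
# forecaster over the test window (2016-2020) and validation window
# (2021-2023). Column order: linear trend, GM(1,1), firefly-tuned GM(1,1),
# firefly-tuned FGM(1,1), firefly-tuned NGBM(1,1).
_REPORTED_FITS = {
    2016: (21815.35, 23395.68, 23286.00, 23290.57, 23319.75),
    2017: (22969.38, 25361.12, 25185.57, 25160.74, 25230.63),
    2018: (24123.40, 27468.77, 27206.26, 27134.44, 27328.94),
    2019: (25277.43, 29920.41, 29539.15, 29450.88, 29625.44),
    2020: (26431.46, 32791.42, 32249.84, 32196.32, 32148.85),
    2021: (27585.49, 35454.39, 35252.98, 35535.79, 34396.90),
    2022: (28739.52, 38426.32, 38130.16, 38559.71, 36945.43),
    2023: (29893.55, 41622.98, 41207.30, 41812.43, 39725.36),
}

REPORTED_MODEL_COLUMNS = ("linear_regression", "gm", "fa_gm", "fa_fgm", "fa_ngbm")


def istanbul_reported_fits() -> pd.DataFrame:
    """Published per-year fitted values for each model on the Istanbul record.

    Returns a frame with columns ``year``, ``window`` (test/validation),
    ``actual`` and one column per model in :data:`REPORTED_MODEL_COLUMNS`.
    Useful for re-deriving the published error metrics from first principles.
    """
    actual = istanbul_fixture()
    rows = []
    for year in _ISTANBUL_YEARS:
        fits = _REPORTED_FITS[year]
        rows.append(
            {
                "year": year,
                "window": "test" if year <= 2020 else "validation",
                "actual": actual.value_at(year),
                **dict(zip(REPORTED_MODEL_COLUMNS, fits)),
            }
        )
    return pd.DataFrame(rows)
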