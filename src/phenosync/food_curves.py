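"""Daily food-availability and food-requirement curves.

Availability is caterpillar biomass (g/m²) interpolated from sparse frass-net
samples; requirement is the summed daily biomass demand (g) of all non-failed
broods whose nestlings are in the critical age window (days 5–15
post-hatching). Both kinds of curve live on an integer day-of-year grid and
can be scaled jointly across seasons to [0, 1] so that between-year height
ratios are preserved.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

logger = logging.getLogger("phenosync")

#: printed per-nestling requirement (g wet caterpillar biomass per day) for
#: nestling ages 5..15; derived from age-specific energy intake divided by
#: 21.4 kJ/g dry weight and multiplied by 5 (80% wet mass).
REQUIREMENT_G = (2.57, 2.92, 3.34, 3.62, 3.90, 3.97, 4.21, 4.37, 4.49, 4.51, 4.51)

AGE_MIN, AGE_MAX = 5, 15


class CurveError(ValueError):
    """Raised for degenerate or invalid curve inputs."""


@dataclass(frozen=True)
class FrassSeries:
    """One season's sparse biomass samples (day-of-year, g/m²)."""

    year: int
    days: np.ndarray
    biomass: np.ndarray

    def __post_init__(self):
        days = np.asarray(self.days, dtype=int)
        biomass = np.asarray(self.biomass, dtype=float)
        if days.shape != biomass.shape:
            raise CurveError("days and biomass must have equal length")
        if np.any(np.diff(days) <= 0):
            raise CurveError("sample days must be strictly increasing")
        if np.any(biomass < 0):
            raise CurveError("biomass must be nonnegative")
        object.__setattr__(self, "days", days)
        object.__setattr__(self, "biomass", biomass)

    def __len__(self) -> int:
        return len(self.days)


@dataclass
class DailyCurve:
    """A per-day series over a season window, availability or requirement."""

    year: int
    days: np.ndarray
    values: np.ndarray
    kind: str  # "availability" | "requirement"
    scaled: bool = False

    def __post_init__(self):
        self.days = np.asarray(self.days, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if self.days.shape != self.values.shape:
            raise CurveError("days and values must have equal length")
        if len(self.days) and np.any(np.diff(self.days) != 1):
            raise CurveError("day grid must be contiguous and increasing")
        if self.kind not in ("availability", "requirement"):
            raise CurveError(f"unknown curve kind {self.kind!r}")
        if np.any(self.values < 0):
            raise CurveError("curve values must be nonnegative")

    def value_on(self, day: int | np.ndarray) -> np.ndarray:
        """Values on arbitrary days; zero outside the grid."""
        day = np.asarray(day, dtype=int)
        idx = day - self.days[0]
        inside = (idx >= 0) & (idx < len(self.days))
        out = np.zeros(day.shape, dtype=float)
        out[inside] = self.values[idx[inside]]
        return out


@dataclass(frozen=True)
class CurveStats:
    peak_date: int
    peak_height: float
    skewness: float
    kurtosis: float  # excess


def interpolate_biomass(series: FrassSeries, window: tuple[int, int]) -> DailyCurve:
    """Interpolate sparse biomass samples onto a daily grid.

    Inside the sampled range an interpolating cubic spline (one knot per
    sampling date) passes exactly through every sample.  Outside it the curve
    extends linearly with the boundary slope of the spline; if that slope
    would make the extrapolation non-decreasing away from the data, the whole
    tail on that side is set to zero instead.  Negative values are clipped
    to zero.
    """
    if len(series) < 3:
        raise CurveError("need at least 3 samples to fit an interpolating spline")
    if len(np.unique(series.days)) != len(series.days):
        raise CurveError("duplicate sampling dates must be averaged before interpolation")
    start, end = int(window[0]), int(window[1])
    if start >= end:
        raise CurveError("window start must precede end")

    spl = CubicSpline(series.days, series.biomass)
    grid = np.arange(start, end + 1)
    vals = np.empty(grid.shape, dtype=float)

    inside = (grid >= series.days[0]) & (grid <= series.days[-1])
    vals[inside] = spl(grid[inside])

    # left tail: away from data means decreasing t, values rise if slope < 0
    left = grid < series.days[0]
    slope_l = float(spl(series.days[0], 1))
    if slope_l <= 0:
        vals[left] = 0.0
    else:
        vals[left] = series.biomass[0] + slope_l * (grid[left] - series.days[0])

    right = grid > series.days[-1]
    slope_r = float(spl(series.days[-1], 1))
    if slope_r >= 0:
        vals[right] = 0.0
    else:
        vals[right] = series.biomass[-1] + slope_r * (grid[right] - series.days[-1])

    n_clip = int(np.sum(vals < 0))
    if n_clip:
        logger.info("year %s: clipped %d negative interpolated values to 0", series.year, n_clip)
    vals = np.clip(vals, 0.0, None)
    return DailyCurve(series.year, grid, vals, kind="availability")


def truncated_sampling_flag(series: FrassSeries, frac: float = 0.25) -> bool:
    """Flag a season whose sampling started or ended mid-rise.

    True when the first or last sample exceeds ``frac`` of that season's
    maximum, i.e. the campaign missed a tail of the biomass bump.  The year
    is flagged (and should be inspected), never silently dropped.
    """
    m = float(series.biomass.max())
    if m == 0:
        return False
    flagged = series.biomass[0] > frac * m or series.biomass[-1] > frac * m
    if flagged:
        logger.warning(
            "year %s: boundary sample exceeds %.0f%% of the seasonal maximum; "
            "the biomass bump may be truncated", series.year, 100 * frac,
        )
    return flagged


def curve_stats(curve: DailyCurve) -> CurveStats:
    """Peak date/height plus shape statistics of a daily curve.

    The curve is treated as a discrete probability mass over days (values
    normalised to sum one); skewness and excess kurtosis are the third and
    fourth standardised central moments of that mass.  Peak-date ties break
    to the earliest day.
    """
    total = float(curve.values.sum())
    if total <= 0:
        raise CurveError("curve has no positive mass")
    p = curve.values / total
    days = curve.days.astype(float)
    mean = float(p @ days)
    var = float(p @ (days - mean) ** 2)
    if var <= 0:
        raise CurveError("degenerate curve: all mass on a single day")
    sd = np.sqrt(var)
    skew = float(p @ ((days - mean) / sd) ** 3)
    kurt = float(p @ ((days - mean) / sd) ** 4) - 3.0
    i = int(np.argmax(curve.values))  # argmax returns the first maximum
    return CurveStats(
        peak_date=int(curve.days[i]),
        peak_height=float(curve.values[i]),
        skewness=skew,
        kurtosis=kurt,
    )


def grams_required(
    energy_kj: float, energy_content: float = 21.4, wet_fraction: float = 0.80
) -> float:
    """Convert a daily energy need (kJ) to grams of wet caterpillar biomass.

    Dry mass is energy divided by the caterpillar energy content
    (default 21.4 kJ/g dry); wet mass follows from the wet-mass proportion
    (default 0.80, i.e. a ×5 dry-to-wet multiplier).
    """
    if energy_kj < 0:
        raise CurveError("energy must be nonnegative")
    if not 0 < wet_fraction < 1:
        raise CurveError("wet_fraction must be in (0, 1)")
    if energy_content <= 0:
        raise CurveError("energy_content must be positive")
    return energy_kj / energy_content / (1.0 - wet_fraction)


def requirement_per_nestling(age_days: int, series=REQUIREMENT_G) -> float:
    """Per-nestling daily requirement (g wet biomass) at a given age.

    Defined only for the critical window, ages 5–15 post-hatching.
    """
    if not AGE_MIN <= age_days <= AGE_MAX:
        raise CurveError(f"age {age_days} outside the critical window [{AGE_MIN}, {AGE_MAX}]")
    if len(series) != AGE_MAX - AGE_MIN + 1:
        raise CurveError("requirement series must have exactly 11 entries")
    return float(series[int(age_days) - AGE_MIN])


def build_requirement_curve(
    breeding: pd.DataFrame,
    year: int,
    window: tuple[int, int],
    series=REQUIREMENT_G,
) -> DailyCurve:
    """Summed daily food requirement (g) of all non-failed broods in a year.

    For each brood and each calendar day on which its nestlings are aged
    5–15, the brood contributes brood_size_d15 × per-nestling requirement.
    Failed broods (no day-15 brood size) contribute nothing.
    """
    start, end = int(window[0]), int(window[1])
    grid = np.arange(start, end + 1)
    vals = np.zeros(grid.shape, dtype=float)
    sub = breeding[(breeding["year"] == year) & (~breeding["failed"])]
    for _, row in sub.iterrows():
        hatch = int(row["hatch_date"])
        size = float(row["brood_size_d15"])
        for age in range(AGE_MIN, AGE_MAX + 1):
            day = hatch + age
            if start <= day <= end:
                vals[day - start] += size * requirement_per_nestling(age, series)
    curve = DailyCurve(int(year), grid, vals, kind="requirement")
    if vals.sum() == 0:
        logger.warning("year %s: no non-failed broods; requirement curve is all zero", year)
    logger.info("year %s: requirement curve from %d broods", year, len(sub))
    return curve


def scale_across_seasons(curves: list[DailyCurve]) -> list[DailyCurve]:
    """Scale a set of same-kind curves to [0, 1] by their joint maximum.

    One global maximum across all years divides every curve, preserving
    within-year shapes and between-year height ratios; availability and
    requirement are scaled independently of one another (call once per kind).
    """
    if not curves:
        raise CurveError("no curves to scale")
    kinds = {c.kind for c in curves}
    if len(kinds) != 1:
        raise CurveError("scale_across_seasons expects curves of a single kind")
    if all(c.scaled for c in curves):
        return [replace(c) for c in curves]  # already in [0,1]; idempotent
    if any(c.scaled for c in curves):
        raise CurveError("cannot mix scaled and unscaled curves")
    gmax = max(float(c.values.max()) for c in curves)
    if gmax <= 0:
        raise CurveError("global maximum is zero; cannot scale")
    return [
        DailyCurve(c.year, c.days.copy(), c.values / gmax, kind=c.kind, scaled=True)
        for c in curves
    ]


@dataclass
class SeasonCurves:
    """All per-year curves and peak statistics of a study."""

    avail_raw: dict[int, DailyCurve]
    avail_scaled: dict[int, DailyCurve]
    req_raw: dict[int, DailyCurve]
    req_scaled: dict[int, DailyCurve]
    stats: dict[int, CurveStats]

    @property
    def peak_dates(self) -> dict[int, int]:
        return {y: s.peak_date for y, s in self.stats.items()}


def build_season_curves(
    frass_list: list[FrassSeries],
    breeding: pd.DataFrame,
    window: tuple[int, int],
    series=REQUIREMENT_G,
) -> SeasonCurves:
    """Per-year availability and requirement curves, raw and jointly scaled.

    Availability is interpolated from each season's frass samples;
    requirement is summed over that season's non-failed broods; each kind is
    then scaled to [0, 1] by its own across-season maximum.  Peak statistics
    come from the raw availability curves.
    """
    avail_raw = {s.year: interpolate_biomass(s, window) for s in frass_list}
    for s in frass_list:
        truncated_sampling_flag(s)
    years = sorted(avail_raw)
    req_raw = {y: build_requirement_curve(breeding, y, window, series) for y in years}
    avail_scaled = dict(zip(years, scale_across_seasons([avail_raw[y] for y in years])))
    req_scaled = dict(zip(years, scale_across_seasons([req_raw[y] for y in years])))
    stats = {y: curve_stats(avail_raw[y]) for y in years}
    return SeasonCurves(avail_raw, avail_scaled, req_raw, req_scaled, stats)


# ---------------------------------------------------------------------------
# Natural cubic smoothing spline with a prescribed effective df
# ---------------------------------------------------------------------------

def _penalty_matrix(x: np.ndarray) -> np.ndarray:
    # Green & Silverman (1994) K = Q R^{-1} Q', natural cubic spline penalty
    n = len(x)
    h = np.diff(x)
    Q = np.zeros((n, n - 2))
    R = np.zeros((n - 2, n - 2))
    for j in range(1, n - 1):
        Q[j - 1, j - 1] = 1.0 / h[j - 1]
        Q[j, j - 1] = -1.0 / h[j - 1] - 1.0 / h[j]
        Q[j + 1, j - 1] = 1.0 / h[j]
        R[j - 1, j - 1] = (h[j - 1] + h[j]) / 3.0
        if j < n - 2:
            R[j - 1, j] = R[j, j - 1] = h[j] / 6.0
    return Q @ np.linalg.solve(R, Q.T)


def smoothing_spline(x: np.ndarray, y: np.ndarray, df: float) -> np.ndarray:
    """Fitted values of a natural cubic smoothing spline with ``df`` effective df.

    The smoother is g = (I + λK)⁻¹ y with K the natural-cubic-spline
    roughness penalty; λ is solved by bisection so that the trace of the hat
    matrix equals ``df``.  df → n gives interpolation, df → 2 the straight
    least-squares line.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 4:
        raise CurveError("smoothing spline needs at least 4 points")
    if np.any(np.diff(x) <= 0):
        raise CurveError("x must be strictly increasing")
    if not 2.0 <= df <= n:
        raise CurveError(f"df must lie in [2, {n}]")
    if df >= n - 1e-8:
        return y.copy()
    key = (x.tobytes(), float(df))
    S = _SMOOTHER_CACHE.get(key)
    if S is None:
        K = _penalty_matrix(x)
        eye = np.eye(n)

        def trace_df(log_lam: float) -> float:
            return float(np.trace(np.linalg.solve(eye + 10.0**log_lam * K, eye)))

        lo, hi = -12.0, 12.0  # trace is decreasing in λ
        for _ in range(80):
            mid = 0.5 * (lo + hi)
            if trace_df(mid) > df:
                lo = mid
            else:
                hi = mid
        lam = 10.0 ** (0.5 * (lo + hi))
        S = np.linalg.solve(eye + lam * K, eye)
        if len(_SMOOTHER_CACHE) > 32:
            _SMOOTHER_CACHE.clear()
        _SMOOTHER_CACHE[key] = S
    return S @ y


_SMOOTHER_CACHE: dict = {}
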