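"""Brood- and population-level phenological synchrony metrics.

Two families of metrics quantify the match between consumer demand and
resource availability:

* **MD** (match in dates) — a difference in days between a consumer phenology
  date and the resource peak date; positive means the consumer is late.
  At the brood level the consumer date is chick day 10 (peak of nestling
  energy needs); at the population level it is the mean egg-laying date plus
  a fixed lay-to-peak-need lag (33 days by default).
* **MO** (match in overlap) — the relative area under the intersection of the
  scaled availability and requirement distributions, normalised by the
  availability integral, so MO ∈ [0, 1].  At the brood level the proxy is
  the total availability over chick ages 5–15, standardised across broods
  within a season.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.othermod.betareg import BetaModel

from .food_curves import AGE_MAX, AGE_MIN, CurveError, DailyCurve

logger = logging.getLogger("phenosync")


def md_brood(hatch_date: int, peak_date: int, chick_age_critical: int = 10) -> int:
    """Brood-level mismatch in days: chick day-10 date minus the peak date.

    Positive values mean the brood was too late relative to the food peak.
    """
    return (int(hatch_date) + int(chick_age_critical)) - int(peak_date)


def md_population(mean_lay_date: float, peak_date: int, lag: int = 33) -> float:
    """Population-level mismatch: mean laying date + lag − peak date.

    The mean is taken over all first broods of known females, failed ones
    included, because laying decisions precede any failure.  Negative values
    mean the population bred on average too early.
    """
    if not np.isfinite(mean_lay_date):
        raise ValueError("mean_lay_date must be finite (no broods?)")
    return float(mean_lay_date) + int(lag) - int(peak_date)


def mo_population(avail_scaled: DailyCurve, req_scaled: DailyCurve) -> float:
    """Relative overlap of the scaled requirement and availability curves.

    Numerator: trapezoidal integral of the pointwise minimum of the two
    curves on the union day grid (each curve is zero outside its support);
    denominator: trapezoidal integral of the availability curve.
    """
    if not (avail_scaled.scaled and req_scaled.scaled):
        raise CurveError("mo_population expects curves scaled to [0, 1]")
    if avail_scaled.kind != "availability" or req_scaled.kind != "requirement":
        raise CurveError("pass (availability, requirement) in that order")
    lo = min(avail_scaled.days[0], req_scaled.days[0])
    hi = max(avail_scaled.days[-1], req_scaled.days[-1])
    grid = np.arange(lo, hi + 1)
    f_avail = avail_scaled.value_on(grid)
    f_req = req_scaled.value_on(grid)
    denom = float(np.trapezoid(f_avail, grid))
    if denom <= 0:
        raise CurveError("availability integral is zero")
    num = float(np.trapezoid(np.minimum(f_avail, f_req), grid))
    return num / denom


def mo_signed(mo_p: float, md_p: float) -> float:
    """Sign the overlap to match the direction of the date mismatch.

    Negative when the population bred too early (md_p < 0); positive
    otherwise (the md_p = 0 tie takes the positive sign).
    """
    if not 0 <= mo_p <= 1:
        raise ValueError("mo_p must lie in [0, 1]")
    return -mo_p if md_p < 0 else mo_p


def mo_brood_raw(hatch_date: int, avail_raw: DailyCurve) -> float:
    """Total availability (raw curve units) over the brood's critical window.

    Sums the availability on the 11 calendar days when the chicks are aged
    5–15 (hatch day = age 0).
    """
    days = int(hatch_date) + np.arange(AGE_MIN, AGE_MAX + 1)
    return float(avail_raw.value_on(days).sum())


def standardize_within_year(raw: np.ndarray) -> np.ndarray:
    """Centre and scale to unit SD (population SD, divisor n) within a year.

    A single brood, or zero spread, maps to all-zero scores by convention.
    """
    raw = np.asarray(raw, dtype=float)
    if len(raw) < 2:
        return np.zeros_like(raw)
    sd = raw.std()  # population SD: deterministic scores for n = 2
    if sd == 0:
        return np.zeros_like(raw)
    return (raw - raw.mean()) / sd


def mo_brood_scores(broods: pd.DataFrame, avail_raw: DailyCurve) -> pd.Series:
    """Within-year standardised MO_b for the non-failed broods of one year.

    ``broods`` must carry ``hatch_date``; the availability curve is the raw
    (unscaled, g/m²) one for the same year — the standardisation makes any
    global scaling irrelevant.
    """
    raw = np.array([mo_brood_raw(h, avail_raw) for h in broods["hatch_date"]])
    return pd.Series(standardize_within_year(raw), index=broods.index, name="mo_b")


def md_mo_association(md_p: np.ndarray, mo_p: np.ndarray) -> dict[str, float]:
    """Quadratic association between MO_p and MD_p across years.

    Fits a beta-regression mean model (logit link) of MO_p on MD_p + MD_p².
    With unimodal curves the overlap is maximal near MD_p = 0, so the
    quadratic coefficient is expected to be negative.  MO values of exactly
    0 or 1 are nudged inward by machine epsilon (logged).
    """
    md_p = np.asarray(md_p, dtype=float)
    mo_p = np.asarray(mo_p, dtype=float)
    if len(md_p) < 6:
        raise ValueError("need at least 6 years for the quadratic fit")
    eps = np.finfo(float).eps
    n_edge = int(np.sum((mo_p <= 0) | (mo_p >= 1)))
    if n_edge:
        logger.info("nudged %d boundary MO_p values inward by machine epsilon", n_edge)
        mo_p = np.clip(mo_p, eps, 1 - eps)
    X = np.column_stack([np.ones_like(md_p), md_p, md_p**2])
    res = BetaModel(mo_p, X).fit(disp=False)
    return {"intercept": res.params[0], "md_p": res.params[1], "md_p2": res.params[2]}


# ---------------------------------------------------------------------------
# Whole-study metric tables
# ---------------------------------------------------------------------------

@dataclass
class SynchronySet:
    """Per-year and per-brood synchrony metrics for a study."""

    year_metrics: pd.DataFrame   # year, md_p, mo_p, mo_p_signed, hcp, skewness, kurtosis, peak_date
    brood_metrics: pd.DataFrame  # brood_id, year, md_b, mo_b


def compute_synchrony(
    breeding: pd.DataFrame,
    avail_raw: dict[int, DailyCurve],
    avail_scaled: dict[int, DailyCurve],
    req_scaled: dict[int, DailyCurve],
    peak_dates: dict[int, int],
    stats: dict[int, "object"],
    lag: int = 33,
    chick_age_critical: int = 10,
) -> SynchronySet:
    """Assemble the full per-year and per-brood metric tables.

    Year-level MD uses the mean lay date over all first broods (failed
    included); brood-level metrics cover non-failed broods only.
    """
    year_rows = []
    brood_frames = []
    for year in sorted(avail_scaled):
        peak = peak_dates[year]
        sub = breeding[breeding["year"] == year]
        md_p = md_population(float(sub["lay_date"].mean()), peak, lag=lag)
        mo_p = mo_population(avail_scaled[year], req_scaled[year])
        st = stats[year]
        year_rows.append({
            "year": year, "peak_date": peak, "md_p": md_p, "mo_p": mo_p,
            "mo_p_signed": mo_signed(mo_p, md_p),
            "hcp": st.peak_height, "skewness": st.skewness, "kurtosis": st.kurtosis,
        })
        ok = sub[~sub["failed"]]
        if len(ok):
            bm = pd.DataFrame({
                "brood_id": ok["brood_id"].to_numpy(),
                "year": year,
                "md_b": [md_brood(h, peak, chick_age_critical) for h in ok["hatch_date"]],
                "mo_b": mo_brood_scores(ok, avail_raw[year]).to_numpy(),
            })
            brood_frames.append(bm)
    year_metrics = pd.DataFrame(year_rows)
    brood_metrics = (
        pd.concat(brood_frames, ignore_index=True)
        if brood_frames
        else pd.DataFrame(columns=["brood_id", "year", "md_b", "mo_b"])
    )
    logger.info(
        "synchrony metrics: %d years, %d broods", len(year_metrics), len(brood_metrics)
    )
    return SynchronySet(year_metrics, brood_metrics)
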