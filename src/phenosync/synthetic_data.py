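"""Study-shaped synthetic data with known ground truth.

Emulates a multi-decade nest-box study of a caterpillar-feeding passerine:
per season, a unimodal (Gaussian-in-expectation) caterpillar biomass curve
sampled every 3–4 days with multiplicative noise, and a set of breeding
records (laying dates, clutch and brood sizes, failures, yearly density and
beech-crop covariates).  Nestling recruitment is generated from a known,
configurable logistic dependence on the brood-level mismatch metrics so that
downstream model comparison can be validated by recovery; an alternative
brood-level Poisson path generates recruit counts from a laying-date ×
mismatch interaction for the selection suite.

Year structure follows the study system: among-year variance of the
population mismatch ≈ 52 days², within-year laying spread ≈ 22.5 days², and
the lay-to-peak-need lag of 33 days holds exactly by construction
(hatch = lay + 23, so chick day 10 = lay + 33).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .food_curves import DailyCurve, FrassSeries
from .synchrony_metrics import md_brood, standardize_within_year

logger = logging.getLogger("phenosync")


@dataclass
class TruthParams:
    """Ground-truth parameters of a synthetic study."""

    n_years: int = 24
    pairs_per_year: int = 85
    season_window: tuple[int, int] = (100, 180)

    # year structure
    lay_mean_base: float = 110.0     # grand mean laying day-of-year
    lay_mean_sd: float = 3.0         # among-year SD of the mean laying date
    lay_sd: float = 4.74             # within-year laying SD (≈ √22.5 days²)
    md_p_sd: float = 7.2             # among-year SD of the population mismatch (≈ √52)
    lay_to_peak_lag: int = 33

    # availability curve (expectation is a Gaussian bump, g/m²)
    curve_height_mean: float = 7.0
    curve_height_cv: float = 0.3
    curve_sd_mean: float = 7.0
    curve_sd_spread: float = 1.0
    sampling_interval: int = 3       # days between frass samples (3 or 4)
    sampling_noise_cv: float = 0.2

    # brood demography
    clutch_base: int = 5             # clutch = base + Binomial(extra_n, extra_p), mean 9
    clutch_extra_n: int = 8
    clutch_extra_p: float = 0.5
    nestling_loss_p: float = 0.08    # per-nestling loss before day 15
    failure_fraction: float = 0.12   # broods failing before day 15
    mother_return_rate: float = 0.5  # chance a previous year's mother breeds again

    # nestling recruitment truth (logit scale)
    recruit_intercept: float = -2.0
    beta_md: float = 0.0             # per day
    beta_md2: float = -0.015         # per day²
    beta_mo: float = 0.0             # per within-year SD of availability
    random_sd_year: float = 0.0
    random_sd_mother: float = 0.0
    random_sd_brood: float = 0.0

    # brood-level selection truth (log scale, Poisson recruit counts)
    sel_intercept: float = -0.7
    sel_beta_eld: float = 0.0
    sel_beta_md_p: float = 0.0
    sel_beta_eld_x_md: float = 0.0

    seed: int = 0

    def __post_init__(self):
        if self.sampling_interval not in (3, 4):
            raise ValueError("sampling_interval must be 3 or 4")
        if self.pairs_per_year < 2:
            raise ValueError("pairs_per_year must be at least 2")
        for name in ("lay_sd", "md_p_sd", "random_sd_year", "random_sd_mother",
                     "random_sd_brood", "sampling_noise_cv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if not 0 <= self.failure_fraction < 1:
            raise ValueError("failure_fraction must be in [0, 1)")


@dataclass
class StudyData:
    """A complete synthetic study: inputs plus per-year/per-brood truth."""

    frass: list[FrassSeries]
    breeding: pd.DataFrame           # io_config breeding schema + failed flag
    truth_years: pd.DataFrame        # year, peak_date, curve height/sd, mean lay, md_p
    true_brood_metrics: pd.DataFrame  # brood_id, year, md_b, mo_b (from the true curve)


def generate_frass_year(
    peak_date: int,
    height: float,
    sd: float,
    window: tuple[int, int],
    interval: int = 3,
    noise_cv: float = 0.2,
    seed: int | np.random.Generator = 0,
) -> FrassSeries:
    """One season of sparse frass samples around a Gaussian biomass bump.

    Samples sit every ``interval`` days across ``window``; the expected value
    at day t is height·exp(−(t−peak)²/2sd²) with multiplicative mean-one
    log-normal noise of coefficient of variation ``noise_cv`` (zero noise
    reproduces the bump exactly); values are clipped at zero.
    """
    if height <= 0 or sd <= 0:
        raise ValueError("height and sd must be positive")
    start, end = int(window[0]), int(window[1])
    if end - start < 2 * interval:
        raise ValueError("window must span at least two sampling intervals")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    days = np.arange(start, end + 1, interval)
    mean = height * np.exp(-((days - peak_date) ** 2) / (2.0 * sd**2))
    if noise_cv > 0:
        s2 = np.log1p(noise_cv**2)
        vals = mean * rng.lognormal(-0.5 * s2, np.sqrt(s2), size=days.shape)
    else:
        vals = mean
    return FrassSeries(0, days, np.clip(vals, 0.0, None))


def true_availability_curve(
    year: int, peak_date: int, height: float, sd: float, window: tuple[int, int]
) -> DailyCurve:
    """The noiseless generating availability bump on the daily grid."""
    days = np.arange(int(window[0]), int(window[1]) + 1)
    vals = height * np.exp(-((days - peak_date) ** 2) / (2.0 * sd**2))
    return DailyCurve(year, days, vals, kind="availability")


def generate_breeding_year(
    year: int,
    mean_lay: float,
    truth: TruthParams,
    rng: np.random.Generator,
    mother_pool: list[int],
    next_ids: list[int],
) -> list[dict]:
    """Brood records for one year (without recruitment outcomes).

    Laying dates are Normal(mean_lay, lay_sd) rounded to days; hatch is
    lay + lag − 10 so that chick day 10 lands exactly at lay + lag.  Mothers
    are a mix of returners from ``mother_pool`` and new ids.
    """
    n = truth.pairs_per_year
    rows = []
    returners = [m for m in mother_pool if rng.random() < truth.mother_return_rate]
    returners = [returners[j] for j in rng.permutation(len(returners))]
    for i in range(n):
        if i < len(returners):
            mother = returners[i]
        else:
            mother = next_ids[0]
            next_ids[0] += 1
        lay = int(np.round(rng.normal(mean_lay, truth.lay_sd)))
        clutch = truth.clutch_base + rng.binomial(truth.clutch_extra_n, truth.clutch_extra_p)
        hatch = lay + truth.lay_to_peak_lag - 10
        failed = rng.random() < truth.failure_fraction
        if failed:
            size = None
        else:
            size = int(clutch - rng.binomial(clutch, truth.nestling_loss_p))
            size = max(size, 1)
        rows.append({
            "brood_id": f"b{year}_{i:03d}", "mother_id": f"f{mother:04d}", "year": year,
            "lay_date": lay, "clutch_size": int(clutch), "hatch_date": hatch,
            "brood_size_d15": size, "recruits": 0, "failed": failed,
        })
    return rows


def generate_recruitment(
    breeding: pd.DataFrame,
    brood_metrics: pd.DataFrame,
    truth: TruthParams,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Draw per-nestling Bernoulli recruitment from the truth model.

    logit p = intercept + β_md·MD_b + β_md2·MD_b² + β_mo·MO_b + year +
    mother + brood random intercepts; the returned table carries the summed
    per-brood recruit counts.  Failed broods keep zero recruits.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    df = breeding.copy()
    met = brood_metrics.set_index("brood_id")
    u_year = {y: rng.normal(0, truth.random_sd_year) if truth.random_sd_year > 0 else 0.0
              for y in sorted(df["year"].unique())}
    u_mother = {m: rng.normal(0, truth.random_sd_mother) if truth.random_sd_mother > 0 else 0.0
                for m in sorted(df["mother_id"].unique())}
    recruits = np.zeros(len(df), dtype=int)
    for pos, (_, row) in enumerate(df.iterrows()):
        if row["failed"]:
            continue
        bid = row["brood_id"]
        if bid not in met.index:
            raise ValueError(f"metrics missing for brood {bid}")
        md_b, mo_b = float(met.loc[bid, "md_b"]), float(met.loc[bid, "mo_b"])
        eta = (
            truth.recruit_intercept
            + truth.beta_md * md_b
            + truth.beta_md2 * md_b**2
            + truth.beta_mo * mo_b
            + u_year[row["year"]]
            + u_mother[row["mother_id"]]
            + (rng.normal(0, truth.random_sd_brood) if truth.random_sd_brood > 0 else 0.0)
        )
        p = expit(eta)
        assert 0.0 < p < 1.0
        recruits[pos] = rng.binomial(int(row["brood_size_d15"]), p)
    df["recruits"] = recruits
    return df


def generate_selection_recruits(
    breeding: pd.DataFrame,
    truth_years: pd.DataFrame,
    truth: TruthParams,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Draw brood-level Poisson recruit counts from the selection truth model.

    log λ = intercept + β_eld·ELD + β_mdp·MD_p + β_int·ELD·MD_p with ELD the
    within-year-centred laying date; all first broods (failed included) get a
    count, mirroring a fitness analysis that conditions on laying decisions.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    df = breeding.copy()
    md_p = truth_years.set_index("year")["md_p"]
    eld = df["lay_date"] - df.groupby("year")["lay_date"].transform("mean")
    m = df["year"].map(md_p).to_numpy(float)
    lam = np.exp(
        truth.sel_intercept
        + truth.sel_beta_eld * eld.to_numpy(float)
        + truth.sel_beta_md_p * m
        + truth.sel_beta_eld_x_md * eld.to_numpy(float) * m
    )
    df["recruits"] = rng.poisson(lam)
    return df


def generate_study(truth: TruthParams, seed: int | None = None) -> StudyData:
    """Generate a full synthetic study from the truth parameters.

    Per year: a mean laying date, a population mismatch MD_p ~ N(0, md_p_sd²)
    fixing the availability peak at mean lay + lag − MD_p, a noisy sampled
    frass series, breeding records, and recruitment outcomes drawn from the
    truth model using brood metrics computed on the *true* (noiseless)
    availability curve.
    """
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    years = np.arange(1, truth.n_years + 1)
    mean_lay = rng.normal(truth.lay_mean_base, truth.lay_mean_sd, truth.n_years)
    md_p = rng.normal(0.0, truth.md_p_sd, truth.n_years)
    peak = np.round(mean_lay + truth.lay_to_peak_lag - md_p).astype(int)
    height = truth.curve_height_mean * np.exp(
        rng.normal(0.0, truth.curve_height_cv, truth.n_years)
    ) if truth.curve_height_cv > 0 else np.full(truth.n_years, truth.curve_height_mean)
    csd = np.clip(
        rng.normal(truth.curve_sd_mean, truth.curve_sd_spread, truth.n_years), 3.0, None
    )
    density = rng.poisson(truth.pairs_per_year, truth.n_years)
    bci = rng.integers(0, 3, truth.n_years)

    frass, rows = [], []
    mother_pool: list[int] = []
    next_ids = [0]
    brood_truth_frames = []
    for i, year in enumerate(years):
        fs = generate_frass_year(
            peak[i], height[i], csd[i], truth.season_window,
            truth.sampling_interval, truth.sampling_noise_cv, rng,
        )
        frass.append(FrassSeries(int(year), fs.days, fs.biomass))
        yr_rows = generate_breeding_year(int(year), mean_lay[i], truth, rng, mother_pool, next_ids)
        for r in yr_rows:
            r["density"] = int(density[i])
            r["bci"] = int(bci[i])
        rows.extend(yr_rows)
        mother_pool = sorted({r["mother_id"] for r in yr_rows})
        mother_pool = [int(m[1:]) for m in mother_pool]

        # truth metrics from the noiseless generating curve
        ok = [r for r in yr_rows if not r["failed"]]
        if ok:
            curve = true_availability_curve(int(year), peak[i], height[i], csd[i], truth.season_window)
            hatches = np.array([r["hatch_date"] for r in ok])
            raw = np.array([
                curve.value_on(h + np.arange(5, 16)).sum() for h in hatches
            ])
            brood_truth_frames.append(pd.DataFrame({
                "brood_id": [r["brood_id"] for r in ok],
                "year": int(year),
                "md_b": [md_brood(h, int(peak[i])) for h in hatches],
                "mo_b": standardize_within_year(raw),
            }))

    breeding = pd.DataFrame(rows)
    breeding["brood_size_d15"] = breeding["brood_size_d15"].astype("Float64")
    true_brood_metrics = pd.concat(brood_truth_frames, ignore_index=True)
    breeding = generate_recruitment(breeding, true_brood_metrics, truth, rng)
    truth_years = pd.DataFrame({
        "year": years, "mean_lay": mean_lay, "md_p": md_p, "peak_date": peak,
        "curve_height": height, "curve_sd": csd, "density": density, "bci": bci,
    })
    logger.info(
        "synthetic study: %d years, %d broods (%d failed)",
        truth.n_years, len(breeding), int(breeding["failed"].sum()),
    )
    return StudyData(frass, breeding, truth_years, true_brood_metrics)
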