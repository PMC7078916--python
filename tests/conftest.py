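import numpy as np
import pandas as pd
import pytest

import phenosync as ps


@pytest.fixture(scope="session")
def small_study():
    """A small noiseless synthetic study shared across read-only tests."""
    truth = ps.TruthParams(
        n_years=10, pairs_per_year=30, sampling_noise_cv=0.0,
        beta_md2=-0.03, random_sd_year=0.0, random_sd_mother=0.0, random_sd_brood=0.0,
        seed=42,
    )
    return truth, ps.generate_study(truth)


@pytest.fixture(scope="session")
def small_curves(small_study):
    truth, study = small_study
    return ps.build_season_curves(study.frass, study.breeding, truth.season_window)


@pytest.fixture(scope="session")
def small_sync(small_study, small_curves):
    truth, study = small_study
    c = small_curves
    return ps.compute_synchrony(
        study.breeding, c.avail_raw, c.avail_scaled, c.req_scaled, c.peak_dates, c.stats
    )


def gaussian_series(peak=140, height=6.0, sd=7.0, window=(110, 170), step=3, year=1):
    days = np.arange(window[0], window[1] + 1, step)
    vals = height * np.exp(-((days - peak) ** 2) / (2 * sd**2))
    return ps.FrassSeries(year, days, vals)


def scaled_curve(days, values, kind):
    return ps.DailyCurve(0, np.asarray(days), np.asarray(values, float), kind=kind, scaled=True)


@pytest.fixture
def toy_breeding():
    """Two non-failed broods plus one failed brood in a single year."""
    df = pd.DataFrame({
        "brood_id": ["b1", "b2", "b3"],
        "mother_id": ["f1", "f2", "f3"],
        "year": [2000, 2000, 2000],
        "lay_date": [107, 110, 112],
        "clutch_size": [9, 9, 8],
        "hatch_date": [130, 133, 135],
        "brood_size_d15": [8.0, 1.0, np.nan],
        "recruits": [2, 0, 0],
        "density": [90, 90, 90],
        "bci": [1, 1, 1],
    })
    df["brood_size_d15"] = df["brood_size_d15"].astype("Float64")
    df["failed"] = df["brood_size_d15"].isna()
    return df
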