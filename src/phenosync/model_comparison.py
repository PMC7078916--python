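"""Candidate-model suites, AICc ranking, bootstrap CIs and VIF diagnostics.

Two suites mirror the study design:

* **Recruitment suite** (binomial, nestling level): does a brood-level date
  mismatch (MD_b, optionally quadratic) or the overlap proxy (MO_b) explain
  nestling recruitment beyond breeding density and beech crop index?  Random
  intercepts: year, mother, brood within mother.
* **Selection suite** (Poisson, brood level): does a population-level
  mismatch metric, alone or interacting with the within-year-centred laying
  date (ELD), explain a female's recruit count?  Random intercepts: year and
  female.

Random-intercept GLMMs are fitted by maximum likelihood with a Laplace
approximation to the marginal likelihood (penalised IRLS inner loop over the
joint mode of fixed and random effects, bounded quasi-Newton outer loop over
the random-effect standard deviations).  When all variance components are
zero the approximation is exact and the fit coincides with the ordinary GLM.
Models are ranked by AICc; candidates within 2 units of the best are
flagged competitive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.optimize import minimize
from scipy.sparse.linalg import splu
from scipy.special import expit, gammaln

logger = logging.getLogger("phenosync")

_ETA_CLIP = 30.0
_SD_FLOOR = 1e-8  # a component below this is treated as absent


class FitError(RuntimeError):
    """A model could not be fitted (separation, non-convergence, ...)."""


def aicc(loglik: float, k: int, n: int) -> float:
    """Akaike information criterion with the small-sample correction.

    AICc = −2·logLik + 2k + 2k(k+1)/(n−k−1); requires n > k + 1.
    """
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n} <= k+1={k + 1}")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


# ---------------------------------------------------------------------------
# Laplace-approximation GLMM
# ---------------------------------------------------------------------------

def _loglik(y: np.ndarray, eta: np.ndarray, family: str) -> float:
    if family == "binomial":
        # exact for binary y, normaliser included
        return float(y @ eta - np.logaddexp(0.0, eta).sum())
    mu = np.exp(eta)
    return float(y @ eta - mu.sum() - gammaln(y + 1).sum())


def _mu_w(eta: np.ndarray, family: str):
    if family == "binomial":
        mu = expit(eta)
        return mu, mu * (1.0 - mu)
    mu = np.exp(eta)
    return mu, mu


def _logdet_spd(M: sparse.csc_matrix) -> float:
    lu = splu(M.tocsc())
    return float(np.sum(np.log(np.abs(lu.U.diagonal()))))


@dataclass
class MixedGLMResult:
    name: str
    family: str
    param_names: list[str]
    params: np.ndarray
    vc_names: list[str]
    vc_sd: np.ndarray
    loglik: float
    k: int
    n: int
    converged: bool
    model: "MixedGLM" = field(repr=False)

    @property
    def aicc(self) -> float:
        return aicc(self.loglik, self.k, self.n)

    def coef_table(self) -> pd.Series:
        return pd.Series(self.params, index=self.param_names, name=self.name)


class MixedGLM:
    """Binomial/Poisson GLM with optional crossed random intercepts.

    ``groups`` is a list of (name, integer codes) pairs; each factor
    contributes one random-intercept standard deviation.  With no groups the
    fit is a plain GLM via IRLS.
    """

    def __init__(self, y, X, family: str, groups=None, param_names=None, name="model"):
        self.y = np.asarray(y, dtype=float)
        self.X = np.asarray(X, dtype=float)
        if self.X.ndim != 2 or len(self.X) != len(self.y):
            raise ValueError("X must be 2-D and conformable with y")
        if family not in ("binomial", "poisson"):
            raise ValueError(f"unsupported family {family!r}")
        self.family = family
        self.name = name
        self.n, self.p = self.X.shape
        self.param_names = list(param_names) if param_names else [f"x{j}" for j in range(self.p)]
        groups = groups or []
        self.vc_names = [g[0] for g in groups]
        self.Zs, self.group_codes = [], []
        for _, codes in groups:
            codes = np.asarray(codes)
            _, idx = np.unique(codes, return_inverse=True)
            q = idx.max() + 1
            Z = sparse.csc_matrix(
                (np.ones(self.n), (np.arange(self.n), idx)), shape=(self.n, q)
            )
            self.Zs.append(Z)
            self.group_codes.append(idx)
        self._Xs = sparse.csc_matrix(self.X)
        self._warm: np.ndarray | None = None

    # -- inner loop: joint mode of (beta, u) at fixed variance components ----

    def _pirls(self, sds: np.ndarray):
        active = [i for i, s in enumerate(sds) if s > _SD_FLOOR]
        blocks = [self._Xs] + [self.Zs[i] for i in active]
        A = sparse.hstack(blocks, format="csc")
        qs = [self.Zs[i].shape[1] for i in active]
        pen = np.concatenate(
            [np.zeros(self.p)] + [np.full(q, 1.0 / sds[i] ** 2) for i, q in zip(active, qs)]
        )
        m = A.shape[1]
        gamma = np.zeros(m)
        if self._warm is not None and len(self._warm) == m:
            gamma = self._warm.copy()

        def pll(g):
            eta = np.clip(A @ g, -_ETA_CLIP, _ETA_CLIP)
            return _loglik(self.y, eta, self.family) - 0.5 * float(pen @ g**2), eta

        cur, eta = pll(gamma)
        for _ in range(100):
            mu, w = _mu_w(eta, self.family)
            grad = A.T @ (self.y - mu) - pen * gamma
            H = (A.T @ sparse.diags(w) @ A + sparse.diags(pen)).tocsc()
            try:
                delta = splu(H).solve(grad)
            except RuntimeError as e:  # singular system
                raise FitError(f"{self.name}: singular PIRLS system ({e})") from e
            step = 1.0
            for _ in range(30):
                cand = gamma + step * delta
                new, eta_new = pll(cand)
                if new >= cur - 1e-12:
                    break
                step *= 0.5
            else:
                break
            moved = new - cur
            gamma, cur, eta = cand, new, eta_new
            if moved < 1e-10:
                break
        self._warm = gamma.copy()
        return gamma, cur, eta, active, qs, pen

    def _laplace_loglik(self, sds: np.ndarray) -> tuple[float, np.ndarray]:
        gamma, pl, eta, active, qs, _ = self._pirls(sds)
        beta = gamma[: self.p]
        if not active:
            return pl, beta
        _, w = _mu_w(eta, self.family)
        Za = sparse.hstack([self.Zs[i] for i in active], format="csc")
        dinv = np.concatenate([np.full(q, 1.0 / sds[i] ** 2) for i, q in zip(active, qs)])
        Huu = (Za.T @ sparse.diags(w) @ Za + sparse.diags(dinv)).tocsc()
        logdet_d = float(np.sum([2.0 * q * np.log(sds[i]) for i, q in zip(active, qs)]))
        return pl - 0.5 * (_logdet_spd(Huu) + logdet_d), beta

    def fit(self, start_sd: float = 0.3, maxfun: int = 60) -> MixedGLMResult:
        m = len(self.Zs)
        if m == 0:
            gamma, ll, _, _, _, _ = self._pirls(np.empty(0))
            return MixedGLMResult(
                self.name, self.family, self.param_names, gamma[: self.p], [],
                np.empty(0), ll, self.p, self.n, True, self,
            )

        def negll(sds):
            ll, _ = self._laplace_loglik(np.asarray(sds))
            return -ll

        res = minimize(
            negll, np.full(m, start_sd), method="L-BFGS-B",
            bounds=[(0.0, 5.0)] * m,
            options={"maxfun": maxfun, "ftol": 1e-9, "gtol": 1e-5, "eps": 1e-4},
        )
        sds = np.asarray(res.x)
        ll, beta = self._laplace_loglik(sds)
        if not np.isfinite(ll):
            raise FitError(f"{self.name}: non-finite marginal log-likelihood")
        k = self.p + m  # each variance component counts as one parameter
        return MixedGLMResult(
            self.name, self.family, self.param_names, beta, list(self.vc_names),
            sds, ll, k, self.n, bool(res.success or res.status == 1), self,
        )


# ---------------------------------------------------------------------------
# Comparison tables
# ---------------------------------------------------------------------------

@dataclass
class ModelComparison:
    """AICc ranking of a candidate-model suite plus the underlying fits."""

    table: pd.DataFrame                 # model, k, n, logLik, AICc, dAICc, competitive
    fits: dict[str, MixedGLMResult]
    excluded: dict[str, str] = field(default_factory=dict)


def comparison_table(fits: dict[str, MixedGLMResult], excluded=None) -> ModelComparison:
    rows = [
        {"model": r.name, "k": r.k, "n": r.n, "logLik": r.loglik, "AICc": r.aicc}
        for r in fits.values()
    ]
    df = pd.DataFrame(rows).sort_values("AICc", kind="stable").reset_index(drop=True)
    df["dAICc"] = df["AICc"] - df["AICc"].min()
    df["competitive"] = df["dAICc"] <= 2.0
    return ModelComparison(df, fits, excluded or {})


def _fit_suite(specs, y, frame, family, groups) -> ModelComparison:
    fits, excluded = {}, {}
    for name, cols in specs:
        X = np.column_stack([np.ones(len(frame))] + [frame[c].to_numpy(float) for c in cols])
        model = MixedGLM(
            y, X, family, groups=groups, param_names=["intercept"] + cols, name=name
        )
        try:
            fits[name] = model.fit()
        except FitError as e:
            excluded[name] = str(e)
            logger.warning("excluding %s from ranking: %s", name, e)
    if not fits:
        raise FitError("no candidate model could be fitted")
    return comparison_table(fits, excluded)


def nestling_table(breeding: pd.DataFrame, brood_metrics: pd.DataFrame) -> pd.DataFrame:
    """Expand non-failed broods to one row per nestling with a binary outcome.

    Each brood contributes ``brood_size_d15`` rows of which ``recruits`` are
    successes.  Brood-level mismatch metrics must be available for every
    non-failed brood.
    """
    ok = breeding[~breeding["failed"]].merge(
        brood_metrics[["brood_id", "md_b", "mo_b"]], on="brood_id", how="left", validate="1:1"
    )
    if ok[["md_b", "mo_b"]].isna().any().any():
        missing = ok.loc[ok["md_b"].isna() | ok["mo_b"].isna(), "brood_id"].tolist()
        raise ValueError(f"metrics missing for brood(s) {missing[:5]}...")
    rows = []
    for _, b in ok.iterrows():
        size, rec = int(b["brood_size_d15"]), int(b["recruits"])
        if rec > size:
            raise ValueError(f"brood {b['brood_id']}: more recruits than nestlings")
        for j in range(size):
            rows.append({
                "brood_id": b["brood_id"], "mother_id": b["mother_id"], "year": b["year"],
                "dens": b["density"], "bci": b["bci"], "md_b": b["md_b"], "mo_b": b["mo_b"],
                "recruited": 1 if j < rec else 0,
            })
    df = pd.DataFrame(rows)
    df["md_b2"] = df["md_b"] ** 2
    return df


RECRUITMENT_CANDIDATES = [
    ("Dens + BCI", ["dens", "bci"]),
    ("Dens + BCI + MD_b", ["dens", "bci", "md_b"]),
    ("Dens + BCI + MD_b + MD_b^2", ["dens", "bci", "md_b", "md_b2"]),
    ("Dens + BCI + MO_b", ["dens", "bci", "mo_b"]),
]


def fit_recruitment_suite(breeding: pd.DataFrame, brood_metrics: pd.DataFrame) -> ModelComparison:
    """Fit the four nestling-recruitment candidates and rank them by AICc.

    Binomial GLMMs on the nestling-level table; random intercepts for year,
    mother and brood (brood ids are unique, so brood-within-mother reduces to
    an independent brood intercept).
    """
    df = nestling_table(breeding, brood_metrics)
    groups = [
        ("year", df["year"].to_numpy()),
        ("mother", df["mother_id"].to_numpy()),
        ("brood", df["brood_id"].to_numpy()),
    ]
    y = df["recruited"].to_numpy(float)
    return _fit_suite(RECRUITMENT_CANDIDATES, y, df, "binomial", groups)


def selection_frame(breeding: pd.DataFrame, year_metrics: pd.DataFrame) -> pd.DataFrame:
    """Brood-level frame for the selection suite (all first broods).

    Laying date is mean-centred within years (``eld``); the signed overlap
    enters as ``mo_s``; peak height and the shape statistics are carried
    over from the year table, shape statistics standardised across years.
    """
    df = breeding.merge(
        year_metrics[["year", "md_p", "mo_p_signed", "hcp", "skewness", "kurtosis"]],
        on="year", how="left", validate="m:1",
    )
    if df["md_p"].isna().any():
        raise ValueError("year metrics missing for some breeding years")
    df = df.rename(columns={"mo_p_signed": "mo_s", "density": "dens", "clutch_size": "cs"})
    df["eld"] = df["lay_date"] - df.groupby("year")["lay_date"].transform("mean")
    df["mo_s2"] = df["mo_s"] ** 2
    df["md_p_x_eld"] = df["md_p"] * df["eld"]
    df["mo_s_x_eld"] = df["mo_s"] * df["eld"]
    for col in ("skewness", "kurtosis"):
        v = df[col].to_numpy(float)
        sd = v.std()
        df[col + "_z"] = (v - v.mean()) / sd if sd > 0 else 0.0
    return df


SELECTION_BASE = ["dens", "cs", "eld", "bci"]
SELECTION_CANDIDATES = [
    ("Base", []),
    ("Base + MD_p", ["md_p"]),
    ("Base + MD_p + MD_p:ELD", ["md_p", "md_p_x_eld"]),
    ("Base + MD_p + MD_p:ELD + HCP", ["md_p", "md_p_x_eld", "hcp"]),
    ("Base + MO_p", ["mo_s"]),
    ("Base + MO_p + MO_p^2", ["mo_s", "mo_s2"]),
    ("Base + MO_p + MO_p:ELD", ["mo_s", "mo_s_x_eld"]),
    ("Base + MO_p + MO_p:ELD + HCP", ["mo_s", "mo_s_x_eld", "hcp"]),
    ("Base + MO_p + MO_p:ELD + MO_p^2", ["mo_s", "mo_s_x_eld", "mo_s2"]),
]


def fit_selection_suite(breeding: pd.DataFrame, year_metrics: pd.DataFrame) -> ModelComparison:
    """Fit the nine selection-on-laying-date candidates (Poisson recruit count).

    Base fixed effects: density, clutch size, within-year-centred laying
    date, beech crop index; random intercepts: year and female.  The signed
    overlap replaces the raw one so that direction of mismatch matters.
    """
    df = selection_frame(breeding, year_metrics)
    groups = [("year", df["year"].to_numpy()), ("female", df["mother_id"].to_numpy())]
    y = df["recruits"].to_numpy(float)
    specs = [(name, SELECTION_BASE + extra) for name, extra in SELECTION_CANDIDATES]
    return _fit_suite(specs, y, df, "poisson", groups)


def fit_selection_shape_variants(
    breeding: pd.DataFrame, year_metrics: pd.DataFrame
) -> ModelComparison:
    """Extend the selection suite with curve-shape covariates.

    The two HCP candidates are refitted with the peak height replaced by the
    across-year-standardised skewness, then kurtosis, of the availability
    curve (four extra rows merged into the comparison).
    """
    base = fit_selection_suite(breeding, year_metrics)
    df = selection_frame(breeding, year_metrics)
    groups = [("year", df["year"].to_numpy()), ("female", df["mother_id"].to_numpy())]
    y = df["recruits"].to_numpy(float)
    extra = []
    for stat in ("skewness_z", "kurtosis_z"):
        tag = stat.replace("_z", "").capitalize()
        extra.append((f"Base + MD_p + MD_p:ELD + {tag}", SELECTION_BASE + ["md_p", "md_p_x_eld", stat]))
        extra.append((f"Base + MO_p + MO_p:ELD + {tag}", SELECTION_BASE + ["mo_s", "mo_s_x_eld", stat]))
    more = _fit_suite(extra, y, df, "poisson", groups)
    fits = {**base.fits, **more.fits}
    return comparison_table(fits, {**base.excluded, **more.excluded})


# ---------------------------------------------------------------------------
# Uncertainty diagnostics
# ---------------------------------------------------------------------------

def bootstrap_ci(result: MixedGLMResult, B: int = 1000, seed: int = 0) -> pd.DataFrame:
    """Parametric-bootstrap 95% CIs for the fixed coefficients.

    Simulates B response vectors from the fitted model — fresh random-effect
    draws at the estimated standard deviations, then binomial or Poisson
    sampling — refits each, and takes the 2.5/97.5 percentiles per
    coefficient.  Errors out if more than 10% of refits fail.
    """
    if B < 100:
        raise ValueError("B must be at least 100")
    model = result.model
    rng = np.random.default_rng(seed)
    eta_fix = model.X @ result.params
    draws, failures = [], 0
    for _ in range(B):
        eta = eta_fix.copy()
        for Z, sd in zip(model.Zs, result.vc_sd):
            if sd > _SD_FLOOR:
                eta += Z @ rng.normal(0.0, sd, Z.shape[1])
        eta = np.clip(eta, -_ETA_CLIP, _ETA_CLIP)
        if model.family == "binomial":
            y_sim = rng.binomial(1, expit(eta)).astype(float)
        else:
            y_sim = rng.poisson(np.exp(eta)).astype(float)
        sim = MixedGLM(
            y_sim, model.X, model.family,
            groups=list(zip(model.vc_names, model.group_codes)),
            param_names=model.param_names, name=result.name,
        )
        try:
            draws.append(sim.fit().params)
        except FitError:
            failures += 1
    if failures > 0.10 * B:
        raise FitError(f"bootstrap refit failure rate {failures / B:.1%} exceeds 10%")
    arr = np.array(draws)
    lo, hi = np.percentile(arr, [2.5, 97.5], axis=0)
    return pd.DataFrame({
        "term": result.param_names, "estimate": result.params, "lo95": lo, "hi95": hi,
    })


def vif(X: pd.DataFrame) -> pd.Series:
    """Variance inflation factor 1/(1−R²) per fixed-effect column.

    Each column is regressed (with intercept) on the remaining ones;
    perfectly collinear columns report ``inf``.
    """
    X = pd.DataFrame(X)
    if X.shape[1] < 2:
        raise ValueError("VIF needs at least 2 non-intercept columns")
    out = {}
    A = X.to_numpy(float)
    for j, col in enumerate(X.columns):
        yj = A[:, j]
        others = np.column_stack([np.ones(len(A)), np.delete(A, j, axis=1)])
        coef, *_ = np.linalg.lstsq(others, yj, rcond=None)
        resid = yj - others @ coef
        tss = float(((yj - yj.mean()) ** 2).sum())
        if tss == 0:
            out[col] = np.inf
            continue
        r2 = 1.0 - float((resid**2).sum()) / tss
        out[col] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out, name="vif")
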