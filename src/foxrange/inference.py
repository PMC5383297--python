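"""Statistical analysis of home-range size.

Log-transformed LoCoH 90% areas are modelled with additive ordinary least
squares over candidate covariate subsets, ranked by AICc.  Conventions are
chosen to reproduce R's output on identical input: natural-log response,
ML residual variance in the log-likelihood (sigma2 = RSS/n), and a
parameter count K = |slopes| + intercept + residual variance = |terms| + 2,
which is the df column printed by MuMIn-style selection tables.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    DomainError,
    InfiniteLikelihoodError,
    InsufficientDataError,
    RankDeficiencyError,
    UndefinedStatisticError,
)


@dataclass
class PairedTestResult:
    t: float
    df: int
    p: float


@dataclass
class OlsFit:
    """An additive OLS fit with the exact-likelihood bookkeeping used for AICc."""

    terms: tuple[str, ...]
    beta: np.ndarray  # intercept first, then one slope per term
    se: np.ndarray
    r2: float
    loglik: float
    K: int  # slopes + intercept + residual variance
    n: int
    rss: float

    @property
    def coefficients(self) -> pd.Series:
        return pd.Series(self.beta, index=("intercept", *self.terms))


def paired_t(a: np.ndarray, b: np.ndarray) -> PairedTestResult:
    """Paired two-sided Student t-test on matched per-animal values."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise DomainError("paired samples must be 1-d and of equal length")
    n = len(a)
    if n < 2:
        raise InsufficientDataError("paired t-test needs at least 2 pairs")
    d = a - b
    sd = d.std(ddof=1)
    if sd == 0.0:
        raise UndefinedStatisticError("zero difference variance; t undefined")
    t = float(d.mean() / (sd / math.sqrt(n)))
    p = float(2.0 * stats.t.sf(abs(t), n - 1))
    return PairedTestResult(t, n - 1, p)


def fit_ols(
    rows: pd.DataFrame, terms: tuple[str, ...], response: str = "log_area"
) -> OlsFit:
    """Ordinary least squares of ``response`` on an intercept plus ``terms``.

    Reports the exact Gaussian log-likelihood at the ML variance estimate,
    logLik = -(n/2) (log(2 pi RSS/n) + 1), and K = |terms| + 2.
    """
    y = rows[response].to_numpy(dtype=float)
    n = len(y)
    p = len(terms) + 1
    if n <= p:
        raise InsufficientDataError(f"n={n} too small for {len(terms)} terms")
    X = np.column_stack([np.ones(n)] + [rows[t].to_numpy(dtype=float) for t in terms])
    if np.linalg.matrix_rank(X) < p:
        for j in range(1, p):  # first column that adds no rank is the alias
            if np.linalg.matrix_rank(X[:, : j + 1]) < j + 1:
                raise RankDeficiencyError(
                    f"design matrix rank deficient: term {terms[j - 1]!r} is aliased"
                )
        raise RankDeficiencyError("design matrix rank deficient")
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    tss = float(((y - y.mean()) ** 2).sum())
    if rss <= 1e-12 * max(tss, 1.0):
        raise InfiniteLikelihoodError(
            "residual sum of squares is zero; Gaussian likelihood diverges"
        )
    sigma2_ml = rss / n
    loglik = -0.5 * n * (math.log(2.0 * math.pi * sigma2_ml) + 1.0)
    cov = np.linalg.inv(X.T @ X) * rss / (n - p)
    se = np.sqrt(np.diag(cov))
    r2 = 1.0 - rss / tss if tss > 0 else float("nan")
    return OlsFit(tuple(terms), beta, se, r2, loglik, len(terms) + 2, n, rss)


def aicc(loglik: float, K: int, n: int) -> float:
    """Akaike's Information Criterion with the small-sample correction."""
    if n <= K + 1:
        raise DomainError(f"AICc undefined for n={n} <= K+1={K + 1}")
    return -2.0 * loglik + 2.0 * K + 2.0 * K * (K + 1) / (n - K - 1)


def enumerate_candidates(covariates: tuple[str, ...]) -> list[tuple[str, ...]]:
    """All 2^p - 1 non-empty additive subsets, smallest first, input order kept.

    The intercept-only null model is not part of the candidate count; fit
    and report it separately for reference.
    """
    if not covariates:
        raise DomainError("need at least one covariate")
    if len(covariates) > 10:
        raise DomainError("more than 10 covariates; candidate set would explode")
    out: list[tuple[str, ...]] = []
    for r in range(1, len(covariates) + 1):
        out.extend(itertools.combinations(covariates, r))
    return out


def fit_null(rows: pd.DataFrame, response: str = "log_area") -> OlsFit:
    """Intercept-only reference model (K = 2)."""
    y = rows[response].to_numpy(dtype=float)
    n = len(y)
    rss = float(((y - y.mean()) ** 2).sum())
    if rss <= 0.0:
        raise InfiniteLikelihoodError("constant response; likelihood diverges")
    loglik = -0.5 * n * (math.log(2.0 * math.pi * rss / n) + 1.0)
    se = np.array([math.sqrt(rss / (n - 1) / n)])
    return OlsFit((), np.array([y.mean()]), se, 0.0, loglik, 2, n, rss)


def rank_models(fits: list[OlsFit]) -> pd.DataFrame:
    """AICc ranking table: delta, Akaike weights and the <=2-unit equivalence set.

    Weights are normalised over the supplied fits; the best model has
    delta exactly 0.  Mirrors the familiar df / logLik / AICc / dAICc /
    weight selection-table layout.
    """
    if not fits:
        raise DomainError("no fitted models to rank")
    rows = []
    for f in fits:
        rows.append(
            {
                "terms": " + ".join(f.terms) if f.terms else "(null)",
                "df": f.K,
                "logLik": f.loglik,
                "AICc": aicc(f.loglik, f.K, f.n),
                "R2": f.r2,
            }
        )
    table = pd.DataFrame(rows)
    table = table.sort_values("AICc", kind="stable").reset_index(drop=True)
    table["delta"] = table["AICc"] - table["AICc"].iloc[0]
    rel = np.exp(-0.5 * table["delta"].to_numpy())
    table["weight"] = rel / rel.sum()
    table["equivalent"] = table["delta"] <= 2.0
    return table


@dataclass
class ScreenResult:
    retained: list[str]
    dropped: list[str]
    report: pd.DataFrame  # pairwise r and, for flagged pairs, the arbitration


def collinearity_screen(
    rows: pd.DataFrame,
    covariates: tuple[str, ...],
    r_limit: float = 0.6,
    response: str = "log_area",
) -> ScreenResult:
    """Drop one member of every highly correlated covariate pair.

    For each pair with |Pearson r| >= r_limit, the two full models that each
    exclude one member are compared by AICc and the member whose exclusion
    gives the lower AICc is dropped (it carried less information).  A
    constant covariate has no defined correlation and is excluded with a
    warning.
    """
    if len(covariates) < 2:
        raise DomainError("collinearity screen needs at least 2 covariates")
    retained = list(covariates)
    dropped: list[str] = []
    for c in covariates:
        if rows[c].nunique() <= 1:
            warnings.warn(f"covariate {c!r} is constant; excluded from the model set")
            retained.remove(c)
            dropped.append(c)
    records = []
    for a, b in itertools.combinations([c for c in covariates if c not in dropped], 2):
        r = float(np.corrcoef(rows[a], rows[b])[0, 1])
        rec = {"a": a, "b": b, "r": r, "flagged": abs(r) >= r_limit, "dropped": None, "delta_aicc": None}
        if abs(r) >= r_limit and a in retained and b in retained:
            without_a = tuple(c for c in retained if c != a)
            without_b = tuple(c for c in retained if c != b)
            fit_wo_a = fit_ols(rows, without_a, response)
            fit_wo_b = fit_ols(rows, without_b, response)
            aicc_wo_a = aicc(fit_wo_a.loglik, fit_wo_a.K, fit_wo_a.n)
            aicc_wo_b = aicc(fit_wo_b.loglik, fit_wo_b.K, fit_wo_b.n)
            loser = a if aicc_wo_a <= aicc_wo_b else b
            retained.remove(loser)
            dropped.append(loser)
            rec["dropped"] = loser
            rec["delta_aicc"] = abs(aicc_wo_a - aicc_wo_b)
        records.append(rec)
    return ScreenResult(retained, dropped, pd.DataFrame(records))


def build_analysis_table(
    areas_km2: pd.Series,
    compositions: pd.DataFrame,
    attributes: pd.DataFrame,
) -> pd.DataFrame:
    """Assemble the per-fox modelling table from areas, composition and attributes.

    ``areas_km2`` is indexed by animal_id (LoCoH 90% areas); compositions
    carry prop_agriculture / prop_settlement / mean_elevation_m /
    centroid_latitude / zone; attributes carry sex and age_class.  The
    response is the natural log of area; sex and age are coded female=0 /
    male=1 and adult=0 / subadult=1.
    """
    if (areas_km2 <= 0).any():
        bad = areas_km2[areas_km2 <= 0].index.tolist()
        raise DomainError(f"non-positive home-range area for {bad}; log undefined")
    df = compositions.set_index("animal_id").loc[areas_km2.index].copy()
    attrs = attributes.set_index("animal_id").loc[areas_km2.index]
    return pd.DataFrame(
        {
            "animal_id": areas_km2.index,
            "log_area": np.log(areas_km2.to_numpy(dtype=float)),
            "area_km2": areas_km2.to_numpy(dtype=float),
            "elevation": df["mean_elevation_m"].to_numpy(dtype=float),
            "agriculture": df["prop_agriculture"].to_numpy(dtype=float),
            "settlement": df["prop_settlement"].to_numpy(dtype=float),
            "sex": (attrs["sex"] == "M").astype(int).to_numpy(),
            "age": (attrs["age_class"] == "subadult").astype(int).to_numpy(),
            "latitude": df["centroid_latitude"].to_numpy(dtype=float),
            "zone": df["zone"].to_numpy(),
        }
    ).reset_index(drop=True)


def summarize_cohort(
    areas: pd.DataFrame, analysis: pd.DataFrame | None = None
) -> dict[str, pd.DataFrame]:
    """Cohort summary tables.

    ``areas`` has columns animal_id, estimator, level, area_km2, sex.
    Returns a by-estimator/level table (mean, SE, min, max overall and per
    sex; SE = SD/sqrt(n), blank for n = 1) and, when an analysis table with
    zone/composition columns is given, a by-zone table of the analysis-level
    areas and covariates (mean and SD).
    """

    def agg(g: pd.DataFrame) -> pd.Series:
        n = len(g)
        a = g["area_km2"]
        return pd.Series(
            {
                "n": n,
                "mean": a.mean(),
                "se": a.std(ddof=1) / math.sqrt(n) if n > 1 else np.nan,
                "min": a.min(),
                "max": a.max(),
            }
        )

    frames = []
    for label, sub in [("all", areas)] + [
        (s, areas[areas["sex"] == s]) for s in ("F", "M")
    ]:
        if len(sub) == 0:
            continue
        t = (
            sub.groupby(["estimator", "level"])[["area_km2"]]
            .apply(agg)
            .reset_index()
        )
        t.insert(0, "group", label)
        frames.append(t)
    by_level = pd.concat(frames, ignore_index=True)

    out = {"by_estimator_level": by_level}
    if analysis is not None:
        rows = []
        for zone, g in analysis.groupby("zone"):
            for label, sub in [("all", g)] + [
                (s, g[g["sex"] == code]) for s, code in (("M", 1), ("F", 0))
            ]:
                if len(sub) == 0:
                    continue
                rows.append(
                    {
                        "zone": zone,
                        "group": label,
                        "n": len(sub),
                        "mean_area_km2": sub["area_km2"].mean(),
                        "sd_area_km2": sub["area_km2"].std(ddof=1) if len(sub) > 1 else np.nan,
                        "mean_settlement": sub["settlement"].mean(),
                        "mean_agriculture": sub["agriculture"].mean(),
                        "mean_elevation_m": sub["elevation"].mean(),
                        "sd_elevation_m": sub["elevation"].std(ddof=1) if len(sub) > 1 else np.nan,
                    }
                )
        out["by_zone"] = pd.DataFrame(rows)
    return out
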