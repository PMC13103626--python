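"""Visitation, fitness, model-comparison and soil-association statistics.

The owned arithmetic here is the availability-adjusted visitation rate,
the finite-sample corrected information criterion (AICc) with Akaike
weights, Spearman + Benjamini-Hochberg soil screening and the PCA on
standardized population-level soil variables.  Maximum-likelihood fitting
of the candidate generalized linear models is delegated to statsmodels;
repeated measurements are averaged within plant before fitting (the
documented fallback for random-intercept models, keeping the owned
AICc/weight arithmetic exact).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CandidateFit",
    "adjusted_visitation",
    "adjusted_visitation_table",
    "fruits_per_plant",
    "germination_rate",
    "aicc",
    "model_selection_table",
    "fit_candidate_set",
    "spearman_fdr",
    "soil_pca",
    "morph_frequency_table",
]

MODEL_LABELS = ("null", "color", "population", "additive", "interaction")

FAMILIES = ("gaussian", "gamma-log", "poisson", "negative binomial", "binomial")


# --------------------------------------------------------------------------
# Defined statistics

def adjusted_visitation(visits: float, minutes: float, proportion: float) -> float:
    """Availability-adjusted visitation rate: (visits/minutes)/proportion.

    A morph absent from the census (proportion 0) has no defined adjusted
    rate; NaN is returned so the row can be flagged, never silently
    dropped.
    """
    if minutes <= 0:
        raise ValueError("minutes must be > 0")
    if visits < 0:
        raise ValueError("visits must be >= 0")
    if not 0.0 <= proportion <= 1.0:
        raise ValueError("proportion must lie in [0, 1]")
    if proportion == 0.0:
        return float("nan")
    return (visits / minutes) / proportion


def adjusted_visitation_table(census: pd.DataFrame) -> pd.DataFrame:
    """Apply the adjusted-rate formula to a census table.

    Expects columns population, morph, visits, minutes, proportion.
    Adds raw_rate, adjusted_rate and a flagged_missing column for
    zero-availability rows.
    """
    required = {"population", "morph", "visits", "minutes", "proportion"}
    missing = required - set(census.columns)
    if missing:
        raise ValueError(f"census table missing columns: {sorted(missing)}")
    out = census.copy()
    out["raw_rate"] = out["visits"] / out["minutes"]
    out["adjusted_rate"] = [
        adjusted_visitation(v, m, p)
        for v, m, p in zip(out["visits"], out["minutes"], out["proportion"])
    ]
    out["flagged_missing"] = out["proportion"] == 0.0
    n_flagged = int(out["flagged_missing"].sum())
    if n_flagged:
        warnings.warn(
            f"{n_flagged} zero-availability census rows flagged as missing"
        )
    return out


def fruits_per_plant(fruits_per_inflorescence: float, n_inflorescences: float) -> int:
    """Fruits per individual: per-inflorescence count times inflorescences.

    The product is rounded half-up to the nearest integer to absorb
    per-inflorescence averages.
    """
    if fruits_per_inflorescence < 0 or n_inflorescences < 0:
        raise ValueError("inputs must be nonnegative")
    return int(math.floor(fruits_per_inflorescence * n_inflorescences + 0.5))


def germination_rate(germinated: "np.ndarray | list", sown: int = 30) -> float:
    """Mean per-fruit germination proportion for one individual."""
    counts = np.asarray(germinated, dtype=float)
    if counts.size == 0:
        raise ValueError("need at least one fruit")
    if np.any(counts < 0) or np.any(counts > sown):
        raise ValueError(f"germinated counts must lie in [0, {sown}]")
    return float(np.mean(counts / sown))


# --------------------------------------------------------------------------
# AICc and model comparison

def aicc(log_likelihood: float, k: int, n: int) -> float:
    """Finite-sample corrected AIC: -2*logLik + 2k + 2k(k+1)/(n-k-1)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n} <= k+1={k + 1}")
    return -2.0 * log_likelihood + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


@dataclass(frozen=True)
class CandidateFit:
    """One fitted candidate model, carrying its own AICc ingredients."""

    model: str
    family: str
    log_likelihood: float
    k: int
    n: int


def model_selection_table(candidates: "list[CandidateFit]") -> pd.DataFrame:
    """AICc ranking with Akaike weights.

    Rows are sorted ascending by AICc; weight_i = exp(-delta_i/2)
    normalized over the candidate set; rows with delta < 2 are flagged
    equally plausible.  All candidates must share the same n.
    """
    if not candidates:
        raise ValueError("no candidates to compare")
    ns = {c.n for c in candidates}
    if len(ns) > 1:
        raise ValueError(f"candidates fitted to differing n: {sorted(ns)}")
    rows = pd.DataFrame(
        {
            "model": [c.model for c in candidates],
            "family": [c.family for c in candidates],
            "log_likelihood": [c.log_likelihood for c in candidates],
            "k": [c.k for c in candidates],
            "n": [c.n for c in candidates],
        }
    )
    rows["aicc"] = [aicc(c.log_likelihood, c.k, c.n) for c in candidates]
    rows["delta_aicc"] = rows["aicc"] - rows["aicc"].min()
    rel = np.exp(-rows["delta_aicc"] / 2.0)
    rows["weight"] = rel / rel.sum()
    rows["equally_plausible"] = rows["delta_aicc"] < 2.0
    return rows.sort_values("aicc", ignore_index=True)


def _design_matrix(df: pd.DataFrame, model: str) -> pd.DataFrame:
    """Treatment-coded design for one candidate model."""
    n = len(df)
    X = pd.DataFrame({"intercept": np.ones(n)}, index=df.index)
    parts = []
    if model in ("color", "additive", "interaction"):
        parts.append(pd.get_dummies(df["morph"], prefix="morph", drop_first=True))
    if model in ("population", "additive", "interaction"):
        parts.append(
            pd.get_dummies(df["population"], prefix="pop", drop_first=True)
        )
    for part in parts:
        X = pd.concat([X, part.astype(float)], axis=1)
    if model == "interaction":
        m = pd.get_dummies(df["morph"], prefix="morph", drop_first=True).astype(float)
        p = pd.get_dummies(df["population"], prefix="pop", drop_first=True).astype(float)
        for mc in m.columns:
            for pc in p.columns:
                col = m[mc] * p[pc]
                if col.sum() > 0:  # drop empty morph x population cells
                    X[f"{mc}:{pc}"] = col
    # guard against rank deficiency (e.g. a morph nested in one population)
    Xv = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(Xv)
    if rank < X.shape[1]:
        keep = [0]
        for j in range(1, X.shape[1]):
            trial = Xv[:, keep + [j]]
            if np.linalg.matrix_rank(trial) > len(keep):
                keep.append(j)
        X = X.iloc[:, keep]
    return X


def _fit_one(y, X: pd.DataFrame, family: str):
    """Return (log_likelihood, k) for one ML fit; k counts the dispersion
    or variance parameter where one is estimated (gaussian, gamma,
    negative binomial)."""
    Xv = X.to_numpy(dtype=float)
    p = Xv.shape[1]
    if family == "gaussian":
        res = sm.OLS(np.asarray(y, dtype=float), Xv).fit()
        return float(res.llf), p + 1
    if family == "gamma-log":
        fam = sm.families.Gamma(link=sm.families.links.Log())
        res = sm.GLM(np.asarray(y, dtype=float), Xv, family=fam).fit(scale="X2")
        return float(res.llf), p + 1
    if family == "poisson":
        res = sm.GLM(np.asarray(y, dtype=float), Xv, family=sm.families.Poisson()).fit()
        return float(res.llf), p
    if family == "negative binomial":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.NegativeBinomial(np.asarray(y, dtype=float), Xv).fit(
                disp=False, maxiter=200
            )
        return float(res.llf), p + 1
    if family == "binomial":
        endog = np.asarray(y, dtype=float)  # columns: successes, failures
        if endog.ndim != 2 or endog.shape[1] != 2:
            raise ValueError("binomial response must be (successes, failures)")
        res = sm.GLM(endog, Xv, family=sm.families.Binomial()).fit()
        return float(res.llf), p
    raise ValueError(f"unknown family {family!r}; expected one of {FAMILIES}")


def fit_candidate_set(
    table: pd.DataFrame,
    response: str,
    family: str,
    failures: str | None = None,
) -> "list[CandidateFit]":
    """Fit the five-candidate model set to one response.

    Candidates: intercept-only, morph-only, population-only, additive,
    and morph x population interaction.  ``table`` must carry ``morph``
    and ``population`` columns plus the response (for the binomial
    family, ``failures`` names the complement-count column).  Rows with
    missing response are dropped with a warning; non-estimable
    candidates (a factor with fewer than two observed levels) are
    excluded with a warning.
    """
    for col in ("morph", "population"):
        if col not in table.columns:
            raise ValueError(f"table lacks required column {col!r}")
    cols = [response] + ([failures] if failures else [])
    df = table.dropna(subset=cols)
    dropped = len(table) - len(df)
    if dropped:
        warnings.warn(f"{dropped} rows with missing {response!r} excluded from fits")
    if df.empty:
        raise ValueError(f"no usable rows for response {response!r}")
    y = df[[response, failures]] if failures else df[response]

    fits: list[CandidateFit] = []
    for model in MODEL_LABELS:
        need_morph = model in ("color", "additive", "interaction")
        need_pop = model in ("population", "additive", "interaction")
        if (need_morph and df["morph"].nunique() < 2) or (
            need_pop and df["population"].nunique() < 2
        ):
            warnings.warn(f"candidate {model!r} non-estimable; excluded")
            continue
        X = _design_matrix(df, model)
        try:
            llf, k = _fit_one(y, X, family)
        except Exception as exc:  # noqa: BLE001 - surface, don't hide
            warnings.warn(f"candidate {model!r} failed to fit: {exc}")
            continue
        fits.append(CandidateFit(model, family, llf, k, len(df)))
    return fits


# --------------------------------------------------------------------------
# Soil association stage

def spearman_fdr(
    soil_means: pd.DataFrame, morph_freqs: pd.DataFrame
) -> pd.DataFrame:
    """Spearman rho per (soil variable, morph) with BH-adjusted p values.

    Both inputs are population-level tables indexed identically (one row
    per population, >= 3 rows).  Constant variables yield NaN rho and are
    flagged rather than dropped.
    """
    if len(soil_means) < 3:
        raise ValueError("need at least 3 populations")
    if len(soil_means) != len(morph_freqs):
        raise ValueError("soil and morph tables must have one aligned row per population")
    rows = []
    for var in soil_means.columns:
        for morph in morph_freqs.columns:
            x = soil_means[var].to_numpy(dtype=float)
            y = morph_freqs[morph].to_numpy(dtype=float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                rows.append(
                    {"soil_variable": var, "morph": morph, "rho": np.nan,
                     "p_value": np.nan, "flagged_constant": True}
                )
                continue
            rho, p = sps.spearmanr(x, y)
            rows.append(
                {"soil_variable": var, "morph": morph, "rho": float(rho),
                 "p_value": float(p), "flagged_constant": False}
            )
    out = pd.DataFrame(rows)
    mask = ~out["p_value"].isna()
    adj = np.full(len(out), np.nan)
    if mask.any():
        adj[mask.to_numpy()] = multipletests(
            out.loc[mask, "p_value"], method="fdr_bh"
        )[1]
    out["p_adjusted"] = adj
    return out


def soil_pca(soil_means: pd.DataFrame) -> "tuple[pd.DataFrame, np.ndarray]":
    """PCA of standardized population-level soil variables.

    Returns (loadings, explained_proportions).  Variables are centered
    and scaled to unit variance; components are eigenvectors of the
    correlation structure ordered by decreasing variance, with the
    largest-magnitude loading of each component made positive.
    Proportions sum to 1.
    """
    if soil_means.isna().any().any():
        raise ValueError("missing values in soil table; impute upstream explicitly")
    if len(soil_means) < 3 or soil_means.shape[1] < 2:
        raise ValueError("need >= 3 populations and >= 2 variables")
    X = soil_means.to_numpy(dtype=float)
    X = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    if not np.all(np.isfinite(X)):
        raise ValueError("constant soil variable; cannot standardize")
    corr = np.cov(X, rowvar=False, ddof=1)
    eigvals, eigvecs = np.linalg.eigh(corr)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]
    for j in range(eigvecs.shape[1]):
        i = int(np.argmax(np.abs(eigvecs[:, j])))
        if eigvecs[i, j] < 0:
            eigvecs[:, j] *= -1.0
    proportions = eigvals / eigvals.sum()
    loadings = pd.DataFrame(
        eigvecs,
        index=soil_means.columns,
        columns=[f"PC{j + 1}" for j in range(eigvecs.shape[1])],
    )
    return loadings, proportions


def morph_frequency_table(
    plants: pd.DataFrame, populations: "list[str] | None" = None
) -> pd.DataFrame:
    """Per-population morph counts and percentages.

    Plants without a morph label are counted under an explicit
    ``unknown`` column; percentages sum to 100 per population.  Expected
    populations with zero plants get a zero row and a warning.
    """
    if "population" not in plants.columns:
        raise ValueError("plant table lacks a population column")
    df = plants.copy()
    df["morph"] = df["morph"].fillna("unknown") if "morph" in df else "unknown"
    counts = (
        df.groupby(["population", "morph"]).size().unstack(fill_value=0).sort_index()
    )
    if populations is not None:
        counts = counts.reindex(populations, fill_value=0)
    totals = counts.sum(axis=1)
    empty = totals[totals == 0].index.tolist()
    if empty:
        warnings.warn(f"populations with no plants: {empty}")
    pct = counts.div(totals.replace(0, np.nan), axis=0) * 100.0
    pct = pct.fillna(0.0).add_suffix("_pct")
    out = pd.concat([counts, pct], axis=1)
    out.insert(0, "n_plants", totals)
    return out.reset_index()
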