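"""Posterior output to reported genetic quantities.

Heritabilities and genetic correlations are computed sample-wise on the
liability scale — ``h2 = g/(g+1)`` with residual variance fixed at 1, and
``r_g = g_he / sqrt(g_h g_e)`` — and then summarized, so the reported
posterior mean is the mean of the transformed samples, not the transform
of the posterior-mean variance.  Prevalence, phenotypic trends, genetic
trends (mean EBV by birth year, loess-smoothed) and the four-path
(SS/SD/DS/DD) selection-response decomposition follow the registry's
conventions: hips 5-7 dysplastic, 1-3 non-dysplastic, 4 borderline
(counted in denominators only); elbows 2-4 dysplastic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import PosteriorChain, extract_ebv, pmcmc
from .pedigree import Pedigree, PATH_CATEGORIES

logger = logging.getLogger(__name__)

DYSPLASTIC = {"hip": (5, 6, 7), "elbow": (2, 3, 4)}
NON_DYSPLASTIC_HIP = (1, 2, 3)
BORDERLINE_HIP = (4,)


# --------------------------------------------------------------------------
# scalar transforms
# --------------------------------------------------------------------------

def heritability(g):
    """Liability-scale heritability g/(g+1); accepts scalars or samples."""
    g = np.asarray(g, float)
    if np.any(g <= 0):
        raise ValueError("genetic variance must be positive")
    out = g / (g + 1.0)
    return float(out) if out.ndim == 0 else out


def genetic_correlation(g_h, g_e, g_he):
    """Genetic correlation g_he / sqrt(g_h * g_e); sample-wise capable."""
    g_h = np.asarray(g_h, float)
    g_e = np.asarray(g_e, float)
    g_he = np.asarray(g_he, float)
    if np.any(g_h <= 0) or np.any(g_e <= 0):
        raise ValueError("genetic variances must be positive")
    out = g_he / np.sqrt(g_h * g_e)
    return float(out) if out.ndim == 0 else out


@dataclass
class GeneticSummary:
    """Heritabilities, genetic correlation, and the per-animal EBV table."""

    h2_mean: dict
    h2_sd: dict
    rg_mean: float | None
    rg_sd: float | None
    rhe_mean: float | None
    ebv: pd.DataFrame

    def to_dict(self) -> dict:
        return {
            "heritability": {t: {"mean": self.h2_mean[t], "sd": self.h2_sd[t]}
                             for t in self.h2_mean},
            "genetic_correlation": None if self.rg_mean is None
            else {"mean": self.rg_mean, "sd": self.rg_sd},
            "residual_correlation": self.rhe_mean,
        }


def summarize_genetics(chain: PosteriorChain) -> GeneticSummary:
    """Sample-wise posterior summaries of h2 (per trait) and r_g."""
    h2_mean, h2_sd = {}, {}
    for m, t in enumerate(chain.traits):
        h2 = heritability(chain.g_samples[:, m, m])
        h2_mean[t] = float(np.mean(h2))
        h2_sd[t] = float(np.std(h2, ddof=1))
    rg_mean = rg_sd = rhe_mean = None
    if len(chain.traits) == 2:
        rg = genetic_correlation(chain.g_samples[:, 0, 0],
                                 chain.g_samples[:, 1, 1],
                                 chain.g_samples[:, 0, 1])
        rg_mean = float(np.mean(rg))
        rg_sd = float(np.std(rg, ddof=1))
        if chain.rhe_samples is not None:
            rhe_mean = float(np.mean(chain.rhe_samples))
    return GeneticSummary(h2_mean, h2_sd, rg_mean, rg_sd, rhe_mean,
                          extract_ebv(chain))


# --------------------------------------------------------------------------
# prevalence and phenotypic trends
# --------------------------------------------------------------------------

def prevalence(records: pd.DataFrame, trait: str) -> float:
    """Percent of scored dogs in the dysplastic categories.

    Hips: scores 5-7 over all scored dogs (borderline 4 counts in the
    denominator only).  Elbows: scores 2-4 over all scored dogs.
    """
    scores = pd.to_numeric(records[f"{trait}_score"], errors="coerce").dropna()
    if scores.empty:
        raise ValueError(f"no scored records for trait {trait!r}")
    return 100.0 * scores.isin(DYSPLASTIC[trait]).mean()


def hip_breakdown(records: pd.DataFrame) -> dict:
    """Percent non-dysplastic (1-3), borderline (4) and dysplastic (5-7)."""
    scores = pd.to_numeric(records["hip_score"], errors="coerce").dropna()
    if scores.empty:
        raise ValueError("no scored hip records")
    return {
        "non_dysplastic": 100.0 * scores.isin(NON_DYSPLASTIC_HIP).mean(),
        "borderline": 100.0 * scores.isin(BORDERLINE_HIP).mean(),
        "dysplastic": 100.0 * scores.isin(DYSPLASTIC["hip"]).mean(),
    }


@dataclass
class TrendSeries:
    """Per-birth-year series (n, value) with an optional smooth."""

    table: pd.DataFrame   # columns: year, n, value [, smooth]
    kind: str             # "phenotypic" or "genetic"
    trait: str | None = None


def phenotypic_trend(records: pd.DataFrame, birth_years: pd.Series,
                     trait: str, category: int = 1) -> TrendSeries:
    """Proportion of dogs scored in ``category`` (1 = excellent/normal) per
    birth year.  ``birth_years`` is indexed by animal id."""
    df = records.copy()
    df["birth_year"] = df["animal"].astype(str).map(birth_years)
    df["score"] = pd.to_numeric(df[f"{trait}_score"], errors="coerce")
    df = df.dropna(subset=["birth_year", "score"])
    grouped = df.groupby(df["birth_year"].astype(int))["score"]
    table = pd.DataFrame({
        "year": grouped.size().index,
        "n": grouped.size().to_numpy(),
        "value": grouped.apply(lambda s: float((s == category).mean())).to_numpy(),
    }).reset_index(drop=True)
    return TrendSeries(table=table, kind="phenotypic", trait=trait)


# --------------------------------------------------------------------------
# loess
# --------------------------------------------------------------------------

def loess_smooth(x, y, span: float = 0.75, degree: int = 2) -> np.ndarray:
    """Locally weighted polynomial regression (tricube weights).

    Evaluated at the input points; ``span`` is the fraction of points in
    each local neighbourhood.  No robustness iterations.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    if n <= degree + 1:
        return y.copy()
    k = max(int(np.ceil(span * n)), degree + 2)
    k = min(k, n)
    out = np.empty(n)
    for i in range(n):
        d = np.abs(x - x[i])
        h = np.sort(d)[k - 1]
        w = np.clip(1.0 - (d / max(h, 1e-12)) ** 3, 0.0, None) ** 3
        use = w > 0
        xm = x[use] - x[i]
        cols = [np.ones(xm.size)]
        for dgr in range(1, degree + 1):
            cols.append(xm ** dgr)
        Xl = np.column_stack(cols)
        sw = np.sqrt(w[use])
        coef, *_ = np.linalg.lstsq(Xl * sw[:, None], y[use] * sw, rcond=None)
        out[i] = coef[0]
    return out


# --------------------------------------------------------------------------
# genetic trend and four-path decomposition
# --------------------------------------------------------------------------

def _ebv_frame(ebvs, trait: str | None) -> pd.Series:
    """Normalize EBV input (long frame from extract_ebv, or a Series indexed
    by animal id) to a Series of one value per animal."""
    if isinstance(ebvs, pd.Series):
        s = ebvs.copy()
        s.index = s.index.astype(str)
        return s
    df = ebvs
    if trait is not None and "trait" in df.columns:
        df = df[df["trait"] == trait]
    return pd.Series(df["ebv"].to_numpy(), index=df["animal"].astype(str))


def genetic_trend(ebvs, ped: Pedigree, trait: str | None = None,
                  span: float = 0.75) -> TrendSeries:
    """Arithmetic mean EBV of all animals per year of birth, loess-smoothed.

    All pedigree animals with a known birth year contribute, phenotyped or
    not; animals without a birth year are excluded (count logged).  A
    population improving over time shows a negative slope under this
    coding (lower liability = sounder joints).
    """
    values = _ebv_frame(ebvs, trait)
    by = pd.Series(ped.birth_year, index=pd.Index(ped.ids, dtype=object))
    df = pd.DataFrame({"ebv": values, "year": by.reindex(values.index)})
    missing = int(df["year"].isna().sum())
    if missing:
        logger.info("genetic_trend: excluded %d animals with unknown birth year",
                    missing)
    df = df.dropna(subset=["year", "ebv"])
    grouped = df.groupby(df["year"].astype(int))["ebv"]
    table = pd.DataFrame({
        "year": grouped.mean().index,
        "n": grouped.size().to_numpy(),
        "value": grouped.mean().to_numpy(),
    }).reset_index(drop=True)
    if len(table) > 1:
        table["smooth"] = loess_smooth(table["year"].to_numpy(float),
                                       table["value"].to_numpy(), span=span)
    return TrendSeries(table=table, kind="genetic", trait=trait)


@dataclass
class FourPathSeries:
    """Mean EBV per birth year within each grand-parental category, with a
    quadratic OLS fit in (mean-centered) birth year per category."""

    table: pd.DataFrame           # columns: category, year, n, mean_ebv
    fits: dict                    # category -> {intercept, linear, quadratic, year_center}


def four_path(ebvs, ped: Pedigree, trait: str | None = None) -> FourPathSeries:
    """Four-path decomposition of the selection history.

    For each of SS, SD, DS, DD the unweighted mean EBV of the member
    animals per year of birth, plus an ordinary-least-squares quadratic fit
    with birth year (centered at its mean) as the independent variable.
    Empty categories are omitted with a warning; a fit needs at least 3
    distinct years.
    """
    values = _ebv_frame(ebvs, trait)
    paths = ped.grandparent_paths()
    by = pd.Series(ped.birth_year, index=pd.Index(ped.ids, dtype=object))
    rows = []
    fits = {}
    for catname in PATH_CATEGORIES:
        members = sorted(paths[catname])
        if not members:
            logger.warning("four_path: category %s is empty", catname)
            continue
        df = pd.DataFrame({
            "ebv": values.reindex(members),
            "year": by.reindex(members),
        }).dropna()
        grouped = df.groupby(df["year"].astype(int))["ebv"]
        for year, mean in grouped.mean().items():
            rows.append({"category": catname, "year": int(year),
                         "n": int(grouped.size()[year]), "mean_ebv": float(mean)})
        years = grouped.mean().index.to_numpy(float)
        means = grouped.mean().to_numpy()
        if years.size >= 3:
            c = years.mean()
            Xq = np.column_stack([np.ones_like(years), years - c, (years - c) ** 2])
            coef, *_ = np.linalg.lstsq(Xq, means, rcond=None)
            fits[catname] = {"intercept": float(coef[0]), "linear": float(coef[1]),
                             "quadratic": float(coef[2]), "year_center": float(c)}
    table = pd.DataFrame(rows, columns=["category", "year", "n", "mean_ebv"])
    return FourPathSeries(table=table, fits=fits)


def sire_dam_contrast(ebvs, ped: Pedigree, trait: str | None = None,
                      n_perm: int = 2000, seed: int = 0) -> dict:
    """Permutation comparison of sire-path vs dam-path mean EBV.

    Compares mean EBV of SS∪SD against DS∪DD animals by label permutation.
    This is an interpretation of "which parental path contributed more",
    not a test stated by the registry analysis itself.
    """
    values = _ebv_frame(ebvs, trait)
    paths = ped.grandparent_paths()
    sire_side = sorted(paths["SS"] | paths["SD"])
    dam_side = sorted((paths["DS"] | paths["DD"]) - set(sire_side))
    xs = values.reindex(sire_side).dropna().to_numpy()
    xd = values.reindex(dam_side).dropna().to_numpy()
    if xs.size == 0 or xd.size == 0:
        raise ValueError("both parental paths need members with EBVs")
    obs = float(xs.mean() - xd.mean())
    pooled = np.concatenate([xs, xd])
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        rng.shuffle(pooled)
        stat = pooled[: xs.size].mean() - pooled[xs.size:].mean()
        if abs(stat) >= abs(obs):
            count += 1
    return {"difference": obs, "p_value": (count + 1) / (n_perm + 1),
            "n_sire_path": int(xs.size), "n_dam_path": int(xd.size)}


# --------------------------------------------------------------------------
# fixed-effect reporting and breed filtering
# --------------------------------------------------------------------------

def sex_age_report(chain: PosteriorChain, alpha: float = 0.05) -> pd.DataFrame:
    """Male-minus-female contrast and age slope per trait with pMCMC.

    A negative sex contrast means males have more favorable (lower
    liability) evaluations.  Effects are flagged significant when
    pMCMC < alpha; degenerate (constant) chains are flagged with a warning
    column rather than a spurious significance call.
    """
    rows = []
    fixed = chain.fixed_series()
    for t in chain.traits:
        for effect, key in (("sex_MvsF", f"{t}:sexM"), ("age_slope", f"{t}:age")):
            x = np.asarray(fixed[key], float)
            degenerate = bool(np.std(x) == 0.0)
            p = pmcmc(x)
            rows.append({
                "trait": t, "effect": effect,
                "estimate": float(np.mean(x)),
                "sd": float(np.std(x, ddof=1)) if x.size > 1 else 0.0,
                "pmcmc": p,
                "significant": (not degenerate) and p < alpha,
                "degenerate": degenerate,
            })
    return pd.DataFrame(rows)


def breed_filter(counts: pd.DataFrame, min_hip: int = 1000,
                 min_elbow: int = 500) -> list:
    """Breeds with MORE THAN ``min_hip`` hip and ``min_elbow`` elbow records
    (strict inequalities).  ``counts`` has columns breed, hip_count,
    elbow_count."""
    ok = (counts["hip_count"] > min_hip) & (counts["elbow_count"] > min_elbow)
    return list(counts.loc[ok, "breed"])
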