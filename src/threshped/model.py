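"""Bayesian threshold (probit liability) animal model for ordinal joint scores.

The observable for each dog is an ordered category — hips scored 1
(excellent) through 7 (severe), elbows 1 (normal) through 4 (grade III
degenerative joint disease).  The model places an unobserved Gaussian
liability behind each score,

    l = mu + sex + beta * age + year + a_animal + e,

where ``a`` is the additive genetic effect with covariance ``G0 (x) A``
(``A`` the pedigree numerator relationship matrix) and the residual
variance is fixed at 1 per trait, the standard identification for probit
threshold models.  Cutpoints partition the liability scale into the
observed categories; the first cutpoint is pinned at 0 (the intercept is
free).  For dogs scored on both joints the residuals are correlated with
coefficient ``r_he``, so the bivariate model also estimates a residual
correlation from doubly-observed dogs.

Inference is by Gibbs sampling with latent-liability augmentation:

1. per trait, cutpoints move by random-walk Metropolis-Hastings with the
   own-trait liabilities integrated out, after which the liabilities are
   redrawn from truncated normals between their category's cutpoints
   (conditioning on the other trait's liability through ``r_he``);
2. fixed effects and animal effects are refreshed in one blocked
   single-site sweep through the sparse mixed-model structure
   (:mod:`threshped._gibbs`);
3. ``G0`` is drawn from its conjugate inverse-Wishart conditional with
   scale ``V*nu + a' A^-1 a`` and degrees of freedom ``nu + n_animals``;
4. the residual covariance moves by Metropolis-Hastings (conjugate where
   possible), proposals leaving R0 non-positive-definite rejected.

A note on identification: reported samples always satisfy the probit
convention — residual variance 1 per trait, first cutpoint 0, intercept
free.  Internally, however, traits with three or more categories are
sampled in the equivalent parameterization that anchors the first TWO
cutpoints and lets the residual variance float.  With unit residuals and
every interior cutpoint free, the liability scale rides a near-flat ridge
(flat cutpoint priors put growing volume at larger scales), which inflates
variance components; anchoring two cutpoints removes the ridge.  Stored
samples are rescaled to the unit-residual scale, under which every
reported quantity (h2 = g/(g+r), correlations, EBV rankings) is invariant.

Defaults follow a 100,000-round chain with 20,000 burn-in and thinning
interval 20 (4,000 stored samples), a diffuse normal prior (variance e^10)
on fixed effects, and inverse-Wishart ``nu = 0.002`` on ``G0`` and the
residual components.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

from ._gibbs import animal_scan
from .pedigree import Pedigree, IntegrityError

logger = logging.getLogger(__name__)

TRAITS = ("hip", "elbow")
N_CATEGORIES = {"hip": 7, "elbow": 4}
MIN_AGE_MONTHS = 24


class ConfigError(ValueError):
    """Inconsistent chain or model configuration."""


class DegenerateDataError(ValueError):
    """Records cannot identify the model (e.g. a single observed category)."""


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ScoreRecord:
    """One dog's evaluation: covariates plus optional ordinal scores."""

    animal_id: str
    sex: str
    age_months: int
    eval_year: int
    hip_score: int | None = None
    elbow_score: int | None = None


@dataclass
class ModelSpec:
    """Which traits are fitted and how the fixed effects are parameterized.

    Sex enters as a male-minus-female contrast (female reference), age as a
    linear regression on age in months (centered at the data mean for
    conditioning), and year of evaluation as a categorical effect with the
    first observed year as reference.
    """

    traits: tuple = TRAITS
    n_categories: dict = field(default_factory=lambda: dict(N_CATEGORIES))

    def __post_init__(self):
        self.traits = tuple(self.traits)
        for t in self.traits:
            if t not in self.n_categories:
                raise ConfigError(f"no category count given for trait {t!r}")


@dataclass
class PriorSpec:
    """Priors: diffuse normals on fixed effects, inverse-Wishart on G0.

    ``nu`` is the inverse-Wishart degree-of-belief parameter; the prior has
    mode ``V * nu / (nu + 2)`` and small ``nu`` (default 0.002) makes it
    effectively flat over the variances.  Residual variances are fixed at
    1.0 per trait; the residual correlation carries the same
    inverse-Wishart density restricted to unit-diagonal R0.
    """

    fixed_effect_variance: float = math.e ** 10
    V: np.ndarray | None = None          # IW scale parameter; identity if None
    nu: float = 0.002

    def scale_matrix(self, dim: int) -> np.ndarray:
        V = np.eye(dim) if self.V is None else np.atleast_2d(np.asarray(self.V, float))
        if V.shape != (dim, dim):
            raise ConfigError(f"prior V has shape {V.shape}, expected {(dim, dim)}")
        if self.nu <= 0:
            raise ConfigError("inverse-Wishart nu must be positive")
        return V


@dataclass
class ChainConfig:
    total_iterations: int = 100_000
    burn_in: int = 20_000
    thin: int = 20
    seed: int = 0

    def __post_init__(self):
        if self.burn_in >= self.total_iterations:
            raise ConfigError("burn_in must be smaller than total_iterations")
        if self.thin < 1:
            raise ConfigError("thin must be >= 1")

    @property
    def n_stored(self) -> int:
        return stored_samples(self.total_iterations, self.burn_in, self.thin)


# --------------------------------------------------------------------------
# small, exactly-testable operations
# --------------------------------------------------------------------------

def stored_samples(total: int, burn_in: int, thin: int) -> int:
    """Number of stored draws for a (total, burn-in, thin) schedule.

    The default schedule (100,000 / 20,000 / 20) stores 4,000 samples.
    """
    if burn_in >= total:
        raise ConfigError("burn_in must be smaller than total iterations")
    if thin < 1:
        raise ConfigError("thin must be >= 1")
    return (total - burn_in) // thin


def iw_mode(V, nu: float):
    """Mode ``V * nu / (nu + 2)`` of the scalar inverse-Wishart prior."""
    if nu <= 0:
        raise ConfigError("inverse-Wishart nu must be positive")
    return np.asarray(V) * nu / (nu + 2.0) if np.ndim(V) else V * nu / (nu + 2.0)


def derive_eval_year(birth_date: str, age_months: int) -> int:
    """Calendar year of (birth date + age in months).

    ``birth_date`` is ISO ``YYYY-MM`` or ``YYYY-MM-DD``.
    """
    s = str(birth_date).strip()
    try:
        year = int(s[:4])
        month = int(s[5:7]) if len(s) >= 7 else 1
    except ValueError as exc:
        raise ValueError(f"unparseable birth date {birth_date!r}") from exc
    if not 1 <= month <= 12:
        raise ValueError(f"unparseable birth date {birth_date!r}")
    return year + (month - 1 + int(age_months)) // 12


def filter_records(records: pd.DataFrame, min_age_months: int = MIN_AGE_MONTHS) -> pd.DataFrame:
    """Keep evaluations of dogs at least ``min_age_months`` old (default 24).

    The boundary is inclusive.  Dropped counts are logged so the filtering
    step stays auditable.
    """
    keep = records["age_months"].astype(float) >= min_age_months
    dropped = int((~keep).sum())
    if dropped:
        logger.info("filter_records: dropped %d of %d records under %d months",
                    dropped, len(records), min_age_months)
    out = records.loc[keep].reset_index(drop=True)
    if out.empty:
        raise DegenerateDataError("no records remain after the age filter")
    return out


def add_eval_year(records: pd.DataFrame) -> pd.DataFrame:
    """Ensure an ``eval_year`` column, deriving it from birth_date + age.

    Records without a resolvable birth date are excluded (and counted in
    the log), matching the derivation of year-of-evaluation from date of
    birth and age at diagnosis.
    """
    out = records.copy()
    if "eval_year" in out.columns and out["eval_year"].notna().all():
        out["eval_year"] = out["eval_year"].astype(int)
        return out
    if "birth_date" not in out.columns:
        raise ValueError("records need either eval_year or birth_date")
    ok = out["birth_date"].notna() & (out["birth_date"].astype(str).str.len() >= 4)
    if (~ok).any():
        logger.warning("add_eval_year: excluding %d records without birth date",
                       int((~ok).sum()))
        out = out.loc[ok].reset_index(drop=True)
    out["eval_year"] = [
        derive_eval_year(b, a) for b, a in zip(out["birth_date"], out["age_months"])
    ]
    return out


def load_records(path) -> pd.DataFrame:
    """Read an evaluation-record table (CSV, blank scores = missing)."""
    df = pd.read_csv(path, dtype={"animal": str, "sex": str, "birth_date": str})
    for t in TRAITS:
        col = f"{t}_score"
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    return df


def pmcmc(samples: np.ndarray) -> float:
    """Twice the smaller tail proportion of a posterior sample around zero.

    The Bayesian analogue of a two-sided p-value used to call fixed-effect
    contrasts significant.
    """
    x = np.asarray(samples, float)
    return 2.0 * min(float(np.mean(x > 0)), float(np.mean(x < 0)))


# --------------------------------------------------------------------------
# posterior container
# --------------------------------------------------------------------------

@dataclass
class PosteriorChain:
    """Thinned post-burn-in samples from one Gibbs chain.

    Animal effects are storage-reduced: running mean and SD per animal and
    trait are always kept; full animal-effect samples only on request.
    """

    traits: tuple
    n_categories: dict
    config: ChainConfig
    fixed_names: list
    age_center: float
    g_samples: np.ndarray            # (S, T, T)
    rhe_samples: np.ndarray | None   # (S,) for bivariate fits
    beta_samples: np.ndarray         # (S, T, p)
    cut_samples: dict                # trait -> (S, K-1) interior boundaries
    animal_ids: list
    ebv_mean: np.ndarray             # (n_ped, T)
    ebv_sd: np.ndarray               # (n_ped, T)
    acceptance: dict
    a_samples: np.ndarray | None = None
    #: posterior-mean latent liabilities per record/trait (reporting scale);
    #: in-memory only, used for generative-consistency checks
    liab_mean: np.ndarray | None = None
    record_animals: list | None = None

    @property
    def n_stored(self) -> int:
        return self.g_samples.shape[0]

    def variance_series(self) -> dict:
        out = {}
        for m, t in enumerate(self.traits):
            out[f"g_{t}"] = self.g_samples[:, m, m]
        if len(self.traits) == 2:
            out["g_he"] = self.g_samples[:, 0, 1]
            if self.rhe_samples is not None:
                out["r_he"] = self.rhe_samples
        return out

    def fixed_series(self) -> dict:
        out = {}
        for m, t in enumerate(self.traits):
            for j, name in enumerate(self.fixed_names):
                out[f"{t}:{name}"] = self.beta_samples[:, m, j]
        return out

    def cutpoint_series(self) -> dict:
        out = {}
        for t in self.traits:
            cuts = self.cut_samples[t]
            for j in range(cuts.shape[1]):
                out[f"{t}:cut{j + 1}"] = cuts[:, j]
        return out

    def all_series(self) -> dict:
        return {**self.variance_series(), **self.fixed_series(), **self.cutpoint_series()}

    def to_long(self) -> pd.DataFrame:
        cfg = self.config
        iters = cfg.burn_in + cfg.thin * (np.arange(self.n_stored) + 1)
        frames = []
        for name, series in self.all_series().items():
            frames.append(pd.DataFrame(
                {"iteration": iters, "parameter": name, "value": series}))
        return pd.concat(frames, ignore_index=True)

    # -- persistence -------------------------------------------------------
    def save(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.to_long().to_csv(outdir / "samples.csv", index=False)
        extract_ebv(self).to_csv(outdir / "ebv.csv", index=False)
        meta = {
            "traits": list(self.traits),
            "n_categories": {t: int(self.n_categories[t]) for t in self.traits},
            "config": {
                "total_iterations": self.config.total_iterations,
                "burn_in": self.config.burn_in,
                "thin": self.config.thin,
                "seed": self.config.seed,
            },
            "fixed_names": self.fixed_names,
            "age_center": self.age_center,
            "acceptance": self.acceptance,
            "n_stored": self.n_stored,
        }
        (outdir / "metadata.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, outdir) -> "PosteriorChain":
        outdir = Path(outdir)
        meta = json.loads((outdir / "metadata.json").read_text())
        long = pd.read_csv(outdir / "samples.csv")
        wide = long.pivot(index="iteration", columns="parameter", values="value")
        traits = tuple(meta["traits"])
        T = len(traits)
        S = wide.shape[0]
        g = np.zeros((S, T, T))
        for m, t in enumerate(traits):
            g[:, m, m] = wide[f"g_{t}"].to_numpy()
        rhe = None
        if T == 2:
            g[:, 0, 1] = g[:, 1, 0] = wide["g_he"].to_numpy()
            if "r_he" in wide:
                rhe = wide["r_he"].to_numpy()
        fixed_names = meta["fixed_names"]
        beta = np.zeros((S, T, len(fixed_names)))
        for m, t in enumerate(traits):
            for j, name in enumerate(fixed_names):
                beta[:, m, j] = wide[f"{t}:{name}"].to_numpy()
        cuts = {}
        for t in traits:
            K = meta["n_categories"][t]
            cuts[t] = np.column_stack(
                [wide[f"{t}:cut{j + 1}"].to_numpy() for j in range(K - 1)])
        ebv = pd.read_csv(outdir / "ebv.csv", dtype={"animal": str})
        # per-trait blocks share one animal ordering (the pedigree's
        # topological order) which must be preserved
        blocks = {t: ebv[ebv["trait"] == t] for t in traits}
        animal_ids = list(blocks[traits[0]]["animal"])
        ebv_mean = np.column_stack([blocks[t]["ebv"].to_numpy() for t in traits])
        ebv_sd = np.column_stack([blocks[t]["ebv_sd"].to_numpy() for t in traits])
        cfg = ChainConfig(**meta["config"])
        return cls(traits=traits, n_categories=meta["n_categories"], config=cfg,
                   fixed_names=fixed_names, age_center=meta["age_center"],
                   g_samples=g, rhe_samples=rhe, beta_samples=beta,
                   cut_samples=cuts, animal_ids=animal_ids, ebv_mean=ebv_mean,
                   ebv_sd=ebv_sd, acceptance=meta.get("acceptance", {}))


def posterior_summary(chain: PosteriorChain) -> pd.DataFrame:
    """Mean, posterior SD, Monte-Carlo SEM, lag-1 autocorrelation and pMCMC
    for every stored parameter series."""
    from .diagnostics import lag1_autocorrelation

    rows = []
    for name, x in chain.all_series().items():
        x = np.asarray(x, float)
        sd = float(np.std(x, ddof=1)) if x.size > 1 else 0.0
        rows.append({
            "parameter": name,
            "mean": float(np.mean(x)),
            "sd": sd,
            "sem": sd / math.sqrt(x.size) if x.size else np.nan,
            "lag1_autocorr": lag1_autocorrelation(x, warn=False),
            "pmcmc": pmcmc(x),
        })
    return pd.DataFrame(rows)


def extract_ebv(chain: PosteriorChain) -> pd.DataFrame:
    """Per-animal, per-trait posterior-mean breeding values.

    EBVs live on the liability (probit) scale and are relative values only:
    they rank animals by predicted disease liability but carry no direct
    mapping to a score category.
    """
    frames = []
    for m, t in enumerate(chain.traits):
        frames.append(pd.DataFrame({
            "animal": chain.animal_ids,
            "trait": t,
            "ebv": chain.ebv_mean[:, m],
            "ebv_sd": chain.ebv_sd[:, m],
        }))
    return pd.concat(frames, ignore_index=True)


# --------------------------------------------------------------------------
# the sampler
# --------------------------------------------------------------------------

def _draw_invwishart(rng: np.ndarray, df: float, scale: np.ndarray) -> np.ndarray:
    """Inverse-Wishart draw via Bartlett decomposition (dim 1 or 2)."""
    p = scale.shape[0]
    L = np.linalg.cholesky(np.linalg.inv(scale))
    A = np.zeros((p, p))
    for i in range(p):
        A[i, i] = math.sqrt(rng.chisquare(df - i))
        for j in range(i):
            A[i, j] = rng.standard_normal()
    W = L @ A
    W = W @ W.T          # ~ Wishart(df, scale^-1)
    return np.linalg.inv(W)


def _empirical_cutpoints(cats: np.ndarray, K: int) -> tuple[np.ndarray, float]:
    """Initial boundaries from empirical cumulative frequencies.

    Returns interior boundaries (length K-1, first pinned at 0) and an
    intercept start so the implied standard-normal category probabilities
    match the data.  Degenerate gaps from empty categories are opened to a
    small epsilon to keep the boundaries strictly increasing.
    """
    counts = np.bincount(cats, minlength=K).astype(float)
    cum = np.clip(np.cumsum(counts)[:-1] / counts.sum(), 1e-4, 1 - 1e-4)
    z = ndtri(cum)
    b = z - z[0]
    for j in range(1, b.size):
        if b[j] <= b[j - 1]:
            b[j] = b[j - 1] + 1e-3
    return b, -z[0]


def _boundaries(interior: np.ndarray) -> np.ndarray:
    return np.concatenate(([-np.inf], interior, [np.inf]))


class _TruncNorm:
    """Vectorized truncated-normal draws via the inverse probit CDF."""

    @staticmethod
    def draw(rng, mean, sd, lo, hi):
        plo = ndtr((lo - mean) / sd)
        phi = ndtr((hi - mean) / sd)
        u = plo + rng.random(mean.shape[0]) * (phi - plo)
        u = np.clip(u, 1e-14, 1 - 1e-14)
        x = mean + sd * ndtri(u)
        bad = ~np.isfinite(x) | (x < lo) | (x > hi)
        if np.any(bad):
            lo_b = np.where(np.isfinite(lo[bad]), lo[bad] + 1e-6, mean[bad])
            hi_b = np.where(np.isfinite(hi[bad]), hi[bad] - 1e-6, mean[bad])
            x[bad] = np.minimum(np.maximum(mean[bad], lo_b), hi_b)
        return x


def gibbs_fit(ped: Pedigree, records: pd.DataFrame | None,
              spec: ModelSpec | None = None,
              priors: PriorSpec | None = None,
              chain: ChainConfig | None = None,
              store_animal_samples: bool = False,
              fixed_cutpoints: dict | None = None) -> PosteriorChain:
    """Fit the uni-/bivariate threshold animal model by Gibbs sampling.

    ``records`` must carry columns ``animal``, ``sex``, ``age_months``,
    ``eval_year`` (or ``birth_date`` from which it is derived) and
    ``<trait>_score`` for each fitted trait, with missing scores blank.
    An empty record table is the documented prior-sampling mode: the chain
    then explores the joint prior of (animal effects, G0), which is how the
    inverse-Wishart prior can be checked by simulation.
    """
    spec = spec or ModelSpec()
    priors = priors or PriorSpec()
    chain = chain or ChainConfig()
    traits = spec.traits
    T = len(traits)
    if T not in (1, 2):
        raise ConfigError("one or two traits supported")
    n_ped = len(ped)
    rng = np.random.default_rng(chain.seed)

    # ---- assemble data arrays -------------------------------------------
    empty = records is None or len(records) == 0
    if empty:
        n_rec = 0
        rec_animal = np.zeros(0, dtype=np.int64)
        obs = np.zeros((0, T), dtype=np.uint8)
        cat = np.zeros((0, T), dtype=np.int64)
        X = np.zeros((0, 1))
        fixed_names = ["mu"]
        age_center = 0.0
    else:
        records = add_eval_year(records)
        missing_ids = [a for a in records["animal"].astype(str) if a not in ped]
        if missing_ids:
            raise IntegrityError(
                f"record animal {missing_ids[0]!r} not present in the pedigree")
        n_rec = len(records)
        rec_animal = np.array(
            [ped.order_index[a] for a in records["animal"].astype(str)], dtype=np.int64)
        obs = np.zeros((n_rec, T), dtype=np.uint8)
        cat = np.zeros((n_rec, T), dtype=np.int64)
        for m, t in enumerate(traits):
            col = records.get(f"{t}_score")
            if col is None:
                raise DegenerateDataError(f"records carry no {t}_score column")
            vals = pd.to_numeric(col, errors="coerce")
            seen = vals.notna().to_numpy()
            obs[:, m] = seen
            K = spec.n_categories[t]
            v = vals.to_numpy(dtype=float)
            if np.any((v[seen] < 1) | (v[seen] > K) | (v[seen] != np.round(v[seen]))):
                raise DegenerateDataError(
                    f"{t} scores must be integers in 1..{K}")
            cat[seen, m] = v[seen].astype(np.int64) - 1
            if np.unique(cat[seen, m]).size < 2:
                raise DegenerateDataError(
                    f"trait {t!r} shows a single observed category")
        if not np.all(obs.any(axis=1)):
            raise DegenerateDataError("records with no observed score present")
        sexm = (records["sex"].astype(str).str.upper() == "M").to_numpy(float)
        age = records["age_months"].to_numpy(float)
        age_center = float(age.mean())
        years = records["eval_year"].astype(int).to_numpy()
        uyears = np.unique(years)
        cols = [np.ones(n_rec), sexm, age - age_center]
        fixed_names = ["mu", "sexM", "age"]
        for y in uyears[1:]:
            cols.append((years == y).astype(float))
            fixed_names.append(f"year{y}")
        X = np.column_stack(cols)

    p = X.shape[1]
    V = priors.scale_matrix(T)
    nu = priors.nu
    prior_prec = 1.0 / priors.fixed_effect_variance

    ainv = ped.inverse_relationship()
    ai_indptr = ainv.indptr.astype(np.int64)
    ai_indices = ainv.indices.astype(np.int64)
    ai_data = ainv.data.astype(np.float64)

    # per-animal record lists (CSR-like)
    counts = np.bincount(rec_animal, minlength=n_ped)
    ar_ptr = np.zeros(n_ped + 1, dtype=np.int64)
    np.cumsum(counts, out=ar_ptr[1:])
    ar_idx = np.argsort(rec_animal, kind="stable").astype(np.int64)

    # ---- initial state ---------------------------------------------------
    beta = np.zeros((T, p))
    interior: dict[int, np.ndarray] = {}
    update_cuts = np.ones(T, dtype=bool)
    for m, t in enumerate(traits):
        K = spec.n_categories[t]
        if fixed_cutpoints is not None and t in fixed_cutpoints:
            b = np.asarray(fixed_cutpoints[t], float)
            update_cuts[m] = False
        elif n_rec and obs[:, m].any():
            b, mu0 = _empirical_cutpoints(cat[obs[:, m] == 1, m], K)
            beta[m, 0] = mu0
        else:
            b = np.arange(K - 1, dtype=float)
        interior[m] = b
    # traits with >= 3 categories are sampled with the first two cutpoints
    # anchored and a floating residual variance (see module docstring);
    # binary traits keep the standard unit-residual identification
    r_free = np.array([spec.n_categories[t] >= 3 for t in traits])
    r_resid = np.ones(T)
    rho = 0.0
    a = np.zeros((n_ped, T))
    G0 = V.copy()
    G0inv = np.linalg.inv(G0)
    liab = np.zeros((n_rec, T))
    for m in range(T):
        idx = obs[:, m] == 1
        bnd = _boundaries(interior[m])
        lo, hi = bnd[cat[idx, m]], bnd[cat[idx, m] + 1]
        mid = np.where(np.isfinite(lo) & np.isfinite(hi), (lo + hi) / 2,
                       np.where(np.isfinite(lo), lo + 0.5, hi - 0.5))
        liab[idx, m] = mid
    e = liab - (X @ beta.T) - a[rec_animal] if n_rec else liab.copy()
    e[obs == 0] = 0.0

    both = (obs.sum(axis=1) == 2) if T == 2 else np.zeros(n_rec, dtype=bool)
    n_both = int(both.sum())
    only = [np.flatnonzero((obs[:, m] == 1) & ~both) for m in range(T)]
    both_idx = np.flatnonzero(both)
    X_only = [X[only[m]] for m in range(T)]
    X_both = X[both_idx]
    gram_only = [X_only[m].T @ X_only[m] for m in range(T)]
    gram_both = X_both.T @ X_both

    # ---- bookkeeping -----------------------------------------------------
    S = chain.n_stored
    g_samples = np.zeros((S, T, T))
    rhe_samples = np.zeros(S) if T == 2 else None
    beta_samples = np.zeros((S, T, p))
    cut_samples = {t: np.zeros((S, spec.n_categories[t] - 1)) for t in traits}
    a_samples = np.zeros((S, n_ped, T)) if store_animal_samples else None
    liab_accum = np.zeros((n_rec, T))
    ebv_mean = np.zeros((n_ped, T))
    ebv_m2 = np.zeros((n_ped, T))
    cut_step = np.full(T, 0.05)
    rho_step = 0.1
    rstep = np.full(T, 0.15)       # log-scale residual-variance steps
    scale_step = np.full(T, 0.05)  # log-scale (a, G0) group-move steps
    cut_acc = np.zeros(T)
    cut_try = np.zeros(T)
    r_acc = np.zeros(T)
    r_try = np.zeros(T)
    scale_acc = np.zeros(T)
    scale_try = np.zeros(T)
    rho_acc = 0.0
    rho_try = 0.0
    cut_acc_win = np.zeros(T)
    cut_try_win = np.zeros(T)
    r_acc_win = np.zeros(T)
    r_try_win = np.zeros(T)
    scale_acc_win = np.zeros(T)
    scale_try_win = np.zeros(T)
    rho_acc_win = 0.0
    rho_try_win = 0.0
    stored = 0

    def _cond_mean_sd(m: int):
        """Per-record liability mean/sd for trait m given the other trait."""
        idx = np.flatnonzero(obs[:, m])
        eta_m = liab[idx, m] - e[idx, m]
        mean = eta_m.copy()
        sd = np.full(idx.size, math.sqrt(r_resid[m]))
        if T == 2 and n_both:
            o = 1 - m
            bmask = both[idx]
            sub = idx[bmask]
            mean[bmask] = eta_m[bmask] + rho * math.sqrt(
                r_resid[m] / r_resid[o]) * e[sub, o]
            sd[bmask] = math.sqrt(max(r_resid[m] * (1.0 - rho * rho), 1e-12))
        return idx, mean, sd

    def _cut_loglik(m, idx, mean, sd, bnd):
        lo = bnd[cat[idx, m]]
        hi = bnd[cat[idx, m] + 1]
        pr = ndtr((hi - mean) / sd) - ndtr((lo - mean) / sd)
        return float(np.sum(np.log(pr + 1e-300)))

    def _draw_fixed(w00b, w01b, w11b, w0s, w1s):
        """Joint conjugate draw of all fixed effects (exact block update).

        Uses y~ = liability - animal part = e + X beta; residuals are then
        reset exactly from the new coefficients, which also prevents any
        incremental float drift in ``e``.
        """
        if n_rec == 0:
            for m in range(T):
                beta[m] = rng.standard_normal(p) / math.sqrt(prior_prec)
            return
        yt_only = [e[only[m], m] + X_only[m] @ beta[m] for m in range(T)]
        yt_both = [e[both_idx, m] + X_both @ beta[m] for m in range(T)]
        if T == 1:
            C = w0s * gram_only[0] + prior_prec * np.eye(p)
            rhs = w0s * (X_only[0].T @ yt_only[0])
        else:
            ws = (w0s, w1s)
            wmm = (w00b, w11b)
            C = np.zeros((2 * p, 2 * p))
            rhs = np.zeros(2 * p)
            for m in range(2):
                sl = slice(m * p, (m + 1) * p)
                C[sl, sl] = (ws[m] * gram_only[m] + wmm[m] * gram_both
                             + prior_prec * np.eye(p))
                rhs[sl] = (ws[m] * (X_only[m].T @ yt_only[m])
                           + wmm[m] * (X_both.T @ yt_both[m])
                           + w01b * (X_both.T @ yt_both[1 - m]))
            C[:p, p:] = C[p:, :p] = w01b * gram_both
        L = np.linalg.cholesky(C)
        mean = np.linalg.solve(C, rhs)
        noise = np.linalg.solve(L.T, rng.standard_normal(C.shape[0]))
        bnew = mean + noise
        for m in range(T):
            beta[m] = bnew[m * p:(m + 1) * p]
            e[only[m], m] = yt_only[m] - X_only[m] @ beta[m]
            e[both_idx, m] = yt_both[m] - X_both @ beta[m]

    for it in range(1, chain.total_iterations + 1):
        in_burn = it <= chain.burn_in
        # ---- per trait: cutpoint MH (liabilities collapsed), then redraw
        for m, t in enumerate(traits):
            K = spec.n_categories[t]
            idx, mean, sd = _cond_mean_sd(m)
            # first two interior boundaries are anchored; remaining ones move
            if K > 3 and idx.size and update_cuts[m]:
                free = interior[m][2:]
                prop = free + rng.normal(0.0, cut_step[m], free.size)
                cut_try[m] += 1
                cut_try_win[m] += 1
                cand = np.concatenate((interior[m][:2], prop))
                if np.all(np.diff(cand) > 0):
                    ll_old = _cut_loglik(m, idx, mean, sd, _boundaries(interior[m]))
                    ll_new = _cut_loglik(m, idx, mean, sd, _boundaries(cand))
                    if math.log(rng.random()) < ll_new - ll_old:
                        interior[m] = cand
                        cut_acc[m] += 1
                        cut_acc_win[m] += 1
            if idx.size:
                bnd = _boundaries(interior[m])
                lo = bnd[cat[idx, m]]
                hi = bnd[cat[idx, m] + 1]
                lnew = _TruncNorm.draw(rng, mean, sd, lo, hi)
                e[idx, m] += lnew - liab[idx, m]
                liab[idx, m] = lnew

        # ---- location effects -------------------------------------------
        if T == 2:
            q = 1.0 - rho * rho
            w00b = 1.0 / (r_resid[0] * q)
            w11b = 1.0 / (r_resid[1] * q)
            w01b = -rho / (math.sqrt(r_resid[0] * r_resid[1]) * q)
            w1s = 1.0 / r_resid[1]
        else:
            w00b = w01b = w11b = 0.0
            w1s = 1.0
        w0s = 1.0 / r_resid[0]
        _draw_fixed(w00b, w01b, w11b, w0s, w1s)
        z_anim = rng.standard_normal((n_ped, T))
        animal_scan(obs, e, a,
                    ai_indptr, ai_indices, ai_data,
                    ar_ptr, ar_idx, G0inv,
                    w00b, w01b, w11b, w0s, w1s, z_anim)

        # ---- genetic covariance -----------------------------------------
        Sq = a.T @ (ainv @ a)
        G0 = _draw_invwishart(rng, nu + n_ped, V * nu + Sq)
        G0inv = np.linalg.inv(G0)

        # ---- multiplicative group move along the (a, G0) scale ridge ----
        # proposes a_m -> s a_m, G0 row/col m -> s; the Gaussian prior term
        # cancels against the Jacobian of the a-map, leaving the record
        # likelihood, the inverse-Wishart prior and the G0-map Jacobian
        for m in range(T):
            s = math.exp(rng.normal(0.0, scale_step[m]))
            scale_try[m] += 1
            scale_try_win[m] += 1
            am_only = a[rec_animal[only[m]], m] if n_rec else np.zeros(0)
            am_both = a[rec_animal[both_idx], m] if n_rec else np.zeros(0)
            eo_old = e[only[m], m]
            eb_old = e[both_idx, m]
            eo_new = eo_old - (s - 1.0) * am_only
            eb_new = eb_old - (s - 1.0) * am_both
            w_ms = w0s if m == 0 else w1s
            w_mm = w00b if m == 0 else w11b
            dlik = -0.5 * w_ms * float(eo_new @ eo_new - eo_old @ eo_old)
            if T == 2 and n_both:
                o = 1 - m
                dlik += -0.5 * w_mm * float(eb_new @ eb_new - eb_old @ eb_old)
                dlik += -w01b * float((eb_new - eb_old) @ e[both_idx, o])
            Dv = np.ones(T)
            Dv[m] = 1.0 / s
            G0inv_new = G0inv * np.outer(Dv, Dv)
            dtr = float(np.sum((V * nu) * (G0inv_new - G0inv)))
            jac = 3.0 if T == 2 else 2.0
            logalpha = (dlik - (nu + T + 1.0) * math.log(s) - 0.5 * dtr
                        + jac * math.log(s))
            if math.log(rng.random()) < logalpha:
                a[:, m] *= s
                G0[m, :] *= s
                G0[:, m] *= s
                G0inv = G0inv_new
                e[only[m], m] = eo_new
                e[both_idx, m] = eb_new
                scale_acc[m] += 1
                scale_acc_win[m] += 1

        # ---- residual covariance ----------------------------------------
        if n_rec and (T == 1 or n_both == 0):
            # no cross-trait coupling: scaled-inverse-chi-square conjugate
            for m in range(T):
                if not r_free[m]:
                    continue
                em = e[obs[:, m] == 1, m]
                r_resid[m] = (nu + float(em @ em)) / rng.chisquare(nu + em.size)
        elif n_rec:
            s_s = [float(e[only[m], m] @ e[only[m], m]) for m in range(2)]
            n_s = [only[m].size for m in range(2)]
            e0 = e[both, 0]
            e1 = e[both, 1]
            s00 = float(e0 @ e0)
            s11 = float(e1 @ e1)
            s01 = float(e0 @ e1)

            def _resid_logpost(r0, r1, rh):
                q = 1.0 - rh * rh
                ll = (-0.5 * n_s[0] * math.log(r0) - s_s[0] / (2 * r0)
                      - 0.5 * n_s[1] * math.log(r1) - s_s[1] / (2 * r1)
                      - 0.5 * n_both * math.log(r0 * r1 * q)
                      - (s00 / r0 - 2 * rh * s01 / math.sqrt(r0 * r1)
                         + s11 / r1) / (2 * q))
                lp = (-(nu / 2 + 1.0) * (math.log(r0) + math.log(r1))
                      - nu / (2 * r0) - nu / (2 * r1)
                      - (nu + 3.0) / 2.0 * math.log(q) - nu / q)
                return ll + lp

            for m in range(2):
                if not r_free[m]:
                    continue
                cur = r_resid[m]
                prop = cur * math.exp(rng.normal(0.0, rstep[m]))
                r_try[m] += 1
                r_try_win[m] += 1
                cand = (prop, r_resid[1]) if m == 0 else (r_resid[0], prop)
                logr = (_resid_logpost(cand[0], cand[1], rho) + math.log(prop)
                        - _resid_logpost(r_resid[0], r_resid[1], rho)
                        - math.log(cur))
                if math.log(rng.random()) < logr:
                    r_resid[m] = prop
                    r_acc[m] += 1
                    r_acc_win[m] += 1
            prop = rho + rng.normal(0.0, rho_step)
            rho_try += 1
            rho_try_win += 1
            if abs(prop) < 1.0:           # positive-definiteness of R0
                if math.log(rng.random()) < (
                        _resid_logpost(r_resid[0], r_resid[1], prop)
                        - _resid_logpost(r_resid[0], r_resid[1], rho)):
                    rho = prop
                    rho_acc += 1
                    rho_acc_win += 1

        # ---- adapt proposal steps during burn-in ------------------------
        if in_burn and it % 50 == 0:
            for m in range(T):
                if cut_try_win[m] >= 25:
                    rate = cut_acc_win[m] / cut_try_win[m]
                    if rate < 0.2:
                        cut_step[m] *= 0.7
                    elif rate > 0.5:
                        cut_step[m] *= 1.4
                    cut_acc_win[m] = cut_try_win[m] = 0.0
                if r_try_win[m] >= 25:
                    rate = r_acc_win[m] / r_try_win[m]
                    if rate < 0.2:
                        rstep[m] *= 0.7
                    elif rate > 0.5:
                        rstep[m] *= 1.4
                    r_acc_win[m] = r_try_win[m] = 0.0
                if scale_try_win[m] >= 25:
                    rate = scale_acc_win[m] / scale_try_win[m]
                    if rate < 0.2:
                        scale_step[m] *= 0.7
                    elif rate > 0.5:
                        scale_step[m] *= 1.4
                    scale_acc_win[m] = scale_try_win[m] = 0.0
            if rho_try_win >= 25:
                rate = rho_acc_win / rho_try_win
                if rate < 0.2:
                    rho_step *= 0.7
                elif rate > 0.5:
                    rho_step = min(rho_step * 1.4, 1.0)
                rho_acc_win = rho_try_win = 0.0

        # ---- store (rescaled to the unit-residual reporting scale) ------
        if not in_burn and (it - chain.burn_in) % chain.thin == 0 and stored < S:
            sr = np.sqrt(r_resid)
            g_samples[stored] = G0 / np.outer(sr, sr)
            if rhe_samples is not None:
                rhe_samples[stored] = rho
            beta_samples[stored] = beta / sr[:, None]
            for m, t in enumerate(traits):
                cut_samples[t][stored] = interior[m] / sr[m]
            a_scaled = a / sr[None, :]
            if a_samples is not None:
                a_samples[stored] = a_scaled
            liab_accum += liab / sr[None, :]
            stored += 1
            delta = a_scaled - ebv_mean
            ebv_mean += delta / stored
            ebv_m2 += delta * (a_scaled - ebv_mean)

    ebv_sd = np.sqrt(ebv_m2 / max(stored - 1, 1))
    acceptance = {
        "cutpoints": {t: (float(cut_acc[m] / cut_try[m]) if cut_try[m] else None)
                      for m, t in enumerate(traits)},
        "residual_variance": {t: (float(r_acc[m] / r_try[m]) if r_try[m] else None)
                              for m, t in enumerate(traits)},
        "scale_move": {t: (float(scale_acc[m] / scale_try[m]) if scale_try[m] else None)
                       for m, t in enumerate(traits)},
        "r_he": float(rho_acc / rho_try) if rho_try else None,
    }
    logger.info("gibbs_fit: stored %d samples; acceptance %s", stored, acceptance)
    return PosteriorChain(
        traits=traits, n_categories=dict(spec.n_categories), config=chain,
        fixed_names=fixed_names, age_center=age_center,
        g_samples=g_samples, rhe_samples=rhe_samples, beta_samples=beta_samples,
        cut_samples=cut_samples, animal_ids=list(ped.ids),
        ebv_mean=ebv_mean, ebv_sd=ebv_sd, acceptance=acceptance,
        a_samples=a_samples,
        liab_mean=(liab_accum / stored if stored and n_rec else None),
        record_animals=(list(records["animal"].astype(str)) if n_rec else None))
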