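"""Forward simulator for pedigrees and ordinal joint scores.

Generates data with exactly the statistical structure the threshold animal
model assumes, so every downstream stage can be tested against a known
truth: founders draw breeding values from N(0, G0); offspring take the
parental average plus a Mendelian deviation with covariance
``0.5 * G0 * (1 - (F_s + F_d)/2)``; liabilities add fixed effects, the
breeding value and a unit-variance residual (correlated across traits with
``r_he`` for doubly-scored dogs); ordinal scores arise by counting
cutpoints below the liability.  Optional truncation selection on the
observed score (or on the true breeding value) emulates the voluntary
phenotypic selection that produces a declining genetic trend in registry
data.

Generations are non-overlapping by default for simple truth bookkeeping;
real registries have overlapping generations and ascertainment quirks the
generator does not attempt to mimic (see the methods note).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .model import derive_eval_year
from .pedigree import Pedigree, PedigreeEntry, _inbreeding_kernel

DEFAULT_CUTPOINTS = {
    "hip": (0.0, 0.75, 1.5, 2.25, 3.0, 3.75),   # 7 categories
    "elbow": (0.0, 0.8, 1.6),                    # 4 categories
}
DEFAULT_MU = {"hip": 1.5, "elbow": 0.8}


class DemographicError(ValueError):
    """Selection or demography leaves no usable parents."""


@dataclass
class TruncationSelection:
    """Keep the best ``proportion`` of candidates as parents.

    ``on`` ranks candidates by observed score ("phenotype") or by true
    breeding value ("true_bv"); ``sexes`` restricts selection to sires,
    dams, or applies it to both.  Ties break by a uniform draw that never
    looks at the liability.
    """

    proportion: float = 0.2
    on: str = "phenotype"
    trait: str = "hip"
    sexes: str = "both"

    def __post_init__(self):
        if not 0 < self.proportion <= 1:
            raise ValueError("truncation proportion must be in (0, 1]")
        if self.sexes not in ("both", "sires", "dams"):
            raise ValueError("sexes must be 'both', 'sires' or 'dams'")


@dataclass
class SimulationTruth:
    """Every generative parameter of one simulated study.

    ``G0`` is the true genetic (co)variance on the liability scale
    (residuals have unit variance, so trait heritability is g/(g+1));
    cutpoints are interior category boundaries with the first pinned at 0.
    Sex, age and year effects default to zero so genetic parameters can be
    recovered in isolation; set them to exercise the fixed-effect part.
    """

    traits: tuple = ("hip", "elbow")
    G0: np.ndarray = field(default_factory=lambda: np.array([[1.0, 0.3], [0.3, 1.0]]))
    r_he: float = 0.2
    mu: tuple | None = None
    sex_effect: tuple | None = None          # male minus female, per trait
    beta_age: tuple | None = None            # per month of age, per trait
    year_effects: dict | None = None         # eval_year -> per-trait offsets
    cutpoints: dict | None = None
    selection: TruncationSelection | None = None
    n_founders: int = 300
    n_generations: int = 4                   # total, founders included
    n_sires: int = 50
    n_dams: int = 150
    offspring_per_dam: int = 3
    base_year: int = 2000
    years_per_generation: int = 2
    age_range: tuple = (24, 120)             # evaluation age window, months
    obs_prob: tuple | None = None            # per-trait scoring probability
    seed: int = 0

    def __post_init__(self):
        self.traits = tuple(self.traits)
        T = len(self.traits)
        self.G0 = np.atleast_2d(np.asarray(self.G0, float))
        if self.G0.shape != (T, T):
            raise ValueError(f"G0 must be {T}x{T}")
        np.linalg.cholesky(self.G0)          # positive-definiteness check
        if T == 2 and not abs(self.r_he) < 1:
            raise ValueError("residual correlation must lie in (-1, 1)")
        if self.mu is None:
            self.mu = tuple(DEFAULT_MU[t] for t in self.traits)
        if self.sex_effect is None:
            self.sex_effect = (0.0,) * T
        if self.beta_age is None:
            self.beta_age = (0.0,) * T
        if self.obs_prob is None:
            self.obs_prob = (1.0,) * T
        self.age_range = (int(self.age_range[0]), int(self.age_range[1]))
        if not 0 < self.age_range[0] <= self.age_range[1]:
            raise ValueError("age_range must be an increasing pair of months")
        if self.cutpoints is None:
            self.cutpoints = {t: DEFAULT_CUTPOINTS[t] for t in self.traits}
        for t in self.traits:
            c = np.asarray(self.cutpoints[t], float)
            if c[0] != 0.0 or np.any(np.diff(c) <= 0):
                raise ValueError(f"cutpoints for {t} must start at 0 and increase")

    @classmethod
    def from_heritabilities(cls, h2, r_g: float = 0.0, **kwargs) -> "SimulationTruth":
        """Build a truth from liability-scale heritabilities.

        ``h2`` is a scalar (univariate) or a sequence per trait; genetic
        variances are ``g = h2/(1-h2)`` since residual variance is 1.
        """
        h2 = np.atleast_1d(np.asarray(h2, float))
        if np.any((h2 <= 0) | (h2 >= 1)):
            raise ValueError("heritabilities must lie in (0, 1)")
        g = h2 / (1.0 - h2)
        if h2.size == 1:
            G0 = np.array([[g[0]]])
        else:
            ghe = r_g * np.sqrt(g[0] * g[1])
            G0 = np.array([[g[0], ghe], [ghe, g[1]]])
        traits = kwargs.pop("traits", ("hip", "elbow")[: h2.size] if h2.size > 1
                            else (kwargs.pop("trait", "hip"),))
        return cls(traits=tuple(traits), G0=G0, **kwargs)

    def heritabilities(self) -> dict:
        g = np.diag(self.G0)
        return {t: float(g[m] / (g[m] + 1.0)) for m, t in enumerate(self.traits)}

    def to_dict(self) -> dict:
        d = asdict(self)
        d["G0"] = self.G0.tolist()
        d["cutpoints"] = {t: list(map(float, c)) for t, c in self.cutpoints.items()}
        return d


@dataclass
class SimulatedDataset:
    pedigree: Pedigree
    records: pd.DataFrame
    true_bv: pd.DataFrame       # columns: animal, trait, true_bv
    truth: SimulationTruth

    def true_bv_wide(self) -> pd.DataFrame:
        return self.true_bv.pivot(index="animal", columns="trait", values="true_bv")

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.pedigree.write(outdir / "pedigree.csv")
        self.records.to_csv(outdir / "records.csv", index=False)
        self.true_bv.to_csv(outdir / "true_bv.csv", index=False)
        (outdir / "truth.json").write_text(json.dumps(self.truth.to_dict(), indent=2))


# --------------------------------------------------------------------------
# score generation
# --------------------------------------------------------------------------

def simulate_scores(bv: np.ndarray, sexes: np.ndarray, birth_years: np.ndarray,
                    ids: list, truth: SimulationTruth,
                    rng: np.random.Generator) -> pd.DataFrame:
    """Ordinal score records for a block of animals.

    Ages draw uniformly on [24, 120] months; the evaluation year follows
    from birth year and age; the liability is mu + sex + beta*age + year +
    breeding value + residual; the score is 1 plus the number of cutpoints
    below the liability.  Per-trait missingness is applied afterwards and
    records losing every score are dropped.
    """
    T = len(truth.traits)
    n = len(ids)
    age = rng.integers(truth.age_range[0], truth.age_range[1] + 1, size=n)
    birth_date = [f"{int(y)}-06" for y in birth_years]
    eval_year = np.array([derive_eval_year(b, a) for b, a in zip(birth_date, age)])
    male = (sexes == "M").astype(float)
    if T == 2:
        Lr = np.linalg.cholesky(np.array([[1.0, truth.r_he], [truth.r_he, 1.0]]))
        resid = rng.standard_normal((n, 2)) @ Lr.T
    else:
        resid = rng.standard_normal((n, 1))
    data = {"animal": ids, "sex": sexes, "birth_date": birth_date,
            "age_months": age, "eval_year": eval_year}
    observed_any = np.zeros(n, dtype=bool)
    for m, t in enumerate(truth.traits):
        liab = (truth.mu[m] + truth.sex_effect[m] * male
                + truth.beta_age[m] * age + bv[:, m] + resid[:, m])
        if truth.year_effects:
            liab = liab + np.array(
                [truth.year_effects.get(int(y), (0.0,) * T)[m] for y in eval_year])
        interior = np.asarray(truth.cutpoints[t], float)
        score = 1 + np.searchsorted(interior, liab, side="left")
        keep = rng.random(n) < truth.obs_prob[m]
        col = score.astype(float)
        col[~keep] = np.nan
        observed_any |= keep
        data[f"{t}_score"] = col
        # true latent liability, kept as an oracle column (ignored by fits)
        data[f"{t}_liability"] = liab
    df = pd.DataFrame(data)
    return df.loc[observed_any].reset_index(drop=True)


def apply_truncation_selection(records: pd.DataFrame, proportion: float,
                               rng: np.random.Generator, trait: str = "hip",
                               score_col: str | None = None) -> list:
    """Ids of the best ``proportion`` of candidates by observed score.

    Lower scores are better; ties (and unscored dogs, ranked worst) break
    by a uniform draw independent of the liability.
    """
    col = score_col or f"{trait}_score"
    n = len(records)
    if n == 0:
        raise DemographicError("no candidates to select from")
    scores = pd.to_numeric(records[col], errors="coerce").to_numpy(float)
    scores = np.where(np.isnan(scores), np.inf, scores)
    tiebreak = rng.random(n)
    order = np.lexsort((tiebreak, scores))
    k = max(int(np.ceil(proportion * n)), 1)
    return [str(records["animal"].iloc[i]) for i in order[:k]]


# --------------------------------------------------------------------------
# pedigree + dataset generation
# --------------------------------------------------------------------------

def simulate_dataset(truth: SimulationTruth) -> SimulatedDataset:
    """Full forward simulation: pedigree, true breeding values and records.

    Deterministic given ``truth`` (including its seed): identical inputs
    reproduce identical outputs byte-for-byte.
    """
    rng = np.random.default_rng(truth.seed)
    T = len(truth.traits)
    Lg = np.linalg.cholesky(truth.G0)

    ids: list[str] = []
    idx_of: dict[str, int] = {}
    sire: list[int] = []
    dam: list[int] = []
    sexes: list[str] = []
    byear: list[int] = []
    bv_rows: list[np.ndarray] = []
    record_blocks: list[pd.DataFrame] = []

    def _new_animal(s: int, d: int, sex: str, year: int, bv: np.ndarray) -> int:
        idx = len(ids)
        ids.append(f"A{idx + 1:06d}")
        idx_of[ids[-1]] = idx
        sire.append(s)
        dam.append(d)
        sexes.append(sex)
        byear.append(year)
        bv_rows.append(bv)
        return idx

    # founders
    nf = truth.n_founders
    founder_sex = np.array(["M"] * (nf // 2) + ["F"] * (nf - nf // 2))
    for i in range(nf):
        bv = Lg @ rng.standard_normal(T)
        _new_animal(-1, -1, founder_sex[i], truth.base_year, bv)
    gen_slices = [range(0, nf)]
    block = simulate_scores(np.array(bv_rows[:nf]), founder_sex,
                            np.array(byear[:nf]), ids[:nf], truth, rng)
    record_blocks.append(block)

    sel = truth.selection
    for g in range(1, truth.n_generations):
        prev = gen_slices[-1]
        F = _inbreeding_kernel(np.array(sire, dtype=np.int64),
                               np.array(dam, dtype=np.int64))
        prev_records = record_blocks[-1]
        year = truth.base_year + g * truth.years_per_generation

        def _parent_pool(sex: str, selected: bool) -> list:
            members = [ids[i] for i in prev if sexes[i] == sex]
            if not members:
                raise DemographicError(f"no {sex} candidates in generation {g - 1}")
            if not selected or sel is None:
                return members
            if sel.on == "true_bv":
                tm = truth.traits.index(sel.trait) if sel.trait in truth.traits else 0
                sub = pd.DataFrame({
                    "animal": members,
                    "score": [bv_rows[idx_of[a]][tm] for a in members]})
                pool = apply_truncation_selection(sub, sel.proportion, rng,
                                                  score_col="score")
            else:
                sub = prev_records[prev_records["animal"].isin(members)]
                if sub.empty:
                    raise DemographicError("no scored candidates for selection")
                pool = apply_truncation_selection(sub, sel.proportion, rng,
                                                  trait=sel.trait)
            if not pool:
                raise DemographicError("selection left no parents")
            return pool

        sire_pool = _parent_pool("M", sel is not None and sel.sexes in ("both", "sires"))
        dam_pool = _parent_pool("F", sel is not None and sel.sexes in ("both", "dams"))
        # at most n_sires distinct studs, each possibly serving several dams;
        # each dam mates once
        studs = rng.choice(len(sire_pool), size=min(truth.n_sires, len(sire_pool)),
                           replace=False)
        n_dams = min(truth.n_dams, len(dam_pool))
        chosen_dams = rng.choice(len(dam_pool), size=n_dams, replace=False)
        stud_of_mating = rng.choice(studs, size=n_dams, replace=True)

        start = len(ids)
        for k in range(n_dams):
            s_idx = idx_of[sire_pool[stud_of_mating[k]]]
            d_idx = idx_of[dam_pool[chosen_dams[k]]]
            mid_bv = 0.5 * (bv_rows[s_idx] + bv_rows[d_idx])
            mend_sd = np.sqrt(0.5 * (1.0 - 0.5 * (F[s_idx] + F[d_idx])))
            for _ in range(truth.offspring_per_dam):
                dev = mend_sd * (Lg @ rng.standard_normal(T))
                sex = "M" if rng.random() < 0.5 else "F"
                _new_animal(s_idx, d_idx, sex, year, mid_bv + dev)
        gen_slices.append(range(start, len(ids)))
        block = simulate_scores(np.array(bv_rows[start:]),
                                np.array(sexes[start:], dtype=object),
                                np.array(byear[start:]),
                                ids[start:], truth, rng)
        record_blocks.append(block)

    entries = [
        PedigreeEntry(
            animal_id=ids[i],
            sire_id=ids[sire[i]] if sire[i] >= 0 else "",
            dam_id=ids[dam[i]] if dam[i] >= 0 else "",
            sex=sexes[i],
            birth_year=byear[i],
        )
        for i in range(len(ids))
    ]
    ped = Pedigree(entries)
    records = pd.concat(record_blocks, ignore_index=True)
    bv_arr = np.array(bv_rows)
    true_bv = pd.concat(
        [pd.DataFrame({"animal": ids, "trait": t, "true_bv": bv_arr[:, m]})
         for m, t in enumerate(truth.traits)],
        ignore_index=True)
    return SimulatedDataset(pedigree=ped, records=records, true_bv=true_bv,
                            truth=truth)


def simulate_pedigree(truth: SimulationTruth) -> tuple[Pedigree, pd.DataFrame]:
    """Pedigree and true breeding values only (records discarded)."""
    ds = simulate_dataset(truth)
    return ds.pedigree, ds.true_bv
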