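"""Pedigree ingestion, validation and relationship algebra.

A pedigree here is the usual animal-breeding object: one row per animal
giving its sire and dam (either possibly unknown), topologically ordered so
every parent precedes all of its offspring.  Unknown parents are treated as
unrelated base-population founders.  On top of that structure the module
computes

* per-animal inbreeding coefficients ``F`` (Meuwissen & Luo style
  single-row L·D·L' traversal),
* the dense numerator relationship matrix ``A`` by the tabular method
  (small pedigrees only; ``diag(A) = 1 + F``),
* the sparse inverse ``A_inv`` by Henderson's rules with the Quaas
  inbreeding adjustment, which is what the mixed-model machinery actually
  consumes, and
* grand-parental path membership (sires of sires, sires of dams, dams of
  sires, dams of dams) for four-path selection-response decomposition.

Identifiers are opaque strings; dense integer indices are assigned in
topological order.
"""

from __future__ import annotations

import io
from collections import deque
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from numba import njit

UNKNOWN = ""
#: accepted encodings for a missing parent / missing field in input files
MISSING_TOKENS = {"", "0", "NA", "na", "nan", "NaN", "None"}

PATH_CATEGORIES = ("SS", "SD", "DS", "DD")


class PedigreeError(ValueError):
    """Base class for structural pedigree problems."""


class CycleError(PedigreeError):
    """An animal appears among its own ancestors."""


class IntegrityError(PedigreeError):
    """Identifier misuse: duplicates, sire/dam conflicts, sex conflicts."""


class CapacityError(PedigreeError):
    """Dense A requested for a pedigree above the dense limit."""


@dataclass(frozen=True)
class PedigreeEntry:
    animal_id: str
    sire_id: str = UNKNOWN
    dam_id: str = UNKNOWN
    sex: str = UNKNOWN          # "M", "F" or "" (unknown)
    birth_year: int | None = None


def _clean_id(value) -> str:
    if value is None:
        return UNKNOWN
    if isinstance(value, float) and np.isnan(value):
        return UNKNOWN
    s = str(value).strip()
    return UNKNOWN if s in MISSING_TOKENS else s


@njit(cache=True)
def _inbreeding_kernel(sire, dam):  # pragma: no cover - exercised via inbreeding()
    n = sire.shape[0]
    F = np.zeros(n)
    L = np.zeros(n)
    for i in range(n):
        if sire[i] < 0 and dam[i] < 0:
            F[i] = 0.0
            continue
        L[i] = 1.0
        fi = -1.0
        for j in range(i, -1, -1):
            lj = L[j]
            if lj == 0.0:
                continue
            sj = sire[j]
            dj = dam[j]
            if sj >= 0:
                L[sj] += 0.5 * lj
            if dj >= 0:
                L[dj] += 0.5 * lj
            if sj >= 0 and dj >= 0:
                dcoef = 0.5 - 0.25 * (F[sj] + F[dj])
            elif sj >= 0:
                dcoef = 0.75 - 0.25 * F[sj]
            elif dj >= 0:
                dcoef = 0.75 - 0.25 * F[dj]
            else:
                dcoef = 1.0
            fi += lj * lj * dcoef
            L[j] = 0.0
        F[i] = fi
    return F


@njit(cache=True)
def _tabular_a_kernel(sire, dam):  # pragma: no cover - exercised via relationship_matrix()
    n = sire.shape[0]
    A = np.zeros((n, n))
    for i in range(n):
        s = sire[i]
        d = dam[i]
        for j in range(i):
            v = 0.0
            if s >= 0:
                v += 0.5 * A[j, s]
            if d >= 0:
                v += 0.5 * A[j, d]
            A[i, j] = v
            A[j, i] = v
        aii = 1.0
        if s >= 0 and d >= 0:
            aii += 0.5 * A[s, d]
        A[i, i] = aii
    return A


class Pedigree:
    """Validated, topologically ordered pedigree.

    Construct with :meth:`from_entries` / :func:`load_pedigree`; the
    constructor assumes ``entries`` are already complete (every parent has
    its own entry) but performs validation and sorting itself.
    """

    def __init__(self, entries: list[PedigreeEntry]):
        entries = _materialize_parents(entries)
        _validate(entries)
        self.entries = _toposort(entries)
        self.ids = [e.animal_id for e in self.entries]
        self.order_index = {a: i for i, a in enumerate(self.ids)}
        n = len(self.entries)
        self.sire_idx = np.full(n, -1, dtype=np.int64)
        self.dam_idx = np.full(n, -1, dtype=np.int64)
        self.sex = np.array([e.sex for e in self.entries], dtype=object)
        self.birth_year = np.array(
            [np.nan if e.birth_year is None else float(e.birth_year) for e in self.entries]
        )
        for i, e in enumerate(self.entries):
            if e.sire_id != UNKNOWN:
                self.sire_idx[i] = self.order_index[e.sire_id]
            if e.dam_id != UNKNOWN:
                self.dam_idx[i] = self.order_index[e.dam_id]
        self._F: np.ndarray | None = None

    # -- basic protocol ---------------------------------------------------
    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, animal_id: str) -> bool:
        return animal_id in self.order_index

    @classmethod
    def from_entries(cls, entries) -> "Pedigree":
        return cls(list(entries))

    @property
    def founder_mask(self) -> np.ndarray:
        return (self.sire_idx < 0) & (self.dam_idx < 0)

    # -- relationship algebra ---------------------------------------------
    def inbreeding(self) -> np.ndarray:
        """Per-animal inbreeding coefficient F; founders get 0."""
        if self._F is None:
            self._F = _inbreeding_kernel(self.sire_idx, self.dam_idx)
        return self._F

    def relationship_matrix(self, max_dense: int = 5000) -> np.ndarray:
        """Dense numerator relationship matrix A by the tabular method."""
        if len(self) > max_dense:
            raise CapacityError(
                f"pedigree has {len(self)} animals, above the dense limit "
                f"{max_dense}; use inverse_relationship() instead"
            )
        return _tabular_a_kernel(self.sire_idx, self.dam_idx)

    def inverse_relationship(self) -> sp.csr_matrix:
        """Sparse A^-1 by Henderson's rules with inbreeding adjustment.

        Each animal i contributes delta_i^-1 times the rank-one block
        (1, -1/2, -1/2) x (1, -1/2, -1/2) on {i, sire, dam}, with
        delta_i = 1/2 - (F_s + F_d)/4 when both parents are known,
        3/4 - F_p/4 with one known parent, and 1 for founders.
        """
        F = self.inbreeding()
        n = len(self)
        rows, cols, vals = [], [], []
        for i in range(n):
            s = self.sire_idx[i]
            d = self.dam_idx[i]
            if s >= 0 and d >= 0:
                delta = 0.5 - 0.25 * (F[s] + F[d])
            elif s >= 0:
                delta = 0.75 - 0.25 * F[s]
            elif d >= 0:
                delta = 0.75 - 0.25 * F[d]
            else:
                delta = 1.0
            w = 1.0 / delta
            members = [(i, 1.0)]
            if s >= 0:
                members.append((s, -0.5))
            if d >= 0:
                members.append((d, -0.5))
            for a, ca in members:
                for b, cb in members:
                    rows.append(a)
                    cols.append(b)
                    vals.append(w * ca * cb)
        ainv = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
        ainv.sum_duplicates()
        return ainv

    def grandparent_paths(self) -> dict[str, set]:
        """Animals with grand-progeny, split by selection path.

        SS: sire of at least one sire; SD: sire of at least one dam;
        DS: dam of at least one sire; DD: dam of at least one dam.
        Membership is per category and unweighted by grand-offspring count;
        one animal may appear in several categories.
        """
        sires = set(self.sire_idx[self.sire_idx >= 0].tolist())
        dams = set(self.dam_idx[self.dam_idx >= 0].tolist())
        out: dict[str, set] = {c: set() for c in PATH_CATEGORIES}
        for j in sires:
            if self.sire_idx[j] >= 0:
                out["SS"].add(self.ids[self.sire_idx[j]])
            if self.dam_idx[j] >= 0:
                out["DS"].add(self.ids[self.dam_idx[j]])
        for j in dams:
            if self.sire_idx[j] >= 0:
                out["SD"].add(self.ids[self.sire_idx[j]])
            if self.dam_idx[j] >= 0:
                out["DD"].add(self.ids[self.dam_idx[j]])
        return out

    # -- IO ----------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "animal": self.ids,
                "sire": [e.sire_id for e in self.entries],
                "dam": [e.dam_id for e in self.entries],
                "sex": [e.sex for e in self.entries],
                "birth_year": [
                    "" if e.birth_year is None else int(e.birth_year) for e in self.entries
                ],
            }
        )

    def write(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _materialize_parents(entries: list[PedigreeEntry]) -> list[PedigreeEntry]:
    """Append founder entries for ids referenced only as parents.

    Sex is inherited from the parental role (sires are male, dams female);
    explicit entries with unknown sex that are used as parents are likewise
    resolved from their role.
    """
    known = {e.animal_id for e in entries}
    out = list(entries)
    seen = set(known)
    resolved_sex: dict[str, str] = {}
    for e in entries:
        if e.sire_id != UNKNOWN:
            resolved_sex.setdefault(e.sire_id, "M")
            if e.sire_id not in seen:
                out.append(PedigreeEntry(e.sire_id, sex="M"))
                seen.add(e.sire_id)
        if e.dam_id != UNKNOWN:
            resolved_sex.setdefault(e.dam_id, "F")
            if e.dam_id not in seen:
                out.append(PedigreeEntry(e.dam_id, sex="F"))
                seen.add(e.dam_id)
    # fill in sex for explicit entries known only through their parental role
    out = [
        PedigreeEntry(e.animal_id, e.sire_id, e.dam_id,
                      e.sex or resolved_sex.get(e.animal_id, UNKNOWN), e.birth_year)
        if e.sex == UNKNOWN
        else e
        for e in out
    ]
    return out


def _validate(entries: list[PedigreeEntry]) -> None:
    ids = [e.animal_id for e in entries]
    if len(ids) != len(set(ids)):
        dupes = sorted({a for a in ids if ids.count(a) > 1})
        raise IntegrityError(f"duplicate animal id(s): {dupes[:5]}")
    sires = {e.sire_id for e in entries if e.sire_id != UNKNOWN}
    dams = {e.dam_id for e in entries if e.dam_id != UNKNOWN}
    both = sires & dams
    if both:
        raise IntegrityError(
            f"id(s) used both as sire and as dam: {sorted(both)[:5]}"
        )
    by_id = {e.animal_id: e for e in entries}
    for a in sires:
        if by_id[a].sex == "F":
            raise IntegrityError(f"animal {a!r} recorded female but used as sire")
    for a in dams:
        if by_id[a].sex == "M":
            raise IntegrityError(f"animal {a!r} recorded male but used as dam")
    for e in entries:
        if e.animal_id in (e.sire_id, e.dam_id):
            raise CycleError(f"animal {e.animal_id!r} is listed as its own parent")


def _toposort(entries: list[PedigreeEntry]) -> list[PedigreeEntry]:
    """Kahn's algorithm over the parent->offspring DAG; stable in input order."""
    index = {e.animal_id: i for i, e in enumerate(entries)}
    n = len(entries)
    indegree = np.zeros(n, dtype=int)
    children: list[list[int]] = [[] for _ in range(n)]
    for i, e in enumerate(entries):
        for p in (e.sire_id, e.dam_id):
            if p != UNKNOWN:
                children[index[p]].append(i)
                indegree[i] += 1
    queue = deque(i for i in range(n) if indegree[i] == 0)
    order = []
    while queue:
        i = queue.popleft()
        order.append(i)
        for c in children[i]:
            indegree[c] -= 1
            if indegree[c] == 0:
                queue.append(c)
    if len(order) < n:
        stuck = next(entries[i].animal_id for i in range(n) if indegree[i] > 0)
        raise CycleError(
            f"pedigree contains a cycle; animal {stuck!r} is its own ancestor"
        )
    return [entries[i] for i in order]


def load_pedigree(source) -> Pedigree:
    """Read a pedigree from delimited text (comma or tab, autodetected).

    Requires a header with at least ``animal,sire,dam``; ``sex`` and
    ``birth_year`` columns are optional.  Missing parents may be encoded as
    an empty field, ``0`` or ``NA``.  Animals referenced only as parents are
    materialized as founders.
    """
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        if isinstance(source, (str,)) or hasattr(source, "__fspath__"):
            with open(source, "r", encoding="utf-8") as fh:
                text = fh.read()
        else:
            text = source.read()
        sep = "\t" if "\t" in text.splitlines()[0] else ","
        df = pd.read_csv(io.StringIO(text), sep=sep, dtype=str, keep_default_na=False)
    df.columns = [str(c).strip().lower() for c in df.columns]
    for col in ("animal", "sire", "dam"):
        if col not in df.columns:
            raise PedigreeError(f"pedigree file missing required column {col!r}")
    entries = []
    for row in df.itertuples(index=False):
        raw_sex = _clean_id(getattr(row, "sex", UNKNOWN)).upper()
        sex = raw_sex if raw_sex in ("M", "F") else UNKNOWN
        by = _clean_id(getattr(row, "birth_year", UNKNOWN))
        entries.append(
            PedigreeEntry(
                animal_id=_clean_id(row.animal),
                sire_id=_clean_id(row.sire),
                dam_id=_clean_id(row.dam),
                sex=sex,
                birth_year=int(float(by)) if by != UNKNOWN else None,
            )
        )
    if any(e.animal_id == UNKNOWN for e in entries):
        raise PedigreeError("pedigree contains a row with a missing animal id")
    return Pedigree(entries)
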