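"""Pedigree handling and additive (numerator) relationship matrices.

A pedigree is a directed acyclic graph of parent-offspring links with a sex
label on every individual.  The additive relationship matrix A gives the
expected proportion of additive genetic variance shared between individuals
(twice the kinship coefficient); its diagonal is 1 + F, where F is the
inbreeding coefficient.  A structures the "animal" (breeding-value) random
effect of the mixed model, and its sparse inverse is what the sampler
actually touches.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import sparse

__all__ = [
    "Pedigree",
    "PedigreeError",
    "RelationshipMatrix",
    "read_pedigree",
    "additive_relationship",
    "inverse_relationship",
    "inbreeding_coefficients",
]

#: tokens that mean "parent unknown" in pedigree files
NA_TOKENS = ("NA", "na", "", "nan")

FEMALE, MALE = 0, 1
_SEX_CODES = {
    "f": FEMALE, "female": FEMALE, "0": FEMALE,
    "m": MALE, "male": MALE, "1": MALE,
}
SEX_LABELS = ("female", "male")


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees."""


@dataclass(frozen=True)
class Pedigree:
    """Validated, topologically sorted pedigree.

    Attributes
    ----------
    ids : list of str
        Identifiers in topological order (every parent precedes its
        offspring).
    dam, sire : ndarray of int
        Position of each individual's parent in ``ids``; -1 when unknown.
    sex : ndarray of int
        0 = female, 1 = male.
    generation : list of str
        Free-form generation labels ("parental"/"offspring" by convention;
        empty string when the input file carried none).
    """

    ids: tuple[str, ...]
    dam: np.ndarray
    sire: np.ndarray
    sex: np.ndarray
    generation: tuple[str, ...]
    index: dict[str, int] = field(repr=False, default_factory=dict)

    def __post_init__(self):
        if not self.index:
            object.__setattr__(self, "index", {s: i for i, s in enumerate(self.ids)})

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def n_founders(self) -> int:
        return int(np.sum((self.dam < 0) & (self.sire < 0)))

    def sex_of(self, ident: str) -> int:
        return int(self.sex[self.index[ident]])

    def to_frame(self) -> pd.DataFrame:
        dam = [self.ids[d] if d >= 0 else "NA" for d in self.dam]
        sire = [self.ids[s] if s >= 0 else "NA" for s in self.sire]
        return pd.DataFrame(
            {
                "id": self.ids,
                "dam": dam,
                "sire": sire,
                "sex": [SEX_LABELS[s] for s in self.sex],
                "generation": self.generation,
            }
        )

    def write(self, path: str | Path, sep: str = ",") -> None:
        self.to_frame().to_csv(path, sep=sep, index=False)

    @classmethod
    def from_records(
        cls,
        records: list[tuple[str, str | None, str | None, str]] | pd.DataFrame,
        generation: list[str] | None = None,
        na_tokens: tuple[str, ...] = NA_TOKENS,
    ) -> "Pedigree":
        """Build and validate a pedigree from (id, dam, sire, sex) records.

        Records may arrive in any order; the result is topologically sorted
        with input order preserved among individuals whose parents are
        already placed (so parsing is idempotent and order-invariant).
        """
        if isinstance(records, pd.DataFrame):
            df = records
            required = {"id", "dam", "sire", "sex"}
            missing = required - set(df.columns)
            if missing:
                raise PedigreeError(f"pedigree table missing columns: {sorted(missing)}")
            gen = (
                df["generation"].astype(str).tolist()
                if "generation" in df.columns
                else [""] * len(df)
            )
            rows = list(
                zip(
                    df["id"].astype(str),
                    df["dam"].astype(str),
                    df["sire"].astype(str),
                    df["sex"].astype(str),
                )
            )
        else:
            rows = [(str(i), str(d), str(s), str(x)) for i, d, s, x in records]
            gen = list(generation) if generation is not None else [""] * len(rows)

        na = {t.lower() for t in na_tokens} | {"none"}

        ids = [r[0] for r in rows]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise PedigreeError(f"duplicate id(s): {dupes}")

        pos = {ident: k for k, ident in enumerate(ids)}
        sex = np.empty(len(rows), dtype=np.int64)
        dam_name: list[str | None] = []
        sire_name: list[str | None] = []
        for k, (ident, d, s, x) in enumerate(rows):
            xl = x.strip().lower()
            if xl in na:
                raise PedigreeError(f"individual {ident!r}: sex is mandatory")
            if xl not in _SEX_CODES:
                raise PedigreeError(f"individual {ident!r}: unknown sex code {x!r}")
            sex[k] = _SEX_CODES[xl]
            dam_name.append(None if d.strip().lower() in na else d.strip())
            sire_name.append(None if s.strip().lower() in na else s.strip())

        for k, (dn, sn) in enumerate(zip(dam_name, sire_name)):
            for role, name, want in (("dam", dn, FEMALE), ("sire", sn, MALE)):
                if name is None:
                    continue
                if name not in pos:
                    raise PedigreeError(
                        f"individual {ids[k]!r}: {role} {name!r} not in pedigree"
                    )
                if sex[pos[name]] != want:
                    raise PedigreeError(
                        f"{role} {name!r} of {ids[k]!r} is not "
                        f"{SEX_LABELS[want]} (sex inconsistency)"
                    )

        order = _toposort(ids, pos, dam_name, sire_name)

        new_pos = {ids[k]: j for j, k in enumerate(order)}
        dam_idx = np.array(
            [new_pos[dam_name[k]] if dam_name[k] is not None else -1 for k in order],
            dtype=np.int64,
        )
        sire_idx = np.array(
            [new_pos[sire_name[k]] if sire_name[k] is not None else -1 for k in order],
            dtype=np.int64,
        )
        return cls(
            ids=tuple(ids[k] for k in order),
            dam=dam_idx,
            sire=sire_idx,
            sex=sex[order].copy(),
            generation=tuple(gen[k] for k in order),
        )


def _toposort(ids, pos, dam_name, sire_name) -> list[int]:
    """Kahn's algorithm with id-lexicographic tie-breaking.

    The tie-break makes the resulting order a canonical function of the
    pedigree itself, so parsing is invariant to input row order.  Raises on
    cycles.
    """
    n = len(ids)
    children: dict[int, list[int]] = {k: [] for k in range(n)}
    indeg = np.zeros(n, dtype=np.int64)
    for k in range(n):
        for name in (dam_name[k], sire_name[k]):
            if name is not None:
                children[pos[name]].append(k)
                indeg[k] += 1
    ready = [(ids[k], k) for k in range(n) if indeg[k] == 0]
    heapq.heapify(ready)
    order: list[int] = []
    while ready:
        _, k = heapq.heappop(ready)
        order.append(k)
        for c in children[k]:
            indeg[c] -= 1
            if indeg[c] == 0:
                heapq.heappush(ready, (ids[c], c))
    if len(order) != n:
        stuck = [ids[k] for k in range(n) if indeg[k] > 0]
        raise PedigreeError(f"cycle detected involving: {stuck[:5]}")
    return order


def read_pedigree(path: str | Path, na_tokens: tuple[str, ...] = NA_TOKENS) -> Pedigree:
    """Read a delimited pedigree file (comma or tab autodetected).

    Expects a header with columns id, dam, sire, sex and optionally
    generation; unknown parents encoded by any of ``na_tokens``.
    """
    df = pd.read_csv(path, sep=None, engine="python", dtype=str, keep_default_na=False)
    df.columns = [c.strip().lower() for c in df.columns]
    return Pedigree.from_records(df, na_tokens=na_tokens)


@dataclass(frozen=True)
class RelationshipMatrix:
    """Additive relationship matrix A with per-individual inbreeding F."""

    order: tuple[str, ...]
    A: np.ndarray
    F: np.ndarray


def additive_relationship(ped: Pedigree) -> RelationshipMatrix:
    """Dense numerator relationship matrix by the tabular (recursive) method.

    A(i,i) = 1 + 0.5 A(dam_i, sire_i); A(i,j) = 0.5 (A(j, dam_i) + A(j, sire_i))
    for j preceding i; an unknown parent contributes 0.
    """
    n = len(ped)
    A = np.zeros((n, n))
    for i in range(n):
        d, s = ped.dam[i], ped.sire[i]
        row = np.zeros(i)
        if d >= 0:
            row += 0.5 * A[d, :i]
        if s >= 0:
            row += 0.5 * A[s, :i]
        A[i, :i] = row
        A[:i, i] = row
        A[i, i] = 1.0 + (0.5 * A[d, s] if d >= 0 and s >= 0 else 0.0)
    F = np.diag(A) - 1.0
    return RelationshipMatrix(order=ped.ids, A=A, F=F)


def inbreeding_coefficients(ped: Pedigree) -> np.ndarray:
    """Inbreeding coefficients by the Meuwissen & Luo recursion.

    Computes F(i) = A(i,i) - 1 through the L D L' decomposition of A without
    materializing A, so it stays cheap on large pedigrees.
    """
    n = len(ped)
    dam, sire = ped.dam, ped.sire
    # F of an unknown parent is taken as -1 so that the Mendelian sampling
    # variance D = 0.5 - 0.25 (F_d + F_s) covers all parent-knowledge cases.
    F = np.zeros(n)
    D = np.zeros(n)
    L = np.zeros(n)
    for i in range(n):
        d, s = dam[i], sire[i]
        fd = F[d] if d >= 0 else -1.0
        fs = F[s] if s >= 0 else -1.0
        D[i] = 0.5 - 0.25 * (fd + fs)
        if d < 0 or s < 0:
            F[i] = 0.0
            continue
        # accumulate A(i,i) = sum_j L(i,j)^2 D(j) over ancestors j
        L[i] = 1.0
        heap = [-i]
        in_heap = {i}
        fi = -1.0
        while heap:
            j = -heapq.heappop(heap)
            in_heap.discard(j)
            lj = L[j]
            for p in (dam[j], sire[j]):
                if p >= 0:
                    L[p] += 0.5 * lj
                    if p not in in_heap:
                        heapq.heappush(heap, -p)
                        in_heap.add(p)
            fi += lj * lj * D[j]
            L[j] = 0.0
        F[i] = fi
        # D was provisional for i only if parents precede it -- they do.
    return F


def inverse_relationship(ped: Pedigree) -> sparse.csr_matrix:
    """Sparse inverse of A assembled directly by Henderson's rules.

    Uses Meuwissen-Luo inbreeding coefficients so the Mendelian sampling
    variances are exact for inbred pedigrees.
    """
    n = len(ped)
    F = inbreeding_coefficients(ped)
    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []

    def add(r, c, v):
        rows.append(r)
        cols.append(c)
        vals.append(v)

    for i in range(n):
        d, s = ped.dam[i], ped.sire[i]
        fd = F[d] if d >= 0 else -1.0
        fs = F[s] if s >= 0 else -1.0
        b = 1.0 / (0.5 - 0.25 * (fd + fs))  # inverse Mendelian variance
        add(i, i, b)
        for p in (d, s):
            if p >= 0:
                add(i, p, -0.5 * b)
                add(p, i, -0.5 * b)
                add(p, p, 0.25 * b)
        if d >= 0 and s >= 0:
            add(d, s, 0.25 * b)
            add(s, d, 0.25 * b)
    Ainv = sparse.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    Ainv.sum_duplicates()
    return Ainv
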