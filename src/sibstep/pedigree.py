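"""Pedigree structures and the numerator relationship matrix A.

The pedigree is the ancestry graph of the breeding program: every animal
carries a sire and dam link (0 = unknown/base population), a generation
label and a full-sib family label.  From it we derive inbreeding
coefficients (Meuwissen & Luo recursion), the numerator relationship
matrix A (tabular method), its sparse inverse (Henderson's rules with
inbreeding) and the genotyped block A22 (Colleau's indirect method, so the
full dense A is never formed for large pedigrees).

Identifiers are arbitrary strings externally and consecutive 1-based
integer codes internally, assigned in topological (parents-first) order.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

__all__ = [
    "Pedigree",
    "PedigreeError",
    "validate_and_renumber",
    "inbreeding",
    "build_A",
    "build_A_inverse",
    "relationship_columns",
    "extract_A22",
]


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees (cycles, self-parenting...)."""


@dataclass
class Pedigree:
    """Validated, topologically ordered pedigree.

    Attributes
    ----------
    ids : object ndarray, original labels in topological order.
    sire, dam : int32 arrays of 1-based internal codes, 0 = unknown.
    generation : object ndarray of generation labels.
    family : object ndarray of full-sib family labels ('' for founders).
    """

    ids: np.ndarray
    sire: np.ndarray
    dam: np.ndarray
    generation: np.ndarray
    family: np.ndarray
    _code: dict = field(default_factory=dict, repr=False)
    _F: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not self._code:
            self._code = {a: i + 1 for i, a in enumerate(self.ids)}

    @property
    def n_animals(self) -> int:
        return len(self.ids)

    def code_of(self, labels) -> np.ndarray:
        """Map external labels to 1-based internal codes."""
        try:
            return np.asarray([self._code[x] for x in np.asarray(labels, dtype=object)])
        except KeyError as exc:  # pragma: no cover - message formatting
            raise PedigreeError(f"unknown animal id: {exc.args[0]!r}") from None

    @property
    def is_founder(self) -> np.ndarray:
        return (self.sire == 0) & (self.dam == 0)

    @property
    def inbreeding(self) -> np.ndarray:
        if self._F is None:
            self._F = inbreeding(self)
        return self._F

    def to_frame(self) -> pd.DataFrame:
        sire_lab = np.where(self.sire > 0, self.ids[np.maximum(self.sire - 1, 0)], "0")
        dam_lab = np.where(self.dam > 0, self.ids[np.maximum(self.dam - 1, 0)], "0")
        return pd.DataFrame(
            {
                "animal_id": self.ids,
                "sire_id": sire_lab,
                "dam_id": dam_lab,
                "generation": self.generation,
                "family_id": self.family,
            }
        )


def validate_and_renumber(raw: pd.DataFrame) -> Pedigree:
    """Validate a raw pedigree table and recode ids topologically.

    ``raw`` needs columns animal_id, sire_id, dam_id; generation and
    family_id are carried through when present.  Unknown parents are 0,
    empty or NA.  Raises :class:`PedigreeError` for duplicate ids,
    self-parenting, sire == dam, or cycles.
    """
    df = raw.copy()
    for col in ("animal_id", "sire_id", "dam_id"):
        if col not in df.columns:
            raise PedigreeError(f"pedigree table lacks required column {col!r}")
        df[col] = df[col].astype(object)

    def _norm(v):
        if pd.isna(v) or v in (0, "0", ""):
            return None
        return str(v)

    animals = [str(a) for a in df["animal_id"]]
    sires = [_norm(v) for v in df["sire_id"]]
    dams = [_norm(v) for v in df["dam_id"]]

    seen: dict[str, int] = {}
    for k, a in enumerate(animals):
        if a in seen:
            raise PedigreeError(f"duplicated animal id {a!r}")
        seen[a] = k
    for a, s, d in zip(animals, sires, dams):
        if s == a or d == a:
            raise PedigreeError(f"animal {a!r} is its own parent")
        if s is not None and s == d:
            raise PedigreeError(f"animal {a!r} has identical sire and dam {s!r}")

    # parents never listed as animals are implicit founders, prepended
    known = set(animals)
    implicit = []
    for p in sires + dams:
        if p is not None and p not in known:
            known.add(p)
            implicit.append(p)

    # Kahn topological sort: parent -> offspring edges
    all_ids = implicit + animals
    idx = {a: i for i, a in enumerate(all_ids)}
    n = len(all_ids)
    indeg = np.zeros(n, dtype=np.int64)
    children: list[list[int]] = [[] for _ in range(n)]
    par_s = np.full(n, -1, dtype=np.int64)
    par_d = np.full(n, -1, dtype=np.int64)
    for a, s, d in zip(animals, sires, dams):
        i = idx[a]
        for p, slot in ((s, par_s), (d, par_d)):
            if p is not None:
                slot[i] = idx[p]
                children[idx[p]].append(i)
                indeg[i] += 1

    heap = [i for i in range(n) if indeg[i] == 0]
    heapq.heapify(heap)
    order = []
    while heap:
        i = heapq.heappop(heap)
        order.append(i)
        for ch in children[i]:
            indeg[ch] -= 1
            if indeg[ch] == 0:
                heapq.heappush(heap, ch)
    if len(order) < n:
        stuck = [all_ids[i] for i in range(n) if indeg[i] > 0][:5]
        raise PedigreeError(f"pedigree contains a cycle involving ids {stuck}")

    pos = np.empty(n, dtype=np.int64)
    pos[order] = np.arange(n)
    new_ids = np.asarray(all_ids, dtype=object)[order]
    code = {a: i + 1 for i, a in enumerate(new_ids)}

    sire_code = np.zeros(n, dtype=np.int32)
    dam_code = np.zeros(n, dtype=np.int32)
    gen = np.full(n, "", dtype=object)
    fam = np.full(n, "", dtype=object)
    gen_col = df["generation"].astype(object) if "generation" in df.columns else None
    fam_col = df["family_id"].astype(object) if "family_id" in df.columns else None
    for k, (a, s, d) in enumerate(zip(animals, sires, dams)):
        i = pos[idx[a]]
        if s is not None:
            sire_code[i] = code[s]
        if d is not None:
            dam_code[i] = code[d]
        if gen_col is not None and not pd.isna(gen_col.iloc[k]):
            gen[i] = str(gen_col.iloc[k])
        if fam_col is not None and not pd.isna(fam_col.iloc[k]):
            fam[i] = str(fam_col.iloc[k])

    return Pedigree(new_ids, sire_code, dam_code, gen, fam, _code=code)


def _mendelian_variance(F: np.ndarray, sire: np.ndarray, dam: np.ndarray) -> np.ndarray:
    """Within-family (Mendelian sampling) variance d_i.

    Uses the F = -1 convention for unknown parents, which collapses the
    three cases (both/one/no parents known) into one expression:
    d_i = 0.5 - 0.25 (F_s + F_d).
    """
    Fpad = np.concatenate(([-1.0], F))
    return 0.5 - 0.25 * (Fpad[sire] + Fpad[dam])


def inbreeding(ped: Pedigree) -> np.ndarray:
    """Inbreeding coefficients by the Meuwissen & Luo ancestor-tracing recursion."""
    n = ped.n_animals
    sire = np.concatenate(([0], ped.sire)).astype(np.int64)
    dam = np.concatenate(([0], ped.dam)).astype(np.int64)
    F = np.zeros(n + 1)

    def d_of(j: int) -> float:
        fs = F[sire[j]] if sire[j] else -1.0
        fd = F[dam[j]] if dam[j] else -1.0
        return 0.5 - 0.25 * (fs + fd)

    for i in range(1, n + 1):
        if sire[i] == 0 or dam[i] == 0:
            F[i] = 0.0
            continue
        # a_ii of i via gene-flow contributions L over ancestors, F_i = a_ii - 1
        L: dict[int, float] = {i: 1.0}
        heap = [-i]
        a_ii = 0.0
        while heap:
            j = -heapq.heappop(heap)
            lj = L.pop(j, 0.0)
            if lj == 0.0:
                continue
            a_ii += lj * lj * d_of(j)
            for p in (sire[j], dam[j]):
                if p:
                    if p not in L:
                        heapq.heappush(heap, -p)
                        L[p] = 0.0
                    L[p] += lj / 2.0
        F[i] = a_ii - 1.0
    return F[1:]


def build_A(ped: Pedigree, max_dense: int = 20_000, force: bool = False) -> np.ndarray:
    """Dense numerator relationship matrix by the tabular method.

    Refuses pedigrees above ``max_dense`` animals unless ``force`` — the
    dense A is quadratic and only needed on small instances (oracles,
    explicit A22 slices).
    """
    n = ped.n_animals
    if n > max_dense and not force:
        raise MemoryError(
            f"dense A of order {n} exceeds the guard ({max_dense}); "
            "pass force=True or use the indirect methods"
        )
    # padded: row/col 0 is the unknown parent (all-zero relationships)
    A = np.zeros((n + 1, n + 1))
    s = ped.sire
    d = ped.dam
    for i in range(1, n + 1):
        si, di = s[i - 1], d[i - 1]
        row = 0.5 * (A[si, :i] + A[di, :i])
        A[i, :i] = row
        A[:i, i] = row
        A[i, i] = 1.0 + 0.5 * A[si, di]
    return A[1:, 1:]


def build_A_inverse(ped: Pedigree) -> sparse.csr_matrix:
    """Sparse A^-1 by Henderson's rules with inbreeding accounted for."""
    n = ped.n_animals
    F = ped.inbreeding
    s = ped.sire.astype(np.int64)
    d = ped.dam.astype(np.int64)
    alpha = 1.0 / _mendelian_variance(F, s, d)

    rows, cols, vals = [], [], []
    i = np.arange(1, n + 1)

    def add(r, c, v):
        rows.append(r)
        cols.append(c)
        vals.append(v)

    add(i, i, alpha)
    for p in (s, d):
        m = p > 0
        add(i[m], p[m], -alpha[m] / 2)
        add(p[m], i[m], -alpha[m] / 2)
        add(p[m], p[m], alpha[m] / 4)
    both = (s > 0) & (d > 0)
    add(s[both], d[both], alpha[both] / 4)
    add(d[both], s[both], alpha[both] / 4)

    rows = np.concatenate(rows) - 1
    cols = np.concatenate(cols) - 1
    vals = np.concatenate(vals)
    return sparse.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()


def relationship_columns(ped: Pedigree, codes: np.ndarray) -> np.ndarray:
    """Columns of A for the given 1-based codes, by Colleau's indirect method.

    Computes A e_j = T D T' e_j with two O(n) gene-flow sweeps per column,
    avoiding the dense tabular A entirely.
    """
    n = ped.n_animals
    s = ped.sire.astype(np.int64)
    d = ped.dam.astype(np.int64)
    Dm = _mendelian_variance(ped.inbreeding, s, d)
    codes = np.asarray(codes, dtype=np.int64)
    k = len(codes)
    # all requested columns swept simultaneously; row 0 is the unknown parent
    Z = np.zeros((n + 1, k))
    Z[codes, np.arange(k)] = 1.0
    for i in range(n, 0, -1):  # Z <- T' Z  (back-substitution)
        zi = Z[i]
        if s[i - 1]:
            Z[s[i - 1]] += 0.5 * zi
        if d[i - 1]:
            Z[d[i - 1]] += 0.5 * zi
    Z[1:] *= Dm[:, None]
    Z[0] = 0.0
    for i in range(1, n + 1):  # Z <- T Z  (forward substitution)
        Z[i] += 0.5 * (Z[s[i - 1]] + Z[d[i - 1]])
    return Z[1:]


def extract_A22(ped: Pedigree, genotyped_ids) -> np.ndarray:
    """Pedigree relationship block among genotyped animals (A22).

    Uses the indirect column method, so only n x n_genotyped work/memory is
    required even for large pedigrees.
    """
    codes = ped.code_of(genotyped_ids)
    cols = relationship_columns(ped, codes)
    return cols[codes - 1, :]
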