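"""Pedigree handling and numerator relationship matrices.

A pedigree is a set of ``(animal, sire, dam)`` triples; unknown parents mark
base-population founders.  The additive (numerator) relationship matrix
``A`` collects expected additive-genetic relationships: ``a_ij`` is twice
the kinship coefficient between *i* and *j*, and the diagonal is ``1 + F_i``
where ``F_i`` is the inbreeding coefficient of *i*.  ``A`` is computed with
the tabular method, processing animals in topological order::

    a_ii = 1 + 0.5 * a_{s(i), d(i)}
    a_ij = 0.5 * (a_{j, s(i)} + a_{j, d(i)})      for j processed before i

with missing-parent terms contributing zero.  Unknown parents are treated
as unique, unrelated, non-inbred founders.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

UNKNOWN = None
_MISSING_TOKENS = {"", "0", "na", "nan", "none", "unknown", "-", "."}


class PedigreeError(ValueError):
    """Structural problem in a pedigree (cycles, duplicates, missing parents)."""


class CycleError(PedigreeError):
    """An animal appears among its own ancestors."""


@dataclass(frozen=True)
class PedigreeRecord:
    """One animal with its (possibly unknown) parents."""

    animal_id: str
    sire_id: str | None = None
    dam_id: str | None = None
    series: str | None = None


@dataclass
class Pedigree:
    """Topologically ordered pedigree: every parent precedes its offspring.

    Attributes
    ----------
    records : list of PedigreeRecord in topological order.
    """

    records: list[PedigreeRecord]
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._index = {r.animal_id: i for i, r in enumerate(self.records)}
        if len(self._index) != len(self.records):
            seen: set[str] = set()
            for r in self.records:
                if r.animal_id in seen:
                    raise PedigreeError(f"duplicate animal id {r.animal_id!r}")
                seen.add(r.animal_id)
        for r in self.records:
            for pid in (r.sire_id, r.dam_id):
                if pid is not None:
                    j = self._index.get(pid)
                    if j is None:
                        raise PedigreeError(
                            f"parent {pid!r} of {r.animal_id!r} is not in the pedigree"
                        )
                    if j >= self._index[r.animal_id]:
                        raise PedigreeError(
                            f"pedigree not topologically sorted: parent {pid!r} "
                            f"does not precede offspring {r.animal_id!r}"
                        )

    # -- basic container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, animal_id: str) -> bool:
        return animal_id in self._index

    def index(self, animal_id: str) -> int:
        try:
            return self._index[animal_id]
        except KeyError:
            raise KeyError(f"animal {animal_id!r} not in pedigree") from None

    @property
    def ids(self) -> list[str]:
        return [r.animal_id for r in self.records]

    def parent_indices(self) -> tuple[np.ndarray, np.ndarray]:
        """Integer positions of sire and dam per animal; -1 for unknown."""
        sire = np.full(len(self.records), -1, dtype=np.int64)
        dam = np.full(len(self.records), -1, dtype=np.int64)
        for i, r in enumerate(self.records):
            if r.sire_id is not None:
                sire[i] = self._index[r.sire_id]
            if r.dam_id is not None:
                dam[i] = self._index[r.dam_id]
        return sire, dam

    @property
    def depth(self) -> int:
        """Longest ancestor chain; founders sit at depth 1."""
        sire, dam = self.parent_indices()
        d = np.ones(len(self.records), dtype=np.int64)
        for i in range(len(self.records)):
            for p in (sire[i], dam[i]):
                if p >= 0:
                    d[i] = max(d[i], d[p] + 1)
        return int(d.max()) if len(d) else 0

    @classmethod
    def from_records(cls, records: Iterable[PedigreeRecord]) -> "Pedigree":
        """Build a pedigree from records in any order (topological re-sort)."""
        recs = list(records)
        by_id: dict[str, PedigreeRecord] = {}
        for r in recs:
            if r.animal_id in by_id:
                raise PedigreeError(f"duplicate animal id {r.animal_id!r}")
            by_id[r.animal_id] = r
        for r in recs:
            for pid in (r.sire_id, r.dam_id):
                if pid is not None and pid not in by_id:
                    raise PedigreeError(
                        f"parent {pid!r} of {r.animal_id!r} is not in the pedigree"
                    )
        # Kahn's algorithm over parent -> offspring edges
        n_parents_left = {r.animal_id: sum(p is not None for p in (r.sire_id, r.dam_id)) for r in recs}
        children: dict[str, list[str]] = {r.animal_id: [] for r in recs}
        for r in recs:
            for pid in {p for p in (r.sire_id, r.dam_id) if p is not None}:
                children[pid].append(r.animal_id)
        ready = [r.animal_id for r in recs if n_parents_left[r.animal_id] == 0]
        ordered: list[PedigreeRecord] = []
        while ready:
            aid = ready.pop()
            ordered.append(by_id[aid])
            for ch in children[aid]:
                # both-parent edges from the same parent count once each
                n = sum(p == aid for p in (by_id[ch].sire_id, by_id[ch].dam_id))
                n_parents_left[ch] -= n
                if n_parents_left[ch] == 0:
                    ready.append(ch)
        if len(ordered) != len(recs):
            stuck = sorted(a for a, n in n_parents_left.items() if n > 0)
            raise CycleError(
                f"pedigree contains a cycle involving {stuck[0]!r} "
                f"({len(stuck)} animals unresolvable)"
            )
        return cls(ordered)


@dataclass
class RelationshipMatrix:
    """Numerator relationship matrix over an ordered id list."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.ids), len(self.ids)):
            raise ValueError("relationship matrix shape does not match id list")

    def loc(self, i: str, j: str) -> float:
        idx = {a: k for k, a in enumerate(self.ids)}
        return float(self.values[idx[i], idx[j]])

    def submatrix(self, keep: Sequence[str]) -> "RelationshipMatrix":
        idx = {a: k for k, a in enumerate(self.ids)}
        pos = [idx[a] for a in keep]
        return RelationshipMatrix(list(keep), self.values[np.ix_(pos, pos)])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def write(self, path: str | Path, sep: str = ",") -> None:
        self.to_dataframe().to_csv(path, sep=sep, index_label="id")


def _clean_id(value: object) -> str | None:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    s = str(value).strip()
    if s.lower() in _MISSING_TOKENS:
        return None
    # pandas reads numeric id columns as floats; normalise "1234.0" -> "1234"
    if s.endswith(".0") and s[:-2].isdigit():
        s = s[:-2]
    return s


def load_pedigree(path: str | Path) -> Pedigree:
    """Read a delimited pedigree file ``animal,sire,dam[,series]``.

    The delimiter (comma or tab) is sniffed; "0", "", "NA" and similar
    tokens in the parent columns mean *unknown*.  Records are returned in
    topological order regardless of file order.
    """
    df = pd.read_csv(path, sep=None, engine="python", dtype=str, skipinitialspace=True)
    if df.shape[1] < 3:
        raise PedigreeError(
            f"pedigree file {path} needs at least 3 columns (animal, sire, dam); "
            f"found {df.shape[1]}"
        )
    cols = list(df.columns)
    records = []
    for row in df.itertuples(index=False):
        aid = _clean_id(row[0])
        if aid is None:
            raise PedigreeError("missing animal id in pedigree file")
        series = _clean_id(row[3]) if len(cols) > 3 else None
        records.append(
            PedigreeRecord(aid, _clean_id(row[1]), _clean_id(row[2]), series)
        )
    return Pedigree.from_records(records)


def additive_relationship(ped: Pedigree) -> RelationshipMatrix:
    """Numerator relationship matrix by the tabular method.

    Founders (both parents unknown) are mutually unrelated with diagonal 1;
    a single known parent contributes its half of the recursion and the
    unknown side contributes zero.
    """
    n = len(ped)
    sire, dam = ped.parent_indices()
    A = np.zeros((n, n))
    for i in range(n):
        s, d = sire[i], dam[i]
        row = np.zeros(i)
        if s >= 0:
            row += 0.5 * A[s, :i]
        if d >= 0:
            row += 0.5 * A[d, :i]
        A[i, :i] = row
        A[:i, i] = row
        A[i, i] = 1.0 + (0.5 * A[s, d] if s >= 0 and d >= 0 else 0.0)
    return RelationshipMatrix(ped.ids, A)


def inbreeding(ped: Pedigree) -> tuple[pd.Series, float]:
    """Per-animal inbreeding coefficients ``F_i = a_ii - 1`` and their mean."""
    A = additive_relationship(ped)
    F = pd.Series(np.diag(A.values) - 1.0, index=ped.ids, name="F")
    return F, float(F.mean())


def prune_to_connected(ped: Pedigree, keep_ids: Iterable[str]) -> Pedigree:
    """Restrict the pedigree to ``keep_ids`` plus all of their ancestors.

    Relationships among the kept animals are unchanged because every path
    between them runs through common ancestors, which are retained.
    """
    keep = set(keep_ids)
    unknown = keep - set(ped.ids)
    if unknown:
        raise KeyError(f"ids not in pedigree: {sorted(unknown)[:5]}")
    sire, dam = ped.parent_indices()
    wanted = np.zeros(len(ped), dtype=bool)
    for aid in keep:
        wanted[ped.index(aid)] = True
    # topological order guarantees one reverse sweep closes the ancestor set
    for i in range(len(ped) - 1, -1, -1):
        if wanted[i]:
            for p in (sire[i], dam[i]):
                if p >= 0:
                    wanted[p] = True
    return Pedigree([r for i, r in enumerate(ped.records) if wanted[i]])
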