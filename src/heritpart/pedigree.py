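"""Pedigree numerator relationship matrix and pedigree summaries.

The A matrix holds expected additive relatedness (twice the coancestry);
it is built with the Henderson recursion after a topological sort, founders
having diagonal exactly 1 and each diagonal equal to 1 + F_i with F_i half
the parents' relatedness.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import PedigreeError

__all__ = [
    "AMatrix",
    "build_A",
    "pedigree_pair_counts",
    "mean_pairwise_relatedness",
    "extend_pedigree",
    "validate_pedigree",
]


@dataclasses.dataclass
class AMatrix:
    """Expected additive relationship matrix over pedigree members."""

    values: np.ndarray
    ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.ids = [str(s) for s in self.ids]
        if self.values.shape != (len(self.ids), len(self.ids)):
            raise ValueError("A matrix shape does not match id count")

    @property
    def n(self) -> int:
        return len(self.ids)

    def subset(self, ids: Sequence[str]) -> "AMatrix":
        pos = {s: i for i, s in enumerate(self.ids)}
        idx = np.array([pos[s] for s in ids])
        return AMatrix(self.values[np.ix_(idx, idx)], list(ids))


def _normalise(ped: pd.DataFrame) -> pd.DataFrame:
    ped = ped.copy()
    ped.columns = [c.lower() for c in ped.columns]
    for col in ("id", "sire", "dam"):
        if col not in ped.columns:
            raise PedigreeError(f"pedigree lacks column '{col}'")
    ped = ped[["id", "sire", "dam"]].astype("string")
    ped = ped.replace({"0": pd.NA, "": pd.NA})
    if ped["id"].duplicated().any():
        dup = ped.loc[ped["id"].duplicated(), "id"].tolist()
        raise PedigreeError(f"duplicate pedigree ids: {dup[:5]}")
    return ped


def _topological_order(ped: pd.DataFrame) -> list[str]:
    """Kahn topological sort, parents before offspring; reports any cycle."""
    ids = ped["id"].tolist()
    known = set(ids)
    parents = {
        row.id: [p for p in (row.sire, row.dam) if pd.notna(p)]
        for row in ped.itertuples()
    }
    unknown = sorted({p for ps in parents.values() for p in ps if p not in known})
    if unknown:
        raise PedigreeError(f"unknown parent ids (not in id column): {unknown[:5]}")
    children: dict[str, list[str]] = {i: [] for i in ids}
    indeg = {i: 0 for i in ids}
    for child, ps in parents.items():
        for p in ps:
            children[p].append(child)
            indeg[child] += 1
    queue = [i for i in ids if indeg[i] == 0]
    order: list[str] = []
    while queue:
        nxt = queue.pop(0)
        order.append(nxt)
        for c in children[nxt]:
            indeg[c] -= 1
            if indeg[c] == 0:
                queue.append(c)
    if len(order) != len(ids):
        cycle = sorted(i for i in ids if indeg[i] > 0)
        raise PedigreeError(f"pedigree contains a cycle involving: {cycle}")
    return order


def validate_pedigree(ped: pd.DataFrame) -> pd.DataFrame:
    """Normalise columns, check uniqueness/acyclicity; return the clean table."""
    ped = _normalise(ped)
    _topological_order(ped)
    return ped


def extend_pedigree(ped: pd.DataFrame, ids: Sequence[str]) -> pd.DataFrame:
    """Add unlisted individuals as unrelated founders (unknown parents).

    Used when the relationship matrix must cover genotyped individuals with
    no known connection to the pedigree.
    """
    ped = _normalise(ped)
    known = set(ped["id"])
    extra = [s for s in ids if s not in known]
    if extra:
        add = pd.DataFrame({"id": extra, "sire": pd.NA, "dam": pd.NA},
                           dtype="string")
        ped = pd.concat([ped, add], ignore_index=True)
    return ped


def build_A(ped: pd.DataFrame, ids: Optional[Sequence[str]] = None) -> AMatrix:
    """Henderson recursion for the numerator relationship matrix.

    ``a_ii = 1 + 0.5 a_sd`` (0 if either parent unknown) and
    ``a_ij = 0.5 (a_js + a_jd)`` for j earlier in a topological order, an
    unknown parent contributing 0.  ``ids`` optionally selects/reorders the
    returned rows.
    """
    ped = _normalise(ped)
    order = _topological_order(ped)
    pos = {s: i for i, s in enumerate(order)}
    prow = ped.set_index("id")
    n = len(order)
    a = np.zeros((n, n))
    for i, ind in enumerate(order):
        s, d = prow.loc[ind, "sire"], prow.loc[ind, "dam"]
        si = pos[s] if pd.notna(s) else None
        di = pos[d] if pd.notna(d) else None
        if i > 0:
            row = np.zeros(i)
            if si is not None:
                row += 0.5 * a[si, :i]
            if di is not None:
                row += 0.5 * a[di, :i]
            a[i, :i] = row
            a[:i, i] = row
        a[i, i] = 1.0 + (0.5 * a[si, di] if si is not None and di is not None else 0.0)
    amat = AMatrix(a, order)
    if ids is None:
        ids = ped["id"].tolist()  # return in input order
    missing = [s for s in ids if s not in pos]
    if missing:
        raise PedigreeError(f"ids not in pedigree: {missing[:5]}")
    return amat.subset(ids)


def pedigree_pair_counts(ped: pd.DataFrame) -> dict[str, int]:
    """Exact counts of parent-offspring, full-sib, half-sib and
    grandparent-grandchild pairs.

    Half-sibs share exactly one parent; pairs sharing both parents count
    only as full sibs.  A grandparent reached through both lineages counts
    once.
    """
    ped = _normalise(ped)
    sires = ped.set_index("id")["sire"]
    dams = ped.set_index("id")["dam"]

    parent_offspring = int(sires.notna().sum() + dams.notna().sum())

    both = ped.dropna(subset=["sire", "dam"])
    full = int(sum(k * (k - 1) // 2 for k in both.groupby(["sire", "dam"]).size()))

    same_sire = int(sum(k * (k - 1) // 2
                        for k in ped.dropna(subset=["sire"]).groupby("sire").size()))
    same_dam = int(sum(k * (k - 1) // 2
                       for k in ped.dropna(subset=["dam"]).groupby("dam").size()))
    half = same_sire + same_dam - 2 * full

    gp_pairs: set[tuple[str, str]] = set()
    for row in ped.itertuples():
        for parent in (row.sire, row.dam):
            if pd.isna(parent) or parent not in sires.index:
                continue
            for gp in (sires.get(parent), dams.get(parent)):
                if pd.notna(gp):
                    gp_pairs.add((gp, row.id))
    return {
        "parent_offspring": parent_offspring,
        "full_sib": full,
        "half_sib": half,
        "grandparent_grandchild": len(gp_pairs),
    }


def mean_pairwise_relatedness(a: AMatrix) -> float:
    """Mean of the off-diagonal upper-triangle entries of A."""
    if a.n < 2:
        raise ValueError("need at least 2 individuals")
    iu = np.triu_indices(a.n, k=1)
    return float(a.values[iu].mean())
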