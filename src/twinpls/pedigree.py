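"""Twin/sibling pedigrees and the expected additive-genetic relatedness matrix.

The classical twin design models the phenotypic covariance among family
members as a function of genetic proximity.  With no genotype data, the
expected coefficient of relationship on the 2*phi scale is 1.0 for
monozygotic (MZ) co-twins, 0.5 for dizygotic (DZ) co-twins and full
siblings, and 0 across families.  That matrix is the covariance kernel of
the polygenic model in :mod:`twinpls.varcomp`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Individual",
    "Pedigree",
    "RelatednessMatrix",
    "build_pedigree",
    "expected_relatedness",
    "family_blocks",
    "read_pedigree_csv",
]

ZYGOSITY_LABELS = frozenset({"MZ", "DZ", "SIB", "NONE"})

#: expected relatedness (2*phi) of co-members of a pair, by zygosity
PAIR_RELATEDNESS = {"MZ": 1.0, "DZ": 0.5, "SIB": 0.5}


class PedigreeError(ValueError):
    """Invalid pedigree structure (duplicate ids, inconsistent pairs, ...)."""


@dataclass(frozen=True)
class Individual:
    id: str
    family_id: str
    zygosity: str
    pair_id: str
    sex: int
    age: float


@dataclass
class Pedigree:
    """Validated cohort structure: families of MZ/DZ pairs, sibs, singletons."""

    individuals: list[Individual]
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._index = {ind.id: i for i, ind in enumerate(self.individuals)}

    def __len__(self) -> int:
        return len(self.individuals)

    @property
    def ids(self) -> list[str]:
        return [ind.id for ind in self.individuals]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [i.id for i in self.individuals],
                "family_id": [i.family_id for i in self.individuals],
                "pair_id": [i.pair_id for i in self.individuals],
                "zygosity": [i.zygosity for i in self.individuals],
                "sex": [i.sex for i in self.individuals],
                "age": [i.age for i in self.individuals],
            }
        )

    def subset(self, ids) -> "Pedigree":
        """Restrict to ``ids`` (kept in pedigree order); pairs losing a
        co-member are demoted to singletons."""
        keep = set(ids)
        records = self.to_frame()
        records = records[records["id"].isin(keep)].reset_index(drop=True)
        return build_pedigree(records)


def build_pedigree(records: pd.DataFrame) -> Pedigree:
    """Validate a table of individual records into a :class:`Pedigree`.

    Required columns: ``id, family_id, zygosity``; ``pair_id`` (empty for
    singletons), ``sex`` in {0,1} and ``age`` are optional with neutral
    defaults.  Row order is preserved.
    """
    records = pd.DataFrame(records).copy()
    required = {"id", "family_id", "zygosity"}
    missing = required - set(records.columns)
    if missing:
        raise PedigreeError(f"missing required columns: {sorted(missing)}")
    if "pair_id" not in records.columns:
        records["pair_id"] = ""
    if "sex" not in records.columns:
        records["sex"] = 0
    if "age" not in records.columns:
        records["age"] = np.nan

    records["id"] = records["id"].astype(str)
    records["family_id"] = records["family_id"].astype(str)
    records["pair_id"] = records["pair_id"].fillna("").astype(str)
    records["zygosity"] = records["zygosity"].astype(str).str.upper()

    if records["id"].duplicated().any():
        dups = records.loc[records["id"].duplicated(), "id"].tolist()
        raise PedigreeError(f"duplicate individual id(s): {dups}")
    bad = set(records["zygosity"]) - ZYGOSITY_LABELS
    if bad:
        raise PedigreeError(f"unknown zygosity label(s): {sorted(bad)}")

    paired = records[records["zygosity"].isin(PAIR_RELATEDNESS)]
    for (pair_id, zyg), grp in paired[paired["pair_id"] != ""].groupby(
        ["pair_id", "zygosity"], sort=False
    ):
        if grp["family_id"].nunique() > 1:
            raise PedigreeError(
                f"{zyg} pair {pair_id!r} spans families "
                f"{sorted(grp['family_id'].unique())}"
            )

    # pairs need a pair_id; a labelled twin without one cannot be matched
    no_pair = paired[paired["pair_id"] == ""]
    if len(no_pair):
        raise PedigreeError(
            f"zygosity {sorted(no_pair['zygosity'].unique())} rows without "
            f"pair_id: {no_pair['id'].tolist()}"
        )

    # demote size-1 "pairs" to singletons, tolerating truncated tables
    counts = paired.groupby("pair_id")["id"].count()
    lonely = set(counts.index[counts < 2])
    if lonely:
        warnings.warn(
            f"pair group(s) of size 1 demoted to singletons: {sorted(lonely)}",
            stacklevel=2,
        )
        mask = records["pair_id"].isin(lonely)
        records.loc[mask, ["zygosity", "pair_id"]] = ["NONE", ""]

    individuals = [
        Individual(
            id=r.id,
            family_id=r.family_id,
            zygosity=r.zygosity,
            pair_id=r.pair_id,
            sex=int(r.sex),
            age=float(r.age),
        )
        for r in records.itertuples(index=False)
    ]
    return Pedigree(individuals)


def read_pedigree_csv(path) -> Pedigree:
    """Read ``id,family_id,pair_id,zygosity,sex,age`` CSV into a Pedigree."""
    return build_pedigree(pd.read_csv(path, comment="#", dtype={"id": str}))


@dataclass
class RelatednessMatrix:
    """Expected relatedness (2*phi scale) with its family block structure.

    ``values`` is symmetric with unit diagonal and is block diagonal over
    ``blocks`` (index sets of families); this structure lets the polygenic
    likelihood be evaluated family by family.
    """

    ids: list[str]
    values: np.ndarray
    blocks: list[np.ndarray]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("relatedness matrix shape does not match ids")

    @property
    def n(self) -> int:
        return len(self.ids)

    def reindex(self, ids) -> "RelatednessMatrix":
        """Reorder/subset to ``ids``; block structure is recomputed."""
        pos = {j: i for i, j in enumerate(self.ids)}
        try:
            idx = np.array([pos[i] for i in ids])
        except KeyError as e:
            raise KeyError(f"id {e.args[0]!r} not in relatedness matrix") from e
        values = self.values[np.ix_(idx, idx)]
        return RelatednessMatrix(list(ids), values, _connected_blocks(values))


def expected_relatedness(pedigree: Pedigree) -> RelatednessMatrix:
    """Expected additive-genetic relatedness implied by the pedigree.

    MZ co-twins (shared pair_id) get 1.0; DZ co-twins and labelled full
    siblings within a family get 0.5; everything else — including unlabelled
    (NONE) co-familial pairs — gets 0.  Half-sibs and multi-generation links
    are not modelled.
    """
    n = len(pedigree)
    K = np.eye(n)
    fam: dict[str, list[int]] = {}
    for i, ind in enumerate(pedigree.individuals):
        fam.setdefault(ind.family_id, []).append(i)
    for members in fam.values():
        for a_pos, i in enumerate(members):
            for j in members[a_pos + 1 :]:
                a, b = pedigree.individuals[i], pedigree.individuals[j]
                r = 0.0
                if a.zygosity == "MZ" and b.zygosity == "MZ" and a.pair_id == b.pair_id:
                    r = 1.0
                elif a.zygosity == "DZ" and b.zygosity == "DZ" and a.pair_id == b.pair_id:
                    r = 0.5
                elif "SIB" in (a.zygosity, b.zygosity) and a.zygosity != "NONE" and b.zygosity != "NONE":
                    r = 0.5
                K[i, j] = K[j, i] = r
    return RelatednessMatrix(pedigree.ids, K, _connected_blocks(K))


def family_blocks(pedigree: Pedigree) -> list[np.ndarray]:
    """Partition indices into maximal sets with any nonzero relatedness."""
    return expected_relatedness(pedigree).blocks


def _connected_blocks(values: np.ndarray) -> list[np.ndarray]:
    """Connected components of the nonzero off-diagonal pattern."""
    n = values.shape[0]
    seen = np.zeros(n, dtype=bool)
    blocks = []
    for start in range(n):
        if seen[start]:
            continue
        stack = [start]
        comp = []
        seen[start] = True
        while stack:
            i = stack.pop()
            comp.append(i)
            nbr = np.nonzero(values[i] != 0)[0]
            for j in nbr:
                if not seen[j]:
                    seen[j] = True
                    stack.append(j)
        blocks.append(np.array(sorted(comp)))
    return blocks
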