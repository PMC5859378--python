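"""Pedigree container: individual / sire / dam triples plus cross block.

Unknown parents are coded ``"0"``.  Founders (both parents unknown) carry the
factorial-block label of the cross they were mated in; offspring inherit the
block of their parents.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

UNKNOWN = "0"


@dataclass
class Pedigree:
    """Wrapper around a ``DataFrame`` with columns id, sire, dam, block."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"id", "sire", "dam"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"pedigree table needs columns {sorted(required)}")
        if "block" not in self.table.columns:
            self.table = self.table.assign(block=0)
        self.table = self.table.astype({"id": str, "sire": str, "dam": str}).reset_index(drop=True)
        if self.table["id"].duplicated().any():
            raise ValueError("duplicate individual ids in pedigree")

    @property
    def ids(self) -> np.ndarray:
        return self.table["id"].to_numpy(dtype=object)

    @property
    def n(self) -> int:
        return len(self.table)

    def founders(self) -> np.ndarray:
        t = self.table
        return t.loc[(t["sire"] == UNKNOWN) & (t["dam"] == UNKNOWN), "id"].to_numpy(dtype=object)

    def offspring(self) -> np.ndarray:
        t = self.table
        return t.loc[(t["sire"] != UNKNOWN) | (t["dam"] != UNKNOWN), "id"].to_numpy(dtype=object)

    def parents_of(self, individual: str) -> tuple[str, str]:
        row = self.table.loc[self.table["id"] == individual]
        if row.empty:
            raise KeyError(f"{individual!r} not in pedigree")
        return str(row["sire"].iloc[0]), str(row["dam"].iloc[0])

    def topological_order(self) -> np.ndarray:
        """Row indices ordered so parents precede offspring.

        Raises ``ValueError`` on a cyclic pedigree or a parent reference to
        an individual not listed in the table (unknown ``"0"`` excepted).
        """
        ids = self.ids
        pos = {s: i for i, s in enumerate(ids)}
        depth: dict[str, int] = {}

        def d(ind: str, trail: frozenset) -> int:
            if ind == UNKNOWN:
                return -1
            if ind in trail:
                raise ValueError("cyclic pedigree")
            if ind in depth:
                return depth[ind]
            if ind not in pos:
                raise ValueError(f"parent {ind!r} not listed as an individual")
            s, m = self.table["sire"].iloc[pos[ind]], self.table["dam"].iloc[pos[ind]]
            trail = trail | {ind}
            depth[ind] = 1 + max(d(s, trail), d(m, trail))
            return depth[ind]

        for ind in ids:
            d(ind, frozenset())
        order = sorted(range(len(ids)), key=lambda i: (depth[ids[i]], i))
        return np.asarray(order, dtype=int)

    def sorted(self) -> "Pedigree":
        return Pedigree(self.table.iloc[self.topological_order()].reset_index(drop=True))

    def family_sizes(self) -> pd.Series:
        """Full-sib family sizes keyed by (sire, dam), offspring only."""
        t = self.table
        off = t[(t["sire"] != UNKNOWN) & (t["dam"] != UNKNOWN)]
        return off.groupby(["sire", "dam"]).size()

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "Pedigree":
        return cls(pd.read_csv(path, dtype={"id": str, "sire": str, "dam": str}))
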