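"""Local labelled reference panel used for chimera screening and OTU naming.

Stands in for live similarity searches against public databases: each
reference carries a full ITS sequence, taxonomic labels at species, genus and
family rank, and the 0-based half-open boundaries of the conserved 5.8S
region (so ITS1 is the prefix and ITS2 the suffix).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from .align import ReferenceIndex

REQUIRED_COLUMNS = (
    "ref_id",
    "sequence",
    "species",
    "genus",
    "family",
    "its1_end",
    "fivep8s_end",
)


@dataclass
class ReferenceDB:
    """Reference sequences with taxonomy and marker-region boundaries."""

    table: pd.DataFrame
    _indexes: dict[str, ReferenceIndex] = field(default_factory=dict, repr=False)

    def __post_init__(self):
        missing = [c for c in REQUIRED_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"reference table lacks columns: {missing}")
        if len(self.table) == 0:
            raise ValueError("reference database is empty")
        self.table = self.table.reset_index(drop=True)
        for _, row in self.table.iterrows():
            n = len(row["sequence"])
            if not 0 < row["its1_end"] < row["fivep8s_end"] <= n:
                raise ValueError(
                    f"reference {row['ref_id']}: region bounds "
                    f"({row['its1_end']}, {row['fivep8s_end']}) invalid for "
                    f"length {n}"
                )

    def __len__(self) -> int:
        return len(self.table)

    def region(self, which: str) -> list[str]:
        """All reference subsequences for 'its1', '5.8s', 'its2' or 'full'."""
        out = []
        for _, row in self.table.iterrows():
            s, a, b = row["sequence"], row["its1_end"], row["fivep8s_end"]
            if which == "its1":
                out.append(s[:a])
            elif which == "5.8s":
                out.append(s[a:b])
            elif which == "its2":
                out.append(s[b:])
            elif which == "full":
                out.append(s)
            else:
                raise ValueError(f"unknown region {which!r}")
        return out

    def index(self, which: str) -> ReferenceIndex:
        if which not in self._indexes:
            self._indexes[which] = ReferenceIndex(self.region(which))
        return self._indexes[which]

    def best_match(self, query: str, which: str = "full") -> tuple[pd.Series, float]:
        """Best-matching reference row and its alignment identity."""
        idx, ident = self.index(which).best_match(query)
        return self.table.iloc[idx], ident

    def conserved_profile(self) -> str:
        """Per-column majority consensus of the 5.8S regions (the conserved
        core used to locate region boundaries in query sequences)."""
        regions = self.region("5.8s")
        length = min(len(r) for r in regions)
        cols = []
        for j in range(length):
            counts = Counter(r[j] for r in regions)
            cols.append(max(sorted(counts), key=counts.get))
        return "".join(cols)

    @classmethod
    def from_metacommunity(cls, community) -> "ReferenceDB":
        tbl = community.references.rename(columns={"otu_id": "ref_id"}).copy()
        return cls(tbl[list(REQUIRED_COLUMNS)])
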