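"""The annual ramet census table.

One row per ramet.  Year-t ramets carry ``size_t`` (log m² surface area),
their fate (``survived``, and ``size_t1`` if they survived) and their
reproduction at t (``flowered``, ``n_flowers``).  Recruits are ramets first
observed at t+1: they have ``is_recruit = 1``, no ``size_t`` and no fate
fields, only ``size_t1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvariantViolationError

__all__ = ["COLUMNS", "RametDataset"]

COLUMNS = [
    "ramet_id",
    "size_t",
    "survived",
    "size_t1",
    "flowered",
    "n_flowers",
    "is_recruit",
]


def _isna(x):
    return pd.isna(x)


@dataclass
class RametDataset:
    """A year-over-year ramet table plus its census-year labels."""

    data: pd.DataFrame
    year_t: int = 2018
    year_t1: int = 2019

    def __post_init__(self):
        missing = [c for c in COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"ramet table missing columns: {missing}")
        self.data = self.data[COLUMNS].reset_index(drop=True)

    # ---- views -----------------------------------------------------------

    @property
    def n_records(self) -> int:
        return len(self.data)

    @property
    def year_t_records(self) -> pd.DataFrame:
        """Ramets present at time t (excludes recruits)."""
        rec = self.data["is_recruit"].fillna(0).astype(float)
        return self.data[rec != 1]

    @property
    def recruit_records(self) -> pd.DataFrame:
        rec = self.data["is_recruit"].fillna(0).astype(float)
        return self.data[rec == 1]

    @property
    def n_survivors(self) -> int:
        return int((self.year_t_records["survived"] == 1).sum())

    @property
    def n_flowering(self) -> int:
        return int((self.year_t_records["flowered"] == 1).sum())

    @property
    def n_recruits(self) -> int:
        return len(self.recruit_records)

    @property
    def total_flowers(self) -> int:
        return int(self.year_t_records["n_flowers"].fillna(0).sum())

    @property
    def recruit_sizes(self) -> np.ndarray:
        return self.recruit_records["size_t1"].to_numpy(dtype=float)

    # ---- validation ------------------------------------------------------

    def check_invariants(self) -> list[tuple[int, str]]:
        """Return (row, message) pairs for every invariant violation."""
        d = self.data
        out: list[tuple[int, str]] = []
        dup = d["ramet_id"].duplicated(keep=False)
        for i in d.index[dup]:
            out.append((int(i), f"duplicate ramet_id {d.at[i, 'ramet_id']!r}"))
        for i in d.index:
            row = d.loc[i]
            recruit = (not _isna(row["is_recruit"])) and row["is_recruit"] == 1
            if recruit:
                if not _isna(row["size_t"]):
                    out.append((int(i), "recruit has size_t present"))
                if _isna(row["size_t1"]):
                    out.append((int(i), "recruit missing size_t1"))
                continue
            if _isna(row["size_t"]):
                out.append((int(i), "year-t record missing size_t"))
            if not _isna(row["survived"]) and row["survived"] == 0 and not _isna(row["size_t1"]):
                out.append((int(i), "dead ramet (survived=0) has size_t1 present"))
            if not _isna(row["survived"]) and row["survived"] == 1 and _isna(row["size_t1"]):
                out.append((int(i), "survivor missing size_t1"))
            if not _isna(row["flowered"]):
                nfl = 0 if _isna(row["n_flowers"]) else row["n_flowers"]
                if row["flowered"] == 1 and nfl < 1:
                    out.append((int(i), "flowered=1 but n_flowers < 1"))
                if row["flowered"] == 0 and nfl >= 1:
                    out.append((int(i), "flowered=0 but n_flowers >= 1"))
        return out

    def validate(self) -> "RametDataset":
        violations = self.check_invariants()
        if violations:
            raise InvariantViolationError(violations)
        return self

    def equals(self, other: "RametDataset") -> bool:
        return (
            self.year_t == other.year_t
            and self.year_t1 == other.year_t1
            and self.data.equals(other.data)
        )
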