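"""Core domain containers.

Expression data are held as a pandas DataFrame (entities x samples) plus a
per-entity class label ("miRNA" or "mRNA").  Identifiers are opaque,
case-sensitive strings throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

MIRNA = "miRNA"
MRNA = "mRNA"


@dataclass
class ExpressionMatrix:
    """Entities x samples real matrix; NaN marks a missing measurement."""

    values: pd.DataFrame                # index = entity ids, columns = sample ids
    entity_class: pd.Series             # entity id -> "miRNA" | "mRNA"

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate entity ids: {dups}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        self.entity_class = self.entity_class.reindex(self.values.index)

    @property
    def entity_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_entities(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def ids_of_class(self, cls: str) -> list[str]:
        return list(self.entity_class.index[self.entity_class == cls])

    def subset(self, entity_ids: Iterable[str]) -> "ExpressionMatrix":
        ids = list(entity_ids)
        return ExpressionMatrix(self.values.loc[ids].copy(),
                                self.entity_class.loc[ids].copy())

    def equals(self, other: "ExpressionMatrix") -> bool:
        return (self.values.equals(other.values)
                and self.entity_class.equals(other.entity_class))

    @classmethod
    def from_array(cls, arr: np.ndarray, entity_ids: list[str],
                   sample_ids: list[str], classes: list[str]) -> "ExpressionMatrix":
        df = pd.DataFrame(np.asarray(arr, dtype=float),
                          index=entity_ids, columns=sample_ids)
        return cls(df, pd.Series(classes, index=entity_ids))


@dataclass
class SurvivalTable:
    """Per-sample follow-up time (days) and event indicator (1 = observed)."""

    table: pd.DataFrame                 # index = sample id; columns: time, event

    def __post_init__(self) -> None:
        missing = {"time", "event"} - set(self.table.columns)
        if missing:
            raise ValueError(f"survival table missing columns: {sorted(missing)}")
        if (self.table["time"] < 0).any():
            bad = self.table.index[self.table["time"] < 0].tolist()
            raise ValueError(f"negative survival time for samples: {bad}")
        if not self.table["event"].isin([0, 1]).all():
            raise ValueError("event column must be 0/1")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)


@dataclass
class BindingNetwork:
    """Putative miRNA -> target-mRNA edge set (bipartite)."""

    edges: set[tuple[str, str]] = field(default_factory=set)

    def __post_init__(self) -> None:
        regs = {u for u, _ in self.edges}
        tgts = {v for _, v in self.edges}
        both = regs & tgts
        if both:
            raise ValueError(
                f"identifiers appear as both regulator and target: {sorted(both)}")

    @property
    def mirnas(self) -> set[str]:
        return {u for u, _ in self.edges}

    @property
    def mrnas(self) -> set[str]:
        return {v for _, v in self.edges}

    def targets_of(self, mirna: str) -> set[str]:
        return {v for u, v in self.edges if u == mirna}

    def regulators_of(self, mrna: str) -> set[str]:
        return {u for u, v in self.edges if v == mrna}

    def restrict(self, mirnas: Iterable[str], mrnas: Iterable[str]) -> "BindingNetwork":
        mi, mr = set(mirnas), set(mrnas)
        return BindingNetwork({(u, v) for u, v in self.edges if u in mi and v in mr})


@dataclass
class GeneList:
    name: str
    members: set[str] = field(default_factory=set)
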