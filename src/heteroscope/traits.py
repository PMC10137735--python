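"""Trait tables for parents and hybrids, and descriptive summaries.

Traits are agronomic measurements (weights in kg, lengths/widths/heights in
cm, leaf numbers as counts).  Entities are parent or hybrid codes from the
diallel design.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd


class TraitError(ValueError):
    pass


@dataclass
class TraitTable:
    """Wide entity × trait table of observed values."""

    data: pd.DataFrame  # index: entity code, columns: trait names, float values

    def __post_init__(self) -> None:
        self.data = self.data.astype(float)

    @property
    def traits(self) -> list[str]:
        return list(self.data.columns)

    @property
    def entities(self) -> list[str]:
        return list(self.data.index)

    def get(self, entity: str, trait: str) -> float:
        return float(self.data.loc[entity, trait])

    # -- I/O: both wide and long dialects ---------------------------------

    @classmethod
    def read_wide(cls, path: str | Path, sep: str = "\t") -> "TraitTable":
        df = pd.read_csv(path, sep=sep, index_col=0, comment="#")
        df.index = df.index.astype(str)
        return cls(df)

    @classmethod
    def read_long(cls, path: str | Path, sep: str = "\t") -> "TraitTable":
        long = pd.read_csv(path, sep=sep, comment="#")
        long.columns = [c.lower() for c in long.columns]
        wide = long.pivot(index="entity", columns="trait", values="value")
        wide.index = wide.index.astype(str)
        wide.columns.name = None
        return cls(wide)

    def write_wide(self, path: str | Path, sep: str = "\t") -> None:
        self.data.to_csv(path, sep=sep, float_format="%.6g", index_label="entity")

    def write_long(self, path: str | Path, sep: str = "\t") -> None:
        long = self.data.stack().rename("value").reset_index()
        long.columns = ["entity", "trait", "value"]
        long.to_csv(path, sep=sep, float_format="%.6g", index=False)


@dataclass(frozen=True)
class SummaryRecord:
    """Descriptive summary of one trait over one group of entities.

    ``cv`` is the coefficient of variation in percent, ``100 * sd / mean``;
    it is ``None`` (flagged undefined) when the mean is not positive.
    """

    group: str
    trait: str
    n: int
    mean: float
    sd: float
    minimum: float
    maximum: float
    cv: float | None


def trait_summary(traits: TraitTable, entities: Iterable[str], trait: str,
                  group: str = "") -> SummaryRecord:
    """Mean, sample SD (n−1), range and CV% of *trait* over *entities*.

    Requires at least two finite values.  Non-finite values are excluded.
    """
    entities = list(entities)
    values = traits.data.loc[entities, trait].to_numpy(dtype=float)
    values = values[np.isfinite(values)]
    if values.size < 2:
        raise TraitError(f"trait {trait!r}: need >= 2 finite values, got {values.size}")
    mean = float(np.mean(values))
    sd = float(np.std(values, ddof=1))
    cv = 100.0 * sd / mean if mean > 0 else None
    return SummaryRecord(group=group, trait=trait, n=int(values.size), mean=mean, sd=sd,
                         minimum=float(values.min()), maximum=float(values.max()), cv=cv)


def summary_table(traits: TraitTable, groups: Mapping[str, Iterable[str]]) -> pd.DataFrame:
    """Summaries for every trait × group, as a tidy DataFrame."""
    rows = []
    for group, entities in groups.items():
        entities = list(entities)
        for trait in traits.traits:
            rec = trait_summary(traits, entities, trait, group=group)
            rows.append({"group": rec.group, "trait": rec.trait, "n": rec.n,
                         "mean": rec.mean, "sd": rec.sd, "min": rec.minimum,
                         "max": rec.maximum, "cv_percent": rec.cv if rec.cv is not None else math.nan})
    return pd.DataFrame(rows)
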