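"""Mid-parent and high-parent heterosis for every hybrid × trait.

Two reporting conventions are supported for both statistics:

``difference`` (default)
    MPH = 100·(F1 − MP)/MP and HPH = 100·(F1 − HP)/HP, i.e. the percent
    deviation of the hybrid from the mid-parent (MP) and better-parent (HP)
    values.  Under this convention HPH ≤ MPH always (HP ≥ MP > 0).

``ratio``
    MPH = 100·F1/MP and HPH = 100·F1/HP, the hybrid as a percentage of the
    parental reference.  Each statistic equals its difference-convention
    value plus exactly 100, so correlations with either are identical.

The "better" parent defaults to the larger trait value for every trait; a
per-trait direction map can override this for traits where smaller is better.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd

from .design import DiallelDesign
from .traits import TraitTable

logger = logging.getLogger(__name__)

CONVENTIONS = ("difference", "ratio")


def compute_heterosis(design: DiallelDesign, traits: TraitTable,
                      convention: str = "difference",
                      better: Mapping[str, str] | None = None) -> pd.DataFrame:
    """One record per (hybrid, trait): F1, MP, HP, MPH, HPH.

    Hybrids lacking a finite positive parental reference for a trait are
    skipped with a warning naming the hybrid and trait (the percent
    statistics are undefined for non-positive denominators).

    Parameters
    ----------
    better:
        optional map trait → ``"max"`` (default) or ``"min"``, choosing the
        better-parent direction per trait.
    """
    if convention not in CONVENTIONS:
        raise ValueError(f"unknown convention {convention!r}; expected one of {CONVENTIONS}")
    better = dict(better or {})
    rows = []
    for trait in traits.traits:
        for cross in design.crosses:
            try:
                f1 = traits.get(cross.hybrid, trait)
                pf = traits.get(cross.female, trait)
                pm = traits.get(cross.male, trait)
            except KeyError:
                logger.warning("heterosis: %s/%s skipped (value missing)", cross.hybrid, trait)
                continue
            if not all(np.isfinite(v) for v in (f1, pf, pm)) or pf <= 0 or pm <= 0:
                logger.warning("heterosis: %s/%s skipped (non-positive or non-finite parent value)",
                               cross.hybrid, trait)
                continue
            mp = (pf + pm) / 2.0
            hp = min(pf, pm) if better.get(trait, "max") == "min" else max(pf, pm)
            if convention == "difference":
                mph = 100.0 * (f1 - mp) / mp
                hph = 100.0 * (f1 - hp) / hp
            else:
                mph = 100.0 * f1 / mp
                hph = 100.0 * f1 / hp
            rows.append({"hybrid": cross.hybrid, "trait": trait, "F1": f1,
                         "MP": mp, "HP": hp, "MPH": mph, "HPH": hph})
    result = pd.DataFrame(rows, columns=["hybrid", "trait", "F1", "MP", "HP", "MPH", "HPH"])
    result.attrs["convention"] = convention
    return result


def parent_mean_heterosis(records: pd.DataFrame, design: DiallelDesign, trait: str,
                          statistic: str = "MPH") -> pd.Series:
    """Per-parent mean of MPH or HPH over all hybrids carrying that parent.

    A hybrid contributes to both its female and its male parent.  Parents
    with no hybrid record for the trait are omitted with a warning.
    """
    if statistic not in ("MPH", "HPH"):
        raise ValueError(f"statistic must be MPH or HPH, got {statistic!r}")
    sub = records[records["trait"] == trait]
    values = dict(zip(sub["hybrid"], sub[statistic]))
    means = {}
    for parent in design.parents:
        contrib = [values[c.hybrid] for c in design.crosses
                   if parent in (c.female, c.male) and c.hybrid in values]
        if not contrib:
            logger.warning("parent %s has no hybrid %s records for trait %s", parent, statistic, trait)
            continue
        means[parent] = float(np.mean(contrib))
    series = pd.Series(means, name=f"mean_{statistic}")
    series.index.name = "parent"
    return series


def heterosis_responses(records: pd.DataFrame, trait: str) -> pd.DataFrame:
    """Hybrid-indexed response table for correlation analyses.

    Columns: ``observed`` (F1 value) and ``MPH`` for *trait*, one row per
    hybrid having a heterosis record.
    """
    sub = records[records["trait"] == trait]
    out = sub.set_index("hybrid")[["F1", "MPH"]].rename(columns={"F1": "observed"})
    out.attrs["convention"] = records.attrs.get("convention", "difference")
    out.attrs["trait"] = trait
    return out
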