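"""Diallel mating design: parsing, validation and grid round-trip I/O.

A complete diallel crosses every pair of inbred parents in both directions
(reciprocals are distinct because the female parent is recorded).  The design
is conventionally written as a square grid whose row header is the female
parent, whose column header is the male parent, whose diagonal is blank, and
whose off-diagonal cells hold either the hybrid's code or a missing-cross
marker.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

#: Marker used for crosses that were not obtained, as written in the grid.
MISSING_MARKER = "/"


class DesignError(ValueError):
    """Raised when a design grid or cross list violates the diallel contract."""


@dataclass(frozen=True)
class Cross:
    """One hybrid: ``female × male`` with its code."""

    hybrid: str
    female: str
    male: str

    @property
    def ordered_pair(self) -> tuple[str, str]:
        return (self.female, self.male)

    @property
    def unordered_pair(self) -> tuple[str, str]:
        return tuple(sorted((self.female, self.male)))  # type: ignore[return-value]


@dataclass(frozen=True)
class DiallelDesign:
    """A (possibly incomplete) diallel design over a set of inbred parents.

    Invariants enforced at construction: no self-crosses, all cross parents
    known, hybrid codes unique, and ``len(crosses) + len(missing)`` equal to
    ``P * (P - 1)`` for ``P`` parents.
    """

    parents: tuple[str, ...]
    crosses: tuple[Cross, ...]
    missing: frozenset[tuple[str, str]] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if len(set(self.parents)) != len(self.parents):
            raise DesignError("duplicate parent codes in design")
        known = set(self.parents)
        seen_codes: set[str] = set()
        seen_cells: set[tuple[str, str]] = set()
        for cross in self.crosses:
            if cross.female == cross.male:
                raise DesignError(f"self-cross {cross.female}×{cross.male} is not allowed")
            for code in (cross.female, cross.male):
                if code not in known:
                    raise DesignError(f"cross {cross.hybrid}: unknown parent {code!r}")
            if cross.hybrid in seen_codes:
                raise DesignError(f"hybrid code {cross.hybrid!r} occurs more than once")
            seen_codes.add(cross.hybrid)
            if cross.ordered_pair in seen_cells:
                raise DesignError(f"cell {cross.female}×{cross.male} occurs more than once")
            seen_cells.add(cross.ordered_pair)
        for female, male in self.missing:
            if female == male or female not in known or male not in known:
                raise DesignError(f"invalid missing cell {female}×{male}")
            if (female, male) in seen_cells:
                raise DesignError(f"cell {female}×{male} is both a cross and missing")
        p = len(self.parents)
        if len(self.crosses) + len(self.missing) != p * (p - 1):
            raise DesignError(
                f"{len(self.crosses)} crosses + {len(self.missing)} missing "
                f"does not cover the {p}·{p - 1} off-diagonal cells"
            )

    # -- lookups -----------------------------------------------------------

    @property
    def n_parents(self) -> int:
        return len(self.parents)

    @property
    def hybrids(self) -> tuple[str, ...]:
        return tuple(c.hybrid for c in self.crosses)

    def parents_of(self, hybrid: str) -> tuple[str, str]:
        """Return ``(female, male)`` for a hybrid code."""
        for cross in self.crosses:
            if cross.hybrid == hybrid:
                return cross.ordered_pair
        raise KeyError(hybrid)

    def ordered_pairs(self) -> list[tuple[str, str]]:
        """Distinct ``(female, male)`` pairs appearing in the crosses."""
        return [c.ordered_pair for c in self.crosses]

    def unordered_pairs(self) -> list[tuple[str, str]]:
        """Sorted distinct unordered parent pairs appearing in the crosses."""
        return sorted({c.unordered_pair for c in self.crosses})


def parse_design(grid: pd.DataFrame, missing_marker: str = MISSING_MARKER) -> DiallelDesign:
    """Parse a square diallel grid (rows = female, columns = male).

    The grid's index and columns must list the same parent codes in the same
    order; the diagonal must be blank; every off-diagonal cell must hold a
    hybrid code or *missing_marker*.
    """
    rows = [str(x) for x in grid.index]
    cols = [str(x) for x in grid.columns]
    if rows != cols:
        raise DesignError(f"grid is not square over one parent set: rows {rows} vs columns {cols}")
    if len(set(rows)) != len(rows):
        raise DesignError(f"duplicate parent codes: {rows}")
    crosses: list[Cross] = []
    missing: set[tuple[str, str]] = set()
    for female in rows:
        for male in cols:
            raw = grid.loc[female, male]
            cell = "" if pd.isna(raw) else str(raw).strip()
            if female == male:
                if cell:
                    raise DesignError(f"diagonal cell {female}×{male} must be blank, got {cell!r}")
                continue
            if cell == missing_marker:
                missing.add((female, male))
            elif cell:
                crosses.append(Cross(hybrid=cell, female=female, male=male))
            else:
                raise DesignError(f"off-diagonal cell {female}×{male} is empty")
    return DiallelDesign(parents=tuple(rows), crosses=tuple(crosses), missing=frozenset(missing))


def design_to_grid(design: DiallelDesign, missing_marker: str = MISSING_MARKER) -> pd.DataFrame:
    """Inverse of :func:`parse_design`: rebuild the square grid."""
    grid = pd.DataFrame("", index=list(design.parents), columns=list(design.parents), dtype=object)
    for female, male in design.missing:
        grid.loc[female, male] = missing_marker
    for cross in design.crosses:
        grid.loc[cross.female, cross.male] = cross.hybrid
    return grid


def complete_design(parents: Iterable[str], missing: Iterable[tuple[str, str]] = (),
                    codes: Mapping[tuple[str, str], str] | None = None) -> DiallelDesign:
    """Build a diallel design directly: every ordered pair not listed in
    *missing* becomes a cross, coded ``female + male`` unless overridden."""
    parents = tuple(parents)
    missing_set = {tuple(m) for m in missing}
    crosses = []
    for female in parents:
        for male in parents:
            if female == male or (female, male) in missing_set:
                continue
            code = (codes or {}).get((female, male), f"{female}{male}")
            crosses.append(Cross(hybrid=code, female=female, male=male))
    return DiallelDesign(parents=parents, crosses=tuple(crosses),
                         missing=frozenset(missing_set))  # type: ignore[arg-type]


def read_design(path: str | Path, sep: str = "\t", missing_marker: str = MISSING_MARKER) -> DiallelDesign:
    """Read a design grid from a delimited text file (first row/column = parents)."""
    grid = pd.read_csv(path, sep=sep, index_col=0, dtype=str, keep_default_na=False,
                       na_values=[], comment="#")
    grid.index = grid.index.astype(str)
    return parse_design(grid, missing_marker=missing_marker)


def write_design(design: DiallelDesign, path: str | Path, sep: str = "\t",
                 missing_marker: str = MISSING_MARKER) -> None:
    """Write the grid form of *design* so that :func:`read_design` round-trips."""
    design_to_grid(design, missing_marker=missing_marker).to_csv(path, sep=sep)
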