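"""Over-representation analysis of a gene set against a term annotation.

Generic hypergeometric ORA: for each term with at least one member in the
query set, the upper-tail probability that a random draw of n genes from the
N-gene background contains k or more of the term's K annotated genes, with
BH adjustment across the tested terms.  The annotation is user-supplied
(two-column gene → term TSV), covering GO- and KEGG-style maps alike.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from scipy import stats

from .correlate import bh_adjust

logger = logging.getLogger(__name__)


class EnrichmentError(ValueError):
    pass


@dataclass
class AnnotationMap:
    """term → annotated gene set, plus the background universe.

    Every annotated gene must belong to the universe; empty terms are
    rejected.
    """

    terms: dict[str, set[str]]
    universe: set[str]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for term, genes in self.terms.items():
            if not genes:
                raise EnrichmentError(f"term {term!r} annotates no genes")
            stray = genes - self.universe
            if stray:
                raise EnrichmentError(f"term {term!r} annotates genes outside the universe: "
                                      f"{sorted(stray)[:3]}...")

    @classmethod
    def read(cls, annotation_path: str | Path, universe, descriptions_path: str | Path | None = None,
             sep: str = "\t") -> "AnnotationMap":
        """Load from a two-column (gene, term) TSV; genes outside *universe*
        are dropped with a warning."""
        universe = set(universe)
        pairs = pd.read_csv(annotation_path, sep=sep, comment="#",
                            names=["gene", "term"], header=0, dtype=str)
        dropped = pairs[~pairs["gene"].isin(universe)]
        if len(dropped):
            logger.warning("annotation: %d gene-term pairs outside the universe dropped", len(dropped))
        pairs = pairs[pairs["gene"].isin(universe)]
        terms = {t: set(g) for t, g in pairs.groupby("term")["gene"]}
        descriptions = {}
        if descriptions_path is not None:
            desc = pd.read_csv(descriptions_path, sep=sep, comment="#",
                               names=["term", "description"], header=0, dtype=str)
            descriptions = dict(zip(desc["term"], desc["description"]))
        return cls(terms=terms, universe=universe, descriptions=descriptions)

    def write(self, path: str | Path, sep: str = "\t") -> None:
        rows = [{"gene": g, "term": t} for t in sorted(self.terms) for g in sorted(self.terms[t])]
        pd.DataFrame(rows).to_csv(path, sep=sep, index=False)


def hypergeom_upper(k: int, K: int, n: int, N: int) -> float:
    """P(X ≥ k) for X ~ Hypergeometric(N, K, n): k or more of the K marked
    genes in a draw of n from N.  Computed via scipy's stable log-space
    survival function."""
    if not (0 <= k <= min(n, K) and K <= N and n <= N and 0 <= n and 0 <= K):
        raise EnrichmentError(f"inconsistent counts k={k}, K={K}, n={n}, N={N}")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def enrich(gene_set, annotation: AnnotationMap, q_max: float = 0.05) -> pd.DataFrame:
    """ORA of *gene_set* against *annotation*; one row per term with k ≥ 1.

    Genes outside the universe are dropped with a warning.  Terms with no
    query member are excluded from the BH universe.  Rows sorted by p.
    """
    if not annotation.universe:
        raise EnrichmentError("empty background universe")
    gene_set = set(gene_set)
    stray = gene_set - annotation.universe
    if stray:
        logger.warning("enrich: %d query genes outside the universe dropped", len(stray))
        gene_set &= annotation.universe
    n, N = len(gene_set), len(annotation.universe)
    rows = []
    for term, members in sorted(annotation.terms.items()):
        k = len(gene_set & members)
        if k == 0:
            continue
        K = len(members)
        rows.append({"term": term,
                     "description": annotation.descriptions.get(term, ""),
                     "k": k, "K": K, "n": n, "N": N,
                     "p": hypergeom_upper(k, K, n, N)})
    out = pd.DataFrame(rows, columns=["term", "description", "k", "K", "n", "N", "p"])
    if len(out):
        out["q"] = bh_adjust(out["p"].to_numpy())
        out["significant"] = out["q"] <= q_max
        out = out.sort_values(["p", "term"], kind="mergesort").reset_index(drop=True)
    else:
        out["q"] = pd.Series(dtype=float)
        out["significant"] = pd.Series(dtype=bool)
    out.attrs["q_max"] = q_max
    return out
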