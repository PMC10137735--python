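"""Expression normalisation, replicate aggregation, and parent-pair DEG calls.

Expression is held as FPKM (fragments per kilobase of transcript per million
mapped fragments).  Differential expression between two parents is called on
replicate FPKM with a Welch (unequal-variance) t-test on log2(FPKM + 1),
Benjamini–Hochberg adjustment across the tested genes, and the conventional
thresholds q < α and |log2FC| > fc_min on the pseudo-counted fold change of
replicate-mean FPKM.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .correlate import bh_adjust


class ExpressionError(ValueError):
    pass


def fpkm(count, gene_length_bp, total_mapped_fragments):
    """FPKM = 1e9 · count / (gene_length_bp · total_mapped_fragments).

    Accepts scalars or broadcastable arrays; counts must be non-negative and
    both denominator terms strictly positive.
    """
    count = np.asarray(count, dtype=float)
    length = np.asarray(gene_length_bp, dtype=float)
    total = np.asarray(total_mapped_fragments, dtype=float)
    if np.any(length <= 0):
        raise ExpressionError("gene length must be positive")
    if np.any(total <= 0):
        raise ExpressionError("total mapped fragments must be positive")
    if np.any(count < 0):
        raise ExpressionError("counts must be non-negative")
    out = 1e9 * count / (length * total)
    return float(out) if out.ndim == 0 else out


def fpkm_matrix(counts: pd.DataFrame, gene_lengths: pd.Series,
                totals: pd.Series | None = None) -> pd.DataFrame:
    """Convert a gene × sample count matrix to FPKM.

    *totals* defaults to the per-sample column sums of *counts*.
    """
    lengths = gene_lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = lengths.index[lengths.isna()][0]
        raise ExpressionError(f"no gene length for {missing!r}")
    if totals is None:
        totals = counts.sum(axis=0)
    values = fpkm(counts.to_numpy(), lengths.to_numpy()[:, None], totals.to_numpy()[None, :])
    return pd.DataFrame(values, index=counts.index, columns=counts.columns)


@dataclass
class ExpressionMatrix:
    """Gene × sample FPKM with the sample → (parent, replicate) map.

    ``sample_map`` is a DataFrame indexed by sample id with columns
    ``parent`` and ``replicate``; replicate indices are distinct within a
    parent.  Raw counts / gene lengths / library sizes are optional.
    """

    fpkm: pd.DataFrame
    sample_map: pd.DataFrame
    counts: pd.DataFrame | None = None
    gene_lengths: pd.Series | None = None
    library_sizes: pd.Series | None = None

    def __post_init__(self) -> None:
        if (self.fpkm.to_numpy() < 0).any():
            raise ExpressionError("FPKM values must be non-negative")
        unknown = set(self.fpkm.columns) - set(self.sample_map.index)
        if unknown:
            raise ExpressionError(f"samples without a parent mapping: {sorted(unknown)}")
        dup = self.sample_map.loc[list(self.fpkm.columns)].duplicated(subset=["parent", "replicate"])
        if dup.any():
            raise ExpressionError("replicate indices must be distinct within a parent")

    @property
    def genes(self) -> pd.Index:
        return self.fpkm.index

    @property
    def parents(self) -> list[str]:
        return sorted(self.sample_map.loc[list(self.fpkm.columns), "parent"].unique())

    def samples_of(self, parent: str) -> list[str]:
        mask = self.sample_map["parent"] == parent
        samples = [s for s in self.fpkm.columns if s in set(self.sample_map.index[mask])]
        if not samples:
            raise ExpressionError(f"unknown parent {parent!r}")
        return samples

    def mean_parent_profile(self, parent: str) -> pd.Series:
        """Arithmetic per-gene mean FPKM over the parent's replicates."""
        profile = self.fpkm[self.samples_of(parent)].mean(axis=1)
        profile.name = parent
        return profile

    def parent_profiles(self) -> pd.DataFrame:
        """Gene × parent matrix of replicate-mean FPKM."""
        return pd.concat([self.mean_parent_profile(p) for p in self.parents], axis=1)

    # -- I/O ---------------------------------------------------------------

    @classmethod
    def read(cls, fpkm_path: str | Path, sample_map_path: str | Path,
             sep: str = "\t") -> "ExpressionMatrix":
        mat = pd.read_csv(fpkm_path, sep=sep, index_col=0, comment="#")
        smap = pd.read_csv(sample_map_path, sep=sep, index_col=0, comment="#", dtype={0: str})
        smap.index = smap.index.astype(str)
        smap["parent"] = smap["parent"].astype(str)
        return cls(fpkm=mat, sample_map=smap)

    def write(self, fpkm_path: str | Path, sample_map_path: str | Path, sep: str = "\t") -> None:
        self.fpkm.to_csv(fpkm_path, sep=sep, float_format="%.6g", index_label="gene")
        self.sample_map.to_csv(sample_map_path, sep=sep, index_label="sample")


@dataclass
class DEGResult:
    """Differential-expression call for one ordered parent pair.

    ``table`` has one row per tested gene: log2FC (female over male, with
    the pseudo-count), p, q and direction in {"up", "down", "ns"}.  Genes
    with zero FPKM in every replicate of both parents are excluded from the
    test universe; their number is ``n_excluded``.
    """

    female: str
    male: str
    alpha: float
    fc_min: float
    pseudo: float
    table: pd.DataFrame
    n_excluded: int = 0

    @property
    def n_up(self) -> int:
        return int((self.table["direction"] == "up").sum())

    @property
    def n_down(self) -> int:
        return int((self.table["direction"] == "down").sum())

    @property
    def n_all(self) -> int:
        return self.n_up + self.n_down

    def counts(self) -> dict[str, int]:
        return {"UP": self.n_up, "DOWN": self.n_down, "ALL": self.n_all}


def call_degs(matrix: ExpressionMatrix, female: str, male: str,
              alpha: float = 0.05, fc_min: float = 1.0, pseudo: float = 0.1) -> DEGResult:
    """Call DEGs between two parents at FDR *alpha* and |log2FC| > *fc_min*.

    log2FC is computed on replicate-mean FPKM with *pseudo* added to both
    means; p-values come from a two-sided Welch t-test on log2(FPKM + 1)
    across replicates and are BH-adjusted over the tested genes.  Both
    parents need at least two replicates.  Zero-variance genes whose group
    means coincide get p = 1; other degenerate t statistics are treated
    conservatively (p = 1).
    """
    f_samples = matrix.samples_of(female)
    m_samples = matrix.samples_of(male)
    if len(f_samples) < 2 or len(m_samples) < 2:
        raise ExpressionError(
            f"DEG test {female} vs {male} needs >= 2 replicates per parent "
            f"(got {len(f_samples)} and {len(m_samples)})")
    f_vals = matrix.fpkm[f_samples].to_numpy(dtype=float)
    m_vals = matrix.fpkm[m_samples].to_numpy(dtype=float)

    expressed = (f_vals.sum(axis=1) + m_vals.sum(axis=1)) > 0
    n_excluded = int((~expressed).sum())
    f_vals, m_vals = f_vals[expressed], m_vals[expressed]
    genes = matrix.genes[expressed]

    log2fc = np.log2((f_vals.mean(axis=1) + pseudo) / (m_vals.mean(axis=1) + pseudo))
    with np.errstate(divide="ignore", invalid="ignore"):
        _, p = stats.ttest_ind(np.log2(f_vals + 1.0), np.log2(m_vals + 1.0),
                               axis=1, equal_var=False)
    p = np.where(np.isfinite(p), p, 1.0)
    q = bh_adjust(p)
    direction = np.where((q < alpha) & (log2fc > fc_min), "up",
                         np.where((q < alpha) & (log2fc < -fc_min), "down", "ns"))
    table = pd.DataFrame({"log2fc": log2fc, "p": p, "q": q, "direction": direction}, index=genes)
    table.index.name = "gene"
    return DEGResult(female=female, male=male, alpha=alpha, fc_min=fc_min, pseudo=pseudo,
                     table=table, n_excluded=n_excluded)


def deg_counts_for_design(matrix: ExpressionMatrix, design, alpha: float = 0.05,
                          fc_min: float = 1.0, pseudo: float = 0.1) -> pd.DataFrame:
    """UP/DOWN/ALL DEG counts for every ordered parent pair in the design.

    The test is computed once per unordered pair; the reciprocal's counts
    follow from antisymmetry (swapping parents negates log2FC, so UP and
    DOWN swap while p and q are unchanged).
    """
    cache: dict[tuple[str, str], DEGResult] = {}
    rows = []
    for female, male in sorted(set(design.ordered_pairs())):
        key = (female, male)
        rev = (male, female)
        if rev in cache:
            res = cache[rev]
            rows.append({"female": female, "male": male, "UP": res.n_down,
                         "DOWN": res.n_up, "ALL": res.n_all})
            continue
        res = call_degs(matrix, female, male, alpha=alpha, fc_min=fc_min, pseudo=pseudo)
        cache[key] = res
        rows.append({"female": female, "male": male, "UP": res.n_up,
                     "DOWN": res.n_down, "ALL": res.n_all})
    out = pd.DataFrame(rows)
    out.attrs.update({"alpha": alpha, "fc_min": fc_min, "pseudo": pseudo})
    return out
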