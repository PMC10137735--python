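"""Correlation analyses relating parental transcriptome summaries to hybrid
performance and heterosis.

Three families of analyses share the same Pearson machinery:

* DEG-count correlations: UP/DOWN/ALL parental DEG numbers vs the hybrids'
  observed trait values or mid-parent heterosis (MPH);
* distance correlations: parental Euclidean/binary transcriptome distances
  vs the same responses (reciprocal hybrids share one distance);
* the gene-level screen: for every gene, the high-/mid-/low-parent
  expression value (HPV/MPV/LPV = max/mean/min of the two parental
  replicate-mean FPKM) across hybrids vs the observed value and MPH of a
  target trait, with Benjamini–Hochberg control within each basis ×
  response family.

MPH is shift-invariant between the "difference" and "ratio" heterosis
conventions (they differ by exactly 100), so every correlation here is
convention-independent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .design import DiallelDesign
from .distance import distance_lookup

logger = logging.getLogger(__name__)

BASES = ("HPV", "MPV", "LPV")


class CorrelationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# primitives


def pearson_test(x, y) -> tuple[float, float]:
    """Sample Pearson r and two-sided p from the exact t reference
    (t = r·sqrt((n−2)/(1−r²)) on n−2 df).

    Requires n ≥ 3 and nonzero variance on both sides.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise CorrelationError(f"need two equal-length series with n >= 3, got {x.size} and {y.size}")
    if np.std(x) == 0 or np.std(y) == 0:
        raise CorrelationError("zero variance: correlation undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def bh_adjust(p) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted q-values, order-preserving,
    clipped at 1."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise CorrelationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def significance_stars(p: float) -> str:
    """'**' below 0.01, '*' below 0.05, '' otherwise."""
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def round_half_away(x: float, decimals: int = 2) -> float:
    """Round half away from zero (the convention of printed tables),
    unlike numpy's banker's rounding."""
    factor = 10.0 ** decimals
    return float(np.sign(x) * np.floor(np.abs(x) * factor + 0.5) / factor)


def _pearson_rows(matrix: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise Pearson r and two-sided p of a (G × n) matrix against y.

    Zero-variance rows yield NaN r/p.  The p-value uses the same beta-form
    null as scipy.stats.pearsonr.
    """
    n = y.size
    xc = matrix - matrix.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    xs = np.sqrt((xc ** 2).sum(axis=1))
    ys = np.sqrt((yc ** 2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (xc @ yc) / (xs * ys)
    r = np.where(xs > 0, r, np.nan)
    r = np.clip(r, -1.0, 1.0)
    # two-sided p: |r| under the null follows a symmetric beta on [-1, 1]
    ab = n / 2.0 - 1.0
    with np.errstate(invalid="ignore"):
        p = 2.0 * stats.beta.sf(np.abs(r), ab, ab, loc=-1.0, scale=2.0)
    return r, np.where(np.isnan(r), np.nan, np.clip(p, 0.0, 1.0))


# ---------------------------------------------------------------------------
# table-level correlations (DEG counts and distances vs responses)


def _correlate_predictors(predictors: pd.DataFrame, responses: pd.DataFrame,
                          trait: str) -> pd.DataFrame:
    """Correlate every predictor column with every response column across
    the hybrids both tables share."""
    common = predictors.index.intersection(responses.index)
    n_dropped = len(responses.index.union(predictors.index)) - len(common)
    rows = []
    for pred in predictors.columns:
        for resp in responses.columns:
            x = predictors.loc[common, pred].to_numpy(dtype=float)
            y = responses.loc[common, resp].to_numpy(dtype=float)
            try:
                r, p = pearson_test(x, y)
                flag = ""
            except CorrelationError as exc:
                r, p, flag = np.nan, np.nan, str(exc)
            rows.append({"predictor": pred, "response": resp, "trait": trait,
                         "n": int(len(common)), "n_dropped": int(n_dropped),
                         "r": r, "p": p,
                         "stars": significance_stars(p) if np.isfinite(p) else "",
                         "flag": flag})
    return pd.DataFrame(rows)


def deg_count_correlation(design: DiallelDesign, deg_counts: pd.DataFrame,
                          responses: pd.DataFrame, trait: str) -> pd.DataFrame:
    """Correlate per-pair UP/DOWN/ALL DEG counts with hybrid responses.

    *deg_counts* has columns female, male, UP, DOWN, ALL (one row per
    ordered pair, female vs male orientation); *responses* is indexed by
    hybrid.  Hybrids without a DEG pair are dropped and counted.
    """
    lookup = {(r.female, r.male): (r.UP, r.DOWN, r.ALL)
              for r in deg_counts.itertuples(index=False)}
    rows = {}
    for cross in design.crosses:
        key = cross.ordered_pair
        if key in lookup and cross.hybrid in responses.index:
            rows[cross.hybrid] = dict(zip(("UP", "DOWN", "ALL"), lookup[key]))
        else:
            logger.warning("deg_count_correlation: hybrid %s dropped (no DEG pair or response)",
                           cross.hybrid)
    predictors = pd.DataFrame.from_dict(rows, orient="index")
    return _correlate_predictors(predictors, responses, trait)


def distance_correlation(distances: pd.DataFrame, design: DiallelDesign,
                         responses: pd.DataFrame, trait: str) -> pd.DataFrame:
    """Correlate parental Euclidean/binary distances with hybrid responses.

    Distances are pair-symmetric, so reciprocal hybrids share one predictor
    value but remain distinct observations.
    """
    lookup = distance_lookup(distances)
    rows = {}
    for cross in design.crosses:
        key = cross.unordered_pair
        if key in lookup and cross.hybrid in responses.index:
            rows[cross.hybrid] = lookup[key]
        else:
            logger.warning("distance_correlation: hybrid %s dropped", cross.hybrid)
    predictors = pd.DataFrame.from_dict(rows, orient="index")[["euclidean", "binary"]]
    return _correlate_predictors(predictors, responses, trait)


# ---------------------------------------------------------------------------
# gene-level screen


def parental_expression_values(profiles: pd.DataFrame, female: str, male: str) -> pd.DataFrame:
    """Per-gene HPV/MPV/LPV (max/mean/min of the two parental profiles)."""
    for parent in (female, male):
        if parent not in profiles.columns:
            raise CorrelationError(f"no expression profile for parent {parent!r}")
    pf = profiles[female].to_numpy(dtype=float)
    pm = profiles[male].to_numpy(dtype=float)
    return pd.DataFrame({"HPV": np.maximum(pf, pm), "MPV": (pf + pm) / 2.0,
                         "LPV": np.minimum(pf, pm)}, index=profiles.index)


def _basis_matrices(profiles: pd.DataFrame, design: DiallelDesign,
                    hybrids: list[str]) -> dict[str, np.ndarray]:
    """G × H matrices of HPV/MPV/LPV per hybrid, built from parent columns."""
    pair_of = {c.hybrid: c.ordered_pair for c in design.crosses}
    f_idx = [profiles.columns.get_loc(pair_of[h][0]) for h in hybrids]
    m_idx = [profiles.columns.get_loc(pair_of[h][1]) for h in hybrids]
    values = profiles.to_numpy(dtype=float)
    pf, pm = values[:, f_idx], values[:, m_idx]
    return {"HPV": np.maximum(pf, pm), "MPV": (pf + pm) / 2.0, "LPV": np.minimum(pf, pm)}


def correlation_screen(predictors: dict[str, pd.DataFrame] | pd.DataFrame,
                       responses: pd.DataFrame, alpha_fdr: float = 0.01,
                       pooled: bool = False) -> pd.DataFrame:
    """Pearson screen of many predictor series against response columns.

    *predictors* maps a basis label to a gene × observation DataFrame (a
    bare DataFrame is treated as a single basis ``"series"``); *responses*
    is observation × response-column.  Every basis × response pair forms one
    BH family (``pooled=True`` adjusts across all families at once).
    Constant predictor rows are flagged (NaN r/p/q) and excluded from the
    BH universe.

    Returns a tidy frame: gene, basis, response, n, r, p, q, significant.
    """
    if isinstance(predictors, pd.DataFrame):
        predictors = {"series": predictors}
    frames = []
    for basis, matrix_df in predictors.items():
        obs = [o for o in matrix_df.columns if o in responses.index]
        if len(obs) < 3:
            raise CorrelationError(f"basis {basis!r}: need >= 3 shared observations, got {len(obs)}")
        matrix = matrix_df[obs].to_numpy(dtype=float)
        for resp in responses.columns:
            y = responses.loc[obs, resp].to_numpy(dtype=float)
            r, p = _pearson_rows(matrix, y)
            frames.append(pd.DataFrame({
                "gene": matrix_df.index, "basis": basis, "response": resp,
                "n": len(obs), "r": r, "p": p,
            }))
    out = pd.concat(frames, ignore_index=True)
    out["q"] = np.nan
    tested = out["p"].notna()
    if pooled:
        out.loc[tested, "q"] = bh_adjust(out.loc[tested, "p"].to_numpy())
    else:
        for (_, _), idx in out[tested].groupby(["basis", "response"]).groups.items():
            out.loc[idx, "q"] = bh_adjust(out.loc[idx, "p"].to_numpy())
    out["significant"] = out["q"] < alpha_fdr
    out.attrs.update({"alpha_fdr": alpha_fdr, "pooled": pooled,
                      "n_constant": int((~tested).sum())})
    return out


def gene_correlation_screen(profiles: pd.DataFrame, design: DiallelDesign,
                            responses: pd.DataFrame, alpha_fdr: float = 0.01,
                            pooled: bool = False) -> pd.DataFrame:
    """Screen every gene × basis × response for association across hybrids.

    For each gene and basis (HPV/MPV/LPV), the basis value of the hybrid's
    two parents is correlated across hybrids with each response column
    (typically ``observed`` and ``MPH`` of the target trait).  BH adjustment
    runs within each basis × response family by default.  Genes whose basis
    value is constant across hybrids are flagged and excluded from the BH
    universe.
    """
    hybrids = [c.hybrid for c in design.crosses if c.hybrid in responses.index]
    if len(hybrids) < 3:
        raise CorrelationError(f"need >= 3 hybrids with responses, got {len(hybrids)}")
    matrices = _basis_matrices(profiles, design, hybrids)
    predictors = {basis: pd.DataFrame(matrices[basis], index=profiles.index, columns=hybrids)
                  for basis in BASES}
    return correlation_screen(predictors, responses.loc[hybrids], alpha_fdr=alpha_fdr,
                              pooled=pooled)


def classify_correlated_genes(records: pd.DataFrame) -> dict[str, set[str]]:
    """Partition screened genes by which responses they are significant for.

    A gene is significant for a response if any basis is significant.  The
    ``both`` set intersects the per-response sets; its sign classes require
    a consistent r sign over the significant bases of each response, and
    genes whose two responses disagree in sign (or are internally mixed)
    land in ``conflicting``.
    """
    responses = list(records["response"].unique())
    if len(responses) != 2:
        raise CorrelationError(f"expected exactly 2 responses, got {responses}")
    sig = records[records["significant"].fillna(False)]
    per_response: dict[str, set[str]] = {r: set(sig[sig["response"] == r]["gene"])
                                         for r in responses}
    obs_resp, mph_resp = responses
    both = per_response[obs_resp] & per_response[mph_resp]

    both_positive, both_negative, conflicting = set(), set(), set()
    sig_both = sig[sig["gene"].isin(both)]
    grouped = sig_both.groupby(["gene", "response"])["r"].agg(lambda v: set(np.sign(v)))
    for gene in both:
        signs = {resp: grouped.get((gene, resp), set()) for resp in responses}
        if all(s == {1.0} for s in signs.values()):
            both_positive.add(gene)
        elif all(s == {-1.0} for s in signs.values()):
            both_negative.add(gene)
        else:
            conflicting.add(gene)
    return {f"{obs_resp}_significant": per_response[obs_resp],
            f"{mph_resp}_significant": per_response[mph_resp],
            "both": both, "both_positive": both_positive,
            "both_negative": both_negative, "conflicting": conflicting}


def pathway_table(records: pd.DataFrame, basis: str = "MPV") -> pd.DataFrame:
    """Pivot one basis of screen output into the per-gene two-response
    schema used by :func:`filter_pathway_records`."""
    sub = records[records["basis"] == basis]
    responses = list(sub["response"].unique())
    obs_resp, mph_resp = responses
    wide = sub.pivot(index="gene", columns="response", values=["r", "q"])
    out = pd.DataFrame({
        "gene": wide.index,
        "symbol": "",
        "r_observed": wide[("r", obs_resp)].to_numpy(),
        "q_observed": wide[("q", obs_resp)].to_numpy(),
        "r_mph": wide[("r", mph_resp)].to_numpy(),
        "q_mph": wide[("q", mph_resp)].to_numpy(),
    }).reset_index(drop=True)
    return out


def filter_pathway_records(records: pd.DataFrame, genes, q_max: float = 0.05
                           ) -> tuple[pd.DataFrame, dict[str, float]]:
    """Keep pathway-member genes significant for both responses.

    *records* must carry columns gene, symbol, r_observed, q_observed,
    r_mph, q_mph.  Rows for genes in *genes* with both q values ≤ *q_max*
    are returned sorted by gene id, together with the min/max of each r
    column rounded half-away-from-zero to two decimals (NaN extrema when no
    row passes).
    """
    genes = set(genes)
    if not genes:
        return records.iloc[0:0].copy(), {}
    sub = records[records["gene"].isin(genes)
                  & (records["q_observed"] <= q_max)
                  & (records["q_mph"] <= q_max)].sort_values("gene").reset_index(drop=True)
    extrema = {}
    for col in ("r_observed", "r_mph"):
        if len(sub):
            extrema[f"min_{col}"] = round_half_away(float(sub[col].min()))
            extrema[f"max_{col}"] = round_half_away(float(sub[col].max()))
        else:
            extrema[f"min_{col}"] = extrema[f"max_{col}"] = float("nan")
    return sub, extrema
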