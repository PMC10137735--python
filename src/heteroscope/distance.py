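"""Transcriptome-based distances between parental expression profiles.

Two indicators of parental difference:

* **Euclidean** distance between the two parents' expression profiles,
  optionally after a log2(x+1) transform (raw FPKM by default, where the
  distance is dominated by highly expressed genes).
* **Binary (asymmetric) distance**: the fraction of genes expressed (above a
  threshold τ) in exactly one of the two parents among genes expressed in at
  least one — the Jaccard dissimilarity of the presence/absence patterns.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

TRANSFORMS = ("identity", "log2p1")


class DistanceError(ValueError):
    pass


def _aligned(x, y) -> tuple[np.ndarray, np.ndarray]:
    """Validate that two profiles cover the same gene universe, in order."""
    if isinstance(x, pd.Series) and isinstance(y, pd.Series):
        if not x.index.equals(y.index):
            for i, (a, b) in enumerate(zip(x.index, y.index)):
                if a != b:
                    raise DistanceError(f"gene universes differ at position {i}: {a!r} vs {b!r}")
            raise DistanceError(
                f"gene universes differ in length: {len(x.index)} vs {len(y.index)}")
        return x.to_numpy(dtype=float), y.to_numpy(dtype=float)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise DistanceError(f"profile shapes differ: {x.shape} vs {y.shape}")
    return x, y


def _transform(values: np.ndarray, transform: str) -> np.ndarray:
    if transform == "identity":
        return values
    if transform == "log2p1":
        return np.log2(values + 1.0)
    raise DistanceError(f"unknown transform {transform!r}; expected one of {TRANSFORMS}")


def euclidean_distance(x, y, transform: str = "identity") -> float:
    """sqrt of the sum of squared per-gene differences after *transform*."""
    xv, yv = _aligned(x, y)
    xv, yv = _transform(xv, transform), _transform(yv, transform)
    return float(np.linalg.norm(xv - yv))


def binary_distance(x, y, tau: float = 0.0) -> float:
    """Asymmetric-binary distance on presence (> τ) patterns.

    With a = #genes present in both, b = present only in x, c = present only
    in y, returns (b + c)/(a + b + c); 0 when no gene is present in either.
    """
    xv, yv = _aligned(x, y)
    px, py = xv > tau, yv > tau
    a = int(np.sum(px & py))
    b = int(np.sum(px & ~py))
    c = int(np.sum(~px & py))
    if a + b + c == 0:
        return 0.0
    return (b + c) / (a + b + c)


def pairwise_distances(profiles: pd.DataFrame, transform: str = "identity",
                       tau: float = 0.0) -> pd.DataFrame:
    """Both distances for every unordered pair of columns of *profiles*.

    *profiles* is a gene × parent matrix (replicate-mean FPKM).  Returns a
    tidy table with columns parent_a, parent_b (sorted), euclidean, binary;
    the configuration is stored in ``attrs``.
    """
    parents = sorted(profiles.columns)
    rows = []
    for i, a in enumerate(parents):
        for b in parents[i + 1:]:
            rows.append({
                "parent_a": a, "parent_b": b,
                "euclidean": euclidean_distance(profiles[a], profiles[b], transform=transform),
                "binary": binary_distance(profiles[a], profiles[b], tau=tau),
            })
    out = pd.DataFrame(rows, columns=["parent_a", "parent_b", "euclidean", "binary"])
    out.attrs.update({"transform": transform, "tau": tau,
                      "n_genes": int(profiles.shape[0])})
    return out


def distance_lookup(distances: pd.DataFrame) -> dict[tuple[str, str], dict[str, float]]:
    """Map each unordered pair (sorted tuple) to its distance record."""
    out = {}
    for row in distances.itertuples(index=False):
        key = tuple(sorted((row.parent_a, row.parent_b)))
        out[key] = {"euclidean": float(row.euclidean), "binary": float(row.binary)}
    return out
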