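"""Expression standardization, binarization, DE calling and co-expression.

The differential-expression rule is a flag-rate rule, not a count-model test:
each matrix element is z-scored within its gene row, flagged when z strictly
exceeds a threshold (default 2.5), and a gene is called differentially
expressed when its flag rate strictly exceeds the matrix-wide mean flag rate.
Z-scores are taken over all samples by default; the flag-rate comparison and
the per-edge Pearson co-expression are computed over the tumor columns by
default, both switchable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, PPINetwork, logger

__all__ = [
    "BinarizedExpression",
    "DEGeneSet",
    "zscore",
    "binarize",
    "call_de_genes",
    "edge_correlations",
]


@dataclass
class BinarizedExpression:
    """Row-standardized z-scores and, once binarized, the extreme-value flags."""

    z: pd.DataFrame                    # genes x samples
    mu: pd.Series                      # per-gene mean
    sigma: pd.Series                   # per-gene sample sd (ddof=1)
    flags: pd.DataFrame | None = None  # 0/1 after binarize()
    tau: float | None = None


def zscore(matrix: ExpressionMatrix, columns: str = "all") -> BinarizedExpression:
    """Standardize each gene row: z = (L - mu_i) / sigma_i with the sample
    standard deviation (m-1 denominator) over the selected columns.

    Rows with sigma = 0 (constant expression) are mapped to z = 0 so they can
    never be flagged as extreme.
    """
    cols = matrix.sample_columns(columns)
    if len(cols) < 2:
        raise ValueError("z-scoring needs >= 2 samples")
    values = matrix.values[cols]
    mu = values.mean(axis=1)
    sigma = values.std(axis=1, ddof=1)
    safe = sigma.replace(0.0, np.nan)
    z = values.sub(mu, axis=0).div(safe, axis=0).fillna(0.0)
    return BinarizedExpression(z=z, mu=mu, sigma=sigma)


def binarize(bexpr: BinarizedExpression, tau: float = 2.5) -> BinarizedExpression:
    """Flag elements with z strictly greater than ``tau`` (default 2.5)."""
    if tau <= 0:
        raise ValueError(f"binarization threshold must be positive, got {tau}")
    bexpr.flags = (bexpr.z > tau).astype(int)
    bexpr.tau = tau
    return bexpr


@dataclass
class DEGeneSet:
    """Genes whose flag rate strictly exceeds the matrix-wide mean rate."""

    genes: frozenset[str]
    global_rate: float

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes

    def __len__(self) -> int:
        return len(self.genes)


def call_de_genes(bexpr: BinarizedExpression,
                  matrix: ExpressionMatrix | None = None,
                  columns: str = "tumor") -> DEGeneSet:
    """Call a gene differentially expressed when its mean flag over the
    selected sample columns strictly exceeds the global mean flag.

    ``columns`` selects which samples the flag rates are counted over
    ("tumor" by default, "all" to use every sample); ``matrix`` supplies the
    condition labels and may be omitted when ``columns="all"``.
    """
    if bexpr.flags is None:
        raise ValueError("binarize() must be applied before DE calling")
    if columns == "all":
        flags = bexpr.flags
    else:
        if matrix is None:
            raise ValueError("condition labels required to select tumor columns")
        cols = matrix.sample_columns(columns)
        if not cols:
            raise ValueError(f"no {columns!r} samples available")
        flags = bexpr.flags[cols]
    arr = flags.to_numpy()
    global_rate = float(arr.mean())
    per_gene = arr.mean(axis=1)
    genes = frozenset(flags.index[per_gene > global_rate])
    logger.info("DE calling: %d/%d genes above global flag rate %.4g",
                len(genes), len(flags.index), global_rate)
    return DEGeneSet(genes, global_rate)


def edge_correlations(matrix: ExpressionMatrix,
                      network: PPINetwork,
                      columns: str = "tumor") -> dict[frozenset[str], float]:
    """Pearson correlation for every PPI edge over the selected samples.

    Edges with an endpoint missing from the expression matrix, or with a
    zero-variance endpoint, get correlation 0.  Returned keyed by the
    unordered gene pair; values lie in [-1, 1].
    """
    cols = matrix.sample_columns(columns)
    if len(cols) < 2:
        raise ValueError("correlation needs >= 2 samples")
    values = matrix.values[cols]
    present = set(values.index)
    arr = values.to_numpy()
    idx = {g: i for i, g in enumerate(values.index)}
    centered = arr - arr.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered ** 2).sum(axis=1))
    out: dict[frozenset[str], float] = {}
    for u, v, _ in network.edges():
        key = frozenset((u, v))
        if u not in present or v not in present:
            out[key] = 0.0
            continue
        nu, nv = norms[idx[u]], norms[idx[v]]
        if nu == 0.0 or nv == 0.0:
            out[key] = 0.0
            continue
        r = float(np.dot(centered[idx[u]], centered[idx[v]]) / (nu * nv))
        out[key] = max(-1.0, min(1.0, r))
    return out
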