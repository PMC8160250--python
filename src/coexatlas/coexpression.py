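"""Signed co-expression networks: Pearson r, Fisher z, hard threshold.

For each tissue the pipeline computes the Pearson correlation r_ij for every
gene pair, applies the Fisher z-transformation

    z_ij = 0.5 * ln((1 + r_ij) / (1 - r_ij)),

and retains only the strongest (anti-)correlations: the signed adjacency
stores A_ij = z_ij when z_ij < -cutoff or z_ij > cutoff (strict, default
cutoff 0.8) and zero otherwise, with a zero diagonal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: |r| is clipped here before the z-transform so duplicate genes (r = 1)
#: map to a large finite z instead of infinity, preserving edge ordering.
R_MAX = 1.0 - 1e-15


@dataclass
class CorrelationNetwork:
    """Per-tissue correlation matrices and thresholded signed adjacency."""

    genes: list[str]
    R: np.ndarray
    Z: np.ndarray
    A: np.ndarray
    cutoff: float = 0.8
    tissue: str = ""

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def edge_list(self) -> pd.DataFrame:
        """Retained edges as a long table (gene_i, gene_j, r, z)."""
        iu, ju = np.nonzero(np.triu(self.A, k=1))
        return pd.DataFrame({
            "gene_i": [self.genes[i] for i in iu],
            "gene_j": [self.genes[j] for j in ju],
            "r": self.R[iu, ju],
            "z": self.Z[iu, ju],
        })


def correlation_matrix(expr) -> tuple[np.ndarray, list[str]]:
    """Pearson correlation between all gene pairs of a genes x samples matrix.

    Zero-variance genes cannot be correlated and are dropped with a logged
    warning.  Returns the r-matrix and the list of retained gene names.
    """
    x = np.asarray(expr.values if hasattr(expr, "values") else expr, float)
    genes = list(getattr(expr, "genes", [f"G{i}" for i in range(x.shape[0])]))
    if x.shape[1] < 3:
        raise ValueError("need >= 3 samples to estimate correlations")
    var = x.var(axis=1)
    keep = var > 0
    if not keep.all():
        dropped = [g for g, k in zip(genes, keep) if not k]
        logger.warning("dropping %d zero-variance gene(s): %s...",
                       len(dropped), dropped[:5])
        x = x[keep]
        genes = [g for g, k in zip(genes, keep) if k]
    r = np.corrcoef(x)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return r, genes


def fisher_z(r) -> np.ndarray | float:
    """Fisher z-transform, z = arctanh(r); odd in r.

    |r| >= 1 is clipped to ``R_MAX`` (with a warning) so the result stays
    finite while preserving the ordering of edge strengths.
    """
    arr = np.asarray(r, dtype=float)
    if np.any(np.abs(arr) >= 1.0):
        logger.warning("clipping %d correlation(s) with |r| >= 1 before the "
                       "z-transform", int(np.sum(np.abs(arr) >= 1.0)))
    clipped = np.clip(arr, -R_MAX, R_MAX)
    z = np.arctanh(clipped)
    return z if arr.ndim else float(z)


def threshold_network(Z: np.ndarray, cutoff: float = 0.8,
                      genes: list[str] | None = None,
                      R: np.ndarray | None = None,
                      tissue: str = "") -> CorrelationNetwork:
    """Hard-threshold a z-matrix into a signed adjacency.

    A_ij = z_ij iff z_ij < -cutoff or z_ij > cutoff (strict inequality:
    entries exactly at +/-cutoff are dropped); A_ii = 0.
    """
    Z = np.asarray(Z, float)
    if Z.ndim != 2 or Z.shape[0] != Z.shape[1]:
        raise ValueError("Z must be square")
    if not np.allclose(Z, Z.T, equal_nan=True):
        raise ValueError("Z must be symmetric")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    A = np.where(np.abs(Z) > cutoff, Z, 0.0)
    np.fill_diagonal(A, 0.0)
    n = Z.shape[0]
    genes = list(genes) if genes is not None else [f"G{i}" for i in range(n)]
    if R is None:
        R = np.tanh(Z)
        np.fill_diagonal(R, 1.0)
    return CorrelationNetwork(genes=genes, R=np.asarray(R, float), Z=Z, A=A,
                              cutoff=cutoff, tissue=tissue)


def build_network(expr, cutoff: float = 0.8) -> CorrelationNetwork:
    """Full per-tissue pipeline: correlations -> Fisher z -> threshold."""
    r, genes = correlation_matrix(expr)
    r_off = r.copy()
    np.fill_diagonal(r_off, 0.0)  # self-correlations are not edges
    z = fisher_z(r_off)
    np.fill_diagonal(z, 0.0)
    return threshold_network(z, cutoff=cutoff, genes=genes, R=r,
                             tissue=getattr(expr, "tissue", ""))
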