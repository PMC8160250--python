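"""Latent-factor estimation by parallel analysis and covariate residualization.

Correlation artefacts from batch effects and other unmodelled heterogeneity
are removed before network construction: the number of latent factors is
estimated by the Buja–Eyuboglu permutation procedure (parallel analysis), the
leading left singular vectors of the centered matrix serve as the factor
estimates, and every gene is residualized against them (plus any known
covariates) by ordinary least squares.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from coexatlas.io import ExpressionMatrix


@dataclass
class ResidualMatrix:
    """Genes x samples residuals plus the names of regressed-out covariates."""

    values: np.ndarray
    genes: list[str]
    samples: list[str]
    tissue: str = ""
    regressed: list[str] = field(default_factory=list)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_samples(self) -> int:
        return len(self.samples)


def _as_values(expr) -> np.ndarray:
    return np.asarray(expr.values if hasattr(expr, "values") else expr, float)


def estimate_num_factors(expr, n_perm: int = 20, alpha: float = 0.05,
                         seed: int = 0) -> int:
    """Estimate the number of latent factors by permutation (parallel analysis).

    Each gene's values are independently permuted across samples ``n_perm``
    times; the k-th singular value of the centered data must exceed the
    (1 - alpha) quantile of the k-th permuted singular values.  The count of
    leading singular values passing this test, stopping at the first failure,
    is returned.

    A constant (or all-zero) matrix has no structure and returns 0.
    """
    x = _as_values(expr)
    if n_perm < 20:
        raise ValueError("n_perm must be >= 20 for a stable null quantile")
    if x.shape[0] < 2 or x.shape[1] < 3:
        raise ValueError("need >= 2 genes and >= 3 samples")
    xc = x - x.mean(axis=1, keepdims=True)
    if not np.any(xc):
        return 0
    sv = np.linalg.svd(xc, compute_uv=False)
    rng = np.random.default_rng(seed)
    perm_sv = np.empty((n_perm, sv.size))
    for k in range(n_perm):
        xp = xc.copy()
        # permute each gene independently across samples
        for i in range(xp.shape[0]):
            rng.shuffle(xp[i])
        xp -= xp.mean(axis=1, keepdims=True)
        perm_sv[k] = np.linalg.svd(xp, compute_uv=False)
    cutoff = np.quantile(perm_sv, 1.0 - alpha, axis=0)
    n_factors = 0
    for s, c in zip(sv, cutoff):
        if s > c:
            n_factors += 1
        else:
            break
    return n_factors


def surrogate_factors(expr, n_factors: int) -> np.ndarray:
    """Leading left-singular-vector factor estimates, as a samples x k matrix."""
    x = _as_values(expr)
    xc = x - x.mean(axis=1, keepdims=True)
    if n_factors == 0:
        return np.empty((x.shape[1], 0))
    _, _, vt = np.linalg.svd(xc, full_matrices=False)
    return vt[:n_factors].T


def residualize(expr, covariates: np.ndarray | None = None,
                names: list[str] | None = None) -> ResidualMatrix:
    """Per-gene OLS residuals against [intercept | covariates].

    Raises on a rank-deficient design, naming the collinear columns.  With no
    covariates the residuals are simply the row-centered data.
    """
    x = _as_values(expr)
    n = x.shape[1]
    if covariates is None or (hasattr(covariates, "size") and covariates.size == 0):
        design = np.ones((n, 1))
        names = []
    else:
        cov = np.asarray(covariates, float)
        if cov.ndim == 1:
            cov = cov[:, None]
        if cov.shape[0] != n:
            raise ValueError("covariates must have one row per sample")
        design = np.column_stack([np.ones(n), cov])
        names = names or [f"cov{j}" for j in range(cov.shape[1])]
        rank = np.linalg.matrix_rank(design)
        if rank < design.shape[1]:
            # identify which columns become redundant, for the error message
            bad = []
            kept = [0]
            for j in range(1, design.shape[1]):
                if np.linalg.matrix_rank(design[:, kept + [j]]) == len(kept):
                    bad.append(names[j - 1])
                else:
                    kept.append(j)
            raise ValueError(f"rank-deficient design: collinear columns {bad}")
    # hat-matrix residualization, shared across genes
    q, _ = np.linalg.qr(design)
    resid = x - (x @ q) @ q.T
    genes = list(getattr(expr, "genes", [f"G{i}" for i in range(x.shape[0])]))
    samples = list(getattr(expr, "samples", [f"S{i}" for i in range(n)]))
    return ResidualMatrix(values=resid, genes=genes, samples=samples,
                          tissue=getattr(expr, "tissue", ""),
                          regressed=["intercept"] + list(names))


def sva_adjust(expr: ExpressionMatrix, n_perm: int = 20, alpha: float = 0.05,
               seed: int = 0,
               extra_covariates: np.ndarray | None = None) -> ResidualMatrix:
    """Estimate latent factors, then residualize against them.

    Known covariates may be regressed alongside the estimated factors via
    ``extra_covariates`` (samples x covariates).
    """
    k = estimate_num_factors(expr, n_perm=n_perm, alpha=alpha, seed=seed)
    factors = surrogate_factors(expr, k)
    names = [f"SV{j + 1}" for j in range(k)]
    if extra_covariates is not None:
        extra = np.asarray(extra_covariates, float)
        if extra.ndim == 1:
            extra = extra[:, None]
        factors = np.column_stack([factors, extra]) if factors.size else extra
        names += [f"known{j}" for j in range(extra.shape[1])]
    return residualize(expr, factors if factors.size else None, names=names)
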