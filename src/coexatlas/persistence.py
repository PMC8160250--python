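"""Bootstrap inference on the global structure of low-dimensional embeddings.

Tissue clusters in a 2-D embedding of the master matrix are summarized by the
matrix of pairwise centroid distances d(i, j).  Repeatedly subsampling 80% of
the samples and re-embedding yields bootstrapped distance matrices V(k),
k = 1..B, from which the estimator's mean and variance are computed.  The
clustering conservation coefficient of two tissues,

    C_(i0,i1) = corr(dbar(i0, .), dbar(i1, .)),

correlates their distance profiles to the remaining tissues; the null of no
conservation is tested with sqrt((n - 3) / 1.06) * arctanh(C) ~ N(0, 1),
where n is the number of tissues entering the correlation and 1.06 is the
Fieller-Hartley-Pearson variance inflation for the Spearman correlation (the
default; Pearson is available, for which the factor is conventionally 1.06
kept as printed).  For a set of tissues the coefficient is the first order
statistic (minimum) over its pairs.  The stability of the whole structure is
summarized by r_k = corr(V(0), V(k)) over the strict upper triangles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import stats
from scipy.spatial.distance import cdist

from coexatlas.io import MasterMatrix

logger = logging.getLogger(__name__)

Backend = Callable[[np.ndarray, int], np.ndarray]


def umap_backend(x: np.ndarray, seed: int, **params) -> np.ndarray:
    """Default embedding backend: UMAP to 2 dimensions, deterministic given
    the seed (single-threaded when random_state is set)."""
    import umap

    n_neighbors = min(int(params.pop("n_neighbors", 15)), x.shape[0] - 1)
    reducer = umap.UMAP(n_components=2, n_neighbors=n_neighbors,
                        random_state=seed, **params)
    return np.asarray(reducer.fit_transform(x), float)


def pca_backend(x: np.ndarray, seed: int, **params) -> np.ndarray:
    """Linear 2-D backend (top two principal components); useful when a fast
    deterministic embedding suffices."""
    xc = x - x.mean(axis=0, keepdims=True)
    _, _, vt = np.linalg.svd(xc, full_matrices=False)
    return xc @ vt[:2].T


_BACKENDS: dict[str, Backend] = {"umap": umap_backend, "pca": pca_backend}


@dataclass
class EmbeddingEnsemble:
    """Reference distance matrix V(0) and B bootstrapped V(k)."""

    tissues: list[str]
    V0: np.ndarray
    Vk: np.ndarray  # shape (B, L, L); NaN rows where a tissue was lost
    frac: float
    seed: int
    backend: str = "umap"
    params: dict = field(default_factory=dict)

    @property
    def B(self) -> int:
        return self.Vk.shape[0]

    @property
    def L(self) -> int:
        return len(self.tissues)


@dataclass
class ConservationResult:
    """Conservation coefficient for a tissue pair or set, with its test."""

    tissues: tuple[str, ...]
    C: float
    statistic: float
    p_value: float
    n_profile: int  # tissues entering the correlation (the test's L)
    method: str = "spearman"


def embed(M: MasterMatrix | np.ndarray, backend: str | Backend = "umap",
          seed: int = 0, **params) -> np.ndarray:
    """Embed samples x features into 2-D with a pluggable backend."""
    x = np.asarray(M.values if hasattr(M, "values") else M, float)
    if x.shape[0] < 2:
        raise ValueError("need >= 2 samples to embed")
    fn = _BACKENDS[backend] if isinstance(backend, str) else backend
    try:
        coords = fn(x, seed, **params)
    except Exception as exc:  # pragma: no cover - backend failure context
        raise RuntimeError(f"embedding backend failed: {exc}") from exc
    return np.asarray(coords, float)


def cluster_distance_matrix(coords: np.ndarray, labels,
                            tissues: list[str] | None = None,
                            method: str = "centroid") -> tuple[np.ndarray, list[str]]:
    """L x L matrix of distances between tissue clusters in embedding space.

    ``method``: "centroid" (Euclidean distance between cluster centroids,
    the default), "medoid", or "average" (mean pairwise linkage).  Tissues in
    ``tissues`` but absent from ``labels`` get NaN rows/columns so that
    downstream means can skip them pairwise.
    """
    coords = np.asarray(coords, float)
    labels = np.asarray(labels)
    if tissues is None:
        tissues = sorted(set(labels.tolist()))
    L = len(tissues)
    centers = np.full((L, 2), np.nan)
    groups: dict[str, np.ndarray] = {}
    for i, t in enumerate(tissues):
        pts = coords[labels == t]
        if pts.size == 0:
            logger.warning("tissue %r absent from this subsample", t)
            continue
        groups[t] = pts
        if method == "centroid":
            centers[i] = pts.mean(axis=0)
        elif method == "medoid":
            d = cdist(pts, pts)
            centers[i] = pts[d.sum(axis=1).argmin()]
        elif method != "average":
            raise ValueError(f"unknown distance method {method!r}")
    if method in ("centroid", "medoid"):
        dm = cdist(centers, centers)
    else:
        dm = np.full((L, L), np.nan)
        for i, ti in enumerate(tissues):
            for j, tj in enumerate(tissues):
                if ti in groups and tj in groups:
                    dm[i, j] = cdist(groups[ti], groups[tj]).mean() if i != j else 0.0
    np.fill_diagonal(dm, 0.0)
    return dm, list(tissues)


def bootstrap_manifolds(M: MasterMatrix, B: int = 500, frac: float = 0.8,
                        backend: str | Backend = "umap", seed: int = 0,
                        replace: bool = False,
                        distance_method: str = "centroid",
                        **params) -> EmbeddingEnsemble:
    """Build the reference V(0) and B bootstrapped distance matrices V(k).

    Each bootstrap draws floor(frac * n) rows -- without replacement by
    default, matching the operational description of drawing from 80% of the
    data points; ``replace=True`` gives classical bootstrap resampling.
    """
    if not 0.0 < frac <= 1.0:
        raise ValueError("frac must lie in (0, 1]")
    if B < 2:
        raise ValueError("need B >= 2 bootstrapped manifolds for a variance")
    x = np.asarray(M.values, float)
    labels = np.asarray(M.tissue_labels)
    tissues = sorted(set(labels.tolist()))
    rng = np.random.default_rng(seed)
    coords0 = embed(x, backend=backend, seed=seed, **params)
    V0, _ = cluster_distance_matrix(coords0, labels, tissues, distance_method)
    n = x.shape[0]
    m = int(np.floor(frac * n))
    Vk = np.full((B, len(tissues), len(tissues)), np.nan)
    for k in range(B):
        idx = rng.choice(n, size=m, replace=replace)
        sub_seed = int(rng.integers(0, 2 ** 31 - 1))
        coords = embed(x[idx], backend=backend, seed=sub_seed, **params)
        Vk[k], _ = cluster_distance_matrix(coords, labels[idx], tissues,
                                           distance_method)
    name = backend if isinstance(backend, str) else getattr(backend, "__name__", "custom")
    return EmbeddingEnsemble(tissues=tissues, V0=V0, Vk=Vk, frac=frac,
                             seed=seed, backend=name, params=dict(params))


def summarize_distances(ens: EmbeddingEnsemble, verbatim: bool = False,
                        normalized: bool = False):
    """Mean and variance of the bootstrapped distance estimator.

    dbar(i,j) is the mean of d(i,j)_(k) over the B manifolds (skipping
    manifolds where a tissue was lost).  The variance is the unbiased sample
    variance by default; ``verbatim=True`` instead evaluates the published
    mixed-denominator form  sum(d^2)/(B-1) - (sum(d)/(B-1))^2,  kept for
    auditability although it is not a consistent variance estimator.  With
    ``normalized=True`` the per-manifold matrices are first divided by their
    median pairwise distance (a scale-robust alternative), and the normalized
    stack is returned as a third element.
    """
    Vk = ens.Vk.copy()
    if normalized:
        L = Vk.shape[1]
        iu, ju = np.triu_indices(L, k=1)
        for k in range(Vk.shape[0]):
            med = np.nanmedian(Vk[k][iu, ju])
            if med > 0:
                Vk[k] = Vk[k] / med
    with np.errstate(invalid="ignore"):
        dbar = np.nanmean(Vk, axis=0)
        if verbatim:
            B1 = np.sum(~np.isnan(Vk), axis=0) - 1.0
            s1 = np.nansum(Vk, axis=0)
            s2 = np.nansum(Vk ** 2, axis=0)
            var = s2 / B1 - (s1 / B1) ** 2
        else:
            var = np.nanvar(Vk, axis=0, ddof=1)
    np.fill_diagonal(var, 0.0)
    if normalized:
        return dbar, var, Vk
    return dbar, var


def conservation_test(profile_a: np.ndarray, profile_b: np.ndarray,
                      method: str = "spearman") -> tuple[float, float, float]:
    """Correlation of two distance profiles and its normal-theory test.

    Returns (C, statistic, two-sided p).  The statistic is
    sqrt((n - 3) / 1.06) * arctanh(C) with n the profile length; a constant
    profile makes C undefined (NaN, flagged by a warning).
    """
    a = np.asarray(profile_a, float)
    b = np.asarray(profile_b, float)
    keep = ~(np.isnan(a) | np.isnan(b))
    a, b = a[keep], b[keep]
    n = a.size
    if n <= 3:
        raise ValueError("profiles must share more than 3 finite entries")
    if a.std() == 0 or b.std() == 0:
        logger.warning("zero-variance distance profile: C undefined")
        return np.nan, np.nan, np.nan
    if method == "spearman":
        C = float(stats.spearmanr(a, b).statistic)
    elif method == "pearson":
        C = float(stats.pearsonr(a, b).statistic)
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    C_clipped = np.clip(C, -1 + 1e-15, 1 - 1e-15)
    stat = float(np.sqrt((n - 3) / 1.06) * np.arctanh(C_clipped))
    p = float(2.0 * stats.norm.sf(abs(stat)))
    return C, stat, p


def conservation_coefficient(dbar: np.ndarray, i0: int | str, i1: int | str,
                             tissues: list[str] | None = None,
                             method: str = "spearman") -> ConservationResult:
    """Clustering conservation coefficient of a tissue pair.

    Correlates the distance profiles dbar(i0, .) and dbar(i1, .) across the
    remaining tissues j not in {i0, i1} (self-distances of zero would inflate
    the correlation).  Requires at least 5 tissues overall.
    """
    dbar = np.asarray(dbar, float)
    L = dbar.shape[0]
    if L < 5:
        raise ValueError("the conservation test needs >= 5 tissues")
    if tissues is None:
        tissues = [str(i) for i in range(L)]
    pos = {t: i for i, t in enumerate(tissues)}
    a = pos[i0] if isinstance(i0, str) else int(i0)
    b = pos[i1] if isinstance(i1, str) else int(i1)
    others = [j for j in range(L) if j not in (a, b)]
    C, stat, p = conservation_test(dbar[a, others], dbar[b, others], method)
    return ConservationResult(tissues=(tissues[a], tissues[b]), C=C,
                              statistic=stat, p_value=p,
                              n_profile=len(others), method=method)


def conservation_set(dbar: np.ndarray, members: list[int | str],
                     tissues: list[str] | None = None,
                     method: str = "spearman") -> ConservationResult:
    """Conservation coefficient of a tissue set: the first order statistic
    (minimum) of the pairwise coefficients."""
    if len(members) < 2:
        raise ValueError("a conservation set needs >= 2 tissues")
    results = [conservation_coefficient(dbar, s, t, tissues, method)
               for i, s in enumerate(members) for t in members[i + 1:]]
    worst = min(results, key=lambda r: (np.inf if np.isnan(r.C) else r.C))
    names = tuple(str(m) for m in members)
    return ConservationResult(tissues=names, C=worst.C,
                              statistic=worst.statistic, p_value=worst.p_value,
                              n_profile=worst.n_profile, method=method)


def structure_correlation(ens: EmbeddingEnsemble) -> np.ndarray:
    """r_k = Pearson correlation between the strict upper triangles of V(0)
    and each V(k), skipping missing entries pairwise."""
    L = ens.L
    iu, ju = np.triu_indices(L, k=1)
    v0 = ens.V0[iu, ju]
    out = np.empty(ens.B)
    for k in range(ens.B):
        vk = ens.Vk[k][iu, ju]
        keep = ~(np.isnan(v0) | np.isnan(vk))
        if keep.sum() < 3 or v0[keep].std() == 0 or vk[keep].std() == 0:
            logger.warning("degenerate distance triangle in manifold %d", k)
            out[k] = np.nan
            continue
        out[k] = stats.pearsonr(v0[keep], vk[keep]).statistic
    return out
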