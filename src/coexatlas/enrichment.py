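"""Gene-set over-representation of communities.

Each community is tested against every set of a collection with the
upper-tail hypergeometric (Fisher's exact) test, followed by
Benjamini-Hochberg adjustment across the sets tested for that community.
Communities with fewer than four genes are reported "not enriched"
regardless of overlap.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

MIN_COMMUNITY_SIZE = 4


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(pvals, float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    # enforce monotonicity from the largest rank down
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.clip(adj, 0.0, 1.0)
    return out


def hypergeom_enrichment(community, collection: dict[str, set[str]],
                         background,
                         min_size: int = MIN_COMMUNITY_SIZE,
                         family: str = "per-community") -> pd.DataFrame:
    """Hypergeometric over-representation of a community in each gene set.

    For a background of N genes containing K set members, drawing n community
    genes with overlap x, the raw p is P(X >= x) under Hypergeom(N, K, n).
    Sets are intersected with the background first.  ``family`` controls the
    BH family ("per-community", the default; "none" skips adjustment so a
    caller can adjust globally).

    Returns a DataFrame (set, overlap, p, adj_p, enriched); for a community
    below ``min_size`` every row is flagged not enriched and p is NaN.
    """
    background = set(background)
    if not background:
        raise ValueError("empty background universe")
    community = set(community)
    if not community <= background:
        raise ValueError("community must be a subset of the background")
    N = len(background)
    n = len(community)
    rows = []
    too_small = n < min_size
    for name, genes in collection.items():
        members = genes & background
        K = len(members)
        x = len(community & members)
        if too_small:
            rows.append((name, x, np.nan))
            continue
        p = float(stats.hypergeom.sf(x - 1, N, K, n)) if K else 1.0
        rows.append((name, x, min(p, 1.0)))
    df = pd.DataFrame(rows, columns=["set", "overlap", "p"])
    if too_small:
        df["adj_p"] = np.nan
        df["enriched"] = False
        return df
    if family == "per-community":
        df["adj_p"] = bh_adjust(df["p"].to_numpy())
    elif family == "none":
        df["adj_p"] = np.nan
    else:
        raise ValueError(f"unknown BH family {family!r}")
    df["enriched"] = df["adj_p"] < 0.05
    return df


def enrich_atlas(atlas, collection: dict[str, set[str]], background,
                 min_size: int = MIN_COMMUNITY_SIZE) -> pd.DataFrame:
    """Run the over-representation test for every community of an atlas."""
    frames = []
    for cid, genes in atlas.communities.items():
        df = hypergeom_enrichment(genes, collection, background,
                                  min_size=min_size)
        df.insert(0, "community_id", cid)
        frames.append(df)
    if not frames:
        return pd.DataFrame(columns=["community_id", "set", "overlap", "p",
                                     "adj_p", "enriched"])
    return pd.concat(frames, ignore_index=True)
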