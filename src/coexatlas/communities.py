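"""Signed-modularity Louvain community detection and community statistics.

Positive and negative edges are treated asymmetrically: positive weight
inside a community counts fully toward the quality of a partition while
negative weight inside a community is penalized with a smaller normalization,
driving anti-correlated genes into different communities.  The quality index
maximized is

    Q* = (1/v+) sum_ij (w+_ij - e+_ij) d_ij
         - (1/(v+ + v-)) sum_ij (w-_ij - e-_ij) d_ij,

where w+_ij (w-_ij) is the positive (negative) part of the edge weight mapped
into [0, 1], e+-_ij = s+-_i s+-_j / v+- is the chance-expected weight given
the node strengths s, v+- is the total positive/negative weight, the sums run
over ordered node pairs (diagonal included; its delta terms are constant
across partitions), and d_ij = 1 when i and j share a community.  A
resolution parameter gamma multiplies e+-_ij.

The Louvain procedure starts from singletons, greedily moves nodes to the
neighboring community with the largest positive gain in Q*, then aggregates
communities into super-nodes and repeats until no gain remains.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from coexatlas.coexpression import CorrelationNetwork

#: convergence tolerance: a full pass improving Q* by less than this stops
_TOL = 1e-10


@dataclass
class Partition:
    """A gene -> community-id map with the resolution it was found at."""

    membership: dict[str, int]
    gamma: float = 1.0
    seed: int | None = None
    modularity: float | None = None

    @property
    def n_communities(self) -> int:
        return len(set(self.membership.values()))

    def communities(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for g, c in self.membership.items():
            out.setdefault(c, []).append(g)
        return out

    def labels(self, genes: list[str]) -> np.ndarray:
        return np.array([self.membership[g] for g in genes])


@dataclass
class CommunityAtlas:
    """Retained (>= min_size member) communities of one tissue."""

    tissue: str
    communities: dict[int, list[str]] = field(default_factory=dict)
    min_size: int = 4

    @property
    def n_communities(self) -> int:
        return len(self.communities)

    def membership(self) -> dict[str, int]:
        return {g: c for c, genes in self.communities.items() for g in genes}

    def genes(self) -> set[str]:
        return {g for genes in self.communities.values() for g in genes}

    def to_records(self) -> pd.DataFrame:
        rows = [(self.tissue, c, g)
                for c, genes in sorted(self.communities.items())
                for g in genes]
        return pd.DataFrame(rows, columns=["tissue", "community_id", "gene"])


def _signed_parts(A: np.ndarray, mapping: str = "clip") -> tuple[np.ndarray, np.ndarray]:
    """Split a signed adjacency into w+ and w- mapped into [0, 1].

    "clip" truncates magnitudes at 1 (thresholded z-weights exceed the cutoff
    by construction, so clipping preserves the ranking of strong edges);
    "rescale" divides by the largest magnitude instead.
    """
    A = np.asarray(A, float)
    if mapping == "clip":
        wp = np.clip(A, 0.0, 1.0)
        wn = np.clip(-A, 0.0, 1.0)
    elif mapping == "rescale":
        m = np.abs(A).max()
        scaled = A / m if m > 0 else A
        wp = np.clip(scaled, 0.0, None)
        wn = np.clip(-scaled, 0.0, None)
    else:
        raise ValueError(f"unknown weight mapping {mapping!r}")
    return wp, wn


def _check_adjacency(A: np.ndarray) -> np.ndarray:
    A = np.asarray(A, float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.allclose(A, A.T):
        raise ValueError("adjacency must be symmetric")
    if np.any(np.diagonal(A) != 0):
        raise ValueError("adjacency must have a zero diagonal")
    return A


def _q_signed(wp: np.ndarray, wn: np.ndarray, labels: np.ndarray,
              gamma: float) -> float:
    """Evaluate Q* from the split weights for a label vector."""
    q = 0.0
    for w, sign in ((wp, +1), (wn, -1)):
        v = w.sum()
        if v == 0:
            continue
        s = w.sum(axis=1)
        inner = 0.0
        for c in np.unique(labels):
            idx = labels == c
            inner += w[np.ix_(idx, idx)].sum() - gamma * s[idx].sum() ** 2 / v
        if sign > 0:
            q += inner / v
        else:
            q -= inner / (wp.sum() + wn.sum())
    return q


def signed_modularity(A: np.ndarray, partition: Partition | dict | np.ndarray,
                      gamma: float = 1.0, genes: list[str] | None = None,
                      mapping: str = "clip") -> float:
    """Signed modularity Q* of a partition on a signed adjacency.

    ``partition`` may be a Partition, a gene -> id dict, or a label vector
    aligned with the adjacency rows.
    """
    A = _check_adjacency(A)
    n = A.shape[0]
    if genes is None:
        genes = [f"G{i}" for i in range(n)]
    if isinstance(partition, Partition):
        labels = partition.labels(genes)
        gamma = partition.gamma
    elif isinstance(partition, dict):
        labels = np.array([partition[g] for g in genes])
    else:
        labels = np.asarray(partition)
    if labels.shape != (n,):
        raise ValueError("partition must assign every node a community")
    wp, wn = _signed_parts(A, mapping)
    return _q_signed(wp, wn, labels, gamma)


def _louvain_pass(wp: np.ndarray, wn: np.ndarray, vp: float, vn: float,
                  gamma: float, rng: np.random.Generator,
                  labels: np.ndarray) -> tuple[np.ndarray, bool]:
    """One full phase of local node moves; returns labels and whether any move
    improved Q* by more than the tolerance."""
    n = wp.shape[0]
    sp = wp.sum(axis=1)
    sn = wn.sum(axis=1)
    sigma_p = np.zeros(n)
    sigma_n = np.zeros(n)
    for c in range(n):
        idx = labels == c
        sigma_p[c] = sp[idx].sum()
        sigma_n[c] = sn[idx].sum()
    vt = vp + vn
    size = np.bincount(labels, minlength=n)
    improved = False
    moved = True
    while moved:
        moved = False
        order = rng.permutation(n)
        for node in order:
            a = labels[node]
            sigma_p[a] -= sp[node]
            sigma_n[a] -= sn[node]
            size[a] -= 1
            labels[node] = -1
            # candidates: the current community, all neighbor communities
            # through either edge sign, and one fresh singleton (a node held
            # only by negative edges may be best off alone)
            nb = np.nonzero((wp[node] > 0) | (wn[node] > 0))[0]
            cands = {int(labels[j]) for j in nb if labels[j] >= 0}
            # the expected-negative-weight term can favor co-placing
            # negative-strength nodes that share no edge, so communities
            # carrying negative strength are candidates too
            if sn[node] > 0:
                cands.update(int(c) for c in
                             np.nonzero((size > 0) & (sigma_n > 1e-12))[0])
            cands.discard(a)
            if size[a] > 0:
                empties = np.nonzero(size == 0)[0]
                if empties.size:
                    cands.add(int(empties[0]))
            cand_list = list(cands)
            rng.shuffle(cand_list)

            best_c, best_gain = a, -np.inf
            for c in [a] + cand_list:  # staying put wins ties
                idx = labels == c
                kp = wp[node, idx].sum()
                kn = wn[node, idx].sum()
                gain = 0.0
                if vp > 0:
                    gain += (2.0 * kp + wp[node, node]
                             - gamma * (2.0 * sp[node] * sigma_p[c]
                                        + sp[node] ** 2) / vp) / vp
                if vn > 0:
                    gain -= (2.0 * kn + wn[node, node]
                             - gamma * (2.0 * sn[node] * sigma_n[c]
                                        + sn[node] ** 2) / vn) / vt
                if gain > best_gain + _TOL:
                    best_gain, best_c = gain, c
            labels[node] = best_c
            sigma_p[best_c] += sp[node]
            sigma_n[best_c] += sn[node]
            size[best_c] += 1
            if best_c != a:
                moved = True
                improved = True
    return labels, improved


def _move_gains(wp, wn, vp, vn, vt, sp, sn, sigma_p, sigma_n, gamma,
                node, cands, labels):
    """Gain of inserting an (already removed) node into each candidate."""
    gains = []
    for c in cands:
        idx = labels == c
        kp = wp[node, idx].sum()
        kn = wn[node, idx].sum()
        gain = 0.0
        if vp > 0:
            gain += (2.0 * kp + wp[node, node]
                     - gamma * (2.0 * sp[node] * sigma_p[c]
                                + sp[node] ** 2) / vp) / vp
        if vn > 0:
            gain -= (2.0 * kn + wn[node, node]
                     - gamma * (2.0 * sn[node] * sigma_n[c]
                                + sn[node] ** 2) / vn) / vt
        gains.append(gain)
    return gains


def _kl_pass(wp: np.ndarray, wn: np.ndarray, vp: float, vn: float,
             gamma: float, rng: np.random.Generator,
             labels: np.ndarray) -> tuple[np.ndarray, float]:
    """Kernighan-Lin-style escape pass.

    Every node is tentatively moved once to its best alternative community
    even when the step is negative; the partition is then rolled back to the
    best prefix of the move sequence.  This crosses modularity barriers that
    block single greedy moves (e.g., a three-way merge whose pairwise steps
    are each negative).  Returns the (possibly improved) labels and the net
    gain of the accepted prefix.
    """
    n = wp.shape[0]
    labels = labels.copy()
    sp = wp.sum(axis=1)
    sn = wn.sum(axis=1)
    sigma_p = np.zeros(n)
    sigma_n = np.zeros(n)
    for c in np.unique(labels):
        idx = labels == c
        sigma_p[c] = sp[idx].sum()
        sigma_n[c] = sn[idx].sum()
    size = np.bincount(labels, minlength=n)
    vt = vp + vn
    cum = 0.0
    best_cum = 0.0
    best_step = -1
    moves: list[tuple[int, int, int]] = []
    for node in rng.permutation(n):
        a = labels[node]
        sigma_p[a] -= sp[node]
        sigma_n[a] -= sn[node]
        size[a] -= 1
        labels[node] = -1
        nb = np.nonzero((wp[node] > 0) | (wn[node] > 0))[0]
        cands = {int(labels[j]) for j in nb if labels[j] >= 0}
        if sn[node] > 0:
            cands.update(int(c) for c in
                         np.nonzero((size > 0) & (sigma_n > 1e-12))[0])
        cands.discard(a)
        if size[a] > 0:
            empties = np.nonzero(size == 0)[0]
            if empties.size:
                cands.add(int(empties[0]))
        cand_list = list(cands)
        rng.shuffle(cand_list)
        all_cands = [a] + cand_list
        gains = _move_gains(wp, wn, vp, vn, vt, sp, sn, sigma_p, sigma_n,
                            gamma, node, all_cands, labels)
        if len(all_cands) > 1:
            alt = 1 + int(np.argmax(gains[1:]))
            target = all_cands[alt]
            cum += gains[alt] - gains[0]
        else:
            target = a
        labels[node] = target
        sigma_p[target] += sp[node]
        sigma_n[target] += sn[node]
        size[target] += 1
        moves.append((int(node), int(a), int(target)))
        if cum > best_cum + _TOL:
            best_cum = cum
            best_step = len(moves) - 1
    # roll back everything after the best prefix
    for node, a, target in reversed(moves[best_step + 1:]):
        labels[node] = a
        sigma_p[target] -= sp[node]
        sigma_n[target] -= sn[node]
        sigma_p[a] += sp[node]
        sigma_n[a] += sn[node]
    return labels, best_cum


def louvain_sign(A: np.ndarray, gamma: float = 1.0, seed: int = 0,
                 genes: list[str] | None = None,
                 mapping: str = "clip", kl_attempts: int = 8) -> Partition:
    """Signed-modularity Louvain community detection.

    Starts from singletons; node visit order is shuffled by ``seed``.  The
    returned partition's Q* is never below that of the all-singleton
    partition.  An empty network yields all-singleton communities.
    """
    A = _check_adjacency(A)
    n = A.shape[0]
    if genes is None:
        genes = [f"G{i}" for i in range(n)]
    rng = np.random.default_rng(seed)
    wp0, wn0 = _signed_parts(A, mapping)
    vp, vn = wp0.sum(), wn0.sum()

    labels_full = np.arange(n)  # partition of the original nodes
    while True:
        while True:
            # aggregate the current partition into super-nodes
            _, comp = np.unique(labels_full, return_inverse=True)
            k = comp.max() + 1
            agg = np.zeros((k, n))
            agg[comp, np.arange(n)] = 1.0
            wp = agg @ wp0 @ agg.T
            wn = agg @ wn0 @ agg.T
            lab, improved_agg = _louvain_pass(wp, wn, vp, vn, gamma, rng,
                                              np.arange(k))
            labels_full = lab[comp]
            # refinement: local moves of the original nodes
            labels_full, improved_ref = _louvain_pass(wp0, wn0, vp, vn,
                                                      gamma, rng, labels_full)
            if not (improved_agg or improved_ref):
                break
        escaped = False
        for _ in range(kl_attempts):
            labels_kl, gain = _kl_pass(wp0, wn0, vp, vn, gamma, rng,
                                       labels_full)
            if gain > _TOL:
                labels_full = labels_kl
                escaped = True
                break
        if not escaped:
            break

    _, final = np.unique(labels_full, return_inverse=True)
    membership = {g: int(c) for g, c in zip(genes, final)}
    part = Partition(membership=membership, gamma=gamma, seed=seed)
    part.modularity = _q_signed(wp0, wn0, final, gamma)
    return part


def filter_communities(partition: Partition, min_size: int = 4,
                       tissue: str = "") -> CommunityAtlas:
    """Drop communities below ``min_size`` members; their genes become
    community-less.  Retained communities get stable ids 0..k-1 ordered by
    decreasing size (ties by first gene name)."""
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    groups = partition.communities()
    kept = [sorted(genes) for genes in groups.values() if len(genes) >= min_size]
    kept.sort(key=lambda gs: (-len(gs), gs[0]))
    return CommunityAtlas(
        tissue=tissue,
        communities={i: gs for i, gs in enumerate(kept)},
        min_size=min_size,
    )


def segregation_stats(network: CorrelationNetwork,
                      atlas: CommunityAtlas) -> dict:
    """Count retained edges leaving each community.

    For every community, the number of network edges with exactly one
    endpoint inside it; the mode and the maximum over communities summarize
    how segregated the communities are from the rest of the network.
    """
    gene_idx = {g: i for i, g in enumerate(network.genes)}
    iu, ju = np.nonzero(np.triu(network.A, k=1))
    counts: dict[int, int] = {}
    for cid, genes in atlas.communities.items():
        members = {gene_idx[g] for g in genes if g in gene_idx}
        c = 0
        for i, j in zip(iu, ju):
            if (int(i) in members) != (int(j) in members):
                c += 1
        counts[cid] = c
    values = list(counts.values())
    mode = Counter(values).most_common(1)[0][0] if values else 0
    return {"counts": counts, "mode": mode,
            "max": max(values) if values else 0}
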