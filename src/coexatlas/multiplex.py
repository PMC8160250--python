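"""Multiplex architectures and the global multiplexity index.

A multiplex network stacks the per-tissue community structures as layers
sharing one gene set.  The global multiplexity index counts, for a gene pair
(i, j), the layers in which the two genes fall in the same retained
community:

    gmi(i, j) = sum_{g=1..L} delta(c_i^g, c_j^g),

so gmi ranges over 0..L and the pairs attaining gmi = L always co-cluster.
The pair distribution pi_k = P(gmi = k | gmi > 0) summarizes tissue sharing,
and the maximal groups are the gene sets whose members pairwise attain
gmi = L.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from coexatlas.communities import CommunityAtlas

logger = logging.getLogger(__name__)


@dataclass
class MultiplexCommunities:
    """A named multiplex architecture with per-layer community memberships.

    Genes absent from a layer's atlas carry a per-gene sentinel membership in
    that layer that never equals any other gene's id, so they can never
    co-cluster there.
    """

    name: str
    layers: list[str]
    universe: list[str]
    #: layers x genes integer membership codes; negative codes are sentinels
    codes: np.ndarray = field(repr=False, default=None)

    @property
    def n_layers(self) -> int:
        return len(self.layers)


@dataclass
class GlobalMultiplexityMatrix:
    """Symmetric gene-pair matrix of gmi values in [0, L]."""

    genes: list[str]
    values: np.ndarray
    n_layers: int

    def to_edge_list(self) -> pd.DataFrame:
        iu, ju = np.nonzero(np.triu(self.values, k=1))
        return pd.DataFrame({
            "gene_i": [self.genes[i] for i in iu],
            "gene_j": [self.genes[j] for j in ju],
            "gmi": self.values[iu, ju].astype(int),
        })


def build_multiplex(atlases: list[CommunityAtlas],
                    architecture: list[str],
                    name: str = "") -> MultiplexCommunities:
    """Assemble a multiplex from per-tissue atlases for the named layers.

    The gene universe is restricted to genes appearing in at least one
    layer's retained communities; never-clustered genes contribute no pairs.
    """
    by_tissue = {a.tissue: a for a in atlases}
    missing = [t for t in architecture if t not in by_tissue]
    if missing:
        raise ValueError(f"unknown tissue(s) {missing}; available: "
                         f"{sorted(by_tissue)}")
    if len(architecture) < 2:
        raise ValueError("a multiplex needs at least 2 layers")
    universe: list[str] = []
    seen: set[str] = set()
    for t in architecture:
        for g in sorted(by_tissue[t].genes()):
            if g not in seen:
                seen.add(g)
                universe.append(g)
    gene_pos = {g: i for i, g in enumerate(universe)}
    codes = np.empty((len(architecture), len(universe)), dtype=np.int64)
    for li, t in enumerate(architecture):
        member = by_tissue[t].membership()
        for g, i in gene_pos.items():
            # sentinel -(i+1): unique per gene, never matches another gene
            codes[li, i] = member.get(g, -(i + 1))
    return MultiplexCommunities(name=name or "+".join(architecture),
                                layers=list(architecture),
                                universe=universe, codes=codes)


def global_multiplexity(mpx: MultiplexCommunities) -> GlobalMultiplexityMatrix:
    """Count, per gene pair, the layers in which the pair co-clusters."""
    n = len(mpx.universe)
    gmi = np.zeros((n, n), dtype=np.int64)
    for li in range(mpx.n_layers):
        row = mpx.codes[li]
        valid = row >= 0  # sentinel memberships never match
        idx = np.nonzero(valid)[0]
        sub = row[idx]
        same = sub[:, None] == sub[None, :]
        gmi[np.ix_(idx, idx)] += same
    np.fill_diagonal(gmi, 0)
    return GlobalMultiplexityMatrix(genes=list(mpx.universe), values=gmi,
                                    n_layers=mpx.n_layers)


def gmi_distribution(gmi: GlobalMultiplexityMatrix,
                     include_zero: bool = False) -> pd.Series:
    """Estimate pi_k, the probability that a gene pair co-clusters in exactly
    k layers, over pairs with a positive index (k = 1..L).

    With ``include_zero`` the denominator is all universe pairs and k = 0 is
    reported too.
    """
    iu, ju = np.triu_indices(len(gmi.genes), k=1)
    vals = gmi.values[iu, ju]
    if not include_zero:
        vals = vals[vals > 0]
        ks = range(1, gmi.n_layers + 1)
    else:
        ks = range(0, gmi.n_layers + 1)
    if vals.size == 0:
        logger.warning("no gene pair has a positive global multiplexity index")
        return pd.Series(dtype=float, name="pi_k")
    counts = np.array([(vals == k).sum() for k in ks], dtype=float)
    return pd.Series(counts / vals.size, index=list(ks), name="pi_k")


def maximal_groups(gmi: GlobalMultiplexityMatrix,
                   L: int | None = None) -> list[list[str]]:
    """Gene groups that co-cluster in every layer (pairwise gmi = L).

    Connected components of the gmi = L graph are returned when they are
    cliques; a non-clique component is split into its maximal cliques, since
    "always in the same community" is a pairwise-all property.
    """
    L = L if L is not None else gmi.n_layers
    g = nx.Graph()
    iu, ju = np.nonzero(np.triu(gmi.values >= L, k=1))
    for i, j in zip(iu, ju):
        g.add_edge(gmi.genes[i], gmi.genes[j])
    groups: list[list[str]] = []
    for comp in nx.connected_components(g):
        sub = g.subgraph(comp)
        m = len(comp)
        if sub.number_of_edges() == m * (m - 1) // 2:
            groups.append(sorted(comp))
        else:
            groups.extend(sorted(c) for c in nx.find_cliques(sub) if len(c) >= 2)
    groups.sort(key=lambda gs: (-len(gs), gs[0]))
    return groups
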