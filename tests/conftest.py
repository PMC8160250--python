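"""Shared fixtures: partition enumeration, an independent signed-modularity
evaluator, random signed toy graphs, and a well-separated planted simulation."""

from __future__ import annotations

import numpy as np
import pytest

from coexatlas import PlantedBlock, SimConfig, generate_expression


def all_partitions(n: int):
    """Every set partition of n items, as restricted-growth label tuples."""
    def rec(i, labels, mx):
        if i == n:
            yield tuple(labels)
            return
        for c in range(mx + 1):
            labels.append(c)
            yield from rec(i + 1, labels, max(mx, c + 1))
            labels.pop()
    yield from rec(0, [], 0)


def brute_force_q(A: np.ndarray, labels, gamma: float = 1.0) -> float:
    """Independent signed-modularity evaluator: a literal double loop over
    ordered node pairs, written directly from the definition."""
    wp = np.clip(A, 0.0, 1.0)
    wn = np.clip(-A, 0.0, 1.0)
    vp, vn = wp.sum(), wn.sum()
    n = A.shape[0]
    q = 0.0
    for i in range(n):
        for j in range(n):
            if labels[i] != labels[j]:
                continue
            if vp > 0:
                q += (wp[i, j] - gamma * wp[i].sum() * wp[j].sum() / vp) / vp
            if vn > 0:
                q -= (wn[i, j] - gamma * wn[i].sum() * wn[j].sum() / vn) / (vp + vn)
    return q


def random_signed_graph(rng: np.random.Generator, n: int,
                        density: float = 0.6) -> np.ndarray:
    A = np.zeros((n, n))
    iu = np.triu_indices(n, 1)
    w = rng.uniform(-1, 1, size=len(iu[0])) * (rng.random(len(iu[0])) < density)
    A[iu] = w
    return A + A.T


@pytest.fixture(scope="session")
def oracle():
    """Bundle of independent evaluators for community detection."""
    return {"all_partitions": all_partitions, "q": brute_force_q,
            "random_graph": random_signed_graph}


@pytest.fixture(scope="session")
def separated_sim():
    """Two tissues, three well-separated planted blocks (b=0.95, sigma=0.31,
    one block with mixed loading signs, one block tissue-specific), n=500."""
    blocks = [
        PlantedBlock(genes=tuple(range(0, 10)),
                     loadings=(0.95,) * 10, tissues=(0, 1)),
        PlantedBlock(genes=tuple(range(10, 20)),
                     loadings=(0.95,) * 5 + (-0.95,) * 5, tissues=(0, 1)),
        PlantedBlock(genes=tuple(range(20, 28)),
                     loadings=(0.95,) * 8, tissues=(0,)),
    ]
    config = SimConfig(n_tissues=2, samples_per_tissue=[500, 500], n_genes=60,
                       planted_blocks=blocks, tissue_effect_sd=1.0,
                       noise_sd=0.31, seed=11)
    matrices, truth = generate_expression(config)
    return config, matrices, truth
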