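"""Embedding, bootstrapped cluster distances, and conservation inference."""

import numpy as np
import pytest
from scipy import stats
from sklearn.metrics import silhouette_score

from coexatlas import bootstrap_manifolds, cluster_distance_matrix, \
    conservation_coefficient, conservation_set, conservation_test, embed, \
    structure_correlation, summarize_distances
from coexatlas.io import MasterMatrix
from coexatlas.persistence import EmbeddingEnsemble


def _gaussian_clouds(seed=0, n_per=40, sep=12.0, n_clusters=3, dim=6):
    rng = np.random.default_rng(seed)
    centers = rng.normal(scale=sep, size=(n_clusters, dim))
    x = np.vstack([centers[k] + rng.normal(size=(n_per, dim))
                   for k in range(n_clusters)])
    labels = np.repeat([f"T{k}" for k in range(n_clusters)], n_per)
    return x, labels


def _master(x, labels):
    return MasterMatrix(values=x, samples=[f"s{i}" for i in range(len(x))],
                        genes=[f"g{j}" for j in range(x.shape[1])],
                        tissue_labels=list(labels))


def test_umap_separates_gaussian_clouds():
    x, labels = _gaussian_clouds()
    coords = embed(x, backend="umap", seed=0)
    assert coords.shape == (len(x), 2)
    assert silhouette_score(coords, labels) > 0.5


def test_umap_deterministic_given_seed():
    x, _ = _gaussian_clouds(n_per=25)
    c1 = embed(x, backend="umap", seed=7)
    c2 = embed(x, backend="umap", seed=7)
    np.testing.assert_array_equal(c1, c2)


def test_duplicated_sample_embeds_near_twin():
    x, _ = _gaussian_clouds(n_per=25)
    x2 = np.vstack([x, x[0]])
    coords = embed(x2, backend="umap", seed=1)
    d_twin = np.linalg.norm(coords[-1] - coords[0])
    spread = np.linalg.norm(coords - coords.mean(0), axis=1).mean()
    assert d_twin < 0.25 * spread


def test_centroid_distance_hand_geometry():
    coords = np.array([[0.0, 0.0], [0.0, 0.0], [3.0, 4.0], [3.0, 4.0]])
    labels = np.array(["A", "A", "B", "B"])
    dm, tissues = cluster_distance_matrix(coords, labels)
    assert tissues == ["A", "B"]
    assert dm[0, 1] == pytest.approx(5.0)
    assert dm[0, 0] == 0.0


def test_identical_label_sets_zero_distance():
    coords = np.array([[1.0, 2.0], [3.0, 4.0], [1.0, 2.0], [3.0, 4.0]])
    labels = np.array(["A", "A", "B", "B"])
    dm, _ = cluster_distance_matrix(coords, labels)
    assert dm[0, 1] == pytest.approx(0.0)


def test_four_cluster_matrix_matches_hand_computation():
    centers = {"A": (0, 0), "B": (1, 0), "C": (0, 2), "D": (3, 4)}
    coords, labels = [], []
    for name, c in centers.items():
        coords += [c, c]
        labels += [name, name]
    dm, tissues = cluster_distance_matrix(np.array(coords, float),
                                          np.array(labels))
    for i, ti in enumerate(tissues):
        for j, tj in enumerate(tissues):
            want = np.hypot(centers[ti][0] - centers[tj][0],
                            centers[ti][1] - centers[tj][1])
            assert dm[i, j] == pytest.approx(want)


def test_missing_tissue_flagged_nan():
    coords = np.zeros((2, 2))
    dm, _ = cluster_distance_matrix(coords, np.array(["A", "A"]),
                                    tissues=["A", "B"])
    assert np.isnan(dm[0, 1])


def test_full_fraction_deterministic_backend_reproduces_v0():
    x, labels = _gaussian_clouds(n_per=15)
    ens = bootstrap_manifolds(_master(x, labels), B=3, frac=1.0,
                              backend="pca", seed=0)
    for k in range(ens.B):
        np.testing.assert_allclose(ens.Vk[k], ens.V0, atol=1e-8)


def test_minimum_bootstrap_count_enforced():
    x, labels = _gaussian_clouds(n_per=10)
    with pytest.raises(ValueError):
        bootstrap_manifolds(_master(x, labels), B=1, backend="pca", seed=0)


def test_bootstrap_mean_within_two_sigma_of_v0():
    x, labels = _gaussian_clouds(n_per=40, sep=15.0)
    ens = bootstrap_manifolds(_master(x, labels), B=30, frac=0.8,
                              backend="pca", seed=1)
    dbar, var = summarize_distances(ens)
    sd = np.sqrt(var)
    iu, ju = np.triu_indices(ens.L, 1)
    assert np.all(np.abs(dbar[iu, ju] - ens.V0[iu, ju]) <= 2 * sd[iu, ju])


def test_sigma_shrinks_with_subsample_size():
    x, labels = _gaussian_clouds(n_per=40, sep=15.0)
    m = _master(x, labels)
    small = bootstrap_manifolds(m, B=40, frac=0.4, backend="pca", seed=2)
    large = bootstrap_manifolds(m, B=40, frac=0.9, backend="pca", seed=2)
    _, var_small = summarize_distances(small)
    _, var_large = summarize_distances(large)
    iu, ju = np.triu_indices(small.L, 1)
    assert var_large[iu, ju].mean() < var_small[iu, ju].mean()


def test_verbatim_variance_formula_algebra():
    """With identical V(k), the published mixed-denominator form gives
    d^2 (1/(B-1) - B/(B-1)^2) while the corrected estimator is exactly 0."""
    d = 3.0
    B = 5
    Vk = np.full((B, 2, 2), 0.0)
    Vk[:, 0, 1] = Vk[:, 1, 0] = d
    ens = EmbeddingEnsemble(tissues=["A", "B"], V0=Vk[0].copy(), Vk=Vk,
                            frac=0.8, seed=0)
    _, var = summarize_distances(ens)
    assert var[0, 1] == pytest.approx(0.0, abs=1e-12)
    _, var_verbatim = summarize_distances(ens, verbatim=True)
    want = (B * d ** 2) / (B - 1) - (B * d / (B - 1)) ** 2
    assert var_verbatim[0, 1] == pytest.approx(want, abs=1e-12)


def test_mean_of_two_values():
    Vk = np.zeros((2, 2, 2))
    Vk[0, 0, 1] = Vk[0, 1, 0] = 1.0
    Vk[1, 0, 1] = Vk[1, 1, 0] = 3.0
    ens = EmbeddingEnsemble(tissues=["A", "B"], V0=Vk[0].copy(), Vk=Vk,
                            frac=0.8, seed=0)
    dbar, _ = summarize_distances(ens)
    assert dbar[0, 1] == pytest.approx(2.0)


def test_median_normalization_identity():
    rng = np.random.default_rng(3)
    L = 5
    V = np.abs(rng.normal(size=(L, L)))
    V = (V + V.T) / 2
    np.fill_diagonal(V, 0.0)
    iu, ju = np.triu_indices(L, 1)
    V = V / np.median(V[iu, ju])  # median pair distance 1
    Vk = np.stack([V, V])
    ens = EmbeddingEnsemble(tissues=list("ABCDE"), V0=V, Vk=Vk, frac=0.8,
                            seed=0)
    _, _, Vk_norm = summarize_distances(ens, normalized=True)
    np.testing.assert_allclose(Vk_norm[0], V, atol=1e-12)


def test_conservation_closed_form_statistic():
    """C = 0.5 at profile length 10 gives statistic arctanh(0.5)*sqrt(7/1.06)
    and the matching two-sided normal p."""
    rng = np.random.default_rng(4)
    a = rng.normal(size=10)
    az = a - a.mean()
    az /= np.linalg.norm(az)
    e = rng.normal(size=10)
    ez = e - e.mean()
    ez -= (ez @ az) * az
    ez /= np.linalg.norm(ez)
    b = 0.5 * az + np.sqrt(0.75) * ez  # exact Pearson corr 0.5 with a
    C, s, p = conservation_test(a, b, method="pearson")
    assert C == pytest.approx(0.5, abs=1e-12)
    want_stat = np.arctanh(C) * np.sqrt(7 / 1.06)
    assert s == pytest.approx(want_stat, abs=1e-12)
    assert p == pytest.approx(2 * stats.norm.sf(abs(want_stat)), abs=1e-12)
    # and the printed reference point: C = 0.5 -> statistic about 1.412
    assert np.arctanh(0.5) * np.sqrt(7 / 1.06) == pytest.approx(1.412, abs=5e-3)


def test_zero_correlation_gives_p_one():
    a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    b = np.array([2.0, 5.0, 3.0, 1.0, 4.0])  # spearman rho = 0
    C, s, p = conservation_test(a, b, method="spearman")
    assert C == pytest.approx(0.0, abs=1e-12)
    assert s == pytest.approx(0.0, abs=1e-12)
    assert p == pytest.approx(1.0, abs=1e-12)


def test_identical_profiles_fully_conserved():
    rng = np.random.default_rng(5)
    L = 8
    d = np.abs(rng.normal(size=(L, L)))
    d = (d + d.T) / 2
    np.fill_diagonal(d, 0.0)
    d[1, :] = d[0, :]
    d[:, 1] = d[:, 0]
    d[1, 1] = 0.0
    res = conservation_coefficient(d, 0, 1)
    assert res.C == pytest.approx(1.0)
    assert res.p_value < 1e-10
    assert res.n_profile == L - 2


def test_pvalue_monotone_in_c():
    pairs = []
    for C in (0.2, 0.5, 0.8):
        stat = np.sqrt((10 - 3) / 1.06) * np.arctanh(C)
        pairs.append(2 * stats.norm.sf(abs(stat)))
    assert pairs[0] > pairs[1] > pairs[2]


def test_conservation_set_is_minimum_over_pairs():
    rng = np.random.default_rng(6)
    L = 7
    d = np.abs(rng.normal(size=(L, L))) + 1
    d = (d + d.T) / 2
    np.fill_diagonal(d, 0.0)
    single = conservation_coefficient(d, 0, 1)
    pair_set = conservation_set(d, [0, 1])
    assert pair_set.C == pytest.approx(single.C)
    trio = conservation_set(d, [0, 1, 2])
    mins = min(conservation_coefficient(d, a, b).C
               for a, b in [(0, 1), (0, 2), (1, 2)])
    assert trio.C == pytest.approx(mins)


def test_structure_correlation_identities():
    rng = np.random.default_rng(7)
    L = 6
    V0 = np.abs(rng.normal(size=(L, L)))
    V0 = (V0 + V0.T) / 2
    np.fill_diagonal(V0, 0.0)
    Vk = np.stack([V0, 2 * V0, V0 + rng.normal(scale=0.01, size=(L, L))])
    ens = EmbeddingEnsemble(tissues=list("ABCDEF"), V0=V0, Vk=Vk, frac=0.8,
                            seed=0)
    rk = structure_correlation(ens)
    assert rk[0] == pytest.approx(1.0)
    assert rk[1] == pytest.approx(1.0)  # scale invariance
    # oracle: hand correlation on flattened triangles
    iu, ju = np.triu_indices(L, 1)
    want = np.corrcoef(V0[iu, ju], Vk[2][iu, ju])[0, 1]
    assert rk[2] == pytest.approx(want, abs=1e-10)


def test_duplicate_tissues_have_smallest_distance():
    """Two tissues with identical generative parameters end up closest."""
    rng = np.random.default_rng(8)
    centers = {"A": (0.0, 0.0), "A2": (0.3, 0.0), "B": (8.0, 0.0),
               "C": (0.0, 9.0), "D": (7.0, 7.0)}
    x, labels = [], []
    for name, c in centers.items():
        x.append(np.array(c) + rng.normal(scale=0.5, size=(30, 2)))
        labels += [name] * 30
    m = _master(np.vstack(x), labels)
    ens = bootstrap_manifolds(m, B=20, frac=0.8, backend="pca", seed=0)
    dbar, _ = summarize_distances(ens)
    iu, ju = np.triu_indices(ens.L, 1)
    pairs = sorted(zip(dbar[iu, ju], zip(iu, ju)))
    closest = {ens.tissues[pairs[0][1][0]], ens.tissues[pairs[0][1][1]]}
    assert closest == {"A", "A2"}
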