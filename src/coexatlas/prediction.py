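"""Prediction power of communities for tissues.

Each community is scored for its ability to separate one tissue from all
others using only the expression of its member genes: a linear
maximum-margin classifier (SVM, linear kernel) with class weights inversely
proportional to class frequencies, evaluated by stratified 3-fold
cross-validation.  The reported score is the positive-class F1 (harmonic
mean of precision and recall), and a community "can predict" a tissue when
the mean F1 across folds is strictly above 0.80.
"""

from __future__ import annotations

import numpy as np
from sklearn import metrics
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from coexatlas.io import MasterMatrix

F1_THRESHOLD = 0.80


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; 0 when either is 0."""
    if not (0.0 <= precision <= 1.0 and 0.0 <= recall <= 1.0):
        raise ValueError("precision and recall must lie in [0, 1]")
    if precision == 0.0 or recall == 0.0:
        return 0.0
    return 2.0 / (1.0 / precision + 1.0 / recall)


def community_prediction_power(M: MasterMatrix, community_genes,
                               tissue: str, seed: int = 0,
                               n_folds: int = 3, C: float = 1.0) -> float:
    """Mean positive-class F1 of a one-vs-rest linear SVM for one tissue.

    The master matrix columns are sliced to the community's genes; samples of
    ``tissue`` form the positive class.  Deterministic given ``seed`` (fold
    assignment is seeded).
    """
    genes = [g for g in community_genes if g in set(M.genes)]
    if not genes:
        raise ValueError("community has no genes present in the master matrix")
    labels = np.asarray(M.tissue_labels)
    y = (labels == tissue).astype(int)
    if y.sum() < n_folds:
        raise ValueError(f"tissue {tissue!r} has fewer than {n_folds} samples;"
                         " stratified folds are infeasible")
    pos = {g: i for i, g in enumerate(M.genes)}
    x = M.values[:, [pos[g] for g in genes]]
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    scores = []
    for train, test in skf.split(x, y):
        clf = SVC(kernel="linear", class_weight="balanced", C=C,
                  random_state=seed)
        clf.fit(x[train], y[train])
        pred = clf.predict(x[test])
        scores.append(metrics.f1_score(y[test], pred, pos_label=1,
                                       zero_division=0))
    return float(np.mean(scores))


def can_predict(mean_f1: float, threshold: float = F1_THRESHOLD) -> bool:
    """A community predicts a tissue when mean F1 is strictly above 0.80."""
    return mean_f1 > threshold


def prediction_report(M: MasterMatrix, atlases, seed: int = 0):
    """Score every (source tissue, community, target tissue) triple.

    Returns a long-format DataFrame (tissue, source_tissue, community_id,
    mean_f1, can_predict) mirroring a per-community prediction-power table.
    """
    import pandas as pd

    tissues = sorted(set(M.tissue_labels))
    rows = []
    for atlas in atlases:
        for cid, genes in atlas.communities.items():
            for target in tissues:
                f1 = community_prediction_power(M, genes, target, seed=seed)
                rows.append((target, atlas.tissue, cid, f1, can_predict(f1)))
    return pd.DataFrame(rows, columns=["tissue", "source_tissue",
                                       "community_id", "mean_f1",
                                       "can_predict"])
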