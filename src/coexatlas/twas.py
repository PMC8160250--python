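"""Community-conditional statistics for gene-level association p-values.

Gene-level association p-values (e.g., from a transcriptome-wide association
study) are stratified by community membership and compared through a
conditional Q-Q plot and the estimated true-positive proportion pi1 = 1 -
pi0.  The Bayes false discovery rate at a p-value threshold is

    FDR(p) = pi0 * F0(p) / F(p),

with F0 the standard-uniform null cdf (F0(p) = p) and F the empirical cdf of
the observed p-values.  pi0 is estimated Storey-style: pi0(lambda) =
#{p > lambda} / ((1 - lambda) m) over a lambda grid, extrapolated to
lambda -> 1 with a cubic smoother.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_LAMBDA_GRID = np.round(np.arange(0.05, 0.96, 0.05), 2)


def _validate_table(table: pd.DataFrame) -> pd.DataFrame:
    required = {"gene", "p", "in_community"}
    if not required <= set(table.columns):
        raise ValueError(f"p-value table needs columns {sorted(required)}")
    if table["gene"].duplicated().any():
        raise ValueError("duplicated gene ids in p-value table")
    if (table["p"] <= 0).any() or (table["p"] > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    return table


def conditional_qq(table: pd.DataFrame, min_stratum: int = 10) -> pd.DataFrame:
    """Per-stratum expected vs observed -log10 p quantiles.

    Within each membership stratum, the sorted p-values are paired with the
    uniform order-statistic expectations i / (m + 1), both on the -log10
    scale.  Returns a long DataFrame (stratum, expected, observed).
    """
    table = _validate_table(table)
    frames = []
    for name, mask in (("community", table["in_community"]),
                       ("complement", ~table["in_community"])):
        p = np.sort(table.loc[mask, "p"].to_numpy())
        m = p.size
        if m < min_stratum:
            logger.warning("stratum %r has only %d genes", name, m)
        if m == 0:
            continue
        expected = np.arange(1, m + 1) / (m + 1)
        frames.append(pd.DataFrame({
            "stratum": name,
            "expected": -np.log10(expected),
            "observed": -np.log10(np.maximum(p, np.finfo(float).tiny)),
        }))
    return pd.concat(frames, ignore_index=True)


def estimate_pi1(pvals, lambda_grid=None) -> float:
    """Storey-type estimate of the non-null proportion pi1 = 1 - pi0.

    pi0(lambda) = #{p > lambda} / ((1 - lambda) m) is computed over the grid
    and a cubic polynomial in lambda is extrapolated to lambda = 1; the
    result is clipped to [0, 1].
    """
    p = np.asarray(pvals, float)
    if p.size < 100:
        raise ValueError("need >= 100 p-values for a stable pi0 estimate")
    if np.all(p == p[0]):
        logger.warning("all p-values identical: pi1 undefined")
        return np.nan
    grid = np.asarray(lambda_grid if lambda_grid is not None
                      else DEFAULT_LAMBDA_GRID, float)
    pi0_lambda = np.array([(p > lam).mean() / (1.0 - lam) for lam in grid])
    coeffs = np.polyfit(grid, pi0_lambda, deg=3)
    pi0 = float(np.clip(np.polyval(coeffs, 1.0), 0.0, 1.0))
    return 1.0 - pi0


def stratum_pi1(table: pd.DataFrame, lambda_grid=None) -> dict[str, float]:
    """pi1 for the community stratum and its complement."""
    table = _validate_table(table)
    mask = table["in_community"].to_numpy(bool)
    return {
        "community": estimate_pi1(table.loc[mask, "p"], lambda_grid),
        "complement": estimate_pi1(table.loc[~mask, "p"], lambda_grid),
    }


def fdr_at_threshold(table: pd.DataFrame, p_threshold: float,
                     pi0: float | None = None) -> float:
    """Bayes FDR(p) = pi0 * p / F(p) with F the empirical p-value cdf."""
    table = _validate_table(table)
    p = table["p"].to_numpy()
    F = float((p <= p_threshold).mean())
    if F == 0:
        raise ValueError("empirical cdf is zero at this threshold")
    if pi0 is None:
        pi0 = 1.0 - estimate_pi1(p)
    return float(min(pi0 * p_threshold / F, 1.0))


def bonferroni_line(table: pd.DataFrame, alpha: float = 0.05) -> float:
    """Bonferroni-adjusted significance threshold for the community stratum,
    reported as a reference line (not a filter)."""
    table = _validate_table(table)
    m = int(table["in_community"].sum())
    if m == 0:
        raise ValueError("no community-member genes in the table")
    return alpha / m
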