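"""File formats and core in-memory containers.

Expression matrices travel as genes x samples TSV (header row of sample ids)
or GCT 1.2.  Gene-set collections are read from GMT.  The master matrix pools
all tissues into a samples x genes table scaled per gene to [0, 1], with zeros
where a gene was absent from a tissue.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values for one tissue.

    Attributes
    ----------
    values : ndarray, shape (n_genes, n_samples)
    genes : list of str
    samples : list of str
    tissue : str
        Tissue label shared by every sample.
    covariates : DataFrame or None
        Optional samples x covariates table (index aligned with `samples`).
    """

    values: np.ndarray
    genes: list[str]
    samples: list[str]
    tissue: str = ""
    covariates: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.samples)} samples"
            )

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.samples)


@dataclass
class MasterMatrix:
    """Samples x genes matrix pooled over tissues, scaled per gene to [0, 1].

    Missing gene-tissue values are zero (no expression in that tissue).
    """

    values: np.ndarray
    samples: list[str]
    genes: list[str]
    tissue_labels: list[str] = field(default_factory=list)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.samples, columns=self.genes)


def read_expression(path: str | Path, format: str | None = None,
                    tissue: str = "") -> ExpressionMatrix:
    """Read a genes x samples expression table from TSV or GCT 1.2.

    Duplicate gene ids are dropped (first occurrence retained) with a logged
    count, mirroring standard preprocessing that removes duplicated and
    unmapped annotations before network construction.
    """
    path = Path(path)
    if format is None:
        format = "gct" if path.suffix.lower() == ".gct" else "tsv"
    if format == "gct":
        with open(path) as fh:
            version = fh.readline().strip()
            if not version.startswith("#1."):
                raise ValueError(f"{path}: not a GCT file (header {version!r})")
            fh.readline()  # dimensions line; we trust the table itself
            df = pd.read_csv(fh, sep="\t", index_col=0)
        # GCT carries a Description column before the sample columns
        if df.columns[0].lower() == "description":
            df = df.drop(columns=df.columns[0])
    elif format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
    else:
        raise ValueError(f"unknown expression format {format!r}")
    if not all(np.issubdtype(dt, np.number) for dt in df.dtypes):
        bad = [c for c, dt in df.dtypes.items() if not np.issubdtype(dt, np.number)]
        raise ValueError(f"{path}: non-numeric expression columns {bad}")
    dup = df.index.duplicated(keep="first")
    if dup.any():
        logger.warning("%s: dropped %d duplicated gene id(s)", path, int(dup.sum()))
        df = df[~dup]
    return ExpressionMatrix(
        values=df.to_numpy(dtype=float),
        genes=[str(g) for g in df.index],
        samples=[str(s) for s in df.columns],
        tissue=tissue or path.stem,
    )


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    """Write a genes x samples TSV with the gene id as the index column."""
    expr.to_frame().to_csv(path, sep="\t", index_label="gene")


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT gene-set collection: name <tab> description <tab> genes..."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = {g for g in parts[2:] if g}
    return sets


def write_gmt(sets: dict[str, Sequence[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, ""] + sorted(genes)) + "\n")


def build_master_matrix(matrices: Sequence[ExpressionMatrix],
                        scale: str = "per-gene") -> MasterMatrix:
    """Pool per-tissue matrices into a samples x union-of-genes master matrix.

    Each gene is min-max scaled to [0, 1] over the pooled samples; a gene
    absent from a tissue contributes zeros for that tissue's samples, read as
    "no expression in that tissue".  Constant genes scale to 0.

    Parameters
    ----------
    scale : {"per-gene", "global", "none"}
        Per-gene min-max scaling is the default so that every gene spans a
        comparable range in downstream embeddings.
    """
    if not matrices:
        raise ValueError("need at least one tissue matrix")
    genes: list[str] = []
    seen: set[str] = set()
    for m in matrices:
        for g in m.genes:
            if g not in seen:
                seen.add(g)
                genes.append(g)
    gene_pos = {g: i for i, g in enumerate(genes)}
    n_samples = sum(m.n_samples for m in matrices)
    values = np.zeros((n_samples, len(genes)))
    samples: list[str] = []
    labels: list[str] = []
    row = 0
    for m in matrices:
        idx = [gene_pos[g] for g in m.genes]
        values[row:row + m.n_samples, idx] = m.values.T
        samples.extend(f"{m.tissue}:{s}" for s in m.samples)
        labels.extend([m.tissue] * m.n_samples)
        row += m.n_samples
    if scale == "per-gene":
        lo = values.min(axis=0)
        span = values.max(axis=0) - lo
        span[span == 0] = 1.0  # constant gene -> 0 after shift
        values = (values - lo) / span
    elif scale == "global":
        lo, hi = values.min(), values.max()
        if hi > lo:
            values = (values - lo) / (hi - lo)
        else:
            values = np.zeros_like(values)
    elif scale != "none":
        raise ValueError(f"unknown scale mode {scale!r}")
    return MasterMatrix(values=values, samples=samples, genes=genes,
                        tissue_labels=labels)
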