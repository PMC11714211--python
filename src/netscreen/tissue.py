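"""Tissue-specificity Z-scores from a gene x tissue expression matrix.

For gene i and tissue t, Z_{i,t} = (E(i,t) - E(i)) / delta_i, where E(i)
and delta_i are the mean and standard deviation of gene i's expression
across all tissues.  The matrix holds precomputed per-tissue mean
expression; whether it is on a log or linear scale is the caller's choice
and is recorded in the metadata -- the statistic itself is scale-agnostic.
Genes above a Z threshold (2.5 is the conventional operating point) in the
target tissue are called tissue-specific.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from netscreen.interactome import GeneSet

__all__ = ["ExpressionMatrix", "tissue_z", "specific_genes", "SPECIFICITY_THRESHOLD"]

SPECIFICITY_THRESHOLD = 2.5


@dataclass
class ExpressionMatrix:
    """Genes x tissues matrix of mean expression values.

    ``scale`` records whether values are log-transformed or linear; it is
    metadata only.  Requires >= 2 tissues and no missing entries.
    """

    data: pd.DataFrame
    scale: str = "linear"

    def __post_init__(self) -> None:
        if self.data.shape[1] < 2:
            raise ValueError("expression matrix needs at least 2 tissues")
        if self.data.isna().any().any():
            raise ValueError("expression matrix contains missing entries")

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    @property
    def tissues(self) -> list[str]:
        return list(self.data.columns)

    @classmethod
    def read_tsv(cls, path: str | Path, scale: str = "linear") -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df, scale=scale)

    def write_tsv(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", float_format="%.10g")


def tissue_z(
    matrix: ExpressionMatrix, tissue: str, ddof: int = 1
) -> dict[str, float]:
    """Per-gene specificity Z for one tissue.

    ``ddof=1`` (sample standard deviation) is the default convention;
    ``ddof=0`` gives the population form, under which each gene's Z values
    sum to zero across tissues.  Genes with zero expression variance get a
    NaN sentinel rather than 0 or infinity.
    """
    if tissue not in matrix.data.columns:
        raise KeyError(f"unknown tissue {tissue!r}; have {list(matrix.data.columns)}")
    values = matrix.data.to_numpy(dtype=float)
    mean = values.mean(axis=1)
    sd = values.std(axis=1, ddof=ddof)
    col = matrix.data[tissue].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (col - mean) / sd
    z = np.where(sd == 0.0, np.nan, z)
    return {g: float(z[i]) for i, g in enumerate(matrix.data.index)}


def specific_genes(
    z: dict[str, float], threshold: float = SPECIFICITY_THRESHOLD, name: str = "tissue_specific"
) -> GeneSet:
    """Genes with Z strictly above the threshold (NaN never qualifies)."""
    if not np.isfinite(threshold) and np.isnan(threshold):
        raise ValueError("threshold must not be NaN")
    members = [g for g, v in z.items() if not np.isnan(v) and v > threshold]
    return GeneSet(name, members)
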