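"""qRT-PCR relative quantification and heatmap preparation.

Relative expression follows the 2^-ddCt convention: per sample, replicate
Ct values are averaged, the reference gene's Ct is subtracted (dCt), the
control sample's dCt is subtracted (ddCt), and fold change is 2^-ddCt, so
the control column is exactly 1 in linear scale (0 in log2).  Row ordering
for heatmaps comes from average-linkage agglomerative clustering.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .errors import ValidationError


@dataclass
class CtTable:
    """Long-format Ct measurements: one row per (gene, sample, replicate)."""

    data: pd.DataFrame  # columns: gene, sample, replicate, ct
    reference_gene: str
    control_sample: str

    def __post_init__(self) -> None:
        required = {"gene", "sample", "replicate", "ct"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValidationError(f"Ct table missing columns {sorted(missing)}")

    @classmethod
    def read_tsv(cls, path: str | Path, reference_gene: str, control_sample: str) -> "CtTable":
        return cls(pd.read_csv(path, sep="\t"), reference_gene, control_sample)

    def write_tsv(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", index=False)


@dataclass
class ExpressionMatrix:
    """Genes x conditions fold-change matrix; scale is 'linear' or 'log2'."""

    values: pd.DataFrame
    scale: str
    control_sample: str


def delta_delta_ct(table: CtTable) -> ExpressionMatrix:
    """2^-ddCt fold changes against the reference gene and control sample.

    Replicates are averaged before any subtraction.  The control column is
    exactly 1 by construction (ddCt of the control sample is identically
    zero), not by rounding.
    """
    df = table.data
    mean_ct = df.groupby(["gene", "sample"])["ct"].mean().unstack("sample")
    if table.reference_gene not in mean_ct.index:
        raise ValidationError(f"reference gene {table.reference_gene!r} absent from table")
    if table.control_sample not in mean_ct.columns:
        raise ValidationError(f"control sample {table.control_sample!r} absent from table")
    ref = mean_ct.loc[table.reference_gene]
    missing_ref = ref[ref.isna()].index.tolist()
    if missing_ref:
        raise ValidationError(f"reference Ct missing for samples {missing_ref}")
    d_ct = mean_ct.sub(ref, axis="columns")
    dd_ct = d_ct.sub(d_ct[table.control_sample], axis="index")
    fold = np.power(2.0, -dd_ct).drop(index=table.reference_gene)
    # make the control column exactly 1 (it is analytically; enforce bitwise)
    fold[table.control_sample] = 1.0
    return ExpressionMatrix(fold, "linear", table.control_sample)


def log2_matrix(m: ExpressionMatrix) -> ExpressionMatrix:
    """Entrywise log2; requires a strictly positive linear matrix."""
    if m.scale != "linear":
        raise ValidationError("log2_matrix expects a linear-scale matrix")
    if (m.values <= 0).any().any():
        bad = m.values[(m.values <= 0).any(axis=1)].index.tolist()
        raise ValidationError(f"nonpositive fold changes for genes {bad}")
    vals = np.log2(m.values)
    vals[m.control_sample] = 0.0
    return ExpressionMatrix(vals, "log2", m.control_sample)


def hclust_order(
    m: ExpressionMatrix, linkage: str = "average", metric: str = "euclidean"
) -> tuple[list[str], np.ndarray]:
    """Row order for heatmap rendering from agglomerative clustering.

    Returns (ordered gene IDs, scipy linkage matrix).  With the
    correlation metric a constant row has no defined correlation and is
    rejected by name.
    """
    if metric not in ("euclidean", "correlation"):
        raise ValidationError(f"unsupported metric {metric!r}")
    vals = m.values
    if len(vals) < 2:
        raise ValidationError("clustering needs at least two rows")
    if metric == "correlation":
        const = vals.index[vals.std(axis=1, ddof=0) == 0].tolist()
        if const:
            raise ValidationError(f"constant rows under correlation metric: {const}")
    dist = pdist(vals.to_numpy(), metric=metric)
    link = hierarchy.linkage(dist, method=linkage)
    order = hierarchy.leaves_list(link)
    return [vals.index[i] for i in order], link
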