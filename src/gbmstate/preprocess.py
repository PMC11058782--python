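"""Quality filtering and normalization.

Single-cell counts are filtered on total UMI (4000-11000 by default) and
mitochondrial fraction (<=20%), then library-size log2-normalized and
gene-centered into the relative-expression layer that all meta-module
scoring consumes. Bulk counts are scaled with median-of-ratios size
factors.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import ExpressionMatrix


class EmptyResultError(ValueError):
    """Raised when a filter removes every cell."""


def qc_filter(
    m: ExpressionMatrix,
    umi_min: float = 4000,
    umi_max: float = 11000,
    mito_max: float = 0.20,
) -> ExpressionMatrix:
    """Keep cells with umi_min <= total UMI <= umi_max and mito fraction <= mito_max.

    A pure subset operation: survivors' values are untouched and cell order
    is preserved. Raises :class:`EmptyResultError` if nothing survives.
    """
    if m.layer != "counts":
        raise ValueError(f"qc_filter needs the counts layer, got {m.layer!r}")
    if m.total_umi is None or m.mito_fraction is None:
        raise ValueError("counts matrix lacks total_umi/mito_fraction; build it with ExpressionMatrix.from_counts")
    keep = (
        (m.total_umi >= umi_min)
        & (m.total_umi <= umi_max)
        & (m.mito_fraction <= mito_max)
    )
    if not keep.any():
        raise EmptyResultError(
            f"no cells pass QC (umi in [{umi_min}, {umi_max}], mito <= {mito_max})"
        )
    return m.subset_cells(m.cell_ids[keep.to_numpy()])


def qc_report(
    m: ExpressionMatrix,
    umi_min: float = 4000,
    umi_max: float = 11000,
    mito_max: float = 0.20,
) -> pd.DataFrame:
    """Per-cell QC table: cell_id, total_umi, mito_fraction, kept flag."""
    keep = (
        (m.total_umi >= umi_min)
        & (m.total_umi <= umi_max)
        & (m.mito_fraction <= mito_max)
    )
    return pd.DataFrame(
        {
            "cell_id": m.cell_ids,
            "total_umi": m.total_umi.to_numpy(),
            "mito_fraction": m.mito_fraction.to_numpy(),
            "kept": keep.to_numpy(),
        }
    )


def lognormalize(m: ExpressionMatrix, scale: float = 10_000.0) -> ExpressionMatrix:
    """Library-size normalize and log2-transform: log2(1 + count / total * scale)."""
    if m.layer != "counts":
        raise ValueError(f"lognormalize needs the counts layer, got {m.layer!r}")
    totals = m.values.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"zero-total cells cannot be normalized: {list(zero.index[:5])}")
    vals = np.log2(1.0 + m.values / totals * scale)
    return ExpressionMatrix(
        values=vals,
        layer="lognorm",
        total_umi=m.total_umi,
        mito_fraction=m.mito_fraction,
    )


def relative_expression(m: ExpressionMatrix) -> ExpressionMatrix:
    """Center each gene on its mean across cells (the Er layer).

    Idempotent; per-gene output means are 0 to numerical precision.
    """
    if m.layer != "lognorm":
        raise ValueError(f"relative_expression needs the lognorm layer, got {m.layer!r}")
    centered = m.values.sub(m.values.mean(axis=1), axis=0)
    return ExpressionMatrix(
        values=centered,
        layer="relative",
        total_umi=m.total_umi,
        mito_fraction=m.mito_fraction,
    )


def median_of_ratios(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors for a bulk genes x samples count table.

    factor_j = median over genes (nonzero in all samples) of
    count_gj / geometric_mean_g(counts). Factors are returned unnormalized.
    """
    if counts.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    vals = counts.to_numpy(dtype=float)
    all_nonzero = (vals > 0).all(axis=1)
    if not all_nonzero.any():
        raise ValueError("no gene is nonzero in every sample; cannot form reference")
    ref = vals[all_nonzero]
    geo_mean = np.exp(np.mean(np.log(ref), axis=1))
    ratios = ref / geo_mean[:, None]
    factors = np.median(ratios, axis=0)
    return pd.Series(factors, index=counts.columns, name="size_factor")
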