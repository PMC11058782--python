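"""Spatially weighted correlation of signature surfaces over tissue regions.

Spot-level signature scores (bin-matched control scores when starting
from a gene grid) are Gaussian-kernel smoothed within each segmented
region, correlated pairwise (Pearson) per sample, stacked over samples
into a (c, c, n) array and mean-reduced to a single c x c matrix. With
bandwidth 0 the weighted correlation reduces exactly to plain Pearson.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .datatypes import SpatialCorrelationArray, SpatialSample
from .scoring import bin_by_aggregate_expression, score_signature


def score_spots(
    sample: SpatialSample,
    sets: dict[str, list[str]],
    n_bins: int = 30,
    k: int = 100,
    seed: int = 0,
) -> SpatialSample:
    """Score each signature per spot with bin-matched controls.

    The sample must carry a genes x spots expression matrix (counts or
    lognorm); it is centered per gene into the relative layer and scored
    exactly like single cells.
    """
    if sample.expr is None:
        raise ValueError("sample carries no gene grid to score")
    from .preprocess import lognormalize, relative_expression

    expr = sample.expr
    if expr.layer == "counts":
        expr = lognormalize(expr)
    if expr.layer != "lognorm":
        raise ValueError(f"cannot score layer {expr.layer!r}")
    rel = relative_expression(expr)
    bins = bin_by_aggregate_expression(expr, n_bins=n_bins)
    rng = np.random.default_rng(seed)
    cols = {}
    for name, genes in sets.items():
        cols[name] = score_signature(rel, genes, bins, k=k, seed=rng)
    scores = pd.DataFrame(cols)
    scores.index = pd.Index(sample.spot_ids, name="spot_id")
    return SpatialSample(spots=sample.spots, scores=scores, expr=sample.expr)


def smooth_surface(sample: SpatialSample, bandwidth: float) -> pd.DataFrame:
    """Gaussian-kernel weighted average of each score surface, within region.

    Weights w_ij = exp(-d_ij^2 / (2 bandwidth^2)) over spots of the same
    region; bandwidth 0 returns the scores unchanged. Spots of other
    regions never contribute.
    """
    if bandwidth < 0:
        raise ValueError("bandwidth must be >= 0")
    if sample.scores is None:
        raise ValueError("sample has no score surface")
    if bandwidth == 0:
        return sample.scores.copy()
    coords = sample.spots[["row", "col"]].to_numpy(dtype=float)
    regions = sample.spots["region"].to_numpy()
    vals = sample.scores.to_numpy(dtype=float)
    out = np.empty_like(vals)
    for region in np.unique(regions):
        mask = regions == region
        d2 = cdist(coords[mask], coords[mask], "sqeuclidean")
        w = np.exp(-d2 / (2 * bandwidth**2))
        out[mask] = (w @ vals[mask]) / w.sum(axis=1, keepdims=True)
    return pd.DataFrame(out, index=sample.scores.index, columns=sample.scores.columns)


def weighted_correlation(
    sample: SpatialSample,
    signatures: list[str] | None = None,
    region: str = "cellular_tumor",
    bandwidth: float = 1.5,
) -> pd.DataFrame:
    """Pearson correlation of kernel-smoothed surfaces within one region.

    Constant surfaces make the correlation undefined: those entries are
    reported as NaN with a warning, never as 0.
    """
    if sample.scores is None:
        raise ValueError("sample has no score surface")
    signatures = list(signatures or sample.scores.columns)
    in_region = (sample.spots["region"] == region).to_numpy()
    if in_region.sum() < 3:
        raise ValueError(f"fewer than 3 spots in region {region!r}")
    smoothed = smooth_surface(sample, bandwidth)
    sub = smoothed[in_region][signatures]
    sds = sub.std(ddof=0)
    flat = sds[sds == 0]
    if len(flat):
        warnings.warn(
            f"constant surface(s) in region {region!r}: {list(flat.index)}; "
            "correlations reported as NaN",
            stacklevel=2,
        )
    corr = sub.corr()  # pandas leaves NaN where an SD is 0
    np.fill_diagonal(corr.to_numpy(), 1.0)
    for name in flat.index:  # undefined even against itself
        corr.loc[name, name] = np.nan
    return corr


def stack_and_reduce(
    matrices: list[pd.DataFrame], region: str = ""
) -> SpatialCorrelationArray:
    """Stack per-sample c x c matrices into (n, c, c) and mean-reduce."""
    if not matrices:
        raise ValueError("no matrices to stack")
    names = list(matrices[0].columns)
    for m in matrices[1:]:
        if list(m.columns) != names or list(m.index) != names:
            raise ValueError("matrices must share signature order")
    stack = np.stack([m.to_numpy(dtype=float) for m in matrices])
    reduced = pd.DataFrame(stack.mean(axis=0), index=names, columns=names)
    return SpatialCorrelationArray(
        signatures=names, stack=stack, reduced=reduced, region=region
    )
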