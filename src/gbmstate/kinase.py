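"""Kinase-activity z-scores from site-level phospho fold-changes (KSEA).

For each kinase with at least min_substrates detected substrate sites,

    z = (ms - mbar) * sqrt(m) / delta

where ms is the mean substrate log2FC, mbar and delta the mean and SD of
all detected site log2FCs, and m the substrate count. Two-sided normal
p-values; significance at p <= 0.01 with a 5-substrate floor by default.
z is invariant to shifting or positively rescaling all fold-changes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import norm

from .datatypes import KinaseActivityResult


def ksea_zscores(
    table: pd.DataFrame,
    ksmap: dict[str, list[str]],
    min_substrates: int = 5,
    p_threshold: float = 0.01,
) -> tuple[list[KinaseActivityResult], pd.DataFrame]:
    """Kinase activity z-scores against the background of all detected sites.

    *table* needs columns site and log2fc; sites with non-finite log2fc are
    excluded before the background statistics are formed. Substrates
    annotated to several kinases count for each. Kinases with fewer than
    min_substrates detected sites are excluded and listed, with reason, in
    the returned exclusion table.

    Returns (results sorted by |z| descending, exclusions frame).
    """
    if table.empty:
        raise ValueError("empty phospho table")
    if not ksmap:
        raise ValueError("empty kinase-substrate map")
    if table["site"].duplicated().any():
        raise ValueError("duplicate site ids in phospho table")
    finite = table[np.isfinite(table["log2fc"])]
    lfc = finite.set_index("site")["log2fc"]
    mbar = float(lfc.mean())
    delta = float(lfc.std(ddof=1))
    if not np.isfinite(delta) or delta == 0:
        raise ValueError("degenerate background: SD of site log2FCs is zero")
    results, excluded = [], []
    for kinase, sites in ksmap.items():
        detected = [s for s in sites if s in lfc.index]
        m = len(detected)
        if m < min_substrates:
            excluded.append(
                {"kinase": kinase, "n_detected": m, "reason": f"fewer than {min_substrates} detected substrates"}
            )
            continue
        ms = float(lfc.loc[detected].mean())
        z = (ms - mbar) * np.sqrt(m) / delta
        p = float(2 * norm.sf(abs(z)))
        results.append(
            KinaseActivityResult(
                kinase=kinase, z=float(z), m=m, p=p, significant=p <= p_threshold
            )
        )
    results.sort(key=lambda r: (-abs(r.z), r.kinase))
    exclusions = pd.DataFrame(excluded, columns=["kinase", "n_detected", "reason"])
    return results, exclusions


def results_frame(results: list[KinaseActivityResult]) -> pd.DataFrame:
    """Results as the exported CSV layout: kinase, z, m, p, significant."""
    return pd.DataFrame(
        [
            {"kinase": r.kinase, "z": r.z, "m": r.m, "p": r.p, "significant": r.significant}
            for r in results
        ]
    )
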