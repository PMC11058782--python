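"""Therapy-induced signature derivation and pre-ranked enrichment.

Covers the derivation chain used for the resistant-state signatures:
rank-sum cluster markers filtered on log fold-change and expressing
fraction, top-n signature selection (150 genes), cross-line intersection
(genes shared by >= 3 of the input sets), a pre-ranked permutation
enrichment (weighted Kolmogorov-Smirnov running sum, gene-set
permutations, sign-matched NES, BH q), the q < 0.25 paired-enrichment
call, and the proteomic per-state mean-log2-ratio trajectories.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import false_discovery_control, mannwhitneyu

from .datatypes import EnrichmentResult, ExpressionMatrix, PairedEnrichmentCall

CALL_UP = "enriched_up"
CALL_DOWN = "enriched_down"
CALL_NO_CHANGE = "no_change"


def derive_cluster_markers(
    m: ExpressionMatrix,
    labels: pd.Series,
    min_lfc: float = 0.5,
    min_pct: float = 0.75,
) -> pd.DataFrame:
    """Per-cluster upregulated markers: rank-sum test of cluster vs rest.

    For each cluster, every gene is tested (two-sided Mann-Whitney) against
    all other cells; genes with log2 fold-change >= min_lfc (difference of
    mean log2 expression) and in-group expressing fraction >= min_pct are
    retained, BH-adjusted within the cluster, and sorted by adjusted p then
    |lfc| descending.

    Returns a frame with columns cluster, gene, lfc, pct_in, pct_out,
    p, p_adj.
    """
    if m.layer != "lognorm":
        raise ValueError(f"derive_cluster_markers needs the lognorm layer, got {m.layer!r}")
    labels = labels.reindex(m.cell_ids)
    if labels.isna().any():
        raise ValueError("labels missing for some cells")
    counts = labels.value_counts()
    if len(counts) < 2:
        raise ValueError("need at least 2 clusters")
    small = counts[counts < 3]
    if len(small):
        raise ValueError(f"clusters with fewer than 3 cells: {list(small.index)}")
    vals = m.values.to_numpy()
    frames = []
    for cluster in counts.index:
        in_mask = (labels == cluster).to_numpy()
        x_in, x_out = vals[:, in_mask], vals[:, ~in_mask]
        lfc = x_in.mean(axis=1) - x_out.mean(axis=1)
        pct_in = (x_in > 0).mean(axis=1)
        pct_out = (x_out > 0).mean(axis=1)
        keep = (lfc >= min_lfc) & (pct_in >= min_pct)
        if not keep.any():
            continue
        _, p = mannwhitneyu(x_in[keep], x_out[keep], axis=1, alternative="two-sided")
        p_adj = false_discovery_control(p)
        sub = pd.DataFrame(
            {
                "cluster": cluster,
                "gene": m.gene_ids[keep],
                "lfc": lfc[keep],
                "pct_in": pct_in[keep],
                "pct_out": pct_out[keep],
                "p": p,
                "p_adj": p_adj,
            }
        )
        sub["_abs_lfc"] = sub["lfc"].abs()
        sub = sub.sort_values(
            ["p_adj", "_abs_lfc", "gene"], ascending=[True, False, True], kind="mergesort"
        ).drop(columns="_abs_lfc")
        frames.append(sub)
    if not frames:
        return pd.DataFrame(
            columns=["cluster", "gene", "lfc", "pct_in", "pct_out", "p", "p_adj"]
        )
    return pd.concat(frames, ignore_index=True)


def select_top_signature(
    markers: pd.DataFrame, n: int = 150, cluster: str | None = None
) -> list[str]:
    """First n genes of a (cluster's) marker table, in its significance order."""
    t = markers if cluster is None else markers[markers["cluster"] == cluster]
    if t.empty:
        raise ValueError("no markers to select from")
    if len(t) < n:
        warnings.warn(f"only {len(t)} markers available, requested {n}", stacklevel=2)
    return t["gene"].head(n).tolist()


def common_upregulated(
    sets: dict[str, list[str]], min_membership: int = 3
) -> tuple[list[str], pd.Series]:
    """Genes present in at least min_membership of the input sets.

    Returns the gene list (sorted by membership count desc, then id) and
    the per-gene membership counts over all genes seen.
    """
    if len(sets) < 2:
        raise ValueError("need at least 2 sets")
    counts: dict[str, int] = {}
    for genes in sets.values():
        for g in set(genes):
            counts[g] = counts.get(g, 0) + 1
    count_s = pd.Series(counts, name="n_sets").sort_index()
    hits = count_s[count_s >= min_membership]
    ordered = hits.sort_values(ascending=False, kind="mergesort")
    return ordered.index.tolist(), count_s


def enrichment_score(
    stats_sorted: np.ndarray, hit_idx: np.ndarray, weight_exp: float = 1.0
) -> float:
    """Signed extreme deviation of the weighted KS running sum.

    *stats_sorted* is the ranking statistic sorted descending; *hit_idx*
    the positions of the set's genes in that order. Hits increment the
    running sum by |stat|^weight_exp (normalized to 1 over hits); misses
    decrement by 1/(N - Nh). ES is the deviation of largest magnitude
    (positive on a magnitude tie).
    """
    n = len(stats_sorted)
    hit_idx = np.sort(np.asarray(hit_idx))
    nh = len(hit_idx)
    if nh == 0 or nh >= n:
        raise ValueError("hit set must be a nonempty proper subset of the ranking")
    w = np.abs(stats_sorted[hit_idx]) ** weight_exp
    wsum = w.sum()
    if wsum == 0:
        raise ValueError("all hit statistics are zero under this weight")
    hit_cum = np.cumsum(w) / wsum
    miss_before = (hit_idx - np.arange(nh)) / (n - nh)
    peaks = hit_cum - miss_before  # running sum just after each hit
    valleys = np.concatenate(([0.0], hit_cum[:-1])) - miss_before  # just before
    es_pos = peaks.max()
    es_neg = min(valleys.min(), 0.0)
    # magnitude ties resolve to the positive extreme; the tolerance keeps the
    # rule stable when exact rational ties land 1 ulp apart in float
    return float(es_pos) if es_pos >= -es_neg - 1e-9 else float(es_neg)


def _perm_es(
    stats_sorted: np.ndarray,
    nh: int,
    n_perm: int,
    weight_exp: float,
    rng: np.random.Generator,
) -> np.ndarray:
    n = len(stats_sorted)
    out = np.empty(n_perm)
    for i in range(n_perm):
        idx = rng.choice(n, size=nh, replace=False)
        out[i] = enrichment_score(stats_sorted, idx, weight_exp)
    return out


def preranked_enrichment(
    ranking: pd.Series,
    genes: list[str],
    n_perm: int = 1000,
    weight_exp: float = 1.0,
    seed: int = 0,
    set_name: str = "set",
) -> EnrichmentResult:
    """Pre-ranked permutation enrichment of one gene set.

    The null is n_perm random same-size gene sets on the same ranking;
    NES = ES / mean(|null ES| of matching sign); p is the same-sign
    empirical tail. q defaults to p for a single set — use
    :func:`preranked_enrichment_batch` for BH across a batch.
    """
    if ranking.index.has_duplicates:
        raise ValueError("duplicate genes in ranking")
    stats = ranking.to_numpy(dtype=float)
    if np.all(stats == 0):
        raise ValueError("all-zero ranking statistics")
    order = np.argsort(-stats, kind="mergesort")
    stats_sorted = stats[order]
    pos = {g: i for i, g in enumerate(ranking.index[order])}
    hit_idx = np.array([pos[g] for g in genes if g in pos])
    if len(hit_idx) < 3:
        raise ValueError(f"set overlaps ranking in only {len(hit_idx)} genes (need >= 3)")
    es = enrichment_score(stats_sorted, hit_idx, weight_exp)
    rng = np.random.default_rng(seed)
    null = _perm_es(stats_sorted, len(hit_idx), n_perm, weight_exp, rng)
    same_sign = null > 0 if es >= 0 else null < 0
    m = int(same_sign.sum())
    if m:
        nes = es / np.abs(null[same_sign]).mean()
        p = float((np.abs(null[same_sign]) >= abs(es)).sum() / m)
    else:  # pathological null all on one side
        nes = es / np.abs(null).mean()
        p = 0.0
    return EnrichmentResult(
        set_name=set_name,
        es=float(es),
        nes=float(nes),
        p=p,
        q=p,
        n_perm=n_perm,
        seed=seed,
        n_hits=len(hit_idx),
    )


def preranked_enrichment_batch(
    ranking: pd.Series,
    catalog,
    n_perm: int = 1000,
    weight_exp: float = 1.0,
    seed: int = 0,
) -> list[EnrichmentResult]:
    """Enrichment of every set in a catalog, with BH q-values over the batch."""
    rng = np.random.default_rng(seed)
    results = [
        preranked_enrichment(
            ranking,
            genes,
            n_perm=n_perm,
            weight_exp=weight_exp,
            seed=int(rng.integers(2**31 - 1)),
            set_name=name,
        )
        for name, genes in catalog.items()
    ]
    if results:
        qs = false_discovery_control([r.p for r in results])
        for r, q in zip(results, qs):
            r.q = float(q)
    return results


def bulk_ranking(
    counts: pd.DataFrame, group_a: list[str], group_b: list[str], pseudocount: float = 1.0
) -> pd.Series:
    """Ranking statistic for a bulk contrast: log2 fold-change of
    median-of-ratios-scaled mean counts, group_a over group_b."""
    from .preprocess import median_of_ratios

    factors = median_of_ratios(counts)
    scaled = counts / factors
    mean_a = scaled[group_a].mean(axis=1)
    mean_b = scaled[group_b].mean(axis=1)
    return np.log2(mean_a + pseudocount) - np.log2(mean_b + pseudocount)


def classify_paired_enrichment(
    result: EnrichmentResult, patient: str = "", q_threshold: float = 0.25
) -> PairedEnrichmentCall:
    """Call a paired profile enriched_up / enriched_down / no_change.

    q >= q_threshold (boundary inclusive) is no_change; otherwise the sign
    of NES decides the direction.
    """
    if result.q >= q_threshold:
        call = CALL_NO_CHANGE
    else:
        call = CALL_UP if result.nes > 0 else CALL_DOWN
    return PairedEnrichmentCall(
        patient=patient or result.set_name, call=call, nes=result.nes, q=result.q
    )


def proteomic_state_scores(
    ratios: pd.DataFrame, marker_sets: dict[str, list[str]]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-state, per-timepoint mean log2 ratio of detected markers.

    *ratios* is genes/proteins x timepoints of log2 ratios; infinite values
    are excluded from each mean. Returns (scores, n_used), both
    states x timepoints.
    """
    vals = ratios.replace([np.inf, -np.inf], np.nan)
    scores, n_used = {}, {}
    for state, genes in marker_sets.items():
        present = [g for g in genes if g in vals.index]
        sub = vals.loc[present]
        scores[state] = sub.mean(axis=0, skipna=True)
        n_used[state] = sub.notna().sum(axis=0)
    return pd.DataFrame(scores).T, pd.DataFrame(n_used).T
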