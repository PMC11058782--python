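"""Bin-matched meta-module scoring, state classification, and the 2-D state map.

A cell's score for a gene set G is the difference between its average
relative expression over G and over a control gene multiset drawn, for
each gene of G, from the same aggregate-expression bin (30 quantile bins
by default, 100 control genes per set gene). The cell is assigned the
state with the highest score among the four meta-modules (NPC-, OPC-,
AC-, MES-like), and projected onto the butterfly map:

    y = max(SC_opc, SC_npc) - max(SC_ac, SC_mes)
    x = log2(|SC_opc - SC_npc| + 1)   if y > 0 (OPC/NPC half)
    x = log2(|SC_ac  - SC_mes| + 1)   otherwise (AC/MES half)
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .datatypes import STATES, ExpressionMatrix

FAMILY_OPC_NPC = "OPC/NPC"
FAMILY_AC_MES = "AC/MES"


def bin_by_aggregate_expression(m: ExpressionMatrix, n_bins: int = 30) -> pd.Series:
    """Quantile-bin genes by mean expression across cells.

    Genes are ranked by their mean expression (ties broken by gene id
    order) and partitioned into *n_bins* near-equal bins, numbered 1
    (lowest expression) to n_bins. Bin sizes differ by at most one.

    Returns a Series gene_id -> bin index.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if m.n_genes < n_bins:
        raise ValueError(f"{m.n_genes} genes cannot fill {n_bins} bins")
    means = m.values.mean(axis=1)
    order = pd.DataFrame({"mean": means, "gene": means.index}).sort_values(
        ["mean", "gene"], kind="mergesort"
    )
    n = len(order)
    ranks = np.arange(n)
    bins = (ranks * n_bins) // n + 1
    return pd.Series(bins, index=order["gene"], name="bin").reindex(m.gene_ids)


def sample_control_set(
    genes: list[str],
    bins: pd.Series,
    k: int = 100,
    seed: int | np.random.Generator = 0,
) -> list[str]:
    """For each set gene, draw k control genes uniformly from its expression bin.

    Draws are without replacement within a bin when the bin holds at least
    k genes, with replacement otherwise, so the control multiset always has
    exactly k * len(genes) members.
    """
    rng = np.random.default_rng(seed)
    missing = [g for g in genes if g not in bins.index or pd.isna(bins.get(g))]
    if missing:
        raise KeyError(f"set genes absent from bin assignment: {missing}")
    by_bin = {b: idx.to_numpy() for b, idx in bins.groupby(bins).groups.items()}
    control: list[str] = []
    for g in genes:
        pool = by_bin[bins[g]]
        replace = len(pool) < k
        control.extend(rng.choice(pool, size=k, replace=replace))
    return control


def score_metamodule(
    m: ExpressionMatrix,
    genes: list[str],
    control: list[str],
    min_present: float = 0.5,
) -> pd.Series:
    """Per-cell score: mean relative expression over the set minus over its control.

    Set genes absent from the matrix are dropped with a warning; fewer than
    *min_present* of the set present is an error. Control genes always come
    from the matrix (they are sampled from its bins).
    """
    if m.layer != "relative":
        raise ValueError(f"score_metamodule needs the relative layer, got {m.layer!r}")
    present = [g for g in genes if g in m.gene_ids]
    if len(present) < max(1, int(np.ceil(min_present * len(genes)))):
        raise ValueError(
            f"only {len(present)}/{len(genes)} set genes present in matrix "
            f"(floor {min_present:.0%})"
        )
    if len(present) < len(genes):
        warnings.warn(
            f"dropped {len(genes) - len(present)} set genes absent from matrix",
            stacklevel=2,
        )
    set_mean = m.values.loc[present].mean(axis=0)
    ctrl_mean = m.values.loc[control].mean(axis=0)  # multiset: repeated rows count
    return (set_mean - ctrl_mean).rename("score")


def score_signature(
    m: ExpressionMatrix,
    genes: list[str],
    bins: pd.Series,
    k: int = 100,
    seed: int | np.random.Generator = 0,
) -> pd.Series:
    """Bin-matched control score for an arbitrary signature (composition of
    :func:`sample_control_set` and :func:`score_metamodule`)."""
    present = [g for g in genes if g in m.gene_ids]
    if not present:
        raise ValueError("signature has no overlap with the matrix")
    control = sample_control_set(present, bins, k=k, seed=seed)
    return score_metamodule(m, genes, control)


def score_states(
    m: ExpressionMatrix,
    catalog,
    bins: pd.Series | None = None,
    k: int = 100,
    seed: int = 0,
    lognorm: ExpressionMatrix | None = None,
) -> pd.DataFrame:
    """Score the four state meta-modules; returns a cells x states frame.

    *catalog* must contain a set per state name in STATES. Bins default to
    quantile bins on the lognorm source (or on the relative layer when no
    source is given — monotone-equivalent ranks up to centering).
    """
    if bins is None:
        bins = bin_by_aggregate_expression(lognorm if lognorm is not None else m)
    rng = np.random.default_rng(seed)
    cols = {}
    for state in STATES:
        if state not in catalog:
            raise KeyError(f"catalog lacks the {state} meta-module")
        cols[state] = score_signature(m, catalog[state], bins, k=k, seed=rng)
    return pd.DataFrame(cols, index=m.cell_ids)


def classify_states(scores: pd.DataFrame) -> pd.DataFrame:
    """Assign each cell the state with the highest score.

    Exact ties are broken by the fixed priority NPC > OPC > AC > MES and
    flagged. Returns a frame with columns ``state`` and ``tie``.
    """
    missing = [s for s in STATES if s not in scores.columns]
    if missing:
        raise KeyError(f"score table missing state columns: {missing}")
    vals = scores[list(STATES)].to_numpy()
    if not np.isfinite(vals).all():
        raise ValueError("non-finite scores")
    best = vals.max(axis=1)
    is_max = vals == best[:, None]
    # first True along the priority-ordered columns wins
    idx = is_max.argmax(axis=1)
    tie = is_max.sum(axis=1) > 1
    return pd.DataFrame(
        {"state": np.array(STATES)[idx], "tie": tie}, index=scores.index
    )


def butterfly_coordinates(scores: pd.DataFrame) -> pd.DataFrame:
    """Project four state scores onto the 2-D butterfly map.

    y separates the OPC/NPC family (y > 0) from AC/MES; x is the log2
    within-family score difference, reported unsigned within each
    half-plane. y == 0 falls to the AC/MES family and is flagged.

    Returns columns x, y, family, assigned_state, tie, boundary.
    """
    missing = [s for s in STATES if s not in scores.columns]
    if missing:
        raise KeyError(f"score table missing state columns: {missing}")
    vals = scores[list(STATES)]
    if not np.isfinite(vals.to_numpy()).all():
        raise ValueError("non-finite scores")
    npc, opc, ac, mes = (vals[s].to_numpy() for s in STATES)
    y = np.maximum(opc, npc) - np.maximum(ac, mes)
    upper = y > 0
    x = np.where(
        upper,
        np.log2(np.abs(opc - npc) + 1.0),
        np.log2(np.abs(ac - mes) + 1.0),
    )
    family = np.where(upper, FAMILY_OPC_NPC, FAMILY_AC_MES)
    assigned = classify_states(scores)
    return pd.DataFrame(
        {
            "x": x,
            "y": y,
            "family": family,
            "assigned_state": assigned["state"],
            "tie": assigned["tie"],
            "boundary": y == 0,
        },
        index=scores.index,
    )


def state_table(
    scores: pd.DataFrame, extra_scores: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Assemble the exported per-cell table: SC_* columns, state, tie, x, y, family."""
    coords = butterfly_coordinates(scores)
    out = pd.DataFrame(index=scores.index)
    out.index.name = "cell_id"
    for state in STATES:
        out[f"SC_{state.lower()}"] = scores[state]
    if extra_scores is not None:
        for col in extra_scores.columns:
            out[col] = extra_scores[col]
    out["state"] = coords["assigned_state"]
    out["tie_flag"] = coords["tie"]
    out["x"] = coords["x"]
    out["y"] = coords["y"]
    out["family"] = coords["family"]
    return out


def butterfly_plot(coords: pd.DataFrame, ax=None, color_by: pd.Series | None = None):
    """Basic state-map scatter: x mirrored by family, colored by state or a score."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    x = np.where(coords["family"] == FAMILY_OPC_NPC, -coords["x"], coords["x"])
    if color_by is None:
        for state, grp in coords.groupby("assigned_state"):
            xs = np.where(grp["family"] == FAMILY_OPC_NPC, -grp["x"], grp["x"])
            ax.scatter(xs, grp["y"], s=4, label=str(state))
        ax.legend(markerscale=3, frameon=False)
    else:
        sc = ax.scatter(x, coords["y"], s=4, c=color_by, cmap="viridis")
        plt.colorbar(sc, ax=ax)
    ax.axhline(0, lw=0.5, color="grey")
    ax.axvline(0, lw=0.5, color="grey")
    ax.set_xlabel("within-family log2 score difference")
    ax.set_ylabel("max(SC_opc, SC_npc) - max(SC_ac, SC_mes)")
    return ax
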