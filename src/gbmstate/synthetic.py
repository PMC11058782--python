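"""Synthetic-data generators with planted ground truth.

Every input the pipeline consumes can be generated here with known truth:
negative-binomial single-cell counts carrying four transcriptional states
plus a hybrid/intermediate state, treatment-induced reprogramming toward
the hybrid state, Gaussian-random-field score surfaces with a target
cross-correlation, site-level phospho log2 fold-changes with planted
kinase activity, exponential dye dilution with lognormal noise, and 2-D
vessel scenes with a controllable vessel-association bias.

All randomness in a call flows from one seeded generator; identical
(config, seed) pairs give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import scipy.ndimage

from .datatypes import (
    HYBRID,
    STATES,
    ExpressionMatrix,
    GeneSetCatalog,
    SpatialSample,
    SyntheticTruth,
    VesselScene,
)
from .quantify import min_distance_to_segments

ALL_STATES = (*STATES, HYBRID)


@dataclass
class SimulationConfig:
    """Parameters of the single-cell count generator.

    Defaults emulate a gliomasphere line profiled at moderate depth: a
    near-balanced mixture of the four states with a small basal hybrid
    fraction, 30 markers per state shifted by one log2 unit, and library
    sizes centered inside the 4000-11000 UMI QC window.
    """

    n_cells: int = 3000
    n_genes: int = 2000
    state_proportions: dict[str, float] = field(
        default_factory=lambda: {
            "NPC": 0.225,
            "OPC": 0.225,
            "AC": 0.225,
            "MES": 0.225,
            "HYBRID": 0.10,
        }
    )
    markers_per_state: int = 30
    marker_effect: float = 1.0  # log2-units mean shift in the marker's state
    nb_dispersion: float = 2.0  # shared NB size parameter (smaller = noisier)
    reprogram_fraction: float = 0.0
    seed: int = 0
    n_mito_genes: int = 10
    mito_count_fraction: float = 0.05
    mean_total_umi: float = 7000.0
    library_size_cv: float = 0.12  # lognormal sigma of per-cell size factors

    def validate(self) -> None:
        props = self.state_proportions
        if set(props) != set(ALL_STATES):
            raise ValueError(f"state_proportions must cover {ALL_STATES}")
        if abs(sum(props.values()) - 1.0) > 1e-9:
            raise ValueError("state_proportions must sum to 1")
        if any(p < 0 for p in props.values()):
            raise ValueError("negative state proportion")
        n_marked = self.markers_per_state * len(STATES)
        if n_marked + self.n_mito_genes > self.n_genes:
            raise ValueError(
                f"n_genes={self.n_genes} too small for {n_marked} markers "
                f"+ {self.n_mito_genes} mito genes"
            )
        if not 0.0 <= self.reprogram_fraction <= 1.0:
            raise ValueError("reprogram_fraction must be in [0, 1]")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")


def _gene_ids(config: SimulationConfig) -> pd.Index:
    n_reg = config.n_genes - config.n_mito_genes
    width = len(str(config.n_genes))
    ids = [f"G{i + 1:0{width}d}" for i in range(n_reg)]
    ids += [f"MT-{i + 1}" for i in range(config.n_mito_genes)]
    return pd.Index(ids, name="gene_id")


def _base_means(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Per-gene baseline mean counts, lognormally spread, scaled so totals
    average mean_total_umi with mito genes at their configured share."""
    lam = rng.lognormal(mean=0.0, sigma=1.0, size=config.n_genes)
    n_reg = config.n_genes - config.n_mito_genes
    reg, mito = lam[:n_reg], lam[n_reg:]
    reg *= config.mean_total_umi * (1 - config.mito_count_fraction) / reg.sum()
    if config.n_mito_genes:
        mito *= config.mean_total_umi * config.mito_count_fraction / mito.sum()
    return np.concatenate([reg, mito])


def _pick_markers(
    config: SimulationConfig, base_means: np.ndarray, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Choose markers_per_state genes per state among well-detected
    (above-median baseline) non-mito genes — state markers in real data are
    reliably captured genes, not dropout-dominated ones."""
    n_reg = config.n_genes - config.n_mito_genes
    reg_means = base_means[:n_reg]
    eligible = np.flatnonzero(reg_means >= np.median(reg_means))
    need = config.markers_per_state * len(STATES)
    if len(eligible) < need:
        eligible = np.arange(n_reg)
    chosen = rng.choice(eligible, size=need, replace=False)
    return {
        state: np.sort(chosen[i * config.markers_per_state : (i + 1) * config.markers_per_state])
        for i, state in enumerate(STATES)
    }


def _state_effect_matrix(
    config: SimulationConfig,
    markers: dict[str, np.ndarray],
    states: np.ndarray,
) -> np.ndarray:
    """log2 mean-shift matrix (genes x cells): marker genes get marker_effect
    in their own state; hybrid cells get half-effect on AC and MES markers."""
    shift = np.zeros((config.n_genes, len(states)))
    for state, gene_idx in markers.items():
        in_state = states == state
        shift[np.ix_(gene_idx, in_state)] += config.marker_effect
    hybrid = states == HYBRID
    if hybrid.any():
        for state in ("AC", "MES"):
            shift[np.ix_(markers[state], hybrid)] += config.marker_effect / 2.0
    return shift


def _draw_counts(
    mu: np.ndarray, dispersion: float, rng: np.random.Generator
) -> np.ndarray:
    """Negative-binomial draws with mean mu and shared size (dispersion)."""
    p = dispersion / (dispersion + mu)
    return rng.negative_binomial(dispersion, p)


def _generate(
    config: SimulationConfig, final_states: np.ndarray | None = None, rng=None
):
    """Shared core: gene params, labels, then counts, in a fixed draw order."""
    config.validate()
    rng = np.random.default_rng(config.seed) if rng is None else rng
    gene_ids = _gene_ids(config)
    base = _base_means(config, rng)
    markers = _pick_markers(config, base, rng)
    props = np.array([config.state_proportions[s] for s in ALL_STATES])
    states = rng.choice(ALL_STATES, size=config.n_cells, p=props / props.sum())
    if final_states is not None:
        states = final_states(states)  # callable: original -> final labels
    size_factors = rng.lognormal(mean=0.0, sigma=config.library_size_cv, size=config.n_cells)
    shift = _state_effect_matrix(config, markers, states)
    mu = base[:, None] * size_factors[None, :] * np.exp2(shift)
    counts = _draw_counts(mu, config.nb_dispersion, rng)
    cell_ids = pd.Index([f"cell{i + 1:05d}" for i in range(config.n_cells)], name="cell_id")
    values = pd.DataFrame(counts, index=gene_ids, columns=cell_ids)
    matrix = ExpressionMatrix.from_counts(values)
    catalog = GeneSetCatalog(
        {state: list(gene_ids[idx]) for state, idx in markers.items()}
    )
    return matrix, catalog, states, cell_ids, markers


def gen_state_counts(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, pd.DataFrame, GeneSetCatalog, SyntheticTruth]:
    """Generate a naive (untreated) single-cell count matrix.

    Returns the counts matrix, a cell metadata table (cell_id, state,
    reprogrammed), the catalog of the four planted marker sets, and the
    full ground truth.
    """
    matrix, catalog, states, cell_ids, markers = _generate(config)
    meta = pd.DataFrame(
        {"cell_id": cell_ids, "state": states, "reprogrammed": False}
    )
    marker_of = pd.Series(
        {g: s for s, idx in markers.items() for g in matrix.gene_ids[idx]},
        name="marker_of",
    )
    truth = SyntheticTruth(
        cell_states=pd.Series(states, index=cell_ids, name="state"),
        reprogrammed=pd.Series(False, index=cell_ids, name="reprogrammed"),
        original_states=pd.Series(states, index=cell_ids, name="original_state"),
        gene_marker_of=marker_of,
        params={**asdict(config)},
    )
    return matrix, meta, catalog, truth


def gen_treated_counts(
    base: SimulationConfig, reprogram_fraction: float, seed: int
) -> tuple[ExpressionMatrix, pd.DataFrame, SyntheticTruth]:
    """Generate a treated sample: a fraction of non-hybrid cells is
    reprogrammed to the hybrid state before counts are drawn.

    With reprogram_fraction = 0 the output is bit-identical to
    :func:`gen_state_counts` under the same base config.
    """
    if not 0.0 <= reprogram_fraction <= 1.0:
        raise ValueError("reprogram_fraction must be in [0, 1]")
    base.validate()
    reprogram_rng = np.random.default_rng(seed)
    captured: dict[str, np.ndarray] = {}

    def reprogram(original: np.ndarray) -> np.ndarray:
        captured["original"] = original.copy()
        final = original.copy()
        candidates = np.flatnonzero(original != HYBRID)
        n_flip = int(round(reprogram_fraction * len(candidates)))
        if n_flip:
            flip = reprogram_rng.choice(candidates, size=n_flip, replace=False)
            final[flip] = HYBRID
        captured["final"] = final
        return final

    matrix, _, states, cell_ids, markers = _generate(base, final_states=reprogram)
    original = captured["original"]
    reprogrammed = (original != HYBRID) & (states == HYBRID)
    meta = pd.DataFrame(
        {"cell_id": cell_ids, "state": states, "reprogrammed": reprogrammed}
    )
    marker_of = pd.Series(
        {g: s for s, idx in markers.items() for g in matrix.gene_ids[idx]},
        name="marker_of",
    )
    truth = SyntheticTruth(
        cell_states=pd.Series(states, index=cell_ids, name="state"),
        reprogrammed=pd.Series(reprogrammed, index=cell_ids, name="reprogrammed"),
        original_states=pd.Series(original, index=cell_ids, name="original_state"),
        gene_marker_of=marker_of,
        params={**asdict(base), "reprogram_fraction": reprogram_fraction, "reprogram_seed": seed},
    )
    return matrix, meta, truth


def gen_spatial_sample(
    grid: tuple[int, int],
    colocalization: float,
    region_map: np.ndarray | None = None,
    noise_sd: float = 0.1,
    seed: int = 0,
    field_sigma: float = 2.0,
    names: tuple[str, str] = ("sig_a", "sig_b"),
) -> tuple[SpatialSample, SyntheticTruth]:
    """Two signature score surfaces on a grid with a planted cross-correlation.

    Each surface is kernel-smoothed white noise (a Gaussian random field);
    the second is built from a component empirically orthogonal to the
    first, so the noise-free surfaces carry exactly the target correlation.
    Spots left of the column midline are labeled infiltrative_cortex, the
    rest cellular_tumor, unless a region_map of labels is given.
    """
    rows, cols = grid
    if rows < 2 or cols < 2:
        raise ValueError("grid must be at least 2x2")
    if not -1.0 <= colocalization <= 1.0:
        raise ValueError("|colocalization| must be <= 1")
    rng = np.random.default_rng(seed)

    def smooth_field() -> np.ndarray:
        f = scipy.ndimage.gaussian_filter(
            rng.standard_normal((rows, cols)), sigma=field_sigma, mode="wrap"
        )
        f -= f.mean()
        sd = f.std()
        return f / sd if sd > 0 else f

    z1 = smooth_field()
    z2 = smooth_field()

    if region_map is None:
        region_map = np.where(
            np.arange(cols)[None, :] < cols // 2, "infiltrative_cortex", "cellular_tumor"
        )
        region_map = np.broadcast_to(region_map, (rows, cols))
    region_map = np.asarray(region_map)
    if region_map.shape != (rows, cols):
        raise ValueError("region_map shape must match grid")

    # plant the target cross-correlation exactly within each segmented
    # region: downstream correlation is always region-restricted, so the
    # planted value must hold there, not just globally
    rho = colocalization
    s1 = np.empty_like(z1)
    s2 = np.empty_like(z1)
    for region in np.unique(region_map):
        mask = region_map == region
        a = z1[mask] - z1[mask].mean()
        a_sd = a.std()
        a = a / a_sd if a_sd > 0 else a
        b = z2[mask] - z2[mask].mean()
        denom = (a * a).sum()
        if denom > 0:
            b = b - (a * b).sum() / denom * a
        b_sd = b.std()
        b = b / b_sd if b_sd > 0 else b
        s1[mask] = a
        s2[mask] = rho * a + np.sqrt(max(0.0, 1 - rho**2)) * b
    s1 = s1 + noise_sd * rng.standard_normal((rows, cols))
    s2 = s2 + noise_sd * rng.standard_normal((rows, cols))

    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    spots = pd.DataFrame(
        {
            "spot_id": [f"spot_{r}_{c}" for r, c in zip(rr.ravel(), cc.ravel())],
            "row": rr.ravel(),
            "col": cc.ravel(),
            "region": region_map.ravel(),
        }
    )
    scores = pd.DataFrame(
        {names[0]: s1.ravel(), names[1]: s2.ravel()},
        index=pd.Index(spots["spot_id"], name="spot_id"),
    )
    truth = SyntheticTruth(
        colocalization=colocalization,
        params={
            "grid": list(grid),
            "colocalization": colocalization,
            "noise_sd": noise_sd,
            "field_sigma": field_sigma,
            "seed": seed,
        },
    )
    return SpatialSample(spots=spots, scores=scores), truth


def make_kinase_map(
    n_kinases: int = 20, substrates_per_kinase: int = 10, seed: int = 0
) -> dict[str, list[str]]:
    """A disjoint kinase -> substrate-site map with well-formed site ids."""
    rng = np.random.default_rng(seed)
    sites = rng.permutation(n_kinases * substrates_per_kinase)
    return {
        f"KIN{k + 1:02d}": [
            f"SUB{sites[k * substrates_per_kinase + j] + 1:04d}_S{10 + j}"
            for j in range(substrates_per_kinase)
        ]
        for k in range(n_kinases)
    }


def gen_phospho_table(
    ksmap: dict[str, list[str]],
    active: dict[str, float],
    n_sites: int = 1000,
    noise_sd: float = 0.5,
    seed: int = 0,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Site-level log2FC table with planted kinase activity.

    All mapped substrate sites plus unmapped background sites (up to
    n_sites total) get N(0, noise_sd^2) fold-changes; substrates of active
    kinases are shifted by their planted effect. Adjusted p-values are BH
    over two-sided normal tails at the background scale.
    """
    unknown = set(active) - set(ksmap)
    if unknown:
        raise KeyError(f"active kinases absent from map: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    mapped = sorted({s for sites in ksmap.values() for s in sites})
    n_bg = max(0, n_sites - len(mapped))
    sites = mapped + [f"BG{i + 1:05d}_S1" for i in range(n_bg)]
    lfc = rng.normal(0.0, noise_sd, size=len(sites))
    site_pos = {s: i for i, s in enumerate(sites)}
    for kinase, effect in active.items():
        for s in ksmap[kinase]:
            lfc[site_pos[s]] += effect
    from scipy.stats import false_discovery_control, norm

    if noise_sd > 0:
        p = 2 * norm.sf(np.abs(lfc), scale=noise_sd)
        p_adj = false_discovery_control(p)
    else:
        p_adj = np.where(lfc == 0, 1.0, 0.0)
    table = pd.DataFrame({"site": sites, "log2fc": lfc, "p_adj": p_adj})
    truth = SyntheticTruth(
        active_kinases=dict(active),
        params={"n_sites": n_sites, "noise_sd": noise_sd, "seed": seed},
    )
    return table, truth


def gen_dye_dilution(
    x_true,
    mfi0: float = 800.0,
    cv: float = 0.1,
    elapsed: float = 72.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Dye-dilution records: final MFI = mfi0 / 2^X with multiplicative
    lognormal(0, cv) noise. x_true may be a scalar or an array of records."""
    x = np.atleast_1d(np.asarray(x_true, dtype=float))
    if (x < 0).any():
        raise ValueError("division counts must be >= 0")
    rng = np.random.default_rng(seed)
    noise = np.exp(rng.normal(0.0, cv, size=len(x))) if cv > 0 else np.ones(len(x))
    final = mfi0 / np.exp2(x) * noise
    ids = pd.Index([f"rec{i + 1:03d}" for i in range(len(x))], name="record_id")
    records = pd.DataFrame(
        {"mfi_initial": mfi0, "mfi_final": final, "elapsed": elapsed}, index=ids
    ).reset_index()
    truth = SyntheticTruth(
        division_counts=pd.Series(x, index=ids, name="x_true"),
        params={"mfi0": mfi0, "cv": cv, "elapsed": elapsed, "seed": seed},
    )
    return records, truth


def default_vessel_segments(field: float = 100.0) -> dict[str, np.ndarray]:
    """Three straight vessel polylines spanning a square field."""
    return {
        "v1": np.array([[0.1 * field, 0.2 * field], [0.9 * field, 0.3 * field]]),
        "v2": np.array([[0.2 * field, 0.8 * field], [0.8 * field, 0.6 * field]]),
        "v3": np.array([[0.5 * field, 0.1 * field], [0.6 * field, 0.9 * field]]),
    }


def gen_vessel_scene(
    n_cells: int = 400,
    vessel_segments: dict[str, np.ndarray] | None = None,
    association_bias: dict[str, float] | None = None,
    contact_radius: float = 5.0,
    region_probs: dict[str, float] | None = None,
    field: float = 100.0,
    seed: int = 0,
) -> tuple[VesselScene, SyntheticTruth]:
    """Place NesHI/NesLO cells in a 2-D field with a planted vessel-association bias.

    A cell of class c is attached (placed within contact_radius of a vessel
    polyline) with probability association_bias[c]; unattached cells are
    rejection-sampled strictly farther than contact_radius from every
    segment, so the measured association fraction estimates the bias alone.
    """
    if n_cells < 1:
        raise ValueError("empty scene")
    segments = vessel_segments if vessel_segments is not None else default_vessel_segments(field)
    if not segments:
        raise ValueError("need at least one vessel segment")
    bias = association_bias or {"NesHI": 0.8, "NesLO": 0.3}
    regions = region_probs or {"invasive_front": 0.5, "core": 0.5}
    rng = np.random.default_rng(seed)
    classes = rng.choice(sorted(bias), size=n_cells)
    region_names = sorted(regions)
    region_p = np.array([regions[r] for r in region_names], dtype=float)
    cell_regions = rng.choice(region_names, size=n_cells, p=region_p / region_p.sum())
    attached = rng.random(n_cells) < np.array([bias[c] for c in classes])

    seg_list = [np.asarray(v, dtype=float) for v in segments.values()]
    xy = np.empty((n_cells, 2))
    for i in range(n_cells):
        if attached[i]:
            verts = seg_list[rng.integers(len(seg_list))]
            j = rng.integers(len(verts) - 1)
            t = rng.random()
            point = verts[j] * (1 - t) + verts[j + 1] * t
            angle = rng.random() * 2 * np.pi
            r = rng.random() * contact_radius * 0.95
            xy[i] = point + r * np.array([np.cos(angle), np.sin(angle)])
        else:
            while True:
                cand = rng.random(2) * field
                d = min_distance_to_segments(cand[None, :], seg_list)[0]
                if d > contact_radius * 1.05:
                    xy[i] = cand
                    break
    cell_ids = [f"c{i + 1:04d}" for i in range(n_cells)]
    cells = pd.DataFrame(
        {
            "cell_id": cell_ids,
            "x": xy[:, 0],
            "y": xy[:, 1],
            "cell_class": classes,
            "region": cell_regions,
        }
    )
    scene = VesselScene(cells=cells, segments=segments, contact_radius=contact_radius)
    truth = SyntheticTruth(
        vessel_attached=pd.Series(attached, index=pd.Index(cell_ids, name="cell_id")),
        params={
            "n_cells": n_cells,
            "association_bias": dict(bias),
            "contact_radius": contact_radius,
            "field": field,
            "seed": seed,
        },
    )
    return scene, truth
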