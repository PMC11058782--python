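"""Readers and writers for the plain-text formats the pipeline exchanges.

Sparse expression goes as MTX triplets (genes x cells, 1-based indices)
next to ``genes.tsv`` / ``barcodes.tsv``; gene sets as GMT; everything
tabular as CSV with documented headers.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .datatypes import ExpressionMatrix, GeneSetCatalog, SpatialSample, VesselScene


def write_mtx(m: ExpressionMatrix, outdir: str | Path) -> None:
    """Write matrix.mtx + genes.tsv + barcodes.tsv into *outdir*."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sparse = scipy.sparse.coo_matrix(m.values.to_numpy())
    scipy.io.mmwrite(str(outdir / "matrix.mtx"), sparse)
    m.gene_ids.to_series().to_csv(outdir / "genes.tsv", sep="\t", header=False, index=False)
    m.cell_ids.to_series().to_csv(outdir / "barcodes.tsv", sep="\t", header=False, index=False)


def read_mtx(indir: str | Path, layer: str = "counts", mito_prefix: str = "MT-") -> ExpressionMatrix:
    """Read an MTX triplet directory written by :func:`write_mtx` (or 10x-style)."""
    indir = Path(indir)
    mat = scipy.io.mmread(str(indir / "matrix.mtx"))
    genes = pd.read_csv(indir / "genes.tsv", sep="\t", header=None)[0].astype(str)
    barcodes = pd.read_csv(indir / "barcodes.tsv", sep="\t", header=None)[0].astype(str)
    dense = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat)
    df = pd.DataFrame(dense, index=pd.Index(genes, name="gene_id"), columns=pd.Index(barcodes, name="cell_id"))
    if layer == "counts":
        return ExpressionMatrix.from_counts(df, mito_prefix=mito_prefix)
    return ExpressionMatrix(values=df, layer=layer)


def write_dense_csv(m: ExpressionMatrix, path: str | Path) -> None:
    m.values.to_csv(path, index_label="gene_id")


def read_dense_csv(path: str | Path, layer: str = "counts", mito_prefix: str = "MT-") -> ExpressionMatrix:
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    if layer == "counts":
        return ExpressionMatrix.from_counts(df, mito_prefix=mito_prefix)
    return ExpressionMatrix(values=df, layer=layer)


def read_gmt(path: str | Path) -> GeneSetCatalog:
    """Read a GMT file: name <tab> description <tab> gene1 <tab> gene2 ..."""
    catalog = GeneSetCatalog()
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line (need name, description, >=1 gene): {line[:80]!r}")
        catalog.add(fields[0], fields[2:])
    return catalog


def write_gmt(catalog: GeneSetCatalog, path: str | Path, description: str = "na") -> None:
    lines = [
        "\t".join([name, description, *genes]) for name, genes in catalog.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def write_spatial_csv(sample: SpatialSample, path: str | Path) -> None:
    """Spot table CSV: spot_id, row, col, region, then one column per signature."""
    out = sample.spots.copy()
    if sample.scores is not None:
        out = out.merge(
            sample.scores.reset_index().rename(columns={"index": "spot_id"}),
            on="spot_id",
        )
    out.to_csv(path, index=False)


def read_spatial_csv(path: str | Path) -> SpatialSample:
    df = pd.read_csv(path)
    meta_cols = ["spot_id", "row", "col", "region"]
    score_cols = [c for c in df.columns if c not in meta_cols]
    scores = None
    if score_cols:
        scores = df.set_index("spot_id")[score_cols]
    return SpatialSample(spots=df[meta_cols], scores=scores)


def write_vessel_scene(scene: VesselScene, cells_path: str | Path, segments_path: str | Path) -> None:
    scene.cells.to_csv(cells_path, index=False)
    rows = []
    for sid, verts in scene.segments.items():
        for order, (x, y) in enumerate(np.asarray(verts, dtype=float)):
            rows.append({"segment_id": sid, "vertex_order": order, "x": x, "y": y})
    pd.DataFrame(rows).to_csv(segments_path, index=False)


def read_vessel_scene(cells_path: str | Path, segments_path: str | Path, contact_radius: float = 5.0) -> VesselScene:
    cells = pd.read_csv(cells_path)
    seg_df = pd.read_csv(segments_path)
    segments = {
        str(sid): grp.sort_values("vertex_order")[["x", "y"]].to_numpy(float)
        for sid, grp in seg_df.groupby("segment_id")
    }
    return VesselScene(cells=cells, segments=segments, contact_radius=contact_radius)


def read_ranking_tsv(path: str | Path) -> pd.Series:
    """Two-column TSV (gene, statistic) -> Series gene -> signed statistic."""
    df = pd.read_csv(path, sep="\t", header=None, names=["gene", "stat"])
    if df["gene"].duplicated().any():
        dupes = df.loc[df["gene"].duplicated(), "gene"].tolist()
        raise ValueError(f"duplicate genes in ranking: {dupes[:5]}")
    return df.set_index("gene")["stat"].astype(float)


def write_ranking_tsv(ranking: pd.Series, path: str | Path) -> None:
    ranking.to_csv(path, sep="\t", header=False)


def read_phospho_tsv(path: str | Path) -> pd.DataFrame:
    """Site-level table TSV with columns site, log2fc, p_adj."""
    df = pd.read_csv(path, sep="\t")
    missing = {"site", "log2fc"} - set(df.columns)
    if missing:
        raise ValueError(f"phospho table missing columns: {sorted(missing)}")
    if df["site"].duplicated().any():
        raise ValueError("duplicate site ids in phospho table")
    return df


def read_kinase_map_tsv(path: str | Path) -> dict[str, list[str]]:
    """Two-column TSV (kinase, site) -> kinase -> substrate site list."""
    df = pd.read_csv(path, sep="\t", header=None, names=["kinase", "site"])
    return {str(k): g["site"].astype(str).tolist() for k, g in df.groupby("kinase")}


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_jsonify) + "\n")


def _jsonify(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON-serializable: {type(x)}")
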