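# gbmstate

Glioblastoma (GBM) cells move between transcriptional states — neural-
progenitor-like (NPC), oligodendrocyte-progenitor-like (OPC), astrocyte-like
(AC) and mesenchymal-like (MES) — and therapy or the vascular niche can push
them into a resistant hybrid state intermediate between AC and MES. `gbmstate`
is a Python toolkit for the quantitative backbone of that kind of study:

- **Meta-module scoring and state maps.** Per-cell scores
  `SC_G(i) = mean(Er(G, i)) − mean(Er(G_ctrl, i))`, where `Er` is
  gene-centered log2 expression and `G_ctrl` draws, for every gene of the
  set `G`, 100 control genes from the same aggregate-expression bin
  (30 quantile bins). Cells take the state of their highest-scoring
  meta-module and are projected onto a 2-D "butterfly" map with
  `y = max(SC_opc, SC_npc) − max(SC_ac, SC_mes)` and
  `x = log2(|within-family score difference| + 1)`.
- **QC and normalization.** UMI-range (4000–11000) and mitochondrial-fraction
  (≤ 20%) filtering, library-size log2 normalization, gene centering, and
  median-of-ratios size factors for bulk counts.
- **Signature derivation and enrichment.** Rank-sum cluster markers filtered
  on log2FC ≥ 0.5 and expressing fraction ≥ 0.75, top-n signature selection,
  cross-line intersection (genes shared by ≥ 3 sets), and pre-ranked
  permutation enrichment (weighted Kolmogorov–Smirnov ES, gene-set
  permutation null, sign-matched NES, BH q) with the q < 0.25 rule for
  calling paired longitudinal profiles up / down / no-change.
- **Kinase activity (KSEA).** `z = (m_s − m̄)·√m / δ` per kinase from
  site-level phospho log2 fold-changes, with a 5-substrate floor and
  p ≤ 0.01 significance.
- **Spatially weighted correlation.** Gaussian-kernel smoothing of per-spot
  signature surfaces within segmented regions (infiltrative cortex vs
  cellular tumor), Pearson correlation per sample, stacked `(c, c, n)` and
  mean-reduced.
- **Functional-assay formulas.** Dye-dilution division number (`2^X = B`
  with `B = MFI_initial / MFI_final`), vascular-association fractions and
  vessel co-option percentages from 2-D cell/vessel scenes, Nestin-positive
  nuclei percentages, and time-lapse reprogramming rates.
- **Synthetic data with planted truth** for every one of those inputs:
  negative-binomial counts with four planted states plus a hybrid,
  treatment-induced reprogramming, Gaussian-random-field score surfaces with
  a target cross-correlation, phospho tables with planted kinase activity,
  noisy dye-dilution records, and vessel scenes with a planted association
  bias — so every analysis can be tested against known ground truth.

## Worked example

```python
import gbmstate as g

config = g.SimulationConfig(n_cells=3000, n_genes=2000,
                            markers_per_state=30, marker_effect=1.0, seed=1)
matrix, meta, catalog, truth = g.gen_state_counts(config)

kept = g.qc_filter(matrix)                       # UMI 4000-11000, mito <= 20%
lognorm = g.lognormalize(kept)
rel = g.relative_expression(lognorm)
scores = g.score_states(rel, catalog, lognorm=lognorm, seed=1)
states = g.classify_states(scores)

truth_states = truth.cell_states[kept.cell_ids]
mask = truth_states != "HYBRID"
acc = (states["state"][mask] == truth_states[mask]).mean()
print(f"{kept.n_cells} cells pass QC; 4-state recovery accuracy {acc:.3f}")
```

prints

```
3000 cells pass QC; 4-state recovery accuracy 0.994
```

i.e. all simulated libraries fall inside the QC window and bin-matched
scoring re-identifies 99.4% of the planted non-hybrid state labels. The same
stages are available from the shell:

```sh
gbmstate simulate --out sim --seed 1
gbmstate qc --input sim --out qc
gbmstate score --input qc --gmt sim/state_markers.gmt --out scores.csv
```

Every subcommand writes a `manifest.json` (parameters, seeds, version,
input checksums) so deterministic stages re-run bit-identically.

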