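# Methods

## Scope and model

`gbmstate` implements the computational core of a glioblastoma cell-state
analysis: per-cell meta-module scoring with expression-matched controls,
four-state classification and 2-D projection, therapy-induced signature
derivation and pre-ranked enrichment, kinase-substrate enrichment from
phosphoproteomes, spatially weighted signature correlation, and closed-form
functional-assay quantifications. A synthetic-data module generates every
input with planted ground truth, so the whole chain is testable end to end.

## Meta-module scoring

A cell i's score for gene set G is
`SC_G(i) = mean_{g in G} Er(g, i) − mean_{g in G_ctrl} Er(g, i)`, where
`Er` is the relative-expression layer: library-size log2-normalized values
(`log2(1 + count/total × 10000)`) centered per gene across cells. The
control multiset draws, for each gene of G, k = 100 genes from the gene's
aggregate-expression bin; genes are quantile-partitioned into 30 bins by
mean expression across cells, ties broken by gene id. The control draw is
without replacement within a bin when the bin holds at least k genes, with
replacement otherwise, so the multiset always has k·|G| members. Binning on
the mean (not summed) lognorm expression is a deliberate reading of
"aggregate expression": both give identical ranks up to the cell count
factor, and quantile bins guarantee every bin is samplable.

Classification is the argmax over the four state scores; exact ties resolve
by the fixed priority NPC > OPC > AC > MES and are flagged. The butterfly
projection uses `y = max(SC_opc, SC_npc) − max(SC_ac, SC_mes)`; cells with
y > 0 form the OPC/NPC half-plane with `x = log2(|SC_opc − SC_npc| + 1)`,
the rest the AC/MES half with the analogous x. x is reported unsigned
within each half-plane (the defining formulas only use absolute
differences); y = 0 falls to the AC/MES family and is flagged. Wherever the
score argmax is strict, the sign of y and the family of the argmax state
agree by construction.

The pipeline deliberately substitutes library-size log-normalization for
regression-based variance stabilization and omits cell-cycle regression:
the scoring math needs only a monotone normalized layer, and the
substitution keeps the pipeline fully specified and dependency-light. The
mitochondrial gene set is "ids starting with `MT-`" by default, as no
curated list is assumed.

## Signature derivation and pre-ranked enrichment

Cluster markers come from a two-sided Mann–Whitney test of cluster vs rest
per gene, after retaining genes with mean log2-expression difference
≥ 0.5 and in-cluster expressing fraction ≥ 0.75; p-values are BH-adjusted
within each cluster and sorted by adjusted p, then |lfc|. Signatures are
the top n (default 150) of that order; cross-line signatures keep genes
present in ≥ 3 of the input sets.

Pre-ranked enrichment sorts the ranking statistic descending and walks a
weighted Kolmogorov–Smirnov running sum: hits add `|stat|^w` (w = 1 by
default, normalized to 1 over the hits), misses subtract `1/(N − N_h)`.
ES is the deviation of largest magnitude, signed; exact magnitude ties
(which arise structurally, e.g. for a contiguous hit block straddling the
balance point) resolve to the positive extreme, with a 1e-9 tolerance so
the rule is stable under float accumulation. The null is gene-set
permutation: n_perm random same-size sets on the same ranking. NES divides
ES by the mean |null ES| of matching sign; p is the same-sign empirical
tail; q is BH over the sets of one batch (equal to p for a single set).
Paired longitudinal profiles are called `no_change` when q ≥ 0.25
(boundary inclusive), otherwise `enriched_up`/`enriched_down` by the sign
of NES. Gene-set (rather than phenotype) permutation is a documented
design choice: it is fully specified and testable at desk scale.

Proteomic state trajectories are the per-timepoint mean of finite log2
ratios over each state's detected markers; infinite ratios (zero
denominators) are excluded and the used count reported.

## Kinase activity

For each kinase with at least 5 detected substrate sites,
`z = (m_s − m̄)·√m / δ`, with m_s the mean substrate log2FC and m̄, δ the
mean and sample SD of all detected sites' log2FCs. Two-sided normal
p-values; significance at p ≤ 0.01. Non-finite fold-changes are excluded
before the background is formed; sites annotated to several kinases count
for each; the background uses all sites (not non-substrate sites only) —
the standard convention, chosen explicitly since the setting is otherwise
underdetermined. z is invariant to shifting or positively rescaling all
fold-changes, which the tests assert.

## Spatially weighted correlation

"Spatially weighted" is realized as Gaussian-kernel smoothing
(`w = exp(−d²/2h²)`, default bandwidth h = 1.5 spot units, the
nearest-neighbor scale of a Visium-like grid) of each signature surface
within its segmented region, followed by plain Pearson correlation of the
smoothed surfaces restricted to that region. At h = 0 this reduces exactly
to Pearson on the raw scores. Spots outside the region never enter either
the smoothing weights or the correlation. Per-sample c × c matrices are
stacked over samples and mean-reduced. Constant surfaces leave the
correlation undefined; those entries are reported as NaN with a warning,
never as 0.

## Functional-assay quantifications

Division number inverts exponential dye dilution: `B = MFI_0 / MFI_T`,
`X = log2 B`, time per division `T/X` for X > 0 (undefined at X = 0). A
final MFI above the initial one is a labeling artifact: X clips at 0 with
a warning. "Attached to a vessel" means Euclidean distance to the nearest
vessel polyline ≤ contact_radius (default 5 distance units, configurable —
the imaging software's pixel criterion is not numerically recoverable, so
the radius is a declared parameter). Vascular association is the attached
fraction within a cell class; vessel co-option is the attached percentage
among invasive-front cells; Nestin positivity and time-lapse
reprogramming rates are the obvious count and area ratios.

## Synthetic data

The generator emulates the statistical structure the analysis assumes, not
raw reads:

- **Counts.** Negative binomial with shared dispersion (default size 2.0)
  and gene means drawn log-normally (σ = 1), scaled so libraries average
  7000 UMI with a 12% lognormal spread — centered inside the 4000–11000 QC
  window. Ten `MT-` genes carry 5% of counts. 30 markers per state are
  drawn from well-detected (above-median baseline) non-mito genes — real
  state markers are reliably captured genes — and shifted by one log2 unit
  in their state's cells. Hybrid cells carry half the effect on both the
  AC and MES marker sets simultaneously, encoding the intermediate AC/MES
  position of the resistant state; the basal hybrid proportion defaults to
  0.10 (a free parameter, as no basal value is established). Treatment is
  modeled by reprogramming a configurable fraction of non-hybrid cells to
  the hybrid state before counts are drawn; with fraction 0 the output is
  bit-identical to the naive generator.
- **Spatial surfaces.** Kernel-smoothed white noise (Gaussian random
  field, σ = 2 spots); the second surface is built from a component
  empirically orthogonalized against the first *within each segmented
  region*, so the planted cross-correlation is exact in every region the
  downstream analysis restricts to, then i.i.d. noise (default SD 0.1) is
  added.
- **Phospho tables.** All mapped substrate sites plus background sites get
  N(0, noise_sd²) log2FCs; active kinases' substrates shift by their
  effect (default scenario: effect 3, noise 0.5, 10 substrates).
- **Dye dilution.** `MFI_T = MFI_0 / 2^X · exp(ε)`, ε ~ N(0, cv²).
- **Vessel scenes.** A cell is attached with its class's bias probability
  and then placed within the contact radius of a random polyline point;
  non-attached cells are rejection-sampled strictly outside the radius, so
  the measured association fraction is a clean binomial estimate of the
  planted bias.

All randomness in a call flows from one seeded generator; identical
(config, seed) pairs reproduce outputs bit-identically. What the generator
does **not** emulate: doublets, ambient RNA, UMI-level read structure,
batch effects, 3-D vessel geometry, spatially varying cell density.
Passing recovery tests therefore show the estimators are correct under the
assumed model, not that they are robust to those artifacts.

## Numerical choices and edge cases

- Quantile bin of the gene at overall rank r (0-based) among n genes is
  `(r·n_bins) // n + 1`; sizes differ by at most one.
- Gene sets missing from a matrix are dropped with a warning down to a 50%
  floor, below which scoring errors out (tolerates cross-species set
  reuse without silently scoring noise).
- A single record's dye-dilution recovery error at cv = 0.1 has SD
  0.1/ln 2 ≈ 0.14, so recovery is asserted on the mean absolute error over
  50 records (expected ≈ 0.115), not per record.
- Median-of-ratios factors are returned unnormalized; scaling one sample
  by f scales its factor *ratio* to every other sample by exactly f (the
  geometric-mean reference itself rescales by f^(1/n), so the individual
  factor moves by f^(1−1/n)).
- The enrichment null p-value is the same-sign empirical tail without the
  +1 correction; over independent null rankings the rejection rate at
  α = 0.05 measures ≈ 0.05. On a single shared ranking, rates for
  different sets are dependent and can drift a point or two either way.
- KSEA errors out when the background SD is zero rather than emitting
  infinite z.

## Problem sizes

Default check sizes: 3000 cells × 2000 genes for state recovery, 500 cells
for null-score calibration, 1000-gene rankings with 50-gene sets
(1000 permutations for power, 200 for the 500-set calibration), 50 × 50
spatial grids, 20-kinase / 600-site phospho tables, 400-cell vessel
scenes. These sizes put Monte-Carlo error comfortably inside the asserted
tolerances while keeping the full suite fast on a single CPU.

## Known limitations

- Enrichment uses gene-set permutation only; phenotype permutation (and
  hence inter-gene-correlation-aware nulls) is out of scope.
- Marker derivation offers a single rank-sum engine, no covariates.
- Scoring operates per matrix; cross-sample harmonization (integration) is
  the caller's responsibility.
- The spatial module takes region labels as input; it does no histology
  segmentation or image registration.
- Kinase-substrate maps are inputs; no database curation is bundled.
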