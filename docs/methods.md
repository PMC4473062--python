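# Methods

## Scope and data model

`crosscell` compares cell-type transcriptomes across species profiled on
heterogeneous platforms. Inputs are per-species feature × sample intensity
matrices (probe or gene level), sample annotations (cell type, replicate),
a per-platform orthology table mapping native features to reference-species
gene symbols (with a probe-functionality flag), and gene sets in GMT.

Expression is held on **linear scale** internally. The fold rules
("≥ 1.5-fold", "> 2-fold") are linear-ratio rules, as is conventional for
normalized microarray intensities; matrices stored as log2 are converted on
ingest (`log2_input=True`). Whether a public matrix is log2 cannot be
detected reliably, so the flag is explicit rather than guessed. Inputs are
assumed already normalized within their platform; background correction and
within-species normalization are out of scope.

Reference symbols are upper-cased on ingest; native feature ids stay
case-sensitive. Cell-type labels are free strings — homology is only ever
asserted by the statistics, never by label matching.

## Fingerprints (Min vs Max rule)

The fingerprint of an index group against a comparator group is the set of
genes with

    ρ = min over ALL replicates of all index cell types
        ──────────────────────────────────────────────  ≥ t
        max over ALL replicates of all comparator types

Replicates are pooled per group, not averaged per cell type: a single low
index replicate (or a single high comparator replicate) excludes a gene.
This is deliberately stringent and deterministic; no variance moderation is
applied. The threshold comparison is inclusive (≥) by default with a
`inclusive=False` switch; t defaults to 1.5 for fingerprints and 1.0 for the
per-species sets feeding conserved signatures. "Absolute" fingerprints use
all other cell types as comparator; "relative" ones a chosen subset. An
empty fingerprint is a legal, flagged result — some cell types genuinely
have no gene passing the rule — and never an exception.

## Translation and conserved signatures

Features with a known reference ortholog are renamed to its symbol;
features without one keep their native id (they can still score within
their own species but will not intersect across species). Conserved
cross-species signatures take the intersection of the translated
per-species sets with one exception: a symbol present in all species but
one is kept when the missing species' platform has **no functional probe**
for it (symbol unmapped, or mapped only by probes flagged non-functional).
The exception compensates for platform gaps without admitting real
biological absence.

## Pairwise GSEA and bubble maps

Ranking metric: signal-to-noise (μa − μb)/(σa + σb) with each σ floored at
max(0.2·|μ|, 0.2) — the desktop-GSEA convention — when both classes have
≥ 3 replicates; otherwise log2 fold change of class means (the fallback is
recorded in the output metadata, and matters here because typical sorted
subsets have 2–3 replicates). Ties are broken by symbol order so rankings
are deterministic.

The enrichment score is the classic weighted running sum: walking the
ranked list, hits add |score|^p (p = 1 by default) normalized by the total
hit weight, misses subtract 1/(N − n_hits); ES is the signed extreme of the
deviation. The null is **gene-set permutation**: random same-size symbol
sets drawn from the ranked list (phenotype permutation is not implemented —
with 2–3 replicates per class it has almost no distinct permutations).
NES = ES / mean(|null ES of the same sign|); the p-value is the
+1-corrected same-sign exceedance fraction, so it can never be exactly
zero. FDR q for a cell is the ratio of the same-sign exceedance fraction in
the pooled normalized null over the same fraction in the pooled observed
NES, clipped to [0, 1]; pooling runs over **all cells of one map** (all
gene sets × all pairs), so the correction is joint across the whole grid.
A cell whose gene set has no overlap with the ranked list is NA — rendered
as an empty position, which is different from a non-significant bubble.

Pairs are unordered with a canonical lexicographic first label; positive
NES means enrichment toward that first label. Iteration order (gene sets
outer, pairs inner) is fixed and per-cell permutation streams are spawned
from one seed, so grids are exactly reproducible. Rendering: bubble area
∝ |NES| (radius ∝ √|NES|), fill color = winning cell type, opacity binned
at FDR {<0.001, <0.01, <0.05, <0.25, ≥0.25} (bins configurable); SVG output
is byte-identical for a fixed grid.

## Cross-normalization (five steps)

1. **Probe collapse** — per gene, keep the probe with the largest total
   signal across samples (values copied, never averaged; ties go to the
   lexicographically smallest probe id). High-signal probes tend to have
   the best signal-to-noise ratio; low-signal probes can show spuriously
   large fold changes at small replicate numbers.
2. **Orthology filter** — keep genes represented on every platform, in one
   common symbol order.
3. **DEG filter + intersection** — per species, for every ordered cell-type
   pair (X, Y) compute r(X,Y) = min(X replicates)/max(Y replicates) and
   keep a gene iff its best pair ratio is strictly > 2; then intersect the
   per-species lists. The pair statistic is a switch (`pair_stat="means"`
   uses ratios of cell-type means); replicate extremes are the default,
   consistent with the fingerprint rule's conservatism. The boundary is
   strict here (> 2) but inclusive for fingerprints (≥ t) — the two rules
   are defined independently and kept that way.
4. **Centering/reduction** — per species and per gene, subtract the mean
   and divide by the sample standard deviation (n − 1). Steps 2–3 exist to
   protect this step: standardizing an unregulated gene would amplify noise
   into artifactual structure.
5. **Merge** — column-concatenate the per-species blocks aligned on
   symbols, prefixing sample labels with the species id. Per-step gene
   counts are recorded as provenance and logged.

A cell-type subset filter restricts samples **before** the DEG filter, so a
lineage-focused rerun re-selects the genes regulated within that subset.

## Clustering and AU support

Distance = 1 − Pearson correlation between merged sample columns; linkage =
UPGMA (scipy's implementation; its merge order is deterministic for a fixed
input, and exact distance ties have measure zero on continuous data).
Multiscale bootstrap resamples genes with replacement at 10 scale factors
r ∈ {0.5, …, 1.4} (n′ = round(r·n)), reclusters, and scores each original
node by the fraction of bootstrap trees containing its exact leaf set
(BP_r). With σ_r = √(1/r) and z_r = Φ⁻¹(1 − BP_r), weighted least squares
fits z(σ) = vσ + c/σ (weights from the binomial delta method,
w = n_boot·φ(z)²/(BP(1−BP))); then AU = 1 − Φ(v − c), and 1 − Φ(v + c)
reproduces BP at σ = 1 as a consistency check. Scales with BP ∈ {0, 1}
carry no curve information and are dropped; BP ≡ 1 (or ≡ 0) across scales
short-circuits to AU = 1 (or 0), and fewer than 3 usable scales falls back
to BP at the scale nearest 1 with a "degenerate" flag — degeneracy is
always flagged, never silent.

**Known limitation.** A node saturated at BP = 1 on most scales can retain
only ~3 near-saturated usable scales; the two-parameter extrapolation from
such points is unstable and can return a large negative curvature and an
AU near 0 despite perfect bootstrap support (observed in roughly one
default-condition replicate in twenty). A binomial maximum-likelihood fit
that uses saturated scales would avoid this; the drop-don't-clamp weighted
fit is kept as the package's stated method and the artifact is documented
and flagged by the companion TSV (inspect nodes whose AU and BP disagree
wildly).

Export: Newick with internal labels `AU_BP` as integer percentages
(0.9999 → "100"), branch lengths from merge heights, plus a per-node TSV
with full-precision AU, BP, v, c and flags.

## Synthetic data generator

The generator emulates the structure of a multi-species sorted-cell
microarray compendium; defaults are the package's reference study
conditions: 3 species × 5 cell types (B, pDC, cDC1, cDC2, MoMP), 3
replicates, a shared universe of 1000 orthologous genes plus 60
species-private genes, 30-gene marker modules at 4-fold, log2 replicate
noise 0.5, per-species per-gene effects of SD 0.3, 1–3 probes per gene with
per-probe efficiency offsets (SD 0.25), 2 % non-functional probes reporting
background-level signal (log2 ≈ 4), 5 % orthology dropout, and one marker
per cell type engineered undetectable in a rotating species (split between
all-probes-non-functional and symbol-unmapped) so the conserved-signature
exception is always exercised. Intensities are log-normal (Normal on log2,
exported linear). Species effects are gene-wise shifts rather than global
scalings, so centering/reduction genuinely removes them — which is exactly
what the cross-normalization claims to do. Fold 1 is the null mode: no
planted signal at all.

Ground truth records marker membership, per-species gene-level
detectability (whether the probe that wins the max-signal collapse is
functional), excuse status (no functional mapped probe at all), expected
per-species fingerprints, expected conserved signatures, and the
sample/cell-type partition — sufficient to score every stage without
re-deriving the simulation.

`divergent_lineage_spec()` is a second documented condition set: cDC1/cDC2
share a 120-gene lineage program, each species expressing a random half of
it in the lineage members (the genes stay differentially expressed via an
anchor cell type, so the DEG intersection keeps them). Standardization
cannot remove this species × lineage interaction, so full-compendium
clustering tends to group cDC samples by species; the focused rerun drops
the program at the subset-level DEG filter and restores grouping by type.

What the generator does **not** model: spatial array artifacts, saturation,
probe cross-hybridization, within-species batch effects, cell-type
contamination gradients. Passing tests therefore demonstrate correctness of
the algorithms under the stated generative model, not performance on any
particular real compendium.

## Numerical and design choices

- Running-sum ES normalizes by the final cumulative hit weight, so the
  vectorized implementation is bit-identical to sequential enumeration.
- Permutation streams derive from `numpy` `SeedSequence.spawn` in grid
  order; all stochastic stages require explicit seeds, and every output is
  reproducible byte-for-byte from inputs + seeds.
- Fingerprint ratios with a zero comparator maximum are an error (the rule
  is undefined), while empty results are flagged, not raised.
- Problem sizes used by the test suite and acceptance script (e.g. 200–1000
  permutations, 200 bootstrap iterations, 10–20 simulation seeds) are
  desk-scale analogues of the reference conditions chosen so a full run
  completes in minutes on one core; the statistics they check are
  calibration and recovery rates, which are sample-size-aware (binomial
  tolerances, KS tests).
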