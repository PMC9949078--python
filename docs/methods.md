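# Methods

This note documents the models, conventions and numerical choices behind
`markerdecon`, and what the synthetic-data tests do and do not establish
about real data.

## The presence model

The core assumption is that of marker-gene deconvolution: if a gene is
expressed in exactly one cell type of a tissue (per a single-cell reference
atlas), then detecting that gene in bulk RNA-Seq of the tissue implies the
cell type is present in the sampled material. The method is deliberately
qualitative — it infers *presence*, never cell-type *proportions*. Marker
abundance depends on per-cell expression as much as on cell number, so no
proportion estimate is attempted (regression-style deconvolution against a
signature matrix is out of scope).

Ambiguity is handled at reference-construction time: a gene listed under two
or more cell types cannot witness any one of them and is removed entirely.
A gene repeated within one cell type is collapsed to a single row keeping
the maximum expression value — the repeat is redundancy, not ambiguity. Gene
symbols are upper-cased and whitespace-trimmed before every comparison,
because official symbols are shared by orthologs but case conventions differ
between species (rat `Lep`, primate `LEP`); this is what lets a rodent
single-cell reference annotate primate bulk data. No alias resolution or
fuzzy matching is attempted: a symbol either matches or it does not, and
unmatched counts are reported rather than repaired.

## Normalization: TMM with a +1 offset

Between-sample normalization follows the trimmed mean of M-values. The
reference sample is the one whose upper-quartile count fraction is closest
to the mean of those fractions. For each other sample, per-gene
`M = log2((count/lib) / (count_ref/lib_ref))` and
`A = (log2(count/lib) + log2(count_ref/lib_ref))/2` are computed over genes
finite in both samples; the top and bottom 30% of M and 5% of A are trimmed;
the factor is `2^f` with `f` the inverse-variance-weighted mean of the
surviving M (binomial delta-method weights). Factors are rescaled to
geometric mean 1. Defaults (trim 0.3/0.05, weighting on) are the standard
published ones. If fewer than 10 genes survive trimming the sample falls
back to the untrimmed weighted mean, with a warning. The implementation
reproduces edgeR's `calcNormFactors(method="TMM")` to ~1e-16 on frozen
negative-binomial fixtures (`tests/data/tmm_edger_factors.json`).

A note on exact invariances: the factors are proportion-based, so rescaling
one sample's counts leaves the *unweighted* factor exactly unchanged; the
precision weights depend on absolute counts, so the default weighted factor
is only approximately scale-invariant (observed drift ~1e-2 when a library
is scaled 7×). The test suite asserts the exact property on the unweighted
variant and a 2% band on the default.

Normalized abundance is `count / (lib · factor) · scale + offset`, with
`scale` the mean raw library size (or 1e6 under `--cpm`) and `offset = 1` by
default, so a zero count maps exactly to 1. The +1 floor is what makes the
presence and exclusivity rules crisp: "expressed" is *strictly* above the
floor, so structural zeros can never support a presence call. Whether the
upstream tool that inspired this convention adds its offset before or after
scaling is not documented anywhere we could verify; adding it after scaling
is the choice here (it preserves the exact floor), and the offset is a
config option.

The low-expression filter removes transcripts whose mean across *all*
samples (groups pooled) is below the threshold; the cut is strict, so a mean
exactly at the threshold survives. With the default offset of 1 and the
default threshold of 1 the filter only removes rows that would sit below the
floor — i.e. it is conservative by construction; users who want to drop
never-expressed transcripts on the offset scale should set `min_mean`
above `offset` (e.g. 2). The filter runs after normalization, in that
order, deliberately.

## Group statistics

Per-transcript comparison uses the unpaired t-test, pooled-variance by
default (the convention of the commercial statistics packages this workflow
replaces), Welch by flag; the QC-metric comparison always uses Welch. A
transcript constant and equal in both groups yields t = 0, p = 1 (no
evidence, not an error); constant but unequal yields p = 0.

Multiplicity is handled by the Benjamini–Krieger–Yekutieli two-stage
adaptive step-up: stage 1 is BH at q′ = q/(1+q); its rejection count r₁
estimates m₀ = m − r₁ true nulls; if 0 < r₁ < m, stage 2 reruns BH at
q′·m/m₀. The implementation delegates to statsmodels
(`fdrcorrection_twostage(method="bky", maxiter=1)`) and is checked against a
brute-force enumerator of both stages; adjusted q-values are reported
clipped to [0, 1], but the *rejection decisions* are the contract — under a
two-stage procedure q can legitimately fall below p, so no q ≥ p invariant
is asserted. The default level is q = 0.05. The output table keeps raw p and
adjusted q side by side, so "significant before correction but not after"
is visible rather than silently resolved.

Presence: a cell type is present in a group iff ≥ 1 of its marker
transcripts has group-mean abundance strictly above the presence threshold
(default = the offset). Supporting marker counts are reported per (cell
type, group). The rule is monotone in the threshold.

Group-exclusive genes: under the default `all-vs-none` rule a gene (any of
its isoforms counts) must be above the floor in **every** sample of the
owning group and in **no** sample of the other; `any-vs-none` relaxes the
first quantifier. The source workflow never defines its criterion
("only found to be expressed in" one group); `all-vs-none` is the strongest
reading and is the default, the relaxed rule is provided for sensitivity
analysis.

QC metrics are tested one Welch test per metric with no correction across
the six metrics — each metric is its own question, reported as its own
panel.

## Variation summaries

CV is the n−1 sample SD divided by the mean, per transcript per group,
computed on the full filtered matrix (not only annotated transcripts). PCA
treats samples as observations and transcripts as features, mean-centers
features without unit-variance scaling (covariance PCA, the default of the
expression-analysis tools this mirrors; correlation PCA by flag), and
reports explained variance over *all* components of the centered data so the
percentages sum to 100. Group ellipsoids are axis-aligned in component
space: center = mean score, radius = 2 × score SD per component. Full
covariance ellipsoids are deliberately out of scope; with 8–9 samples per
group a 3-D covariance estimate is noisy and the axis-aligned 2-SD box is
what the figure convention describes.

## The synthetic-data generator

`simulate` emulates the target study design: a reference atlas of 43 cell
types (default 3 unique markers each, ~129 unique genes, plus 10 genes
deliberately shared between two cell types to exercise duplicate removal),
and a bulk experiment of 8 vs 9 samples. Bulk counts are gamma-Poisson
(negative binomial, gene dispersion 0.1 — standard bulk overdispersion) with
expected marker abundance proportional to mixture-weight × marker-intensity;
mixture weights are a Dirichlet draw blended 70/30 with the uniform so every
mixed-in cell type stays above 0.3/k and is genuinely detectable; library
sizes are lognormal (CV 0.1) around 10⁶. Background genes (default 2000,
scaled down from genome scale for fast tests) have lognormal intensities and
a 25% structurally silent fraction. Optional plantings: log2 fold changes in
the second group, group-exclusive genes (structural zeros in the other
group, boosted in the owner so every owning sample detects them), cell types
with zero weight in both groups, and two-isoform genes (20% of markers).
Everything is a pure function of the config including its seed, and output
files are byte-stable.

What passing the simulation tests shows: the algorithms recover exactly the
structure the generator planted, under idealized conditions. What it does
not show: robustness to the ways real data violate the model —
marker genes that are not truly unique in the new species, cross-species
expression divergence, mappability and annotation artifacts, batch effects,
or compositional coupling between cell types. The generator deliberately
does not attempt to fit any real dataset.

Error-control studies use a direct Gaussian two-group sampler
(`simulate_gaussian_groups`): 200 exchangeable transcripts, 8 vs 9 samples,
optionally 10 transcripts shifted by 3 SD in one group. At these sizes the
suite observes mean null false-discovery proportion ≤ 0.075 at q = 0.05
(200 replicates) and sensitivity ≳ 0.97 with empirical FDR ≈ 0.05 on the
planted effects (100 replicates); problem sizes were chosen to keep the
whole suite in the tens of seconds.

## Numerical and I/O choices

- CSVs are written with `%.12g` floats; matrix round-trips are exact to
  1e-9 and the pipeline consumes its own written artifacts, so a chained
  `run` is file-for-file identical to running the stage commands by hand,
  and reruns are byte-identical.
- The reference-sample quartile uses linear (type-7) interpolation; M/A
  trimming uses average ranks, matching the reference TMM implementation's
  tie handling.
- Degenerate inputs fail loudly with typed errors (zero library size,
  duplicate transcript ids, empty reference after duplicate removal, zero
  annotation matches) rather than producing empty outputs.
- `top_expressed` breaks mean-abundance ties by transcript id so rankings
  are deterministic.

## Known limitations

- Presence calls inherit the reference's notion of "uniquely expressed";
  a marker unique in the atlas species need not be unique in the target
  species.
- The +1 floor makes the default mean≥1 filter a no-op except for exact
  floor rows; this mirrors the source convention but means filtering
  stringency effectively lives in the `min_mean` option.
- With n = 8–9 per group, per-transcript t-tests have limited power for
  subtle composition shifts; the method is best at detecting gross
  presence/absence differences.
- Exactly two groups are supported; multi-group designs would need a
  different testing layer.
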