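# Methods

## Study design assumed by the pipeline

The pipeline models a two-group, one-colour microarray comparison with
a small number of pooled biological samples per group (default 3 vs 3,
groups labelled `depression` and `healthy`; fold changes are always
oriented depression/healthy, so "up" means higher in the
depression-microbiota group). Three feature panels — mRNA, lncRNA and
miRNA — are screened independently and then integrated through target
tables and a genomic annotation. miRNA target relations are *inputs*
(database-export style tables), never predicted from sequence: the
package's scope starts at the intensity tables and target maps.

## Differential expression

1. **Replicate collapse.** Duplicate probe ids are mean-collapsed
   (foreground and background averaged; each cell keeps its most
   detected flag, Present > Marginal > Absent).
2. **Detection filter.** A probe is kept when at least
   `min_flagged_samples` (default 3) of its cells carry a Present or
   Marginal flag. Flag symbols accept both single letters and full
   words, case-insensitively; anything else is a parse error.
3. **Intensity filter (miRNA only).** Mean raw foreground across all
   arrays must be ≥ `min_intensity` (default 30 fluorescence units,
   boundary inclusive). The mean-across-arrays reading was chosen over
   per-array readings because it is stable for low-abundance miRNAs
   and makes the filter a single interpretable number per probe.
4. **Normalization.** `x[f,s] = (FG[f,s] − BG[f,s]) / median_s`, where
   `median_s` is sample *s*'s median net intensity over the retained
   features; each sample's median normalized value is therefore 1. A
   nonpositive sample median aborts with the sample named. Negative
   cells (background exceeding foreground) are kept as-is here and
   floored at 1e-6 just before ratios/logs, keeping the pipeline a
   total function without imputation.
5. **Test.** On log₂ of the floored values. The default is a
   pooled-variance t with empirical-Bayes variance moderation: the
   per-feature residual variances s² (d = n₁+n₂−2 df) are fit to a
   scaled inverse-chi-square prior (d₀, s₀²) by matching the mean and
   variance of log s² (digamma/trigamma moment equations, trigamma
   inverted by Newton iteration), and the posterior variance
   s̃² = (d₀s₀² + d·s²)/(d₀+d) feeds a t-statistic with d + d₀ df
   (normal when d₀ is infinite, i.e. homogeneous variances). With two
   to three arrays per group a plain per-feature t is dominated by its
   4-df variance estimate: in the package's own recovery benchmark
   (2000 features, 5% planted effects at fold 2.5, CV 0.10, 3 vs 3)
   Welch recalls only ~0.68 of planted effects after BH, while the
   moderated test recalls essentially all of them at zero empirical
   false-discovery proportion — hence the default. `method="welch"`
   restores the unmoderated test; the moderated implementation is
   cross-checked against the reference R implementation in the test
   suite.
6. **FDR and calls.** Benjamini–Hochberg step-up (step-up minimum
   capped at 1, input order preserved, ties stable). Significant means
   |FC| ≥ `min_abs_fc` (1.5) **and** FDR < `max_fdr` (0.05). The
   optional `rescue_raw_p` retains fold-change-passing features whose
   raw p clears the cutoff even though their FDR does not, marking
   them `rescued` — an explicit, off-by-default mechanism rather than
   a silent widening of the FDR threshold, so borderline keeps (such
   as a miRNA with p < 0.05 but FDR ≈ 0.066) stay visible in the
   output.

Degenerate inputs: identical groups give FC = 1 and p = 1; zero
variance with differing means gives p → 0 (Welch) or a finite
moderated p; fewer than two samples per group is an error.

## Genomic annotation

Coordinates are 0-based half-open throughout (BED convention at I/O).
Positional lncRNA classes are assigned by gene-body overlap with
precedence sense_overlap > antisense_overlap > bidirectional >
intergenic. *Bidirectional* means divergent transcription: opposite
strands, no overlap, 5′ ends within `bidirectional_window` (default
1 kb — the conventional bidirectional-promoter span; configurable
since annotations differ on it). Exon-level overlap is not modelled;
gene bodies are the unit because the upstream annotation is
probe-level. lncRNAs on chromosomes absent from the coding annotation
are reported intergenic with a logged warning.

*Cis* targets pair a lincRNA with every coding gene whose body lies
within `cis_window` (default 300 kb) of the lincRNA body, measured
between closest interval edges (overlap counts as distance 0),
symmetric upstream/downstream and strand-agnostic. Edge-to-edge rather
than TSS-to-TSS was chosen because the relation is defined on loci,
not promoters.

Intersections with differential features resolve identity at
**transcript-accession level**, not gene symbol: one symbol probed by
two transcripts (possibly moving in opposite directions) contributes
two distinct targets and two network nodes.

## Network, modules, triads

Nodes are restricted to significant features and carry class,
direction and symbol; edges are typed (mirna–mrna, mirna–lncrna,
mrna–mrna). Gene–gene interaction edges arrive at symbol level with a
confidence score and are kept iff score > `score_cutoff`
(default 0.4, strict, the usual medium-confidence setting); rows
touching filtered-out features are dropped with a logged count. The
graph is simple — duplicate target rows collapse to one edge.

Hubs are all maximum-degree nodes, ties reported lexicographically.

Dense modules use an MCODE-style procedure: vertex weight = (k of the
highest k-core of the vertex's closed neighbourhood) × (density of
that core), with sub-`degree_cutoff` vertices weighted 0; complexes
grow from the highest-weight unassigned seed, absorbing neighbours
whose weight is ≥ (1 − `node_score_cutoff`) × seed weight; complexes
lacking a `k_core`-core are discarded and, with haircut on, trimmed to
their 2-core; ranking is density × size. Defaults are the canonical
ones (degree cutoff 2, node score cutoff 0.2, k-core 2, haircut on,
fluff off). Graphs with fewer than 3 nodes yield no modules.

A ceRNA triad (l, m, g) is emitted for every miRNA m with target edges
to mRNA g and lncRNA l where direction(g) ≠ direction(m) and
direction(l) ≠ direction(m). "Negative regulation" is this sign rule
on differential directions, not an expression correlation: with three
samples per group correlation estimates are unstable, and the sign
pattern is exactly what a sponge relationship implies for a
differential miRNA. Output order is deterministic (miRNA, lncRNA,
mRNA lexicographic). The functional restriction is an explicit
user-supplied gene-symbol set applied to the triad's mRNA; no
automated GO-driven narrowing is attempted because such choices are
not algorithmically reproducible.

## Enrichment

Upper-tail hypergeometric over-representation:
p = P[X ≥ overlap] for X ~ Hypergeom(universe, term∩universe, query),
BH-adjusted across terms, sorted by p. The universe defaults to all
annotated genes in the bundle. This is a documented generic stand-in
for annotation-service enrichment; term content is entirely the
caller's.

## Synthetic-data generator

The generator emulates the study design, not the biology of any
particular tissue:

- **Intensities.** Per-feature baseline 2^N(`baseline_log2_mean`=8,
  `baseline_log2_sd`=1.5); multiplicative log-normal noise with
  coefficient of variation `noise_cv` (mean-1 corrected);
  foreground = background + signal with background uniform on
  [5, 15]. Planted features multiply the depression-group mean by
  `effect_fold` (up) or its inverse (down), so the realized group-mean
  ratio converges to the planted fold as noise vanishes.
- **Detection.** A `frac_absent` share of features per class is
  unexpressed: background-level signal everywhere and all cells
  flagged Absent (so the cell-level Absent fraction equals
  `frac_absent` exactly and both the flag and intensity filters have
  real work to do). Expressed cells are Present with a 5% Marginal
  admixture. Real arrays also show sporadic per-cell dropouts in
  expressed probes; that mode is not simulated, so the flag filter's
  partial-detection branch is exercised by the packaged unit tests
  rather than by generated data.
- **Planted effects.** Exactly `round(frac_de · n)` expressed features
  per class, directions uniform. One candidate triad per differential
  miRNA is drawn over disjoint differential partners with guaranteed
  target-map edges; a `frac_coupled_triads` share is wired
  sponge-consistently by `plant_sponge_signal`, which flips a
  partner's direction by rescaling its depression-group net signal by
  `effect_fold`^±2 and records the flip in the ground truth.
- **Annotation.** Coding genes on a sparse 1-Mb grid so every window
  relation is unambiguous; lncRNA positional classes allocated by
  largest remainder at 50/26/12/12 (the composition observed on mouse
  lncRNA arrays); `n_cis_de_pairs` (default 4) differential lincRNAs
  planted 10–250 kb from differential genes, all other intergenic
  lincRNAs placed mid-gap, > 300 kb from every gene — so the planted
  cis pairs are exactly the recoverable ones.
- **Target maps / interactions / terms.** Poisson out-degrees
  (`targets_per_mirna`=8 mRNA targets, a quarter as many lncRNA
  targets), Erdős–Rényi gene–gene edges at `interaction_density`=0.01
  with uniform scores, twenty random term sets plus one seeded from
  the planted differential genes.
- **Determinism.** All randomness flows from one
  `numpy.random.Generator` seeded by `SimulationConfig.seed`;
  identical configurations produce byte-identical written bundles.

What passing the synthetic suite shows — and does not. Recovery at
fold 2.5/CV 0.10 (differential screen) and fold 4/CV 0.05 (sponge
triads, cis pairs) demonstrates that the machinery is correct and
calibrated under a well-specified generative model with independent
features. It does not establish performance on real arrays, where
probe effects are correlated, variance depends on intensity, target
databases disagree, and pooling three animals per sample hides
within-group structure (pooling is modelled as plain per-sample
noise).

## Problem sizes

Default desk-scale panels are 2000 mRNA / 500 lncRNA / 200 miRNA
probes; the recovery benchmarks sweep 20 seeds at those sizes, which
keeps the full test suite around twenty seconds and the acceptance
script under a minute on one CPU while leaving every count large
enough for stable proportions.

## Known limitations

- No raw array-file parsing (Agilent FE, GPR); the intensity tables
  are the entry point.
- No sequence-based miRNA target prediction and no live database
  queries; target tables are inputs by design.
- Enrichment is annotation-agnostic; it cannot reproduce the output of
  proprietary pathway services.
- The moderated test assumes log-scale normality and exchangeable
  variances across features; grossly heteroskedastic platforms should
  use `method="welch"` and more replicates.
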