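# Methods

This note documents the statistical model behind `nascentshift`, the
parameters that matter, what the synthetic-data generator does and does
not emulate, and the design decisions taken where the procedure admitted
more than one reasonable reading.

## 1. Spike-in anchored normalization

### Model

Counts `x[g,s]` for feature `g` in sample `s` are treated as Poisson with
mean `μ[g] · β[g,c(s)] · d[s]`, where `μ[g]` is the feature's baseline
expression, `β[g,c]` the biological fold change in condition `c`
(`β ≡ 1` in the reference condition), and `d[s]` a sample-specific depth.
ERCC spike-ins are added in fixed amount per cell-equivalent, so for them
`β ≡ 1` in every condition: their counts vary only with `d[s]`. The
scale factor `f[s] = E_ref / E[s]` (ratio of spike-in totals, reference =
first sample by default) is therefore a consistent estimator of
`d[ref]/d[s]`, and normalized counts `x·f` sit on a per-cell scale on
which global shifts (all `β` moved in the same direction) remain visible.
Library-size factors estimate `d·⟨β⟩` instead and absorb the global shift
— both behaviours are asserted in the test suite, and
`compute_scale_factors(..., method="total")` exposes the library-size
variant precisely for that contrast.

Factors are relative; all downstream ratios are invariant to the
reference choice (tested). Condition-level class totals pool replicates by
summing normalized per-sample totals; per-sample totals are also emitted.

### ERCC-anchored RPKM

The expression ranking key is
`rpkm(g) = mean_norm(g) · 10⁹ / (L(g) · T)` with `L` the gene-body span in
bp and `T` the mean per-replicate total of non-spike-in normalized reads
in the chosen (control) condition. The denominator convention matters
only up to a condition-wide constant — any monotone variant yields the
same ranking — and this form reduces to textbook RPKM when all factors
are 1. Gene length is the annotated body span (`end − start`), not summed
exon length: nascent transcription covers introns, and coverage profiling
operates on the same span. This is a documented convention; analyses that
define gene size as exonic length will rank long multi-exon genes
differently.

## 2. Exact Poisson differential test

Replicates are pooled by summing raw counts per condition: sums of
independent Poissons are Poisson, so the pooled pair `(x_ref, x_alt)` is
sufficient. With exposures `w_ref, w_alt` (pooled spike-in totals — a
deeper-sequenced condition expects proportionally more counts under the
null), conditioning on `n = x_ref + x_alt` gives
`X_alt ~ Binomial(n, p0)`, `p0 = w_alt/(w_ref + w_alt)`, independent of
the unknown baseline. The reported p-value is the one-tail binomial
probability in the direction of the observed normalized fold change (no
doubling); `n = 0` returns 1. Working on raw integers with exposure
weights keeps the test exact; rescaling counts to non-integer values
first would not.

Numerical notes: tails come from `scipy.stats.binom.sf/cdf`; results are
clipped into `(0, 1]` (the lower clip only matters when `sf` underflows
to exactly 0 at astronomically extreme counts, keeping BH input valid).
Equivalence with brute-force tail enumeration is asserted to `1e-12` over
the full grid of counts ≤ 50 at three weight ratios.

A `per_replicate=True` mode tests replicate pairs separately and combines
p-values by maximum — deliberately conservative, available for
sensitivity analysis; pooled is the default and the better-justified
choice under the Poisson model.

### Calling rule and multiplicity

`FDR = Benjamini–Hochberg`, computed by the step-up formula
`min_{j≥i} p_(j)·n/j` clipped at 1, order-preserving. A gene is called
`up` when `FC ≥ fc_threshold` (default 1.5) and `FDR < fdr_threshold`
(default 0.05); `down` symmetrically with `FC ≤ 1/1.5`. Fold change is
computed on ERCC-normalized pooled counts with a pseudocount (default 1
normalized unit) so zero-count genes are defined. Spike-in rows are never
tested; rDNA, histone and protein-coding classes are tested together with
joint BH by default (a `classes` argument restricts the universe when a
protein-coding-only analysis is wanted — note the adjusted values depend
on that choice). The combination of the FDR gate *and* the fold-change
gate makes realized false-discovery proportions in simulations
essentially zero at moderate depths: the FC filter removes the small-
effect false positives BH alone would admit.

### Z-scores and stratified summaries

Heat-map z-scores are per-gene across all samples on normalized counts:
`(x − mean)/SD` with sample (n−1) SD; zero-variance rows map to zeros
rather than NaNs. Normalized (not raw) counts are used so that depth
differences do not masquerade as condition structure; this is a
documented choice. The top-N expression slice sorts DEGs by control
RPKM (descending, ties lexicographic, default N = 100). Gene-length
contrasts between call groups use the two-sided Wilcoxon rank-sum test:
exact when both groups have ≤ 10 members and no ties (verified against
full enumeration), normal approximation otherwise; an all-tied degenerate
input short-circuits to p = 1, and an empty group reports NaN rather than
crashing.

## 3. Screen scoring

Guide abundances are normalized per population as
`raw/total × 10⁶ + 1` — reads-per-million with a +1 floor, so normalized
values are ≥ 1 and fold changes of unobserved guides are defined. The
enrichment fold change and `CRISPR score = log2(FC)` use these floored
values; the p-value deliberately does not: it is the same exact
conditional test as above on raw counts with population totals (assigned
reads only) as exposures, tail fixed to enrichment because the sort
selects the EU-high population. BH runs jointly across all guides, not
per gene. A gene is a hit when at least one guide has `padj ≤ 0.01` and
`FC ≥ 1.5`.

Extraction is exact-match only: first occurrence of the 5′ anchor, the
next 20 nt as candidate, 3′ anchor required immediately after, exact
dictionary lookup in the library. Mismatch tolerance would change counts
silently and is intentionally excluded; everything that fails any step is
an explicit `unassigned` tally.

## 4. Metagene profiling and the 5′/3′ statistic

Bodies are rescaled to `body_bins` (default 100) bins; base `i` of an
`L`-base body maps to bin `⌊i·bins/L⌋` (deterministic, platform-stable);
the bin value is the mean coverage of its bases. Flanks span `flank_bp`
(default 3000, i.e. 3 kb) at `flank_bins` (default 60, 50 bp each) fixed-
width bins. Minus-strand genes are reversed so bin 0 is always 5′. Genes
shorter than `body_bins` bases are skipped with a logged warning and a
tally. Genes contribute unweighted (each gene equally), matching
average-profile semantics.

The initiation-vs-elongation readout: `r5`/`r3` are the means of the
first/second half of body bins (middle bin to the 3′ half when odd);
the cross-condition ratio-of-ratios `(r5/r3)_alt / (r5/r3)_ref` is exactly
1 when the perturbed condition loses coverage uniformly across the body
(initiation-level repression — fewer polymerases enter but travel the
whole gene) and rises above 1 when loss concentrates in the 3′ half
(elongation-level). The half-split window is a convention — the
qualitative claim it operationalizes names only the gene "ends" — and is
configurable; the statistic is undefined (hard error) when a 3′ half mean
is 0.

## 5. The synthetic-data generator

`simulate_nascent_experiment` draws each count Poisson at
`baseline(g) · fc(g, condition) · depth(sample)`. Defaults encode the
emulated design: 2 conditions × 2 replicates; 92 spike-ins; 20 rDNA-like
features at 100× the protein-coding baseline (so rDNA dominates read
mass, as it does in nascent RNA); 2,000 protein-coding and 60 histone-like
genes. Per-gene baselines are log-uniform within class
(`baseline_log10_spread`, default 0.5 decades) so an expression ranking
exists. Spike-in means scale with depth but never with biology — the
invariant the normalization relies on, asserted across seeds.
`selection="expression_ranked"` (default) programs the down-regulated set
as the most highly expressed protein-coding genes and draws the
up-regulated set from the remainder, reproducing the expression-dependent
structure of the radiation response; `"random"` decouples effect from
expression for FDR-calibration experiments. Noise is pure Poisson to
match the test's assumed model, making type-I-error checks interpretable;
a negative-binomial switch (`overdispersion`, gamma-mixed Poisson) exists
for robustness experiments and defaults off.

`simulate_coverage` is deterministic: uniform bodies at an exact level,
or a 5′→3′ linear ramp with mean exactly `level` (base `i` of `L` gets
`2·level·(L−i)/(L+1)`), strand-aware; the perturbed condition multiplies
the whole body or only its 3′ half by a stated factor. Determinism keeps
the profile-shape contracts exact.

`simulate_screen` draws a log-normally skewed library
(`library_sigma = 0.5` natural-log SD — real guide libraries are skewed,
which keeps normalization non-trivial), Poisson counts at depth 10⁶ per
population by default, 2,000 genes × 5 guides, 20 regulator genes with 3
of 5 guides enriched 4-fold in the sorted pool (relative abundances
re-normalized, so realized fold changes sit slightly below the programmed
value — by ~2 % at these settings). `simulate_guide_fastq` renders a
count table as anchored reads for the extraction round trip, which is
exact by construction and verified at full depth.

Every generator spawns its RNG stream from the seed via stable spawn
keys, so adding a call does not perturb earlier artifacts, and identical
seeds give bitwise-identical outputs.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: overdispersion beyond Poisson (real biological
replicates are noisier; the exact test is anti-conservative under
overdispersion), mapping and counting artifacts (multi-mapping to rDNA
repeats, rRNA homology — the class label on count rows stands in for the
upstream rDNA-first alignment step), ERCC dose-response nonlinearity,
guide-extraction sequencing errors, and cell-sorting impurity in the
screen gate. Claims of sensitivity ≥ 0.95 or near-zero false discovery
are claims about the Poisson regime at the stated depths.

## 6. Problem sizes in tests and the acceptance script

The shipped checks run at the design scale where their guarantees are
law-of-large-numbers statements: global-shift recovery at ≥ 10⁵ expected
class counts (5 % tolerance), DEG recovery at expected pooled counts
≥ 200 over 20 seeds, the screen at 2,000 genes × 5 guides × depth 10⁶
with a full-depth FASTQ round trip, exact-oracle grids at counts ≤ 50 and
10⁴ random BH vectors. These sizes were chosen so each statement is
comfortably inside its stochastic tolerance while the whole suite runs in
well under a minute of compute.

## 7. Known limitations

* The exact test assumes Poisson counts; with biological overdispersion
  its p-values are optimistic. Use the negative-binomial generator switch
  to quantify the effect for a given depth before trusting borderline
  calls on real data.
* Gene length = body span is the right quantity for nascent coverage but
  differs from exonic length by up to an order of magnitude for long
  genes; length-stratified conclusions depend on this convention.
* BH adjustment depends on the tested universe (joint across classes by
  default); restricting to protein-coding changes adjusted values.
* Guide extraction is exact-match; libraries with near-duplicate
  sequences or high sequencing error rates will undercount.
* The 5′/3′ ratio is a two-number summary of a profile; it cannot
  distinguish a 3′ loss from a 5′ gain.
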