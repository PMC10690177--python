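# nascentshift

Spike-in-anchored differential analysis of nascent transcription, with a
matched pooled-CRISPR-screen scoring arm.

## The problem

After DNA double-strand-break damage (ionizing radiation, IR), cells
transiently shut down a large part of ongoing transcription. That shutdown
is *global*: total nascent-RNA output drops, dominated by the highly
transcribed rDNA repeats and histone genes, while a set of moderately
expressed protein-coding genes is induced. Ordinary RNA-seq normalization
(library size, TPM, median-of-ratios) equalizes totals across samples and
therefore *erases exactly this signal*. The fix is external spike-ins: a
fixed amount of the 92 ERCC standards is added per cell-equivalent before
library preparation, so equalizing total spike-in counts restores an
absolute per-cell scale on which global shifts are visible.

`nascentshift` implements that analysis end to end for metabolically
labelled (EU) nascent RNA-seq and for a FACS-sorted genome-wide CRISPR
knockout screen read out on the same nascent-RNA signal. It is aimed at
computational biologists analysing spike-in anchored nascent-transcription
experiments, and ships a synthetic-data generator with programmed ground
truth so every statistical guarantee is testable.

## Methods at a glance

**Scale factors.** For sample *s*,
`factor(s) = ERCC_total(reference) / ERCC_total(s)`; normalized counts are
`x[g,s] · factor(s)`. Class totals (rDNA / histone / protein-coding /
total) per sample and per condition quantify the global response.

**Differential testing.** Replicates are pooled by summing raw counts per
condition. For a gene with pooled counts `x_ref`, `x_alt` and condition
exposures `w = pooled ERCC totals`, the exact two-sample Poisson test
conditions on `n = x_ref + x_alt`:

    X ~ Binomial(n, p0),  p0 = w_alt / (w_ref + w_alt)

and returns the one-tail binomial probability in the direction of the
observed normalized fold change. A gene is a DEG when `FC > 1.5` and
Benjamini–Hochberg `FDR < 0.05`. Expression ranking uses ERCC-anchored
RPKM (normalized counts per kb of gene-body span per million non-spike-in
normalized reads of the control condition); heat-map style z-scores are
per-gene `(x − mean)/SD` across all samples.

**Screen scoring.** Per guide and population,
`normalized = raw / total × 10⁶ + 1`; `FC = norm_sorted / norm_unsorted`;
`CRISPR score = log2(FC)`; p-values come from the same exact Poisson test
(enrichment tail, population totals as exposures), BH-adjusted across all
guides. A gene is a hit when ≥ 1 guide has `padj ≤ 0.01` and `FC ≥ 1.5`.

**Metagene profiling.** Spike-scaled coverage is averaged over gene bodies
rescaled to 100 bins plus 3 kb fixed-width flanks, strand-aware (bin 0 is
always 5′). The 5′/3′ statistic compares the body's first-half to
second-half mean across conditions: a ratio-of-ratios ≈ 1 means uniform
body-wide loss (repression at initiation), > 1 a 3′-biased loss
(elongation defect).

## Worked example

```python
import nascentshift as ns

# simulate the study design: 2 conditions x 2 replicates, 92 spike-ins,
# rDNA transcription halved after the perturbation
cfg = ns.NascentSimConfig(
    n_protein_coding=2000, n_rdna=20, n_histone=0,
    global_shift={"rdna": 0.5, "histone": 1.0, "protein_coding": 1.0},
    rng_seed=1,
)
matrix, truth = ns.simulate_nascent_experiment(cfg)

factors = ns.compute_scale_factors(matrix)          # ERCC-anchored
totals = ns.compute_class_totals(ns.normalize_counts(matrix, factors))
rdna = totals.per_condition.loc["rdna"]
print(f"rdna shift estimate: {rdna['ir'] / rdna['ctrl']:.4f}")

results = ns.call_degs(matrix, factors)
n_down = sum(r.call == "down" for r in results)
print(f"{n_down} genes called down of {len(results)} tested")
```

Output:

```
rdna shift estimate: 0.4987
23 genes called down of 2020 tested
```

The spike-in-anchored estimate recovers the programmed 0.5× rDNA shift to
a fraction of a percent (library-size normalization on the same matrix
estimates ≈ 0.62 — it absorbs most of the decline into the scale factors).
The 23 down-calls are the 20 rDNA features plus 3 borderline genes; the
2,000 unperturbed protein-coding genes are otherwise left uncalled by the
FC > 1.5 / FDR < 0.05 rule.

The same pipeline runs from the shell:

```sh
nascentshift --seed 1 --out-dir sim simulate nascent --rdna-shift 0.5
nascentshift --out-dir out normalize --counts sim/counts.tsv \
    --annotation sim/annotation.tsv --design sim/design.tsv
nascentshift --out-dir out diffexpr --counts sim/counts.tsv \
    --annotation sim/annotation.tsv --design sim/design.tsv
```

## Layout

| module | contents |
| --- | --- |
| `nascentshift.core_io` | domain types, TSV/GTF/bedGraph/FASTQ-adjacent I/O, config, logging |
| `nascentshift.synthetic_data` | count-matrix, coverage and screen generators with ground truth |
| `nascentshift.spikein_norm` | scale factors, normalization, class totals, RPKM ranking |
| `nascentshift.diffexpr` | exact Poisson test, BH, DEG calling, z-scores, length comparison |
| `nascentshift.screen` | guide extraction, normalization, CRISPR scores, hit calling |
| `nascentshift.metagene` | body/flank binning and the 5′/3′ ratio statistic |

See `docs/methods.md` for the full statistical account and design
decisions.
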