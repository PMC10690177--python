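"""ERCC spike-in anchored normalization and expression summaries.

A global transcriptional shift (for example, the bulk shutdown of rDNA
transcription after ionizing radiation) changes every sample's library size
in the same direction and is therefore erased by total-count normalization.
Spike-ins break the degeneracy: a fixed amount of the 92 ERCC standards is
added per cell-equivalent, so equalizing total spike-in signal across
samples restores an absolute per-cell scale.

This module computes the per-sample scale factors, the normalized matrix,
class-level totals (the global / rDNA / protein-coding readout) and an
ERCC-anchored RPKM used to rank genes by expression in the reference
condition.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core_io import (
    FLOAT_FORMAT,
    AnnotationSet,
    CountMatrix,
    InputError,
    ScaleFactors,
    logger,
)

__all__ = [
    "NormalizedMatrix",
    "ClassTotals",
    "ExpressionSummary",
    "compute_scale_factors",
    "normalize_counts",
    "compute_class_totals",
    "compute_rpkm",
]


@dataclass
class NormalizedMatrix:
    """Counts rescaled so that total spike-in signal is equal across samples.

    ``values[f, s] = counts[f, s] * factor_of[s]``.  The reference sample is
    unchanged; after normalization every sample's spike-in total equals the
    reference's by construction.
    """

    values: pd.DataFrame
    class_of: dict[str, str]
    condition_of: dict[str, str]
    factors: ScaleFactors

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def class_series(self) -> pd.Series:
        return pd.Series({f: self.class_of[f] for f in self.values.index})

    def samples_of(self, condition: str) -> list[str]:
        return [s for s in self.samples if self.condition_of.get(s) == condition]

    def conditions(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.samples:
            if s in self.condition_of:
                seen.setdefault(self.condition_of[s], None)
        return list(seen)

    def to_tsv(self, path: str | Path) -> None:
        self.values.to_csv(path, sep="\t", index_label="feature_id",
                           float_format=FLOAT_FORMAT)


@dataclass
class ClassTotals:
    """Per-sample and per-condition (replicate-pooled) normalized totals by
    feature class, plus the all-non-spike-in total."""

    per_sample: pd.DataFrame        # rows: feature classes, cols: samples
    per_condition: pd.DataFrame     # rows: feature classes, cols: conditions
    total_non_spikein_per_sample: pd.Series
    total_non_spikein_per_condition: pd.Series

    def to_tsv(self, path: str | Path) -> None:
        df = self.per_sample.copy()
        df.loc["total_non_spikein"] = self.total_non_spikein_per_sample
        df.to_csv(path, sep="\t", index_label="class",
                  float_format=FLOAT_FORMAT)


@dataclass
class ExpressionSummary:
    """Per-gene mean normalized counts per condition and the RPKM ranking key.

    ``rpkm`` is computed for one stated condition (typically the control):
    mean normalized count over that condition's replicates, per kilobase of
    gene-body span, per million non-spike-in normalized reads of the
    condition.  ``ranked_ids`` sorts genes by rpkm descending, ties broken
    lexicographically by feature_id.
    """

    table: pd.DataFrame
    condition: str
    ranked_ids: list[str]

    def rpkm_of(self, gene: str) -> float:
        return float(self.table.loc[gene, "rpkm"])

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index_label="feature_id",
                          float_format=FLOAT_FORMAT)


def compute_scale_factors(
    counts: CountMatrix,
    reference: str = "first",
    method: str = "ercc",
) -> ScaleFactors:
    """Per-sample scale factors from spike-in totals.

    ``factor_of[s] = total(reference) / total(s)`` with totals over spike-in
    rows (``method="ercc"``, the default) or over all rows
    (``method="total"``, ordinary library-size normalization, provided for
    comparison — it cannot see global shifts).

    ``reference="first"`` uses the first sample column; factors are relative,
    so downstream ratios do not depend on the choice.
    """
    if method == "ercc":
        if not counts.spikein_features():
            raise InputError(
                "count matrix has no spikein-class features; spike-in "
                "normalization requires at least one"
            )
        totals = counts.ercc_totals()
    elif method == "total":
        totals = counts.counts.sum(axis=0)
    else:
        raise InputError(f"unknown normalization method {method!r}")

    zero = [s for s in counts.samples if totals[s] <= 0]
    if zero:
        raise InputError(
            f"zero {'ERCC' if method == 'ercc' else 'library'} total in "
            f"sample(s) {zero!r}; cannot form scale factors"
        )
    ref = counts.samples[0] if reference == "first" else reference
    if ref not in counts.samples:
        raise InputError(f"reference sample {ref!r} not in matrix")
    ref_total = int(totals[ref])
    factors = {s: ref_total / int(totals[s]) for s in counts.samples}
    logger.debug("scale factors (%s, ref=%s): %s", method, ref, factors)
    return ScaleFactors(
        factor_of=factors,
        reference_sample=ref,
        reference_total=ref_total,
        total_of={s: int(totals[s]) for s in counts.samples},
        method=method,
    )


def normalize_counts(counts: CountMatrix, factors: ScaleFactors) -> NormalizedMatrix:
    """Multiply each sample column by its scale factor."""
    missing = [s for s in counts.samples if s not in factors.factor_of]
    if missing:
        raise InputError(f"sample(s) missing a scale factor: {missing!r}")
    fac = pd.Series({s: factors.factor_of[s] for s in counts.samples})
    values = counts.counts.astype(float).mul(fac, axis=1)
    return NormalizedMatrix(
        values=values,
        class_of=dict(counts.class_of),
        condition_of=dict(counts.condition_of),
        factors=factors,
    )


def compute_class_totals(norm: NormalizedMatrix) -> ClassTotals:
    """Sum normalized signal per feature class, per sample and per condition.

    Condition-level totals pool replicates by summing their normalized
    per-sample totals.
    """
    cls = norm.class_series()
    per_sample = norm.values.groupby(cls).sum()
    non_spike = per_sample.drop(index="spikein", errors="ignore").sum(axis=0)

    conds = norm.conditions()
    if conds:
        per_condition = pd.DataFrame(
            {c: per_sample[norm.samples_of(c)].sum(axis=1) for c in conds}
        )
        non_spike_cond = pd.Series(
            {c: float(non_spike[norm.samples_of(c)].sum()) for c in conds}
        )
    else:
        per_condition = pd.DataFrame(index=per_sample.index)
        non_spike_cond = pd.Series(dtype=float)
    return ClassTotals(
        per_sample=per_sample,
        per_condition=per_condition,
        total_non_spikein_per_sample=non_spike,
        total_non_spikein_per_condition=non_spike_cond,
    )


def compute_rpkm(
    norm: NormalizedMatrix,
    annotation: AnnotationSet,
    condition: str,
) -> ExpressionSummary:
    """ERCC-anchored RPKM for one condition, used as the expression ranking.

    For gene g::

        rpkm(g) = mean_norm(g) * 1e9 / (length_bp(g) * condition_total)

    where ``mean_norm`` averages the condition's replicate columns and
    ``condition_total`` is the mean per-replicate total of non-spike-in
    normalized reads.  This reduces to standard RPKM when all factors are 1.
    Spike-in rows are excluded.
    """
    reps = norm.samples_of(condition)
    if not reps:
        raise InputError(f"no samples labelled condition {condition!r}")
    cls = norm.class_series()
    genes = norm.values.index[cls != "spikein"]
    lengths = pd.Series(
        {g: annotation[g].length_bp for g in genes}, dtype=float
    )
    if (lengths <= 0).any():
        bad = lengths.index[lengths <= 0][0]
        raise InputError(f"gene {bad!r} has non-positive length")

    sub = norm.values.loc[genes, reps]
    mean_norm = sub.mean(axis=1)
    condition_total = float(sub.sum(axis=0).mean())
    if condition_total <= 0:
        raise InputError(
            f"condition {condition!r} has zero non-spike-in signal"
        )
    rpkm = mean_norm * 1e9 / (lengths * condition_total)

    table = pd.DataFrame(index=genes)
    for c in norm.conditions():
        table[f"mean_norm_{c}"] = norm.values.loc[genes, norm.samples_of(c)].mean(axis=1)
    table["length_bp"] = lengths.astype(int)
    table["rpkm"] = rpkm
    ranked = sorted(genes, key=lambda g: (-rpkm[g], g))
    return ExpressionSummary(table=table, condition=condition, ranked_ids=ranked)
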