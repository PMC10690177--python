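"""One-tail Poisson differential testing of spike-normalized nascent counts.

The test
--------
Raw counts stay integers.  Let ``x_ref`` and ``x_alt`` be the pooled raw
counts of a gene in the two conditions and let ``w_ref``, ``w_alt`` be the
conditions' effective exposures — the pooled spike-in totals, so that a
sample sequenced deeper (larger ERCC total) carries proportionally more
expected counts under the null of no biological change.  If the two pooled
counts are independent Poissons with rates proportional to the exposures,
then conditionally on ``n = x_ref + x_alt`` the alt count is
``Binomial(n, p0)`` with ``p0 = w_alt / (w_ref + w_alt)``.  The one-tail
p-value is the exact binomial tail in the direction of the observed
normalized fold change.  This is the classical exact two-sample Poisson
(conditional binomial) test, performed on raw integers with ERCC-derived
exposures rather than on rescaled non-integer values.

Calling
-------
A gene is differentially expressed when its normalized fold change exceeds
1.5 (or falls below 1/1.5) at Benjamini-Hochberg FDR < 0.05.  Fold change
uses a pseudocount (default 1, in normalized units) to avoid division by
zero.  Spike-in rows are never tested.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import (
    AnalysisConfig,
    AnnotationSet,
    CountMatrix,
    InputError,
    ScaleFactors,
    logger,
)
from .spikein_norm import ExpressionSummary, NormalizedMatrix

__all__ = [
    "DiffResult",
    "ZScoreMatrix",
    "LengthComparison",
    "poisson_two_sample_test",
    "bh_fdr",
    "call_degs",
    "zscore_matrix",
    "rank_and_slice_top",
    "compare_lengths",
]


@dataclass
class DiffResult:
    """Per-gene differential call between reference and perturbed condition."""

    gene: str
    count_ref: int
    count_alt: int
    fc: float
    log2fc: float
    p_value: float
    fdr: float
    call: str                # up | down | unchanged
    mean_expression: float   # mean normalized count across all samples


@dataclass
class ZScoreMatrix:
    """Per-gene z-scores across all samples (mean 0, sample SD 1 per row;
    zero-variance rows are all-zero)."""

    values: pd.DataFrame
    mean: pd.Series
    sd: pd.Series


@dataclass
class LengthComparison:
    """Gene-body lengths of activated / repressed / unchanged genes with
    pairwise two-sided Wilcoxon rank-sum p-values (NaN where a group is
    empty)."""

    lengths_up: list[int]
    lengths_down: list[int]
    lengths_unchanged: list[int]
    p_up_vs_down: float
    p_up_vs_unchanged: float
    p_down_vs_unchanged: float


# ---------------------------------------------------------------------------
# Primitives
# ---------------------------------------------------------------------------

def poisson_two_sample_test(
    x_ref: int,
    x_alt: int,
    s_ref: float,
    s_alt: float,
    tail: str = "greater",
) -> float:
    """Exact conditional (binomial) two-sample Poisson test.

    Parameters
    ----------
    x_ref, x_alt
        Raw integer counts in the reference and alternative condition.
    s_ref, s_alt
        Effective exposure weights (proportional to spike-in totals, i.e.
        to 1/scale-factor); the null expects counts split
        ``p0 = s_alt / (s_ref + s_alt)`` toward alt.
    tail
        ``"greater"``: P(X >= x_alt); ``"less"``: P(X <= x_alt), for
        ``X ~ Binomial(x_ref + x_alt, p0)``.

    Returns a p-value in (0, 1]; ``x_ref = x_alt = 0`` gives 1 (no
    evidence).
    """
    if x_ref < 0 or x_alt < 0:
        raise InputError(f"counts must be non-negative (got {x_ref}, {x_alt})")
    if int(x_ref) != x_ref or int(x_alt) != x_alt:
        raise InputError("counts must be integers")
    if not (s_ref > 0 and s_alt > 0):
        raise InputError(f"exposures must be > 0 (got {s_ref}, {s_alt})")
    n = int(x_ref) + int(x_alt)
    if n == 0:
        return 1.0
    p0 = s_alt / (s_ref + s_alt)
    if tail == "greater":
        p = float(stats.binom.sf(int(x_alt) - 1, n, p0))
    elif tail == "less":
        p = float(stats.binom.cdf(int(x_alt), n, p0))
    else:
        raise InputError(f"tail must be 'greater' or 'less' (got {tail!r})")
    return min(max(p, np.nextafter(0.0, 1.0)), 1.0)


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Input order is preserved; adjusted values are clipped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~(p > 0)) or np.any(p > 1):
        bad = p[(~(p > 0)) | (p > 1)][0]
        raise InputError(f"p-value {bad} outside (0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.empty(n, dtype=float)
    adj[order] = np.minimum(adj_sorted, 1.0)
    return adj


# ---------------------------------------------------------------------------
# DEG calling
# ---------------------------------------------------------------------------

def _resolve_conditions(
    counts: CountMatrix,
    ref_condition: str | None,
    alt_condition: str | None,
) -> tuple[str, str]:
    conds = counts.conditions()
    if len(conds) != 2:
        raise InputError(
            f"differential testing needs exactly 2 conditions, got {conds!r}"
        )
    ref = ref_condition if ref_condition is not None else conds[0]
    alt = alt_condition if alt_condition is not None else [c for c in conds if c != ref][0]
    if ref not in conds or alt not in conds or ref == alt:
        raise InputError(f"bad condition pair ({ref!r}, {alt!r}) among {conds!r}")
    return ref, alt


def call_degs(
    counts: CountMatrix,
    factors: ScaleFactors,
    cfg: AnalysisConfig | None = None,
    ref_condition: str | None = None,
    alt_condition: str | None = None,
    classes: Iterable[str] = ("rdna", "histone", "protein_coding"),
    per_replicate: bool = False,
) -> list[DiffResult]:
    """Call differentially expressed genes between two conditions.

    Replicates are pooled by summing raw counts per condition (Poisson sums
    are Poisson, so the pooled counts are the sufficient statistics); the
    exact one-tail test then uses the pooled spike-in totals as exposures.
    Fold change is computed on ERCC-normalized pooled counts with the
    config pseudocount, the tail follows the direction of the observed
    fold change, and BH adjustment runs jointly across all tested genes.
    Spike-in rows are excluded.

    ``per_replicate=True`` instead tests each replicate pair (paired by
    order within condition) and combines p-values conservatively by
    maximum; requires equal replicate numbers.
    """
    cfg = cfg or AnalysisConfig()
    ref, alt = _resolve_conditions(counts, ref_condition, alt_condition)
    ref_samples = counts.samples_of(ref)
    alt_samples = counts.samples_of(alt)

    keep = [f for f in counts.features if counts.class_of[f] in set(classes)]
    raw = counts.counts.loc[keep]
    x_ref = raw[ref_samples].sum(axis=1).to_numpy()
    x_alt = raw[alt_samples].sum(axis=1).to_numpy()

    # effective exposures: pooled spike-in totals per condition
    w_ref = float(sum(factors.total_of[s] for s in ref_samples))
    w_alt = float(sum(factors.total_of[s] for s in alt_samples))

    fac = pd.Series(factors.factor_of)
    norm = raw.astype(float).mul(fac[raw.columns], axis=1)
    norm_ref = norm[ref_samples].sum(axis=1).to_numpy()
    norm_alt = norm[alt_samples].sum(axis=1).to_numpy()
    pc = cfg.pseudocount
    fc = (norm_alt + pc) / (norm_ref + pc)
    mean_expr = norm.mean(axis=1).to_numpy()

    if per_replicate:
        if len(ref_samples) != len(alt_samples):
            raise InputError(
                "per-replicate testing requires equal replicate numbers"
            )
        pvals = np.ones(len(keep))
        for i, g in enumerate(keep):
            tail = "greater" if fc[i] >= 1 else "less"
            p_pairs = [
                poisson_two_sample_test(
                    int(raw.at[g, rs]), int(raw.at[g, asm]),
                    float(factors.total_of[rs]), float(factors.total_of[asm]),
                    tail,
                )
                for rs, asm in zip(ref_samples, alt_samples)
            ]
            pvals[i] = max(p_pairs)
    else:
        pvals = np.array(
            [
                poisson_two_sample_test(
                    int(x_ref[i]), int(x_alt[i]), w_ref, w_alt,
                    "greater" if fc[i] >= 1 else "less",
                )
                for i in range(len(keep))
            ]
        )

    fdr = bh_fdr(pvals)
    results = []
    for i, g in enumerate(keep):
        if fdr[i] < cfg.fdr_threshold and fc[i] >= cfg.fc_threshold:
            call = "up"
        elif fdr[i] < cfg.fdr_threshold and fc[i] <= 1.0 / cfg.fc_threshold:
            call = "down"
        else:
            call = "unchanged"
        results.append(
            DiffResult(
                gene=g,
                count_ref=int(x_ref[i]),
                count_alt=int(x_alt[i]),
                fc=float(fc[i]),
                log2fc=float(np.log2(fc[i])),
                p_value=float(pvals[i]),
                fdr=float(fdr[i]),
                call=call,
                mean_expression=float(mean_expr[i]),
            )
        )
    n_up = sum(r.call == "up" for r in results)
    n_down = sum(r.call == "down" for r in results)
    logger.info(
        "call_degs: %d genes tested (%s vs %s), %d up, %d down",
        len(results), alt, ref, n_up, n_down,
    )
    return results


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

def zscore_matrix(
    norm: NormalizedMatrix,
    genes: Iterable[str] | None = None,
) -> ZScoreMatrix:
    """Row-wise z-scores: subtract each gene's mean across all samples and
    divide by its sample (n-1) standard deviation; zero-SD rows map to
    all-zero rows."""
    values = norm.values if genes is None else norm.values.loc[list(genes)]
    mean = values.mean(axis=1)
    sd = values.std(axis=1, ddof=1)
    centred = values.sub(mean, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = centred.div(sd, axis=0)
    z[sd == 0] = 0.0
    return ZScoreMatrix(values=z, mean=mean, sd=sd)


def rank_and_slice_top(
    results: Sequence[DiffResult],
    summary: ExpressionSummary,
    n: int = 100,
) -> list[DiffResult]:
    """The top-``n`` differentially expressed genes by control-condition
    RPKM (descending; ties broken lexicographically by gene id)."""
    if n < 1:
        raise InputError(f"n must be >= 1 (got {n})")
    degs = [r for r in results if r.call in ("up", "down")]
    degs.sort(key=lambda r: (-summary.rpkm_of(r.gene), r.gene))
    return degs[:n]


def _ranksum_p(a: Sequence[float], b: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum p: exact for both groups <= 10 and
    tie-free, normal approximation otherwise; degenerate all-equal pooled
    input gives 1."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(a) <= 10 and len(b) <= 10 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=False
    )
    return float(min(res.pvalue, 1.0))


def compare_lengths(
    results: Sequence[DiffResult],
    annotation: AnnotationSet,
    scope: str = "all_degs",
    top_ids: Iterable[str] | None = None,
) -> LengthComparison:
    """Compare gene-body lengths across call groups.

    ``scope="all_degs"`` partitions every tested gene by its call;
    ``scope="top_n"`` restricts to ``top_ids`` (e.g. the ids from
    :func:`rank_and_slice_top`).  Pairs with an empty group report NaN.
    """
    if scope == "top_n":
        if top_ids is None:
            raise InputError("scope='top_n' requires top_ids")
        wanted = set(top_ids)
        pool = [r for r in results if r.gene in wanted]
    elif scope == "all_degs":
        pool = list(results)
    else:
        raise InputError(f"unknown scope {scope!r}")

    groups = {"up": [], "down": [], "unchanged": []}
    for r in pool:
        groups[r.call].append(annotation[r.gene].length_bp)

    def pair(x: list[int], y: list[int]) -> float:
        if not x or not y:
            return float("nan")
        return _ranksum_p(x, y)

    return LengthComparison(
        lengths_up=groups["up"],
        lengths_down=groups["down"],
        lengths_unchanged=groups["unchanged"],
        p_up_vs_down=pair(groups["up"], groups["down"]),
        p_up_vs_unchanged=pair(groups["up"], groups["unchanged"]),
        p_down_vs_unchanged=pair(groups["down"], groups["unchanged"]),
    )
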