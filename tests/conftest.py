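import numpy as np
import pandas as pd
import pytest

from nascentshift import (
    AnnotationSet,
    CountMatrix,
    FeatureAnnotation,
)


@pytest.fixture
def tiny_annotation() -> AnnotationSet:
    """3 genes + 2 spike-ins on one synthetic chromosome."""
    return AnnotationSet(
        [
            FeatureAnnotation("geneA", "chr1", 1000, 2000, "+", 1000, "protein_coding"),
            FeatureAnnotation("geneB", "chr1", 5000, 9000, "-", 4000, "protein_coding"),
            FeatureAnnotation("rdna1", "chr1", 20000, 33000, "+", 13000, "rdna"),
            FeatureAnnotation("ERCC-00002", ".", 0, 1061, ".", 1061, "spikein"),
            FeatureAnnotation("ERCC-00003", ".", 0, 1023, ".", 1023, "spikein"),
        ]
    )


@pytest.fixture
def tiny_counts(tiny_annotation) -> CountMatrix:
    """2 conditions x 1 replicate with equal ERCC totals."""
    df = pd.DataFrame(
        {
            "ctrl_r1": [100, 100, 1000, 60, 40],
            "ir_r1": [200, 40, 500, 70, 30],
        },
        index=["geneA", "geneB", "rdna1", "ERCC-00002", "ERCC-00003"],
    )
    return CountMatrix(
        counts=df,
        class_of=tiny_annotation.class_of(),
        condition_of={"ctrl_r1": "ctrl", "ir_r1": "ir"},
    )


def binom_tail_oracle(x_ref: int, x_alt: int, w_ref: float, w_alt: float,
                      tail: str) -> float:
    """Brute-force enumeration of the conditional binomial tail."""
    from math import comb

    n = x_ref + x_alt
    if n == 0:
        return 1.0
    p0 = w_alt / (w_ref + w_alt)
    if tail == "greater":
        ks = range(x_alt, n + 1)
    else:
        ks = range(0, x_alt + 1)
    return sum(comb(n, k) * p0**k * (1 - p0) ** (n - k) for k in ks)


def bh_oracle(p):
    """Independent sort-based Benjamini-Hochberg: explicit suffix-min loop."""
    import math

    n = len(p)
    order = sorted(range(n), key=lambda i: p[i])
    adj = [0.0] * n
    running = math.inf
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * n / rank)
        adj[i] = min(running, 1.0)
    return adj


def ranksum_exact_oracle(a, b):
    """Two-sided exact Wilcoxon rank-sum by full enumeration of group
    assignments (tie-free inputs)."""
    import itertools

    pooled = sorted(list(a) + list(b))
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    w_obs = sum(ranks[v] for v in a)
    n = len(pooled)
    total = 0
    at_least = 0
    mean_w = len(a) * (n + 1) / 2
    for comb in itertools.combinations(range(1, n + 1), len(a)):
        total += 1
        if abs(sum(comb) - mean_w) >= abs(w_obs - mean_w) - 1e-9:
            at_least += 1
    return at_least / total
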