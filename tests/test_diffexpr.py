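"""Exact Poisson test, BH adjustment, DEG calling and summaries."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nascentshift import (
    AnalysisConfig,
    AnnotationSet,
    CountMatrix,
    FeatureAnnotation,
    InputError,
    bh_fdr,
    call_degs,
    compare_lengths,
    compute_rpkm,
    compute_scale_factors,
    normalize_counts,
    poisson_two_sample_test,
    rank_and_slice_top,
    zscore_matrix,
)
from nascentshift.diffexpr import DiffResult

from conftest import binom_tail_oracle, bh_oracle, ranksum_exact_oracle


# ---------------------------------------------------------------------------
# exact test
# ---------------------------------------------------------------------------

def test_no_counts_gives_p_one():
    assert poisson_two_sample_test(0, 0, 1, 1, "greater") == 1.0
    assert poisson_two_sample_test(0, 0, 1, 1, "less") == 1.0


def test_equal_weight_enumeration_examples():
    # P(X >= 20 | n=30, 1/2) = 53009102 / 2^30
    assert poisson_two_sample_test(10, 20, 1, 1, "greater") == pytest.approx(
        53009102 / 2**30, abs=1e-12
    )
    # P(X >= 5 | n=10, 1/2) = 638/1024
    assert poisson_two_sample_test(5, 5, 1, 1, "greater") == pytest.approx(
        638 / 1024, abs=1e-12
    )


@pytest.mark.parametrize("w_ref,w_alt", [(1, 1), (1, 2), (2, 1)])
def test_small_grid_matches_brute_force(w_ref, w_alt):
    for x_ref, x_alt in itertools.product(range(0, 16), repeat=2):
        for tail in ("greater", "less"):
            got = poisson_two_sample_test(x_ref, x_alt, w_ref, w_alt, tail)
            want = binom_tail_oracle(x_ref, x_alt, w_ref, w_alt, tail)
            assert got == pytest.approx(want, abs=1e-12), (x_ref, x_alt, tail)


@settings(derandomize=True, deadline=None, max_examples=200)
@given(
    st.integers(0, 200), st.integers(0, 200),
    st.floats(0.1, 10), st.floats(0.1, 10),
)
def test_condition_swap_symmetry(x_ref, x_alt, w_ref, w_alt):
    """Swapping conditions and flipping the tail returns the same p."""
    p1 = poisson_two_sample_test(x_ref, x_alt, w_ref, w_alt, "greater")
    p2 = poisson_two_sample_test(x_alt, x_ref, w_alt, w_ref, "less")
    assert p1 == pytest.approx(p2, rel=1e-12)


def test_greater_tail_monotone_in_alt_count():
    ps = [poisson_two_sample_test(10, x, 1.0, 1.0, "greater") for x in range(0, 40)]
    assert all(a >= b for a, b in zip(ps, ps[1:]))


def test_exact_test_contracts():
    with pytest.raises(InputError):
        poisson_two_sample_test(-1, 0, 1, 1, "greater")
    with pytest.raises(InputError):
        poisson_two_sample_test(1, 1, 0, 1, "greater")
    with pytest.raises(InputError):
        poisson_two_sample_test(1, 1, 1, 1, "both")


# ---------------------------------------------------------------------------
# BH
# ---------------------------------------------------------------------------

def test_bh_worked_example_and_degenerate_cases():
    np.testing.assert_allclose(
        bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
    )
    np.testing.assert_allclose(bh_fdr([0.37]), [0.37])
    np.testing.assert_allclose(bh_fdr([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])
    with pytest.raises(InputError):
        bh_fdr([0.5, 0.0])
    with pytest.raises(InputError):
        bh_fdr([1.5])


@settings(derandomize=True, deadline=None, max_examples=100)
@given(st.lists(st.floats(1e-12, 1.0), min_size=1, max_size=200))
def test_bh_matches_independent_oracle_exactly(p):
    got = bh_fdr(p)
    want = bh_oracle(p)
    assert list(got) == want


def test_bh_matches_statsmodels():
    from statsmodels.stats.multitest import multipletests

    rng = np.random.default_rng(11)
    for _ in range(50):
        p = rng.uniform(1e-10, 1, size=rng.integers(1, 300))
        _, want, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(bh_fdr(p), want, rtol=1e-12)


# ---------------------------------------------------------------------------
# DEG calling
# ---------------------------------------------------------------------------

def _toy_matrix():
    """3 genes, equal ERCC totals: up / unchanged / down by construction."""
    df = pd.DataFrame(
        {"ctrl_r1": [100, 100, 100, 1000], "ir_r1": [200, 101, 40, 1000]},
        index=["gene1", "gene2", "gene3", "ERCC-1"],
    )
    class_of = {g: "protein_coding" for g in ["gene1", "gene2", "gene3"]}
    class_of["ERCC-1"] = "spikein"
    return CountMatrix(
        counts=df, class_of=class_of,
        condition_of={"ctrl_r1": "ctrl", "ir_r1": "ir"},
    )


def test_toy_calls_up_unchanged_down():
    m = _toy_matrix()
    factors = compute_scale_factors(m)
    results = {r.gene: r for r in call_degs(m, factors)}
    assert results["gene1"].call == "up"
    assert results["gene2"].call == "unchanged"
    assert results["gene3"].call == "down"
    assert "ERCC-1" not in results
    # fold changes with pseudocount 1 on normalized pooled counts
    assert results["gene1"].fc == pytest.approx(201 / 101)
    assert results["gene2"].fc == pytest.approx(102 / 101)
    assert results["gene3"].fc == pytest.approx(41 / 101)
    # p-values reproduce the enumeration oracle with pooled exposures
    for g, tail in (("gene1", "greater"), ("gene3", "less")):
        want = binom_tail_oracle(
            results[g].count_ref, results[g].count_alt, 1000, 1000, tail
        )
        assert results[g].p_value == pytest.approx(want, rel=1e-12)
    # BH across the three tested genes
    ps = [results[g].p_value for g in ("gene1", "gene2", "gene3")]
    want_fdr = bh_oracle(ps)
    for g, w in zip(("gene1", "gene2", "gene3"), want_fdr):
        assert results[g].fdr == pytest.approx(w, rel=1e-12)


def test_identical_conditions_yield_zero_calls():
    df = pd.DataFrame(
        {"ctrl_r1": [120, 80, 500], "ir_r1": [120, 80, 500]},
        index=["gene1", "gene2", "ERCC-1"],
    )
    m = CountMatrix(
        counts=df,
        class_of={"gene1": "protein_coding", "gene2": "protein_coding",
                  "ERCC-1": "spikein"},
        condition_of={"ctrl_r1": "ctrl", "ir_r1": "ir"},
    )
    results = call_degs(m, compute_scale_factors(m))
    assert all(r.call == "unchanged" for r in results)


def test_more_than_two_conditions_rejected():
    df = pd.DataFrame(
        {"a": [1, 10], "b": [1, 10], "c": [1, 10]}, index=["g", "ERCC-1"]
    )
    m = CountMatrix(
        counts=df,
        class_of={"g": "protein_coding", "ERCC-1": "spikein"},
        condition_of={"a": "x", "b": "y", "c": "z"},
    )
    with pytest.raises(InputError, match="2 conditions"):
        call_degs(m, compute_scale_factors(m))


def test_per_replicate_mode_is_no_less_conservative():
    rng = np.random.default_rng(3)
    genes = [f"g{i}" for i in range(50)]
    idx = genes + ["ERCC-1"]
    cols = {}
    for s, cond in [("ctrl_r1", 1), ("ctrl_r2", 1), ("ir_r1", 2), ("ir_r2", 2)]:
        cols[s] = np.append(rng.poisson(100 * cond, size=50), 5000)
    m = CountMatrix(
        counts=pd.DataFrame(cols, index=idx),
        class_of={**{g: "protein_coding" for g in genes}, "ERCC-1": "spikein"},
        condition_of={"ctrl_r1": "ctrl", "ctrl_r2": "ctrl",
                      "ir_r1": "ir", "ir_r2": "ir"},
    )
    f = compute_scale_factors(m)
    pooled = {r.gene: r.p_value for r in call_degs(m, f)}
    paired = {r.gene: r.p_value for r in call_degs(m, f, per_replicate=True)}
    assert all(paired[g] >= pooled[g] * (1 - 1e-12) for g in genes)


# ---------------------------------------------------------------------------
# z-scores
# ---------------------------------------------------------------------------

def _norm_of(df, class_of, condition_of):
    m = CountMatrix(counts=df, class_of=class_of, condition_of=condition_of)
    return normalize_counts(m, compute_scale_factors(m))


def test_zscore_row_example_and_degenerate_row():
    df = pd.DataFrame(
        [[1, 2, 3, 4], [7, 7, 7, 7], [10, 10, 10, 10]],
        index=["g1", "g2", "ERCC-1"],
        columns=["a", "b", "c", "d"],
    )
    norm = _norm_of(
        df,
        {"g1": "protein_coding", "g2": "protein_coding", "ERCC-1": "spikein"},
        {},
    )
    z = zscore_matrix(norm, ["g1", "g2"])
    np.testing.assert_allclose(
        z.values.loc["g1"], [-1.161895, -0.387298, 0.387298, 1.161895],
        atol=1e-6,
    )
    assert (z.values.loc["g2"] == 0).all()


def test_zscore_rows_standardized():
    rng = np.random.default_rng(5)
    df = pd.DataFrame(
        rng.integers(0, 1000, size=(20, 4)),
        index=[f"g{i}" for i in range(19)] + ["ERCC-1"],
        columns=list("abcd"),
    )
    class_of = {f"g{i}": "protein_coding" for i in range(19)}
    class_of["ERCC-1"] = "spikein"
    z = zscore_matrix(_norm_of(df, class_of, {}))
    nonzero = z.sd > 0
    np.testing.assert_allclose(z.values[nonzero].mean(axis=1), 0, atol=1e-12)
    np.testing.assert_allclose(z.values[nonzero].std(axis=1, ddof=1), 1, atol=1e-12)


# ---------------------------------------------------------------------------
# ranking and length comparison
# ---------------------------------------------------------------------------

def _fake_result(gene, call):
    return DiffResult(gene, 0, 0, 1.0, 0.0, 1.0, 1.0, call, 0.0)


class _FakeSummary:
    def __init__(self, rpkm):
        self._rpkm = rpkm

    def rpkm_of(self, gene):
        return self._rpkm[gene]


def test_rank_and_slice_clamps_and_breaks_ties_lexicographically():
    results = [
        _fake_result("b", "up"), _fake_result("a", "down"),
        _fake_result("c", "up"), _fake_result("d", "unchanged"),
    ]
    summary = _FakeSummary({"a": 5.0, "b": 5.0, "c": 9.0, "d": 100.0})
    top = rank_and_slice_top(results, summary, n=10)
    assert [r.gene for r in top] == ["c", "a", "b"]  # d is not a DEG
    assert [r.gene for r in rank_and_slice_top(results, summary, n=2)] == ["c", "a"]
    with pytest.raises(InputError):
        rank_and_slice_top(results, summary, n=0)


def _length_annotation(lengths):
    feats = []
    pos = 0
    for g, L in lengths.items():
        feats.append(FeatureAnnotation(g, "chr1", pos, pos + L, "+", L,
                                       "protein_coding"))
        pos += L + 100
    return AnnotationSet(feats)


def test_length_comparison_exact_example():
    results = [_fake_result(f"u{i}", "up") for i in range(3)] + [
        _fake_result(f"d{i}", "down") for i in range(3)
    ]
    lengths = {"u0": 1000, "u1": 2000, "u2": 3000, "d0": 100, "d1": 200, "d2": 300}
    ann = _length_annotation(lengths)
    comp = compare_lengths(results, ann)
    # complete separation of 3 vs 3: two-sided p = 2/C(6,3) = 0.1
    assert comp.p_up_vs_down == pytest.approx(0.1)
    assert comp.p_up_vs_down == pytest.approx(
        ranksum_exact_oracle([1000, 2000, 3000], [100, 200, 300])
    )
    assert math.isnan(comp.p_up_vs_unchanged)


def test_length_comparison_identical_groups_p_one():
    results = [_fake_result(f"u{i}", "up") for i in range(3)] + [
        _fake_result(f"d{i}", "down") for i in range(3)
    ]
    lengths = {"u0": 500, "u1": 500, "u2": 500, "d0": 500, "d1": 500, "d2": 500}
    comp = compare_lengths(results, _length_annotation(lengths))
    assert comp.p_up_vs_down == 1.0


def test_length_comparison_matches_enumeration_on_random_tiefree_groups():
    rng = np.random.default_rng(9)
    for _ in range(5):
        vals = rng.choice(np.arange(100, 10000, 7), size=9, replace=False)
        a, b = [int(v) for v in vals[:4]], [int(v) for v in vals[4:]]
        results = [_fake_result(f"u{i}", "up") for i in range(len(a))] + [
            _fake_result(f"d{i}", "down") for i in range(len(b))
        ]
        lengths = {f"u{i}": v for i, v in enumerate(a)}
        lengths.update({f"d{i}": v for i, v in enumerate(b)})
        comp = compare_lengths(results, _length_annotation(lengths))
        assert comp.p_up_vs_down == pytest.approx(ranksum_exact_oracle(a, b))
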