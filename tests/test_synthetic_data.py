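"""Generator contracts: programmed truth, determinism, spike-in behaviour."""

import numpy as np
import pandas as pd
import pytest

from nascentshift import (
    InputError,
    NascentSimConfig,
    build_annotation,
    compute_class_totals,
    compute_scale_factors,
    extract_guides,
    normalize_counts,
    simulate_coverage,
    simulate_guide_fastq,
    simulate_nascent_experiment,
    simulate_screen,
)
from nascentshift.screen import GuideLibrary


def _class_ratio(matrix, cls):
    norm = normalize_counts(matrix, compute_scale_factors(matrix))
    t = compute_class_totals(norm)
    return t.per_condition.at[cls, "ir"] / t.per_condition.at[cls, "ctrl"]


def test_null_configuration_centres_on_no_change():
    cfg = NascentSimConfig(n_protein_coding=2000, rng_seed=42)
    matrix, truth = simulate_nascent_experiment(cfg)
    assert all(fc == 1.0 for fc in truth.true_fc_of.values())
    for cls in ("protein_coding", "rdna", "histone"):
        assert _class_ratio(matrix, cls) == pytest.approx(1.0, rel=0.03)


def test_programmed_rdna_shift_recovered():
    cfg = NascentSimConfig(
        n_protein_coding=500,
        global_shift={"rdna": 0.5, "histone": 1.0, "protein_coding": 1.0},
        rng_seed=7,
    )
    matrix, truth = simulate_nascent_experiment(cfg)
    assert truth.true_fc_of["rdna00001"] == 0.5
    # rdna class expected counts ~2e5 per condition: 5% recovery
    assert _class_ratio(matrix, "rdna") == pytest.approx(0.5, rel=0.05)


def test_same_seed_bitwise_identical_different_seed_not():
    cfg = NascentSimConfig(n_protein_coding=100, rng_seed=5)
    m1, _ = simulate_nascent_experiment(cfg)
    m2, _ = simulate_nascent_experiment(cfg)
    pd.testing.assert_frame_equal(m1.counts, m2.counts)
    cfg2 = NascentSimConfig(n_protein_coding=100, rng_seed=6)
    m3, _ = simulate_nascent_experiment(cfg2)
    assert not m1.counts.equals(m3.counts)


def test_spikeins_track_depth_not_biology():
    """With a strong biological shift and unequal depths, mean ERCC count
    ratio between conditions follows the depth ratio."""
    cfg = NascentSimConfig(
        n_protein_coding=200,
        global_shift={"rdna": 0.3, "histone": 0.3, "protein_coding": 0.3},
        depth_factor_by_sample={"ctrl_r1": 1.0, "ctrl_r2": 1.0,
                                "ir_r1": 2.0, "ir_r2": 2.0},
        rng_seed=11,
    )
    matrix, _ = simulate_nascent_experiment(cfg)
    spikes = matrix.counts.loc[matrix.spikein_features()]
    ratio = (
        spikes[["ir_r1", "ir_r2"]].to_numpy().mean()
        / spikes[["ctrl_r1", "ctrl_r2"]].to_numpy().mean()
    )
    assert ratio == pytest.approx(2.0, rel=0.05)


def test_bad_depth_factor_rejected():
    cfg = NascentSimConfig(n_protein_coding=10,
                           depth_factor_by_sample={"ctrl_r1": 0.0})
    with pytest.raises(InputError, match="depth factor"):
        simulate_nascent_experiment(cfg)


def test_expression_ranked_selection_targets_top_genes():
    cfg = NascentSimConfig(
        n_protein_coding=500, frac_downregulated=0.1, down_fc=0.5,
        selection="expression_ranked", rng_seed=3,
    )
    matrix, truth = simulate_nascent_experiment(cfg)
    ctrl = matrix.counts[["ctrl_r1", "ctrl_r2"]].sum(axis=1)
    pc = [g for g, c in truth.true_class_of.items() if c == "protein_coding"]
    down = [g for g in pc if truth.true_fc_of[g] == 0.5]
    assert len(down) == 50
    null_genes = [g for g in pc if truth.true_fc_of[g] == 1.0]
    assert min(ctrl[g] for g in down) > np.median([ctrl[g] for g in null_genes])


# ---------------------------------------------------------------------------
# coverage
# ---------------------------------------------------------------------------

def _one_gene_annotation(strand="+", length=1000):
    return build_annotation(
        ["geneA"], {"geneA": "protein_coding"}, {"geneA": length},
        strands={"geneA": strand}, gap=4000,
    )


def test_uniform_coverage_covers_every_body_base():
    ann = _one_gene_annotation("+")
    tracks = simulate_coverage(ann, shape="uniform", level=5.0)
    f = ann["geneA"]
    body = tracks["ctrl"].values(f.chrom, f.start, f.end)
    assert (body == 5.0).all()
    assert tracks["ctrl"].values(f.chrom, f.start - 100, f.start).sum() == 0


def test_minus_strand_ramp_increases_left_to_right():
    """5'->3' decreasing ramp on a minus-strand gene must increase in
    genomic coordinates; oracle is explicit base-wise construction."""
    L = 500
    ann = _one_gene_annotation("-", length=L)
    f = ann["geneA"]
    tracks = simulate_coverage(ann, shape="ramp_5to3", level=4.0)
    got = tracks["ctrl"].values(f.chrom, f.start, f.end)
    expected_5to3 = 2.0 * 4.0 * (L - np.arange(L)) / (L + 1)
    np.testing.assert_allclose(got, expected_5to3[::-1])
    assert got[0] < got[-1]


def test_perturbation_factor_halves_body_sum_exactly():
    ann = _one_gene_annotation("+")
    tracks = simulate_coverage(ann, shape="uniform", level=6.0, perturb_factor=0.5)
    f = ann["geneA"]
    s_ref = tracks["ctrl"].region_sum(f.chrom, f.start, f.end)
    s_alt = tracks["ir"].region_sum(f.chrom, f.start, f.end)
    assert s_alt == s_ref / 2


def test_coverage_level_contract():
    ann = _one_gene_annotation()
    with pytest.raises(InputError, match="level"):
        simulate_coverage(ann, level=0.0)


# ---------------------------------------------------------------------------
# screen
# ---------------------------------------------------------------------------

def test_null_screen_abundances_agree():
    table, truth = simulate_screen(
        n_genes=300, n_regulators=0, depth_unsorted=300_000,
        depth_sorted=300_000, seed=2,
    )
    assert truth.true_regulators == set()
    rel_u = table["raw_unsorted"] / table["raw_unsorted"].sum()
    rel_s = table["raw_sorted"] / table["raw_sorted"].sum()
    # no systematic enrichment: mean log-ratio ~ 0
    keep = (table["raw_unsorted"] > 20) & (table["raw_sorted"] > 20)
    assert np.abs(np.log2(rel_s[keep] / rel_u[keep]).mean()) < 0.02


def test_regulator_guides_centre_on_programmed_fold_change():
    table, truth = simulate_screen(
        n_genes=500, n_regulators=10, regulator_guide_fc=4.0,
        guides_affected_per_regulator=3, depth_unsorted=1_000_000,
        depth_sorted=1_000_000, seed=4,
    )
    norm_u = table["raw_unsorted"] / table["raw_unsorted"].sum()
    norm_s = table["raw_sorted"] / table["raw_sorted"].sum()
    affected = table["guide_id"].map(truth.true_guide_fc) == 4.0
    assert affected.sum() == 30
    fcs = (norm_s / norm_u)[affected]
    assert np.median(fcs) == pytest.approx(4.0, rel=0.10)


def test_screen_determinism_and_contracts():
    t1, _ = simulate_screen(n_genes=50, seed=9)
    t2, _ = simulate_screen(n_genes=50, seed=9)
    pd.testing.assert_frame_equal(t1, t2)
    with pytest.raises(InputError):
        simulate_screen(n_genes=10, guides_per_gene=5,
                        guides_affected_per_regulator=6)


# ---------------------------------------------------------------------------
# FASTQ round trip
# ---------------------------------------------------------------------------

A5, A3 = "TTGTGGAAAGGACGAAACACCG", "GTTTTAGAGCTAGAAATAGCAAG"


def test_fastq_emission_and_round_trip(tmp_path):
    table, _ = simulate_screen(n_genes=20, depth_unsorted=5000,
                               depth_sorted=5000, seed=1)
    lib = GuideLibrary(table[["guide_id", "gene", "sequence"]])
    counts_in = dict(zip(table["guide_id"], table["raw_unsorted"]))
    path = tmp_path / "reads.fastq"
    n = simulate_guide_fastq(counts_in, table, A5, A3, path, seed=8)
    assert n == sum(counts_in.values())
    got, unassigned = extract_guides(path, lib, A5, A3)
    assert unassigned == 0
    assert got == {g: int(c) for g, c in counts_in.items()}


def test_empty_table_writes_empty_fastq(tmp_path):
    table, _ = simulate_screen(n_genes=5, n_regulators=0, seed=1)
    path = tmp_path / "empty.fastq"
    n = simulate_guide_fastq({}, table, A5, A3, path)
    assert n == 0 and path.read_text() == ""


def test_unknown_guide_id_rejected(tmp_path):
    table, _ = simulate_screen(n_genes=5, n_regulators=0, seed=1)
    with pytest.raises(InputError, match="not in library"):
        simulate_guide_fastq({"nope_sg1": 3}, table, A5, A3,
                             tmp_path / "x.fastq")
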