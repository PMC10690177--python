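"""Synthetic fixtures with the statistical structure the analysis assumes.

Three generators emulate the study design end to end:

* :func:`simulate_nascent_experiment` — a 2-condition x 2-replicate nascent
  count matrix.  Counts are Poisson around ``baseline x fold-change x
  depth``; spike-in rows feel sequencing depth but not biology (their
  expected counts are condition-independent up to the depth factor), which
  is exactly the property ERCC normalization exploits.  A programmed global
  shift can depress the high-expression classes (rDNA-like, histone-like)
  while elevating moderate/low-expression protein-coding genes.
* :func:`simulate_coverage` — per-base tracks with uniform or 5'->3' ramped
  body profiles, strand-aware, with a body-wide (or 3'-half-only)
  perturbation factor.  Deterministic: the stated shapes are exact.
* :func:`simulate_screen` / :func:`simulate_guide_fastq` — a guide library
  (default 5 guides/gene) with log-normally skewed abundances, an unsorted
  pool and a sorted pool in which designated regulator genes carry enriched
  guides; optionally rendered as FASTQ reads (anchor5 + 20-mer + anchor3 +
  filler) for the extraction round trip.

Every generator returns a :class:`SimTruth` alongside its artifact so that
parameter-recovery tests can compare estimates against programmed values.
RNG streams are spawned per artifact from the config seed via stable
spawn keys, so adding a generator call does not perturb earlier outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import AnnotationSet, CountMatrix, CoverageTrack, FeatureAnnotation, InputError

__all__ = [
    "NascentSimConfig",
    "SimTruth",
    "simulate_nascent_experiment",
    "simulate_coverage",
    "simulate_screen",
    "simulate_guide_fastq",
    "build_annotation",
]

_BASES = np.array(list("ACGT"))


def _rng(seed: int, key: int) -> np.random.Generator:
    """A stable sub-stream: same (seed, key) always yields the same stream."""
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(key,)))


@dataclass
class SimTruth:
    """Ground truth of a simulation, for parameter-recovery tests."""

    true_class_of: dict[str, str] = field(default_factory=dict)
    true_fc_of: dict[str, float] = field(default_factory=dict)
    true_regulators: set[str] = field(default_factory=set)
    true_guide_fc: dict[str, float] = field(default_factory=dict)

    def to_tsv(self, path: str | Path) -> None:
        rows = []
        for f, c in self.true_class_of.items():
            rows.append({"id": f, "kind": "feature", "class": c,
                         "true_fc": self.true_fc_of.get(f, 1.0)})
        for g, fc in self.true_guide_fc.items():
            rows.append({"id": g, "kind": "guide", "class": "", "true_fc": fc})
        for g in sorted(self.true_regulators):
            rows.append({"id": g, "kind": "regulator", "class": "", "true_fc": ""})
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


@dataclass
class NascentSimConfig:
    """Study conditions for the nascent count-matrix simulation.

    The defaults mirror the sequencing design: two conditions ("ctrl" and
    "ir") with two replicates each, 92 spike-ins, a small number of
    rDNA-like features dominating the read mass, histone-like genes, and a
    protein-coding majority.  ``global_shift`` multiplies every gene of a
    class in the perturbed condition; ``frac_upregulated``/``up_fc`` (and
    the symmetric down fields) program gene-level effects on protein-coding
    genes.  With ``selection="expression_ranked"`` the down-set is the most
    highly expressed protein-coding genes and the up-set is drawn from the
    remainder — the expression-dependence the radiation response showed;
    ``"random"`` decouples effect from expression.
    """

    n_protein_coding: int = 2000
    n_histone: int = 60
    n_rdna: int = 20
    n_spikein: int = 92
    baseline_mean_by_class: Mapping[str, float] = field(
        default_factory=lambda: {
            "protein_coding": 50.0,
            "histone": 500.0,
            "rdna": 5000.0,
            "spikein": 500.0,
        }
    )
    rdna_fraction_target: float | None = None
    global_shift: Mapping[str, float] = field(
        default_factory=lambda: {"protein_coding": 1.0, "histone": 1.0, "rdna": 1.0}
    )
    frac_upregulated: float = 0.0
    up_fc: float = 2.0
    frac_downregulated: float = 0.0
    down_fc: float = 0.5
    selection: str = "expression_ranked"
    n_replicates: int = 2
    depth_factor_by_sample: Mapping[str, float] | None = None
    baseline_log10_spread: float = 0.5
    overdispersion: float | None = None   # NB size parameter; None = pure Poisson
    rng_seed: int = 0
    conditions: tuple[str, str] = ("ctrl", "ir")

    def __post_init__(self) -> None:
        for cls, m in self.global_shift.items():
            if not m > 0:
                raise InputError(f"global_shift[{cls!r}] must be > 0")
        for name in ("frac_upregulated", "frac_downregulated"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise InputError(f"{name} must lie in [0, 1]")
        if self.n_replicates < 1:
            raise InputError("n_replicates must be >= 1")
        if not self.up_fc > 0 or not self.down_fc > 0:
            raise InputError("programmed fold changes must be > 0")
        if self.selection not in ("expression_ranked", "random"):
            raise InputError(f"unknown selection mode {self.selection!r}")

    def sample_names(self) -> list[str]:
        return [
            f"{cond}_r{i + 1}"
            for cond in self.conditions
            for i in range(self.n_replicates)
        ]


def simulate_nascent_experiment(
    cfg: NascentSimConfig,
) -> tuple[CountMatrix, SimTruth]:
    """Draw a nascent count matrix under the configured conditions.

    Each count is Poisson with mean ``baseline(g) x fc(g, condition) x
    depth_factor(sample)``.  Gene baselines are log-uniform within class
    (width ``baseline_log10_spread`` decades around the class mean) so an
    expression ranking exists.  Spike-in means never carry a biological
    fold change.  Identical seed -> identical matrix.
    """
    rng = _rng(cfg.rng_seed, 1)
    samples = cfg.sample_names()
    depth = dict.fromkeys(samples, 1.0)
    if cfg.depth_factor_by_sample:
        depth.update(cfg.depth_factor_by_sample)
    for s, d in depth.items():
        if not d > 0:
            raise InputError(f"depth factor for sample {s!r} must be > 0")

    n_by_class = {
        "rdna": cfg.n_rdna,
        "histone": cfg.n_histone,
        "protein_coding": cfg.n_protein_coding,
        "spikein": cfg.n_spikein,
    }
    ids: list[str] = []
    classes: list[str] = []
    baselines: list[np.ndarray] = []
    prefix = {"rdna": "rdna", "histone": "hist", "protein_coding": "gene",
              "spikein": "ERCC-"}
    for cls in ("rdna", "histone", "protein_coding", "spikein"):
        n = n_by_class[cls]
        ids += [f"{prefix[cls]}{i + 1:05d}" for i in range(n)]
        classes += [cls] * n
        spread = cfg.baseline_log10_spread
        base = cfg.baseline_mean_by_class[cls] * 10 ** rng.uniform(
            -spread / 2, spread / 2, size=n
        )
        baselines.append(base)
    baseline = np.concatenate(baselines) if baselines else np.empty(0)
    classes_arr = np.array(classes)

    if cfg.rdna_fraction_target is not None:
        non_spike = classes_arr != "spikein"
        rdna = classes_arr == "rdna"
        other = non_spike & ~rdna
        t = cfg.rdna_fraction_target
        if not (0 < t < 1):
            raise InputError("rdna_fraction_target must lie in (0, 1)")
        cur_rdna = baseline[rdna].sum()
        cur_other = baseline[other].sum()
        if cur_rdna > 0 and cur_other > 0:
            baseline = baseline.copy()
            baseline[rdna] *= (t / (1 - t)) * cur_other / cur_rdna

    # per-gene biological fold change in the perturbed condition
    fc = np.array([cfg.global_shift.get(c, 1.0) if c != "spikein" else 1.0
                   for c in classes], dtype=float)
    pc_idx = np.flatnonzero(classes_arr == "protein_coding")
    n_down = int(round(cfg.frac_downregulated * len(pc_idx)))
    n_up = int(round(cfg.frac_upregulated * len(pc_idx)))
    if n_down + n_up > len(pc_idx):
        raise InputError("frac_upregulated + frac_downregulated exceed 1")
    if cfg.selection == "expression_ranked":
        ranked = pc_idx[np.argsort(-baseline[pc_idx], kind="stable")]
        down_idx = ranked[:n_down]
        rest = ranked[n_down:]
        up_idx = rng.choice(rest, size=n_up, replace=False) if n_up else rest[:0]
    else:
        chosen = rng.choice(pc_idx, size=n_down + n_up, replace=False)
        down_idx, up_idx = chosen[:n_down], chosen[n_down:]
    fc[down_idx] *= cfg.down_fc
    fc[up_idx] *= cfg.up_fc

    counts = np.empty((len(ids), len(samples)), dtype=np.int64)
    for j, s in enumerate(samples):
        cond = next(c for c in cfg.conditions if s.startswith(c + "_"))
        bio = fc if cond == cfg.conditions[1] else np.ones_like(fc)
        mean = baseline * bio * depth[s]
        if cfg.overdispersion is None:
            counts[:, j] = rng.poisson(mean)
        else:
            size = cfg.overdispersion
            lam = rng.gamma(shape=size, scale=mean / size)
            counts[:, j] = rng.poisson(lam)

    df = pd.DataFrame(counts, index=ids, columns=samples)
    condition_of = {
        s: next(c for c in cfg.conditions if s.startswith(c + "_"))
        for s in samples
    }
    matrix = CountMatrix(
        counts=df,
        class_of=dict(zip(ids, classes)),
        condition_of=condition_of,
    )
    truth = SimTruth(
        true_class_of=dict(zip(ids, classes)),
        true_fc_of={g: float(fc[i]) for i, g in enumerate(ids)},
    )
    return matrix, truth


def build_annotation(
    feature_ids: Sequence[str],
    class_of: Mapping[str, str],
    length_of: Mapping[str, int],
    strands: Mapping[str, str] | None = None,
    chrom: str = "chrSim",
    gap: int = 1000,
) -> AnnotationSet:
    """Lay features end to end on a synthetic chromosome.

    Spike-in features get the sentinel chromosome "." at 0..length.  All
    other features are placed with ``gap`` bp between bodies on ``chrom``,
    strand from ``strands`` (default ``+``).
    """
    feats = []
    pos = gap
    for fid in feature_ids:
        cls = class_of[fid]
        L = int(length_of[fid])
        if cls == "spikein":
            feats.append(FeatureAnnotation(fid, ".", 0, L, ".", L, cls))
            continue
        strand = (strands or {}).get(fid, "+")
        feats.append(FeatureAnnotation(fid, chrom, pos, pos + L, strand, L, cls))
        pos += L + gap
    return AnnotationSet(feats)


def simulate_coverage(
    annotation: AnnotationSet,
    shape: str = "uniform",
    level: float = 5.0,
    perturb_factor: float = 1.0,
    perturb_region: str = "body",
    conditions: tuple[str, str] = ("ctrl", "ir"),
    seed: int = 0,
) -> dict[str, CoverageTrack]:
    """Deterministic per-condition coverage tracks over annotated bodies.

    ``uniform``: constant ``level`` on each body base.  ``ramp_5to3``:
    linearly decreasing in transcription orientation, from ``2*level*L/(L+1)``
    at the 5'-most base toward 0, mean exactly ``level`` (strand-aware: on
    the minus strand genomic-coordinate coverage increases left to right).
    The perturbed (second) condition multiplies ``perturb_region`` (whole
    body, or its 3' half only) by ``perturb_factor``.  Flanks are
    uncovered.  The tracks are noise-free so the stated shapes hold
    exactly; ``seed`` is accepted for interface stability.
    """
    del seed
    if not level > 0:
        raise InputError(f"level must be > 0 (got {level})")
    if not perturb_factor > 0:
        raise InputError(f"perturb_factor must be > 0 (got {perturb_factor})")
    if shape not in ("uniform", "ramp_5to3"):
        raise InputError(f"unknown coverage shape {shape!r}")
    if perturb_region not in ("body", "three_prime_half"):
        raise InputError(f"unknown perturb_region {perturb_region!r}")

    dense: dict[str, dict[str, np.ndarray]] = {c: {} for c in conditions}
    chrom_len: dict[str, int] = {}
    genes = [f for f in annotation if f.feature_class != "spikein"]
    for f in genes:
        chrom_len[f.chrom] = max(chrom_len.get(f.chrom, 0), f.end)
    for cond in conditions:
        for chromname, L in chrom_len.items():
            dense[cond][chromname] = np.zeros(L, dtype=float)

    for f in genes:
        L = f.end - f.start
        if shape == "uniform":
            body = np.full(L, level, dtype=float)  # 5'->3' orientation
        else:
            body = 2.0 * level * (L - np.arange(L)) / (L + 1)
        for ci, cond in enumerate(conditions):
            b = body.copy()
            if ci == 1:
                if perturb_region == "body":
                    b *= perturb_factor
                else:
                    b[L - L // 2:] *= perturb_factor  # 3' half, 5'->3' frame
            genomic = b if f.strand == "+" else b[::-1]
            dense[cond][f.chrom][f.start:f.end] = genomic

    return {c: CoverageTrack.from_dense(dense[c]) for c in conditions}


# ---------------------------------------------------------------------------
# CRISPR screen fixtures
# ---------------------------------------------------------------------------

def _random_unique_kmers(rng: np.random.Generator, n: int, k: int = 20) -> list[str]:
    seqs: set[str] = set()
    out: list[str] = []
    while len(out) < n:
        block = rng.integers(0, 4, size=(n - len(out), k))
        for row in block:
            s = "".join(_BASES[row])
            if s not in seqs:
                seqs.add(s)
                out.append(s)
    return out


def simulate_screen(
    n_genes: int = 2000,
    guides_per_gene: int = 5,
    n_regulators: int = 20,
    regulator_guide_fc: float = 4.0,
    guides_affected_per_regulator: int = 3,
    depth_unsorted: int = 1_000_000,
    depth_sorted: int = 1_000_000,
    library_sigma: float = 0.5,
    seed: int = 0,
) -> tuple[pd.DataFrame, SimTruth]:
    """Simulate a sorted-vs-unsorted pooled knockout screen.

    The library is log-normally skewed (``library_sigma`` on the natural
    log scale).  Unsorted counts are Poisson at ``depth_unsorted`` times
    each guide's relative abundance; sorted counts multiply regulator
    guides' relative abundance by ``regulator_guide_fc`` (for
    ``guides_affected_per_regulator`` of each regulator's guides),
    renormalize to sum 1 and draw Poisson at ``depth_sorted``.

    Returns a table with columns ``guide_id, gene, sequence,
    raw_unsorted, raw_sorted`` and the ground truth.
    """
    if guides_affected_per_regulator > guides_per_gene:
        raise InputError(
            "guides_affected_per_regulator cannot exceed guides_per_gene"
        )
    if n_regulators > n_genes:
        raise InputError("n_regulators cannot exceed n_genes")
    rng = _rng(seed, 2)

    genes = [f"gene{i + 1:05d}" for i in range(n_genes)]
    guide_ids = [
        f"{g}_sg{k + 1}" for g in genes for k in range(guides_per_gene)
    ]
    sequences = _random_unique_kmers(rng, len(guide_ids))
    gene_of = np.repeat(np.arange(n_genes), guides_per_gene)

    regulators = rng.choice(n_genes, size=n_regulators, replace=False)
    guide_fc = np.ones(len(guide_ids))
    for gi in regulators:
        first = gi * guides_per_gene
        affected = rng.choice(
            guides_per_gene, size=guides_affected_per_regulator, replace=False
        )
        guide_fc[first + affected] = regulator_guide_fc

    skew = rng.lognormal(mean=0.0, sigma=library_sigma, size=len(guide_ids))
    abund_unsorted = skew / skew.sum()
    weighted = abund_unsorted * guide_fc
    abund_sorted = weighted / weighted.sum()

    raw_unsorted = rng.poisson(depth_unsorted * abund_unsorted)
    raw_sorted = rng.poisson(depth_sorted * abund_sorted)

    table = pd.DataFrame(
        {
            "guide_id": guide_ids,
            "gene": [genes[i] for i in gene_of],
            "sequence": sequences,
            "raw_unsorted": raw_unsorted.astype(np.int64),
            "raw_sorted": raw_sorted.astype(np.int64),
        }
    )
    truth = SimTruth(
        true_regulators={genes[i] for i in regulators},
        true_guide_fc=dict(zip(guide_ids, guide_fc.astype(float))),
    )
    return table, truth


def simulate_guide_fastq(
    counts: Mapping[str, int],
    library: pd.DataFrame,
    anchor5: str,
    anchor3: str,
    path: str | Path,
    seed: int = 0,
    read_length: int = 75,
) -> int:
    """Write one FASTQ read per counted guide instance.

    Each read is ``anchor5 + guide 20-mer + anchor3`` padded with random
    bases to ``read_length``; read order is shuffled by ``seed``.  Returns
    the number of reads written.  A guide id absent from ``library``
    (columns ``guide_id``, ``sequence``) is a hard error.
    """
    rng = _rng(seed, 3)
    seq_of = dict(zip(library["guide_id"], library["sequence"]))
    missing = [g for g in counts if g not in seq_of]
    if missing:
        raise InputError(f"guide id(s) not in library: {missing[:5]!r}")

    guide_list = list(counts)
    reps = np.array([int(counts[g]) for g in guide_list], dtype=np.int64)
    if np.any(reps < 0):
        raise InputError("guide counts must be non-negative")
    expanded = np.repeat(np.arange(len(guide_list)), reps)
    rng.shuffle(expanded)

    core_len = len(anchor5) + 20 + len(anchor3)
    pad = max(read_length - core_len, 0)
    n_total = int(expanded.size)
    written = 0
    chunk = 100_000
    with open(path, "w") as fh:
        for lo in range(0, n_total, chunk):
            idx = expanded[lo:lo + chunk]
            fillers = rng.integers(0, 4, size=(len(idx), pad)) if pad else None
            lines: list[str] = []
            for k, gi in enumerate(idx):
                seq = anchor5 + seq_of[guide_list[gi]] + anchor3
                if pad:
                    seq += "".join(_BASES[fillers[k]])
                lines.append(
                    f"@read{written + k + 1}\n{seq}\n+\n{'I' * len(seq)}\n"
                )
            fh.write("".join(lines))
            written += len(idx)
    return written
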