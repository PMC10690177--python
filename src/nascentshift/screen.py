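"""Pooled CRISPR screen arm: guide extraction, normalization, enrichment.

The screen sorts the cells with the most nascent-RNA signal (EU-high, the
top decile) after irradiation and asks which knockouts let transcription
keep running: guides against the responsible factors are over-represented
in the sorted pool relative to the unsorted population.

Scoring follows the printed recipe:

* ``normalized reads per gRNA = raw / population_total * 1e6 + 1`` (reads
  per million with a +1 floor), applied independently per population;
* ``fc = norm_sorted / norm_unsorted`` and
  ``CRISPR score = log2(fc)``;
* the p-value is the same exact two-sample Poisson (conditional binomial)
  test used for genes, on raw counts with population totals as exposures,
  tail fixed to enrichment; BH adjustment runs jointly across all guides;
* a gene is a hit when at least one of its guides has adjusted p <= 0.01
  and fc >= 1.5.

Guide extraction is exact-match only: the 20-mer between the two anchor
sequences must match a library sequence verbatim; everything else counts
as unassigned.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import IO, Mapping

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .core_io import FLOAT_FORMAT, AnalysisConfig, InputError, logger
from .diffexpr import bh_fdr, poisson_two_sample_test

__all__ = [
    "GuideLibrary",
    "GuideCounts",
    "read_guide_library",
    "extract_guides",
    "normalize_guide_counts",
    "score_guides",
    "call_hit_genes",
]


@dataclass
class GuideLibrary:
    """The guide library: one row per guide (guide_id, gene, 20-nt sequence).

    Sequences must be unique — extraction is an exact dictionary match.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["guide_id", "gene", "sequence"]
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise InputError(f"guide library missing column(s) {missing}")
        if self.table["guide_id"].duplicated().any():
            dup = self.table.loc[self.table["guide_id"].duplicated(), "guide_id"].iloc[0]
            raise InputError(f"duplicate guide_id {dup!r} in library")
        if self.table["sequence"].duplicated().any():
            dup = self.table.loc[self.table["sequence"].duplicated(), "sequence"].iloc[0]
            raise InputError(f"duplicate guide sequence {dup!r} in library")
        badlen = self.table.loc[self.table["sequence"].str.len() != 20, "guide_id"]
        if len(badlen):
            raise InputError(
                f"guide {badlen.iloc[0]!r}: sequence must be 20 nt"
            )

    @property
    def guide_ids(self) -> list[str]:
        return self.table["guide_id"].tolist()

    def gene_of(self) -> dict[str, str]:
        return dict(zip(self.table["guide_id"], self.table["gene"]))

    def sequence_to_guide(self) -> dict[str, str]:
        return dict(zip(self.table["sequence"], self.table["guide_id"]))


def read_guide_library(path: str | Path) -> GuideLibrary:
    """Read a TSV with columns guide_id, gene, sequence."""
    return GuideLibrary(pd.read_csv(path, sep="\t", dtype=str))


@dataclass
class GuideCounts:
    """Raw guide counts for the two screen populations.

    ``table`` is indexed by guide_id with columns ``raw_unsorted`` and
    ``raw_sorted``; population totals are the per-guide sums (unassigned
    reads are tracked separately and excluded from normalization totals,
    matching "total reads for all sgRNAs in sample").
    """

    table: pd.DataFrame
    unassigned_unsorted: int = 0
    unassigned_sorted: int = 0

    def __post_init__(self) -> None:
        for col in ("raw_unsorted", "raw_sorted"):
            if col not in self.table.columns:
                raise InputError(f"guide counts missing column {col!r}")
            if (self.table[col] < 0).any():
                raise InputError(f"negative guide count in {col}")

    @property
    def total_unsorted(self) -> int:
        return int(self.table["raw_unsorted"].sum())

    @property
    def total_sorted(self) -> int:
        return int(self.table["raw_sorted"].sum())

    @classmethod
    def from_populations(
        cls,
        library: GuideLibrary,
        unsorted_counts: Mapping[str, int],
        sorted_counts: Mapping[str, int],
        unassigned_unsorted: int = 0,
        unassigned_sorted: int = 0,
    ) -> "GuideCounts":
        idx = library.guide_ids
        table = pd.DataFrame(
            {
                "raw_unsorted": [int(unsorted_counts.get(g, 0)) for g in idx],
                "raw_sorted": [int(sorted_counts.get(g, 0)) for g in idx],
            },
            index=pd.Index(idx, name="guide_id"),
        )
        return cls(table, unassigned_unsorted, unassigned_sorted)


def extract_guides(
    reads: str | Path | IO[str],
    library: GuideLibrary,
    anchor5: str,
    anchor3: str,
) -> tuple[dict[str, int], int]:
    """Count exact guide matches in a FASTQ stream (one population).

    For each read: locate the first occurrence of ``anchor5``, take the
    following 20 nt as the candidate guide and require ``anchor3`` to
    follow immediately; an exact library match increments that guide,
    anything else (missing anchors, truncated or unknown 20-mer) counts as
    unassigned.  Returns ``(counts_by_guide_id, n_unassigned)``.
    """
    if not anchor5 or not anchor3:
        raise InputError("anchors must be non-empty")
    seq2guide = library.sequence_to_guide()
    counts: dict[str, int] = dict.fromkeys(library.guide_ids, 0)
    unassigned = 0
    a5len = len(anchor5)

    def _scan(handle: IO[str]) -> None:
        nonlocal unassigned
        for _title, seq, _qual in FastqGeneralIterator(handle):
            i = seq.find(anchor5)
            if i < 0:
                unassigned += 1
                continue
            start = i + a5len
            candidate = seq[start:start + 20]
            if len(candidate) < 20 or not seq.startswith(anchor3, start + 20):
                unassigned += 1
                continue
            guide = seq2guide.get(candidate)
            if guide is None:
                unassigned += 1
            else:
                counts[guide] += 1

    if hasattr(reads, "read"):
        _scan(reads)  # type: ignore[arg-type]
    else:
        with open(reads) as fh:
            _scan(fh)
    logger.info(
        "extract_guides: %d assigned, %d unassigned",
        sum(counts.values()), unassigned,
    )
    return counts, unassigned


def normalize_guide_counts(counts: GuideCounts) -> pd.DataFrame:
    """Reads-per-million-plus-one, independently per population:
    ``normalized = raw / population_total * 1e6 + 1``."""
    out = pd.DataFrame(index=counts.table.index)
    for pop, total in (
        ("unsorted", counts.total_unsorted),
        ("sorted", counts.total_sorted),
    ):
        if total <= 0:
            raise InputError(f"zero total reads in {pop} population")
        out[f"norm_{pop}"] = counts.table[f"raw_{pop}"] / total * 1e6 + 1.0
    return out


def score_guides(counts: GuideCounts, library: GuideLibrary | None = None) -> pd.DataFrame:
    """Per-guide enrichment of the sorted over the unsorted population.

    Columns: raw and normalized abundances, ``fc`` (normalized ratio),
    ``crispr_score = log2(fc)``, exact one-tail Poisson ``p_value``
    (enrichment direction) with population totals as exposures, and BH
    ``padj`` across all guides.
    """
    norm = normalize_guide_counts(counts)
    df = counts.table.join(norm)
    if library is not None:
        gene_of = library.gene_of()
        unknown = [g for g in df.index if g not in gene_of]
        if unknown:
            raise InputError(f"guide(s) not in library: {unknown[:5]!r}")
        df.insert(0, "gene", [gene_of[g] for g in df.index])
    df["fc"] = df["norm_sorted"] / df["norm_unsorted"]
    df["crispr_score"] = np.log2(df["fc"])
    w_ref = float(counts.total_unsorted)
    w_alt = float(counts.total_sorted)
    df["p_value"] = [
        poisson_two_sample_test(int(xu), int(xs), w_ref, w_alt, "greater")
        for xu, xs in zip(df["raw_unsorted"], df["raw_sorted"])
    ]
    df["padj"] = bh_fdr(df["p_value"].to_numpy())
    return df


def call_hit_genes(
    enrichments: pd.DataFrame,
    library: GuideLibrary,
    cfg: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Gene-level hit calling: a gene is a hit when at least one of its
    guides passes ``padj <= guide_padj_threshold`` and
    ``fc >= guide_fc_threshold``.

    Returns one row per library gene: ``n_guides_passing``, ``best_padj``
    (smallest), ``best_fc`` (largest), ``is_hit``.
    """
    cfg = cfg or AnalysisConfig()
    gene_of = library.gene_of()
    unknown = [g for g in enrichments.index if g not in gene_of]
    if unknown:
        raise InputError(f"guide(s) with unknown gene: {unknown[:5]!r}")
    df = enrichments.copy()
    df["gene"] = [gene_of[g] for g in df.index]
    df["passes"] = (df["padj"] <= cfg.guide_padj_threshold) & (
        df["fc"] >= cfg.guide_fc_threshold
    )
    grouped = df.groupby("gene", sort=True)
    out = pd.DataFrame(
        {
            "n_guides_passing": grouped["passes"].sum().astype(int),
            "best_padj": grouped["padj"].min(),
            "best_fc": grouped["fc"].max(),
        }
    )
    out["is_hit"] = out["n_guides_passing"] >= 1
    out.index.name = "gene"
    n_hits = int(out["is_hit"].sum())
    logger.info("call_hit_genes: %d hit gene(s) of %d", n_hits, len(out))
    return out
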