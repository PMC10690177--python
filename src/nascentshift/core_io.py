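"""Shared domain types, file formats, configuration and logging.

The pipeline quantifies genome-wide shifts in nascent transcription
(metabolically labelled RNA) between two conditions.  Because a global
change in transcription is invisible to library-size normalization, every
count table carries ERCC spike-in rows: synthetic RNA standards added in a
fixed amount per cell-equivalent, whose totals anchor all between-sample
scaling.

Everything downstream consumes the containers defined here:

* :class:`FeatureAnnotation` / :class:`AnnotationSet` — gene coordinates,
  strand, length and a feature class (``rdna``, ``histone``,
  ``protein_coding`` or ``spikein``).
* :class:`CountMatrix` — raw integer counts, features x samples, with a
  condition label per sample and a class per feature.
* :class:`ScaleFactors` — per-sample multipliers derived from spike-in
  totals.
* :class:`CoverageTrack` — sparse per-base coverage (bedGraph semantics).
* :class:`AnalysisConfig` — the thresholds and binning parameters used by
  the differential, screen and metagene stages.

Coordinates are 0-based half-open throughout (BED convention); GTF input is
converted on read.  Gene length is the annotated gene-body span
(``end - start``), not summed exon length — nascent transcription covers
introns, and the span is what coverage profiling operates on.
"""

from __future__ import annotations

import logging
import re
import sys
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FEATURE_CLASSES",
    "InputError",
    "FeatureAnnotation",
    "AnnotationSet",
    "CountMatrix",
    "ScaleFactors",
    "CoverageTrack",
    "AnalysisConfig",
    "read_annotation",
    "read_count_matrix",
    "read_design",
    "read_bedgraph",
    "write_bedgraph",
    "write_results_table",
    "read_results_table",
    "setup_logging",
    "logger",
]

FEATURE_CLASSES = frozenset({"rdna", "histone", "protein_coding", "spikein"})

#: Fixed float precision for all written tables: 6 significant digits, so
#: that diffs are reproducible and a write/read round trip is lossless at
#: the stated precision.
FLOAT_FORMAT = "%.6g"

logger = logging.getLogger("nascentshift")


class InputError(ValueError):
    """Malformed or contract-violating input; message names the offender."""


def setup_logging(level: str = "INFO") -> None:
    """Route package logs to stderr with timestamps (idempotent)."""
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(
        logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s")
    )
    logger.handlers.clear()
    logger.addHandler(handler)
    logger.setLevel(level.upper())


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FeatureAnnotation:
    """One annotated feature.

    ``start``/``end`` are 0-based half-open genomic coordinates;
    ``length_bp`` is the gene-body span ``end - start``.  Spike-in features
    need no genomic placement: their ``chrom`` may be the sentinel ``"."``
    and strand ``"."`` is tolerated for them only.
    """

    feature_id: str
    chrom: str
    start: int
    end: int
    strand: str
    length_bp: int
    feature_class: str

    def __post_init__(self) -> None:
        if self.feature_class not in FEATURE_CLASSES:
            raise InputError(
                f"unknown feature class {self.feature_class!r} for "
                f"{self.feature_id!r} (expected one of {sorted(FEATURE_CLASSES)})"
            )
        if self.end <= self.start:
            raise InputError(
                f"feature {self.feature_id!r}: end ({self.end}) must exceed "
                f"start ({self.start})"
            )
        if self.length_bp <= 0:
            raise InputError(f"feature {self.feature_id!r}: length_bp must be > 0")
        if self.strand not in ("+", "-"):
            if not (self.strand == "." and self.feature_class == "spikein"):
                raise InputError(
                    f"feature {self.feature_id!r}: strand must be '+' or '-' "
                    f"(got {self.strand!r}); strand is required for metagene "
                    "profiling"
                )


class AnnotationSet:
    """An ordered, id-unique collection of :class:`FeatureAnnotation`."""

    def __init__(self, features: Iterable[FeatureAnnotation]):
        self._features: dict[str, FeatureAnnotation] = {}
        for f in features:
            if f.feature_id in self._features:
                raise InputError(f"duplicate feature_id {f.feature_id!r}")
            self._features[f.feature_id] = f

    def __len__(self) -> int:
        return len(self._features)

    def __iter__(self) -> Iterator[FeatureAnnotation]:
        return iter(self._features.values())

    def __contains__(self, feature_id: str) -> bool:
        return feature_id in self._features

    def __getitem__(self, feature_id: str) -> FeatureAnnotation:
        try:
            return self._features[feature_id]
        except KeyError:
            raise KeyError(f"feature {feature_id!r} not in annotation") from None

    @property
    def ids(self) -> list[str]:
        return list(self._features)

    def class_of(self) -> dict[str, str]:
        return {f.feature_id: f.feature_class for f in self}

    def length_of(self) -> dict[str, int]:
        return {f.feature_id: f.length_bp for f in self}

    def subset(self, feature_ids: Iterable[str]) -> "AnnotationSet":
        return AnnotationSet(self[i] for i in feature_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (f.feature_id, f.chrom, f.start, f.end, f.strand, f.length_bp,
                 f.feature_class)
                for f in self
            ],
            columns=["feature_id", "chrom", "start", "end", "strand",
                     "length_bp", "class"],
        )

    def to_tsv(self, path: str | Path) -> None:
        df = self.to_frame().drop(columns="length_bp")
        df.to_csv(path, sep="\t", index=False)


_GENE_ID_RE = re.compile(r'gene_id\s+"([^"]+)"')


def _read_annotation_tsv(path: str | Path) -> AnnotationSet:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    except Exception as exc:  # noqa: BLE001 - rewrap with path context
        raise InputError(f"cannot parse annotation TSV {path}: {exc}") from exc
    required = ["feature_id", "chrom", "start", "end", "strand", "class"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise InputError(
            f"annotation TSV {path} missing column(s) {missing}; "
            f"expected {required}"
        )
    feats = []
    for lineno, row in enumerate(df.to_dict("records"), start=2):
        try:
            start, end = int(row["start"]), int(row["end"])
        except ValueError as exc:
            raise InputError(
                f"{path} line {lineno}: non-integer coordinate ({exc})"
            ) from exc
        try:
            feats.append(
                FeatureAnnotation(
                    feature_id=row["feature_id"],
                    chrom=row["chrom"],
                    start=start,
                    end=end,
                    strand=row["strand"],
                    length_bp=end - start,
                    feature_class=row["class"],
                )
            )
        except InputError as exc:
            raise InputError(f"{path} line {lineno}: {exc}") from exc
    return AnnotationSet(feats)


def _read_annotation_gtf(
    path: str | Path,
    class_map: Mapping[str, str] | None,
    default_class: str,
) -> AnnotationSet:
    feats = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise InputError(
                    f"{path} line {lineno}: expected 9 tab-separated GTF "
                    f"columns, got {len(parts)}"
                )
            _, _, feature, start_s, end_s, _, strand, _, attrs = parts
            if feature != "gene":
                continue
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError as exc:
                raise InputError(
                    f"{path} line {lineno}: non-integer coordinate"
                ) from exc
            m = _GENE_ID_RE.search(attrs)
            if m is None:
                raise InputError(f"{path} line {lineno}: no gene_id attribute")
            gene_id = m.group(1)
            cls = (class_map or {}).get(gene_id, default_class)
            # GTF is 1-based inclusive; convert to 0-based half-open.
            start0, end0 = start1 - 1, end1
            try:
                feats.append(
                    FeatureAnnotation(
                        feature_id=gene_id,
                        chrom=parts[0],
                        start=start0,
                        end=end0,
                        strand=strand,
                        length_bp=end0 - start0,
                        feature_class=cls,
                    )
                )
            except InputError as exc:
                raise InputError(f"{path} line {lineno}: {exc}") from exc
    return AnnotationSet(feats)


def read_annotation(
    path: str | Path,
    dialect: str = "tsv",
    class_map: Mapping[str, str] | None = None,
    default_class: str = "protein_coding",
) -> AnnotationSet:
    """Read a feature annotation.

    Parameters
    ----------
    path
        TSV with columns ``feature_id chrom start end strand class``
        (0-based half-open), or a 9-column GTF whose gene-level records are
        used (1-based inclusive, converted on read).
    dialect
        ``"tsv"`` or ``"gtf"``.
    class_map
        For GTF input only: gene_id -> feature class; genes absent from the
        map get ``default_class``.
    """
    if dialect == "tsv":
        return _read_annotation_tsv(path)
    if dialect == "gtf":
        return _read_annotation_gtf(path, class_map, default_class)
    raise InputError(f"unknown annotation dialect {dialect!r}")


# ---------------------------------------------------------------------------
# Count matrix
# ---------------------------------------------------------------------------

@dataclass
class CountMatrix:
    """Raw integer counts, features x samples, with class and condition maps.

    ``counts`` rows are features, columns are samples.  ``class_of`` must
    cover every feature; ``condition_of`` maps each sample to its condition
    label (it may be empty until a design is attached).
    """

    counts: pd.DataFrame
    class_of: dict[str, str]
    condition_of: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        vals = self.counts.to_numpy()
        if vals.size and (not np.issubdtype(vals.dtype, np.integer)):
            if not np.all(np.equal(np.mod(vals, 1), 0)):
                bad = np.argwhere(np.not_equal(np.mod(vals, 1), 0))[0]
                raise InputError(
                    f"non-integer count at feature "
                    f"{self.counts.index[bad[0]]!r}, sample "
                    f"{self.counts.columns[bad[1]]!r}"
                )
            self.counts = self.counts.astype(np.int64)
            vals = self.counts.to_numpy()
        if vals.size and vals.min() < 0:
            bad = np.argwhere(vals < 0)[0]
            raise InputError(
                f"negative count at feature {self.counts.index[bad[0]]!r}, "
                f"sample {self.counts.columns[bad[1]]!r}"
            )
        missing = [f for f in self.counts.index if f not in self.class_of]
        if missing:
            raise InputError(
                f"feature(s) without annotation/class: {missing[:5]!r}"
                + ("..." if len(missing) > 5 else "")
            )

    @property
    def features(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def class_series(self) -> pd.Series:
        return pd.Series({f: self.class_of[f] for f in self.counts.index})

    def spikein_features(self) -> list[str]:
        return [f for f in self.counts.index if self.class_of[f] == "spikein"]

    def ercc_totals(self) -> pd.Series:
        """Total spike-in counts per sample."""
        spikes = self.spikein_features()
        return self.counts.loc[spikes].sum(axis=0)

    def conditions(self) -> list[str]:
        """Condition labels in first-appearance (sample) order."""
        seen: dict[str, None] = {}
        for s in self.samples:
            if s in self.condition_of:
                seen.setdefault(self.condition_of[s], None)
        return list(seen)

    def samples_of(self, condition: str) -> list[str]:
        return [s for s in self.samples if self.condition_of.get(s) == condition]


def read_count_matrix(
    path: str | Path,
    annotation: AnnotationSet,
    condition_of: Mapping[str, str] | None = None,
) -> CountMatrix:
    """Read a TSV count matrix (first column feature_id, header sample ids).

    Every feature row must be covered by ``annotation``; cells must be
    non-negative integers.  Row/column order is preserved.
    """
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:  # noqa: BLE001
        raise InputError(f"cannot parse count matrix {path}: {exc}") from exc
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise InputError(f"duplicate feature rows in {path}: {dups[:5]!r}")
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            bad = df[~df[col].astype(str).str.fullmatch(r"-?\d+")].index
            raise InputError(
                f"non-integer count at feature {bad[0]!r}, sample {col!r} "
                f"in {path}"
            )
    missing = [f for f in df.index if f not in annotation]
    if missing:
        raise InputError(
            f"feature(s) in {path} without annotation: {missing[:5]!r}"
            + ("..." if len(missing) > 5 else "")
        )
    class_of = {f: annotation[f].feature_class for f in df.index}
    return CountMatrix(
        counts=df, class_of=class_of,
        condition_of=dict(condition_of or {}),
    )


def read_design(path: str | Path) -> dict[str, str]:
    """Read a 2-column TSV (sample, condition) into a sample->condition map."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise InputError(f"design file {path} needs columns sample, condition")
    sample_col, cond_col = df.columns[:2]
    return dict(zip(df[sample_col], df[cond_col]))


def write_count_matrix(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index_label="feature_id",
                  float_format=FLOAT_FORMAT)


# ---------------------------------------------------------------------------
# Scale factors
# ---------------------------------------------------------------------------

@dataclass
class ScaleFactors:
    """Per-sample multipliers equalizing total spike-in signal.

    ``factor_of[s] = reference_total / total(s)`` where totals are spike-in
    count sums (or full-library sums when computed with ``method="total"``);
    the reference sample's factor is exactly 1.
    """

    factor_of: dict[str, float]
    reference_sample: str
    reference_total: int
    total_of: dict[str, int]
    method: str = "ercc"

    def __post_init__(self) -> None:
        for s, f in self.factor_of.items():
            if not f > 0:
                raise InputError(f"scale factor for sample {s!r} must be > 0")

    def as_series(self) -> pd.Series:
        return pd.Series(self.factor_of, name="scale_factor")

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            {
                "sample": list(self.factor_of),
                "total": [self.total_of[s] for s in self.factor_of],
                "scale_factor": [self.factor_of[s] for s in self.factor_of],
            }
        )
        df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


# ---------------------------------------------------------------------------
# Coverage (bedGraph semantics)
# ---------------------------------------------------------------------------

class CoverageTrack:
    """Sparse per-base coverage: sorted, non-overlapping half-open intervals.

    Uncovered bases read as 0.  Intervals are held per chromosome as three
    parallel numpy arrays (starts, ends, values).
    """

    def __init__(self, intervals: Mapping[str, tuple[np.ndarray, np.ndarray, np.ndarray]] | None = None):
        self._ivs: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        if intervals:
            for chrom, (s, e, v) in intervals.items():
                self._add_chrom(chrom, np.asarray(s, dtype=np.int64),
                                np.asarray(e, dtype=np.int64),
                                np.asarray(v, dtype=float))

    def _add_chrom(self, chrom: str, s: np.ndarray, e: np.ndarray, v: np.ndarray) -> None:
        order = np.argsort(s, kind="stable")
        s, e, v = s[order], e[order], v[order]
        if np.any(v < 0):
            i = int(np.argmax(v < 0))
            raise InputError(
                f"negative coverage value {v[i]} on {chrom}:{s[i]}-{e[i]}"
            )
        if np.any(e <= s):
            i = int(np.argmax(e <= s))
            raise InputError(f"empty/inverted interval {chrom}:{s[i]}-{e[i]}")
        if len(s) > 1 and np.any(s[1:] < e[:-1]):
            i = int(np.argmax(s[1:] < e[:-1]))
            raise InputError(
                f"overlapping intervals on {chrom}: "
                f"[{s[i]},{e[i]}) and [{s[i + 1]},{e[i + 1]})"
            )
        self._ivs[chrom] = (s, e, v)

    @property
    def chroms(self) -> list[str]:
        return list(self._ivs)

    def intervals(self, chrom: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return self._ivs.get(
            chrom,
            (np.empty(0, np.int64), np.empty(0, np.int64), np.empty(0, float)),
        )

    def values(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Dense per-base coverage over ``[start, end)``.

        Coordinates outside any covered interval (including negative ones)
        read as 0.
        """
        if end <= start:
            raise InputError(f"empty query interval [{start}, {end})")
        out = np.zeros(end - start, dtype=float)
        s, e, v = self.intervals(chrom)
        if len(s) == 0:
            return out
        lo = int(np.searchsorted(e, start, side="right"))
        hi = int(np.searchsorted(s, end, side="left"))
        for i in range(lo, hi):
            a = max(s[i], start) - start
            b = min(e[i], end) - start
            if b > a:
                out[a:b] = v[i]
        return out

    def region_sum(self, chrom: str, start: int, end: int) -> float:
        """Sum of per-base coverage over ``[start, end)`` without expansion."""
        s, e, v = self.intervals(chrom)
        if len(s) == 0:
            return 0.0
        lo = int(np.searchsorted(e, start, side="right"))
        hi = int(np.searchsorted(s, end, side="left"))
        sl = slice(lo, hi)
        widths = np.minimum(e[sl], end) - np.maximum(s[sl], start)
        return float(np.sum(widths * v[sl]))

    def scale(self, factor: float) -> "CoverageTrack":
        if not factor > 0:
            raise InputError(f"scale factor must be > 0 (got {factor})")
        return CoverageTrack(
            {c: (s.copy(), e.copy(), v * factor)
             for c, (s, e, v) in self._ivs.items()}
        )

    @classmethod
    def from_dense(cls, chrom_arrays: Mapping[str, np.ndarray]) -> "CoverageTrack":
        """Build a track from dense per-base arrays (index 0 = base 0),
        run-length compressed; zero runs are left uncovered."""
        ivs = {}
        for chrom, arr in chrom_arrays.items():
            arr = np.asarray(arr, dtype=float)
            if arr.size == 0:
                continue
            change = np.nonzero(np.diff(arr))[0] + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [arr.size]))
            vals = arr[starts]
            keep = vals != 0
            if keep.any():
                ivs[chrom] = (starts[keep].astype(np.int64),
                              ends[keep].astype(np.int64),
                              vals[keep])
        return cls(ivs)


def read_bedgraph(path: str | Path) -> CoverageTrack:
    """Read a 4-column bedGraph (0-based half-open) into a CoverageTrack.

    Overlapping intervals or negative values are a hard error; an empty
    file yields an all-zero track.
    """
    cols = ["chrom", "start", "end", "value"]
    try:
        df = pd.read_csv(
            path, sep=r"\s+", header=None, names=cols, comment="#",
            dtype={"chrom": str}, skip_blank_lines=True,
        )
    except pd.errors.EmptyDataError:
        return CoverageTrack()
    except Exception as exc:  # noqa: BLE001
        raise InputError(f"cannot parse bedGraph {path}: {exc}") from exc
    # track definition lines, if present, fail the numeric conversion
    try:
        starts = df["start"].astype(np.int64)
        ends = df["end"].astype(np.int64)
        vals = df["value"].astype(float)
    except (ValueError, TypeError) as exc:
        raise InputError(f"malformed bedGraph line in {path}: {exc}") from exc
    ivs: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom, grp in df.assign(start=starts, end=ends, value=vals).groupby(
        "chrom", sort=False
    ):
        ivs[chrom] = (
            grp["start"].to_numpy(),
            grp["end"].to_numpy(),
            grp["value"].to_numpy(),
        )
    return CoverageTrack(ivs)


def write_bedgraph(track: CoverageTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom in track.chroms:
            s, e, v = track.intervals(chrom)
            for i in range(len(s)):
                fh.write(f"{chrom}\t{s[i]}\t{e[i]}\t{FLOAT_FORMAT % v[i]}\n")


# ---------------------------------------------------------------------------
# Results tables
# ---------------------------------------------------------------------------

def write_results_table(records: Sequence | pd.DataFrame, path: str | Path) -> None:
    """Write a homogeneous record list (dataclasses, dicts or a DataFrame)
    as TSV with a header, deterministic column order and fixed float
    precision (6 significant digits)."""
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        rows = []
        columns: list[str] | None = None
        for r in records:
            if hasattr(r, "__dataclass_fields__"):
                d = {f.name: getattr(r, f.name) for f in fields(r)}
            elif isinstance(r, Mapping):
                d = dict(r)
            else:
                raise InputError(
                    f"unsupported record type {type(r).__name__}"
                )
            if columns is None:
                columns = list(d)
            elif list(d) != columns:
                raise InputError("records do not share a schema")
            rows.append(d)
        df = pd.DataFrame(rows, columns=columns or [])
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_results_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class AnalysisConfig:
    """Thresholds and binning parameters for the analysis stages.

    Defaults are the study's printed rules: a differentially expressed gene
    has fold change > 1.5 at FDR < 0.05; a screen hit gene has at least one
    guide at adjusted p <= 0.01 and fold change >= 1.5; metagene flanks are
    3 kb.
    """

    fc_threshold: float = 1.5
    fdr_threshold: float = 0.05
    guide_padj_threshold: float = 0.01
    guide_fc_threshold: float = 1.5
    flank_bp: int = 3000
    body_bins: int = 100
    flank_bins: int = 60
    pseudocount: float = 1.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("fc_threshold", "guide_fc_threshold", "flank_bp"):
            if not getattr(self, name) > 0:
                raise InputError(f"{name} must be strictly positive")
        for name in ("fdr_threshold", "guide_padj_threshold"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise InputError(f"{name} must lie in (0, 1)")
        for name in ("body_bins", "flank_bins"):
            if getattr(self, name) < 1:
                raise InputError(f"{name} must be >= 1")
        if self.pseudocount < 0:
            raise InputError("pseudocount must be non-negative")

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisConfig":
        """Parse a flat ``key=value`` / ``key: value`` config file."""
        values: dict[str, object] = {}
        types = {f.name: f.type for f in fields(cls)}
        casts = {"float": float, "int": int}
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" in line:
                    key, _, raw = line.partition("=")
                elif ":" in line:
                    key, _, raw = line.partition(":")
                else:
                    raise InputError(
                        f"{path} line {lineno}: expected key=value or "
                        "key: value"
                    )
                key, raw = key.strip(), raw.strip()
                if key not in types:
                    raise InputError(f"{path} line {lineno}: unknown key {key!r}")
                values[key] = casts[types[key]](raw)
        return cls(**values)  # type: ignore[arg-type]
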