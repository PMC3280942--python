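"""Capture-performance analytics from alignments.

A read is an on-target fragment-end tag when the coordinate of its first
sequenced base (alignment start for forward reads, alignment end for
reverse reads, both half-open boundary coordinates) coincides with the
anchored boundary of a target region, within a configurable slack
(default 0), and the read overlaps that region. Reads matching several
regions at a shared cut are disambiguated by the overlap requirement
first, then by lexicographic oligo id. Duplicate reads are not
collapsed: tag counts are raw.
"""

from __future__ import annotations

import json
import math
import warnings
from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam
from scipy import stats

from .design import CaptureOligo
from .genome_model import Interval, merge_intervals

THREE_PRIME = "three_prime"
FIVE_PRIME = "five_prime"


@dataclass(frozen=True)
class TargetRegion:
    """A read-length-wide interval extending from a fragment-end boundary
    into the captured circle."""

    oligo_id: str
    end_label: str  # three_prime | five_prime
    interval: Interval
    anchor: int  # boundary coordinate the tag must hit


@dataclass(frozen=True)
class AlignmentRecord:
    qname: str
    contig: str
    start: int
    end: int
    reverse: bool

    @property
    def tag_position(self) -> int:
        """Boundary coordinate of the read's first sequenced base."""
        return self.end if self.reverse else self.start


@dataclass
class AlignmentSet:
    records: list[AlignmentRecord]
    total_reads: int
    unmapped_reads: int

    @property
    def mapped_reads(self) -> int:
        return len(self.records)


@dataclass
class TagResult:
    labels: list[str | None]  # per mapped record: oligo id or None
    per_oligo_counts: dict[str, int]
    on_target: int
    off_target: int


@dataclass
class CoverageMetrics:
    target_bases: int
    bases_at: dict[int, int]
    mean_coverage: float
    _depth: dict[str, tuple[list[int], list[int], np.ndarray]] = field(repr=False, default_factory=dict)

    def depth_at(self, contig: str, pos: int) -> int:
        if contig not in self._depth:
            return 0
        starts, offsets, depth = self._depth[contig]
        i = bisect_right(starts, pos) - 1
        if i < 0:
            return 0
        start = starts[i]
        span = (offsets[i + 1] - offsets[i]) if i + 1 < len(offsets) else 0
        if pos >= start + span:
            return 0
        return int(depth[offsets[i] + (pos - start)])

    def per_base_depth(self) -> dict[tuple[str, int], int]:
        out: dict[tuple[str, int], int] = {}
        for contig, (starts, offsets, depth) in self._depth.items():
            for i, start in enumerate(starts):
                span = (offsets[i + 1] - offsets[i]) if i + 1 < len(offsets) else len(depth) - offsets[i]
                for j in range(span):
                    out[(contig, start + j)] = int(depth[offsets[i] + j])
        return out


@dataclass
class YieldCorrelates:
    spearman_rho: float
    spearman_p: float
    n: int
    gc_table: pd.DataFrame


@dataclass
class CaptureReport:
    total_reads: int
    mapped_reads: int
    on_target_reads: int
    off_target_reads: int
    off_target_fraction_of_mapped: float
    target_bases: int
    bases_at_1x: int
    bases_at_30x: int
    mean_on_target_coverage: float
    per_oligo_counts: dict[str, int]
    classification: dict[str, str]
    correlates: YieldCorrelates | None

    def summary_dict(self) -> dict:
        labels = list(self.classification.values())
        d = {
            "total_reads": self.total_reads,
            "mapped_reads": self.mapped_reads,
            "on_target_reads": self.on_target_reads,
            "off_target_reads": self.off_target_reads,
            "off_target_fraction_of_mapped": self.off_target_fraction_of_mapped,
            "target_bases": self.target_bases,
            "bases_at_1x": self.bases_at_1x,
            "bases_at_30x": self.bases_at_30x,
            "mean_on_target_coverage": self.mean_on_target_coverage,
            "n_oligos": len(self.per_oligo_counts),
            "n_failed": labels.count("failed"),
            "n_moderate": labels.count("moderate"),
            "n_high": labels.count("high"),
        }
        if self.correlates is not None:
            d["yield_vs_circle_spearman_rho"] = self.correlates.spearman_rho
            d["yield_vs_circle_spearman_p"] = self.correlates.spearman_p
        return d

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.summary_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")

    def to_tsv(self, path: str | Path, header_comments: Iterable[str] = ()) -> None:
        with open(path, "w") as fh:
            for comment in header_comments:
                fh.write(f"# {comment}\n")
            fh.write("metric\tvalue\n")
            for key, value in self.summary_dict().items():
                fh.write(f"{key}\t{value}\n")


# ---------------------------------------------------------------------------
# Target regions
# ---------------------------------------------------------------------------

def build_target_regions(
    oligos: Sequence[CaptureOligo],
    read_length: int = 42,
    mode: str = "single",
) -> list[TargetRegion]:
    """One (single mode) or two (paired mode) tag regions per oligo.

    The three_prime region abuts the anchored cut; the five_prime region
    abuts the circle-start boundary. Regions are clipped (with a warning)
    when the read length exceeds the circle size.
    """
    if mode not in ("single", "paired"):
        raise ValueError(f"mode must be single or paired, got {mode!r}")
    regions: list[TargetRegion] = []
    for o in oligos:
        L = read_length
        if L > o.circle_size:
            warnings.warn(
                f"{o.id}: read length {L} exceeds circle size {o.circle_size}; "
                "clipping region",
                stacklevel=2,
            )
            L = o.circle_size
        contig = o.contig
        anchor = o.anchored_cut
        cstart = o.circle_start
        if o.captured_strand == "+":
            regions.append(
                TargetRegion(o.id, THREE_PRIME, Interval(contig, anchor - L, anchor), anchor)
            )
            if mode == "paired":
                regions.append(
                    TargetRegion(o.id, FIVE_PRIME, Interval(contig, cstart, cstart + L), cstart)
                )
        else:
            regions.append(
                TargetRegion(o.id, THREE_PRIME, Interval(contig, anchor, anchor + L), anchor)
            )
            if mode == "paired":
                regions.append(
                    TargetRegion(o.id, FIVE_PRIME, Interval(contig, cstart - L, cstart), cstart)
                )
    return regions


def write_regions_bed(regions: Sequence[TargetRegion], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in regions:
            iv = r.interval
            fh.write(
                f"{iv.contig}\t{iv.start}\t{iv.end}\t{r.oligo_id}|{r.end_label}\t0\t+\n"
            )


# ---------------------------------------------------------------------------
# Alignment ingestion
# ---------------------------------------------------------------------------

def ingest_alignments(path: str | Path) -> AlignmentSet:
    """Read SAM/BAM; 1-based POS becomes 0-based start at this boundary."""
    path = str(path)
    records: list[AlignmentRecord] = []
    total = 0
    unmapped = 0
    try:
        fh = pysam.AlignmentFile(path)
    except ValueError as exc:
        if (
            "file has no sequences defined" in str(exc)
            or "does not contain alignment data" in str(exc)
            or "empty" in str(exc).lower()
        ):
            return AlignmentSet(records=[], total_reads=0, unmapped_reads=0)
        raise
    with fh:
        for aln in fh.fetch(until_eof=True):
            total += 1
            if aln.is_unmapped:
                unmapped += 1
                continue
            if aln.reference_name is None:
                raise ValueError(f"{path}: mapped record without reference contig")
            records.append(
                AlignmentRecord(
                    qname=aln.query_name or "",
                    contig=aln.reference_name,
                    start=aln.reference_start,
                    end=aln.reference_end
                    if aln.reference_end is not None
                    else aln.reference_start + (aln.query_length or 0),
                    reverse=aln.is_reverse,
                )
            )
    return AlignmentSet(records=records, total_reads=total, unmapped_reads=unmapped)


# ---------------------------------------------------------------------------
# Tagging
# ---------------------------------------------------------------------------

def tag_reads(
    records: Sequence[AlignmentRecord],
    regions: Sequence[TargetRegion],
    slack: int = 0,
) -> TagResult:
    """Label each mapped read on/off-target and attribute tags per oligo."""
    if slack < 0:
        raise ValueError("slack must be >= 0")
    by_anchor: dict[tuple[str, int], list[TargetRegion]] = {}
    for region in regions:
        by_anchor.setdefault((region.interval.contig, region.anchor), []).append(region)
    for lst in by_anchor.values():
        lst.sort(key=lambda r: (r.oligo_id, r.end_label))

    labels: list[str | None] = []
    counts: dict[str, int] = {}
    for region in regions:
        counts.setdefault(region.oligo_id, 0)
    on = 0
    for rec in records:
        tag = rec.tag_position
        hit: TargetRegion | None = None
        for t in range(tag - slack, tag + slack + 1):
            for region in by_anchor.get((rec.contig, t), ()):
                iv = region.interval
                if rec.start < iv.end and iv.start < rec.end:  # must overlap
                    if hit is None or (region.oligo_id, region.end_label) < (
                        hit.oligo_id,
                        hit.end_label,
                    ):
                        hit = region
        if hit is None:
            labels.append(None)
        else:
            labels.append(hit.oligo_id)
            counts[hit.oligo_id] += 1
            on += 1
    return TagResult(
        labels=labels,
        per_oligo_counts=counts,
        on_target=on,
        off_target=len(records) - on,
    )


# ---------------------------------------------------------------------------
# Coverage
# ---------------------------------------------------------------------------

def coverage_metrics(
    records: Sequence[AlignmentRecord],
    regions: Sequence[TargetRegion],
    thresholds: Sequence[int] = (1, 30),
    slack: int = 0,
    tags: TagResult | None = None,
) -> CoverageMetrics:
    """Per-base depth over the deduplicated union of target regions,
    computed from on-target reads only and clipped to that union."""
    if tags is None:
        tags = tag_reads(records, regions, slack=slack)
    merged = merge_intervals([r.interval for r in regions])
    by_contig: dict[str, tuple[list[int], list[int], np.ndarray]] = {}
    grouped: dict[str, list[Interval]] = {}
    for iv in merged:
        grouped.setdefault(iv.contig, []).append(iv)
    target_bases = 0
    for contig, ivs in grouped.items():
        ivs.sort(key=lambda v: v.start)
        starts = [iv.start for iv in ivs]
        offsets = []
        off = 0
        for iv in ivs:
            offsets.append(off)
            off += iv.length
        by_contig[contig] = (starts, offsets, np.zeros(off, dtype=np.int64))
        target_bases += off

    for rec, label in zip(records, tags.labels):
        if label is None or rec.contig not in by_contig:
            continue
        starts, offsets, depth = by_contig[rec.contig]
        ivs = grouped[rec.contig]
        i = bisect_right(starts, rec.start) - 1
        i = max(i, 0)
        while i < len(ivs) and ivs[i].start < rec.end:
            lo = max(rec.start, ivs[i].start)
            hi = min(rec.end, ivs[i].end)
            if lo < hi:
                base = offsets[i]
                depth[base + (lo - ivs[i].start) : base + (hi - ivs[i].start)] += 1
            i += 1

    all_depth = (
        np.concatenate([d for (_, _, d) in by_contig.values()])
        if by_contig
        else np.zeros(0, dtype=np.int64)
    )
    bases_at = {
        int(t): int((all_depth >= t).sum()) for t in thresholds
    }
    mean_cov = float(all_depth.mean()) if all_depth.size else 0.0
    return CoverageMetrics(
        target_bases=target_bases,
        bases_at=bases_at,
        mean_coverage=mean_cov,
        _depth=by_contig,
    )


# ---------------------------------------------------------------------------
# Uniformity, classification, correlates
# ---------------------------------------------------------------------------

def uniformity_curve(per_oligo_counts: "Sequence[int] | dict[str, int]") -> np.ndarray:
    """Counts sorted ascending and divided by their median."""
    if isinstance(per_oligo_counts, dict):
        values = np.array(sorted(per_oligo_counts.values()), dtype=float)
    else:
        values = np.array(sorted(per_oligo_counts), dtype=float)
    if values.size == 0 or values.max() == 0:
        raise ValueError("uniformity_curve requires at least one nonzero count")
    median = float(np.median(values))
    if median == 0:
        raise ValueError("median yield is zero; curve undefined")
    return values / median


def flatness(curve: np.ndarray) -> float:
    """max/min over the nonzero part of a normalized curve (lower = flatter)."""
    nonzero = curve[curve > 0]
    return float(nonzero.max() / nonzero.min())


def classify_performance(
    per_oligo_counts: dict[str, int],
    high_fraction: float = 0.25,
    high_count: int | None = None,
) -> dict[str, str]:
    """failed (zero tags) / high (top fraction by count) / moderate (rest).

    ``high_count`` overrides the fraction with an absolute number of high
    performers. Ties are broken by oligo id; the three labels partition
    the oligo set.
    """
    n = len(per_oligo_counts)
    if n == 0:
        return {}
    if high_count is None:
        n_high = math.ceil(high_fraction * n)
    else:
        n_high = high_count
    labels = {oid: "failed" for oid, c in per_oligo_counts.items() if c == 0}
    nonfailed = sorted(
        ((oid, c) for oid, c in per_oligo_counts.items() if c > 0),
        key=lambda t: (-t[1], t[0]),
    )
    n_high = min(n_high, len(nonfailed))
    for i, (oid, _) in enumerate(nonfailed):
        labels[oid] = "high" if i < n_high else "moderate"
    return labels


def yield_correlates(
    per_oligo_counts: dict[str, int],
    circle_sizes: dict[str, int],
    arm_gcs: dict[str, tuple[float, float]],
    gc_bin_width: float = 0.1,
) -> YieldCorrelates:
    """Rank correlation of yield vs circle size plus GC-binned yield table.

    Each oligo contributes two GC points: its higher-GC arm and its
    lower-GC arm, summarized separately. With fewer than 5 oligos the
    correlation is reported as undefined (NaN).
    """
    ids = sorted(per_oligo_counts)
    missing = [i for i in ids if i not in circle_sizes or i not in arm_gcs]
    if missing:
        raise ValueError(f"missing circle size or GC for oligos: {missing[:5]}")
    yields = np.array([per_oligo_counts[i] for i in ids], dtype=float)
    sizes = np.array([circle_sizes[i] for i in ids], dtype=float)
    n = len(ids)
    if n < 5 or np.unique(sizes).size < 2 or np.unique(yields).size < 2:
        rho, pval = float("nan"), float("nan")
    else:
        res = stats.spearmanr(sizes, yields)
        rho, pval = float(res.statistic), float(res.pvalue)

    rows = []
    for oid in ids:
        gc5, gc3 = arm_gcs[oid]
        hi, lo = max(gc5, gc3), min(gc5, gc3)
        for arm_class, gc in (("high_gc_arm", hi), ("low_gc_arm", lo)):
            b = min(int(gc / gc_bin_width), int(1 / gc_bin_width) - 1)
            rows.append(
                {
                    "arm_class": arm_class,
                    "gc_bin_low": round(b * gc_bin_width, 6),
                    "gc_bin_high": round((b + 1) * gc_bin_width, 6),
                    "yield": per_oligo_counts[oid],
                }
            )
    df = pd.DataFrame(rows)
    table = (
        df.groupby(["arm_class", "gc_bin_low", "gc_bin_high"], as_index=False)
        .agg(n=("yield", "size"), mean_yield=("yield", "mean"))
        .sort_values(["arm_class", "gc_bin_low"], ignore_index=True)
    )
    return YieldCorrelates(spearman_rho=rho, spearman_p=pval, n=n, gc_table=table)


# ---------------------------------------------------------------------------
# Report orchestration
# ---------------------------------------------------------------------------

def make_report(
    alignments: AlignmentSet,
    oligos: Sequence[CaptureOligo],
    read_length: int = 42,
    mode: str = "single",
    slack: int = 0,
    thresholds: Sequence[int] = (1, 30),
    high_fraction: float = 0.25,
    high_count: int | None = None,
) -> CaptureReport:
    regions = build_target_regions(oligos, read_length=read_length, mode=mode)
    tags = tag_reads(alignments.records, regions, slack=slack)
    cov = coverage_metrics(
        alignments.records, regions, thresholds=thresholds, tags=tags
    )
    classification = classify_performance(
        tags.per_oligo_counts, high_fraction=high_fraction, high_count=high_count
    )
    correlates: YieldCorrelates | None = None
    if oligos:
        correlates = yield_correlates(
            tags.per_oligo_counts,
            {o.id: o.circle_size for o in oligos},
            {o.id: (o.gc5, o.gc3) for o in oligos},
        )
    mapped = alignments.mapped_reads
    return CaptureReport(
        total_reads=alignments.total_reads,
        mapped_reads=mapped,
        on_target_reads=tags.on_target,
        off_target_reads=tags.off_target,
        off_target_fraction_of_mapped=(tags.off_target / mapped) if mapped else 0.0,
        target_bases=cov.target_bases,
        bases_at_1x=cov.bases_at.get(1, 0),
        bases_at_30x=cov.bases_at.get(30, 0),
        mean_on_target_coverage=cov.mean_coverage,
        per_oligo_counts=tags.per_oligo_counts,
        classification=classification,
        correlates=correlates,
    )


def write_per_oligo_tsv(
    report: CaptureReport,
    path: str | Path,
    header_comments: Iterable[str] = (),
) -> None:
    with open(path, "w") as fh:
        for comment in header_comments:
            fh.write(f"# {comment}\n")
        fh.write("id\tcount\tclass\n")
        for oid in sorted(report.per_oligo_counts):
            fh.write(
                f"{oid}\t{report.per_oligo_counts[oid]}\t"
                f"{report.classification.get(oid, '.')}\n"
            )


def write_uniformity_tsv(curve: np.ndarray, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("rank\tmedian_normalized_yield\n")
        for i, v in enumerate(curve):
            fh.write(f"{i}\t{v:.6g}\n")
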