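"""Capture-oligonucleotide enumeration, QC filtering, selection and tiling.

A capture oligo splints the two ends of a restriction fragment into a
circle. Its 3'-side arm must sit exactly on a restriction cut boundary
(perfect hybridization is required there); the 5'-side arm may be
displaced into the fragment interior, because a 5' overhang is cleaved
off during circularization. Circle size is therefore measured from the
5'-arm start to the anchored cut.

Arm sequences are stored as reference-strand substrings together with
the captured strand; complementation is deferred to assembly so that
coordinates have a single source of truth.
"""

from __future__ import annotations

import csv
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .digest import CUT_SITE, Fragment, fragments_overlapping
from .genome_model import (
    Interval,
    Reference,
    VariantSet,
    gc_fraction,
    merge_intervals,
    revcomp,
)

# QC flag names
FLAG_SNP = "snp_overlap"
FLAG_NONUNIQUE = "nonunique"
FLAG_SOFTMASKED = "softmasked"
FLAG_HOMOPOLYMER = "homopolymer"
FLAG_SIZE = "size_out_of_range"
FLAG_GC = "gc_out_of_range"

REASON_HARD_SIZE = "circle_above_hard_max"
REASON_REDUNDANCY = "redundancy_limit"

#: arm GC value preferred when breaking ties between otherwise equal candidates
_GC_TARGET = 0.45


@dataclass
class DesignConfig:
    """Tunable design constraints.

    Defaults encode the empirically optimal capture window: circles of
    200-600 bases (800 as a hard upper limit) and arm G+C of 30-60%.
    """

    arm_length: int = 20
    circle_min: int = 200
    circle_max: int = 600
    circle_hard_max: int = 800
    gc_min: float = 0.30
    gc_max: float = 0.60
    uniqueness_k: int = 20
    max_kmer_hits: int = 1
    max_homopolymer: int = 8
    redundancy: int = 2
    flap_stride: int = 50
    check_uniqueness: bool = True
    check_softmask: bool = True
    check_homopolymer: bool = True
    softmask_max_fraction: float = 0.5

    def __post_init__(self) -> None:
        if not (0 < self.circle_min < self.circle_max <= self.circle_hard_max):
            raise ValueError(
                "require 0 < circle_min < circle_max <= circle_hard_max"
            )
        if not (0 <= self.gc_min < self.gc_max <= 1):
            raise ValueError("require 0 <= gc_min < gc_max <= 1")
        if self.arm_length < 1 or self.flap_stride < 1 or self.redundancy < 1:
            raise ValueError("arm_length, flap_stride, redundancy must be >= 1")


@dataclass(frozen=True)
class ArmPair:
    """The two 20-nt target sites of one oligo, as reference-strand substrings.

    ``arm3`` hybridizes the captured strand's 3' end and is anchored at a
    cut boundary; ``arm5`` hybridizes the (possibly flap-displaced) 5' end.
    """

    arm5: str
    arm3: str
    arm5_interval: Interval
    arm3_interval: Interval
    captured_strand: str


@dataclass
class CaptureOligo:
    id: str
    arm_pair: ArmPair
    fragment: Fragment
    circle_size: int
    gc5: float
    gc3: float
    qc_flags: set[str] = field(default_factory=set)
    rejected: bool = False
    full_fragment: bool = False
    assembled_sequence: str | None = None

    @property
    def contig(self) -> str:
        return self.fragment.contig

    @property
    def captured_strand(self) -> str:
        return self.arm_pair.captured_strand

    @property
    def anchored_cut(self) -> int:
        """Reference coordinate of the anchored (3'-side) cut boundary."""
        if self.captured_strand == "+":
            return self.arm_pair.arm3_interval.end
        return self.arm_pair.arm3_interval.start

    @property
    def circle_start(self) -> int:
        """Reference coordinate of the 5'-arm outer boundary (circle start)."""
        if self.captured_strand == "+":
            return self.arm_pair.arm5_interval.start
        return self.arm_pair.arm5_interval.end

    @property
    def captured_interval(self) -> Interval:
        """The genomic span that ends up inside the circle."""
        lo = min(self.arm_pair.arm5_interval.start, self.arm_pair.arm3_interval.start)
        hi = max(self.arm_pair.arm5_interval.end, self.arm_pair.arm3_interval.end)
        return Interval(self.contig, lo, hi)

    @property
    def mean_gc(self) -> float:
        return 0.5 * (self.gc5 + self.gc3)

    def passes(self) -> bool:
        return not self.qc_flags and not self.rejected


@dataclass(frozen=True)
class Rejection:
    oligo_id: str
    reasons: tuple[str, ...]


@dataclass
class TilingResult:
    tiles: list[CaptureOligo]
    gaps: list[Fragment]


@dataclass
class RoiCoverage:
    per_roi: list[tuple[Interval, int, float]]
    aggregate: float


# ---------------------------------------------------------------------------
# Candidate enumeration
# ---------------------------------------------------------------------------

def _candidate_id(fragment: Fragment, strand: str, offset: int) -> str:
    s = "p" if strand == "+" else "m"
    return f"{fragment.contig}:{fragment.start}-{fragment.end}:{s}:{offset}"


def enumerate_candidates(
    reference: Reference,
    fragments: Sequence[Fragment],
    roi: Interval,
    cfg: DesignConfig,
) -> list[CaptureOligo]:
    """All candidate oligos for fragments overlapping a ROI.

    Per fragment and per captured strand: one candidate anchored at each
    valid cut with the 5' arm at the far fragment end (offset 0, a
    full-fragment circle), plus flap-style candidates whose 5' arm is
    displaced interior to the fragment in steps of ``flap_stride``.
    Fragments shorter than two arm lengths yield no candidates.
    """
    arm = cfg.arm_length
    out: list[CaptureOligo] = []
    for frag in fragments_overlapping(fragments, roi):
        if frag.length < 2 * arm:
            continue
        contig = frag.contig
        # captured strand '+': 3' end of the captured (top) strand is the
        # fragment's right boundary, which must be a genuine cut.
        if frag.right_kind == CUT_SITE:
            arm3_iv = Interval(contig, frag.end - arm, frag.end)
            offset = 0
            while True:
                s = frag.start + offset
                if s + arm > frag.end - arm:
                    break
                arm5_iv = Interval(contig, s, s + arm)
                out.append(
                    _make_candidate(reference, frag, "+", offset, arm5_iv, arm3_iv)
                )
                offset += cfg.flap_stride
        # captured strand '-': 3' end of the bottom strand maps to the
        # fragment's left boundary in reference coordinates.
        if frag.left_kind == CUT_SITE:
            arm3_iv = Interval(contig, frag.start, frag.start + arm)
            offset = 0
            while True:
                e = frag.end - offset
                if e - arm < frag.start + arm:
                    break
                arm5_iv = Interval(contig, e - arm, e)
                out.append(
                    _make_candidate(reference, frag, "-", offset, arm5_iv, arm3_iv)
                )
                offset += cfg.flap_stride
    return out


def _make_candidate(
    reference: Reference,
    frag: Fragment,
    strand: str,
    offset: int,
    arm5_iv: Interval,
    arm3_iv: Interval,
) -> CaptureOligo:
    arm5_seq = reference.fetch(arm5_iv)
    arm3_seq = reference.fetch(arm3_iv)
    if strand == "+":
        circle = arm3_iv.end - arm5_iv.start
    else:
        circle = arm5_iv.end - arm3_iv.start
    pair = ArmPair(arm5_seq, arm3_seq, arm5_iv, arm3_iv, strand)
    return CaptureOligo(
        id=_candidate_id(frag, strand, offset),
        arm_pair=pair,
        fragment=frag,
        circle_size=circle,
        gc5=gc_fraction(arm5_seq),
        gc3=gc_fraction(arm3_seq),
        full_fragment=(circle == frag.length),
    )


# ---------------------------------------------------------------------------
# QC filters
# ---------------------------------------------------------------------------

def snp_filter(oligo: CaptureOligo, variants: VariantSet) -> bool:
    """True (and flag set) iff a known variant falls inside either arm."""
    hit = variants.overlaps(oligo.arm_pair.arm5_interval) or variants.overlaps(
        oligo.arm_pair.arm3_interval
    )
    if hit:
        oligo.qc_flags.add(FLAG_SNP)
    return hit


class KmerIndex:
    """Exact forward k-mer multiplicities over a whole reference.

    Lookup adds the reverse-complement count (palindromes counted once).
    k-mers containing N are not indexed.
    """

    def __init__(self, reference: Reference, k: int) -> None:
        self.k = k
        counts: Counter[str] = Counter()
        for name in reference.names:
            seq = reference[name]
            for i in range(len(seq) - k + 1):
                kmer = seq[i : i + k]
                if "N" not in kmer:
                    counts[kmer] += 1
        self._counts = counts

    def count(self, seq: str) -> int:
        if len(seq) != self.k:
            raise ValueError(f"query length {len(seq)} != k {self.k}")
        n = self._counts[seq]
        rc = revcomp(seq)
        if rc != seq:
            n += self._counts[rc]
        return n


def max_homopolymer_run(seq: str) -> int:
    best = run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best if seq else 0


def uniqueness_filter(
    oligo: CaptureOligo,
    reference: Reference,
    cfg: DesignConfig,
    kmer_index: KmerIndex | None = None,
) -> set[str]:
    """Repeat-avoidance QC via three measurable proxies.

    nonunique: either arm (or its reverse complement) occurs more than
    ``max_kmer_hits`` times in the reference. softmasked: > half of an
    arm's bases were lowercase in the source FASTA. homopolymer: a
    single-base run of ``max_homopolymer`` or longer within an arm.
    """
    added: set[str] = set()
    pair = oligo.arm_pair
    if cfg.check_uniqueness:
        idx = kmer_index or KmerIndex(reference, cfg.arm_length)
        if any(idx.count(arm) > cfg.max_kmer_hits for arm in (pair.arm5, pair.arm3)):
            added.add(FLAG_NONUNIQUE)
    if cfg.check_softmask:
        if any(
            reference.softmask_fraction(iv) > cfg.softmask_max_fraction
            for iv in (pair.arm5_interval, pair.arm3_interval)
        ):
            added.add(FLAG_SOFTMASKED)
    if cfg.check_homopolymer:
        if any(
            max_homopolymer_run(arm) >= cfg.max_homopolymer
            for arm in (pair.arm5, pair.arm3)
        ):
            added.add(FLAG_HOMOPOLYMER)
    oligo.qc_flags |= added
    return added


def size_gc_filter(oligo: CaptureOligo, cfg: DesignConfig) -> set[str]:
    """Size / GC window flags; circles above the hard cap are rejected outright."""
    added: set[str] = set()
    if not (cfg.circle_min <= oligo.circle_size <= cfg.circle_max):
        added.add(FLAG_SIZE)
    if not (cfg.gc_min <= oligo.gc5 <= cfg.gc_max) or not (
        cfg.gc_min <= oligo.gc3 <= cfg.gc_max
    ):
        added.add(FLAG_GC)
    if oligo.circle_size > cfg.circle_hard_max:
        oligo.rejected = True
    oligo.qc_flags |= added
    return added


def apply_filters(
    candidates: Iterable[CaptureOligo],
    reference: Reference,
    variants: VariantSet,
    cfg: DesignConfig,
    kmer_index: KmerIndex | None = None,
) -> None:
    if cfg.check_uniqueness and kmer_index is None:
        kmer_index = KmerIndex(reference, cfg.arm_length)
    for oligo in candidates:
        snp_filter(oligo, variants)
        uniqueness_filter(oligo, reference, cfg, kmer_index)
        size_gc_filter(oligo, cfg)


# ---------------------------------------------------------------------------
# Selection
# ---------------------------------------------------------------------------

def _preference_key(oligo: CaptureOligo, cfg: DesignConfig):
    mid = 0.5 * (cfg.circle_min + cfg.circle_max)
    leftmost = min(
        oligo.arm_pair.arm5_interval.start, oligo.arm_pair.arm3_interval.start
    )
    return (
        len(oligo.qc_flags),
        abs(oligo.mean_gc - _GC_TARGET),
        abs(oligo.circle_size - mid),
        leftmost,
        oligo.id,
    )


def select(
    candidates: Sequence[CaptureOligo],
    cfg: DesignConfig,
    mode: str = "strict",
) -> tuple[list[CaptureOligo], list[Rejection]]:
    """Pick up to ``cfg.redundancy`` oligos per fragment.

    strict keeps only flag-free candidates; permissive falls back to
    flagged-but-not-rejected candidates for fragments that would
    otherwise end up with zero oligos. Every dropped candidate lands in
    the rejection table with its reasons.
    """
    if mode not in ("strict", "permissive"):
        raise ValueError(f"unknown selection mode {mode!r}")
    seen: set[str] = set()
    groups: dict[tuple[str, int, int], list[CaptureOligo]] = {}
    for cand in candidates:
        if cand.id in seen:
            continue
        seen.add(cand.id)
        key = (cand.contig, cand.fragment.start, cand.fragment.end)
        groups.setdefault(key, []).append(cand)

    selected: list[CaptureOligo] = []
    rejections: list[Rejection] = []
    for key in sorted(groups):
        group = groups[key]
        hard = [c for c in group if c.rejected]
        clean = [c for c in group if not c.rejected and not c.qc_flags]
        flagged = [c for c in group if not c.rejected and c.qc_flags]
        for c in hard:
            rejections.append(
                Rejection(c.id, tuple(sorted(c.qc_flags)) + (REASON_HARD_SIZE,))
            )
        pool: list[CaptureOligo]
        dropped: list[CaptureOligo]
        if clean:
            pool, dropped = clean, flagged
        elif mode == "permissive" and flagged:
            pool, dropped = flagged, []
        else:
            pool, dropped = [], flagged
        for c in dropped:
            rejections.append(Rejection(c.id, tuple(sorted(c.qc_flags))))
        pool.sort(key=lambda c: _preference_key(c, cfg))
        keep = pool[: cfg.redundancy]
        for c in pool[cfg.redundancy :]:
            rejections.append(
                Rejection(c.id, tuple(sorted(c.qc_flags)) + (REASON_REDUNDANCY,))
            )
        selected.extend(keep)
    selected.sort(
        key=lambda c: (c.contig, c.fragment.start, c.fragment.end, c.id)
    )
    return selected, rejections


def tile_region(
    reference: Reference,
    fragments: Sequence[Fragment],
    roi: Interval,
    cfg: DesignConfig,
    variants: VariantSet | None = None,
) -> TilingResult:
    """One full-fragment oligo per overlapping fragment, in genomic order.

    Only full-fragment (offset-0) candidates are considered so that
    consecutive captured fragments share their cut boundaries and the
    tiling is gap-free wherever capture succeeds; fragments with no
    passing candidate are reported as gaps.
    """
    variants = variants or VariantSet()
    kmer_index = KmerIndex(reference, cfg.arm_length) if cfg.check_uniqueness else None
    tiles: list[CaptureOligo] = []
    gaps: list[Fragment] = []
    for frag in fragments_overlapping(fragments, roi):
        cands = [
            c
            for c in enumerate_candidates(
                reference, [frag], frag.interval, cfg
            )
            if c.full_fragment
        ]
        apply_filters(cands, reference, variants, cfg, kmer_index)
        passing = [c for c in cands if c.passes()]
        if passing:
            passing.sort(key=lambda c: _preference_key(c, cfg))
            tiles.append(passing[0])
        else:
            gaps.append(frag)
    return TilingResult(tiles=tiles, gaps=gaps)


def roi_coverage(
    selected: Sequence[CaptureOligo], rois: Sequence[Interval]
) -> RoiCoverage:
    """Fraction of ROI bases inside the union of captured intervals."""
    captured = merge_intervals([o.captured_interval for o in selected]) if selected else []
    by_contig: dict[str, list[Interval]] = {}
    for iv in captured:
        by_contig.setdefault(iv.contig, []).append(iv)
    per_roi: list[tuple[Interval, int, float]] = []
    total_roi = 0
    total_cov = 0
    for roi in rois:
        covered = 0
        for iv in by_contig.get(roi.contig, []):
            covered += max(0, min(iv.end, roi.end) - max(iv.start, roi.start))
        per_roi.append((roi, covered, covered / roi.length))
        total_roi += roi.length
        total_cov += covered
    aggregate = total_cov / total_roi if total_roi else 0.0
    return RoiCoverage(per_roi=per_roi, aggregate=aggregate)


def design_oligos(
    reference: Reference,
    fragments: Sequence[Fragment],
    rois: Sequence[Interval],
    variants: VariantSet,
    cfg: DesignConfig,
    mode: str = "strict",
) -> tuple[list[CaptureOligo], list[Rejection], RoiCoverage]:
    """Enumerate, filter and select oligos for a panel of ROIs."""
    kmer_index = KmerIndex(reference, cfg.arm_length) if cfg.check_uniqueness else None
    candidates: list[CaptureOligo] = []
    seen: set[str] = set()
    for roi in rois:
        for cand in enumerate_candidates(reference, fragments, roi, cfg):
            if cand.id not in seen:
                seen.add(cand.id)
                candidates.append(cand)
    apply_filters(candidates, reference, variants, cfg, kmer_index)
    selected, rejections = select(candidates, cfg, mode=mode)
    coverage = roi_coverage(selected, rois)
    return selected, rejections, coverage


# ---------------------------------------------------------------------------
# Manifest I/O
# ---------------------------------------------------------------------------

MANIFEST_COLUMNS = [
    "id",
    "contig",
    "captured_strand",
    "frag_start",
    "frag_end",
    "left_kind",
    "right_kind",
    "arm5_start",
    "arm5_end",
    "arm5_seq",
    "arm3_start",
    "arm3_end",
    "arm3_seq",
    "circle_size",
    "gc5",
    "gc3",
    "full_fragment",
    "flags",
]


def write_manifest(
    oligos: Sequence[CaptureOligo],
    path: str | Path,
    header_comments: Iterable[str] = (),
) -> None:
    """TSV manifest, one row per oligo; flags '.' when empty."""
    with open(path, "w") as fh:
        for comment in header_comments:
            fh.write(f"# {comment}\n")
        fh.write("\t".join(MANIFEST_COLUMNS) + "\n")
        for o in oligos:
            p = o.arm_pair
            row = [
                o.id,
                o.contig,
                p.captured_strand,
                str(o.fragment.start),
                str(o.fragment.end),
                o.fragment.left_kind,
                o.fragment.right_kind,
                str(p.arm5_interval.start),
                str(p.arm5_interval.end),
                p.arm5,
                str(p.arm3_interval.start),
                str(p.arm3_interval.end),
                p.arm3,
                str(o.circle_size),
                f"{o.gc5:.6g}",
                f"{o.gc3:.6g}",
                "1" if o.full_fragment else "0",
                ",".join(sorted(o.qc_flags)) if o.qc_flags else ".",
            ]
            fh.write("\t".join(row) + "\n")


def read_manifest(path: str | Path) -> list[CaptureOligo]:
    """Rebuild CaptureOligo records from a manifest TSV."""
    from .digest import Fragment  # local to avoid confusion with module-level import

    oligos: list[CaptureOligo] = []
    with open(path) as fh:
        rows = [line for line in fh if not line.startswith("#")]
    reader = csv.DictReader(rows, delimiter="\t")
    if reader.fieldnames is None or reader.fieldnames[0] != "id":
        raise ValueError(f"{path}: not a circlecap oligo manifest")
    for rec in reader:
        contig = rec["contig"]
        frag = Fragment(
            interval=Interval(contig, int(rec["frag_start"]), int(rec["frag_end"])),
            left_kind=rec["left_kind"],
            right_kind=rec["right_kind"],
        )
        pair = ArmPair(
            arm5=rec["arm5_seq"],
            arm3=rec["arm3_seq"],
            arm5_interval=Interval(
                contig, int(rec["arm5_start"]), int(rec["arm5_end"])
            ),
            arm3_interval=Interval(
                contig, int(rec["arm3_start"]), int(rec["arm3_end"])
            ),
            captured_strand=rec["captured_strand"],
        )
        flags = set() if rec["flags"] == "." else set(rec["flags"].split(","))
        oligos.append(
            CaptureOligo(
                id=rec["id"],
                arm_pair=pair,
                fragment=frag,
                circle_size=int(rec["circle_size"]),
                gc5=float(rec["gc5"]),
                gc3=float(rec["gc3"]),
                qc_flags=flags,
                full_fragment=rec["full_fragment"] == "1",
            )
        )
    return oligos
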