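"""Synthetic references, a capture-yield model, and fragment-end read simulation.

The yield model is multiplicative: a decreasing logistic in circle size
(half-maximal at ``size_half_max``, exactly zero beyond twice that) times
a G+C plateau window per arm whose low-GC shoulder narrows as the
hybridization temperature rises — low-GC arms anneal poorly at high
temperature, high-GC arms resist denaturation at any temperature. The
model is a qualitative construct: its parameters live in SimConfig and
nothing is fitted to experimental counts.

Reads are fragment-end tags: the first ``read_length`` bases of the
captured circle from its anchored 3' end (both ends in paired mode,
read 2 from the 5' end). The first 20 bases of every on-target read
therefore reproduce the assembled oligo's 3'-side arm sequence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pysam

from .assemble import AdapterSet
from .design import CaptureOligo
from .digest import MSEI, Enzyme
from .genome_model import Interval, Reference, VariantSet, revcomp

OFF_TARGET = "off_target"
ADAPTER = "adapter"

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class SimConfig:
    """Knobs for synthetic reference construction and read simulation."""

    seed: int | None = None
    # reference construction
    contig_name: str = "sim1"
    contig_length: int = 100_000
    fragment_length_range: tuple[int, int] = (50, 1500)
    site_spacing: tuple[int, ...] | None = None
    snp_rate: float = 0.0
    repeat_count: int = 0
    balance_end_gc: bool = False
    # capture-yield model
    hybridization_temp_c: float = 55.0
    size_half_max: int = 600
    size_steepness: float = 40.0
    gc_opt_low: float = 0.30
    gc_opt_high: float = 0.60
    gc_shoulder_per_degree: float = 0.005
    gc_shoulder_ref_temp: float = 65.0
    gc_shoulder_high: float = 0.05
    # read simulation
    off_target_rate: float = 0.10
    adapter_read_rate: float = 0.02
    pcr: bool = True
    pcr_lognormal_sigma: float = 0.8
    read_length: int = 42
    mode: str = "single"
    total_reads: int = 10_000
    error_rate: float = 0.0
    zero_yield_oligos: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("SimConfig.seed is mandatory")
        for name in ("snp_rate", "off_target_rate", "adapter_read_rate", "error_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.off_target_rate + self.adapter_read_rate >= 1.0:
            raise ValueError("off_target_rate + adapter_read_rate must be < 1")
        if self.read_length < 20:
            raise ValueError("read_length must be >= 20")
        if self.mode not in ("single", "paired"):
            raise ValueError(f"mode must be single or paired, got {self.mode!r}")


@dataclass(frozen=True)
class SimRead:
    name: str
    sequence: str
    provenance: str  # oligo id, "off_target" or "adapter"
    read_index: int = 1  # 1 or 2
    contig: str | None = None  # None => unmapped (adapter contaminants)
    start: int = -1
    end: int = -1
    reverse: bool = False


@dataclass
class TruthTable:
    """Ground truth emitted alongside simulated reads."""

    expected_weights: dict[str, float]
    provenance: list[tuple[str, str]]  # (read name, label); one row per read
    per_oligo_counts: dict[str, int]
    features: list[tuple[str, Interval]] = field(default_factory=list)

    @property
    def n_reads(self) -> int:
        return len(self.provenance)


@dataclass
class SimResult:
    reads: list[SimRead]
    truth: TruthTable
    mode: str


# ---------------------------------------------------------------------------
# Synthetic reference construction
# ---------------------------------------------------------------------------

def _random_dna(rng: np.random.Generator, n: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, n)]


def _scrub_sites(
    arr: np.ndarray, rec: bytes, rng: np.random.Generator, protected: set[int]
) -> None:
    """Mutate bases until the recognition sequence no longer occurs,
    leaving protected positions untouched."""
    k = len(rec)
    seq = arr.tobytes()
    i = seq.find(rec)
    guard = 0
    while i != -1:
        target = None
        for j in range(i, i + k):
            if j not in protected:
                target = j
                break
        if target is None:  # fully protected occurrence (a planted site)
            i = seq.find(rec, i + 1)
            continue
        current = arr[target]
        choices = [b for b in _BASES if b != current]
        arr[target] = choices[rng.integers(0, len(choices))]
        seq = arr.tobytes()
        i = seq.find(rec, max(0, i - k))
        guard += 1
        if guard > 10 * len(arr):
            raise RuntimeError("site scrubbing failed to converge")


def make_synthetic_reference(
    cfg: SimConfig, enzyme: Enzyme = MSEI
) -> tuple[Reference, VariantSet, list[tuple[str, Interval]]]:
    """A random contig with recognition sites planted at controlled spacing.

    Returns the reference, a VariantSet of planted SNP positions, and a
    feature list of planted sites/SNPs/repeats. The fragment lengths
    between planted cuts equal the requested spacings exactly; accidental
    recognition occurrences elsewhere are scrubbed out. Reproducible per
    seed.
    """
    rng = np.random.default_rng(cfg.seed)
    rec = enzyme.recognition
    k = len(rec)
    lo, hi = cfg.fragment_length_range
    if cfg.site_spacing is not None:
        spacings = list(cfg.site_spacing)
    else:
        spacings = []
        total = 0
        while total < cfg.contig_length:
            s = int(rng.integers(lo, hi + 1))
            spacings.append(s)
            total += s
    if any(s < 2 * k for s in spacings):
        raise ValueError(f"spacings must be >= {2 * k} bases")
    if len(spacings) < 1:
        raise ValueError("at least one fragment required")

    length = sum(spacings)
    cuts = list(np.cumsum(spacings[:-1], dtype=int))
    arr = _random_dna(rng, length)

    # plant one recognition occurrence per cut: cut position p means the
    # site starts at p - cut_offset.
    protected: set[int] = set()
    for p in cuts:
        site_start = p - enzyme.cut_offset
        for j, base in enumerate(rec):
            arr[site_start + j] = base.encode()
            protected.add(site_start + j)
    _scrub_sites(arr, rec.encode(), rng, protected)

    if cfg.balance_end_gc:
        _balance_fragment_ends(arr, cuts, length, enzyme, rng, protected)
        _scrub_sites(arr, rec.encode(), rng, protected)

    features: list[tuple[str, Interval]] = []
    contig = cfg.contig_name
    for p in cuts:
        features.append(
            ("site", Interval(contig, p - enzyme.cut_offset, p - enzyme.cut_offset + k))
        )

    # planted SNP mask positions (the sequence itself is left unchanged;
    # these stand in for known-variant annotations)
    positions: set[tuple[str, int]] = set()
    if cfg.snp_rate > 0:
        n_snps = int(round(cfg.snp_rate * length))
        candidates = np.setdiff1d(
            np.arange(length), np.fromiter(protected, dtype=int, count=len(protected))
        )
        chosen = rng.choice(candidates, size=min(n_snps, len(candidates)), replace=False)
        for pos in sorted(int(x) for x in chosen):
            positions.add((contig, pos))
            features.append(("snp", Interval(contig, pos, pos + 1)))

    # planted repeats: copy a 20-mer elsewhere, keeping sites intact
    for r in range(cfg.repeat_count):
        for _ in range(100):
            src = int(rng.integers(0, length - 20))
            dst = int(rng.integers(0, length - 20))
            src_range = set(range(src, src + 20))
            dst_range = set(range(dst - k, dst + 20 + k))
            if src_range & protected or set(range(dst, dst + 20)) & protected:
                continue
            if abs(src - dst) < 20:
                continue
            snapshot = arr[dst : dst + 20].copy()
            arr[dst : dst + 20] = arr[src : src + 20]
            window = arr[max(0, dst - k) : dst + 20 + k].tobytes().decode()
            if rec in window:
                arr[dst : dst + 20] = snapshot
                continue
            features.append(("repeat", Interval(contig, src, src + 20)))
            features.append(("repeat", Interval(contig, dst, dst + 20)))
            break
        else:
            raise RuntimeError("failed to place planted repeat")

    reference = Reference({contig: arr.tobytes().decode()})
    return reference, VariantSet(frozenset(positions)), features


def _balance_fragment_ends(
    arr: np.ndarray,
    cuts: list[int],
    length: int,
    enzyme: Enzyme,
    rng: np.random.Generator,
    protected: set[int],
    arm: int = 20,
) -> None:
    """Force the 20-mers flanking every fragment boundary to 50% G+C,
    preserving planted site bases."""
    rec = enzyme.recognition
    boundaries = [0, *cuts, length]
    for b in boundaries:
        # right arm of the fragment ending at b: [b - arm, b)
        if b - arm >= 0 and b > 0:
            window = _rebuild_window(arr, b - arm, b, rng, protected, rec, arm // 2)
            arr[b - arm : b] = np.frombuffer(window.encode(), dtype="S1")
        # left arm of the fragment starting at b: [b, b + arm)
        if b + arm <= length and b < length:
            window = _rebuild_window(arr, b, b + arm, rng, protected, rec, arm // 2)
            arr[b : b + arm] = np.frombuffer(window.encode(), dtype="S1")


def _rebuild_window(
    arr: np.ndarray,
    start: int,
    end: int,
    rng: np.random.Generator,
    protected: set[int],
    rec: str,
    gc_count: int,
) -> str:
    fixed = {
        i - start: arr[i].decode() for i in range(start, end) if i in protected
    }
    n = end - start
    gc_fixed = sum(c in "GC" for c in fixed.values())
    free_idx = [i for i in range(n) if i not in fixed]
    gc_free = gc_count - gc_fixed
    gc_free = max(0, min(gc_free, len(free_idx)))
    for _ in range(500):
        picks = ["GC"[rng.integers(0, 2)] for _ in range(gc_free)]
        picks += ["AT"[rng.integers(0, 2)] for _ in range(len(free_idx) - gc_free)]
        order = rng.permutation(len(free_idx))
        chars = [""] * n
        for i, c in fixed.items():
            chars[i] = c
        for slot, pick_i in enumerate(order):
            chars[free_idx[slot]] = picks[pick_i]
        window = "".join(chars)
        if rec not in window:
            return window
    raise RuntimeError("failed to rebuild balanced fragment-end window")


# ---------------------------------------------------------------------------
# Capture-yield model
# ---------------------------------------------------------------------------

def _size_factor(circle_size: float, cfg: SimConfig) -> float:
    if circle_size > 2 * cfg.size_half_max:
        return 0.0
    z = (circle_size - cfg.size_half_max) / cfg.size_steepness
    return 1.0 / (1.0 + math.exp(z))


def _gc_factor(gc: float, cfg: SimConfig) -> float:
    if cfg.gc_opt_low <= gc <= cfg.gc_opt_high:
        return 1.0
    w_low = max(
        0.01,
        cfg.gc_shoulder_per_degree
        * (cfg.gc_shoulder_ref_temp - cfg.hybridization_temp_c),
    )
    if gc < cfg.gc_opt_low:
        return math.exp(-(((cfg.gc_opt_low - gc) / w_low) ** 2))
    return math.exp(-(((gc - cfg.gc_opt_high) / cfg.gc_shoulder_high) ** 2))


def capture_yield(oligo: CaptureOligo, cfg: SimConfig) -> float:
    """Expected relative capture yield of one oligo (>= 0)."""
    return capture_yield_terms(oligo.circle_size, oligo.gc5, oligo.gc3, cfg)


def capture_yield_terms(
    circle_size: float, gc5: float, gc3: float, cfg: SimConfig
) -> float:
    return _size_factor(circle_size, cfg) * _gc_factor(gc5, cfg) * _gc_factor(gc3, cfg)


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

def _fragment_end_reads(
    oligo: CaptureOligo, reference: Reference, read_length: int, paired: bool
) -> list[tuple[str, str, int, int, bool, int]]:
    """Template reads for one oligo: (seq, contig, start, end, reverse, index)."""
    contig = oligo.contig
    anchor = oligo.anchored_cut
    circle_start = oligo.circle_start
    L = min(read_length, oligo.circle_size)
    out = []
    if oligo.captured_strand == "+":
        # 3' end of the captured top strand: read leftward from the cut
        start, end = anchor - L, anchor
        out.append((revcomp(reference.fetch(Interval(contig, start, end))), contig, start, end, True, 1))
        if paired:
            s2, e2 = circle_start, circle_start + L
            out.append((reference.fetch(Interval(contig, s2, e2)), contig, s2, e2, False, 2))
    else:
        start, end = anchor, anchor + L
        out.append((reference.fetch(Interval(contig, start, end)), contig, start, end, False, 1))
        if paired:
            s2, e2 = circle_start - L, circle_start
            out.append((revcomp(reference.fetch(Interval(contig, s2, e2))), contig, s2, e2, True, 2))
    return out


def _apply_errors(seq: str, rng: np.random.Generator, rate: float) -> str:
    if rate <= 0:
        return seq
    chars = list(seq)
    for i in range(len(chars)):
        if rng.random() < rate:
            current = chars[i]
            alts = [b for b in "ACGT" if b != current]
            chars[i] = alts[rng.integers(0, 3)]
    return "".join(chars)


def simulate_reads(
    oligos: Sequence[CaptureOligo],
    reference: Reference,
    cfg: SimConfig,
    adapters: AdapterSet | None = None,
) -> SimResult:
    """Draw capture events and emit fragment-end reads with ground truth.

    On-target reads are multinomial across oligos with probabilities
    proportional to capture_yield (times a per-oligo log-normal factor
    when pcr is on); off-target reads are uniform over the reference,
    excluding start positions that would mimic a true fragment-end tag;
    adapter contaminant reads are substrings of the adapter components
    and are emitted as unmapped.
    """
    if not oligos:
        raise ValueError("simulate_reads requires at least one oligo")
    rng = np.random.default_rng(cfg.seed)
    adapters = adapters or AdapterSet()
    paired = cfg.mode == "paired"
    L = cfg.read_length

    weights = np.array(
        [
            0.0 if o.id in cfg.zero_yield_oligos else capture_yield(o, cfg)
            for o in oligos
        ],
        dtype=float,
    )
    expected = {o.id: float(w) for o, w in zip(oligos, weights)}
    if cfg.pcr:
        weights = weights * rng.lognormal(0.0, cfg.pcr_lognormal_sigma, len(weights))
    if weights.sum() <= 0:
        raise ValueError("no oligo has positive capture yield")

    p_on = 1.0 - cfg.off_target_rate - cfg.adapter_read_rate
    n_on, n_off, n_adp = rng.multinomial(
        cfg.total_reads, [p_on, cfg.off_target_rate, cfg.adapter_read_rate]
    )
    per_oligo = rng.multinomial(n_on, weights / weights.sum())

    # coordinates whose tag would collide with a genuine fragment-end
    anchors: set[tuple[str, int]] = set()
    for o in oligos:
        anchors.add((o.contig, o.anchored_cut))
        anchors.add((o.contig, o.circle_start))

    reads: list[SimRead] = []
    provenance: list[tuple[str, str]] = []
    counts: dict[str, int] = {o.id: 0 for o in oligos}

    for idx, (oligo, n) in enumerate(zip(oligos, per_oligo)):
        if n == 0:
            continue
        templates = _fragment_end_reads(oligo, reference, L, paired)
        counts[oligo.id] = int(n)
        for i in range(int(n)):
            name = f"on_{idx}_{i}"
            for seq, contig, start, end, reverse, ridx in templates:
                reads.append(
                    SimRead(
                        name=name,
                        sequence=_apply_errors(seq, rng, cfg.error_rate),
                        provenance=oligo.id,
                        read_index=ridx,
                        contig=contig,
                        start=start,
                        end=end,
                        reverse=reverse,
                    )
                )
            provenance.append((name, oligo.id))

    contig_names = reference.names
    lengths = np.array([reference.length(c) for c in contig_names], dtype=float)
    contig_p = lengths / lengths.sum()
    for i in range(int(n_off)):
        name = f"off_{i}"
        for _ in range(1000):
            ci = int(rng.choice(len(contig_names), p=contig_p))
            contig = contig_names[ci]
            clen = int(lengths[ci])
            if clen <= L:
                continue
            start = int(rng.integers(0, clen - L))
            end = start + L
            reverse = bool(rng.integers(0, 2))
            tag = end if reverse else start
            if (contig, tag) in anchors:
                continue
            break
        else:
            raise RuntimeError("could not place off-target read away from anchors")
        seq = reference.fetch(Interval(contig, start, end))
        if reverse:
            seq = revcomp(seq)
        reads.append(
            SimRead(
                name=name,
                sequence=_apply_errors(seq, rng, cfg.error_rate),
                provenance=OFF_TARGET,
                contig=contig,
                start=start,
                end=end,
                reverse=reverse,
            )
        )
        provenance.append((name, OFF_TARGET))

    pool = adapters.common_region
    pool = pool + pool  # allow any offset for short components
    for i in range(int(n_adp)):
        name = f"adp_{i}"
        off = int(rng.integers(0, len(adapters.common_region)))
        seq = pool[off : off + L]
        if rng.integers(0, 2):
            seq = revcomp(seq)
        reads.append(
            SimRead(
                name=name,
                sequence=_apply_errors(seq, rng, cfg.error_rate),
                provenance=ADAPTER,
            )
        )
        provenance.append((name, ADAPTER))

    truth = TruthTable(
        expected_weights=expected,
        provenance=provenance,
        per_oligo_counts=counts,
    )
    return SimResult(reads=reads, truth=truth, mode=cfg.mode)


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_fastq(result: SimResult, prefix: str | Path) -> list[Path]:
    """reads.fastq for single mode, reads_1/reads_2.fastq for paired."""
    prefix = Path(prefix)
    if result.mode == "paired":
        paths = [Path(f"{prefix}_1.fastq"), Path(f"{prefix}_2.fastq")]
        handles = [open(p, "w") for p in paths]
    else:
        paths = [Path(f"{prefix}.fastq")]
        handles = [open(paths[0], "w")]
    try:
        for read in result.reads:
            fh = handles[read.read_index - 1] if result.mode == "paired" else handles[0]
            qual = "I" * len(read.sequence)
            fh.write(f"@{read.name}\n{read.sequence}\n+\n{qual}\n")
    finally:
        for fh in handles:
            fh.close()
    return paths


def write_truth_tsv(truth: TruthTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# circlecap truth table\n")
        fh.write("record\tkey\tvalue\n")
        for oid in truth.expected_weights:
            fh.write(f"weight\t{oid}\t{truth.expected_weights[oid]:.8g}\n")
        for oid in truth.per_oligo_counts:
            fh.write(f"count\t{oid}\t{truth.per_oligo_counts[oid]}\n")
        for name, label in truth.provenance:
            fh.write(f"read\t{name}\t{label}\n")


def read_truth_tsv(path: str | Path) -> TruthTable:
    weights: dict[str, float] = {}
    counts: dict[str, int] = {}
    provenance: list[tuple[str, str]] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or line.startswith("record\t"):
                continue
            record, key, value = line.rstrip("\n").split("\t")
            if record == "weight":
                weights[key] = float(value)
            elif record == "count":
                counts[key] = int(value)
            elif record == "read":
                provenance.append((key, value))
    return TruthTable(
        expected_weights=weights, provenance=provenance, per_oligo_counts=counts
    )


def write_truth_sam(
    result: SimResult, reference: Reference, path: str | Path
) -> None:
    """Emit the simulator's true placements as SAM alignments.

    Error-free simulated reads align perfectly at their true positions,
    so this stands in for an external aligner; adapter contaminants are
    written as unmapped records.
    """
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [
            {"SN": name, "LN": reference.length(name)} for name in reference.names
        ],
    }
    paired = result.mode == "paired"
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        tid = {name: i for i, name in enumerate(reference.names)}
        for read in result.reads:
            a = pysam.AlignedSegment(out.header)
            a.query_name = read.name
            flag = 0
            if paired:
                flag |= 0x1 | (0x40 if read.read_index == 1 else 0x80)
            seq = read.sequence
            if read.contig is None:
                flag |= 0x4
                a.query_name = read.name
                a.flag = flag
                a.reference_id = -1
                a.reference_start = -1
                a.mapping_quality = 0
                a.query_sequence = seq
                a.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
            else:
                if read.reverse:
                    flag |= 0x10
                    seq = revcomp(seq)  # SAM stores the forward-strand sequence
                a.flag = flag
                a.reference_id = tid[read.contig]
                a.reference_start = read.start
                a.mapping_quality = 60
                a.cigartuples = [(0, read.end - read.start)]
                a.query_sequence = seq
                a.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
            out.write(a)


def write_features_bed(
    features: Sequence[tuple[str, Interval]], path: str | Path
) -> None:
    with open(path, "w") as fh:
        for label, iv in features:
            fh.write(f"{iv.contig}\t{iv.start}\t{iv.end}\t{label}\t0\t+\n")
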