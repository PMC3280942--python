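"""Core sequence and interval types plus flat-file readers/writers.

All coordinates are 0-based half-open throughout the package; BED is
ingested verbatim, SAM/VCF positions are converted at the boundary.
Soft-masked (lowercase) reference bases are uppercased on load but a
per-base mask is retained for downstream repeat QC.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np

_REFERENCE_ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTUNacgtun", "TGCAANtgcaan")


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True)
class Interval:
    """A 0-based half-open genomic interval; ``length == end - start``."""

    contig: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.contig}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return (
            self.contig == other.contig
            and self.start < other.end
            and other.start < self.end
        )

    def contains_position(self, contig: str, pos: int) -> bool:
        return contig == self.contig and self.start <= pos < self.end

    def replace(self, **kwargs) -> "Interval":
        return dataclasses.replace(self, **kwargs)


class Reference:
    """An ordered collection of uppercase DNA contigs over {A,C,G,T,N}.

    ``softmask[name]`` is a boolean array flagging bases that were
    lowercase in the source FASTA.
    """

    def __init__(
        self,
        contigs: dict[str, str],
        softmask: dict[str, np.ndarray] | None = None,
    ) -> None:
        self.contigs: dict[str, str] = {}
        self.softmask: dict[str, np.ndarray] = {}
        for name, seq in contigs.items():
            if not seq:
                raise ValueError(f"contig {name!r} is empty")
            up = seq.upper()
            bad = set(up) - _REFERENCE_ALPHABET
            if bad:
                raise ValueError(
                    f"contig {name!r} contains invalid characters: {sorted(bad)}"
                )
            self.contigs[name] = up
            if softmask is not None and name in softmask:
                mask = np.asarray(softmask[name], dtype=bool)
                if mask.shape != (len(up),):
                    raise ValueError(f"softmask length mismatch for {name!r}")
            else:
                mask = np.fromiter(
                    (c.islower() for c in seq), dtype=bool, count=len(seq)
                )
            self.softmask[name] = mask

    @property
    def names(self) -> list[str]:
        return list(self.contigs)

    def __contains__(self, name: str) -> bool:
        return name in self.contigs

    def __getitem__(self, name: str) -> str:
        return self.contigs[name]

    def length(self, name: str) -> int:
        return len(self.contigs[name])

    def fetch(self, interval: Interval) -> str:
        seq = self.contigs[interval.contig]
        if interval.end > len(seq):
            raise ValueError(f"{interval} exceeds contig length {len(seq)}")
        return seq[interval.start : interval.end]

    def softmask_fraction(self, interval: Interval) -> float:
        mask = self.softmask[interval.contig]
        return float(mask[interval.start : interval.end].mean())


@dataclass(frozen=True)
class VariantSet:
    """Known-variant positions as a set of (contig, 0-based position)."""

    positions: frozenset[tuple[str, int]] = field(default_factory=frozenset)

    def __len__(self) -> int:
        return len(self.positions)

    def __contains__(self, item: tuple[str, int]) -> bool:
        return item in self.positions

    def overlapping(self, interval: Interval) -> list[int]:
        return sorted(
            pos
            for contig, pos in self.positions
            if contig == interval.contig and interval.start <= pos < interval.end
        )

    def overlaps(self, interval: Interval) -> bool:
        return any(
            contig == interval.contig and interval.start <= pos < interval.end
            for contig, pos in self.positions
        )


def revcomp(seq: str) -> str:
    """Reverse complement over {A,C,G,T,N,U}; U pairs with A."""
    bad = set(seq) - set("ACGTUNacgtun")
    if bad:
        raise ValueError(f"cannot reverse-complement characters {sorted(bad)}")
    return seq.translate(_COMPLEMENT)[::-1]


def gc_fraction(seq: str) -> float:
    """(#G + #C) / len(seq); N counts toward the denominator only."""
    if not seq:
        raise ValueError("gc_fraction of empty sequence")
    up = seq.upper()
    return (up.count("G") + up.count("C")) / len(up)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def load_reference(path: str | Path) -> Reference:
    """Read a FASTA file into a Reference, tracking softmask per base.

    A deliberately small reader so parse errors can name the offending
    line; sequences are validated/uppercased by the Reference constructor.
    """
    path = Path(path)
    contigs: dict[str, str] = {}
    order: list[str] = []
    chunks: list[str] = []
    name: str | None = None
    name_line = 0

    def _commit(lineno: int) -> None:
        if name is None:
            return
        seq = "".join(chunks)
        if not seq:
            raise ParseError(f"{path}:{name_line}: record {name!r} has no sequence")
        contigs[name] = seq
        chunks.clear()

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                _commit(lineno)
                name = line[1:].split()[0] if len(line) > 1 else ""
                if not name:
                    raise ParseError(f"{path}:{lineno}: empty FASTA header")
                if name in contigs or name in order:
                    raise ParseError(f"{path}:{lineno}: duplicate contig {name!r}")
                order.append(name)
                name_line = lineno
            else:
                if name is None:
                    raise ParseError(
                        f"{path}:{lineno}: sequence before first FASTA header"
                    )
                bad = set(line.upper()) - _REFERENCE_ALPHABET
                if bad:
                    raise ParseError(
                        f"{path}:{lineno}: invalid characters {sorted(bad)}"
                    )
                chunks.append(line)
        _commit(lineno if name is not None else 0)
    if not contigs:
        raise ParseError(f"{path}: no FASTA records found")
    return Reference({n: contigs[n] for n in order})


def write_fasta(
    records: "Reference | dict[str, str] | Iterable[tuple[str, str]]",
    path: str | Path,
    width: int = 60,
) -> None:
    """Write sequences as FASTA with fixed line wrapping."""
    if isinstance(records, Reference):
        items: Iterable[tuple[str, str]] = records.contigs.items()
    elif isinstance(records, dict):
        items = records.items()
    else:
        items = records
    with open(path, "w") as fh:
        for name, seq in items:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def load_intervals(path: str | Path) -> list[Interval]:
    """Read a 3+ column BED file; column 6 (strand) honored, default '+'."""
    path = Path(path)
    out: list[Interval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >= 3 BED columns")
            contig = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            if start < 0 or start >= end:
                raise ParseError(
                    f"{path}:{lineno}: invalid BED interval {start}-{end}"
                )
            strand = "+"
            if len(fields) >= 6 and fields[5] in ("+", "-"):
                strand = fields[5]
            out.append(Interval(contig, start, end, strand))
    return out


def write_bed(
    intervals: Iterable[Interval],
    path: str | Path,
    names: Iterable[str] | None = None,
    header_comments: Iterable[str] = (),
) -> None:
    """Write BED3 (or BED6 when names are given)."""
    intervals = list(intervals)
    name_list = list(names) if names is not None else None
    with open(path, "w") as fh:
        for comment in header_comments:
            fh.write(f"# {comment}\n")
        for i, iv in enumerate(intervals):
            if name_list is None:
                fh.write(f"{iv.contig}\t{iv.start}\t{iv.end}\n")
            else:
                fh.write(
                    f"{iv.contig}\t{iv.start}\t{iv.end}\t{name_list[i]}\t0\t{iv.strand}\n"
                )


# ---------------------------------------------------------------------------
# Variant positions (BED or minimal VCF; only CHROM/POS consulted)
# ---------------------------------------------------------------------------

def load_variants(path: str | Path) -> VariantSet:
    path = Path(path)
    if path.suffix.lower() == ".vcf":
        return _load_variants_vcf(path)
    positions: set[tuple[str, int]] = set()
    for iv in load_intervals(path):
        for pos in range(iv.start, iv.end):
            positions.add((iv.contig, pos))
    return VariantSet(frozenset(positions))


def _load_variants_vcf(path: Path) -> VariantSet:
    positions: set[tuple[str, int]] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ParseError(f"{path}:{lineno}: expected CHROM and POS")
            try:
                pos = int(fields[1])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer POS") from exc
            if pos < 1:
                raise ParseError(f"{path}:{lineno}: VCF POS must be >= 1")
            positions.add((fields[0], pos - 1))  # VCF is 1-based
    return VariantSet(frozenset(positions))


def merge_intervals(intervals: Iterable[Interval]) -> list[Interval]:
    """Union of intervals per contig, strand-ignored, sorted."""
    by_contig: dict[str, list[Interval]] = {}
    for iv in intervals:
        by_contig.setdefault(iv.contig, []).append(iv)
    merged: list[Interval] = []
    for contig in sorted(by_contig):
        ivs = sorted(by_contig[contig], key=lambda v: (v.start, v.end))
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_end:
                cur_end = max(cur_end, iv.end)
            else:
                merged.append(Interval(contig, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
        merged.append(Interval(contig, cur_start, cur_end))
    return merged


def iter_intervals_bases(intervals: Iterable[Interval]) -> Iterator[tuple[str, int]]:
    for iv in merge_intervals(intervals):
        for pos in range(iv.start, iv.end):
            yield iv.contig, pos
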