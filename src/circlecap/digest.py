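"""In-silico restriction digestion of a reference into fragments.

Digestion is modeled on the top strand only; palindromic recognition
sequences (e.g. MseI T^TAA) make this exact. Complete digestion is
assumed — capture inefficiency is the simulator's job, not the digest's.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .genome_model import Interval, Reference, revcomp

CUT_SITE = "cut_site"
CONTIG_START = "contig_start"
CONTIG_END = "contig_end"


@dataclass(frozen=True)
class Enzyme:
    """A restriction enzyme: recognition sequence plus top-strand cut offset."""

    name: str
    recognition: str
    cut_offset: int

    def __post_init__(self) -> None:
        rec = self.recognition
        if not rec or set(rec) - set("ACGT"):
            raise ValueError(
                f"enzyme {self.name!r}: recognition must be non-empty over ACGT "
                "(ambiguity codes unsupported)"
            )
        if not (0 <= self.cut_offset <= len(rec)):
            raise ValueError(
                f"enzyme {self.name!r}: cut_offset {self.cut_offset} outside "
                f"[0, {len(rec)}]"
            )

    @property
    def is_palindromic(self) -> bool:
        return self.recognition == revcomp(self.recognition)


#: MseI cuts T^TAA.
MSEI = Enzyme("MseI", "TTAA", 1)

BUILTIN_ENZYMES = {"MseI": MSEI}


def require_palindromic(enzymes: Iterable[Enzyme]) -> None:
    """Top-strand-only scanning is exact only for palindromic sites."""
    for enz in enzymes:
        if not enz.is_palindromic:
            raise ValueError(
                f"enzyme {enz.name!r} has non-palindromic recognition "
                f"{enz.recognition!r}; only palindromic enzymes are supported"
            )


@dataclass(frozen=True)
class Fragment:
    """A restriction fragment with boundary provenance.

    Fragments are strandless and stored on '+'; the enzymes responsible
    for each internal cut boundary are recorded.
    """

    interval: Interval
    left_kind: str
    right_kind: str
    left_enzymes: tuple[str, ...] = ()
    right_enzymes: tuple[str, ...] = ()

    @property
    def contig(self) -> str:
        return self.interval.contig

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end

    @property
    def length(self) -> int:
        return self.interval.length

    def sequence(self, reference: Reference) -> str:
        return reference.fetch(self.interval)


def find_sites(seq: str, enzyme: Enzyme) -> list[int]:
    """All top-strand cut positions (site_start + cut_offset), sorted.

    Overlapping recognition occurrences are all reported. Windows
    containing N never match because recognition is N-free.
    """
    rec = enzyme.recognition
    positions: list[int] = []
    i = seq.find(rec)
    while i != -1:
        positions.append(i + enzyme.cut_offset)
        i = seq.find(rec, i + 1)
    return positions


def digest(
    reference: Reference, enzymes: Sequence[Enzyme]
) -> dict[str, list[Fragment]]:
    """Cut every contig at the union of enzyme cut positions.

    Returns fragments per contig that tile the contig exactly. Cut
    positions falling on a contig edge are dropped (no empty fragments).
    """
    if not enzymes:
        raise ValueError("digest requires at least one enzyme")
    out: dict[str, list[Fragment]] = {}
    for contig in reference.names:
        seq = reference[contig]
        cuts: dict[int, list[str]] = {}
        for enz in enzymes:
            for pos in find_sites(seq, enz):
                if 0 < pos < len(seq):
                    cuts.setdefault(pos, []).append(enz.name)
        boundaries = [0, *sorted(cuts), len(seq)]
        provenance = {p: tuple(sorted(set(v))) for p, v in cuts.items()}
        frags: list[Fragment] = []
        for left, right in zip(boundaries, boundaries[1:]):
            frags.append(
                Fragment(
                    interval=Interval(contig, left, right),
                    left_kind=CUT_SITE if left in provenance else CONTIG_START,
                    right_kind=CUT_SITE if right in provenance else CONTIG_END,
                    left_enzymes=provenance.get(left, ()),
                    right_enzymes=provenance.get(right, ()),
                )
            )
        out[contig] = frags
    return out


def fragments_overlapping(
    fragments: Sequence[Fragment], roi: Interval
) -> list[Fragment]:
    """Fragments with >= 1 base of overlap with the ROI, in genomic order."""
    if not fragments:
        return []
    contigs = {f.contig for f in fragments}
    if roi.contig not in contigs:
        raise ValueError(
            f"ROI contig {roi.contig!r} not present among fragments {sorted(contigs)}"
        )
    hits = [
        f
        for f in fragments
        if f.contig == roi.contig and f.start < roi.end and roi.start < f.end
    ]
    return sorted(hits, key=lambda f: f.start)


def flatten(fragments_by_contig: dict[str, list[Fragment]]) -> list[Fragment]:
    out: list[Fragment] = []
    for contig in fragments_by_contig:
        out.extend(fragments_by_contig[contig])
    return out
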