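"""Full-length oligo and vector sequence construction.

Each assembled capture oligo is armA + forward component + reverse
component + armB: the arms are reverse complements of the target sites
they bridge (the oligo is a splint hybridizing the captured strand), and
the middle common region carries the two sequencing-adapter components
in inverted orientation. The universal vector is the reverse complement
of that common region. A fixed number of thymines in the common region
are substituted with uracils so the splint can be fragmented away after
circularization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .design import CaptureOligo
from .genome_model import revcomp, write_fasta

# Placeholder adapter components (the real vendor sequences are not
# redistributable); lengths 58/61 match the standard paired-end adapter
# component lengths. Supply real sequences via AdapterSet/config.
PLACEHOLDER_FORWARD = (
    "TTGTAACTAGACAATAGTGAAACTATAATGACGCAGTAGATCCGTCCATTATATCGTG"
)
PLACEHOLDER_REVERSE = (
    "TATTTACGCGTAGAAGAATTCCTAAGTGTCTCGCTGGGGGGATTCACGCATAACGTATTAG"
)


@dataclass(frozen=True)
class AdapterSet:
    """Forward/reverse sequencing-adapter components embedded in every oligo."""

    forward_component: str = PLACEHOLDER_FORWARD
    reverse_component: str = PLACEHOLDER_REVERSE
    forward_name: str = "adapter_fwd_placeholder"
    reverse_name: str = "adapter_rev_placeholder"
    #: swap which component abuts which arm (adapter polarity is a convention)
    flip_components: bool = False

    def __post_init__(self) -> None:
        for label, seq in (
            ("forward_component", self.forward_component),
            ("reverse_component", self.reverse_component),
        ):
            if not seq or set(seq) - set("ACGT"):
                raise ValueError(f"{label} must be non-empty over ACGT")

    @property
    def common_region(self) -> str:
        if self.flip_components:
            return self.reverse_component + self.forward_component
        return self.forward_component + self.reverse_component


@dataclass(frozen=True)
class AssembledOligo:
    oligo_id: str
    sequence: str  # over {A,C,G,T,U}
    layout: tuple[tuple[str, int, int], ...]  # (segment, start, end)
    u_positions: tuple[int, ...] = ()

    def __len__(self) -> int:
        return len(self.sequence)

    def segment(self, name: str) -> str:
        for seg, start, end in self.layout:
            if seg == name:
                return self.sequence[start:end]
        raise KeyError(name)

    @property
    def common_region(self) -> str:
        return self.segment("common_region")

    def without_uracils(self) -> str:
        return self.sequence.replace("U", "T")


def build_capture_oligo(
    oligo: CaptureOligo, adapters: AdapterSet
) -> AssembledOligo:
    """Assemble armA + common region + armB for one designed oligo.

    armA is complementary to the captured strand's 3'-end target site and
    armB to its 5'-end site, so that the assembled oligo splints the two
    fragment ends. With default 58/61-nt components and 20-nt arms the
    assembled length is 159 and the vector length 119.
    """
    if adapters is None:
        raise ValueError("adapter components are required for assembly")
    pair = oligo.arm_pair
    # stored arm sequences are reference-strand substrings; complement
    # relative to the captured strand here and nowhere else.
    if pair.captured_strand == "+":
        arm_a = revcomp(pair.arm3)  # site on captured strand == stored seq
        arm_b = revcomp(pair.arm5)
    else:
        arm_a = pair.arm3  # revcomp(revcomp(stored))
        arm_b = pair.arm5
    common = adapters.common_region
    sequence = arm_a + common + arm_b
    n_a = len(arm_a)
    layout = (
        ("arm_a", 0, n_a),
        ("common_region", n_a, n_a + len(common)),
        ("arm_b", n_a + len(common), len(sequence)),
    )
    return AssembledOligo(oligo_id=oligo.id, sequence=sequence, layout=layout)


def build_vector(adapters: AdapterSet) -> str:
    """The universal vector: reverse complement of the common region."""
    return revcomp(adapters.common_region)


def uracil_substitute(assembled: AssembledOligo, n: int = 10) -> AssembledOligo:
    """Substitute n thymines with uracils, evenly spaced by T rank.

    Substitution is restricted to the common region (arms are never
    modified). With m thymines available, the substituted T ranks are
    ceil(m*i/n) for i = 1..n; if m < n all thymines are substituted and
    a warning is issued.
    """
    if n < 0:
        raise ValueError("substitution count must be >= 0")
    if n == 0:
        return assembled
    _, cstart, cend = next(
        (seg for seg in assembled.layout if seg[0] == "common_region")
    )
    t_positions = [
        i for i in range(cstart, cend) if assembled.sequence[i] == "T"
    ]
    m = len(t_positions)
    if m < n:
        warnings.warn(
            f"{assembled.oligo_id}: only {m} thymines in common region; "
            f"substituting all instead of {n}",
            stacklevel=2,
        )
        chosen = t_positions
    else:
        ranks = sorted({-(-m * i // n) for i in range(1, n + 1)})  # ceil
        chosen = [t_positions[r - 1] for r in ranks]
    seq = list(assembled.sequence)
    for pos in chosen:
        seq[pos] = "U"
    return AssembledOligo(
        oligo_id=assembled.oligo_id,
        sequence="".join(seq),
        layout=assembled.layout,
        u_positions=tuple(chosen),
    )


def assemble_all(
    oligos: Sequence[CaptureOligo],
    adapters: AdapterSet,
    n_uracils: int = 10,
) -> list[AssembledOligo]:
    out = []
    for o in oligos:
        asm = uracil_substitute(build_capture_oligo(o, adapters), n=n_uracils)
        o.assembled_sequence = asm.sequence
        out.append(asm)
    return out


def write_assembled_fasta(
    assembled: Iterable[AssembledOligo], path: str | Path
) -> None:
    write_fasta(((a.oligo_id, a.sequence) for a in assembled), path)


def write_layout_tsv(
    assembled: Iterable[AssembledOligo],
    path: str | Path,
    header_comments: Iterable[str] = (),
) -> None:
    with open(path, "w") as fh:
        for comment in header_comments:
            fh.write(f"# {comment}\n")
        fh.write("id\tlength\tsegment\tstart\tend\tu_positions\n")
        for a in assembled:
            u_str = ",".join(map(str, a.u_positions)) if a.u_positions else "."
            for seg, start, end in a.layout:
                fh.write(f"{a.oligo_id}\t{len(a)}\t{seg}\t{start}\t{end}\t{u_str}\n")
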