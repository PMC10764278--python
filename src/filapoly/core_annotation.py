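"""Residue-span arithmetic for the tau(297–391) construct.

The construct is the proteolytically stable core region of Alzheimer
paired helical filaments: residues 297–391 of the longest human brain tau
isoform (2N4R, 441 residues).  All spans are 1-based inclusive in that
isoform numbering; no 0-based spans cross module boundaries.

In a filament structure only part of the construct is resolved (the
*ordered core*); the rest remains disordered.  :func:`core_stats` does the
bookkeeping: e.g. the first intermediate amyloid orders only residues
302–316 — 15 ordered, 80 unresolved, 84% of the construct disordered —
whereas later intermediates order residues 305–380.

The construct sequence is embedded from the canonical 441-residue isoform
record and validated at import time against two independently printed
subsequences (302–316 and the PHF6 motif 306–311), so a transcription error
cannot silently become ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "ResidueSpan",
    "ConstructSequence",
    "TAU_297_391",
    "CONSTRUCT_SPAN",
    "FIA_CORE_SPAN",
    "PHF6_SPAN",
    "core_subsequence",
    "core_stats",
]


@dataclass(frozen=True, order=True)
class ResidueSpan:
    """1-based inclusive residue span in isoform-441 numbering."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"span start {self.start} exceeds end {self.end}")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def __contains__(self, other: "ResidueSpan") -> bool:
        return self.start <= other.start and other.end <= self.end


# tau(297-391) of the 441-residue isoform; validated below
_TAU_297_391_SEQ = (
    "IKHVPGGGSVQIVYKPVDLS"   # 297-316
    "KVTSKCGSLGNIHHKPGGGQ"   # 317-336
    "VEVKSEKLDFKDRVQSKIGS"   # 337-356
    "LDNITHVPGGGNKKIETHKL"   # 357-376
    "TFRENAKAKTDHGAE"        # 377-391
)

CONSTRUCT_SPAN = ResidueSpan(297, 391)
FIA_CORE_SPAN = ResidueSpan(302, 316)   # ordered core of the first intermediate
PHF6_SPAN = ResidueSpan(306, 311)       # VQIVYK hexapeptide


@dataclass(frozen=True)
class ConstructSequence:
    """An amino-acid sequence anchored at a first residue number."""

    first_residue: int
    sequence: str

    @property
    def span(self) -> ResidueSpan:
        return ResidueSpan(
            self.first_residue, self.first_residue + len(self.sequence) - 1
        )

    def subsequence(self, span: ResidueSpan) -> str:
        if span not in self.span:
            raise ValueError(
                f"span {span.start}-{span.end} outside construct "
                f"{self.span.start}-{self.span.end}"
            )
        off = span.start - self.first_residue
        return self.sequence[off : off + len(span)]

    def to_fasta(self, name: str = "tau_297-391", width: int = 60) -> str:
        lines = [f">{name}"]
        lines += [self.sequence[i : i + width]
                  for i in range(0, len(self.sequence), width)]
        return "\n".join(lines) + "\n"


TAU_297_391 = ConstructSequence(297, _TAU_297_391_SEQ)

# validation anchors: fail loudly at import if the embedded sequence drifts
assert len(_TAU_297_391_SEQ) == len(CONSTRUCT_SPAN) == 95
assert TAU_297_391.subsequence(FIA_CORE_SPAN) == "GGGSVQIVYKPVDLS"
assert TAU_297_391.subsequence(PHF6_SPAN) == "VQIVYK"


def core_subsequence(
    construct: ConstructSequence, span: ResidueSpan | tuple[int, int]
) -> str:
    """Amino-acid sequence of an ordered-core span, in isoform numbering."""
    if not isinstance(span, ResidueSpan):
        span = ResidueSpan(*span)
    return construct.subsequence(span)


def core_stats(
    construct_span: ResidueSpan | tuple[int, int],
    core_span: ResidueSpan | tuple[int, int],
) -> tuple[int, int, int]:
    """(ordered, disordered, percent-disordered) residue counts.

    ``ordered`` is the core length, ``disordered`` the rest of the
    construct, and the percentage is rounded to the nearest integer.

    >>> core_stats((297, 391), (302, 316))
    (15, 80, 84)
    """
    if not isinstance(construct_span, ResidueSpan):
        construct_span = ResidueSpan(*construct_span)
    if not isinstance(core_span, ResidueSpan):
        core_span = ResidueSpan(*core_span)
    if core_span not in construct_span:
        raise ValueError(
            f"core {core_span.start}-{core_span.end} outside construct "
            f"{construct_span.start}-{construct_span.end}"
        )
    ordered = len(core_span)
    total = len(construct_span)
    disordered = total - ordered
    return ordered, disordered, round(100.0 * disordered / total)
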