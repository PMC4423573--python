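"""Core domain types shared by all categorization methods.

Coordinates are 1-based and fully closed, following the SAM convention.
``Genome.A`` / ``Genome.B`` are the two subgenome labels; ``Genome.N`` marks
fragments that could not be confidently assigned and ``Genome.UNMAPPED``
fragments with no mapping to any reference.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional

# SAM flag bits
FLAG_PAIRED = 0x1
FLAG_UNMAPPED = 0x4
FLAG_MATE_UNMAPPED = 0x8
FLAG_REVERSE = 0x10
FLAG_READ1 = 0x40
FLAG_READ2 = 0x80
FLAG_SECONDARY = 0x100
FLAG_DUP = 0x400
FLAG_SUPPLEMENTARY = 0x800

# CIGAR ops that consume read bases / reference bases
_READ_OPS = frozenset("MIS=X")
_REF_OPS = frozenset("MDN=X")
_ALIGNED_OPS = frozenset("M=X")


class Genome(str, enum.Enum):
    """Subgenome label of a fragment."""

    A = "A"
    B = "B"
    N = "N"
    UNMAPPED = "unmapped"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value

    def flipped(self) -> "Genome":
        """Label after swapping the two references (A<->B; N/unmapped fixed)."""
        if self is Genome.A:
            return Genome.B
        if self is Genome.B:
            return Genome.A
        return self


class Criterion(str, enum.Enum):
    """Which rule produced a category decision."""

    UNIQUE_MAPPING = "unique_mapping"
    MAPQ = "mapq"
    ALIGN_LENGTH = "align_length"
    MATCHES = "matches"
    TIE = "tie"
    NONE_MAPPED = "none_mapped"
    # Vote-based categorization only: fragment overlapped zero index positions,
    # so its N label means "no evidence" rather than "conflicting evidence".
    NO_EVIDENCE = "no_evidence"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class CategoryDecision:
    genome: Genome
    criterion: Criterion

    def __post_init__(self) -> None:
        if self.genome is Genome.UNMAPPED and self.criterion is not Criterion.NONE_MAPPED:
            raise ValueError("unmapped fragments must carry criterion NONE_MAPPED")
        if self.genome is Genome.N and self.criterion not in (
            Criterion.TIE,
            Criterion.NO_EVIDENCE,
        ):
            raise ValueError("N fragments must carry criterion TIE or NO_EVIDENCE")
        if self.genome in (Genome.A, Genome.B) and self.criterion in (
            Criterion.TIE,
            Criterion.NONE_MAPPED,
            Criterion.NO_EVIDENCE,
        ):
            raise ValueError(f"genome {self.genome} incompatible with {self.criterion}")


@dataclass
class AlignmentRecord:
    """One read's primary mapping to one reference (a thin SAM record mirror).

    ``pos`` is the 1-based leftmost reference coordinate; ``cigar`` is an
    ordered list of ``(op, length)`` with op a SAM CIGAR character.
    ``edit_distance`` follows NM semantics: mismatches plus inserted plus
    deleted bases.
    """

    read_name: str
    flag: int = FLAG_UNMAPPED
    chrom: Optional[str] = None
    pos: int = 0
    mapq: int = 0
    cigar: tuple = ()
    seq: str = ""
    qual: Optional[str] = None
    edit_distance: Optional[int] = None
    md: Optional[str] = None
    tags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.cigar = tuple(self.cigar)
        if self.is_mapped and self.cigar and self.seq:
            consumed = sum(n for op, n in self.cigar if op in _READ_OPS)
            if consumed != len(self.seq):
                raise ValueError(
                    f"{self.read_name}: CIGAR consumes {consumed} read bases "
                    f"but SEQ has {len(self.seq)}"
                )

    # -- flag helpers -------------------------------------------------
    @property
    def is_mapped(self) -> bool:
        return not self.flag & FLAG_UNMAPPED

    @property
    def is_paired(self) -> bool:
        return bool(self.flag & FLAG_PAIRED)

    @property
    def is_read1(self) -> bool:
        return not self.is_paired or bool(self.flag & FLAG_READ1)

    @property
    def is_read2(self) -> bool:
        return bool(self.flag & FLAG_READ2)

    @property
    def is_reverse(self) -> bool:
        return bool(self.flag & FLAG_REVERSE)

    @property
    def is_secondary(self) -> bool:
        return bool(self.flag & FLAG_SECONDARY)

    @property
    def is_supplementary(self) -> bool:
        return bool(self.flag & FLAG_SUPPLEMENTARY)

    # -- coordinate helpers -------------------------------------------
    @property
    def reference_end(self) -> int:
        """1-based inclusive rightmost reference coordinate covered."""
        if not self.is_mapped:
            raise ValueError(f"{self.read_name}: unmapped record has no span")
        span = sum(n for op, n in self.cigar if op in _REF_OPS)
        return self.pos + span - 1

    @property
    def aligned_bases(self) -> int:
        """Read bases under M/=/X ops (soft clips and insertions excluded)."""
        return sum(n for op, n in self.cigar if op in _ALIGNED_OPS)


@dataclass(frozen=True)
class AlignmentStats:
    """Comparison statistics for one mapped record or a whole fragment."""

    aligned_bases: int
    match_score: int  # aligned_bases - edit distance; may go negative with big deletions
    mapq: int

    def __add__(self, other: "AlignmentStats") -> "AlignmentStats":
        # Mate combination: evidence (aligned bases, matches) accumulates, but
        # MAPQ is a per-alignment confidence, so the fragment takes the max —
        # a mapper emitting uniform MAPQs then ties on MAPQ and mate-count
        # differences fall through to the alignment-length criterion.
        return AlignmentStats(
            self.aligned_bases + other.aligned_bases,
            self.match_score + other.match_score,
            max(self.mapq, other.mapq),
        )


EMPTY_STATS = AlignmentStats(0, 0, 0)


class FragmentView:
    """The (up to two) primary records of one fragment against ONE reference.

    Combined aligned bases and match score sum over the mapped mates that are
    present, so a doubly-mapped fragment outscores a singly-mapped one on
    alignment length; combined MAPQ is the per-mate maximum.
    """

    __slots__ = ("read_name", "mate1", "mate2", "_combined")

    def __init__(
        self,
        read_name: str,
        mate1: Optional[AlignmentRecord] = None,
        mate2: Optional[AlignmentRecord] = None,
    ):
        self.read_name = read_name
        self.mate1 = mate1
        self.mate2 = mate2
        self._combined: Optional[AlignmentStats] = None
        for rec in (mate1, mate2):
            if rec is not None and rec.read_name != read_name:
                raise ValueError(
                    f"record name {rec.read_name!r} does not match fragment {read_name!r}"
                )

    @property
    def mates(self):
        return tuple(m for m in (self.mate1, self.mate2) if m is not None)

    @property
    def mapped_mates(self):
        return tuple(m for m in self.mates if m.is_mapped)

    @property
    def any_mapped(self) -> bool:
        return any(m.is_mapped for m in self.mates)

    @property
    def combined(self) -> AlignmentStats:
        if self._combined is None:
            from .io_alignments import alignment_stats  # local import avoids cycle

            total = EMPTY_STATS
            for rec in self.mapped_mates:
                total = total + alignment_stats(rec)
            self._combined = total
        return self._combined

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (
            f"FragmentView({self.read_name!r}, mapped={len(self.mapped_mates)}"
            f"/{len(self.mates)})"
        )


@dataclass(frozen=True)
class FragmentDecision:
    """Per-fragment outcome with enough context for downstream accounting."""

    read_name: str
    genome: Genome
    criterion: Criterion
    mapped_a: bool = False
    mapped_b: bool = False

    @property
    def mapped_any(self) -> bool:
        return self.mapped_a or self.mapped_b
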