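"""Vote-majority categorization against a homoeo-SNP index.

Fragments are mapped to a single reference; at every indexed position a read
overlaps, the read base votes for the genome whose diagnostic allele it
matches. If at least a threshold fraction (default 75%, inclusive) of
informative votes favor one genome, the fragment is categorized to it;
otherwise it stays N. Bases matching neither allele are counted separately
and excluded from the denominator.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Optional, Tuple

from .model import (
    AlignmentRecord,
    CategoryDecision,
    Criterion,
    FragmentDecision,
    FragmentView,
    Genome,
)

_BASES = frozenset("ACGT")


class SNPIndexError(ValueError):
    """Malformed homoeo-SNP index input."""


@dataclass(frozen=True)
class HomoeoSNP:
    """A reference position carrying the two genome-diagnostic alleles."""

    chrom: str
    pos: int  # 1-based
    allele_a: str
    allele_b: str

    def __post_init__(self) -> None:
        if self.allele_a not in _BASES or self.allele_b not in _BASES:
            raise SNPIndexError(
                f"{self.chrom}:{self.pos}: alleles must be single A/C/G/T bases, "
                f"got {self.allele_a!r}/{self.allele_b!r}"
            )
        if self.allele_a == self.allele_b:
            raise SNPIndexError(
                f"{self.chrom}:{self.pos}: the two alleles must differ"
            )

    def swapped(self) -> "HomoeoSNP":
        return HomoeoSNP(self.chrom, self.pos, self.allele_b, self.allele_a)


class SNPIndex:
    """Queryable collection of homoeo-SNPs, at most one per (chrom, pos)."""

    def __init__(self, snps: Iterable[HomoeoSNP] = (), source_label: str = ""):
        self._by_chrom: Dict[str, Dict[int, HomoeoSNP]] = {}
        self._positions: Dict[str, List[int]] = {}
        self.source_label = source_label
        for snp in snps:
            self.add(snp)

    def add(self, snp: HomoeoSNP) -> None:
        chrom = self._by_chrom.setdefault(snp.chrom, {})
        if snp.pos in chrom:
            raise SNPIndexError(f"duplicate SNP at {snp.chrom}:{snp.pos}")
        chrom[snp.pos] = snp
        self._positions.pop(snp.chrom, None)  # invalidate sorted cache

    def _sorted_positions(self, chrom: str) -> List[int]:
        cached = self._positions.get(chrom)
        if cached is None:
            cached = sorted(self._by_chrom.get(chrom, ()))
            self._positions[chrom] = cached
        return cached

    def get(self, chrom: str, pos: int) -> Optional[HomoeoSNP]:
        return self._by_chrom.get(chrom, {}).get(pos)

    def overlapping(self, chrom: str, start: int, end: int) -> Iterator[HomoeoSNP]:
        """SNPs with start <= pos <= end (1-based, closed interval)."""
        positions = self._sorted_positions(chrom)
        lookup = self._by_chrom.get(chrom, {})
        lo = bisect.bisect_left(positions, start)
        hi = bisect.bisect_right(positions, end)
        for pos in positions[lo:hi]:
            yield lookup[pos]

    def __len__(self) -> int:
        return sum(len(v) for v in self._by_chrom.values())

    def __iter__(self) -> Iterator[HomoeoSNP]:
        for chrom in sorted(self._by_chrom):
            for pos in self._sorted_positions(chrom):
                yield self._by_chrom[chrom][pos]

    def __eq__(self, other) -> bool:
        if not isinstance(other, SNPIndex):
            return NotImplemented
        return list(self) == list(other)

    def swapped(self) -> "SNPIndex":
        """The same index with alleleA and alleleB exchanged everywhere."""
        return SNPIndex((snp.swapped() for snp in self), source_label=self.source_label)


# ---------------------------------------------------------------------------
# index I/O
# ---------------------------------------------------------------------------

def read_snp_index(path) -> SNPIndex:
    """Load a tab-separated index: chrom, pos (1-based), alleleA, alleleB.

    Lines starting with '#' are comments. Duplicate positions and malformed
    lines are reported with their line numbers.
    """
    index = SNPIndex(source_label=str(path))
    seen_lines: Dict[Tuple[str, int], int] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise SNPIndexError(
                    f"{path}:{lineno}: expected 4 tab-separated columns, got {len(fields)}"
                )
            chrom, pos_str, allele_a, allele_b = fields[:4]
            try:
                pos = int(pos_str)
            except ValueError as exc:
                raise SNPIndexError(f"{path}:{lineno}: bad position {pos_str!r}") from exc
            if pos < 1:
                raise SNPIndexError(f"{path}:{lineno}: position must be >= 1")
            key = (chrom, pos)
            if key in seen_lines:
                raise SNPIndexError(
                    f"{path}:{lineno}: duplicate of {chrom}:{pos} first seen on "
                    f"line {seen_lines[key]}"
                )
            seen_lines[key] = lineno
            try:
                index.add(HomoeoSNP(chrom, pos, allele_a.upper(), allele_b.upper()))
            except SNPIndexError as exc:
                raise SNPIndexError(f"{path}:{lineno}: {exc}") from exc
    return index


def write_snp_index(index: SNPIndex, path) -> int:
    with open(path, "w") as out:
        out.write("#chrom\tpos\talleleA\talleleB\n")
        n = 0
        for snp in index:
            out.write(f"{snp.chrom}\t{snp.pos}\t{snp.allele_a}\t{snp.allele_b}\n")
            n += 1
    return n


def read_snp_index_vcf(path) -> SNPIndex:
    """Build an index from a bi-allelic SNV VCF: REF -> alleleA, ALT -> alleleB."""
    import pysam

    index = SNPIndex(source_label=str(path))
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1:
                continue
            ref, alt = rec.ref.upper(), rec.alts[0].upper()
            if len(ref) != 1 or len(alt) != 1 or ref not in _BASES or alt not in _BASES:
                continue
            index.add(HomoeoSNP(rec.chrom, rec.pos, ref, alt))
    return index


# ---------------------------------------------------------------------------
# voting
# ---------------------------------------------------------------------------

def base_at(rec: AlignmentRecord, ref_pos: int) -> Optional[str]:
    """The read base aligned to reference position ``ref_pos`` (1-based).

    Returns None when the position falls in a deletion/skip or outside the
    aligned blocks of the record.
    """
    if not rec.is_mapped:
        return None
    ref = rec.pos  # 1-based coordinate of next reference base
    query = 0  # 0-based offset of next read base
    for op, n in rec.cigar:
        if op in "M=X":
            if ref <= ref_pos < ref + n:
                return rec.seq[query + (ref_pos - ref)].upper()
            ref += n
            query += n
        elif op in "DN":
            if ref <= ref_pos < ref + n:
                return None  # deleted / skipped on the read
            ref += n
        elif op in "IS":
            query += n
        # H and P consume nothing relevant
    return None


@dataclass
class VoteTally:
    """Per-fragment vote counts over the homoeo-SNP index."""

    votes_a: int = 0
    votes_b: int = 0
    uninformative_bases: int = 0

    @property
    def informative(self) -> int:
        return self.votes_a + self.votes_b


def tally_fragment(
    view: FragmentView,
    index: SNPIndex,
    min_base_quality: int = 0,
) -> VoteTally:
    """Pool both mates' bases at indexed positions into one tally.

    Each mate's base votes independently, so a SNP covered by both mates
    contributes two votes. ``min_base_quality`` (default off) drops votes from
    low-quality base calls.
    """
    tally = VoteTally()
    for rec in view.mapped_mates:
        for snp in index.overlapping(rec.chrom, rec.pos, rec.reference_end):
            base = base_at(rec, snp.pos)
            if base is None:
                tally.uninformative_bases += 1
                continue
            if min_base_quality > 0 and rec.qual is not None:
                # qual is a phred+33 string indexed like seq; re-locate the offset
                offset = _query_offset(rec, snp.pos)
                if offset is not None and ord(rec.qual[offset]) - 33 < min_base_quality:
                    tally.uninformative_bases += 1
                    continue
            if base == snp.allele_a:
                tally.votes_a += 1
            elif base == snp.allele_b:
                tally.votes_b += 1
            else:
                tally.uninformative_bases += 1
    return tally


def _query_offset(rec: AlignmentRecord, ref_pos: int) -> Optional[int]:
    ref = rec.pos
    query = 0
    for op, n in rec.cigar:
        if op in "M=X":
            if ref <= ref_pos < ref + n:
                return query + (ref_pos - ref)
            ref += n
            query += n
        elif op in "DN":
            if ref <= ref_pos < ref + n:
                return None
            ref += n
        elif op in "IS":
            query += n
    return None


DEFAULT_THRESHOLD = 0.75


def decide_category(tally: VoteTally, threshold: float = DEFAULT_THRESHOLD) -> CategoryDecision:
    """Apply the inclusive vote-majority rule.

    3 of 4 votes categorizes at the default 0.75 threshold. Zero informative
    votes gives N with criterion NO_EVIDENCE; a failed majority gives N with
    criterion TIE (conflicting evidence).
    """
    if not 0.5 < threshold <= 1.0:
        raise ValueError(f"threshold must be in (0.5, 1.0], got {threshold}")
    if tally.informative == 0:
        return CategoryDecision(Genome.N, Criterion.NO_EVIDENCE)
    best = max(tally.votes_a, tally.votes_b)
    if best / tally.informative >= threshold:
        genome = Genome.A if tally.votes_a >= tally.votes_b else Genome.B
        return CategoryDecision(genome, Criterion.MATCHES)
    return CategoryDecision(Genome.N, Criterion.TIE)


def categorize_fragments(
    fragments: Iterable[FragmentView],
    index: SNPIndex,
    threshold: float = DEFAULT_THRESHOLD,
    min_base_quality: int = 0,
) -> Iterator[Tuple[FragmentView, CategoryDecision]]:
    for view in fragments:
        if not view.any_mapped:
            yield view, CategoryDecision(Genome.UNMAPPED, Criterion.NONE_MAPPED)
            continue
        tally = tally_fragment(view, index, min_base_quality)
        yield view, decide_category(tally, threshold)


def vote_stream(
    fragments: Iterable[FragmentView],
    index: SNPIndex,
    threshold: float = DEFAULT_THRESHOLD,
    min_base_quality: int = 0,
) -> Tuple[List[FragmentDecision], Dict[str, int]]:
    """Categorize a whole single-reference run, with summary counts."""
    decisions: List[FragmentDecision] = []
    summary = {"fragments": 0, "mapped": 0, "A": 0, "B": 0, "N": 0}
    for view, decision in categorize_fragments(fragments, index, threshold, min_base_quality):
        summary["fragments"] += 1
        if decision.genome is not Genome.UNMAPPED:
            summary["mapped"] += 1
            summary[decision.genome.value] += 1
        decisions.append(
            FragmentDecision(
                read_name=view.read_name,
                genome=decision.genome,
                criterion=decision.criterion,
                mapped_a=view.any_mapped,
                mapped_b=False,
            )
        )
    return decisions, summary
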