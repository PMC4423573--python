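"""Independent brute-force oracles used to cross-check the library.

Everything here is deliberately naive and shares no code with the package:
direct base-by-base walks, full-scan alignment, and a literal restatement of
the serial decision rules over plain tuples.
"""

from __future__ import annotations

from typing import List, Optional, Tuple

_RC = {"A": "T", "C": "G", "G": "C", "T": "A"}


def rc(seq: str) -> str:
    return "".join(_RC[b] for b in reversed(seq))


def aligned_columns(pos: int, cigar) -> List[Tuple[Optional[int], Optional[int]]]:
    """Explicit (query_offset, ref_pos) column list for a CIGAR at 1-based pos.

    Deletions/skips give (None, ref_pos); insertions and soft clips give
    (query_offset, None).
    """
    columns = []
    q = 0
    r = pos
    for op, n in cigar:
        for _ in range(n):
            if op in "M=X":
                columns.append((q, r))
                q += 1
                r += 1
            elif op in "DN":
                columns.append((None, r))
                r += 1
            elif op in "IS":
                columns.append((q, None))
                q += 1
            elif op == "H":
                pass
            else:
                raise ValueError(op)
    return columns


def oracle_stats(read: str, reference: str, pos: int, cigar) -> Tuple[int, int]:
    """(aligned_bases, match_score) by direct base comparison.

    match_score = exact matches - inserted bases - deleted bases, which equals
    aligned_bases - NM.
    """
    aligned = 0
    matches = 0
    indels = 0
    for q, r in aligned_columns(pos, cigar):
        if q is not None and r is not None:
            aligned += 1
            if read[q].upper() == reference[r - 1].upper():
                matches += 1
        elif q is None or (q is not None and r is None):
            # deletion column, or insertion/soft-clip column
            pass
    for op, n in cigar:
        if op in "ID":
            indels += n
    return aligned, matches - indels


def oracle_base_at(read: str, pos: int, cigar, ref_pos: int) -> Optional[str]:
    for q, r in aligned_columns(pos, cigar):
        if r == ref_pos:
            return read[q].upper() if q is not None else None
    return None


def oracle_map(
    read: str, reference: str, max_mismatches: int
) -> Optional[Tuple[int, bool, int]]:
    """Full scan over every position and both strands; unique-best only.

    Returns (0-based position, is_reverse, mismatches) or None.
    """
    read = read.upper()
    reference = reference.upper()
    hits = []
    for strand, oriented in ((0, read), (1, rc(read))):
        for pos in range(len(reference) - len(read) + 1):
            mm = sum(
                1 for a, b in zip(oriented, reference[pos : pos + len(read)]) if a != b
            )
            if mm <= max_mismatches:
                hits.append((mm, pos, strand))
    hits.sort()
    if not hits or (len(hits) > 1 and hits[0][0] == hits[1][0]):
        return None
    mm, pos, strand = hits[0]
    return pos, bool(strand), mm


def oracle_serial_decision(
    side_a: Optional[Tuple[int, int, int]],
    side_b: Optional[Tuple[int, int, int]],
) -> Tuple[str, str]:
    """Serial rules over (mapq, aligned, score) tuples; None = side unmapped.

    Returns (genome, criterion) as plain strings.
    """
    if side_a is None and side_b is None:
        return "unmapped", "none_mapped"
    if side_b is None:
        return "A", "unique_mapping"
    if side_a is None:
        return "B", "unique_mapping"
    for i, criterion in enumerate(("mapq", "align_length", "matches")):
        if side_a[i] > side_b[i]:
            return "A", criterion
        if side_b[i] > side_a[i]:
            return "B", criterion
    return "N", "tie"


def oracle_vote(votes_a: int, votes_b: int, threshold: float) -> str:
    informative = votes_a + votes_b
    if informative == 0:
        return "N"
    if votes_a / informative >= threshold and votes_a > votes_b:
        return "A"
    if votes_b / informative >= threshold and votes_b > votes_a:
        return "B"
    return "N"


def oracle_error_rate(rows, truth_of) -> Tuple[int, int]:
    """(wrong, mapped) recount over (name, genome, mapped_any) rows."""
    wrong = mapped = 0
    for name, genome, mapped_any in rows:
        if not mapped_any:
            continue
        mapped += 1
        if genome in ("A", "B") and genome != truth_of(name):
            wrong += 1
    return wrong, mapped
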