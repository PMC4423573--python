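"""Homoeo-SNP index construction from categorized read sets.

The tetraploid-specific index is built by piling up reads previously
categorized to each genome on the shared reference, calling a consensus base
per position per set, and emitting the positions where the two consensuses
confidently disagree. Iterating categorize -> rebuild sharpens an initial
index toward the polyploid's own divergence.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Tuple

from .model import AlignmentRecord, FragmentView, Genome
from .snpcat import DEFAULT_THRESHOLD, HomoeoSNP, SNPIndex, categorize_fragments

#: defaults chosen to give zero false calls on clean simulations
DEFAULT_MIN_DEPTH = 4
DEFAULT_MIN_AGREEMENT = 0.8

_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class ConsensusCall:
    """Majority base at one covered reference position, or NOCALL (base None)."""

    chrom: str
    pos: int
    base: Optional[str]
    depth: int
    agreement: float


def _pileup_counts(records: Iterable[AlignmentRecord]) -> Dict[Tuple[str, int], Counter]:
    """Per-position base counts. Deleted/skipped positions add no depth."""
    counts: Dict[Tuple[str, int], Counter] = {}
    for rec in records:
        if not rec.is_mapped:
            continue
        ref = rec.pos
        query = 0
        for op, n in rec.cigar:
            if op in "M=X":
                for i in range(n):
                    base = rec.seq[query + i].upper()
                    if base in _BASES:
                        key = (rec.chrom, ref + i)
                        counter = counts.get(key)
                        if counter is None:
                            counter = counts[key] = Counter()
                        counter[base] += 1
                ref += n
                query += n
            elif op in "DN":
                ref += n
            elif op in "IS":
                query += n
    return counts


def pileup_consensus(
    records: Iterable[AlignmentRecord],
    min_depth: int = DEFAULT_MIN_DEPTH,
    min_agreement: float = DEFAULT_MIN_AGREEMENT,
) -> Dict[Tuple[str, int], ConsensusCall]:
    """Consensus call for every covered position of a single-reference pileup."""
    if min_depth < 1:
        raise ValueError("min_depth must be >= 1")
    if not 0.5 < min_agreement <= 1.0:
        raise ValueError("min_agreement must be in (0.5, 1.0]")
    calls: Dict[Tuple[str, int], ConsensusCall] = {}
    for (chrom, pos), counter in _pileup_counts(records).items():
        depth = sum(counter.values())
        base, best = counter.most_common(1)[0]
        agreement = best / depth
        if depth < min_depth or agreement < min_agreement:
            base = None
        calls[(chrom, pos)] = ConsensusCall(chrom, pos, base, depth, agreement)
    return calls


def call_homoeo_snps(
    cons_a: Dict[Tuple[str, int], ConsensusCall],
    cons_b: Dict[Tuple[str, int], ConsensusCall],
    source_label: str = "consensus-diff",
) -> SNPIndex:
    """Positions where both consensuses are confidently called and differ."""
    index = SNPIndex(source_label=source_label)
    for key in cons_a.keys() & cons_b.keys():
        call_a, call_b = cons_a[key], cons_b[key]
        if call_a.base is None or call_b.base is None:
            continue
        if call_a.base != call_b.base:
            index.add(HomoeoSNP(call_a.chrom, call_a.pos, call_a.base, call_b.base))
    return index


def build_index_from_categorized(
    records_a: Iterable[AlignmentRecord],
    records_b: Iterable[AlignmentRecord],
    min_depth: int = DEFAULT_MIN_DEPTH,
    min_agreement: float = DEFAULT_MIN_AGREEMENT,
) -> SNPIndex:
    """One-shot index build from two already-categorized record sets."""
    cons_a = pileup_consensus(records_a, min_depth, min_agreement)
    cons_b = pileup_consensus(records_b, min_depth, min_agreement)
    return call_homoeo_snps(cons_a, cons_b)


def iterate_index(
    initial_index: SNPIndex,
    fragments: List[FragmentView],
    rounds: int = 1,
    threshold: float = DEFAULT_THRESHOLD,
    min_depth: int = DEFAULT_MIN_DEPTH,
    min_agreement: float = DEFAULT_MIN_AGREEMENT,
) -> Tuple[SNPIndex, List[int]]:
    """Refine an index by repeated categorize/split/rebuild rounds.

    Returns the final index plus per-round index sizes for convergence
    reporting (no stopping rule is applied; an empty initial index stays
    empty, as nothing can be categorized in round one).
    """
    if rounds < 1:
        raise ValueError("rounds must be >= 1")
    index = initial_index
    sizes: List[int] = []
    for _ in range(rounds):
        recs_a: List[AlignmentRecord] = []
        recs_b: List[AlignmentRecord] = []
        for view, decision in categorize_fragments(fragments, index, threshold):
            if decision.genome is Genome.A:
                recs_a.extend(view.mapped_mates)
            elif decision.genome is Genome.B:
                recs_b.extend(view.mapped_mates)
        index = build_index_from_categorized(recs_a, recs_b, min_depth, min_agreement)
        sizes.append(len(index))
    return index, sizes
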