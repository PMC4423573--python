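"""Dual-reference serial-criteria categorization.

Each fragment is mapped independently to reference A and reference B; the two
resulting :class:`~homeosort.model.FragmentView` objects are compared through
four criteria applied strictly in order:

1. unique mapping — mapped to only one of the references;
2. mapping quality (combined MAPQ, higher wins);
3. alignment length (combined aligned bases, longer wins);
4. exact matches (combined aligned bases minus edit distance, higher wins;
   insertions and deletions each cost one point, like a mismatch).

A later criterion is consulted only if every earlier one ties. A fragment
tying on all four is reported as N; a fragment mapped to neither reference is
reported unmapped.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator, List, Tuple

from .model import (
    CategoryDecision,
    Criterion,
    FragmentDecision,
    FragmentView,
    Genome,
)

_SERIAL_STEPS = (
    ("mapq", Criterion.MAPQ),
    ("aligned_bases", Criterion.ALIGN_LENGTH),
    ("match_score", Criterion.MATCHES),
)


def categorize_fragment(view_a: FragmentView, view_b: FragmentView) -> CategoryDecision:
    """Decide one fragment's genome of origin from its two mappings."""
    if view_a.read_name != view_b.read_name:
        raise ValueError(
            f"fragment mismatch: {view_a.read_name!r} vs {view_b.read_name!r}"
        )
    mapped_a, mapped_b = view_a.any_mapped, view_b.any_mapped
    if not mapped_a and not mapped_b:
        return CategoryDecision(Genome.UNMAPPED, Criterion.NONE_MAPPED)
    if mapped_a != mapped_b:
        genome = Genome.A if mapped_a else Genome.B
        return CategoryDecision(genome, Criterion.UNIQUE_MAPPING)
    stats_a, stats_b = view_a.combined, view_b.combined
    for attr, criterion in _SERIAL_STEPS:
        va, vb = getattr(stats_a, attr), getattr(stats_b, attr)
        if va != vb:
            return CategoryDecision(Genome.A if va > vb else Genome.B, criterion)
    return CategoryDecision(Genome.N, Criterion.TIE)


@dataclass
class StepAttribution:
    """How many fragments each serial step decided.

    Fractions are relative to fragments mapped to at least one reference.
    """

    counts: Counter = field(default_factory=Counter)
    total_fragments: int = 0

    @property
    def mapped_fragments(self) -> int:
        return self.total_fragments - self.counts.get(Criterion.NONE_MAPPED, 0)

    def record(self, decision: CategoryDecision) -> None:
        self.total_fragments += 1
        self.counts[decision.criterion] += 1

    def fractions(self) -> dict:
        mapped = self.mapped_fragments
        if mapped == 0:
            return {}
        return {
            crit.value: self.counts[crit] / mapped
            for crit in (
                Criterion.UNIQUE_MAPPING,
                Criterion.MAPQ,
                Criterion.ALIGN_LENGTH,
                Criterion.MATCHES,
                Criterion.TIE,
            )
            if self.counts.get(crit)
        }

    def to_dict(self) -> dict:
        return {
            "total_fragments": self.total_fragments,
            "mapped_fragments": self.mapped_fragments,
            "counts": {crit.value: n for crit, n in sorted(self.counts.items())},
            "fractions_of_mapped": self.fractions(),
        }


def categorize_pairs(
    pairs: Iterable[Tuple[FragmentView, FragmentView]],
) -> Iterator[Tuple[FragmentView, FragmentView, CategoryDecision]]:
    """Lazily attach a decision to each collated fragment pair."""
    for view_a, view_b in pairs:
        yield view_a, view_b, categorize_fragment(view_a, view_b)


def categorize_stream(
    pairs: Iterable[Tuple[FragmentView, FragmentView]],
) -> Tuple[List[FragmentDecision], StepAttribution]:
    """Categorize every collated fragment pair, keeping input order."""
    decisions: List[FragmentDecision] = []
    attribution = StepAttribution()
    for view_a, view_b in pairs:
        decision = categorize_fragment(view_a, view_b)
        attribution.record(decision)
        decisions.append(
            FragmentDecision(
                read_name=view_a.read_name,
                genome=decision.genome,
                criterion=decision.criterion,
                mapped_a=view_a.any_mapped,
                mapped_b=view_b.any_mapped,
            )
        )
    return decisions, attribution
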