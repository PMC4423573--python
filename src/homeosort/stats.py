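"""Error-rate estimation and cross-method comparison reports.

With reads of known origin (a diploid read set, or simulated reads with a
truth table), the fraction of mapped fragments assigned to the wrong genome
approximates a method's error rate. N and unmapped fragments are never
counted as wrong, but stay in the mapped denominator, so conservative
methods show low error *and* a visible N rate.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Union

import pandas as pd

from .model import FragmentDecision, Genome


class DenominatorPolicy(str, enum.Enum):
    """What counts as a 'mapped' fragment in the error-rate denominator."""

    MAPPED_EITHER = "mapped-either"
    MAPPED_ON_REF_A = "mapped-on-ref-A"
    MAPPED_ON_REF_B = "mapped-on-ref-B"


@dataclass(frozen=True)
class ErrorReport:
    method: str
    policy: DenominatorPolicy
    mapped_count: int
    wrong_count: int
    n_count: int

    @property
    def error_rate(self) -> float:
        return self.wrong_count / self.mapped_count if self.mapped_count else 0.0

    @property
    def n_rate(self) -> float:
        return self.n_count / self.mapped_count if self.mapped_count else 0.0

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "policy": self.policy.value,
            "mapped": self.mapped_count,
            "wrong": self.wrong_count,
            "n": self.n_count,
            "error_rate": self.error_rate,
            "n_rate": self.n_rate,
        }


TruthLike = Union[Genome, Mapping[str, Genome], "object"]


def _truth_lookup(truth: TruthLike):
    if isinstance(truth, Genome):
        return lambda name: truth
    if hasattr(truth, "genome_of"):
        return truth.genome_of
    if isinstance(truth, Mapping):
        return truth.__getitem__
    raise TypeError(f"unsupported truth source: {type(truth)!r}")


def _in_denominator(decision: FragmentDecision, policy: DenominatorPolicy) -> bool:
    if policy is DenominatorPolicy.MAPPED_EITHER:
        return decision.mapped_any
    if policy is DenominatorPolicy.MAPPED_ON_REF_A:
        return decision.mapped_a
    return decision.mapped_b


def error_rate(
    decisions: Iterable[FragmentDecision],
    truth: TruthLike,
    policy: DenominatorPolicy = DenominatorPolicy.MAPPED_EITHER,
    method: str = "",
) -> ErrorReport:
    """Wrong-genome fraction of mapped fragments.

    ``truth`` may be a single :class:`Genome` (every fragment shares one
    origin, the diploid setting), a mapping, or a truth table. Under the
    per-reference policies only fragments mapped on the named reference are
    counted, numerator and denominator alike — the cross-reference variant
    that exposes reference-quality asymmetry.
    """
    lookup = _truth_lookup(truth)
    mapped = wrong = n_count = 0
    for decision in decisions:
        if not _in_denominator(decision, policy):
            continue
        mapped += 1
        if decision.genome is Genome.N:
            n_count += 1
        elif decision.genome in (Genome.A, Genome.B):
            expected = lookup(decision.read_name)
            if expected is None:
                raise ValueError(f"no truth label for decided fragment {decision.read_name!r}")
            if decision.genome is not expected:
                wrong += 1
    return ErrorReport(
        method=method,
        policy=policy,
        mapped_count=mapped,
        wrong_count=wrong,
        n_count=n_count,
    )


# ---------------------------------------------------------------------------
# method comparison
# ---------------------------------------------------------------------------

def summarize_decisions(decisions: Iterable[FragmentDecision]) -> Dict[str, int]:
    counts = {"fragments": 0, "mapped": 0, "A": 0, "B": 0, "N": 0}
    for decision in decisions:
        counts["fragments"] += 1
        if decision.genome is not Genome.UNMAPPED:
            counts["mapped"] += 1
            counts[decision.genome.value] += 1
    return counts


def compare_methods(
    runs: Mapping[str, List[FragmentDecision]],
    truth: Optional[TruthLike] = None,
    require_same_reads: bool = True,
) -> pd.DataFrame:
    """Per-method mapped / A / B / N table, with error rates when truth is given."""
    if not runs:
        raise ValueError("need at least one method run")
    if require_same_reads and len(runs) > 1:
        universes = {
            name: frozenset(d.read_name for d in decisions)
            for name, decisions in runs.items()
        }
        first_name, first = next(iter(universes.items()))
        for name, universe in universes.items():
            if universe != first:
                raise ValueError(
                    f"method runs cover different read sets: {first_name!r} vs {name!r}"
                )
    rows = []
    for name, decisions in runs.items():
        row: dict = {"method": name}
        row.update(summarize_decisions(decisions))
        row["categorized"] = row["A"] + row["B"]
        if truth is not None:
            report = error_rate(decisions, truth, method=name)
            row["wrong"] = report.wrong_count
            row["error_rate"] = report.error_rate
            row["n_rate"] = report.n_rate
        rows.append(row)
    return pd.DataFrame(rows).set_index("method")


def write_comparison(table: pd.DataFrame, tsv_path=None, json_path=None) -> None:
    if tsv_path is not None:
        table.to_csv(tsv_path, sep="\t")
    if json_path is not None:
        with open(json_path, "w") as out:
            json.dump(
                {method: row.to_dict() for method, row in table.iterrows()},
                out,
                indent=2,
                sort_keys=True,
            )
            out.write("\n")


# ---------------------------------------------------------------------------
# decision TSV plumbing (CLI surface)
# ---------------------------------------------------------------------------

def write_decisions(decisions: Iterable[FragmentDecision], path) -> int:
    n = 0
    with open(path, "w") as out:
        out.write("#read\tgenome\tcriterion\tmapped_a\tmapped_b\n")
        for d in decisions:
            out.write(
                f"{d.read_name}\t{d.genome.value}\t{d.criterion.value}\t"
                f"{int(d.mapped_a)}\t{int(d.mapped_b)}\n"
            )
            n += 1
    return n


def read_decisions(path) -> List[FragmentDecision]:
    from .model import Criterion

    decisions = []
    with open(path) as handle:
        for line in handle:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            name, genome, criterion, mapped_a, mapped_b = line.split("\t")
            decisions.append(
                FragmentDecision(
                    read_name=name,
                    genome=Genome(genome),
                    criterion=Criterion(criterion),
                    mapped_a=bool(int(mapped_a)),
                    mapped_b=bool(int(mapped_b)),
                )
            )
    return decisions
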