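"""SAM input/output, per-alignment match statistics, and fragment collation.

All alignment traffic goes through :class:`~homeosort.model.AlignmentRecord`;
pysam handles the container formats (SAM and BAM are both accepted on input,
output defaults to SAM so results stay inspectable with standard tools).
"""

from __future__ import annotations

import os
import re
import warnings
from typing import Dict, Iterable, Iterator, Optional, Tuple

import pysam

from .model import (
    AlignmentRecord,
    AlignmentStats,
    CategoryDecision,
    FragmentView,
    Genome,
    _ALIGNED_OPS,
)

_CIGAR_OPS = "MIDNSHP=X"

#: default cap on fragments held in memory during collation
DEFAULT_MAX_FRAGMENTS = 5_000_000

_MD_TOKEN = re.compile(r"(\d+)|(\^[A-Za-z]+)|([A-Za-z])")


class CannotScoreError(ValueError):
    """Raised when an alignment's edit distance cannot be determined."""


class CollationError(ValueError):
    """Raised on inconsistent primary records during fragment collation."""


# ---------------------------------------------------------------------------
# pysam conversion
# ---------------------------------------------------------------------------

def record_from_pysam(seg: pysam.AlignedSegment) -> AlignmentRecord:
    tags = dict(seg.get_tags())
    cigar = ()
    if seg.cigartuples:
        cigar = tuple((_CIGAR_OPS[op], length) for op, length in seg.cigartuples)
    return AlignmentRecord(
        read_name=seg.query_name,
        flag=seg.flag,
        chrom=seg.reference_name if not seg.is_unmapped else None,
        pos=seg.reference_start + 1 if not seg.is_unmapped else 0,
        mapq=seg.mapping_quality,
        cigar=cigar,
        seq=seg.query_sequence or "",
        qual=seg.qual,
        edit_distance=tags.get("NM"),
        md=tags.get("MD"),
        tags=tags,
    )


def record_to_pysam(rec: AlignmentRecord, header: pysam.AlignmentHeader) -> pysam.AlignedSegment:
    seg = pysam.AlignedSegment(header)
    seg.query_name = rec.read_name
    seg.flag = rec.flag
    if rec.is_mapped:
        seg.reference_id = header.get_tid(rec.chrom)
        seg.reference_start = rec.pos - 1
        seg.cigarstring = "".join(f"{n}{op}" for op, n in rec.cigar)
    else:
        seg.reference_id = -1
        seg.reference_start = -1
    seg.mapping_quality = rec.mapq
    seg.query_sequence = rec.seq or None
    seg.qual = rec.qual
    seg.next_reference_id = -1
    seg.next_reference_start = -1
    seg.set_tags(sorted(rec.tags.items()))
    return seg


def read_sam(path, keep_unmapped: bool = True) -> Tuple[pysam.AlignmentHeader, Iterator[AlignmentRecord]]:
    """Open a SAM/BAM file, skipping secondary and supplementary records."""
    handle = pysam.AlignmentFile(str(path), check_sq=False)

    def _iter():
        with handle:
            for seg in handle:
                if seg.is_secondary or seg.is_supplementary:
                    continue
                if seg.is_unmapped and not keep_unmapped:
                    continue
                yield record_from_pysam(seg)

    return handle.header, _iter()


def write_sam(path, header, records: Iterable[AlignmentRecord]) -> int:
    """Write records as SAM text (``.bam`` suffix switches to BAM). Returns count."""
    mode = "wb" if str(path).endswith(".bam") else "wh"
    n = 0
    if not isinstance(header, pysam.AlignmentHeader):
        header = pysam.AlignmentHeader.from_dict(header)
    with pysam.AlignmentFile(str(path), mode, header=header) as out:
        for rec in records:
            out.write(record_to_pysam(rec, header))
            n += 1
    return n


def make_header(references: Dict[str, int], program: Optional[str] = "homeosort") -> pysam.AlignmentHeader:
    head = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": name, "LN": length} for name, length in references.items()],
    }
    if program:
        head["PG"] = [{"ID": program, "PN": program}]
    return pysam.AlignmentHeader.from_dict(head)


# ---------------------------------------------------------------------------
# match statistics
# ---------------------------------------------------------------------------

def _mismatches_from_md(md: str) -> int:
    """Count substitution mismatches encoded in an MD tag (deletions excluded)."""
    mism = 0
    pos = 0
    for m in _MD_TOKEN.finditer(md):
        if m.end() != m.start() and m.start() != pos:
            raise ValueError(f"malformed MD tag: {md!r}")
        pos = m.end()
        if m.group(3):
            mism += 1
    if pos != len(md):
        raise ValueError(f"malformed MD tag: {md!r}")
    return mism


def _indel_bases(rec: AlignmentRecord) -> int:
    return sum(n for op, n in rec.cigar if op in "ID")


def _edit_distance_from_reference(rec: AlignmentRecord, reference: str) -> int:
    """Recompute NM by walking the CIGAR against the reference sequence."""
    nm = 0
    rpos = rec.pos - 1  # 0-based
    qpos = 0
    for op, n in rec.cigar:
        if op in "M=X":
            ref_slice = reference[rpos : rpos + n]
            read_slice = rec.seq[qpos : qpos + n]
            nm += sum(1 for a, b in zip(ref_slice.upper(), read_slice.upper()) if a != b)
            rpos += n
            qpos += n
        elif op == "I":
            nm += n
            qpos += n
        elif op == "D":
            nm += n
            rpos += n
        elif op == "N":
            rpos += n
        elif op in "SH":
            if op == "S":
                qpos += n
        else:  # pragma: no cover - P ops unused
            raise ValueError(f"unsupported CIGAR op {op!r}")
    return nm


def resolve_edit_distance(rec: AlignmentRecord, reference: Optional[str] = None) -> int:
    """NM tag if present, else MD-based recomputation, else reference walk.

    A disagreement between NM and MD is reported as a warning; NM wins.
    """
    nm_md = None
    if rec.md is not None:
        try:
            nm_md = _mismatches_from_md(rec.md) + _indel_bases(rec)
        except ValueError:
            nm_md = None
    if rec.edit_distance is not None:
        if nm_md is not None and nm_md != rec.edit_distance:
            warnings.warn(
                f"{rec.read_name}: NM={rec.edit_distance} disagrees with MD-derived "
                f"{nm_md}; using NM",
                stacklevel=2,
            )
        return rec.edit_distance
    if nm_md is not None:
        return nm_md
    if reference is not None:
        return _edit_distance_from_reference(rec, reference)
    raise CannotScoreError(
        f"cannot score read {rec.read_name!r}: no NM tag, no MD tag, "
        "and no reference sequence supplied"
    )


def alignment_stats(rec: AlignmentRecord, reference: Optional[str] = None) -> AlignmentStats:
    """Aligned length and exact-match score of one mapped record.

    ``match_score = aligned_bases - edit_distance``: every substitution and
    every inserted or deleted base costs one point, so indels are penalized
    like mismatches. Soft-clipped bases contribute nothing.
    """
    if not rec.is_mapped:
        raise ValueError(f"{rec.read_name}: cannot score an unmapped record")
    aligned = sum(n for op, n in rec.cigar if op in _ALIGNED_OPS)
    nm = resolve_edit_distance(rec, reference)
    return AlignmentStats(aligned_bases=aligned, match_score=aligned - nm, mapq=rec.mapq)


# ---------------------------------------------------------------------------
# fragment collation
# ---------------------------------------------------------------------------

def _mate_slot(rec: AlignmentRecord) -> int:
    if rec.is_paired and rec.is_read2:
        return 1
    return 0


def group_fragments(
    records: Iterable[AlignmentRecord],
    max_fragments: int = DEFAULT_MAX_FRAGMENTS,
) -> "Dict[str, FragmentView]":
    """Group one stream's primary records into fragments keyed by read name.

    Insertion order of the returned dict is first-appearance order.
    """
    slots: Dict[str, list] = {}
    for rec in records:
        if rec.is_secondary or rec.is_supplementary:
            continue
        pair = slots.get(rec.read_name)
        if pair is None:
            if len(slots) >= max_fragments:
                raise CollationError(
                    f"more than {max_fragments} fragments in memory; "
                    "name-sort the inputs and raise the cap"
                )
            pair = [None, None]
            slots[rec.read_name] = pair
        slot = _mate_slot(rec)
        if pair[slot] is not None:
            raise CollationError(
                f"duplicate primary record for read {rec.read_name!r} "
                f"mate {slot + 1}; expected unique best mappings"
            )
        pair[slot] = rec
    return {
        name: FragmentView(name, mate1=pair[0], mate2=pair[1])
        for name, pair in slots.items()
    }


def collate_fragments(
    stream_x: Iterable[AlignmentRecord],
    stream_y: Iterable[AlignmentRecord],
    max_fragments: int = DEFAULT_MAX_FRAGMENTS,
) -> Iterator[Tuple[FragmentView, FragmentView]]:
    """Pair up the two mappings of each fragment by read name.

    Yields one ``(view_x, view_y)`` pair per read name seen in either stream,
    in first-appearance order (stream X first). A name absent from one stream
    yields an empty view on that side (mappers may omit unmapped records).
    """
    frags_x = group_fragments(stream_x, max_fragments)
    frags_y = group_fragments(stream_y, max_fragments)
    for name, view_x in frags_x.items():
        yield view_x, frags_y.pop(name, None) or FragmentView(name)
    for name, view_y in frags_y.items():
        yield FragmentView(name), view_y


# ---------------------------------------------------------------------------
# categorized output
# ---------------------------------------------------------------------------

def categorized_paths(out_prefix, fmt: str = "sam") -> Dict[str, str]:
    """The four per-genome sinks plus N sinks and the unmapped sink."""
    p = str(out_prefix)
    paths = {}
    for genome in ("A", "B", "N"):
        for ref in ("A", "B"):
            paths[f"{genome}.on{ref}"] = f"{p}.{genome}.on{ref}.{fmt}"
    paths["unmapped"] = f"{p}.unmapped.{fmt}"
    return paths


def write_categorized(
    pairs_with_decisions: Iterable[Tuple[FragmentView, FragmentView, CategoryDecision]],
    header_a,
    header_b,
    out_prefix,
    fmt: str = "sam",
) -> Dict[str, int]:
    """Split fragments into the four-way output contract.

    Produces A-reads-on-refA, A-reads-on-refB, B-reads-on-refA, B-reads-on-refB,
    N-reads on each reference, and an unmapped sink; every mapped input record
    lands in exactly one sink.
    """
    paths = categorized_paths(out_prefix, fmt)
    if not isinstance(header_a, pysam.AlignmentHeader):
        header_a = pysam.AlignmentHeader.from_dict(header_a)
    if not isinstance(header_b, pysam.AlignmentHeader):
        header_b = pysam.AlignmentHeader.from_dict(header_b)
    mode = "wb" if fmt == "bam" else "wh"
    sinks = {}
    counts = {key: 0 for key in paths}
    try:
        for key, path in paths.items():
            header = header_b if key.endswith("onB") else header_a
            sinks[key] = pysam.AlignmentFile(path, mode, header=header)
        for view_a, view_b, decision in pairs_with_decisions:
            genome = decision.genome
            if genome is Genome.UNMAPPED:
                for rec in view_a.mates + view_b.mates:
                    sinks["unmapped"].write(record_to_pysam(rec, header_a))
                    counts["unmapped"] += 1
                continue
            label = genome.value  # A, B or N
            for rec in view_a.mapped_mates:
                sinks[f"{label}.onA"].write(record_to_pysam(rec, header_a))
                counts[f"{label}.onA"] += 1
            for rec in view_b.mapped_mates:
                sinks[f"{label}.onB"].write(record_to_pysam(rec, header_b))
                counts[f"{label}.onB"] += 1
    finally:
        for sink in sinks.values():
            sink.close()
    return counts
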