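"""Synthetic allopolyploid data: diverged genome pair, labeled reads, naive mapper.

A random ancestor sequence is evolved into two genomes by independent
substitutions and small indels; disjoint ancestor segments are replaced by
novel sequence in one genome or the other, producing genome-unique regions on
both sides. Paired-end reads are drawn length-proportionally from the two
genomes with per-read truth labels, and a deliberately simple exhaustive
seed-and-verify mapper (gapless, unique-best-only) closes the loop so the
whole pipeline runs without external aligners.

Everything is a pure function of the configuration seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .model import (
    FLAG_MATE_UNMAPPED,
    FLAG_PAIRED,
    FLAG_READ1,
    FLAG_READ2,
    FLAG_REVERSE,
    FLAG_UNMAPPED,
    AlignmentRecord,
    Genome,
)

_CODE_TO_BASE = np.frombuffer(b"ACGT", dtype=np.uint8)
_RC_TABLE = str.maketrans("ACGTacgt", "TGCAtgca")

DEFAULT_CHROM = "chr1"

#: fixed MAPQ for mapped records (unique-best-only, so no confidence gradation)
NAIVE_MAPQ = 40


def revcomp(seq: str) -> str:
    return seq.translate(_RC_TABLE)[::-1]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimConfig:
    """Toy-scale profile: 200 kb ancestor, 2% substitutions per lineage,
    0.1% indels, 5% unique segments per genome, 100 bp paired reads."""

    ancestor_length: int = 200_000
    substitution_rate: float = 0.02
    indel_rate: float = 0.001
    indel_max_len: int = 10
    unique_segment_fraction: float = 0.05
    unique_segment_length: int = 2_000
    n_fragments: int = 20_000
    read_length: int = 100
    insert_mean: int = 300
    insert_sd: int = 30
    seq_error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("substitution_rate", "indel_rate", "unique_segment_fraction",
                     "seq_error_rate"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        expected_per_base = self.substitution_rate + self.indel_rate * (
            1 + self.indel_max_len
        ) / 2
        if expected_per_base > 1.0:
            raise ValueError(
                f"rates imply {expected_per_base:.2f} expected mutations per base (> 1)"
            )
        if self.read_length > self.insert_mean:
            raise ValueError("read_length must not exceed insert_mean")
        if self.ancestor_length < 2 * self.unique_segment_length:
            raise ValueError("ancestor too short for the unique-segment length")


@dataclass(frozen=True)
class TrueDiff:
    """One substitution difference between the genomes, in both coordinate systems."""

    pos_a: int  # 1-based on genome A
    pos_b: int  # 1-based on genome B
    base_a: str
    base_b: str


@dataclass
class EvolvedGenomes:
    chrom: str
    seq_a: str
    seq_b: str
    diffs: List[TrueDiff]
    unique_regions_a: List[Tuple[int, int]]  # 1-based closed intervals on A
    unique_regions_b: List[Tuple[int, int]]

    def write_fastas(self, path_a, path_b) -> None:
        write_fasta(path_a, {self.chrom: self.seq_a})
        write_fasta(path_b, {self.chrom: self.seq_b})

    def write_diff_index(self, path, reference: str = "A") -> int:
        """True-difference table usable directly as a homoeo-SNP index."""
        with open(path, "w") as out:
            out.write("#chrom\tpos\talleleA\talleleB\n")
            for diff in self.diffs:
                pos = diff.pos_a if reference == "A" else diff.pos_b
                out.write(f"{self.chrom}\t{pos}\t{diff.base_a}\t{diff.base_b}\n")
        return len(self.diffs)


# ---------------------------------------------------------------------------
# genome evolution
# ---------------------------------------------------------------------------

def _apply_substitutions(codes: np.ndarray, rate: float, rng) -> np.ndarray:
    out = codes.copy()
    if rate > 0:
        hit = np.nonzero(rng.random(codes.size) < rate)[0]
        out[hit] = (out[hit] + rng.integers(1, 4, hit.size)) % 4
    return out


def _draw_indels(length: int, cfg: SimConfig, rng) -> Tuple[Dict[int, np.ndarray], Dict[int, int]]:
    insertions: Dict[int, np.ndarray] = {}
    deletions: Dict[int, int] = {}
    if cfg.indel_rate <= 0:
        return insertions, deletions
    for pos in np.nonzero(rng.random(length) < cfg.indel_rate)[0]:
        size = int(rng.integers(1, cfg.indel_max_len + 1))
        if rng.random() < 0.5:
            insertions[int(pos)] = rng.integers(0, 4, size)
        else:
            deletions[int(pos)] = size
    return insertions, deletions


def _apply_indels(
    codes: np.ndarray,
    insertions: Dict[int, np.ndarray],
    deletions: Dict[int, int],
) -> Tuple[np.ndarray, np.ndarray]:
    """Derived sequence plus the ancestor->derived coordinate map (-1 = deleted)."""
    out: List[int] = []
    posmap = np.full(codes.size, -1, dtype=np.int64)
    i = 0
    while i < codes.size:
        dele = deletions.get(i)
        if dele is not None:
            i += dele
            continue
        posmap[i] = len(out)
        out.append(int(codes[i]))
        ins = insertions.get(i)
        if ins is not None:
            out.extend(int(b) for b in ins)
        i += 1
    return np.asarray(out, dtype=codes.dtype), posmap


def _choose_unique_segments(cfg: SimConfig, rng) -> Tuple[np.ndarray, np.ndarray]:
    """Disjoint ancestor segments to replace: boolean masks for A and for B."""
    length, seg = cfg.ancestor_length, cfg.unique_segment_length
    mask_a = np.zeros(length, dtype=bool)
    mask_b = np.zeros(length, dtype=bool)
    n_per_genome = int(round(cfg.unique_segment_fraction * length / seg))
    if n_per_genome == 0:
        return mask_a, mask_b
    n_slots = length // seg
    if 2 * n_per_genome > n_slots:
        raise ValueError("unique_segment_fraction too large for the ancestor length")
    slots = rng.choice(n_slots, size=2 * n_per_genome, replace=False)
    for slot in slots[:n_per_genome]:
        mask_a[slot * seg : (slot + 1) * seg] = True
    for slot in slots[n_per_genome:]:
        mask_b[slot * seg : (slot + 1) * seg] = True
    return mask_a, mask_b


def _mask_to_regions(mask_anc: np.ndarray, posmap: np.ndarray) -> List[Tuple[int, int]]:
    regions: List[Tuple[int, int]] = []
    padded = np.diff(np.concatenate(([0], mask_anc.view(np.int8), [0])))
    starts = np.nonzero(padded == 1)[0]
    ends = np.nonzero(padded == -1)[0]  # exclusive
    for s, e in zip(starts, ends):
        derived = posmap[s:e]
        derived = derived[derived >= 0]
        if derived.size:
            regions.append((int(derived.min()) + 1, int(derived.max()) + 1))
    return sorted(regions)


def evolve_genomes(cfg: SimConfig) -> EvolvedGenomes:
    """Evolve the two genomes and record every true substitution difference.

    The difference table covers homoeologous regions only: positions replaced
    by genome-unique sequence or lost to a deletion in either lineage are
    excluded.
    """
    root = np.random.SeedSequence(cfg.seed)
    rng_anc, rng_a, rng_b = (np.random.default_rng(s) for s in root.spawn(3))
    ancestor = rng_anc.integers(0, 4, cfg.ancestor_length).astype(np.int8)

    mask_a, mask_b = _choose_unique_segments(cfg, rng_anc)

    sub_a = _apply_substitutions(ancestor, cfg.substitution_rate, rng_a)
    sub_b = _apply_substitutions(ancestor, cfg.substitution_rate, rng_b)
    sub_a[mask_a] = rng_a.integers(0, 4, int(mask_a.sum()))
    sub_b[mask_b] = rng_b.integers(0, 4, int(mask_b.sum()))

    ins_a, del_a = _draw_indels(cfg.ancestor_length, cfg, rng_a)
    ins_b, del_b = _draw_indels(cfg.ancestor_length, cfg, rng_b)
    codes_a, posmap_a = _apply_indels(sub_a, ins_a, del_a)
    codes_b, posmap_b = _apply_indels(sub_b, ins_b, del_b)

    shared = (~mask_a) & (~mask_b) & (posmap_a >= 0) & (posmap_b >= 0)
    diff_positions = np.nonzero(shared & (sub_a != sub_b))[0]
    diffs = [
        TrueDiff(
            pos_a=int(posmap_a[p]) + 1,
            pos_b=int(posmap_b[p]) + 1,
            base_a=chr(_CODE_TO_BASE[sub_a[p]]),
            base_b=chr(_CODE_TO_BASE[sub_b[p]]),
        )
        for p in diff_positions
    ]

    # every replaced segment leaves unique sequence in BOTH genomes: the novel
    # bases in the replaced genome, the orphaned ancestral bases in the other
    either = mask_a | mask_b
    return EvolvedGenomes(
        chrom=DEFAULT_CHROM,
        seq_a=codes_to_str(codes_a),
        seq_b=codes_to_str(codes_b),
        diffs=diffs,
        unique_regions_a=_mask_to_regions(either, posmap_a),
        unique_regions_b=_mask_to_regions(either, posmap_b),
    )


def codes_to_str(codes: np.ndarray) -> str:
    return _CODE_TO_BASE[codes.astype(np.int8)].tobytes().decode("ascii")


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TruthEntry:
    genome: Genome
    chrom: str
    start: int  # 1-based fragment interval in the source genome
    end: int


class TruthTable:
    """Read name -> true genome of origin (plus the source fragment interval)."""

    def __init__(self):
        self._entries: Dict[str, TruthEntry] = {}

    def add(self, name: str, entry: TruthEntry) -> None:
        if name in self._entries:
            raise ValueError(f"duplicate truth entry for {name!r}")
        self._entries[name] = entry

    def genome_of(self, name: str) -> Genome:
        return self._entries[name].genome

    def __getitem__(self, name: str) -> TruthEntry:
        return self._entries[name]

    def __contains__(self, name: str) -> bool:
        return name in self._entries

    def __len__(self) -> int:
        return len(self._entries)

    def items(self):
        return self._entries.items()

    def write(self, path) -> None:
        with open(path, "w") as out:
            out.write("#read\tgenome\tchrom\tstart\tend\n")
            for name, e in self._entries.items():
                out.write(f"{name}\t{e.genome.value}\t{e.chrom}\t{e.start}\t{e.end}\n")

    @classmethod
    def read(cls, path) -> "TruthTable":
        table = cls()
        with open(path) as handle:
            for line in handle:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                name, genome, chrom, start, end = line.split("\t")
                table.add(name, TruthEntry(Genome(genome), chrom, int(start), int(end)))
        return table


@dataclass(frozen=True)
class SimRead:
    name: str
    seq: str
    is_read1: bool


def simulate_reads(
    genomes: EvolvedGenomes,
    cfg: SimConfig,
    source_genome: Optional[Genome] = None,
) -> Tuple[List[SimRead], List[SimRead], TruthTable]:
    """Draw paired-end fragments and their truth labels.

    Fragments come from the two genomes proportionally to length unless
    ``source_genome`` pins them to one genome (the diploid error-analysis
    setting). Read names carry no truth information.
    """
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(4)[3])
    seqs = {Genome.A: genomes.seq_a, Genome.B: genomes.seq_b}
    len_a, len_b = len(genomes.seq_a), len(genomes.seq_b)
    reads1: List[SimRead] = []
    reads2: List[SimRead] = []
    truth = TruthTable()
    rl = cfg.read_length
    for i in range(cfg.n_fragments):
        if source_genome is not None:
            genome = source_genome
        else:
            genome = Genome.A if rng.random() < len_a / (len_a + len_b) else Genome.B
        seq = seqs[genome]
        insert = int(round(rng.normal(cfg.insert_mean, cfg.insert_sd)))
        insert = max(rl, min(insert, len(seq)))
        if insert > len(seq):
            raise ValueError("fragment longer than source genome")
        start = int(rng.integers(0, len(seq) - insert + 1))
        fragment = seq[start : start + insert]
        if rng.random() < 0.5:
            fragment = revcomp(fragment)
        r1, r2 = fragment[:rl], revcomp(fragment[-rl:])
        if cfg.seq_error_rate > 0:
            r1 = _add_errors(r1, cfg.seq_error_rate, rng)
            r2 = _add_errors(r2, cfg.seq_error_rate, rng)
        name = f"frag{i:07d}"
        reads1.append(SimRead(name, r1, True))
        reads2.append(SimRead(name, r2, False))
        truth.add(name, TruthEntry(genome, genomes.chrom, start + 1, start + insert))
    return reads1, reads2, truth


def _add_errors(seq: str, rate: float, rng) -> str:
    hits = np.nonzero(rng.random(len(seq)) < rate)[0]
    if hits.size == 0:
        return seq
    chars = list(seq)
    for pos in hits:
        chars[pos] = "ACGT"[(("ACGT".index(chars[pos]) + int(rng.integers(1, 4))) % 4)]
    return "".join(chars)


# ---------------------------------------------------------------------------
# FASTA / FASTQ plumbing
# ---------------------------------------------------------------------------

def write_fasta(path, sequences: Dict[str, str]) -> None:
    with open(path, "w") as out:
        for name, seq in sequences.items():
            out.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                out.write(seq[i : i + 60] + "\n")


def read_fasta(path) -> Dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fastq(path, reads: Sequence[SimRead]) -> None:
    with open(path, "w") as out:
        for read in reads:
            out.write(f"@{read.name}\n{read.seq}\n+\n{'I' * len(read.seq)}\n")


def read_fastq(path, is_read1: bool = True) -> List[SimRead]:
    from Bio import SeqIO

    return [
        SimRead(rec.id, str(rec.seq).upper(), is_read1)
        for rec in SeqIO.parse(str(path), "fastq")
    ]


# ---------------------------------------------------------------------------
# naive unique-best mapper
# ---------------------------------------------------------------------------

MAX_NAIVE_REFERENCE = 5_000_000


class NaiveMapper:
    """Exhaustive seed-and-verify mapper: gapless, full-length, unique-best.

    Non-overlapping k-mer seeds guarantee (by pigeonhole) that every gapless
    alignment with at most ``len(read)//k - 1`` mismatches is examined. The
    single best candidate by (mismatches, position, strand) is reported only
    when strictly fewer mismatches than the runner-up; any tie, within or
    across strands, leaves the read unmapped — emulating a strict
    unique-best-mapping aligner.
    """

    def __init__(
        self,
        reference: str,
        ref_name: str = DEFAULT_CHROM,
        k: int = 12,
        max_mismatches: Optional[int] = None,
    ):
        if len(reference) > MAX_NAIVE_REFERENCE:
            raise ValueError(
                f"reference of {len(reference)} bp exceeds the exhaustive-mapper "
                f"guard ({MAX_NAIVE_REFERENCE} bp); use a real aligner"
            )
        if k < 4:
            raise ValueError("seed length k must be >= 4")
        self.reference = reference.upper()
        self.ref_name = ref_name
        self.k = k
        self.max_mismatches = max_mismatches
        self._ref_arr = np.frombuffer(self.reference.encode("ascii"), dtype=np.uint8)
        self._index: Dict[bytes, List[int]] = {}
        ref_bytes = self.reference.encode("ascii")
        for pos in range(len(ref_bytes) - k + 1):
            kmer = ref_bytes[pos : pos + k]
            self._index.setdefault(kmer, []).append(pos)

    def _effective_max(self, read_len: int) -> int:
        n_seeds = read_len // self.k
        if n_seeds < 1:
            raise ValueError(f"read of {read_len} bp shorter than seed k={self.k}")
        guarantee = n_seeds - 1
        if self.max_mismatches is None:
            return guarantee
        if self.max_mismatches > guarantee:
            raise ValueError(
                f"max_mismatches={self.max_mismatches} exceeds the exhaustive "
                f"guarantee of {guarantee} for {read_len} bp reads with k={self.k}"
            )
        return self.max_mismatches

    def _candidates(self, seq_bytes: bytes, read_len: int) -> List[int]:
        limit = len(self.reference) - read_len
        positions = set()
        for off in range(0, read_len - self.k + 1, self.k):
            for hit in self._index.get(seq_bytes[off : off + self.k], ()):
                start = hit - off
                if 0 <= start <= limit:
                    positions.add(start)
        return sorted(positions)

    def all_hits(self, seq: str) -> List[Tuple[int, int, int]]:
        """Every candidate placement as (mismatches, pos, strand<0|1>)."""
        seq = seq.upper()
        read_len = len(seq)
        max_mm = self._effective_max(read_len)
        hits: List[Tuple[int, int, int]] = []
        for strand, oriented in ((0, seq), (1, revcomp(seq))):
            arr = np.frombuffer(oriented.encode("ascii"), dtype=np.uint8)
            for pos in self._candidates(oriented.encode("ascii"), read_len):
                mm = int(np.count_nonzero(self._ref_arr[pos : pos + read_len] != arr))
                if mm <= max_mm:
                    hits.append((mm, pos, strand))
        return hits

    def mismatch_offsets(self, seq: str, pos: int, strand: int) -> np.ndarray:
        oriented = seq.upper() if strand == 0 else revcomp(seq.upper())
        arr = np.frombuffer(oriented.encode("ascii"), dtype=np.uint8)
        return np.nonzero(self._ref_arr[pos : pos + len(seq)] != arr)[0]

    def map_read(self, seq: str) -> Optional[Tuple[int, bool, int, np.ndarray]]:
        """Best unique gapless placement: (0-based pos, is_reverse, NM, mismatch offsets)."""
        hits = self.all_hits(seq)
        if not hits:
            return None
        hits.sort()
        if len(hits) > 1 and hits[0][0] == hits[1][0]:
            return None  # not a unique best
        mm, pos, strand = hits[0]
        return pos, bool(strand), mm, self.mismatch_offsets(seq, pos, strand)


class MultiMapper:
    """Unique-best mapping across several reference sequences at once.

    Candidate hits from every sequence compete in one pool, so a read placed
    equally well on two different sequences (e.g. the two genome copies of a
    concatenated reference) is unmapped — the behavior a strict unique-best
    aligner shows on a combined reference.
    """

    def __init__(
        self,
        references: Dict[str, str],
        k: int = 12,
        max_mismatches: Optional[int] = None,
    ):
        if sum(len(s) for s in references.values()) > MAX_NAIVE_REFERENCE:
            raise ValueError("combined reference exceeds the exhaustive-mapper guard")
        self.names = list(references)
        self.mappers = {
            name: NaiveMapper(seq, name, k=k, max_mismatches=max_mismatches)
            for name, seq in references.items()
        }

    def map_read(self, seq: str) -> Optional[Tuple[str, int, bool, int, np.ndarray]]:
        hits: List[Tuple[int, int, int, int]] = []  # (mm, name_idx, pos, strand)
        for idx, name in enumerate(self.names):
            for mm, pos, strand in self.mappers[name].all_hits(seq):
                hits.append((mm, idx, pos, strand))
        if not hits:
            return None
        hits.sort()
        if len(hits) > 1 and hits[0][0] == hits[1][0]:
            return None
        mm, idx, pos, strand = hits[0]
        name = self.names[idx]
        mism = self.mappers[name].mismatch_offsets(seq, pos, strand)
        return name, pos, bool(strand), mm, mism


def _md_string(reference: str, pos: int, read_len: int, mism_offsets: np.ndarray) -> str:
    parts = []
    prev = 0
    for off in mism_offsets:
        parts.append(str(int(off) - prev))
        parts.append(reference[pos + int(off)])
        prev = int(off) + 1
    parts.append(str(read_len - prev))
    return "".join(parts)


def map_reads(
    reads: Iterable[SimRead],
    mapper,
    paired: bool = True,
) -> List[AlignmentRecord]:
    """Map each read independently, emitting NM and MD tags (unmapped kept).

    ``mapper`` is a :class:`NaiveMapper` or :class:`MultiMapper`.
    """
    multi = isinstance(mapper, MultiMapper)
    records: List[AlignmentRecord] = []
    for read in reads:
        flag = 0
        if paired:
            flag |= FLAG_PAIRED | (FLAG_READ1 if read.is_read1 else FLAG_READ2)
            flag |= FLAG_MATE_UNMAPPED  # mate state is not tracked by this mapper
        hit = mapper.map_read(read.seq)
        if hit is None:
            records.append(
                AlignmentRecord(read_name=read.name, flag=flag | FLAG_UNMAPPED, seq=read.seq)
            )
            continue
        if multi:
            chrom, pos, is_reverse, nm, mism = hit
            reference = mapper.mappers[chrom].reference
        else:
            pos, is_reverse, nm, mism = hit
            chrom, reference = mapper.ref_name, mapper.reference
        if is_reverse:
            flag |= FLAG_REVERSE
        seq = revcomp(read.seq) if is_reverse else read.seq
        md = _md_string(reference, pos, len(seq), mism)
        records.append(
            AlignmentRecord(
                read_name=read.name,
                flag=flag,
                chrom=chrom,
                pos=pos + 1,
                mapq=NAIVE_MAPQ,
                cigar=(("M", len(seq)),),
                seq=seq,
                qual="I" * len(seq),
                edit_distance=nm,
                md=md,
                tags={"NM": nm, "MD": md},
            )
        )
    return records


def map_read_set(
    reads1: Sequence[SimRead],
    reads2: Optional[Sequence[SimRead]],
    reference,
    ref_name: str = DEFAULT_CHROM,
    k: int = 12,
    max_mismatches: Optional[int] = None,
) -> List[AlignmentRecord]:
    """Map an R1 (and optional R2) read set.

    ``reference`` is one sequence (named ``ref_name``) or a dict of
    name -> sequence, in which case unique-best competition spans all of them.
    """
    if isinstance(reference, dict):
        mapper = MultiMapper(reference, k=k, max_mismatches=max_mismatches)
    else:
        mapper = NaiveMapper(reference, ref_name, k=k, max_mismatches=max_mismatches)
    records = map_reads(reads1, mapper, paired=reads2 is not None)
    if reads2 is not None:
        records.extend(map_reads(reads2, mapper, paired=True))
    return records
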