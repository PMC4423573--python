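import numpy as np
import pytest

from homeosort import io_alignments, simgen
from homeosort.model import (
    FLAG_PAIRED,
    FLAG_READ1,
    FLAG_READ2,
    FLAG_UNMAPPED,
    AlignmentRecord,
    FragmentView,
)

BASES = "ACGT"


def make_record(
    name="r1",
    chrom="chr1",
    pos=1,
    cigar=(("M", 10),),
    seq=None,
    mapq=40,
    nm=0,
    md=None,
    mapped=True,
    paired=False,
    read2=False,
    **kwargs,
):
    """Convenience constructor for hand-built alignment records."""
    flag = 0
    if paired:
        flag |= FLAG_PAIRED | (FLAG_READ2 if read2 else FLAG_READ1)
    if not mapped:
        return AlignmentRecord(read_name=name, flag=flag | FLAG_UNMAPPED, seq=seq or "")
    if seq is None:
        read_len = sum(n for op, n in cigar if op in "MIS=X")
        seq = "A" * read_len
    tags = {"NM": nm}
    if md is not None:
        tags["MD"] = md
    return AlignmentRecord(
        read_name=name,
        flag=flag,
        chrom=chrom,
        pos=pos,
        mapq=mapq,
        cigar=cigar,
        seq=seq,
        edit_distance=nm,
        md=md,
        tags=tags,
        **kwargs,
    )


def make_view(name="r1", *records):
    mate1 = mate2 = None
    for rec in records:
        if rec.is_paired and rec.is_read2:
            mate2 = rec
        else:
            mate1 = rec
    return FragmentView(name, mate1=mate1, mate2=mate2)


def random_seq(rng, length):
    return "".join(BASES[i] for i in rng.integers(0, 4, length))


@pytest.fixture(scope="session")
def sim_cfg():
    """Small but structurally complete simulation profile."""
    return simgen.SimConfig(
        ancestor_length=60_000,
        substitution_rate=0.02,
        indel_rate=0.001,
        unique_segment_fraction=0.05,
        unique_segment_length=2_000,
        n_fragments=3_000,
        seed=20240901,
    )


@pytest.fixture(scope="session")
def sim_genomes(sim_cfg):
    return simgen.evolve_genomes(sim_cfg)


@pytest.fixture(scope="session")
def sim_reads(sim_genomes, sim_cfg):
    return simgen.simulate_reads(sim_genomes, sim_cfg)


@pytest.fixture(scope="session")
def sim_mapped(sim_genomes, sim_reads):
    """Both single-reference mappings of the simulated read set."""
    reads1, reads2, _ = sim_reads
    recs_a = simgen.map_read_set(reads1, reads2, sim_genomes.seq_a)
    recs_b = simgen.map_read_set(reads1, reads2, sim_genomes.seq_b)
    return recs_a, recs_b


@pytest.fixture(scope="session")
def sim_pairs(sim_mapped):
    recs_a, recs_b = sim_mapped
    return list(io_alignments.collate_fragments(recs_a, recs_b))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
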