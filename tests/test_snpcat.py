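import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from homeosort import snpcat
from homeosort.model import Criterion, Genome
from homeosort.snpcat import (
    HomoeoSNP,
    SNPIndex,
    SNPIndexError,
    VoteTally,
    base_at,
    decide_category,
    read_snp_index,
    tally_fragment,
    vote_stream,
    write_snp_index,
)

from conftest import make_record, make_view
from oracles import oracle_base_at, oracle_vote


class TestIndexIO:
    def test_basic_line(self, tmp_path):
        path = tmp_path / "snps.tsv"
        path.write_text("chr1\t101\tA\tG\n")
        index = read_snp_index(path)
        assert len(index) == 1
        assert index.get("chr1", 101) == HomoeoSNP("chr1", 101, "A", "G")

    def test_comments_and_blank_lines(self, tmp_path):
        path = tmp_path / "snps.tsv"
        path.write_text("# header\n\nchr1\t5\tC\tT\n")
        assert len(read_snp_index(path)) == 1

    def test_duplicate_position_names_both_lines(self, tmp_path):
        path = tmp_path / "snps.tsv"
        path.write_text("chr1\t101\tA\tG\nchr1\t101\tC\tT\n")
        with pytest.raises(SNPIndexError, match=r"line 1"):
            read_snp_index(path)

    def test_empty_file_is_valid_empty_index(self, tmp_path):
        path = tmp_path / "snps.tsv"
        path.write_text("")
        assert len(read_snp_index(path)) == 0

    def test_identical_alleles_rejected(self, tmp_path):
        path = tmp_path / "snps.tsv"
        path.write_text("chr1\t101\tA\tA\n")
        with pytest.raises(SNPIndexError, match="differ"):
            read_snp_index(path)

    def test_non_acgt_allele_rejected(self, tmp_path):
        path = tmp_path / "snps.tsv"
        path.write_text("chr1\t101\tA\tN\n")
        with pytest.raises(SNPIndexError):
            read_snp_index(path)

    def test_round_trip(self, tmp_path):
        index = SNPIndex(
            [HomoeoSNP("chr1", 5, "A", "C"), HomoeoSNP("chr1", 9, "G", "T")]
        )
        path = tmp_path / "out.tsv"
        write_snp_index(index, path)
        assert read_snp_index(path) == index

    def test_vcf_ingestion(self, tmp_path):
        vcf = tmp_path / "snps.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##contig=<ID=chr1,length=1000>\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
            "chr1\t101\t.\tA\tG\t.\t.\t.\n"
            "chr1\t150\t.\tC\tCT\t.\t.\t.\n"  # indel: skipped
        )
        index = snpcat.read_snp_index_vcf(vcf)
        assert len(index) == 1
        assert index.get("chr1", 101) == HomoeoSNP("chr1", 101, "A", "G")


class TestBaseAt:
    def test_direct_offset(self):
        rec = make_record(pos=101, cigar=(("M", 10),), seq="ACGTACGTAC")
        assert base_at(rec, 105) == "A"  # offset 4

    def test_deleted_position_absent(self):
        # CIGAR 3M2D7M at pos 101: ref 104 falls in the deletion
        rec = make_record(pos=101, cigar=(("M", 3), ("D", 2), ("M", 7)), seq="ACGTACGTAC")
        assert base_at(rec, 104) is None
        assert oracle_base_at("ACGTACGTAC", 101, rec.cigar, 104) is None

    def test_insertion_shifts_read_not_reference(self):
        # CIGAR 3M2I7M at pos 101: ref 106 is read offset 7 (hand-walked)
        seq = "ACGTTACGTAGC"  # 3M + 2I + 7M consumes 12 read bases
        rec = make_record(pos=101, cigar=(("M", 3), ("I", 2), ("M", 7)), seq=seq)
        assert oracle_base_at(seq, 101, rec.cigar, 106) == seq[7]
        assert base_at(rec, 106) == seq[7]

    def test_outside_span_absent(self):
        rec = make_record(pos=101, cigar=(("M", 10),), seq="ACGTACGTAC")
        assert base_at(rec, 100) is None
        assert base_at(rec, 111) is None

    def test_oracle_equivalence_randomized(self, rng):
        ops = ["M", "I", "D", "S"]
        for _ in range(300):
            cigar = []
            read_len = 0
            cigar.append(("M", int(rng.integers(1, 20))))
            for _ in range(int(rng.integers(0, 4))):
                op = ops[int(rng.integers(0, 4))]
                cigar.append((op, int(rng.integers(1, 6))))
                cigar.append(("M", int(rng.integers(1, 20))))
            read_len = sum(n for op, n in cigar if op in "MIS")
            seq = "".join("ACGT"[i] for i in rng.integers(0, 4, read_len))
            pos = int(rng.integers(1, 50))
            rec = make_record(pos=pos, cigar=tuple(cigar), seq=seq)
            span = sum(n for op, n in cigar if op in "MD")
            for ref_pos in range(pos - 2, pos + span + 2):
                assert base_at(rec, ref_pos) == oracle_base_at(seq, pos, cigar, ref_pos)


class TestTally:
    def make_index(self):
        return SNPIndex(
            [
                HomoeoSNP("chr1", 102, "A", "G"),
                HomoeoSNP("chr1", 104, "C", "T"),
                HomoeoSNP("chr1", 107, "G", "A"),
                HomoeoSNP("chr1", 109, "T", "C"),
            ]
        )

    def test_unanimous_a(self):
        view = make_view("r", make_record(name="r", pos=101, cigar=(("M", 10),), seq="NANCNNGNTN"))
        tally = tally_fragment(view, self.make_index())
        assert (tally.votes_a, tally.votes_b) == (4, 0)

    def test_no_overlap(self):
        view = make_view("r", make_record(name="r", pos=500, cigar=(("M", 10),), seq="ACGTACGTAC"))
        tally = tally_fragment(view, self.make_index())
        assert tally.informative == 0

    def test_mismatching_base_is_uninformative(self):
        # matches alleleA at 102 and 104, matches neither at 107 (C)
        view = make_view("r", make_record(name="r", pos=101, cigar=(("M", 8),), seq="NANCNNCN"))
        tally = tally_fragment(view, self.make_index())
        assert tally.informative == 2
        assert tally.uninformative_bases == 1

    def test_mates_pool_and_vote_independently(self):
        rec1 = make_record(name="r", pos=101, cigar=(("M", 4),), seq="NANC", paired=True)
        rec2 = make_record(name="r", pos=103, cigar=(("M", 5),), seq="NCNNG", paired=True, read2=True)
        view = make_view("r", rec1, rec2)
        tally = tally_fragment(view, self.make_index())
        # SNP 104 covered by both mates: two independent A votes; 102 and 107 one each
        assert (tally.votes_a, tally.votes_b) == (4, 0)


class TestDecide:
    def test_three_of_four_is_inclusive(self):
        decision = decide_category(VoteTally(votes_a=3, votes_b=1))
        assert decision.genome is Genome.A
        assert decision.criterion is Criterion.MATCHES

    def test_even_split_is_n(self):
        decision = decide_category(VoteTally(votes_a=2, votes_b=2))
        assert decision.genome is Genome.N
        assert decision.criterion is Criterion.TIE

    def test_unanimous(self):
        assert decide_category(VoteTally(votes_a=5, votes_b=0)).genome is Genome.A
        assert decide_category(VoteTally(votes_a=0, votes_b=5)).genome is Genome.B

    def test_no_evidence_marked_distinctly(self):
        decision = decide_category(VoteTally())
        assert decision.genome is Genome.N
        assert decision.criterion is Criterion.NO_EVIDENCE

    @pytest.mark.parametrize("threshold", [0.0, 0.5, 1.01, -1.0])
    def test_invalid_threshold(self, threshold):
        with pytest.raises(ValueError):
            decide_category(VoteTally(votes_a=1), threshold)

    @given(
        votes_a=st.integers(0, 30),
        votes_b=st.integers(0, 30),
        threshold=st.floats(0.51, 1.0),
    )
    @settings(max_examples=300, deadline=None)
    def test_matches_vote_oracle(self, votes_a, votes_b, threshold):
        decision = decide_category(VoteTally(votes_a=votes_a, votes_b=votes_b), threshold)
        assert decision.genome.value == oracle_vote(votes_a, votes_b, threshold)

    @given(votes_a=st.integers(0, 30), votes_b=st.integers(0, 30))
    @settings(max_examples=200, deadline=None)
    def test_threshold_monotonicity(self, votes_a, votes_b):
        tally = VoteTally(votes_a=votes_a, votes_b=votes_b)
        categorized_at = [
            decide_category(tally, t).genome in (Genome.A, Genome.B)
            for t in (0.51, 0.6, 0.75, 0.9, 1.0)
        ]
        # once lost, never regained as the threshold rises
        for earlier, later in zip(categorized_at, categorized_at[1:]):
            assert earlier or not later
        if categorized_at[-1]:
            assert votes_a == 0 or votes_b == 0  # threshold 1.0 demands unanimity


class TestLocality:
    def test_non_index_bases_never_change_the_tally(self, rng):
        index = SNPIndex([HomoeoSNP("chr1", p, "A", "G") for p in (110, 130, 150)])
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 100))
        rec = make_record(name="r", pos=101, cigar=(("M", 100),), seq=seq)
        baseline = tally_fragment(make_view("r", rec), index)
        index_offsets = {110 - 101, 130 - 101, 150 - 101}
        for _ in range(50):
            off = int(rng.integers(0, 100))
            if off in index_offsets:
                continue
            mutated = seq[:off] + "ACGT"[int(rng.integers(0, 4))] + seq[off + 1 :]
            rec2 = make_record(name="r", pos=101, cigar=(("M", 100),), seq=mutated)
            tally = tally_fragment(make_view("r", rec2), index)
            assert (tally.votes_a, tally.votes_b, tally.uninformative_bases) == (
                baseline.votes_a,
                baseline.votes_b,
                baseline.uninformative_bases,
            )


class TestVoteStream:
    def test_all_uninformative_is_all_n(self):
        index = SNPIndex()
        views = [
            make_view(f"r{i}", make_record(name=f"r{i}", pos=1, cigar=(("M", 10),)))
            for i in range(5)
        ]
        decisions, summary = vote_stream(views, index)
        assert summary["A"] == summary["B"] == 0
        assert summary["N"] == 5
        assert all(d.criterion is Criterion.NO_EVIDENCE for d in decisions)

    def test_single_a_voting_fragment(self):
        index = SNPIndex([HomoeoSNP("chr1", 3, "C", "T")])
        view = make_view("r", make_record(name="r", pos=1, cigar=(("M", 10),), seq="NNCNNNNNNN"))
        decisions, summary = vote_stream([view], index)
        assert summary == {"fragments": 1, "mapped": 1, "A": 1, "B": 0, "N": 0}

    def test_conservation_on_simulated_run(self, sim_genomes, sim_mapped, tmp_path):
        from homeosort import io_alignments

        index_path = tmp_path / "true.tsv"
        sim_genomes.write_diff_index(index_path, "A")
        index = read_snp_index(index_path)
        recs_a, _ = sim_mapped
        fragments = io_alignments.group_fragments(recs_a)
        decisions, summary = vote_stream(fragments.values(), index)
        assert summary["A"] + summary["B"] + summary["N"] == summary["mapped"]
        assert summary["mapped"] > 0

    def test_error_free_reads_with_true_index_never_wrong(
        self, sim_genomes, sim_mapped, sim_reads, tmp_path
    ):
        from homeosort import io_alignments, stats

        _, _, truth = sim_reads
        index_path = tmp_path / "true.tsv"
        sim_genomes.write_diff_index(index_path, "A")
        index = read_snp_index(index_path)
        recs_a, _ = sim_mapped
        fragments = io_alignments.group_fragments(recs_a)
        decisions, _ = vote_stream(fragments.values(), index)
        report = stats.error_rate(decisions, truth, method="snpcat")
        assert report.wrong_count == 0
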