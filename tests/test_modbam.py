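import numpy as np
import pysam
import pytest

from methcohort import (
    aggregate_cpg,
    bam_to_table,
    cpg_sites,
    decode_read_mods,
    dequantize,
    partition_reads,
)
from methcohort.errors import MalformedTagError, NoModificationTagsError
from methcohort.modbam import BaseModCall
from methcohort.simulate import encode_mm_ml, revcomp
from oracles import naive_decode, regex_cpg


def random_read(rng, with_clip=True):
    """Random (seq, is_reverse, aligned_pairs, mm, ml) in sequenced orientation."""
    length = int(rng.integers(20, 120))
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, length))
    is_reverse = bool(rng.integers(2))
    # Alignment: optional leading soft clip and one internal insertion.
    clip = int(rng.integers(0, 8)) if with_clip else 0
    ins_at = int(rng.integers(clip + 2, length - 2)) if length > clip + 6 else None
    ins_len = int(rng.integers(1, 4)) if ins_at else 0
    aligned_pairs = {}
    ref = 50
    for sam_i in range(length):
        if sam_i < clip:
            continue
        if ins_at is not None and ins_at <= sam_i < ins_at + ins_len:
            continue
        aligned_pairs[sam_i] = ref
        ref += 1
    c_positions = [i for i, b in enumerate(seq) if b == "C"]
    n_listed = int(rng.integers(0, len(c_positions) + 1)) if c_positions else 0
    listed = sorted(rng.choice(c_positions, size=n_listed, replace=False))
    calls = {int(i): int(rng.integers(0, 256)) for i in listed}
    flag = "?" if rng.integers(2) else "."
    if flag == ".":
        # '.' implies unlisted Cs are unmodified; keep listed scores high so
        # the encoder's "list only modified" convention is exercised.
        calls = {i: int(rng.integers(128, 256)) for i in calls}
    mm, ml = encode_mm_ml(seq, calls, flag=flag)
    return seq, is_reverse, aligned_pairs, mm, ml


class TestDecoder:
    def test_hand_decoded_example(self):
        # Two C calls on "ACGTCG": scores 230 and 10 dequantize to the
        # interval midpoints (q + 0.5) / 256.
        calls = decode_read_mods(
            "ACGTCG", False, {i: i + 1 for i in range(6)}, "C+m?,0,0;", [230, 10]
        )
        assert [(c.ref_position, round(c.probability, 4)) for c in calls] == [
            (2, 0.9004),
            (5, 0.041),
        ]

    def test_empty_run_yields_no_calls(self):
        assert decode_read_mods("ACGT", False, {0: 1}, "C+m?;", []) == []

    def test_implicit_unmodified_dot_flag(self):
        # '.' run listing nothing: every aligned C becomes a p=0 call.
        calls = decode_read_mods(
            "CCACC", False, {0: 1, 1: 2, 3: 4}, "C+m.;", []
        )
        assert {(c.ref_position, c.probability) for c in calls} == {
            (1, 0.0),
            (2, 0.0),
            (4, 0.0),
        }

    def test_multi_code_run_orders_probabilities_per_position(self):
        calls = decode_read_mods(
            "ACAC", False, {i: i + 1 for i in range(4)},
            "C+mh?,0,0;", [200, 20, 10, 100],
        )
        by_key = {(c.ref_position, c.mod_code): c.probability for c in calls}
        assert by_key[(2, "m")] == dequantize(200)
        assert by_key[(2, "h")] == dequantize(20)
        assert by_key[(4, "m")] == dequantize(10)
        assert by_key[(4, "h")] == dequantize(100)

    @pytest.mark.parametrize(
        "mm, ml, fragment",
        [
            ("C+m?,0,0;", [230], "ML"),
            ("C+m?,0;", [230, 10], "ML"),
            ("Z+m?,0;", [230], "canonical"),
            ("C+m?,-1;", [230], "negative"),
            ("C+m?,99;", [230], "overrun"),
        ],
    )
    def test_malformed_tags_raise_with_read_id(self, mm, ml, fragment):
        with pytest.raises(MalformedTagError, match=fragment):
            decode_read_mods(
                "CCCC", False, {i: i + 1 for i in range(4)}, mm, ml,
                read_id="readX",
            )

    def test_matches_naive_walking_decoder_on_random_reads(self):
        rng = np.random.default_rng(2024)
        for _ in range(300):
            seq, rev, pairs, mm, ml = random_read(rng)
            ours = decode_read_mods(seq, rev, pairs, mm, ml)
            ref = naive_decode(seq, rev, pairs, mm, ml)
            got = {
                (c.ref_position, c.mod_code): (c.probability, c.strand_of_call)
                for c in ours
            }
            assert got == ref

    def test_agrees_with_pysam_modified_bases(self):
        # Independent cross-check: pysam's own MM/ML parser on a real record.
        header = pysam.AlignmentHeader.from_dict(
            {"HD": {"VN": "1.6"}, "SQ": [{"SN": "c", "LN": 1000}]}
        )
        rng = np.random.default_rng(7)
        for rev in (False, True):
            sam_seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 60))
            seq = revcomp(sam_seq) if rev else sam_seq
            cs = [i for i, b in enumerate(seq) if b == "C"][:5]
            calls = {i: int(rng.integers(0, 256)) for i in cs}
            mm, ml = encode_mm_ml(seq, calls, flag="?")
            read = pysam.AlignedSegment(header)
            read.query_name = "r"
            read.query_sequence = sam_seq
            read.flag = 16 if rev else 0
            read.reference_id = 0
            read.reference_start = 10
            read.mapping_quality = 60
            read.cigartuples = [(0, 60)]
            read.set_tag("MM", mm)
            read.set_tag("ML", list(calls[i] for i in sorted(calls)))
            pairs = {q: r + 1 for q, r in read.get_aligned_pairs(matches_only=True)}
            ours = {
                c.ref_position: c.probability
                for c in decode_read_mods(seq, rev, pairs, mm, ml)
            }
            theirs = {}
            for (_, _, _), hits in read.modified_bases.items():
                for sam_i, q in hits:
                    theirs[pairs[sam_i]] = dequantize(q)
            assert ours == theirs


class TestCpGSites:
    @pytest.mark.parametrize(
        "seq, expected",
        [("ACGTCGA", [2, 5]), ("CCCC", []), ("CG", [1]), ("", []), ("cgCg", [1, 3])],
    )
    def test_direct_scan(self, seq, expected):
        assert cpg_sites(seq) == expected

    def test_matches_regex_oracle_on_random_sequences(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 500))
            assert cpg_sites(seq) == regex_cpg(seq)


def mkcall(pos, strand, p, code="m"):
    return BaseModCall("r", "chr1", pos, strand, code, p)


class TestAggregate:
    def test_counts_and_boundary(self):
        calls = [mkcall(10, "+", p) for p in (0.9, 0.9, 0.9, 0.1)]
        [sc] = aggregate_cpg(calls, [10])
        assert (sc.n_modified, sc.n_valid, sc.frequency) == (3, 4, 0.75)
        # p exactly at the threshold counts as modified
        [sc] = aggregate_cpg([mkcall(10, "+", 0.5)], [10])
        assert sc.n_modified == 1

    def test_strand_combining_maps_g_calls_to_forward_c(self):
        calls = [mkcall(10, "+", 0.9), mkcall(11, "-", 0.9), mkcall(11, "-", 0.1)]
        [sc] = aggregate_cpg(calls, [10])
        assert (sc.n_modified, sc.n_valid) == (2, 3)

    def test_non_cpg_calls_ignored(self):
        assert aggregate_cpg([mkcall(99, "+", 0.9)], [10]) == []

    def test_min_confidence_band(self):
        calls = [mkcall(10, "+", p) for p in (0.9, 0.5, 0.1)]
        [sc] = aggregate_cpg(calls, [10], min_confidence=0.8)
        assert (sc.n_modified, sc.n_valid) == (1, 2)

    def test_frequency_times_valid_is_modified(self):
        rng = np.random.default_rng(3)
        calls = [mkcall(10, "+", float(p)) for p in rng.random(50)]
        [sc] = aggregate_cpg(calls, [10])
        assert sc.frequency * sc.n_valid == sc.n_modified


class FakeRead:
    def __init__(self, tags):
        self.tags = tags

    def has_tag(self, name):
        return name in self.tags

    def get_tag(self, name):
        return self.tags[name]


class TestPartition:
    def test_direct_grouping(self):
        reads = [FakeRead({"HP": 1}), FakeRead({"HP": 1}), FakeRead({"HP": 2}),
                 FakeRead({})]
        groups = partition_reads(reads)
        assert {k: len(v) for k, v in groups.items()} == {
            "H1": 2, "H2": 1, "ungrouped": 1
        }

    def test_all_untagged(self):
        groups = partition_reads([FakeRead({}), FakeRead({})])
        assert list(groups) == ["ungrouped"]

    def test_disjoint_cover_property(self):
        rng = np.random.default_rng(5)
        reads = [
            FakeRead({"HP": int(rng.integers(1, 4))} if rng.integers(2) else {})
            for _ in range(100)
        ]
        groups = partition_reads(reads, tag_name="HP", prefix="Hap")
        seen = [r for g in groups.values() for r in g]
        assert len(seen) == 100 and len(set(map(id, seen))) == 100
        assert all(k.startswith("Hap") or k == "ungrouped" for k in groups)


class TestBamToTable:
    def test_frequencies_match_generator_truth_exactly(self, sim_cohort):
        spec, bams, fasta, truth = sim_cohort
        table = bam_to_table(bams, fasta, partition=True)
        assert table == truth.to_table(spec.chrom)

    def test_partitioned_column_arithmetic(self, sim_cohort):
        spec, bams, fasta, _ = sim_cohort
        table = bam_to_table(bams[:2], fasta, partition=True)
        assert len(table.samples) == 4
        assert table.samples == ["IND1_H1", "IND1_H2", "IND2_H1", "IND2_H2"]

    def test_thread_count_invariance(self, sim_cohort):
        spec, bams, fasta, _ = sim_cohort
        t1 = bam_to_table(bams, fasta, partition=True, threads=1)
        t4 = bam_to_table(bams, fasta, partition=True, threads=4)
        assert t1 == t4 and t1.samples == t4.samples

    def test_region_restriction(self, sim_cohort):
        from methcohort import GenomicRegion

        spec, bams, fasta, truth = sim_cohort
        whole = bam_to_table(bams, fasta, partition=True)
        region = GenomicRegion(spec.chrom, 1, 55)
        sub = bam_to_table(bams, fasta, partition=True, region=region)
        assert sub == whole.subset(region)

    def test_no_mod_tags_is_explicit_error(self, tmp_path, sim_cohort):
        spec, bams, fasta, _ = sim_cohort
        plain = tmp_path / "plain.bam"
        with pysam.AlignmentFile(bams[0]) as src:
            with pysam.AlignmentFile(plain, "wb", header=src.header) as out:
                for read in src:
                    read.set_tag("MM", None)
                    read.set_tag("ML", None)
                    out.write(read)
        pysam.index(str(plain))
        with pytest.raises(NoModificationTagsError, match="plain.bam"):
            bam_to_table([plain], fasta)
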