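"""Tests for reference-set construction and competitive read recruitment."""


import pytest

import metasat as m
from metasat._seq import revcomp_str
from metasat.recruitment import export_sam, import_sam
from metasat.synthetic import ROLE_CONSERVED


def _plant_mismatches(seq: str, positions) -> str:
    alt = {"A": "C", "C": "G", "G": "T", "T": "A"}
    out = list(seq)
    for p in positions:
        out[p] = alt[out[p]]
    return "".join(out)


class TestReferenceSet:
    def test_offsets_tile_concatenation(self):
        g1 = m.generate_genome(10_000, 0.4, 1, seed=1, id="a")
        g2 = m.generate_genome(20_000, 0.4, 1, seed=2, id="b")
        refs = m.build_reference_set([g1, g2])
        assert refs.offsets == {"a": (0, 10_000), "b": (10_000, 20_000)}
        # boundary round-trips
        assert refs.global_to_local(0) == ("a", "a_c1", 0)
        assert refs.global_to_local(9_999) == ("a", "a_c1", 9_999)
        assert refs.global_to_local(10_000) == ("b", "b_c1", 0)
        assert refs.global_to_local(29_999) == ("b", "b_c1", 19_999)

    def test_mask_excision_length(self, small_genome):
        masks = {small_genome.id: [(small_genome.contigs[0][0], 1000, 1500)]}
        refs = m.build_reference_set([small_genome], masks=masks)
        assert refs.genome_length(small_genome.id) == 9500
        assert refs.excised[small_genome.id] == [
            (small_genome.contigs[0][0], 1000, 1500)
        ]

    def test_excised_coordinates_recoverable(self, small_genome):
        cid = small_genome.contigs[0][0]
        masks = {small_genome.id: [(cid, 1000, 1500)]}
        refs = m.build_reference_set([small_genome], masks=masks)
        assert refs.to_original_coord(small_genome.id, cid, 500) == 500
        assert refs.to_original_coord(small_genome.id, cid, 1000) == 1500
        # the excised sequence really is gone
        masked = refs.genomes[0].contig_seq(cid)
        orig = small_genome.contig_seq(cid)
        assert masked == orig[:1000] + orig[1500:]

    def test_duplicate_ids_error(self, small_genome):
        with pytest.raises(ValueError, match="duplicate"):
            m.build_reference_set([small_genome, small_genome])

    def test_mask_outside_contig_error(self, small_genome):
        cid = small_genome.contigs[0][0]
        with pytest.raises(ValueError):
            m.build_reference_set(
                [small_genome], masks={small_genome.id: [(cid, 9000, 11_000)]}
            )

    def test_k_larger_than_contig_error(self):
        g = m.GenomeSequence(id="tiny", contigs=[("tiny_c1", "ACGTACGTAC")])
        with pytest.raises(ValueError, match="k"):
            m.build_reference_set([g], k=31)


class TestRecruitReads:
    def test_exact_read_identity_100(self, small_genome):
        seq = small_genome.contigs[0][1]
        reads = m.ReadSet(ids=["x"], seqs=[seq[2000:2150]])
        refs = m.build_reference_set([small_genome])
        (a,) = m.recruit_reads(reads, refs)
        assert (a.genome_id, a.contig, a.start0, a.strand) == (
            small_genome.id, small_genome.contigs[0][0], 2000, "+",
        )
        assert a.identity == 100.0

    def test_mismatch_threshold_bracketing(self):
        # 7 mismatches -> 95.33% assigned; 8 -> 94.67% unassigned
        g = m.generate_genome(200_000, 0.42, 1, seed=61, id="gbig")
        seq = g.contigs[0][1][5000:5150]
        r7 = _plant_mismatches(seq, [35, 50, 65, 80, 95, 110, 125])
        r8 = _plant_mismatches(seq, [35, 50, 65, 80, 95, 110, 125, 140])
        reads = m.ReadSet(ids=["m7", "m8"], seqs=[r7, r8])
        refs = m.build_reference_set([g])
        alignments = m.recruit_reads(reads, refs, min_identity=95.0)
        assert [a.read_id for a in alignments] == ["m7"]
        assert alignments[0].mismatches == 7
        assert alignments[0].identity == pytest.approx(100 * 143 / 150)

    def test_reverse_strand_read(self, small_genome):
        seq = small_genome.contigs[0][1]
        reads = m.ReadSet(ids=["rc"], seqs=[revcomp_str(seq[4000:4150])])
        refs = m.build_reference_set([small_genome])
        (a,) = m.recruit_reads(reads, refs)
        assert (a.start0, a.strand, a.mismatches) == (4000, "-", 0)

    def test_error_free_truth_recovery(self):
        g = m.generate_genome(200_000, 0.42, 1, seed=62, id="g")
        spec = m.CommunitySpec([(g, 1.0)], 150, 0.0, seed=63)
        reads = m.simulate_reads(spec, 20_000)
        refs = m.build_reference_set([g])
        alignments = m.recruit_reads(reads, refs)
        exact = sum(
            (a.genome_id, a.contig, a.start0, a.strand) == reads.truth[a.read_id]
            for a in alignments
        )
        assert exact / 20_000 >= 0.999

    def test_competitive_single_assignment(self):
        # two genomes sharing a near-identical core: each read appears once
        g1 = m.generate_genome(30_000, 0.42, 1, seed=64, id="a")
        g2 = m.derive_relative(g1, 0.01, 0.2, seed=65, id="b")
        spec = m.CommunitySpec([(g1, 0.5), (g2, 0.5)], 150, 0.0, seed=66)
        reads = m.simulate_reads(spec, 4000)
        refs = m.build_reference_set([g1, g2])
        alignments = m.recruit_reads(reads, refs)
        ids = [a.read_id for a in alignments]
        assert len(ids) == len(set(ids))

    def test_tie_break_lexicographic_genome(self):
        g1 = m.generate_genome(10_000, 0.42, 1, seed=67, id="zzz")
        g2 = m.GenomeSequence(id="aaa", contigs=[("aaa_c1", g1.contigs[0][1])])
        reads = m.ReadSet(ids=["t"], seqs=[g1.contigs[0][1][100:250]])
        refs = m.build_reference_set([g1, g2])
        (a,) = m.recruit_reads(reads, refs)
        assert a.genome_id == "aaa"

    def test_tie_break_smallest_coordinate(self):
        base = m.generate_genome(20_000, 0.42, 1, seed=68, id="dup")
        seq = base.contigs[0][1]
        segment = seq[500:1000]
        doubled = seq[:5000] + segment + seq[5000:15000] + segment
        g = m.GenomeSequence(id="dup", contigs=[("dup_c1", doubled)])
        reads = m.ReadSet(ids=["t"], seqs=[segment[:150]])
        refs = m.build_reference_set([g])
        (a,) = m.recruit_reads(reads, refs)
        assert a.start0 == min(doubled.find(segment[:150]), 5000)

    def test_deterministic_rerun(self, small_genome):
        spec = m.CommunitySpec([(small_genome, 1.0)], 150, 0.01, seed=69)
        reads = m.simulate_reads(spec, 1000)
        refs = m.build_reference_set([small_genome])
        a1 = m.recruit_reads(reads, refs)
        a2 = m.recruit_reads(reads, refs)
        assert a1 == a2

    def test_short_reads_unassigned_with_warning(self, small_genome, caplog):
        reads = m.ReadSet(ids=["s"], seqs=["ACGTACGT"])
        refs = m.build_reference_set([small_genome])
        with caplog.at_level("WARNING"):
            assert m.recruit_reads(reads, refs) == []
        assert "shorter than k" in caplog.text

    def test_identity_never_below_threshold(self, small_genome):
        spec = m.CommunitySpec([(small_genome, 1.0)], 150, 0.05, seed=70)
        reads = m.simulate_reads(spec, 2000)
        refs = m.build_reference_set([small_genome])
        for a in m.recruit_reads(reads, refs, min_identity=95.0):
            assert a.identity >= 95.0
            assert a.aligned_length == 150

    def test_distant_relative_specificity(self):
        """<5% of an 85%-ANI relative's reads recruited, concentrated in
        its annotated conserved islands."""
        ref = m.generate_genome(300_000, 0.42, 1, seed=71, id="ref")
        rel = m.derive_relative(
            ref, 0.155, 0.0, seed=72, id="rel",
            conserved_fraction=0.03, conserved_rate=0.005,
            n_conserved_islands=10,
        )
        spec = m.CommunitySpec([(rel, 1.0)], 150, 0.002, seed=73)
        reads = m.simulate_reads(spec, 20_000, track_truth=False)
        refs = m.build_reference_set([ref])
        alignments = m.recruit_reads(reads, refs)
        assert len(alignments) / 20_000 < 0.05
        islands = rel.intervals(ROLE_CONSERVED)
        in_island = sum(
            any(a.start0 < e and a.start0 + 150 > s for _, s, e in islands)
            for a in alignments
        )
        assert in_island / len(alignments) >= 0.9


class TestSamInterop:
    def test_round_trip_agrees_with_recruiter(self, small_genome, tmp_path):
        spec = m.CommunitySpec([(small_genome, 1.0)], 150, 0.01, seed=74)
        reads = m.simulate_reads(spec, 1000)
        refs = m.build_reference_set([small_genome])
        alignments = m.recruit_reads(reads, refs)
        sam = tmp_path / "out.sam"
        export_sam(alignments, refs, sam, reads=reads)
        back = import_sam(sam, refs)
        assert len(back) == len(alignments)
        by_id = {a.read_id: a for a in alignments}
        for b in back:
            a = by_id[b.read_id]
            assert (b.genome_id, b.contig, b.start0, b.strand) == (
                a.genome_id, a.contig, a.start0, a.strand,
            )
            assert b.identity == pytest.approx(a.identity)

    def _write_sam(self, path, refs, records):
        gid = refs.genomes[0].id
        cid = refs.genomes[0].contigs[0][0]
        ln = refs.genome_length(gid)
        lines = [
            "@HD\tVN:1.6",
            f"@SQ\tSN:{gid}:{cid}\tLN:{ln}",
        ]
        lines += records
        path.write_text("\n".join(lines) + "\n")

    def test_nm_identity_arithmetic(self, small_genome, tmp_path):
        refs = m.build_reference_set([small_genome])
        gid, cid = small_genome.id, small_genome.contigs[0][0]
        seq = "A" * 150
        sam = tmp_path / "in.sam"
        self._write_sam(
            sam, refs,
            [f"r1\t0\t{gid}:{cid}\t11\t60\t150M\t*\t0\t0\t{seq}\t*\tNM:i:3"],
        )
        (a,) = import_sam(sam, refs)
        assert a.identity == pytest.approx(98.0)
        assert a.start0 == 10  # SAM is 1-based

    def test_unmapped_skipped(self, small_genome, tmp_path):
        refs = m.build_reference_set([small_genome])
        sam = tmp_path / "in.sam"
        self._write_sam(
            sam, refs, ["r1\t4\t*\t0\t0\t*\t*\t0\t0\t" + "A" * 150 + "\t*"]
        )
        assert import_sam(sam, refs) == []

    def test_low_identity_dropped(self, small_genome, tmp_path):
        refs = m.build_reference_set([small_genome])
        gid, cid = small_genome.id, small_genome.contigs[0][0]
        sam = tmp_path / "in.sam"
        self._write_sam(
            sam, refs,
            [f"r1\t0\t{gid}:{cid}\t1\t60\t150M\t*\t0\t0\t{'A' * 150}\t*\tNM:i:10"],
        )
        assert import_sam(sam, refs) == []  # 93.33 < 95

    def test_clipped_dropped_when_full_length_required(
        self, small_genome, tmp_path
    ):
        refs = m.build_reference_set([small_genome])
        gid, cid = small_genome.id, small_genome.contigs[0][0]
        sam = tmp_path / "in.sam"
        self._write_sam(
            sam, refs,
            [f"r1\t0\t{gid}:{cid}\t1\t60\t10S140M\t*\t0\t0\t{'A' * 150}\t*\tNM:i:0"],
        )
        assert import_sam(sam, refs, require_full_length=True) == []
        assert len(import_sam(sam, refs, require_full_length=False)) == 1

    def test_missing_nm_skipped_with_warning(self, small_genome, tmp_path, caplog):
        refs = m.build_reference_set([small_genome])
        gid, cid = small_genome.id, small_genome.contigs[0][0]
        sam = tmp_path / "in.sam"
        self._write_sam(
            sam, refs,
            [f"r1\t0\t{gid}:{cid}\t1\t60\t150M\t*\t0\t0\t{'A' * 150}\t*"],
        )
        with caplog.at_level("WARNING"):
            assert import_sam(sam, refs) == []
        assert "NM" in caplog.text

    def test_unknown_reference_name_error(self, small_genome, tmp_path):
        refs = m.build_reference_set([small_genome])
        sam = tmp_path / "in.sam"
        lines = [
            "@HD\tVN:1.6",
            "@SQ\tSN:mystery\tLN:5000",
            "r1\t0\tmystery\t1\t60\t150M\t*\t0\t0\t" + "A" * 150 + "\t*\tNM:i:0",
        ]
        sam.write_text("\n".join(lines) + "\n")
        with pytest.raises(ValueError, match="resolve"):
            import_sam(sam, refs)
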