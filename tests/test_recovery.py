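"""Read merging, barcode extraction, variant tables, Sanger comparison."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cellver import codec, recovery
from cellver.recovery import AnalyzerConfig, MergedRead, Read

from helpers import rc


def _random_dna(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


def _pair_from_template(template, read_len, quality=30):
    r1 = Read("p", template[:read_len], [quality] * read_len)
    r1.mate = Read("p", rc(template[-read_len:]), [quality] * read_len)
    return r1


class TestMergePairs:
    @given(tlen=st.integers(60, 300), overlap=st.integers(20, 100))
    @settings(max_examples=60, deadline=None)
    def test_error_free_pairs_reconstruct_template(self, tlen, overlap):
        overlap = min(overlap, tlen)
        read_len = (tlen + overlap) // 2
        if read_len > tlen or 2 * read_len - tlen < 20:
            return
        rng = np.random.default_rng(tlen * 1000 + overlap)
        template = _random_dna(rng, tlen)
        merged, unmerged = recovery.merge_pairs([_pair_from_template(template, read_len)])
        assert not unmerged
        assert merged[0].sequence == template
        assert merged[0].overlap_len == 2 * read_len - tlen

    def test_disagreement_resolved_by_quality(self):
        rng = np.random.default_rng(0)
        template = _random_dna(rng, 100)
        read_len = 60
        pair = _pair_from_template(template, read_len)
        # corrupt one overlap base on mate 1, but give mate 2 higher quality
        pos = 50  # inside the 20-nt overlap [40, 60)
        wrong = "A" if pair.sequence[pos] != "A" else "C"
        pair.sequence = pair.sequence[:pos] + wrong + pair.sequence[pos + 1 :]
        pair.quality = [10] * read_len
        pair.mate.quality = [40] * read_len
        merged, _ = recovery.merge_pairs([pair])
        assert merged[0].sequence == template  # Q40 mate-2 base kept
        assert merged[0].disagreements_resolved == 1

    def test_tie_goes_to_mate_one(self):
        rng = np.random.default_rng(1)
        template = _random_dna(rng, 100)
        pair = _pair_from_template(template, 60)
        pos = 50
        wrong = "A" if pair.sequence[pos] != "A" else "C"
        pair.sequence = pair.sequence[:pos] + wrong + pair.sequence[pos + 1 :]
        merged, _ = recovery.merge_pairs([pair])  # equal qualities
        assert merged[0].sequence[pos] == wrong

    def test_unrelated_mates_unmerged(self):
        rng = np.random.default_rng(2)
        r = Read("x", _random_dna(rng, 120), None)
        r.mate = Read("x", _random_dna(rng, 120), None)
        merged, unmerged = recovery.merge_pairs([r])
        assert merged == [] and unmerged == ["x"]

    def test_missing_mate_is_an_error(self):
        with pytest.raises(recovery.AnalysisError):
            recovery.merge_pairs([Read("lonely", "ACGT" * 10)])


class TestLocateBarcode:
    def test_exact_cassette_mid_read(self, default_spec):
        bc = codec.encode(777, default_spec)
        rng = np.random.default_rng(3)
        read = _random_dna(rng, 60) + bc.cassette + _random_dna(rng, 60)
        insert, report = recovery.locate_barcode(read, default_spec)
        assert insert == bc.insert and report["strand"] == "+"

    def test_reverse_strand_cassette(self, default_spec):
        bc = codec.encode(777, default_spec)
        rng = np.random.default_rng(4)
        read = _random_dna(rng, 50) + rc(bc.cassette) + _random_dna(rng, 50)
        insert, report = recovery.locate_barcode(read, default_spec)
        assert insert == bc.insert and report["strand"] == "-"

    def test_flank_mismatch_threshold(self, default_spec):
        bc = codec.encode(777, default_spec)
        cassette = list(bc.cassette)
        for p in (0, 5, 9):  # three substitutions in the 5' flank
            cassette[p] = "A" if cassette[p] != "A" else "C"
        read = "".join(cassette) + "ACGT" * 10
        with pytest.raises(recovery.FlankNotFoundError):
            recovery.locate_barcode(read, default_spec, max_flank_mismatch=2)

    def test_two_tolerated_mismatches(self, default_spec):
        bc = codec.encode(42, default_spec)
        cassette = list(bc.cassette)
        for p in (2, 7):
            cassette[p] = "A" if cassette[p] != "A" else "C"
        insert, report = recovery.locate_barcode("".join(cassette), default_spec)
        assert insert == bc.insert and report["flank_5p_mismatches"] == 2


class TestRecoverCommit:
    def test_clean_reads_full_support(self, store):
        r = store.init_repository("r", "", {"name": "E. coli", "taxon_ref": "562"}, "public")
        c = store.new_commit(r, "main", "alice", "m", request_barcode=True)
        reads = [c.barcode["cassette"]] * 10
        res = recovery.recover_commit(reads, store)
        assert res.best["uid"] == c.uid and res.best["support"] == 10
        assert res.best["in_store"] and not res.ambiguous

    def test_corrupted_read_drops_out(self, store):
        r = store.init_repository("r", "", {"name": "E. coli", "taxon_ref": "562"}, "public")
        c = store.new_commit(r, "main", "alice", "m", request_barcode=True)
        reads = [c.barcode["cassette"]] * 9 + ["ACGT" * 30]
        res = recovery.recover_commit(reads, store)
        assert res.best["support"] == 9 and res.n_failed == 1

    def test_unregistered_barcode_reported(self, store, default_spec):
        foreign = codec.encode(123456, default_spec)
        res = recovery.recover_commit([foreign.cassette] * 3, store)
        assert res.best["in_store"] is False and res.best["support"] == 3

    def test_no_decodable_reads(self, store):
        with pytest.raises(recovery.AnalysisError):
            recovery.recover_commit(["ACGT" * 40], store)


class TestVariantTable:
    REF = "ATCGGCATTACGAGTCAGGCTTACGGATCACGTAGCTTGA"  # 40 nt, non-periodic

    def _mutate(self, seq, pos, alt):
        return seq[:pos] + alt + seq[pos + 1 :]

    def test_identical_reads_no_variants(self):
        vt = recovery.variant_table([self.REF] * 10, self.REF)
        assert vt.read_mutation_fraction == 0.0
        assert vt.called_variants == []
        assert vt.n_reads == 10

    def test_half_mutated_called_at_threshold(self):
        mut = self._mutate(self.REF, 7, "C")
        vt = recovery.variant_table([self.REF] * 5 + [mut] * 5, self.REF)
        assert vt.read_mutation_fraction == 0.5
        assert vt.called_variants == [
            {"position": 8, "ref": self.REF[7], "alt": "C", "frequency": 0.5}
        ]

    def test_forty_percent_not_called(self):
        mut = self._mutate(self.REF, 7, "C")
        vt = recovery.variant_table([self.REF] * 6 + [mut] * 4, self.REF)
        assert vt.read_mutation_fraction == 0.4
        assert vt.called_variants == []

    def test_count_conservation_invariant(self):
        rng = np.random.default_rng(8)
        reads = []
        for _ in range(30):
            seq = self.REF
            if rng.random() < 0.5:
                pos = int(rng.integers(0, len(seq)))
                seq = self._mutate(seq, pos, "ACGT"[int(rng.integers(0, 4))])
            if rng.random() < 0.2:  # deletion
                pos = int(rng.integers(0, len(seq)))
                seq = seq[:pos] + seq[pos + 1 :]
            reads.append(seq)
        vt = recovery.variant_table(reads, self.REF)
        per_pos = sum(vt.counts[b] for b in "ACGT") + vt.counts["del"]
        assert (per_pos == vt.coverage).all()
        assert (vt.coverage <= vt.n_reads).all()

    def test_deletion_counted_per_position(self):
        del_read = self.REF[:10] + self.REF[11:]
        vt = recovery.variant_table([del_read] * 6 + [self.REF] * 4, self.REF)
        # gap placement may shift within a homopolymer, but exactly one
        # reference base is deleted in 6 of 10 reads
        assert vt.counts["del"].sum() == 6
        dels = [v for v in vt.called_variants if v["alt"] == "del"]
        assert len(dels) == 1 and dels[0]["frequency"] == 0.6
        assert vt.read_mutation_fraction == 0.6

    def test_insertion_keyed_after_position(self):
        ins_read = self.REF[:10] + "A" + self.REF[10:]
        vt = recovery.variant_table([ins_read] * 5 + [self.REF] * 5, self.REF)
        assert sum(vt.ins_after.values()) == 5
        assert vt.read_mutation_fraction == 0.5
        # insertions do not consume coverage
        assert (vt.coverage == 10).all()

    def test_frame_layout(self):
        vt = recovery.variant_table([self.REF] * 3, self.REF)
        df = vt.to_frame()
        assert list(df.columns[:2]) == ["position", "ref"]
        assert df.shape[0] == len(self.REF)


class TestSangerVerify:
    REF = "ACGTTGCAACGGTTACGATCGTACGATCGGTA"

    def test_identical(self):
        out = recovery.sanger_verify(self.REF, self.REF)
        assert out["identical"] and out["differences"] == []

    def test_single_deletion_position(self):
        query = self.REF[:12] + self.REF[13:]
        out = recovery.sanger_verify(query, self.REF)
        assert not out["identical"]
        dels = [d for d in out["differences"] if d["type"] == "deletion"]
        assert len(dels) == 1 and dels[0]["position"] in (13, 14)

    def test_reverse_complement_autodetected(self):
        out = recovery.sanger_verify(rc(self.REF), self.REF)
        assert out["identical"] and out["orientation"] == "-"


class TestIO:
    def test_fastq_pairing_round_trip(self, tmp_path):
        from cellver.simulate import write_paired_fastq

        reads = []
        rng = np.random.default_rng(9)
        for i in range(5):
            r = Read(f"r{i}", _random_dna(rng, 50), [30] * 50)
            r.mate = Read(f"r{i}", _random_dna(rng, 50), [25] * 50)
            reads.append(r)
        p1, p2 = write_paired_fastq(reads, tmp_path / "r1.fastq", tmp_path / "r2.fastq.gz")
        rs = recovery.read_paired_fastq(p1, p2)
        assert len(rs) == 5
        assert rs.reads[0].mate is not None
        assert rs.reads[0].quality == [30] * 50 and rs.reads[0].mate.quality == [25] * 50

    def test_unpaired_files_rejected(self, tmp_path):
        from cellver.simulate import write_fastq

        write_fastq([Read("a", "ACGT", [30] * 4)], tmp_path / "r1.fastq")
        write_fastq([Read("b", "ACGT", [30] * 4)], tmp_path / "r2.fastq")
        with pytest.raises(recovery.AnalysisError):
            recovery.read_paired_fastq(tmp_path / "r1.fastq", tmp_path / "r2.fastq")


def test_analyzer_config_threshold_bounds():
    with pytest.raises(ValueError):
        AnalyzerConfig(min_variant_frequency=0.0)
    with pytest.raises(ValueError):
        AnalyzerConfig(min_variant_frequency=1.5)
    assert AnalyzerConfig(min_variant_frequency=1.0).min_variant_frequency == 1.0


def test_merged_read_dataclass_roundtrip():
    m = MergedRead("r", "ACGT", 4, 0)
    vt = recovery.variant_table([m], "ACGT")
    assert vt.n_reads == 1 and vt.read_mutation_fraction == 0.0
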