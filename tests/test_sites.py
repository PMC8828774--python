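"""Insertion-site selection: parsing, curation, gap finding, screening."""

import numpy as np
import pytest

from cellver import sites

from helpers import rc

GFF = """##gff-version 3
##sequence-region chr1 1 2000
chr1\ttest\tgene\t100\t400\t.\t+\t.\tID=geneA;Name=dnaA;Alias=oldA
chr1\ttest\tgene\t500\t900\t.\t-\t.\tID=geneB;Name=dnaN
chr1\ttest\tgene\t1200\t1600\t.\t+\t.\tID=geneC;Name=gyrB
chr1\ttest\tregulatory_region\t430\t450\t.\t+\t.\tID=promX
"""


def _write_fixture(tmp_path, gff_text=GFF, contig_len=2000, newline="\n"):
    rng = np.random.default_rng(99)
    seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, contig_len)])
    fasta = tmp_path / "g.fasta"
    fasta.write_text(f">chr1\n{seq}\n")
    gff = tmp_path / "g.gff3"
    gff.write_bytes(gff_text.replace("\n", newline).encode())
    return gff, fasta, seq


@pytest.fixture
def annotation(tmp_path):
    gff, fasta, _ = _write_fixture(tmp_path)
    return sites.load_annotation(gff, fasta)


def _mini_annotation(genes, contig_len=5000, features=()):
    """Build a GenomeAnnotation directly: genes = (id, start, end, strand)."""
    rng = np.random.default_rng(1)
    seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, contig_len)])
    return sites.GenomeAnnotation(
        contigs={"chr1": seq},
        genes=[
            sites.Gene(g[0], (g[0],), (), "chr1", g[1], g[2], g[3], "gene")
            for g in genes
        ],
        other_features=[
            sites.Gene(f[0], (), (), "chr1", f[1], f[2], "+", "regulatory_region")
            for f in features
        ],
    )


class TestLoadAnnotation:
    def test_fixture_echo(self, annotation):
        assert len(annotation.genes) == 3
        strands = {g.gene_id: g.strand for g in annotation.genes}
        assert strands == {"geneA": "+", "geneB": "-", "geneC": "+"}
        assert [f.gene_id for f in annotation.other_features] == ["promX"]
        assert annotation.genes[0].start == 100 and annotation.genes[0].end == 400

    def test_crlf_equals_lf(self, tmp_path):
        g1, f1, _ = _write_fixture(tmp_path / "a" if (tmp_path / "a").mkdir() or True else None)
        g2, f2, _ = _write_fixture(tmp_path / "b" if (tmp_path / "b").mkdir() or True else None, newline="\r\n")
        a = sites.load_annotation(g1, f1)
        b = sites.load_annotation(g2, f2)
        assert [(g.gene_id, g.start, g.end, g.strand) for g in a.genes] == [
            (g.gene_id, g.start, g.end, g.strand) for g in b.genes
        ]

    def test_feature_beyond_contig(self, tmp_path):
        bad = GFF + "chr1\ttest\tgene\t1900\t2100\t.\t+\t.\tID=geneD\n"
        gff, fasta, _ = _write_fixture(tmp_path, gff_text=bad)
        with pytest.raises(sites.AnnotationError, match="geneD"):
            sites.load_annotation(gff, fasta)

    def test_unknown_contig(self, tmp_path):
        bad = GFF + "chr9\ttest\tgene\t10\t20\t.\t+\t.\tID=geneX\n"
        gff, fasta, _ = _write_fixture(tmp_path, gff_text=bad)
        with pytest.raises(sites.AnnotationError, match="chr9"):
            sites.load_annotation(gff, fasta)


class TestNormalizeNames:
    def test_case_insensitive_match(self, annotation):
        ess = sites.normalize_names(annotation, ["DNAA", "dnan"])
        assert ess.normalized == {"geneA", "geneB"}
        assert ess.mapping_report == {"DNAA": "geneA", "dnan": "geneB"}

    def test_synonym_and_id_match(self, annotation):
        ess = sites.normalize_names(annotation, ["oldA", "geneC"])
        assert ess.normalized == {"geneA", "geneC"}

    def test_unmatched_reported(self, annotation):
        ess = sites.normalize_names(annotation, ["notAGene"])
        assert ess.normalized == set()
        assert ess.mapping_report["notAGene"] == "unmatched"

    def test_ambiguous_excluded(self):
        ann = _mini_annotation([("g1", 100, 200, "+"), ("g2", 300, 400, "+")])
        ann.genes[0] = sites.Gene("g1", ("shared",), (), "chr1", 100, 200, "+", "gene")
        ann.genes[1] = sites.Gene("g2", ("shared",), (), "chr1", 300, 400, "+", "gene")
        ess = sites.normalize_names(ann, ["shared"])
        assert ess.mapping_report["shared"] == "ambiguous"
        assert ess.normalized == set()


class TestAdjacentPairs:
    def test_hand_enumerated_example(self):
        ann = _mini_annotation([("E1", 100, 400, "+"), ("E2", 500, 900, "-")])
        out = sites.find_adjacent_essential_pairs(ann, {"E1", "E2"}, min_len=50, max_len=1000)
        assert len(out) == 1
        s = out[0]
        assert (s.start, s.end, s.length) == (401, 499, 99)
        assert s.orientations == ("+", "-")
        assert s.sequence == ann.contigs["chr1"][400:499]

    def test_nonessential_neighbor_gives_nothing(self):
        ann = _mini_annotation([("E1", 100, 400, "+"), ("N1", 500, 900, "+")])
        assert sites.find_adjacent_essential_pairs(ann, {"E1"}) == []

    def test_overlapping_essentials_give_nothing(self):
        ann = _mini_annotation([("E1", 100, 400, "+"), ("E2", 390, 900, "+")])
        assert sites.find_adjacent_essential_pairs(ann, {"E1", "E2"}) == []

    def test_nested_gene_blocks_gap(self):
        # a third gene inside the would-be gap invalidates it
        ann = _mini_annotation(
            [("E1", 100, 400, "+"), ("N1", 420, 440, "+"), ("E2", 600, 900, "+")]
        )
        assert sites.find_adjacent_essential_pairs(ann, {"E1", "E2"}) == []


class TestClusters:
    def test_single_intervening_gene(self):
        ann = _mini_annotation(
            [("E1", 100, 400, "+"), ("N1", 500, 700, "+"), ("E2", 800, 1100, "-")]
        )
        out = sites.find_essential_clusters(ann, {"E1", "E2"}, max_intervening=1)
        intervals = {(s.start, s.end) for s in out}
        assert intervals == {(401, 499), (701, 799)}
        assert all(s.intervening_nonessential == 1 for s in out)
        assert all((s.left_gene, s.right_gene) == ("E1", "E2") for s in out)

    def test_zero_intervening_reduces_to_adjacency(self):
        ann = _mini_annotation(
            [("E1", 100, 400, "+"), ("N1", 500, 700, "+"), ("E2", 800, 1100, "-")]
        )
        assert sites.find_essential_clusters(ann, {"E1", "E2"}, max_intervening=0) == []

    def test_cluster_bound_exceeded(self):
        ann = _mini_annotation(
            [
                ("E1", 100, 400, "+"),
                ("N1", 500, 700, "+"),
                ("N2", 800, 1000, "+"),
                ("E2", 1100, 1400, "+"),
            ]
        )
        assert sites.find_essential_clusters(ann, {"E1", "E2"}, max_intervening=1) == []


class TestConservation:
    def test_exact_presence(self):
        ann = _mini_annotation([("E1", 100, 400, "+"), ("E2", 500, 900, "+")])
        [site] = sites.find_adjacent_essential_pairs(ann, {"E1", "E2"})
        genome = "T" * 300 + site.sequence + "G" * 300
        res = sites.check_conservation(site, {"labstrain": genome})
        assert res["labstrain"]["present"] and res["labstrain"]["identity"] == 1.0

    def test_reverse_strand_presence(self):
        ann = _mini_annotation([("E1", 100, 400, "+"), ("E2", 500, 900, "+")])
        [site] = sites.find_adjacent_essential_pairs(ann, {"E1", "E2"})
        genome = "T" * 200 + rc(site.sequence) + "G" * 200
        assert sites.check_conservation(site, {"s": genome})["s"]["present"]

    def test_absent_in_random_genome(self):
        ann = _mini_annotation([("E1", 100, 400, "+"), ("E2", 500, 900, "+")])
        [site] = sites.find_adjacent_essential_pairs(ann, {"E1", "E2"})
        rng = np.random.default_rng(5)
        genome = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 20000)])
        assert not sites.check_conservation(site, {"rand": genome})["rand"]["present"]

    def test_divergent_copy_identity(self):
        """Planted copy with 5% substitutions: present, identity about 0.95."""
        ann = _mini_annotation([("E1", 100, 400, "+"), ("E2", 500, 900, "+")])
        [site] = sites.find_adjacent_essential_pairs(ann, {"E1", "E2"})
        rng = np.random.default_rng(6)
        mutated = list(site.sequence)
        n_sub = max(1, int(0.05 * len(mutated)))
        for pos in rng.choice(len(mutated), size=n_sub, replace=False):
            mutated[pos] = {"A": "G", "C": "T", "G": "A", "T": "C"}[mutated[pos]]
        genome = "T" * 100 + "".join(mutated) + "A" * 100
        res = sites.check_conservation(site, {"div": genome})["div"]
        expected_id = 1 - n_sub / len(mutated)
        assert res["present"] and abs(res["identity"] - expected_id) < 0.02

    def test_too_short_inputs(self):
        ann = _mini_annotation([("E1", 100, 400, "+"), ("E2", 500, 900, "+")])
        [site] = sites.find_adjacent_essential_pairs(ann, {"E1", "E2"})
        with pytest.raises(ValueError):
            sites.check_conservation(site, {"tiny": "ACGT"})


class TestFeatureOverlap:
    @pytest.mark.parametrize(
        "fstart,fend,expected",
        [
            (420, 440, True),   # fully inside the gap [401, 499]
            (380, 400, False),  # abuts (ends at start-1): closed intervals
            (499, 520, True),   # 1-nt overlap
            (500, 520, False),  # just outside
        ],
    )
    def test_closed_interval_semantics(self, fstart, fend, expected):
        ann = _mini_annotation(
            [("E1", 100, 400, "+"), ("E2", 500, 900, "+")],
            features=[("feat", fstart, fend)],
        )
        [site] = sites.find_adjacent_essential_pairs(ann, {"E1", "E2"})
        sites.flag_feature_overlap(site, ann.other_features)
        assert site.overlaps_feature is expected


class TestRanking:
    def _sites(self):
        ann = _mini_annotation(
            [
                ("E1", 100, 400, "+"),
                ("E2", 600, 900, "+"),
                ("E3", 1100, 1400, "+"),
                ("E4", 1600, 1900, "+"),
            ]
        )
        return sites.find_adjacent_essential_pairs(ann, {"E1", "E2", "E3", "E4"})

    def test_unflagged_ranks_above_flagged(self):
        out = self._sites()
        out[0].overlaps_feature = True
        ranked = sites.rank_candidates(out)
        assert ranked[-1].overlaps_feature and not ranked[0].overlaps_feature

    def test_ties_break_by_coordinate(self):
        out = self._sites()  # all gaps identical length, nothing flagged
        ranked = sites.rank_candidates(out)
        assert [s.start for s in ranked] == sorted(s.start for s in ranked)

    def test_ranking_is_permutation(self):
        out = self._sites()
        ranked = sites.rank_candidates(out)
        assert sorted((s.start, s.end) for s in ranked) == sorted(
            (s.start, s.end) for s in out
        )


class TestCassetteDesign:
    def test_arms_are_genome_substrings(self):
        ann = _mini_annotation([("E1", 100, 400, "+"), ("E2", 500, 900, "+")])
        [site] = sites.find_adjacent_essential_pairs(ann, {"E1", "E2"})
        design = sites.design_cassette(site, "ACGT" * 10, ann, arm_len=40)
        contig = ann.contigs["chr1"]
        assert design.arm_5p in contig and design.arm_3p in contig
        p = design.insertion_point
        assert contig[p - 40 : p] == design.arm_5p
        assert contig[p : p + 40] == design.arm_3p

    def test_default_midpoint(self):
        ann = _mini_annotation([("E1", 100, 400, "+"), ("E2", 500, 900, "+")])
        [site] = sites.find_adjacent_essential_pairs(ann, {"E1", "E2"})
        design = sites.design_cassette(site, "ACGT", ann)
        assert design.insertion_point == site.start + (site.length + 1) // 2 - 1

    def test_assembled_length_additivity(self):
        ann = _mini_annotation([("E1", 100, 400, "+"), ("E2", 500, 900, "+")])
        [site] = sites.find_adjacent_essential_pairs(ann, {"E1", "E2"})
        design = sites.design_cassette(site, "ACGTACGT", ann, arm_len=25)
        assert len(design.assembled) == 2 * 25 + 8

    def test_arm_off_contig_end(self):
        ann = _mini_annotation([("E1", 10, 60, "+"), ("E2", 120, 180, "+")], contig_len=200)
        [site] = sites.find_adjacent_essential_pairs(ann, {"E1", "E2"}, min_len=10)
        with pytest.raises(ValueError, match="contig"):
            sites.design_cassette(site, "ACGT", ann, arm_len=150)


def test_reports_roundtrip():
    ann = _mini_annotation([("E1", 100, 400, "+"), ("E2", 500, 900, "+")])
    found = sites.find_adjacent_essential_pairs(ann, {"E1", "E2"})
    df = sites.sites_to_table(found)
    assert list(df["start"]) == [401] and list(df["length"]) == [99]
    bed = sites.sites_to_bed(found)
    assert bed == "chr1\t400\t499\tE1|E2\t0\t+\n"
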