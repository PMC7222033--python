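import itertools
import random

import pytest

from gffkit.model import Gene, GenomicInterval
from gffkit.transform import (FilterSpec, cluster_loci, filter_transcripts,
                              force_exons, gene_to_exon, is_pseudogene,
                              merge_close_exons, remove_redundant, to_table,
                              transcripts_match)

from conftest import make_set, make_tx, random_annotation_set


class TestFilters:
    def test_empty_spec_is_identity(self, fixture_set):
        out = filter_transcripts(fixture_set.reference, FilterSpec())
        assert set(out.transcripts) == set(fixture_set.reference.transcripts)

    def test_min_len_uses_spliced_length(self):
        s = make_set(
            make_tx("a", "c", "+", [(1, 150)]),                 # 150
            make_tx("b", "c", "+", [(1, 200), (301, 500)]),     # 400
            make_tx("d", "c", "+", [(1000, 1089)]),             # 90
        )
        out = filter_transcripts(s, FilterSpec(min_len=100))
        assert set(out.transcripts) == {"a", "b"}

    def test_max_intron(self):
        t = make_tx("a", "c", "+", [(1, 100), (1001, 1100), (62001, 62100)])
        # introns: 900 and 60900
        out = filter_transcripts(make_set(t), FilterSpec(max_intron=50000))
        assert len(out) == 0
        out = filter_transcripts(make_set(t), FilterSpec(max_intron=61000))
        assert len(out) == 1

    def test_range_containment_vs_overlap(self):
        spanning = make_tx("a", "chr1", "+", [(900, 1500)])
        inside = make_tx("b", "chr1", "+", [(1100, 1900)])
        s = make_set(spanning, inside)
        contained = filter_transcripts(
            s, FilterSpec(range=("chr1", 1000, 2000), range_contained=True))
        assert set(contained.transcripts) == {"b"}
        overlapping = filter_transcripts(
            s, FilterSpec(range=("chr1", 1000, 2000)))
        assert set(overlapping.transcripts) == {"a", "b"}

    def test_strand_qualified_range(self):
        s = make_set(make_tx("a", "chr1", "+", [(100, 200)]),
                     make_tx("b", "chr1", "-", [(100, 200)]))
        out = filter_transcripts(
            s, FilterSpec(range=("chr1", 1, 500, "-")))
        assert set(out.transcripts) == {"b"}

    def test_single_exon_and_coding_filters(self):
        s = make_set(
            make_tx("se", "c", "+", [(1, 100)]),
            make_tx("me", "c", "+", [(1, 100), (201, 300)],
                    cds=[(10, 90)]),
        )
        assert set(filter_transcripts(
            s, FilterSpec(drop_single_exon=True)).transcripts) == {"me"}
        assert set(filter_transcripts(
            s, FilterSpec(coding_only=True)).transcripts) == {"me"}
        assert set(filter_transcripts(
            s, FilterSpec(noncoding_only=True)).transcripts) == {"se"}

    def test_coding_and_noncoding_mutually_exclusive(self):
        with pytest.raises(ValueError):
            FilterSpec(coding_only=True, noncoding_only=True)

    def test_genome_requiring_flag_without_genome(self):
        s = make_set(make_tx("a", "c", "+", [(1, 100)]))
        with pytest.raises(ValueError):
            filter_transcripts(s, FilterSpec(drop_inframe_stop=True))


class TestPseudogene:
    def test_feature_type(self):
        t = make_tx("a", "c", "+", [(1, 100)], feature_type="pseudogene")
        assert is_pseudogene(t)

    @pytest.mark.parametrize("key", ["biotype", "gene_biotype",
                                     "transcript_type"])
    def test_biotype_attributes(self, key):
        t = make_tx("a", "c", "+", [(1, 100)])
        t.attributes[key] = "processed_pseudogene"
        assert is_pseudogene(t)

    def test_pseudo_true_attribute(self):
        t = make_tx("a", "c", "+", [(1, 100)])
        t.attributes["pseudo"] = "true"
        assert is_pseudogene(t)

    def test_parent_gene_evidence(self):
        t = make_tx("a", "c", "+", [(1, 100)])
        g = Gene(id="g", attributes={"gene_biotype": "pseudogene"})
        assert is_pseudogene(t, g)

    def test_plain_mrna_is_not(self):
        assert not is_pseudogene(make_tx("a", "c", "+", [(1, 100)]))


class TestClusterLoci:
    def test_chained_overlap(self):
        s = make_set(make_tx("A", "c", "+", [(100, 200)]),
                     make_tx("B", "c", "+", [(150, 250)]),
                     make_tx("C", "c", "+", [(300, 400)]))
        loci = cluster_loci(s)
        groups = sorted(sorted(l.transcript_ids) for l in loci)
        assert groups == [["A", "B"], ["C"]]

    def test_strand_separates(self):
        s = make_set(make_tx("A", "c", "+", [(100, 200)]),
                     make_tx("B", "c", "-", [(150, 250)]))
        assert len(cluster_loci(s)) == 2

    def test_transitive_closure(self):
        s = make_set(make_tx("A", "c", "+", [(100, 200)]),
                     make_tx("B", "c", "+", [(190, 300)]),
                     make_tx("C", "c", "+", [(290, 400)]))
        loci = cluster_loci(s)
        assert len(loci) == 1
        assert sorted(loci[0].transcript_ids) == ["A", "B", "C"]

    def test_span_overlap_without_exon_overlap_does_not_join(self):
        # B sits inside A's intron: spans overlap, exons do not
        s = make_set(make_tx("A", "c", "+", [(100, 200), (500, 600)]),
                     make_tx("B", "c", "+", [(300, 400)]))
        assert len(cluster_loci(s)) == 2

    def test_partition_property(self, fixture_set):
        loci = cluster_loci(fixture_set.queries[0])
        ids = list(itertools.chain.from_iterable(
            l.transcript_ids for l in loci))
        assert sorted(ids) == sorted(fixture_set.queries[0].transcripts)

    def test_matches_brute_force_components(self):
        rng = random.Random(31)
        s = random_annotation_set(rng, n=120, span=20_000)
        loci = cluster_loci(s)
        # brute-force union-find over the full pairwise matrix
        txs = list(s)
        parent = {t.id: t.id for t in txs}

        def find(x):
            while parent[x] != x:
                x = parent[x]
            return x

        for a, b in itertools.combinations(txs, 2):
            if a.seqid == b.seqid and a.strand == b.strand \
                    and a.exonic_overlap(b) > 0:
                parent[find(a.id)] = find(b.id)
        expected = {}
        for t in txs:
            expected.setdefault(find(t.id), set()).add(t.id)
        got = {frozenset(l.transcript_ids) for l in loci}
        assert got == {frozenset(v) for v in expected.values()}


class TestTranscriptsMatch:
    def test_intron_chain_identity_ignores_ends(self):
        a = make_tx("a", "c", "+", [(100, 200), (300, 500)])
        b = make_tx("b", "c", "+", [(150, 200), (300, 560)])
        assert transcripts_match(a, b)

    def test_single_exon_eighty_percent_rule(self):
        a = make_tx("a", "c", "+", [(100, 200)])   # len 101
        b = make_tx("b", "c", "+", [(120, 220)])   # overlap 81
        assert transcripts_match(a, b)  # 81/101 > 0.8
        c = make_tx("c2", "c", "+", [(125, 225)])  # overlap 76
        assert not transcripts_match(a, c)

    def test_different_introns_do_not_match(self):
        a = make_tx("a", "c", "+", [(100, 200), (300, 500)])
        b = make_tx("b", "c", "+", [(100, 200), (301, 500)])
        assert not transcripts_match(a, b)

    def test_single_vs_multi_never_match(self):
        a = make_tx("a", "c", "+", [(100, 500)])
        b = make_tx("b", "c", "+", [(100, 200), (300, 500)])
        assert not transcripts_match(a, b)


class TestRemoveRedundant:
    def _contained_pair(self):
        return (make_tx("big", "c", "+", [(100, 200), (300, 900)]),
                make_tx("small", "c", "+", [(150, 200), (300, 700)]))

    def test_merge_discards_contained_duplicate(self):
        big, small = self._contained_pair()
        out = remove_redundant(make_set(big, small), "merge")
        assert set(out.transcripts) == {"big"}

    def test_contain_mode_subchain(self):
        big = make_tx("big", "c", "+",
                      [(100, 200), (300, 400), (500, 600), (700, 800)])
        small = make_tx("small", "c", "+", [(350, 400), (500, 560)])
        assert set(remove_redundant(make_set(big, small),
                                    "merge").transcripts) == {"big", "small"}
        assert set(remove_redundant(make_set(big, small),
                                    "contain").transcripts) == {"big"}

    def test_relaxed_drops_containment_requirement(self):
        big = make_tx("big", "c", "+",
                      [(100, 200), (300, 400), (500, 600), (700, 800)])
        protruding = make_tx("small", "c", "+", [(350, 400), (500, 850)])
        assert set(remove_redundant(make_set(big, protruding),
                                    "contain").transcripts) == {"big", "small"}
        assert set(remove_redundant(make_set(big, protruding),
                                    "relaxed").transcripts) == {"big"}

    def test_idempotent(self):
        rng = random.Random(17)
        s = random_annotation_set(rng, n=60, span=8000)
        for mode in ("merge", "contain", "relaxed"):
            once = remove_redundant(s, mode)
            twice = remove_redundant(once, mode)
            assert set(once.transcripts) == set(twice.transcripts)


class TestCloseExonMerge:
    def test_fuses_below_threshold(self):
        t = make_tx("t", "c", "+", [(100, 200), (204, 300)])  # intron len 3
        m = merge_close_exons(t)
        assert [(e.start, e.end) for e in m.exons] == [(100, 300)]

    def test_keeps_at_threshold(self):
        t = make_tx("t", "c", "+", [(100, 200), (205, 300)])  # intron len 4
        assert merge_close_exons(t) is t

    def test_single_exon_identity(self):
        t = make_tx("t", "c", "+", [(100, 300)])
        assert merge_close_exons(t) is t

    def test_iterative_left_to_right(self):
        t = make_tx("t", "c", "+", [(100, 200), (203, 300), (303, 400)])
        m = merge_close_exons(t)
        assert [(e.start, e.end) for e in m.exons] == [(100, 400)]


class TestReshaping:
    def test_force_exons_from_cds(self):
        t = make_tx("t", "c", "+", [], cds=[(100, 200), (300, 400)])
        out = force_exons(t)
        assert [(e.start, e.end) for e in out.exons] \
            == [(100, 200), (300, 400)]

    def test_force_exons_identity_when_present(self):
        t = make_tx("t", "c", "+", [(100, 400)])
        assert force_exons(t) is t

    def test_gene_to_exon(self):
        g = Gene(id="g", interval=GenomicInterval("c", 500, 900, "+"))
        t = gene_to_exon(g)
        assert t.num_exons == 1 and (t.start, t.end) == (500, 900)


class TestRenameSeqids:
    def test_mapping_applied_and_unlisted_kept(self):
        from gffkit.transform import rename_seqids
        s = make_set(make_tx("a", "chr1", "+", [(1, 10)]),
                     make_tx("b", "chrUn", "+", [(1, 10)]))
        out = rename_seqids(s, {"chr1": "1"})
        assert out.transcripts["a"].seqid == "1"
        assert out.transcripts["b"].seqid == "chrUn"


class TestTable:
    def test_pseudo_attributes(self):
        t = make_tx("t1", "chr1", "-", [(100, 200), (300, 500)],
                    cds=[(150, 200), (300, 350)])
        rows = to_table(make_set(t), ["@id", "@numexons", "@covlen",
                                      "@strand", "@exons", "@cdslen"])
        assert rows == [["t1", "2", "302", "-", "100-200,300-500", "102"]]

    def test_missing_attribute_renders_dot(self):
        t = make_tx("t1", "chr1", "+", [(1, 10)])
        assert to_table(make_set(t), ["nope"]) == [["."]]
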