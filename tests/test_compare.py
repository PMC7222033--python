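import itertools
import random

from gffkit import fixtures as fx
from gffkit.compare import (CompareOptions, compute_stats, dedup_queries,
                            merge_samples, render_stats, _sample_cell,
                            refmap_rows, tmap_rows, write_tracking)

from conftest import distinct_structure_set, make_set, make_tx


# ---------------------------------------------------------------------------
# brute-force six-level oracle, written from first principles

def oracle_stats(query, ref, tol=100, se=0.8):
    out = {}
    # base: per-position sets, strand-aware
    qb = {(t.seqid, t.strand, p) for t in query for e in t.exons
          for p in range(e.start, e.end + 1)}
    rb = {(t.seqid, t.strand, p) for t in ref for e in t.exons
          for p in range(e.start, e.end + 1)}
    out["base"] = (len(qb & rb), len(qb - rb), len(rb - qb))

    # exon: unique intervals with free outer edges of terminal exons
    def uniq_exons(s):
        d = {}
        for t in s:
            for i, e in enumerate(t.exons):
                k = (t.seqid, t.strand, e.start, e.end)
                f = d.setdefault(k, [False, False])
                f[0] |= i == 0
                f[1] |= i == t.num_exons - 1
        return d

    qe, re_ = uniq_exons(query), uniq_exons(ref)

    def exon_match(qk, qf, rk, rf):
        if qk[:2] != rk[:2]:
            return False
        s_ok = qk[2] == rk[2] or (qf[0] and rf[0] and abs(qk[2] - rk[2]) <= tol)
        e_ok = qk[3] == rk[3] or (qf[1] and rf[1] and abs(qk[3] - rk[3]) <= tol)
        return s_ok and e_ok

    mq = sum(1 for qk, qf in qe.items()
             if any(exon_match(qk, qf, rk, rf) for rk, rf in re_.items()))
    mr = sum(1 for rk, rf in re_.items()
             if any(exon_match(qk, qf, rk, rf) for qk, qf in qe.items()))
    out["exon"] = (mq, len(qe) - mq, len(re_) - mr)

    # intron: exact interval identity
    qi = {(t.seqid, t.strand, s, e) for t in query for s, e in t.introns()}
    ri = {(t.seqid, t.strand, s, e) for t in ref for s, e in t.introns()}
    out["intron"] = (len(qi & ri), len(qi - ri), len(ri - qi))

    # intron chain (multi-exon transcripts only)
    qc = [(t.seqid, t.strand, t.intron_chain()) for t in query
          if t.num_exons > 1]
    rc = [(t.seqid, t.strand, t.intron_chain()) for t in ref
          if t.num_exons > 1]
    tp = sum(1 for c in qc if c in set(rc))
    fn = sum(1 for c in rc if c not in set(qc))
    out["intron_chain"] = (tp, len(qc) - tp, fn)

    # transcript
    def tx_match(q, r):
        if q.seqid != r.seqid or q.strand != r.strand:
            return False
        if q.num_exons > 1 and r.num_exons > 1:
            return (q.intron_chain() == r.intron_chain()
                    and abs(q.start - r.start) <= tol
                    and abs(q.end - r.end) <= tol)
        if q.num_exons == 1 and r.num_exons == 1:
            ov = q.exonic_overlap(r)
            return ov > se * max(q.exonic_length, r.exonic_length)
        return False

    tp = sum(1 for q in query if any(tx_match(q, r) for r in ref))
    fn = sum(1 for r in ref if not any(tx_match(q, r) for q in query))
    out["transcript"] = (tp, len(list(query)) - tp, fn)

    # locus: connected components of same-strand exon overlap per side
    def loci(s):
        ts = list(s)
        parent = {t.id: t.id for t in ts}

        def find(x):
            while parent[x] != x:
                x = parent[x]
            return x

        for a, b in itertools.combinations(ts, 2):
            if a.seqid == b.seqid and a.strand == b.strand \
                    and a.exonic_overlap(b) > 0:
                parent[find(a.id)] = find(b.id)
        groups = {}
        for t in ts:
            groups.setdefault(find(t.id), []).append(t)
        return list(groups.values())

    q_loci, r_loci = loci(query), loci(ref)
    m_q = sum(1 for g in q_loci
              if any(tx_match(q, r) for q in g for r in ref))
    m_r = sum(1 for g in r_loci
              if any(tx_match(q, r) for r in g for q in query))
    out["locus"] = (m_q, len(q_loci) - m_q, len(r_loci) - m_r)
    return out


class TestComputeStats:
    def test_self_comparison_is_perfect(self, fixture_set):
        rep = compute_stats([fixture_set.reference], fixture_set.reference)
        for lvl, st in rep.samples[0].levels.items():
            assert st.sensitivity == 1.0, lvl
            assert st.precision == 1.0, lvl

    def test_terminal_end_slack_at_exon_level(self):
        ref = make_set(make_tx("r", "c", "+", [(100, 200), (300, 400)]))
        q = make_set(make_tx("q", "c", "+", [(150, 200), (300, 350)]))
        rep = compute_stats([q], ref)
        st = rep.samples[0].levels
        assert st["intron"].sensitivity == 1.0
        assert st["intron"].precision == 1.0
        assert st["exon"].sensitivity == 1.0  # free ends within 100
        assert st["exon"].precision == 1.0

    def test_locus_level_partial(self):
        ref = make_set(make_tx("r1", "c", "+", [(100, 200), (300, 400)]),
                       make_tx("r2", "c", "+", [(5000, 5200), (5400, 5600)]))
        q = make_set(make_tx("q1", "c", "+", [(100, 200), (300, 400)]))
        st = compute_stats([q], ref).samples[0].levels["locus"]
        assert st.sensitivity == 0.5
        assert st.precision == 1.0

    def test_matches_brute_force_oracle(self):
        for seed in (3, 7, 13):
            rng = random.Random(seed)
            ref = distinct_structure_set(rng, n_multi=10, n_single=3)
            query = distinct_structure_set(rng, n_multi=10, n_single=3)
            rep = compute_stats([query], ref,
                                CompareOptions(close_exon_merge=False))
            exp = oracle_stats(query, ref)
            for lvl in ("base", "intron", "intron_chain", "transcript"):
                st = rep.samples[0].levels[lvl]
                assert (st.tp, st.fp, st.fn) == exp[lvl], (seed, lvl)
            st = rep.samples[0].levels["exon"]
            e_tp, e_fp, e_fn = exp["exon"]
            assert (st.tp, st.fp) == (e_tp, e_fp), (seed, "exon")
            assert st.fn == e_fn, (seed, "exon fn")
            st = rep.samples[0].levels["locus"]
            l_tp, l_fp, l_fn = exp["locus"]
            assert (st.tp, st.fp, st.fn) == (l_tp, l_fp, l_fn), (seed, "locus")

    def test_unmatched_query_cannot_raise_precision(self, fixture_set):
        ref = fixture_set.reference
        q = fixture_set.queries[0]
        before = compute_stats([q], ref).samples[0]
        extra = q.subset(list(q.transcripts))
        far = max(t.end for t in q) + 50_000
        extra.add(make_tx("noise", "chr1", "+", [(far, far + 500)]))
        after = compute_stats([extra], ref).samples[0]
        for lvl in before.levels:
            assert after.levels[lvl].precision <= before.levels[lvl].precision

    def test_restrict_ref_never_decreases_sensitivity(self, fixture_set):
        ref, q = fixture_set.reference, fixture_set.queries[0]
        plain = compute_stats([q], ref).samples[0]
        restricted = compute_stats([q], ref,
                                   CompareOptions(restrict_ref=True)
                                   ).samples[0]
        for lvl in plain.levels:
            assert restricted.levels[lvl].sensitivity \
                >= plain.levels[lvl].sensitivity

    def test_restrict_query_never_decreases_precision(self, fixture_set):
        ref, q = fixture_set.reference, fixture_set.queries[0]
        plain = compute_stats([q], ref).samples[0]
        restricted = compute_stats([q], ref,
                                   CompareOptions(restrict_query=True)
                                   ).samples[0]
        for lvl in plain.levels:
            assert restricted.levels[lvl].precision \
                >= plain.levels[lvl].precision

    def test_ignore_single_exon(self):
        ref = make_set(make_tx("r1", "c", "+", [(100, 200), (300, 400)]),
                       make_tx("r2", "c", "+", [(5000, 5200)]))
        q = make_set(make_tx("q1", "c", "+", [(100, 200), (300, 400)]))
        st = compute_stats([q], ref, CompareOptions(ignore_single_exon=True))
        assert st.samples[0].levels["transcript"].sensitivity == 1.0

    def test_render_stats_mentions_all_levels(self, fixture_set):
        rep = compute_stats([fixture_set.queries[0]], fixture_set.reference)
        text = render_stats(rep, ["q1"])
        for word in ("base", "exon", "intron", "intron chain", "transcript",
                     "locus", "Missed", "Novel"):
            assert word in text


class TestDedup:
    def test_contained_duplicate_removed_in_both_modes(self):
        a = make_tx("a", "c", "+", [(100, 200), (300, 900)])
        b = make_tx("b", "c", "+", [(150, 200), (300, 800)])
        for mode in ("D", "S"):
            out = dedup_queries(make_set(a, b), mode)
            assert set(out.transcripts) == {"a"}, mode

    def test_staggered_duplicates_only_removed_by_d(self):
        a = make_tx("a", "c", "+", [(100, 200), (300, 800)])
        b = make_tx("b", "c", "+", [(150, 200), (300, 900)])
        assert len(dedup_queries(make_set(a, b), "D")) == 1
        assert len(dedup_queries(make_set(a, b), "S")) == 2

    def test_distinct_chains_untouched(self):
        a = make_tx("a", "c", "+", [(100, 200), (300, 800)])
        b = make_tx("b", "c", "+", [(100, 200), (301, 800)])
        assert len(dedup_queries(make_set(a, b), "D")) == 2


class TestMergeSamples:
    def _samples(self):
        s1 = make_set(make_tx("s1t", "c", "+", [(100, 200), (300, 400)],
                              gene_id="g1"))
        s2 = make_set(make_tx("s2t", "c", "+", [(120, 200), (300, 450)],
                              gene_id="g2"))
        return [s1, s2]

    def test_equivalent_transfrags_collapse(self):
        combined, rows = merge_samples(self._samples())
        assert len(combined) == 1
        assert len(rows) == 1
        assert rows[0].cells[0].startswith("q1:") \
            and rows[0].cells[1].startswith("q2:")

    def test_no_duplicate_chains_in_output(self, fixture_set):
        qs = [fixture_set.queries[0], fixture_set.queries[0]]
        combined, _ = merge_samples(qs)
        seen = set()
        for t in combined:
            if t.num_exons > 1:
                key = (t.seqid, t.strand, t.intron_chain())
                assert key not in seen
                seen.add(key)

    def test_contained_collapsing_modes(self):
        big = make_tx("big", "c", "+",
                      [(100, 200), (300, 400), (500, 600), (700, 800)],
                      gene_id="g")
        # starts mid-container (different 5' exon): A exempts it
        small = make_tx("small", "c", "+", [(350, 400), (500, 560)],
                        gene_id="g")
        samples = [make_set(big), make_set(small)]
        for mode, n in (("union", 2), ("C", 1), ("A", 2), ("X", 1)):
            combined, _ = merge_samples(samples, mode=mode)
            assert len(combined) == n, mode

    def test_alternate_tss_exempt_in_a_mode(self):
        big = make_tx("big", "c", "+",
                      [(100, 200), (300, 400), (500, 600), (700, 800)])
        # contained, chain = middle intron only, 5' exon differs
        alt = make_tx("alt", "c", "+", [(330, 400), (500, 580)])
        samples = [make_set(big), make_set(alt)]
        c, _ = merge_samples(samples, mode="C")
        assert len(c) == 1
        a, _ = merge_samples(samples, mode="A")
        assert len(a) == 2  # alt's chain starts mid-container: alternate TSS
        # a transfrag sharing the 5'-most intron is discarded by A
        shared5 = make_tx("sh5", "c", "+", [(150, 200), (300, 380)])
        a2, _ = merge_samples([make_set(big), make_set(shared5)], mode="A")
        assert len(a2) == 1

    def test_protruding_ends_only_discarded_by_x(self):
        big = make_tx("big", "c", "+",
                      [(100, 200), (300, 400), (500, 600), (700, 800)])
        # contained in span but start pokes into the container's first intron
        poking = make_tx("poke", "c", "+", [(250, 400), (500, 560)])
        samples = [make_set(big), make_set(poking)]
        c, _ = merge_samples(samples, mode="C")
        assert len(c) == 2
        x, _ = merge_samples(samples, mode="X")
        assert len(x) == 1

    def test_keep_ref_matches_protects(self):
        big = make_tx("big", "c", "+",
                      [(100, 200), (300, 400), (500, 600), (700, 800)])
        small = make_tx("small", "c", "+", [(350, 400), (500, 560)])
        ref = make_set(make_tx("R", "c", "+", [(350, 400), (500, 560)]))
        with_k, _ = merge_samples([make_set(big), make_set(small)], ref,
                                  mode="C", keep_ref_matches=True)
        assert len(with_k) == 2

    def test_tcons_numbering_format(self):
        combined, rows = merge_samples(self._samples())
        assert rows[0].tcons_id == "TCONS_00000001"
        assert rows[0].xloc_id == "XLOC_000001"


class TestReportFormats:
    def test_tracking_cell_byte_format(self):
        exons = [(i * 300, i * 300 + 276) for i in range(1, 10)]  # 9 x 277
        exons.append((3000, 3273))                                # + 274
        t = make_tx("STRG.377.2", "c", "+", exons, gene_id="STRG.377")
        t.attributes.update({"FPKM": "0.304785", "TPM": "0.760185",
                             "cov": "2.205239"})
        assert t.num_exons == 10 and t.exonic_length == 2767
        cell = _sample_cell(t, 1)
        assert cell == ("q1:STRG.377|STRG.377.2|10|0.304785|0.760185|"
                        "2.205239|2767")

    def test_tracking_row_layout(self):
        from gffkit.compare import TrackingRow
        row = TrackingRow("TCONS_00403479", "XLOC_006534",
                          "TCEA3|rna-XM_006710864.2", "j",
                          ["q1:STRG.377|STRG.377.2|10|0.304785|0.760185|"
                           "2.205239|2767"])
        text = write_tracking([row])
        assert text == ("TCONS_00403479\tXLOC_006534\t"
                        "TCEA3|rna-XM_006710864.2\tj\t"
                        "q1:STRG.377|STRG.377.2|10|0.304785|0.760185|"
                        "2.205239|2767\n")

    def test_refmap_full_and_partial(self):
        ref = make_set(make_tx("uc007crl.1", "c", "+",
                               [(100, 200), (300, 400)],
                               gene_name="Myog"))
        full = make_tx("STRG.223.1", "c", "+", [(100, 200), (300, 400)],
                       gene_id="STRG.223")
        partial = make_tx("STRG.224.1", "c", "+", [(330, 400), (500, 600)],
                          gene_id="STRG.224")
        rows = refmap_rows(make_set(full), ref)
        assert rows == [("Myog", "uc007crl.1", "=",
                         "STRG.223|STRG.223.1")]
        rows = refmap_rows(make_set(full, partial), ref)
        assert rows[0][2] == "="
        assert rows[0][3] == "STRG.223|STRG.223.1"
        rows = refmap_rows(make_set(partial), ref)
        assert rows == [("Myog", "uc007crl.1", "c",
                         "STRG.224|STRG.224.1")]

    def test_tmap_columns(self):
        ref = make_set(make_tx("uc007crl.1", "c", "+",
                               [(100, 200), (300, 400)],
                               gene_name="Myog"))
        q = make_tx("STRG.1.1", "c", "+", [(100, 200), (300, 400)],
                    gene_id="STRG.1")
        q.attributes["FPKM"] = "1.4567"
        rows = tmap_rows(make_set(q), ref)
        assert len(rows) == 1
        r = rows[0]
        assert r[0] == "Myog" and r[1] == "uc007crl.1" and r[2] == "="
        assert r[3] == "STRG.1" and r[4] == "STRG.1.1" and r[5] == "2"
        assert r[6] == "1.456700" and r[7] == "0.000000"
        assert r[10] == "STRG.1.1"
        assert r[11] == "202"  # longest exonic overlap

    def test_tmap_unmatched_uses_dashes(self):
        ref = make_set(make_tx("r", "c", "+", [(100, 200)]))
        q = make_tx("far", "c", "+", [(90_000, 90_100)])
        r = tmap_rows(make_set(q), ref)[0]
        assert r[0] == "-" and r[1] == "-" and r[2] == "u" and r[11] == "-"

    def test_major_isoform_by_expression(self):
        ref = make_set(make_tx("r", "c", "+", [(100, 400)]))
        a = make_tx("g.1", "c", "+", [(100, 400)], gene_id="g")
        b = make_tx("g.2", "c", "+", [(100, 300)], gene_id="g")
        a.attributes["FPKM"] = "1.0"
        b.attributes["FPKM"] = "5.0"
        rows = tmap_rows(make_set(a, b), ref)
        assert all(r[10] == "g.2" for r in rows)


class TestAnnotate:
    def test_attributes_added(self, fixture_set):
        from gffkit.compare import annotate
        out = annotate(fixture_set.queries[0], fixture_set.reference)
        assert len(out) == len(fixture_set.queries[0])
        for t in out:
            assert "class_code" in t.attributes
            assert "xloc" in t.attributes
        exact = out.transcripts["q001_exact_copy"]
        assert exact.attributes["class_code"] == "="
        assert exact.attributes["cmp_ref"].startswith("G")

    def test_runon_has_no_cmp_ref(self, fixture_set):
        from gffkit.compare import annotate
        out = annotate(fixture_set.queries[0], fixture_set.reference)
        runon = out.transcripts["q013_downstream_offset"]
        assert runon.attributes["class_code"] == "p"
        assert "cmp_ref" not in runon.attributes

    def test_close_starts_share_tss(self):
        ref = make_set(make_tx("r", "c", "+", [(1000, 2000)]))
        q = make_set(make_tx("a", "c", "+", [(1000, 2000)]),
                     make_tx("b", "c", "+", [(1080, 2100)]))
        from gffkit.compare import annotate
        out = annotate(q, ref)
        assert out.transcripts["a"].attributes["tss_id"] \
            == out.transcripts["b"].attributes["tss_id"]
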