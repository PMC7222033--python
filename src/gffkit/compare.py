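"""Sample-vs-reference comparison: multi-level accuracy metrics, duplicate
handling, multi-sample merging, and the tracking/refmap/tmap report files.

Accuracy is measured at six increasingly stringent levels — base, exon,
intron, intron chain, transcript, locus — with

    Sensitivity = TP / (TP + FN)        Precision = TP / (TP + FP)

where TP are query features confirmed by the reference, FN reference
features absent from the query, and FP query features absent from the
reference.  At levels where the slack rules can match query and reference
features many-to-one (exon terminal-end tolerance, locus), the
matched-reference count drives sensitivity and the matched-query count
drives precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .model import AnnotationSet, Transcript
from .transform import (cluster_loci, merge_close_exons, transcripts_match,
                        _is_subchain)
from .classify import (assign_tss, best_reference, build_superloci,
                       classify_unmatched, nearest_reference,
                       SINGLE_EXON_OVERLAP_FRACTION, TSS_GROUPING_DISTANCE,
                       RUNON_MAX_DISTANCE)

LEVELS = ("base", "exon", "intron", "intron_chain", "transcript", "locus")

# exons separated by introns shorter than this are pre-merged (--no-merge off)
COMPARE_CLOSE_MERGE_MIN_INTRON = 5
END_TOLERANCE = 100


@dataclass
class CompareOptions:
    restrict_ref: bool = False        # -R: sensitivity correction
    restrict_query: bool = False      # -Q: precision correction
    ignore_single_exon: bool = False  # -M: drop single-exon everywhere
    ignore_single_ref: bool = False   # -N: drop single-exon references
    end_tolerance: int = END_TOLERANCE            # -e
    tss_distance: int = TSS_GROUPING_DISTANCE     # -d
    close_exon_merge: bool = True     # --no-merge disables
    close_merge_min_intron: int = COMPARE_CLOSE_MERGE_MIN_INTRON
    se_overlap: float = SINGLE_EXON_OVERLAP_FRACTION
    runon_max_distance: int = RUNON_MAX_DISTANCE


@dataclass
class LevelStats:
    level: str
    tp: int = 0          # matched query features
    fp: int = 0
    fn: int = 0
    tp_ref: int | None = None  # matched reference features when != tp

    @property
    def sensitivity(self) -> float:
        tp = self.tp if self.tp_ref is None else self.tp_ref
        denom = tp + self.fn
        return tp / denom if denom else 0.0

    @property
    def precision(self) -> float:
        denom = self.tp + self.fp
        return self.tp / denom if denom else 0.0


@dataclass
class SampleStats:
    levels: dict[str, LevelStats]
    novel_exons: int = 0
    missed_exons: int = 0
    novel_introns: int = 0
    missed_introns: int = 0
    novel_loci: int = 0
    missed_loci: int = 0
    n_query: int = 0
    n_query_multi: int = 0
    n_query_loci: int = 0


@dataclass
class StatsReport:
    samples: list[SampleStats]
    n_ref: int = 0
    n_ref_multi: int = 0
    n_ref_loci: int = 0


# ---------------------------------------------------------------------------
# internal de-duplication (structural equivalence within loci)

def _dedup_equivalent(annset: AnnotationSet,
                      se_overlap: float = SINGLE_EXON_OVERLAP_FRACTION
                      ) -> AnnotationSet:
    """One survivor per structural-equivalence class (longer span wins)."""
    discard: set = set()
    for locus in cluster_loci(annset):
        members = sorted((annset.transcripts[i] for i in locus.transcript_ids),
                         key=lambda t: (-(t.end - t.start + 1), t.start, t.id))
        for i, keep in enumerate(members):
            if keep.id in discard:
                continue
            for t in members[i + 1:]:
                if t.id not in discard and transcripts_match(keep, t,
                                                             se_overlap):
                    discard.add(t.id)
    return annset.subset([t.id for t in annset if t.id not in discard])


def dedup_queries(annset: AnnotationSet, mode: str = "D") -> AnnotationSet:
    """-D: one survivor per identical intron chain (longest span);
    -S: discard only when boundaries are fully contained in the other."""
    if mode not in ("D", "S"):
        raise ValueError(f"unknown dedup mode {mode!r}")
    discard: set = set()
    txs = sorted(annset, key=lambda t: (-(t.end - t.start + 1), t.start, t.id))
    for i, keep in enumerate(txs):
        if keep.id in discard:
            continue
        for t in txs[i + 1:]:
            if t.id in discard:
                continue
            if t.seqid != keep.seqid or t.strand != keep.strand:
                continue
            if t.num_exons >= 2 and keep.num_exons >= 2 \
                    and t.intron_chain() == keep.intron_chain():
                if mode == "D" or (keep.start <= t.start
                                   and t.end <= keep.end):
                    discard.add(t.id)
    return annset.subset([t.id for t in annset if t.id not in discard])


# ---------------------------------------------------------------------------
# per-level counting primitives

def _merged_intervals(ivs):
    out: list[list[int]] = []
    for s, e in sorted(ivs):
        if out and s <= out[-1][1] + 1:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return out


def _coverage_len(merged) -> int:
    return sum(e - s + 1 for s, e in merged)


def _intersect_len(a, b) -> int:
    i = j = total = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if s <= e:
            total += e - s + 1
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return total


def _base_level(query: AnnotationSet, ref: AnnotationSet) -> LevelStats:
    keys = set()
    for t in list(query) + list(ref):
        keys.add((t.seqid, t.strand))
    tp = fp = fn = 0
    for (seqid, strand) in keys:
        q_ivs = _merged_intervals(
            (e.start, e.end) for t in query
            if t.seqid == seqid and t.strand == strand for e in t.exons)
        r_ivs = _merged_intervals(
            (e.start, e.end) for t in ref
            if t.seqid == seqid and t.strand == strand for e in t.exons)
        inter = _intersect_len(q_ivs, r_ivs)
        tp += inter
        fp += _coverage_len(q_ivs) - inter
        fn += _coverage_len(r_ivs) - inter
    return LevelStats("base", tp=tp, fp=fp, fn=fn)


def _unique_exons(annset: AnnotationSet):
    """Distinct exon intervals with free-end flags.

    An exon boundary is "free" when in some transcript it is the outer edge
    of a terminal exon (single exons are free on both sides); only free
    edges may use the -e slack.
    """
    exons: dict[tuple, list[bool]] = {}
    for t in annset:
        for i, e in enumerate(t.exons):
            key = (t.seqid, t.strand, e.start, e.end)
            flags = exons.setdefault(key, [False, False])
            if i == 0:
                flags[0] = True
            if i == t.num_exons - 1:
                flags[1] = True
    return exons


def _exon_level(query: AnnotationSet, ref: AnnotationSet,
                tol: int) -> tuple[LevelStats, int, int]:
    q_exons = _unique_exons(query)
    r_exons = _unique_exons(ref)

    def match(qk, qflags, rk, rflags):
        if qk[0] != rk[0] or qk[1] != rk[1]:
            return False
        start_ok = qk[2] == rk[2] or (qflags[0] and rflags[0]
                                      and abs(qk[2] - rk[2]) <= tol)
        end_ok = qk[3] == rk[3] or (qflags[1] and rflags[1]
                                    and abs(qk[3] - rk[3]) <= tol)
        return start_ok and end_ok

    matched_q = matched_r = 0
    r_hit = {k: False for k in r_exons}
    for qk, qf in q_exons.items():
        hit = False
        for rk, rf in r_exons.items():
            if match(qk, qf, rk, rf):
                hit = True
                r_hit[rk] = True
        if hit:
            matched_q += 1
    matched_r = sum(r_hit.values())

    def overlaps_any(k, others) -> bool:
        return any(o[0] == k[0] and o[1] == k[1]
                   and o[2] <= k[3] and k[2] <= o[3] for o in others)

    novel = sum(1 for k in q_exons if not overlaps_any(k, r_exons))
    missed = sum(1 for k in r_exons if not overlaps_any(k, q_exons))
    stats = LevelStats("exon", tp=matched_q, fp=len(q_exons) - matched_q,
                       fn=len(r_exons) - matched_r,
                       tp_ref=matched_r if matched_r != matched_q else None)
    return stats, novel, missed


def _unique_introns(annset: AnnotationSet) -> set:
    return {(t.seqid, t.strand, s, e) for t in annset for s, e in t.introns()}


def _intron_level(query: AnnotationSet,
                  ref: AnnotationSet) -> tuple[LevelStats, int, int]:
    qi, ri = _unique_introns(query), _unique_introns(ref)
    tp = len(qi & ri)
    stats = LevelStats("intron", tp=tp, fp=len(qi) - tp, fn=len(ri) - tp)

    def overlaps_any(k, others):
        return any(o[0] == k[0] and o[1] == k[1]
                   and o[2] <= k[3] and k[2] <= o[3] for o in others)

    novel = sum(1 for k in qi if not overlaps_any(k, ri))
    missed = sum(1 for k in ri if not overlaps_any(k, qi))
    return stats, novel, missed


def _chain_level(query: AnnotationSet, ref: AnnotationSet) -> LevelStats:
    q_multi = [t for t in query if t.num_exons >= 2]
    r_multi = [t for t in ref if t.num_exons >= 2]
    r_chains = {(t.seqid, t.strand, t.intron_chain()) for t in r_multi}
    q_chains = {(t.seqid, t.strand, t.intron_chain()) for t in q_multi}
    tp = sum(1 for t in q_multi
             if (t.seqid, t.strand, t.intron_chain()) in r_chains)
    fn = sum(1 for t in r_multi
             if (t.seqid, t.strand, t.intron_chain()) not in q_chains)
    return LevelStats("intron_chain", tp=tp, fp=len(q_multi) - tp, fn=fn)


def transcript_level_match(q: Transcript, r: Transcript, tol: int,
                           se_overlap: float) -> bool:
    """Full exon-chain match: equal intron chains with terminal outer ends
    within ``tol`` bases; single-exon pairs match at > ``se_overlap`` of the
    longer transcript."""
    if q.seqid != r.seqid or q.strand != r.strand:
        return False
    if q.num_exons >= 2 and r.num_exons >= 2:
        return (q.intron_chain() == r.intron_chain()
                and abs(q.start - r.start) <= tol
                and abs(q.end - r.end) <= tol)
    if q.num_exons == 1 and r.num_exons == 1:
        longer = max(q.exonic_length, r.exonic_length)
        return q.exonic_overlap(r) > se_overlap * longer
    return False


def _transcript_level(query: AnnotationSet, ref: AnnotationSet, tol: int,
                      se_overlap: float) -> LevelStats:
    r_list = list(ref)
    matched_r: set = set()
    tp = 0
    for q in query:
        hits = [r for r in ref.overlap_candidates(q.interval)
                if transcript_level_match(q, r, tol, se_overlap)]
        if hits:
            tp += 1
            matched_r.update(r.id for r in hits)
    fn = sum(1 for r in r_list if r.id not in matched_r)
    return LevelStats("transcript", tp=tp, fp=len(query) - tp, fn=fn,
                      tp_ref=(len(matched_r)
                              if len(matched_r) != tp else None))


def _locus_level(query: AnnotationSet, ref: AnnotationSet, tol: int,
                 se_overlap: float):
    q_loci = cluster_loci(query)
    r_loci = cluster_loci(ref)
    matched_q = matched_r = 0
    r_matched_flags = []
    for rl in r_loci:
        ok = False
        for rid in rl.transcript_ids:
            r = ref.transcripts[rid]
            for q in query.overlap_candidates(r.interval):
                if transcript_level_match(q, r, tol, se_overlap):
                    ok = True
                    break
            if ok:
                break
        r_matched_flags.append(ok)
    matched_r = sum(r_matched_flags)
    for ql in q_loci:
        ok = False
        for qid in ql.transcript_ids:
            q = query.transcripts[qid]
            for r in ref.overlap_candidates(q.interval):
                if transcript_level_match(q, r, tol, se_overlap):
                    ok = True
                    break
            if ok:
                break
        if ok:
            matched_q += 1
    stats = LevelStats("locus", tp=matched_q, fp=len(q_loci) - matched_q,
                       fn=len(r_loci) - matched_r,
                       tp_ref=matched_r if matched_r != matched_q else None)
    novel = 0
    for ql in q_loci:
        if not any(
            ref.overlap_candidates(query.transcripts[tid].interval)
            and any(query.transcripts[tid].exonic_overlap(r) > 0
                    for r in ref.overlap_candidates(
                        query.transcripts[tid].interval))
            for tid in ql.transcript_ids
        ):
            novel += 1
    missed = 0
    for rl in r_loci:
        if not any(
            any(ref.transcripts[tid].exonic_overlap(q) > 0
                for q in query.overlap_candidates(
                    ref.transcripts[tid].interval))
            for tid in rl.transcript_ids
        ):
            missed += 1
    return stats, novel, missed, len(q_loci), len(r_loci)


# ---------------------------------------------------------------------------

def _preprocess(annset: AnnotationSet, opts: CompareOptions,
                is_ref: bool) -> AnnotationSet:
    out = AnnotationSet(seqid_order=list(annset.seqid_order))
    for g in annset.genes.values():
        out.add_gene(g)
    for t in annset:
        if opts.close_exon_merge and not is_ref:
            t = merge_close_exons(t, opts.close_merge_min_intron)
        if opts.ignore_single_exon and t.num_exons < 2:
            continue
        if is_ref and opts.ignore_single_ref and t.num_exons < 2:
            continue
        out.add(t)
    return _dedup_equivalent(out, opts.se_overlap)


def compute_stats(queries: list[AnnotationSet], reference: AnnotationSet,
                  opts: CompareOptions | None = None) -> StatsReport:
    """Six-level sensitivity/precision for each sample against the reference.

    Queries are close-exon pre-merged and structurally de-duplicated before
    counting; the reference is de-duplicated the same way so duplicated
    annotation records do not double-count FN.
    """
    opts = opts or CompareOptions()
    ref = _preprocess(reference, opts, is_ref=True)
    qsets = [_preprocess(q, opts, is_ref=False) for q in queries]

    if opts.restrict_ref:
        keep = [r.id for r in ref
                if any(q.overlap_candidates(r.interval) for q in qsets)]
        ref = ref.subset(keep)
    if opts.restrict_query:
        qsets = [q.subset([t.id for t in q
                           if ref.overlap_candidates(t.interval)])
                 for q in qsets]

    report = StatsReport(samples=[], n_ref=len(ref),
                         n_ref_multi=sum(1 for t in ref if t.num_exons >= 2),
                         n_ref_loci=len(cluster_loci(ref)))
    for q in qsets:
        levels: dict[str, LevelStats] = {}
        levels["base"] = _base_level(q, ref)
        levels["exon"], novel_e, missed_e = _exon_level(q, ref,
                                                        opts.end_tolerance)
        levels["intron"], novel_i, missed_i = _intron_level(q, ref)
        levels["intron_chain"] = _chain_level(q, ref)
        levels["transcript"] = _transcript_level(q, ref, opts.end_tolerance,
                                                 opts.se_overlap)
        locus_stats, novel_l, missed_l, n_ql, _ = _locus_level(
            q, ref, opts.end_tolerance, opts.se_overlap)
        levels["locus"] = locus_stats
        report.samples.append(SampleStats(
            levels=levels,
            novel_exons=novel_e, missed_exons=missed_e,
            novel_introns=novel_i, missed_introns=missed_i,
            novel_loci=novel_l, missed_loci=missed_l,
            n_query=len(q),
            n_query_multi=sum(1 for t in q if t.num_exons >= 2),
            n_query_loci=n_ql,
        ))
    return report


def render_stats(report: StatsReport, query_names: list[str] | None = None,
                 prefix: str = "gffcmp") -> str:
    """Human-readable .stats text (layout is ours; quantities are standard)."""
    lines = [f"# {prefix}: transcript comparison against reference",
             f"# reference transcripts: {report.n_ref} "
             f"({report.n_ref_multi} multi-exon) in {report.n_ref_loci} loci",
             ""]
    for i, s in enumerate(report.samples):
        name = query_names[i] if query_names else f"q{i + 1}"
        lines.append(f"#= Sample {name}: {s.n_query} query transfrags "
                     f"({s.n_query_multi} multi-exon) in {s.n_query_loci} loci")
        lines.append(f"{'Level':>16} {'Sensitivity':>12} {'Precision':>10}")
        for lvl in LEVELS:
            st = s.levels[lvl]
            lines.append(f"{lvl.replace('_', ' '):>16} "
                         f"{100 * st.sensitivity:>11.1f} "
                         f"{100 * st.precision:>10.1f}")
        lines.append(f"  Missed exons: {s.missed_exons}   "
                     f"Novel exons: {s.novel_exons}")
        lines.append(f"  Missed introns: {s.missed_introns}   "
                     f"Novel introns: {s.novel_introns}")
        lines.append(f"  Missed loci: {s.missed_loci}   "
                     f"Novel loci: {s.novel_loci}")
        lines.append("")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# multi-sample merging and tracking

@dataclass
class TrackingRow:
    tcons_id: str
    xloc_id: str
    ref_gene_tx: str          # "gene|transcript" or "-"
    class_code: str
    cells: list[str] = field(default_factory=list)  # one per sample


def _expr_attr(t: Transcript, key: str) -> float:
    for k, v in t.attributes.items():
        if k.lower() == key.lower():
            try:
                return float(v)
            except ValueError:
                return 0.0
    return 0.0


def _sample_cell(t: Transcript, sample_no: int) -> str:
    gid = t.gene_id or t.id
    return (f"q{sample_no}:{gid}|{t.id}|{t.num_exons}|"
            f"{_expr_attr(t, 'FPKM'):.6f}|{_expr_attr(t, 'TPM'):.6f}|"
            f"{_expr_attr(t, 'cov'):.6f}|{t.exonic_length}")


def _tss5_index(t: Transcript, container: Transcript) -> bool:
    """Does ``t`` share its 5'-terminal exon position in the container's
    chain (i.e. no alternate TSS)?"""
    tc, cc = t.intron_chain(), container.intron_chain()
    pos = _is_subchain(tc, cc)
    if pos is None:
        return False
    if t.strand == "-":
        return pos + len(tc) == len(cc)
    return pos == 0


def _contained_redundant(t: Transcript, c: Transcript,
                         allow_protrusion: bool) -> bool:
    """Contained, intron-redundant transfrag (cross-sample -C/-X semantics)."""
    if t.seqid != c.seqid or t.strand != c.strand:
        return False
    if not (c.start <= t.start and t.end <= c.end):
        return False
    if t.num_exons == 1:
        if c.num_exons == 1:
            return True
        if allow_protrusion:
            return True
        return any(e.contains(t.exons[0]) for e in c.exons)
    if c.num_exons < 2:
        return False
    tc, cc = t.intron_chain(), c.intron_chain()
    if tc == cc:
        return True
    pos = _is_subchain(tc, cc)
    if pos is None:
        return False
    if allow_protrusion:
        return True
    # ends must not stick out into the container's introns
    return (c.exons[pos].start <= t.start
            and t.end <= c.exons[pos + len(tc)].end)


def merge_samples(queries: list[AnnotationSet],
                  reference: AnnotationSet | None = None,
                  mode: str = "union", keep_ref_matches: bool = False,
                  tcons_prefix: str = "TCONS",
                  se_overlap: float = SINGLE_EXON_OVERLAP_FRACTION,
                  end_tolerance: int = END_TOLERANCE
                  ) -> tuple[AnnotationSet, list[TrackingRow]]:
    """Union of all transfrags with structural duplicates collapsed.

    mode: "union" collapses only structurally equivalent transfrags;
    "C" also discards contained intron-redundant transfrags; "A" exempts
    those starting at a different 5' exon (alternate TSS); "X" additionally
    discards contained transfrags whose ends stick into container introns.
    keep_ref_matches protects transfrags matching a reference transcript.
    """
    if mode not in ("union", "C", "A", "X"):
        raise ValueError(f"unknown merge mode {mode!r}")
    superloci = build_superloci(queries, reference)

    combined = AnnotationSet()
    rows: list[TrackingRow] = []
    counter = 0
    for sl in superloci:
        members = [(s, queries[s].transcripts[tid]) for s, tid in sl.query_ids]
        if not members:
            continue
        refs = [reference.transcripts[rid] for rid in sl.ref_ids] \
            if reference is not None else []
        # equivalence classes under structural match (single linkage)
        classes: list[list[tuple[int, Transcript]]] = []
        for s, t in members:
            placed = None
            for cls in classes:
                if any(transcripts_match(t, u, se_overlap) for _, u in cls):
                    if placed is None:
                        cls.append((s, t))
                        placed = cls
                    else:
                        placed.extend(cls)
                        cls.clear()
            if placed is None:
                classes.append([(s, t)])
        classes = [c for c in classes if c]

        # representative: longest span
        reps = []
        for cls in classes:
            rep = max((t for _, t in cls), key=lambda t: (t.end - t.start + 1,
                                                          -t.start))
            reps.append((rep, cls))

        # containment-based discarding across samples
        kept = []
        if mode == "union":
            kept = reps
        else:
            allow = (mode == "X")
            for rep, cls in reps:
                redundant = False
                for other, _ in reps:
                    if other is rep:
                        continue
                    if not _contained_redundant(rep, other, allow):
                        continue
                    if mode == "A" and not _tss5_index(rep, other):
                        continue  # alternate TSS: keep
                    if keep_ref_matches and any(
                            transcripts_match(rep, r, se_overlap)
                            for r in refs):
                        continue
                    redundant = True
                    break
                if not redundant:
                    kept.append((rep, cls))

        kept.sort(key=lambda rc: (rc[0].start, rc[0].end))
        for rep, cls in kept:
            counter += 1
            tcons = f"{tcons_prefix}_{counter:08d}"
            best = best_reference(rep, refs, end_tolerance, se_overlap)
            if best is not None:
                ref_t, code = best
                gene = ref_t.gene_name or ref_t.gene_id or "-"
                ref_cell = f"{gene}|{ref_t.id}"
            else:
                ref_cell, code = "-", "u"
            cells = []
            per_sample = {s: t for s, t in cls}
            for s in range(len(queries)):
                t = per_sample.get(s)
                cells.append(_sample_cell(t, s + 1) if t is not None else "-")
            rows.append(TrackingRow(tcons, sl.xloc_id, ref_cell, code, cells))
            new = rep.copy(id=tcons)
            new.attributes = dict(rep.attributes)
            new.attributes["oId"] = rep.id
            new.gene_id = sl.xloc_id
            combined.add(new)
    return combined, rows


# ---------------------------------------------------------------------------
# single-sample annotation

def annotate(query: AnnotationSet, reference: AnnotationSet,
             genome=None, opts: CompareOptions | None = None
             ) -> AnnotationSet:
    """Return the query set with xloc, tss_id, cmp_ref and class_code added.

    Every input transcript is retained.  Queries with no reference overlap
    get p/r/u (run-on / repeat / intergenic) and no cmp_ref.
    """
    opts = opts or CompareOptions()
    superloci = build_superloci([query], reference)
    out = AnnotationSet(seqid_order=list(query.seqid_order))
    for g in query.genes.values():
        out.add_gene(g)
    tss_counter = 0
    for sl in superloci:
        members = [query.transcripts[tid] for _, tid in sl.query_ids]
        if not members:
            continue
        refs = [reference.transcripts[rid] for rid in sl.ref_ids]
        tss_map = assign_tss(members + refs, opts.tss_distance, tss_counter)
        if tss_map:
            tss_counter = max(int(v.split("_")[1]) for v in tss_map.values())
        for t in members:
            new = t.copy()
            new.attributes = dict(t.attributes)
            new.attributes["xloc"] = sl.xloc_id
            if t.id in tss_map:
                new.attributes["tss_id"] = tss_map[t.id]
            best = best_reference(t, refs, opts.end_tolerance, opts.se_overlap)
            if best is not None:
                ref_t, code = best
                new.attributes["cmp_ref"] = ref_t.id
                new.attributes["class_code"] = code
            else:
                near = nearest_reference(t, reference,
                                         opts.runon_max_distance)
                new.attributes["class_code"] = classify_unmatched(
                    t, near, genome,
                    runon_max_distance=opts.runon_max_distance)
            out.add(new)
    return out


# ---------------------------------------------------------------------------
# report files

def write_tracking(rows: list[TrackingRow]) -> str:
    return "\n".join(
        "\t".join([r.tcons_id, r.xloc_id, r.ref_gene_tx, r.class_code,
                   *r.cells])
        for r in rows) + ("\n" if rows else "")


# same-strand exonic-overlap codes counted as at least a partial match
_PARTIAL_MATCH_CODES = set("=ckmnjeo")


def refmap_rows(query: AnnotationSet, reference: AnnotationSet,
                opts: CompareOptions | None = None):
    """(ref_gene_name, ref_id, '='|'c', matches) per matched reference."""
    opts = opts or CompareOptions()
    out = []
    for seqid in reference.seqid_order:
        for r in reference.by_seqid(seqid):
            full, partial = [], []
            for q in query.overlap_candidates(r.interval):
                from .classify import classify_pair
                code = classify_pair(q, r, opts.end_tolerance, opts.se_overlap)
                if code == "=":
                    full.append(q)
                elif code in _PARTIAL_MATCH_CODES:
                    partial.append(q)
            if not full and not partial:
                continue
            qs = full if full else partial
            matches = ",".join(f"{q.gene_id or q.id}|{q.id}" for q in qs)
            gene = r.gene_name or r.gene_id or "-"
            out.append((gene, r.id, "=" if full else "c", matches))
    return out


def write_refmap(query: AnnotationSet, reference: AnnotationSet,
                 opts: CompareOptions | None = None) -> str:
    header = "ref_gene\tref_id\tclass_code\tqry_id_list"
    lines = [header] + ["\t".join(row)
                        for row in refmap_rows(query, reference, opts)]
    return "\n".join(lines) + "\n"


def tmap_rows(query: AnnotationSet, reference: AnnotationSet,
              genome=None, opts: CompareOptions | None = None):
    opts = opts or CompareOptions()
    # major isoform per query gene: highest FPKM, then coverage, then length
    best_iso: dict[str, str] = {}
    best_key: dict[str, tuple] = {}
    for t in query:
        gid = t.gene_id or t.id
        key = (_expr_attr(t, "FPKM"), _expr_attr(t, "cov"), t.exonic_length)
        if gid not in best_key or key > best_key[gid]:
            best_key[gid] = key
            best_iso[gid] = t.id
    rows = []
    for seqid in query.seqid_order:
        for t in query.by_seqid(seqid):
            best = best_reference(t, reference.overlap_candidates(t.interval),
                                  opts.end_tolerance, opts.se_overlap)
            if best is not None:
                ref_t, code = best
                gene = ref_t.gene_name or ref_t.gene_id or "-"
                ref_id = ref_t.id
            else:
                near = nearest_reference(t, reference,
                                         opts.runon_max_distance)
                code = classify_unmatched(
                    t, near, genome,
                    runon_max_distance=opts.runon_max_distance)
                gene, ref_id = "-", "-"
            overlaps = [t.exonic_overlap(r)
                        for r in reference.overlap_candidates(t.interval)]
            ref_match_len = max(overlaps, default=0)
            rows.append([
                gene, ref_id, code, t.gene_id or t.id, t.id,
                str(t.num_exons),
                f"{_expr_attr(t, 'FPKM'):.6f}", f"{_expr_attr(t, 'TPM'):.6f}",
                f"{_expr_attr(t, 'cov'):.6f}", str(t.exonic_length),
                best_iso.get(t.gene_id or t.id, t.id),
                str(ref_match_len) if ref_match_len > 0 else "-",
            ])
    return rows


def write_tmap(query: AnnotationSet, reference: AnnotationSet,
               genome=None, opts: CompareOptions | None = None) -> str:
    header = ("ref_gene_id\tref_id\tclass_code\tqry_gene_id\tqry_id\t"
              "num_exons\tFPKM\tTPM\tcov\tlen\tmajor_iso_id\tref_match_len")
    lines = [header] + ["\t".join(r)
                        for r in tmap_rows(query, reference, genome, opts)]
    return "\n".join(lines) + "\n"
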