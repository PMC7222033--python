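"""Streaming overlap classification against a reference interval tree.

The reference annotation is loaded once into per-chromosome interval
trees; query transcripts are then processed one at a time, so memory use
is proportional to the reference alone.  Every overlapping reference is
reported with its class code (codes p/r/u never appear: queries with no
overlap produce no record).
"""

from __future__ import annotations

from intervaltree import IntervalTree

from .model import AnnotationSet, GenomicInterval, Transcript
from .classify import classify_pair


class RefIntervalTree:
    """Per-seqid interval tree keyed by transcript span."""

    def __init__(self, reference: AnnotationSet):
        self._trees: dict[str, IntervalTree] = {}
        for t in reference:
            # intervaltree uses half-open [begin, end); shift the inclusive end
            self._trees.setdefault(t.seqid, IntervalTree()).addi(
                t.start, t.end + 1, t)

    def overlapping(self, interval: GenomicInterval) -> list[Transcript]:
        tree = self._trees.get(interval.seqid)
        if tree is None:
            return []
        hits = [iv.data for iv in tree.overlap(interval.start,
                                               interval.end + 1)]
        hits.sort(key=lambda t: (t.start, t.end, t.id))
        return hits


def build_tree(reference: AnnotationSet) -> RefIntervalTree:
    return RefIntervalTree(reference)


def classify_query(tree: RefIntervalTree, q: Transcript,
                   **classify_kwargs) -> list[tuple[str, Transcript]]:
    """All (code, reference) hits for one query, ordered by reference
    start then id."""
    out = []
    for r in tree.overlapping(q.interval):
        out.append((classify_pair(q, r, **classify_kwargs), r))
    return out


def stream_classify(tree: RefIntervalTree, queries, simple: bool = False):
    """Yield one formatted text block per query with >= 1 overlap.

    ``queries`` is any iterable of Transcript; only the tree and the
    current query are held in memory.
    """
    for q in queries:
        if simple:
            line = format_simple(q, tree.overlapping(q.interval))
            if line is not None:
                yield line
        else:
            hits = classify_query(tree, q)
            if hits:
                yield format_record(q, hits)


def _exon_list(t: Transcript) -> str:
    return ",".join(f"{e.start}-{e.end}" for e in t.exons)


def format_record(q: Transcript, hits) -> str:
    """Pseudo-FASTA block: '>' query header, one tab-delimited hit line per
    overlapping reference.  All coordinates 1-based."""
    lines = [f">{q.id} {q.seqid}:{q.start}-{q.end}{q.strand} "
             f"exons:{_exon_list(q)}"]
    for code, r in hits:
        lines.append("\t".join([
            code, r.seqid, r.strand, str(r.start), str(r.end), r.id,
            _exon_list(r)]))
    return "\n".join(lines)


def format_simple(q: Transcript, refs: list[Transcript]) -> str | None:
    """-S mode: one line per query with per-reference overlap percentages
    (shared exonic bases as a percentage of the query's exonic length)."""
    if not refs:
        return None
    qlen = q.exonic_length
    parts = []
    for r in refs:
        pct = 100.0 * q.exonic_overlap(r) / qlen if qlen else 0.0
        parts.append(f"{r.id}:{pct:.1f}")
    return (f"{q.id}\t{q.seqid}:{q.start}-{q.end}{q.strand}\t"
            + ",".join(parts))
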