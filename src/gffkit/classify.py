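"""Overlap classification of query transcripts against a reference.

Each query/reference pair receives a single-character class code describing
their structural relationship; codes form a total priority order and the
highest-priority code whose definition holds is assigned:

  =  complete, exact intron chain match
  c  contained in the reference (intron compatible)
  k  contains the reference (reverse containment)
  m  retained reference intron(s), full intron chain match everywhere else
  n  completely overlaps a reference intron, partial/no chain match elsewhere
  j  multi-exon with at least one junction match
  e  single exon partially covering a reference intron
  o  other same-strand exonic overlap
  s  intron match on the opposite strand (likely a mapping error)
  x  exonic overlap on the opposite strand
  i  fully contained within a reference intron
  y  contains a reference within its intron(s)
  p  possible polymerase run-on (close to a reference, no overlap)
  r  repeat (at least 50% of bases soft-masked)
  u  none of the above (intergenic, unknown)

p/r/u apply only to queries that overlap no reference transcript.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .model import AnnotationSet, GenomicInterval, Transcript
from .transform import SINGLE_EXON_OVERLAP_FRACTION, _components, _is_subchain

CLASS_CODE_PRIORITY = "=ckmnjeosxiypru"

# how far a single exon must reach past a reference exon boundary into the
# adjacent intron before the pair is called "e" rather than "o"
E_INTRUSION_MIN = 10
# default distance within which a non-overlapping query counts as run-on (p)
RUNON_MAX_DISTANCE = 2000
# minimum soft-masked fraction of exonic bases for the repeat code (r)
REPEAT_FRACTION_MIN = 0.5


def code_priority(code: str) -> int:
    return CLASS_CODE_PRIORITY.index(code)


def _strand_compatible(a: str, b: str) -> bool:
    return a == b or a == "." or b == "."


def _exon_within_union(exon: GenomicInterval, segs) -> bool:
    return any(s.start <= exon.start and exon.end <= s.end for s in segs)


def _contained_code(q: Transcript, r: Transcript) -> bool:
    """True when q is contained in r, intron compatible ("c" seen from q)."""
    if not (r.start <= q.start and q.end <= r.end):
        return False
    if q.num_exons == 1:
        # single exon inside one reference exon
        return _exon_within_union(q.exons[0], r.exons)
    qc, rc = q.intron_chain(), r.intron_chain()
    if r.num_exons < 2:
        return False
    pos = _is_subchain(qc, rc)
    if pos is None:
        return False
    # terminal q exons must stay inside the flanking reference exons
    left_bound = r.exons[pos].start
    right_bound = r.exons[pos + len(qc)].end
    return left_bound <= q.start and q.end <= right_bound


def _retained_introns(q: Transcript, r: Transcript) -> tuple[int, int, int]:
    """(matched, retained, other) partition of the reference introns.

    matched: exactly present in q's chain; retained: fully inside one q
    exon; other: everything else.
    """
    qintrons = set(q.intron_chain())
    matched = retained = other = 0
    for (s, e) in r.intron_chain():
        if (s, e) in qintrons:
            matched += 1
        elif any(x.start <= s and e <= x.end for x in q.exons):
            retained += 1
        else:
            other += 1
    return matched, retained, other


def classify_pair(q: Transcript, r: Transcript,
                  end_tolerance: int = 100,
                  se_overlap: float = SINGLE_EXON_OVERLAP_FRACTION,
                  e_intrusion: int = E_INTRUSION_MIN) -> str:
    """Class code for a query/reference pair whose spans overlap.

    ``end_tolerance`` does not demote "=": terminal-exon end differences are
    assessed at the accuracy-metric level, not here.
    """
    if q.seqid != r.seqid:
        raise ValueError("classify_pair requires transcripts on the same "
                         "reference sequence")
    same_strand = _strand_compatible(q.strand, r.strand)
    exonic = q.exonic_overlap(r)
    qc, rc = q.intron_chain(), r.intron_chain()

    if same_strand:
        # "="
        if q.num_exons >= 2 and r.num_exons >= 2 and qc == rc:
            return "="
        if q.num_exons == 1 and r.num_exons == 1:
            longer = max(q.exonic_length, r.exonic_length)
            if exonic > se_overlap * longer:
                return "="
        # "c" / "k"
        if _contained_code(q, r):
            return "c"
        if _contained_code(r, q):
            return "k"
        # "m" / "n": reference introns retained inside query exons
        if r.num_exons >= 2 and exonic > 0:
            matched, retained, other = _retained_introns(q, r)
            if retained >= 1:
                q_novel = [i for i in qc if i not in set(rc)]
                if other == 0 and not q_novel:
                    return "m"
                return "n"
        # "j": at least one junction (splice site) shared
        if q.num_exons >= 2 and r.num_exons >= 2 and exonic > 0:
            r_sites = {s for i in rc for s in i}
            if any(s in r_sites or e in r_sites for (s, e) in qc):
                return "j"
        # "e": single exon reaching into a reference intron
        if q.num_exons == 1 and exonic > 0 and r.num_exons >= 2:
            qe = q.exons[0]
            for (s, e) in rc:
                inside = min(qe.end, e) - max(qe.start, s) + 1
                if 0 < inside <= (e - s + 1) - 0 and inside > e_intrusion \
                        and not (qe.start <= s and e <= qe.end):
                    return "e"
        if exonic > 0:
            return "o"
    else:
        # "s": an intron of q exactly matches a reference intron, opposite strand
        if qc and rc and set(qc) & set(rc):
            return "s"
        if exonic > 0:
            return "x"
    # containment within an intron (either direction), any strand
    for (s, e) in rc:
        if s <= q.start and q.end <= e:
            return "i"
    for (s, e) in qc:
        if s <= r.start and r.end <= e:
            return "y"
    # span overlap without exonic overlap that fits no interval containment
    return "o" if same_strand else "x"


def masked_fraction(t: Transcript, genome) -> float:
    """Fraction of exonic bases that are soft-masked (lower-case)."""
    total = lower = 0
    for e in t.exons:
        s = genome.fetch(e.seqid, e.start, e.end)
        total += len(s)
        lower += sum(1 for c in s if c.islower())
    return lower / total if total else 0.0


def classify_unmatched(q: Transcript, nearest_ref=None, genome=None,
                       repeat_fraction_min: float = REPEAT_FRACTION_MIN,
                       runon_max_distance: int = RUNON_MAX_DISTANCE) -> str:
    """Code for a query overlapping no reference: r, p or u.

    ``nearest_ref`` is (Transcript, distance) for the closest same-strand
    reference, or None.
    """
    if genome is not None and q.seqid in genome \
            and masked_fraction(q, genome) >= repeat_fraction_min:
        return "r"
    if nearest_ref is not None:
        ref, dist = nearest_ref
        if dist <= runon_max_distance and _strand_compatible(q.strand,
                                                             ref.strand):
            return "p"
    return "u"


def nearest_reference(q: Transcript, reference: AnnotationSet,
                      max_distance: int = RUNON_MAX_DISTANCE):
    """Closest same-strand non-overlapping reference within max_distance."""
    best = None
    lo = GenomicInterval(q.seqid, max(1, q.start - max_distance),
                         q.end + max_distance, q.strand)
    for r in reference.overlap_candidates(lo):
        if not _strand_compatible(q.strand, r.strand):
            continue
        if r.start <= q.end and q.start <= r.end:
            continue  # overlapping refs handled elsewhere
        dist = r.start - q.end if r.start > q.end else q.start - r.end
        if best is None or dist < best[1]:
            best = (r, dist)
    return best


def best_reference(q: Transcript, refs: list[Transcript],
                   end_tolerance: int = 100,
                   se_overlap: float = SINGLE_EXON_OVERLAP_FRACTION):
    """Highest-priority (reference, code) over all overlapping references.

    Ties break on larger exonic overlap, then smaller reference id.
    """
    best = None
    for r in refs:
        if r.seqid != q.seqid or not r.interval.overlaps(q.interval):
            continue
        code = classify_pair(q, r, end_tolerance, se_overlap)
        key = (code_priority(code), -q.exonic_overlap(r), r.id)
        if best is None or key < best[0]:
            best = (key, r, code)
    if best is None:
        return None
    return best[1], best[2]


# ---------------------------------------------------------------------------
# super-loci

@dataclass
class SuperLocus:
    """Region where query and reference transcripts cluster by exon overlap
    (across all samples and both strands); labeled XLOC_######."""

    xloc_id: str
    interval: GenomicInterval
    query_ids: list[tuple[int, str]] = field(default_factory=list)  # (sample, id)
    ref_ids: list[str] = field(default_factory=list)


class _Member:
    __slots__ = ("t", "sample")

    def __init__(self, t: Transcript, sample: int):
        self.t = t
        self.sample = sample  # -1 for reference

    @property
    def start(self):
        return self.t.start

    @property
    def end(self):
        return self.t.end


def build_superloci(queries: list[AnnotationSet],
                    reference: AnnotationSet | None) -> list[SuperLocus]:
    """Connected components of exon overlap over all queries + reference.

    Strand-agnostic: cross-strand exon overlaps merge, since the s/x codes
    require cross-strand comparison within a locus.
    """
    members: list[_Member] = []
    seq_order: list[str] = []
    sets = ([(-1, reference)] if reference is not None else []) + \
        list(enumerate(queries))
    for sample, annset in sets:
        for s in annset.seqid_order:
            if s not in seq_order:
                seq_order.append(s)
        for t in annset:
            members.append(_Member(t, sample))

    def joined(a: _Member, b: _Member) -> bool:
        return (a.t.seqid == b.t.seqid and a.t.exonic_overlap(b.t) > 0)

    loci: list[SuperLocus] = []
    by_seq: dict[str, list[_Member]] = {}
    for m in members:
        by_seq.setdefault(m.t.seqid, []).append(m)
    for seqid in seq_order:
        for comp in _components(by_seq.get(seqid, []), joined):
            iv = GenomicInterval(seqid, min(m.start for m in comp),
                                 max(m.end for m in comp))
            sl = SuperLocus(xloc_id="", interval=iv)
            for m in sorted(comp, key=lambda m: (m.start, m.end)):
                if m.sample < 0:
                    sl.ref_ids.append(m.t.id)
                else:
                    sl.query_ids.append((m.sample, m.t.id))
            loci.append(sl)
    loci.sort(key=lambda l: (seq_order.index(l.interval.seqid),
                             l.interval.start, l.interval.end))
    for i, l in enumerate(loci, 1):
        l.xloc_id = f"XLOC_{i:06d}"
    return loci


# ---------------------------------------------------------------------------
# TSS grouping

TSS_GROUPING_DISTANCE = 100


def tss_position(t: Transcript) -> int:
    """Strand-aware transcription start: genomic start on +, end on -."""
    return t.start if t.strand != "-" else t.end


def assign_tss(transcripts: list[Transcript],
               d: int = TSS_GROUPING_DISTANCE,
               start_index: int = 0) -> dict[str, str]:
    """Group same-strand transcripts by 5' start with single-linkage at
    distance <= d; unknown-strand transcripts get no tss_id.

    Returns transcript id -> tss_id; ids are TSS_ + counter continuing from
    ``start_index``.
    """
    assignments: dict[str, str] = {}
    counter = start_index
    for strand in ("+", "-"):
        members = [t for t in transcripts if t.strand == strand]
        members.sort(key=tss_position)
        group: list[Transcript] = []
        groups: list[list[Transcript]] = []
        for t in members:
            if group and tss_position(t) - tss_position(group[-1]) <= d:
                group.append(t)
            else:
                if group:
                    groups.append(group)
                group = [t]
        if group:
            groups.append(group)
        for g in groups:
            counter += 1
            for t in g:
                assignments[t.id] = f"TSS_{counter}"
    return assignments
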