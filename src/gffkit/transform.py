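"""Filtering, locus clustering, redundancy removal and reshaping.

These are the gffread-style whole-set transforms: every operation takes an
AnnotationSet (or a Transcript) and returns a new one, leaving the input
untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .model import AnnotationSet, Gene, GenomicInterval, Transcript
from . import seq as _seq

# attribute keys inspected for pseudogene evidence
_PSEUDO_ATTR_KEYS = ("biotype", "gene_biotype", "transcript_biotype",
                     "gene_type", "transcript_type", "pseudo")

# smallest intron kept by the close-exon merge; gffread fuses introns < 4
CLOSE_EXON_MIN_INTRON = 4


@dataclass
class FilterSpec:
    """Predicates a transcript must all pass to survive filtering."""

    max_intron: int | None = None
    min_len: int | None = None
    range: tuple | None = None          # (seqid, start, end[, strand])
    range_contained: bool = False       # -R
    drop_single_exon: bool = False      # -U
    coding_only: bool = False           # -C
    noncoding_only: bool = False        # --nc
    drop_inframe_stop: bool = False     # -V (needs genome)
    canonical_splice_only: bool = False  # -N (needs genome)
    complete_cds_only: bool = False     # -J (needs genome)
    drop_pseudo: bool = False           # --no-pseudo

    def __post_init__(self) -> None:
        if self.coding_only and self.noncoding_only:
            raise ValueError("coding_only and noncoding_only are mutually "
                             "exclusive")

    @property
    def needs_genome(self) -> bool:
        return (self.drop_inframe_stop or self.canonical_splice_only
                or self.complete_cds_only)


def is_pseudogene(t: Transcript, parent_gene: Gene | None = None) -> bool:
    """Pseudogene evidence on the transcript or its parent gene record."""
    def check(ftype: str, attrs: dict) -> bool:
        if "pseudogene" in ftype.lower():
            return True
        for k in _PSEUDO_ATTR_KEYS:
            v = attrs.get(k)
            if v is None:
                continue
            if "pseudogene" in v.lower():
                return True
            if k == "pseudo" and v.lower() == "true":
                return True
        return False

    if check(t.feature_type, t.attributes):
        return True
    if parent_gene is not None and check(parent_gene.feature_type,
                                         parent_gene.attributes):
        return True
    return False


def filter_transcripts(annset: AnnotationSet, spec: FilterSpec,
                       genome=None) -> AnnotationSet:
    if spec.needs_genome and genome is None:
        raise ValueError("this filter configuration requires a genome (-g)")
    keep = []
    for t in annset:
        if spec.min_len is not None and t.exonic_length < spec.min_len:
            continue
        if spec.max_intron is not None and any(
                e - s + 1 > spec.max_intron for s, e in t.introns()):
            continue
        if spec.drop_single_exon and t.num_exons < 2:
            continue
        if spec.coding_only and not t.cds_segments:
            continue
        if spec.noncoding_only and t.cds_segments:
            continue
        if spec.drop_pseudo and is_pseudogene(
                t, annset.genes.get(t.gene_id) if t.gene_id else None):
            continue
        if spec.range is not None and not _range_ok(t, spec.range,
                                                    spec.range_contained):
            continue
        if spec.canonical_splice_only and t.num_exons >= 2 \
                and not _seq.has_canonical_splice_sites(t, genome):
            continue
        if (spec.drop_inframe_stop or spec.complete_cds_only) and t.cds_segments:
            status = _seq.validate_cds(t, genome)
            if spec.drop_inframe_stop and status.inframe_stop_positions:
                continue
            if spec.complete_cds_only and not status.is_complete:
                continue
        elif spec.complete_cds_only and not t.cds_segments:
            continue
        keep.append(t.id)
    return annset.subset(keep)


def _range_ok(t: Transcript, rng: tuple, contained: bool) -> bool:
    seqid, start, end = rng[0], rng[1], rng[2]
    strand = rng[3] if len(rng) > 3 and rng[3] else None
    if t.seqid != seqid:
        return False
    if strand and t.strand != strand:
        return False
    if contained:
        return start <= t.start and t.end <= end
    return t.start <= end and start <= t.end


# ---------------------------------------------------------------------------
# locus clustering

@dataclass
class Locus:
    """Connected component of same-strand, exon-overlapping transcripts."""

    id: str
    interval: GenomicInterval
    strand: str
    transcript_ids: list[str] = field(default_factory=list)
    gene_ids: list[str] = field(default_factory=list)


def _exonic_overlap_same_strand(a: Transcript, b: Transcript) -> bool:
    return (a.seqid == b.seqid and a.strand == b.strand
            and a.exonic_overlap(b) > 0)


def cluster_loci(annset: AnnotationSet, id_prefix: str = "RLOC") -> list[Locus]:
    """Group transcripts into loci: same strand, >=1 exonic base shared,
    closed transitively.  Unknown-strand transcripts form their own stratum.
    """
    loci: list[Locus] = []
    counter = 0
    for seqid in annset.seqid_order:
        txs = annset.by_seqid(seqid)
        for strand in ("+", "-", "."):
            group = [t for t in txs if t.strand == strand]
            for comp in _components(group, _exonic_overlap_same_strand):
                counter += 1
                comp.sort(key=lambda t: (t.start, t.end))
                iv = GenomicInterval(seqid, min(t.start for t in comp),
                                     max(t.end for t in comp), strand)
                gene_ids: list[str] = []
                for t in comp:
                    if t.gene_id and t.gene_id not in gene_ids:
                        gene_ids.append(t.gene_id)
                loci.append(Locus(
                    id=f"{id_prefix}_{counter:06d}", interval=iv, strand=strand,
                    transcript_ids=[t.id for t in comp], gene_ids=gene_ids))
    loci.sort(key=lambda l: (annset.seqid_order.index(l.interval.seqid),
                             l.interval.start))
    for i, l in enumerate(loci, 1):
        l.id = f"{id_prefix}_{i:06d}"
    return loci


def _components(items: list, joined) -> list[list]:
    """Connected components under the pairwise predicate ``joined``.

    Items are swept in coordinate order so only an active frontier is
    compared, but correctness does not depend on interval structure.
    """
    n = len(items)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    order = sorted(range(n), key=lambda i: (items[i].start, items[i].end))
    active: list[int] = []
    for idx in order:
        t = items[idx]
        active = [j for j in active if items[j].end >= t.start]
        for j in active:
            if joined(items[j], t):
                union(j, idx)
        active.append(idx)
    comps: dict[int, list] = {}
    for i in range(n):
        comps.setdefault(find(i), []).append(items[i])
    return list(comps.values())


# ---------------------------------------------------------------------------
# structural equivalence & redundancy

SINGLE_EXON_OVERLAP_FRACTION = 0.8


def transcripts_match(a: Transcript, b: Transcript,
                      se_fraction: float = SINGLE_EXON_OVERLAP_FRACTION) -> bool:
    """Structural equivalence: identical intron chains, or for a single-exon
    pair an overlap exceeding ``se_fraction`` of the longer transcript.
    A single-exon and a multi-exon transcript never match."""
    if a.seqid != b.seqid or a.strand != b.strand:
        return False
    if a.num_exons >= 2 and b.num_exons >= 2:
        return a.intron_chain() == b.intron_chain()
    if a.num_exons == 1 and b.num_exons == 1:
        longer = max(a.exonic_length, b.exonic_length)
        return a.exonic_overlap(b) > se_fraction * longer
    return False


def _is_subchain(small: tuple, big: tuple) -> int | None:
    """Index at which ``small`` occurs as a contiguous run of ``big``."""
    if not small or len(small) > len(big):
        return None
    for i in range(len(big) - len(small) + 1):
        if big[i:i + len(small)] == small:
            return i
    return None


def _redundant_in(t: Transcript, container: Transcript, mode: str) -> bool:
    """Is ``t`` made redundant by ``container`` under the given mode?

    merge (-M): identical intron chain, boundaries contained or equal.
    contain (-K): additionally a strict contiguous sub-chain with boundary
    containment.  relaxed (-Q): sub-chain (or single-exon 80% overlap)
    without requiring boundary containment.
    """
    if t.seqid != container.seqid or t.strand != container.strand:
        return False
    contained = (container.start <= t.start and t.end <= container.end)
    if t.num_exons >= 2 and container.num_exons >= 2:
        tc, cc = t.intron_chain(), container.intron_chain()
        if tc == cc:
            return contained if mode in ("merge", "contain") else True
        if mode == "merge":
            return False
        if _is_subchain(tc, cc) is None:
            return False
        return contained if mode == "contain" else True
    if t.num_exons == 1 and container.num_exons == 1:
        if mode in ("merge", "contain"):
            return contained and container.interval.overlaps(t.interval)
        longer = max(t.exonic_length, container.exonic_length)
        return t.exonic_overlap(container) > SINGLE_EXON_OVERLAP_FRACTION * longer
    if t.num_exons == 1 and container.num_exons >= 2:
        # empty intron chain trivially matches part of any chain
        if mode == "merge":
            return False
        if mode == "contain":
            return any(e.contains(t.exons[0]) for e in container.exons)
        return (t.exonic_overlap(container)
                > SINGLE_EXON_OVERLAP_FRACTION * t.exonic_length)
    return False


def _survivor_rank(t: Transcript):
    # longer first, then earlier start, then lexicographically smaller id
    return (-(t.end - t.start + 1), t.start, t.id)


def remove_redundant(annset: AnnotationSet, mode: str = "merge") -> AnnotationSet:
    """Discard transcripts redundant w.r.t. another transcript in their locus.

    Modes mirror gffread -M (merge), -M -K (contain), -M -Q [-K] (relaxed).
    Among exact structural equals the survivor is the longer transcript
    (ties: earlier start, then smaller id).
    """
    if mode not in ("merge", "contain", "relaxed"):
        raise ValueError(f"unknown redundancy mode {mode!r}")
    discard: set = set()
    for locus in cluster_loci(annset):
        members = sorted((annset.transcripts[i] for i in locus.transcript_ids),
                         key=_survivor_rank)
        for i, container in enumerate(members):
            if container.id in discard:
                continue
            for t in members[i + 1:]:
                if t.id in discard:
                    continue
                if _redundant_in(t, container, mode):
                    discard.add(t.id)
    return annset.subset([t.id for t in annset if t.id not in discard])


# ---------------------------------------------------------------------------
# per-transcript reshaping

def merge_close_exons(t: Transcript,
                      min_kept_intron: int = CLOSE_EXON_MIN_INTRON) -> Transcript:
    """Fuse consecutive exons separated by an intron shorter than
    ``min_kept_intron`` bases (gffread -Z default: introns < 4 fuse)."""
    if t.num_exons < 2:
        return t
    merged = [t.exons[0]]
    for e in t.exons[1:]:
        gap = e.start - merged[-1].end - 1
        if gap < min_kept_intron:
            last = merged.pop()
            merged.append(GenomicInterval(last.seqid, last.start, e.end,
                                          last.strand))
        else:
            merged.append(e)
    if len(merged) == t.num_exons:
        return t
    return t.copy(exons=merged)


def force_exons(t: Transcript) -> Transcript:
    """Give a CDS-only transcript exon features equal to its CDS segments."""
    if t.exons:
        return t
    return t.copy(exons=list(t.cds_segments))


def gene_to_exon(g: Gene) -> Transcript:
    """Turn a childless single-line gene into a one-exon transcript."""
    if g.interval is None:
        raise ValueError(f"gene {g.id} has no interval")
    iv = g.interval
    return Transcript(
        id=g.id, gene_id=g.id, gene_name=g.name,
        exons=[GenomicInterval(iv.seqid, iv.start, iv.end, iv.strand)],
        source=g.source, feature_type="transcript",
        attributes=dict(g.attributes))


# ---------------------------------------------------------------------------
# reference-sequence renaming

def rename_seqids(annset: AnnotationSet,
                  mapping: dict[str, str]) -> AnnotationSet:
    """Apply a two-column old-name -> new-name table to every feature."""
    def mv(iv: GenomicInterval) -> GenomicInterval:
        new = mapping.get(iv.seqid)
        if new is None:
            return iv
        return GenomicInterval(new, iv.start, iv.end, iv.strand)

    out = AnnotationSet()
    for g in annset.genes.values():
        out.add_gene(Gene(g.id, g.name,
                          mv(g.interval) if g.interval else None,
                          list(g.transcript_ids), g.feature_type, g.source,
                          dict(g.attributes)))
    for seqid in annset.seqid_order:
        for t in annset.by_seqid(seqid):
            out.add(t.copy(exons=[mv(e) for e in t.exons],
                           cds_segments=[mv(c) for c in t.cds_segments]))
    return out


# ---------------------------------------------------------------------------
# tabular output

_TABLE_FIELDS = {"@id", "@geneid", "@chr", "@start", "@end", "@strand",
                 "@numexons", "@exons", "@cds", "@covlen", "@cdslen"}


def _intervals_str(ivs) -> str:
    return ",".join(f"{i.start}-{i.end}" for i in ivs) or "."


def table_row(t: Transcript, attrlist: list[str]) -> list[str]:
    row = []
    for name in attrlist:
        if name == "@id":
            row.append(t.id)
        elif name == "@geneid":
            row.append(t.gene_id or ".")
        elif name == "@chr":
            row.append(t.seqid)
        elif name == "@start":
            row.append(str(t.start))
        elif name == "@end":
            row.append(str(t.end))
        elif name == "@strand":
            row.append(t.strand)
        elif name == "@numexons":
            row.append(str(t.num_exons))
        elif name == "@exons":
            row.append(_intervals_str(t.exons))
        elif name == "@cds":
            row.append(_intervals_str(t.cds_segments))
        elif name == "@covlen":
            row.append(str(t.exonic_length))
        elif name == "@cdslen":
            row.append(str(t.cds_length))
        elif name.startswith("@"):
            raise ValueError(f"unknown pseudo-attribute {name!r}")
        else:
            row.append(t.attributes.get(name, "."))
    return row


def to_table(annset: AnnotationSet, attrlist: list[str]) -> list[list[str]]:
    """One row per transcript, columns per ``attrlist`` (@-prefixed
    pseudo-attributes or plain attribute names; missing values render ".")."""
    rows = []
    for seqid in annset.seqid_order:
        for t in annset.by_seqid(seqid):
            rows.append(table_row(t, attrlist))
    return rows
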