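"""In-memory model for hierarchical transcript annotations.

All coordinates are 1-based inclusive (GFF native).  BED's 0-based
half-open convention is converted at the I/O boundary only.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field, replace


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A closed interval [start, end] on a named reference sequence."""

    seqid: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    strand: str = "."  # one of + - .

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(f"end {self.end} < start {self.start}")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"bad strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.seqid == other.seqid
            and self.start <= other.end
            and other.start <= self.end
        )

    def overlap_len(self, other: "GenomicInterval") -> int:
        if self.seqid != other.seqid:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start) + 1)

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.seqid == other.seqid
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass
class Transcript:
    """One transcript: exon chain, optional CDS segments, strand, attributes.

    Invariants: exons are non-overlapping, sorted by start, all on the same
    seqid/strand; the transcript span is [min exon start, max exon end];
    CDS segments lie within the exon union.
    """

    id: str
    exons: list[GenomicInterval]
    gene_id: str | None = None
    gene_name: str | None = None
    cds_segments: list[GenomicInterval] = field(default_factory=list)
    cds_phase: list[int] = field(default_factory=list)
    score: float | None = None
    source: str = "."
    feature_type: str = "mRNA"
    attributes: dict[str, str] = field(default_factory=dict)
    extra_children: list = field(default_factory=list)  # opaque sub-features

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons, key=lambda e: (e.start, e.end))
        self.cds_segments = sorted(self.cds_segments, key=lambda c: (c.start, c.end))
        if not self.exons and self.cds_segments:
            # CDS-only record: span still well defined via CDS
            pass
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start <= a.end:
                raise ValueError(f"overlapping exons in transcript {self.id}")

    # -- derived geometry ---------------------------------------------------

    @property
    def seqid(self) -> str:
        return (self.exons or self.cds_segments)[0].seqid

    @property
    def strand(self) -> str:
        return (self.exons or self.cds_segments)[0].strand

    @property
    def start(self) -> int:
        return (self.exons or self.cds_segments)[0].start

    @property
    def end(self) -> int:
        segs = self.exons or self.cds_segments
        return segs[-1].end

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.seqid, self.start, self.end, self.strand)

    @property
    def num_exons(self) -> int:
        return len(self.exons)

    @property
    def exonic_length(self) -> int:
        return sum(len(e) for e in self.exons)

    @property
    def cds_length(self) -> int:
        return sum(len(c) for c in self.cds_segments)

    def introns(self) -> list[tuple[int, int]]:
        """Intron intervals (1-based inclusive), in genomic order."""
        return [
            (a.end + 1, b.start - 1) for a, b in zip(self.exons, self.exons[1:])
        ]

    def intron_chain(self) -> tuple[tuple[int, int], ...]:
        return tuple(self.introns())

    def exonic_overlap(self, other: "Transcript") -> int:
        """Shared exonic bases with another transcript (same seqid)."""
        if self.seqid != other.seqid:
            return 0
        total = 0
        for a in self.exons:
            for b in other.exons:
                total += a.overlap_len(b)
        return total

    def copy(self, **changes) -> "Transcript":
        t = replace(
            self,
            exons=list(changes.pop("exons", self.exons)),
            cds_segments=list(changes.pop("cds_segments", self.cds_segments)),
            cds_phase=list(changes.pop("cds_phase", self.cds_phase)),
            attributes=dict(changes.pop("attributes", self.attributes)),
            extra_children=list(self.extra_children),
            **changes,
        )
        return t


@dataclass
class Gene:
    id: str
    name: str | None = None
    interval: GenomicInterval | None = None
    transcript_ids: list[str] = field(default_factory=list)
    feature_type: str = "gene"
    source: str = "."
    attributes: dict[str, str] = field(default_factory=dict)


class AnnotationSet:
    """Transcripts grouped by reference sequence with a coordinate-sorted index.

    ``seqid_order`` preserves first-encountered order, which is the default
    output block order.  The per-seqid index is sorted by (start, end) and
    supports binary-search overlap queries.
    """

    def __init__(self, transcripts=(), genes=(), seqid_order=None):
        self.transcripts: dict[str, Transcript] = {}
        self.genes: dict[str, Gene] = {}
        self.seqid_order: list[str] = list(seqid_order or [])
        self._index: dict[str, list[Transcript]] | None = None
        for g in genes:
            self.add_gene(g)
        for t in transcripts:
            self.add(t)

    def __len__(self) -> int:
        return len(self.transcripts)

    def __iter__(self):
        return iter(self.transcripts.values())

    def __contains__(self, tid: str) -> bool:
        return tid in self.transcripts

    def add(self, t: Transcript) -> None:
        if t.id in self.transcripts:
            raise ValueError(f"duplicate transcript id {t.id}")
        self.transcripts[t.id] = t
        if t.seqid not in self.seqid_order:
            self.seqid_order.append(t.seqid)
        if t.gene_id:
            g = self.genes.get(t.gene_id)
            if g is not None and t.id not in g.transcript_ids:
                g.transcript_ids.append(t.id)
        self._index = None

    def add_gene(self, g: Gene) -> None:
        self.genes[g.id] = g

    def remove(self, tid: str) -> None:
        del self.transcripts[tid]
        self._index = None

    def subset(self, tids) -> "AnnotationSet":
        keep = set(tids)
        out = AnnotationSet(seqid_order=list(self.seqid_order))
        for g in self.genes.values():
            out.add_gene(
                Gene(g.id, g.name, g.interval,
                     [i for i in g.transcript_ids if i in keep],
                     g.feature_type, g.source, dict(g.attributes))
            )
        for t in self.transcripts.values():
            if t.id in keep:
                out.add(t)
        out.seqid_order = [s for s in self.seqid_order
                           if any(t.seqid == s for t in out)] or []
        return out

    # -- sorted index / overlap queries -------------------------------------

    def _ensure_index(self) -> dict[str, list[Transcript]]:
        if self._index is None:
            idx: dict[str, list[Transcript]] = {}
            for t in self.transcripts.values():
                idx.setdefault(t.seqid, []).append(t)
            for lst in idx.values():
                lst.sort(key=lambda t: (t.start, t.end))
            self._index = idx
        return self._index

    def by_seqid(self, seqid: str) -> list[Transcript]:
        return list(self._ensure_index().get(seqid, []))

    def overlap_candidates(self, interval: GenomicInterval) -> list[Transcript]:
        """All transcripts whose span shares >= 1 base with ``interval``.

        Binary search narrows the left edge; because spans sorted by start can
        still reach arbitrarily far right, a max-end prefix scan bounds the
        walk-back.
        """
        lst = self._ensure_index().get(interval.seqid, [])
        if not lst:
            return []
        starts = [t.start for t in lst]
        hi = bisect.bisect_right(starts, interval.end)
        out = [t for t in lst[:hi] if t.end >= interval.start]
        return out
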