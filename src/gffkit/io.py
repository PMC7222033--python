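"""Readers and writers for GFF3, GTF and BED12 transcript annotations.

The parser is tolerant of unsorted and unordered input: hierarchically
linked features (gene -> transcript -> exon/CDS) may arrive in any order
and are linked after the whole stream has been read.  Internal coordinates
are always 1-based inclusive; BED is converted at this boundary.
"""

from __future__ import annotations

import io as _io
import re
import sys
from dataclasses import dataclass, field
from urllib.parse import unquote

from .model import AnnotationSet, Gene, GenomicInterval, Transcript

# feature types recognised as transcript containers even without exon children
_TX_TYPE_RE = re.compile(
    r"(^mRNA$|transcript$|^t?RNA|RNA$|^ncRNA|^primary_transcript$)", re.IGNORECASE
)
_GFF3_ESCAPE = {";": "%3B", "=": "%3D", "%": "%25", "&": "%26", ",": "%2C"}


class ParseError(ValueError):
    pass


@dataclass
class Diagnostics:
    """Per-line parser messages; ``strict`` turns malformed lines fatal."""

    strict: bool = False
    verbose: bool = False
    messages: list[str] = field(default_factory=list)

    def warn(self, msg: str, lineno: int | None = None) -> None:
        text = f"line {lineno}: {msg}" if lineno is not None else msg
        self.messages.append(text)
        if self.verbose:
            print(f"Warning: {text}", file=sys.stderr)

    def error(self, msg: str, lineno: int | None = None) -> None:
        if self.strict:
            raise ParseError(f"line {lineno}: {msg}" if lineno else msg)
        self.warn(msg, lineno)


@dataclass
class OutputOptions:
    keep_attrs: bool = False        # -F: preserve all original attributes
    keep_genes: bool = False        # also emit gene records
    transcript_feature: str | None = None  # force feature type on output


# ---------------------------------------------------------------------------
# attribute field parsing

def parse_gff3_attributes(text: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for part in text.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        if "=" in part:
            k, _, v = part.partition("=")
            attrs[k.strip()] = unquote(v.strip())
        else:
            attrs[part] = "true"
    return attrs


def parse_gtf_attributes(text: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for m in re.finditer(r'(\w+)\s+(?:"([^"]*)"|([^;]+))\s*;?', text.strip()):
        key = m.group(1)
        val = m.group(2) if m.group(2) is not None else m.group(3).strip()
        if key not in attrs:
            attrs[key] = val
    return attrs


def _encode_gff3_value(v: str) -> str:
    return "".join(_GFF3_ESCAPE.get(c, c) for c in v)


# ---------------------------------------------------------------------------
# format sniffing

def sniff_format(text: str) -> str:
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("##gff-version"):
            return "gff3"
        if line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) >= 9 and fields[3].isdigit() and fields[4].isdigit():
            if 'transcript_id "' in fields[8] or re.search(r'\w+ "', fields[8]):
                return "gtf"
            return "gff3"
        if len(fields) >= 3 and fields[1].isdigit() and fields[2].isdigit():
            return "bed"
        if len(fields) == 9:
            return "gff3"
    raise ParseError("cannot determine annotation format from content")


# ---------------------------------------------------------------------------
# raw GFF/GTF line records

@dataclass
class _Rec:
    lineno: int
    seqid: str
    source: str
    ftype: str
    start: int
    end: int
    score: float | None
    strand: str
    frame: str
    attrs: dict[str, str]


def _read_records(stream, attr_parser, diag: Diagnostics) -> list[_Rec]:
    recs = []
    for lineno, line in enumerate(stream, 1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9:
            diag.error(f"expected 9 tab-separated fields, got {len(fields)}", lineno)
            continue
        try:
            start, end = int(fields[3]), int(fields[4])
        except ValueError:
            diag.error(f"malformed coordinates {fields[3]!r}..{fields[4]!r}", lineno)
            continue
        if start < 1 or end < start:
            diag.error(f"invalid coordinate range {start}..{end}", lineno)
            continue
        score = None
        if fields[5] not in (".", ""):
            try:
                score = float(fields[5])
            except ValueError:
                diag.error(f"malformed score {fields[5]!r}", lineno)
        strand = fields[6] if fields[6] in ("+", "-") else "."
        recs.append(
            _Rec(lineno, fields[0], fields[1], fields[2], start, end,
                 score, strand, fields[7], attr_parser(fields[8]))
        )
    return recs


# ---------------------------------------------------------------------------
# GFF3

def _is_gene_type(ftype: str) -> bool:
    return "gene" in ftype.lower()


def _unique_id(base: str, taken: set, diag: Diagnostics, lineno: int) -> str:
    if base not in taken:
        return base
    n = 1
    while f"{base}.d{n}" in taken:
        n += 1
    newid = f"{base}.d{n}"
    diag.warn(f"duplicate ID {base!r} renamed to {newid!r}", lineno)
    return newid


def _build_transcript(tid, container, exons, cds, diag) -> Transcript | None:
    """Assemble one Transcript from collected child records."""
    strands = {r.strand for r in exons} | {r.strand for r in cds}
    if container is not None:
        strands.add(container.strand)
    strands.discard(".")
    if len(strands) > 1:
        diag.error(f"transcript {tid}: exons on mixed strands, record rejected")
        return None
    strand = strands.pop() if strands else "."
    seqids = {r.seqid for r in exons} | {r.seqid for r in cds}
    if container is not None:
        seqids.add(container.seqid)
    if len(seqids) > 1:
        diag.error(f"transcript {tid}: features on multiple sequences, rejected")
        return None

    def mk(recs):
        ivs = sorted((r.start, r.end) for r in recs)
        merged: list[list[int]] = []
        for s, e in ivs:
            if merged and s <= merged[-1][1] + 0:  # exact duplicates/overlaps fuse
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        return [GenomicInterval(seqids_pop, s, e, strand) for s, e in merged]

    seqids_pop = next(iter(seqids)) if seqids else None
    exon_ivs = mk(exons)
    cds_recs = sorted(cds, key=lambda r: (r.start, r.end))
    cds_ivs = [GenomicInterval(seqids_pop, r.start, r.end, strand) for r in cds_recs]
    phases = []
    for r in cds_recs:
        phases.append(int(r.frame) if r.frame in ("0", "1", "2") else 0)
    if not exon_ivs and not cds_ivs:
        if container is None:
            return None
        exon_ivs = [GenomicInterval(container.seqid, container.start,
                                    container.end, strand)]
    attrs = {}
    score = None
    source = "."
    ftype = "mRNA"
    if container is not None:
        attrs = {k: v for k, v in container.attrs.items()
                 if k not in ("ID", "Parent")}
        score = container.score
        source = container.source
        ftype = container.ftype
    return Transcript(
        id=tid, exons=exon_ivs, cds_segments=cds_ivs, cds_phase=phases,
        score=score, source=source, feature_type=ftype, attributes=attrs,
    )


def parse_gff3(stream, diag: Diagnostics | None = None) -> AnnotationSet:
    diag = diag or Diagnostics()
    recs = _read_records(stream, parse_gff3_attributes, diag)

    by_id: dict[str, _Rec] = {}
    dup_alias: dict[int, str] = {}  # lineno -> effective id for duplicated IDs
    dup_base: dict[str, str] = {}   # effective id -> original duplicated ID
    for r in recs:
        rid = r.attrs.get("ID")
        if rid is None:
            continue
        if rid in by_id:
            eff = _unique_id(rid, set(by_id), diag, r.lineno)
            dup_alias[r.lineno] = eff
            dup_base[eff] = rid
            dup_base.setdefault(rid, rid)
            by_id[eff] = r
        else:
            by_id[rid] = r

    def eff_id(r: _Rec) -> str | None:
        if r.lineno in dup_alias:
            return dup_alias[r.lineno]
        return r.attrs.get("ID")

    # children grouped by parent; multi-parent features duplicated per parent
    children: dict[str, list[_Rec]] = {}
    top: list[_Rec] = []
    for r in recs:
        parents = r.attrs.get("Parent")
        if parents:
            for p in parents.split(","):
                children.setdefault(p, []).append(r)
        else:
            top.append(r)

    # a record is a transcript if exon/CDS children reference it, or its type
    # looks transcript-like; a record is a gene if its type says so or a
    # transcript references it
    tx_ids: list[str] = []
    seen_tx: set = set()

    def mark_tx(tid: str) -> None:
        if tid not in seen_tx:
            seen_tx.add(tid)
            tx_ids.append(tid)

    for pid, kids in children.items():
        if any(k.ftype.lower() in ("exon", "cds") for k in kids):
            parent_rec = by_id.get(pid)
            if parent_rec is not None and _is_gene_type(parent_rec.ftype) and not any(
                _TX_TYPE_RE.search(k.ftype) for k in kids
            ):
                # exons attached straight to a gene: treat the gene as its
                # own single transcript container
                mark_tx(pid)
            else:
                mark_tx(pid)
    for r in recs:
        rid = eff_id(r)
        if rid and _TX_TYPE_RE.search(r.ftype) and not _is_gene_type(r.ftype):
            mark_tx(rid)

    gene_ids = [eff_id(r) for r in recs
                if eff_id(r) and _is_gene_type(r.ftype) and eff_id(r) not in seen_tx]

    out = AnnotationSet()
    for gid in gene_ids:
        gr = by_id[gid]
        out.add_gene(Gene(
            id=gid,
            name=gr.attrs.get("Name") or gr.attrs.get("gene_name"),
            interval=GenomicInterval(gr.seqid, gr.start, gr.end, gr.strand),
            feature_type=gr.ftype, source=gr.source,
            attributes={k: v for k, v in gr.attrs.items()
                        if k not in ("ID", "Parent")},
        ))

    # orphan exons: Parent never defined and never marked transcript-like
    for pid, kids in children.items():
        if pid not in by_id and pid not in seen_tx:
            if any(k.ftype.lower() in ("exon", "cds") for k in kids):
                diag.warn(f"features reference unknown Parent {pid!r}; "
                          "building transcript from orphans")
                mark_tx(pid)

    taken_tids: set = set()
    for tid in tx_ids:
        container = by_id.get(tid)
        kids = children.get(tid, [])
        if tid in dup_base:
            # ID was duplicated: children referencing the shared Parent are
            # attributed to the container on the same reference sequence
            base = dup_base[tid]
            if container is not None:
                kids = [k for k in children.get(base, [])
                        if k.seqid == container.seqid]
        # also mark duplicated container ids as transcripts
        for eff, base in dup_base.items():
            if base == tid and eff not in seen_tx and eff != tid:
                mark_tx(eff)
        exon_recs = [k for k in kids if k.ftype.lower() == "exon"]
        cds_recs = [k for k in kids if k.ftype.lower() == "cds"]
        other = [k for k in kids if k.ftype.lower() not in ("exon", "cds")]
        t = _build_transcript(tid, container, exon_recs, cds_recs, diag)
        if t is None:
            continue
        final_id = _unique_id(tid, taken_tids, diag,
                              container.lineno if container else 0)
        taken_tids.add(final_id)
        t.id = final_id
        # link to parent gene
        parent = container.attrs.get("Parent") if container else None
        if parent and (parent in out.genes or parent in by_id):
            t.gene_id = parent.split(",")[0]
            g = out.genes.get(t.gene_id)
            if g is not None:
                t.gene_name = g.name
        if t.gene_id is None:
            t.gene_id = t.attributes.get("geneID") or t.attributes.get("gene_id")
        if t.gene_name is None:
            t.gene_name = t.attributes.get("gene_name")
        t.extra_children = [
            (k.ftype, k.start, k.end, k.strand, k.frame,
             {a: v for a, v in k.attrs.items() if a != "Parent"})
            for k in other
        ]
        out.add(t)
    return out


# ---------------------------------------------------------------------------
# GTF

def parse_gtf(stream, diag: Diagnostics | None = None) -> AnnotationSet:
    diag = diag or Diagnostics()
    recs = _read_records(stream, parse_gtf_attributes, diag)

    order: list[str] = []
    exon_map: dict[str, list[_Rec]] = {}
    cds_map: dict[str, list[_Rec]] = {}
    meta: dict[str, _Rec] = {}
    gene_recs: dict[str, _Rec] = {}
    for r in recs:
        ft = r.ftype.lower()
        if ft == "gene":
            gid = r.attrs.get("gene_id")
            if gid:
                gene_recs[gid] = r
            continue
        tid = r.attrs.get("transcript_id")
        if tid is None:
            diag.error("GTF record lacks transcript_id", r.lineno)
            continue
        if tid not in exon_map and tid not in cds_map and tid not in meta:
            order.append(tid)
        if ft == "exon":
            exon_map.setdefault(tid, []).append(r)
        elif ft == "cds":
            cds_map.setdefault(tid, []).append(r)
        elif ft in ("transcript", "mrna"):
            meta[tid] = r
        # start_codon/stop_codon/UTR lines contribute no structure here

    out = AnnotationSet()
    for gid, gr in gene_recs.items():
        out.add_gene(Gene(
            id=gid, name=gr.attrs.get("gene_name"),
            interval=GenomicInterval(gr.seqid, gr.start, gr.end, gr.strand),
            source=gr.source,
            attributes={k: v for k, v in gr.attrs.items() if k != "gene_id"},
        ))

    taken: set = set()
    for tid in order:
        exons = exon_map.get(tid, [])
        cds = cds_map.get(tid, [])
        container = meta.get(tid)
        t = _build_transcript(tid, container, exons, cds, diag)
        if t is None:
            continue
        src_rec = container or (exons + cds)[0]
        attrs = {k: v for k, v in src_rec.attrs.items()
                 if k not in ("transcript_id", "gene_id")}
        t.attributes = attrs
        t.feature_type = "mRNA" if t.cds_segments else "transcript"
        t.source = src_rec.source
        if container:
            t.score = container.score
        final_id = _unique_id(tid, taken, diag, src_rec.lineno)
        taken.add(final_id)
        t.id = final_id
        t.gene_id = src_rec.attrs.get("gene_id")
        t.gene_name = attrs.get("gene_name")
        if t.gene_id and t.gene_id not in out.genes and t.gene_id in gene_recs:
            pass
        out.add(t)
    return out


# ---------------------------------------------------------------------------
# BED

def parse_bed(stream, diag: Diagnostics | None = None) -> AnnotationSet:
    diag = diag or Diagnostics()
    out = AnnotationSet()
    taken: set = set()
    n_anon = 0
    for lineno, line in enumerate(stream, 1):
        line = line.rstrip("\n")
        if (not line or line.startswith(("#", "track", "browser"))):
            continue
        f = line.split("\t")
        if len(f) < 3:
            diag.error("BED line has fewer than 3 columns", lineno)
            continue
        try:
            chrom_start, chrom_end = int(f[1]), int(f[2])
        except ValueError:
            diag.error(f"malformed BED coordinates {f[1]!r},{f[2]!r}", lineno)
            continue
        if chrom_end <= chrom_start:
            diag.error(f"empty/negative BED interval {chrom_start}..{chrom_end}",
                       lineno)
            continue
        name = f[3] if len(f) > 3 and f[3] not in ("", ".") else None
        if name is None:
            n_anon += 1
            name = f"bed_{n_anon}"
        score = None
        if len(f) > 4 and f[4] not in (".", ""):
            try:
                score = float(f[4])
            except ValueError:
                pass
        strand = f[5] if len(f) > 5 and f[5] in ("+", "-") else "."
        start1 = chrom_start + 1  # to 1-based inclusive
        end1 = chrom_end

        exons: list[GenomicInterval] = []
        if len(f) >= 12:
            try:
                count = int(f[9])
                sizes = [int(x) for x in f[10].rstrip(",").split(",")]
                offs = [int(x) for x in f[11].rstrip(",").split(",")]
            except ValueError:
                diag.error("malformed BED block columns", lineno)
                continue
            if not (len(sizes) == len(offs) == count):
                diag.error("BED blockCount disagrees with block lists", lineno)
                continue
            for sz, off in zip(sizes, offs):
                es = chrom_start + off + 1
                exons.append(GenomicInterval(f[0], es, es + sz - 1, strand))
        else:
            exons = [GenomicInterval(f[0], start1, end1, strand)]

        cds: list[GenomicInterval] = []
        if len(f) >= 8:
            try:
                thick_s, thick_e = int(f[6]), int(f[7])
            except ValueError:
                thick_s = thick_e = chrom_start
            if thick_e > thick_s:
                ts1, te1 = thick_s + 1, thick_e
                for e in exons:
                    s = max(e.start, ts1)
                    en = min(e.end, te1)
                    if s <= en:
                        cds.append(GenomicInterval(f[0], s, en, strand))
        tid = name
        if tid in taken:
            tid = _unique_id(tid, taken, diag, lineno)
        taken.add(tid)
        out.add(Transcript(id=tid, exons=exons, cds_segments=cds,
                           cds_phase=_phases_for(cds, strand),
                           score=score, source="bed",
                           feature_type="mRNA" if cds else "transcript"))
    return out


def _phases_for(cds: list[GenomicInterval], strand: str) -> list[int]:
    """Frame column for each CDS segment assuming translation starts in frame."""
    if not cds:
        return []
    phases = [0] * len(cds)
    order = range(len(cds)) if strand != "-" else range(len(cds) - 1, -1, -1)
    consumed = 0
    for i in order:
        phases[i] = (3 - consumed % 3) % 3
        consumed += len(cds[i])
    return phases


# ---------------------------------------------------------------------------
# unified entry points

def parse_annotation(source, format: str = "auto",
                     diag: Diagnostics | None = None) -> AnnotationSet:
    """Parse GFF3, GTF or BED from a path, text, or open stream."""
    if hasattr(source, "read"):
        text = source.read()
    elif isinstance(source, str) and ("\n" in source or "\t" in source):
        text = source
    else:
        with open(source) as fh:
            text = fh.read()
    fmt = sniff_format(text) if format == "auto" else format
    stream = _io.StringIO(text)
    if fmt == "gff3":
        return parse_gff3(stream, diag)
    if fmt == "gtf":
        return parse_gtf(stream, diag)
    if fmt == "bed":
        return parse_bed(stream, diag)
    raise ValueError(f"unknown format {fmt!r}")


# ---------------------------------------------------------------------------
# writers

def _iter_sorted(annset: AnnotationSet):
    for seqid in annset.seqid_order:
        for t in annset.by_seqid(seqid):
            yield t


def _basic_attrs_gff3(t: Transcript) -> str:
    parts = [f"ID={_encode_gff3_value(t.id)}"]
    if t.gene_id:
        parts.append(f"geneID={_encode_gff3_value(t.gene_id)}")
    if t.gene_name:
        parts.append(f"gene_name={_encode_gff3_value(t.gene_name)}")
    return ";".join(parts)


def write_gff3(annset: AnnotationSet, options: OutputOptions | None = None) -> str:
    opt = options or OutputOptions()
    lines = ["##gff-version 3"]
    written_genes: set = set()
    for t in _iter_sorted(annset):
        if opt.keep_genes and t.gene_id and t.gene_id in annset.genes \
                and t.gene_id not in written_genes:
            g = annset.genes[t.gene_id]
            iv = g.interval or t.interval
            gattrs = [f"ID={_encode_gff3_value(g.id)}"]
            if g.name:
                gattrs.append(f"Name={_encode_gff3_value(g.name)}")
            lines.append("\t".join([
                iv.seqid, g.source, g.feature_type, str(iv.start), str(iv.end),
                ".", iv.strand, ".", ";".join(gattrs)]))
            written_genes.add(g.id)
        attrs = _basic_attrs_gff3(t)
        if opt.keep_attrs:
            extra = ";".join(
                f"{k}={_encode_gff3_value(v)}" for k, v in t.attributes.items()
                if k not in ("ID", "Parent", "geneID", "gene_name")
            )
            if extra:
                attrs = attrs + ";" + extra
        score = "." if t.score is None else _fmt_score(t.score)
        parent = f"Parent={_encode_gff3_value(t.gene_id)};" \
            if (opt.keep_genes and t.gene_id in written_genes) else ""
        lines.append("\t".join([
            t.seqid, t.source, t.feature_type, str(t.start), str(t.end),
            score, t.strand, ".", (parent + attrs) if parent else attrs]))
        for e in t.exons:
            lines.append("\t".join([
                t.seqid, t.source, "exon", str(e.start), str(e.end),
                ".", t.strand, ".", f"Parent={_encode_gff3_value(t.id)}"]))
        for c, ph in zip(t.cds_segments,
                         t.cds_phase or [0] * len(t.cds_segments)):
            lines.append("\t".join([
                t.seqid, t.source, "CDS", str(c.start), str(c.end),
                ".", t.strand, str(ph), f"Parent={_encode_gff3_value(t.id)}"]))
    return "\n".join(lines) + "\n"


def _fmt_score(s: float) -> str:
    return str(int(s)) if float(s).is_integer() else f"{s:g}"


def _gtf_attrs(t: Transcript, keep: bool) -> str:
    gid = t.gene_id or t.id
    parts = [f'transcript_id "{t.id}"', f'gene_id "{gid}"']
    if t.gene_name:
        parts.append(f'gene_name "{t.gene_name}"')
    if keep:
        for k, v in t.attributes.items():
            if k not in ("transcript_id", "gene_id", "gene_name"):
                parts.append(f'{k} "{v}"')
    return "; ".join(parts) + ";"


def write_gtf(annset: AnnotationSet, options: OutputOptions | None = None) -> str:
    opt = options or OutputOptions()
    lines = []
    for t in _iter_sorted(annset):
        attrs = _gtf_attrs(t, opt.keep_attrs)
        score = "." if t.score is None else _fmt_score(t.score)
        lines.append("\t".join([
            t.seqid, t.source, "transcript", str(t.start), str(t.end),
            score, t.strand, ".", attrs]))
        for e in t.exons:
            lines.append("\t".join([
                t.seqid, t.source, "exon", str(e.start), str(e.end),
                ".", t.strand, ".", attrs]))
        for c, ph in zip(t.cds_segments,
                         t.cds_phase or [0] * len(t.cds_segments)):
            lines.append("\t".join([
                t.seqid, t.source, "CDS", str(c.start), str(c.end),
                ".", t.strand, str(ph), attrs]))
    return "\n".join(lines) + "\n"


def write_bed(annset: AnnotationSet, options: OutputOptions | None = None) -> str:
    lines = []
    for t in _iter_sorted(annset):
        chrom_start = t.start - 1
        chrom_end = t.end
        if t.cds_segments:
            thick_s = t.cds_segments[0].start - 1
            thick_e = t.cds_segments[-1].end
        else:
            thick_s = thick_e = chrom_start
        sizes = ",".join(str(len(e)) for e in t.exons) + ","
        offs = ",".join(str(e.start - 1 - chrom_start) for e in t.exons) + ","
        score = "0" if t.score is None else _fmt_score(t.score)
        lines.append("\t".join([
            t.seqid, str(chrom_start), str(chrom_end), t.id, score, t.strand,
            str(thick_s), str(thick_e), "0", str(len(t.exons)), sizes, offs]))
    return "\n".join(lines) + "\n"


def write_annotation(annset: AnnotationSet, format: str = "gff3",
                     options: OutputOptions | None = None) -> str:
    if format == "gff3":
        return write_gff3(annset, options)
    if format == "gtf":
        return write_gtf(annset, options)
    if format == "bed":
        return write_bed(annset, options)
    raise ValueError(f"unknown output format {format!r}")


# ---------------------------------------------------------------------------
# sorting

def sort_annotation(annset: AnnotationSet, mode: str = "default",
                    name_list: list[str] | None = None,
                    diag: Diagnostics | None = None) -> AnnotationSet:
    """Reorder reference-sequence blocks; transcripts within a block are
    always coordinate-sorted (the writers enforce that)."""
    diag = diag or Diagnostics()
    order = list(annset.seqid_order)
    if mode == "alpha":
        order = sorted(order)
    elif mode == "by_list":
        if name_list is None:
            raise ValueError("by_list sorting requires a name list")
        listed = [s for s in name_list if s in order]
        missing = [s for s in order if s not in name_list]
        for s in missing:
            diag.warn(f"reference sequence {s!r} absent from sort list; "
                      "placed after listed sequences")
        order = listed + missing
    elif mode != "default":
        raise ValueError(f"unknown sort mode {mode!r}")
    out = AnnotationSet(seqid_order=order)
    for g in annset.genes.values():
        out.add_gene(g)
    for t in annset.transcripts.values():
        out.add(t)
    out.seqid_order = order + [s for s in out.seqid_order if s not in order]
    return out
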