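"""Deterministic synthetic genomes, reference annotations and perturbed
query sets with known expected class codes.

The generator builds non-overlapping gene territories on a random genome,
plants canonical splice dinucleotides (GT..AG on the transcript strand)
at every intron and a valid ATG..STOP coding sequence where requested,
then derives query transcripts by structural perturbations whose class
code against the reference is known by construction.  Every piece of
randomness flows from one explicit seed.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from .model import AnnotationSet, Gene, GenomicInterval, Transcript
from .seq import reverse_complement

_BASES = "ACGT"
# codons that can never introduce an in-frame stop
_SAFE_CODONS = ["GCT", "GCC", "AAA", "GAA", "CTG", "TTC", "GGT", "CCA",
                "ATG", "TCT", "CAT", "CGT"]


class GenomeBuilder:
    """Mutable random genome that transcripts can patch (splice sites,
    start/stop codons, soft-masked tracts) before freezing to FASTA."""

    def __init__(self, seed: int, lengths: dict[str, int]):
        rng = random.Random(seed)
        self.seqs = {name: [rng.choice(_BASES) for _ in range(n)]
                     for name, n in lengths.items()}

    def set(self, name: str, pos: int, bases: str) -> None:
        """Overwrite bases starting at 1-based position ``pos``."""
        s = self.seqs[name]
        for i, b in enumerate(bases):
            s[pos - 1 + i] = b

    def get(self, name: str, start: int, end: int) -> str:
        return "".join(self.seqs[name][start - 1:end])

    def softmask(self, name: str, start: int, end: int) -> None:
        s = self.seqs[name]
        for i in range(start - 1, end):
            s[i] = s[i].lower()

    def length(self, name: str) -> int:
        return len(self.seqs[name])

    def fasta(self, width: int = 60) -> str:
        out = []
        for name, s in self.seqs.items():
            out.append(f">{name}")
            text = "".join(s)
            for i in range(0, len(text), width):
                out.append(text[i:i + width])
        return "\n".join(out) + "\n"


def make_genome(seed: int, n_seqs: int = 1,
                lengths: list[int] | None = None) -> str:
    """Random uppercase A/C/G/T multi-FASTA, reproducible for a fixed seed."""
    lengths = lengths or [10000] * n_seqs
    builder = GenomeBuilder(seed, {f"chr{i + 1}": n
                                   for i, n in enumerate(lengths)})
    return builder.fasta()


# ---------------------------------------------------------------------------
# reference generation

GENE_SPAN_BUDGET = 4000
GENE_GAP = 9000  # leaves room for run-on/intergenic placements


def _plant_transcript(builder: GenomeBuilder, t: Transcript) -> None:
    """Patch canonical splice sites and (if coding) a valid CDS."""
    name = t.seqid
    for (s, e) in t.introns():
        if t.strand == "-":
            builder.set(name, s, "CT")
            builder.set(name, e - 1, "AC")
        else:
            builder.set(name, s, "GT")
            builder.set(name, e - 1, "AG")
    if t.cds_segments:
        total = sum(len(c) for c in t.cds_segments)
        rng = random.Random(hash(t.id) & 0x7FFFFFFF)
        n_codons = total // 3
        body = "".join(rng.choice(_SAFE_CODONS)
                       for _ in range(max(0, n_codons - 2)))
        coding = ("ATG" + body + "TAA")[:total]
        # write the coding-strand sequence back through the segments
        if t.strand == "-":
            genomic = reverse_complement(coding)
        else:
            genomic = coding
        offset = 0
        for c in t.cds_segments:
            builder.set(name, c.start, genomic[offset:offset + len(c)])
            offset += len(c)


def make_reference(seed: int, builder: GenomeBuilder | None = None,
                   n_genes: int = 5, isoforms_per_gene: int = 1,
                   seq_name: str = "chr1", coding: bool = True,
                   exons_per_transcript: tuple[int, int] = (3, 5),
                   start_offset: int = 3000) -> AnnotationSet:
    """Reference annotation with non-overlapping gene territories.

    When a GenomeBuilder is given, splice sites and CDS content are planted
    so the transcripts validate as complete under CDS checking.
    """
    rng = random.Random(seed)
    annset = AnnotationSet()
    pos = start_offset
    for gi in range(n_genes):
        strand = rng.choice("+-")
        gid = f"G{gi + 1:03d}"
        n_exons = rng.randint(*exons_per_transcript)
        exon_lens = [rng.randint(120, 300) for _ in range(n_exons)]
        intron_lens = [rng.randint(80, 400) for _ in range(n_exons - 1)]
        exons = []
        p = pos
        for i, el in enumerate(exon_lens):
            exons.append(GenomicInterval(seq_name, p, p + el - 1, strand))
            p += el
            if i < n_exons - 1:
                p += intron_lens[i]
        gene_end = exons[-1].end
        if builder is not None and gene_end > builder.length(seq_name):
            raise ValueError("gene territories do not fit in the genome")
        for iso in range(isoforms_per_gene):
            tid = f"{gid}.{iso + 1}"
            iso_exons = list(exons)
            if iso > 0 and n_exons >= 3:
                # alternate isoform: skip one internal exon
                drop = 1 + (iso - 1) % (n_exons - 2)
                iso_exons = [e for i, e in enumerate(exons) if i != drop]
            cds = []
            # only the first isoform carries a CDS: planted coding content
            # for overlapping isoforms would overwrite each other
            if coding and iso == 0:
                cds_len_target = (sum(len(e) for e in iso_exons) // 2) // 3 * 3
                cds = _carve_cds(iso_exons, cds_len_target, strand)
            t = Transcript(
                id=tid, gene_id=gid, gene_name=f"gene{gi + 1}",
                exons=iso_exons, cds_segments=cds,
                cds_phase=_phases(cds, strand),
                source="sim", feature_type="mRNA" if cds else "transcript",
            )
            if builder is not None:
                _plant_transcript(builder, t)
            annset.add_gene(annset.genes.get(gid) or Gene(
                id=gid, name=f"gene{gi + 1}",
                interval=GenomicInterval(seq_name, exons[0].start, gene_end,
                                         strand)))
            annset.add(t)
        pos = gene_end + GENE_GAP
    return annset


def _carve_cds(exons, target_len, strand):
    """CDS segments of total length ``target_len`` centred in the exon
    chain, starting 30 bases into the 5' terminal exon."""
    order = exons if strand != "-" else list(reversed(exons))
    segs = []
    remaining = target_len
    first = True
    for e in order:
        if remaining <= 0:
            break
        if strand != "-":
            s = e.start + (30 if first else 0)
            avail = e.end - s + 1
            take = min(avail, remaining)
            segs.append(GenomicInterval(e.seqid, s, s + take - 1, strand))
        else:
            en = e.end - (30 if first else 0)
            avail = en - e.start + 1
            take = min(avail, remaining)
            segs.append(GenomicInterval(e.seqid, en - take + 1, en, strand))
        remaining -= take
        first = False
    segs.sort(key=lambda c: c.start)
    return segs


def _phases(cds, strand):
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
# query perturbations

@dataclass
class PerturbationSpec:
    """One structural perturbation and the class code it must produce."""

    operation: str
    expected_code: str
    params: dict = field(default_factory=dict)


def default_spec_list() -> list[PerturbationSpec]:
    """One spec per class code, covering the full 15-code table."""
    return [
        PerturbationSpec("exact_copy", "="),
        PerturbationSpec("containment_fragment", "c"),
        PerturbationSpec("reverse_containment", "k"),
        PerturbationSpec("retain_intron", "m", {"k": 0}),
        PerturbationSpec("retain_plus_novel", "n"),
        PerturbationSpec("shift_intron", "j", {"k": 0, "delta": 18}),
        PerturbationSpec("shift_into_intron", "e", {"intrusion": 50}),
        PerturbationSpec("upstream_extension", "o"),
        PerturbationSpec("strand_flip", "s"),
        PerturbationSpec("opposite_strand_exon", "x"),
        PerturbationSpec("within_intron", "i"),
        PerturbationSpec("bridge_reference", "y"),
        PerturbationSpec("downstream_offset", "p", {"d": 500}),
        PerturbationSpec("softmask_fraction", "r", {"f": 0.6}),
        PerturbationSpec("intergenic", "u"),
    ]


def _flip(iv: GenomicInterval) -> GenomicInterval:
    return GenomicInterval(iv.seqid, iv.start, iv.end,
                           "-" if iv.strand == "+" else "+")


def _multi_exon_refs(reference: AnnotationSet, min_exons: int = 3):
    return [t for t in reference if t.num_exons >= min_exons]


def make_query(reference: AnnotationSet,
               specs: list[PerturbationSpec] | None = None,
               seed: int = 0, builder: GenomeBuilder | None = None
               ) -> tuple[AnnotationSet, dict[str, str]]:
    """Perturbed query set plus a ledger mapping query id -> expected code.

    Specs needing a genome (softmask_fraction) are skipped with a ledger
    omission when no builder is supplied; specs inapplicable to any
    reference transcript are skipped likewise.
    """
    specs = specs if specs is not None else default_spec_list()
    rng = random.Random(seed)
    out = AnnotationSet()
    ledger: dict[str, str] = {}
    eligible = _multi_exon_refs(reference)
    if not eligible:
        raise ValueError("reference has no transcript with >= 3 exons")
    qn = 0
    for spec in specs:
        ref = eligible[rng.randrange(len(eligible))]
        qn += 1
        qid = f"q{qn:03d}_{spec.operation}"
        built = _apply(spec, ref, reference, qid, rng, builder)
        if built is None:
            continue
        out.add(built)
        ledger[built.id] = spec.expected_code
    return out, ledger


def _apply(spec: PerturbationSpec, ref: Transcript,
           reference: AnnotationSet, qid: str, rng: random.Random,
           builder: GenomeBuilder | None) -> Transcript | None:
    op, p = spec.operation, spec.params
    exons = list(ref.exons)
    seqid, strand = ref.seqid, ref.strand

    def tx(exlist, strand=strand, gene=None):
        return Transcript(id=qid, gene_id=gene or f"{qid}.g", exons=exlist,
                          source="sim", feature_type="transcript")

    def clip(iv, ds=0, de=0):
        return GenomicInterval(iv.seqid, iv.start + ds, iv.end + de,
                               iv.strand)

    if op == "exact_copy":
        return tx(exons)
    if op == "trim_ends":
        n = p.get("n", 20)
        return tx([clip(exons[0], ds=n)] + exons[1:-1]
                  + [clip(exons[-1], de=-n)])
    if op == "extend_ends":
        n = p.get("n", 20)
        return tx([clip(exons[0], ds=-n)] + exons[1:-1]
                  + [clip(exons[-1], de=n)])
    if op == "drop_terminal_exon":
        return tx(exons[:-1]) if len(exons) >= 3 else None
    if op == "containment_fragment":
        # keep the middle of the chain: contained, intron compatible
        return tx(exons[1:-1])
    if op == "reverse_containment":
        # add a spliced extra exon beyond the reference 3' end
        last = exons[-1]
        extra = GenomicInterval(seqid, last.end + 200, last.end + 320, strand)
        return tx(exons + [extra])
    if op == "retain_intron":
        k = p.get("k", 0)
        fused = GenomicInterval(seqid, exons[k].start, exons[k + 1].end,
                                strand)
        return tx(exons[:k] + [fused] + exons[k + 2:])
    if op == "retain_plus_novel":
        if len(exons) < 3:
            return None
        fused = GenomicInterval(seqid, exons[0].start, exons[1].end, strand)
        rest = exons[2:]
        # shift the last intron inward: novel junction
        delta = 15
        rest = rest[:-1] + [clip(rest[-1], ds=delta)]
        return tx([fused] + rest)
    if op == "shift_intron":
        k, delta = p.get("k", 0), p.get("delta", 18)
        shifted = [clip(exons[k], de=delta), clip(exons[k + 1], ds=delta)]
        return tx(exons[:k] + shifted + exons[k + 2:])
    if op == "shift_into_intron":
        intrusion = p.get("intrusion", 50)
        introns = ref.introns()
        for i, (s, e) in enumerate(introns):
            if e - s + 1 > intrusion + 10:
                ex = exons[i]
                return tx([GenomicInterval(seqid, ex.start,
                                           ex.end + intrusion, strand)])
        return None
    if op == "upstream_extension":
        first = exons[0]
        if first.start <= 100:
            return None
        return tx([GenomicInterval(seqid, first.start - 80,
                                   first.start + 40, strand)])
    if op == "strand_flip":
        return tx([_flip(e) for e in exons],
                  strand="-" if strand == "+" else "+")
    if op == "opposite_strand_exon":
        ex = exons[0]
        return tx([_flip(GenomicInterval(seqid, ex.start + 5, ex.end - 5,
                                         ex.strand))],
                  strand="-" if strand == "+" else "+")
    if op == "within_intron":
        for (s, e) in ref.introns():
            if e - s + 1 >= 80:
                return tx([GenomicInterval(seqid, s + 10, s + 60, strand)])
        return None
    if op == "bridge_reference":
        left = GenomicInterval(seqid, max(1, ref.start - 400),
                               ref.start - 300, strand)
        right = GenomicInterval(seqid, ref.end + 300, ref.end + 400, strand)
        return tx([left, right])
    if op == "downstream_offset":
        d = p.get("d", 500)
        return tx([GenomicInterval(seqid, ref.end + d, ref.end + d + 150,
                                   strand)])
    if op in ("softmask_fraction", "intergenic"):
        # far from every gene: past the last annotated transcript
        tail = max(t.end for t in reference) + 5000
        if op == "intergenic":
            tail += 3000  # keep the repeat and intergenic placements apart
        ex = GenomicInterval(seqid, tail, tail + 199, strand)
        if op == "softmask_fraction":
            if builder is None:
                return None
            f = p.get("f", 0.6)
            n_mask = int(round(f * len(ex)))
            if ex.end > builder.length(seqid):
                return None
            builder.softmask(seqid, ex.start, ex.start + n_mask - 1)
        return tx([ex])
    raise ValueError(f"unknown perturbation {op!r}")


# ---------------------------------------------------------------------------
# one-call dataset

@dataclass
class FixtureSet:
    genome_fasta: str
    reference: AnnotationSet
    queries: list[AnnotationSet]
    ledgers: list[dict[str, str]]


def make_fixture_set(seed: int, n_genes: int = 5, n_samples: int = 1,
                     isoforms_per_gene: int = 1,
                     seq_len: int = 120_000,
                     specs: list[PerturbationSpec] | None = None
                     ) -> FixtureSet:
    """Genome + reference + perturbed query sample(s), all from one seed."""
    builder = GenomeBuilder(seed, {"chr1": seq_len})
    reference = make_reference(seed + 1, builder, n_genes=n_genes,
                               isoforms_per_gene=isoforms_per_gene)
    queries, ledgers = [], []
    for s in range(n_samples):
        q, led = make_query(reference, specs, seed=seed + 2 + s,
                            builder=builder)
        queries.append(q)
        ledgers.append(led)
    return FixtureSet(builder.fasta(), reference, queries, ledgers)
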