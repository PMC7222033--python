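import random

import pytest

from gffkit.model import AnnotationSet, GenomicInterval, Transcript
from gffkit import fixtures as fx


def make_tx(tid, seqid, strand, exons, cds=(), gene_id=None, **kw):
    """Terse transcript constructor for hand-built cases."""
    return Transcript(
        id=tid, gene_id=gene_id,
        exons=[GenomicInterval(seqid, s, e, strand) for s, e in exons],
        cds_segments=[GenomicInterval(seqid, s, e, strand) for s, e in cds],
        **kw)


def make_set(*transcripts):
    return AnnotationSet(transcripts=transcripts)


def random_annotation_set(rng: random.Random, n: int = 30,
                          seqids=("chr1", "chr2"),
                          span: int = 50_000) -> AnnotationSet:
    """Random transcripts, possibly overlapping, mixed strands."""
    out = AnnotationSet()
    for i in range(n):
        seqid = rng.choice(seqids)
        strand = rng.choice("+-")
        start = rng.randint(1, span)
        n_ex = rng.randint(1, 4)
        exons = []
        p = start
        for j in range(n_ex):
            el = rng.randint(30, 200)
            exons.append((p, p + el - 1))
            p += el + rng.randint(40, 300)
        out.add(make_tx(f"t{i:03d}", seqid, strand, exons))
    return out


def distinct_structure_set(rng: random.Random, n_multi: int = 12,
                           n_single: int = 4, seqid: str = "chrD"
                           ) -> AnnotationSet:
    """Structurally distinct transcripts (no pair matches), for metric
    oracles that must not involve de-duplication effects."""
    out = AnnotationSet()
    pos = 1000
    for i in range(n_multi):
        strand = rng.choice("+-")
        n_ex = rng.randint(2, 4)
        exons = []
        p = pos + rng.randint(0, 50)
        for j in range(n_ex):
            el = rng.randint(50, 150)
            exons.append((p, p + el - 1))
            p += el + rng.randint(30, 120)
        out.add(make_tx(f"d{i:03d}", seqid, strand, exons))
        pos = p + 2000  # disjoint territories: chains cannot coincide
    for i in range(n_single):
        strand = rng.choice("+-")
        start = pos + rng.randint(0, 50)
        out.add(make_tx(f"s{i:03d}", seqid, strand,
                        [(start, start + rng.randint(80, 200))]))
        pos = start + 2000
    return out


@pytest.fixture(scope="session")
def fixture_set():
    return fx.make_fixture_set(11, n_genes=5)


@pytest.fixture()
def genome_index(tmp_path, fixture_set):
    from gffkit.seq import FastaIndex
    p = tmp_path / "genome.fa"
    p.write_text(fixture_set.genome_fasta)
    return FastaIndex(str(p))
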