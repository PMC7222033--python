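# gffkit

A Python toolkit for manipulating and comparing transcript annotations in
GFF3, GTF and BED format, aimed at genome-annotation and RNA-Seq assembly
pipelines. It provides three tool families over a single in-memory
transcript model:

* **`gffkit read`** — validate, convert (GFF3 ↔ GTF ↔ BED), sort, filter and
  cluster transcript records; extract spliced transcript, CDS and protein
  sequences from a genome FASTA; check CDS validity (START/STOP presence,
  in-frame stop codons) and splice-site consensus (GT-AG, GC-AG, AT-AC).
* **`gffkit compare`** — classify query transcripts ("transfrags") against a
  reference annotation, merge structurally equivalent transfrags across
  samples, and report assembly accuracy.
* **`gffkit trmap`** — stream arbitrarily many query transcripts against a
  reference loaded into an interval tree, reporting *every* overlapping
  reference with its classification code.

## The model

Two transcripts are **structurally equivalent** when they share all their
introns (the *intron chain*); single-exon transcripts are equivalent when
they overlap by more than 80% of the longer one. Terminal exon ends are
allowed to vary, since they differ routinely between samples of the same
biological transcript.

Each query transcript is assigned one of 15 **class codes** describing its
relationship to the reference transcript it most closely overlaps, in
decreasing priority: `=` (exact intron-chain match), `c` (contained,
intron-compatible), `k` (contains the reference), `m` (retained intron(s),
full match elsewhere), `n` (retained intron, partial match), `j` (at least
one junction match), `e` (single exon reaching into a reference intron),
`o` (other same-strand exonic overlap), `s` (opposite-strand intron match),
`x` (opposite-strand exonic overlap), `i` (inside a reference intron),
`y` (reference inside a query intron), and for queries with no overlap at
all `p` (run-on: within 2 kb of a reference), `r` (repeat: ≥ 50%
soft-masked bases), `u` (intergenic).

Accuracy against the reference is summarised at six increasingly stringent
levels — base, exon, intron, intron chain, transcript, locus — as

```
Sensitivity = TP / (TP + FN)        Precision = TP / (TP + FP)
```

where TP are query features confirmed by the reference, FN reference
features absent from the query, and FP query features without reference
support.

## Worked example

The package ships a deterministic fixture generator that builds a random
genome, plants a reference annotation with canonical splice sites and valid
CDSs, and derives query transcripts whose class codes are known by
construction:

```sh
gffkit fixtures --seed 3 --out fx --samples 2
gffkit compare -r fx/reference.gff3 -s fx/genome.fa -o cmp fx/query1.gtf fx/query2.gtf
head cmp.stats
```

prints (abridged):

```
#= Sample query1.gtf: 15 query transfrags (7 multi-exon) in 12 loci
           Level  Sensitivity  Precision
            base        77.7       54.6
            exon        47.4       31.0
          intron        50.0       46.7
    intron chain        20.0       14.3
      transcript        20.0        6.7
           locus        20.0        8.3
```

The sample contains one exact copy of a reference transcript plus fourteen
deliberate perturbations, so exactly one of the five reference transcripts
(20%) is recovered at the transcript level, while most query transfrags are
structural variants that count as false positives (precision 6.7%). The
`cmp.tracking` file lists each structurally distinct transfrag with its
consensus id (`TCONS_…`), super-locus (`XLOC_…`), closest reference and
class code, e.g.

```
TCONS_00000003  XLOC_000002  gene1|G001.1  n  q1:…|q005_retain_plus_novel|3|0.000000|0.000000|0.000000|879  q2:…
```

and `gffkit trmap fx/reference.gff3 fx/query1.gtf` reports every overlap
per query in a pseudo-FASTA block:

```
>q005_retain_plus_novel chr1:3000-4097+ exons:3000-3492,3607-3848,3954-4097
n	chr1	+	3000	4097	G001.1	3000-3145,3272-3492,3607-3848,3939-4097
```

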