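# Methods

## Transcript model and coordinates

All features live in one hierarchy: genes parent transcripts, transcripts
carry an exon chain and optionally CDS segments with per-segment frame.
Coordinates are 1-based inclusive throughout (the GFF convention); BED's
0-based half-open blocks are converted only at the I/O boundary
(`bed_start = gff_start − 1`, `bed_end = gff_end`). A transcript's span is
always derived from its exons, never trusted from the container line.
Parsing is order-independent: features are collected first and linked
after the whole stream is read, so an exon may precede its mRNA line or
reference a transcript defined thousands of lines later. Per-sequence
transcript arrays are kept coordinate-sorted; overlap queries narrow the
candidate window with binary search and are verified against a brute-force
scan in the test suite.

Dialect choices where the formats are loose:

* GFF3 attribute values are percent-decoded on read and the reserved
  characters `;=%&,` re-encoded on write; GTF values are double-quoted.
* A duplicated transcript ID gets a numeric discriminator (`id.d1`) and a
  warning; child features are attributed to the container on the same
  reference sequence.
* Features of unknown type beneath a transcript are retained as opaque
  children and dropped in transcript-only output.
* Transcripts of unknown strand (`.`) parse normally; strand-dependent
  operations treat them per that operation's contract (they form their own
  clustering stratum, get no `tss_id`, and their splice sites are reported
  non-assessable).
* CDS-only transcripts are recorded faithfully; exon synthesis is an
  explicit transform (`force_exons`), not a parsing side effect.

## Sequence operations

Genome access goes through a faidx-compatible index (pyfaidx); case is
preserved so soft-masking survives into repeat classification. Spliced
sequences concatenate segments in genomic order and reverse-complement the
result on the minus strand. Translation uses the standard genetic code,
trims the initial frame offset (taken from the 5′-most CDS segment on the
coding strand; a missing frame column is treated as 0 with a warning),
renders a stop codon as `.` and halts there, and ignores a trailing
incomplete codon. CDS extraction does not silently trim a terminal stop
codon: what the segments cover is what is returned. CDS status reports
START presence (first codon ATG after splicing), STOP presence (terminal
codon ∈ {TAA, TAG, TGA}) and all in-frame stops strictly before the
terminal codon; the partialness vocabulary is `complete`, `missing_start`,
`missing_stop`, `missing_both`, with `,inframe_stop` appended when
applicable. Only the standard code is supported (no alternative tables or
selenocysteine; ambiguous codons translate to X).

## Filtering, clustering, redundancy

A transcript survives filtering iff it passes every enabled predicate;
transcript length is the sum of exon lengths. The range filter tests
overlap by default and full containment with the `-R` analogue; a
strand-qualified range also requires strand equality. Pseudogene detection
looks for "pseudogene" in the feature type or in the biotype-style
attributes (`biotype`, `gene_biotype`, `transcript_biotype`, `gene_type`,
`transcript_type`), or `pseudo=true`, on the transcript or its parent
gene.

Loci are connected components of same-strand transcripts sharing at least
one exonic base, closed transitively; a sweep over coordinate-sorted
members keeps the construction near-linear, and the result is checked
against a full pairwise union-find in the tests.

Redundancy removal has three escalating modes mirroring `-M`, `-M -K` and
`-M -Q`: *merge* discards a transcript whose intron chain is identical to
another's and whose boundaries are contained; *contain* also discards
transcripts whose chain is a contiguous sub-chain of a container's chain
under boundary containment (a single-exon transcript inside one exon of a
container counts, its empty chain matching trivially); *relaxed* drops the
boundary-containment requirement — a chain (sub-)match suffices for
multi-exon transcripts and > 80% overlap for single-exon ones. Among exact
structural equals the survivor is the longer transcript, ties broken by
earlier start, then lexicographically smaller id (the discarded set is
what matters; the survivor rule only fixes a representative). A mixed
single-/multi-exon pair is never "equivalent" — the 80% rule applies only
between single-exon transcripts.

Close-exon merging fuses consecutive exons separated by an intron shorter
than the threshold, iteratively left to right. The standalone transform
(`-Z` analogue) keeps introns of 4 bases and larger; the comparison
pipeline's pre-merge keeps 5 and larger. Fusion happens before CDS
validation so validation sees the final exon chain.

## Classification

`classify_pair` evaluates the 15-code table in priority order and returns
the first code whose definition holds. Decisions the code table leaves
open, resolved here:

* **c/k containment** requires the contained transcript's chain to occur
  as a contiguous run of the container's chain with its terminal exons
  inside the flanking container exons (no protrusion into introns); a
  single-exon transcript must sit inside one container exon.
* **m vs n**: `m` requires every reference intron to be either exactly
  matched or fully spanned by a single query exon, with no novel query
  introns; any other configuration with at least one fully spanned
  reference intron is `n`.
* **j** requires one shared splice site between a query intron and a
  reference intron (either boundary).
* **e** requires a single-exon query to reach more than 10 bases past a
  reference exon boundary into the adjacent intron (configurable; the
  boundary between `e` and `o` is not quantified in the code table).
* **s** requires at least one query intron to exactly match a reference
  intron on the opposite strand.
* The terminal-end tolerance does **not** demote `=`: end offsets are
  assessed at the transcript accuracy level, not during code assignment.
* For non-overlapping queries, the repeat test runs first (≥ 50% of exonic
  bases lower-case, counted over exons only, requires a genome), then
  run-on (nearest same-strand reference within 2000 bases — a default
  chosen here, the table says only "close"), else intergenic. Run-on is
  not restricted to single-exon queries.

Super-loci are connected components of exon overlap pooled over all query
samples and the reference, merged across strands (the `s`/`x` codes need
cross-strand pairs inside one locus); ids are `XLOC_` + a six-digit
counter in genomic order. TSS groups chain same-strand transcripts whose
strand-aware 5′ starts differ by at most 100 bases under single linkage;
unknown-strand transcripts get no `tss_id`.

`best_reference` returns the highest-priority code over all overlapping
references, breaking ties by larger exonic overlap, then smaller
reference id.

## Accuracy metrics

Queries are close-exon pre-merged (introns < 5 fused) and both sides are
structurally de-duplicated before counting, so duplicated annotation
records cannot double-count FN or FP. The six levels:

* **base** — strand-aware per-coordinate exon coverage; intersection,
  query-only and reference-only base counts give TP/FP/FN.
* **exon** — de-duplicated exon intervals; boundaries must match exactly
  except the *free* outer edges of terminal exons, which may differ by up
  to the end tolerance (100). Because slack matching can be many-to-one,
  sensitivity uses the matched-reference count and precision the
  matched-query count.
* **intron** — de-duplicated intron intervals, exact coordinates.
* **intron chain** — multi-exon query transcripts whose chain equals some
  reference chain exactly (single-exon transcripts are excluded at this
  level).
* **transcript** — full exon-chain match: equal chains with terminal ends
  within 100 bases; single-exon pairs match at > 80% overlap of the longer
  transcript (exonic overlap, identical to span overlap for single
  exons).
* **locus** — same-strand exon-overlap clusters on each side; a reference
  locus counts when at least one of its transcripts has a transcript-level
  match, and symmetrically for query loci.

`-R` restricts the reference to transcripts overlapped by any query
(sensitivity correction); `-Q` restricts queries to those overlapping the
reference (precision correction). Missed/novel exons, introns and loci
count features with no overlap at all on the other side. The `.stats`
layout is this package's own; it carries the standard quantities but makes
no byte-compatibility claim.

## Merging and report files

Across samples, transfrags collapse into equivalence classes under
structural matching (single linkage within a super-locus); the
representative is the longest member and receives a `TCONS_` + eight-digit
id in genomic order. Mode `C` additionally discards contained
intron-redundant transfrags whose ends stay inside the container's exons,
`A` exempts those whose chain does not begin at the container's 5′-most
intron (alternate TSS, strand-aware), `X` also discards containments whose
ends protrude into container introns, and the `-K` analogue protects any
transfrag structurally matching a reference. Tracking rows carry
`qN:gene|transcript|num_exons|FPKM|TPM|cov|len` cells; the expression
attributes FPKM/TPM/cov are recognised case-insensitively and rendered
with six decimals, 0.000000 when absent. The refmap lists each reference
with at least one same-strand exonic-overlap query (codes `=ckmnjeo`),
labelled `=` when some query matches fully and `c` otherwise. The tmap's
major-isoform column picks the query gene's isoform with the highest FPKM
(then coverage, then length), and the reference-match-length column is the
longest exonic overlap with any reference, `-` when there is none.

## Streaming classification

The reference is loaded into per-chromosome interval trees (the
`intervaltree` package, half-open intervals shifted by one); queries are
then processed strictly one at a time. Queries with no overlap produce no
output, so the `p`/`r`/`u` codes never appear in streaming mode. The
default output is a pseudo-FASTA block per query; simple mode emits one
line per query with per-reference overlap percentages, defined as shared
exonic bases over the query's exonic length — the mode's output formula
is this package's choice, as is the hit ordering (reference start, then
id).

## Synthetic data generator

The generator emulates the structural situations the classifier must
distinguish, not realistic transcriptomes. A uniform-random genome gets
non-overlapping gene territories (3–5 exons of 120–300 bases, introns of
80–400 bases, 9 kb gaps so run-on/intergenic placements stay clean);
canonical splice dinucleotides are written at every intron boundary and a
valid ATG…TAA coding sequence, free of in-frame stops, is written through
the CDS segments (first isoform of each gene only — overlapping isoforms
would overwrite each other's planted codons). Query sets are derived by
perturbations (end trims, terminal-exon drops, intron retention/shifts,
strand flips, intronic/intergenic placements, soft-masked tracts) whose
expected class code is known by construction; one spec list covers all 15
codes. Everything derives from one explicit seed — same seed, same bytes.

What the generator does *not* emulate: expression levels (FPKM/TPM pass
through as zeros), sequencing noise, overlapping gene territories,
fragmented assemblies, or realistic length/GC distributions. Passing
tests demonstrate the algorithms implement their definitions, not that
accuracy numbers on real assemblies will look like the fixture numbers.

## Problem sizes and numerical choices

Tests and the acceptance sweeps run on deliberately small instances
(5-gene references, ≤ 500-transcript random sets, 100–200-point
boundary sweeps) — the quantities being checked are exact decision
boundaries and count identities, which do not sharpen with scale. All
thresholds are integers or exact fractions; no floating-point tolerances
are needed anywhere except the trivially exact sensitivity/precision
ratios. Known limitations: multi-parent GFF3 features are duplicated per
parent rather than shared; reference-name remapping is a plain two-column
rename; expression estimation is out of scope.
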