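"""Genome-backed sequence operations.

Random access into the genome goes through a faidx-compatible index
(pyfaidx); soft-masking case is preserved so downstream repeat
classification can count lower-case bases.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

from Bio.Seq import Seq
from pyfaidx import Fasta

from .model import Transcript

_COMPLEMENT = str.maketrans("ACGTacgtNnRYKMrykm", "TGCAtgcaNnYRMKyrmk")

STOP_CODONS = {"TAA", "TAG", "TGA"}
CANONICAL_SPLICE = {("GT", "AG"), ("GC", "AG"), ("AT", "AC")}


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class FastaIndex:
    """Random-access view of a genome FASTA with a faidx-compatible sidecar.

    ``fetch`` coordinates are 1-based inclusive, matching the annotation
    model.  If the FASTA has ragged line widths the index cannot be built;
    the whole file is then loaded in memory with a warning.
    """

    def __init__(self, path: str):
        self.path = path
        self._mem: dict[str, str] | None = None
        try:
            self._fa = Fasta(path, as_raw=True, sequence_always_upper=False)
        except Exception:
            import sys
            print(f"Warning: cannot index {path}; loading in memory",
                  file=sys.stderr)
            self._fa = None
            self._mem = _read_fasta(path)

    @classmethod
    def from_text(cls, fasta_text: str, workdir: str) -> "FastaIndex":
        path = os.path.join(workdir, "genome.fa")
        with open(path, "w") as fh:
            fh.write(fasta_text)
        return cls(path)

    @property
    def names(self) -> list[str]:
        if self._mem is not None:
            return list(self._mem)
        return list(self._fa.keys())

    def __contains__(self, name: str) -> bool:
        return name in self.names

    def length(self, name: str) -> int:
        if self._mem is not None:
            return len(self._mem[name])
        return len(self._fa[name])

    def fetch(self, name: str, start: int, end: int) -> str:
        """Subsequence [start, end], 1-based inclusive, case preserved."""
        if start < 1 or end < start:
            raise ValueError(f"bad fetch range {start}..{end}")
        if name not in self:
            raise KeyError(f"sequence {name!r} not in genome")
        if end > self.length(name):
            raise ValueError(
                f"range {start}..{end} exceeds length of {name} "
                f"({self.length(name)})")
        if self._mem is not None:
            return self._mem[name][start - 1:end]
        return str(self._fa[name][start - 1:end])


def _read_fasta(path: str) -> dict[str, str]:
    seqs: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if name is not None:
                    seqs[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            else:
                chunks.append(line)
    if name is not None:
        seqs[name] = "".join(chunks)
    return seqs


def build_index(path: str) -> FastaIndex:
    return FastaIndex(path)


# ---------------------------------------------------------------------------

def spliced_sequence(t: Transcript, genome: FastaIndex,
                     segments: str = "exons") -> str:
    """Concatenated segment sequence on the transcript's coding strand.

    Segments are concatenated in genomic order; on the minus strand the
    reverse complement of the concatenation is returned.  Genome case is
    preserved (soft-masking survives).
    """
    segs = t.exons if segments == "exons" else t.cds_segments
    if not segs:
        raise ValueError(f"transcript {t.id} has no {segments}")
    parts = []
    for s in segs:
        try:
            parts.append(genome.fetch(s.seqid, s.start, s.end))
        except ValueError as e:
            raise ValueError(
                f"transcript {t.id}: segment {s.start}-{s.end} "
                f"out of bounds ({e})") from None
    joined = "".join(parts)
    if t.strand == "-":
        return reverse_complement(joined)
    return joined


# ---------------------------------------------------------------------------
# translation

def translate_cds(cds_dna: str, phase: int = 0) -> str:
    """Translate a spliced CDS with the standard genetic code.

    The first ``phase`` bases are trimmed; a stop codon is rendered as "."
    and terminates the protein; a trailing incomplete codon is ignored;
    ambiguous codons translate to X.
    """
    dna = cds_dna[phase:].upper()
    if len(dna) < 3:
        return ""
    dna = dna[:len(dna) - len(dna) % 3]
    aa = str(Seq(dna).translate())
    stop = aa.find("*")
    if stop >= 0:
        return aa[:stop] + "."
    return aa


@dataclass
class CdsStatus:
    """Outcome of CDS validity checks for one coding transcript."""

    has_start: bool
    has_stop: bool
    inframe_stop_positions: list[int] = field(default_factory=list)
    phase_inconsistent: bool = False

    @property
    def is_complete(self) -> bool:
        return self.has_start and self.has_stop and not self.inframe_stop_positions

    @property
    def partialness_label(self) -> str:
        if self.has_start and self.has_stop:
            label = "complete"
        elif self.has_start:
            label = "missing_stop"
        elif self.has_stop:
            label = "missing_start"
        else:
            label = "missing_both"
        if self.inframe_stop_positions:
            label += ",inframe_stop"
        return label


def cds_start_phase(t: Transcript) -> int:
    """Frame offset of the 5'-most CDS segment on the coding strand."""
    if not t.cds_phase:
        return 0
    if t.strand == "-":
        return t.cds_phase[-1]
    return t.cds_phase[0]


def validate_cds(t: Transcript, genome: FastaIndex) -> CdsStatus:
    """Check a coding transcript for START/STOP presence and in-frame stops."""
    if not t.cds_segments:
        raise ValueError(f"transcript {t.id} has no CDS")
    dna = spliced_sequence(t, genome, "cds").upper()
    phase = cds_start_phase(t)
    dna = dna[phase:]
    n_codons = len(dna) // 3
    has_start = dna[:3] == "ATG"
    has_stop = n_codons >= 1 and dna[(n_codons - 1) * 3:n_codons * 3] in STOP_CODONS
    inframe = [
        i for i in range(n_codons - 1)
        if dna[i * 3:i * 3 + 3] in STOP_CODONS
    ]
    return CdsStatus(
        has_start=has_start, has_stop=has_stop,
        inframe_stop_positions=inframe,
        phase_inconsistent=(len(dna) % 3 != 0),
    )


# ---------------------------------------------------------------------------
# splice sites

def splice_sites(t: Transcript, genome: FastaIndex):
    """Donor/acceptor dinucleotides per intron, read on the transcript strand.

    Returns a list of (donor, acceptor, canonical) with canonical=None for
    transcripts of unknown strand.  Canonical pairs: GT-AG, GC-AG, AT-AC.
    """
    sites = []
    for (istart, iend) in t.introns():
        left = genome.fetch(t.seqid, istart, istart + 1).upper()
        right = genome.fetch(t.seqid, iend - 1, iend).upper()
        if t.strand == "-":
            donor = reverse_complement(right).upper()
            acceptor = reverse_complement(left).upper()
        elif t.strand == "+":
            donor, acceptor = left, right
        else:
            sites.append((left, right, None))
            continue
        sites.append((donor, acceptor, (donor, acceptor) in CANONICAL_SPLICE))
    return sites


def has_canonical_splice_sites(t: Transcript, genome: FastaIndex) -> bool:
    if t.num_exons < 2:
        return True
    return all(c is True for _, _, c in splice_sites(t, genome))


# ---------------------------------------------------------------------------
# FASTA output

def wrap_fasta(name: str, seq: str, width: int = 60,
               description: str = "") -> str:
    header = f">{name} {description}".rstrip()
    body = "\n".join(seq[i:i + width] for i in range(0, len(seq), width))
    return f"{header}\n{body}\n" if seq else f"{header}\n"
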