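"""Nucleotide containers, translation, and six-frame scanning of contigs.

Draft genome assemblies arrive as unannotated nucleotide contigs.  The
homology search operates on peptides, so every contig is translated in all
six reading frames and cut at stop codons; the surviving open peptide
segments are the search targets.  Coordinates are 0-based half-open and
always reported on the forward strand with an explicit strand field, so a
segment can be re-extracted from its contig and re-translated exactly.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Data.CodonTable import unambiguous_dna_by_id
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_STANDARD_TABLE = unambiguous_dna_by_id[1]
CODON_TO_AA = dict(_STANDARD_TABLE.forward_table)
for _stop in _STANDARD_TABLE.stop_codons:
    CODON_TO_AA[_stop] = "*"

NUC_ALPHABET = set("ACGTN")
_IUPAC_COMPLEMENT = dict(zip("ACGTNRYSWKMBDHV", "TGCANYRSWMKVHDB"))

FRAMES = (1, 2, 3, -1, -2, -3)

#: Default minimum peptide-segment length retained by six-frame scanning.
#: Profile hits much shorter than ~20 residues carry too little information
#: to classify, and published draft-assembly matches of interest were still
#: tens of residues long.
DEFAULT_MIN_SEGMENT_LEN = 20


def reverse_complement(nuc: str) -> str:
    """Reverse complement over the IUPAC nucleotide alphabet (N -> N)."""
    out = []
    for i, base in enumerate(reversed(nuc.upper())):
        comp = _IUPAC_COMPLEMENT.get(base)
        if comp is None:
            pos = len(nuc) - 1 - i
            raise ValueError(f"invalid nucleotide {base!r} at position {pos}")
        out.append(comp)
    return "".join(out)


def translate(nuc: str, frame: int) -> str:
    """Translate in one signed frame under the standard genetic code.

    Frames +1/+2/+3 read the given strand at offsets 0/1/2; -1/-2/-3 apply
    the same offsets to the reverse complement.  The trailing partial codon
    is dropped, stops appear as '*', and any codon containing N translates
    to 'X'.  An empty effective sequence gives the empty string.
    """
    if frame not in FRAMES:
        raise ValueError(f"frame must be one of {FRAMES}, got {frame}")
    seq = nuc.upper()
    for i, base in enumerate(seq):
        if base not in _IUPAC_COMPLEMENT:
            raise ValueError(f"invalid nucleotide {base!r} at position {i}")
    if frame < 0:
        seq = reverse_complement(seq)
    offset = abs(frame) - 1
    seq = seq[offset:]
    aa = []
    for i in range(0, len(seq) - len(seq) % 3, 3):
        codon = seq[i:i + 3]
        if set(codon) <= {"A", "C", "G", "T"}:
            aa.append(CODON_TO_AA[codon])
        else:
            aa.append("X")
    return "".join(aa)


@dataclass
class NucContig:
    """A nucleotide contig restricted to the {A,C,G,T,N} alphabet."""

    id: str
    seq: str
    species: str = ""

    def __post_init__(self) -> None:
        self.seq = self.seq.upper()
        if not self.seq:
            raise ValueError(f"contig {self.id!r} has empty sequence")
        for i, base in enumerate(self.seq):
            if base not in NUC_ALPHABET:
                raise ValueError(
                    f"contig {self.id!r}: invalid base {base!r} at position {i}")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class PeptideSegment:
    """A stop-free translated segment mapped back to contig coordinates.

    nuc_start/nuc_end are 0-based half-open forward-strand coordinates of
    the encoding nucleotide span; for strand '-', the peptide is the
    translation of the reverse complement of that span.
    """

    contig_id: str
    frame: int
    aa_seq: str
    nuc_start: int
    nuc_end: int
    strand: str
    species: str = ""

    @property
    def id(self) -> str:
        return f"{self.contig_id}|{self.frame:+d}|{self.nuc_start}-{self.nuc_end}"

    def __len__(self) -> int:
        return len(self.aa_seq)


def six_frame_segments(contig: NucContig,
                       min_len: int = DEFAULT_MIN_SEGMENT_LEN) -> list[PeptideSegment]:
    """Translate a contig in all six frames and cut at stop codons.

    Each frame's translation is split at '*'; runs of at least min_len
    residues are returned with coordinates that round-trip: extracting
    [nuc_start, nuc_end) (reverse-complemented when strand is '-') and
    translating in frame +1 reproduces aa_seq exactly.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    n = len(contig)
    segments: list[PeptideSegment] = []
    if n < 3:
        return segments
    for frame in FRAMES:
        aa = translate(contig.seq, frame)
        offset = abs(frame) - 1
        strand = "+" if frame > 0 else "-"
        start = 0
        for chunk in aa.split("*"):
            if len(chunk) >= min_len:
                i, j = start, start + len(chunk)
                if strand == "+":
                    nuc_start, nuc_end = offset + 3 * i, offset + 3 * j
                else:
                    nuc_start, nuc_end = n - (offset + 3 * j), n - (offset + 3 * i)
                segments.append(PeptideSegment(
                    contig_id=contig.id, frame=frame, aa_seq=chunk,
                    nuc_start=nuc_start, nuc_end=nuc_end, strand=strand,
                    species=contig.species))
            start += len(chunk) + 1
    return segments


def extract_segment(contig: NucContig, segment: PeptideSegment) -> str:
    """Return the nucleotide sequence encoding a segment, reading-strand oriented."""
    span = contig.seq[segment.nuc_start:segment.nuc_end]
    return reverse_complement(span) if segment.strand == "-" else span


@dataclass
class MsAlignment:
    """A gapped protein multiple sequence alignment with optional subfamily labels."""

    rows: list[tuple[str, str]]
    labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("alignment has no rows")
        ncol = len(self.rows[0][1])
        for name, seq in self.rows:
            if len(seq) != ncol:
                raise ValueError(f"row {name!r} has length {len(seq)} != {ncol}")

    @property
    def ncols(self) -> int:
        return len(self.rows[0][1])

    @property
    def nrows(self) -> int:
        return len(self.rows)

    @property
    def ids(self) -> list[str]:
        return [name for name, _ in self.rows]

    def column(self, k: int) -> str:
        return "".join(seq[k] for _, seq in self.rows)

    def subset(self, ids: set[str] | list[str]) -> "MsAlignment":
        keep = set(ids)
        rows = [(n, s) for n, s in self.rows if n in keep]
        labels = {n: l for n, l in self.labels.items() if n in keep}
        return MsAlignment(rows, labels)

    def subfamilies(self) -> list[str]:
        return sorted(set(self.labels.values()))


def read_fasta_contigs(path: str, species: str = "") -> list[NucContig]:
    return [NucContig(rec.id, str(rec.seq), species=species)
            for rec in SeqIO.parse(path, "fasta")]


def write_fasta(path: str, records: list[tuple[str, str]]) -> None:
    recs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records]
    SeqIO.write(recs, path, "fasta")


def read_alignment(path: str, fmt: str = "fasta",
                   labels: dict[str, str] | None = None) -> MsAlignment:
    """Read an aligned FASTA or Stockholm file into an MsAlignment."""
    rows = [(rec.id, str(rec.seq).upper().replace(".", "-"))
            for rec in SeqIO.parse(path, fmt)]
    return MsAlignment(rows, labels or {})


def read_labels(path: str) -> dict[str, str]:
    """Read a two-column TSV (sequence id, subfamily) into a dict."""
    labels = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            name, subfam = line.split("\t")[:2]
            labels[name] = subfam
    return labels


SEGMENT_TSV_COLUMNS = ("contig", "start", "end", "strand", "frame", "peptide")


def write_segments_tsv(path: str, segments: list[PeptideSegment]) -> None:
    """Write segments as a BED-like 6-column TSV (0-based half-open)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(SEGMENT_TSV_COLUMNS)
        for s in segments:
            w.writerow([s.contig_id, s.nuc_start, s.nuc_end, s.strand,
                        s.frame, s.aa_seq])


def read_segments_tsv(path: str) -> list[PeptideSegment]:
    segments = []
    with open(path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader)
        if tuple(header) != SEGMENT_TSV_COLUMNS:
            raise ValueError(f"unexpected segment TSV header: {header}")
        for row in reader:
            contig, start, end, strand, frame, pep = row
            segments.append(PeptideSegment(
                contig_id=contig, frame=int(frame), aa_seq=pep,
                nuc_start=int(start), nuc_end=int(end), strand=strand))
    return segments
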