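"""Core sequence domain types, translation, and FASTA/GFF3 I/O.

Coordinates are 0-based half-open internally and converted to 1-based
inclusive only when writing GFF3.  DNA alphabet is {A, C, G, T, N};
lowercase input is uppercased on read and U (RNA) is rejected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable

from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

DNA_ALPHABET = frozenset("ACGTN")
AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY*X")

#: codon -> amino acid for the standard genetic code, stops as '*'
CODON_TABLE: dict[str, str] = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    CODON_TABLE[_stop] = "*"

STOP_CODONS = frozenset(standard_dna_table.stop_codons)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class SequenceError(ValueError):
    """Malformed sequence input (bad alphabet, bad length, bad format)."""


@dataclass(frozen=True)
class Contig:
    """A genomic contig/scaffold from one species' assembly."""

    id: str
    species: str
    seq: str

    def __post_init__(self) -> None:
        bad = set(self.seq) - DNA_ALPHABET
        if bad:
            raise SequenceError(
                f"contig {self.id}: invalid DNA characters {sorted(bad)!r}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class ProteinSeq:
    """An amino-acid sequence; '*' allowed, 'X' for unknown residues."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        bad = set(self.seq) - AA_ALPHABET
        if bad:
            raise SequenceError(
                f"protein {self.id}: invalid residues {sorted(bad)!r}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval on a contig strand."""

    contig_id: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise SequenceError(
                f"invalid interval [{self.start}, {self.end}) on {self.contig_id}"
            )
        if self.strand not in "+-":
            raise SequenceError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.contig_id == other.contig_id
            and self.strand == other.strand
            and self.start < other.end
            and other.start < self.end
        )


def translate(dna: str, table: int = 1) -> str:
    """Translate an in-frame CDS; N-containing codons give 'X', stops '*'.

    Raises :class:`SequenceError` if the length is not a multiple of 3
    (a malformed CDS) or on alphabet violations.
    """
    if table != 1:
        raise ValueError("only the standard genetic code (table 1) is supported")
    if len(dna) % 3:
        raise SequenceError(
            f"CDS length {len(dna)} is not a multiple of 3"
        )
    bad = set(dna) - DNA_ALPHABET
    if bad:
        raise SequenceError(f"invalid DNA characters {sorted(bad)!r}")
    out = []
    for i in range(0, len(dna), 3):
        codon = dna[i : i + 3]
        out.append(CODON_TABLE.get(codon, "X"))
    return "".join(out)


def reverse_complement(dna: str) -> str:
    bad = set(dna) - DNA_ALPHABET
    if bad:
        raise SequenceError(f"invalid DNA characters {sorted(bad)!r}")
    return dna.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Frame:
    """One of the six translation frames of a contig.

    ``label`` is +1/+2/+3/-1/-2/-3.  ``offset`` is the 0-based position on
    the *frame's own strand* where the first full codon starts.
    """

    label: int
    contig_id: str
    contig_length: int
    protein: str
    offset: int

    @property
    def strand(self) -> str:
        return "+" if self.label > 0 else "-"

    def codon_interval(self, aa_pos: int) -> GenomicInterval:
        """Map a protein position to its 3-nt genomic interval (forward coords)."""
        if not 0 <= aa_pos < len(self.protein):
            raise IndexError(f"residue {aa_pos} outside frame of {len(self.protein)}")
        s = self.offset + 3 * aa_pos
        if self.strand == "+":
            return GenomicInterval(self.contig_id, s, s + 3, "+")
        # position s on the reverse strand maps back to forward coordinates
        fwd_end = self.contig_length - s
        return GenomicInterval(self.contig_id, fwd_end - 3, fwd_end, "-")

    def genomic_start(self, aa_pos: int) -> int:
        """Forward-strand start coordinate of the codon for ``aa_pos``."""
        return self.codon_interval(aa_pos).start


def six_frame_translate(contig: Contig) -> list[Frame]:
    """Translate a contig in all six frames, dropping trailing partial codons."""
    if len(contig) < 3:
        warnings.warn(f"contig {contig.id} shorter than 3 nt; no frames")
        return []
    frames: list[Frame] = []
    rc = reverse_complement(contig.seq)
    for label, seq in ((1, contig.seq), (-1, rc)):
        for off in range(3):
            usable = (len(seq) - off) // 3 * 3
            prot = translate(seq[off : off + usable]) if usable else ""
            frames.append(
                Frame(
                    label=label * (off + 1),
                    contig_id=contig.id,
                    contig_length=len(contig),
                    protein=prot,
                    offset=off,
                )
            )
    return frames


# ---------------------------------------------------------------------------
# FASTA / GFF3 I/O
# ---------------------------------------------------------------------------

def read_fasta(path, dna: bool = True) -> list[tuple[str, str]]:
    """Read a multi-FASTA into (id, sequence) pairs.

    Sequences are uppercased; duplicate ids and malformed headers raise
    :class:`SequenceError`.  With ``dna=True``, 'U' is rejected (DNA only).
    """
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    rid: str | None = None
    chunks: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith(">"):
                if rid is not None:
                    records.append((rid, "".join(chunks)))
                header = line[1:].strip()
                if not header:
                    raise SequenceError(f"{path}:{lineno}: empty FASTA header")
                rid = header.split()[0]
                if rid in seen:
                    raise SequenceError(f"{path}:{lineno}: duplicate id {rid!r}")
                seen.add(rid)
                chunks = []
            else:
                if rid is None:
                    raise SequenceError(
                        f"{path}:{lineno}: sequence before first header"
                    )
                chunk = line.strip().upper()
                if dna and "U" in chunk:
                    raise SequenceError(f"{path}:{lineno}: RNA 'U' not accepted")
                chunks.append(chunk)
    if rid is not None:
        records.append((rid, "".join(chunks)))
    return records


def write_fasta(records: Iterable[tuple[str, str]], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_gff3(models, path) -> None:
    """Write gene models as GFF3 (gene/mRNA/exon/CDS rows, 1-based inclusive).

    Column 9 carries ``status`` and, for two-exon models, the junction
    dipeptide and intron codon index.
    """
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            exons = sorted(m.exons, key=lambda e: e.start)
            gstart = exons[0].start + 1
            gend = exons[-1].end
            contig = exons[0].contig_id
            attrs = [f"ID={m.name}", f"status={m.status}"]
            if m.junction is not None:
                attrs.append(f"junction={m.junction.left_aa}{m.junction.right_aa}")
            if m.intron_codon_index is not None:
                attrs.append(f"intron_codon_index={m.intron_codon_index}")
            base = f"{contig}\ttaarminer"
            fh.write(
                f"{base}\tgene\t{gstart}\t{gend}\t.\t{m.strand}\t.\t"
                + ";".join(attrs) + "\n"
            )
            fh.write(
                f"{base}\tmRNA\t{gstart}\t{gend}\t.\t{m.strand}\t.\t"
                f"ID={m.name}.t1;Parent={m.name}\n"
            )
            # phase of each CDS chunk in transcription order
            order = exons if m.strand == "+" else exons[::-1]
            phase = 0
            phases = {}
            for e in order:
                phases[(e.start, e.end)] = phase
                phase = (3 - ((len(e) - phase) % 3)) % 3
            for i, e in enumerate(exons, 1):
                fh.write(
                    f"{base}\texon\t{e.start + 1}\t{e.end}\t.\t{m.strand}\t.\t"
                    f"ID={m.name}.e{i};Parent={m.name}.t1\n"
                )
                fh.write(
                    f"{base}\tCDS\t{e.start + 1}\t{e.end}\t.\t{m.strand}\t"
                    f"{phases[(e.start, e.end)]}\t"
                    f"ID={m.name}.c;Parent={m.name}.t1\n"
                )
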