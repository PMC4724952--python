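"""Sequence and coordinate primitives shared by every pipeline stage.

Coordinates are 0-based, half-open everywhere inside the package; conversion
to 1-based inclusive happens only when writing GFF3.  Nucleotide sequences are
uppercase strings over ``{A, C, G, T, N}``; lowercase and ``U`` are normalised
on ingestion.  Translation uses the ciliate nuclear genetic code (NCBI table
6) by default, under which ``TAA`` and ``TAG`` encode glutamine and ``TGA`` is
the sole stop codon.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_NUCLEOTIDES = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class DuplicateContigError(ValueError):
    """Raised when a FASTA file contains two contigs with the same name."""


@dataclass(frozen=True, order=True)
class Interval:
    """A genomic interval: 0-based, half-open, stranded.

    ``strand`` is "+" or "-"; strandless features conventionally use "+".
    """

    contig: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return (
            self.contig == other.contig
            and self.start < other.end
            and other.start < self.end
        )

    def gap_to(self, other: "Interval") -> int:
        """Distance in bp between the nearest ends of two intervals (0 if they
        overlap or abut)."""
        if self.contig != other.contig:
            raise ValueError("intervals on different contigs")
        return max(self.start - other.end, other.start - self.end, 0)


@dataclass
class GeneticCode:
    """A codon translation table.

    ``table`` maps each of the 64 codons to a one-letter amino acid, with
    stop codons mapping to ``*``.
    """

    table_id: int
    table: dict[str, str]
    stop_codons: frozenset[str]

    @classmethod
    def from_ncbi(cls, table_id: int) -> "GeneticCode":
        ncbi = CodonTable.unambiguous_dna_by_id[table_id]
        table = dict(ncbi.forward_table)
        for stop in ncbi.stop_codons:
            table[stop] = "*"
        return cls(table_id=table_id, table=table, stop_codons=frozenset(ncbi.stop_codons))

    def amino_acid(self, codon: str) -> str:
        """Translate one codon; codons containing non-ACGT characters give X."""
        aa = self.table.get(codon)
        return aa if aa is not None else "X"

    def is_stop(self, codon: str) -> bool:
        return codon in self.stop_codons


#: The ciliate nuclear code (TAA/TAG -> Q, TGA the sole stop).
CILIATE_CODE = GeneticCode.from_ncbi(6)
#: The standard code, used only for property checks against table 6.
STANDARD_CODE = GeneticCode.from_ncbi(1)


def normalize_nucleotides(seq: str) -> str:
    """Uppercase, map U->T, and validate the alphabet."""
    s = seq.upper().replace("U", "T")
    for i, ch in enumerate(s):
        if ch not in VALID_NUCLEOTIDES:
            raise ValueError(f"invalid nucleotide {ch!r} at position {i}")
    return s


def reverse_complement(seq: str) -> str:
    for i, ch in enumerate(seq):
        if ch not in VALID_NUCLEOTIDES:
            raise ValueError(f"invalid nucleotide {ch!r} at position {i}")
    return seq.translate(_COMPLEMENT)[::-1]


def translate(seq: str, code: GeneticCode = CILIATE_CODE) -> str:
    """Translate a nucleotide sequence codon by codon.

    A trailing remainder (length not divisible by 3) is dropped with a
    warning; codons containing N translate to X; stop codons render as ``*``.
    Empty input gives empty output.
    """
    n = len(seq)
    if n % 3:
        warnings.warn(f"dropping {n % 3} trailing nucleotide(s) before translation")
        seq = seq[: n - n % 3]
    return "".join(code.amino_acid(seq[i : i + 3]) for i in range(0, len(seq), 3))


@dataclass
class GenomeAssembly:
    """An ordered collection of named contigs."""

    contigs: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.contigs = {name: normalize_nucleotides(s) for name, s in self.contigs.items()}
        for name in self.contigs:
            if not name:
                raise ValueError("empty contig name")

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.contigs.values())

    def __len__(self) -> int:
        return len(self.contigs)

    def __getitem__(self, name: str) -> str:
        return self.contigs[name]

    def __contains__(self, name: str) -> bool:
        return name in self.contigs

    def names(self) -> list[str]:
        return list(self.contigs)

    def fetch(self, iv: Interval) -> str:
        """Sequence of an interval on its recorded strand."""
        if iv.end > len(self.contigs[iv.contig]):
            raise ValueError(
                f"interval [{iv.start}, {iv.end}) exceeds contig {iv.contig} "
                f"of length {len(self.contigs[iv.contig])}"
            )
        s = self.contigs[iv.contig][iv.start : iv.end]
        return s if iv.strand == "+" else reverse_complement(s)

    @classmethod
    def from_fasta(cls, path: str | Path) -> "GenomeAssembly":
        contigs: dict[str, str] = {}
        for rec in SeqIO.parse(str(path), "fasta"):
            if rec.id in contigs:
                raise DuplicateContigError(f"duplicate contig name {rec.id!r}")
            contigs[rec.id] = str(rec.seq)
        return cls(contigs=contigs)

    def to_fasta(self, path: str | Path, width: int = 70) -> None:
        records = [SeqRecord(Seq(s), id=name, description="") for name, s in self.contigs.items()]
        with open(path, "w") as fh:
            writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
            writer.write_file(records)


def read_fasta(path: str | Path) -> GenomeAssembly:
    return GenomeAssembly.from_fasta(path)


def write_fasta(assembly: GenomeAssembly, path: str | Path, width: int = 70) -> None:
    assembly.to_fasta(path, width=width)


# ---------------------------------------------------------------------------
# Track I/O: BED (0-based half-open) and GFF3 (1-based inclusive)
# ---------------------------------------------------------------------------

def read_bed(path: str | Path) -> list[Interval]:
    intervals = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            contig, start, end = parts[0], int(parts[1]), int(parts[2])
            strand = parts[5] if len(parts) > 5 and parts[5] in "+-" else "+"
            intervals.append(Interval(contig, start, end, strand))
    return intervals


def write_bed(intervals: Iterable[Interval], path: str | Path, names: Iterable[str] | None = None) -> None:
    names = list(names) if names is not None else None
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            name = names[i] if names else "."
            fh.write(f"{iv.contig}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")


@dataclass
class GFF3Feature:
    interval: Interval
    feature_type: str
    source: str = "tbescan"
    score: str = "."
    attributes: dict[str, str] = field(default_factory=dict)


def write_gff3(features: Iterable[GFF3Feature], path: str | Path) -> None:
    """Write features, converting internal 0-based half-open coordinates to
    the 1-based inclusive GFF3 convention."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            iv = f.interval
            attrs = ";".join(f"{k}={v}" for k, v in f.attributes.items()) or "."
            fh.write(
                f"{iv.contig}\t{f.source}\t{f.feature_type}\t{iv.start + 1}\t{iv.end}\t"
                f"{f.score}\t{iv.strand}\t.\t{attrs}\n"
            )


def read_gff3(path: str | Path) -> list[GFF3Feature]:
    feats = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            contig, source, ftype, start, end, score, strand = cols[:7]
            attrs: dict[str, str] = {}
            if len(cols) > 8 and cols[8] != ".":
                for kv in cols[8].split(";"):
                    if "=" in kv:
                        k, v = kv.split("=", 1)
                        attrs[k] = v
            feats.append(
                GFF3Feature(
                    interval=Interval(contig, int(start) - 1, int(end), strand if strand in "+-" else "+"),
                    feature_type=ftype,
                    source=source,
                    score=score,
                    attributes=attrs,
                )
            )
    return feats


def read_track(path: str | Path) -> list[Interval]:
    """Read a BED or GFF3 file into a list of intervals (sniffed by content)."""
    path = Path(path)
    with open(path) as fh:
        head = fh.read(2048)
    if head.startswith("##gff-version") or path.suffix.lower() in (".gff", ".gff3"):
        return [f.interval for f in read_gff3(path)]
    return read_bed(path)
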