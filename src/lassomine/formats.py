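"""Readers and writers for the formats the mining pipeline touches.

Sequences travel as :class:`SequenceRecord` with a declared alphabet
(nucleotide or protein); annotations as :class:`Feature` with 0-based
half-open coordinates; the digitized per-tool gene presence table as
:class:`GenePresenceMatrix`.

All coordinates are 0-based half-open internally.  GFF3 I/O converts the
1-based inclusive convention at the boundary, so interval arithmetic inside
the package is unambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

NUCLEOTIDE = "nucleotide"
PROTEIN = "protein"

_NT_ALPHABET = set("ACGTN")
_AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY") | {"X", "*"}

TOOLS = ("bagel4", "antismash5")
GENES = ("lasA", "lasB", "lasC", "lasD")

PRESENCE_COLUMNS = ["genome_label"] + [
    f"{tool}_{gene}" for tool in TOOLS for gene in GENES
]


class FormatError(ValueError):
    """Malformed input file."""


class AlphabetError(ValueError):
    """A residue outside the declared alphabet."""


class SchemaError(ValueError):
    """A tabular input does not match the expected schema."""


@dataclass(frozen=True)
class SequenceRecord:
    """One FASTA entry with a declared alphabet.

    ``residues`` are stored uppercase; validity against the declared
    alphabet is checked at construction.
    """

    id: str
    residues: str
    alphabet: str = NUCLEOTIDE
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise FormatError(f"record id must be a non-empty token: {self.id!r}")
        if not self.residues:
            raise FormatError(f"record {self.id!r} has an empty sequence")
        object.__setattr__(self, "residues", self.residues.upper())
        allowed = _NT_ALPHABET if self.alphabet == NUCLEOTIDE else _AA_ALPHABET
        bad = set(self.residues) - allowed
        if bad:
            raise AlphabetError(
                f"record {self.id!r}: characters {sorted(bad)} outside the "
                f"declared {self.alphabet} alphabet"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class Feature:
    """A genomic feature in 0-based half-open coordinates."""

    contig: str
    begin: int
    end: int
    strand: str
    kind: str
    attributes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0 <= self.begin < self.end):
            raise FormatError(
                f"feature on {self.contig}: invalid interval "
                f"[{self.begin}, {self.end})"
            )
        if self.strand not in "+-":
            raise FormatError(f"feature strand must be + or -, got {self.strand!r}")

    @property
    def product(self) -> str:
        return self.attributes.get("product", "")


@dataclass
class GenePresenceMatrix:
    """Per-genome, per-tool booleans for the four cluster genes.

    ``cells[genome][(tool, gene)]`` holds the call of one mining tool for
    one of lasA/lasB/lasC/lasD; every genome carries all 8 cells.
    """

    genomes: list[str]
    cells: dict[str, dict[tuple[str, str], bool]]

    def __post_init__(self) -> None:
        if len(set(self.genomes)) != len(self.genomes):
            raise SchemaError("genome labels must be unique")
        expected = {(t, g) for t in TOOLS for g in GENES}
        for genome in self.genomes:
            if set(self.cells.get(genome, {})) != expected:
                raise SchemaError(f"genome {genome!r} is missing presence cells")

    def presence(self, genome: str, tool: str, gene: str) -> bool:
        return self.cells[genome][(tool, gene)]


def read_fasta(path: str | Path, alphabet: str) -> list[SequenceRecord]:
    """Read a FASTA file into validated records; order preserved."""
    path = Path(path)
    records: list[SequenceRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq)
        if "-" in seq or "." in seq:
            raise FormatError(f"record {rec.id!r} contains gap characters")
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        records.append(
            SequenceRecord(id=rec.id, residues=seq, alphabet=alphabet,
                           description=desc)
        )
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path,
                wrap: int = 60) -> None:
    """Write records as FASTA, wrapping sequence lines at ``wrap`` columns."""
    records = list(records)
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise FormatError("duplicate record ids in FASTA output")
    path = Path(path)
    with path.open("w") as fh:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.residues), wrap):
                fh.write(rec.residues[i:i + wrap] + "\n")


def _parse_gff_attributes(text: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for part in text.strip().split(";"):
        if not part:
            continue
        if "=" in part:
            key, _, value = part.partition("=")
            attrs[key.strip()] = value.strip()
    return attrs


def read_gff(path: str | Path) -> list[Feature]:
    """Parse GFF3 feature lines into 0-based half-open :class:`Feature` s.

    A ``##FASTA`` section terminates parsing; embedded sequence is ignored.
    Strand "." is stored as "+" and flagged via ``strand_unknown=1`` in the
    attributes, since context windows are strand-symmetric.
    """
    features: list[Feature] = []
    with Path(path).open() as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("##FASTA"):
                break
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FormatError(f"GFF3 line does not have 9 columns: {line!r}")
            contig, _source, kind, start, end, _score, strand, _phase, attr = cols
            start_i, end_i = int(start), int(end)
            if end_i < start_i:
                raise FormatError(f"GFF3 feature with end < start: {line!r}")
            attrs = _parse_gff_attributes(attr)
            if strand == ".":
                strand = "+"
                attrs["strand_unknown"] = "1"
            features.append(
                Feature(contig=contig, begin=start_i - 1, end=end_i,
                        strand=strand, kind=kind, attributes=attrs)
            )
    return features


def write_gff(features: Iterable[Feature], path: str | Path) -> None:
    """Emit features as GFF3 (coordinates converted back to 1-based)."""
    with Path(path).open("w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            attrs = ";".join(f"{k}={v}" for k, v in f.attributes.items()) or "."
            fh.write(
                f"{f.contig}\t.\t{f.kind}\t{f.begin + 1}\t{f.end}\t.\t"
                f"{f.strand}\t.\t{attrs}\n"
            )


def read_presence_matrix(path: str | Path) -> GenePresenceMatrix:
    """Read the per-tool gene presence TSV.

    Schema: ``genome_label`` then ``bagel4_lasA..lasD`` and
    ``antismash5_lasA..lasD``; cells are 0/1.
    """
    path = Path(path)
    with path.open() as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise SchemaError(f"{path}: empty presence matrix")
    header = lines[0].split("\t")
    if header != PRESENCE_COLUMNS:
        missing = set(PRESENCE_COLUMNS) - set(header)
        raise SchemaError(
            f"{path}: presence-matrix header mismatch; missing {sorted(missing)}"
        )
    genomes: list[str] = []
    cells: dict[str, dict[tuple[str, str], bool]] = {}
    for line in lines[1:]:
        cols = line.split("\t")
        if len(cols) != len(PRESENCE_COLUMNS):
            raise SchemaError(f"{path}: row with wrong column count: {line!r}")
        genome = cols[0]
        row: dict[tuple[str, str], bool] = {}
        for (tool, gene), value in zip(
            ((t, g) for t in TOOLS for g in GENES), cols[1:]
        ):
            if value not in ("0", "1"):
                raise FormatError(
                    f"{path}: presence cell for {genome!r} must be 0/1, "
                    f"got {value!r}"
                )
            row[(tool, gene)] = value == "1"
        genomes.append(genome)
        cells[genome] = row
    return GenePresenceMatrix(genomes=genomes, cells=cells)


def to_seqrecords(records: Iterable[SequenceRecord]) -> list[SeqRecord]:
    """Convert to Biopython records (interop helper)."""
    return [
        SeqRecord(Seq(r.residues), id=r.id, description=r.description)
        for r in records
    ]
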