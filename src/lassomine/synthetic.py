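"""Synthetic genomes, precursors, and reads with known ground truth.

Every pipeline stage is exercised offline: genomes carry planted anchor
genes (reverse-translated maturation-protein homologs) and precursor
ORFs whose coordinates are recorded as truth; reads are drawn from genes
at known counts.  Generators are deterministic under a fixed seed.

The module also loads the packaged fixtures: the digitized per-tool gene
presence matrix (34 genomes), the 35-entry precursor table (leader/core
splits with printed and recomputed core lengths), and the synthetic
reference protein panels.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .formats import (
    NUCLEOTIDE,
    PROTEIN,
    Feature,
    GenePresenceMatrix,
    SequenceRecord,
    read_fasta,
    read_presence_matrix,
)
from .grammar import DEFAULT_GRAMMAR, GrammarConfig, best_split
from .orfs import reverse_complement

# residue frequencies approximating rumen Firmicutes proteomes; the exact
# vector only shapes background composition, not any truth label
_AA = "ACDEFGHIKLMNPQRSTVWY"
_AA_FREQ = np.array([
    0.079, 0.011, 0.052, 0.066, 0.043, 0.071, 0.020, 0.071, 0.072, 0.092,
    0.026, 0.042, 0.040, 0.037, 0.049, 0.059, 0.054, 0.070, 0.012, 0.034,
])
_AA_FREQ = _AA_FREQ / _AA_FREQ.sum()

# codons per amino acid, NCBI table 11
_CODONS: dict[str, list[str]] = {}
_BASES = "TCAG"
_TABLE11 = (
    "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
)
for _i, _aa in enumerate(_TABLE11):
    _codon = _BASES[_i // 16] + _BASES[(_i // 4) % 4] + _BASES[_i % 4]
    _CODONS.setdefault(_aa, []).append(_codon)

STOP_CODONS = tuple(_CODONS["*"])


class IntegrityError(RuntimeError):
    """A packaged fixture fails its checksum."""


@dataclass(frozen=True)
class PlantedCluster:
    """One biosynthetic cluster to plant in a synthetic contig."""

    anchor_proteins: tuple[SequenceRecord, ...]
    precursor: str                     # full precursor peptide (leader+core)
    intergenic_gap: int = 150
    strand: str = "+"
    n_decoys: int = 2                  # grammar-violating short ORFs


@dataclass(frozen=True)
class SyntheticGenomeSpec:
    seed: int
    contig_length: int = 30000
    gc: float = 0.42
    clusters: tuple[PlantedCluster, ...] = ()
    contig_id: str = "syncontig"


@dataclass(frozen=True)
class SyntheticReadSpec:
    seed: int
    read_length: int = 80
    counts: dict[str, int] = field(default_factory=dict)
    error_rate: float = 0.0


def sample_precursor(
    config: GrammarConfig = DEFAULT_GRAMMAR,
    seed: int | np.random.Generator = 0,
    max_total_aa: int = 80,
) -> str:
    """Draw one peptide guaranteed to pass the grammar it was sampled from.

    Leader and core lengths are uniform within the config bounds, jointly
    constrained to ``max_total_aa`` so every sampled precursor fits the
    short-ORF scanner's default envelope; the donor, acceptor, and leader
    threonine are placed per the rules; all other residues are i.i.d.
    over a rumen-like composition.  The peptide starts with M so it can
    be planted as an ORF.
    """
    rng = (
        seed if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    while True:
        leader_len = int(rng.integers(config.min_leader_aa,
                                      config.max_leader_aa + 1))
        core_len = int(rng.integers(config.min_core_aa, config.max_core_aa + 1))
        if leader_len + core_len <= max_total_aa:
            break
    residues = list(rng.choice(list(_AA), size=leader_len + core_len, p=_AA_FREQ))
    residues[0] = "M"
    residues[leader_len] = sorted(config.ring_donors)[
        int(rng.integers(len(config.ring_donors)))
    ]
    acceptor_pos = int(
        np.asarray(config.acceptor_positions)[
            int(rng.integers(len(config.acceptor_positions)))
        ]
    )
    residues[leader_len + acceptor_pos - 1] = sorted(config.ring_acceptors)[
        int(rng.integers(len(config.ring_acceptors)))
    ]
    thr_off = int(
        np.asarray(config.leader_thr_window)[
            int(rng.integers(len(config.leader_thr_window)))
        ]
    )
    residues[leader_len + thr_off] = "T"
    peptide = "".join(residues)
    assert best_split(peptide, config) is not None
    return peptide


def sample_decoy(
    config: GrammarConfig = DEFAULT_GRAMMAR, seed: int | np.random.Generator = 0
) -> str:
    """A short peptide guaranteed to violate the grammar.

    Sampled over an alphabet without the donor residue (and without T),
    so no candidate split can exist; the truth label is exactly negative.
    """
    rng = (
        seed if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    banned = set(config.ring_donors) | {"T"}
    letters = [a for a in _AA if a not in banned]
    freqs = np.array([_AA_FREQ[_AA.index(a)] for a in letters])
    freqs = freqs / freqs.sum()
    length = int(rng.integers(18, 40))
    residues = list(rng.choice(letters, size=length, p=freqs))
    residues[0] = "M"
    peptide = "".join(residues)
    assert best_split(peptide, config) is None
    return peptide


def reverse_translate(peptide: str, rng: np.random.Generator) -> str:
    """Uniform-codon reverse translation (table 11), no stop appended."""
    codons = []
    for aa in peptide:
        if aa == "X":
            aa = "A"  # ambiguous residues get an arbitrary codon
        options = _CODONS[aa]
        codons.append(options[int(rng.integers(len(options)))])
    return "".join(codons)


def _orf_nucleotides(peptide: str, rng: np.random.Generator) -> str:
    """ATG-started coding sequence for a peptide, stop codon appended."""
    body = reverse_translate(peptide[1:], rng)
    return "ATG" + body + "TAA"


def _random_dna(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(list("ACGT"), size=n, p=p))


def make_genome(
    spec: SyntheticGenomeSpec,
    grammar: GrammarConfig = DEFAULT_GRAMMAR,
) -> tuple[SequenceRecord, list[Feature], pd.DataFrame]:
    """Assemble a contig with planted clusters and exact truth labels.

    Returns the contig, truth features (GFF3-ready), and a truth table of
    every planted element (kind, coordinates, strand, sequence).  After
    assembly a repair pass mutates any chance background ORF that would
    pass the grammar, so planted precursors are the only grammar-passing
    ORFs outside the anchor genes — giving exact positive/negative labels
    for end-to-end evaluation.
    """
    rng = np.random.default_rng(spec.seed)
    contig = list(_random_dna(rng, spec.contig_length, spec.gc))
    features: list[Feature] = []
    truth_rows: list[dict] = []
    planted: list[tuple[int, int]] = []

    # lay clusters left to right with even spacing
    n_clusters = len(spec.clusters)
    if n_clusters:
        slot = spec.contig_length // n_clusters
    for ci, cluster in enumerate(spec.clusters):
        elements: list[tuple[str, str, str]] = []  # (kind, name, nt)
        for anchor in cluster.anchor_proteins:
            elements.append(
                ("anchor", anchor.id, _orf_nucleotides(anchor.residues, rng))
            )
        elements.append(
            ("precursor", f"precursor_{ci}", _orf_nucleotides(cluster.precursor, rng))
        )
        for di in range(cluster.n_decoys):
            decoy = sample_decoy(grammar, rng)
            elements.append(
                ("decoy", f"decoy_{ci}_{di}", _orf_nucleotides(decoy, rng))
            )
        total = sum(len(nt) for _, _, nt in elements)
        total += cluster.intergenic_gap * (len(elements) - 1)
        start = ci * slot + (slot - total) // 2
        if start < 0 or start + total > spec.contig_length:
            raise ValueError("planted cluster exceeds contig length")
        pos = start
        for kind, name, nt in elements:
            if cluster.strand == "-":
                nt = reverse_complement(nt)
            begin, end = pos, pos + len(nt)
            contig[begin:end] = list(nt)
            planted.append((begin, end))
            if kind in ("precursor", "decoy"):
                # guard stop immediately upstream in frame, so the planted
                # ATG is the first start of its stop-to-stop segment
                if cluster.strand == "+" and begin >= 3:
                    contig[begin - 3:begin] = list("TAA")
                    planted.append((begin - 3, begin))
                elif cluster.strand == "-" and end + 3 <= spec.contig_length:
                    contig[end:end + 3] = list(reverse_complement("TAA"))
                    planted.append((end, end + 3))
            peptide = {
                "anchor": next(
                    (a.residues for a in cluster.anchor_proteins if a.id == name),
                    "",
                ),
                "precursor": cluster.precursor,
                "decoy": "",
            }[kind]
            features.append(
                Feature(
                    contig=spec.contig_id, begin=begin, end=end,
                    strand=cluster.strand, kind="CDS",
                    attributes={"ID": name, "product": kind},
                )
            )
            truth_rows.append(
                {
                    "kind": kind, "name": name, "begin": begin, "end": end,
                    "strand": cluster.strand, "cluster": ci,
                    "peptide": peptide,
                }
            )
            pos = end + cluster.intergenic_gap

    seq = _repair_background("".join(contig), planted, truth_rows, grammar)
    record = SequenceRecord(id=spec.contig_id, residues=seq, alphabet=NUCLEOTIDE)
    truth = pd.DataFrame(
        truth_rows,
        columns=["kind", "name", "begin", "end", "strand", "cluster", "peptide"],
    )
    return record, features, truth


def _repair_background(
    seq: str,
    planted: list[tuple[int, int]],
    truth_rows: list[dict],
    grammar: GrammarConfig,
    max_rounds: int = 50,
) -> str:
    """Break chance grammar-passing ORFs outside the planted elements.

    Offending ORFs receive an early in-frame stop codon at a position not
    covered by any planted interval; ORFs fully inside planted intervals
    are left alone (the mining pipeline excludes anchor-internal ORFs).
    """
    from .orfs import find_orfs  # deferred: orfs imports nothing from here

    precursor_intervals = {
        (r["begin"], r["end"]) for r in truth_rows if r["kind"] == "precursor"
    }

    def covered(p: int) -> bool:
        return any(b <= p < e for b, e in planted)

    chars = list(seq)
    for _ in range(max_rounds):
        offenders = []
        for orf in find_orfs("".join(chars), min_aa=15, max_aa=80):
            if (orf.begin, orf.end) in precursor_intervals:
                continue
            if any(b <= orf.begin and orf.end <= e for b, e in planted):
                continue  # nested in a planted gene; pipeline filters these
            if best_split(orf.peptide, grammar) is not None:
                offenders.append(orf)
        if not offenders:
            return "".join(chars)
        for orf in offenders:
            _insert_stop(chars, orf, covered)
    raise RuntimeError("background repair did not converge")


def _insert_stop(chars: list[str], orf, covered) -> None:
    n_codons = (orf.end - orf.begin) // 3
    for ci in range(1, n_codons - 1):
        if orf.strand == "+":
            p = orf.begin + 3 * ci
            codon = "TAA"
        else:
            p = orf.end - 3 * (ci + 1)
            codon = reverse_complement("TAA")
        if not any(covered(q) for q in range(p, p + 3)):
            chars[p:p + 3] = list(codon)
            return
    raise RuntimeError("no mutable codon in offending ORF")


def make_reads(
    genes: list[SequenceRecord],
    read_spec: SyntheticReadSpec,
) -> tuple[list[SequenceRecord], dict[str, int]]:
    """Draw reads uniformly within each gene at the specified counts.

    Substitution errors are applied at ``error_rate`` per base.  Returns
    the reads and the truth counts actually drawn.
    """
    if not genes:
        raise ValueError("make_reads requires at least one gene")
    rng = np.random.default_rng(read_spec.seed)
    by_id = {g.id: g for g in genes}
    reads: list[SequenceRecord] = []
    truth: dict[str, int] = {}
    for gene_id in sorted(read_spec.counts):
        count = read_spec.counts[gene_id]
        gene = by_id[gene_id]
        if read_spec.read_length > len(gene):
            raise ValueError(
                f"read length {read_spec.read_length} exceeds gene "
                f"{gene_id!r} length {len(gene)}"
            )
        truth[gene_id] = count
        span = len(gene) - read_spec.read_length
        for i in range(count):
            start = int(rng.integers(0, span + 1))
            read = list(gene.residues[start:start + read_spec.read_length])
            if read_spec.error_rate > 0:
                mask = rng.random(len(read)) < read_spec.error_rate
                for j in np.flatnonzero(mask):
                    alternatives = [b for b in "ACGT" if b != read[j]]
                    read[j] = alternatives[int(rng.integers(3))]
            reads.append(
                SequenceRecord(
                    id=f"{gene_id}|read{i}",
                    residues="".join(read),
                    alphabet=NUCLEOTIDE,
                )
            )
    return reads, truth


def write_fastq(reads: list[SequenceRecord], path: str | Path) -> None:
    """Constant-quality FASTQ emission for simulated reads."""
    with Path(path).open("w") as fh:
        for read in reads:
            fh.write(f"@{read.id}\n{read.residues}\n+\n{'I' * len(read)}\n")


def read_fastq(path: str | Path) -> list[SequenceRecord]:
    reads = []
    with Path(path).open() as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    for i in range(0, len(lines) - 3, 4):
        reads.append(
            SequenceRecord(
                id=lines[i][1:].split()[0],
                residues=lines[i + 1],
                alphabet=NUCLEOTIDE,
            )
        )
    return reads


# ---------------------------------------------------------------------------
# packaged fixtures

def _data_path(name: str) -> Path:
    return Path(resources.files("lassomine") / "data" / name)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def load_fixtures() -> tuple[GenePresenceMatrix, pd.DataFrame, list[SequenceRecord]]:
    """Load the packaged presence matrix, precursor table, and anchor panel.

    Fixture files are checksum-verified against the packaged manifest;
    a mismatch raises :class:`IntegrityError`.
    """
    manifest = json.loads(_data_path("manifest.json").read_text())
    for name, digest in manifest.items():
        actual = _sha256(_data_path(name))
        if actual != digest:
            raise IntegrityError(f"fixture {name} checksum mismatch")
    matrix = read_presence_matrix(_data_path("table1_presence.tsv"))
    precursors = pd.read_csv(_data_path("table3_precursors.tsv"), sep="\t")
    panel = read_fasta(_data_path("synthetic_anchor_panel.faa"), PROTEIN)
    return matrix, precursors, panel


def load_core_panel() -> list[SequenceRecord]:
    """The packaged synthetic known-core panel (68 short peptides)."""
    return read_fasta(_data_path("synthetic_core_panel.faa"), PROTEIN)


def precursor_records(
    precursors: pd.DataFrame, expand_multiplicity: bool = False
) -> list[tuple[str, str]]:
    """(label, full peptide) pairs from the precursor fixture table.

    With ``expand_multiplicity`` a row carrying multiplicity m yields m
    copies (the table stores one sequence shared by several predicted
    precursors once).
    """
    out = []
    for _, row in precursors.iterrows():
        n = int(row["multiplicity"]) if expand_multiplicity else 1
        for _i in range(n):
            out.append((row["entry_label"], row["leader"] + row["core"]))
    return out
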