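"""Dereplication, read counting, and RPKM for biosynthetic genes.

Expression of cluster genes in a metatranscriptome is summarized as
RPKM = C * 1e9 / (L * N): C mapped reads on a gene of length L nt, N
total primary mapped reads in the dataset.  Near-duplicate genes are
collapsed first so each representative is counted once.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import pysam

from .formats import FormatError, SequenceRecord
from .homology import global_identity
from .orfs import reverse_complement


@dataclass(frozen=True)
class ExpressionRecord:
    gene_id: str
    length_nt: int
    count: int
    total_mapped: int
    rpkm_value: float

    def __post_init__(self) -> None:
        if self.count < 0 or self.total_mapped <= 0 or self.length_nt <= 0:
            raise ValueError("invalid expression record")


@dataclass
class DereplicationGroup:
    """One cluster of mutually similar genes with a representative."""

    representative: str
    members: list[str] = field(default_factory=list)
    identities: dict[str, float] = field(default_factory=dict)


def rpkm(count: int, length_nt: int, total_mapped: int) -> float:
    """Reads per kilobase per million mapped reads: C * 1e9 / (L * N)."""
    if length_nt <= 0 or total_mapped <= 0:
        raise ValueError("gene length and total mapped reads must be positive")
    if count < 0:
        raise ValueError("negative read count")
    return count * 1e9 / (length_nt * total_mapped)


def dereplicate(
    genes: Sequence[SequenceRecord], identity_threshold: float = 50.0
) -> list[DereplicationGroup]:
    """Greedy identity clustering; groups partition the input.

    Records are visited longest-first; each joins the first existing
    representative it matches with global identity strictly above the
    threshold, else founds its own group.
    """
    if not genes:
        raise ValueError("dereplicate requires at least one record")
    ordered = sorted(genes, key=lambda r: (-len(r), r.id))
    groups: list[DereplicationGroup] = []
    reps: dict[str, SequenceRecord] = {}
    for rec in ordered:
        placed = False
        for group in groups:
            ident = global_identity(rec.residues, reps[group.representative].residues)
            if ident > identity_threshold:
                group.members.append(rec.id)
                group.identities[rec.id] = ident
                placed = True
                break
        if not placed:
            groups.append(
                DereplicationGroup(representative=rec.id, members=[rec.id],
                                   identities={rec.id: 100.0})
            )
            reps[rec.id] = rec
    return groups


def count_reads(path: str | Path) -> tuple[dict[str, int], int]:
    """Per-reference primary mapped counts and the dataset total N.

    Accepts a SAM file (header required) or a two-column (gene, count)
    TSV.  For SAM, C counts primary mapped alignments per reference and
    N is the total of primary mapped alignments in the whole file;
    secondary and supplementary alignments are excluded from both.
    """
    path = Path(path)
    with path.open() as fh:
        first = fh.readline()
    if first.startswith("@"):
        return _count_sam(path)
    if first.startswith("\t") or len(first.split("\t")) == 2:
        return _count_tsv(path)
    raise FormatError(f"{path}: SAM input must carry a header")


def _count_sam(path: Path) -> tuple[dict[str, int], int]:
    counts: dict[str, int] = defaultdict(int)
    total = 0
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for aln in sam:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            total += 1
            counts[aln.reference_name] += 1
    return dict(counts), total


def _count_tsv(path: Path) -> tuple[dict[str, int], int]:
    counts: dict[str, int] = {}
    with path.open() as fh:
        for line in fh:
            if not line.strip():
                continue
            gene, value = line.rstrip("\n").split("\t")
            c = int(value)
            if c < 0:
                raise FormatError(f"{path}: negative count for {gene!r}")
            counts[gene] = counts.get(gene, 0) + c
    return counts, sum(counts.values())


def naive_map(
    reads: Sequence[SequenceRecord],
    genes: Sequence[SequenceRecord],
    min_exact_seed: int = 31,
) -> dict[str, int]:
    """Exact-substring read assignment (test stand-in for a real aligner).

    A read is assigned to a gene iff they share an exact substring of at
    least ``min_exact_seed`` nt on either strand; reads matching several
    genes go to the one with the longest shared substring, ties are
    discarded.  Returns per-gene counts (genes with zero reads included).
    """
    k = min_exact_seed
    index: dict[str, set[str]] = defaultdict(set)
    for gene in genes:
        seq = gene.residues
        for i in range(len(seq) - k + 1):
            index[seq[i:i + k]].add(gene.id)
    gene_seq = {g.id: g.residues for g in genes}
    counts = {g.id: 0 for g in genes}
    for read in reads:
        if len(read) < k:
            continue
        candidates: set[str] = set()
        for seq in (read.residues, reverse_complement(read.residues)):
            for i in range(len(seq) - k + 1):
                candidates |= index.get(seq[i:i + k], set())
        if not candidates:
            continue
        if len(candidates) == 1:
            counts[next(iter(candidates))] += 1
            continue
        scored = {
            gid: max(
                _longest_shared_substring(read.residues, gene_seq[gid]),
                _longest_shared_substring(
                    reverse_complement(read.residues), gene_seq[gid]
                ),
            )
            for gid in candidates
        }
        best = max(scored.values())
        winners = [gid for gid, s in scored.items() if s == best]
        if len(winners) == 1:
            counts[winners[0]] += 1
        # multi-mapped ties discarded
    return counts


def _longest_shared_substring(a: str, b: str) -> int:
    """Length of the longest common substring (small inputs only)."""
    if not a or not b:
        return 0
    prev = [0] * (len(b) + 1)
    best = 0
    for i in range(1, len(a) + 1):
        cur = [0] * (len(b) + 1)
        ai = a[i - 1]
        for j in range(1, len(b) + 1):
            if ai == b[j - 1]:
                cur[j] = prev[j - 1] + 1
                if cur[j] > best:
                    best = cur[j]
        prev = cur
    return best


def expression_table(
    counts: dict[str, int],
    gene_lengths: dict[str, int],
    total_mapped: int,
    dataset: str = "dataset",
) -> pd.DataFrame:
    """Long-format per-gene expression rows (gene, dataset, C, L, N, RPKM)."""
    rows = []
    for gene, length in sorted(gene_lengths.items()):
        c = counts.get(gene, 0)
        rows.append(
            {
                "gene": gene,
                "dataset": dataset,
                "C": c,
                "L": length,
                "N": total_mapped,
                "RPKM": rpkm(c, length, total_mapped),
            }
        )
    return pd.DataFrame(rows)
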