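"""Genomic-context windows and short-ORF enumeration.

The maturation-enzyme homologs found by the homology screen anchor a
window of flanking sequence; candidate precursor peptides are the short
open reading frames inside it, read in all six frames with the
bacterial/archaeal genetic code (table 11).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from Bio.Seq import Seq

from .formats import NUCLEOTIDE, FormatError, SequenceRecord
from .homology import GENETIC_CODE_TABLE, AnchorHit

START_CODONS = ("ATG", "GTG", "TTG")
STOP_CODONS = ("TAA", "TAG", "TGA")

DEFAULT_FLANK = 8500  # bp each side; examined context regions span roughly 5-17 kb

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(dna: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet."""
    return dna.upper().translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomicWindow:
    """A context window around one or more anchor hits (0-based half-open)."""

    contig: str
    begin: int
    end: int
    anchor_ids: tuple[str, ...]

    def __len__(self) -> int:
        return self.end - self.begin


@dataclass(frozen=True)
class OrfCandidate:
    """A short ORF translated from a window.

    The nucleotide interval is 0-based half-open in window coordinates and
    includes the stop codon; ``peptide`` excludes the terminal stop and
    always starts with M (alternative starts are translated as M).
    ``has_ambiguous`` flags peptides containing X from N-codons.
    """

    contig: str
    begin: int
    end: int
    strand: str
    frame: int
    peptide: str
    distance_to_anchor: int = -1
    has_ambiguous: bool = False

    def __post_init__(self) -> None:
        if (self.end - self.begin) % 3 != 0:
            raise ValueError("ORF interval length must be divisible by 3")
        if len(self.peptide) != (self.end - self.begin) // 3 - 1:
            raise ValueError("peptide length inconsistent with interval")
        if not self.peptide.startswith("M"):
            raise ValueError("ORF peptide must start with M")


def extract_window(
    contig: SequenceRecord,
    anchors: Sequence[AnchorHit],
    flank: int = DEFAULT_FLANK,
) -> GenomicWindow:
    """Window spanning all anchors plus ``flank`` bp each side, clipped."""
    if contig.alphabet != NUCLEOTIDE:
        raise FormatError("extract_window requires a nucleotide contig")
    anchors = [a for a in anchors if a.subject_id == contig.id]
    if not anchors:
        raise ValueError(f"no anchors on contig {contig.id!r}")
    begin = max(0, min(a.subject_begin for a in anchors) - flank)
    end = min(len(contig), max(a.subject_end for a in anchors) + flank)
    return GenomicWindow(
        contig=contig.id,
        begin=begin,
        end=end,
        anchor_ids=tuple(a.query_id for a in anchors),
    )


def _translate_codon(codon: str) -> str:
    if "N" in codon:
        return "X"
    return str(Seq(codon).translate(table=GENETIC_CODE_TABLE))


def _orfs_one_strand(
    seq: str, strand: str, window_len: int, min_aa: int, max_aa: int,
    contig: str,
) -> list[OrfCandidate]:
    out: list[OrfCandidate] = []
    n = len(seq)
    for frame in range(3):
        codon_starts = range(frame, n - 2, 3)
        codons = [seq[i:i + 3] for i in codon_starts]
        # split into stop-to-stop segments, keep only segments ending in a stop
        seg_start = 0
        for idx, codon in enumerate(codons):
            if codon in STOP_CODONS:
                _emit_segment(
                    out, codons, seg_start, idx, frame, strand, window_len,
                    min_aa, max_aa, contig,
                )
                seg_start = idx + 1
        # trailing segment has no stop codon: not a complete ORF, skipped
    return out


def _emit_segment(
    out: list[OrfCandidate],
    codons: list[str],
    seg_start: int,
    stop_idx: int,
    frame: int,
    strand: str,
    window_len: int,
    min_aa: int,
    max_aa: int,
    contig: str,
) -> None:
    """Report ORFs of one stop-to-stop segment (``stop_idx`` holds the stop).

    The primary ORF runs from the first start codon in the segment.  When
    its peptide exceeds ``max_aa``, internal starts giving peptides within
    bounds are reported instead (precursors are short).
    """
    starts = [
        i for i in range(seg_start, stop_idx)
        if codons[i] in START_CODONS
    ]
    if not starts:
        return
    chosen: list[int] = []
    first = starts[0]
    primary_len = stop_idx - first
    if primary_len <= max_aa:
        if primary_len >= min_aa:
            chosen.append(first)
    else:
        chosen.extend(
            s for s in starts[1:]
            if min_aa <= stop_idx - s <= max_aa
        )
    for s in chosen:
        length_aa = stop_idx - s
        pep = "M" + "".join(_translate_codon(c) for c in codons[s + 1:stop_idx])
        nt_begin_on_strand = frame + 3 * s
        nt_end_on_strand = frame + 3 * (stop_idx + 1)
        if strand == "+":
            begin, end = nt_begin_on_strand, nt_end_on_strand
        else:
            begin = window_len - nt_end_on_strand
            end = window_len - nt_begin_on_strand
        out.append(
            OrfCandidate(
                contig=contig,
                begin=begin,
                end=end,
                strand=strand,
                frame=frame,
                peptide=pep,
                has_ambiguous="X" in pep,
            )
        )
        assert len(pep) == length_aa


def find_orfs(
    window_seq: str,
    min_aa: int = 15,
    max_aa: int = 80,
    contig: str = "window",
) -> list[OrfCandidate]:
    """Enumerate complete short ORFs in six frames of a window sequence.

    An ORF runs from the first ATG/GTG/TTG after an in-frame stop to the
    next in-frame stop (stop included in the interval).  Peptides outside
    ``[min_aa, max_aa]`` are dropped; if the primary ORF of a segment is
    longer than ``max_aa``, in-bounds internal-start ORFs are reported.
    Reverse-strand ORFs are reported in forward window coordinates.
    """
    seq = window_seq.upper()
    bad = set(seq) - set("ACGTN")
    if bad:
        raise FormatError(f"non-DNA characters in window: {sorted(bad)}")
    if len(seq) < 3 * (min_aa + 1):
        return []
    orfs = _orfs_one_strand(seq, "+", len(seq), min_aa, max_aa, contig)
    orfs += _orfs_one_strand(
        reverse_complement(seq), "-", len(seq), min_aa, max_aa, contig
    )
    orfs.sort(key=lambda o: (o.begin, o.end, o.strand))
    return orfs


def annotate_distance(
    orfs: Sequence[OrfCandidate],
    window: GenomicWindow,
    anchors: Sequence[AnchorHit],
) -> list[OrfCandidate]:
    """Attach each ORF's bp distance to the nearest anchor interval.

    ORF coordinates are window-relative; anchors are contig-relative and
    are shifted by the window origin before measuring.
    """
    rel = [
        (a.subject_begin - window.begin, a.subject_end - window.begin)
        for a in anchors
    ]
    out = []
    for orf in orfs:
        dist = min(
            (
                0
                if orf.begin < e and b < orf.end
                else (b - orf.end if b >= orf.end else orf.begin - e)
            )
            for b, e in rel
        )
        out.append(
            OrfCandidate(
                contig=orf.contig,
                begin=orf.begin,
                end=orf.end,
                strand=orf.strand,
                frame=orf.frame,
                peptide=orf.peptide,
                distance_to_anchor=dist,
                has_ambiguous=orf.has_ambiguous,
            )
        )
    return out
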