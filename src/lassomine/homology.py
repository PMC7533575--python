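"""Anchor-gene homology screening.

Detects homologs of the lasso maturation proteins (leader peptidase,
cyclase, ABC transporter) and of known core peptides in protein sets or
six-frame translations of genomic sequence, using exact Smith-Waterman
local alignment with affine gaps instead of a heuristic search: targets
here are desk-scale and determinism matters more than speed.

Hits are filtered on percent identity and a Karlin-Altschul E-value
E = K * m * n * exp(-lambda * S).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq

from .formats import NUCLEOTIDE, SequenceRecord

# NCBI translation table for bacteria/archaea
GENETIC_CODE_TABLE = 11


@dataclass(frozen=True)
class AlignmentParams:
    """Scoring parameters for the local-alignment screen.

    A gap of length k costs ``gap_open + (k - 1) * gap_extend``.  K and
    lambda are the commonly published gapped-BLOSUM62 constants used in
    the E-value formula; they are configurable because published values
    vary with the scoring system.
    """

    matrix: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1
    karlin_K: float = 0.041
    karlin_lambda: float = 0.267

    def __post_init__(self) -> None:
        if not (self.gap_open >= self.gap_extend >= 1):
            raise ValueError("require gap_open >= gap_extend >= 1")
        if self.karlin_K <= 0 or self.karlin_lambda <= 0:
            raise ValueError("Karlin K and lambda must be positive")


DEFAULT_PARAMS = AlignmentParams()


@dataclass(frozen=True)
class AnchorHit:
    """A positive local-alignment match of a reference protein in a target.

    ``subject_begin``/``subject_end`` are 0-based half-open on the subject;
    for genomic subjects they are nucleotide coordinates on the forward
    strand and ``strand`` records the hit orientation, otherwise strand is
    "+" and coordinates are residue positions.
    """

    query_id: str
    subject_id: str
    score: int
    identity_pct: float
    evalue: float
    subject_begin: int
    subject_end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0.0 <= self.identity_pct <= 100.0):
            raise ValueError("identity_pct outside [0, 100]")
        if self.evalue < 0:
            raise ValueError("negative E-value")
        if self.score <= 0:
            raise ValueError("hits require a positive alignment score")


def _aligner(params: AlignmentParams) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load(params.matrix)
    aligner.open_gap_score = -params.gap_open
    aligner.extend_gap_score = -params.gap_extend
    return aligner


def local_align(
    query: str,
    subject: str,
    params: AlignmentParams = DEFAULT_PARAMS,
) -> tuple[int, float, tuple[tuple[int, int], tuple[int, int]]]:
    """Best affine-gap local alignment of two protein sequences.

    Returns ``(score, identity_pct, ((q_begin, q_end), (s_begin, s_end)))``.
    Identity is identical columns over all alignment columns (internal gaps
    included, end overhangs excluded — local alignments have none).  A pair
    with no positive-scoring alignment returns score 0 and empty intervals.
    Equal-score alignments are resolved to the earliest subject start, then
    earliest query start.
    """
    query = query.upper().replace("*", "X")
    subject = subject.upper().replace("*", "X")
    if not query or not subject:
        raise ValueError("local_align requires non-empty sequences")
    aligner = _aligner(params)
    score = aligner.score(query, subject)
    if score <= 0:
        return 0, 0.0, ((0, 0), (0, 0))
    alignments = aligner.align(query, subject)
    best = None
    best_key = None
    # cap enumeration: co-optimal alignments can be numerous but the
    # deterministic tie-break only needs the lexicographic minimum
    for i, aln in enumerate(alignments):
        q_blocks, s_blocks = aln.aligned[0], aln.aligned[1]
        key = (int(s_blocks[0][0]), int(q_blocks[0][0]))
        if best_key is None or key < best_key:
            best_key = key
            best = aln
        if i >= 63:
            break
    assert best is not None
    identities = 0
    columns = 0
    q_blocks, s_blocks = best.aligned[0], best.aligned[1]
    prev_q = prev_s = None
    for (qb, qe), (sb, se) in zip(q_blocks, s_blocks):
        if prev_q is not None:
            columns += (qb - prev_q) + (sb - prev_s)  # internal gap columns
        for off in range(qe - qb):
            columns += 1
            if query[qb + off] == subject[sb + off]:
                identities += 1
        prev_q, prev_s = qe, se
    identity_pct = 100.0 * identities / columns if columns else 0.0
    q_iv = (int(q_blocks[0][0]), int(q_blocks[-1][1]))
    s_iv = (int(s_blocks[0][0]), int(s_blocks[-1][1]))
    return int(score), identity_pct, (q_iv, s_iv)


def evalue(
    score: float,
    query_len: int,
    subject_total_len: int,
    params: AlignmentParams = DEFAULT_PARAMS,
) -> float:
    """Karlin-Altschul expect value ``K * m * n * exp(-lambda * S)``.

    ``subject_total_len`` is the summed length of the searched database, so
    E scales linearly with search space, as in BLAST.
    """
    if query_len <= 0 or subject_total_len <= 0:
        raise ValueError("sequence lengths must be positive")
    return (
        params.karlin_K * query_len * subject_total_len
        * math.exp(-params.karlin_lambda * score)
    )


def six_frame_translations(dna: str) -> list[tuple[str, str, int]]:
    """Translate all six frames with genetic code table 11.

    Returns ``(peptide, strand, frame)`` triples; stops are '*'.
    """
    out = []
    seq = Seq(dna.upper())
    rc = seq.reverse_complement()
    for strand, s in (("+", seq), ("-", rc)):
        for frame in range(3):
            sub = s[frame:]
            sub = sub[: len(sub) - len(sub) % 3]
            if len(sub) == 0:
                continue
            out.append((str(sub.translate(table=GENETIC_CODE_TABLE)),
                        strand, frame))
    return out


def _protein_to_genomic(
    strand: str, frame: int, contig_len: int, p_begin: int, p_end: int
) -> tuple[int, int]:
    """Map a protein interval in a translation frame to forward-strand nt."""
    nt_begin = frame + 3 * p_begin
    nt_end = frame + 3 * p_end
    if strand == "+":
        return nt_begin, nt_end
    return contig_len - nt_end, contig_len - nt_begin


def screen_proteins(
    queries: Sequence[SequenceRecord],
    targets: Sequence[SequenceRecord],
    min_identity: float = 30.0,
    max_evalue: float = 1e-5,
    params: AlignmentParams = DEFAULT_PARAMS,
) -> list[AnchorHit]:
    """Screen a reference protein panel against protein or nucleotide targets.

    Nucleotide targets are searched in all six reading frames and hit
    coordinates are reported in forward-strand nucleotide space.  A hit
    must reach ``identity_pct >= min_identity`` and ``evalue < max_evalue``.
    Hits are sorted by ascending E-value (then query/subject id).
    """
    if not queries:
        raise ValueError("empty query panel")
    if not targets:
        return []
    # database size for E-values: total residues searched
    subject_frames: list[tuple[SequenceRecord, str, str, int]] = []
    total_len = 0
    for target in targets:
        if target.alphabet == NUCLEOTIDE:
            for pep, strand, frame in six_frame_translations(target.residues):
                subject_frames.append((target, pep, strand, frame))
                total_len += len(pep)
        else:
            subject_frames.append((target, target.residues, "+", -1))
            total_len += len(target)
    hits: list[AnchorHit] = []
    for query in queries:
        for target, pep, strand, frame in subject_frames:
            score, ident, (q_iv, s_iv) = local_align(query.residues, pep, params)
            if score <= 0:
                continue
            ev = evalue(score, len(query), total_len, params)
            if ident >= min_identity and ev < max_evalue:
                if frame >= 0:
                    begin, end = _protein_to_genomic(
                        strand, frame, len(target), s_iv[0], s_iv[1]
                    )
                else:
                    begin, end = s_iv
                hits.append(
                    AnchorHit(
                        query_id=query.id,
                        subject_id=target.id,
                        score=score,
                        identity_pct=ident,
                        evalue=ev,
                        subject_begin=begin,
                        subject_end=end,
                        strand=strand if frame >= 0 else "+",
                    )
                )
    hits.sort(key=lambda h: (h.evalue, h.query_id, h.subject_id, h.subject_begin))
    return hits


def screen_cores(
    known_cores: Sequence[SequenceRecord],
    candidates: Sequence[SequenceRecord],
    min_identity: float = 70.0,
    params: AlignmentParams = DEFAULT_PARAMS,
) -> list[AnchorHit]:
    """Match candidate core peptides against the known-core panel.

    Follows the strict ">70%"-style rule: a hit requires
    ``identity_pct > min_identity``, with identity taken over an
    end-to-end alignment of the two cores — short peptides are compared
    whole, so a high-identity fragment cannot mask a divergent tail.
    No E-value gate; cores are too short for meaningful expect values.
    """
    hits: list[AnchorHit] = []
    for cand in candidates:
        for core in known_cores:
            ident = global_identity(core.residues, cand.residues, params)
            if ident > min_identity:
                score, _, (_, s_iv) = local_align(core.residues, cand.residues,
                                                  params)
                hits.append(
                    AnchorHit(
                        query_id=core.id,
                        subject_id=cand.id,
                        score=max(score, 1),
                        identity_pct=ident,
                        evalue=0.0,
                        subject_begin=s_iv[0],
                        subject_end=s_iv[1],
                    )
                )
    hits.sort(key=lambda h: (-h.identity_pct, h.query_id, h.subject_id))
    return hits


def global_identity(
    a: str, b: str, params: AlignmentParams = DEFAULT_PARAMS
) -> float:
    """Percent identity from an end-to-end (Needleman-Wunsch) alignment.

    Used by expression dereplication; identity = matches / alignment
    columns * 100, terminal gaps included (full-gene comparison intent).
    """
    if not a or not b:
        raise ValueError("global_identity requires non-empty sequences")
    a, b = a.upper(), b.upper()
    aligner = _aligner(params)
    aligner.mode = "global"
    try:
        aln = aligner.align(a, b)[0]
    except ValueError:
        # nucleotide input: BLOSUM62 lacks some letters; fall back to match/mismatch
        aligner = PairwiseAligner()
        aligner.mode = "global"
        aligner.match_score = 2
        aligner.mismatch_score = -1
        aligner.open_gap_score = -4
        aligner.extend_gap_score = -1
        aln = aligner.align(a, b)[0]
    q_blocks, s_blocks = aln.aligned[0], aln.aligned[1]
    identities = 0
    aligned_cols = 0
    for (qb, qe), (sb, se) in zip(q_blocks, s_blocks):
        for off in range(qe - qb):
            aligned_cols += 1
            if a[qb + off] == b[sb + off]:
                identities += 1
    # total columns of the global alignment = len(a) + len(b) - aligned pairs
    columns = len(a) + len(b) - aligned_cols
    return 100.0 * identities / columns if columns else 0.0


def hits_to_rows(hits: Sequence[AnchorHit]) -> list[dict]:
    """Flatten hits for TSV emission."""
    return [
        {
            "query": h.query_id,
            "subject": h.subject_id,
            "score": h.score,
            "pident": round(h.identity_pct, 2),
            "evalue": h.evalue,
            "sstart": h.subject_begin,
            "send": h.subject_end,
            "strand": h.strand,
        }
        for h in hits
    ]
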