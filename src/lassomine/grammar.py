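"""The residue-position grammar for lasso precursor recognition.

A lasso precursor splits into a leader peptide and a core peptide.  The
core starts with the macrolactam ring donor (glycine at core position 1)
whose N-terminal amine condenses with the side-chain carboxyl of an
aspartate at core position 8 or 9; leader cleavage happens just after a
conserved threonine sitting a few residues before the core.  Most cores
additionally keep a serine near their C-terminus.  This module enumerates
every split of a peptide consistent with those rules, scores the stated
preferences (threonine exactly at -3, C-terminal serine), and picks the
best split deterministically.

Positions follow the field convention: core positions are 1-based from
the donor; the threonine offset is negative, relative to the core start
(-3 means third residue before the donor).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .formats import _AA_ALPHABET


@dataclass(frozen=True)
class GrammarConfig:
    """Tunable rules of the precursor grammar.

    Defaults encode the glycine-1 / aspartate-8-or-9 ring, a leader
    threonine within 2-4 residues of the cleavage site, and the length
    envelope of observed rumen precursors.  Cys donors and Glu acceptors,
    allowed by the broader lasso definition, are off by default because
    the rumen sequences all use G/D; switch by widening the residue sets.
    """

    ring_donors: frozenset[str] = frozenset({"G"})
    ring_acceptors: frozenset[str] = frozenset({"D"})
    acceptor_positions: tuple[int, ...] = (8, 9)
    leader_thr_window: tuple[int, ...] = (-4, -3, -2)
    min_leader_aa: int = 10
    max_leader_aa: int = 40
    min_core_aa: int = 15
    max_core_aa: int = 50
    cterm_ser_window: int = 6

    def __post_init__(self) -> None:
        if not self.acceptor_positions or not self.leader_thr_window:
            raise ValueError("acceptor and threonine windows must be non-empty")
        if any(p < 2 or p > self.min_core_aa for p in self.acceptor_positions):
            raise ValueError("acceptor positions must lie in [2, min_core_aa]")
        if not (0 < self.min_leader_aa <= self.max_leader_aa):
            raise ValueError("bad leader length bounds")
        if not (0 < self.min_core_aa <= self.max_core_aa):
            raise ValueError("bad core length bounds")


DEFAULT_GRAMMAR = GrammarConfig()


@dataclass(frozen=True)
class PrecursorSplit:
    """A leader/core partition of one precursor peptide."""

    full: str
    leader: str
    core: str
    acceptor_pos: int          # 1-based core position of the ring acceptor
    thr_offset: int            # negative offset of the leader Thr from core start
    has_cterm_ser: bool
    score: float = 0.0

    def __post_init__(self) -> None:
        if self.leader + self.core != self.full:
            raise ValueError("leader + core must reconstruct the full peptide")

    @property
    def donor_pos(self) -> int:
        """Core position of the ring donor (always 1)."""
        return 1

    @property
    def donor_residue(self) -> str:
        return self.core[0]

    @property
    def acceptor_residue(self) -> str:
        return self.core[self.acceptor_pos - 1]


def _check_protein(peptide: str) -> str:
    peptide = peptide.upper()
    bad = set(peptide) - _AA_ALPHABET
    if bad:
        raise ValueError(f"non-protein characters in peptide: {sorted(bad)}")
    return peptide


def enumerate_splits(
    peptide: str, config: GrammarConfig = DEFAULT_GRAMMAR
) -> list[PrecursorSplit]:
    """All splits of ``peptide`` consistent with the grammar.

    One candidate per donor position g (0-based index into the peptide)
    such that the residue at g is a ring donor, a ring acceptor sits at a
    permitted core position, a threonine lies in the leader window before
    g, and leader/core lengths are within bounds.  When acceptors are
    available at several permitted positions the smallest is taken.
    """
    peptide = _check_protein(peptide)
    out: list[PrecursorSplit] = []
    n = len(peptide)
    for g in range(n):
        if peptide[g] not in config.ring_donors:
            continue
        leader_len = g
        core_len = n - g
        if not (config.min_leader_aa <= leader_len <= config.max_leader_aa):
            continue
        if not (config.min_core_aa <= core_len <= config.max_core_aa):
            continue
        acceptor_pos = None
        for pos in sorted(config.acceptor_positions):
            idx = g + pos - 1
            if idx < n and peptide[idx] in config.ring_acceptors:
                acceptor_pos = pos
                break
        if acceptor_pos is None:
            continue
        # prefer the canonical -3 threonine, then the nearest-to-cleavage T
        thr_offset = None
        preference = sorted(config.leader_thr_window,
                            key=lambda off: (off != -3, -off))
        for off in preference:
            idx = g + off
            if 0 <= idx < g and peptide[idx] == "T":
                thr_offset = off
                break
        if thr_offset is None:
            continue
        core = peptide[g:]
        tail = core[-config.cterm_ser_window:]
        split = PrecursorSplit(
            full=peptide,
            leader=peptide[:g],
            core=core,
            acceptor_pos=acceptor_pos,
            thr_offset=thr_offset,
            has_cterm_ser="S" in tail,
        )
        out.append(split)
    return [
        PrecursorSplit(
            full=s.full, leader=s.leader, core=s.core,
            acceptor_pos=s.acceptor_pos, thr_offset=s.thr_offset,
            has_cterm_ser=s.has_cterm_ser, score=score_split(s, config),
        )
        for s in out
    ]


def score_split(
    candidate: PrecursorSplit, config: GrammarConfig = DEFAULT_GRAMMAR
) -> float:
    """Additive preference score for one candidate split.

    +2 for the canonical threonine exactly at -3, +1 for -4 or -2; +1 for
    a serine in the core's C-terminal window; +1 for a permitted acceptor
    position (always true for enumerated candidates, keeping scores >= 2).
    """
    score = 0.0
    if candidate.thr_offset == -3:
        score += 2.0
    elif candidate.thr_offset in (-4, -2):
        score += 1.0
    if candidate.has_cterm_ser:
        score += 1.0
    if candidate.acceptor_pos in config.acceptor_positions:
        score += 1.0
    return score


def best_split(
    peptide: str, config: GrammarConfig = DEFAULT_GRAMMAR
) -> PrecursorSplit | None:
    """Highest-scoring split, or None when the grammar rejects the peptide.

    Ties go to the longest leader (latest donor), then the smallest
    acceptor position — matching how the curated splits favour late
    donors in these precursors.
    """
    candidates = enumerate_splits(peptide, config)
    if not candidates:
        return None
    return max(
        candidates,
        key=lambda s: (s.score, len(s.leader), -s.acceptor_pos),
    )


def strip_label_suffix(label: str) -> str:
    """Genome label with any parenthetical precursor suffix removed."""
    return label.split("(")[0].strip()


def batch_split(
    records: Iterable[tuple[str, str]],
    config: GrammarConfig = DEFAULT_GRAMMAR,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Run :func:`best_split` over (label, peptide) pairs.

    Returns the per-record table (one row per input, with empty leader/core
    for peptides the grammar rejects) and a summary with the number of
    passing records and the number of distinct genome labels among them
    (parenthetical suffixes such as "(#1)" stripped).
    """
    rows = []
    passing_genomes: set[str] = set()
    n_pass = 0
    for label, peptide in records:
        split = best_split(peptide, config)
        if split is None:
            rows.append(
                {"label": label, "leader": "", "core": "", "core_length": 0,
                 "donor_pos": 0, "acceptor_pos": 0, "thr_offset": 0,
                 "cterm_ser": False, "score": float("nan"), "passed": False}
            )
            continue
        n_pass += 1
        passing_genomes.add(strip_label_suffix(label))
        rows.append(
            {
                "label": label,
                "leader": split.leader,
                "core": split.core,
                "core_length": len(split.core),
                "donor_pos": split.donor_pos,
                "acceptor_pos": split.acceptor_pos,
                "thr_offset": split.thr_offset,
                "cterm_ser": split.has_cterm_ser,
                "score": split.score,
                "passed": True,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=["label", "leader", "core", "core_length", "donor_pos",
                 "acceptor_pos", "thr_offset", "cterm_ser", "score", "passed"],
    )
    summary = {"n_passing": n_pass, "n_distinct_genomes": len(passing_genomes)}
    return table, summary


def ring_annotation(split: PrecursorSplit) -> tuple[str, str, int]:
    """Describe the macrolactam ring of a split.

    Returns (donor, acceptor, ring length) where donor/acceptor are
    residue+core-position strings (e.g. "G1", "D8") and ring length is
    the number of residues enclosed, donor through acceptor inclusive.
    """
    donor = f"{split.donor_residue}{split.donor_pos}"
    acceptor = f"{split.acceptor_residue}{split.acceptor_pos}"
    return donor, acceptor, split.acceptor_pos
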