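"""Positional conservation profiles for precursor sets.

Precursors are stacked on the shared ring-donor landmark (the core-start
glycine), leaders right-justified before it and cores left-justified
after — a deterministic anchor layout standing in for a multiple aligner,
meaningful here because every precursor shares the donor column.  Each
column then yields residue frequencies, occupancy, and information
content in bits, the quantities a sequence logo displays.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .grammar import PrecursorSplit

GAP = "-"
_LOG2_20 = math.log2(20)


@dataclass
class PositionProfile:
    """Per-column statistics of an aligned precursor matrix.

    ``frequencies[i]`` maps residues to frequencies summing to 1 over the
    non-gap residues of column i; ``occupancy[i]`` is the non-gap
    fraction; ``information[i]`` is (log2 20 - H) * occupancy in bits,
    zero for all-gap columns.  ``donor_column`` is the index of the
    shared core-start column when built from an anchor layout.
    """

    frequencies: list[dict[str, float]]
    occupancy: list[float]
    information: list[float]
    donor_column: int = -1

    def __len__(self) -> int:
        return len(self.frequencies)


def anchor_align(splits: Sequence[PrecursorSplit]) -> list[str]:
    """Equal-length rows aligned on the core start.

    The donor glycine of every split lands in one shared column (index =
    longest leader); gaps pad short leaders on the left and short cores
    on the right.
    """
    if len(splits) < 2:
        raise ValueError("anchor alignment needs at least 2 splits")
    max_leader = max(len(s.leader) for s in splits)
    max_core = max(len(s.core) for s in splits)
    rows = []
    for s in splits:
        row = (
            GAP * (max_leader - len(s.leader))
            + s.leader
            + s.core
            + GAP * (max_core - len(s.core))
        )
        rows.append(row)
    return rows


def build_profile(matrix: Sequence[str], donor_column: int = -1) -> PositionProfile:
    """Column frequencies, occupancy, and information content in bits."""
    if not matrix:
        raise ValueError("empty alignment matrix")
    width = len(matrix[0])
    if any(len(row) != width for row in matrix):
        raise ValueError("alignment rows must have equal length")
    n_rows = len(matrix)
    frequencies: list[dict[str, float]] = []
    occupancy: list[float] = []
    information: list[float] = []
    for col in range(width):
        residues = [row[col] for row in matrix if row[col] != GAP]
        occ = len(residues) / n_rows
        occupancy.append(occ)
        if not residues:
            frequencies.append({})
            information.append(0.0)
            continue
        freq: dict[str, float] = {}
        for r in residues:
            freq[r] = freq.get(r, 0.0) + 1.0
        total = len(residues)
        freq = {r: c / total for r, c in freq.items()}
        frequencies.append(freq)
        entropy = -sum(p * math.log2(p) for p in freq.values() if p > 0)
        information.append(max(0.0, (_LOG2_20 - entropy) * occ))
    return PositionProfile(
        frequencies=frequencies,
        occupancy=occupancy,
        information=information,
        donor_column=donor_column,
    )


def profile_splits(splits: Sequence[PrecursorSplit]) -> PositionProfile:
    """Anchor-align splits and profile the result in one step."""
    rows = anchor_align(splits)
    donor_column = max(len(s.leader) for s in splits)
    return build_profile(rows, donor_column=donor_column)


def consensus(profile: PositionProfile, min_freq: float = 0.5) -> str:
    """Majority-residue string with '.' at low-consensus columns.

    The column letter is the argmax residue when its frequency reaches
    ``min_freq``; argmax ties break alphabetically.
    """
    letters = []
    for freq in profile.frequencies:
        if not freq:
            letters.append(".")
            continue
        best = min(freq, key=lambda r: (-freq[r], r))
        letters.append(best if freq[best] >= min_freq else ".")
    return "".join(letters)


def profile_table(profile: PositionProfile, top_n: int = 3) -> pd.DataFrame:
    """Flatten a profile for TSV emission (position, occupancy, IC, top residues)."""
    rows = []
    for i, freq in enumerate(profile.frequencies):
        ranked = sorted(freq.items(), key=lambda kv: (-kv[1], kv[0]))[:top_n]
        rows.append(
            {
                "position": i,
                "occupancy": round(profile.occupancy[i], 6),
                "information_bits": round(profile.information[i], 6),
                "top_residues": ",".join(
                    f"{r}:{p:.3f}" for r, p in ranked
                ),
            }
        )
    return pd.DataFrame(rows)
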