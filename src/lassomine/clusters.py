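"""Cluster completeness calls and genomic-context co-occurrence tallies.

A biosynthetic cluster is *complete* when the union of the two mining
tools' calls covers all three essential genes (precursor lasA, peptidase
lasB, cyclase lasC); the transporter lasD never affects completeness.
Genomes with some but not all essential machinery are *incomplete*.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

from .formats import GENES, TOOLS, Feature, GenePresenceMatrix

ESSENTIAL = ("lasA", "lasB", "lasC")

DEFAULT_KEYWORDS: dict[str, tuple[str, ...]] = {
    "kinase": ("kinase",),
    "transcriptional regulator": ("transcriptional regulator",
                                  "response regulator"),
    "glycosyltransferase": ("glycosyltransferase", "epsh"),
    "nucleotidyltransferase": ("nucleotidyltransferase",),
    "PqqD": ("pqqd", "coenzyme pqq"),
    "transporter": ("transporter",),
}


@dataclass(frozen=True)
class CompletenessCall:
    genome: str
    presence: Mapping[str, bool]        # union over tools, per gene
    status: str                         # complete | incomplete | none

    @property
    def genus(self) -> str:
        return self.genome.split()[0]


def union_presence(matrix: GenePresenceMatrix, genome: str) -> dict[str, bool]:
    """Logical OR of the two tools' calls for each gene."""
    if genome not in matrix.cells:
        raise KeyError(f"unknown genome {genome!r}")
    return {
        gene: any(matrix.presence(genome, tool, gene) for tool in TOOLS)
        for gene in GENES
    }


def _status(presence: Mapping[str, bool]) -> str:
    if all(presence[g] for g in ESSENTIAL):
        return "complete"
    if not any(presence.values()):
        return "none"
    return "incomplete"


def classify(
    matrix: GenePresenceMatrix,
) -> tuple[list[CompletenessCall], dict[str, int]]:
    """Completeness call per genome plus {complete, incomplete} counts."""
    calls = [
        CompletenessCall(
            genome=g, presence=union_presence(matrix, g),
            status=_status(union_presence(matrix, g)),
        )
        for g in matrix.genomes
    ]
    counts = Counter(c.status for c in calls)
    return calls, {
        "complete": counts.get("complete", 0),
        "incomplete": counts.get("incomplete", 0),
    }


def per_tool_counts(matrix: GenePresenceMatrix) -> dict[str, dict[str, int]]:
    """Per-tool positive genomes and lasD carriage within the positives.

    A genome is positive for a tool iff that tool alone marks at least one
    essential gene; lasD is counted inside each tool's positive set.
    """
    out: dict[str, dict[str, int]] = {}
    for tool in TOOLS:
        positive = [
            g for g in matrix.genomes
            if any(matrix.presence(g, tool, gene) for gene in ESSENTIAL)
        ]
        with_lasD = [g for g in positive if matrix.presence(g, tool, "lasD")]
        out[tool] = {"positive": len(positive), "with_lasD": len(with_lasD)}
    return out


def genus_summary(
    calls: Sequence[CompletenessCall],
) -> dict[str, dict[str, int]]:
    """Complete/incomplete counts per genus (first token of the label)."""
    out: dict[str, dict[str, int]] = {}
    for call in calls:
        bucket = out.setdefault(call.genus,
                                {"complete": 0, "incomplete": 0, "none": 0})
        bucket[call.status] += 1
    return out


def tally_cooccurrence(
    windows: Sequence[Sequence[Feature]],
    keywords: Mapping[str, Sequence[str]] | None = None,
) -> dict[str, dict[str, float]]:
    """Count co-occurring gene categories across cluster context windows.

    ``windows`` is one feature list per cluster; a cluster counts once per
    category no matter how many member genes match.  Product text is
    matched case-insensitively against the keyword substrings; features
    matching no category fall into "other".  Fractions are over the number
    of clusters (0 when there are no clusters).
    """
    keywords = keywords or DEFAULT_KEYWORDS
    n_clusters = len(windows)
    counts: Counter[str] = Counter()
    for features in windows:
        seen: set[str] = set()
        for feat in features:
            product = feat.product.lower()
            if not product:
                continue
            matched = False
            for category, needles in keywords.items():
                if any(needle.lower() in product for needle in needles):
                    seen.add(category)
                    matched = True
            if not matched:
                seen.add("other")
        counts.update(seen)
    categories = list(keywords) + ["other"]
    return {
        cat: {
            "count": counts.get(cat, 0),
            "fraction": counts.get(cat, 0) / n_clusters if n_clusters else 0.0,
        }
        for cat in categories
    }
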