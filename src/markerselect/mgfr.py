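"""Replicate-block marker detection (the MGFR algorithm).

For each gene, the expression profile is sorted decreasingly across samples.
If the top block — as many positions as the top sample type has replicates —
is occupied entirely by that type with every value at or above an expression
cutoff (default 1 on the matrix scale), the gene is a candidate marker for
that type.  A second block is then grown from the next position until every
sample type it touches has all of its replicates inside, and the specificity
score is the ratio of the second block's mean to the top block's mean:
0 means perfectly type-exclusive expression, values near 1 mean no contrast.

Conventions the algorithm needs but the informal description leaves open:

* ties in the decreasing sort are broken by original sample index
  (ascending), making every output deterministic;
* a candidate whose top block ties exactly with the next value of a
  different type passes on position and is flagged (``boundary_tie``);
* genes that are all zero, or constant across every sample, are skipped
  before sorting — a profile without contrast cannot mark anything.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix, ExpressionMatrixError, SampleAnnotation


class ProfileEntry(NamedTuple):
    value: float
    sample_type: str
    sample_index: int


#: A gene's expression profile sorted decreasingly; a permutation of one row.
SortedProfile = list[ProfileEntry]


@dataclass
class MarkerCall:
    """One candidate marker: gene, target type, score and cut-point positions.

    ``cut1``/``cut2`` are 1-based counts of samples before each cut-point;
    they are ``None`` for detectors that do not define cut-points.
    ``boundary_tie`` marks calls whose candidacy was decided by the
    positional tie rule at the first cut-point.
    """

    gene_id: str
    sample_type: str
    score: float
    cut1: Optional[int] = None
    cut2: Optional[int] = None
    boundary_tie: bool = False


@dataclass
class DetectorResult:
    """Per-sample-type ranked marker lists with a declared score polarity.

    ``polarity`` is ``"low_is_specific"`` (MGFR: rank ascending) or
    ``"high_is_specific"`` (SPM, z-score: rank descending).  A gene appears
    under at most one type for MGFR; threshold-based detectors may list a
    gene under several types.
    """

    detector: str
    polarity: str
    markers: dict[str, list[MarkerCall]]

    def __post_init__(self) -> None:
        if self.polarity not in ("low_is_specific", "high_is_specific"):
            raise ValueError(f"unknown polarity {self.polarity!r}")

    def marker_sets(self) -> dict[str, set[str]]:
        return {t: {c.gene_id for c in calls} for t, calls in self.markers.items()}

    def marker_union(self) -> list[str]:
        """All marker genes, deduplicated, in type-then-rank order."""
        out: list[str] = []
        seen: set[str] = set()
        for calls in self.markers.values():
            for c in calls:
                if c.gene_id not in seen:
                    seen.add(c.gene_id)
                    out.append(c.gene_id)
        return out

    def ranking(self, sample_type: str) -> tuple[list[str], np.ndarray]:
        """Genes and scores for one type, already ordered most→least specific."""
        calls = self.markers[sample_type]
        return [c.gene_id for c in calls], np.array([c.score for c in calls])

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "gene_id": c.gene_id,
                "sample_type": t,
                "score": c.score,
                "cut1": c.cut1 if c.cut1 is not None else "",
                "cut2": c.cut2 if c.cut2 is not None else "",
                "detector": self.detector,
            }
            for t in self.markers
            for c in self.markers[t]
        ]
        return pd.DataFrame(
            rows, columns=["gene_id", "sample_type", "score", "cut1", "cut2", "detector"]
        )

    def write_table(self, path: str | Path) -> None:
        """Tab-separated marker table, grouped by type, scores to 6 decimals."""
        df = self.to_frame()
        df["score"] = df["score"].map(lambda x: f"{x:.6f}")
        df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Per-step operations
# ---------------------------------------------------------------------------

def sort_profile(
    values: Sequence[float], annotation: SampleAnnotation
) -> SortedProfile:
    """Stable decreasing sort of one gene's profile; ties keep index order."""
    labels = list(annotation.mapping.values())
    if len(values) != len(labels):
        raise ExpressionMatrixError(
            f"profile length {len(values)} does not match annotation "
            f"({len(labels)} samples)"
        )
    entries = [
        ProfileEntry(float(v), labels[i], i) for i, v in enumerate(values)
    ]
    return sorted(entries, key=lambda e: (-e.value, e.sample_index))


def cut_point_one(
    p: SortedProfile, ann: SampleAnnotation, cutoff: float = 1.0
) -> tuple[bool, str, int]:
    """First cut-point: is the top replicate block pure and above the cutoff?

    Returns ``(is_candidate, target_type, cut1)`` where ``target_type`` is the
    type of the highest value and ``cut1`` its replicate count.
    """
    target = p[0].sample_type
    r = ann.replicate_counts[target]
    block = p[:r]
    ok = all(e.sample_type == target for e in block) and all(
        e.value >= cutoff for e in block
    )
    return ok, target, r


def cut_point_two(p: SortedProfile, cut1: int, ann: SampleAnnotation) -> int:
    """Second cut-point: grow a window past ``cut1`` until every sample type it
    contains has all of its replicates inside; returns the window end (1-based
    count of samples before the cut, capped at ``s``)."""
    s = len(p)
    if cut1 >= s:
        raise ExpressionMatrixError("no samples beyond the first cut-point")
    last_pos: dict[str, int] = {}
    for i, e in enumerate(p):
        last_pos[e.sample_type] = i
    first = p[cut1].sample_type
    end = min(cut1 + ann.replicate_counts[first], s)
    changed = True
    while changed:
        changed = False
        for e in p[cut1:end]:
            need = last_pos[e.sample_type] + 1
            if need > end:
                end = need
                changed = True
    return end


def specificity_score(p: SortedProfile, cut1: int, cut2: int) -> float:
    """Mean of the second block divided by mean of the top block, in [0, 1]."""
    if not (0 < cut1 < cut2 <= len(p)):
        raise ExpressionMatrixError(f"invalid cut-points {cut1}, {cut2}")
    top = float(np.mean([e.value for e in p[:cut1]]))
    second = float(np.mean([e.value for e in p[cut1:cut2]]))
    if top <= 0:
        raise ExpressionMatrixError("zero mean before the first cut-point")
    return second / top


def evaluate_gene(
    values: Sequence[float], ann: SampleAnnotation, cutoff: float = 1.0
) -> Optional[MarkerCall]:
    """Run the full per-gene procedure; ``None`` if the gene is not a candidate."""
    vmax = max(values)
    if vmax <= 0 or vmax == min(values):  # all-zero or constant: no contrast
        return None
    p = sort_profile(values, ann)
    ok, target, cut1 = cut_point_one(p, ann, cutoff)
    if not ok:
        return None
    cut2 = cut_point_two(p, cut1, ann)
    score = specificity_score(p, cut1, cut2)
    tie = p[cut1 - 1].value == p[cut1].value
    return MarkerCall("", target, score, cut1, cut2, boundary_tie=tie)


# ---------------------------------------------------------------------------
# Full detector
# ---------------------------------------------------------------------------

def detect_markers(
    m: ExpressionMatrix, ann: SampleAnnotation, cutoff: float = 1.0
) -> DetectorResult:
    """Detect candidate markers for every sample type in the matrix.

    Each gene is assigned to at most one type (that of its highest value);
    per-type lists are sorted ascending by score (most specific first), with
    gene order as tie-break.
    """
    labels = ann.labels_for(m.sample_ids)
    if len(set(labels)) < 2:
        raise ExpressionMatrixError(
            "marker detection needs at least two sample types"
        )
    # re-key the annotation to the matrix's sample order
    ordered = SampleAnnotation.from_labels(m.sample_ids, labels)
    per_type: dict[str, list[MarkerCall]] = {t: [] for t in ordered.types}
    for i, gene in enumerate(m.gene_ids):
        call = evaluate_gene(m.values[i], ordered, cutoff)
        if call is not None:
            call.gene_id = gene
            per_type[call.sample_type].append(call)
    for t in per_type:
        per_type[t].sort(key=lambda c: c.score)
    return DetectorResult("mgfr", "low_is_specific", per_type)


def read_marker_table(path: str | Path) -> DetectorResult:
    """Read back a marker table written by :meth:`DetectorResult.write_table`."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "sample_type": str})
    detector = str(df["detector"].iloc[0]) if len(df) else "mgfr"
    polarity = "low_is_specific" if detector == "mgfr" else "high_is_specific"
    markers: dict[str, list[MarkerCall]] = {}
    for _, row in df.iterrows():
        cut1 = int(row["cut1"]) if pd.notna(row["cut1"]) and row["cut1"] != "" else None
        cut2 = int(row["cut2"]) if pd.notna(row["cut2"]) and row["cut2"] != "" else None
        markers.setdefault(row["sample_type"], []).append(
            MarkerCall(row["gene_id"], row["sample_type"], float(row["score"]), cut1, cut2)
        )
    return DetectorResult(detector, polarity, markers)
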