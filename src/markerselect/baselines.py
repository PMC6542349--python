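"""Comparison marker detectors: SPM, z-score and a random baseline.

Both score-based baselines work on per-type mean profiles (length ``t``),
putting every detector on the same per-type ranking footing.  SPM is the
cosine between the profile and the one-hot vector of a type, so scores lie
in [0, 1] and the published 0.4 selection threshold applies; the z-score is
the standardized deviation of a type's mean from the gene's profile mean
(sample standard deviation, ``ddof=1``), selected at the published
threshold of 1.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix, ExpressionMatrixError, SampleAnnotation
from .mgfr import DetectorResult, MarkerCall

SPM_CUTOFF = 0.4
ZSCORE_CUTOFF = 1.0


def type_mean_profiles(
    m: ExpressionMatrix, ann: SampleAnnotation
) -> pd.DataFrame:
    """Genes x types matrix of replicate means."""
    labels = np.array(ann.labels_for(m.sample_ids))
    cols = {t: m.values[:, labels == t].mean(axis=1) for t in ann.types}
    return pd.DataFrame(cols, index=m.gene_ids)


def spm_scores(profile: Sequence[float]) -> np.ndarray:
    """Cosine of the profile with each type's one-hot vector: x_i / ||x||."""
    x = np.asarray(profile, dtype=float)
    norm = np.linalg.norm(x)
    if norm == 0:
        warnings.warn("all-zero profile: SPM scores set to 0", UserWarning)
        return np.zeros_like(x)
    return x / norm


def zscore_scores(profile: Sequence[float], ddof: int = 1) -> np.ndarray:
    """Standardized per-type deviation (x_i - mean) / sd, sd with n-1 by default."""
    x = np.asarray(profile, dtype=float)
    if x.size < 2:
        raise ExpressionMatrixError("z-scores need at least two sample types")
    sd = x.std(ddof=ddof)
    if sd == 0:
        warnings.warn("constant profile: z-scores set to 0", UserWarning)
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def threshold_select(
    scores: Mapping[str, Mapping[str, float]], polarity: str, cutoff: float
) -> dict[str, set[str]]:
    """Per-type marker sets from per-type gene scores at an inclusive cutoff."""
    if polarity not in ("high_is_specific", "low_is_specific"):
        raise ExpressionMatrixError(f"unknown polarity {polarity!r}")
    out: dict[str, set[str]] = {}
    for t, gene_scores in scores.items():
        if polarity == "high_is_specific":
            out[t] = {g for g, v in gene_scores.items() if v >= cutoff}
        else:
            out[t] = {g for g, v in gene_scores.items() if v <= cutoff}
    return out


def random_markers(
    gene_universe: Sequence[str],
    sizes_per_type: Mapping[str, int],
    seed: int | np.random.Generator | None = None,
) -> dict[str, set[str]]:
    """Uniform draws without replacement per type, independent across types."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    universe = list(gene_universe)
    out: dict[str, set[str]] = {}
    for t in sizes_per_type:
        k = sizes_per_type[t]
        if k > len(universe):
            raise ExpressionMatrixError(
                f"requested {k} random markers for {t!r} from a universe of "
                f"{len(universe)} genes"
            )
        idx = rng.choice(len(universe), size=k, replace=False)
        out[t] = {universe[i] for i in idx}
    return out


# ---------------------------------------------------------------------------
# Full-detector wrappers returning DetectorResult
# ---------------------------------------------------------------------------

def _score_matrix_detect(
    m: ExpressionMatrix,
    ann: SampleAnnotation,
    score_fn,
    cutoff: float,
    name: str,
) -> DetectorResult:
    profiles = type_mean_profiles(m, ann)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        score_rows = np.vstack([score_fn(row) for row in profiles.to_numpy()])
    markers: dict[str, list[MarkerCall]] = {}
    for j, t in enumerate(profiles.columns):
        col = score_rows[:, j]
        keep = np.nonzero(col >= cutoff)[0]
        calls = [MarkerCall(m.gene_ids[i], t, float(col[i])) for i in keep]
        calls.sort(key=lambda c: -c.score)  # most specific (highest) first
        markers[t] = calls
    return DetectorResult(name, "high_is_specific", markers)


def spm_detect(
    m: ExpressionMatrix, ann: SampleAnnotation, cutoff: float = SPM_CUTOFF
) -> DetectorResult:
    """SPM detector at the published SPM >= 0.4 threshold."""
    return _score_matrix_detect(m, ann, spm_scores, cutoff, "spm")


def zscore_detect(
    m: ExpressionMatrix, ann: SampleAnnotation, cutoff: float = ZSCORE_CUTOFF,
    ddof: int = 1,
) -> DetectorResult:
    """z-score detector at the published z >= 1 threshold."""
    return _score_matrix_detect(
        m, ann, lambda x: zscore_scores(x, ddof=ddof), cutoff, "zscore"
    )


def random_detect(
    m: ExpressionMatrix,
    ann: SampleAnnotation,
    sizes_per_type: Mapping[str, int],
    seed: int | np.random.Generator | None = None,
) -> DetectorResult:
    """Random baseline matching the per-type set sizes of a detector under test.

    Scores are all zero and carry no ranking information.
    """
    sets = random_markers(m.gene_ids, sizes_per_type, seed)
    markers = {
        t: [MarkerCall(g, t, 0.0) for g in sorted(genes)] for t, genes in sets.items()
    }
    return DetectorResult("random", "high_is_specific", markers)
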