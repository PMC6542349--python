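"""scikit-learn style marker selectors.

Marker detection is feature selection: ``fit(X, y)`` takes a samples x genes
matrix with sample-type labels and learns per-type marker lists; ``transform``
restricts a matrix to the union of detected markers, so the selectors compose
with :class:`~sklearn.pipeline.Pipeline` and model selection.

Fitted attributes
-----------------
markers_ : dict[str, list[MarkerCall]]
    Per-type marker calls, ranked most specific first.
classes_ : ndarray
    Sample-type labels in first-appearance order.
polarity_ : str
    ``"low_is_specific"`` (MGFR) or ``"high_is_specific"`` (SPM, z-score).
support_ : ndarray of bool, shape (n_features,)
    Mask over genes in the union of the per-type marker lists.
"""

from __future__ import annotations

from typing import Mapping, Optional

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted, column_or_1d, validate_data

from .baselines import (
    SPM_CUTOFF,
    ZSCORE_CUTOFF,
    random_detect,
    spm_detect,
    zscore_detect,
)
from .matrix import ExpressionMatrix, SampleAnnotation
from .mgfr import DetectorResult, detect_markers


class _BaseMarkerSelector(SelectorMixin, BaseEstimator):
    """Shared fit/transform plumbing; subclasses implement ``_detect``."""

    def fit(self, X, y):
        X = validate_data(self, X, dtype=np.float64, ensure_min_samples=2)
        y = column_or_1d(np.asarray(y, dtype=object))
        if y.shape[0] != X.shape[0]:
            raise ValueError("X and y have inconsistent numbers of samples")
        if np.any(X < 0):
            raise ValueError(
                "negative values in X; expression matrices must be non-negative"
            )
        gene_ids = [str(g) for g in getattr(self, "feature_names_in_", [])] or [
            f"g{i}" for i in range(X.shape[1])
        ]
        sample_ids = [f"s{i}" for i in range(X.shape[0])]
        m = ExpressionMatrix(X.T, gene_ids, sample_ids)
        ann = SampleAnnotation.from_labels(sample_ids, [str(v) for v in y])
        result = self._detect(m, ann)
        self.result_ = result
        self.markers_ = result.markers
        self.polarity_ = result.polarity
        self.classes_ = np.asarray(ann.types, dtype=object)
        union = set(result.marker_union())
        self.support_ = np.array([g in union for g in gene_ids])
        self.gene_ids_ = gene_ids
        return self

    def _detect(self, m: ExpressionMatrix, ann: SampleAnnotation) -> DetectorResult:
        raise NotImplementedError

    def _get_support_mask(self):
        check_is_fitted(self)
        return self.support_

    def marker_sets(self) -> dict[str, set[str]]:
        check_is_fitted(self)
        return self.result_.marker_sets()


class MGFRSelector(_BaseMarkerSelector):
    """Replicate-block marker selector (MGFR).

    Parameters
    ----------
    cutoff : float, default=1.0
        Minimum expression (on the matrix scale) required of every value in
        the top replicate block for a gene to be a candidate marker.
    """

    def __init__(self, cutoff: float = 1.0):
        self.cutoff = cutoff

    def _detect(self, m, ann):
        return detect_markers(m, ann, cutoff=self.cutoff)


class SPMSelector(_BaseMarkerSelector):
    """Specificity-measure (cosine) selector at the published SPM >= 0.4 cutoff."""

    def __init__(self, cutoff: float = SPM_CUTOFF):
        self.cutoff = cutoff

    def _detect(self, m, ann):
        return spm_detect(m, ann, cutoff=self.cutoff)


class ZScoreSelector(_BaseMarkerSelector):
    """z-score selector at the published z >= 1 cutoff (sd with ``ddof``)."""

    def __init__(self, cutoff: float = ZSCORE_CUTOFF, ddof: int = 1):
        self.cutoff = cutoff
        self.ddof = ddof

    def _detect(self, m, ann):
        return zscore_detect(m, ann, cutoff=self.cutoff, ddof=self.ddof)


class RandomSelector(_BaseMarkerSelector):
    """Random baseline: per-type uniform draws without replacement.

    Parameters
    ----------
    n_markers : int or mapping type -> int, default=10
        Per-type set sizes; pass another detector's set sizes to match it.
    random_state : int, Generator or None
        Seed for the draws.
    """

    def __init__(
        self,
        n_markers: int | Mapping[str, int] = 10,
        random_state: Optional[int] = None,
    ):
        self.n_markers = n_markers
        self.random_state = random_state

    def _detect(self, m, ann):
        if isinstance(self.n_markers, Mapping):
            sizes = dict(self.n_markers)
        else:
            sizes = {t: int(self.n_markers) for t in ann.types}
        return random_detect(m, ann, sizes, seed=self.random_state)
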