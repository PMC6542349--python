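"""Benchmark protocols for marker detectors.

Two complementary evaluations:

1. *Clustering quality*: restrict the matrix to the union of a detector's
   markers, embed the samples with PCA (first two components, features
   centered), cluster with k-means (random centroid initialization, repeated
   ``runs`` times) and score each partition against the known sample types
   with NMI, purity and the adjusted Rand index.
2. *Gold-standard agreement*: rank each type's markers from most to least
   specific, sweep the score as a cutoff against a curated marker list to
   build precision-recall and ROC curves (AUPRC / AUROC), and test whether
   the detected set overlaps the gold standard more than random same-size
   sets via a permutation z-test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import (
    adjusted_rand_score,
    normalized_mutual_info_score,
    roc_auc_score,
)

from .matrix import ExpressionMatrix, ExpressionMatrixError, SampleAnnotation
from .mgfr import DetectorResult

#: type label -> set of curated marker gene ids
GoldStandard = dict[str, set[str]]


def read_gold_standard(path: str | Path) -> GoldStandard:
    """Read a two-column TSV ``sample_type<TAB>gene_id`` gold-standard file."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["sample_type", "gene_id"]:
        raise ExpressionMatrixError(
            "gold-standard table must have columns 'sample_type' and 'gene_id'"
        )
    gold: GoldStandard = {}
    for t, g in zip(df["sample_type"], df["gene_id"]):
        gold.setdefault(t, set()).add(g)
    return gold


def write_gold_standard(gold: GoldStandard, path: str | Path) -> None:
    rows = [(t, g) for t in gold for g in sorted(gold[t])]
    pd.DataFrame(rows, columns=["sample_type", "gene_id"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# Clustering benchmark
# ---------------------------------------------------------------------------

@dataclass
class ClusteringQuality:
    """Mean and sd of NMI / purity / ARI over repeated k-means runs."""

    nmi: float
    purity: float
    ari: float
    nmi_sd: float
    purity_sd: float
    ari_sd: float
    n_runs: int


def pca_embed(m: ExpressionMatrix, scale: bool = False) -> np.ndarray:
    """First two principal-component coordinates of the samples.

    Samples are observations and genes are features; features are centered
    (optionally unit-scaled).  The sign of each component is fixed by making
    its largest-magnitude gene loading positive, so embeddings are
    reproducible across runs and row orders.
    """
    if m.n < 2:
        raise ExpressionMatrixError("PCA needs at least two genes")
    if m.s < 3:
        raise ExpressionMatrixError("PCA needs at least three samples")
    X = m.values.T.astype(float)  # samples x genes
    if scale:
        sd = X.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        X = (X - X.mean(axis=0)) / sd
    pca = PCA(n_components=2, svd_solver="full")
    coords = pca.fit_transform(X)
    for j in range(coords.shape[1]):
        loadings = pca.components_[j]
        if loadings[np.argmax(np.abs(loadings))] < 0:
            coords[:, j] = -coords[:, j]
    return coords


def nmi(a: Sequence, b: Sequence, average_method: str = "arithmetic") -> float:
    """Normalized mutual information between two partitions.

    Normalization by the arithmetic mean of the entropies by default;
    ``geometric`` / ``min`` / ``max`` variants are available.
    """
    if len(a) != len(b):
        raise ExpressionMatrixError("partitions differ in length")
    return float(normalized_mutual_info_score(a, b, average_method=average_method))


def purity(pred: Sequence, truth: Sequence) -> float:
    """Fraction of samples in the majority truth class of their cluster.

    Not symmetric in its arguments; one cluster per sample trivially scores 1.
    """
    if len(pred) != len(truth):
        raise ExpressionMatrixError("partitions differ in length")
    ct = pd.crosstab(pd.Series(pred), pd.Series(truth))
    return float(ct.max(axis=1).sum() / len(pred))


def adjusted_rand_index(a: Sequence, b: Sequence) -> float:
    """Permutation-model-adjusted Rand index."""
    if len(a) != len(b):
        raise ExpressionMatrixError("partitions differ in length")
    return float(adjusted_rand_score(a, b))


def kmeans_quality(
    coords: np.ndarray,
    true_labels: Sequence,
    k: int,
    runs: int = 100,
    seed: int = 0,
    average_method: str = "arithmetic",
) -> ClusteringQuality:
    """Average clustering quality over repeated randomly-initialized k-means.

    Each run is a single k-means++ initialization followed by Lloyd
    iterations (tol 1e-6, max 300 iterations) with its own RNG substream
    derived from the master seed; NMI / purity / ARI of every partition
    against ``true_labels`` are averaged (sd with ``ddof=1``).  k-means++
    rather than uniform random-point seeding: with coincident replicate
    coordinates (e.g. noise-free data) uniform seeding can place two
    centroids on the same point and converge with a merged cluster.
    """
    coords = np.asarray(coords, dtype=float)
    if k > coords.shape[0]:
        raise ExpressionMatrixError("k cannot exceed the number of samples")
    if runs < 1:
        raise ExpressionMatrixError("runs must be >= 1")
    substreams = np.random.SeedSequence(seed).generate_state(runs)
    truth = list(true_labels)
    nmis, purs, aris = [], [], []
    for r in range(runs):
        km = KMeans(
            n_clusters=k,
            init="k-means++",
            n_init=1,
            max_iter=300,
            tol=1e-6,
            random_state=int(substreams[r]),
        )
        part = km.fit_predict(coords)
        nmis.append(nmi(part, truth, average_method))
        purs.append(purity(part, truth))
        aris.append(adjusted_rand_index(part, truth))
    sd = (lambda x: float(np.std(x, ddof=1))) if runs > 1 else (lambda x: 0.0)
    return ClusteringQuality(
        nmi=float(np.mean(nmis)), purity=float(np.mean(purs)),
        ari=float(np.mean(aris)), nmi_sd=sd(nmis), purity_sd=sd(purs),
        ari_sd=sd(aris), n_runs=runs,
    )


# ---------------------------------------------------------------------------
# Gold-standard benchmark
# ---------------------------------------------------------------------------

def _ranking_scores(
    genes: Sequence[str], scores: Sequence[float], polarity: str
) -> np.ndarray:
    """Map scores so that larger always means more specific."""
    s = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(s)):
        raise ExpressionMatrixError("non-finite marker scores")
    if polarity == "low_is_specific":
        return -s
    if polarity == "high_is_specific":
        return s
    raise ExpressionMatrixError(f"unknown polarity {polarity!r}")


def pr_curve_and_auprc(
    genes: Sequence[str],
    scores: Sequence[float],
    polarity: str,
    gold: set[str],
    universe: Optional[Sequence[str]] = None,
) -> tuple[pd.DataFrame, float]:
    """Precision-recall curve and non-interpolated AUPRC for one ranking.

    The score is swept from most to least specific; tied scores enter
    together.  Recall is counted against the gold genes present in
    ``universe`` when given (genes a detector never listed then cap recall
    below 1), otherwise against the gold genes in the ranking itself.
    AUPRC is the step summation  sum_k (R_k - R_{k-1}) P_k.
    """
    genes = list(genes)
    if universe is not None:
        uni = set(universe)
        outside = [g for g in genes if g not in uni]
        if outside:
            raise ExpressionMatrixError(
                f"ranked genes outside the universe: {outside[:5]}"
            )
        total_pos = len(gold & uni)
    else:
        total_pos = sum(1 for g in genes if g in gold)
    if total_pos == 0:
        raise ExpressionMatrixError("no gold-standard genes to recall")
    spec = _ranking_scores(genes, scores, polarity)
    order = np.argsort(-spec, kind="stable")
    rel = np.array([genes[i] in gold for i in order])
    sorted_spec = spec[order]
    tp = np.cumsum(rel)
    n_seen = np.arange(1, len(genes) + 1)
    # indices where a tie group ends (last occurrence of each distinct score)
    ends = np.nonzero(np.append(np.diff(sorted_spec) != 0, True))[0]
    precision = tp[ends] / n_seen[ends]
    recall = tp[ends] / total_pos
    auprc = float(np.sum(np.diff(np.concatenate(([0.0], recall))) * precision))
    curve = pd.DataFrame(
        {"threshold": sorted_spec[ends], "precision": precision, "recall": recall}
    )
    return curve, auprc


def roc_auroc(
    genes: Sequence[str],
    scores: Sequence[float],
    polarity: str,
    gold: set[str],
    universe: Optional[Sequence[str]] = None,
) -> tuple[pd.DataFrame, float]:
    """ROC curve and AUROC for one ranking.

    AUROC equals the Mann-Whitney probability that a random gold gene
    outranks a random non-gold gene, with ties contributing 1/2.  With a
    ``universe``, unlisted genes enter tied at the least-specific end.
    """
    genes = list(genes)
    spec = _ranking_scores(genes, scores, polarity)
    if universe is not None:
        uni = list(dict.fromkeys(universe))
        listed = dict(zip(genes, spec))
        floor = (spec.min() if len(spec) else 0.0) - 1.0
        genes = uni
        spec = np.array([listed.get(g, floor) for g in uni])
    y = np.array([g in gold for g in genes], dtype=int)
    if y.sum() == 0 or y.sum() == len(y):
        raise ExpressionMatrixError(
            "ROC needs both gold and non-gold genes in the ranking"
        )
    if np.all(spec == spec[0]):  # degenerate all-tied ranking
        auroc = 0.5
        curve = pd.DataFrame({"fpr": [0.0, 1.0], "tpr": [0.0, 1.0]})
        return curve, auroc
    auroc = float(roc_auc_score(y, spec))
    from sklearn.metrics import roc_curve as _roc_curve

    fpr, tpr, _ = _roc_curve(y, spec)
    return pd.DataFrame({"fpr": fpr, "tpr": tpr}), auroc


@dataclass
class OverlapTest:
    """Observed overlap with a gold set vs. random same-size draws."""

    observed: int
    random_mean: float
    random_sd: float
    z: float
    p: float


def overlap_ztest(
    predicted: set[str],
    gold: set[str],
    universe: Sequence[str],
    n_random: int = 1000,
    seed: int = 0,
) -> OverlapTest:
    """One-sided (enrichment) z-test of gold overlap against random sets.

    Draws ``n_random`` uniform subsets of ``len(predicted)`` genes from the
    universe, compares the observed intersection size with the random
    distribution via z = (obs - mean) / sd and reports the upper-tail normal
    p-value.
    """
    universe = sorted(set(universe))
    if not predicted <= set(universe):
        raise ExpressionMatrixError("predicted set must be a subset of the universe")
    gold_in = gold & set(universe)
    if not gold_in:
        raise ExpressionMatrixError("gold set does not intersect the universe")
    rng = np.random.default_rng(seed)
    k = len(predicted)
    gold_mask = np.array([g in gold_in for g in universe])
    overlaps = np.empty(n_random, dtype=int)
    for i in range(n_random):
        idx = rng.choice(len(universe), size=k, replace=False)
        overlaps[i] = int(gold_mask[idx].sum())
    observed = len(predicted & gold_in)
    mean = float(overlaps.mean())
    sd = float(overlaps.std(ddof=1))
    if sd == 0:
        warnings.warn("degenerate random-overlap distribution (sd = 0)", UserWarning)
        p = 0.0 if observed > mean else 1.0
        z = np.inf if observed > mean else 0.0
    else:
        z = (observed - mean) / sd
        p = float(norm.sf(z))
    return OverlapTest(observed, mean, sd, float(z), p)


# ---------------------------------------------------------------------------
# Report assembly
# ---------------------------------------------------------------------------

def evaluate_detector(
    m: ExpressionMatrix,
    ann: SampleAnnotation,
    result: DetectorResult,
    gold: Optional[GoldStandard] = None,
    k: Optional[int] = None,
    runs: int = 100,
    n_random: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Full per-detector evaluation: clustering quality plus gold-standard rows.

    Returns a tidy table with one ``clustering`` row (NMI/purity/ARI mean and
    sd over ``runs`` k-means restarts on the marker-restricted PCA embedding)
    and, when ``gold`` is given, one row per evaluable type with AUPRC,
    AUROC and the overlap z-test (universe = all genes in the matrix).
    """
    labels = ann.labels_for(m.sample_ids)
    k = k if k is not None else len(set(labels))
    rows: list[dict] = []
    union = result.marker_union()
    if len(union) >= 2:
        sub = m.subset_genes(union)
        quality = kmeans_quality(pca_embed(sub), labels, k, runs=runs, seed=seed)
        rows.append(
            {
                "detector": result.detector, "section": "clustering",
                "sample_type": "", "n_markers": len(union),
                "nmi_mean": quality.nmi, "nmi_sd": quality.nmi_sd,
                "purity_mean": quality.purity, "purity_sd": quality.purity_sd,
                "ari_mean": quality.ari, "ari_sd": quality.ari_sd,
            }
        )
    if gold is not None:
        unknown = [t for t in gold if t not in ann.types]
        if unknown:
            raise ExpressionMatrixError(
                f"gold standard references unknown sample types: {unknown}"
            )
        for t, gold_set in gold.items():
            calls = result.markers.get(t, [])
            if not calls or not (gold_set & set(m.gene_ids)):
                continue
            genes, scores = result.ranking(t)
            row: dict = {
                "detector": result.detector, "section": "gold",
                "sample_type": t, "n_markers": len(genes),
            }
            try:
                _, row["auprc"] = pr_curve_and_auprc(
                    genes, scores, result.polarity, gold_set, universe=m.gene_ids
                )
            except ExpressionMatrixError:
                row["auprc"] = np.nan
            try:
                _, row["auroc"] = roc_auroc(
                    genes, scores, result.polarity, gold_set, universe=m.gene_ids
                )
            except ExpressionMatrixError:
                row["auroc"] = np.nan
            ot = overlap_ztest(
                set(genes), gold_set, m.gene_ids, n_random=n_random, seed=seed
            )
            row["overlap"] = ot.observed
            row["overlap_p"] = ot.p
            rows.append(row)
    return pd.DataFrame(rows)


def write_report(report: pd.DataFrame, path: str | Path) -> None:
    report.to_csv(path, sep="\t", index=False)
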