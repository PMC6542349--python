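"""Synthetic expression matrices with planted type-specific markers.

The generator emulates the structure of small grouped RNA-seq / scRNA-seq
studies: ``t`` sample types with a handful of replicates each, a minority of
genes strongly expressed in exactly one type (the planted markers), and a
background of non-specific (housekeeping-like) and silent genes.  Values
live on the log2(x + 1) working scale: each marker / housekeeping gene draws
a per-gene base level from a normal on that scale (log-normal in raw units),
per-cell Gaussian noise of a configurable sd is added, optional Bernoulli
dropout zeroes cells, and everything is clipped at 0.
"""

from __future__ import annotations

import warnings
from dataclasses import asdict, dataclass, field

import numpy as np

from .evaluation import GoldStandard
from .matrix import ExpressionMatrix, ExpressionMatrixError, SampleAnnotation


@dataclass
class SimulationParams:
    """Generator knobs (all on the log2 working scale) with study-like defaults:
    5 types x 3 replicates, 10 planted markers per type over a background of
    500 genes (half housekeeping-like, half silent)."""

    n_types: int = 5
    n_replicates: int = 3
    markers_per_type: int = 10
    n_background: int = 500
    marker_mean: float = 8.0
    marker_level_sd: float = 1.0
    marker_low_mean: float = 0.0
    background_mean: float = 4.0
    background_level_sd: float = 1.0
    background_silent_frac: float = 0.5
    noise_sd: float = 1.0
    dropout_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_types < 2:
            raise ExpressionMatrixError("need at least two sample types")
        if self.n_replicates < 2:
            raise ExpressionMatrixError("need at least two replicates per type")
        if self.markers_per_type < 0 or self.n_background < 0:
            raise ExpressionMatrixError("gene counts must be non-negative")
        if not 0 <= self.background_silent_frac <= 1:
            raise ExpressionMatrixError("background_silent_frac must be in [0, 1]")
        if not 0 <= self.dropout_rate < 1:
            raise ExpressionMatrixError("dropout_rate must be in [0, 1)")
        if self.noise_sd < 0 or self.marker_level_sd < 0:
            raise ExpressionMatrixError("standard deviations must be non-negative")


@dataclass
class SimulationTruth:
    """Planted marker sets per type plus the parameters that generated them."""

    params: SimulationParams
    markers: dict[str, set[str]] = field(default_factory=dict)

    def to_manifest(self) -> dict:
        return {
            "params": asdict(self.params),
            "markers": {t: sorted(g) for t, g in self.markers.items()},
        }


def simulate_expression(
    params: SimulationParams | None = None, **overrides
) -> tuple[ExpressionMatrix, SampleAnnotation, SimulationTruth]:
    """Generate (matrix, annotation, truth), fully determined by ``params.seed``.

    Marker genes are high (per-gene log-normal level around ``marker_mean``)
    in their own type and at ``marker_low_mean`` elsewhere; housekeeping
    genes share one level across all samples; silent genes are zero.
    """
    if params is None:
        params = SimulationParams(**overrides)
    elif overrides:
        params = SimulationParams(**{**asdict(params), **overrides})
    params.validate()
    rng = np.random.default_rng(params.seed)

    types = [f"T{i + 1}" for i in range(params.n_types)]
    sample_ids = [f"{t}_r{j + 1}" for t in types for j in range(params.n_replicates)]
    labels = [t for t in types for _ in range(params.n_replicates)]
    s = len(sample_ids)

    n_silent = int(round(params.n_background * params.background_silent_frac))
    n_house = params.n_background - n_silent

    gene_ids: list[str] = []
    blocks: list[np.ndarray] = []
    truth_sets: dict[str, set[str]] = {t: set() for t in types}

    for ti, t in enumerate(types):
        levels = rng.normal(
            params.marker_mean, params.marker_level_sd, params.markers_per_type
        )
        for gi in range(params.markers_per_type):
            gene = f"M_{t}_{gi + 1:03d}"
            gene_ids.append(gene)
            truth_sets[t].add(gene)
            row = np.full(s, params.marker_low_mean, dtype=float)
            own = slice(ti * params.n_replicates, (ti + 1) * params.n_replicates)
            row[own] = max(levels[gi], 0.0)
            blocks.append(row)

    house_levels = rng.normal(params.background_mean, params.background_level_sd, n_house)
    for gi in range(n_house):
        gene_ids.append(f"H_{gi + 1:04d}")
        blocks.append(np.full(s, max(house_levels[gi], 0.0), dtype=float))
    for gi in range(n_silent):
        gene_ids.append(f"Z_{gi + 1:04d}")
        blocks.append(np.zeros(s, dtype=float))

    values = np.vstack(blocks) if blocks else np.zeros((0, s))
    if params.noise_sd > 0:
        values = values + rng.normal(0.0, params.noise_sd, values.shape)
    if params.dropout_rate > 0:
        values[rng.random(values.shape) < params.dropout_rate] = 0.0
    values = np.clip(values, 0.0, None)

    m = ExpressionMatrix(values, gene_ids, sample_ids)
    ann = SampleAnnotation.from_labels(sample_ids, labels)
    truth = SimulationTruth(params=params, markers=truth_sets)
    return m, ann, truth


def make_gold_standard(truth: SimulationTruth) -> GoldStandard:
    """Planted sets in the gold-standard format; empty types are dropped."""
    gold: GoldStandard = {}
    for t, genes in truth.markers.items():
        if not genes:
            warnings.warn(f"no planted markers for type {t!r}; omitted", UserWarning)
            continue
        gold[t] = set(genes)
    return gold
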