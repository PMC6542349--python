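import warnings

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import markerselect as ms

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def annotation(labels, sample_ids=None):
    """SampleAnnotation for positional labels, silencing singleton warnings."""
    if sample_ids is None:
        sample_ids = [f"s{i + 1}" for i in range(len(labels))]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        return ms.SampleAnnotation.from_labels(sample_ids, labels)


@pytest.fixture
def toy_annotation():
    """Six samples, types A (3 replicates), B (2) and a singleton C."""
    return annotation(["A", "A", "A", "B", "B", "C"])


@pytest.fixture
def toy_matrix(toy_annotation):
    """Three genes: a clean A-marker, a step-3 failure, and all zeros."""
    values = np.array(
        [
            [10.0, 9.0, 8.0, 4.0, 3.0, 2.0],  # g1: marker of A
            [10.0, 9.0, 0.5, 8.0, 3.0, 2.0],  # g2: third A value under cutoff
            [0.0, 0.0, 0.0, 0.0, 0.0, 0.0],  # g3: silent
        ]
    )
    m = ms.ExpressionMatrix(values, ["g1", "g2", "g3"], list(toy_annotation.mapping))
    return m


@pytest.fixture
def zero_noise_sim():
    """The separable study construction: planted markers, no noise or dropout."""
    return ms.simulate_expression(noise_sd=0.0, dropout_rate=0.0, seed=11)


def random_grouped_matrix(rng, n_genes, reps=(2, 2, 2), zero_frac=0.3, scale=5.0):
    """Random non-negative matrix plus annotation for the given replicate layout."""
    labels = [f"T{i + 1}" for i, r in enumerate(reps) for _ in range(r)]
    s = len(labels)
    values = rng.exponential(scale, size=(n_genes, s))
    values[rng.random((n_genes, s)) < zero_frac] = 0.0
    sample_ids = [f"s{i}" for i in range(s)]
    m = ms.ExpressionMatrix(values, [f"g{i}" for i in range(n_genes)], sample_ids)
    return m, annotation(labels, sample_ids)
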