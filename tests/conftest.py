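import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cndiff.core import CountMatrix, GenomicInterval, Peak

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


def build_matrix(counts, n_test, n_control, chrom="chr1", width=500, spacing=2000):
    """CountMatrix around a counts array with test columns first."""
    counts = np.asarray(counts, dtype=float)
    n = counts.shape[0]
    assert counts.shape[1] == n_test + n_control
    peaks = [
        Peak(GenomicInterval(chrom, i * spacing, i * spacing + width), name=f"p{i:04d}")
        for i in range(n)
    ]
    samples = [f"test_{j + 1}" for j in range(n_test)] + [
        f"control_{j + 1}" for j in range(n_control)
    ]
    condition = {s: ("test" if s.startswith("test") else "control") for s in samples}
    return CountMatrix(peaks=peaks, samples=samples, condition=condition, counts=counts)


@pytest.fixture
def matrix_factory():
    return build_matrix


def nb_counts(rng, mean, dispersion, size):
    """Direct NB2 draws for oracle simulations."""
    if dispersion < 1e-8:
        return rng.poisson(mean, size=size).astype(float)
    r = 1.0 / dispersion
    return rng.negative_binomial(r, r / (r + mean), size=size).astype(float)
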