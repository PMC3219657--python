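import numpy as np
import pytest

from skewatlas import properties, synth_fixtures
from skewatlas.genome_io import GenomicFeature, SequenceRecord


@pytest.fixture
def small_record():
    return SequenceRecord(id="seq1", name="test sequence", residues="GGGGGCCCCC")


@pytest.fixture
def skewed_genome():
    """100 kb circular genome, oriC at 60 kb, terminus at 10 kb."""
    spec = synth_fixtures.SkewGenomeSpec(
        length=100_000, oric_pos=60_000, ter_pos=10_000,
        skew_strength=0.3, noise_sd=0.05, seed=7,
    )
    return spec, synth_fixtures.make_skewed_genome(spec)


@pytest.fixture
def noisy_skew_track(skewed_genome):
    """1 kb tiled GC skew of the skewed genome (noisy square wave)."""
    _, record = skewed_genome
    return properties.sliding_property(record, 1000, fn=properties.gc_skew, name="gc_skew")


@pytest.fixture
def two_cds_features():
    return [
        GenomicFeature(seq_id="seq1", start=100, end=400, strand="+", label="geneA",
                       category="CDS"),
        GenomicFeature(seq_id="seq1", start=600, end=900, strand="-", label="geneB",
                       category="CDS"),
    ]


def brute_force_acf(x: np.ndarray) -> np.ndarray:
    """O(N^2) biased sample autocorrelation, lags 0..N-1."""
    x = np.asarray(x, dtype=float)
    n = x.size
    d = x - x.mean()
    denom = float(d @ d)
    return np.array(
        [sum(d[t] * d[t + k] for t in range(n - k)) for k in range(n)]
    ) / denom


def brute_force_ccf(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """O(N^2) biased sample cross-correlation, lags -(N-1)..(N-1)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    ax, ay = x - x.mean(), y - y.mean()
    sx = np.sqrt(float(ax @ ax) / n)
    sy = np.sqrt(float(ay @ ay) / n)
    out = []
    for k in range(-(n - 1), n):
        s = 0.0
        for t in range(n):
            if 0 <= t + k < n:
                s += ax[t + k] * ay[t]
        out.append(s / (n * sx * sy))
    return np.array(out)


def circular_distance(a: int, b: int, length: int) -> int:
    d = abs(a - b)
    return min(d, length - d)
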