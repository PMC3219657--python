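"""Dyadic condensation, MODWT denoising, and lagged-correlation analysis.

A windowed genomic property is condensed into a vector of length 2^m and
treated as a one-dimensional signal.  The maximal-overlap discrete
wavelet transform (MODWT) splits it into per-level detail coefficients
(high-frequency content) plus a level-J smooth (the global identity);
zeroing all details and inverting the transform yields a denoised
version.  Autocorrelation exposes rhythmic structure; cross-correlation
aligns two properties irrespective of where each chromosome's first
base was defined.  Significance of a correlation coefficient is judged
against the large-sample bound CI = Z_p / sqrt(N).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy import stats as _scipy_stats

from .properties import PropertyTrack, cumulate

# MODWT filters are the unit-energy DWT filters rescaled by 1/sqrt(2).
# haar/d4/la8 scaling filters come from PyWavelets; the 4-tap
# Fejer-Korovkin scaling filter is embedded directly (it is not shipped
# with every PyWavelets build).
_FK4_SCALING = (
    0.6539275555697651,
    0.7532724928394872,
    0.05317922877905981,
    -0.04616571481521770,
)

_FILTER_ALIASES = {"haar": "haar", "d4": "db2", "la8": "sym8"}
SUPPORTED_FILTERS = ("haar", "d4", "la8", "fk4")


def _modwt_filters(filter_name: str) -> tuple[np.ndarray, np.ndarray]:
    """Return (g~, h~): MODWT scaling and wavelet filters."""
    if filter_name not in SUPPORTED_FILTERS:
        raise ValueError(
            f"unsupported wavelet filter {filter_name!r}; supported: {', '.join(SUPPORTED_FILTERS)}"
        )
    if filter_name == "fk4":
        g = np.asarray(_FK4_SCALING, dtype=float)
    else:
        g = np.asarray(pywt.Wavelet(_FILTER_ALIASES[filter_name]).rec_lo, dtype=float)
    # quadrature mirror: h_l = (-1)^l g_{L-1-l}
    L = len(g)
    h = np.array([(-1.0) ** l * g[L - 1 - l] for l in range(L)])
    return g / math.sqrt(2.0), h / math.sqrt(2.0)


@dataclass
class CondensedVector:
    """A property resampled to dyadic length N = 2^m for signal analysis."""

    values: np.ndarray
    m: int
    bin_width: float
    source: str = ""
    seq_length: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.size
        if n < 2 or n & (n - 1):
            raise ValueError(f"condensed vector length {n} is not a power of two >= 2")

    @property
    def n(self) -> int:
        return self.values.size


@dataclass
class WaveletResult:
    """Per-level MODWT coefficients plus the smooth-only reconstruction."""

    filter_name: str
    J: int
    details: list[np.ndarray]
    smooth: np.ndarray
    denoised: np.ndarray

    @property
    def panels(self) -> list[tuple[str, np.ndarray]]:
        """Plot panels in display order: per-level details then denoised."""
        out = [(f"level-{j} coefficients", w) for j, w in enumerate(self.details, start=1)]
        out.append(("denoised", self.denoised))
        return out


@dataclass
class CorrelationSeries:
    """Lagged correlation coefficients with a significance bound."""

    kind: str
    lags: np.ndarray
    coefficients: np.ndarray
    N: int
    confidence_level: float
    ci: float
    bin_width: float = 1.0

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=int)
        self.coefficients = np.asarray(self.coefficients, dtype=float)


@dataclass
class CorrelationPeak:
    lag_bins: int
    lag_bp: float
    coefficient: float
    significant: bool


def resample_weighted(
    starts: np.ndarray, window: int, values: np.ndarray, seq_length: float, n_bins: int
) -> np.ndarray:
    """Overlap-weighted mean of source windows onto ``n_bins`` equal bins.

    Bin j covers [j*w, (j+1)*w) bp (0-based, w = seq_length/n_bins); its
    value is the mean of all source-window values weighted by bp overlap.
    Bins with no overlapping window inherit the nearest preceding value.
    """
    starts = np.asarray(starts, dtype=float)
    values = np.asarray(values, dtype=float)
    width = seq_length / n_bins
    acc = np.zeros(n_bins)
    wsum = np.zeros(n_bins)
    for s, v in zip(starts, values):
        lo = s - 1.0  # 0-based bp
        hi = min(lo + window, seq_length)
        j0 = int(lo // width)
        j1 = min(int(math.ceil(hi / width)), n_bins)
        for j in range(j0, j1):
            overlap = min(hi, (j + 1) * width) - max(lo, j * width)
            if overlap > 0:
                acc[j] += v * overlap
                wsum[j] += overlap
    out = np.empty(n_bins)
    last = values[0] if values.size else 0.0
    for j in range(n_bins):
        if wsum[j] > 0:
            last = acc[j] / wsum[j]
        out[j] = last
    return out


def condense(track: PropertyTrack, m: int) -> CondensedVector:
    """Resample a windowed property into a vector of length 2^m.

    Downsampling averages source windows overlapping each bin
    (bp-overlap weighted); upsampling replicates values proportionally
    (piecewise-constant).
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    if len(track) == 0:
        raise ValueError("cannot condense an empty track")
    n = 2**m
    seq_length = track.coverage_length
    vals = resample_weighted(
        np.asarray(track.starts), track.window_size,
        np.asarray(track.values), float(seq_length), n,
    )
    return CondensedVector(
        values=vals, m=m, bin_width=seq_length / n,
        source=track.name, seq_length=seq_length,
    )


def _vector(x) -> np.ndarray:
    if isinstance(x, CondensedVector):
        return x.values
    return np.asarray(x, dtype=float)


def modwt(x, filter_name: str = "haar", J: int = 4) -> WaveletResult:
    """Maximal-overlap DWT via the pyramid algorithm, periodic boundary.

    Each level yields N coefficients; energy is conserved
    (||x||^2 == sum_j ||W_j||^2 + ||V_J||^2) and the transform inverts
    exactly.  With the Haar filter the level-1 detail is
    W_{1,t} = (x_t - x_{t-1 mod N}) / 2.
    """
    data = _vector(x)
    N = data.size
    if J < 1:
        raise ValueError("decomposition level J must be >= 1")
    if 2**J > N:
        raise ValueError(f"J={J} exceeds log2(N)={int(math.log2(N))}")
    g, h = _modwt_filters(filter_name)
    details: list[np.ndarray] = []
    v = data.copy()
    for j in range(1, J + 1):
        stride = 2 ** (j - 1)
        w_j = np.zeros(N)
        v_j = np.zeros(N)
        for l, (gl, hl) in enumerate(zip(g, h)):
            shifted = np.roll(v, stride * l)
            w_j += hl * shifted
            v_j += gl * shifted
        details.append(w_j)
        v = v_j
    smooth = v
    denoised = _inverse_pyramid(
        [np.zeros(N) for _ in details], smooth, g, h
    )
    return WaveletResult(
        filter_name=filter_name, J=J, details=details, smooth=smooth, denoised=denoised
    )


def _inverse_pyramid(
    details: list[np.ndarray], smooth: np.ndarray, g: np.ndarray, h: np.ndarray
) -> np.ndarray:
    v = smooth.copy()
    for j in range(len(details), 0, -1):
        stride = 2 ** (j - 1)
        w_j = details[j - 1]
        v_prev = np.zeros_like(v)
        for l, (gl, hl) in enumerate(zip(g, h)):
            v_prev += hl * np.roll(w_j, -stride * l) + gl * np.roll(v, -stride * l)
        v = v_prev
    return v


def imodwt(result: WaveletResult) -> np.ndarray:
    """Invert a MODWT (perfect reconstruction of the analysed vector)."""
    g, h = _modwt_filters(result.filter_name)
    return _inverse_pyramid(result.details, result.smooth, g, h)


def denoise(x, filter_name: str = "haar", J: int = 4) -> np.ndarray:
    """Smooth-only reconstruction: invert the MODWT with all details zeroed."""
    return modwt(x, filter_name=filter_name, J=J).denoised


def confidence_interval(N: int, p: float = 0.999) -> float:
    """Large-sample significance bound Z_p / sqrt(N) for correlation series.

    Z_p is the two-sided standard-normal critical value: the area
    between -Z_p and Z_p equals p (1.96 / 2.58 / 3.29 for p = 0.95 /
    0.99 / 0.999).
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    if not 0.0 < p < 1.0:
        raise ValueError(f"confidence level must be in (0, 1), got {p}")
    z = _scipy_stats.norm.ppf((1.0 + p) / 2.0)
    return float(z / math.sqrt(N))


def autocorrelation(x, p: float = 0.999) -> CorrelationSeries:
    """Sample ACF at lags 0..N-1, biased (divide-by-N) convention.

    r(k) = sum_{t=1}^{N-k} (x_t - xbar)(x_{t+k} - xbar) / sum (x_t - xbar)^2.
    """
    data = _vector(x)
    N = data.size
    if N < 2:
        raise ValueError("autocorrelation requires N >= 2")
    d = data - data.mean()
    denom = float(d @ d)
    if denom == 0.0:
        raise ValueError("autocorrelation undefined for a zero-variance input")
    full = np.correlate(d, d, mode="full")
    r = full[N - 1 :] / denom
    return CorrelationSeries(
        kind="auto", lags=np.arange(N), coefficients=r, N=N,
        confidence_level=p, ci=confidence_interval(N, p),
        bin_width=x.bin_width if isinstance(x, CondensedVector) else 1.0,
    )


def cross_correlation(x, y, p: float = 0.999) -> CorrelationSeries:
    """Sample CCF at lags -(N-1)..(N-1), biased convention.

    r_xy(k) = (1/N) sum_t (x_{t+k} - xbar)(y_t - ybar) / (s_x s_y) with
    biased standard deviations, so ccf(x, y)(k) == ccf(y, x)(-k) and
    ccf(x, x)(0) == 1.
    """
    dx = _vector(x)
    dy = _vector(y)
    if dx.size != dy.size:
        raise ValueError(f"vector sizes differ: {dx.size} vs {dy.size}")
    N = dx.size
    if N < 2:
        raise ValueError("cross-correlation requires N >= 2")
    ax = dx - dx.mean()
    ay = dy - dy.mean()
    sx = math.sqrt(float(ax @ ax) / N)
    sy = math.sqrt(float(ay @ ay) / N)
    if sx == 0.0 or sy == 0.0:
        raise ValueError("cross-correlation undefined for a zero-variance input")
    # np.correlate(ax, ay, 'full')[N-1+k] == sum_t ax[t+k] * ay[t]
    full = np.correlate(ax, ay, mode="full")
    r = full / (N * sx * sy)
    return CorrelationSeries(
        kind="cross", lags=np.arange(-(N - 1), N), coefficients=r, N=N,
        confidence_level=p, ci=confidence_interval(N, p),
        bin_width=x.bin_width if isinstance(x, CondensedVector) else 1.0,
    )


def find_peak(series: CorrelationSeries, min_lag_bins: int = 1) -> CorrelationPeak:
    """Strongest local extremum of |r| at |lag| >= min_lag_bins.

    A local extremum has strictly greater |r| than both neighbours; ties
    go to the smallest |lag|.  Lag 0 is excluded for autocorrelation
    (r(0) = 1 is structural).  If no local extremum exists in range, the
    global max-|r| lag in range is returned flagged not-significant.
    """
    lags = series.lags
    mags = np.abs(series.coefficients)
    if lags.size == 0:
        raise ValueError("empty correlation series")
    in_range = np.abs(lags) >= max(min_lag_bins, 1 if series.kind == "auto" else 0)
    if series.kind == "auto":
        in_range &= lags != 0
    if not in_range.any():
        raise ValueError("no lags satisfy the minimum-lag constraint")
    is_local = np.zeros_like(in_range)
    interior = np.arange(1, lags.size - 1)
    local = interior[
        (mags[interior] > mags[interior - 1]) & (mags[interior] > mags[interior + 1])
    ]
    is_local[local] = True
    candidates = np.flatnonzero(is_local & in_range)
    significant_peak = candidates.size > 0
    if not significant_peak:
        candidates = np.flatnonzero(in_range)
    order = sorted(candidates, key=lambda i: (-mags[i], abs(int(lags[i])), int(lags[i])))
    best = order[0]
    coeff = float(series.coefficients[best])
    return CorrelationPeak(
        lag_bins=int(lags[best]),
        lag_bp=float(lags[best]) * series.bin_width,
        coefficient=coeff,
        significant=significant_peak and abs(coeff) > series.ci,
    )


def max_correlation(x, y, p: float = 0.999) -> float:
    """Signed CCF coefficient of largest magnitude over all lags."""
    series = cross_correlation(x, y, p=p)
    i = int(np.abs(series.coefficients).argmax())
    return float(series.coefficients[i])


def similarity_summary(x, y, filter_name: str = "haar", J: int = 4, p: float = 0.999) -> float:
    """Scale-by-scale similarity of two condensed properties, in [0, 1].

    Averages the maximum |CCF| between the level-j detail coefficients
    of the two inputs (j = 1..J) with the maximum |CCF| between their
    denoised versions: (J + 1) magnitudes in total.
    """
    wx = modwt(x, filter_name=filter_name, J=J)
    wy = modwt(y, filter_name=filter_name, J=J)
    maxima = [
        abs(max_correlation(wx.details[j], wy.details[j], p=p)) for j in range(J)
    ]
    maxima.append(abs(max_correlation(wx.denoised, wy.denoised, p=p)))
    return float(np.mean(maxima))


def haar_reverse_cumulative_similarity(raw: CondensedVector | np.ndarray, J: int = 1) -> float:
    """Haar-specific diagnostic: details of the cumulative track the smooth of the raw.

    With the Haar filter, the level-J detail coefficients of a cumulated
    signal approximate a smoothed version of the raw (non-cumulative)
    signal.  Returns the Pearson correlation between (a) the level-J
    Haar details of cumsum(raw) and (b) the level-J denoised raw.
    """
    values = _vector(raw)
    if np.ptp(values) == 0.0:
        raise ValueError("similarity undefined for a constant input (zero variance)")
    cum = np.cumsum(values)
    details_cum = modwt(cum, filter_name="haar", J=J).details[J - 1]
    denoised_raw = denoise(values, filter_name="haar", J=J)
    r = np.corrcoef(details_cum, denoised_raw)[0, 1]
    return float(r)


def pairwise_cross_correlations(
    vectors: dict[str, CondensedVector], p: float = 0.999
) -> dict[tuple[str, str], CorrelationSeries]:
    """CCF for each unordered pair of named vectors: k(k-1)/2 results."""
    out: dict[tuple[str, str], CorrelationSeries] = {}
    for (na, va), (nb, vb) in itertools.combinations(vectors.items(), 2):
        out[(na, nb)] = cross_correlation(va, vb, p=p)
    return out


def cumulate_condensed(x: CondensedVector) -> CondensedVector:
    """Running sum of a condensed vector (same binning)."""
    return CondensedVector(
        values=np.cumsum(x.values), m=x.m, bin_width=x.bin_width,
        source=f"{x.source} cumulative", seq_length=x.seq_length,
    )


# re-export for callers that build analysis pipelines from this module
__all__ = [
    "CondensedVector", "WaveletResult", "CorrelationSeries", "CorrelationPeak",
    "SUPPORTED_FILTERS", "condense", "resample_weighted", "modwt", "imodwt",
    "denoise", "autocorrelation", "cross_correlation", "confidence_interval",
    "find_peak", "max_correlation", "similarity_summary",
    "haar_reverse_cumulative_similarity", "pairwise_cross_correlations",
    "cumulate_condensed", "cumulate",
]
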