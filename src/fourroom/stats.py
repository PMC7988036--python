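"""Custom statistics and single-unit quality metrics.

Implements the chi-square test of expected proportions, the sequential
Holm-Bonferroni correction (with the convention that rejected p values are
reported as 0.99 and surviving ones left unadjusted), and the tetrode
cluster-quality measures (isolation distance and L-ratio) computed from
squared Mahalanobis distances of non-cluster spikes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float


def chi2_expected_proportions(observed, expected) -> ChiSquareResult:
    """Chi-square goodness of fit: X^2 = sum (O_i - E_i)^2 / E_i, df = N-1."""
    obs = np.asarray(observed, dtype=float)
    exp = np.asarray(expected, dtype=float)
    if obs.shape != exp.shape or obs.ndim != 1:
        raise ValueError("observed and expected must be 1-D arrays of equal length")
    if obs.size < 2:
        raise ValueError("need at least 2 categories")
    if np.any(exp <= 0):
        raise ValueError("expected counts must be positive")
    x2 = float(np.sum((obs - exp) ** 2 / exp))
    df = obs.size - 1
    p = float(sps.chi2.sf(x2, df))
    return ChiSquareResult(x2, df, p)


def holm_bonferroni(p_values, alpha: float = 0.05) -> np.ndarray:
    """Sequential Holm correction with cutoff alpha / (n - rank + 1).

    p values are ranked ascending; the first one exceeding its cutoff and
    every later one are set to 0.99, earlier ones are returned unadjusted.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    order = np.argsort(p, kind="stable")
    out = p.astype(float).copy()
    n = p.size
    failed = False
    for rank, idx in enumerate(order, start=1):
        cutoff = alpha / (n - rank + 1)
        if failed or p[idx] > cutoff:
            failed = True
            out[idx] = 0.99
    return out


def _mahalanobis_sq(cluster: np.ndarray, other: np.ndarray) -> np.ndarray:
    """Squared Mahalanobis distance of each row of ``other`` to the cluster
    mean under the cluster covariance."""
    mu = cluster.mean(axis=0)
    cov = np.cov(cluster, rowvar=False)
    cov = np.atleast_2d(cov)
    try:
        cov_inv = np.linalg.inv(cov)
    except np.linalg.LinAlgError as e:
        raise ValueError(
            "singular cluster covariance; consider regularizing features "
            "(e.g. add small diagonal jitter) or dropping collinear channels"
        ) from e
    d = other - mu
    return np.einsum("ij,jk,ik->i", d, cov_inv, d)


@dataclass(frozen=True)
class ClusterQualityResult:
    isolation_distance: float | None  # None when undefined (too few non-C spikes)
    L: float
    L_ratio: float
    n_cluster: int
    n_other: int


def isolation_distance(cluster_features, noncluster_features) -> float | None:
    """Squared Mahalanobis distance of the n_C-th closest non-cluster spike.

    Undefined (returns None) when there are fewer non-cluster spikes than
    cluster spikes.
    """
    c = np.asarray(cluster_features, dtype=float)
    o = np.asarray(noncluster_features, dtype=float)
    if c.ndim != 2 or o.ndim != 2 or c.shape[1] != o.shape[1]:
        raise ValueError("feature matrices must be 2-D with equal dimension")
    n_c = c.shape[0]
    if o.shape[0] < n_c:
        return None
    d2 = np.sort(_mahalanobis_sq(c, o))
    return float(d2[n_c - 1])


def l_ratio(cluster_features, noncluster_features, df: int | None = None) -> tuple[float, float]:
    """L = sum over non-cluster spikes of 1 - CDF_chi2(df)(D^2); L_ratio = L/n_C.

    ``df`` defaults to the feature dimension (8 for the canonical two
    features x four channels tetrode space).
    """
    c = np.asarray(cluster_features, dtype=float)
    o = np.asarray(noncluster_features, dtype=float)
    if c.ndim != 2 or o.ndim != 2 or c.shape[1] != o.shape[1]:
        raise ValueError("feature matrices must be 2-D with equal dimension")
    if df is None:
        df = c.shape[1]
    if o.shape[0] == 0:
        return 0.0, 0.0
    d2 = _mahalanobis_sq(c, o)
    L = float(np.sum(sps.chi2.sf(d2, df)))
    return L, L / c.shape[0]


def cluster_quality(cluster_features, noncluster_features, df: int | None = None) -> ClusterQualityResult:
    c = np.asarray(cluster_features, dtype=float)
    o = np.asarray(noncluster_features, dtype=float)
    iso = isolation_distance(c, o)
    L, lr = l_ratio(c, o, df=df)
    return ClusterQualityResult(iso, L, lr, c.shape[0], o.shape[0])


def width_of_waveform(waveforms, sampling_rate_hz: float) -> float:
    """Peak-to-trough time in microseconds, on the highest-amplitude channel.

    ``waveforms`` is (n_channels, n_samples) of mean spike waveforms; the
    width is the absolute time between the maximum and minimum sample of the
    channel whose peak absolute amplitude is greatest.
    """
    w = np.atleast_2d(np.asarray(waveforms, dtype=float))
    if w.shape[1] < 2:
        raise ValueError("waveform needs at least 2 samples")
    amps = np.max(np.abs(w), axis=1)
    ch = int(np.argmax(amps))
    trace = w[ch]
    if np.allclose(trace, trace[0]):
        raise ValueError("flat waveform: width undefined")
    i_max = int(np.argmax(trace))
    i_min = int(np.argmin(trace))
    return abs(i_max - i_min) / sampling_rate_hz * 1e6


def percentage(count: int, total: int, decimals: int = 1) -> float:
    """Proportion as a percentage rounded the way results tables print it."""
    if total <= 0:
        raise ValueError("total must be positive")
    return round(100.0 * count / total, decimals)
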