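"""Normalized squared error (NSE) statistics and spatial correlation decay.

The NSE between paired response vectors x and y is

    NSE = mu((x - y)^2) / (mu(x^2) + mu(y^2) - 2 mu(x) mu(y))

It is 0 for identical responses, 1 for statistically independent responses,
and at most 2 for zero-mean perfectly anticorrelated responses.  Expanding
the numerator, the NSE depends on the power terms mu(x^2), mu(y^2), the
means, and the cross-product mu(x o y).  Means and cross-products are
unbiased by zero-mean measurement noise, but power is biased upward by the
noise power.  Given two independent measurements x1, x2 of the same
condition, the residual power mu((x1 - x2)^2) equals twice the noise power
in expectation, so

    mu_hat(x^2) = 1/2 mu(x1^2) + 1/2 mu(x2^2) - 1/2 mu((x1 - x2)^2)

is an unbiased power estimate, and substituting corrected powers into the
NSE gives a statistic whose noise floor is zero.  Voxels are only trusted
when their test-retest NSE (between the two measurement splits) is below
0.4.

The module also provides the noise-corrected signal variance
(var(r1 + r2) - var(r1 - r2)) / 4 and the spatial correlation profile with
its 75%-decay distance tau75, defined by f(tau75) = 0.25 f(0) after
subtracting the minimum correlation across distances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datasets import ResponseMatrix, VoxelGeometry

__all__ = [
    "nse",
    "noise_corrected_power",
    "noise_corrected_nse",
    "noise_corrected_variance",
    "test_retest_nse",
    "nse_map",
    "NSEResult",
    "SpatialCorrelationProfile",
    "spatial_correlation_profile",
    "tau75",
    "RELIABILITY_GATE",
]

RELIABILITY_GATE = 0.4


def _mu(a: np.ndarray) -> np.ndarray:
    return np.mean(a, axis=-1)


def _rows(*arrays):
    out = [np.atleast_2d(np.asarray(a, dtype=float)) for a in arrays]
    n = {a.shape for a in out}
    if len(n) > 1:
        raise ValueError(f"shape mismatch: {sorted(n)}")
    return out


def nse(x, y):
    """Normalized squared error between paired vectors (vectorized over rows).

    Scalar for 1-D inputs; per-row values for 2-D inputs.  A zero denominator
    (both vectors constant with equal means) is undefined and returned NaN.
    """
    x2, y2 = _rows(x, y)
    if x2.shape[-1] < 2:
        raise ValueError("vectors must have length >= 2")
    num = _mu((x2 - y2) ** 2)
    den = _mu(x2 ** 2) + _mu(y2 ** 2) - 2 * _mu(x2) * _mu(y2)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(den != 0, num / np.where(den != 0, den, 1.0), np.nan)
    return out if np.asarray(x).ndim > 1 else float(out[0])


def noise_corrected_power(x1, x2):
    """Unbiased response power from two independent measurements:
    1/2 mu(x1^2) + 1/2 mu(x2^2) - 1/2 mu((x1-x2)^2).  May be negative by
    sampling noise; retained as-is."""
    a, b = _rows(x1, x2)
    out = 0.5 * _mu(a ** 2) + 0.5 * _mu(b ** 2) - 0.5 * _mu((a - b) ** 2)
    return out if np.asarray(x1).ndim > 1 else float(out[0])


def _corrected_terms(x1, x2, y1, y2, noise_from="both"):
    x1, x2, y1, y2 = _rows(x1, x2, y1, y2)
    if noise_from == "both":
        px = noise_corrected_power(x1, x2)
        py = noise_corrected_power(y1, y2)
    elif noise_from == "x":
        # only the x condition is repeated: estimate the noise power from its
        # residual and subtract it from both conditions
        npow = 0.5 * _mu((x1 - x2) ** 2)
        px = 0.5 * _mu(x1 ** 2) + 0.5 * _mu(x2 ** 2) - npow
        py = 0.5 * _mu(y1 ** 2) + 0.5 * _mu(y2 ** 2) - npow
    else:
        raise ValueError("noise_from must be 'both' or 'x'")
    mx = 0.5 * (_mu(x1) + _mu(x2))
    my = 0.5 * (_mu(y1) + _mu(y2))
    # cross-product averaged over the four split pairings: each term is an
    # unbiased estimate because the splits' noises are independent
    cross = 0.25 * (_mu(x1 * y1) + _mu(x1 * y2) + _mu(x2 * y1) + _mu(x2 * y2))
    return px, py, mx, my, cross


def noise_corrected_nse(x1, x2, y1, y2, noise_from="both"):
    """Noise-corrected NSE from two independent splits of each condition.

    Expected value 0 when x and y share the same underlying signal,
    regardless of measurement noise; 1 for independent signals.  Negative
    values can occur by sampling noise and are reported as-is.
    """
    px, py, mx, my, cross = _corrected_terms(x1, x2, y1, y2, noise_from)
    num = px + py - 2 * cross
    den = px + py - 2 * mx * my
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(den != 0, num / np.where(den != 0, den, 1.0), np.nan)
    return out if np.asarray(x1).ndim > 1 else float(out[0])


def noise_corrected_variance(r1, r2):
    """Unbiased shared-signal variance: (var(r1+r2) - var(r1-r2)) / 4.

    With r_i = s + n_i and independent zero-mean noises, the numerator is
    var(2s + n1 + n2) - var(n1 - n2) = 4 var(s)."""
    a, b = _rows(r1, r2)
    out = (np.var(a + b, axis=-1) - np.var(a - b, axis=-1)) / 4.0
    return out if np.asarray(r1).ndim > 1 else float(out[0])


def test_retest_nse(split1, split2):
    """Per-voxel NSE between two measurement splits of the same responses."""
    return nse(split1, split2)


@dataclass
class NSEResult:
    """Per-voxel NSE map with its reliability gate."""

    raw_nse: np.ndarray
    corrected_nse: np.ndarray
    test_retest_nse: np.ndarray
    valid_mask: np.ndarray     # reliable voxels: test-retest NSE < gate and
                               # positive corrected denominator
    gate: float = RELIABILITY_GATE


def nse_map(x1, x2, y1, y2, gate: float = RELIABILITY_GATE,
            noise_from: str = "both") -> NSEResult:
    """Raw and noise-corrected NSE per voxel between conditions x and y,
    each measured in two independent splits (rows = voxels).

    Voxels whose test-retest NSE (pooled across both conditions) exceeds
    ``gate``, or whose corrected denominator is not positive, are excluded
    from ``valid_mask`` but their values are still reported.
    """
    x1, x2, y1, y2 = _rows(x1, x2, y1, y2)
    raw = nse(0.5 * (x1 + x2), 0.5 * (y1 + y2))
    corrected = noise_corrected_nse(x1, x2, y1, y2, noise_from=noise_from)
    tr = nse(np.concatenate([x1, y1], axis=-1), np.concatenate([x2, y2], axis=-1))
    px, py, mx, my, _ = _corrected_terms(x1, x2, y1, y2, noise_from)
    den = px + py - 2 * mx * my
    valid = np.isfinite(corrected) & (tr < gate) & (den > 0)
    return NSEResult(raw_nse=np.atleast_1d(raw),
                     corrected_nse=np.atleast_1d(corrected),
                     test_retest_nse=np.atleast_1d(tr),
                     valid_mask=np.atleast_1d(valid), gate=gate)


# ---------------------------------------------------------------------------
# spatial correlation profile and tau75
# ---------------------------------------------------------------------------

@dataclass
class SpatialCorrelationProfile:
    distance_bins: np.ndarray    # bin centers, mm (first bin is 0 mm)
    mean_correlation: np.ndarray
    bin_size: float
    n_pairs: np.ndarray


def _zscore_rows(a: np.ndarray) -> np.ndarray:
    a = a - a.mean(axis=1, keepdims=True)
    sd = a.std(axis=1, keepdims=True)
    return a / np.where(sd > 0, sd, np.nan)


def spatial_correlation_profile(split_a: ResponseMatrix, split_b: ResponseMatrix,
                                geometry: VoxelGeometry, bin_size: float = 0.5,
                                voxel_mask=None) -> SpatialCorrelationProfile:
    """Mean between-voxel response correlation as a function of distance.

    For every voxel pair (i, j) the correlation across sounds between voxel
    i in split A and voxel j in split B is computed (and symmetrized); pairs
    are binned by Euclidean distance.  Because splits come from independent
    repetitions, the 0 mm bin (i = j) measures test-retest reliability
    rather than trivially equaling 1.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be > 0")
    mask = np.ones(geometry.n_voxels, bool) if voxel_mask is None else np.asarray(voxel_mask, bool)
    A = _zscore_rows(split_a.values[mask])
    B = _zscore_rows(split_b.values[mask])
    n_sounds = A.shape[1]
    C = (A @ B.T) / n_sounds
    C = 0.5 * (C + C.T)
    dist = geometry.pairwise_distances(mask)
    finite = np.isfinite(C)
    # 0 mm bin = diagonal; others binned at [k-0.5, k+0.5) * bin_size
    bins = np.round(dist / bin_size).astype(int)
    n_bins = bins.max() + 1
    centers, means, counts = [], [], []
    for k in range(n_bins):
        sel = (bins == k) & finite
        if not sel.any():
            continue
        centers.append(k * bin_size)
        means.append(C[sel].mean())
        counts.append(int(sel.sum()))
    return SpatialCorrelationProfile(distance_bins=np.asarray(centers),
                                     mean_correlation=np.asarray(means),
                                     bin_size=bin_size,
                                     n_pairs=np.asarray(counts))


def tau75(profile: SpatialCorrelationProfile) -> float:
    """Distance at which the correlation decays by 75%.

    The minimum correlation across distances is subtracted first (to remove
    any global shared-response floor); the first crossing of 25% of the 0 mm
    value is found by linear interpolation.  NaN if the profile never
    crosses.
    """
    f = profile.mean_correlation - profile.mean_correlation.min()
    d = profile.distance_bins
    if f[0] <= 0:
        return float("nan")
    target = 0.25 * f[0]
    below = np.flatnonzero(f <= target)
    below = below[below > 0]
    if below.size == 0:
        return float("nan")
    j = below[0]
    i = j - 1
    # linear interpolation between the bracketing bins
    frac = (f[i] - target) / (f[i] - f[j])
    return float(d[i] + frac * (d[j] - d[i]))
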