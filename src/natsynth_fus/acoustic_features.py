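"""Cochlear and modulation energy descriptors of sounds.

A cochleagram is computed with a bank of 4th-order gammatone filters on a
log-spaced frequency axis (envelope via the analytic signal, power-law
compression with exponent 0.3).  Modulation energy is measured by filtering
the cochleagram with log-Gaussian transfer functions in its 2D Fourier
domain: nine temporal-rate filters (0.5-128 Hz, octave spaced), six
spectral-scale filters (0.25-8 cycles/octave), and their 54 joint
rate-scale products.  Modulation strength of a filtered cochleagram is the
standard deviation across time of each frequency channel, averaged across
channels; cochlear energy is the time-averaged cochleagram.

Component-feature attribution uses the maximum correlation across feature
columns with a permutation null (shuffling the sound axis), two-sided.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "TEMPORAL_RATES_HZ",
    "SPECTRAL_SCALES_CPO",
    "Cochleagram",
    "cochleagram",
    "FeatureTable",
    "modulation_energy",
    "feature_table",
    "feature_correlation_test",
]

TEMPORAL_RATES_HZ = (0.5, 1.0, 2.0, 4.0, 8.0, 16.0, 32.0, 64.0, 128.0)
SPECTRAL_SCALES_CPO = (0.25, 0.5, 1.0, 2.0, 4.0, 8.0)


@dataclass
class Cochleagram:
    values: np.ndarray        # (time, channels), compressed envelopes
    env_sr: float             # envelope sample rate, Hz
    center_freqs: np.ndarray  # channel centers, Hz

    @property
    def octaves_per_channel(self) -> float:
        f = self.center_freqs
        return float(np.log2(f[-1] / f[0]) / (f.size - 1))


def cochleagram(wave: np.ndarray, sr: float, n_channels: int = 40,
                fmin: float = 100.0, fmax: float | None = None,
                compression: float = 0.3, env_sr: float = 400.0,
                rms_normalize: bool = True) -> Cochleagram:
    """Gammatone filterbank cochleagram with compressed envelopes.

    ``rms_normalize`` scales the waveform to unit RMS first, making the
    features insensitive to overall presentation level.
    """
    wave = np.asarray(wave, dtype=float)
    if wave.ndim != 1:
        raise ValueError("mono audio required")
    if not np.all(np.isfinite(wave)):
        raise ValueError("audio contains NaN/Inf")
    fmax = fmax or min(20000.0, 0.4 * sr)
    if sr < 2 * fmax:
        raise ValueError("sample rate too low for requested top channel")
    rms = np.sqrt(np.mean(wave ** 2))
    if rms_normalize and rms > 0:
        wave = wave / rms
    freqs = np.geomspace(fmin, fmax, n_channels)
    down = max(int(round(sr / env_sr)), 1)
    env_sr_eff = sr / down
    rows = []
    for fc in freqs:
        b, a = signal.gammatone(fc, "iir", fs=sr)
        band = signal.lfilter(b, a, wave)
        env = np.abs(signal.hilbert(band))
        env = signal.resample_poly(env, 1, down)
        rows.append(np.maximum(env, 0.0) ** compression)
    values = np.stack(rows, axis=1)
    return Cochleagram(values=values, env_sr=env_sr_eff, center_freqs=freqs)


@dataclass
class FeatureTable:
    """Per-sound acoustic descriptors (all energies >= 0 by construction of
    the underlying statistics except centered correlations downstream)."""

    cochlear: pd.DataFrame          # sounds x channels (Hz-labelled)
    temporal: pd.DataFrame          # sounds x 9 rates
    spectral: pd.DataFrame          # sounds x 6 scales
    spectrotemporal: pd.DataFrame   # sounds x 54 rate-scale pairs

    def groups(self):
        return {"cochlear": self.cochlear, "temporal": self.temporal,
                "spectral": self.spectral,
                "spectrotemporal": self.spectrotemporal}


def _log_gaussian(freq_axis: np.ndarray, center: float, sigma_oct: float = 0.5):
    """Log-Gaussian transfer magnitude over a (possibly signed) frequency
    axis; zero at DC."""
    H = np.zeros_like(freq_axis)
    nz = freq_axis != 0
    H[nz] = np.exp(-0.5 * (np.log2(np.abs(freq_axis[nz]) / center) / sigma_oct) ** 2)
    return H


def _filter_2d(cgram: Cochleagram, rate: float | None, scale: float | None) -> np.ndarray:
    C = cgram.values
    T, F = C.shape
    ft = np.fft.fftfreq(T, d=1.0 / cgram.env_sr)            # Hz
    fs = np.fft.fftfreq(F, d=cgram.octaves_per_channel)     # cycles/octave
    Ht = _log_gaussian(ft, rate) if rate is not None else np.ones(T)
    Hs = _log_gaussian(fs, scale) if scale is not None else np.ones(F)
    H = np.outer(Ht, Hs)
    return np.real(np.fft.ifft2(np.fft.fft2(C) * H))


def modulation_energy(cgram: Cochleagram,
                      rates=TEMPORAL_RATES_HZ,
                      scales=SPECTRAL_SCALES_CPO):
    """Cochlear energy and temporal/spectral/joint modulation energies of
    one cochleagram.

    Modulation strength per filter = s.d. across time of each channel of
    the filtered cochleagram, averaged across channels.  Rates above the
    envelope Nyquist, and slow rates with fewer than two periods in the
    signal, are returned NaN (flagged unreliable).
    """
    dur = cgram.values.shape[0] / cgram.env_sr
    nyq = cgram.env_sr / 2

    def strength(filtered):
        return float(filtered.std(axis=0).mean())

    cochlear = cgram.values.mean(axis=0)
    temporal = {r: (strength(_filter_2d(cgram, r, None))
                    if (r < nyq and dur * r >= 2) else np.nan) for r in rates}
    spectral = {s: strength(_filter_2d(cgram, None, s)) for s in scales}
    joint = {}
    for r in rates:
        for s in scales:
            ok = r < nyq and dur * r >= 2
            joint[(r, s)] = (strength(_filter_2d(cgram, r, s)) if ok else np.nan)
    return cochlear, temporal, spectral, joint


def feature_table(waves: list, sr: float, **cochleagram_kwargs) -> FeatureTable:
    """FeatureTable for a list of waveforms sharing one sample rate."""
    coch_rows, t_rows, s_rows, j_rows = [], [], [], []
    freqs = None
    for w in waves:
        cg = cochleagram(w, sr, **cochleagram_kwargs)
        freqs = cg.center_freqs
        ce, te, se, je = modulation_energy(cg)
        coch_rows.append(ce)
        t_rows.append(te)
        s_rows.append(se)
        j_rows.append(je)
    cochlear = pd.DataFrame(np.asarray(coch_rows),
                            columns=[f"{f:.0f}Hz" for f in freqs])
    temporal = pd.DataFrame(t_rows)
    temporal.columns = [f"{r}Hz" for r in temporal.columns]
    spectral = pd.DataFrame(s_rows)
    spectral.columns = [f"{s}cyc/oct" for s in spectral.columns]
    joint = pd.DataFrame(j_rows)
    joint.columns = [f"{r}Hz_{s}cyc/oct" for r, s in joint.columns]
    return FeatureTable(cochlear=cochlear, temporal=temporal,
                        spectral=spectral, spectrotemporal=joint)


# ---------------------------------------------------------------------------
# max-statistic permutation test
# ---------------------------------------------------------------------------

def _corr_columns(y: np.ndarray, F: np.ndarray) -> np.ndarray:
    """Pearson correlation of y with every column of F (constant columns
    excluded upstream)."""
    yc = y - y.mean()
    Fc = F - F.mean(axis=0, keepdims=True)
    den = np.linalg.norm(yc) * np.linalg.norm(Fc, axis=0)
    return (Fc.T @ yc) / den


def feature_correlation_test(profiles: np.ndarray, features: FeatureTable,
                             n_perm: int = 1000, seed: int = 0) -> pd.DataFrame:
    """Max-statistic permutation test of component-feature correlations.

    For each component and each feature group (frequency channels;
    modulation columns), the statistic is the maximum signed correlation
    across the group's columns.  The null permutes the correspondence
    between sounds' features and the component profile (``n_perm``
    permutations, seeded); the two-sided p-value doubles the smaller tail
    overlap and is floored at 2 / (n_perm + 1).
    """
    P = np.atleast_2d(np.asarray(profiles, dtype=float).T).T
    rng = np.random.default_rng(seed)
    n_sounds = P.shape[0]
    perms = np.stack([rng.permutation(n_sounds) for _ in range(n_perm)])
    rows = []
    for gname, frame in features.groups().items():
        F = frame.to_numpy(dtype=float)
        keep = np.nanstd(F, axis=0) > 0
        keep &= ~np.isnan(F).any(axis=0)
        F = F[:, keep]
        if F.shape[1] == 0:
            continue
        Fc = F - F.mean(axis=0, keepdims=True)
        Fn = Fc / np.linalg.norm(Fc, axis=0)
        for k in range(P.shape[1]):
            y = P[:, k]
            obs_r = _corr_columns(y, F)
            obs = obs_r.max()
            Yp = y[perms]
            Yc = Yp - Yp.mean(axis=1, keepdims=True)
            Yn = Yc / np.linalg.norm(Yc, axis=1, keepdims=True)
            null = (Yn @ Fn).max(axis=1)
            ge = (1 + (null >= obs).sum()) / (n_perm + 1)
            le = (1 + (null <= obs).sum()) / (n_perm + 1)
            p = min(1.0, 2.0 * min(ge, le))
            p = max(p, 2.0 / (n_perm + 1))
            rows.append({"group": gname, "component": k,
                         "max_correlation": float(obs),
                         "best_column": frame.columns[keep][int(np.argmax(obs_r))],
                         "p_value": float(p)})
    return pd.DataFrame(rows)
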