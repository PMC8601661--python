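"""From raw measurements to baseline-normalized, time-averaged responses.

Covers power-Doppler image formation with an SVD clutter filter, conversion
of trial timecourses to percent signal change, window averaging into
:class:`~natsynth_fus.datasets.ResponseMatrix` splits, and best-frequency
(tonotopy) maps from pure-tone datasets.
"""

from __future__ import annotations

import logging

import numpy as np

from .datasets import ResponseMatrix, TrialDataset

__all__ = [
    "power_doppler",
    "percent_signal_change",
    "time_average",
    "response_splits",
    "best_frequency_map",
]

log = logging.getLogger(__name__)


def power_doppler(frames: np.ndarray, n_discard: int = 55) -> np.ndarray:
    """Blood-signal power per pixel after an SVD clutter filter.

    The frame stack is reshaped to (time x pixels); the first ``n_discard``
    principal components over the time dimension (ordered by singular value)
    are removed, and the per-pixel sum of squared magnitudes across frames is
    returned.  Tissue motion is high-energy and low-rank, so discarding the
    leading components isolates the blood signal.
    """
    frames = np.asarray(frames, dtype=float)
    n_frames = frames.shape[0]
    if n_discard >= n_frames:
        raise ValueError(f"n_discard={n_discard} must be < n_frames={n_frames}")
    shape = frames.shape[1:]
    X = frames.reshape(n_frames, -1)
    if n_discard > 0:
        U, s, Vt = np.linalg.svd(X, full_matrices=False)
        X = X - (U[:, :n_discard] * s[:n_discard]) @ Vt[:n_discard]
    return (X ** 2).sum(axis=0).reshape(shape)


def percent_signal_change(dataset: TrialDataset) -> TrialDataset:
    """Normalize each trial by the pre-stimulus baseline.

    Per trial, the mean signal over the baseline window is subtracted; the
    result is divided by the voxel's mean baseline over the whole session,
    yielding fractional signal change.  Voxels with non-positive session
    baseline cannot be normalized and are returned as NaN (and logged).
    """
    base = dataset.timing.baseline_samples
    if base.size == 0:
        raise ValueError("baseline window is empty")
    trial_base = dataset.data[:, :, base].mean(axis=2)       # (V, trials)
    session_base = trial_base.mean(axis=1)                   # (V,)
    bad = session_base <= 0
    if bad.any():
        log.warning("%d voxels with non-positive session baseline flagged NaN",
                    int(bad.sum()))
    denom = np.where(bad, np.nan, session_base)
    out = (dataset.data - trial_base[:, :, None]) / denom[:, None, None]
    return dataset.copy_with(out, units="fractional")


def _check_units(dataset: TrialDataset) -> None:
    if dataset.units == "raw":
        raise ValueError("apply percent_signal_change before time averaging")


def time_average(dataset: TrialDataset, window=(3.0, 11.0),
                 split: str = "all") -> ResponseMatrix:
    """One value per voxel x sound: mean over the analysis window, then over
    the split's repetitions.

    ``split`` is "all", "odd", "even", or "rep{i}"; repetitions of the same
    sound are averaged (voxels keep their slice identity, so pooling across
    slices happens along the voxel axis automatically).
    """
    _check_units(dataset)
    win = dataset.timing.window_samples(*window)
    if win.size == 0:
        raise ValueError("analysis window contains no samples")
    reps = np.arange(dataset.n_reps)
    if split == "all":
        use = reps
    elif split == "odd":
        use = reps[1::2]   # second, fourth, ... repetition (0-based index 1, 3)
    elif split == "even":
        use = reps[0::2]
    elif split.startswith("rep"):
        use = np.array([int(split[3:])])
    else:
        raise ValueError(f"unknown split {split!r}")
    tt = dataset.trial_table
    present = np.intersect1d(use, tt["rep"].unique())
    if present.size == 0:
        raise ValueError(f"split {split!r} selects no repetitions; "
                         f"missing reps {sorted(set(use.tolist()))}")
    wmean = dataset.data[:, :, win].mean(axis=2)   # (V, trials)
    S = dataset.n_sounds
    values = np.zeros((dataset.n_voxels, S))
    for s in range(S):
        sel = tt.index[(tt["sound"] == s) & tt["rep"].isin(present)].to_numpy()
        values[:, s] = wmean[:, sel].mean(axis=1)
    return ResponseMatrix(values=values, split_id=split,
                          sound_table=dataset.sound_table.copy())


def response_splits(dataset: TrialDataset, window=(3.0, 11.0)):
    """(odd, even) ResponseMatrix pair — the two independent measurements
    used by every noise-corrected statistic."""
    return (time_average(dataset, window, "odd"),
            time_average(dataset, window, "even"))


def best_frequency_map(tone_dataset: TrialDataset, window=(3.0, 5.0)):
    """Per-voxel best frequency: the tone evoking the largest windowed
    response.  Ties are broken toward the lower frequency (and counted).

    Returns ``(best_freq_hz, tie_flag)`` arrays over voxels.
    """
    if "frequency_hz" not in tone_dataset.sound_table.columns:
        raise ValueError("tone dataset must label sounds with 'frequency_hz'")
    resp = time_average(tone_dataset, window=window, split="all")
    freqs = tone_dataset.sound_table["frequency_hz"].to_numpy(dtype=float)
    order = np.argsort(freqs)            # argmax scans low to high -> ties go low
    vals = resp.values[:, order]
    best = np.argmax(vals, axis=1)
    ties = (vals == vals[np.arange(len(vals)), best][:, None]).sum(axis=1) > 1
    if ties.any():
        log.info("%d voxels with tied best-frequency responses (tie -> lower "
                 "frequency)", int(ties.sum()))
    return freqs[order][best], ties
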