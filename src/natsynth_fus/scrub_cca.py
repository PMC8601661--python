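"""Denoising part I: canonical-correlation scrubbing of shared noise.

Out-of-cortex voxels cannot contain stimulus-driven cortical responses but
do pick up motion and other global artifacts.  Timecourses that are shared
between in- and out-of-cortex voxels are therefore noise — but because
animals move more during some sounds, a naive shared-timecourse search would
also capture genuine sound-evoked activity.  The trick is to fit the shared
basis on *residuals* after removing each sound's across-repetition mean
(sound-locked activity is reliable across repetitions, motion is not), and
then project the fitted noise timecourses out of the full data.

CCA here is ridge-regularized (shrinkage added to both covariances) because
voxel counts can exceed timepoints.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .datasets import TrialDataset, VoxelGeometry

__all__ = [
    "NoiseBasis",
    "trial_residuals",
    "fit_noise_basis",
    "remove_noise_components",
    "scrub",
]

log = logging.getLogger(__name__)

DEFAULT_K = 20
DEFAULT_SHRINKAGE = 1e-3


@dataclass
class NoiseBasis:
    """Canonical noise timecourses (columns unit-norm, correlations sorted
    descending).  Timecourses live on the concatenated-trial time axis."""

    timecourses: np.ndarray            # (time, k)
    canonical_correlations: np.ndarray  # (k,) in [0, 1]
    meta: dict = field(default_factory=dict)


def trial_residuals(dataset: TrialDataset):
    """Residual activity after removing trial-averaged (sound-locked)
    responses.

    For each voxel and each sound, the across-repetition mean timecourse is
    subtracted from every trial of that sound.  Sounds with fewer than two
    repetitions carry no residual information and their trials are excluded
    (with a warning).

    Returns ``(residuals, used_trials)`` where residuals is
    ``(n_voxels, n_used_trials, n_samples)`` and ``used_trials`` indexes the
    dataset's trial axis.
    """
    tt = dataset.trial_table
    res = np.array(dataset.data)
    used = []
    for s in range(dataset.n_sounds):
        idx = tt.index[tt["sound"] == s].to_numpy()
        if idx.size < 2:
            log.warning("sound %d has %d repetition(s); excluded from "
                        "residuals", s, idx.size)
            continue
        res[:, idx, :] -= res[:, idx, :].mean(axis=1, keepdims=True)
        used.extend(idx.tolist())
    used = np.sort(np.asarray(used, dtype=int))
    return res[:, used, :], used


def _concat(res: np.ndarray) -> np.ndarray:
    """(voxels, trials, samples) -> (time, voxels) concatenated over trials."""
    V = res.shape[0]
    return res.reshape(V, -1).T


def _reg_invsqrt(C: np.ndarray, shrinkage: float) -> np.ndarray:
    gamma = shrinkage * np.trace(C) / C.shape[0]
    w, Q = np.linalg.eigh(C + gamma * np.eye(C.shape[0]))
    w = np.clip(w, 1e-12, None)
    return Q @ np.diag(w ** -0.5) @ Q.T


def fit_noise_basis(in_res: np.ndarray, out_res: np.ndarray, k: int = DEFAULT_K,
                    shrinkage: float = DEFAULT_SHRINKAGE,
                    meta: dict | None = None) -> NoiseBasis:
    """CCA between in-cortex and out-of-cortex residual timecourses.

    Inputs are (time, voxels) matrices sharing the time axis.  The noise
    basis is built from the out-of-cortex canonical variates — by
    construction those voxels contain no cortical stimulus response, so
    their variates are safe to treat as noise.  ``k`` is capped at the
    smaller effective rank (logged when reduced).
    """
    X = in_res - in_res.mean(axis=0, keepdims=True)
    Y = out_res - out_res.mean(axis=0, keepdims=True)
    if X.shape[0] != Y.shape[0]:
        raise ValueError("residual matrices must share the time axis")
    T = X.shape[0]
    k_max = min(X.shape[1], Y.shape[1], T - 1)
    if k > k_max:
        log.info("noise basis rank reduced from %d to %d", k, k_max)
        k = k_max
    if k == 0:
        return NoiseBasis(np.zeros((T, 0)), np.zeros(0), meta or {})
    Cxx = X.T @ X / T
    Cyy = Y.T @ Y / T
    Cxy = X.T @ Y / T
    Wx = _reg_invsqrt(Cxx, shrinkage)
    Wy = _reg_invsqrt(Cyy, shrinkage)
    M = Wx @ Cxy @ Wy
    U, s, Vt = np.linalg.svd(M, full_matrices=False)
    corrs = np.clip(s[:k], 0.0, 1.0)
    Z = Y @ (Wy @ Vt[:k].T)          # out-of-cortex canonical variates
    norms = np.linalg.norm(Z, axis=0)
    Z = Z / np.where(norms > 0, norms, 1.0)
    return NoiseBasis(timecourses=Z, canonical_correlations=corrs,
                      meta=meta or {})


def remove_noise_components(data: np.ndarray, basis: NoiseBasis) -> np.ndarray:
    """Subtract each voxel's least-squares projection onto the noise
    timecourses.

    ``data`` is (voxels, time) or (voxels, trials, samples); the basis time
    axis must match the (concatenated) time axis.  The basis was fit on
    residuals but is applied to the full timecourses: projecting out of the
    residuals alone would leave the noise contribution that is correlated
    with sound identity in place.
    """
    shape = data.shape
    X = data.reshape(shape[0], -1)
    B = basis.timecourses
    if B.shape[1] == 0:
        return np.array(data)
    if B.shape[0] != X.shape[1]:
        raise ValueError("basis time axis does not match data")
    Q, _ = np.linalg.qr(B)
    clean = X - (X @ Q) @ Q.T
    return clean.reshape(shape)


def scrub(dataset: TrialDataset, geometry: VoxelGeometry, k: int = DEFAULT_K,
          shrinkage: float = DEFAULT_SHRINKAGE):
    """Full part-I pipeline, slice by slice.

    Each slice is an independent session, so the noise basis is fit within
    slice: residuals of its in-cortex vs out-of-cortex voxels, CCA, and
    projection of the top-k canonical timecourses out of every voxel in the
    slice.  Returns ``(cleaned_dataset, {slice_id: NoiseBasis})``.
    """
    clean = np.array(dataset.data)
    bases = {}
    for sl in np.unique(geometry.slice_id):
        vox = geometry.slice_id == sl
        sub = dataset.data[vox]
        res, used = trial_residuals(
            dataset.copy_with(sub))
        in_vox = geometry.cortex_mask[vox]
        basis = fit_noise_basis(_concat(res[in_vox]), _concat(res[~in_vox]),
                                k=k, shrinkage=shrinkage,
                                meta={"slice": int(sl), "trials": used.tolist()})
        full = sub[:, used, :]
        cleaned = remove_noise_components(full, basis)
        clean[np.ix_(vox, used)] = cleaned.reshape(full.shape)
        bases[int(sl)] = basis
    return dataset.copy_with(clean), bases
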