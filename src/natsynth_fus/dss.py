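"""Denoising part II: reliability-biased component extraction (DSS).

Plain PCA extracts high-variance components; denoising source separation
(DSS, also called joint decorrelation) extracts components with high
variance *after a biasing operation*.  Here the bias favors reliability:
each (repetition, slice) data matrix is whitened individually, whitened
matrices are averaged across repetitions (reinforcing repeatable activity),
the repetition-averaged matrices are concatenated across slices along the
voxel dimension (slices are separate sessions, so their noise is
independent), and PCA of the concatenation yields the "reliable components"
R.  Denoising is projection onto their span:

    D_denoised = R R+ D

Component count N is chosen by cross-validation over sounds: reliable
components and voxel weights W = R+ D are fit on 75% of the sound pairs and
applied to the held-out 25% (D_test W+ W), and the gain in split-half
reliability is measured against the sqrt-reliability upper bound.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datasets import TrialDataset, VoxelGeometry

__all__ = [
    "ReliableComponents",
    "whiten",
    "timecourse_matrices",
    "rep_average_matrix",
    "fit_reliable_components",
    "project_denoise",
    "split_sound_pairs",
    "crossval_component_count",
    "denoise_dataset",
]

log = logging.getLogger(__name__)

RANK_TOL = 1e-6
DEFAULT_N = 8
TRAIN_FRAC = 0.75


@dataclass
class ReliableComponents:
    """Orthonormal reliable-component timecourses (time x N)."""

    R: np.ndarray
    n_components: int
    singular_values: np.ndarray = field(default_factory=lambda: np.zeros(0))
    provenance: dict = field(default_factory=dict)


def whiten(X: np.ndarray, rank_tol: float = RANK_TOL) -> np.ndarray:
    """SVD whitening: output has identity covariance on its retained
    subspace (dimensions with singular value <= rank_tol * max are dropped).
    Shape is preserved (time x voxels); zero-variance voxels contribute
    nothing."""
    X = np.asarray(X, dtype=float)
    T = X.shape[0]
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    keep = s > rank_tol * (s[0] if s.size else 1.0)
    return np.sqrt(T) * U[:, keep] @ Vt[keep]


def timecourse_matrices(dataset: TrialDataset, geometry: VoxelGeometry,
                        sounds=None, cortex_only: bool = True) -> dict:
    """Per (rep, slice) matrices of concatenated sound timecourses.

    Each matrix is (n_sounds * n_samples, n_slice_voxels); rows are ordered
    by sound then within-trial sample, identically for every repetition and
    slice.  Only in-cortex voxels are included by default.
    """
    tt = dataset.trial_table
    sounds = np.arange(dataset.n_sounds) if sounds is None else np.asarray(sounds)
    out = {}
    for sl in np.unique(geometry.slice_id):
        vox = geometry.slice_id == sl
        if cortex_only:
            vox = vox & geometry.cortex_mask
        if not vox.any():
            continue
        for r in sorted(tt["rep"].unique()):
            rows = []
            for s in sounds:
                idx = tt.index[(tt["sound"] == s) & (tt["rep"] == r)].to_numpy()
                if idx.size != 1:
                    raise ValueError(f"sound {s} rep {r} appears {idx.size} times")
                rows.append(dataset.data[vox][:, idx[0], :])
            out[(int(r), int(sl))] = np.concatenate(rows, axis=1).T
    return out


def rep_average_matrix(dataset: TrialDataset, geometry: VoxelGeometry,
                       reps=None, sounds=None, cortex_only: bool = True) -> np.ndarray:
    """Repetition-averaged concatenated timecourse matrix (time x voxels),
    voxels ordered as in the geometry (cortex voxels only by default)."""
    mats = timecourse_matrices(dataset, geometry, sounds=sounds,
                               cortex_only=cortex_only)
    reps_all = sorted({r for r, _ in mats})
    reps = reps_all if reps is None else [r for r in reps_all if r in set(np.atleast_1d(reps))]
    if not reps:
        raise ValueError("no repetitions selected")
    slices = sorted({sl for _, sl in mats})
    blocks = [np.mean([mats[(r, sl)] for r in reps], axis=0) for sl in slices]
    return np.concatenate(blocks, axis=1)


def fit_reliable_components(matrices: dict, n_components: int = DEFAULT_N) -> ReliableComponents:
    """Whiten each (rep, slice) matrix, average across repetitions within
    slice, concatenate across slices along the voxel axis, and take the top
    principal components of the concatenation."""
    slices = sorted({sl for _, sl in matrices})
    blocks = []
    for sl in slices:
        reps = sorted(r for r, s in matrices if s == sl)
        if not reps:
            continue
        white = [whiten(matrices[(r, sl)]) for r in reps]
        # repetitions may differ in retained rank; average on common columns
        ncol = min(w.shape[1] for w in white)
        blocks.append(np.mean([w[:, :ncol] for w in white], axis=0))
    concat = np.concatenate(blocks, axis=1)
    U, s, _ = np.linalg.svd(concat, full_matrices=False)
    rank = int((s > RANK_TOL * s[0]).sum())
    if n_components > rank:
        log.warning("requested %d components exceeds rank %d; truncated",
                    n_components, rank)
        n_components = rank
    return ReliableComponents(R=U[:, :n_components], n_components=n_components,
                              singular_values=s[:n_components],
                              provenance={"slices": slices})


def project_denoise(D: np.ndarray, components: ReliableComponents) -> np.ndarray:
    """Project the data matrix (time x voxels) onto the span of the reliable
    components: D_denoised = R R+ D (output rank <= N)."""
    R = components.R
    if R.shape[1] == 0:
        return np.zeros_like(D)
    if R.shape[0] != D.shape[0]:
        raise ValueError("time axes of R and D are incompatible")
    return R @ (np.linalg.pinv(R) @ D)


def split_sound_pairs(sound_table: pd.DataFrame, train_frac: float = TRAIN_FRAC,
                      seed: int = 0):
    """Stratified train/test split of natural/synthetic *pairs*.

    A natural sound and its matched synthetic always land on the same side
    (no train/test leakage through shared acoustics); within each category
    the pairs are split ``train_frac`` / ``1 - train_frac``, fractional seats
    assigned round-robin across categories.

    Returns ``(train_sounds, test_sounds)`` as arrays of sound indices.
    """
    rng = np.random.default_rng(seed)
    nat = sound_table[sound_table["is_natural"]].sort_values("pair")
    train_pairs, test_pairs = [], []
    carry = 0.0
    for cat in sorted(nat["category"].unique()):
        pairs = nat.loc[nat["category"] == cat, "pair"].to_numpy()
        pairs = rng.permutation(pairs)
        exact = train_frac * pairs.size + carry
        n_train = int(np.floor(exact))
        carry = exact - n_train
        n_train = min(max(n_train, 1 if pairs.size > 1 else pairs.size), pairs.size)
        train_pairs.extend(pairs[:n_train])
        test_pairs.extend(pairs[n_train:])
    if not test_pairs:
        log.warning("categories too small to hold out pairs; moving one "
                    "train pair to test")
        test_pairs.append(train_pairs.pop())
    def sounds_of(pairs):
        sel = sound_table["pair"].isin(pairs)
        return sound_table.index[sel].to_numpy()
    return sounds_of(train_pairs), sounds_of(test_pairs)


def _window_average(mat: np.ndarray, dataset: TrialDataset, sounds, window) -> np.ndarray:
    """(n_sounds*T, voxels) concatenated matrix -> (voxels, n_sounds)."""
    T = dataset.timing.n_samples
    win = dataset.timing.window_samples(*window)
    n_sounds = len(sounds)
    stacked = mat.reshape(n_sounds, T, -1)
    return stacked[:, win, :].mean(axis=1).T


def _rowcorr(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    a = a - a.mean(axis=1, keepdims=True)
    b = b - b.mean(axis=1, keepdims=True)
    num = (a * b).sum(axis=1)
    den = np.sqrt((a ** 2).sum(axis=1) * (b ** 2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)


def crossval_component_count(dataset: TrialDataset, geometry: VoxelGeometry,
                             n_range=range(1, 17), window=(3.0, 11.0),
                             train_frac: float = TRAIN_FRAC, seed: int = 0,
                             n_splits: int = 1) -> pd.DataFrame:
    """Reliability of held-out denoised responses as a function of N.

    For each candidate component count N: reliable components are fit on the
    training sounds, voxel weights W = R_train+ D_train are computed, and
    test-sound responses are denoised as (D_test W+) W — nothing is refit on
    test data.  Per-voxel split-half correlations (odd vs even repetitions)
    of window-averaged test responses are summarized before denoising, after
    denoising one split, after denoising both, and against the
    sqrt-reliability upper bound.

    ``n_splits > 1`` repeats the procedure over that many independent
    stratified train/test splits and averages the summaries (repeated
    cross-validation), which stabilizes the curve when the test set is
    small.
    """
    if n_splits > 1:
        tables = [crossval_component_count(dataset, geometry, n_range, window,
                                           train_frac, seed=seed + 1000 * i,
                                           n_splits=1)
                  for i in range(n_splits)]
        out = tables[0].copy()
        for col in out.columns:
            if col != "n_components":
                out[col] = np.mean([t[col] for t in tables], axis=0)
        return out
    train_sounds, test_sounds = split_sound_pairs(dataset.sound_table,
                                                  train_frac, seed)
    reps = np.arange(dataset.n_reps)
    odd, even = reps[1::2], reps[0::2]
    train_mats = timecourse_matrices(dataset, geometry, sounds=train_sounds)
    D_train = rep_average_matrix(dataset, geometry, sounds=train_sounds)
    D_test = {"odd": rep_average_matrix(dataset, geometry, reps=odd, sounds=test_sounds),
              "even": rep_average_matrix(dataset, geometry, reps=even, sounds=test_sounds)}
    raw = {k: _window_average(v, dataset, test_sounds, window)
           for k, v in D_test.items()}
    r_before = _rowcorr(raw["odd"], raw["even"])
    bound = np.sqrt(np.clip(r_before, 0.0, 1.0))

    rows = []
    max_n = max(n_range)
    comps = fit_reliable_components(train_mats, n_components=max_n)
    for N in n_range:
        R_train = ReliableComponents(R=comps.R[:, :N], n_components=N)
        W = np.linalg.pinv(R_train.R) @ D_train          # (N, voxels)
        W_pinv = np.linalg.pinv(W)
        den = {k: (v @ W_pinv) @ W for k, v in D_test.items()}
        den_avg = {k: _window_average(v, dataset, test_sounds, window)
                   for k, v in den.items()}
        r_one = 0.5 * (_rowcorr(den_avg["odd"], raw["even"])
                       + _rowcorr(den_avg["even"], raw["odd"]))
        r_both = _rowcorr(den_avg["odd"], den_avg["even"])
        rows.append({
            "n_components": N,
            "median_before": float(np.nanmedian(r_before)),
            "median_denoised_one": float(np.nanmedian(r_one)),
            "median_denoised_both": float(np.nanmedian(r_both)),
            "median_upper_bound": float(np.nanmedian(bound)),
        })
    return pd.DataFrame(rows)


def denoise_dataset(dataset: TrialDataset, geometry: VoxelGeometry,
                    n_components: int = DEFAULT_N):
    """Fit reliable components on all sounds and project the per-repetition
    data of every cortical voxel onto them.  Returns
    ``(denoised_dataset, ReliableComponents)``; out-of-cortex voxels are
    left untouched."""
    mats = timecourse_matrices(dataset, geometry)
    comps = fit_reliable_components(mats, n_components)
    clean = np.array(dataset.data)
    tt = dataset.trial_table
    T = dataset.timing.n_samples
    vox_order = []
    slices = sorted(np.unique(geometry.slice_id[geometry.cortex_mask]))
    for sl in slices:
        vox_order.extend(np.flatnonzero((geometry.slice_id == sl)
                                        & geometry.cortex_mask).tolist())
    vox_order = np.asarray(vox_order)
    for r in sorted(tt["rep"].unique()):
        rows = []
        for s in range(dataset.n_sounds):
            idx = tt.index[(tt["sound"] == s) & (tt["rep"] == r)].to_numpy()
            rows.append(dataset.data[vox_order][:, idx[0], :])
        D = np.concatenate(rows, axis=1).T       # (S*T, voxels)
        Dd = project_denoise(D, comps)
        stacked = Dd.reshape(dataset.n_sounds, T, -1)
        for s in range(dataset.n_sounds):
            idx = tt.index[(tt["sound"] == s) & (tt["rep"] == r)].to_numpy()
            clean[vox_order, idx[0], :] = stacked[s].T
    return dataset.copy_with(clean), comps
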