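"""Map-level analyses: surface projection, annular NSE profiles, slope
tests, model-comparison bootstraps, category-wise NSE, normalized difference
maps, and the video motion index.

The central spatial summary is the annular profile: voxels are binned by
their distance to the tonotopically defined center of primary auditory
cortex (PAC) and the median noise-corrected NSE per bin is plotted against
distance.  The slope of that curve (per absolute mm) is the per-subject
statistic compared across species with an exact sign test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import nse as nse_mod
from .datasets import Timing, VoxelGeometry

__all__ = [
    "surface_projection",
    "AnnularProfile",
    "annular_profile",
    "compare_slopes",
    "bootstrap_model_comparison",
    "category_nse",
    "category_nse_per_sound",
    "difference_map",
    "MotionTable",
    "motion_index",
]

log = logging.getLogger(__name__)


def surface_projection(values: np.ndarray, geometry: VoxelGeometry,
                       column_axes=(0, 1), depth_axis: int = 2):
    """View-from-above map: mean of ``values`` over each vertical column of
    in-cortex voxels.

    Columns are defined by the voxel coordinates along ``column_axes``;
    averaging runs along ``depth_axis`` (perpendicular to the cortical
    surface).  Returns a DataFrame with one row per column (coordinates and
    mean); columns with no valid voxel are absent.
    """
    mask = geometry.cortex_mask & np.isfinite(values)
    df = pd.DataFrame({
        "u": geometry.coords[mask, column_axes[0]],
        "v": geometry.coords[mask, column_axes[1]],
        "value": values[mask],
    })
    return df.groupby(["u", "v"], as_index=False)["value"].mean()


@dataclass
class AnnularProfile:
    bin_centers: np.ndarray     # mm
    median_nse: np.ndarray
    n_voxels: np.ndarray
    bin_size: float
    slope: float                # NSE change per mm over populated bins
    intercept: float
    subject: str = ""


def annular_profile(nse_values: np.ndarray, geometry: VoxelGeometry,
                    bin_size: float = 0.5, valid_mask=None,
                    subject: str = "") -> AnnularProfile:
    """Median NSE in annular distance-to-PAC bins, plus the least-squares
    slope of median vs (absolute) distance over populated bins."""
    if bin_size <= 0:
        raise ValueError("bin_size must be > 0")
    d = geometry.distance_to_pac
    ok = geometry.cortex_mask & np.isfinite(d) & np.isfinite(nse_values)
    if valid_mask is not None:
        ok &= np.asarray(valid_mask, bool)
    bins = np.floor(d[ok] / bin_size).astype(int)
    vals = nse_values[ok]
    centers, medians, counts = [], [], []
    for b in np.unique(bins):
        sel = bins == b
        centers.append((b + 0.5) * bin_size)
        medians.append(float(np.median(vals[sel])))
        counts.append(int(sel.sum()))
    centers, medians = np.asarray(centers), np.asarray(medians)
    if centers.size >= 2:
        slope, intercept = np.polyfit(centers, medians, 1)
    else:
        log.warning("fewer than 2 populated bins; slope undefined")
        slope, intercept = np.nan, np.nan
    return AnnularProfile(bin_centers=centers, median_nse=medians,
                          n_voxels=np.asarray(counts), bin_size=bin_size,
                          slope=float(slope), intercept=float(intercept),
                          subject=subject)


def compare_slopes(ferret_slope: float, human_slopes) -> float:
    """Exact two-sided sign test of one ferret slope against the
    distribution of human slopes.  Ties are dropped (logged).  With a single
    comparator the test is uninformative (p = 1)."""
    h = np.asarray(human_slopes, dtype=float)
    ties = h == ferret_slope
    if ties.any():
        log.info("dropping %d tied slopes from sign test", int(ties.sum()))
    h = h[~ties]
    n = h.size
    if n < 1:
        return 1.0
    k = int((h < ferret_slope).sum())
    return float(stats.binomtest(k, n, 0.5, alternative="two-sided").pvalue)


def bootstrap_model_comparison(model_splits: dict, n_boot: int = 1000,
                               seed: int = 0) -> pd.DataFrame:
    """Bootstrap comparison of median NSE between synthesis models.

    ``model_splits`` maps model name to ``(x1, x2, y1, y2)`` response
    matrices (voxels x sounds): natural splits and that model's synthetic
    splits.  Per bootstrap draw the sound axis is resampled with
    replacement, the per-voxel corrected NSE recomputed, and the median
    across voxels taken.  The two-sided p-value for each model pair doubles
    the smaller overlap fraction (floored at 2 / n_boot).
    """
    rng = np.random.default_rng(seed)
    names = list(model_splits)
    n_sounds = model_splits[names[0]][0].shape[1]
    draws = {m: np.empty(n_boot) for m in names}
    for b in range(n_boot):
        take = rng.integers(0, n_sounds, size=n_sounds)
        for m in names:
            x1, x2, y1, y2 = (a[:, take] for a in model_splits[m])
            vals = nse_mod.noise_corrected_nse(x1, x2, y1, y2)
            draws[m][b] = np.nanmedian(vals)
    rows = []
    for i, a in enumerate(names):
        for b_name in names[i + 1:]:
            d = draws[a] - draws[b_name]
            frac = min((d >= 0).mean(), (d <= 0).mean())
            p = max(2.0 * frac, 2.0 / n_boot)
            rows.append({"model_a": a, "model_b": b_name,
                         "median_a": float(np.median(draws[a])),
                         "median_b": float(np.median(draws[b_name])),
                         "p_value": float(min(p, 1.0))})
    return pd.DataFrame(rows)


def category_nse(x1, x2, y1, y2, categories) -> pd.DataFrame:
    """Noise-corrected NSE per sound category with a shared denominator.

    The numerator (corrected residual power between natural and synthetic)
    is restricted to each category's sounds; the denominator is computed
    from *all* sounds so the normalization is identical across categories
    and real category differences are not normalized away.  Values are
    per-voxel; the table reports the median across voxels per category.
    """
    x1, x2, y1, y2 = (np.atleast_2d(np.asarray(a, float)) for a in (x1, x2, y1, y2))
    categories = np.asarray(categories)
    px, py, mx, my, _ = nse_mod._corrected_terms(x1, x2, y1, y2)
    den = px + py - 2 * mx * my
    rows = []
    for cat in sorted(pd.unique(categories)):
        sel = categories == cat
        if sel.sum() < 2:
            log.warning("category %r has < 2 sounds; excluded", cat)
            continue
        pxc, pyc, _, _, crossc = nse_mod._corrected_terms(
            x1[:, sel], x2[:, sel], y1[:, sel], y2[:, sel])
        num = pxc + pyc - 2 * crossc
        with np.errstate(invalid="ignore", divide="ignore"):
            vals = np.where(den != 0, num / np.where(den != 0, den, 1.0), np.nan)
        rows.append({"category": cat, "n_sounds": int(sel.sum()),
                     "median_nse": float(np.nanmedian(vals)),
                     "values": vals})
    return pd.DataFrame(rows)


def category_nse_per_sound(x1, x2, y1, y2, categories) -> pd.DataFrame:
    """Per-sound corrected NSE (single-sound numerator, all-sound
    denominator), median across voxels — the distribution a Wilcoxon
    rank-sum test compares between categories."""
    x1, x2, y1, y2 = (np.atleast_2d(np.asarray(a, float)) for a in (x1, x2, y1, y2))
    px, py, mx, my, _ = nse_mod._corrected_terms(x1, x2, y1, y2)
    den = px + py - 2 * mx * my
    rows = []
    for s in range(x1.shape[1]):
        sl = slice(s, s + 1)
        num = (0.5 * ((x1[:, sl] - y1[:, sl]) * (x1[:, sl] - y2[:, sl])).mean(-1)
               + 0.5 * ((x2[:, sl] - y1[:, sl]) * (x2[:, sl] - y2[:, sl])).mean(-1))
        with np.errstate(invalid="ignore", divide="ignore"):
            vals = np.where(den != 0, num / np.where(den != 0, den, 1.0), np.nan)
        rows.append({"sound": s, "category": categories[s],
                     "nse": float(np.nanmedian(vals))})
    return pd.DataFrame(rows)


def difference_map(natural: np.ndarray, synthetic: np.ndarray,
                   categories, all_responses: np.ndarray) -> pd.DataFrame:
    """Per-voxel normalized natural-minus-synthetic difference per category.

    ``natural`` and ``synthetic`` are (voxels, pairs) aligned by pair;
    ``all_responses`` (voxels, all sounds) provides each voxel's response
    s.d. used as the normalizer (zero-s.d. voxels become NaN), so maps are
    in units of response s.d. and comparable across subjects.
    """
    natural, synthetic = np.asarray(natural, float), np.asarray(synthetic, float)
    sd = np.asarray(all_responses, float).std(axis=1)
    sd = np.where(sd > 0, sd, np.nan)
    categories = np.asarray(categories)
    rows = []
    for cat in sorted(pd.unique(categories)):
        sel = categories == cat
        diff = (natural[:, sel] - synthetic[:, sel]).mean(axis=1) / sd
        rows.append({"category": cat, "values": diff})
    return pd.DataFrame(rows)


@dataclass
class MotionTable:
    per_sound: pd.DataFrame       # sound, category, is_natural, motion index
    per_session: pd.DataFrame     # session, normalization s.d.


def motion_index(frames: np.ndarray, roi: np.ndarray, timing: Timing,
                 sounds: np.ndarray, session_ids: np.ndarray,
                 sound_table: pd.DataFrame, window=(3.0, 11.0)) -> MotionTable:
    """Sound-evoked motion from a face video.

    ``frames`` is (n_trials, n_samples, h, w) on the trial sampling grid.
    The per-frame index is the sum over ROI pixels of absolute frame-to-
    frame deviations (the first sample repeats the first available
    difference).  Evoked motion is computed like the imaging signal:
    baseline mean removed per trial, divided by the session's mean baseline
    motion, averaged over the analysis window; sessions are normalized by
    their s.d. across sounds (canceling camera gain/angle differences) and
    averaged.
    """
    roi = np.asarray(roi, bool)
    diffs = np.abs(np.diff(frames, axis=1))           # (trials, T-1, h, w)
    idx = diffs[:, :, roi].sum(axis=2)                # (trials, T-1)
    idx = np.concatenate([idx[:, :1], idx], axis=1)   # pad to T samples
    base = timing.baseline_samples
    win = timing.window_samples(*window)
    sounds = np.asarray(sounds)
    session_ids = np.asarray(session_ids)
    per_trial_base = idx[:, base].mean(axis=1)
    rows, sess_rows = [], []
    per_sound_sessions = []
    for sess in np.unique(session_ids):
        sel = session_ids == sess
        sess_base = per_trial_base[sel].mean()
        if sess_base <= 0:        # perfectly still camera: no evoked motion
            evoked = np.zeros_like(idx[sel])
        else:
            evoked = (idx[sel] - per_trial_base[sel][:, None]) / sess_base
        evoked_win = evoked[:, win].mean(axis=1)
        snd = sounds[sel]
        per_sound = pd.Series(evoked_win).groupby(snd).mean()
        sd = per_sound.std()
        sess_rows.append({"session": sess, "norm_sd": float(sd)})
        per_sound_sessions.append(per_sound / (sd if sd > 0 else 1.0))
    combined = pd.concat(per_sound_sessions, axis=1).mean(axis=1)
    st = sound_table
    for s, val in combined.items():
        rows.append({"sound": int(s), "category": st.loc[s, "category"],
                     "is_natural": bool(st.loc[s, "is_natural"]),
                     "motion": float(val)})
    return MotionTable(per_sound=pd.DataFrame(rows),
                       per_session=pd.DataFrame(sess_rows))
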