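"""Synthetic trial-structured datasets with known ground truth.

Emulates the structure of a passive-listening functional ultrasound (fUS)
experiment: a sound set of natural sounds and statistics-matched synthetic
counterparts, presented in 20 s trials (7 s baseline / 10 s sound / 3 s
post-stimulus) and repeated a few times while successive coronal slices are
imaged in separate sessions.  The generator plants:

* a low-rank sound-evoked response (``K`` latent components, default 8) with
  heavy-tailed, spatially smooth voxel weights (ICA-identifiable);
* a gamma-shaped hemodynamic build-up convolved with the stimulus boxcar;
* a configurable natural-vs-synthetic response gap that either grows with
  distance to primary auditory cortex ("human" profile) or is absent
  everywhere ("ferret" profile);
* motion artifacts shared between in- and out-of-cortex voxels, with
  amplitudes drawn per trial from a half-normal whose scale depends on the
  sound category (animals move more during some natural sounds);
* slice-common noise that is independent across slices, plus white
  repetition noise.

Every random draw funnels through one :class:`numpy.random.Generator` seeded
from the config; the module never touches global random state.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats
from scipy.ndimage import gaussian_filter1d

from .datasets import Timing, TrialDataset, VoxelGeometry

__all__ = [
    "SimConfig",
    "GroundTruth",
    "Simulation",
    "FrameStack",
    "make_ground_truth",
    "simulate_trials",
    "simulate",
    "simulate_doppler_frames",
    "simulate_tone_trials",
    "simulate_video",
    "hemodynamic_response",
]

DEFAULT_CATEGORIES = {"speech": 8, "music": 8, "vocalization": 4, "environment": 20}


@dataclass
class SimConfig:
    """Dimensions, effect sizes and noise levels of one simulated dataset.

    ``snr`` is the ratio of sound-evoked response variance (across sounds, of
    the time-window-averaged response) to the variance of the repetition
    noise after the same time averaging; ``snr = 1`` therefore means a single
    repetition measures the tuning curve at noise level equal to signal.
    """

    # sound set
    n_pairs: int = 40
    category_counts: dict = field(default_factory=lambda: dict(DEFAULT_CATEGORIES))
    # latent structure
    n_components: int = 8
    weight_sigma: float = 0.7          # log-normal shape of voxel weights
    weight_smooth_mm: float = 0.4      # spatial smoothing of weight fields
    category_selectivity: float = 1.5  # per-component category preference
    # natural-vs-synthetic gap
    gap_profile: str = "ferret"        # "ferret" (no gap) or "human"
    gap_max: float = 1.0               # gap at the most distal voxel, in units
                                       # of each voxel's response s.d.
    gap_categories: tuple | None = None  # None = all categories
    # geometry
    n_slices: int = 6
    slice_shape: tuple = (16, 4)       # in-cortex voxels per slice (y, z)
    n_out_voxels: int = 20             # out-of-cortex voxels per slice
    voxel_pitch_mm: float = 0.25
    slice_pitch_mm: float = 0.6
    # design
    n_reps: int = 4
    timing: Timing = field(default_factory=Timing)
    window: tuple = (3.0, 11.0)
    # signal and noise levels (fractional signal change)
    signal_sd: float = 0.05
    snr: float = 1.0
    sigma_slice: float = 0.01
    motion_scale_default: float = 0.02
    motion_scales: dict = field(default_factory=lambda: {"vocalization": 0.08,
                                                         "speech": 0.05})
    motion_stripe_period_mm: float = 1.0
    seed: int = 0

    @property
    def sigma_rep(self) -> float:
        """Per-sample repetition noise s.d. implied by ``snr``."""
        n_win = len(self.timing.window_samples(*self.window))
        if self.snr <= 0:
            return 0.0
        return self.signal_sd * np.sqrt(n_win / self.snr)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["timing"] = asdict(self.timing)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "timing" in d and isinstance(d["timing"], dict):
            d["timing"] = Timing(**d["timing"])
        for key in ("slice_shape", "window", "gap_categories"):
            if key in d and isinstance(d[key], list):   # YAML has no tuples
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class GroundTruth:
    """Planted latent structure of one simulated dataset."""

    component_profiles: np.ndarray   # (n_sounds, K), synthetic rows match natural
    component_weights: np.ndarray    # (n_voxels, K); zero outside cortex
    natsynth_gap: np.ndarray         # (n_voxels,) in units of response s.d.
    motion_loading: np.ndarray       # (n_voxels,)
    noise_spec: dict
    noiseless_responses: np.ndarray  # (n_voxels, n_sounds) window-averaged, no noise
    geometry: VoxelGeometry
    sound_table: pd.DataFrame
    config: SimConfig
    seed: int

    def timeavg_noise_var(self) -> float:
        """Variance of the window-averaged single-repetition measurement
        noise (repetition + slice noise; excludes motion).

        Includes the baseline-normalization term: subtracting the trial's
        noisy baseline estimate adds ``sigma^2 / n_baseline`` that is common
        to all samples of the trial and therefore does not average down over
        the analysis window.
        """
        timing = self.config.timing
        n_win = len(timing.window_samples(*self.config.window))
        n_base = len(timing.baseline_samples)
        var = self.noise_spec["sigma_rep"] ** 2 + self.noise_spec["sigma_slice"] ** 2
        return var * (1.0 / n_win + 1.0 / n_base)


@dataclass
class Simulation:
    dataset: TrialDataset
    geometry: VoxelGeometry
    truth: GroundTruth
    motion_traces: np.ndarray   # (n_slices, n_trials, n_samples), unit-RMS traces
    motion_amps: np.ndarray     # (n_slices, n_trials)


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------

def hemodynamic_response(timing: Timing, window=(3.0, 11.0),
                         shape: float = 3.0, scale: float = 0.7) -> np.ndarray:
    """Gamma-variate hemodynamic build-up convolved with the stimulus boxcar.

    Returns one trial's evoked timecourse (length ``timing.n_samples``),
    normalized so its mean over the analysis window is 1: a voxel whose
    planted window-averaged response is ``a`` gets an evoked timecourse of
    ``a`` times this curve.  The kernel rises over ~2 s and the convolved
    response peaks inside the 3-11 s window.
    """
    t = timing.times
    t_post = t - timing.baseline_s
    # response = gamma CDF build-up minus its echo at stimulus offset
    g = stats.gamma(a=shape, scale=scale)
    b = g.cdf(t_post) - g.cdf(t_post - timing.stim_s)
    b[t_post < 0] = 0.0
    win = timing.window_samples(*window)
    b /= b[win].mean()
    return b


def _make_sound_table(config: SimConfig) -> pd.DataFrame:
    cats = []
    for cat, n in config.category_counts.items():
        cats.extend([cat] * n)
    if len(cats) != config.n_pairs:
        raise ValueError("category counts must sum to n_pairs")
    rows = []
    for flag in (True, False):
        for pair, cat in enumerate(cats):
            rows.append({"category": cat, "is_natural": flag, "pair": pair})
    return pd.DataFrame(rows)


def _make_geometry(config: SimConfig) -> VoxelGeometry:
    ny, nz = config.slice_shape
    pitch, spitch = config.voxel_pitch_mm, config.slice_pitch_mm
    coords, mask, slice_id = [], [], []
    for sl in range(config.n_slices):
        x = sl * spitch
        for iy in range(ny):
            for iz in range(nz):
                coords.append((x, iy * pitch, iz * pitch))
                mask.append(True)
                slice_id.append(sl)
        # out-of-cortex voxels sit below the cortical sheet
        for j in range(config.n_out_voxels):
            coords.append((x, (j % ny) * pitch, (nz + 2 + j // ny) * pitch))
            mask.append(False)
            slice_id.append(sl)
    coords = np.asarray(coords)
    mask = np.asarray(mask)
    # PAC center: middle of the cortical sheet of the central slice
    pac = coords[mask].mean(axis=0)
    dist = np.linalg.norm(coords - pac, axis=1)
    dist[~mask] = np.nan
    return VoxelGeometry(coords=coords, cortex_mask=mask,
                         slice_id=np.asarray(slice_id), distance_to_pac=dist)


def _smooth_field(z: np.ndarray, coords: np.ndarray, scale_mm: float) -> np.ndarray:
    """Gaussian-kernel smoothing of per-voxel values over 3D positions."""
    if scale_mm <= 0:
        return z
    d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1)
    kern = np.exp(-0.5 * d2 / scale_mm ** 2)
    out = kern @ z
    # restore unit scale per column
    out /= out.std(axis=0, keepdims=True)
    return out


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------

def make_ground_truth(config: SimConfig) -> GroundTruth:
    """Draw the latent structure (components, weights, gap, motion loadings)."""
    K = config.n_components
    sound_table = _make_sound_table(config)
    n_sounds = len(sound_table)
    if K < 1 or K > min(config.n_pairs, np.prod(config.slice_shape) * config.n_slices):
        raise ValueError(f"invalid component count K={K} for these dimensions")
    rng = np.random.default_rng(config.seed)
    geom = _make_geometry(config)
    V = geom.n_voxels
    in_mask = geom.cortex_mask

    # component response profiles over natural sounds; synthetic sounds are
    # statistics-matched, so their latent profiles are identical
    prof_nat = rng.standard_normal((config.n_pairs, K))
    cats = sound_table[sound_table["is_natural"]].sort_values("pair")["category"].to_numpy()
    cat_names = list(config.category_counts)
    for k in range(min(K, len(cat_names))):
        prof_nat[cats == cat_names[k], k] += config.category_selectivity
    profiles = np.zeros((n_sounds, K))
    nat_idx = sound_table.index[sound_table["is_natural"]].to_numpy()
    syn_idx = sound_table.index[~sound_table["is_natural"]].to_numpy()
    order_nat = sound_table.loc[nat_idx].sort_values("pair").index.to_numpy()
    order_syn = sound_table.loc[syn_idx].sort_values("pair").index.to_numpy()
    profiles[order_nat] = prof_nat
    profiles[order_syn] = prof_nat

    # heavy-tailed, spatially smooth voxel weights (zero outside cortex)
    weights = np.zeros((V, K))
    z = rng.standard_normal((int(in_mask.sum()), K))
    z = _smooth_field(z, geom.coords[in_mask], config.weight_smooth_mm)
    if config.weight_sigma <= 0:
        warnings.warn("weight_sigma <= 0 gives Gaussian/degenerate weights; "
                      "histogram-entropy decomposition will be unidentifiable")
        w = z
    else:
        w = np.exp(config.weight_sigma * z)
        w -= np.median(w, axis=0, keepdims=True)
    w /= w.std(axis=0, keepdims=True)
    weights[in_mask] = w

    # natural-vs-synthetic gap vs distance to PAC
    gap = np.zeros(V)
    if config.gap_profile == "human":
        d = geom.distance_to_pac[in_mask]
        gap[in_mask] = config.gap_max * (d - d.min()) / (d.max() - d.min())
    elif config.gap_profile != "ferret":
        raise ValueError("gap_profile must be 'ferret' or 'human'")

    # motion loadings: spatially striped, nonzero inside and outside cortex
    y = geom.coords[:, 1]
    loading = np.sin(2 * np.pi * y / config.motion_stripe_period_mm) \
        + 0.3 * rng.standard_normal(V)

    # noiseless window-averaged responses, in fractional signal change
    A = weights @ profiles.T
    sd = A[in_mask].std(axis=1).mean()
    if sd > 0:
        A *= config.signal_sd / sd
    voxel_sd = A.std(axis=1)
    gap_cats = (set(config.gap_categories) if config.gap_categories is not None
                else set(config.category_counts))
    gap_sound = np.array([(r.is_natural and r.category in gap_cats)
                          for r in sound_table.itertuples()], dtype=float)
    A = A + np.outer(gap * voxel_sd, gap_sound)

    noise_spec = {
        "sigma_rep": config.sigma_rep,
        "sigma_slice": config.sigma_slice,
        "motion_scale_default": config.motion_scale_default,
        "motion_scales": dict(config.motion_scales),
    }
    return GroundTruth(component_profiles=profiles, component_weights=weights,
                       natsynth_gap=gap, motion_loading=loading,
                       noise_spec=noise_spec, noiseless_responses=A,
                       geometry=geom, sound_table=sound_table,
                       config=config, seed=config.seed)


# ---------------------------------------------------------------------------
# trial simulation
# ---------------------------------------------------------------------------

def simulate_trials(truth: GroundTruth, n_reps: int | None = None,
                    seed: int | None = None) -> Simulation:
    """Render trials from planted structure plus motion and noise.

    Each trial timecourse is ``hemodynamic curve x planted response`` plus a
    motion signal shared between in- and out-of-cortex voxels of the same
    slice (the animal moves once per session), slice-common noise, and white
    repetition noise, all in fractional units around a per-voxel raw baseline.
    """
    cfg = truth.config
    timing = cfg.timing
    n_reps = cfg.n_reps if n_reps is None else n_reps
    rng = np.random.default_rng(cfg.seed + 1 if seed is None else seed)
    geom = truth.geometry
    V, S, T = geom.n_voxels, len(truth.sound_table), timing.n_samples

    trial_table = pd.DataFrame(
        [{"sound": s, "rep": r} for r in range(n_reps) for s in range(S)])
    n_trials = len(trial_table)
    b = hemodynamic_response(timing, cfg.window)

    # evoked part: identical across reps, scaled per voxel x sound
    sounds = trial_table["sound"].to_numpy()
    evoked = truth.noiseless_responses[:, sounds][:, :, None] * b[None, None, :]

    # motion: per (slice, trial) half-normal amplitude with category-dependent
    # scale, times a smooth unit-RMS trace confined to the stimulus period
    st = truth.sound_table
    scale_per_sound = np.array([
        cfg.motion_scales.get(r.category, cfg.motion_scale_default)
        if r.is_natural else cfg.motion_scale_default
        for r in st.itertuples()])
    stim = (timing.times >= timing.baseline_s)
    n_slices = cfg.n_slices
    traces = gaussian_filter1d(rng.standard_normal((n_slices, n_trials, T)),
                               sigma=1.5, axis=-1)
    traces[:, :, ~stim] = 0.0
    rms = np.sqrt((traces[:, :, stim] ** 2).mean(axis=-1, keepdims=True))
    traces[:, :, stim] /= np.where(rms > 0, rms, 1.0)
    amps = np.abs(rng.standard_normal((n_slices, n_trials))) * scale_per_sound[sounds]

    data = np.array(evoked)  # (V, n_trials, T)
    slice_noise = cfg.sigma_slice * rng.standard_normal((n_slices, n_trials, T))
    for sl in range(n_slices):
        vox = geom.slice_id == sl
        m = amps[sl][:, None] * traces[sl]
        data[vox] += truth.motion_loading[vox][:, None, None] * m[None, :, :]
        data[vox] += slice_noise[sl][None, :, :]
    if cfg.sigma_rep > 0:
        data += cfg.sigma_rep * rng.standard_normal((V, n_trials, T))

    baseline = rng.uniform(80.0, 120.0, size=V)
    raw = baseline[:, None, None] * (1.0 + data)
    dataset = TrialDataset(data=raw, trial_table=trial_table,
                           sound_table=st.copy(), timing=timing, units="raw")
    return Simulation(dataset=dataset, geometry=geom, truth=truth,
                      motion_traces=amps[:, :, None] * traces, motion_amps=amps)


def simulate(config: SimConfig | None = None, **overrides) -> Simulation:
    """Convenience: ground truth + trials in one call."""
    if config is None:
        config = SimConfig(**overrides)
    elif overrides:
        config = SimConfig.from_dict({**config.to_dict(), **overrides})
    return simulate_trials(make_ground_truth(config))


# ---------------------------------------------------------------------------
# raw Doppler frames and video
# ---------------------------------------------------------------------------

@dataclass
class FrameStack:
    frames: np.ndarray       # (n_frames, ny, nx)
    blood_power: np.ndarray  # (ny, nx) ground-truth blood signal power


def simulate_doppler_frames(n_frames: int = 300, shape=(64, 64),
                            tissue_rank: int = 5, tissue_amp: float = 100.0,
                            blood_amp: float = 1.0, noise_amp: float = 0.1,
                            seed: int = 0) -> FrameStack:
    """Ultrafast frame ensemble: low-rank high-energy tissue motion plus a
    wideband blood signal plus white noise.

    The tissue component is confined to ``tissue_rank`` principal directions
    so a clutter filter discarding at least that many components leaves the
    blood signal (whose power per pixel is stored as ground truth).  The
    vascular map mirrors real tissue: bright vessels on top of a diffuse
    perfusion background, so the blood signal is spread over the whole image
    rather than a handful of pixels (as it is in vivo, where discarding a
    few dozen components cannot swallow it).
    """
    if tissue_rank >= n_frames:
        raise ValueError("tissue_rank must be < n_frames")
    rng = np.random.default_rng(seed)
    npix = int(np.prod(shape))
    frames = np.zeros((n_frames, npix))
    for i in range(tissue_rank):
        u = gaussian_filter1d(rng.standard_normal(n_frames), sigma=8.0)
        u /= np.linalg.norm(u)
        v = rng.standard_normal(npix)
        v /= np.linalg.norm(v)
        frames += tissue_amp / (i + 1) * np.outer(u, v)
    # vascular map: smooth vessels plus diffuse perfusion background
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    blood_map = np.full(shape, 0.25)
    for _ in range(4):
        cy, cx = rng.uniform(0, shape[0]), rng.uniform(0, shape[1])
        ang = rng.uniform(0, np.pi)
        along = (yy - cy) * np.cos(ang) + (xx - cx) * np.sin(ang)
        across = -(yy - cy) * np.sin(ang) + (xx - cx) * np.cos(ang)
        blood_map += np.exp(-(across ** 2) / 4.0 - (along ** 2) / 200.0)
    blood_map = blood_amp * blood_map / max(blood_map.max(), 1e-12)
    frames += rng.standard_normal((n_frames, npix)) * blood_map.ravel()
    frames += noise_amp * rng.standard_normal((n_frames, npix))
    blood_power = n_frames * blood_map ** 2
    return FrameStack(frames=frames.reshape(n_frames, *shape),
                      blood_power=blood_power)


TONE_FREQS_HZ = (602.0, 1430.0, 3400.0, 8087.0, 19234.0)


def simulate_tone_trials(geometry: VoxelGeometry, freqs=TONE_FREQS_HZ,
                         n_reps: int = 4, response_sd: float = 0.05,
                         noise_sd: float = 0.02, seed: int = 0,
                         timing: Timing | None = None) -> TrialDataset:
    """Pure-tone dataset with a planted tonotopic gradient along the y axis.

    Each cortical voxel's best frequency increases monotonically with its y
    coordinate; responses fall off with octave distance from the best
    frequency.  Used to exercise best-frequency mapping.
    """
    timing = timing or Timing(dt=1.0, baseline_s=7.0, stim_s=2.0, post_s=3.0)
    rng = np.random.default_rng(seed)
    freqs = np.asarray(freqs, dtype=float)
    n_tones = freqs.size
    V = geometry.n_voxels
    y = geometry.coords[:, 1]
    # planted best-frequency index: linear in y
    pos = (y - y.min()) / max(y.max() - y.min(), 1e-12)
    bf = pos * (n_tones - 1)
    oct_axis = np.log2(freqs / freqs[0]) / np.log2(freqs[-1] / freqs[0]) * (n_tones - 1)
    amp = response_sd * np.exp(-0.5 * ((bf[:, None] - oct_axis[None, :]) / 0.8) ** 2)
    amp[~geometry.cortex_mask] = 0.0

    sound_table = pd.DataFrame({
        "category": ["tone"] * n_tones,
        "is_natural": [True] * n_tones,
        "pair": np.arange(n_tones),
        "frequency_hz": freqs,
    })
    trial_table = pd.DataFrame(
        [{"sound": s, "rep": r} for r in range(n_reps) for s in range(n_tones)])
    b = hemodynamic_response(timing, window=(3.0, 5.0))
    sounds = trial_table["sound"].to_numpy()
    data = amp[:, sounds][:, :, None] * b[None, None, :]
    data += noise_sd * rng.standard_normal(data.shape)
    baseline = rng.uniform(80.0, 120.0, size=V)
    raw = baseline[:, None, None] * (1.0 + data)
    return TrialDataset(data=raw, trial_table=trial_table,
                        sound_table=sound_table, timing=timing, units="raw")


def simulate_video(motion_amps: np.ndarray, timing: Timing, shape=(16, 16),
                   baseline_motion: float = 0.2, seed: int = 0) -> np.ndarray:
    """Video frames whose frame-to-frame jitter follows a planted motion
    schedule.

    ``motion_amps`` is ``(n_trials,)``: extra jitter amplitude during each
    trial's stimulus period, on top of a constant baseline jitter.  Returns
    frames shaped ``(n_trials, n_samples, h, w)`` on the trial sampling grid.
    """
    rng = np.random.default_rng(seed)
    motion_amps = np.asarray(motion_amps, dtype=float)
    n_trials, T = motion_amps.size, timing.n_samples
    stim = timing.times >= timing.baseline_s
    base = rng.uniform(0.0, 1.0, size=shape)
    frames = np.empty((n_trials, T, *shape))
    for tr in range(n_trials):
        level = baseline_motion + motion_amps[tr] * stim
        jitter = rng.standard_normal((T, *shape)) * level[:, None, None]
        frames[tr] = base[None] + jitter
    return frames
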