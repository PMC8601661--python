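"""Core data containers for trial-based hemodynamic imaging experiments.

The unit of almost every analysis in this package is one of three containers:

``TrialDataset``
    voxel x trial x time responses together with a per-trial table (sound,
    repetition) and a per-sound table (category, natural/synthetic flag,
    pairing key).  Slices are a property of the *voxel* (each imaging slice is
    recorded in its own session), so every voxel sees the full trial grid of
    its own slice and the trial axis is shared across voxels.

``VoxelGeometry``
    3D voxel coordinates in mm, an in-cortex mask, slice membership, and the
    distance of each voxel to the tonotopically defined center of primary
    auditory cortex (PAC).

``ResponseMatrix``
    voxel x sound time-averaged responses for one repetition split; the input
    to every dissimilarity statistic.

Datasets round-trip through HDF5 (groups ``/data``, ``/trial_table``,
``/geometry``) and simulation configs through YAML.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

__all__ = [
    "Timing",
    "TrialDataset",
    "VoxelGeometry",
    "ResponseMatrix",
    "save_dataset",
    "load_dataset",
    "load_config",
    "save_config",
]


@dataclass(frozen=True)
class Timing:
    """Trial timing grid.

    Every trial is sampled on the same grid: ``baseline_s`` seconds of
    silence, ``stim_s`` seconds of sound, ``post_s`` seconds of silence, at
    ``dt`` seconds per sample.  Times are measured from trial start; stimulus
    onset is at ``baseline_s``.
    """

    dt: float = 1.0
    baseline_s: float = 7.0
    stim_s: float = 10.0
    post_s: float = 3.0

    @property
    def n_samples(self) -> int:
        return int(round((self.baseline_s + self.stim_s + self.post_s) / self.dt))

    @property
    def times(self) -> np.ndarray:
        """Sample-center times in seconds from trial start."""
        return (np.arange(self.n_samples) + 0.5) * self.dt

    def window_samples(self, start_s: float, end_s: float) -> np.ndarray:
        """Sample indices whose centers fall in ``[start, end)`` seconds
        post stimulus onset (half-open to avoid double counting)."""
        t_post = self.times - self.baseline_s
        return np.flatnonzero((t_post >= start_s) & (t_post < end_s))

    @property
    def baseline_samples(self) -> np.ndarray:
        return np.flatnonzero(self.times < self.baseline_s)


@dataclass
class TrialDataset:
    """Trial-structured voxel responses.

    Parameters
    ----------
    data
        ``(n_voxels, n_trials, n_samples)`` array.  Raw units are power
        Doppler a.u.; after :func:`~natsynth_fus.preprocess.percent_signal_change`
        units are fractional signal change.
    trial_table
        One row per trial with columns ``sound`` (integer id into
        ``sound_table``) and ``rep`` (repetition index).
    sound_table
        One row per sound with columns ``category`` (str), ``is_natural``
        (bool) and ``pair`` (int key linking each synthetic sound to its
        natural original; keys form a bijection between the two subsets).
    """

    data: np.ndarray
    trial_table: pd.DataFrame
    sound_table: pd.DataFrame
    timing: Timing = field(default_factory=Timing)
    units: str = "raw"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be (voxels, trials, samples)")
        if len(self.trial_table) != self.data.shape[1]:
            raise ValueError("trial_table length must match trial axis")
        if self.data.shape[2] != self.timing.n_samples:
            raise ValueError("sample axis does not match timing grid")
        pairs = self.sound_table["pair"].to_numpy()
        nat = self.sound_table["is_natural"].to_numpy(dtype=bool)
        nat_keys, syn_keys = np.sort(pairs[nat]), np.sort(pairs[~nat])
        if nat_keys.size and syn_keys.size and not np.array_equal(nat_keys, syn_keys):
            raise ValueError("pair keys must form a bijection between natural "
                             "and synthetic sound subsets")

    @property
    def n_voxels(self) -> int:
        return self.data.shape[0]

    @property
    def n_trials(self) -> int:
        return self.data.shape[1]

    @property
    def n_sounds(self) -> int:
        return len(self.sound_table)

    @property
    def n_reps(self) -> int:
        return int(self.trial_table["rep"].max()) + 1

    def trials_of_rep(self, reps) -> np.ndarray:
        """Trial indices for the given repetition indices, ordered by sound."""
        reps = np.atleast_1d(reps)
        sub = self.trial_table[self.trial_table["rep"].isin(reps)]
        return sub.sort_values(["rep", "sound"]).index.to_numpy()

    def copy_with(self, data: np.ndarray, units: str | None = None) -> "TrialDataset":
        return replace(self, data=data, units=self.units if units is None else units)


@dataclass
class VoxelGeometry:
    """Voxel positions and anatomical annotations."""

    coords: np.ndarray                   # (n_voxels, 3) mm
    cortex_mask: np.ndarray              # (n_voxels,) bool
    slice_id: np.ndarray                 # (n_voxels,) int
    distance_to_pac: np.ndarray          # (n_voxels,) mm, NaN outside cortex
    subject_id: str = "sim"
    hemisphere: str = "left"

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.cortex_mask = np.asarray(self.cortex_mask, dtype=bool)
        self.slice_id = np.asarray(self.slice_id, dtype=int)
        self.distance_to_pac = np.asarray(self.distance_to_pac, dtype=float)
        n = self.coords.shape[0]
        if not (self.cortex_mask.size == self.slice_id.size
                == self.distance_to_pac.size == n):
            raise ValueError("geometry fields must share the voxel axis")
        d = self.distance_to_pac[np.isfinite(self.distance_to_pac)]
        if d.size and d.min() < 0:
            raise ValueError("distances must be non-negative")

    @property
    def n_voxels(self) -> int:
        return self.coords.shape[0]

    def pairwise_distances(self, idx=None) -> np.ndarray:
        from scipy.spatial.distance import squareform, pdist

        c = self.coords if idx is None else self.coords[idx]
        return squareform(pdist(c))


@dataclass
class ResponseMatrix:
    """Time-averaged voxel x sound responses for one repetition split."""

    values: np.ndarray           # (n_voxels, n_sounds)
    split_id: str                # "all", "odd", "even", or "rep{i}"
    sound_table: pd.DataFrame

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape[1] != len(self.sound_table):
            raise ValueError("sound axis must match sound_table")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("response values must be finite")

    @property
    def n_voxels(self) -> int:
        return self.values.shape[0]

    def natural(self) -> np.ndarray:
        """Natural-sound columns ordered by pair key."""
        st = self.sound_table
        order = st[st["is_natural"]].sort_values("pair").index.to_numpy()
        return self.values[:, order]

    def synthetic(self) -> np.ndarray:
        """Synthetic-sound columns ordered by pair key (aligned to natural())."""
        st = self.sound_table
        order = st[~st["is_natural"]].sort_values("pair").index.to_numpy()
        return self.values[:, order]

    def natural_categories(self) -> np.ndarray:
        st = self.sound_table
        return st[st["is_natural"]].sort_values("pair")["category"].to_numpy()


# ---------------------------------------------------------------------------
# HDF5 / YAML round trips
# ---------------------------------------------------------------------------

def _write_frame(grp: h5py.Group, frame: pd.DataFrame) -> None:
    for col in frame.columns:
        vals = frame[col].to_numpy()
        if vals.dtype == object or vals.dtype.kind == "U":
            vals = np.asarray([str(v) for v in vals], dtype="S")
        grp.create_dataset(col, data=vals)
    grp.attrs["columns"] = list(frame.columns)


def _read_frame(grp: h5py.Group) -> pd.DataFrame:
    cols = {}
    for col in grp.attrs["columns"]:
        vals = grp[col][()]
        if vals.dtype.kind == "S":
            vals = vals.astype(str)
        cols[col] = vals
    return pd.DataFrame(cols)


def save_dataset(path, dataset: TrialDataset, geometry: VoxelGeometry | None = None) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=dataset.data)
        f.attrs["units"] = dataset.units
        for k in ("dt", "baseline_s", "stim_s", "post_s"):
            f.attrs[k] = getattr(dataset.timing, k)
        _write_frame(f.create_group("trial_table"), dataset.trial_table)
        _write_frame(f.create_group("sound_table"), dataset.sound_table)
        if geometry is not None:
            g = f.create_group("geometry")
            g.create_dataset("coords", data=geometry.coords)
            g.create_dataset("cortex_mask", data=geometry.cortex_mask)
            g.create_dataset("slice_id", data=geometry.slice_id)
            g.create_dataset("distance_to_pac", data=geometry.distance_to_pac)
            g.attrs["subject_id"] = geometry.subject_id
            g.attrs["hemisphere"] = geometry.hemisphere


def load_dataset(path) -> tuple[TrialDataset, VoxelGeometry | None]:
    with h5py.File(path, "r") as f:
        timing = Timing(dt=float(f.attrs["dt"]), baseline_s=float(f.attrs["baseline_s"]),
                        stim_s=float(f.attrs["stim_s"]), post_s=float(f.attrs["post_s"]))
        ds = TrialDataset(
            data=f["data"][()],
            trial_table=_read_frame(f["trial_table"]),
            sound_table=_read_frame(f["sound_table"]),
            timing=timing,
            units=str(f.attrs["units"]),
        )
        geom = None
        if "geometry" in f:
            g = f["geometry"]
            geom = VoxelGeometry(
                coords=g["coords"][()],
                cortex_mask=g["cortex_mask"][()].astype(bool),
                slice_id=g["slice_id"][()],
                distance_to_pac=g["distance_to_pac"][()],
                subject_id=str(g.attrs["subject_id"]),
                hemisphere=str(g.attrs["hemisphere"]),
            )
    return ds, geom


def load_config(path) -> dict:
    with open(path) as f:
        return yaml.safe_load(f)


def save_config(path, config: dict) -> None:
    Path(path).write_text(yaml.safe_dump(config, sort_keys=False))
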