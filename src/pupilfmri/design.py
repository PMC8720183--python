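"""First-level design construction: HRF convolution, parametric
modulation of task regressors by pupil measures, and the nuisance set
(motion + derivatives, DVARS outlier dummies, aCompCor components).

Four task-model variants are supported, mirroring the two headline
analyses and their controls:

* pupil size: one blockwise regressor (all 8 blocks, 40-s duration)
  parametrically modulated by the per-block mean pupil size;
* pupil change (pooled): the same blocks divided into 1-s bins, each
  modulated by the mean 1-Hz pupil change in the bin;
* pupil change per condition / block-mean / demeaned-per-condition:
  the condition-split and the two control variants that separate
  between-block mean differences from within-block fluctuations;
* trial peaks: one regressor over all 2.5-s trials modulated by the
  trial-wise pupil peak amplitude.

Modulators are mean-centered across events and the modulated column is
residualized against its unmodulated parent, so the main effect and the
modulation are separable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import PupilRecording, condition_means, downsample, pupil_change
from .task import TaskSchedule

TR = 2.5
N_VOLUMES = 176
N_DISCARD = 4
DRIFT_CUTOFF = 128.0  # s, discrete-cosine high-pass cutoff

#: voxel label vocabulary for the synthetic grid
LABELS = ("null", "FPN", "salience", "DMN", "WM", "CSF")

CHANGE_VARIANTS = ("pooled", "per_condition", "block_mean", "demeaned_per_condition")


@dataclass(frozen=True)
class Hrf:
    """Canonical double-gamma hemodynamic response function.

    The kernel is the difference of two gamma densities (peak at
    ``peak_delay``, undershoot at ``undershoot_delay``, amplitude ratio
    ``ratio``), sampled at ``dt`` over ``length`` seconds and scaled to
    unit peak.
    """

    peak_delay: float = 6.0
    undershoot_delay: float = 16.0
    peak_dispersion: float = 1.0
    undershoot_dispersion: float = 1.0
    ratio: float = 6.0
    length: float = 32.0
    dt: float = 0.1

    def kernel(self) -> np.ndarray:
        t = np.arange(0, self.length, self.dt)
        h = stats.gamma.pdf(t, self.peak_delay / self.peak_dispersion, scale=self.peak_dispersion)
        h = h - stats.gamma.pdf(
            t, self.undershoot_delay / self.undershoot_dispersion,
            scale=self.undershoot_dispersion) / self.ratio
        return h / h.max()


@dataclass(frozen=True)
class BoldDataset:
    """4-D BOLD signal on a small abstract grid, with voxel labels.

    ``data`` has shape (x, y, z, t) including the ``discard`` initial
    non-steady-state volumes; ``labels`` assigns each voxel one of
    ``LABELS`` (integer codes).
    """

    data: np.ndarray
    tr: float = TR
    labels: np.ndarray | None = None
    discard: int = N_DISCARD

    @property
    def n_volumes(self) -> int:
        return self.data.shape[-1]

    def kept(self) -> np.ndarray:
        """Volumes after discarding the initial non-steady-state frames."""
        return self.data[..., self.discard:]

    def frame_times(self) -> np.ndarray:
        """Acquisition times of kept volumes on the task clock (t=0 at
        the first kept volume)."""
        return np.arange(self.n_volumes - self.discard) * self.tr

    def label_mask(self, name: str) -> np.ndarray:
        if self.labels is None:
            raise ValueError("dataset has no voxel labels")
        return self.labels == LABELS.index(name)


@dataclass(frozen=True)
class DesignMatrix:
    """TR-gridded design with named task, drift, and nuisance columns."""

    frame_times: np.ndarray
    matrix: pd.DataFrame
    modulated_columns: tuple[str, ...] = ()

    def __post_init__(self):
        if len(self.matrix) != len(self.frame_times):
            raise ValueError("matrix rows must match frame_times")
        if self.matrix.columns.duplicated().any():
            raise ValueError("design column names must be unique")

    @property
    def values(self) -> np.ndarray:
        return self.matrix.to_numpy(float)

    def check_full_rank(self):
        # all-zero modulated columns (zero-variance modulator, already
        # warned at construction) are unestimable but tolerated here
        keep = [i for i, c in enumerate(self.matrix.columns)
                if not (c in self.modulated_columns
                        and np.allclose(self.matrix[c], 0.0))]
        X = self.values[:, keep]
        r = np.linalg.matrix_rank(X)
        if r < X.shape[1]:
            # name the offending columns for the error message
            names = [self.matrix.columns[i] for i in keep]
            q, rr = np.linalg.qr(X)
            bad = [names[i] for i in range(X.shape[1])
                   if abs(rr[i, i]) < 1e-8 * abs(rr).max()]
            raise ValueError(f"design matrix is rank deficient (rank {r} < {X.shape[1]}); "
                             f"collinear columns: {bad}")


def default_frame_times(n_volumes: int = N_VOLUMES, tr: float = TR,
                        discard: int = N_DISCARD) -> np.ndarray:
    return np.arange(n_volumes - discard) * tr


def dct_drift(frame_times: np.ndarray, cutoff: float = DRIFT_CUTOFF) -> pd.DataFrame:
    """Discrete-cosine low-frequency drift basis (high-pass cutoff in s)."""
    n = len(frame_times)
    duration = n * (frame_times[1] - frame_times[0])
    order = int(np.floor(2 * duration / cutoff))
    cols = {}
    grid = (np.arange(n) + 0.5) / n
    for r in range(1, order + 1):
        cols[f"drift_{r}"] = np.cos(np.pi * r * grid)
    return pd.DataFrame(cols)


def build_modulated_regressor(
    onsets: np.ndarray,
    durations: np.ndarray,
    modulator: np.ndarray,
    frame_times: np.ndarray,
    hrf: Hrf | None = None,
    residualize: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """HRF-convolved main and parametrically modulated columns.

    The main column is the unit-amplitude boxcar over the events
    convolved with the HRF on a microtime grid and sampled at
    ``frame_times``.  The modulated column scales each event's boxcar by
    the mean-centered modulator before convolution and is then
    residualized against the main column.
    """
    hrf = hrf or Hrf()
    onsets = np.asarray(onsets, float)
    durations = np.broadcast_to(np.asarray(durations, float), onsets.shape)
    modulator = np.asarray(modulator, float)
    if modulator.shape != onsets.shape:
        raise ValueError("one modulator value per event is required")
    if not np.all(np.isfinite(modulator)):
        raise ValueError("modulator values must be finite")

    centered = modulator - modulator.mean()
    if np.allclose(centered, 0.0):
        warnings.warn("zero-variance modulator; modulated column is identically zero")

    dt = hrf.dt
    t_max = max(frame_times[-1] + tr_step(frame_times), float(np.max(onsets + durations)))
    n_micro = int(np.ceil(t_max / dt)) + 1
    main_m = np.zeros(n_micro)
    mod_m = np.zeros(n_micro)
    for on, dur, m in zip(onsets, durations, centered):
        i0 = int(round(on / dt))
        i1 = max(i0 + 1, int(round((on + dur) / dt)))
        main_m[i0:i1] += 1.0
        mod_m[i0:i1] += m
    k = hrf.kernel()
    main_c = np.convolve(main_m, k)[:n_micro] * dt
    mod_c = np.convolve(mod_m, k)[:n_micro] * dt
    idx = np.round(np.asarray(frame_times) / dt).astype(int)
    main = main_c[idx]
    mod = mod_c[idx]
    if residualize and main.dot(main) > 0:
        mod = mod - main * (main.dot(mod) / main.dot(main))
    return main, mod


def tr_step(frame_times: np.ndarray) -> float:
    return float(frame_times[1] - frame_times[0]) if len(frame_times) > 1 else TR


def _assemble(frame_times, task_cols: dict[str, np.ndarray],
              modulated: tuple[str, ...],
              nuisance: pd.DataFrame | None = None,
              drift_cutoff: float | None = DRIFT_CUTOFF) -> DesignMatrix:
    mat = pd.DataFrame(task_cols)
    for name in task_cols:
        if name not in modulated and np.allclose(mat[name], 0.0):
            raise ValueError(f"all-zero task column: {name}")
    if drift_cutoff:
        mat = pd.concat([mat, dct_drift(frame_times, drift_cutoff)], axis=1)
    if nuisance is not None:
        if len(nuisance) != len(frame_times):
            raise ValueError("nuisance length does not match frame times")
        mat = pd.concat([mat, nuisance.reset_index(drop=True)], axis=1)
    mat["constant"] = 1.0
    dm = DesignMatrix(frame_times=np.asarray(frame_times, float), matrix=mat,
                      modulated_columns=modulated)
    dm.check_full_rank()
    return dm


def build_pupilsize_glm(
    schedule: TaskSchedule,
    rec: PupilRecording,
    frame_times: np.ndarray | None = None,
    nuisance: pd.DataFrame | None = None,
    hrf: Hrf | None = None,
) -> DesignMatrix:
    """Blockwise regressor modulated by per-block mean pupil size."""
    if frame_times is None:
        frame_times = default_frame_times()
    block_means, _ = condition_means(rec, schedule)
    onsets = np.array([b.onset for b in schedule.blocks])
    durations = np.full(len(onsets), schedule.blocks[0].duration)
    main, mod = build_modulated_regressor(
        onsets, durations, block_means["mean_pupil"].to_numpy(), frame_times, hrf)
    return _assemble(
        frame_times,
        {"task_block": main, "task_block_x_pupil_size": mod},
        modulated=("task_block_x_pupil_size",),
        nuisance=nuisance,
    )


def change_bins_per_block(schedule: TaskSchedule, rec: PupilRecording,
                          per_second: bool = False) -> pd.DataFrame:
    """1-Hz pupil-change bins tiling each block (40 bins of 1 s per block).

    Raises if the bins do not tile a block exactly.
    """
    ct, cv = pupil_change(rec, per_second=per_second)
    bt, bv = downsample(ct, cv, 1.0, rec.sample_rate)
    rows = []
    for b, block in enumerate(schedule.blocks):
        sel = (bt >= block.onset - 1e-9) & (bt < block.end - 1e-9)
        n = int(sel.sum())
        if n != int(round(block.duration)):
            raise ValueError(
                f"block {b}: expected {int(block.duration)} 1-s change bins, got {n}; "
                "bins must tile blocks exactly")
        for onset, value in zip(bt[sel], bv[sel]):
            rows.append({"block_index": b, "condition": block.condition.value,
                         "onset": float(onset), "change": float(value)})
    return pd.DataFrame(rows)


def build_pupilchange_glm(
    schedule: TaskSchedule,
    rec: PupilRecording,
    variant: str = "pooled",
    frame_times: np.ndarray | None = None,
    nuisance: pd.DataFrame | None = None,
    hrf: Hrf | None = None,
) -> DesignMatrix:
    """Pupil-change GLM in one of four variants.

    pooled
        one regressor of 1-s events (8 x 40 bins) modulated by the
        per-bin mean pupil change;
    per_condition
        four such regressor pairs, split by condition;
    block_mean
        blockwise regressor modulated by the per-block mean pupil
        change (one value per block);
    demeaned_per_condition
        per-condition regressors whose modulator has each block's mean
        subtracted bin-wise, removing all between-block mean
        differences.
    """
    if variant not in CHANGE_VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; expected one of {CHANGE_VARIANTS}")
    if frame_times is None:
        frame_times = default_frame_times()
    bins = change_bins_per_block(schedule, rec)

    if variant == "block_mean":
        grp = bins.groupby("block_index")["change"].mean()
        onsets = np.array([b.onset for b in schedule.blocks])
        durations = np.full(len(onsets), schedule.blocks[0].duration)
        main, mod = build_modulated_regressor(
            onsets, durations, grp.to_numpy(), frame_times, hrf)
        return _assemble(frame_times,
                         {"task_block": main, "task_block_x_change_mean": mod},
                         modulated=("task_block_x_change_mean",), nuisance=nuisance)

    if variant == "pooled":
        main, mod = build_modulated_regressor(
            bins["onset"].to_numpy(), 1.0, bins["change"].to_numpy(), frame_times, hrf)
        return _assemble(frame_times,
                         {"task_bins": main, "task_bins_x_change": mod},
                         modulated=("task_bins_x_change",), nuisance=nuisance)

    # condition-split variants
    if variant == "demeaned_per_condition":
        bins = bins.copy()
        bins["change"] = bins["change"] - bins.groupby("block_index")["change"].transform("mean")
    cols: dict[str, np.ndarray] = {}
    modulated = []
    for cond, grp in bins.groupby("condition", sort=False):
        tag = cond.replace("-", "")
        main, mod = build_modulated_regressor(
            grp["onset"].to_numpy(), 1.0, grp["change"].to_numpy(), frame_times, hrf)
        cols[f"task_{tag}"] = main
        cols[f"task_{tag}_x_change"] = mod
        modulated.append(f"task_{tag}_x_change")
    return _assemble(frame_times, cols, modulated=tuple(modulated), nuisance=nuisance)


def build_trialpeak_glm(
    schedule: TaskSchedule,
    features: pd.DataFrame,
    frame_times: np.ndarray | None = None,
    nuisance: pd.DataFrame | None = None,
    hrf: Hrf | None = None,
    include_fixation: bool = True,
) -> DesignMatrix:
    """Single trial regressor (2.5-s events) modulated by peak amplitude."""
    if frame_times is None:
        frame_times = default_frame_times()
    trials = [(b, j, tr) for b, j, tr in schedule.trials()
              if include_fixation or tr.condition.is_active]
    feat = features.set_index(["block_index", "trial_index"])
    onsets, amps = [], []
    for b, j, trial in trials:
        try:
            amp = feat.loc[(b, j), "peak_amplitude"]
        except KeyError:
            raise ValueError(f"missing peak feature for block {b} trial {j}")
        if not np.isfinite(amp):
            raise ValueError(f"non-finite peak feature for block {b} trial {j}")
        onsets.append(trial.onset)
        amps.append(float(amp))
    main, mod = build_modulated_regressor(
        np.array(onsets), trials[0][2].trial_duration, np.array(amps), frame_times, hrf)
    return _assemble(frame_times,
                     {"task_trials": main, "task_trials_x_peak": mod},
                     modulated=("task_trials_x_peak",), nuisance=nuisance)


def compute_dvars(bold: BoldDataset, brain_mask: np.ndarray | None = None):
    """DVARS series and outlier dummy matrix over the kept volumes.

    DVARS_i is the root-mean-squared intensity difference between
    volumes i and i-1 over in-brain voxels (DVARS_0 = 0).  Volumes whose
    DVARS exceeds Q3 + 1.5 x IQR of the DVARS distribution are flagged,
    one 0/1 indicator column per flagged volume (the latter volume of
    each differenced pair).
    """
    data = bold.kept()
    if data.shape[-1] < 2:
        raise ValueError("DVARS requires at least 2 volumes")
    flat = data.reshape(-1, data.shape[-1])
    if brain_mask is not None:
        flat = flat[brain_mask.reshape(-1)]
    diffs = np.diff(flat, axis=1)
    dvars = np.concatenate([[0.0], np.sqrt(np.mean(diffs ** 2, axis=0))])
    q1, q3 = np.percentile(dvars[1:], [25, 75])
    thr = q3 + 1.5 * (q3 - q1)
    flagged = np.flatnonzero(dvars > thr)
    dummies = pd.DataFrame(
        {f"dvars_outlier_{v}": (np.arange(len(dvars)) == v).astype(float) for v in flagged}
    )
    if dummies.empty:
        dummies = pd.DataFrame(index=range(len(dvars)))
    return dvars, dummies


def compute_compcor(bold: BoldDataset, wm_mask: np.ndarray, csf_mask: np.ndarray,
                    n_components: int = 5) -> pd.DataFrame:
    """aCompCor nuisance components from the combined WM+CSF mask.

    Principal component time courses (unit variance) of the temporally
    demeaned voxel x time matrix, by SVD.  Returns fewer components with
    a warning if the mask has fewer voxels than requested.
    """
    mask = wm_mask | csf_mask
    if not mask.any():
        raise ValueError("empty WM/CSF mask")
    data = bold.kept().reshape(-1, bold.n_volumes - bold.discard)[mask.reshape(-1)]
    X = (data - data.mean(axis=1, keepdims=True)).T  # time x voxel
    k = min(n_components, X.shape[1], X.shape[0])
    if k < n_components:
        warnings.warn(f"only {k} aCompCor components available (requested {n_components})")
    u, s, _ = np.linalg.svd(X, full_matrices=False)
    comps = u[:, :k]
    sd = comps.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    comps = comps / sd
    return pd.DataFrame({f"compcor_{i + 1}": comps[:, i] for i in range(k)})


def assemble_nuisance(motion: pd.DataFrame, dvars_dummies: pd.DataFrame,
                      compcor: pd.DataFrame) -> pd.DataFrame:
    """12 motion columns (6 + backward-difference derivatives, first
    element 0) + DVARS outlier dummies + aCompCor components."""
    if motion.shape[1] != 6:
        raise ValueError("expected 6 motion parameter columns")
    n = len(motion)
    for other, name in ((dvars_dummies, "DVARS dummies"), (compcor, "compcor")):
        if len(other) not in (0, n):
            raise ValueError(f"{name} length {len(other)} does not match motion length {n}")
    out = motion.reset_index(drop=True).copy()
    for col in motion.columns:
        d = np.diff(motion[col].to_numpy(), prepend=motion[col].iloc[0])
        out[f"{col}_deriv"] = d
    for df in (dvars_dummies, compcor):
        for col in df.columns:
            out[col] = df[col].to_numpy()
    return out
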