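"""Pupil preprocessing: blink interpolation, smoothing, z-transform, QC,
derivative, downsampling, and trial-wise peak extraction.

The preprocessing order is fixed: blink interpolation first, then a
200-ms sliding-window mean, then a whole-recording z-transform.  Pupil
change (the first-order derivative) and any downsampling act on the
z-scored trace.  QC excludes a subject when any block has more than 20%
interpolated samples or more than 20% of gaze samples outside a cutoff
window of 3.3 reference SDs around the subject's median gaze position.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .task import TaskSchedule, Trial

#: cohort-level gaze dispersion references (screen units)
DEFAULT_GAZE_SD_X = 105.34
DEFAULT_GAZE_SD_Y = 91.40
GAZE_SD_MULTIPLIER = 3.3
MISSING_FRACTION_MAX = 0.20
GAZE_OUTSIDE_FRACTION_MAX = 0.20

#: trial-wise peak search window and baseline window (s relative to onset)
PEAK_WINDOW = (1.0, 2.5)
BASELINE_WINDOW = (0.0, 0.5)


@dataclass(frozen=True)
class PupilRecording:
    """Continuous pupil/gaze samples with blink and saccade annotations.

    ``pupil`` is in arbitrary (or z) units and may contain NaN during
    blinks.  ``blinks`` and ``saccades`` are (start, end) intervals in
    seconds; saccade markers are taken as given (vendor software).
    """

    t: np.ndarray
    pupil: np.ndarray
    gaze_x: np.ndarray
    gaze_y: np.ndarray
    sample_rate: float
    blinks: tuple[tuple[float, float], ...] = ()
    saccades: tuple[tuple[float, float], ...] = ()

    def __post_init__(self):
        for name in ("t", "pupil", "gaze_x", "gaze_y"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if not (len(self.t) == len(self.pupil) == len(self.gaze_x) == len(self.gaze_y)):
            raise ValueError("sample streams must have equal length")

    @property
    def n_samples(self) -> int:
        return len(self.t)

    def to_frame(self) -> pd.DataFrame:
        blink_flag = _interval_flags(self.t, self.blinks)
        saccade_flag = _interval_flags(self.t, self.saccades)
        return pd.DataFrame({
            "time": self.t, "pupil": self.pupil,
            "gaze_x": self.gaze_x, "gaze_y": self.gaze_y,
            "blink_flag": blink_flag.astype(int),
            "saccade_flag": saccade_flag.astype(int),
        })

    @classmethod
    def from_frame(cls, df: pd.DataFrame, sample_rate: float) -> "PupilRecording":
        t = df["time"].to_numpy(float)
        return cls(
            t=t, pupil=df["pupil"].to_numpy(float),
            gaze_x=df["gaze_x"].to_numpy(float), gaze_y=df["gaze_y"].to_numpy(float),
            sample_rate=sample_rate,
            blinks=_flags_to_intervals(t, df["blink_flag"].to_numpy(bool), sample_rate),
            saccades=_flags_to_intervals(t, df["saccade_flag"].to_numpy(bool), sample_rate),
        )


def _interval_flags(t: np.ndarray, intervals) -> np.ndarray:
    flags = np.zeros(len(t), dtype=bool)
    for s, e in intervals:
        flags[(t >= s - 1e-9) & (t < e - 1e-9)] = True
    return flags


def _flags_to_intervals(t, flags, rate):
    edges = np.flatnonzero(np.diff(np.concatenate([[0], flags.view(np.int8), [0]])))
    out = []
    for i in range(0, len(edges), 2):
        out.append((float(t[edges[i]]), float(t[edges[i + 1] - 1] + 1.0 / rate)))
    return tuple(out)


@dataclass(frozen=True)
class QcReport:
    """Per-block data-quality fractions and the subject-level pass flag."""

    per_block: pd.DataFrame
    gaze_center: tuple[float, float]
    cutoff_half_widths: tuple[float, float]
    missing_fraction_max: float
    gaze_outside_fraction_max: float

    @property
    def passed(self) -> bool:
        return bool(
            (self.per_block["missing_fraction"] <= self.missing_fraction_max).all()
            and (self.per_block["gaze_outside_fraction"] <= self.gaze_outside_fraction_max).all()
        )

    def to_dict(self) -> dict:
        return {
            "passed": self.passed,
            "gaze_center": list(self.gaze_center),
            "cutoff_half_widths": list(self.cutoff_half_widths),
            "missing_fraction_max": self.missing_fraction_max,
            "gaze_outside_fraction_max": self.gaze_outside_fraction_max,
            "per_block": self.per_block.to_dict(orient="records"),
        }


def interpolate_blinks(rec: PupilRecording) -> tuple[PupilRecording, np.ndarray, list[str]]:
    """Linearly interpolate blink gaps between saccade anchor samples.

    For each blink, pupil values between the last sample of the saccade
    preceding blink onset and the first sample of the saccade following
    blink offset are replaced by linear interpolation between the anchor
    values.  A blink without a saccade anchor on one side falls back to
    the nearest valid sample (recorded in the returned log); a blink at
    the recording edge is filled with the nearest valid value.

    Returns the interpolated recording, a boolean mask of replaced
    samples, and a list of fallback log messages.
    """
    pupil = rec.pupil.copy()
    mask = np.zeros(rec.n_samples, dtype=bool)
    log: list[str] = []
    n = rec.n_samples
    tol = 0.5 / rec.sample_rate

    sacc = sorted(rec.saccades)
    sacc_start_idx = [int(np.searchsorted(rec.t, s - tol)) for s, _ in sacc]
    sacc_end_idx = [int(np.searchsorted(rec.t, e - tol)) - 1 for _, e in sacc]

    for b0, b1 in sorted(rec.blinks):
        g0 = int(np.searchsorted(rec.t, b0 - tol))
        g1 = int(np.searchsorted(rec.t, b1 - tol))  # gap is [g0, g1)
        # left anchor: last sample of the last saccade ending at/before blink onset
        ai = None
        for k in range(len(sacc) - 1, -1, -1):
            if sacc[k][1] <= b0 + tol:
                ai = sacc_end_idx[k]
                break
        if ai is None or ai < 0 or not np.isfinite(pupil[ai]):
            valid = np.flatnonzero(np.isfinite(pupil[:g0]))
            ai = int(valid[-1]) if valid.size else None
            log.append(f"blink at {b0:.3f}s: no left saccade anchor, using nearest valid sample")
        # right anchor: first sample of the first saccade starting at/after blink offset
        aj = None
        for k in range(len(sacc)):
            if sacc[k][0] >= b1 - tol:
                aj = sacc_start_idx[k]
                break
        if aj is None or aj >= n or not np.isfinite(pupil[aj]):
            valid = np.flatnonzero(np.isfinite(pupil[g1:]))
            aj = int(g1 + valid[0]) if valid.size else None
            log.append(f"blink at {b0:.3f}s: no right saccade anchor, using nearest valid sample")

        if ai is None and aj is None:
            raise ValueError("recording has no valid samples to anchor blink interpolation")
        if ai is None:  # blink extends past recording start
            pupil[:aj] = pupil[aj]
            mask[:aj] = True
            log.append(f"blink at {b0:.3f}s: extends past recording start, edge-filled")
            continue
        if aj is None:  # blink extends past recording end
            pupil[ai + 1:] = pupil[ai]
            mask[ai + 1:] = True
            log.append(f"blink at {b0:.3f}s: extends past recording end, edge-filled")
            continue
        span = aj - ai
        if span > 1:
            w = np.arange(1, span) / span
            pupil[ai + 1:aj] = (1 - w) * pupil[ai] + w * pupil[aj]
            mask[ai + 1:aj] = True

    # safety net: any residual NaN outside declared blinks
    bad = ~np.isfinite(pupil)
    if bad.any():
        good = np.flatnonzero(~bad)
        pupil[bad] = np.interp(np.flatnonzero(bad), good, pupil[good])
        mask |= bad
    return replace(rec, pupil=pupil), mask, log


def _windowed_mean(x: np.ndarray, nw: int) -> np.ndarray:
    n = len(x)
    half_l = nw // 2
    half_r = nw - half_l
    c = np.concatenate([[0.0], np.cumsum(x)])
    idx = np.arange(n)
    lo = np.clip(idx - half_l, 0, n)
    hi = np.clip(idx + half_r, 0, n)
    return (c[hi] - c[lo]) / (hi - lo)


def smooth_sliding_mean(rec: PupilRecording, window: float = 0.2) -> PupilRecording:
    """Centered sliding-window mean (default 200 ms), truncated at edges."""
    if not np.all(np.isfinite(rec.pupil)):
        raise ValueError("smoothing requires a gap-free trace; interpolate blinks first")
    nw = int(round(window * rec.sample_rate))
    if nw < 2:
        warnings.warn("smoothing window shorter than 2 samples; returning input unchanged")
        return rec
    return replace(rec, pupil=_windowed_mean(rec.pupil, nw))


def ztransform(rec: PupilRecording) -> PupilRecording:
    """Z-score the pupil trace over the whole recording (population SD)."""
    x = rec.pupil
    if not np.all(np.isfinite(x)):
        raise ValueError("z-transform requires finite values")
    sd = float(np.std(x))
    if sd == 0.0:
        raise ValueError("zero-variance pupil trace cannot be z-transformed")
    return replace(rec, pupil=(x - np.mean(x)) / sd)


def preprocess(rec: PupilRecording, window: float = 0.2, zscore: bool = True):
    """Run the fixed pipeline: interpolate -> smooth -> z-transform.

    Returns (recording, interpolation mask, fallback log).
    """
    interp, mask, log = interpolate_blinks(rec)
    smoothed = smooth_sliding_mean(interp, window=window)
    return (ztransform(smoothed) if zscore else smoothed), mask, log


def qc_subject(
    rec: PupilRecording,
    schedule: TaskSchedule,
    mask: np.ndarray | None = None,
    sd_x: float = DEFAULT_GAZE_SD_X,
    sd_y: float = DEFAULT_GAZE_SD_Y,
    multiplier: float = GAZE_SD_MULTIPLIER,
    missing_fraction_max: float = MISSING_FRACTION_MAX,
    gaze_outside_fraction_max: float = GAZE_OUTSIDE_FRACTION_MAX,
    recompute_sds: bool = False,
) -> QcReport:
    """Per-block missing-data and gaze-excursion quality control.

    The gaze cutoff window is ``multiplier`` x the reference SDs around
    the subject's median gaze position.  Reference SDs default to
    cohort-level values; ``recompute_sds`` estimates them from this
    recording instead (for synthetic cohorts).  ``mask`` marks
    interpolated (blink-related missing) samples; if omitted, NaN
    samples of the raw trace are used.
    """
    if mask is None:
        mask = ~np.isfinite(rec.pupil)
    cx = float(np.median(rec.gaze_x))
    cy = float(np.median(rec.gaze_y))
    if recompute_sds:
        sd_x = float(np.std(rec.gaze_x))
        sd_y = float(np.std(rec.gaze_y))
    hx, hy = multiplier * sd_x, multiplier * sd_y
    outside = (np.abs(rec.gaze_x - cx) > hx) | (np.abs(rec.gaze_y - cy) > hy)
    rows = []
    for b, block in enumerate(schedule.blocks):
        sel = (rec.t >= block.onset) & (rec.t < block.end)
        n = int(sel.sum())
        rows.append({
            "block_index": b,
            "condition": block.condition.value,
            "missing_fraction": float(mask[sel].sum() / n) if n else 0.0,
            "gaze_outside_fraction": float(outside[sel].sum() / n) if n else 0.0,
        })
    return QcReport(
        per_block=pd.DataFrame(rows),
        gaze_center=(cx, cy),
        cutoff_half_widths=(hx, hy),
        missing_fraction_max=missing_fraction_max,
        gaze_outside_fraction_max=gaze_outside_fraction_max,
    )


def pupil_change(rec: PupilRecording, per_second: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """First-order derivative of pupil size.

    Returns (times, values) with length n-1, each difference timestamped
    at the latter sample.  Units are z per sample by default; set
    ``per_second`` to rescale to z/s.
    """
    d = np.diff(rec.pupil)
    if per_second:
        d = d * rec.sample_rate
    return rec.t[1:], d


def downsample(t: np.ndarray, x: np.ndarray, target_rate: float, sample_rate: float):
    """Non-overlapping bin means on the session clock.

    Bin *k* covers ``[k/target_rate, (k+1)/target_rate)`` and is
    timestamped at its start.  ``target_rate`` must divide
    ``sample_rate``; empty leading/trailing bins are dropped.
    """
    ratio = sample_rate / target_rate
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValueError(f"target rate {target_rate} does not divide sample rate {sample_rate}")
    bins = np.floor(np.asarray(t) * target_rate + 1e-9).astype(int)
    first = bins.min()
    counts = np.bincount(bins - first)
    sums = np.bincount(bins - first, weights=x)
    keep = counts > 0
    means = sums[keep] / counts[keep]
    starts = (np.flatnonzero(keep) + first) / target_rate
    return starts, means


def extract_trial_peak(
    rec: PupilRecording, trial: Trial, mask: np.ndarray | None = None
) -> dict:
    """Baseline, peak, and peak amplitude of one trial.

    baseline = mean pupil over [onset, onset+0.5) (stimulus window);
    peak = maximum over the search window [onset+1.0, onset+2.5) (after
    the stimulus and the light reflex); peak_amplitude = peak - baseline.
    A feature whose baseline or search window contains only interpolated
    samples is flagged low-confidence but still computed.
    """
    t, x = rec.t, rec.pupil
    b_sel = (t >= trial.onset + BASELINE_WINDOW[0] - 1e-9) & (t < trial.onset + BASELINE_WINDOW[1] - 1e-9)
    p_sel = (t >= trial.onset + PEAK_WINDOW[0] - 1e-9) & (t < trial.onset + PEAK_WINDOW[1] - 1e-9)
    if not b_sel.any() or not p_sel.any():
        raise ValueError("trial windows fall outside the recording")
    baseline = float(np.mean(x[b_sel]))
    peak = float(np.max(x[p_sel]))
    low_confidence = False
    if mask is not None:
        low_confidence = bool(mask[b_sel].all() or mask[p_sel].all())
    return {
        "baseline": baseline,
        "peak": peak,
        "peak_amplitude": peak - baseline,
        "low_confidence": low_confidence,
    }


def trial_features(
    rec: PupilRecording,
    schedule: TaskSchedule,
    mask: np.ndarray | None = None,
    mean_rate: float = 10.0,
) -> pd.DataFrame:
    """Per-trial pupil features: peak amplitude and 10-Hz trial mean.

    The trial mean is computed from the trace downsampled to
    ``mean_rate`` over the full 2.5-s trial.
    """
    starts, means = downsample(rec.t, rec.pupil, mean_rate, rec.sample_rate)
    rows = []
    for b, j, trial in schedule.trials():
        feat = extract_trial_peak(rec, trial, mask=mask)
        sel = (starts >= trial.onset - 1e-9) & (starts < trial.onset + trial.trial_duration - 1e-9)
        rows.append({
            "block_index": b, "trial_index": j,
            "condition": trial.condition.value, "is_target": trial.is_target,
            "onset": trial.onset, **feat,
            "trial_mean_pupil": float(np.mean(means[sel])),
        })
    return pd.DataFrame(rows)


def condition_means(rec: PupilRecording, schedule: TaskSchedule):
    """Per-block and per-condition mean pupil size.

    A block mean is the mean over [onset, onset+40); a condition mean is
    the mean of that condition's two block means.
    """
    rows = []
    for b, block in enumerate(schedule.blocks):
        sel = (rec.t >= block.onset - 1e-9) & (rec.t < block.end - 1e-9)
        rows.append({
            "block_index": b, "condition": block.condition.value,
            "mean_pupil": float(np.mean(rec.pupil[sel])),
        })
    block_means = pd.DataFrame(rows)
    cond_means = block_means.groupby("condition", sort=False)["mean_pupil"].mean()
    return block_means, cond_means
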