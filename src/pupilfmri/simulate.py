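"""Synthetic N-back session generator: pupil/gaze streams, button
presses, and BOLD volumes with planted network couplings.

The generator emulates the statistical structure the analyses assume:

* a load-dependent tonic pupil level per condition with target-evoked
  phasic dilations (gamma-shaped, peaking ~1.3 s after stimulus onset)
  whose default amplitudes follow the reported group means, a small
  stimulus-driven light-reflex dip, AR(1) noise, blinks inserted as
  missing-value gaps bracketed by synthetic saccades, and drifting gaze
  with occasional excursions;
* button presses with per-condition hit probability and truncated-normal
  reaction times;
* BOLD voxel time series built from the *true* pupil trace through the
  same design-construction code the analysis uses, so planted couplings
  are exactly recoverable in the noiseless limit, plus low-frequency
  drift, structured WM/CSF noise (for aCompCor to find), spike volumes
  (for DVARS), and correlated motion parameters.

Everything is bit-reproducible given (seed, config).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal as sps_signal
from scipy import stats as sps

from . import design as dsg
from .preprocess import PupilRecording
from .task import ACTIVE_CONDITIONS, ResponseLog, TaskSchedule

#: reported group-mean phasic peak amplitudes (z units), target / non-target
DEFAULT_TARGET_AMP = {"0-back": 0.72, "1-back": 0.66, "2-back": 0.57}
DEFAULT_NONTARGET_AMP = {"0-back": 0.13, "1-back": 0.26, "2-back": 0.34}
#: reported between-subject SDs of the same cells
DEFAULT_TARGET_AMP_SD = {"0-back": 0.36, "1-back": 0.33, "2-back": 0.33}
DEFAULT_NONTARGET_AMP_SD = {"0-back": 0.13, "1-back": 0.21, "2-back": 0.22}

#: reported per-condition behavioral parameters (RT in s)
DEFAULT_RT_MEAN = {"0-back": 0.400, "1-back": 0.432, "2-back": 0.498}
DEFAULT_RT_SD_BETWEEN = {"0-back": 0.045, "1-back": 0.087, "2-back": 0.082}
DEFAULT_ACCURACY = {"0-back": 0.980, "1-back": 0.970, "2-back": 0.929}
DEFAULT_ACCURACY_SD_BETWEEN = {"0-back": 0.037, "1-back": 0.034, "2-back": 0.066}

#: tonic pupil level per condition (z units); ordering matches the
#: reported load effect, values themselves are generator choices
DEFAULT_TONIC = {"fixation": -0.5, "0-back": -0.2, "1-back": 0.1, "2-back": 0.5}

SESSION_DURATION = (dsg.N_VOLUMES - dsg.N_DISCARD) * dsg.TR  # 430 s


@dataclass(frozen=True)
class PupilGenConfig:
    """Parameters of the pupil/gaze generator (one subject)."""

    sample_rate: float = 250.0
    duration: float = SESSION_DURATION
    tonic_mean: dict = field(default_factory=lambda: dict(DEFAULT_TONIC))
    baseline_level: float = -0.5
    phasic_target_amp: dict = field(default_factory=lambda: dict(DEFAULT_TARGET_AMP))
    phasic_nontarget_amp: dict = field(default_factory=lambda: dict(DEFAULT_NONTARGET_AMP))
    phasic_peak_latency: float = 1.3  # s; inside the 1.0-2.5 s search window
    phasic_shape: float = 12.0  # gamma shape; larger = more compact response
    light_reflex_amp: float = 0.15
    light_reflex_latency: float = 0.3
    light_reflex_peak: float = 0.35  # s after latency
    light_reflex_shape: float = 8.0
    tonic_ramp: dict = field(default_factory=dict)  # z-units gained over a block
    blink_rate: float = 15.0  # per minute
    blink_duration_range: tuple = (0.1, 0.4)
    saccade_duration: float = 0.04
    noise_ar1_coeff: float = 0.97  # at 250 Hz
    noise_sd: float = 0.05  # marginal SD of the AR(1) noise (z units)
    gaze_center: tuple = (512.0, 384.0)
    gaze_drift_sd: float = 30.0
    gaze_excursion_rate: float = 2.0  # per minute
    gaze_excursion_duration: tuple = (0.5, 2.0)
    gaze_excursion_amp: tuple = (400.0, 800.0)
    seed: int = 0

    def __post_init__(self):
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if not 1.0 < self.phasic_peak_latency < 2.5:
            raise ValueError("phasic_peak_latency must lie inside the search window (1.0, 2.5) s")


@dataclass(frozen=True)
class BoldGenConfig:
    """Parameters of the BOLD generator (one subject)."""

    grid_shape: tuple = (12, 12, 6)
    tr: float = dsg.TR
    n_volumes: int = dsg.N_VOLUMES
    discard: int = dsg.N_DISCARD
    beta_size: float = 0.5      # FPN coupling to the pupil-size modulation
    beta_change: float = 0.5    # salience coupling to the pupil-change modulation
    beta_dmn: float = -0.5      # DMN (negative) coupling to the pupil-size modulation
    change_coupling: str = "pooled"  # which change variant salience couples to
    noise_sd: float = 1.0
    drift_amplitude: float = 0.5
    structured_noise_sd: float = 1.0
    n_structured: int = 3
    motion_magnitude: float = 0.3
    spike_prob: float = 0.02
    spike_amplitude: float = 6.0
    seed: int = 0

    def __post_init__(self):
        if self.n_volumes <= self.discard:
            raise ValueError("n_volumes must exceed the discard count")


@dataclass(frozen=True)
class SimulationTruth:
    """Planted ground truth for recovery tests."""

    pupil: dict | None = None
    behavior: dict | None = None
    bold: dict | None = None


def _unit_peak_gamma(t: np.ndarray, shape: float, peak: float) -> np.ndarray:
    """Gamma density on ``t`` rescaled to unit maximum, mode at ``peak``."""
    scale = peak / (shape - 1.0)
    k = sps.gamma.pdf(t, shape, scale=scale)
    return k / k.max()


def _ar1_noise(n: int, coeff: float, marginal_sd: float, rng: np.random.Generator) -> np.ndarray:
    if marginal_sd == 0:
        return np.zeros(n)
    innov_sd = marginal_sd * np.sqrt(1.0 - coeff ** 2)
    e = rng.normal(0.0, innov_sd, n)
    e[0] = rng.normal(0.0, marginal_sd)
    return sps_signal.lfilter([1.0], [1.0, -coeff], e)


def _draw_blinks(cfg: PupilGenConfig, rng: np.random.Generator):
    """Non-overlapping blink intervals with flanking saccade margins."""
    n_blinks = rng.poisson(cfg.blink_rate * cfg.duration / 60.0)
    starts = np.sort(rng.uniform(1.0, cfg.duration - 1.5, n_blinks))
    durations = rng.uniform(*cfg.blink_duration_range, n_blinks)
    blinks = []
    last_end = -np.inf
    margin = cfg.saccade_duration + 0.05
    for s, d in zip(starts, durations):
        if s - margin > last_end + margin:
            blinks.append((float(s), float(s + d)))
            last_end = s + d
    return blinks


def simulate_pupil(schedule: TaskSchedule, cfg: PupilGenConfig) -> tuple[PupilRecording, dict]:
    """Generate one subject's pupil/gaze recording plus ground truth.

    The trace is the sum of a condition-dependent tonic level, per-trial
    light-reflex dips, per-trial phasic dilations (amplitude by
    condition and target status), and AR(1) noise; blinks are inserted
    as NaN gaps bracketed by synthetic saccade markers.
    """
    rng = np.random.default_rng(cfg.seed)
    rate = cfg.sample_rate
    n = int(round(cfg.duration * rate))
    t = np.arange(n) / rate

    # tonic level (piecewise constant per block, optional within-block ramp)
    tonic = np.full(n, cfg.baseline_level)
    for block in schedule.blocks:
        sel = (t >= block.onset) & (t < block.end)
        level = cfg.tonic_mean[block.condition.value]
        tonic[sel] = level
        ramp = cfg.tonic_ramp.get(block.condition.value, 0.0)
        if ramp:
            tonic[sel] += ramp * (t[sel] - block.onset) / block.duration

    # per-trial kernels
    k_t = np.arange(0, 5.0, 1.0 / rate)
    phasic_kernel = _unit_peak_gamma(k_t, cfg.phasic_shape, cfg.phasic_peak_latency)
    lr_t = np.arange(0, 2.5, 1.0 / rate)
    lr_kernel = _unit_peak_gamma(lr_t, cfg.light_reflex_shape, cfg.light_reflex_peak)

    phasic = np.zeros(n)
    trial_amps = []
    for b, j, trial in schedule.trials():
        cond = trial.condition.value
        if trial.condition.is_active:
            amp = (cfg.phasic_target_amp if trial.is_target else cfg.phasic_nontarget_amp)[cond]
        else:
            amp = 0.0
        trial_amps.append({"block_index": b, "trial_index": j, "condition": cond,
                           "is_target": trial.is_target, "amplitude": amp})
        i0 = int(round(trial.onset * rate))
        if amp:
            seg = phasic_kernel[: n - i0]
            phasic[i0:i0 + len(seg)] += amp * seg
        if cfg.light_reflex_amp:
            i_lr = int(round((trial.onset + cfg.light_reflex_latency) * rate))
            if i_lr < n:
                seg = lr_kernel[: n - i_lr]
                phasic[i_lr:i_lr + len(seg)] -= cfg.light_reflex_amp * seg

    noise = _ar1_noise(n, cfg.noise_ar1_coeff, cfg.noise_sd, rng)
    clean = tonic + phasic
    trace = clean + noise

    # blinks: NaN gaps with saccade markers flanking each gap
    blinks = _draw_blinks(cfg, rng)
    pupil = trace.copy()
    gap_mask = np.zeros(n, dtype=bool)
    saccades = []
    for b0, b1 in blinks:
        g0, g1 = int(round(b0 * rate)), int(round(b1 * rate))
        pupil[g0:g1] = np.nan
        gap_mask[g0:g1] = True
        saccades.append((b0 - cfg.saccade_duration, b0))
        saccades.append((b1, b1 + cfg.saccade_duration))

    # gaze: slow drift around the center plus occasional excursions
    gx = cfg.gaze_center[0] + _ar1_noise(n, 0.999, cfg.gaze_drift_sd, rng)
    gy = cfg.gaze_center[1] + _ar1_noise(n, 0.999, cfg.gaze_drift_sd, rng)
    n_exc = rng.poisson(cfg.gaze_excursion_rate * cfg.duration / 60.0)
    exc_mask = np.zeros(n, dtype=bool)
    for _ in range(n_exc):
        s = rng.uniform(0, cfg.duration - cfg.gaze_excursion_duration[1])
        d = rng.uniform(*cfg.gaze_excursion_duration)
        amp = rng.uniform(*cfg.gaze_excursion_amp) * rng.choice([-1, 1])
        axis = rng.integers(2)
        i0, i1 = int(s * rate), int((s + d) * rate)
        (gx if axis == 0 else gy)[i0:i1] += amp
        exc_mask[i0:i1] = True

    rec = PupilRecording(t=t, pupil=pupil, gaze_x=gx, gaze_y=gy,
                         sample_rate=rate, blinks=tuple(blinks),
                         saccades=tuple(sorted(saccades)))
    truth = {
        "trace_nogaps": trace,
        "clean": clean,
        "tonic": tonic,
        "gap_mask": gap_mask,
        "gap_fraction": float(gap_mask.mean()),
        "gaze_excursion_mask": exc_mask,
        "trial_amplitudes": pd.DataFrame(trial_amps),
        "config": cfg,
    }
    return rec, truth


def sample_subject_pupil_config(base: PupilGenConfig, rng: np.random.Generator,
                                amp_subject_sd: float | dict | None = None) -> PupilGenConfig:
    """Per-subject phasic amplitudes: base means + Gaussian inter-subject
    variation, independent per condition x target-status cell.

    By default each cell uses its reported between-subject SD; a scalar
    or ``{(condition, is_target): sd}`` mapping overrides it.
    """
    def cell_sd(cond, is_target):
        if amp_subject_sd is None:
            return (DEFAULT_TARGET_AMP_SD if is_target else DEFAULT_NONTARGET_AMP_SD)[cond]
        if isinstance(amp_subject_sd, dict):
            return amp_subject_sd[(cond, is_target)]
        return float(amp_subject_sd)

    tgt = {c: m + rng.normal(0.0, cell_sd(c, True))
           for c, m in base.phasic_target_amp.items()}
    non = {c: m + rng.normal(0.0, cell_sd(c, False))
           for c, m in base.phasic_nontarget_amp.items()}
    return replace(base, phasic_target_amp=tgt, phasic_nontarget_amp=non,
                   seed=int(rng.integers(2 ** 31)))


def simulate_behavior(
    schedule: TaskSchedule,
    rt_means: dict | None = None,
    rt_sds: dict | float = 0.1,
    accuracy: dict | None = None,
    seed: int = 0,
) -> ResponseLog:
    """Generate button presses for one subject.

    On each target trial a hit occurs with the condition's accuracy and
    its RT is drawn from a normal truncated to the response window; on
    each non-target trial a false alarm occurs with probability
    1 - accuracy, so the expected accuracy over 4 targets and 12
    non-targets equals the configured value.
    """
    rt_means = rt_means or dict(DEFAULT_RT_MEAN)
    accuracy = accuracy or dict(DEFAULT_ACCURACY)
    if isinstance(rt_sds, (int, float)):
        rt_sds = {c: float(rt_sds) for c in rt_means}
    for a in accuracy.values():
        if not 0.0 <= a <= 1.0:
            raise ValueError("accuracy values must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    presses = []
    lo, hi = 0.05, 1.45  # inside the 1.5-s response window
    for _, _, trial in schedule.trials():
        if not trial.condition.is_active:
            continue
        cond = trial.condition.value
        p_press = accuracy[cond] if trial.is_target else 1.0 - accuracy[cond]
        if rng.random() < p_press:
            mu, sd = rt_means[cond], rt_sds[cond]
            if sd == 0:
                rt = float(np.clip(mu, lo, hi))
            else:
                a, b = (lo - mu) / sd, (hi - mu) / sd
                rt = float(sps.truncnorm.rvs(a, b, loc=mu, scale=sd, random_state=rng))
            presses.append(trial.onset + rt)
    return ResponseLog(presses=np.array(sorted(presses)))


def default_label_map(shape: tuple = (12, 12, 6)) -> np.ndarray:
    """Deterministic voxel-label layout: slabs along x for
    FPN / salience / DMN / WM / CSF, remainder null."""
    labels = np.zeros(shape, dtype=int)  # null
    nx = shape[0]
    slabs = {
        "FPN": (0, 2), "salience": (2, 4), "DMN": (4, 6),
        "WM": (6, 8), "CSF": (8, 9),
    }
    for name, (a, b) in slabs.items():
        labels[min(a, nx):min(b, nx)] = dsg.LABELS.index(name)
    return labels


def _coupling_columns(schedule: TaskSchedule, rec: PupilRecording,
                      frame_times: np.ndarray, variant: str) -> np.ndarray:
    """Modulated pupil-change column(s) for the requested variant,
    summed into a single coupling series."""
    dm = dsg.build_pupilchange_glm(schedule, rec, variant=variant,
                                   frame_times=frame_times)
    cols = [dm.matrix[c].to_numpy() for c in dm.modulated_columns]
    return np.sum(cols, axis=0)


def simulate_bold(
    schedule: TaskSchedule,
    rec: PupilRecording,
    cfg: BoldGenConfig,
    labels: np.ndarray | None = None,
) -> tuple[dsg.BoldDataset, dict, pd.DataFrame]:
    """Generate one subject's BOLD volumes, ground truth, and motion table.

    ``rec`` must be the gap-free true pupil trace (the generator's
    ``trace_nogaps``); voxel signal is planted on the *standardized*
    modulated regressors built by the design code from that trace, so a
    planted beta is a per-frame contrast-to-noise ratio.
    """
    if not np.all(np.isfinite(rec.pupil)):
        raise ValueError("simulate_bold requires a gap-free pupil trace")
    n_kept = cfg.n_volumes - cfg.discard
    frame_times = np.arange(n_kept) * cfg.tr
    if schedule.span > n_kept * cfg.tr + 1e-9:
        raise ValueError("schedule span exceeds n_volumes x tr after discards")
    if rec.t[-1] + 1.0 / rec.sample_rate < schedule.span - 1e-9:
        raise ValueError("pupil recording does not cover the session span")

    rng = np.random.default_rng(cfg.seed)
    labels = default_label_map(cfg.grid_shape) if labels is None else labels
    if labels.shape != tuple(cfg.grid_shape):
        raise ValueError("label map shape does not match grid shape")
    n_vox = int(np.prod(cfg.grid_shape))
    flat_labels = labels.reshape(-1)

    # coupling regressors built by the analysis code from the true trace
    size_dm = dsg.build_pupilsize_glm(schedule, rec, frame_times=frame_times)
    size_col = size_dm.matrix["task_block_x_pupil_size"].to_numpy()
    change_col = _coupling_columns(schedule, rec, frame_times, cfg.change_coupling)

    def standardize(col):
        sd = col.std()
        return (col / sd if sd > 0 else col), float(sd)

    size_z, size_scale = standardize(size_col)
    change_z, change_scale = standardize(change_col)

    beta_size_map = np.zeros(n_vox)
    beta_change_map = np.zeros(n_vox)
    beta_size_map[flat_labels == dsg.LABELS.index("FPN")] = cfg.beta_size
    beta_size_map[flat_labels == dsg.LABELS.index("DMN")] = cfg.beta_dmn
    beta_change_map[flat_labels == dsg.LABELS.index("salience")] = cfg.beta_change

    signal = np.outer(beta_size_map, size_z) + np.outer(beta_change_map, change_z)

    # low-frequency drift: per-voxel random-phase slow cosine
    periods = rng.uniform(100.0, 300.0, n_vox)
    phases = rng.uniform(0, 2 * np.pi, n_vox)
    drift = cfg.drift_amplitude * np.cos(
        2 * np.pi * frame_times[None, :] / periods[:, None] + phases[:, None])

    # shared structured noise in WM/CSF voxels (aCompCor target)
    tissue = np.isin(flat_labels, [dsg.LABELS.index("WM"), dsg.LABELS.index("CSF")])
    structured = np.zeros((n_vox, n_kept))
    latent = np.stack([_ar1_noise(n_kept, 0.9, 1.0, rng) for _ in range(cfg.n_structured)])
    loadings = np.zeros((n_vox, cfg.n_structured))
    loadings[tissue] = rng.normal(0.0, 1.0, (int(tissue.sum()), cfg.n_structured))
    structured = cfg.structured_noise_sd * loadings @ latent

    noise = rng.normal(0.0, cfg.noise_sd, (n_vox, n_kept))

    kept = signal + drift + structured + noise

    # spike volumes: global intensity jumps
    spikes = np.flatnonzero(rng.random(n_kept) < cfg.spike_prob)
    kept[:, spikes] += cfg.spike_amplitude * cfg.noise_sd

    # initial non-steady-state volumes (discarded downstream)
    dummy = (cfg.noise_sd * np.linspace(8, 2, cfg.discard)[None, :]
             + rng.normal(0.0, cfg.noise_sd, (n_vox, cfg.discard)))
    data = np.concatenate([dummy, kept], axis=1).reshape(*cfg.grid_shape, cfg.n_volumes)

    # motion: slow sinusoids + jitter, with jumps at spike volumes
    motion = {}
    for name in ("trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"):
        period = rng.uniform(60.0, 200.0)
        phase = rng.uniform(0, 2 * np.pi)
        series = (cfg.motion_magnitude * np.sin(2 * np.pi * frame_times / period + phase)
                  + rng.normal(0.0, 0.02, n_kept))
        motion[name] = series
    for name in ("trans_x", "trans_y", "trans_z"):
        motion[name][spikes] += 2.0 * cfg.motion_magnitude
    motion_df = pd.DataFrame(motion)

    truth = {
        "beta_size_map": beta_size_map.reshape(cfg.grid_shape),
        "beta_change_map": beta_change_map.reshape(cfg.grid_shape),
        "size_col_scale": size_scale,
        "change_col_scale": change_scale,
        "spike_volumes": spikes,
        "labels": labels,
        "change_coupling": cfg.change_coupling,
        "config": cfg,
    }
    bold = dsg.BoldDataset(data=data, tr=cfg.tr, labels=labels, discard=cfg.discard)
    return bold, truth, motion_df


def simulate_subject(
    schedule: TaskSchedule,
    pupil_cfg: PupilGenConfig,
    bold_cfg: BoldGenConfig | None = None,
    rt_means: dict | None = None,
    rt_sds: dict | float = 0.1,
    accuracy: dict | None = None,
):
    """Generate everything for one subject.

    Returns (pupil recording, response log, bold dataset or None,
    motion table or None, SimulationTruth).  BOLD coupling uses the
    gap-free true trace, as the generator contract requires.
    """
    rec, pupil_truth = simulate_pupil(schedule, pupil_cfg)
    log = simulate_behavior(schedule, rt_means=rt_means, rt_sds=rt_sds,
                            accuracy=accuracy, seed=pupil_cfg.seed + 1)
    behavior_truth = {"rt_means": rt_means or dict(DEFAULT_RT_MEAN),
                      "accuracy": accuracy or dict(DEFAULT_ACCURACY)}
    bold = motion = bold_truth = None
    if bold_cfg is not None:
        clean_rec = replace(rec, pupil=pupil_truth["trace_nogaps"])
        bold, bold_truth, motion = simulate_bold(schedule, clean_rec, bold_cfg)
    truth = SimulationTruth(pupil=pupil_truth, behavior=behavior_truth, bold=bold_truth)
    return rec, log, bold, motion, truth
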