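"""End-to-end pipeline: simulate -> preprocess -> behavior -> design ->
fit -> group, with file-based stage contracts.

Each stage consumes only files written by earlier stages, so any stage
can be re-run (or fail loudly if its inputs are missing).  Subjects
failing pupil QC are excluded from the imaging stages and listed in
``qc_summary.json``, never silently dropped.  Every run directory
carries provenance (config hash, seed, package version); re-running the
same configuration reproduces byte-identical numeric outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import design as dsg
from . import inference as inf
from . import io as pio
from .preprocess import (
    PupilRecording,
    condition_means,
    preprocess as preprocess_pupil,
    qc_subject,
    trial_features,
)
from . import simulate as sim
from . import stats
from . import task as tsk
from .config import RunConfig

STAGES = ("simulate", "preprocess", "behavior", "design", "fit", "group")

#: design variants fitted per subject
VARIANTS = ("size", "change_pooled", "change_block_mean", "change_demeaned", "trialpeak")

_CHANGE_VARIANT_NAME = {
    "change_pooled": "pooled",
    "change_block_mean": "block_mean",
    "change_demeaned": "demeaned_per_condition",
}


@dataclass
class RunResult:
    out_dir: Path
    stages_run: list
    excluded: list

    @property
    def exit_code(self) -> int:
        return 2 if self.excluded else 0


def _sub_dir(out: Path, s: int) -> Path:
    d = out / f"sub-{s:02d}"
    d.mkdir(parents=True, exist_ok=True)
    return d


def _subjects(config: RunConfig):
    return list(range(config.n_subjects))


def _subject_seeds(config: RunConfig, s: int) -> np.ndarray:
    ss = np.random.SeedSequence([config.seed, s])
    return ss.generate_state(4) % (2 ** 31)


def _included_subjects(config: RunConfig, out: Path):
    qc = pio.read_json(out / "qc_summary.json")
    return [int(s) for s in qc["included"]]


def stage_simulate(config: RunConfig, out: Path) -> None:
    for s in _subjects(config):
        seeds = _subject_seeds(config, s)
        rng = np.random.default_rng(seeds[0])
        schedule = tsk.build_schedule(int(seeds[1]))
        pupil_cfg = sim.sample_subject_pupil_config(
            replace(config.pupil, seed=int(seeds[2])), rng,
            amp_subject_sd=config.amp_subject_sd)
        beh = config.behavior
        rt_means = {c: float(rng.normal(m, beh.rt_sds_between[c]))
                    for c, m in beh.rt_means.items()}
        accuracy = {c: float(np.clip(rng.normal(a, beh.accuracy_sds_between[c]), 0.0, 1.0))
                    for c, a in beh.accuracy.items()}
        bold_cfg = replace(config.bold, seed=int(seeds[3]))
        rec, log, bold, motion, truth = sim.simulate_subject(
            schedule, pupil_cfg, bold_cfg,
            rt_means=rt_means, rt_sds=beh.trial_rt_sd, accuracy=accuracy)
        d = _sub_dir(out, s)
        pio.write_events(schedule, d / "events.tsv")
        pio.write_tsv(rec.to_frame(), d / "pupil.tsv")
        pio.write_presses(log, d / "presses.tsv")
        pio.write_tsv(motion, d / "motion.tsv")
        pio.save_bold(bold, d / "bold.nii")
        pio.save_labels(truth.bold["labels"], d / "labels.nii", d / "labels.json")
        pio.save_map(truth.bold["beta_size_map"], d / "truth_beta_size.nii")
        pio.save_map(truth.bold["beta_change_map"], d / "truth_beta_change.nii")
        pio.write_json({
            "subject": s,
            "gap_fraction": truth.pupil["gap_fraction"],
            "rt_means": rt_means,
            "accuracy": accuracy,
            "phasic_target_amp": pupil_cfg.phasic_target_amp,
            "phasic_nontarget_amp": pupil_cfg.phasic_nontarget_amp,
            "size_col_scale": truth.bold["size_col_scale"],
            "change_col_scale": truth.bold["change_col_scale"],
            "spike_volumes": truth.bold["spike_volumes"],
        }, d / "truth.json")


def stage_preprocess(config: RunConfig, out: Path) -> None:
    included, excluded = [], []
    for s in _subjects(config):
        d = _sub_dir(out, s)
        rec = PupilRecording.from_frame(
            pio.read_tsv(d / "pupil.tsv"), config.preprocess.sample_rate)
        schedule = pio.schedule_from_events(pio.read_tsv(d / "events.tsv"))
        proc, mask, log = preprocess_pupil(rec, window=config.preprocess.smooth_window)
        qc = qc_subject(
            rec, schedule, mask=mask,
            sd_x=config.qc.sd_x, sd_y=config.qc.sd_y,
            multiplier=config.qc.gaze_sd_multiplier,
            missing_fraction_max=config.qc.missing_fraction_max,
            gaze_outside_fraction_max=config.qc.gaze_outside_fraction_max)
        pio.write_tsv(
            pd.DataFrame({"time": proc.t, "pupil": proc.pupil,
                          "interpolated": mask.astype(int)}),
            d / "preproc_pupil.tsv")
        pio.write_json({**qc.to_dict(), "interpolation_log": log}, d / "qc.json")
        features = trial_features(proc, schedule, mask=mask,
                                       mean_rate=config.preprocess.trial_mean_rate)
        pio.write_tsv(features, d / "features.tsv")
        block_means, _ = condition_means(proc, schedule)
        pio.write_tsv(block_means, d / "block_means.tsv")
        (included if qc.passed else excluded).append(s)
    pio.write_json({"included": included, "excluded": excluded}, out / "qc_summary.json")


def stage_behavior(config: RunConfig, out: Path) -> None:
    summaries = []
    for s in _subjects(config):
        d = _sub_dir(out, s)
        schedule = pio.schedule_from_events(pio.read_tsv(d / "events.tsv"))
        log = pio.read_presses(d / "presses.tsv")
        outcomes = tsk.score_responses(schedule, log)
        pio.write_tsv(outcomes, d / "outcomes.tsv")
        summary = tsk.summarize_behavior(outcomes)
        pio.write_tsv(summary, d / "behavior_summary.tsv")
        summary = summary.assign(subject=s)
        summaries.append(summary)
    all_sum = pd.concat(summaries, ignore_index=True)
    group: dict = {"n_subjects": config.n_subjects}
    for measure in ("mean_rt", "accuracy"):
        wide = all_sum.pivot(index="subject", columns="condition", values=measure)
        wide = wide.dropna()
        if len(wide) >= 3:
            group[f"rm_anova_{measure}"] = stats.rm_anova(wide).to_dict()
    # pooled trial-wise pupil-RT correlation over preprocessed subjects
    try:
        included = _included_subjects(config, out)
    except FileNotFoundError:
        included = []
    feats, outs = [], []
    for s in included:
        d = _sub_dir(out, s)
        f = d / "features.tsv"
        if f.exists():
            feats.append(pio.read_tsv(f).assign(subject=s))
            outs.append(pio.read_tsv(d / "outcomes.tsv").assign(subject=s))
    if feats:
        try:
            group["pupil_rt_correlation"] = stats.pupil_rt_correlation(
                pd.concat(feats, ignore_index=True), pd.concat(outs, ignore_index=True))
        except ValueError as err:
            group["pupil_rt_correlation"] = {"error": str(err)}
    pio.write_json(group, out / "behavior_group.json")


def _load_preproc_recording(config: RunConfig, d: Path) -> PupilRecording:
    df = pio.read_tsv(d / "preproc_pupil.tsv")
    z = np.zeros(len(df))
    return PupilRecording(t=df["time"].to_numpy(float),
                               pupil=df["pupil"].to_numpy(float),
                               gaze_x=z, gaze_y=z,
                               sample_rate=config.preprocess.sample_rate)


def stage_design(config: RunConfig, out: Path) -> None:
    frame_times = np.arange(config.design.n_volumes - config.design.discard) * config.design.tr
    hrf = dsg.Hrf()
    for s in _included_subjects(config, out):
        d = _sub_dir(out, s)
        schedule = pio.schedule_from_events(pio.read_tsv(d / "events.tsv"))
        rec = _load_preproc_recording(config, d)
        labels = pio.load_labels(d / "labels.nii")
        bold = pio.load_bold(d / "bold.nii", labels=labels, discard=config.design.discard)
        motion = pio.read_tsv(d / "motion.tsv")
        _, dummies = dsg.compute_dvars(bold)
        compcor = dsg.compute_compcor(bold, bold.label_mask("WM"), bold.label_mask("CSF"))
        nuisance = dsg.assemble_nuisance(motion, dummies, compcor)
        pio.write_tsv(nuisance, d / "nuisance.tsv")
        features = pio.read_tsv(d / "features.tsv")
        for variant in VARIANTS:
            if variant == "size":
                dm = dsg.build_pupilsize_glm(schedule, rec, frame_times=frame_times,
                                             nuisance=nuisance, hrf=hrf)
            elif variant == "trialpeak":
                dm = dsg.build_trialpeak_glm(schedule, features, frame_times=frame_times,
                                             nuisance=nuisance, hrf=hrf)
            else:
                dm = dsg.build_pupilchange_glm(
                    schedule, rec, variant=_CHANGE_VARIANT_NAME[variant],
                    frame_times=frame_times, nuisance=nuisance, hrf=hrf)
            mat = dm.matrix.copy()
            pio.write_tsv(mat, d / f"design_{variant}.tsv")
            pio.write_json({"modulated_columns": list(dm.modulated_columns)},
                           d / f"design_{variant}.json")


def stage_fit(config: RunConfig, out: Path) -> None:
    for s in _included_subjects(config, out):
        d = _sub_dir(out, s)
        labels = pio.load_labels(d / "labels.nii")
        bold = pio.load_bold(d / "bold.nii", labels=labels, discard=config.design.discard)
        frame_times = bold.frame_times()
        for variant in VARIANTS:
            mat = pio.read_tsv(d / f"design_{variant}.tsv")
            meta = pio.read_json(d / f"design_{variant}.json")
            dm = dsg.DesignMatrix(frame_times=frame_times, matrix=mat,
                                  modulated_columns=tuple(meta["modulated_columns"]))
            fit = inf.fit_first_level(bold, dm)
            for col in dm.modulated_columns:
                pio.save_map(fit.contrast(col), d / f"contrast_{variant}__{col}.nii")
            pio.write_json({"dof": fit.dof}, d / f"fit_{variant}.json")


def stage_group(config: RunConfig, out: Path) -> None:
    included = _included_subjects(config, out)
    gdir = out / "group"
    gdir.mkdir(parents=True, exist_ok=True)
    if len(included) < 3:
        pio.write_json({"error": "fewer than 3 QC-passed subjects"}, gdir / "summary.json")
        return
    labels = pio.load_labels(_sub_dir(out, included[0]) / "labels.nii")
    summary: dict = {"n_subjects": len(included), "subjects": included}
    demeaned_t_maps = []
    for variant in VARIANTS:
        meta = pio.read_json(_sub_dir(out, included[0]) / f"design_{variant}.json")
        summary[variant] = {}
        for col in meta["modulated_columns"]:
            maps = np.stack([
                pio.load_map(_sub_dir(out, s) / f"contrast_{variant}__{col}.nii")
                for s in included])
            res = {}
            for sign, name in ((+1, "pos"), (-1, "neg")):
                grp = inf.second_level_onesample(sign * maps)
                if sign > 0:
                    pio.save_map(grp.t, gdir / f"{variant}__{col}__t.nii")
                    pio.save_map(grp.d, gdir / f"{variant}__{col}__d.nii")
                    pio.save_map(grp.logbf, gdir / f"{variant}__{col}__logbf.nii")
                res[name] = {
                    f"d>={dmin}": inf.mask_counts(
                        grp.threshold_mask(dmin, config.inference.logbf_min),
                        labels, dsg.LABELS)
                    for dmin in config.inference.d_thresholds
                }
            summary[variant][col] = res
            if variant == "change_demeaned" and "fixation" not in col:
                grp = inf.second_level_onesample(maps)
                demeaned_t_maps.append(grp.t)
    if len(demeaned_t_maps) >= 2:
        mn = inf.conjunction(demeaned_t_maps)
        pio.save_map(mn, gdir / "conjunction_change_demeaned.nii")
    pio.write_json(summary, gdir / "summary.json")


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "preprocess": stage_preprocess,
    "behavior": stage_behavior,
    "design": stage_design,
    "fit": stage_fit,
    "group": stage_group,
}


def run_pipeline(config: RunConfig, out_dir, stages=None) -> RunResult:
    """Execute the selected stages in canonical order.

    Later stages fail loudly (missing-file errors) if their inputs were
    never produced.  Returns a RunResult whose ``exit_code`` is 2 when
    the run completed but QC excluded subjects, 0 otherwise.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if stages is None:
        stages = list(STAGES)
    else:
        unknown = set(stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        stages = [s for s in STAGES if s in set(stages)]
    config.to_yaml(out / "config.yaml")
    pio.write_json({"config_hash": config.hash(), "seed": config.seed,
                    "version": __version__, "stages": stages},
                   out / "provenance.json")
    for stage in stages:
        _STAGE_FUNCS[stage](config, out)
    excluded = []
    qc_path = out / "qc_summary.json"
    if qc_path.exists():
        excluded = pio.read_json(qc_path)["excluded"]
    return RunResult(out_dir=out, stages_run=stages, excluded=excluded)
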