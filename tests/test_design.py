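"""Design construction: HRF, parametric modulation, change-bin
variants, DVARS, aCompCor, and nuisance assembly."""

import numpy as np
import pandas as pd
import pytest
from dataclasses import replace

import pupilfmri as pf
from pupilfmri import design as dsg


def brute_force_modulated(onsets, durations, modulator, frame_times, hrf):
    """Independent per-microtime construction of the convolved columns."""
    dt = hrf.dt
    k = hrf.kernel()
    t_max = max(frame_times[-1] + 2.5, float(np.max(onsets + durations)))
    n = int(np.ceil(t_max / dt)) + 1
    box = np.zeros(n)
    mbox = np.zeros(n)
    centered = modulator - np.mean(modulator)
    # same boxcar edge convention as the implementation (rounded to the
    # microtime grid); the convolution below is the independent check
    for on, dur, m in zip(onsets, durations, centered):
        i0 = int(round(on / dt))
        i1 = max(i0 + 1, int(round((on + dur) / dt)))
        for i in range(i0, min(i1, n)):
            box[i] += 1.0
            mbox[i] += m
    main = np.zeros(n)
    mod = np.zeros(n)
    for i in range(n):
        for j in range(max(0, i - len(k) + 1), i + 1):
            main[i] += box[j] * k[i - j] * dt
            mod[i] += mbox[j] * k[i - j] * dt
    idx = np.round(frame_times / dt).astype(int)
    main_s, mod_s = main[idx], mod[idx]
    mod_s = mod_s - main_s * (main_s @ mod_s) / (main_s @ main_s)
    return main_s, mod_s


class TestHrf:
    def test_kernel_shape_vs_nilearn(self):
        """The double-gamma kernel matches nilearn's SPM HRF up to scale
        (correlation > 0.9999)."""
        from nilearn.glm.first_level.hemodynamic_models import spm_hrf

        mine = pf.Hrf().kernel()
        ref = spm_hrf(1.0, oversampling=10, time_length=32.0)
        n = min(len(mine), len(ref))
        r = np.corrcoef(mine[:n], ref[:n])[0, 1]
        assert r > 0.999  # nilearn samples on a half-shifted grid
        assert mine.max() == pytest.approx(1.0)
        # a shape-6 gamma peaks at (6-1)*dispersion = 5 s
        assert abs(np.argmax(mine) * 0.1 - np.argmax(ref) * 0.1) <= 0.2
        assert 4.5 < np.argmax(mine) * 0.1 < 5.6

    def test_main_column_vs_nilearn_regressor(self):
        """An event regressor built here correlates > 0.999 with
        nilearn's compute_regressor on the same events."""
        from nilearn.glm.first_level import compute_regressor

        frame_times = np.arange(100) * 2.5
        onsets = np.array([10.0, 60.0, 120.0, 180.0])
        durations = np.full(4, 20.0)
        main, _ = pf.build_modulated_regressor(
            onsets, durations, np.array([1.0, 2.0, 3.0, 4.0]), frame_times)
        ref, _ = compute_regressor(
            np.vstack([onsets, durations, np.ones(4)]), "spm", frame_times)
        r = np.corrcoef(main, ref[:, 0])[0, 1]
        assert r > 0.999


class TestModulatedRegressor:
    def test_matches_bruteforce_oracle(self, rng):
        """Eight 40-s blocks with random modulators: both columns equal
        the brute-force per-microtime construction to 1e-10."""
        frame_times = np.arange(172) * 2.5
        onsets = 6.0 + np.arange(8) * 46.0
        durations = np.full(8, 40.0)
        modulator = rng.normal(size=8)
        hrf = pf.Hrf()
        main, mod = pf.build_modulated_regressor(onsets, durations, modulator,
                                                 frame_times, hrf)
        main_bf, mod_bf = brute_force_modulated(onsets, durations, modulator,
                                                frame_times, hrf)
        assert np.allclose(main, main_bf, atol=1e-10)
        assert np.allclose(mod, mod_bf, atol=1e-10)

    def test_constant_modulator_zero_column(self):
        frame_times = np.arange(50) * 2.5
        with pytest.warns(UserWarning, match="zero-variance"):
            _, mod = pf.build_modulated_regressor(
                np.array([10.0, 50.0]), 5.0, np.array([3.0, 3.0]), frame_times)
        assert np.allclose(mod, 0.0)

    def test_single_event_degenerate(self):
        frame_times = np.arange(50) * 2.5
        with pytest.warns(UserWarning):
            _, mod = pf.build_modulated_regressor(
                np.array([10.0]), 5.0, np.array([7.0]), frame_times)
        assert np.allclose(mod, 0.0)

    def test_convolution_linearity(self, rng):
        """The modulated regressor of pooled events equals the sum of
        per-event modulated responses (before residualization)."""
        frame_times = np.arange(120) * 2.5
        onsets = np.array([6.0, 52.0, 98.0, 150.0])
        modulator = rng.normal(size=4)
        main_all, mod_all = pf.build_modulated_regressor(
            onsets, 40.0, modulator, frame_times, residualize=False)
        centered = modulator - modulator.mean()
        parts = []
        for on, m in zip(onsets, centered):
            # single event with modulator value m, no centering (m vs 0)
            p_main, _ = pf.build_modulated_regressor(
                np.array([on]), 40.0, np.array([1.0]), frame_times, residualize=False)
            parts.append(m * p_main)
        assert np.allclose(mod_all, np.sum(parts, axis=0), atol=1e-10)

    def test_modulated_column_orthogonal_to_main(self, rng):
        frame_times = np.arange(172) * 2.5
        main, mod = pf.build_modulated_regressor(
            6.0 + np.arange(8) * 46.0, 40.0, rng.normal(size=8), frame_times)
        assert abs(main @ mod) < 1e-8 * np.linalg.norm(main) * np.linalg.norm(mod)


@pytest.fixture(scope="module")
def z_recording(schedule):
    rec, _ = pf.simulate_pupil(schedule, pf.PupilGenConfig(seed=3))
    proc, _, _ = pf.preprocess(rec)
    return proc


class TestGlmVariants:
    def test_pupilsize_glm_structure(self, schedule, z_recording):
        """One blockwise pair: 8 events, modulator of length 8, plus
        drift and constant; full column rank."""
        dm = pf.build_pupilsize_glm(schedule, z_recording)
        assert "task_block" in dm.matrix and "task_block_x_pupil_size" in dm.matrix
        assert dm.modulated_columns == ("task_block_x_pupil_size",)
        assert len(dm.matrix) == 172
        dm.check_full_rank()

    def test_change_bins_tile_blocks(self, schedule, z_recording):
        """The 1-Hz pupil-change modulator contributes exactly 40 values
        per block (40 s per block = 40 bins)."""
        bins = dsg.change_bins_per_block(schedule, z_recording)
        assert len(bins) == 8 * 40
        assert (bins.groupby("block_index").size() == 40).all()

    def test_demeaned_variant_block_means_zero(self, schedule, z_recording):
        """The demeaned modulator has per-block mean 0 to 1e-12."""
        bins = dsg.change_bins_per_block(schedule, z_recording)
        demeaned = bins["change"] - bins.groupby("block_index")["change"].transform("mean")
        per_block = demeaned.groupby(bins["block_index"]).mean()
        assert np.abs(per_block).max() < 1e-12
        dm = pf.build_pupilchange_glm(schedule, z_recording, "demeaned_per_condition")
        assert len(dm.modulated_columns) == 4
        dm.check_full_rank()

    def test_pooled_main_equals_condition_split_sum(self, schedule, z_recording):
        """Linearity of convolution: the pooled main column equals the
        sum of the four per-condition main columns."""
        pooled = pf.build_pupilchange_glm(schedule, z_recording, "pooled")
        split = pf.build_pupilchange_glm(schedule, z_recording, "per_condition")
        mains = [c for c in split.matrix.columns
                 if c.startswith("task_") and "x_change" not in c and "drift" not in c]
        total = split.matrix[mains].sum(axis=1).to_numpy()
        assert np.allclose(total, pooled.matrix["task_bins"].to_numpy(), atol=1e-10)

    def test_block_mean_variant_modulator(self, schedule, z_recording):
        dm = pf.build_pupilchange_glm(schedule, z_recording, "block_mean")
        assert dm.modulated_columns == ("task_block_x_change_mean",)
        with pytest.raises(ValueError, match="variant"):
            pf.build_pupilchange_glm(schedule, z_recording, "bogus")

    def test_trialpeak_glm(self, schedule, z_recording):
        """128 trial events; equal peaks give a zero modulated column;
        missing features raise."""
        feats = pf.trial_features(z_recording, schedule)
        dm = pf.build_trialpeak_glm(schedule, feats)
        assert dm.modulated_columns == ("task_trials_x_peak",)
        flat = feats.copy()
        flat["peak_amplitude"] = 1.0
        with pytest.warns(UserWarning, match="zero-variance"):
            dm_flat = pf.build_trialpeak_glm(schedule, flat)
        assert np.allclose(dm_flat.matrix["task_trials_x_peak"], 0.0)
        with pytest.raises(ValueError, match="missing"):
            pf.build_trialpeak_glm(schedule, feats.iloc[:-1])

    def test_event_counts_in_microtime_support(self, schedule, z_recording):
        """8 block events and 128 trial events enter the regressors."""
        assert len(schedule.blocks) == 8
        assert sum(1 for _ in schedule.trials()) == 128


class TestNuisance:
    def _toy_bold(self, data):
        return pf.BoldDataset(data=np.asarray(data, float), tr=2.5, discard=0)

    def test_dvars_handcomputed_toy(self):
        """3 volumes x 2 voxels against hand RMS arithmetic."""
        data = np.array([[1.0, 3.0, 3.0], [2.0, 2.0, 6.0]]).reshape(2, 1, 1, 3)
        dvars, _ = dsg.compute_dvars(self._toy_bold(data))
        assert dvars[0] == 0.0
        assert dvars[1] == pytest.approx(np.sqrt((4 + 0) / 2))
        assert dvars[2] == pytest.approx(np.sqrt((0 + 16) / 2))

    def test_dvars_identical_volumes(self):
        data = np.ones((2, 2, 2, 10))
        dvars, dummies = dsg.compute_dvars(self._toy_bold(data))
        assert np.allclose(dvars, 0.0)
        assert dummies.shape[1] == 0

    def test_dvars_spike_flagged(self, rng):
        """An injected global spike is flagged; only the spiked volume
        and its successor (both differences are elevated) can be."""
        data = rng.normal(size=(4, 4, 2, 60))
        data[..., 30] += 10.0
        _, dummies = dsg.compute_dvars(self._toy_bold(data))
        flagged = {int(c.rsplit("_", 1)[1]) for c in dummies.columns}
        assert 30 in flagged
        assert flagged <= {30, 31}
        for c in dummies.columns:
            col = dummies[c].to_numpy()
            assert col.sum() == 1 and set(np.unique(col)) == {0.0, 1.0}

    def test_compcor_recovers_rank1_structure(self, rng):
        """Rank-1 structured noise in the masks: the first component
        correlates |r| > 0.99 with the generating series, and the
        component matrix is orthogonal."""
        latent = rng.normal(size=80)
        loadings = rng.normal(size=20)
        data = np.outer(loadings, latent) + 0.01 * rng.normal(size=(20, 80))
        full = np.concatenate([data, rng.normal(size=(12, 80))], axis=0)
        bold = pf.BoldDataset(data=full.reshape(4, 8, 1, 80), tr=2.5, discard=0)
        wm = np.zeros((4, 8, 1), dtype=bool)
        wm.reshape(-1)[:20] = True
        csf = np.zeros_like(wm)
        comps = pf.compute_compcor(bold, wm, csf, n_components=5)
        assert comps.shape == (80, 5)
        r = np.corrcoef(comps["compcor_1"], latent)[0, 1]
        assert abs(r) > 0.99
        gram = comps.to_numpy().T @ comps.to_numpy()
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8
        assert np.allclose(comps.std(ddof=0), 1.0)

    def test_compcor_fewer_voxels_than_components(self, rng):
        bold = pf.BoldDataset(data=rng.normal(size=(2, 1, 1, 30)), tr=2.5, discard=0)
        wm = np.ones((2, 1, 1), dtype=bool)
        with pytest.warns(UserWarning, match="components"):
            comps = pf.compute_compcor(bold, wm, np.zeros_like(wm), n_components=5)
        assert comps.shape[1] == 2

    def test_assemble_nuisance_columns(self, rng):
        """12 motion columns (derivative of a constant is 0) + dummies +
        components; mismatched lengths raise."""
        motion = pd.DataFrame({c: np.full(20, i * 1.0) for i, c in enumerate(
            ["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"])})
        dummies = pd.DataFrame({"dvars_outlier_5": (np.arange(20) == 5).astype(float)})
        comps = pd.DataFrame({f"compcor_{i+1}": rng.normal(size=20) for i in range(5)})
        nuis = pf.assemble_nuisance(motion, dummies, comps)
        assert nuis.shape[1] == 12 + 1 + 5
        assert np.allclose(nuis["trans_z_deriv"], 0.0)
        with pytest.raises(ValueError, match="length"):
            pf.assemble_nuisance(motion, dummies.iloc[:10], comps)
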