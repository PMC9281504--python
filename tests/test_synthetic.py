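"""Generator determinism, closed-form ground truth, and study structure."""

import math

import numpy as np
import pandas as pd
import pytest

from pushrim import AnalysisConfig, analyze_wheel
from pushrim.io import CHANNELS
from pushrim.segmentation import detect_pushes, total_force
from pushrim.synthetic import (
    FieldEffect,
    PushProfile,
    TrialRecipe,
    generate_study,
    generate_trial,
    null_effects,
    racket_effects,
    run_simulated_study,
    simulate_parameter_studies,
)


class TestGenerateTrial:
    def test_deterministic_given_seed(self):
        a, _ = generate_trial(TrialRecipe(seed=42))
        b, _ = generate_trial(TrialRecipe(seed=42))
        for ch in CHANNELS:
            np.testing.assert_array_equal(a.channel(ch), b.channel(ch))
        c, _ = generate_trial(TrialRecipe(seed=43))
        assert not np.array_equal(a.fx, c.fx)

    def test_force_nonnegative_and_zero_between_pushes(self, noisefree_recipe):
        ts, truth = generate_trial(noisefree_recipe)
        ftot = total_force(ts)
        assert np.all(ftot >= -1e-12)
        # sample midway through a recovery phase: exactly zero force
        mid_gap = int((truth.t_start[1] - 0.3) * ts.fs)
        assert ftot[mid_gap] == 0.0

    def test_channels_reconstruct_resultant(self, noisefree_recipe):
        """The 80/20 split preserves fx^2+fy^2+fz^2 = Ftot^2 exactly."""
        ts, truth = generate_trial(noisefree_recipe)
        i = int((truth.t_start[2] + truth.push_duration[2] / 2) * ts.fs)
        ftot = math.sqrt(ts.fx[i] ** 2 + ts.fy[i] ** 2 + ts.fz[i] ** 2)
        assert ftot == pytest.approx(float(truth.peak_force[2]), rel=1e-3)

    def test_invalid_recipe_rejected(self):
        with pytest.raises(ValueError):
            TrialRecipe(n_pushes=3)
        with pytest.raises(ValueError):
            PushProfile(peak_force=20.0)
        with pytest.raises(ValueError):
            PushProfile(push_duration=1.5, cycle_duration=1.2)

    def test_noisefree_recovery_matches_ground_truth(
        self, noisefree_recipe, clean_config
    ):
        """8 generated pushes: 8 detected, 5 analyzed, parameters within
        1% of the closed forms (2 samples for the temporal ones)."""
        ts, truth = generate_trial(noisefree_recipe)
        summary, metrics, ps, vel = analyze_wheel(
            ts, noisefree_recipe.geometry, clean_config
        )
        assert ps.n_detected == 8
        assert ps.n_analyzed == 5
        tm = truth.metrics(threshold=clean_config.threshold_n)
        meas = pd.DataFrame([m.to_dict() for m in metrics])
        for c in ("ftot_peak", "mz_peak", "ror", "fef", "po_peak", "ai"):
            rel = np.abs(meas[c].to_numpy() - tm[c].to_numpy()) / tm[c].to_numpy()
            assert rel.max() < 0.01, c
        for c in ("pt", "ct"):
            err = np.nanmax(
                np.abs(meas[c].to_numpy() - tm[c].to_numpy())
            ) * ts.fs
            assert err <= 2.0, c
        # push angle is boundary-quantized: within the angle of 2 samples
        pa_quantum = math.degrees(truth.omega_base / ts.fs)
        pa_err = np.abs(meas["pa"].to_numpy() - tm["pa"].to_numpy()).max()
        assert pa_err <= 2.0 * pa_quantum

    def test_fef_closed_form(self, clean_config):
        recipe = TrialRecipe(
            n_pushes=8,
            profile=PushProfile(tangential_fraction=0.35),
            push_cv={},
            noise_sd=0.0,
            ripple_amp=0.0,
            seed=1,
        )
        ts, _ = generate_trial(recipe)
        summary, *_ = analyze_wheel(ts, recipe.geometry, clean_config)
        assert summary.means["fef"] == pytest.approx(35.0, abs=0.5)

    def test_ground_truth_ideal_forms(self, noisefree_recipe):
        """threshold=0 truth reduces to the stated closed forms."""
        _, truth = generate_trial(noisefree_recipe)
        tm = truth.metrics(threshold=0.0, analyzed_only=False)
        F, tf = 100.0, 0.35
        pt, ct = 0.4, 1.2
        r = noisefree_recipe.geometry.handrim_radius
        omega = 1.4 / noisefree_recipe.geometry.wheel_radius
        assert tm["ftot_peak"].iloc[0] == F
        assert tm["ror"].iloc[0] == pytest.approx(math.pi * F / pt)
        assert tm["ai"].iloc[0] == pytest.approx((2 / math.pi) * F * tf * r * pt)
        assert tm["fef"].iloc[0] == pytest.approx(100 * tf)
        assert tm["pt"].iloc[0] == pytest.approx(pt)
        assert tm["ct"].iloc[0] == pytest.approx(ct)
        assert tm["pa"].iloc[0] == pytest.approx(math.degrees(omega * pt))
        assert tm["po_peak"].iloc[0] == pytest.approx(omega * tf * F * r)

    def test_detection_count_under_noise(self):
        """Detection finds exactly the generated pushes for moderate noise
        and detectable peaks."""
        for seed in range(5):
            rec = TrialRecipe(seed=seed, noise_sd=5.0,
                              profile=PushProfile(peak_force=70.0))
            ts, _ = generate_trial(rec)
            from pushrim.preprocessing import lowpass_kinetics

            ftot = total_force(lowpass_kinetics(ts, 20.0))
            assert detect_pushes(ftot, ts.fs).n_detected == rec.n_pushes


class TestGenerateStudy:
    def test_minimal_study_shape(self):
        res = generate_study(n_participants=2, seed=0)
        assert len(res.trials) == 4  # 2 participants x 2 conditions
        assert all(len(t.wheels) == 2 for t in res.trials)
        assert len(res.truth) == 8

    def test_study_files_and_manifest(self, tmp_path):
        res = generate_study(n_participants=2, seed=0, out_dir=tmp_path)
        assert res.manifest is not None
        res.manifest.validate_design()
        assert len(list(tmp_path.glob("*.csv"))) == 9  # 8 wheels + truth
        from pushrim import run_study

        report = run_study(res.manifest)
        assert len(report.summaries) == 8
        assert set(report.bilateral["parameter"]) == {
            "ftot_peak", "mz_peak", "ror", "fef", "po_peak", "ai", "pt",
            "ct", "pa",
        }

    def test_effects_move_cell_medians(self):
        eff = racket_effects()
        res = generate_study(n_participants=4, effects=eff, seed=5)
        t = res.truth
        dom = t[t.side == "dominant"].set_index(["participant", "condition"])
        for pid in dom.index.get_level_values(0).unique():
            w = dom.loc[(pid, "with_racket")]
            wo = dom.loc[(pid, "without_racket")]
            assert float(w.peak_force) > float(wo.peak_force)
            assert float(w.cycle_duration) < float(wo.cycle_duration)

    def test_parameter_level_sampler_shapes_and_null(self):
        params = simulate_parameter_studies(50, 8, seed=3)
        assert set(params) == {
            "ftot_peak", "mz_peak", "ror", "fef", "po_peak", "ai", "pt",
            "ct", "pa",
        }
        assert params["pt"].shape == (50, 8, 2, 2)
        # null effects: with/without cell medians agree to sampling error
        ratio = params["ftot_peak"][..., 0, :] / params["ftot_peak"][..., 1, :]
        assert np.median(ratio) == pytest.approx(1.0, abs=0.02)

    def test_parameter_level_effect_direction(self):
        params = simulate_parameter_studies(
            200, 16, effects=racket_effects(), seed=4
        )
        fef = params["fef"]
        # dominant side, with vs without racket: lower FEF with racket
        diff = fef[..., 0, 0] - fef[..., 1, 0]
        assert np.mean(diff.mean(axis=1) < 0) > 0.95


class TestRunSimulatedStudy:
    def test_in_memory_summaries_match_file_path(self, tmp_path):
        """The in-memory runner reproduces the file-backed pipeline."""
        from pushrim import run_study

        res = generate_study(n_participants=2, seed=9, out_dir=tmp_path)
        cfg = AnalysisConfig()
        mem = run_simulated_study(res, cfg).sort_values(
            ["participant", "condition", "side"]
        ).reset_index(drop=True)
        file_report = run_study(res.manifest, cfg)
        disk = file_report.summaries.sort_values(
            ["participant", "condition", "side"]
        ).reset_index(drop=True)
        for c in ("ftot_peak", "fef", "pt", "mean_velocity"):
            np.testing.assert_allclose(
                mem[c].to_numpy(), disk[c].to_numpy(), rtol=1e-5
            )
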