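"""Baseline correction, contact location, step detection, classification."""

from dataclasses import replace

import numpy as np
import pytest

from scfs.datamodel import CurveMetadata
from scfs.detection import (
    DetectionParams,
    ProcessedCurve,
    classify_event,
    correct_baseline,
    detect_steps,
    detection_benchmark,
    find_contact_point,
    process_curve,
)
from scfs.errors import InsufficientDataError, ValidationError
from scfs.presets import preset_condition
from scfs.simulate import NoiseModel, simulate_retract_curve


def _processed(force, sd=0.0, curve_id="t"):
    n = len(force)
    p = ProcessedCurve(
        z=np.linspace(1000, 0, n),
        force=np.asarray(force, dtype=float),
        baseline_sd=sd,
        metadata=CurveMetadata(curve_id=curve_id),
    )
    p.separation = np.linspace(0, 1.5 * (n - 1), n)
    p.contact_index = 0
    return p


class TestBaseline:
    def test_drift_recovered_within_one_percent(self, params):
        cfg = preset_condition("NF-NF", seed=21)
        cfg = replace(cfg, noise=NoiseModel(deflection_sd=0.02, drift_slope=0.01))
        curve, _ = simulate_retract_curve(cfg)
        p = correct_baseline(curve, params)
        assert p.provenance["baseline_slope_pN_per_nm"] == pytest.approx(0.01, rel=0.01)

    def test_zero_noise_zero_drift_correction_is_null(self, params):
        cfg = preset_condition("NF-NF", seed=21)
        cfg = replace(
            cfg,
            bond=replace(cfg.bond, n_bonds=0.0),
            tether=replace(cfg.tether, n_tethers=0.0),
            noise=NoiseModel(0.0, 0.0),
        )
        curve, _ = simulate_retract_curve(cfg)
        p = correct_baseline(curve, params)
        ret = curve.force()[curve.retract_indices]
        np.testing.assert_allclose(p.force, ret, atol=1e-9)
        assert p.baseline_sd == pytest.approx(0.0, abs=1e-9)

    def test_corrected_baseline_centred_on_zero(self, nf_curve, params):
        curve, _ = nf_curve
        p = correct_baseline(curve, params)
        n_base = int(round(params.baseline_fraction * p.n))
        tail = p.force[-n_base:]
        assert abs(tail.mean()) < 3 * p.baseline_sd / np.sqrt(n_base)

    def test_short_baseline_rejected(self, params):
        cfg = preset_condition("NF-NF", seed=1)
        curve, _ = simulate_retract_curve(cfg)
        short = replace(params, baseline_fraction=0.001)
        with pytest.raises(InsufficientDataError):
            correct_baseline(curve, short)


class TestContactPoint:
    def test_known_contact_recovered(self, clean_curve, params):
        curve, _ = clean_curve
        p = correct_baseline(curve, params)
        contact = find_contact_point(p)
        # generator unloads 3000 pN over 100 nm at 1.5 nm/sample -> ~sample 67
        assert abs(contact - 67) <= params.window_w
        assert not p.contact_flagged

    def test_translation_equivariance(self, clean_curve, params):
        curve, _ = clean_curve
        p1 = correct_baseline(curve, params)
        find_contact_point(p1)
        shifted = replace(curve, z_position=curve.z_position + 100.0)
        p2 = correct_baseline(shifted, params)
        find_contact_point(p2)
        assert p2.contact_index == p1.contact_index
        assert p2.z[p2.contact_index] == pytest.approx(p1.z[p1.contact_index] + 100.0)

    def test_all_zero_trace_flagged(self):
        p = _processed(np.zeros(500), sd=1.0)
        find_contact_point(p)
        assert p.contact_index == 0 and p.contact_flagged


class TestDetectSteps:
    def test_single_clean_step_localised_exactly(self, params):
        force = np.zeros(1000)
        force[:500] -= 30.0  # release of 30 pN at index 500
        p = _processed(force)
        cands = detect_steps(p, params)
        assert [c.index for c in cands] == [500]
        assert cands[0].step_force_pN == pytest.approx(30.0, abs=1e-9)

    def test_two_steps_three_windows_apart(self, params):
        force = np.zeros(2000)
        force[:700] -= 70.0
        force[:700 + 3 * params.window_w] -= 40.0
        p = _processed(force)
        cands = detect_steps(p, params)
        assert [c.index for c in cands] == [700, 700 + 3 * params.window_w]

    def test_pure_noise_rarely_fires(self, params):
        rng = np.random.default_rng(2024)
        clean = 0
        n_trials = 200
        for _ in range(n_trials):
            p = _processed(rng.normal(0, 3.0, 10000), sd=3.0)
            if not detect_steps(p, params):
                clean += 1
        assert clean >= 0.99 * n_trials

    def test_sub_gate_steps_ignored(self, params):
        force = np.zeros(1000)
        force[:500] -= 2.0  # below the absolute floor
        p = _processed(force)
        assert detect_steps(p, params) == []

    def test_short_curve_rejected(self, params):
        with pytest.raises(InsufficientDataError):
            detect_steps(_processed(np.zeros(4 * params.window_w - 1)), params)

    def test_noise_free_oracle_equivalence(self, clean_curve, params):
        curve, _ = clean_curve
        p = correct_baseline(curve, params)
        contact = find_contact_point(p)
        diffs = np.diff(p.force)
        oracle = np.flatnonzero(diffs >= params.min_step_force_pN) + 1
        oracle = [int(i) for i in oracle if i > contact + params.window_w]
        det = [c.index for c in detect_steps(p, params) if c.index > contact + params.window_w]
        assert len(det) == len(oracle)
        assert all(abs(d - o) <= 1 for d, o in zip(det, oracle))

    def test_force_linearity_in_spring_constant(self, params):
        cfg = preset_condition("NF-NF", seed=17)
        curve, _ = simulate_retract_curve(cfg)
        _, ev1 = process_curve(curve, params)
        scaled = replace(curve, metadata=replace(curve.metadata, spring_constant_k=120.0))
        _, ev2 = process_curve(scaled, params)
        common = set(e.index for e in ev1) & set(e.index for e in ev2)
        assert len(common) >= max(1, len(ev1) - 1)
        f1 = {e.index: e.force_F for e in ev1}
        f2 = {e.index: e.force_F for e in ev2}
        for i in common:
            assert f2[i] == pytest.approx(2.0 * f1[i], rel=1e-6)


class TestClassification:
    def test_loaded_ramp_is_jump_with_correct_loading_rate(self, params):
        # bond ramp at k_eff = 0.2 pN/nm, separation grid 1.5 nm/sample
        n = 2000
        sep = np.linspace(0, 1.5 * (n - 1), n)
        force = np.zeros(n)
        ramp = (sep >= 150) & (sep < 600)
        force[ramp] = -0.2 * (sep[ramp] - 150)
        force[sep < 150] = 0.0
        p = _processed(force)
        cands = detect_steps(p, params)
        assert len(cands) == 1
        ev = classify_event(p, cands[0], params)
        assert ev.event_class == "jump"
        assert ev.loading_rate_r == pytest.approx(0.2 * 3000.0, rel=0.05)
        assert ev.force_F == pytest.approx(ev.step_height_d * 60.0, rel=1e-12)

    def test_flat_plateau_is_tether(self, params):
        n = 2000
        force = np.zeros(n)
        force[:900] -= 30.0
        p = _processed(force)
        cands = detect_steps(p, params)
        ev = classify_event(p, cands[0], params)
        assert ev.event_class == "tether"
        assert abs(ev.pre_slope) < params.slope_min

    def test_requires_contact_point(self, params):
        p = _processed(np.zeros(500))
        p.separation = None
        from scfs.detection import StepCandidate

        with pytest.raises(ValidationError):
            classify_event(p, StepCandidate(100, 30.0, 10.0), params)


class TestProcessCurve:
    def test_event_free_curve_yields_no_events(self, params):
        cfg = preset_condition("NF-NF", seed=9)
        cfg = replace(cfg, bond=replace(cfg.bond, n_bonds=0.0), tether=replace(cfg.tether, n_tethers=0.0))
        curve, _ = simulate_retract_curve(cfg)
        _, events = process_curve(curve, params)
        assert events == []

    def test_composition_matches_manual_stages(self, nf_curve, params):
        curve, _ = nf_curve
        _, events = process_curve(curve, params)
        p = correct_baseline(curve, params)
        contact = find_contact_point(p)
        cands = [c for c in detect_steps(p, params) if c.index > contact + params.window_w]
        assert [e.index for e in sorted(events, key=lambda e: e.index)] == [c.index for c in cands]

    def test_error_annotated_with_curve_id(self, params):
        cfg = preset_condition("NF-NF", seed=9)
        curve, _ = simulate_retract_curve(cfg)
        keep = curve.segment_labels == "retract"
        short = replace(
            curve,
            time=curve.time[keep][:100],
            z_position=curve.z_position[keep][:100],
            deflection=curve.deflection[keep][:100],
            segment_labels=curve.segment_labels[keep][:100],
        )
        with pytest.raises(InsufficientDataError, match=short.metadata.curve_id):
            process_curve(short, params)


class TestBenchmark:
    def _ev(self, idx, force=50.0, cid="c", klass="jump"):
        from scfs.datamodel import RuptureEvent

        return RuptureEvent(cid, idx, idx * 1.5, force / 60.0, force, klass, 600.0, -0.2)

    def test_perfect_detection(self):
        truth = [self._ev(100), self._ev(300)]
        bm = detection_benchmark(truth, list(truth))
        assert bm.recall == 1.0 and bm.precision == 1.0 and bm.force_rmse_pN == pytest.approx(0.0)

    def test_empty_detection(self):
        bm = detection_benchmark([self._ev(100)], [])
        assert bm.recall == 0.0 and bm.precision == 1.0

    def test_one_sample_jitter_tolerated(self):
        truth = [self._ev(100), self._ev(300)]
        jittered = [self._ev(101), self._ev(299)]
        assert detection_benchmark(truth, jittered).recall == 1.0

    def test_sub_resolution_truth_merged(self):
        truth = [self._ev(100, 60.0), self._ev(101, 40.0)]
        det = [self._ev(100, 100.0)]
        bm = detection_benchmark(truth, det)
        assert bm.recall == 1.0
        assert bm.force_rmse_pN == pytest.approx(0.0, abs=1e-9)
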