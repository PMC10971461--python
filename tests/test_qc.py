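"""Eye-in-head conversion and the iterative robust (median/MAD) screen."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ofrlab import qc
from ofrlab.qc import QcConfig, SchemaError, apply_qc, compute_eye_in_head, robust_outlier_filter
from ofrlab.synthetic import SubjectModel, simulate_trial_table


def brute_force_filter(values, k=3.0, max_iter=50):
    """Independent step-by-step reference for the iterative screen."""
    vals = list(values)
    kept = [True] * len(vals)
    for _ in range(max_iter):
        current = [v for v, keep in zip(vals, kept) if keep]
        m = float(np.median(current))
        s = 1.4826 * float(np.median([abs(v - m) for v in current]))
        dropped = False
        for i, v in enumerate(vals):
            if not kept[i]:
                continue
            out = (v != m) if s == 0 else (abs(v - m) > k * s)
            if out:
                kept[i] = False
                dropped = True
        if not dropped:
            break
    return np.array(kept)


class TestRobustFilter:
    def test_hand_computed_example(self):
        # median 0.11, MAD 0.01 -> s = 0.0148, 3s = 0.044: only 5.0 is out;
        # the second pass drops nothing
        values = np.array([0.1, 0.12, 0.11, 0.09, 5.0])
        kept = robust_outlier_filter(values)
        np.testing.assert_array_equal(kept, [True, True, True, True, False])

    def test_identical_values_all_kept(self):
        kept = robust_outlier_filter(np.full(10, 0.42))
        assert kept.all()

    def test_degenerate_mad_keeps_only_median(self):
        # >= half the values identical -> s = 0 -> keep exact-median values only
        kept = robust_outlier_filter(np.array([1.0, 1.0, 1.0, 1.0, 1.4, 0.6]))
        np.testing.assert_array_equal(kept, [True, True, True, True, False, False])

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            robust_outlier_filter(np.array([1.0, 2.0]))

    def test_matches_bruteforce_on_pathological_two_cluster(self):
        values = np.concatenate([np.zeros(6), np.full(4, 10.0), [0.1, -0.1]])
        np.testing.assert_array_equal(robust_outlier_filter(values), brute_force_filter(values))

    @given(st.integers(0, 300))
    def test_matches_bruteforce_on_random_inputs(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 25))
        values = rng.normal(0, 1, n)
        if rng.random() < 0.5:  # inject outliers half the time
            values[: max(1, n // 5)] += rng.choice([-1, 1]) * rng.uniform(5, 50)
        np.testing.assert_array_equal(robust_outlier_filter(values), brute_force_filter(values))


class TestEyeInHead:
    def test_subtraction_and_unit_conversion(self):
        table = pd.DataFrame({
            "trial_id": [0], "condition": ["correlated"], "direction": ["up"],
            "dx_pupil_fix": [0.0], "dy_pupil_fix": [2.0],
            "dx_pupil_mov": [0.0], "dy_pupil_mov": [12.0],
            "dx_marker_fix": [0.0], "dy_marker_fix": [2.0],
            "dx_marker_mov": [0.0], "dy_marker_mov": [0.0],
        })
        eye = compute_eye_in_head(table, px_per_deg=40.0)
        assert eye.loc[0, "eye_dy_mov"] == pytest.approx(0.30)
        # pure head motion in the fixation epoch: eye-in-head is zero
        assert eye.loc[0, "eye_dy_fix"] == pytest.approx(0.0)
        assert eye.loc[0, "head_dy_fix"] == pytest.approx(2.0)

    def test_missing_columns_schema_error(self):
        with pytest.raises(SchemaError):
            compute_eye_in_head(pd.DataFrame({"dy_marker_fix": [1.0]}), 40.0)

    def test_blink_flags_propagate(self):
        model = SubjectModel(blink_rate=0.25, n_trials_per_cell=4, seed=5)
        table = simulate_trial_table(model)
        eye = compute_eye_in_head(table, 40.0)
        assert (eye["excluded_reason"] == "blink").sum() == 4


def _session(seed=0, **kw):
    model = SubjectModel(seed=seed, **kw)
    return compute_eye_in_head(simulate_trial_table(model), model.px_per_deg)


class TestApplyQc:
    def test_zero_noise_session_keeps_everything(self):
        eye = _session(seed=1, fixation_noise_sd_deg=0.0, head_noise_sd_px=0.0)
        kept, report = apply_qc(eye)
        assert report["n_kept"] == report["n_total"]
        assert report["excluded_fraction_total"] == 0.0

    def test_injected_saccades_removed_exactly_in_zero_noise_regime(self):
        # with no fixation noise the clean values are exactly equal, the MAD
        # degenerates to zero, and the excluded set provably equals the
        # injected set
        model = SubjectModel(saccade_rate=0.2, fixation_noise_sd_deg=0.0,
                             head_noise_sd_px=0.0, seed=2)
        table = simulate_trial_table(model)
        eye = compute_eye_in_head(table, model.px_per_deg)
        kept, report = apply_qc(eye)
        excluded_ids = set(eye["trial_id"]) - set(kept["trial_id"])
        injected_ids = set(table.loc[table.contaminated == "saccade", "trial_id"])
        assert excluded_ids == injected_ids
        assert len(excluded_ids) == 24

    def test_injected_saccades_removed_under_noise(self):
        model = SubjectModel(saccade_rate=0.2, fixation_noise_sd_deg=0.15, seed=3)
        table = simulate_trial_table(model)
        eye = compute_eye_in_head(table, model.px_per_deg)
        kept, report = apply_qc(eye)
        injected = set(table.loc[table.contaminated == "saccade", "trial_id"])
        assert injected.isdisjoint(set(kept["trial_id"]))
        # accounting identity
        assert report["excluded_fraction_total"] == pytest.approx(
            1 - report["n_kept"] / report["n_total"]
        )

    def test_idempotent_on_own_kept_set(self):
        eye = _session(seed=4, saccade_rate=0.15)
        kept, _ = apply_qc(eye)
        kept2, report2 = apply_qc(kept)
        assert len(kept2) == len(kept)
        assert report2["n_outlier_excluded"] == 0

    def test_order_invariance(self):
        eye = _session(seed=5, saccade_rate=0.1)
        kept_a, _ = apply_qc(eye)
        shuffled = eye.sample(frac=1.0, random_state=9).reset_index(drop=True)
        kept_b, _ = apply_qc(shuffled)
        assert set(kept_a["trial_id"]) == set(kept_b["trial_id"])

    @given(st.floats(0.1, 100.0))
    def test_scale_equivariance(self, c):
        eye = _session(seed=6, saccade_rate=0.1)
        kept_a, _ = apply_qc(eye)
        scaled = eye.copy()
        for col in ("eye_dy_fix", "eye_dx_fix"):
            scaled[col] = scaled[col] * c
        kept_b, _ = apply_qc(scaled)
        assert set(kept_a["trial_id"]) == set(kept_b["trial_id"])

    def test_exclusion_reason_priority(self):
        model = SubjectModel(saccade_rate=0.2, blink_rate=0.1, seed=7)
        table = simulate_trial_table(model)
        eye = compute_eye_in_head(table, model.px_per_deg)
        # blink trials never appear among the kept and keep their reason
        full, _ = apply_qc(eye)
        blink_ids = set(table.loc[table.blink_flag, "trial_id"])
        assert blink_ids.isdisjoint(set(full["trial_id"]))

    def test_empty_session_rejected(self):
        with pytest.raises(ValueError):
            apply_qc(pd.DataFrame(columns=["eye_dy_fix"]))

    def test_paperlike_contamination_gives_plausible_exclusion(self):
        # with moderate contamination the total exclusion fraction lands in
        # the clinically reported 5-45% band (qualitative sanity check)
        eye = _session(seed=8, saccade_rate=0.12, blink_rate=0.05)
        _, report = apply_qc(eye)
        assert 0.05 <= report["excluded_fraction_total"] <= 0.45
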