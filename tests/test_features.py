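"""Feature extraction: brute-force oracles, arithmetic examples, naming and
count invariants, mirror/scale properties."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from plantargait import (
    PressureRecording,
    WaveformParams,
    default_layout,
    extract_participant_features,
    generate_recording,
    participant_feature_names,
    symmetry_index,
)
from plantargait.core import DT, GaitCycle
from plantargait.features import (
    BIPEDAL_FEATURES,
    SINGLE_FOOT_FEATURES,
    aggregate_cycles,
    cop_features,
    feature_dictionary,
    pg_features,
    ppp_features,
    pti_features,
    sided,
    temporal_features,
    weak_foot_features,
)

LAYOUT = default_layout()


def _cycle(channels, p1=3, valley=6, p2=9, toe_off=12):
    channels = np.asarray(channels, dtype=float)
    return GaitCycle(foot="left", heel_strike=0, peak1=p1, valley=valley,
                     peak2=p2, toe_off=toe_off, cycle_end=channels.shape[0],
                     channels=channels)


class TestPPP:
    def test_all_zero_cycle(self):
        vals = ppp_features(_cycle(np.zeros((20, 8))))
        for s in range(1, 9):
            assert vals[f"{s}_PPP"] == 0
        assert np.isnan(vals["4/2_PPP"]) and np.isnan(vals["8/7_PPP"])

    def test_equal_sensor_peaks_give_unit_ratio(self):
        ch = np.zeros((20, 8))
        ch[4, 1] = ch[7, 3] = 0.8          # sensors 2 and 4 same peak
        ch[3, 6] = ch[5, 7] = 0.5          # sensors 7 and 8 same peak
        vals = ppp_features(_cycle(ch))
        assert vals["4/2_PPP"] == pytest.approx(1.0)
        assert vals["8/7_PPP"] == pytest.approx(1.0)

    def test_matches_brute_force(self, random_cycle_factory):
        rng = np.random.default_rng(5)
        for _ in range(20):
            c = random_cycle_factory(rng)
            vals = ppp_features(c)
            ch = c.channels
            for s in range(8):
                assert vals[f"{s+1}_PPP"] == max(ch[t, s] for t in range(len(ch)))
            assert vals["1-4_PPP"] == max(sum(ch[t, :4]) for t in range(len(ch)))
            total = ch.sum(axis=1)
            assert vals["peak1"] == total[c.peak1]
            assert vals["4/2_PPP"] == pytest.approx(ch[:, 3].max() / ch[:, 1].max())


class TestPG:
    def test_constant_slope_ramp(self):
        ch = np.zeros((11, 8))
        ch[:, 0] = 2.0 * np.arange(11) * DT  # slope 2 %BW/s
        vals = pg_features(_cycle(ch, p1=3, valley=5, p2=7, toe_off=9))
        assert vals["1_MaxPG"] == pytest.approx(2.0)
        assert vals["1_MinPG"] == pytest.approx(2.0)

    def test_valley_pg_arithmetic(self):
        # total: 1.0 -> 0.6 in 4 steps then back up in 4 steps between peaks
        total = np.r_[0.2, 0.6, 1.0, 0.9, 0.8, 0.7, 0.6, 0.7, 0.8, 0.9, 1.0,
                      0.5, 0.1, 0.0, 0.0, 0.0]
        ch = np.zeros((16, 8))
        ch[:, 0] = total
        vals = pg_features(_cycle(ch, p1=2, valley=6, p2=10, toe_off=13))
        assert vals["valleyPG"] == pytest.approx(16.0)

    def test_load_and_unload_rates(self):
        total = np.r_[0.0, 0.5, 1.0, 0.7, 0.6, 0.7, 0.9, 0.4, 0.0, 0.0]
        ch = np.zeros((10, 8))
        ch[:, 0] = total
        vals = pg_features(_cycle(ch, p1=2, valley=4, p2=6, toe_off=8))
        assert vals["loadr"] == pytest.approx(1.0 / (2 * DT))
        assert vals["unloadr"] == pytest.approx((0.0 - 0.9) / (2 * DT))
        assert vals["unloadr"] < 0  # off-loading rate is stored signed

    def test_matches_brute_force(self, random_cycle_factory):
        rng = np.random.default_rng(6)
        for _ in range(20):
            c = random_cycle_factory(rng)
            vals = pg_features(c)
            ch = c.channels
            for s in range(8):
                diffs = [(ch[t + 1, s] - ch[t, s]) / DT
                         for t in range(len(ch) - 1)]
                assert vals[f"{s+1}_MaxPG"] == pytest.approx(max(diffs))
                assert vals[f"{s+1}_MinPG"] == pytest.approx(min(diffs))
            total = ch.sum(axis=1)
            expect = sum(abs(total[t + 1] - total[t]) / DT
                         for t in range(c.peak1, c.peak2))
            assert vals["valleyPG"] == pytest.approx(expect)


class TestTemporal:
    def test_stance_swing_arithmetic(self):
        # 1.0 s cycle (20 samples), stance 0.6 s, peak1 at 0.2 s
        c = GaitCycle(foot="left", heel_strike=0, peak1=4, valley=7, peak2=9,
                      toe_off=12, cycle_end=20,
                      channels=np.zeros((20, 8)))
        vals = temporal_features(c)
        assert vals["t_st/sw"] == pytest.approx(1.5)
        assert vals["t_T"] == pytest.approx(1.0)
        assert vals["t_st/T"] == pytest.approx(0.6)
        assert vals["t_t1/T"] == pytest.approx(0.2)


class TestPTI:
    def test_rectangle(self):
        ch = np.zeros((16, 8))
        ch[:11, 0] = 0.8                      # 0.5 s plateau incl. endpoints
        c = _cycle(ch, p1=3, valley=5, p2=8, toe_off=10)
        assert pti_features(c)["PTI_st"] == pytest.approx(0.4)

    def test_triangle_to_first_peak(self):
        ch = np.zeros((16, 8))
        ch[:5, 0] = np.linspace(0, 1, 5)      # rise 0 -> 1 over 0.2 s
        c = _cycle(ch, p1=4, valley=6, p2=9, toe_off=12)
        assert pti_features(c)["PTI_1"] == pytest.approx(0.1)

    def test_against_dense_grid_oracle(self):
        # closed-form waveform: total = sin(pi t / 0.6) over a 0.6 s stance
        n, toe = 20, 12
        t = np.arange(n) * DT
        total = np.where(t <= 0.6, np.sin(np.pi * t / 0.6), 0.0)
        ch = np.zeros((n, 8))
        ch[:, 0] = total
        c = _cycle(ch, p1=4, valley=6, p2=8, toe_off=toe)
        dense_t = np.linspace(0, toe * DT, 20001)
        dense = np.trapezoid(np.sin(np.pi * dense_t / 0.6), dense_t)
        # trapezoid on the 20 Hz grid: error <= (b-a) dt^2 max|f''| / 12
        bound = 0.6 * DT**2 * (np.pi / 0.6) ** 2 / 12
        assert pti_features(c)["PTI_st"] == pytest.approx(dense, abs=bound)


class TestCOP:
    def test_single_active_sensor_fixed_point(self):
        ch = np.zeros((20, 8))
        ch[:12, 5] = 0.7
        vals = cop_features(_cycle(ch), LAYOUT)
        x, y = LAYOUT.normalized_coords[5]
        assert vals["xcop_mean"] == pytest.approx(x)
        assert vals["ycop_mean"] == pytest.approx(y)
        for name in ("cop_len", "cop_MRD", "cop_SRD"):
            assert vals[name] == pytest.approx(0.0, abs=1e-12)

    def test_two_equal_sensors_midpoint(self):
        ch = np.zeros((20, 8))
        ch[:12, 0] = ch[:12, 7] = 0.5
        vals = cop_features(_cycle(ch), LAYOUT)
        mid = (LAYOUT.normalized_coords[0] + LAYOUT.normalized_coords[7]) / 2
        assert vals["xcop_mean"] == pytest.approx(mid[0])
        assert vals["ycop_mean"] == pytest.approx(mid[1])

    def test_unloaded_stance_flagged_missing(self):
        vals = cop_features(_cycle(np.zeros((20, 8))), LAYOUT, threshold=0.01)
        assert all(np.isnan(v) for v in vals.values())

    def test_matches_brute_force(self, random_cycle_factory):
        rng = np.random.default_rng(7)
        coords = LAYOUT.normalized_coords
        for _ in range(20):
            c = random_cycle_factory(rng)
            vals = cop_features(c, LAYOUT)
            pts = []
            for t in range(c.toe_off):
                p = c.channels[t]
                w = p.sum()
                pts.append((p @ coords[:, 0] / w, p @ coords[:, 1] / w))
            pts = np.array(pts)
            assert vals["xcop_mean"] == pytest.approx(pts[:, 0].mean())
            length = sum(np.hypot(*(pts[i + 1] - pts[i]))
                         for i in range(len(pts) - 1))
            assert vals["cop_len"] == pytest.approx(length)
            mean_pt = pts.mean(axis=0)
            rd = np.linalg.norm(pts - mean_pt, axis=1)
            assert vals["cop_MRD"] == pytest.approx(rd.mean())


class TestAggregation:
    def test_identical_cycles_zero_std(self):
        row = {sided(s, b): 1.0 for s in "LR" for b in SINGLE_FOOT_FEATURES}
        row.update({b: 0.5 for b in BIPEDAL_FEATURES})
        per_cycle = pd.DataFrame([row] * 50)
        means, stds = aggregate_cycles(per_cycle)
        assert len(means) == 110 and len(stds) == 108
        assert (stds == 0).all()

    def test_alternating_values_mean(self):
        row_a = {sided(s, b): 2.0 for s in "LR" for b in SINGLE_FOOT_FEATURES}
        row_b = {sided(s, b): 4.0 for s in "LR" for b in SINGLE_FOOT_FEATURES}
        for r in (row_a, row_b):
            r.update({b: 0.0 for b in BIPEDAL_FEATURES})
        means, _ = aggregate_cycles(pd.DataFrame([row_a, row_b] * 25))
        assert means[sided("L", "peak1")] == pytest.approx(3.0)

    def test_nan_flagged_values_excluded(self):
        rng = np.random.default_rng(8)
        cols = [sided(s, b) for s in "LR" for b in SINGLE_FOOT_FEATURES]
        df = pd.DataFrame(rng.normal(size=(50, len(cols))), columns=cols)
        df.iloc[::7, 0] = np.nan
        means, stds = aggregate_cycles(df.assign(**{b: 0.0 for b in BIPEDAL_FEATURES}))
        valid = df.iloc[:, 0].dropna()
        assert means.iloc[0] == pytest.approx(valid.mean())
        assert stds.iloc[0] == pytest.approx(valid.std(ddof=1))


class TestSymmetryIndex:
    def test_equal_sides_zero(self):
        assert symmetry_index(2.5, 2.5) == 0.0

    def test_three_to_one_is_hundred(self):
        assert symmetry_index(3.0, 1.0) == pytest.approx(100.0)

    def test_zero_mean_flagged(self):
        assert np.isnan(symmetry_index(1.0, -1.0))

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(a=st.floats(0.01, 100), b=st.floats(0.01, 100))
    def test_symmetric_and_nonnegative(self, a, b):
        assert symmetry_index(a, b) == symmetry_index(b, a) >= 0


class TestWeakFoot:
    def _series(self, l_std, r_std):
        means = pd.Series({sided(s, b): (1.0 if s == "L" else 2.0)
                           for s in "LR" for b in SINGLE_FOOT_FEATURES})
        means[sided("L", "ycop_std")] = l_std
        means[sided("R", "ycop_std")] = r_std
        stds = pd.Series({f"{sided(s, b)}_STD": (3.0 if s == "L" else 4.0)
                          for s in "LR" for b in SINGLE_FOOT_FEATURES})
        return means, stds

    def test_larger_ap_variability_marks_weak(self):
        means, stds = self._series(l_std=2.0, r_std=1.0)
        weak, vals = weak_foot_features(means, stds)
        assert weak == "L"
        assert vals[sided("W", "peak1")] == means[sided("L", "peak1")]
        assert vals[f"{sided('W', 'peak1')}_STD"] == 3.0

    def test_tie_resolves_left(self):
        means, stds = self._series(l_std=1.0, r_std=1.0)
        assert weak_foot_features(means, stds)[0] == "L"

    def test_planted_right_variability(self):
        params = WaveformParams(cycle_jitter_sd=0.03,
                                left_right_asymmetry=0.15, seed=4)
        rec = generate_recording(params, body_weight=60.0)
        feats = extract_participant_features(rec)
        # weak-foot copies must equal one side's means exactly
        w = feats[sided("W", "peak1")]
        assert w in (feats[sided("L", "peak1")], feats[sided("R", "peak1")])


class TestAssembly:
    def test_feature_counts_and_names(self, zero_noise_recording):
        feats = extract_participant_features(
            zero_noise_recording,
            physical={"age": 63, "height": 158, "weight": 60, "BMI": 24.0})
        assert len(feats) == 384
        assert list(feats.index) == participant_feature_names()
        gait = feats.drop(["age", "height", "weight", "BMI"])
        assert len(gait) == 380
        assert not feats.isna().any()

    def test_group_counts_match_inventory(self):
        d = feature_dictionary()
        counts = {}
        for info in d.values():
            counts[info["group"]] = counts.get(info["group"], 0) + 1
        assert counts["PPP"] == 30 and counts["PG"] == 50
        assert counts["temporal"] == 12 and counts["PTI"] == 4
        assert counts["COP"] == 14
        assert counts["SI"] == 54 and counts["STD"] == 108
        assert counts["weak_foot"] == 108 and counts["physical"] == 4

    def test_zero_asymmetry_si_zero_and_zero_jitter_std_zero(
            self, zero_noise_recording):
        feats = extract_participant_features(zero_noise_recording)
        si = feats[[f"SI_{b}" for b in SINGLE_FOOT_FEATURES]]
        assert np.allclose(si, 0.0)
        stds = feats[[c for c in feats.index if c.endswith("_STD")]]
        assert np.allclose(stds, 0.0, atol=1e-10)

    def test_mirror_property(self):
        # zero jitter so the half-cycle window shift cannot perturb means
        params = WaveformParams(cycle_jitter_sd=0.0, left_right_asymmetry=0.12,
                                seed=2)
        rec = generate_recording(params, body_weight=62.0)
        feats = extract_participant_features(rec)
        swapped = PressureRecording(
            participant_id=rec.participant_id, left=rec.right.copy(),
            right=rec.left.copy(), body_weight=rec.body_weight,
            layout=rec.layout)
        feats_sw = extract_participant_features(swapped)
        for b in SINGLE_FOOT_FEATURES:
            assert feats[sided("L", b)] == pytest.approx(
                feats_sw[sided("R", b)], rel=1e-9)
            assert feats[f"SI_{b}"] == pytest.approx(
                feats_sw[f"SI_{b}"], rel=1e-9)
            assert feats[sided("W", b)] == pytest.approx(
                feats_sw[sided("W", b)], rel=1e-9)

    def test_scale_property(self, zero_noise_recording):
        rec = zero_noise_recording
        c = 3.0
        scaled = PressureRecording(
            participant_id=rec.participant_id, left=rec.left * c,
            right=rec.right * c, body_weight=rec.body_weight,
            layout=rec.layout)
        f0 = extract_participant_features(rec)
        f1 = extract_participant_features(scaled)
        for b in ("1_PPP", "peak1", "1-4_PPP", "valleyPG", "loadr", "PTI_st"):
            assert f1[sided("L", b)] == pytest.approx(c * f0[sided("L", b)])
        for b in ("t_st/T", "t_T", "4/2_PPP", "xcop_mean", "ycop_mean"):
            assert f1[sided("L", b)] == pytest.approx(f0[sided("L", b)])
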