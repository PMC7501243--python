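"""Classification pipeline: mobility, coilability, force, bursts, breaks."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest

from fmtkit.archive import MoleculeRecord, new_uid
from fmtkit.classify import (
    BurstRecord,
    ClassificationError,
    ClassifyConfig,
    assess_mobility,
    calibrate_turn_slope,
    classify_archive,
    classify_coilability,
    classify_molecule,
    classify_reaction_mode,
    count_treadmill_cycles,
    detect_breaks,
    detect_bursts,
    fit_dose_response,
    measure_force,
    pool_break_stats,
    projected_length,
)
from fmtkit.protocol import default_timeline
from fmtkit.simulate import GyraseKinetics, simulate_protocol_trace


def _record_from_xy(t, x, y):
    return MoleculeRecord(
        uid=new_uid(np.random.default_rng(0)),
        trajectory=pd.DataFrame({"frame": np.arange(len(t)), "t_s": t,
                                 "x_um": x, "y_um": y}))


class TestMobility:
    def test_symmetric_reversal_midpoint_attachment(self, timeline):
        ph = timeline.phase("reversal")
        t = np.linspace(ph.t0 + 0.1, ph.t1 - 0.1, 100)
        x = np.where(t < (ph.t0 + ph.t1) / 2, 6.0, 14.0)  # +-4 um around 10
        rec = _record_from_xy(t, x, np.full_like(t, 3.0))
        mobile, attachment, amp = assess_mobility(rec, timeline)
        assert mobile
        assert attachment == (10.0, 3.0)
        assert amp == 8.0

    def test_stuck_bead_below_threshold(self, timeline):
        ph = timeline.phase("reversal")
        t = np.linspace(ph.t0 + 0.1, ph.t1 - 0.1, 100)
        rng = np.random.default_rng(1)
        rec = _record_from_xy(t, 10 + rng.normal(0, 0.01, 100),
                              3 + rng.normal(0, 0.01, 100))
        mobile, _, amp = assess_mobility(rec, timeline)
        assert not mobile
        assert amp < 0.5

    def test_missing_reversal_phase_raises(self, timeline):
        from fmtkit.protocol import ProtocolTimeline

        tl = ProtocolTimeline(phases=[p for p in timeline.phases
                                      if p.name != "reversal"][:1])
        rec = _record_from_xy(np.arange(10.0), np.zeros(10), np.zeros(10))
        with pytest.raises(ClassificationError):
            assess_mobility(rec, tl)

    def test_cohort_mobility_labels_all_correct(self, small_cohort, timeline):
        arch, truth = small_cohort
        correct = 0
        for rec in arch:
            mobile, _, _ = assess_mobility(rec, timeline)
            is_stuck = "truth:stuck" in rec.tags
            correct += mobile != is_stuck
        assert correct == len(arch)


class TestProjectedLength:
    def test_three_four_five(self):
        rec = _record_from_xy(np.array([0.0]), np.array([13.0]), np.array([24.0]))
        l = projected_length(rec, (10.0, 20.0))
        assert l.iloc[0] == pytest.approx(5.0)

    def test_zero_at_attachment(self):
        rec = _record_from_xy(np.array([0.0]), np.array([10.0]), np.array([20.0]))
        assert projected_length(rec, (10.0, 20.0)).iloc[0] == 0.0


class TestCoilability:
    @pytest.mark.parametrize("label,coilable,single", [
        ("single", True, True),
        ("nicked", False, False),
        ("multi", True, False),
    ])
    def test_class_signatures(self, timeline, label, coilable, single):
        rec = simulate_protocol_trace(label, timeline, force_pn=0.2,
                                      rng=np.random.default_rng(3))
        _, attachment, _ = assess_mobility(rec, timeline)
        l_xy = projected_length(rec, attachment)
        got_coil, got_single = classify_coilability(l_xy, timeline)
        assert got_coil == coilable
        assert got_single == single

    def test_cohort_class_labels(self, small_cohort, timeline):
        arch, truth = small_cohort
        res, _ = classify_archive(arch, timeline)
        df = res.merge(truth, on="uid", suffixes=("", "_truth"))
        mobile = df[df["class"] != "stuck"]
        acc = ((mobile["class"] == "single") == mobile["accepted"]).mean()
        assert acc >= 0.95


class TestForce:
    def test_simulated_window_recovers_force(self, timeline):
        rec = simulate_protocol_trace("single", timeline, force_pn=0.2,
                                      rng=np.random.default_rng(4))
        f, l = measure_force(rec, timeline)
        assert f == pytest.approx(0.2, rel=0.10)

    def test_deterministic(self, timeline):
        rec = simulate_protocol_trace("single", timeline, force_pn=0.3,
                                      rng=np.random.default_rng(5))
        assert measure_force(rec, timeline) == measure_force(rec, timeline)

    def test_rank_correlation_across_forces(self, timeline):
        from scipy.stats import spearmanr

        forces = np.geomspace(0.1, 1.0, 15)
        est = []
        for i, f in enumerate(forces):
            rec = simulate_protocol_trace("single", timeline, force_pn=f,
                                          rng=np.random.default_rng(100 + i))
            est.append(measure_force(rec, timeline)[0])
        rho = spearmanr(forces, est).statistic
        assert rho >= 0.95

    def test_short_window_rejected(self, timeline):
        ph = timeline.phase("force_window")
        t = np.linspace(ph.t0, ph.t0 + 1.0, 50)
        rec = _record_from_xy(t, np.zeros(50), np.zeros(50))
        with pytest.raises(ClassificationError, match="100"):
            measure_force(rec, timeline)


class TestTurnSlope:
    def _lxy_from_phase(self, timeline, slope_nm, noise_sd, rng):
        ph = timeline.phase("partial_uncoil")
        t = np.arange(ph.t0, ph.t1, 1 / ph.frame_rate)
        turns = ph.turns_at(t)
        l = 2.0 + slope_nm * 1e-3 * (turns[0] - turns)
        l = l + rng.normal(0, noise_sd, len(t))
        return pd.Series(l, index=t)

    def test_noiseless_exact(self, timeline):
        l_xy = self._lxy_from_phase(timeline, 50.0, 0.0, np.random.default_rng(0))
        assert calibrate_turn_slope(l_xy, timeline) == pytest.approx(50.0, rel=1e-9)

    def test_noisy_within_5pct(self, timeline):
        errs = []
        for seed in range(50):
            l_xy = self._lxy_from_phase(timeline, 50.0, 0.05,
                                        np.random.default_rng(seed))
            errs.append(abs(calibrate_turn_slope(l_xy, timeline) - 50.0) / 50.0)
        assert np.median(errs) < 0.05
        assert max(errs) < 0.10

    def test_non_compacting_molecule_raises(self, timeline):
        ph = timeline.phase("partial_uncoil")
        t = np.arange(ph.t0, ph.t1, 1 / ph.frame_rate)
        flat = pd.Series(3.8 + 0.0 * t, index=t)
        with pytest.raises(ClassificationError, match="calibrate"):
            calibrate_turn_slope(flat, timeline)


class TestBursts:
    def _reaction_series(self, timeline, segments, noise=0.0, seed=0):
        """Piecewise-linear l_xy over the reaction phase from
        (duration, slope um/s) pairs."""
        ph = timeline.phase("reaction")
        t = np.arange(ph.t0, ph.t1, 1 / ph.frame_rate)
        l = np.empty_like(t)
        cur, t_mark = 1.8, ph.t0
        vals = []
        for ti in t:
            for dur, slope in segments:
                if ti < t_mark + dur:
                    vals.append(cur + slope * (ti - t_mark))
                    break
                cur += slope * dur
                t_mark += dur
            else:
                vals.append(cur)
            cur, t_mark = 1.8, ph.t0  # reset scan
        # simpler: rebuild cumulatively
        l = np.empty_like(t)
        cur, t_mark, idx = 1.8, ph.t0, 0
        seg = list(segments)
        for i, ti in enumerate(t):
            while seg and ti >= t_mark + seg[0][0]:
                cur += seg[0][1] * seg[0][0]
                t_mark += seg[0][0]
                seg.pop(0)
            l[i] = cur + (seg[0][1] if seg else 0.0) * (ti - t_mark)
        rng = np.random.default_rng(seed)
        if noise:
            l = l + rng.normal(0, noise, len(l))
        return pd.Series(l, index=t)

    def test_arithmetic_oracle_velocities(self, timeline):
        # extension at 100 nm/s then compaction at -50 nm/s, slope 50 nm/turn
        l_xy = self._reaction_series(timeline,
                                     [(20, 0.0), (30, 0.100), (20, 0.0), (60, -0.050)])
        bursts = detect_bursts(l_xy, 50.0, timeline)
        by_sign = {b.sign: b for b in bursts}
        assert by_sign["positive_relaxation"].velocity == pytest.approx(1.0, rel=1e-6)
        assert by_sign["negative_introduction"].velocity == pytest.approx(0.5, rel=1e-6)

    def test_velocity_invariant(self, timeline):
        l_xy = self._reaction_series(
            timeline, [(20, 0.0), (30, 0.100), (20, 0.0), (60, -0.050)],
            noise=0.05, seed=3)
        for b in detect_bursts(l_xy, 50.0, timeline):
            assert b.velocity * 50.0 * 2.0 == pytest.approx(abs(b.slope_nm_s))

    def test_flat_reaction_no_bursts(self, timeline):
        l_xy = self._reaction_series(timeline, [(300, 0.0)], noise=0.05, seed=4)
        assert detect_bursts(l_xy, 50.0, timeline) == []

    def test_simulated_cohort_velocity_medians(self, small_cohort, timeline):
        arch, truth = small_cohort
        res, _ = classify_archive(arch, timeline)
        df = res.merge(truth, on="uid", suffixes=("", "_truth"))
        singles = df[(df["class"] == "single") & df["accepted"]]
        assert singles["v_pos"].median() == pytest.approx(1.26, rel=0.05)
        alpha = singles[singles["alpha"] == 1.0]
        assert alpha["v_neg"].median() == pytest.approx(0.65, rel=0.05)

    def test_short_reaction_phase_rejected(self, timeline):
        ph = timeline.phase("reaction")
        t = np.arange(ph.t0, ph.t0 + 5.0, 0.25)
        l_xy = pd.Series(np.ones_like(t), index=t)
        with pytest.raises(ClassificationError, match="window"):
            detect_bursts(l_xy, 50.0, timeline)


class TestReactionMode:
    def _series(self, timeline, final_offset, end_early=0.0):
        ph = timeline.phase("reaction")
        t = np.arange(ph.t0 - 40.0, ph.t1 - end_early, 0.25)
        l = np.where(t < ph.t0 + 30, 1.8,
                     np.where(t < ph.t0 + 60,
                              1.8 + (t - ph.t0 - 30) / 30 * final_offset,
                              1.8 + final_offset))
        return pd.Series(l, index=t)

    def test_ending_below_baseline_is_alpha(self, timeline):
        assert classify_reaction_mode(self._series(timeline, -1.0), timeline) == "alpha"

    def test_relaxing_to_above_baseline_is_chi(self, timeline):
        assert classify_reaction_mode(self._series(timeline, +2.0), timeline) == "chi"

    def test_truncated_trace_untagged_with_warning(self, timeline):
        with pytest.warns(UserWarning, match="mid-reaction"):
            mode = classify_reaction_mode(self._series(timeline, -1.0, end_early=100.0),
                                          timeline)
        assert mode is None

    def test_cohort_mode_tags_match_truth(self, small_cohort, timeline):
        arch, truth = small_cohort
        res, _ = classify_archive(arch, timeline)
        df = res.merge(truth, on="uid", suffixes=("", "_truth"))
        tagged = df[(df["class"] == "single") & (df["mode"] != "")]
        agree = ((tagged["alpha"] == 1.0) == (tagged["mode"] == "alpha")).mean()
        assert agree >= 0.98


class TestBreaks:
    def test_toy_rate_arithmetic(self):
        # 2 breaks in 100 s burst vs 2 breaks in 600 s background -> ratio 6
        rows = pd.DataFrame([
            {"uid": "a", "broke": True, "t_break": 1.0, "in_burst": True,
             "burst_time": 50.0, "background_time": 300.0},
            {"uid": "b", "broke": True, "t_break": 2.0, "in_burst": True,
             "burst_time": 50.0, "background_time": 300.0},
            {"uid": "c", "broke": True, "t_break": 3.0, "in_burst": False,
             "burst_time": 0.0, "background_time": 0.0},
            {"uid": "d", "broke": True, "t_break": 4.0, "in_burst": False,
             "burst_time": 0.0, "background_time": 0.0},
        ])
        st = pool_break_stats(rows, n_boot=0)
        assert st.ratio == pytest.approx(6.0)

    def test_no_breaks_flagged_not_raised(self, timeline):
        rows = pd.DataFrame([{"uid": "a", "broke": False, "t_break": np.nan,
                              "in_burst": False, "burst_time": 10.0,
                              "background_time": 100.0}])
        st = pool_break_stats(rows, n_boot=5)
        assert st.events == []
        assert st.burst_rate == 0.0 and st.background_rate == 0.0
        assert math.isnan(st.ratio)

    def test_zero_background_breaks_infinite_ratio(self):
        rows = pd.DataFrame([{"uid": "a", "broke": True, "t_break": 1.0,
                              "in_burst": True, "burst_time": 10.0,
                              "background_time": 100.0}])
        st = pool_break_stats(rows, n_boot=5)
        assert st.infinite and math.isinf(st.ratio)

    def test_cohort_breaks_detected(self, small_cohort, timeline):
        arch, truth = small_cohort
        _, bursts = classify_archive(arch, timeline)
        st = detect_breaks(arch, bursts, timeline, rng=np.random.default_rng(0))
        assert len(st.events) == int(truth["break_t"].notna().sum())


class TestDoseResponse:
    CONC = np.array([0.0, 0.1, 0.3, 1.0, 3.0, 10.0, 30.0, 100.0])

    @staticmethod
    def model(x, top, bottom, ic50):
        return bottom + (top - bottom) / (1 + x / ic50)

    def test_exact_recovery(self):
        y = self.model(self.CONC, 1.2, 0.1, 1.0)
        fit = fit_dose_response(self.CONC, y)
        assert fit.ic50 == pytest.approx(1.0, rel=1e-6)
        assert fit.top == pytest.approx(1.2, rel=1e-6)
        assert fit.bottom == pytest.approx(0.1, abs=1e-6)

    def test_noisy_recovery_within_20pct_median(self):
        errs = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            y = self.model(self.CONC, 1.2, 0.1, 1.0) * rng.normal(1, 0.05, len(self.CONC))
            fit = fit_dose_response(self.CONC, y)
            errs.append(abs(fit.ic50 - 1.0))
        assert np.median(errs) < 0.20

    def test_ci_brackets_truth_for_exact_data(self):
        y = self.model(self.CONC, 1.2, 0.1, 1.0)
        fit = fit_dose_response(self.CONC, y)
        assert fit.ci95[0] <= 1.0 <= fit.ci95[1]

    def test_flat_response_rejected(self):
        with pytest.raises(ClassificationError):
            fit_dose_response(self.CONC, np.ones_like(self.CONC))

    def test_too_few_concentrations_rejected(self):
        with pytest.raises(ClassificationError):
            fit_dose_response(np.array([0, 1, 2.0]), np.array([1.0, 0.5, 0.2]))


class TestTreadmill:
    def test_eight_turns_per_second_is_four_cycles(self):
        assert count_treadmill_cycles(8.0, 1.0) == 4.0

    def test_zero_rate(self):
        assert count_treadmill_cycles(0.0, 100.0) == 0.0

    def test_campaign_totals_98_million(self):
        total = sum(7801 * count_treadmill_cycles(r, 30 * 60) for r in (2, 4, 8))
        assert total == pytest.approx(98.3e6, rel=0.01)


class TestPipelineInvariants:
    def test_funnel_monotonicity(self, small_cohort, timeline):
        arch, _ = small_cohort
        res, _ = classify_archive(arch, timeline)
        assert (res["accepted"] <= res["coilable"]).all()
        assert (res["coilable"] <= res["mobile"]).all()
        acc = res[res["accepted"]]
        assert acc["mobile"].all() and acc["single"].all()
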