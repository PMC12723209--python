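"""Longitudinal Bloch simulation of the interleaved 4-heartbeat sequence."""

import math

import numpy as np
import pytest

from cardiomap import bloch
from cardiomap.params import (
    CardiacTiming,
    ConfigurationError,
    Prep,
    SequenceParams,
    TimingError,
    TissueParams,
    replace,
)


class TestApplyPrep:
    def test_inversion_flips_sign(self, seq, myocardium):
        assert bloch.apply_prep(0.8, Prep.IR, myocardium, seq) == pytest.approx(-0.8)

    def test_imperfect_inversion_scales(self, seq, myocardium):
        seq2 = replace(seq, inversion_efficiency=0.9)
        assert bloch.apply_prep(1.0, Prep.IR, myocardium, seq2) == pytest.approx(-0.9)

    def test_spin_lock_is_exponential_decay(self, seq):
        tissue = TissueParams(t1=1.0, t1rho=0.040)
        out = bloch.apply_prep(1.0, Prep.T1RHO, tissue, seq)
        assert out == pytest.approx(math.exp(-1.0), rel=1e-12)

    def test_none_is_identity(self, seq, myocardium):
        assert bloch.apply_prep(0.37, Prep.NONE, myocardium, seq) == 0.37


class TestRfSpoiledTrain:
    def test_90_degree_pulse_resets_mz(self, myocardium):
        mz, at_pulses = bloch.rf_spoiled_train(0.5, 90.0, 0.01, 1, myocardium)
        expected = myocardium.m0 * (1 - math.exp(-0.01 / myocardium.t1))
        assert at_pulses == [0.5]
        assert mz == pytest.approx(expected, rel=1e-12)

    def test_zero_flip_angle_is_free_relaxation(self, myocardium):
        n, tr, mz0 = 7, 0.012, 0.2
        mz, _ = bloch.rf_spoiled_train(mz0, 0.0, tr, n, myocardium)
        closed = myocardium.m0 + (mz0 - myocardium.m0) * math.exp(
            -n * tr / myocardium.t1
        )
        assert mz == pytest.approx(closed, rel=1e-12)

    def test_matches_stepwise_oracle(self):
        """Independent scalar pulse-by-pulse recursion, 8 deg / 16 pulses."""
        tissue = TissueParams(t1=0.700, t1rho=0.056)
        fa, tr, n = 8.0, 0.00971, 16
        mz_oracle = 0.63
        history = []
        for _ in range(n):
            history.append(mz_oracle)
            mz_oracle = mz_oracle * math.cos(math.radians(fa))
            mz_oracle = tissue.m0 - (tissue.m0 - mz_oracle) * math.exp(
                -tr / tissue.t1
            )
        mz, at_pulses = bloch.rf_spoiled_train(0.63, fa, tr, n, tissue)
        assert mz == pytest.approx(mz_oracle, rel=1e-12)
        np.testing.assert_allclose(at_pulses, history, rtol=1e-12)

    def test_negative_tr_rejected(self, myocardium):
        with pytest.raises(ConfigurationError):
            bloch.rf_spoiled_train(1.0, 8.0, -0.01, 1, myocardium)


def _event_list_oracle(seq: SequenceParams, rr: float, tissue: TissueParams):
    """Independent event-list simulator: builds the explicit (op, arg) list
    for one block and folds it over Mz until steady state."""
    events = []
    gap = seq.ti - seq.n_inav_pulses * seq.tr_imaging
    for prep in seq.prep_pattern:
        used = seq.ti + seq.imaging_duration + (
            seq.tsl if prep is Prep.T1RHO else 0.0
        )
        events.append(("prep", prep))
        events.append(("relax", gap))
        for _ in range(seq.n_inav_pulses):
            events.append(("pulse", seq.fa_inav))
            events.append(("relax", seq.tr_imaging))
        events.append(("record", None))
        for _ in range(seq.n_segments_per_hb):
            events.append(("pulse", seq.fa_imaging))
            events.append(("relax", seq.tr_imaging))
        events.append(("relax", rr - used))

    def run_block(mz):
        rec = []
        for op, arg in events:
            if op == "prep":
                if arg is Prep.IR:
                    mz = -seq.inversion_efficiency * mz
                elif arg is Prep.T1RHO:
                    mz *= math.exp(-seq.tsl / tissue.t1rho)
            elif op == "relax":
                mz = tissue.m0 + (mz - tissue.m0) * math.exp(-arg / tissue.t1)
            elif op == "pulse":
                mz *= math.cos(math.radians(arg))
            else:
                rec.append(mz * math.sin(math.radians(seq.fa_imaging)))
        return mz, rec

    mz = tissue.m0
    for _ in range(100):
        prev = mz
        mz, rec = run_block(mz)
        if abs(mz - prev) < 1e-6 * tissue.m0:
            break
    return np.array(rec)


class TestSimulateSignals:
    def test_zero_imaging_flip_angle_gives_zero_signal(self, timing60, myocardium):
        seq0 = SequenceParams(fa_imaging=0.0)
        out = bloch.simulate_signals(seq0, timing60, myocardium)
        np.testing.assert_allclose(out.signals, 0.0, atol=1e-15)

    def test_zero_spin_lock_degenerates_to_no_prep(self, timing60, myocardium):
        """TSL=0 makes the spin-lock prep an identity: with no other prep in
        the block all four volumes coincide; with the IR prep present the
        volume-4 signal moves toward volume 3 (the beats differ only through
        the decaying inversion residual, so exact equality cannot hold)."""
        seq_none = SequenceParams(tsl=0.0, prep_pattern=(Prep.NONE,) * 4)
        out = bloch.simulate_signals(seq_none, timing60, myocardium)
        assert np.ptp(out.signals) < 1e-6 * myocardium.m0
        gap = {}
        for tsl in (0.040, 0.0):
            out = bloch.simulate_signals(
                SequenceParams(tsl=tsl), timing60, myocardium
            )
            gap[tsl] = abs(out.signals[3] - out.signals[2])
        assert gap[0.0] < 0.2 * gap[0.040]

    def test_matches_event_list_oracle(self, seq, timing60, myocardium):
        out = bloch.simulate_signals(seq, timing60, myocardium)
        oracle = _event_list_oracle(seq, 1.0, myocardium)
        np.testing.assert_allclose(out.signals, oracle, rtol=1e-10)

    @pytest.mark.parametrize("hr", [60, 80, 100, 120])
    def test_oracle_agreement_across_heart_rates(self, seq, myocardium, hr):
        timing = CardiacTiming.from_hr(hr)
        out = bloch.simulate_signals(seq, timing, myocardium)
        oracle = _event_list_oracle(seq, 60.0 / hr, myocardium)
        np.testing.assert_allclose(out.signals, oracle, rtol=1e-10)

    def test_steady_state_is_fixed_point(self, seq, timing60):
        """One extra block after convergence changes each signal < 1e-6 M0."""
        t1 = np.array([0.1, 0.7, 3.0])
        t1rho = np.array([0.02, 0.056, 0.3])
        s_n, _, conv = bloch.simulate_signals_grid(
            seq, timing60, t1, t1rho, tol=0.0, max_blocks=60
        )
        s_n1, _, _ = bloch.simulate_signals_grid(
            seq, timing60, t1, t1rho, tol=0.0, max_blocks=61
        )
        assert not conv.any()  # tol=0 never certifies convergence
        assert np.abs(s_n1 - s_n).max() < 1e-6

    def test_signals_scale_linearly_in_m0(self, seq, timing60):
        a = bloch.simulate_signals(seq, timing60, TissueParams(0.7, 0.056, m0=1.0))
        b = bloch.simulate_signals(seq, timing60, TissueParams(0.7, 0.056, m0=3.5))
        np.testing.assert_allclose(b.signals, 3.5 * a.signals, rtol=1e-9)

    @pytest.mark.parametrize("t1_ms", [100, 300, 700, 1500, 3000])
    def test_ir_volume_below_unprepped_volume(self, seq, timing60, t1_ms):
        out = bloch.simulate_signals(
            seq, timing60, TissueParams(t1_ms / 1000.0, 0.056)
        )
        assert out.signals[0] < out.signals[1]

    def test_volume4_continuous_in_tsl(self, timing60, myocardium):
        """Volume 4 approaches its no-spin-lock limit continuously."""
        limit = bloch.simulate_signals(
            SequenceParams(tsl=0.0), timing60, myocardium
        ).signals[3]
        gaps = []
        for tsl in (0.004, 0.002, 0.001):
            out = bloch.simulate_signals(
                SequenceParams(tsl=tsl), timing60, myocardium
            )
            gaps.append(abs(out.signals[3] - limit))
        assert gaps[2] < gaps[1] < gaps[0]
        assert gaps[2] < 5e-3 * myocardium.m0

    def test_infeasible_timing_raises(self, seq, myocardium):
        with pytest.raises(TimingError):
            bloch.simulate_signals(seq, CardiacTiming.from_hr(200), myocardium)

    def test_grid_matches_scalar_path(self, seq, timing60):
        t1 = np.array([0.3, 0.7, 1.4])
        t1rho = np.array([0.03, 0.056, 0.08])
        grid, _, _ = bloch.simulate_signals_grid(seq, timing60, t1, t1rho)
        for i in range(3):
            scalar = bloch.simulate_signals(
                seq, timing60, TissueParams(t1[i], t1rho[i])
            )
            # the grid run iterates until the slowest tissue converges, so
            # agreement is bounded by the steady-state tolerance
            np.testing.assert_allclose(grid[i], scalar.signals, atol=2e-6)
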