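"""Detector: envelope, suppression thresholding, phase counting, bursts,
all-channel consensus, epoch delimitation and the summary chain."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import bsdetect as bd
from bsdetect.detect import ParameterError

FS = 178.0


def sine(freq, dur, amp=1.0, fs=FS, phase=0.0):
    t = np.arange(int(round(dur * fs))) / fs
    return amp * np.sin(2 * np.pi * freq * t + phase)


class TestEnvelope:
    def test_constant_signals(self):
        assert np.allclose(bd.amplitude_envelope(np.full(1000, 10.0), FS, 0.5), 10.0)
        assert np.allclose(bd.amplitude_envelope(np.full(1000, -10.0), FS, 0.5), 10.0)
        assert np.allclose(bd.amplitude_envelope(np.zeros(1000), FS, 0.5), 0.0)

    def test_sine_interior_envelope_is_two_over_pi(self):
        # mean |sin| over whole cycles = 2/pi; 0.5 s of 10 Hz = 5 cycles
        env = bd.amplitude_envelope(sine(10, 10, amp=10), FS, 0.5)
        interior = env[int(FS) : -int(FS)]
        assert np.allclose(interior, 2 / np.pi * 10, rtol=0.02)

    def test_same_length_nonnegative_truncated_edges(self, rng):
        x = rng.normal(size=500)
        env = bd.amplitude_envelope(x, FS, 0.5)
        assert env.shape == x.shape
        assert (env >= 0).all()
        # edge value is a truncated mean, not padded toward zero
        assert env[0] == pytest.approx(np.abs(x[: int(0.5 * FS) // 2 + 1]).mean())

    def test_subsample_window_rejected(self):
        with pytest.raises(ParameterError):
            bd.amplitude_envelope(np.zeros(100), FS, 0.001)


class TestSuppressions:
    def test_flat_zero_channel_is_one_full_interval(self):
        sup = bd.detect_suppressions(np.zeros(int(10 * FS)), FS, bd.DetectionParams())
        assert len(sup) == 1
        assert sup[0].onset == 0.0
        assert sup[0].duration == pytest.approx(10.0)

    def test_large_sine_has_no_suppressions(self):
        sup = bd.detect_suppressions(sine(10, 10, amp=50), FS, bd.DetectionParams())
        assert sup == []

    def test_sandwiched_silence_boundaries_within_half_window(self):
        params = bd.DetectionParams()
        x = np.concatenate([sine(10, 5, amp=50), np.zeros(int(5 * FS)), sine(10, 5, amp=50)])
        sup = bd.detect_suppressions(x, FS, params)
        assert len(sup) == 1
        assert sup[0].onset == pytest.approx(5.0, abs=params.w_env / 2)
        assert sup[0].end == pytest.approx(10.0, abs=params.w_env / 2)

    @settings(max_examples=60, deadline=None)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_one_sample_window_equals_brute_force_scan(self, seed):
        """With w_env of one sample and no minimum duration, the detector
        must reproduce an independent per-sample |x| < theta scan."""
        rng = np.random.default_rng(seed)
        n = int(10 * FS)
        # piecewise signal alternating quiet and loud stretches
        x = rng.normal(0, rng.choice([1.0, 20.0], size=n))
        params = bd.DetectionParams(theta_supp=5.0, w_env=1 / FS, d_supp_min=1 / FS)
        got = bd.detect_suppressions(x, FS, params)
        # oracle: boolean scan, maximal runs
        below = np.abs(x) < 5.0
        oracle = []
        i = 0
        while i < n:
            if below[i]:
                j = i
                while j < n and below[j]:
                    j += 1
                oracle.append((i / FS, j / FS))
                i = j
            else:
                i += 1
        assert [(s.onset, s.end) for s in got] == [
            (pytest.approx(a), pytest.approx(b)) for a, b in oracle
        ]

    def test_bs_duration_monotone_in_threshold(self, rng):
        """A larger suppression threshold can only classify more samples as
        suppressed, so total detected duration is non-decreasing in theta."""
        x = rng.normal(0, 6.0, size=int(20 * FS))
        durs = []
        for theta in [1, 3, 5, 8, 12, 20]:
            p = bd.DetectionParams(theta_supp=float(theta), d_supp_min=1 / FS)
            durs.append(sum(s.duration for s in bd.detect_suppressions(x, FS, p)))
        assert all(a <= b + 1e-12 for a, b in zip(durs, durs[1:]))


class TestPhases:
    def test_half_cycle_is_one_phase(self):
        seg = np.sin(np.linspace(0, np.pi, 90, endpoint=False))
        assert bd.count_phases(seg) == 1

    def test_full_cycle_is_two_phases(self):
        # one interior zero crossing + 1
        seg = np.sin(np.linspace(0, 2 * np.pi, 178, endpoint=False))
        assert bd.count_phases(seg) == 2

    def test_point_six_seconds_of_ten_hz_is_twelve_phases(self):
        # 0.6 s x 10 Hz = 6 cycles = 12 half-waves; brute-force crossing count agrees
        seg = sine(10, 0.6)
        centered = seg - seg.mean()
        s = np.sign(centered)
        s = s[s != 0]
        brute = int(np.count_nonzero(np.diff(s))) + 1
        assert bd.count_phases(seg) == brute == 12

    def test_too_short_segment_rejected(self):
        with pytest.raises(ParameterError):
            bd.count_phases(np.array([1.0]))


class TestBursts:
    def _channel_with_gap(self, gap_dur, gap_freq=10.0, amp=40.0):
        """5 s silence | gap of oscillation | 5 s silence."""
        quiet = np.zeros(int(5 * FS))
        gap = sine(gap_freq, gap_dur, amp=amp)
        return np.concatenate([quiet, gap, quiet])

    def test_polyphasic_gap_is_a_burst(self):
        params = bd.DetectionParams()
        x = self._channel_with_gap(1.0)
        sup = bd.detect_suppressions(x, FS, params)
        bursts = bd.detect_bursts(x, FS, sup, params)
        assert len(bursts) == 1
        assert bursts[0].duration == pytest.approx(1.0, abs=params.w_env)

    def test_short_gap_rejected(self):
        # exact suppression intervals around a 0.3 s gap: 0.3 < 0.5 minimum
        params = bd.DetectionParams()
        x = self._channel_with_gap(0.3, amp=200.0)
        sup = [
            bd.Interval(0.0, 5.0, "suppression"),
            bd.Interval(5.3, 5.0, "suppression"),
        ]
        bursts = bd.detect_bursts(x, FS, sup, params)
        assert bursts == []

    def test_no_suppressions_no_bursts(self):
        params = bd.DetectionParams()
        x = sine(10, 10, amp=50)
        assert bd.detect_bursts(x, FS, [], params) == []

    def test_oligophasic_gap_rejected(self):
        # 1 s at 1 Hz = 2 phases < 4
        params = bd.DetectionParams()
        x = self._channel_with_gap(1.0, gap_freq=1.0, amp=200.0)
        sup = bd.detect_suppressions(x, FS, params)
        bursts = bd.detect_bursts(x, FS, sup, params)
        assert bursts == []


class TestConsensus:
    def test_all_flat_channels_full_consensus(self):
        params = bd.DetectionParams()
        n = int(10 * FS)
        sups = [bd.detect_suppressions(np.zeros(n), FS, params) for _ in range(4)]
        cons = bd.consensus_mask(sups, params, n, FS)
        assert len(cons) == 1 and cons[0].duration == pytest.approx(10.0)

    def test_one_active_channel_vetoes_consensus(self):
        params = bd.DetectionParams()
        n = int(10 * FS)
        flat = [bd.detect_suppressions(np.zeros(n), FS, params) for _ in range(3)]
        active = bd.detect_suppressions(sine(10, 10, amp=50), FS, params)
        cons = bd.consensus_mask(flat + [active], params, n, FS)
        assert cons == []

    def test_consensus_is_interval_intersection(self):
        params = bd.DetectionParams()
        n = int(6 * FS)
        a = [bd.Interval(0.0, 4.0, "suppression", "Fp1")]
        b = [bd.Interval(2.0, 4.0, "suppression", "Fp2")]
        rest = [[bd.Interval(0.0, 6.0, "suppression", c)] for c in ("F7", "F8")]
        cons = bd.consensus_mask([a, b] + rest, params, n, FS)
        assert len(cons) == 1
        assert cons[0].onset == pytest.approx(2.0, abs=1 / FS)
        assert cons[0].end == pytest.approx(4.0, abs=1 / FS)

    @settings(max_examples=30, deadline=None)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_consensus_contained_in_each_channel(self, seed):
        rng = np.random.default_rng(seed)
        params = bd.DetectionParams(d_supp_min=2 / FS)
        n = int(8 * FS)
        chans = [rng.normal(0, rng.choice([1.0, 20.0], size=n)) for _ in range(3)]
        sups = [bd.detect_suppressions(c, FS, params) for c in chans]
        cons = bd.consensus_mask(sups, params, n, FS)
        for channel_sups in sups:
            for civ in cons:
                assert any(
                    s.onset <= civ.onset + 1e-9 and civ.end <= s.end + 1e-9
                    for s in channel_sups
                )


class TestEpochs:
    def test_chaining_within_gap_limit(self):
        params = bd.DetectionParams()
        sups = [bd.Interval(10.0, 2.0, "suppression"), bd.Interval(15.0, 2.0, "suppression")]
        epochs = bd.delimit_bs_epochs(sups, params)
        assert len(epochs) == 1
        assert (epochs[0].onset, epochs[0].end) == (10.0, 17.0)

    def test_split_beyond_gap_limit(self):
        params = bd.DetectionParams()
        sups = [bd.Interval(10.0, 2.0, "suppression"), bd.Interval(100.0, 2.0, "suppression")]
        epochs = bd.delimit_bs_epochs(sups, params)
        assert len(epochs) == 2

    def test_single_suppression_is_its_own_epoch(self):
        params = bd.DetectionParams()
        sups = [bd.Interval(3.0, 1.5, "suppression")]
        epochs = bd.delimit_bs_epochs(sups, params)
        assert (epochs[0].onset, epochs[0].duration) == (3.0, 1.5)

    def test_no_suppressions_no_epochs(self):
        assert bd.delimit_bs_epochs([], bd.DetectionParams()) == []


class TestSummarize:
    def _recording(self, channels):
        return bd.EEGRecording(
            np.vstack(channels), fs=FS, channel_labels=[f"c{i}" for i in range(len(channels))]
        )

    def test_bsr_arithmetic(self):
        # 300 s with 30 s of all-channel silence -> BSR 10%
        active = sine(10, 135, amp=50)
        x = np.concatenate([active, np.zeros(int(30 * FS)), active])
        rec = self._recording([x, x.copy()])
        s = bd.summarize(rec)
        assert s.bsr == pytest.approx(10.0, abs=0.2)
        assert s.bs_duration == pytest.approx(30.0, abs=0.5)
        assert 0 <= s.bs_duration <= s.epoch_span + 1e-9
        assert s.epoch_span <= s.analyzed_duration

    def test_fully_active_recording(self):
        rec = self._recording([sine(10, 60, amp=50)] * 4)
        s = bd.summarize(rec)
        assert s.bs_duration == 0.0
        assert not s.any_bs
        assert s.episodes == []

    def test_any_bs_is_derived_from_duration(self):
        rec = self._recording([np.zeros(int(10 * FS))] * 2)
        s = bd.summarize(rec)
        assert s.any_bs and s.bs_duration > 0

    def test_recording_shorter_than_window_rejected(self):
        rec = self._recording([np.zeros(10)])
        with pytest.raises(ParameterError):
            bd.summarize(rec, bd.DetectionParams(w_env=0.5))

    def test_recovers_injected_ground_truth_within_boundary_smear(self):
        """Detected total suppression equals injected truth up to envelope
        boundary smearing (at most w_env per episode boundary)."""
        params = bd.DetectionParams()
        spec = bd.EEGSimSpec(
            agent="propofol",
            duration=300.0,
            episode_plan=[
                bd.Episode(onset=50.0, supp_duration=10.0, burst_duration=1.0, n_alternations=3),
                bd.Episode(onset=200.0, supp_duration=23.0, burst_duration=1.0, n_alternations=0),
            ],
            seed=11,
        )
        rec, truth = bd.generate_eeg(spec)
        s = bd.summarize(rec, params)
        true_total = truth.total_duration("suppression")
        assert true_total == pytest.approx(63.0)
        n_boundaries = 2 * len(truth.select("suppression"))
        assert abs(s.bs_duration - true_total) <= params.w_env * n_boundaries

    def test_bsr_invariant_under_resampling(self):
        """For a piecewise-constant signal the BSR is a time fraction and
        must not depend on the sampling rate."""
        bsrs = []
        for fs in (100.0, 178.0, 400.0):
            x = np.concatenate(
                [np.full(int(20 * fs), 50.0), np.zeros(int(10 * fs)), np.full(int(20 * fs), 50.0)]
            )
            rec = bd.EEGRecording(np.vstack([x, x]), fs=fs, channel_labels=["a", "b"])
            bsrs.append(bd.summarize(rec).bsr)
        assert max(bsrs) - min(bsrs) < 0.1
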