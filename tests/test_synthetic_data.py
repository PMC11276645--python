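"""Stochastic trace generation, filtering and trace I/O."""

import numpy as np
import pytest
from scipy import stats

from clcgating import (
    ChannelSpec,
    IonCondition,
    Protocol,
    Trace,
    apply_filter,
    build_generator,
    read_trace,
    simulate_macroscopic,
    simulate_single_channel,
    simulate_single_channel_events,
    stationary_distribution,
    write_trace,
)

from conftest import recovery_protocol, two_state_scheme


COND = IonCondition(v_m=-60.0)


def locked_open_spec(fo, fc, noise=0.06, amp=-0.6):
    """Slow gate pinned open; only the two fast gates move."""
    return ChannelSpec(
        slow_scheme=two_state_scheme(0.0, 0.1),
        fast_open_rate=fo,
        fast_close_rate=fc,
        single_pore_amplitude=amp,
        noise_sd=noise,
    )


class TestSingleChannel:
    def test_seed_determinism_bitwise(self):
        spec = locked_open_spec(0.05, 0.05)
        proto = Protocol(segments=[(2000.0, COND)], sampling_interval=0.5)
        a = simulate_single_channel(spec, proto, 99)
        b = simulate_single_channel(spec, proto, 99)
        assert np.array_equal(a.samples, b.samples)
        c = simulate_single_channel(spec, proto, 100)
        assert not np.array_equal(a.samples, c.samples)

    def test_trace_length_matches_protocol(self):
        spec = locked_open_spec(0.05, 0.05)
        proto = Protocol(segments=[(1234.5, COND)], sampling_interval=0.5)
        trace = simulate_single_channel(spec, proto, 1)
        assert abs(trace.duration - 1234.5) <= trace.dt

    def test_locked_open_constant_current(self):
        # fast rates zero: both pores stay open -> two-pore current + noise
        spec = locked_open_spec(0.0, 0.0, noise=0.06)
        proto = Protocol(segments=[(5000.0, COND)], sampling_interval=0.5)
        trace = simulate_single_channel(spec, proto, 3)
        se = 0.06 / np.sqrt(len(trace.samples))
        assert abs(trace.samples.mean() - 2 * (-0.6)) < 3 * se

    def test_binomial_level_occupancies_at_half_open(self):
        # stationary fast-gate open prob 0.5 -> levels 0/1/2 occupy 1/4, 1/2, 1/4
        spec = locked_open_spec(0.05, 0.05, noise=0.0)
        proto = Protocol(segments=[(200000.0, COND)], sampling_interval=0.5)
        _, events = simulate_single_channel_events(spec, proto, 8)
        total = sum(d for _, d in events)
        frac = {
            lv: sum(d for l, d in events if l == lv) / total for lv in (0, 1, 2)
        }
        n_events = len(events)
        tol = 4.0 / np.sqrt(n_events)
        assert frac[0] == pytest.approx(0.25, abs=tol)
        assert frac[1] == pytest.approx(0.5, abs=tol)
        assert frac[2] == pytest.approx(0.25, abs=tol)

    def test_acidic_segment_reduces_conducting_fraction(self, c212s_scheme):
        spec = ChannelSpec(
            slow_scheme=c212s_scheme,
            fast_open_rate=0.0,
            fast_close_rate=0.0,
            single_pore_amplitude=-0.6,
            noise_sd=0.0,
        )
        proto = recovery_protocol(pre_ms=2000.0, acid_ms=2000.0, rec_ms=100.0, dt=0.5)
        trace = simulate_single_channel(spec, proto, 21)
        t = trace.times
        frac_neutral = np.mean(trace.samples[t < 2000.0] != 0.0)
        frac_acid = np.mean(trace.samples[(t >= 2000.0) & (t < 4000.0)] != 0.0)
        assert frac_acid < frac_neutral

    def test_slow_gate_time_fractions_match_stationary_distribution(self):
        # chi-square goodness of fit of simulated state occupancy, alpha=0.01
        scheme = two_state_scheme(0.01, 0.02)  # pi = (2/3, 1/3)
        gen = build_generator(scheme, "pH7.4")
        pi = stationary_distribution(gen)
        spec = ChannelSpec(
            slow_scheme=scheme, fast_open_rate=0.0, fast_close_rate=0.0,
            single_pore_amplitude=-0.6, noise_sd=0.0,
        )
        proto = Protocol(segments=[(100000.0, COND)], sampling_interval=1.0)
        open_time = np.zeros(2)
        n_rep = 8
        for rep in range(n_rep):
            trace = simulate_single_channel(spec, proto, 500 + rep)
            is_open = trace.samples != 0.0
            open_time += [is_open.sum(), (~is_open).sum()]
        expected = pi * open_time.sum()
        # effective sample count: dwell pairs, not correlated samples
        n_eff = n_rep * 100000.0 * (0.01 * 0.02) / (0.01 + 0.02)
        observed_eff = open_time / open_time.sum() * n_eff
        expected_eff = pi * n_eff
        chi2 = np.sum((observed_eff - expected_eff) ** 2 / expected_eff)
        assert stats.chi2.sf(chi2, df=1) > 0.01

    def test_mean_closed_dwell_matches_fast_open_rate(self):
        # one pore so closed dwells are pure exponential(1/fo)
        spec = ChannelSpec(
            slow_scheme=two_state_scheme(0.0, 0.1),
            fast_open_rate=0.1,
            fast_close_rate=0.1,
            n_pores=1,
            single_pore_amplitude=-0.6,
            noise_sd=0.0,
        )
        proto = Protocol(segments=[(150000.0, COND)], sampling_interval=1.0)
        _, events = simulate_single_channel_events(spec, proto, 17)
        closed = [d for lv, d in events[1:-1] if lv == 0]
        assert len(closed) >= 5000
        assert np.mean(closed) == pytest.approx(1.0 / 0.1, rel=0.05)


class TestMacroscopic:
    def test_deterministic_decay_is_exact_exponential(self):
        # irreversible two-state closure: current is A exp(-t/tau) exactly
        scheme = two_state_scheme(0.002, 0.0)
        spec = ChannelSpec(slow_scheme=scheme, single_pore_amplitude=-0.6, noise_sd=0.0)
        proto = Protocol(
            segments=[(3000.0, IonCondition(v_m=-60.0))], sampling_interval=1.0
        )
        trace = simulate_macroscopic(spec, proto, 100, mode="deterministic", seed=0)
        expected = 100 * 2 * (-0.6) * np.exp(-trace.times * 0.002)
        assert np.max(np.abs(trace.samples - expected)) < 1e-8

    def test_ensemble_mean_within_clt_envelope_of_deterministic(self, c212s_scheme):
        proto = recovery_protocol(pre_ms=200.0, acid_ms=300.0, rec_ms=1500.0, dt=1.0)
        spec = ChannelSpec(slow_scheme=c212s_scheme, single_pore_amplitude=-0.6, noise_sd=0.0)
        n_ch = 400
        det = simulate_macroscopic(spec, proto, n_ch, mode="deterministic", seed=1)
        ens = simulate_macroscopic(spec, proto, n_ch, mode="ensemble", seed=1)
        # per-channel current is in [-1.2, 0]: bound the SD by half the range
        envelope = 4.0 * np.sqrt(n_ch) * 0.6
        assert np.max(np.abs(ens.samples - det.samples)) < envelope

    def test_single_channel_consistency_at_n_1(self, c212s_scheme):
        proto = recovery_protocol(pre_ms=100.0, acid_ms=100.0, rec_ms=100.0, dt=1.0)
        spec = ChannelSpec(slow_scheme=c212s_scheme, single_pore_amplitude=-0.6, noise_sd=0.0)
        ens = simulate_macroscopic(spec, proto, 1, mode="ensemble", seed=4)
        # a single noiseless channel only visits (time-averages of) the
        # discrete levels 0, -0.6, -1.2 pA
        assert ens.samples.min() >= -1.2 - 1e-9 and ens.samples.max() <= 1e-9

    def test_rejects_bad_mode_and_channel_count(self, c212s_scheme):
        proto = recovery_protocol(rec_ms=100.0)
        spec = ChannelSpec(slow_scheme=c212s_scheme)
        with pytest.raises(ValueError):
            simulate_macroscopic(spec, proto, 0)
        with pytest.raises(ValueError):
            simulate_macroscopic(spec, proto, 10, mode="bogus")


class TestFilter:
    def test_constant_trace_unchanged(self):
        trace = Trace(t0=0.0, dt=0.5, samples=np.full(4000, -3.2))
        out = apply_filter(trace, 5.0)
        assert np.max(np.abs(out.samples + 3.2)) < 1e-9

    def test_white_noise_sd_reduction_at_heavy_filtering(self):
        rng = np.random.default_rng(0)
        trace = Trace(t0=0.0, dt=0.5, samples=rng.normal(0.0, 1.0, 200000))
        out = apply_filter(trace, 5.0)
        assert trace.samples.std() / out.samples.std() >= 10.0

    def test_long_square_pulse_plateau_preserved(self):
        dt = 0.5
        y = np.zeros(20000)
        y[5000:15000] = -2.0  # 5000 ms pulse >> 3.3 ms rise time at 100 Hz
        out = apply_filter(Trace(t0=0.0, dt=dt, samples=y), 100.0)
        plateau = out.samples[9000:11000]
        assert np.max(np.abs(plateau + 2.0)) < 0.002  # 0.1% of amplitude

    def test_cutoff_at_or_above_nyquist_raises(self):
        trace = Trace(t0=0.0, dt=0.5, samples=np.zeros(100))
        with pytest.raises(ValueError):
            apply_filter(trace, 1000.0)  # Nyquist for dt=0.5 ms


class TestTraceIO:
    def test_round_trip_is_bitwise(self, tmp_path):
        rng = np.random.default_rng(1)
        trace = Trace(
            t0=0.0, dt=0.5, samples=rng.normal(0, 1, 500),
            meta={"seed": 1, "note": "fixture"},
        )
        path = tmp_path / "trace.csv"
        write_trace(trace, path)
        back = read_trace(path)
        assert np.array_equal(trace.samples, back.samples)
        assert back.dt == trace.dt
        assert back.meta == trace.meta

    def test_missing_header_raises_with_line_number(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("time_ms,current_pA\n0.0,1.0\n")
        with pytest.raises(ValueError, match="dt_ms"):
            read_trace(path)

    def test_malformed_row_names_line(self, tmp_path):
        path = tmp_path / "bad2.csv"
        path.write_text("# dt_ms=0.5\ntime_ms,current_pA\n0.0,1.0\n0.5,oops\n")
        with pytest.raises(ValueError, match=":4:"):
            read_trace(path)

    def test_sample_count_mismatch_warns(self, tmp_path):
        path = tmp_path / "warn.csv"
        path.write_text("# dt_ms=0.5\n# n_samples=3\ntime_ms,current_pA\n0.0,1.0\n0.5,2.0\n")
        with pytest.warns(UserWarning, match="declares 3"):
            read_trace(path)
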