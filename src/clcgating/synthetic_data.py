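"""Synthetic patch-clamp traces for a two-protopore channel with a common slow gate.

This module stands in for the unpublished recordings the analysis stages were
designed for.  A channel is two independent protopores (millisecond "fast"
gating, current levels 0/1/2) in series with one common slow gate modelled by
a :class:`~clcgating.kinetic_model.StateScheme`: when the slow gate occupies
any nonconducting state both pores are silent.  Traces are produced by exact
event-driven (Gillespie) simulation of the joint process with exponential
waiting times, binned to the sampling grid by time-weighted averaging within
each sample, then overlaid with additive white Gaussian recording noise.
Macroscopic currents come either from the deterministic occupancy solution or
from summing independent stochastic channels.

Acquisition emulation follows typical settings: 5 kHz sampling with a 1 kHz
Gaussian filter for macroscopic work, 2 kHz sampling for single-channel
presets, with 100 Hz and 5 Hz zero-phase Gaussian filters applied at analysis
time (see :func:`apply_filter`).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Union

import numpy as np
from scipy import linalg as sla
from scipy.ndimage import gaussian_filter1d

from .conditions import IonCondition, Protocol
from .kinetic_model import StateScheme, build_generator, occupancy

__all__ = [
    "Trace",
    "ChannelSpec",
    "simulate_single_channel",
    "simulate_macroscopic",
    "apply_filter",
    "write_trace",
    "read_trace",
]

# -3 dB relation for a Gaussian filter: |H(f)| = exp(-2 pi^2 sigma_t^2 f^2),
# so sigma_t = sqrt(ln 2) / (2 pi f_c).
_GAUSS_SIGMA_FACTOR = float(np.sqrt(np.log(2.0)) / (2.0 * np.pi))


@dataclass
class Trace:
    """Uniformly sampled current record.

    ``samples`` are in pA (or dimensionless after normalization); ``dt`` is
    the sampling interval in ms; sample i is the time-average of the current
    over [t0 + i*dt, t0 + (i+1)*dt).  ``meta`` carries provenance (seed,
    protocol, amplitudes, filter cutoffs, normalization divisor, ...).
    """

    t0: float
    dt: float
    samples: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be > 0 ms")
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be 1-D")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")

    @property
    def times(self) -> np.ndarray:
        """Left-edge sample times in ms."""
        return self.t0 + np.arange(len(self.samples)) * self.dt

    @property
    def duration(self) -> float:
        return len(self.samples) * self.dt


@dataclass(frozen=True)
class ChannelSpec:
    """Kinetic description of one channel for simulation.

    ``fast_open_rate`` / ``fast_close_rate`` (1/ms) may be scalars or mappings
    {condition_label: rate}.  ``single_pore_amplitude`` is the one-pore
    current (pA) at ``reference_driving_force`` (mV); the instantaneous
    amplitude scales linearly with the driving force V_m - E_rev of the
    active condition (set ``reference_driving_force=None`` to disable the
    scaling).  ``noise_sd`` defaults to 0.1x the single-pore amplitude.
    """

    slow_scheme: StateScheme
    fast_open_rate: Union[float, Mapping[str, float]] = 0.0
    fast_close_rate: Union[float, Mapping[str, float]] = 0.0
    n_pores: int = 2
    single_pore_amplitude: float = -0.6
    reference_driving_force: Optional[float] = -60.0
    noise_sd: Optional[float] = None

    def __post_init__(self) -> None:
        if self.n_pores < 1:
            raise ValueError("n_pores must be >= 1")
        if self.noise_sd is not None and self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def _rate(self, table, label: str) -> float:
        r = table.get(label, table.get("default", 0.0)) if isinstance(table, Mapping) else float(table)
        if r < 0:
            raise ValueError("fast-gate rates must be >= 0")
        return r

    def fast_rates(self, label: str) -> tuple[float, float]:
        return (self._rate(self.fast_open_rate, label), self._rate(self.fast_close_rate, label))

    @property
    def noise_sd_pA(self) -> float:
        return self.noise_sd if self.noise_sd is not None else 0.1 * abs(self.single_pore_amplitude)


def _amplitude_scale(spec: ChannelSpec, cond: IonCondition) -> float:
    if spec.reference_driving_force is None:
        return 1.0
    return cond.driving_force_mv() / spec.reference_driving_force


def _bin_piecewise(breaks, values, n_samples: int, dt: float) -> np.ndarray:
    """Time-weighted average of a piecewise-constant signal on a uniform grid.

    ``breaks``: ascending change times including 0 and the final time;
    ``values[k]`` holds on [breaks[k], breaks[k+1]).
    """
    acc = np.zeros(n_samples)
    for k in range(len(values)):
        ta, tb, v = breaks[k], breaks[k + 1], values[k]
        if v == 0.0 or tb <= ta:
            continue
        i0 = min(int(ta / dt), n_samples - 1)
        i1 = min(int(tb / dt - 1e-12), n_samples - 1)
        if i0 == i1:
            acc[i0] += v * (tb - ta)
        else:
            acc[i0] += v * ((i0 + 1) * dt - ta)
            acc[i1] += v * (tb - i1 * dt)
            if i1 > i0 + 1:
                acc[i0 + 1 : i1] += v * dt
    return acc / dt


def _gillespie_path(
    spec: ChannelSpec, protocol: Protocol, rng: np.random.Generator
) -> tuple[list[float], list[int], list[float]]:
    """Exact event-driven path of the joint (slow gate, pore gates) process.

    Returns ``(breaks, levels, currents)``: ``levels[k]`` (number of open
    pores if the slow gate conducts, else 0) and ``currents[k]`` (pA before
    noise) hold on [breaks[k], breaks[k+1]).
    """
    scheme = spec.slow_scheme
    conducting = scheme.conducting_vector().astype(bool)
    slow_state = 0  # start in the first state (conventionally the open state)
    pores = np.ones(spec.n_pores, dtype=bool)
    breaks = [0.0]
    levels: list[int] = []
    currents: list[float] = []
    t_global = 0.0

    for seg_dur, cond in protocol.segments:
        label = cond.rate_label
        gen = build_generator(scheme, label, v_m=cond.v_m)
        fo, fc = spec.fast_rates(label)
        amp = spec.single_pore_amplitude * _amplitude_scale(spec, cond)
        t_seg_end = t_global + seg_dur
        while t_global < t_seg_end:
            is_open = conducting[slow_state]
            slow_rates = np.clip(gen.q[slow_state].copy(), 0.0, None)
            slow_rates[slow_state] = 0.0
            pore_rates = np.where(pores, fc, fo) if is_open else np.zeros(spec.n_pores)
            total = slow_rates.sum() + pore_rates.sum()
            level = int(pores.sum()) if is_open else 0
            if total <= 0.0:
                if len(protocol.segments) > 1:
                    warnings.warn(
                        f"no transitions available from state "
                        f"{scheme.state_names[slow_state]!r} in condition {label!r}; "
                        "state frozen for the segment",
                        stacklevel=3,
                    )
                t_event = t_seg_end
            else:
                t_event = t_global + rng.exponential(1.0 / total)
            if t_event >= t_seg_end:
                breaks.append(t_seg_end)
                levels.append(level)
                currents.append(level * amp)
                t_global = t_seg_end
                break
            breaks.append(t_event)
            levels.append(level)
            currents.append(level * amp)
            t_global = t_event
            u = rng.uniform(0.0, total)
            if u < slow_rates.sum():
                slow_state = int(np.searchsorted(np.cumsum(slow_rates), u, side="right"))
            else:
                u -= slow_rates.sum()
                pore = int(np.searchsorted(np.cumsum(pore_rates), u, side="right"))
                pores[pore] = ~pores[pore]
    return breaks, levels, currents


def simulate_single_channel(spec: ChannelSpec, protocol: Protocol, seed: int) -> Trace:
    """Exact stochastic simulation of one channel under a protocol.

    Event-driven Gillespie simulation of the joint (slow gate, pore gates)
    process.  While the slow gate is conducting, the pores open and close
    independently with the condition's fast rates and the current level is
    the number of open pores; in any nonconducting slow-gate state the pores
    are silent and their gates frozen.  The level path is binned to the
    sampling grid by time-weighted averaging, scaled to pA by the single-pore
    amplitude and driving force, and Gaussian noise is added.  Identical
    (spec, protocol, seed) yield identical traces.
    """
    rng = np.random.default_rng(seed)
    if protocol.exchange_tau > 0:
        warnings.warn(
            "stochastic simulation treats solution exchange as instantaneous; "
            "exchange_tau is honoured only by deterministic macroscopic mode",
            stacklevel=2,
        )
    dt = protocol.sampling_interval
    n_samples = int(round(protocol.total_duration / dt))
    breaks, _levels, currents = _gillespie_path(spec, protocol, rng)
    samples = _bin_piecewise(breaks, currents, n_samples, dt)
    if spec.noise_sd_pA > 0:
        samples = samples + rng.normal(0.0, spec.noise_sd_pA, n_samples)
    meta = {
        "kind": "single_channel",
        "seed": int(seed) if np.isscalar(seed) else None,
        "n_channels": 1,
        "single_pore_amplitude_pA": spec.single_pore_amplitude,
        "noise_sd_pA": spec.noise_sd_pA,
        "segments": [[d, c.rate_label] for d, c in protocol.segments],
    }
    return Trace(t0=0.0, dt=dt, samples=samples, meta=meta)


def _deterministic_occupancy_path(
    scheme: StateScheme, protocol: Protocol, p0: np.ndarray, times: np.ndarray
) -> np.ndarray:
    """Occupancy at sample times across protocol segments (piecewise generator).

    When ``exchange_tau`` > 0 the generator of each segment is blended with
    the previous segment's via w(t) = 1 - exp(-dt/tau) on a fine sub-grid
    (first 6 exchange time constants), stepping with the matrix exponential.
    """
    n_states = scheme.n_states
    out = np.empty((len(times), n_states))
    p = np.asarray(p0, dtype=float)
    t_seg = 0.0
    idx = 0
    prev_gen = None
    for seg_dur, cond in protocol.segments:
        gen = build_generator(scheme, cond.rate_label, v_m=cond.v_m)
        t_end = t_seg + seg_dur
        in_seg = (times >= t_seg) & (times < t_end)
        seg_times = times[in_seg]
        tau_x = protocol.exchange_tau
        if tau_x > 0 and prev_gen is not None:
            # blend generators on a fine grid over the exchange transient
            t_mix_end = min(t_seg + 6.0 * tau_x, t_end)
            n_sub = max(int(np.ceil((t_mix_end - t_seg) / (tau_x / 20.0))), 1)
            sub_edges = np.linspace(t_seg, t_mix_end, n_sub + 1)
            p_grid, p_run, t_run = [], p.copy(), t_seg
            eval_pts = list(seg_times[seg_times < t_mix_end])
            for a, b in zip(sub_edges[:-1], sub_edges[1:]):
                w = 1.0 - np.exp(-((a + b) / 2.0 - t_seg) / tau_x)
                q_mix = (1.0 - w) * prev_gen.q + w * gen.q
                step = sla.expm(q_mix * (b - a))
                while eval_pts and eval_pts[0] < b:
                    frac_step = sla.expm(q_mix * (eval_pts.pop(0) - a))
                    p_grid.append(p_run @ frac_step)
                p_run = p_run @ step
            for row in p_grid:
                out[idx] = row
                idx += 1
            p = p_run
            t_seg_eff = t_mix_end
            seg_times = seg_times[seg_times >= t_mix_end]
        else:
            t_seg_eff = t_seg
        if len(seg_times):
            occ = occupancy(
                build_generator(scheme, cond.rate_label, v_m=cond.v_m),
                p / p.sum(),
                seg_times - t_seg_eff,
            )
            out[idx : idx + len(seg_times)] = occ
            idx += len(seg_times)
        # advance p to the end of the segment
        p = occupancy(gen, p / p.sum(), np.array([t_end - t_seg_eff]))[0]
        prev_gen = gen
        t_seg = t_end
    if idx < len(times):  # times exactly at the protocol end
        out[idx:] = p
    return out


def simulate_macroscopic(
    spec: ChannelSpec,
    protocol: Protocol,
    n_channels: int,
    mode: str = "deterministic",
    seed: int = 0,
) -> Trace:
    """Macroscopic (many-channel) current under a protocol.

    ``deterministic`` mode evaluates n_channels x P(conducting)(t) x
    (stationary fast-gate open pores) x single-pore amplitude from the
    occupancy solution; ``ensemble`` mode sums independent stochastic
    channels.  Both add one Gaussian noise realisation at the end.
    """
    if n_channels < 1:
        raise ValueError("n_channels must be >= 1")
    if mode not in ("deterministic", "ensemble"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    dt = protocol.sampling_interval
    n_samples = int(round(protocol.total_duration / dt))
    noise_sd = spec.noise_sd_pA

    if mode == "ensemble":
        quiet = ChannelSpec(
            slow_scheme=spec.slow_scheme,
            fast_open_rate=spec.fast_open_rate,
            fast_close_rate=spec.fast_close_rate,
            n_pores=spec.n_pores,
            single_pore_amplitude=spec.single_pore_amplitude,
            reference_driving_force=spec.reference_driving_force,
            noise_sd=0.0,
        )
        total = np.zeros(n_samples)
        child_seeds = np.random.SeedSequence(seed).spawn(n_channels)
        for ss in child_seeds:
            total += simulate_single_channel(quiet, protocol, ss).samples
        samples = total
    else:
        scheme = spec.slow_scheme
        times = np.arange(n_samples) * dt
        p0 = np.zeros(scheme.n_states)
        p0[0] = 1.0
        occ = _deterministic_occupancy_path(scheme, protocol, p0, times)
        p_cond = occ @ scheme.conducting_vector()
        samples = np.zeros(n_samples)
        t_seg = 0.0
        for seg_dur, cond in protocol.segments:
            fo, fc = spec.fast_rates(cond.rate_label)
            p_fast = 1.0 if fo + fc == 0 else fo / (fo + fc)
            amp = spec.single_pore_amplitude * _amplitude_scale(spec, cond)
            in_seg = (times >= t_seg) & (times < t_seg + seg_dur)
            samples[in_seg] = n_channels * p_cond[in_seg] * spec.n_pores * p_fast * amp
            t_seg += seg_dur
    if noise_sd > 0:
        samples = samples + rng.normal(0.0, noise_sd, n_samples)
    meta = {
        "kind": f"macroscopic_{mode}",
        "seed": int(seed),
        "n_channels": int(n_channels),
        "single_pore_amplitude_pA": spec.single_pore_amplitude,
        "noise_sd_pA": noise_sd,
        "segments": [[d, c.rate_label] for d, c in protocol.segments],
    }
    return Trace(t0=0.0, dt=dt, samples=samples, meta=meta)


def simulate_single_channel_events(
    spec: ChannelSpec, protocol: Protocol, seed: int
) -> tuple[Trace, list[tuple[int, float]]]:
    """Like :func:`simulate_single_channel` but also return the true level path.

    The second element is the exact merged (level, duration-ms) event list of
    the underlying Gillespie path — ground truth for idealization benchmarks.
    """
    rng = np.random.default_rng(seed)
    dt = protocol.sampling_interval
    n_samples = int(round(protocol.total_duration / dt))
    breaks, levels, currents = _gillespie_path(spec, protocol, rng)
    samples = _bin_piecewise(breaks, currents, n_samples, dt)
    if spec.noise_sd_pA > 0:
        samples = samples + rng.normal(0.0, spec.noise_sd_pA, n_samples)
    trace = Trace(
        t0=0.0,
        dt=dt,
        samples=samples,
        meta={
            "kind": "single_channel",
            "seed": int(seed),
            "n_channels": 1,
            "single_pore_amplitude_pA": spec.single_pore_amplitude,
            "noise_sd_pA": spec.noise_sd_pA,
        },
    )
    events: list[tuple[int, float]] = []
    for k, lv in enumerate(levels):
        dur = breaks[k + 1] - breaks[k]
        if dur <= 0:
            continue
        if events and events[-1][0] == lv:
            events[-1] = (lv, events[-1][1] + dur)
        else:
            events.append((int(lv), dur))
    return trace, events


def apply_filter(trace: Trace, cutoff_hz: float) -> Trace:
    """Zero-phase Gaussian low-pass with its -3 dB point at ``cutoff_hz``.

    DC gain is exactly 1 (edge handling by nearest-sample extension), so the
    mean of long traces is preserved.  Raises when the cutoff is at or above
    the Nyquist frequency of the trace.
    """
    nyquist_hz = 1000.0 / (2.0 * trace.dt)
    if cutoff_hz <= 0:
        raise ValueError("cutoff_hz must be > 0")
    if cutoff_hz >= nyquist_hz:
        raise ValueError(f"cutoff {cutoff_hz} Hz >= Nyquist {nyquist_hz} Hz")
    sigma_ms = _GAUSS_SIGMA_FACTOR / (cutoff_hz / 1000.0)
    filtered = gaussian_filter1d(trace.samples, sigma_ms / trace.dt, mode="nearest")
    meta = dict(trace.meta)
    meta["cutoff_hz"] = float(cutoff_hz)
    return Trace(t0=trace.t0, dt=trace.dt, samples=filtered, meta=meta)


def gaussian_rise_time_ms(cutoff_hz: float) -> float:
    """10-90% step rise time of the Gaussian filter in ms (~0.3321/f_c)."""
    return 0.3321 / cutoff_hz * 1000.0


def write_trace(trace: Trace, path) -> None:
    """Write a trace as delimited text with a comment-prefixed header."""
    with open(path, "w") as fh:
        fh.write(f"# dt_ms={trace.dt!r}\n")
        fh.write(f"# t0_ms={trace.t0!r}\n")
        fh.write(f"# n_samples={len(trace.samples)}\n")
        fh.write(f"# meta_json={json.dumps(trace.meta, default=str)}\n")
        fh.write("time_ms,current_pA\n")
        for t, y in zip(trace.times, trace.samples):
            fh.write(f"{float(t)!r},{float(y)!r}\n")


def read_trace(path) -> Trace:
    """Read a trace written by :func:`write_trace`.

    Malformed content raises ``ValueError`` naming the offending line; a
    mismatch between the declared sample count and the rows found raises a
    validation warning (the data read are kept).
    """
    header: dict[str, str] = {}
    samples: list[float] = []
    saw_columns = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "=" not in line:
                    raise ValueError(f"{path}:{lineno}: malformed header line {line!r}")
                key, _, val = line[1:].partition("=")
                header[key.strip()] = val.strip()
                continue
            if not saw_columns:
                if line.replace(" ", "") != "time_ms,current_pA":
                    raise ValueError(f"{path}:{lineno}: expected column header, got {line!r}")
                saw_columns = True
                continue
            parts = line.split(",")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
            try:
                samples.append(float(parts[1]))
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-numeric current {parts[1]!r}") from None
    if "dt_ms" not in header or not saw_columns:
        raise ValueError(f"{path}: missing required header (dt_ms) or column row")
    meta = json.loads(header["meta_json"]) if "meta_json" in header else {}
    declared = header.get("n_samples")
    if declared is not None and int(declared) != len(samples):
        warnings.warn(
            f"{path}: header declares {declared} samples but {len(samples)} rows found",
            stacklevel=2,
        )
    return Trace(
        t0=float(header.get("t0_ms", 0.0)),
        dt=float(header["dt_ms"]),
        samples=np.array(samples),
        meta=meta,
    )
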