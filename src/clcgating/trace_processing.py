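"""Raw-trace conditioning and multi-level idealization.

Three stages turn a sampled current record into analysis-ready objects:

* :func:`normalize_to_preacid` rescales a macroscopic trace to the mean
  current just before the acidic solution step, the convention used for all
  recovery fits (a negative baseline current yields positive normalized
  values, since the divisor keeps its sign).
* :func:`estimate_levels` locates the discrete current levels (2 for the
  heavily filtered slow-gating view, 3 for the fast-gating view) from the
  all-points histogram via quantile-seeded 1-D k-means.
* :func:`idealize` converts the trace into an alternating (level, dwell)
  event list by half-amplitude threshold crossing with dead-time merging —
  the transparent, simulator-testable idealization standard.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks

from .synthetic_data import Trace

__all__ = [
    "IdealizedTrace",
    "LevelEstimate",
    "normalize_to_preacid",
    "estimate_levels",
    "idealize",
    "dead_time_ms",
    "write_events",
    "read_events",
]

#: Dead time as a multiple of 1/cutoff: t_d = 0.5322 / f_c, roughly twice the
#: Gaussian-filter rise time.  Events shorter than t_d are unresolvable and
#: merged into their neighbours.
DEAD_TIME_FACTOR = 0.5322


def dead_time_ms(cutoff_hz: float) -> float:
    """Default idealization dead time (ms) for a Gaussian filter cutoff."""
    return DEAD_TIME_FACTOR / cutoff_hz * 1000.0


@dataclass
class IdealizedTrace:
    """Alternating (level, dwell-duration ms) event list from a trace.

    Adjacent events always have different levels and total duration equals
    the analyzed trace duration to within one sample.  ``level_amplitudes``
    are the per-level currents (pA, ascending level index) used for the
    thresholds; ``source_cutoff_hz`` records the analysis filter.
    """

    events: Sequence[tuple[int, float]]
    level_amplitudes: Sequence[float]
    source_cutoff_hz: Optional[float] = None
    merged_events: int = 0

    def __post_init__(self) -> None:
        prev_level = None
        for lv, dur in self.events:
            if dur <= 0:
                raise ValueError("event durations must be > 0")
            if lv < 0:
                raise ValueError("levels must be >= 0")
            if prev_level is not None and lv == prev_level:
                raise ValueError("adjacent events must have different levels")
            prev_level = lv
        self.events = tuple((int(lv), float(d)) for lv, d in self.events)

    @property
    def total_duration(self) -> float:
        return sum(d for _, d in self.events)

    @property
    def n_levels(self) -> int:
        return len(self.level_amplitudes)

    def durations(self, level: int) -> np.ndarray:
        return np.array([d for lv, d in self.events if lv == level])

    def time_fraction(self, level: int) -> float:
        tot = self.total_duration
        return float(self.durations(level).sum() / tot) if tot > 0 else 0.0


def _noise_sd_estimate(samples: np.ndarray) -> float:
    """Robust noise SD from median absolute first differences."""
    d = np.diff(samples)
    if len(d) == 0:
        return 0.0
    return float(np.median(np.abs(d - np.median(d))) / 0.6745 / np.sqrt(2.0))


def normalize_to_preacid(trace: Trace, acid_onset: float, window: float) -> Trace:
    """Normalize to the mean current just before the acidic application.

    Divides all samples by the mean over [acid_onset - window, acid_onset).
    The (signed) divisor is recorded in ``meta['normalization_divisor_pA']``;
    a negative pre-acid current therefore gives a positive normalized trace.
    Refuses to normalize when the pre-acid mean is indistinguishable from
    noise (|mean| < 5x a robust noise-SD estimate of the window).
    """
    if window > acid_onset:
        raise ValueError("window must not extend before the trace start")
    if window <= 0:
        raise ValueError("window must be > 0 ms")
    t = trace.times
    mask = (t >= acid_onset - window) & (t < acid_onset)
    if not mask.any():
        raise ValueError("empty pre-acid window")
    w = trace.samples[mask]
    divisor = float(w.mean())
    noise_sd = _noise_sd_estimate(w)
    if abs(divisor) < 5.0 * noise_sd:
        raise ValueError(
            f"pre-acid current ({divisor:.3g} pA) is within noise "
            f"(SD estimate {noise_sd:.3g} pA); refusing to normalize"
        )
    meta = dict(trace.meta)
    meta["normalization_divisor_pA"] = divisor
    meta["normalized"] = True
    return Trace(t0=trace.t0, dt=trace.dt, samples=trace.samples / divisor, meta=meta)


@dataclass(frozen=True)
class LevelEstimate:
    """Level amplitudes (ascending) with equidistance diagnostics."""

    amplitudes: tuple[float, ...]
    equidistant: bool = True
    spacings: tuple[float, ...] = ()

    def __iter__(self):
        return iter(self.amplitudes)

    def __len__(self):
        return len(self.amplitudes)


def estimate_levels(trace: Trace, n_levels: int) -> LevelEstimate:
    """Current-level amplitudes from the all-points histogram.

    Quantile-seeded 1-D k-means (Lloyd iterations) refines ``n_levels``
    amplitudes; with three levels the two spacings are averaged into an
    equidistant ladder when they agree within 20%, otherwise the estimate is
    flagged non-equidistant.  Raises when fewer distinct modes than
    ``n_levels`` are separable from the noise.
    """
    if n_levels not in (2, 3):
        raise ValueError("n_levels must be 2 or 3")
    y = trace.samples
    if np.ptp(y) == 0:
        raise ValueError(f"constant trace: found 1 current mode, need {n_levels}")

    # all-points histogram, lightly smoothed, peak-picked for mode seeds
    n_bins = int(np.clip(len(y) // 50, 50, 400))
    counts, edges = np.histogram(y, bins=n_bins)
    smooth = gaussian_filter1d(counts.astype(float), 2.0)
    peaks, props = find_peaks(smooth, prominence=0.005 * smooth.max())
    if len(peaks) < n_levels:
        raise ValueError(
            f"found {len(peaks)} current mode(s) in the all-points histogram, "
            f"need {n_levels}"
        )
    top = peaks[np.argsort(props["prominences"])[-n_levels:]]
    centers = np.sort((edges[top] + edges[top + 1]) / 2.0)

    for _ in range(100):
        assign = np.argmin(np.abs(y[:, None] - centers[None, :]), axis=1)
        new = np.array(
            [y[assign == k].mean() if (assign == k).any() else centers[k] for k in range(n_levels)]
        )
        if np.allclose(new, centers, rtol=0, atol=1e-12):
            break
        centers = new
    centers = np.sort(centers)
    assign = np.argmin(np.abs(y[:, None] - centers[None, :]), axis=1)
    # robust within-level spread (MAD) resists filter-transition samples
    within_sd = max(
        float(np.median(np.abs(y[assign == k] - centers[k])) * 1.4826)
        for k in range(n_levels)
        if (assign == k).any()
    )
    gaps = np.diff(centers)
    if np.min(gaps) <= 0 or np.min(gaps) < 3.0 * within_sd:
        raise ValueError(
            f"found fewer than {n_levels} separable current levels "
            f"(min gap {np.min(gaps):.3g} pA vs within-level spread {within_sd:.3g} pA)"
        )
    equidistant = True
    if n_levels == 3:
        lo, hi = sorted(abs(g) for g in gaps)
        if (hi - lo) / hi < 0.20:
            spacing = float(np.mean(gaps))
            centers = np.array([centers[0], centers[0] + spacing, centers[0] + 2 * spacing])
        else:
            equidistant = False
    # orient as a conductance ladder: level 0 (all pores shut) is the end of
    # the ladder nearest zero current, so inward (negative) currents yield a
    # descending amplitude sequence
    if abs(centers[-1]) < abs(centers[0]):
        centers = centers[::-1]
    return LevelEstimate(
        amplitudes=tuple(float(c) for c in centers),
        equidistant=equidistant,
        spacings=tuple(float(g) for g in gaps),
    )


def idealize(
    trace: Trace,
    level_amplitudes,
    dead_time: Optional[float] = None,
    cutoff_hz: Optional[float] = None,
) -> IdealizedTrace:
    """Half-amplitude threshold idealization with dead-time merging.

    ``level_amplitudes`` are given in level-index order (level 0 = all pores
    shut, then increasing conductance) and must be strictly monotone —
    ascending for outward current, descending for inward.  Samples are
    assigned the level whose half-amplitude band they fall in (thresholds at
    midpoints between adjacent level amplitudes); runs are collapsed to
    events, and events shorter than the dead time are merged into their
    longer-lived neighbours.  The default dead time is ``0.5322/cutoff_hz``
    when a filter cutoff is known (from the argument or
    ``trace.meta['cutoff_hz']``), else one sample.

    Adding a constant offset to both the trace and the level amplitudes
    leaves the result unchanged.
    """
    amps = [float(a) for a in level_amplitudes]
    if len(amps) < 2:
        raise ValueError("need at least 2 level amplitudes")
    diffs = np.diff(amps)
    if not (np.all(diffs > 0) or np.all(diffs < 0)):
        raise ValueError("level_amplitudes must be strictly monotone in level order")
    if cutoff_hz is None:
        cutoff_hz = trace.meta.get("cutoff_hz")
    if dead_time is None:
        dead_time = dead_time_ms(cutoff_hz) if cutoff_hz else trace.dt
    sorted_amps = np.array(amps) if diffs[0] > 0 else np.array(amps[::-1])
    thresholds = (sorted_amps[:-1] + sorted_amps[1:]) / 2.0
    idx = np.searchsorted(thresholds, trace.samples, side="right")
    levels = idx if diffs[0] > 0 else (len(amps) - 1) - idx

    # run-length encode
    change = np.flatnonzero(np.diff(levels)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [len(levels)]))
    events = [[int(levels[s]), float((e - s) * trace.dt)] for s, e in zip(starts, ends)]

    # merge events below the dead time into their neighbours, shortest first
    merged = 0
    while len(events) > 1:
        durations = [d for _, d in events]
        i = int(np.argmin(durations))
        if durations[i] >= dead_time:
            break
        dur = events[i][1]
        if 0 < i < len(events) - 1:
            left, right = events[i - 1], events[i + 1]
            if left[0] == right[0]:
                left[1] += dur + right[1]
                del events[i : i + 2]
            elif left[1] >= right[1]:
                left[1] += dur
                del events[i]
            else:
                right[1] += dur
                del events[i]
        elif i == 0:
            events[1][1] += dur
            del events[0]
        else:
            events[i - 1][1] += dur
            del events[i]
        merged += 1
    # collapse any adjacent equal levels produced by merging
    collapsed: list[list] = []
    for lv, d in events:
        if collapsed and collapsed[-1][0] == lv:
            collapsed[-1][1] += d
        else:
            collapsed.append([lv, d])
    return IdealizedTrace(
        events=[(lv, d) for lv, d in collapsed],
        level_amplitudes=tuple(amps),
        source_cutoff_hz=cutoff_hz,
        merged_events=merged,
    )


def write_events(ideal: IdealizedTrace, path) -> None:
    """Write an event list as delimited text with header metadata."""
    with open(path, "w") as fh:
        fh.write(f"# level_amplitudes_pA={','.join(repr(a) for a in ideal.level_amplitudes)}\n")
        fh.write(f"# source_cutoff_hz={ideal.source_cutoff_hz!r}\n")
        fh.write("level,duration_ms\n")
        for lv, d in ideal.events:
            fh.write(f"{lv},{d!r}\n")


def read_events(path) -> IdealizedTrace:
    amps: tuple[float, ...] = ()
    cutoff = None
    events: list[tuple[int, float]] = []
    saw_columns = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line[1:].partition("=")
                key = key.strip()
                if key == "level_amplitudes_pA":
                    amps = tuple(float(x) for x in val.split(","))
                elif key == "source_cutoff_hz":
                    cutoff = None if val.strip() == "None" else float(val)
                continue
            if not saw_columns:
                if line.replace(" ", "") != "level,duration_ms":
                    raise ValueError(f"{path}:{lineno}: expected column header, got {line!r}")
                saw_columns = True
                continue
            lv, _, d = line.partition(",")
            events.append((int(lv), float(d)))
    return IdealizedTrace(events=events, level_amplitudes=amps, source_cutoff_hz=cutoff)
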