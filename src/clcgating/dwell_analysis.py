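"""Open-probability estimators and dwell-time statistics.

The fast gate of the two-protopore channel is summarised by

    Po = f1/2 + f2,

where f1 and f2 are the time fractions of current levels 1 and 2 in a
three-level idealization; nonconducting (level-0) events longer than an
exclusion cutoff (50 ms by default) are removed — from numerator and
denominator alike — so the statistic reflects fast gating only and not the
seconds-long slow-gate closures.  The slow gate is summarised by the
open-time fraction of the two-level (heavily filtered) view.

Dwell-time distributions are compiled into fixed-bin histograms (8-ms bins
for the fast-gating view, 200-ms bins for the slow-gating view) and fit with
a mono-exponential.  Both fit routes are reported: maximum-likelihood on the
raw durations when they are available, and least squares on the log counts of
nonzero bins.  A likelihood-ratio statistic against a two-exponential mixture
flags distributions whose tails deviate from a single exponential — the
operational signature of slow-gate closures mixed in with fast-gate closures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .trace_processing import IdealizedTrace

__all__ = [
    "DwellHistogram",
    "DwellFit",
    "fast_gate_po",
    "slow_gate_po",
    "dwell_histogram",
    "fit_dwell_exponential",
]

#: Default cutoff excluding slow-gate closures from the fast-gate Po (ms).
DEFAULT_EXCLUSION_MS = 50.0

#: Significance level of the likelihood-ratio deviation flag.
_LRT_ALPHA = 0.01


def fast_gate_po(ideal: IdealizedTrace, exclusion_ms: float = DEFAULT_EXCLUSION_MS) -> float:
    """Fast-gate open probability Po = f1/2 + f2 from a 3-level idealization.

    Level-0 events longer than ``exclusion_ms`` are treated as slow-gate
    closures: their time is removed from the denominator before the level
    time fractions are computed, making Po a conditional time fraction over
    fast-gating activity.  Use ``exclusion_ms=math.inf`` to keep everything.
    """
    if ideal.n_levels != 3:
        raise ValueError("fast-gate Po requires a 3-level idealization")
    kept_total = 0.0
    kept_level = {0: 0.0, 1: 0.0, 2: 0.0}
    for lv, dur in ideal.events:
        if lv == 0 and dur > exclusion_ms:
            continue
        kept_total += dur
        kept_level[lv] = kept_level.get(lv, 0.0) + dur
    if kept_total <= 0:
        raise ValueError("no time remains after exclusion; cannot compute Po")
    f1 = kept_level[1] / kept_total
    f2 = kept_level[2] / kept_total
    return f1 / 2.0 + f2


def slow_gate_po(ideal: IdealizedTrace) -> float:
    """Slow-gate open probability: open-time fraction of the 2-level view."""
    if ideal.n_levels != 2:
        raise ValueError("slow-gate Po requires a 2-level idealization")
    return ideal.time_fraction(1)


@dataclass
class DwellHistogram:
    """Fixed-width dwell-time histogram for one current level.

    ``counts[k]`` counts dwells with duration in [bin_edges[k],
    bin_edges[k+1]); dwells at or beyond the last edge are tallied in
    ``overflow`` (mirroring a display cutoff such as 200 ms), so
    sum(counts) + overflow = n_events.  ``durations`` retains the raw binned
    dwells for maximum-likelihood fitting.
    """

    level: int
    bin_width: float
    bin_edges: np.ndarray
    counts: np.ndarray
    n_events: int
    total_time: float
    overflow: int = 0
    durations: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def bin_centers(self) -> np.ndarray:
        return (self.bin_edges[:-1] + self.bin_edges[1:]) / 2.0


def dwell_histogram(
    ideal: IdealizedTrace,
    level: int,
    bin_width: float,
    max_duration: Optional[float] = None,
) -> DwellHistogram:
    """Compile the dwell-time histogram of one level.

    ``max_duration`` caps the binned range (events at or beyond it go into
    the overflow tally); by default the range covers the longest dwell.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0 ms")
    durations = ideal.durations(level)
    if max_duration is None:
        max_duration = float(durations.max()) + bin_width if len(durations) else bin_width
    n_bins = max(int(math.ceil(max_duration / bin_width)), 1)
    edges = np.arange(n_bins + 1) * bin_width
    in_range = durations[durations < edges[-1]]
    counts, _ = np.histogram(in_range, bins=edges)
    return DwellHistogram(
        level=level,
        bin_width=float(bin_width),
        bin_edges=edges,
        counts=counts.astype(int),
        n_events=len(durations),
        total_time=float(durations.sum()),
        overflow=int(len(durations) - len(in_range)),
        durations=in_range,
    )


@dataclass(frozen=True)
class DwellFit:
    """Mono-exponential dwell fit with a multi-exponential deviation flag.

    ``tau_ml`` is the maximum-likelihood exponential mean of the raw
    durations; ``tau_lsq`` the least-squares slope of log-counts over nonzero
    bins.  ``lrt_statistic`` is 2*(loglik two-exponential mixture - loglik
    single exponential); ``deviation_flag`` is set when it exceeds the
    chi-square(2) critical value at the 1% level, indicating the dwell
    distribution is not mono-exponential.
    """

    tau_ml: float
    tau_lsq: float
    n: int
    lrt_statistic: float
    lrt_pvalue: float
    deviation_flag: bool

    @property
    def tau(self) -> float:
        return self.tau_ml


def _exp_mixture_loglik(x: np.ndarray, w: float, tau1: float, tau2: float) -> float:
    pdf = w / tau1 * np.exp(-x / tau1) + (1.0 - w) / tau2 * np.exp(-x / tau2)
    return float(np.sum(np.log(np.maximum(pdf, 1e-300))))


def _fit_two_exp_em(x: np.ndarray, n_iter: int = 200) -> tuple[float, float, float, float]:
    """EM fit of a two-exponential mixture; returns (loglik, w, tau1, tau2)."""
    lo, hi = np.quantile(x, [0.25, 0.9])
    tau1, tau2 = max(lo, 1e-9), max(hi, 2e-9)
    if tau2 <= tau1:
        tau2 = tau1 * 3.0
    w = 0.5
    ll_prev = -np.inf
    for _ in range(n_iter):
        p1 = w / tau1 * np.exp(-x / tau1)
        p2 = (1.0 - w) / tau2 * np.exp(-x / tau2)
        tot = np.maximum(p1 + p2, 1e-300)
        r = p1 / tot
        w = float(np.clip(r.mean(), 1e-6, 1.0 - 1e-6))
        tau1 = float(np.sum(r * x) / max(np.sum(r), 1e-300))
        tau2 = float(np.sum((1 - r) * x) / max(np.sum(1 - r), 1e-300))
        tau1, tau2 = max(tau1, 1e-9), max(tau2, 1e-9)
        ll = _exp_mixture_loglik(x, w, tau1, tau2)
        if ll - ll_prev < 1e-10:
            break
        ll_prev = ll
    return _exp_mixture_loglik(x, w, tau1, tau2), w, tau1, tau2


def fit_dwell_exponential(hist: DwellHistogram) -> DwellFit:
    """Mono-exponential fit of a dwell histogram, with deviation diagnostics.

    Requires at least 3 nonzero bins.  The ML estimate is the sample mean of
    the raw binned durations (the exponential MLE); the least-squares
    estimate regresses log counts on bin centers over nonzero bins.  The
    deviation flag comes from a likelihood-ratio test of a two-exponential
    mixture (df = 2) against the single exponential on the raw durations.
    """
    nonzero = int(np.count_nonzero(hist.counts))
    if nonzero < 3:
        raise ValueError(f"need >= 3 nonzero bins, got {nonzero}")
    x = np.asarray(hist.durations, dtype=float)
    x = x[x > 0]
    if len(x) == 0:
        raise ValueError("histogram carries no raw durations")
    tau_ml = float(x.mean())

    mask = hist.counts > 0
    slope, intercept = np.polyfit(hist.bin_centers[mask], np.log(hist.counts[mask]), 1)
    tau_lsq = float(-1.0 / slope) if slope < 0 else float("inf")

    ll1 = float(np.sum(-np.log(tau_ml) - x / tau_ml))
    ll2, _, _, _ = _fit_two_exp_em(x)
    lrt = max(2.0 * (ll2 - ll1), 0.0)
    pval = float(stats.chi2.sf(lrt, df=2))
    return DwellFit(
        tau_ml=tau_ml,
        tau_lsq=tau_lsq,
        n=len(x),
        lrt_statistic=lrt,
        lrt_pvalue=pval,
        deviation_flag=pval < _LRT_ALPHA,
    )
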