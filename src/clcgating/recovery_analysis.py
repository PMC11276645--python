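"""Multi-exponential fitting of current recovery and downstream analyses.

The observable is the macroscopic current after washout of an acidic
intracellular solution, normalized to the pre-acid level.  Its recovery is
described by a sum of exponentials

    I(t) = sum_i A_i * exp(-t / tau_i) + C,        i = 1..n (n <= 3)

fit by trust-region nonlinear least squares with an analytic Jacobian and
multi-start initialisation over log-spaced time constants.  Each component is
summarised by its fraction

    F_i = A_i / sum_j A_j,

the amplitude normalized by the summed amplitudes.  Model order is chosen by
AIC (an incremental F-test is also offered), alongside two reported
heuristics: whether the fitted amplitudes cover the observed recovery span
(underfitting leaves the "fraction sum" short of unity) and a runs test for
systematic residual structure.

Condition sweeps tabulate tau_i and F_i against voltage, [Cl-] and anion
species with replicate mean +/- SEM, and the exposure-duration analysis fits
the decay of the fast recovery fraction against the acidic exposure time —
the observable that reports the transition rate from the shallowest
inactivated state to the next deeper one.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import least_squares

from .conditions import IonCondition
from .synthetic_data import Trace

__all__ = [
    "ExpFitResult",
    "ExposureSeriesResult",
    "SweepResult",
    "fit_recovery",
    "component_fractions",
    "select_model_order",
    "condition_sweep",
    "exposure_series_fit",
]

#: Multi-start count for the tau seeds.
N_STARTS = 8

#: tau ratio below which two fitted components are flagged collinear.
COLLINEAR_TAU_RATIO = 1.5

#: Guard band for matching components across fits by nearest log-tau.
MATCH_GUARD_FACTOR = 3.0


@dataclass
class ExpFitResult:
    """Fitted multi-exponential recovery.

    ``components`` are (amplitude, tau_ms) sorted by tau ascending; ``c`` is
    the offset (the recovery plateau, which may sit below 1 when recovery is
    partial).  ``fractions`` are amplitude fractions F_i = A_i / sum(A);
    the fitted curve at the recovery start equals c + sum(A_i) identically.
    ``aic`` uses k = 2n+1 parameters; ``truncated`` flags a fit whose largest
    tau exceeds a third of the fitted span.
    """

    n: int
    components: Sequence[tuple[float, float]]
    c: float
    rss: float
    dof: int
    aic: float
    recovery_start: float
    span: float
    n_points: int
    converged: bool = True
    collinear: bool = False
    truncated: bool = False
    runs_pvalue: float = float("nan")
    message: str = ""

    @property
    def amplitudes(self) -> np.ndarray:
        return np.array([a for a, _ in self.components])

    @property
    def taus(self) -> np.ndarray:
        return np.array([tau for _, tau in self.components])

    @property
    def fractions(self) -> np.ndarray:
        return component_fractions(self)

    def evaluate(self, t: np.ndarray) -> np.ndarray:
        """Model value at absolute times ``t`` (ms, same axis as the trace)."""
        tt = np.asarray(t, dtype=float) - self.recovery_start
        out = np.full_like(tt, self.c, dtype=float)
        for a, tau in self.components:
            out += a * np.exp(-tt / tau)
        return out


def component_fractions(fit: ExpFitResult) -> np.ndarray:
    """Amplitude fractions F_i = A_i / sum_j A_j (sum to 1 identically).

    Raises on a zero amplitude sum; warns when amplitudes carry mixed signs,
    where the fraction definition becomes ill-behaved.
    """
    amps = fit.amplitudes
    total = amps.sum()
    if total == 0:
        raise ValueError("zero amplitude sum; fractions are undefined")
    if len(amps) > 1 and (np.min(amps) < 0 < np.max(amps)):
        warnings.warn(
            "mixed-sign amplitudes: component fractions are ill-behaved",
            stacklevel=2,
        )
    return amps / total


def _model_and_jacobian(params: np.ndarray, t: np.ndarray, n: int):
    """Model residual ingredients for C + sum A_i exp(-t/tau_i), tau = e^theta."""
    amps = params[:n]
    c = params[n]
    taus = np.exp(params[n + 1 :])
    basis = np.exp(-t[:, None] / taus[None, :])  # (m, n)
    y = basis @ amps + c
    jac = np.empty((len(t), 2 * n + 1))
    jac[:, :n] = basis
    jac[:, n] = 1.0
    # d/d theta_i of A_i exp(-t e^{-theta_i}) = A_i exp(.) * (t / tau_i)
    jac[:, n + 1 :] = amps[None, :] * basis * (t[:, None] / taus[None, :])
    return y, jac


def _linear_init(t: np.ndarray, y: np.ndarray, taus: np.ndarray) -> tuple[np.ndarray, float]:
    basis = np.column_stack([np.exp(-t[:, None] / taus[None, :]), np.ones_like(t)])
    sol, *_ = np.linalg.lstsq(basis, y, rcond=None)
    return sol[:-1], float(sol[-1])


def _runs_pvalue(residuals: np.ndarray) -> float:
    """Wald-Wolfowitz runs test p-value on residual signs (two-sided)."""
    s = np.sign(residuals)
    s = s[s != 0]
    n_pos = int(np.sum(s > 0))
    n_neg = int(np.sum(s < 0))
    n = n_pos + n_neg
    if n_pos == 0 or n_neg == 0 or n < 10:
        return float("nan")
    runs = 1 + int(np.sum(s[1:] != s[:-1]))
    mu = 2.0 * n_pos * n_neg / n + 1.0
    var = (mu - 1.0) * (mu - 2.0) / (n - 1.0)
    if var <= 0:
        return float("nan")
    z = (runs - mu) / math.sqrt(var)
    return float(2.0 * stats.norm.sf(abs(z)))


def fit_recovery(trace: Trace, recovery_start: float, n: int) -> ExpFitResult:
    """Fit the recovery phase of a (normalized) trace with ``n`` exponentials.

    Nonlinear least squares (trust-region reflective, analytic Jacobian) on
    samples with t >= ``recovery_start``; time constants are parameterised on
    a log scale and bounded to [0.5*dt, 10*span].  Eight starts with
    log-spaced tau seeds are attempted and the best residual sum of squares
    wins (ties broken by the smaller parameter norm).  Components are
    returned sorted by ascending tau; a tau ratio under 1.5 raises a
    collinearity warning.
    """
    if n not in (1, 2, 3):
        raise ValueError("n must be 1, 2 or 3")
    t_all = trace.times
    mask = t_all >= recovery_start
    if int(mask.sum()) < 2 * n + 2:
        raise ValueError("too few samples after recovery_start for the requested order")
    t = t_all[mask] - recovery_start
    y = trace.samples[mask]
    span = float(t[-1] - t[0]) if len(t) > 1 else trace.dt
    lo_tau, hi_tau = 0.5 * trace.dt, 10.0 * span

    best = None
    factors = np.geomspace(0.25, 4.0, N_STARTS)
    for fac in factors:
        tau_seeds = np.geomspace(
            max(1.0 * fac, lo_tau * 1.01), min(span * fac, hi_tau * 0.99), n + 2
        )[1:-1]
        tau_seeds = np.clip(np.sort(tau_seeds), lo_tau * 1.01, hi_tau * 0.99)
        # nudge coincident seeds apart
        for i in range(1, n):
            if tau_seeds[i] <= tau_seeds[i - 1] * 1.05:
                tau_seeds[i] = min(tau_seeds[i - 1] * 1.5, hi_tau * 0.99)
        amps0, c0 = _linear_init(t, y, tau_seeds)
        p0 = np.concatenate([amps0, [c0], np.log(tau_seeds)])
        lb = np.concatenate([np.full(n + 1, -np.inf), np.full(n, math.log(lo_tau))])
        ub = np.concatenate([np.full(n + 1, np.inf), np.full(n, math.log(hi_tau))])
        try:
            res = least_squares(
                lambda p: _model_and_jacobian(p, t, n)[0] - y,
                p0,
                jac=lambda p: _model_and_jacobian(p, t, n)[1],
                bounds=(lb, ub),
                method="trf",
                max_nfev=400,
            )
        except Exception:  # singular start; try the next one
            continue
        rss = float(np.sum(res.fun**2))
        if (
            best is None
            or rss < best[0] * (1 - 1e-9)
            or (abs(rss - best[0]) <= 1e-9 * max(best[0], 1e-300)
                and np.linalg.norm(res.x) < np.linalg.norm(best[1].x))
        ):
            best = (rss, res)
    if best is None:
        raise RuntimeError("recovery fit failed to converge from any start")
    rss, res = best
    amps = res.x[:n]
    c = float(res.x[n])
    taus = np.exp(res.x[n + 1 :])
    order = np.argsort(taus)
    comps = [(float(amps[i]), float(taus[i])) for i in order]
    collinear = any(
        comps[i + 1][1] / comps[i][1] < COLLINEAR_TAU_RATIO for i in range(n - 1)
    )
    if collinear:
        warnings.warn(
            f"fitted time constants are nearly collinear (ratio < {COLLINEAR_TAU_RATIO})",
            stacklevel=2,
        )
    m = len(t)
    k = 2 * n + 1
    aic = m * math.log(max(rss / m, 1e-300)) + 2 * k
    fit = ExpFitResult(
        n=n,
        components=comps,
        c=c,
        rss=rss,
        dof=m - k,
        aic=aic,
        recovery_start=float(recovery_start),
        span=span,
        n_points=m,
        converged=bool(res.success),
        collinear=collinear,
        truncated=span < 3.0 * comps[-1][1],
        runs_pvalue=_runs_pvalue(res.fun),
        message=res.message,
    )
    return fit


@dataclass
class ModelOrderResult:
    """Per-order fits with the criterion's selection and the reported heuristics."""

    best_n: int
    fits: dict[int, ExpFitResult]
    criterion: str
    amplitude_coverage: dict[int, float] = field(default_factory=dict)
    coverage_flags: dict[int, bool] = field(default_factory=dict)
    residual_structure_flags: dict[int, bool] = field(default_factory=dict)

    @property
    def best_fit(self) -> ExpFitResult:
        return self.fits[self.best_n]


def _amplitude_coverage(trace: Trace, fit: ExpFitResult) -> float:
    """Fitted amplitude sum relative to the observed recovery span.

    Underfitting (too few components) leaves part of the observed rise
    unexplained, so the ratio falls short of 1 — the "fraction sum does not
    reach unity" heuristic.
    """
    t = trace.times
    mask = t >= fit.recovery_start
    y = trace.samples[mask]
    n_tail = max(len(y) // 20, 1)
    observed = float(np.mean(y[-n_tail:]) - np.mean(y[: max(n_tail // 4, 1)]))
    modeled = -float(fit.amplitudes.sum())  # rise = C - y(0) = -sum(A)
    if observed == 0:
        return float("nan")
    return modeled / observed


def select_model_order(
    trace: Trace,
    recovery_start: float,
    max_n: int = 3,
    criterion: str = "AIC",
) -> ModelOrderResult:
    """Fit n = 1..max_n exponentials and pick the preferred order.

    ``criterion="AIC"`` picks the minimum-AIC order; ``"Ftest"`` accepts each
    additional component only while the incremental F-test against the
    lower-order fit is significant at the 5% level.  Also reported per order:
    the amplitude-coverage heuristic (flagged when the fitted amplitudes
    explain <95% of the observed recovery span) and a runs-test flag for
    systematic residual structure (p < 0.01).
    """
    if criterion not in ("AIC", "Ftest"):
        raise ValueError("criterion must be 'AIC' or 'Ftest'")
    fits: dict[int, ExpFitResult] = {}
    for n in range(1, max_n + 1):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                fits[n] = fit_recovery(trace, recovery_start, n)
            except (RuntimeError, ValueError):
                continue
    if not fits:
        raise RuntimeError("no model order could be fit")
    orders = sorted(fits)
    if criterion == "AIC":
        best_n = min(orders, key=lambda n: fits[n].aic)
    else:
        best_n = orders[0]
        for n_prev, n_next in zip(orders[:-1], orders[1:]):
            f_prev, f_next = fits[n_prev], fits[n_next]
            df1 = 2 * (n_next - n_prev)
            df2 = f_next.dof
            if f_next.rss <= 0 or df2 <= 0:
                break
            f_stat = ((f_prev.rss - f_next.rss) / df1) / (f_next.rss / df2)
            p = float(stats.f.sf(f_stat, df1, df2))
            if p < 0.05:
                best_n = n_next
            else:
                break
    coverage = {n: _amplitude_coverage(trace, f) for n, f in fits.items()}
    return ModelOrderResult(
        best_n=best_n,
        fits=fits,
        criterion=criterion,
        amplitude_coverage=coverage,
        coverage_flags={n: (cov < 0.95) for n, cov in coverage.items()},
        residual_structure_flags={
            n: (f.runs_pvalue < 0.01 if np.isfinite(f.runs_pvalue) else False)
            for n, f in fits.items()
        },
    )


# ---------------------------------------------------------------------------
# Component matching and sweeps
# ---------------------------------------------------------------------------


def _match_to_reference(taus: np.ndarray, ref_taus: np.ndarray) -> list[Optional[int]]:
    """Assign each tau to the nearest reference tau in log space.

    Returns the reference index per tau, or None when the nearest reference
    lies outside the 3x guard band.  Assignments never swap the ascending
    ordering (both lists are sorted).
    """
    out: list[Optional[int]] = []
    for tau in taus:
        j = int(np.argmin(np.abs(np.log(ref_taus) - math.log(tau))))
        ratio = max(tau / ref_taus[j], ref_taus[j] / tau)
        out.append(j if ratio <= MATCH_GUARD_FACTOR else None)
    return out


@dataclass
class SweepResult:
    """Tidy per-replicate component table and mean +/- SEM summary."""

    table: pd.DataFrame
    summary: pd.DataFrame


def _condition_columns(cond: IonCondition) -> dict:
    return {
        "v_m_mv": cond.v_m,
        "ph_i": cond.ph_i,
        "cl_in_mM": cond.anion_in.get("Cl", 0.0),
        "cl_out_mM": cond.anion_out.get("Cl", 0.0),
        "anions_in": "+".join(sorted(k for k, v in cond.anion_in.items() if v > 0)),
        "condition": cond.rate_label,
    }


def condition_sweep(
    items: Sequence[tuple[IonCondition, Trace]],
    recovery_start: float,
    n_policy: Union[str, int] = "auto",
    max_n: int = 3,
) -> SweepResult:
    """Fit every (condition, trace) pair and tabulate tau_i and F_i.

    ``n_policy`` is ``"auto"`` (AIC model-order selection per trace) or a
    fixed integer order.  Components are labelled consistently across the
    sweep by nearest-log-tau matching (3x guard band) to a reference set
    taken from the fit with the most components; the summary reports
    replicate mean +/- SEM of tau and fraction per (condition, component).
    """
    if len(items) < 2:
        raise ValueError("a sweep needs at least 2 (condition, trace) entries")
    fits: list[tuple[IonCondition, ExpFitResult]] = []
    for cond, trace in items:
        if isinstance(n_policy, int):
            fit = fit_recovery(trace, recovery_start, n_policy)
        else:
            fit = select_model_order(trace, recovery_start, max_n=max_n).best_fit
        fits.append((cond, fit))

    ref_fit = max((f for _, f in fits), key=lambda f: f.n)
    ref_taus = ref_fit.taus
    rows = []
    replicate_counter: dict[str, int] = {}
    for cond, fit in fits:
        key = str(sorted(_condition_columns(cond).items()))
        replicate_counter[key] = replicate_counter.get(key, 0) + 1
        labels = _match_to_reference(fit.taus, ref_taus)
        fracs = fit.fractions
        for i, ((a, tau), lab) in enumerate(zip(fit.components, labels)):
            rows.append(
                {
                    **_condition_columns(cond),
                    "replicate": replicate_counter[key],
                    "component": f"comp{lab + 1}" if lab is not None else f"unmatched_{i + 1}",
                    "tau_ms": tau,
                    "amplitude": a,
                    "fraction": float(fracs[i]),
                    "n_selected": fit.n,
                    "aic": fit.aic,
                    "rss": fit.rss,
                }
            )
    table = pd.DataFrame(rows)
    group_cols = ["condition", "v_m_mv", "cl_in_mM", "cl_out_mM", "anions_in", "component"]
    summary = (
        table.groupby(group_cols, as_index=False)
        .agg(
            tau_ms_mean=("tau_ms", "mean"),
            tau_ms_sem=("tau_ms", "sem"),
            fraction_mean=("fraction", "mean"),
            fraction_sem=("fraction", "sem"),
            n_replicates=("replicate", "count"),
        )
        .sort_values(group_cols)
        .reset_index(drop=True)
    )
    return SweepResult(table=table, summary=summary)


# ---------------------------------------------------------------------------
# Exposure-duration series
# ---------------------------------------------------------------------------


@dataclass
class ExposureSeriesResult:
    """Decay of the fast recovery fraction with acidic exposure duration.

    ``decay_tau`` is the mono-exponential time constant of
    F_fast(T) = plateau + (f0 - plateau) * exp(-T/decay_tau); it is None when
    a constant model is preferred by AIC (``time_dependent`` False) — the
    signature of an unresolvably fast transition out of the shallowest
    inactivated state.
    """

    exposures: np.ndarray
    fast_fraction: np.ndarray
    decay_tau: Optional[float]
    plateau: float
    f0: float
    time_dependent: bool
    aic_exponential: float
    aic_constant: float


def exposure_series_fit(
    results: Sequence[tuple[float, ExpFitResult]],
    min_amplitude: float = 0.05,
) -> ExposureSeriesResult:
    """Fit the exposure-duration dependence of the fast component fraction.

    The fast component of each fit is identified by nearest-log-tau matching
    against the smallest reference tau (pooled across exposures, 3x guard
    band); an exposure whose fit has no matching component is an error.
    F_fast(T) is then fit with a mono-exponential decay toward a plateau and
    compared against a constant model by small-sample AIC; the series is
    declared time dependent only when the exponential both wins that
    comparison and predicts a fraction change across the measured exposure
    range of at least ``min_amplitude`` (fractions are typically resolved no
    better than ~0.05 across replicates, so smaller drifts are noise).
    """
    if len(results) < 4:
        raise ValueError("need >= 4 exposure durations")
    exposures = np.array([float(T) for T, _ in results])
    if np.any(np.diff(exposures) <= 0):
        raise ValueError("exposures must be strictly increasing")
    ref_tau = min(min(f.taus) for _, f in results)
    fracs = []
    for T, f in results:
        labels = _match_to_reference(f.taus, np.array([ref_tau]))
        matched = [i for i, lab in enumerate(labels) if lab == 0]
        if not matched:
            raise ValueError(
                f"no component matching the fast reference tau {ref_tau:.3g} ms "
                f"at exposure {T} ms"
            )
        fracs.append(float(f.fractions[matched[0]]))
    f_arr = np.array(fracs)

    def _aicc(rss: float, m: int, k: int) -> float:
        # small-sample AIC: exposure series are short (typically 4-10 points)
        aic = m * math.log(max(rss / m, 1e-300)) + 2 * k
        if m - k - 1 > 0:
            aic += 2.0 * k * (k + 1) / (m - k - 1)
        return aic

    # constant model
    const = float(f_arr.mean())
    rss_c = float(np.sum((f_arr - const) ** 2))
    m = len(f_arr)
    aic_c = _aicc(rss_c, m, 1)

    # exponential model: plateau + (f0 - plateau) exp(-T/tau); fractions are
    # bounded quantities, so the curve's endpoints are confined near [0, 1]
    # and the decay constant to scales the exposure grid can resolve
    def resid(p):
        plateau, f0, log_tau = p
        return plateau + (f0 - plateau) * np.exp(-exposures / np.exp(log_tau)) - f_arr

    span = exposures[-1] - exposures[0]
    min_gap = float(np.min(np.diff(exposures)))
    lo = np.array([-0.5, -0.5, math.log(min_gap / 2.0)])
    hi = np.array([1.5, 1.5, math.log(10.0 * span)])
    best = None
    for tau0 in np.geomspace(min_gap, span * 5.0, 6):
        p0 = np.array(
            [np.clip(f_arr[-1], -0.4, 1.4), np.clip(f_arr[0], -0.4, 1.4), math.log(tau0)]
        )
        try:
            res = least_squares(resid, p0, bounds=(lo, hi), method="trf", max_nfev=2000)
        except Exception:
            continue
        rss = float(np.sum(res.fun**2))
        if best is None or rss < best[0]:
            best = (rss, res)
    if best is None:
        raise RuntimeError("exposure-series exponential fit failed")
    rss_e, res = best
    plateau, f0 = float(res.x[0]), float(res.x[1])
    tau = float(np.exp(res.x[2]))
    aic_e = _aicc(rss_e, m, 3)
    predicted_change = abs(
        (f0 - plateau)
        * (math.exp(-exposures[0] / tau) - math.exp(-exposures[-1] / tau))
    )
    time_dependent = (aic_e < aic_c) and (predicted_change >= min_amplitude)
    return ExposureSeriesResult(
        exposures=exposures,
        fast_fraction=f_arr,
        decay_tau=tau if time_dependent else None,
        plateau=plateau if time_dependent else const,
        f0=f0,
        time_dependent=time_dependent,
        aic_exponential=aic_e,
        aic_constant=aic_c,
    )
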