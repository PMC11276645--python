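"""Markov gating schemes and their deterministic relaxation behaviour.

A gating scheme is a small continuous-time Markov chain over named states,
each either conducting or nonconducting.  The slow (common) gate of CLC-0 is
modelled as a linear chain O - I1 - I2 - I3: one conducting open state and a
ladder of progressively deeper nonconducting inactivated states, entered under
acidic intracellular pH and exited (recovery) at neutral pH.  A simpler
three-state variant (open - inhibited - inactivated) is also shipped.

Rates are condition-labelled constants (1/ms) supplied by a rate table keyed
on a condition label such as ``"pH7.4"`` or ``"pH5"``; voltage and [Cl-]
dependence enter through per-condition tables and through the initial
occupancy at the start of a relaxation, not through a parametric rate law.
An optional exponential voltage factor k(V) = k0 * exp(V/Vs) is available per
edge but off by default.

The deterministic machinery is spectral: occupancies p(t) = p0 * exp(Q t) and
the relaxation spectrum of any linear observable are computed from the
eigendecomposition of the generator Q.  A connected n-state scheme has one
zero eigenvalue (the stationary mode) and n-1 decaying modes; the four-state
chain therefore relaxes tri-exponentially, which is exactly the structure of
the empirical recovery fits in :mod:`clcgating.recovery_analysis`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Optional, Sequence

import numpy as np
import yaml
from scipy import linalg as sla

__all__ = [
    "StateScheme",
    "Generator",
    "Spectrum",
    "build_generator",
    "occupancy",
    "relaxation_spectrum",
    "stationary_distribution",
    "load_scheme",
    "preset_scheme",
    "PRESET_SCHEMES",
]

#: Relative amplitude below which a spectral component is dropped (reported
#: in Spectrum.dropped): |A_i| < AMPLITUDE_FLOOR * dynamic range.
AMPLITUDE_FLOOR = 1e-6

#: Relative tau difference below which two spectral components are merged.
TAU_MERGE_RTOL = 1e-9


class ConfigurationError(ValueError):
    """A scheme/rate-table lookup failed."""


@dataclass(frozen=True)
class StateScheme:
    """States, edges and per-condition rates of a gating scheme.

    ``states``: ordered (name, conducting?) pairs.  ``edges``: directed
    (from, to, rate_key) triples; a reversible transition is two edges.
    ``rate_table``: {condition_label: {rate_key: rate per ms}}.
    ``voltage_slope_mv``: optional {rate_key: Vs} enabling the multiplicative
    factor exp(V_m / Vs) on that rate (disabled for keys not present).
    """

    states: Sequence[tuple[str, bool]]
    edges: Sequence[tuple[str, str, str]]
    rate_table: Mapping[str, Mapping[str, float]]
    voltage_slope_mv: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = [n for n, _ in self.states]
        if len(set(names)) != len(names):
            raise ValueError("duplicate state names")
        name_set = set(names)
        for frm, to, _key in self.edges:
            if frm not in name_set or to not in name_set:
                raise ValueError(f"edge {frm}->{to} references unknown state")
            if frm == to:
                raise ValueError("self-loops are not allowed")
        for label, rates in self.rate_table.items():
            for key, r in rates.items():
                if r < 0:
                    raise ValueError(f"rate {key}@{label} = {r} is negative")
        # connectivity of the undirected scheme graph
        adj: dict[str, set[str]] = {n: set() for n in names}
        for frm, to, _ in self.edges:
            adj[frm].add(to)
            adj[to].add(frm)
        seen = {names[0]}
        stack = [names[0]]
        while stack:
            for nb in adj[stack.pop()]:
                if nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        if seen != name_set:
            raise ValueError(f"scheme graph is disconnected: unreachable {name_set - seen}")

    @property
    def state_names(self) -> list[str]:
        return [n for n, _ in self.states]

    @property
    def n_states(self) -> int:
        return len(self.states)

    def conducting_vector(self) -> np.ndarray:
        """Indicator weights (1 = conducting) in state order."""
        return np.array([1.0 if cond else 0.0 for _, cond in self.states])

    def index(self, name: str) -> int:
        return self.state_names.index(name)

    def rate(self, key: str, condition_label: str, v_m: Optional[float] = None) -> float:
        try:
            r = self.rate_table[condition_label][key]
        except KeyError:
            raise ConfigurationError(
                f"no rate {key!r} for condition {condition_label!r}; "
                f"known labels: {sorted(self.rate_table)}"
            ) from None
        if v_m is not None and key in self.voltage_slope_mv:
            r *= math.exp(v_m / self.voltage_slope_mv[key])
        return r


@dataclass(frozen=True)
class Generator:
    """Transition-rate matrix Q (1/ms), row convention.

    Off-diagonal q[i, j] is the rate i -> j; each diagonal entry is minus its
    row's off-diagonal sum, so rows sum to zero and p(t) = p0 @ expm(Q t).
    """

    q: np.ndarray
    state_names: Sequence[str] = ()

    def __post_init__(self) -> None:
        q = np.asarray(self.q, dtype=float)
        if q.ndim != 2 or q.shape[0] != q.shape[1]:
            raise ValueError("generator must be square")
        off = q.copy()
        np.fill_diagonal(off, 0.0)
        if np.any(off < 0):
            raise ValueError("off-diagonal rates must be >= 0")
        if np.max(np.abs(q.sum(axis=1))) > 1e-12 * max(1.0, np.max(np.abs(q))):
            raise ValueError("generator rows must sum to 0")
        object.__setattr__(self, "q", q)

    @property
    def n_states(self) -> int:
        return self.q.shape[0]


@dataclass(frozen=True)
class Spectrum:
    """Multi-exponential decomposition of a relaxation observable.

    observable(t) = offset + sum_i amplitude_i * exp(-t / tau_i), taus in ms,
    strictly ascending.  ``dropped`` records components removed by the
    amplitude floor; ``fallback`` flags a numerically ill-conditioned
    eigendecomposition (in which case the caller should fit a numeric
    trajectory instead).
    """

    components: Sequence[tuple[float, float]]  # (amplitude, tau_ms)
    offset: float
    dropped: Sequence[tuple[float, float]] = ()
    fallback: bool = False

    @property
    def taus(self) -> np.ndarray:
        return np.array([tau for _, tau in self.components])

    @property
    def amplitudes(self) -> np.ndarray:
        return np.array([a for a, _ in self.components])

    def evaluate(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        out = np.full_like(t, self.offset, dtype=float)
        for a, tau in self.components:
            out += a * np.exp(-t / tau)
        for a, tau in self.dropped:
            out += a * np.exp(-t / tau)
        return out


def build_generator(scheme: StateScheme, condition_label: str, v_m: Optional[float] = None) -> Generator:
    """Assemble the generator matrix for one condition label.

    Raises :class:`ConfigurationError` when a rate key is missing for the
    label.  ``v_m`` activates the optional exponential voltage factor on
    edges that declare a slope.
    """
    n = scheme.n_states
    q = np.zeros((n, n))
    for frm, to, key in scheme.edges:
        q[scheme.index(frm), scheme.index(to)] += scheme.rate(key, condition_label, v_m)
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    return Generator(q=q, state_names=tuple(scheme.state_names))


def _validate_p0(p0, n: int) -> np.ndarray:
    p0 = np.asarray(p0, dtype=float)
    if p0.shape != (n,):
        raise ValueError(f"p0 must have shape ({n},), got {p0.shape}")
    if np.any(p0 < -1e-12) or abs(p0.sum() - 1.0) > 1e-9:
        raise ValueError("p0 must be a probability vector (nonnegative, sums to 1)")
    return np.clip(p0, 0.0, None)


def _eig(gen: Generator):
    """Eigendecomposition of Q with a conditioning guard.

    Returns (eigenvalues, right eigenvectors V, V^-1) such that
    Q = V diag(lam) V^-1.  Raises LinAlgError-ish ValueError when V is too
    ill-conditioned for a trustworthy spectral solution.
    """
    lam, vr = np.linalg.eig(gen.q.T)  # left eigen problem of Q via Q^T
    cond = np.linalg.cond(vr)
    if not np.isfinite(cond) or cond > 1e10:
        raise np.linalg.LinAlgError(f"eigenvector matrix ill-conditioned (cond={cond:.2e})")
    return lam, vr, np.linalg.inv(vr)


def occupancy(gen: Generator, p0, t_grid) -> np.ndarray:
    """State occupancies p(t) = p0 @ exp(Q t) on a time grid (ms).

    The solution is spectral (eigendecomposition of Q); if Q is too
    ill-conditioned to diagonalise, falls back to scipy's scaling-and-squaring
    matrix exponential per time point.  Rows of the result sum to 1.
    """
    p0 = _validate_p0(p0, gen.n_states)
    t = np.asarray(t_grid, dtype=float)
    if np.any(t < 0):
        raise ValueError("t_grid must be nonnegative")
    if t.ndim != 1 or (len(t) > 1 and np.any(np.diff(t) < 0)):
        raise ValueError("t_grid must be a 1-D ascending array")
    try:
        lam, vr, vinv = _eig(gen)
        # p(t)^T = V e^{lam t} V^-1 p0^T  (decomposition of Q^T)
        coef = vinv @ p0  # spectral coordinates of p0
        modes = vr * coef[np.newaxis, :]  # columns: state-space mode shapes
        out = np.real(modes @ np.exp(np.outer(lam, t))).T
    except np.linalg.LinAlgError:
        out = np.array([p0 @ sla.expm(gen.q * ti) for ti in t])
    out = np.clip(out, 0.0, None)
    out /= out.sum(axis=1, keepdims=True)
    return out


def stationary_distribution(gen: Generator) -> np.ndarray:
    """Stationary occupancy pi with pi @ Q = 0, normalised to sum 1."""
    ns = sla.null_space(gen.q.T)
    if ns.shape[1] != 1:
        raise ValueError(
            "generator has a degenerate stationary space (disconnected scheme?)"
        )
    pi = np.real(ns[:, 0])
    pi = np.clip(pi * np.sign(pi.sum()), 0.0, None)
    return pi / pi.sum()


def relaxation_spectrum(gen: Generator, p0, observable) -> Spectrum:
    """Exponential decomposition of observable(t) = p(t) @ w.

    Decomposes the linear observable over the eigenmodes of Q: the zero
    eigenvalue contributes the steady-state offset; each nonzero eigenvalue
    lambda_i contributes amplitude A_i on time constant tau_i = -1/Re(lambda_i).
    Components with |A_i| below the amplitude floor (relative to the dynamic
    range) are dropped but reported; components with numerically equal taus
    are merged.  Complex eigenvalues (possible only for non-reversible
    schemes) raise with guidance to use :func:`occupancy` numerically.
    """
    p0 = _validate_p0(p0, gen.n_states)
    w = np.asarray(observable, dtype=float)
    if w.shape != (gen.n_states,):
        raise ValueError("observable weight vector has wrong length")
    try:
        lam, vr, vinv = _eig(gen)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            f"generator not reliably diagonalizable ({exc}); compute a numeric "
            "trajectory with occupancy() and fit it instead"
        ) from exc
    if np.max(np.abs(lam.imag)) > 1e-9 * max(1.0, np.max(np.abs(lam.real))):
        raise ValueError(
            "generator has complex eigenvalues (oscillatory modes); use a "
            "numeric occupancy trajectory and an empirical fit instead"
        )
    lam = lam.real
    # observable(t) = sum_i (vinv @ p0)_i (w @ vr[:, i]) e^{lam_i t}
    amps = np.real((vinv @ p0) * (w @ vr))
    zero_mask = np.abs(lam) <= 1e-12 * max(1.0, np.max(np.abs(lam)))
    offset = float(amps[zero_mask].sum())
    comps = [(-1.0 / l, a) for l, a in zip(lam[~zero_mask], amps[~zero_mask])]
    comps.sort()  # ascending tau
    # merge numerically equal taus
    merged: list[list[float]] = []
    for tau, a in comps:
        if merged and abs(tau - merged[-1][0]) <= TAU_MERGE_RTOL * merged[-1][0]:
            merged[-1][1] += a
        else:
            merged.append([tau, a])
    dyn_range = max(abs(offset) + sum(abs(a) for _, a in merged), 1e-300)
    kept, dropped = [], []
    for tau, a in merged:
        (kept if abs(a) >= AMPLITUDE_FLOOR * dyn_range else dropped).append((a, tau))
    return Spectrum(components=tuple(kept), offset=offset, dropped=tuple(dropped))


# ---------------------------------------------------------------------------
# Scheme presets and config I/O
# ---------------------------------------------------------------------------

PRESET_SCHEMES = ("model1", "model2", "c212s", "y512a", "e166a", "e166q")


def load_scheme(source) -> StateScheme:
    """Read a scheme config (YAML path or mapping).

    Keys: ``states`` (list of {name, conducting}), ``edges`` (list of
    {from, to, rate_key}), ``rates`` ({condition_label: {rate_key: per_ms}}),
    optional ``voltage_slope_mv`` ({rate_key: mV}).
    """
    if isinstance(source, Mapping):
        doc = source
    else:
        with open(source) as fh:
            doc = yaml.safe_load(fh)
    try:
        states = [(s["name"], bool(s.get("conducting", False))) for s in doc["states"]]
        edges = [(e["from"], e["to"], e["rate_key"]) for e in doc["edges"]]
        rates = {str(lbl): {str(k): float(v) for k, v in tbl.items()} for lbl, tbl in doc["rates"].items()}
    except (KeyError, TypeError) as exc:
        raise ConfigurationError(f"malformed scheme config: {exc}") from exc
    slopes = {str(k): float(v) for k, v in (doc.get("voltage_slope_mv") or {}).items()}
    return StateScheme(states=states, edges=edges, rate_table=rates, voltage_slope_mv=slopes)


def preset_scheme(name: str) -> StateScheme:
    """Load one of the shipped gating-scheme presets.

    ``model1``: three states open - inhibited - inactivated.  ``model2``: the
    four-state chain O - I1 - I2 - I3.  ``c212s``/``y512a``/``e166a``/``e166q``
    are model-2 rate sets whose recovery relaxations sit near the 10/100/1000 ms
    calibration time constants; they are illustrative fixtures, not fitted
    parameters.
    """
    if name not in PRESET_SCHEMES:
        raise ConfigurationError(f"unknown preset {name!r}; choose from {PRESET_SCHEMES}")
    ref = resources.files("clcgating") / "schemes" / f"{name}.yaml"
    with resources.as_file(ref) as path:
        return load_scheme(path)
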