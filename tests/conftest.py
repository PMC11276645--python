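"""Shared fixtures: small gating schemes, protocols and simulated traces."""

from __future__ import annotations

import numpy as np
import pytest

from clcgating import (
    ChannelSpec,
    IonCondition,
    Protocol,
    StateScheme,
    preset_scheme,
    simulate_macroscopic,
)


def two_state_scheme(k_close: float, k_open: float, label: str = "pH7.4") -> StateScheme:
    """Open <-> closed scheme with the given rates (1/ms) under one label."""
    return StateScheme(
        states=[("O", True), ("C", False)],
        edges=[("O", "C", "kc"), ("C", "O", "ko")],
        rate_table={label: {"kc": k_close, "ko": k_open}},
    )


def unit_chain(n: int = 4) -> StateScheme:
    """Linear chain with every rate 1/ms; first state conducting."""
    states = [("O", True)] + [(f"I{i}", False) for i in range(1, n)]
    names = [s for s, _ in states]
    edges, rates = [], {}
    for a, b in zip(names[:-1], names[1:]):
        edges += [(a, b, f"{a}_{b}"), (b, a, f"{b}_{a}")]
        rates[f"{a}_{b}"] = 1.0
        rates[f"{b}_{a}"] = 1.0
    return StateScheme(states=states, edges=edges, rate_table={"x": rates})


def recovery_protocol(
    pre_ms: float = 300.0,
    acid_ms: float = 500.0,
    rec_ms: float = 8000.0,
    dt: float = 1.0,
    v_m: float = -40.0,
) -> Protocol:
    """Neutral -> acidic -> washout protocol at one voltage."""
    return Protocol(
        segments=[
            (pre_ms, IonCondition(v_m=v_m, ph_i=7.4)),
            (acid_ms, IonCondition(v_m=v_m, ph_i=5.0, label="pH5")),
            (rec_ms, IonCondition(v_m=v_m, ph_i=7.4)),
        ],
        sampling_interval=dt,
    )


@pytest.fixture(scope="session")
def c212s_scheme():
    return preset_scheme("c212s")


@pytest.fixture(scope="session")
def c212s_recovery_trace(c212s_scheme):
    """Deterministic noisy macroscopic recovery of the C212S-like preset."""
    spec = ChannelSpec(slow_scheme=c212s_scheme, single_pore_amplitude=-0.6, noise_sd=1.0)
    proto = recovery_protocol(v_m=40.0)
    return simulate_macroscopic(spec, proto, 400, mode="deterministic", seed=11)


def mono_exp_trace(tau: float, noise_sd: float, seed: int, dt: float = 1.0,
                   span: float | None = None, c: float = 1.0, a: float = -1.0):
    """Trace holding c + a*exp(-t/tau) plus Gaussian noise, starting at t=0."""
    from clcgating import Trace

    span = span if span is not None else 6.0 * tau
    t = np.arange(0.0, span, dt)
    y = c + a * np.exp(-t / tau)
    if noise_sd > 0:
        y = y + np.random.default_rng(seed).normal(0.0, noise_sd, len(t))
    return Trace(t0=0.0, dt=dt, samples=y)


def multi_exp_trace(amps, taus, noise_sd: float, seed: int, dt: float = 1.0,
                    span: float | None = None, c: float = 1.0):
    from clcgating import Trace

    span = span if span is not None else 6.0 * max(taus)
    t = np.arange(0.0, span, dt)
    y = np.full_like(t, c)
    for a, tau in zip(amps, taus):
        y = y + a * np.exp(-t / tau)
    if noise_sd > 0:
        y = y + np.random.default_rng(seed).normal(0.0, noise_sd, len(t))
    return Trace(t0=0.0, dt=dt, samples=y)
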