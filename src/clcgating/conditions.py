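"""Experimental conditions and solution-exchange protocols.

Units are fixed package-wide: time in ms, voltage in mV, concentration in mM,
current in pA, temperature in kelvin.

An :class:`IonCondition` captures one steady ionic/voltage/pH environment of
an excised inside-out patch; a :class:`Protocol` strings timed segments of
such conditions together (e.g. neutral bath -> acidic intracellular step ->
washout) and carries the sampling interval used to digitise the simulated
current.  Equilibrium electrochemistry (Nernst reversal potential, driving
force) lives here too.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import yaml
from scipy import constants as _const

__all__ = [
    "IonCondition",
    "Protocol",
    "ConditionAt",
    "nernst",
    "driving_force",
    "condition_at",
    "load_protocol",
    "DEFAULT_TEMPERATURE_K",
]

#: Default bath temperature (K), ~22 degC room temperature.  The recording
#: temperature is an assumption, flagged here and in every config.
DEFAULT_TEMPERATURE_K = 295.0


def nernst(c_in: float, c_out: float, valence: int, temperature: float = DEFAULT_TEMPERATURE_K) -> float:
    """Nernst equilibrium potential in mV.

    E = (R*T)/(z*F) * ln(c_out / c_in), with concentrations in mM (only the
    ratio matters) and the physiological sign convention (inside relative to
    outside).  For a monovalent anion (z = -1), raising the intracellular
    concentration shifts E positive.

    Parameters
    ----------
    c_in, c_out : float
        Intracellular / extracellular concentration (mM), strictly positive.
    valence : int
        Ionic charge, nonzero (Cl- is -1).
    temperature : float
        Absolute temperature (K).

    Raises
    ------
    ValueError
        If a concentration is not strictly positive, valence is 0, or
        temperature is not positive.
    """
    if c_in <= 0 or c_out <= 0:
        raise ValueError(f"concentrations must be > 0, got c_in={c_in}, c_out={c_out}")
    if valence == 0:
        raise ValueError("valence must be nonzero")
    if temperature <= 0:
        raise ValueError(f"temperature must be > 0 K, got {temperature}")
    rt_over_f_mv = 1e3 * _const.R * temperature / _const.physical_constants["Faraday constant"][0]
    return rt_over_f_mv / valence * math.log(c_out / c_in)


@dataclass(frozen=True)
class IonCondition:
    """One steady recording condition (voltage, pH, anion composition).

    ``anion_in`` / ``anion_out`` map anion species name (e.g. ``"Cl"``,
    ``"SCN"``, ``"Br"``) to concentration in mM.  ``label`` optionally names
    the condition for rate-table lookup in kinetic schemes; when omitted a
    label is derived from the intracellular pH (``"pH7.4"``, ``"pH5"``),
    which is the axis the gating schemes here key on.
    """

    v_m: float = -40.0
    ph_i: float = 7.4
    ph_o: float = 7.4
    anion_in: Mapping[str, float] = field(default_factory=lambda: {"Cl": 140.0})
    anion_out: Mapping[str, float] = field(default_factory=lambda: {"Cl": 140.0})
    temperature: float = DEFAULT_TEMPERATURE_K
    label: Optional[str] = None

    def __post_init__(self) -> None:
        for side, conc in (("anion_in", self.anion_in), ("anion_out", self.anion_out)):
            if not conc:
                raise ValueError(f"{side} must contain at least one anion species")
            for name, c in conc.items():
                if c < 0:
                    raise ValueError(f"{side}[{name!r}] = {c} mM is negative")
            if all(c == 0 for c in conc.values()):
                raise ValueError(f"{side} has no permeant anion present")
        for name, ph in (("ph_i", self.ph_i), ("ph_o", self.ph_o)):
            if not 0.0 <= ph <= 14.0:
                raise ValueError(f"{name} = {ph} outside [0, 14]")
        if self.temperature <= 0:
            raise ValueError(f"temperature must be > 0 K, got {self.temperature}")

    @property
    def rate_label(self) -> str:
        """Condition label used to look up kinetic rate tables."""
        if self.label is not None:
            return self.label
        return f"pH{self.ph_i:g}"

    def e_rev(self, species: str = "Cl") -> float:
        """Nernst reversal potential (mV) for one anion species.

        Falls back to the dominant intracellular anion if ``species`` is
        absent on either side (selectivity differences between anions are
        carried by condition-specific rate tables, not a permeability model).
        """
        if species not in self.anion_in or species not in self.anion_out:
            species = max(self.anion_in, key=self.anion_in.get)  # type: ignore[arg-type]
            if species not in self.anion_out:
                raise ValueError(f"no shared permeant anion to compute a reversal potential")
        return nernst(self.anion_in[species], self.anion_out[species], -1, self.temperature)

    def driving_force_mv(self, species: str = "Cl") -> float:
        return driving_force(self, self.e_rev(species))


def driving_force(cond: IonCondition, e_rev: float) -> float:
    """Electrochemical driving force V_m - E_rev in mV."""
    return cond.v_m - e_rev


@dataclass(frozen=True)
class Protocol:
    """Ordered timed segments of conditions plus digitisation settings.

    ``exchange_tau`` is the solution-exchange time constant in ms; 0 means an
    instantaneous switch (the default — a fast exchanger).  ``sampling_interval``
    is the digitisation period in ms.
    """

    segments: Sequence[tuple[float, IonCondition]]
    exchange_tau: float = 0.0
    sampling_interval: float = 0.2

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("protocol needs at least one segment")
        for dur, _ in self.segments:
            if dur <= 0:
                raise ValueError(f"segment duration must be > 0 ms, got {dur}")
        if self.sampling_interval <= 0:
            raise ValueError("sampling_interval must be > 0 ms")
        if self.exchange_tau < 0:
            raise ValueError("exchange_tau must be >= 0 ms")
        object.__setattr__(self, "segments", tuple((float(d), c) for d, c in self.segments))

    @property
    def total_duration(self) -> float:
        return sum(d for d, _ in self.segments)

    def segment_starts(self) -> list[float]:
        starts, t = [], 0.0
        for dur, _ in self.segments:
            starts.append(t)
            t += dur
        return starts


@dataclass(frozen=True)
class ConditionAt:
    """Condition active at a query time, with solution-exchange mixing.

    ``weight`` is the fraction of the *current* segment's solution present:
    1 for an instantaneous exchanger, 1 - exp(-dt/exchange_tau) otherwise,
    where dt is the time since the segment switch.  ``previous`` is the
    condition being washed out (equals ``condition`` in the first segment).
    """

    condition: IonCondition
    previous: IonCondition
    weight: float


def condition_at(protocol: Protocol, t: float) -> ConditionAt:
    """Condition active at time ``t`` (ms from protocol start).

    Raises a ``ValueError`` when ``t`` lies outside [0, total duration].
    ``t`` equal to the total duration maps to the final segment.
    """
    total = protocol.total_duration
    if t < 0 or t > total:
        raise ValueError(f"t={t} ms outside protocol span [0, {total}]")
    t_start = 0.0
    prev_cond = protocol.segments[0][1]
    for dur, cond in protocol.segments:
        if t < t_start + dur or t_start + dur >= total:
            dt = t - t_start
            if protocol.exchange_tau > 0:
                w = 1.0 - math.exp(-dt / protocol.exchange_tau)
            else:
                w = 1.0
            return ConditionAt(condition=cond, previous=prev_cond, weight=w)
        t_start += dur
        prev_cond = cond
    raise AssertionError("unreachable")  # pragma: no cover


def _condition_from_dict(d: Mapping) -> IonCondition:
    return IonCondition(
        v_m=float(d.get("v_m_mv", -40.0)),
        ph_i=float(d.get("ph_i", 7.4)),
        ph_o=float(d.get("ph_o", 7.4)),
        anion_in={str(k): float(v) for k, v in (d.get("anions_in") or {"Cl": 140.0}).items()},
        anion_out={str(k): float(v) for k, v in (d.get("anions_out") or {"Cl": 140.0}).items()},
        temperature=float(d.get("temperature_k", DEFAULT_TEMPERATURE_K)),
        label=d.get("label"),
    )


def load_protocol(path) -> Protocol:
    """Read a protocol config (YAML).

    Expected keys: ``segments`` (list of mappings with ``duration_ms``,
    ``v_m_mv``, ``ph_i``, ``ph_o``, ``anions_in``, ``anions_out``, optional
    ``label``), optional ``exchange_tau_ms`` and ``sampling_khz``.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "segments" not in doc:
        raise ValueError(f"{path}: protocol config must define 'segments'")
    segments = []
    for seg in doc["segments"]:
        if "duration_ms" not in seg:
            raise ValueError(f"{path}: each segment needs 'duration_ms'")
        segments.append((float(seg["duration_ms"]), _condition_from_dict(seg)))
    sampling_khz = float(doc.get("sampling_khz", 5.0))
    return Protocol(
        segments=segments,
        exchange_tau=float(doc.get("exchange_tau_ms", 0.0)),
        sampling_interval=1.0 / sampling_khz,
    )
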