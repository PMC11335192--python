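"""Core trace containers: voltage-step protocol, single sweeps, recording sets.

A :class:`Sweep` is one current trace recorded while the membrane is stepped
from the holding potential to a single test potential.  A
:class:`RecordingSet` groups one sweep per protocol potential for one solution
condition (e.g. "ND98", "betaine 10 mM", "SKF89976a 30 uM").
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InputDomainError, ProtocolMismatchError


@dataclass(frozen=True)
class VoltageStepProtocol:
    """Square voltage-step protocol.

    Defaults reproduce the standard TEVC protocol for GAT1 oocyte recordings:
    holding -60 mV, 0.8 s steps from -140 to +40 mV in 20 mV increments,
    sampled at 1 kHz.
    """

    holding_mV: float = -60.0
    step_start_s: float = 0.1
    step_duration_s: float = 0.8
    test_potentials_mV: tuple = tuple(float(v) for v in range(-140, 41, 20))
    sample_rate_hz: float = 1000.0
    post_step_s: float = 0.1

    def __post_init__(self):
        if self.step_duration_s <= 0:
            raise InputDomainError("step_duration_s must be > 0")
        if self.sample_rate_hz <= 0:
            raise InputDomainError("sample_rate_hz must be > 0")
        pots = tuple(float(v) for v in self.test_potentials_mV)
        if len(pots) < 1 or any(b <= a for a, b in zip(pots, pots[1:])):
            raise InputDomainError("test potentials must be strictly increasing")
        object.__setattr__(self, "test_potentials_mV", pots)

    @property
    def step_end_s(self) -> float:
        return self.step_start_s + self.step_duration_s

    @property
    def total_duration_s(self) -> float:
        return self.step_end_s + self.post_step_s

    def time_axis(self) -> np.ndarray:
        n = int(round(self.total_duration_s * self.sample_rate_hz))
        return np.arange(n) / self.sample_rate_hz

    def timing_fields(self) -> dict:
        return {
            "holding_mV": self.holding_mV,
            "step_start_s": self.step_start_s,
            "step_duration_s": self.step_duration_s,
            "sample_rate_hz": self.sample_rate_hz,
        }


@dataclass
class Sweep:
    """One current trace at one test potential (inward current negative)."""

    test_potential_mV: float
    time_s: np.ndarray
    current_nA: np.ndarray

    def __post_init__(self):
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.current_nA = np.asarray(self.current_nA, dtype=float)
        if self.time_s.shape != self.current_nA.shape or self.time_s.size < 2:
            raise InputDomainError("time and current must be equal-length arrays of >= 2 samples")
        dt = np.diff(self.time_s)
        if np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-9, atol=1e-12):
            raise InputDomainError("time axis must be strictly increasing with constant spacing")

    @property
    def sample_rate_hz(self) -> float:
        return 1.0 / (self.time_s[1] - self.time_s[0])

    def copy_with(self, current_nA: np.ndarray) -> "Sweep":
        return Sweep(self.test_potential_mV, self.time_s.copy(), np.asarray(current_nA, float))


@dataclass
class RecordingSet:
    """One sweep per protocol potential for a single solution condition."""

    condition_label: str
    solution: dict
    sweeps: dict  # test_potential_mV -> Sweep
    protocol: VoltageStepProtocol
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        pots = set(float(v) for v in self.protocol.test_potentials_mV)
        have = set(float(v) for v in self.sweeps)
        if pots != have:
            raise InputDomainError(
                f"recording set must hold exactly one sweep per protocol potential; "
                f"missing {sorted(pots - have)}, extra {sorted(have - pots)}"
            )
        for v, sw in self.sweeps.items():
            if float(sw.test_potential_mV) != float(v):
                raise InputDomainError(f"sweep keyed {v} mV carries test potential {sw.test_potential_mV}")

    def sweep_at(self, v_mV: float) -> Sweep:
        return self.sweeps[float(v_mV)]

    def potentials(self) -> list:
        return list(self.protocol.test_potentials_mV)


def check_protocols_match(a: VoltageStepProtocol, b: VoltageStepProtocol) -> None:
    """Raise :class:`ProtocolMismatchError` naming the first differing field."""
    for name in ("holding_mV", "step_start_s", "step_duration_s", "sample_rate_hz",
                 "test_potentials_mV", "post_step_s"):
        va, vb = getattr(a, name), getattr(b, name)
        if va != vb:
            raise ProtocolMismatchError(f"protocol field {name!r} differs: {va} vs {vb}")
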