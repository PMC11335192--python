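"""Forward simulator of voltage-clamp recordings, dose-response tables,
GABA x betaine competition grids, and superfusion efflux time courses.

Every analysis stage in this package is validated by parameter recovery
against this generator, so the generator is first-class, tested code with
known closed forms.

Charge-movement model
---------------------
A two-state Eyring scheme with a symmetric barrier: one elementary charge
packet of effective valence ``z_eff`` distributes between an outer and an
inner position.  With the reduced potential ``u = (V - V_half)/sigma`` where
``sigma = R*T/(z_eff*F)``:

* inward rate   ``beta(V)  = k0 * exp(-u/2)``
* outward rate  ``alpha(V) = k0 * exp(+u/2)``
* steady-state inward occupancy ``f(V) = 1/(1 + exp(u))`` (a Boltzmann)
* relaxation time constant ``tau(V) = 1/(alpha + beta)``

After a step from the holding potential Vh to V the displaced charge relaxes
mono-exponentially; the transient current is ``dQ/tau * exp(-t/tau)`` with
``dQ = Qmax*(f(V) - f(Vh))``, so the trace integral equals dQ exactly.

Steady transport model
----------------------
Two substrates G (GABA-like, uM) and B (betaine-like, mM) compete for the
transport site; each carries current in proportion to its occupancy:

    I = factor(V) * (I_G*g + I_B*b) / (1 + g + b),   g = G/K_G, b = B/K_B

This pure competitive form is a Moebius function of B and is therefore
strictly monotone in B at fixed G: it reproduces competitive inhibition but
can never produce a biphasic (dual-effect) row.  To emulate a slow secondary
substrate that also throttles the primary substrate's turnover — betaine
captures outward-facing transporters and slows the cycle, an effect that
saturating GABA outcompetes — an optional high-affinity slowdown term
``K_inh`` divides the G-current term by ``1 + (B/K_inh)/(1+g)^2``.  With
``K_inh=None`` (the default) the pinned competitive form is recovered
exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .constants import DEFAULT_TEMPERATURE_K, boltzmann_sigma_mV
from .errors import InputDomainError
from .protocol import RecordingSet, Sweep, VoltageStepProtocol

__all__ = [
    "ChargeMovementParams",
    "CellParams",
    "TwoSubstrateParams",
    "NoiseSpec",
    "EffluxSimParams",
    "SolutionCondition",
    "steady_state_two_substrate",
    "simulate_sweep",
    "simulate_condition_set",
    "simulate_dose_response",
    "default_tevc_noise_sd",
    "peak_pss_amplitude",
    "simulate_efflux",
    "EffluxTimeCourse",
]


# --------------------------------------------------------------------------- #
# parameter containers
# --------------------------------------------------------------------------- #

@dataclass(frozen=True)
class ChargeMovementParams:
    """Ground-truth parameters of the two-state charge movement.

    Qmax
        Total displaceable charge (nC).
    V_half
        Midpoint potential of the Boltzmann occupancy (mV).
    z_eff
        Effective valence of the moving charge (dimensionless, > 0).
    k0
        Rate scale at V = V_half (1/s); tau(V_half) = 1/(2*k0).  The default
        keeps the fastest relaxation in the protocol (~12 ms at -140 mV)
        well resolved at the 1 kHz sampling rate.
    temperature_K
        Absolute temperature; sets sigma = R*T/(z_eff*F).
    """

    Qmax: float = 10.0
    V_half: float = -32.87
    z_eff: float = 1.0
    k0: float = 10.0
    temperature_K: float = DEFAULT_TEMPERATURE_K

    def __post_init__(self):
        if self.Qmax == 0:
            raise InputDomainError("Qmax must be nonzero")
        if self.z_eff <= 0:
            raise InputDomainError("z_eff must be > 0")
        if self.k0 <= 0:
            raise InputDomainError("k0 must be > 0")
        if not np.isfinite(self.sigma_mV) or self.sigma_mV <= 0:
            raise InputDomainError("derived sigma must be finite and positive")

    @property
    def sigma_mV(self) -> float:
        return boltzmann_sigma_mV(self.z_eff, self.temperature_K)

    # closed forms ---------------------------------------------------------- #
    def reduced_potential(self, V_mV):
        return (np.asarray(V_mV, float) - self.V_half) / self.sigma_mV

    def occupancy(self, V_mV):
        """Steady-state inward occupancy f(V) = 1/(1+exp(u)); decreasing in V."""
        return 1.0 / (1.0 + np.exp(self.reduced_potential(V_mV)))

    def Q_in(self, V_mV):
        return self.Qmax * self.occupancy(V_mV)

    def inrate(self, V_mV):
        """beta(V) = k0*exp(-u/2): rate of charge moving into the vestibule."""
        return self.k0 * np.exp(-0.5 * self.reduced_potential(V_mV))

    def outrate(self, V_mV):
        """alpha(V) = k0*exp(+u/2): rate of charge leaving the vestibule."""
        return self.k0 * np.exp(+0.5 * self.reduced_potential(V_mV))

    def tau(self, V_mV):
        return 1.0 / (self.inrate(V_mV) + self.outrate(V_mV))

    def delta_Q(self, V_mV, holding_mV: float):
        """Charge displaced by a step Vh -> V (nC)."""
        return self.Qmax * (self.occupancy(V_mV) - self.occupancy(holding_mV))


@dataclass(frozen=True)
class CellParams:
    """Passive cell properties: membrane capacitance and linear leak."""

    Cm: float = 200.0          # nF; stage V-VI oocyte scale
    tau_c: float = 1.0         # ms; capacitive relaxation
    g_leak: float = 1.0        # nA/mV
    E_leak: float = -20.0      # mV

    def __post_init__(self):
        if self.Cm < 0:
            raise InputDomainError("Cm must be >= 0")
        if self.tau_c <= 0:
            raise InputDomainError("tau_c must be > 0")
        if self.g_leak < 0:
            raise InputDomainError("g_leak must be >= 0")

    def leak_current(self, V_mV):
        return self.g_leak * (np.asarray(V_mV, float) - self.E_leak)


def _default_voltage_scale(V_mV):
    """Monotone sigmoid in [0,1]: more transport at hyperpolarized potentials."""
    return 1.0 / (1.0 + np.exp((np.asarray(V_mV, float) - 0.0) / 30.0))


@dataclass(frozen=True)
class TwoSubstrateParams:
    """Parameters of the competitive two-substrate transport current.

    I_G / K_G: maximal current (nA, inward negative) and half-maximal
    concentration (uM) for the primary substrate G.  I_B / K_B: same for the
    secondary substrate B (mM).  ``voltage_scale`` maps V (mV) to a factor in
    [0,1].  ``K_inh`` (mM), when set, is the high-affinity slowdown constant
    of the dual-effect extension; None disables it.
    """

    I_G: float = -150.0
    K_G: float = 16.0
    I_B: float = -80.0
    K_B: float = 11.57
    voltage_scale: Callable = _default_voltage_scale
    K_inh: Optional[float] = None

    def __post_init__(self):
        if self.K_G <= 0 or self.K_B <= 0:
            raise InputDomainError("K_G and K_B must be > 0")
        if self.K_inh is not None and self.K_inh <= 0:
            raise InputDomainError("K_inh must be > 0 when set")

    def factor(self, V_mV):
        f = np.asarray(self.voltage_scale(V_mV), float)
        if np.any(f < 0) or np.any(f > 1):
            raise InputDomainError("voltage_scale factor must lie in [0,1]")
        return f


@dataclass(frozen=True)
class NoiseSpec:
    """Additive white Gaussian noise (post-filter) and the seed that makes it
    reproducible.  ``sd_rel`` is an optional multiplicative component used by
    the table generators (dose-response, efflux)."""

    sd_current: float = 0.0    # nA, additive
    seed: Optional[int] = None
    sd_rel: float = 0.0        # dimensionless, multiplicative

    def __post_init__(self):
        if self.sd_current < 0 or self.sd_rel < 0:
            raise InputDomainError("noise standard deviations must be >= 0")

    @property
    def is_noisy(self) -> bool:
        return self.sd_current > 0 or self.sd_rel > 0

    def require_seed(self):
        if self.is_noisy and self.seed is None:
            raise InputDomainError("NoiseSpec with nonzero noise requires an explicit seed")

    def rng(self, *spawn_key: int) -> np.random.Generator:
        seed = 0 if self.seed is None else int(self.seed)
        return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=list(spawn_key)))


@dataclass(frozen=True)
class EffluxSimParams:
    """Superfusion release-assay generator parameters.

    basal_rate: basal fractional release (% per min).  k_max: maximal
    drug-induced fractional release (% per min).  K_half: half-maximal drug
    concentration (dose-axis units).  rise_fractions: fractions needed to
    reach the plateau.  monensin_factor: multiplicative scaling of the
    induced component when monensin is present.  total_load: initial tracer
    content (counts).
    """

    basal_rate: float = 0.12
    k_max: float = 0.8
    K_half: float = 6.73
    rise_fractions: int = 2
    monensin_factor: float = 2.0
    total_load: float = 1.0e5
    fraction_minutes: float = 2.0

    def __post_init__(self):
        if self.basal_rate < 0 or self.k_max < 0:
            raise InputDomainError("basal_rate and k_max must be >= 0")
        if self.K_half <= 0:
            raise InputDomainError("K_half must be > 0")
        if self.total_load <= 0:
            raise InputDomainError("total_load must be > 0")
        if self.rise_fractions < 1:
            raise InputDomainError("rise_fractions must be >= 1")
        if self.monensin_factor < 0:
            raise InputDomainError("monensin_factor must be >= 0")


@dataclass(frozen=True)
class SolutionCondition:
    """Descriptor of one perfused solution in a voltage-step experiment."""

    label: str
    gaba_uM: float = 0.0
    betaine_mM: float = 0.0
    blocker: bool = False          # e.g. SKF89976a: no PSS, no transport
    zero_transport: bool = False   # e.g. TMA98 sodium substitution

    def __post_init__(self):
        if self.gaba_uM < 0 or self.betaine_mM < 0:
            raise InputDomainError("concentrations must be >= 0")


# --------------------------------------------------------------------------- #
# steady-state transport
# --------------------------------------------------------------------------- #

def steady_state_two_substrate(G: float, B: float, params: TwoSubstrateParams,
                               V: float = -60.0) -> float:
    """Steady transport current (nA) for substrate concentrations G (uM) and
    B (mM) at potential V.

    Pure competitive occupancy model; when ``params.K_inh`` is set the
    G-current term is additionally divided by ``1 + (B/K_inh)/(1+g)^2``
    (slow-substrate capture of free transporters, outcompeted by G).
    """
    G = np.asarray(G, float)
    B = np.asarray(B, float)
    if np.any(G < 0) or np.any(B < 0):
        raise InputDomainError("concentrations must be >= 0")
    g = G / params.K_G
    b = B / params.K_B
    term_G = params.I_G * g
    if params.K_inh is not None:
        term_G = term_G / (1.0 + (B / params.K_inh) / (1.0 + g) ** 2)
    current = params.factor(V) * (term_G + params.I_B * b) / (1.0 + g + b)
    return float(current) if np.ndim(current) == 0 else current


# --------------------------------------------------------------------------- #
# voltage-step sweeps
# --------------------------------------------------------------------------- #

def pss_components(protocol: VoltageStepProtocol, test_V: float,
                   cm_params: ChargeMovementParams) -> tuple:
    """(dQ, tau) of the ON pre-steady-state relaxation for one step."""
    dQ = float(cm_params.delta_Q(test_V, protocol.holding_mV))
    tau = float(cm_params.tau(test_V))
    return dQ, tau


def simulate_sweep(protocol: VoltageStepProtocol, test_V: float,
                   cm_params: Optional[ChargeMovementParams], cell: CellParams,
                   steady_current: float = 0.0,
                   noise: NoiseSpec = NoiseSpec(),
                   _rng: Optional[np.random.Generator] = None) -> Sweep:
    """Simulate one voltage-step sweep.

    The trace is the sum of a capacitive transient, ohmic leak, the ON (and
    OFF) pre-steady-state relaxation, the steady transport current during the
    step, and optional Gaussian noise.  ``cm_params=None`` suppresses the
    charge movement (blocker-like condition).
    """
    test_V = float(test_V)
    if test_V not in [float(v) for v in protocol.test_potentials_mV]:
        raise InputDomainError(
            f"test potential {test_V} mV is not in the protocol {protocol.test_potentials_mV}")
    noise.require_seed()

    t = protocol.time_axis()
    i = np.zeros_like(t)
    on = (t >= protocol.step_start_s) & (t < protocol.step_end_s)
    off = t >= protocol.step_end_s
    t_on = t[on] - protocol.step_start_s
    t_off = t[off] - protocol.step_end_s
    dV = test_V - protocol.holding_mV
    tau_c_s = cell.tau_c * 1e-3

    # leak (holding-level leak outside the step)
    i += cell.leak_current(protocol.holding_mV)
    i[on] += cell.leak_current(test_V) - cell.leak_current(protocol.holding_mV)

    # capacitive transients: integral of the ON transient equals Cm*dV
    if cell.Cm > 0 and dV != 0:
        amp_c = 1e-3 * cell.Cm * dV / tau_c_s  # nF*mV = pC -> nC/s = nA
        i[on] += amp_c * np.exp(-t_on / tau_c_s)
        i[off] += -amp_c * np.exp(-t_off / tau_c_s)

    # pre-steady-state relaxation
    if cm_params is not None:
        dQ, tau = pss_components(protocol, test_V, cm_params)
        if dQ != 0.0:
            i[on] += dQ / tau * np.exp(-t_on / tau)
            tau_h = float(cm_params.tau(protocol.holding_mV))
            # charge relaxes back at the holding potential after the step
            dQ_back = dQ * np.exp(-protocol.step_duration_s / tau)  # undissipated part ~ 0
            i[off] += -(dQ - dQ_back) / tau_h * np.exp(-t_off / tau_h)

    i[on] += steady_current

    if noise.sd_current > 0:
        rng = _rng if _rng is not None else noise.rng()
        i = i + rng.normal(0.0, noise.sd_current, size=i.shape)

    return Sweep(test_V, t, i)


def peak_pss_amplitude(protocol: VoltageStepProtocol,
                       cm_params: ChargeMovementParams,
                       at_offset_s: float = 0.0,
                       voltage_range: Optional[tuple] = None) -> float:
    """Peak |PSS current| over the protocol potentials (nA).

    ``at_offset_s`` evaluates the transient a fixed delay after the step
    onset — at the default capacitive-exclusion delay this is the peak as
    actually observable on a recording.  ``voltage_range`` optionally
    restricts the potentials considered (e.g. the analysis range).
    """
    pots = protocol.test_potentials_mV
    if voltage_range is not None:
        lo, hi = voltage_range
        pots = [v for v in pots if lo <= v <= hi]
    amps = [abs(cm_params.delta_Q(v, protocol.holding_mV) / cm_params.tau(v))
            * np.exp(-at_offset_s / cm_params.tau(v)) for v in pots]
    return float(max(amps))


def default_tevc_noise_sd(protocol: VoltageStepProtocol,
                          cm_params: ChargeMovementParams,
                          fraction: float = 0.05,
                          at_offset_s: float = 0.005,
                          voltage_range: tuple = (-120.0, 20.0)) -> float:
    """Canonical TEVC noise level: a fraction (default 5%) of the PSS peak
    as observable at the start of the analysis window, over the analyzed
    voltage range."""
    return fraction * peak_pss_amplitude(protocol, cm_params, at_offset_s,
                                         voltage_range)


def modulated_charge_movement(cm_params: ChargeMovementParams,
                              transport: TwoSubstrateParams,
                              cond: SolutionCondition,
                              modulation_c: float = 4.0) -> ChargeMovementParams:
    """Substrate modulation of the charge movement.

    The combined substrate load L = G/K_G + B/K_B scales Qmax by 1/(1+L)
    (charge displacement shrinks toward saturation) and k0 by (1+c*L)
    (relaxations speed up), reproducing the empirical disappearance of PSS
    currents at saturating substrate without claiming a mechanism.  The
    default c = 4 makes the transient at >= 20x-saturating substrate too fast
    to observe past the capacitive window (< 1% of the substrate-free peak).
    """
    L = cond.gaba_uM / transport.K_G + cond.betaine_mM / transport.K_B
    return replace(cm_params, Qmax=cm_params.Qmax / (1.0 + L),
                   k0=cm_params.k0 * (1.0 + modulation_c * L))


def simulate_condition_set(protocol: VoltageStepProtocol,
                           cm_params: ChargeMovementParams,
                           cell: CellParams,
                           transport: TwoSubstrateParams,
                           conditions: Sequence[SolutionCondition],
                           noise: NoiseSpec = NoiseSpec(),
                           modulation_c: float = 4.0) -> dict:
    """Simulate one :class:`RecordingSet` per solution condition.

    Blocker conditions contain capacitive + leak only; substrate conditions
    carry modulated charge movement and the competitive steady current.
    Identical seeds yield bit-identical outputs.
    """
    labels = [c.label for c in conditions]
    if len(set(labels)) != len(labels):
        raise InputDomainError(f"duplicate condition labels: {labels}")
    noise.require_seed()

    out = {}
    for ci, cond in enumerate(conditions):
        sweeps = {}
        for vi, v in enumerate(protocol.test_potentials_mV):
            if cond.blocker or cond.zero_transport:
                cmp_, steady = None, 0.0
            else:
                cmp_ = modulated_charge_movement(cm_params, transport, cond, modulation_c)
                steady = steady_state_two_substrate(cond.gaba_uM, cond.betaine_mM,
                                                    transport, v)
            rng = noise.rng(ci, vi) if noise.sd_current > 0 else None
            sweeps[float(v)] = simulate_sweep(protocol, v, cmp_, cell, steady,
                                              noise, _rng=rng)
        out[cond.label] = RecordingSet(
            condition_label=cond.label,
            solution={"gaba_uM": cond.gaba_uM, "betaine_mM": cond.betaine_mM,
                      "blocker": cond.blocker, "zero_transport": cond.zero_transport},
            sweeps=sweeps, protocol=protocol,
            meta={"seed": noise.seed, "condition_index": ci,
                  "generator": generator_params_dict(cm_params, cell, transport,
                                                     noise=noise)},
        )
    return out


def generator_params_dict(cm_params: Optional[ChargeMovementParams] = None,
                          cell: Optional[CellParams] = None,
                          transport: Optional[TwoSubstrateParams] = None,
                          efflux: Optional[EffluxSimParams] = None,
                          noise: Optional[NoiseSpec] = None) -> dict:
    """All generator parameter sets as one plain dict (e.g. for a YAML config
    or a file-header comment).  ``voltage_scale`` is a callable and is not
    serialized; loading applies the default sigmoid."""
    out = {}
    if cm_params is not None:
        out["charge_movement"] = {
            "Qmax": cm_params.Qmax, "V_half": cm_params.V_half,
            "z_eff": cm_params.z_eff, "k0": cm_params.k0,
            "temperature_K": cm_params.temperature_K}
    if cell is not None:
        out["cell"] = {"Cm": cell.Cm, "tau_c": cell.tau_c,
                       "g_leak": cell.g_leak, "E_leak": cell.E_leak}
    if transport is not None:
        out["transport"] = {"I_G": transport.I_G, "K_G": transport.K_G,
                            "I_B": transport.I_B, "K_B": transport.K_B,
                            "K_inh": transport.K_inh}
    if efflux is not None:
        out["efflux"] = {
            "basal_rate": efflux.basal_rate, "k_max": efflux.k_max,
            "K_half": efflux.K_half, "rise_fractions": efflux.rise_fractions,
            "monensin_factor": efflux.monensin_factor,
            "total_load": efflux.total_load,
            "fraction_minutes": efflux.fraction_minutes}
    if noise is not None:
        out["noise"] = {"sd_current": noise.sd_current, "seed": noise.seed,
                        "sd_rel": noise.sd_rel}
    return out


def generator_params_from_dict(d: dict) -> dict:
    """Inverse of :func:`generator_params_dict`: rebuild the parameter
    dataclasses present in ``d`` (keys: charge_movement, cell, transport,
    efflux, noise)."""
    builders = {"charge_movement": ChargeMovementParams, "cell": CellParams,
                "transport": TwoSubstrateParams, "efflux": EffluxSimParams,
                "noise": NoiseSpec}
    return {key: builders[key](**d[key]) for key in d if key in builders}


# --------------------------------------------------------------------------- #
# dose-response tables
# --------------------------------------------------------------------------- #

def hill_current(S, Imax: float, K_half: float, p: float = 1.0):
    """Logistic (Hill) transport current through the origin."""
    S = np.asarray(S, float)
    return Imax * S ** p / (S ** p + K_half ** p)


def simulate_dose_response(Imax: float, K_half: float, p: float,
                           concs: Sequence[float],
                           noise: NoiseSpec = NoiseSpec(),
                           n_replicates: int = 8,
                           unit: str = "mM") -> pd.DataFrame:
    """Simulate a dose-response table: mean +- SEM of ``n_replicates`` cells
    per concentration, with multiplicative (sd_rel) and additive (sd_current)
    Gaussian noise."""
    concs = np.asarray(sorted(float(c) for c in concs))
    if np.any(concs <= 0):
        raise InputDomainError("concentrations must be > 0")
    if p <= 0:
        raise InputDomainError("Hill exponent p must be > 0")
    if K_half <= 0:
        raise InputDomainError("K_half must be > 0")
    noise.require_seed()

    rows = []
    for k, S in enumerate(concs):
        mu = hill_current(S, Imax, K_half, p)
        if noise.is_noisy:
            rng = noise.rng(k)
            vals = mu * (1.0 + rng.normal(0.0, noise.sd_rel, n_replicates))
            vals = vals + rng.normal(0.0, noise.sd_current, n_replicates)
            mean = float(np.mean(vals))
            sem = float(np.std(vals, ddof=1) / np.sqrt(n_replicates))
        else:
            mean, sem = float(mu), 0.0
        rows.append({"concentration": S, "unit": unit, "mean_current_nA": mean,
                     "sem_nA": sem, "n_cells": n_replicates, "n_batches": 1})
    return pd.DataFrame(rows)


def simulate_competition_records(transport: TwoSubstrateParams,
                                 gaba_concs_uM: Sequence[float],
                                 betaine_concs_mM: Sequence[float],
                                 noise: NoiseSpec = NoiseSpec(),
                                 n_cells: int = 6,
                                 V: float = -60.0) -> pd.DataFrame:
    """Long-format per-cell currents over the full (GABA+0) x (betaine+0)
    factorial, the layout of an 84-condition competition assay."""
    noise.require_seed()
    g_levels = [0.0] + sorted(float(g) for g in gaba_concs_uM)
    b_levels = [0.0] + sorted(float(b) for b in betaine_concs_mM)
    rows = []
    idx = 0
    for G in g_levels:
        for B in b_levels:
            mu = steady_state_two_substrate(G, B, transport, V)
            for cell_i in range(n_cells):
                val = mu
                if noise.is_noisy:
                    rng = noise.rng(idx, cell_i)
                    val = mu * (1.0 + rng.normal(0.0, noise.sd_rel)) \
                        + rng.normal(0.0, noise.sd_current)
                rows.append({"gaba_uM": G, "betaine_mM": B, "current_nA": float(val),
                             "cell_id": f"c{cell_i}", "batch_id": "b0"})
            idx += 1
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------- #
# efflux
# --------------------------------------------------------------------------- #

@dataclass
class EffluxTimeCourse:
    """Per-fraction released tracer counts from one superfused well."""

    fraction_minutes: float
    released_counts: np.ndarray
    remaining_counts: float
    condition: dict = field(default_factory=dict)

    def __post_init__(self):
        self.released_counts = np.asarray(self.released_counts, dtype=float)
        if self.released_counts.size < 2:
            raise InputDomainError("a time course needs >= 2 fractions")
        if np.any(self.released_counts < 0) or self.remaining_counts < 0:
            raise InputDomainError("counts must be >= 0")

    @property
    def total_counts(self) -> float:
        return float(self.released_counts.sum() + self.remaining_counts)

    @property
    def n_fractions(self) -> int:
        return int(self.released_counts.size)


def simulate_efflux(params: EffluxSimParams, dose: float,
                    n_basal: int = 4, n_drug: int = 5,
                    monensin: bool = False,
                    noise: NoiseSpec = NoiseSpec()) -> EffluxTimeCourse:
    """Simulate one well's efflux time course.

    Basal fractions release ``basal_rate * fraction_minutes`` percent of the
    content remaining at each fraction start; drug fractions ramp linearly
    over ``rise_fractions`` to a plateau of
    ``(basal_rate + scaled k_max * dose/(dose+K_half)) * fraction_minutes``
    percent.  Depletion is cumulative, so released + remaining is conserved.
    """
    if dose < 0:
        raise InputDomainError("dose must be >= 0")
    if n_basal < 1 or n_drug < 1:
        raise InputDomainError("n_basal and n_drug must be >= 1")
    noise.require_seed()

    k_ind = params.k_max * dose / (dose + params.K_half)
    if monensin:
        k_ind *= params.monensin_factor
    plateau = params.basal_rate + k_ind
    rates = [params.basal_rate] * n_basal
    for j in range(n_drug):
        ramp = min(1.0, (j + 1) / params.rise_fractions)
        rates.append(params.basal_rate + ramp * k_ind)
    rates = np.asarray(rates)

    rng = noise.rng() if noise.is_noisy else None
    remaining = params.total_load
    released = []
    for r in rates:
        frac = r * params.fraction_minutes / 100.0
        amount = frac * remaining
        if rng is not None:
            amount *= max(0.0, 1.0 + rng.normal(0.0, noise.sd_rel))
            amount += rng.normal(0.0, noise.sd_current)
            amount = min(max(amount, 0.0), remaining)
        released.append(amount)
        remaining -= amount
    return EffluxTimeCourse(
        fraction_minutes=params.fraction_minutes,
        released_counts=np.asarray(released),
        remaining_counts=remaining,
        condition={"dose": dose, "monensin": monensin, "n_basal": n_basal,
                   "n_drug": n_drug, "plateau_rate_pct_per_min": plateau,
                   "seed": noise.seed},
    )
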