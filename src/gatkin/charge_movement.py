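"""Pre-steady-state (PSS) charge-movement pipeline.

Stages, in pipeline order: blocker subtraction -> per-potential
mono-exponential relaxation fit -> charge integration -> Boltzmann Q-V fit ->
unidirectional rate constants, plus steady-current measurement and trace
utilities.

The central identities are the Boltzmann description of the displaced charge,

    Q(V) = Q_offset + Qmax / (1 + exp[-(V - V_half)/sigma]),

and the decomposition of the relaxation rate into unidirectional rate
constants,

    inrate(V)  = (1/tau) * Qin/Qmax,
    outrate(V) = (1/tau) * (1 - Qin/Qmax),

so that inrate + outrate = 1/tau holds exactly at every potential.  "inrate"
is the rate of charge moving into the transporter vestibule (the occupancy
that saturates at hyperpolarized potentials) and "outrate" the rate of charge
leaving it; the Greek aliases alpha (outrate) and beta (inrate) are display
names only.

Conventions
-----------
* The relaxation amplitude ``A`` is referenced to the step onset, not to the
  start of the fit window: the fitted model is
  ``I(t) = A*exp(-(t - step_start)/tau) + baseline`` evaluated inside the
  window.  ``Q = A*tau`` is then the total displaced charge, independent of
  where the capacitive-exclusion window begins.
* Only ON transients (at the test potential) are analyzed; OFF transients at
  the return to holding are ignored.
* The Boltzmann fit carries a free offset because integrated charge is only
  defined relative to the holding potential; reported parameters are
  normalized to sigma > 0 with the curve orientation kept as a flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import GatkinError, InputDomainError
from .protocol import RecordingSet, Sweep, VoltageStepProtocol, check_protocols_match

__all__ = [
    "RelaxationFit", "QVPoint", "BoltzmannFit", "RateTable", "PssConfig", "PssResult",
    "smooth_adjacent_average", "subtract_blocker", "fit_relaxation",
    "integrate_charge", "trapezoid_charge", "fit_boltzmann", "derive_rates",
    "measure_steady_current", "measure_plateau_current", "run_pss_pipeline",
]


# --------------------------------------------------------------------------- #
# containers
# --------------------------------------------------------------------------- #

@dataclass
class RelaxationFit:
    """Mono-exponential fit of one subtracted sweep's ON relaxation."""

    test_potential_mV: float
    amplitude_nA: float            # referenced to step onset
    tau_s: float
    baseline_nA: float
    fit_window_s: tuple            # absolute (start, end) in sweep time
    step_start_s: float
    rss: float
    converged: bool
    se_amplitude_nA: float = np.nan
    se_tau_s: float = np.nan
    cov_amp_tau: float = np.nan
    reason: str = ""

    @property
    def charge_se_nC(self) -> float:
        """Delta-method standard error of Q = A*tau from the fit covariance."""
        if not (np.isfinite(self.se_amplitude_nA) and np.isfinite(self.se_tau_s)):
            return np.nan
        var = ((self.tau_s * self.se_amplitude_nA) ** 2
               + (self.amplitude_nA * self.se_tau_s) ** 2
               + 2.0 * self.amplitude_nA * self.tau_s
               * (self.cov_amp_tau if np.isfinite(self.cov_amp_tau) else 0.0))
        return float(np.sqrt(max(var, 0.0)))


@dataclass(frozen=True)
class QVPoint:
    test_potential_mV: float
    Q_nC: float


@dataclass
class BoltzmannFit:
    """Sigmoid Q-V fit, normalized so sigma > 0.

    ``orientation`` is "increasing" when the fitted curve grows with V
    (Qmax_nC > 0) and "decreasing" otherwise (Qmax_nC < 0, the usual case for
    charge referenced to a depolarized-saturating zero)."""

    Qmax_nC: float
    V_half_mV: float
    sigma_mV: float
    Q_offset_nC: float
    se: dict = field(default_factory=dict)          # per-parameter standard errors
    covariance: Optional[np.ndarray] = None         # order: offset, Qmax, V_half, sigma
    converged: bool = False
    orientation: str = "decreasing"

    def curve(self, V_mV):
        V = np.asarray(V_mV, float)
        with np.errstate(over="ignore"):
            return self.Q_offset_nC + self.Qmax_nC / (
                1.0 + np.exp(-(V - self.V_half_mV) / self.sigma_mV))

    def fraction_in(self, V_mV):
        """Boltzmann occupancy that saturates at hyperpolarized potentials.

        This is Qin/Qmax of the rate decomposition: 1 at V -> -inf, 1/2 at
        V_half, 0 at V -> +inf, with the normalized (positive) sigma.
        """
        V = np.asarray(V_mV, float)
        with np.errstate(over="ignore"):
            return 1.0 / (1.0 + np.exp((V - self.V_half_mV) / self.sigma_mV))


@dataclass
class RateTable:
    """Unidirectional rate constants per analyzed potential."""

    test_potentials_mV: np.ndarray
    inrate_per_s: np.ndarray
    outrate_per_s: np.ndarray
    tau_s: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "V_mV": self.test_potentials_mV,
            "inrate_per_s": self.inrate_per_s,
            "outrate_per_s": self.outrate_per_s,
            "tau_s": self.tau_s,
        })


# --------------------------------------------------------------------------- #
# trace utilities
# --------------------------------------------------------------------------- #

def smooth_adjacent_average(sweep: Sweep, window: int = 10) -> Sweep:
    """Adjacent-averaging smoother: each sample becomes the mean of the window
    centered on it, truncated at the trace edges.

    Even windows are widened by one to stay centered (the conventional
    ten-point filter becomes eleven).  ``window=1`` is the identity.
    """
    if window < 1:
        raise InputDomainError("window must be >= 1")
    if window % 2 == 0:
        window += 1
    n = sweep.current_nA.size
    if window > n:
        raise InputDomainError(f"window {window} exceeds trace length {n}")
    kernel = np.ones(window)
    sums = np.convolve(sweep.current_nA, kernel, mode="same")
    counts = np.convolve(np.ones(n), kernel, mode="same")
    return sweep.copy_with(sums / counts)


def subtract_blocker(test: RecordingSet, blocker: RecordingSet) -> RecordingSet:
    """Pointwise per-potential difference test - blocker.

    Subtraction removes every component common to the two conditions
    (capacitive transient, leak, holding current), isolating the
    transport-associated PSS and steady currents.
    """
    check_protocols_match(test.protocol, blocker.protocol)
    sweeps = {}
    for v in test.protocol.test_potentials_mV:
        a, b = test.sweep_at(v), blocker.sweep_at(v)
        if a.current_nA.size != b.current_nA.size:
            raise InputDomainError(
                f"sample count differs at {v} mV: {a.current_nA.size} vs {b.current_nA.size}")
        sweeps[float(v)] = a.copy_with(a.current_nA - b.current_nA)
    return RecordingSet(
        condition_label=f"{test.condition_label} - {blocker.condition_label}",
        solution={"test": test.solution, "blocker": blocker.solution},
        sweeps=sweeps, protocol=test.protocol,
        meta={"subtracted": True},
    )


# --------------------------------------------------------------------------- #
# relaxation fitting and charge integration
# --------------------------------------------------------------------------- #

def fit_relaxation(sweep: Sweep, protocol: VoltageStepProtocol,
                   window_start_offset_s: float = 0.005,
                   window_end_offset_s: Optional[float] = None) -> RelaxationFit:
    """Least-squares mono-exponential fit of the ON relaxation.

    The window is given as offsets from the step onset; the default start of
    5 ms excludes the capacitive transient.  The fit never raises on
    optimizer failure: ``converged`` is False when the optimizer fails or the
    amplitude is indistinguishable from zero at the noise level.
    """
    if window_end_offset_s is None:
        window_end_offset_s = protocol.step_duration_s
    if not (0.0 <= window_start_offset_s < window_end_offset_s
            <= protocol.step_duration_s + 1e-12):
        raise InputDomainError(
            f"fit window [{window_start_offset_s}, {window_end_offset_s}] s must lie "
            f"within the step [0, {protocol.step_duration_s}] s")
    t0 = protocol.step_start_s
    w_lo, w_hi = t0 + window_start_offset_s, t0 + window_end_offset_s
    # half-open window [start, end): the step-end sample already belongs to
    # the OFF phase and must not enter the ON fit
    mask = (sweep.time_s >= w_lo - 1e-12) & (sweep.time_s < w_hi - 1e-12)
    t = sweep.time_s[mask]
    y = sweep.current_nA[mask]
    if t.size < 10:
        raise InputDomainError(f"fit window holds {t.size} samples; >= 10 required")

    dt = 1.0 / sweep.sample_rate_hz
    span = window_end_offset_s - window_start_offset_s
    tau_lo, tau_hi = 2.0 * dt, 2.0 * span
    base0 = float(np.mean(y[-max(3, t.size // 10):]))
    a_win0 = float(y[0] - y[-1])

    # two starts: the coarse window/5 guess, plus a 1/e-crossing estimate that
    # rescues fast relaxations from shallow local minima
    tau_starts = [span / 5.0]
    dev = np.abs(y - base0)
    if dev[0] > 0:
        below = np.flatnonzero(dev <= dev[0] / np.e)
        if below.size:
            tau_starts.append(max(float(t[below[0]] - t[0]), dt))
    starts = []
    for tau0 in tau_starts:
        tau0 = min(max(tau0, tau_lo), tau_hi)
        starts.append([a_win0 * np.exp(window_start_offset_s / tau0), tau0, base0])

    def model(tt, A, tau, base):
        return A * np.exp(-(tt - t0) / tau) + base

    best = None
    for p0 in starts:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, pcov = curve_fit(
                    model, t, y, p0=p0,
                    bounds=([-np.inf, tau_lo, -np.inf], [np.inf, tau_hi, np.inf]),
                    maxfev=20000)
        except (RuntimeError, ValueError):
            continue
        rss = float(np.sum((y - model(t, *popt)) ** 2))
        if best is None or rss < best[2]:
            best = (popt, pcov, rss)
    if best is None:
        return RelaxationFit(sweep.test_potential_mV, 0.0, starts[0][1], base0,
                             (w_lo, w_hi), t0, float(np.sum((y - np.mean(y)) ** 2)),
                             converged=False, reason="optimizer failed")
    popt, pcov, _ = best

    A, tau, base = (float(p) for p in popt)
    resid = y - model(t, *popt)
    rss = float(np.sum(resid ** 2))
    with np.errstate(invalid="ignore"):
        perr = np.sqrt(np.diag(pcov))
    se_A, se_tau = float(perr[0]), float(perr[1])
    ok = np.isfinite(se_A) and abs(A) > 2.0 * se_A
    reason = "" if ok else "amplitude indistinguishable from zero"
    return RelaxationFit(sweep.test_potential_mV, A, tau, base, (w_lo, w_hi), t0,
                         rss, converged=bool(ok), se_amplitude_nA=se_A,
                         se_tau_s=se_tau, cov_amp_tau=float(pcov[0, 1]),
                         reason=reason)


def integrate_charge(fit: RelaxationFit) -> QVPoint:
    """Displaced charge from the fitted exponential: Q = A*tau (nC).

    Because the amplitude is referenced to the step onset, this is the full
    analytic integral of the relaxation, immune to leak/baseline
    contamination and to the capacitive-exclusion window.
    """
    if not fit.converged:
        raise InputDomainError(
            f"relaxation fit at {fit.test_potential_mV} mV did not converge ({fit.reason})")
    return QVPoint(fit.test_potential_mV, fit.amplitude_nA * fit.tau_s)


def trapezoid_charge(sweep: Sweep, protocol: VoltageStepProtocol,
                     baseline_nA: float = 0.0) -> float:
    """Diagnostic: numeric trapezoid of (I - baseline) over the step (nC)."""
    mask = (sweep.time_s >= protocol.step_start_s) & (sweep.time_s < protocol.step_end_s)
    return float(np.trapezoid(sweep.current_nA[mask] - baseline_nA,
                              sweep.time_s[mask]))


# --------------------------------------------------------------------------- #
# Boltzmann Q-V and rates
# --------------------------------------------------------------------------- #

def _boltzmann(V, Q_offset, Qmax, V_half, sigma):
    return Q_offset + Qmax / (1.0 + np.exp(-(V - V_half) / sigma))


def fit_boltzmann(points: Sequence[QVPoint],
                  se: Optional[Sequence[float]] = None) -> BoltzmannFit:
    """Least-squares Boltzmann fit of a Q-V relation.

    Requires >= 5 points spanning >= 80 mV.  The slope sign is free during
    optimization; the result is normalized to sigma > 0 with the orientation
    recorded.  Standard errors come from the local covariance.  When
    per-point charge uncertainties ``se`` (same order as ``points``) are all
    positive and finite the fit is weighted by 1/se^2; otherwise it is
    unweighted.
    """
    order = np.argsort([p.test_potential_mV for p in points])
    pts = [points[i] for i in order]
    V = np.array([p.test_potential_mV for p in pts], float)
    Q = np.array([p.Q_nC for p in pts], float)
    sigma_w = None
    if se is not None:
        se_arr = np.asarray(se, float)[order]
        if se_arr.shape == V.shape and np.all(np.isfinite(se_arr)) and np.all(se_arr > 0):
            sigma_w = se_arr
    if V.size < 5:
        raise InputDomainError(f"Boltzmann fit needs >= 5 points, got {V.size}")
    if V[-1] - V[0] < 80.0:
        raise InputDomainError(
            f"Boltzmann fit needs >= 80 mV of span, got {V[-1] - V[0]:.1f} mV")

    qmax0 = Q[-1] - Q[0]
    if qmax0 == 0:
        qmax0 = max(np.ptp(Q), 1e-9)
    off0 = Q[0]
    vh0 = float(V[np.argmin(np.abs(Q - (off0 + qmax0 / 2.0)))])
    sig0 = (V[-1] - V[0]) / 6.0
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, pcov = curve_fit(_boltzmann, V, Q, p0=[off0, qmax0, vh0, sig0],
                                   sigma=sigma_w, maxfev=20000)
    except (RuntimeError, ValueError):
        return BoltzmannFit(np.nan, np.nan, np.nan, np.nan, converged=False)

    off, qmax, vh, sig = (float(p) for p in popt)
    with np.errstate(invalid="ignore"):
        perr = np.sqrt(np.diag(pcov))
    se = {"Q_offset_nC": float(perr[0]), "Qmax_nC": float(perr[1]),
          "V_half_mV": float(perr[2]), "sigma_mV": float(perr[3])}
    if sig < 0:
        # 1/(1+e^{-x/s}) with s<0 equals 1 - 1/(1+e^{-x/|s|})
        off, qmax, sig = off + qmax, -qmax, -sig
        if np.all(np.isfinite(pcov)):
            se["Q_offset_nC"] = float(np.sqrt(pcov[0, 0] + pcov[1, 1] + 2 * pcov[0, 1]))
    if not np.isfinite(qmax) or qmax == 0 or not np.isfinite(sig) or sig == 0:
        return BoltzmannFit(qmax, vh, sig, off, se, pcov, converged=False)
    return BoltzmannFit(qmax, vh, sig, off, se, pcov, converged=True,
                        orientation="increasing" if qmax > 0 else "decreasing")


def derive_rates(boltz: BoltzmannFit, tau_table: dict) -> RateTable:
    """Unidirectional rate constants from the Boltzmann fraction and the
    per-potential relaxation time constants.

    inrate = fraction_in/tau and outrate = (1 - fraction_in)/tau, so
    inrate + outrate == 1/tau exactly and both are equal to 1/(2*tau) at
    V_half.
    """
    if not boltz.converged:
        raise InputDomainError("Boltzmann fit did not converge; cannot derive rates")
    V = np.array(sorted(tau_table), float)
    tau = np.array([tau_table[v] for v in V], float)
    if np.any(tau <= 0):
        raise InputDomainError("all relaxation time constants must be > 0")
    f = boltz.fraction_in(V)
    return RateTable(V, f / tau, (1.0 - f) / tau, tau)


# --------------------------------------------------------------------------- #
# steady currents
# --------------------------------------------------------------------------- #

def measure_steady_current(sweep: Sweep, protocol: VoltageStepProtocol,
                           tail_s: float = 0.1) -> float:
    """Steady transport current: mean over the last ``tail_s`` seconds of the
    step minus the pre-step holding baseline (nA)."""
    if tail_s <= 0 or tail_s > protocol.step_duration_s:
        raise InputDomainError(
            f"tail_s must lie in (0, {protocol.step_duration_s}] s, got {tail_s}")
    tail = (sweep.time_s >= protocol.step_end_s - tail_s) & \
           (sweep.time_s < protocol.step_end_s)
    pre = sweep.time_s < protocol.step_start_s
    if not np.any(tail):
        raise InputDomainError("tail window holds no samples")
    baseline = float(np.mean(sweep.current_nA[pre])) if np.any(pre) else 0.0
    return float(np.mean(sweep.current_nA[tail])) - baseline


def measure_plateau_current(trace: Sweep, t_start_s: float = 4.0,
                            t_end_s: float = 6.0) -> tuple:
    """Mean and SD of a perfusion record over the closed window
    [t_start_s, t_end_s] (the plateau-reading rule for slow solution-exchange
    recordings)."""
    if t_end_s <= t_start_s:
        raise InputDomainError("t_end_s must exceed t_start_s")
    if trace.time_s[0] > t_start_s + 1e-12 or trace.time_s[-1] < t_end_s - 1e-12:
        raise InputDomainError(
            f"record [{trace.time_s[0]}, {trace.time_s[-1]}] s does not cover "
            f"[{t_start_s}, {t_end_s}] s")
    m = (trace.time_s >= t_start_s - 1e-12) & (trace.time_s <= t_end_s + 1e-12)
    vals = trace.current_nA[m]
    return float(np.mean(vals)), float(np.std(vals))


# --------------------------------------------------------------------------- #
# the pipeline
# --------------------------------------------------------------------------- #

@dataclass(frozen=True)
class PssConfig:
    """Configuration of the PSS pipeline."""

    voltage_range_mV: tuple = (-120.0, 20.0)
    fit_window_start_offset_s: float = 0.005
    fit_window_end_offset_s: Optional[float] = None
    tail_s: float = 0.1
    smooth_window: Optional[int] = None


@dataclass
class PssResult:
    qv: pd.DataFrame                      # V_mV, Q_nC
    tau_v: pd.DataFrame                   # V_mV, tau_s, se
    boltzmann: BoltzmannFit
    rates: Optional[RateTable]
    iv: pd.DataFrame                      # V_mV, I_nA
    relaxations: dict                     # V -> RelaxationFit
    excluded: list                        # (V, reason)
    config: PssConfig


def run_pss_pipeline(test: RecordingSet, blocker: RecordingSet,
                     config: PssConfig = PssConfig()) -> PssResult:
    """Full PSS analysis: subtract -> fit relaxations -> integrate charge ->
    Boltzmann Q-V -> rate constants, plus the I-V table.

    Analysis is restricted to ``config.voltage_range_mV``; potentials whose
    relaxation fit does not converge are excluded from the Q-V/tau-V tables
    and reported in ``excluded``.  A failed Boltzmann fit (e.g. blocker vs
    blocker input) is flagged via ``boltzmann.converged`` — never an
    exception.
    """
    try:
        diff = subtract_blocker(test, blocker)
    except GatkinError as e:
        raise GatkinError(f"[subtract_blocker] {e}") from e

    proto = test.protocol
    lo, hi = config.voltage_range_mV
    analyzed = [v for v in proto.test_potentials_mV if lo <= v <= hi]

    relaxations, excluded, qv_rows, tau_rows, iv_rows = {}, [], [], [], []
    for v in analyzed:
        sw = diff.sweep_at(v)
        if config.smooth_window:
            sw = smooth_adjacent_average(sw, config.smooth_window)
        try:
            iv_rows.append({"V_mV": v,
                            "I_nA": measure_steady_current(sw, proto, config.tail_s)})
        except GatkinError as e:
            raise GatkinError(f"[measure_steady_current @ {v} mV] {e}") from e
        try:
            fit = fit_relaxation(sw, proto, config.fit_window_start_offset_s,
                                 config.fit_window_end_offset_s)
        except GatkinError as e:
            raise GatkinError(f"[fit_relaxation @ {v} mV] {e}") from e
        relaxations[v] = fit
        if not fit.converged:
            excluded.append((v, fit.reason or "fit not converged"))
            continue
        qv_rows.append({"V_mV": v, "Q_nC": integrate_charge(fit).Q_nC,
                        "se": fit.charge_se_nC})
        tau_rows.append({"V_mV": v, "tau_s": fit.tau_s, "se": fit.se_tau_s})

    qv = pd.DataFrame(qv_rows, columns=["V_mV", "Q_nC", "se"])
    tau_v = pd.DataFrame(tau_rows, columns=["V_mV", "tau_s", "se"])
    iv = pd.DataFrame(iv_rows, columns=["V_mV", "I_nA"])

    points = [QVPoint(r.V_mV, r.Q_nC) for r in qv.itertuples()]
    if len(points) >= 5 and points[-1].test_potential_mV - points[0].test_potential_mV >= 80:
        boltz = fit_boltzmann(points, se=qv["se"].to_numpy())
    else:
        boltz = BoltzmannFit(np.nan, np.nan, np.nan, np.nan, converged=False)
        if not excluded:
            excluded.append((np.nan, "too few converged potentials for Boltzmann fit"))

    rates = None
    if boltz.converged:
        tau_table = {r.V_mV: r.tau_s for r in tau_v.itertuples()}
        rates = derive_rates(boltz, tau_table)

    return PssResult(qv, tau_v, boltz, rates, iv, relaxations, excluded, config)
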