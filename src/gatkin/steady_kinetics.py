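"""Dose-response kinetics and GABA x betaine competition analysis.

The dose-response model is the logistic (Hill) transport current through the
origin,

    I(S) = Imax * S^p / (S^p + K_half^p),

with the exponent p free by default (initialized at 1) and reported so it can
be fixed by the caller.  Transport efficiency is the lumped low-substrate
capacity Imax/K_half, with its standard error from first-order (delta-method)
propagation of the fit covariance.

The competition analysis builds a mean +- SEM grid over all
(GABA, betaine) combinations including the zero level on each axis, and
characterizes per-GABA-row dual-effect (biphasic) behaviour: the row is split
at the betaine level of minimal |current|; the descending limb is fitted with
a decreasing logistic (IC50-style) and the ascending limb with a Hill fit on
the increment above the minimum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import InputDomainError

__all__ = [
    "DoseResponseFit", "CompetitionGrid", "DualEffectFit", "BranchFit",
    "fit_dose_response", "transport_efficiency", "build_competition_grid",
    "analyze_dual_effect", "normalized_inhibition", "fit_hill",
]


# --------------------------------------------------------------------------- #
# Hill fitting
# --------------------------------------------------------------------------- #

def _hill(S, Imax, K, p):
    return Imax * S ** p / (S ** p + K ** p)


def fit_hill(x: np.ndarray, y: np.ndarray, sigma: Optional[np.ndarray] = None,
             fix_p: Optional[float] = None) -> dict:
    """Shared Hill/logistic fitter used by dose-response, dual-effect and
    efflux kinetics.  Returns a dict with parameters, standard errors, the
    covariance (order Imax, K_half[, p]) and a convergence flag."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if np.any(x <= 0):
        raise InputDomainError("concentrations must be > 0")
    if np.all(y == 0) or np.ptp(y) == 0:
        return {"Imax": 0.0, "K_half": np.nan, "p": np.nan, "se": {},
                "covariance": None, "converged": False}

    imax0 = y[np.argmax(np.abs(y))]
    half = imax0 / 2.0
    k0 = float(x[np.argmin(np.abs(y - half))])
    k0 = min(max(k0, x.min()), x.max())
    kw = dict(maxfev=20000)
    if sigma is not None and np.all(np.asarray(sigma) > 0):
        kw["sigma"] = np.asarray(sigma, float)

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if fix_p is None:
                popt, pcov = curve_fit(
                    _hill, x, y, p0=[imax0, k0, 1.0],
                    bounds=([-np.inf, 1e-12, 0.05], [np.inf, np.inf, 10.0]), **kw)
                imax, k, p = (float(v) for v in popt)
            else:
                popt, pcov = curve_fit(
                    lambda S, Imax, K: _hill(S, Imax, K, fix_p), x, y,
                    p0=[imax0, k0], bounds=([-np.inf, 1e-12], [np.inf, np.inf]), **kw)
                imax, k = (float(v) for v in popt)
                p = float(fix_p)
    except (RuntimeError, ValueError):
        return {"Imax": np.nan, "K_half": np.nan, "p": np.nan, "se": {},
                "covariance": None, "converged": False}

    with np.errstate(invalid="ignore"):
        perr = np.sqrt(np.diag(pcov))
    se = {"Imax": float(perr[0]), "K_half": float(perr[1])}
    if fix_p is None:
        se["p"] = float(perr[2])
    converged = np.isfinite(k) and k > 0 and np.isfinite(imax)
    return {"Imax": imax, "K_half": k, "p": p, "se": se, "covariance": pcov,
            "converged": bool(converged)}


# --------------------------------------------------------------------------- #
# dose-response
# --------------------------------------------------------------------------- #

@dataclass
class DoseResponseFit:
    """Hill fit of a dose-response table, plus the transport efficiency."""

    Imax_nA: float
    K_half: float
    p: float
    unit: str = "mM"
    se: dict = field(default_factory=dict)
    covariance: Optional[np.ndarray] = None        # order: Imax, K_half[, p]
    efficiency: float = np.nan                     # Imax/K_half, nA per unit
    efficiency_se: Optional[float] = None
    converged: bool = False

    def curve(self, S):
        return _hill(np.asarray(S, float), self.Imax_nA, self.K_half, self.p)


def _validate_dose_table(table: pd.DataFrame) -> pd.DataFrame:
    required = {"concentration", "mean_current_nA"}
    missing = required - set(table.columns)
    if missing:
        raise InputDomainError(f"dose-response table lacks columns {sorted(missing)}")
    t = table.sort_values("concentration").reset_index(drop=True)
    conc = t["concentration"].to_numpy(float)
    if np.any(conc <= 0):
        raise InputDomainError("concentrations must be > 0")
    if np.any(np.diff(conc) <= 0):
        raise InputDomainError("concentrations must be strictly increasing (no duplicates)")
    if "unit" in t.columns and t["unit"].nunique() > 1:
        raise InputDomainError(f"inconsistent concentration units: {sorted(t['unit'].unique())}")
    return t


def fit_dose_response(table: pd.DataFrame, fix_p: Optional[float] = None) -> DoseResponseFit:
    """Weighted (1/sem^2 where SEMs are available) Hill fit through the origin.

    Needs >= 4 concentrations (>= 3 when p is fixed).  A degenerate table
    (all currents zero) yields ``converged=False`` rather than an error.
    """
    t = _validate_dose_table(table)
    n_min = 3 if fix_p is not None else 4
    if len(t) < n_min:
        raise InputDomainError(f"need >= {n_min} concentrations, got {len(t)}")
    unit = str(t["unit"].iloc[0]) if "unit" in t.columns else "mM"
    sem = t["sem_nA"].to_numpy(float) if "sem_nA" in t.columns else None
    if sem is not None and not np.all(sem > 0):
        sem = None  # fall back to unweighted
    res = fit_hill(t["concentration"].to_numpy(float),
                   t["mean_current_nA"].to_numpy(float), sigma=sem, fix_p=fix_p)
    fit = DoseResponseFit(res["Imax"], res["K_half"], res["p"], unit,
                          res["se"], res["covariance"], converged=res["converged"])
    if fit.converged:
        fit.efficiency, fit.efficiency_se = transport_efficiency(fit)
    return fit


def transport_efficiency(fit: DoseResponseFit) -> tuple:
    """Transport efficiency Imax/K_half (nA per concentration unit) with its
    delta-method standard error; SE is None when the covariance is missing."""
    if fit.Imax_nA == 0:
        return 0.0, (0.0 if fit.covariance is not None else None)
    if not np.isfinite(fit.K_half) or fit.K_half <= 0:
        raise InputDomainError("K_half must be positive and finite")
    eff = fit.Imax_nA / fit.K_half
    if fit.covariance is None or not np.all(np.isfinite(fit.covariance[:2, :2])):
        return eff, None
    grad = np.array([1.0 / fit.K_half, -fit.Imax_nA / fit.K_half ** 2])
    var = float(grad @ fit.covariance[:2, :2] @ grad)
    return eff, float(np.sqrt(max(var, 0.0)))


# --------------------------------------------------------------------------- #
# competition grid
# --------------------------------------------------------------------------- #

@dataclass
class CompetitionGrid:
    """Mean +- SEM current grid over (GABA incl 0) x (betaine incl 0)."""

    gaba_concs_uM: np.ndarray
    betaine_concs_mM: np.ndarray
    mean_current_nA: np.ndarray    # shape (len(gaba), len(betaine))
    sem_nA: np.ndarray
    n: np.ndarray
    n_conditions: int = 0

    def row(self, gaba_uM: float) -> pd.DataFrame:
        idx = np.flatnonzero(np.isclose(self.gaba_concs_uM, gaba_uM))
        if idx.size == 0:
            raise InputDomainError(
                f"GABA level {gaba_uM} uM not in grid {list(self.gaba_concs_uM)}")
        i = int(idx[0])
        return pd.DataFrame({"betaine_mM": self.betaine_concs_mM,
                             "mean_current_nA": self.mean_current_nA[i],
                             "sem_nA": self.sem_nA[i], "n": self.n[i]})


def build_competition_grid(records: pd.DataFrame,
                           expected_conditions: Optional[int] = None) -> CompetitionGrid:
    """Aggregate long-format per-cell measurements into a condition grid.

    ``records`` columns: gaba_uM, betaine_mM, current_nA (cell_id/batch_id
    optional).  SEM is NaN where a condition has a single measurement.  When
    ``expected_conditions`` is given (e.g. 84 for the full 7 x 12 factorial)
    a mismatch triggers a warning, never an error.
    """
    for col in ("gaba_uM", "betaine_mM", "current_nA"):
        if col not in records.columns:
            raise InputDomainError(f"competition records lack column {col!r}")
    g_levels = np.array(sorted(records["gaba_uM"].unique()), float)
    b_levels = np.array(sorted(records["betaine_mM"].unique()), float)
    if 0.0 not in g_levels or 0.0 not in b_levels:
        raise InputDomainError("grid needs a zero level on each axis (buffer-only reference)")

    shape = (g_levels.size, b_levels.size)
    mean = np.full(shape, np.nan)
    sem = np.full(shape, np.nan)
    n = np.zeros(shape, dtype=int)
    grouped = records.groupby(["gaba_uM", "betaine_mM"])["current_nA"]
    for (G, B), vals in grouped:
        i = int(np.flatnonzero(np.isclose(g_levels, G))[0])
        j = int(np.flatnonzero(np.isclose(b_levels, B))[0])
        v = vals.to_numpy(float)
        mean[i, j] = v.mean()
        n[i, j] = v.size
        sem[i, j] = v.std(ddof=1) / np.sqrt(v.size) if v.size > 1 else np.nan
    if np.isnan(mean[np.isclose(g_levels, 0)][:, np.isclose(b_levels, 0)]).any():
        raise InputDomainError("zero-zero (buffer-only) condition is missing")

    n_cond = int(np.sum(n > 0))
    if expected_conditions is not None and n_cond != expected_conditions:
        warnings.warn(f"grid holds {n_cond} conditions, expected {expected_conditions}",
                      stacklevel=2)
    return CompetitionGrid(g_levels, b_levels, mean, sem, n, n_cond)


# --------------------------------------------------------------------------- #
# dual-effect analysis
# --------------------------------------------------------------------------- #

@dataclass
class BranchFit:
    """One limb of a dual-effect row."""

    params: dict = field(default_factory=dict)
    se: dict = field(default_factory=dict)
    converged: bool = False
    n_points: int = 0
    reason: str = ""


@dataclass
class DualEffectFit:
    gaba_conc_uM: float
    split_betaine_mM: float
    inhibition_branch: Optional[BranchFit]
    transport_branch: Optional[BranchFit]
    biphasic: bool
    reason: str = ""


def _dec_logistic(B, top, bottom, IC50, p):
    return bottom + (top - bottom) / (1.0 + (B / IC50) ** p)


def analyze_dual_effect(grid: CompetitionGrid, gaba_row: float,
                        fix_p: Optional[float] = 1.0) -> DualEffectFit:
    """Characterize one GABA row of the competition grid.

    The split is the tested betaine level minimizing |mean current| (ties
    broken toward the lower concentration).  ``biphasic`` requires the
    minimum to be interior and at least 3 betaine levels on each side of the
    split; otherwise the flag is False with a reason and no limb is fitted
    where points are lacking.
    """
    row = grid.row(gaba_row).dropna(subset=["mean_current_nA"])
    B = row["betaine_mM"].to_numpy(float)
    I = row["mean_current_nA"].to_numpy(float)
    sem = row["sem_nA"].to_numpy(float)
    mag = np.abs(I)
    split_idx = int(np.argmin(mag))  # argmin takes the first (lowest B) on ties
    split_B = float(B[split_idx])

    interior = 0 < split_idx < B.size - 1
    n_lo = split_idx                 # levels strictly below the split
    n_hi = B.size - 1 - split_idx    # levels strictly above
    reason = ""
    if not interior:
        reason = "row |current| minimum is at a boundary (monotone row)"
    elif n_lo < 3 or n_hi < 3:
        reason = f"too few betaine levels per limb (low {n_lo}, high {n_hi})"
    biphasic = interior and n_lo >= 3 and n_hi >= 3

    inhibition = None
    if n_lo >= 3:
        lo = slice(0, split_idx + 1)
        x, y = B[lo], mag[lo]
        xs = np.where(x > 0, x, np.nan)
        p_fit = 1.0 if fix_p is None else fix_p
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, pcov = curve_fit(
                    lambda b, top, bottom, ic50: _dec_logistic(b, top, bottom, ic50, p_fit),
                    x, y, p0=[y[0], y[-1], max(np.nanmedian(xs), 1e-6)],
                    bounds=([-np.inf, -np.inf, 1e-12], [np.inf, np.inf, np.inf]),
                    maxfev=20000)
            perr = np.sqrt(np.diag(pcov))
            inhibition = BranchFit(
                {"top_nA": float(popt[0]), "bottom_nA": float(popt[1]),
                 "IC50_mM": float(popt[2]), "p": p_fit},
                {"top_nA": float(perr[0]), "bottom_nA": float(perr[1]),
                 "IC50_mM": float(perr[2])},
                converged=True, n_points=int(x.size))
        except (RuntimeError, ValueError):
            inhibition = BranchFit(converged=False, n_points=int(x.size),
                                   reason="descending-limb fit failed")
    elif split_idx > 0:
        inhibition = BranchFit(converged=False, n_points=n_lo,
                               reason="too few points for descending limb")

    transport = None
    if n_hi >= 3:
        hi = slice(split_idx + 1, B.size)
        x = B[hi]
        y = mag[hi] - mag[split_idx]   # increment above the minimum
        res = fit_hill(x, y, sigma=sem[hi] if np.all(sem[hi] > 0) else None,
                       fix_p=fix_p)
        transport = BranchFit(
            {"Imax_increment_nA": res["Imax"], "K_half_mM": res["K_half"],
             "p": res["p"]},
            res["se"], converged=res["converged"], n_points=int(x.size))
    elif split_idx < B.size - 1:
        transport = BranchFit(converged=False, n_points=n_hi,
                              reason="too few points for ascending limb")

    return DualEffectFit(float(gaba_row), split_B, inhibition, transport,
                         biphasic, reason)


def normalized_inhibition(grid: CompetitionGrid, gaba_row: float) -> pd.DataFrame:
    """Per-betaine current as a fraction of the GABA-alone (betaine 0) mean,
    with delta-method standard errors."""
    row = grid.row(gaba_row)
    ref_mask = np.isclose(row["betaine_mM"].to_numpy(float), 0.0)
    if not ref_mask.any():
        raise InputDomainError("GABA-alone (betaine 0) cell missing from row")
    m0 = float(row.loc[ref_mask, "mean_current_nA"].iloc[0])
    s0 = float(row.loc[ref_mask, "sem_nA"].iloc[0])
    if m0 == 0:
        raise InputDomainError("GABA-alone current is zero; cannot normalize")
    m = row["mean_current_nA"].to_numpy(float)
    s = row["sem_nA"].to_numpy(float)
    frac = m / m0
    if np.isfinite(s0):
        se = np.sqrt((s / m0) ** 2 + (m * s0 / m0 ** 2) ** 2)
    else:
        se = np.full_like(frac, np.nan)
    return pd.DataFrame({"betaine_mM": row["betaine_mM"], "fraction": frac, "se": se})
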