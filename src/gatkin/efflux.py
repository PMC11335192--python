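"""Quantification of superfusion (batch release) assays.

Cells preloaded with a radiotracer are washed in timed fractions; the tracer
counts released per fraction, expressed as a percentage of the total (sum of
all released fractions plus the content remaining in the cells at the end),
measure efflux.  The basal rate is the mean percent of the drug-free
fractions divided by the fraction length; the drug-induced rate is read at
the plateau of the drug phase; induced rates over a dose series are fitted
with the logistic (Hill) model to give the half-maximal dose K_half.

The plateau rule: the first drug-phase fraction whose percent differs from
the next fraction by less than ``plateau_threshold`` (default 10%) of the
drug-phase range; when no fraction qualifies the final fraction is used and
flagged.  Both basal-corrected and uncorrected induced rates are reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import InputDomainError
from .simulate import EffluxTimeCourse
from .steady_kinetics import fit_hill

__all__ = [
    "EffluxTimeCourse", "InducedEfflux", "EffluxKinetics",
    "fractional_release", "basal_rate", "induced_efflux", "fit_efflux_kinetics",
]


def fractional_release(time_course: EffluxTimeCourse) -> np.ndarray:
    """Per-fraction released tracer as percent of the total load.

    total = sum(released) + remaining, so the percent series plus the
    remaining percent sums to exactly 100.
    """
    total = time_course.total_counts
    if total <= 0:
        raise InputDomainError("total tracer content must be > 0")
    return 100.0 * time_course.released_counts / total


def basal_rate(time_course: EffluxTimeCourse, n_basal_fractions: int = 4) -> tuple:
    """Basal efflux rate (% per min) with its standard error from
    between-fraction scatter of the first ``n_basal_fractions`` fractions."""
    if n_basal_fractions < 2:
        raise InputDomainError("need >= 2 basal fractions")
    if time_course.n_fractions < n_basal_fractions:
        raise InputDomainError(
            f"time course holds {time_course.n_fractions} fractions, "
            f"fewer than the {n_basal_fractions} basal fractions requested")
    pct = fractional_release(time_course)[:n_basal_fractions]
    fl = time_course.fraction_minutes
    rate = float(np.mean(pct) / fl)
    se = float(np.std(pct, ddof=1) / np.sqrt(n_basal_fractions) / fl)
    return rate, se


@dataclass
class InducedEfflux:
    """Plateau-read drug-induced efflux for one time course."""

    uncorrected_pct_per_min: float
    corrected_pct_per_min: float        # basal-subtracted
    basal_pct_per_min: float
    plateau_fraction_index: int         # index within the drug phase
    plateau_found: bool


def induced_efflux(time_course: EffluxTimeCourse,
                   n_basal_fractions: Optional[int] = None,
                   plateau_threshold: float = 0.1) -> InducedEfflux:
    """Drug-induced efflux (% per min) read at the drug-phase plateau.

    Emits both the uncorrected value (plateau percent / fraction length) and
    the basal-corrected one; when no plateau is detectable the final fraction
    is used with ``plateau_found=False``.
    """
    if n_basal_fractions is None:
        n_basal_fractions = int(time_course.condition.get("n_basal", 4))
    pct = fractional_release(time_course)
    drug = pct[n_basal_fractions:]
    if drug.size < 2:
        raise InputDomainError("need >= 2 drug-phase fractions")

    rng = float(np.ptp(drug))
    plateau_idx, found = drug.size - 1, False
    if rng == 0.0:
        plateau_idx, found = 0, True
    else:
        for i in range(drug.size - 1):
            if abs(drug[i + 1] - drug[i]) < plateau_threshold * rng:
                plateau_idx, found = i, True
                break
    fl = time_course.fraction_minutes
    unc = float(drug[plateau_idx] / fl)
    bas, _ = basal_rate(time_course, n_basal_fractions)
    return InducedEfflux(unc, unc - bas, bas, plateau_idx, found)


@dataclass
class EffluxKinetics:
    """Concentration-response of induced efflux."""

    basal_rate: float = np.nan
    basal_se: float = np.nan
    doses: np.ndarray = field(default_factory=lambda: np.array([]))
    induced: np.ndarray = field(default_factory=lambda: np.array([]))
    induced_se: Optional[np.ndarray] = None
    K_half: float = np.nan
    K_half_se: float = np.nan
    max_induced: float = np.nan
    max_induced_se: float = np.nan
    p: float = np.nan
    covariance: Optional[np.ndarray] = None
    with_monensin: bool = False
    converged: bool = False


def fit_efflux_kinetics(doses: Sequence[float], induced_values: Sequence[float],
                        induced_se: Optional[Sequence[float]] = None,
                        with_monensin: bool = False,
                        fix_p: Optional[float] = None,
                        basal: float = np.nan,
                        basal_se: float = np.nan) -> EffluxKinetics:
    """Hill fit induced(d) = max_induced * d^p / (d^p + K_half^p).

    Needs >= 4 doses.  Degenerate responses (all equal, e.g. a blocked
    negative control) yield ``converged=False``.  Monensin datasets are
    fitted independently; the flag is carried for bookkeeping only.
    """
    d = np.asarray(doses, float)
    y = np.asarray(induced_values, float)
    if d.size != y.size:
        raise InputDomainError("doses and induced values must have equal length")
    if d.size < 4:
        raise InputDomainError(f"need >= 4 doses, got {d.size}")
    if np.any(d <= 0):
        raise InputDomainError("doses must be > 0")
    order = np.argsort(d)
    d, y = d[order], y[order]
    se = None
    if induced_se is not None:
        se = np.asarray(induced_se, float)[order]
        if not np.all(se > 0):
            se = None

    res = fit_hill(d, y, sigma=se, fix_p=fix_p)
    out = EffluxKinetics(basal_rate=basal, basal_se=basal_se, doses=d, induced=y,
                         induced_se=se, with_monensin=with_monensin,
                         covariance=res["covariance"], converged=res["converged"],
                         p=res["p"])
    if res["converged"]:
        out.K_half = res["K_half"]
        out.K_half_se = res["se"].get("K_half", np.nan)
        out.max_induced = res["Imax"]
        out.max_induced_se = res["se"].get("Imax", np.nan)
    return out
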