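"""Exposure metrics, infant-dose quantities and prediction-error statistics.

Infant exposure via breastfeeding is summarised as

    DID  = C_milk * milk intake (0.150 L/kg/day)          [mg/kg/day]
    RID  = 100 * DID / (daily maternal dose / maternal weight)   [%]
    RID_therapeutic = 100 * DID / therapeutic infant dose        [%]

using the average (AUC/tau) and maximum milk concentrations over a dosing
interval at steady state.  Model evaluation uses the fold error
10^|log10(pred/obs)| with the conventional two-fold acceptance bound and the
geometric mean fold error (GMFE) as aggregate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "LactationConstants",
    "ExposureMetrics",
    "InfantDoseReport",
    "trapezoid_auc",
    "exposure_metrics",
    "mp_ratio",
    "daily_infant_dose",
    "relative_infant_dose",
    "relative_therapeutic_dose",
    "fold_error",
    "within_two_fold",
    "gmfe",
    "infant_dose_report",
]


@dataclass(frozen=True)
class LactationConstants:
    """Fixed constants of the infant-dose calculation.

    ``milk_intake`` is the daily human-milk intake of the infant in L/kg/day
    (150 mL/kg body weight); ``maternal_weight`` the average three-months
    postpartum maternal weight in kg.
    """

    milk_intake: float = 0.150  # L/kg/day
    maternal_weight: float = 60.3  # kg

    def __post_init__(self) -> None:
        if self.milk_intake <= 0 or self.maternal_weight <= 0:
            raise ValueError("constants must be > 0")


DEFAULT_CONSTANTS = LactationConstants()


@dataclass(frozen=True)
class ExposureMetrics:
    """AUC, Cmax, tmax and average concentration over a stated interval."""

    auc: float  # mg*h/L
    cmax: float  # mg/L
    tmax: float  # h
    cave: float  # mg/L


@dataclass(frozen=True)
class InfantDoseReport:
    """Milk-to-plasma ratio and infant-dose metrics for one regimen."""

    mp_ratio: float
    did_ave: float  # mg/kg/day
    did_max: float  # mg/kg/day
    rid_ave: float  # %
    rid_max: float  # %
    rid_therapeutic_ave: Optional[float] = None  # %
    rid_therapeutic_max: Optional[float] = None  # %
    constants: LactationConstants = DEFAULT_CONSTANTS
    plasma: Optional[ExposureMetrics] = None
    milk: Optional[ExposureMetrics] = None


def trapezoid_auc(
    times: Sequence[float],
    conc: Sequence[float],
    t0: Optional[float] = None,
    t1: Optional[float] = None,
) -> float:
    """Linear-trapezoid AUC on ``[t0, t1]`` with interpolated bounds."""
    t = np.asarray(times, dtype=float)
    c = np.asarray(conc, dtype=float)
    if t0 is None:
        t0 = float(t[0])
    if t1 is None:
        t1 = float(t[-1])
    eps = 1e-9 * max(1.0, abs(float(t[-1])))
    if not (t[0] - eps <= t0 < t1 <= t[-1] + eps):
        raise ValueError(
            f"[{t0}, {t1}] outside sampled range [{t[0]}, {t[-1]}] or empty"
        )
    inner = t[(t > t0) & (t < t1)]
    grid = np.concatenate([[t0], inner, [t1]])
    vals = np.interp(grid, t, c)
    return float(np.trapezoid(vals, grid))


def exposure_metrics(
    times: Sequence[float],
    conc: Sequence[float],
    t0: Optional[float] = None,
    t1: Optional[float] = None,
) -> ExposureMetrics:
    """Interval AUC, Cmax, tmax and Cave (= AUC / interval length)."""
    t = np.asarray(times, dtype=float)
    c = np.asarray(conc, dtype=float)
    if t0 is None:
        t0 = float(t[0])
    if t1 is None:
        t1 = float(t[-1])
    auc = trapezoid_auc(t, c, t0, t1)
    sel = (t >= t0) & (t <= t1)
    imax = int(np.argmax(c[sel]))
    return ExposureMetrics(
        auc=auc,
        cmax=float(c[sel][imax]),
        tmax=float(t[sel][imax]),
        cave=auc / (t1 - t0),
    )


def mp_ratio(auc_milk: float, auc_plasma: float) -> float:
    """AUC-based milk-to-plasma ratio over a dosing interval."""
    if auc_plasma <= 0:
        raise ValueError("auc_plasma must be > 0")
    return auc_milk / auc_plasma


def daily_infant_dose(
    c_milk: float, constants: LactationConstants = DEFAULT_CONSTANTS
) -> float:
    """DID in mg/kg/day; pass Cave for DID_ave, Cmax for DID_max."""
    if c_milk < 0:
        raise ValueError("c_milk must be >= 0")
    return c_milk * constants.milk_intake


def relative_infant_dose(
    did: float,
    daily_maternal_dose: float,
    constants: LactationConstants = DEFAULT_CONSTANTS,
) -> float:
    """RID in %: infant dose relative to the weight-normalised maternal dose."""
    if daily_maternal_dose <= 0:
        raise ValueError("daily_maternal_dose must be > 0")
    return 100.0 * did / (daily_maternal_dose / constants.maternal_weight)


def relative_therapeutic_dose(did: float, therapeutic_dose: float) -> float:
    """DID as a percentage of the therapeutic infant dose (mg/kg/day)."""
    if therapeutic_dose <= 0:
        raise ValueError("therapeutic_dose must be > 0")
    return 100.0 * did / therapeutic_dose


def fold_error(predicted: float, observed: float) -> float:
    """Fold error 10^|log10(pred/obs)|, always >= 1."""
    if predicted <= 0 or observed <= 0:
        raise ValueError("predicted and observed must be > 0")
    return 10.0 ** abs(math.log10(predicted / observed))


def within_two_fold(predicted: float, observed: float) -> bool:
    return fold_error(predicted, observed) <= 2.0


def gmfe(pairs: Iterable[Tuple[float, float]]) -> float:
    """Geometric mean fold error over (predicted, observed) pairs."""
    logs = [abs(math.log10(p / o)) for p, o in pairs]
    if not logs:
        raise ValueError("gmfe needs at least one pair")
    return 10.0 ** (sum(logs) / len(logs))


def infant_dose_report(
    sim,
    daily_maternal_dose: float,
    therapeutic_dose: Optional[float] = None,
    constants: LactationConstants = DEFAULT_CONSTANTS,
) -> InfantDoseReport:
    """Build an :class:`InfantDoseReport` from a steady-state interval sim.

    ``sim`` is a :class:`~lactopk.pk_engine.SimResult` covering exactly one
    dosing interval at (periodic) steady state.
    """
    plasma = exposure_metrics(sim.times, sim.c_plasma)
    milk = exposure_metrics(sim.times, sim.c_milk)
    did_ave = daily_infant_dose(milk.cave, constants)
    did_max = daily_infant_dose(milk.cmax, constants)
    kw = {}
    if therapeutic_dose is not None:
        kw["rid_therapeutic_ave"] = relative_therapeutic_dose(did_ave, therapeutic_dose)
        kw["rid_therapeutic_max"] = relative_therapeutic_dose(did_max, therapeutic_dose)
    return InfantDoseReport(
        mp_ratio=mp_ratio(milk.auc, plasma.auc),
        did_ave=did_ave,
        did_max=did_max,
        rid_ave=relative_infant_dose(did_ave, daily_maternal_dose, constants),
        rid_max=relative_infant_dose(did_max, daily_maternal_dose, constants),
        constants=constants,
        plasma=plasma,
        milk=milk,
        **kw,
    )
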