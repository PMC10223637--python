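"""Maternal compartmental PK model coupled to a fixed-volume milk compartment.

The maternal disposition is a reduced 1--3 compartment model (central volume,
optional peripherals, optional first-order oral absorption with lag).  The
milk compartment has a fixed volume (default 0.5 L) and exchanges with the
central compartment through unbound-concentration-driven clearances:

    dN_milk/dt = C_plasma * fu_plasma * CLsec - C_milk * fu_milk_total * CLre

with no other milk outflow (no nursing removal).  An optional
perfusion-limited breast-tissue compartment can be enabled for structural
fidelity; it does not intercept the plasma<->milk exchange.

All compartment states are amounts in mg; concentrations are mg/L.  The
system is linear and time-invariant between dose events, so integration is
restarted exactly at every discontinuity.  Two integrators are offered:
``"lsoda"`` (stiff-capable ``scipy.integrate.solve_ivp``) and ``"expm"``
(piecewise matrix-exponential propagation, exact for this linear system).
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy.integrate import solve_ivp
from scipy.linalg import expm

from .milk_transfer import MilkTransferParams
from .physchem import DrugPhysChem

__all__ = [
    "Route",
    "DoseEvent",
    "MaternalPKParams",
    "LactationPhysiology",
    "Regimen",
    "LactationModel",
    "SimResult",
    "SimulationError",
    "build_model",
    "simulate",
    "simulate_to_steady_state",
    "nca_terminal_slope",
    "nca_auc_to_inf",
]

ML_PER_L = 1000.0


class SimulationError(RuntimeError):
    """Raised when the integrator fails or produces an invalid state."""


class Route(str, Enum):
    iv_bolus = "iv_bolus"
    iv_infusion = "iv_infusion"
    oral = "oral"


@dataclass(frozen=True)
class DoseEvent:
    """A single administration: time (h), amount (mg), route.

    ``duration`` (h) applies to infusions only.
    """

    time: float
    amount: float
    route: Route = Route.iv_bolus
    duration: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "route", Route(self.route))
        if self.time < 0:
            raise ValueError(f"dose time must be >= 0, got {self.time}")
        if self.amount < 0:
            raise ValueError(f"dose amount must be >= 0, got {self.amount}")
        if self.route is Route.iv_infusion and self.duration <= 0:
            raise ValueError("iv_infusion requires duration > 0")


@dataclass(frozen=True)
class MaternalPKParams:
    """Reduced maternal disposition parameters.

    ``peripherals`` is a sequence of ``(volume L, intercompartmental
    clearance L/h)`` pairs.  ``ka`` (1/h) is required only for oral dosing.
    """

    cl: float
    vc: float
    peripherals: Tuple[Tuple[float, float], ...] = ()
    ka: Optional[float] = None
    f: float = 1.0
    tlag: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "peripherals", tuple((float(v), float(q)) for v, q in self.peripherals)
        )
        if self.cl <= 0 or self.vc <= 0:
            raise ValueError("cl and vc must be > 0")
        for v, q in self.peripherals:
            if v <= 0 or q <= 0:
                raise ValueError("peripheral volumes and clearances must be > 0")
        if not 0.0 < self.f <= 1.0:
            raise ValueError(f"f must be in (0, 1], got {self.f}")
        if self.ka is not None and self.ka <= 0:
            raise ValueError("ka must be > 0 when given")
        if self.tlag < 0:
            raise ValueError("tlag must be >= 0")


@dataclass(frozen=True)
class LactationPhysiology:
    """Physiological constants of the lactating state (three months postpartum).

    The milk compartment volume is fixed (default 0.5 L, population
    geometric SD 1.16).  Breast volume, specific blood flow and the
    vascular/interstitial/intracellular sub-fractions are carried for the
    optional breast-tissue state; hematocrit is a standard adult reference
    value (not part of the published constants, configurable).
    """

    v_milk: float = 0.5  # L
    v_milk_gsd: float = 1.16
    breast_volume: float = 1.0  # L
    breast_flow: float = 27.0  # mL/min/100 g organ
    frac_vascular: float = 0.14
    frac_interstitial: float = 0.10
    frac_intracellular: float = 0.76
    hematocrit: float = 0.47

    def __post_init__(self) -> None:
        if self.v_milk <= 0 or self.breast_volume <= 0 or self.breast_flow <= 0:
            raise ValueError("volumes and flows must be > 0")
        if self.v_milk_gsd < 1.0:
            raise ValueError("v_milk_gsd must be >= 1")
        s = self.frac_vascular + self.frac_interstitial + self.frac_intracellular
        if abs(s - 1.0) > 1e-3:
            raise ValueError(f"breast sub-fractions must sum to 1, got {s}")
        if not 0.0 < self.hematocrit < 1.0:
            raise ValueError("hematocrit must be in (0, 1)")

    @property
    def breast_flow_l_h(self) -> float:
        """Breast blood flow in L/h (density 1 kg/L assumed)."""
        # mL/min/100 g * (1000 g/L * V L / 100 g) * 60 min/h / 1000 mL/L
        return self.breast_flow * self.breast_volume * 0.6


_REGIMEN_RE = re.compile(
    r"^\s*(?P<dose>\d+(?:\.\d+)?)\s*mg\s+q(?P<tau>\d+(?:\.\d+)?)h"
    r"(?:\s*x(?P<n>\d+))?\s+(?P<route>po|iv|ivinf)(?::(?P<dur>\d+(?:\.\d+)?)h)?\s*$"
)

_ROUTE_ALIASES = {"po": Route.oral, "iv": Route.iv_bolus, "ivinf": Route.iv_infusion}


@dataclass(frozen=True)
class Regimen:
    """A dosing schedule: an explicit, time-sorted tuple of dose events.

    Periodic regimens remember ``(dose, interval, n_doses, route)`` so the
    steady-state driver can iterate single cycles.
    """

    events: Tuple[DoseEvent, ...]
    interval: Optional[float] = None  # h, set for periodic regimens

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "events", tuple(sorted(self.events, key=lambda e: e.time))
        )
        if self.interval is not None and self.interval <= 0:
            raise ValueError("interval must be > 0")

    @classmethod
    def single(cls, amount: float, route: Route = Route.iv_bolus, time: float = 0.0,
               duration: float = 0.0) -> "Regimen":
        return cls(events=(DoseEvent(time, amount, route, duration),))

    @classmethod
    def periodic(cls, dose: float, interval: float, n_doses: int,
                 route: Route = Route.oral, duration: float = 0.0) -> "Regimen":
        if n_doses < 1:
            raise ValueError("n_doses must be >= 1")
        events = tuple(
            DoseEvent(i * interval, dose, route, duration) for i in range(n_doses)
        )
        return cls(events=events, interval=float(interval))

    @classmethod
    def from_string(cls, text: str, n_doses: Optional[int] = None) -> "Regimen":
        """Parse ``"<dose>mg q<tau>h [x<n>] <po|iv|ivinf[:<dur>h]>"``.

        Examples: ``"1000mg q8h x15 po"``, ``"100mg q24h iv"``,
        ``"500mg q12h x10 ivinf:1h"``.
        """
        m = _REGIMEN_RE.match(text)
        if m is None:
            raise ValueError(
                f"cannot parse regimen {text!r}; expected e.g. '1000mg q8h x15 po'"
            )
        dose = float(m.group("dose"))
        tau = float(m.group("tau"))
        n = n_doses if n_doses is not None else (int(m.group("n")) if m.group("n") else 1)
        route = _ROUTE_ALIASES[m.group("route")]
        dur = float(m.group("dur")) if m.group("dur") else 0.0
        return cls.periodic(dose, tau, n, route, dur)

    @property
    def t_last_dose(self) -> float:
        return self.events[-1].time if self.events else 0.0

    @property
    def daily_dose(self) -> float:
        """Average administered dose per day, mg/day (periodic regimens)."""
        if self.interval is None:
            raise ValueError("daily_dose is defined for periodic regimens only")
        return self.events[0].amount * 24.0 / self.interval


@dataclass(frozen=True)
class LactationModel:
    """Assembled linear ODE system: maternal PK + milk exchange.

    State layout (amounts, mg): optional oral depot, central, peripherals,
    optional breast tissue, milk, cumulative eliminated (bookkeeping state).
    """

    drug: DrugPhysChem
    pk: MaternalPKParams
    transfer: MilkTransferParams
    physio: LactationPhysiology = field(default_factory=LactationPhysiology)
    include_breast_tissue: bool = False
    kp_breast: float = 1.0

    def __post_init__(self) -> None:
        if self.kp_breast <= 0:
            raise ValueError("kp_breast must be > 0")

    @property
    def has_depot(self) -> bool:
        return self.pk.ka is not None

    @property
    def labels(self) -> Tuple[str, ...]:
        names: List[str] = []
        if self.has_depot:
            names.append("depot")
        names.append("central")
        names.extend(f"peripheral{i + 1}" for i in range(len(self.pk.peripherals)))
        if self.include_breast_tissue:
            names.append("breast")
        names.append("milk")
        names.append("eliminated")
        return tuple(names)

    @property
    def n_compartments(self) -> int:
        """Physical compartments (milk included, eliminated excluded)."""
        return len(self.labels) - 1

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def matrix(self) -> np.ndarray:
        """System matrix A such that dx/dt = A x (+ infusion input)."""
        labels = self.labels
        n = len(labels)
        A = np.zeros((n, n))
        ic = labels.index("central")
        im = labels.index("milk")
        ie = labels.index("eliminated")
        vc = self.pk.vc
        vmilk = self.physio.v_milk
        # unbound-concentration-driven milk exchange, L/h
        cls_u = self.drug.fu_plasma * self.transfer.clsec / ML_PER_L
        clr_u = self.transfer.fu_milk_total * self.transfer.clre / ML_PER_L

        A[ic, ic] -= self.pk.cl / vc
        A[ie, ic] += self.pk.cl / vc
        A[im, ic] += cls_u / vc
        A[ic, ic] -= cls_u / vc
        A[ic, im] += clr_u / vmilk
        A[im, im] -= clr_u / vmilk
        if self.has_depot:
            idp = labels.index("depot")
            A[idp, idp] -= self.pk.ka
            A[ic, idp] += self.pk.ka
        for i, (v, q) in enumerate(self.pk.peripherals):
            ip = labels.index(f"peripheral{i + 1}")
            A[ip, ic] += q / vc
            A[ic, ic] -= q / vc
            A[ic, ip] += q / v
            A[ip, ip] -= q / v
        if self.include_breast_tissue:
            ib = labels.index("breast")
            qb = self.physio.breast_flow_l_h
            vb = self.physio.breast_volume
            A[ib, ic] += qb / vc
            A[ic, ic] -= qb / vc
            A[ic, ib] += qb / (vb * self.kp_breast)
            A[ib, ib] -= qb / (vb * self.kp_breast)
        return A


def build_model(
    drug: DrugPhysChem,
    pk: MaternalPKParams,
    transfer: MilkTransferParams,
    physio: Optional[LactationPhysiology] = None,
    *,
    include_breast_tissue: bool = False,
    kp_breast: float = 1.0,
) -> LactationModel:
    """Assemble the coupled maternal + milk ODE system."""
    return LactationModel(
        drug=drug,
        pk=pk,
        transfer=transfer,
        physio=physio if physio is not None else LactationPhysiology(),
        include_breast_tissue=include_breast_tissue,
        kp_breast=kp_breast,
    )


@dataclass
class SimResult:
    """Time-stamped trajectories of one simulation.

    ``states`` has one row per output time and one column per state in
    ``labels`` (amounts, mg).  ``administered`` is the cumulative amount
    delivered to the system up to each time (oral doses scaled by F).
    """

    times: np.ndarray
    states: np.ndarray
    labels: Tuple[str, ...]
    model: LactationModel
    administered: np.ndarray
    ss_flag: bool = False
    n_cycles: Optional[int] = None

    def _col(self, label: str) -> np.ndarray:
        return self.states[:, self.labels.index(label)]

    @property
    def c_plasma(self) -> np.ndarray:
        return self._col("central") / self.model.pk.vc

    @property
    def c_milk(self) -> np.ndarray:
        return self._col("milk") / self.model.physio.v_milk

    @property
    def amounts(self) -> Dict[str, np.ndarray]:
        return {lab: self._col(lab) for lab in self.labels if lab != "eliminated"}

    @property
    def cumulative_eliminated(self) -> np.ndarray:
        return self._col("eliminated")

    def mass_balance_error(self) -> float:
        """Max relative violation of amount conservation over the run."""
        total = self.states.sum(axis=1)
        expected = total[0] + self.administered - self.administered[0]
        scale = max(float(np.max(expected)), 1e-12)
        return float(np.max(np.abs(total - expected)) / scale)

    def to_frame(self):
        import pandas as pd

        data = {"time_h": self.times,
                "c_plasma_mg_per_L": self.c_plasma,
                "c_milk_mg_per_L": self.c_milk}
        for lab in self.labels:
            data[f"amount_{lab}_mg"] = self._col(lab)
        return pd.DataFrame(data)


def _dose_schedule(model: LactationModel, regimen: Regimen):
    """Expand a regimen into bolus additions and infusion windows.

    Returns ``(boluses, infusions)`` where boluses is a list of
    ``(time, state_index, amount)`` and infusions a list of
    ``(t_start, t_stop, rate mg/h)`` into the central compartment.
    """
    boluses: List[Tuple[float, int, float]] = []
    infusions: List[Tuple[float, float, float]] = []
    ic = model.index("central")
    for ev in regimen.events:
        if ev.amount == 0:
            continue
        if ev.route is Route.oral:
            if not model.has_depot:
                raise SimulationError(
                    "oral dose event but the model has no absorption constant (ka)"
                )
            boluses.append((ev.time + model.pk.tlag, model.index("depot"),
                            ev.amount * model.pk.f))
        elif ev.route is Route.iv_bolus:
            boluses.append((ev.time, ic, ev.amount))
        else:
            infusions.append((ev.time, ev.time + ev.duration, ev.amount / ev.duration))
    return boluses, infusions


def _administered(times: np.ndarray, model: LactationModel, regimen: Regimen) -> np.ndarray:
    adm = np.zeros_like(times, dtype=float)
    for ev in regimen.events:
        if ev.amount == 0:
            continue
        if ev.route is Route.oral:
            t0 = ev.time + model.pk.tlag
            adm += ev.amount * model.pk.f * (times >= t0 - 1e-12)
        elif ev.route is Route.iv_bolus:
            adm += ev.amount * (times >= ev.time - 1e-12)
        else:
            frac = np.clip((times - ev.time) / ev.duration, 0.0, 1.0)
            adm += ev.amount * frac
    return adm


class _ExpmStepper:
    """Affine propagator x(t+h) = E x(t) + g for dx/dt = A x + u.

    Uses the augmented-matrix trick so singular A (the bookkeeping row) is
    handled without inversion; propagators are cached per (h, u)."""

    def __init__(self, A: np.ndarray):
        self.A = A
        self.n = A.shape[0]
        self._cache: Dict[Tuple[float, bytes], Tuple[np.ndarray, np.ndarray]] = {}

    def step(self, y: np.ndarray, u: np.ndarray, h: float) -> np.ndarray:
        key = (round(h, 12), u.tobytes())
        if key not in self._cache:
            M = np.zeros((self.n + 1, self.n + 1))
            M[: self.n, : self.n] = self.A * h
            M[: self.n, self.n] = u * h
            P = expm(M)
            self._cache[key] = (P[: self.n, : self.n], P[: self.n, self.n])
        E, g = self._cache[key]
        return E @ y + g


def simulate(
    model: LactationModel,
    regimen: Regimen,
    t_end: float,
    dt_out: Optional[float] = None,
    *,
    n_out: Optional[int] = None,
    method: str = "lsoda",
    rtol: float = 1e-8,
    atol: float = 1e-12,
    y0: Optional[np.ndarray] = None,
) -> SimResult:
    """Integrate the model under ``regimen`` on a dense output grid.

    Integration is restarted exactly at every dose discontinuity.  At a dose
    time the reported state is post-dose.  ``method`` is ``"lsoda"``,
    ``"bdf"`` (both via :func:`scipy.integrate.solve_ivp`) or ``"expm"``
    (matrix-exponential propagation, exact for this linear system).
    """
    if t_end <= 0:
        raise ValueError("t_end must be > 0")
    if n_out is not None:
        times = np.linspace(0.0, t_end, n_out + 1)
    else:
        if dt_out is None:
            dt_out = t_end / 500.0
        times = np.arange(0.0, t_end + dt_out * 0.5, dt_out)
        times[-1] = min(times[-1], t_end)

    labels = model.labels
    n = len(labels)
    A = model.matrix()
    boluses, infusions = _dose_schedule(model, regimen)
    ic = model.index("central")

    breakpoints = {0.0, float(t_end)}
    for t, _, _ in boluses:
        if t < t_end:
            breakpoints.add(float(t))
    for t0, t1, _ in infusions:
        if t0 < t_end:
            breakpoints.add(float(t0))
        if t1 < t_end:
            breakpoints.add(float(t1))
    bp = sorted(breakpoints)

    y = np.zeros(n) if y0 is None else np.array(y0, dtype=float)
    if y.shape != (n,):
        raise ValueError(f"y0 must have shape ({n},)")

    out = np.empty((len(times), n))
    filled = np.zeros(len(times), dtype=bool)
    stepper = _ExpmStepper(A) if method == "expm" else None

    def record(t: float, yv: np.ndarray) -> None:
        mask = np.isclose(times, t, rtol=0.0, atol=1e-9) & ~filled
        if mask.any():
            out[mask] = yv
            filled[mask] = True

    for k in range(len(bp)):
        a = bp[k]
        for t, idx, amt in boluses:
            if math.isclose(t, a, abs_tol=1e-9):
                y[idx] += amt
        record(a, y)
        if k == len(bp) - 1:
            break
        b = bp[k + 1]
        u = np.zeros(n)
        for t0, t1, rate in infusions:
            if t0 - 1e-9 <= a < t1 - 1e-9:
                u[ic] += rate
        inner = times[(times > a + 1e-9) & (times < b - 1e-9)]
        targets = np.concatenate([inner, [b]])
        if method == "expm":
            t_prev = a
            for t in targets:
                y = stepper.step(y, u, t - t_prev)
                t_prev = t
                if t < b - 1e-12:
                    record(t, y)
        else:
            ivp_method = {"lsoda": "LSODA", "bdf": "BDF"}.get(method)
            if ivp_method is None:
                raise ValueError(f"unknown method {method!r}")
            sol = solve_ivp(
                lambda t, yv: A @ yv + u,
                (a, b),
                y,
                method=ivp_method,
                t_eval=targets,
                jac=lambda t, yv: A,
                rtol=rtol,
                atol=atol,
            )
            if not sol.success:
                raise SimulationError(
                    f"solver failed on [{a:g}, {b:g}] h: {sol.message}"
                )
            for t, yv in zip(sol.t[:-1], sol.y.T[:-1]):
                record(t, yv)
            y = sol.y[:, -1].copy()

    if not filled.all():
        # grid points coinciding with breakpoints within tolerance
        missing = np.where(~filled)[0]
        raise SimulationError(f"internal error: unfilled output times {times[missing]}")

    neg_floor = -max(1e-9 * max(float(np.max(out)), 1.0), 100 * atol)
    if float(np.min(out)) < neg_floor:
        raise SimulationError(
            f"negative state detected (min {np.min(out):g}); integration aborted"
        )
    out[out < 0] = 0.0

    return SimResult(
        times=times,
        states=out,
        labels=labels,
        model=model,
        administered=_administered(times, model, regimen),
    )


def _converged(history: List[float], tol: float) -> bool:
    """AUC sequence convergence with geometric-tail extrapolation.

    The plain 'relative change < tol' test can declare convergence while a
    slowly equilibrating compartment is still accumulating; the remaining
    tail is therefore estimated from the ratio of successive increments.
    """
    if len(history) < 3:
        return False
    cur = history[-1]
    if cur == 0.0:
        return True
    d1 = history[-2] - history[-3]
    d2 = history[-1] - history[-2]
    rel = abs(d2) / cur
    if rel >= tol:
        return False
    if d1 == 0.0 or abs(d2) >= abs(d1):
        return True
    r = abs(d2 / d1)
    remaining = abs(d2) * r / (1.0 - r)
    return remaining / cur < tol


def simulate_to_steady_state(
    model: LactationModel,
    regimen_cycle: Union[Tuple, Regimen, DoseEvent],
    *,
    n_out: int = 200,
    ss_rtol: float = 1e-3,
    max_cycles: int = 200,
    method: str = "lsoda",
    rtol: float = 1e-8,
    atol: float = 1e-12,
) -> SimResult:
    """Repeat one dosing cycle until the interval AUCs stop changing.

    ``regimen_cycle`` is ``(dose, interval, route[, duration])``, a periodic
    :class:`Regimen` (its first event and interval are used) or a
    :class:`DoseEvent` plus interval via a Regimen.  Convergence requires
    both the plasma and the milk interval AUC to be stationary within
    ``ss_rtol`` (including the extrapolated geometric tail).  On
    non-convergence a warning is issued, ``ss_flag`` is False and the last
    interval is returned.

    The returned :class:`SimResult` covers the final interval with times
    relative to its start.
    """
    if isinstance(regimen_cycle, Regimen):
        if regimen_cycle.interval is None:
            raise ValueError("steady-state driver needs a periodic regimen")
        ev = regimen_cycle.events[0]
        dose, tau, route, duration = ev.amount, regimen_cycle.interval, ev.route, ev.duration
    else:
        parts = tuple(regimen_cycle)
        if len(parts) == 3:
            dose, tau, route = parts
            duration = 0.0
        else:
            dose, tau, route, duration = parts
    route = Route(route)
    cycle = Regimen.single(dose, route, time=0.0, duration=duration)

    y = None
    auc_p_hist: List[float] = []
    auc_m_hist: List[float] = []
    sim: Optional[SimResult] = None
    converged = False
    cycles_run = 0
    for i in range(max_cycles):
        sim = simulate(
            model, cycle, tau, n_out=n_out, method=method, rtol=rtol, atol=atol, y0=y
        )
        y = sim.states[-1].copy()
        cycles_run = i + 1
        auc_p_hist.append(float(np.trapezoid(sim.c_plasma, sim.times)))
        auc_m_hist.append(float(np.trapezoid(sim.c_milk, sim.times)))
        if _converged(auc_p_hist, ss_rtol) and _converged(auc_m_hist, ss_rtol):
            converged = True
            break
    assert sim is not None
    if not converged:
        warnings.warn(
            f"steady state not reached within {max_cycles} cycles "
            f"(last plasma AUC change "
            f"{abs(auc_p_hist[-1] - auc_p_hist[-2]) / max(auc_p_hist[-1], 1e-300):.2e})",
            stacklevel=2,
        )
    sim.ss_flag = converged
    sim.n_cycles = cycles_run
    return sim


def nca_terminal_slope(
    times: Sequence[float], conc: Sequence[float], n_points: int = 3
) -> float:
    """Terminal elimination slope lambda_z (1/h) by log-linear regression.

    Uses the last ``n_points`` samples, which must all be positive and
    overall decreasing; raises :class:`ValueError` otherwise.
    """
    if n_points < 3:
        raise ValueError("need at least 3 points for the terminal slope")
    t = np.asarray(times, dtype=float)[-n_points:]
    c = np.asarray(conc, dtype=float)[-n_points:]
    if len(t) < n_points:
        raise ValueError("fewer samples than n_points")
    if np.any(c <= 0):
        raise ValueError("terminal concentrations must all be positive")
    slope, _ = np.polyfit(t, np.log(c), 1)
    lam = -float(slope)
    if lam <= 0:
        raise ValueError(
            f"terminal phase is not decreasing (lambda_z = {lam:g} 1/h)"
        )
    return lam


def nca_auc_to_inf(
    times: Sequence[float], conc: Sequence[float], n_points: int = 3
) -> float:
    """AUC from the first sample to infinity: trapezoid + C_last/lambda_z."""
    t = np.asarray(times, dtype=float)
    c = np.asarray(conc, dtype=float)
    lam = nca_terminal_slope(t, c, n_points)
    return float(np.trapezoid(c, t) + c[-1] / lam)
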