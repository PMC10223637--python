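"""Semi-mechanistic plasma <-> milk transfer quantities.

Bidirectional clearances are predicted from molecular descriptors by the
log-linear regressions

    log10 CLsec = -3.912 - 0.015*PSA + 3.367*log10(MW) - 0.164*LogD(7.4)
    log10 CLre  =  2.793 + 0.179*LogP - 0.132*HBD            [mL/h]

and milk binding from the plasma unbound fraction and the milk-lipid
partition coefficient

    log10 Pmilk    = -0.88 + 1.29*LogD(7.2)
    fu_skim        = fu_p^0.448 / ((6.94e-4)^0.448 + fu_p^0.448)
    fu_milk_total  = 1 / (0.955/fu_skim + 0.045*Pmilk)

The steady-state milk-to-plasma AUC ratio of the coupled transfer system has
the closed form fu_plasma*CLsec / (fu_milk_total*CLre): at periodic steady
state the drug amount secreted into milk over one dosing interval equals the
amount taken back up, so the concentration AUCs are locked to the clearance
ratio.  ``fu_milk_total`` is deliberately not capped at 1; values slightly
above 1 occur for weakly bound drugs and are required for consistency.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

from .physchem import DrugPhysChem, logd

__all__ = [
    "MilkTransferParams",
    "compute_clsec",
    "compute_clre",
    "compute_pmilk",
    "compute_fu_skim",
    "compute_fu_milk_total",
    "mp_ratio_steady_state",
    "derive_milk_transfer",
    "transfer_table",
]

# milk protein binding constant, (6.94e-4)^0.448
_KM_POW = (6.94e-4) ** 0.448

PH_SECRETION = 7.4  # pH convention for the CLsec regression
PH_MILK = 7.2  # pH convention for the milk-lipid partition


@dataclass(frozen=True)
class MilkTransferParams:
    """Derived milk-transfer quantities for one drug.

    Clearances are stored in mL/h (the regression's native unit); the PK
    engine converts to L/h at its boundary.
    """

    clsec: float  # mL/h
    clre: float  # mL/h
    pmilk: float  # dimensionless
    fu_skim: float
    fu_milk_total: float  # may slightly exceed 1 by construction
    mp_ss: float

    def __post_init__(self) -> None:
        # zero clearances are admitted so a decoupled (no-transfer) model is
        # constructible; derived records always carry positive values
        if self.clsec < 0 or self.clre < 0:
            raise ValueError("clearances must be >= 0")
        if self.pmilk < 0:
            raise ValueError("pmilk must be >= 0")
        if not 0.0 < self.fu_skim <= 1.0:
            raise ValueError(f"fu_skim must be in (0, 1], got {self.fu_skim}")
        if self.fu_milk_total <= 0:
            raise ValueError("fu_milk_total must be > 0")
        if self.mp_ss < 0:
            raise ValueError("mp_ss must be >= 0")


def compute_clsec(psa: float, mw: float, logd74: float) -> float:
    """Secretion clearance plasma -> milk, mL/h."""
    if psa < 0:
        raise ValueError(f"psa must be >= 0, got {psa}")
    if mw <= 0:
        raise ValueError(f"mw must be > 0, got {mw}")
    return 10.0 ** (-3.912 - 0.015 * psa + 3.367 * math.log10(mw) - 0.164 * logd74)


def compute_clre(logp: float, hbd: int) -> float:
    """Reuptake clearance milk -> plasma, mL/h."""
    if hbd < 0:
        raise ValueError(f"hbd must be >= 0, got {hbd}")
    return 10.0 ** (2.793 + 0.179 * logp - 0.132 * hbd)


def compute_pmilk(logd72: float) -> float:
    """Milk lipid : milk ultrafiltrate partition coefficient."""
    return 10.0 ** (-0.88 + 1.29 * logd72)


def compute_fu_skim(fu_plasma: float) -> float:
    """Unbound fraction in skimmed milk from the plasma unbound fraction."""
    if not 0.0 < fu_plasma <= 1.0:
        raise ValueError(f"fu_plasma must be in (0, 1], got {fu_plasma}")
    x = fu_plasma**0.448
    return x / (_KM_POW + x)


def compute_fu_milk_total(fu_skim: float, pmilk: float) -> float:
    """Total unbound fraction in whole milk (protein + lipid binding).

    Not capped at 1: for weakly bound drugs with negligible lipid partition
    the value is ~1/0.955 ~ 1.047, and the closed-form M/P relies on that.
    """
    if fu_skim <= 0:
        raise ValueError("fu_skim must be > 0")
    if pmilk < 0:
        raise ValueError("pmilk must be >= 0")
    return 1.0 / (0.955 / fu_skim + 0.045 * pmilk)


def mp_ratio_steady_state(
    fu_plasma: float, clsec: float, fu_milk_total: float, clre: float
) -> float:
    """Closed-form AUC-based milk-to-plasma ratio at periodic steady state.

    Exactly equal to AUC_milk/AUC_plasma of the coupled two-way transfer
    system over a dosing interval at periodic steady state (inflow integral
    equals outflow integral over one period).
    """
    if min(fu_plasma, clsec, fu_milk_total, clre) <= 0:
        raise ValueError("all inputs must be > 0")
    return (fu_plasma * clsec) / (fu_milk_total * clre)


def derive_milk_transfer(drug: DrugPhysChem) -> MilkTransferParams:
    """Chain the regressions into a full :class:`MilkTransferParams` record."""
    logd74 = logd(drug, PH_SECRETION)
    logd72 = logd(drug, PH_MILK)
    clsec = compute_clsec(drug.psa, drug.mw, logd74)
    clre = compute_clre(drug.logp, drug.hbd)
    pmilk = compute_pmilk(logd72)
    fu_skim = compute_fu_skim(drug.fu_plasma)
    fu_milk_total = compute_fu_milk_total(fu_skim, pmilk)
    mp_ss = mp_ratio_steady_state(drug.fu_plasma, clsec, fu_milk_total, clre)
    return MilkTransferParams(
        clsec=clsec,
        clre=clre,
        pmilk=pmilk,
        fu_skim=fu_skim,
        fu_milk_total=fu_milk_total,
        mp_ss=mp_ss,
    )


def transfer_table(drugs: Iterable[DrugPhysChem]):
    """Batch derivation: one row per drug, mirroring the clearance table.

    Returns a :class:`pandas.DataFrame` with clearances in mL/h, the milk
    binding quantities and the closed-form steady-state M/P.
    """
    import pandas as pd

    rows = []
    for d in drugs:
        p = derive_milk_transfer(d)
        rows.append(
            {
                "name": d.name,
                "clsec_ml_h": p.clsec,
                "clre_ml_h": p.clre,
                "pmilk": p.pmilk,
                "fu_skim": p.fu_skim,
                "fu_milk_total": p.fu_milk_total,
                "mp_ss": p.mp_ss,
            }
        )
    return pd.DataFrame(rows)
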