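"""Drug physicochemical records and pH-dependent distribution coefficients.

A :class:`DrugPhysChem` record carries the handful of molecular descriptors
(MW, LogP, ionization constants, H-bond donor count, polar surface area,
unbound plasma fraction) that drive the milk-transfer regressions.  The only
computation here is the Henderson--Hasselbalch neutral fraction and the
derived octanol:buffer distribution coefficient LogD at a given pH.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Optional, Sequence, Tuple

__all__ = [
    "GroupKind",
    "IonizationGroup",
    "DrugPhysChem",
    "fraction_neutral",
    "logd",
]


class GroupKind(str, Enum):
    """Acid/base character of an ionizable group."""

    acid = "acid"
    base = "base"


@dataclass(frozen=True)
class IonizationGroup:
    """A single ionizable group with its acid/base type and pKa.

    pKa values outside 0--14 are accepted with a warning (they produce
    degenerate but well-defined Henderson--Hasselbalch fractions).
    """

    kind: GroupKind
    pka: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "kind", GroupKind(self.kind))
        object.__setattr__(self, "pka", float(self.pka))
        if not 0.0 < self.pka < 14.0:
            warnings.warn(
                f"pKa {self.pka:g} lies outside the 0-14 range; the neutral "
                "fraction will be degenerate at physiological pH",
                stacklevel=2,
            )

    def fraction_neutral(self, ph: float) -> float:
        """Henderson--Hasselbalch neutral fraction of this group at ``ph``."""
        if self.kind is GroupKind.acid:
            return 1.0 / (1.0 + 10.0 ** (ph - self.pka))
        return 1.0 / (1.0 + 10.0 ** (self.pka - ph))


@dataclass(frozen=True)
class DrugPhysChem:
    """Physicochemical identity of a medicine.

    Parameters
    ----------
    name : str
        Identifier, e.g. ``"caffeine"``.
    mw : float
        Molecular weight, g/mol (> 0).
    logp : float
        log10 octanol/water partition coefficient of the neutral species.
    groups : sequence of IonizationGroup, optional
        Ionizable groups; empty for a neutral drug.
    hbd, hba : int
        Hydrogen-bond donor/acceptor counts (>= 0).
    psa : float
        Polar surface area, A^2 (>= 0).
    fu_plasma : float
        Fraction unbound in plasma, in (0, 1].
    logd74_override, logd72_override : float, optional
        Measured LogD values at pH 7.4 / 7.2.  When present they take
        precedence over the Henderson--Hasselbalch calculation.
    """

    name: str
    mw: float
    logp: float
    groups: Tuple[IonizationGroup, ...] = ()
    hbd: int = 0
    hba: int = 0
    psa: float = 0.0
    fu_plasma: float = 1.0
    logd74_override: Optional[float] = None
    logd72_override: Optional[float] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "groups", tuple(self.groups))
        if self.mw <= 0:
            raise ValueError(f"{self.name}: mw must be > 0, got {self.mw}")
        if self.psa < 0:
            raise ValueError(f"{self.name}: psa must be >= 0, got {self.psa}")
        for attr in ("hbd", "hba"):
            v = getattr(self, attr)
            if not (isinstance(v, (int,)) and v >= 0):
                raise ValueError(f"{self.name}: {attr} must be a nonnegative integer, got {v!r}")
        if not 0.0 < self.fu_plasma <= 1.0:
            raise ValueError(
                f"{self.name}: fu_plasma must be in (0, 1], got {self.fu_plasma}"
            )

    @property
    def is_neutral(self) -> bool:
        return not self.groups

    def with_overrides(
        self,
        logd74: Optional[float] = None,
        logd72: Optional[float] = None,
        logp: Optional[float] = None,
    ) -> "DrugPhysChem":
        """Return a copy with measured LogD overrides and/or an effective LogP."""
        kw = {}
        if logd74 is not None:
            kw["logd74_override"] = logd74
        if logd72 is not None:
            kw["logd72_override"] = logd72
        if logp is not None:
            kw["logp"] = logp
        return replace(self, **kw)


def fraction_neutral(drug: DrugPhysChem, ph: float) -> float:
    """Neutral fraction of ``drug`` at ``ph``.

    For a single acid this is ``1/(1 + 10**(ph - pKa))``, for a single base
    ``1/(1 + 10**(pKa - ph))``; multiple groups multiply (each group must be
    neutral simultaneously).  A drug without ionizable groups returns 1.
    """
    if not 0.0 < ph < 14.0:
        raise ValueError(f"ph must be in (0, 14), got {ph}")
    f = 1.0
    for g in drug.groups:
        f *= g.fraction_neutral(ph)
    return f


def logd(drug: DrugPhysChem, ph: float) -> float:
    """log10 octanol:buffer distribution coefficient at ``ph``.

    If the record carries a measured override for the requested pH (7.4 or
    7.2) it is returned verbatim; otherwise LogD is derived from LogP and the
    Henderson--Hasselbalch neutral fraction.
    """
    if drug.logd74_override is not None and math.isclose(ph, 7.4, abs_tol=1e-6):
        return drug.logd74_override
    if drug.logd72_override is not None and math.isclose(ph, 7.2, abs_tol=1e-6):
        return drug.logd72_override
    return drug.logp + math.log10(fraction_neutral(drug, ph))
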