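"""Reproducible synthetic drug generation for property-based testing."""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Tuple

import numpy as np

from ..physchem import DrugPhysChem, GroupKind, IonizationGroup

__all__ = ["SyntheticDrugSpec", "generate_synthetic_drugs"]


def _check_range(name: str, rng: Tuple[float, float]) -> None:
    if not rng[0] < rng[1]:
        raise ValueError(f"{name} range must be non-degenerate, got {rng}")


@dataclass(frozen=True)
class SyntheticDrugSpec:
    """Sampling ranges spanning a physicochemically diverse drug space."""

    mw: Tuple[float, float] = (100.0, 600.0)
    logp: Tuple[float, float] = (-3.0, 6.0)
    hbd: Tuple[int, int] = (0, 6)
    psa: Tuple[float, float] = (10.0, 200.0)
    fu_plasma: Tuple[float, float] = (0.01, 1.0)
    pka: Tuple[float, float] = (2.0, 12.0)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("mw", "logp", "psa", "fu_plasma", "pka"):
            _check_range(name, getattr(self, name))
        if not (0 <= self.hbd[0] < self.hbd[1]):
            raise ValueError(f"hbd range must be non-degenerate, got {self.hbd}")


def generate_synthetic_drugs(spec: SyntheticDrugSpec, n: int) -> List[DrugPhysChem]:
    """Draw ``n`` random but valid drug records; deterministic per seed.

    Ionization is drawn from {neutral, monoprotic acid, monoprotic base,
    amphoteric} so the Henderson--Hasselbalch branches are all exercised.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(spec.seed)
    drugs: List[DrugPhysChem] = []
    for i in range(n):
        kind = rng.choice(["neutral", "acid", "base", "amphoteric"],
                          p=[0.3, 0.3, 0.3, 0.1])
        groups = []
        if kind in ("acid", "amphoteric"):
            groups.append(IonizationGroup(GroupKind.acid, float(rng.uniform(*spec.pka))))
        if kind in ("base", "amphoteric"):
            groups.append(IonizationGroup(GroupKind.base, float(rng.uniform(*spec.pka))))
        hbd = int(rng.integers(spec.hbd[0], spec.hbd[1] + 1))
        drugs.append(
            DrugPhysChem(
                name=f"synthetic-{i:04d}",
                mw=float(rng.uniform(*spec.mw)),
                logp=float(rng.uniform(*spec.logp)),
                groups=tuple(groups),
                hbd=hbd,
                hba=hbd + int(rng.integers(0, 6)),
                psa=float(rng.uniform(*spec.psa)),
                fu_plasma=float(rng.uniform(*spec.fu_plasma)),
            )
        )
    return drugs
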