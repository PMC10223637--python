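"""Drug configuration documents and packaged fixtures.

A drug config is a YAML document with the physicochemical record, optional
maternal PK parameters, a default regimen string, an optional therapeutic
infant dose, per-section provenance tags and, where relevant, published
reference clearances plus the effective inputs back-calculated from them.

Provenance is one of ``published`` (taken from the printed source tables),
``backcalculated`` (inferred from published outputs) or ``user``
(placeholder supplied with this package, not from the source).
"""

from __future__ import annotations

import io
from dataclasses import asdict, dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Union

import yaml

from ..physchem import DrugPhysChem, GroupKind, IonizationGroup
from ..pk_engine import MaternalPKParams, Regimen

__all__ = [
    "ConfigError",
    "DrugConfig",
    "load_drug_config",
    "dump_drug_config",
    "validate_config",
    "apply_effective",
    "list_fixtures",
    "load_fixture",
    "PROVENANCE_VALUES",
]

PROVENANCE_VALUES = ("published", "backcalculated", "user")

_TOP_KEYS = {
    "name",
    "physchem",
    "maternal_pk",
    "regimen",
    "therapeutic_infant_dose",
    "reference_clearances",
    "effective",
    "provenance",
    "notes",
}
_PHYSCHEM_KEYS = {
    "mw", "logp", "pka", "hbd", "hba", "psa", "fu_plasma",
    "logd74_override", "logd72_override",
}
_PK_KEYS = {"cl", "vc", "peripherals", "ka", "f", "tlag"}
_EFFECTIVE_KEYS = {"logp", "logd74", "logd72"}
_REFCL_KEYS = {"clsec", "clre"}


class ConfigError(ValueError):
    """Schema violation in a drug configuration document."""


@dataclass(frozen=True)
class DrugConfig:
    """A fully parsed drug configuration."""

    name: str
    physchem: DrugPhysChem
    maternal_pk: Optional[MaternalPKParams] = None
    regimen: Optional[str] = None
    therapeutic_infant_dose: Optional[float] = None  # mg/kg/day
    reference_clearances: Optional[Dict[str, float]] = None  # mL/h, published
    effective: Optional[Dict[str, float]] = None  # back-calculated inputs
    provenance: Dict[str, str] = field(default_factory=dict)
    notes: str = ""

    def default_regimen(self) -> Regimen:
        if self.regimen is None:
            raise ConfigError(f"{self.name}: no default regimen in config")
        return Regimen.from_string(self.regimen)


def _require_keys(mapping: Mapping, allowed: set, where: str) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise ConfigError(f"{where}: unknown key(s) {sorted(unknown)}")


def _parse_physchem(name: str, doc: Mapping) -> DrugPhysChem:
    _require_keys(doc, _PHYSCHEM_KEYS, f"{name}.physchem")
    for key in ("mw", "logp", "psa", "fu_plasma"):
        if key not in doc:
            raise ConfigError(f"{name}.physchem: missing required key {key!r}")
    groups = []
    for i, g in enumerate(doc.get("pka") or []):
        _require_keys(g, {"kind", "value"}, f"{name}.physchem.pka[{i}]")
        try:
            groups.append(IonizationGroup(GroupKind(g["kind"]), float(g["value"])))
        except (KeyError, ValueError) as exc:
            raise ConfigError(f"{name}.physchem.pka[{i}]: {exc}") from exc
    try:
        return DrugPhysChem(
            name=name,
            mw=float(doc["mw"]),
            logp=float(doc["logp"]),
            groups=tuple(groups),
            hbd=int(doc.get("hbd", 0)),
            hba=int(doc.get("hba", 0)),
            psa=float(doc["psa"]),
            fu_plasma=float(doc["fu_plasma"]),
            logd74_override=(
                float(doc["logd74_override"]) if doc.get("logd74_override") is not None else None
            ),
            logd72_override=(
                float(doc["logd72_override"]) if doc.get("logd72_override") is not None else None
            ),
        )
    except ValueError as exc:
        raise ConfigError(f"{name}.physchem: {exc}") from exc


def _parse_pk(name: str, doc: Mapping) -> MaternalPKParams:
    _require_keys(doc, _PK_KEYS, f"{name}.maternal_pk")
    for key in ("cl", "vc"):
        if key not in doc:
            raise ConfigError(f"{name}.maternal_pk: missing required key {key!r}")
    try:
        return MaternalPKParams(
            cl=float(doc["cl"]),
            vc=float(doc["vc"]),
            peripherals=tuple(
                (float(p["v"]), float(p["q"])) for p in doc.get("peripherals") or []
            ),
            ka=float(doc["ka"]) if doc.get("ka") is not None else None,
            f=float(doc.get("f", 1.0)),
            tlag=float(doc.get("tlag", 0.0)),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise ConfigError(f"{name}.maternal_pk: {exc}") from exc


def _parse_config(doc: Mapping, source: str = "<config>") -> DrugConfig:
    if not isinstance(doc, Mapping):
        raise ConfigError(f"{source}: document must be a mapping")
    _require_keys(doc, _TOP_KEYS, source)
    if "name" not in doc:
        raise ConfigError(f"{source}: missing required key 'name'")
    if "physchem" not in doc:
        raise ConfigError(f"{source}: missing required key 'physchem'")
    name = str(doc["name"])
    physchem = _parse_physchem(name, doc["physchem"])
    pk = _parse_pk(name, doc["maternal_pk"]) if doc.get("maternal_pk") else None
    provenance = dict(doc.get("provenance") or {})
    for section, tag in provenance.items():
        if tag not in PROVENANCE_VALUES:
            raise ConfigError(
                f"{name}.provenance.{section}: {tag!r} not in {PROVENANCE_VALUES}"
            )
    effective = doc.get("effective")
    if effective is not None:
        _require_keys(effective, _EFFECTIVE_KEYS, f"{name}.effective")
        effective = {k: float(v) for k, v in effective.items()}
    refcl = doc.get("reference_clearances")
    if refcl is not None:
        _require_keys(refcl, _REFCL_KEYS, f"{name}.reference_clearances")
        refcl = {k: float(v) for k, v in refcl.items()}
    regimen = doc.get("regimen")
    if regimen is not None:
        Regimen.from_string(str(regimen))  # fail fast on bad grammar
    tid = doc.get("therapeutic_infant_dose")
    return DrugConfig(
        name=name,
        physchem=physchem,
        maternal_pk=pk,
        regimen=str(regimen) if regimen is not None else None,
        therapeutic_infant_dose=float(tid) if tid is not None else None,
        reference_clearances=refcl,
        effective=effective,
        provenance=provenance,
        notes=str(doc.get("notes", "")),
    )


def load_drug_config(path: Union[str, Path]) -> DrugConfig:
    """Read and validate a drug configuration from a YAML file."""
    path = Path(path)
    with path.open() as fh:
        doc = yaml.safe_load(fh)
    return _parse_config(doc, source=str(path))


def _config_to_doc(config: DrugConfig) -> dict:
    doc: dict = {
        "name": config.name,
        "physchem": {
            "mw": config.physchem.mw,
            "logp": config.physchem.logp,
            "pka": [
                {"kind": g.kind.value, "value": g.pka} for g in config.physchem.groups
            ],
            "hbd": config.physchem.hbd,
            "hba": config.physchem.hba,
            "psa": config.physchem.psa,
            "fu_plasma": config.physchem.fu_plasma,
        },
    }
    if config.physchem.logd74_override is not None:
        doc["physchem"]["logd74_override"] = config.physchem.logd74_override
    if config.physchem.logd72_override is not None:
        doc["physchem"]["logd72_override"] = config.physchem.logd72_override
    if config.maternal_pk is not None:
        pk = config.maternal_pk
        doc["maternal_pk"] = {
            "cl": pk.cl,
            "vc": pk.vc,
            "peripherals": [{"v": v, "q": q} for v, q in pk.peripherals],
            "ka": pk.ka,
            "f": pk.f,
            "tlag": pk.tlag,
        }
    if config.regimen is not None:
        doc["regimen"] = config.regimen
    if config.therapeutic_infant_dose is not None:
        doc["therapeutic_infant_dose"] = config.therapeutic_infant_dose
    if config.reference_clearances is not None:
        doc["reference_clearances"] = dict(config.reference_clearances)
    if config.effective is not None:
        doc["effective"] = dict(config.effective)
    if config.provenance:
        doc["provenance"] = dict(config.provenance)
    if config.notes:
        doc["notes"] = config.notes
    return doc


def dump_drug_config(config: DrugConfig, path: Union[str, Path]) -> None:
    """Write a config as YAML; ``load_drug_config`` round-trips it."""
    with Path(path).open("w") as fh:
        yaml.safe_dump(_config_to_doc(config), fh, sort_keys=False)


def validate_config(config: DrugConfig) -> List[str]:
    """Return a list of problems (empty means valid).

    Type invariants are enforced at parse time; this reports softer issues.
    """
    report: List[str] = []
    for g in config.physchem.groups:
        if not 0.0 < g.pka < 14.0:
            report.append(f"pKa {g.pka:g} outside 0-14")
    if config.maternal_pk is None:
        report.append("no maternal PK parameters: simulation unavailable")
    elif config.regimen is not None:
        reg = Regimen.from_string(config.regimen)
        if reg.events[0].route.value == "oral" and config.maternal_pk.ka is None:
            report.append("oral default regimen but maternal_pk.ka missing")
    for section in ("physchem", "maternal_pk"):
        if section not in config.provenance:
            report.append(f"no provenance tag for {section}")
    return report


def apply_effective(config: DrugConfig) -> DrugConfig:
    """Apply the back-calculated effective inputs to the physchem record.

    Effective LogP replaces the tabulated LogP (affecting the reuptake
    clearance and derived LogD); effective LogD values are installed as
    overrides (affecting the secretion clearance / milk partition).
    """
    if not config.effective:
        return config
    pc = config.physchem.with_overrides(
        logd74=config.effective.get("logd74"),
        logd72=config.effective.get("logd72"),
        logp=config.effective.get("logp"),
    )
    return replace(config, physchem=pc)


def _fixture_root():
    return resources.files("lactopk.io_cli") / "fixtures"


def list_fixtures() -> List[str]:
    """Names of the packaged drug fixtures."""
    return sorted(
        p.name[: -len(".yaml")] for p in _fixture_root().iterdir() if p.name.endswith(".yaml")
    )


def load_fixture(name: str) -> DrugConfig:
    """Load a packaged fixture by name (see :func:`list_fixtures`)."""
    res = _fixture_root() / f"{name}.yaml"
    try:
        text = res.read_text()
    except FileNotFoundError as exc:
        raise ConfigError(
            f"no packaged fixture {name!r}; available: {', '.join(list_fixtures())}"
        ) from exc
    return _parse_config(yaml.safe_load(io.StringIO(text)), source=f"fixture:{name}")
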