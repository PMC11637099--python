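"""Assay-protocol definitions, validation and config-file I/O.

Two library-preparation assays are built in: a *mechanical*
(sonication-based) fragmentation assay and an *enzymatic* fragmentation
assay.  Both run on a capillary/384-well platform and share a common
stage sequence — cartridge surface passivation (pretreatment),
fragmentation / end-repair-and-adenylation, adapter ligation, a
post-ligation SPRI bead wash, capillary PCR, a post-PCR SPRI wash and a
final elution — differing only in selected volumes, temperatures,
incubation times and PCR schedules.

Protocols are plain dataclasses, serialised to schema-versioned YAML so
they remain user-editable inputs.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import yaml

SCHEMA_VERSION = 1

#: Interior volume of one 384 deep-well (3.48 mm x 3.48 mm x 19.3 mm), in uL.
WELL_CAPACITY_UL = 3.48 * 3.48 * 19.3 / 1000.0 * 1000.0  # mm^3 == uL

#: Minimum reliable automated transfer volume, uL.  Transfers at or below
#: this volume showed >10% CV on the platform's syringe pump, so a valid
#: protocol must move strictly more than this between wells.
MIN_TRANSFER_UL = 5.0


class StageKind(str, enum.Enum):
    PRETREAT = "pretreat"
    MIX = "mix"
    TRANSFER = "transfer"
    INCUBATE = "incubate"
    THERMOCYCLE = "thermocycle"
    SPRI_WASH = "spri_wash"
    ELUTE = "elute"
    DISPENSE = "dispense"


@dataclass
class Stage:
    """One step of an assay protocol.

    ``volume`` is the working liquid volume in uL; ``temperature`` (degC),
    ``duration`` (s) and ``pressure`` (atm) are present only where the
    stage heats, incubates or pressurises the fluid slug.  ``pump_speed``
    (uL/s) is recorded as metadata only and carries no semantics.
    """

    name: str
    kind: StageKind
    volume: float
    temperature: Optional[float] = None
    duration: Optional[float] = None
    pressure: Optional[float] = None
    source_well: Optional[str] = None
    dest_well: Optional[str] = None
    pump_speed: Optional[float] = None

    def __post_init__(self) -> None:
        self.kind = StageKind(self.kind)
        if self.volume < 0:
            raise ValueError(f"stage {self.name!r}: volume must be >= 0")
        if self.duration is not None and self.duration < 0:
            raise ValueError(f"stage {self.name!r}: duration must be >= 0")
        if self.temperature is not None and not (4.0 <= self.temperature <= 98.0):
            raise ValueError(
                f"stage {self.name!r}: temperature {self.temperature} degC "
                "outside [4, 98]"
            )
        if self.pressure is not None and not (1.0 <= self.pressure <= 2.5):
            raise ValueError(
                f"stage {self.name!r}: pressure {self.pressure} atm outside [1.0, 2.5]"
            )


@dataclass
class AssayProtocol:
    """Ordered stages plus the global volumes and PCR schedule of one assay.

    ``pcr_schedule`` is the fully expanded list of (temperature degC,
    hold s) pairs, including the initial denaturation, every cycle and
    the final extension, so hold-time totals are recomputable from the
    stored schedule alone.
    """

    name: str
    stages: list[Stage]
    n_pcr_cycles: int
    pcr_schedule: list[tuple[float, float]]
    elution_volume_final: float  # V_16, uL
    wash_volume: float           # V_4, uL
    resuspension_volume: float   # V_RsB, uL
    schema_version: int = SCHEMA_VERSION

    def __post_init__(self) -> None:
        if not self.stages:
            raise ValueError("protocol must contain at least one stage")
        if self.n_pcr_cycles < 0:
            raise ValueError("n_pcr_cycles must be >= 0")
        self.pcr_schedule = [(float(t), float(h)) for t, h in self.pcr_schedule]

    def pcr_hold_total(self) -> float:
        """Total scripted PCR hold time in seconds (ramps excluded)."""
        return sum(h for _, h in self.pcr_schedule)


def _pcr_schedule(
    init: tuple[float, float],
    denat: tuple[float, float],
    anneal: tuple[float, float],
    extend: tuple[float, float],
    final: tuple[float, float],
    n_cycles: int,
) -> list[tuple[float, float]]:
    sched = [init]
    for _ in range(n_cycles):
        sched.extend([denat, anneal, extend])
    sched.append(final)
    return sched


def _mechanical() -> AssayProtocol:
    stages = [
        Stage("pretreatment mix", StageKind.MIX, 50.0),
        Stage("pretreatment heat", StageKind.PRETREAT, 50.0,
              temperature=75.0, duration=600.0, pressure=1.90),
        Stage("era mix", StageKind.MIX, 50.0),
        Stage("era incubation", StageKind.INCUBATE, 50.0,
              temperature=65.0, duration=1800.0, pressure=1.90),
        Stage("to ligation well", StageKind.TRANSFER, 50.0,
              source_well="era", dest_well="ligation"),
        Stage("ligation", StageKind.INCUBATE, 60.0,
              temperature=25.0, duration=900.0),
        Stage("to spri well 1", StageKind.TRANSFER, 60.0,
              source_well="ligation", dest_well="spri1"),
        Stage("post-ligation spri wash", StageKind.SPRI_WASH, 100.0),
        Stage("elution 1", StageKind.ELUTE, 28.0),
        Stage("to pcr mix well", StageKind.TRANSFER, 28.0,
              source_well="spri1", dest_well="pcr"),
        Stage("capillary pcr", StageKind.THERMOCYCLE, 50.0, pressure=1.90),
        Stage("to spri well 2", StageKind.TRANSFER, 50.0,
              source_well="pcr", dest_well="spri2"),
        Stage("post-pcr spri wash", StageKind.SPRI_WASH, 100.0),
        Stage("final elution", StageKind.DISPENSE, 30.0,
              source_well="spri2", dest_well="output"),
    ]
    return AssayProtocol(
        name="mechanical",
        stages=stages,
        n_pcr_cycles=8,
        pcr_schedule=_pcr_schedule(
            init=(98.0, 30.0), denat=(98.0, 15.0), anneal=(65.0, 30.0),
            extend=(72.0, 30.0), final=(72.0, 120.0), n_cycles=8,
        ),
        elution_volume_final=30.0,
        wash_volume=100.0,
        resuspension_volume=33.0,
    )


def _enzymatic() -> AssayProtocol:
    stages = [
        Stage("pretreatment mix", StageKind.MIX, 50.0),
        Stage("pretreatment heat", StageKind.PRETREAT, 50.0,
              temperature=75.0, duration=600.0, pressure=1.90),
        Stage("frag/era mix", StageKind.MIX, 50.0),
        Stage("fragmentation", StageKind.INCUBATE, 50.0,
              temperature=37.0, duration=900.0, pressure=1.90),
        Stage("era incubation", StageKind.INCUBATE, 50.0,
              temperature=65.0, duration=1800.0, pressure=1.90),
        Stage("to ligation well", StageKind.TRANSFER, 50.0,
              source_well="frag", dest_well="ligation"),
        Stage("ligation", StageKind.INCUBATE, 60.0,
              temperature=25.0, duration=900.0),
        Stage("to spri well 1", StageKind.TRANSFER, 60.0,
              source_well="ligation", dest_well="spri1"),
        Stage("post-ligation spri wash", StageKind.SPRI_WASH, 60.0),
        Stage("elution 1", StageKind.ELUTE, 23.0),
        Stage("to pcr mix well", StageKind.TRANSFER, 23.0,
              source_well="spri1", dest_well="pcr"),
        Stage("capillary pcr", StageKind.THERMOCYCLE, 43.0, pressure=1.90),
        Stage("to spri well 2", StageKind.TRANSFER, 43.0,
              source_well="pcr", dest_well="spri2"),
        Stage("post-pcr spri wash", StageKind.SPRI_WASH, 60.0),
        Stage("final elution", StageKind.DISPENSE, 20.0,
              source_well="spri2", dest_well="output"),
    ]
    return AssayProtocol(
        name="enzymatic",
        stages=stages,
        n_pcr_cycles=8,
        pcr_schedule=_pcr_schedule(
            init=(98.0, 45.0), denat=(98.0, 15.0), anneal=(60.0, 30.0),
            extend=(72.0, 30.0), final=(72.0, 60.0), n_cycles=8,
        ),
        elution_volume_final=20.0,
        wash_volume=60.0,
        resuspension_volume=22.0,
    )


_BUILTINS = {"mechanical": _mechanical, "enzymatic": _enzymatic}


def builtin_protocol(name: str) -> AssayProtocol:
    """Return a fully populated built-in protocol.

    Parameters
    ----------
    name : {"mechanical", "enzymatic"}

    Raises
    ------
    KeyError
        If ``name`` names no built-in protocol.
    """
    try:
        factory = _BUILTINS[name]
    except KeyError:
        raise KeyError(
            f"no such protocol: {name!r} (built-ins: {sorted(_BUILTINS)})"
        ) from None
    return factory()


@dataclass
class Violation:
    """One broken validation rule; violations are data, not exceptions."""

    stage: str
    rule: str
    value: float


def validate_protocol(
    protocol: AssayProtocol, well_capacity: float = WELL_CAPACITY_UL
) -> list[Violation]:
    """Check a protocol against the platform's liquid-handling rules.

    Rules: every inter-well transfer must move strictly more than 5 uL
    (smaller volumes pipette with >10% CV on the syringe pump); no stage
    volume may exceed the well capacity; temperatures and pressures must
    lie in their physical operating ranges.  Returns one record per
    violated rule; an empty list means the protocol is valid.
    """
    violations: list[Violation] = []
    for st in protocol.stages:
        moves_liquid = st.kind in (
            StageKind.TRANSFER, StageKind.DISPENSE, StageKind.ELUTE
        )
        if moves_liquid and st.volume <= MIN_TRANSFER_UL:
            violations.append(Violation(st.name, "transfer <= 5 uL", st.volume))
        if st.volume > well_capacity:
            violations.append(
                Violation(st.name, "exceeds well capacity", st.volume)
            )
        if st.temperature is not None and not (4.0 <= st.temperature <= 98.0):
            violations.append(
                Violation(st.name, "temperature outside [4, 98] degC", st.temperature)
            )
        if st.pressure is not None and not (1.0 <= st.pressure <= 2.5):
            violations.append(
                Violation(st.name, "pressure outside [1.0, 2.5] atm", st.pressure)
            )
    return violations


class ProtocolSchemaError(ValueError):
    """Raised when a protocol config file is missing or mangles a field."""


_REQUIRED_FIELDS = (
    "schema_version", "name", "stages", "n_pcr_cycles", "pcr_schedule",
    "elution_volume_final", "wash_volume", "resuspension_volume",
)


def save_protocol(protocol: AssayProtocol, path: str | Path) -> None:
    """Write a protocol to a schema-versioned YAML file."""
    doc = asdict(protocol)
    doc["stages"] = [
        {k: (v.value if isinstance(v, StageKind) else v)
         for k, v in asdict(st).items() if v is not None}
        for st in protocol.stages
    ]
    doc["pcr_schedule"] = [[t, h] for t, h in protocol.pcr_schedule]
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_protocol(path: str | Path) -> AssayProtocol:
    """Load a protocol from YAML, checking schema version and fields."""
    doc = yaml.safe_load(Path(path).read_text())
    if not isinstance(doc, dict):
        raise ProtocolSchemaError(f"{path}: not a protocol document")
    for fieldname in _REQUIRED_FIELDS:
        if fieldname not in doc:
            raise ProtocolSchemaError(f"{path}: missing required field {fieldname!r}")
    if doc["schema_version"] != SCHEMA_VERSION:
        raise ProtocolSchemaError(
            f"{path}: schema version {doc['schema_version']} != {SCHEMA_VERSION}"
        )
    try:
        stages = [Stage(**st) for st in doc["stages"]]
    except (TypeError, ValueError) as exc:
        raise ProtocolSchemaError(f"{path}: bad stage entry: {exc}") from exc
    return AssayProtocol(
        name=doc["name"],
        stages=stages,
        n_pcr_cycles=int(doc["n_pcr_cycles"]),
        pcr_schedule=[(float(t), float(h)) for t, h in doc["pcr_schedule"]],
        elution_volume_final=float(doc["elution_volume_final"]),
        wash_volume=float(doc["wash_volume"]),
        resuspension_volume=float(doc["resuspension_volume"]),
    )
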