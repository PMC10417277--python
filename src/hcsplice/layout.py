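"""Plate-layout configuration: parsing, validation, serialisation.

A layout maps wells to conditions and control roles and carries the
generator parameters of each condition.  YAML schema::

    plate:
      min_fields: 12          # acquisition minimum per well
    conditions:
      WT:    {inclusion_mean: 0.35, role: sample}
      mock:  {transfection_rate: 0.0, role: negative_control}
    wells:
      A1: {condition: WT, role: sample, replicate: 1}
      B1: {condition: WT, role: sample, dose: "100 nM"}
      H1: {condition: mock, role: negative_control}

Doses parse from ``"<value> <unit>"`` strings (e.g. ``"100 nM"``) or bare
numbers; they are stored in nM.  Parsing and serialisation round-trip.
"""

from __future__ import annotations

import dataclasses
import io
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import LayoutError
from .synth import CHANNELS, ROLES, ConditionSpec

DOSE_UNIT = "nM"


@dataclass(frozen=True)
class WellSpec:
    """One well's assignment: condition, control role, optional dose (nM)
    and replicate id."""

    well: str
    condition: str
    role: str = "sample"
    dose: float | None = None
    replicate: int | None = None

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise LayoutError(
                f"well {self.well!r}: unknown role {self.role!r}; expected one of {ROLES}"
            )
        if self.dose is not None and self.dose < 0:
            raise LayoutError(f"well {self.well!r}: dose must be non-negative")


@dataclass
class PlateLayout:
    """Validated plate layout: wells, condition specs, acquisition globals."""

    wells: dict[str, WellSpec]
    conditions: dict[str, ConditionSpec]
    min_fields: int = 12
    channels: tuple[str, ...] = CHANNELS

    def __post_init__(self) -> None:
        if self.min_fields < 1:
            raise LayoutError("min_fields must be >= 1")
        for wid, w in self.wells.items():
            if w.condition not in self.conditions:
                raise LayoutError(
                    f"well {wid!r} references undefined condition {w.condition!r}"
                )

    def wells_with_role(self, role: str) -> list[str]:
        return sorted(w for w, s in self.wells.items() if s.role == role)


def parse_dose(value) -> float | None:
    """Parse a dose like ``"100 nM"``, ``100`` or ``None`` into nM."""
    if value is None:
        return None
    if isinstance(value, (int, float)):
        return float(value)
    text = str(value).strip()
    parts = text.split()
    try:
        if len(parts) == 1:
            return float(parts[0])
        if len(parts) == 2 and parts[1].lower() == DOSE_UNIT.lower():
            return float(parts[0])
    except ValueError:
        pass
    raise LayoutError(f"cannot parse dose {value!r}; expected e.g. '100 nM'")


def parse_layout(source) -> PlateLayout:
    """Parse a layout from YAML text, a path, or an already-loaded mapping.

    Errors name the offending well or field; duplicate well ids (possible
    when wells are given as a list of entries) are rejected.
    """
    if isinstance(source, dict):
        doc = source
    else:
        text = Path(source).read_text() if _is_path(source) else str(source)
        doc = yaml.safe_load(text)
    if not isinstance(doc, dict) or "wells" not in doc:
        raise LayoutError("layout must be a mapping with a 'wells' section")

    plate = doc.get("plate") or {}
    min_fields = int(plate.get("min_fields", 12))

    conditions: dict[str, ConditionSpec] = {}
    for name, fields in (doc.get("conditions") or {}).items():
        fields = dict(fields or {})
        unknown = set(fields) - {f.name for f in dataclasses.fields(ConditionSpec)}
        if unknown:
            raise LayoutError(f"condition {name!r}: unknown fields {sorted(unknown)}")
        conditions[name] = ConditionSpec(name=name, **fields)

    wells_doc = doc["wells"]
    entries: list[tuple[str, dict]] = []
    if isinstance(wells_doc, dict):
        entries = [(str(k), dict(v or {})) for k, v in wells_doc.items()]
    elif isinstance(wells_doc, list):
        for item in wells_doc:
            if "well" not in item:
                raise LayoutError("each wells[] entry needs a 'well' field")
            item = dict(item)
            entries.append((str(item.pop("well")), item))
    else:
        raise LayoutError("'wells' must be a mapping or a list of entries")

    wells: dict[str, WellSpec] = {}
    for wid, fields in entries:
        if wid in wells:
            raise LayoutError(f"duplicate well id {wid!r}")
        if "condition" not in fields:
            raise LayoutError(f"well {wid!r}: missing 'condition'")
        wells[wid] = WellSpec(
            well=wid,
            condition=str(fields["condition"]),
            role=str(fields.get("role", "sample")),
            dose=parse_dose(fields.get("dose")),
            replicate=(int(fields["replicate"]) if fields.get("replicate") is not None else None),
        )

    # conditions may be implicit (analysis-only layouts without generation)
    for wid, w in wells.items():
        if w.condition not in conditions:
            conditions[w.condition] = ConditionSpec(name=w.condition, role=w.role)
    return PlateLayout(wells=wells, conditions=conditions, min_fields=min_fields)


def serialize_layout(layout: PlateLayout) -> str:
    """Layout back to YAML; ``parse_layout(serialize_layout(x)) == x``."""
    defaults = ConditionSpec(name="_")
    cond_doc = {}
    for name, c in layout.conditions.items():
        entry = {}
        for f in dataclasses.fields(ConditionSpec):
            if f.name == "name":
                continue
            value = getattr(c, f.name)
            if value != getattr(defaults, f.name):
                entry[f.name] = value
        cond_doc[name] = entry
    wells_doc = {}
    for wid, w in layout.wells.items():
        entry: dict = {"condition": w.condition, "role": w.role}
        if w.dose is not None:
            entry["dose"] = f"{w.dose:g} {DOSE_UNIT}"
        if w.replicate is not None:
            entry["replicate"] = w.replicate
        wells_doc[wid] = entry
    doc = {
        "plate": {"min_fields": layout.min_fields},
        "conditions": cond_doc,
        "wells": wells_doc,
    }
    buf = io.StringIO()
    yaml.safe_dump(doc, buf, sort_keys=True)
    return buf.getvalue()


def _is_path(source) -> bool:
    if isinstance(source, Path):
        return True
    return isinstance(source, str) and "\n" not in source and source.endswith((".yaml", ".yml"))
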