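"""Domain types and file I/O for kinase-inhibitor drug screens.

A screen couples two measurements: per-drug IC50s against a tumor culture
(how much drug halves cell viability) and per-drug-per-target EC50s (how
much drug half-inhibits each kinase).  EC50 panels are drugs x targets
delimited text with blank cells meaning "no recorded interaction"; IC50
tables are drugs x cultures.  All concentrations are nM.

JSON writers for derived artifacts (target sets, TIMs, circuits) live here
too; they emit versioned, key-sorted JSON so output is byte-stable.
"""

from __future__ import annotations

import csv
import io
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence


class ScreenFormatError(ValueError):
    """Raised when a screen file violates the expected layout."""


@dataclass(frozen=True)
class KinaseUniverse:
    """Ordered set of kinase-target identifiers covered by a screen."""

    names: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.names) < 1:
            raise ScreenFormatError("universe must contain at least one target")
        if len(set(self.names)) != len(self.names):
            dupes = sorted({n for n in self.names if self.names.count(n) > 1})
            raise ScreenFormatError(f"duplicate target names: {dupes}")

    @property
    def n(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        return self.names.index(name)

    def __contains__(self, name: str) -> bool:
        return name in self.names


#: Sentinel tokens understood to mean "IC50 not reached within dosing".
NOT_REACHED_TOKENS = frozenset({"", "na", "nr", "nan", ">maxdose"})


@dataclass
class DrugProfile:
    """One drug's EC50 interaction vector plus screen IC50 and dosing.

    ``ec50`` maps target index -> EC50 in nM; absent keys mean no recorded
    interaction.  ``ic50`` is None when the screen never reached 50% kill
    within the allotted dosing ("not reached").
    """

    drug_id: str
    ec50: dict[int, float] = field(default_factory=dict)
    ic50: float | None = None
    cmax: float | None = None
    maxdose: float | None = None

    def validate(self, universe: KinaseUniverse) -> None:
        for j, v in self.ec50.items():
            if not (0 <= j < universe.n):
                raise ScreenFormatError(
                    f"{self.drug_id}: ec50 index {j} outside universe of {universe.n}"
                )
            if not v > 0:
                raise ScreenFormatError(f"{self.drug_id}: non-positive EC50 {v}")
        for label, v in (("ic50", self.ic50), ("cmax", self.cmax), ("maxdose", self.maxdose)):
            if v is not None and not v > 0:
                raise ScreenFormatError(f"{self.drug_id}: non-positive {label} {v}")

    @property
    def ic50_reached(self) -> bool:
        return self.ic50 is not None and (self.maxdose is None or self.ic50 < self.maxdose)

    def targets(self) -> list[int]:
        """Indices of targets with a recorded interaction, sorted."""
        return sorted(self.ec50)


@dataclass
class ScreenDataset:
    """A culture's worth of drug profiles over a common kinase universe."""

    universe: KinaseUniverse
    drugs: list[DrugProfile]
    culture_id: str = ""

    def __post_init__(self) -> None:
        ids = [d.drug_id for d in self.drugs]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ScreenFormatError(f"duplicate drug ids: {dupes}")
        if not self.drugs:
            raise ScreenFormatError("screen must contain at least one drug")
        for d in self.drugs:
            d.validate(self.universe)

    @property
    def m(self) -> int:
        return len(self.drugs)


# ---------------------------------------------------------------------------
# delimited-text readers / writers


def _sniff_delimiter(sample: str, override: str | None) -> str:
    if override is not None:
        return override
    try:
        return csv.Sniffer().sniff(sample, delimiters="\t,;").delimiter
    except csv.Error:
        return "\t" if "\t" in sample else ","


def _parse_cell(text: str, *, row: str, col: str) -> float | None:
    text = text.strip()
    if text == "":
        return None
    try:
        value = float(text)
    except ValueError as exc:
        raise ScreenFormatError(f"non-numeric cell at row {row!r}, column {col!r}: {text!r}") from exc
    if not value > 0:
        raise ScreenFormatError(f"non-positive cell at row {row!r}, column {col!r}: {value}")
    return value


def read_ec50_panel(
    path: str | Path, *, delimiter: str | None = None
) -> tuple[KinaseUniverse, list[DrugProfile]]:
    """Read a drugs x targets EC50 panel.

    Layout: header row ``drug, <target1>, <target2>, ...`` then one row per
    drug.  Empty cells mean no interaction.  Returns the universe in file
    column order and one partial :class:`DrugProfile` per row (no IC50 or
    dosing attached yet).
    """
    text = Path(path).read_text()
    delim = _sniff_delimiter(text.splitlines()[0], delimiter)
    rows = list(csv.reader(io.StringIO(text), delimiter=delim))
    rows = [r for r in rows if any(c.strip() for c in r)]
    if len(rows) < 2:
        raise ScreenFormatError(f"{path}: need a header and at least one drug row")
    header = [c.strip() for c in rows[0]]
    universe = KinaseUniverse(tuple(header[1:]))
    profiles: list[DrugProfile] = []
    seen: set[str] = set()
    for row in rows[1:]:
        drug_id = row[0].strip()
        if drug_id in seen:
            raise ScreenFormatError(f"{path}: duplicate drug id {drug_id!r}")
        seen.add(drug_id)
        ec50: dict[int, float] = {}
        for j, cell in enumerate(row[1:]):
            if j >= universe.n:
                raise ScreenFormatError(f"{path}: row {drug_id!r} has more cells than targets")
            value = _parse_cell(cell, row=drug_id, col=universe.names[j])
            if value is not None:
                ec50[j] = value
        profiles.append(DrugProfile(drug_id=drug_id, ec50=ec50))
    return universe, profiles


def write_ec50_panel(
    path: str | Path,
    universe: KinaseUniverse,
    profiles: Sequence[DrugProfile],
    *,
    delimiter: str = "\t",
) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(["drug", *universe.names])
        for p in profiles:
            row = [p.drug_id] + [
                repr(p.ec50[j]) if j in p.ec50 else "" for j in range(universe.n)
            ]
            writer.writerow(row)


def read_ic50_table(
    path: str | Path, culture: str, *, delimiter: str | None = None
) -> dict[str, float | None]:
    """Read one culture's IC50 column from a drugs x cultures table.

    Sentinel cells (empty, ``NR``, or ``>``-prefixed) map to None, the
    "not reached" marker.
    """
    text = Path(path).read_text()
    delim = _sniff_delimiter(text.splitlines()[0], delimiter)
    rows = list(csv.reader(io.StringIO(text), delimiter=delim))
    rows = [r for r in rows if any(c.strip() for c in r)]
    header = [c.strip() for c in rows[0]]
    if culture not in header[1:]:
        raise ScreenFormatError(
            f"{path}: culture {culture!r} not found; available: {header[1:]}"
        )
    col = header.index(culture)
    out: dict[str, float | None] = {}
    for row in rows[1:]:
        drug_id = row[0].strip()
        cell = row[col].strip() if col < len(row) else ""
        if cell.lower() in NOT_REACHED_TOKENS or cell.startswith(">"):
            out[drug_id] = None
        else:
            out[drug_id] = _parse_cell(cell, row=drug_id, col=culture)
    return out


def read_dosing_table(
    path: str | Path, *, delimiter: str | None = None
) -> dict[str, tuple[float | None, float]]:
    """Read ``drug, cmax, maxdose`` rows -> {drug_id: (cmax, maxdose)}."""
    text = Path(path).read_text()
    delim = _sniff_delimiter(text.splitlines()[0], delimiter)
    rows = list(csv.reader(io.StringIO(text), delimiter=delim))
    rows = [r for r in rows if any(c.strip() for c in r)]
    out: dict[str, tuple[float | None, float]] = {}
    for row in rows[1:]:
        drug_id = row[0].strip()
        cmax = _parse_cell(row[1], row=drug_id, col="cmax")
        maxdose = _parse_cell(row[2], row=drug_id, col="maxdose")
        if maxdose is None:
            raise ScreenFormatError(f"{path}: missing maxdose for {drug_id!r}")
        out[drug_id] = (cmax, maxdose)
    return out


def build_screen(
    universe: KinaseUniverse,
    profiles: Sequence[DrugProfile],
    ic50s: Mapping[str, float | None],
    dosing: Mapping[str, tuple[float | None, float]] | None = None,
    culture_id: str = "",
) -> ScreenDataset:
    """Merge an EC50 panel with a culture's IC50s (and optional dosing).

    Drugs present in the IC50 table but absent from the panel are dropped
    with a warning; an IC50 at or above MaxDose becomes "not reached".
    """
    by_id = {p.drug_id: p for p in profiles}
    missing = sorted(set(ic50s) - set(by_id))
    if missing:
        warnings.warn(
            f"dropping {len(missing)} drug(s) absent from EC50 panel: {missing}",
            stacklevel=2,
        )
    drugs: list[DrugProfile] = []
    for drug_id, profile in by_id.items():
        if drug_id not in ic50s:
            continue
        ic50 = ic50s[drug_id]
        cmax, maxdose = (dosing or {}).get(drug_id, (None, None))
        if ic50 is not None and maxdose is not None and ic50 >= maxdose:
            ic50 = None  # beyond the screened range: score as ineffective
        drugs.append(
            DrugProfile(drug_id=drug_id, ec50=dict(profile.ec50), ic50=ic50, cmax=cmax, maxdose=maxdose)
        )
    return ScreenDataset(universe=universe, drugs=drugs, culture_id=culture_id)


# ---------------------------------------------------------------------------
# versioned JSON artifacts

_FORMATS = {"tim": "timkit.tim/1", "circuit": "timkit.circuit/1", "targets": "timkit.targets/1"}


def _dump_json(payload: dict, path: str | Path, meta: dict | None = None) -> None:
    if meta:
        payload = {**payload, "meta": meta}
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def write_tim_json(tim, path: str | Path, meta: dict | None = None) -> None:
    """Serialize a TIM (lossless, deterministic key order)."""
    _dump_json({"format": _FORMATS["tim"], **tim.to_dict()}, path, meta)


def read_tim_json(path: str | Path):
    from .tim_inference import TIM

    payload = json.loads(Path(path).read_text())
    if payload.get("format") != _FORMATS["tim"]:
        raise ScreenFormatError(f"{path}: not a TIM artifact")
    return TIM.from_dict(payload)


def write_circuit_json(circuit, path: str | Path, meta: dict | None = None) -> None:
    _dump_json({"format": _FORMATS["circuit"], **circuit.to_dict()}, path, meta)


def read_circuit_json(path: str | Path):
    from .circuit import Circuit

    payload = json.loads(Path(path).read_text())
    if payload.get("format") != _FORMATS["circuit"]:
        raise ScreenFormatError(f"{path}: not a circuit artifact")
    return Circuit.from_dict(payload)


def write_target_set_json(
    names: Iterable[str], score: float, path: str | Path, meta: dict | None = None
) -> None:
    _dump_json(
        {"format": _FORMATS["targets"], "targets": list(names), "score": score}, path, meta
    )


def read_target_set_json(path: str | Path) -> tuple[list[str], float]:
    payload = json.loads(Path(path).read_text())
    if payload.get("format") != _FORMATS["targets"]:
        raise ScreenFormatError(f"{path}: not a target-set artifact")
    return list(payload["targets"]), float(payload["score"])
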