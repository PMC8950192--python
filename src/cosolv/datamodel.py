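"""Dataset schema, unit annotations, and readers/writers.

A :class:`SolubilityDataset` bundles a drug, a binary solvent pair, and a
collection of saturation records (temperature, solute-free solvent
composition, saturated solubility, optional saturated-solution density).
Every record of a dataset shares one solvent-composition basis and one
solute-concentration unit; the nine basis/unit combinations are encoded by
:class:`UnitCode`.

Temperatures are stored in kelvin only.  The CSV reader accepts a ``T_C``
column and converts on ingest.  The second solvent's fraction is never
stored; it is always ``1 - w1``.
"""

from __future__ import annotations

import csv
import enum
import io
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

__all__ = [
    "SolventBasis",
    "SoluteUnit",
    "DrugSpec",
    "SolventSpec",
    "SaturationRecord",
    "SolubilityDataset",
    "UnitCode",
    "ValidationError",
    "FormatError",
    "read_dataset",
    "write_dataset",
]

#: float format preserving 17 significant digits (lossless for IEEE doubles)
_FLOAT_FMT = "%.17g"

_CSV_COLUMNS = [
    "T_K",
    "w1",
    "solvent_basis",
    "solubility",
    "solubility_unit",
    "rho_sat_g_per_mL",
]


class ValidationError(ValueError):
    """A dataset violates a structural invariant."""


class FormatError(ValueError):
    """A file does not conform to the documented schema."""


class SolventBasis(str, enum.Enum):
    """Solute-free solvent-composition basis."""

    MOLE = "mole"
    MASS = "mass"
    VOLUME = "volume"


class SoluteUnit(str, enum.Enum):
    """Solute concentration unit of the saturated solubility."""

    MOLE_FRACTION = "mole_fraction"
    MOLAR = "molar"  # mol / L
    GRAM_PER_LITER = "gram_per_liter"  # g / L


# basis x unit -> code, laid out as a 3x3 grid:
# rows = solvent basis (mole, mass, volume), columns = solute unit
# (mole fraction, molar, gram/liter); codes run 1..9 row-major.
_BASIS_ORDER = (SolventBasis.MOLE, SolventBasis.MASS, SolventBasis.VOLUME)
_UNIT_ORDER = (SoluteUnit.MOLE_FRACTION, SoluteUnit.MOLAR, SoluteUnit.GRAM_PER_LITER)


@dataclass(frozen=True)
class UnitCode:
    """One of the nine solute-unit x solvent-basis combinations (codes 1-9)."""

    code: int

    def __post_init__(self) -> None:
        if not (1 <= self.code <= 9):
            raise ValueError(f"unit code must be in 1..9, got {self.code}")

    @property
    def solvent_basis(self) -> SolventBasis:
        return _BASIS_ORDER[(self.code - 1) // 3]

    @property
    def solute_unit(self) -> SoluteUnit:
        return _UNIT_ORDER[(self.code - 1) % 3]

    @classmethod
    def from_basis_unit(cls, basis: SolventBasis, unit: SoluteUnit) -> "UnitCode":
        return cls(_BASIS_ORDER.index(basis) * 3 + _UNIT_ORDER.index(unit) + 1)

    def __int__(self) -> int:
        return self.code

    def __str__(self) -> str:
        return f"code {self.code} ({self.solvent_basis.value} basis, {self.solute_unit.value})"


@dataclass(frozen=True)
class DrugSpec:
    """Solute identity and molar mass (g/mol)."""

    name: str
    molar_mass: float

    def __post_init__(self) -> None:
        if not self.molar_mass > 0:
            raise ValidationError(f"drug molar_mass must be > 0, got {self.molar_mass}")


@dataclass(frozen=True)
class SolventSpec:
    """Solvent identity, molar mass (g/mol), and pure density (g/mL).

    The reference temperature of ``pure_density`` is bookkeeping metadata;
    conversions treat the density as temperature independent.
    """

    name: str
    molar_mass: float
    pure_density: float
    density_ref_note: str = ""

    def __post_init__(self) -> None:
        if not self.molar_mass > 0:
            raise ValidationError(
                f"solvent molar_mass must be > 0, got {self.molar_mass}"
            )
        if not self.pure_density > 0:
            raise ValidationError(
                f"solvent pure_density must be > 0, got {self.pure_density}"
            )


@dataclass(frozen=True)
class SaturationRecord:
    """One saturation measurement.

    ``solvent_fraction_1`` is the solute-free fraction of solvent 1 in the
    record's basis; the fraction of solvent 2 is implicitly ``1 - w1``.
    """

    temperature: float  # K
    solvent_fraction_1: float
    solvent_basis: SolventBasis
    solubility_value: float
    solubility_unit: SoluteUnit
    saturated_density: Optional[float] = None  # g/mL

    def validate(self, index: Optional[int] = None) -> None:
        where = "" if index is None else f" (record {index})"
        if not self.temperature > 0:
            raise ValidationError(f"temperature must be > 0 K{where}")
        if not 0.0 <= self.solvent_fraction_1 <= 1.0:
            raise ValidationError(f"solvent_fraction_1 must be in [0, 1]{where}")
        if not self.solubility_value > 0:
            raise ValidationError(f"solubility_value must be > 0{where}")
        if (
            self.solubility_unit is SoluteUnit.MOLE_FRACTION
            and not self.solubility_value < 1
        ):
            raise ValidationError(f"mole-fraction solubility must be < 1{where}")
        if self.saturated_density is not None and not self.saturated_density > 0:
            raise ValidationError(f"saturated_density must be > 0{where}")


# mixture density table: temperature (K) -> {mass fraction w1 -> rho (g/mL)}
DensityTable = Mapping[float, Mapping[float, float]]


@dataclass
class SolubilityDataset:
    """A drug + binary solvent system with its saturation records.

    Invariants (checked by :meth:`validate`): at least 5 records; all records
    share one solvent basis and one solubility unit; for each distinct
    temperature, mono-solvent anchor records at ``w1 = 0`` and ``w1 = 1``
    exist.
    """

    label: str
    drug: DrugSpec
    solvent1: SolventSpec
    solvent2: SolventSpec
    records: list[SaturationRecord] = field(default_factory=list)
    mixture_density_table: Optional[DensityTable] = None

    # -- invariants -----------------------------------------------------

    def validate(self) -> "SolubilityDataset":
        if len(self.records) < 5:
            raise ValidationError(
                f"dataset {self.label!r}: needs >= 5 records, has {len(self.records)}"
            )
        for i, rec in enumerate(self.records):
            rec.validate(index=i)
        bases = {rec.solvent_basis for rec in self.records}
        if len(bases) != 1:
            raise ValidationError(
                f"dataset {self.label!r}: records mix solvent bases {sorted(b.value for b in bases)}"
            )
        units = {rec.solubility_unit for rec in self.records}
        if len(units) != 1:
            raise ValidationError(
                f"dataset {self.label!r}: records mix solubility units {sorted(u.value for u in units)}"
            )
        for T in self.temperatures():
            at_T = [r for r in self.records if r.temperature == T]
            if not any(r.solvent_fraction_1 == 0.0 for r in at_T):
                raise ValidationError(
                    f"dataset {self.label!r}: missing mono-solvent anchor w1=0 at T={T} K"
                )
            if not any(r.solvent_fraction_1 == 1.0 for r in at_T):
                raise ValidationError(
                    f"dataset {self.label!r}: missing mono-solvent anchor w1=1 at T={T} K"
                )
        return self

    # -- convenience ----------------------------------------------------

    @property
    def solvent_basis(self) -> SolventBasis:
        return self.records[0].solvent_basis

    @property
    def solubility_unit(self) -> SoluteUnit:
        return self.records[0].solubility_unit

    def temperatures(self) -> list[float]:
        """Distinct record temperatures in order of first appearance."""
        seen: dict[float, None] = {}
        for rec in self.records:
            seen.setdefault(rec.temperature, None)
        return list(seen)

    def anchor(self, temperature: float, which: int) -> SaturationRecord:
        """Return the mono-solvent anchor record (which=1 -> w1=1, 2 -> w1=0)."""
        target = 1.0 if which == 1 else 0.0
        for rec in self.records:
            if rec.temperature == temperature and rec.solvent_fraction_1 == target:
                return rec
        raise ValidationError(
            f"dataset {self.label!r}: no mono-solvent anchor w1={target} at T={temperature} K"
        )

    def with_records(self, records: Sequence[SaturationRecord]) -> "SolubilityDataset":
        return replace(self, records=list(records))

    def __len__(self) -> int:
        return len(self.records)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SolubilityDataset):
            return NotImplemented
        return (
            self.label == other.label
            and self.drug == other.drug
            and self.solvent1 == other.solvent1
            and self.solvent2 == other.solvent2
            and self.records == other.records
            and _density_table_equal(self.mixture_density_table, other.mixture_density_table)
        )


def _density_table_equal(a: Optional[DensityTable], b: Optional[DensityTable]) -> bool:
    if a is None or b is None:
        return a is None and b is None
    if set(a) != set(b):
        return False
    return all(dict(a[T]) == dict(b[T]) for T in a)


# ----------------------------------------------------------------------
# serialization
# ----------------------------------------------------------------------


def _fmt(x: float) -> str:
    return _FLOAT_FMT % x


def _drug_to_dict(d: DrugSpec) -> dict:
    return {"name": d.name, "molar_mass_g_per_mol": d.molar_mass}


def _solvent_to_dict(s: SolventSpec) -> dict:
    out = {
        "name": s.name,
        "molar_mass_g_per_mol": s.molar_mass,
        "pure_density_g_per_mL": s.pure_density,
    }
    if s.density_ref_note:
        out["density_ref_note"] = s.density_ref_note
    return out


def _drug_from_dict(d: Mapping) -> DrugSpec:
    try:
        return DrugSpec(name=str(d["name"]), molar_mass=float(d["molar_mass_g_per_mol"]))
    except KeyError as exc:
        raise FormatError(f"drug spec missing field {exc}") from exc


def _solvent_from_dict(d: Mapping) -> SolventSpec:
    try:
        return SolventSpec(
            name=str(d["name"]),
            molar_mass=float(d["molar_mass_g_per_mol"]),
            pure_density=float(d["pure_density_g_per_mL"]),
            density_ref_note=str(d.get("density_ref_note", "")),
        )
    except KeyError as exc:
        raise FormatError(f"solvent spec missing field {exc}") from exc


def _density_table_to_json(table: Optional[DensityTable]) -> Optional[dict]:
    if table is None:
        return None
    return {_fmt(T): {_fmt(w): rho for w, rho in row.items()} for T, row in table.items()}


def _density_table_from_json(obj: Optional[Mapping]) -> Optional[DensityTable]:
    if obj is None:
        return None
    return {
        float(T): {float(w): float(rho) for w, rho in row.items()}
        for T, row in obj.items()
    }


def _parse_basis(s: str) -> SolventBasis:
    try:
        return SolventBasis(s)
    except ValueError:
        raise FormatError(
            f"unknown solvent_basis {s!r}; expected one of "
            f"{[b.value for b in SolventBasis]}"
        ) from None


def _parse_unit(s: str) -> SoluteUnit:
    try:
        return SoluteUnit(s)
    except ValueError:
        raise FormatError(
            f"unknown solubility_unit {s!r}; expected one of "
            f"{[u.value for u in SoluteUnit]}"
        ) from None


def _record_to_dict(rec: SaturationRecord) -> dict:
    return {
        "T_K": rec.temperature,
        "w1": rec.solvent_fraction_1,
        "solvent_basis": rec.solvent_basis.value,
        "solubility": rec.solubility_value,
        "solubility_unit": rec.solubility_unit.value,
        "rho_sat_g_per_mL": rec.saturated_density,
    }


def _record_from_dict(d: Mapping) -> SaturationRecord:
    if "T_K" in d:
        T = float(d["T_K"])
    elif "T_C" in d:
        T = float(d["T_C"]) + 273.15
    else:
        raise FormatError("record missing temperature column (T_K or T_C)")
    rho = d.get("rho_sat_g_per_mL")
    if rho in (None, ""):
        rho_val = None
    else:
        rho_val = float(rho)
    try:
        return SaturationRecord(
            temperature=T,
            solvent_fraction_1=float(d["w1"]),
            solvent_basis=_parse_basis(str(d["solvent_basis"])),
            solubility_value=float(d["solubility"]),
            solubility_unit=_parse_unit(str(d["solubility_unit"])),
            saturated_density=rho_val,
        )
    except KeyError as exc:
        raise FormatError(f"record missing field {exc}") from exc


def _dataset_to_dict(ds: SolubilityDataset) -> dict:
    return {
        "label": ds.label,
        "drug": _drug_to_dict(ds.drug),
        "solvent1": _solvent_to_dict(ds.solvent1),
        "solvent2": _solvent_to_dict(ds.solvent2),
        "mixture_density_table": _density_table_to_json(ds.mixture_density_table),
        "records": [_record_to_dict(r) for r in ds.records],
    }


def _dataset_from_dict(d: Mapping) -> SolubilityDataset:
    try:
        ds = SolubilityDataset(
            label=str(d["label"]),
            drug=_drug_from_dict(d["drug"]),
            solvent1=_solvent_from_dict(d["solvent1"]),
            solvent2=_solvent_from_dict(d["solvent2"]),
            records=[_record_from_dict(r) for r in d["records"]],
            mixture_density_table=_density_table_from_json(d.get("mixture_density_table")),
        )
    except KeyError as exc:
        raise FormatError(f"dataset missing field {exc}") from exc
    return ds.validate()


def write_dataset(
    dataset: SolubilityDataset, path: Union[str, Path], format: str = "csv"
) -> None:
    """Serialize a validated dataset to CSV or JSON.

    The CSV flavor carries the drug/solvent specs in a leading ``#``-prefixed
    JSON header block; the JSON flavor mirrors the full schema with a
    ``records`` array.  Values survive the round trip to at least 12
    significant digits (17 are written).
    """
    dataset.validate()
    path = Path(path)
    if format == "json":
        payload = _dataset_to_dict(dataset)
        path.write_text(json.dumps(payload, indent=1, default=_json_float) + "\n")
    elif format == "csv":
        meta = _dataset_to_dict(dataset)
        meta.pop("records")
        buf = io.StringIO()
        for line in json.dumps(meta, indent=1, default=_json_float).splitlines():
            buf.write(f"# {line}\n")
        writer = csv.writer(buf)
        writer.writerow(_CSV_COLUMNS)
        for rec in dataset.records:
            rho = "" if rec.saturated_density is None else _fmt(rec.saturated_density)
            writer.writerow(
                [
                    _fmt(rec.temperature),
                    _fmt(rec.solvent_fraction_1),
                    rec.solvent_basis.value,
                    _fmt(rec.solubility_value),
                    rec.solubility_unit.value,
                    rho,
                ]
            )
        path.write_text(buf.getvalue())
    else:
        raise ValueError(f"unknown format {format!r}; expected 'csv' or 'json'")


def _json_float(x):  # json fallback for numpy scalars
    try:
        return float(x)
    except Exception:  # pragma: no cover
        raise TypeError(f"not JSON serializable: {x!r}")


def read_dataset(path: Union[str, Path], format: Optional[str] = None) -> SolubilityDataset:
    """Read and validate a dataset from CSV or JSON.

    ``format`` defaults to the file extension.  Raises
    :class:`FormatError` on schema problems and :class:`ValidationError`
    on invariant violations (e.g. missing mono-solvent anchors).
    """
    path = Path(path)
    if format is None:
        format = path.suffix.lstrip(".").lower() or "csv"
    if format == "json":
        try:
            payload = json.loads(path.read_text())
        except json.JSONDecodeError as exc:
            raise FormatError(f"{path}: invalid JSON: {exc}") from exc
        return _dataset_from_dict(payload)
    if format == "csv":
        text = path.read_text()
        header_lines = []
        body_lines = []
        for line in text.splitlines():
            if line.startswith("#"):
                header_lines.append(line.lstrip("#").strip())
            else:
                body_lines.append(line)
        if not header_lines:
            raise FormatError(f"{path}: missing '#' metadata header block")
        try:
            meta = json.loads("\n".join(header_lines))
        except json.JSONDecodeError as exc:
            raise FormatError(f"{path}: invalid JSON metadata header: {exc}") from exc
        reader = csv.DictReader([ln for ln in body_lines if ln.strip()])
        meta["records"] = list(reader)
        return _dataset_from_dict(meta)
    raise ValueError(f"unknown format {format!r}; expected 'csv' or 'json'")


def read_datasets_dir(directory: Union[str, Path]) -> list[SolubilityDataset]:
    """Read every ``.csv``/``.json`` dataset file in a directory (sorted)."""
    directory = Path(directory)
    out = []
    for p in sorted(directory.iterdir()):
        if p.suffix.lower() in (".csv", ".json"):
            out.append(read_dataset(p))
    return out
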