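"""Exact algebraic conversions between concentration units.

Solvent-composition bases (solute-free): mole, mass, and volume fraction.
Solute units: mole fraction, molarity (mol/L), and gram/liter.  Volume
fractions follow the volume-additive (ideal-mixing) convention computed
from pure-solvent densities, which is exactly invertible.  Solute
conversions between the gravimetric (mole fraction) and volumetric
(molar, g/L) scales require the saturated-solution density; when a record
lacks one and no mixture-density table entry applies, conversion fails
loudly rather than estimating.

All conversions run in double precision with no intermediate rounding, so
representations that differ only by a constant factor (molar vs g/L) stay
consistent to machine precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from cosolv.datamodel import (
    SaturationRecord,
    SolubilityDataset,
    SoluteUnit,
    SolventBasis,
    UnitCode,
)

__all__ = [
    "ConversionError",
    "ConvertedDataset",
    "solvent_mole_to_mass",
    "solvent_mass_to_mole",
    "solvent_mass_to_volume",
    "solvent_volume_to_mass",
    "convert_solvent_fraction",
    "solute_molefrac_to_molar",
    "solute_molar_to_molefrac",
    "molar_to_gram_per_liter",
    "gram_per_liter_to_molar",
    "convert_dataset",
]


class ConversionError(ValueError):
    """A unit conversion cannot be carried out with the available inputs."""


# ----------------------------------------------------------------------
# solvent-composition basis conversions (solute-free, binary)
# ----------------------------------------------------------------------


def solvent_mole_to_mass(x1: float, M1: float, M2: float) -> float:
    """Mole fraction -> mass fraction of solvent 1.

    w1 = x1*M1 / (x1*M1 + (1-x1)*M2).  Monotone increasing in ``x1`` and
    endpoint preserving.
    """
    m1 = x1 * M1
    return m1 / (m1 + (1.0 - x1) * M2)


def solvent_mass_to_mole(w1: float, M1: float, M2: float) -> float:
    """Mass fraction -> mole fraction of solvent 1 (inverse of the above)."""
    n1 = w1 / M1
    return n1 / (n1 + (1.0 - w1) / M2)


def solvent_mass_to_volume(w1: float, rho1: float, rho2: float) -> float:
    """Mass fraction -> volume fraction, volume-additive convention.

    v1 = (w1/rho1) / (w1/rho1 + (1-w1)/rho2); equals ``w1`` when the pure
    densities coincide.
    """
    v1 = w1 / rho1
    return v1 / (v1 + (1.0 - w1) / rho2)


def solvent_volume_to_mass(v1: float, rho1: float, rho2: float) -> float:
    """Volume fraction -> mass fraction (inverse of volume-additive mixing)."""
    m1 = v1 * rho1
    return m1 / (m1 + (1.0 - v1) * rho2)


def convert_solvent_fraction(
    value: float,
    source: SolventBasis,
    target: SolventBasis,
    M1: float,
    M2: float,
    rho1: float,
    rho2: float,
) -> float:
    """Convert a solute-free solvent-1 fraction between any two bases.

    Mole <-> volume routes through the mass basis.  Endpoints 0 and 1 map
    to themselves exactly in every basis.
    """
    if source is target or value in (0.0, 1.0):
        return value
    # normalize to mass basis first
    if source is SolventBasis.MOLE:
        w = solvent_mole_to_mass(value, M1, M2)
    elif source is SolventBasis.VOLUME:
        w = solvent_volume_to_mass(value, rho1, rho2)
    else:
        w = value
    if target is SolventBasis.MASS:
        return w
    if target is SolventBasis.MOLE:
        return solvent_mass_to_mole(w, M1, M2)
    return solvent_mass_to_volume(w, rho1, rho2)


# ----------------------------------------------------------------------
# solute-concentration conversions (saturated ternary solution)
# ----------------------------------------------------------------------


def solute_molefrac_to_molar(
    x_d: float,
    w1_mole: float,
    M_d: float,
    M1: float,
    M2: float,
    rho_sat: float,
) -> float:
    """Drug mole fraction -> molarity (mol/L) in the saturated solution.

    ``w1_mole`` is the solute-free solvent-1 mole fraction; inside the
    saturated ternary the solvent mole fractions are ``(1-x_d)*w1_mole``
    and ``(1-x_d)*(1-w1_mole)``.  With mean molar mass
    ``Mbar = x_d*M_d + (1-x_d)*(w1_mole*M1 + (1-w1_mole)*M2)`` (g/mol) and
    saturated density ``rho_sat`` (g/mL):

        C = 1000 * x_d * rho_sat / Mbar    [mol/L]
    """
    M_solv = w1_mole * M1 + (1.0 - w1_mole) * M2
    mbar = x_d * M_d + (1.0 - x_d) * M_solv
    return 1000.0 * x_d * rho_sat / mbar


def solute_molar_to_molefrac(
    C: float,
    w1_mole: float,
    M_d: float,
    M1: float,
    M2: float,
    rho_sat: float,
) -> float:
    """Molarity (mol/L) -> drug mole fraction; exact inverse of the above."""
    M_solv = w1_mole * M1 + (1.0 - w1_mole) * M2
    return C * M_solv / (1000.0 * rho_sat - C * (M_d - M_solv))


def molar_to_gram_per_liter(C: float, M_d: float) -> float:
    """Molarity -> g/L: S = C * M_d, exactly."""
    return C * M_d


def gram_per_liter_to_molar(S: float, M_d: float) -> float:
    """g/L -> molarity: C = S / M_d."""
    return S / M_d


# ----------------------------------------------------------------------
# dataset-level conversion
# ----------------------------------------------------------------------


@dataclass
class ConvertedDataset:
    """A dataset expressed in one of the nine unit codes.

    Parallel arrays, one entry per source record: temperature, solvent-1
    fraction in the target basis, solubility in the target unit, and the
    mono-solvent solubilities ``x1_T``/``x2_T`` (target unit) at that
    record's temperature.
    """

    source: SolubilityDataset
    code: UnitCode
    temperature: np.ndarray  # K
    w1: np.ndarray  # target basis
    x_m: np.ndarray  # target solute unit
    x1_T: np.ndarray
    x2_T: np.ndarray

    def __len__(self) -> int:
        return len(self.x_m)

    @property
    def drug_molar_mass(self) -> float:
        return self.source.drug.molar_mass


def _resolve_rho_sat(
    dataset: SolubilityDataset, rec: SaturationRecord, w1_mass: float
) -> Optional[float]:
    """Record density, else a mixture-density-table match, else None."""
    if rec.saturated_density is not None:
        return rec.saturated_density
    table = dataset.mixture_density_table
    if table is None:
        return None
    for T, row in table.items():
        if math.isclose(T, rec.temperature, rel_tol=0.0, abs_tol=1e-9):
            for w, rho in row.items():
                if math.isclose(w, w1_mass, rel_tol=0.0, abs_tol=1e-9):
                    return rho
    return None


def _convert_solute(
    value: float,
    source_unit: SoluteUnit,
    target_unit: SoluteUnit,
    w1_mole: float,
    M_d: float,
    M1: float,
    M2: float,
    rho_sat: Optional[float],
) -> float:
    if source_unit is target_unit:
        return value
    needs_rho = SoluteUnit.MOLE_FRACTION in (source_unit, target_unit)
    if needs_rho and rho_sat is None:
        raise ConversionError("saturated density required")
    # normalize to molar
    if source_unit is SoluteUnit.MOLE_FRACTION:
        C = solute_molefrac_to_molar(value, w1_mole, M_d, M1, M2, rho_sat)
    elif source_unit is SoluteUnit.GRAM_PER_LITER:
        C = gram_per_liter_to_molar(value, M_d)
    else:
        C = value
    if target_unit is SoluteUnit.MOLAR:
        return C
    if target_unit is SoluteUnit.GRAM_PER_LITER:
        return molar_to_gram_per_liter(C, M_d)
    return solute_molar_to_molefrac(C, w1_mole, M_d, M1, M2, rho_sat)


def convert_dataset(dataset: SolubilityDataset, code: UnitCode) -> ConvertedDataset:
    """Express a dataset in the target unit code.

    Converts every record's solvent fraction to the target basis and its
    solubility to the target solute unit, and attaches the converted
    mono-solvent anchor solubilities at each record's temperature.  Record
    count and temperatures are never altered; endpoint compositions map to
    endpoints in every basis.

    Raises :class:`ConversionError` listing the offending record indices
    when a required saturated density is missing.
    """
    dataset.validate()
    if isinstance(code, int):
        code = UnitCode(code)
    drug, s1, s2 = dataset.drug, dataset.solvent1, dataset.solvent2
    M_d, M1, M2 = drug.molar_mass, s1.molar_mass, s2.molar_mass
    rho1, rho2 = s1.pure_density, s2.pure_density
    src_basis = dataset.solvent_basis
    src_unit = dataset.solubility_unit

    def _one(rec: SaturationRecord, idx: int) -> tuple[float, float]:
        w1_tgt = convert_solvent_fraction(
            rec.solvent_fraction_1, src_basis, code.solvent_basis, M1, M2, rho1, rho2
        )
        w1_mole = convert_solvent_fraction(
            rec.solvent_fraction_1, src_basis, SolventBasis.MOLE, M1, M2, rho1, rho2
        )
        w1_mass = convert_solvent_fraction(
            rec.solvent_fraction_1, src_basis, SolventBasis.MASS, M1, M2, rho1, rho2
        )
        rho_sat = _resolve_rho_sat(dataset, rec, w1_mass)
        try:
            x = _convert_solute(
                rec.solubility_value, src_unit, code.solute_unit,
                w1_mole, M_d, M1, M2, rho_sat,
            )
        except ConversionError:
            raise ConversionError(
                f"dataset {dataset.label!r}, record {idx}: saturated density "
                f"required to convert {src_unit.value} -> {code.solute_unit.value} "
                f"but none is available"
            ) from None
        return w1_tgt, x

    missing = []
    for idx, rec in enumerate(dataset.records):
        if SoluteUnit.MOLE_FRACTION in (src_unit, code.solute_unit) \
                and src_unit is not code.solute_unit:
            w1_mass = convert_solvent_fraction(
                rec.solvent_fraction_1, src_basis, SolventBasis.MASS, M1, M2, rho1, rho2
            )
            if _resolve_rho_sat(dataset, rec, w1_mass) is None:
                missing.append(idx)
    if missing:
        raise ConversionError(
            f"dataset {dataset.label!r}: saturated density required for "
            f"{src_unit.value} -> {code.solute_unit.value} but missing on "
            f"records {missing}"
        )

    n = len(dataset.records)
    w1_arr = np.empty(n)
    x_arr = np.empty(n)
    T_arr = np.array([rec.temperature for rec in dataset.records])
    for idx, rec in enumerate(dataset.records):
        w1_arr[idx], x_arr[idx] = _one(rec, idx)

    # converted anchors per temperature
    anchors: dict[float, tuple[float, float]] = {}
    for T in dataset.temperatures():
        a1 = dataset.anchor(T, 1)
        a2 = dataset.anchor(T, 2)
        i1 = dataset.records.index(a1)
        i2 = dataset.records.index(a2)
        anchors[T] = (x_arr[i1], x_arr[i2])
    x1_arr = np.array([anchors[T][0] for T in T_arr])
    x2_arr = np.array([anchors[T][1] for T in T_arr])

    if not np.all(x_arr > 0):
        raise ConversionError(
            f"dataset {dataset.label!r}: non-positive converted solubility"
        )
    return ConvertedDataset(
        source=dataset,
        code=code,
        temperature=T_arr,
        w1=w1_arr,
        x_m=x_arr,
        x1_T=x1_arr,
        x2_T=x2_arr,
    )
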