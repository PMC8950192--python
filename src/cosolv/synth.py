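"""Synthetic saturated-solution datasets with known ground truth.

Datasets are generated forward from the cosolvency model: mono-solvent
log solubilities follow a van't-Hoff law ``ln x_pure(T) = A + B/T``, mixed
compositions get the interaction polynomial with configurable true J
coefficients, and optional additive Gaussian noise on ``ln x_m``
(multiplicative log-normal on the solubility).  Mono-solvent anchors are
noise-free by default since the model treats them as known inputs.

A saturated-solution density is attached to every record from a simple
invertible model: volume-additive solvent-mixture density times
``(1 + kappa * x_drug)``, so all nine unit codes are computable for every
generated dataset.
"""

from __future__ import annotations

import copy
import dataclasses
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from cosolv.datamodel import (
    DrugSpec,
    SaturationRecord,
    SolubilityDataset,
    SoluteUnit,
    SolventBasis,
    SolventSpec,
)
from cosolv.units import convert_solvent_fraction

__all__ = [
    "GeneratorConfig",
    "generate_dataset",
    "inject_outlier",
    "make_paper_like_suite",
]

DEFAULT_GRID = tuple(np.round(np.linspace(0.0, 1.0, 11), 10))
DEFAULT_TEMPERATURES = (298.2, 308.2, 318.2)


@dataclass
class GeneratorConfig:
    """Everything needed to generate one dataset.

    ``vant_hoff`` holds one (A, B) pair per solvent with
    ``ln x_pure(T) = A + B/T``, expressed in ``solubility_unit`` (keep the
    values negative over the temperature range when generating mole
    fractions, so x < 1).  The forward model is applied directly in
    ``solubility_unit`` on the ``grid_basis`` composition grid, so fitting
    the matching unit code reproduces ``j_true`` exactly at zero noise.
    """

    j_true: Sequence[float] = (900.0, -1400.0, 1700.0)
    vant_hoff: Sequence[Sequence[float]] = ((-1.0, -1000.0), (-2.0, -1500.0))
    temperatures: Sequence[float] = DEFAULT_TEMPERATURES
    composition_grid: Sequence[float] = DEFAULT_GRID
    grid_basis: SolventBasis = SolventBasis.MASS
    solubility_unit: SoluteUnit = SoluteUnit.MOLE_FRACTION
    noise_sigma: float = 0.0
    seed: int = 0
    drug: DrugSpec = field(default_factory=lambda: DrugSpec("synthetic-drug", 250.0))
    solvent1: SolventSpec = field(
        default_factory=lambda: SolventSpec("cosolvent", 46.07, 0.789)
    )
    solvent2: SolventSpec = field(
        default_factory=lambda: SolventSpec("water", 18.02, 0.997)
    )
    kappa: float = 0.1  # drug-content coupling of the saturated density
    noisy_anchors: bool = False
    label: str = "synthetic"

    def validate(self) -> "GeneratorConfig":
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if len(self.vant_hoff) != 2:
            raise ValueError("vant_hoff needs one (A, B) pair per solvent")
        grid = list(self.composition_grid)
        if not all(0.0 <= g <= 1.0 for g in grid):
            raise ValueError("composition grid values must be in [0, 1]")
        if 0.0 not in grid or 1.0 not in grid:
            raise ValueError("composition grid must include the endpoints 0 and 1")
        if not all(t > 0 for t in self.temperatures):
            raise ValueError("temperatures must be > 0 K")
        if not (1 <= len(self.j_true) <= 5):
            raise ValueError("j_true must have 1..5 coefficients (np in 0..4)")
        return self

    # -- declarative round trip (for config files) ----------------------

    def to_dict(self) -> dict:
        return {
            "j_true": list(map(float, self.j_true)),
            "vant_hoff": [list(map(float, ab)) for ab in self.vant_hoff],
            "temperatures": list(map(float, self.temperatures)),
            "composition_grid": list(map(float, self.composition_grid)),
            "grid_basis": self.grid_basis.value,
            "solubility_unit": self.solubility_unit.value,
            "noise_sigma": float(self.noise_sigma),
            "seed": int(self.seed),
            "drug": {"name": self.drug.name, "molar_mass_g_per_mol": self.drug.molar_mass},
            "solvent1": {
                "name": self.solvent1.name,
                "molar_mass_g_per_mol": self.solvent1.molar_mass,
                "pure_density_g_per_mL": self.solvent1.pure_density,
            },
            "solvent2": {
                "name": self.solvent2.name,
                "molar_mass_g_per_mol": self.solvent2.molar_mass,
                "pure_density_g_per_mL": self.solvent2.pure_density,
            },
            "kappa": float(self.kappa),
            "noisy_anchors": bool(self.noisy_anchors),
            "label": self.label,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        kwargs = dict(d)
        if "grid_basis" in kwargs:
            kwargs["grid_basis"] = SolventBasis(kwargs["grid_basis"])
        if "solubility_unit" in kwargs:
            kwargs["solubility_unit"] = SoluteUnit(kwargs["solubility_unit"])
        for key, spec_cls in (("drug", DrugSpec),):
            if key in kwargs and isinstance(kwargs[key], dict):
                s = kwargs[key]
                kwargs[key] = DrugSpec(s["name"], float(s["molar_mass_g_per_mol"]))
        for key in ("solvent1", "solvent2"):
            if key in kwargs and isinstance(kwargs[key], dict):
                s = kwargs[key]
                kwargs[key] = SolventSpec(
                    s["name"],
                    float(s["molar_mass_g_per_mol"]),
                    float(s["pure_density_g_per_mL"]),
                )
        allowed = {f.name for f in dataclasses.fields(cls)}
        unknown = set(kwargs) - allowed
        if unknown:
            raise ValueError(f"unknown generator-config fields: {sorted(unknown)}")
        return cls(**kwargs)


def _rho_saturated(cfg: GeneratorConfig, w1_mass: float, x_drug: float) -> float:
    """Volume-additive mixture density with a weak drug-content coupling."""
    rho_mix = 1.0 / (
        w1_mass / cfg.solvent1.pure_density
        + (1.0 - w1_mass) / cfg.solvent2.pure_density
    )
    return rho_mix * (1.0 + cfg.kappa * x_drug)


def generate_dataset(config: GeneratorConfig) -> SolubilityDataset:
    """Generate a mole-fraction solubility dataset from the forward model.

    For every temperature and grid composition w1 (in ``grid_basis``)::

        ln x_m = w1*ln x1(T) + w2*ln x2(T)
                 + (w1*w2/T) * sum_i J_i*(w1-w2)**i  [+ Normal(0, sigma^2)]

    Noise applies to mixed compositions; anchors stay noise-free unless
    ``noisy_anchors`` is set.  Deterministic given ``seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    J = np.asarray(config.j_true, dtype=float)
    (A1, B1), (A2, B2) = config.vant_hoff
    records = []
    for T in config.temperatures:
        ln_x1 = A1 + B1 / T
        ln_x2 = A2 + B2 / T
        for w1 in config.composition_grid:
            w2 = 1.0 - w1
            if w1 == 1.0:
                ln_xm = ln_x1
            elif w1 == 0.0:
                ln_xm = ln_x2
            else:
                diff = w1 - w2
                inter = sum(J[i] * diff**i for i in range(len(J)))
                ln_xm = w1 * ln_x1 + w2 * ln_x2 + (w1 * w2 / T) * inter
            is_anchor = w1 in (0.0, 1.0)
            if config.noise_sigma > 0 and (config.noisy_anchors or not is_anchor):
                ln_xm += rng.normal(0.0, config.noise_sigma)
            x = math.exp(ln_xm)
            if config.solubility_unit is SoluteUnit.MOLE_FRACTION and not x < 1.0:
                raise ValueError(
                    f"generated mole-fraction solubility >= 1 at T={T}, w1={w1}; "
                    f"choose van't-Hoff anchors with ln x < 0"
                )
            w1_mass = convert_solvent_fraction(
                w1,
                config.grid_basis,
                SolventBasis.MASS,
                config.solvent1.molar_mass,
                config.solvent2.molar_mass,
                config.solvent1.pure_density,
                config.solvent2.pure_density,
            )
            # the kappa coupling needs the drug mole fraction, known only
            # when generating on the mole-fraction scale
            x_d = x if config.solubility_unit is SoluteUnit.MOLE_FRACTION else 0.0
            records.append(
                SaturationRecord(
                    temperature=T,
                    solvent_fraction_1=float(w1),
                    solvent_basis=config.grid_basis,
                    solubility_value=x,
                    solubility_unit=config.solubility_unit,
                    saturated_density=_rho_saturated(config, w1_mass, x_d),
                )
            )
    return SolubilityDataset(
        label=config.label,
        drug=config.drug,
        solvent1=config.solvent1,
        solvent2=config.solvent2,
        records=records,
    ).validate()


def inject_outlier(
    dataset: SolubilityDataset, record_index: int, factor: float
) -> SolubilityDataset:
    """Return a copy with one record's solubility multiplied by ``factor``."""
    if factor <= 0:
        raise ValueError("factor must be > 0")
    if not 0 <= record_index < len(dataset.records):
        raise IndexError(f"record index {record_index} out of range")
    records = list(dataset.records)
    rec = records[record_index]
    records[record_index] = dataclasses.replace(
        rec, solubility_value=rec.solubility_value * factor
    )
    out = copy.copy(dataset)
    out.records = records
    return out


# ----------------------------------------------------------------------
# study-scale suites
# ----------------------------------------------------------------------

_PRESETS = {
    # anchors span many decades so molar solubilities range over >= 1e6;
    # upper cap keeps ln x + interaction bump below 0 (mole fraction < 1)
    "wide-magnitude": {"ln_x_range": (-25.0, -4.0)},
    # heavy cosolvent vs light water: mass-uniform grids are strongly
    # skewed once re-expressed as mole fractions
    "skewed": {"solvent1_molar_mass": 78.0, "solvent2_molar_mass": 18.0},
}


def make_paper_like_suite(
    n_datasets: int,
    seed: int = 0,
    preset: Optional[str] = None,
    noise_sigma_range: tuple[float, float] = (0.02, 0.08),
    j0_range: tuple[float, float] = (300.0, 1500.0),
    ln_x_range: tuple[float, float] = (-9.0, -2.0),
    grid_basis: SolventBasis = SolventBasis.MASS,
    n_terms: int = 3,
) -> list[SolubilityDataset]:
    """Generate a batch of heterogeneous but valid datasets.

    Grids are uniform in ``grid_basis`` (mass by default), solvent molar
    masses and mono-solvent solubility magnitudes vary across the batch,
    and each dataset gets its own noise level and true J vector.  Presets:
    ``"wide-magnitude"`` stretches mono-solvent solubilities so molar
    solubilities span >= 6 orders of magnitude; ``"skewed"`` fixes a
    solvent molar-mass ratio > 4 so mole-fraction compositions skew low.
    """
    if n_datasets < 1:
        raise ValueError("n_datasets must be >= 1")
    opts = dict(_PRESETS.get(preset, {})) if preset else {}
    if preset and preset not in _PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {sorted(_PRESETS)}")
    lo, hi = opts.get("ln_x_range", ln_x_range)
    rng = np.random.default_rng(seed)
    suite = []
    for k in range(n_datasets):
        M1 = opts.get("solvent1_molar_mass", float(rng.uniform(30.0, 120.0)))
        M2 = opts.get("solvent2_molar_mass", float(rng.uniform(18.0, 60.0)))
        rho1 = float(rng.uniform(0.75, 1.1))
        rho2 = float(rng.uniform(0.9, 1.05))
        A_ln1 = float(rng.uniform(lo, hi))
        A_ln2 = float(rng.uniform(lo, hi))
        B1 = float(rng.uniform(-2500.0, -500.0))
        B2 = float(rng.uniform(-2500.0, -500.0))
        Tref = 298.2
        # pin ln x at Tref to the sampled level, pivot with the B slope
        vant_hoff = ((A_ln1 - B1 / Tref, B1), (A_ln2 - B2 / Tref, B2))
        sign = 1.0 if rng.uniform() < 0.5 else -1.0
        j = [float(sign * rng.uniform(*j0_range))]
        for _ in range(n_terms - 1):
            j.append(float(rng.uniform(-1500.0, 1500.0)))
        cfg = GeneratorConfig(
            j_true=tuple(j),
            vant_hoff=vant_hoff,
            noise_sigma=float(rng.uniform(*noise_sigma_range)),
            seed=int(rng.integers(0, 2**31 - 1)),
            drug=DrugSpec(f"drug-{k}", float(rng.uniform(120.0, 500.0))),
            solvent1=SolventSpec(f"cosolvent-{k}", M1, rho1),
            solvent2=SolventSpec(f"water-like-{k}", M2, rho2),
            grid_basis=grid_basis,
            label=f"SN-{k + 1}",
        )
        suite.append(generate_dataset(cfg))
    return suite
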