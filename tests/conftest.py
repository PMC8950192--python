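import numpy as np
import pytest

from cosolv.datamodel import (
    DrugSpec,
    SaturationRecord,
    SolubilityDataset,
    SoluteUnit,
    SolventBasis,
    SolventSpec,
)
from cosolv.synth import GeneratorConfig, generate_dataset

# worked-example three-term coefficient sets (kelvin) used as generator
# ground truth throughout the suite
J_SET_A = (897.693, -1417.112, 1671.752)
J_SET_B = (967.341, -1304.172, 1264.565)


@pytest.fixture
def ethanol() -> SolventSpec:
    return SolventSpec("ethanol", 46.07, 0.789)


@pytest.fixture
def water() -> SolventSpec:
    return SolventSpec("water", 18.02, 0.997)


@pytest.fixture
def drug() -> DrugSpec:
    return DrugSpec("modeldrug", 250.0)


@pytest.fixture
def base_config(drug, ethanol, water) -> GeneratorConfig:
    """Mass-basis, mole-fraction unit, noise-free 3x11 grid."""
    return GeneratorConfig(
        j_true=J_SET_A,
        vant_hoff=((-4.0, -900.0), (-7.5, -1100.0)),
        drug=drug,
        solvent1=ethanol,
        solvent2=water,
        seed=11,
        label="fixture",
    )


@pytest.fixture
def noise_free_dataset(base_config) -> SolubilityDataset:
    return generate_dataset(base_config)


@pytest.fixture
def noisy_dataset(base_config) -> SolubilityDataset:
    import dataclasses

    return generate_dataset(dataclasses.replace(base_config, noise_sigma=0.05, seed=7))


def make_manual_dataset(
    drug,
    solvent1,
    solvent2,
    temperatures=(298.15, 308.15),
    w_grid=(0.0, 0.25, 0.5, 0.75, 1.0),
    basis=SolventBasis.MASS,
    unit=SoluteUnit.MOLE_FRACTION,
    rho_sat=1.0,
    label="manual",
):
    """A tiny hand-built dataset (Yalkowsky-plane solubilities)."""
    records = []
    for T in temperatures:
        ln1, ln2 = -3.0 - 300.0 / T, -6.0 - 500.0 / T
        for w in w_grid:
            ln = w * ln1 + (1 - w) * ln2
            records.append(
                SaturationRecord(
                    temperature=T,
                    solvent_fraction_1=w,
                    solvent_basis=basis,
                    solubility_value=float(np.exp(ln)),
                    solubility_unit=unit,
                    saturated_density=rho_sat,
                )
            )
    return SolubilityDataset(
        label=label, drug=drug, solvent1=solvent1, solvent2=solvent2, records=records
    ).validate()


@pytest.fixture
def manual_dataset(drug, ethanol, water) -> SolubilityDataset:
    return make_manual_dataset(drug, ethanol, water)
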