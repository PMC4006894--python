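import pytest

from thermogrowth import StrainParams, UniversalParams, default_config, simulate_dataset
from thermogrowth.constants import GROUP_REFERENCE, UNIVERSAL_REFERENCE


@pytest.fixture(scope="session")
def u_ref() -> UniversalParams:
    """Reference universal unfolding parameters."""
    return UniversalParams(**UNIVERSAL_REFERENCE)


@pytest.fixture(scope="session")
def meso() -> StrainParams:
    """Mesophile reference enzyme parameters (c scaled so max rate = 1)."""
    return StrainParams(c=4.977e10, dH_act=75300.0, dCp=59.9, n=422.0,
                        group="mesophile")


@pytest.fixture(scope="session")
def group_params() -> dict:
    return {g: StrainParams(c=1.0, group=g, **GROUP_REFERENCE[g])
            for g in GROUP_REFERENCE}


@pytest.fixture(scope="session")
def small_dataset():
    """Six strains in two thermal groups, eight points each (48 records)."""
    cfg = default_config(
        seed=7, points_per_strain=8,
        strains_per_group={"psychrophile": 0, "mesophile": 3, "ascomycota": 0,
                           "thermophile": 3, "hyperthermophile": 0})
    return simulate_dataset(cfg)
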