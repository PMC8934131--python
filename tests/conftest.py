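import numpy as np
import pytest

from sbmodel import SynthConfig, fixture_exposure_table, fixture_rr_table, generate_bundle


@pytest.fixture(scope="session")
def exposure_fixture():
    return fixture_exposure_table()


@pytest.fixture(scope="session")
def rr_fixture():
    return fixture_rr_table()


@pytest.fixture(scope="session")
def synth_cfg():
    return SynthConfig(seed=123)


@pytest.fixture(scope="session")
def bundle(synth_cfg):
    return generate_bundle(synth_cfg)


def symmetric_bundle(seed: int = 5):
    """Bundle identical across the sexes except for the two female-only diseases."""
    cfg = SynthConfig(seed=seed)
    inputs = generate_bundle(cfg)
    pop = inputs.population
    from sbmodel.lifetable import PopulationTable

    sym_pop = PopulationTable(
        ages=pop.ages,
        population={s: pop.population["female"].copy() for s in ("female", "male")},
        mortality={s: pop.mortality["female"].copy() for s in ("female", "male")},
        total_yld_rate={s: pop.total_yld_rate["female"].copy() for s in ("female", "male")},
    )
    from sbmodel.exposure import ExposureTable

    strata = {}
    for (sex, band), st in inputs.exposure.strata.items():
        if sex == "female":
            strata[(sex, band)] = st
            strata[("male", band)] = st.replace(sex="male")
    sym_exposure = ExposureTable(strata)
    return inputs.replace(population=sym_pop, exposure=sym_exposure)


@pytest.fixture(scope="session")
def sym_bundle():
    return symmetric_bundle()
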