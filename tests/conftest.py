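import pytest
from hypothesis import settings

from bin1meta import SimulationTruth, build_effects, load_bundled_roster, simulate_studies

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def roster():
    """The bundled 37-study rs744373 roster."""
    return load_bundled_roster()


@pytest.fixture(scope="session")
def additive_effects(roster):
    """Harmonised additive (C vs T) effects reconstructed from the roster."""
    return build_effects(roster, model="additive")


@pytest.fixture(scope="session")
def genotype_roster():
    """A small simulated roster carrying per-arm CC/CT/TT genotype counts."""
    table, _ = simulate_studies(SimulationTruth(true_or=1.3, tau2=0.01, k=6, seed=7))
    return table


@pytest.fixture()
def roster_csv(tmp_path):
    """Write a minimal 3-study roster CSV and return its path."""
    path = tmp_path / "roster.csv"
    path.write_text(
        "label,group,n_case,n_control,maf,or\n"
        "A 2020,east_asian,100,120,0.30,1.10\n"
        "B 2021,caucasian,200,210,0.25,0.95\n"
        "C 2022,caucasian,150,160,0.28,1.05\n"
    )
    return path
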