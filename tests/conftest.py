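import numpy as np
import pytest

from mobiloscope.simulate import (
    CassettePlan,
    FamilyPlan,
    GenePlan,
    SimulationConfig,
    default_library,
    simulate,
)


@pytest.fixture(scope="session")
def library():
    return default_library()


@pytest.fixture(scope="session")
def simdir(tmp_path_factory, library):
    """A small, fully ground-truthed synthetic mobilome used across tests."""
    out = tmp_path_factory.mktemp("sim") / "mobilome"
    cfg = SimulationConfig(
        seed=42,
        genome=(("chr1", 400_000),),
        families=(
            FamilyPlan(library[1], copy_count=40, true_age_mya=5.0, te_class="SINE"),
            FamilyPlan(library[2], copy_count=10, true_age_mya=40.0, te_class="LTR"),
        ),
        gene_plan=GenePlan(n_pc=10, n_lnc=5, genic_te_fraction=0.8),
        cassette_plan=CassettePlan(
            lengths=(100, 200, 300),
            chimeric_fraction=0.6,
            n_ests_per_mrna=1,
            n_decoy_ests=3,
        ),
    )
    truth = simulate(cfg, out)
    return out, truth, cfg


@pytest.fixture
def rng():
    return np.random.default_rng(0)
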