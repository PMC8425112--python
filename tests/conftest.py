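import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import snpxe

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20210907)


@pytest.fixture(scope="session")
def null_data():
    """n=600 dataset with no SNP, environment, or interaction effect."""
    cfg = snpxe.SimulationConfig(
        n=600, snps=[("snp1", 0.3), ("snp2", 0.45)], baseline=0.0, seed=11
    )
    return snpxe.simulate_dataset(cfg)


@pytest.fixture(scope="session")
def planted_data():
    """n=2000 dataset with a strong Int_RE_or interaction planted on snp1."""
    cfg = snpxe.SimulationConfig(
        n=2000,
        snps=[("snp1", 0.35)],
        truth=[
            snpxe.PlantedEffect(
                spec=snpxe.parse_label("Int_RE_or"),
                snp_name="snp1",
                interaction_coefs=(np.log(4.3), np.log(1.8)),
            )
        ],
        baseline=-1.2,
        seed=7,
    )
    return snpxe.simulate_dataset(cfg)


@pytest.fixture()
def toy_counts_2x2():
    """Binary exposure x with (cases, controls) = (10, 40) at x=1, (5, 45) at x=0."""
    x = np.repeat([1, 1, 0, 0], [10, 40, 5, 45])
    y = np.repeat([1, 0, 1, 0], [10, 40, 5, 45])
    return pd.DataFrame({"const": 1.0, "x": x.astype(float)}), y.astype(float)
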