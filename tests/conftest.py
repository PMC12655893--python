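import numpy as np
import pandas as pd
import pytest

import rhizojip as rj


@pytest.fixture
def design6() -> pd.DataFrame:
    """Four-group design (TN/TA/SN/SA) with 6 samples per group."""
    return rj.make_design(6)


@pytest.fixture
def design2() -> pd.DataFrame:
    return rj.make_design(2)


@pytest.fixture
def small_table() -> rj.AbundanceTable:
    """4 samples x 3 taxa toy table with parseable lineages."""
    taxa = [
        "k__Bacteria;p__P1;c__C1;o__O1;f__F1;g__GenusA;s__Sp1",
        "k__Bacteria;p__P1;c__C1;o__O1;f__F1;g__GenusB;s__Sp2",
        "k__Bacteria;p__P2;c__C2;o__O2;f__F2;g__GenusC;s__Sp3",
    ]
    counts = pd.DataFrame(
        [[10, 5, 0], [8, 6, 1], [2, 2, 16], [1, 3, 14]],
        index=["TN01", "TN02", "TA01", "TA02"],
        columns=taxa,
    )
    return rj.AbundanceTable(counts)


@pytest.fixture
def random_transient_params():
    """Draw valid random transient parameters (seeded factory)."""

    def factory(rng: np.random.Generator) -> rj.TransientParams:
        wj = rng.uniform(0.35, 0.6)
        wi = rng.uniform(0.15, 0.35)
        return rj.TransientParams(
            F0=rng.uniform(300, 500),
            Fm=rng.uniform(1500, 2500),
            wJ=wj,
            wI=wi,
            wP=1.0 - wj - wi,
            tauJ=rng.uniform(0.4, 0.9),
            tauI=rng.uniform(5, 15),
            tauP=rng.uniform(80, 200),
            kappa=rng.uniform(0, 0.2),
        )

    return factory
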