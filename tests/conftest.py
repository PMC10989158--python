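import numpy as np
import pandas as pd
import pytest

from soilwebdex.io_tables import ActivityTable, CommunityTable
from soilwebdex import synth

ENZYMES = ["AG", "BG", "CB", "XS", "NAG", "LAP", "PHOX", "PEOX"]


@pytest.fixture()
def activity_table() -> ActivityTable:
    """16 samples x 8 canonical enzymes, reproducible positive activities."""
    rng = np.random.default_rng(42)
    base = np.array([20, 120, 35, 25, 60, 180, 900, 1400], dtype=float)
    values = base * rng.lognormal(0.0, 0.3, size=(16, 8))
    idx = [f"s{i + 1}" for i in range(16)]
    return ActivityTable(pd.DataFrame(values, index=idx, columns=ENZYMES))


@pytest.fixture()
def nematode_table() -> CommunityTable:
    """Five-genus nematode table with trophic and cp annotations."""
    counts = pd.DataFrame(
        {
            "Rhabditis": [30, 40, 10],       # bacterivore cp1
            "Acrobeloides": [20, 10, 30],    # bacterivore cp2
            "Aphelenchus": [10, 20, 40],     # fungivore cp2
            "Dorylaimus": [25, 15, 10],      # omnivore-predator cp4
            "Helicotylenchus": [15, 15, 10], # herbivore cp3
        },
        index=["s1", "s2", "s3"],
    )
    ann = pd.DataFrame(
        {
            "trophic_group": ["bacterivore", "bacterivore", "fungivore",
                              "omnivore-predator", "herbivore"],
            "cp_class": [1, 2, 2, 4, 3],
        },
        index=pd.Index(counts.columns, name="taxon"),
    )
    return CommunityTable(group="nematode", counts=counts, annotations=ann)


@pytest.fixture()
def protozoa_table() -> CommunityTable:
    counts = pd.DataFrame(
        {"pA": [40, 10], "pB": [10, 10], "pC": [30, 20], "pD": [20, 60]},
        index=["s1", "s2"],
    )
    ann = pd.DataFrame(
        {"feeding_habit": ["bacterivore", "fungivore", "other", "bacterivore"]},
        index=pd.Index(counts.columns, name="taxon"),
    )
    return CommunityTable(group="protozoa", counts=counts, annotations=ann)


@pytest.fixture(scope="session")
def small_bundle():
    """One reduced-size study-like synthetic bundle shared across tests."""
    return synth.generate(synth.PRESETS["paper-like-small"](seed=7))
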