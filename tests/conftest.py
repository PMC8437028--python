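import numpy as np
import pandas as pd
import pytest

from poolsel import synthetic_data as sd


@pytest.fixture(scope="session")
def neutral_experiment():
    """Small neutral-scenario dataset: counts, survival, truth."""
    sc = sd.make_scenario("neutral", n_loci=40, seed=11)
    counts, survival, truth = sd.simulate_experiment(sc)
    return counts, survival, truth


@pytest.fixture(scope="session")
def balanced_experiment():
    sc = sd.make_scenario("balanced", n_loci=40, seed=12)
    counts, survival, truth = sd.simulate_experiment(sc)
    return counts, survival, truth


@pytest.fixture()
def clean_count_table():
    """A tiny hand-built count table that passes every filter rule."""
    rows = []
    for locus in ("L1", "L2"):
        q = 0.3 if locus == "L1" else 0.1
        rows.append((locus, "s1", 1 if locus == "L1" else 500, f"tag_{locus}", "egg", 0,
                     int(100 * (1 - q)), int(100 * q)))
        for day in (2, 6):
            for rep in ("R1", "R2", "R3"):
                rows.append((locus, "s1", 1 if locus == "L1" else 500, f"tag_{locus}", rep, day,
                             int(200 * (1 - q)), int(200 * q)))
    return pd.DataFrame(rows, columns=sd.COUNT_COLUMNS)
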