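import numpy as np
import pandas as pd
import pytest

from molbench import SyntheticSpec, generate_activity_dataset


@pytest.fixture(scope="session")
def small_activity():
    """A small scaffold-grouped activity dataset with planted cliffs and
    edge groups; noiseless, so the ground truth is exact."""
    spec = SyntheticSpec(
        n_scaffolds=40,
        ac_scaffold_fraction=0.1,
        edge_group_fraction=0.1,
        seed=7,
        name="small",
    )
    return generate_activity_dataset(spec)


@pytest.fixture(scope="session")
def activity_table():
    """A raw activity table (SMILES + nM potencies) exercising curation rules."""
    rows = [
        # exact duplicate pair
        {"smiles": "CCO", "value": 1000.0, "relation": "=", "measure": "IC50"},
        {"smiles": "OCC", "value": 1000.0, "relation": "=", "measure": "IC50"},
        # contradictory molecule: pIC50 5.0 vs 7.5
        {"smiles": "c1ccccc1O", "value": 10000.0, "relation": "=", "measure": "Ki"},
        {"smiles": "Oc1ccccc1", "value": 10.0**1.5, "relation": "=", "measure": "Ki"},
        # aggregable pair: span 0.5 -> median
        {"smiles": "Cc1ccccc1", "value": 100.0, "relation": "=", "measure": "IC50"},
        {"smiles": "Cc1ccccc1", "value": 100.0 * 10**0.5, "relation": "=", "measure": "EC50"},
        # plain single measurements
        {"smiles": "CCN", "value": 50.0, "relation": "=", "measure": "Kd"},
        {"smiles": "c1ccncc1", "value": 5.0, "relation": "=", "measure": "IC50"},
    ]
    df = pd.DataFrame(rows)
    df["pic50"] = 9.0 - np.log10(df["value"])
    return df
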