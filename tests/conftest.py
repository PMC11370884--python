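import numpy as np
import pandas as pd
import pytest

import toxdescent as td


@pytest.fixture(scope="session")
def suite1():
    return td.suite1_tree()


@pytest.fixture(scope="session")
def suite2():
    return td.suite2_tree()


@pytest.fixture(scope="session")
def sim():
    """One suite-1-like simulated dataset shared across read-only tests."""
    cfg = td.suite1_like(seed=11)
    profiles, truth = td.simulate_profiles(cfg)
    return cfg, profiles, truth


def make_profiles(tree, rows, classes=None):
    """Build a ProfileMatrix from {family: {species: count}} (absent -> 0)."""
    data = {
        fam: [sp.get(l, 0) for l in tree.leaf_labels] for fam, sp in rows.items()
    }
    mat = pd.DataFrame.from_dict(data, orient="index", columns=tree.leaf_labels)
    mat.index.name = "family_id"
    cls = pd.Series(classes or "unlabeled", index=mat.index)
    return td.ProfileMatrix(mat, cls)


@pytest.fixture
def toy(suite1):
    """Three hand-made families on the 12-species tree."""
    return make_profiles(
        suite1,
        {
            "famA": {l: 1 for l in suite1.leaf_labels},
            "famB": {"Homo_sapiens": 2, "Mus_musculus": 1},
            "famC": {"Homo_sapiens": 1, "Drosophila_melanogaster": 3},
        },
        classes=["disease", "non_disease", "mixed"],
    )
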