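import numpy as np
import pandas as pd
import pytest

from locomorph import morphometrics, synthetic, treeops
from locomorph.morphometrics import MEASUREMENT_NAMES


def random_measurement_table(rng, n_specimens=12, n_species=4, classes=("a", "b")):
    """Specimen table with positive random measurements (no class structure)."""
    rows = []
    for i in range(n_specimens):
        sp = f"sp{i % n_species}"
        rows.append(
            {
                "specimen_id": f"s{i}",
                "species": sp,
                "locomotion": "terrestrial",
                **dict(zip(MEASUREMENT_NAMES, rng.uniform(0.5, 30.0, 15))),
            }
        )
    return pd.DataFrame(rows)


def gaussian_species_means(rng, n_per_class, class_means, sd=1.0, columns=None):
    """SpeciesMeans with Gaussian clusters at given class mean vectors."""
    p = len(next(iter(class_means.values())))
    columns = columns or [f"m{i}" for i in range(p)]
    values, labels, names = [], [], []
    for cls, mu in class_means.items():
        for i in range(n_per_class):
            values.append(np.asarray(mu) + sd * rng.standard_normal(p))
            labels.append(cls)
            names.append(f"{cls}_{i}")
    vals = pd.DataFrame(values, index=names, columns=columns)
    return morphometrics.SpeciesMeans(
        values=vals,
        n=pd.Series(1, index=names),
        locomotion=pd.Series(labels, index=names),
        columns=tuple(columns),
    )


@pytest.fixture(scope="session")
def small_bundle():
    """One moderate synthetic dataset reused across tests."""
    cfg = synthetic.SimConfig(n_species=48, seed=3, fossil_fraction=0.1)
    return synthetic.simulate_dataset(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def balanced_tree():
    return treeops.tree_from_newick("((A:1,B:1):1,(C:1,D:1):1);")
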