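import numpy as np
import pandas as pd
import pytest

import plastiqtl as pq
from plastiqtl import phenotypes as phen_mod


@pytest.fixture(scope="session")
def small_map():
    """Two chromosomes, markers every 5 cM."""
    return pq.make_map([40.0, 30.0], 5.0)


@pytest.fixture(scope="session")
def study_map():
    """Five chromosomes with the study's terminal positions, 2 cM spacing."""
    return pq.make_map([100.0, 70.0, 80.0, 80.0, 100.0], 2.0)


@pytest.fixture(scope="session")
def small_genotypes(small_map):
    return pq.simulate_ril_genotypes(small_map, 60, seed=11)


@pytest.fixture()
def balanced_dataset():
    """2 genotypes x 2 treatments x 2 replicates, hand-chosen values."""
    rows = []
    values = {
        ("g1", "control", "r1"): [10.0, 5.0],
        ("g1", "control", "r2"): [11.0, 5.5],
        ("g1", "SA", "r1"): [14.0, 5.2],
        ("g1", "SA", "r2"): [15.0, 5.8],
        ("g2", "control", "r1"): [8.0, 7.0],
        ("g2", "control", "r2"): [9.0, 7.4],
        ("g2", "SA", "r1"): [10.0, 7.1],
        ("g2", "SA", "r2"): [11.5, 7.6],
    }
    meta = []
    for (g, t, r), vals in values.items():
        sample = f"{g}_{t}_{r}"
        rows.append(pd.Series(vals, index=["tx1", "tx2"], name=sample))
        meta.append({"sample": sample, "genotype": g, "treatment": t,
                     "replicate": r})
    return pq.ExpressionDataset(pd.DataFrame(rows),
                                pd.DataFrame(meta).set_index("sample"))


@pytest.fixture(scope="session")
def simulated_run(study_map):
    """A seeded mid-size simulation shared by scan/classify tests."""
    geno = pq.simulate_ril_genotypes(study_map, 210, seed=5)
    arch = pq.plant_architecture(
        study_map, 120,
        pq.ArchitectureConfig(n_cis=15, n_trans=15,
                              hotspots=[("2", 48.0, 25)],
                              opposing_fraction=0.0, min_effect=0.5),
        seed=6)
    ds = pq.simulate_expression(geno, arch, 2, seed=7, include_parents=True)
    phen = phen_mod.build_phenotypes(ds)
    return {"map": study_map, "geno": geno, "arch": arch, "dataset": ds,
            "phenotypes": phen}
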