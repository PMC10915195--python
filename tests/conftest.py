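import warnings

import numpy as np
import pandas as pd
import pytest

import ssgwas as sg
from ssgwas.io import PedigreeTable, PhenotypeTable


@pytest.fixture(autouse=True)
def _quiet_convergence_warnings():
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="REML did not converge")
        yield


@pytest.fixture
def trio_pedigree():
    """Sire and dam founders plus one offspring."""
    bf = pd.DataFrame({"holstein": [1.0, 0.625, 0.8125], "other": [0.0, 0.375, 0.1875]},
                      index=pd.Index(["s", "d", "o"], name="animal"))
    return PedigreeTable(["s", "d", "o"], ["0", "0", "s"], ["0", "0", "d"], bf)


def random_pedigree(rng, n_max=30):
    """Random acyclic pedigree: each animal's parents drawn from earlier ones."""
    n = int(rng.integers(3, n_max + 1))
    animals = [f"a{i}" for i in range(n)]
    sires, dams = [], []
    for i in range(n):
        if i < 2 or rng.random() < 0.3:
            sires.append("0")
            dams.append("0")
        else:
            s, d = rng.choice(i, size=2, replace=True)
            sires.append(animals[s])
            dams.append(animals[d])
    bf = pd.DataFrame({"holstein": np.ones(n)}, index=pd.Index(animals, name="animal"))
    return PedigreeTable(animals, sires, dams, bf)


@pytest.fixture(scope="session")
def small_sim():
    """One moderate synthetic dataset shared by read-only tests."""
    spec = sg.SimulationSpec(
        n_sires=10, n_dams=20, n_bulls_phenotyped=40, records_per_bull=6,
        n_genotyped_bulls=25, n_genotyped_dams=5, n_chromosomes=2,
        markers_per_chromosome=80, n_contemporary_groups=8, seed=42)
    return sg.simulate_dataset(spec)


def make_phenotypes(values, animals, traits=("T1", "T2", "T3")):
    """Minimal phenotype table around given trait values (no covariate signal)."""
    values = np.asarray(values, dtype=float)
    n = len(values)
    df = pd.DataFrame(values, columns=list(traits))
    df.insert(0, "animal", animals)
    df["contemporary_group"] = "cg1"
    df["ejaculate_order"] = "1"
    df["age_months"] = 36.0
    df["ambient_temp_C"] = 28.0
    df["heterozygosity"] = 0.0
    return PhenotypeTable(df, list(traits))
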