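"""Shared fixtures: toy pedigrees, a random-pedigree factory, and a couple
of session-scoped simulated fits reused across property tests (Gibbs runs
are the expensive part of this suite)."""

import numpy as np
import pytest

from threshped import (ChainConfig, ModelSpec, Pedigree, PedigreeEntry,
                       SimulationTruth, gibbs_fit, simulate_dataset)


def make_random_pedigree(seed: int, n: int = 50) -> Pedigree:
    """Multi-generation random pedigree with consistent sexes (males only
    ever sires, females only ever dams)."""
    rng = np.random.default_rng(seed)
    sexes = ["M" if rng.random() < 0.5 else "F" for _ in range(n)]
    entries = []
    for i in range(n):
        males = [j for j in range(i) if sexes[j] == "M"]
        females = [j for j in range(i) if sexes[j] == "F"]
        sire = dam = ""
        if males and rng.random() < 0.7:
            sire = f"A{rng.choice(males)}"
        if females and rng.random() < 0.7:
            dam = f"A{rng.choice(females)}"
        entries.append(PedigreeEntry(f"A{i}", sire, dam, sexes[i],
                                     2000 + i // 10))
    return Pedigree(entries)


@pytest.fixture
def trio_pedigree():
    return Pedigree([
        PedigreeEntry("C", "A", "B"),
        PedigreeEntry("A", sex="M"),
        PedigreeEntry("B", sex="F"),
    ])


@pytest.fixture
def fullsib_mating_pedigree():
    """Founders A, B; full sibs C, D; E = C x D (inbred, F = 0.25)."""
    return Pedigree([
        PedigreeEntry("A", sex="M"),
        PedigreeEntry("B", sex="F"),
        PedigreeEntry("C", "A", "B", "M"),
        PedigreeEntry("D", "A", "B", "F"),
        PedigreeEntry("E", "C", "D"),
    ])


@pytest.fixture
def halfsib_mating_pedigree():
    """C and D share sire A only; E = C x D has F = 0.125."""
    return Pedigree([
        PedigreeEntry("A", sex="M"),
        PedigreeEntry("B", sex="F"),
        PedigreeEntry("B2", sex="F"),
        PedigreeEntry("C", "A", "B", "M"),
        PedigreeEntry("D", "A", "B2", "F"),
        PedigreeEntry("E", "C", "D"),
    ])


@pytest.fixture(scope="session")
def fit_h2_06():
    """Univariate 7-category fit on ~1,650 dogs simulated at h2 = 0.6."""
    truth = SimulationTruth.from_heritabilities(0.6, trait="hip", seed=1)
    ds = simulate_dataset(truth)
    chain = gibbs_fit(ds.pedigree, ds.records,
                      spec=ModelSpec(traits=("hip",)),
                      chain=ChainConfig(total_iterations=6000, burn_in=1500,
                                        thin=5, seed=1))
    return ds, chain


@pytest.fixture(scope="session")
def fit_bivariate_small():
    """Small bivariate fit used for sample-wise invariant checks."""
    truth = SimulationTruth.from_heritabilities(
        (0.5, 0.3), r_g=0.4, r_he=0.2, seed=2,
        n_founders=120, n_generations=3, n_sires=25, n_dams=60,
        offspring_per_dam=3)
    ds = simulate_dataset(truth)
    chain = gibbs_fit(ds.pedigree, ds.records, spec=ModelSpec(),
                      chain=ChainConfig(total_iterations=3000, burn_in=1000,
                                        thin=4, seed=2))
    return ds, chain
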