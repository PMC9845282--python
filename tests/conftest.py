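import numpy as np
import pandas as pd
import pytest

from sibstep import (
    ModelSpec,
    drop_genes,
    make_kinship_inverse,
    reduced_config,
    simulate_pedigree,
    simulate_phenotypes,
)
from sibstep.mixed_model import build_design


def small_config(seed: int, **overrides):
    """A miniature breeding design that keeps every structural feature
    (three cohorts, semi-nested matings, family rearing) but runs in
    milliseconds."""
    base = dict(
        families_per_generation=(8, 7, 4),
        offspring_mean=12.0,
        n_snp=60,
        n_qtl=15,
        genotyped_families=4,
        genotyped_individuals=30,
    )
    base.update(overrides)
    return reduced_config(seed=seed, **base)


@pytest.fixture(scope="session")
def small_sim():
    """One small simulated dataset shared by read-only tests."""
    cfg = small_config(seed=42)
    ped = simulate_pedigree(cfg)
    geno, truth = drop_genes(ped, cfg)
    pheno = simulate_phenotypes(ped, truth, cfg)
    return cfg, ped, geno, truth, pheno


@pytest.fixture(scope="session")
def small_mme(small_sim):
    """Design matrices + A-inverse for the small dataset."""
    cfg, ped, geno, truth, pheno = small_sim
    design = build_design(pheno, ModelSpec(), ped)
    K_inv, logdet_K, _ = make_kinship_inverse(ped)
    y = pheno["tag_weight_g"].to_numpy(float)
    return ped, pheno, design, K_inv, logdet_K, y


@pytest.fixture()
def trio_frame():
    """Two founders and one offspring."""
    return pd.DataFrame(
        {
            "animal_id": ["s", "d", "o"],
            "sire_id": ["0", "0", "s"],
            "dam_id": ["0", "0", "d"],
        }
    )


def rng(seed=0):
    return np.random.default_rng(seed)
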