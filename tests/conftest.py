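import numpy as np
import pandas as pd
import pytest

from pathassoc.simulate import CausalPathway, SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def null_cohort():
    """Small cohort with no planted effects, some missingness and injected
    case-only variants."""
    cfg = SimulationConfig(
        n_cases=120,
        n_controls=140,
        n_genes=20,
        n_pathways=4,
        variants_per_gene=12,
        missing_rate=0.01,
        caseonly_injection=5,
        caseonly_carrier_counts=(5, 4, 1, 2, 2),
        seed=11,
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def causal_cohort():
    """Cohort with a planted effect in one pathway (liability model)."""
    cfg = SimulationConfig(
        n_cases=300,
        n_controls=300,
        n_genes=20,
        n_pathways=4,
        variants_per_gene=15,
        maf_spectrum=("beta", 2.0, 2.0),  # common-variant architecture
        causal_pathways=(
            CausalPathway(pathway_id="hsa04000", lnor_mean=0.5, fraction_causal=0.3),
        ),
        seed=23,
    )
    return simulate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def balanced_genotypes(rng, n, mafs):
    """Genotypes plus a shuffled balanced case/control labelling."""
    G = rng.binomial(2, np.asarray(mafs), size=(n, len(mafs))).astype(float)
    y = np.zeros(n)
    y[: n // 2] = 1
    rng.shuffle(y)
    return G, y
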