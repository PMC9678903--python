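"""Shared fixtures: small synthetic datasets reused across test modules."""

import numpy as np
import pandas as pd
import pytest

from exwas import (
    CovariateTable,
    ExposomeTable,
    ExposureVariable,
    PlantedEffect,
    generate_dataset,
    mini_scenario,
)


@pytest.fixture(scope="session")
def planted_mini():
    """Mini cohort with latent factors and a handful of planted effects."""
    scenario = mini_scenario(
        seed=11,
        n_latent_factors=2,
        planted_effects=[
            PlantedEffect("metals_01_chil", "childhood", "expression_0005", "expression", 0.5),
            PlantedEffect("metals_01_chil", "childhood", "protein_0003", "protein", 0.6),
            PlantedEffect("organochlorines_00_chil", "childhood", "protein_0003", "protein", 0.5),
            PlantedEffect("metals_00_preg", "pregnancy", "methylation_0001", "methylation", 1.5),
            PlantedEffect("diet_01_chil", "childhood", "serum_metab_0000", "serum_metab", 0.8),
        ],
    )
    return scenario, generate_dataset(scenario)


@pytest.fixture(scope="session")
def null_mini():
    """Mini cohort with no planted effects and no latent factors."""
    scenario = mini_scenario(seed=23, n_latent_factors=0)
    return scenario, generate_dataset(scenario)


@pytest.fixture
def toy_exposome():
    """Six samples, one continuous and one categorical exposure."""
    samples = [f"s{i}" for i in range(6)]
    values = pd.DataFrame(
        {
            "hg": [0.1, 0.5, 0.9, 1.4, 2.0, 2.5],
            "smoking": ["no", "yes", "no", "no", "yes", "no"],
        },
        index=samples,
    )
    variables = [
        ExposureVariable("hg", "childhood", "metals"),
        ExposureVariable("smoking", "pregnancy", "tobacco", "categorical", ("no", "yes")),
    ]
    return ExposomeTable(values, variables)


@pytest.fixture
def toy_covariates():
    rng = np.random.default_rng(5)
    n = 6
    return CovariateTable(
        pd.DataFrame(
            {
                "cohort": ["a", "a", "b", "b", "a", "b"],
                "sex": ["female", "male"] * 3,
                "age": rng.uniform(6, 11, n),
                "zbmi": rng.normal(0, 1, n),
                "ancestry": ["european"] * n,
                "maternal_education": ["low", "medium", "high"] * 2,
            },
            index=[f"s{i}" for i in range(n)],
        )
    )
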