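import numpy as np
import pandas as pd
import pytest

from pathprs import (
    DosageMatrix,
    PhenotypeTable,
    SimulationConfig,
    VariantTable,
    default_true_weights,
    default_variant_table,
    simulate_cohorts,
)


def make_variants(rows) -> VariantTable:
    """rows: (variant_id, beta, maf, apoe_flag) tuples on a toy panel."""
    return VariantTable(
        pd.DataFrame(
            [
                {
                    "variant_id": vid,
                    "chrom": "1",
                    "pos": 1000 + i,
                    "effect_allele": "A",
                    "other_allele": "G",
                    "beta": beta,
                    "maf": maf,
                    "apoe_flag": apoe,
                    "locus_label": f"L{i}",
                }
                for i, (vid, beta, maf, apoe) in enumerate(rows)
            ]
        )
    )


def make_dosages(subject_ids, variant_ids, values, missing=None) -> DosageMatrix:
    values = np.asarray(values, dtype=float)
    if missing is None:
        missing = np.zeros_like(values, dtype=bool)
    return DosageMatrix(list(subject_ids), list(variant_ids), values, missing)


def make_phenotypes(subject_ids, cohorts, sexes=None, rng_seed=0) -> PhenotypeTable:
    rng = np.random.default_rng(rng_seed)
    n = len(subject_ids)
    if sexes is None:
        sexes = ["female" if i % 2 else "male" for i in range(n)]
    df = pd.DataFrame(
        {
            "subject_id": subject_ids,
            "cohort": cohorts,
            "sex": sexes,
            "age": 60.0 + rng.random(n),
        }
    )
    for i in range(1, 6):
        df[f"pc{i}"] = rng.normal(size=n)
    return PhenotypeTable(df)


@pytest.fixture(scope="session")
def panel() -> VariantTable:
    return default_variant_table()


@pytest.fixture(scope="session")
def true_weights():
    return default_true_weights()


@pytest.fixture(scope="session")
def small_study():
    """A modest synthetic three-cohort study shared across tests."""
    config = SimulationConfig(
        n_population=500, n_case=500, n_centenarian=120, seed=11
    )
    return config, simulate_cohorts(config)
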