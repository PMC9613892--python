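import warnings

import numpy as np
import pandas as pd
import pytest

from pdprog.genetics import GenotypeData
from pdprog.synthetic import (N_ITEMS, PART_NAMES, LongitudinalCohort,
                              SimConfig, generate_cohort)


@pytest.fixture(scope="session")
def small_cohort():
    """One 250-subject cohort + genotypes shared across read-only tests."""
    cohort, geno = generate_cohort(SimConfig(n_subjects=250, seed=7))
    return cohort, geno


@pytest.fixture(scope="session")
def medium_cohort():
    """A 1500-subject cohort for tests that need planted-effect power."""
    cohort, geno = generate_cohort(SimConfig(n_subjects=1500, seed=17))
    return cohort, geno


def make_toy_cohort(part_values: dict, treated: dict | None = None
                    ) -> LongitudinalCohort:
    """Build a minimal valid cohort from explicit subpart sums.

    ``part_values``: {participant_id: {month: (sum_i, sum_ii, sum_iii)}}.
    The whole subpart sum is placed on item 01 so the item-sum invariant
    holds trivially.
    """
    treated = treated or {}
    rows = []
    for pid, months in part_values.items():
        for month, sums in months.items():
            row = {"participant_id": pid, "visit_month": month}
            total = 0
            for p, n, s in zip(PART_NAMES, N_ITEMS, sums):
                for k in range(1, n + 1):
                    row[f"mds_updrs_{p}_item_{k:02d}"] = s if k == 1 else 0
                row[f"mds_updrs_{p}_summary_score"] = s
                total += s
            row["mds_updrs_total_score"] = total
            rows.append(row)
    visits = pd.DataFrame(rows)
    subjects = pd.DataFrame({
        "participant_id": list(part_values),
        "treated_any": [int(treated.get(p, 0)) for p in part_values],
    })
    return LongitudinalCohort(subjects=subjects, visits=visits)


def make_genotypes(dosages: np.ndarray, ref: str = "A", alt: str = "G",
                   chrom: int = 1) -> GenotypeData:
    """GenotypeData from a raw (subjects x variants) array."""
    n, p = dosages.shape
    variants = pd.DataFrame({
        "variant_id": [f"v{j}" for j in range(p)],
        "chrom": chrom, "pos": np.arange(1, p + 1) * 1000,
        "ref": ref, "alt": alt})
    df = pd.DataFrame(dosages,
                      index=pd.Index([f"S{i}" for i in range(n)],
                                     name="participant_id"),
                      columns=variants["variant_id"].tolist())
    return GenotypeData(df, variants)


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("always")
        yield
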