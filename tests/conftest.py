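import numpy as np
import pandas as pd
import pytest

from cryptaxon.core import GenotypeMatrix, VariantTable


def make_variants(n, contig="3R", spacing=100, ref="A", alt="T"):
    pos = np.arange(1, n + 1, dtype=np.int64) * spacing
    return VariantTable([contig] * n, pos, [ref] * n, [alt] * n, [True] * n)


def gm_from_calls(calls):
    calls = np.asarray(calls, dtype=np.int8)
    ids = [f"s{i}" for i in range(calls.shape[1])]
    return GenotypeMatrix(calls, ids)


@pytest.fixture(scope="session")
def study_scenario():
    """The standard three-taxa study fixture shared by the slower tests."""
    from cryptaxon.synthetic import AdmixtureSpec, three_taxa_scenario

    return three_taxa_scenario(
        seed=20260926,
        n_variants=50_000,
        cohort_size=60,
        admixed=AdmixtureSpec("BIS", "CO", 0.5),
        admixed_size=40,
    )


@pytest.fixture(scope="session")
def scenario_cohorts(study_scenario):
    return {
        name: grp["sample_id"].tolist()
        for name, grp in study_scenario.samples.groupby("cohort")
    }
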