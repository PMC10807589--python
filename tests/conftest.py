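import numpy as np
import pandas as pd
import pytest

from crcrisk.cohort import (
    ClinicalRecord,
    Cohort,
    Group,
    VariantClass,
    VariantRecord,
)


def make_variant(sample="S1", gene="TP53", chrom="chr17", pos=100, ref="C", alt="T",
                 vclass=VariantClass.MISSENSE, protein_pos=None, context3=None):
    return VariantRecord(
        sample_id=sample, gene=gene, chrom=chrom, pos=pos, ref=ref, alt=alt,
        variant_class=vclass, protein_pos=protein_pos, context3=context3,
    )


def make_cohort(matrix: pd.DataFrame, groups: dict[str, str],
                tmb=None, tmb_high=None, msi_h=None) -> Cohort:
    """Hand-assemble a cohort from a binary matrix and group labels."""
    ids = list(matrix.index)
    clinical = [
        ClinicalRecord(sample_id=s, group=Group(groups[s]), msisensor_score=0.0)
        for s in ids
    ]
    flags = pd.DataFrame(
        {
            "tmb": tmb if tmb is not None else [1.0] * len(ids),
            "tmb_high": tmb_high if tmb_high is not None else [False] * len(ids),
            "msi_h": msi_h if msi_h is not None else [False] * len(ids),
            "pole_exo": [False] * len(ids),
        },
        index=ids,
    )
    return Cohort(clinical=clinical, mutation_matrix=matrix.astype(np.int8), flags=flags)


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort shared across read-only tests."""
    from crcrisk.simulate import simulate_cohort

    cohort, truth = simulate_cohort(seed=123)
    return cohort, truth


@pytest.fixture(scope="session")
def confounder_cohort():
    from crcrisk.simulate import SimulationParams, simulate_cohort

    params = SimulationParams(penalty_confounder=True)
    cohort, truth = simulate_cohort(params, seed=123)
    return cohort, truth
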