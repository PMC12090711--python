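import numpy as np
import pytest

from pgscreen import OgFamily, PhenotypeGroups


@pytest.fixture
def worked_fam() -> OgFamily:
    """Four-strain family with two divergent allele pairs (hand-checkable)."""
    return OgFamily(
        "og_demo",
        {"s1": "AAAA", "s2": "AAAT", "s3": "GGGG", "s4": "GGGT"},
        aligned=True,
    )


@pytest.fixture
def worked_groups() -> PhenotypeGroups:
    """Phenotype split aligned with the worked family's allele clusters."""
    return PhenotypeGroups(
        species="L_plantarum",
        cytokine="IL10",
        median=1.0,
        active=frozenset({"s1", "s2"}),
        silent=frozenset({"s3", "s4"}),
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
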