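import pandas as pd
import pytest

from exotriage.simulate import (
    candidate_recovery_config, default_config, simulate_cohort,
)

#: pooled allele-count tables of the four basement-membrane/junction genes
#: (case ref, case alt, control ref, control alt) with their published
#: odds ratios at 6 d.p.
BURDEN_TABLES = {
    "CDH1": ((2199, 721, 15703, 2461), 2.092093),
    "ITGB4": ((6911, 3129, 70734, 15974), 2.004838),
    "LAMA3": ((6048, 1712, 56560, 8570), 1.868188),
    "LAMB3": ((2524, 1356, 19589, 6683), 1.574748),
}

#: (term_id, description, observed, background count, published strength)
#: for a 12-gene query against a 19,566-gene universe
ENRICHMENT_ROWS = [
    ("GO:0034329", "Cell junction assembly", 4, 280, 1.37),
    ("GO:0030198", "Extracellular matrix organization", 5, 338, 1.38),
    ("GO:0005604", "Basement membrane", 3, 96, 1.71),
    ("GOCC:0005610", "laminin-5 complex", 2, 7, 2.67),
    ("KW-0272", "Extracellular matrix", 4, 265, 1.39),
]


@pytest.fixture(scope="session")
def default_data():
    """Study-structured synthetic cohort (20/100, 12 panel genes, 13 planted)."""
    return simulate_cohort(default_config(seed=11))


@pytest.fixture(scope="session")
def recovery_data():
    """Scenario where the 13 planted candidates are the only rare
    MODERATE/HIGH variation in panel genes."""
    return simulate_cohort(candidate_recovery_config(seed=11))


@pytest.fixture()
def annotation_row():
    """A minimal annotation mapping for prioritizer tests."""
    def _make(**overrides):
        row = {
            "variant_key": "1:100:C:T",
            "effect": "missense_variant",
            "cadd": 25.0,
            "clinical_sig": None,
        }
        row.update(overrides)
        return row
    return _make
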