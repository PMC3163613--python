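import pytest

from sscount import (
    DICE_FR_DESIGN,
    MEPHEDRONE_BASELINE_PROBS,
    FRResponseSet,
    SSCDesign,
    SSCResponseSet,
)

#: Per-category respondent counts of the pilot SSC item (469 affirmatives
#: from 237 respondents).
MEPHEDRONE_COUNTS = {0: 15, 1: 64, 2: 89, 3: 51, 4: 16, 5: 2}


@pytest.fixture(scope="session")
def ssc_pilot() -> SSCResponseSet:
    return SSCResponseSet.from_counts(MEPHEDRONE_COUNTS, m=4)


@pytest.fixture(scope="session")
def fr_pilot() -> FRResponseSet:
    return FRResponseSet(n_yes=74, n=318)


@pytest.fixture(scope="session")
def equal_design() -> SSCDesign:
    return SSCDesign.equal(m=4)


@pytest.fixture(scope="session")
def general_design() -> SSCDesign:
    return SSCDesign(m=4, probs=MEPHEDRONE_BASELINE_PROBS)


@pytest.fixture(scope="session")
def dice_design():
    return DICE_FR_DESIGN
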