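"""Packaged example datasets: the mephedrone pilot survey.

A 318-respondent UK pilot study of recent mephedrone use answered both
designs: 237 respondents completed the 4+1 Single Sample Count item
(469 affirmative answers in total; category counts reconstructed from the
published observed category proportions) and all 318 answered the
two-dice Forced Response item (74 'yes'). Both ship as CSV fixtures so
every worked example runs offline.
"""

from __future__ import annotations

from importlib import resources

from .designs import (
    DICE_FR_DESIGN,
    MEPHEDRONE_BASELINE_PROBS,
    FRDesign,
    FRResponseSet,
    SSCDesign,
    SSCResponseSet,
)

__all__ = [
    "data_path",
    "load_mephedrone_ssc",
    "load_mephedrone_fr",
    "mephedrone_ssc_design",
    "mephedrone_fr_design",
]

#: Per-category respondent counts of the SSC item (totals 0..5).
MEPHEDRONE_SSC_COUNTS = {0: 15, 1: 64, 2: 89, 3: 51, 4: 16, 5: 2}


def data_path(name: str):
    """Filesystem path of a packaged data file."""
    return resources.files("sscount").joinpath("data", name)


def load_mephedrone_ssc() -> SSCResponseSet:
    """The SSC arm of the mephedrone pilot: n = 237, 469 affirmatives."""
    from .io import read_responses

    with resources.as_file(data_path("mephedrone_ssc.csv")) as path:
        return read_responses(path, model="ssc", m=4)


def load_mephedrone_fr() -> FRResponseSet:
    """The FR arm of the mephedrone pilot: 74 'yes' of 318."""
    from .io import read_responses

    with resources.as_file(data_path("mephedrone_fr.csv")) as path:
        return read_responses(path, model="fr")


def mephedrone_ssc_design(general: bool = False) -> SSCDesign:
    """The pilot's 4+1 design; ``general=True`` uses the empirically
    estimated innocuous probabilities instead of the equal 0.5s."""
    if general:
        return SSCDesign(m=4, probs=MEPHEDRONE_BASELINE_PROBS)
    return SSCDesign.equal(m=4)


def mephedrone_fr_design() -> FRDesign:
    """The pilot's two-dice Forced Response device."""
    return DICE_FR_DESIGN
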