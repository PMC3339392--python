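"""Shared fixtures: compiled resources and worked-example passages."""

import pytest

from lignominer.pipeline import Resources, load_resources

# Worked-example sentences from the enzyme-characterization literature used
# throughout the tests (temperature/pH profile reporting and an enzyme
# purification passage with an author-coined abbreviation).
TEMPERATURE_SENTENCE = (
    "The purified enzyme exhibited maximum activity at 55°C, with 84% relative "
    "activity at 60°C and 29% activity at 70°C under the assay conditions used."
)
PH_SENTENCE = (
    "The enzyme displayed an optimum activity at pH 5.0 and retained 80% "
    "activity at pH 3.0 and also at pH 8.0."
)
EG_PASSAGE = (
    "The extracellular endoglucanase (EG) was purified to homogeneity from the "
    "culture supernatant by ethanol precipitation (75%, v/v), CM Bio-Gel A column "
    "chromatography, and Bio-Gel A-0.5 m gel filtration. The purified EG "
    "(specific activity 43.33 U/mg protein) was a monomeric protein with a "
    "molecular weight of 27 000."
)
STABILITY_SENTENCE = (
    "The enzyme stability at different pH values was measured by the residual "
    "activity after the enzyme was incubated at 25°C for 3 h."
)


@pytest.fixture(scope="session")
def resources() -> Resources:
    return load_resources()
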