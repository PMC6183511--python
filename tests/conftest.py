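import pytest
from hypothesis import settings

from raricount import CountSession, TaxonConfig

settings.register_profile("suite", max_examples=50, deadline=None, derandomize=True)
settings.load_profile("suite")


@pytest.fixture
def taxa():
    return [
        TaxonConfig("Antarctissa", "strelkovi", button=True, button_label="As"),
        TaxonConfig("Antarctissa", "denticulata", button=True, button_label="Ad"),
        TaxonConfig("Cycladophora", "davisiana", button=False, category="Plagiacanthidae"),
        TaxonConfig("Lithomelissa", "setosa", button=False, category="Plagiacanthidae"),
    ]


@pytest.fixture
def session(taxa):
    return CountSession(taxa, sample_metadata={"Sample": "test"})


@pytest.fixture
def o_metadata():
    return {
        "Fossil group": "radiolarians",
        "Observer": "test observer",
        "Site": "751",
        "Hole": "A",
        "Sample": "751A-6H-6",
        "Core": "6H",
        "Section": "6",
        "Interval (cm)": "98-100",
    }
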