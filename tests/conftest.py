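import pytest

from briefminer import analyze_corpus, default_config
from briefminer.synthetic import generate_corpus, paper_default


@pytest.fixture
def config():
    return default_config()


@pytest.fixture(scope="session")
def preset_corpus(tmp_path_factory):
    """The calibrated preset corpus, generated once per session."""
    directory = tmp_path_factory.mktemp("preset_corpus")
    truth = generate_corpus(paper_default(), directory)
    return directory, truth


@pytest.fixture(scope="session")
def preset_result(preset_corpus):
    """Full pipeline run on the clean preset corpus."""
    directory, _ = preset_corpus
    return analyze_corpus(directory)


@pytest.fixture(scope="session")
def typo_corpus(tmp_path_factory):
    """Preset corpus with one injected edit per keyword occurrence."""
    directory = tmp_path_factory.mktemp("typo_corpus")
    truth = generate_corpus(paper_default(typo_rate=1.0), directory)
    return directory, truth


@pytest.fixture(scope="session")
def typo_result(typo_corpus):
    directory, _ = typo_corpus
    return analyze_corpus(directory)
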