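import pytest

from scribe_audit import GeneratorConfig, generate_corpus, write_corpus


@pytest.fixture(scope="session")
def small_corpus():
    """30 synthetic encounters with ground truth (fixed seed)."""
    return generate_corpus(GeneratorConfig(n_encounters=30, seed=7))


@pytest.fixture()
def corpus_dir(tmp_path, small_corpus):
    """The small corpus written out; returns (manifest_path, truth)."""
    encounters, truth = small_corpus
    manifest = write_corpus(encounters, truth, tmp_path / "corpus")
    return manifest, truth
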