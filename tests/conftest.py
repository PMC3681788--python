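import pytest

from ddikernels import fixtures


@pytest.fixture(scope="session")
def golden():
    """The worked-example blinded instance (distance 5, two specific drugs)."""
    return fixtures.golden_instance()


@pytest.fixture(scope="session")
def small_corpus():
    """20-sentence deterministic synthetic corpus with parses and snapshot."""
    config = fixtures.SyntheticConfig(n_sentences=20, seed=42, noise_rate=0.0)
    records, snapshot = fixtures.generate_records(config)
    return records, snapshot


@pytest.fixture(scope="session")
def small_instances(small_corpus):
    from ddikernels.corpus_io import generate_instances

    records, _ = small_corpus
    out = []
    for rec in records:
        out.extend(generate_instances(rec))
    return out
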