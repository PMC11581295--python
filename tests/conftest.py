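import pytest

from lungbm.lexicon import default_lexicon
from lungbm.synthetic import GeneratorConfig, generate_corpus


@pytest.fixture(scope="session")
def lexicon():
    return default_lexicon()


@pytest.fixture(scope="session")
def zero_noise_corpus():
    """A noiseless synthetic corpus with its ground truth."""
    cfg = GeneratorConfig(n_cases=800, seed=11)
    reports, truths = generate_corpus(cfg)
    return cfg, reports, truths


@pytest.fixture(scope="session")
def large_truth():
    """A large corpus for marginal-recovery checks (truth side only)."""
    cfg = GeneratorConfig(n_cases=10_000, seed=1)
    reports, truths = generate_corpus(cfg)
    return cfg, reports, truths
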