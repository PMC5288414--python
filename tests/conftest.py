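import numpy as np
import pytest

from asdscreen.synthetic import CorpusSpec, FormImageSpec, generate_corpus, \
    generate_form_image


@pytest.fixture(scope="session")
def flat_form():
    """Unrotated, noise-free synthetic form with its ground truth."""
    return generate_form_image(FormImageSpec(skew_deg=0.0, noise_rate=0.0,
                                             seed=11))


@pytest.fixture(scope="session")
def skewed_form():
    """Form rotated by +3 degrees, noise-free."""
    return generate_form_image(FormImageSpec(skew_deg=3.0, noise_rate=0.0,
                                             seed=12))


@pytest.fixture(scope="session")
def small_corpus():
    """Separable 12+18 document corpus with known generating distributions."""
    spec = CorpusSpec(n_pos=12, n_neg=18, vocab_size=30, doc_length_mean=40,
                      class_divergence=6.0, n_topics_true=2, seed=21)
    return generate_corpus(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
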