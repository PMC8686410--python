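import numpy as np
import pytest

from radner.crf import CRFParameters
from radner.documents import AnnotatedDocument, EntitySpan
from radner.synthetic import GeneratorConfig, generate_corpus


@pytest.fixture(scope="session")
def small_corpus():
    """60 deterministic synthetic narratives."""
    return generate_corpus(GeneratorConfig(n_docs=60, seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_crf_instance(rng, T, K):
    """A random small emissions/parameters pair for oracle checks."""
    e = rng.normal(size=(T, K))
    p = CRFParameters(
        rng.normal(size=(K, K)), rng.normal(size=K), rng.normal(size=K)
    )
    return e, p


def make_doc(doc_id, text, spans):
    return AnnotatedDocument(
        doc_id, text, tuple(EntitySpan(s, e, t) for t, s, e in spans)
    )
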