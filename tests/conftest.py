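import numpy as np
import pytest

from cannanet.synthetic import SyntheticSpec


def topic_sentences(seed: int = 0, n: int = 400) -> list[list[str]]:
    """Toy training corpus: each distractor word owns a context vocabulary,
    while the planted synonyms 'analgesic'/'antinociceptive' share one."""
    rng = np.random.default_rng(seed)
    topics = {i: [f"ctx{i}w{j}" for j in range(6)] for i in range(6)}
    words = {
        0: ["analgesic", "antinociceptive"],
        1: ["limonene"],
        2: ["myrcene"],
        3: ["pinene"],
        4: ["sedative"],
        5: ["antioxidant"],
    }
    sents = []
    for _ in range(n):
        t = int(rng.integers(6))
        w = words[t][int(rng.integers(len(words[t])))]
        ctx = [str(c) for c in rng.choice(topics[t], size=4, replace=False)]
        pos = int(rng.integers(5))
        sents.append(ctx[:pos] + [w] + ctx[pos:])
    return sents


@pytest.fixture(scope="session")
def toy_sentences() -> list[list[str]]:
    return topic_sentences()


NULL_ENTITIES = (
    ("cbd", "chemical", 0.1),
    ("thc", "chemical", 0.1),
    ("limonene", "chemical", 0.1),
    ("myrcene", "chemical", 0.1),
    ("cbdas", "gene", 0.1),
    ("thcas", "gene", 0.1),
    ("analgesic", "property", 0.1),
    ("antiviral", "property", 0.1),
)


def null_spec(seed: int, n_docs: int = 10, paras_per_doc: int = 200) -> SyntheticSpec:
    """No planted dependence: every admissible pair is null."""
    return SyntheticSpec(
        entities=NULL_ENTITIES,
        dependent_pairs=(),
        n_docs=n_docs,
        paras_per_doc=paras_per_doc,
        seed=seed,
    )


def planted_spec(seed: int = 11, boost: float = 8.0, paras_per_doc: int = 50, n_docs: int = 100) -> SyntheticSpec:
    """One strongly dependent gene-chemical pair among independent fillers."""
    return SyntheticSpec(
        entities=(
            ("cbda", "chemical", 0.05),
            ("cbga", "chemical", 0.05),
            ("olivetolic acid", "chemical", 0.05),
            ("cbdas", "gene", 0.05),
            ("thcas", "gene", 0.05),
            ("analgesic", "property", 0.05),
        ),
        dependent_pairs=(("cbda", "cbdas", boost),),
        n_docs=n_docs,
        paras_per_doc=paras_per_doc,
        seed=seed,
    )
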