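import numpy as np
import pytest

from sspr import (
    ModelConfig,
    MolGraph,
    ProteinRecord,
    SyntheticSpec,
    build_molecular_graph,
    generate_synthetic,
)
from sspr import bayes
from sspr.mna import DescriptorSet
from sspr.pipeline import make_examples


@pytest.fixture(scope="session")
def water():
    return MolGraph.from_atoms_bonds(["H", "O", "H"], [(0, 1), (1, 2)])


@pytest.fixture(scope="session")
def methanol():
    return MolGraph.from_atoms_bonds(
        ["C", "O", "H", "H", "H", "H"],
        [(0, 1), (0, 2), (0, 3), (0, 4), (1, 5)],
    )


@pytest.fixture(scope="session")
def glycine():
    return build_molecular_graph("G")


@pytest.fixture(scope="session")
def diglycine():
    return build_molecular_graph("GG")


@pytest.fixture(scope="session")
def protein():
    return ProteinRecord(gene="SYNX", sequence="ACDEFGHIKLMNPQRSTVWY" * 3)


def random_descriptor_dataset(rng, n, vocab=12, level=5):
    """Random (DescriptorSet, label) examples over a small descriptor vocab."""
    vocabulary = [f"d{i}" for i in range(vocab)]
    examples = []
    for _ in range(n):
        size = rng.integers(1, vocab // 2 + 1)
        items = frozenset(rng.choice(vocabulary, size=size, replace=False))
        label = bayes.PATHOGENIC if rng.random() < 0.5 else bayes.BENIGN
        examples.append((DescriptorSet(level=level, items=items), label))
    # guarantee both classes with >= 2 members each
    examples[0] = (examples[0][0], bayes.PATHOGENIC)
    examples[1] = (examples[1][0], bayes.PATHOGENIC)
    examples[2] = (examples[2][0], bayes.BENIGN)
    examples[3] = (examples[3][0], bayes.BENIGN)
    return examples


@pytest.fixture(scope="session")
def synthetic_examples():
    """Descriptor-set examples from the default synthetic study conditions."""
    spec = SyntheticSpec(seed=11)
    protein, variants = generate_synthetic(spec)
    config = ModelConfig(pl=9, level=5)
    return make_examples(protein, variants, config), config


def naive_loo_scores(examples, config):
    """Retrain-from-scratch leave-one-out oracle."""
    out = []
    for i, (dset, label) in enumerate(examples):
        rest = [ex for j, ex in enumerate(examples) if j != i]
        model = bayes.fit(rest, config)
        out.append((i, bayes.score(model, dset), label))
    return out
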