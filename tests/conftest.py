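"""Shared fixtures: a toy treebank, harvested memory, lexicon and a
synthetic self-paced-reading corpus, all seeded and session-scoped."""

import warnings

import pytest

import ratparse as rp

warnings.filterwarnings("ignore", category=FutureWarning, module="arviz")


@pytest.fixture(scope="session")
def grammar():
    return rp.ToyGrammar()


@pytest.fixture(scope="session")
def train_trees(grammar):
    return [rp.prepare(t) for t in rp.read_trees(rp.toy_treebank(grammar, 200, seed=11))]


@pytest.fixture(scope="session")
def memory(train_trees):
    return rp.collect_chunks(train_trees, prepared=True)


@pytest.fixture(scope="session")
def lexicon(grammar):
    return rp.build_lexicon(grammar.lexicon_frequencies())


@pytest.fixture(scope="session")
def test_trees(grammar):
    return [rp.prepare(t) for t in rp.read_trees(rp.toy_treebank(grammar, 160, seed=12))]


@pytest.fixture(scope="session")
def spr_corpus(test_trees, memory, lexicon):
    """(table, context) at the reference true parameters F=0.014, f=0.66."""
    return rp.synth_spr_corpus(
        test_trees, memory, lexicon, true_F=0.014, true_f=0.66,
        noise_sd_ms=20.0, seed=13, n_stories=2,
    )


@pytest.fixture(scope="session")
def default_params():
    return rp.ActivationParams()
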