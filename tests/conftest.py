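"""Shared fixtures: fixture molecules, tiny encoder configs, a tiny
pre-trained checkpoint reused by the transfer-learning tests."""

import numpy as np
import pytest

import linemol as lm
from linemol.light import LiGhTConfig, LiGhTModel
from linemol.pretrain import PretrainConfig, prepare_corpus, pretrain_run


@pytest.fixture(scope="session")
def fixture_smiles():
    """200 deterministic drug-like molecules."""
    return lm.generate_fixture_molecules(200, seed=11)


@pytest.fixture(scope="session")
def small_corpus():
    """40 molecules, parsed and knowledge-annotated once per session."""
    return prepare_corpus(lm.generate_fixture_molecules(40, seed=21))


@pytest.fixture
def tiny_config():
    return LiGhTConfig(n_layers=2, hidden=32, n_heads=4, dropout=0.0, seed=0)


@pytest.fixture
def tiny_model(tiny_config):
    return LiGhTModel.init(tiny_config)


@pytest.fixture(scope="session")
def tiny_pretrained():
    """A briefly pre-trained tiny encoder (checkpointable, deterministic)."""
    smiles = lm.generate_fixture_molecules(40, seed=21)
    cfg = PretrainConfig(
        light=LiGhTConfig(n_layers=2, hidden=32, n_heads=4, dropout=0.0),
        n_steps=8, batch_size=8, lr=1e-3, seed=13,
    )
    return pretrain_run(smiles, cfg)


@pytest.fixture
def benzene_aug(small_corpus):
    g = lm.parse_smiles("c1ccccc1")
    lg = lm.to_line_graph(g)
    kv = lm.build_knowledge_vector(g, small_corpus.normalizer)
    return lm.augment_with_k_node(lg, kv.vector)
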