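import pytest

from koti import (SynthConfig, WhitespaceTokenizer, generate_corpus,
                  make_mock_backend, packaged_task, synth_task_spec)


@pytest.fixture(scope="session")
def dys_spec():
    return packaged_task("dys")


@pytest.fixture()
def tokenizer():
    return WhitespaceTokenizer()


@pytest.fixture(scope="session")
def small_cfg():
    """A small, fast synthetic corpus configuration."""
    return SynthConfig(n_notes=40, sentences_per_note=(8, 16),
                       over_budget_fraction=0.5, budget_tokens=256,
                       distractor_rate=0.1, seed=11)


def mock_setup(cfg, model_max=512, **mock_overrides):
    """Corpus + task + tokenizer + mock backend wired together."""
    corpus = generate_corpus(cfg)
    spec = synth_task_spec(cfg)
    tok = WhitespaceTokenizer()
    notes = [n.to_note() for n in corpus]
    for note in notes:
        tok.encode(note.text)
    backend = make_mock_backend(spec, tok,
                                cfg.mock_backend_config(**mock_overrides),
                                max_input=model_max)
    return corpus, notes, spec, tok, backend
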