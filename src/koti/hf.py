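"""Optional adapters for pretrained Hugging Face checkpoints.

These adapters are the only place real-model identifiers appear. They are
thin wrappers around ``transformers`` pipelines and require that optional
dependency (plus downloaded weights) at construction time; nothing in the
test suite touches them.
"""

from __future__ import annotations


class HFBackend:
    """Masked or causal scoring backed by a ``transformers`` checkpoint."""

    trainable = False

    def __init__(self, model_name: str, kind: str = "masked",
                 max_input: int = 512) -> None:
        if kind not in ("masked", "causal"):
            raise ValueError(f"kind must be masked|causal, got {kind!r}")
        try:
            import torch  # noqa: F401
            import transformers
        except ImportError as exc:
            raise ImportError(
                "hf-* backends need the optional 'transformers' and "
                "'torch' dependencies; install them to score pretrained "
                "checkpoints") from exc
        self.kind = kind
        self.max_input = max_input
        if kind == "masked":
            self._model = transformers.AutoModelForMaskedLM.from_pretrained(
                model_name)
        else:
            self._model = transformers.AutoModelForCausalLM.from_pretrained(
                model_name)
        self._model.eval()
        self.tokenizer = transformers.AutoTokenizer.from_pretrained(
            model_name)

    def score(self, pinput):
        import torch

        ids = torch.tensor([list(pinput.tokens)])
        with torch.no_grad():
            logits = self._model(input_ids=ids).logits[0]
        pos = (pinput.mask_index if self.kind == "masked"
               else ids.shape[1] - 1)
        return logits[pos].numpy()
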