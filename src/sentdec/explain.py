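"""Token attributions and the interpretability audit.

Three attribution methods share one report format: ``gradient_input``
(L2 norm of the predicted-class logit's gradient w.r.t. each token's
embedded input, elementwise-multiplied by that input),
``integrated_gradients`` (Riemann path integral from the zero-embedding
baseline, 32 steps), and ``attention`` (the pooling weights themselves).
Scores are renormalized to sum to 1 over the sequence.

The audit computes two metrics per (method, k):

* fidelity — mean relative drop of the predicted class's probability when
  the top-k attributed tokens are replaced by the reserved mask embedding,
  clamped to [0, 1];
* stability — mean Jaccard similarity between the top-k token sets before
  and after replacing a fraction rho of token positions with random
  vocabulary tokens, over R seeded repeats.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .autodiff import Tensor
from .corpus import LabeledExample
from .encoder import MASK_TOKEN, embed_batch, forward_from_embeddings
from .estimator import GatedSentimentClassifier, _pad_batch

logger = logging.getLogger("sentdec")

__all__ = ["AttributionReport", "AuditResult", "gradient_attributions",
           "top_k_tokens", "jaccard", "fidelity", "stability", "audit",
           "audit_result", "write_attribution_jsonl", "METHODS"]

METHODS = ("gradient_input", "integrated_gradients", "attention")
IG_STEPS = 32


@dataclass
class AttributionReport:
    example_id: str
    method: str
    tokens: tuple[str, ...]
    scores: np.ndarray                       # normalized, >= 0, sums to 1
    top_k: dict[int, frozenset[int]] = field(default_factory=dict)

    def __post_init__(self):
        s = np.asarray(self.scores, dtype=float)
        if np.any(s < -1e-12) or abs(s.sum() - 1.0) > 1e-6:
            raise ValueError("attribution scores must be non-negative and sum to 1")
        self.scores = s


@dataclass
class AuditResult:
    fidelity: dict[int, float]
    stability: dict[int, float]
    n_examples: int
    rho: float
    repeats: int
    seed: int


def _normalize(raw: np.ndarray) -> np.ndarray:
    raw = np.maximum(np.asarray(raw, dtype=float), 0.0)
    total = raw.sum()
    if total <= 1e-12:
        logger.warning("all-zero attribution scores; reporting uniform attribution")
        return np.full(len(raw), 1.0 / len(raw))
    return raw / total


def _input_gradient(model: GatedSentimentClassifier, X0: np.ndarray,
                    mask: np.ndarray, target_class: int) -> np.ndarray:
    X = Tensor(X0, requires_grad=True)
    frozen = {k: v.detach() for k, v in model.params_.items()}
    _, _, logits = forward_from_embeddings(X, frozen, model.config_, mask)
    logits[0, target_class].backward()
    return X.grad[0]


def gradient_attributions(model: GatedSentimentClassifier,
                          example: LabeledExample | Sequence[str],
                          method: str = "gradient_input") -> AttributionReport:
    """Per-token attribution scores for the model's predicted class."""
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}")
    tokens = tuple(example.tokens if isinstance(example, LabeledExample)
                   else example)
    example_id = (example.example_id if isinstance(example, LabeledExample)
                  else "<adhoc>")
    ids, mask = _pad_batch([tokens], model.vocab_index_)
    X0 = embed_batch(ids, model.params_, model.config_).data

    if method == "attention":
        from .autodiff import no_grad
        from .encoder import encode_batch, gated_attention_pool_batch
        with no_grad():
            H, _ = encode_batch(ids, model.params_, model.config_, mask=mask)
            alpha, _ = gated_attention_pool_batch(H, model.params_, mask=mask)
        raw = alpha.data[0]
    else:
        pred = int(model.predict([tokens])[0])
        if method == "gradient_input":
            g = _input_gradient(model, X0, mask, pred)
            raw = np.linalg.norm(g * X0[0], axis=-1)
        else:  # integrated_gradients, midpoint Riemann sum from zero baseline
            acc = np.zeros_like(X0[0])
            for i in range(IG_STEPS):
                s = (i + 0.5) / IG_STEPS
                acc += _input_gradient(model, s * X0, mask, pred)
            ig = X0[0] * acc / IG_STEPS
            raw = np.linalg.norm(ig, axis=-1)

    return AttributionReport(example_id=example_id, method=method,
                             tokens=tokens, scores=_normalize(raw))


def top_k_tokens(report: AttributionReport | np.ndarray, k: int) -> frozenset[int]:
    """Indices of the k largest scores; ties broken toward the lowest index."""
    if k < 1:
        raise ValueError("k must be >= 1")
    scores = (report.scores if isinstance(report, AttributionReport)
              else np.asarray(report, dtype=float))
    T = len(scores)
    order = sorted(range(T), key=lambda i: (-scores[i], i))
    return frozenset(order[:min(k, T)])


def jaccard(a: Iterable, b: Iterable) -> float:
    a, b = set(a), set(b)
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


def fidelity(model: GatedSentimentClassifier,
             examples: Sequence[LabeledExample | Sequence[str]],
             method: str = "gradient_input", k: int = 3) -> float:
    """Mean clamped relative confidence drop under top-k masking."""
    if k < 1:
        raise ValueError("k must be >= 1")
    drops = []
    for ex in examples:
        tokens = tuple(ex.tokens if isinstance(ex, LabeledExample) else ex)
        proba = model.predict_proba([tokens])[0]
        pred = int(np.argmax(proba))
        p0 = float(proba[pred])
        if p0 < 1e-9:
            logger.info("fidelity: skipping example with vanishing confidence")
            continue
        report = gradient_attributions(model, tokens, method)
        top = top_k_tokens(report, k)
        masked = tuple(MASK_TOKEN if i in top else t
                       for i, t in enumerate(tokens))
        p1 = float(model.predict_proba([masked])[0][pred])
        drops.append(float(np.clip((p0 - p1) / p0, 0.0, 1.0)))
    return float(np.mean(drops)) if drops else 0.0


def stability(model: GatedSentimentClassifier,
              examples: Sequence[LabeledExample | Sequence[str]],
              method: str = "gradient_input", k: int = 3, rho: float = 0.1,
              repeats: int = 10, seed: int = 0) -> float:
    """Mean Jaccard similarity of top-k sets under random token substitution."""
    if not (0.0 < rho < 1.0):
        raise ValueError("rho must lie in (0, 1)")
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    rng = np.random.default_rng(seed)
    vocab = model.vocabulary_
    sims = []
    for ex in examples:
        tokens = tuple(ex.tokens if isinstance(ex, LabeledExample) else ex)
        T = len(tokens)
        n_replace = math.ceil(rho * T)
        if n_replace >= T:
            raise ValueError(
                f"perturbation would replace all {T} tokens (rho={rho})")
        before = top_k_tokens(gradient_attributions(model, tokens, method), k)
        for _ in range(repeats):
            positions = rng.choice(T, size=n_replace, replace=False)
            perturbed = list(tokens)
            for pos in positions:
                perturbed[pos] = str(vocab[rng.integers(len(vocab))])
            after = top_k_tokens(
                gradient_attributions(model, tuple(perturbed), method), k)
            sims.append(jaccard(before, after))
    return float(np.mean(sims)) if sims else 0.0


def audit(model: GatedSentimentClassifier,
          examples: Sequence[LabeledExample],
          methods: Sequence[str] = ("gradient_input",),
          k_list: Sequence[int] = (1, 3), rho: float = 0.1,
          repeats: int = 10, seed: int = 0) -> pd.DataFrame:
    """Full methods x k cross of fidelity and stability, as a tidy table."""
    if len(examples) == 0:
        raise ValueError("audit requires a non-empty split")
    rows = []
    for method in methods:
        for k in k_list:
            rows.append({
                "method": method, "k": int(k),
                "fidelity": fidelity(model, examples, method, k),
                "stability": stability(model, examples, method, k,
                                       rho=rho, repeats=repeats, seed=seed),
                "n": len(examples), "rho": rho, "repeats": repeats,
                "seed": seed})
    return pd.DataFrame(rows)


def audit_result(model: GatedSentimentClassifier,
                 examples: Sequence[LabeledExample],
                 method: str = "gradient_input",
                 k_list: Sequence[int] = (1, 3), rho: float = 0.1,
                 repeats: int = 10, seed: int = 0) -> AuditResult:
    """One method's audit as a structured summary keyed by k."""
    table = audit(model, examples, methods=(method,), k_list=k_list,
                  rho=rho, repeats=repeats, seed=seed)
    return AuditResult(
        fidelity={int(r.k): float(r.fidelity) for r in table.itertuples()},
        stability={int(r.k): float(r.stability) for r in table.itertuples()},
        n_examples=len(examples), rho=rho, repeats=repeats, seed=seed)


def write_attribution_jsonl(model: GatedSentimentClassifier,
                            examples: Sequence[LabeledExample],
                            methods: Sequence[str], path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", encoding="utf-8") as fh:
        for ex in examples:
            for method in methods:
                report = gradient_attributions(model, ex, method)
                fh.write(json.dumps({
                    "example_id": report.example_id, "method": method,
                    "tokens": list(report.tokens),
                    "scores": [float(s) for s in report.scores]}) + "\n")
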