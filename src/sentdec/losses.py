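"""Loss terms of the training objective and their weighted composition.

Two presets mirror the two stages of the framework: the encoder-side
objective ``L = L_CE + lambda_pol*L_pol + lambda_con*L_con`` (cross-entropy,
lexicon polarity regularization, prototype contrastive loss) and the
decoupling objective
``L = L_CE + lambda_adv*L_adv + lambda_contrast*L_contrast +
lambda_attr*L_attr + lambda_align*L_align`` (domain-adversarial loss under
gradient reversal, pairwise contrastive loss, attribution-guided
regularization, cross-domain alignment). The ``full`` preset is the union of
both term sets.

Conventions: sums over tokens and pairs as each definition writes them,
means over the batch dimension, so the weights are scale-free with respect
to batch size. The adversarial term is reported as the discriminator's
cross-entropy (>= 0); gradient reversal lives in the encoder graph, not in
the reported number.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .autodiff import Tensor, as_tensor
from .corpus import SentimentLexicon
from .encoder import discriminate_domain

logger = logging.getLogger("sentdec")

__all__ = [
    "LossWeights", "LossBreakdown", "PrototypeBank",
    "cross_entropy_loss", "cross_entropy_from_logits", "polarity_loss",
    "prototype_contrastive_loss", "pairwise_contrastive_loss",
    "domain_adversarial_loss", "attribution_loss", "alignment_loss",
    "total_objective",
]

PRESETS = ("encoder", "decoupling", "full")


@dataclass(frozen=True)
class LossWeights:
    """Objective coefficients, margin m, attribution target eta, GRL scale.

    ``eta=None`` asks the trainer to use twice the uniform attribution weight
    at the mean training sequence length.
    """

    lambda_pol: float = 0.1
    lambda_con: float = 0.1
    lambda_adv: float = 1.0
    lambda_contrast: float = 0.1
    lambda_attr: float = 0.1
    lambda_align: float = 0.1
    margin: float = 1.0
    eta: float | None = None
    grl_scale: float = 1.0
    preset: str = "full"

    def __post_init__(self):
        for name in ("lambda_pol", "lambda_con", "lambda_adv", "lambda_contrast",
                     "lambda_attr", "lambda_align", "grl_scale"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")
        if self.margin <= 0:
            raise ValueError("margin must be positive")
        if self.eta is not None and not (0.0 < self.eta <= 1.0):
            raise ValueError("eta must lie in (0, 1]")
        if self.preset not in PRESETS:
            raise ValueError(f"preset must be one of {PRESETS}")


@dataclass
class LossBreakdown:
    ce: float = 0.0
    pol: float = 0.0
    con_prototype: float = 0.0
    adv: float = 0.0
    contrast_pairwise: float = 0.0
    attr: float = 0.0
    align: float = 0.0
    total: float = 0.0

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in
                ("ce", "pol", "con_prototype", "adv", "contrast_pairwise",
                 "attr", "align", "total")}


class PrototypeBank:
    """Exponential running means of per-class sentence vectors.

    The prototype for a class is initialized from the first batch that
    contains the class and thereafter updated as
    ``c <- momentum * c + (1 - momentum) * batch_mean``.
    """

    def __init__(self, n_classes: int, dim: int, momentum: float = 0.9):
        if not (0.0 <= momentum < 1.0):
            raise ValueError("momentum must lie in [0, 1)")
        self.momentum = momentum
        self.prototypes = np.zeros((n_classes, dim))
        self.counts = np.zeros(n_classes, dtype=int)

    def update(self, z: np.ndarray, labels: np.ndarray) -> None:
        for c in np.unique(labels):
            mean = z[labels == c].mean(axis=0)
            if self.counts[c] == 0:
                self.prototypes[c] = mean
            else:
                self.prototypes[c] = (self.momentum * self.prototypes[c]
                                      + (1.0 - self.momentum) * mean)
            self.counts[c] += 1

    def prototype(self, c: int) -> np.ndarray:
        if self.counts[c] == 0:
            raise ValueError(f"no prototype recorded yet for class {c}")
        return self.prototypes[c]


# ----------------------------------------------------------------- losses

def cross_entropy_loss(probabilities: Tensor | np.ndarray,
                       labels: Sequence[int]) -> Tensor:
    """Mean negative log-probability of the true class.

    Rows must lie on the probability simplex; a zero probability at the true
    label is clamped at 1e-12 with a logged warning.
    """
    p = as_tensor(probabilities)
    rowsums = p.data.sum(axis=-1)
    if np.any(np.abs(rowsums - 1.0) > 1e-4) or np.any(p.data < -1e-12):
        raise ValueError("probability rows must lie on the simplex")
    labels = np.asarray(labels, dtype=int)
    picked = p[np.arange(len(labels)), labels]
    if np.any(picked.data < 1e-12):
        logger.warning("true-label probability underflow clamped at 1e-12")
    return -(picked.clamp_min(1e-12).log().mean())


def cross_entropy_from_logits(logits: Tensor, labels: Sequence[int]) -> Tensor:
    labels = np.asarray(labels, dtype=int)
    logp = logits.log_softmax(axis=-1)
    return -(logp[np.arange(len(labels)), labels].mean())


def _lexicon_masks(token_batch: Sequence[Sequence[str]], lexicon: SentimentLexicon,
                   T: int) -> tuple[np.ndarray, np.ndarray]:
    """(indicator, polarity target), each (B, T)."""
    B = len(token_batch)
    ind = np.zeros((B, T))
    target = np.zeros((B, T))
    for i, toks in enumerate(token_batch):
        for t, tok in enumerate(toks):
            pol = lexicon.polarity(tok)
            if pol is not None:
                ind[i, t] = 1.0
                target[i, t] = pol
    return ind, target


def polarity_loss(token_scores: Tensor, token_batch: Sequence[Sequence[str]],
                  lexicon: SentimentLexicon, mode: str = "train_soft") -> Tensor:
    """Lexicon-anchored token polarity penalty.

    ``sum_t I[w_t in V_s] (score_t - p(w_t))^2`` per sequence, mean over the
    batch. ``train_soft`` uses the tanh surrogate scores as given;
    ``eval_hard`` replaces them by their hard sign.
    """
    if mode not in ("train_soft", "eval_hard"):
        raise ValueError("mode must be 'train_soft' or 'eval_hard'")
    scores = as_tensor(token_scores)
    ind, target = _lexicon_masks(token_batch, lexicon, scores.shape[-1])
    if mode == "eval_hard":
        scores = Tensor(np.sign(scores.data))
    sq = (scores - Tensor(target)) ** 2
    return (sq * Tensor(ind)).sum(axis=-1).mean()


def prototype_contrastive_loss(z_pos: Tensor, z_neg: Tensor, bank: PrototypeBank,
                               m: float, form: str = "intended") -> Tensor:
    """Prototype-anchored hinge between matched positive/negative pairs.

    intended:   mean_i max(0, m + ||z+_i - c+||^2 - ||z+_i - z-_i||^2)
    as_printed: mean_i max(0, m - ||z+_i - c+||^2 + ||z+_i - z-_i||^2)

    The intended form pulls positives toward their prototype and pushes
    positive/negative pairs at least m apart; the literal printed form (sign
    of the two squared distances exchanged) is kept selectable.
    """
    if form not in ("intended", "as_printed"):
        raise ValueError("form must be 'intended' or 'as_printed'")
    zp, zn = as_tensor(z_pos), as_tensor(z_neg)
    if zp.shape[0] == 0 or zn.shape[0] == 0:
        logger.info("prototype contrastive loss skipped: one side of the batch is empty")
        return Tensor(0.0)
    k = min(zp.shape[0], zn.shape[0])
    zp, zn = zp[np.arange(k)], zn[np.arange(k)]
    c = Tensor(bank.prototype(1))
    d_proto = ((zp - c) ** 2).sum(axis=-1)
    d_pair = ((zp - zn) ** 2).sum(axis=-1)
    if form == "intended":
        hinge = (m + d_proto - d_pair).clamp_min(0.0)
    else:
        hinge = (m - d_proto + d_pair).clamp_min(0.0)
    return hinge.mean()


def pairwise_contrastive_loss(z: Tensor, labels: Sequence[int], m: float) -> Tensor:
    """All-pairs compactness/separation hinge, normalized by the pair count."""
    z = as_tensor(z)
    labels = np.asarray(labels, dtype=int)
    B = z.shape[0]
    if B < 2:
        logger.info("pairwise contrastive loss skipped: batch of size %d", B)
        return Tensor(0.0)
    diff = z.reshape(B, 1, -1) - z.reshape(1, B, -1)
    sq = (diff ** 2).sum(axis=-1)                      # (B, B) squared distances
    iu = np.triu(np.ones((B, B)), k=1)                 # unordered pairs
    same = (labels[:, None] == labels[None, :]) * iu
    other = (labels[:, None] != labels[None, :]) * iu
    pull = (sq * Tensor(same)).sum()
    push = ((m - sq).clamp_min(0.0) * Tensor(other)).sum()
    n_pairs = B * (B - 1) / 2
    return (pull + push) * (1.0 / n_pairs)


def domain_adversarial_loss(z: Tensor, domain_labels: Sequence[int],
                            params: Mapping[str, Tensor],
                            grl_scale: float | None = None) -> Tensor:
    """Discriminator cross-entropy over domains.

    Minimizing the returned value trains the discriminator. When
    ``grl_scale`` is given, the gradient reaching the encoder through z is
    multiplied by ``-grl_scale``, so the same minimization step pushes the
    encoder toward maximal domain confusion.
    """
    domain_labels = np.asarray(domain_labels, dtype=int)
    n_domains = params["disc.W" if "disc.W" in params else "disc.W2"].shape[-1]
    if n_domains < 2:
        logger.info("adversarial term disabled: fewer than 2 domains")
        return Tensor(0.0)
    logp = discriminate_domain(as_tensor(z), params, grl_scale=grl_scale)
    return -(logp[np.arange(len(domain_labels)), domain_labels].mean())


def attribution_loss(attributions: Tensor, token_batch: Sequence[Sequence[str]],
                     lexicon: SentimentLexicon, eta: float) -> Tensor:
    """Pull attribution weight on lexicon tokens toward the target eta.

    ``sum_t I[w_t in V_s] (alpha_t - eta)^2`` per sequence, mean over the
    batch. Each attribution row must sum to 1 over its real tokens.
    """
    alpha = as_tensor(attributions)
    sums = np.array([alpha.data[i, :len(toks)].sum()
                     for i, toks in enumerate(token_batch)])
    if np.any(np.abs(sums - 1.0) > 1e-4):
        raise ValueError("attribution rows must be normalized to sum to 1")
    ind, _ = _lexicon_masks(token_batch, lexicon, alpha.shape[-1])
    return (((alpha - eta) ** 2) * Tensor(ind)).sum(axis=-1).mean()


def alignment_loss(z_a: Tensor, z_b: Tensor) -> Tensor:
    """Mean squared distance between same-sentence cross-domain renderings."""
    za, zb = as_tensor(z_a), as_tensor(z_b)
    if za.shape[0] == 0:
        logger.info("alignment loss skipped: empty pair set")
        return Tensor(0.0)
    return ((za - zb) ** 2).sum(axis=-1).mean()


# ------------------------------------------------------------- composition

def total_objective(terms: Mapping[str, Tensor | float],
                    weights: LossWeights) -> tuple[Tensor, LossBreakdown]:
    """Weighted composition per the active preset.

    ``terms`` may omit inactive components; omitted or inactive terms are
    reported as 0. Returns the differentiable total and a float breakdown.
    """

    def get(name: str) -> Tensor:
        return as_tensor(terms.get(name, 0.0))

    ce = get("ce")
    active_encoder = weights.preset in ("encoder", "full")
    active_decoupling = weights.preset in ("decoupling", "full")
    pol = get("pol") if active_encoder else Tensor(0.0)
    con = get("con_prototype") if active_encoder else Tensor(0.0)
    adv = get("adv") if active_decoupling else Tensor(0.0)
    contrast = get("contrast_pairwise") if active_decoupling else Tensor(0.0)
    attr = get("attr") if active_decoupling else Tensor(0.0)
    align = get("align") if active_decoupling else Tensor(0.0)

    total = ce
    if active_encoder:
        total = total + weights.lambda_pol * pol + weights.lambda_con * con
    if active_decoupling:
        total = (total + weights.lambda_adv * adv
                 + weights.lambda_contrast * contrast
                 + weights.lambda_attr * attr
                 + weights.lambda_align * align)

    breakdown = LossBreakdown(
        ce=float(ce.data), pol=float(pol.data), con_prototype=float(con.data),
        adv=float(adv.data), contrast_pairwise=float(contrast.data),
        attr=float(attr.data), align=float(align.data), total=float(total.data))
    return total, breakdown
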