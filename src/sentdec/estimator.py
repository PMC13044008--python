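"""Scikit-learn style estimator for domain-decoupled sentiment classification.

`GatedSentimentClassifier` wraps the gated transformer encoder, the composite
objective, and the alternating adversarial training loop behind the familiar
``fit`` / ``predict`` / ``predict_proba`` / ``transform`` surface, so the
model composes with sklearn pipelines and model selection. ``X`` is a
sequence of token sequences; optional ``domains``, ``lexicon`` and
``domain_markers`` fit-parameters activate the domain-adversarial,
polarity/attribution, and cross-domain alignment terms respectively.

Training alternates, per batch, one discriminator update (encoder frozen)
with one encoder/head update in which the adversarial term reaches the
encoder through a gradient-reversal node. The gradient-reversal scale warms
up linearly over ``grl_warmup_steps`` optimizer steps.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from . import losses as L
from .autodiff import Tensor, no_grad
from .corpus import Corpus, LabeledExample, SentimentLexicon, make_domain_pair
from .encoder import (ModelConfig, build_vocab_index,
                      discriminator_param_names, embed_batch, encode_batch,
                      encoder_param_names, forward_from_embeddings,
                      gated_attention_pool_batch, init_params,
                      predict_head_batch, token_polarity_score_batch,
                      tokens_to_ids)

logger = logging.getLogger("sentdec")

__all__ = ["GatedSentimentClassifier", "TrainingDivergedError", "Adam"]


class TrainingDivergedError(RuntimeError):
    """Raised when the objective becomes non-finite during training."""

    def __init__(self, message: str, last_params: dict | None = None):
        super().__init__(message)
        self.last_params = last_params


class Adam:
    """Adam with optional decoupled weight decay, over a dict of tensors."""

    def __init__(self, params: Mapping[str, Tensor], lr: float = 1e-2,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = dict(params)
        self.lr, self.betas, self.eps, self.weight_decay = lr, betas, eps, weight_decay
        self.m = {k: np.zeros_like(v.data) for k, v in self.params.items()}
        self.v = {k: np.zeros_like(v.data) for k, v in self.params.items()}
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g ** 2
            mhat = self.m[k] / (1 - b1 ** self.t)
            vhat = self.v[k] / (1 - b2 ** self.t)
            if self.weight_decay:
                p.data -= self.lr * self.weight_decay * p.data
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None


def _pad_batch(token_batch: Sequence[Sequence[str]],
               vocab_index: Mapping[str, int]) -> tuple[np.ndarray, np.ndarray]:
    """Pad with the reserved mask row; returns (ids (B,T), mask (B,T))."""
    B = len(token_batch)
    T = max(len(t) for t in token_batch)
    pad_id = len(vocab_index)
    ids = np.full((B, T), pad_id, dtype=np.int64)
    mask = np.zeros((B, T))
    for i, toks in enumerate(token_batch):
        ids[i, :len(toks)] = tokens_to_ids(toks, vocab_index)
        mask[i, :len(toks)] = 1.0
    return ids, mask


class GatedSentimentClassifier(BaseEstimator, ClassifierMixin):
    """Gated transformer sentiment classifier with domain decoupling.

    Parameters mirror the three ingredient groups: architecture dimensions,
    objective coefficients (with ``preset`` selecting which terms are
    active), and optimization settings. ``eta=None`` resolves to twice the
    uniform attribution weight at the mean training sequence length.

    Fitted attributes
    -----------------
    params_ : dict of named parameter tensors (encoder, head, discriminator)
    classes_ : sorted class labels seen in ``y``
    vocabulary_, vocab_index_ : token inventory backing the embedding table
    history_ : list of per-step loss-breakdown dicts
    validation_history_ : list of per-epoch validation metric dicts
    """

    def __init__(self, embed_dim: int = 32, n_layers: int = 2, n_heads: int = 2,
                 ffn_hidden: int = 64, pool_hidden: int = 16, disc_hidden: int = 16,
                 disc_linear: bool = False,
                 max_length: int = 64, dropout_rate: float = 0.0,
                 layer_norm: bool = True, positional: bool = True,
                 lambda_pol: float = 0.1, lambda_con: float = 0.1,
                 lambda_adv: float = 1.0, lambda_contrast: float = 0.1,
                 lambda_attr: float = 0.1, lambda_align: float = 0.1,
                 margin: float = 1.0, eta: float | None = None,
                 grl_scale: float = 1.0, preset: str = "full",
                 epochs: int = 10, batch_size: int = 32,
                 learning_rate: float = 1e-2, weight_decay: float = 0.0,
                 grl_warmup_steps: int = 100, disc_steps: int = 1,
                 disc_lr: float | None = None,
                 early_stop_patience: int | None = None,
                 prototype_momentum: float = 0.9, seed: int = 0):
        self.embed_dim = embed_dim
        self.n_layers = n_layers
        self.n_heads = n_heads
        self.ffn_hidden = ffn_hidden
        self.pool_hidden = pool_hidden
        self.disc_hidden = disc_hidden
        self.disc_linear = disc_linear
        self.max_length = max_length
        self.dropout_rate = dropout_rate
        self.layer_norm = layer_norm
        self.positional = positional
        self.lambda_pol = lambda_pol
        self.lambda_con = lambda_con
        self.lambda_adv = lambda_adv
        self.lambda_contrast = lambda_contrast
        self.lambda_attr = lambda_attr
        self.lambda_align = lambda_align
        self.margin = margin
        self.eta = eta
        self.grl_scale = grl_scale
        self.preset = preset
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.weight_decay = weight_decay
        self.grl_warmup_steps = grl_warmup_steps
        self.disc_steps = disc_steps
        self.disc_lr = disc_lr
        self.early_stop_patience = early_stop_patience
        self.prototype_momentum = prototype_momentum
        self.seed = seed

    # ------------------------------------------------------------- plumbing
    def _model_config(self, n_domains: int) -> ModelConfig:
        return ModelConfig(
            embed_dim=self.embed_dim, n_layers=self.n_layers, n_heads=self.n_heads,
            ffn_hidden=self.ffn_hidden, pool_hidden=self.pool_hidden,
            disc_hidden=self.disc_hidden, disc_linear=self.disc_linear,
            n_classes=2, n_domains=max(n_domains, 1),
            max_length=self.max_length, dropout_rate=self.dropout_rate,
            layer_norm=self.layer_norm, positional=self.positional, seed=self.seed)

    def _loss_weights(self, eta: float) -> L.LossWeights:
        return L.LossWeights(
            lambda_pol=self.lambda_pol, lambda_con=self.lambda_con,
            lambda_adv=self.lambda_adv, lambda_contrast=self.lambda_contrast,
            lambda_attr=self.lambda_attr, lambda_align=self.lambda_align,
            margin=self.margin, eta=eta, grl_scale=self.grl_scale,
            preset=self.preset)

    def _forward_z(self, ids: np.ndarray, mask: np.ndarray
                   ) -> tuple[Tensor, Tensor, Tensor]:
        """(final token states H, pooling weights alpha, sentence vectors z)."""
        H, _ = encode_batch(ids, self.params_, self.config_, mask=mask)
        alpha, z = gated_attention_pool_batch(H, self.params_, mask=mask)
        return H, alpha, z

    def _embedding_gradients(self, ids: np.ndarray, mask: np.ndarray
                             ) -> np.ndarray:
        """d(predicted-class logit)/d(embedded input), detached, (B, T, d)."""
        X = Tensor(embed_batch(ids, self.params_, self.config_).data,
                   requires_grad=True)
        frozen = {k: v.detach() for k, v in self.params_.items()}
        _, _, logits = forward_from_embeddings(X, frozen, self.config_, mask)
        picked = logits[np.arange(ids.shape[0]),
                        np.argmax(logits.data, axis=-1)]
        picked.sum().backward()
        return X.grad.copy()

    def _training_attributions(self, ids: np.ndarray, mask: np.ndarray) -> Tensor:
        """First-order gradient-times-input attributions, rows summing to 1.

        The gradient factor is detached; the embedding factor stays in the
        graph, so the attribution penalty has a usable first-order gradient
        without differentiating through the attribution gradient itself.
        """
        g = self._embedding_gradients(ids, mask)
        E = embed_batch(ids, self.params_, self.config_)
        # epsilon keeps the norm's gradient finite at exactly-zero rows (padding)
        raw = (((Tensor(g) * E) ** 2).sum(axis=-1) + 1e-24).sqrt() * Tensor(mask)
        total = raw.sum(axis=-1, keepdims=True)
        uniform = Tensor(mask / np.maximum(mask.sum(axis=-1, keepdims=True), 1.0))
        if np.any(total.data <= 1e-12):
            logger.warning("all-zero attribution scores; using uniform fallback")
            return uniform
        return raw / total

    # ------------------------------------------------------------------ fit
    def fit(self, X: Sequence[Sequence[str]], y: Sequence[int],
            domains: Sequence[int] | None = None,
            lexicon: SentimentLexicon | None = None,
            domain_markers: Mapping[int, frozenset[str]] | None = None,
            vocabulary: Sequence[str] | None = None,
            validation: tuple | None = None):
        X = [tuple(toks) for toks in X]
        y = np.asarray(y, dtype=int)
        if len(X) == 0:
            raise ValueError("cannot fit on an empty corpus")
        self.classes_ = np.unique(y)
        if len(self.classes_) > 2:
            raise ValueError("only binary sentiment is supported")
        if vocabulary is None:
            vocabulary = sorted({t for toks in X for t in toks})
        self.vocabulary_ = list(vocabulary)
        self.vocab_index_ = build_vocab_index(self.vocabulary_)
        domains = (np.asarray(domains, dtype=int) if domains is not None
                   else np.zeros(len(X), dtype=int))
        n_domains = int(domains.max()) + 1
        self.config_ = self._model_config(n_domains)
        self.params_ = init_params(self.config_, len(self.vocabulary_))
        self.lexicon_ = lexicon
        self.domain_markers_ = dict(domain_markers) if domain_markers else None

        mean_len = float(np.mean([len(t) for t in X]))
        eta = self.eta if self.eta is not None else min(1.0, 2.0 / mean_len)
        self.eta_ = eta
        weights = self._loss_weights(eta)
        self.loss_weights_ = weights

        rng = np.random.default_rng(self.seed)
        enc_opt = Adam({k: self.params_[k] for k in encoder_param_names(self.params_)},
                       lr=self.learning_rate, weight_decay=self.weight_decay)
        disc_opt = Adam({k: self.params_[k]
                         for k in discriminator_param_names(self.params_)},
                        lr=self.disc_lr if self.disc_lr is not None
                        else self.learning_rate)
        bank = L.PrototypeBank(2, self.config_.embed_dim,
                               momentum=self.prototype_momentum)
        self.prototype_bank_ = bank

        use_adv = (weights.preset in ("decoupling", "full") and weights.lambda_adv > 0
                   and n_domains >= 2)
        use_align = (weights.preset in ("decoupling", "full") and weights.lambda_align > 0
                     and self.domain_markers_ is not None and n_domains >= 2)
        use_attr = (weights.preset in ("decoupling", "full") and weights.lambda_attr > 0
                    and lexicon is not None)
        use_pol = (weights.preset in ("encoder", "full") and weights.lambda_pol > 0
                   and lexicon is not None)
        use_con = weights.preset in ("encoder", "full") and weights.lambda_con > 0
        use_contrast = (weights.preset in ("decoupling", "full")
                        and weights.lambda_contrast > 0)
        pair_corpus = None
        if use_align:
            pair_corpus = Corpus(examples=[], vocabulary=self.vocabulary_,
                                 lexicon=lexicon or SentimentLexicon({}),
                                 domain_markers={d: frozenset(m) for d, m in
                                                 self.domain_markers_.items()},
                                 spec=None)

        self.history_: list[dict] = []
        self.validation_history_: list[dict] = []
        best_val, best_params, patience_left = -np.inf, None, self.early_stop_patience
        step = 0
        n = len(X)
        last_finite = {k: v.data.copy() for k, v in self.params_.items()}
        for epoch in range(self.epochs):
            order = rng.permutation(n)
            for start in range(0, n, self.batch_size):
                idx = order[start:start + self.batch_size]
                toks = [X[i] for i in idx]
                yb, db = y[idx], domains[idx]
                ids, mask = _pad_batch(toks, self.vocab_index_)
                try:
                    step = self._train_step(ids, mask, toks, yb, db, step,
                                            weights, eta, bank, enc_opt,
                                            disc_opt, rng, n_domains, epoch,
                                            use_adv, use_pol, use_con,
                                            use_contrast, use_attr, use_align,
                                            lexicon, pair_corpus)
                except (FloatingPointError, TrainingDivergedError) as exc:
                    raise TrainingDivergedError(
                        f"objective became non-finite at step {step}: {exc}",
                        last_params=last_finite) from exc
                last_finite = {k: v.data.copy()
                               for k, v in self.params_.items()}

            if validation is not None:
                val_acc = self.score(validation[0], validation[1])
                self.validation_history_.append({"epoch": epoch,
                                                 "val_accuracy": val_acc})
                if val_acc > best_val:
                    best_val = val_acc
                    best_params = {k: v.data.copy()
                                   for k, v in self.params_.items()}
                    patience_left = self.early_stop_patience
                elif patience_left is not None:
                    patience_left -= 1
                    if patience_left < 0:
                        logger.info("early stop at epoch %d", epoch)
                        break

        if best_params is not None:
            for k, v in best_params.items():
                self.params_[k].data = v
        return self

    def _train_step(self, ids, mask, toks, yb, db, step, weights, eta, bank,
                    enc_opt, disc_opt, rng, n_domains, epoch, use_adv,
                    use_pol, use_con, use_contrast, use_attr, use_align,
                    lexicon, pair_corpus) -> int:
        # phase 1: discriminator update(s), encoder frozen
        if use_adv:
            with no_grad():
                _, _, z_frozen = self._forward_z(ids, mask)
            for _ in range(max(self.disc_steps, 1)):
                z_const = Tensor(z_frozen.data)
                disc_loss = L.domain_adversarial_loss(z_const, db,
                                                      self.params_)
                disc_opt.zero_grad()
                disc_loss.backward()
                disc_opt.step()

        # phase 2: encoder + head update on the composite objective
        H, alpha, z = self._forward_z(ids, mask)
        logits = predict_head_batch(z, self.params_)
        terms: dict[str, Tensor] = {
            "ce": L.cross_entropy_from_logits(logits, yb)}
        if use_pol:
            scores = token_polarity_score_batch(H, self.params_)
            terms["pol"] = L.polarity_loss(scores, toks, lexicon,
                                           mode="train_soft")
        if use_con:
            bank.update(z.data, yb)
            pos_idx = np.flatnonzero(yb == 1)
            neg_idx = np.flatnonzero(yb == 0)
            if len(pos_idx) and len(neg_idx):
                rng.shuffle(pos_idx)
                rng.shuffle(neg_idx)
                terms["con_prototype"] = L.prototype_contrastive_loss(
                    z[pos_idx], z[neg_idx], bank, weights.margin)
        if use_adv:
            scale = weights.grl_scale * min(
                1.0, (step + 1) / max(self.grl_warmup_steps, 1))
            terms["adv"] = L.domain_adversarial_loss(
                z, db, self.params_, grl_scale=scale)
        if use_contrast:
            terms["contrast_pairwise"] = L.pairwise_contrastive_loss(
                z, yb, weights.margin)
        if use_attr:
            attrib = self._training_attributions(ids, mask)
            terms["attr"] = L.attribution_loss(attrib, toks, lexicon, eta)
        if use_align:
            targets = (db + 1 + rng.integers(0, n_domains - 1, len(db))) \
                % n_domains
            paired = []
            for i, (t, d_src, d_tgt) in enumerate(zip(toks, db, targets)):
                ex = LabeledExample(tokens=t, sentiment_label=0,
                                    domain_label=int(d_src),
                                    example_id=f"b{i}")
                paired.append(make_domain_pair(ex, pair_corpus,
                                               int(d_tgt), rng=rng).tokens)
            ids_p, mask_p = _pad_batch(paired, self.vocab_index_)
            _, _, z_p = self._forward_z(ids_p, mask_p)
            terms["align"] = L.alignment_loss(z, z_p)

        total, breakdown = L.total_objective(terms, weights)
        if not np.isfinite(breakdown.total):
            raise TrainingDivergedError("non-finite objective")
        enc_opt.zero_grad()
        disc_opt.zero_grad()  # adversarial term also reaches disc params
        total.backward()
        enc_opt.step()
        self.history_.append({"step": step, "epoch": epoch,
                              **breakdown.as_dict()})
        return step + 1

    def fit_corpus(self, train: Corpus, validation: Corpus | None = None):
        """Fit from generated/loaded corpora; wires lexicon and markers through."""
        val = None
        if validation is not None and len(validation):
            val = ([ex.tokens for ex in validation.examples],
                   [ex.sentiment_label for ex in validation.examples])
        return self.fit(
            [ex.tokens for ex in train.examples],
            [ex.sentiment_label for ex in train.examples],
            domains=[ex.domain_label for ex in train.examples],
            lexicon=train.lexicon, domain_markers=dict(train.domain_markers),
            vocabulary=train.vocabulary, validation=val)

    # ------------------------------------------------------------ inference
    def _check_fitted(self) -> None:
        if not hasattr(self, "params_"):
            raise RuntimeError("estimator is not fitted")

    def transform(self, X: Sequence[Sequence[str]]) -> np.ndarray:
        """Frozen sentence vectors z, (n, d)."""
        self._check_fitted()
        out = []
        bs = max(self.batch_size, 1)
        with no_grad():
            for start in range(0, len(X), bs):
                toks = [tuple(t) for t in X[start:start + bs]]
                ids, mask = _pad_batch(toks, self.vocab_index_)
                _, _, z = self._forward_z(ids, mask)
                out.append(z.data)
        return np.concatenate(out, axis=0)

    def decision_scores(self, X: Sequence[Sequence[str]]) -> np.ndarray:
        self._check_fitted()
        with no_grad():
            z = Tensor(self.transform(X))
            logits = predict_head_batch(z, self.params_)
        return logits.data

    def predict_proba(self, X: Sequence[Sequence[str]]) -> np.ndarray:
        logits = self.decision_scores(X)
        e = np.exp(logits - logits.max(axis=-1, keepdims=True))
        return e / e.sum(axis=-1, keepdims=True)

    def predict(self, X: Sequence[Sequence[str]]) -> np.ndarray:
        return np.argmax(self.predict_proba(X), axis=-1)

    def score(self, X: Sequence[Sequence[str]], y: Sequence[int]) -> float:
        return float(np.mean(self.predict(X) == np.asarray(y)))

    def token_polarity_signs(self, tokens: Sequence[str]) -> np.ndarray:
        """Hard-sign polarity of each token's final-layer state."""
        self._check_fitted()
        ids, mask = _pad_batch([tuple(tokens)], self.vocab_index_)
        with no_grad():
            H, _ = encode_batch(ids, self.params_, self.config_, mask=mask)
            s = token_polarity_score_batch(H, self.params_)
        return np.sign(s.data[0, :len(tokens)])
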