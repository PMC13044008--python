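"""Functional training, evaluation and probing surface over the estimator.

`train` runs the alternating adversarial loop on corpus splits and returns
the fitted model plus a per-step metrics table. `evaluate_classification`
computes accuracy / macro recall / macro F1 / AUC together with the
intra-class vs inter-class compactness of the sentence vectors.
`probe_domain` fits a fresh softmax probe on frozen representations to
measure how much domain information they leak — near-chance probe accuracy
certifies domain invariance.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import (accuracy_score, f1_score, recall_score,
                             roc_auc_score)
from sklearn.model_selection import train_test_split

from .corpus import Corpus
from .encoder import ModelConfig, load_checkpoint, save_checkpoint
from .estimator import GatedSentimentClassifier
from .losses import LossWeights

__all__ = ["TrainConfig", "EvalReport", "train", "evaluate_classification",
           "probe_domain", "save_model", "load_model"]


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 10
    batch_size: int = 32
    learning_rate: float = 1e-2
    weight_decay: float = 0.0
    optimizer: str = "adam"
    grl_warmup_steps: int = 100
    early_stop_patience: int | None = None
    checkpoint_path: str | None = None
    metrics_path: str | None = None
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 0 or self.batch_size < 1:
            raise ValueError("epochs must be >= 0 and batch_size >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.optimizer != "adam":
            raise ValueError("only the 'adam' optimizer is implemented")


@dataclass
class EvalReport:
    accuracy: float
    recall_macro: float
    f1_macro: float
    auc: float | None              # None marks "undefined" (single-class split)
    per_class_counts: dict[int, int]
    intra_class_mean_dist: float
    inter_class_mean_dist: float
    domain_probe_accuracy: float | None = None

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["auc"] = "undefined" if self.auc is None else self.auc
        return d


def build_estimator(model_config: ModelConfig, weights: LossWeights,
                    train_config: TrainConfig) -> GatedSentimentClassifier:
    """Map the three config dataclasses onto estimator hyperparameters."""
    return GatedSentimentClassifier(
        embed_dim=model_config.embed_dim, n_layers=model_config.n_layers,
        n_heads=model_config.n_heads, ffn_hidden=model_config.ffn_hidden,
        pool_hidden=model_config.pool_hidden, disc_hidden=model_config.disc_hidden,
        max_length=model_config.max_length, dropout_rate=model_config.dropout_rate,
        layer_norm=model_config.layer_norm, positional=model_config.positional,
        lambda_pol=weights.lambda_pol, lambda_con=weights.lambda_con,
        lambda_adv=weights.lambda_adv, lambda_contrast=weights.lambda_contrast,
        lambda_attr=weights.lambda_attr, lambda_align=weights.lambda_align,
        margin=weights.margin, eta=weights.eta, grl_scale=weights.grl_scale,
        preset=weights.preset, epochs=train_config.epochs,
        batch_size=train_config.batch_size,
        learning_rate=train_config.learning_rate,
        weight_decay=train_config.weight_decay,
        grl_warmup_steps=train_config.grl_warmup_steps,
        early_stop_patience=train_config.early_stop_patience,
        seed=train_config.seed)


def train(train_corpus: Corpus, val_corpus: Corpus | None,
          model_config: ModelConfig, weights: LossWeights,
          train_config: TrainConfig
          ) -> tuple[GatedSentimentClassifier, pd.DataFrame]:
    """Alternating encoder/discriminator training on corpus splits.

    Returns the fitted model (best-validation parameters when a validation
    corpus is supplied) and the per-step loss-breakdown table. Writes the
    checkpoint archive and metrics CSV when paths are configured.
    """
    if len(train_corpus) == 0:
        raise ValueError("training split is empty")
    model = build_estimator(model_config, weights, train_config)
    model.fit_corpus(train_corpus, validation=val_corpus)
    metrics = pd.DataFrame(model.history_,
                           columns=["step", "epoch", "ce", "pol", "con_prototype",
                                    "adv", "contrast_pairwise", "attr", "align",
                                    "total"])
    if train_config.metrics_path:
        Path(train_config.metrics_path).parent.mkdir(parents=True, exist_ok=True)
        metrics.to_csv(train_config.metrics_path, index=False)
    if train_config.checkpoint_path:
        save_model(train_config.checkpoint_path, model)
    return model, metrics


def save_model(path, model: GatedSentimentClassifier) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    save_checkpoint(path, model.params_, model.config_, len(model.vocabulary_),
                    extra_meta={"vocabulary": model.vocabulary_,
                                "classes": [int(c) for c in model.classes_],
                                "hyperparams": model.get_params()})


def load_model(path) -> GatedSentimentClassifier:
    """Rehydrate a fitted estimator from a checkpoint archive."""
    params, config, meta = load_checkpoint(path)
    model = GatedSentimentClassifier(**meta.get("hyperparams", {}))
    model.params_ = params
    model.config_ = config
    model.vocabulary_ = list(meta["vocabulary"])
    from .encoder import build_vocab_index
    model.vocab_index_ = build_vocab_index(model.vocabulary_)
    model.classes_ = np.asarray(meta.get("classes", [0, 1]))
    model.lexicon_ = None
    model.domain_markers_ = None
    return model


def _pairwise_sq_dists(z: np.ndarray) -> np.ndarray:
    sq = ((z[:, None, :] - z[None, :, :]) ** 2).sum(axis=-1)
    return sq


def class_distance_gap(z: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """(mean intra-class, mean inter-class) pairwise Euclidean distance of z."""
    d = np.sqrt(_pairwise_sq_dists(z))
    same = y[:, None] == y[None, :]
    iu = np.triu(np.ones_like(d, dtype=bool), k=1)
    intra = d[same & iu]
    inter = d[~same & iu]
    return (float(intra.mean()) if intra.size else np.nan,
            float(inter.mean()) if inter.size else np.nan)


def evaluate_classification(model: GatedSentimentClassifier, corpus: Corpus,
                            probe_domains: bool = False,
                            seed: int = 0) -> EvalReport:
    """Accuracy / macro recall / macro F1 / AUC plus representation geometry."""
    if len(corpus) == 0:
        raise ValueError("evaluation split is empty")
    X = [ex.tokens for ex in corpus.examples]
    y = np.array([ex.sentiment_label for ex in corpus.examples])
    proba = model.predict_proba(X)
    pred = np.argmax(proba, axis=-1)
    counts = {int(c): int(n) for c, n in zip(*np.unique(y, return_counts=True))}
    if len(counts) < 2:
        auc = None
    else:
        auc = float(roc_auc_score(y, proba[:, 1]))
    z = model.transform(X)
    intra, inter = class_distance_gap(z, y)
    probe_acc = None
    if probe_domains:
        probe_acc = probe_domain(model, corpus, seed=seed)
    return EvalReport(
        accuracy=float(accuracy_score(y, pred)),
        recall_macro=float(recall_score(y, pred, average="macro",
                                        zero_division=0)),
        f1_macro=float(f1_score(y, pred, average="macro", zero_division=0)),
        auc=auc, per_class_counts=counts,
        intra_class_mean_dist=intra, inter_class_mean_dist=inter,
        domain_probe_accuracy=probe_acc)


def probe_domain(model: GatedSentimentClassifier, corpus: Corpus,
                 probe_train_fraction: float = 0.5, seed: int = 0,
                 z: np.ndarray | None = None,
                 domains: np.ndarray | None = None) -> float:
    """Domain-leakage probe on frozen sentence vectors.

    Fits a fresh multinomial logistic probe on one half of the split and
    reports its accuracy on the other half. ``z``/``domains`` can be passed
    directly to probe arbitrary representations.
    """
    if z is None:
        if len(corpus) == 0:
            raise ValueError("probe split is empty")
        z = model.transform([ex.tokens for ex in corpus.examples])
        domains = np.array([ex.domain_label for ex in corpus.examples])
    domains = np.asarray(domains)
    if len(np.unique(domains)) < 2:
        raise ValueError("domain probe requires at least 2 domains in the split")
    z_tr, z_te, d_tr, d_te = train_test_split(
        z, domains, train_size=probe_train_fraction, random_state=seed,
        stratify=domains)
    probe = LogisticRegression(max_iter=2000, random_state=seed)
    probe.fit(z_tr, d_tr)
    return float(accuracy_score(d_te, probe.predict(z_te)))
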