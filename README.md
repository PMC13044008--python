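# sentdec

Domain-decoupled sentiment classification with gated transformer encoders,
lexicon-guided regularization, and a built-in explanation audit.

Clinical sentiment classifiers (patient reviews, drug-effect complaints)
face two coupled problems: the domain a text comes from confounds the
sentiment signal, and the models' evidence for a prediction is opaque.
`sentdec` is a research library for studying both at once on fully
controlled synthetic corpora. It provides:

* a **gated transformer encoder**: each layer computes a per-token
  sentiment gate `γ_t = σ(W_s x_t + b_s)` and interpolates the token state
  with its attention/FFN transform
  (`x̃_t = γ_t·MHAttn(x_t, X, X) + (1−γ_t)·x_t`), followed by gated
  attention pooling `z = Σ_t α_t h̃_t`,
  `α = softmax(u⊤ tanh(W_h h̃ + b_h))`, and a softmax head;
* a **composite objective** combining cross-entropy with lexicon polarity
  regularization `Σ_t 1[w_t∈V_s](s_t − p(w_t))²`, prototype and pairwise
  contrastive hinges with margin `m`, a domain-adversarial term trained
  under gradient reversal, attribution-guided regularization
  `Σ_t 1[w_t∈V_s](α_t − η)²`, and cross-domain alignment
  `‖z^d − z^d'‖²` of the same sentence rendered in two domains;
* an **interpretability audit**: token attributions (gradient×input,
  integrated gradients, attention), explanation *fidelity* (relative
  confidence drop under top-k masking) and *stability* (Jaccard overlap of
  top-k sets under random token substitution);
* a **synthetic multi-domain corpus generator** with planted lexicon
  tokens, domain-marker tokens, controllable label noise and controllable
  label–domain confounding, so every claim can be checked against known
  ground truth.

Everything runs in float64 numpy on a small bundled reverse-mode autodiff
engine — no GPU or deep-learning framework required.

## Worked example

```python
import sentdec as sd

spec = sd.CorpusSpec(n_examples=1000, vocab_size=200, seed=7)
corpus = sd.generate_corpus(spec)
train, val, test = sd.split_corpus(corpus, (0.7, 0.15, 0.15), seed=7)

clf = sd.GatedSentimentClassifier(
    embed_dim=24, n_layers=1, n_heads=2, ffn_hidden=48, pool_hidden=12,
    preset="full", epochs=5, batch_size=32, learning_rate=0.01, seed=7)
clf.fit_corpus(train, validation=val)

report = sd.evaluate_classification(clf, test)
print(report.accuracy, report.f1_macro, report.auc)

ex = test.examples[0]
rep = sd.gradient_attributions(clf, ex, "gradient_input")
print(ex.tokens, sorted(sd.top_k_tokens(rep, 3)))
```

Output of the session above:

```
accuracy      0.967
macro F1      0.967
AUC           0.994
intra / inter 1.39 / 3.31
domain probe  0.653
tokens: pos2 w127 dom1_m3 pos11 w40 pos6 dom1_m1 w126
label : 1  predicted: 1
top-3 attributed tokens: ['pos11', 'pos6', 'w126']
fidelity@3  0.280
stability@3 0.736
```

Reading this: the classifier recovers the planted lexicon signal almost
perfectly (96.7% held-out accuracy, AUC 0.994). Same-sentiment sentence
vectors sit much closer together (mean distance 1.39) than
opposite-sentiment ones (3.31). A logistic probe trained on the frozen
sentence vectors recovers the domain at 65% — close to chance, i.e. the
representation leaks little domain information. Two of the three
most-attributed tokens for the example are planted positive lexicon words;
masking the top-3 tokens costs 28% of the predicted-class confidence, and
the top-3 set is 74% stable (Jaccard) under 10% random token substitution.

The estimator is scikit-learn compatible (`fit`/`predict`/`predict_proba`/
`transform`, `get_params`/`set_params`), so it composes with sklearn model
selection; `sentdec.train`/`evaluate_classification`/`probe_domain` offer a
functional surface over corpora, and `fit` accepts plain token sequences
with optional `domains`, `lexicon` and `domain_markers`.

## Command line

A `sentdec` console script drives the full pipeline from one YAML file
(sections `data`, `model`, `objective`, `train`, `audit`; one root seed):

```bash
sentdec generate run.yaml            # corpus JSONL + sidecars
sentdec train    run.yaml            # checkpoint.npz + metrics.csv
sentdec eval     run.yaml out/checkpoint.npz
sentdec explain  run.yaml out/checkpoint.npz   # attribution JSONL
sentdec audit    run.yaml out/checkpoint.npz   # fidelity/stability CSV
```

Exit codes: 0 success, 2 configuration/input error, 3 training divergence.

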