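# Methods

`sentdec` implements a sentiment classifier whose design goal is to
*decouple* the sentiment content of a sentence from the domain it was
written in, and to make the model's evidence for a prediction auditable at
the token level. This note documents the model, the objectives, the
synthetic data the package is validated on, and the numerical and design
choices a maintainer would want to know about.

## Model

An input is a sequence of abstract tokens `x = (w_1, …, w_T)`. Tokens are
embedded (`e(w_t) ∈ R^d`, plus fixed sinusoidal positional encodings) and
passed through `L` *gated* transformer layers. Each layer computes a
per-token sentiment modulation gate

    γ_t = σ(W_s x_t + b_s) ∈ (0, 1)

and interpolates the token's state with its transformed state twice — around
multi-head self-attention and, reusing the same gate, around the
position-wise feed-forward block:

    x̃_t = γ_t · MHAttn(x_t, X, X) + (1 − γ_t) · x_t
    h̃_t = γ_t · FFN(x̃_t)        + (1 − γ_t) · x̃_t

Layer normalization follows each sublayer (post-norm; disable with
`layer_norm=False` to recover an exactly checkable identity path when all
gates are driven to 0). Gated attention pooling collapses the final token
states into a sentence vector

    α_t = softmax_t( u⊤ tanh(W_h h̃_t + b_h) ),    z = Σ_t α_t h̃_t

and a softmax head maps `z` to class probabilities. Applying the same head
to an individual final-layer token state and taking
`tanh(logit_pos − logit_neg)` gives a *token polarity score* in (−1, 1); its
hard sign is the model's claimed polarity for that token. The tanh
scalarization replaces a non-differentiable sign during training; the hard
sign is used for evaluation. Head parameters are shared between the
sentence-level and token-level readouts deliberately: the token score is
"what the classifier would say about this token alone".

## Objectives

Two presets reflect the two stages of the method; `full` is their union.
Sums run over tokens/pairs, means over the batch, so the λ coefficients are
batch-size free.

Encoder-side (`encoder`):

* cross-entropy `L_CE`;
* polarity regularization `L_pol = Σ_t 1[w_t ∈ V_s] (s_t − p(w_t))²`, where
  `V_s` is a sentiment lexicon with polarity `p(w) ∈ {−1, +1}` and `s_t` the
  (soft) token polarity score;
* a prototype contrastive hinge between matched positive/negative sentence
  pairs, `max(0, m + ‖z⁺ − c⁺‖² − ‖z⁺ − z⁻‖²)`, where `c⁺` is an
  exponential running mean (momentum 0.9, initialized from the first batch)
  of positive-class sentence vectors. A variant with the two squared
  distances' signs exchanged is selectable (`form="as_printed"`); it rewards
  pushing positives *away* from their own prototype and is kept only for
  comparison — the default is the semantically coherent form.

Decoupling-side (`decoupling`):

* a domain-adversarial term: a discriminator (2-layer MLP by default,
  optionally linear) is trained to classify the domain from `z`; the same
  cross-entropy reaches the encoder through a *gradient-reversal* node that
  multiplies the gradient by `−grl_scale`, so one minimization step trains
  the discriminator and pushes the encoder toward domain confusion;
* an all-pairs contrastive hinge (same-label pairs pulled together,
  different-label pairs pushed at least `√m` apart), normalized by the pair
  count;
* attribution-guided regularization
  `L_attr = Σ_t 1[w_t ∈ V_s] (α_t − η)²` on *normalized gradient
  attributions* (not the pooling weights), pulling attribution weight on
  lexicon tokens toward a target `η`;
* a cross-domain alignment term: the squared distance between `z` of a
  sentence and `z` of the same sentence re-rendered in another domain by
  marker substitution.

### First-order attribution gradient

`L_attr` needs attributions that are differentiable in the parameters, but
differentiating *through* a gradient would be second-order. The training
attribution therefore freezes the gradient factor: with
`g_t = ∂(predicted-class logit)/∂(embedded input)_t` detached, the raw score
is `‖g_t ⊙ e_t‖₂` with the embedding factor `e_t` live, renormalized
differentiably over real tokens. This keeps the cost linear and empirically
steers attribution mass (see below); the alternative of a fully detached
attribution would make `L_attr` gradient-free and inert.

`η` defaults to twice the uniform weight at the mean training sequence
length (`2/T̄`) — "lexicon tokens should matter more than average". Note
that a freshly trained model often *already* concentrates ≈half of its
attribution mass on the planted lexicon tokens, which satisfies this
default; studies of the steering effect use a more ambitious explicit target
(η = 0.3 with ≈3 lexicon tokens per sentence).

### Adversarial alternation

Each batch performs `disc_steps` discriminator updates on frozen
representations, then one encoder/head update on the composite objective.
The default is 1:1, but for measurable *information removal* the
discriminator must track the encoder closely: with a lagging discriminator
the encoder maximizes the current discriminator's loss by re-encoding domain
information where the discriminator happens to be wrong (anti-alignment), and
a freshly fitted probe reads the domain *better* after "adversarial"
training. The domain-invariance study therefore runs `disc_steps=10` with a
slightly higher discriminator learning rate, and warms the reversal scale
from 0 over 200 steps so sentiment features form first. `grl_scale`
trades suppression strength against collateral damage to sentiment accuracy;
2.2 was adopted for the study configuration.

## Synthetic corpus generator

The generator emulates exactly the structure the method assumes: sentiment
is carried by lexicon words, domain by domain-specific marker words, and the
rest is neutral filler.

* Each example plants `lexicon_tokens_per_example` lexicon tokens whose
  strict majority polarity equals the example's planted label, plus
  `domain_marker_tokens_per_example` markers from its own domain's pool, and
  uniform filler; positions are shuffled. Marker pools are pairwise disjoint
  and disjoint from the lexicon, so planted signals are exactly recoverable
  from the tokens.
* `label_flip_rate` flips the observed label independently per example
  after planting — one knob for annotation noise.
* `domain_label_correlation` couples the domain with the **observed**
  label: with that probability the domain is set to the observed label's
  index instead of a balanced draw. Tying the confound to the post-noise
  label is what makes domain markers carry label information *beyond* the
  lexicon (they hint at whether the label was flipped); tying it to the
  planted label would leave markers informationally redundant and give an
  unregularized model no incentive to encode them — there would be nothing
  for the adversary to remove.
* Class marginals are balanced to ±1; domain marginals are balanced when
  the correlation is 0. Everything is determined by the spec's seed.

What the generator does **not** emulate: word order semantics, negation and
scope, token frequency skew, multi-domain mixtures within one sentence,
subword structure, or label noise that correlates with content. Passing
tests therefore certify the mechanics of the objectives and architecture on
corpora satisfying the method's own assumptions, not clinical-text
performance.

## Interpretability audit

Attribution methods: `gradient_input` (L2 norm of gradient ⊙ input per
token), `integrated_gradients` (midpoint Riemann sum, 32 steps, zero
embedding baseline), `attention` (pooling weights). All reports are
normalized to sum to 1; ties in top-k selection break toward the lower
index.

* **Fidelity** at k: replace the top-k attributed tokens with a reserved
  zero mask embedding and measure the relative drop of the originally
  predicted class's probability, clamped to [0, 1] (1 = total confidence
  collapse). The zero mask matches the integrated-gradients baseline.
* **Stability** at k: replace ⌈ρT⌉ random positions with random vocabulary
  tokens (defaults ρ = 0.1, R = 10 repeats, seeded) and measure the Jaccard
  similarity of the top-k sets before and after.

## Evaluation protocol and problem sizes

The package validates its claims on these study configurations (3 seeds,
medians, all runnable on one CPU):

* **Signal recovery**: separable corpus (n = 2000, vocab 200, no noise),
  full objective, d = 24, 1 layer, ≤10 epochs with early stopping —
  held-out accuracy ≥ 0.90 (typically ≈1.0), and mean intra-class distance
  of `z` strictly below inter-class distance.
* **Domain invariance**: confounded corpus (correlation 0.6, flip rate
  0.1, n = 2000), d = 32, 2 layers, adversarial term only, protocol as
  above (grl 2.2, disc_steps 10, 24 epochs, batch 64, lr 3e-3, weight decay
  0.01). A logistic probe on frozen `z` over the whole corpus loses ≥ 15
  accuracy points when λ_adv = 1 versus λ_adv = 0 while sentiment accuracy
  changes by < 5 points.
* **Polarity recovery**: n = 1000 clean corpus, encoder preset; with
  λ_pol = 1 ≥ 95% of held-out lexicon tokens get the lexicon-consistent
  hard sign.
* **Attribution steering**: n = 800, λ_attr = 2 vs 0 paired by seed,
  η = 0.3 — lexicon attribution mass strictly larger in every pair.

## Numerical choices

* All computation is float64 on a small reverse-mode autodiff engine built
  on numpy (verified against central finite differences); no GPU framework
  is used.
* Softmax and log-softmax are max-shifted; the sigmoid uses the
  numerically stable split form; the attribution norm adds 1e-24 inside the
  square root so padded rows have finite gradients.
* Cross-entropy clamps the true-class probability at 1e-12 (logged).
* Argmax ties break toward the lowest class index; top-k ties toward the
  lowest token index.
* Padding uses the reserved mask row (index `|V|`, zero embedding) with
  additive −1e9 masking in attention and pooling softmaxes.
* Optimization is Adam (β = 0.9/0.999, ε = 1e-8) with optional decoupled
  weight decay; training aborts with the last finite parameter snapshot if
  the objective becomes non-finite.

## Known limitations

* Binary sentiment only; the token polarity score is defined through the
  two-class logit difference.
* The adversarial game is a heuristic equilibrium: suppression quality
  depends on the discriminator tracking the encoder (see alternation note);
  residual probe accuracy stays above the label-correlation floor by
  construction whenever the representation still predicts sentiment.
* Gradient attributions are aggregated per token by L2 norm, discarding
  sign; "importance" here means magnitude of influence.
* The prototype bank tracks only class means; no dispersion estimate.
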