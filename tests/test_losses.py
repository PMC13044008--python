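"""Objective terms vs independent straight-loop reimplementations."""

import numpy as np
import pytest

import sentdec as sd
from sentdec.autodiff import Tensor
from sentdec.encoder import ModelConfig, init_params
from sentdec.losses import LossWeights, PrototypeBank, cross_entropy_from_logits

LEX = sd.SentimentLexicon({"good": 1, "fine": 1, "bad": -1, "awful": -1})


# ---------------------------------------------------------------- oracles
def ce_loop(probs, labels):
    return float(np.mean([-np.log(p[y]) for p, y in zip(probs, labels)]))


def polarity_loop(scores, token_batch, lexicon, hard):
    per_seq = []
    for row, toks in zip(scores, token_batch):
        s = 0.0
        for t, tok in enumerate(toks):
            pol = lexicon.polarity(tok)
            if pol is not None:
                v = np.sign(row[t]) if hard else row[t]
                s += (v - pol) ** 2
        per_seq.append(s)
    return float(np.mean(per_seq))


def pairwise_loop(z, labels, m):
    n = len(z)
    vals = []
    for i in range(n):
        for j in range(i + 1, n):
            d2 = float(np.sum((z[i] - z[j]) ** 2))
            vals.append(d2 if labels[i] == labels[j] else max(0.0, m - d2))
    return float(np.sum(vals) / len(vals))


def prototype_loop(zp, zn, c, m, intended):
    k = min(len(zp), len(zn))
    vals = []
    for i in range(k):
        dp = float(np.sum((zp[i] - c) ** 2))
        dn = float(np.sum((zp[i] - zn[i]) ** 2))
        vals.append(max(0.0, m + dp - dn) if intended else max(0.0, m - dp + dn))
    return float(np.mean(vals))


def attribution_loop(alpha, token_batch, lexicon, eta):
    per_seq = []
    for row, toks in zip(alpha, token_batch):
        s = sum((row[t] - eta) ** 2 for t, tok in enumerate(toks)
                if tok in lexicon)
        per_seq.append(s)
    return float(np.mean(per_seq))


def align_loop(za, zb):
    return float(np.mean([np.sum((a - b) ** 2) for a, b in zip(za, zb)]))


# ------------------------------------------------------------ cross-entropy
class TestCrossEntropy:
    def test_perfect_predictions_give_zero(self):
        p = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert sd.cross_entropy_loss(p, [0, 1]).item() == pytest.approx(0.0)

    def test_uniform_binary_is_ln_two(self):
        p = np.full((4, 2), 0.5)
        assert sd.cross_entropy_loss(p, [0, 1, 0, 1]).item() \
            == pytest.approx(np.log(2), abs=1e-9)

    def test_two_example_arithmetic(self):
        p = np.array([[0.8, 0.2], [0.5, 0.5]])
        expected = (-np.log(0.8) - np.log(0.5)) / 2
        assert sd.cross_entropy_loss(p, [0, 0]).item() \
            == pytest.approx(expected, abs=1e-9)
        assert expected == pytest.approx(0.458145, abs=1e-6)

    def test_off_simplex_rows_rejected(self):
        with pytest.raises(ValueError, match="simplex"):
            sd.cross_entropy_loss(np.array([[0.7, 0.7]]), [0])

    def test_zero_probability_clamped_with_warning(self, caplog):
        p = np.array([[0.0, 1.0]])
        with caplog.at_level("WARNING", logger="sentdec"):
            val = sd.cross_entropy_loss(p, [0]).item()
        assert val == pytest.approx(-np.log(1e-12))
        assert "clamp" in caplog.text

    def test_matches_logit_formulation(self, rng):
        logits = rng.normal(size=(6, 2))
        labels = rng.integers(0, 2, 6)
        p = np.exp(logits) / np.exp(logits).sum(axis=1, keepdims=True)
        assert cross_entropy_from_logits(Tensor(logits), labels).item() \
            == pytest.approx(sd.cross_entropy_loss(p, labels).item(), abs=1e-9)


# ---------------------------------------------------------------- polarity
class TestPolarityLoss:
    def test_no_lexicon_tokens_is_zero(self):
        scores = Tensor(np.array([[0.5, -0.5]]))
        assert sd.polarity_loss(scores, [("w1", "w2")], LEX).item() == 0.0

    def test_hard_sign_mismatch_contributes_four(self):
        scores = Tensor(np.array([[-0.3]]))
        val = sd.polarity_loss(scores, [("good",)], LEX, mode="eval_hard")
        assert val.item() == pytest.approx(4.0)

    def test_soft_score_arithmetic(self):
        scores = Tensor(np.array([[0.462117]]))
        val = sd.polarity_loss(scores, [("good",)], LEX, mode="train_soft")
        assert val.item() == pytest.approx(0.289318, abs=1e-5)

    @pytest.mark.parametrize("mode", ["train_soft", "eval_hard"])
    def test_matches_loop_oracle_on_random_batches(self, rng, mode):
        toks = [tuple(rng.choice(["good", "bad", "w", "fine", "x"], size=5))
                for _ in range(4)]
        scores = rng.uniform(-1, 1, size=(4, 5))
        got = sd.polarity_loss(Tensor(scores), toks, LEX, mode=mode).item()
        want = polarity_loop(scores, toks, LEX, hard=(mode == "eval_hard"))
        assert got == pytest.approx(want, abs=1e-6)


# ----------------------------------------------------------- contrastive
class TestPrototypeContrastive:
    def bank(self, c):
        bank = PrototypeBank(2, len(c))
        bank.update(np.array([c]), np.array([1]))
        return bank

    def test_hinge_inactive_at_prototype_with_distant_negative(self):
        c = np.zeros(3)
        zp = np.zeros((1, 3))
        zn = np.full((1, 3), 2.0)   # squared distance 12 >= m
        val = sd.prototype_contrastive_loss(Tensor(zp), Tensor(zn),
                                            self.bank(c), m=1.0)
        assert val.item() == 0.0

    def test_intended_form_arithmetic(self):
        c = np.zeros(2)
        zp = np.array([[np.sqrt(0.5), 0.0]])        # ||zp-c||^2 = 0.5
        zn = zp - np.array([[0.5, 0.0]])            # ||zp-zn||^2 = 0.25
        val = sd.prototype_contrastive_loss(Tensor(zp), Tensor(zn),
                                            self.bank(c), m=1.0,
                                            form="intended")
        assert val.item() == pytest.approx(1.25, abs=1e-9)

    def test_printed_form_arithmetic(self):
        c = np.zeros(2)
        zp = np.array([[np.sqrt(0.5), 0.0]])
        zn = zp - np.array([[0.5, 0.0]])
        val = sd.prototype_contrastive_loss(Tensor(zp), Tensor(zn),
                                            self.bank(c), m=1.0,
                                            form="as_printed")
        assert val.item() == pytest.approx(0.75, abs=1e-9)

    def test_empty_side_skips_with_zero(self):
        val = sd.prototype_contrastive_loss(
            Tensor(np.zeros((0, 2))), Tensor(np.ones((2, 2))),
            self.bank(np.zeros(2)), m=1.0)
        assert val.item() == 0.0

    @pytest.mark.parametrize("form", ["intended", "as_printed"])
    def test_matches_loop_oracle(self, rng, form):
        c = rng.normal(size=4)
        zp, zn = rng.normal(size=(5, 4)), rng.normal(size=(5, 4))
        got = sd.prototype_contrastive_loss(Tensor(zp), Tensor(zn),
                                            self.bank(c), m=1.0,
                                            form=form).item()
        assert got == pytest.approx(
            prototype_loop(zp, zn, c, 1.0, form == "intended"), abs=1e-6)


class TestPairwiseContrastive:
    def test_identical_same_label_batch_is_zero(self):
        z = np.ones((4, 3))
        assert sd.pairwise_contrastive_loss(Tensor(z), [1, 1, 1, 1],
                                            m=2.0).item() == 0.0

    def test_distant_cross_label_pair_is_zero(self):
        z = np.array([[0.0, 0.0], [3.0, 0.0]])
        assert sd.pairwise_contrastive_loss(Tensor(z), [0, 1],
                                            m=2.0).item() == 0.0

    def test_single_cross_pair_arithmetic(self):
        z = np.array([[0.0, 0.0], [1.0, 0.0]])
        assert sd.pairwise_contrastive_loss(Tensor(z), [0, 1], m=2.0).item() \
            == pytest.approx(1.0)

    def test_batch_of_one_is_zero(self):
        assert sd.pairwise_contrastive_loss(Tensor(np.ones((1, 2))), [0],
                                            m=1.0).item() == 0.0

    def test_matches_loop_oracle(self, rng):
        z = rng.normal(size=(7, 3))
        labels = rng.integers(0, 2, 7)
        got = sd.pairwise_contrastive_loss(Tensor(z), labels, m=1.5).item()
        assert got == pytest.approx(pairwise_loop(z, labels, 1.5), abs=1e-6)

    def test_hinge_inactive_when_classes_coincident_and_separated(self, rng):
        a = rng.normal(size=3)
        b = a + 10.0
        z = np.stack([a, a, b, b])
        assert sd.pairwise_contrastive_loss(Tensor(z), [0, 0, 1, 1],
                                            m=4.0).item() == 0.0


# --------------------------------------------------------------- adversarial
class TestDomainAdversarial:
    @pytest.fixture()
    def params(self):
        return init_params(ModelConfig(embed_dim=4, n_heads=1, pool_hidden=2,
                                       disc_hidden=3, n_domains=2, seed=0), 5)

    def test_perfect_discriminator_gives_zero(self, params):
        # drive the discriminator output to near-certainty via huge weights
        params["disc.W1"].data = np.eye(4, 3) * 100
        params["disc.b1"].data[:] = 0.0
        params["disc.W2"].data = np.array([[100.0, -100.0], [0, 0], [0, 0.0]])
        params["disc.b2"].data[:] = 0.0
        z = np.array([[1.0, 0, 0, 0]])
        val = sd.domain_adversarial_loss(Tensor(z), [0], params)
        assert val.item() == pytest.approx(0.0, abs=1e-6)

    def test_uniform_discriminator_gives_ln_two(self, params):
        for k in ("disc.W1", "disc.b1", "disc.W2", "disc.b2"):
            params[k].data[:] = 0.0
        z = np.ones((3, 4))
        val = sd.domain_adversarial_loss(Tensor(z), [0, 1, 0], params)
        assert val.item() == pytest.approx(np.log(2), abs=1e-9)

    def test_single_domain_disabled(self):
        params = init_params(ModelConfig(embed_dim=4, n_heads=1, pool_hidden=2,
                                         n_domains=1, seed=0), 5)
        val = sd.domain_adversarial_loss(Tensor(np.ones((2, 4))), [0, 0],
                                         params)
        assert val.item() == 0.0

    @pytest.mark.parametrize("grl_scale", [0.5, 1.0, 2.0])
    def test_reversed_slope_is_minus_scale_times_forward_slope(self, grl_scale):
        """Finite differences on a 2-parameter toy encoder."""
        params = init_params(ModelConfig(embed_dim=2, n_heads=1, pool_hidden=2,
                                         disc_hidden=2, n_domains=2, seed=3), 5)
        theta = np.array([0.7, -0.4])
        x = np.array([[1.0, 2.0], [0.5, -1.0]])
        d = [0, 1]

        def disc_loss(theta_arr, scale):
            enc = Tensor(theta_arr, requires_grad=True)
            z = Tensor(x) * enc          # toy encoder: elementwise scaling
            return enc, sd.domain_adversarial_loss(z, d, params,
                                                   grl_scale=scale)

        enc, loss = disc_loss(theta, grl_scale)
        loss.backward()
        reversed_grad = enc.grad.copy()

        eps = 1e-6
        forward = np.zeros(2)
        for i in range(2):
            t_hi, t_lo = theta.copy(), theta.copy()
            t_hi[i] += eps
            t_lo[i] -= eps
            forward[i] = (disc_loss(t_hi, None)[1].item()
                          - disc_loss(t_lo, None)[1].item()) / (2 * eps)
        np.testing.assert_allclose(reversed_grad, -grl_scale * forward,
                                   rtol=1e-3)


# --------------------------------------------------------------- attribution
class TestAttributionLoss:
    def test_no_lexicon_tokens_is_zero(self):
        alpha = Tensor(np.array([[0.5, 0.5]]))
        assert sd.attribution_loss(alpha, [("w1", "w2")], LEX,
                                   eta=0.3).item() == 0.0

    def test_on_target_attribution_is_zero(self):
        alpha = Tensor(np.array([[0.3, 0.7]]))
        assert sd.attribution_loss(alpha, [("good", "w")], LEX,
                                   eta=0.3).item() == pytest.approx(0.0)

    def test_off_target_arithmetic(self):
        alpha = Tensor(np.array([[0.1, 0.9]]))
        assert sd.attribution_loss(alpha, [("good", "w")], LEX,
                                   eta=0.3).item() == pytest.approx(0.04)

    def test_unnormalized_rows_rejected(self):
        with pytest.raises(ValueError, match="normalized"):
            sd.attribution_loss(Tensor(np.array([[0.9, 0.9]])),
                                [("good", "w")], LEX, eta=0.3)

    def test_matches_loop_oracle(self, rng):
        raw = rng.uniform(0.1, 1.0, size=(3, 6))
        alpha = raw / raw.sum(axis=1, keepdims=True)
        toks = [tuple(rng.choice(["good", "bad", "w", "v", "fine", "u"],
                                 size=6)) for _ in range(3)]
        got = sd.attribution_loss(Tensor(alpha), toks, LEX, eta=0.25).item()
        assert got == pytest.approx(attribution_loop(alpha, toks, LEX, 0.25),
                                    abs=1e-6)


# ------------------------------------------------------------------ alignment
class TestAlignmentLoss:
    def test_identical_pairs_are_zero(self, rng):
        z = rng.normal(size=(4, 3))
        assert sd.alignment_loss(Tensor(z), Tensor(z.copy())).item() == 0.0

    def test_unit_displacement_arithmetic(self):
        za = np.array([[1.0, 0.0]])
        zb = np.array([[0.0, 1.0]])
        assert sd.alignment_loss(Tensor(za), Tensor(zb)).item() \
            == pytest.approx(2.0)

    def test_doubling_pairs_preserves_mean(self, rng):
        za, zb = rng.normal(size=(3, 4)), rng.normal(size=(3, 4))
        one = sd.alignment_loss(Tensor(za), Tensor(zb)).item()
        two = sd.alignment_loss(Tensor(np.vstack([za, za])),
                                Tensor(np.vstack([zb, zb]))).item()
        assert one == pytest.approx(two, abs=1e-9)

    def test_empty_pair_set_is_zero(self):
        assert sd.alignment_loss(Tensor(np.zeros((0, 3))),
                                 Tensor(np.zeros((0, 3)))).item() == 0.0

    def test_scaling_z_scales_loss_quadratically(self, rng):
        za, zb = rng.normal(size=(5, 3)), rng.normal(size=(5, 3))
        base = sd.alignment_loss(Tensor(za), Tensor(zb)).item()
        scaled = sd.alignment_loss(Tensor(3.0 * za), Tensor(3.0 * zb)).item()
        assert scaled == pytest.approx(9.0 * base, rel=1e-9)

    def test_matches_loop_oracle(self, rng):
        za, zb = rng.normal(size=(4, 3)), rng.normal(size=(4, 3))
        assert sd.alignment_loss(Tensor(za), Tensor(zb)).item() \
            == pytest.approx(align_loop(za, zb), abs=1e-9)


# ------------------------------------------------------------- composition
class TestTotalObjective:
    def test_all_weights_zero_reduces_to_ce(self):
        w = LossWeights(lambda_pol=0, lambda_con=0, lambda_adv=0,
                        lambda_contrast=0, lambda_attr=0, lambda_align=0,
                        preset="full")
        total, bd = sd.total_objective({"ce": Tensor(0.7), "pol": Tensor(5.0)},
                                       w)
        assert total.item() == pytest.approx(0.7)
        assert bd.total == pytest.approx(0.7)

    def test_encoder_preset_weighted_sum(self):
        w = LossWeights(lambda_pol=0.1, lambda_con=0.2, preset="encoder")
        total, bd = sd.total_objective(
            {"ce": Tensor(0.5), "pol": Tensor(4.0),
             "con_prototype": Tensor(1.25), "adv": Tensor(99.0)}, w)
        assert total.item() == pytest.approx(1.15)
        assert bd.adv == 0.0   # inactive terms reported as zero

    def test_decoupling_preset_ignores_encoder_terms(self):
        w = LossWeights(lambda_adv=1.0, lambda_contrast=0.5, lambda_attr=0.25,
                        lambda_align=2.0, preset="decoupling")
        total, bd = sd.total_objective(
            {"ce": Tensor(1.0), "pol": Tensor(100.0), "adv": Tensor(0.2),
             "contrast_pairwise": Tensor(0.4), "attr": Tensor(0.08),
             "align": Tensor(0.1)}, w)
        assert total.item() == pytest.approx(1.0 + 0.2 + 0.2 + 0.02 + 0.2)
        assert bd.pol == 0.0

    def test_full_preset_with_all_components_zero(self):
        total, _ = sd.total_objective({}, LossWeights(preset="full"))
        assert total.item() == 0.0

    def test_breakdown_total_consistent_with_weighted_sum(self, rng):
        w = LossWeights(preset="full")
        terms = {k: Tensor(float(rng.uniform(0, 2))) for k in
                 ("ce", "pol", "con_prototype", "adv", "contrast_pairwise",
                  "attr", "align")}
        total, bd = sd.total_objective(terms, w)
        expected = (bd.ce + w.lambda_pol * bd.pol + w.lambda_con
                    * bd.con_prototype + w.lambda_adv * bd.adv
                    + w.lambda_contrast * bd.contrast_pairwise
                    + w.lambda_attr * bd.attr + w.lambda_align * bd.align)
        assert bd.total == pytest.approx(expected, abs=1e-6)

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError):
            LossWeights(lambda_adv=-0.1)
        with pytest.raises(ValueError):
            LossWeights(margin=0.0)
        with pytest.raises(ValueError):
            LossWeights(eta=1.5)


def test_prototype_bank_momentum_running_mean():
    bank = PrototypeBank(2, 2, momentum=0.9)
    bank.update(np.array([[1.0, 0.0]]), np.array([1]))
    np.testing.assert_allclose(bank.prototype(1), [1.0, 0.0])
    bank.update(np.array([[0.0, 1.0]]), np.array([1]))
    np.testing.assert_allclose(bank.prototype(1), [0.9, 0.1])
    with pytest.raises(ValueError):
        bank.prototype(0)
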