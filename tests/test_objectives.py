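"""Loss analytics: exact values, accounting identities, gradient isolation."""

import numpy as np
import pytest

from fi2ffa.networks import (
    DiscriminatorConfig,
    GeneratorConfig,
    PatchDiscriminator,
    TranslationBundle,
    UNetGenerator,
)
from fi2ffa.nn import Tensor
from fi2ffa.objectives import (
    DirectionTerms,
    LossConfig,
    cycle_losses,
    generation_loss,
    l1_loss,
    lsgan_d_loss,
    lsgan_g_loss,
    structure_loss,
    total_objectives,
)


class TestAnalyticValues:
    def test_l1_basics(self, rng):
        a = rng.random((4, 4), dtype=np.float32)
        assert float(l1_loss(a, a).data) == 0.0
        got = float(l1_loss(np.full((3, 3), 0.3), np.full((3, 3), 0.5)).data)
        assert np.isclose(got, 0.2, atol=1e-8)
        b = rng.random((4, 4), dtype=np.float32)
        assert np.isclose(float(l1_loss(a, b).data), float(l1_loss(b, a).data), atol=1e-8)
        with pytest.raises(ValueError):
            l1_loss(np.ones((2, 2)), np.ones((3, 3)))

    def test_structure_loss_is_half_against_uniform_half_prediction(self, rng):
        for frac in (0.1, 0.5, 0.9):
            label = (rng.random((16, 16)) < frac).astype(np.float32)
            pred = np.full((16, 16), 0.5, dtype=np.float32)
            assert np.isclose(float(structure_loss(pred, label).data), 0.5, atol=1e-8)

    def test_structure_loss_hand_computed_fixture(self):
        pred = np.array(
            [[0.0, 0.2, 0.4, 0.6], [0.8, 1.0, 0.1, 0.3],
             [0.5, 0.7, 0.9, 0.2], [0.4, 0.6, 0.8, 1.0]], dtype=np.float32)
        label = np.array(
            [[0, 0, 1, 1], [1, 1, 0, 0], [0, 1, 1, 0], [1, 0, 1, 1]], dtype=np.float32)
        # sum of |pred - label| written out by hand over the 16 entries
        hand = (0.0 + 0.2 + 0.6 + 0.4 + 0.2 + 0.0 + 0.1 + 0.3
                + 0.5 + 0.3 + 0.1 + 0.2 + 0.6 + 0.6 + 0.2 + 0.0) / 16
        assert np.isclose(float(structure_loss(pred, label).data), hand, atol=1e-7)

    def test_generation_loss_scales_with_lambda(self, rng):
        a = np.full((5, 5), 0.0, dtype=np.float32)
        b = np.full((5, 5), 0.1, dtype=np.float32)
        assert np.isclose(float(generation_loss(a, b, 10.0).data), 1.0, atol=1e-8)
        assert float(generation_loss(a, b, 0.0).data) == 0.0
        x, y = rng.random((6, 6)), rng.random((6, 6))
        assert np.isclose(
            float(generation_loss(x, y, 8.0).data), 2 * float(generation_loss(x, y, 4.0).data),
            atol=1e-8)

    def test_lsgan_values(self):
        ones, zeros, halves = np.ones((3, 3)), np.zeros((3, 3)), np.full((3, 3), 0.5)
        assert float(lsgan_d_loss(ones, zeros).data) == 0.0
        assert np.isclose(float(lsgan_d_loss(halves, halves).data), 0.25, atol=1e-8)
        assert float(lsgan_g_loss(ones).data) == 0.0
        assert float(lsgan_g_loss(zeros).data) == 1.0
        assert np.isclose(float(lsgan_g_loss(halves).data), 0.25, atol=1e-8)

    def test_lsgan_d_minimized_at_target_codes(self):
        # grid search over constant discriminator outputs
        grid = np.linspace(-0.5, 1.5, 41)
        vals = {(r, f): float(lsgan_d_loss(np.full((2, 2), r), np.full((2, 2), f)).data)
                for r in grid for f in grid}
        best = min(vals, key=vals.get)
        assert np.isclose(best[0], 1.0) and np.isclose(best[1], 0.0)

    def test_cycle_losses_identity_and_flip(self, rng):
        x = Tensor((rng.random((1, 3, 8, 8)) > 0.5).astype(np.float32))
        s = (rng.random((1, 1, 8, 8)) > 0.7).astype(np.float32)
        perfect = TranslationBundle(x=x, y_hat=x, s_hat=Tensor(s), x_cyc=x, s_cyc=Tensor(s))
        ci, cs = cycle_losses(perfect, s, 10.0)
        assert float(ci.data) == 0.0 and float(cs.data) == 0.0
        flipped = TranslationBundle(x=x, y_hat=x, s_hat=Tensor(s),
                                    x_cyc=Tensor(1.0 - x.data), s_cyc=Tensor(s))
        ci, _ = cycle_losses(flipped, s, 7.0)
        assert np.isclose(float(ci.data), 7.0, atol=1e-6)  # binary x: |1-2x| = 1
        with pytest.raises(ValueError):
            cycle_losses(TranslationBundle(x=x, y_hat=x, s_hat=None), s, 1.0)

    def test_cycle_losses_hand_computed_fixture(self):
        x = np.array([[0.0, 0.5], [1.0, 0.25]], dtype=np.float32).reshape(1, 1, 2, 2)
        xc = np.array([[0.1, 0.4], [0.7, 0.45]], dtype=np.float32).reshape(1, 1, 2, 2)
        s = np.array([[1, 0], [1, 0]], dtype=np.float32).reshape(1, 1, 2, 2)
        sc = np.array([[0.9, 0.2], [0.6, 0.1]], dtype=np.float32).reshape(1, 1, 2, 2)
        b = TranslationBundle(x=Tensor(np.repeat(x, 3, 1)), y_hat=Tensor(x),
                              s_hat=Tensor(s), x_cyc=Tensor(np.repeat(xc, 3, 1)), s_cyc=Tensor(sc))
        ci, cs = cycle_losses(b, s, 10.0)
        assert np.isclose(float(ci.data), 10.0 * (0.1 + 0.1 + 0.3 + 0.2) / 4, atol=1e-6)
        assert np.isclose(float(cs.data), 10.0 * (0.1 + 0.2 + 0.4 + 0.1) / 4, atol=1e-6)


def _perfect_direction(rng):
    x = Tensor((rng.random((1, 3, 8, 8))).astype(np.float32))
    s = (rng.random((1, 1, 8, 8)) > 0.6).astype(np.float32)
    bundle = TranslationBundle(x=x, y_hat=Tensor(x.data.copy()), s_hat=Tensor(s.copy()),
                               x_cyc=Tensor(x.data.copy()), s_cyc=Tensor(s.copy()))
    ones = np.ones((1, 1, 3, 3), dtype=np.float32)
    zeros = np.zeros_like(ones)
    return DirectionTerms(
        bundle=bundle, source_structure=s, target_image=Tensor(x.data.copy()),
        g_scores_image=Tensor(ones), g_scores_structure=Tensor(ones),
        d_scores={"ffa": (Tensor(ones), Tensor(zeros)), "fis": (Tensor(ones), Tensor(zeros))},
    )


class TestTotalObjective:
    def test_perfect_oracle_stubs_give_zero_totals(self, rng):
        fwd = _perfect_direction(rng)
        bwd = _perfect_direction(rng)
        bwd.d_scores = {"fi": bwd.d_scores["ffa"], "ffas": bwd.d_scores["fis"]}
        tg, td, comps = total_objectives(fwd, bwd, LossConfig())
        assert float(tg.data) == 0.0 and float(td.data) == 0.0
        assert comps.total_g == 0.0 and all(v == 0.0 for v in comps.as_dict().values())

    def test_total_equals_sum_of_reported_parts(self, rng):
        fwd, bwd = _imperfect_pair(rng)
        _, _, comps = total_objectives(fwd, bwd, LossConfig())
        assert np.isclose(comps.total_g, sum(comps.generator_parts().values()), atol=1e-6)
        d_sum = comps.adv_d_fi + comps.adv_d_ffa + comps.adv_d_fis + comps.adv_d_ffas
        assert np.isclose(comps.total_d, d_sum, atol=1e-6)

    def test_disabling_ssm_and_cl_reduces_to_paired_lsgan_objective(self, rng):
        fwd, bwd = _imperfect_pair(rng)
        cfg = LossConfig()
        tg, _, _ = total_objectives(fwd, bwd, cfg, use_ssm=False, use_cl=False)
        # independently composed reduced objective
        expected = 0.0
        for d, lam in ((fwd, cfg.lambda2), (bwd, cfg.lambda1)):
            expected += float(generation_loss(d.bundle.y_hat, d.target_image, lam).data)
            expected += float(lsgan_g_loss(d.g_scores_image).data)
        assert np.isclose(float(tg.data), expected, atol=1e-6)

    def test_deviation_scaling_scales_l1_components(self, rng):
        x = rng.random((1, 3, 8, 8)).astype(np.float32)
        t = rng.random((1, 3, 8, 8)).astype(np.float32)
        base = float(l1_loss(x, t).data)
        scaled = float(l1_loss(t + 3.0 * (x - t), t).data)
        assert np.isclose(scaled, 3.0 * base, atol=1e-5)


def _imperfect_pair(rng):
    def mk(critics):
        x = Tensor(rng.random((1, 3, 8, 8)).astype(np.float32))
        s = (rng.random((1, 1, 8, 8)) > 0.6).astype(np.float32)
        bundle = TranslationBundle(
            x=x, y_hat=Tensor(rng.random((1, 3, 8, 8)).astype(np.float32)),
            s_hat=Tensor(rng.random((1, 1, 8, 8)).astype(np.float32)),
            x_cyc=Tensor(rng.random((1, 3, 8, 8)).astype(np.float32)),
            s_cyc=Tensor(rng.random((1, 1, 8, 8)).astype(np.float32)),
        )
        sc = lambda: Tensor(rng.random((1, 1, 3, 3)).astype(np.float32))
        return DirectionTerms(
            bundle=bundle, source_structure=s,
            target_image=Tensor(rng.random((1, 3, 8, 8)).astype(np.float32)),
            g_scores_image=sc(), g_scores_structure=sc(),
            d_scores={c: (sc(), sc()) for c in critics},
        )

    return mk(("ffa", "fis")), mk(("fi", "ffas"))


class TestGradientIsolation:
    def test_adversarial_losses_touch_only_their_own_network(self):
        rng = np.random.default_rng(0)
        gen = UNetGenerator(GeneratorConfig.tiny(), rng=rng)
        disc = PatchDiscriminator(DiscriminatorConfig(3, 2, 8), rng=rng)
        x = Tensor(rng.random((1, 3, 16, 16)).astype(np.float32))
        fake, _ = gen(x, with_structure=False)

        # discriminator update path: fake detached
        d_loss = lsgan_d_loss(disc(Tensor(rng.random((1, 3, 16, 16)).astype(np.float32))),
                              disc(fake.detach()))
        d_loss.backward()
        assert all(p.grad is None for p in gen.parameters())
        assert any(p.grad is not None and np.abs(p.grad).sum() > 0 for p in disc.parameters())

        gen.zero_grad()
        disc.zero_grad()
        # generator update path: gradients flow through D into G, and only
        # the generator optimizer steps -- assert G actually receives grads
        g_loss = lsgan_g_loss(disc(fake))
        g_loss.backward()
        assert any(p.grad is not None and np.abs(p.grad).sum() > 0 for p in gen.parameters())
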