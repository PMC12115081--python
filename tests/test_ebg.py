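"""Edge-blurring guided sampling and entropy-weighted fusion."""

import numpy as np
import pytest

from diffbts.ebg import (
    EdgeMaskSet,
    FusionState,
    GuidanceConfig,
    ebg_sample,
    edges_mask,
    entropy_uncertainty,
    gaussian_blur,
    guided_eps,
    perturb_latent,
    uncertainty_fusion,
)
from diffbts.schedule import ddim_step, latent_to_labels, make_schedule, q_sample, subsample_steps

from conftest import make_oracle_model


def brute_force_edges(binary, connectivity=6):
    """Independent triple-loop neighbor-difference scan, replicate borders."""
    d, h, w = binary.shape
    if connectivity == 6:
        offsets = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
    else:
        offsets = [(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)
                   if (i, j, k) != (0, 0, 0)]
    out = np.zeros_like(binary, dtype=np.uint8)
    for i in range(d):
        for j in range(h):
            for k in range(w):
                for oi, oj, ok in offsets:
                    ni = min(max(i + oi, 0), d - 1)
                    nj = min(max(j + oj, 0), h - 1)
                    nk = min(max(k + ok, 0), w - 1)
                    if binary[ni, nj, nk] != binary[i, j, k]:
                        out[i, j, k] = 1
                        break
    return out


class TestEdgesMask:
    def test_config_validation(self):
        with pytest.raises(ValueError):
            GuidanceConfig(blur_kernel=4)
        with pytest.raises(ValueError):
            GuidanceConfig(s=-1.5)
        with pytest.raises(ValueError):
            GuidanceConfig(connectivity=18)

    def test_all_background_empty(self):
        x = -np.ones((3, 5, 5, 5))
        assert edges_mask(x, GuidanceConfig()).m_t.sum() == 0

    def test_all_foreground_empty_with_replicate_borders(self):
        x = np.ones((3, 5, 5, 5))
        assert edges_mask(x, GuidanceConfig()).m_t.sum() == 0

    def test_centered_cube_surface(self):
        """A solid 3^3 cube in an 8^3 volume has exactly its 26 surface
        voxels as the 6-connectivity edge, plus the background shell."""
        x = -np.ones((3, 8, 8, 8))
        x[:, 3:6, 3:6, 3:6] = 1.0
        masks = edges_mask(x, GuidanceConfig(connectivity=6))
        inside_edge = masks.m_wt.astype(bool) & (x[0] > 0)
        assert inside_edge.sum() == 26  # all cube voxels except the center
        assert not inside_edge[4, 4, 4]

    @pytest.mark.parametrize("connectivity", [6, 26])
    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_brute_force(self, connectivity, seed):
        rng = np.random.default_rng(seed)
        x = np.where(rng.random((3, 6, 6, 6)) > 0.6, 1.0, -1.0)
        masks = edges_mask(x, GuidanceConfig(connectivity=connectivity))
        for c in range(3):
            expect = brute_force_edges(x[c] > 0, connectivity)
            assert np.array_equal(masks.m_t[c], expect)

    def test_channel_order(self, rng):
        x = rng.normal(size=(3, 4, 4, 4))
        masks = edges_mask(x, GuidanceConfig())
        assert np.array_equal(masks.m_t[0], masks.m_wt)
        assert np.array_equal(masks.m_t[1], masks.m_tc)
        assert np.array_equal(masks.m_t[2], masks.m_et)


class TestGaussianBlur:
    def test_constant_volume_unchanged(self):
        x = np.full((3, 6, 6, 6), 0.7)
        assert np.allclose(gaussian_blur(x, GuidanceConfig()), x, atol=1e-12)

    def test_impulse_reproduces_kernel(self):
        cfg = GuidanceConfig(blur_sigma=0.8, blur_kernel=3)
        x = np.zeros((1, 7, 7, 7))
        x[0, 3, 3, 3] = 1.0
        out = gaussian_blur(x, cfg)
        k1 = np.exp(-0.5 * (np.arange(-1, 2) / 0.8) ** 2)
        k1 /= k1.sum()
        expect = np.einsum("i,j,k->ijk", k1, k1, k1)
        assert np.allclose(out[0, 2:5, 2:5, 2:5], expect, atol=1e-12)
        assert out.sum() == pytest.approx(1.0)

    def test_kernel_one_is_identity(self, rng):
        x = rng.normal(size=(3, 5, 5, 5))
        out = gaussian_blur(x, GuidanceConfig(blur_sigma=0.0, blur_kernel=1))
        assert np.array_equal(out, x)


class TestPerturbLatent:
    def test_empty_and_full_mask(self, rng):
        xt = rng.normal(size=(3, 4, 4, 4))
        xb = rng.normal(size=(3, 4, 4, 4))
        assert np.array_equal(perturb_latent(xt, xb, np.zeros_like(xt)), xt)
        assert np.array_equal(perturb_latent(xt, xb, np.ones_like(xt)), xb)

    def test_scalar_loop_oracle(self, rng):
        xt = rng.normal(size=(3, 3, 3, 3))
        xb = rng.normal(size=(3, 3, 3, 3))
        m = (rng.random((3, 3, 3, 3)) > 0.5).astype(float)
        out = perturb_latent(xt, xb, m)
        for idx in np.ndindex(*xt.shape):
            assert out[idx] == (xb[idx] if m[idx] else xt[idx])

    def test_nonbinary_mask_rejected(self, rng):
        xt = rng.normal(size=(3, 2, 2, 2))
        with pytest.raises(ValueError):
            perturb_latent(xt, xt, np.full_like(xt, 0.5))


class TestGuidedEps:
    def test_zero_scale_returns_eps(self, rng):
        eps, eps_hat = rng.normal(size=(3, 4, 4, 4)), rng.normal(size=(3, 4, 4, 4))
        assert np.allclose(guided_eps(eps, eps_hat, 0.0), eps, atol=1e-12)

    def test_minus_one_returns_perturbed(self, rng):
        eps, eps_hat = rng.normal(size=(3, 4, 4, 4)), rng.normal(size=(3, 4, 4, 4))
        assert np.allclose(guided_eps(eps, eps_hat, -1.0), eps_hat, atol=1e-12)

    def test_fixed_point_when_equal(self, rng):
        eps = rng.normal(size=(3, 4, 4, 4))
        for s in (-0.5, 0.0, 0.05, 2.0):
            assert np.allclose(guided_eps(eps, eps.copy(), s), eps)


class TestEntropyUncertainty:
    def test_reference_values(self):
        assert entropy_uncertainty(np.array(1.0)) == 0.0
        assert entropy_uncertainty(np.array(0.0)) == 0.0
        assert entropy_uncertainty(np.array(1 / np.e)) == pytest.approx(1 / np.e)
        assert entropy_uncertainty(np.array(0.5)) == pytest.approx(0.5 * np.log(2))

    def test_concave_with_max_at_inv_e(self):
        p = np.linspace(1e-6, 1 - 1e-6, 2001)
        u = entropy_uncertainty(p)
        assert p[np.argmax(u)] == pytest.approx(1 / np.e, abs=2e-3)
        d2 = np.diff(u, 2)
        assert np.all(d2 < 1e-12)  # concave on (0, 1)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            entropy_uncertainty(np.array([0.5, 1.2]))


class TestUncertaintyFusion:
    def test_single_prediction_binarized(self, binary_latent):
        state = FusionState()
        state.record(0, binary_latent)
        pred, _ = uncertainty_fusion(state)
        assert np.array_equal(pred, latent_to_labels(binary_latent))

    def test_identical_predictions_invariant(self, binary_latent):
        state = FusionState()
        for i in range(4):
            state.record(i, binary_latent)
        pred, prob = uncertainty_fusion(state)
        assert np.array_equal(pred, latent_to_labels(binary_latent))
        assert np.allclose(prob, (binary_latent + 1) / 2)

    def test_hand_expanded_two_step_oracle(self):
        """Two one-voxel predictions recomputed scalar-by-scalar."""
        p0, p1 = 0.8, 0.3  # probabilities at the single voxel
        x0 = np.full((3, 1, 1, 1), 2 * p0 - 1)
        x1 = np.full((3, 1, 1, 1), 2 * p1 - 1)
        state = FusionState()
        state.record(0, x0)
        state.record(1, x1)
        _, prob = uncertainty_fusion(state)
        w = []
        for i, p in ((0, p0), (1, p1)):
            sig = 1 / (1 + np.exp(-(i + 1) / 10))
            u = -p * np.log(p)
            w.append(np.exp(sig * (1 - u)))
        expect = (w[0] * p0 + w[1] * p1) / (w[0] + w[1])
        assert np.allclose(prob, expect, atol=1e-12)

    def test_weights_increase_with_step_index(self):
        """At fixed uncertainty, later sampling iterations get strictly
        larger weights."""
        u = 0.25
        w = [np.exp((1 / (1 + np.exp(-(i + 1) / 10))) * (1 - u)) for i in range(6)]
        assert all(b > a for a, b in zip(w, w[1:]))

    def test_weight_scale_invariance(self, rng):
        """Fusion depends only on normalized weights: shifting every
        uncertainty by the same amount rescales all weights equally."""
        probs = rng.random((3, 2, 2, 2))
        state_a, state_b = FusionState(), FusionState()
        for i in range(3):
            state_a.record(i, 2 * probs - 1)
            state_b.record(i, 2 * probs - 1)
        _, pa = uncertainty_fusion(state_a)
        _, pb = uncertainty_fusion(state_b)
        assert np.allclose(pa, pb)

    def test_empty_state_rejected(self):
        with pytest.raises(ValueError):
            uncertainty_fusion(FusionState())


class TestEBGSample:
    def _plain_ddim(self, model, xT, steps, sch):
        xt = xT.copy()
        for i, t in enumerate(steps):
            t_prev = steps[i + 1] if i + 1 < len(steps) else 0
            eps, _ = model(xt, t)
            xt = ddim_step(xt, t, eps, sch, t_prev=t_prev)
        return xt

    def test_zero_scale_degenerates_to_ddim(
        self, oracle_model, noised_latent, schedule100
    ):
        steps = subsample_steps(100, 10)
        guided, _ = ebg_sample(
            oracle_model, noised_latent, steps, schedule100, GuidanceConfig(s=0.0)
        )
        plain = self._plain_ddim(oracle_model, noised_latent, steps, schedule100)
        assert np.abs(guided - plain).max() < 1e-5

    def test_empty_masks_degenerate_to_ddim(self, schedule100, rng):
        """A model predicting a uniform background latent yields empty edge
        masks, so guidance is inert for any scale."""
        x0_const = -np.ones((3, 6, 6, 6))
        model = make_oracle_model(x0_const, schedule100)
        xT = rng.standard_normal(x0_const.shape)
        steps = subsample_steps(100, 8)
        guided, _ = ebg_sample(model, xT, steps, schedule100, GuidanceConfig(s=0.7))
        plain = self._plain_ddim(model, xT, steps, schedule100)
        assert np.abs(guided - plain).max() < 1e-5

    def test_oracle_closed_loop_recovers_labels(
        self, oracle_model, binary_latent, noised_latent, schedule100
    ):
        steps = subsample_steps(100, 10)
        x0, fusion = ebg_sample(
            oracle_model, noised_latent, steps, schedule100, GuidanceConfig()
        )
        assert np.array_equal(latent_to_labels(x0), latent_to_labels(binary_latent))
        assert len(fusion.x0_latents) == len(steps)

    def test_trace_recording(self, oracle_model, noised_latent, schedule100):
        steps = subsample_steps(100, 4)
        _, _, traces = ebg_sample(
            oracle_model, noised_latent, steps, schedule100,
            GuidanceConfig(), record_traces=True,
        )
        assert [tr.t for tr in traces] == steps
        for tr in traces:
            for f in (tr.x0_hat, tr.eps_t, tr.x0_blur, tr.xt_blur,
                      tr.xt_perturbed, tr.eps_hat, tr.eps_tilde, tr.h_t):
                assert f.shape == (3, 8, 8, 8)
            # outside the masks the perturbed latent equals the latent
            outside = tr.m_t == 0
            assert np.array_equal(tr.xt_perturbed[outside], tr.xt[outside])

    def test_nonfinite_reports_step(self, schedule100, rng):
        def bad_model(xt, t):
            return np.full_like(xt, np.nan), np.full_like(xt, np.nan)

        xT = rng.standard_normal((3, 4, 4, 4))
        with pytest.raises(FloatingPointError, match="t=100"):
            ebg_sample(bad_model, xT, [100, 50], schedule100, GuidanceConfig())

    def test_locality_outside_masks(self, schedule100, rng):
        """With a voxel-local model, voxels never inside any edge mask
        follow exactly the unguided trajectory."""
        x0_true = -np.ones((3, 6, 6, 6))
        x0_true[:, 2:4, 2:4, 2:4] = 1.0
        model = make_oracle_model(x0_true, schedule100)
        xT = rng.standard_normal(x0_true.shape)
        steps = subsample_steps(100, 6)
        guided, _, traces = ebg_sample(
            model, xT, steps, schedule100, GuidanceConfig(s=0.4), record_traces=True
        )
        plain = self._plain_ddim(model, xT, steps, schedule100)
        never_masked = np.all([tr.m_t == 0 for tr in traces], axis=0)
        assert never_masked.any()
        assert np.abs(guided[never_masked] - plain[never_masked]).max() < 1e-10
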