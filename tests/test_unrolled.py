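"""Prox-nets, the unrolled iteration, training, and the subsumption embedding."""

import numpy as np
import pytest

from eqrecon import (
    CyclicGroup,
    FeatureField,
    NetConfig,
    RadonGeometry,
    build_net,
    equivariance_residual,
    erm_loss,
    generate_cartesian_mask,
    load_checkpoint,
    make_dataset,
    mri_operator,
    PhantomSpec,
    prox_net_apply,
    prox_tikhonov,
    proximal_gradient,
    radon_apply,
    radon_operator,
    save_checkpoint,
    subsumption_embed,
    tikhonov_functional,
    train_erm,
    trivial_representation,
    unrolled_reconstruct,
)
from eqrecon.unrolled import _loss_and_grads, _net_params, _set_net_params


@pytest.fixture(scope="module")
def small_ct():
    geom = RadonGeometry(16, n_angles=10)
    return geom, radon_operator(geom)


@pytest.fixture(scope="module")
def small_cfg():
    return NetConfig(modality="ct", width_product=8, it=3)


class TestBuildNet:
    def test_channel_accounting_ct(self, small_ct, small_cfg):
        _, op = small_ct
        net = build_net("equivariant", small_cfg, op, seed=0)
        lift = net.prox_nets[0].lift.layer
        proj = net.prox_nets[0].project.layer
        assert lift.c_in == 1 + 5 + 1  # image + memory + gradient channels
        assert proj.c_out == 1 + 5

    def test_channel_accounting_mri(self):
        samp = generate_cartesian_mask((16, 16), 0.4, 0.1, seed=0)
        op = mri_operator(samp)
        cfg = NetConfig(modality="mri", width_product=8, it=2)
        net = build_net("equivariant", cfg, op, seed=0)
        assert net.prox_nets[0].lift.layer.c_in == 2 + 5 + 2
        assert net.prox_nets[0].project.layer.c_out == 2 + 5

    def test_width_matching_field_counts(self, small_ct):
        _, op = small_ct
        cfg = NetConfig(modality="ct", width_product=96, it=1)
        eq = build_net("equivariant", cfg, op, seed=0)
        odd = build_net("ordinary", cfg, op, seed=0)
        # 96 = |Z4| * 24 regular fields; ordinary counterpart has 96 channels
        assert len(eq.prox_nets[0].lift.layer.out_types) == 24
        assert all(r.dim == 4 for r in eq.prox_nets[0].lift.layer.out_types)
        assert odd.prox_nets[0].lift.kernel.shape[0] == 96

    def test_group_must_divide_width(self, small_ct):
        _, op = small_ct
        with pytest.raises(ValueError):
            build_net("equivariant", NetConfig(width_product=30), op)

    def test_z1_equivariant_matches_ordinary_param_count(self, small_ct):
        _, op = small_ct
        cfg = NetConfig(modality="ct", width_product=8, it=1, group_order=1)
        eq = build_net("equivariant", cfg, op, seed=0)
        odd = build_net("ordinary", cfg, op, seed=0)

        def count(net):
            return sum(
                v.size
                for tree in _net_params(net)
                for lp in tree.values()
                for v in lp.values()
            )

        # the Z1 kernel constraint is empty; biases are tied per (scalar) field
        assert count(eq) == count(odd)

    def test_intermediate_initialised_to_zero(self, small_ct, small_cfg):
        _, op = small_ct
        for flavour in ("equivariant", "ordinary"):
            net = build_net(flavour, small_cfg, op, seed=3)
            p = net.prox_nets[0].intermediate.params()
            assert all(np.all(v == 0.0) for v in p.values())

    def test_untied_weights_across_iterations(self, small_ct, small_cfg, rng):
        _, op = small_ct
        net = build_net("ordinary", small_cfg, op, seed=0)
        before = net.prox_nets[1].lift.kernel.copy()
        net.prox_nets[0].lift.kernel += 1.0
        np.testing.assert_array_equal(net.prox_nets[1].lift.kernel, before)


class TestProxNet:
    def test_zero_intermediate_makes_residual_branch_identity(self, small_ct, small_cfg, rng):
        _, op = small_ct
        net = build_net("ordinary", small_cfg, op, seed=1)
        pnet = net.prox_nets[0]
        u = rng.normal(size=(1, 16, 16))
        s = rng.normal(size=(5, 16, 16))
        g = rng.normal(size=(1, 16, 16))
        u1, s1, _ = prox_net_apply(pnet, u, s, g)
        x = np.concatenate([u, s, g])
        direct = pnet.project.forward(pnet.lift.forward(x))
        np.testing.assert_allclose(np.concatenate([u1, s1]), direct, atol=1e-12)

    def test_zero_input_zero_bias_gives_zero(self, small_ct, small_cfg):
        _, op = small_ct
        net = build_net("equivariant", small_cfg, op, seed=1)
        z = np.zeros((1, 16, 16))
        u1, s1, _ = prox_net_apply(net.prox_nets[0], z, np.zeros((5, 16, 16)), z)
        np.testing.assert_allclose(u1, 0.0, atol=1e-14)
        np.testing.assert_allclose(s1, 0.0, atol=1e-14)

    def test_equivariant_prox_net_commutes_with_quarter_turns(self, small_ct, rng):
        _, op = small_ct
        cfg = NetConfig(modality="ct", width_product=8, it=1, padding="circular")
        net = build_net("equivariant", cfg, op, seed=2)
        pnet = net.prox_nets[0]
        # exercise the nonlinearity too
        p = pnet.intermediate.params()
        for k in p:
            p[k] = p[k] + 0.1 * rng.normal(size=p[k].shape)
        pnet.intermediate.set_params(p)
        triv = trivial_representation(CyclicGroup(4))

        def mapfn(f):
            u, s, g = f.values[:1], f.values[1:6], f.values[6:]
            un, sn, _ = prox_net_apply(pnet, u, s, g)
            return FeatureField(np.concatenate([un, sn]), [triv] * 6)

        fld = FeatureField(rng.normal(size=(7, 16, 16)), [triv] * 7)
        for k in range(4):
            assert equivariance_residual(mapfn, fld, k, (2, 3)) <= 1e-5


class TestUnrolledReconstruct:
    def test_zero_nets_give_zero_output(self, small_ct, small_cfg, rng):
        geom, op = small_ct
        net = build_net("ordinary", small_cfg, op, seed=0)
        for pnet in net.prox_nets:
            for layer in pnet.layers().values():
                p = layer.params()
                for k in p:
                    p[k] = np.zeros_like(p[k])
                layer.set_params(p)
        y = rng.normal(size=geom.sinogram_shape)
        assert np.all(unrolled_reconstruct(net, y) == 0.0)

    def test_output_finite_and_image_shaped(self, small_ct, small_cfg, rng):
        geom, op = small_ct
        net = build_net("equivariant", small_cfg, op, seed=4)
        out = unrolled_reconstruct(net, rng.normal(size=geom.sinogram_shape))
        assert out.shape == (16, 16)
        assert np.all(np.isfinite(out))

    def test_classical_prox_substitution_reproduces_proximal_gradient(self, small_ct, rng):
        # Alg. 2 with the classical update prox_{tau J}(u - tau g) per step
        # must equal Alg. 1 exactly
        geom, op = small_ct
        lam, tau, it = 0.5, 0.01, 5
        u_true = rng.normal(size=(16, 16))
        y = radon_apply(u_true, geom)

        def classical(u, s, g):
            return prox_tikhonov(u - g, tau, lam), s

        cfg = NetConfig(modality="ct", width_product=8, it=it, grad_scale=tau)
        net = build_net("ordinary", cfg, op, seed=0)
        net.prox_nets = [classical] * it
        ours = unrolled_reconstruct(net, y)
        ref, _ = proximal_gradient(
            y, op, tikhonov_functional(lam), n_iter=it, tau=tau
        )
        np.testing.assert_allclose(ours, ref, atol=1e-12)

    def test_nan_iterate_aborts_with_index(self, small_ct, small_cfg, rng):
        geom, op = small_ct
        net = build_net("ordinary", small_cfg, op, seed=0)
        net.prox_nets[1] = lambda u, s, g: (u * np.nan, s)
        with pytest.raises(FloatingPointError, match="iteration 2"):
            unrolled_reconstruct(net, rng.normal(size=geom.sinogram_shape))


class TestTraining:
    def _tiny_problem(self, rng, n=3):
        geom = RadonGeometry(16, n_angles=10)
        op = radon_operator(geom)
        ds = make_dataset(n, "ct", PhantomSpec(size=16), seed=0, geometry=geom)
        return geom, op, ds

    @pytest.mark.parametrize("flavour", ["equivariant", "ordinary"])
    def test_parameter_gradients_match_finite_differences(self, flavour, rng):
        geom, op, ds = self._tiny_problem(rng)
        cfg = NetConfig(modality="ct", width_product=8, it=2)
        net = build_net(flavour, cfg, op, seed=2)
        for pnet in net.prox_nets:  # make the intermediate branch active
            for layer in pnet.layers().values():
                p = layer.params()
                for k in p:
                    p[k] = p[k] + 0.05 * rng.normal(size=p[k].shape)
                layer.set_params(p)
        u_true, y = ds.images[0], ds.measurements[0]
        _, grads = _loss_and_grads(net, u_true, y)
        params = _net_params(net)
        check_rng = np.random.default_rng(0)
        for _ in range(4):
            i = int(check_rng.integers(len(params)))
            ln = ["lift", "intermediate", "project"][int(check_rng.integers(3))]
            key = list(params[i][ln])[int(check_rng.integers(len(params[i][ln])))]
            arr = params[i][ln][key]
            idx = tuple(int(check_rng.integers(d)) for d in arr.shape)
            eps, old = 1e-6, arr[idx]
            arr[idx] = old + eps
            _set_net_params(net, params)
            lp = _loss_and_grads(net, u_true, y)[0]
            arr[idx] = old - eps
            _set_net_params(net, params)
            lm = _loss_and_grads(net, u_true, y)[0]
            arr[idx] = old
            _set_net_params(net, params)
            fd = (lp - lm) / (2 * eps)
            an = grads[i][ln][key][idx]
            assert fd == pytest.approx(an, rel=1e-3, abs=1e-4)

    @pytest.mark.parametrize("flavour", ["equivariant", "ordinary"])
    def test_training_reduces_empirical_risk(self, flavour, rng):
        geom, op, ds = self._tiny_problem(rng)
        cfg = NetConfig(modality="ct", width_product=8, it=2)
        finals, inits = [], []
        for seed in range(3):
            net = build_net(flavour, cfg, op, seed=seed)
            inits.append(erm_loss(net, ds))
            train_erm(net, ds, n_iters=60, lr=1e-3, seed=seed + 10)
            finals.append(erm_loss(net, ds))
        assert np.median(finals) < np.median(inits)

    def test_training_deterministic_given_seed(self, rng):
        geom, op, ds = self._tiny_problem(rng)
        cfg = NetConfig(modality="ct", width_product=8, it=2)
        outs = []
        for _ in range(2):
            net = build_net("ordinary", cfg, op, seed=5)
            train_erm(net, ds, n_iters=20, lr=1e-3, seed=6)
            outs.append(unrolled_reconstruct(net, ds.measurements[0]))
        np.testing.assert_array_equal(outs[0], outs[1])

    def test_zero_target_dataset_drives_loss_down(self, rng):
        geom, op, _ = self._tiny_problem(rng)
        cfg = NetConfig(modality="ct", width_product=8, it=2)
        net = build_net("ordinary", cfg, op, seed=1)
        zeros = [(np.zeros((16, 16)), rng.normal(size=geom.sinogram_shape))]
        trace = train_erm(net, zeros, n_iters=150, lr=1e-2, seed=0)
        assert trace[-1] < 0.05 * trace[0]


class TestSubsumption:
    def test_embedded_ordinary_net_matches_bitwise(self, small_ct, rng):
        geom, op = small_ct
        cfg = NetConfig(modality="ct", width_product=8, it=3)
        eq = build_net("equivariant", cfg, op, seed=7)
        for pnet in eq.prox_nets:  # nonzero intermediate exercises phi
            p = pnet.intermediate.params()
            for k in p:
                p[k] = p[k] + 0.1 * rng.normal(size=p[k].shape)
            pnet.intermediate.set_params(p)
        emb = subsumption_embed(eq)
        y = rng.normal(size=geom.sinogram_shape)
        a = unrolled_reconstruct(eq, y)
        b = unrolled_reconstruct(emb, y)
        assert np.abs(a - b).max() <= 1e-12

    def test_zero_equivariant_net_embeds_to_zero(self, small_ct, small_cfg):
        _, op = small_ct
        eq = build_net("equivariant", small_cfg, op, seed=0)
        for pnet in eq.prox_nets:
            for layer in pnet.layers().values():
                p = layer.params()
                for k in p:
                    p[k] = np.zeros_like(p[k])
                layer.set_params(p)
        emb = subsumption_embed(eq)
        for pnet in emb.prox_nets:
            assert all(np.all(v == 0.0) for v in pnet.lift.params().values())

    def test_embedded_net_gradients_finite(self, small_ct, rng):
        geom, op = small_ct
        cfg = NetConfig(modality="ct", width_product=8, it=2)
        emb = subsumption_embed(build_net("equivariant", cfg, op, seed=3))
        u = rng.normal(size=(16, 16))
        y = radon_apply(u, geom)
        _, grads = _loss_and_grads(emb, u, y)
        for tree in grads:
            for lp in tree.values():
                for v in lp.values():
                    assert np.all(np.isfinite(v))

    def test_ordinary_net_rejected(self, small_ct, small_cfg):
        _, op = small_ct
        with pytest.raises(ValueError):
            subsumption_embed(build_net("ordinary", small_cfg, op, seed=0))


class TestCheckpoint:
    def test_roundtrip_preserves_outputs(self, small_ct, small_cfg, tmp_path, rng):
        geom, op = small_ct
        net = build_net("equivariant", small_cfg, op, seed=9)
        path = tmp_path / "ckpt.h5"
        save_checkpoint(path, net, extra={"note": "test"})
        loaded = load_checkpoint(path, op)
        y = rng.normal(size=geom.sinogram_shape)
        np.testing.assert_array_equal(
            unrolled_reconstruct(net, y), unrolled_reconstruct(loaded, y)
        )
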