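"""Architecture assembly, shape contracts and gradient correctness."""

import numpy as np
import pytest

from psaeegnet import (AblationSpec, NetworkConfig, PSAConfig, build,
                       stage_shapes, variant_config)
from psaeegnet.training import _ce_grad, weighted_cross_entropy

TABLE_SHAPES = {
    "temporal_conv": (8, 62, 250),
    "spatial_depthwise": (16, 1, 250),
    "psa_psfe": (16, 1, 250),
    "pool1": (16, 1, 31),
    "separable_depthwise": (16, 1, 31),
    "psa_dtfe": (16, 1, 31),
    "pool2": (16, 1, 4),
    "flatten": (64,),
    "classifier": (2,),
}


class TestStageShapes:
    def test_default_walk_reproduces_reference_table(self):
        shapes = dict(stage_shapes(NetworkConfig()))
        assert shapes["input"] == (62, 250)
        assert shapes["reshape"] == (1, 62, 250)
        for name, expected in TABLE_SHAPES.items():
            assert shapes[name] == expected, name

    def test_double_samples_doubles_prepool_lengths(self):
        shapes = dict(stage_shapes(NetworkConfig(n_samples=500)))
        assert shapes["temporal_conv"] == (8, 62, 500)
        assert shapes["spatial_depthwise"] == (16, 1, 500)
        assert shapes["pool1"] == (16, 1, 62)  # 500 // 8

    def test_eegnet_variant_drops_psa_rows(self):
        cfg = variant_config(NetworkConfig(), AblationSpec("EEGNet"))
        names = [n for n, _ in stage_shapes(cfg)]
        assert "psa_psfe" not in names and "psa_dtfe" not in names
        full = [n for n, _ in stage_shapes(NetworkConfig())]
        assert [n for n in full if not n.startswith(("psa", "bn3", "elu2"))] == names


class TestForward:
    def test_probe_stage_outputs_match_symbolic_walk(self):
        net = build(NetworkConfig(), seed=0)
        x = np.random.default_rng(0).normal(size=(3, 62, 250)).astype(np.float32)
        actual = {n: o.shape[1:] for n, o in net.stage_outputs(x)}
        for name, expected in dict(stage_shapes(net.config)).items():
            if name == "input":
                continue
            assert actual[name] == tuple(expected), name

    def test_rows_sum_to_one(self):
        net = build(NetworkConfig(), seed=1)
        x = np.random.default_rng(1).normal(size=(5, 62, 250)).astype(np.float32)
        p = net.forward(x)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)
        assert p.shape == (5, 2)

    def test_eval_mode_deterministic(self):
        net = build(NetworkConfig(), seed=2)
        x = np.random.default_rng(2).normal(size=(4, 62, 250)).astype(np.float32)
        np.testing.assert_array_equal(net.forward(x), net.forward(x))

    def test_zero_classifier_gives_half(self, tiny_config):
        net = build(tiny_config, seed=0)
        clf = dict(net.net.layers)["classifier"]
        clf.params["w"][...] = 0.0
        clf.params["b"][...] = 0.0
        x = np.random.default_rng(3).normal(size=(4, 8, 24))
        np.testing.assert_allclose(net.forward(x), 0.5, atol=1e-7)

    def test_shape_mismatch_reported(self):
        net = build(NetworkConfig(), seed=0)
        with pytest.raises(ValueError, match="62"):
            net.forward(np.zeros((2, 60, 250)))

    def test_train_mode_single_sample_rejected(self, tiny_config):
        net = build(tiny_config, seed=0)
        x = np.zeros((1, 8, 24))
        with pytest.raises(ValueError, match="batch"):
            net.forward(x, mode="train")
        net.forward(x, mode="eval")  # eval accepts batch of 1


class TestParameterCount:
    def test_psa_adds_parameters(self):
        base = NetworkConfig()
        aa = build(variant_config(base, AblationSpec("A+A")), seed=0)
        eeg = build(variant_config(base, AblationSpec("EEGNet")), seed=0)
        assert eeg.parameter_count() < aa.parameter_count()

    def test_doubling_filters_increases_count(self):
        small = build(NetworkConfig(), seed=0).parameter_count()
        big = build(NetworkConfig(temporal_filters=16, depth_multiplier=2),
                    seed=0).parameter_count()
        assert big > small

    def test_count_matches_shape_sum_oracle(self):
        net = build(NetworkConfig(), seed=0)
        # independent sum over the declared weight shapes of the default model
        f1, k, ch, f2 = 8, 125, 62, 16
        expected = f1 * k                      # temporal conv
        expected += 2 * f1                     # bn1
        expected += f1 * 2 * ch                # spatial depthwise
        expected += 2 * f2                     # bn2
        psa = 0
        for kernels in ((3, 5, 7, 9), (1, 3, 5, 7)):
            cb = f2 // 4
            hidden = max(cb // 4, 1)
            for kk in kernels:
                psa += cb * cb * kk            # branch conv
                psa += cb * hidden + hidden    # fc1 (+bias)
                psa += hidden * cb + cb        # fc2 (+bias)
        expected += psa
        expected += 2 * f2                     # bn3
        expected += f2 * 16                    # separable depthwise (1,16)
        expected += f2 * f2                    # pointwise
        expected += 2 * f2                     # bn4
        expected += 64 * 2 + 2                 # classifier
        assert net.parameter_count() == expected


class TestGradients:
    def test_finite_difference_check(self, tiny_config):
        """Analytic gradients agree with central differences through the
        whole network (convs, batch norm, PSA, pools, classifier)."""
        net = build(tiny_config, seed=1, dtype=np.float64)
        rng = np.random.default_rng(2)
        x = rng.normal(size=(6, 8, 24))
        y = rng.integers(0, 2, 6)
        w = np.array([1.0, 2.0])

        p = net.forward(x, mode="train")
        net.backward(_ce_grad(p, y, w))
        analytic = dict(net.net.named_grads(""))
        params = net.named_params()

        check_rng = np.random.default_rng(3)
        for name, arr in params.items():
            flat = arr.ravel()
            for idx in check_rng.choice(flat.size, size=min(3, flat.size),
                                        replace=False):
                eps, old = 1e-6, flat[idx]
                flat[idx] = old + eps
                lp = weighted_cross_entropy(net.forward(x, mode="train"), y, w)
                flat[idx] = old - eps
                lm = weighted_cross_entropy(net.forward(x, mode="train"), y, w)
                flat[idx] = old
                num = (lp - lm) / (2 * eps)
                got = analytic[name].ravel()[idx]
                assert got == pytest.approx(num, rel=1e-4, abs=1e-7), name

    def test_gradient_flow_everywhere(self, tiny_config):
        net = build(tiny_config, seed=4, dtype=np.float64)
        rng = np.random.default_rng(5)
        x = rng.normal(size=(8, 8, 24))
        y = rng.integers(0, 2, 8)
        p = net.forward(x, mode="train")
        net.backward(_ce_grad(p, y, np.ones(2)))
        for name, g in net.net.named_grads(""):
            assert np.abs(g).max() > 0, f"dead gradient in {name}"


class TestAblationNesting:
    def test_psa_replaced_by_identity_matches_smaller_variant(self, tiny_config):
        """An A+A network whose second PSA is forced to the identity map
        computes the same function as the A+0 network with shared weights."""
        from dataclasses import replace

        cfg_aa = tiny_config
        cfg_a0 = replace(tiny_config, psa_dtfe=None)
        net_aa = build(cfg_aa, seed=7, dtype=np.float64)
        net_a0 = build(cfg_a0, seed=7, dtype=np.float64)

        # share every co-named parameter
        params_aa = net_aa.named_params()
        for name, arr in net_a0.named_params().items():
            arr[...] = params_aa[name]

        # force the extra PSA block to the identity
        class _Identity:
            def forward(self, x, training=False, rng=None):
                return x

        layers = net_aa.net.layers
        idx = [i for i, (n, _) in enumerate(layers) if n == "psa_dtfe"][0]
        layers[idx] = ("psa_dtfe", _Identity())

        x = np.random.default_rng(8).normal(size=(4, 8, 24))
        np.testing.assert_allclose(net_aa.forward(x), net_a0.forward(x),
                                   rtol=1e-10)

    def test_all_variants_build_and_run(self):
        x = np.random.default_rng(9).normal(size=(2, 62, 250)).astype(np.float32)
        for name in ("A+A", "A+0", "0+A", "EEGNet"):
            cfg = variant_config(NetworkConfig(), AblationSpec(name))
            p = build(cfg, seed=0).forward(x)
            np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)


def test_invalid_config_rejected_before_compute():
    with pytest.raises(ValueError):
        NetworkConfig(dropout_p=1.5).validate()
    with pytest.raises(ValueError):
        NetworkConfig(psa_psfe=PSAConfig((3, 5, 7))).validate()  # 16 % 3 != 0
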