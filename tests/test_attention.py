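"""Attention primitives vs independent nested-loop references."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from arunet.attention import (
    aca_gate,
    adaptive_kernel_size,
    dta,
    dta_branch,
    fc_channel_attention,
    global_avg_pool,
    scaled_tanh,
)
from arunet.exceptions import ConfigurationError, ParameterError

from oracles import aca_gate_ref, dta_branch_ref, dta_ref, fc_attention_ref


def random_fm(shape, seed):
    return np.random.default_rng(seed).normal(size=shape)


class TestBasics:
    def test_gap_constant_channel(self):
        fm = np.zeros((3, 3, 2))
        fm[:, :, 0] = 5.0
        fm[:, :, 1] = -1.5
        assert np.allclose(global_avg_pool(fm), [5.0, -1.5])

    def test_gap_small_example(self):
        fm = np.array([[1.0, 2.0], [3.0, 4.0]]).reshape(2, 2, 1)
        assert global_avg_pool(fm)[0] == 2.5

    def test_gap_linearity(self):
        fm = random_fm((4, 5, 3), 0)
        assert np.allclose(global_avg_pool(3.0 * fm), 3.0 * global_avg_pool(fm))

    def test_scaled_tanh_range_and_monotonicity(self):
        # strict (-1, 1) bounds hold wherever float64 can represent them
        x = np.linspace(-8, 8, 101)
        y = scaled_tanh(x, alpha=2.0)
        assert scaled_tanh(np.zeros(1), 1.0)[0] == 0.0
        assert np.all(np.abs(y) < 1.0)
        assert np.all(np.diff(y) >= 0)
        with pytest.raises(ParameterError):
            scaled_tanh(x, alpha=0.0)


class TestAdaptiveKernelSize:
    @pytest.mark.parametrize("channels,expected", [(2, 1), (64, 3), (256, 5), (1, 1)])
    def test_derived_values(self, channels, expected):
        assert adaptive_kernel_size(channels) == expected

    def test_odd_and_nondecreasing_over_range(self):
        ks = [adaptive_kernel_size(c) for c in range(1, 1025)]
        assert all(k % 2 == 1 for k in ks)
        assert all(a <= b for a, b in zip(ks, ks[1:]))

    @given(st.integers(min_value=1, max_value=10 ** 6))
    @settings(max_examples=200, deadline=None)
    def test_always_odd_positive(self, channels):
        k = adaptive_kernel_size(channels)
        assert k >= 1 and k % 2 == 1


class TestAcaGate:
    def test_zero_kernel_residual_gate_is_identity(self):
        fm = random_fm((3, 3, 4), 1)
        out = aca_gate(fm, np.zeros(adaptive_kernel_size(4)))
        assert np.allclose(out, fm)

    def test_zero_kernel_literal_gate_annihilates(self):
        fm = random_fm((3, 3, 4), 2)
        out = aca_gate(fm, np.zeros(adaptive_kernel_size(4)), gate="literal")
        assert np.allclose(out, 0.0)

    def test_identical_channels_get_identical_gates(self):
        base = random_fm((4, 4, 1), 3)
        fm = np.repeat(base, 4, axis=2)
        kernel = np.array([0.3, -0.2, 0.5])[: adaptive_kernel_size(4)]
        out = aca_gate(fm, kernel, gate="literal")
        # interior channels see the same neighbourhood -> equal gate values
        assert np.allclose(out[:, :, 1], out[:, :, 2])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        c = int(rng.integers(1, 5))
        fm = rng.normal(size=(int(rng.integers(1, 5)), int(rng.integers(1, 5)), c))
        kernel = rng.normal(size=adaptive_kernel_size(c))
        alpha = float(rng.uniform(0.5, 2.0))
        for gate in ("residual", "literal"):
            assert np.allclose(aca_gate(fm, kernel, alpha, gate),
                               aca_gate_ref(fm, kernel, alpha, gate), atol=1e-12)

    def test_kernel_length_mismatch_rejected(self):
        with pytest.raises(ConfigurationError):
            aca_gate(random_fm((2, 2, 64), 0), np.zeros(5))


class TestFcChannelAttention:
    def test_zero_ub_residual_gate_is_identity(self):
        fm = random_fm((3, 3, 4), 4)
        ua = random_fm((4, 2), 5)
        out = fc_channel_attention(fm, ua, np.zeros((2, 4)))
        assert np.allclose(out, fm)

    def test_matches_matrix_oracle(self):
        rng = np.random.default_rng(6)
        fm = rng.normal(size=(3, 4, 4))
        ua = rng.normal(size=(4, 2))
        ub = rng.normal(size=(2, 4))
        for gate in ("residual", "literal"):
            assert np.allclose(fc_channel_attention(fm, ua, ub, 1.3, gate),
                               fc_attention_ref(fm, ua, ub, 1.3, gate), atol=1e-12)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ConfigurationError):
            fc_channel_attention(random_fm((2, 2, 4), 0),
                                 np.zeros((3, 2)), np.zeros((2, 4)))


class TestDta:
    def test_zero_kernels_zero_output(self):
        fm = random_fm((3, 3, 2), 7)
        k = np.zeros((2, 3, 3))
        gated, omega = dta_branch(fm, "height-width", k)
        assert np.allclose(omega, 0.0) and np.allclose(gated, 0.0)
        assert np.allclose(dta(fm, [k, k, k]), 0.0)

    def test_constant_input_gives_spatially_constant_gate(self):
        fm = np.full((4, 4, 3), 2.0)
        kernel = np.zeros((2, 3, 3))
        kernel[:, 1, 1] = 0.5  # centre tap only: no border effects
        _, omega = dta_branch(fm, "height-width", kernel)
        assert np.allclose(omega, omega.ravel()[0])

    def test_unit_gates_recover_input(self):
        # forcing every branch gate to one averages three copies of the input
        fm = random_fm((4, 4, 3), 8)
        acc = np.zeros_like(fm)
        from arunet.attention import DTA_BRANCHES

        for branch, axis in DTA_BRANCHES.items():
            x_hat = np.moveaxis(fm, axis, 0)
            acc += np.moveaxis(x_hat * 1.0, 0, axis)
        assert np.allclose(acc / 3.0, fm)

    @pytest.mark.parametrize("branch", ["height-channel", "width-channel", "height-width"])
    def test_branch_matches_loop_oracle(self, branch):
        rng = np.random.default_rng(hash(branch) % 2 ** 31)
        for _ in range(4):
            fm = rng.normal(size=(int(rng.integers(2, 5)), int(rng.integers(2, 5)),
                                  int(rng.integers(1, 5))))
            kernel = rng.normal(size=(2, 3, 3))
            alpha = float(rng.uniform(0.5, 2.0))
            gated, omega = dta_branch(fm, branch, kernel, alpha)
            gated_ref, omega_ref = dta_branch_ref(fm, branch, kernel, alpha)
            assert np.allclose(omega, omega_ref, atol=1e-12)
            assert np.allclose(gated, gated_ref, atol=1e-12)

    def test_full_dta_matches_composed_oracle(self):
        rng = np.random.default_rng(9)
        fm = rng.normal(size=(4, 4, 3))
        kernels = [rng.normal(size=(2, 3, 3)) for _ in range(3)]
        assert np.allclose(dta(fm, kernels, 1.1), dta_ref(fm, kernels, 1.1), atol=1e-12)

    def test_unknown_branch_rejected(self):
        with pytest.raises(ConfigurationError):
            dta_branch(random_fm((2, 2, 2), 0), "depth-channel", np.zeros((2, 3, 3)))


class TestModuleConsistency:
    """The autograd attention layers implement the same mathematics."""

    def test_aca_module_matches_functional(self):
        from arunet.nn import AcaGate
        from arunet.nn.tensor import Tensor

        rng = np.random.default_rng(10)
        fm = rng.normal(size=(3, 4, 8))  # H, W, C
        mod = AcaGate(8, alpha=1.2, gate="residual")
        mod.kernel.data = rng.normal(size=mod.kernel_size)
        out_mod = mod(Tensor(fm.transpose(2, 0, 1)[None])).data[0].transpose(1, 2, 0)
        out_fun = aca_gate(fm, mod.kernel.data, alpha=1.2, gate="residual")
        assert np.allclose(out_mod, out_fun, atol=1e-10)

    def test_triplet_module_matches_functional(self):
        from arunet.nn import TripletAttention
        from arunet.nn.tensor import Tensor

        rng = np.random.default_rng(11)
        fm = rng.normal(size=(5, 4, 3))  # H, W, C
        mod = TripletAttention(alpha=0.9, kernel_size=3)
        kernels = []
        for conv in (mod.conv_hc, mod.conv_wc, mod.conv_hw):
            conv.weight.data = rng.normal(size=conv.weight.shape)
            kernels.append(conv.weight.data[0])
        out_mod = mod(Tensor(fm.transpose(2, 0, 1)[None])).data[0].transpose(1, 2, 0)
        out_fun = dta(fm, kernels, alpha=0.9)
        assert np.allclose(out_mod, out_fun, atol=1e-10)

    def test_fc_module_matches_functional(self):
        from arunet.nn import FcChannelAttention
        from arunet.nn.tensor import Tensor

        rng = np.random.default_rng(12)
        fm = rng.normal(size=(3, 3, 4))
        mod = FcChannelAttention(4, reduction=2, alpha=1.0)
        mod.ua.data = rng.normal(size=mod.ua.shape)
        mod.ub.data = rng.normal(size=mod.ub.shape)
        out_mod = mod(Tensor(fm.transpose(2, 0, 1)[None])).data[0].transpose(1, 2, 0)
        out_fun = fc_channel_attention(fm, mod.ua.data, mod.ub.data)
        assert np.allclose(out_mod, out_fun, atol=1e-10)

    def test_shape_preserved_and_gates_bounded(self):
        from arunet.nn import AcaGate, TripletAttention
        from arunet.nn.tensor import Tensor

        rng = np.random.default_rng(13)
        x = Tensor(rng.normal(size=(2, 4, 4, 4)))
        aca = AcaGate(4)
        aca.kernel.data = rng.normal(size=aca.kernel_size)
        out = aca(x)
        assert out.shape == x.shape
        omega = aca.gate_weights(x).data
        assert np.all(np.abs(omega) < 1.0)
        dta_mod = TripletAttention(kernel_size=3)
        assert dta_mod(x).shape == x.shape
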