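"""Structural and behavioural contracts of the dual-stream networks."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import vesselseg as vs
from vesselseg.exceptions import InputError, MergeError, StructuralValidationError
from vesselseg.network import NetworkSpec, SegmentationModel

# frozen by hand from the reference schedule (bias-free 3x3 convs + BN
# scale/shift, two k=4 transposed convs, 1x1 classifier with bias)
REFERENCE_PARAM_TOTAL = 1_523_090


@pytest.fixture(scope="module")
def dsf():
    return vs.build_network(NetworkSpec.reference("DSF"), seed=0)


@pytest.fixture(scope="module")
def dsa():
    return vs.build_network(NetworkSpec.reference("DSA"), seed=0)


# ---- spec validation --------------------------------------------------------

class TestSpecValidation:
    def test_reference_specs_are_valid(self):
        for v in ("DSF", "DSA"):
            NetworkSpec.reference(v).validate()

    def test_three_pools_rejected(self):
        spec = NetworkSpec.reference("DSA")
        spec.stream_b = [[64, True], [128, True], [256, True]]
        with pytest.raises(StructuralValidationError, match="pooling"):
            spec.validate()

    def test_wrong_stride_product_rejected(self):
        spec = NetworkSpec.reference("DSF")
        spec.stream_a = [[64, 2], [256, 1]]
        with pytest.raises(StructuralValidationError, match="stride product"):
            spec.validate()

    def test_unequal_stream_depths_rejected(self):
        spec = NetworkSpec.reference("DSF")
        spec.stream_a = [[64, 2], [128, 2]]
        with pytest.raises(StructuralValidationError, match="depths differ"):
            spec.validate()

    def test_wrong_conv_count_rejected(self):
        spec = NetworkSpec.reference("DSA")
        spec.input_block = [16]
        with pytest.raises(StructuralValidationError, match="must be 9"):
            spec.validate()

    def test_build_rejects_invalid_spec(self):
        spec = NetworkSpec.reference("DSA")
        spec.final_block = spec.final_block + [32]
        with pytest.raises(StructuralValidationError):
            vs.build_network(spec)


# ---- merge ops --------------------------------------------------------------

class TestMerges:
    def test_zero_maps_fuse_to_zero(self):
        z = np.zeros((4, 5, 3))
        np.testing.assert_array_equal(vs.fuse_residual(z, z), z)

    def test_fusion_is_elementwise_sum(self):
        g = np.full((3, 3, 2), 1.5)
        k = np.full((3, 3, 2), -0.5)
        np.testing.assert_allclose(vs.fuse_residual(g, k), 1.0)

    def test_fusion_preserves_shape_at_encoder_scale(self):
        g = np.zeros((163, 163, 8), np.float32)
        assert vs.fuse_residual(g, g).shape == (163, 163, 8)

    def test_fusion_shape_mismatch_raises(self):
        with pytest.raises(MergeError):
            vs.fuse_residual(np.zeros((3, 3, 2)), np.zeros((3, 4, 2)))

    def test_concatenation_order_and_depth(self):
        g = np.array([[[1.0, 2.0]]])
        k = np.array([[[3.0]]])
        np.testing.assert_array_equal(vs.aggregate_dense(g, k)[0, 0], [1, 2, 3])

    def test_concatenation_depth_doubles_at_encoder_scale(self):
        g = np.zeros((163, 163, 4), np.float32)
        assert vs.aggregate_dense(g, g).shape == (163, 163, 8)

    def test_zero_depth_rejected(self):
        with pytest.raises(MergeError):
            vs.aggregate_dense(np.zeros((3, 3, 0)), np.zeros((3, 3, 1)))

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_fusion_commutative_concatenation_not(self, seed):
        rng = np.random.default_rng(seed)
        g = rng.normal(size=(4, 4, 3))
        k = rng.normal(size=(4, 4, 3))
        np.testing.assert_allclose(vs.fuse_residual(g, k), vs.fuse_residual(k, g))
        gk = vs.aggregate_dense(g, k)
        assert gk.shape[-1] == 6
        assert not np.allclose(gk, vs.aggregate_dense(k, g))


# ---- shape calculus ---------------------------------------------------------

class TestEncoderOutputSize:
    @pytest.mark.parametrize("hw,expected", [
        ((650, 650), (163, 163)),
        ((4, 4), (1, 1)),
        ((565, 584), (142, 146)),
    ])
    def test_known_sizes(self, hw, expected):
        assert vs.encoder_output_size(*hw) == expected

    def test_small_dims_rejected(self):
        with pytest.raises(InputError):
            vs.encoder_output_size(3, 100)

    def test_matches_layer_graph_simulation(self, rng):
        """Closed form equals simulating each downsampling layer's
        ceil-mode arithmetic (stride-2 conv and 2x2 ceil pooling both map
        n -> ceil(n/2))."""
        def simulate(n):
            for _ in range(2):  # two downsampling stages per stream
                n = -(-n // 2)
            return n

        for _ in range(50):
            h, w = rng.integers(4, 1025, size=2)
            assert vs.encoder_output_size(h, w) == (simulate(h), simulate(w))


# ---- parameter accounting ---------------------------------------------------

class TestParameterBudget:
    def test_nine_3x3_convolutions(self, dsf, dsa):
        assert vs.count_conv3x3(dsf) == 9
        assert vs.count_conv3x3(dsa) == 9

    def test_totals_equal_and_round_to_1p5m(self, dsf, dsa):
        n_dsf, n_dsa = vs.count_parameters(dsf), vs.count_parameters(dsa)
        assert n_dsf == n_dsa == REFERENCE_PARAM_TOTAL
        assert round(n_dsf / 1e6, 1) == 1.5

    def test_single_conv_weight_count(self):
        from vesselseg._nn.layers import Conv2d
        conv = Conv2d(256, 256, 3, rng=np.random.default_rng(0))
        assert conv.weight.size == 589_824  # 3*3*256*256
        bottleneck = Conv2d(512, 128, 3, rng=np.random.default_rng(0))
        assert bottleneck.weight.size == 589_824  # the DSA parity identity


# ---- forward pass -----------------------------------------------------------

class TestForward:
    @pytest.mark.parametrize("hw", [(16, 16), (17, 23), (48, 31)])
    def test_mask_shape_equals_input_shape(self, dsa, hw, rng):
        img = rng.integers(0, 256, size=(*hw, 3), dtype=np.uint8)
        prob, mask = vs.segment(dsa, img)
        assert mask.shape == hw and prob.shape == (*hw, 2)
        assert set(np.unique(mask)) <= {0, 1}

    def test_shape_conserved_at_dataset_sizes(self, dsa, rng):
        """Native fundus sizes, including odd dims, survive the
        encode/decode round trip."""
        for hw in [(565, 584), (605, 700), (960, 999)]:
            img = rng.integers(0, 256, size=(*hw, 3), dtype=np.uint8)
            _, mask = vs.segment(dsa, img)
            assert mask.shape == hw

    def test_probabilities_sum_to_one(self, dsf, rng):
        x = rng.uniform(size=(2, 20, 24, 3)).astype(np.float32)
        prob = dsf.predict_proba(x)
        np.testing.assert_allclose(prob.sum(-1), 1.0, atol=1e-5)

    def test_pre_decoder_map_is_quarter_scale(self, dsa, rng):
        """The merged encoder feature for a 64x64 input sits at 16x16."""
        x = rng.uniform(size=(1, 64, 64, 3)).astype(np.float32)
        dsa.forward_logits(x)
        h, w = vs.encoder_output_size(64, 64)
        assert (h, w) == (16, 16)
        oy, ox, dh, dw = dsa._crop
        assert (dh, dw) == (4 * h, 4 * w)

    def test_untrained_inference_is_deterministic(self, rng):
        img = rng.integers(0, 256, size=(32, 32, 3), dtype=np.uint8)
        m1 = vs.build_network(NetworkSpec.reference("DSA"), seed=11)
        m2 = vs.build_network(NetworkSpec.reference("DSA"), seed=11)
        p1, _ = vs.segment(m1, img)
        p2, _ = vs.segment(m2, img)
        np.testing.assert_array_equal(p1, p2)

    def test_channel_mismatch_rejected(self, dsa):
        with pytest.raises(InputError):
            vs.segment(dsa, np.zeros((16, 16, 4), np.uint8))


# ---- checkpointing ----------------------------------------------------------

def test_checkpoint_round_trip_is_bit_exact(tmp_path, rng):
    model = vs.build_network(NetworkSpec.reference("DSF"), seed=5)
    x = rng.uniform(size=(1, 16, 16, 3)).astype(np.float32)
    before = model.predict_proba(x)
    path = tmp_path / "model.npz"
    vs.save_checkpoint(model, path)
    loaded = vs.load_checkpoint(path)
    assert loaded.spec == model.spec
    for a, b in zip(model.parameters(), loaded.parameters()):
        np.testing.assert_array_equal(a.data, b.data)
    np.testing.assert_array_equal(before, loaded.predict_proba(x))
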