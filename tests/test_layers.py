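"""Layer semantics: sparse/dense convolution equivalence, generation span,
pruning, normalization, activations, and per-layer gradient checks."""

import numpy as np
import pytest

from sparsevox.layers import (
    LayerParams,
    PruneConfig,
    activation,
    activation_bwd,
    activation_fwd,
    conv_bwd,
    dense_conv_reference,
    generative_transposed_conv,
    generative_transposed_conv_fwd,
    init_layer_params,
    normalize,
    normalize_bwd,
    normalize_fwd,
    prune,
    prune_fwd,
    sparse_conv,
    sparse_conv_fwd,
)
from sparsevox.sparse import CoordinateManager, SparseTensor, kernel_offsets
from sparsevox.voxgrid import VoxelGrid, dense_to_sparse


def random_sparse(shape, occupancy, seed, channels=1):
    rng = np.random.default_rng(seed)
    mask = rng.random(shape) < occupancy
    coords = np.argwhere(mask)
    feats = rng.standard_normal((coords.shape[0], channels))
    return SparseTensor(coords, feats), mask


def dense_from_sparse(st, shape, channels):
    vol = np.zeros(shape + (channels,))
    vol[st.coords[:, 0], st.coords[:, 1], st.coords[:, 2]] = st.feats
    return vol


class TestSparseConv:
    def test_identity_kernel_preserves_features(self):
        st, _ = random_sparse((6, 6, 6), 0.3, seed=0, channels=3)
        p = LayerParams(weight=np.eye(3)[None], bias=np.zeros(3))
        out = sparse_conv(st, p, 1)
        assert np.array_equal(out.coords, st.coords)
        assert np.allclose(out.feats, st.feats)

    def test_lone_point_all_ones_kernel_only_center_fires(self):
        st = SparseTensor(np.array([[2, 2, 2]]), np.ones((1, 1)))
        p = LayerParams(weight=np.ones((27, 1, 1)), bias=np.zeros(1))
        out = sparse_conv(st, p, 3, out_coords=st.coords)
        assert out.feats[0, 0] == pytest.approx(1.0)

    @pytest.mark.parametrize("ks,stride", [(1, 1), (2, 1), (3, 1), (4, 1), (2, 2), (3, 2)])
    def test_matches_dense_reference_at_computed_coords(self, ks, stride):
        rng = np.random.default_rng(ks * 10 + stride)
        st, _ = random_sparse((12, 12, 12), 0.2, seed=ks * 7 + stride, channels=2)
        p = init_layer_params(rng, ks, 2, 3, with_norm=False)
        out = sparse_conv(st, p, ks, stride)
        dense_in = dense_from_sparse(st, (12, 12, 12), 2)
        ref = dense_conv_reference(dense_in, p, ks, stride)
        idx = out.coords // stride
        assert np.abs(out.feats - ref[idx[:, 0], idx[:, 1], idx[:, 2]]).max() < 1e-6

    def test_channel_mismatch_raises(self):
        st, _ = random_sparse((4, 4, 4), 0.5, seed=1, channels=2)
        p = init_layer_params(np.random.default_rng(0), 3, 3, 2, with_norm=False)
        with pytest.raises(ValueError):
            sparse_conv(st, p, 3)

    def test_linearity_in_features(self):
        st, _ = random_sparse((8, 8, 8), 0.2, seed=2, channels=2)
        rng = np.random.default_rng(3)
        p = init_layer_params(rng, 3, 2, 2, with_norm=False)
        f1 = rng.standard_normal(st.feats.shape)
        f2 = rng.standard_normal(st.feats.shape)
        a, b = 1.7, -0.4
        def run(f):
            return sparse_conv(SparseTensor(st.coords, f), p, 3).feats
        assert np.allclose(run(a * f1 + b * f2), a * run(f1) + b * run(f2))

    def test_permutation_invariance(self):
        st, _ = random_sparse((8, 8, 8), 0.2, seed=4, channels=2)
        rng = np.random.default_rng(5)
        p = init_layer_params(rng, 3, 2, 2, with_norm=False)
        perm = rng.permutation(len(st))
        st_p = SparseTensor(st.coords[perm], st.feats[perm])
        out1 = sparse_conv(st, p, 3)
        out2 = sparse_conv(st_p, p, 3)
        d1 = {tuple(c): tuple(f) for c, f in zip(out1.coords, np.round(out1.feats, 10))}
        d2 = {tuple(c): tuple(f) for c, f in zip(out2.coords, np.round(out2.feats, 10))}
        assert d1 == d2

    def test_empty_input_propagates(self):
        st = SparseTensor(np.empty((0, 3), dtype=int), np.empty((0, 2)))
        p = init_layer_params(np.random.default_rng(0), 3, 2, 4, with_norm=False)
        out = sparse_conv(st, p, 3)
        assert len(out) == 0 and out.num_channels == 4


class TestDenseReference:
    def test_impulse_response_is_the_flipped_kernel(self):
        rng = np.random.default_rng(6)
        p = init_layer_params(rng, 3, 1, 1, with_norm=False)
        vol = np.zeros((7, 7, 7, 1))
        vol[3, 3, 3, 0] = 1.0
        out = dense_conv_reference(vol, p, 3)
        offs = kernel_offsets(3)
        for k, off in enumerate(offs):
            pos = np.array([3, 3, 3]) - off
            assert out[pos[0], pos[1], pos[2], 0] == pytest.approx(p.weight[k, 0, 0])

    def test_zero_input_gives_bias_everywhere(self):
        p = LayerParams(weight=np.zeros((27, 1, 2)), bias=np.array([0.3, -0.7]))
        out = dense_conv_reference(np.zeros((5, 5, 5, 1)), p, 3)
        assert np.allclose(out, np.broadcast_to([0.3, -0.7], out.shape))


class TestGenerativeTransposedConv:
    def test_single_point_ks3_spans_27(self):
        st = SparseTensor(np.array([[4, 4, 4]]), np.ones((1, 1)))
        p = init_layer_params(np.random.default_rng(7), 3, 1, 1, with_norm=False)
        out = generative_transposed_conv(st, p, 3, 1)
        assert len(out) == 27
        assert np.abs(out.coords - [4, 4, 4]).max() == 1

    def test_ks1_identity_weights_is_identity(self):
        st, _ = random_sparse((6, 6, 6), 0.2, seed=8, channels=2)
        p = LayerParams(weight=np.eye(2)[None], bias=np.zeros(2))
        out = generative_transposed_conv(st, p, 1, 1)
        assert np.array_equal(out.coords, st.coords)
        assert np.allclose(out.feats, st.feats)

    def test_two_points_generate_45_coordinates(self):
        st = SparseTensor(np.array([[10, 10, 10], [12, 10, 10]]), np.ones((2, 1)))
        p = init_layer_params(np.random.default_rng(9), 3, 1, 1, with_norm=False)
        out = generative_transposed_conv(st, p, 3, 1)
        assert len(out) == 45

    def test_output_satisfies_neighbour_constraint_exactly(self):
        rng = np.random.default_rng(10)
        st, _ = random_sparse((10, 10, 10), 0.1, seed=10, channels=1)
        p = init_layer_params(rng, 3, 1, 2, with_norm=False)
        out = generative_transposed_conv(st, p, 3, 1)
        # brute force: output coords = union of Chebyshev-1 balls
        expected = set()
        for c in st.coords:
            for off in kernel_offsets(3):
                expected.add(tuple(c + off))
        assert {tuple(c) for c in out.coords} == expected

    def test_upstride_halves_tensor_stride(self):
        st = SparseTensor(np.array([[0, 0, 0], [4, 0, 0]]), np.ones((2, 1)), tensor_stride=4)
        p = init_layer_params(np.random.default_rng(11), 2, 1, 1, with_norm=False)
        out = generative_transposed_conv(st, p, 2, 2)
        assert out.tensor_stride == 2
        assert np.all(out.coords % 2 == 0)

    def test_indivisible_stride_rejected(self):
        st = SparseTensor(np.array([[0, 0, 0]]), np.ones((1, 1)), tensor_stride=3)
        p = init_layer_params(np.random.default_rng(12), 2, 1, 1, with_norm=False)
        with pytest.raises(ValueError):
            generative_transposed_conv(st, p, 2, 2)

    def test_transposed_agrees_with_dense_scatter(self):
        # features must equal a dense transposed convolution (scatter of
        # W onto each input's span) evaluated at the output coords
        rng = np.random.default_rng(13)
        st, _ = random_sparse((8, 8, 8), 0.15, seed=13, channels=2)
        p = init_layer_params(rng, 3, 2, 3, with_norm=False)
        out = generative_transposed_conv(st, p, 3, 1)
        dense = np.zeros((10 + 8, 10 + 8, 10 + 8, 3))  # padded workspace
        off0 = 5
        for c, f in zip(st.coords, st.feats):
            for k, off in enumerate(kernel_offsets(3)):
                x = c + off + off0
                dense[x[0], x[1], x[2]] += f @ p.weight[k]
        ref = dense[out.coords[:, 0] + off0, out.coords[:, 1] + off0, out.coords[:, 2] + off0]
        assert np.abs(out.feats - (ref + p.bias)).max() < 1e-9


class TestPrune:
    def test_threshold_keeps_nonnegative_scores(self):
        st = SparseTensor(np.array([[0, 0, 0], [1, 1, 1]]), np.ones((2, 1)))
        out = prune(st, np.array([0.5, -0.5]), PruneConfig())
        assert np.array_equal(out.coords, [[0, 0, 0]])

    def test_all_negative_scores_empty_tensor_is_legal(self):
        st, _ = random_sparse((4, 4, 4), 0.3, seed=14)
        out = prune(st, -np.ones(len(st)), PruneConfig())
        assert len(out) == 0

    def test_training_mode_rescues_ground_truth_rows(self):
        rng = np.random.default_rng(15)
        coords = np.unique(rng.integers(0, 8, size=(10, 3)), axis=0)[:10]
        st = SparseTensor(coords, np.ones((coords.shape[0], 1)))
        gt = CoordinateManager(coords[:3])
        out = prune(st, -np.ones(len(st)), PruneConfig(training=True), gt_occupancy=gt)
        assert {tuple(c) for c in out.coords} == {tuple(c) for c in coords[:3]}

    def test_training_mode_without_gt_rejected(self):
        st, _ = random_sparse((4, 4, 4), 0.3, seed=16)
        with pytest.raises(ValueError):
            prune(st, np.zeros(len(st)), PruneConfig(training=True))

    def test_never_introduces_coordinates(self):
        st, _ = random_sparse((6, 6, 6), 0.3, seed=17)
        rng = np.random.default_rng(18)
        out = prune(st, rng.standard_normal(len(st)), PruneConfig())
        in_set = {tuple(c) for c in st.coords}
        assert all(tuple(c) in in_set for c in out.coords)
        assert len(out) <= len(st)


class TestNormalize:
    def test_affine_identity_on_standardized_features(self):
        rng = np.random.default_rng(19)
        x = rng.standard_normal((200, 3))
        x = (x - x.mean(0)) / x.std(0)
        st = SparseTensor(np.argwhere(np.ones((200, 1, 1))), x)
        p = LayerParams(weight=np.zeros((1, 3, 3)), bias=np.zeros(3),
                        norm_scale=np.ones(3), norm_shift=np.zeros(3),
                        running_mean=np.zeros(3), running_var=np.ones(3))
        out = normalize(st, p, training=True)
        assert np.abs(out.feats - x).max() < 1e-4

    def test_constant_column_maps_to_shift(self):
        st = SparseTensor(np.arange(12).reshape(4, 3) * 3, np.full((4, 2), 7.0))
        p = LayerParams(weight=np.zeros((1, 2, 2)), bias=np.zeros(2),
                        norm_scale=np.ones(2), norm_shift=np.array([0.3, -0.1]),
                        running_mean=np.zeros(2), running_var=np.ones(2))
        out = normalize(st, p, training=True)
        assert np.allclose(out.feats, [[0.3, -0.1]] * 4)

    def test_single_row_batch_is_well_defined(self):
        st = SparseTensor(np.array([[0, 0, 0]]), np.array([[2.0, -1.0]]))
        p = LayerParams(weight=np.zeros((1, 2, 2)), bias=np.zeros(2),
                        norm_scale=np.ones(2), norm_shift=np.zeros(2),
                        running_mean=np.zeros(2), running_var=np.ones(2))
        out = normalize(st, p, training=True)
        assert np.isfinite(out.feats).all()


class TestActivation:
    def test_sigmoid_at_zero(self):
        st = SparseTensor(np.array([[0, 0, 0]]), np.array([[0.0]]))
        assert activation(st, "sigmoid").feats[0, 0] == pytest.approx(0.5)

    def test_relu_clips_negatives(self):
        st = SparseTensor(np.array([[0, 0, 0]]), np.array([[-3.0]]))
        assert activation(st, "relu").feats[0, 0] == 0.0

    def test_sigmoid_is_monotone(self):
        rng = np.random.default_rng(20)
        x = rng.standard_normal(100)
        st = SparseTensor(np.stack([np.arange(100)] * 3, axis=1), x[:, None])
        y = activation(st, "sigmoid").feats[:, 0]
        assert np.array_equal(np.argsort(x), np.argsort(y))

    def test_unknown_kind_rejected(self):
        st = SparseTensor(np.array([[0, 0, 0]]), np.array([[1.0]]))
        with pytest.raises(ValueError):
            activation(st, "tanh")


class TestLayerGradients:
    """Central finite differences vs analytic gradients, per layer type."""

    def _fd_check(self, forward, backward, params_list, x0, seed, rtol=1e-4):
        rng = np.random.default_rng(seed)
        y0, cache = forward(x0)
        d_out = rng.standard_normal(y0.shape)
        loss = lambda y: float((y * d_out).sum())
        analytic = backward(cache, d_out)
        eps = 1e-6
        for arr, grad in zip([x0] + params_list, analytic):
            if grad is None:
                continue
            for _ in range(5):
                idx = tuple(rng.integers(s) for s in arr.shape)
                orig = arr[idx]
                arr[idx] = orig + eps
                lp = loss(forward(arr is x0 and x0 or x0)[0]) if False else loss(forward(x0)[0])
                arr[idx] = orig - eps
                lm = loss(forward(x0)[0])
                arr[idx] = orig
                fd = (lp - lm) / (2 * eps)
                assert abs(fd - grad[idx]) <= rtol * max(1.0, abs(fd)), (
                    f"fd={fd} analytic={grad[idx]} at {idx}"
                )

    @pytest.mark.parametrize("ks,stride", [(1, 1), (3, 1), (2, 2)])
    def test_sparse_conv_gradients(self, ks, stride):
        rng = np.random.default_rng(21)
        st, _ = random_sparse((6, 6, 6), 0.3, seed=21, channels=2)
        p = init_layer_params(rng, ks, 2, 3, with_norm=False)

        def forward(_x):
            return sparse_conv_fwd(SparseTensor(st.coords, st.feats), p, ks, stride)

        out, cache = forward(None)
        d_out = rng.standard_normal(out.feats.shape)
        d_in, d_w, d_b = conv_bwd(cache, d_out)
        eps = 1e-6
        for arr, grad in ((st.feats, d_in), (p.weight, d_w), (p.bias, d_b)):
            for _ in range(6):
                idx = tuple(rng.integers(s) for s in arr.shape)
                orig = arr[idx]
                arr[idx] = orig + eps
                lp = float((forward(None)[0].feats * d_out).sum())
                arr[idx] = orig - eps
                lm = float((forward(None)[0].feats * d_out).sum())
                arr[idx] = orig
                fd = (lp - lm) / (2 * eps)
                assert abs(fd - grad[idx]) <= 1e-4 * max(1.0, abs(fd))

    def test_generative_conv_gradients(self):
        rng = np.random.default_rng(22)
        st, _ = random_sparse((6, 6, 6), 0.2, seed=22, channels=2)
        p = init_layer_params(rng, 3, 2, 2, with_norm=False)

        def forward():
            return generative_transposed_conv_fwd(SparseTensor(st.coords, st.feats), p, 3, 1)

        out, cache = forward()
        d_out = rng.standard_normal(out.feats.shape)
        d_in, d_w, d_b = conv_bwd(cache, d_out)
        eps = 1e-6
        for arr, grad in ((st.feats, d_in), (p.weight, d_w), (p.bias, d_b)):
            for _ in range(6):
                idx = tuple(rng.integers(s) for s in arr.shape)
                orig = arr[idx]
                arr[idx] = orig + eps
                lp = float((forward()[0].feats * d_out).sum())
                arr[idx] = orig - eps
                lm = float((forward()[0].feats * d_out).sum())
                arr[idx] = orig
                fd = (lp - lm) / (2 * eps)
                assert abs(fd - grad[idx]) <= 1e-4 * max(1.0, abs(fd))

    def test_normalize_gradients(self):
        rng = np.random.default_rng(23)
        feats = rng.standard_normal((30, 3))
        coords = np.stack([np.arange(30)] * 3, axis=1)
        p = LayerParams(weight=np.zeros((1, 3, 3)), bias=np.zeros(3),
                        norm_scale=rng.uniform(0.5, 1.5, 3), norm_shift=rng.standard_normal(3),
                        running_mean=np.zeros(3), running_var=np.ones(3))

        def forward():
            return normalize_fwd(SparseTensor(coords, feats), p, training=True)

        out, cache = forward()
        d_out = rng.standard_normal(out.feats.shape)
        d_in, d_sc, d_sh = normalize_bwd(cache, d_out)
        eps = 1e-6
        for arr, grad in ((feats, d_in), (p.norm_scale, d_sc), (p.norm_shift, d_sh)):
            for _ in range(6):
                idx = tuple(rng.integers(s) for s in arr.shape)
                orig = arr[idx]
                arr[idx] = orig + eps
                lp = float((forward()[0].feats * d_out).sum())
                arr[idx] = orig - eps
                lm = float((forward()[0].feats * d_out).sum())
                arr[idx] = orig
                fd = (lp - lm) / (2 * eps)
                assert abs(fd - grad[idx]) <= 1e-4 * max(1.0, abs(fd))

    @pytest.mark.parametrize("kind", ["relu", "sigmoid"])
    def test_activation_gradients(self, kind):
        rng = np.random.default_rng(24)
        feats = rng.standard_normal((20, 2)) + 0.05  # keep off the relu kink
        coords = np.stack([np.arange(20)] * 3, axis=1)

        def forward():
            return activation_fwd(SparseTensor(coords, feats), kind)

        out, cache = forward()
        d_out = rng.standard_normal(out.feats.shape)
        d_in = activation_bwd(cache, d_out)
        eps = 1e-6
        for _ in range(8):
            idx = tuple(rng.integers(s) for s in feats.shape)
            orig = feats[idx]
            feats[idx] = orig + eps
            lp = float((forward()[0].feats * d_out).sum())
            feats[idx] = orig - eps
            lm = float((forward()[0].feats * d_out).sum())
            feats[idx] = orig
            fd = (lp - lm) / (2 * eps)
            assert abs(fd - d_in[idx]) <= 1e-4 * max(1.0, abs(fd))

    def test_prune_routes_gradient_to_kept_rows(self):
        st, _ = random_sparse((5, 5, 5), 0.4, seed=25, channels=2)
        rng = np.random.default_rng(26)
        scores = rng.standard_normal(len(st))
        out, cache = prune_fwd(st, scores, PruneConfig())
        d_out = rng.standard_normal(out.feats.shape)
        from sparsevox.layers import prune_bwd

        d_in = prune_bwd(cache, d_out, 2)
        kept = cache["kept"]
        assert np.array_equal(d_in[kept], d_out)
        mask = np.ones(len(st), dtype=bool)
        mask[kept] = False
        assert not d_in[mask].any()
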