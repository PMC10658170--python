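"""Sparse network layers: convolution, generative transposed convolution,
pruning, normalization, nonlinearities — with hand-derived gradients.

Every forward op has a ``*_fwd`` variant returning ``(output, cache)`` and a
matching ``*_bwd`` taking the cache plus the gradient w.r.t. the output
features; the network chains these for training.  A dense zero-padded
convolution (:func:`dense_conv_reference`) serves both as the correctness
oracle for the sparse path and as the layer primitive of the dense baseline.

All feature arithmetic is float64: the engine targets desk-scale problems
where exact reproducibility and clean finite-difference checks matter more
than throughput.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sparse import (
    CoordinateManager,
    KernelMap,
    SparseTensor,
    build_kernel_map,
    generative_out_coords,
    kernel_offsets,
    stride_coords,
)


@dataclass
class LayerParams:
    """Weights of one convolution, optionally with per-channel normalization."""

    weight: np.ndarray  # (Ks^3, C_in, C_out)
    bias: np.ndarray  # (C_out,)
    norm_scale: np.ndarray | None = None
    norm_shift: np.ndarray | None = None
    running_mean: np.ndarray | None = None
    running_var: np.ndarray | None = None

    @property
    def c_in(self) -> int:
        return self.weight.shape[1]

    @property
    def c_out(self) -> int:
        return self.weight.shape[2]


@dataclass
class PruneConfig:
    """Pruning rule: threshold tau (0 in the reference setup) and mode."""

    threshold: float = 0.0
    training: bool = False


def init_layer_params(
    rng: np.random.Generator,
    ks: int,
    c_in: int,
    c_out: int,
    with_norm: bool = True,
    bias_value: float = 0.0,
) -> LayerParams:
    """Fan-in-scaled uniform weight init; zero (or fixed) bias."""
    fan_in = ks**3 * c_in
    bound = float(np.sqrt(1.0 / fan_in))
    w = rng.uniform(-bound, bound, size=(ks**3, c_in, c_out))
    b = np.full(c_out, bias_value, dtype=np.float64)
    p = LayerParams(weight=w, bias=b)
    if with_norm:
        p.norm_scale = np.ones(c_out)
        # slightly positive shift keeps freshly standardized (often exactly
        # zero) features off the ReLU kink so gradient flows from step one
        p.norm_shift = np.full(c_out, 0.1)
        p.running_mean = np.zeros(c_out)
        p.running_var = np.ones(c_out)
    return p


# ---------------------------------------------------------------------------
# sparse convolution


def _apply_kernel_map(
    in_feats: np.ndarray, kmap: KernelMap, weight: np.ndarray, bias: np.ndarray, n_out: int
) -> np.ndarray:
    out = np.tile(bias, (n_out, 1))
    for k, (in_rows, out_rows) in kmap.pairs.items():
        # within one offset both row lists are duplicate-free, so fancy
        # indexing with += is exact
        out[out_rows] += in_feats[in_rows] @ weight[k]
    return out


def _kernel_map_backward(
    d_out: np.ndarray, in_feats: np.ndarray, kmap: KernelMap, weight: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    d_in = np.zeros_like(in_feats)
    d_w = np.zeros_like(weight)
    for k, (in_rows, out_rows) in kmap.pairs.items():
        g = d_out[out_rows]
        x = in_feats[in_rows]
        d_w[k] = x.T @ g
        d_in[in_rows] += g @ weight[k].T
    d_b = d_out.sum(axis=0)
    return d_in, d_w, d_b


def sparse_conv_fwd(
    st: SparseTensor,
    params: LayerParams,
    ks: int,
    stride: int = 1,
    out_coords: np.ndarray | None = None,
) -> tuple[SparseTensor, dict]:
    if params.c_in != st.num_channels:
        raise ValueError(
            f"layer expects {params.c_in} input channels, tensor has {st.num_channels}"
        )
    if stride < 1:
        raise ValueError("stride must be >= 1")
    if out_coords is None:
        if stride == 1:
            out_coords = st.coords
            out_manager = st.manager
        else:
            out_coords = stride_coords(st.coords, st.tensor_stride, stride)
            out_manager = CoordinateManager(out_coords)
    else:
        out_manager = CoordinateManager(out_coords)
        out_coords = out_manager.coords
    kmap = build_kernel_map(st.manager, out_coords, ks, st.tensor_stride)
    out_feats = _apply_kernel_map(st.feats, kmap, params.weight, params.bias, out_coords.shape[0])
    out = SparseTensor(out_coords, out_feats, st.tensor_stride * stride, manager=out_manager)
    cache = {"in_feats": st.feats, "kmap": kmap, "weight": params.weight}
    return out, cache


def sparse_conv(
    st: SparseTensor,
    params: LayerParams,
    ks: int,
    stride: int = 1,
    out_coords: np.ndarray | None = None,
) -> SparseTensor:
    """Sparse convolution: for every output coordinate, bias + sum over the
    kernel-map pairs of weight[k] @ input features."""
    return sparse_conv_fwd(st, params, ks, stride, out_coords)[0]


def conv_bwd(cache: dict, d_out: np.ndarray):
    """Gradients of a (plain or generative) sparse convolution."""
    return _kernel_map_backward(d_out, cache["in_feats"], cache["kmap"], cache["weight"])


def generative_transposed_conv_fwd(
    st: SparseTensor, params: LayerParams, ks: int, upstride: int = 1, bounds=None
) -> tuple[SparseTensor, dict]:
    if params.c_in != st.num_channels:
        raise ValueError(
            f"layer expects {params.c_in} input channels, tensor has {st.num_channels}"
        )
    if upstride < 1 or st.tensor_stride % upstride != 0:
        raise ValueError(
            f"tensor stride {st.tensor_stride} not divisible by upstride {upstride}"
        )
    t_out = st.tensor_stride // upstride
    out_coords = generative_out_coords(st.coords, ks, t_out, bounds=bounds)
    out_manager = CoordinateManager(out_coords)
    # map built input-major: every in-bounds (input i, offset k) expansion
    # x = i + t_out * k exists in the output, so the neighbour constraint is
    # satisfied by construction and exhaustively
    offsets = kernel_offsets(ks).astype(np.int64) * t_out
    pairs: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    n_in = len(st)
    n_k = offsets.shape[0]
    in_rows_all = np.arange(n_in, dtype=np.int64)
    queries = (
        st.coords[None, :, :].astype(np.int64) + offsets[:, None, :]
    ).reshape(-1, 3)
    all_rows = out_manager.lookup(queries).reshape(n_k, n_in)
    for k in range(n_k):
        hit = all_rows[k] >= 0
        pairs[k] = (in_rows_all[hit], all_rows[k][hit])
    kmap = KernelMap(kernel_offsets(ks), pairs)
    out_feats = _apply_kernel_map(st.feats, kmap, params.weight, params.bias, out_coords.shape[0])
    out = SparseTensor(out_coords, out_feats, t_out, manager=out_manager)
    cache = {"in_feats": st.feats, "kmap": kmap, "weight": params.weight}
    return out, cache


def generative_transposed_conv(
    st: SparseTensor, params: LayerParams, ks: int, upstride: int = 1, bounds=None
) -> SparseTensor:
    """Transposed convolution whose output coordinates are the kernel-span
    expansion of the input — it *generates* points absent from the input."""
    return generative_transposed_conv_fwd(st, params, ks, upstride, bounds=bounds)[0]


# ---------------------------------------------------------------------------
# dense reference


def dense_conv_reference(
    arr: np.ndarray, params: LayerParams, ks: int, stride: int = 1
) -> np.ndarray:
    """Zero-padded ("same" for odd ks) strided dense 3-D convolution.

    ``arr`` is (X, Y, Z, C_in); output position p (a multiple of the stride on
    the input lattice) takes value ``bias + sum_k W[k] @ arr[p + k]`` — the
    dense statement of exactly what the sparse path computes, used as its
    oracle and as the dense-baseline primitive.
    """
    arr = np.asarray(arr, dtype=np.float64)
    if arr.ndim == 3:
        arr = arr[..., None]
    X, Y, Z, _ = arr.shape
    offs = kernel_offsets(ks)
    m = int(np.abs(offs).max()) if offs.size else 0
    padded = np.pad(arr, ((m, m), (m, m), (m, m), (0, 0)))
    out_shape = tuple((d + stride - 1) // stride for d in (X, Y, Z))
    out = np.tile(params.bias, out_shape + (1,)).astype(np.float64)
    for k, off in enumerate(offs):
        ox, oy, oz = (int(o) for o in off)
        view = padded[m + ox : m + ox + X : stride,
                      m + oy : m + oy + Y : stride,
                      m + oz : m + oz + Z : stride]
        out += view @ params.weight[k]
    return out


# ---------------------------------------------------------------------------
# pruning


def prune(
    st: SparseTensor,
    scores: np.ndarray,
    cfg: PruneConfig,
    gt_occupancy: CoordinateManager | None = None,
) -> SparseTensor:
    """Drop points whose score falls below tau.

    Inference keeps rows with ``score >= tau``.  Training additionally keeps
    every row whose coordinate is present in the ground-truth occupancy at
    this tensor stride (teacher forcing), so supervision targets are never
    starved early in training.
    """
    st2, _ = prune_fwd(st, scores, cfg, gt_occupancy)
    return st2


def prune_fwd(
    st: SparseTensor,
    scores: np.ndarray,
    cfg: PruneConfig,
    gt_occupancy: CoordinateManager | None = None,
) -> tuple[SparseTensor, dict]:
    scores = np.asarray(scores, dtype=np.float64).reshape(-1)
    if scores.shape[0] != len(st):
        raise ValueError("scores must be row-aligned with the tensor")
    keep = scores >= cfg.threshold
    if cfg.training:
        if gt_occupancy is None:
            raise ValueError("training-mode pruning requires the ground-truth occupancy")
        if len(st):
            keep = keep | gt_occupancy.contains(st.coords)
    idx = np.nonzero(keep)[0]
    out = SparseTensor(st.coords[idx], st.feats[idx], st.tensor_stride)
    return out, {"kept": idx, "n_in": len(st)}


def prune_bwd(cache: dict, d_out: np.ndarray, c: int) -> np.ndarray:
    d_in = np.zeros((cache["n_in"], c))
    d_in[cache["kept"]] = d_out
    return d_in


# ---------------------------------------------------------------------------
# normalization

_EPS = 1e-5


def normalize_fwd(
    st: SparseTensor, params: LayerParams, training: bool, momentum: float = 0.1
) -> tuple[SparseTensor, dict]:
    """Per-channel standardization over the rows of the batch + affine."""
    x = st.feats
    if len(st) == 0:
        return SparseTensor(st.coords, x.copy(), st.tensor_stride, manager=st.manager), {
            "empty": True
        }
    if training and len(st) == 1:
        # a one-row batch has no spread to standardize: standardizing would
        # collapse the bottleneck to the shift value and destroy the encoded
        # information; apply the affine part only
        y = x * params.norm_scale + params.norm_shift
        out = SparseTensor(st.coords, y, st.tensor_stride, manager=st.manager)
        return out, {"empty": False, "affine_only": True, "x": x, "scale": params.norm_scale}
    if training:
        mean = x.mean(axis=0)
        var = x.var(axis=0)
        if params.running_mean is not None:
            params.running_mean += momentum * (mean - params.running_mean)
            params.running_var += momentum * (var - params.running_var)
    else:
        mean = params.running_mean if params.running_mean is not None else x.mean(axis=0)
        var = params.running_var if params.running_var is not None else x.var(axis=0)
    invstd = 1.0 / np.sqrt(var + _EPS)
    xhat = (x - mean) * invstd
    y = xhat * params.norm_scale + params.norm_shift
    out = SparseTensor(st.coords, y, st.tensor_stride, manager=st.manager)
    cache = {"empty": False, "xhat": xhat, "invstd": invstd,
             "scale": params.norm_scale, "training": training}
    return out, cache


def normalize(st: SparseTensor, params: LayerParams, training: bool = False) -> SparseTensor:
    return normalize_fwd(st, params, training)[0]


def normalize_bwd(cache: dict, d_out: np.ndarray):
    """Returns (d_in, d_scale, d_shift)."""
    if cache.get("empty"):
        return d_out, None, None
    if cache.get("affine_only"):
        d_scale = (d_out * cache["x"]).sum(axis=0)
        d_shift = d_out.sum(axis=0)
        return d_out * cache["scale"], d_scale, d_shift
    xhat, invstd, scale = cache["xhat"], cache["invstd"], cache["scale"]
    d_scale = (d_out * xhat).sum(axis=0)
    d_shift = d_out.sum(axis=0)
    if not cache["training"]:
        return d_out * scale * invstd, d_scale, d_shift
    n = xhat.shape[0]
    d_xhat = d_out * scale
    d_in = (invstd / n) * (n * d_xhat - d_xhat.sum(axis=0) - xhat * (d_xhat * xhat).sum(axis=0))
    return d_in, d_scale, d_shift


# ---------------------------------------------------------------------------
# nonlinearities


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    e = np.exp(x[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def activation_fwd(st: SparseTensor, kind: str) -> tuple[SparseTensor, dict]:
    x = st.feats
    if kind == "relu":
        y = np.maximum(x, 0.0)
        cache = {"kind": kind, "mask": x > 0}
    elif kind == "sigmoid":
        y = _sigmoid(x)
        cache = {"kind": kind, "y": y}
    else:
        raise ValueError(f"unknown activation {kind!r}")
    return SparseTensor(st.coords, y, st.tensor_stride, manager=st.manager), cache


def activation(st: SparseTensor, kind: str) -> SparseTensor:
    """Elementwise nonlinearity; coordinates unchanged."""
    return activation_fwd(st, kind)[0]


def activation_bwd(cache: dict, d_out: np.ndarray) -> np.ndarray:
    if cache["kind"] == "relu":
        return d_out * cache["mask"]
    y = cache["y"]
    return d_out * y * (1.0 - y)
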