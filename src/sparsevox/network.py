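"""Encoder-decoder assembly and analytic cost accounting.

The architecture is a 13-convolution encoder (one stem convolution, then six
blocks of stride-2 kernel-2 convolution followed by a kernel-3 convolution,
walking a 7-element channel list ch[0..6]) and a generative decoder of six
blocks (generative transposed convolution upsampling by 2 — kernel 4 for the
first block, kernel 2 for the rest — a kernel-3 convolution, and a 1-channel
scoring convolution driving a pruning layer), closed by a 1x1 projection to a
single logit channel.  Every convolution except the final projection carries
per-channel affine normalization; with that convention the analytic parameter
count reproduces the published totals for both reference channel lists
(0.435M and 18.14M).
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np

from . import layers as L
from .sparse import CoordinateManager, SparseTensor, stride_coords

CH1 = (8, 8, 16, 16, 32, 32, 64)
CH2 = (22, 32, 32, 128, 156, 256, 388)


@dataclass
class LayerSpec:
    """One convolution of the architecture."""

    name: str
    role: str  # conv | strided-conv | generative-transposed-conv | scoring-conv | final-projection
    c_in: int
    c_out: int
    ks: int
    stride: int = 1  # downsampling stride, or upsampling factor for generative layers
    has_normalization: bool = True
    has_pruning: bool = False

    def __post_init__(self):
        if self.ks < 1 or self.stride not in (1, 2):
            raise ValueError(f"invalid layer spec {self}")
        if self.c_in < 1 or self.c_out < 1:
            raise ValueError("channel counts must be positive")

    def n_params(self) -> int:
        n = self.ks**3 * self.c_in * self.c_out + self.c_out
        if self.has_normalization:
            n += 2 * self.c_out
        return n


@dataclass
class NetworkConfig:
    """Channel list + task + pruning threshold + experimental flags."""

    ch: tuple[int, ...] = CH1
    task: str = "completion"
    tau: float = 0.0
    additive_skips: bool = False
    normalization: bool = True

    def __post_init__(self):
        self.ch = tuple(int(c) for c in self.ch)
        if len(self.ch) != 7 or any(c < 1 for c in self.ch):
            raise ValueError("ch must be a 7-element list of positive channel counts")
        if self.task not in ("completion", "superres"):
            raise ValueError(f"unknown task {self.task!r}")


def layer_specs(cfg: NetworkConfig) -> list[LayerSpec]:
    """The ordered convolution list of the architecture."""
    ch = cfg.ch
    norm = cfg.normalization
    specs = [LayerSpec("enc0", "conv", 1, ch[0], 3, 1, norm)]
    for i in range(6):
        specs.append(LayerSpec(f"enc{i+1}s", "strided-conv", ch[i], ch[i + 1], 2, 2, norm))
        specs.append(LayerSpec(f"enc{i+1}c", "conv", ch[i + 1], ch[i + 1], 3, 1, norm))
    for j in range(6):
        a, b = ch[6 - j], ch[5 - j]
        specs.append(
            LayerSpec(f"dec{j}g", "generative-transposed-conv", a, b, 4 if j == 0 else 2, 2, norm)
        )
        specs.append(LayerSpec(f"dec{j}c", "conv", b, b, 3, 1, norm))
        specs.append(
            LayerSpec(f"dec{j}score", "scoring-conv", b, 1, 1, 1, False, has_pruning=True)
        )
    specs.append(LayerSpec("proj", "final-projection", ch[0], 1, 1, 1, False))
    return specs


def count_parameters(cfg: NetworkConfig) -> int:
    """Analytic parameter count: Ks^3*C_in*C_out + C_out per convolution, plus
    2*C_out per normalization layer; must match exact enumeration of a built
    network's tensors."""
    return sum(s.n_params() for s in layer_specs(cfg))


# ---------------------------------------------------------------------------
# cost model


@dataclass
class CostModel:
    rows: list[dict]
    totals: dict

    def as_text(self) -> str:
        buf = io.StringIO()
        cols = list(self.rows[0].keys()) if self.rows else []
        buf.write("\t".join(cols) + "\n")
        for r in self.rows:
            buf.write("\t".join(str(r[c]) for c in cols) + "\n")
        buf.write("totals: " + ", ".join(f"{k}={v}" for k, v in self.totals.items()) + "\n")
        return buf.getvalue()


def _dense_size_printed(n: float, ks: int, stride: int, p: int) -> float:
    # the published linear estimate 1/s * (n + 2p - ks); differs from the
    # conventional output-size formula by one — both are reported
    return (n + 2 * p - ks) / stride


def _dense_size_conventional(n: int, ks: int, stride: int, p: int) -> int:
    return (n + 2 * p - ks) // stride + 1


def activation_sizes(
    cfg: NetworkConfig,
    input_spatial_size: tuple[int, int, int],
    input_voxel_count: int,
) -> CostModel:
    """Per-layer activation-size accounting.

    Dense-path sizes follow the published linear estimate per axis alongside
    the conventional formula; sparse-path sizes are voxel counts propagated
    through stride/generation rules (upper bounds for generative layers,
    which pruning then reduces).
    """
    rows = []
    dims_printed = [float(d) for d in input_spatial_size]
    dims_conv = list(input_spatial_size)
    n_sparse = int(input_voxel_count)
    for s in layer_specs(cfg):
        if s.role == "generative-transposed-conv":
            dims_printed = [d * s.stride for d in dims_printed]
            dims_conv = [d * s.stride for d in dims_conv]
            n_sparse = n_sparse * s.ks**3
        elif s.role in ("conv", "strided-conv", "scoring-conv", "final-projection"):
            p = (s.ks - 1) // 2 if s.ks % 2 == 1 else 0
            dims_printed = [_dense_size_printed(d, s.ks, s.stride, p) for d in dims_printed]
            dims_conv = [_dense_size_conventional(int(d), s.ks, s.stride, p) for d in dims_conv]
        rows.append(
            {
                "name": s.name,
                "role": s.role,
                "dense_size_printed": round(float(np.prod(dims_printed)) * s.c_out, 1),
                "dense_size_conventional": int(np.prod(dims_conv)) * s.c_out,
                "sparse_voxels_upper_bound": n_sparse * s.c_out if input_voxel_count else 0,
            }
        )
    totals = {
        "dense_printed": round(sum(r["dense_size_printed"] for r in rows), 1),
        "dense_conventional": sum(r["dense_size_conventional"] for r in rows),
        "sparse_upper_bound": sum(r["sparse_voxels_upper_bound"] for r in rows),
    }
    return CostModel(rows, totals)


def flops_estimate(cfg: NetworkConfig, voxel_counts) -> CostModel:
    """FLOP accounting: per layer, N_f * Ks^3 * C_in * C_out.

    ``voxel_counts`` is either a scalar (same active-voxel count at every
    layer — the sparse steady-state approximation) or a per-layer sequence.
    Totals are linear in the voxel counts.
    """
    specs = layer_specs(cfg)
    if np.isscalar(voxel_counts):
        counts = [int(voxel_counts)] * len(specs)
    else:
        counts = [int(v) for v in voxel_counts]
        if len(counts) != len(specs):
            raise ValueError(f"expected {len(specs)} per-layer voxel counts, got {len(counts)}")
    rows = []
    for s, n in zip(specs, counts):
        rows.append(
            {
                "name": s.name,
                "role": s.role,
                "flops": n * s.ks**3 * s.c_in * s.c_out,
            }
        )
    return CostModel(rows, {"flops": sum(r["flops"] for r in rows)})


# ---------------------------------------------------------------------------
# the executable network


SCORE_BIAS_INIT = 0.5  # positive so an untrained net does not prune everything
PROJ_BIAS_INIT = 0.1  # likewise keeps the untrained final logits above zero


class SparseGenerativeNet:
    """The executable encoder-decoder with training-time tape for gradients."""

    def __init__(self, cfg: NetworkConfig, seed: int = 0):
        self.cfg = cfg
        self.specs = layer_specs(cfg)
        self.seed = int(seed)
        rng = np.random.default_rng(self.seed)
        self.params: dict[str, L.LayerParams] = {}
        for s in self.specs:
            if s.role == "scoring-conv":
                bias0 = SCORE_BIAS_INIT
            elif s.role == "final-projection":
                bias0 = PROJ_BIAS_INIT
            else:
                bias0 = 0.0
            self.params[s.name] = L.init_layer_params(
                rng, s.ks, s.c_in, s.c_out, with_norm=s.has_normalization, bias_value=bias0
            )

    # -- parameter bookkeeping ------------------------------------------------

    def parameter_arrays(self) -> dict[str, np.ndarray]:
        out = {}
        for name, p in self.params.items():
            out[f"{name}.weight"] = p.weight
            out[f"{name}.bias"] = p.bias
            if p.norm_scale is not None:
                out[f"{name}.norm_scale"] = p.norm_scale
                out[f"{name}.norm_shift"] = p.norm_shift
        return out

    def buffer_arrays(self) -> dict[str, np.ndarray]:
        out = {}
        for name, p in self.params.items():
            if p.running_mean is not None:
                out[f"{name}.running_mean"] = p.running_mean
                out[f"{name}.running_var"] = p.running_var
        return out

    def n_parameters(self) -> int:
        return sum(int(a.size) for a in self.parameter_arrays().values())

    # -- forward --------------------------------------------------------------

    def forward(
        self,
        st: SparseTensor,
        training: bool = False,
        gt_pyramid: dict[int, CoordinateManager] | None = None,
        bounds=None,
        teacher_force: bool | None = None,
    ) -> dict:
        """Run the network; returns a record with the final logit tensor, the
        per-stage pruning scores, and (in training mode) the tape for backward.

        ``gt_pyramid`` maps tensor stride -> ground-truth occupancy manager and
        is required for training-mode pruning (teacher forcing).  ``bounds``
        (the grid shape) clips generated coordinates to the volume; without it
        an untrained decoder over-generates far outside the grid.
        """
        if teacher_force is None:
            teacher_force = training
        if teacher_force and gt_pyramid is None:
            raise ValueError("teacher-forced forward requires gt_pyramid")
        tape: list[dict] = []
        stages: list[dict] = []
        spec_by_name = {s.name: s for s in self.specs}
        enc_outputs: dict[int, tuple[int, SparseTensor]] = {}  # stride -> (tape idx, st)

        def run_conv(name: str, x: SparseTensor) -> SparseTensor:
            s = spec_by_name[name]
            p = self.params[name]
            if s.role == "generative-transposed-conv":
                y, cache = L.generative_transposed_conv_fwd(x, p, s.ks, s.stride, bounds=bounds)
            else:
                y, cache = L.sparse_conv_fwd(x, p, s.ks, s.stride)
            tape.append({"kind": "conv", "name": name, "cache": cache})
            if s.has_normalization:
                y, cache = L.normalize_fwd(y, p, training)
                tape.append({"kind": "norm", "name": name, "cache": cache})
                y, cache = L.activation_fwd(y, "relu")
                tape.append({"kind": "relu", "cache": cache})
            return y

        x = st
        x = run_conv("enc0", x)
        enc_outputs[x.tensor_stride] = (len(tape) - 1, x)
        for i in range(6):
            x = run_conv(f"enc{i+1}s", x)
            x = run_conv(f"enc{i+1}c", x)
            enc_outputs[x.tensor_stride] = (len(tape) - 1, x)
        for j in range(6):
            x = run_conv(f"dec{j}g", x)
            x = run_conv(f"dec{j}c", x)
            if self.cfg.additive_skips and x.tensor_stride in enc_outputs:
                src_idx, enc_st = enc_outputs[x.tensor_stride]
                if enc_st.num_channels == x.num_channels:
                    enc_rows = enc_st.manager.lookup(x.coords)
                    hit = enc_rows >= 0
                    if hit.any():
                        feats = x.feats.copy()
                        feats[hit] += enc_st.feats[enc_rows[hit]]
                        x = SparseTensor(x.coords, feats, x.tensor_stride, manager=x.manager)
                        tape.append(
                            {
                                "kind": "skip",
                                "src_idx": src_idx,
                                "src_rows": enc_rows[hit],
                                "dst_rows": np.nonzero(hit)[0],
                                "src_shape": enc_st.feats.shape,
                            }
                        )
            # scoring + pruning
            sname = f"dec{j}score"
            score_st, score_cache = L.sparse_conv_fwd(x, self.params[sname], 1)
            scores = score_st.feats[:, 0]
            gt_mgr = gt_pyramid.get(x.tensor_stride) if gt_pyramid else None
            cfg_prune = L.PruneConfig(threshold=self.cfg.tau, training=teacher_force)
            pruned, prune_cache = L.prune_fwd(x, scores, cfg_prune, gt_mgr)
            stages.append(
                {
                    "scores": scores,
                    "coords": x.coords,
                    "tensor_stride": x.tensor_stride,
                }
            )
            tape.append(
                {
                    "kind": "stage",
                    "stage": j,
                    "name": sname,
                    "score_cache": score_cache,
                    "prune_cache": prune_cache,
                    "c": x.num_channels,
                }
            )
            x = pruned
        final_logits, proj_cache = L.sparse_conv_fwd(x, self.params["proj"], 1)
        tape.append({"kind": "conv", "name": "proj", "cache": proj_cache})
        return {"final": final_logits, "stages": stages, "tape": tape}

    # -- backward -------------------------------------------------------------

    def backward(
        self,
        record: dict,
        d_final: np.ndarray,
        d_stage_scores: list[np.ndarray | None],
    ) -> dict[str, np.ndarray]:
        """Chain the per-layer backward passes over the forward tape.

        ``d_final`` is the loss gradient w.r.t. the final logit features
        (N_final x 1); ``d_stage_scores[j]`` the gradient w.r.t. decoder stage
        j's pruning scores (length = rows seen by that stage's scorer), or
        None.  Returns a flat gradient dict keyed like ``parameter_arrays``.
        """
        grads: dict[str, np.ndarray] = {
            k: np.zeros_like(v) for k, v in self.parameter_arrays().items()
        }
        pending: dict[int, np.ndarray] = {}
        d = np.asarray(d_final, dtype=np.float64)
        tape = record["tape"]
        for i in range(len(tape) - 1, -1, -1):
            if i in pending:
                d = d + pending.pop(i)
            entry = tape[i]
            kind = entry["kind"]
            if kind == "conv":
                d_in, d_w, d_b = L.conv_bwd(entry["cache"], d)
                name = entry["name"]
                grads[f"{name}.weight"] += d_w
                grads[f"{name}.bias"] += d_b
                d = d_in
            elif kind == "norm":
                d_in, d_sc, d_sh = L.normalize_bwd(entry["cache"], d)
                if d_sc is not None:
                    name = entry["name"]
                    grads[f"{name}.norm_scale"] += d_sc
                    grads[f"{name}.norm_shift"] += d_sh
                d = d_in
            elif kind == "relu":
                d = L.activation_bwd(entry["cache"], d)
            elif kind == "stage":
                d_in = L.prune_bwd(entry["prune_cache"], d, entry["c"])
                ds = d_stage_scores[entry["stage"]]
                if ds is not None:
                    ds = np.asarray(ds, dtype=np.float64).reshape(-1, 1)
                    d_sc_in, d_w, d_b = L.conv_bwd(entry["score_cache"], ds)
                    name = entry["name"]
                    grads[f"{name}.weight"] += d_w
                    grads[f"{name}.bias"] += d_b
                    d_in = d_in + d_sc_in
                d = d_in
            elif kind == "skip":
                extra = np.zeros(entry["src_shape"])
                extra[entry["src_rows"]] = d[entry["dst_rows"]]
                key = entry["src_idx"]
                pending[key] = pending.get(key, 0) + extra
            else:  # pragma: no cover
                raise RuntimeError(f"unknown tape entry {kind!r}")
        return grads


def build_network(cfg: NetworkConfig, seed: int = 0) -> SparseGenerativeNet:
    """Assemble the architecture from a channel list with seeded initialization."""
    return SparseGenerativeNet(cfg, seed=seed)


def gt_pyramid(gt_coords: np.ndarray, max_level: int = 6) -> dict[int, CoordinateManager]:
    """Ground-truth occupancy managers at tensor strides 1, 2, ..., 2**max_level.

    The occupancy at stride t is the block-max downsampling of the stride-1
    occupancy: a coarse cell is occupied iff any fine ground-truth voxel
    floors into it.
    """
    out: dict[int, CoordinateManager] = {}
    for lvl in range(max_level + 1):
        t = 2**lvl
        out[t] = CoordinateManager(stride_coords(gt_coords, 1, t))
    return out
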