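"""Losses, optimization, and the two task pipelines.

The sparse network trains with binary cross-entropy: a final-stage term over
the predicted coordinates (target = membership in the ground-truth occupancy)
plus one pruning-supervision term per decoder stage, where each stage's
1-channel scoring convolution is pushed toward the ground-truth occupancy
block-max-downsampled to that stage's tensor stride.  Ground-truth points a
sparse output never reached carry their learning signal through exactly these
stage terms — teacher forcing keeps them alive during training so the terms
are never starved.

The dense baseline trains the same layer list, rendered densely, with the
two-class squared-denominator Dice loss.
"""

from __future__ import annotations

import json
import zipfile
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .metrics import dsc
from .network import NetworkConfig, SparseGenerativeNet, build_network, gt_pyramid
from .sparse import SparseTensor
from .synth import CompletionSample, SuperResPair
from .voxgrid import VoxelGrid, dense_to_sparse


@dataclass
class TrainConfig:
    """Optimization settings; every checkpoint records its seed."""

    task: str = "completion"
    ch: tuple[int, ...] = (4, 4, 8, 8, 8, 8, 16)
    epochs: int = 10
    batch_size: int = 1
    lr: float = 1e-3
    optimizer: str = "adam"
    seed: int = 0
    tau: float = 0.0
    additive_skips: bool = False
    # step learning-rate schedule: multiply lr by lr_step_factor from epoch
    # lr_step on (None = constant lr)
    lr_step: int | None = None
    lr_step_factor: float = 0.1
    # warm restarts: every restart_every epochs, reset the optimizer moments
    # and the shuffling stream (None = continuous training)
    restart_every: int | None = None
    # snapshot ensembling: collect a parameter snapshot at every restart
    # boundary from this epoch on (plus the final state); prediction then
    # majority-votes the snapshots (None = single final model)
    snapshot_from: int | None = None
    # random orientation augmentation during training: apply one of the 48
    # axis-permutation/flip grid symmetries to each sample each step
    augment_orientations: bool = False
    # teacher forcing (ground-truth rescue inside training-time pruning) runs
    # until this epoch, then pruning follows the inference rule so the
    # decoder adapts to its own coordinate decisions (None = always on)
    teacher_forcing_until: int | None = None
    final_loss_weight: float = 1.0
    stage_loss_weight: float = 1.0
    pos_weight: float = 1.0  # positive-label weight inside each BCE term
    val_fraction: float = 0.0
    # completion's output is defined to contain the input coordinates, so the
    # prediction is united with the input by default there; super-resolution
    # must be free to prune input voxels, so never by default
    union_input: bool | None = None

    def __post_init__(self):
        self.ch = tuple(int(c) for c in self.ch)
        if self.epochs < 1 or self.lr < 0:
            raise ValueError("epochs must be >= 1 and lr >= 0")
        if self.task not in ("completion", "superres"):
            raise ValueError(f"unknown task {self.task!r}")


# ---------------------------------------------------------------------------
# losses


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500)))


def bce_loss(logits, targets, pos_weight: float = 1.0) -> float:
    """Mean binary cross-entropy from logits.

    The negative of the published log-likelihood form, evaluated point-wise
    and averaged; computed via softplus so extreme logits are safe.  An empty
    evaluation set is defined as loss 0.  ``pos_weight`` scales the
    positive-label term (occupied points are rare, and the hard positives —
    the implant region — rarer still).
    """
    z = np.asarray(logits, dtype=np.float64).reshape(-1)
    y = np.asarray(targets, dtype=np.float64).reshape(-1)
    if z.size == 0:
        import logging

        logging.getLogger(__name__).warning("BCE over an empty coordinate union: 0")
        return 0.0
    # softplus(z) - y*z == y*softplus(-z) + (1-y)*softplus(z)
    return float(np.mean(pos_weight * y * _softplus(-z) + (1.0 - y) * _softplus(z)))


def bce_grad(logits, targets, pos_weight: float = 1.0) -> np.ndarray:
    """d(mean BCE)/d(logits): ((1-y)*sigmoid(z) - w*y*(1-sigmoid(z))) / n."""
    z = np.asarray(logits, dtype=np.float64).reshape(-1)
    y = np.asarray(targets, dtype=np.float64).reshape(-1)
    if z.size == 0:
        return np.zeros(0)
    s = _sigmoid(z)
    return ((1.0 - y) * s - pos_weight * y * (1.0 - s)) / z.size


def dice_loss(pred_probs: np.ndarray, target: np.ndarray) -> float:
    """Two-class squared-denominator Dice loss.

    ``-2 * sum_i (sum y_i∘y'_i) / (sum y_i∘y_i + sum y'_i∘y'_i)`` over the
    background (i=0) and target (i=1) channels; -2 at a perfect binary match.
    Used by the dense baseline only.
    """
    p = np.asarray(pred_probs, dtype=np.float64)
    t = np.asarray(target, dtype=np.float64)
    loss = 0.0
    for cls in (0, 1):
        y = p if cls == 1 else 1.0 - p
        yp = t if cls == 1 else 1.0 - t
        denom = float((y * y).sum() + (yp * yp).sum())
        if denom > 0:
            loss += float((y * yp).sum()) / denom
    return -2.0 * loss


def dice_loss_grad(pred_probs: np.ndarray, target: np.ndarray) -> np.ndarray:
    p = np.asarray(pred_probs, dtype=np.float64)
    t = np.asarray(target, dtype=np.float64)
    grad = np.zeros_like(p)
    for cls in (0, 1):
        y = p if cls == 1 else 1.0 - p
        yp = t if cls == 1 else 1.0 - t
        denom = float((y * y).sum() + (yp * yp).sum())
        if denom > 0:
            num = float((y * yp).sum())
            d_y = yp / denom - 2.0 * y * num / denom**2
            grad += -2.0 * d_y * (1.0 if cls == 1 else -1.0)
    return grad


# ---------------------------------------------------------------------------
# optimizer


class Adam:
    """Adam over a dict of named parameter arrays (updates in place)."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        c1 = 1.0 - self.b1**self.t
        c2 = 1.0 - self.b2**self.t
        for k, p in self.params.items():
            g = grads[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            p -= self.lr * (self.m[k] / c1) / (np.sqrt(self.v[k] / c2) + self.eps)


# ---------------------------------------------------------------------------
# the shared training step


def completion_loss(
    net: SparseGenerativeNet,
    input_st: SparseTensor,
    gt_coords: np.ndarray,
    cfg: TrainConfig,
    with_grads: bool = True,
    bounds=None,
    teacher_force: bool = True,
):
    """Forward + loss (+ gradients) for one sample.

    Returns ``(loss, grads_or_None, record)``.
    """
    pyramid = gt_pyramid(gt_coords, max_level=6)
    record = net.forward(
        input_st, training=True, gt_pyramid=pyramid, bounds=bounds,
        teacher_force=teacher_force,
    )
    final = record["final"]
    y_final = (
        pyramid[final.tensor_stride].contains(final.coords).astype(np.float64)
        if len(final)
        else np.zeros(0)
    )
    z_final = final.feats[:, 0]
    w = cfg.pos_weight
    loss = cfg.final_loss_weight * bce_loss(z_final, y_final, w)
    stage_targets = []
    for stage in record["stages"]:
        t = stage["tensor_stride"]
        y = pyramid[t].contains(stage["coords"]).astype(np.float64)
        stage_targets.append(y)
        loss += cfg.stage_loss_weight * bce_loss(stage["scores"], y, w)
    if not with_grads:
        return loss, None, record
    d_final = (cfg.final_loss_weight * bce_grad(z_final, y_final, w)).reshape(-1, 1)
    d_scores = [
        cfg.stage_loss_weight * bce_grad(s["scores"], y, w)
        for s, y in zip(record["stages"], stage_targets)
    ]
    grads = net.backward(record, d_final, d_scores)
    return loss, grads, record


def _sample_to_pair(sample, task: str) -> tuple[VoxelGrid, VoxelGrid]:
    if task == "completion":
        return sample.defective, sample.complete
    return sample.upscaled, sample.target


def _train(dataset, cfg: TrainConfig, net: SparseGenerativeNet | None = None):
    """Shared optimization loop for both tasks."""
    if net is None:
        net = build_network(
            NetworkConfig(
                ch=cfg.ch, task=cfg.task, tau=cfg.tau, additive_skips=cfg.additive_skips
            ),
            seed=cfg.seed,
        )
    params = net.parameter_arrays()
    opt = Adam(params, lr=cfg.lr)
    history = []
    # pre-extract sparse inputs and gt coordinate sets once
    pairs = []
    for sample in dataset:
        grid_in, grid_gt = _sample_to_pair(sample, cfg.task)
        pairs.append(
            (
                dense_to_sparse(grid_in),
                np.argwhere(grid_gt.data != 0),
                grid_gt.shape,
                (grid_in.data, grid_gt.data),
            )
        )
    aug_rng = np.random.default_rng([cfg.seed, 0xF11B])
    order_rng = np.random.default_rng([cfg.seed, 0xA11CE])
    snapshots: list[dict[str, np.ndarray]] = []

    def take_snapshot():
        snapshots.append(
            {k: v.copy() for k, v in {**params, **net.buffer_arrays()}.items()}
        )

    for epoch in range(cfg.epochs):
        if cfg.restart_every and epoch > 0 and epoch % cfg.restart_every == 0:
            if cfg.snapshot_from is not None and epoch >= cfg.snapshot_from:
                take_snapshot()
            opt = Adam(params, lr=cfg.lr)
            order_rng = np.random.default_rng([cfg.seed, 0xA11CE])
        if cfg.lr_step is not None:
            opt.lr = cfg.lr * (cfg.lr_step_factor if epoch >= cfg.lr_step else 1.0)
        order = order_rng.permutation(len(pairs))
        losses = []
        n_pred = []
        teacher = (
            True
            if cfg.teacher_forcing_until is None
            else epoch < cfg.teacher_forcing_until
        )
        for si in order:
            st_in, gt_coords, shape, grids = pairs[si]
            if cfg.augment_orientations:
                perm = aug_rng.permutation(3)
                flips = aug_rng.integers(0, 2, size=3)

                def orient(a):
                    a = np.transpose(a, perm)
                    for ax in range(3):
                        if flips[ax]:
                            a = np.flip(a, axis=ax)
                    return np.ascontiguousarray(a)

                g_in, g_gt = orient(grids[0]), orient(grids[1])
                st_in = dense_to_sparse(VoxelGrid(g_in))
                gt_coords = np.argwhere(g_gt != 0)
                shape = g_in.shape
            loss, grads, record = completion_loss(
                net, st_in, gt_coords, cfg, bounds=shape, teacher_force=teacher
            )
            if cfg.lr > 0:
                opt.step(grads)
            losses.append(loss)
            n_pred.append(len(record["final"]))
        if max(n_pred) == 0:
            raise RuntimeError(
                f"over-pruning: no predicted coordinates in epoch {epoch}"
            )
        entry = {
            "epoch": epoch,
            "loss": float(np.mean(losses)),
            "mean_pred_voxels": float(np.mean(n_pred)),
        }
        if cfg.val_fraction > 0:
            n_val = max(1, int(cfg.val_fraction * len(dataset)))
            val_dsc = [
                dsc(predict(net, _sample_to_pair(s, cfg.task)[0], cfg), _sample_to_pair(s, cfg.task)[1])
                for s in dataset[-n_val:]
            ]
            entry["val_dsc"] = float(np.mean(val_dsc))
        history.append(entry)
    if cfg.snapshot_from is not None:
        take_snapshot()
        net.snapshots = snapshots
    return net, history


def _restore_snapshot(net: SparseGenerativeNet, snapshot: dict[str, np.ndarray]) -> None:
    arrays = {**net.parameter_arrays(), **net.buffer_arrays()}
    for k, v in snapshot.items():
        arrays[k][...] = v


def train_completion(samples: list[CompletionSample], cfg: TrainConfig):
    """Train the sparse completion network; returns ``(net, history)``."""
    cfg.task = "completion"
    return _train(samples, cfg)


def train_superres(pairs: list[SuperResPair], cfg: TrainConfig):
    """Train the super-resolution network (same machinery; the up-scaled
    coarse grid is the input, the high-resolution grid the target).

    The up-scaled input and the target must live on the same lattice.
    """
    cfg.task = "superres"
    for p in pairs:
        if p.upscaled.shape != p.target.shape:
            raise ValueError(
                f"input/target lattice mismatch: {p.upscaled.shape} vs {p.target.shape}"
            )
    return _train(pairs, cfg)


def predict(net: SparseGenerativeNet, grid: VoxelGrid, cfg: TrainConfig | None = None) -> VoxelGrid:
    """Inference: tau-threshold pruning only; a voxel is predicted occupied iff
    it survives the final pruning stage and its final sigmoid output exceeds
    0.5 (logit > 0).  Coordinates generated outside the grid are discarded at
    densification.

    If the net carries warm-restart snapshots (snapshot ensembling), each
    snapshot votes and a voxel is kept when at least half the snapshots
    predict it.
    """
    snapshots = getattr(net, "snapshots", None)
    if snapshots:
        current = {
            k: v.copy()
            for k, v in {**net.parameter_arrays(), **net.buffer_arrays()}.items()
        }
        votes = np.zeros(grid.shape, dtype=np.int32)
        try:
            for snap in snapshots:
                _restore_snapshot(net, snap)
                votes += _predict_single(net, grid).data
        finally:
            _restore_snapshot(net, current)
        data = (votes * 2 >= len(snapshots)).astype(np.uint8)
        out = VoxelGrid(data, grid.spacing, grid.origin)
        return _maybe_union(out, grid, cfg)
    return _maybe_union(_predict_single(net, grid), grid, cfg)


def _maybe_union(pred: VoxelGrid, grid: VoxelGrid, cfg: TrainConfig | None) -> VoxelGrid:
    if cfg is not None:
        union = cfg.union_input
        if union is None:
            union = cfg.task == "completion"
        if union:
            return VoxelGrid(pred.data | grid.data, grid.spacing, grid.origin)
    return pred


def _predict_single(net: SparseGenerativeNet, grid: VoxelGrid) -> VoxelGrid:
    st_in = dense_to_sparse(grid)
    record = net.forward(st_in, training=False, bounds=grid.shape)
    final = record["final"]
    shape = np.asarray(grid.shape)
    if len(final):
        keep = (final.feats[:, 0] > 0.0) & (final.coords >= 0).all(axis=1) & (
            final.coords < shape
        ).all(axis=1)
        coords = final.coords[keep]
    else:
        coords = final.coords
    data = np.zeros(grid.shape, dtype=np.uint8)
    if coords.shape[0]:
        data[coords[:, 0], coords[:, 1], coords[:, 2]] = 1
    return VoxelGrid(data, grid.spacing, grid.origin)


# ---------------------------------------------------------------------------
# checkpoints


CHECKPOINT_VERSION = 1


def save_checkpoint(path, net: SparseGenerativeNet, cfg: TrainConfig, history=None) -> None:
    """Single-file archive: parameter arrays + network/train config + version."""
    path = Path(path)
    meta = {
        "version": CHECKPOINT_VERSION,
        "network": {
            "ch": list(net.cfg.ch),
            "task": net.cfg.task,
            "tau": net.cfg.tau,
            "additive_skips": net.cfg.additive_skips,
            "normalization": net.cfg.normalization,
        },
        "seed": net.seed,
        "train_config": asdict(cfg) if cfg else None,
        "history": history,
    }
    arrays = {**net.parameter_arrays(), **net.buffer_arrays()}
    with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as zf:
        zf.writestr("meta.json", json.dumps(meta, sort_keys=True))
        for name, arr in arrays.items():
            buf = arr.astype(np.float64).tobytes()
            zf.writestr(f"arrays/{name}|{'x'.join(map(str, arr.shape))}", buf)


def load_checkpoint(path) -> tuple[SparseGenerativeNet, TrainConfig | None]:
    path = Path(path)
    with zipfile.ZipFile(path) as zf:
        meta = json.loads(zf.read("meta.json"))
        if meta.get("version") != CHECKPOINT_VERSION:
            raise ValueError(
                f"checkpoint version {meta.get('version')} != {CHECKPOINT_VERSION}"
            )
        net = build_network(NetworkConfig(**meta["network"]), seed=meta["seed"])
        arrays = {**net.parameter_arrays(), **net.buffer_arrays()}
        for info in zf.namelist():
            if not info.startswith("arrays/"):
                continue
            name, shape_s = info[len("arrays/"):].split("|")
            shape = tuple(int(s) for s in shape_s.split("x")) if shape_s else ()
            arr = np.frombuffer(zf.read(info), dtype=np.float64).reshape(shape)
            arrays[name][...] = arr
    tcfg = TrainConfig(**meta["train_config"]) if meta.get("train_config") else None
    return net, tcfg


# ---------------------------------------------------------------------------
# dense baseline (toy scale)


class DenseBaseline:
    """The same layer list rendered densely, trained with the Dice loss.

    Kept deliberately minimal: it exists for the sparse-vs-dense comparison at
    toy scale, not as a production dense segmentation model.
    """

    def __init__(self, cfg: NetworkConfig, seed: int = 0):
        from .network import layer_specs
        from . import layers as L

        self.cfg = cfg
        self.specs = [s for s in layer_specs(cfg) if s.role != "scoring-conv"]
        rng = np.random.default_rng(seed)
        self.params = {
            s.name: L.init_layer_params(rng, s.ks, s.c_in, s.c_out, with_norm=False)
            for s in self.specs
        }

    def forward(self, vol: np.ndarray) -> np.ndarray:
        """Dense forward; transposed stages are rendered as nearest-neighbour
        upsampling followed by the stage convolution."""
        from . import layers as L

        x = np.asarray(vol, dtype=np.float64)[..., None]
        for s in self.specs:
            if s.role == "generative-transposed-conv":
                x = x.repeat(s.stride, axis=0).repeat(s.stride, axis=1).repeat(s.stride, axis=2)
                x = L.dense_conv_reference(x, self.params[s.name], s.ks, 1)
            else:
                x = L.dense_conv_reference(x, self.params[s.name], s.ks, s.stride)
            if s.role not in ("final-projection",):
                x = np.maximum(x, 0.0)
        return 1.0 / (1.0 + np.exp(-np.clip(x[..., 0], -500, 500)))
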