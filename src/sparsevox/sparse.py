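"""Sparse-tensor data model and coordinate management.

A sparse tensor stores a binary (or multichannel) voxel volume as the list of
its occupied coordinates plus a feature row per coordinate.  Everything the
network does — convolution, generation, pruning — is phrased in terms of
coordinate lookups, so this module owns the hash-based coordinate index
(FNV-1a 64-bit keys with exact-coordinate chaining), stride bookkeeping, and
kernel-map construction.

Conventions
-----------
* Coordinates are 0-based voxel indices in (x, y, z) order and always live on
  the *original* input lattice: after k stride-2 downsamplings a tensor has
  ``tensor_stride == 2**k`` and every coordinate is a multiple of it.
* Coordinate order is deterministic: managers preserve the insertion order of
  the deduplicated coordinate stream.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

FNV_OFFSET_BASIS = np.uint64(0xCBF29CE484222325)
FNV_PRIME = np.uint64(0x100000001B3)


def fnv1a64(data: bytes) -> int:
    """FNV-1a 64-bit hash of a byte string."""
    h = FNV_OFFSET_BASIS
    with np.errstate(over="ignore"):
        for byte in data:
            h = np.uint64(h ^ np.uint64(byte)) * FNV_PRIME
    return int(h)


def fnv1a64_rows(coords: np.ndarray) -> np.ndarray:
    """Vectorized FNV-1a 64 over coordinate rows.

    Each row is serialized as little-endian 4-byte signed integers per axis
    and hashed independently; returns a uint64 array of length N.
    """
    coords = np.ascontiguousarray(coords, dtype="<i4")
    if coords.size == 0:
        return np.empty(0, dtype=np.uint64)
    nbytes = coords.shape[1] * 4
    raw = coords.view(np.uint8).reshape(coords.shape[0], nbytes)
    h = np.full(coords.shape[0], FNV_OFFSET_BASIS, dtype=np.uint64)
    with np.errstate(over="ignore"):
        for j in range(nbytes):
            h = (h ^ raw[:, j].astype(np.uint64)) * FNV_PRIME
    return h


def _as_coords(coords) -> np.ndarray:
    arr = np.asarray(coords)
    if arr.size == 0:
        return arr.reshape(0, 3).astype(np.int32)
    if not np.issubdtype(arr.dtype, np.integer):
        if np.issubdtype(arr.dtype, np.floating) and np.allclose(arr, np.round(arr)):
            arr = np.round(arr).astype(np.int64)
        else:
            raise TypeError("coordinates must be integer-valued")
    if arr.ndim != 2:
        raise ValueError("coordinate matrix must be 2-D (N x dim)")
    return arr.astype(np.int32)


def _pack_rows(coords: np.ndarray) -> np.ndarray:
    """Exact 63-bit encoding of a coordinate row (the chaining comparator).

    Works for plain 3-D rows and for rows with a leading batch index
    (63 // dim bits per component: +/-2**20 for 3-D, +/-2**14 for 4-D).
    """
    dim = coords.shape[1]
    width = 63 // dim
    bias = np.int64(1) << (width - 1)
    c = coords.astype(np.int64) + bias
    if c.size and (c.min() < 0 or c.max() >= (bias << 1)):
        raise ValueError(
            f"coordinates outside the supported range [-2**{width - 1}, 2**{width - 1})"
        )
    packed = c[:, 0]
    for j in range(1, dim):
        packed = (packed << width) | c[:, j]
    return packed


class CoordinateManager:
    """Hash-indexed coordinate table with deterministic row order.

    Duplicate coordinates collapse to their first occurrence; row indices
    follow the insertion order of the deduplicated stream.  Lookups go through
    FNV-1a 64-bit keys over the serialized coordinates; hash collisions are
    resolved by comparing an exact packed encoding of the coordinates
    (chaining), so correctness never depends on hash quality.
    """

    _DENSE_LIMIT = 1 << 22  # max bounding-box cells for the O(1) index table

    def __init__(self, coords):
        coords = _as_coords(coords)
        if coords.shape[0] == 0:
            self.coords = coords
            self._packed = np.empty(0, dtype=np.int64)
        else:
            packed = _pack_rows(coords)
            # first-occurrence dedup, preserving stream order
            _, first = np.unique(packed, return_index=True)
            first.sort()
            self.coords = coords[first]
            self._packed = packed[first]
        self._hash_index = None
        self._dense_index = None

    def __len__(self) -> int:
        return self.coords.shape[0]

    @property
    def dim(self) -> int:
        return self.coords.shape[1]

    @property
    def keys(self) -> np.ndarray:
        """FNV-1a 64 key per row."""
        return self._hash()[0]

    def _hash(self):
        if self._hash_index is None:
            keys = fnv1a64_rows(self.coords)
            order = np.argsort(keys, kind="stable")
            self._hash_index = (keys, order, keys[order], self._packed[order])
        return self._hash_index

    def _dense(self):
        """O(1) index table over the coordinate bounding box, when small
        enough; an internal acceleration of the hash table, never a semantic
        change (falls back to hashed lookup for large or degenerate boxes)."""
        if self._dense_index is None:
            if self.dim != 3:
                self._dense_index = False
                return self._dense_index
            lo = self.coords.min(axis=0).astype(np.int64)
            ext = self.coords.max(axis=0).astype(np.int64) - lo + 1
            if np.prod(ext) > self._DENSE_LIMIT:
                self._dense_index = False
            else:
                tbl = np.full(tuple(ext), -1, dtype=np.int64)
                c = self.coords.astype(np.int64) - lo
                tbl[c[:, 0], c[:, 1], c[:, 2]] = np.arange(len(self))
                self._dense_index = (lo, ext, tbl)
        return self._dense_index

    def lookup(self, queries) -> np.ndarray:
        """Row index for each query coordinate, or -1 where absent."""
        queries = _as_coords(queries)
        n = queries.shape[0]
        out = np.full(n, -1, dtype=np.int64)
        if n == 0 or len(self) == 0:
            return out
        dense = self._dense()
        if dense is not False:
            lo, ext, tbl = dense
            q = queries.astype(np.int64) - lo
            inb = (q >= 0).all(axis=1) & (q < ext).all(axis=1)
            qi = q[inb]
            out[inb] = tbl[qi[:, 0], qi[:, 1], qi[:, 2]]
            return out
        _, order, sorted_keys, sorted_packed = self._hash()
        qkeys = fnv1a64_rows(queries)
        qpacked = _pack_rows(queries)
        pos = np.searchsorted(sorted_keys, qkeys, side="left")
        valid = pos < len(self)
        pos_c = np.minimum(pos, len(self) - 1)
        hit = valid & (sorted_keys[pos_c] == qkeys)
        exact = hit & (sorted_packed[pos_c] == qpacked)
        out[exact] = order[pos_c[exact]]
        # hash collision chains: same FNV key, different coordinate — walk on
        maybe = np.nonzero(hit & ~exact)[0]
        for qi in maybe:
            p = pos[qi] + 1
            while p < len(self) and sorted_keys[p] == qkeys[qi]:
                if sorted_packed[p] == qpacked[qi]:
                    out[qi] = order[p]
                    break
                p += 1
        return out

    def lookup_hashed(self, queries) -> np.ndarray:
        """Row lookup forced through the FNV-1a hash table (no dense path);
        used to cross-check the two lookup routes."""
        dense_saved = self._dense_index
        self._dense_index = False
        try:
            return self.lookup(queries)
        finally:
            self._dense_index = dense_saved

    def contains(self, queries) -> np.ndarray:
        return self.lookup(queries) >= 0


class SparseTensor:
    """Coordinate matrix + feature matrix + tensor stride (the engine currency).

    ``coords`` is N×3 (int), ``feats`` N×C (float); every coordinate is a
    multiple of ``tensor_stride`` on each axis and unique under the manager's
    key.  The manager is built lazily on first access (internal layer outputs
    often never need one); building it also asserts row uniqueness.
    """

    def __init__(self, coords, feats, tensor_stride: int = 1, manager=None):
        self.coords = _as_coords(coords)
        self.feats = np.atleast_2d(np.asarray(feats, dtype=np.float64))
        if self.feats.shape[0] == 0:
            self.feats = self.feats.reshape(0, self.feats.shape[1] if self.feats.ndim == 2 else 1)
        if self.coords.shape[0] != self.feats.shape[0]:
            raise ValueError(
                f"coords rows ({self.coords.shape[0]}) != feats rows ({self.feats.shape[0]})"
            )
        if tensor_stride < 1:
            raise ValueError("tensor_stride must be a positive integer")
        self.tensor_stride = int(tensor_stride)
        if self.coords.size and np.any(self.coords % self.tensor_stride != 0):
            raise ValueError("coordinates must be integer multiples of tensor_stride")
        self._manager = manager
        if manager is not None and len(manager) != self.coords.shape[0]:
            raise ValueError("duplicate coordinate rows in SparseTensor")

    @property
    def manager(self) -> CoordinateManager:
        if self._manager is None:
            self._manager = CoordinateManager(self.coords)
            if len(self._manager) != self.coords.shape[0]:
                raise ValueError("duplicate coordinate rows in SparseTensor")
        return self._manager

    def __repr__(self) -> str:
        return (
            f"SparseTensor(n={len(self)}, channels={self.num_channels}, "
            f"tensor_stride={self.tensor_stride})"
        )

    def __len__(self) -> int:
        return self.coords.shape[0]

    @property
    def num_channels(self) -> int:
        return self.feats.shape[1]

    def to_table(self) -> str:
        """Debug dump: one line per point, ``x y z f1 ... fc``."""
        lines = []
        for c, f in zip(self.coords, self.feats):
            lines.append(" ".join(map(str, c)) + " " + " ".join(f"{v:.6g}" for v in f))
        return "\n".join(lines)


def build_manager(coords) -> CoordinateManager:
    return CoordinateManager(coords)


def stride_coords(coords, tensor_stride: int, stride: int) -> np.ndarray:
    """Coarsen coordinates by an integer stride.

    Floors each coordinate to the coarse lattice ``tensor_stride * stride``
    (floor division, so negative coordinates round toward -inf) and
    deduplicates, preserving first-occurrence order.  The caller's new tensor
    stride is ``tensor_stride * stride``.
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    coords = _as_coords(coords)
    step = tensor_stride * stride
    coarse = (coords // step) * step
    return CoordinateManager(coarse).coords


def kernel_offsets(ks: int, dimension: int = 3) -> np.ndarray:
    """Integer offset vectors of a cubic kernel, in lexicographic order.

    Odd ks: the symmetric cube {-(ks-1)/2, ..., (ks-1)/2}^d.  Even ks: the
    one-step-positive-biased cube {-ks/2+1, ..., ks/2}^d (the common sparse-CNN
    convention; the symmetric span formula is only integral for odd ks).
    Cardinality is ks**dimension.
    """
    if ks < 1:
        raise ValueError("kernel size must be >= 1")
    if ks % 2 == 1:
        rng = range(-(ks - 1) // 2, (ks - 1) // 2 + 1)
    else:
        rng = range(-ks // 2 + 1, ks // 2 + 1)
    return np.array(list(itertools.product(rng, repeat=dimension)), dtype=np.int32)


@dataclass
class KernelMap:
    """Per-offset pairing of input rows to output rows.

    ``pairs[k] = (in_rows, out_rows)`` for kernel offset index k; within one
    offset an output row pairs with at most one input row.
    """

    offsets: np.ndarray
    pairs: dict[int, tuple[np.ndarray, np.ndarray]]

    def total_pairs(self) -> int:
        return sum(len(i) for i, _ in self.pairs.values())


def build_kernel_map(
    in_manager: CoordinateManager,
    out_coords: np.ndarray,
    ks: int,
    in_tensor_stride: int,
) -> KernelMap:
    """Connect output coordinates to input coordinates through kernel offsets.

    For offset k, output coordinate D' pairs with the input coordinate
    ``D = D' + k * in_tensor_stride`` whenever D exists in the input — the
    per-axis neighbour constraint |D - D'| <= span * stride, enumerated
    offset by offset.  Works unchanged for stride-1, strided, and transposed
    layers because coordinates always live on the common original lattice.
    """
    offsets = kernel_offsets(ks)
    out_coords = _as_coords(out_coords)
    pairs: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    n_out = out_coords.shape[0]
    if n_out == 0 or len(in_manager) == 0:
        return KernelMap(offsets, pairs)
    # one batched lookup over all offsets
    n_k = offsets.shape[0]
    queries = (
        out_coords[None, :, :].astype(np.int64)
        + offsets[:, None, :].astype(np.int64) * in_tensor_stride
    ).reshape(-1, 3)
    rows = in_manager.lookup(queries).reshape(n_k, n_out)
    out_rows_all = np.arange(n_out, dtype=np.int64)
    for k in range(n_k):
        hit = rows[k] >= 0
        if hit.any():
            pairs[k] = (rows[k][hit], out_rows_all[hit])
    return KernelMap(offsets, pairs)


def generative_out_coords(
    in_coords: np.ndarray, ks: int, out_tensor_stride: int, bounds=None
) -> np.ndarray:
    """Output coordinate set of a generative transposed convolution.

    The kernel-span expansion ``{c + t' * k}`` over all input coordinates c and
    kernel offsets k, deduplicated in generation order (input-major, offsets in
    lexicographic order).  ``bounds`` (a shape tuple) optionally restricts the
    expansion to [0, bounds) — points generated outside the volume can never be
    part of a valid occupancy and would otherwise snowball through the decoder.
    """
    in_coords = _as_coords(in_coords)
    if in_coords.shape[0] == 0:
        return in_coords
    offsets = kernel_offsets(ks).astype(np.int64) * out_tensor_stride
    expanded = (in_coords[:, None, :].astype(np.int64) + offsets[None, :, :]).reshape(-1, 3)
    if bounds is not None:
        b = np.asarray(bounds, dtype=np.int64)
        keep = (expanded >= 0).all(axis=1) & (expanded < b).all(axis=1)
        expanded = expanded[keep]
    return CoordinateManager(expanded).coords
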