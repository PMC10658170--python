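"""Synthetic skull-like shells, craniotomy-style defects, and datasets.

Real cranial datasets (MRI skull-strip surfaces, CT threshold masks) are thin
closed shells occupying roughly 10% or less of their voxel grid, with a
cranial vault from which surgical defects are cut.  This module emulates that
statistical structure with perturbed two-surface ellipsoid shells: sparse,
closed, single-component, with sub-voxel sinusoidal surface detail that is
lost under block-max downsampling and must be re-generated by the
super-resolution network — the premise of both task pipelines, without any
data download.

All randomness flows from explicit seeds; sample i of a dataset uses the seed
sequence ``(seed, i)`` so datasets are reproducible and extensible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage

from .voxgrid import VoxelGrid, downsample, downsample_mean, upscale, write_grid

# shells for the super-resolution task are thicker (in voxels at the target
# resolution) so that fractional-coverage downsampling and re-upscaling keep
# the total occupancy statistically stable, as in real multi-resolution CT
SUPERRES_THICKNESS_SCALE = 2.5

REFERENCE_RESOLUTION = 64  # shell thickness is quoted in voxels at this size


@dataclass
class ShellSpec:
    """Geometry of one synthetic skull shell."""

    size: int = 64
    semi_axes: tuple[float, float, float] = (0.42, 0.38, 0.34)  # fractions of grid size
    thickness: float = 2.0  # voxels at the reference resolution
    detail_amplitude: float = 0.06
    detail_frequency: int = 6
    rotation: tuple[float, float, float] = (0.0, 0.0, 0.0)  # radians, z-y-x Euler
    seed: int = 0

    def __post_init__(self):
        if self.size < 8:
            raise ValueError("grid size must be >= 8")
        if any(not 0 < a <= 0.5 for a in self.semi_axes):
            raise ValueError("semi-axes must be in (0, 0.5] of the grid size")
        if self.thickness < 1:
            raise ValueError("shell thickness must be >= 1 voxel")

    @classmethod
    def random(cls, rng: np.random.Generator, size: int = 64, seed: int = 0) -> "ShellSpec":
        """A randomized but realistic spec: mild axis anisotropy, small
        rotation, moderate surface detail."""
        semi = tuple(rng.uniform(0.32, 0.44) * np.array([1.0, 0.92, 0.85]))
        return cls(
            size=size,
            semi_axes=semi,
            thickness=float(rng.uniform(1.5, 2.5)),
            detail_amplitude=float(rng.uniform(0.03, 0.08)),
            detail_frequency=int(rng.integers(4, 9)),
            rotation=tuple(rng.uniform(-0.3, 0.3, size=3)),
            seed=seed,
        )


@dataclass
class DefectSpec:
    """A craniotomy-style defect cut from the upper (cranial) part of a shell."""

    shape: str = "sphere"  # sphere | box
    size: float = 0.25  # fraction of the shell's mean outer radius
    seed: int = 0
    max_tries: int = 20

    def __post_init__(self):
        if self.shape not in ("sphere", "box"):
            raise ValueError(f"unknown defect shape {self.shape!r}")
        if not 0 < self.size <= 1.5:
            raise ValueError("defect size must be a positive fraction of the outer radius")


def _rotation_matrix(angles) -> np.ndarray:
    az, ay, ax = angles
    cz, sz = np.cos(az), np.sin(az)
    cy, sy = np.cos(ay), np.sin(ay)
    cx, sx = np.cos(ax), np.sin(ax)
    rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    return rz @ ry @ rx


def make_shell(spec: ShellSpec) -> VoxelGrid:
    """Voxelize a perturbed two-surface ellipsoid shell.

    A voxel is occupied iff its normalized ellipsoid radius falls between the
    (direction-dependent) outer surface ``1 + detail`` and the inner surface
    one shell-thickness below it.  Thickness is scaled with resolution so the
    same spec family yields geometrically consistent multi-resolution grids.
    """
    n = spec.size
    semi = np.asarray(spec.semi_axes) * n
    center = (n - 1) / 2.0
    r = _rotation_matrix(spec.rotation)
    idx = np.indices((n, n, n), dtype=np.float64)
    p = idx.reshape(3, -1).T - center
    q = (p @ r.T) / semi
    s = np.linalg.norm(q, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = np.arctan2(q[:, 1], q[:, 0])
        phi = np.arccos(np.clip(q[:, 2] / np.where(s > 0, s, 1.0), -1, 1))
    f = spec.detail_frequency
    detail = spec.detail_amplitude * (
        0.6 * np.sin(f * theta) * np.sin(phi) ** 2 + 0.4 * np.cos(f * phi)
    )
    t_vox = max(1.0, spec.thickness * n / REFERENCE_RESOLUTION)
    t_norm = t_vox / semi.min()
    outer = 1.0 + detail
    inner = outer - t_norm
    occ = (s <= outer) & (s >= inner)
    return VoxelGrid(occ.reshape(n, n, n).astype(np.uint8))


def apply_defect(grid: VoxelGrid, spec: DefectSpec) -> tuple[VoxelGrid, VoxelGrid]:
    """Cut a defect: returns ``(defective, implant)`` with
    defective ∪ implant = grid, defective ∩ implant = ∅, implant nonempty.

    The defect center is drawn from shell voxels in the upper (cranial) third
    of the occupied z-range; draws that would empty either side are resampled
    up to ``max_tries`` times.
    """
    occ = np.argwhere(grid.data != 0)
    if occ.shape[0] == 0:
        raise ValueError("cannot cut a defect from an empty grid")
    rng = np.random.default_rng(spec.seed)
    zmin, zmax = occ[:, 2].min(), occ[:, 2].max()
    z_cut = zmin + 2.0 * (zmax - zmin) / 3.0
    upper = occ[occ[:, 2] >= z_cut]
    if upper.shape[0] == 0:
        upper = occ
    extents = occ.max(axis=0) - occ.min(axis=0) + 1
    radius = max(1.0, spec.size * float(extents.mean()) / 2.0)
    idx = np.indices(grid.shape).reshape(3, -1).T
    for _ in range(spec.max_tries):
        center = upper[rng.integers(upper.shape[0])]
        if spec.shape == "sphere":
            region = (np.linalg.norm(idx - center, axis=1) <= radius).reshape(grid.shape)
        else:
            region = (np.abs(idx - center) <= radius).all(axis=1).reshape(grid.shape)
        implant = grid.data & region
        defective = grid.data & ~region
        if implant.any() and defective.any():
            return VoxelGrid(defective, grid.spacing, grid.origin), VoxelGrid(
                implant, grid.spacing, grid.origin
            )
    raise ValueError("failed to place a defect intersecting the shell")


@dataclass
class CompletionSample:
    """One completion training case: defective input, complete target, implant."""

    defective: VoxelGrid
    complete: VoxelGrid
    implant: VoxelGrid
    sample_id: str = ""


@dataclass
class SuperResPair:
    """One super-resolution case: coarse input, its up-scaled version (the
    network input), and the high-resolution target on the same lattice."""

    coarse: VoxelGrid
    upscaled: VoxelGrid
    target: VoxelGrid
    sample_id: str = ""


def make_completion_samples(
    n: int, resolution: int = 32, seed: int = 0, defect: DefectSpec | None = None
) -> list[CompletionSample]:
    """In-memory completion dataset at one resolution."""
    out = []
    for i in range(n):
        rng = np.random.default_rng([seed, i])
        shell = ShellSpec.random(rng, size=resolution, seed=i)
        grid = make_shell(shell)
        dspec = defect or DefectSpec()
        dspec = DefectSpec(dspec.shape, dspec.size, seed=int(rng.integers(2**31)))
        defective, implant = apply_defect(grid, dspec)
        out.append(CompletionSample(defective, grid, implant, sample_id=f"s{i:04d}"))
    return out


def make_superres_samples(
    n: int, res_lo: int = 16, res_hi: int = 32, seed: int = 0
) -> list[SuperResPair]:
    """In-memory super-resolution dataset: hi-res shell, block-max coarse
    version, and the trilinear up-scaling of the coarse version."""
    if res_hi % res_lo != 0:
        raise ValueError("res_hi must be a multiple of res_lo")
    factor = res_hi // res_lo
    out = []
    for i in range(n):
        rng = np.random.default_rng([seed, i])
        shell = ShellSpec.random(rng, size=res_hi, seed=i)
        shell = ShellSpec(
            **{**asdict(shell), "thickness": shell.thickness * SUPERRES_THICKNESS_SCALE}
        )
        target = make_shell(shell)
        coarse = downsample_mean(target, factor)
        up = upscale(coarse, factor)
        out.append(SuperResPair(coarse, up, target, sample_id=f"s{i:04d}"))
    return out


def make_dataset(
    n: int,
    resolutions,
    task: str,
    seed: int,
    out_dir,
    defect: DefectSpec | None = None,
    train_fraction: float = 0.75,
) -> dict:
    """Write an on-disk dataset (NRRD files + manifest.json) and return the manifest.

    For completion, each sample carries the complete shell at every requested
    resolution plus a defective/implant decomposition cut at that resolution
    (so the conservation identity holds exactly per resolution).  For
    super-resolution, the two extreme resolutions form coarse/up-scaled/target
    triples.
    """
    resolutions = sorted(int(r) for r in resolutions)
    if task not in ("completion", "superres"):
        raise ValueError(f"unknown task {task!r}")
    if task == "superres" and len(resolutions) < 2:
        raise ValueError("superres datasets need at least two resolutions")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    n_train = int(np.ceil(train_fraction * n))
    manifest = {
        "task": task,
        "n": n,
        "seed": int(seed),
        "resolutions": resolutions,
        "samples": [],
    }
    max_res = resolutions[-1]
    for i in range(n):
        rng = np.random.default_rng([seed, i])
        base = ShellSpec.random(rng, size=max_res, seed=i)
        sid = f"s{i:04d}"
        rec = {
            "id": sid,
            "split": "train" if i < n_train else "test",
            "shell_spec": asdict(base),
            "files": {},
            "counts": {},
        }
        grid_hi = make_shell(base)
        if task == "completion":
            defect_seed = int(rng.integers(2**31))
            for res in resolutions:
                spec_r = ShellSpec(**{**asdict(base), "size": res})
                grid = make_shell(spec_r) if res != max_res else grid_hi
                dspec = defect or DefectSpec()
                dspec = DefectSpec(dspec.shape, dspec.size, seed=defect_seed)
                defective, implant = apply_defect(grid, dspec)
                for tag, g in (("complete", grid), ("defective", defective), ("implant", implant)):
                    fname = f"{sid}_{tag}_{res}.nrrd"
                    write_grid(g, out_dir / fname)
                    rec["files"][f"{tag}_{res}"] = fname
                    rec["counts"][f"{tag}_{res}"] = g.nonzero_count()
        else:
            res_lo, res_hi = resolutions[0], resolutions[-1]
            factor = res_hi // res_lo
            base = ShellSpec(
                **{**asdict(base), "thickness": base.thickness * SUPERRES_THICKNESS_SCALE}
            )
            grid_hi = make_shell(base)
            rec["shell_spec"] = asdict(base)
            coarse = downsample_mean(grid_hi, factor)
            up = upscale(coarse, factor)
            for tag, g in (("coarse", coarse), ("upscaled", up), ("target", grid_hi)):
                fname = f"{sid}_{tag}.nrrd"
                write_grid(g, out_dir / fname)
                rec["files"][tag] = fname
                rec["counts"][tag] = g.nonzero_count()
        manifest["samples"].append(rec)
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def connected_components(grid: VoxelGrid) -> int:
    """Number of 26-connected components of the occupancy."""
    _, num = ndimage.label(grid.data, structure=np.ones((3, 3, 3), dtype=int))
    return int(num)
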