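"""Masked-grid volume data model shared by every analysis stage.

A :class:`BrainGrid` couples a 3-D voxel lattice to world (MNI millimetre)
space through a 4x4 affine and carries the boolean in-brain mask.  All
statistical fields (modelled-activation maps, ALE scores, p-values, Z maps,
difference maps, binary masks) live in :class:`StatVolume` objects on such a
grid.  Connected-component clustering and volumetric Gaussian smoothing are
implemented here because the meta-analytic and the resting-state stages both
need them.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.special import ndtr

log = logging.getLogger(__name__)

FWHM_TO_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))  # fwhm = sigma * 2.3548...

#: volume kinds and the value ranges they promise
VALID_KINDS = ("MA", "ALE", "P", "Z", "DIFF", "R", "MASK", "POSTERIOR", "T")

_CONNECTIVITY_RANK = {"face": 1, "face+edge": 2, "face+edge+corner": 3}


def round_half_away(x: np.ndarray) -> np.ndarray:
    """Round to nearest integer, halves away from zero (focus-placement rule)."""
    x = np.asarray(x, dtype=float)
    return np.trunc(x + np.copysign(0.5, x)).astype(np.int64)


@dataclass(frozen=True)
class BrainGrid:
    """A 3-D voxel lattice with a world affine and an in-brain mask.

    Parameters
    ----------
    shape : tuple of int
        Voxels per axis.
    affine : (4, 4) ndarray
        Maps 0-based voxel indices to the voxel-centre position in MNI mm.
    mask : ndarray of bool
        In-brain voxels; at least one voxel must be inside.
    """

    shape: tuple
    affine: np.ndarray
    mask: np.ndarray

    def __post_init__(self):
        shape = tuple(int(s) for s in self.shape)
        object.__setattr__(self, "shape", shape)
        aff = np.asarray(self.affine, dtype=float)
        if aff.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(aff[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")
        object.__setattr__(self, "affine", aff)
        mask = np.asarray(self.mask, dtype=bool)
        if mask.shape != shape:
            raise ValueError(f"mask shape {mask.shape} != grid shape {shape}")
        if not mask.any():
            raise ValueError("mask has no in-brain voxel")
        object.__setattr__(self, "mask", mask)
        if np.any(self.voxel_sizes <= 0):
            raise ValueError("voxel sizes must be strictly positive")

    @property
    def voxel_sizes(self) -> np.ndarray:
        """Column norms of the linear part, mm per voxel along each axis."""
        return np.linalg.norm(np.asarray(self.affine)[:3, :3], axis=0)

    @property
    def n_in_mask(self) -> int:
        return int(self.mask.sum())

    @property
    def mask_indices(self) -> np.ndarray:
        """(n_in_mask, 3) integer indices of in-mask voxels, C order."""
        return np.argwhere(self.mask)

    def voxel_to_mm(self, ijk) -> np.ndarray:
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        mm = ijk @ self.affine[:3, :3].T + self.affine[:3, 3]
        return mm if mm.shape[0] > 1 else mm[0]

    def mm_to_voxel(self, coords_mm) -> np.ndarray:
        """Nearest-voxel index of world coordinates (no bounds clamp).

        Rounds half away from zero; indices outside the grid are returned
        as-is for the caller to flag.
        """
        coords = np.atleast_2d(np.asarray(coords_mm, dtype=float))
        inv = np.linalg.inv(self.affine)
        vox = coords @ inv[:3, :3].T + inv[:3, 3]
        out = round_half_away(vox)
        return out if coords.shape[0] > 1 else out[0]

    def in_bounds(self, ijk) -> np.ndarray:
        ijk = np.atleast_2d(ijk)
        ok = np.ones(ijk.shape[0], dtype=bool)
        for ax in range(3):
            ok &= (ijk[:, ax] >= 0) & (ijk[:, ax] < self.shape[ax])
        return ok

    def contains(self, ijk) -> np.ndarray:
        """In grid bounds and inside the brain mask."""
        ijk = np.atleast_2d(ijk)
        ok = self.in_bounds(ijk)
        res = np.zeros(ijk.shape[0], dtype=bool)
        sel = ijk[ok]
        res[ok] = self.mask[sel[:, 0], sel[:, 1], sel[:, 2]]
        return res

    def with_mask(self, mask: np.ndarray) -> "BrainGrid":
        return BrainGrid(self.shape, self.affine, mask)


def mm_to_voxel(coord_mm, grid: BrainGrid) -> np.ndarray:
    """Functional alias for :meth:`BrainGrid.mm_to_voxel`."""
    return grid.mm_to_voxel(coord_mm)


def voxel_to_mm(ijk, grid: BrainGrid) -> np.ndarray:
    return grid.voxel_to_mm(ijk)


def _ellipsoid(shape, semi_frac=0.9) -> np.ndarray:
    """Boolean ellipsoid inscribed in a box (procedural stand-in brain)."""
    idx = np.indices(shape).astype(float)
    c = (np.asarray(shape, float) - 1.0) / 2.0
    semi = semi_frac * np.maximum((np.asarray(shape, float) - 1.0) / 2.0, 0.5)
    r2 = sum(((idx[a] - c[a]) / semi[a]) ** 2 for a in range(3))
    return r2 <= 1.0


def ellipsoid_grid(shape=(24, 28, 24), voxel_size_mm=4.0, semi_frac=0.9) -> BrainGrid:
    """Small analysis grid with an ellipsoidal brain mask, centred on (0,0,0) mm.

    The default desk-scale testing space: no template download required.
    """
    shape = tuple(int(s) for s in shape)
    vs = float(voxel_size_mm)
    affine = np.diag([vs, vs, vs, 1.0])
    affine[:3, 3] = -vs * (np.asarray(shape, float) - 1.0) / 2.0
    return BrainGrid(shape, affine, _ellipsoid(shape, semi_frac))


def mni_like_grid(voxel_size_mm=2.0) -> BrainGrid:
    """MNI-bounding-box grid with a procedural ellipsoidal brain mask.

    Covers x in [-78, 78], y in [-112, 76], z in [-70, 86] mm so the standard
    frontal/parietal seed coordinates fall inside.  Real template masks can be
    substituted via :func:`read_nifti`; they are never required.
    """
    vs = float(voxel_size_mm)
    lo = np.array([-78.0, -112.0, -70.0])
    hi = np.array([78.0, 76.0, 86.0])
    shape = tuple(int(np.floor((hi[a] - lo[a]) / vs)) + 1 for a in range(3))
    affine = np.diag([vs, vs, vs, 1.0])
    affine[:3, 3] = lo
    return BrainGrid(shape, affine, _ellipsoid(shape, semi_frac=0.92))


def sphere_mask(grid: BrainGrid, center_mm, radius_mm: float,
                clip_to_mask: bool = True) -> "StatVolume":
    """Binary sphere around a world coordinate (seed-region fixture helper)."""
    ijk = np.indices(grid.shape).astype(float).reshape(3, -1).T
    mm = grid.voxel_to_mm(ijk)
    d2 = np.sum((mm - np.asarray(center_mm, float)) ** 2, axis=1)
    data = (d2 <= float(radius_mm) ** 2).reshape(grid.shape)
    if clip_to_mask:
        data &= grid.mask
    return StatVolume(grid, data.astype(float), kind="MASK")


class StatVolume:
    """A scalar field over the in-mask voxels of a :class:`BrainGrid`.

    ``data`` is stored as a full 3-D array (zero outside the mask except for
    P-maps, where out-of-mask voxels are 1).  ``kind`` states what the values
    are and is validated: MA/ALE in [0, 1], P in (0, 1], MASK in {0, 1}.
    """

    def __init__(self, grid: BrainGrid, data: np.ndarray, kind: str):
        if kind not in VALID_KINDS:
            raise ValueError(f"unknown volume kind {kind!r}")
        data = np.asarray(data, dtype=float)
        if data.shape != grid.shape:
            raise ValueError(f"data shape {data.shape} != grid shape {grid.shape}")
        self.grid = grid
        self.data = data
        self.kind = kind
        self._validate()

    def _validate(self):
        v = self.values
        tol = 1e-9
        if self.kind in ("MA", "ALE"):
            if v.size and (v.min() < -tol or v.max() > 1 + tol):
                raise ValueError(f"{self.kind} values outside [0, 1]")
        elif self.kind == "P":
            if v.size and (v.min() <= 0 or v.max() > 1 + tol):
                raise ValueError("P values outside (0, 1]")
        elif self.kind == "MASK":
            if not np.all((v == 0) | (v == 1)):
                raise ValueError("MASK values must be 0 or 1")

    @property
    def values(self) -> np.ndarray:
        """In-mask values as a flat vector (C order of mask indices)."""
        return self.data[self.grid.mask]

    @property
    def binary(self) -> np.ndarray:
        """Boolean 3-D array (only meaningful for MASK volumes)."""
        return (self.data > 0.5) & self.grid.mask

    def with_values(self, values: np.ndarray, kind=None, fill=0.0) -> "StatVolume":
        """New volume on the same grid from an in-mask value vector."""
        data = np.full(self.grid.shape, float(fill))
        data[self.grid.mask] = values
        return StatVolume(self.grid, data, kind or self.kind)

    def copy(self) -> "StatVolume":
        return StatVolume(self.grid, self.data.copy(), self.kind)

    def __repr__(self):
        v = self.values
        return (f"StatVolume(kind={self.kind}, shape={self.grid.shape}, "
                f"in_mask={self.grid.n_in_mask}, range=[{v.min():.4g}, {v.max():.4g}])")


def volume_from_values(grid: BrainGrid, values: np.ndarray, kind: str,
                       fill: float = 0.0) -> StatVolume:
    data = np.full(grid.shape, float(fill))
    data[grid.mask] = np.asarray(values, dtype=float)
    return StatVolume(grid, data, kind)


# ---------------------------------------------------------------------------
# Gaussian smoothing
# ---------------------------------------------------------------------------

def integrated_gaussian_kernel_1d(sigma_vox: float, truncate: float = 4.0) -> np.ndarray:
    """1-D kernel of per-voxel integrated Gaussian mass, normalised to sum 1.

    Each tap holds the probability mass a unit-total Gaussian places in a
    voxel-wide bin, i.e. Phi((k+1/2)/sigma) - Phi((k-1/2)/sigma), so an
    impulse response reproduces the exact per-voxel masses rather than
    sampled densities.
    """
    if sigma_vox <= 0:
        raise ValueError("sigma must be positive")
    r = max(1, int(math.ceil(truncate * sigma_vox)))
    k = np.arange(-r, r + 1, dtype=float)
    w = ndtr((k + 0.5) / sigma_vox) - ndtr((k - 0.5) / sigma_vox)
    return w / w.sum()


def gaussian_smooth(vol: StatVolume, fwhm_mm: float, truncate: float = 4.0) -> StatVolume:
    """Separable Gaussian smoothing of a volume, FWHM given in mm.

    Values outside the mask are treated as zero and the result is re-masked
    (no edge renormalisation); per-axis sigma adapts to anisotropic voxels.
    """
    if fwhm_mm <= 0:
        raise ValueError("fwhm_mm must be positive")
    grid = vol.grid
    sigmas = (fwhm_mm / FWHM_TO_SIGMA) / grid.voxel_sizes
    data = np.where(grid.mask, vol.data, 0.0)
    data = smooth_array(data, sigmas, truncate)
    data[~grid.mask] = 0.0
    kind = vol.kind if vol.kind in ("MA", "ALE", "Z", "DIFF", "R", "T") else "Z"
    if vol.kind in ("MA", "ALE"):
        data = np.clip(data, 0.0, 1.0)
    return StatVolume(grid, data, kind)


def smooth_array(data: np.ndarray, sigmas_vox, truncate: float = 4.0) -> np.ndarray:
    """Separable integrated-Gaussian convolution of a (possibly 4-D) array.

    ``sigmas_vox`` gives the per-spatial-axis sigma in voxels; trailing axes
    (e.g. time) are left untouched.
    """
    out = np.asarray(data, dtype=float).copy()
    for ax, s in enumerate(np.atleast_1d(sigmas_vox)):
        if s <= 0:
            continue
        k = integrated_gaussian_kernel_1d(float(s), truncate)
        out = ndimage.convolve1d(out, k, axis=ax, mode="constant", cval=0.0)
    return out


# ---------------------------------------------------------------------------
# Connected components
# ---------------------------------------------------------------------------

@dataclass
class ClusterTable:
    """Connected components of a suprathreshold map.

    ``table`` has one row per cluster: cluster_id, size_voxels, peak_value,
    peak mm coordinates; ``members`` holds each cluster's voxel indices.
    Clusters are sorted by descending size (ties: lexicographic peak index).
    """

    table: pd.DataFrame
    members: list = field(default_factory=list)
    label_map: np.ndarray | None = None

    def __len__(self):
        return len(self.table)

    @property
    def sizes(self) -> np.ndarray:
        return self.table["size_voxels"].to_numpy()

    def filter_min_size(self, min_voxels: int) -> "ClusterTable":
        keep = [i for i, s in enumerate(self.sizes) if s >= min_voxels]
        table = self.table.iloc[keep].reset_index(drop=True)
        table["cluster_id"] = np.arange(1, len(keep) + 1)
        members = [self.members[i] for i in keep]
        lm = None
        if self.label_map is not None:
            lm = np.zeros_like(self.label_map)
            for new_id, m in enumerate(members, start=1):
                lm[tuple(m.T)] = new_id
        return ClusterTable(table, members, lm)

    def to_mask(self, grid: BrainGrid) -> StatVolume:
        data = np.zeros(grid.shape)
        for m in self.members:
            data[tuple(m.T)] = 1.0
        return StatVolume(grid, data, "MASK")


def connectivity_structure(connectivity: str = "face") -> np.ndarray:
    if connectivity not in _CONNECTIVITY_RANK:
        raise ValueError(f"connectivity must be one of {sorted(_CONNECTIVITY_RANK)}")
    return ndimage.generate_binary_structure(3, _CONNECTIVITY_RANK[connectivity])


def label_clusters(binary: StatVolume, connectivity: str = "face",
                   values: StatVolume | None = None) -> ClusterTable:
    """Connected components of a binary volume.

    ``values`` optionally supplies the statistic whose per-cluster peak is
    reported; defaults to the binary map itself (peak 1.0).
    """
    if binary.kind != "MASK":
        raise ValueError("label_clusters expects a MASK volume")
    grid = binary.grid
    struct = connectivity_structure(connectivity)
    lab, n = ndimage.label(binary.binary, structure=struct)
    vals = values.data if values is not None else binary.data
    rows, members = [], []
    for cid in range(1, n + 1):
        idx = np.argwhere(lab == cid)
        v = vals[tuple(idx.T)]
        top = np.flatnonzero(v == v.max())
        # lexicographically smallest index among peak ties (argwhere is C-ordered)
        peak_idx = idx[top[0]]
        rows.append((len(idx), float(v.max()), tuple(peak_idx)))
        members.append(idx)
    order = sorted(range(n), key=lambda i: (-rows[i][0], rows[i][2]))
    out_rows = []
    out_members = []
    label_map = np.zeros_like(lab)
    for new_id, i in enumerate(order, start=1):
        size, peak_value, peak_idx = rows[i]
        mm = grid.voxel_to_mm(np.asarray(peak_idx, dtype=float))
        out_rows.append({
            "cluster_id": new_id, "size_voxels": size, "peak_value": peak_value,
            "peak_x_mm": mm[0], "peak_y_mm": mm[1], "peak_z_mm": mm[2],
            "peak_i": peak_idx[0], "peak_j": peak_idx[1], "peak_k": peak_idx[2],
        })
        out_members.append(members[i])
        label_map[tuple(members[i].T)] = new_id
    cols = ["cluster_id", "size_voxels", "peak_value", "peak_x_mm", "peak_y_mm",
            "peak_z_mm", "peak_i", "peak_j", "peak_k"]
    return ClusterTable(pd.DataFrame(out_rows, columns=cols), out_members, label_map)


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def read_nifti(path, kind: str = "Z", reference: BrainGrid | None = None,
               mask: np.ndarray | None = None) -> StatVolume:
    """Read a 3-D NIfTI image as a StatVolume.

    If ``reference`` is given the image must match its shape and affine
    (affine to 1e-4 mm); the reference mask is then used.  Otherwise the mask
    is all-true (or ``mask`` if supplied); MASK-kind images use their own
    nonzero support as both mask and values.
    """
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D image, got shape {data.shape}")
    affine = img.affine
    if reference is not None:
        if tuple(data.shape) != tuple(reference.shape):
            raise ValueError(f"{path}: shape {data.shape} does not match reference "
                             f"grid {reference.shape}")
        if not np.allclose(affine, reference.affine, atol=1e-4):
            raise ValueError(f"{path}: affine mismatch against reference grid")
        grid = reference
    else:
        if kind == "MASK":
            m = data > 0.5
        elif mask is not None:
            m = np.asarray(mask, bool)
        else:
            m = np.ones(data.shape, bool)
        grid = BrainGrid(data.shape, affine, m)
    if kind == "MASK":
        uniq = np.unique(data)
        if not np.all(np.isin(uniq, (0.0, 1.0))):
            raise ValueError(f"{path}: mask image contains values other than 0/1")
    return StatVolume(grid, data, kind)


def read_bold_nifti(path):
    """Read a 4-D BOLD NIfTI; returns (data[x,y,z,t], affine)."""
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"{path}: expected a 4-D image, got shape {data.shape}")
    return data, img.affine


def write_nifti(vol: StatVolume, path) -> None:
    """Write a volume as NIfTI-1: masks as uint8, statistics as float32."""
    import nibabel as nib

    if vol.kind == "MASK":
        data = vol.data.astype(np.uint8)
    else:
        data = vol.data.astype(np.float32)
    nib.Nifti1Image(data, vol.grid.affine).to_filename(str(path))


def write_bold_nifti(data: np.ndarray, affine: np.ndarray, path) -> None:
    import nibabel as nib

    nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine).to_filename(str(path))
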