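"""Activation likelihood estimation (ALE) for coordinate-based meta-analysis.

Each reported activation focus is modelled as a 3-D Gaussian probability
distribution over voxels, expressing the spatial uncertainty of the peak.
Per experiment these focus kernels combine (voxelwise maximum) into a
modelled-activation (MA) map; the union across experiments' MA maps,

    ALE(v) = 1 - prod_i (1 - MA_i(v)),

is the probability that at least one experiment "truly" activates voxel v.
Convergence beyond a random spatial association of experiments is assessed
against an empirical null distribution of ALE scores, obtained either
exactly (histogram combination of the MA-value distributions) or by
Monte-Carlo sampling of random in-mask voxels.  Inference uses a
cluster-forming voxel threshold plus a family-wise-error-corrected minimum
cluster extent derived from a max-cluster-size Monte-Carlo null.

The :class:`ALE` estimator / :class:`ALEResults` pair is the high-level
interface; the module-level functions expose each step individually.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

from .foci import Experiment, FociDatabase
from .grids import (BrainGrid, ClusterTable, StatVolume, FWHM_TO_SIGMA,
                    label_clusters, volume_from_values)

log = logging.getLogger(__name__)

Z_FLOOR = -8.2  # documented floor applied where p = 1


# ---------------------------------------------------------------------------
# Kernel policies and per-experiment kernels
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FixedFWHM:
    """Kernel policy: one FWHM (mm) for every experiment (default 10 mm)."""

    fwhm_mm: float = 10.0

    def __call__(self, n_subjects: int) -> float:
        return float(self.fwhm_mm)


@dataclass(frozen=True)
class SubjectsTableFWHM:
    """Kernel policy from a user-supplied n_subjects -> FWHM (mm) table.

    Lets a published empirical between-subject uncertainty model be plugged
    in; subject counts not in the table fall back to the nearest entry.
    """

    table: tuple  # ((n_subjects, fwhm_mm), ...) sorted by n_subjects

    def __init__(self, mapping):
        object.__setattr__(self, "table",
                           tuple(sorted((int(k), float(v)) for k, v in dict(mapping).items())))
        if not self.table:
            raise ValueError("empty FWHM table")

    def __call__(self, n_subjects: int) -> float:
        ns = np.array([t[0] for t in self.table])
        i = int(np.argmin(np.abs(ns - int(n_subjects))))
        return self.table[i][1]


def _as_policy(kernel_policy) -> object:
    if kernel_policy is None:
        return FixedFWHM()
    if callable(kernel_policy):
        return kernel_policy
    return FixedFWHM(float(kernel_policy))


@dataclass(frozen=True)
class Kernel3D:
    """Separable integrated-Gaussian focus kernel on the voxel lattice.

    ``support`` holds per-voxel probability masses (odd-sized box, sums to
    1); ``radii`` are the per-axis half-widths in voxels.
    """

    fwhm_mm: float
    support: np.ndarray
    radii: tuple

    def __post_init__(self):
        s = np.asarray(self.support, dtype=float)
        if np.any(s < 0) or abs(s.sum() - 1.0) > 1e-6:
            raise ValueError("kernel masses must be >= 0 and sum to 1")

    @property
    def central_mass(self) -> float:
        return float(self.support[self.radii[0], self.radii[1], self.radii[2]])


def kernel_for_experiment(n_subjects: int, grid: BrainGrid,
                          fwhm_policy=None, truncate_sd: float = 3.5) -> Kernel3D:
    """Build the focus kernel for an experiment of ``n_subjects`` subjects.

    The per-voxel mass is the product over axes of 1-D Gaussian CDF
    differences across the voxel extent; the support is truncated at
    ``truncate_sd`` standard deviations and renormalised to unit mass.
    """
    policy = _as_policy(fwhm_policy)
    fwhm = float(policy(int(n_subjects)))
    if fwhm <= 0:
        raise ValueError("FWHM must be positive")
    sigma_mm = fwhm / FWHM_TO_SIGMA
    vs = grid.voxel_sizes
    axes = []
    radii = []
    for ax in range(3):
        sigma_vox = sigma_mm / vs[ax]
        r = max(1, int(math.ceil(truncate_sd * sigma_vox)))
        k = np.arange(-r, r + 1, dtype=float)
        w = ndtr((k + 0.5) / sigma_vox) - ndtr((k - 0.5) / sigma_vox)
        axes.append(w)
        radii.append(r)
    support = axes[0][:, None, None] * axes[1][None, :, None] * axes[2][None, None, :]
    support = support / support.sum()
    return Kernel3D(fwhm, support, tuple(radii))


def _place_kernel_max(data: np.ndarray, kernel: Kernel3D, ijk) -> None:
    """data <- max(data, kernel centred at voxel ijk), clipped to the grid."""
    shape = data.shape
    r = kernel.radii
    lo = [int(ijk[a]) - r[a] for a in range(3)]
    hi = [int(ijk[a]) + r[a] + 1 for a in range(3)]
    dlo = [max(0, lo[a]) for a in range(3)]
    dhi = [min(shape[a], hi[a]) for a in range(3)]
    if any(dlo[a] >= dhi[a] for a in range(3)):
        return
    klo = [dlo[a] - lo[a] for a in range(3)]
    khi = [klo[a] + (dhi[a] - dlo[a]) for a in range(3)]
    dst = data[dlo[0]:dhi[0], dlo[1]:dhi[1], dlo[2]:dhi[2]]
    src = kernel.support[klo[0]:khi[0], klo[1]:khi[1], klo[2]:khi[2]]
    np.maximum(dst, src, out=dst)


def ma_map(exp: Experiment, grid: BrainGrid, kernel: Kernel3D) -> StatVolume:
    """Modelled-activation map of one experiment.

    The value at a voxel is the *maximum* of the masses its foci place there
    (non-additive within experiment, so multiple nearby peaks from one study
    cannot inflate convergence).  Foci whose nearest voxel is outside the
    brain mask are logged and dropped; an experiment with no usable focus is
    an error.
    """
    ijk = np.atleast_2d(grid.mm_to_voxel(exp.foci))
    usable = grid.contains(ijk)
    n_dropped = int((~usable).sum())
    if n_dropped:
        log.info("experiment %r: dropped %d out-of-mask focus/foci", exp.id, n_dropped)
    ijk = ijk[usable]
    if ijk.shape[0] == 0:
        raise ValueError(f"experiment {exp.id!r} has no usable (in-mask) focus")
    data = np.zeros(grid.shape)
    for row in ijk:
        _place_kernel_max(data, kernel, row)
    data[~grid.mask] = 0.0
    return StatVolume(grid, data, "MA")


def ma_matrix(db: FociDatabase, grid: BrainGrid, fwhm_policy=None):
    """In-mask MA values for every experiment, as an (n_exp, n_voxel) array.

    Returns ``(matrix, kernels)``; kernels are reused by the Monte-Carlo
    cluster-extent simulation.
    """
    if len(db) == 0:
        raise ValueError("empty database")
    policy = _as_policy(fwhm_policy)
    kernels = [kernel_for_experiment(e.n_subjects, grid, policy) for e in db]
    mat = np.empty((len(db), grid.n_in_mask))
    for i, (e, k) in enumerate(zip(db, kernels)):
        mat[i] = ma_map(e, grid, k).values
    return mat, kernels


# ---------------------------------------------------------------------------
# Union ALE
# ---------------------------------------------------------------------------

def ale_from_ma(ma_maps) -> StatVolume:
    """Union of MA maps: ALE(v) = 1 - prod_i (1 - MA_i(v))."""
    ma_maps = list(ma_maps)
    if not ma_maps:
        raise ValueError("ale_from_ma: empty MA-map list")
    grid = ma_maps[0].grid
    for m in ma_maps[1:]:
        if m.grid is not grid and (m.grid.shape != grid.shape
                                   or not np.allclose(m.grid.affine, grid.affine)):
            raise ValueError("MA maps must share one grid")
    keep = np.ones(grid.n_in_mask)
    for m in ma_maps:
        keep *= (1.0 - m.values)
    return volume_from_values(grid, 1.0 - keep, "ALE")


def ale_from_matrix(mat: np.ndarray) -> np.ndarray:
    """Union rule on an (n_exp, n_voxel) MA matrix -> in-mask ALE vector."""
    return 1.0 - np.prod(1.0 - mat, axis=0)


# ---------------------------------------------------------------------------
# Empirical null of random spatial association
# ---------------------------------------------------------------------------

class NullDistribution:
    """Distribution of ALE scores under random spatial association.

    analytic_histogram: each experiment's MA map is discretised into a value
    histogram (bin width ``bin_width``); histograms are combined pairwise
    under the union rule, yielding the distribution of the ALE score at a
    voxel receiving one independent uniformly-placed contribution per
    experiment.  sampling: that process is simulated ``n_draws`` times.
    """

    def __init__(self, method: str, bin_width: float = 1e-5, bins=None,
                 probs=None, samples=None):
        self.method = method
        self.bin_width = float(bin_width)
        if method == "analytic_histogram":
            self.bins = np.asarray(bins, dtype=np.int64)
            probs = np.asarray(probs, dtype=float)
            self.probs = probs / probs.sum()
            if abs(self.probs.sum() - 1.0) > 1e-9:
                raise ValueError("null probabilities must sum to 1")
            # tail[i] = P(X >= bins[i]); appended 0 for beyond-support queries
            self._tail = np.concatenate(
                [np.cumsum(self.probs[::-1])[::-1], [0.0]])
            self._cum = np.concatenate([[0.0], np.cumsum(self.probs)])
            self.samples = None
            self.n_draws = None
        elif method == "sampling":
            self.samples = np.sort(np.asarray(samples, dtype=float))
            self.n_draws = self.samples.size
            self.bins = None
            self.probs = None
        else:
            raise ValueError(f"unknown null method {method!r}")

    # -- constructors ------------------------------------------------------

    @classmethod
    def analytic(cls, mat: np.ndarray, bin_width: float = 1e-5) -> "NullDistribution":
        w = float(bin_width)
        bins, probs = _value_hist(mat[0], w)
        for i in range(1, mat.shape[0]):
            b2, p2 = _value_hist(mat[i], w)
            va = bins * w
            vb = b2 * w
            union = 1.0 - (1.0 - va)[:, None] * (1.0 - vb)[None, :]
            idx = np.rint(union / w).astype(np.int64).ravel()
            pr = (probs[:, None] * p2[None, :]).ravel()
            dense = np.bincount(idx, weights=pr)
            nz = np.flatnonzero(dense)
            bins, probs = nz.astype(np.int64), dense[nz]
        return cls("analytic_histogram", bin_width=w, bins=bins, probs=probs)

    @classmethod
    def from_sampling(cls, mat: np.ndarray, n_draws: int, rng) -> "NullDistribution":
        if n_draws < 1000:
            log.warning("sampling null with n_draws=%d (< 1000) is noisy", n_draws)
        rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        n_exp, n_vox = mat.shape
        keep = np.ones(int(n_draws))
        for i in range(n_exp):  # one uniform in-mask voxel per experiment per draw
            picks = rng.integers(0, n_vox, size=int(n_draws))
            keep *= 1.0 - mat[i, picks]
        return cls("sampling", samples=1.0 - keep)

    # -- queries -----------------------------------------------------------

    def sf(self, x) -> np.ndarray:
        """P(X >= x); ties count as 'greater or equal'.

        For sampling nulls the +1-corrected estimator (count+1)/(n+1) is
        used so p is never 0; analytic queries beyond the support return the
        smallest representable tail mass (the top bin's probability).
        """
        x = np.asarray(x, dtype=float)
        if self.method == "analytic_histogram":
            xb = np.rint(x / self.bin_width).astype(np.int64)
            i = np.searchsorted(self.bins, xb, side="left")
            p = self._tail[i]
            return np.maximum(p, self.probs[-1])
        count_ge = self.n_draws - np.searchsorted(self.samples, x, side="left")
        return (count_ge + 1.0) / (self.n_draws + 1.0)

    def cdf(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.method == "analytic_histogram":
            xb = np.rint(x / self.bin_width).astype(np.int64)
            i = np.searchsorted(self.bins, xb, side="right")
            return self._cum[i]
        return np.searchsorted(self.samples, x, side="right") / self.n_draws

    def ale_threshold(self, voxel_p: float) -> float:
        """Smallest ALE value whose sf is < voxel_p (cluster-forming cut)."""
        if self.method == "analytic_histogram":
            ok = np.flatnonzero(self._tail[:-1] < voxel_p)
            if ok.size == 0:
                return np.inf
            return float(self.bins[ok[0]] * self.bin_width)
        k = int(np.ceil(voxel_p * (self.n_draws + 1) - 1))
        if k <= 0:
            return np.inf
        return float(self.samples[self.n_draws - k])


def _value_hist(vals: np.ndarray, w: float):
    idx = np.rint(vals / w).astype(np.int64)
    bins, counts = np.unique(idx, return_counts=True)
    return bins, counts / vals.size


def null_distribution(ma_maps, method: str = "analytic_histogram",
                      n_draws: int = 100_000, rng_seed=None,
                      bin_width: float = 1e-5) -> NullDistribution:
    """Empirical null of ALE under random spatial association.

    ``ma_maps`` may be a list of MA StatVolumes or an (n_exp, n_voxel)
    matrix of in-mask MA values.
    """
    if isinstance(ma_maps, np.ndarray):
        mat = ma_maps
    else:
        ma_maps = list(ma_maps)
        if not ma_maps:
            raise ValueError("need at least one MA map")
        mat = np.stack([m.values for m in ma_maps])
    if method in ("analytic_histogram", "analytic"):
        return NullDistribution.analytic(mat, bin_width)
    if method == "sampling":
        return NullDistribution.from_sampling(mat, n_draws, rng_seed)
    raise ValueError(f"unknown null method {method!r}")


# ---------------------------------------------------------------------------
# p / Z maps and cluster-level FWE
# ---------------------------------------------------------------------------

def p_map(ale: StatVolume, null: NullDistribution) -> StatVolume:
    """Voxelwise p = P_null(X >= ALE(v)); out-of-mask voxels are set to 1."""
    p = np.clip(null.sf(ale.values), None, 1.0)
    return volume_from_values(ale.grid, p, "P", fill=1.0)


def z_map(p: StatVolume) -> StatVolume:
    """Z(v) = Phi^-1(1 - p(v)), floored at -8.2 where p = 1."""
    with np.errstate(divide="ignore"):
        z = -ndtri(p.values)
    z = np.maximum(z, Z_FLOOR)
    return volume_from_values(p.grid, z, "Z")


@dataclass(frozen=True)
class ThresholdSpec:
    """Voxel-level cluster-forming p, cluster-level alpha, and MC effort."""

    voxel_p: float = 0.001
    cluster_alpha: float = 0.05
    n_cluster_sims: int = 100

    def __post_init__(self):
        if not (0 < self.voxel_p < 1) or not (0 < self.cluster_alpha < 1):
            raise ValueError("voxel_p and cluster_alpha must be in (0, 1)")
        if self.n_cluster_sims < 1:
            raise ValueError("n_cluster_sims must be >= 1")


def cluster_fwe_threshold(db: FociDatabase, grid: BrainGrid, kernel_policy,
                          spec: ThresholdSpec, rng_seed,
                          null: NullDistribution | None = None,
                          kernels=None, connectivity: str = "face") -> int:
    """Minimum FWE-surviving cluster extent by Monte-Carlo simulation.

    Each iteration relocates every experiment's foci to uniform random
    in-mask voxels, recomputes the ALE map and its voxel p-values (against
    the empirical null, which is invariant under such relocation, so it is
    computed once), binarises at the cluster-forming threshold and records
    the maximum cluster size.  Returns the smallest extent k such that the
    simulated probability of a maximum null cluster of >= k voxels is at
    most ``cluster_alpha`` (at least 1).
    """
    if spec.n_cluster_sims < 100:
        log.warning("cluster FWE with %d simulations (< 100) is unstable",
                    spec.n_cluster_sims)
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) \
        else np.random.default_rng(rng_seed)
    policy = _as_policy(kernel_policy)
    if kernels is None:
        kernels = [kernel_for_experiment(e.n_subjects, grid, policy) for e in db]
    if null is None:
        mat, _ = ma_matrix(db, grid, policy)
        null = NullDistribution.analytic(mat)
    ale_crit = null.ale_threshold(spec.voxel_p)
    n_foci = [e.n_foci for e in db]
    mask_idx = grid.mask_indices
    max_sizes = np.zeros(spec.n_cluster_sims, dtype=int)
    from .grids import connectivity_structure
    from scipy import ndimage
    struct = connectivity_structure(connectivity)
    for s in range(spec.n_cluster_sims):
        keep = np.ones(grid.n_in_mask)
        data = np.empty(grid.shape)
        for kern, nf in zip(kernels, n_foci):
            data[:] = 0.0
            picks = mask_idx[rng.integers(0, mask_idx.shape[0], size=nf)]
            for row in picks:
                _place_kernel_max(data, kern, row)
            keep *= 1.0 - data[grid.mask]
        supra = np.zeros(grid.shape, dtype=bool)
        supra[grid.mask] = (1.0 - keep) >= ale_crit
        if supra.any():
            lab, n = ndimage.label(supra, structure=struct)
            if n:
                max_sizes[s] = np.bincount(lab.ravel())[1:].max()
    k = 1
    while np.mean(max_sizes >= k) > spec.cluster_alpha:
        k += 1
    return int(k)


# ---------------------------------------------------------------------------
# Model / Results interface
# ---------------------------------------------------------------------------

class ALE:
    """ALE meta-analysis model over a foci database on an analysis grid.

    Parameters
    ----------
    db : FociDatabase
    grid : BrainGrid
    kernel_policy : callable, float or None
        Maps n_subjects to a kernel FWHM in mm (default: fixed 10 mm).
    null_method : {"analytic_histogram", "sampling"}
    n_null_draws : int
        Draws for the sampling null (ignored for the analytic one).
    """

    def __init__(self, db: FociDatabase, grid: BrainGrid, kernel_policy=None,
                 null_method: str = "analytic_histogram",
                 n_null_draws: int = 100_000, bin_width: float = 1e-5):
        if len(db) == 0:
            raise ValueError("cannot model an empty database")
        self.db = db
        self.grid = grid
        self.kernel_policy = _as_policy(kernel_policy)
        self.null_method = null_method
        self.n_null_draws = int(n_null_draws)
        self.bin_width = float(bin_width)

    def fit(self, spec: ThresholdSpec | None = None, seed=None,
            connectivity: str = "face") -> "ALEResults":
        spec = spec or ThresholdSpec()
        rng = seed if isinstance(seed, np.random.Generator) \
            else np.random.default_rng(seed)
        mat, kernels = ma_matrix(self.db, self.grid, self.kernel_policy)
        ale_vals = ale_from_matrix(mat)
        if self.null_method == "sampling":
            null = NullDistribution.from_sampling(mat, self.n_null_draws, rng)
        else:
            null = NullDistribution.analytic(mat, self.bin_width)
        ale = volume_from_values(self.grid, ale_vals, "ALE")
        p = p_map(ale, null)
        z = z_map(p)
        k_min = cluster_fwe_threshold(self.db, self.grid, self.kernel_policy,
                                      spec, rng, null=null, kernels=kernels,
                                      connectivity=connectivity)
        supra = volume_from_values(self.grid,
                                   (p.values < spec.voxel_p).astype(float), "MASK")
        clusters = label_clusters(supra, connectivity, values=z)
        clusters = clusters.filter_min_size(k_min)
        return ALEResults(model=self, spec=spec, ma=mat, ale=ale, p=p, z=z,
                          null=null, cluster_min_size=k_min, clusters=clusters,
                          connectivity=connectivity)


@dataclass
class ALEResults:
    """Fitted ALE maps, empirical null and FWE-thresholded clusters."""

    model: ALE
    spec: ThresholdSpec
    ma: np.ndarray
    ale: StatVolume
    p: StatVolume
    z: StatVolume
    null: NullDistribution
    cluster_min_size: int
    clusters: ClusterTable
    connectivity: str = "face"

    @property
    def thresholded_mask(self) -> StatVolume:
        """Binary map of FWE-surviving clusters (the 'main effect')."""
        return self.clusters.to_mask(self.ale.grid)

    def summary(self) -> str:
        lines = [
            "ALE meta-analysis results",
            "=" * 60,
            f"experiments: {len(self.model.db)}   foci: {self.model.db.n_foci}",
            f"grid: {self.model.grid.shape}, "
            f"{self.model.grid.n_in_mask} in-mask voxels, "
            f"voxel sizes {np.round(self.model.grid.voxel_sizes, 2).tolist()} mm",
            f"null: {self.null.method}",
            f"voxel p < {self.spec.voxel_p:g}, cluster alpha {self.spec.cluster_alpha:g}"
            f" -> min extent {self.cluster_min_size} voxels"
            f" ({self.spec.n_cluster_sims} simulations)",
            f"max ALE: {self.ale.values.max():.5f}   "
            f"max Z: {self.z.values.max():.3f}",
            f"surviving clusters: {len(self.clusters)}",
        ]
        if len(self.clusters):
            tbl = self.clusters.table[["cluster_id", "size_voxels", "peak_value",
                                       "peak_x_mm", "peak_y_mm", "peak_z_mm"]]
            lines += ["", tbl.to_string(index=False,
                                        float_format=lambda v: f"{v:.2f}")]
        return "\n".join(lines)
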