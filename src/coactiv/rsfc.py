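"""Task-independent ("resting state") seed-based functional connectivity.

Per subject, the BOLD time-series are denoised with a nuisance model —
six rigid-body motion parameters, their first derivatives, mean grey /
white / CSF signals, the first five whole-brain PCA components, and
second-order (squared) terms of everything except the PCA components —
then band-pass filtered to 0.01-0.08 Hz, where coherent resting-state
fluctuations live.  The seed time course is the first eigenvariate of the
seed voxels; its Pearson correlation with every grey-matter voxel is
Fisher-Z transformed.  Group inference on a two-seed contrast uses the
paired (within-subject) difference of the two connectivity maps with a
one-sample t statistic and sign-flip permutation cluster-level correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .grids import (BrainGrid, ClusterTable, StatVolume, FWHM_TO_SIGMA,
                    label_clusters, smooth_array, volume_from_values)

log = logging.getLogger(__name__)

R_CLIP = 1.0 - 1e-7  # correlation clip before atanh


# ---------------------------------------------------------------------------
# Data model
# ---------------------------------------------------------------------------

@dataclass
class TimeSeriesDataset:
    """One subject's 4-D BOLD run with motion parameters and tissue masks.

    ``bold`` is (x, y, z, T); ``motion`` is (T, 6), row-aligned with the
    BOLD frames; ``n_discard`` initial frames are dropped by :meth:`trim`
    before any modelling (T2*-equilibration frames).
    """

    subject_id: str
    bold: np.ndarray
    tr_s: float
    motion: np.ndarray
    tissue_masks: dict
    grid: BrainGrid
    n_discard: int = 0

    def __post_init__(self):
        self.bold = np.asarray(self.bold, dtype=float)
        if self.bold.ndim != 4:
            raise ValueError("bold must be 4-D (x, y, z, t)")
        if tuple(self.bold.shape[:3]) != tuple(self.grid.shape):
            raise ValueError("bold spatial shape does not match grid")
        self.motion = np.asarray(self.motion, dtype=float)
        T = self.bold.shape[3]
        if self.motion.shape != (T, 6):
            raise ValueError(f"motion must be ({T}, 6)")
        if self.tr_s <= 0:
            raise ValueError("tr_s must be positive")
        if T <= self.n_discard + 20:
            raise ValueError("too few timepoints after discard (need > 20)")
        for name in ("grey", "white", "csf"):
            if name not in self.tissue_masks:
                raise ValueError(f"missing tissue mask {name!r}")
            m = self.tissue_masks[name]
            if tuple(m.grid.shape) != tuple(self.grid.shape):
                raise ValueError(f"tissue mask {name!r} grid mismatch")

    @property
    def n_timepoints(self) -> int:
        return self.bold.shape[3]

    def trim(self) -> "TimeSeriesDataset":
        """Drop the first ``n_discard`` frames (BOLD and motion rows)."""
        if self.n_discard == 0:
            return self
        return replace(self, bold=self.bold[..., self.n_discard:],
                       motion=self.motion[self.n_discard:], n_discard=0)


@dataclass
class NuisanceMatrix:
    """T x K design of nuisance regressors; all but the intercept centred."""

    matrix: np.ndarray
    column_labels: list

    @property
    def K(self) -> int:
        return self.matrix.shape[1]


@dataclass
class SubjectConnMap:
    """One subject's Fisher-Z seed-connectivity map."""

    subject_id: str
    seed_id: str
    z: StatVolume


def _center(x: np.ndarray) -> np.ndarray:
    return x - x.mean(axis=0, keepdims=True)


def build_nuisance(ds: TimeSeriesDataset, n_pca: int = 5) -> NuisanceMatrix:
    """Nuisance design: motion, motion derivatives, tissue means, PCA,
    squared terms of all non-PCA columns, intercept (K = 42 by default).

    Derivatives are backward differences with a zero first row; PCA runs on
    the column-centred T x V in-mask matrix; squares are computed on the
    centred columns and re-centred.  Requires an already-trimmed dataset.
    """
    if ds.n_discard != 0:
        raise ValueError("build_nuisance expects a trimmed dataset "
                         "(call .trim() first)")
    T = ds.n_timepoints
    motion = _center(ds.motion)
    deriv = np.zeros_like(ds.motion)
    deriv[1:] = np.diff(ds.motion, axis=0)
    deriv = _center(deriv)

    tissue_cols, tissue_labels = [], []
    for name in ("grey", "white", "csf"):
        m = ds.tissue_masks[name].binary
        if not m.any():
            raise ValueError(f"tissue mask {name!r} is empty")
        tissue_cols.append(_center(ds.bold[m].mean(axis=0)[:, None]))
        tissue_labels.append(f"{name}_mean")
    tissue = np.hstack(tissue_cols)

    Y = _center(ds.bold[ds.grid.mask].T)  # T x V, whole brain
    # principal component time courses, descending variance
    u, s, _ = np.linalg.svd(Y, full_matrices=False)
    pca = u[:, :n_pca] * s[:n_pca]

    first_order = np.hstack([motion, deriv, tissue])
    squares = _center(first_order ** 2)
    cols = [first_order, _center(pca), squares, np.ones((T, 1))]
    labels = ([f"motion_{i+1}" for i in range(6)]
              + [f"motion_deriv_{i+1}" for i in range(6)]
              + tissue_labels
              + [f"pca_{i+1}" for i in range(n_pca)]
              + [f"motion_{i+1}_sq" for i in range(6)]
              + [f"motion_deriv_{i+1}_sq" for i in range(6)]
              + [f"{t}_sq" for t in tissue_labels]
              + ["intercept"])
    X = np.hstack(cols)
    if T < X.shape[1]:
        raise ValueError(f"T={T} < K={X.shape[1]}: nuisance model unidentifiable")
    return NuisanceMatrix(X, labels)


def regress_out(ts: np.ndarray, nm: NuisanceMatrix) -> np.ndarray:
    """Least-squares residuals of a T-vector or T x V matrix on the design.

    Rank-deficient designs are handled by the pseudoinverse (dependent
    columns effectively dropped, logged); residuals are orthogonal to every
    column to numerical precision.
    """
    X = nm.matrix
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        log.info("nuisance design rank %d < %d columns; pseudoinverse "
                 "projection drops the dependent directions", rank, X.shape[1])
    ts = np.asarray(ts, dtype=float)
    one_d = ts.ndim == 1
    Y = ts[:, None] if one_d else ts
    pinv = np.linalg.pinv(X)
    resid = Y - X @ (pinv @ Y)
    # one refinement pass: drives residual-column inner products to
    # machine precision even for ill-conditioned designs
    resid = resid - X @ (pinv @ resid)
    return resid[:, 0] if one_d else resid


def bandpass(ts: np.ndarray, tr_s: float, f_lo: float = 0.01,
             f_hi: float = 0.08) -> np.ndarray:
    """Zero-phase band-pass keeping [f_lo, f_hi] Hz (time on axis 0).

    Linear detrend followed by an FFT filter with raised-cosine transition
    bands confined to (f_lo/2, f_lo) and (f_hi, 2*f_hi): unit gain across
    the passband, zero gain at and beyond half/double the band edges.
    """
    nyq = 0.5 / tr_s
    if not (0 < f_lo < f_hi):
        raise ValueError("need 0 < f_lo < f_hi")
    if f_hi >= nyq:
        raise ValueError(f"f_hi={f_hi} >= Nyquist {nyq:.4f} Hz")
    ts = np.asarray(ts, dtype=float)
    one_d = ts.ndim == 1
    Y = ts[:, None] if one_d else ts
    T = Y.shape[0]
    from scipy.signal import detrend
    Y = detrend(Y, axis=0, type="linear")
    freqs = np.fft.rfftfreq(T, d=tr_s)
    w = np.zeros_like(freqs)
    lo_a, lo_b = 0.55 * f_lo, f_lo
    hi_a, hi_b = f_hi, 1.5 * f_hi
    ramp_up = (freqs >= lo_a) & (freqs < lo_b)
    w[ramp_up] = 0.5 * (1 - np.cos(np.pi * (freqs[ramp_up] - lo_a) / (lo_b - lo_a)))
    w[(freqs >= lo_b) & (freqs <= hi_a)] = 1.0
    ramp_dn = (freqs > hi_a) & (freqs <= hi_b)
    w[ramp_dn] = 0.5 * (1 + np.cos(np.pi * (freqs[ramp_dn] - hi_a) / (hi_b - hi_a)))
    out = np.fft.irfft(np.fft.rfft(Y, axis=0) * w[:, None], n=T, axis=0)
    return out[:, 0] if one_d else out


@dataclass
class CleanedBold:
    """Denoised, filtered in-mask time-series (T x n_in_mask) on a grid."""

    grid: BrainGrid
    data: np.ndarray
    tr_s: float

    def seed_columns(self, seed: StatVolume) -> np.ndarray:
        if seed.kind != "MASK":
            raise ValueError("seed must be a MASK volume")
        cols = seed.binary[self.grid.mask]
        return self.data[:, cols]


def seed_eigenvariate(bold_cleaned: CleanedBold, seed: StatVolume) -> np.ndarray:
    """First eigenvariate of the seed voxels' time courses.

    The dominant left singular vector of the T x V_seed matrix, scaled to
    unit variance, with its sign chosen so that it correlates non-negatively
    with the seed-mean time course.
    """
    Y = bold_cleaned.seed_columns(seed)
    if Y.shape[1] == 0:
        raise ValueError("seed contains no in-mask voxel")
    if not np.any(Y.std(axis=0) > 0):
        raise ValueError("all seed voxels have zero variance")
    u, s, _ = np.linalg.svd(Y, full_matrices=False)
    ev = u[:, 0]
    if ev @ Y.mean(axis=1) < 0:
        ev = -ev
    sd = ev.std()
    if sd == 0:
        raise ValueError("degenerate eigenvariate (zero variance)")
    return ev / sd


def seed_corr_map(bold_cleaned: CleanedBold, seed_ts: np.ndarray,
                  grey_mask: StatVolume, subject_id: str = "",
                  seed_id: str = "") -> SubjectConnMap:
    """Pearson correlation of the seed time course with every grey-matter
    voxel, Fisher-Z transformed (r clipped to +-(1-1e-7) before atanh)."""
    grid = bold_cleaned.grid
    cols = grey_mask.binary[grid.mask]
    Y = bold_cleaned.data[:, cols]
    s = (seed_ts - seed_ts.mean())
    s_sd = s.std()
    if s_sd == 0:
        raise ValueError("seed time course has zero variance")
    Yc = Y - Y.mean(axis=0, keepdims=True)
    sd = Yc.std(axis=0)
    ok = sd > 0
    n_flat = int((~ok).sum())
    if n_flat:
        log.info("seed_corr_map: %d zero-variance voxels set to z=0", n_flat)
    r = np.zeros(Y.shape[1])
    r[ok] = (Yc[:, ok] * s[:, None]).mean(axis=0) / (sd[ok] * s_sd)
    z = np.arctanh(np.clip(r, -R_CLIP, R_CLIP))
    zvals = np.zeros(grid.n_in_mask)
    zvals[cols] = z
    return SubjectConnMap(subject_id, seed_id,
                          volume_from_values(grid, zvals, "Z"))


# ---------------------------------------------------------------------------
# Subject-level pipeline
# ---------------------------------------------------------------------------

class SubjectConnectivity:
    """Single-subject seed-connectivity pipeline.

    Order of operations: discard equilibration frames -> spatial smoothing
    (5-mm FWHM by default) -> nuisance regression -> band-pass filtering ->
    seed eigenvariate -> voxelwise correlation -> Fisher Z.

    ``filter_regressors=True`` switches to the variant where data and
    nuisance columns are band-passed before the regression (a sensitivity
    option preventing confound reintroduction); the default applies the
    filter to the residuals, matching the documented order.
    ``denoise=False`` skips the nuisance regression entirely (for bias
    demonstrations), keeping the rest of the pipeline.
    """

    def __init__(self, dataset: TimeSeriesDataset, seeds: dict,
                 smooth_fwhm_mm: float | None = 5.0, band=(0.01, 0.08),
                 denoise: bool = True, filter_regressors: bool = False):
        self.dataset = dataset
        self.seeds = dict(seeds)
        self.smooth_fwhm_mm = smooth_fwhm_mm
        self.band = tuple(band)
        self.denoise = denoise
        self.filter_regressors = filter_regressors

    def fit(self) -> "SubjectConnectivityResults":
        ds = self.dataset.trim()
        grid = ds.grid
        bold = ds.bold
        if self.smooth_fwhm_mm:
            sig = (self.smooth_fwhm_mm / FWHM_TO_SIGMA) / grid.voxel_sizes
            bold = np.where(grid.mask[..., None], bold, 0.0)
            bold = smooth_array(bold, sig)
            bold[~grid.mask] = 0.0
            ds = replace(ds, bold=bold)
        Y = ds.bold[grid.mask].T  # T x V
        f_lo, f_hi = self.band
        if self.denoise:
            nm = build_nuisance(ds)
            if self.filter_regressors:
                Y = bandpass(Y, ds.tr_s, f_lo, f_hi)
                Xf = nm.matrix.copy()
                Xf[:, :-1] = bandpass(Xf[:, :-1], ds.tr_s, f_lo, f_hi)
                Y = regress_out(Y, NuisanceMatrix(Xf, nm.column_labels))
            else:
                Y = regress_out(Y, nm)
                Y = bandpass(Y, ds.tr_s, f_lo, f_hi)
        else:
            nm = None
            Y = bandpass(Y, ds.tr_s, f_lo, f_hi)
        cleaned = CleanedBold(grid, Y, ds.tr_s)
        grey = ds.tissue_masks["grey"]
        maps = {}
        for name, seed in self.seeds.items():
            ev = seed_eigenvariate(cleaned, seed)
            maps[name] = seed_corr_map(cleaned, ev, grey,
                                       subject_id=ds.subject_id, seed_id=name)
        return SubjectConnectivityResults(self, cleaned, nm, maps)


@dataclass
class SubjectConnectivityResults:
    model: SubjectConnectivity
    cleaned: CleanedBold
    nuisance: NuisanceMatrix | None
    maps: dict

    def summary(self) -> str:
        ds = self.model.dataset
        return "\n".join([
            f"Subject {ds.subject_id}: T={ds.n_timepoints - ds.n_discard} "
            f"retained frames, TR={ds.tr_s} s",
            f"denoise: {self.model.denoise} "
            f"(K={self.nuisance.K if self.nuisance else 0} regressors), "
            f"band {self.model.band} Hz, "
            f"smoothing {self.model.smooth_fwhm_mm} mm",
            "seeds: " + ", ".join(self.maps),
        ])


# ---------------------------------------------------------------------------
# Group-level paired contrast
# ---------------------------------------------------------------------------

@dataclass
class GroupContrastResults:
    """Paired group contrast of two seeds' connectivity maps."""

    t: StatVolume
    mask_AgtB: StatVolume
    mask_BgtA: StatVolume
    clusters_AgtB: ClusterTable
    clusters_BgtA: ClusterTable
    cluster_min_size: int
    n_subjects: int
    voxel_p: float
    cluster_alpha: float
    n_permutations: int

    def summary(self) -> str:
        return "\n".join([
            "Paired seed-connectivity contrast (random effects)",
            "=" * 60,
            f"subjects: {self.n_subjects}   voxel p < {self.voxel_p:g}   "
            f"cluster alpha {self.cluster_alpha:g}",
            f"sign-flip permutations: {self.n_permutations}   "
            f"min cluster extent: {self.cluster_min_size} voxels",
            f"A>B: {len(self.clusters_AgtB)} clusters, "
            f"{int(self.mask_AgtB.values.sum())} voxels",
            f"B>A: {len(self.clusters_BgtA)} clusters, "
            f"{int(self.mask_BgtA.values.sum())} voxels",
        ])


def group_contrast(maps_a, maps_b, voxel_p: float = 0.001,
                   cluster_alpha: float = 0.05, n_perm: int = 1000,
                   rng_seed=None, connectivity: str = "face") -> GroupContrastResults:
    """Random-effects paired contrast of two seeds across subjects.

    For each subject the voxelwise difference d_s = z_A,s - z_B,s enters a
    one-sample t test; the voxel threshold is p < ``voxel_p`` per direction
    and cluster-level FWE is controlled by a sign-flipping permutation null
    of the maximum cluster size (both directions pooled into one null).
    """
    maps_a = {m.subject_id: m for m in maps_a}
    maps_b = {m.subject_id: m for m in maps_b}
    common = [sid for sid in maps_a if sid in maps_b]
    if len(common) != len(maps_a) or len(common) != len(maps_b):
        raise ValueError("group_contrast requires paired subjects "
                         "(same ids in both lists)")
    n = len(common)
    if n < 6:
        raise ValueError(f"need at least 6 paired subjects, got {n}")
    grid = maps_a[common[0]].z.grid
    D = np.stack([maps_a[s].z.values - maps_b[s].z.values for s in common])
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) \
        else np.random.default_rng(rng_seed)

    t_crit = stats.t.ppf(1.0 - voxel_p, n - 1)
    mean_sq = (D ** 2).mean(axis=0)

    def t_stat(mean):
        var = (mean_sq - mean ** 2) * n / (n - 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = mean / np.sqrt(var / n)
        return np.nan_to_num(t, nan=0.0, posinf=0.0, neginf=0.0)

    t_obs = t_stat(D.mean(axis=0))

    from scipy import ndimage
    from .grids import connectivity_structure
    struct = connectivity_structure(connectivity)

    def max_cluster(tvals):
        worst = 0
        for supra_vals in (tvals > t_crit, tvals < -t_crit):
            if not supra_vals.any():
                continue
            vol = np.zeros(grid.shape, dtype=bool)
            vol[grid.mask] = supra_vals
            lab, ncl = ndimage.label(vol, structure=struct)
            if ncl:
                worst = max(worst, int(np.bincount(lab.ravel())[1:].max()))
        return worst

    max_sizes = np.zeros(n_perm, dtype=int)
    block = max(1, min(200, n_perm))
    done = 0
    while done < n_perm:
        b = min(block, n_perm - done)
        signs = rng.choice([-1.0, 1.0], size=(b, n))
        means = (signs @ D) / n
        for i in range(b):
            max_sizes[done + i] = max_cluster(t_stat(means[i]))
        done += b
    k = 1
    while np.mean(max_sizes >= k) > cluster_alpha:
        k += 1

    t_vol = volume_from_values(grid, t_obs, "T")

    def direction_mask(supra_vals):
        vol = volume_from_values(grid, supra_vals.astype(float), "MASK")
        clusters = label_clusters(vol, connectivity, values=t_vol)
        clusters = clusters.filter_min_size(k)
        return clusters.to_mask(grid), clusters

    mask_a, cl_a = direction_mask(t_obs > t_crit)
    mask_b, cl_b = direction_mask(t_obs < -t_crit)
    return GroupContrastResults(t_vol, mask_a, mask_b, cl_a, cl_b, int(k),
                                n, voxel_p, cluster_alpha, int(n_perm))


class PairedSeedContrast:
    """Model-style wrapper: PairedSeedContrast(maps_a, maps_b).fit()."""

    def __init__(self, maps_a, maps_b):
        self.maps_a = list(maps_a)
        self.maps_b = list(maps_b)

    def fit(self, voxel_p: float = 0.001, cluster_alpha: float = 0.05,
            n_perm: int = 1000, seed=None,
            connectivity: str = "face") -> GroupContrastResults:
        return group_contrast(self.maps_a, self.maps_b, voxel_p,
                              cluster_alpha, n_perm, seed, connectivity)


# ---------------------------------------------------------------------------
# Motion-parameter text I/O (realignment-parameter dialect)
# ---------------------------------------------------------------------------

def read_motion_params(path) -> np.ndarray:
    arr = np.loadtxt(path)
    if arr.ndim != 2 or arr.shape[1] != 6:
        raise ValueError(f"{path}: expected a T x 6 motion-parameter file")
    return arr


def write_motion_params(motion: np.ndarray, path) -> None:
    np.savetxt(path, np.asarray(motion, dtype=float), fmt="%.6e")
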