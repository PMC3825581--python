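"""Permutation-based difference maps between two ALE analyses.

The observed voxelwise ALE difference between two experiment sets is
compared against an empirical null built by pooling the experiments,
randomly re-dividing them into groups of the original sizes, and recording
the ALE difference of each random division.  The per-voxel posterior
probability of a true difference is the (mid-p corrected) fraction of
permutation differences smaller than the observed one; voxels with
posterior > 0.95 are flagged A>B and posterior < 0.05 B>A.  Flagged maps
are then masked with the minuend's own significant main effect and pruned
to a minimum cohesive cluster extent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .ale import ALE, ALEResults, ThresholdSpec, _as_policy, ale_from_matrix, \
    ma_matrix, z_map, p_map, NullDistribution
from .foci import FociDatabase
from .grids import BrainGrid, StatVolume, label_clusters, volume_from_values

log = logging.getLogger(__name__)


@dataclass
class ContrastResult:
    """Observed difference, permutation posterior, and surviving masks."""

    diff_observed: StatVolume           # ALE_A - ALE_B (or Z_A - Z_B, see flag)
    posterior: StatVolume               # per-voxel P(true difference A > B)
    surviving_mask_AgtB: StatVolume
    surviving_mask_BgtA: StatVolume
    n_permutations: int
    rng_seed: object = None
    posterior_high: float = 0.95
    posterior_low: float = 0.05
    masked: bool = False
    min_extent: int | None = None

    def __post_init__(self):
        a = self.surviving_mask_AgtB.binary
        b = self.surviving_mask_BgtA.binary
        if np.any(a & b):
            raise ValueError("surviving masks must be disjoint")

    def swap_directions(self) -> "ContrastResult":
        post = self.posterior.with_values(1.0 - self.posterior.values)
        return replace(self,
                       diff_observed=self.diff_observed.with_values(
                           -self.diff_observed.values),
                       posterior=post,
                       surviving_mask_AgtB=self.surviving_mask_BgtA,
                       surviving_mask_BgtA=self.surviving_mask_AgtB)

    def summary(self) -> str:
        lines = [
            "ALE permutation contrast",
            "=" * 60,
            f"permutations: {self.n_permutations}   "
            f"posterior thresholds: >{self.posterior_high:g} / <{self.posterior_low:g}",
            f"masked by main effects: {self.masked}"
            + (f", min extent {self.min_extent} voxels" if self.min_extent else ""),
            f"A>B voxels: {int(self.surviving_mask_AgtB.values.sum())}   "
            f"B>A voxels: {int(self.surviving_mask_BgtA.values.sum())}",
        ]
        return "\n".join(lines)


def _random_partitions(rng: np.random.Generator, n_total: int, n_a: int,
                       n_perm: int) -> np.ndarray:
    """(n_perm, n_total) boolean indicator of membership in group A."""
    out = np.zeros((n_perm, n_total), dtype=bool)
    for i in range(n_perm):
        out[i, rng.permutation(n_total)[:n_a]] = True
    return out


def ale_difference(db_a: FociDatabase, db_b: FociDatabase, grid: BrainGrid,
                   kernel_policy=None, n_perm: int = 10_000, rng_seed=None,
                   posterior_high: float = 0.95, posterior_low: float = 0.05,
                   observed_on: str = "ale",
                   perm_block: int = 500) -> ContrastResult:
    """Permutation test of ALE differences between two experiment sets.

    The pooled experiments are repeatedly re-divided into random groups of
    sizes |A| and |B| (experiments selected by both seeds contribute one
    token per membership); posterior(v) is the mid-p estimate
    (#{perm diff < observed} + 0.5) / (n_perm + 1).

    ``observed_on="z"`` reports the observed difference of the two analyses'
    Z maps instead of their ALE maps (a literal reading of thresholding
    "Z-score differences"); significance is always assessed on ALE-score
    differences, the quantity the permutation null is built from.
    """
    if len(db_a) == 0 or len(db_b) == 0:
        raise ValueError("both databases must be non-empty")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) \
        else np.random.default_rng(rng_seed)
    policy = _as_policy(kernel_policy)

    pooled = FociDatabase(list(db_a.experiments) + list(db_b.experiments)) \
        if not (set(db_a.ids) & set(db_b.ids)) else None
    if pooled is not None:
        mat, _ = ma_matrix(pooled, grid, policy)
    else:  # overlapping experiments: keep one token per membership
        mat_a, _ = ma_matrix(db_a, grid, policy)
        mat_b, _ = ma_matrix(db_b, grid, policy)
        mat = np.vstack([mat_a, mat_b])
    n_a, n_total = len(db_a), len(db_a) + len(db_b)

    with np.errstate(divide="ignore"):
        logs = np.log1p(-mat)  # log(1 - MA); -inf only if MA == 1 (degenerate)
    total = logs.sum(axis=0)
    obs_sum_a = logs[:n_a].sum(axis=0)
    ale_a = 1.0 - np.exp(obs_sum_a)
    ale_b = 1.0 - np.exp(total - obs_sum_a)
    obs_diff = ale_a - ale_b

    count_smaller = np.zeros(mat.shape[1])
    done = 0
    while done < n_perm:
        block = min(perm_block, n_perm - done)
        part = _random_partitions(rng, n_total, n_a, block)
        sum_a = part.astype(float) @ logs
        diff_perm = np.exp(total[None, :] - sum_a) - np.exp(sum_a)
        count_smaller += (diff_perm < obs_diff[None, :]).sum(axis=0)
        done += block
    posterior_vals = (count_smaller + 0.5) / (n_perm + 1.0)

    if observed_on == "z":
        za = z_map(p_map(volume_from_values(grid, ale_a, "ALE"),
                         NullDistribution.analytic(mat[:n_a])))
        zb = z_map(p_map(volume_from_values(grid, ale_b, "ALE"),
                         NullDistribution.analytic(mat[n_a:])))
        diff_vol = volume_from_values(grid, za.values - zb.values, "DIFF")
    elif observed_on == "ale":
        diff_vol = volume_from_values(grid, obs_diff, "DIFF")
    else:
        raise ValueError("observed_on must be 'ale' or 'z'")

    posterior = volume_from_values(grid, posterior_vals, "POSTERIOR")
    a_gt_b = volume_from_values(grid, (posterior_vals > posterior_high).astype(float),
                                "MASK")
    b_gt_a = volume_from_values(grid, (posterior_vals < posterior_low).astype(float),
                                "MASK")
    return ContrastResult(diff_vol, posterior, a_gt_b, b_gt_a, int(n_perm),
                          rng_seed=rng_seed, posterior_high=posterior_high,
                          posterior_low=posterior_low)


def _prune(mask: StatVolume, keep_in: StatVolume, min_extent: int,
           connectivity: str) -> StatVolume:
    data = (mask.binary & keep_in.binary).astype(float)
    vol = StatVolume(mask.grid, data, "MASK")
    if min_extent > 1:
        clusters = label_clusters(vol, connectivity)
        vol = clusters.filter_min_size(min_extent).to_mask(mask.grid)
    return vol


def apply_contrast_masking(res: ContrastResult, main_effect_a: StatVolume,
                           main_effect_b: StatVolume, min_extent: int = 20,
                           connectivity: str = "face") -> ContrastResult:
    """Minuend masking plus minimum-extent filtering of a contrast.

    A>B voxels must lie inside A's own FWE-thresholded main effect (and
    symmetrically for B>A): a difference is only reported where the minuend
    shows significant connectivity at all.  Surviving clusters smaller than
    ``min_extent`` cohesive voxels (face adjacency by default) are removed.
    """
    a = _prune(res.surviving_mask_AgtB, main_effect_a, min_extent, connectivity)
    b = _prune(res.surviving_mask_BgtA, main_effect_b, min_extent, connectivity)
    return replace(res, surviving_mask_AgtB=a, surviving_mask_BgtA=b,
                   masked=True, min_extent=min_extent)


class ALESubtraction:
    """Two-sample ALE contrast model (main effects + permutation difference).

    ``fit`` runs both single-set ALE analyses (for the minuend masks), the
    permutation difference test, and the masking/extent rules; it returns a
    :class:`ALESubtractionResults` bundling all three.
    """

    def __init__(self, db_a: FociDatabase, db_b: FociDatabase, grid: BrainGrid,
                 kernel_policy=None):
        self.db_a = db_a
        self.db_b = db_b
        self.grid = grid
        self.kernel_policy = _as_policy(kernel_policy)

    def fit(self, spec: ThresholdSpec | None = None, n_perm: int = 10_000,
            seed=None, min_extent: int = 20,
            observed_on: str = "ale") -> "ALESubtractionResults":
        spec = spec or ThresholdSpec()
        rng = seed if isinstance(seed, np.random.Generator) \
            else np.random.default_rng(seed)
        res_a = ALE(self.db_a, self.grid, self.kernel_policy).fit(spec, rng)
        res_b = ALE(self.db_b, self.grid, self.kernel_policy).fit(spec, rng)
        raw = ale_difference(self.db_a, self.db_b, self.grid,
                             self.kernel_policy, n_perm=n_perm, rng_seed=rng,
                             observed_on=observed_on)
        masked = apply_contrast_masking(raw, res_a.thresholded_mask,
                                        res_b.thresholded_mask,
                                        min_extent=min_extent)
        return ALESubtractionResults(self, res_a, res_b, raw, masked)


@dataclass
class ALESubtractionResults:
    model: ALESubtraction
    main_effect_a: ALEResults
    main_effect_b: ALEResults
    contrast_raw: ContrastResult
    contrast: ContrastResult

    def summary(self) -> str:
        return "\n\n".join([
            f"Group A: {len(self.model.db_a)} experiments, "
            f"{len(self.main_effect_a.clusters)} significant clusters",
            f"Group B: {len(self.model.db_b)} experiments, "
            f"{len(self.main_effect_b.clusters)} significant clusters",
            self.contrast.summary(),
        ])
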