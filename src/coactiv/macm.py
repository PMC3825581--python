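"""Meta-analytic connectivity modelling (MACM) pipelines.

MACM estimates task-based functional connectivity of a seed region as
above-chance co-activation: all experiments in a foci database that report
at least one activation inside the seed are selected, and the ALE
meta-analysis of their foci delineates where they converge.  Because the
selection conditions on seed activation, the strongest convergence is
expected in (or abutting) the seed itself; significant convergence
elsewhere indicates co-activation, i.e. connectivity.

This module orchestrates single-seed MACM runs, pairwise seed contrasts
(permutation subtraction with minuend masking), and the reciprocal
reseeding recipe: seed the regions a contrast discovered, and check —
inside the original seeds used as inclusive masks — that the connectivity
difference points back the right way.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ale import ALE, ALEResults, ThresholdSpec, _as_policy
from .contrast import ALESubtraction, ALESubtractionResults, ContrastResult, replace
from .foci import FociDatabase, select_by_seed
from .grids import BrainGrid, ClusterTable, StatVolume, sphere_mask

log = logging.getLogger(__name__)

#: Published working-memory meta-analysis peaks used as demo seed centres
#: (MNI mm).  The dorsal-right z-coordinate of 15 is reproduced verbatim
#: from the source meta-analysis even though it is inconsistent with a
#: posterior superior frontal location (plausibly a typo for z ~ 51); it is
#: flagged here rather than silently corrected.
SEED_PEAKS_MM = {
    "ventral_left": (-40.0, 12.0, 32.0),
    "ventral_right": (42.0, 6.0, 26.0),
    "dorsal_left": (-20.0, 10.0, 56.0),
    "dorsal_right": (24.0, 12.0, 15.0),
}


def fixture_seeds(grid: BrainGrid, radius_mm: float = 6.0) -> dict:
    """Spherical demo seeds at the published frontal peaks, plus the
    bilateral unions ('ventral', 'dorsal') the analyses operate on."""
    seeds = {name: sphere_mask(grid, c, radius_mm)
             for name, c in SEED_PEAKS_MM.items()}
    for side in ("ventral", "dorsal"):
        left = seeds[f"{side}_left"].binary
        right = seeds[f"{side}_right"].binary
        seeds[side] = StatVolume(grid, (left | right).astype(float), "MASK")
    return seeds


@dataclass
class MacmRun:
    """One seed's task-based connectivity analysis with full provenance."""

    seed: StatVolume
    selected_db: FociDatabase
    results: ALEResults | None
    provenance: dict = field(default_factory=dict)

    @property
    def z(self) -> StatVolume | None:
        return None if self.results is None else self.results.z

    @property
    def clusters(self) -> ClusterTable | None:
        return None if self.results is None else self.results.clusters

    @property
    def thresholded_mask(self) -> StatVolume | None:
        return None if self.results is None else self.results.thresholded_mask

    def summary(self) -> str:
        head = (f"MACM run: {len(self.selected_db)} experiments selected "
                f"by the seed ({int(self.seed.values.sum())} voxels)")
        if self.results is None:
            return head + "\n(no experiment activates the seed: empty run)"
        return head + "\n" + self.results.summary()


def run_macm(db: FociDatabase, seed_mask: StatVolume, grid: BrainGrid,
             spec: ThresholdSpec | None = None, kernel_policy=None,
             rng_seed=None) -> MacmRun:
    """Seed-based experiment selection followed by an ALE meta-analysis."""
    if not seed_mask.binary.any():
        raise ValueError("seed mask is empty")
    spec = spec or ThresholdSpec()
    selected = select_by_seed(db, seed_mask)
    prov = {
        "n_selected": len(selected), "spec": spec, "rng_seed": rng_seed,
        "kernel_policy": repr(_as_policy(kernel_policy)),
        "seed_voxels": int(seed_mask.values.sum()),
    }
    if len(selected) == 0:
        log.warning("run_macm: seed selects no experiments; returning empty run")
        return MacmRun(seed_mask, selected, None, prov)
    if len(selected) < 10:
        log.warning("run_macm: only %d experiments selected; the empirical "
                    "null is unstable", len(selected))
    results = ALE(selected, grid, kernel_policy).fit(spec, rng_seed)
    return MacmRun(seed_mask, selected, results, prov)


class MACM:
    """Model-style wrapper: MACM(db, seed, grid).fit() -> MacmRun."""

    def __init__(self, db: FociDatabase, seed_mask: StatVolume, grid: BrainGrid,
                 kernel_policy=None):
        self.db = db
        self.seed_mask = seed_mask
        self.grid = grid
        self.kernel_policy = kernel_policy

    def fit(self, spec: ThresholdSpec | None = None, seed=None) -> MacmRun:
        return run_macm(self.db, self.seed_mask, self.grid, spec,
                        self.kernel_policy, seed)


def run_macm_contrast(db: FociDatabase, seed_a: StatVolume, seed_b: StatVolume,
                      grid: BrainGrid, spec: ThresholdSpec | None = None,
                      n_perm: int = 10_000, rng_seed=None, kernel_policy=None,
                      min_extent: int = 20) -> ALESubtractionResults:
    """Contrast the task-based connectivity of two seeds.

    Selects each seed's co-activating experiments, runs the permutation
    subtraction test on the two selections, and applies minuend masking
    (each direction restricted to its own seed's FWE-corrected main effect)
    plus the minimum-extent rule.
    """
    spec = spec or ThresholdSpec()
    db_a = select_by_seed(db, seed_a)
    db_b = select_by_seed(db, seed_b)
    if len(db_a) == 0 or len(db_b) == 0:
        raise ValueError("a seed selects no experiments; cannot contrast")
    model = ALESubtraction(db_a, db_b, grid, kernel_policy)
    return model.fit(spec, n_perm=n_perm, seed=rng_seed, min_extent=min_extent)


class MACMContrast:
    """Model-style wrapper around :func:`run_macm_contrast`."""

    def __init__(self, db: FociDatabase, seed_a: StatVolume, seed_b: StatVolume,
                 grid: BrainGrid, kernel_policy=None):
        self.db = db
        self.seed_a = seed_a
        self.seed_b = seed_b
        self.grid = grid
        self.kernel_policy = kernel_policy

    def fit(self, spec: ThresholdSpec | None = None, n_perm: int = 10_000,
            seed=None, min_extent: int = 20) -> ALESubtractionResults:
        return run_macm_contrast(self.db, self.seed_a, self.seed_b, self.grid,
                                 spec, n_perm, seed, self.kernel_policy,
                                 min_extent)


@dataclass
class ReseedReport:
    """Reciprocal-reseeding outcome: masked contrasts plus an overlap table.

    ``table`` rows report, per original seed, how many voxels of each
    contrast direction fall inside it — i.e. which discovered region
    connects more strongly with that seed.
    """

    contrasts: list
    table: pd.DataFrame

    def summary(self) -> str:
        return ("Reciprocal reseeding (discovered regions -> original seeds)\n"
                + "=" * 60 + "\n" + self.table.to_string(index=False))


def reciprocal_reseed(db: FociDatabase, discovered_masks, original_seeds,
                      grid: BrainGrid, spec: ThresholdSpec | None = None,
                      n_perm: int = 1000, rng_seed=None, kernel_policy=None,
                      min_extent: int = 20,
                      seed_names=None) -> ReseedReport:
    """Seed the discovered regions against each other; mask by the originals.

    ``discovered_masks`` is an ordered pair (or longer list contrasted
    pairwise in order) of regions found by a previous contrast;
    ``original_seeds`` are the seeds that defined them.  Each reseeded
    contrast is restricted (inclusive masking) to the union of the original
    seeds, and the report tabulates the directional overlap with each one.
    """
    discovered_masks = list(discovered_masks)
    original_seeds = list(original_seeds)
    if len(discovered_masks) < 2:
        raise ValueError("need at least two discovered regions to contrast")
    union = np.zeros(grid.shape, dtype=bool)
    for s in original_seeds:
        union |= s.binary
    inclusive = StatVolume(grid, union.astype(float), "MASK")
    seed_names = list(seed_names) if seed_names is not None else \
        [f"seed_{i+1}" for i in range(len(original_seeds))]

    contrasts, rows = [], []
    for i in range(0, len(discovered_masks) - 1, 2):
        ra, rb = discovered_masks[i], discovered_masks[i + 1]
        res = run_macm_contrast(db, ra, rb, grid, spec, n_perm, rng_seed,
                                kernel_policy, min_extent)
        a_in = StatVolume(grid, (res.contrast.surviving_mask_AgtB.binary
                                 & inclusive.binary).astype(float), "MASK")
        b_in = StatVolume(grid, (res.contrast.surviving_mask_BgtA.binary
                                 & inclusive.binary).astype(float), "MASK")
        masked = replace(res.contrast, surviving_mask_AgtB=a_in,
                         surviving_mask_BgtA=b_in)
        contrasts.append(masked)
        for name, seed in zip(seed_names, original_seeds):
            rows.append({
                "pair": i // 2 + 1,
                "original_seed": name,
                "voxels_AgtB": int((a_in.binary & seed.binary).sum()),
                "voxels_BgtA": int((b_in.binary & seed.binary).sum()),
            })
    return ReseedReport(contrasts, pd.DataFrame(rows))
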