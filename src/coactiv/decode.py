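"""Minimum-statistic conjunctions and binomial functional decoding.

Conjunctions across modalities (task-based MACM vs resting state) and
across seed contrasts are intersections of already-thresholded binary
maps — the minimum statistic on cluster-FWE-corrected inputs.

Functional characterisation asks which taxonomy labels (behavioural
domains / paradigm classes) are over-represented among the experiments
activating one region (or region-plus-network) versus another.  From the
pool of experiments activating either side, the baserate is the a priori
probability of membership on side A; for each label the conditional
probability of side-A membership given the label is compared to that
baserate with a one-sided exact binomial test, Bonferroni-corrected over
all tested (label, direction) pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .contrast import ContrastResult
from .foci import FociDatabase
from .grids import StatVolume

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Conjunctions
# ---------------------------------------------------------------------------

def min_conjunction(maps) -> StatVolume:
    """Voxelwise logical AND of thresholded binary maps (minimum statistic)."""
    maps = list(maps)
    if not maps:
        raise ValueError("min_conjunction: empty map list")
    grid = maps[0].grid
    out = np.ones(grid.shape, dtype=bool)
    for m in maps:
        if m.kind != "MASK":
            raise ValueError("min_conjunction expects MASK volumes")
        if m.grid.shape != grid.shape or not np.allclose(m.grid.affine, grid.affine):
            raise ValueError("conjunction maps must share one grid")
        out &= m.binary
    return StatVolume(grid, out.astype(float), "MASK")


def conjunction_of_contrasts(macm_contrast: ContrastResult,
                             rsfc_contrast_masks: dict) -> dict:
    """Conjunction (across modalities) of the contrasts (between seeds).

    ``rsfc_contrast_masks`` maps direction names 'AgtB'/'BgtA' to the
    resting-state surviving masks; each direction is intersected with the
    corresponding MACM surviving mask.
    """
    macm = {"AgtB": macm_contrast.surviving_mask_AgtB,
            "BgtA": macm_contrast.surviving_mask_BgtA}
    out = {}
    for direction in ("AgtB", "BgtA"):
        if direction not in rsfc_contrast_masks:
            raise ValueError(f"missing resting-state mask for {direction!r}")
        out[direction] = min_conjunction([macm[direction],
                                          rsfc_contrast_masks[direction]])
    return out


# ---------------------------------------------------------------------------
# Pool construction
# ---------------------------------------------------------------------------

def _foci_in_mask(exp, mask: StatVolume) -> int:
    grid = mask.grid
    ijk = np.atleast_2d(grid.mm_to_voxel(exp.foci))
    ok = grid.in_bounds(ijk)
    if not ok.any():
        return 0
    sel = ijk[ok]
    return int(mask.binary[sel[:, 0], sel[:, 1], sel[:, 2]].sum())


@dataclass
class Pool:
    """Experiment pool with per-experiment A/B membership and focus counts."""

    db: FociDatabase
    memberships: dict      # id -> set of {"A", "B"}
    foci_counts: dict      # id -> (n_foci_in_A, n_foci_in_B)


def build_pool(db: FociDatabase, region_a: StatVolume, region_b: StatVolume,
               network_mode: bool = False, partners_a=(), partners_b=()) -> Pool:
    """Experiments activating region A or region B (or, in network mode,
    a region AND at least one of its partner regions).

    Membership on both sides is allowed; each experiment's focus counts
    inside A and B are recorded for the focus-level counting unit.
    """
    if not region_a.binary.any() or not region_b.binary.any():
        raise ValueError("regions must be non-empty")
    partners_a, partners_b = list(partners_a), list(partners_b)
    if network_mode and (not partners_a or not partners_b):
        raise ValueError("network mode requires partner regions for both sides")
    selected, memberships, counts = [], {}, {}
    for e in db:
        in_a = _foci_in_mask(e, region_a)
        in_b = _foci_in_mask(e, region_b)
        mem = set()
        if network_mode:
            if in_a and any(_foci_in_mask(e, p) for p in partners_a):
                mem.add("A")
            if in_b and any(_foci_in_mask(e, p) for p in partners_b):
                mem.add("B")
        else:
            if in_a:
                mem.add("A")
            if in_b:
                mem.add("B")
        if mem:
            selected.append(e)
            memberships[e.id] = mem
            counts[e.id] = (in_a, in_b)
    if not selected:
        raise ValueError("empty pool: no experiment activates either region")
    return Pool(FociDatabase(selected), memberships, counts)


# ---------------------------------------------------------------------------
# Binomial characterisation
# ---------------------------------------------------------------------------

@dataclass
class CharacterizationResult:
    """Enrichment of one label in one direction of the pool."""

    label: str
    direction: str        # "A" or "B"
    n_label: int          # label-carrying counting units in the pool
    k: int                # of those, on this direction's side
    cond_prob: float
    baserate: float
    p_raw: float
    p_bonferroni: float
    significant: bool


def binomial_p_one_sided(k: int, n: int, p0: float) -> float:
    """Exact one-sided over-representation p-value P(X >= k | n, p0)."""
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    return float(stats.binom.sf(k - 1, n, p0))


def characterize(pool: Pool, alpha: float = 0.05, min_n: int = 5,
                 unit: str = "experiment") -> pd.DataFrame:
    """Binomial baserate test of label enrichment per direction.

    With the default experiment counting unit, the baserate for side A is
    (#A memberships) / (#A + #B memberships) over the whole pool; for each
    label with at least ``min_n`` label-carrying memberships, k counts the
    label's A-side memberships and p_raw = P(Binom(n_label, baserate_A) >=
    k).  The symmetric test runs for side B; Bonferroni corrects over all
    tested (label, direction) pairs.  ``unit="focus"`` counts region-hitting
    foci instead of experiment memberships (the literal focus-level
    reading).

    Returns a DataFrame sorted by p_raw, one row per tested pair; the
    record objects are available via :func:`characterize_records`.
    """
    if unit not in ("experiment", "focus"):
        raise ValueError("unit must be 'experiment' or 'focus'")

    def units_of(e):
        if unit == "experiment":
            mem = pool.memberships[e.id]
            return (1 if "A" in mem else 0, 1 if "B" in mem else 0)
        return pool.foci_counts[e.id]

    tot_a = sum(units_of(e)[0] for e in pool.db)
    tot_b = sum(units_of(e)[1] for e in pool.db)
    baserate_a = tot_a / (tot_a + tot_b)
    if baserate_a in (0.0, 1.0):
        raise ValueError("degenerate baserate (all units on one side)")

    labels = sorted({lab for e in pool.db for lab in e.labels})
    rows = []
    for lab in labels:
        la = sum(units_of(e)[0] for e in pool.db if lab in e.labels)
        lb = sum(units_of(e)[1] for e in pool.db if lab in e.labels)
        n_lab = la + lb
        if n_lab < min_n:
            continue
        for direction, k, p0 in (("A", la, baserate_a), ("B", lb, 1 - baserate_a)):
            rows.append({
                "label": lab, "direction": direction, "n_label": n_lab,
                "k": k, "cond_prob": k / n_lab, "baserate": p0,
                "p_raw": binomial_p_one_sided(k, n_lab, p0),
            })
    if not rows:
        return pd.DataFrame(columns=["label", "direction", "n_label", "k",
                                     "cond_prob", "baserate", "p_raw",
                                     "p_bonferroni", "significant"])
    df = pd.DataFrame(rows)
    m = len(df)
    df["p_bonferroni"] = np.minimum(1.0, df["p_raw"] * m)
    df["significant"] = df["p_bonferroni"] < alpha
    return df.sort_values("p_raw", kind="stable").reset_index(drop=True)


def characterize_records(pool: Pool, alpha: float = 0.05, min_n: int = 5,
                         unit: str = "experiment") -> list:
    """Same test as :func:`characterize`, as CharacterizationResult objects."""
    df = characterize(pool, alpha, min_n, unit)
    return [CharacterizationResult(r.label, r.direction, int(r.n_label),
                                   int(r.k), float(r.cond_prob),
                                   float(r.baserate), float(r.p_raw),
                                   float(r.p_bonferroni), bool(r.significant))
            for r in df.itertuples(index=False)]
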