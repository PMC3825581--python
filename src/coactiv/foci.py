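"""Activation-focus databases: data model, Sleuth/TSV I/O, seed selection.

An :class:`Experiment` is one group-analysis contrast from the literature —
a subject count plus the activation peaks it reported in MNI millimetre
space, optionally tagged with taxonomy labels (behavioural domain /
paradigm class).  A :class:`FociDatabase` is the substrate of every
meta-analytic stage; the seed-constrained selection implemented here is the
"co-activation" filter of meta-analytic connectivity modelling.
"""

from __future__ import annotations

import io
import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grids import BrainGrid, StatVolume

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class Experiment:
    """One published group analysis: id, subject count, peak coordinates."""

    id: str
    n_subjects: int
    foci: np.ndarray  # (n_foci, 3) MNI mm
    labels: frozenset = frozenset()

    def __post_init__(self):
        foci = np.atleast_2d(np.asarray(self.foci, dtype=float))
        if foci.size == 0:
            raise ValueError(f"experiment {self.id!r} has no foci")
        if foci.shape[1] != 3:
            raise ValueError(f"experiment {self.id!r}: foci must be (n, 3)")
        if not np.all(np.isfinite(foci)):
            raise ValueError(f"experiment {self.id!r}: non-finite focus coordinate")
        if int(self.n_subjects) < 1:
            raise ValueError(f"experiment {self.id!r}: n_subjects must be >= 1")
        object.__setattr__(self, "n_subjects", int(self.n_subjects))
        object.__setattr__(self, "foci", foci)
        object.__setattr__(self, "labels", frozenset(self.labels))

    @property
    def n_foci(self) -> int:
        return self.foci.shape[0]


@dataclass
class FociDatabase:
    """An ordered collection of experiments in one stereotaxic space."""

    experiments: list
    space_tag: str = "MNI"

    def __post_init__(self):
        if self.space_tag != "MNI":
            raise ValueError(f"unsupported space {self.space_tag!r} (only MNI)")
        ids = [e.id for e in self.experiments]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate experiment ids: {dup[:5]}")

    def __len__(self):
        return len(self.experiments)

    def __iter__(self):
        return iter(self.experiments)

    def __getitem__(self, i):
        return self.experiments[i]

    @property
    def ids(self):
        return [e.id for e in self.experiments]

    @property
    def n_foci(self) -> int:
        return sum(e.n_foci for e in self.experiments)

    def subset(self, ids) -> "FociDatabase":
        ids = set(ids)
        return FociDatabase([e for e in self.experiments if e.id in ids])

    def with_labels(self, label_map: dict) -> "FociDatabase":
        """Attach labels from an id -> iterable-of-labels mapping."""
        exps = []
        for e in self.experiments:
            labels = frozenset(label_map.get(e.id, e.labels))
            exps.append(Experiment(e.id, e.n_subjects, e.foci, labels))
        return FociDatabase(exps)


# ---------------------------------------------------------------------------
# Sleuth-style text format
# ---------------------------------------------------------------------------

_REF_RE = re.compile(r"^//\s*Reference\s*=\s*(\S+)", re.IGNORECASE)
_SUBJ_RE = re.compile(r"^//\s*Subjects\s*=\s*(\S+)", re.IGNORECASE)


def parse_sleuth_text(text: str) -> FociDatabase:
    """Parse a Sleuth-dialect foci file.

    Expected layout::

        // Reference=MNI
        // <Author Year>: <contrast>
        // Subjects=<n>
        x y z
        ...
        <blank line between experiment blocks>

    Talairach (or any non-MNI) reference is rejected — no coordinate
    conversion is implemented.
    """
    lines = text.splitlines()
    space = None
    blocks: list[list[str]] = []
    current: list[str] = []
    for ln in lines:
        m = _REF_RE.match(ln.strip())
        if m and space is None:
            space = m.group(1)
            continue
        if ln.strip() == "":
            if current:
                blocks.append(current)
                current = []
        else:
            current.append(ln.rstrip())
    if current:
        blocks.append(current)
    if space is None:
        raise ValueError("missing '// Reference=' header")
    if space.upper() != "MNI":
        raise ValueError(f"unsupported space {space!r} (Talairach conversion "
                         "is not implemented)")

    experiments = []
    seen = {}
    for bi, block in enumerate(blocks, start=1):
        title_parts, n_subjects, coords = [], None, []
        for ln in block:
            s = ln.strip()
            m = _SUBJ_RE.match(s)
            if m:
                try:
                    n_subjects = int(m.group(1))
                except ValueError:
                    raise ValueError(f"block {bi}: non-integer Subjects value "
                                     f"{m.group(1)!r}") from None
                continue
            if s.startswith("//"):
                title_parts.append(s[2:].strip())
                continue
            parts = s.split()
            if len(parts) != 3:
                raise ValueError(f"block {bi}: expected 'x y z', got {s!r}")
            try:
                coords.append([float(p) for p in parts])
            except ValueError:
                raise ValueError(f"block {bi}: non-numeric coordinate in {s!r}") from None
        title = " ".join(title_parts) if title_parts else f"experiment_{bi}"
        if n_subjects is None:
            raise ValueError(f"block {bi} ({title!r}): missing '// Subjects=' line")
        if not coords:
            raise ValueError(f"block {bi} ({title!r}): no coordinates")
        eid = title
        if eid in seen:  # disambiguate repeated titles deterministically
            seen[eid] += 1
            eid = f"{eid} #{seen[title]}"
        else:
            seen[eid] = 1
        experiments.append(Experiment(eid, n_subjects, np.asarray(coords)))
    return FociDatabase(experiments)


def to_sleuth_text(db: FociDatabase) -> str:
    buf = io.StringIO()
    buf.write("// Reference=MNI\n\n")
    for e in db:
        buf.write(f"// {e.id}\n// Subjects={e.n_subjects}\n")
        for xyz in e.foci:
            buf.write(f"{xyz[0]:g}\t{xyz[1]:g}\t{xyz[2]:g}\n")
        buf.write("\n")
    return buf.getvalue()


def read_sleuth(path) -> FociDatabase:
    with open(path) as fh:
        return parse_sleuth_text(fh.read())


def write_sleuth(db: FociDatabase, path) -> None:
    with open(path, "w") as fh:
        fh.write(to_sleuth_text(db))


# ---------------------------------------------------------------------------
# Tabular (TSV) format: id, n_subjects, x, y, z, labels  (one row per focus)
# ---------------------------------------------------------------------------

def to_table(db: FociDatabase) -> pd.DataFrame:
    rows = []
    for e in db:
        labels = ";".join(sorted(e.labels))
        for xyz in e.foci:
            rows.append((e.id, e.n_subjects, xyz[0], xyz[1], xyz[2], labels))
    return pd.DataFrame(rows, columns=["id", "n_subjects", "x", "y", "z", "labels"])


def from_table(df: pd.DataFrame) -> FociDatabase:
    required = {"id", "n_subjects", "x", "y", "z"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"foci table missing columns: {sorted(missing)}")
    exps = []
    for eid, g in df.groupby("id", sort=False):
        n = int(g["n_subjects"].iloc[0])
        foci = g[["x", "y", "z"]].to_numpy(dtype=float)
        labels: frozenset = frozenset()
        if "labels" in g.columns:
            raw = g["labels"].iloc[0]
            if isinstance(raw, str) and raw.strip():
                labels = frozenset(t.strip() for t in raw.split(";") if t.strip())
        exps.append(Experiment(str(eid), n, foci, labels))
    return FociDatabase(exps)


def read_foci_table(path) -> FociDatabase:
    return from_table(pd.read_csv(path, sep="\t"))


def write_foci_table(db: FociDatabase, path) -> None:
    to_table(db).to_csv(path, sep="\t", index=False)


def read_label_table(path) -> dict:
    """Read a TSV of (experiment_id, label) rows into id -> set-of-labels."""
    df = pd.read_csv(path, sep="\t")
    if not {"experiment_id", "label"} <= set(df.columns):
        raise ValueError("label table needs columns experiment_id, label")
    out: dict = {}
    for eid, g in df.groupby("experiment_id", sort=False):
        out[str(eid)] = set(g["label"].astype(str))
    return out


# ---------------------------------------------------------------------------
# Selection and permutation plumbing
# ---------------------------------------------------------------------------

def select_by_seed(db: FociDatabase, seed: StatVolume) -> FociDatabase:
    """Experiments with at least one focus whose nearest voxel is in the seed.

    Order is preserved; an empty selection is allowed (logged as a warning).
    """
    if seed.kind != "MASK":
        raise ValueError("seed must be a MASK volume")
    grid = seed.grid
    seed_bin = seed.binary
    selected = []
    for e in db:
        ijk = grid.mm_to_voxel(e.foci)
        ijk = np.atleast_2d(ijk)
        ok = grid.in_bounds(ijk)
        hit = False
        if ok.any():
            sel = ijk[ok]
            hit = bool(seed_bin[sel[:, 0], sel[:, 1], sel[:, 2]].any())
        if hit:
            selected.append(e)
    if not selected:
        log.warning("select_by_seed: no experiment has a focus inside the seed")
    return FociDatabase(selected)


def pool_and_split(db_a: FociDatabase, db_b: FociDatabase, rng_seed) -> tuple:
    """Pool two experiment sets and randomly re-divide into the original sizes.

    Experiments present in both inputs contribute one token per membership
    (the pooled-relabelling scheme of the permutation subtraction test), so
    the multiset of experiments is conserved and group sizes are exactly
    |db_a| and |db_b|.
    """
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) \
        else np.random.default_rng(rng_seed)
    pooled = list(db_a.experiments) + list(db_b.experiments)
    n_a = len(db_a)
    perm = rng.permutation(len(pooled))
    x = [pooled[i] for i in perm[:n_a]]
    y = [pooled[i] for i in perm[n_a:]]
    return _from_tokens(x), _from_tokens(y)


def _from_tokens(exps) -> FociDatabase:
    """Build a database from possibly-duplicated experiment tokens."""
    seen: dict = {}
    out = []
    for e in exps:
        if e.id in seen:
            seen[e.id] += 1
            out.append(Experiment(f"{e.id} [token {seen[e.id]}]", e.n_subjects,
                                  e.foci, e.labels))
        else:
            seen[e.id] = 1
            out.append(e)
    return FociDatabase(out)
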