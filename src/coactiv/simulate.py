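"""Synthetic data with planted ground truth for every pipeline stage.

Two generators:

* :func:`simulate_foci_db` emulates a coordinate database with
  network-structured co-activation — experiments belonging to a network
  report foci near that network's member regions (with per-member
  co-report probabilities and millimetre jitter) on top of uniformly
  placed background foci, and carry taxonomy labels tied to their network
  with configurable fidelity.

* :func:`simulate_bold` emulates a multi-subject resting-state cohort with
  planted seed-target correlations: band-limited (0.01-0.08 Hz) latent
  signals per region, with targets mixed from source signals so the
  expected correlation equals the planted value, contaminated by a global
  fluctuation, motion-coupled confounds (with the motion parameters
  emitted as realignment-style T x 6 series), low-order drift and white
  noise, plus geometric grey/white/CSF tissue masks.

The defaults define the study conditions every recovery test runs under;
ground truth is returned alongside the data so tests never re-derive it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .foci import Experiment, FociDatabase
from .grids import BrainGrid, StatVolume, ellipsoid_grid, sphere_mask
from .rsfc import TimeSeriesDataset, bandpass

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Foci databases
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Region:
    name: str
    center_mm: tuple
    radius_mm: float = 6.0


@dataclass(frozen=True)
class Network:
    """A co-activation network: member regions with co-report probabilities.

    An experiment drawn from this network reports, for each member region
    independently with probability ``members[region]``, one focus at the
    region centre plus isotropic Gaussian jitter.  ``label`` is attached
    with probability ``label_fidelity`` (otherwise a random other label
    from the catalogue).
    """

    name: str
    members: tuple          # ((region_name, q), ...)
    prevalence: float
    label: str
    label_fidelity: float = 0.9

    def __init__(self, name, members, prevalence, label, label_fidelity=0.9):
        object.__setattr__(self, "name", name)
        object.__setattr__(self, "members",
                           tuple((str(r), float(q)) for r, q in dict(members).items()))
        object.__setattr__(self, "prevalence", float(prevalence))
        object.__setattr__(self, "label", str(label))
        object.__setattr__(self, "label_fidelity", float(label_fidelity))
        if not (0 < self.prevalence <= 1):
            raise ValueError("prevalence must be in (0, 1]")
        if not (0 < self.label_fidelity <= 1):
            raise ValueError("label_fidelity must be in (0, 1]")


@dataclass(frozen=True)
class NetworkSpec:
    """Generative description of a foci database on an analysis grid."""

    grid: BrainGrid
    regions: tuple
    networks: tuple
    background_rate: float = 2.0      # Poisson mean of uniform background foci
    focus_jitter_sd_mm: float = 5.0   # between-study spatial scatter
    n_experiments: int = 150
    subjects_range: tuple = (10, 30)
    label_catalogue: tuple = ("action", "cognition", "perception", "emotion")

    def __post_init__(self):
        object.__setattr__(self, "regions", tuple(self.regions))
        object.__setattr__(self, "networks", tuple(self.networks))
        object.__setattr__(self, "label_catalogue", tuple(self.label_catalogue))
        prev = sum(n.prevalence for n in self.networks)
        if prev > 1 + 1e-9:
            raise ValueError("network prevalences sum to > 1")
        if self.background_rate < 0 or self.focus_jitter_sd_mm < 0:
            raise ValueError("rates must be non-negative")
        names = [r.name for r in self.regions]
        if len(set(names)) != len(names):
            raise ValueError("duplicate region names")
        for n in self.networks:
            for rname, q in n.members:
                if rname not in names:
                    raise ValueError(f"network {n.name!r}: unknown region {rname!r}")
                if not (0 <= q <= 1):
                    raise ValueError("co-report probability must be in [0, 1]")
            if n.label not in self.label_catalogue:
                raise ValueError(f"label {n.label!r} not in catalogue")
        centers = {r.name: np.asarray(r.center_mm, float) for r in self.regions}
        for i, a in enumerate(self.regions):
            for b in self.regions[i + 1:]:
                d = float(np.linalg.norm(centers[a.name] - centers[b.name]))
                if d < 2 * max(a.radius_mm, b.radius_mm):
                    log.warning("regions %r and %r are closer (%.1f mm) than "
                                "twice the larger radius", a.name, b.name, d)

    def region_masks(self) -> dict:
        return {r.name: sphere_mask(self.grid, r.center_mm, r.radius_mm)
                for r in self.regions}


def paper_like_network_spec(grid: BrainGrid | None = None,
                            n_experiments: int = 150,
                            q_partner: float = 0.8,
                            q_cross: float = 0.05) -> NetworkSpec:
    """Two crossed seed-partner networks (the double-dissociation substrate).

    Network A experiments always hit seed region A, co-report the partner
    region P_A with probability ``q_partner`` and the other network's
    partner with the background-level probability ``q_cross`` (and
    symmetrically for B); the remaining prevalence is unstructured
    background.  Labels: A -> "action", B -> "cognition", fidelity 0.9.
    """
    grid = grid or ellipsoid_grid((20, 22, 20), 4.0)
    # 10-mm region spheres: commensurate with meta-analytic seed clusters
    # and with the 5-mm reporting jitter (~3/4 of member foci land inside)
    regions = (
        Region("seedA", (-20.0, 0.0, 0.0), 10.0),
        Region("seedB", (20.0, 0.0, 0.0), 10.0),
        Region("P_A", (0.0, 24.0, 8.0), 10.0),
        Region("P_B", (0.0, -24.0, 8.0), 10.0),
    )
    networks = (
        Network("netA", {"seedA": 1.0, "P_A": q_partner, "P_B": q_cross},
                prevalence=0.4, label="action", label_fidelity=0.9),
        Network("netB", {"seedB": 1.0, "P_B": q_partner, "P_A": q_cross},
                prevalence=0.4, label="cognition", label_fidelity=0.9),
    )
    return NetworkSpec(grid=grid, regions=regions, networks=networks,
                       background_rate=2.0, focus_jitter_sd_mm=5.0,
                       n_experiments=n_experiments, subjects_range=(10, 30))


def background_only_spec(grid: BrainGrid | None = None,
                         n_experiments: int = 150,
                         rate: float = 4.0) -> NetworkSpec:
    """Structureless database: only uniform background foci (null process)."""
    grid = grid or ellipsoid_grid((16, 16, 16), 4.0)
    return NetworkSpec(grid=grid, regions=(), networks=(),
                       background_rate=rate, n_experiments=n_experiments,
                       subjects_range=(10, 30))


def simulate_foci_db(spec: NetworkSpec, rng_seed=None,
                     max_retries: int = 50) -> tuple:
    """Draw a foci database from a network spec.

    Returns ``(db, ground_truth)`` where ground_truth records, per
    experiment, its network, attached label, and per-focus provenance
    (member region or 'background').  Experiments that come out with zero
    foci are redrawn (bounded retries).
    """
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) \
        else np.random.default_rng(rng_seed)
    grid = spec.grid
    mask_mm = grid.voxel_to_mm(grid.mask_indices.astype(float))
    centers = {r.name: np.asarray(r.center_mm, float) for r in spec.regions}
    prevs = np.array([n.prevalence for n in spec.networks])
    cum = np.cumsum(prevs)
    exps, truth = [], {}
    for i in range(spec.n_experiments):
        eid = f"exp{i+1:04d}"
        for attempt in range(max_retries):
            u = rng.random()
            net_i = int(np.searchsorted(cum, u, side="right"))
            network = spec.networks[net_i] if net_i < len(spec.networks) else None
            foci, prov = [], []
            if network is not None:
                for rname, q in network.members:
                    if rng.random() < q:
                        foci.append(centers[rname]
                                    + rng.normal(0.0, spec.focus_jitter_sd_mm, 3))
                        prov.append(rname)
            n_bg = rng.poisson(spec.background_rate)
            if n_bg:
                picks = rng.integers(0, mask_mm.shape[0], size=n_bg)
                foci.extend(mask_mm[picks])
                prov.extend(["background"] * n_bg)
            if foci:
                break
        else:
            raise RuntimeError(f"{eid}: no foci after {max_retries} redraws "
                               "(increase background_rate or co-report q)")
        n_subj = int(rng.integers(spec.subjects_range[0],
                                  spec.subjects_range[1] + 1))
        if network is not None:
            if rng.random() < network.label_fidelity:
                label = network.label
            else:
                others = [l for l in spec.label_catalogue if l != network.label]
                label = others[rng.integers(0, len(others))] if others \
                    else network.label
        else:
            label = spec.label_catalogue[rng.integers(0, len(spec.label_catalogue))]
        exps.append(Experiment(eid, n_subj, np.asarray(foci),
                               labels=frozenset([label])))
        truth[eid] = {
            "network": network.name if network is not None else None,
            "label": label,
            "foci_provenance": prov,
        }
    ground_truth = {
        "experiments": truth,
        "networks": {n.name: dict(n.members) for n in spec.networks},
        "labels": {n.name: n.label for n in spec.networks},
    }
    return FociDatabase(exps), ground_truth


# ---------------------------------------------------------------------------
# BOLD cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BoldSpec:
    """Generative description of a resting-state cohort at desk scale.

    Defaults mirror a typical single-site protocol: 300 frames at
    TR = 2.2 s with the first four discarded, on a 24 x 28 x 24 grid of
    4-mm voxels.  ``planted_r`` maps each target region to its source
    regions' correlations; sources get independent band-limited latents.
    Confound amplitudes are in units of the unit-variance regional signal.
    """

    n_subjects: int = 20
    shape: tuple = (24, 28, 24)
    voxel_size_mm: float = 4.0
    T: int = 300
    tr_s: float = 2.2
    n_discard: int = 4
    regions: tuple = (
        Region("seed", (-16.0, 10.0, 0.0), 8.0),
        Region("target", (14.0, -18.0, 4.0), 8.0),
    )
    planted_r: tuple = (("target", (("seed", 0.5),)),)
    motion_coupling: float = 0.8
    global_amp: float = 1.0
    drift_amp: float = 1.0
    noise_sd: float = 0.3
    n_physio: int = 2
    physio_amp: float = 0.5
    physio_fwhm_mm: float = 24.0
    parcel_size_mm: float = 24.0
    parcel_coherence: float = 0.85
    band: tuple = (0.01, 0.08)

    def __post_init__(self):
        object.__setattr__(self, "regions", tuple(self.regions))
        pr = tuple((str(t), tuple((str(s), float(r)) for s, r in dict(srcs).items()))
                   for t, srcs in dict(self.planted_r).items())
        object.__setattr__(self, "planted_r", pr)
        if self.T <= 50:
            raise ValueError("T must exceed 50")
        names = {r.name for r in self.regions}
        for t, srcs in self.planted_r:
            if t not in names:
                raise ValueError(f"unknown target region {t!r}")
            tot = sum(r ** 2 for _, r in srcs)
            if tot >= 1:
                raise ValueError(f"target {t!r}: sum of squared planted r >= 1")
            for s, r in srcs:
                if s not in names:
                    raise ValueError(f"unknown source region {s!r}")
                if not (-1 < r < 1):
                    raise ValueError("planted r must be in (-1, 1)")

    @property
    def grid(self) -> BrainGrid:
        return ellipsoid_grid(self.shape, self.voxel_size_mm)

    def region_masks(self) -> dict:
        g = self.grid
        return {r.name: sphere_mask(g, r.center_mm, r.radius_mm)
                for r in self.regions}


def crossed_bold_spec(r_strong: float = 0.5, r_weak: float = 0.05,
                      n_subjects: int = 20) -> BoldSpec:
    """Two seeds with crossed planted connectivity to two parietal-analogue
    targets (the resting-state double-dissociation substrate)."""
    regions = (
        Region("seedA", (-16.0, 12.0, 0.0), 8.0),
        Region("seedB", (16.0, 12.0, 0.0), 8.0),
        Region("P_A", (-14.0, -20.0, 4.0), 8.0),
        Region("P_B", (14.0, -20.0, 4.0), 8.0),
    )
    planted = (
        ("P_A", (("seedA", r_strong), ("seedB", r_weak))),
        ("P_B", (("seedA", r_weak), ("seedB", r_strong))),
    )
    return replace(BoldSpec(), regions=regions, planted_r=planted,
                   n_subjects=n_subjects)


def tissue_masks_for(grid: BrainGrid) -> dict:
    """Concentric geometric tissue labels: grey core, white shell, CSF rim."""
    idx = np.indices(grid.shape).astype(float)
    c = (np.asarray(grid.shape, float) - 1.0) / 2.0
    semi = 0.9 * (np.asarray(grid.shape, float) - 1.0) / 2.0
    r2 = sum(((idx[a] - c[a]) / semi[a]) ** 2 for a in range(3))
    r = np.sqrt(r2)
    grey = (r <= 0.70) & grid.mask
    white = (r > 0.70) & (r <= 0.85) & grid.mask
    csf = (r > 0.85) & grid.mask
    return {name: StatVolume(grid, m.astype(float), "MASK")
            for name, m in (("grey", grey), ("white", white), ("csf", csf))}


def band_limited_noise(T: int, tr_s: float, band, rng,
                       size: int = 1) -> np.ndarray:
    """Unit-variance Gaussian signals confined to the analysis passband.

    Shaped (T, size); generated directly in-band so the analysis band-pass
    is (approximately) information-preserving on them.
    """
    x = rng.standard_normal((T, size))
    y = bandpass(x, tr_s, band[0], band[1])
    sd = y.std(axis=0, keepdims=True)
    sd[sd == 0] = 1.0
    return y / sd


def _simulate_motion(T: int, rng) -> np.ndarray:
    """Slow random-walk rigid-body parameters (mm translations, rad rotations)."""
    steps = rng.standard_normal((T, 6)) * np.array([0.02] * 3 + [4e-4] * 3)
    return np.cumsum(steps, axis=0)


def simulate_subject(spec: BoldSpec, subject_index: int, rng_seed=None) -> tuple:
    """Generate one subject; returns (TimeSeriesDataset, latents dict)."""
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) \
        else np.random.default_rng(rng_seed)
    grid = spec.grid
    T = spec.T
    masks = spec.region_masks()
    targets = dict(spec.planted_r)
    source_names = [r.name for r in spec.regions if r.name not in targets]

    latents = {}
    for name in source_names:
        latents[name] = band_limited_noise(T, spec.tr_s, spec.band, rng)[:, 0]
    for tname, srcs in spec.planted_r:
        mix = np.zeros(T)
        tot = 0.0
        for sname, r in srcs:
            mix += r * latents[sname]
            tot += r ** 2
        resid = band_limited_noise(T, spec.tr_s, spec.band, rng)[:, 0]
        latents[tname] = mix + np.sqrt(1.0 - tot) * resid

    n_vox = grid.n_in_mask
    tissues = tissue_masks_for(grid)
    t_cols = {name: m.binary[grid.mask] for name, m in tissues.items()}

    def tissue_factor(grey_f, white_f, csf_f):
        f = np.full(n_vox, grey_f)
        f[t_cols["white"]] = white_f
        f[t_cols["csf"]] = csf_f
        return f

    # background neural fluctuation: grey matter is organised into coherent
    # parcels (resting networks everywhere, not just the planted ones), so
    # the grey-mean regressor is dominated by the many background parcels
    # rather than by the planted pair; white matter / CSF carry only weak
    # signal.  Planted regions are overwritten by their region latent.
    idxs = grid.mask_indices
    block = max(1, int(round(spec.parcel_size_mm / float(grid.voxel_sizes.mean()))))
    _, parcel_of = np.unique(idxs // block, axis=0, return_inverse=True)
    parcel_lat = band_limited_noise(T, spec.tr_s, spec.band, rng,
                                    size=int(parcel_of.max()) + 1)
    indep = band_limited_noise(T, spec.tr_s, spec.band, rng, size=n_vox)
    c = spec.parcel_coherence
    signal = c * parcel_lat[:, parcel_of] + np.sqrt(1.0 - c ** 2) * indep
    signal *= tissue_factor(1.0, 0.3, 0.3)[None, :]
    for name, m in masks.items():
        cols = m.binary[grid.mask]
        signal[:, cols] = latents[name][:, None]

    g = band_limited_noise(T, spec.tr_s, spec.band, rng)[:, 0]
    motion = _simulate_motion(T, rng)
    mz = (motion - motion.mean(0)) / np.where(motion.std(0) == 0, 1, motion.std(0))
    w = rng.standard_normal(6) / np.sqrt(6)
    m_conf = mz @ w
    m_conf = m_conf / (m_conf.std() or 1.0)
    lin = np.linspace(-1.0, 1.0, T)
    quad = lin ** 2 - (lin ** 2).mean()
    # scanner drift is always present; only its sign/size vary by subject
    c1 = rng.uniform(0.5, 1.5) * rng.choice([-1.0, 1.0])
    c2 = rng.uniform(0.5, 1.5) * rng.choice([-1.0, 1.0])
    drift = c1 * lin + c2 * quad

    # spatially heterogeneous (signed) coupling patterns, as for real
    # motion/drift artefacts; heterogeneity keeps the three rank-1 confound
    # terms linearly independent of the uniform global mode.  Per-tissue
    # multipliers give the compartments genuinely distinct confound
    # signatures (CSF pulsates most; motion artefacts strongest at the rim),
    # so the three tissue-mean regressors span well-separated directions.
    m_coef = (1.0 + rng.standard_normal(n_vox)) * tissue_factor(1.0, 1.2, 1.5)
    d_coef = (1.0 + rng.standard_normal(n_vox)) * tissue_factor(1.0, 1.3, 0.8)
    g_coef = tissue_factor(1.0, 0.6, 1.5)
    data = (signal
            + spec.global_amp * np.outer(g, g_coef)
            + spec.motion_coupling * np.outer(m_conf, m_coef)
            + spec.drift_amp * np.outer(drift, d_coef)
            + spec.noise_sd * rng.standard_normal((T, n_vox)))
    # spatially broad physiological fluctuations (respiratory/cardiac-like
    # aliased modes): coherent over much of the brain, so whole-brain PCA
    # components have realistic broad targets to capture
    from .grids import smooth_array
    sig_vox = (spec.physio_fwhm_mm / 2.3548) / grid.voxel_sizes
    p_fac = tissue_factor(1.0, 0.6, 1.5)
    for _ in range(spec.n_physio):
        w = rng.standard_normal(grid.shape)
        w = smooth_array(w, sig_vox)[grid.mask]
        w = (w - w.mean()) / (w.std() or 1.0)
        pt = band_limited_noise(T, spec.tr_s, spec.band, rng)[:, 0]
        data += spec.physio_amp * np.outer(pt, w * p_fac)

    bold = np.zeros(grid.shape + (T,))
    bold[grid.mask] = data.T
    ds = TimeSeriesDataset(subject_id=f"sub{subject_index+1:02d}", bold=bold,
                           tr_s=spec.tr_s, motion=motion,
                           tissue_masks=tissues, grid=grid,
                           n_discard=spec.n_discard)
    return ds, latents


def simulate_bold(spec: BoldSpec, rng_seed=None) -> tuple:
    """Generate the whole cohort; returns (datasets, ground_truth).

    ground_truth holds the planted correlations, the region masks, and the
    per-subject latent signals.  For memory-lean processing generate
    subjects one at a time with :func:`simulate_subject` and the per-subject
    seeds in ``subject_seeds``.
    """
    ss = np.random.SeedSequence(rng_seed if not isinstance(rng_seed, np.random.Generator)
                                else rng_seed.integers(2 ** 31))
    child_seeds = ss.spawn(spec.n_subjects)
    datasets, all_latents = [], {}
    for i, cs in enumerate(child_seeds):
        ds, lat = simulate_subject(spec, i, np.random.default_rng(cs))
        datasets.append(ds)
        all_latents[ds.subject_id] = lat
    ground_truth = {
        "planted_r": {t: dict(s) for t, s in spec.planted_r},
        "region_masks": spec.region_masks(),
        "latents": all_latents,
        "subject_seeds": [cs.entropy for cs in child_seeds],
    }
    return datasets, ground_truth
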