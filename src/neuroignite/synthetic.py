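"""Synthetic cohort generator: parcellated BOLD-like signals, tumor masks
and cognitive scores with known ground truth.

The generative model is event propagation, not an oscillator model: each
region emits seed events as a Bernoulli process; every seed event recruits
each other region at the same timepoint with probability
``coupling_within`` (same network) or ``coupling_between`` (different
network), scaled by the *target* region's propagation multiplier. Spike
trains are smoothed with a Gaussian kernel and Gaussian noise is added.
Because the propagation probability is the very quantity the ignition
metric measures, group manipulations (a global multiplier for diffuse,
glioma-like subjects; a focal multiplier on tumor-involved regions for
meningioma-like subjects) are directly recoverable downstream.

Randomness is organised as one global seed expanded into per-subject
substreams, so adding a subject never perturbs the draws of the others.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .containers import ParcellatedBold, ValidationError
from .tumor import TumorOverlap

logger = logging.getLogger(__name__)

GROUPS = ("control", "meningioma", "glioma")

#: share of subjects scanned at TR 2100 ms, per group (the remainder at
#: 2400 ms), mirroring the mixed-TR acquisition of the emulated cohort
TR2100_SHARE = {"control": 0.4, "meningioma": 5 / 14, "glioma": 0.2}

#: glioma-like subjects carry, on top of the diffuse global attenuation, a
#: small number of severely infiltrated networks whose propagation is almost
#: abolished; which networks are hit varies across subjects, mirroring the
#: patient-to-patient variability of tumor location
GLIOMA_N_FOCUS_NETWORKS = 2
GLIOMA_FOCUS_FACTOR = 0.15


def default_network_assignment(n_regions: int, n_networks: int = 7) -> np.ndarray:
    """Contiguous-block region -> network assignment (0-based labels)."""
    if n_networks < 1 or n_regions < n_networks:
        raise ValidationError("need n_regions >= n_networks >= 1")
    return np.repeat(
        np.arange(n_networks), -(-n_regions // n_networks)
    )[:n_regions]


def _check(cond: bool, name: str, msg: str) -> None:
    if not cond:
        raise ValidationError(f"invalid CohortSpec field {name!r}: {msg}")


@dataclass
class CohortSpec:
    """Study conditions of a synthetic cohort.

    Defaults emulate the target acquisition: 10 controls, 14 meningioma-like
    and 10 glioma-like subjects; 268 regions over 7 networks; mixed TRs of
    2100/2400 ms; 180 timepoints (~6-7 min of scan). ``event_rate`` governs
    *seed* (cascade-initiating) events; at the default 268-region scale it
    yields roughly one global cascade every couple of TRs, each recruiting
    about half of the seeding region's network and ~18% of the rest of the
    brain — sparse, large co-activation cascades on top of the background
    threshold crossings that band-passed noise produces in every region.
    """

    n_control: int = 10
    n_meningioma: int = 14
    n_glioma: int = 10
    n_regions: int = 268
    n_networks: int = 7
    network_assignment: np.ndarray | None = None
    tr_ms: dict | None = None  # subject -> 2100 or 2400; None = default mix
    n_timepoints: int = 180
    event_rate: float = 0.2  # expected seed (cascade) events per region per 100 TRs
    coupling_within: float = 0.5
    coupling_between: float = 0.18
    glioma_global_attenuation: float = 0.6
    meningioma_focal_attenuation: float = 0.5
    noise_sd: float = 0.08
    hrf_width: float = 2.0  # Gaussian smoothing SD, in timepoints
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_control", "n_meningioma", "n_glioma", "n_regions",
                     "n_networks", "n_timepoints"):
            _check(int(getattr(self, name)) > 0, name, "must be positive")
        _check(0 < self.event_rate, "event_rate", "must be positive")
        for name in ("coupling_within", "coupling_between"):
            _check(0 <= getattr(self, name) <= 1, name, "must lie in [0, 1]")
        for name in ("glioma_global_attenuation", "meningioma_focal_attenuation"):
            _check(0 < getattr(self, name) <= 1, name, "must lie in (0, 1]")
        _check(self.noise_sd >= 0, "noise_sd", "must be >= 0")
        _check(self.hrf_width > 0, "hrf_width", "must be positive")
        if self.network_assignment is None:
            self.network_assignment = default_network_assignment(
                self.n_regions, self.n_networks
            )
        self.network_assignment = np.asarray(self.network_assignment)
        _check(
            self.network_assignment.shape == (self.n_regions,),
            "network_assignment",
            "must assign every region exactly once",
        )
        _check(
            set(np.unique(self.network_assignment)) <= set(range(self.n_networks)),
            "network_assignment",
            f"labels must lie in 0..{self.n_networks - 1}",
        )

    # -- subject bookkeeping ------------------------------------------------

    @property
    def subjects(self) -> list:
        return (
            [f"ctl-{i + 1:02d}" for i in range(self.n_control)]
            + [f"men-{i + 1:02d}" for i in range(self.n_meningioma)]
            + [f"gli-{i + 1:02d}" for i in range(self.n_glioma)]
        )

    @property
    def groups(self) -> dict:
        out = {}
        for sub in self.subjects:
            out[sub] = {"ctl": "control", "men": "meningioma", "gli": "glioma"}[
                sub[:3]
            ]
        return out

    def subject_tr(self, subject: str) -> int:
        if self.tr_ms is not None:
            tr = self.tr_ms[subject]
            _check(tr in (2100, 2400), "tr_ms", f"{subject}: TR must be 2100 or 2400")
            return int(tr)
        group = self.groups[subject]
        index = int(subject.split("-")[1]) - 1
        n_group = {"control": self.n_control, "meningioma": self.n_meningioma,
                   "glioma": self.n_glioma}[group]
        n_2100 = int(round(TR2100_SHARE[group] * n_group))
        return 2100 if index < n_2100 else 2400

    def _rng(self, stream: int, subject_index: int) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed, spawn_key=(stream, subject_index))
        )


@dataclass
class GroundTruth:
    """Recoverable ground truth of a generated cohort."""

    groups: dict
    tr_ms: dict
    multipliers: dict  # subject -> per-region propagation multiplier
    tumor_fractions: dict  # subject -> per-region involvement fraction
    network_assignment: np.ndarray = None
    latency_coupling_slope: dict = field(
        default_factory=lambda: {"control": -30.0, "meningioma": 0.0, "glioma": 0.0}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        for sub, group in self.groups.items():
            if group == "control":
                assert (self.multipliers[sub] == 1).all(), "control multipliers"
                assert (self.tumor_fractions[sub] == 0).all(), "control fractions"


# -- tumor geometry ---------------------------------------------------------


def _tumor_fractions(spec: CohortSpec) -> dict:
    """Per-subject involvement fractions (shared by signals and masks)."""
    fractions = {}
    for idx, sub in enumerate(spec.subjects):
        group = spec.groups[sub]
        frac = np.zeros(spec.n_regions)
        rng = spec._rng(1, idx)
        if group == "meningioma":
            # contiguous focal block spanning all three nonzero bins
            block = max(6, spec.n_regions // 25)
            start = int(rng.integers(0, spec.n_regions - block + 1))
            k_high = max(1, block // 5)
            k_mid = max(1, block // 4)
            pos = start
            frac[pos : pos + k_high] = rng.uniform(0.70, 1.0, k_high)
            pos += k_high
            frac[pos : pos + k_mid] = rng.uniform(0.35, 0.60, k_mid)
            pos += k_mid
            frac[pos : start + block] = rng.uniform(0.02, 0.30, start + block - pos)
        elif group == "glioma":
            # diffuse scatter, mostly low-grade involvement
            involved = rng.random(spec.n_regions) < 0.3
            frac[involved] = rng.beta(1.2, 5.0, involved.sum())
        fractions[sub] = frac
    return fractions


def _multipliers(spec: CohortSpec, fractions: dict) -> dict:
    """Per-region propagation multipliers encoding each group's pathology.

    Glioma-like subjects carry the diffuse global attenuation everywhere
    plus a few severely infiltrated networks (chosen at random per subject)
    whose propagation is almost abolished; meningioma-like subjects are
    attenuated only in tumor-involved regions.
    """
    mult = {}
    for idx, sub in enumerate(spec.subjects):
        group = spec.groups[sub]
        m = np.ones(spec.n_regions)
        if group == "glioma":
            rng = spec._rng(4, idx)
            h_net = np.ones(spec.n_networks)
            n_hit = min(GLIOMA_N_FOCUS_NETWORKS, spec.n_networks)
            h_net[rng.choice(spec.n_networks, size=n_hit, replace=False)] = (
                GLIOMA_FOCUS_FACTOR
            )
            m = np.clip(
                spec.glioma_global_attenuation * h_net[spec.network_assignment],
                1e-6,
                1.0,
            )
        elif group == "meningioma":
            m[fractions[sub] > 0] = spec.meningioma_focal_attenuation
        mult[sub] = m
    return mult


def _ground_truth(spec: CohortSpec) -> GroundTruth:
    fractions = _tumor_fractions(spec)
    return GroundTruth(
        groups=spec.groups,
        tr_ms={s: spec.subject_tr(s) for s in spec.subjects},
        multipliers=_multipliers(spec, fractions),
        tumor_fractions=fractions,
        network_assignment=spec.network_assignment,
        seed=spec.seed,
    )


# -- signals ----------------------------------------------------------------


def _simulate_subject(
    spec: CohortSpec, rng: np.random.Generator, mult: np.ndarray
) -> np.ndarray:
    N, T = spec.n_regions, spec.n_timepoints
    net = spec.network_assignment
    p_seed = spec.event_rate / 100.0
    seeds = rng.random((N, T)) < p_seed

    onehot = np.zeros((spec.n_networks, N))
    onehot[net, np.arange(N)] = 1.0
    seeds_net = onehot @ seeds  # (n_networks, T) seed counts per network
    total = seeds.sum(axis=0)  # (T,)

    n_within = seeds_net[net] - seeds  # seeds in own network, excluding self
    n_between = total[None, :] - seeds_net[net]
    p_w = np.clip(spec.coupling_within * mult, 0, 1)[:, None]
    p_b = np.clip(spec.coupling_between * mult, 0, 1)[:, None]
    received = rng.binomial(n_within.astype(int), p_w) + rng.binomial(
        n_between.astype(int), p_b
    )
    spikes = seeds.astype(float) + received
    smooth = gaussian_filter1d(spikes, sigma=spec.hrf_width, axis=1, mode="reflect")
    if spec.noise_sd > 0:
        # attenuated regions are also noisier: pathology that weakens a
        # region's participation in propagation degrades its signal-to-noise
        # ratio in proportion
        noise_scale = (spec.noise_sd / np.clip(mult, 1e-3, None))[:, None]
        smooth = smooth + rng.normal(0.0, 1.0, (N, T)) * noise_scale
    return smooth


def generate_bold(spec: CohortSpec) -> tuple[dict, GroundTruth]:
    """Generate the cohort's region x time signals plus ground truth.

    Deterministic given ``(spec, spec.seed)``; each subject draws from its
    own substream.
    """
    truth = _ground_truth(spec)
    cohort = {}
    for idx, sub in enumerate(spec.subjects):
        rng = spec._rng(0, idx)
        signal = _simulate_subject(spec, rng, truth.multipliers[sub])
        cohort[sub] = ParcellatedBold(
            signal=signal,
            tr_ms=truth.tr_ms[sub],
            region_ids=[f"r{i:03d}" for i in range(spec.n_regions)],
            subject_id=sub,
        )
    return cohort, truth


# -- voxel masks ------------------------------------------------------------


def toy_atlas(n_regions: int, shape: tuple = (20, 20, 20)) -> np.ndarray:
    """Integer-labelled toy lattice: boxes on a 3-D grid of blocks.

    Axes are split into near-equal slabs whose product covers ``n_regions``;
    surplus blocks are merged into the last label so every region is
    non-empty.
    """
    kx = max(1, int(np.ceil(n_regions ** (1 / 3))))
    ky = max(1, int(np.ceil(np.sqrt(n_regions / kx))))
    kz = max(1, int(np.ceil(n_regions / (kx * ky))))
    ix = np.minimum(np.arange(shape[0]) * kx // shape[0], kx - 1)
    iy = np.minimum(np.arange(shape[1]) * ky // shape[1], ky - 1)
    iz = np.minimum(np.arange(shape[2]) * kz // shape[2], kz - 1)
    block = (
        ix[:, None, None] * (ky * kz) + iy[None, :, None] * kz + iz[None, None, :]
    )
    atlas = np.minimum(block + 1, n_regions)  # labels 1..n_regions
    return atlas.astype(np.int32)


def fractions_to_mask(
    fractions: np.ndarray, atlas: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Probabilistic voxel mask realizing the given region fractions.

    Per region, ``round(f * n_vox)`` voxels get probabilities >= 0.1; a few
    extra voxels of involved regions get sub-threshold probabilities so the
    0.1 cutoff is exercised.
    """
    mask = np.zeros(atlas.shape, dtype=float)
    flat_mask = mask.ravel()
    flat_atlas = atlas.ravel()
    for r, f in enumerate(fractions, start=1):
        voxels = np.flatnonzero(flat_atlas == r)
        k = int(round(f * voxels.size))
        if k > 0:
            chosen = rng.choice(voxels, size=k, replace=False)
            flat_mask[chosen] = rng.uniform(0.1, 0.95, k)
            rest = np.setdiff1d(voxels, chosen)
            n_sub = min(2, rest.size)
            if n_sub:
                flat_mask[rest[:n_sub]] = rng.uniform(0.01, 0.0999, n_sub)
    return flat_mask.reshape(atlas.shape)


def generate_tumor_masks(
    spec: CohortSpec, with_voxels: bool = False, lattice_shape: tuple = (20, 20, 20)
) -> dict | tuple:
    """Per-subject tumor overlaps; optionally voxel masks on a toy lattice.

    Controls are all-zero; meningioma-like subjects carry a contiguous
    focal block spanning all nonzero bins; glioma-like subjects a diffuse
    scatter. With ``with_voxels`` the voxel-grid masks reproduce the same
    fractions (to within one voxel of rounding) through
    :func:`neuroignite.tumor.mask_to_region_fraction`.
    """
    fractions = _tumor_fractions(spec)
    overlaps = {
        sub: TumorOverlap(
            region_ids=[f"r{i:03d}" for i in range(spec.n_regions)],
            fractions=fractions[sub],
            subject_id=sub,
        )
        for sub in spec.subjects
    }
    if not with_voxels:
        return overlaps
    atlas = toy_atlas(spec.n_regions, lattice_shape)
    masks = {}
    for idx, sub in enumerate(spec.subjects):
        rng = spec._rng(3, idx)
        masks[sub] = fractions_to_mask(fractions[sub], atlas, rng)
    return overlaps, masks, atlas


# -- cognition --------------------------------------------------------------


def generate_cognition(
    truth: GroundTruth,
    ignition: dict,
    intercept: float = 400.0,
    slopes: dict | None = None,
    noise_sd: float = 15.0,
    standardize: bool = True,
    equalize_means: bool = True,
    rng: np.random.Generator | None = None,
) -> dict:
    """Latency scores coupled to ignition in controls only.

    latency = intercept + slope_group * x + noise, where x is the subject's
    ignition (cohort-standardized by default, so slopes are in ms per
    cohort-SD of ignition). With ``equalize_means`` the predictor is
    centered within group, making group mean latencies equal by
    construction — tumor groups show no gross deficit, only decoupling.
    """
    slopes = dict(truth.latency_coupling_slope if slopes is None else slopes)
    missing = [s for s in truth.groups if s not in ignition]
    if missing:
        raise ValueError(f"missing ignition values for subjects: {missing}")
    if rng is None:
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=truth.seed, spawn_key=(2,))
        )
    subs = list(truth.groups)
    x = np.array([float(ignition[s]) for s in subs])
    if standardize:
        sd = x.std()
        if sd == 0:
            raise ValueError("ignition values have zero variance; cannot standardize")
        x = (x - x.mean()) / sd
    latency = {}
    for group in set(truth.groups.values()):
        members = [i for i, s in enumerate(subs) if truth.groups[s] == group]
        xg = x[members]
        center = xg.mean() if equalize_means else 0.0
        for i in members:
            eps = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
            latency[subs[i]] = float(
                intercept + slopes[group] * (x[i] - center) + eps
            )
    return latency
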