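"""Synthetic normative-connectome scenes with known ground truth.

The generator emulates the statistical structure the mapping pipeline
assumes, not real BOLD physiology: per subject, a latent AR(1) signal
``u(t)`` with unit marginal variance drives every voxel of an acupoint's
seed region and planted network,

    x_v(t) = lambda * u(t) + eps_v(t),        eps_v iid N(0, noise_sd^2),

so any two driven voxels correlate at ``lambda^2 / (lambda^2 + noise_sd^2)``
in expectation, while off-network voxels are pure noise.  Different
acupoints get independent latents, so their planted systems are
uncorrelated.  Every generator is deterministic given its seed, with
independent sub-streams per subject / unit / map via seed-sequence
spawning.

Default study conditions: 40 subjects, 120 timepoints, driven-pair
correlation 0.4 (lambda = sqrt(2/3), noise_sd = 1), two acupoint-like
labels with 14 and 4 units of reported coordinates, a 20x24x20 voxel
grid at 3 mm with an ellipsoidal brain mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import CANONICAL_NAMES, CanonicalAtlas
from .grid_io import FocusRecord, ReferenceGrid, VolumeSeries, voxel_to_mm
from .molecular import NT_MAP_NAMES, NeurotransmitterMap, ParcelVector, Parcellation

__all__ = [
    "AcupointSpec",
    "SyntheticScene",
    "gen_scene",
    "gen_connectome",
    "gen_foci",
    "gen_atlas_and_parcellation",
    "gen_nt_catalogue",
]

MIN_SHAPE = (12, 12, 12)

#: defaults giving a driven-pair correlation of 0.4
DEFAULT_LAMBDA = float(np.sqrt(2.0 / 3.0))
DEFAULT_NOISE_SD = 1.0
DEFAULT_PHI = 0.3
DEFAULT_N_SUBJECTS = 40
DEFAULT_T = 120


@dataclass(frozen=True)
class AcupointSpec:
    """Where one acupoint's seed region and planted network live (voxel units)."""

    name: str
    seed_center: tuple[int, int, int]
    seed_radius_vox: float = 1.5
    network_center: tuple[int, int, int] | None = None
    network_radius_vox: float = 4.0


@dataclass
class SyntheticScene:
    """Ground truth for one simulated experiment."""

    grid: ReferenceGrid
    true_network_masks: dict[str, np.ndarray]
    seed_region_masks: dict[str, np.ndarray]
    latent_loading: float = DEFAULT_LAMBDA
    noise_sd: float = DEFAULT_NOISE_SD
    ar1_coefficient: float = DEFAULT_PHI
    n_subjects: int = DEFAULT_N_SUBJECTS
    n_timepoints: int = DEFAULT_T
    rng_seed: int = 0

    def __post_init__(self):
        if not (0 <= self.ar1_coefficient < 1):
            raise ValueError("ar1_coefficient must be in [0, 1)")
        for name, seed_mask in self.seed_region_masks.items():
            if (seed_mask & ~self.grid.brain_mask).any():
                raise ValueError(f"seed region of {name} leaves the brain mask")

    @property
    def expected_driven_correlation(self) -> float:
        lam2 = self.latent_loading**2
        return lam2 / (lam2 + self.noise_sd**2)

    def driven_mask(self, acupoint: str) -> np.ndarray:
        return self.true_network_masks[acupoint] | self.seed_region_masks[acupoint]


def _ball(shape, center, radius) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    d2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    return d2 <= radius**2 + 1e-9


def _default_specs(shape) -> list[AcupointSpec]:
    nx, ny, nz = shape
    return [
        AcupointSpec(
            "ST36",
            seed_center=(nx // 4, ny // 3, nz // 2),
            network_center=(nx // 4, ny // 3, nz // 2),
        ),
        AcupointSpec(
            "GB34",
            seed_center=(3 * nx // 4, 2 * ny // 3, nz // 2),
            network_center=(3 * nx // 4, 2 * ny // 3, nz // 2),
        ),
    ]


def gen_scene(
    shape: tuple[int, int, int] = (20, 24, 20),
    acupoint_specs: list[AcupointSpec] | None = None,
    rng_seed: int = 0,
    voxel_size_mm: float = 3.0,
    require_disjoint: bool = True,
    **scene_kwargs,
) -> SyntheticScene:
    """Build a deterministic scene: ellipsoidal brain mask + planted regions."""
    if any(s < m for s, m in zip(shape, MIN_SHAPE)):
        raise ValueError(f"shape {shape} below minimum {MIN_SHAPE}")
    affine = np.diag([voxel_size_mm] * 3 + [1.0])
    affine[:3, 3] = -np.array(shape) * voxel_size_mm / 2.0  # roughly centered
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    center = [(s - 1) / 2.0 for s in shape]
    semi = [s / 2.0 - 0.5 for s in shape]
    ellip = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semi)) <= 1.0
    grid = ReferenceGrid(shape, affine, ellip)

    specs = acupoint_specs if acupoint_specs is not None else _default_specs(shape)
    seed_masks: dict[str, np.ndarray] = {}
    net_masks: dict[str, np.ndarray] = {}
    for spec in specs:
        seed = _ball(shape, spec.seed_center, spec.seed_radius_vox) & grid.brain_mask
        net_center = spec.network_center or spec.seed_center
        net = _ball(shape, net_center, spec.network_radius_vox) & grid.brain_mask
        if not seed.any():
            raise ValueError(f"seed region of {spec.name} is empty")
        seed_masks[spec.name] = seed
        net_masks[spec.name] = net | seed
    if require_disjoint:
        names = list(net_masks)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                if (net_masks[a] & net_masks[b]).any():
                    raise ValueError(
                        f"planted systems of {a} and {b} overlap (disjointness requested)"
                    )
    return SyntheticScene(
        grid=grid,
        true_network_masks=net_masks,
        seed_region_masks=seed_masks,
        rng_seed=rng_seed,
        **scene_kwargs,
    )


def _ar1(T: int, phi: float, rng: np.random.Generator) -> np.ndarray:
    """AR(1) series with unit marginal variance."""
    e = rng.standard_normal(T)
    u = np.empty(T)
    u[0] = e[0]
    innov_sd = np.sqrt(1.0 - phi**2)
    for t in range(1, T):
        u[t] = phi * u[t - 1] + innov_sd * e[t]
    return u


def gen_connectome(scene: SyntheticScene) -> list[VolumeSeries]:
    """Simulate the scene's resting-state volumes for every subject."""
    ss = np.random.SeedSequence(scene.rng_seed, spawn_key=(1,))
    subject_seeds = ss.spawn(scene.n_subjects)
    T = scene.n_timepoints
    shape = scene.grid.shape
    acupoints = sorted(scene.true_network_masks)
    out: list[VolumeSeries] = []
    for i, sseed in enumerate(subject_seeds):
        rng = np.random.default_rng(sseed)
        data = rng.normal(0.0, scene.noise_sd, size=shape + (T,)).astype(np.float32)
        for name in acupoints:
            u = _ar1(T, scene.ar1_coefficient, rng)
            driven = scene.driven_mask(name)
            data[driven] += (scene.latent_loading * u).astype(np.float32)
        out.append(VolumeSeries(scene.grid, data, subject_id=f"sub-{i:03d}"))
    return out


def gen_foci(
    scene: SyntheticScene,
    n_units: dict[str, int] | None = None,
    jitter_sd_mm: float = 1.0,
    rng_seed: int = 0,
    foci_per_unit: tuple[int, int] = (1, 5),
) -> list[FocusRecord]:
    """Emulate literature-reported coordinates around the seed regions.

    Per unit (study), 1-5 coordinates are drawn from seed-region voxel
    centers with Gaussian mm jitter.  Default unit counts follow the
    14-study / 4-study two-acupoint scenario.
    """
    if n_units is None:
        n_units = {name: n for name, n in zip(sorted(scene.seed_region_masks),
                                              (4, 14))}
        # sorted order is GB34, ST36 for the default scene -> 4 and 14 units
    rng = np.random.default_rng(np.random.SeedSequence(rng_seed, spawn_key=(2,)))
    records: list[FocusRecord] = []
    lo, hi = foci_per_unit
    for acupoint in sorted(n_units):
        seed_vox = np.argwhere(scene.seed_region_masks[acupoint])
        for unit in range(n_units[acupoint]):
            study_id = f"{acupoint}_study{unit + 1:02d}"
            n_foci = int(rng.integers(lo, hi + 1))
            n_subjects = int(rng.integers(10, 41))
            picks = seed_vox[rng.integers(0, len(seed_vox), size=n_foci)]
            for j, vox in enumerate(picks):
                mm = voxel_to_mm(scene.grid, vox)
                mm = mm + rng.normal(0.0, jitter_sd_mm, size=3)
                records.append(
                    FocusRecord(
                        study_id=study_id,
                        contrast_id=f"c{j + 1}",
                        acupoint=acupoint,
                        x=float(mm[0]), y=float(mm[1]), z=float(mm[2]),
                        space="MNI",
                        n_subjects=n_subjects,
                    )
                )
    return records


def gen_atlas_and_parcellation(
    scene: SyntheticScene,
    n_canonical: int = 8,
    n_parcels: int = 119,
    rng_seed: int = 0,
    designated_labels: dict[str, str] | None = None,
    designated_fraction: float = 0.8,
) -> tuple[CanonicalAtlas, Parcellation]:
    """Space-filling Voronoi labelings of the brain mask.

    ``designated_labels`` maps an acupoint to a canonical-network name; that
    fraction of its planted network's voxels is then reassigned to the named
    label, so overlap profiles have a known dominant system.
    """
    rng = np.random.default_rng(np.random.SeedSequence(rng_seed, spawn_key=(3,)))
    mask_vox = np.argwhere(scene.grid.brain_mask)

    def voronoi(n_labels: int) -> np.ndarray:
        centers = mask_vox[rng.choice(len(mask_vox), size=n_labels, replace=False)]
        d2 = ((mask_vox[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        lab = np.zeros(scene.grid.shape, dtype=np.int32)
        lab[tuple(mask_vox.T)] = d2.argmin(axis=1) + 1
        return lab

    atlas_labels = voronoi(n_canonical)
    names = {i + 1: CANONICAL_NAMES[i % len(CANONICAL_NAMES)]
             for i in range(n_canonical)}
    if designated_labels:
        name_to_int = {v: k for k, v in names.items()}
        for acupoint, label_name in designated_labels.items():
            target = name_to_int[label_name]
            net_vox = np.argwhere(scene.true_network_masks[acupoint])
            n_assign = int(np.ceil(designated_fraction * len(net_vox)))
            chosen = net_vox[rng.choice(len(net_vox), size=n_assign, replace=False)]
            atlas_labels[tuple(chosen.T)] = target
        # reassignment may empty a small label; regrow empties from leftovers
        for lab in names:
            if not (atlas_labels == lab).any():
                free = mask_vox[rng.integers(0, len(mask_vox))]
                atlas_labels[tuple(free)] = lab
    atlas = CanonicalAtlas(scene.grid, atlas_labels, names)

    parc_labels = voronoi(n_parcels)
    parc = Parcellation(scene.grid, parc_labels)
    return atlas, parc


def gen_nt_catalogue(
    parc: Parcellation,
    target_pattern: ParcelVector,
    rho_targets: dict[str, float] | None = None,
    rng_seed: int = 0,
    gm_loading: float = 0.0,
) -> tuple[list[NeurotransmitterMap], ParcelVector]:
    """Receptor/transporter catalogue with controlled Spearman association.

    Each map is drawn by Gaussian-copula mixing with the target pattern's
    normal scores: ``y = rho_g * g(target) + sqrt(1 - rho_g^2) * z`` with
    ``rho_g = 2 sin(pi * rho_s / 6)`` so the realized Spearman correlation
    approximates the requested ``rho_s``.  Maps absent from ``rho_targets``
    get rho 0.  The gray-matter covariate is generated with its own
    (default zero) loading on the target.
    """
    rho_targets = rho_targets or {}
    R = target_pattern.n_regions
    if R != parc.n_regions:
        raise ValueError("target pattern length does not match parcellation")
    ranks = stats.rankdata(target_pattern.values, method="average")
    g = stats.norm.ppf((ranks - 0.5) / R)

    ss = np.random.SeedSequence(rng_seed, spawn_key=(4,))
    seeds = ss.spawn(len(NT_MAP_NAMES) + 1)
    catalogue: list[NeurotransmitterMap] = []
    for name, child in zip(NT_MAP_NAMES, seeds[:-1]):
        rho_s = float(rho_targets.get(name, 0.0))
        rho_g = 2.0 * np.sin(np.pi * rho_s / 6.0)
        rng = np.random.default_rng(child)
        z = rng.standard_normal(R)
        y = rho_g * g + np.sqrt(max(0.0, 1.0 - rho_g**2)) * z
        catalogue.append(NeurotransmitterMap(name, ParcelVector(y)))
    rng = np.random.default_rng(seeds[-1])
    z = rng.standard_normal(R)
    gm = gm_loading * g + np.sqrt(max(0.0, 1.0 - gm_loading**2)) * z
    # gray-matter probabilities live in [0,1]; squash the Gaussian scores
    gm = stats.norm.cdf(gm)
    return catalogue, ParcelVector(gm)


def catalogue_to_frame(catalogue: list[NeurotransmitterMap]) -> pd.DataFrame:
    """Region x map matrix for CSV export."""
    return pd.DataFrame({m.name: m.parcel_values.values for m in catalogue})
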