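"""Core network-mapping statistics: seed-to-whole-brain connectivity,
group inference, FDR thresholding, and probability-map construction.

The pipeline per aggregation unit (study or contrast):

1. mean time series over the unit's seed voxels;
2. per-subject voxel-wise Pearson correlation with that series, Fisher
   z-transformed (``z = atanh(r)``, r clipped to ``±(1 - 1e-7)``);
3. voxel-wise one-sample t-test across subjects;
4. Benjamini–Hochberg FDR at q (default 0.01) within the brain mask,
   keeping positive-connectivity voxels only, binarized;
5. binary maps overlaid into a probability map and thresholded (default
   60%, inclusive) to give the consensus network.

This module is deterministic; all randomness lives in
:mod:`fcnm.synthetic_data`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .grid_io import FocusRecord, ReferenceGrid, ScalarMap, VolumeSeries
from .seeds import SeedMask, SeedSpec, seeds_per_unit

__all__ = [
    "PipelineConfig",
    "SubjectFCMap",
    "GroupResult",
    "BinaryNetworkMap",
    "ProbabilityMap",
    "AcupointNetwork",
    "DegenerateSeedError",
    "seed_mean_timeseries",
    "subject_fc_map",
    "group_onesample",
    "fdr_select",
    "binarize_positive",
    "probability_map",
    "threshold_probability",
    "run_fcnm",
]

log = logging.getLogger(__name__)

R_CLIP = 1.0 - 1e-7  # keeps Fisher z finite


class DegenerateSeedError(ValueError):
    """The seed's mean time series is constant, so correlation is undefined."""


@dataclass
class PipelineConfig:
    """All tunable parameters of the pipeline, with the standard defaults."""

    radius_mm: float = 4.0
    fdr_q: float = 0.01
    probability_threshold: float = 0.60
    positive_only: bool = True
    two_sided: bool = True
    unit: str = "study"
    n_permutations: int = 10_000
    nt_fdr_alpha: float = 0.05
    tal_method: str = "lancaster"
    always_include_containing_voxel: bool = True
    rng_seed: int = 0

    def __post_init__(self):
        if not (0 < self.fdr_q < 1):
            raise ValueError("fdr_q must be in (0, 1)")
        if not (0 < self.probability_threshold <= 1):
            raise ValueError("probability_threshold must be in (0, 1]")

    @property
    def seed_spec(self) -> SeedSpec:
        return SeedSpec(self.radius_mm, self.always_include_containing_voxel)


@dataclass
class SubjectFCMap:
    """Per-subject Fisher-z seed-to-whole-brain connectivity map."""

    grid: ReferenceGrid
    data: np.ndarray            # 3D z values, zero outside brain mask
    subject_id: str
    seed_id: str
    zero_variance: np.ndarray | None = None  # flagged voxels (z forced to 0)

    def __post_init__(self):
        if self.data.shape != self.grid.shape:
            raise ValueError("FC map shape mismatch")
        if not np.isfinite(self.data).all():
            raise ValueError("non-finite z values")


@dataclass
class GroupResult:
    """Voxel-wise one-sample t-test over subject FC maps."""

    t_map: ScalarMap
    p_map: ScalarMap
    df: int
    n_subjects: int
    degenerate: np.ndarray | None = None  # sd == 0 with mean != 0


@dataclass
class BinaryNetworkMap:
    """Thresholded, binarized group connectivity for one unit."""

    grid: ReferenceGrid
    mask: np.ndarray
    seed_id: str = ""

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.grid.shape:
            raise ValueError("binary map shape mismatch")
        if (self.mask & ~self.grid.brain_mask).any():
            raise ValueError("binary network extends outside brain mask")

    @property
    def voxels(self) -> frozenset:
        return frozenset(map(tuple, np.argwhere(self.mask)))

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


@dataclass
class ProbabilityMap:
    """Across-unit voxel agreement: fraction of binary maps containing a voxel."""

    grid: ReferenceGrid
    data: np.ndarray
    n_maps: int

    def __post_init__(self):
        counts = self.data * self.n_maps
        if not np.allclose(counts, np.round(counts), atol=1e-6):
            raise ValueError("probability values must be integer multiples of 1/n_maps")

    def as_scalar_map(self) -> ScalarMap:
        return ScalarMap(self.grid, self.data, kind="probability")


@dataclass
class AcupointNetwork:
    """Consensus network: probability map thresholded at >= threshold."""

    grid: ReferenceGrid
    mask: np.ndarray
    threshold: float
    n_maps: int
    acupoint: str = ""

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def voxels(self) -> frozenset:
        return frozenset(map(tuple, np.argwhere(self.mask)))

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


def seed_mean_timeseries(series: VolumeSeries, seed: SeedMask) -> np.ndarray:
    """Unweighted mean over seed voxels at each timepoint (length T)."""
    series.grid.require_match(seed.grid)
    vol = seed.as_volume()
    return series.data[vol].mean(axis=0)


def subject_fc_map(
    series: VolumeSeries,
    seed: SeedMask,
    grid: ReferenceGrid | None = None,
) -> SubjectFCMap:
    """Voxel-wise Pearson correlation with the seed mean series, Fisher z.

    Voxels with zero temporal variance get z = 0 and are flagged; the seed
    series itself being constant raises :class:`DegenerateSeedError`.
    """
    grid = grid or series.grid
    grid.require_match(series.grid)
    s = seed_mean_timeseries(series, seed).astype(np.float64)
    s = s - s.mean()
    s_norm = np.linalg.norm(s)
    if s_norm < 1e-12:
        raise DegenerateSeedError(
            f"seed {seed.source_contrast!r} has a constant mean time series"
        )
    mask = grid.brain_mask
    x = series.data[mask].astype(np.float64)
    x = x - x.mean(axis=1, keepdims=True)
    x_norm = np.linalg.norm(x, axis=1)
    zero_var = x_norm < 1e-12
    denom = np.where(zero_var, 1.0, x_norm * s_norm)
    r = (x @ s) / denom
    r[zero_var] = 0.0
    z = np.arctanh(np.clip(r, -R_CLIP, R_CLIP))
    out = np.zeros(grid.shape, dtype=np.float64)
    out[mask] = z
    flagged = np.zeros(grid.shape, dtype=bool)
    flagged[mask] = zero_var
    return SubjectFCMap(grid, out, series.subject_id, seed.source_contrast, flagged)


def group_onesample(maps: list[SubjectFCMap], two_sided: bool = True) -> GroupResult:
    """Voxel-wise one-sample t-test of the subject Fisher-z maps against zero.

    Degenerate voxels (zero across-subject sd) get p = 0 if the mean is
    nonzero (flagged) and t = 0, p = 1 if the mean is zero too.
    """
    if len(maps) < 3:
        raise ValueError(f"need at least 3 subject maps, got {len(maps)}")
    grid = maps[0].grid
    seed_id = maps[0].seed_id
    for m in maps[1:]:
        grid.require_match(m.grid)
        if m.seed_id != seed_id:
            raise ValueError("subject maps come from different seeds")
    stack = np.stack([m.data[grid.brain_mask] for m in maps])  # (n, V)
    n = stack.shape[0]
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1)
    zero_sd = sd < 1e-15
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    df = n - 1
    t[zero_sd & (np.abs(mean) < 1e-15)] = 0.0
    t[zero_sd & (np.abs(mean) >= 1e-15)] = np.sign(mean[zero_sd & (np.abs(mean) >= 1e-15)]) * np.inf
    if two_sided:
        p = 2.0 * stats.t.sf(np.abs(t), df)
    else:
        p = stats.t.sf(t, df)
    p[zero_sd & (np.abs(mean) < 1e-15)] = 1.0
    p[zero_sd & (np.abs(mean) >= 1e-15)] = 0.0

    t_vol = np.zeros(grid.shape)
    p_vol = np.ones(grid.shape)
    t_vol[grid.brain_mask] = np.where(np.isinf(t), np.sign(t) * 1e30, t)
    p_vol[grid.brain_mask] = p
    degen = np.zeros(grid.shape, dtype=bool)
    degen[grid.brain_mask] = zero_sd & (np.abs(mean) >= 1e-15)
    if degen.any():
        log.warning("%d degenerate voxels (zero sd, nonzero mean)", degen.sum())
    return GroupResult(
        t_map=ScalarMap(grid, t_vol, kind="t"),
        p_map=ScalarMap(grid, p_vol, kind="p"),
        df=df,
        n_subjects=n,
        degenerate=degen,
    )


def fdr_select(p_values, q: float) -> np.ndarray:
    """Benjamini–Hochberg step-up selection at level q.

    Rejects the k smallest p-values where ``k = max{i : p_(i) <= i*q/m}``;
    ties at the threshold value are all rejected.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return reject


def binarize_positive(
    group: GroupResult, q: float, positive_only: bool = True
) -> BinaryNetworkMap:
    """FDR-threshold a group result and binarize, keeping positive t only.

    The FDR family m contains brain-mask voxels only; an empty result is
    allowed (logged) — the unit still counts toward the probability map's N.
    """
    grid = group.t_map.grid
    mask = grid.brain_mask
    p = group.p_map.data[mask]
    t = group.t_map.data[mask]
    reject = fdr_select(p, q)
    if positive_only:
        reject &= t > 0
    out = np.zeros(grid.shape, dtype=bool)
    out[mask] = reject
    if not out.any():
        log.info("binarized map is empty at q=%g", q)
    return BinaryNetworkMap(grid, out)


def probability_map(binary_maps: list[BinaryNetworkMap]) -> ProbabilityMap:
    """Voxel-wise fraction of units whose binary network contains the voxel."""
    if len(binary_maps) < 2:
        raise ValueError("need at least 2 binary maps")
    grid = binary_maps[0].grid
    for m in binary_maps[1:]:
        grid.require_match(m.grid)
    counts = np.zeros(grid.shape, dtype=np.int64)
    for m in binary_maps:
        counts += m.mask
    n = len(binary_maps)
    return ProbabilityMap(grid, counts / n, n_maps=n)


def threshold_probability(
    pmap: ProbabilityMap, threshold: float, acupoint: str = ""
) -> AcupointNetwork:
    """Keep voxels whose agreement fraction is >= threshold (inclusive)."""
    if not (0 < threshold <= 1):
        raise ValueError("threshold must be in (0, 1]")
    mask = pmap.data >= threshold - 1e-12  # inclusive under float representation
    return AcupointNetwork(
        pmap.grid, mask, threshold=threshold, n_maps=pmap.n_maps, acupoint=acupoint
    )


@dataclass
class FcnmRun:
    """All per-acupoint artifacts of one pipeline execution."""

    acupoint: str
    seeds: dict[str, SeedMask]
    group_results: dict[str, GroupResult]
    binary_maps: dict[str, BinaryNetworkMap]
    prob_map: ProbabilityMap
    network: AcupointNetwork
    provenance: dict


def run_fcnm(
    foci: list[FocusRecord],
    connectome: list[VolumeSeries],
    config: PipelineConfig,
    grid: ReferenceGrid,
    keep_group_results: bool = False,
) -> dict[str, FcnmRun]:
    """Full pipeline: foci -> seeds -> FC -> group t -> FDR -> probability -> network.

    Returns one :class:`FcnmRun` per acupoint label present in the foci.
    Units whose binarized map is empty are logged and still counted in N.
    """
    if not foci:
        raise ValueError("no foci")
    if len(connectome) < 3:
        raise ValueError("need at least 3 subjects")
    mni = [f.to_mni(config.tal_method) for f in foci]
    results: dict[str, FcnmRun] = {}
    for acupoint in sorted({f.acupoint for f in mni}):
        records = [f for f in mni if f.acupoint == acupoint]
        seed_masks = seeds_per_unit(records, config.unit, config.seed_spec, grid)
        binaries: dict[str, BinaryNetworkMap] = {}
        groups: dict[str, GroupResult] = {}
        for unit_id in sorted(seed_masks):
            seed = seed_masks[unit_id]
            fc_maps = [subject_fc_map(s, seed, grid) for s in connectome]
            group = group_onesample(fc_maps, two_sided=config.two_sided)
            binary = binarize_positive(group, config.fdr_q, config.positive_only)
            binary.seed_id = unit_id
            binaries[unit_id] = binary
            if keep_group_results:
                groups[unit_id] = group
            if binary.n_voxels == 0:
                log.warning("unit %s: empty binarized network (still counted)", unit_id)
        pmap = probability_map(list(binaries.values()))
        network = threshold_probability(
            pmap, config.probability_threshold, acupoint=acupoint
        )
        provenance = {
            "acupoint": acupoint,
            "n_units": len(seed_masks),
            "unit": config.unit,
            "radius_mm": config.radius_mm,
            "fdr_q": config.fdr_q,
            "probability_threshold": config.probability_threshold,
            "n_subjects": len(connectome),
            "seed_sizes": {k: len(v) for k, v in seed_masks.items()},
            "binary_sizes": {k: v.n_voxels for k, v in binaries.items()},
            "network_voxels": network.n_voxels,
        }
        results[acupoint] = FcnmRun(
            acupoint=acupoint,
            seeds=seed_masks,
            group_results=groups,
            binary_maps=binaries,
            prob_map=pmap,
            network=network,
            provenance=provenance,
        )
    return results
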