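"""Parcel-wise spatial association with neurotransmitter density maps.

Mirrors the JuSpace-style analysis: reduce the consensus network (or
per-subject FC maps) to parcel means on a ~119-region parcellation,
compute the partial Spearman correlation with each receptor/transporter
density map controlling for gray-matter probability, obtain exact
permutation p-values by shuffling parcel values, and apply BH-FDR across
the catalogue at alpha = 0.05.

Partial Spearman here means: rank-transform x, y and the covariate over
the jointly valid parcels (average ranks on ties), residualize the x and y
ranks on the covariate ranks (with intercept), and Pearson-correlate the
residuals.  ``rho_z = atanh(rho)`` with clipping at ``±(1 - 1e-7)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .fcnm_core import fdr_select
from .grid_io import ReferenceGrid, ScalarMap

__all__ = [
    "NT_MAP_NAMES",
    "Parcellation",
    "ParcelVector",
    "NeurotransmitterMap",
    "MolecularAssociation",
    "UndefinedCorrelationError",
    "parcel_means",
    "partial_spearman",
    "permutation_pvalue",
    "molecular_screen",
]

R_CLIP = 1.0 - 1e-7

#: the 16-map receptor/transporter catalogue
NT_MAP_NAMES = (
    "5HT1a", "5HT1b", "5HT2a", "SERT",
    "D1", "D2", "DAT", "FDOPA",
    "GABAa", "KappaOp", "MU", "NAT",
    "CB1", "NMDA", "VAChT", "mGluR5",
)


class UndefinedCorrelationError(ValueError):
    """An input is constant after ranking, so the correlation is undefined."""


@dataclass
class Parcellation:
    """Integer-label brain parcellation with contiguous region ids 1..R."""

    grid: ReferenceGrid
    labels: np.ndarray
    region_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.shape != self.grid.shape:
            raise ValueError("parcellation shape mismatch")
        present = np.unique(self.labels)
        present = present[present > 0]
        if present.size == 0:
            raise ValueError("parcellation has no regions")
        self.n_regions = int(present.max())
        if not self.region_names:
            self.region_names = [f"region_{i:03d}" for i in range(1, self.n_regions + 1)]
        if len(self.region_names) != self.n_regions:
            raise ValueError("region_names length does not match region count")


@dataclass
class ParcelVector:
    """One value per parcellation region; missing regions flagged."""

    values: np.ndarray
    missing: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("ParcelVector must be 1D")
        if self.missing is None:
            self.missing = ~np.isfinite(self.values)
        self.missing = np.asarray(self.missing, dtype=bool)
        if self.missing.shape != self.values.shape:
            raise ValueError("missing flags shape mismatch")

    @property
    def n_regions(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class NeurotransmitterMap:
    """Named receptor/transporter density pattern summarized per parcel."""

    name: str
    parcel_values: ParcelVector

    def __post_init__(self):
        if self.name not in NT_MAP_NAMES:
            raise ValueError(
                f"{self.name!r} is not in the {len(NT_MAP_NAMES)}-map catalogue"
            )


@dataclass
class MolecularAssociation:
    """Adjusted Spearman statistic for one neurotransmitter map."""

    name: str
    rho: float
    rho_z: float
    p_perm: float
    p_fdr: float = float("nan")
    significant: bool = False


def parcel_means(map3d: ScalarMap, parc: Parcellation) -> ParcelVector:
    """Mean of the map over each region's voxels; empty regions flagged missing."""
    map3d.grid.require_match(parc.grid)
    labels = parc.labels.ravel()
    data = np.asarray(map3d.data, dtype=float).ravel()
    sums = np.bincount(labels, weights=data, minlength=parc.n_regions + 1)
    counts = np.bincount(labels, minlength=parc.n_regions + 1)
    with np.errstate(invalid="ignore"):
        means = sums[1:] / counts[1:]
    missing = counts[1:] == 0
    means[missing] = np.nan
    return ParcelVector(means, missing)


def _joint_valid(*vectors: ParcelVector) -> np.ndarray:
    valid = ~vectors[0].missing
    for v in vectors[1:]:
        if v.n_regions != vectors[0].n_regions:
            raise ValueError("parcel vectors have different lengths")
        valid &= ~v.missing
    return valid


def _rank(a: np.ndarray) -> np.ndarray:
    return stats.rankdata(a, method="average")


def _residualize(ranks: np.ndarray, covar_ranks: np.ndarray) -> np.ndarray:
    """Residuals of ranks after OLS on [1, covar_ranks]."""
    design = np.column_stack([np.ones_like(covar_ranks), covar_ranks])
    beta, *_ = np.linalg.lstsq(design, ranks, rcond=None)
    return ranks - design @ beta


def partial_spearman(
    x: ParcelVector, y: ParcelVector, covar: ParcelVector | None = None
) -> tuple[float, float]:
    """Spearman correlation of x and y controlling for a covariate.

    Returns ``(rho, rho_z)``.  A constant covariate reduces exactly to the
    plain Spearman correlation.  Needs >= 5 jointly non-missing regions.
    """
    if covar is None:
        covar = ParcelVector(np.zeros(x.n_regions))
    valid = _joint_valid(x, y, covar)
    if valid.sum() < 5:
        raise UndefinedCorrelationError(
            f"only {int(valid.sum())} jointly valid regions (need >= 5)"
        )
    xr, yr, cr = (_rank(v.values[valid]) for v in (x, y, covar))
    if np.ptp(xr) == 0 or np.ptp(yr) == 0:
        raise UndefinedCorrelationError("constant input after ranking")
    xres = _residualize(xr, cr)
    yres = _residualize(yr, cr)
    denom = np.linalg.norm(xres) * np.linalg.norm(yres)
    if denom < 1e-12:
        raise UndefinedCorrelationError("inputs fully explained by the covariate")
    rho = float(xres @ yres / denom)
    rho_z = float(np.arctanh(np.clip(rho, -R_CLIP, R_CLIP)))
    return rho, rho_z


def _null_rhos(
    x: ParcelVector,
    y: ParcelVector,
    covar: ParcelVector | None,
    n_perm: int,
    rng: np.random.Generator,
) -> tuple[float, np.ndarray]:
    """Observed rho and a vector of n_perm null rhos (y parcel values permuted)."""
    if covar is None:
        covar = ParcelVector(np.zeros(x.n_regions))
    valid = _joint_valid(x, y, covar)
    if valid.sum() < 5:
        raise UndefinedCorrelationError("too few jointly valid regions")
    xr, yr, cr = (_rank(v.values[valid]) for v in (x, y, covar))
    if np.ptp(xr) == 0 or np.ptp(yr) == 0:
        raise UndefinedCorrelationError("constant input after ranking")
    n = xr.size
    # residual-maker via orthonormal basis of [1, covar_ranks]
    design = np.column_stack([np.ones(n), cr])
    q, _ = np.linalg.qr(design)

    def resid(rows: np.ndarray) -> np.ndarray:
        return rows - (rows @ q) @ q.T

    xres = resid(xr[None, :])[0]
    xres /= np.linalg.norm(xres)
    # permuting y's raw values then ranking == permuting y's ranks
    ynull = resid(rng.permuted(np.tile(yr, (n_perm, 1)), axis=1))
    ynorm = np.linalg.norm(ynull, axis=1)
    ynorm[ynorm < 1e-12] = np.inf
    rhos_null = (ynull @ xres) / ynorm
    yres = resid(yr[None, :])[0]
    rho_obs = float(xres @ yres / np.linalg.norm(yres))
    return rho_obs, rhos_null


def permutation_pvalue(
    x: ParcelVector,
    y: ParcelVector,
    covar: ParcelVector | None,
    n_perm: int,
    rng_seed: int,
) -> float:
    """Two-sided exact permutation p for the partial Spearman correlation.

    The null permutes y's region values uniformly (covariate stays attached
    to its regions); ``p = (1 + #{|rho_null| >= |rho_obs|}) / (n_perm + 1)``.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = np.random.default_rng(rng_seed)
    rho_obs, rhos_null = _null_rhos(x, y, covar, n_perm, rng)
    exceed = int(np.sum(np.abs(rhos_null) >= abs(rho_obs) - 1e-12))
    return (1 + exceed) / (n_perm + 1)


def molecular_screen(
    network: ScalarMap | list[ScalarMap],
    nt_catalogue: list[NeurotransmitterMap],
    parc: Parcellation,
    gm: ParcelVector | None,
    n_perm: int = 10_000,
    fdr_alpha: float = 0.05,
    rng_seed: int = 0,
) -> list[MolecularAssociation]:
    """Screen the catalogue for spatial association with the network.

    Single-map mode (a :class:`ScalarMap`): one partial Spearman rho per
    neurotransmitter map with a permutation p.  Subject-level mode (a list
    of maps): per-subject rhos are Fisher-z transformed and a one-sample t
    against zero is computed, with its null built from the same parcel
    permutations applied simultaneously to all subjects.  BH-FDR is applied
    across the catalogue either way.
    """
    if not nt_catalogue:
        raise ValueError("empty neurotransmitter catalogue")
    single = isinstance(network, ScalarMap)
    maps = [network] if single else list(network)
    vectors = [parcel_means(m, parc) for m in maps]

    associations: list[MolecularAssociation] = []
    ss = np.random.SeedSequence(rng_seed)
    child_seeds = ss.spawn(len(nt_catalogue))
    for nt, child in zip(nt_catalogue, child_seeds):
        rng = np.random.default_rng(child)
        if single:
            rho_obs, rhos_null = _null_rhos(vectors[0], nt.parcel_values, gm, n_perm, rng)
            p = (1 + int(np.sum(np.abs(rhos_null) >= abs(rho_obs) - 1e-12))) / (n_perm + 1)
            rho_z = float(np.arctanh(np.clip(rho_obs, -R_CLIP, R_CLIP)))
            associations.append(MolecularAssociation(nt.name, rho_obs, rho_z, p))
        else:
            obs, nulls = [], []
            # one shared permutation stream so the subject-level t shares a null
            perm_seed = int(rng.integers(2**31 - 1))
            for vec in vectors:
                r = np.random.default_rng(perm_seed)
                rho_i, null_i = _null_rhos(vec, nt.parcel_values, gm, n_perm, r)
                obs.append(np.arctanh(np.clip(rho_i, -R_CLIP, R_CLIP)))
                nulls.append(np.arctanh(np.clip(null_i, -R_CLIP, R_CLIP)))
            obs = np.asarray(obs)
            nulls = np.asarray(nulls)  # (S, n_perm)
            t_obs = _onesample_t(obs)
            t_null = _onesample_t(nulls)
            p = (1 + int(np.sum(np.abs(t_null) >= abs(t_obs) - 1e-12))) / (n_perm + 1)
            mean_rho = float(np.tanh(obs.mean()))
            associations.append(
                MolecularAssociation(nt.name, mean_rho, float(obs.mean()), p)
            )
    p_perm = np.array([a.p_perm for a in associations])
    reject = fdr_select(p_perm, fdr_alpha)
    # BH adjusted p for reporting (monotone in p_perm)
    from statsmodels.stats.multitest import multipletests

    _, p_adj, *_ = multipletests(p_perm, alpha=fdr_alpha, method="fdr_bh")
    for a, rej, padj in zip(associations, reject, p_adj):
        a.p_fdr = float(padj)
        a.significant = bool(rej)
    return associations


def _onesample_t(z: np.ndarray) -> np.ndarray | float:
    """t statistic of rows... axis 0 holds subjects."""
    mean = z.mean(axis=0)
    sd = z.std(axis=0, ddof=1)
    n = z.shape[0]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(sd > 0, mean / (sd / np.sqrt(n)), np.sign(mean) * np.inf)
    return t


def associations_table(associations: list[MolecularAssociation]) -> pd.DataFrame:
    """Results table with one row per map (name, rho, Fisher-z rho, p, FDR p)."""
    return pd.DataFrame(
        [
            {
                "map": a.name,
                "rho": a.rho,
                "rho_z": a.rho_z,
                "p_perm": a.p_perm,
                "p_fdr": a.p_fdr,
                "significant": a.significant,
            }
            for a in associations
        ]
    )
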