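"""Synthetic multi-subject response-map cohorts with planted covariance.

Pharmacological MRI response maps are a single 3D amplitude image per
subject; connectivity is defined by correlating, *across subjects*, the
amplitudes of voxel pairs. This module emulates that situation with a
block-covariance model: an atlas partitions an ellipsoidal "brain" into
contiguous regions, each region has a latent per-subject factor, and every
in-mask voxel's amplitude is

    amplitude = region_loading * factor(region) + noise_sd * noise,

with the latent factors drawn from a zero-mean multivariate normal whose
correlation matrix couples the regions. The induced population correlation
between a voxel in region p and a voxel in region q is

    rho_pq = L_p L_q R_pq / sqrt((L_p^2 + s^2)(L_q^2 + s^2)),

with L the loadings, R the cross-region correlation matrix and s the noise
scale. Region-concentrated loadings therefore plant high-degree,
high-clustering foci in the thresholded networks downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import DataError

#: Subject counts of the four study cohorts (three active drugs + vehicle).
DEFAULT_COHORT_SIZES = {
    "drug_a": 17,
    "drug_b": 7,
    "drug_c": 9,
    "vehicle": 7,
}

_PSD_TOL = 1e-8


@dataclass(frozen=True)
class VOIAtlas:
    """Integer-labelled parcellation of the voxel grid.

    ``label_grid`` holds 0 for background/non-brain and labels >= 1 for
    regions; ``cortical`` carries the cortical/subcortical flag used for
    the cortical-vs-subcortical scatter grouping.
    """

    label_grid: np.ndarray
    label_names: dict[int, str]
    voxel_size_mm: tuple[float, float, float]
    cortical: dict[int, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        grid = np.asarray(self.label_grid)
        if grid.ndim != 3:
            raise ValueError("label_grid must be 3D")
        if grid.min() < 0:
            raise ValueError("label_grid must be nonnegative")
        present = set(np.unique(grid)) - {0}
        named = set(self.label_names)
        if present != named:
            raise ValueError(
                f"label/name mismatch: labels in grid {sorted(present)} vs "
                f"named {sorted(named)}"
            )

    @property
    def labels(self) -> list[int]:
        return sorted(self.label_names)

    @property
    def n_regions(self) -> int:
        return len(self.label_names)

    @property
    def mask(self) -> np.ndarray:
        return np.asarray(self.label_grid) > 0

    def region_sizes(self) -> dict[int, int]:
        grid = np.asarray(self.label_grid)
        return {lab: int((grid == lab).sum()) for lab in self.labels}


@dataclass(frozen=True)
class CovarianceSpec:
    """Planted inter-subject covariance structure for one cohort.

    region_loading : per-region coupling of voxels to the region factor,
        each in [0, 1] (unitless).
    cross_region_corr : latent-factor correlation matrix (unit diagonal,
        symmetric, positive semidefinite).
    noise_sd : scale of the independent per-voxel noise (> 0).
    """

    region_loading: np.ndarray
    cross_region_corr: np.ndarray
    noise_sd: float
    n_subjects: int
    seed: int

    def __post_init__(self) -> None:
        loading = np.asarray(self.region_loading, dtype=float)
        corr = np.asarray(self.cross_region_corr, dtype=float)
        object.__setattr__(self, "region_loading", loading)
        object.__setattr__(self, "cross_region_corr", corr)
        if loading.ndim != 1:
            raise ValueError("region_loading must be 1D")
        if np.any(loading < 0) or np.any(loading > 1):
            raise ValueError("region_loading entries must lie in [0, 1]")
        r = loading.size
        if corr.shape != (r, r):
            raise ValueError(
                f"cross_region_corr must be {r}x{r}, got {corr.shape}"
            )
        if not np.allclose(corr, corr.T, atol=1e-12):
            raise ValueError("cross_region_corr must be symmetric")
        if not np.allclose(np.diag(corr), 1.0, atol=1e-12):
            raise ValueError("cross_region_corr must have unit diagonal")
        if np.linalg.eigvalsh(corr).min() < -_PSD_TOL:
            raise ValueError("cross_region_corr must be positive semidefinite")
        if not self.noise_sd > 0:
            raise ValueError("noise_sd must be > 0")
        if self.n_subjects < 3:
            raise ValueError("n_subjects must be >= 3")

    @property
    def n_regions(self) -> int:
        return self.region_loading.size


@dataclass(frozen=True)
class ResponseMapSet:
    """Stacked per-subject 3D response-amplitude maps on a shared grid."""

    maps: np.ndarray  # (n_subjects, nx, ny, nz)
    mask: np.ndarray  # (nx, ny, nz) bool
    voxel_size_mm: tuple[float, float, float]
    subject_ids: list[str]

    def __post_init__(self) -> None:
        maps = np.asarray(self.maps, dtype=float)
        mask = np.asarray(self.mask, dtype=bool)
        object.__setattr__(self, "maps", maps)
        object.__setattr__(self, "mask", mask)
        if maps.ndim != 4:
            raise ValueError("maps must be 4D (subject, x, y, z)")
        if maps.shape[1:] != mask.shape:
            raise DataError(
                f"map grid {maps.shape[1:]} does not match mask {mask.shape}"
            )
        if maps.shape[0] < 3:
            raise ValueError("need at least 3 subjects")
        if len(self.subject_ids) != maps.shape[0]:
            raise ValueError("subject_ids length must equal n_subjects")
        if not np.isfinite(maps[:, mask]).all():
            raise DataError("non-finite values inside the brain mask")

    @property
    def n_subjects(self) -> int:
        return self.maps.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.maps.shape[1:]


def ellipsoid_mask(shape: tuple[int, int, int], fill: float = 0.92) -> np.ndarray:
    """Axis-aligned ellipsoidal mask centred on the grid.

    ``fill`` scales the semi-axes relative to the half-dimensions.
    """
    nx, ny, nz = shape
    centre = (np.array(shape) - 1) / 2.0
    semi = np.maximum(fill * (np.array(shape) - 1) / 2.0, 0.5)
    x, y, z = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    d2 = (
        ((x - centre[0]) / semi[0]) ** 2
        + ((y - centre[1]) / semi[1]) ** 2
        + ((z - centre[2]) / semi[2]) ** 2
    )
    return d2 <= 1.0


_NEIGHBOURS = np.array(
    [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]]
)


def generate_atlas(
    shape: tuple[int, int, int],
    n_regions: int,
    seed: int,
    voxel_size_mm: tuple[float, float, float] = (0.3, 0.3, 0.3),
    growth_weights: np.ndarray | None = None,
) -> VOIAtlas:
    """Grow ``n_regions`` contiguous regions inside an ellipsoidal brain.

    Regions are grown by seeded accretion: random in-mask seed voxels, then
    one frontier voxel accreted at a time with per-region growth rates drawn
    from the RNG. The rates make region volumes unequal, as anatomical
    structures are. Regions whose centroid lies in the dorsal half of the
    grid (third axis) are flagged cortical.

    Deterministic given ``seed``; the nonzero voxels of the result partition
    the ellipsoid into ``n_regions`` contiguous blocks.
    """
    shape = tuple(int(s) for s in shape)
    if len(shape) != 3 or any(s < 2 for s in shape):
        raise ValueError(f"degenerate shape {shape}: all dims must be >= 2")
    if n_regions < 2:
        raise ValueError("n_regions must be >= 2")
    if np.prod(shape) < 10 * n_regions:
        raise ValueError("grid too small for requested number of regions")

    rng = np.random.default_rng(seed)
    mask = ellipsoid_mask(shape)
    coords = np.argwhere(mask)
    if coords.shape[0] < n_regions:
        raise ValueError("mask smaller than number of regions")

    labels = np.zeros(shape, dtype=np.int32)
    seeds = coords[rng.choice(coords.shape[0], size=n_regions, replace=False)]
    if growth_weights is None:
        # Unequal growth rates -> unequal region volumes (factor ~4 spread).
        rates = rng.uniform(0.5, 2.0, size=n_regions)
    else:
        rates = np.asarray(growth_weights, dtype=float)
        if rates.shape != (n_regions,) or np.any(rates <= 0):
            raise ValueError("growth_weights must be n_regions positive rates")

    frontiers: list[list[tuple[int, int, int]]] = []
    for lab, (x, y, z) in enumerate(seeds, start=1):
        labels[x, y, z] = lab
        frontiers.append([(x, y, z)])

    n_left = coords.shape[0] - n_regions
    active = list(range(n_regions))
    while n_left > 0 and active:
        weights = rates[active] / rates[active].sum()
        ridx = active[rng.choice(len(active), p=weights)]
        frontier = frontiers[ridx]
        grown = False
        while frontier and not grown:
            pick = rng.integers(len(frontier))
            x, y, z = frontier[pick]
            candidates = []
            for dx, dy, dz in _NEIGHBOURS:
                nxc, nyc, nzc = x + dx, y + dy, z + dz
                if (
                    0 <= nxc < shape[0]
                    and 0 <= nyc < shape[1]
                    and 0 <= nzc < shape[2]
                    and mask[nxc, nyc, nzc]
                    and labels[nxc, nyc, nzc] == 0
                ):
                    candidates.append((nxc, nyc, nzc))
            if not candidates:
                # exhausted voxel: lazy-delete from the frontier
                frontier[pick] = frontier[-1]
                frontier.pop()
                continue
            new = candidates[rng.integers(len(candidates))]
            labels[new] = ridx + 1
            frontier.append(new)
            n_left -= 1
            grown = True
        if not frontier:
            active.remove(ridx)

    if n_left > 0:  # pragma: no cover - accretion always fills a connected mask
        raise RuntimeError("atlas accretion failed to fill the mask")

    mid_z = (shape[2] - 1) / 2.0
    label_names = {}
    cortical = {}
    for lab in range(1, n_regions + 1):
        zc = np.argwhere(labels == lab)[:, 2].mean()
        cortical[lab] = bool(zc >= mid_z)
        kind = "ctx" if cortical[lab] else "sub"
        label_names[lab] = f"{kind}_region_{lab:02d}"
    return VOIAtlas(
        label_grid=labels,
        label_names=label_names,
        voxel_size_mm=tuple(float(v) for v in voxel_size_mm),
        cortical=cortical,
    )


def population_correlation(
    spec: CovarianceSpec, region_p: int, region_q: int, same_voxel: bool = False
) -> float:
    """Closed-form population inter-subject correlation between a voxel in
    region ``region_p`` and a distinct voxel in region ``region_q``
    (0-based region indices)."""
    load = spec.region_loading
    s2 = spec.noise_sd**2
    lp, lq = load[region_p], load[region_q]
    rho = spec.cross_region_corr[region_p, region_q]
    if same_voxel:
        return 1.0
    return float(lp * lq * rho / np.sqrt((lp**2 + s2) * (lq**2 + s2)))


def generate_cohort(atlas: VOIAtlas, spec: CovarianceSpec) -> ResponseMapSet:
    """Draw one cohort of response maps under the block-covariance model.

    Bit-identical output for identical ``spec`` (including seed).
    """
    if spec.n_regions != atlas.n_regions:
        raise ValueError(
            f"spec has {spec.n_regions} regions but atlas has {atlas.n_regions}"
        )
    grid = np.asarray(atlas.label_grid)
    mask = grid > 0
    in_lab = grid[mask] - 1  # 0-based region index per in-mask voxel
    n_vox = int(mask.sum())

    rng = np.random.default_rng(spec.seed)
    w, v = np.linalg.eigh(spec.cross_region_corr)
    root = v * np.sqrt(np.clip(w, 0.0, None))
    factors = rng.standard_normal((spec.n_subjects, spec.n_regions)) @ root.T
    noise = rng.standard_normal((spec.n_subjects, n_vox))

    amplitudes = (
        spec.region_loading[in_lab][None, :] * factors[:, in_lab]
        + spec.noise_sd * noise
    )
    maps = np.zeros((spec.n_subjects,) + grid.shape)
    maps[:, mask] = amplitudes
    subject_ids = [f"S{i + 1:02d}" for i in range(spec.n_subjects)]
    return ResponseMapSet(
        maps=maps,
        mask=mask,
        voxel_size_mm=atlas.voxel_size_mm,
        subject_ids=subject_ids,
    )


def baseline_covariance(
    n_regions: int,
    n_subjects: int,
    seed: int,
    loading_range: tuple[float, float] = (0.02, 0.1),
    background_corr: float = 0.1,
    noise_sd: float = 0.7,
) -> CovarianceSpec:
    """Vehicle-like study conditions: region loadings near the noise floor
    and weak uniform cross-region coupling.

    Loadings follow a quadratic ramp over the loading range, permuted
    across regions by the RNG. The default range keeps every baseline
    region's population correlation far below the 2%-sparsity retention
    threshold, mirroring the scattered control network whose anatomical
    structure is only slight: retained baseline edges are then dominated
    by sampling noise, with no region-level common factor near the
    threshold, and a planted drug effect stands out cleanly.
    """
    if n_regions < 2:
        raise ValueError("n_regions must be >= 2")
    rng = np.random.default_rng(seed)
    lo, hi = loading_range
    ramp = lo + (hi - lo) * np.linspace(0.0, 1.0, n_regions) ** 2
    loading = ramp[rng.permutation(n_regions)]
    corr = np.full((n_regions, n_regions), background_corr)
    np.fill_diagonal(corr, 1.0)
    return CovarianceSpec(
        region_loading=loading,
        cross_region_corr=corr,
        noise_sd=noise_sd,
        n_subjects=n_subjects,
        seed=seed,
    )


def heavy_tail_growth_weights(
    n_regions: int, seed: int, alpha: float = 1.2, cap: float = 20.0
) -> np.ndarray:
    """Pareto-distributed atlas growth weights for the heavy-tailed regime.

    Anatomical structure volumes are themselves heavy-tailed; Pareto(alpha)
    weights give many small regions and a few large ones.
    """
    rng = np.random.default_rng(seed)
    return np.clip((1.0 - rng.random(n_regions)) ** (-1.0 / alpha), None, cap)


def heavy_tailed_covariance(
    n_regions: int,
    n_subjects: int,
    seed: int,
    loading: float = 0.6,
    background_corr: float = 0.1,
    noise_sd: float = 0.7,
) -> CovarianceSpec:
    """Scale-free-regime conditions: uniform moderate loading over regions
    whose volumes follow a power law (:func:`heavy_tail_growth_weights`).

    Under equi-sparse thresholding a coherently responding region forms a
    partially retained clique whose node degree scales with the region's
    volume; power-law volumes therefore yield the heavy-tailed,
    hub-dominated degree distributions drug response maps exhibit, with
    the node count per degree level falling as the degree rises.
    """
    corr = np.full((n_regions, n_regions), background_corr)
    np.fill_diagonal(corr, 1.0)
    return CovarianceSpec(
        region_loading=np.full(n_regions, loading),
        cross_region_corr=corr,
        noise_sd=noise_sd,
        n_subjects=n_subjects,
        seed=seed,
    )


def planted_effect(
    spec: CovarianceSpec,
    region: int,
    loading: float = 0.95,
    partners: tuple[int, ...] = (),
    coupling: float = 0.6,
    seed: int | None = None,
) -> CovarianceSpec:
    """Drug-like variant of ``spec``: raise one region's loading and couple
    it to partner regions (all indices 0-based).

    Emulates a pharmacological challenge recruiting a focal circuit on top
    of the vehicle covariance structure.
    """
    if not 0 <= region < spec.n_regions:
        raise ValueError("region index out of range")
    load = spec.region_loading.copy()
    load[region] = loading
    corr = spec.cross_region_corr.copy()
    for p in partners:
        if p == region or not 0 <= p < spec.n_regions:
            raise ValueError(f"invalid partner region {p}")
        corr[region, p] = corr[p, region] = coupling
    if np.linalg.eigvalsh(corr).min() < -_PSD_TOL:
        raise ValueError("planted coupling makes cross_region_corr non-PSD")
    return replace(
        spec,
        region_loading=load,
        cross_region_corr=corr,
        seed=spec.seed if seed is None else seed,
    )


def planting_site(atlas: VOIAtlas, max_fraction: float = 0.08) -> int:
    """Canonical planting site for a focal drug effect: the largest region
    not exceeding ``max_fraction`` of the in-mask volume.

    A strongly loaded region forms a near-complete clique, so its degree
    scales with its size; capping the size below a tenth of the brain
    keeps the whole focal region inside the top decile of degree. Falls
    back to the smallest region when every region exceeds the cap.
    """
    sizes = atlas.region_sizes()
    total = sum(sizes.values())
    eligible = {l: s for l, s in sizes.items() if s <= max_fraction * total}
    if not eligible:
        return min(sizes, key=lambda lab: (sizes[lab], lab))
    return max(eligible, key=lambda lab: (eligible[lab], -lab))
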