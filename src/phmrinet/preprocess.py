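"""Spatial preprocessing of response maps before network construction.

The pipeline order mirrors the study workflow: Gaussian smoothing of each
subject's 3D map, in-plane rebinning (block averaging over the first two
axes), then mask application to produce the node-by-subject response
matrix. Node identifiers are defined by raster order over in-mask voxels
(x fastest, then y, then z; 0-based coordinates).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .errors import DataError
from .synthetic import ResponseMapSet, VOIAtlas

logger = logging.getLogger(__name__)

#: FWHM of a Gaussian = sigma * 2*sqrt(2*ln 2)
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

#: Kernel truncation radius in units of sigma.
_TRUNCATE = 4.0


def smooth_maps(maps: ResponseMapSet, fwhm_mm: float) -> ResponseMapSet:
    """Convolve each subject's map with an isotropic Gaussian kernel.

    ``fwhm_mm`` is the kernel full width at half maximum in millimetres;
    the per-axis sigma in voxel units follows from ``voxel_size_mm``.
    Boundaries are zero-padded and the kernel is truncated at 4 sigma, so
    total mass is conserved up to truncation error. ``fwhm_mm = 0``
    returns the input unchanged.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be >= 0")
    if fwhm_mm == 0:
        return maps
    sigma_vox = fwhm_mm * FWHM_TO_SIGMA / np.asarray(maps.voxel_size_mm)
    smoothed = np.empty_like(maps.maps)
    for s in range(maps.n_subjects):
        ndimage.gaussian_filter(
            maps.maps[s],
            sigma=sigma_vox,
            output=smoothed[s],
            mode="constant",
            cval=0.0,
            truncate=_TRUNCATE,
        )
    return replace(maps, maps=smoothed)


def _crop_inplane(shape: tuple[int, int, int], factor: int) -> tuple[int, int]:
    nx = (shape[0] // factor) * factor
    ny = (shape[1] // factor) * factor
    if (nx, ny) != shape[:2]:
        warnings.warn(
            f"in-plane dims {shape[:2]} not divisible by {factor}; "
            f"dropping trailing rows/columns to {(nx, ny)}",
            stacklevel=3,
        )
    return nx, ny


def _block_view(a: np.ndarray, factor: int) -> np.ndarray:
    nx, ny = a.shape[0], a.shape[1]
    return a.reshape(nx // factor, factor, ny // factor, factor, a.shape[2])


def rebin_inplane(maps: ResponseMapSet, factor: int) -> ResponseMapSet:
    """Replace each in-plane ``factor x factor`` voxel block by its mean.

    The slice dimension (third axis) is untouched. The mask is rebinned by
    majority vote with ties counted as in-mask; in-plane voxel size is
    multiplied by ``factor``. Trailing rows/columns that do not fill a
    block are dropped with a warning.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    if factor == 1:
        return maps
    nx, ny = _crop_inplane(maps.shape, factor)
    nz = maps.shape[2]
    data = maps.maps[:, :nx, :ny, :]
    new = data.reshape(
        maps.n_subjects, nx // factor, factor, ny // factor, factor, nz
    ).mean(axis=(2, 4))

    mask_counts = _block_view(
        maps.mask[:nx, :ny, :].astype(np.int32), factor
    ).sum(axis=(1, 3))
    new_mask = 2 * mask_counts >= factor * factor

    vx, vy, vz = maps.voxel_size_mm
    return ResponseMapSet(
        maps=new,
        mask=new_mask,
        voxel_size_mm=(vx * factor, vy * factor, vz),
        subject_ids=list(maps.subject_ids),
    )


def rebin_atlas(atlas: VOIAtlas, factor: int) -> VOIAtlas:
    """Rebin a label atlas consistently with :func:`rebin_inplane`.

    Each block takes the most frequent nonzero label among its voxels when
    the block's majority-vote mask is in-brain (ties counted in), and 0
    otherwise. Label ties break toward the smaller label.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    if factor == 1:
        return atlas
    grid = np.asarray(atlas.label_grid)
    nx, ny = _crop_inplane(grid.shape, factor)
    blocks = _block_view(grid[:nx, :ny, :], factor)
    out = np.zeros((nx // factor, ny // factor, grid.shape[2]), dtype=grid.dtype)
    n_in = (blocks > 0).sum(axis=(1, 3))
    in_mask = 2 * n_in >= factor * factor
    for i, j, k in np.argwhere(in_mask):
        block = blocks[i, :, j, :, k].ravel()
        block = block[block > 0]
        labs, counts = np.unique(block, return_counts=True)
        out[i, j, k] = labs[np.argmax(counts)]
    present = set(np.unique(out)) - {0}
    return VOIAtlas(
        label_grid=out,
        label_names={l: atlas.label_names[l] for l in present},
        voxel_size_mm=(
            atlas.voxel_size_mm[0] * factor,
            atlas.voxel_size_mm[1] * factor,
            atlas.voxel_size_mm[2],
        ),
        cortical={l: atlas.cortical[l] for l in present if l in atlas.cortical},
    )


def upsample_atlas_inplane(atlas: VOIAtlas, factor: int) -> VOIAtlas:
    """Replicate each in-plane atlas voxel into a ``factor x factor`` block.

    Inverse of :func:`rebin_atlas` for block-aligned atlases: an atlas
    defined at the analysis resolution (as VOI atlases are, on the
    template grid) is expanded to the acquisition grid so that simulated
    maps can be generated at full resolution and rebinned back without
    mixed-label blocks.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    if factor == 1:
        return atlas
    grid = np.asarray(atlas.label_grid)
    up = np.repeat(np.repeat(grid, factor, axis=0), factor, axis=1)
    return VOIAtlas(
        label_grid=up,
        label_names=dict(atlas.label_names),
        voxel_size_mm=(
            atlas.voxel_size_mm[0] / factor,
            atlas.voxel_size_mm[1] / factor,
            atlas.voxel_size_mm[2],
        ),
        cortical=dict(atlas.cortical),
    )


@dataclass(frozen=True)
class ResponseMatrix:
    """Node-by-subject response matrix with the node <-> voxel bijection.

    Row ``i`` of ``values`` is the response vector of node ``i`` across
    subjects; ``node_coords[i]`` is its (x, y, z) voxel coordinate. Nodes
    are ordered by raster scan of the in-mask voxels with x varying
    fastest, then y, then z.
    """

    values: np.ndarray  # (n_nodes, n_subjects)
    node_coords: np.ndarray  # (n_nodes, 3) int
    voxel_size_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        coords = np.asarray(self.node_coords, dtype=np.int64)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "node_coords", coords)
        if values.ndim != 2 or values.shape[0] < 2:
            raise ValueError("need at least 2 nodes")
        if values.shape[1] < 3:
            raise ValueError("need at least 3 subjects")
        if coords.shape != (values.shape[0], 3):
            raise ValueError("node_coords must be (n_nodes, 3)")

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    @property
    def n_subjects(self) -> int:
        return self.values.shape[1]

    def coord_to_node(self) -> dict[tuple[int, int, int], int]:
        """Inverse of the node -> coordinate map."""
        return {tuple(c): i for i, c in enumerate(self.node_coords)}

    def node_labels(self, atlas: VOIAtlas) -> np.ndarray:
        """VOI label of every node (0 where the atlas has background)."""
        grid = np.asarray(atlas.label_grid)
        if np.any(self.node_coords.max(axis=0) >= grid.shape):
            raise DataError("atlas grid does not cover node coordinates")
        x, y, z = self.node_coords.T
        return grid[x, y, z]


def extract_response_matrix(maps: ResponseMapSet) -> ResponseMatrix:
    """Stack in-mask voxels into the node-by-subject response matrix."""
    mask = maps.mask
    if not mask.any():
        raise ValueError("mask is empty")
    coords = np.argwhere(mask)
    # raster order: x fastest, then y, then z (np.lexsort: last key primary)
    order = np.lexsort((coords[:, 0], coords[:, 1], coords[:, 2]))
    coords = coords[order]
    values = maps.maps[:, coords[:, 0], coords[:, 1], coords[:, 2]].T
    bad = np.argwhere(~np.isfinite(values))
    if bad.size:
        x, y, z = coords[bad[0, 0]]
        raise DataError(
            f"non-finite response at voxel ({x}, {y}, {z}), "
            f"subject index {bad[0, 1]}"
        )
    logger.info("response matrix: %d nodes x %d subjects", *values.shape)
    return ResponseMatrix(
        values=values, node_coords=coords, voxel_size_mm=maps.voxel_size_mm
    )
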