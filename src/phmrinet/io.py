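"""Standard-format readers and writers.

Voxel grids travel as NIfTI-1 (via nibabel) with the voxel size in the
affine; binary adjacency as Matrix Market pattern plus a JSON sidecar
recording N, E, sparsity, z_thresh and the node-index convention; tabular
outputs as TSV. All writers are matched by readers so every artifact
round-trips through the package's own code.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import io as sio
from scipy import sparse

from .metrics import DegreeHistogram, GlobalMetrics, NodeMetrics
from .network import BinaryNetwork
from .preprocess import ResponseMatrix
from .synthetic import ResponseMapSet, VOIAtlas

#: Provenance string for the node ordering convention.
RASTER_CONVENTION = "in-mask voxels, raster order, x fastest then y then z, 0-based"


def _affine(voxel_size_mm) -> np.ndarray:
    return np.diag(list(voxel_size_mm) + [1.0])


def save_maps(maps: ResponseMapSet, path: str | Path) -> None:
    """Write the 4D response maps (subject axis last, NIfTI convention)."""
    img = nib.Nifti1Image(
        np.moveaxis(maps.maps, 0, -1).astype(np.float32), _affine(maps.voxel_size_mm)
    )
    nib.save(img, str(path))


def save_mask(maps: ResponseMapSet, path: str | Path) -> None:
    img = nib.Nifti1Image(
        maps.mask.astype(np.uint8), _affine(maps.voxel_size_mm)
    )
    nib.save(img, str(path))


def load_maps(
    maps_path: str | Path, mask_path: str | Path, subject_ids=None
) -> ResponseMapSet:
    img = nib.load(str(maps_path))
    data = np.moveaxis(np.asarray(img.dataobj, dtype=float), -1, 0)
    mask = np.asarray(nib.load(str(mask_path)).dataobj) > 0
    vox = tuple(float(z) for z in img.header.get_zooms()[:3])
    if subject_ids is None:
        subject_ids = [f"S{i + 1:02d}" for i in range(data.shape[0])]
    return ResponseMapSet(
        maps=data, mask=mask, voxel_size_mm=vox, subject_ids=list(subject_ids)
    )


def save_atlas(atlas: VOIAtlas, nii_path: str | Path, json_path: str | Path) -> None:
    img = nib.Nifti1Image(
        np.asarray(atlas.label_grid, dtype=np.int16), _affine(atlas.voxel_size_mm)
    )
    nib.save(img, str(nii_path))
    meta = {
        "label_names": {str(k): v for k, v in atlas.label_names.items()},
        "cortical": {str(k): bool(v) for k, v in atlas.cortical.items()},
        "voxel_size_mm": list(atlas.voxel_size_mm),
    }
    Path(json_path).write_text(json.dumps(meta, indent=2))


def load_atlas(nii_path: str | Path, json_path: str | Path) -> VOIAtlas:
    grid = np.asarray(nib.load(str(nii_path)).dataobj).astype(np.int32)
    meta = json.loads(Path(json_path).read_text())
    return VOIAtlas(
        label_grid=grid,
        label_names={int(k): v for k, v in meta["label_names"].items()},
        voxel_size_mm=tuple(meta["voxel_size_mm"]),
        cortical={int(k): bool(v) for k, v in meta.get("cortical", {}).items()},
    )


def save_response_matrix(rm: ResponseMatrix, path: str | Path) -> None:
    df = pd.DataFrame(rm.node_coords, columns=["x", "y", "z"])
    df.insert(0, "node_id", np.arange(rm.n_nodes))
    for j in range(rm.n_subjects):
        df[f"subject_{j + 1:02d}"] = rm.values[:, j]
    df.to_csv(path, sep="\t", index=False)


def save_binary_network(bn: BinaryNetwork, prefix: str | Path) -> None:
    """Write ``<prefix>.mtx`` (symmetric pattern) and ``<prefix>.json``."""
    prefix = Path(prefix)
    # mmwrite keeps only the lower triangle when symmetry is declared
    lower = sparse.tril(bn.adjacency, k=-1).tocoo()
    sio.mmwrite(
        str(prefix.with_suffix(".mtx")),
        lower,
        field="pattern",
        symmetry="symmetric",
    )
    sidecar = {
        "n_nodes": bn.n_nodes,
        "n_edges": bn.n_edges,
        "sparsity": bn.sparsity,
        "z_thresh": bn.z_thresh,
        "voxel_size_mm": list(bn.voxel_size_mm),
        "node_index": RASTER_CONVENTION,
        "node_coords": bn.node_coords.tolist(),
    }
    prefix.with_suffix(".json").write_text(json.dumps(sidecar))


def load_binary_network(prefix: str | Path) -> BinaryNetwork:
    prefix = Path(prefix)
    adj = sio.mmread(str(prefix.with_suffix(".mtx"))).tocsr().astype(np.int8)
    meta = json.loads(prefix.with_suffix(".json").read_text())
    return BinaryNetwork(
        adjacency=adj,
        z_thresh=float(meta["z_thresh"]),
        sparsity=float(meta["sparsity"]),
        node_coords=np.asarray(meta["node_coords"], dtype=np.int64),
        voxel_size_mm=tuple(meta["voxel_size_mm"]),
    )


def save_node_metrics(
    nm: NodeMetrics, path: str | Path, atlas: VOIAtlas | None = None
) -> None:
    df = pd.DataFrame(nm.node_coords, columns=["x", "y", "z"])
    df.insert(0, "node_id", np.arange(nm.n_nodes))
    df["k"] = nm.k
    df["c"] = nm.c
    if atlas is not None:
        grid = np.asarray(atlas.label_grid)
        labels = grid[nm.node_coords[:, 0], nm.node_coords[:, 1], nm.node_coords[:, 2]]
        df["voi_label"] = labels
        df["cortical_flag"] = [
            int(atlas.cortical.get(int(lab), False)) for lab in labels
        ]
    df.to_csv(path, sep="\t", index=False)


def save_global_metrics(gm: GlobalMetrics, path: str | Path) -> None:
    Path(path).write_text(json.dumps(gm.to_dict(), indent=2))


def save_histogram(h: DegreeHistogram, path: str | Path) -> None:
    pd.DataFrame({"bin_center": h.bin_centers, "count": h.counts}).to_csv(
        path, sep="\t", index=False
    )


def save_metric_map(
    grid: np.ndarray, voxel_size_mm, path: str | Path
) -> None:
    dtype = np.int16 if np.issubdtype(grid.dtype, np.integer) else np.float32
    nib.save(
        nib.Nifti1Image(grid.astype(dtype), _affine(voxel_size_mm)), str(path)
    )
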