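"""GIFTI and CSV input/output with validation on load.

Per-vertex data travel as GIFTI (surface .surf.gii, metric .func.gii /
.shape.gii, label .label.gii); parcel tables and matrices travel as CSV
with parcel-id headers, undefined entries serialized as "NA". Data
arrays are written in float64 so round trips are exact.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from nibabel.gifti import GiftiDataArray, GiftiImage, GiftiLabel, GiftiLabelTable

from .surface import Parcellation, SurfaceMesh

__all__ = [
    "write_surface", "read_surface",
    "write_metric", "read_metric",
    "write_labels", "read_labels",
    "write_matrix", "read_matrix",
    "write_mesh_bundle", "read_mesh_bundle",
    "write_json", "read_json",
]

_FLOAT64 = "NIFTI_TYPE_FLOAT64"


def _save(img: GiftiImage, path) -> None:
    # float64 darrays are outside the strict GIFTI datatype set; write in
    # "force" mode so round trips stay exact (nibabel reads them back fine)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        img.to_filename(str(path), mode="force")


def write_surface(path, coords: np.ndarray, triangles: np.ndarray) -> None:
    """Write one coordinate set + topology as a GIFTI surface file."""
    img = GiftiImage(darrays=[
        GiftiDataArray(np.asarray(coords, dtype=np.float64),
                       intent="NIFTI_INTENT_POINTSET", datatype=_FLOAT64),
        GiftiDataArray(np.asarray(triangles, dtype=np.int32),
                       intent="NIFTI_INTENT_TRIANGLE", datatype="NIFTI_TYPE_INT32"),
    ])
    _save(img, path)


def read_surface(path) -> tuple[np.ndarray, np.ndarray]:
    """Read (coords, triangles) from a GIFTI surface file."""
    img = nib.load(str(path))
    coords = triangles = None
    for da in img.darrays:
        if da.intent == nib.nifti1.intent_codes["NIFTI_INTENT_POINTSET"]:
            coords = np.asarray(da.data, dtype=float)
        elif da.intent == nib.nifti1.intent_codes["NIFTI_INTENT_TRIANGLE"]:
            triangles = np.asarray(da.data, dtype=np.int64)
    if coords is None or triangles is None:
        raise ValueError(f"{path}: not a surface GIFTI (needs pointset and triangle arrays)")
    return coords, triangles


def write_mesh_bundle(directory, mesh: SurfaceMesh, stem: str = "mesh") -> None:
    """Write midsurface plus companion coordinate sets as sibling surf.gii files."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_surface(directory / f"{stem}.midsurface.surf.gii", mesh.vertex_coords, mesh.triangles)
    for name, coords in mesh.companion_coords.items():
        write_surface(directory / f"{stem}.{name}.surf.gii", coords, mesh.triangles)


def read_mesh_bundle(directory, stem: str = "mesh") -> SurfaceMesh:
    directory = Path(directory)
    coords, tris = read_surface(directory / f"{stem}.midsurface.surf.gii")
    companions = {}
    for f in sorted(directory.glob(f"{stem}.*.surf.gii")):
        name = f.name[len(stem) + 1:-len(".surf.gii")]
        if name == "midsurface":
            continue
        c, t = read_surface(f)
        if c.shape != coords.shape:
            raise ValueError(f"{f}: vertex count mismatch with midsurface")
        companions[name] = c
    return SurfaceMesh(coords, tris, companions)


def write_metric(path, values: np.ndarray) -> None:
    """Write per-vertex scalar(s) as a GIFTI metric file (one darray per column)."""
    values = np.asarray(values, dtype=np.float64)
    cols = values[:, None] if values.ndim == 1 else values
    img = GiftiImage(darrays=[
        GiftiDataArray(np.ascontiguousarray(cols[:, c]), intent="NIFTI_INTENT_SHAPE",
                       datatype=_FLOAT64)
        for c in range(cols.shape[1])
    ])
    _save(img, path)


def read_metric(path, n_vertices: int | None = None) -> np.ndarray:
    img = nib.load(str(path))
    if not img.darrays:
        raise ValueError(f"{path}: metric GIFTI has no data arrays")
    cols = [np.asarray(da.data, dtype=float) for da in img.darrays]
    lengths = {len(c) for c in cols}
    if len(lengths) != 1:
        raise ValueError(f"{path}: data arrays have inconsistent lengths {sorted(lengths)}")
    out = np.column_stack(cols)
    if n_vertices is not None and out.shape[0] != n_vertices:
        raise ValueError(
            f"{path}: vertex count {out.shape[0]} does not match surface ({n_vertices})"
        )
    return out[:, 0] if out.shape[1] == 1 else out


def write_labels(path, parcellation: Parcellation) -> None:
    """Write a parcellation as a GIFTI label file; mask/centroids ride in metadata."""
    table = GiftiLabelTable()
    for p in range(parcellation.n_parcels):
        lbl = GiftiLabel(key=p)
        lbl.label = f"parcel_{p}"
        table.labels.append(lbl)
    img = GiftiImage(labeltable=table, darrays=[
        GiftiDataArray(parcellation.labels.astype(np.int32),
                       intent="NIFTI_INTENT_LABEL", datatype="NIFTI_TYPE_INT32"),
    ])
    img.meta["included_mask"] = json.dumps(parcellation.included_mask.astype(int).tolist())
    img.meta["centroid_vertex"] = json.dumps(parcellation.centroid_vertex.tolist())
    _save(img, path)


def read_labels(path, n_vertices: int | None = None) -> Parcellation:
    img = nib.load(str(path))
    if not img.darrays:
        raise ValueError(f"{path}: label GIFTI has no data arrays")
    labels = np.asarray(img.darrays[0].data, dtype=np.int64)
    if n_vertices is not None and len(labels) != n_vertices:
        raise ValueError(f"{path}: vertex count {len(labels)} does not match surface")
    meta = dict(img.meta)
    if "included_mask" not in meta or "centroid_vertex" not in meta:
        raise ValueError(f"{path}: label file lacks parcellation metadata "
                         "(included_mask / centroid_vertex)")
    mask = np.asarray(json.loads(meta["included_mask"]), dtype=bool)
    cent = np.asarray(json.loads(meta["centroid_vertex"]), dtype=np.int64)
    return Parcellation(labels, mask, cent)


def write_matrix(path, values: np.ndarray, parcel_ids=None) -> None:
    """Write a parcel matrix as CSV with id header row/column; NaN -> "NA"."""
    values = np.asarray(values, dtype=float)
    ids = np.arange(values.shape[0]) if parcel_ids is None else np.asarray(parcel_ids)
    df = pd.DataFrame(values, index=ids, columns=ids)
    df.to_csv(path, na_rep="NA", float_format="%.17g")


def read_matrix(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a parcel matrix CSV; returns (values, parcel_ids)."""
    try:
        df = pd.read_csv(path, index_col=0, na_values=["NA"],
                         float_precision="round_trip")
    except Exception as err:
        raise ValueError(f"{path}: failed to parse matrix CSV: {err}") from err
    if df.shape[0] != df.shape[1]:
        raise ValueError(f"{path}: matrix is not square ({df.shape[0]}x{df.shape[1]}); "
                         "missing parcel-id header?")
    try:
        ids = df.index.to_numpy(dtype=np.int64)
        col_ids = np.asarray([int(c) for c in df.columns])
    except (TypeError, ValueError) as err:
        raise ValueError(f"{path}: non-integer parcel ids in header: {err}") from err
    if not np.array_equal(ids, col_ids):
        raise ValueError(f"{path}: row and column parcel ids disagree")
    return df.to_numpy(dtype=float), ids


def write_json(path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=str))


def read_json(path):
    return json.loads(Path(path).read_text())
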