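"""Tabular, container and surface-map I/O.

Canonical on-disk formats: TSV with one header row and one header column
for small numeric artifacts (written at 17 significant digits so float64
values round-trip bit-exactly), HDF5 for dense connectivity matrices, JSON
sidecars for provenance, and GIFTI metric/label files (via nibabel) or PNG
flatmap heatmaps for surface maps.
"""

from __future__ import annotations

import json
import hashlib
from pathlib import Path

import h5py
import matplotlib

matplotlib.use("Agg")
import matplotlib.image as mpimg
import matplotlib.pyplot as plt  # noqa: F401  (users grab plt from here)
import numpy as np
import pandas as pd

from .connectivity import ConnectivityMatrix
from .grids import FlatmapGrid


def write_matrix_table(path, values, row_labels=None, col_labels=None) -> Path:
    """Write a matrix as TSV with header row and header column.

    Values are printed with ``%.17g`` so finite float64 entries round-trip
    bit-exactly through :func:`read_matrix_table`.
    """
    path = Path(path)
    values = np.asarray(values, dtype=float)
    if values.ndim != 2:
        raise ValueError("values must be 2D")
    n, m = values.shape
    rows = [f"r{i}" for i in range(n)] if row_labels is None else list(row_labels)
    cols = [f"c{j}" for j in range(m)] if col_labels is None else list(col_labels)
    df = pd.DataFrame(values, index=rows, columns=cols)
    df.to_csv(path, sep="\t", float_format="%.17g", index_label="id")
    return path


def read_matrix_table(path):
    """Read a TSV matrix table; returns ``(values, row_labels, col_labels)``.

    Ragged rows and non-numeric cells raise with the offending location;
    an empty file raises explicitly.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"{path}: empty input file") from exc
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: malformed table ({exc})") from exc
    if df.shape[1] == 0:
        raise ValueError(f"{path}: table has no data columns")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"{path}: non-numeric cell at line {i + 2}, column "
            f"{df.columns[j]!r}: {df.iat[i, j]!r}"
        )
    return numeric.to_numpy(dtype=float), list(df.index), list(df.columns)


def write_sidecar(path, meta: dict) -> Path:
    """Write a JSON provenance sidecar next to an artifact."""
    side = Path(str(path) + ".json")
    side.write_text(json.dumps(meta, indent=2, default=_json_default, sort_keys=True))
    return side


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def config_hash(config_dict: dict) -> str:
    canon = json.dumps(config_dict, sort_keys=True, default=_json_default)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def save_connectivity_h5(path, matrices: dict) -> Path:
    """Save named ConnectivityMatrix objects into one HDF5 container."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        for name, m in matrices.items():
            d = f.create_dataset(name, data=m.values)
            d.attrs["row_kind"] = m.row_kind
            d.attrs["col_kind"] = m.col_kind
            d.attrs["species_tag"] = m.species_tag
            d.attrs["averaged_over"] = m.averaged_over
    return path


def load_connectivity_h5(path) -> dict:
    out = {}
    with h5py.File(path, "r") as f:
        for name in f:
            d = f[name]
            out[name] = ConnectivityMatrix(
                values=d[()],
                row_kind=d.attrs["row_kind"],
                col_kind=d.attrs["col_kind"],
                species_tag=d.attrs["species_tag"],
                averaged_over=int(d.attrs["averaged_over"]),
            )
    return out


def export_surface_maps(values, target, path, labels=None) -> Path:
    """Export a per-element map to disk.

    ``target`` is either a :class:`FlatmapGrid` (written as a PNG heatmap
    with exactly n_ap x n_pd pixels) or a mesh tuple ``(vertices, faces)``
    (written as a GIFTI metric file, or a label file when ``labels`` gives
    the label-id -> name table).
    """
    path = Path(path)
    values = np.asarray(values)
    if isinstance(target, FlatmapGrid):
        if values.size != target.n_vertices:
            raise ValueError("map length does not match grid")
        img = values.reshape(target.n_ap, target.n_pd).astype(float)
        mpimg.imsave(path, img, cmap="viridis")
        return path
    import nibabel as nib
    from nibabel import gifti

    vertices, _faces = target
    if values.size != np.asarray(vertices).shape[0]:
        raise ValueError("map length does not match mesh vertex count")
    if labels is None:
        darr = gifti.GiftiDataArray(
            values.astype(np.float32), intent="NIFTI_INTENT_ESTIMATE"
        )
        img = gifti.GiftiImage(darrays=[darr])
    else:
        table = gifti.GiftiLabelTable()
        for key, name in labels.items():
            lab = gifti.GiftiLabel(key=int(key))
            lab.label = name
            table.labels.append(lab)
        darr = gifti.GiftiDataArray(
            values.astype(np.int32), intent="NIFTI_INTENT_LABEL"
        )
        img = gifti.GiftiImage(darrays=[darr], labeltable=table)
    nib.save(img, path)
    return path


def read_gifti_map(path) -> np.ndarray:
    import nibabel as nib

    img = nib.load(str(path))
    return img.darrays[0].data
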