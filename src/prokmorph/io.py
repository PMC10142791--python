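"""Stable file formats: cell tables, images, configuration, provenance.

Cell tables are comma-separated UTF-8 CSV with a mandatory header and
optional ``# key: value`` provenance comment lines at the top (tool
version, seed, config hash). Images are 16-bit grayscale TIFF (8-bit PNG
accepted on read). Malformed rows are rejected with their line numbers
logged and reported on the returned table's ``attrs``.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__

log = logging.getLogger(__name__)

REQUIRED_CELL_COLUMNS = ("cell_id", "cruise", "station", "depth_m",
                         "morphotype", "L_um", "W_um", "curvature_class")


class SchemaError(ValueError):
    """A table is missing required columns or has the wrong types."""


def _metadata_lines(metadata: dict | None) -> str:
    meta = {"tool": f"prokmorph {__version__}"}
    meta.update(metadata or {})
    return "".join(f"# {k}: {v}\n" for k, v in meta.items())


def write_cell_table(df: pd.DataFrame, path, metadata: dict | None = None):
    """Write a cell table with provenance comment headers."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        fh.write(_metadata_lines(metadata))
        df.to_csv(fh, index=False)
    return path


def read_cell_table(path) -> pd.DataFrame:
    """Read and validate a cell table.

    Missing required columns raise :class:`SchemaError` naming them.
    Rows with non-numeric or non-positive dimensions, or W > L, are
    dropped; their 1-based file line numbers are logged and stored in
    ``df.attrs['rejected_lines']``.
    """
    path = Path(path)
    n_comments = 0
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                n_comments += 1
            else:
                break
    df = pd.read_csv(path, comment="#")
    missing = [c for c in REQUIRED_CELL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"cell table {path} missing column(s): {', '.join(missing)}")
    header_line = n_comments + 1
    lines = df.index.to_numpy() + header_line + 1  # 1-based data line numbers
    L = pd.to_numeric(df["L_um"], errors="coerce")
    W = pd.to_numeric(df["W_um"], errors="coerce")
    bad = L.isna() | W.isna() | (L <= 0) | (W <= 0) | (W > L)
    rejected = lines[bad.to_numpy()].tolist()
    if rejected:
        log.warning("rejected %d malformed row(s) at line(s) %s",
                    len(rejected), rejected)
    out = df.loc[~bad].copy()
    out["L_um"] = L[~bad]
    out["W_um"] = W[~bad]
    out.attrs["rejected_lines"] = rejected
    return out.reset_index(drop=True)


def write_image(image: np.ndarray, path):
    """Write a grayscale image: 16-bit TIFF or 8-bit PNG by extension."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile
        tifffile.imwrite(path, np.asarray(image, dtype=np.uint16))
    elif path.suffix.lower() == ".png":
        import imageio.v3 as iio
        img = np.asarray(image)
        if img.dtype != np.uint8:
            img = (img / max(img.max(), 1) * 255).astype(np.uint8)
        iio.imwrite(path, img)
    else:
        raise ValueError(f"unsupported image format {path.suffix!r}")
    return path


def read_image(path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile
        return tifffile.imread(path)
    import imageio.v3 as iio
    img = iio.imread(path)
    if img.ndim == 3:
        img = img[..., 0]
    return img


def write_json(obj, path, metadata: dict | None = None):
    meta = {"tool": f"prokmorph {__version__}"}
    meta.update(metadata or {})
    payload = {"_meta": meta}
    payload.update(obj)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=_json_default)
        fh.write("\n")
    return Path(path)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON-serialisable: {type(o)}")


def config_hash(obj) -> str:
    """Stable short hash of a JSON-serialisable configuration."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
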