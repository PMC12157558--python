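"""File formats: multi-channel TIFF images with embedded pixel-size
metadata, and schema-versioned CSV tables.

Tables are plain CSV with a single header comment line of the form
``# centroscreen-table v1 kind=<kind>``; numeric fields round-trip at full
precision (shortest-repr floats) and missing values are written as empty
fields. Images are multi-page TIFFs whose description tag carries a JSON
blob with the pixel size and channel names; when the metadata pixel size
conflicts with the caller's configuration, the metadata wins and a notice is
logged.
"""

from __future__ import annotations

import io as _io
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

log = logging.getLogger(__name__)

TABLE_MAGIC = "# centroscreen-table"
TABLE_VERSION = 1

__all__ = ["write_table", "read_table", "write_image", "read_image"]


def write_table(df: pd.DataFrame, path, kind: str) -> None:
    """Write a table as schema-versioned CSV (missing values -> empty)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    buf = _io.StringIO()
    buf.write(f"{TABLE_MAGIC} v{TABLE_VERSION} kind={kind}\n")
    df.to_csv(buf, index=False)
    path.write_text(buf.getvalue())


def read_table(path, expect_kind: str | None = None) -> pd.DataFrame:
    """Read a schema-versioned CSV, checking magic, version and kind."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header.startswith(TABLE_MAGIC):
            raise ValueError(f"{path}: not a centroscreen table")
        fields = header[len(TABLE_MAGIC):].split()
        version = int(fields[0].lstrip("v"))
        if version != TABLE_VERSION:
            raise ValueError(
                f"{path}: schema version {version} != expected "
                f"{TABLE_VERSION}")
        kind = dict(f.split("=", 1) for f in fields[1:]).get("kind")
        if expect_kind is not None and kind != expect_kind:
            raise ValueError(
                f"{path}: table kind {kind!r} != expected {expect_kind!r}")
        df = pd.read_csv(fh)
    df.attrs["kind"] = kind
    return df


def write_image(path, image: np.ndarray, pixel_size_um: float,
                channels: list[str]) -> None:
    """Write a (C, Y, X) stack as a multi-page TIFF with JSON metadata."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arr = np.asarray(image)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.shape[0] != len(channels):
        raise ValueError(
            f"{path}: {arr.shape[0]} pages but {len(channels)} channel "
            "names")
    meta = {"pixel_size_um": pixel_size_um, "channels": list(channels)}
    tifffile.imwrite(path, arr, description=json.dumps(meta))


def read_image(path, config_pixel_size_um: float | None = None,
               ) -> tuple[np.ndarray, dict]:
    """Read a multi-page TIFF written by :func:`write_image`.

    Returns (array, metadata). Embedded pixel-size metadata overrides
    ``config_pixel_size_um`` on conflict, with a logged notice; when no
    metadata is present the config value is used.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        arr = tf.asarray()
        desc = tf.pages[0].description
    meta: dict = {}
    if desc:
        try:
            meta = json.loads(desc)
        except (json.JSONDecodeError, TypeError):
            meta = {}
    px_meta = meta.get("pixel_size_um")
    if px_meta is not None and config_pixel_size_um is not None \
            and abs(px_meta - config_pixel_size_um) > 1e-12:
        log.warning(
            "%s: metadata pixel size %.6f um overrides configured %.6f um",
            path, px_meta, config_pixel_size_um)
    meta["pixel_size_um"] = (px_meta if px_meta is not None
                             else config_pixel_size_um)
    if arr.ndim == 2:
        arr = arr[None]
    return arr, meta
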