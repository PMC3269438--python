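"""File I/O: 16-bit TIFF images, spot-center tables, results TSV + manifest.

Center tables are CSV with columns ``spot_id, x, y`` in pixel units (an
optional ``block`` column is carried through).  GenePix-style results tables
that store centers in microns are handled by passing ``microns_per_pixel``;
scanner resolution is metadata the file itself may lack, so it is an explicit
configuration scalar, never guessed.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .grid import GridSpec
from .quantify import SpotQuantification

__all__ = ["read_image", "read_centers", "write_results", "read_results",
           "RESULT_COLUMNS"]

RESULT_COLUMNS = ["spot_id", "K", "bg", "fg", "corrected", "n_pixels", "n_fg",
                  "n_intermediate", "n_saturated", "fg_empirical_median", "flags"]

_GENEPIX_COLS = {"X": "x", "Y": "y", "Name": "spot_id", "ID": "spot_id"}


def read_image(path) -> np.ndarray:
    """Read a single-channel grayscale TIFF of at most 16-bit unsigned depth."""
    arr = tifffile.imread(str(path))
    if arr.ndim == 3 and arr.shape[0] == 1:
        arr = arr[0]
    if arr.ndim != 2:
        raise ValueError(f"expected a single-channel image, got shape {arr.shape}")
    if arr.dtype not in (np.uint8, np.uint16):
        raise ValueError(f"expected unsigned <=16-bit pixel depth, got {arr.dtype}")
    return arr


def read_centers(path, image_shape: tuple[int, int], pitch: float | None = None,
                 grid_type: str = "hex", microns_per_pixel: float = 1.0) -> GridSpec:
    """Read a spot-center table and assemble a :class:`GridSpec`.

    Requires columns ``spot_id, x, y`` (GenePix-style ``Name/ID, X, Y``
    accepted, converted by ``microns_per_pixel``).  When ``pitch`` is omitted
    it is estimated as the median nearest-neighbor center distance.
    """
    df = pd.read_csv(path)
    if not {"spot_id", "x", "y"}.issubset(df.columns):
        renamed = df.rename(columns=_GENEPIX_COLS)
        if {"spot_id", "x", "y"}.issubset(renamed.columns):
            df = renamed
            df["x"] = df["x"] / microns_per_pixel
            df["y"] = df["y"] / microns_per_pixel
        else:
            raise ValueError(
                f"centers file must have columns spot_id, x, y; got {list(df.columns)}")
    centers = df[["x", "y"]].to_numpy(dtype=float)
    if pitch is None:
        if len(centers) < 2:
            raise ValueError("cannot estimate pitch from a single center")
        from scipy.spatial import cKDTree
        d, _ = cKDTree(centers).query(centers, k=2)
        pitch = float(np.median(d[:, 1]))
    grid = GridSpec(grid_type=grid_type, centers=centers, pitch=pitch,
                    image_shape=image_shape)
    object.__setattr__(grid, "spot_ids", df["spot_id"].astype(str).tolist())
    return grid


def _quant_row(q: SpotQuantification) -> dict:
    set_flags = sorted(k for k, v in q.flags.items() if v)
    return {
        "spot_id": q.spot_id,
        "K": q.K_selected,
        "bg": q.bg_intensity,
        "fg": q.fg_intensity,
        "corrected": q.corrected_intensity,
        "n_pixels": q.n_bg + q.n_intermediate + q.n_fg,
        "n_fg": q.n_fg,
        "n_intermediate": q.n_intermediate,
        "n_saturated": q.n_saturated,
        "fg_empirical_median": q.fg_empirical_median,
        "flags": ";".join(set_flags) if set_flags else "",
    }


def write_results(path, rows, manifest: dict | None = None) -> None:
    """Write spot quantifications as TSV plus a JSON run manifest.

    ``rows`` may be :class:`SpotQuantification` objects or plain dicts using
    the same schema.  Missing intensities (blank spots) are written as NA.
    The manifest (parameters, version, seed) goes to ``<path>.manifest.json``.
    """
    path = Path(path)
    recs = [_quant_row(r) if isinstance(r, SpotQuantification) else dict(r)
            for r in rows]
    df = pd.DataFrame(recs, columns=RESULT_COLUMNS)
    df.to_csv(path, sep="\t", index=False, na_rep="NA")
    if manifest is not None:
        with open(path.with_name(path.name + ".manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)


def read_results(path) -> pd.DataFrame:
    """Read back a results TSV written by :func:`write_results`."""
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    df["flags"] = df["flags"].fillna("")
    return df
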