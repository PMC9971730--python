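"""Dataset-manifest and image I/O.

A manifest is a plain CSV with header ``reference,distorted,length,angle,mos``
— one row per (reference, distorted) pair with the blur parameters that
produced the distortion and, once a subjective study (real or synthetic) has
been run, the mean opinion score.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

__all__ = ["MANIFEST_COLUMNS", "read_manifest", "write_manifest", "load_image"]

MANIFEST_COLUMNS = ["reference", "distorted", "length", "angle", "mos"]


class ManifestError(ValueError):
    """Raised for malformed manifest files; messages carry line numbers."""


def read_manifest(path: str | os.PathLike) -> pd.DataFrame:
    """Read and validate a manifest CSV.

    Rows must parse as (str, str, int >= 1, float, optional float in [1,5]);
    malformed rows are rejected with their 1-based file line number.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ManifestError(f"{path}: missing manifest columns {missing}")
    df = df[MANIFEST_COLUMNS]

    out = {c: [] for c in MANIFEST_COLUMNS}
    for idx, row in df.iterrows():
        line = idx + 2  # header is line 1
        ref, dist = row["reference"].strip(), row["distorted"].strip()
        if not ref or not dist:
            raise ManifestError(f"{path}: line {line}: empty image path")
        try:
            length = int(float(row["length"]))
            if length < 1:
                raise ValueError
        except ValueError:
            raise ManifestError(
                f"{path}: line {line}: invalid blur length {row['length']!r}"
            ) from None
        try:
            angle = float(row["angle"])
        except ValueError:
            raise ManifestError(
                f"{path}: line {line}: invalid blur angle {row['angle']!r}"
            ) from None
        mos_raw = row["mos"].strip()
        if mos_raw == "":
            mos = np.nan
        else:
            try:
                mos = float(mos_raw)
            except ValueError:
                raise ManifestError(
                    f"{path}: line {line}: invalid mos {row['mos']!r}"
                ) from None
            if not 1.0 <= mos <= 5.0:
                raise ManifestError(
                    f"{path}: line {line}: mos {mos} outside [1, 5]"
                )
        out["reference"].append(ref)
        out["distorted"].append(dist)
        out["length"].append(length)
        out["angle"].append(angle)
        out["mos"].append(mos)
    return pd.DataFrame(out, columns=MANIFEST_COLUMNS)


def write_manifest(manifest: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a normalized manifest CSV (stable column order, LF endings).

    Missing MOS values are serialized as empty fields, never ``nan``.
    """
    df = manifest.copy()
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ManifestError(f"manifest is missing columns {missing}")
    df = df[MANIFEST_COLUMNS]
    with open(path, "w", newline="\n") as fh:
        df.to_csv(fh, index=False, na_rep="", lineterminator="\n")


def load_image(path: str | os.PathLike) -> np.ndarray:
    """Load a raster image as float64 on [0, 255] (grayscale or RGB)."""
    import imageio.v3 as iio

    try:
        arr = iio.imread(path)
    except Exception as exc:
        raise IOError(f"cannot read image {os.fspath(path)!r}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[..., :3]  # drop alpha
    return arr.astype(np.float64)
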