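"""Readers/writers for the formats the pipeline exchanges.

NIfTI via nibabel; expression matrices and metadata as TSV; gene sets as GMT;
truth/config/summary as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .alff import TimeSeriesImage

__all__ = [
    "save_nifti",
    "load_nifti_map",
    "load_timeseries",
    "save_timeseries",
    "write_tsv",
    "read_tsv",
    "write_gmt",
    "read_gmt",
    "write_json",
    "read_json",
]


def save_nifti(data: np.ndarray, affine: np.ndarray, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float64), affine), str(path))


def load_nifti_map(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.get_fdata()), img.affine


def save_timeseries(ts: TimeSeriesImage, path: str | Path) -> None:
    img = nib.Nifti1Image(ts.data, ts.affine)
    img.header.set_zooms((*img.header.get_zooms()[:3], ts.tr))
    nib.save(img, str(path))


def load_timeseries(path: str | Path, tr: float | None = None,
                    mask: np.ndarray | None = None) -> TimeSeriesImage:
    img = nib.load(str(path))
    if tr is None:
        tr = float(img.header.get_zooms()[3])
    return TimeSeriesImage(np.asarray(img.get_fdata()), img.affine, tr, mask)


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_tsv(path: str | Path, index_col: int | None = 0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_gmt(gene_sets: dict[str, set[str]], path: str | Path,
              description: str = "na") -> None:
    with open(path, "w") as fh:
        for name in sorted(gene_sets):
            genes = "\t".join(sorted(gene_sets[name]))
            fh.write(f"{name}\t{description}\t{genes}\n")


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    out: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2 or not parts[0]:
                continue
            out[parts[0]] = set(g for g in parts[2:] if g)
    return out


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, set):
        return sorted(obj)
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_jsonable)
        fh.write("\n")


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)
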