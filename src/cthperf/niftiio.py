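"""NIfTI and CSV plumbing shared by the command-line stages."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .deconv import Aif, ConfigurationError


def write_volume(data, affine, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float64), np.asarray(affine))
    nib.save(img, str(path))
    return path


def read_volume(path: str | Path):
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"missing NIfTI input: {path}")
    try:
        img = nib.load(str(path))
        return np.asanyarray(img.dataobj), img.affine
    except Exception as e:  # corrupt header etc.
        raise ConfigurationError(f"could not read NIfTI file {path}: {e}") from e


def write_aif_csv(aif: Aif, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"time_s": aif.times, "conc": aif.conc}).to_csv(path, index=False)
    return path


def read_aif_csv(path: str | Path) -> Aif:
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"missing AIF table: {path}")
    df = pd.read_csv(path)
    for col in ("time_s", "conc"):
        if col not in df.columns:
            raise ConfigurationError(f"AIF table {path} lacks required column {col!r}")
    return Aif(times=df["time_s"].to_numpy(float), conc=df["conc"].to_numpy(float))


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(path: str | Path, payload: dict) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as f:
        json.dump(payload, f, indent=2, sort_keys=True, default=str)
    return path
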