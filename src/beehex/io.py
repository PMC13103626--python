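"""CSV input/output with provenance headers.

Every file the pipeline writes starts with ``# key: value`` comment lines
recording at minimum the seed, the config hash, the excitation mode and
the discrimination threshold, so any output can be traced back to the
run that produced it.  Readers skip comment lines transparently.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .spectra import Spectrum

__all__ = [
    "config_hash",
    "write_csv",
    "read_csv",
    "read_header",
    "spectra_from_long",
    "spectra_to_long",
]

SPECTRA_COLUMNS = ("sample_id", "flower_id", "target", "wavelength_nm", "reflectance")


def config_hash(obj) -> str:
    """Stable short hash of any JSON-serializable configuration object."""
    text = json.dumps(obj, sort_keys=True, default=str)
    return hashlib.sha256(text.encode()).hexdigest()[:12]


def write_csv(df: pd.DataFrame, path: "str | Path", header: Mapping | None = None) -> Path:
    """Write a dataframe with ``# key: value`` provenance comment lines."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for key, value in (header or {}).items():
            fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, index=False)
    return path


def read_csv(path: "str | Path", **kwargs) -> pd.DataFrame:
    """Read a CSV, skipping provenance comment lines."""
    return pd.read_csv(path, comment="#", **kwargs)


def read_header(path: "str | Path") -> dict:
    """Parse the leading ``# key: value`` lines of a pipeline CSV."""
    out: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if ":" in body:
                key, value = body.split(":", 1)
                out[key.strip()] = value.strip()
    return out


def spectra_from_long(df: pd.DataFrame) -> "list[Spectrum]":
    """Build Spectrum objects from a long-format table.

    Required columns: sample_id, flower_id, target, wavelength_nm,
    reflectance.  A ``unit`` column (``fraction`` or ``percent``) must be
    present; percent values are divided by 100 — the unit is never
    guessed from magnitudes.  An optional ``morph`` column is carried
    into the metadata.
    """
    missing = set(SPECTRA_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"spectra table missing columns: {sorted(missing)}")
    if "unit" not in df.columns:
        raise ValueError(
            "spectra table must declare a 'unit' column (fraction|percent)"
        )
    bad = set(df["unit"].unique()) - {"fraction", "percent"}
    if bad:
        raise ValueError(f"unknown reflectance units: {sorted(bad)}")
    bad_target = set(df["target"].unique()) - {"petal", "spot"}
    if bad_target:
        raise ValueError(f"unknown target labels: {sorted(bad_target)}")

    specs = []
    for (sample, flower, target), grp in df.groupby(
        ["sample_id", "flower_id", "target"], sort=True
    ):
        grp = grp.sort_values("wavelength_nm")
        vals = grp["reflectance"].to_numpy(dtype=float)
        vals = np.where(grp["unit"].to_numpy() == "percent", vals / 100.0, vals)
        meta = {"sample_id": sample, "flower_id": flower, "target": target}
        if "morph" in grp.columns:
            meta["morph"] = grp["morph"].iloc[0]
        specs.append(Spectrum(grp["wavelength_nm"].to_numpy(dtype=float), vals, meta))
    return specs


def spectra_to_long(spectra: Iterable[Spectrum]) -> pd.DataFrame:
    """Inverse of :func:`spectra_from_long`; always writes fractions."""
    frames = []
    for i, spec in enumerate(spectra, start=1):
        meta = dict(spec.meta)
        frames.append(
            pd.DataFrame(
                {
                    "sample_id": meta.get("sample_id", f"S{i:04d}"),
                    "flower_id": meta.get("flower_id", f"F{i:04d}"),
                    "target": meta.get("target", "petal"),
                    "morph": meta.get("morph", ""),
                    "wavelength_nm": spec.wavelengths,
                    "reflectance": spec.values,
                    "unit": "fraction",
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
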