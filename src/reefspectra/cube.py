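"""Hyperspectral cube container and ENVI-style BIL file I/O."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional

import numpy as np

__all__ = ["HyperspectralCube", "write_envi", "read_envi"]


@dataclass
class HyperspectralCube:
    """A push-broom scan: lines (along-track) x samples (cross-track) x bands.

    ``radiance`` holds at-sensor radiance in arbitrary linear units until
    plate normalization converts it to estimated reflectance.
    """

    radiance: np.ndarray
    wavelengths_nm: np.ndarray
    plate_mask: np.ndarray
    provenance: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.radiance = np.asarray(self.radiance, dtype=np.float32)
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        self.plate_mask = np.asarray(self.plate_mask, dtype=bool)
        if self.radiance.ndim != 3:
            raise ValueError("radiance must be lines x samples x bands")
        if self.radiance.shape[2] != len(self.wavelengths_nm):
            raise ValueError(
                f"band axis ({self.radiance.shape[2]}) must match wavelength "
                f"vector ({len(self.wavelengths_nm)})"
            )
        if self.plate_mask.shape != self.radiance.shape[:2]:
            raise ValueError("plate_mask shape must match spatial shape")
        if np.any(np.diff(self.wavelengths_nm) <= 0):
            raise ValueError("wavelengths must be strictly increasing")

    @property
    def shape(self) -> tuple:
        return self.radiance.shape

    @property
    def n_bands(self) -> int:
        return self.radiance.shape[2]

    def copy(self) -> "HyperspectralCube":
        return HyperspectralCube(
            self.radiance.copy(),
            self.wavelengths_nm.copy(),
            self.plate_mask.copy(),
            list(self.provenance),
        )

    def log(self, step: str) -> None:
        self.provenance.append(step)


def write_envi(cube: HyperspectralCube, path: str | Path) -> Path:
    """Write a cube as raw BIL binary with an ENVI text header.

    ``path`` is the data-file path; ``<path>.hdr`` and a JSON sidecar
    (plate mask extent + provenance) are written next to it.
    """
    path = Path(path)
    lines, samples, bands = cube.radiance.shape
    # BIL: per line, band-major, samples within band
    bil = np.ascontiguousarray(np.transpose(cube.radiance, (0, 2, 1)), dtype="<f4")
    bil.tofile(path)
    wl = ", ".join(f"{w:.4f}" for w in cube.wavelengths_nm)
    hdr = (
        "ENVI\n"
        "description = {reefspectra simulated push-broom scan}\n"
        f"samples = {samples}\n"
        f"lines = {lines}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        "data type = 4\n"
        "interleave = bil\n"
        "byte order = 0\n"
        "wavelength units = Nanometers\n"
        "wavelength = {" + wl + "}\n"
    )
    Path(str(path) + ".hdr").write_text(hdr)
    sidecar = {
        "plate_rows": _mask_extent(cube.plate_mask, axis=0),
        "plate_cols": _mask_extent(cube.plate_mask, axis=1),
        "provenance": cube.provenance,
    }
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1))
    return path


def read_envi(path: str | Path) -> HyperspectralCube:
    """Read a BIL cube written by :func:`write_envi`."""
    path = Path(path)
    hdr_path = Path(str(path) + ".hdr")
    if not hdr_path.exists():
        raise FileNotFoundError(f"missing ENVI header {hdr_path}")
    fields = _parse_envi_header(hdr_path.read_text())
    lines = int(fields["lines"])
    samples = int(fields["samples"])
    bands = int(fields["bands"])
    if fields.get("interleave", "bil").lower() != "bil":
        raise ValueError("only BIL interleave is supported")
    if int(fields.get("data type", 4)) != 4:
        raise ValueError("only float32 (data type 4) is supported")
    raw = np.fromfile(path, dtype="<f4", count=lines * samples * bands)
    if raw.size != lines * samples * bands:
        raise ValueError("data file size does not match header dimensions")
    radiance = np.transpose(raw.reshape(lines, bands, samples), (0, 2, 1))
    wavelengths = np.array(
        [float(x) for x in fields["wavelength"].split(",")], dtype=float
    )
    plate_mask = np.zeros((lines, samples), dtype=bool)
    provenance: List[str] = []
    sidecar_path = Path(str(path) + ".json")
    if sidecar_path.exists():
        sidecar = json.loads(sidecar_path.read_text())
        pr, pc = sidecar.get("plate_rows"), sidecar.get("plate_cols")
        if pr is not None and pc is not None:
            plate_mask[pr[0] : pr[1], pc[0] : pc[1]] = True
        provenance = list(sidecar.get("provenance", []))
    return HyperspectralCube(radiance, wavelengths, plate_mask, provenance)


def _mask_extent(mask: np.ndarray, axis: int) -> Optional[list]:
    idx = np.where(mask.any(axis=1 - axis))[0]
    if idx.size == 0:
        return None
    return [int(idx[0]), int(idx[-1] + 1)]


def _parse_envi_header(text: str) -> dict:
    fields: dict = {}
    key, buf, in_braces = None, [], False
    for line in text.splitlines():
        if not in_braces:
            if "=" not in line:
                continue
            key, _, value = line.partition("=")
            key = key.strip().lower()
            value = value.strip()
            if value.startswith("{") and not value.endswith("}"):
                in_braces, buf = True, [value[1:]]
            elif value.startswith("{"):
                fields[key] = value[1:-1].strip()
            else:
                fields[key] = value
        else:
            if line.strip().endswith("}"):
                buf.append(line.strip()[:-1])
                fields[key] = " ".join(buf).strip()
                in_braces = False
            else:
                buf.append(line.strip())
    return fields
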