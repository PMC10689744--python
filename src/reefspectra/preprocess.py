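"""Hyperspectral preprocessing: spectral smoothing, low-signal band
removal, and normalization against the in-scene grey reference plate.

The intended order is smooth -> drop -> normalize (see
:func:`preprocess_cube`); each step appends to the cube's provenance log.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from scipy.signal import savgol_filter

from .cube import HyperspectralCube

__all__ = [
    "smooth_spectra",
    "drop_low_signal_bands",
    "relative_signal_threshold",
    "normalize_to_plate",
    "plate_spectrum",
    "preprocess_cube",
]

MIN_SURVIVING_BANDS = 5


def smooth_spectra(
    cube: HyperspectralCube, window: int = 7, polyorder: int = 2
) -> HyperspectralCube:
    """Savitzky-Golay smoothing along the spectral axis of every pixel.

    Polynomial-preserving for degree <= ``polyorder``; spatial axes are
    untouched, so no information leaks between pixels.
    """
    if window % 2 == 0:
        raise ValueError(f"window must be odd, got {window}")
    if window <= polyorder:
        raise ValueError(f"window ({window}) must exceed polyorder ({polyorder})")
    if window > cube.n_bands:
        raise ValueError(f"window ({window}) exceeds band count ({cube.n_bands})")
    sm = savgol_filter(cube.radiance.astype(np.float64), window, polyorder, axis=2)
    out = HyperspectralCube(
        sm.astype(np.float32),
        cube.wavelengths_nm.copy(),
        cube.plate_mask.copy(),
        list(cube.provenance),
    )
    out.log(f"smooth_spectra: savgol window={window} polyorder={polyorder}")
    return out


def relative_signal_threshold(cube: HyperspectralCube, fraction: float = 0.02) -> float:
    """Low-signal threshold relative to the scene's well-lit bands.

    Returns ``fraction`` times the 95th percentile of the per-band
    scene-wide median radiance, the default criterion for culling
    water-absorbed red/NIR bands.
    """
    band_medians = np.median(cube.radiance.reshape(-1, cube.n_bands), axis=0)
    return float(fraction * np.percentile(band_medians, 95))


def drop_low_signal_bands(
    cube: HyperspectralCube, min_median_signal: float
) -> HyperspectralCube:
    """Remove bands whose scene-wide median radiance falls below threshold."""
    if min_median_signal < 0:
        raise ValueError("min_median_signal must be >= 0")
    band_medians = np.median(cube.radiance.reshape(-1, cube.n_bands), axis=0)
    keep = band_medians >= min_median_signal
    n_keep = int(keep.sum())
    if n_keep < MIN_SURVIVING_BANDS:
        raise ValueError(
            f"only {n_keep} bands have median signal >= {min_median_signal}; "
            f"at least {MIN_SURVIVING_BANDS} must survive"
        )
    out = HyperspectralCube(
        cube.radiance[:, :, keep],
        cube.wavelengths_nm[keep],
        cube.plate_mask.copy(),
        list(cube.provenance),
    )
    out.log(
        f"drop_low_signal_bands: threshold={min_median_signal:.6g}, "
        f"kept {n_keep}/{cube.n_bands} bands"
    )
    return out


def plate_spectrum(cube: HyperspectralCube, statistic: str = "mean") -> np.ndarray:
    """Per-band plate signal estimated over the plate-mask pixels."""
    if not cube.plate_mask.any():
        raise ValueError("cube has no reference plate pixels (empty plate mask)")
    px = cube.radiance[cube.plate_mask]
    if statistic == "mean":
        return px.mean(axis=0).astype(np.float64)
    if statistic == "median":
        return np.median(px, axis=0).astype(np.float64)
    raise ValueError(f"unknown plate statistic {statistic!r}")


def normalize_to_plate(
    cube: HyperspectralCube,
    plate_reflectance: np.ndarray,
    statistic: str = "mean",
) -> HyperspectralCube:
    """Convert radiance to estimated reflectance via the grey plate.

    Each pixel spectrum is divided band-wise by
    (observed plate spectrum / known plate reflectance), cancelling the
    incident-light term; plate pixels map back to ~plate_reflectance.
    """
    plate_reflectance = np.asarray(plate_reflectance, dtype=float)
    if plate_reflectance.shape != (cube.n_bands,):
        raise ValueError("plate reflectance must be on the cube's band grid")
    observed = plate_spectrum(cube, statistic=statistic)
    if np.any(observed <= 0):
        band = int(np.argmax(observed <= 0))
        raise ZeroDivisionError(
            f"plate signal is zero at band {band} "
            f"({cube.wavelengths_nm[band]:.1f} nm); cannot normalize"
        )
    factor = (observed / plate_reflectance).astype(np.float32)
    out = HyperspectralCube(
        cube.radiance / factor[None, None, :],
        cube.wavelengths_nm.copy(),
        cube.plate_mask.copy(),
        list(cube.provenance),
    )
    out.log(f"normalize_to_plate: statistic={statistic}")
    return out


def preprocess_cube(
    cube: HyperspectralCube,
    plate_reflectance: np.ndarray,
    window: int = 7,
    polyorder: int = 2,
    signal_fraction: float = 0.02,
    min_median_signal: Optional[float] = None,
) -> HyperspectralCube:
    """Full chain: smooth -> drop low-signal bands -> plate-normalize.

    Returns the reflectance cube on the retained band grid; the plate
    reflectance is subset to the surviving bands automatically.
    """
    sm = smooth_spectra(cube, window=window, polyorder=polyorder)
    if min_median_signal is None:
        min_median_signal = relative_signal_threshold(sm, signal_fraction)
    dropped = drop_low_signal_bands(sm, min_median_signal)
    keep_idx = np.searchsorted(cube.wavelengths_nm, dropped.wavelengths_nm)
    plate_ref = np.asarray(plate_reflectance, dtype=float)[keep_idx]
    return normalize_to_plate(dropped, plate_ref)
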