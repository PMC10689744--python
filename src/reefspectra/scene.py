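"""Synthetic benthic scenes and push-broom hyperspectral rendering.

Stands in for field data: generates patchy multi-category benthic class
maps for 50 m x ~1 m transect swaths, then renders them line-by-line into
hyperspectral cubes through a simple forward optical model — lamp
illumination, per-category reflectance, multiplicative shading, two-way
Beer-Lambert water attenuation over the camera-to-bottom path, and sensor
noise. A matte grey reference plate is placed at the start of every
transect, mirroring field practice.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .cube import HyperspectralCube

__all__ = [
    "SpectralLibrary",
    "ReefScene",
    "OpticsConfig",
    "default_wavelengths",
    "demo_library",
    "default_optics",
    "generate_scene",
    "render_cube",
    "make_site",
    "derive_transect_plan",
    "scene_dims",
]


def default_wavelengths(
    start_nm: float = 400.0, stop_nm: float = 750.0, step_nm: float = 2.9
) -> np.ndarray:
    """Default VIS wavelength grid: 400-750 nm at 2.9 nm (121 bands)."""
    n = int(np.floor((stop_nm - start_nm) / step_nm)) + 1
    return start_nm + step_nm * np.arange(n)


@dataclass
class SpectralLibrary:
    """Endmember reflectance spectra on a shared wavelength grid."""

    wavelengths_nm: np.ndarray
    endmembers: Dict[int, np.ndarray]
    plate_reflectance: np.ndarray

    def __post_init__(self) -> None:
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        if np.any(np.diff(self.wavelengths_nm) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if len(self.endmembers) < 2:
            raise ValueError("library needs at least 2 categories")
        nb = len(self.wavelengths_nm)
        for cat, spec in self.endmembers.items():
            spec = np.asarray(spec, dtype=float)
            if spec.shape != (nb,):
                raise ValueError(f"endmember {cat} not on the wavelength grid")
            if spec.min() < 0 or spec.max() > 1:
                raise ValueError(f"endmember {cat} reflectance outside [0, 1]")
            self.endmembers[cat] = spec
        self.plate_reflectance = np.asarray(self.plate_reflectance, dtype=float)
        if self.plate_reflectance.shape != (nb,):
            raise ValueError("plate reflectance not on the wavelength grid")
        if self.plate_reflectance.min() < 0 or self.plate_reflectance.max() > 1:
            raise ValueError("plate reflectance outside [0, 1]")

    @property
    def categories(self) -> List[int]:
        return sorted(self.endmembers)

    def endmember_matrix(self, categories: Optional[Sequence[int]] = None) -> np.ndarray:
        cats = list(categories) if categories is not None else self.categories
        return np.stack([self.endmembers[c] for c in cats])


def demo_library(
    categories: Sequence[int],
    wavelengths_nm: Optional[np.ndarray] = None,
    seed: int = 7,
) -> SpectralLibrary:
    """Deterministic synthetic endmember library.

    Each category reflectance is a smooth baseline plus 2-3 Gaussian
    features with category-specific centers, loosely imitating pigment
    absorption/reflectance structure. Spectra are distinct by construction
    (peak positions are spread over the grid per category index), except
    that for libraries of 4+ categories the last two share a spectral
    shape and differ only in albedo — emulating pairs like turf algae over
    pavement vs. bare pavement, which angle-based classification cannot
    separate but a magnitude-aware classifier can.
    """
    wl = default_wavelengths() if wavelengths_nm is None else np.asarray(wavelengths_nm)
    rng = np.random.default_rng(seed)
    endmembers: Dict[int, np.ndarray] = {}
    span = wl[-1] - wl[0]
    for idx, cat in enumerate(sorted(categories)):
        base = 0.08 + 0.10 * rng.uniform()
        spec = np.full(wl.shape, base)
        # one anchored peak per category keeps spectra pairwise separable
        center0 = wl[0] + span * (idx + 0.5) / len(categories)
        for p, center in enumerate([center0, wl[0] + span * rng.uniform()]):
            amp = (0.25 if p == 0 else 0.12) * (0.7 + 0.6 * rng.uniform())
            width = 25.0 + 40.0 * rng.uniform()
            spec = spec + amp * np.exp(-0.5 * ((wl - center) / width) ** 2)
        # gentle red-edge slope for the algae-like half of the ids
        if idx % 2:
            spec = spec + 0.08 * (wl - wl[0]) / span
        endmembers[int(cat)] = np.clip(spec, 0.0, 1.0)
    cats_sorted = sorted(endmembers)
    if len(cats_sorted) >= 4:
        dark, bright = cats_sorted[-2], cats_sorted[-1]
        endmembers[dark] = np.clip(0.55 * endmembers[bright], 0.0, 1.0)
    plate = np.full(wl.shape, 0.30) + 0.01 * (wl - wl.mean()) / span
    return SpectralLibrary(wl, endmembers, np.clip(plate, 0, 1))


@dataclass
class OpticsConfig:
    """Forward-model optics: lamp spectrum, water attenuation, noise."""

    illumination_spectrum: np.ndarray
    attenuation_k: np.ndarray  # 1/m, per band
    sensor_height_m: float = 1.0
    noise_sd_additive: float = 0.0
    noise_sd_multiplicative: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.illumination_spectrum = np.asarray(self.illumination_spectrum, dtype=float)
        self.attenuation_k = np.asarray(self.attenuation_k, dtype=float)
        if np.any(self.illumination_spectrum < 0):
            raise ValueError("illumination must be nonnegative")
        if np.any(self.attenuation_k < 0):
            raise ValueError("attenuation coefficients must be nonnegative")
        if self.sensor_height_m <= 0:
            raise ValueError("sensor height must be positive")
        if self.noise_sd_additive < 0 or self.noise_sd_multiplicative < 0:
            raise ValueError("noise parameters must be >= 0")


def default_optics(
    wavelengths_nm: np.ndarray,
    sensor_height_m: float = 1.0,
    noise_sd_additive: float = 0.002,
    noise_sd_multiplicative: float = 0.01,
    seed: int = 0,
) -> OpticsConfig:
    """Full-spectrum lamp with a water-like attenuation profile.

    Attenuation is small and flat in the blue-green and rises steeply
    toward red/NIR, so the longest wavelengths are rendered with very low
    signal (they are later culled by preprocessing).
    """
    wl = np.asarray(wavelengths_nm, dtype=float)
    illum = 0.85 + 0.15 * np.exp(-0.5 * ((wl - 560.0) / 130.0) ** 2)
    x = np.clip((wl - 400.0) / 350.0, 0.0, None)
    k = 0.02 + 2.6 * x**4  # 1/m; monotone nondecreasing toward NIR
    return OpticsConfig(
        illumination_spectrum=illum,
        attenuation_k=k,
        sensor_height_m=sensor_height_m,
        noise_sd_additive=noise_sd_additive,
        noise_sd_multiplicative=noise_sd_multiplicative,
        seed=seed,
    )


@dataclass
class ReefScene:
    """Ground-truth benthic map for one transect swath."""

    class_map: np.ndarray  # rows = along-transect lines, cols = cross-track
    pixel_size_m: float
    depth_map_m: np.ndarray
    shade_map: np.ndarray
    plate_mask: np.ndarray
    true_cover: Dict[int, float]

    def __post_init__(self) -> None:
        self.class_map = np.asarray(self.class_map, dtype=np.int32)
        self.depth_map_m = np.asarray(self.depth_map_m, dtype=float)
        self.shade_map = np.asarray(self.shade_map, dtype=float)
        self.plate_mask = np.asarray(self.plate_mask, dtype=bool)
        shp = self.class_map.shape
        for name, arr in [
            ("depth_map_m", self.depth_map_m),
            ("shade_map", self.shade_map),
            ("plate_mask", self.plate_mask),
        ]:
            if arr.shape != shp:
                raise ValueError(f"{name} shape {arr.shape} != class_map {shp}")
        if self.pixel_size_m <= 0:
            raise ValueError("pixel size must be positive")
        if np.any(self.depth_map_m < 0):
            raise ValueError("depths must be nonnegative")
        if np.any(self.shade_map <= 0) or np.any(self.shade_map > 1):
            raise ValueError("shade must lie in (0, 1]")
        total = sum(self.true_cover.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"true cover sums to {total}, expected 1")

    @property
    def shape(self) -> tuple:
        return self.class_map.shape

    @property
    def categories(self) -> List[int]:
        return sorted(self.true_cover)

    def realized_cover(self) -> Dict[int, float]:
        """Pixel-count cover fractions over non-plate pixels."""
        vals = self.class_map[~self.plate_mask]
        cats, counts = np.unique(vals, return_counts=True)
        return {int(c): float(n) / vals.size for c, n in zip(cats, counts)}


def scene_dims(
    length_m: float = 50.0, width_m: float = 1.0, pixel_size_m: float = 0.02
) -> Tuple[int, int]:
    """Raster dimensions (rows, cols) for a transect swath."""
    return int(round(length_m / pixel_size_m)), int(round(width_m / pixel_size_m))


def _smooth_unit_field(rng: np.random.Generator, shape, sigma_px: float) -> np.ndarray:
    f = rng.standard_normal(shape)
    if sigma_px > 0:
        f = ndimage.gaussian_filter(f, sigma=sigma_px, mode="reflect")
    sd = f.std()
    return f / sd if sd > 0 else f


def generate_scene(
    categories: Sequence[int],
    target_cover: Dict[int, float] | Sequence[float],
    patch_scale_m: float,
    dims: Tuple[int, int],
    pixel_size_m: float,
    seed: int,
    plate_size_m: float = 0.10,
    shade_strength: float = 0.0,
    shade_floor: float = 0.4,
    depth_mean_m: float = 9.0,
) -> ReefScene:
    """Generate a patchy ground-truth class map with controlled cover.

    Each category gets a smoothed Gaussian random field (correlation
    length ``patch_scale_m``); the per-pixel category is the argmax of the
    fields plus per-category offsets. Offsets are calibrated by a monotone
    iteration so the realized pixel fractions track ``target_cover``.
    """
    categories = [int(c) for c in categories]
    if len(categories) < 1:
        raise ValueError("need at least 1 category")
    if isinstance(target_cover, dict):
        cover = np.array([float(target_cover[c]) for c in categories])
    else:
        cover = np.asarray(target_cover, dtype=float)
        if len(cover) != len(categories):
            raise ValueError("target_cover length must match categories")
    if np.any(cover < 0):
        raise ValueError("cover fractions must be nonnegative")
    if abs(cover.sum() - 1.0) > 1e-9:
        raise ValueError(f"target cover sums to {cover.sum():.12f}, expected 1")
    rows, cols = dims
    if rows <= 0 or cols <= 0:
        raise ValueError("dims must be positive")
    if patch_scale_m <= 0:
        raise ValueError("patch_scale_m must be positive")

    rng = np.random.default_rng(seed)
    keep = cover > 0
    cats_used = [c for c, k in zip(categories, keep) if k]
    cov_used = cover[keep]
    cov_used = cov_used / cov_used.sum()

    if len(cats_used) == 1:
        class_map = np.full(dims, cats_used[0], dtype=np.int32)
    else:
        sigma_px = patch_scale_m / pixel_size_m
        fields = np.stack(
            [_smooth_unit_field(rng, dims, sigma_px) for _ in cats_used]
        )
        # monotone offset calibration: raising w_c can only grow category c
        w = np.zeros(len(cats_used))
        best_w, best_err = w.copy(), np.inf
        rate = 2.5
        for _ in range(80):
            class_idx = np.argmax(fields + w[:, None, None], axis=0)
            realized = np.bincount(class_idx.ravel(), minlength=len(cats_used)) / class_idx.size
            err = np.abs(realized - cov_used).max()
            if err < best_err:
                best_err, best_w = err, w.copy()
            if err < 1e-3:
                break
            w = w + rate * (cov_used - realized)
            w -= w.mean()
            rate *= 0.97
        class_idx = np.argmax(fields + best_w[:, None, None], axis=0)
        class_map = np.asarray(cats_used, dtype=np.int32)[class_idx]

    # grey reference plate: contiguous rectangle at the transect start
    plate_px = max(1, int(round(plate_size_m / pixel_size_m)))
    plate_px_r = min(plate_px, rows)
    plate_px_c = min(plate_px, cols)
    c0 = (cols - plate_px_c) // 2
    plate_mask = np.zeros(dims, dtype=bool)
    plate_mask[0:plate_px_r, c0 : c0 + plate_px_c] = True

    depth_map = depth_mean_m + 0.5 * _smooth_unit_field(rng, dims, 25.0)
    depth_map = np.clip(depth_map, 0.0, None)

    if shade_strength > 0:
        u = _smooth_unit_field(rng, dims, 8.0)
        u = (u - u.min()) / max(u.max() - u.min(), 1e-12)
        shade = 1.0 - shade_strength * u
        shade = np.clip(shade, shade_floor, 1.0)
    else:
        shade = np.ones(dims)

    vals = class_map[~plate_mask]
    cats_r, counts = np.unique(vals, return_counts=True)
    true_cover = {int(c): float(n) / vals.size for c, n in zip(cats_r, counts)}

    return ReefScene(
        class_map=class_map,
        pixel_size_m=pixel_size_m,
        depth_map_m=depth_map,
        shade_map=shade,
        plate_mask=plate_mask,
        true_cover=true_cover,
    )


def render_cube(
    scene: ReefScene, library: SpectralLibrary, optics: OpticsConfig
) -> HyperspectralCube:
    """Render a scene into an at-sensor radiance cube.

    radiance(x, lambda) = illumination(lambda) * rho(x, lambda) * shade(x)
    * exp(-k(lambda) * 2 * h) + noise, where rho is the category endmember
    (plate reflectance on plate pixels) and the factor 2h is the two-way
    lamp-to-bottom-to-sensor path of a camera-mounted light rig. Values
    are clipped at zero; deterministic given ``optics.seed``.
    """
    nb = len(library.wavelengths_nm)
    if len(optics.illumination_spectrum) != nb or len(optics.attenuation_k) != nb:
        raise ValueError("optics spectra must be on the library wavelength grid")
    missing = set(np.unique(scene.class_map).tolist()) - set(library.endmembers)
    if missing:
        raise LookupError(f"categories without endmember spectra: {sorted(missing)}")

    cats = sorted(library.endmembers)
    lut = np.full(max(cats) + 1, -1, dtype=int)
    for i, c in enumerate(cats):
        lut[c] = i
    em = library.endmember_matrix(cats).astype(np.float32)
    refl = em[lut[scene.class_map]]  # rows x cols x bands
    refl[scene.plate_mask] = library.plate_reflectance.astype(np.float32)

    atten = np.exp(-optics.attenuation_k * 2.0 * optics.sensor_height_m)
    signal = (
        refl
        * scene.shade_map[:, :, None].astype(np.float32)
        * (optics.illumination_spectrum * atten).astype(np.float32)[None, None, :]
    )

    rng = np.random.default_rng(optics.seed)
    if optics.noise_sd_multiplicative > 0:
        signal = signal * (
            1.0 + optics.noise_sd_multiplicative * rng.standard_normal(signal.shape)
        ).astype(np.float32)
    if optics.noise_sd_additive > 0:
        signal = signal + (
            optics.noise_sd_additive * rng.standard_normal(signal.shape)
        ).astype(np.float32)
    signal = np.clip(signal, 0.0, None)

    cube = HyperspectralCube(
        radiance=signal,
        wavelengths_nm=library.wavelengths_nm,
        plate_mask=scene.plate_mask,
        provenance=[
            f"render: h={optics.sensor_height_m} m, "
            f"noise=({optics.noise_sd_additive},{optics.noise_sd_multiplicative}), "
            f"seed={optics.seed}"
        ],
    )
    return cube


def derive_transect_plan(
    site_seed: int,
    n_transects: int,
    site_cover: Dict[int, float],
    concentration: Optional[float] = 200.0,
) -> List[dict]:
    """Deterministic per-transect parameters derived from a site seed.

    Per-transect cover is jittered around the site mean by a Dirichlet
    draw with the given concentration (``None`` disables jitter; larger
    values mean transects more alike). Returns one dict per transect with
    ``cover``, ``scene_seed`` and ``optics_seed``.
    """
    if n_transects < 1:
        raise ValueError("n_transects must be >= 1")
    cats = sorted(site_cover)
    mean = np.array([site_cover[c] for c in cats], dtype=float)
    if abs(mean.sum() - 1.0) > 1e-9:
        raise ValueError("site cover must sum to 1")
    ss = np.random.SeedSequence(site_seed)
    children = ss.spawn(n_transects)
    rng = np.random.default_rng(ss.spawn(n_transects + 1)[-1])
    plan = []
    for t in range(n_transects):
        state = children[t].generate_state(2)
        if concentration is None:
            cov = mean.copy()
        else:
            pos = mean > 0
            alpha = np.clip(concentration * mean[pos], 1e-3, None)
            draw = rng.dirichlet(alpha)
            cov = np.zeros_like(mean)
            cov[pos] = draw
        plan.append(
            {
                "cover": {c: float(v) for c, v in zip(cats, cov)},
                "scene_seed": int(state[0] % 2**31),
                "optics_seed": int(state[1] % 2**31),
            }
        )
    return plan


def make_site(
    n_transects: int,
    site_cover: Dict[int, float],
    library: SpectralLibrary,
    seed: int,
    transect_length_m: float = 50.0,
    swath_width_m: float = 1.0,
    pixel_size_m: float = 0.02,
    patch_scale_m: float = 0.3,
    concentration: Optional[float] = 200.0,
    shade_strength: float = 0.0,
    sensor_height_m: float = 1.0,
    noise_sd_additive: float = 0.002,
    noise_sd_multiplicative: float = 0.01,
    optics: Optional[OpticsConfig] = None,
) -> List[Tuple[ReefScene, HyperspectralCube]]:
    """Simulate one survey site: n transects drawn from shared site cover."""
    plan = derive_transect_plan(seed, n_transects, site_cover, concentration)
    dims = scene_dims(transect_length_m, swath_width_m, pixel_size_m)
    out = []
    for entry in plan:
        scene = generate_scene(
            categories=sorted(entry["cover"]),
            target_cover=entry["cover"],
            patch_scale_m=patch_scale_m,
            dims=dims,
            pixel_size_m=pixel_size_m,
            seed=entry["scene_seed"],
            shade_strength=shade_strength,
        )
        if optics is None:
            opt = default_optics(
                library.wavelengths_nm,
                sensor_height_m=sensor_height_m,
                noise_sd_additive=noise_sd_additive,
                noise_sd_multiplicative=noise_sd_multiplicative,
                seed=entry["optics_seed"],
            )
        else:
            opt = OpticsConfig(
                illumination_spectrum=optics.illumination_spectrum,
                attenuation_k=optics.attenuation_k,
                sensor_height_m=optics.sensor_height_m,
                noise_sd_additive=optics.noise_sd_additive,
                noise_sd_multiplicative=optics.noise_sd_multiplicative,
                seed=entry["optics_seed"],
            )
        out.append((scene, render_cube(scene, library, opt)))
    return out
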