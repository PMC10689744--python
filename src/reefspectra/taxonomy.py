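"""Benthic category hierarchies and ROI annotation bookkeeping.

Benthic monitoring identifies organisms at fine resolution (genus/species
plus abiotic substrates), then aggregates to a high-resolution tier of
genera/species-complexes and a broad tier of ~10 taxonomic or functional
groups for rapid assessments. This module manages those fine -> high ->
broad mappings, samples training regions of interest (ROIs) from synthetic
ground truth, and splits labeled pixels 90/10 into train/validation sets.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .scene import ReefScene

__all__ = [
    "BROAD_GROUP_NAMES",
    "CategoryHierarchy",
    "Roi",
    "AnnotationSet",
    "load_hierarchy",
    "save_hierarchy",
    "demo_hierarchy",
    "sample_rois",
    "annotations_from_csv",
    "merge_annotations",
    "split_train_validation",
    "aggregate_cover_vector",
]

logger = logging.getLogger(__name__)

# The ten broad taxonomic/functional groups standard in rapid reef
# monitoring; the demo hierarchy labels its broad tier with a subset.
BROAD_GROUP_NAMES = [
    "Scleractinia",
    "Corallinophycidae",
    "Peyssonneliales",
    "other red macroalgae",
    "green macroalgae",
    "brown macroalgae",
    "Porifera",
    "octocorals/hydrozoans",
    "other benthic invertebrates",
    "turf algae/cyanobacteria/bare substrate",
]


@dataclass
class CategoryHierarchy:
    """Total maps from fine category ids to high and broad group labels."""

    fine_ids: List[int]
    to_high: Dict[int, str]
    to_broad: Dict[int, str]

    def __post_init__(self) -> None:
        self.fine_ids = [int(f) for f in self.fine_ids]
        if len(set(self.fine_ids)) != len(self.fine_ids):
            dupes = sorted({f for f in self.fine_ids if self.fine_ids.count(f) > 1})
            raise ValueError(f"duplicate fine ids: {dupes}")
        missing_high = [f for f in self.fine_ids if f not in self.to_high]
        missing_broad = [f for f in self.fine_ids if f not in self.to_broad]
        if missing_high or missing_broad:
            raise ValueError(
                f"unmapped fine ids: high={missing_high}, broad={missing_broad}"
            )
        # fine -> high -> broad must be a consistent composition: every
        # high group maps into exactly one broad group
        high_to_broad: Dict[str, str] = {}
        for f in self.fine_ids:
            h, b = self.to_high[f], self.to_broad[f]
            if h in high_to_broad and high_to_broad[h] != b:
                raise ValueError(
                    f"high group {h!r} maps to both {high_to_broad[h]!r} and {b!r}"
                )
            high_to_broad[h] = b

    @property
    def high_names(self) -> List[str]:
        return list(dict.fromkeys(self.to_high[f] for f in self.fine_ids))

    @property
    def broad_names(self) -> List[str]:
        return list(dict.fromkeys(self.to_broad[f] for f in self.fine_ids))

    def mapping(self, tier: str) -> Dict[int, str]:
        if tier == "high":
            return dict(self.to_high)
        if tier == "broad":
            return dict(self.to_broad)
        if tier == "fine":
            return {f: str(f) for f in self.fine_ids}
        raise ValueError(f"unknown tier {tier!r} (expected fine/high/broad)")


def load_hierarchy(path: str | Path) -> CategoryHierarchy:
    """Load a fine/high/broad mapping table from CSV."""
    df = pd.read_csv(path)
    required = {"fine", "high", "broad"}
    if not required.issubset(df.columns):
        raise ValueError(f"hierarchy table needs columns {sorted(required)}")
    missing = df.loc[df[["high", "broad"]].isna().any(axis=1), "fine"].tolist()
    if missing:
        raise ValueError(f"fine ids with missing mappings: {missing}")
    if df["fine"].duplicated().any():
        dupes = df.loc[df["fine"].duplicated(), "fine"].tolist()
        raise ValueError(f"duplicate fine ids in table: {dupes}")
    fine = df["fine"].astype(int).tolist()
    return CategoryHierarchy(
        fine_ids=fine,
        to_high=dict(zip(fine, df["high"].astype(str))),
        to_broad=dict(zip(fine, df["broad"].astype(str))),
    )


def save_hierarchy(h: CategoryHierarchy, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(
        {
            "fine": h.fine_ids,
            "high": [h.to_high[f] for f in h.fine_ids],
            "broad": [h.to_broad[f] for f in h.fine_ids],
        }
    ).to_csv(path, index=False)
    return path


def demo_hierarchy() -> CategoryHierarchy:
    """Demo taxonomy: 12 fine categories -> 8 high groups -> 5 broad groups."""
    rows = [
        # fine, high, broad
        (1, "massive Porites", "Scleractinia"),
        (2, "massive Porites", "Scleractinia"),
        (3, "Porites rus/monticulosa", "Scleractinia"),
        (4, "Leptoria phrygia", "Scleractinia"),
        (5, "coralline algae", "Corallinophycidae"),
        (6, "coralline algae", "Corallinophycidae"),
        (7, "Halimeda", "green macroalgae"),
        (8, "Halimeda", "green macroalgae"),
        (9, "sponges", "Porifera"),
        (10, "sponges", "Porifera"),
        (11, "turf algae/cyanobacteria", "turf algae/cyanobacteria/bare substrate"),
        (12, "pavement/bare substrate", "turf algae/cyanobacteria/bare substrate"),
    ]
    return CategoryHierarchy(
        fine_ids=[r[0] for r in rows],
        to_high={r[0]: r[1] for r in rows},
        to_broad={r[0]: r[2] for r in rows},
    )


# ---------------------------------------------------------------------------
# ROI annotation
# ---------------------------------------------------------------------------


@dataclass
class Roi:
    transect_id: str
    pixels: np.ndarray  # (n, 2) integer (row, col)
    category: int


@dataclass
class AnnotationSet:
    """Labeled pixels grouped into ROIs, optionally train/val split."""

    rois: List[Roi]
    # split: per-pixel boolean, aligned with pixel_table() rows; None before split
    train_flag: Optional[np.ndarray] = None

    def pixel_table(self) -> pd.DataFrame:
        """One row per labeled pixel: transect, row, col, category, roi index."""
        frames = []
        for i, roi in enumerate(self.rois):
            frames.append(
                pd.DataFrame(
                    {
                        "transect": roi.transect_id,
                        "row": roi.pixels[:, 0],
                        "col": roi.pixels[:, 1],
                        "category": roi.category,
                        "roi": i,
                    }
                )
            )
        if not frames:
            return pd.DataFrame(columns=["transect", "row", "col", "category", "roi"])
        return pd.concat(frames, ignore_index=True)

    @property
    def counts(self) -> Dict[int, int]:
        table = self.pixel_table()
        return table.groupby("category").size().to_dict()

    @property
    def n_pixels(self) -> int:
        return sum(len(r.pixels) for r in self.rois)

    def subset(self, train: bool) -> pd.DataFrame:
        if self.train_flag is None:
            raise ValueError("annotation set has not been split yet")
        table = self.pixel_table()
        return table[self.train_flag if train else ~self.train_flag]

    def to_csv(self, path: str | Path) -> Path:
        table = self.pixel_table()
        if self.train_flag is not None:
            table["train"] = self.train_flag
        table.to_csv(path, index=False)
        return Path(path)

    def to_label_raster(self, shape: tuple, transect_id: str, fill: int = -1) -> np.ndarray:
        """Label raster aligned to the transect's cube (fill = unlabeled)."""
        raster = np.full(shape, fill, dtype=np.int32)
        for roi in self.rois:
            if roi.transect_id == transect_id:
                raster[roi.pixels[:, 0], roi.pixels[:, 1]] = roi.category
        return raster


def sample_rois(
    scene: ReefScene,
    n_rois: int,
    roi_size_px: int = 7,
    skew: float = 1.0,
    seed: int = 0,
    transect_id: str = "T1",
    max_tries_per_roi: int = 200,
) -> AnnotationSet:
    """Sample pure-class square ROIs from ground truth.

    Category sampling frequency is proportional to cover**skew; skew > 1
    exaggerates the dominance of abundant categories, emulating the strong
    annotation imbalance typical of field libraries. Each ROI is a
    roi_size x roi_size square entirely of one ground-truth class (the
    annotator labels what they see); ROIs do not overlap the plate and do
    not overlap each other. If a pure region cannot be found after bounded
    retries the ROI is dropped with a warning, never silently.
    """
    if n_rois < 1:
        raise ValueError("n_rois must be >= 1")
    if roi_size_px < 1:
        raise ValueError("roi_size_px must be >= 1")
    rng = np.random.default_rng(seed)
    rows, cols = scene.shape
    cover = scene.realized_cover()
    cats = sorted(cover)
    weights = np.array([cover[c] ** skew for c in cats])
    weights = weights / weights.sum()

    taken = scene.plate_mask.copy()
    rois: List[Roi] = []
    dropped = 0
    for _ in range(n_rois):
        cat = int(rng.choice(cats, p=weights))
        placed = False
        for _try in range(max_tries_per_roi):
            r0 = int(rng.integers(0, max(rows - roi_size_px, 0) + 1))
            c0 = int(rng.integers(0, max(cols - roi_size_px, 0) + 1))
            block = scene.class_map[r0 : r0 + roi_size_px, c0 : c0 + roi_size_px]
            tk = taken[r0 : r0 + roi_size_px, c0 : c0 + roi_size_px]
            if block.shape != (roi_size_px, roi_size_px):
                continue
            if np.all(block == cat) and not tk.any():
                rr, cc = np.meshgrid(
                    np.arange(r0, r0 + roi_size_px),
                    np.arange(c0, c0 + roi_size_px),
                    indexing="ij",
                )
                rois.append(
                    Roi(
                        transect_id=transect_id,
                        pixels=np.column_stack([rr.ravel(), cc.ravel()]),
                        category=cat,
                    )
                )
                taken[r0 : r0 + roi_size_px, c0 : c0 + roi_size_px] = True
                placed = True
                break
        if not placed:
            dropped += 1
    if dropped:
        warnings.warn(
            f"{dropped}/{n_rois} ROIs could not be placed in a pure region "
            f"after {max_tries_per_roi} tries each",
            stacklevel=2,
        )
    if not rois:
        raise RuntimeError("no ROI could be placed; scene too fragmented")
    return AnnotationSet(rois=rois)


def annotations_from_csv(path: str | Path) -> AnnotationSet:
    """Rebuild an AnnotationSet written by :meth:`AnnotationSet.to_csv`."""
    table = pd.read_csv(path)
    rois: List[Roi] = []
    for roi_idx, sub in table.groupby("roi", sort=True):
        rois.append(
            Roi(
                transect_id=str(sub["transect"].iloc[0]),
                pixels=sub[["row", "col"]].to_numpy(),
                category=int(sub["category"].iloc[0]),
            )
        )
    flag = table["train"].to_numpy(dtype=bool) if "train" in table.columns else None
    # to_csv writes rows in pixel_table order (roi-major), so the flag aligns
    return AnnotationSet(rois=rois, train_flag=flag)


def merge_annotations(sets: Sequence[AnnotationSet]) -> AnnotationSet:
    rois: List[Roi] = []
    for s in sets:
        rois.extend(s.rois)
    return AnnotationSet(rois=rois)


def split_train_validation(
    annotations: AnnotationSet,
    train_fraction: float = 0.9,
    seed: int = 0,
    unit: str = "pixel",
) -> AnnotationSet:
    """Per-category stratified split into train and validation.

    ``unit="pixel"`` (default) splits labeled pixels directly, matching the
    convention of splitting annotated pixels 90/10; it is optimistic
    because pixels of one ROI are spatially correlated. ``unit="roi"``
    assigns whole ROIs to one side, which gives honest validation at the
    cost of coarser stratification. Categories with fewer than 2 units go
    wholly to train (logged). The split is a partition and reproducible
    given the seed.
    """
    if not (0.0 < train_fraction < 1.0):
        raise ValueError("train_fraction must be in (0, 1)")
    if unit not in ("pixel", "roi"):
        raise ValueError(f"unknown split unit {unit!r}")
    table = annotations.pixel_table()
    n = len(table)
    rng = np.random.default_rng(seed)
    flag = np.zeros(n, dtype=bool)
    if unit == "pixel":
        for cat, idx in table.groupby("category").indices.items():
            idx = np.asarray(idx)
            if len(idx) < 2:
                flag[idx] = True
                logger.info("category %s has < 2 pixels; assigned wholly to train", cat)
                continue
            n_train = int(round(train_fraction * len(idx)))
            n_train = min(max(n_train, 1), len(idx) - 1)
            chosen = rng.choice(idx, size=n_train, replace=False)
            flag[chosen] = True
    else:
        cats = np.array([r.category for r in annotations.rois])
        for cat in np.unique(cats):
            roi_ids = np.where(cats == cat)[0]
            if len(roi_ids) < 2:
                flag[table["roi"].isin(roi_ids)] = True
                logger.info("category %s has < 2 ROIs; assigned wholly to train", cat)
                continue
            n_train = int(round(train_fraction * len(roi_ids)))
            n_train = min(max(n_train, 1), len(roi_ids) - 1)
            chosen = rng.choice(roi_ids, size=n_train, replace=False)
            flag[table["roi"].isin(chosen)] = True
    return AnnotationSet(rois=list(annotations.rois), train_flag=flag)


def aggregate_cover_vector(
    cover: Dict[int, float], hierarchy: CategoryHierarchy, tier: str
) -> Dict[str, float]:
    """Sum a fine-category cover vector into high or broad groups.

    Total cover is preserved exactly (the tiers partition the fine ids).
    """
    mapping = hierarchy.mapping(tier)
    out: Dict[str, float] = {}
    for f, v in cover.items():
        if int(f) not in mapping:
            raise ValueError(f"fine category {f} not in hierarchy")
        key = mapping[int(f)]
        out[key] = out.get(key, 0.0) + float(v)
    return out
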