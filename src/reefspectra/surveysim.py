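"""Point-intercept photoquadrat simulation, cover-from-prediction, and the
certainty-threshold scan comparing the two survey methods.

The photoquadrat survey images a 0.25 m^2 quadrat at every meter along
each transect and overlays 20 nonaligned, systematically sampled points
(a fixed grid of cells, one uniform random point per cell); cover is the
category frequency over all points. Hyperspectral cover is the label
frequency over retained pixels of a prediction map, where retention is
controlled by a certainty threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .classify import PLATE, UNCLASSIFIED, PredictionMap
from .ecostats import anosim, bray_curtis
from .scene import ReefScene
from .taxonomy import CategoryHierarchy

__all__ = [
    "QuadratSample",
    "CommunityMatrix",
    "run_photoquadrat_survey",
    "cover_from_prediction",
    "threshold_grid",
    "threshold_scan",
    "select_optimal_threshold",
    "aggregate_cover",
]


@dataclass
class QuadratSample:
    transect_id: str
    quadrat_index: int
    origin_m: float
    points: np.ndarray  # (n_points, 2) pixel (row, col)
    labels: np.ndarray  # fine category per point (PLATE where on the plate)


@dataclass
class CommunityMatrix:
    """Samples x categories cover table with per-row method tags."""

    ids: List[str]
    columns: List
    values: np.ndarray
    methods: List[str]
    transects: List[str]
    tier: str = "fine"
    normalized: bool = True

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.ids), len(self.columns)):
            raise ValueError("values shape must be (n ids, n columns)")
        if len(self.methods) != len(self.ids) or len(self.transects) != len(self.ids):
            raise ValueError("methods/transects must align with ids")
        if np.any(self.values < 0):
            raise ValueError("cover values must be nonnegative")
        if self.normalized:
            sums = self.values.sum(axis=1)
            if not np.allclose(sums, 1.0, atol=1e-9):
                raise ValueError("normalized matrix rows must sum to 1 (+/-1e-9)")

    @property
    def index(self) -> List[str]:
        return self.ids

    def copy(self) -> "CommunityMatrix":
        return CommunityMatrix(
            list(self.ids),
            list(self.columns),
            self.values.copy(),
            list(self.methods),
            list(self.transects),
            self.tier,
            self.normalized,
        )

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, index=self.ids, columns=[str(c) for c in self.columns])
        df.insert(0, "method", self.methods)
        df.insert(1, "transect", self.transects)
        return df

    def row_cover(self, i: int) -> Dict:
        return {c: v for c, v in zip(self.columns, self.values[i])}

    def subset_columns(self, keep: Sequence, renormalize: bool = True) -> "CommunityMatrix":
        """Restrict to a category subset (e.g. scleractinian corals only)."""
        keep = [c for c in self.columns if c in set(keep)]
        if not keep:
            raise ValueError("no requested columns present")
        idx = [self.columns.index(c) for c in keep]
        vals = self.values[:, idx]
        if renormalize:
            sums = vals.sum(axis=1, keepdims=True)
            if np.any(sums <= 0):
                bad = [self.ids[i] for i in np.where(sums.ravel() <= 0)[0]]
                raise ValueError(f"rows with zero cover in subset: {bad}")
            vals = vals / sums
        return CommunityMatrix(
            list(self.ids), keep, vals, list(self.methods), list(self.transects),
            self.tier, renormalize,
        )

    @staticmethod
    def from_rows(
        rows: Sequence[Tuple[str, str, str, Dict]],
        columns: Optional[Sequence] = None,
        tier: str = "fine",
    ) -> "CommunityMatrix":
        """Build from (sample_id, method, transect, cover_dict) tuples."""
        if columns is None:
            cols: list = sorted({c for *_ , cov in rows for c in cov})
        else:
            cols = list(columns)
        vals = np.zeros((len(rows), len(cols)))
        for i, (_, _, _, cov) in enumerate(rows):
            for c, v in cov.items():
                vals[i, cols.index(c)] = v
        return CommunityMatrix(
            ids=[r[0] for r in rows],
            columns=cols,
            values=vals,
            methods=[r[1] for r in rows],
            transects=[r[2] for r in rows],
            tier=tier,
        )

    @staticmethod
    def concat(matrices: Sequence["CommunityMatrix"]) -> "CommunityMatrix":
        tiers = {m.tier for m in matrices}
        if len(tiers) != 1:
            raise ValueError(f"cannot concat mixed tiers {tiers}")
        cols = sorted({c for m in matrices for c in m.columns}, key=str)
        rows, methods, transects, ids = [], [], [], []
        for m in matrices:
            aligned = np.zeros((len(m.ids), len(cols)))
            for j, c in enumerate(m.columns):
                aligned[:, cols.index(c)] = m.values[:, j]
            rows.append(aligned)
            ids.extend(m.ids)
            methods.extend(m.methods)
            transects.extend(m.transects)
        return CommunityMatrix(
            ids, cols, np.vstack(rows), methods, transects, tiers.pop(),
            normalized=all(m.normalized for m in matrices),
        )


# ---------------------------------------------------------------------------
# photoquadrat survey
# ---------------------------------------------------------------------------


def _point_grid_dims(n_points: int) -> Tuple[int, int]:
    """Cell grid (along, across) for the nonaligned systematic design."""
    best = (n_points, 1)
    for a in range(1, int(np.sqrt(n_points)) + 1):
        if n_points % a == 0:
            best = (n_points // a, a)
    return best


def run_photoquadrat_survey(
    scene: ReefScene,
    transect_length_m: float = 50.0,
    spacing_m: float = 1.0,
    quadrat_area_m2: float = 0.25,
    points_per_quadrat: int = 20,
    seed: int = 0,
    transect_id: str = "T1",
    observer_confusion: Optional[Dict[int, Dict[int, float]]] = None,
) -> Tuple[List[QuadratSample], Dict[int, float]]:
    """Point-intercept photoquadrat survey of one transect.

    floor(length/spacing) quadrats are placed along the transect; each
    quadrat footprint is tiled by a cell grid (5x4 for 20 points) with one
    uniform random point per cell. Point labels are read from ground truth
    (the photoquadrat is treated as the reference method); points landing
    on the reference plate are excluded from cover. An optional observer
    error model relabels each point via ``observer_confusion``, a map
    true category -> {observed category: probability} (rows must sum
    to 1; categories without a row are read perfectly). Returns the
    quadrat samples and the transect cover vector (label frequencies over
    points).
    """
    if observer_confusion is not None:
        for cat, row in observer_confusion.items():
            total = sum(row.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"observer confusion row for category {cat} sums to {total}"
                )
    if spacing_m <= 0:
        raise ValueError("spacing must be positive")
    rows, cols = scene.shape
    side_m = float(np.sqrt(quadrat_area_m2))
    side_px = max(1, int(round(side_m / scene.pixel_size_m)))
    if side_px > cols:
        raise ValueError(
            f"quadrat side {side_m} m ({side_px} px) exceeds swath width ({cols} px)"
        )
    n_quadrats = int(np.floor(transect_length_m / spacing_m))
    ga, gc = _point_grid_dims(points_per_quadrat)
    rng = np.random.default_rng(seed)
    col0 = (cols - side_px) // 2

    samples: List[QuadratSample] = []
    all_labels: List[np.ndarray] = []
    for q in range(n_quadrats):
        origin_m = q * spacing_m
        row0 = int(round(origin_m / scene.pixel_size_m))
        row0 = min(row0, rows - side_px)
        # nonaligned systematic: one uniform point per grid cell
        cell_h = side_px / ga
        cell_w = side_px / gc
        pts = np.empty((points_per_quadrat, 2), dtype=int)
        k = 0
        for i in range(ga):
            for j in range(gc):
                r = row0 + int(rng.uniform(i * cell_h, (i + 1) * cell_h))
                c = col0 + int(rng.uniform(j * cell_w, (j + 1) * cell_w))
                pts[k] = (min(r, rows - 1), min(c, cols - 1))
                k += 1
        labels = scene.class_map[pts[:, 0], pts[:, 1]].astype(np.int32)
        if observer_confusion is not None:
            for j, true_cat in enumerate(labels):
                row = observer_confusion.get(int(true_cat))
                if row is not None:
                    obs = list(row)
                    labels[j] = obs[rng.choice(len(obs), p=list(row.values()))]
        labels[scene.plate_mask[pts[:, 0], pts[:, 1]]] = PLATE
        samples.append(
            QuadratSample(
                transect_id=transect_id,
                quadrat_index=q,
                origin_m=origin_m,
                points=pts,
                labels=labels,
            )
        )
        all_labels.append(labels)

    lab = np.concatenate(all_labels)
    lab = lab[lab != PLATE]
    cats, counts = np.unique(lab, return_counts=True)
    cover = {int(c): float(n) / lab.size for c, n in zip(cats, counts)}
    return samples, cover


# ---------------------------------------------------------------------------
# cover from prediction maps
# ---------------------------------------------------------------------------


def cover_from_prediction(
    pred: PredictionMap, threshold: float = 0.0, renormalize: bool = True
) -> Tuple[Dict[int, float], float]:
    """Cover fractions among pixels whose certainty passes the threshold.

    Threshold 0 means "no threshold" (all classified pixels). By default
    cover is renormalized over retained pixels (the primary convention);
    with ``renormalize=False`` frequencies are reported relative to all
    non-plate pixels, so they sum to the retained fraction instead of 1.
    ``retained_fraction`` (retained / total non-plate pixels) is returned
    so the loss of rare categories at high thresholds can be audited.
    """
    if not (0.0 <= threshold < 1.0):
        raise ValueError("threshold must be in [0, 1)")
    non_plate = pred.labels != PLATE
    retained = non_plate & (pred.labels != UNCLASSIFIED) & (pred.certainty >= threshold)
    n_total = int(non_plate.sum())
    n_ret = int(retained.sum())
    if n_total == 0:
        raise ValueError("prediction map has no non-plate pixels")
    if n_ret == 0:
        raise ValueError(f"no pixels retained at certainty threshold {threshold}")
    lab = pred.labels[retained]
    cats, counts = np.unique(lab, return_counts=True)
    denom = n_ret if renormalize else n_total
    cover = {int(c): float(n) / denom for c, n in zip(cats, counts)}
    return cover, n_ret / n_total


def threshold_grid() -> np.ndarray:
    """The 21-value certainty grid: 0, 0.05, ..., 0.95, 0.99."""
    return np.concatenate([np.arange(0.0, 0.96, 0.05), [0.99]])


def aggregate_cover(
    matrix: CommunityMatrix, hierarchy: CategoryHierarchy, tier: str
) -> CommunityMatrix:
    """Sum fine-category columns into high or broad groups.

    Row sums are preserved exactly because the tiers partition the fine
    categories.
    """
    if matrix.tier != "fine":
        raise ValueError(f"matrix tier is {matrix.tier!r}; expected 'fine'")
    if tier not in ("high", "broad"):
        raise ValueError(f"unknown tier {tier!r}")
    mapping = hierarchy.mapping(tier)
    unmapped = [c for c in matrix.columns if int(c) not in mapping]
    if unmapped:
        raise ValueError(f"categories without a {tier} mapping: {unmapped}")
    groups = list(dict.fromkeys(mapping[int(c)] for c in matrix.columns))
    vals = np.zeros((len(matrix.ids), len(groups)))
    for j, c in enumerate(matrix.columns):
        vals[:, groups.index(mapping[int(c)])] += matrix.values[:, j]
    return CommunityMatrix(
        list(matrix.ids), groups, vals, list(matrix.methods), list(matrix.transects),
        tier, matrix.normalized,
    )


def threshold_scan(
    pred_maps: Dict[str, PredictionMap],
    pq_matrix: CommunityMatrix,
    grid: Optional[np.ndarray] = None,
    hierarchy: Optional[CategoryHierarchy] = None,
    tier: Optional[str] = None,
    n_permutations: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """ANOSIM method-comparison across the certainty-threshold grid.

    For each threshold, hyperspectral cover rows (one per transect) are
    recomputed over the retained pixels, combined with the photoquadrat
    rows, optionally aggregated to a tier, and compared by ANOSIM with
    survey method as the grouping factor. A threshold at which some
    transect retains zero pixels is recorded as a missing row. Columns:
    threshold, anosim_R, significance, mean_retained_fraction, n_rows.
    """
    if grid is None:
        grid = threshold_grid()
    if len(pred_maps) < 2 or len(pq_matrix.ids) < 2:
        raise ValueError("need at least 2 transects per method")
    records = []
    for thr in grid:
        try:
            rows = []
            fractions = []
            for tid in sorted(pred_maps):
                cover, frac = cover_from_prediction(pred_maps[tid], float(thr))
                rows.append((f"HS-{tid}", "HS", tid, cover))
                fractions.append(frac)
            hs = CommunityMatrix.from_rows(rows, tier="fine")
            combined = CommunityMatrix.concat([hs, pq_matrix])
            if hierarchy is not None and tier is not None and tier != "fine":
                combined = aggregate_cover(combined, hierarchy, tier)
            dist = bray_curtis(combined.values, ids=combined.ids)
            res = anosim(dist, combined.methods, n_permutations=n_permutations, seed=seed)
            records.append(
                {
                    "threshold": float(thr),
                    "anosim_R": res.R,
                    "significance": res.significance,
                    "mean_retained_fraction": float(np.mean(fractions)),
                    "n_rows": len(combined.ids),
                }
            )
        except ValueError:
            records.append(
                {
                    "threshold": float(thr),
                    "anosim_R": np.nan,
                    "significance": np.nan,
                    "mean_retained_fraction": np.nan,
                    "n_rows": 0,
                }
            )
    return pd.DataFrame.from_records(records)


def select_optimal_threshold(scan: pd.DataFrame) -> float:
    """Threshold with maximal ANOSIM significance (most method-similar).

    Ties resolve to the smallest threshold, so an all-flat significance
    curve selects "no threshold".
    """
    valid = scan.dropna(subset=["significance"])
    if not len(valid):
        raise ValueError("scan contains no valid rows")
    best = valid["significance"].max()
    return float(valid.loc[valid["significance"] >= best - 1e-12, "threshold"].min())
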