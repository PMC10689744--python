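"""End-to-end experiment orchestration.

Runs the full comparison study on synthetic data: simulate a survey site
(transect scenes + hyperspectral cubes), preprocess, annotate ROIs, train
the spectral-spatial residual network, predict every pixel, run the
concurrent photoquadrat survey, scan certainty thresholds, and compare the
two methods' community estimates with ANOSIM / nMDS / ANOVA+Tukey at the
broad and high-resolution taxonomy tiers. Every stage reads and writes
documented files in a work directory, so each stage is re-runnable from
disk (the CLI exposes one verb per stage).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from . import classify as cl
from . import ecostats as es
from . import preprocess as pp
from . import scene as sc
from . import surveysim as sv
from . import taxonomy as tx
from .cube import HyperspectralCube, read_envi, write_envi

__all__ = [
    "ExperimentConfig",
    "ExperimentReport",
    "run_experiment",
    "compare_methods",
    "export_habitat_map",
    "import_habitat_map",
    "preprocess_site",
    "default_site_cover",
]

logger = logging.getLogger(__name__)

# fixed qualitative palette for habitat maps (RGB); two reserved entries
_PALETTE = [
    (31, 119, 180), (255, 127, 14), (44, 160, 44), (214, 39, 40),
    (148, 103, 189), (140, 86, 75), (227, 119, 194), (127, 127, 127),
    (188, 189, 34), (23, 190, 207), (174, 199, 232), (255, 187, 120),
]
_UNCLASSIFIED_COLOR = (40, 40, 40)
_PLATE_COLOR = (255, 255, 255)


def default_site_cover() -> Dict[int, float]:
    """Site-mean cover for the 12-category demo taxonomy.

    Dominated by turf/pavement and a few coral categories with a long tail
    of rarer groups, the typical skew of Indo-Pacific fringing reefs.
    """
    return {
        1: 0.10, 2: 0.06, 3: 0.08, 4: 0.04,
        5: 0.05, 6: 0.02, 7: 0.045, 8: 0.02,
        9: 0.03, 10: 0.035, 11: 0.30, 12: 0.22,
    }


@dataclass
class ExperimentConfig:
    seed: int = 0
    n_transects: int = 6
    transect_length_m: float = 50.0
    swath_width_m: float = 1.0
    pixel_size_m: float = 0.02
    patch_scale_m: float = 0.3
    site_cover: Optional[Dict[int, float]] = None
    concentration: float = 200.0
    shade_strength: float = 0.2
    sensor_height_m: float = 1.0
    noise_sd_additive: float = 0.002
    noise_sd_multiplicative: float = 0.01
    taxonomy_file: Optional[str] = None
    rois_per_transect: int = 60
    roi_size_px: int = 5
    roi_skew: float = 1.4
    train_fraction: float = 0.9
    ssrn: cl.SSRNConfig = field(default_factory=cl.SSRNConfig)
    pq_spacing_m: float = 1.0
    quadrat_area_m2: float = 0.25
    points_per_quadrat: int = 20
    n_permutations: int = 999
    nmds_restarts: int = 8
    alpha: float = 0.05
    sqrt_transform_high_tier: bool = True
    signal_fraction: float = 0.02

    def __post_init__(self) -> None:
        if isinstance(self.ssrn, dict):
            self.ssrn = cl.SSRNConfig(**self.ssrn)
        if self.site_cover is None:
            self.site_cover = default_site_cover()
        self.site_cover = {int(k): float(v) for k, v in self.site_cover.items()}
        if self.n_transects < 2:
            raise ValueError(
                "n_transects must be >= 2: ANOSIM needs at least 2 samples "
                "per survey method"
            )
        total = sum(self.site_cover.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"site cover sums to {total}, expected 1")

    def hierarchy(self) -> tx.CategoryHierarchy:
        if self.taxonomy_file:
            return tx.load_hierarchy(self.taxonomy_file)
        return tx.demo_hierarchy()

    def to_yaml(self, path: str | Path) -> Path:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))
        return Path(path)

    @staticmethod
    def from_yaml(path: str | Path) -> "ExperimentConfig":
        return ExperimentConfig(**yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:12]

    def derived_seeds(self) -> Dict[str, int]:
        ss = np.random.SeedSequence(self.seed)
        names = ["site", "rois", "split", "ssrn", "pq", "stats"]
        kids = ss.spawn(len(names))
        return {n: int(k.generate_state(1)[0] % 2**31) for n, k in zip(names, kids)}

    def transect_ids(self) -> List[str]:
        return [f"T{i+1}" for i in range(self.n_transects)]


@dataclass
class ExperimentReport:
    config_hash: str
    seeds: Dict[str, int]
    cover_tables: Dict[str, pd.DataFrame]
    anosim: Dict[str, dict]
    anova_scleractinia: dict
    similarity: Dict[str, float]
    threshold_scan: pd.DataFrame
    optimal_threshold: float
    nmds: Dict[str, pd.DataFrame]
    training_history: Dict[str, list]
    timings_s: Dict[str, float]

    def to_json_dict(self) -> dict:
        return {
            "config_hash": self.config_hash,
            "seeds": self.seeds,
            "anosim": self.anosim,
            "anova_scleractinia": self.anova_scleractinia,
            "similarity": self.similarity,
            "optimal_threshold": self.optimal_threshold,
            "training_history": self.training_history,
            "timings_s": self.timings_s,
        }


# ---------------------------------------------------------------------------
# in-memory stages
# ---------------------------------------------------------------------------


def simulate_site(
    config: ExperimentConfig, library: Optional[sc.SpectralLibrary] = None
) -> Tuple[List[sc.ReefScene], List[HyperspectralCube], sc.SpectralLibrary]:
    seeds = config.derived_seeds()
    hierarchy = config.hierarchy()
    if library is None:
        library = sc.demo_library(hierarchy.fine_ids)
    pairs = sc.make_site(
        n_transects=config.n_transects,
        site_cover=config.site_cover,
        library=library,
        seed=seeds["site"],
        transect_length_m=config.transect_length_m,
        swath_width_m=config.swath_width_m,
        pixel_size_m=config.pixel_size_m,
        patch_scale_m=config.patch_scale_m,
        concentration=config.concentration,
        shade_strength=config.shade_strength,
        sensor_height_m=config.sensor_height_m,
        noise_sd_additive=config.noise_sd_additive,
        noise_sd_multiplicative=config.noise_sd_multiplicative,
    )
    return [p[0] for p in pairs], [p[1] for p in pairs], library


def preprocess_site(
    cubes: List[HyperspectralCube],
    plate_reflectance: np.ndarray,
    window: int = 7,
    polyorder: int = 2,
    signal_fraction: float = 0.02,
) -> List[HyperspectralCube]:
    """Preprocess all transects of a site onto one common band grid.

    Bands are culled by the site-wide (pooled across transects) median
    signal so every transect retains the same wavelengths; plate
    normalization then runs per transect against its own plate.
    """
    smoothed = [pp.smooth_spectra(c, window, polyorder) for c in cubes]
    meds = np.stack(
        [np.median(c.radiance.reshape(-1, c.n_bands), axis=0) for c in smoothed]
    )
    band_medians = np.median(meds, axis=0)
    threshold = float(signal_fraction * np.percentile(band_medians, 95))
    keep = band_medians >= threshold
    if keep.sum() < pp.MIN_SURVIVING_BANDS:
        raise ValueError(
            f"only {int(keep.sum())} bands survive threshold {threshold:.4g}"
        )
    out = []
    plate_ref = np.asarray(plate_reflectance, dtype=float)[keep]
    for c in smoothed:
        sub = HyperspectralCube(
            c.radiance[:, :, keep], c.wavelengths_nm[keep], c.plate_mask,
            list(c.provenance),
        )
        sub.log(
            f"drop_low_signal_bands(site): threshold={threshold:.6g}, "
            f"kept {int(keep.sum())}/{len(keep)} bands"
        )
        out.append(pp.normalize_to_plate(sub, plate_ref))
    return out


def annotate_site(
    scenes: List[sc.ReefScene], config: ExperimentConfig
) -> tx.AnnotationSet:
    seeds = config.derived_seeds()
    ss = np.random.SeedSequence(seeds["rois"]).spawn(len(scenes))
    tids = config.transect_ids()
    sets = []
    for i, scene in enumerate(scenes):
        sets.append(
            tx.sample_rois(
                scene,
                n_rois=config.rois_per_transect,
                roi_size_px=config.roi_size_px,
                skew=config.roi_skew,
                seed=int(ss[i].generate_state(1)[0] % 2**31),
                transect_id=tids[i],
            )
        )
    merged = tx.merge_annotations(sets)
    return tx.split_train_validation(merged, config.train_fraction, seed=seeds["split"])


def survey_site(
    scenes: List[sc.ReefScene], config: ExperimentConfig
) -> Tuple[sv.CommunityMatrix, pd.DataFrame]:
    """Photoquadrat point-intercept survey of every transect."""
    seeds = config.derived_seeds()
    pq_ss = np.random.SeedSequence(seeds["pq"]).spawn(len(scenes))
    tids = config.transect_ids()
    hierarchy = config.hierarchy()
    rows, frames = [], []
    for i, (tid, scene) in enumerate(zip(tids, scenes)):
        samples, cover = sv.run_photoquadrat_survey(
            scene,
            transect_length_m=config.transect_length_m,
            spacing_m=config.pq_spacing_m,
            quadrat_area_m2=config.quadrat_area_m2,
            points_per_quadrat=config.points_per_quadrat,
            seed=int(pq_ss[i].generate_state(1)[0] % 2**31),
            transect_id=tid,
        )
        rows.append((f"PQ-{tid}", "PQ", tid, cover))
        for s in samples:
            frames.append(
                pd.DataFrame(
                    {
                        "transect": s.transect_id,
                        "quadrat": s.quadrat_index,
                        "origin_m": s.origin_m,
                        "row": s.points[:, 0],
                        "col": s.points[:, 1],
                        "label": s.labels,
                    }
                )
            )
    pq_fine = sv.CommunityMatrix.from_rows(
        rows, columns=sorted(hierarchy.fine_ids), tier="fine"
    )
    return pq_fine, pd.concat(frames, ignore_index=True)


def compare_methods(
    pred_maps: Dict[str, cl.PredictionMap],
    pq_fine: sv.CommunityMatrix,
    hierarchy: tx.CategoryHierarchy,
    config: ExperimentConfig,
) -> dict:
    """Threshold scan + all method-comparison statistics.

    Main statistics (ANOSIM per tier, nMDS, Scleractinia ANOVA/Tukey and
    Scleractinia-only community ANOSIM, Table-style percent similarity)
    are computed on the no-threshold predictions; the scan records how the
    method agreement degrades as the certainty threshold rises.
    """
    seeds = config.derived_seeds()
    all_fine = sorted(hierarchy.fine_ids)
    scan = sv.threshold_scan(
        pred_maps,
        pq_fine,
        hierarchy=hierarchy,
        tier="broad",
        n_permutations=config.n_permutations,
        seed=seeds["stats"],
    )
    optimal_thr = sv.select_optimal_threshold(scan)

    hs_rows = []
    for tid in sorted(pred_maps):
        cover, _ = sv.cover_from_prediction(pred_maps[tid], 0.0)
        hs_rows.append((f"HS-{tid}", "HS", tid, cover))
    hs_fine = sv.CommunityMatrix.from_rows(hs_rows, columns=all_fine, tier="fine")
    combined_fine = sv.CommunityMatrix.concat([hs_fine, pq_fine])

    anosim_results: Dict[str, dict] = {}
    nmds_results: Dict[str, pd.DataFrame] = {}
    cover_tables: Dict[str, pd.DataFrame] = {"fine_hs": hs_fine.to_dataframe()}
    tier_matrices: Dict[str, sv.CommunityMatrix] = {}
    for tier in ("broad", "high"):
        mat = sv.aggregate_cover(combined_fine, hierarchy, tier)
        tier_matrices[tier] = mat
        cover_tables[tier] = mat.to_dataframe()
        stat_values = mat.values
        if tier == "high" and config.sqrt_transform_high_tier:
            stat_values = es.sqrt_transform(mat.values)
        dist = es.bray_curtis(stat_values, ids=mat.ids)
        res = es.anosim(
            dist, mat.methods, n_permutations=config.n_permutations,
            seed=seeds["stats"],
        )
        anosim_results[tier] = {
            "R": res.R,
            "significance": res.significance,
            "n_permutations": res.n_permutations,
            "method": res.method,
        }
        nm = es.nmds(dist, k=2, n_restarts=config.nmds_restarts, seed=seeds["stats"])
        nmds_results[tier] = pd.DataFrame(
            nm.coordinates, index=mat.ids, columns=["MDS1", "MDS2"]
        ).assign(method=mat.methods, stress=nm.stress)

    # Scleractinia-focused comparisons (coral cover is the headline metric)
    scler_fine = [
        f for f in hierarchy.fine_ids if hierarchy.to_broad[f] == "Scleractinia"
    ]
    anova_result: dict = {"available": False}
    if scler_fine:
        broad = tier_matrices["broad"]
        scol = broad.columns.index("Scleractinia")
        av = es.anova_tukey(broad.values[:, scol], broad.methods, alpha=config.alpha)
        anova_result = {
            "available": True,
            "F": av.F,
            "df": [av.df_between, av.df_within],
            "p": av.p,
            "tukey": [
                {"pair": list(pair), "mean_diff": d, "adjusted_p": p_adj}
                for pair, d, p_adj in av.tukey
            ],
        }
        try:
            scler_mat = combined_fine.subset_columns(scler_fine)
            dist = es.bray_curtis(scler_mat.values, ids=scler_mat.ids)
            res = es.anosim(
                dist, scler_mat.methods, n_permutations=config.n_permutations,
                seed=seeds["stats"],
            )
            anosim_results["scleractinia"] = {
                "R": res.R,
                "significance": res.significance,
                "n_permutations": res.n_permutations,
                "method": res.method,
            }
        except ValueError as exc:
            anosim_results["scleractinia"] = {"error": str(exc)}

    # Table-style percent similarity at the broad tier, two schemes
    broad = tier_matrices["broad"]
    hs_v = broad.values[[m == "HS" for m in broad.methods]]
    pq_v = broad.values[[m == "PQ" for m in broad.methods]]
    pair_bc = [
        es.bray_curtis(np.vstack([h, p])).values[0, 1] for h, p in zip(hs_v, pq_v)
    ]
    bc_profile = es.bray_curtis(
        np.vstack([hs_v.mean(axis=0), pq_v.mean(axis=0)])
    ).values[0, 1]
    similarity = {
        "mean_transect_pairs": float(
            np.mean([es.similarity_percent(b) for b in pair_bc])
        ),
        "site_mean_profiles": es.similarity_percent(bc_profile),
    }
    return {
        "scan": scan,
        "optimal_threshold": optimal_thr,
        "anosim": anosim_results,
        "nmds": nmds_results,
        "cover_tables": cover_tables,
        "anova_scleractinia": anova_result,
        "similarity": similarity,
        "hs_fine": hs_fine,
    }


def run_experiment(
    config: ExperimentConfig,
    outdir: Optional[str | Path] = None,
) -> ExperimentReport:
    """Execute the full pipeline and assemble the comparison report.

    Stages: simulate -> preprocess -> annotate -> train -> predict ->
    photoquadrat survey -> threshold scan + statistics -> export.
    Deterministic: the config seed fully determines every number. When
    ``outdir`` is given every stage writes its artifacts there.
    """
    t_start = time.time()
    timings: Dict[str, float] = {}
    hierarchy = config.hierarchy()
    seeds = config.derived_seeds()
    tids = config.transect_ids()
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        config.to_yaml(out / "config.yaml")

    def tic(stage: str, t0: float) -> None:
        timings[stage] = round(time.time() - t0, 3)
        logger.info("stage %-12s %.1fs", stage, timings[stage])

    t0 = time.time()
    scenes, cubes, library = simulate_site(config)
    tic("simulate", t0)
    if out is not None:
        tdir = out / "transects"
        tdir.mkdir(exist_ok=True)
        save_library(library, tdir / "library.csv")
        for tid, scene, cube in zip(tids, scenes, cubes):
            write_envi(cube, tdir / f"{tid}.bil")
            save_scene(scene, tdir / f"{tid}_scene.npz")

    t0 = time.time()
    pre = preprocess_site(
        cubes, library.plate_reflectance, signal_fraction=config.signal_fraction
    )
    tic("preprocess", t0)
    if out is not None:
        pdir = out / "preprocessed"
        pdir.mkdir(exist_ok=True)
        for tid, cube in zip(tids, pre):
            write_envi(cube, pdir / f"{tid}.bil")

    t0 = time.time()
    annotations = annotate_site(scenes, config)
    tic("annotate", t0)
    if out is not None:
        annotations.to_csv(out / "annotations.csv")

    t0 = time.time()
    cube_map = dict(zip(tids, pre))
    n_classes = len(set(r.category for r in annotations.rois))
    ssrn_cfg = dataclasses.replace(config.ssrn, seed=seeds["ssrn"])
    model = cl.build_model(ssrn_cfg, pre[0].n_bands, n_classes)
    model = cl.train(model, cube_map, annotations, ssrn_cfg)
    tic("train", t0)
    if out is not None:
        cl.save_model(model, out / "model.npz")

    t0 = time.time()
    pred_maps = {tid: cl.predict_map(model, cube_map[tid]) for tid in tids}
    tic("predict", t0)
    if out is not None:
        pdir = out / "predictions"
        pdir.mkdir(exist_ok=True)
        for tid, pm in pred_maps.items():
            np.savez(pdir / f"{tid}.npz", labels=pm.labels, certainty=pm.certainty)

    t0 = time.time()
    pq_fine, quadrats = survey_site(scenes, config)
    true_rows = [
        (f"TRUE-{tid}", "TRUE", tid, scene.true_cover)
        for tid, scene in zip(tids, scenes)
    ]
    true_fine = sv.CommunityMatrix.from_rows(
        true_rows, columns=sorted(hierarchy.fine_ids), tier="fine"
    )
    tic("survey", t0)
    if out is not None:
        sdir = out / "survey"
        sdir.mkdir(exist_ok=True)
        quadrats.to_csv(sdir / "quadrats.csv", index=False)
        pq_fine.to_dataframe().to_csv(sdir / "pq_fine.csv")
        true_fine.to_dataframe().to_csv(sdir / "true_fine.csv")

    t0 = time.time()
    cmp = compare_methods(pred_maps, pq_fine, hierarchy, config)
    tic("compare", t0)

    cover_tables = {
        "fine_pq": pq_fine.to_dataframe(),
        "fine_true": true_fine.to_dataframe(),
        **cmp["cover_tables"],
    }
    report = ExperimentReport(
        config_hash=config.config_hash(),
        seeds=seeds,
        cover_tables=cover_tables,
        anosim=cmp["anosim"],
        anova_scleractinia=cmp["anova_scleractinia"],
        similarity=cmp["similarity"],
        threshold_scan=cmp["scan"],
        optimal_threshold=cmp["optimal_threshold"],
        nmds=cmp["nmds"],
        training_history=model.history,
        timings_s=timings,
    )

    if out is not None:
        write_report(report, pred_maps, hierarchy, config, out)
    timings["total"] = round(time.time() - t_start, 3)
    return report


def write_report(
    report: ExperimentReport,
    pred_maps: Dict[str, cl.PredictionMap],
    hierarchy: tx.CategoryHierarchy,
    config: ExperimentConfig,
    out: Path,
) -> None:
    cdir = out / "compare"
    cdir.mkdir(exist_ok=True)
    report.threshold_scan.to_csv(cdir / "threshold_scan.csv", index=False)
    for tier, df in report.nmds.items():
        df.to_csv(cdir / f"nmds_{tier}.csv")
    for name, df in report.cover_tables.items():
        df.to_csv(cdir / f"cover_{name}.csv")
    (cdir / "stats.json").write_text(
        json.dumps(report.to_json_dict(), indent=1, default=float)
    )
    mdir = out / "maps"
    mdir.mkdir(exist_ok=True)
    for tid, pm in pred_maps.items():
        export_habitat_map(
            pm, hierarchy, "broad", mdir / f"{tid}_broad.png",
            pixel_size_m=config.pixel_size_m,
        )


# ---------------------------------------------------------------------------
# disk-based stage runners (the CLI verbs)
# ---------------------------------------------------------------------------


def _load_config(workdir: Path) -> ExperimentConfig:
    cfg_path = workdir / "config.yaml"
    if not cfg_path.exists():
        raise FileNotFoundError(
            f"{cfg_path} not found; run the simulate stage (or `all`) first"
        )
    return ExperimentConfig.from_yaml(cfg_path)


def _load_cubes(workdir: Path, sub: str, config: ExperimentConfig):
    return {
        tid: read_envi(workdir / sub / f"{tid}.bil") for tid in config.transect_ids()
    }


def _load_scenes(workdir: Path, config: ExperimentConfig):
    return [
        load_scene(workdir / "transects" / f"{tid}_scene.npz")
        for tid in config.transect_ids()
    ]


def stage_simulate(config: ExperimentConfig, workdir: Path) -> None:
    workdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(workdir / "config.yaml")
    scenes, cubes, library = simulate_site(config)
    tdir = workdir / "transects"
    tdir.mkdir(exist_ok=True)
    save_library(library, tdir / "library.csv")
    for tid, scene, cube in zip(config.transect_ids(), scenes, cubes):
        write_envi(cube, tdir / f"{tid}.bil")
        save_scene(scene, tdir / f"{tid}_scene.npz")


def stage_preprocess(workdir: Path) -> None:
    config = _load_config(workdir)
    library = load_library(workdir / "transects" / "library.csv")
    cubes = _load_cubes(workdir, "transects", config)
    pre = preprocess_site(
        list(cubes.values()), library.plate_reflectance,
        signal_fraction=config.signal_fraction,
    )
    pdir = workdir / "preprocessed"
    pdir.mkdir(exist_ok=True)
    for tid, cube in zip(config.transect_ids(), pre):
        write_envi(cube, pdir / f"{tid}.bil")


def stage_annotate(workdir: Path) -> None:
    config = _load_config(workdir)
    annotations = annotate_site(_load_scenes(workdir, config), config)
    annotations.to_csv(workdir / "annotations.csv")


def stage_train(workdir: Path) -> None:
    config = _load_config(workdir)
    seeds = config.derived_seeds()
    cubes = _load_cubes(workdir, "preprocessed", config)
    annotations = tx.annotations_from_csv(workdir / "annotations.csv")
    n_classes = len(set(r.category for r in annotations.rois))
    ssrn_cfg = dataclasses.replace(config.ssrn, seed=seeds["ssrn"])
    model = cl.build_model(ssrn_cfg, next(iter(cubes.values())).n_bands, n_classes)
    model = cl.train(model, cubes, annotations, ssrn_cfg)
    cl.save_model(model, workdir / "model.npz")


def stage_predict(workdir: Path) -> None:
    config = _load_config(workdir)
    model = cl.load_model(workdir / "model.npz")
    cubes = _load_cubes(workdir, "preprocessed", config)
    pdir = workdir / "predictions"
    pdir.mkdir(exist_ok=True)
    for tid, cube in cubes.items():
        pm = cl.predict_map(model, cube)
        np.savez(pdir / f"{tid}.npz", labels=pm.labels, certainty=pm.certainty)


def stage_survey(workdir: Path) -> None:
    config = _load_config(workdir)
    scenes = _load_scenes(workdir, config)
    pq_fine, quadrats = survey_site(scenes, config)
    sdir = workdir / "survey"
    sdir.mkdir(exist_ok=True)
    quadrats.to_csv(sdir / "quadrats.csv", index=False)
    pq_fine.to_dataframe().to_csv(sdir / "pq_fine.csv")


def _load_predictions(workdir: Path, config: ExperimentConfig):
    pred_maps = {}
    for tid in config.transect_ids():
        with np.load(workdir / "predictions" / f"{tid}.npz") as d:
            pred_maps[tid] = cl.PredictionMap(
                labels=d["labels"], certainty=d["certainty"]
            )
    return pred_maps


def stage_compare(workdir: Path) -> ExperimentReport:
    config = _load_config(workdir)
    hierarchy = config.hierarchy()
    pred_maps = _load_predictions(workdir, config)
    pq_fine = community_matrix_from_csv(workdir / "survey" / "pq_fine.csv", tier="fine")
    cmp = compare_methods(pred_maps, pq_fine, hierarchy, config)
    history = {}
    model_path = workdir / "model.npz"
    if model_path.exists():
        history = cl.load_model(model_path).history
    report = ExperimentReport(
        config_hash=config.config_hash(),
        seeds=config.derived_seeds(),
        cover_tables={"fine_pq": pq_fine.to_dataframe(), **cmp["cover_tables"]},
        anosim=cmp["anosim"],
        anova_scleractinia=cmp["anova_scleractinia"],
        similarity=cmp["similarity"],
        threshold_scan=cmp["scan"],
        optimal_threshold=cmp["optimal_threshold"],
        nmds=cmp["nmds"],
        training_history=history,
        timings_s={},
    )
    write_report(report, pred_maps, hierarchy, config, workdir)
    return report


def stage_report(workdir: Path) -> ExperimentReport:
    return stage_compare(workdir)


# ---------------------------------------------------------------------------
# persistence helpers
# ---------------------------------------------------------------------------


def save_scene(scene: sc.ReefScene, path: str | Path) -> Path:
    path = Path(path)
    np.savez(
        path,
        class_map=scene.class_map,
        depth_map_m=scene.depth_map_m,
        shade_map=scene.shade_map,
        plate_mask=scene.plate_mask,
        pixel_size_m=np.array([scene.pixel_size_m]),
    )
    return path


def load_scene(path: str | Path) -> sc.ReefScene:
    with np.load(path) as d:
        class_map = d["class_map"]
        plate_mask = d["plate_mask"]
        vals = class_map[~plate_mask]
        cats, counts = np.unique(vals, return_counts=True)
        return sc.ReefScene(
            class_map=class_map,
            pixel_size_m=float(d["pixel_size_m"][0]),
            depth_map_m=d["depth_map_m"],
            shade_map=d["shade_map"],
            plate_mask=plate_mask,
            true_cover={int(c): float(n) / vals.size for c, n in zip(cats, counts)},
        )


def export_ground_truth(scene: sc.ReefScene, path: str | Path) -> Tuple[Path, Path]:
    """Write the class map as a single-band 16-bit PNG plus a CSV legend.

    Plate pixels are written as 0; category ids are stored verbatim
    (must be positive and < 65536). Returns (raster path, legend path).
    """
    import imageio.v3 as iio

    cats = sorted(scene.true_cover)
    if min(cats) < 1 or max(cats) > 65535:
        raise ValueError("category ids must be in 1..65535 for PNG export")
    raster = scene.class_map.astype(np.uint16)
    raster[scene.plate_mask] = 0
    path = Path(path)
    iio.imwrite(path, raster)
    legend_path = path.with_suffix(".legend.csv")
    pd.DataFrame(
        [(0, "plate", np.nan)]
        + [(c, f"category {c}", scene.true_cover[c]) for c in cats],
        columns=["id", "name", "true_cover"],
    ).to_csv(legend_path, index=False)
    Path(str(path) + ".pgw").write_text(
        f"{scene.pixel_size_m}\n0.0\n0.0\n{-scene.pixel_size_m}\n0.0\n0.0\n"
    )
    return path, legend_path


def save_library(library: sc.SpectralLibrary, path: str | Path) -> Path:
    df = pd.DataFrame({"wavelength_nm": library.wavelengths_nm})
    for cat in library.categories:
        df[f"cat_{cat}"] = library.endmembers[cat]
    df["plate"] = library.plate_reflectance
    df.to_csv(path, index=False)
    return Path(path)


def load_library(path: str | Path) -> sc.SpectralLibrary:
    df = pd.read_csv(path)
    wl = df["wavelength_nm"].to_numpy()
    endmembers = {
        int(c.removeprefix("cat_")): df[c].to_numpy()
        for c in df.columns
        if c.startswith("cat_")
    }
    return sc.SpectralLibrary(wl, endmembers, df["plate"].to_numpy())


def community_matrix_from_csv(path: str | Path, tier: str = "fine") -> sv.CommunityMatrix:
    df = pd.read_csv(path, index_col=0)
    methods = df.pop("method").tolist()
    transects = df.pop("transect").astype(str).tolist()
    cols: list = []
    for c in df.columns:
        try:
            cols.append(int(c))
        except ValueError:
            cols.append(c)
    return sv.CommunityMatrix(
        ids=[str(i) for i in df.index],
        columns=cols,
        values=df.to_numpy(),
        methods=methods,
        transects=transects,
        tier=tier,
    )


# ---------------------------------------------------------------------------
# habitat map export
# ---------------------------------------------------------------------------


def _tier_palette(groups: List[str], palette=None) -> Dict[str, tuple]:
    if palette is not None:
        return {g: tuple(palette[g]) for g in groups}
    return {g: _PALETTE[i % len(_PALETTE)] for i, g in enumerate(groups)}


def export_habitat_map(
    pred: cl.PredictionMap,
    hierarchy: tx.CategoryHierarchy,
    tier: str,
    path: str | Path,
    pixel_size_m: float = 0.02,
    palette: Optional[dict] = None,
    threshold: float = 0.0,
) -> Tuple[Path, Path]:
    """Export a prediction map as a color raster with a CSV legend.

    Pixels below the certainty threshold render as unclassified (reserved
    dark color); plate pixels render white. A world-file-style sidecar
    records the local-coordinate pixel size (no geodetic georeferencing).
    Returns (raster path, legend path).
    """
    import imageio.v3 as iio

    if tier not in ("fine", "high", "broad"):
        raise ValueError(f"unknown tier {tier!r}")
    mapping = hierarchy.mapping(tier)
    groups = list(dict.fromkeys(mapping[f] for f in hierarchy.fine_ids))
    colors = _tier_palette(groups, palette)

    labels = pred.labels
    rgb = np.zeros((*labels.shape, 3), dtype=np.uint8)
    rgb[:] = _UNCLASSIFIED_COLOR
    below = pred.certainty < threshold
    for f in hierarchy.fine_ids:
        m = (labels == f) & ~below
        rgb[m] = colors[mapping[f]]
    rgb[labels == cl.PLATE] = _PLATE_COLOR

    path = Path(path)
    iio.imwrite(path, rgb)
    legend = pd.DataFrame(
        [(g, *colors[g]) for g in groups]
        + [("unclassified", *_UNCLASSIFIED_COLOR), ("plate", *_PLATE_COLOR)],
        columns=["group", "r", "g", "b"],
    )
    legend_path = path.with_suffix(".legend.csv")
    legend.to_csv(legend_path, index=False)
    # world-file sidecar: pixel size, rotation, top-left origin (local coords)
    Path(str(path) + ".pgw").write_text(
        f"{pixel_size_m}\n0.0\n0.0\n{-pixel_size_m}\n0.0\n0.0\n"
    )
    return path, legend_path


def import_habitat_map(
    path: str | Path, hierarchy: tx.CategoryHierarchy, tier: str
) -> np.ndarray:
    """Re-import an exported habitat raster as a group-index raster.

    Returns an integer raster of group indices (-1 unclassified,
    -2 plate), the exact inverse of :func:`export_habitat_map`'s coloring
    at the group level.
    """
    import imageio.v3 as iio

    legend = pd.read_csv(Path(path).with_suffix(".legend.csv"))
    rgb = iio.imread(path)
    out = np.full(rgb.shape[:2], -99, dtype=np.int32)
    groups = [g for g in legend["group"] if g not in ("unclassified", "plate")]
    for _, row in legend.iterrows():
        m = np.all(rgb == (row["r"], row["g"], row["b"]), axis=2)
        if row["group"] == "unclassified":
            out[m] = -1
        elif row["group"] == "plate":
            out[m] = -2
        else:
            out[m] = groups.index(row["group"])
    return out
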