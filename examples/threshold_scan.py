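"""Certainty-threshold scan comparing the two survey methods.

Builds matched synthetic data (hyperspectral labels equal ground truth;
per-pixel certainty higher for dominant categories, as trained classifiers
behave) and scans ANOSIM agreement across the 21-threshold grid
{0, 0.05, ..., 0.95, 0.99}. Raising the threshold biases retained cover
toward dominant taxa, so agreement collapses at high thresholds.
"""

import numpy as np

from reefspectra import classify as cl
from reefspectra import scene as sc
from reefspectra import surveysim as sv
from reefspectra import taxonomy as tx
from reefspectra.pipeline import default_site_cover

hierarchy = tx.demo_hierarchy()
site_cover = default_site_cover()
max_cov = max(site_cover.values())
plan = sc.derive_transect_plan(404, 6, site_cover, concentration=200.0)
dims = sc.scene_dims(12.0, 1.0, 0.02)
rng = np.random.default_rng(99)

pred_maps, rows = {}, []
for i, entry in enumerate(plan):
    tid = f"T{i+1}"
    scene = sc.generate_scene(
        sorted(entry["cover"]), entry["cover"], 0.3, dims, 0.02,
        seed=entry["scene_seed"],
    )
    labels = scene.class_map.astype(np.int32).copy()
    certainty = np.empty(labels.shape, dtype=np.float32)
    for cat, cov in site_cover.items():
        m = labels == cat
        mc = 0.45 + 0.5 * (cov / max_cov)  # dominant taxa -> higher certainty
        certainty[m] = rng.beta(10 * mc, 10 * (1 - mc), size=int(m.sum()))
    labels[scene.plate_mask] = cl.PLATE
    certainty[scene.plate_mask] = 0
    pred_maps[tid] = cl.PredictionMap(labels=labels, certainty=certainty)
    _, cover = sv.run_photoquadrat_survey(
        scene, transect_length_m=12.0, seed=900 + i, transect_id=tid
    )
    rows.append((f"PQ-{tid}", "PQ", tid, cover))

pq = sv.CommunityMatrix.from_rows(rows, columns=sorted(hierarchy.fine_ids), tier="fine")
scan = sv.threshold_scan(
    pred_maps, pq, hierarchy=hierarchy, tier="broad", n_permutations=999, seed=5
)
print(scan.to_string(index=False,
                     float_format=lambda x: f"{x:.3f}"))
print("\nselected threshold:", sv.select_optimal_threshold(scan))
# significance stays flat while nearly all pixels are retained, then drops
# sharply once thresholding strips the rarer categories: the scan selects
# (near) zero, i.e. "use all pixels".
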