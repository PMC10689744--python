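"""Per-pixel benthic classification with certainty values.

The primary classifier is a spectral-spatial residual network operating on
a small patch around each pixel: a 1x1 convolution first reduces the
spectral dimension, residual units then build spectral features pointwise,
a channel adjustment rescales the feature dimension, spatial residual
units (3x3 convolutions) build spatial features, and average pooling over
the window feeds a softmax classifier. Every prediction carries a
certainty value, defined as the maximum softmax probability.

A transparent spectral-angle mapper (SAM) is included as a reference
classifier for oracle comparisons and as a training-free fallback.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np

from . import nn
from .cube import HyperspectralCube
from .scene import SpectralLibrary
from .taxonomy import AnnotationSet

__all__ = [
    "UNCLASSIFIED",
    "PLATE",
    "SSRNConfig",
    "PredictionMap",
    "SSRNModel",
    "build_model",
    "train",
    "predict_map",
    "sam_classify",
    "save_model",
    "load_model",
]

UNCLASSIFIED = -1
PLATE = -2


@dataclass
class SSRNConfig:
    patch_size: int = 7
    reduced_channels: int = 24
    n_spectral_blocks: int = 2
    n_spatial_blocks: int = 2
    filters: int = 24
    epochs: int = 30
    batch_size: int = 256
    learning_rate: float = 1e-3
    early_stop_patience: int = 6
    class_weighting: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.patch_size < 3 or self.patch_size % 2 == 0:
            raise ValueError("patch_size must be odd and >= 3")
        for name in (
            "reduced_channels",
            "n_spectral_blocks",
            "n_spatial_blocks",
            "filters",
            "epochs",
            "batch_size",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


@dataclass
class PredictionMap:
    """Per-pixel predicted fine category with certainty in [0, 1].

    ``labels`` uses UNCLASSIFIED (-1) for pixels no class could be
    assigned to and PLATE (-2) for reference-plate pixels, which are
    excluded from all downstream cover accounting.
    """

    labels: np.ndarray
    certainty: np.ndarray
    threshold_applied: float = 0.0
    class_probabilities: Optional[np.ndarray] = None
    class_ids: Optional[List[int]] = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int32)
        self.certainty = np.asarray(self.certainty, dtype=np.float32)
        if self.labels.shape != self.certainty.shape:
            raise ValueError("labels and certainty must share shape")
        if self.certainty.size and (
            self.certainty.min() < -1e-6 or self.certainty.max() > 1 + 1e-6
        ):
            raise ValueError("certainty must lie in [0, 1]")
        if not (0.0 <= self.threshold_applied < 1.0):
            raise ValueError("threshold_applied must be in [0, 1)")


class SSRNModel:
    """Spectral-spatial residual network (numpy implementation)."""

    def __init__(self, config: SSRNConfig, n_bands: int, n_classes: int):
        if n_bands < 5:
            raise ValueError("need at least 5 bands")
        if n_classes < 2:
            raise ValueError("need at least 2 classes")
        self.config = config
        self.n_bands = n_bands
        self.n_classes = n_classes
        self.class_ids: List[int] = list(range(n_classes))
        self.feat_mean = np.zeros(n_bands, dtype=np.float32)
        self.feat_std = np.ones(n_bands, dtype=np.float32)
        rng = np.random.default_rng(config.seed)
        c, f = config.reduced_channels, config.filters
        p: nn.Params = {}
        p["red_w"] = nn.he_init(rng, (n_bands, c), n_bands)
        p["red_b"] = np.zeros(c, dtype=np.float32)
        for i in range(config.n_spectral_blocks):
            p[f"spec{i}_w1"] = nn.he_init(rng, (c, c), c)
            p[f"spec{i}_b1"] = np.zeros(c, dtype=np.float32)
            p[f"spec{i}_w2"] = nn.he_init(rng, (c, c), c)
            p[f"spec{i}_b2"] = np.zeros(c, dtype=np.float32)
        p["adj_w"] = nn.he_init(rng, (c, f), c)
        p["adj_b"] = np.zeros(f, dtype=np.float32)
        for i in range(config.n_spatial_blocks):
            p[f"spat{i}_w1"] = nn.he_init(rng, (9 * f, f), 9 * f)
            p[f"spat{i}_b1"] = np.zeros(f, dtype=np.float32)
            p[f"spat{i}_w2"] = nn.he_init(rng, (9 * f, f), 9 * f)
            p[f"spat{i}_b2"] = np.zeros(f, dtype=np.float32)
        p["out_w"] = nn.he_init(rng, (f, n_classes), f)
        p["out_b"] = np.zeros(n_classes, dtype=np.float32)
        self.params = p
        self.history: Dict[str, list] = {"train_loss": [], "val_accuracy": []}

    # -- forward / backward -------------------------------------------------

    def forward(self, x: np.ndarray, need_cache: bool = False):
        """Logits for a batch of patches (B, P, P, n_bands)."""
        cfg = self.config
        p = self.params
        cache: dict = {}
        z, _ = nn.pointwise(x, p["red_w"], p["red_b"])
        if need_cache:
            cache["x"] = x
        spec_caches = []
        for i in range(cfg.n_spectral_blocks):
            a1, m1 = nn.relu(z)
            h1, c1 = nn.pointwise(a1, p[f"spec{i}_w1"], p[f"spec{i}_b1"])
            a2, m2 = nn.relu(h1)
            h2, c2 = nn.pointwise(a2, p[f"spec{i}_w2"], p[f"spec{i}_b2"])
            z = z + h2
            if need_cache:
                spec_caches.append((m1, c1, m2, c2))
        aa, ma = nn.relu(z)
        z, cadj = nn.pointwise(aa, p["adj_w"], p["adj_b"])
        spat_caches = []
        for i in range(cfg.n_spatial_blocks):
            a1, m1 = nn.relu(z)
            h1, c1 = nn.conv3x3(a1, p[f"spat{i}_w1"], p[f"spat{i}_b1"])
            a2, m2 = nn.relu(h1)
            h2, c2 = nn.conv3x3(a2, p[f"spat{i}_w2"], p[f"spat{i}_b2"])
            z = z + h2
            if need_cache:
                spat_caches.append((m1, c1, m2, c2))
        pooled = z.mean(axis=(1, 2))
        logits = pooled @ p["out_w"] + p["out_b"]
        if need_cache:
            cache.update(
                spec=spec_caches,
                spat=spat_caches,
                ma=ma,
                cadj=cadj,
                pooled=pooled,
                patch_hw=z.shape[1:3],
            )
            return logits, cache
        return logits

    def backward(self, dlogits: np.ndarray, cache: dict) -> nn.Params:
        cfg = self.config
        p = self.params
        grads: nn.Params = {}
        pooled = cache["pooled"]
        grads["out_w"] = (pooled.T @ dlogits).astype(np.float32)
        grads["out_b"] = dlogits.sum(axis=0).astype(np.float32)
        dpooled = dlogits @ p["out_w"].T
        ph, pw = cache["patch_hw"]
        dz = np.broadcast_to(
            dpooled[:, None, None, :] / (ph * pw),
            (dlogits.shape[0], ph, pw, dpooled.shape[1]),
        ).astype(np.float32).copy()
        for i in reversed(range(cfg.n_spatial_blocks)):
            m1, c1, m2, c2 = cache["spat"][i]
            da2, dw2, db2 = nn.conv3x3_back(dz, c2, p[f"spat{i}_w2"])
            grads[f"spat{i}_w2"], grads[f"spat{i}_b2"] = dw2, db2
            dh1 = nn.relu_back(da2, m2)
            da1, dw1, db1 = nn.conv3x3_back(dh1, c1, p[f"spat{i}_w1"])
            grads[f"spat{i}_w1"], grads[f"spat{i}_b1"] = dw1, db1
            dz = dz + nn.relu_back(da1, m1)
        daa, dw, db = nn.pointwise_back(dz, cache["cadj"], p["adj_w"])
        grads["adj_w"], grads["adj_b"] = dw, db
        dz = nn.relu_back(daa, cache["ma"])
        for i in reversed(range(cfg.n_spectral_blocks)):
            m1, c1, m2, c2 = cache["spec"][i]
            da2, dw2, db2 = nn.pointwise_back(dz, c2, p[f"spec{i}_w2"])
            grads[f"spec{i}_w2"], grads[f"spec{i}_b2"] = dw2, db2
            dh1 = nn.relu_back(da2, m2)
            da1, dw1, db1 = nn.pointwise_back(dh1, c1, p[f"spec{i}_w1"])
            grads[f"spec{i}_w1"], grads[f"spec{i}_b1"] = dw1, db1
            dz = dz + nn.relu_back(da1, m1)
        _, dw, db = nn.pointwise_back(dz, cache["x"], p["red_w"])
        grads["red_w"], grads["red_b"] = dw, db
        return grads

    def predict_proba_patches(self, patches: np.ndarray) -> np.ndarray:
        return nn.softmax(self.forward(patches.astype(np.float32)))

    def checksum(self) -> float:
        return float(sum(np.abs(v).sum() for v in self.params.values()))


def build_model(config: SSRNConfig, n_bands: int, n_classes: int) -> SSRNModel:
    """Seeded construction of the spectral-spatial residual network."""
    return SSRNModel(config, n_bands, n_classes)


# ---------------------------------------------------------------------------
# patch extraction
# ---------------------------------------------------------------------------


def _padded(cube_data: np.ndarray, r: int) -> np.ndarray:
    return np.pad(cube_data, ((r, r), (r, r), (0, 0)), mode="reflect")


def extract_patches(
    data: np.ndarray, coords: np.ndarray, patch_size: int
) -> np.ndarray:
    """Patches centered at (row, col) coords with reflect border padding."""
    r = patch_size // 2
    padded = _padded(data, r)
    from numpy.lib.stride_tricks import sliding_window_view

    win = sliding_window_view(padded, (patch_size, patch_size), axis=(0, 1))
    # win shape: (H, W, bands, P, P)
    sel = win[coords[:, 0], coords[:, 1]]  # (N, bands, P, P)
    return np.ascontiguousarray(np.moveaxis(sel, 1, -1))  # (N, P, P, bands)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


def train(
    model: SSRNModel,
    cubes: Dict[str, HyperspectralCube] | HyperspectralCube,
    annotations: AnnotationSet,
    config: Optional[SSRNConfig] = None,
) -> SSRNModel:
    """Train on patches centered at annotated pixels (cross-entropy/Adam).

    ``cubes`` maps transect id -> cube (or a single cube for one-transect
    annotation sets). The annotation set must already carry a train/
    validation split. Per-epoch mean training loss and validation accuracy
    are recorded in ``model.history``; training stops early when
    validation accuracy plateaus. Deterministic given the config seed.
    """
    cfg = config or model.config
    if isinstance(cubes, HyperspectralCube):
        ids = set(r.transect_id for r in annotations.rois)
        cubes = {tid: cubes for tid in ids}
    if annotations.train_flag is None:
        raise ValueError("annotations must be split into train/validation first")

    table = annotations.pixel_table()
    for tid, cube in cubes.items():
        sub = table[table["transect"] == tid]
        if len(sub) and (
            sub["row"].max() >= cube.shape[0] or sub["col"].max() >= cube.shape[1]
        ):
            raise ValueError(f"annotations outside cube extent for transect {tid}")
        if cube.n_bands != model.n_bands:
            raise ValueError(
                f"cube has {cube.n_bands} bands, model expects {model.n_bands}"
            )
        if cfg.patch_size > min(cube.shape[0], cube.shape[1]):
            raise ValueError("patch larger than transect extent")

    train_tab = table[annotations.train_flag]
    val_tab = table[~annotations.train_flag]
    train_classes = sorted(train_tab["category"].unique().tolist())
    all_classes = sorted(table["category"].unique().tolist())
    absent = [c for c in all_classes if c not in train_classes]
    if absent:
        raise ValueError(f"classes absent from the train split: {absent}")
    if len(train_classes) < 2:
        raise ValueError("need at least 2 categories in the train split")
    if len(train_classes) != model.n_classes:
        raise ValueError(
            f"model built for {model.n_classes} classes but train split has "
            f"{len(train_classes)}"
        )
    model.class_ids = [int(c) for c in train_classes]
    class_index = {c: i for i, c in enumerate(model.class_ids)}

    # per-band standardization from the training pixels' center spectra
    center_spectra = []
    for tid, cube in cubes.items():
        sub = train_tab[train_tab["transect"] == tid]
        if len(sub):
            center_spectra.append(
                cube.radiance[sub["row"].to_numpy(), sub["col"].to_numpy()]
            )
    centers = np.concatenate(center_spectra, axis=0)
    model.feat_mean = centers.mean(axis=0).astype(np.float32)
    model.feat_std = np.clip(centers.std(axis=0), 1e-6, None).astype(np.float32)

    def load_split(tab) -> Tuple[np.ndarray, np.ndarray]:
        xs, ys = [], []
        for tid, cube in cubes.items():
            sub = tab[tab["transect"] == tid]
            if not len(sub):
                continue
            data = (cube.radiance - model.feat_mean) / model.feat_std
            coords = sub[["row", "col"]].to_numpy()
            xs.append(extract_patches(data, coords, cfg.patch_size))
            ys.append(sub["category"].map(class_index).to_numpy())
        return (
            np.concatenate(xs, axis=0).astype(np.float32),
            np.concatenate(ys, axis=0),
        )

    x_train, y_train = load_split(train_tab)
    x_val, y_val = (None, None)
    if len(val_tab):
        x_val, y_val = load_split(val_tab)

    weights = None
    if cfg.class_weighting:
        counts = np.bincount(y_train, minlength=model.n_classes).astype(float)
        weights = (counts.sum() / np.clip(counts, 1, None)).astype(np.float32)
        weights /= weights.mean()

    rng = np.random.default_rng(cfg.seed + 1)
    opt = nn.Adam(model.params, lr=cfg.learning_rate)
    n = len(y_train)
    best_val, best_params, stale = -np.inf, None, 0
    model.history = {"train_loss": [], "val_accuracy": []}
    for _epoch in range(cfg.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            logits, cache = model.forward(x_train[idx], need_cache=True)
            probs = nn.softmax(logits)
            loss, dlogits = nn.cross_entropy(probs, y_train[idx], weights)
            grads = model.backward(dlogits, cache)
            opt.step(model.params, grads)
            losses.append(loss)
        model.history["train_loss"].append(float(np.mean(losses)))
        if x_val is not None:
            val_acc = _batched_accuracy(model, x_val, y_val)
        else:
            val_acc = float("nan")
        model.history["val_accuracy"].append(val_acc)
        if x_val is not None:
            if val_acc > best_val + 1e-4:
                best_val = val_acc
                best_params = {k: v.copy() for k, v in model.params.items()}
                stale = 0
            else:
                stale += 1
                if stale >= cfg.early_stop_patience:
                    break
    if best_params is not None:
        model.params = best_params
    return model


def _batched_accuracy(model: SSRNModel, x: np.ndarray, y: np.ndarray, batch=1024) -> float:
    correct = 0
    for start in range(0, len(y), batch):
        logits = model.forward(x[start : start + batch])
        correct += int((logits.argmax(axis=1) == y[start : start + batch]).sum())
    return correct / len(y)


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------


def predict_map(
    model: SSRNModel,
    cube: HyperspectralCube,
    batch_size: int = 2048,
    store_probabilities: bool = False,
) -> PredictionMap:
    """Predict a label + certainty for every non-plate pixel of a cube.

    Certainty is the maximum softmax probability; plate pixels are labeled
    PLATE with certainty 0 and excluded downstream. Borders are handled by
    reflective padding. Deterministic.
    """
    if cube.n_bands != model.n_bands:
        raise ValueError(
            f"cube has {cube.n_bands} bands but model expects {model.n_bands}"
        )
    h, w = cube.shape[:2]
    p = model.config.patch_size
    r = p // 2
    data = ((cube.radiance - model.feat_mean) / model.feat_std).astype(np.float32)
    padded = _padded(data, r)
    from numpy.lib.stride_tricks import sliding_window_view

    win = sliding_window_view(padded, (p, p), axis=(0, 1))  # (H, W, B, P, P)

    labels = np.full((h, w), UNCLASSIFIED, dtype=np.int32)
    certainty = np.zeros((h, w), dtype=np.float32)
    probs_full = (
        np.zeros((h, w, model.n_classes), dtype=np.float32)
        if store_probabilities
        else None
    )
    class_arr = np.asarray(model.class_ids, dtype=np.int32)
    flat_idx = np.arange(h * w)
    for start in range(0, h * w, batch_size):
        idx = flat_idx[start : start + batch_size]
        rows, cols = np.unravel_index(idx, (h, w))
        patches = np.ascontiguousarray(np.moveaxis(win[rows, cols], 1, -1))
        probs = model.predict_proba_patches(patches)
        labels.ravel()[idx] = class_arr[probs.argmax(axis=1)]
        certainty.ravel()[idx] = probs.max(axis=1)
        if probs_full is not None:
            probs_full.reshape(-1, model.n_classes)[idx] = probs
    labels[cube.plate_mask] = PLATE
    certainty[cube.plate_mask] = 0.0
    return PredictionMap(
        labels=labels,
        certainty=certainty,
        threshold_applied=0.0,
        class_probabilities=probs_full,
        class_ids=list(model.class_ids),
    )


def sam_classify(cube: HyperspectralCube, library: SpectralLibrary) -> PredictionMap:
    """Spectral angle mapper: label = nearest endmember by spectral angle.

    angle(x, e) = arccos(<x, e> / (|x||e|)); certainty is
    1 - angle_min / angle_second_min clipped to [0, 1]. Zero-norm pixels
    are labeled UNCLASSIFIED with certainty 0.
    """
    if len(library.wavelengths_nm) != cube.n_bands or not np.allclose(
        library.wavelengths_nm, cube.wavelengths_nm
    ):
        raise ValueError("library endmembers must be on the cube's wavelength grid")
    cats = library.categories
    em = library.endmember_matrix(cats)
    em_n = em / np.linalg.norm(em, axis=1, keepdims=True)
    h, w = cube.shape[:2]
    x = cube.radiance.reshape(-1, cube.n_bands).astype(np.float64)
    norms = np.linalg.norm(x, axis=1)
    ok = norms > 0
    cos = np.zeros((x.shape[0], len(cats)))
    cos[ok] = (x[ok] / norms[ok, None]) @ em_n.T
    angles = np.arccos(np.clip(cos, -1.0, 1.0))

    labels = np.full(x.shape[0], UNCLASSIFIED, dtype=np.int32)
    certainty = np.zeros(x.shape[0], dtype=np.float32)
    if len(cats) >= 2:
        part = np.partition(angles[ok], 1, axis=1)
        a1, a2 = part[:, 0], part[:, 1]
        cert_ok = np.where(a2 > 0, 1.0 - a1 / np.where(a2 == 0, 1.0, a2), 0.0)
    else:  # pragma: no cover - library enforces >= 2 categories
        a1 = angles[ok][:, 0]
        cert_ok = np.ones_like(a1)
    labels[ok] = np.asarray(cats, dtype=np.int32)[angles[ok].argmin(axis=1)]
    certainty[ok] = np.clip(cert_ok, 0.0, 1.0)

    labels = labels.reshape(h, w)
    certainty = certainty.reshape(h, w)
    labels[cube.plate_mask] = PLATE
    certainty[cube.plate_mask] = 0.0
    return PredictionMap(labels=labels, certainty=certainty, class_ids=list(cats))


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------


def save_model(model: SSRNModel, path: str | Path) -> Path:
    path = Path(path)
    meta = {
        "config": asdict(model.config),
        "n_bands": model.n_bands,
        "n_classes": model.n_classes,
        "class_ids": model.class_ids,
        "history": model.history,
    }
    np.savez(
        path,
        __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
        feat_mean=model.feat_mean,
        feat_std=model.feat_std,
        **model.params,
    )
    return path if path.suffix == ".npz" else Path(str(path) + ".npz")


def load_model(path: str | Path) -> SSRNModel:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        model = SSRNModel(
            SSRNConfig(**meta["config"]), meta["n_bands"], meta["n_classes"]
        )
        model.class_ids = [int(c) for c in meta["class_ids"]]
        model.history = meta["history"]
        model.feat_mean = data["feat_mean"]
        model.feat_std = data["feat_std"]
        for k in model.params:
            model.params[k] = data[k]
    return model
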