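"""Candidate-object classification: Daphnia vs. noise.

Each candidate's bounding-box crop is resized to 8x8 by exact area
averaging, normalized to [0, 1], and transformed into a 64-vector of
Sobel gradient magnitudes. A random forest (default) or an RBF support
vector machine is trained on a labelled patch database and applied per
frame; only objects predicted as Daphnia are passed on to the tracker.

Confusion-matrix metrics use the standard definitions:

    accuracy  = (TP + TN) / (TP + TN + FP + FN)
    recall    = TP / (TP + FN)
    precision = TP / (TP + FP)
    F1        = 2 * precision * recall / (precision + recall)

Undefined ratios (zero denominators) are reported as ``None`` rather
than silently as 0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

DAPHNIA = "daphnia"
NOISE = "noise"

PATCH_SIZE = 8


# ---------------------------------------------------------------------------
# patch extraction


def _interval_weights(n_in: int, n_out: int) -> np.ndarray:
    """(n_out, n_in) row-stochastic matrix averaging input cells over
    equal-length output intervals, with fractional coverage at the edges."""
    W = np.zeros((n_out, n_in))
    scale = n_in / n_out
    for i in range(n_out):
        lo, hi = i * scale, (i + 1) * scale
        j0, j1 = int(np.floor(lo)), int(np.ceil(hi))
        for j in range(j0, min(j1, n_in)):
            overlap = min(hi, j + 1) - max(lo, j)
            if overlap > 0:
                W[i, j] = overlap
    W /= W.sum(axis=1, keepdims=True)
    return W


def area_average_resize(img: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Resize by exact area averaging (each output pixel is the mean of the
    source region it covers). Separable: rows then columns."""
    img = np.asarray(img, dtype=np.float64)
    Wr = _interval_weights(img.shape[0], shape[0])
    Wc = _interval_weights(img.shape[1], shape[1])
    return Wr @ img @ Wc.T


def extract_patch(frame: np.ndarray, obj) -> np.ndarray:
    """Crop an object's bbox from the frame and resize to 8x8 in [0, 1].

    ``obj`` may be a CandidateObject or a bare (x, y, w, h) tuple.
    """
    bbox = obj.bbox if hasattr(obj, "bbox") else tuple(obj)
    x, y, w, h = (int(round(v)) for v in bbox)
    if w <= 0 or h <= 0:
        raise ValueError(f"degenerate bbox {bbox}")
    frame = np.asarray(frame, dtype=np.float64)
    H, W = frame.shape
    if x < 0 or y < 0 or x + w > W or y + h > H:
        raise ValueError(f"bbox {bbox} outside frame {frame.shape}")
    crop = frame[y : y + h, x : x + w] / 255.0
    if crop.shape == (PATCH_SIZE, PATCH_SIZE):
        return crop.copy()
    return area_average_resize(crop, (PATCH_SIZE, PATCH_SIZE))


# ---------------------------------------------------------------------------
# features


def sobel_features(patch: np.ndarray) -> np.ndarray:
    """Per-pixel Sobel gradient magnitude of an 8x8 patch, flattened row-major.

    Standard 3x3 Sobel kernels with edge replication at the borders;
    magnitude = sqrt(Gx^2 + Gy^2). A constant patch maps to the zero vector.
    """
    patch = np.asarray(patch, dtype=np.float64)
    if patch.shape != (PATCH_SIZE, PATCH_SIZE):
        raise ValueError(f"expected {PATCH_SIZE}x{PATCH_SIZE} patch, got {patch.shape}")
    gx = ndimage.sobel(patch, axis=1, mode="nearest")
    gy = ndimage.sobel(patch, axis=0, mode="nearest")
    return np.sqrt(gx**2 + gy**2).ravel()


def sobel_features_xy(patch: np.ndarray) -> np.ndarray:
    """128-dim variant: signed Gx and Gy responses concatenated."""
    patch = np.asarray(patch, dtype=np.float64)
    gx = ndimage.sobel(patch, axis=1, mode="nearest")
    gy = ndimage.sobel(patch, axis=0, mode="nearest")
    return np.concatenate([gx.ravel(), gy.ravel()])


def features_from_patches(patches: np.ndarray, feature_set: str = "magnitude") -> np.ndarray:
    fn = sobel_features if feature_set == "magnitude" else sobel_features_xy
    return np.array([fn(p) for p in patches])


# ---------------------------------------------------------------------------
# model


@dataclass
class ClassifierModel:
    """A fitted Daphnia/noise classifier plus the metadata to rebuild it."""

    method: str  # "rf" | "svm"
    estimator: object
    seed: int | None
    feature_set: str = "magnitude"
    hyperparams: dict = field(default_factory=dict)
    decision_threshold: float = 0.5

    def score(self, features: np.ndarray) -> np.ndarray:
        """P(daphnia) in [0, 1] for each feature row."""
        X = np.atleast_2d(np.asarray(features, dtype=np.float64))
        proba = self.estimator.predict_proba(X)
        idx = list(self.estimator.classes_).index(DAPHNIA)
        return proba[:, idx]

    def predict(self, features: np.ndarray) -> np.ndarray:
        s = self.score(features)
        return np.where(s >= self.decision_threshold, DAPHNIA, NOISE)


_DEFAULT_RF = dict(n_estimators=100, criterion="gini", max_features="sqrt")
_DEFAULT_SVM = dict(kernel="rbf", C=1.0)


def train_classifier(
    features: np.ndarray,
    labels,
    method: str = "rf",
    hyperparams: dict | None = None,
    seed: int | None = 0,
) -> ClassifierModel:
    """Fit a random forest or SVM on labelled Sobel-feature vectors.

    Both classes must be present; refitting with the same data and seed
    reproduces predictions exactly.
    """
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.svm import SVC

    X = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels)
    classes = set(np.unique(y))
    if classes != {DAPHNIA, NOISE}:
        raise ValueError(f"training set must contain both classes, got {sorted(classes)}")

    method = method.lower()
    if method == "rf":
        hp = {**_DEFAULT_RF, **(hyperparams or {})}
        est = RandomForestClassifier(random_state=seed, **hp)
    elif method == "svm":
        hp = {**_DEFAULT_SVM, **(hyperparams or {})}
        est = SVC(probability=True, random_state=seed, **hp)
    else:
        raise ValueError(f"unknown method {method!r} (expected 'rf' or 'svm')")
    est.fit(X, y)
    return ClassifierModel(method=method, estimator=est, seed=seed, hyperparams=hp)


def classify_objects(model: ClassifierModel, frame: np.ndarray, objects, feature_set: str | None = None):
    """Return the Daphnia-labelled subset of candidates with their scores.

    Noise-labelled candidates are discarded. Output: list of
    (CandidateObject, score) pairs in input order.
    """
    if not objects:
        return []
    fs = feature_set or model.feature_set
    patches = [extract_patch(frame, o) for o in objects]
    X = features_from_patches(np.array(patches), fs)
    scores = model.score(X)
    return [(o, float(s)) for o, s in zip(objects, scores) if s >= model.decision_threshold]


def save_model(model: ClassifierModel, path: str | Path) -> None:
    """Persist the fitted estimator plus a JSON metadata sidecar."""
    import joblib

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    joblib.dump(model.estimator, path)
    meta = {
        "method": model.method,
        "seed": model.seed,
        "feature_set": model.feature_set,
        "hyperparams": model.hyperparams,
        "decision_threshold": model.decision_threshold,
    }
    path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(meta, indent=2))


def load_model(path: str | Path) -> ClassifierModel:
    import joblib

    path = Path(path)
    est = joblib.load(path)
    meta = json.loads(path.with_suffix(path.suffix + ".meta.json").read_text())
    return ClassifierModel(
        method=meta["method"],
        estimator=est,
        seed=meta["seed"],
        feature_set=meta["feature_set"],
        hyperparams=meta["hyperparams"],
        decision_threshold=meta["decision_threshold"],
    )


# ---------------------------------------------------------------------------
# patch database on disk


def save_patch_db(patches: np.ndarray, labels, out_dir: str | Path) -> Path:
    """Write patches as per-class 8x8 PNGs plus a CSV manifest (filename,label)."""
    import imageio.v3 as iio

    out = Path(out_dir)
    rows = []
    counters: dict[str, int] = {}
    for patch, label in zip(patches, labels):
        counters[label] = counters.get(label, 0) + 1
        d = out / label
        d.mkdir(parents=True, exist_ok=True)
        name = f"{label}/{counters[label]:05d}.png"
        iio.imwrite(out / name, np.clip(np.asarray(patch) * 255, 0, 255).astype(np.uint8))
        rows.append(f"{name},{label}")
    manifest = out / "manifest.csv"
    manifest.write_text("filename,label\n" + "\n".join(rows) + "\n")
    return manifest


def load_patch_db(manifest: str | Path) -> tuple[np.ndarray, np.ndarray]:
    import imageio.v3 as iio

    manifest = Path(manifest)
    root = manifest.parent
    patches, labels = [], []
    for line in manifest.read_text().splitlines()[1:]:
        if not line.strip():
            continue
        name, label = line.rsplit(",", 1)
        patches.append(np.asarray(iio.imread(root / name), dtype=np.float64) / 255.0)
        labels.append(label)
    return np.array(patches), np.array(labels)


# ---------------------------------------------------------------------------
# confusion metrics


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion counts with derived metrics (None when undefined)."""

    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def accuracy(self) -> float | None:
        return (self.tp + self.tn) / self.total if self.total else None

    @property
    def recall(self) -> float | None:
        d = self.tp + self.fn
        return self.tp / d if d else None

    @property
    def precision(self) -> float | None:
        d = self.tp + self.fp
        return self.tp / d if d else None

    @property
    def f1(self) -> float | None:
        p, r = self.precision, self.recall
        if p is None or r is None or p + r == 0:
            return None
        return 2 * p * r / (p + r)


def confusion_metrics(pred_labels, true_labels, positive: str = DAPHNIA) -> ConfusionCounts:
    """Count TP/TN/FP/FN for equal-length label sequences."""
    pred = np.asarray(pred_labels)
    true = np.asarray(true_labels)
    if pred.size == 0:
        raise ValueError("empty label sequences")
    if pred.shape != true.shape:
        raise ValueError("label sequences differ in length")
    p = pred == positive
    t = true == positive
    return ConfusionCounts(
        tp=int(np.sum(p & t)),
        tn=int(np.sum(~p & ~t)),
        fp=int(np.sum(p & ~t)),
        fn=int(np.sum(~p & t)),
    )


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall."""
    if precision + recall == 0:
        raise ValueError("precision + recall is zero; F1 undefined")
    return 2 * precision * recall / (precision + recall)
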