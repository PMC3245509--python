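"""Random-forest motion prediction from encoded sequence windows.

Three classifiers — one per window-location category (CS, PS, RS) — are
trained to assign windows to the flexible/intermediate/rigid classes. At
prediction time the predicted class is converted to a continuous score
through the per-(category, class) statistics of the normalized NMA score:

    score = avg + SD × z

with z = 0 by default (the cell mean; an "expected-score" policy using the
forest's vote fractions is also available). Scores are smoothed with a
five-residue moving average. External motion uses two sub-models trained on
short (≤ 9 residues) versus long flexible runs, combined wherever the long
model predicts a flexible run of more than 9 residues. Regions of three or
more consecutive residues with smoothed score above 1 are reported as
high-motion (conformational-change candidate) regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .annotations import AnnotatedSequence
from .dataset import (
    CATEGORIES,
    ClassStats,
    WindowLabel,
    assign_window_labels,
    category_score_stats,
    class_statistics,
    ss_category,
)
from .features import FeatureTable, build_feature_table, encode_sequence, variable_names
from . import dataset as _dataset

__all__ = [
    "TrainConfig",
    "MotionModel",
    "PredictionResult",
    "Region",
    "train_motion_model",
    "train_from_corpus",
    "prepare_training_data",
    "class_to_score",
    "predict_profile",
    "predict_external",
    "smooth_scores",
    "combine_external",
    "extract_flexible_regions",
    "variable_importance",
    "save_models",
    "load_models",
]

MOTION_TYPES = ("internal", "external_short", "external_long")
DEFAULT_WINDOW = {"internal": 11, "external_short": 17, "external_long": 17}


@dataclass
class TrainConfig:
    """Random-forest and scoring configuration.

    ntree/mtry/nodesize mirror the classification defaults of the classical
    randomForest implementation: 500 trees, sqrt(p) candidate variables per
    split, minimum node size 1.
    """

    ntree: int = 500
    mtry: int | str = "sqrt"
    nodesize: int = 1
    seed: int = 0
    z_policy: str = "mean"      # "mean" (z = 0) or "expected" (vote-weighted)
    z: float = 0.0
    oob: bool = False


@dataclass
class MotionModel:
    """Per-category classifiers plus everything needed to score a sequence."""

    motion_type: str
    window_size: int
    classifiers: dict[str, RandomForestClassifier]
    class_stats: ClassStats
    feature_table: FeatureTable
    config: TrainConfig
    variable_names: list[str] = field(default_factory=list)

    @property
    def model_id(self) -> str:
        return f"{self.motion_type}-w{self.window_size}-seed{self.config.seed}"


def class_to_score(
    stats: ClassStats, category: str, cls: str, z: float = 0.0
) -> float:
    """Convert a predicted class to a continuous score: avg + SD × z."""
    return stats.score(category, cls, z)


def train_motion_model(
    x: np.ndarray,
    categories: np.ndarray,
    classes: np.ndarray,
    motion_type: str,
    class_stats: ClassStats,
    feature_table: FeatureTable,
    window_size: int | None = None,
    config: TrainConfig | None = None,
    run_lengths: np.ndarray | None = None,
) -> MotionModel:
    """Train one classifier per category on encoded windows.

    For the external sub-models, flexible-class windows are filtered by the
    length of the y > 1 run they belong to (``run_lengths``): external_short
    keeps runs of ≤ 9 residues, external_long keeps longer runs; the other
    classes are shared.
    """
    if motion_type not in MOTION_TYPES:
        raise ValueError(f"motion_type must be one of {MOTION_TYPES}")
    config = config or TrainConfig()
    window_size = window_size or DEFAULT_WINDOW[motion_type]
    categories = np.asarray(categories)
    classes = np.asarray(classes)

    keep = np.ones(len(x), dtype=bool)
    if motion_type != "internal":
        if run_lengths is None:
            raise ValueError(f"{motion_type} training requires run_lengths")
        run_lengths = np.asarray(run_lengths)
        is_flex = classes == "flexible"
        if motion_type == "external_short":
            keep = ~is_flex | (run_lengths <= 9)
        else:
            keep = ~is_flex | (run_lengths > 9)

    classifiers: dict[str, RandomForestClassifier] = {}
    for ci, cat in enumerate(CATEGORIES):
        sel = keep & (categories == cat)
        if not sel.any():
            raise ValueError(f"no training windows in category {cat}")
        y = classes[sel]
        big = [c for c in set(y) if (y == c).sum() >= 10]
        if len(big) < 2:
            raise ValueError(
                f"category {cat} of {motion_type}: fewer than 2 classes with "
                f"≥ 10 windows (counts: { {c: int((y == c).sum()) for c in set(y)} })"
            )
        clf = RandomForestClassifier(
            n_estimators=config.ntree,
            max_features=config.mtry,
            min_samples_leaf=config.nodesize,
            random_state=config.seed + ci,
            oob_score=config.oob,
            n_jobs=1,
        )
        clf.fit(x[sel], y)
        classifiers[cat] = clf

    return MotionModel(
        motion_type=motion_type,
        window_size=window_size,
        classifiers=classifiers,
        class_stats=class_stats,
        feature_table=feature_table,
        config=config,
        variable_names=variable_names(window_size),
    )


def prepare_training_data(
    corpus,
    motion_type: str,
    window_size: int | None = None,
    asa_thresholds: tuple[float, float] = (11.0, 27.0),
):
    """Turn a synthetic corpus into encoded windows with labels.

    Runs the full labeling pipeline: per-chain normalized profiles →
    corpus-wide mobility propensities → feature table → corpus-wide
    per-category score statistics → window labels → encoded matrices.

    Returns a dict with keys x, categories, classes, run_lengths,
    class_stats, feature_table, labels, chain_slices.
    """
    window_size = window_size or DEFAULT_WINDOW[motion_type]
    profiles = [c.normalized(motion_type) for c in corpus.chains]

    sequences = [c.annotated.sequence for c in corpus.chains]
    groups = [
        _dataset.assign_mobility_groups(p.scores) for p in profiles
    ]
    propensity = _dataset.compute_mobility_propensity(sequences, groups)
    table = build_feature_table(propensity, asa_thresholds)

    all_cats = np.concatenate(
        [ss_category(c.annotated.ss) for c in corpus.chains]
    )
    all_scores = np.concatenate([p.scores for p in profiles])
    cat_stats = category_score_stats(all_cats, all_scores)

    xs, cats, clss, runs, labels_all, slices = [], [], [], [], [], []
    pos = 0
    for chain, prof in zip(corpus.chains, profiles):
        labels = assign_window_labels(
            chain.annotated, prof, window_size, cat_stats
        )
        x, centers = encode_sequence(chain.annotated, window_size, table)
        by_center = {int(c): i for i, c in enumerate(centers)}
        rows = [by_center[lab.center] for lab in labels]
        xs.append(x[rows])
        cats.extend(lab.category for lab in labels)
        clss.extend(lab.cls for lab in labels)
        runs.extend(lab.flexible_run_length for lab in labels)
        labels_all.append(labels)
        slices.append((pos, pos + len(labels)))
        pos += len(labels)

    all_labels = [lab for chain_labels in labels_all for lab in chain_labels]
    return {
        "x": np.concatenate(xs),
        "categories": np.array(cats),
        "classes": np.array(clss),
        "run_lengths": np.array(runs),
        "class_stats": class_statistics(all_labels),
        "feature_table": table,
        "labels": labels_all,
        "chain_slices": slices,
        "category_stats": cat_stats,
    }


def train_from_corpus(
    corpus,
    motion_type: str,
    window_size: int | None = None,
    config: TrainConfig | None = None,
    asa_thresholds: tuple[float, float] = (11.0, 27.0),
) -> MotionModel:
    """End-to-end training on a synthetic corpus for one motion type."""
    data = prepare_training_data(corpus, motion_type, window_size, asa_thresholds)
    return train_motion_model(
        data["x"],
        data["categories"],
        data["classes"],
        motion_type,
        data["class_stats"],
        data["feature_table"],
        window_size=window_size or DEFAULT_WINDOW[motion_type],
        config=config,
        run_lengths=data["run_lengths"],
    )


@dataclass
class PredictionResult:
    """Per-residue prediction output for one motion model."""

    residue_ids: np.ndarray
    categories: np.ndarray
    classes: np.ndarray
    raw: np.ndarray
    smoothed: np.ndarray
    mask: np.ndarray
    model_id: str = ""
    seed: int = 0

    def __len__(self) -> int:
        return len(self.raw)


def smooth_scores(
    raw: np.ndarray, window: int = 5, mask: np.ndarray | None = None
) -> np.ndarray:
    """Centered moving average; masked residues are excluded from both the
    numerator and the denominator, and the window shrinks at the termini."""
    if window % 2 == 0:
        raise ValueError("smoothing window must be odd")
    raw = np.asarray(raw, dtype=float)
    n = len(raw)
    if mask is None:
        mask = np.isfinite(raw)
    else:
        mask = np.asarray(mask, dtype=bool) & np.isfinite(raw)
    half = window // 2
    out = np.full(n, np.nan)
    for i in range(n):
        if not mask[i]:
            continue
        lo, hi = max(0, i - half), min(n, i + half + 1)
        vals = raw[lo:hi][mask[lo:hi]]
        out[i] = vals.mean()
    return out


def predict_profile(
    annotated: AnnotatedSequence, model: MotionModel
) -> PredictionResult:
    """Predict per-residue motion scores for an annotated sequence."""
    n = len(annotated)
    x, centers = encode_sequence(annotated, model.window_size, model.feature_table)
    cats = ss_category(annotated.ss)

    classes = np.full(n, "", dtype="U12")
    raw = np.full(n, np.nan)
    mask = np.zeros(n, dtype=bool)
    stats = model.class_stats
    z = model.config.z if model.config.z_policy == "mean" else None

    for cat in CATEGORIES:
        sel = np.array([cats[c] == cat for c in centers])
        if not sel.any():
            continue
        clf = model.classifiers[cat]
        rows = x[sel]
        pred = clf.predict(rows)
        idx = centers[sel]
        classes[idx] = pred
        if model.config.z_policy == "expected":
            proba = clf.predict_proba(rows)
            cell_means = np.array(
                [stats.stats.get((cat, c), (np.nan, 0.0))[0] for c in clf.classes_]
            )
            raw[idx] = proba @ cell_means
        else:
            raw[idx] = [class_to_score(stats, cat, p, z) for p in pred]
        mask[idx] = True

    smoothed = smooth_scores(raw, window=5, mask=mask)
    return PredictionResult(
        residue_ids=annotated.residue_ids.copy(),
        categories=cats,
        classes=classes,
        raw=raw,
        smoothed=smoothed,
        mask=mask,
        model_id=model.model_id,
        seed=model.config.seed,
    )


def combine_external(
    short_result: PredictionResult, long_result: PredictionResult
) -> PredictionResult:
    """Merge the external sub-models' outputs.

    The short model's result is the default; wherever the long model
    predicts a maximal flexible run longer than 9 residues, those residues
    take the long model's scores and classes. Idempotent, and a no-op when
    no long flexible run exists.
    """
    if len(short_result) != len(long_result):
        raise ValueError("prediction length mismatch between sub-models")
    n = len(short_result)
    take_long = np.zeros(n, dtype=bool)
    i = 0
    flex = long_result.classes == "flexible"
    while i < n:
        if flex[i]:
            j = i
            while j < n and flex[j]:
                j += 1
            if j - i > 9:
                take_long[i:j] = True
            i = j
        else:
            i += 1

    out = PredictionResult(
        residue_ids=short_result.residue_ids.copy(),
        categories=short_result.categories.copy(),
        classes=short_result.classes.copy(),
        raw=short_result.raw.copy(),
        smoothed=short_result.smoothed.copy(),
        mask=short_result.mask.copy(),
        model_id=f"{short_result.model_id}+{long_result.model_id}",
        seed=short_result.seed,
    )
    out.classes[take_long] = long_result.classes[take_long]
    out.raw[take_long] = long_result.raw[take_long]
    out.smoothed[take_long] = long_result.smoothed[take_long]
    return out


def predict_external(
    annotated: AnnotatedSequence,
    short_model: MotionModel,
    long_model: MotionModel,
) -> PredictionResult:
    """Run both external sub-models and combine their results."""
    return combine_external(
        predict_profile(annotated, short_model),
        predict_profile(annotated, long_model),
    )


@dataclass
class Region:
    """1-based inclusive residue range of consecutive high scores."""

    start: int
    end: int
    mean_score: float

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def extract_flexible_regions(
    scores,
    threshold: float = 1.0,
    min_len: int = 3,
    mask: np.ndarray | None = None,
    residue_ids: np.ndarray | None = None,
) -> list[Region]:
    """Maximal runs of ≥ min_len consecutive residues with score > threshold.

    Accepts a plain score array or a :class:`PredictionResult` (whose
    smoothed scores, mask and residue ids are then used). Coordinates are
    1-based inclusive.
    """
    if isinstance(scores, PredictionResult):
        residue_ids = scores.residue_ids
        mask = scores.mask
        scores = scores.smoothed
    scores = np.asarray(scores, dtype=float)
    n = len(scores)
    if mask is None:
        mask = np.ones(n, dtype=bool)
    if residue_ids is None:
        residue_ids = np.arange(1, n + 1)
    with np.errstate(invalid="ignore"):
        above = mask & (np.nan_to_num(scores, nan=-np.inf) > threshold)
    regions = []
    i = 0
    while i < n:
        if above[i]:
            j = i
            while j < n and above[j]:
                j += 1
            if j - i >= min_len:
                regions.append(
                    Region(
                        start=int(residue_ids[i]),
                        end=int(residue_ids[j - 1]),
                        mean_score=float(scores[i:j].mean()),
                    )
                )
            i = j
        else:
            i += 1
    return regions


def variable_importance(
    model: MotionModel, top_k: int | None = None
) -> list[tuple[str, float]]:
    """Impurity-based variable importances, averaged over the three
    category classifiers and ranked in decreasing order."""
    imp = np.mean(
        [clf.feature_importances_ for clf in model.classifiers.values()], axis=0
    )
    order = np.argsort(imp)[::-1]
    if top_k is not None:
        order = order[:top_k]
    names = model.variable_names
    return [(names[i], float(imp[i])) for i in order]


def save_models(models: dict[str, MotionModel], path) -> None:
    """Persist one or more motion models in a single bundle file."""
    joblib.dump({"format": "flexmotion-model", "version": 1, "models": models}, path)


def load_models(path) -> dict[str, MotionModel]:
    bundle = joblib.load(path)
    if not isinstance(bundle, dict) or bundle.get("format") != "flexmotion-model":
        raise ValueError(f"{path} is not a flexmotion model bundle")
    return bundle["models"]
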