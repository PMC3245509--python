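"""Normalization, mobility propensities, and training-label assignment.

Raw per-residue motion magnitudes are not comparable across chains (chain
size and packing set the absolute scale), so each chain's profile is
z-normalized:

    y_i = (y'_i − ȳ) / s,   i = 1..M

with ȳ and s the per-chain sample mean and standard deviation. The
normalized score drives everything downstream: mobility groups (y > 1 high,
y < −1 low, otherwise normal), the log2 mobility-propensity table, and the
flexible/intermediate/rigid class labels.

Window labels combine a *category* — where the window center sits relative
to secondary structure (CS: deep inside an ss run; RS: deep inside a non-ss
run; PS: near a boundary) — with a *class* from the normalized score relative
to the per-category mean ± 1 SD.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .annotations import AnnotatedSequence

__all__ = [
    "NormalizedProfile",
    "MobilityPropensityTable",
    "WindowLabel",
    "ClassStats",
    "normalize_scores",
    "assign_mobility_groups",
    "compute_mobility_propensity",
    "ss_category",
    "assign_window_labels",
    "category_score_stats",
    "class_statistics",
    "run_length_distribution",
    "flexible_run_lengths",
    "AMINO_ACIDS",
    "CATEGORIES",
    "CLASSES",
    "MOBILITY_GROUPS",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
CATEGORIES = ("CS", "PS", "RS")
CLASSES = ("flexible", "intermediate", "rigid")
MOBILITY_GROUPS = ("high_mob", "normal_mob", "low_mob")


@dataclass
class NormalizedProfile:
    """Per-chain z-normalized motion scores for one motion type."""

    scores: np.ndarray
    mask: np.ndarray
    chain_mean: float
    chain_sd: float

    def __len__(self) -> int:
        return len(self.scores)


def normalize_scores(
    raw: np.ndarray, mask: np.ndarray | None = None
) -> NormalizedProfile:
    """Z-normalize a raw motion profile over its valid residues.

    Uses the sample standard deviation (ddof = 1). Masked residues stay
    masked and carry NaN scores.
    """
    raw = np.asarray(raw, dtype=float)
    if mask is None:
        mask = np.ones(len(raw), dtype=bool)
    else:
        mask = np.asarray(mask, dtype=bool)
    valid = raw[mask]
    if len(valid) < 2:
        raise ValueError("need at least 2 valid residues to normalize")
    mean = float(valid.mean())
    sd = float(valid.std(ddof=1))
    if sd == 0.0:
        raise ValueError("degenerate profile: zero variance")
    scores = np.full(len(raw), np.nan)
    scores[mask] = (raw[mask] - mean) / sd
    return NormalizedProfile(scores=scores, mask=mask, chain_mean=mean, chain_sd=sd)


def assign_mobility_groups(scores: np.ndarray) -> np.ndarray:
    """Map normalized scores to mobility groups.

    y > 1 → high_mob; y < −1 → low_mob; otherwise (boundaries included)
    normal_mob. NaN scores map to the empty string.
    """
    scores = np.asarray(scores, dtype=float)
    groups = np.full(len(scores), "", dtype="U10")
    with np.errstate(invalid="ignore"):
        groups[scores > 1] = "high_mob"
        groups[scores < -1] = "low_mob"
        groups[(scores >= -1) & (scores <= 1)] = "normal_mob"
    return groups


@dataclass
class MobilityPropensityTable:
    """log2 mobility propensities and the six derived binary features.

    ``prop[n][g]`` = log2(freq(n,g) / Σ_g freq(n,g)) where freq(n,g) is the
    relative frequency of amino acid n within mobility group g. For each
    group, amino acids whose propensity lies more than one SD above (below)
    the mean of the 20 propensities get the ``<g>_high`` (``<g>_low``)
    feature set to 1.
    """

    prop: dict[str, dict[str, float]]
    features: dict[str, dict[str, int]]
    counts: dict[str, dict[str, float]] = field(default_factory=dict)

    FEATURE_NAMES = (
        "high_mob_high", "high_mob_low",
        "nor_mob_high", "nor_mob_low",
        "low_mob_high", "low_mob_low",
    )

    def feature_vector(self, aa: str) -> np.ndarray:
        """Six 0/1 mobility features for one amino acid (zeros if unknown)."""
        if aa not in self.features:
            return np.zeros(6, dtype=int)
        f = self.features[aa]
        return np.array([f[name] for name in self.FEATURE_NAMES], dtype=int)


_GROUP_TO_PREFIX = {"high_mob": "high_mob", "normal_mob": "nor_mob", "low_mob": "low_mob"}


def compute_mobility_propensity(
    sequences: list[str],
    groups: list[np.ndarray],
    pseudo_count: str | float = "auto",
) -> MobilityPropensityTable:
    """Build the mobility-propensity table from a labeled corpus.

    Parameters
    ----------
    sequences, groups
        Parallel lists: amino acid string and per-residue mobility group
        (empty string entries are skipped).
    pseudo_count
        "auto" adds 1 to every count only if some (amino acid, group) cell
        is empty — needed on small corpora to keep the log finite; a float
        forces that pseudo-count; 0 disables it.
    """
    if not sequences:
        raise ValueError("empty corpus")
    counts = {n: dict.fromkeys(MOBILITY_GROUPS, 0.0) for n in AMINO_ACIDS}
    for seq, grp in zip(sequences, groups):
        for aa, g in zip(seq, grp):
            if g and aa in counts:
                counts[aa][g] += 1
    if pseudo_count == "auto":
        has_zero = any(
            counts[n][g] == 0 for n in AMINO_ACIDS for g in MOBILITY_GROUPS
        )
        pc = 1.0 if has_zero else 0.0
    else:
        pc = float(pseudo_count)
    if pc:
        for n in AMINO_ACIDS:
            for g in MOBILITY_GROUPS:
                counts[n][g] += pc

    group_totals = {
        g: sum(counts[n][g] for n in AMINO_ACIDS) for g in MOBILITY_GROUPS
    }
    if any(t == 0 for t in group_totals.values()):
        raise ValueError("a mobility group is empty; use a pseudo-count")

    prop: dict[str, dict[str, float]] = {}
    for n in AMINO_ACIDS:
        freq = {g: counts[n][g] / group_totals[g] for g in MOBILITY_GROUPS}
        total = sum(freq.values())
        prop[n] = {g: float(np.log2(freq[g] / total)) for g in MOBILITY_GROUPS}

    features = {n: {} for n in AMINO_ACIDS}
    for g in MOBILITY_GROUPS:
        vals = np.array([prop[n][g] for n in AMINO_ACIDS])
        mean, sd = vals.mean(), vals.std(ddof=1)
        prefix = _GROUP_TO_PREFIX[g]
        for n, v in zip(AMINO_ACIDS, vals):
            features[n][f"{prefix}_high"] = int(v > mean + sd)
            features[n][f"{prefix}_low"] = int(v < mean - sd)
    return MobilityPropensityTable(prop=prop, features=features, counts=counts)


def _runs(mask: np.ndarray) -> list[tuple[int, int, bool]]:
    """Maximal runs of a boolean mask as (start, stop, value), stop exclusive."""
    out = []
    start = 0
    for i in range(1, len(mask) + 1):
        if i == len(mask) or mask[i] != mask[start]:
            out.append((start, i, bool(mask[start])))
            start = i
    return out


def ss_category(ss: str) -> np.ndarray:
    """Per-residue window-location category from the ss string.

    CS: inside a secondary-structure run (H or E), ≥ 3 residues from both
    run ends; RS: inside a non-ss run, ≥ 3 residues from both run ends;
    PS: everything else.
    """
    is_ss = np.array([c in "HE" for c in ss])
    cats = np.full(len(ss), "PS", dtype="U2")
    for start, stop, val in _runs(is_ss):
        for i in range(start, stop):
            if i - start >= 3 and stop - 1 - i >= 3:
                cats[i] = "CS" if val else "RS"
    return cats


@dataclass
class WindowLabel:
    center: int          # 0-based residue index of the window center
    category: str        # CS / PS / RS
    cls: str             # flexible / intermediate / rigid
    score: float         # normalized NMA score of the center residue
    flexible_run_length: int = 0  # length of the y > 1 run containing center


def category_score_stats(
    categories: np.ndarray, scores: np.ndarray
) -> dict[str, tuple[float, float]]:
    """Per-category (mean, sample SD) of the normalized scores."""
    out = {}
    categories = np.asarray(categories)
    scores = np.asarray(scores, dtype=float)
    for cat in CATEGORIES:
        vals = scores[(categories == cat) & np.isfinite(scores)]
        if len(vals) >= 2:
            out[cat] = (float(vals.mean()), float(vals.std(ddof=1)))
    return out


def assign_window_labels(
    annotated: AnnotatedSequence,
    profile: NormalizedProfile,
    window_size: int,
    category_stats: dict[str, tuple[float, float]] | None = None,
) -> list[WindowLabel]:
    """Label every non-excluded residue with (category, class).

    floor(window_size / 2) residues at each terminus are excluded (a centered
    window cannot be formed there). The class is intermediate when the
    center's normalized score lies within one SD of its category's mean
    (boundaries inclusive), flexible above, rigid below. ``category_stats``
    supplies corpus-level per-category (mean, SD); when omitted they are
    computed from this chain alone.
    """
    if window_size % 2 == 0:
        raise ValueError("window_size must be odd")
    n = len(annotated)
    half = window_size // 2
    cats = ss_category(annotated.ss)
    scores = profile.scores
    if category_stats is None:
        category_stats = category_score_stats(cats, scores)
    run_len = flexible_run_lengths(scores)
    labels = []
    for i in range(half, n - half):
        y = scores[i]
        if not np.isfinite(y):
            continue
        cat = cats[i]
        if cat not in category_stats:
            continue
        mean, sd = category_stats[cat]
        if y > mean + sd:
            cls = "flexible"
        elif y < mean - sd:
            cls = "rigid"
        else:
            cls = "intermediate"
        labels.append(
            WindowLabel(
                center=i, category=cat, cls=cls, score=float(y),
                flexible_run_length=int(run_len[i]),
            )
        )
    return labels


@dataclass
class ClassStats:
    """Average and SD of the normalized score per (category, class) cell."""

    stats: dict[tuple[str, str], tuple[float, float]]
    counts: dict[tuple[str, str], int]
    sparse_cells: list[tuple[str, str]] = field(default_factory=list)

    def score(self, category: str, cls: str, z: float = 0.0) -> float:
        """Class-to-score transform: avg + SD × z."""
        if (category, cls) not in self.stats:
            raise KeyError(f"no statistics for cell ({category}, {cls})")
        avg, sd = self.stats[(category, cls)]
        return avg + sd * z


def class_statistics(labels: list[WindowLabel]) -> ClassStats:
    """Aggregate per-cell score statistics over labeled windows.

    Cells with fewer than 2 windows are flagged in ``sparse_cells`` rather
    than raising.
    """
    cells: dict[tuple[str, str], list[float]] = {}
    for lab in labels:
        cells.setdefault((lab.category, lab.cls), []).append(lab.score)
    stats, counts, sparse = {}, {}, []
    for key, vals in cells.items():
        counts[key] = len(vals)
        arr = np.array(vals)
        if len(vals) >= 2:
            stats[key] = (float(arr.mean()), float(arr.std(ddof=1)))
        else:
            stats[key] = (float(arr.mean()), 0.0)
            sparse.append(key)
    return ClassStats(stats=stats, counts=counts, sparse_cells=sparse)


def flexible_run_lengths(
    scores: np.ndarray, threshold: float = 1.0
) -> np.ndarray:
    """Per-residue length of the maximal y > threshold run containing it.

    Residues at or below the threshold (or NaN) get 0.
    """
    scores = np.asarray(scores, dtype=float)
    with np.errstate(invalid="ignore"):
        above = np.nan_to_num(scores, nan=-np.inf) > threshold
    out = np.zeros(len(scores), dtype=int)
    for start, stop, val in _runs(above):
        if val:
            out[start:stop] = stop - start
    return out


def run_length_distribution(
    profiles: list[np.ndarray], threshold: float = 1.0
) -> Counter:
    """Histogram of maximal run lengths of residues with y > threshold."""
    hist: Counter = Counter()
    for scores in profiles:
        scores = np.asarray(scores, dtype=float)
        with np.errstate(invalid="ignore"):
            above = np.nan_to_num(scores, nan=-np.inf) > threshold
        for start, stop, val in _runs(above):
            if val:
                hist[stop - start] += 1
    return hist
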