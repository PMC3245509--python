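"""Paired-amino-acid window encoding.

Each residue is described by 18 binary features in four groups:

* physicochem. (7): hydrophobic, polar, aromatic, aliphatic, small,
  positive, negative — fixed sets from the classical amino acid
  classification (configurable).
* mobility (6): high/nor/low_mob × high/low — thresholded log2 mobility
  propensities computed from the training corpus.
* ss (3): helix / sheet / other — one-hot from the per-residue annotation.
* ASA (2): exposed / buried — thresholded per-residue ASA value.

A window of W residues around a center produces one variable per (feature
pair, partner offset): the first feature is evaluated on the central
residue, the second on the partner, and the variable value is their sum
(0, 1 or 2). The pair list is 7×7 + 6×6 + 3 (ss diagonal only) + 2×2 = 92
pairs, giving 92 × (W − 1) variables — 920 for W = 11 and 1,472 for W = 17.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .annotations import AnnotatedSequence
from .dataset import AMINO_ACIDS, MobilityPropensityTable

__all__ = [
    "FeatureTable",
    "build_feature_table",
    "encode_window",
    "encode_sequence",
    "variable_names",
    "PHYSICOCHEM_SETS",
    "PHYSICOCHEM_NAMES",
    "N_PAIRS",
]

PHYSICOCHEM_SETS: dict[str, str] = {
    "hydrophobic": "ACFGHIKLMTVWY",
    "polar": "CDEHKNQRSTWY",
    "aromatic": "FHWY",
    "aliphatic": "ILV",
    "small": "ACDGNPSTV",
    "positive": "HKR",
    "negative": "DE",
}
PHYSICOCHEM_NAMES = tuple(PHYSICOCHEM_SETS)
MOBILITY_NAMES = MobilityPropensityTable.FEATURE_NAMES
SS_NAMES = ("helix", "sheet", "other")
ASA_NAMES = ("exposed", "buried")

#: ordered feature pairs (f1 on the center, f2 on the partner)
_PAIRS: list[tuple[str, str]] = (
    [(a, b) for a in PHYSICOCHEM_NAMES for b in PHYSICOCHEM_NAMES]
    + [(a, b) for a in MOBILITY_NAMES for b in MOBILITY_NAMES]
    + [(s, s) for s in SS_NAMES]
    + [(a, b) for a in ASA_NAMES for b in ASA_NAMES]
)
N_PAIRS = len(_PAIRS)  # 49 + 36 + 3 + 4 = 92

ALL_FEATURE_NAMES = PHYSICOCHEM_NAMES + MOBILITY_NAMES + SS_NAMES + ASA_NAMES


@dataclass
class FeatureTable:
    """Resolved 18-feature assignment.

    ``aa_features`` maps each amino acid to its 13 identity-derived features
    (7 physicochem + 6 mobility); ss and ASA features are resolved per
    residue at encoding time from the annotation.
    """

    aa_features: dict[str, np.ndarray]
    asa_thresholds: tuple[float, float] = (11.0, 27.0)
    physicochem_sets: dict[str, str] = field(
        default_factory=lambda: dict(PHYSICOCHEM_SETS)
    )

    def residue_features(self, aa: str, ss: str, asa: float) -> np.ndarray:
        """Full 18-feature 0/1 vector for one annotated residue."""
        ident = self.aa_features.get(aa)
        if ident is None:
            warnings.warn(f"unknown amino acid {aa!r}: all-zero features")
            ident = np.zeros(13, dtype=np.int8)
        ss_vec = np.array(
            [ss == "H", ss == "E", ss == "C"], dtype=np.int8
        )
        buried_max, exposed_min = self.asa_thresholds
        asa_vec = np.array(
            [asa > exposed_min, asa < buried_max], dtype=np.int8
        )
        return np.concatenate([ident, ss_vec, asa_vec])


def build_feature_table(
    propensity: MobilityPropensityTable,
    asa_thresholds: tuple[float, float] = (11.0, 27.0),
    physicochem_sets: dict[str, str] | None = None,
) -> FeatureTable:
    """Assemble the per-amino-acid feature table.

    ``asa_thresholds`` is (buried_max, exposed_min): buried fires below the
    first value, exposed above the second. The preset (1, 3) suits
    class-coded ASA inputs.
    """
    if asa_thresholds[0] > asa_thresholds[1]:
        raise ValueError("buried_max must be <= exposed_min")
    sets = dict(PHYSICOCHEM_SETS if physicochem_sets is None else physicochem_sets)
    aa_features = {}
    for aa in AMINO_ACIDS:
        phys = np.array(
            [aa in sets[name] for name in PHYSICOCHEM_NAMES], dtype=np.int8
        )
        mob = propensity.feature_vector(aa).astype(np.int8)
        aa_features[aa] = np.concatenate([phys, mob])
    return FeatureTable(
        aa_features=aa_features,
        asa_thresholds=tuple(asa_thresholds),
        physicochem_sets=sets,
    )


def _offsets(window_size: int) -> list[int]:
    half = window_size // 2
    return [o for o in range(-half, half + 1) if o != 0]


def variable_names(window_size: int) -> list[str]:
    """Names of all 92 × (W − 1) variables as 'f1-f2@offset'."""
    names = []
    for off in _offsets(window_size):
        for f1, f2 in _PAIRS:
            names.append(f"{f1}-{f2}@{off:+d}")
    return names


def _residue_feature_matrix(
    annotated: AnnotatedSequence, table: FeatureTable
) -> np.ndarray:
    return np.array(
        [
            table.residue_features(aa, ss, asa)
            for aa, ss, asa in zip(annotated.sequence, annotated.ss, annotated.asa)
        ],
        dtype=np.int8,
    )


_PAIR_IDX = np.array(
    [
        (ALL_FEATURE_NAMES.index(f1), ALL_FEATURE_NAMES.index(f2))
        for f1, f2 in _PAIRS
    ]
)


def encode_window(
    annotated: AnnotatedSequence,
    center: int,
    window_size: int,
    table: FeatureTable,
) -> np.ndarray:
    """Encode one window into its 92 × (W − 1) variable vector.

    ``center`` is 0-based and must be at least floor(W/2) residues from both
    termini. Every entry is the sum of the first feature on the central
    residue and the second on the partner, hence in {0, 1, 2}.
    """
    half = window_size // 2
    n = len(annotated)
    if center < half or center >= n - half:
        raise ValueError(
            f"excluded residue: center {center} within {half} of a terminus"
        )
    feats = _residue_feature_matrix(annotated, table)
    return _encode_from_matrix(feats, center, window_size)


def _encode_from_matrix(
    feats: np.ndarray, center: int, window_size: int
) -> np.ndarray:
    f1 = feats[center][_PAIR_IDX[:, 0]]           # (92,)
    out = np.empty(N_PAIRS * (window_size - 1), dtype=np.int8)
    for i, off in enumerate(_offsets(window_size)):
        f2 = feats[center + off][_PAIR_IDX[:, 1]]
        out[i * N_PAIRS : (i + 1) * N_PAIRS] = f1 + f2
    return out


def encode_sequence(
    annotated: AnnotatedSequence,
    window_size: int,
    table: FeatureTable,
) -> tuple[np.ndarray, np.ndarray]:
    """Encode every non-excluded residue of a sequence.

    Returns (X, centers): X is (n_windows, 92 × (W − 1)) with rows in
    residue order, centers the corresponding 0-based indices. The
    floor(W/2) terminal residues on each side are excluded.
    """
    n = len(annotated)
    if n < window_size:
        raise ValueError(
            f"sequence too short: {n} residues < window {window_size}"
        )
    half = window_size // 2
    feats = _residue_feature_matrix(annotated, table)
    centers = np.arange(half, n - half)
    x = np.stack(
        [_encode_from_matrix(feats, c, window_size) for c in centers]
    )
    return x, centers
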