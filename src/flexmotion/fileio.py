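"""CSV/TSV/JSON readers and writers for pipeline artifacts.

All user-facing residue coordinates are 1-based inclusive; CSVs are
comma-separated UTF-8 with a mandatory header row, and may start with
``#``-prefixed comment lines carrying the generating configuration.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from .annotations import AnnotatedSequence
from .elastic_nma import MotionProfile
from .predictor import PredictionResult, Region

__all__ = [
    "write_profile_csv",
    "read_profile_csv",
    "write_prediction_csv",
    "read_prediction_csv",
    "write_regions_tsv",
    "write_report_json",
]


def _write_with_header(df: pd.DataFrame, path, meta: dict | None, sep=",") -> None:
    with open(path, "w") as fh:
        if meta:
            fh.write(f"# flexmotion {json.dumps(meta, sort_keys=True)}\n")
        df.to_csv(fh, index=False, sep=sep)


def write_profile_csv(profile: MotionProfile, path, meta: dict | None = None) -> None:
    df = pd.DataFrame(
        {
            "residue_id": profile.residue_ids,
            "aa": profile.residue_names,
            "internal_raw": profile.internal,
            "external_raw": profile.external,
            "mask": profile.mask.astype(int),
        }
    )
    _write_with_header(df, path, meta)


def read_profile_csv(path) -> MotionProfile:
    df = pd.read_csv(path, comment="#")
    n = len(df)
    return MotionProfile(
        residue_ids=df["residue_id"].to_numpy(),
        residue_names=df["aa"].to_numpy(dtype="U1"),
        internal=df["internal_raw"].to_numpy(),
        external=df["external_raw"].to_numpy(),
        cross=np.zeros(n),
        total_msd=np.full(n, np.nan),
        mask=df["mask"].to_numpy(dtype=bool),
    )


def write_prediction_csv(
    result: PredictionResult,
    annotated: AnnotatedSequence,
    path,
    meta: dict | None = None,
) -> None:
    df = pd.DataFrame(
        {
            "residue_id": result.residue_ids,
            "aa": list(annotated.sequence),
            "category": result.categories,
            "class": result.classes,
            "raw_score": result.raw,
            "smoothed_score": result.smoothed,
            "mask": result.mask.astype(int),
        }
    )
    _write_with_header(df, path, meta)


def read_prediction_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_regions_tsv(
    regions: list[Region], path, chain: str = "A", meta: dict | None = None
) -> None:
    """High-motion regions as TSV: chain, start, end, mean_score
    (coordinates 1-based inclusive)."""
    df = pd.DataFrame(
        {
            "chain": [chain] * len(regions),
            "start": [r.start for r in regions],
            "end": [r.end for r in regions],
            "mean_score": [r.mean_score for r in regions],
        }
    )
    header = dict(meta or {}, coordinates="1-based inclusive")
    _write_with_header(df, path, header, sep="\t")


def write_report_json(report: dict, path, meta: dict | None = None) -> None:
    payload = dict(report)
    if meta:
        payload["config"] = meta
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=float)
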