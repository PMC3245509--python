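"""Naïve secondary-structure-based score model.

The baseline encodes the crude expectation that motion is small inside
secondary structure and large in loops, decaying with distance from the run
center: for a residue inside an ss run (H or E),

    Nscore = −1.5 × SD × 1 / (1 + separation from run center) + avg

and for a residue in a non-ss run,

    Nscore = 3 × SD × 1 / (1 + separation from run center) + avg

where avg and SD are the dataset-wide mean and standard deviation of the
normalized NMA score. The published constants are avg = 6.80e-6 (internal)
and 7.49e-3 (external), with SD = 1.00 and 1.01 respectively.

A direct H→E transition ends a run (helix and sheet runs are separate);
even-length runs use the half-integer center.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["NaiveConfig", "naive_score", "INTERNAL_NAIVE", "EXTERNAL_NAIVE"]


@dataclass
class NaiveConfig:
    avg: float
    sd: float
    motion_type: str = "internal"

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError("SD must be positive")


#: published dataset-wide constants
INTERNAL_NAIVE = NaiveConfig(avg=6.80e-6, sd=1.00, motion_type="internal")
EXTERNAL_NAIVE = NaiveConfig(avg=7.49e-3, sd=1.01, motion_type="external")


def naive_score(ss_string: str, config: NaiveConfig) -> np.ndarray:
    """Per-residue naïve motion scores from the ss string alone."""
    bad = set(ss_string) - set("HEC")
    if bad:
        raise ValueError(f"unknown ss symbols: {sorted(bad)}")
    if not ss_string:
        raise ValueError("empty ss string")
    n = len(ss_string)
    scores = np.empty(n)
    start = 0
    for i in range(1, n + 1):
        if i == n or ss_string[i] != ss_string[start]:
            center = (start + i - 1) / 2.0
            in_ss = ss_string[start] in "HE"
            for j in range(start, i):
                sep = abs(j - center)
                if in_ss:
                    scores[j] = -1.5 * config.sd / (1.0 + sep) + config.avg
                else:
                    scores[j] = 3.0 * config.sd / (1.0 + sep) + config.avg
            start = i
    return scores
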