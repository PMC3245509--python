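"""Per-residue sequence annotations: the predictor's only input.

An :class:`AnnotatedSequence` carries the amino acid string together with a
three-state secondary-structure assignment (H = helix, E = sheet, C = other)
and a per-residue accessible-surface-area value. In production these
annotations come from external sequence-based predictors; here they are read
from a simple tab-separated format (or a PSIPRED horizontal file for the
secondary structure).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "AnnotatedSequence",
    "read_annotation",
    "write_annotation",
    "read_fasta",
    "read_psipred_horizontal",
    "AnnotationError",
]

SS_STATES = ("H", "E", "C")


class AnnotationError(ValueError):
    """Raised for malformed annotation input."""


@dataclass
class AnnotatedSequence:
    """Amino acid sequence with per-residue ss state and ASA value."""

    sequence: str
    ss: str
    asa: np.ndarray
    residue_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.asa = np.asarray(self.asa, dtype=float)
        if not (len(self.sequence) == len(self.ss) == len(self.asa)):
            raise AnnotationError("sequence, ss and asa lengths differ")
        bad = set(self.ss) - set(SS_STATES)
        if bad:
            raise AnnotationError(f"unknown ss symbols: {sorted(bad)}")
        if self.residue_ids is None:
            self.residue_ids = np.arange(1, len(self.sequence) + 1)
        else:
            self.residue_ids = np.asarray(self.residue_ids, dtype=int)

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def is_ss(self) -> np.ndarray:
        """Boolean mask of residues inside secondary structure (H or E)."""
        return np.array([c in "HE" for c in self.ss])


def read_annotation(path) -> AnnotatedSequence:
    """Read a per-residue annotation TSV with columns residue_id, aa, ss, asa.

    Residue ids must be 1-based and contiguous; errors name the offending line
    (1-based, counting the header as line 1).
    """
    df = pd.read_csv(path, sep="\t")
    required = ["residue_id", "aa", "ss", "asa"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise AnnotationError(f"{path}: missing columns {missing}")
    ids = df["residue_id"].to_numpy()
    expected = np.arange(1, len(df) + 1)
    if not np.array_equal(ids, expected):
        bad = int(np.argmax(ids != expected))
        raise AnnotationError(
            f"{path}: residue ids must be 1..{len(df)} contiguous; "
            f"first problem at line {bad + 2}"
        )
    for i, s in enumerate(df["ss"]):
        if s not in SS_STATES:
            raise AnnotationError(
                f"{path}: invalid ss symbol {s!r} at line {i + 2}"
            )
    try:
        asa = df["asa"].astype(float).to_numpy()
    except ValueError as exc:
        raise AnnotationError(f"{path}: non-numeric asa value ({exc})") from exc
    return AnnotatedSequence(
        sequence="".join(df["aa"]),
        ss="".join(df["ss"]),
        asa=asa,
        residue_ids=ids,
    )


def write_annotation(annotated: AnnotatedSequence, path) -> None:
    df = pd.DataFrame(
        {
            "residue_id": annotated.residue_ids,
            "aa": list(annotated.sequence),
            "ss": list(annotated.ss),
            "asa": annotated.asa,
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into an ordered {header: sequence} mapping."""
    records: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    records[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            else:
                chunks.append(line)
    if name is not None:
        records[name] = "".join(chunks)
    if not records:
        raise AnnotationError(f"{path}: no FASTA records")
    return records


def read_psipred_horizontal(path) -> tuple[str, str]:
    """Read a PSIPRED horizontal (.horiz) file.

    Returns (sequence, ss) with the ss alphabet mapped to {H, E, C}.
    """
    seq_parts: list[str] = []
    ss_parts: list[str] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("Pred:"):
                ss_parts.append(line[5:].strip())
            elif line.startswith("  AA:") or line.startswith("AA:"):
                seq_parts.append(line.split(":", 1)[1].strip())
    seq = "".join(seq_parts)
    ss = "".join(ss_parts).replace("C", "C").replace("G", "H")
    ss = "".join("C" if c not in "HE" else c for c in ss)
    if not seq or len(seq) != len(ss):
        raise AnnotationError(f"{path}: malformed PSIPRED horizontal file")
    return seq, ss
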