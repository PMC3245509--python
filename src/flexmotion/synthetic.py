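"""Synthetic Cα structures, annotations, and labeled training corpora.

The generator builds idealized single-chain Cα traces from a secondary
structure string: helices use ideal α-helix geometry (1.5 Å rise per
residue, ~100° twist, 2.3 Å radius), strands an extended zigzag (~3.4 Å
rise), and coil a self-avoiding random walk with 3.8 Å steps. Runs are
chained head-to-tail with gentle random turns, giving compact mixed
topologies whose elastic-network modes show the qualitative structure the
method assumes: loops deform (high internal motion), secondary-structure
cores move rigidly (high external / low internal motion).

Sequences are drawn with a configurable secondary-structure bias so
mobility propensities carry signal; ASA is a geometric proxy (inverse
neighbor count, scaled per chain into the buried < 11 / exposed > 27
threshold regime) because only the two binary threshold features ever reach
the model. Everything is deterministic under the given seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.spatial

from .annotations import AnnotatedSequence
from .dataset import NormalizedProfile, normalize_scores
from .elastic_nma import (
    FragmentedStructureError,
    ModeSet,
    MotionProfile,
    build_anm_modes,
    compute_motion_profile,
)
from .structure import CaStructure

__all__ = [
    "TopologySpec",
    "SyntheticChain",
    "SyntheticCorpus",
    "generate_toy_structure",
    "generate_annotated_sequence",
    "generate_training_corpus",
    "random_topology",
]

_STEP = 3.8           # Å, consecutive Cα–Cα distance
_HELIX_RISE = 1.5     # Å per residue along the helix axis
_HELIX_TWIST = np.deg2rad(100.0)
_HELIX_RADIUS = 2.3   # Å
_STRAND_RISE = 3.4    # Å per residue along the strand axis
_STRAND_OFFSET = 0.8  # Å perpendicular zigzag amplitude

#: amino acid pools biased per secondary-structure state
_SS_POOLS = {"H": "AELMQKRH", "E": "VIFYWTC", "C": "GPSNDQ"}

#: minimum ratio of the softest to the stiffest vibrational eigenvalue for a
#: 60-residue structure to count as well-packed; smaller gaps indicate a
#: quasi-mechanism (a nearly free hinge or protruding run) whose thermal
#: amplitude leaves the harmonic regime the motion decomposition assumes.
#: The softest eigenvalue of a chain-like elastic body scales roughly as
#: 1/n², so the floor is referenced to 60 residues and scaled accordingly.
MIN_SPECTRAL_GAP = 5e-4

#: weaker floor used for training-corpus chains: genuinely soft surface
#: loops are the signal being modeled and must be kept; only structures with
#: a near-mechanism (nearly-zero) mode are rejected
CORPUS_MIN_GAP = 1e-5


def spectral_gap_ok(modes: ModeSet, min_gap: float | None = None) -> bool:
    """Whether a mode set has no quasi-mechanism (floppy) modes."""
    if min_gap is None:
        min_gap = MIN_SPECTRAL_GAP * (60.0 / modes.n_atoms) ** 2
    return bool(modes.eigenvalues[0] >= min_gap * modes.eigenvalues[-1])


@dataclass
class TopologySpec:
    """Recipe for one synthetic chain."""

    ss_string: str
    jitter: float = 0.0   # SD of Gaussian coordinate noise, Å
    seed: int = 0

    def __post_init__(self) -> None:
        bad = set(self.ss_string) - set("HEC")
        if bad:
            raise ValueError(f"unknown ss symbols in spec: {sorted(bad)}")


def _basis_from_axis(axis: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Orthonormal basis (columns e1, e2, axis) with a random roll about axis."""
    axis = axis / np.linalg.norm(axis)
    ref = np.array([0.0, 0.0, 1.0])
    if abs(axis @ ref) > 0.9:
        ref = np.array([1.0, 0.0, 0.0])
    e1 = np.cross(ref, axis)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    phi = rng.uniform(0, 2 * np.pi)
    e1r = np.cos(phi) * e1 + np.sin(phi) * e2
    e2r = np.cross(axis, e1r)
    return np.column_stack([e1r, e2r, axis])


def _perturb_direction(
    u: np.ndarray, rng: np.random.Generator, max_angle: float
) -> np.ndarray:
    """Rotate a unit vector by a random angle up to max_angle (radians)."""
    angle = rng.uniform(0, max_angle)
    basis = _basis_from_axis(u, rng)
    v = (
        np.cos(angle) * u
        + np.sin(angle) * (np.cos(rng.uniform(0, 2 * np.pi)) * basis[:, 0]
                           + np.sin(rng.uniform(0, 2 * np.pi)) * basis[:, 1])
    )
    return v / np.linalg.norm(v)


def _confinement_radius(n: int) -> float:
    """Globule-like confinement radius in Å for an n-residue chain."""
    return 3.2 * n ** (1 / 3)


def _steer(
    direction: np.ndarray, pos: np.ndarray, placed: np.ndarray | None, r0: float
) -> np.ndarray:
    """Bend a step direction back toward the chain centroid outside r0."""
    if placed is None or len(placed) == 0:
        return direction
    centroid = placed.mean(axis=0)
    disp = pos - centroid
    dist = np.linalg.norm(disp)
    if dist <= r0:
        return direction
    w = min(0.9, (dist - r0) / r0)
    v = (1 - w) * direction - w * disp / dist
    return v / np.linalg.norm(v)


def _helix_run(m: int) -> np.ndarray:
    j = np.arange(m)
    theta = j * _HELIX_TWIST
    return np.column_stack(
        [
            _HELIX_RADIUS * np.cos(theta),
            _HELIX_RADIUS * np.sin(theta),
            j * _HELIX_RISE,
        ]
    )


def _strand_run(m: int) -> np.ndarray:
    j = np.arange(m)
    return np.column_stack(
        [
            _STRAND_OFFSET * (-1.0) ** j,
            np.zeros(m),
            j * _STRAND_RISE,
        ]
    )


def _coil_run(
    m: int,
    start: np.ndarray,
    u: np.ndarray,
    rng: np.random.Generator,
    placed: list[np.ndarray],
    r0: float,
    excurse: bool = False,
) -> np.ndarray:
    """Self-avoiding 3.8 Å-step random walk of m points, first point = start.

    With ``excurse`` the walk behaves like a surface loop: its first half is
    steered away from the chain centroid and its second half back, so the
    loop bulges out of the globule and keeps few non-local contacts.
    """
    pts = [start]
    direction = u.copy()
    body = np.array(placed) if placed else None
    centroid = body.mean(axis=0) if body is not None else start
    for step in range(m - 1):
        best, best_clash = None, np.inf
        for _attempt in range(40):
            cand_dir = _perturb_direction(direction, rng, np.deg2rad(75))
            if excurse and body is not None:
                radial = pts[-1] - centroid
                nr = np.linalg.norm(radial)
                tgt = radial / nr if nr > 0 else cand_dir
                if step >= (m - 1) // 2:
                    tgt = -tgt
                cand_dir = 0.4 * cand_dir + 0.6 * tgt
                cand_dir /= np.linalg.norm(cand_dir)
            else:
                cand_dir = _steer(cand_dir, pts[-1], body, r0)
            cand = pts[-1] + _STEP * cand_dir
            prior = pts[:-1]
            clash = 0.0
            mind = np.inf
            if prior:
                d = np.linalg.norm(np.array(prior) - cand, axis=1)
                mind = min(mind, d.min())
            if body is not None:
                d = np.linalg.norm(body - cand, axis=1)
                mind = min(mind, d.min())
            if mind >= 3.2:
                best = cand_dir
                break
            clash = 3.2 - mind
            if clash < best_clash:
                best_clash, best = clash, cand_dir
        direction = best
        pts.append(pts[-1] + _STEP * direction)
    return np.array(pts)


def generate_toy_structure(spec: TopologySpec) -> CaStructure:
    """Build an idealized Cα trace realizing the recipe's ss string."""
    rng = np.random.default_rng(spec.seed)
    ss = spec.ss_string
    runs: list[tuple[str, int]] = []
    start = 0
    for i in range(1, len(ss) + 1):
        if i == len(ss) or ss[i] != ss[start]:
            runs.append((ss[start], i - start))
            start = i

    coords: list[np.ndarray] = []
    r0 = _confinement_radius(len(ss))
    heading = _perturb_direction(np.array([0.0, 0.0, 1.0]), rng, np.pi)
    for kind, m in runs:
        if coords:
            heading = _steer(heading, coords[-1], np.array(coords), r0)
            anchor = coords[-1] + _STEP * heading
        else:
            anchor = np.zeros(3)
        if kind == "C":
            # long coils behave as surface loops rather than packed segments
            run_pts = _coil_run(
                m, anchor, heading, rng, coords[:-1], r0, excurse=(m >= 9)
            )
        else:
            local = _helix_run(m) if kind == "H" else _strand_run(m)
            basis = _basis_from_axis(heading, rng)
            run_pts = (local - local[0]) @ basis.T + anchor
        coords.extend(run_pts)
        if len(coords) >= 2:
            tail = coords[-1] - coords[-2]
            tail /= np.linalg.norm(tail)
            heading = _perturb_direction(tail, rng, np.deg2rad(55))

    arr = np.array(coords)
    if spec.jitter > 0:
        arr = arr + rng.normal(0.0, spec.jitter, arr.shape)
    n = len(arr)
    return CaStructure(
        residue_ids=np.arange(1, n + 1),
        residue_names=np.full(n, "X", dtype="U1"),
        coords=arr,
    )


def generate_annotated_sequence(
    structure: CaStructure,
    spec: TopologySpec,
    ss_bias: float = 0.7,
    flip_rate: float = 0.0,
    seed: int | None = None,
) -> AnnotatedSequence:
    """Draw a sequence and annotations consistent with a toy structure.

    Amino acids come from an ss-biased pool with probability ``ss_bias``
    (uniform background otherwise), so mobility propensities are learnable.
    The ss annotation equals the generating string, optionally corrupted at
    ``flip_rate`` per residue. ASA is a per-chain monotone decreasing
    function of the 10 Å neighbor count, scaled onto [0, 50] so both the
    buried (< 11) and exposed (> 27) feature thresholds fire.
    """
    from .dataset import AMINO_ACIDS

    rng = np.random.default_rng(spec.seed + 1 if seed is None else seed)
    ss = spec.ss_string
    seq = []
    for c in ss:
        if rng.random() < ss_bias:
            pool = _SS_POOLS[c]
        else:
            pool = AMINO_ACIDS
        seq.append(pool[rng.integers(len(pool))])

    ann_ss = list(ss)
    if flip_rate > 0:
        states = "HEC"
        for i in range(len(ann_ss)):
            if rng.random() < flip_rate:
                ann_ss[i] = states[rng.integers(3)]

    d = scipy.spatial.distance.squareform(
        scipy.spatial.distance.pdist(structure.coords)
    )
    ncount = ((d > 0) & (d <= 10.0)).sum(axis=1).astype(float)
    lo, hi = ncount.min(), ncount.max()
    if hi > lo:
        asa = 50.0 * (hi - ncount) / (hi - lo)
    else:
        asa = np.full(len(ncount), 25.0)

    return AnnotatedSequence(
        sequence="".join(seq),
        ss="".join(ann_ss),
        asa=asa,
        residue_ids=structure.residue_ids.copy(),
    )


def random_topology(
    rng: np.random.Generator,
    target_length: int,
    plant_long_coil: bool = True,
) -> tuple[str, list[tuple[int, int]]]:
    """Random run topology of roughly target_length residues.

    Alternates coil and secondary-structure runs. When ``plant_long_coil``
    is set, one interior coil run is stretched to 13–16 residues; planted
    regions are returned as 0-based (start, stop-exclusive) tuples.
    """
    # short terminal tails; interior coils 3-8 residues between ss runs
    runs: list[tuple[str, int]] = [("C", int(rng.integers(3, 6)))]
    total = runs[0][1]
    while total < target_length:
        kind = "H" if rng.random() < 0.6 else "E"
        slen = int(rng.integers(6, 15)) if kind == "H" else int(rng.integers(4, 9))
        runs.append((kind, slen))
        total += slen
        clen = int(rng.integers(3, 9))
        runs.append(("C", clen))
        total += clen
    if runs[-1][0] == "C":
        runs[-1] = ("C", int(rng.integers(3, 6)))
    else:
        runs.append(("C", int(rng.integers(3, 6))))

    planted: list[tuple[int, int]] = []
    if plant_long_coil:
        coil_idx = [i for i, (k, _) in enumerate(runs) if k == "C"][1:-1]
        if coil_idx:
            pick = int(rng.choice(coil_idx))
        else:
            pick = len(runs) // 2 | 1  # fall back to some interior run
            runs[pick] = ("C", runs[pick][1])
        runs[pick] = ("C", int(rng.integers(13, 17)))
        pos = 0
        for i, (k, m) in enumerate(runs):
            if i == pick:
                planted.append((pos, pos + m))
            pos += m
    ss = "".join(k * m for k, m in runs)
    return ss, planted


@dataclass
class SyntheticChain:
    """One fully labeled synthetic chain: geometry, annotation, ground truth."""

    structure: CaStructure
    annotated: AnnotatedSequence
    modes: ModeSet
    profile: MotionProfile
    norm_internal: NormalizedProfile
    norm_external: NormalizedProfile
    planted_regions: list[tuple[int, int]]
    spec: TopologySpec

    def normalized(self, motion_type: str) -> NormalizedProfile:
        if motion_type.startswith("internal"):
            return self.norm_internal
        return self.norm_external


@dataclass
class SyntheticCorpus:
    chains: list[SyntheticChain]
    seed: int
    params: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.chains)


def generate_training_corpus(
    n_chains: int,
    seed: int,
    length_range: tuple[int, int] = (60, 120),
    jitter: float = 0.15,
    ss_bias: float = 0.7,
    flip_rate: float = 0.0,
    cutoff: float = 13.0,
    segment_length: int = 9,
    plant_long_coil: bool = True,
) -> SyntheticCorpus:
    """Generate a labeled corpus end-to-end: geometry → modes → profiles.

    Each chain gets a random mixed topology, an idealized structure, all
    elastic-network modes, the 9-residue-segment motion decomposition, and
    per-chain z-normalized internal/external profiles.
    """
    if n_chains < 1:
        raise ValueError("n_chains must be >= 1")
    rng = np.random.default_rng(seed)
    chains = []
    for c in range(n_chains):
        # reject-and-resample: a drawn topology occasionally leaves an
        # under-constrained contact network (a floppy protruding run); such
        # geometries are discarded, keeping the stream deterministic
        for _attempt in range(20):
            target = int(rng.integers(length_range[0], length_range[1] + 1))
            ss, planted = random_topology(rng, target, plant_long_coil)
            spec = TopologySpec(
                ss_string=ss, jitter=jitter, seed=int(rng.integers(2**31 - 1))
            )
            structure = generate_toy_structure(spec)
            try:
                modes = build_anm_modes(structure, cutoff=cutoff)
            except FragmentedStructureError:
                continue
            if spectral_gap_ok(modes, min_gap=CORPUS_MIN_GAP):
                break
        else:
            raise FragmentedStructureError(
                "could not generate a connected structure in 20 attempts"
            )
        annotated = generate_annotated_sequence(
            structure, spec, ss_bias=ss_bias, flip_rate=flip_rate
        )
        structure.residue_names = np.array(list(annotated.sequence), dtype="U1")
        profile = compute_motion_profile(structure, modes, segment_length)
        chains.append(
            SyntheticChain(
                structure=structure,
                annotated=annotated,
                modes=modes,
                profile=profile,
                norm_internal=normalize_scores(profile.internal, profile.mask),
                norm_external=normalize_scores(profile.external, profile.mask),
                planted_regions=planted,
                spec=spec,
            )
        )
    return SyntheticCorpus(
        chains=chains,
        seed=seed,
        params=dict(
            n_chains=n_chains, length_range=length_range, jitter=jitter,
            ss_bias=ss_bias, flip_rate=flip_rate, cutoff=cutoff,
            segment_length=segment_length, plant_long_coil=plant_long_coil,
        ),
    )
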