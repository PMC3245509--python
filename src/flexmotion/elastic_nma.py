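"""Elastic-network normal modes and internal/external motion decomposition.

The engine is a Cα anisotropic network model (ANM): every pair of Cα atoms
within a distance cutoff is joined by a Hookean spring of uniform force
constant γ. Diagonalizing the 3n × 3n Hessian yields 3n − 6 non-rigid modes
with eigenvalues λ_k and orthonormal eigenvectors u_k; each mode's
displacement field is scaled to its root-mean-square thermal amplitude,
D_ak = sqrt(k_BT / λ_k) · u_ak with k_BT ≡ 1 model unit (only relative
magnitudes matter downstream, where per-chain z-normalization removes the
absolute scale).

For a short backbone segment, each mode's displacement is split into an
*external* part — the best-fitting rigid-body (rotation + translation) motion
of the segment, obtained by least-squares (Kabsch) superposition — and an
*internal* part, the residual deformation:

    D_ak = D_ak^e + D_ak^i          (exactly, per atom and mode)

Summing squared parts over modes and averaging over segment atoms gives the
per-residue external and internal mean-square motions; the interference term
2⟨D^e · D^i⟩ is near zero at the rigid-fit optimum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg
import scipy.spatial

from .structure import CaStructure

__all__ = [
    "ModeSet",
    "MotionProfile",
    "build_anm_modes",
    "best_fit_rigid_displacement",
    "compute_motion_profile",
    "cross_term_fraction",
    "FragmentedStructureError",
]

#: eigenvalues below this fraction of the largest are treated as rigid-body modes
ZERO_MODE_RTOL = 1e-8


class FragmentedStructureError(ValueError):
    """The contact network is disconnected (more than 6 zero modes)."""


@dataclass
class ModeSet:
    """Non-rigid normal modes of a Cα elastic network.

    Attributes
    ----------
    eigenvalues : (N,) array, ascending, all > 0
        Spring-constant-scaled mode stiffnesses λ_k.
    displacements : (N, n, 3) array
        Thermally scaled displacement vectors D_ak = sqrt(1/λ_k) u_ak in Å
        (model units); the underlying eigenvectors are orthonormal, so
        Σ_a |D_ak|² = 1/λ_k.
    """

    eigenvalues: np.ndarray
    displacements: np.ndarray
    cutoff: float
    gamma: float

    @property
    def n_modes(self) -> int:
        return len(self.eigenvalues)

    @property
    def n_atoms(self) -> int:
        return self.displacements.shape[1]

    def total_msd(self) -> np.ndarray:
        """Per-atom total mean-square displacement ⟨D_a²⟩ = Σ_k |D_ak|²."""
        return np.einsum("kai,kai->a", self.displacements, self.displacements)


@dataclass
class MotionProfile:
    """Per-residue internal and external motion magnitudes.

    ``internal`` and ``external`` hold ⟨|D^i|²⟩^1/2 and ⟨|D^e|²⟩^1/2 — square
    roots of segment-averaged mean-square parts; ``cross`` holds the signed
    interference term 2⟨D^e·D^i⟩; ``total_msd`` the segment-averaged ⟨D²⟩.
    ``mask`` is False where no segment of at least 5 residues could be formed.
    """

    residue_ids: np.ndarray
    residue_names: np.ndarray
    internal: np.ndarray
    external: np.ndarray
    cross: np.ndarray
    total_msd: np.ndarray
    mask: np.ndarray
    segment_length: int = 9

    def __len__(self) -> int:
        return len(self.internal)


def build_anm_modes(
    structure: CaStructure, cutoff: float = 13.0, gamma: float = 1.0
) -> ModeSet:
    """Compute all non-rigid ANM modes of a Cα structure.

    Parameters
    ----------
    structure : CaStructure
        At least 10 residues; its contact graph under ``cutoff`` must be
        connected (exactly 6 near-zero Hessian eigenvalues).
    cutoff : float
        Spring distance cutoff in Å (default 13).
    gamma : float
        Uniform spring force constant (model units).

    Returns
    -------
    ModeSet
        3n − 6 modes, eigenvalues ascending, displacement vectors scaled to
        root-mean-square thermal amplitude sqrt(1/λ_k).
    """
    n = len(structure)
    if n < 10:
        raise ValueError(f"structure has {n} residues; at least 10 required")
    coords = structure.coords
    dists = scipy.spatial.distance.squareform(
        scipy.spatial.distance.pdist(coords)
    )
    contact = (dists > 0) & (dists <= cutoff)
    if not contact.any(axis=1).all():
        raise FragmentedStructureError(
            f"fragmented structure: isolated atom under cutoff {cutoff} Å"
        )

    hessian = np.zeros((3 * n, 3 * n))
    for i in range(n):
        (js,) = np.nonzero(contact[i])
        dvec = coords[js] - coords[i]          # (m, 3)
        d2 = dists[i, js] ** 2
        blocks = -gamma * dvec[:, :, None] * dvec[:, None, :] / d2[:, None, None]
        for j, blk in zip(js, blocks):
            hessian[3 * i : 3 * i + 3, 3 * j : 3 * j + 3] = blk
        hessian[3 * i : 3 * i + 3, 3 * i : 3 * i + 3] = -blocks.sum(axis=0)

    evals, evecs = scipy.linalg.eigh(hessian)
    zero_thresh = max(evals[-1], 0.0) * ZERO_MODE_RTOL
    n_zero = int(np.sum(evals < zero_thresh))
    if n_zero > 6:
        raise FragmentedStructureError(
            f"fragmented structure: {n_zero} near-zero modes (expected 6); "
            f"increase the cutoff or check the input geometry"
        )
    if n_zero < 6:
        # collinear or otherwise degenerate geometry
        raise ValueError(
            f"degenerate geometry: only {n_zero} rigid-body modes found"
        )
    evals = evals[6:]
    evecs = evecs[:, 6:]
    displacements = (evecs / np.sqrt(evals)).T.reshape(-1, n, 3)
    return ModeSet(
        eigenvalues=evals, displacements=displacements, cutoff=cutoff, gamma=gamma
    )


def _kabsch_rotations(ref_c: np.ndarray, disp_c: np.ndarray) -> np.ndarray:
    """Batched Kabsch rotations mapping centered ref onto centered targets.

    ref_c : (m, 3); disp_c : (K, m, 3) centered. Returns (K, 3, 3) proper
    rotations R_k minimizing Σ_a |R_k ref_a − disp_ka|².
    """
    h = np.einsum("ai,kaj->kij", ref_c, disp_c)
    u, _, vt = np.linalg.svd(h)
    det = np.linalg.det(np.einsum("kij,kjl->kil", u, vt).transpose(0, 2, 1))
    # fix improper rotations by flipping the smallest singular direction
    flip = np.ones((len(h), 3))
    flip[:, 2] = np.sign(det)
    r = np.einsum("kji,kj,klj->kil", vt, flip, u)
    return r


def best_fit_rigid_displacement(
    ref_coords: np.ndarray, displaced_coords: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Split a displacement into rigid-body (external) and residual (internal).

    Finds the rigid motion (rotation + translation) that best superposes
    ``ref_coords`` onto ``displaced_coords`` in the least-squares sense.
    The external part of each atom's displacement is its motion under that
    rigid map; the internal part is the remainder, whose squared norm is the
    minimum over all rigid motions.

    Returns
    -------
    (external, internal) : two (m, 3) arrays with
        external + internal == displaced_coords − ref_coords exactly.
    """
    ref = np.asarray(ref_coords, dtype=float)
    disp = np.asarray(displaced_coords, dtype=float)
    if ref.shape != disp.shape or ref.ndim != 2 or ref.shape[1] != 3:
        raise ValueError("ref and displaced coordinates must both be (m, 3)")
    m = len(ref)
    if m < 3:
        raise ValueError("rigid fit under-determined: fewer than 3 points")
    ref_c = ref - ref.mean(axis=0)
    # collinearity check: rank of the centered reference
    if np.linalg.matrix_rank(ref_c, tol=1e-8) < 2:
        raise ValueError("rigid fit under-determined: collinear points")
    disp_c = disp - disp.mean(axis=0)
    r = _kabsch_rotations(ref_c, disp_c[None])[0]
    fitted = ref_c @ r.T + disp.mean(axis=0)
    external = fitted - ref
    internal = disp - fitted
    return external, internal


def _segment_bounds(n: int, i: int, half: int) -> tuple[int, int]:
    return max(0, i - half), min(n, i + half + 1)


def compute_motion_profile(
    structure: CaStructure,
    modes: ModeSet,
    segment_length: int = 9,
    top_modes: int | None = None,
) -> MotionProfile:
    """Per-residue internal/external motion magnitudes from a mode set.

    For each residue a segment of ``segment_length`` residues centered on it
    (truncated at the termini, minimum 5) is taken; every mode's segment
    displacement at thermal amplitude is decomposed by best-fit rigid
    superposition; squared external and internal parts are summed over modes
    and averaged over the segment's atoms.

    ``top_modes`` optionally restricts the sum to the m softest modes.
    """
    if segment_length % 2 == 0:
        raise ValueError("segment_length must be odd")
    if segment_length < 5:
        raise ValueError("segment_length must be at least 5")
    n = len(structure)
    half = segment_length // 2
    disp = modes.displacements
    if top_modes is not None:
        disp = disp[:top_modes]
    coords = structure.coords

    internal_sq = np.zeros(n)
    external_sq = np.zeros(n)
    cross = np.zeros(n)
    total = np.zeros(n)
    mask = np.zeros(n, dtype=bool)

    for i in range(n):
        lo, hi = _segment_bounds(n, i, half)
        if hi - lo < 5:
            continue
        ref = coords[lo:hi]                        # (m, 3)
        seg_disp = disp[:, lo:hi, :]               # (K, m, 3)
        ref_c = ref - ref.mean(axis=0)
        target = ref[None] + seg_disp
        t_mean = target.mean(axis=1, keepdims=True)
        target_c = target - t_mean
        r = _kabsch_rotations(ref_c, target_c)     # (K, 3, 3)
        fitted = np.einsum("kij,aj->kai", r, ref_c) + t_mean
        ext = fitted - ref[None]                   # (K, m, 3)
        itn = target - fitted
        # sum over modes, average over atoms
        e2 = np.einsum("kai,kai->", ext, ext)
        i2 = np.einsum("kai,kai->", itn, itn)
        x = 2.0 * np.einsum("kai,kai->", ext, itn)
        m_atoms = hi - lo
        external_sq[i] = e2 / m_atoms
        internal_sq[i] = i2 / m_atoms
        cross[i] = x / m_atoms
        total[i] = np.einsum("kai,kai->", seg_disp, seg_disp) / m_atoms
        mask[i] = True

    return MotionProfile(
        residue_ids=structure.residue_ids.copy(),
        residue_names=structure.residue_names.copy(),
        internal=np.sqrt(internal_sq),
        external=np.sqrt(external_sq),
        cross=cross,
        total_msd=total,
        mask=mask,
        segment_length=segment_length,
    )


def cross_term_fraction(
    structure: CaStructure, modes: ModeSet, segment_length: int = 9
) -> np.ndarray:
    """Relative magnitude of the interference term per residue.

    Returns |2⟨D^e·D^i⟩| / (⟨|D^e|²⟩ + ⟨|D^i|²⟩) for every residue with a
    valid segment (NaN elsewhere). The ratio is invariant under uniform
    rescaling of mode amplitudes.
    """
    prof = compute_motion_profile(structure, modes, segment_length)
    denom = prof.external**2 + prof.internal**2
    frac = np.full(len(prof), np.nan)
    valid = prof.mask & (denom > 0)
    frac[valid] = np.abs(prof.cross[valid]) / denom[valid]
    return frac
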