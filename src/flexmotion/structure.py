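"""Cα-trace structures and PDB input/output.

The normal-mode engine operates on the Cα trace alone, so the only structural
container in the package is an ordered list of Cα positions with residue
identifiers. PDB files are read and written through biotite; only ``ATOM``
records of the first model are considered and alternate locations are resolved
to the blank/'A' conformer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import biotite.structure as struc
import biotite.structure.io.pdb as pdb

__all__ = ["CaStructure", "read_ca_pdb", "write_ca_pdb", "StructureError"]


class StructureError(ValueError):
    """Raised for malformed or unusable structural input."""


_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
_ONE_TO_THREE = {v: k for k, v in _THREE_TO_ONE.items()}


@dataclass
class CaStructure:
    """Ordered Cα coordinates of a single protein chain.

    Attributes
    ----------
    residue_ids : (n,) int array
        1-based residue labels in chain order.
    residue_names : (n,) array of one-letter codes
        Amino acid identity per residue ('X' when unknown).
    coords : (n, 3) float array
        Cα positions in Å — the minimum-energy reference conformation
        the normal modes fluctuate around.
    """

    residue_ids: np.ndarray
    residue_names: np.ndarray
    coords: np.ndarray
    chain_id: str = "A"

    def __post_init__(self) -> None:
        self.residue_ids = np.asarray(self.residue_ids)
        self.residue_names = np.asarray(self.residue_names, dtype="U1")
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise StructureError("coords must be an (n, 3) array")
        if len(self.residue_ids) != len(self.coords):
            raise StructureError("residue_ids and coords length mismatch")
        if not np.all(np.isfinite(self.coords)):
            raise StructureError("coordinates must be finite")

    def __len__(self) -> int:
        return len(self.coords)

    @property
    def sequence(self) -> str:
        return "".join(self.residue_names)

    def ca_distances(self) -> np.ndarray:
        """Consecutive Cα–Cα distances in Å, length n − 1."""
        return np.linalg.norm(np.diff(self.coords, axis=0), axis=1)


def read_ca_pdb(path, chain: str | None = None) -> CaStructure:
    """Read the Cα trace of one chain from a PDB file.

    Only the first model is used; altLoc is resolved to ' '/'A'. When
    ``chain`` is None the file must contain a single chain.
    """
    pdb_file = pdb.PDBFile.read(str(path))
    atoms = pdb_file.get_structure(model=1, altloc="first")
    atoms = atoms[(atoms.atom_name == "CA") & ~atoms.hetero]
    if atoms.array_length() == 0:
        raise StructureError(f"no Cα ATOM records in {path}")
    chains = sorted(set(atoms.chain_id))
    if chain is None:
        if len(chains) > 1:
            raise StructureError(
                f"file contains chains {chains}; select one with chain="
            )
        chain = chains[0]
    if chain not in chains:
        raise StructureError(f"chain {chain!r} not found (available: {chains})")
    atoms = atoms[atoms.chain_id == chain]
    names = np.array(
        [_THREE_TO_ONE.get(rn, "X") for rn in atoms.res_name], dtype="U1"
    )
    ids = atoms.res_id.astype(int)
    return CaStructure(
        residue_ids=ids, residue_names=names, coords=atoms.coord, chain_id=chain
    )


def write_ca_pdb(structure: CaStructure, path) -> None:
    """Write a Cα trace as standard ATOM records (single chain)."""
    n = len(structure)
    atoms = struc.AtomArray(n)
    atoms.coord = structure.coords
    atoms.chain_id[:] = structure.chain_id
    atoms.res_id = structure.residue_ids
    atoms.res_name = np.array(
        [_ONE_TO_THREE.get(a, "UNK") for a in structure.residue_names]
    )
    atoms.atom_name[:] = "CA"
    atoms.element[:] = "C"
    atoms.hetero[:] = False
    pdb_file = pdb.PDBFile()
    pdb_file.set_structure(atoms)
    pdb_file.write(str(path))
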