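"""Residue-indexed protein chains with per-residue confidence.

Structure files follow the AlphaFold convention of storing the per-residue
confidence score (pLDDT, 0-100) in the B-factor column.  A chain is an
ordered list of residues; each residue carries a 1-based index, a 1-letter
amino-acid code, one or more atoms and a single pLDDT value taken from its
first atom's B-factor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np

from .errors import EmptyInputError, FormatError, ValidationError

logger = logging.getLogger(__name__)

AA_3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA_1TO3 = {v: k for k, v in AA_3TO1.items()}


@dataclass(frozen=True)
class Atom:
    """One atom: PDB atom name and Cartesian coordinates in Angstrom."""

    name: str
    x: float
    y: float
    z: float

    @property
    def pos(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)


@dataclass(frozen=True)
class Residue:
    """One residue: 1-based sequence index, 1-letter code, atoms, pLDDT."""

    index: int
    amino_acid: str
    atoms: tuple[Atom, ...]
    plddt: float

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValidationError(f"residue {self.index} has no atoms")
        if not 0.0 <= self.plddt <= 100.0:
            raise ValidationError(
                f"pLDDT {self.plddt} of residue {self.index} outside [0, 100]"
            )


@dataclass
class StructureChain:
    """An ordered chain of residues with strictly increasing indices."""

    chain_id: str
    residues: list[Residue] = field(default_factory=list)

    def __post_init__(self) -> None:
        idx = [r.index for r in self.residues]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValidationError(
                f"chain {self.chain_id}: residue indices not strictly increasing"
            )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def indices(self) -> np.ndarray:
        return np.array([r.index for r in self.residues], dtype=int)

    @property
    def plddt(self) -> np.ndarray:
        return np.array([r.plddt for r in self.residues], dtype=float)

    def residue(self, index: int) -> Residue:
        for r in self.residues:
            if r.index == index:
                return r
        raise KeyError(f"chain {self.chain_id} has no residue {index}")

    def atom_coords(self) -> tuple[np.ndarray, np.ndarray]:
        """All atom coordinates as an (n_atoms, 3) array plus, per atom, the
        residue index it belongs to."""
        coords, owner = [], []
        for r in self.residues:
            for a in r.atoms:
                coords.append((a.x, a.y, a.z))
                owner.append(r.index)
        return np.asarray(coords, dtype=float), np.asarray(owner, dtype=int)


def read_structure(path: str | Path) -> list[StructureChain]:
    """Read a PDB or mmCIF file into chains, taking per-residue confidence
    from the B-factor of each residue's first atom.

    Mixed per-atom B-factors within a residue are tolerated with a warning;
    AlphaFold writes uniform values per residue.
    """
    path = Path(path)
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"cannot parse structure file {path}: {exc}") from exc
    st.setup_entities()
    if len(st) == 0 or all(len(ch) == 0 for ch in st[0]):
        raise EmptyInputError(f"{path}: no residues in any chain")

    chains: list[StructureChain] = []
    for ch in st[0]:
        residues = []
        for res in ch:
            atoms = tuple(
                Atom(a.name, a.pos.x, a.pos.y, a.pos.z) for a in res
            )
            if not atoms:
                continue
            bvals = {round(a.b_iso, 2) for a in res}
            if len(bvals) > 1:
                logger.warning(
                    "%s %s%d: mixed per-atom B-factors %s; using first atom",
                    ch.name, res.name, res.seqid.num, sorted(bvals),
                )
            residues.append(
                Residue(
                    index=res.seqid.num,
                    amino_acid=AA_3TO1.get(res.name.upper(), "X"),
                    atoms=atoms,
                    plddt=float(res[0].b_iso),
                )
            )
        if residues:
            chains.append(StructureChain(chain_id=ch.name, residues=residues))
    if not chains:
        raise EmptyInputError(f"{path}: parsed structure contains no residues")
    return chains


def write_structure(chains: Sequence[StructureChain], path: str | Path) -> None:
    """Write chains as a single-model PDB (or mmCIF by .cif extension),
    storing each residue's pLDDT in the B-factor of all its atoms."""
    if not chains:
        raise EmptyInputError("no chains to write")
    st = gemmi.Structure()
    st.name = "varmech"
    model = gemmi.Model("1")
    for chain in chains:
        gch = gemmi.Chain(chain.chain_id)
        for res in chain.residues:
            gres = gemmi.Residue()
            gres.name = AA_1TO3.get(res.amino_acid, "UNK")
            gres.seqid = gemmi.SeqId(res.index, " ")
            for atom in res.atoms:
                ga = gemmi.Atom()
                ga.name = atom.name
                ga.pos = gemmi.Position(atom.x, atom.y, atom.z)
                ga.b_iso = res.plddt
                ga.occ = 1.0
                ga.element = gemmi.Element(atom.name[:1])
                gres.add_atom(ga)
            gch.add_residue(gres)
        model.add_chain(gch)
    st.add_model(model)
    st.setup_entities()
    path = Path(path)
    if path.suffix.lower() == ".cif":
        st.make_mmcif_document().write_file(str(path))
    else:
        st.write_pdb(str(path))


def single_point_chain(
    chain_id: str,
    coords: np.ndarray,
    plddt: Iterable[float],
    amino_acids: Sequence[str] | None = None,
    atom_name: str = "CB",
) -> StructureChain:
    """Build a chain of single-pseudo-atom residues from an (n, 3) coordinate
    array — the representation used throughout the synthetic generators."""
    coords = np.asarray(coords, dtype=float)
    plddt = list(plddt)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise ValidationError("coords must be an (n, 3) array")
    if len(plddt) != coords.shape[0]:
        raise ValidationError("plddt length must match number of residues")
    if amino_acids is None:
        amino_acids = ["A"] * coords.shape[0]
    residues = [
        Residue(
            index=i + 1,
            amino_acid=amino_acids[i],
            atoms=(Atom(atom_name, *coords[i]),),
            plddt=float(plddt[i]),
        )
        for i in range(coords.shape[0])
    ]
    return StructureChain(chain_id=chain_id, residues=residues)
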