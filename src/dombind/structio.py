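"""Parsing of protein-ligand co-complex structures and residue-to-ligand geometry.

Structures are read with :mod:`gemmi` (PDB and mmCIF) and distilled into a
light-weight :class:`StructureModel`: protein/nucleic chains with per-residue
heavy atoms, plus the set of ligand instances (HETATM groups, nucleic-acid
polymer chains, and bound peptides of at most 30 residues).  All geometry
downstream of parsing works on heavy atoms only; hydrogens and deuteriums are
dropped at parse time, waters are never ligands, alternate locations are
resolved to the highest-occupancy conformer, and only the first coordinate
model of a multi-model (NMR) entry is kept.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "Chain",
    "LigandInstance",
    "StructureModel",
    "StructureParseError",
    "EmptyStructureError",
    "ChainNotFoundError",
    "parse_structure",
    "min_sidechain_distance",
    "min_any_atom_distance",
    "select_chain_for_ligand",
    "write_pdb",
]

#: atom names considered protein backbone (everything else is side chain)
PROTEIN_BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}

#: elements removed at parse time
HYDROGEN_ELEMENTS = {"H", "D"}

#: maximum length for a protein chain to also count as a peptide ligand
PEPTIDE_LIGAND_MAX_LEN = 30

WATER_NAMES = {"HOH", "DOD", "WAT"}

AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "MSE": "M", "SEC": "U", "PYL": "O",
}

NUC_TO_1 = {
    "DA": "a", "DC": "c", "DG": "g", "DT": "t", "DU": "u", "DI": "i",
    "A": "a", "C": "c", "G": "g", "U": "u", "I": "i", "T": "t",
}


class StructureParseError(ValueError):
    """Raised when a structure file cannot be parsed."""


class EmptyStructureError(ValueError):
    """Raised when a parsed structure contains no protein chain."""


class ChainNotFoundError(KeyError):
    """Raised when no chain matches a requested sequence or identifier."""


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    position: tuple[float, float, float]
    occupancy: float = 1.0
    alt_loc: str = ""


@dataclass
class Residue:
    chain_id: str
    number: int
    insertion_code: str
    name: str
    atoms: list[Atom]

    @property
    def key(self) -> tuple[int, str]:
        """Author residue number plus insertion code — the canonical key."""
        return (self.number, self.insertion_code)

    def sidechain_atoms(self, glycine_mode: str = "ca_proxy") -> list[Atom]:
        """Heavy side-chain atoms; for residues lacking any (e.g. glycine),
        either the CA atom stands in (``ca_proxy``) or the list is empty
        (``exclude``)."""
        side = [a for a in self.atoms if a.name not in PROTEIN_BACKBONE_ATOMS]
        if side:
            return side
        if glycine_mode == "ca_proxy":
            return [a for a in self.atoms if a.name == "CA"]
        if glycine_mode == "exclude":
            return []
        raise ValueError(f"unknown glycine_mode: {glycine_mode!r}")


@dataclass
class Chain:
    id: str
    residues: list[Residue]
    sequence: str
    kind: str = "protein"  # protein | nucleic

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.residues):
            raise ValueError("sequence length must equal residue count")


@dataclass
class LigandInstance:
    component_id: str
    copy_key: tuple[str, int]
    atoms: list[Atom]
    kind_hint: str = "non-polymer"  # non-polymer | polymer

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError("ligand instance has no heavy atoms")

    def coords(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float)


@dataclass
class StructureModel:
    entry_id: str
    chains: list[Chain]
    ligands: list[LigandInstance]
    model_index: int = 0


def _is_amino(name: str) -> bool:
    return name in AA3_TO_1


def _is_nucleotide(name: str) -> bool:
    return name in NUC_TO_1


def _resolve_altlocs(raw_atoms: list[gemmi.Atom]) -> list[gemmi.Atom]:
    # keep the highest-occupancy conformer per atom name; ties -> first in file
    best: dict[str, gemmi.Atom] = {}
    order: list[str] = []
    for a in raw_atoms:
        if a.name not in best:
            best[a.name] = a
            order.append(a.name)
        elif a.occ > best[a.name].occ:
            best[a.name] = a
    return [best[n] for n in order]


def _convert_residue(chain_id: str, res: gemmi.Residue) -> Residue:
    atoms = []
    for a in _resolve_altlocs(list(res)):
        elem = a.element.name.upper()
        if elem in HYDROGEN_ELEMENTS:
            continue
        pos = (a.pos.x, a.pos.y, a.pos.z)
        if not all(math.isfinite(v) for v in pos):
            raise StructureParseError(
                f"non-finite coordinate in residue {res.name} {res.seqid.num}"
            )
        atoms.append(
            Atom(
                name=a.name,
                element=elem,
                position=pos,
                occupancy=a.occ,
                alt_loc=a.altloc if a.altloc != "\0" else "",
            )
        )
    icode = res.seqid.icode.strip() if res.seqid.icode else ""
    return Residue(chain_id, res.seqid.num, icode, res.name, atoms)


def parse_structure(path: str | Path, format: str = "auto") -> StructureModel:
    """Parse a PDB or mmCIF co-complex into a :class:`StructureModel`.

    Hydrogens are removed, alt-locs resolved to the highest-occupancy
    conformer, and only the first model of a multi-model entry is kept.
    Protein chains of <= 30 residues and nucleic-acid chains are additionally
    exposed as polymer :class:`LigandInstance` objects, since bound peptides
    and DNA/RNA molecules act as ligands for the partner chains.
    """
    path = Path(path)
    if not path.exists():
        raise StructureParseError(f"no such file: {path}")
    fmt = format.lower()
    try:
        if fmt == "pdb":
            st = gemmi.read_pdb(str(path))
        elif fmt in ("mmcif", "cif"):
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
        elif fmt == "auto":
            st = gemmi.read_structure(str(path))
        else:
            raise ValueError(f"unknown format: {format!r}")
    except (RuntimeError, ValueError) as exc:
        raise StructureParseError(f"cannot parse {path}: {exc}") from exc

    if len(st) == 0:
        raise EmptyStructureError(f"{path}: no coordinate model")
    model = st[0]  # first model only for NMR ensembles

    chains: list[Chain] = []
    ligands: list[LigandInstance] = []
    for gchain in model:
        poly_res: list[Residue] = []
        kinds: list[str] = []
        for gres in gchain:
            if gres.name in WATER_NAMES:
                continue
            res = _convert_residue(gchain.name, gres)
            if not res.atoms:
                continue
            if _is_amino(gres.name):
                poly_res.append(res)
                kinds.append("protein")
            elif _is_nucleotide(gres.name):
                poly_res.append(res)
                kinds.append("nucleic")
            else:
                ligands.append(
                    LigandInstance(
                        component_id=gres.name,
                        copy_key=(gchain.name, gres.seqid.num),
                        atoms=res.atoms,
                        kind_hint="non-polymer",
                    )
                )
        if not poly_res:
            continue
        kind = "nucleic" if kinds.count("nucleic") > len(kinds) / 2 else "protein"
        if kind == "protein":
            seq = "".join(AA3_TO_1.get(r.name, "X") for r in poly_res)
        else:
            seq = "".join(NUC_TO_1.get(r.name, "x") for r in poly_res)
        chains.append(Chain(gchain.name, poly_res, seq, kind=kind))

    # polymer ligands: nucleic chains and short peptide chains
    for chain in chains:
        atoms = [a for r in chain.residues for a in r.atoms]
        if not atoms:
            continue
        if chain.kind == "nucleic":
            ligands.append(
                LigandInstance(f"NUC:{chain.id}", (chain.id, 0), atoms, "polymer")
            )
        elif len(chain.residues) <= PEPTIDE_LIGAND_MAX_LEN:
            ligands.append(
                LigandInstance(f"PEP:{chain.id}", (chain.id, 0), atoms, "polymer")
            )

    if not any(c.kind == "protein" for c in chains):
        raise EmptyStructureError(f"{path}: no protein chain")

    return StructureModel(
        entry_id=st.name or path.stem,
        chains=chains,
        ligands=ligands,
        model_index=0,
    )


def _pairwise_min(coords_a: np.ndarray, coords_b: np.ndarray) -> float:
    diff = coords_a[:, None, :] - coords_b[None, :, :]
    return float(np.sqrt((diff * diff).sum(axis=2)).min())


def min_sidechain_distance(
    residue: Residue,
    ligand: LigandInstance,
    glycine_mode: str = "ca_proxy",
) -> Optional[float]:
    """Minimum Euclidean distance from a residue's heavy side-chain atoms to
    any heavy ligand atom, in Angstroms.

    Returns ``None`` (the "no side chain" sentinel) when the residue carries
    no eligible atom, e.g. glycine under ``glycine_mode='exclude'`` or a
    residue with missing side-chain density.
    """
    side = residue.sidechain_atoms(glycine_mode=glycine_mode)
    if not side:
        return None
    coords_r = np.array([a.position for a in side], dtype=float)
    return _pairwise_min(coords_r, ligand.coords())


def min_any_atom_distance(chain: Chain, ligand: LigandInstance) -> float:
    """Minimum distance between any heavy atom of the chain and the ligand."""
    coords_c = np.array(
        [a.position for r in chain.residues for a in r.atoms], dtype=float
    )
    return _pairwise_min(coords_c, ligand.coords())


def select_chain_for_ligand(
    model: StructureModel, sequence: str, ligand: LigandInstance
) -> Chain:
    """Among chains whose sequence equals ``sequence``, pick the one closest
    to the ligand (ties broken by lexicographically smaller chain id).

    Crystal asymmetric units often contain several copies of the same chain;
    only the copy actually engaging the ligand should contribute distances.
    """
    candidates = [c for c in model.chains if c.sequence == sequence]
    if not candidates:
        raise ChainNotFoundError(
            f"no chain in {model.entry_id} matches the given sequence"
        )
    return min(candidates, key=lambda c: (min_any_atom_distance(c, ligand), c.id))


def resolve_chain(model: StructureModel, protein_id: str) -> Chain:
    """Find a chain by ``protein_id``, accepting either a bare chain id or
    an ``entry:chain`` composite."""
    chain_id = protein_id.rsplit(":", 1)[-1]
    for c in model.chains:
        if c.id == chain_id:
            return c
    raise ChainNotFoundError(f"chain {chain_id!r} not in {model.entry_id}")


# ---------------------------------------------------------------------------
# minimal fixed-column PDB writer (used by the fixture generator and for
# round-trip testing)

def _pdb_atom_line(
    serial: int, record: str, atom: Atom, res_name: str, chain_id: str, res_num: int
) -> str:
    name = atom.name
    # standard PDB alignment: 1-3 char names start in column 14
    name_field = f" {name:<3s}" if len(name) < 4 else name
    x, y, z = atom.position
    return (
        f"{record:<6s}{serial:>5d} {name_field}{'':1s}{res_name:>3s} "
        f"{chain_id:1s}{res_num:>4d}{'':1s}   "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{0.0:6.2f}"
        f"          {atom.element:>2s}"
    )


def write_pdb(model: StructureModel, path: str | Path) -> None:
    """Serialize a :class:`StructureModel` as a minimal valid PDB file."""
    lines = [f"HEADER    {'SYNTHETIC COMPLEX':<40s}{'':12s}{model.entry_id[:4].upper():<4s}"]
    serial = 1
    for chain in model.chains:
        for res in chain.residues:
            for atom in res.atoms:
                lines.append(
                    _pdb_atom_line(serial, "ATOM", atom, res.name, chain.id, res.number)
                )
                serial += 1
        lines.append(f"TER   {serial:>5d}")
        serial += 1
    for lig in model.ligands:
        if lig.kind_hint == "polymer":
            continue  # polymer ligands are already written as chains
        chain_id, res_num = lig.copy_key
        for atom in lig.atoms:
            lines.append(
                _pdb_atom_line(
                    serial, "HETATM", atom, lig.component_id, chain_id, res_num
                )
            )
            serial += 1
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")
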