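"""Ligand classification: nucleic-acid base/backbone partition, ion naming,
and metabolite / drug-likeness by chemical-fingerprint similarity.

Ligands are grouped into biologically meaningful classes.  Nucleic-acid
chains are typed DNA vs RNA by the presence of the ribose 2'-hydroxyl (the
O2' atom), and their atoms split into base vs backbone sets, since residues
contacting bases tend to determine binding specificity while backbone
contacts contribute stability.  Compounds whose full chemical name contains
the standalone word "ion" form the ion class; all remaining compounds are
small molecules and are additionally labelled metabolite-like and/or
drug-like when their fingerprint Tanimoto similarity to a reference compound
set reaches a cutoff (0.9 by default; lowering it only grows the sets).

SMILES parsing and fingerprinting are delegated to RDKit; the Tanimoto
coefficient itself is computed here on plain bit vectors.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import rdmolops

from .structio import Chain, Residue

RDLogger.DisableLog("rdApp.*")

logger = logging.getLogger(__name__)

__all__ = [
    "LigandClass",
    "CompoundRecord",
    "ReferenceCompoundSet",
    "NUCLEIC_BACKBONE_ATOMS",
    "classify_nucleic_chain",
    "partition_nucleic_atoms",
    "classify_ligand",
    "tanimoto",
    "fingerprint",
    "load_reference_set",
    "load_compound_table",
]


class LigandClass:
    """Ligand group labels.  METABOLITE and DRUGLIKE always co-occur with
    SMALL_MOLECULE; a single ligand may carry several labels."""

    DNA_BASE = "DNA_BASE"
    DNA_BACKBONE = "DNA_BACKBONE"
    RNA_BASE = "RNA_BASE"
    RNA_BACKBONE = "RNA_BACKBONE"
    PEPTIDE = "PEPTIDE"
    ION = "ION"
    METABOLITE = "METABOLITE"
    DRUGLIKE = "DRUGLIKE"
    SMALL_MOLECULE = "SMALL_MOLECULE"

    ALL = (
        DNA_BASE, DNA_BACKBONE, RNA_BASE, RNA_BACKBONE,
        PEPTIDE, ION, METABOLITE, DRUGLIKE, SMALL_MOLECULE,
    )


@dataclass(frozen=True)
class CompoundRecord:
    component_id: str
    full_name: str
    smiles: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.component_id:
            raise ValueError("component_id must be non-empty")


@dataclass
class ReferenceCompoundSet:
    name: str
    smiles_list: list[str]
    _fps: Optional[list[np.ndarray]] = field(default=None, repr=False)

    def fingerprints(self, n_bits: int = 1024) -> list[np.ndarray]:
        if self._fps is None:
            fps = []
            for smi in self.smiles_list:
                fp = fingerprint(smi, n_bits=n_bits)
                if fp is None:
                    raise ValueError(f"unparseable reference SMILES: {smi!r}")
                fps.append(fp)
            self._fps = fps
        return self._fps


#: phosphate + sugar atom names of a nucleotide; every other heavy atom is base
NUCLEIC_BACKBONE_ATOMS = {
    "P", "OP1", "OP2", "OP3",
    "O5'", "C5'", "C4'", "O4'", "C3'", "O3'", "C2'", "O2'", "C1'",
}

_STANDARD_NUCLEOTIDES = {
    "DA", "DC", "DG", "DT", "DU", "DI", "A", "C", "G", "U", "I", "T",
}

_ION_WORD = re.compile(r"(?<![A-Za-z])ion(?![A-Za-z])", re.IGNORECASE)


def classify_nucleic_chain(chain: Chain) -> str:
    """Type a nucleic-acid chain as ``"RNA"`` or ``"DNA"`` by the presence of
    the 2'-hydroxyl oxygen (O2') in any of its riboses."""
    if not chain.residues:
        raise ValueError("empty chain")
    for res in chain.residues:
        if any(a.name == "O2'" for a in res.atoms):
            return "RNA"
    return "DNA"


def partition_nucleic_atoms(residue: Residue) -> dict[str, set[str]]:
    """Split a nucleotide residue's heavy atoms into backbone
    (phosphate + sugar) and base atom-name sets.

    Modified nucleotides are partitioned over whatever standard atom names
    they present.  Returns ``{"base": ..., "backbone": ...}``; the two sets
    partition the residue's heavy atoms.
    """
    if not _is_nucleotide_like(residue):
        raise ValueError(f"residue {residue.name!r} is not a nucleotide")
    names = {a.name for a in residue.atoms}
    backbone = names & NUCLEIC_BACKBONE_ATOMS
    base = names - backbone
    return {"base": base, "backbone": backbone}


def _is_nucleotide_like(residue: Residue) -> bool:
    if residue.name in _STANDARD_NUCLEOTIDES:
        return True
    # modified nucleotides: recognizable by sugar/phosphate atom names
    names = {a.name for a in residue.atoms}
    return len(names & NUCLEIC_BACKBONE_ATOMS) >= 3


def fingerprint(smiles: str, n_bits: int = 1024) -> Optional[np.ndarray]:
    """Linear-path bit fingerprint of a SMILES string as a boolean vector, or
    ``None`` when the SMILES does not parse."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return None
    fp = rdmolops.RDKFingerprint(mol, fpSize=n_bits)
    arr = np.zeros(n_bits, dtype=bool)
    for bit in fp.GetOnBits():
        arr[bit] = True
    return arr


def tanimoto(fp_a: np.ndarray, fp_b: np.ndarray) -> float:
    """Tanimoto coefficient |a AND b| / |a OR b| of two same-length bit
    fingerprints; defined as 0 when both are empty."""
    fp_a = np.asarray(fp_a, dtype=bool)
    fp_b = np.asarray(fp_b, dtype=bool)
    if fp_a.shape != fp_b.shape:
        raise ValueError(
            f"fingerprint length mismatch: {fp_a.shape} vs {fp_b.shape}"
        )
    union = int(np.logical_or(fp_a, fp_b).sum())
    if union == 0:
        return 0.0
    return int(np.logical_and(fp_a, fp_b).sum()) / union


def _max_tanimoto(fp: np.ndarray, refs: Sequence[np.ndarray]) -> float:
    return max((tanimoto(fp, r) for r in refs), default=0.0)


def classify_ligand(
    compound: CompoundRecord,
    metabolites: Optional[ReferenceCompoundSet] = None,
    drugs: Optional[ReferenceCompoundSet] = None,
    threshold: float = 0.9,
    n_bits: int = 1024,
) -> set[str]:
    """Assign ligand-group labels to a chemical compound.

    A compound whose full name contains the standalone word "ion" is an ION
    and nothing else.  Every other compound is a SMALL_MOLECULE; it gains
    METABOLITE (resp. DRUGLIKE) when the maximum Tanimoto similarity of its
    fingerprint against the metabolite (resp. drug) reference set reaches
    ``threshold``.  A small molecule with unparseable SMILES is skipped with
    a logged warning (empty label set), never silently classified.
    """
    if _ION_WORD.search(compound.full_name):
        return {LigandClass.ION}
    labels = {LigandClass.SMALL_MOLECULE}
    if metabolites is None and drugs is None:
        return labels
    if compound.smiles is None:
        logger.warning(
            "compound %s has no SMILES; skipping similarity classification",
            compound.component_id,
        )
        return set()
    fp = fingerprint(compound.smiles, n_bits=n_bits)
    if fp is None:
        logger.warning(
            "compound %s: unparseable SMILES %r; skipped",
            compound.component_id, compound.smiles,
        )
        return set()
    if metabolites is not None and _max_tanimoto(
        fp, metabolites.fingerprints(n_bits)
    ) >= threshold:
        labels.add(LigandClass.METABOLITE)
    if drugs is not None and _max_tanimoto(fp, drugs.fingerprints(n_bits)) >= threshold:
        labels.add(LigandClass.DRUGLIKE)
    return labels


def load_reference_set(path: str | Path, name: str) -> ReferenceCompoundSet:
    """Read a reference compound set: one SMILES per line, optionally followed
    by a tab-separated identifier; blank lines and '#' comments ignored."""
    smiles = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        smiles.append(line.split("\t")[0])
    if not smiles:
        raise ValueError(f"reference set {path} is empty")
    return ReferenceCompoundSet(name, smiles)


def load_compound_table(path: str | Path) -> list[CompoundRecord]:
    """Read a compound table: TSV of (component_id, full_name[, smiles])."""
    records = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 2:
            raise ValueError(f"{path}:{ln}: expected at least 2 columns")
        smiles = parts[2] if len(parts) > 2 and parts[2] else None
        records.append(CompoundRecord(parts[0], parts[1], smiles))
    return records
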