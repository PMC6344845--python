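"""Synthetic co-complex families and proteomes with planted ground truth.

Everything the pipeline consumes — structures, hit tables, domain-model
metadata, binding annotations, query FASTA and site lists — can be generated
here with known answers, so every stage is testable without any external
database.  A toy family consists of single-chain structures whose residues
are two-atom stubs (CA plus one side-chain atom) arranged around a small
pseudo-ligand; residues at designated binding states are placed at a
controlled distance below the 3.6 A contact cutoff and all others well
beyond it, with optional Gaussian jitter and sequence mutation.  Geometry is
exact: each side-chain atom sits at its sampled distance from the nearest
ligand atom, so the planted per-state distances are recovered verbatim by
the distance code.  No attempt is made at physical realism (sterics,
rotamers, energies); the fixtures exercise contracts, not chemistry.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .domhits import (
    AMINO_ALPHABET,
    DomainHit,
    DomainModel,
    save_domain_models,
    write_domain_hits,
)
from .structio import Atom, Chain, LigandInstance, Residue, StructureModel, write_pdb

__all__ = [
    "FamilySpec",
    "ToyFamily",
    "make_toy_family",
    "build_family",
    "make_toy_proteome",
    "load_annotation_table",
]

# sequences avoid glycine so every stub residue carries a real side-chain atom
_FAMILY_ALPHABET = AMINO_ALPHABET.replace("G", "")

_ONE_TO_THREE = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
    "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU", "M": "MET",
    "N": "ASN", "P": "PRO", "Q": "GLN", "R": "ARG", "S": "SER",
    "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR", "G": "GLY",
}

#: minimum physically plausible heavy-atom contact distance
MIN_CONTACT_DISTANCE = 1.5

_LIGAND_ATOM_SPACING = 1.4


@dataclass
class FamilySpec:
    """Parameters of a planted domain-ligand family.

    Defaults describe a mid-sized family: 20 match states of which 5 bind,
    contact distances centred at 3.0 A (inside the 3.6 A cutoff) against
    7.5 A for non-binding states, moderate jitter and sequence divergence.
    """

    n_states: int = 20
    n_instances: int = 10
    binding_states: tuple[int, ...] = (3, 7, 8, 14, 19)
    binding_distance_mean: float = 3.0
    nonbinding_distance_mean: float = 7.5
    distance_noise_sd: float = 0.25
    mutation_rate: float = 0.15
    redundancy: int = 0
    n_ligand_atoms: int = 5
    accession: str = "TOY00001"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.binding_distance_mean < 3.6 < self.nonbinding_distance_mean):
            raise ValueError(
                "binding mean must be < 3.6 A and nonbinding mean > 3.6 A"
            )
        if not 0 <= self.mutation_rate <= 1:
            raise ValueError("mutation_rate must lie in [0, 1]")
        if not all(1 <= s <= self.n_states for s in self.binding_states):
            raise ValueError("binding states must lie in [1, n_states]")
        if not (3 <= self.n_ligand_atoms <= 8):
            raise ValueError("pseudo-ligand has 3-8 heavy atoms")
        if self.nonbinding_distance_mean - 4 * self.distance_noise_sd <= 3.6:
            raise ValueError(
                "nonbinding distances would cross the 3.6 A cutoff; "
                "lower the noise or raise the mean"
            )


@dataclass
class ToyFamily:
    """In-memory view of a generated family with its planted truth."""

    spec: FamilySpec
    model: DomainModel
    structures: list[StructureModel]
    hits: list[DomainHit]
    ligands: list[LigandInstance]
    sequences: dict[str, str]  # protein_id -> chain sequence
    distances: np.ndarray  # (n_total_instances, n_states) planted distances
    annotation: dict[str, set[int]]  # entry_id -> binding residue indices

    @property
    def instances(self) -> list[tuple[DomainHit, StructureModel, LigandInstance]]:
        return list(zip(self.hits, self.structures, self.ligands))


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lower: float) -> float:
    if sd == 0:
        if mean < lower:
            raise ValueError(f"degenerate distance {mean} below {lower}")
        return mean
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if x >= lower:
            return float(x)
    raise ValueError("geometric placement infeasible under spec")


def _mutate(rng: np.random.Generator, consensus: str, rate: float) -> str:
    out = []
    for ch in consensus:
        if rate > 0 and rng.random() < rate:
            choices = [c for c in _FAMILY_ALPHABET if c != ch]
            out.append(choices[rng.integers(0, len(choices))])
        else:
            out.append(ch)
    return "".join(out)


def _build_structure(
    entry_id: str, sequence: str, dists: np.ndarray, n_ligand_atoms: int
) -> tuple[StructureModel, LigandInstance, np.ndarray]:
    """Place residue stubs around the pseudo-ligand at the requested
    distances.  Coordinates are rounded to the 3 decimals PDB files carry;
    the returned array holds the distances realized by the rounded
    coordinates, which round-trip exactly through serialization."""
    n = len(sequence)
    lig_atoms = [
        Atom(f"C{k + 1}", "C", (0.0, 0.0, k * _LIGAND_ATOM_SPACING))
        for k in range(n_ligand_atoms)
    ]
    ligand = LigandInstance("LIG", ("L", 1), lig_atoms, "non-polymer")
    residues = []
    realized = np.empty(n)
    for i in range(n):
        d = dists[i]
        theta = 2 * math.pi * (i + 1) / (n + 1)
        anchor_z = (i % n_ligand_atoms) * _LIGAND_ATOM_SPACING
        cx, cy = math.cos(theta), math.sin(theta)
        bx, by = round(d * cx, 3), round(d * cy, 3)
        cb = Atom("CB", "C", (bx, by, anchor_z))
        ca = Atom("CA", "C",
                  (round((d + 2.0) * cx, 3), round((d + 2.0) * cy, 3), anchor_z))
        residues.append(
            Residue("A", i + 1, "", _ONE_TO_THREE[sequence[i]], [ca, cb])
        )
        # the anchor atom shares the CB's z, every other ligand atom is
        # farther, so the realized minimum distance is in the xy-plane
        realized[i] = math.hypot(bx, by)
    chain = Chain("A", residues, sequence, kind="protein")
    model = StructureModel(entry_id, [chain], [ligand])
    return model, ligand, realized


def build_family(spec: FamilySpec) -> ToyFamily:
    """Generate a toy family in memory (see :func:`make_toy_family` for the
    on-disk form)."""
    rng = np.random.default_rng(spec.seed)
    consensus = "".join(
        _FAMILY_ALPHABET[rng.integers(0, len(_FAMILY_ALPHABET))]
        for _ in range(spec.n_states)
    )
    binding = set(spec.binding_states)
    structures, hits, ligands = [], [], []
    sequences: dict[str, str] = {}
    all_dists = []
    annotation: dict[str, set[int]] = {}
    base_records: list[tuple[str, np.ndarray]] = []

    for i in range(spec.n_instances):
        seq = _mutate(rng, consensus, spec.mutation_rate)
        dists = np.array(
            [
                _truncated_normal(
                    rng,
                    spec.binding_distance_mean
                    if (s + 1) in binding
                    else spec.nonbinding_distance_mean,
                    spec.distance_noise_sd,
                    MIN_CONTACT_DISTANCE,
                )
                for s in range(spec.n_states)
            ]
        )
        base_records.append((seq, dists))
    # exact duplicates of the first instance test redundancy neutralization
    for r in range(spec.redundancy):
        base_records.append(base_records[0])

    for i, (seq, dists) in enumerate(base_records):
        entry = f"T{i:03d}"
        model, ligand, dists = _build_structure(
            entry, seq, dists, spec.n_ligand_atoms
        )
        protein_id = f"{entry}:A"
        hit = DomainHit(
            protein_id,
            spec.accession,
            bit_score=100.0,
            state_map={s: s for s in range(1, spec.n_states + 1)},
        )
        structures.append(model)
        hits.append(hit)
        ligands.append(ligand)
        sequences[protein_id] = seq
        all_dists.append(dists)
        annotation[entry] = {
            s for s in range(1, spec.n_states + 1) if dists[s - 1] <= 3.6
        }

    # emissions: consensus residue at 60 %, the rest uniform — diffuse enough
    # that no state reaches the 4-bit invariance filter on mutated sequences
    emissions = np.full((spec.n_states, 20), 0.4 / 19)
    for s, ch in enumerate(consensus):
        emissions[s, AMINO_ALPHABET.index(ch)] = 0.6
    model_meta = DomainModel(spec.accession, spec.n_states, 10.0, emissions)

    return ToyFamily(
        spec=spec,
        model=model_meta,
        structures=structures,
        hits=hits,
        ligands=ligands,
        sequences=sequences,
        distances=np.vstack(all_dists),
        annotation=annotation,
    )


def make_toy_family(spec: FamilySpec, outdir: str | Path) -> ToyFamily:
    """Generate a toy family and write it in the exact dialects the reader
    modules consume: one PDB per instance, a hit table, domain-model JSON,
    and a binding-annotation TSV.  Byte-identical for identical specs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fam = build_family(spec)
    for st in fam.structures:
        write_pdb(st, outdir / f"{st.entry_id}.pdb")
    write_domain_hits(fam.hits, fam.sequences, outdir / "hits.tsv")
    save_domain_models([fam.model], outdir / "models.json")
    lines = ["#entry_id\tchain\tcomponent_id\tbinding_residues"]
    for st in fam.structures:
        res = sorted(fam.annotation[st.entry_id])
        lines.append(
            f"{st.entry_id}\tA\tLIG\t{','.join(map(str, res))}"
        )
    (outdir / "annotation.tsv").write_text("\n".join(lines) + "\n")
    return fam


def load_annotation_table(path: str | Path) -> dict[tuple[str, str], set[int]]:
    """Read a binding-annotation TSV into (entry_id, chain) -> residue set."""
    out: dict[tuple[str, str], set[int]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        entry, chain, _comp, residues = line.rstrip("\n").split("\t")
        positions = {int(x) for x in residues.split(",") if x}
        out.setdefault((entry, chain), set()).update(positions)
    return out


# ---------------------------------------------------------------------------
# synthetic proteome for overlap testing


def make_toy_proteome(
    n_proteins: int = 20,
    length_range: tuple[int, int] = (200, 400),
    binding_fraction: float = 0.15,
    n_interest_sites: int = 1000,
    enrichment: float = 1.0,
    seed: int = 0,
    outdir: Optional[str | Path] = None,
) -> tuple[dict[str, str], dict[str, set[int]], list[tuple[str, int]]]:
    """Generate a proteome with planted binding sites and interest sites.

    Interest sites are drawn independently over all residues with weight
    ``enrichment`` inside binding sites and 1 elsewhere, so ``enrichment=1``
    realizes exactly the Poisson-binomial null of the overlap test and
    ``enrichment=0`` yields zero overlap.  Optionally writes FASTA plus
    binding-site and site-list TSVs to ``outdir``.
    """
    if enrichment < 0:
        raise ValueError("enrichment must be >= 0")
    if n_proteins < 1 or n_interest_sites < 1:
        raise ValueError("need at least one protein and one interest site")
    rng = np.random.default_rng(seed)
    proteins: dict[str, str] = {}
    binding: dict[str, set[int]] = {}
    flat: list[tuple[str, int]] = []
    weights: list[float] = []
    for i in range(n_proteins):
        pid = f"P{i:04d}"
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        seq = "".join(
            AMINO_ALPHABET[j] for j in rng.integers(0, 20, size=length)
        )
        n_binding = int(round(length * binding_fraction))
        sites = set(
            (rng.permutation(length)[:n_binding] + 1).tolist()
        )
        proteins[pid] = seq
        binding[pid] = sites
        for pos in range(1, length + 1):
            flat.append((pid, pos))
            weights.append(enrichment if pos in sites else 1.0)
    w = np.asarray(weights)
    if w.sum() == 0:
        raise ValueError("all residue weights are zero")
    idx = rng.choice(len(flat), size=n_interest_sites, replace=True, p=w / w.sum())
    interest = [flat[j] for j in idx]

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        fasta = []
        for pid, seq in proteins.items():
            fasta.append(f">{pid}")
            fasta.extend(seq[k:k + 60] for k in range(0, len(seq), 60))
        (outdir / "proteome.fasta").write_text("\n".join(fasta) + "\n")
        (outdir / "binding_sites.tsv").write_text(
            "\n".join(
                f"{pid}\t{pos}"
                for pid in sorted(binding)
                for pos in sorted(binding[pid])
            )
            + "\n"
        )
        (outdir / "interest_sites.tsv").write_text(
            "\n".join(f"{pid}\t{pos}" for pid, pos in interest) + "\n"
        )
    return proteins, binding, interest
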