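"""Per-domain-position binding frequencies.

The scoring engine at the heart of the package.  For a domain family and a
ligand class, every qualifying structural instance contributes, at each
match state it maps, the minimum distance between the mapped residue's heavy
side-chain atoms and the ligand's heavy atoms.  The per-state binding
frequency is then the sequence-weighted fraction of instances whose residue
sits within a contact cutoff (3.6 A by default — wide enough for hydrogen
bonds and van der Waals contacts, short enough to exclude water-mediated
interactions).  Henikoff-Henikoff position-based weights down-weight
redundant instance sequences so that repeatedly crystallized proteins do not
dominate.  Uncertainty per state is estimated as the standard deviation of
the frequency over bootstrap resamples of the instances.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .domhits import DomainHit
from .ligandtype import LigandClass, partition_nucleic_atoms
from .structio import (
    Atom,
    LigandInstance,
    StructureModel,
    min_sidechain_distance,
    resolve_chain,
    select_chain_for_ligand,
)

__all__ = [
    "DistanceProfile",
    "WeightVector",
    "BindingFrequencyTable",
    "DEFAULT_DISTANCE_CUTOFF",
    "restrict_ligand_atoms",
    "build_distance_profile",
    "henikoff_weights",
    "binding_frequency",
    "bootstrap_se",
    "write_frequency_table",
    "read_frequency_table",
]

#: default residue-to-ligand contact cutoff in Angstroms
DEFAULT_DISTANCE_CUTOFF = 3.6

GAP = "-"

#: atom-subset restriction per nucleic ligand class
_NUCLEIC_SUBSET = {
    LigandClass.DNA_BASE: "base",
    LigandClass.DNA_BACKBONE: "backbone",
    LigandClass.RNA_BASE: "base",
    LigandClass.RNA_BACKBONE: "backbone",
}


@dataclass
class DistanceProfile:
    """Per match state, the (instance_id, min distance) observations."""

    accession: str
    ligand_class: str
    entries: dict[int, list[tuple[str, float]]]
    instance_ids: list[str]

    def states(self) -> list[int]:
        return sorted(self.entries)

    def distance_matrix(self) -> tuple[np.ndarray, list[int]]:
        """Instances x states matrix of distances, NaN where unmapped."""
        states = self.states()
        idx = {iid: i for i, iid in enumerate(self.instance_ids)}
        mat = np.full((len(self.instance_ids), len(states)), np.nan)
        for j, s in enumerate(states):
            for iid, d in self.entries[s]:
                mat[idx[iid], j] = d
        return mat, states

    def subset(self, instance_ids: Sequence[str]) -> "DistanceProfile":
        """Profile restricted to (possibly repeated) instances; repeats get
        suffixed ids so each draw counts separately."""
        new_ids = []
        alias: list[tuple[str, str]] = []
        seen: dict[str, int] = {}
        for iid in instance_ids:
            n = seen.get(iid, 0)
            seen[iid] = n + 1
            new_id = iid if n == 0 else f"{iid}#dup{n}"
            new_ids.append(new_id)
            alias.append((iid, new_id))
        entries: dict[int, list[tuple[str, float]]] = {}
        for s, obs in self.entries.items():
            by_id = dict(obs)
            lst = [
                (new_id, by_id[iid]) for iid, new_id in alias if iid in by_id
            ]
            if lst:
                entries[s] = lst
        return DistanceProfile(self.accession, self.ligand_class, entries, new_ids)


@dataclass
class WeightVector:
    weights: dict[str, float]

    def __post_init__(self) -> None:
        total = sum(self.weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"weights sum to {total}, not 1")
        if any(w <= 0 for w in self.weights.values()):
            raise ValueError("weights must be positive")


@dataclass
class BindingFrequencyTable:
    accession: str
    ligand_class: str
    frequency: dict[int, float]
    bootstrap_se: dict[int, float] = field(default_factory=dict)
    n_instances: dict[int, int] = field(default_factory=dict)

    def states(self) -> list[int]:
        return sorted(self.frequency)


def restrict_ligand_atoms(ligand: LigandInstance, ligand_class: str) -> LigandInstance:
    """For nucleic ligand classes, restrict the ligand to its base or
    backbone atoms (by atom name); other classes pass through unchanged."""
    side = _NUCLEIC_SUBSET.get(ligand_class)
    if side is None:
        return ligand
    from .ligandtype import NUCLEIC_BACKBONE_ATOMS

    if side == "backbone":
        atoms = [a for a in ligand.atoms if a.name in NUCLEIC_BACKBONE_ATOMS]
    else:
        atoms = [a for a in ligand.atoms if a.name not in NUCLEIC_BACKBONE_ATOMS]
    if not atoms:
        raise ValueError(
            f"ligand {ligand.component_id} has no {side} atoms for {ligand_class}"
        )
    return LigandInstance(ligand.component_id, ligand.copy_key, atoms, ligand.kind_hint)


def instance_key(model: StructureModel, hit: DomainHit, ligand: LigandInstance) -> str:
    return (
        f"{model.entry_id}|{hit.protein_id}|{ligand.component_id}"
        f"|{ligand.copy_key[0]}{ligand.copy_key[1]}"
    )


def build_distance_profile(
    instances: Sequence[tuple[DomainHit, StructureModel, LigandInstance]],
    ligand_class: str,
    glycine_mode: str = "ca_proxy",
) -> DistanceProfile:
    """Aggregate per-state minimum side-chain-to-ligand distances across
    structural instances of one domain family and one ligand class.

    For each instance the contributing chain is the copy, among chains with
    the hit's sequence, closest to the ligand.  States a hit does not map —
    or whose residue has no eligible side-chain atom — contribute nothing.
    """
    if not instances:
        raise ValueError("no instances")
    accessions = {hit.accession for hit, _, _ in instances}
    if len(accessions) != 1:
        raise ValueError(f"mixed accessions in profile: {sorted(accessions)}")

    entries: dict[int, list[tuple[str, float]]] = {}
    ids: list[str] = []
    for hit, model, ligand in instances:
        lig = restrict_ligand_atoms(ligand, ligand_class)
        named = resolve_chain(model, hit.protein_id)
        chain = select_chain_for_ligand(model, named.sequence, lig)
        iid = instance_key(model, hit, ligand)
        ids.append(iid)
        res_by_pos = {i + 1: r for i, r in enumerate(chain.residues)}
        for state, pos in hit.state_map.items():
            residue = res_by_pos.get(pos)
            if residue is None:
                raise ValueError(
                    f"{iid}: mapped residue {pos} outside chain {chain.id}"
                )
            d = min_sidechain_distance(residue, lig, glycine_mode=glycine_mode)
            if d is None:  # "no side chain" sentinel: treat state as unmapped
                continue
            entries.setdefault(state, []).append((iid, d))
    return DistanceProfile(accessions.pop(), ligand_class, entries, ids)


def henikoff_weights(alignment: Mapping[str, str]) -> WeightVector:
    """Henikoff-Henikoff position-based sequence weights, normalized to 1.

    In each alignment column with ``r`` distinct residue types where type
    ``a`` occurs in ``n_a`` rows, a row carrying ``a`` scores ``1/(r*n_a)``.
    A row's raw weight is the mean of its scores over its non-gap columns;
    gap characters neither define a residue type nor receive a score.
    """
    ids = list(alignment)
    if not ids:
        raise ValueError("empty alignment")
    rows = [alignment[i] for i in ids]
    ncol = len(rows[0])
    if ncol == 0 or any(len(r) != ncol for r in rows):
        raise ValueError("alignment rows must share a positive length")

    scores = np.zeros((len(ids), ncol))
    counted = np.zeros((len(ids), ncol), dtype=bool)
    for c in range(ncol):
        col = [r[c] for r in rows]
        types: dict[str, int] = {}
        for ch in col:
            if ch != GAP:
                types[ch] = types.get(ch, 0) + 1
        r_c = len(types)
        if r_c == 0:
            continue
        for i, ch in enumerate(col):
            if ch != GAP:
                scores[i, c] = 1.0 / (r_c * types[ch])
                counted[i, c] = True

    n_cols = counted.sum(axis=1)
    if (n_cols == 0).any():
        bad = [ids[i] for i in np.flatnonzero(n_cols == 0)]
        raise ValueError(f"all-gap instance(s): {bad}")
    raw = scores.sum(axis=1) / n_cols
    raw /= raw.sum()
    return WeightVector(dict(zip(ids, raw)))


def binding_frequency(
    profile: DistanceProfile,
    weights: WeightVector,
    cutoff: float = DEFAULT_DISTANCE_CUTOFF,
) -> BindingFrequencyTable:
    """Weighted fraction of instances, per match state, whose residue lies
    within ``cutoff`` of the ligand.  The denominator counts only instances
    that map the state; states mapped by no instance are absent, not 0."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    freq: dict[int, float] = {}
    n_inst: dict[int, int] = {}
    for state, obs in profile.entries.items():
        num = sum(weights.weights[iid] for iid, d in obs if d <= cutoff)
        den = sum(weights.weights[iid] for iid, _ in obs)
        if den > 0:
            freq[state] = num / den
            n_inst[state] = len(obs)
    return BindingFrequencyTable(
        profile.accession, profile.ligand_class, freq, {}, n_inst
    )


def _alignment_subset(
    alignment: Mapping[str, str], ids: Sequence[str], new_ids: Sequence[str]
) -> dict[str, str]:
    return {nid: alignment[iid] for iid, nid in zip(ids, new_ids)}


def bootstrap_se(
    profile: DistanceProfile,
    alignment: Mapping[str, str],
    B: int = 1000,
    seed: int = 0,
    cutoff: float = DEFAULT_DISTANCE_CUTOFF,
    recompute_weights: bool = True,
) -> dict[int, float]:
    """Bootstrap standard errors of per-state binding frequencies.

    Instances are resampled with replacement ``B`` times; in each resample
    the Henikoff weights and the frequencies are recomputed (optionally the
    original weights are reused) and the per-state standard deviation over
    resamples is returned.  States absent from a resample contribute no
    value for that resample.
    """
    if B < 2:
        raise ValueError("need at least 2 bootstrap resamples")
    if len(profile.instance_ids) < 2:
        raise ValueError("need at least 2 instances to bootstrap")
    rng = np.random.default_rng(seed)
    ids = profile.instance_ids
    base_weights = None if recompute_weights else henikoff_weights(alignment)
    samples: dict[int, list[float]] = {s: [] for s in profile.entries}
    for _ in range(B):
        draw = [ids[i] for i in rng.integers(0, len(ids), size=len(ids))]
        sub = profile.subset(draw)
        if recompute_weights:
            w = henikoff_weights(_alignment_subset(alignment, draw, sub.instance_ids))
        else:
            raw = {nid: base_weights.weights[iid] for iid, nid in zip(draw, sub.instance_ids)}
            total = sum(raw.values())
            w = WeightVector({k: v / total for k, v in raw.items()})
        table = binding_frequency(sub, w, cutoff=cutoff)
        for s, f in table.frequency.items():
            samples[s].append(f)
    return {
        s: float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
        for s, vals in samples.items()
    }


# ---------------------------------------------------------------------------
# release-table I/O

_TABLE_COLUMNS = (
    "domain_accession", "ligand_class", "match_state",
    "binding_frequency", "bootstrap_se", "n_instances",
)


def write_frequency_table(
    tables: Iterable[BindingFrequencyTable], path: str | Path
) -> None:
    rows = []
    for t in tables:
        for s in t.states():
            rows.append(
                (
                    t.accession,
                    t.ligand_class,
                    s,
                    t.frequency[s],
                    t.bootstrap_se.get(s, float("nan")),
                    t.n_instances.get(s, 0),
                )
            )
    df = pd.DataFrame(rows, columns=_TABLE_COLUMNS)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_frequency_table(path: str | Path) -> list[BindingFrequencyTable]:
    df = pd.read_csv(path, sep="\t")
    tables = []
    for (acc, lc), grp in df.groupby(["domain_accession", "ligand_class"], sort=True):
        tables.append(
            BindingFrequencyTable(
                accession=acc,
                ligand_class=lc,
                frequency=dict(zip(grp["match_state"], grp["binding_frequency"])),
                bootstrap_se=dict(zip(grp["match_state"], grp["bootstrap_se"])),
                n_instances=dict(zip(grp["match_state"], grp["n_instances"])),
            )
        )
    return tables
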