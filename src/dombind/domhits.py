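"""Domain models, domain-instance hits, and instance-inclusion filters.

A domain family is summarized by its profile's match states: the number of
states, the curated gathering bit-score threshold, and per-state amino-acid
emission distributions.  A hit maps match states (1-based) onto residue
positions (1-based) of one protein chain; insertions relative to the model
leave jumps in the mapped residue indices, deletions leave missing states.

Structural instances enter the aggregation only if they (i) score at or
above the family's gathering threshold, (ii) carry residues at the first
and last match states, (iii) show the modal amino acid at every mapped
high-information state (information content >= 4 bits against a uniform
background, i.e. essentially invariant positions), and (iv) include at
least one annotated binding residue.

Hit-table dialect
-----------------
Tab-separated columns::

    protein_id  accession  bit_score  hmm_start  seq_start  hmm_align  seq_align

``hmm_align`` marks match columns with letters and insert columns with
``.``; ``seq_align`` holds residue letters with ``-`` at deleted match
columns.  This mirrors the alignment blocks of profile-HMM search output.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

__all__ = [
    "AMINO_ALPHABET",
    "DomainModel",
    "DomainHit",
    "InstanceFilterReport",
    "information_content",
    "filter_instance",
    "parse_domain_hits",
    "write_domain_hits",
    "load_domain_models",
    "save_domain_models",
]

AMINO_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(AMINO_ALPHABET)}

#: bits of information above which a state's modal residue is required
HIGH_IC_BITS = 4.0


@dataclass
class DomainModel:
    accession: str
    n_match_states: int
    gathering_threshold: float
    emissions: np.ndarray  # (n_match_states, 20), rows sum to 1

    def __post_init__(self) -> None:
        self.emissions = np.asarray(self.emissions, dtype=float)
        if self.emissions.shape != (self.n_match_states, len(AMINO_ALPHABET)):
            raise ValueError(
                f"emissions shape {self.emissions.shape} does not match "
                f"{self.n_match_states} states x 20 amino acids"
            )
        sums = self.emissions.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("emission rows must each sum to 1")

    def modal_residues(self, state: int) -> set[str]:
        """Amino acid(s) with maximal emission probability at a match state
        (1-based); ties return all tied maxima."""
        row = self.emissions[state - 1]
        mx = row.max()
        return {AMINO_ALPHABET[i] for i in np.flatnonzero(row >= mx - 1e-12)}


@dataclass
class DomainHit:
    protein_id: str
    accession: str
    bit_score: float
    state_map: dict[int, int]  # match state (1-based) -> residue index (1-based)

    def __post_init__(self) -> None:
        keys = list(self.state_map)
        vals = list(self.state_map.values())
        if any(k2 <= k1 for k1, k2 in zip(keys, keys[1:])) or any(
            v2 <= v1 for v1, v2 in zip(vals, vals[1:])
        ):
            raise ValueError("state_map must be strictly increasing")

    def aligned_row(self, sequence: str, n_states: int) -> str:
        """One alignment row over the model's match states: the residue letter
        where the state is mapped, '-' where it is deleted."""
        return "".join(
            sequence[self.state_map[s] - 1] if s in self.state_map else "-"
            for s in range(1, n_states + 1)
        )


@dataclass
class InstanceFilterReport:
    passed: bool
    reasons: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.passed != (not self.reasons):
            raise ValueError("passed must mirror an empty reason list")


def information_content(emission: Sequence[float]) -> float:
    """Information content of an emission distribution in bits:
    log2(20) minus its Shannon entropy (uniform background)."""
    p = np.asarray(emission, dtype=float)
    total = p.sum()
    if abs(total - 1.0) > 1e-6:
        raise ValueError(f"emission probabilities sum to {total}, not 1")
    nz = p[p > 0]
    entropy = float(-(nz * np.log2(nz)).sum())
    return math.log2(len(p)) - entropy


def filter_instance(
    hit: DomainHit,
    model: DomainModel,
    sequence: str,
    binding_residues: set[int],
    high_ic_bits: float = HIGH_IC_BITS,
) -> InstanceFilterReport:
    """Apply the four instance-inclusion filters to one domain hit.

    ``binding_residues`` holds 1-based residue indices annotated as
    ligand-binding for this protein chain.
    """
    if hit.accession != model.accession:
        raise ValueError(
            f"hit accession {hit.accession} does not match model {model.accession}"
        )
    reasons = []
    if hit.bit_score < model.gathering_threshold:
        reasons.append("gathering")
    if 1 not in hit.state_map or model.n_match_states not in hit.state_map:
        reasons.append("terminal_positions")
    for state, pos in hit.state_map.items():
        if information_content(model.emissions[state - 1]) >= high_ic_bits:
            if sequence[pos - 1] not in model.modal_residues(state):
                reasons.append("consensus_at_high_IC")
                break
    if not (set(hit.state_map.values()) & binding_residues):
        reasons.append("no_binding_residue")
    return InstanceFilterReport(passed=not reasons, reasons=reasons)


# ---------------------------------------------------------------------------
# hit-table I/O

_HIT_COLUMNS = (
    "protein_id", "accession", "bit_score", "hmm_start", "seq_start",
    "hmm_align", "seq_align",
)


def _state_map_from_alignment(
    hmm_align: str, seq_align: str, hmm_start: int, seq_start: int
) -> dict[int, int]:
    if len(hmm_align) != len(seq_align):
        raise ValueError("hmm_align and seq_align differ in length")
    state_map: dict[int, int] = {}
    state, pos = hmm_start, seq_start
    for hc, sc in zip(hmm_align, seq_align):
        if hc == ".":  # insert column: residue with no match state
            if sc == "-":
                raise ValueError("gap in both model and sequence")
            pos += 1
        elif sc == "-":  # deletion: match state with no residue
            state += 1
        else:
            state_map[state] = pos
            state += 1
            pos += 1
    return state_map


def parse_domain_hits(
    path: str | Path, models: Optional[Mapping[str, DomainModel]] = None
) -> list[DomainHit]:
    """Parse a hit table (dialect above) into :class:`DomainHit` objects.

    When ``models`` is given, hits to unknown accessions or with states
    outside the model's range raise immediately with the offending line.
    """
    hits = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != len(_HIT_COLUMNS):
            raise ValueError(
                f"{path}:{ln}: expected {len(_HIT_COLUMNS)} columns, got {len(parts)}"
            )
        protein_id, accession, bit_score, hmm_start, seq_start, ha, sa = parts
        try:
            state_map = _state_map_from_alignment(
                ha, sa, int(hmm_start), int(seq_start)
            )
            hit = DomainHit(protein_id, accession, float(bit_score), state_map)
        except ValueError as exc:
            raise ValueError(f"{path}:{ln}: {exc}") from exc
        if models is not None:
            model = models.get(accession)
            if model is None:
                raise ValueError(f"{path}:{ln}: unknown accession {accession}")
            if state_map and max(state_map) > model.n_match_states:
                raise ValueError(
                    f"{path}:{ln}: state {max(state_map)} beyond model length"
                )
        hits.append(hit)
    return hits


def write_domain_hits(
    hits: Iterable[DomainHit],
    sequences: Mapping[str, str],
    path: str | Path,
) -> None:
    """Serialize hits back to the tabular dialect (inverse of
    :func:`parse_domain_hits`); insertions inside the hit span are restored
    from the full protein sequence."""
    lines = ["#" + "\t".join(_HIT_COLUMNS)]
    for hit in hits:
        seq = sequences[hit.protein_id]
        states = sorted(hit.state_map)
        hmm_start = states[0]
        seq_start = hit.state_map[states[0]]
        ha, sa = [], []
        prev_state, prev_pos = None, None
        for s in range(states[0], states[-1] + 1):
            if prev_state is not None and s in hit.state_map:
                # emit insert columns for skipped residues
                for p in range(prev_pos + 1, hit.state_map[s]):
                    ha.append(".")
                    sa.append(seq[p - 1])
            if s in hit.state_map:
                ha.append("M")
                sa.append(seq[hit.state_map[s] - 1])
                prev_state, prev_pos = s, hit.state_map[s]
            else:
                ha.append("M")
                sa.append("-")
        lines.append(
            "\t".join(
                [
                    hit.protein_id,
                    hit.accession,
                    repr(hit.bit_score),
                    str(hmm_start),
                    str(seq_start),
                    "".join(ha),
                    "".join(sa),
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def load_domain_models(path: str | Path) -> dict[str, DomainModel]:
    """Load domain metadata from JSON: a list of objects with keys
    accession, n_match_states, gathering_threshold, emissions."""
    raw = json.loads(Path(path).read_text())
    models = {}
    for entry in raw:
        m = DomainModel(
            accession=entry["accession"],
            n_match_states=int(entry["n_match_states"]),
            gathering_threshold=float(entry["gathering_threshold"]),
            emissions=np.array(entry["emissions"], dtype=float),
        )
        models[m.accession] = m
    return models


def save_domain_models(models: Iterable[DomainModel], path: str | Path) -> None:
    payload = [
        {
            "accession": m.accession,
            "n_match_states": m.n_match_states,
            "gathering_threshold": m.gathering_threshold,
            "emissions": m.emissions.tolist(),
        }
        for m in models
    ]
    Path(path).write_text(json.dumps(payload))
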