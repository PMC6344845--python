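"""Projection of per-state binding frequencies onto query protein residues.

Every residue of a query protein that a domain hit maps to a match state
inherits that state's binding frequency for each ligand class.  A site is
flagged confident when its (domain, ligand class) pair belongs to the
confident set and its frequency reaches that pair's cross-validated
threshold.  Residues covered by several domains or ligand classes keep one
site per source; a per-residue maximum view is available as a collapse.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .bindfreq import BindingFrequencyTable
from .domhits import DomainHit
from .evalcv import ConfidentInteraction

logger = logging.getLogger(__name__)

__all__ = [
    "AnnotatedSite",
    "transfer_frequencies",
    "collapse_max",
    "write_sites_tsv",
    "write_confident_bed",
]


@dataclass(frozen=True)
class AnnotatedSite:
    protein_id: str
    residue_index: int  # 1-based
    ligand_class: str
    frequency: float
    source_accession: str
    confident: bool


def _confident_index(
    confident: Iterable[ConfidentInteraction],
) -> dict[tuple[str, str], ConfidentInteraction]:
    return {(c.accession, c.ligand_class): c for c in confident}


def transfer_frequencies(
    hits: Sequence[DomainHit],
    tables: Iterable[BindingFrequencyTable],
    confident: Iterable[ConfidentInteraction] = (),
) -> list[AnnotatedSite]:
    """Annotate query residues with domain-inferred binding frequencies.

    ``tables`` provide per-state frequencies per (domain, ligand class);
    ``confident`` lists the cross-validated interactions with their
    thresholds.  Hits to domains absent from the tables are skipped with a
    warning.  Output order is deterministic: by protein, residue, domain,
    ligand class.
    """
    by_acc: dict[str, list[BindingFrequencyTable]] = {}
    for t in tables:
        by_acc.setdefault(t.accession, []).append(t)
    conf = _confident_index(confident)
    sites = []
    for hit in hits:
        acc_tables = by_acc.get(hit.accession)
        if acc_tables is None:
            logger.warning("hit on %s to unknown domain %s skipped",
                           hit.protein_id, hit.accession)
            continue
        for table in acc_tables:
            ci = conf.get((hit.accession, table.ligand_class))
            for state, pos in hit.state_map.items():
                f = table.frequency.get(state)
                if f is None:
                    continue
                is_conf = ci is not None and f >= ci.threshold
                sites.append(
                    AnnotatedSite(
                        hit.protein_id, pos, table.ligand_class,
                        f, hit.accession, is_conf,
                    )
                )
    sites.sort(key=lambda s: (s.protein_id, s.residue_index,
                              s.source_accession, s.ligand_class))
    return sites


def collapse_max(sites: Iterable[AnnotatedSite]) -> list[AnnotatedSite]:
    """Per (protein, residue, ligand class), keep the maximum-frequency site;
    the collapsed site is confident if any contributing site was."""
    best: dict[tuple[str, int, str], AnnotatedSite] = {}
    for s in sites:
        key = (s.protein_id, s.residue_index, s.ligand_class)
        cur = best.get(key)
        if cur is None or s.frequency > cur.frequency:
            merged_conf = s.confident or (cur.confident if cur else False)
            best[key] = AnnotatedSite(
                s.protein_id, s.residue_index, s.ligand_class,
                s.frequency, s.source_accession, merged_conf,
            )
        elif s.confident and not cur.confident:
            best[key] = AnnotatedSite(
                cur.protein_id, cur.residue_index, cur.ligand_class,
                cur.frequency, cur.source_accession, True,
            )
    return sorted(best.values(), key=lambda s: (s.protein_id, s.residue_index,
                                                s.ligand_class))


def write_sites_tsv(sites: Iterable[AnnotatedSite], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            (s.protein_id, s.residue_index, s.ligand_class,
             s.source_accession, s.frequency, int(s.confident))
            for s in sites
        ],
        columns=["protein_id", "residue_index", "ligand_class",
                 "domain", "frequency", "confident"],
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_confident_bed(sites: Iterable[AnnotatedSite], path: str | Path) -> None:
    """Export contiguous runs of confident residues as BED-like 0-based
    half-open intervals, one track per (protein, ligand class)."""
    runs: dict[tuple[str, str], list[int]] = {}
    for s in sites:
        if s.confident:
            runs.setdefault((s.protein_id, s.ligand_class), []).append(
                s.residue_index
            )
    lines = []
    for (pid, lc), positions in sorted(runs.items()):
        positions = sorted(set(positions))
        start = prev = positions[0]
        for p in positions[1:] + [None]:
            if p is None or p != prev + 1:
                lines.append(f"{pid}\t{start - 1}\t{prev}\t{lc}")
                if p is not None:
                    start = p
            prev = p if p is not None else prev
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))
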