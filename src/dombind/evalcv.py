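"""Interface-consistency scoring and cross-validated precision-recall
evaluation of binding frequencies.

Two complementary checks ask whether a domain family binds its ligand the
same way across structural instances.  The consistency score randomly halves
the instances, averages the per-state minimum distances within each half,
and correlates the two resulting vectors (Pearson), averaged over
repetitions.  The cross-validation check splits instances (or <90 %-identity
groups of instances) into up to 10 folds, scores each held-out position with
the binding frequency computed from the remaining folds, and summarizes the
ranking of truly binding vs non-binding held-out positions as a
precision-recall curve.  Area under the curve uses the average-precision
step integrator (no interpolation between points; tied scores cross each
threshold together).  A domain-ligand pair whose curve reaches precision
>= 0.5 at some binding-frequency threshold enters the confident set, with
the most permissive such threshold (maximal recall, ties broken toward
higher precision) recorded for downstream transfer.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .bindfreq import (
    DEFAULT_DISTANCE_CUTOFF,
    DistanceProfile,
    binding_frequency,
    henikoff_weights,
)

logger = logging.getLogger(__name__)

__all__ = [
    "FoldAssignment",
    "PRCurve",
    "ConfidentInteraction",
    "consistency_pcc",
    "pairwise_identity",
    "alignment_identity",
    "cluster_by_identity",
    "assign_folds",
    "pr_curve",
    "cross_validate",
    "confident_threshold",
]


@dataclass
class FoldAssignment:
    unit_ids: list[str]
    fold_of: dict[str, int]  # unit -> fold index in [1, k]
    mode: str = "instance"  # instance | identity90

    @property
    def k(self) -> int:
        return max(self.fold_of.values())

    def folds(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {f: [] for f in range(1, self.k + 1)}
        for u in self.unit_ids:
            out[self.fold_of[u]].append(u)
        return out


@dataclass
class PRCurve:
    """Precision-recall points in descending score-threshold order."""

    thresholds: list[float]
    precision: list[float]
    recall: list[float]
    auprc: float
    baseline: float
    fold_auprcs: list[float] = field(default_factory=list)

    @property
    def points(self) -> list[tuple[float, float]]:
        return list(zip(self.recall, self.precision))


@dataclass
class ConfidentInteraction:
    accession: str
    ligand_class: str
    threshold: float
    achieved_precision: float


def consistency_pcc(
    profile: DistanceProfile,
    reps: int = 10,
    seed: int = 0,
    min_shared_states: int = 2,
) -> float:
    """Mean two-fold interface-consistency Pearson correlation.

    Each repetition randomly halves the instances, computes per-state mean
    minimum distances within each half, and correlates the two vectors over
    states represented in both halves.  Repetitions sharing fewer than
    ``min_shared_states`` states are skipped with a warning.
    """
    ids = profile.instance_ids
    if len(ids) < 2:
        raise ValueError("need at least 2 instances")
    mat, _ = profile.distance_matrix()
    rng = np.random.default_rng(seed)
    pccs = []
    for rep in range(reps):
        perm = rng.permutation(len(ids))
        half = len(ids) // 2
        a, b = perm[:half], perm[half:]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mean_a = np.nanmean(mat[a], axis=0)
            mean_b = np.nanmean(mat[b], axis=0)
        shared = ~np.isnan(mean_a) & ~np.isnan(mean_b)
        if shared.sum() < min_shared_states:
            logger.warning("consistency rep %d: <%d shared states, skipped",
                           rep, min_shared_states)
            continue
        va, vb = mean_a[shared], mean_b[shared]
        if np.ptp(va) == 0 or np.ptp(vb) == 0:
            # constant vector: correlation undefined; identical geometry in
            # both halves counts as perfectly consistent
            pccs.append(1.0 if np.allclose(va, va[0]) and np.allclose(vb, vb[0])
                        and np.allclose(va, vb) else 0.0)
            continue
        pccs.append(float(stats.pearsonr(va, vb).statistic))
    if not pccs:
        raise ValueError("all consistency repetitions were skipped")
    return float(np.mean(pccs))


def alignment_identity(row_a: str, row_b: str) -> float:
    """Fraction of identical residues over match-state columns where both
    rows are non-gap; 0 when no column is shared."""
    shared = matches = 0
    for ca, cb in zip(row_a, row_b):
        if ca != "-" and cb != "-":
            shared += 1
            if ca == cb:
                matches += 1
    return matches / shared if shared else 0.0


def pairwise_identity(hit_a, seq_a: str, hit_b, seq_b: str) -> float:
    """Sequence identity between two domain instances over the match states
    both of them map."""
    if hit_a.accession != hit_b.accession:
        raise ValueError("hits belong to different domain families")
    shared = set(hit_a.state_map) & set(hit_b.state_map)
    if not shared:
        return 0.0
    matches = sum(
        seq_a[hit_a.state_map[s] - 1] == seq_b[hit_b.state_map[s] - 1]
        for s in shared
    )
    return matches / len(shared)


def cluster_by_identity(
    alignment: Mapping[str, str], threshold: float = 0.90
) -> list[list[str]]:
    """Single-linkage clusters of instances with pairwise identity >=
    ``threshold``; identities between members of different clusters are all
    below it.  Clusters are returned sorted by their smallest member id."""
    ids = list(alignment)
    parent = {i: i for i in ids}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            if alignment_identity(alignment[a], alignment[b]) >= threshold:
                ra, rb = find(a), find(b)
                if ra != rb:
                    parent[ra] = rb
    groups: dict[str, list[str]] = {}
    for x in ids:
        groups.setdefault(find(x), []).append(x)
    return sorted(groups.values(), key=lambda g: min(g))


def assign_folds(
    units: Sequence[str], k_max: int = 10, seed: int = 0, mode: str = "instance"
) -> FoldAssignment:
    """Randomly split units into ``min(k_max, len(units))`` near-equal folds."""
    units = list(units)
    if len(units) < 2:
        raise ValueError("need at least 2 units for cross-validation")
    k = min(k_max, len(units))
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(units))
    fold_of: dict[str, int] = {}
    for f, idx in enumerate(np.array_split(perm, k), start=1):
        for i in idx:
            fold_of[units[i]] = f
    return FoldAssignment(units, fold_of, mode=mode)


def pr_curve(scores: Sequence[float], labels: Sequence[int]) -> PRCurve:
    """Precision-recall curve over all distinct score thresholds (descending),
    with average-precision area.  All pairs tied at a threshold cross it
    together."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape or scores.size == 0:
        raise ValueError("scores and labels must be equal-length and non-empty")
    n_pos = int(labels.sum())
    baseline = n_pos / labels.size
    order = np.argsort(-scores, kind="stable")
    s_sorted, y_sorted = scores[order], labels[order]
    thresholds, precision, recall = [], [], []
    tp = fp = 0
    i = 0
    n = scores.size
    while i < n:
        j = i
        while j < n and s_sorted[j] == s_sorted[i]:
            tp += int(y_sorted[j])
            fp += 1 - int(y_sorted[j])
            j += 1
        thresholds.append(float(s_sorted[i]))
        precision.append(tp / (tp + fp))
        recall.append(tp / n_pos if n_pos else 0.0)
        i = j
    # average precision: sum of precision * recall increments
    ap = 0.0
    prev_r = 0.0
    for p, r in zip(precision, recall):
        ap += p * (r - prev_r)
        prev_r = r
    return PRCurve(thresholds, precision, recall, ap, baseline)


def cross_validate(
    profile: DistanceProfile,
    alignment: Mapping[str, str],
    folds: FoldAssignment,
    label_cutoff: float = DEFAULT_DISTANCE_CUTOFF,
    score_cutoff: float = DEFAULT_DISTANCE_CUTOFF,
    labels: Optional[Mapping[str, set[int]]] = None,
    groups: Optional[Mapping[str, Sequence[str]]] = None,
    mode: str = "per_fold",
) -> PRCurve:
    """Cross-validated precision-recall evaluation of binding frequencies.

    For each fold in turn, binding frequencies are computed from the
    remaining folds and used to score every mapped state of every held-out
    instance; a held-out state's binary label is taken from the annotation
    table when ``labels`` maps instance id -> set of binding states, else
    from actual contact at ``label_cutoff``.  States absent from the
    training folds score 0.  ``mode='per_fold'`` (default) reports the mean
    of per-fold average precisions, matching fold-wise evaluation;
    ``mode='pooled'`` integrates a single curve over all held-out pairs.
    The returned curve's points are always the pooled curve; ``auprc``
    follows the chosen mode, and per-fold values are kept in
    ``fold_auprcs``.  With ``groups`` (identity-cluster mode) the fold units
    are group ids and a group never straddles folds.
    """
    fold_members = folds.folds()
    if groups is not None:
        fold_members = {
            f: [iid for g in units for iid in groups[g]]
            for f, units in fold_members.items()
        }
    all_scores: list[float] = []
    all_labels: list[int] = []
    fold_auprcs: list[float] = []
    dist_by_instance: dict[str, dict[int, float]] = {
        iid: {} for iid in profile.instance_ids
    }
    for s, obs in profile.entries.items():
        for iid, d in obs:
            dist_by_instance[iid][s] = d

    for f, held_out in fold_members.items():
        train_ids = [i for i in profile.instance_ids if i not in set(held_out)]
        if not train_ids:
            raise ValueError(f"fold {f}: empty training complement")
        sub = profile.subset(train_ids)
        w = henikoff_weights({i: alignment[i] for i in train_ids})
        table = binding_frequency(sub, w, cutoff=score_cutoff)
        fold_scores: list[float] = []
        fold_labels: list[int] = []
        for iid in held_out:
            for s, d in dist_by_instance[iid].items():
                score = table.frequency.get(s, 0.0)
                if labels is not None:
                    y = int(s in labels.get(iid, set()))
                else:
                    y = int(d <= label_cutoff)
                fold_scores.append(score)
                fold_labels.append(y)
        all_scores.extend(fold_scores)
        all_labels.extend(fold_labels)
        if fold_labels and any(fold_labels):
            fold_auprcs.append(pr_curve(fold_scores, fold_labels).auprc)

    pooled = pr_curve(all_scores, all_labels)
    if mode == "per_fold" and fold_auprcs:
        auprc = float(np.mean(fold_auprcs))
    else:
        auprc = pooled.auprc
    return PRCurve(
        pooled.thresholds, pooled.precision, pooled.recall,
        auprc, pooled.baseline, fold_auprcs,
    )


def confident_threshold(
    curve: PRCurve,
    min_precision: float = 0.5,
    accession: str = "",
    ligand_class: str = "",
) -> Optional[ConfidentInteraction]:
    """Pick the binding-frequency threshold defining confident sites.

    Among thresholds whose pooled precision reaches ``min_precision``, the
    one with maximal recall is chosen; ties in recall resolve toward higher
    precision (i.e. the largest such threshold).  Returns ``None`` when no
    threshold qualifies.
    """
    best = None
    for t, p, r in zip(curve.thresholds, curve.precision, curve.recall):
        if p >= min_precision:
            key = (r, p)
            if best is None or key > best[0]:
                best = (key, t, p)
    if best is None:
        return None
    return ConfidentInteraction(accession, ligand_class, best[1], best[2])
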