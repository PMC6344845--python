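"""Significance tests for binding-site overlap.

The central question: do sites of interest (e.g. positions carrying common
population variants, disease mutations, or somatic mutations) fall inside
inferred ligand-binding sites more or less often than chance predicts?  The
N sites are modeled as independent Bernoulli trials whose success
probability p_i is the proportion of the host protein's residues that are
putative binding sites, so that proteins rich in binding sites cannot bias
the global trend.  The number of overlaps K is then Poisson-binomial
distributed under the null; both tails Pr(X >= K) and Pr(X <= K) are
computed from the exact PMF (iterative convolution), with zero-valued tail
probabilities floored at 1e-15.  Conventional 2x2 machinery (odds ratios,
Fisher's exact test) and the exact binomial test round out the module.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "P_VALUE_FLOOR",
    "OverlapTestResult",
    "ContingencyTable2x2",
    "poibin_pmf",
    "overlap_test",
    "odds_ratio",
    "fisher_exact",
    "binomial_test",
]

#: smallest reported tail probability; exact zeros are floored here
P_VALUE_FLOOR = 1e-15


@dataclass
class OverlapTestResult:
    K: int
    expected: float
    fold_change: float
    p_ge: float  # Pr(X >= K)
    p_le: float  # Pr(X <= K)
    n_sites: int


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts (a, b, c, d) = (binding-deleterious, binding-tolerated,
    nonbinding-deleterious, nonbinding-tolerated)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)


def poibin_pmf(p: Sequence[float]) -> np.ndarray:
    """Exact Poisson-binomial PMF over 0..N successes by iterative
    convolution of the per-trial (1-p_i, p_i) distributions."""
    p = np.asarray(p, dtype=float)
    if p.size and (p.min() < 0 or p.max() > 1):
        raise ValueError("success probabilities must lie in [0, 1]")
    pmf = np.array([1.0])
    for pi in p:
        pmf = np.convolve(pmf, [1.0 - pi, pi])
    # guard against drift from many convolutions
    pmf = np.clip(pmf, 0.0, None)
    return pmf / pmf.sum()


def overlap_test(
    sites: Sequence[tuple[str, int]],
    binding_sites: Mapping[str, set[int]],
    protein_lengths: Mapping[str, int],
) -> OverlapTestResult:
    """Poisson-binomial test of overlap between sites of interest and
    per-protein binding-site sets.

    ``sites`` are (protein_id, 1-based residue index) pairs; each site's
    success probability is the fraction of its protein's residues that are
    binding sites.  Returns both tails at the observed overlap K, floored
    at 1e-15.
    """
    probs = []
    K = 0
    for pid, pos in sites:
        if pid not in protein_lengths:
            raise KeyError(f"unknown protein {pid!r}")
        length = protein_lengths[pid]
        if not (1 <= pos <= length):
            raise ValueError(f"site {pid}:{pos} outside protein of length {length}")
        bs = binding_sites.get(pid, set())
        probs.append(len(bs) / length)
        if pos in bs:
            K += 1
    pmf = poibin_pmf(probs)
    p_ge = float(pmf[K:].sum())
    p_le = float(pmf[: K + 1].sum())
    expected = float(np.sum(probs))
    return OverlapTestResult(
        K=K,
        expected=expected,
        fold_change=K / expected if expected > 0 else float("inf") if K else 0.0,
        p_ge=max(min(p_ge, 1.0), P_VALUE_FLOOR),
        p_le=max(min(p_le, 1.0), P_VALUE_FLOOR),
        n_sites=len(probs),
    )


def odds_ratio(t: ContingencyTable2x2) -> float:
    """Sample odds ratio ad/bc (no continuity correction)."""
    if t.b == 0 or t.c == 0 or t.d == 0:
        raise ZeroDivisionError("odds ratio undefined: zero denominator cell")
    return (t.a * t.d) / (t.b * t.c)


_SIDE_ALIASES = {"greater": "greater", "less": "less", "two": "two-sided",
                 "two-sided": "two-sided"}


def fisher_exact(t: ContingencyTable2x2, side: str = "greater") -> float:
    """Fisher's exact test on a 2x2 table: one-sided hypergeometric tail or
    the two-sided sum over tables no more likely than the observed one."""
    alternative = _SIDE_ALIASES.get(side)
    if alternative is None:
        raise ValueError(f"side must be greater|less|two, got {side!r}")
    p = float(stats.fisher_exact(t.as_array(), alternative=alternative).pvalue)
    return min(max(p, np.nextafter(0, 1)), 1.0)


def binomial_test(k: int, n: int, p0: float, side: str = "greater") -> float:
    """Exact binomial tail probability of ``k`` successes in ``n`` trials."""
    if not (0 <= k <= n):
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    if not (0 < p0 < 1):
        raise ValueError("null probability must lie strictly in (0, 1)")
    alternative = _SIDE_ALIASES.get(side)
    if alternative is None:
        raise ValueError(f"side must be greater|less|two, got {side!r}")
    return float(stats.binomtest(k, n, p0, alternative=alternative).pvalue)
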