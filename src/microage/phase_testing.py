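"""Pairwise PERMANOVA between sample groups and source selection.

The source-selection rule: run pairwise PERMANOVA between all sampling
time points on the Bray-Curtis matrix, correct p-values with
Benjamini-Hochberg, count for every time point the number of
significantly different pairs (adjusted p below ``alpha``, default
0.01), and pick per life phase the member time point with the fewest
such pairs — the most "representative" community of its phase.  Ties
break toward the earlier age.

PERMANOVA follows Anderson's pseudo-F:

    SS_total  = (1/N) sum_{i<j} d_ij^2
    SS_within = sum_g (1/n_g) sum_{i<j in g} d_ij^2
    F = ((SS_total - SS_within)/(a-1)) / (SS_within/(N-a))

with significance from uniform label permutations.  When the number of
distinct label arrangements is at most 10,000 an exhaustive enumeration
replaces Monte-Carlo and the p-value is exact.  Permutations shuffle
samples freely (not stratified by cage or mouse) — a documented
limitation for repeated-measures designs.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Callable, Hashable, Mapping, Sequence

import numpy as np
from skbio import DistanceMatrix
from statsmodels.stats.multitest import multipletests

from .io_formats import PHASE_ORDER

__all__ = [
    "PermanovaResult",
    "SourceSelection",
    "permanova",
    "pairwise_permanova",
    "bh_adjust",
    "select_sources",
    "count_significant_pairs",
    "EXHAUSTIVE_LIMIT",
]

#: Exhaustive enumeration replaces Monte-Carlo below this arrangement count.
EXHAUSTIVE_LIMIT = 10_000


@dataclass
class PermanovaResult:
    group_a: Hashable
    group_b: Hashable
    pseudo_F: float
    p_value: float
    p_adjusted: float
    n_permutations: int


@dataclass
class SourceSelection:
    phase: str
    chosen_timepoint: float
    n_significant_pairs: int
    tie_broken: bool


def _group_codes(labels: Sequence[Hashable]) -> tuple[np.ndarray, list[Hashable]]:
    uniq = list(dict.fromkeys(labels))
    codes = np.array([uniq.index(l) for l in labels], dtype=np.int64)
    return codes, uniq

def _pseudo_f(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    n = len(codes)
    ss_total = d2.sum() / (2 * n)
    ss_within = 0.0
    for g in range(n_groups):
        mask = codes == g
        ng = int(mask.sum())
        ss_within += d2[np.ix_(mask, mask)].sum() / (2 * ng)
    ss_among = ss_total - ss_within
    num = ss_among / (n_groups - 1)
    den = ss_within / (n - n_groups)
    if den == 0.0:
        return math.inf if num > 0 else 0.0
    return num / den


def _n_arrangements(group_sizes: Sequence[int]) -> int:
    n = sum(group_sizes)
    out = math.factorial(n)
    for s in group_sizes:
        out //= math.factorial(s)
    return out


def _batch_pseudo_f(d2: np.ndarray, codes_matrix: np.ndarray,
                    n_groups: int) -> np.ndarray:
    """Pseudo-F for many label arrangements at once (rows of codes_matrix)."""
    n = codes_matrix.shape[1]
    ss_total = d2.sum() / (2 * n)
    ss_within = np.zeros(codes_matrix.shape[0])
    for g in range(n_groups):
        m = (codes_matrix == g).astype(float)
        ng = m[0].sum()  # group sizes are permutation-invariant
        ss_within += 0.5 * ((m @ d2) * m).sum(axis=1) / ng
    ss_among = ss_total - ss_within
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ss_among / (n_groups - 1)) / (ss_within / (n - n_groups))
    f = np.where(ss_within == 0, np.where(ss_among > 0, np.inf, 0.0), f)
    return f


def permanova(dm: DistanceMatrix, labels: Sequence[Hashable],
              n_permutations: int = 9999, seed: int = 0,
              exhaustive: bool | None = None) -> tuple[float, float]:
    """One-way PERMANOVA; returns (pseudo_F, p_value).

    ``exhaustive=None`` auto-enables exact enumeration when the number
    of distinct label arrangements is at most ``EXHAUSTIVE_LIMIT``.
    Monte-Carlo p is (1 + #{F_perm >= F_obs}) / (n_permutations + 1).
    """
    if len(labels) != len(dm.ids):
        raise ValueError("labels length must match distance matrix size")
    codes, uniq = _group_codes(labels)
    sizes = Counter(codes.tolist())
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups")
    if min(sizes.values()) < 2:
        small = [uniq[g] for g, s in sizes.items() if s < 2]
        raise ValueError(f"groups with fewer than 2 samples: {small}")
    d2 = np.asarray(dm.data, dtype=float) ** 2
    a = len(uniq)
    f_obs = _pseudo_f(d2, codes, a)

    n_arr = _n_arrangements(list(sizes.values()))
    if exhaustive is None:
        exhaustive = n_arr <= EXHAUSTIVE_LIMIT
    # tolerance so the observed arrangement always counts itself despite
    # float-path differences between the single and batch F computations
    tol = 1e-8 * max(1.0, abs(f_obs)) if math.isfinite(f_obs) else 0.0
    if exhaustive:
        from sympy.utilities.iterables import multiset_permutations

        arr = np.array(list(multiset_permutations(codes.tolist())), dtype=np.int64)
        f_perm = _batch_pseudo_f(d2, arr, a)
        p = float(np.count_nonzero(f_perm >= f_obs - tol)) / len(arr)
    else:
        rng = np.random.default_rng([seed, 51])
        perms = rng.permuted(np.tile(codes, (n_permutations, 1)), axis=1)
        f_perm = _batch_pseudo_f(d2, perms, a)
        p = (1.0 + np.count_nonzero(f_perm >= f_obs - tol)) / (n_permutations + 1.0)
    return float(f_obs), float(p)


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjustment, returned in input order."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    _, adjusted, _, _ = multipletests(p, method="fdr_bh")
    return [float(x) for x in adjusted]


def pairwise_permanova(dm: DistanceMatrix, labels: Sequence[Hashable],
                       n_permutations: int = 9999, seed: int = 0,
                       ) -> list[PermanovaResult]:
    """PERMANOVA on every unordered group pair, BH-adjusted across pairs."""
    codes, uniq = _group_codes(labels)
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups")
    ids = np.asarray(dm.ids)
    results = []
    raw_p = []
    for i in range(len(uniq)):
        for j in range(i + 1, len(uniq)):
            mask = (codes == i) | (codes == j)
            sub = dm.filter(ids[mask])
            sub_labels = [labels[k] for k in np.flatnonzero(mask)]
            f, p = permanova(sub, sub_labels, n_permutations,
                             seed=seed + 1000 * i + j)
            results.append(PermanovaResult(uniq[i], uniq[j], f, p, p,
                                           n_permutations))
            raw_p.append(p)
    adjusted = bh_adjust(raw_p)
    for r, padj in zip(results, adjusted):
        r.p_adjusted = padj
    return results


def count_significant_pairs(results: Sequence[PermanovaResult],
                            alpha: float) -> dict[Hashable, int]:
    """Per group label, the number of pairs with adjusted p < alpha."""
    counts: dict[Hashable, int] = {}
    for r in results:
        counts.setdefault(r.group_a, 0)
        counts.setdefault(r.group_b, 0)
        if r.p_adjusted < alpha:
            counts[r.group_a] += 1
            counts[r.group_b] += 1
    return counts


def select_sources(results: Sequence[PermanovaResult],
                   phase_map: Mapping[Hashable, str] | Callable[[float], str],
                   alpha: float = 0.01) -> list[SourceSelection]:
    """Pick one source time point per life phase.

    ``results`` are pairwise PERMANOVAs between time points (group
    labels are ages in weeks); ``phase_map`` assigns each time point to
    a phase.  Per phase the member minimizing the significant-pair
    count wins; ties break toward the earlier age (``tie_broken`` set).
    """
    counts = count_significant_pairs(results, alpha)
    mapper = phase_map if callable(phase_map) else phase_map.__getitem__
    by_phase: dict[str, list[float]] = {}
    for tp in counts:
        phase = mapper(tp)
        if phase in PHASE_ORDER:
            by_phase.setdefault(phase, []).append(tp)
    selections = []
    for phase in PHASE_ORDER:
        members = sorted(by_phase.get(phase, []))
        if not members:
            raise ValueError(f"phase {phase} has no time points")
        best = min(counts[tp] for tp in members)
        winners = [tp for tp in members if counts[tp] == best]
        selections.append(SourceSelection(
            phase=phase, chosen_timepoint=float(winners[0]),
            n_significant_pairs=int(best), tie_broken=len(winners) > 1))
    return selections
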