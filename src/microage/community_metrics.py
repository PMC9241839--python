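"""Rarefaction, alpha diversity, beta diversity and ordination.

Conventions follow the QIIME-era toolchain: a single rarefaction draw
per sample (uniform subsampling without replacement), Shannon entropy in
nats, Simpson reported as 1 - D (probability two reads differ), Chao1 in
its bias-corrected form, Pielou's evenness H / ln(S), weighted UniFrac
unnormalized (branch length x |difference in descendant read fractions|),
and principal-coordinate analysis as classical scaling with negative
eigenvalues dropped.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg
import scipy.spatial.distance
from skbio import DistanceMatrix, TreeNode
from skbio.diversity import beta_diversity
from skbio.diversity.alpha import chao1 as _skbio_chao1
from skbio.diversity.alpha import shannon as _skbio_shannon
from skbio.diversity.alpha import simpson as _skbio_simpson

from .io_formats import CountTable

__all__ = [
    "RarefactionReport",
    "AlphaDiversityRecord",
    "PcoaResult",
    "rarefy",
    "alpha_diversity",
    "bray_curtis",
    "weighted_unifrac",
    "pcoa",
]


# ---------------------------------------------------------------------------
# Rarefaction
# ---------------------------------------------------------------------------

@dataclass
class RarefactionReport:
    """Samples removed because their total read count fell below depth."""

    depth: int
    dropped: list[str]


def rarefy(table: CountTable, depth: int, seed: int,
           ) -> tuple[CountTable, RarefactionReport]:
    """Subsample every sample to exactly ``depth`` reads without replacement.

    Samples with fewer than ``depth`` reads are dropped and listed in
    the report.  A sample already at ``depth`` is returned unchanged.
    Single draw per sample, reproducible given ``seed``.
    """
    if depth <= 0:
        raise ValueError("rarefaction depth must be positive")
    totals = table.sample_totals()
    keep = totals >= depth
    dropped = [s for s, k in zip(table.sample_ids, keep) if not k]
    rng = np.random.default_rng([seed, 41])
    cols = []
    for j in np.flatnonzero(keep):
        col = table.counts[:, j]
        if totals[j] == depth:
            cols.append(col.copy())
        else:
            cols.append(rng.multivariate_hypergeometric(col, depth))
    kept_ids = [s for s, k in zip(table.sample_ids, keep) if k]
    counts = (np.column_stack(cols) if cols
              else np.zeros((table.n_taxa, 0), dtype=np.int64))
    return (CountTable(list(table.taxon_ids), kept_ids, counts),
            RarefactionReport(depth=depth, dropped=dropped))


# ---------------------------------------------------------------------------
# Alpha diversity
# ---------------------------------------------------------------------------

@dataclass
class AlphaDiversityRecord:
    sample_id: str
    shannon: float       # nats
    simpson: float       # 1 - D
    chao1: float         # bias-corrected
    pielou: float | None  # None for single-taxon samples


def alpha_diversity(table: CountTable) -> list[AlphaDiversityRecord]:
    """Shannon, Simpson (1-D), bias-corrected Chao1 and Pielou per sample."""
    records = []
    for j, sid in enumerate(table.sample_ids):
        counts = table.counts[:, j]
        if counts.sum() == 0:
            raise ValueError(f"zero-total sample: {sid!r}")
        h = float(_skbio_shannon(counts, base=math.e))
        s_obs = int((counts > 0).sum())
        pielou = h / math.log(s_obs) if s_obs >= 2 else None
        records.append(AlphaDiversityRecord(
            sample_id=sid,
            shannon=h,
            simpson=float(_skbio_simpson(counts)),
            chao1=float(_skbio_chao1(counts, bias_corrected=True)),
            pielou=pielou,
        ))
    return records


# ---------------------------------------------------------------------------
# Beta diversity
# ---------------------------------------------------------------------------

def _check_positive_totals(table: CountTable) -> None:
    totals = table.sample_totals()
    if (totals == 0).any():
        bad = [s for s, t in zip(table.sample_ids, totals) if t == 0]
        raise ValueError(f"zero-total samples: {bad}")


def bray_curtis(table: CountTable) -> DistanceMatrix:
    """Bray-Curtis dissimilarity, d(A,B) = sum|a-b| / sum(a+b)."""
    _check_positive_totals(table)
    condensed = scipy.spatial.distance.pdist(table.counts.T.astype(float),
                                             metric="braycurtis")
    return DistanceMatrix(scipy.spatial.distance.squareform(condensed),
                          ids=table.sample_ids)


def weighted_unifrac(table: CountTable, tree: str | TreeNode,
                     normalized: bool = False) -> DistanceMatrix:
    """Weighted UniFrac over a rooted tree whose tips cover all taxa.

    Unnormalized by default: each branch contributes its length times
    the absolute difference in the fraction of reads descending it.
    """
    _check_positive_totals(table)
    if isinstance(tree, str):
        tree = TreeNode.read([tree])
    tip_names = {t.name for t in tree.tips()}
    missing = [t for t in table.taxon_ids if t not in tip_names]
    if missing:
        raise ValueError(f"taxa missing from tree: {missing[:10]}"
                         + ("..." if len(missing) > 10 else ""))
    metric = "weighted_unifrac"
    return beta_diversity(metric, table.counts.T, ids=table.sample_ids,
                          taxa=table.taxon_ids, tree=tree,
                          normalized=normalized)


# ---------------------------------------------------------------------------
# Ordination
# ---------------------------------------------------------------------------

@dataclass
class PcoaResult:
    sample_ids: list[str]
    coordinates: np.ndarray        # (samples, axes)
    explained_fraction: np.ndarray  # per axis, relative to positive eigenvalues


def pcoa(dm: DistanceMatrix, n_axes: int = 3) -> PcoaResult:
    """Classical scaling (principal-coordinate analysis).

    Double-centers -D^2/2, eigendecomposes, keeps positive eigenvalues
    only; coordinates are eigenvectors scaled by sqrt(eigenvalue) and
    explained fractions are eigenvalues over the positive-eigenvalue sum.
    Requests beyond the matrix rank are truncated.
    """
    if n_axes < 1:
        raise ValueError("n_axes must be positive")
    d = np.asarray(dm.data, dtype=float)
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    eigvals, eigvecs = scipy.linalg.eigh(b)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    positive = eigvals > max(1e-10 * abs(eigvals).max(initial=1.0), 1e-12)
    eigvals, eigvecs = eigvals[positive], eigvecs[:, positive]
    if n_axes > len(eigvals):
        warnings.warn(f"requested {n_axes} axes but rank is {len(eigvals)}; "
                      "truncating", stacklevel=2)
    k = min(n_axes, len(eigvals))
    if k == 0:
        return PcoaResult(list(dm.ids), np.zeros((n, n_axes)), np.zeros(n_axes))
    coords = eigvecs[:, :k] * np.sqrt(eigvals[:k])
    explained = eigvals[:k] / eigvals.sum()
    return PcoaResult(list(dm.ids), coords, explained)
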