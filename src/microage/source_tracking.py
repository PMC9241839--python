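"""Bayesian attribution of sink communities to known sources plus "unknown".

The model is the standard collapsed Dirichlet-multinomial mixture used
for microbial source tracking.  Each read i of a sink carries a taxon
t_i and a latent source assignment z_i in {1..V, unknown}:

* known source v emits taxa with fixed smoothed probabilities
  phi_v(t) = (m_vt + alpha_known) / (M_v + T * alpha_known), where m is
  the source count matrix (no resampling of source profiles);
* the unknown source is a Dirichlet(alpha_unknown)-multinomial learned
  from the reads currently assigned to it;
* mixing proportions carry a symmetric Dirichlet(beta) prior,
  collapsed, giving the full conditional

  P(z_i = v | z_-i) ∝ phi_v(t_i) * (n_v^-i + beta),

  with phi for the unknown source computed from the leave-one-out
  unknown counts.

Each restart draws a random initial assignment, runs ``burnins`` full
sweeps, and retains a single draw of the proportions n_v / N; the
reported attribution is the mean over restarts and ``restart_sd`` their
standard deviation.  Sinks are rarefied to ``rarefaction_depth`` first
(and dropped, with a report, if shallower).  An exhaustive-enumeration
oracle computes the exact posterior mean on tiny instances for
validation.

This is a reimplementation of the published model class, not a port of
any particular tool.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import product
from typing import Mapping, Sequence

import numpy as np
from numba import njit

from .io_formats import PHASE_ORDER, CountTable

__all__ = [
    "SourceTrackingParams",
    "SourceSet",
    "Attribution",
    "ShallowSinkError",
    "prepare_sources",
    "gibbs_attribute",
    "oracle_attribute",
    "attribute_all",
]

UNKNOWN = "unknown"


class ShallowSinkError(ValueError):
    """Sink (or pooled source) total below the rarefaction depth."""


@dataclass
class SourceTrackingParams:
    """Sampler hyperparameters.

    ``burnins``/``restarts``/``rarefaction_depth`` default to the study
    settings (100, 10, 2733); the pseudocounts follow the reference
    implementation's published defaults.
    """

    alpha_known: float = 0.001
    alpha_unknown: float = 0.1
    beta: float = 10.0
    burnins: int = 100
    restarts: int = 10
    rarefaction_depth: int = 2733
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.alpha_known, self.alpha_unknown, self.beta) <= 0:
            raise ValueError("pseudocounts and beta must be positive")
        if min(self.burnins, self.restarts, self.rarefaction_depth) < 1:
            raise ValueError("burnins, restarts and rarefaction_depth must be >= 1")


@dataclass
class SourceSet:
    """Known source communities: one pooled, rarefied row per label.

    Labels are phase names (``MR`` .. ``VO``); calibration rows use
    ``<phase>#cal<i>`` and collapse onto their phase at prediction time.
    """

    labels: list[str]
    source_counts: np.ndarray  # (n_sources, n_taxa) int
    taxon_ids: list[str]

    def __post_init__(self) -> None:
        self.source_counts = np.asarray(self.source_counts, dtype=np.int64)
        if self.source_counts.shape != (len(self.labels), len(self.taxon_ids)):
            raise ValueError("source_counts shape does not match labels/taxa")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("source labels must be unique")

    def phase_of(self, label: str) -> str:
        return label.split("#", 1)[0]


@dataclass
class Attribution:
    """Per-sink mixing proportions over source labels plus "unknown"."""

    sink_id: str
    proportions: dict[str, float]
    restart_sd: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        total = sum(self.proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"proportions sum to {total}, not 1")

    @property
    def unknown(self) -> float:
        return self.proportions.get(UNKNOWN, 0.0)

    def by_phase(self, source_set: SourceSet | None = None) -> dict[str, float]:
        """Collapse calibration rows onto their phase labels."""
        out: dict[str, float] = {}
        for label, p in self.proportions.items():
            phase = label if label == UNKNOWN else label.split("#", 1)[0]
            out[phase] = out.get(phase, 0.0) + p
        return out


# ---------------------------------------------------------------------------
# Source preparation
# ---------------------------------------------------------------------------

def _harmonize(tables: Mapping[str, CountTable]) -> tuple[list[str], dict[str, np.ndarray]]:
    """Union taxa across tables (first-seen order); zero-fill absentees."""
    union: dict[str, int] = {}
    for table in tables.values():
        for t in table.taxon_ids:
            union.setdefault(t, len(union))
    pooled = {}
    for label, table in tables.items():
        vec = np.zeros(len(union), dtype=np.int64)
        idx = [union[t] for t in table.taxon_ids]
        vec[idx] = table.counts.sum(axis=1)
        pooled[label] = vec
    return list(union), pooled


def _rarefy_vector(vec: np.ndarray, depth: int, rng: np.random.Generator) -> np.ndarray:
    total = int(vec.sum())
    if total == depth:
        return vec.copy()
    return rng.multivariate_hypergeometric(vec, depth)


def prepare_sources(tables: Mapping[str, CountTable],
                    params: SourceTrackingParams) -> SourceSet:
    """Pool each phase's samples into one community, rarefied to depth.

    ``tables`` maps source label (phase) to the slice of samples at the
    chosen time point.  Taxa are harmonized to the union across phases.
    """
    if not tables:
        raise ValueError("no source tables given")
    for label, table in tables.items():
        if table.n_samples == 0:
            raise ValueError(f"phase {label}: empty source slice")
    taxon_ids, pooled = _harmonize(tables)
    rows = []
    labels = list(tables)
    for i, label in enumerate(labels):
        vec = pooled[label]
        if vec.sum() < params.rarefaction_depth:
            raise ShallowSinkError(
                f"phase {label}: pooled total {int(vec.sum())} below "
                f"rarefaction depth {params.rarefaction_depth}")
        rng = np.random.default_rng([params.seed, 71, i])
        rows.append(_rarefy_vector(vec, params.rarefaction_depth, rng))
    return SourceSet(labels=labels, source_counts=np.vstack(rows),
                     taxon_ids=taxon_ids)


# ---------------------------------------------------------------------------
# Gibbs sampler
# ---------------------------------------------------------------------------

@njit(cache=True)
def _gibbs_chain(read_taxa, phi_known, alpha_unknown, beta, burnins, seed):
    """One restart: random init, `burnins` sweeps, return assignment counts."""
    np.random.seed(seed)
    n_reads = read_taxa.shape[0]
    n_src = phi_known.shape[0]
    n_tax = phi_known.shape[1]
    z = np.empty(n_reads, dtype=np.int64)
    nv = np.zeros(n_src + 1, dtype=np.int64)
    u = np.zeros(n_tax, dtype=np.int64)
    for i in range(n_reads):
        zi = np.random.randint(0, n_src + 1)
        z[i] = zi
        nv[zi] += 1
        if zi == n_src:
            u[read_taxa[i]] += 1
    u_total = nv[n_src]
    probs = np.empty(n_src + 1)
    for _ in range(burnins):
        for i in range(n_reads):
            t = read_taxa[i]
            zi = z[i]
            nv[zi] -= 1
            if zi == n_src:
                u[t] -= 1
                u_total -= 1
            total = 0.0
            for v in range(n_src):
                p = phi_known[v, t] * (nv[v] + beta)
                probs[v] = p
                total += p
            p = ((u[t] + alpha_unknown) / (u_total + n_tax * alpha_unknown)
                 * (nv[n_src] + beta))
            probs[n_src] = p
            total += p
            r = np.random.random() * total
            acc = 0.0
            zi = n_src
            for v in range(n_src + 1):
                acc += probs[v]
                if r < acc:
                    zi = v
                    break
            z[i] = zi
            nv[zi] += 1
            if zi == n_src:
                u[t] += 1
                u_total += 1
    return nv


def _phi_known(sources: SourceSet, alpha_known: float) -> np.ndarray:
    m = sources.source_counts.astype(np.float64)
    t = m.shape[1]
    return (m + alpha_known) / (m.sum(axis=1, keepdims=True) + t * alpha_known)


def _child_seed(*key: int) -> int:
    return int(np.random.SeedSequence(key).generate_state(1)[0] % (2 ** 31))


def gibbs_attribute(sink: np.ndarray, sources: SourceSet,
                    params: SourceTrackingParams, sink_id: str = "sink",
                    stream: int = 0) -> Attribution:
    """Attribute one sink count vector to the sources plus "unknown".

    ``stream`` indexes the per-sink random substream so that serial and
    parallel runs over many sinks agree.
    """
    sink = np.asarray(sink, dtype=np.int64)
    if sink.ndim != 1 or sink.shape[0] != len(sources.taxon_ids):
        raise ValueError(
            f"sink vector length {sink.shape} does not match "
            f"{len(sources.taxon_ids)} source taxa")
    total = int(sink.sum())
    if total < 1:
        raise ValueError(f"empty sink: {sink_id!r}")
    depth = params.rarefaction_depth
    if total < depth:
        raise ShallowSinkError(
            f"sink {sink_id!r}: total {total} below rarefaction depth {depth}")
    if total > depth:
        rng = np.random.default_rng([params.seed, 72, stream])
        sink = rng.multivariate_hypergeometric(sink, depth)

    read_taxa = np.repeat(np.arange(sink.shape[0]), sink).astype(np.int64)
    n_reads = read_taxa.shape[0]
    phi = _phi_known(sources, params.alpha_known)
    draws = np.empty((params.restarts, len(sources.labels) + 1))
    for r in range(params.restarts):
        seed_r = _child_seed(params.seed, 73, stream, r)
        nv = _gibbs_chain(read_taxa, phi, params.alpha_unknown, params.beta,
                          params.burnins, seed_r)
        draws[r] = nv / n_reads
    mean = draws.mean(axis=0)
    sd = draws.std(axis=0, ddof=1) if params.restarts > 1 else np.zeros_like(mean)
    labels = list(sources.labels) + [UNKNOWN]
    # guard against float drift in the sum-to-one invariant
    mean = mean / mean.sum()
    return Attribution(
        sink_id=sink_id,
        proportions={l: float(p) for l, p in zip(labels, mean)},
        restart_sd={l: float(s) for l, s in zip(labels, sd)})


def attribute_all(sinks: CountTable, sources: SourceSet,
                  params: SourceTrackingParams,
                  ) -> tuple[list[Attribution], list[str]]:
    """Attribute every sink sample; returns (attributions, dropped ids).

    Sink taxa absent from the source set are appended (zero-filled in
    every known source) so the unknown source can absorb them.  Sinks
    shallower than the rarefaction depth are skipped and reported.
    """
    union: dict[str, int] = {t: i for i, t in enumerate(sources.taxon_ids)}
    for t in sinks.taxon_ids:
        union.setdefault(t, len(union))
    n_union = len(union)
    src_counts = np.zeros((len(sources.labels), n_union), dtype=np.int64)
    src_counts[:, :len(sources.taxon_ids)] = sources.source_counts
    aligned_sources = SourceSet(list(sources.labels), src_counts, list(union))
    sink_rows = np.zeros((n_union, sinks.n_samples), dtype=np.int64)
    idx = [union[t] for t in sinks.taxon_ids]
    sink_rows[idx, :] = sinks.counts

    attributions: list[Attribution] = []
    dropped: list[str] = []
    for k, sid in enumerate(sinks.sample_ids):
        try:
            attributions.append(gibbs_attribute(
                sink_rows[:, k], aligned_sources, params, sink_id=sid, stream=k))
        except ShallowSinkError:
            dropped.append(sid)
    return attributions, dropped


# ---------------------------------------------------------------------------
# Exhaustive-posterior oracle
# ---------------------------------------------------------------------------

def oracle_attribute(sink: np.ndarray, sources: SourceSet,
                     params: SourceTrackingParams) -> dict[str, float]:
    """Exact posterior mean proportions by enumerating all assignments.

    Same joint model as the Gibbs sampler: fixed smoothed known-source
    emissions, collapsed Dirichlet-multinomial unknown source, collapsed
    symmetric Dirichlet(beta) mixing prior.  Restricted to tiny sinks
    (total <= 10 reads and at most 10^6 assignment vectors).
    """
    sink = np.asarray(sink, dtype=np.int64)
    n_reads = int(sink.sum())
    n_src = len(sources.labels)
    n_tax = len(sources.taxon_ids)
    if n_reads > 10 or (n_src + 1) ** n_reads > 10 ** 6:
        raise ValueError("instance too large for exhaustive enumeration")
    if sink.shape[0] != n_tax:
        raise ValueError("sink vector length does not match source taxa")
    read_taxa = np.repeat(np.arange(n_tax), sink)
    log_phi = np.log(_phi_known(sources, params.alpha_known))
    a_u, beta = params.alpha_unknown, params.beta

    log_weights = []
    prop_rows = []
    for z in product(range(n_src + 1), repeat=n_reads):
        nv = np.zeros(n_src + 1, dtype=np.int64)
        u = np.zeros(n_tax, dtype=np.int64)
        logw = 0.0
        for i, zi in enumerate(z):
            nv[zi] += 1
            if zi == n_src:
                u[read_taxa[i]] += 1
            else:
                logw += log_phi[zi, read_taxa[i]]
        logw += sum(math.lgamma(c + beta) for c in nv)
        logw += sum(math.lgamma(c + a_u) - math.lgamma(a_u) for c in u)
        logw += math.lgamma(n_tax * a_u) - math.lgamma(int(u.sum()) + n_tax * a_u)
        log_weights.append(logw)
        prop_rows.append(nv / n_reads)
    log_weights = np.asarray(log_weights)
    w = np.exp(log_weights - log_weights.max())
    w /= w.sum()
    mean = (np.asarray(prop_rows) * w[:, None]).sum(axis=0)
    labels = list(sources.labels) + [UNKNOWN]
    return {l: float(p) for l, p in zip(labels, mean)}
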