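"""Synthetic longitudinal mouse-cohort generator.

Emulates the structure the downstream analysis assumes: a cohort of mice
sampled repeatedly from 9 to 112 weeks of age whose gut community turns
over in phase-structured succession — early decliners that dominate
maturing mice, long-term commensals (Bacteroidota-like) that rise to a
middle-age peak, mid- and late-successors, and transients — with a
Bacteroidota/Firmicutes balance that tips toward Bacteroidota in middle
age and converges again late in life.  Per-mouse individuality is a
persistent multiplicative log-normal perturbation of the expected
profile; sequencing is multinomial at a depth drawn around
``depth_mean`` so that rarefaction is exercised.

Counts only: no reads, no chimeras, no primer bias.
"""

from __future__ import annotations

import copy
import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .io_formats import (
    INTERMEDIATE,
    PHASE_ORDER,
    DEFAULT_PHASE_MIDPOINTS,
    DEFAULT_PHASE_RANGES,
    CountTable,
    SampleMetadata,
    phase_of_age,
)

__all__ = [
    "SuccessionArchetype",
    "CohortDesign",
    "GeneratedCohort",
    "default_archetype_mix",
    "default_timepoints",
    "small_design",
    "build_phase_profiles",
    "simulate_cohort",
    "simulate_tree",
    "apply_diet_shift",
]

#: Sampling ages (weeks): arrival and early checks at 9/10/12 weeks, then
#: 4- to 5-week intervals from 17 to 112 weeks — 26 time points.
DEFAULT_TIMEPOINTS: tuple[float, ...] = (
    9, 10, 12, 17, 22, 26, 30, 34, 39, 43, 47, 52, 56, 60, 64,
    69, 73, 77, 82, 86, 90, 95, 99, 103, 108, 112,
)


def default_timepoints() -> list[float]:
    return list(DEFAULT_TIMEPOINTS)


@dataclass(frozen=True)
class SuccessionArchetype:
    """A succession pattern: mean relative abundance per life phase.

    ``phase_means`` anchors a piecewise-linear trajectory at the phase
    midpoints; ``phylum_label`` tags the taxon group for coarse
    Bacteroidota/Firmicutes bookkeeping.
    """

    name: str
    phase_means: dict[str, float]
    phylum_label: str = "Firmicutes-like"

    def __post_init__(self) -> None:
        vals = [self.phase_means.get(p, 0.0) for p in PHASE_ORDER]
        if any(v < 0 for v in vals) or not any(v > 0 for v in vals):
            raise ValueError(f"archetype {self.name!r}: phase means must be "
                             "nonnegative with at least one positive")
        argmax = PHASE_ORDER[int(np.argmax(vals))]
        if self.name == "early_decliner" and argmax != "MR":
            raise ValueError("early_decliner must peak at MR")
        if self.name == "late_successor" and argmax not in ("OD", "VO"):
            raise ValueError("late_successor must peak at OD or VO")


def default_archetype_mix(n_taxa: int) -> list[tuple[SuccessionArchetype, int]]:
    """Default succession mix (fractions of the community rounded to counts)."""
    archetypes = [
        (SuccessionArchetype(
            "early_decliner",
            {"MR": 1.0, "MA": 0.25, "MD": 0.05, "OD": 0.03, "VO": 0.03}), 0.15),
        (SuccessionArchetype(
            "long_term_commensal",
            {"MR": 0.25, "MA": 0.9, "MD": 1.2, "OD": 0.7, "VO": 0.75},
            phylum_label="Bacteroidota-like"), 0.30),
        (SuccessionArchetype(
            "mid_successor",
            {"MR": 0.05, "MA": 0.45, "MD": 0.9, "OD": 0.4, "VO": 0.35}), 0.20),
        (SuccessionArchetype(
            "late_successor",
            {"MR": 0.01, "MA": 0.05, "MD": 0.15, "OD": 0.7, "VO": 0.85}), 0.20),
        (SuccessionArchetype(
            "transient",
            {"MR": 0.35, "MA": 0.6, "MD": 0.3, "OD": 0.3, "VO": 0.3}), 0.15),
    ]
    counts = [int(round(frac * n_taxa)) for _, frac in archetypes]
    counts[-1] += n_taxa - sum(counts)
    return [(a, c) for (a, _), c in zip(archetypes, counts)]


@dataclass
class CohortDesign:
    """Cohort layout and noise model.

    Defaults give 20 mice x 26 time points (ages 9–112 weeks) and 651
    taxa — the scale of the community the study analysed.  ``overdispersion``
    is the sigma of the per-mouse log-normal taxon factors.
    """

    n_mice: int = 20
    timepoints_weeks: list[float] = field(default_factory=default_timepoints)
    n_taxa: int = 651
    depth_mean: int = 10_000
    overdispersion: float = 0.3
    archetype_mix: list[tuple[SuccessionArchetype, int]] | None = None
    taxon_weight_sigma: float = 0.75
    phylum_tolerance: float = 0.25
    seed: int = 0
    survival: dict[float, int] | None = None  # age -> mice alive; None = all

    def __post_init__(self) -> None:
        tp = list(self.timepoints_weeks)
        if not all(a < b for a, b in zip(tp, tp[1:])):
            raise ValueError("timepoints must be strictly increasing")
        if tp and not (tp[0] >= 9 and tp[-1] <= 112):
            raise ValueError("timepoints must lie within [9, 112] weeks")
        if self.archetype_mix is None:
            self.archetype_mix = default_archetype_mix(self.n_taxa)
        if sum(c for _, c in self.archetype_mix) != self.n_taxa:
            raise ValueError("archetype counts must sum to n_taxa")
        if self.n_mice < 1 or self.n_taxa < 1 or self.depth_mean < 1:
            raise ValueError("n_mice, n_taxa and depth_mean must be positive")
        if self.overdispersion < 0:
            raise ValueError("overdispersion must be nonnegative")


def small_design(seed: int = 0, n_mice: int = 6, n_taxa: int = 60,
                 depth_mean: int = 6000) -> CohortDesign:
    """Down-scaled preset used throughout the test suite."""
    return CohortDesign(n_mice=n_mice, n_taxa=n_taxa, depth_mean=depth_mean,
                        archetype_mix=default_archetype_mix(n_taxa), seed=seed)


@dataclass
class GeneratedCohort:
    """A simulated cohort: counts, metadata, tree, and ground truth."""

    table: CountTable
    metadata: list[SampleMetadata]
    tree: str
    truth: dict[str, tuple[float, str]]
    generator_params: CohortDesign
    expected_profiles: np.ndarray = None  # (taxa, samples), each column sums to 1
    depths: np.ndarray = None

    def __post_init__(self) -> None:
        if (self.table.sample_totals() <= 0).any():
            raise ValueError("every sample must have positive total count")
        for m in self.metadata:
            if self.truth[m.sample_id][0] != m.age_weeks:
                raise ValueError(f"truth age mismatch for {m.sample_id}")


# ---------------------------------------------------------------------------
# Expected profiles
# ---------------------------------------------------------------------------

def _taxon_weights(design: CohortDesign) -> np.ndarray:
    """Per-taxon log-normal magnitudes; make taxa within an archetype distinct."""
    rng = np.random.default_rng([design.seed, 11])
    if design.taxon_weight_sigma == 0:
        return np.ones(design.n_taxa)
    return rng.lognormal(0.0, design.taxon_weight_sigma, design.n_taxa)


def _phylum_labels(design: CohortDesign) -> np.ndarray:
    labels = []
    for arch, count in design.archetype_mix:
        labels.extend([arch.phylum_label] * count)
    return np.array(labels)


def build_phase_profiles(design: CohortDesign) -> np.ndarray:
    """Expected relative-abundance matrix (taxa x timepoints).

    Each taxon follows its archetype's phase means, interpolated
    piecewise-linearly in age between the phase midpoints (clamped
    outside), scaled by a per-taxon magnitude and column-normalised.
    """
    midpoint_ages = np.array([DEFAULT_PHASE_MIDPOINTS[p] for p in PHASE_ORDER])
    ages = np.asarray(design.timepoints_weeks, dtype=float)
    weights = _taxon_weights(design)
    rows = []
    for arch, count in design.archetype_mix:
        means = np.array([arch.phase_means.get(p, 0.0) for p in PHASE_ORDER])
        curve = np.interp(ages, midpoint_ages, means)
        rows.extend([curve] * count)
    profile = np.asarray(rows) * weights[:, None]
    colsums = profile.sum(axis=0)
    if (colsums <= 0).any():
        bad = ages[colsums <= 0]
        raise ValueError(f"degenerate profile: all-zero column at ages {bad}")
    return profile / colsums


def phylum_balance(design: CohortDesign) -> tuple[np.ndarray, np.ndarray]:
    """Summed expected Bacteroidota-like vs Firmicutes-like fraction per timepoint."""
    profile = build_phase_profiles(design)
    labels = _phylum_labels(design)
    bact = profile[labels == "Bacteroidota-like"].sum(axis=0)
    firm = profile[labels == "Firmicutes-like"].sum(axis=0)
    return bact, firm


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

def _mice_alive_at(design: CohortDesign, age: float) -> int:
    if design.survival is None:
        return design.n_mice
    alive = design.n_mice
    for cutoff in sorted(design.survival):
        if age >= cutoff:
            alive = design.survival[cutoff]
    return min(alive, design.n_mice)


def simulate_cohort(design: CohortDesign) -> GeneratedCohort:
    """Draw a full cohort count table, metadata, tree and truth map.

    Per mouse, a persistent log-normal factor vector perturbs the
    expected profile (individuality); per sample, counts are multinomial
    at a depth drawn uniformly in [0.8, 1.2] x ``depth_mean``.  Fully
    reproducible from ``design.seed``.
    """
    profiles = build_phase_profiles(design)
    n_taxa = design.n_taxa
    taxon_ids = [f"ASV{i + 1:04d}" for i in range(n_taxa)]

    mouse_rng = np.random.default_rng([design.seed, 21])
    if design.overdispersion > 0:
        mouse_factors = mouse_rng.lognormal(0.0, design.overdispersion,
                                            (design.n_mice, n_taxa))
    else:
        mouse_factors = np.ones((design.n_mice, n_taxa))
    depth_rng = np.random.default_rng([design.seed, 22])
    lo, hi = int(np.ceil(0.8 * design.depth_mean)), int(np.floor(1.2 * design.depth_mean))

    sample_ids: list[str] = []
    metadata: list[SampleMetadata] = []
    truth: dict[str, tuple[float, str]] = {}
    expected_cols: list[np.ndarray] = []
    counts_cols: list[np.ndarray] = []
    depths: list[int] = []
    k = 0
    for j, age in enumerate(design.timepoints_weeks):
        alive = _mice_alive_at(design, age)
        for m in range(design.n_mice):
            if m >= alive:
                continue
            p = profiles[:, j] * mouse_factors[m]
            p = p / p.sum()
            depth = int(depth_rng.integers(lo, hi + 1))
            counts = np.random.default_rng([design.seed, 23, k]).multinomial(depth, p)
            sid = f"M{m + 1:02d}_w{age:g}"
            phase = phase_of_age(age)
            sample_ids.append(sid)
            metadata.append(SampleMetadata(
                sample_id=sid, mouse_id=f"M{m + 1:02d}", age_weeks=float(age),
                life_phase=phase, diet="standard", cage=f"C{m // 5 + 1}"))
            truth[sid] = (float(age), phase)
            expected_cols.append(p)
            counts_cols.append(counts)
            depths.append(depth)
            k += 1

    table = CountTable(taxon_ids, sample_ids,
                       np.column_stack(counts_cols).astype(np.int64))
    tree = simulate_tree(n_taxa, design.seed, taxon_ids=taxon_ids)
    return GeneratedCohort(
        table=table, metadata=metadata, tree=tree, truth=truth,
        generator_params=design,
        expected_profiles=np.column_stack(expected_cols),
        depths=np.asarray(depths))


def simulate_tree(n_taxa: int, seed: int,
                  taxon_ids: list[str] | None = None) -> str:
    """Random rooted bifurcating tree with positive branch lengths, as newick.

    Built by repeated random pairwise joins; n tips yield n-1 internal
    nodes.  Deterministic given ``seed``.
    """
    if n_taxa < 2:
        raise ValueError("a tree needs at least 2 taxa")
    if taxon_ids is None:
        taxon_ids = [f"t{i + 1}" for i in range(n_taxa)]
    if len(taxon_ids) != n_taxa:
        raise ValueError("taxon_ids length must equal n_taxa")
    rng = np.random.default_rng([seed, 31])
    items = list(taxon_ids)
    while len(items) > 1:
        i, j = sorted(rng.choice(len(items), size=2, replace=False))
        b = items.pop(j)
        a = items.pop(i)
        la, lb = rng.exponential(0.2, 2) + 1e-3
        items.append(f"({a}:{la:.6f},{b}:{lb:.6f})")
    return items[0] + ";"


def apply_diet_shift(cohort: GeneratedCohort, target_samples: list[str],
                     shift_strength: float) -> GeneratedCohort:
    """Blend target samples toward the cohort's late-life configuration.

    Models the western-diet effect: a target sample's expected profile
    is mixed with weight ``shift_strength`` toward that mouse's very-old
    (VO) expected profile, then its counts are redrawn from the same
    per-sample random stream — at strength 0 the table is unchanged, at
    strength 1 the expected profile equals the VO-phase profile and the
    operation is idempotent.
    """
    if not 0.0 <= shift_strength <= 1.0:
        raise ValueError("shift_strength must lie in [0, 1]")
    design = cohort.generator_params
    table = cohort.table
    for sid in target_samples:
        if sid not in table.sample_ids:
            raise KeyError(f"unknown sample id: {sid!r}")

    # per-mouse VO-phase expected profile = mean of that mouse's expected
    # columns over VO timepoints
    vo_ages = [a for a in design.timepoints_weeks
               if phase_of_age(a) == "VO"]
    if not vo_ages:
        raise ValueError("design has no VO timepoints to shift toward")
    meta_by_id = {m.sample_id: m for m in cohort.metadata}
    vo_profile: dict[str, np.ndarray] = {}
    for i, sid in enumerate(table.sample_ids):
        m = meta_by_id[sid]
        if m.age_weeks in vo_ages:
            vo_profile.setdefault(m.mouse_id, []).append(cohort.expected_profiles[:, i])
    vo_profile = {mouse: np.mean(cols, axis=0) / np.mean(cols, axis=0).sum()
                  for mouse, cols in vo_profile.items()}

    new_expected = cohort.expected_profiles.copy()
    new_counts = table.counts.copy()
    new_meta = list(cohort.metadata)
    index_of = {sid: i for i, sid in enumerate(table.sample_ids)}
    for sid in target_samples:
        i = index_of[sid]
        mouse = meta_by_id[sid].mouse_id
        if mouse not in vo_profile:
            raise ValueError(f"mouse {mouse} has no VO-phase samples")
        p = (1.0 - shift_strength) * cohort.expected_profiles[:, i] \
            + shift_strength * vo_profile[mouse]
        p = p / p.sum()
        new_expected[:, i] = p
        new_counts[:, i] = np.random.default_rng(
            [design.seed, 23, i]).multinomial(int(cohort.depths[i]), p)
        if shift_strength > 0:
            new_meta[i] = dataclasses.replace(new_meta[i], diet="western")

    return GeneratedCohort(
        table=CountTable(list(table.taxon_ids), list(table.sample_ids), new_counts),
        metadata=new_meta, tree=cohort.tree, truth=dict(cohort.truth),
        generator_params=copy.deepcopy(design),
        expected_profiles=new_expected, depths=cohort.depths.copy())
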