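# Methods

## The model in one paragraph

A mouse's age is inferred from how its fecal community apportions among
five reference communities, one per life phase.  Given a sink sample's
rarefied read vector, a collapsed Gibbs sampler assigns each read to a
known phase source or to an adaptive "unknown" source; the resulting
phase proportions x, renormalized over the known phases, are combined
with the phase midpoints a (MR 10.5, MA 19.5, MD 51.5, OD 93, VO 110
weeks) as y = Σ a·x.  The prediction is therefore a convex combination
of midpoints: it is bounded by [10.5, 110] weeks, compresses at both
ends of life, and is only as good as the separation between the phase
sources.

## Source-tracking model and sampler

Reads are exchangeable tokens carrying a taxon index.  Known source v
emits taxon t with fixed probability
phi_v(t) = (m_vt + α_known)/(M_v + T·α_known), where m is the pooled,
rarefied source count matrix — source profiles are not resampled.  The
unknown source is a symmetric Dirichlet(α_unknown)-multinomial learned
from the reads currently assigned to it.  Mixing proportions carry a
collapsed symmetric Dirichlet(β) prior, giving the full conditional
P(z_i = v | z_−i) ∝ phi_v(t_i)·(n_v^−i + β).

Sampler schedule: per restart, a uniform random initial assignment,
`burnins` full sweeps (default 100), then a single retained draw of the
proportions n_v/N.  The attribution is the mean over `restarts`
independent chains (default 10) and `restart_sd` their sample standard
deviation — a cheap dispersion diagnostic in lieu of autocorrelation
analysis.  Hyperparameters default to α_known = 0.001,
α_unknown = 0.1, β = 10, the published defaults of the reference
implementation of this model class; all are configurable.

Correctness is checked against an exhaustive-posterior oracle that
enumerates every assignment vector on instances with ≤ 6 reads and
computes exact posterior means under the same joint model; Gibbs
estimates agree within 0.03 on the test grid.

Two properties of this model are worth knowing before interpreting
output.  First, the unknown source can adapt to fit any sink, so even a
sink drawn exactly from a known source's profile cedes it a share
(~5–10% at depths of 500–2,733 reads); attributed known-source
proportions are mildly conservative.  Second, proportions are pulled
toward uniform by β; at the default β = 10 this effect is negligible
beyond a few hundred reads.

## Source selection

Pairwise PERMANOVA (Anderson's pseudo-F) between all sampling time
points on the Bray-Curtis matrix of the rarefied table, p-values from
uniform label permutations (9,999 by default; exact enumeration is
substituted automatically when the number of distinct arrangements is
≤ 10,000), Benjamini-Hochberg correction across pairs.  Each phase's
source is its member time point with the fewest pairs at adjusted
p < 0.01; ties break toward the earlier age and are flagged.  All
samples at the chosen time point are summed into a single pooled
community and rarefied to the source-tracking depth.  Permutations
shuffle samples freely rather than respecting the repeated-measures
structure (no stratification by mouse or cage); for longitudinal data
this anticonservative choice is a known limitation and matches the
common practice the pipeline reproduces.

## Diversity conventions

* Rarefaction: one uniform draw without replacement per sample
  (multivariate hypergeometric), samples below depth dropped and
  reported.  Default depth 2,733 reads.
* Shannon in nats; Simpson reported as 1 − D; Chao1 bias-corrected
  (S_obs + F1(F1−1)/(2(F2+1))); Pielou H/ln S_obs, undefined for
  single-taxon samples.
* Bray-Curtis Σ|a−b|/Σ(a+b); weighted UniFrac unnormalized
  (Σ_b l_b·|p_A(b) − p_B(b)|), with an optional normalized mode.
* PCoA is classical scaling; negative eigenvalues are dropped and
  explained fractions are taken relative to the positive-eigenvalue
  sum.

## Age model

Renormalization by (1 − unknown) before the weighted sum is the
default: the midpoint formula has five terms and no unknown term, and
renormalization keeps predictions inside the midpoint range.  A raw
mode performs the literal term-by-term sum instead.  The uncertainty
filter is strict: unknown > 0.30 excludes, exactly 0.30 retains.
Evaluation uses Spearman rho plus a degree-2 least-squares polynomial
(adjusted R²); the degree is configurable — the predicted-vs-actual
relationship saturates late in life, and a quadratic is the smallest
family that captures that.  The young/old stratum split defaults to 62
weeks, the midpoint between 60- and 64-week sampling ages.

Batch calibration: control samples from a new batch are mapped to
phases by age (each sample individually, via the phase windows), pooled
per phase, rarefied, and appended as `<phase>#cal` source rows.  At
prediction time calibration rows fold back onto their phase, letting
the sampler absorb batch-specific compositional offsets without
altering the age formula.

## Synthetic cohort

The generator emulates the structure the analysis assumes, not any real
sequencing run:

* 20 mice × 26 sampling ages (9, 10, 12, then 4–5-week intervals from
  17 to 112 weeks), four cages of five mice, 651 taxa, mean depth
  10,000 reads (uniform ±20% so rarefaction is exercised).
* Five succession archetypes (early decliner, long-term commensal,
  mid-successor, late successor, transient) anchor piecewise-linear
  expected trajectories at the phase midpoints; per-taxon log-normal
  magnitudes (σ = 0.75) make taxa within an archetype distinct.  The
  long-term commensals are tagged Bacteroidota-like, the rest
  Firmicutes-like, so the expected Bacteroidota share exceeds the
  Firmicutes share in middle age and the two converge (within a 25%
  relative band) in old and very old animals.
* Mouse individuality is a persistent per-mouse, per-taxon log-normal
  factor with σ = `overdispersion`, default 0.3.  This value was set
  during generator design so that the cohort shows clear
  interindividual variation while the bulk of sinks stay under the 30%
  unknown filter — the regime in which the original analysis operated,
  with most longitudinal samples attributable to phase sources.
* Phase windows for labelling ages: MR 9–12, MA 17–22, MD 47–56,
  OD 86–100, VO 108–112 weeks; ages between windows are
  "intermediate" and never used as sources.  The windows are an
  interpretation anchored at the midpoints and are configurable.
* An optional survival schedule can retire mice at later ages
  (default off).  A western-diet scenario blends selected samples'
  expected profiles toward the same mouse's very-old profile with a
  chosen strength and redraws counts from the same random substream,
  so strength 0 is a byte-identical no-op and strength 1 is
  idempotent.

What the generator does **not** emulate: sequence-level artifacts
(chimeras, primer bias), taxon-taxon interactions, cage effects beyond
mouse identity, real phylogenetic signal (the tree is a random
bifurcating tree, so weighted UniFrac is exercised but carries no
ecological meaning), or the slow drift of a real facility's microbiota.
Passing tests therefore demonstrate that the pipeline's machinery is
correct and internally consistent under the assumed succession
structure — not that the age model would reach any particular accuracy
on real sequencing data.

## Problem sizes and numerics

The test suite runs the full pipeline on a down-scaled preset (6 mice,
60 taxa, mean depth 6,000; `small_design()`), chosen as the smallest
cohort that preserves every qualitative contract (phase-monotone
medians, source selection, diversity trends); the source-selection
check also runs the full 651-taxon, 520-sample default cohort with
pairwise PERMANOVA at 199 permutations.  The Gibbs inner loop is
numba-compiled; per-sink and per-restart seeds derive from a master
seed through independent substreams, so results are reproducible and
order-independent.  Attribution proportions are renormalized against
float drift before the sum-to-one invariant is enforced at 1e-9.
Degenerate cases: a sink or pooled source shallower than the
rarefaction depth raises (or, in batch attribution, is skipped and
reported); an all-unknown attribution has no defined age and is never
retained; constant predictions make Spearman rho undefined and it is
reported as missing.

## Known limitations

* Unstratified permutations in PERMANOVA (see above).
* The unknown-source share biases known proportions slightly downward;
  the uncertainty filter partially compensates by discarding
  poorly-explained sinks.
* Sources are single pooled communities; within-time-point variation
  is not propagated into attribution uncertainty (only across-restart
  dispersion is reported).
* The age formula is piecewise-constant in spirit: it cannot
  extrapolate beyond the midpoint range, and resolution between OD and
  VO is intrinsically poor because their communities are similar.
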