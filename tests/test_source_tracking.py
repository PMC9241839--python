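import math

import numpy as np
import pytest

import microage as ma
from microage.source_tracking import (
    UNKNOWN,
    ShallowSinkError,
    SourceSet,
    SourceTrackingParams,
)


def _toy_sources() -> SourceSet:
    return SourceSet(["A", "B"], np.array([[8, 1, 1], [1, 8, 1]]),
                     ["t1", "t2", "t3"])


def _toy_params(**kwargs) -> SourceTrackingParams:
    defaults = dict(burnins=50, restarts=50, rarefaction_depth=6, seed=1)
    defaults.update(kwargs)
    return SourceTrackingParams(**defaults)


class TestPrepareSources:
    def test_identity_when_single_sample_at_depth(self):
        params = SourceTrackingParams(rarefaction_depth=100, seed=0)
        tables = {
            "MR": ma.CountTable(["t1", "t2"], ["s1"], np.array([[60], [40]])),
        }
        sources = ma.prepare_sources(tables, params)
        assert sources.labels == ["MR"]
        assert np.array_equal(sources.source_counts, [[60, 40]])

    def test_five_phases_five_rows(self, small_cohort):
        meta = {m.sample_id: m for m in small_cohort.metadata}
        tables = {}
        for phase, (lo, hi) in ma.DEFAULT_PHASE_RANGES.items():
            sids = [s for s in small_cohort.table.sample_ids
                    if lo <= meta[s].age_weeks <= hi]
            tables[phase] = small_cohort.table.select_samples(sids)
        sources = ma.prepare_sources(tables, ma.SourceTrackingParams(seed=0))
        assert sources.labels == list(ma.PHASE_ORDER)
        assert sources.source_counts.shape == (5, small_cohort.table.n_taxa)
        assert (sources.source_counts.sum(axis=1) == 2733).all()

    def test_pooling_preserves_expected_composition(self):
        # two identical samples pooled then rarefied: mean composition
        # over seeds stays within 2% of the sample composition
        col = np.array([600, 300, 100])
        fractions = []
        for seed in range(40):
            params = SourceTrackingParams(rarefaction_depth=500, seed=seed)
            tables = {"MR": ma.CountTable(["a", "b", "c"], ["s1", "s2"],
                                          np.column_stack([col, col]))}
            out = ma.prepare_sources(tables, params)
            fractions.append(out.source_counts[0] / 500)
        assert np.abs(np.mean(fractions, axis=0) - col / 1000).max() <= 0.02

    def test_shallow_pool_names_phase(self):
        params = SourceTrackingParams(rarefaction_depth=1000, seed=0)
        tables = {"VO": ma.CountTable(["t1"], ["s1"], np.array([[10]]))}
        with pytest.raises(ShallowSinkError, match="VO"):
            ma.prepare_sources(tables, params)


class TestOracle:
    def test_symmetric_sources_exactly_equal(self):
        src = SourceSet(["A", "B"], np.array([[5, 5], [5, 5]]), ["t1", "t2"])
        out = ma.oracle_attribute(np.array([2, 2]), src,
                                  _toy_params(rarefaction_depth=4))
        assert out["A"] == pytest.approx(out["B"], abs=1e-12)

    def test_single_read_closed_form(self):
        # one read of a taxon; posterior over {A, unknown} has two terms:
        # w_A = phi_A(t) * beta, w_u = (alpha_u / (T alpha_u)) * beta
        params = _toy_params(rarefaction_depth=1)
        src = SourceSet(["A"], np.array([[9, 0]]), ["t1", "t2"])
        out = ma.oracle_attribute(np.array([1, 0]), src, params)
        phi_a = (9 + params.alpha_known) / (9 + 2 * params.alpha_known)
        w_a = phi_a * params.beta
        w_u = (params.alpha_unknown / (2 * params.alpha_unknown)) * params.beta
        assert out["A"] == pytest.approx(w_a / (w_a + w_u), abs=1e-12)
        assert out[UNKNOWN] == pytest.approx(w_u / (w_a + w_u), abs=1e-12)

    def test_instance_size_guard(self):
        src = _toy_sources()
        with pytest.raises(ValueError, match="too large"):
            ma.oracle_attribute(np.array([10, 10, 10]), src, _toy_params())


class TestGibbs:
    def test_matches_oracle_on_toy(self):
        params = _toy_params()
        sink = np.array([3, 2, 1])
        gibbs = ma.gibbs_attribute(sink, _toy_sources(), params)
        exact = ma.oracle_attribute(sink, _toy_sources(), params)
        for label in exact:
            assert abs(gibbs.proportions[label] - exact[label]) <= 0.03

    def test_proportions_sum_to_one(self):
        attr = ma.gibbs_attribute(np.array([3, 2, 1]), _toy_sources(),
                                  _toy_params(restarts=3))
        assert sum(attr.proportions.values()) == pytest.approx(1.0, abs=1e-9)

    def test_identical_sources_near_symmetric(self):
        src = SourceSet(["A", "B"], np.array([[50, 50], [50, 50]]), ["t1", "t2"])
        params = SourceTrackingParams(burnins=50, restarts=20,
                                      rarefaction_depth=100, seed=3)
        attr = ma.gibbs_attribute(np.array([60, 40]), src, params)
        assert abs(attr.proportions["A"] - attr.proportions["B"]) <= 0.10

    def test_disjoint_sources_recovered(self):
        # sources with disjoint support; sinks drawn from source A's
        # profile at depth 500 attribute >= 90% to A on average (the
        # adaptive unknown source retains a small share by construction)
        t = 40
        src_counts = np.zeros((2, t), dtype=int)
        src_counts[0, :20] = 25
        src_counts[1, 20:] = 25
        src = SourceSet(["A", "B"], src_counts, [f"t{i}" for i in range(t)])
        profile_a = src_counts[0] / src_counts[0].sum()
        props = []
        for seed in range(5):
            sink = np.random.default_rng(seed).multinomial(500, profile_a)
            attr = ma.gibbs_attribute(sink, src,
                                      SourceTrackingParams(
                                          burnins=50, restarts=5,
                                          rarefaction_depth=500, seed=seed))
            props.append(attr.proportions["A"])
        assert np.mean(props) >= 0.90

    def test_foreign_taxa_go_to_unknown(self):
        # sink entirely on taxa absent from every known source
        src = SourceSet(["A", "B"],
                        np.array([[5, 5, 0, 0], [5, 5, 0, 0]]),
                        ["t1", "t2", "t3", "t4"])
        params = _toy_params(rarefaction_depth=6)
        sink = np.array([0, 0, 3, 3])
        exact = ma.oracle_attribute(sink, src, params)
        gibbs = ma.gibbs_attribute(sink, src, params)
        assert exact[UNKNOWN] >= 0.5
        assert gibbs.proportions[UNKNOWN] >= 0.5

    def test_empty_and_shallow_sink_errors(self):
        with pytest.raises(ValueError, match="empty"):
            ma.gibbs_attribute(np.array([0, 0, 0]), _toy_sources(),
                               SourceTrackingParams(rarefaction_depth=1))
        with pytest.raises(ShallowSinkError):
            ma.gibbs_attribute(np.array([1, 0, 0]), _toy_sources(),
                               SourceTrackingParams(rarefaction_depth=5))

    def test_misaligned_taxa_error(self):
        with pytest.raises(ValueError, match="does not match"):
            ma.gibbs_attribute(np.array([1, 1]), _toy_sources(), _toy_params())

    def test_restart_sd_shrinks_with_depth(self):
        rng = np.random.default_rng(7)
        t = 30
        p_a = rng.dirichlet(np.ones(t))
        p_b = rng.dirichlet(np.ones(t))
        src_counts = np.vstack([rng.multinomial(2000, p_a),
                                rng.multinomial(2000, p_b)])
        mix = 0.6 * p_a + 0.4 * p_b
        sds = {}
        for depth in (100, 2000):
            vals = []
            for seed in range(5):
                src = SourceSet(["A", "B"],
                                np.vstack([
                                    np.random.default_rng([seed, 0]).multinomial(depth, p_a),
                                    np.random.default_rng([seed, 1]).multinomial(depth, p_b)]),
                                [f"t{i}" for i in range(t)])
                sink = np.random.default_rng([seed, 2]).multinomial(depth, mix)
                attr = ma.gibbs_attribute(
                    sink, src, SourceTrackingParams(burnins=50, restarts=10,
                                                    rarefaction_depth=depth,
                                                    seed=seed))
                vals.append(np.mean(list(attr.restart_sd.values())))
            sds[depth] = np.median(vals)
        assert sds[2000] < sds[100]


class TestAttributeAll:
    def test_deterministic_and_reports_shallow(self):
        src = _toy_sources()
        sinks = ma.CountTable(["t1", "t2", "t3"], ["deep1", "thin", "deep2"],
                              np.array([[5, 1, 1], [3, 0, 2], [2, 0, 7]]))
        params = _toy_params(restarts=3)
        attrs1, dropped1 = ma.attribute_all(sinks, src, params)
        attrs2, dropped2 = ma.attribute_all(sinks, src, params)
        assert dropped1 == dropped2 == ["thin"]
        assert [a.sink_id for a in attrs1] == ["deep1", "deep2"]
        for a, b in zip(attrs1, attrs2):
            assert a.proportions == b.proportions

    def test_empty_sink_list(self):
        sinks = ma.CountTable(["t1", "t2", "t3"], [],
                              np.zeros((3, 0), dtype=int))
        attrs, dropped = ma.attribute_all(sinks, _toy_sources(), _toy_params())
        assert attrs == [] and dropped == []

    def test_sink_only_taxa_are_absorbed(self):
        src = _toy_sources()
        sinks = ma.CountTable(["t1", "tz"], ["s"], np.array([[3], [3]]))
        attrs, _ = ma.attribute_all(sinks, src, _toy_params(restarts=10))
        assert attrs[0].proportions[UNKNOWN] > 0.2

    def test_source_sample_attributed_to_own_phase(self, small_cohort):
        meta = {m.sample_id: m for m in small_cohort.metadata}
        tables = {}
        chosen_age = {}
        for phase, (lo, hi) in ma.DEFAULT_PHASE_RANGES.items():
            age = next(a for a in small_cohort.generator_params.timepoints_weeks
                       if lo <= a <= hi)
            chosen_age[phase] = age
            sids = [s for s in small_cohort.table.sample_ids
                    if meta[s].age_weeks == age]
            tables[phase] = small_cohort.table.select_samples(sids)
        params = SourceTrackingParams(seed=2)
        sources = ma.prepare_sources(tables, params)
        # a source-timepoint sample analysed as a sink attributes mostly
        # to its own phase
        sid = tables["MD"].sample_ids[0]
        sinks = small_cohort.table.select_samples([sid])
        attrs, _ = ma.attribute_all(sinks, sources, params)
        props = attrs[0].proportions
        known = {k: v for k, v in props.items() if k != UNKNOWN}
        assert max(known, key=known.get) == "MD"
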