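"""Model validation, canonicalization and semantic equality."""

import copy
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import demesim as d
from demesim.demography import (
    ALL,
    DemographicModel,
    LineageMove,
    MigrationChange,
    PopulationDef,
    SizeGrowthChange,
    canonicalize,
    model_from_canonical,
    models_equal,
    state_at_time,
    validate_model,
)


def two_pop(sizes=(1000.0, 2000.0), m=((0.0, 1e-4), (1e-4, 0.0)), events=()):
    return DemographicModel(
        id="TwoPop",
        populations=[PopulationDef("a"), PopulationDef("b")],
        initial_sizes=list(sizes),
        initial_growth_rates=[0.0, 0.0],
        migration_matrix=[list(r) for r in m],
        events=list(events),
    )


class TestValidate:
    def test_well_formed_im_model_is_clean(self, im_model):
        assert validate_model(im_model) == []

    def test_negative_migration_rate_is_named(self):
        m = two_pop(m=((0.0, -0.1), (0.0, 0.0)))
        violations = validate_model(m)
        assert len(violations) == 1
        assert "migration_matrix[0][1]" in violations[0]

    def test_out_of_range_lineage_move_names_event_index(self):
        m = two_pop(events=[LineageMove(time=10.0, source=3, dest=0)])
        violations = validate_model(m)
        assert len(violations) == 1
        assert "events[0]" in violations[0]

    @pytest.mark.parametrize(
        "bad",
        [
            dict(initial_sizes=[0.0, 1.0]),
            dict(initial_sizes=[1000.0]),
            dict(events=[SizeGrowthChange(time=-1.0, new_size=5.0)]),
            dict(events=[LineageMove(time=1.0, source=0, dest=1, proportion=1.5)]),
            dict(events=[SizeGrowthChange(time=1.0)]),  # nothing set
            dict(migration_matrix=[[0.0, 1.0, 0.0], [0.0, 0.0, 0.0]]),
            dict(populations=[PopulationDef("a"), PopulationDef("a")]),
        ],
    )
    def test_invariant_violations_are_reported(self, bad):
        m = two_pop()
        for k, v in bad.items():
            setattr(m, k, v)
        assert validate_model(m) != []


class TestCanonicalize:
    def test_redundant_migration_changes_collapse_to_one_boundary(self):
        ev = [
            MigrationChange(time=100.0, source=0, dest=1, new_rate=5e-4),
            MigrationChange(time=100.0, source=0, dest=1, new_rate=5e-4),
        ]
        canon = canonicalize(two_pop(events=ev))
        assert [e.t_start for e in canon.epochs] == [0.0, 100.0]
        assert canon.epochs[1].migration_matrix[0, 1] == 5e-4

    def test_noop_event_creates_no_epoch(self):
        ev = [MigrationChange(time=100.0, source=0, dest=1, new_rate=1e-4)]
        canon = canonicalize(two_pop(events=ev))  # rate already 1e-4
        assert len(canon.epochs) == 1

    def test_piecewise_constant_two_epochs(self):
        m = d.generic_piecewise_constant([1000.0, 500.0], [200.0])
        canon = canonicalize(m)
        assert [(e.t_start, e.t_end) for e in canon.epochs] == [(0.0, 200.0), (200.0, math.inf)]
        assert canon.epochs[0].start_sizes[0] == 1000.0
        assert canon.epochs[1].start_sizes[0] == 500.0

    def test_im_model_structure(self, im_model):
        canon = canonicalize(im_model)
        assert len(canon.lineage_moves) == 1
        mv = canon.lineage_moves[0]
        assert (mv.source, mv.dest, mv.proportion) == (1, 0, 1.0)
        assert len(canon.epochs) == 2
        assert np.all(canon.epochs[1].migration_matrix == 0.0)
        assert canon.epochs[1].start_sizes[0] == 7300.0

    def test_idempotence(self, im_model, two_epoch_model):
        for m in (im_model, two_epoch_model):
            c1 = canonicalize(m)
            rebuilt = model_from_canonical(c1)
            c2 = canonicalize(rebuilt)
            assert models_equal(m, rebuilt).equal
            assert len(c1.epochs) == len(c2.epochs)

    def test_invalid_model_raises_with_violations(self):
        m = two_pop(m=((0.0, -1.0), (0.0, 0.0)))
        with pytest.raises(d.demography.ModelValidationError) as err:
            canonicalize(m)
        assert "migration_matrix" in str(err.value)


class TestModelsEqual:
    def test_independently_constructed_im_models_equal(self):
        a = d.generic_im(7300, 10000, 10000, 4000, 1e-4, 1e-4)
        # a "second developer" construction: explicit events, different order
        b = DemographicModel(
            id="IMReimplementation",
            populations=[PopulationDef("p0"), PopulationDef("p1")],
            initial_sizes=[10000.0, 10000.0],
            initial_growth_rates=[0.0, 0.0],
            migration_matrix=[[0.0, 1e-4], [1e-4, 0.0]],
            events=[
                LineageMove(time=4000.0, source=1, dest=0, proportion=1.0),
                MigrationChange(time=4000.0, source=ALL, dest=ALL, new_rate=0.0),
                SizeGrowthChange(time=4000.0, population=0, new_size=7300.0),
            ],
        )
        assert models_equal(a, b).equal

    def test_ancient_migration_bug_is_caught_and_named(self):
        """Nonzero migration left on in the single-ancestral-population epoch
        (the classic three-population out-of-Africa implementation slip) must
        fail equality with a difference naming the epoch and matrix entry."""
        a = d.generic_im(7300, 10000, 10000, 4000, 1e-4, 1e-4)
        b = d.generic_im(7300, 10000, 10000, 4000, 1e-4, 1e-4)
        # b forgets to zero m[0][1] at the merge: only m[1][0] is switched off
        b.events = [
            e for e in b.events if not isinstance(e, MigrationChange)
        ] + [MigrationChange(time=4000.0, source=1, dest=0, new_rate=0.0)]
        report = models_equal(a, b)
        assert not report.equal
        (interval, path, va, vb), = report.differences
        assert interval == (4000.0, math.inf)
        assert path == "migration_matrix[0][1]"
        assert (va, vb) == (0.0, 1e-4)

    def test_sizes_within_half_tolerance_are_equal(self):
        a = two_pop(sizes=(1000.0, 2000.0))
        b = two_pop(sizes=(1000.0 * (1 + 5e-7), 2000.0))
        assert models_equal(a, b, rel_tol=1e-6).equal
        assert not models_equal(a, b, rel_tol=1e-8).equal

    def test_population_count_mismatch_is_single_structural_difference(self, im_model):
        single = d.generic_piecewise_constant([1000.0])
        report = models_equal(im_model, single)
        assert not report.equal
        assert len(report.differences) == 1
        assert report.differences[0][1] == "num_populations"

    def test_reflexive_on_deep_copy_at_zero_tolerance(self, im_model):
        assert models_equal(im_model, copy.deepcopy(im_model), rel_tol=0.0).equal

    def test_symmetric(self, im_model):
        b = d.generic_im(7300, 10000, 9999, 4000, 1e-4, 1e-4)
        assert models_equal(im_model, b).equal == models_equal(b, im_model).equal

    def test_invariant_to_order_preserving_event_reordering(self):
        ev1 = [
            SizeGrowthChange(time=50.0, population=0, new_size=500.0),
            MigrationChange(time=100.0, source=0, dest=1, new_rate=2e-4),
        ]
        ev2 = [
            MigrationChange(time=100.0, source=0, dest=1, new_rate=2e-4),
            SizeGrowthChange(time=50.0, population=0, new_size=500.0),
        ]
        assert models_equal(two_pop(events=ev1), two_pop(events=ev2)).equal


class TestGenericFamilies:
    def test_constant_model_is_degenerate_single_epoch(self):
        canon = canonicalize(d.generic_piecewise_constant([10000.0]))
        assert len(canon.epochs) == 1
        assert canon.epochs[0].start_sizes[0] == 10000.0

    def test_oscillating_six_epoch_model(self):
        sizes = [10000.0, 1000.0, 10000.0, 1000.0, 10000.0, 1000.0]
        times = [100.0, 200.0, 400.0, 800.0, 1600.0]
        canon = canonicalize(d.generic_piecewise_constant(sizes, times))
        assert len(canon.epochs) == 6
        assert [e.start_sizes[0] for e in canon.epochs] == sizes

    @pytest.mark.parametrize(
        "sizes,times",
        [([10000.0, 1000.0], [500.0, 600.0]), ([1000.0], [1.0]), ([1000.0, 1.0], [5.0, 2.0])],
    )
    def test_piecewise_bad_arguments_raise(self, sizes, times):
        with pytest.raises(ValueError):
            d.generic_piecewise_constant(sizes, times)

    def test_im_clean_split_validates_with_one_lineage_move(self):
        m = d.generic_im(7300, 10000, 10000, 4000, 0.0, 0.0)
        assert validate_model(m) == []
        assert len(canonicalize(m).lineage_moves) == 1

    def test_im_migration_only_pre_split(self, im_model):
        canon = canonicalize(im_model)
        assert canon.epochs[0].migration_matrix[0, 1] == 1e-4
        assert np.all(canon.epochs[1].migration_matrix == 0.0)

    @pytest.mark.parametrize("kw", [dict(T_div=0.0), dict(N1=-5.0), dict(N_anc=0.0)])
    def test_im_domain_errors(self, kw):
        args = dict(N_anc=7300.0, N1=1e4, N2=1e4, T_div=4000.0, m12=0.0, m21=0.0)
        args.update(kw)
        with pytest.raises(ValueError):
            d.generic_im(**args)


class TestStateAtTime:
    def test_constant_model_everywhere(self, constant_model):
        assert state_at_time(constant_model, 5000.0).start_sizes[0] == 1000.0

    def test_exponential_growth_closed_form(self):
        alpha = 2e-3
        m = DemographicModel(
            id="Growth",
            populations=[PopulationDef("a")],
            initial_sizes=[10000.0],
            initial_growth_rates=[alpha],
            migration_matrix=[[0.0]],
        )
        t = 700.0
        expected = 10000.0 * math.exp(-alpha * t)
        assert state_at_time(m, t).start_sizes[0] == pytest.approx(expected, rel=1e-12)

    def test_beyond_last_event_uses_last_epoch(self, two_epoch_model):
        assert state_at_time(two_epoch_model, 1e7).start_sizes[0] == 1000.0

    def test_negative_time_rejected(self, constant_model):
        with pytest.raises(ValueError):
            state_at_time(constant_model, -1.0)


@settings(deadline=None, max_examples=30, derandomize=True)
@given(
    sizes=st.lists(st.floats(10.0, 1e6), min_size=1, max_size=5),
    seed=st.integers(0, 10),
)
def test_piecewise_models_canonicalize_idempotently(sizes, seed):
    rng = np.random.default_rng(seed)
    times = sorted(rng.uniform(1.0, 1e4, size=len(sizes) - 1)) if len(sizes) > 1 else []
    if len(set(times)) != len(times):
        return
    m = d.generic_piecewise_constant(sizes, times)
    c1 = canonicalize(m)
    c2 = canonicalize(model_from_canonical(c1))
    assert len(c1.epochs) == len(c2.epochs)
    for e1, e2 in zip(c1.epochs, c2.epochs):
        assert e1.t_start == pytest.approx(e2.t_start)
        np.testing.assert_allclose(e1.start_sizes, e2.start_sizes)
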