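"""Junction fragmentation model, routing, cohort and cascade simulation."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ctctransit.geometry import ChannelSegment, BifurcationDevice, get_device
from ctctransit.transit import (
    ClusterState,
    JunctionModel,
    LysisMode,
    RoutingMode,
    events_to_frame,
    fragment_size_pmf,
    fragments_from_breaks,
    p_at_least_one,
    route_fragments,
    sample_breaks,
    simulate_cascade,
    simulate_cohort,
)


def flat_lookup(p):
    return lambda device, n_cells, treated: p if n_cells >= 2 else 0.0


def make_clusters(sizes, treated=False):
    return [ClusterState(f"c{i}", int(n), treated=treated) for i, n in enumerate(sizes)]


class TestAtLeastOne:
    @pytest.mark.parametrize(
        "p,n,expected",
        [
            (0.51, 1, 0.51),
            (0.51, 2, 0.7599),
            (0.51, 3, 0.882351),
            (0.3, 0, 0.0),
            (1.0, 4, 1.0),
        ],
    )
    def test_closed_form(self, p, n, expected):
        assert p_at_least_one(p, n) == pytest.approx(expected, abs=1e-12)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            p_at_least_one(0.5, -1)
        with pytest.raises(ValueError):
            p_at_least_one(1.5, 2)

    @given(
        p=st.floats(min_value=0.0, max_value=1.0),
        n=st.integers(min_value=0, max_value=20),
    )
    @settings(derandomize=True, max_examples=60)
    def test_monotone_in_both_arguments(self, p, n):
        base = p_at_least_one(p, n)
        assert p_at_least_one(min(p + 0.1, 1.0), n) >= base - 1e-12
        assert p_at_least_one(p, n + 1) >= base - 1e-12


class TestSampleBreaks:
    def test_degenerate_probabilities(self, rng):
        assert sample_breaks(JunctionModel(0.0, 5), rng) == frozenset()
        assert sample_breaks(JunctionModel(1.0, 5), rng) == frozenset({1, 2, 3, 4, 5})

    def test_monte_carlo_matches_closed_form(self, rng):
        # P(>=1 break) for n=3, p=0.51 over 1e5 draws vs 0.882351
        model = JunctionModel(0.51, 3)
        hits = sum(bool(sample_breaks(model, rng)) for _ in range(100_000))
        expected = p_at_least_one(0.51, 3)
        se = np.sqrt(expected * (1 - expected) / 100_000)
        assert abs(hits / 100_000 - expected) < 3 * se

    def test_shared_frailty_preserves_marginal_and_couples(self, rng):
        model = JunctionModel(0.4, 2, correlation_rho=0.99)
        draws = [sample_breaks(model, rng) for _ in range(20_000)]
        rate = np.mean([len(d) for d in draws]) / 2.0
        assert rate == pytest.approx(0.4, abs=0.02)
        # near-perfect coupling: both-or-neither dominates
        both_or_none = np.mean([len(d) in (0, 2) for d in draws])
        assert both_or_none > 0.9


class TestFragments:
    def test_examples(self):
        assert fragments_from_breaks(7, {2}) == [2, 5]
        assert fragments_from_breaks(4, set()) == [4]
        assert fragments_from_breaks(3, {1, 2}) == [1, 1, 1]

    def test_out_of_range_junction(self):
        with pytest.raises(ValueError):
            fragments_from_breaks(4, {4})
        with pytest.raises(ValueError):
            fragments_from_breaks(4, {0})

    @given(
        n=st.integers(min_value=1, max_value=12),
        data=st.data(),
    )
    @settings(derandomize=True, max_examples=60)
    def test_conservation_and_fragment_count(self, n, data):
        breaks = data.draw(st.sets(st.integers(min_value=1, max_value=max(n - 1, 1))))
        breaks = {b for b in breaks if b <= n - 1}
        frags = fragments_from_breaks(n, breaks)
        assert sum(frags) == n
        assert len(frags) == len(breaks) + 1
        assert all(f >= 1 for f in frags)

    @pytest.mark.parametrize("n", [2, 3, 4, 5, 6])
    @pytest.mark.parametrize("p", [0.2, 0.51])
    def test_pmf_matches_composition_oracle(self, n, p):
        # Independent oracle: an ordered composition (a1..ak) of n occurs
        # iff exactly the junctions at the k-1 cut points break, so its
        # probability is p^(k-1) * (1-p)^(n-k).
        def compositions(total):
            if total == 0:
                yield ()
                return
            for first in range(1, total + 1):
                for rest in compositions(total - first):
                    yield (first, *rest)

        oracle = {c: p ** (len(c) - 1) * (1 - p) ** (n - len(c)) for c in compositions(n)}
        pmf = fragment_size_pmf(n, p)
        assert set(pmf) == set(oracle)
        for sizes, prob in oracle.items():
            assert pmf[sizes] == pytest.approx(prob, abs=1e-12)
        assert sum(pmf.values()) == pytest.approx(1.0, abs=1e-12)


def _strongly_unequal_device():
    h = 7.0
    return BifurcationDevice(
        code="UNA_2/9",
        parent=ChannelSegment(9.5, h),
        daughter1=ChannelSegment(2.0, h),
        daughter2=ChannelSegment(9.0, h),
    )


class TestRouting:
    def test_equal_device_single_fragment_is_fair(self, rng):
        dev = get_device("ENA_7/7")
        picks = [
            route_fragments([2], dev, RoutingMode.independent_flow_split, rng)[0]
            for _ in range(10_000)
        ]
        assert np.mean([b == 2 for b in picks]) == pytest.approx(0.5, abs=0.02)

    def test_strongly_unequal_capture(self, rng):
        dev = _strongly_unequal_device()
        assert dev.flow_split() >= 0.9
        for mode in RoutingMode:
            assert route_fragments([1, 1, 2], dev, mode, rng) == [2, 2, 2]

    def test_occlusion_matches_closed_form_for_doublets(self, rng):
        # two fragments in an equal device split with prob kappa/(kappa+1)
        dev = get_device("ENA_7/7")
        kappa = 4.0
        diff = [
            len(set(route_fragments([1, 1], dev, RoutingMode.occlusion_alternating, rng, kappa)))
            == 2
            for _ in range(20_000)
        ]
        expected = kappa / (kappa + 1.0)
        se = np.sqrt(expected * (1 - expected) / 20_000)
        assert np.mean(diff) == pytest.approx(expected, abs=3 * se)

    def test_non_bifurcating_device_rejected(self, rng):
        with pytest.raises(ValueError):
            route_fragments([2], get_device("LINEAR"), "independent_flow_split", rng)


class TestSimulateCohort:
    def test_doublet_frequency_recovers_p(self):
        dev = get_device("ENA_7/7")
        rng = np.random.default_rng(0)
        events = simulate_cohort(make_clusters([2] * 20_000), dev, flat_lookup(0.51), None, rng)
        freq = np.mean([e.dissociated for e in events])
        se = np.sqrt(0.51 * 0.49 / 20_000)
        assert freq == pytest.approx(0.51, abs=3 * se)

    def test_zero_break_probability_keeps_everything_intact(self, rng):
        dev = get_device("ENA_7/7")
        events = simulate_cohort(make_clusters([2, 3, 4, 7]), dev, flat_lookup(0.0), None, rng)
        assert all(not e.dissociated for e in events)
        assert all(e.fragment_sizes == [e.n_cells_in] for e in events)

    def test_cell_conservation_every_event(self, rng):
        dev = get_device("ENA_7/7")
        sizes = rng.integers(2, 9, size=2000)
        events = simulate_cohort(make_clusters(sizes), dev, flat_lookup(0.5), None, rng)
        for ev in events:
            assert sum(ev.fragment_sizes) == ev.n_cells_in
            assert len(ev.fragment_branches) == len(ev.fragment_sizes)

    def test_lysis_remove_mode_accounts_for_every_cell(self, rng):
        dev = get_device("ENA_7/7")
        events = simulate_cohort(
            make_clusters([4] * 500),
            dev,
            flat_lookup(0.5),
            lambda cond: 0.3,
            rng,
            lysis_mode=LysisMode.remove,
        )
        for ev in events:
            assert sum(ev.fragment_sizes) + ev.n_lysed == ev.n_cells_in

    def test_mean_cells_per_unit_decreases(self, rng):
        dev = get_device("ENA_7/7")
        sizes = [2] * 760 + [3] * 160 + [4] * 80
        events = simulate_cohort(make_clusters(sizes), dev, flat_lookup(0.51), None, rng)
        post = [s for e in events for s in e.fragment_sizes]
        assert np.mean(post) < np.mean(sizes)

    def test_dissociation_monotone_in_p_and_size(self, rng):
        dev = get_device("ENA_7/7")

        def freq(size, p, seed):
            r = np.random.default_rng(seed)
            evs = simulate_cohort(make_clusters([size] * 4000), dev, flat_lookup(p), None, r)
            return np.mean([e.dissociated for e in evs])

        assert freq(3, 0.3, 7) < freq(3, 0.6, 7)
        assert freq(2, 0.4, 8) < freq(5, 0.4, 8)

    def test_identical_seed_gives_identical_event_table(self):
        dev = get_device("UNA_5/9")
        out = []
        for _ in range(2):
            rng = np.random.default_rng(99)
            events = simulate_cohort(
                make_clusters([2, 3, 5, 4]), dev, flat_lookup(0.51), lambda c: 0.1, rng
            )
            out.append(events_to_frame(events, seed=99).to_csv(index=False))
        assert out[0] == out[1]


class TestCascade:
    def test_single_level_reduces_to_cohort(self):
        dev = get_device("ENA_7/7")
        clusters = make_clusters([2, 3, 4])
        e1 = simulate_cohort(clusters, dev, flat_lookup(0.4), None, np.random.default_rng(5))
        levels = simulate_cascade(clusters, [dev], flat_lookup(0.4), None, np.random.default_rng(5))
        assert len(levels) == 1
        assert events_to_frame(levels[0]).equals(events_to_frame(e1))

    def test_certain_breakage_singles_after_first_level(self, rng):
        dev = get_device("ENA_7/7")
        levels = simulate_cascade(make_clusters([5, 3]), [dev, dev], flat_lookup(1.0), None, rng)
        assert all(s == 1 for ev in levels[1] for s in ev.fragment_sizes)

    def test_conservation_and_max_size_across_levels(self, rng):
        dev = get_device("ENA_7/7")
        clusters = make_clusters([4] * 300 + [6] * 100)
        total_in = sum(c.n_cells for c in clusters)
        levels = simulate_cascade(clusters, [dev] * 3, flat_lookup(0.51), None, rng)
        prev_max = max(c.n_cells for c in clusters)
        for evs in levels:
            assert sum(s for e in evs for s in e.fragment_sizes) == total_in
            level_max = max(s for e in evs for s in e.fragment_sizes)
            assert level_max <= prev_max
            prev_max = level_max

    def test_repeated_exposure_beats_single_level(self, rng):
        dev = get_device("ENA_7/7")
        clusters = make_clusters([4] * 4000)
        levels = simulate_cascade(clusters, [dev] * 3, flat_lookup(0.51), None, rng)
        diss_level1 = np.mean([e.dissociated for e in levels[0]])
        assert diss_level1 == pytest.approx(p_at_least_one(0.51, 3), abs=0.03)
        # a quadruplet counts as dissociated if any of its lineage broke at
        # any level; repeated exposure can only add events
        broken_roots = {
            e.cluster_id.split("/")[0] for evs in levels for e in evs if e.dissociated
        }
        diss_any_level = len(broken_roots) / len(clusters)
        assert diss_any_level >= diss_level1
        assert diss_any_level >= p_at_least_one(0.51, 3) - 0.03

    def test_empty_device_list_rejected(self, rng):
        with pytest.raises(ValueError):
            simulate_cascade(make_clusters([2]), [], flat_lookup(0.5), None, rng)
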