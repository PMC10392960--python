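import numpy as np
import pandas as pd
import pytest

from conflictcascades import actor_overlap, data_fraction, omega_threshold
from conflictcascades.avalanches import Avalanche, ConflictZone
from conflictcascades.mesoscale import mesoscale_scan


def av(aid, bins, events):
    return Avalanche(avalanche_id=aid, active_bins=set(bins), event_ids=set(events))


def zone(zid, dist, n_events=10):
    return ConflictZone(zone_id=zid, cells=set(), member_avalanches=set(),
                        actor_distribution=dict(dist), n_events=n_events)


def events_named(ids):
    return pd.DataFrame({"event_id": list(ids)})


class TestDataFraction:
    def test_all_events_in_one_avalanche(self):
        avs = [av(0, [(0, 0), (0, 1)], [f"E{i}" for i in range(10)])]
        assert data_fraction(avs, events_named(f"E{i}" for i in range(10))) == 1.0

    def test_half_singletons_gives_half(self):
        avs = [av(0, [(0, 0), (1, 1)], [f"E{i}" for i in range(5)])]
        avs += [av(1 + i, [(2 + i, 0)], [f"S{i}"]) for i in range(5)]
        events = events_named([f"E{i}" for i in range(5)] + [f"S{i}" for i in range(5)])
        assert data_fraction(avs, events) == 0.5

    def test_zero_events_rejected(self):
        with pytest.raises(ValueError):
            data_fraction([], events_named([]))


class TestActorOverlap:
    def test_disjoint_actor_sets_give_exact_zero(self):
        zones = [zone(0, {"a": 1.0}), zone(1, {"b": 0.6, "c": 0.4}),
                 zone(2, {"d": 1.0})]
        assert actor_overlap(zones) == 0.0

    def test_identical_distributions_give_exact_one(self):
        dist = {"a": 0.6, "b": 0.4}
        assert actor_overlap([zone(i, dist) for i in range(3)]) == pytest.approx(1.0)

    def test_worked_two_zone_example(self):
        # zone 0: all events actor a; zone 1: half a, half b (single-actor
        # events). w_01 = 0.5, mean over ordered pairs = 0.75, rescaled to 0.5
        zones = [zone(0, {"a": 1.0}), zone(1, {"a": 0.5, "b": 0.5})]
        assert actor_overlap(zones) == pytest.approx(0.5)

    def test_single_zone_is_maximally_overlapping(self):
        assert actor_overlap([zone(0, {"a": 1.0})]) == 1.0

    def test_invariant_under_actor_relabeling_and_zone_order(self):
        rng = np.random.default_rng(0)
        zones = [zone(i, {f"a{j}": f for j, f in
                          enumerate(rng.dirichlet(np.ones(4)))}) for i in range(5)]
        base = actor_overlap(zones)
        relabeled = [zone(z.zone_id, {k.upper(): v for k, v in
                                      z.actor_distribution.items()}) for z in zones]
        assert actor_overlap(relabeled) == pytest.approx(base)
        assert actor_overlap(zones[::-1]) == pytest.approx(base)

    def test_multi_actor_fractions_tolerated(self):
        # fractions need not sum to 1 when events list several actors
        zones = [zone(0, {"a": 1.0, "b": 1.0}), zone(1, {"a": 1.0, "b": 1.0})]
        assert actor_overlap(zones) == pytest.approx(1.0)

    def test_zero_event_zone_excluded(self):
        zones = [zone(0, {"a": 1.0}), zone(1, {}, n_events=0), zone(2, {"a": 1.0})]
        assert actor_overlap(zones) == pytest.approx(1.0)


class TestOmegaThreshold:
    @pytest.mark.parametrize("omegas, expected", [
        ([0.01, 0.3, 1.0], 0.1),
        ([0.04, 0.1, 0.25], 0.1),
        ([0.2, 0.2, 0.2], 0.2),
    ])
    def test_log_midpoint(self, omegas, expected):
        assert omega_threshold(omegas) == pytest.approx(expected)

    def test_zeros_excluded_from_endpoints(self):
        assert omega_threshold([0.0, 0.01, 1.0]) == pytest.approx(0.1)

    def test_no_positive_values_rejected(self):
        with pytest.raises(ValueError):
            omega_threshold([0.0, 0.0])


class TestMesoscaleScan:
    def test_noise_only_data_has_low_phi_at_small_scales(self, region):
        from conflictcascades import generate_synthetic_events

        events, _ = generate_synthetic_events(
            region, horizon_days=1460, background_rate=3e-7,
            branching_ratio=0.0, seed=2)
        mask, points = mesoscale_scan(events, region, a_list=[8.0],
                                      b_list=[60.0], n_realizations=2,
                                      master_seed=0)
        phis = [p.phi for p in points]
        assert max(phis) < 3 / 4

    def test_scan_records_one_point_per_scale_and_realization(self, region,
                                                              clustered_events):
        events, _ = clustered_events
        mask, points = mesoscale_scan(events, region, a_list=[16.0, 64.0],
                                      b_list=[100.0], n_realizations=2,
                                      master_seed=1)
        assert len(points) == 4
        assert mask.inclusion_probability.shape == (2, 1)
        assert np.all((mask.inclusion_probability >= 0)
                      & (mask.inclusion_probability <= 1))

    def test_oversized_cells_excluded_from_mask(self, region, clustered_events):
        # b beyond the region's capacity -> stage error -> never in the mask
        events, _ = clustered_events
        mask, points = mesoscale_scan(events, region, a_list=[32.0],
                                      b_list=[900.0], n_realizations=1,
                                      master_seed=0)
        assert len(points) == 0
        assert mask.inclusion_probability[0, 0] == 0.0
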