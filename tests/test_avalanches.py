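import networkx as nx
import numpy as np
import pytest

from conflictcascades import build_avalanches, build_conflict_zones
from conflictcascades.activity import ActivityField
from conflictcascades.avalanches import Avalanche, linking_edges
from conflictcascades.network import CausalNetwork
from conflictcascades.tessellation import Tessellation
from oracles import components_brute


def toy_network(n_cells, sig_edges=(), sig_loops=()):
    g = nx.DiGraph()
    g.add_nodes_from(range(n_cells))
    for u, v in sig_edges:
        g.add_edge(u, v, measure="te", value_bits=1.0, exceedance=0.0,
                   significant=True)
    for c in sig_loops:
        g.add_edge(c, c, measure="mi", value_bits=1.0, exceedance=0.0,
                   significant=True)
    return CausalNetwork(graph=g, p_cut=1 / 20, n_shuffles=100, seed=0)


def field_from(values, event_index=None):
    return ActivityField(values=np.asarray(values, dtype=bool), grid=None,
                         event_index=event_index or {})


class TestBuildAvalanches:
    def test_linked_chain_forms_single_avalanche(self):
        # activity (c0,0),(c1,1),(c1,2); edge c0->c1 and self-loop on c1
        vals = np.zeros((2, 3), dtype=bool)
        vals[0, 0] = vals[1, 1] = vals[1, 2] = True
        net = toy_network(2, sig_edges=[(0, 1)], sig_loops=[1])
        avs = build_avalanches(field_from(vals), net)
        assert len(avs) == 1
        assert avs[0].active_bins == {(0, 0), (1, 1), (1, 2)}
        assert avs[0].start_bin == 0 and avs[0].end_bin == 2

    def test_no_significant_structure_gives_singletons(self):
        vals = np.zeros((2, 3), dtype=bool)
        vals[0, 0] = vals[1, 1] = vals[1, 2] = True
        avs = build_avalanches(field_from(vals), toy_network(2))
        assert len(avs) == 3
        assert all(av.is_singleton for av in avs)

    def test_events_inherit_their_bins_avalanche(self):
        vals = np.zeros((2, 2), dtype=bool)
        vals[0, 0] = vals[1, 1] = True
        index = {(0, 0): ["A", "B"], (1, 1): ["C"]}
        net = toy_network(2, sig_edges=[(0, 1)])
        avs = build_avalanches(field_from(vals, index), net)
        assert len(avs) == 1
        assert avs[0].event_ids == {"A", "B", "C"}

    @pytest.mark.parametrize("trial", range(10))
    def test_components_match_union_find_oracle(self, trial):
        rng = np.random.default_rng(trial)
        n_cells = int(rng.integers(3, 11))
        n_bins = int(rng.integers(4, 21))
        vals = rng.random((n_cells, n_bins)) < 0.3
        pairs = [(i, j) for i in range(n_cells) for j in range(n_cells) if i != j]
        sig_edges = [p for p in pairs if rng.random() < 0.2]
        sig_loops = [c for c in range(n_cells) if rng.random() < 0.3]
        net = toy_network(n_cells, sig_edges, sig_loops)
        field = field_from(vals)
        avs = build_avalanches(field, net)
        got = frozenset(frozenset(av.active_bins) for av in avs)
        nodes = [(int(c), int(t)) for c, t in zip(*np.nonzero(vals))]
        expected = components_brute(nodes, linking_edges(field, net))
        assert got == expected

    def test_every_active_bin_in_exactly_one_avalanche(self):
        rng = np.random.default_rng(5)
        vals = rng.random((6, 15)) < 0.4
        net = toy_network(6, sig_edges=[(0, 1), (1, 2), (3, 4)], sig_loops=[2, 5])
        avs = build_avalanches(field_from(vals), net)
        seen = [p for av in avs for p in av.active_bins]
        assert len(seen) == len(set(seen)) == int(vals.sum())

    def test_adding_edge_never_increases_avalanche_count(self):
        rng = np.random.default_rng(8)
        vals = rng.random((5, 12)) < 0.35
        edges = [(0, 1), (1, 2), (2, 3), (3, 4), (4, 0), (1, 0)]
        counts = []
        for k in range(len(edges) + 1):
            net = toy_network(5, sig_edges=edges[:k])
            counts.append(len(build_avalanches(field_from(vals), net)))
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestConflictZones:
    def make_tess(self, n):
        return Tessellation(centers_lon=np.arange(n, dtype=float),
                            centers_lat=np.zeros(n), region=None,
                            scale_b=100.0, seed=0,
                            adjacency=[set() for _ in range(n)])

    def av(self, aid, bins, events=()):
        return Avalanche(avalanche_id=aid, active_bins=set(bins),
                         event_ids=set(events))

    def test_intersecting_avalanches_merge(self):
        avs = [self.av(0, [(0, 0), (1, 1)]), self.av(1, [(1, 3), (2, 4)])]
        zones = build_conflict_zones(avs, self.make_tess(3))
        assert len(zones) == 1
        assert zones[0].cells == {0, 1, 2}

    def test_disjoint_avalanches_stay_separate(self):
        avs = [self.av(0, [(0, 0)]), self.av(1, [(1, 1)]), self.av(2, [(2, 0)])]
        zones = build_conflict_zones(avs, self.make_tess(3))
        assert len(zones) == 3

    def test_merge_order_independent(self):
        rng = np.random.default_rng(1)
        avs = [self.av(i, [(int(c), int(t)) for c, t in
                           zip(rng.integers(0, 8, 3), rng.integers(0, 10, 3))])
               for i in range(12)]
        base = build_conflict_zones(avs, self.make_tess(8))
        base_sets = sorted(sorted(z.cells) for z in base)
        for _ in range(5):
            perm = list(rng.permutation(len(avs)))
            zones = build_conflict_zones([avs[i] for i in perm], self.make_tess(8))
            assert sorted(sorted(z.cells) for z in zones) == base_sets

    def test_transitive_merging_to_fixed_point(self):
        avs = [self.av(0, [(0, 0)]), self.av(1, [(0, 1), (1, 1)]),
               self.av(2, [(1, 2), (2, 2)]), self.av(3, [(3, 0)])]
        zones = build_conflict_zones(avs, self.make_tess(4))
        assert len(zones) == 2
        assert {frozenset(z.cells) for z in zones} == {frozenset({0, 1, 2}),
                                                       frozenset({3})}
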