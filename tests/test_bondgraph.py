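"""Bond perception, fragments, canonical signatures, event detection."""

import itertools

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nanoreactor.bondgraph import (BondGraph, canonical_signature,
                                   covalent_radius, detect_events, fragments,
                                   hill_formula, perceive_graph)
from nanoreactor.packing import (BondEdit, ScriptedEventSpec,
                                 make_scripted_trajectory,
                                 random_scripted_specs,
                                 revert_within_window_spec, score_detection)


class TestPerception:
    def test_cc_single_bond_distance(self):
        # 1.54 Å ≤ 1.3 · (0.76 + 0.76) = 1.976 Å with the shipped radii
        assert covalent_radius("C") == 0.76
        g = perceive_graph(np.array([[0, 0, 0], [0, 0, 1.54]]), ("C", "C"))
        assert (0, 1) in g.edges

    def test_distant_atoms_never_bond(self):
        g = perceive_graph(np.array([[0, 0, 0], [0, 0, 10.0]]), ("C", "C"),
                           form_factor=2.0, break_factor=2.0)
        assert not g.edges

    def test_hysteresis_keeps_previous_bond(self):
        els = ("C", "C")
        rsum = 2 * 0.76
        mid = 1.4 * rsum   # between form (1.3) and break (1.6) thresholds
        pos = np.array([[0, 0, 0], [0, 0, mid]])
        bonded_prev = BondGraph(2, frozenset({(0, 1)}), els)
        empty_prev = BondGraph(2, frozenset(), els)
        g1 = perceive_graph(pos, els, 1.3, 1.6, previous_graph=bonded_prev)
        g2 = perceive_graph(pos, els, 1.3, 1.6, previous_graph=empty_prev)
        assert (0, 1) in g1.edges
        assert (0, 1) not in g2.edges

    def test_unknown_element_raises(self):
        with pytest.raises(KeyError, match="covalent-radius"):
            perceive_graph(np.zeros((1, 3)), ("Xx",))

    def test_factor_bounds_enforced(self):
        with pytest.raises(ValueError):
            perceive_graph(np.zeros((2, 3)), ("C", "C"), form_factor=0.5)


class TestFragments:
    def test_edgeless_graph(self):
        g = BondGraph(3, frozenset(), ("H", "C", "N"))
        frs = fragments(g)
        assert len(frs) == 3
        assert [f.formula for f in frs] == ["C", "H", "N"]

    def test_pyridine_plus_cn(self):
        # pyridine ring C5H5N (atoms 0-10) and a separate CN (11, 12)
        ring = [(0, 1), (1, 2), (2, 3), (3, 4), (4, 5), (0, 5)]  # C5N ring
        hs = [(0, 6), (1, 7), (2, 8), (3, 9), (4, 10)]
        els = ("C", "C", "C", "C", "C", "N", "H", "H", "H", "H", "H", "C", "N")
        g = BondGraph(13, frozenset(ring + hs + [(11, 12)]), els)
        frs = fragments(g)
        assert [f.formula for f in frs] == ["C5H5N", "CN"]

    def test_fully_connected_single_fragment(self):
        edges = frozenset((i, j) for i in range(4) for j in range(i + 1, 4))
        g = BondGraph(4, edges, ("C", "C", "H", "H"))
        assert len(fragments(g)) == 1

    def test_hill_order(self):
        assert hill_formula(["H", "C", "N", "H", "C"]) == "C2H2N"
        assert hill_formula(["N", "H", "H"]) == "H2N"   # no carbon: alphabetical


def permute_graph(g: BondGraph, perm):
    inv = {old: new for new, old in enumerate(perm)}
    edges = frozenset((min(inv[i], inv[j]), max(inv[i], inv[j])) for i, j in g.edges)
    els = tuple(g.elements[p] for p in perm)
    return BondGraph(g.n_atoms, edges, els)


class TestCanonicalSignature:
    def test_single_atom_form(self):
        assert canonical_signature(BondGraph(1, frozenset(), ("N",))) == "N"

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_permutation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 7))
        els = tuple(rng.choice(["C", "H", "N"], size=n))
        # random connected labeled graph: spanning tree + extra edges
        edges = set()
        for i in range(1, n):
            j = int(rng.integers(0, i))
            edges.add((j, i))
        for _ in range(int(rng.integers(0, n))):
            i, j = sorted(rng.choice(n, size=2, replace=False).tolist())
            edges.add((i, j))
        g = BondGraph(n, frozenset(edges), els)
        sig = canonical_signature(g)
        perm = rng.permutation(n).tolist()
        assert canonical_signature(permute_graph(g, perm)) == sig

    def test_linear_vs_branched_isomers(self):
        els = ("H", "C", "C", "C", "N")
        linear = BondGraph(5, frozenset([(0, 1), (1, 2), (2, 3), (3, 4)]), els)
        branched = BondGraph(5, frozenset([(0, 1), (1, 2), (1, 3), (3, 4)]), els)
        assert canonical_signature(linear) != canonical_signature(branched)

    def test_matches_exhaustive_isomorphism_oracle(self):
        """On every connected ≤5-node C/H-labeled graph over a fixed label
        multiset, signatures agree exactly with networkx isomorphism."""
        labels = ("C", "C", "H", "H", "N")
        n = len(labels)
        all_pairs = list(itertools.combinations(range(n), 2))
        graphs = []
        for bits in range(1 << len(all_pairs)):
            edges = frozenset(p for k, p in enumerate(all_pairs) if bits >> k & 1)
            g = BondGraph(n, edges, labels)
            if len(g.connected_components()) == 1:
                graphs.append(g)
        # sample to keep runtime modest but deterministic
        rng = np.random.default_rng(0)
        sample = [graphs[i] for i in rng.choice(len(graphs), size=120, replace=False)]

        def to_nx(g):
            G = nx.Graph()
            for i, e in enumerate(g.elements):
                G.add_node(i, element=e)
            G.add_edges_from(g.edges)
            return G

        sigs = [canonical_signature(g) for g in sample]
        nm = nx.algorithms.isomorphism.categorical_node_match("element", None)
        for a in range(len(sample)):
            for b in range(a + 1, min(a + 25, len(sample))):
                iso = nx.is_isomorphic(to_nx(sample[a]), to_nx(sample[b]), node_match=nm)
                assert iso == (sigs[a] == sigs[b]), (sample[a], sample[b])

    def test_disconnected_input_rejected(self):
        g = BondGraph(2, frozenset(), ("C", "C"))
        with pytest.raises(ValueError, match="connected"):
            canonical_signature(g)


class TestDetectEvents:
    def test_single_dissociation_one_event(self):
        from nanoreactor.packing import _three_diatomics
        spec = ScriptedEventSpec(
            base_system=_three_diatomics(),
            bond_edits=[BondEdit(frame_index=50, atom_i=2, atom_j=3, kind="break")],
            n_frames=120, jitter_sigma=0.01, seed=1)
        traj = make_scripted_trajectory(spec)
        events = detect_events(traj, persistence_frames=25)
        assert len(events) == 1
        assert len(events[0].product_fragments) == 2
        assert {f.formula for f in events[0].product_fragments} == {"C", "N"}

    def test_fragment_count_increases_after_break(self):
        from nanoreactor.packing import _three_diatomics
        spec = ScriptedEventSpec(
            base_system=_three_diatomics(),
            bond_edits=[BondEdit(frame_index=50, atom_i=0, atom_j=1, kind="break")],
            n_frames=100, jitter_sigma=0.0, seed=0)
        traj = make_scripted_trajectory(spec)
        n_frags = [len(fragments(perceive_graph(f, traj.elements)))
                   for f in traj.frames]
        assert all(n == 3 for n in n_frags[:50])
        assert all(n == 4 for n in n_frags[56:])

    def test_revert_within_window_suppressed(self):
        traj = make_scripted_trajectory(revert_within_window_spec(5))
        assert detect_events(traj, persistence_frames=25) == []

    def test_consecutive_events_chain(self):
        from nanoreactor.packing import _three_diatomics
        spec = ScriptedEventSpec(
            base_system=_three_diatomics(),
            bond_edits=[BondEdit(frame_index=30, atom_i=0, atom_j=1, kind="break"),
                        BondEdit(frame_index=100, atom_i=2, atom_j=3, kind="break")],
            n_frames=180, jitter_sigma=0.01, seed=2)
        traj = make_scripted_trajectory(spec)
        events = detect_events(traj, persistence_frames=25)
        assert len(events) == 2
        assert events[0].onset_frame < events[1].onset_frame

    def test_atom_conservation_every_event(self):
        for spec, _ in random_scripted_specs(10, seed=7):
            traj = make_scripted_trajectory(spec)
            for ev in detect_events(traj, persistence_frames=25):
                r = sorted(a for f in ev.reactant_fragments for a in f.atoms)
                p = sorted(a for f in ev.product_fragments for a in f.atoms)
                assert r == p

    def test_perfect_precision_recall_on_random_suite(self):
        tp = fp = fn = 0
        for spec, expected in random_scripted_specs(50, seed=42):
            traj = make_scripted_trajectory(spec)
            events = detect_events(traj, persistence_frames=25)
            a, b, c = score_detection([e.onset_frame for e in events], expected)
            tp, fp, fn = tp + a, fp + b, fn + c
        assert fp == 0 and fn == 0 and tp > 0

    def test_determinism(self):
        spec, _ = random_scripted_specs(1, seed=9)[0]
        traj = make_scripted_trajectory(spec)
        e1 = detect_events(traj, persistence_frames=25)
        e2 = detect_events(traj, persistence_frames=25)
        assert [e.reaction_signature for e in e1] == [e.reaction_signature for e in e2]

    def test_raising_break_factor_never_adds_events(self):
        spec, _ = random_scripted_specs(3, seed=13)[2]
        traj = make_scripted_trajectory(spec)
        counts = [len(detect_events(traj, persistence_frames=25,
                                    form_factor=1.3, break_factor=bf))
                  for bf in (1.3, 1.45, 1.6, 1.8)]
        assert all(c1 >= c2 for c1, c2 in zip(counts, counts[1:]))

    def test_short_trajectory_warns_and_returns_empty(self):
        from nanoreactor.packing import _three_diatomics
        spec = ScriptedEventSpec(base_system=_three_diatomics(), bond_edits=[],
                                 n_frames=10, seed=0)
        traj = make_scripted_trajectory(spec)
        with pytest.warns(UserWarning, match="persistence"):
            assert detect_events(traj, persistence_frames=25) == []
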