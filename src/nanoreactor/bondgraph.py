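"""Bond perception, fragment analysis and reaction-event detection.

A pair of atoms is bonded when its distance is at most ``form_factor``
times the sum of the atoms' covalent radii (Cordero et al. 2008 table,
shipped as package data).  With ``break_factor > form_factor`` the
criterion is hysteretic: an existing bond survives until the distance
exceeds the larger break threshold, which suppresses vibrational
flicker.  A reaction event is a *lasting* change of the molecular graph:
the perceived graph must differ from the last settled graph and then
persist unchanged for at least ``persistence_frames`` snapshots.

Fragment identity uses an exact canonical form of the element-labeled
connectivity graph: iterative neighborhood (color) refinement, followed
by individualization-refinement when the refined coloring is not yet
discrete.  Two fragments get the same signature iff their labeled graphs
are isomorphic.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .system import Trajectory, _load_json_data

#: single-bond covalent radii, Å
COVALENT_RADII: dict[str, float] = _load_json_data("covalent_radii.json")

DEFAULT_FORM_FACTOR = 1.3
DEFAULT_BREAK_FACTOR = 1.3
DEFAULT_PERSISTENCE_FRAMES = 25


def covalent_radius(symbol: str) -> float:
    try:
        return COVALENT_RADII[symbol]
    except KeyError:
        raise KeyError(f"element {symbol!r} missing from the covalent-radius table") from None


@dataclass(frozen=True)
class BondGraph:
    """Undirected element-labeled connectivity graph over atom indices."""

    n_atoms: int
    edges: frozenset  # of (i, j) tuples with i < j
    elements: tuple[str, ...]

    def __post_init__(self) -> None:
        for (i, j) in self.edges:
            if i == j:
                raise ValueError("self-edges are not allowed")
            if not (0 <= i < j < self.n_atoms):
                raise ValueError(f"edge ({i}, {j}) out of range or unordered")

    def neighbors(self) -> list[list[int]]:
        nbr: list[list[int]] = [[] for _ in range(self.n_atoms)]
        for (i, j) in self.edges:
            nbr[i].append(j)
            nbr[j].append(i)
        return nbr

    def connected_components(self) -> list[tuple[int, ...]]:
        nbr = self.neighbors()
        seen = [False] * self.n_atoms
        comps = []
        for start in range(self.n_atoms):
            if seen[start]:
                continue
            stack, comp = [start], []
            seen[start] = True
            while stack:
                u = stack.pop()
                comp.append(u)
                for w in nbr[u]:
                    if not seen[w]:
                        seen[w] = True
                        stack.append(w)
            comps.append(tuple(sorted(comp)))
        return comps

    def subgraph(self, atoms: Sequence[int]) -> "BondGraph":
        atoms = tuple(atoms)
        index = {a: k for k, a in enumerate(atoms)}
        edges = frozenset(
            (min(index[i], index[j]), max(index[i], index[j]))
            for (i, j) in self.edges if i in index and j in index)
        return BondGraph(len(atoms), edges, tuple(self.elements[a] for a in atoms))


def hill_formula(elements: Sequence[str]) -> str:
    """Molecular formula in Hill order (C, H, then alphabetical)."""
    counts = Counter(elements)
    parts: list[str] = []
    order: list[str] = []
    if "C" in counts:
        order = ["C"] + (["H"] if "H" in counts else [])
        order += sorted(e for e in counts if e not in ("C", "H"))
    else:
        order = sorted(counts)
    for e in order:
        n = counts[e]
        parts.append(e if n == 1 else f"{e}{n}")
    return "".join(parts)


def perceive_graph(frame, elements: Sequence[str],
                   form_factor: float = DEFAULT_FORM_FACTOR,
                   break_factor: float = DEFAULT_BREAK_FACTOR,
                   previous_graph: Optional[BondGraph] = None) -> BondGraph:
    """Perceive connectivity from interatomic distances.

    ``frame`` may be a Frame or a raw (n, 3) position array.  Pair (i, j)
    bonds when d ≤ form_factor·(r_cov,i + r_cov,j); with hysteresis a
    previously bonded pair persists until d > break_factor·(...).
    """
    if not (1.0 <= form_factor <= break_factor):
        raise ValueError("require 1.0 <= form_factor <= break_factor")
    positions = getattr(frame, "positions", frame)
    positions = np.asarray(positions, dtype=float)
    elements = tuple(elements)
    radii = np.array([covalent_radius(e) for e in elements])
    rsum = radii[:, None] + radii[None, :]
    d = squareform(pdist(positions))
    bonded = d <= form_factor * rsum
    if previous_graph is not None and break_factor > form_factor:
        for (i, j) in previous_graph.edges:
            if d[i, j] <= break_factor * rsum[i, j]:
                bonded[i, j] = bonded[j, i] = True
    n = len(elements)
    edges = frozenset((i, j) for i in range(n) for j in range(i + 1, n) if bonded[i, j])
    return BondGraph(n, edges, elements)


@dataclass(frozen=True)
class Fragment:
    """A connected component: atom indices (into the parent system),
    Hill formula, canonical signature, and optionally its geometry."""

    atoms: tuple[int, ...]
    formula: str
    signature: str
    elements: tuple[str, ...] = ()
    positions: Optional[np.ndarray] = None


def fragments(graph: BondGraph, positions: Optional[np.ndarray] = None) -> list[Fragment]:
    """Connected components, sorted by (size descending, formula)."""
    out = []
    for comp in graph.connected_components():
        sub = graph.subgraph(comp)
        out.append(Fragment(
            atoms=comp,
            formula=hill_formula(sub.elements),
            signature=canonical_signature(sub),
            elements=sub.elements,
            positions=None if positions is None else np.asarray(positions)[list(comp)].copy(),
        ))
    return sorted(out, key=lambda f: (-len(f.atoms), f.formula, f.signature))


# ---------------------------------------------------------------------------
# canonical signatures

def _refine_colors(labels: list[str], nbr: list[list[int]]) -> list[str]:
    n = len(labels)
    while True:
        keys = [f"{labels[i]}|{','.join(sorted(labels[j] for j in nbr[i]))}"
                for i in range(n)]
        ranks = {k: r for r, k in enumerate(sorted(set(keys)))}
        new = [f"{labels[i].split('~')[0]}~{ranks[keys[i]]}" for i in range(n)]
        if len(set(new)) == len(set(labels)):
            return new
        labels = new


def _canonical_string(graph: BondGraph, labels: list[str]) -> str:
    order = sorted(range(graph.n_atoms), key=lambda i: labels[i])
    pos = {a: k for k, a in enumerate(order)}
    elems = "".join(graph.elements[a] for a in order)
    edges = sorted((min(pos[i], pos[j]), max(pos[i], pos[j])) for (i, j) in graph.edges)
    estr = ";".join(f"{i}-{j}" for i, j in edges)
    return f"{elems}:{estr}"


def _canonize(graph: BondGraph, labels: list[str], nbr: list[list[int]]) -> str:
    labels = _refine_colors(labels, nbr)
    counts = Counter(labels)
    non_singleton = sorted(c for c in counts if counts[c] > 1)
    if not non_singleton:
        return _canonical_string(graph, labels)
    target = non_singleton[0]
    best = None
    for i in range(graph.n_atoms):
        if labels[i] != target:
            continue
        branched = list(labels)
        branched[i] = target + "*"
        s = _canonize(graph, branched, nbr)
        if best is None or s < best:
            best = s
    return best


def canonical_signature(fragment_graph: BondGraph) -> str:
    """Canonical string of a connected element-labeled graph.

    Invariant under atom re-indexing; equal iff isomorphic (exact, via
    refinement plus individualization).  A single atom's signature is its
    element symbol.
    """
    if len(fragment_graph.connected_components()) != 1:
        raise ValueError("canonical_signature requires a connected fragment")
    if fragment_graph.n_atoms == 1:
        return fragment_graph.elements[0]
    nbr = fragment_graph.neighbors()
    canon = _canonize(fragment_graph, list(fragment_graph.elements), nbr)
    return f"{hill_formula(fragment_graph.elements)}[{canon}]"


# ---------------------------------------------------------------------------
# reaction events

@dataclass
class ReactionEvent:
    """A lasting connectivity change between two settled molecular graphs."""

    onset_frame: int
    settled_frame: int
    reactant_fragments: list[Fragment]
    product_fragments: list[Fragment]
    reaction_signature: str = ""

    def __post_init__(self) -> None:
        ra = sorted(a for f in self.reactant_fragments for a in f.atoms)
        pa = sorted(a for f in self.product_fragments for a in f.atoms)
        if ra != pa:
            raise ValueError("reactant and product fragments must partition the same atoms")
        if not self.reaction_signature:
            lhs = "+".join(sorted(f.signature for f in self.reactant_fragments))
            rhs = "+".join(sorted(f.signature for f in self.product_fragments))
            self.reaction_signature = f"{lhs}>>{rhs}"

    @property
    def atoms(self) -> tuple[int, ...]:
        return tuple(sorted(a for f in self.reactant_fragments for a in f.atoms))


def _event_atom_closure(old: BondGraph, new: BondGraph) -> tuple[int, ...]:
    """Atoms participating in the change: closure of the differing edges'
    endpoints under both graphs' component partitions."""
    changed = old.edges.symmetric_difference(new.edges)
    atoms = {a for e in changed for a in e}
    comps = old.connected_components() + new.connected_components()
    while True:
        grown = set(atoms)
        for comp in comps:
            if grown.intersection(comp):
                grown.update(comp)
        if grown == atoms:
            return tuple(sorted(atoms))
        atoms = grown


def _restricted_fragments(graph: BondGraph, atoms: tuple[int, ...],
                          positions: Optional[np.ndarray]) -> list[Fragment]:
    frs = []
    for f in fragments(graph, positions):
        if set(f.atoms).issubset(atoms):
            frs.append(f)
    return frs


def detect_events(trajectory: Trajectory,
                  persistence_frames: int = DEFAULT_PERSISTENCE_FRAMES,
                  form_factor: float = DEFAULT_FORM_FACTOR,
                  break_factor: float = DEFAULT_BREAK_FACTOR) -> list[ReactionEvent]:
    """Detect lasting connectivity changes in a trajectory.

    The graph of frame 0 is the initial settled state.  When the perceived
    graph departs from the settled graph and one *new* graph then persists
    unchanged for ``persistence_frames`` consecutive frames, an event is
    emitted (onset = first differing frame, settled = last frame of the
    persistence window) and the new graph becomes the settled state, so
    consecutive events chain.  Changes that revert within the window are
    suppressed, as are identity exchanges whose fragment signature
    multiset is unchanged (the graph still advances).

    Fragment geometries are attached from the frame just before onset
    (reactants) and the settled frame (products).
    """
    if persistence_frames < 1:
        raise ValueError("persistence_frames must be >= 1")
    n_frames = len(trajectory.frames)
    if n_frames <= persistence_frames:
        warnings.warn("trajectory shorter than the persistence window; no events detectable")
        return []
    graphs: list[BondGraph] = []
    prev = None
    for f in trajectory.frames:
        g = perceive_graph(f, trajectory.elements, form_factor, break_factor, prev)
        graphs.append(g)
        prev = g

    events: list[ReactionEvent] = []
    settled = graphs[0]
    settled_at = 0           # frame index where the settled graph last held
    onset: Optional[int] = None
    run_graph: Optional[BondGraph] = None
    run_start = 0
    f = 1
    while f < n_frames:
        g = graphs[f]
        if g.edges == settled.edges:
            onset = None
            run_graph = None
            settled_at = f
        else:
            if onset is None:
                onset = f
            if run_graph is None or g.edges != run_graph.edges:
                run_graph = g
                run_start = f
            if f - run_start + 1 >= persistence_frames:
                atoms = _event_atom_closure(settled, run_graph)
                if atoms:
                    react = _restricted_fragments(
                        settled, atoms, trajectory.frames[max(onset - 1, settled_at)].positions)
                    prod = _restricted_fragments(run_graph, atoms, trajectory.frames[f].positions)
                    same = (sorted(x.signature for x in react)
                            == sorted(x.signature for x in prod))
                    if not same:
                        events.append(ReactionEvent(
                            onset_frame=onset, settled_frame=f,
                            reactant_fragments=react, product_fragments=prod))
                settled = run_graph
                settled_at = f
                onset = None
                run_graph = None
        f += 1
    return events


def event_to_dict(event: ReactionEvent) -> dict:
    """JSON-serializable record of an event."""
    def frag(f: Fragment) -> dict:
        return {"atoms": list(f.atoms), "formula": f.formula, "signature": f.signature}
    return {
        "onset_frame": event.onset_frame,
        "settled_frame": event.settled_frame,
        "reaction_signature": event.reaction_signature,
        "reactants": [frag(f) for f in event.reactant_fragments],
        "products": [frag(f) for f in event.product_fragments],
    }
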