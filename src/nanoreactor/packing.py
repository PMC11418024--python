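"""Initial-configuration packing and scripted synthetic trajectories.

``pack_sphere`` plays the role of Packmol at desk scale: molecules are
placed as rigid bodies (uniform random rotation, uniform-in-ball
translation) by rejection sampling until every atom lies inside the
requested sphere and all inter-molecular contacts respect the minimum
separation.

``make_scripted_trajectory`` manufactures trajectories with *planted*
bond edits — pairs driven smoothly between clearly-bonded (0.9 × the
covalent-radius sum) and clearly-separated (3.0 ×) distances — so the
event-detection stage can be scored against a known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .bondgraph import covalent_radius
from .system import AtomicSystem, Frame, Trajectory

PACK_RETRY_BUDGET = 10_000
BONDED_FACTOR = 0.9
SEPARATED_FACTOR = 3.0
TRANSITION_FRAMES = 5


class PackingError(RuntimeError):
    """No feasible placement found within the retry budget."""


@dataclass
class PackSpec:
    templates: list[tuple[AtomicSystem, int]]
    sphere_radius: float
    min_separation: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sphere_radius <= 0 or self.min_separation <= 0:
            raise ValueError("sphere_radius and min_separation must be positive")
        for _, count in self.templates:
            if count < 1:
                raise ValueError("template counts must be >= 1")


def pack_sphere(spec: PackSpec) -> AtomicSystem:
    """Pack rigid copies of the template molecules into a sphere.

    Deterministic per seed.  Raises :class:`PackingError` (reporting the
    attempted density) when the retry budget is exhausted.
    """
    rng = np.random.default_rng(spec.seed)
    placed_positions: list[np.ndarray] = []
    elements: list[str] = []
    masses: list[float] = []
    n_atoms_total = sum(t.n_atoms * c for t, c in spec.templates)
    for template, count in spec.templates:
        centered = template.positions - template.positions.mean(axis=0)
        extent = float(np.max(np.linalg.norm(centered, axis=1)))
        for _ in range(count):
            for _attempt in range(PACK_RETRY_BUDGET):
                rot = Rotation.random(random_state=rng)
                body = rot.apply(centered) if template.n_atoms > 1 else centered.copy()
                direction = rng.normal(size=3)
                direction /= np.linalg.norm(direction)
                max_r = max(spec.sphere_radius - extent, 0.0)
                radius = max_r * rng.random() ** (1.0 / 3.0)
                candidate = body + direction * radius
                if np.any(np.linalg.norm(candidate, axis=1) > spec.sphere_radius):
                    continue
                ok = True
                for other in placed_positions:
                    d = np.linalg.norm(candidate[:, None, :] - other[None, :, :], axis=-1)
                    if d.min() < spec.min_separation:
                        ok = False
                        break
                if ok:
                    placed_positions.append(candidate)
                    elements.extend(template.elements)
                    masses.extend(template.masses)
                    break
            else:
                volume = 4.0 / 3.0 * np.pi * spec.sphere_radius**3
                raise PackingError(
                    f"could not place a copy of {template.label or 'molecule'} "
                    f"after {PACK_RETRY_BUDGET} attempts "
                    f"(attempted density {n_atoms_total / volume:.3g} atoms/Å³)")
    return AtomicSystem(tuple(elements), np.array(masses),
                        np.vstack(placed_positions), label="packed")


@dataclass
class BondEdit:
    frame_index: int
    atom_i: int
    atom_j: int
    kind: Literal["make", "break"]

    def __post_init__(self) -> None:
        if self.atom_i == self.atom_j:
            raise ValueError("bond edit needs two distinct atoms")
        if self.kind not in ("make", "break"):
            raise ValueError(f"unknown edit kind {self.kind!r}")
        if self.atom_i > self.atom_j:
            self.atom_i, self.atom_j = self.atom_j, self.atom_i


@dataclass
class ScriptedEventSpec:
    base_system: AtomicSystem
    bond_edits: list[BondEdit]
    n_frames: int
    jitter_sigma: float = 0.0
    seed: int = 0
    dt: float = 0.5   # fs between frames

    def __post_init__(self) -> None:
        n = self.base_system.n_atoms
        for e in self.bond_edits:
            if not (0 <= e.frame_index < self.n_frames):
                raise ValueError(f"edit frame {e.frame_index} outside 0..{self.n_frames - 1}")
            if not (0 <= e.atom_i < n and 0 <= e.atom_j < n):
                raise ValueError("edit atom index out of range")
        seen: dict[tuple[int, int], int] = {}
        for e in sorted(self.bond_edits, key=lambda e: e.frame_index):
            key = (e.atom_i, e.atom_j)
            # a follow-up edit may begin at the last transition frame of the
            # previous one (fast revert fixtures), but not earlier
            if key in seen and e.frame_index - seen[key] < TRANSITION_FRAMES - 1:
                raise ValueError(
                    f"conflicting edits on pair {key} within the transition window")
            seen[key] = e.frame_index


def _scripted_graph_edges(spec: ScriptedEventSpec, positions: np.ndarray) -> set:
    """Initial connectivity implied by the base geometry (bonded when the
    pair sits below the bonded distance times a small margin)."""
    from .bondgraph import perceive_graph
    g = perceive_graph(positions, spec.base_system.elements)
    return set(g.edges)


def make_scripted_trajectory(spec: ScriptedEventSpec) -> Trajectory:
    """Build a trajectory realizing the scripted connectivity timeline.

    Each edit moves the group of atoms on the far side of the edited pair
    rigidly along the pair axis, ramping the pair distance between
    0.9·Σr_cov (bonded) and 3.0·Σr_cov (separated) over
    ``TRANSITION_FRAMES`` frames starting at the edit frame.  Gaussian
    jitter of ``jitter_sigma`` Å (σ ≤ 0.02 never crosses the perception
    thresholds) is added on top.
    """
    rng = np.random.default_rng(spec.seed)
    base = spec.base_system.positions.copy()
    elements = spec.base_system.elements
    edges = _scripted_graph_edges(spec, base)
    edits = sorted(spec.bond_edits, key=lambda e: e.frame_index)

    def moving_group(edge_set: set, i: int, j: int) -> list[int]:
        """Atoms connected to j when the i-j edge is ignored."""
        nbr: dict[int, list[int]] = {}
        for (a, b) in edge_set:
            if (a, b) == (i, j):
                continue
            nbr.setdefault(a, []).append(b)
            nbr.setdefault(b, []).append(a)
        seen = {j}
        stack = [j]
        while stack:
            u = stack.pop()
            for w in nbr.get(u, []):
                if w not in seen and w != i:
                    seen.add(w)
                    stack.append(w)
        return sorted(seen)

    n = spec.base_system.n_atoms
    frames: list[Frame] = []
    pos = base.copy()
    # per-edit state: (edit, group, axis unit vector, start distance, end distance)
    plans = []
    sim_edges = set(edges)
    for e in edits:
        rsum = covalent_radius(elements[e.atom_i]) + covalent_radius(elements[e.atom_j])
        plans.append({"edit": e, "rsum": rsum})

    applied_shift = np.zeros_like(base)
    for f in range(spec.n_frames):
        for plan in plans:
            e = plan["edit"]
            if not (e.frame_index <= f < e.frame_index + TRANSITION_FRAMES):
                continue
            if "group" not in plan:
                plan["group"] = moving_group(sim_edges, e.atom_i, e.atom_j)
                vec = (base[e.atom_j] + applied_shift[e.atom_j]
                       - base[e.atom_i] - applied_shift[e.atom_i])
                r = np.linalg.norm(vec)
                plan["axis"] = vec / r
                plan["r0"] = r
                plan["r1"] = (SEPARATED_FACTOR if e.kind == "break" else BONDED_FACTOR) * plan["rsum"]
                if e.kind == "make":
                    sim_edges.add((e.atom_i, e.atom_j))
                else:
                    sim_edges.discard((e.atom_i, e.atom_j))
            frac = (f - e.frame_index + 1) / TRANSITION_FRAMES
            target = plan["r0"] + (plan["r1"] - plan["r0"]) * frac
            vec = (base[e.atom_j] + applied_shift[e.atom_j]
                   - base[e.atom_i] - applied_shift[e.atom_i])
            r = np.linalg.norm(vec)
            delta = (target - r) * plan["axis"]
            for a in plan["group"]:
                applied_shift[a] += delta
        pos = base + applied_shift
        noise = rng.normal(scale=spec.jitter_sigma, size=(n, 3)) if spec.jitter_sigma > 0 else 0.0
        frames.append(Frame(time=f * spec.dt, positions=pos + noise))
    return Trajectory(elements, spec.base_system.masses.copy(), frames)


# ---------------------------------------------------------------------------
# randomized ground-truth suites for scoring the event detector

def _three_diatomics() -> AtomicSystem:
    """Three well-separated diatomics (H2, CN, NH), bonds along z."""
    pos = np.array([
        [0.0, 0.0, 0.0], [0.0, 0.0, 0.741],        # H-H
        [8.0, 0.0, 0.0], [8.0, 0.0, 1.17],         # C-N
        [16.0, 0.0, 0.0], [16.0, 0.0, 1.01],       # N-H
    ])
    return AtomicSystem.from_elements(["H", "H", "C", "N", "N", "H"], pos)


def random_scripted_specs(n_scripts: int, seed: int,
                          persistence_frames: int = 25,
                          jitter_sigma: float = 0.01
                          ) -> list[tuple[ScriptedEventSpec, list[int]]]:
    """Seeded suite of scripted trajectories with known planted events.

    Each script plants 1–3 bond edits (breaks, and re-makes of previously
    broken bonds) on separate diatomics, spaced widely enough that every
    edit must register as one lasting event.  Returns (spec,
    expected_onset_frames) pairs; a perfect detector scores precision =
    recall = 1 against the expected list.
    """
    rng = np.random.default_rng(seed)
    gap = persistence_frames + TRANSITION_FRAMES + 10
    out = []
    bonds = [(0, 1), (2, 3), (4, 5)]
    for _ in range(n_scripts):
        n_edits = int(rng.integers(1, 4))
        chosen = rng.choice(len(bonds), size=n_edits, replace=False)
        frames_needed = 10 + gap * (n_edits + 1)
        edits = []
        f = int(rng.integers(5, 15))
        broken: list[tuple[int, int]] = []
        for c in chosen:
            i, j = bonds[c]
            edits.append(BondEdit(frame_index=f, atom_i=i, atom_j=j, kind="break"))
            broken.append((i, j))
            f += gap + int(rng.integers(0, 6))
        if broken and rng.random() < 0.5 and f + gap < frames_needed:
            i, j = broken[int(rng.integers(0, len(broken)))]
            edits.append(BondEdit(frame_index=f, atom_i=i, atom_j=j, kind="make"))
        spec = ScriptedEventSpec(base_system=_three_diatomics(), bond_edits=edits,
                                 n_frames=frames_needed,
                                 jitter_sigma=jitter_sigma,
                                 seed=int(rng.integers(0, 2**31 - 1)))
        out.append((spec, sorted(e.frame_index for e in edits)))
    return out


def revert_within_window_spec(seed: int = 0,
                              persistence_frames: int = 25) -> ScriptedEventSpec:
    """A break immediately re-made, shorter than the persistence window —
    a transient the detector must suppress entirely."""
    return ScriptedEventSpec(
        base_system=_three_diatomics(),
        bond_edits=[BondEdit(frame_index=20, atom_i=0, atom_j=1, kind="break"),
                    BondEdit(frame_index=24, atom_i=0, atom_j=1, kind="make")],
        n_frames=40 + 2 * persistence_frames,
        jitter_sigma=0.01, seed=seed)


def score_detection(detected_onsets: Sequence[int], expected_onsets: Sequence[int],
                    tolerance: int = TRANSITION_FRAMES + 2) -> tuple[int, int, int]:
    """Greedy one-to-one matching of detected to expected onsets.

    Returns (true_positives, false_positives, false_negatives); an onset
    matches when it falls within ``tolerance`` frames after the planted
    edit frame.
    """
    expected = list(expected_onsets)
    tp = 0
    fp = 0
    for onset in sorted(detected_onsets):
        hit = next((e for e in expected if e <= onset <= e + tolerance), None)
        if hit is None:
            fp += 1
        else:
            expected.remove(hit)
            tp += 1
    return tp, fp, len(expected)
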