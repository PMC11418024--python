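"""Pluggable energy/force providers.

The discovery engine is backend-agnostic: anything exposing
``evaluate(positions, elements) -> (energy, forces)`` (internal units:
amu·Å²·fs⁻², forces amu·Å·fs⁻²) can drive the dynamics.  Bundled here are
desk-scale stand-ins for a quantum-chemistry engine:

* an all-pairs Morse potential (bonds can form and break freely, so
  reactivity emerges from geometry alone) with Lennard-Jones terms for
  helium, which acts purely as an inert energy-transfer agent;
* a LEPS (London–Eyring–Polanyi–Sato) surface for a three-atom exchange
  system A + BC ⇌ AB + C — the classic reactive toy with a genuine
  first-order saddle in the exchange channel — built from the same Morse
  pair table, with helium again handled by Lennard-Jones;
* the Müller–Brown analytic 2-D surface used as an oracle-checkable
  benchmark for the refinement algorithms.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass
from importlib import resources
from typing import Optional, Protocol, Sequence

import numpy as np


class ForceProvider(Protocol):
    """Energy/force provider contract: forces must be −∇E, translation-
    invariant and rotation-equivariant."""

    def evaluate(self, positions: np.ndarray, elements: Sequence[str]):
        """Return ``(energy, forces)`` for Cartesian positions (n, d)."""
        ...


# ---------------------------------------------------------------------------
# parameter table

@dataclass(frozen=True)
class MorseParams:
    De: float   # well depth, internal energy units
    a: float    # width, 1/Å
    re: float   # equilibrium separation, Å


@dataclass(frozen=True)
class LJParams:
    eps: float
    sigma: float


class MorseTable:
    """Symmetric pair-parameter table with geometric-mean combination.

    Pairs absent from the table are combined from the homonuclear entries:
    De and a by geometric mean, re by arithmetic mean.  Helium pairs are
    Lennard-Jones (``He-He`` entry, ``He-*`` for He against anything else).
    """

    def __init__(self, morse: dict[tuple[str, str], MorseParams],
                 lj: dict[tuple[str, str], LJParams], sato: float = 0.15):
        self._morse = {tuple(sorted(k)): v for k, v in morse.items()}
        self._lj = {tuple(sorted(k)): v for k, v in lj.items()}
        self.sato = sato

    @classmethod
    def default(cls) -> "MorseTable":
        raw = json.loads(
            resources.files("nanoreactor.data").joinpath("morse_params.json").read_text())
        morse = {tuple(k.split("-")): MorseParams(**v) for k, v in raw["morse"].items()}
        lj = {tuple(k.split("-")): LJParams(**v) for k, v in raw["lj"].items()}
        return cls(morse, lj, raw.get("sato", 0.15))

    def is_lj_pair(self, e1: str, e2: str) -> bool:
        return e1 == "He" or e2 == "He"

    def lj(self, e1: str, e2: str) -> LJParams:
        key = tuple(sorted((e1, e2)))
        if key in self._lj:
            return self._lj[key]
        generic = tuple(sorted(("He", "*")))
        if "He" in key and generic in self._lj:
            return self._lj[generic]
        raise KeyError(f"no Lennard-Jones parameters for pair {key}")

    def morse(self, e1: str, e2: str) -> MorseParams:
        key = tuple(sorted((e1, e2)))
        if key in self._morse:
            return self._morse[key]
        try:
            p1 = self._morse[(e1, e1)]
            p2 = self._morse[(e2, e2)]
        except KeyError:
            raise KeyError(
                f"no Morse parameters for pair {key} and no homonuclear "
                "entries to combine") from None
        return MorseParams(
            De=float(np.sqrt(p1.De * p2.De)),
            a=float(np.sqrt(p1.a * p2.a)),
            re=0.5 * (p1.re + p2.re),
        )


def _morse_v_dv(r: np.ndarray, De, a, re):
    ex = np.exp(-a * (r - re))
    v = De * ((1.0 - ex) ** 2 - 1.0)
    dv = 2.0 * De * a * ex * (1.0 - ex)
    return v, dv


def _lj_v_dv(r: np.ndarray, eps, sigma):
    sr6 = (sigma / r) ** 6
    v = 4.0 * eps * (sr6**2 - sr6)
    dv = 4.0 * eps * (-12.0 * sr6**2 + 6.0 * sr6) / r
    return v, dv


class MorseProvider:
    """All-pairs Morse + He Lennard-Jones reactive toy potential.

    There is no fixed bond list: every non-He pair interacts through a
    Morse curve, so bonds break and form wherever the geometry takes them.
    """

    def __init__(self, table: Optional[MorseTable] = None):
        self.table = table if table is not None else MorseTable.default()
        self._cache: dict[tuple[str, ...], tuple] = {}

    def _params_for(self, elements: tuple[str, ...]):
        if elements in self._cache:
            return self._cache[elements]
        n = len(elements)
        ii, jj = np.triu_indices(n, k=1)
        De = np.empty(len(ii)); a = np.empty(len(ii)); re = np.empty(len(ii))
        eps = np.zeros(len(ii)); sig = np.ones(len(ii))
        is_lj = np.zeros(len(ii), dtype=bool)
        for p, (i, j) in enumerate(zip(ii, jj)):
            e1, e2 = elements[i], elements[j]
            if self.table.is_lj_pair(e1, e2):
                is_lj[p] = True
                prm = self.table.lj(e1, e2)
                eps[p], sig[p] = prm.eps, prm.sigma
                De[p] = a[p] = re[p] = 1.0  # unused
            else:
                prm = self.table.morse(e1, e2)
                De[p], a[p], re[p] = prm.De, prm.a, prm.re
        out = (ii, jj, De, a, re, eps, sig, is_lj)
        self._cache[elements] = out
        return out

    def evaluate(self, positions: np.ndarray, elements: Sequence[str]):
        positions = np.asarray(positions, dtype=float)
        elements = tuple(elements)
        ii, jj, De, a, re, eps, sig, is_lj = self._params_for(elements)
        forces = np.zeros_like(positions)
        if len(ii) == 0:
            return 0.0, forces
        dvec = positions[ii] - positions[jj]
        r = np.linalg.norm(dvec, axis=1)
        v = np.empty_like(r); dv = np.empty_like(r)
        m = ~is_lj
        if np.any(m):
            v[m], dv[m] = _morse_v_dv(r[m], De[m], a[m], re[m])
        if np.any(is_lj):
            v[is_lj], dv[is_lj] = _lj_v_dv(r[is_lj], eps[is_lj], sig[is_lj])
        energy = float(np.sum(v))
        fpair = (-dv / r)[:, None] * dvec   # force on atom i from pair (i, j)
        np.add.at(forces, ii, fpair)
        np.add.at(forces, jj, -fpair)
        return energy, forces


def morse_provider(table: Optional[MorseTable] = None) -> MorseProvider:
    return MorseProvider(table)


class LEPSProvider:
    """LEPS exchange surface for up to three non-He atoms, LJ for helium.
    With fewer than three reactive atoms the surface reduces exactly to
    the Morse pair curve (the missing atom at infinity).

    The three reactive atoms (in order of appearance) are A, B, C; the
    surface binds one bond at a time (A–B or B–C), giving the textbook
    exchange barrier between the A + BC and AB + C valleys.  The Sato
    parameter (from the pair table) sets how anti-bonding the triplet
    curves are and thereby the barrier height.
    """

    def __init__(self, table: Optional[MorseTable] = None):
        self.table = table if table is not None else MorseTable.default()

    def _qj(self, r, prm: MorseParams):
        d = self.table.sato
        x = np.exp(-prm.a * (r - prm.re))
        pref = prm.De / (4.0 * (1.0 + d))
        q = pref * ((3.0 + d) * x**2 - (2.0 + 6.0 * d) * x)
        j = pref * ((1.0 + 3.0 * d) * x**2 - (6.0 + 2.0 * d) * x)
        dq = pref * prm.a * (-2.0 * (3.0 + d) * x**2 + (2.0 + 6.0 * d) * x)
        dj = pref * prm.a * (-2.0 * (1.0 + 3.0 * d) * x**2 + (6.0 + 2.0 * d) * x)
        return q, j, dq, dj

    def evaluate(self, positions: np.ndarray, elements: Sequence[str]):
        positions = np.asarray(positions, dtype=float)
        elements = tuple(elements)
        reactive = [i for i, e in enumerate(elements) if e != "He"]
        if len(reactive) > 3:
            raise ValueError(
                f"LEPS provider handles at most 3 non-He atoms, got {len(reactive)}")
        forces = np.zeros_like(positions)
        energy = 0.0

        if len(reactive) == 2:
            # third atom at infinity: the surface reduces to the Morse pair
            i, j = reactive
            prm = self.table.morse(elements[i], elements[j])
            vec = positions[i] - positions[j]
            r = float(np.linalg.norm(vec))
            v, dv = _morse_v_dv(np.array(r), prm.De, prm.a, prm.re)
            energy += float(v)
            f = -float(dv) * vec / r
            forces[i] += f
            forces[j] -= f
        if len(reactive) < 3:
            return self._add_helium(positions, elements, energy, forces)

        A, B, C = reactive
        pairs = [(A, B), (B, C), (A, C)]
        qs, js, dqs, djs, rhat, rlen = [], [], [], [], [], []
        for (i, j) in pairs:
            prm = self.table.morse(elements[i], elements[j])
            vec = positions[i] - positions[j]
            r = float(np.linalg.norm(vec))
            q, jj_, dq, dj = self._qj(r, prm)
            qs.append(q); js.append(jj_); dqs.append(dq); djs.append(dj)
            rhat.append(vec / r); rlen.append(r)
        j1, j2, j3 = js
        s2 = 0.5 * ((j1 - j2) ** 2 + (j2 - j3) ** 2 + (j3 - j1) ** 2)
        s = float(np.sqrt(max(s2, 1e-300)))
        energy += float(sum(qs)) - s
        dS_dJ = [((j1 - j2) + (j1 - j3)) / (2.0 * s),
                 ((j2 - j1) + (j2 - j3)) / (2.0 * s),
                 ((j3 - j1) + (j3 - j2)) / (2.0 * s)]
        for p, (i, j) in enumerate(pairs):
            dV_dr = dqs[p] - dS_dJ[p] * djs[p]
            f = -dV_dr * rhat[p]
            forces[i] += f
            forces[j] -= f

        return self._add_helium(positions, elements, energy, forces)

    def _add_helium(self, positions, elements, energy, forces):
        """Lennard-Jones terms between He and every other atom."""
        key = tuple(elements)
        cached = getattr(self, "_he_cache", {}).get(key)
        if cached is None:
            ii, jj, eps, sig = [], [], [], []
            for i, ei in enumerate(elements):
                for j in range(i + 1, len(elements)):
                    if ei != "He" and elements[j] != "He":
                        continue
                    prm = self.table.lj(ei, elements[j])
                    ii.append(i); jj.append(j)
                    eps.append(prm.eps); sig.append(prm.sigma)
            cached = (np.array(ii, dtype=int), np.array(jj, dtype=int),
                      np.array(eps), np.array(sig))
            if not hasattr(self, "_he_cache"):
                self._he_cache = {}
            self._he_cache[key] = cached
        ii, jj, eps, sig = cached
        if len(ii) == 0:
            return energy, forces
        dvec = positions[ii] - positions[jj]
        r = np.linalg.norm(dvec, axis=1)
        v, dv = _lj_v_dv(r, eps, sig)
        energy += float(np.sum(v))
        fpair = (-dv / r)[:, None] * dvec
        np.add.at(forces, ii, fpair)
        np.add.at(forces, jj, -fpair)
        return energy, forces


def leps_provider(table: Optional[MorseTable] = None) -> LEPSProvider:
    return LEPSProvider(table)


class CompositeProvider:
    """Weighted sum of providers (e.g. physical potential + boundary)."""

    def __init__(self, providers: Sequence[ForceProvider],
                 weights: Optional[Sequence[float]] = None):
        if len(providers) < 1:
            raise ValueError("need at least one provider")
        self.providers = list(providers)
        self.weights = list(weights) if weights is not None else [1.0] * len(providers)
        if len(self.weights) != len(self.providers):
            raise ValueError("weights length must match providers")

    def evaluate(self, positions, elements):
        total_e = 0.0
        total_f = np.zeros_like(np.asarray(positions, dtype=float))
        for w, p in zip(self.weights, self.providers):
            e, f = p.evaluate(positions, elements)
            total_e += w * e
            total_f += w * f
        return total_e, total_f


def composite_provider(providers, weights=None) -> CompositeProvider:
    return CompositeProvider(providers, weights)


# ---------------------------------------------------------------------------
# Müller–Brown analytic 2-D benchmark surface

_MB_A = np.array([-200.0, -100.0, -170.0, 15.0])
_MB_a = np.array([-1.0, -1.0, -6.5, 0.7])
_MB_b = np.array([0.0, 0.0, 11.0, 0.6])
_MB_c = np.array([-10.0, -10.0, -6.5, 0.7])
_MB_x0 = np.array([1.0, 0.0, -0.5, -1.0])
_MB_y0 = np.array([0.0, 0.5, 1.5, 1.0])


def muller_brown(x: float, y: float, centers_shift=(0.0, 0.0)):
    """Müller–Brown potential V(x, y) and its gradient.

    The standard four-Gaussian parameterization.  ``centers_shift``
    translates all four Gaussian centers rigidly (used only to exercise
    translation covariance).
    """
    dx = x - (_MB_x0 + centers_shift[0])
    dy = y - (_MB_y0 + centers_shift[1])
    e = _MB_A * np.exp(_MB_a * dx**2 + _MB_b * dx * dy + _MB_c * dy**2)
    v = float(np.sum(e))
    gx = float(np.sum(e * (2.0 * _MB_a * dx + _MB_b * dy)))
    gy = float(np.sum(e * (_MB_b * dx + 2.0 * _MB_c * dy)))
    return v, np.array([gx, gy])


class AnalyticSurface2D:
    """A named 2-D analytic surface exposed through the provider contract.

    Positions are (1, 2) arrays — one particle living on the surface —
    so the refinement machinery runs unchanged on it.
    """

    def __init__(self, name: str = "muller_brown"):
        if name != "muller_brown":
            raise ValueError(f"unknown analytic surface {name!r}")
        self.name = name

    def evaluate(self, positions, elements=("X",)):
        positions = np.asarray(positions, dtype=float).reshape(1, 2)
        v, g = muller_brown(positions[0, 0], positions[0, 1])
        return v, -g.reshape(1, 2)


# ---------------------------------------------------------------------------
# verification helper

def check_gradient(provider: ForceProvider, positions: np.ndarray,
                   elements, h: float = 1e-5) -> float:
    """Max relative deviation between analytic forces and central finite
    differences of the energy (used by the provider contract tests)."""
    positions = np.asarray(positions, dtype=float)
    _, forces = provider.evaluate(positions, elements)
    num = np.zeros_like(positions)
    for idx in np.ndindex(positions.shape):
        p = positions.copy(); p[idx] += h
        ep, _ = provider.evaluate(p, elements)
        p[idx] -= 2 * h
        em, _ = provider.evaluate(p, elements)
        num[idx] = -(ep - em) / (2 * h)
    scale = max(float(np.max(np.abs(forces))), 1e-10)
    return float(np.max(np.abs(num - forces)) / scale)
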