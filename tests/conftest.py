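"""Shared fixtures: small molecular systems and providers."""

import numpy as np
import pytest

from nanoreactor.forcefields import (AnalyticSurface2D, MorseTable,
                                     leps_provider, morse_provider)
from nanoreactor.system import AtomicSystem


@pytest.fixture(scope="session")
def table() -> MorseTable:
    return MorseTable.default()


@pytest.fixture(scope="session")
def morse(table):
    return morse_provider(table)


@pytest.fixture(scope="session")
def leps(table):
    return leps_provider(table)


@pytest.fixture(scope="session")
def mb_surface():
    return AnalyticSurface2D("muller_brown")


@pytest.fixture
def h2():
    return AtomicSystem.from_elements(["H", "H"], [[0, 0, 0], [0, 0, 0.741]], label="H2")


@pytest.fixture
def he_atom():
    return AtomicSystem.from_elements(["He"], [[0, 0, 0]], label="He")


@pytest.fixture(scope="session")
def mb_stationary_points(mb_surface):
    """Independent dense-grid + descent oracle for the Müller–Brown surface.

    Stationary points are located by scanning a fine grid for small
    gradients and polishing each candidate with a root find on ∇V = 0
    (scipy), then classified by the analytic-FD Hessian.  This shares no
    code with the package optimizers.
    """
    from scipy.optimize import fsolve
    from nanoreactor.forcefields import muller_brown

    def grad(p):
        return muller_brown(p[0], p[1])[1]

    xs = np.linspace(-1.8, 1.2, 121)
    ys = np.linspace(-0.4, 2.2, 105)
    seen = {}
    candidates = [(x, y) for x in xs for y in ys
                  if np.linalg.norm(grad((x, y))) <= 40.0]
    with np.errstate(over="ignore"):
        for x, y in candidates:
            sol, info, ok, _ = fsolve(grad, (x, y), full_output=True)
            if ok != 1 or np.linalg.norm(grad(sol)) > 1e-8:
                continue
            key = (round(sol[0], 6), round(sol[1], 6))
            if key in seen:
                continue
            h = 1e-5
            H = np.empty((2, 2))
            for a in range(2):
                pp = np.array(sol); pp[a] += h
                pm = np.array(sol); pm[a] -= h
                H[a] = (grad(pp) - grad(pm)) / (2 * h)
            H = 0.5 * (H + H.T)
            eig = np.linalg.eigvalsh(H)
            kind = "min" if eig[0] > 0 else ("saddle" if eig[1] > 0 else "max")
            seen[key] = (np.array(sol), muller_brown(*sol)[0], kind)
    minima = sorted((v for v in seen.values() if v[2] == "min"), key=lambda t: t[1])
    saddles = sorted((v for v in seen.values() if v[2] == "saddle"), key=lambda t: t[1])
    return {"minima": minima, "saddles": saddles}
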