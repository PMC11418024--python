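"""Refinement stage: minimization, NEB paths, transition-state search,
IRC verification, harmonic frequencies/ZPVE, prereaction complexes and
constrained distance scans.

All routines work on any :class:`~nanoreactor.forcefields.ForceProvider`
and on coordinate arrays of shape (n_particles, dim) — dim is 3 for
molecules and 2 for the analytic benchmark surfaces — so the exact same
code path is exercised on the Müller–Brown oracle surface and on the
molecular toy potentials.

Numerical conventions (defaults, overridable per call):

* minimization: BFGS with the per-iteration displacement capped at a
  0.015 Å per-atom norm and backtracking so accepted steps never raise
  the energy; converged when the largest gradient component is at or
  below ``grad_tol`` (internal units).
* NEB: linear interpolation in Cartesian coordinates, improved-tangent
  projection, optional climbing image, relaxed with a FIRE optimizer.
* TS search: eigenvector following — uphill along the lowest Hessian
  mode, downhill along the rest — with finite-difference Hessians.
* IRC: displacement ±δ along the imaginary mode, then damped
  steepest descent in mass-weighted coordinates with a fixed step.
* frequencies: central finite-difference Hessian (0.005 Å), mass
  weighting, rigid translations/rotations projected out; imaginary
  frequencies are reported as negative wavenumbers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from . import units
from .forcefields import ForceProvider

DEFAULT_MAX_STEP = 0.015      # Å, per-atom displacement cap (minimization)
DEFAULT_GRAD_TOL = 1e-4       # internal units, max |gradient component|
HESSIAN_DISPLACEMENT = 0.005  # Å
IRC_STEP = 0.02               # amu^1/2 · Å
IRC_DELTA = 0.01              # Å, initial displacement off the saddle


def _grad(provider: ForceProvider, x: np.ndarray, elements) -> tuple[float, np.ndarray]:
    e, f = provider.evaluate(x, elements)
    return e, -np.asarray(f, dtype=float)


# ---------------------------------------------------------------------------
# minimization

@dataclass
class OptResult:
    positions: np.ndarray
    energy: float                 # internal units (provider units)
    grad_max: float               # max |gradient component|
    n_iterations: int
    converged: bool

    @property
    def energy_kj_per_mol(self) -> float:
        return self.energy * units.EU_TO_KJ_PER_MOL


def _cap_step(step: np.ndarray, max_step: float) -> np.ndarray:
    norms = np.linalg.norm(step, axis=1)
    biggest = norms.max() if len(norms) else 0.0
    if biggest > max_step:
        step = step * (max_step / biggest)
    return step


def minimize(geometry: np.ndarray, provider: ForceProvider,
             elements: Sequence[str] = (),
             max_step: float = DEFAULT_MAX_STEP,
             grad_tol: float = DEFAULT_GRAD_TOL,
             max_iter: int = 5000) -> OptResult:
    """Quasi-Newton (BFGS) energy minimization with a hard step cap.

    Accepted iterations never increase the energy (backtracking line
    search); an exhausted iteration budget returns an unconverged result
    rather than raising.
    """
    x = np.asarray(geometry, dtype=float).copy()
    shape = x.shape
    n_dof = x.size

    def fresh_h(gradient):
        # scale so the first step has max_step length even for the weak
        # long-range gradients of van-der-Waals approaches
        scale = max_step / max(float(np.max(np.abs(gradient))), 1e-300)
        return np.eye(n_dof) * min(scale, 1e12)

    e, g = _grad(provider, x, elements)
    H = fresh_h(g)
    it = 0
    while it < max_iter:
        gmax = float(np.max(np.abs(g)))
        if gmax <= grad_tol:
            return OptResult(x, e, gmax, it, True)
        p = -(H @ g.ravel()).reshape(shape)
        if np.vdot(p, g) >= 0:       # not a descent direction: reset
            H = fresh_h(g)
            p = -(H @ g.ravel()).reshape(shape)
        p = _cap_step(p, max_step)
        alpha = 1.0
        for _ in range(25):
            x_new = x + alpha * p
            e_new, g_new = _grad(provider, x_new, elements)
            if e_new <= e + 1e-13 * max(1.0, abs(e)):
                break
            alpha *= 0.5
        else:
            # no progress possible along this direction
            H = fresh_h(g)
            it += 1
            continue
        s = (x_new - x).ravel()
        y = (g_new - g).ravel()
        sy = float(s @ y)
        if sy > 1e-12 * float(np.linalg.norm(s) * np.linalg.norm(y) + 1e-300):
            rho = 1.0 / sy
            I = np.eye(n_dof)
            V = I - rho * np.outer(s, y)
            H = V @ H @ V.T + rho * np.outer(s, s)
        x, e, g = x_new, e_new, g_new
        it += 1
    gmax = float(np.max(np.abs(g)))
    return OptResult(x, e, gmax, it, gmax <= grad_tol)


# ---------------------------------------------------------------------------
# FIRE relaxation on an arbitrary force field (used by NEB)

def _fire(x0: np.ndarray, force_fn: Callable[[np.ndarray], np.ndarray],
          tol: float, max_iter: int, max_disp: float,
          dt_start: float = 0.02) -> tuple[np.ndarray, int, bool]:
    """FIRE relaxation; converges when max |force component| <= tol."""
    x = x0.copy()
    v = np.zeros_like(x)
    dt = dt_start
    dt_max = 10 * dt_start
    n_pos = 0
    alpha = 0.1
    f = force_fn(x)
    for it in range(max_iter):
        if np.max(np.abs(f)) <= tol:
            return x, it, True
        p = float(np.vdot(f, v))
        if p > 0:
            n_pos += 1
            fn = np.linalg.norm(f)
            vn = np.linalg.norm(v)
            v = (1 - alpha) * v + alpha * (f / (fn + 1e-300)) * vn
            if n_pos > 5:
                dt = min(dt * 1.1, dt_max)
                alpha *= 0.99
        else:
            v[:] = 0.0
            dt *= 0.5
            alpha = 0.1
            n_pos = 0
        v = v + dt * f
        dx = dt * v
        dxmax = np.max(np.abs(dx))
        if dxmax > max_disp:
            dx *= max_disp / dxmax
        x = x + dx
        f = force_fn(x)
    return x, max_iter, bool(np.max(np.abs(f)) <= tol)


# ---------------------------------------------------------------------------
# NEB

@dataclass
class NEBPath:
    images: list[np.ndarray]
    energies: np.ndarray
    spring_k: float
    climbing_index: Optional[int]
    converged: bool
    n_iterations: int = 0

    @property
    def highest_index(self) -> int:
        return int(np.argmax(self.energies))


def _neb_tangent(x_prev, x_here, x_next, e_prev, e_here, e_next):
    """Improved (energy-weighted upwind) tangent of Henkelman & Jónsson."""
    tp = x_next - x_here
    tm = x_here - x_prev
    if e_next > e_here > e_prev:
        tau = tp
    elif e_next < e_here < e_prev:
        tau = tm
    else:
        dmax = max(abs(e_next - e_here), abs(e_prev - e_here))
        dmin = min(abs(e_next - e_here), abs(e_prev - e_here))
        if e_next > e_prev:
            tau = tp * dmax + tm * dmin
        else:
            tau = tp * dmin + tm * dmax
    n = np.linalg.norm(tau)
    return tau / (n + 1e-300)


def neb(minimum_a: np.ndarray, minimum_b: np.ndarray, provider: ForceProvider,
        elements: Sequence[str] = (), n_images: int = 11,
        spring_k: float = 1.0, climbing: bool = True,
        tol: float = 1e-3, max_iter: int = 5000,
        max_disp: float = 0.05) -> NEBPath:
    """Nudged-elastic-band minimum-energy path between two minima.

    The initial path is a linear interpolation in Cartesian coordinates;
    endpoints stay fixed.  When ``climbing`` is set, the highest interior
    image switches to climbing mode once the band is roughly relaxed
    (perpendicular force below 100·tol), driving it to the saddle.
    """
    a = np.asarray(minimum_a, dtype=float)
    b = np.asarray(minimum_b, dtype=float)
    if n_images < 3:
        raise ValueError("n_images must be >= 3")
    if np.linalg.norm(a - b) < 1e-8:
        raise ValueError("degenerate input: the two minima coincide")
    ts = np.linspace(0.0, 1.0, n_images)
    images = [a + (b - a) * t for t in ts]
    shape = a.shape
    state = {"climb": None}

    def energies_of(imgs):
        return np.array([provider.evaluate(im, elements)[0] for im in imgs])

    def band_force(flat):
        imgs = [a] + [flat[k].reshape(shape) for k in range(n_images - 2)] + [b]
        es = np.empty(n_images)
        gs = [None] * n_images
        for k in range(n_images):
            es[k], gs[k] = _grad(provider, imgs[k], elements)
        out = np.zeros_like(flat)
        ci = state["climb"]
        for k in range(1, n_images - 1):
            tau = _neb_tangent(imgs[k - 1], imgs[k], imgs[k + 1],
                               es[k - 1], es[k], es[k + 1])
            f_true = -gs[k]
            if ci == k:
                f = f_true - 2.0 * np.vdot(f_true, tau) * tau
            else:
                f_perp = f_true - np.vdot(f_true, tau) * tau
                f_spr = spring_k * (np.linalg.norm(imgs[k + 1] - imgs[k])
                                    - np.linalg.norm(imgs[k] - imgs[k - 1])) * tau
                f = f_perp + f_spr
            out[k - 1] = f
        return out

    interior = np.array([im.copy() for im in images[1:-1]])
    total_iter = 0
    # stage 1: plain band
    interior, it1, conv = _fire(interior, band_force, tol=tol if not climbing else 100 * tol,
                                max_iter=max_iter, max_disp=max_disp)
    total_iter += it1
    if climbing:
        imgs = [a] + [im.reshape(shape) for im in interior] + [b]
        es = energies_of(imgs)
        state["climb"] = int(np.argmax(es[1:-1])) + 1
        interior, it2, conv = _fire(interior, band_force, tol=tol,
                                    max_iter=max_iter, max_disp=max_disp)
        total_iter += it2
    final = [a] + [im.reshape(shape) for im in interior] + [b]
    for k in range(n_images - 1):
        if np.linalg.norm(final[k + 1] - final[k]) < 1e-6:
            raise RuntimeError(
                "NEB path collapse: adjacent images coincide; use more images")
    return NEBPath(images=final, energies=energies_of(final), spring_k=spring_k,
                   climbing_index=state["climb"], converged=conv,
                   n_iterations=total_iter)


# ---------------------------------------------------------------------------
# Hessians

def fd_hessian(geometry: np.ndarray, provider: ForceProvider,
               elements: Sequence[str] = (),
               displacement: float = HESSIAN_DISPLACEMENT) -> np.ndarray:
    """Central finite-difference Hessian from analytic gradients."""
    x = np.asarray(geometry, dtype=float)
    n = x.size
    H = np.empty((n, n))
    flat = x.ravel()
    for k in range(n):
        xp = flat.copy(); xp[k] += displacement
        xm = flat.copy(); xm[k] -= displacement
        _, gp = _grad(provider, xp.reshape(x.shape), elements)
        _, gm = _grad(provider, xm.reshape(x.shape), elements)
        if not (np.all(np.isfinite(gp)) and np.all(np.isfinite(gm))):
            raise RuntimeError(f"non-finite gradient at Hessian displacement {k}")
        H[k] = (gp.ravel() - gm.ravel()) / (2.0 * displacement)
    return 0.5 * (H + H.T)


# ---------------------------------------------------------------------------
# transition-state optimization

@dataclass
class SaddleResult:
    positions: np.ndarray
    energy: float
    hessian_eigenvalues: np.ndarray
    n_imaginary: int
    converged: bool
    n_iterations: int = 0

    @property
    def is_first_order(self) -> bool:
        return self.converged and self.n_imaginary == 1

    @property
    def energy_kj_per_mol(self) -> float:
        return self.energy * units.EU_TO_KJ_PER_MOL


def _count_negative(eigvals: np.ndarray) -> int:
    # zero (translation/rotation) modes carry finite-difference noise of
    # order 1e-6·scale; genuine imaginary modes sit orders of magnitude
    # below that on every bundled surface.  The absolute floor keeps the
    # all-noise spectrum of a flat (fully dissociated) region from
    # counting as curvature at all.
    scale = float(np.max(np.abs(eigvals))) if eigvals.size else 1.0
    return int(np.sum(eigvals < -max(1e-4 * scale, 1e-7)))


def ts_optimize(start_geometry: np.ndarray, provider: ForceProvider,
                elements: Sequence[str] = (),
                grad_tol: float = DEFAULT_GRAD_TOL,
                max_step: float = 0.05, max_iter: int = 200,
                displacement: float = HESSIAN_DISPLACEMENT) -> SaddleResult:
    """Eigenvector-following saddle search from a near-saddle start.

    Each iteration maximizes along the lowest Hessian eigenmode and
    minimizes along all others; convergence to a stationary point without
    exactly one negative eigenvalue is reported as a flagged failure
    (``is_first_order`` False) together with the eigenvalue spectrum.
    """
    x = np.asarray(start_geometry, dtype=float).copy()
    shape = x.shape
    for it in range(max_iter):
        e, g = _grad(provider, x, elements)
        gmax = float(np.max(np.abs(g)))
        H = fd_hessian(x, provider, elements, displacement)
        lam, vec = np.linalg.eigh(H)
        if gmax <= grad_tol:
            return SaddleResult(x, e, lam, _count_negative(lam), True, it)
        gt = vec.T @ g.ravel()
        scale = float(np.max(np.abs(lam)))
        reg = max(1e-8, 1e-6 * scale)
        denom = np.maximum(np.abs(lam), reg)
        step_modes = -gt / denom
        step_modes[0] = +gt[0] / max(abs(lam[0]), reg)   # uphill on lowest mode
        step = (vec @ step_modes).reshape(shape)
        step = _cap_step(step if step.ndim > 1 else step.reshape(1, -1), max_step)
        x = x + step.reshape(shape)
    e, g = _grad(provider, x, elements)
    H = fd_hessian(x, provider, elements, displacement)
    lam = np.linalg.eigvalsh(H)
    gmax = float(np.max(np.abs(g)))
    return SaddleResult(x, e, lam, _count_negative(lam), gmax <= grad_tol, max_iter)


# ---------------------------------------------------------------------------
# IRC

@dataclass
class IRCBranch:
    geometries: list[np.ndarray]
    energies: list[float]
    endpoint: OptResult
    completed: bool


@dataclass
class IRCResult:
    path_minus: IRCBranch
    path_plus: IRCBranch


def irc(saddle: np.ndarray, provider: ForceProvider,
        elements: Sequence[str] = (), masses: Optional[np.ndarray] = None,
        step: float = IRC_STEP, delta: float = IRC_DELTA,
        grad_tol: float = DEFAULT_GRAD_TOL, max_iter: int = 20000,
        displacement: float = HESSIAN_DISPLACEMENT) -> IRCResult:
    """Intrinsic reaction coordinate: steepest descent in mass-weighted
    coordinates from both sides of a first-order saddle.

    The saddle must have exactly one imaginary mode (checked); each branch
    starts ±delta Å along that mode and descends with fixed mass-weighted
    steps until the gradient is small, then the endpoint is polished with
    :func:`minimize`.
    """
    x0 = np.asarray(saddle, dtype=float)
    n, dim = x0.shape
    if masses is None:
        masses = np.ones(n)
    masses = np.asarray(masses, dtype=float)
    sqm = np.repeat(np.sqrt(masses), dim)

    H = fd_hessian(x0, provider, elements, displacement)
    Hmw = H / np.outer(sqm, sqm)
    lam, vec = np.linalg.eigh(Hmw)
    if _count_negative(lam) != 1:
        raise ValueError(
            f"IRC requires exactly one imaginary mode, found {_count_negative(lam)}")
    mode_x = (vec[:, 0] / sqm)
    mode_x = mode_x / np.linalg.norm(mode_x)
    mode_x = mode_x.reshape(n, dim)

    def descend(sign: float) -> IRCBranch:
        x = x0 + sign * delta * mode_x
        e_cur, g = _grad(provider, x, elements)
        geoms = [x.copy()]
        es = [e_cur]
        done = False
        for _ in range(max_iter):
            if np.max(np.abs(g)) <= 10 * grad_tol:
                done = True
                break
            g_mw = g.ravel() / sqm
            dq = -step * g_mw / np.linalg.norm(g_mw)
            dx = (dq / sqm).reshape(n, dim)
            scale = 1.0
            for _ in range(15):   # damp the step when it would climb
                x_try = x + scale * dx
                e_try, g_try = _grad(provider, x_try, elements)
                if e_try <= e_cur:
                    break
                scale *= 0.5
            else:
                done = True       # pinned at the basin bottom
                break
            x, e_cur, g = x_try, e_try, g_try
            geoms.append(x.copy())
            es.append(e_cur)
        end = minimize(x, provider, elements, grad_tol=grad_tol)
        geoms.append(end.positions.copy())
        es.append(end.energy)
        return IRCBranch(geoms, es, end, done and end.converged)

    return IRCResult(path_minus=descend(-1.0), path_plus=descend(+1.0))


# ---------------------------------------------------------------------------
# harmonic frequencies / ZPVE

@dataclass
class FreqResult:
    frequencies_cm: np.ndarray    # imaginary modes reported negative
    modes: np.ndarray             # columns: mass-weighted eigenvectors
    zpve_kj_per_mol: float
    n_imaginary: int


def _tr_projection_basis(positions: np.ndarray, masses: np.ndarray) -> np.ndarray:
    """Orthonormal basis of mass-weighted rigid translations + rotations."""
    n = len(positions)
    sqm = np.sqrt(masses)
    com = np.average(positions, axis=0, weights=masses)
    rel = positions - com
    vecs = []
    for k in range(3):
        t = np.zeros((n, 3)); t[:, k] = 1.0
        vecs.append((t * sqm[:, None]).ravel())
    for k in range(3):
        axis = np.zeros(3); axis[k] = 1.0
        r = np.cross(rel, axis)
        vecs.append((r * sqm[:, None]).ravel())
    B = np.array(vecs).T
    # orthonormalize, dropping rank deficiency (linear molecules: 5 vectors)
    q, s, _ = np.linalg.svd(B, full_matrices=False)
    keep = s > 1e-8 * s.max()
    return q[:, keep]


def hessian_frequencies(geometry: np.ndarray, provider: ForceProvider,
                        masses: np.ndarray, elements: Sequence[str] = (),
                        displacement: float = HESSIAN_DISPLACEMENT,
                        project: bool = True,
                        grad_warn: float = 1e-3) -> FreqResult:
    """Harmonic frequencies (cm⁻¹) and ZPVE (kJ/mol) at a stationary point.

    Central finite-difference Hessian, mass-weighted; rigid translations
    and rotations are projected out when ``project`` is set (3-D only).
    ZPVE = ½ Σ hν over the real modes.
    """
    x = np.asarray(geometry, dtype=float)
    n, dim = x.shape
    masses = np.asarray(masses, dtype=float)
    _, g = _grad(provider, x, elements)
    if np.max(np.abs(g)) > grad_warn:
        warnings.warn("hessian_frequencies called at a non-stationary geometry")
    H = fd_hessian(x, provider, elements, displacement)
    sqm = np.repeat(np.sqrt(masses), dim)
    Hmw = H / np.outer(sqm, sqm)
    n_zero = 0
    if project and dim == 3 and n > 1:
        Q = _tr_projection_basis(x, masses)
        P = np.eye(n * dim) - Q @ Q.T
        Hmw = P @ Hmw @ P
        n_zero = Q.shape[1]
    elif project and dim == 3 and n == 1:
        n_zero = 3
    lam, vec = np.linalg.eigh(Hmw)
    if n_zero:
        order = np.argsort(np.abs(lam))
        drop = set(order[:n_zero].tolist())
        keep = [k for k in range(len(lam)) if k not in drop]
        lam, vec = lam[keep], vec[:, keep]
    nu_fs = np.sign(lam) * np.sqrt(np.abs(lam)) / (2.0 * np.pi)   # fs^-1, signed
    freq_cm = nu_fs * units.FS_INV_TO_CM_INV
    order = np.argsort(freq_cm)
    freq_cm, vec, nu_fs = freq_cm[order], vec[:, order], nu_fs[order]
    real = nu_fs > 0
    zpve = 0.5 * float(np.sum([units.hz_to_kj_per_mol(v * units.FS_INV_TO_HZ)
                               for v in nu_fs[real]]))
    return FreqResult(frequencies_cm=freq_cm, modes=vec, zpve_kj_per_mol=zpve,
                      n_imaginary=int(np.sum(~real)))


# ---------------------------------------------------------------------------
# prereaction complexes

def _kabsch_place(fragment: np.ndarray, template: np.ndarray) -> np.ndarray:
    """Rigidly place ``fragment`` onto ``template`` (best-fit rotation +
    centroid match) without distorting it."""
    fc = fragment - fragment.mean(axis=0)
    tc = template - template.mean(axis=0)
    if len(fragment) == 1:
        return template.copy()
    rot, _ = Rotation.align_vectors(tc, fc)
    return rot.apply(fc) + template.mean(axis=0)


@dataclass
class ComplexResult:
    opt: OptResult
    initial_positions: np.ndarray
    binding_energy: float          # internal units, E_complex - E_A - E_B

    @property
    def binding_energy_kj_per_mol(self) -> float:
        return self.binding_energy * units.EU_TO_KJ_PER_MOL


def prereaction_complex(fragment_a: np.ndarray, fragment_b: np.ndarray,
                        template_a: np.ndarray, template_b: np.ndarray,
                        provider: ForceProvider, elements: Sequence[str],
                        min_separation: float = 5.0,
                        max_step: float = DEFAULT_MAX_STEP,
                        grad_tol: float = DEFAULT_GRAD_TOL) -> ComplexResult:
    """Build and relax a prereaction complex of two rigid fragments.

    The minimized fragments are placed in the relative orientation given
    by the template geometries (e.g. the first post-event intermediate),
    pushed apart along the centroid axis until every inter-fragment
    contact exceeds ``min_separation`` (default 5.00 Å), then jointly
    minimized with the capped-step optimizer.  ``elements`` covers the
    concatenated system (A atoms first).
    """
    a = _kabsch_place(np.asarray(fragment_a, dtype=float), np.asarray(template_a, dtype=float))
    b = _kabsch_place(np.asarray(fragment_b, dtype=float), np.asarray(template_b, dtype=float))
    axis = b.mean(axis=0) - a.mean(axis=0)
    norm = np.linalg.norm(axis)
    if norm < 1e-8:
        raise ValueError("fragments overlap after placement: coincident centroids")
    axis = axis / norm
    for _ in range(1000):
        d = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=-1)
        closest = float(d.min())
        if closest > min_separation:
            break
        b = b + axis * (min_separation - closest + 0.1)
    start = np.vstack([a, b])
    e_a, _ = provider.evaluate(a, elements[: len(a)])
    e_b, _ = provider.evaluate(b, elements[len(a):])
    opt = minimize(start, provider, elements, max_step=max_step, grad_tol=grad_tol)
    return ComplexResult(opt=opt, initial_positions=start,
                         binding_energy=opt.energy - e_a - e_b)


# ---------------------------------------------------------------------------
# constrained distance scans

def constrained_scan(geometry: np.ndarray, provider: ForceProvider,
                     elements: Sequence[str], atom_pair: tuple[int, int],
                     distance_grid: Sequence[float],
                     max_step: float = DEFAULT_MAX_STEP,
                     grad_tol: float = DEFAULT_GRAD_TOL,
                     max_iter: int = 2000) -> list[tuple[float, float, np.ndarray]]:
    """Relaxed scan along one interatomic distance.

    For each grid value the remaining degrees of freedom are minimized
    with the gradient projected onto the constraint surface; the pair
    distance is re-imposed exactly after every step.  Each point warm
    starts from the previous one.  Returns ``(distance, energy,
    geometry)`` triples.
    """
    i, j = atom_pair
    if i == j:
        raise ValueError("constraint atoms must be distinct")
    grid = np.asarray(distance_grid, dtype=float)
    if len(grid) > 1:
        diffs = np.diff(grid)
        if not (np.all(diffs > 0) or np.all(diffs < 0)):
            raise ValueError("distance grid must be monotone")
    x = np.asarray(geometry, dtype=float).copy()

    def set_distance(pos, target):
        vec = pos[j] - pos[i]
        r = np.linalg.norm(vec)
        if r < 1e-12:
            raise ValueError("constrained atoms coincide")
        shift = 0.5 * (target - r) * vec / r
        pos = pos.copy()
        pos[i] -= shift
        pos[j] += shift
        return pos

    def project(g, pos):
        vec = pos[j] - pos[i]
        u = vec / np.linalg.norm(vec)
        c = np.zeros_like(pos)
        c[i] = -u
        c[j] = u
        cflat = c.ravel()
        cflat = cflat / np.linalg.norm(cflat)
        gflat = g.ravel() - float(g.ravel() @ cflat) * cflat
        return gflat.reshape(pos.shape)

    profile = []
    for target in grid:
        x = set_distance(x, float(target))
        e, g = _grad(provider, x, elements)
        for _ in range(max_iter):
            gp = project(g, x)
            if np.max(np.abs(gp)) <= grad_tol:
                break
            step = _cap_step(-gp, max_step)
            alpha = 1.0
            for _ in range(20):
                x_try = set_distance(x + alpha * step, float(target))
                e_try, g_try = _grad(provider, x_try, elements)
                if e_try <= e + 1e-13 * max(1.0, abs(e)):
                    break
                alpha *= 0.5
            else:
                break
            x, e, g = x_try, e_try, g_try
        profile.append((float(target), e, x.copy()))
    return profile
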