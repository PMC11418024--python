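"""End-to-end orchestration: discovery → selection → refinement.

This module glues the stages together behind plain functions so the CLI
stays a thin argument-parsing layer and tests can drive the identical
code path.  All artifacts are JSON or (extended-)XYZ text files; every
JSON artifact embeds a provenance block (config hash, seed, package
version) so re-runs are attributable and byte-reproducible apart from
that block's hash inputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from . import __version__, units
from .bondgraph import ReactionEvent, detect_events, event_to_dict, fragments, perceive_graph
from .config import RunConfig
from .dynamics import run_nanoreactor
from .forcefields import ForceProvider, leps_provider, morse_provider
from .packing import pack_sphere
from .refine import (constrained_scan, hessian_frequencies, irc, minimize,
                     neb, ts_optimize)
from .screening import (ReactionRecord, build_record, filter_bimolecular,
                        filter_exothermic_reverse, reverse_and_dedup)
from .system import AtomicSystem, Trajectory, write_systems_xyz, write_xyz

REPORT_SCHEMA_VERSION = 1


def make_provider(name: str) -> ForceProvider:
    if name == "morse":
        return morse_provider()
    if name == "leps":
        return leps_provider()
    raise ValueError(f"unknown provider {name!r}")


def provenance_block(config: RunConfig) -> dict:
    cfg_text = yaml.safe_dump(config.raw, sort_keys=True)
    return {
        "config_sha256": hashlib.sha256(cfg_text.encode()).hexdigest(),
        "seed": config.seed,
        "package": "nanoreactor",
        "version": __version__,
        "numpy": np.__version__,
    }


def _write_json(obj: dict, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# stage drivers

def stage_pack(config: RunConfig, minimize_packed: bool = True) -> AtomicSystem:
    """Pack the initial sphere and (optionally) energy-minimize it, the
    way each starting configuration is relaxed before the dynamics."""
    packed = pack_sphere(config.pack)
    if minimize_packed:
        provider = make_provider(config.provider)
        opt = minimize(packed.positions, provider, packed.elements,
                       max_step=config.refine.max_step,
                       grad_tol=1e-3, max_iter=200)
        packed = AtomicSystem(packed.elements, packed.masses, opt.positions,
                              label=packed.label)
    return packed


def stage_dynamics(config: RunConfig, packed: AtomicSystem) -> Trajectory:
    provider = make_provider(config.provider)
    return run_nanoreactor(packed, provider, config.piston, config.integrator)


def stage_detect(config: RunConfig, trajectory: Trajectory) -> list[ReactionEvent]:
    d = config.detect
    return detect_events(trajectory, persistence_frames=d.persistence_frames,
                         form_factor=d.form_factor, break_factor=d.break_factor)


def stage_screen(config: RunConfig, events: list[ReactionEvent],
                 trajectory_id: str = "traj") -> dict:
    """Build energetic records for all events, apply both plausibility
    filters, and reverse+dedup the survivors into synthesis candidates."""
    provider = make_provider(config.provider)
    records = [build_record(ev, provider, trajectory_id=trajectory_id, event_index=k,
                            grad_tol=config.refine.grad_tol,
                            max_step=config.refine.max_step)
               for k, ev in enumerate(events)]
    rep_bi = filter_bimolecular(records)
    rep_exo = filter_exothermic_reverse(records)
    passing = sorted(set(rep_bi.passed_indices) & set(rep_exo.passed_indices))
    reversed_records = reverse_and_dedup([records[i] for i in passing])
    return {
        "records": records,
        "filter_reports": [rep_bi, rep_exo],
        "passing_indices": passing,
        "reversed_records": reversed_records,
    }


def event_side_geometry(event: ReactionEvent, side: str) -> tuple[tuple[str, ...], np.ndarray, np.ndarray]:
    """Concatenate an event side's fragment geometries into one local
    system (atoms in ascending original index order).  Returns
    (elements, masses placeholder-free positions array, atom index array)."""
    frs = event.reactant_fragments if side == "reactant" else event.product_fragments
    pairs = []
    for f in frs:
        if f.positions is None:
            raise ValueError("event fragments carry no geometry")
        for a, el, pos in zip(f.atoms, f.elements, f.positions):
            pairs.append((a, el, pos))
    pairs.sort(key=lambda t: t[0])
    elements = tuple(p[1] for p in pairs)
    positions = np.array([p[2] for p in pairs])
    atom_idx = np.array([p[0] for p in pairs], dtype=int)
    return elements, positions, atom_idx


@dataclass
class RefinedPath:
    """Outcome of refining one reversed record back to a verified MEP."""

    record: ReactionRecord
    reactant_opt_energy: float       # kJ/mol (reverse-direction reactant side)
    product_opt_energy: float        # kJ/mol
    saddle_energy: float             # kJ/mol
    barrier_forward: float           # kJ/mol, saddle - reactants (reverse dir.)
    barrier_reverse: float           # kJ/mol, saddle - products
    n_imaginary: int
    zpve_ts: float                   # kJ/mol
    imaginary_frequency_cm: Optional[float]
    irc_endpoint_signatures: tuple[tuple[str, ...], tuple[str, ...]]
    endpoints_match_event: bool
    neb_converged: bool
    saddle_converged: bool
    images: list[np.ndarray] = field(default_factory=list)
    elements: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "record": self.record.to_dict(),
            "reactant_opt_energy_kj_per_mol": self.reactant_opt_energy,
            "product_opt_energy_kj_per_mol": self.product_opt_energy,
            "saddle_energy_kj_per_mol": self.saddle_energy,
            "barrier_forward_kj_per_mol": self.barrier_forward,
            "barrier_reverse_kj_per_mol": self.barrier_reverse,
            "n_imaginary": self.n_imaginary,
            "zpve_ts_kj_per_mol": self.zpve_ts,
            "imaginary_frequency_cm": self.imaginary_frequency_cm,
            "irc_endpoint_signatures": [list(s) for s in self.irc_endpoint_signatures],
            "endpoints_match_event": self.endpoints_match_event,
            "neb_converged": self.neb_converged,
            "saddle_converged": self.saddle_converged,
        }


def _fragment_signatures(elements, positions) -> tuple[str, ...]:
    g = perceive_graph(np.asarray(positions), elements)
    return tuple(sorted(f.signature for f in fragments(g)))


def _align(mobile: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Rigid (proper-rotation) least-squares alignment of one endpoint onto
    the other, so the interpolated path carries no spurious overall
    translation/rotation."""
    import warnings as _w
    from scipy.spatial.transform import Rotation
    mc = mobile - mobile.mean(axis=0)
    rc = reference - reference.mean(axis=0)
    with _w.catch_warnings():
        # near-collinear clusters make the optimal rotation ill-defined in
        # one angle; any representative is fine here
        _w.simplefilter("ignore", UserWarning)
        rot, _ = Rotation.align_vectors(rc, mc)
    return rot.apply(mc) + reference.mean(axis=0)


def _scan_saddle_guess(r_pos: np.ndarray, p_pos: np.ndarray,
                       elements, provider, grad_tol: float):
    """Entrance-channel barrier search: relaxed scan along the bond that
    forms between the two sides, returning the profile-maximum geometry.

    Used when the NEB's highest image does not tighten to a first-order
    saddle (discrete images can step across a thin ridge unsampled)."""
    g_r = perceive_graph(r_pos, elements)
    g_p = perceive_graph(p_pos, elements)
    formed = sorted(g_p.edges - g_r.edges) or sorted(g_r.edges - g_p.edges)
    if not formed:
        return None
    i, j = formed[0]
    d0 = min(float(np.linalg.norm(r_pos[i] - r_pos[j])), 4.0)
    d1 = float(np.linalg.norm(p_pos[i] - p_pos[j]))
    if d0 <= d1:
        return None
    grid = np.linspace(d0, d1, 25)
    profile = constrained_scan(r_pos, provider, elements, (i, j), grid,
                               grad_tol=grad_tol)
    energies = [e for _, e, _ in profile]
    k = int(np.argmax(energies))
    if k in (0, len(profile) - 1):
        return None
    return profile[k][2]


def refine_event(event: ReactionEvent, record: ReactionRecord,
                 provider: ForceProvider, config: RunConfig,
                 masses_by_element=None) -> RefinedPath:
    """Refine one screened event into a verified minimum-energy path.

    Both event-side geometries (restricted to the atoms that changed) are
    minimized; a climbing-image NEB connects them; the highest image is
    tightened to a first-order saddle; frequencies give the imaginary
    mode and ZPVE; and the IRC is descended both ways to check that the
    path really connects the event's fragment sets.  Barrier heights are
    quoted for the *reversed* (synthesis) direction: forward = saddle −
    product-side complex of the fragmentation = reactant side of the
    synthesis.
    """
    from .system import mass_of
    rc = config.refine
    elements, r_pos, _ = event_side_geometry(event, "reactant")
    _, p_pos, _ = event_side_geometry(event, "product")
    masses = np.array([mass_of(e) for e in elements])

    opt_r = minimize(r_pos, provider, elements, max_step=rc.max_step, grad_tol=rc.grad_tol)
    opt_p = minimize(p_pos, provider, elements, max_step=rc.max_step, grad_tol=rc.grad_tol)
    p_aligned = _align(opt_p.positions, opt_r.positions)
    band = neb(opt_r.positions, p_aligned, provider, elements,
               n_images=rc.n_images, spring_k=rc.spring_k, climbing=True,
               tol=rc.neb_tol, max_iter=rc.neb_max_iter)
    start = band.images[band.highest_index]
    ts = ts_optimize(start, provider, elements, grad_tol=rc.grad_tol)
    if not ts.is_first_order:
        guess = _scan_saddle_guess(opt_r.positions, p_aligned, elements,
                                   provider, rc.grad_tol)
        if guess is not None:
            ts = ts_optimize(guess, provider, elements, grad_tol=rc.grad_tol)
    freq = hessian_frequencies(ts.positions, provider, masses, elements)
    ev_r = tuple(sorted(f.signature for f in event.reactant_fragments))
    ev_p = tuple(sorted(f.signature for f in event.product_fragments))
    if ts.is_first_order:
        irc_res = irc(ts.positions, provider, elements, masses=masses,
                      grad_tol=rc.grad_tol)
        sig_minus = _fragment_signatures(elements, irc_res.path_minus.endpoint.positions)
        sig_plus = _fragment_signatures(elements, irc_res.path_plus.endpoint.positions)
        match = {sig_minus, sig_plus} == {ev_r, ev_p}
    else:
        # no genuine saddle (e.g. a barrierless association read in
        # reverse): report the spectrum, skip the IRC
        sig_minus = sig_plus = ()
        match = False

    e_r, e_p = opt_r.energy_kj_per_mol, opt_p.energy_kj_per_mol
    e_ts = ts.energy_kj_per_mol
    imag = [f for f in freq.frequencies_cm if f < 0]
    # synthesis direction: its reactants are the fragmentation's products
    return RefinedPath(
        record=record,
        reactant_opt_energy=e_p, product_opt_energy=e_r,
        saddle_energy=e_ts,
        barrier_forward=e_ts - e_p, barrier_reverse=e_ts - e_r,
        n_imaginary=freq.n_imaginary,
        zpve_ts=freq.zpve_kj_per_mol,
        imaginary_frequency_cm=float(imag[0]) if imag else None,
        irc_endpoint_signatures=(sig_minus, sig_plus),
        endpoints_match_event=match,
        neb_converged=band.converged, saddle_converged=ts.converged,
        images=[im.copy() for im in band.images],
        elements=elements,
    )


# ---------------------------------------------------------------------------
# report

def emit_report(records, filter_reports, refinements, path,
                provenance: Optional[dict] = None,
                n_events_detected: Optional[int] = None,
                refinement_failures: Optional[list] = None) -> dict:
    """Assemble and validate the single machine-readable run report."""
    report = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "provenance": provenance or {},
        "n_events_detected": (n_events_detected if n_events_detected is not None
                              else len(records)),
        "reactions": [r.to_dict() for r in records],
        "filters": [fr.to_dict() for fr in filter_reports],
        "refinements": [r.to_dict() for r in refinements],
        "refinement_failures": refinement_failures or [],
    }
    counts = {
        "detected": report["n_events_detected"],
        "records": len(records),
        "passed_all_filters": len(
            set.intersection(*[set(fr.passed_indices) for fr in filter_reports])
            if filter_reports else set()),
    }
    report["counts"] = counts
    validate_report(report)
    if path is not None:
        _write_json(report, Path(path))
    return report


def validate_report(report: dict) -> None:
    required = ("schema_version", "provenance", "reactions", "filters",
                "refinements", "counts", "n_events_detected")
    missing = [k for k in required if k not in report]
    if missing:
        raise ValueError(f"report schema violation: missing keys {missing}")
    if report["schema_version"] != REPORT_SCHEMA_VERSION:
        raise ValueError("report schema violation: wrong schema_version")
    if report["counts"]["records"] != len(report["reactions"]):
        raise ValueError("report schema violation: record count mismatch")
    for fr in report["filters"]:
        if len(fr["entries"]) != len(report["reactions"]):
            raise ValueError("report schema violation: filter does not cover all records")


# ---------------------------------------------------------------------------
# full pipeline

def run_pipeline(config: RunConfig, output_dir: Optional[Path] = None,
                 trajectory_id: str = "traj") -> dict:
    """Discovery → selection → refinement, writing all artifacts.

    Returns a summary dict with the report and in-memory stage outputs.
    """
    out = Path(output_dir) if output_dir is not None else config.output_dir
    out.mkdir(parents=True, exist_ok=True)
    prov_block = provenance_block(config)
    provider = make_provider(config.provider)

    packed = stage_pack(config)
    write_systems_xyz([packed], out / "packed.xyz")
    traj = stage_dynamics(config, packed)
    write_xyz(traj, out / "trajectory.xyz")

    events = stage_detect(config, traj)
    _write_json({"provenance": prov_block,
                 "events": [event_to_dict(e) for e in events]},
                out / "events.json")

    screen = stage_screen(config, events, trajectory_id)
    _write_json({"provenance": prov_block,
                 "records": [r.to_dict() for r in screen["records"]],
                 "filters": [fr.to_dict() for fr in screen["filter_reports"]],
                 "passing": screen["passing_indices"]},
                out / "screening.json")

    refinements: list[RefinedPath] = []
    failures: list[dict] = []
    for rev in screen["reversed_records"]:
        src_traj, src_idx = rev.provenance[0]
        try:
            refined = refine_event(events[src_idx], rev, provider, config)
        except (ValueError, RuntimeError) as exc:
            failures.append({"record": rev.to_dict(), "reason": str(exc)})
            continue
        refinements.append(refined)
        stem = out / f"path_{len(refinements) - 1}"
        write_systems_xyz(
            [AtomicSystem.from_elements(refined.elements, im)
             for im in refined.images],
            stem.with_suffix(".xyz"))

    report = emit_report(screen["records"], screen["filter_reports"], refinements,
                         out / "report.json", provenance=prov_block,
                         n_events_detected=len(events),
                         refinement_failures=failures)
    return {"packed": packed, "trajectory": traj, "events": events,
            "screen": screen, "refinements": refinements,
            "refinement_failures": failures, "report": report}
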