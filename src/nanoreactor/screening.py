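"""Retrosynthetic screening of detected reaction events.

Events discovered in the compression-driven dynamics run in the
*fragmentation* direction (the target molecule breaks apart).  Reading
them in reverse turns an endothermic fragmentation into a candidate
exothermic synthesis route.  Two astrochemical plausibility filters are
applied before reversal:

* bimolecularity — the fragmentation must yield exactly two products, so
  the reversed reaction is a two-body collision (three-body encounters
  are negligible at interstellar densities, and isolated unimolecular
  rearrangements are not spontaneously driven at ≤20 K);
* exothermic reverse — the forward ΔE must be strictly positive, i.e.
  the precursors of the reversed reaction lie above its products.

Energies are electronic minimized-fragment sums in kJ/mol; records with
|ΔE| below 5 kJ/mol are flagged ``marginal`` for human review rather
than auto-decided.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from . import units
from .bondgraph import Fragment, ReactionEvent
from .forcefields import ForceProvider
from .refine import minimize

MARGINAL_KJ_PER_MOL = 5.0

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def _composition(fragments) -> Counter:
    total: Counter = Counter()
    for frag in fragments:
        for sym, count in _FORMULA_TOKEN.findall(frag.formula):
            if sym:
                total[sym] += int(count) if count else 1
    return total


@dataclass(frozen=True)
class FragmentEnergy:
    signature: str
    formula: str
    energy_kj_per_mol: float
    positions: Optional[np.ndarray] = None
    elements: tuple[str, ...] = ()
    converged: bool = True


@dataclass
class ReactionRecord:
    reactants: list[FragmentEnergy]
    products: list[FragmentEnergy]
    e_reactants: float            # kJ/mol, sum of minimized fragment energies
    e_products: float             # kJ/mol
    delta_e: float                # kJ/mol, products - reactants
    direction: str = "forward"    # "forward" | "reversed"
    provenance: list[tuple[str, int]] = field(default_factory=list)
    flags: list[str] = field(default_factory=list)
    annotation: str = ""          # free text (e.g. novelty notes); never filtered on

    def __post_init__(self) -> None:
        if abs(self.delta_e - (self.e_products - self.e_reactants)) > 1e-9:
            raise ValueError("delta_e inconsistent with e_products - e_reactants")
        if _composition(self.reactants) != _composition(self.products):
            raise ValueError("atom conservation violated across reaction sides")

    @property
    def signature_pair(self) -> tuple[tuple[str, ...], tuple[str, ...]]:
        return (tuple(sorted(f.signature for f in self.reactants)),
                tuple(sorted(f.signature for f in self.products)))

    def to_dict(self) -> dict:
        def side(frs):
            return [{"signature": f.signature, "formula": f.formula,
                     "energy_kj_per_mol": f.energy_kj_per_mol} for f in frs]
        return {
            "reactants": side(self.reactants),
            "products": side(self.products),
            "e_reactants_kj_per_mol": self.e_reactants,
            "e_products_kj_per_mol": self.e_products,
            "delta_e_kj_per_mol": self.delta_e,
            "direction": self.direction,
            "provenance": [list(p) for p in self.provenance],
            "flags": list(self.flags),
            "annotation": self.annotation,
        }


def _minimized_fragment(frag: Fragment, provider: ForceProvider,
                        grad_tol: float, max_step: float) -> FragmentEnergy:
    if frag.positions is None:
        raise ValueError(f"fragment {frag.formula} carries no geometry")
    if len(frag.atoms) == 1:
        e, _ = provider.evaluate(np.asarray(frag.positions, dtype=float), frag.elements)
        return FragmentEnergy(frag.signature, frag.formula,
                              e * units.EU_TO_KJ_PER_MOL,
                              np.asarray(frag.positions, dtype=float),
                              frag.elements, True)
    opt = minimize(frag.positions, provider, frag.elements,
                   max_step=max_step, grad_tol=grad_tol)
    return FragmentEnergy(frag.signature, frag.formula, opt.energy_kj_per_mol,
                          opt.positions, frag.elements, opt.converged)


def build_record(event: ReactionEvent, provider: ForceProvider,
                 trajectory_id: str = "traj", event_index: int = 0,
                 grad_tol: float = 1e-4, max_step: float = 0.015) -> ReactionRecord:
    """Minimize each event fragment independently (no piston) and assemble
    the energetic reaction record; unconverged minimizations flag the
    record instead of dropping it."""
    reactants = [_minimized_fragment(f, provider, grad_tol, max_step)
                 for f in event.reactant_fragments]
    products = [_minimized_fragment(f, provider, grad_tol, max_step)
                for f in event.product_fragments]
    e_r = sum(f.energy_kj_per_mol for f in reactants)
    e_p = sum(f.energy_kj_per_mol for f in products)
    flags = []
    for side, frs in (("reactants", reactants), ("products", products)):
        for f in frs:
            if not f.converged:
                flags.append(f"unconverged_minimization:{side}:{f.formula}")
    if abs(e_p - e_r) < MARGINAL_KJ_PER_MOL:
        flags.append("marginal")
    return ReactionRecord(reactants=reactants, products=products,
                          e_reactants=e_r, e_products=e_p, delta_e=e_p - e_r,
                          provenance=[(trajectory_id, event_index)], flags=flags)


@dataclass
class FilterReport:
    criterion: str
    entries: list[tuple[int, bool, str]]   # (record index, passed, reason)

    @property
    def passed_indices(self) -> list[int]:
        return [i for i, ok, _ in self.entries if ok]

    def to_dict(self) -> dict:
        return {"criterion": self.criterion,
                "entries": [{"record": i, "passed": ok, "reason": r}
                            for i, ok, r in self.entries]}


def filter_bimolecular(records: Sequence[ReactionRecord]) -> FilterReport:
    """Pass iff the forward (fragmentation) side has exactly two products,
    so the reversed synthesis is a two-body collision."""
    entries = []
    for idx, rec in enumerate(records):
        n = len(rec.products)
        if n == 2:
            entries.append((idx, True, "bimolecular reverse"))
        elif n == 1:
            entries.append((idx, False, "unimolecular (no spontaneous rearrangement "
                                        "at interstellar conditions)"))
        else:
            entries.append((idx, False, "termolecular reverse"))
    return FilterReport("bimolecular", entries)


def filter_exothermic_reverse(records: Sequence[ReactionRecord]) -> FilterReport:
    """Pass iff forward ΔE > 0 strictly: the reversed synthesis direction is
    exothermic (precursors above products)."""
    entries = []
    for idx, rec in enumerate(records):
        if rec.delta_e > 0:
            entries.append((idx, True, f"forward endothermic (+{rec.delta_e:.2f} kJ/mol)"))
        elif rec.delta_e == 0:
            entries.append((idx, False, "thermoneutral (strict inequality required)"))
        else:
            entries.append((idx, False, f"forward exothermic ({rec.delta_e:.2f} kJ/mol)"))
    return FilterReport("exothermic_reverse", entries)


def apply_zpve(record: ReactionRecord, zpve_reactants: Sequence[float],
               zpve_products: Sequence[float]) -> ReactionRecord:
    """Return a copy with per-fragment ZPVEs (kJ/mol) folded into the
    energies, for workflows that have run the frequency analysis; the
    default records stay electronic-only."""
    if len(zpve_reactants) != len(record.reactants) or \
            len(zpve_products) != len(record.products):
        raise ValueError("one ZPVE per fragment required")
    reactants = [replace(f, energy_kj_per_mol=f.energy_kj_per_mol + z)
                 for f, z in zip(record.reactants, zpve_reactants)]
    products = [replace(f, energy_kj_per_mol=f.energy_kj_per_mol + z)
                for f, z in zip(record.products, zpve_products)]
    e_r = sum(f.energy_kj_per_mol for f in reactants)
    e_p = sum(f.energy_kj_per_mol for f in products)
    return replace(record, reactants=reactants, products=products,
                   e_reactants=e_r, e_products=e_p, delta_e=e_p - e_r,
                   flags=record.flags + ["zpve_corrected"])


def reverse_record(record: ReactionRecord) -> ReactionRecord:
    """Swap sides, negate ΔE and toggle the direction flag (an involution)."""
    return replace(
        record,
        reactants=list(record.products),
        products=list(record.reactants),
        e_reactants=record.e_products,
        e_products=record.e_reactants,
        delta_e=-record.delta_e,
        direction="reversed" if record.direction == "forward" else "forward",
        provenance=list(record.provenance),
        flags=list(record.flags),
    )


def reverse_and_dedup(records: Sequence[ReactionRecord]) -> list[ReactionRecord]:
    """Reverse all records into the synthesis direction and merge duplicates.

    Records whose unordered (reactant-signatures, product-signatures)
    pairs coincide are merged into one, concatenating provenance — the
    "observed twice in separate simulations" case.
    """
    merged: dict = {}
    order: list = []
    for rec in records:
        rev = reverse_record(rec)
        key = rev.signature_pair
        if key in merged:
            merged[key].provenance.extend(rev.provenance)
            for fl in rev.flags:
                if fl not in merged[key].flags:
                    merged[key].flags.append(fl)
        else:
            merged[key] = rev
            order.append(key)
    return [merged[k] for k in order]
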