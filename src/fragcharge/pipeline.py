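"""Fragment -> fit -> assemble orchestration shared by the CLI, the MEP
sweep and the self-consistent solvation loop."""

from __future__ import annotations

from dataclasses import dataclass, field

from .assembly import AssemblyLedger, TwoBodyFits, assemble_charges
from .espfit import FitConfig, SubsystemFitResult, fit_subsystem
from .fragmentation import (build_concaps, build_fragments,
                            find_two_body_pairs)
from .qm import QMBackend
from .structure import ChargeSet, Structure


@dataclass
class ChargeResult:
    charges: ChargeSet
    ledger: AssemblyLedger
    fragment_fits: list[SubsystemFitResult]
    concap_fits: list[SubsystemFitResult]
    pair_fits: list[TwoBodyFits]
    residuals: dict[str, float] = field(default_factory=dict)


def compute_charges(structure: Structure, reference: ChargeSet,
                    backend: QMBackend, lam: float = 4.0,
                    fit_config: FitConfig | None = None,
                    extra_background=None) -> ChargeResult:
    """Run the full charge pipeline on one structure.

    ``extra_background`` (positions, values) is appended to every
    subsystem's embedding background; the solvation loop feeds induced
    surface charges through it.
    """
    fit_config = fit_config or FitConfig()
    fragments = build_fragments(structure, reference)
    concaps = build_concaps(structure, reference)
    pairs = find_two_body_pairs(structure, lam, reference)

    frag_fits: dict[int, SubsystemFitResult] = {}
    residuals: dict[str, float] = {}
    fragment_results = []
    for frag in fragments:
        fit = fit_subsystem(structure, frag, backend, reference, fit_config,
                            extra_background=extra_background)
        frag_fits[frag.center_residue_index] = fit
        fragment_results.append(fit)
        residuals[frag.label] = fit.fitted.rms_residual

    concap_results = []
    for concap in concaps:
        fit = fit_subsystem(structure, concap, backend, reference, fit_config,
                            fragment_fits=frag_fits,
                            extra_background=extra_background)
        concap_results.append(fit)
        residuals[concap.label] = fit.fitted.rms_residual

    pair_results = []
    for tb in pairs:
        fits = {}
        for key, sub in (("pair", tb.pair), ("mono_i", tb.mono_i),
                         ("mono_j", tb.mono_j)):
            fit = fit_subsystem(structure, sub, backend, reference,
                                fit_config, extra_background=extra_background)
            fits[key] = fit
            residuals[sub.label] = fit.fitted.rms_residual
        pair_results.append(TwoBodyFits(fits["pair"], fits["mono_i"],
                                        fits["mono_j"], tb))

    charges, ledger = assemble_charges(structure, fragment_results,
                                       concap_results, pair_results)
    return ChargeResult(charges=charges, ledger=ledger,
                        fragment_fits=fragment_results,
                        concap_fits=concap_results,
                        pair_fits=pair_results,
                        residuals=residuals)


def charges_to_json(structure: Structure, result: ChargeResult) -> dict:
    """JSON-serialisable summary of a charge run."""
    return {
        "provenance": result.charges.provenance,
        "total_charge": result.charges.total,
        "charges": [
            {"serial": a.serial, "name": a.name,
             "residue": structure.residues[a.residue_index - 1].name,
             "residue_index": a.residue_index,
             "charge": round(float(result.charges.values[i]), 10)}
            for i, a in enumerate(structure.atoms)],
        "fit_residuals": {k: round(v, 12)
                          for k, v in sorted(result.residuals.items())},
        "n_fragments": len(result.fragment_fits),
        "n_concaps": len(result.concap_fits),
        "n_pairs": len(result.pair_fits),
    }


def manifest_for(structure: Structure, fragments, concaps, pairs) -> dict:
    """Subsystem inventory with atom index maps and flagged link atoms."""
    def sub_entry(sub):
        return {
            "label": sub.label,
            "kind": sub.kind,
            "net_charge": sub.net_charge,
            "member_atoms": list(map(int, sub.member_atoms)),
            "link_atoms": [
                {"position": [round(float(x), 6) for x in la.position],
                 "donor": int(la.donor_index),
                 "removed": int(la.removed_index),
                 "cut_bond": la.description}
                for la in sub.link_atoms],
        }

    return {
        "n_atoms": structure.n_atoms,
        "n_residues": structure.n_residues,
        "chain_breaks": list(map(int, structure.chain_breaks)),
        "fragments": [sub_entry(f) for f in fragments],
        "concaps": [sub_entry(c) for c in concaps],
        "pairs": [{"i": tb.i, "j": tb.j,
                   "closest_distance": round(float(tb.closest_distance), 6),
                   "pair": sub_entry(tb.pair),
                   "mono_i": sub_entry(tb.mono_i),
                   "mono_j": sub_entry(tb.mono_j)} for tb in pairs],
    }
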