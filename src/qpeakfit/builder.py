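"""Turn a match into an atomic model and suggest the manual polishing steps.

Matched peaks are first placed as carbon atoms — element assignment from
residual-map heights alone is unreliable, so chemistry-aware reassignment is
emitted as an explicit suggestion list instead of being applied silently.
Candidate atoms with no matching peak are added at their transformed
template positions and flagged, mirroring the completion a crystallographer
would perform by hand.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .candidates import Candidate
from .matching import Cluster, MatchResult
from .structures import AtomSite, HostStructure

__all__ = ["GuestModel", "place_guest_as_carbons", "suggest_atom_types", "polish_checklist"]

_DEFAULT_U_ISO = 0.05  # Å²; starting displacement parameter for placed atoms


@dataclass
class GuestModel:
    """Guest-only atomic model with per-atom provenance.

    ``provenance[k]`` is the matched peak label, or ``"added"`` for an atom
    completed from the candidate template.  ``suggested_elements`` carries
    the candidate's element for every atom (the sites themselves stay carbon
    until suggestions are applied).  ``rings`` lists aromatic rings by atom
    label for downstream π-stacking analysis.
    """

    atoms: list[AtomSite]
    provenance: list[str]
    suggested_elements: list[str]
    candidate_name: str = ""
    rings: list[tuple[str, ...]] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.atoms)
        if len(self.provenance) != n or len(self.suggested_elements) != n:
            raise ValueError("provenance and suggested_elements must cover every atom")

    def atom_by_label(self, label: str) -> AtomSite:
        for a in self.atoms:
            if a.label == label:
                return a
        raise KeyError(label)


def place_guest_as_carbons(
    match: MatchResult, cluster: Cluster, host: HostStructure, candidate: Candidate
) -> GuestModel:
    """Place matched peaks as carbons; complete missing atoms from the template.

    Matched atoms sit exactly at the realized cluster coordinates of their
    peaks; unmatched candidate atoms are placed at the match transform's
    image of the template geometry and flagged ``provenance="added"``.
    Occupancies start at 1.0.
    """
    if not match.correspondence:
        raise ValueError("match has an empty correspondence")
    if match.candidate_name != candidate.name:
        raise ValueError(
            f"match is for {match.candidate_name!r}, candidate is {candidate.name!r}"
        )
    bad = [i for i in match.correspondence if not 0 <= i < len(cluster)]
    if bad:
        raise ValueError(f"match references cluster points {bad} outside the cluster")

    conf = candidate.conformers[match.conformer_index]
    atom_to_peak = {a: i for i, a in match.correspondence.items()}
    carts = []
    provenance: list[str] = []
    labels_by_atom: dict[int, str] = {}
    for a in range(candidate.n_atoms):
        labels_by_atom[a] = f"C{a + 1}"
        if a in atom_to_peak:
            peak_idx = atom_to_peak[a]
            carts.append(cluster.coords[peak_idx])
            provenance.append(cluster.peak_refs[peak_idx][0])
        else:
            carts.append(match.rotation @ conf[a] + match.translation)
            provenance.append("added")
    fracs = np.array([host.cell.cart_to_frac(c) for c in carts])
    # wrap the molecule rigidly (centroid into the cell) — wrapping atoms
    # independently would tear a guest sitting across a cell face
    fracs -= np.floor(fracs.mean(axis=0))
    atoms = [
        AtomSite(
            label=labels_by_atom[a],
            element="C",
            frac=fracs[a],
            occupancy=1.0,
            u_iso=_DEFAULT_U_ISO,
        )
        for a in range(candidate.n_atoms)
    ]
    rings = [tuple(labels_by_atom[a] for a in ring) for ring in candidate.rings]
    return GuestModel(
        atoms=atoms,
        provenance=provenance,
        suggested_elements=list(candidate.elements),
        candidate_name=candidate.name,
        rings=rings,
    )


def suggest_atom_types(model: GuestModel) -> list[tuple[str, str]]:
    """Element reassignments implied by the candidate: ``(atom label, target)``.

    Empty exactly when the candidate is all-carbon (e.g. cyclohexane);
    applying every suggestion reproduces the candidate's heavy-atom formula.
    """
    return [
        (atom.label, want)
        for atom, want in zip(model.atoms, model.suggested_elements)
        if want != atom.element
    ]


def apply_suggestions(model: GuestModel) -> GuestModel:
    """Return a copy of the model with all element suggestions applied."""
    atoms = [
        AtomSite(
            label=a.label, element=want, frac=np.array(a.frac),
            occupancy=a.occupancy, u_iso=a.u_iso,
        )
        for a, want in zip(model.atoms, model.suggested_elements)
    ]
    return GuestModel(
        atoms=atoms,
        provenance=list(model.provenance),
        suggested_elements=list(model.suggested_elements),
        candidate_name=model.candidate_name,
        rings=list(model.rings),
    )


def polish_checklist(model: GuestModel, unexplained_peaks: list[str]) -> dict:
    """Machine-readable checklist of the manual refinement steps that remain.

    The builder never deletes peaks it cannot explain; they are surfaced here
    for a chemist's judgement."""
    reassignments = suggest_atom_types(model)
    return {
        "candidate": model.candidate_name,
        "atom_type_reassignments": [
            {"atom": label, "from": "C", "to": el} for label, el in reassignments
        ],
        "added_atoms": [
            a.label for a, prov in zip(model.atoms, model.provenance) if prov == "added"
        ],
        "unexplained_peaks": list(unexplained_peaks),
        "remaining_manual_steps": [
            "review unexplained peaks; remove spurious atoms if chemically implausible",
            "apply suggested atom-type reassignments",
            "anisotropic refinement of non-hydrogen atoms",
            "add hydrogen atoms from chemical knowledge",
            "geometric (DFIX) and displacement (SIMU/ISOR/EADP) restraints if needed",
            "extinction correction (EXTI) if refinement statistics warrant it",
        ],
    }
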