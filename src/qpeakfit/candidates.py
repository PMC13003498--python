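"""Candidate guest molecules: element-labeled heavy-atom graphs with 3D conformers.

Candidates come either from SMILES (distance-geometry embedding + force-field
cleanup through RDKit) or from user-supplied template coordinates.  Hydrogens
are stripped after embedding: residual electron-diffraction maps in this
regime resolve heavy atoms only, so matching is done on the heavy-atom
skeleton throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem, Lipinski

__all__ = [
    "Candidate",
    "CandidateSet",
    "candidate_from_smiles",
    "candidate_from_coords",
    "default_candidates",
    "BUILTIN_GUESTS",
]

#: Heavy-atom bond-length window (Å) for organic molecules; used both to
#: validate templates and as the default peak-connectivity window downstream.
BOND_WINDOW = (1.1, 1.8)

#: The ten screening guests shipped as the default library: common lab
#: solvents, solids and vapors spanning sizes, polarities and binding motifs.
BUILTIN_GUESTS: dict[str, str] = {
    "DMF": "CN(C)C=O",
    "DEF": "CCN(CC)C=O",
    "pyridine": "c1ccncc1",
    "cyclohexane": "C1CCCCC1",
    "urea": "NC(N)=O",
    "2-methylimidazole": "Cc1ncc[nH]1",
    "benzoic acid": "OC(=O)c1ccccc1",
    "ethyl acetate": "CCOC(C)=O",
    "benzaldehyde": "O=Cc1ccccc1",
    "isovaleraldehyde": "CC(C)CC=O",
}


@dataclass
class Candidate:
    """A guest hypothesis: heavy-atom elements, bonds and ≥1 conformer (Å).

    ``rings`` lists aromatic rings as index tuples; used downstream for
    π-stacking analysis of the placed guest.
    """

    name: str
    elements: list[str]
    conformers: list[np.ndarray]
    bonds: list[tuple[int, int]]
    smiles: str | None = None
    rings: list[tuple[int, ...]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.conformers:
            raise ValueError(f"candidate {self.name!r} has no conformers")
        n = len(self.elements)
        for k, conf in enumerate(self.conformers):
            conf = np.asarray(conf, dtype=float)
            if conf.shape != (n, 3):
                raise ValueError(f"candidate {self.name!r} conformer {k} has wrong shape")
            self.conformers[k] = conf
        if any(e.upper() == "H" for e in self.elements):
            raise ValueError(f"candidate {self.name!r} contains hydrogen entries")
        lo, hi = BOND_WINDOW
        for (i, j) in self.bonds:
            for k, conf in enumerate(self.conformers):
                d = float(np.linalg.norm(conf[i] - conf[j]))
                if not lo <= d <= hi:
                    raise ValueError(
                        f"candidate {self.name!r}: bond {i}-{j} is {d:.3f} Å in conformer {k}, "
                        f"outside [{lo}, {hi}] Å"
                    )

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def pairwise_distances(self, conformer_index: int = 0) -> np.ndarray:
        """Symmetric heavy-atom distance matrix (Å) of one conformer."""
        if not 0 <= conformer_index < len(self.conformers):
            raise IndexError(
                f"conformer index {conformer_index} out of range for {self.name!r} "
                f"({len(self.conformers)} conformers)"
            )
        c = self.conformers[conformer_index]
        diff = c[:, None, :] - c[None, :, :]
        return np.sqrt((diff * diff).sum(axis=-1))


@dataclass
class CandidateSet:
    candidates: list[Candidate]

    def __post_init__(self) -> None:
        names = [c.name for c in self.candidates]
        if len(set(names)) != len(names):
            raise ValueError("candidate names are not unique")

    def __iter__(self):
        return iter(self.candidates)

    def __len__(self) -> int:
        return len(self.candidates)

    def get(self, name: str) -> Candidate:
        for c in self.candidates:
            if c.name == name:
                return c
        raise KeyError(name)


def candidate_from_smiles(
    name: str,
    smiles: str,
    n_conformers: int | None = None,
    seed: int = 0xC0FFEE & 0x7FFFFFFF,
) -> Candidate:
    """Build a candidate from SMILES via seeded distance-geometry embedding.

    Embeds with hydrogens, relaxes with MMFF (UFF fallback), then strips
    hydrogens.  ``n_conformers`` defaults to 5 for molecules with at least
    one rotatable bond and 1 otherwise; matching later picks the best
    conformer, which is how torsional flexibility is handled.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparsable SMILES for candidate {name!r}: {smiles!r}")
    if n_conformers is None:
        n_conformers = 5 if Lipinski.NumRotatableBonds(mol) >= 1 else 1
    if n_conformers < 1:
        raise ValueError("n_conformers must be >= 1")

    molh = Chem.AddHs(mol)
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed) & 0x7FFFFFFF
    conf_ids = AllChem.EmbedMultipleConfs(molh, numConfs=n_conformers, params=params)
    if len(conf_ids) == 0:
        # retry with random coordinates before giving up
        params.useRandomCoords = True
        conf_ids = AllChem.EmbedMultipleConfs(molh, numConfs=n_conformers, params=params)
    if len(conf_ids) == 0:
        raise ValueError(f"3D embedding failed for candidate {name!r} ({smiles!r})")
    try:
        AllChem.MMFFOptimizeMoleculeConfs(molh, maxIters=500)
    except Exception:
        AllChem.UFFOptimizeMoleculeConfs(molh, maxIters=500)

    heavy = Chem.RemoveHs(molh)
    elements = [a.GetSymbol() for a in heavy.GetAtoms()]
    conformers = [np.array(heavy.GetConformer(cid).GetPositions()) for cid in range(heavy.GetNumConformers())]
    bonds = [
        (b.GetBeginAtomIdx(), b.GetEndAtomIdx()) for b in heavy.GetBonds()
    ]
    rings = [
        tuple(ring)
        for ring in heavy.GetRingInfo().AtomRings()
        if all(heavy.GetAtomWithIdx(i).GetIsAromatic() for i in ring)
    ]
    return Candidate(
        name=name, elements=elements, conformers=conformers, bonds=bonds,
        smiles=smiles, rings=rings,
    )


def candidate_from_coords(
    name: str,
    elements: list[str],
    coords: np.ndarray,
    bonds: list[tuple[int, int]],
) -> Candidate:
    """Single-conformer candidate from template coordinates (Å).

    Bond lengths are validated against the organic heavy-atom window; a bond
    outside it raises listing the offending pair.
    """
    coords = np.asarray(coords, dtype=float)
    if not np.all(np.isfinite(coords)):
        raise ValueError(f"candidate {name!r}: non-finite coordinates")
    return Candidate(name=name, elements=list(elements), conformers=[coords], bonds=list(bonds))


def default_candidates(seed: int = 0xC0FFEE & 0x7FFFFFFF) -> CandidateSet:
    """The built-in ten-guest screening library, embedded deterministically."""
    return CandidateSet(
        [candidate_from_smiles(name, smi, seed=seed) for name, smi in BUILTIN_GUESTS.items()]
    )
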