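"""Host–guest interaction classification and the symmetry-clash occupancy cap.

Contacts are classified into four mutually exclusive kinds in priority
order: metal coordination (metal···guest O), hydrogen bonding
(donor/acceptor heavy atoms N/O···O/N — hydrogen positions are unavailable
before refinement, so the donor–acceptor distance stands in for the D–H···A
geometry), offset π-stacking (aromatic-ring centroid of the guest to the
nearest framework atom), and van der Waals as the residual class for guests
with none of the specific contacts.  All distances are minimum-image and
symmetry-aware.

The occupancy cap formalizes a steric argument: if a guest overlaps
sterically with k−1 of its own symmetry images (mutually), at most one copy
in k can be present in any given cell, so the site occupancy cannot exceed
1/k — e.g. 50% for a guest clashing with exactly one twofold-related image.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .builder import GuestModel
from .cell import SymOp, UnitCell, wrap_frac
from .structures import HostStructure

__all__ = [
    "InteractionParams",
    "Interaction",
    "classify_contacts",
    "ring_centroid",
    "occupancy_cap",
    "check_occupancy",
]


@dataclass(frozen=True)
class InteractionParams:
    """Distance windows (Å) for contact classification.

    ``coord_range`` is the metal–oxygen coordination window (default the
    Bi-carboxylate/Bi-oxo range 2.4–2.86 Å); ``hbond_range`` the
    donor–acceptor N/O···O/N window; ``pistack_max`` the guest-ring-centroid
    to framework-atom cutoff; ``clash_dist`` the heavy-atom separation below
    which simultaneous occupancy is chemically infeasible.
    """

    coord_range: tuple[float, float] = (2.4, 2.86)
    hbond_range: tuple[float, float] = (2.5, 3.1)
    pistack_max: float = 3.7
    clash_dist: float = 2.2
    metals: tuple[str, ...] = ("Bi",)

    def __post_init__(self) -> None:
        for name in ("coord_range", "hbond_range"):
            lo, hi = getattr(self, name)
            if not 0 < lo < hi:
                raise ValueError(f"{name} must be positive and ordered")
        if self.pistack_max <= 0 or self.clash_dist <= 0:
            raise ValueError("pistack_max and clash_dist must be positive")


@dataclass
class Interaction:
    """One classified host–guest contact."""

    kind: str  # coordination | hydrogen_bond | pi_stacking | van_der_waals
    guest_atom: str  # atom label or "centroid(<labels>)"
    host_atom: str
    distance: float
    symop: str  # triplet of the host-site image realizing the distance


def _sym_min_distance(
    cell: UnitCell, symops: list[SymOp], p_frac: np.ndarray, q_frac: np.ndarray
) -> tuple[float, SymOp]:
    """Minimum-image distance from p to the nearest symmetry image of q."""
    best, best_op = np.inf, symops[0]
    for op in symops:
        d = cell.min_image_distance(p_frac, wrap_frac(op.apply(q_frac)))
        if d < best:
            best, best_op = d, op
    return best, best_op


def ring_centroid(model: GuestModel, ring_atom_labels: list[str], cell: UnitCell) -> np.ndarray:
    """Unweighted Cartesian centroid (Å) of an approximately coplanar ring.

    Rejects rings of fewer than three atoms or with out-of-plane deviation
    above 0.3 Å (which also rejects collinear, degenerate 'rings')."""
    if len(ring_atom_labels) < 3:
        raise ValueError("ring needs at least 3 atoms")
    pts = np.array([cell.frac_to_cart(model.atom_by_label(lb).frac) for lb in ring_atom_labels])
    center = pts.mean(axis=0)
    centered = pts - center
    # smallest singular vector = best-fit plane normal; collinear sets have
    # two near-zero singular values and every normal fits, so check spread too
    u, s, vt = np.linalg.svd(centered)
    if s[1] < 1e-6:
        raise ValueError("ring atoms are collinear (degenerate ring)")
    deviation = np.abs(centered @ vt[2])
    if deviation.max() > 0.3:
        raise ValueError(
            f"ring atoms deviate {deviation.max():.2f} Å from coplanarity (> 0.3 Å)"
        )
    return center


def classify_contacts(
    host: HostStructure,
    guest: GuestModel,
    params: InteractionParams = InteractionParams(),
) -> list[Interaction]:
    """Classify every host–guest contact; guarantees ≥1 label per guest.

    Pair kinds are mutually exclusive (coordination takes precedence over
    hydrogen bonding); a guest with no specific contact is reported as a
    single van-der-Waals-stabilized entry citing its nearest framework
    contact."""
    cell = host.cell
    out: list[Interaction] = []
    classified_pairs: set[tuple[str, str]] = set()

    nearest_any = (np.inf, "", "", SymOp.identity())
    for ga in guest.atoms:
        g_el = ga.element
        for hs in host.sites:
            d, op = _sym_min_distance(cell, host.symops, ga.frac, hs.frac)
            if d < nearest_any[0]:
                nearest_any = (d, ga.label, hs.label, op)
            pair = (ga.label, hs.label)
            if (
                hs.element in params.metals
                and g_el == "O"
                and params.coord_range[0] <= d <= params.coord_range[1]
            ):
                out.append(Interaction("coordination", ga.label, hs.label, d, op.triplet()))
                classified_pairs.add(pair)
            elif (
                g_el in ("N", "O")
                and hs.element in ("N", "O")
                and params.hbond_range[0] <= d <= params.hbond_range[1]
                and pair not in classified_pairs
            ):
                out.append(Interaction("hydrogen_bond", ga.label, hs.label, d, op.triplet()))
                classified_pairs.add(pair)

    for ring in guest.rings:
        try:
            centroid = ring_centroid(guest, list(ring), cell)
        except ValueError:
            continue
        c_frac = cell.cart_to_frac(centroid)
        best = (np.inf, "", SymOp.identity())
        for hs in host.sites:
            d, op = _sym_min_distance(cell, host.symops, c_frac, hs.frac)
            if d < best[0]:
                best = (d, hs.label, op)
        if best[0] <= params.pistack_max:
            out.append(
                Interaction(
                    "pi_stacking",
                    f"centroid({','.join(ring)})",
                    best[1],
                    best[0],
                    best[2].triplet(),
                )
            )

    if not out:
        d, glabel, hlabel, op = nearest_any
        out.append(Interaction("van_der_waals", glabel, hlabel, d, op.triplet()))
    return out


def _guest_images(
    host: HostStructure, guest_frac: np.ndarray
) -> list[tuple[SymOp, tuple[int, int, int], np.ndarray]]:
    """All symmetry+one-shell-lattice images of the guest, reference excluded.

    The molecule is wrapped rigidly (by its centroid), never atom-by-atom:
    independent wrapping would tear a molecule that straddles a cell face
    and create phantom partial overlaps with the reference copy."""
    images = []
    for op in host.symops:
        base = np.array([op.apply(f) for f in guest_frac])
        base -= np.floor(base.mean(axis=0))  # rigid shift: centroid into [0,1)^3
        for shift in itertools.product((-1, 0, 1), repeat=3):
            img = base + np.asarray(shift, dtype=float)
            if np.abs(img - guest_frac).max() < 1e-8:
                continue  # the reference copy itself
            images.append((op, shift, img))
    return images


def occupancy_cap(
    host: HostStructure,
    guest: GuestModel,
    params: InteractionParams = InteractionParams(),
) -> float:
    """Maximum chemically allowed site occupancy under symmetry self-clash.

    Builds the clash graph over the reference guest copy and its
    symmetry/lattice images (clash = any heavy-atom pair closer than
    ``clash_dist``) and returns 1/k where k is the largest mutually
    clashing set containing the reference; 1.0 when no image clashes.
    Images coinciding with the reference (guest on a special position) are
    not counted as clashes."""
    cell = host.cell
    ref_frac = np.array([a.frac for a in guest.atoms])
    ref_cart = cell.frac_to_cart(ref_frac)

    def clashes(c1: np.ndarray, c2: np.ndarray) -> bool:
        diff = c1[:, None, :] - c2[None, :, :]
        dmin = np.sqrt((diff * diff).sum(axis=-1)).min()
        return dmin < params.clash_dist

    candidates = []
    for op, shift, frac in _guest_images(host, ref_frac):
        cart = cell.frac_to_cart(frac)
        # a coincident image (special position) is the same physical molecule
        if np.abs(cart - ref_cart).max() < 1e-6:
            continue
        if clashes(ref_cart, cart):
            candidates.append(cart)
    if not candidates:
        return 1.0

    graph = nx.Graph()
    graph.add_node(-1)  # the reference copy
    for i, cart in enumerate(candidates):
        graph.add_node(i)
        graph.add_edge(-1, i)
    for i, j in itertools.combinations(range(len(candidates)), 2):
        if clashes(candidates[i], candidates[j]):
            graph.add_edge(i, j)

    k = max(len(c) for c in nx.find_cliques(graph) if -1 in c)
    return 1.0 / k


def check_occupancy(refined_occupancy: float, cap: float) -> dict:
    """Sanity-check a refined occupancy against the symmetry-clash cap."""
    return {
        "refined_occupancy": refined_occupancy,
        "cap": cap,
        "consistent": refined_occupancy <= cap + 1e-9,
    }
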