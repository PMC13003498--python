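"""Seeded synthetic Q-peak generator with known ground truth.

Emulates the observable the matcher consumes — a residual-map peak list for
a guest sitting in a periodic host — with controlled corruption: isotropic
Gaussian positional jitter (σ), random peak deletion, and spurious peaks
placed away from the molecule.  What it deliberately does not emulate:
electron scattering physics, peak-height systematics of real refinement
residuals, framework relaxation, or disorder.  Passing recovery tests on
this generator therefore demonstrates the geometric identification logic,
not map quality on real data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .candidates import CandidateSet
from .cell import SymOp, UnitCell, parse_symop, wrap_frac
from .structures import AtomSite, HostStructure, QPeak, QPeakSet

__all__ = [
    "SimulationSpec",
    "SimulatedCase",
    "simulate_qpeaks",
    "make_host_fixture",
    "I2A_TRIPLETS",
    "SPONGE_HOST_CELL",
]

#: Full operator list of space group I2/a (order 8: 4 general positions x
#: I-centering), shipped explicitly rather than derived from a symbol table.
I2A_TRIPLETS = (
    "x,y,z",
    "-x+1/2,y,-z",
    "-x,-y,-z",
    "x+1/2,-y,z",
    "x+1/2,y+1/2,z+1/2",
    "-x,y+1/2,-z+1/2",
    "-x+1/2,-y+1/2,-z+1/2",
    "x,-y+1/2,z+1/2",
)

#: Synthetic monoclinic I-centered cell of roughly the volume of a
#: bismuth-tricarboxylate sponge framework (~3650 Å³).
SPONGE_HOST_CELL = UnitCell(15.2, 11.1, 21.8, 90.0, 96.1, 90.0)


def make_host_fixture() -> HostStructure:
    """Synthetic sponge-like host: I2/a symmetry, one Bi center, a few O sites.

    A stand-in framework for interaction and round-trip tests — the metal
    and oxygen sites are placed at plausible but invented positions."""
    ops = [parse_symop(t) for t in I2A_TRIPLETS]
    sites = [
        AtomSite("BI1", "Bi", np.array([0.104, 0.121, 0.083]), u_iso=0.02),
        AtomSite("O1", "O", np.array([0.148, 0.253, 0.104]), u_iso=0.03),
        AtomSite("O2", "O", np.array([0.021, 0.049, 0.132]), u_iso=0.03),
        AtomSite("O1W", "O", np.array([0.201, 0.047, 0.021]), u_iso=0.04),
        AtomSite("C1", "C", np.array([0.230, 0.310, 0.140]), u_iso=0.04),
    ]
    return HostStructure(
        cell=SPONGE_HOST_CELL, symops=ops, sites=sites, name="synthetic-sponge-host"
    )


@dataclass(frozen=True)
class SimulationSpec:
    """Conditions for one synthetic Q-peak set.

    ``sigma`` is the isotropic per-atom positional jitter (Å); each true
    peak is deleted with probability ``p_miss`` (or exactly ``n_miss`` peaks
    when that is set); ``n_spurious`` extra peaks are placed uniformly in
    the cell at least ``min_spurious_sep`` Å from every true peak so ground
    truth stays unambiguous.  ``height_model = (true mean, spurious mean,
    spread)`` in the arbitrary height units of residual maps; true peaks
    stochastically dominate spurious ones.
    """

    candidate_name: str
    seed: int
    cell: UnitCell = SPONGE_HOST_CELL
    symop_triplets: tuple[str, ...] = ("x,y,z",)
    sigma: float = 0.05
    p_miss: float = 0.0
    n_miss: int | None = None
    n_spurious: int = 0
    height_model: tuple[float, float, float] = (4.0, 1.5, 0.5)
    min_spurious_sep: float = 2.5

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if not 0 <= self.p_miss < 1:
            raise ValueError("p_miss must be in [0, 1)")
        if self.n_spurious < 0:
            raise ValueError("n_spurious must be >= 0")

    @property
    def symops(self) -> list[SymOp]:
        return [parse_symop(t) for t in self.symop_triplets]


@dataclass
class SimulatedCase:
    """A synthetic Q-peak set plus the ground truth that produced it."""

    qpeaks: QPeakSet
    candidate_name: str
    rotation: np.ndarray  # candidate conformer-0 frame -> cell Cartesian frame
    translation: np.ndarray  # Å
    peak_truth: dict[str, int | str]  # label -> source atom index, or "spurious"


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
            [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
            [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
        ]
    )


def simulate_qpeaks(spec: SimulationSpec, candidates: CandidateSet) -> SimulatedCase:
    """Generate one seeded Q-peak set from a posed, jittered, corrupted guest.

    The pose is a uniform random rotation plus a translation that keeps every
    heavy atom inside one cell (so the reference copy needs no wrapping);
    symmetry images then arise downstream in clustering.  Fully reproducible
    per seed."""
    rng = np.random.default_rng(spec.seed)
    cand = candidates.get(spec.candidate_name)
    conf = cand.conformers[0]
    centered = conf - conf.mean(axis=0)

    rotation = _random_rotation(rng)
    rotated = centered @ rotation.T

    placed_cart = None
    translation = None
    for _ in range(500):
        center_frac = rng.uniform(0.2, 0.8, size=3)
        center_cart = spec.cell.frac_to_cart(center_frac)
        cart = rotated + center_cart
        frac = spec.cell.cart_to_frac(cart)
        if np.all(frac > 0.02) and np.all(frac < 0.98):
            placed_cart = cart
            translation = center_cart - rotation @ conf.mean(axis=0)
            break
    if placed_cart is None:
        raise RuntimeError(
            f"could not place {spec.candidate_name!r} inside the cell after 500 attempts"
        )

    true_cart = placed_cart + rng.normal(0.0, spec.sigma, size=placed_cart.shape)
    n = len(true_cart)

    if spec.n_miss is not None:
        if spec.n_miss >= n:
            raise ValueError("n_miss must leave at least one peak")
        deleted = set(rng.choice(n, size=spec.n_miss, replace=False).tolist())
    else:
        deleted = set(np.nonzero(rng.random(n) < spec.p_miss)[0].tolist())
    kept = [i for i in range(n) if i not in deleted]

    true_fracs = spec.cell.cart_to_frac(true_cart)
    spurious_fracs = []
    for _ in range(spec.n_spurious):
        for _attempt in range(500):
            f = rng.uniform(0.0, 1.0, size=3)
            if all(
                spec.cell.min_image_distance(f, tf) >= spec.min_spurious_sep
                for tf in true_fracs
            ):
                spurious_fracs.append(f)
                break
        else:
            raise RuntimeError("could not place a spurious peak away from the molecule")

    mu_t, mu_s, sd = spec.height_model
    true_heights = np.maximum(rng.normal(mu_t, sd, size=len(kept)), 0.05)
    spur_heights = np.maximum(rng.normal(mu_s, sd, size=len(spurious_fracs)), 0.05)

    records = [(true_fracs[i], float(h), i) for i, h in zip(kept, true_heights)]
    records += [(f, float(h), "spurious") for f, h in zip(spurious_fracs, spur_heights)]
    records.sort(key=lambda r: -r[1])

    peaks = []
    truth: dict[str, int | str] = {}
    for k, (frac, height, src) in enumerate(records, start=1):
        label = f"Q{k}"
        peaks.append(QPeak(label=label, frac=wrap_frac(frac), height=height))
        truth[label] = src

    host = HostStructure(
        cell=spec.cell,
        symops=spec.symops,
        sites=[AtomSite("X1", "C", np.zeros(3))],  # placeholder framework marker
        name=f"synthetic:{spec.candidate_name}",
    )
    return SimulatedCase(
        qpeaks=QPeakSet(host=host, peaks=peaks),
        candidate_name=spec.candidate_name,
        rotation=rotation,
        translation=np.asarray(translation),
        peak_truth=truth,
    )
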