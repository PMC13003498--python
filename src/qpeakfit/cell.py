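"""Crystallographic geometry: unit cells, symmetry operators, periodic distances.

All fractional coordinates are dimensionless triples referred to the cell
axes; Cartesian coordinates are in Å under the standard orthogonalization
convention (``a`` along ``x``, ``b`` in the ``xy`` plane).  Distances are
convention-independent.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import gemmi
import numpy as np

__all__ = [
    "UnitCell",
    "SymOp",
    "parse_symop",
    "expand_equivalents",
    "wrap_frac",
]


def wrap_frac(p: np.ndarray) -> np.ndarray:
    """Reduce fractional coordinates into [0, 1)."""
    return np.asarray(p, dtype=float) % 1.0


@dataclass(frozen=True)
class UnitCell:
    """Triclinic unit cell: edge lengths in Å, angles in degrees.

    The orthogonalization matrix ``M`` maps fractional to Cartesian
    coordinates, ``x = M @ p``.  Its columns are the cell vectors with
    ``a`` along Cartesian x and ``b`` in the xy-plane.
    """

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) <= 0:
            raise ValueError(f"cell lengths must be positive: {(self.a, self.b, self.c)}")
        for name in ("alpha", "beta", "gamma"):
            ang = getattr(self, name)
            if not 0.0 < ang < 180.0:
                raise ValueError(f"cell angle {name}={ang} outside (0, 180)")
        ca, cb, cg = (math.cos(math.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        v2 = 1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg
        if v2 <= 0.0:
            raise ValueError("degenerate cell: metric tensor is not positive-definite")

    @property
    def volume(self) -> float:
        ca, cb, cg = (math.cos(math.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        v2 = 1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg
        return self.a * self.b * self.c * math.sqrt(v2)

    @property
    def orthogonalization_matrix(self) -> np.ndarray:
        ca, cb, cg = (math.cos(math.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        sg = math.sin(math.radians(self.gamma))
        v = math.sqrt(1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg)
        return np.array(
            [
                [self.a, self.b * cg, self.c * cb],
                [0.0, self.b * sg, self.c * (ca - cb * cg) / sg],
                [0.0, 0.0, self.c * v / sg],
            ]
        )

    @property
    def metric_tensor(self) -> np.ndarray:
        m = self.orthogonalization_matrix
        return m.T @ m

    def frac_to_cart(self, p: np.ndarray) -> np.ndarray:
        """Cartesian image (Å) of fractional point(s); works on (..., 3) arrays."""
        p = np.asarray(p, dtype=float)
        return p @ self.orthogonalization_matrix.T

    def cart_to_frac(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return x @ np.linalg.inv(self.orthogonalization_matrix).T

    def _perpendicular_widths(self) -> np.ndarray:
        # width of the cell slab along each axis = V / (area of opposite face);
        # bounds how many lattice shells can still shorten a distance
        m = self.orthogonalization_matrix
        av, bv, cv = m[:, 0], m[:, 1], m[:, 2]
        vol = abs(np.dot(av, np.cross(bv, cv)))
        areas = np.array(
            [
                np.linalg.norm(np.cross(bv, cv)),
                np.linalg.norm(np.cross(cv, av)),
                np.linalg.norm(np.cross(av, bv)),
            ]
        )
        return vol / areas

    def min_image_distance(self, p: np.ndarray, q: np.ndarray) -> float:
        """Shortest distance (Å) between fractional points over all lattice translations.

        The wrapped difference vector gives an upper bound; the search radius
        along each axis is then derived from the cell's perpendicular widths,
        which makes the result exact for arbitrarily skewed cells.
        """
        d = np.asarray(p, dtype=float) - np.asarray(q, dtype=float)
        d -= np.round(d)
        d0 = float(np.linalg.norm(self.frac_to_cart(d)))
        if d0 == 0.0:
            return 0.0
        widths = self._perpendicular_widths()
        nmax = np.ceil(d0 / widths).astype(int)
        shifts = np.array(
            list(
                itertools.product(
                    *(range(-int(n), int(n) + 1) for n in nmax)
                )
            ),
            dtype=float,
        )
        cart = self.frac_to_cart(d + shifts)
        return float(np.sqrt((cart * cart).sum(axis=1).min()))

    def min_image_distance_bruteforce(self, p, q, shells: int = 2) -> float:
        """Reference minimum over a fixed (2*shells+1)^3 translation block."""
        d = np.asarray(p, dtype=float) - np.asarray(q, dtype=float)
        rng = range(-shells, shells + 1)
        shifts = np.array(list(itertools.product(rng, rng, rng)), dtype=float)
        cart = self.frac_to_cart(d + shifts)
        return float(np.sqrt((cart * cart).sum(axis=1).min()))


@dataclass(frozen=True)
class SymOp:
    """Space-group operation on fractional coordinates: x' = R x + t (mod 1).

    ``rot`` entries are integers in the fractional basis; ``tran`` components
    are crystallographic fractions reduced modulo 1.
    """

    rot: tuple = field(default=((1, 0, 0), (0, 1, 0), (0, 0, 1)))
    tran: tuple = field(default=(0.0, 0.0, 0.0))

    def __post_init__(self) -> None:
        r = np.asarray(self.rot, dtype=float)
        if r.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        det = round(np.linalg.det(r))
        if det not in (-1, 1):
            raise ValueError(f"rotation determinant {det} is not ±1")
        object.__setattr__(self, "rot", tuple(tuple(int(round(x)) for x in row) for row in r))
        object.__setattr__(self, "tran", tuple(float(t) % 1.0 for t in self.tran))

    @property
    def rot_array(self) -> np.ndarray:
        return np.asarray(self.rot, dtype=float)

    @property
    def tran_array(self) -> np.ndarray:
        return np.asarray(self.tran, dtype=float)

    @property
    def is_identity(self) -> bool:
        return self.rot == ((1, 0, 0), (0, 1, 0), (0, 0, 1)) and all(
            abs(t) < 1e-9 or abs(t - 1.0) < 1e-9 for t in self.tran
        )

    def apply(self, p: np.ndarray) -> np.ndarray:
        """Image of fractional point(s) under the operation (not wrapped)."""
        p = np.asarray(p, dtype=float)
        return p @ self.rot_array.T + self.tran_array

    def compose(self, other: "SymOp") -> "SymOp":
        """self ∘ other, translation reduced modulo lattice."""
        r = self.rot_array @ other.rot_array
        t = self.rot_array @ other.tran_array + self.tran_array
        return SymOp(tuple(map(tuple, r.astype(int))), tuple(t % 1.0))

    def triplet(self) -> str:
        """CIF xyz-triplet form, e.g. ``x+1/2,-y,z``."""
        den = gemmi.Op.DEN
        op = gemmi.Op()
        op.rot = [[int(v) * den for v in row] for row in self.rot]
        op.tran = [int(round(t * den)) for t in self.tran]
        return op.triplet()

    @classmethod
    def identity(cls) -> "SymOp":
        return cls()


def parse_symop(text: str) -> SymOp:
    """Parse a CIF ``_symmetry_equiv_pos_as_xyz`` triplet such as ``"1/2+x, -y, z"``.

    Raises ``ValueError`` naming the offending triplet on malformed input or
    non-crystallographic coefficients.
    """
    try:
        op = gemmi.Op(text)
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"cannot parse symmetry triplet {text!r}: {exc}") from exc
    den = gemmi.Op.DEN
    rot = np.asarray(op.rot, dtype=float) / den
    if not np.allclose(rot, np.round(rot)):
        raise ValueError(f"non-integral rotation part in symmetry triplet {text!r}")
    tran = np.asarray(op.tran, dtype=float) / den
    return SymOp(tuple(map(tuple, np.round(rot).astype(int))), tuple(tran))


def expand_equivalents(
    cell: UnitCell, ops: list[SymOp], p: np.ndarray, dedup_tol: float = 0.1
) -> list[np.ndarray]:
    """Orbit of fractional point ``p`` under ``ops``, wrapped into [0,1)³.

    Images closer than ``dedup_tol`` Å (minimum-image metric) are merged, so a
    point on a special position returns fewer images than the group order.
    """
    if not ops:
        raise ValueError("operator list is empty")
    if not any(op.is_identity for op in ops):
        raise ValueError("operator list must contain the identity")
    out: list[np.ndarray] = []
    for op in ops:
        img = wrap_frac(op.apply(p))
        if all(cell.min_image_distance(img, prev) >= dedup_tol for prev in out):
            out.append(img)
    return out
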