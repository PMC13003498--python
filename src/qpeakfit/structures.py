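"""Core containers: atom sites, host structures and residual-density peaks."""

from __future__ import annotations

from dataclasses import dataclass, field

import gemmi
import numpy as np

from .cell import SymOp, UnitCell, wrap_frac

__all__ = ["AtomSite", "HostStructure", "QPeak", "QPeakSet"]


def _check_element(symbol: str) -> str:
    el = gemmi.Element(symbol)
    if el.atomic_number == 0:
        raise ValueError(f"unrecognized element symbol {symbol!r}")
    return el.name


@dataclass
class AtomSite:
    """One crystallographic site: label, element, fractional position, occupancy."""

    label: str
    element: str
    frac: np.ndarray
    occupancy: float = 1.0
    u_iso: float | None = None
    raw: str | None = field(default=None, compare=False, repr=False)

    def __post_init__(self) -> None:
        self.element = _check_element(self.element)
        self.frac = np.asarray(self.frac, dtype=float)
        if self.frac.shape != (3,):
            raise ValueError("frac must be a 3-vector")
        if not 0.0 < self.occupancy <= 1.0:
            raise ValueError(f"occupancy {self.occupancy} outside (0, 1]")


@dataclass
class HostStructure:
    """Guest-free framework model: cell, symmetry and atom sites.

    Fractional coordinates are normalized into [0,1) on construction.  When
    parsed from a SHELX file the original header lines are retained so a
    guest-extended ins file can preserve them verbatim.
    """

    cell: UnitCell
    symops: list[SymOp]
    sites: list[AtomSite]
    name: str = "host"
    shelx_header: list[str] | None = field(default=None, compare=False, repr=False)

    def __post_init__(self) -> None:
        if not self.sites:
            raise ValueError("host structure has no atom sites")
        if not self.symops:
            self.symops = [SymOp.identity()]
        for s in self.sites:
            s.frac = wrap_frac(s.frac)

    @property
    def elements(self) -> list[str]:
        seen: list[str] = []
        for s in self.sites:
            if s.element not in seen:
                seen.append(s.element)
        return seen


@dataclass
class QPeak:
    """A residual electrostatic-potential maximum.

    Heights are kept exactly as read; only their relative ordering is
    meaningful (refinement programs do not put them on an absolute scale).
    """

    label: str
    frac: np.ndarray
    height: float

    def __post_init__(self) -> None:
        self.frac = np.asarray(self.frac, dtype=float)
        if self.frac.shape != (3,):
            raise ValueError("frac must be a 3-vector")


@dataclass
class QPeakSet:
    """Q-peak list tied to the host whose residual map produced it."""

    host: HostStructure
    peaks: list[QPeak]

    def __post_init__(self) -> None:
        labels = [p.label for p in self.peaks]
        if len(set(labels)) != len(labels):
            raise ValueError("Q-peak labels are not unique")

    def sorted_by_height(self) -> list[QPeak]:
        return sorted(self.peaks, key=lambda p: -p.height)
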