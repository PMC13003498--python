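"""Readers and writers: SHELX res/ins, CIF, tabular Q-peak lists, JSON reports.

SHELX files are the native carriers of Q-peaks (refinement programs append
them after the atom list of a ``.res`` file); CIF covers hosts coming from
databases; a plain TSV dialect (label, x, y, z, height) serves users without
SHELX output.  All files are UTF-8 and use decimal points regardless of
locale.
"""

from __future__ import annotations

import json
from pathlib import Path

import gemmi
import numpy as np

from .cell import SymOp, UnitCell, parse_symop, wrap_frac
from .structures import AtomSite, HostStructure, QPeak, QPeakSet

__all__ = [
    "read_res",
    "read_cif_structure",
    "read_qpeaks_tsv",
    "write_ins_model",
    "write_report",
    "read_report",
]

# SHELX instruction keywords; any other leading token with >=5 fields is an atom
_SHELX_KEYWORDS = {
    "TITL", "CELL", "ZERR", "LATT", "SYMM", "SFAC", "DISP", "UNIT", "LAUE",
    "REM", "MORE", "TIME", "OMIT", "SHEL", "BASF", "TWIN", "EXTI", "SWAT",
    "HOPE", "MERG", "SPEC", "RESI", "MOVE", "ANIS", "AFIX", "HFIX", "FRAG",
    "FEND", "EXYZ", "EADP", "EQIV", "CONN", "PART", "BIND", "FREE", "DFIX",
    "DANG", "BUMP", "SAME", "SADI", "CHIV", "FLAT", "DELU", "SIMU", "DEFS",
    "ISOR", "NCSY", "SUMP", "L.S.", "CGLS", "BLOC", "DAMP", "STIR", "WGHT",
    "FVAR", "BOND", "CONF", "MPLA", "RTAB", "HTAB", "LIST", "ACTA", "SIZE",
    "TEMP", "WPDB", "FMAP", "GRID", "PLAN", "MOLE", "HKLF", "END", "ABIN",
    "ANSC", "ANSR", "NEUT", "PRIG", "XNPD", "TANG",
}

# LATT centering translations by |code|
_LATT_CENTERING = {
    1: [],
    2: [(0.5, 0.5, 0.5)],
    3: [(2 / 3, 1 / 3, 1 / 3), (1 / 3, 2 / 3, 2 / 3)],
    4: [(0.0, 0.5, 0.5), (0.5, 0.0, 0.5), (0.5, 0.5, 0.0)],
    5: [(0.0, 0.5, 0.5)],
    6: [(0.5, 0.0, 0.5)],
    7: [(0.5, 0.5, 0.0)],
}


def expand_latt_symm(latt: int, symm_ops: list[SymOp]) -> list[SymOp]:
    """Expand SHELX LATT/SYMM cards into the full operator list.

    SYMM cards list the non-identity rotational part of the primitive group;
    a positive LATT code adds the inversion through the origin, and |LATT|
    selects the centering translations.
    """
    code = abs(latt)
    if code not in _LATT_CENTERING:
        raise ValueError(f"unknown LATT code {latt}")
    base = [SymOp.identity()] + [op for op in symm_ops if not op.is_identity]
    if latt > 0:
        inv = SymOp(((-1, 0, 0), (0, -1, 0), (0, 0, -1)))
        base = base + [inv.compose(op) for op in base]
    ops: list[SymOp] = []
    seen: set = set()
    for op in base:
        for t in [(0.0, 0.0, 0.0)] + _LATT_CENTERING[code]:
            shifted = SymOp(op.rot, tuple((np.asarray(op.tran) + t) % 1.0))
            key = (shifted.rot, tuple(round(x * 24) % 24 for x in shifted.tran))
            if key not in seen:
                seen.add(key)
                ops.append(shifted)
    return ops


def _parse_floats(tokens: list[str], lineno: int, path: str) -> list[float]:
    try:
        return [float(t) for t in tokens]
    except ValueError as exc:
        raise ValueError(f"{path}:{lineno}: non-numeric field in {tokens}") from exc


def read_res(path) -> tuple[HostStructure, QPeakSet]:
    """Parse a SHELX res/ins file into a host structure plus its Q-peak list.

    Q-peaks (labels ``Q1``, ``Q2``, ...) are returned sorted by height
    descending.  The header lines up to the first atom are retained on the
    host for verbatim round-tripping through :func:`write_ins_model`.
    """
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()

    cell: UnitCell | None = None
    latt = 1  # SHELX default: centrosymmetric primitive
    symm: list[SymOp] = []
    sfac: list[str] = []
    name = path.stem
    header: list[str] = []
    sites: list[AtomSite] = []
    peaks: list[QPeak] = []
    in_atoms = False

    for lineno, rawline in enumerate(lines, start=1):
        line = rawline.rstrip()
        if not line.strip():
            continue
        tokens = line.split()
        key = tokens[0].upper()
        if key in _SHELX_KEYWORDS:
            if key == "TITL":
                name = line[4:].strip() or name
            elif key == "CELL":
                vals = _parse_floats(tokens[1:8], lineno, str(path))
                if len(vals) < 7:
                    raise ValueError(f"{path}:{lineno}: CELL needs wavelength + 6 parameters")
                cell = UnitCell(*vals[1:7])
            elif key == "LATT":
                latt = int(tokens[1])
            elif key == "SYMM":
                symm.append(parse_symop(line[4:].strip()))
            elif key == "SFAC":
                sfac.extend(t.capitalize() for t in tokens[1:] if not _is_number(t))
            if not in_atoms and key not in ("HKLF", "END"):
                header.append(line)
            continue
        # atom or Q-peak line
        if len(tokens) < 5:
            raise ValueError(f"{path}:{lineno}: atom line has fewer than 5 fields: {line!r}")
        label = tokens[0]
        numeric = _parse_floats(tokens[1:], lineno, str(path))
        if len(numeric) < 4:
            raise ValueError(f"{path}:{lineno}: atom line has fewer than 5 numeric fields")
        in_atoms = True
        sfac_idx = int(numeric[0])
        xyz = np.array(numeric[1:4])
        sof = numeric[4] if len(numeric) > 4 else 11.0
        occ = sof - 10.0 if sof >= 10.0 else sof
        if label.upper().startswith("Q") and label[1:].isdigit():
            height = numeric[-1]
            peaks.append(QPeak(label=label, frac=xyz, height=height))
            continue
        if not 1 <= sfac_idx <= len(sfac):
            raise ValueError(
                f"{path}:{lineno}: scattering-factor index {sfac_idx} outside SFAC list {sfac}"
            )
        u_iso = numeric[5] if len(numeric) > 5 else None
        sites.append(
            AtomSite(
                label=label,
                element=sfac[sfac_idx - 1],
                frac=xyz,
                occupancy=min(occ, 1.0),
                u_iso=u_iso,
                raw=line,
            )
        )

    if cell is None:
        raise ValueError(f"{path}: missing CELL card")
    host = HostStructure(
        cell=cell,
        symops=expand_latt_symm(latt, symm),
        sites=sites,
        name=name,
        shelx_header=header,
    )
    peaks.sort(key=lambda p: -p.height)
    return host, QPeakSet(host=host, peaks=peaks)


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


def read_cif_structure(path) -> HostStructure:
    """Read a host structure from a CIF file (cell, symmetry loop, atom sites).

    Occupancy defaults to 1.0 when the ``_atom_site_occupancy`` column is
    absent; an absent symmetry loop means P1.
    """
    doc = gemmi.cif.read(str(path))
    block = doc.sole_block()

    def need(tag: str) -> str:
        val = block.find_value(tag)
        if val is None:
            raise ValueError(f"{path}: missing mandatory CIF tag {tag}")
        return val

    cell = UnitCell(
        *(gemmi.cif.as_number(need(t)) for t in (
            "_cell_length_a", "_cell_length_b", "_cell_length_c",
            "_cell_angle_alpha", "_cell_angle_beta", "_cell_angle_gamma",
        ))
    )
    symops = []
    for tag in ("_symmetry_equiv_pos_as_xyz", "_space_group_symop_operation_xyz"):
        col = block.find_loop(tag)
        triplets = [gemmi.cif.as_string(v) for v in col]
        if triplets:
            symops = [parse_symop(t) for t in triplets]
            break
    if not symops:
        symops = [SymOp.identity()]

    labels = block.find_loop("_atom_site_label")
    if not list(labels):
        raise ValueError(f"{path}: missing mandatory CIF loop _atom_site_label")
    table = block.find(
        "_atom_site_",
        ["label", "?type_symbol", "fract_x", "fract_y", "fract_z", "?occupancy", "?U_iso_or_equiv"],
    )
    sites = []
    for row in table:
        label = row.str(0)
        element = row.str(1) if row.has(1) else _element_from_label(label)
        frac = np.array([gemmi.cif.as_number(row[i]) for i in (2, 3, 4)])
        occ = gemmi.cif.as_number(row[5]) if row.has(5) else 1.0
        u = gemmi.cif.as_number(row[6]) if row.has(6) else None
        sites.append(AtomSite(label=label, element=element, frac=frac, occupancy=occ, u_iso=u))
    return HostStructure(cell=cell, symops=symops, sites=sites, name=block.name or Path(path).stem)


def _element_from_label(label: str) -> str:
    head = "".join(c for c in label if c.isalpha())[:2]
    if len(head) == 2 and gemmi.Element(head).atomic_number == 0:
        head = head[0]
    return head.capitalize()


def read_qpeaks_tsv(path, host: HostStructure) -> QPeakSet:
    """Read the plain tabular Q-peak dialect: label, x, y, z, height per line."""
    peaks = []
    for lineno, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        tokens = line.split()
        if len(tokens) < 5:
            raise ValueError(f"{path}:{lineno}: expected 'label x y z height'")
        vals = _parse_floats(tokens[1:5], lineno, str(path))
        peaks.append(QPeak(label=tokens[0], frac=np.array(vals[:3]), height=vals[3]))
    peaks.sort(key=lambda p: -p.height)
    return QPeakSet(host=host, peaks=peaks)


def _format_atom_line(site: AtomSite, sfac_index: int) -> str:
    sof = 10.0 + site.occupancy  # SHELX fixed-parameter convention
    u = site.u_iso if site.u_iso is not None else 0.05
    return (
        f"{site.label:<8s}{sfac_index:>2d} {site.frac[0]:10.6f} {site.frac[1]:10.6f} "
        f"{site.frac[2]:10.6f} {sof:10.5f} {u:9.5f}"
    )


def write_ins_model(host: HostStructure, guest_atoms: list[AtomSite], path) -> None:
    """Write a refinement-ready SHELX ins file: host plus placed guest atoms.

    When the host was parsed from a res file its header and atom lines are
    reproduced byte-for-byte; guest atoms are appended with the scattering
    factor index of their element, extending the SFAC card if needed.
    """
    sfac: list[str] = []
    lines: list[str] = []
    if host.shelx_header is not None:
        lines = list(host.shelx_header)
        for ln in lines:
            if ln.split() and ln.split()[0].upper() == "SFAC":
                sfac = [t.capitalize() for t in ln.split()[1:] if not _is_number(t)]
    else:
        sfac = list(host.elements)
        lines.append(f"TITL {host.name}")
        c = host.cell
        lines.append(
            f"CELL 0.02510 {c.a:9.4f} {c.b:9.4f} {c.c:9.4f} {c.alpha:8.3f} {c.beta:8.3f} {c.gamma:8.3f}"
        )
        lines.append("ZERR 1 0 0 0 0 0 0")
        lines.append("LATT -1")
        for op in host.symops:
            if not op.is_identity:
                lines.append(f"SYMM {op.triplet()}")
        lines.append("SFAC " + " ".join(sfac))
        lines.append("UNIT " + " ".join("1" for _ in sfac))
        lines.append("FVAR 1.00000")

    # extend SFAC for guest elements not yet representable
    extra = [a.element for a in guest_atoms if a.element not in sfac]
    for el in extra:
        if el not in sfac:
            sfac.append(el)
    if extra:
        for i, ln in enumerate(lines):
            toks = ln.split()
            if toks and toks[0].upper() == "SFAC":
                lines[i] = "SFAC " + " ".join(sfac)
            elif toks and toks[0].upper() == "UNIT":
                lines[i] = "UNIT " + " ".join(["1"] * len(sfac))

    body: list[str] = []
    for site in host.sites:
        if site.raw is not None:
            body.append(site.raw)
        else:
            body.append(_format_atom_line(site, sfac.index(site.element) + 1))
    for site in guest_atoms:
        body.append(_format_atom_line(site, sfac.index(site.element) + 1))

    text = "\n".join(lines + body + ["HKLF 4", "END"]) + "\n"
    Path(path).write_text(text, encoding="utf-8")


REPORT_SCHEMA_VERSION = 1


def ranking_to_dict(ranking) -> dict:
    return {
        "schema_version": REPORT_SCHEMA_VERSION,
        "tie_tol": ranking.tie_tol,
        "entries": [
            {
                "rank": e.rank,
                "candidate": r.candidate_name,
                "conformer": r.conformer_index,
                "rmsd": r.rmsd,
                "coverage": r.coverage,
                "score": r.score,
                "matched_peaks": list(r.matched_peak_labels),
                "correspondence": {str(k): v for k, v in r.correspondence.items()},
                "rotation": np.asarray(r.rotation).tolist(),
                "translation": np.asarray(r.translation).tolist(),
            }
            if r is not None
            else {"rank": e.rank, "candidate": e.candidate_name, "score": None}
            for e in ranking.entries
            for r in [e.result]
        ],
    }


def write_report(ranking, path) -> None:
    """Serialize a candidate ranking as versioned JSON."""
    if not ranking.entries:
        raise ValueError("refusing to write an empty ranking report")
    Path(path).write_text(
        json.dumps(ranking_to_dict(ranking), indent=2, sort_keys=True) + "\n",
        encoding="utf-8",
    )


def read_report(path):
    """Reconstruct a Ranking from a JSON report written by :func:`write_report`."""
    from .matching import MatchResult, Ranking, RankedEntry

    data = json.loads(Path(path).read_text(encoding="utf-8"))
    entries = []
    for e in data["entries"]:
        if e.get("score") is None:
            entries.append(RankedEntry(rank=e["rank"], candidate_name=e["candidate"], result=None))
            continue
        res = MatchResult(
            candidate_name=e["candidate"],
            conformer_index=e["conformer"],
            correspondence={int(k): v for k, v in e["correspondence"].items()},
            rotation=np.array(e["rotation"]),
            translation=np.array(e["translation"]),
            rmsd=e["rmsd"],
            coverage=e["coverage"],
            score=e["score"],
            matched_peak_labels=tuple(e["matched_peaks"]),
        )
        entries.append(RankedEntry(rank=e["rank"], candidate_name=e["candidate"], result=res))
    return Ranking(entries=entries, tie_tol=data.get("tie_tol", 0.01))
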