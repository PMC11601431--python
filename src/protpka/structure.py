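"""Protein structure I/O and per-structure geometry.

Reads PDB (and mmCIF) files into a light-weight heavy-atom representation,
locates the six titratable residue types, and computes solvent-accessible
surface area (Shrake–Rupley) and a three-state secondary-structure
assignment.  Parsing itself is delegated to gemmi; this module owns the
conventions: one conformer per atom (highest occupancy, first on tie),
hydrogens dropped, waters and other heteroatoms kept in a separate ligand
list.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np
from scipy.spatial import cKDTree

from . import _geometry

__all__ = [
    "AtomRecord", "ResidueRecord", "ProteinStructure", "TitratableSite",
    "StructureFormatError", "read_structure", "write_pdb", "make_structure",
    "identify_titratable_sites", "shrake_rupley_sasa",
    "assign_secondary_structure", "ANCHOR_ATOMS", "TITRATABLE_AA",
    "VDW_RADII",
]


class StructureFormatError(ValueError):
    """Raised for unparseable or empty structure input."""


STANDARD_AA = frozenset({
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
})

#: Proton-bearing sidechain atoms of the six titratable residue types.
ANCHOR_ATOMS: dict[str, tuple[str, ...]] = {
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
    "HIS": ("ND1", "NE2"),
    "CYS": ("SG",),
    "TYR": ("OH",),
    "LYS": ("NZ",),
}
TITRATABLE_AA = frozenset(ANCHOR_ATOMS)

#: Fixed heavy-atom van der Waals radii (Å) used for SASA.
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80}
_GENERIC_RADIUS = 1.80


@dataclass
class AtomRecord:
    serial: int
    name: str
    element: str
    coords: np.ndarray
    occupancy: float = 1.0
    altloc: str = ""
    residue_key: tuple[str, int, str] = ("", 0, "")

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"non-finite coordinates for atom {self.name}")
        if not self.element:
            raise ValueError(f"empty element for atom {self.name}")


@dataclass
class ResidueRecord:
    chain: str
    resseq: int
    icode: str
    resname: str
    atoms: list[AtomRecord] = field(default_factory=list)

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain, self.resseq, self.icode)

    def atom(self, name: str) -> AtomRecord | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def coords(self, *names: str) -> np.ndarray | None:
        got = [self.atom(n) for n in names]
        if any(a is None for a in got):
            return None
        return np.array([a.coords for a in got])


@dataclass
class ProteinStructure:
    residues: list[ResidueRecord]
    source_id: str = "structure"
    ligands: list[ResidueRecord] = field(default_factory=list)

    def __post_init__(self):
        if not self.residues:
            raise StructureFormatError("no protein residues")
        keys = [r.key for r in self.residues]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate residue keys")

    def get_residue(self, chain: str, resseq: int, icode: str = "") -> ResidueRecord | None:
        for r in self.residues:
            if r.key == (chain, resseq, icode):
                return r
        return None

    def iter_atoms(self):
        for res in self.residues:
            for atom in res.atoms:
                yield res, atom

    def atom_coords(self) -> np.ndarray:
        return np.array([a.coords for _, a in self.iter_atoms()])


@dataclass
class TitratableSite:
    residue_key: tuple[str, int, str]
    aa: str
    anchor_atoms: tuple[str, ...]
    anchor_point: np.ndarray

    def __post_init__(self):
        if self.aa not in TITRATABLE_AA:
            raise ValueError(f"{self.aa} is not a titratable residue type")
        if not self.anchor_atoms:
            raise ValueError("site has no anchor atoms")
        self.anchor_point = np.asarray(self.anchor_point, dtype=float)


def _element_of(atom: gemmi.Atom) -> str:
    el = atom.element.name.upper() if atom.element else ""
    if not el or el == "X":
        stripped = atom.name.lstrip("0123456789 ")
        el = stripped[:1].upper() if stripped else ""
    return el


def _looks_like_pdb_text(source: str) -> bool:
    head = source.lstrip()[:6].upper()
    return ("\n" in source or head.startswith(("ATOM", "HETATM", "HEADER",
                                              "REMARK", "CRYST", "MODEL")))


def read_structure(source: str | Path) -> ProteinStructure:
    """Read a PDB (or mmCIF) file or PDB-format text.

    Keeps one conformer per atom name (highest occupancy, first on tie),
    drops hydrogens/deuteriums, and routes waters and other non-polymer
    residues to ``ligands``.
    """
    if isinstance(source, Path) or (isinstance(source, str)
                                    and not _looks_like_pdb_text(source)):
        path = Path(source)
        if not path.exists():
            raise StructureFormatError(f"no such structure file: {path}")
        try:
            st = gemmi.read_structure(str(path))
        except (RuntimeError, ValueError) as exc:
            raise StructureFormatError(str(exc)) from exc
        source_id = st.name.strip().lower() or path.stem
    else:
        text = str(source)
        lines = text.splitlines()
        record_lines = [ln for ln in lines
                        if ln[:6].rstrip() in ("ATOM", "HETATM")]
        if not record_lines:
            first = lines[0] if lines else "<empty input>"
            raise StructureFormatError(
                f"no ATOM/HETATM records found; first line: {first!r}")
        bad = [ln for ln in record_lines if len(ln) < 54]
        if bad:
            raise StructureFormatError(f"truncated coordinate record: {bad[0]!r}")
        try:
            st = gemmi.read_pdb_string(text)
        except (RuntimeError, ValueError) as exc:
            raise StructureFormatError(str(exc)) from exc
        info = dict(st.info)
        title = info.get("_struct.title", "").strip()
        source_id = title or "structure"

    if len(st) == 0:
        raise StructureFormatError("structure contains no models")
    model = st[0]
    residues: list[ResidueRecord] = []
    ligands: list[ResidueRecord] = []
    for chain in model:
        for res in chain:
            icode = res.seqid.icode.strip()
            rec = ResidueRecord(chain=chain.name, resseq=res.seqid.num,
                                icode=icode, resname=res.name)
            chosen: dict[str, AtomRecord] = {}
            for atom in res:
                el = _element_of(atom)
                if el in ("H", "D"):
                    continue
                record = AtomRecord(
                    serial=atom.serial, name=atom.name, element=el,
                    coords=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                    occupancy=float(atom.occ),
                    altloc=(atom.altloc or "").strip(),
                    residue_key=rec.key)
                prev = chosen.get(atom.name)
                if prev is None or record.occupancy > prev.occupancy:
                    chosen[atom.name] = record
            rec.atoms = list(chosen.values())
            if not rec.atoms:
                continue
            if res.name in STANDARD_AA:
                residues.append(rec)
            else:
                # waters and other heteroatoms live outside the protein
                # residue list and do not participate in features
                ligands.append(rec)
    if not residues:
        raise StructureFormatError("no protein residues")
    return ProteinStructure(residues=residues, source_id=source_id,
                            ligands=ligands)


def write_pdb(structure: ProteinStructure) -> str:
    """Serialize the retained heavy-atom content back to PDB text.

    The source id is carried in a TITLE record so a write/read round trip
    preserves it.
    """
    lines = [f"TITLE     {structure.source_id}"]
    serial = 0
    for group in (structure.residues, structure.ligands):
        record = "ATOM  " if group is structure.residues else "HETATM"
        for res in group:
            for atom in res.atoms:
                serial += 1
                name = atom.name
                if len(name) < 4 and len(atom.element) == 1:
                    name = " " + name
                lines.append(
                    f"{record}{serial:5d} {name:<4s} {res.resname:>3s} "
                    f"{res.chain[:1]:1s}{res.resseq:4d}{res.icode[:1]:1s}   "
                    f"{atom.coords[0]:8.3f}{atom.coords[1]:8.3f}"
                    f"{atom.coords[2]:8.3f}{atom.occupancy:6.2f}{0.0:6.2f}"
                    f"          {atom.element:>2s}")
    lines.append("END")
    return "\n".join(lines) + "\n"


def make_structure(residue_specs, source_id: str = "synthetic") -> ProteinStructure:
    """Build a ProteinStructure from ``(chain, resseq, icode, resname, {atom: xyz})`` tuples."""
    residues = []
    serial = 0
    for chain, resseq, icode, resname, atom_map in residue_specs:
        rec = ResidueRecord(chain=chain, resseq=resseq, icode=icode,
                            resname=resname)
        for name, xyz in atom_map.items():
            serial += 1
            rec.atoms.append(AtomRecord(
                serial=serial, name=name, element=name.lstrip("0123456789")[0],
                coords=np.asarray(xyz, dtype=float), residue_key=rec.key))
        residues.append(rec)
    return ProteinStructure(residues=residues, source_id=source_id)


def identify_titratable_sites(structure: ProteinStructure) -> list[TitratableSite]:
    """One site per Asp/Glu/His/Cys/Tyr/Lys residue with >= 1 anchor atom.

    The anchor point is the centroid of the anchor atoms present; residues
    missing all anchor atoms are reported via a warning and skipped.
    """
    sites = []
    for res in structure.residues:
        if res.resname not in TITRATABLE_AA:
            continue
        present = [res.atom(n) for n in ANCHOR_ATOMS[res.resname]]
        present = [a for a in present if a is not None]
        if not present:
            warnings.warn(
                f"{structure.source_id}: {res.resname} {res.key} has no "
                f"anchor atoms; skipped", stacklevel=2)
            continue
        anchor = np.mean([a.coords for a in present], axis=0)
        sites.append(TitratableSite(
            residue_key=res.key, aa=res.resname,
            anchor_atoms=tuple(a.name for a in present),
            anchor_point=anchor))
    return sites


def _sphere_points(n: int) -> np.ndarray:
    """Golden-spiral quadrature points on the unit sphere."""
    i = np.arange(n)
    z = 1.0 - (2.0 * i + 1.0) / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    golden = np.pi * (3.0 - np.sqrt(5.0))
    theta = golden * i
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def shrake_rupley_sasa(structure: ProteinStructure, probe_radius: float = 1.4,
                       n_sphere_points: int = 960) -> dict[tuple, float]:
    """Per-atom solvent-accessible surface area (Å²), Shrake–Rupley.

    Returns a map keyed by ``(chain, resseq, icode, atom_name)``.  Only
    protein heavy atoms participate (ligands are neither scored nor
    occluding).  Unknown elements fall back to a generic 1.8 Å radius with
    a warning.
    """
    atoms = [(res, atom) for res, atom in structure.iter_atoms()]
    coords = np.array([a.coords for _, a in atoms])
    radii = np.empty(len(atoms))
    unknown = set()
    for k, (_, atom) in enumerate(atoms):
        r = VDW_RADII.get(atom.element)
        if r is None:
            unknown.add(atom.element)
            r = _GENERIC_RADIUS
        radii[k] = r
    if unknown:
        warnings.warn(f"unknown element(s) {sorted(unknown)}; using generic "
                      f"{_GENERIC_RADIUS} Å radius", stacklevel=2)
    expanded = radii + probe_radius
    unit = _sphere_points(n_sphere_points)
    tree = cKDTree(coords)
    out: dict[tuple, float] = {}
    for k, (res, atom) in enumerate(atoms):
        rk = expanded[k]
        neighbors = [j for j in tree.query_ball_point(coords[k], rk + expanded.max())
                     if j != k and np.linalg.norm(coords[j] - coords[k]) < rk + expanded[j]]
        pts = coords[k] + rk * unit
        if neighbors:
            d2 = ((pts[:, None, :] - coords[neighbors][None, :, :]) ** 2).sum(-1)
            buried = (d2 < (expanded[neighbors] ** 2)[None, :]).any(axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        out[(res.chain, res.resseq, res.icode, atom.name)] = (
            4.0 * np.pi * rk * rk * frac)
    return out


# Dihedral windows for the DSSP-lite 3-state assignment (degrees).
_HELIX_PHI = (-100.0, -30.0)
_HELIX_PSI = (-80.0, -4.0)


def assign_secondary_structure(structure: ProteinStructure) -> dict[tuple, str]:
    """3-state secondary structure {H, E, C} per residue.

    Helix requires helical backbone dihedrals plus an i->i+4 or i->i+3
    amide H-bond surrogate (carbonyl O to amide N distance <= 3.5 Å);
    strand requires extended dihedrals.  Residues with incomplete backbone
    context are coil.
    """
    by_chain: dict[str, list[ResidueRecord]] = {}
    for res in structure.residues:
        by_chain.setdefault(res.chain, []).append(res)
    result = {res.key: "C" for res in structure.residues}
    for chain_residues in by_chain.values():
        n = len(chain_residues)
        phi = [None] * n
        psi = [None] * n
        bb = [r.coords("N", "CA", "C", "O") for r in chain_residues]
        for i in range(n):
            if bb[i] is None:
                continue
            if i > 0 and bb[i - 1] is not None and _bonded(bb[i - 1][2], bb[i][0]):
                phi[i] = _geometry.dihedral(bb[i - 1][2], bb[i][0], bb[i][1], bb[i][2])
            if i < n - 1 and bb[i + 1] is not None and _bonded(bb[i][2], bb[i + 1][0]):
                psi[i] = _geometry.dihedral(bb[i][0], bb[i][1], bb[i][2], bb[i + 1][0])
        for i, res in enumerate(chain_residues):
            if bb[i] is None or phi[i] is None or psi[i] is None:
                continue
            if (_HELIX_PHI[0] <= phi[i] <= _HELIX_PHI[1]
                    and _HELIX_PSI[0] <= psi[i] <= _HELIX_PSI[1]
                    and _helix_hbond(bb, i)):
                result[res.key] = "H"
            elif phi[i] < -90.0 and (psi[i] >= 90.0 or psi[i] <= -150.0):
                result[res.key] = "E"
    return result


def _bonded(c_coord: np.ndarray, n_coord: np.ndarray) -> bool:
    return np.linalg.norm(c_coord - n_coord) < 2.0


def _helix_hbond(bb, i: int, cutoff: float = 3.5) -> bool:
    for j in (i - 4, i - 3):
        if j >= 0 and bb[j] is not None:
            if np.linalg.norm(bb[j][3] - bb[i][0]) <= cutoff:
                return True
    for j in (i + 3, i + 4):
        if j < len(bb) and bb[j] is not None:
            if np.linalg.norm(bb[i][3] - bb[j][0]) <= cutoff:
                return True
    return False
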