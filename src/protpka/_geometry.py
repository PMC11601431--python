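"""Ideal-geometry peptide construction and torsion utilities.

Backbones are grown with the natural-extension-reference-frame (NeRF)
construction from standard bond lengths and angles (Engh–Huber-like values);
sidechains are attached from a small internal-coordinate table with extended
(chi = 180) rotamers.  The geometry is idealised, clash-free and intended for
synthetic microenvironments and reference calculations, not for modelling
real proteins.
"""

from __future__ import annotations

import numpy as np

# backbone geometry (Å, degrees)
B_N_CA = 1.458
B_CA_C = 1.525
B_C_N = 1.329
B_C_O = 1.231
A_N_CA_C = 111.2
A_CA_C_N = 116.2
A_C_N_CA = 121.7
A_CA_C_O = 120.5


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle: float, torsion: float) -> np.ndarray:
    """Position atom D from reference atoms A-B-C.

    ``bond`` is |C-D|, ``angle`` the B-C-D angle in degrees, ``torsion`` the
    A-B-C-D dihedral in degrees.
    """
    ang = np.deg2rad(angle)
    tor = np.deg2rad(torsion)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * np.cos(ang),
        bond * np.sin(ang) * np.cos(tor),
        bond * np.sin(ang) * np.sin(tor),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray,
             p3: np.ndarray) -> float:
    """Signed dihedral angle p0-p1-p2-p3 in degrees, in (-180, 180]."""
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    ang = np.degrees(np.arctan2(y, x))
    return 180.0 if ang <= -180.0 else ang


# Sidechain internal coordinates: atom -> (ref1, ref2, ref3, bond, angle, torsion)
# where the new atom is placed from ref3 with dihedral ref1-ref2-ref3-atom.
# Extended rotamers; ring geometry approximate but clash-free.
_SIDECHAINS: dict[str, list[tuple[str, str, str, str, float, float, float]]] = {
    "ALA": [("CB", "C", "N", "CA", 1.53, 110.5, -122.0)],
    "SER": [("CB", "C", "N", "CA", 1.53, 110.5, -122.0),
            ("OG", "N", "CA", "CB", 1.42, 110.8, 180.0)],
    "CYS": [("CB", "C", "N", "CA", 1.53, 110.5, -122.0),
            ("SG", "N", "CA", "CB", 1.81, 114.4, 180.0)],
    "THR": [("CB", "C", "N", "CA", 1.53, 110.5, -122.0),
            ("OG1", "N", "CA", "CB", 1.43, 109.6, 180.0),
            ("CG2", "N", "CA", "CB", 1.52, 110.5, -60.0)],
    "VAL": [("CB", "C", "N", "CA", 1.53, 110.5, -122.0),
            ("CG1", "N", "CA", "CB", 1.52, 110.5, 180.0),
            ("CG2", "N", "CA", "CB", 1.52, 110.5, -60.0)],
    "LEU": [("CB", "C", "N", "CA", 1.53, 110.5, -122.0),
            ("CG", "N", "CA", "CB", 1.53, 116.3, 180.0),
            ("CD1", "CA", "CB", "CG", 1.52, 110.7, 180.0),
            ("CD2", "CA", "CB", "CG", 1.52, 110.7, 60.0)],
    "ILE": [("CB", "C", "N", "CA", 1.53, 110.5, -122.0),
            ("CG1", "N", "CA", "CB", 1.53, 110.4, 180.0),
            ("CG2", "N", "CA", "CB", 1.52, 110.5, -60.0),
            ("CD1", "CA", "CB", "CG1", 1.51, 113.9, 180.0)],
    "MET": [("CB", "C", "N", "CA", 1.53, 110.5, -122.0),
            ("CG", "N", "CA", "CB", 1.52, 114.1, 180.0),
            ("SD", "CA", "CB", "CG", 1.80, 112.7, 180.0),
            ("CE", "CB", "CG", "SD", 1.79, 100.8, 180.0)],
    "ASP": [("CB", "C", "N", "CA", 1.53, 110.5, -122.0),
            ("CG", "N", "CA", "CB", 1.52, 112.6, 180.0),
            ("OD1", "CA", "CB", "CG", 1.25, 118.4, 0.0),
            ("OD2", "CA", "CB", "CG", 1.25, 118.4, 180.0)],
    "ASN": [("CB", "C", "N", "CA", 1.53, 110.5, -122.0),
            ("CG", "N", "CA", "CB", 1.52, 112.6, 180.0),
            ("OD1", "CA", "CB", "CG", 1.23, 120.8, 0.0),
            ("ND2", "CA", "CB", "CG", 1.33, 116.4, 180.0)],
    "GLU": [("CB", "C", "N", "CA", 1.53, 110.5, -122.0),
            ("CG", "N", "CA", "CB", 1.52, 114.1, 180.0),
            ("CD", "CA", "CB", "CG", 1.52, 112.6, 180.0),
            ("OE1", "CB", "CG", "CD", 1.25, 118.4, 0.0),
            ("OE2", "CB", "CG", "CD", 1.25, 118.4, 180.0)],
    "GLN": [("CB", "C", "N", "CA", 1.53, 110.5, -122.0),
            ("CG", "N", "CA", "CB", 1.52, 114.1, 180.0),
            ("CD", "CA", "CB", "CG", 1.52, 112.6, 180.0),
            ("OE1", "CB", "CG", "CD", 1.23, 120.8, 0.0),
            ("NE2", "CB", "CG", "CD", 1.33, 116.4, 180.0)],
    "LYS": [("CB", "C", "N", "CA", 1.53, 110.5, -122.0),
            ("CG", "N", "CA", "CB", 1.52, 114.1, 180.0),
            ("CD", "CA", "CB", "CG", 1.52, 111.3, 180.0),
            ("CE", "CB", "CG", "CD", 1.52, 111.3, 180.0),
            ("NZ", "CG", "CD", "CE", 1.49, 111.9, 180.0)],
    "ARG": [("CB", "C", "N", "CA", 1.53, 110.5, -122.0),
            ("CG", "N", "CA", "CB", 1.52, 114.1, 180.0),
            ("CD", "CA", "CB", "CG", 1.52, 111.3, 180.0),
            ("NE", "CB", "CG", "CD", 1.46, 112.0, 180.0),
            ("CZ", "CG", "CD", "NE", 1.33, 124.2, 180.0),
            ("NH1", "CD", "NE", "CZ", 1.33, 120.0, 0.0),
            ("NH2", "CD", "NE", "CZ", 1.33, 120.0, 180.0)],
    "HIS": [("CB", "C", "N", "CA", 1.53, 110.5, -122.0),
            ("CG", "N", "CA", "CB", 1.50, 113.8, 180.0),
            ("ND1", "CA", "CB", "CG", 1.38, 122.7, 90.0),
            ("CD2", "CA", "CB", "CG", 1.36, 129.7, -90.0),
            ("CE1", "CB", "CG", "ND1", 1.32, 109.2, 180.0),
            ("NE2", "CG", "ND1", "CE1", 1.32, 108.2, 0.0)],
    "PHE": [("CB", "C", "N", "CA", 1.53, 110.5, -122.0),
            ("CG", "N", "CA", "CB", 1.51, 113.9, 180.0),
            ("CD1", "CA", "CB", "CG", 1.39, 120.8, 90.0),
            ("CD2", "CA", "CB", "CG", 1.39, 120.8, -90.0),
            ("CE1", "CB", "CG", "CD1", 1.39, 121.0, 180.0),
            ("CE2", "CB", "CG", "CD2", 1.39, 121.0, 180.0),
            ("CZ", "CG", "CD1", "CE1", 1.39, 120.0, 0.0)],
    "TYR": [("CB", "C", "N", "CA", 1.53, 110.5, -122.0),
            ("CG", "N", "CA", "CB", 1.51, 113.9, 180.0),
            ("CD1", "CA", "CB", "CG", 1.39, 120.8, 90.0),
            ("CD2", "CA", "CB", "CG", 1.39, 120.8, -90.0),
            ("CE1", "CB", "CG", "CD1", 1.39, 121.0, 180.0),
            ("CE2", "CB", "CG", "CD2", 1.39, 121.0, 180.0),
            ("CZ", "CG", "CD1", "CE1", 1.39, 120.0, 0.0),
            ("OH", "CD1", "CE1", "CZ", 1.38, 119.9, 180.0)],
    "TRP": [("CB", "C", "N", "CA", 1.53, 110.5, -122.0),
            ("CG", "N", "CA", "CB", 1.50, 113.6, 180.0),
            ("CD1", "CA", "CB", "CG", 1.37, 126.9, 90.0),
            ("CD2", "CA", "CB", "CG", 1.43, 126.7, -90.0),
            ("NE1", "CB", "CG", "CD1", 1.38, 110.2, 180.0),
            ("CE2", "CG", "CD1", "NE1", 1.37, 109.0, 0.0)],
    "PRO": [("CB", "C", "N", "CA", 1.53, 103.2, -120.0),
            ("CG", "N", "CA", "CB", 1.49, 104.5, 30.0),
            ("CD", "CA", "CB", "CG", 1.50, 106.1, -30.0)],
    "GLY": [],
}

SUPPORTED_RESIDUES = frozenset(_SIDECHAINS)


def build_peptide(sequence: list[str] | tuple[str, ...],
                  phi: float = -140.0, psi: float = 135.0,
                  omega: float = 180.0) -> list[tuple[str, dict[str, np.ndarray]]]:
    """Build an ideal-geometry peptide with uniform backbone torsions.

    Returns one ``(resname, {atom_name: xyz})`` pair per residue, in chain
    order.  Default torsions give an extended (beta-like) conformation;
    ``phi=-57, psi=-47`` gives an ideal alpha helix.
    """
    unknown = [r for r in sequence if r not in _SIDECHAINS]
    if unknown:
        raise ValueError(f"unsupported residue(s): {unknown}")
    residues: list[tuple[str, dict[str, np.ndarray]]] = []
    n_prev = ca_prev = c_prev = None
    for i, resname in enumerate(sequence):
        atoms: dict[str, np.ndarray] = {}
        if i == 0:
            atoms["N"] = np.zeros(3)
            atoms["CA"] = np.array([B_N_CA, 0.0, 0.0])
            ang = np.deg2rad(A_N_CA_C)
            atoms["C"] = atoms["CA"] + B_CA_C * np.array(
                [-np.cos(ang), np.sin(ang), 0.0])
        else:
            atoms["N"] = place_atom(n_prev, ca_prev, c_prev,
                                    B_C_N, A_CA_C_N, psi)
            atoms["CA"] = place_atom(ca_prev, c_prev, atoms["N"],
                                     B_N_CA, A_C_N_CA, omega)
            atoms["C"] = place_atom(c_prev, atoms["N"], atoms["CA"],
                                    B_CA_C, A_N_CA_C, phi)
        # carbonyl O anti to the next amide N (torsion psi + 180)
        atoms["O"] = place_atom(atoms["N"], atoms["CA"], atoms["C"],
                                B_C_O, A_CA_C_O, psi + 180.0)
        for name, r1, r2, r3, bond, angle, torsion in _SIDECHAINS[resname]:
            atoms[name] = place_atom(atoms[r1], atoms[r2], atoms[r3],
                                     bond, angle, torsion)
        residues.append((resname, atoms))
        n_prev, ca_prev, c_prev = atoms["N"], atoms["CA"], atoms["C"]
    return residues


def rigid_transform(coords: np.ndarray, rotation: np.ndarray,
                    translation: np.ndarray) -> np.ndarray:
    """Apply a rotation matrix then a translation to an (n, 3) array."""
    return coords @ np.asarray(rotation).T + np.asarray(translation)


def rotation_matrix(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rodrigues rotation matrix about ``axis`` by ``angle_deg`` degrees."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    t = np.deg2rad(angle_deg)
    k = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(t) * k + (1 - np.cos(t)) * (k @ k)
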