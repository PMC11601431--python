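"""Atom graphs of 10 Å titratable-site microenvironments.

A site's graph holds every protein heavy atom within 10 Å of the anchor
point (the approximate range of pKa-relevant electrostatics), with
undirected edges between atoms within a 4 Å cutoff (covalent bonds and
close contacts).  Each node carries a 66-wide embedding: a 42-wide
physicochemical block (residue type, per-atom chargeability, aromaticity,
donor/acceptor character, backbone/sidechain role, radial position
relative to the anchor, element group, and flags tying the node to the
central residue) plus a 24-wide one-hot over protein heavy-atom type
classes.  The regression label is the pKa shift ΔpKa = experimental pKa
minus the residue type's solution value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from ..features import model_pka
from ..structure import (ANCHOR_ATOMS, ProteinStructure, TitratableSite,
                         identify_titratable_sites)

__all__ = ["ResidueGraph", "build_graph", "graphs_for_records",
           "NODE_FEATURE_VERSION", "NODE_WIDTH", "BASE_WIDTH",
           "ATOM_TYPE_CLASSES"]

NODE_FEATURE_VERSION = "protpka-node-v1"
BASE_WIDTH = 42
#: 23 named protein heavy-atom type classes plus a catch-all.
ATOM_TYPE_CLASSES = (
    "N", "CA", "C", "O", "OXT", "CB", "CG", "CG1", "CG2", "CD", "CD1",
    "CD2", "CE", "CE1", "CE2", "CZ", "NZ", "NE*", "NH*", "ND*", "OD*",
    "OE*", "O_hydroxyl_thiol", "other")
NODE_WIDTH = BASE_WIDTH + len(ATOM_TYPE_CLASSES)

_AA20 = ("ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS",
         "ILE", "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP",
         "TYR", "VAL")

_NEGATIVE = {("ASP", "OD1"), ("ASP", "OD2"), ("GLU", "OE1"), ("GLU", "OE2")}
_POSITIVE = {("LYS", "NZ"), ("ARG", "NH1"), ("ARG", "NH2"), ("ARG", "NE"),
             ("HIS", "ND1"), ("HIS", "NE2")}
_AROMATIC = {
    "PHE": {"CG", "CD1", "CD2", "CE1", "CE2", "CZ"},
    "TYR": {"CG", "CD1", "CD2", "CE1", "CE2", "CZ"},
    "TRP": {"CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"},
    "HIS": {"CG", "ND1", "CD2", "CE1", "NE2"},
}
_DONOR_SC = {
    "SER": {"OG"}, "THR": {"OG1"}, "TYR": {"OH"}, "CYS": {"SG"},
    "LYS": {"NZ"}, "ARG": {"NE", "NH1", "NH2"}, "ASN": {"ND2"},
    "GLN": {"NE2"}, "HIS": {"ND1", "NE2"}, "TRP": {"NE1"},
}
_ACCEPTOR_SC = {
    "ASP": {"OD1", "OD2"}, "GLU": {"OE1", "OE2"}, "ASN": {"OD1"},
    "GLN": {"OE1"}, "SER": {"OG"}, "THR": {"OG1"}, "TYR": {"OH"},
    "HIS": {"ND1", "NE2"}, "MET": {"SD"},
}
_BACKBONE = {"N", "CA", "C", "O", "OXT"}


def _atom_type_class(name: str) -> int:
    if name in ATOM_TYPE_CLASSES[:17]:
        return ATOM_TYPE_CLASSES.index(name)
    if name in ("NE", "NE1", "NE2"):
        return ATOM_TYPE_CLASSES.index("NE*")
    if name in ("NH1", "NH2"):
        return ATOM_TYPE_CLASSES.index("NH*")
    if name in ("ND1", "ND2"):
        return ATOM_TYPE_CLASSES.index("ND*")
    if name in ("OD1", "OD2"):
        return ATOM_TYPE_CLASSES.index("OD*")
    if name in ("OE1", "OE2"):
        return ATOM_TYPE_CLASSES.index("OE*")
    if name in ("OG", "OG1", "OH", "SG", "SD"):
        return ATOM_TYPE_CLASSES.index("O_hydroxyl_thiol")
    return ATOM_TYPE_CLASSES.index("other")


def _node_vector(res, atom, site: TitratableSite, radius: float) -> np.ndarray:
    v = np.zeros(NODE_WIDTH, dtype=np.float32)
    if res.resname in _AA20:
        v[_AA20.index(res.resname)] = 1.0
    key = (res.resname, atom.name)
    charge_slot = 21  # neutral
    if key in _NEGATIVE or atom.name == "OXT":
        charge_slot = 20
    elif key in _POSITIVE:
        charge_slot = 22
    v[charge_slot] = 1.0
    if atom.name in _AROMATIC.get(res.resname, ()):
        v[23] = 1.0
    if atom.name == "N" or atom.name in _DONOR_SC.get(res.resname, ()):
        v[24] = 1.0
    if atom.name in ("O", "OXT") or atom.name in _ACCEPTOR_SC.get(res.resname, ()):
        v[25] = 1.0
    if atom.name in _BACKBONE:
        v[26] = 1.0
    else:
        v[27] = 1.0
    d = float(np.linalg.norm(atom.coords - site.anchor_point))
    bin_edges = (2.5, 5.0, 7.5)
    slot = 28 + sum(d >= edge for edge in bin_edges)
    v[slot] = 1.0
    v[32] = d / radius
    is_central = res.key == site.residue_key
    if is_central and atom.name in ANCHOR_ATOMS[site.aa]:
        v[33] = 1.0
    if is_central:
        v[34] = 1.0
    if site.aa in ("ASP", "GLU", "CYS", "TYR"):
        v[35] = 1.0
    else:
        v[36] = 1.0
    el = atom.element
    el_slot = {"C": 37, "N": 38, "O": 39, "S": 40}.get(el, 41)
    v[el_slot] = 1.0
    v[BASE_WIDTH + _atom_type_class(atom.name)] = 1.0
    return v


@dataclass
class ResidueGraph:
    node_features: np.ndarray          # (n, NODE_WIDTH) float32
    edges: np.ndarray                  # (m, 2) int, undirected pairs i < j
    label: float | None                # ΔpKa, or None for unlabeled graphs
    site_ref: dict
    node_ids: list[tuple]              # (chain, resseq, icode, atom_name)
    feature_version: str = NODE_FEATURE_VERSION

    @property
    def n_nodes(self) -> int:
        return self.node_features.shape[0]

    @property
    def aa(self) -> str:
        return self.site_ref["aa"]


def build_graph(structure: ProteinStructure, site: TitratableSite,
                radius: float = 10.0, edge_cutoff: float = 4.0,
                pka_exp: float | None = None) -> ResidueGraph:
    """Graph over all heavy atoms within ``radius`` of the site's anchor.

    Nodes are deterministically ordered by (chain, resseq, icode, atom
    name); edges join node pairs within ``edge_cutoff``.  When ``pka_exp``
    is given the graph is labeled with the pKa shift.
    """
    picked = []
    for res, atom in structure.iter_atoms():
        d = float(np.linalg.norm(atom.coords - site.anchor_point))
        if d <= radius:
            picked.append(((res.chain, res.resseq, res.icode, atom.name),
                           res, atom))
    picked.sort(key=lambda item: item[0])
    if len(picked) < 4:
        raise ValueError(f"environment too sparse: {len(picked)} atom(s) "
                         f"within {radius} Å")
    feats = np.stack([_node_vector(res, atom, site, radius)
                      for _, res, atom in picked])
    coords = np.array([atom.coords for _, _, atom in picked])
    tree = cKDTree(coords)
    pairs = sorted(tree.query_pairs(edge_cutoff))
    edges = np.array(pairs, dtype=np.int64).reshape(-1, 2)
    label = None if pka_exp is None else float(pka_exp - model_pka(site.aa))
    return ResidueGraph(
        node_features=feats, edges=edges, label=label,
        site_ref={"structure_id": structure.source_id, "aa": site.aa,
                  "residue_key": site.residue_key},
        node_ids=[ids for ids, _, _ in picked])


def graphs_for_records(records, structures, radius: float = 10.0,
                       edge_cutoff: float = 4.0) -> list[ResidueGraph]:
    """Labeled graphs for (record, structure) pairs.

    ``structures`` maps structure ids to ProteinStructure objects or PDB
    text/paths.  Acids and bases share one graph set — the acid/base
    character is a node feature, not a model split.
    """
    from ..structure import read_structure
    cache: dict[str, tuple] = {}
    out = []
    for rec in records:
        for sid in rec.structure_refs:
            if sid not in cache:
                src = structures[sid]
                st = src if hasattr(src, "residues") else read_structure(src)
                st.source_id = sid
                cache[sid] = (st, identify_titratable_sites(st))
            st, sites = cache[sid]
            match = [s for s in sites
                     if s.residue_key[0] == rec.chain
                     and s.residue_key[1] == rec.resseq]
            if len(match) != 1:
                raise KeyError(f"no unique titratable site "
                               f"({rec.chain}, {rec.resseq}) in {sid}")
            out.append(build_graph(st, match[0], radius, edge_cutoff,
                                   pka_exp=rec.pka_exp))
    return out
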