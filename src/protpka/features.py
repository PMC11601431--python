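"""Microenvironment features of titratable sites.

The tree regressors see each titratable residue through a fixed, versioned
catalog of descriptors of its structural microenvironment, grouped into the
three physical determinants of pKa shifts — desolvation (burial/packing),
hydrogen bonding, and electrostatics — plus categorical context (residue
type, secondary structure, local net charge).  All distances are measured
from the anchor point (centroid of the proton-bearing sidechain atoms) to
candidate partner atoms; counts are residue-level (a residue counts once no
matter how many qualifying atoms it has); absent partners saturate at a
20 Å sentinel.
"""

from __future__ import annotations

import functools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _geometry
from .structure import (ProteinStructure, TitratableSite, TITRATABLE_AA,
                        assign_secondary_structure,
                        identify_titratable_sites, make_structure,
                        shrake_rupley_sasa)

__all__ = [
    "FeatureCatalog", "FeatureVector", "DEFAULT_CATALOG", "MODEL_PKA",
    "SENTINEL_DISTANCE", "model_pka", "buried_ratio", "count_in_radius",
    "nearest_distance", "featurize_site", "featurize_structure",
    "reference_sidechain_sasa", "SELECTIONS",
]

#: Solution (model) pKa of each titratable sidechain, pH units.
MODEL_PKA = {"ASP": 3.7, "GLU": 4.2, "HIS": 6.5, "CYS": 8.5,
             "TYR": 9.5, "LYS": 10.4}

#: Distance reported when no qualifying partner exists (Å) — twice the
#: 10 Å electrostatic-relevance radius, a plateau tree models handle well.
SENTINEL_DISTANCE = 20.0

BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})

# ---------------------------------------------------------------------------
# atom-class selections

_POLAR_SC = {
    "SER": {"OG"}, "THR": {"OG1"}, "ASN": {"OD1", "ND2"},
    "GLN": {"OE1", "NE2"}, "TYR": {"OH"}, "HIS": {"ND1", "NE2"},
    "CYS": {"SG"}, "TRP": {"NE1"},
}
_NEG_O = {"ASP": {"OD1", "OD2"}, "GLU": {"OE1", "OE2"}}
_POS_N = {"LYS": {"NZ"}, "ARG": {"NH1", "NH2", "NE"},
          "HIS": {"ND1", "NE2"}}
_HIS_N = {"HIS": {"ND1", "NE2"}}


def _table_selection(table, extra_names=frozenset()):
    def predicate(res, atom):
        return (atom.name in table.get(res.resname, ())
                or atom.name in extra_names)
    return predicate


#: Named atom-class predicates ``f(residue, atom) -> bool``.
SELECTIONS = {
    "polar": _table_selection(_POLAR_SC),
    "neg_O": _table_selection(_NEG_O, extra_names=frozenset({"OXT"})),
    "pos_N": _table_selection(_POS_N),
    "hbond_h": _table_selection(_HIS_N),
    "bb_O": lambda res, atom: atom.name == "O",
    "bb_N": lambda res, atom: atom.name == "N",
    "heavy": lambda res, atom: True,
}


# ---------------------------------------------------------------------------
# catalog

@dataclass(frozen=True)
class FeatureEntry:
    name: str
    unit: str
    group: str  # accessibility | hbond | electrostatics | categorical | identity


@dataclass(frozen=True)
class FeatureCatalog:
    """Ordered, versioned list of feature definitions."""

    version: str
    entries: tuple[FeatureEntry, ...]

    def __post_init__(self):
        names = [e.name for e in self.entries]
        if len(set(names)) != len(names):
            raise ValueError("duplicate feature names in catalog")
        required = {"buried_ratio", "n_polar10", "n_polar15",
                    "d0_hbond_h", "d0_neg_O", "model_pka"}
        missing = required - set(names)
        if missing:
            raise ValueError(f"catalog missing required features: {missing}")

    @property
    def names(self) -> list[str]:
        return [e.name for e in self.entries]

    @property
    def numeric_names(self) -> list[str]:
        return [e.name for e in self.entries if e.group != "categorical"]

    @property
    def categorical_names(self) -> list[str]:
        return [e.name for e in self.entries if e.group == "categorical"]

    def encode(self, table: pd.DataFrame) -> pd.DataFrame:
        """Numeric design matrix: ordinal-coded categoricals, fixed levels."""
        levels = {"res_type": sorted(TITRATABLE_AA), "ss_site": ["C", "E", "H"],
                  "ss_env10": ["C", "E", "H"], "net_charge_sign": ["-", "0", "+"]}
        out = table[self.numeric_names].astype(float).copy()
        for name in self.categorical_names:
            cats = levels[name]
            out[name] = pd.Categorical(table[name], categories=cats).codes
        return out[self.names]


def _default_catalog() -> FeatureCatalog:
    e = []
    e.append(FeatureEntry("model_pka", "pKa", "identity"))
    e.append(FeatureEntry("buried_ratio", "fraction", "accessibility"))
    e.append(FeatureEntry("sasa_sidechain", "A^2", "accessibility"))
    for r in (6, 8, 10):
        e.append(FeatureEntry(f"n_heavy{r}", "count", "accessibility"))
    for r in (10, 15):
        e.append(FeatureEntry(f"n_polar{r}", "count", "hbond"))
    for r in (10, 15):
        e.append(FeatureEntry(f"n_pos{r}", "count", "electrostatics"))
    for r in (10, 15):
        e.append(FeatureEntry(f"n_neg{r}", "count", "electrostatics"))
    for sel, grp in (("polar", "hbond"), ("hbond_h", "hbond"),
                     ("neg_O", "electrostatics"), ("pos_N", "electrostatics"),
                     ("bb_O", "hbond"), ("bb_N", "hbond")):
        e.append(FeatureEntry(f"d0_{sel}", "A", grp))
        e.append(FeatureEntry(f"d1_{sel}", "A", grp))
    for name in ("res_type", "ss_site", "ss_env10", "net_charge_sign"):
        e.append(FeatureEntry(name, "-", "categorical"))
    return FeatureCatalog(version="protpka-feat-v1", entries=tuple(e))


DEFAULT_CATALOG = _default_catalog()


@dataclass
class FeatureVector:
    site_ref: dict
    catalog_version: str
    numeric: dict[str, float] = field(default_factory=dict)
    categorical: dict[str, str] = field(default_factory=dict)

    def as_series(self) -> pd.Series:
        data = {**self.site_ref, **self.numeric, **self.categorical}
        return pd.Series(data)


# ---------------------------------------------------------------------------
# elementary features

def model_pka(aa: str) -> float:
    """Solution reference pKa of a titratable residue type."""
    try:
        return MODEL_PKA[aa.upper()]
    except KeyError:
        raise ValueError(f"{aa!r} is not a titratable residue type") from None


@functools.lru_cache(maxsize=32)
def reference_sidechain_sasa(aa: str) -> float:
    """Max sidechain SASA (Å²) of ``aa`` in an extended Gly-X-Gly tripeptide.

    Computed once with the package's own geometry builder and SASA engine so
    that the buried-ratio scale is self-consistent.
    """
    if aa not in _geometry.SUPPORTED_RESIDUES or aa == "GLY":
        raise ValueError(f"no sidechain reference for {aa!r}")
    built = _geometry.build_peptide(["GLY", aa, "GLY"])
    specs = [("A", i + 1, "", resname, atoms)
             for i, (resname, atoms) in enumerate(built)]
    tripeptide = make_structure(specs, source_id=f"ref-{aa.lower()}")
    sasa = shrake_rupley_sasa(tripeptide)
    return sum(v for (ch, seq, ic, name), v in sasa.items()
               if seq == 2 and name not in BACKBONE_ATOMS)


def buried_ratio(site: TitratableSite, structure: ProteinStructure,
                 sasa_map: dict[tuple, float]) -> float:
    """1 - (sidechain SASA in context / reference maximum), clamped to [0, 1]."""
    res = structure.get_residue(*site.residue_key)
    sc_atoms = [a for a in res.atoms if a.name not in BACKBONE_ATOMS]
    expected = [name for name, *_ in _geometry._SIDECHAINS[site.aa]]
    if len(sc_atoms) < len(expected):
        warnings.warn(f"{site.aa} {site.residue_key}: sidechain incomplete; "
                      f"buried ratio computed over present atoms", stacklevel=2)
    context = sum(sasa_map[(res.chain, res.resseq, res.icode, a.name)]
                  for a in sc_atoms)
    ref = reference_sidechain_sasa(site.aa)
    return float(np.clip(1.0 - context / ref, 0.0, 1.0))


def _partner_atoms(site: TitratableSite, structure: ProteinStructure,
                   selection) -> list[tuple[tuple, float]]:
    """(residue_key, distance) for every selected atom outside the site."""
    out = []
    for res, atom in structure.iter_atoms():
        if res.key == site.residue_key:
            continue
        if selection(res, atom):
            out.append((res.key, float(np.linalg.norm(
                atom.coords - site.anchor_point))))
    return out


def count_in_radius(site: TitratableSite, structure: ProteinStructure,
                    selection, radius: float) -> int:
    """Residues (not atoms) with >= 1 selected atom within ``radius`` (inclusive)."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    if isinstance(selection, str):
        selection = SELECTIONS[selection]
    hits = {key for key, d in _partner_atoms(site, structure, selection)
            if d <= radius}
    return len(hits)


def nearest_distance(site: TitratableSite, structure: ProteinStructure,
                     selection, rank: int = 0,
                     sentinel: float = SENTINEL_DISTANCE) -> float:
    """rank-th smallest anchor-to-selected-atom distance (self excluded)."""
    if rank < 0:
        raise ValueError("rank must be >= 0")
    if isinstance(selection, str):
        selection = SELECTIONS[selection]
    dists = sorted(d for _, d in _partner_atoms(site, structure, selection))
    return dists[rank] if rank < len(dists) else sentinel


def _net_charge_sign(site: TitratableSite, structure: ProteinStructure,
                     radius: float = 10.0) -> str:
    """Sign of summed formal charges within ``radius``, standard states at pH 7."""
    total = 0
    for res in structure.residues:
        if res.key == site.residue_key:
            continue
        atoms_in = [a for a in res.atoms
                    if np.linalg.norm(a.coords - site.anchor_point) <= radius]
        if not atoms_in:
            continue
        names = {a.name for a in atoms_in}
        if res.resname in ("ASP", "GLU") and names & _NEG_O[res.resname]:
            total -= 1
        elif res.resname == "LYS" and "NZ" in names:
            total += 1
        elif res.resname == "ARG" and names & _POS_N["ARG"]:
            total += 1
        if "OXT" in names:
            total -= 1
    return "-" if total < 0 else ("+" if total > 0 else "0")


def _env_ss_majority(site: TitratableSite, structure: ProteinStructure,
                     ss: dict[tuple, str], radius: float = 10.0) -> str:
    counts = {"H": 0, "E": 0, "C": 0}
    for res in structure.residues:
        if any(np.linalg.norm(a.coords - site.anchor_point) <= radius
               for a in res.atoms):
            counts[ss[res.key]] += 1
    # deterministic tie-break: C, then E, then H
    return max(("C", "E", "H"), key=lambda c: (counts[c], -("CEH".index(c))))


def featurize_site(structure: ProteinStructure, site: TitratableSite,
                   catalog: FeatureCatalog = DEFAULT_CATALOG,
                   sasa_map: dict | None = None,
                   ss: dict | None = None) -> FeatureVector:
    """Fill every catalog entry for one site (deterministic)."""
    if catalog.version != DEFAULT_CATALOG.version:
        raise ValueError(f"unsupported catalog version {catalog.version!r}")
    if sasa_map is None:
        sasa_map = shrake_rupley_sasa(structure)
    if ss is None:
        ss = assign_secondary_structure(structure)
    res = structure.get_residue(*site.residue_key)
    num: dict[str, float] = {}
    num["model_pka"] = model_pka(site.aa)
    num["buried_ratio"] = buried_ratio(site, structure, sasa_map)
    num["sasa_sidechain"] = sum(
        sasa_map[(res.chain, res.resseq, res.icode, a.name)]
        for a in res.atoms if a.name not in BACKBONE_ATOMS)
    # partner lists computed once per atom class, shared by counts and ranks
    partners = {name: _partner_atoms(site, structure, SELECTIONS[name])
                for name in SELECTIONS}

    def _count(name, radius):
        return len({k for k, d in partners[name] if d <= radius})

    def _rank_dist(name, rank):
        dists = sorted(d for _, d in partners[name])
        return dists[rank] if rank < len(dists) else SENTINEL_DISTANCE

    for r in (6, 8, 10):
        num[f"n_heavy{r}"] = _count("heavy", r)
    for sel, name in (("polar", "polar"), ("pos", "pos_N"), ("neg", "neg_O")):
        for r in (10, 15):
            num[f"n_{sel}{r}"] = _count(name, r)
    for sel in ("polar", "hbond_h", "neg_O", "pos_N", "bb_O", "bb_N"):
        num[f"d0_{sel}"] = _rank_dist(sel, 0)
        num[f"d1_{sel}"] = _rank_dist(sel, 1)
    cat = {
        "res_type": site.aa,
        "ss_site": ss[site.residue_key],
        "ss_env10": _env_ss_majority(site, structure, ss),
        "net_charge_sign": _net_charge_sign(site, structure),
    }
    ref = {"structure_id": structure.source_id,
           "chain": site.residue_key[0], "resseq": site.residue_key[1],
           "icode": site.residue_key[2], "aa": site.aa}
    return FeatureVector(site_ref=ref, catalog_version=catalog.version,
                         numeric=num, categorical=cat)


def featurize_structure(structure: ProteinStructure,
                        catalog: FeatureCatalog = DEFAULT_CATALOG,
                        sites: list[TitratableSite] | None = None) -> pd.DataFrame:
    """One feature row per titratable site; SASA and SS computed once."""
    if sites is None:
        sites = identify_titratable_sites(structure)
    if not sites:
        cols = (["structure_id", "chain", "resseq", "icode", "aa",
                 "catalog_version"] + catalog.names)
        return pd.DataFrame(columns=cols)
    sasa_map = shrake_rupley_sasa(structure)
    ss = assign_secondary_structure(structure)
    rows = []
    for site in sites:
        vec = featurize_site(structure, site, catalog, sasa_map, ss)
        row = vec.as_series()
        row["catalog_version"] = vec.catalog_version
        rows.append(row)
    df = pd.DataFrame(rows).reset_index(drop=True)
    order = (["structure_id", "chain", "resseq", "icode", "aa",
              "catalog_version"] + catalog.names)
    return df[order]
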