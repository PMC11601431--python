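"""Seeded synthetic microenvironments with known ground-truth pKa's.

Each synthetic site is a Gly-X-Gly tripeptide carrying one titratable
residue, surrounded by (a) surrogate neighbor residues — single-residue
fragments whose contact atom (Ser OG, Asp OD1, Lys NZ, His ND1) is placed
at a planned distance from the anchor point — and (b) a burial cage of
carbon atoms on nested spherical shells whose occupancy is monotone in the
requested burial level.  Labels follow a monotone ground-truth function of
the *featurized* descriptors (so generator and featurizer are consistent by
construction) with the sign structure acids and bases exhibit in real
proteins: burial and polar crowding raise acid pKa's and lower base pKa's,
while a nearby carboxylate oxygen lowers acid pKa's and raises base pKa's.

These fixtures emulate controllable burial and neighbor composition, not
real protein folds; conformational coupling, waters and backbone
flexibility are absent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _geometry
from .dataset import PkaRecord, write_pkad_table
from .features import DEFAULT_CATALOG, SENTINEL_DISTANCE, model_pka
from .features import featurize_structure
from .structure import (ProteinStructure, make_structure, read_structure,
                        write_pdb)

__all__ = ["SyntheticSpec", "SitePlan", "GroundTruthModel", "ClashError",
            "SyntheticDataset", "generate_structure", "ground_truth_pka",
            "generate_dataset", "jitter_conformers"]

_SURROGATE = {  # neighbor kind -> (residue type, contact atom)
    "polar": ("SER", "OG"),
    "negative": ("ASP", "OD1"),
    "positive": ("LYS", "NZ"),
    "his": ("HIS", "ND1"),
}

MIN_CONTACT = 2.4  # Å, clash-free floor for any planned inter-fragment distance


class ClashError(ValueError):
    """An infeasible neighbor plan (steric clash that retries cannot fix)."""


@dataclass
class SitePlan:
    aa: str
    burial_level: float
    neighbors: list[tuple[str, float]]  # (kind, anchor distance Å)

    def __post_init__(self):
        if not 0.0 <= self.burial_level <= 1.0:
            raise ValueError("burial_level must lie in [0, 1]")
        for kind, dist in self.neighbors:
            if kind not in _SURROGATE:
                raise ValueError(f"unknown neighbor kind {kind!r}")
            if dist <= MIN_CONTACT:
                raise ValueError(f"planned distance {dist} Å clashes "
                                 f"(< {MIN_CONTACT} Å)")

    def expected_counts(self, radius: float = 10.0) -> dict[str, int]:
        """Residue-level class counts the featurizer should report.

        His sidechain nitrogens are simultaneously polar and positively
        chargeable, so a His surrogate contributes to both classes.
        """
        n = {"polar": 0, "negative": 0, "positive": 0}
        for kind, dist in self.neighbors:
            if dist > radius:
                continue
            if kind in ("polar", "his"):
                n["polar"] += 1
            if kind in ("positive", "his"):
                n["positive"] += 1
            if kind == "negative":
                n["negative"] += 1
        return n


@dataclass
class SyntheticSpec:
    """Sampling plan for a set of synthetic sites; fully seed-determined."""

    n_sites: int = 100
    # default mix follows the relative abundance of experimentally measured
    # residues across the six types (Glu > Asp > His > Lys > Cys > Tyr)
    aa_mix: dict[str, float] = field(default_factory=lambda: {
        "ASP": 0.29, "GLU": 0.35, "HIS": 0.16, "CYS": 0.06,
        "TYR": 0.04, "LYS": 0.10})
    burial_levels: list[float] | None = None  # explicit per-site overrides
    max_polar: int = 4
    max_negative: int = 2
    max_positive: int = 2
    max_his: int = 1
    min_neighbor_dist: float = 3.5
    max_neighbor_dist: float = 9.5
    noise_sigma: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.min_neighbor_dist <= MIN_CONTACT:
            raise ValueError("min_neighbor_dist must exceed clash floor")
        total = sum(self.aa_mix.values())
        self.aa_mix = {k: v / total for k, v in self.aa_mix.items()}

    def _rng(self, site_index: int, stream: int = 0) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence([self.seed, site_index, stream]))

    def site_plan(self, site_index: int) -> SitePlan:
        rng = self._rng(site_index)
        aas = sorted(self.aa_mix)
        probs = np.array([self.aa_mix[a] for a in aas])
        aa = rng.choice(aas, p=probs)
        if self.burial_levels is not None:
            burial = float(self.burial_levels[site_index % len(self.burial_levels)])
        else:
            # most residues modestly buried, a tail of deeply buried ones —
            # keeps large (> 2 unit) shifts a minority but well represented
            burial = float(rng.beta(1.0, 2.0))
        neighbors: list[tuple[str, float]] = []
        for kind, cap in (("polar", self.max_polar),
                          ("negative", self.max_negative),
                          ("positive", self.max_positive),
                          ("his", self.max_his)):
            for _ in range(int(rng.integers(0, cap + 1))):
                dist = float(rng.uniform(self.min_neighbor_dist,
                                         self.max_neighbor_dist))
                neighbors.append((kind, dist))
        return SitePlan(aa=str(aa), burial_level=burial, neighbors=neighbors)


@dataclass
class GroundTruthModel:
    """Monotone label function with field-realistic sign structure.

    Acid pKa's rise with burial and polar crowding and fall when a
    carboxylate oxygen is near; base pKa's do the opposite.  The intercept
    is always the residue type's model pKa.
    """

    acid_burial: float = 3.0       # > 0
    acid_polar: float = 0.25       # > 0, per polar sidechain within 10 Å
    acid_neg_prox: float = -1.0    # < 0, per unit proximity
    base_burial: float = -2.0      # < 0
    base_polar: float = -0.25      # < 0, per polar sidechain within 15 Å
    base_neg_prox: float = 1.5     # > 0

    def __post_init__(self):
        if self.acid_burial <= 0:
            raise ValueError("acid burial coefficient must be positive")
        if self.base_polar >= 0:
            raise ValueError("base polar-count coefficient must be negative")


def _proximity(distance: float, cap: float = SENTINEL_DISTANCE) -> float:
    """1 at contact, 0 at/beyond the sentinel distance."""
    return float(np.clip((cap - distance) / cap, 0.0, 1.0))


def ground_truth_pka(features, model: GroundTruthModel = GroundTruthModel()
                     ) -> float:
    """Noise-free label for one featurized site (Series or mapping)."""
    aa = features["res_type"] if "res_type" in features else features["aa"]
    base_value = model_pka(aa)
    prox = _proximity(float(features["d0_neg_O"]))
    if aa in ("ASP", "GLU", "CYS", "TYR"):
        shift = (model.acid_burial * float(features["buried_ratio"])
                 + model.acid_polar * float(features["n_polar10"])
                 + model.acid_neg_prox * prox)
    else:
        shift = (model.base_burial * float(features["buried_ratio"])
                 + model.base_polar * float(features["n_polar15"])
                 + model.base_neg_prox * prox)
    return base_value + shift


# ---------------------------------------------------------------------------
# structure realization

_CAGE_SHELLS = ((6.0, 48), (8.2, 64))  # (radius Å, max atoms)


def _rotation_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Rotation matrix taking unit vector ``a`` onto unit vector ``b``."""
    c = float(np.dot(a, b))
    if c > 1.0 - 1e-12:
        return np.eye(3)
    if c < -1.0 + 1e-12:
        # opposite: rotate 180 deg about any axis orthogonal to a
        helper = np.array([1.0, 0.0, 0.0])
        if abs(a[0]) > 0.9:
            helper = np.array([0.0, 1.0, 0.0])
        axis = np.cross(a, helper)
        return _geometry.rotation_matrix(axis, 180.0)
    axis = np.cross(a, b)
    angle = np.degrees(np.arccos(np.clip(c, -1.0, 1.0)))
    return _geometry.rotation_matrix(axis, angle)


def _fibonacci_directions(n: int) -> np.ndarray:
    i = np.arange(n)
    z = 1.0 - (2.0 * i + 1.0) / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    golden = np.pi * (3.0 - np.sqrt(5.0))
    return np.column_stack([r * np.cos(golden * i),
                            r * np.sin(golden * i), z])


def _build_central(aa: str) -> tuple[list, np.ndarray]:
    built = _geometry.build_peptide(["GLY", aa, "GLY"])
    specs = [("A", i + 1, "", resname, dict(atoms))
             for i, (resname, atoms) in enumerate(built)]
    from .structure import ANCHOR_ATOMS
    anchors = [specs[1][4][name] for name in ANCHOR_ATOMS[aa]]
    anchor = np.mean(anchors, axis=0)
    return specs, anchor


def generate_structure(spec: SyntheticSpec, site_index: int) -> str:
    """PDB-format text realizing one site plan; byte-identical per (spec, seed)."""
    plan = spec.site_plan(site_index)
    rng = spec._rng(site_index, stream=1)
    specs, anchor = _build_central(plan.aa)
    placed = [xyz for _, _, _, _, atoms in specs for xyz in atoms.values()]

    # surrogate neighbors
    for j, (kind, dist) in enumerate(plan.neighbors):
        restype, contact = _SURROGATE[kind]
        fragment = dict(_geometry.build_peptide([restype])[0][1])
        centroid = np.mean(list(fragment.values()), axis=0)
        outward = centroid - fragment[contact]
        outward /= np.linalg.norm(outward)
        ok = False
        for _ in range(100):
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            # orient the fragment to extend radially away from the site,
            # with a random spin about the radial axis
            rot = (_geometry.rotation_matrix(u, float(rng.uniform(0, 360)))
                   @ _rotation_between(outward, u))
            moved = {name: rot @ (xyz - fragment[contact])
                     for name, xyz in fragment.items()}
            offset = anchor + dist * u
            moved = {name: xyz + offset for name, xyz in moved.items()}
            coords = np.array(list(moved.values()))
            dmin = np.min(np.linalg.norm(
                coords[:, None, :] - np.array(placed)[None, :, :], axis=-1))
            if dmin >= MIN_CONTACT:
                specs.append(("B", j + 1, "", restype, moved))
                placed.extend(moved.values())
                ok = True
                break
        if not ok:
            raise ClashError(
                f"cannot place {kind} neighbor at {dist:.2f} Å from anchor "
                f"of site {site_index} ({plan.aa}) without clashes")

    # burial cage: nested shells of single-carbon residues; occupancy is
    # monotone in burial_level because positions are consumed in fixed order
    shells = [list(anchor + radius * _fibonacci_directions(n_max))
              for radius, n_max in _CAGE_SHELLS]
    cage_positions = []
    while any(shells):  # interleave shells so both fill proportionally
        for shell in shells:
            if shell:
                cage_positions.append(shell.pop(0))
    n_cage = int(round(plan.burial_level * len(cage_positions)))
    existing = np.array(placed)
    taken = 0
    cage_idx = 0
    for pos in cage_positions:
        if taken >= n_cage:
            break
        cage_idx += 1
        if np.min(np.linalg.norm(existing - pos, axis=-1)) < MIN_CONTACT:
            continue
        specs.append(("C", cage_idx, "", "GLY", {"CA": pos}))
        taken += 1

    structure = make_structure(specs, source_id=f"SYN{site_index:05d}_m0")
    return write_pdb(structure)


@dataclass
class SyntheticDataset:
    spec: SyntheticSpec
    truth_model: GroundTruthModel
    structures: dict[str, str]            # structure id -> PDB text
    records: list[PkaRecord]
    features: pd.DataFrame                # one row per site, default catalog
    ground_truth: np.ndarray              # noise-free labels

    @property
    def table(self) -> pd.DataFrame:
        return write_pkad_table(self.records)

    @property
    def labels(self) -> np.ndarray:
        return np.array([r.pka_exp for r in self.records])


def generate_dataset(spec: SyntheticSpec,
                     truth_model: GroundTruthModel = GroundTruthModel()
                     ) -> SyntheticDataset:
    """Structures + labeled table, with labels = ground truth + N(0, sigma).

    Labels are clipped to [0, 16].  Each site is its own "protein" so unique
    keys are one-per-site.
    """
    structures: dict[str, str] = {}
    records: list[PkaRecord] = []
    rows = []
    truths = []
    for i in range(spec.n_sites):
        pdb_text = generate_structure(spec, i)
        st = read_structure(pdb_text)
        structures[st.source_id] = pdb_text
        feats = featurize_structure(st, DEFAULT_CATALOG)
        row = feats.iloc[0]
        truth = ground_truth_pka(row, truth_model)
        noise_rng = spec._rng(i, stream=2)
        label = float(np.clip(truth + noise_rng.normal(0.0, spec.noise_sigma),
                              0.0, 16.0))
        truths.append(truth)
        rows.append(row)
        records.append(PkaRecord(
            protein=f"SYN{i:05d}", aa=str(row["aa"]), chain="A", resseq=2,
            mutation="WT", conf_state="", pka_exp=label,
            structure_refs=(st.source_id,)))
    features = pd.DataFrame(rows).reset_index(drop=True)
    return SyntheticDataset(spec=spec, truth_model=truth_model,
                            structures=structures, records=records,
                            features=features,
                            ground_truth=np.array(truths))


def jitter_conformers(structure: ProteinStructure | str, k: int,
                      amplitude: float = 0.3, seed: int = 0) -> list[str]:
    """k clash-checked Gaussian coordinate perturbations as PDB texts.

    Stands in for alternative (predicted-model) conformations of the same
    residue; site identity and atom names are preserved.
    """
    if k < 0 or k > 10:
        raise ValueError("k must lie in [0, 10]")
    if amplitude < 0 or amplitude > 0.5:
        raise ValueError("amplitude must lie in [0, 0.5] Å")
    if isinstance(structure, str):
        structure = read_structure(structure)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    out = []
    import warnings as _warnings
    for c in range(k):
        pdb = _perturbed_pdb(structure, amplitude, rng, c)
        if pdb is None:
            _warnings.warn(f"could not produce conformer {c} without clashes; "
                           f"returning {len(out)} conformer(s)", stacklevel=2)
            break
        out.append(pdb)
    return out


def _perturbed_pdb(structure: ProteinStructure, amplitude: float,
                   rng: np.random.Generator, index: int) -> str | None:
    orig = np.array([a.coords for res in structure.residues
                     for a in res.atoms])
    offsets = (rng.normal(0.0, amplitude, size=orig.shape)
               if amplitude > 0 else np.zeros_like(orig))
    d0 = np.linalg.norm(orig[:, None] - orig[None, :], axis=-1)
    nonbonded = d0 >= 2.2
    coords = orig + offsets
    # repair clashes by damping the displacement of offending atoms; the
    # perturbation contracts toward the (clash-free) original, so this
    # converges unless the input itself is clashed
    ok = len(orig) < 2 or amplitude == 0
    for _ in range(100):
        if ok:
            break
        d = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        clash = nonbonded & (d < 2.0)
        if not clash.any():
            ok = True
            break
        offenders = np.unique(np.nonzero(clash)[0])
        offsets[offenders] *= 0.5
        coords = orig + offsets
    if not ok:
        return None
    specs = []
    pos = 0
    for res in structure.residues:
        atoms = {a.name: coords[pos + j] for j, a in enumerate(res.atoms)}
        pos += len(res.atoms)
        specs.append((res.chain, res.resseq, res.icode, res.resname, atoms))
    st = make_structure(specs,
                        source_id=f"{structure.source_id}_c{index + 1}")
    return write_pdb(st)
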