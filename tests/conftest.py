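"""Shared fixtures: ideal-geometry structures and small synthetic datasets."""

from __future__ import annotations

import numpy as np
import pytest

from protpka import _geometry
from protpka.structure import ProteinStructure, make_structure
from protpka.synth import SyntheticSpec, generate_dataset


def peptide_structure(sequence, phi=-140.0, psi=135.0,
                      source_id="fixture") -> ProteinStructure:
    built = _geometry.build_peptide(list(sequence), phi=phi, psi=psi)
    specs = [("A", i + 1, "", resname, atoms)
             for i, (resname, atoms) in enumerate(built)]
    return make_structure(specs, source_id=source_id)


def cage_around(structure: ProteinStructure, center: np.ndarray,
                radii=(4.0, 6.0), n_per_shell=100,
                clearance=2.0) -> ProteinStructure:
    """Add dense carbon shells centred on ``center`` (single-atom residues)."""
    specs = [(r.chain, r.resseq, r.icode, r.resname,
              {a.name: a.coords for a in r.atoms})
             for r in structure.residues]
    existing = structure.atom_coords()
    idx = 0
    for radius in radii:
        i = np.arange(n_per_shell)
        z = 1.0 - (2.0 * i + 1.0) / n_per_shell
        r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
        golden = np.pi * (3.0 - np.sqrt(5.0))
        pts = center + radius * np.column_stack(
            [r * np.cos(golden * i), r * np.sin(golden * i), z])
        for p in pts:
            if np.min(np.linalg.norm(existing - p, axis=-1)) < clearance:
                continue
            idx += 1
            specs.append(("Z", idx, "", "GLY", {"CA": p}))
    return make_structure(specs, source_id=structure.source_id + "-caged")


@pytest.fixture(scope="session")
def gly_asp_gly() -> ProteinStructure:
    return peptide_structure(["GLY", "ASP", "GLY"], source_id="gdg")


@pytest.fixture(scope="session")
def helix12() -> ProteinStructure:
    return peptide_structure(["ALA"] * 12, phi=-57.0, psi=-47.0,
                             source_id="helix")


@pytest.fixture(scope="session")
def small_dataset():
    """30 mixed-type synthetic sites with moderate noise."""
    return generate_dataset(SyntheticSpec(n_sites=30, seed=9,
                                          noise_sigma=0.2))


@pytest.fixture(scope="session")
def overfit_graphs():
    """20 noise-free graphs for capacity/ensemble/freeze checks."""
    from protpka.gat import graphs_for_records
    ds = generate_dataset(SyntheticSpec(n_sites=20, seed=3, noise_sigma=0.0))
    return graphs_for_records(ds.records, ds.structures)
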