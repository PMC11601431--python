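"""Published summary statistics of the PKAD experimental pKa databases.

Per-residue-type counts of unique residues, measured pKa's and PDB
structures for the cleaned PKAD-2 release and its PKAD-3 expansion, as
printed in the databases' summary table.  These counts are inputs for
bookkeeping arithmetic (partition sizes, growth percentages) and for
building count-faithful synthetic record tables; the databases themselves
are not bundled.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["PKAD2_COUNTS", "PKAD3_COUNTS", "counts_frame",
           "percent_increase", "records_from_counts"]

# aa -> (unique residues, measured pKa's, PDB structures)
PKAD2_COUNTS = {
    "ASP": (175, 214, 403),
    "GLU": (218, 258, 447),
    "HIS": (116, 170, 243),
    "CYS": (20, 20, 20),
    "TYR": (19, 20, 22),
    "LYS": (67, 81, 151),
}

PKAD3_COUNTS = {
    "ASP": (291, 330, 520),
    "GLU": (342, 382, 580),
    "HIS": (155, 219, 293),
    "CYS": (57, 60, 62),
    "TYR": (38, 39, 41),
    "LYS": (109, 137, 216),
}


def counts_frame(counts: dict) -> pd.DataFrame:
    return pd.DataFrame.from_dict(
        counts, orient="index",
        columns=["unique_residues", "n_pka", "n_structures"])


def percent_increase(aa: str, column: str = "unique_residues") -> float:
    """Growth of a count from PKAD-2 to PKAD-3, in percent."""
    idx = ["unique_residues", "n_pka", "n_structures"].index(column)
    old = PKAD2_COUNTS[aa][idx]
    new = PKAD3_COUNTS[aa][idx]
    return 100.0 * (new - old) / old


def records_from_counts(counts: dict):
    """Synthetic PkaRecord list reproducing a count table exactly.

    For each residue type, ``unique_residues`` distinct residue keys are
    created and the surplus measurements (``n_pka - unique_residues``) are
    assigned as repeat measurements of the first keys, so summarize/partition
    arithmetic over the records matches the printed table.  pKa values are
    placeholders (the residue type's model pKa).
    """
    from .dataset import PkaRecord
    from .features import model_pka

    records = []
    for aa, (n_res, n_pka, n_pdb) in counts.items():
        extra = n_pka - n_res
        structures = [f"{aa.lower()}_s{j}" for j in range(n_pdb)]
        # distribute structures round-robin over residues so each residue
        # has at least one structure reference
        per_res: list[list[str]] = [[] for _ in range(n_res)]
        for j, sid in enumerate(structures):
            per_res[j % n_res].append(sid)
        for i in range(n_res):
            records.append(PkaRecord(
                protein=f"{aa}_{i:04d}", aa=aa, chain="A", resseq=i + 1,
                mutation="WT", conf_state="", pka_exp=model_pka(aa),
                structure_refs=tuple(per_res[i])))
        for i in range(extra):
            base = records[-n_res + (i % n_res)]
            records.append(PkaRecord(
                protein=base.protein, aa=aa, chain="A", resseq=base.resseq,
                mutation="WT", conf_state="", pka_exp=model_pka(aa) + 0.1,
                structure_refs=base.structure_refs))
    return records
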