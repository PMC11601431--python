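"""Experimental pKa tables, leakage-free splits, conformer augmentation.

Labels are keyed by a *unique residue* identity (protein accession, residue
number, mutation tag, conformational state).  A residue may carry several
measured pKa's and several usable structures; all of them travel together
through every train/test split, which is what makes the splits leakage-free
at the residue level.  Stratification is on pKa quantile bins so train and
test see comparable label distributions.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedShuffleSplit

from .features import MODEL_PKA, model_pka

__all__ = ["PkaRecord", "SplitPlan", "AugmentationPolicy", "SchemaError",
           "read_pkad_table", "write_pkad_table", "partition_acid_base",
           "make_splits", "augment_training", "summarize_table",
           "ACID_AA", "BASE_AA"]

ACID_AA = frozenset({"ASP", "GLU", "CYS", "TYR"})
BASE_AA = frozenset({"HIS", "LYS"})

MANDATORY_COLUMNS = ("protein", "res_name", "res_id", "pka_exp",
                     "structure_refs")


class SchemaError(ValueError):
    """A mandatory column is missing from a pKa table."""


@dataclass(frozen=True)
class PkaRecord:
    protein: str
    aa: str
    chain: str
    resseq: int
    mutation: str
    conf_state: str
    pka_exp: float
    structure_refs: tuple[str, ...]
    augmented: bool = False

    def __post_init__(self):
        if not np.isfinite(self.pka_exp) or not 0.0 <= self.pka_exp <= 16.0:
            raise ValueError(f"pka_exp {self.pka_exp} outside [0, 16]")
        if self.aa not in MODEL_PKA:
            raise ValueError(f"{self.aa!r} is not a titratable residue type")
        if not self.structure_refs:
            raise ValueError("record has no structure references")

    @property
    def unique_key(self) -> tuple[str, int, str, str]:
        return (self.protein, self.resseq, self.mutation, self.conf_state)

    @property
    def pka_shift(self) -> float:
        return self.pka_exp - model_pka(self.aa)


@dataclass
class AugmentationPolicy:
    """Add alternative conformations of strongly shifted training residues."""
    shift_threshold: float = 2.0
    max_conformers: int = 10

    def __post_init__(self):
        if self.shift_threshold <= 0:
            raise ValueError("shift_threshold must be > 0")
        if self.max_conformers < 1:
            raise ValueError("max_conformers must be >= 1")


@dataclass
class SplitPlan:
    n_splits: int
    test_fraction: float
    seed: int
    assignments: list[dict[str, list[tuple]]] = field(default_factory=list)

    def train_keys(self, split: int) -> set[tuple]:
        return {tuple(k) for k in self.assignments[split]["train"]}

    def test_keys(self, split: int) -> set[tuple]:
        return {tuple(k) for k in self.assignments[split]["test"]}

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {"n_splits": self.n_splits,
                   "test_fraction": self.test_fraction, "seed": self.seed,
                   "assignments": [
                       {"train": [list(k) for k in a["train"]],
                        "test": [list(k) for k in a["test"]]}
                       for a in self.assignments]}
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "SplitPlan":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        payload = json.loads(text)
        plan = cls(n_splits=payload["n_splits"],
                   test_fraction=payload["test_fraction"],
                   seed=payload["seed"])
        plan.assignments = [
            {"train": [tuple(k) for k in a["train"]],
             "test": [tuple(k) for k in a["test"]]}
            for a in payload["assignments"]]
        return plan


def read_pkad_table(source) -> list[PkaRecord]:
    """Read a delimited experimental pKa table.

    Expected columns: protein, res_name, res_id, pka_exp, structure_refs
    (semicolon-separated structure ids), optionally chain, mutation,
    conf_state.  Rows with unparseable or out-of-range pKa's (e.g. values
    given as ranges, ">9") are skipped with a warning.
    """
    df = pd.read_csv(source, sep=None, engine="python", dtype=str,
                     skipinitialspace=True)
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {missing}")
    records: list[PkaRecord] = []
    skipped = 0
    for _, row in df.iterrows():
        pka = pd.to_numeric(row["pka_exp"], errors="coerce")
        aa = str(row["res_name"]).strip().upper()
        if not np.isfinite(pka) or not 0.0 <= pka <= 16.0 or aa not in MODEL_PKA:
            skipped += 1
            continue
        refs = tuple(s.strip() for s in str(row["structure_refs"]).split(";")
                     if s.strip())
        if not refs:
            skipped += 1
            continue
        def _opt(column, default):
            value = row.get(column, default)
            if pd.isna(value):
                return default
            return str(value).strip() or default

        records.append(PkaRecord(
            protein=str(row["protein"]).strip(), aa=aa,
            chain=_opt("chain", "A"), resseq=int(row["res_id"]),
            mutation=_opt("mutation", "WT"), conf_state=_opt("conf_state", ""),
            pka_exp=float(pka), structure_refs=refs))
    if skipped:
        warnings.warn(f"skipped {skipped} row(s) with unparseable/out-of-range "
                      f"pKa or unsupported residue type", stacklevel=2)
    return records


def write_pkad_table(records: list[PkaRecord], path: str | Path | None = None
                     ) -> pd.DataFrame:
    """Serialize records to the documented column schema (CSV if path given)."""
    df = pd.DataFrame([{
        "protein": r.protein, "res_name": r.aa, "chain": r.chain,
        "res_id": r.resseq, "mutation": r.mutation,
        "conf_state": r.conf_state, "pka_exp": r.pka_exp,
        "structure_refs": ";".join(r.structure_refs)} for r in records])
    if path is not None:
        df.to_csv(path, index=False)
    return df


def partition_acid_base(records: list[PkaRecord]
                        ) -> tuple[list[PkaRecord], list[PkaRecord]]:
    """Disjoint exhaustive split into acidic (Asp/Glu/Cys/Tyr) and basic (His/Lys)."""
    acid = [r for r in records if r.aa in ACID_AA]
    base = [r for r in records if r.aa in BASE_AA]
    return acid, base


def _stratum_labels(key_pkas: np.ndarray, n_bins: int = 5) -> np.ndarray:
    """Quantile-bin labels, merging bins until every stratum has >= 2 keys."""
    for q in range(n_bins, 0, -1):
        try:
            labels = pd.qcut(key_pkas, q=q, labels=False, duplicates="drop")
        except ValueError:
            continue
        counts = pd.Series(labels).value_counts()
        if (counts >= 2).all() and counts.size > 0:
            if q < n_bins:
                warnings.warn(f"sparse pKa strata: merged to {q} quantile "
                              f"bin(s)", stacklevel=3)
            return np.asarray(labels)
    return np.zeros(len(key_pkas), dtype=int)


def make_splits(records: list[PkaRecord], n_splits: int = 20,
                test_fraction: float = 0.10, seed: int = 0,
                n_strata: int = 5) -> SplitPlan:
    """Stratified residue-level train/test partitions.

    Splits are drawn over unique residue keys (all measurements and all
    structures of a key travel together), stratified on quantile bins of the
    per-key mean pKa.  The master seed deterministically spawns one child
    seed per split via numpy's SeedSequence.
    """
    keys = sorted({r.unique_key for r in records})
    if len(keys) < 20:
        raise ValueError(f"need >= 20 unique keys, got {len(keys)}")
    by_key: dict[tuple, list[float]] = {}
    for r in records:
        by_key.setdefault(r.unique_key, []).append(r.pka_exp)
    key_pkas = np.array([np.mean(by_key[k]) for k in keys])
    # a stratified draw needs at least one test key per stratum
    max_bins = max(1, int(np.floor(test_fraction * len(keys))))
    if max_bins < n_strata:
        warnings.warn(f"small key set: merging to {max_bins} pKa strata",
                      stacklevel=2)
    strata = _stratum_labels(key_pkas, n_bins=min(n_strata, max_bins))
    child_seeds = [int(s.generate_state(1)[0] % (2 ** 31))
                   for s in np.random.SeedSequence(seed).spawn(n_splits)]
    plan = SplitPlan(n_splits=n_splits, test_fraction=test_fraction, seed=seed)
    key_arr = np.arange(len(keys))
    for child in child_seeds:
        sss = StratifiedShuffleSplit(n_splits=1, test_size=test_fraction,
                                     random_state=child)
        train_idx, test_idx = next(sss.split(key_arr.reshape(-1, 1), strata))
        plan.assignments.append({
            "train": [keys[i] for i in sorted(train_idx)],
            "test": [keys[i] for i in sorted(test_idx)]})
    return plan


def augment_training(train_records: list[PkaRecord], conformer_source,
                     policy: AugmentationPolicy = AugmentationPolicy()
                     ) -> list[PkaRecord]:
    """Add conformer copies of strongly shifted training records.

    ``conformer_source`` maps a unique key to alternative structure ids
    (mapping or callable).  Only records with |pKa shift| above the policy
    threshold gain copies, capped at ``max_conformers``; each copy carries
    the original label.  Apply strictly after splitting, to training records
    only.
    """
    lookup = conformer_source if callable(conformer_source) \
        else lambda key: conformer_source.get(key, [])
    out = list(train_records)
    for rec in train_records:
        if abs(rec.pka_shift) <= policy.shift_threshold:
            continue
        conformers = list(lookup(rec.unique_key) or [])[:policy.max_conformers]
        for sid in conformers:
            out.append(replace(rec, structure_refs=(sid,), augmented=True))
    return out


def summarize_table(records: list[PkaRecord]) -> pd.DataFrame:
    """Per-residue-type counts of unique residues, measurements, structures."""
    aas = sorted(MODEL_PKA)
    rows = {}
    for aa in aas:
        sub = [r for r in records if r.aa == aa]
        rows[aa] = {
            "unique_residues": len({r.unique_key for r in sub}),
            "n_pka": len(sub),
            "n_structures": len({s for r in sub for s in r.structure_refs}),
        }
    return pd.DataFrame.from_dict(rows, orient="index")
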