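"""Dataset curation: parsing, standardization, deduplication and splitting.

Raw activity tables (CSV/TSV/SMILES/SDF) are turned into standardized
:class:`MoleculeRecord` objects: the largest organic fragment is kept, a
canonical tautomer is chosen, aromaticity is perceived, and duplicates are
collapsed on the stereochemistry-aware standard InChI.  Records whose label
disagrees within an InChI group are surfaced as conflict groups and resolved
by an explicit policy.  Splitting is stratified by activity class so that the
rare active class is represented in every partition.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem.MolStandardize import rdMolStandardize

logger = logging.getLogger(__name__)

RDLogger.DisableLog("rdApp.*")

VALID_LABELS = ("active", "inactive", "unknown")
VALID_SOURCES = ("chembl", "pubchem", "literature", "synthetic", "library")

#: tokens accepted in input tables, normalised to canonical labels
LABEL_TOKENS = {
    "active": "active", "1": "active", "act": "active", "pos": "active",
    "inactive": "inactive", "0": "inactive", "inact": "inactive",
    "neg": "inactive", "unknown": "unknown", "": "unknown", "na": "unknown",
}


class CurationError(ValueError):
    """Raised for unrecoverable curation problems (bad file, bad policy)."""


class EmptyStructureError(CurationError):
    """Standardization removed every organic fragment (e.g. a pure salt)."""


@dataclass(frozen=True)
class MoleculeRecord:
    """One standardized molecule with identifiers, label and provenance."""

    id: str
    smiles: str
    inchi: str = ""
    label: str = "unknown"
    source: str = "synthetic"
    assay_note: str = ""

    def __post_init__(self) -> None:
        if self.label not in VALID_LABELS:
            raise CurationError(f"unknown label {self.label!r} for {self.id}")


@dataclass(frozen=True)
class Reject:
    """A row that could not be turned into a record, with the reason."""

    row: int
    identifier: str
    reason: str


@dataclass
class DatasetSplit:
    """Record-id partitions of a curated dataset.

    ``test2`` is optionally carved out of the training ids after the primary
    train/test1 split, mirroring a nested hold-out scheme in which a second
    test set validates models tuned on the reduced training set.
    """

    train: list[str]
    test1: list[str]
    test2: list[str] = field(default_factory=list)
    seed: int = 0
    fractions: tuple[float, ...] = ()


# ---------------------------------------------------------------------------
# parsing

def _records_from_frame(frame: pd.DataFrame, column_map: dict[str, str],
                        source: str) -> tuple[list[MoleculeRecord], list[Reject]]:
    id_col = column_map.get("id")
    smiles_col = column_map["smiles"]
    label_col = column_map.get("label")
    records: list[MoleculeRecord] = []
    rejects: list[Reject] = []
    for row_no, row in enumerate(frame.itertuples(index=False)):
        row_d = dict(zip(frame.columns, row))
        mol_id = str(row_d[id_col]) if id_col else f"ROW{row_no:06d}"
        smiles = str(row_d[smiles_col]).strip()
        token = str(row_d[label_col]).strip().lower() if label_col else ""
        if token not in LABEL_TOKENS:
            raise CurationError(f"unknown label token {token!r} (row {row_no})")
        mol = Chem.MolFromSmiles(smiles)
        if mol is None or mol.GetNumHeavyAtoms() == 0:
            rejects.append(Reject(row_no, mol_id, f"unparseable SMILES {smiles!r}"))
            continue
        records.append(MoleculeRecord(id=mol_id, smiles=Chem.MolToSmiles(mol),
                                      label=LABEL_TOKENS[token], source=source))
    return records, rejects


def parse_molecule_table(path: str | Path, format: str | None = None,
                         column_map: dict[str, str] | None = None,
                         source: str = "literature",
                         ) -> tuple[list[MoleculeRecord], list[Reject]]:
    """Read a molecule table and return ``(records, rejects)``.

    ``format`` is one of ``csv``, ``tsv``, ``smi``, ``sdf`` (inferred from the
    suffix when omitted).  Unparseable structures are reported in the reject
    list, never silently dropped.
    """
    path = Path(path)
    if not path.exists():
        raise CurationError(f"no such file: {path}")
    fmt = format or path.suffix.lstrip(".").lower()
    if fmt not in ("csv", "tsv", "smi", "sdf"):
        raise CurationError(f"unknown format {fmt!r}")

    if fmt in ("csv", "tsv"):
        frame = pd.read_csv(path, sep="," if fmt == "csv" else "\t",
                            dtype=str, keep_default_na=False)
        cmap = column_map or {"id": "id", "smiles": "smiles", "label": "label"}
        cmap = {k: v for k, v in cmap.items() if v in frame.columns}
        if "smiles" not in cmap:
            raise CurationError(f"no SMILES column in {path}")
        records, rejects = _records_from_frame(frame, cmap, source)
    elif fmt == "smi":
        rows = []
        for line in path.read_text().splitlines():
            parts = line.split()
            if parts:
                rows.append({"smiles": parts[0],
                             "id": parts[1] if len(parts) > 1 else ""})
        frame = pd.DataFrame(rows, columns=["smiles", "id"])
        frame.loc[frame["id"] == "", "id"] = [
            f"ROW{i:06d}" for i in frame.index[frame["id"] == ""]]
        records, rejects = _records_from_frame(
            frame, {"id": "id", "smiles": "smiles"}, source)
    else:  # sdf
        records, rejects = [], []
        supplier = Chem.SDMolSupplier(str(path), removeHs=False)
        for row_no, mol in enumerate(supplier):
            if mol is None or mol.GetNumHeavyAtoms() == 0:
                rejects.append(Reject(row_no, f"SDF{row_no:06d}",
                                      "unparseable SDF record"))
                continue
            mol_id = mol.GetProp("_Name") if mol.HasProp("_Name") else ""
            token = (mol.GetProp("label").strip().lower()
                     if mol.HasProp("label") else "")
            if token not in LABEL_TOKENS:
                raise CurationError(f"unknown label token {token!r} (record {row_no})")
            records.append(MoleculeRecord(
                id=mol_id or f"SDF{row_no:06d}",
                smiles=Chem.MolToSmiles(Chem.RemoveHs(mol)),
                label=LABEL_TOKENS[token], source=source))

    if not records:
        raise CurationError(f"no parseable rows in {path}")
    logger.info("parsed %s: %d records, %d rejects", path, len(records), len(rejects))
    return records, rejects


# ---------------------------------------------------------------------------
# standardization

# tautomer canonicalization must not erase stereocentres: deduplication is
# chirality-aware, so enantiomers have to stay distinct records
_TAUTOMER_PARAMS = rdMolStandardize.CleanupParameters()
_TAUTOMER_PARAMS.tautomerRemoveSp3Stereo = False
_TAUTOMER_PARAMS.tautomerRemoveBondStereo = False
_TAUTOMERIZER = rdMolStandardize.TautomerEnumerator(_TAUTOMER_PARAMS)
_NORMALIZER = rdMolStandardize.Normalizer()


def _largest_organic_fragment(mol: Chem.Mol) -> Chem.Mol:
    """Keep the carbon-containing fragment with the most heavy atoms.

    Ties are broken by lexicographic order of the fragment's canonical SMILES,
    so the choice is reproducible regardless of atom numbering.
    """
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    organic = [f for f in frags
               if any(a.GetAtomicNum() == 6 for a in f.GetAtoms())]
    if not organic:
        raise EmptyStructureError(
            f"no organic fragment left in {Chem.MolToSmiles(mol)!r}")
    return max(organic,
               key=lambda f: (f.GetNumHeavyAtoms(), Chem.MolToSmiles(f)))


def standardize(record: MoleculeRecord) -> MoleculeRecord:
    """Standardize a record: fragment stripping, normalization, tautomer.

    The pipeline is (1) keep the largest organic fragment, (2) normalise
    functional-group/mesomeric representation, (3) pick the canonical tautomer
    by RDKit's deterministic tautomer scoring, (4) perceive aromaticity and
    emit canonical SMILES plus the stereo-aware standard InChI.  The procedure
    is idempotent: standardizing an already-standard record is a no-op.
    """
    mol = Chem.MolFromSmiles(record.smiles)
    if mol is None:
        raise CurationError(f"unparseable SMILES for {record.id}")
    mol = _largest_organic_fragment(mol)
    Chem.SanitizeMol(mol)
    mol = _NORMALIZER.normalize(mol)
    mol = _TAUTOMERIZER.Canonicalize(mol)
    smiles = Chem.MolToSmiles(mol)
    inchi = Chem.MolToInchi(mol, treatWarningAsError=False)
    if not inchi:
        raise CurationError(f"empty InChI for {record.id}")
    return replace(record, smiles=smiles, inchi=inchi)


# ---------------------------------------------------------------------------
# deduplication and conflict resolution

def deduplicate(records: list[MoleculeRecord],
                ) -> tuple[list[MoleculeRecord], list[list[MoleculeRecord]]]:
    """Collapse records sharing a stereo-aware InChI.

    Returns the surviving records (one per InChI whose members agree on the
    label) and the conflict groups (members disagree) for explicit resolution.
    The result is independent of input order: groups are keyed by InChI and
    the survivor of an agreeing group is its lexicographically first id.
    """
    groups: dict[str, list[MoleculeRecord]] = {}
    for rec in records:
        if not rec.inchi:
            raise CurationError(f"record {rec.id} not standardized (no InChI)")
        groups.setdefault(rec.inchi, []).append(rec)

    survivors: list[MoleculeRecord] = []
    conflicts: list[list[MoleculeRecord]] = []
    for inchi in sorted(groups):
        members = sorted(groups[inchi], key=lambda r: r.id)
        labels = {m.label for m in members}
        if len(labels) == 1:
            survivors.append(members[0])
        else:
            conflicts.append(members)
    return survivors, conflicts


def resolve_conflicts(conflict_groups: list[list[MoleculeRecord]],
                      policy: str = "drop") -> list[MoleculeRecord]:
    """Resolve label-conflicting duplicate groups.

    Policies: ``drop`` discards the whole group (conservative default),
    ``prefer_active``/``prefer_inactive`` keep one record with the preferred
    label, ``majority`` keeps the most frequent label (ties resolved to
    ``drop``).  The resolution is recorded in ``assay_note``.
    """
    if policy not in ("prefer_active", "prefer_inactive", "drop", "majority"):
        raise CurationError(f"unknown policy {policy!r}")
    resolved: list[MoleculeRecord] = []
    for group in conflict_groups:
        members = sorted(group, key=lambda r: r.id)
        labels = [m.label for m in members]
        if policy == "drop":
            continue
        if policy == "majority":
            counts = {lab: labels.count(lab) for lab in set(labels)}
            top = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
            if len(top) > 1 and top[0][1] == top[1][1]:
                continue  # tie: fall back to drop
            winner = top[0][0]
        else:
            winner = policy.removeprefix("prefer_")
            if winner not in labels:
                continue
        keeper = next(m for m in members if m.label == winner)
        note = f"label conflict {sorted(set(labels))} resolved by {policy}"
        resolved.append(replace(keeper, assay_note=note))
    return resolved


# ---------------------------------------------------------------------------
# splitting

def split_dataset(records: list[MoleculeRecord], test_fraction: float = 0.03,
                  seed: int = 0, carve_test2: int | None = None) -> DatasetSplit:
    """Stratified random train/test split, optionally carving a second test set.

    ``test_fraction`` of each class (rounded, at least one molecule when the
    class is present) goes to ``test1``.  When ``carve_test2`` is given, that
    many molecules are drawn — again stratified — from the training ids to
    form ``test2``, so ``|train| + |test1|`` still equals the curated dataset
    size.  Deterministic for a fixed seed.
    """
    if not 0 < test_fraction < 1:
        raise CurationError("test_fraction must be in (0,1)")
    by_class: dict[str, list[str]] = {}
    for rec in records:
        by_class.setdefault(rec.label, []).append(rec.id)
    if set(by_class) != {"active", "inactive"}:
        raise CurationError(
            f"both classes required for a modelling split, got {sorted(by_class)}")

    rng = np.random.default_rng(seed)
    train: list[str] = []
    test1: list[str] = []
    for label in sorted(by_class):
        ids = sorted(by_class[label])
        rng.shuffle(ids)
        n_test = max(1, round(test_fraction * len(ids)))
        test1.extend(ids[:n_test])
        train.extend(ids[n_test:])

    test2: list[str] = []
    if carve_test2:
        label_of = {r.id: r.label for r in records}
        frac2 = carve_test2 / len(train)
        remaining: list[str] = []
        train_by_class: dict[str, list[str]] = {}
        for mid in train:
            train_by_class.setdefault(label_of[mid], []).append(mid)
        for label in sorted(train_by_class):
            ids = sorted(train_by_class[label])
            rng.shuffle(ids)
            n2 = max(1, round(frac2 * len(ids)))
            test2.extend(ids[:n2])
            remaining.extend(ids[n2:])
        # train keeps test2 members out only for the nested stage; the primary
        # partition (train/test1) is unchanged
        split = DatasetSplit(train=sorted(train), test1=sorted(test1),
                             test2=sorted(test2), seed=seed,
                             fractions=(1 - test_fraction, test_fraction))
        split.train_reduced = sorted(remaining)  # type: ignore[attr-defined]
        return split
    return DatasetSplit(train=sorted(train), test1=sorted(test1), seed=seed,
                        fractions=(1 - test_fraction, test_fraction))


# ---------------------------------------------------------------------------
# persistence

def write_curated(records: list[MoleculeRecord], path: str | Path) -> None:
    pd.DataFrame([r.__dict__ for r in records]).to_csv(path, index=False)


def read_curated(path: str | Path) -> list[MoleculeRecord]:
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    return [MoleculeRecord(**row) for row in frame.to_dict("records")]


def write_rejects(rejects: list[Reject], path: str | Path) -> None:
    pd.DataFrame([r.__dict__ for r in rejects],
                 columns=["row", "identifier", "reason"]).to_csv(path, index=False)


def write_split_manifest(split: DatasetSplit, path: str | Path) -> None:
    payload = {"seed": split.seed, "fractions": list(split.fractions),
               "train": split.train, "test1": split.test1, "test2": split.test2}
    if hasattr(split, "train_reduced"):
        payload["train_reduced"] = split.train_reduced
    Path(path).write_text(json.dumps(payload, indent=1))
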