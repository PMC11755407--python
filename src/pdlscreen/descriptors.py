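"""Molecular descriptor families: fingerprints, 2D panel, 3D and voxel grids.

Implements every descriptor family used by the screening models:

* binary fingerprints — 166 MACCS structural keys, 1024-bit hashed circular
  (Morgan, radius 2 by default) and 2048-bit hashed path fingerprints;
* a frozen 242-column 2D panel (42 molecular quantum numbers + 200 named
  RDKit whole-molecule descriptors, see :mod:`pdlscreen._manifest_2d`);
* 3D families computed on a conformer — AUTOCORR3D (80), MoRSE (224,
  unweighted plus mass/van-der-Waals-volume/polarizability/ion-polarity/
  I-state weighted variants), RDF (210) and WHIM (114);
* property-weighted voxel grids — per-atom weights (atomic number, Crippen
  logP or molar-refractivity contributions, Gasteiger or MMFF partial
  charges) smeared onto a cubic grid with a truncated Gaussian kernel.

Docked poses can replace embedded geometries via :func:`adopt_docked_pose`,
which reconciles atom order between a pre-docking and a post-docking SDF
record by graph matching.
"""

from __future__ import annotations

import builtins
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import AllChem, Descriptors, MACCSkeys, rdFingerprintGenerator, rdMolDescriptors

from ._manifest_2d import DESCRIPTOR_2D_NAMES, MQN_NAMES, RDKIT_2D_NAMES
from .curation import MoleculeRecord

logger = logging.getLogger(__name__)

FAMILY_SIZES = {
    "maccs": 166, "morgan": 1024, "pathfp": 2048, "d2d": 242,
    "autocorr3d": 80, "morse": 224, "rdf": 210, "whim": 114, "voxel": 1331,
}
FINGERPRINT_FAMILIES = ("maccs", "morgan", "pathfp")
THREED_FAMILIES = ("autocorr3d", "morse", "rdf", "whim")

GRID_PROPERTIES = ("atomic_number", "logp", "mr", "gasteiger", "mmff")


class DescriptorError(ValueError):
    """Raised for unusable inputs to descriptor computations."""


@dataclass(frozen=True)
class GridSpec:
    """Geometry and property choice for a voxel-grid descriptor.

    ``n_per_axis`` voxels per axis on a cube of side ``edge_length`` Å; each
    atom's property weight is deposited with a Gaussian of width ``sigma``
    (default 0.7 × voxel pitch) truncated at 3σ.
    """

    n_per_axis: int = 11
    edge_length: float = 15.0
    sigma: float | None = None
    property: str = "mr"

    def __post_init__(self) -> None:
        if self.n_per_axis < 1 or self.edge_length <= 0:
            raise DescriptorError("grid must have positive size")
        if self.sigma is not None and self.sigma <= 0:
            raise DescriptorError("sigma must be positive")
        if self.property not in GRID_PROPERTIES:
            raise DescriptorError(f"unknown grid property {self.property!r}")

    @builtins.property
    def pitch(self) -> float:
        return self.edge_length / self.n_per_axis

    @builtins.property
    def effective_sigma(self) -> float:
        return self.sigma if self.sigma is not None else 0.7 * self.pitch

    @builtins.property
    def n_voxels(self) -> int:
        return self.n_per_axis ** 3


@dataclass
class Conformer:
    """A molecule with one set of 3D coordinates."""

    molecule_id: str
    mol: Chem.Mol
    pose_source: str = "embedded"  # embedded | docked

    def __post_init__(self) -> None:
        if self.mol.GetNumConformers() == 0:
            raise DescriptorError(f"{self.molecule_id}: no 3D coordinates")
        if self.mol.GetNumHeavyAtoms() < 1:
            raise DescriptorError(f"{self.molecule_id}: no heavy atoms")
        coords = self.mol.GetConformer().GetPositions()
        if not np.all(np.isfinite(coords)):
            raise DescriptorError(f"{self.molecule_id}: non-finite coordinates")


@dataclass
class DescriptorMatrix:
    """Dense named descriptor matrix; rows are molecules, columns descriptors."""

    row_ids: list[str]
    column_names: list[str]
    values: np.ndarray
    family_tags: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.column_names)) != len(self.column_names):
            raise DescriptorError("duplicate column names")
        if self.values.shape != (len(self.row_ids), len(self.column_names)):
            raise DescriptorError("matrix shape does not match row/column names")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.row_ids,
                            columns=self.column_names)

    def subset_columns(self, names: list[str]) -> "DescriptorMatrix":
        index = {c: i for i, c in enumerate(self.column_names)}
        missing = [n for n in names if n not in index]
        if missing:
            raise DescriptorError(f"missing columns: {missing[:5]}")
        cols = [index[n] for n in names]
        return DescriptorMatrix(self.row_ids, list(names),
                                self.values[:, cols],
                                {n: self.family_tags[n] for n in names})

    def family_columns(self, family: str) -> list[str]:
        return [c for c in self.column_names if self.family_tags[c] == family]

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index_label="id")
        Path(str(path) + ".families.csv").write_text(
            "\n".join(f"{c},{self.family_tags[c]}" for c in self.column_names))

    @classmethod
    def from_csv(cls, path: str | Path) -> "DescriptorMatrix":
        frame = pd.read_csv(path, index_col="id")
        fam = dict(line.split(",") for line in
                   Path(str(path) + ".families.csv").read_text().splitlines())
        return cls([str(i) for i in frame.index], list(frame.columns),
                   frame.to_numpy(dtype=np.float64), fam)


def _as_mol(mol_or_smiles: Chem.Mol | str | MoleculeRecord) -> Chem.Mol:
    if isinstance(mol_or_smiles, MoleculeRecord):
        mol_or_smiles = mol_or_smiles.smiles
    if isinstance(mol_or_smiles, str):
        mol = Chem.MolFromSmiles(mol_or_smiles)
        if mol is None:
            raise DescriptorError(f"unparseable SMILES {mol_or_smiles!r}")
        return mol
    return mol_or_smiles


# ---------------------------------------------------------------------------
# fingerprints

def compute_maccs(mol: Chem.Mol | str) -> np.ndarray:
    """166 MACCS structural keys as a 0/1 vector (key 1 .. key 166)."""
    mol = _as_mol(mol)
    bv = MACCSkeys.GenMACCSKeys(mol)  # 167 bits; bit 0 is unused padding
    arr = np.zeros(167, dtype=np.uint8)
    for b in bv.GetOnBits():
        arr[b] = 1
    return arr[1:]


def compute_morgan(mol: Chem.Mol | str, n_bits: int = 1024,
                   radius: int = 2) -> np.ndarray:
    """Hashed circular-environment (Morgan) fingerprint."""
    mol = _as_mol(mol)
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    return gen.GetFingerprintAsNumPy(mol).astype(np.uint8)


def compute_path_fp(mol: Chem.Mol | str, n_bits: int = 2048) -> np.ndarray:
    """Hashed path-based (RDKit) fingerprint."""
    mol = _as_mol(mol)
    bv = Chem.RDKFingerprint(mol, fpSize=n_bits)
    arr = np.zeros(n_bits, dtype=np.uint8)
    for b in bv.GetOnBits():
        arr[b] = 1
    return arr


# ---------------------------------------------------------------------------
# 2D panel

def compute_2d(mol: Chem.Mol | str,
               return_flags: bool = False):
    """The frozen 242-descriptor 2D panel (42 MQN + 200 RDKit descriptors).

    A descriptor that is undefined or non-finite for the molecule is imputed
    as 0 and flagged; with ``return_flags`` the flagged names are returned too.
    """
    mol = _as_mol(mol)
    values = np.zeros(len(DESCRIPTOR_2D_NAMES), dtype=np.float64)
    flags: list[str] = []
    values[:42] = rdMolDescriptors.MQNs_(mol)
    fns = dict(Descriptors._descList)
    for j, name in enumerate(RDKIT_2D_NAMES, start=42):
        try:
            v = float(fns[name](mol))
        except Exception:
            v = np.nan
        if not np.isfinite(v):
            flags.append(name)
            v = 0.0
        values[j] = v
    if flags:
        logger.warning("2D descriptors undefined, imputed 0: %s", flags)
    return (values, flags) if return_flags else values


# ---------------------------------------------------------------------------
# conformers

def embed_conformer(record: MoleculeRecord | str, seed: int = 0,
                    molecule_id: str | None = None) -> Conformer:
    """Generate one ETKDG 3D conformer (hydrogens added then stripped)."""
    smiles = record.smiles if isinstance(record, MoleculeRecord) else record
    mid = molecule_id or (record.id if isinstance(record, MoleculeRecord)
                          else smiles)
    mol = Chem.AddHs(_as_mol(smiles))
    params = AllChem.ETKDGv3()
    params.randomSeed = seed & 0x7FFFFFFF
    if AllChem.EmbedMolecule(mol, params) != 0:
        params.useRandomCoords = True
        if AllChem.EmbedMolecule(mol, params) != 0:
            raise DescriptorError(f"{mid}: embedding failed")
    mol = Chem.RemoveHs(mol)
    return Conformer(molecule_id=mid, mol=mol, pose_source="embedded")


def read_sdf(path: str | Path) -> list[tuple[str, Chem.Mol]]:
    """Read a V2000 SDF; returns (name, mol-with-conformer) pairs."""
    out = []
    for i, mol in enumerate(Chem.SDMolSupplier(str(path), removeHs=False)):
        if mol is None:
            logger.warning("unreadable SDF record %d in %s", i, path)
            continue
        name = mol.GetProp("_Name") if mol.HasProp("_Name") else f"SDF{i:06d}"
        out.append((name, mol))
    return out


def write_sdf(conformers: list[Conformer], path: str | Path) -> None:
    writer = Chem.SDWriter(str(path))
    for conf in conformers:
        conf.mol.SetProp("_Name", conf.molecule_id)
        writer.write(conf.mol)
    writer.close()


def adopt_docked_pose(pre_mol: Chem.Mol, post_mol: Chem.Mol,
                      molecule_id: str | None = None) -> Conformer:
    """Transfer docked coordinates onto the pre-docking atom order.

    Both records must describe the same molecule (equal standard InChI,
    coordinates ignored); the post-docking record carries the pose.  Atom
    order is reconciled by graph matching; among automorphic matches the one
    whose mapped coordinates stay closest to the pre-docking geometry is
    chosen, which resolves symmetry-equivalent atoms deterministically.
    """
    pre = Chem.RemoveHs(Chem.Mol(pre_mol))
    post = Chem.RemoveHs(Chem.Mol(post_mol))
    if pre.GetNumAtoms() != post.GetNumAtoms():
        raise DescriptorError("atom-count mismatch between pre and post records")
    if Chem.MolToInchi(pre) != Chem.MolToInchi(post):
        raise DescriptorError("InChI mismatch: pre and post records differ")
    matches = post.GetSubstructMatches(pre, uniquify=False, useChirality=False,
                                       maxMatches=10000)
    if not matches:
        raise DescriptorError("graph matching failed")
    pre_xyz = pre.GetConformer().GetPositions()
    post_xyz = post.GetConformer().GetPositions()
    cost = [float(np.sum((post_xyz[list(m)] - pre_xyz) ** 2)) for m in matches]
    best = matches[int(np.argmin(cost))]
    out = Chem.Mol(pre)
    conf = out.GetConformer()
    for i, j in enumerate(best):
        conf.SetAtomPosition(i, post.GetConformer().GetAtomPosition(int(j)))
    mid = molecule_id or (pre_mol.GetProp("_Name")
                          if pre_mol.HasProp("_Name") else "docked")
    return Conformer(molecule_id=mid, mol=out, pose_source="docked")


# ---------------------------------------------------------------------------
# 3D families

_3D_FNS = {
    "autocorr3d": rdMolDescriptors.CalcAUTOCORR3D,
    "morse": rdMolDescriptors.CalcMORSE,
    "rdf": rdMolDescriptors.CalcRDF,
    "whim": rdMolDescriptors.CalcWHIM,
}


def compute_3d(conformer: Conformer, return_flags: bool = False):
    """Concatenated AUTOCORR3D + MoRSE + RDF + WHIM vector (628 entries).

    Families whose geometric terms are undefined for the conformer (e.g. a
    single heavy atom) are zero-filled and flagged.
    """
    values: list[np.ndarray] = []
    flags: list[str] = []
    for family in THREED_FAMILIES:
        try:
            vec = np.asarray(_3D_FNS[family](conformer.mol), dtype=np.float64)
            if not np.all(np.isfinite(vec)):
                raise ValueError("non-finite")
        except Exception:
            vec = np.zeros(FAMILY_SIZES[family])
            flags.append(family)
        values.append(vec)
    if flags:
        logger.warning("%s: 3D families zero-filled: %s",
                       conformer.molecule_id, flags)
    out = np.concatenate(values)
    return (out, flags) if return_flags else out


def threed_names() -> list[str]:
    names: list[str] = []
    for family in THREED_FAMILIES:
        names += [f"{family.upper()}_{i:03d}" for i in range(FAMILY_SIZES[family])]
    return names


# ---------------------------------------------------------------------------
# voxel grids

def _atom_weights(mol: Chem.Mol, prop: str) -> np.ndarray:
    """Per-heavy-atom property weights for grid deposition."""
    if prop == "atomic_number":
        return np.array([a.GetAtomicNum() for a in mol.GetAtoms()], dtype=float)
    if prop in ("logp", "mr"):
        contribs = rdMolDescriptors._CalcCrippenContribs(mol)
        idx = 0 if prop == "logp" else 1
        return np.array([c[idx] for c in contribs], dtype=float)
    if prop == "gasteiger":
        work = Chem.Mol(mol)
        Chem.rdPartialCharges.ComputeGasteigerCharges(work)
        # fold the implicit-hydrogen contribution onto each heavy atom so a
        # neutral molecule's grid sums to ~0
        w = np.array([float(a.GetProp("_GasteigerCharge"))
                      + float(a.GetProp("_GasteigerHCharge"))
                      for a in work.GetAtoms()])
        return np.nan_to_num(w)
    if prop == "mmff":
        work = Chem.AddHs(Chem.Mol(mol))
        props = AllChem.MMFFGetMoleculeProperties(work)
        if props is None:
            raise DescriptorError("molecule not MMFF-typeable")
        charges = np.array([props.GetMMFFPartialCharge(i)
                            for i in range(work.GetNumAtoms())])
        # fold hydrogen charges onto their heavy neighbours so the grid sees
        # the heavy-atom skeleton only
        heavy = [a.GetIdx() for a in work.GetAtoms() if a.GetAtomicNum() > 1]
        folded = charges.copy()
        for atom in work.GetAtoms():
            if atom.GetAtomicNum() == 1:
                nb = atom.GetNeighbors()[0].GetIdx()
                folded[nb] += charges[atom.GetIdx()]
        return folded[heavy]
    raise DescriptorError(f"unknown grid property {prop!r}")


def compute_voxel_grid(conformer: Conformer, grid_spec: GridSpec,
                       return_clipped: bool = False):
    """Deposit per-atom property weights on a centered cubic voxel grid.

    The molecule is translated so its heavy-atom centroid coincides with the
    grid center.  Each atom's weight w is spread over grid points within 3σ
    with Gaussian factors normalised over the (unbounded) truncation ball, so
    the grid total equals Σw exactly for atoms whose 3σ ball lies inside the
    grid; weight falling on out-of-grid lattice points is reported as the
    clipped fraction.
    """
    mol = conformer.mol
    n, edge = grid_spec.n_per_axis, grid_spec.edge_length
    pitch, sigma = grid_spec.pitch, grid_spec.effective_sigma
    trunc = 3.0 * sigma

    xyz = mol.GetConformer().GetPositions()
    heavy = [a.GetIdx() for a in mol.GetAtoms() if a.GetAtomicNum() > 1]
    xyz = xyz[heavy] if len(heavy) < len(xyz) else xyz
    xyz = xyz - xyz.mean(axis=0)  # centroid at grid center
    weights = _atom_weights(mol, grid_spec.property)
    if len(weights) != len(xyz):
        raise DescriptorError("weight/coordinate length mismatch")

    # lattice coordinates: voxel centers at (i - (n-1)/2) * pitch
    half = (n - 1) / 2.0
    grid = np.zeros((n, n, n))
    clipped = 0.0
    reach = int(np.ceil(trunc / pitch))
    offs = np.arange(-reach, reach + 1)
    for pos, w in zip(xyz, weights):
        centers_idx = np.round(pos / pitch).astype(int)
        ii = centers_idx[0] + offs
        jj = centers_idx[1] + offs
        kk = centers_idx[2] + offs
        gi, gj, gk = np.meshgrid(ii, jj, kk, indexing="ij")
        px = np.stack([gi, gj, gk], axis=-1) * pitch
        d2 = np.sum((px - pos) ** 2, axis=-1)
        kern = np.exp(-d2 / (2 * sigma ** 2))
        kern[d2 > trunc ** 2] = 0.0
        total = kern.sum()
        if total <= 0:
            continue
        kern *= w / total
        inside = ((np.abs(gi) <= half) & (np.abs(gj) <= half)
                  & (np.abs(gk) <= half))
        clipped += float(np.abs(kern[~inside]).sum())
        np.add.at(grid,
                  (gi[inside] + int(half), gj[inside] + int(half),
                   gk[inside] + int(half)),
                  kern[inside])
    total_w = float(np.abs(weights).sum())
    clipped_frac = clipped / max(1.0, total_w)
    if clipped_frac > 0.02:
        logger.warning("%s: %.1f%% of grid mass clipped (molecule larger "
                       "than the %g Å grid)", conformer.molecule_id,
                       100 * clipped_frac, edge)
    flat = grid.ravel()
    return (flat, clipped_frac) if return_clipped else flat


def voxel_names(grid_spec: GridSpec) -> list[str]:
    prefix = {"atomic_number": "VOXZ", "logp": "VOXLOGP", "mr": "VOXMR",
              "gasteiger": "VOXGAST", "mmff": "VOXMMFF"}[grid_spec.property]
    return [f"{prefix}_{i:04d}" for i in range(grid_spec.n_voxels)]


# ---------------------------------------------------------------------------
# assembly

def assemble_matrix(records: list[MoleculeRecord],
                    conformers: dict[str, Conformer] | None = None,
                    families: tuple[str, ...] = ("morgan",),
                    grid_specs: tuple[GridSpec, ...] = (),
                    morgan_bits: int = 1024, morgan_radius: int = 2,
                    pathfp_bits: int = 2048) -> DescriptorMatrix:
    """Compute the requested families for every record into one named matrix.

    Column order is deterministic: families in the order requested, voxel
    grids last in ``grid_specs`` order.  Any 3D or voxel family requires a
    conformer for every record.
    """
    if not records:
        raise DescriptorError("empty record list")
    needs_3d = [f for f in families if f in THREED_FAMILIES] or grid_specs
    if needs_3d and not conformers:
        raise DescriptorError("3D/voxel families requested without conformers")
    if needs_3d:
        missing = [r.id for r in records if r.id not in (conformers or {})]
        if missing:
            raise DescriptorError(f"missing conformers for {missing[:5]}")

    col_names: list[str] = []
    tags: dict[str, str] = {}
    want_3d = tuple(f for f in families if f in THREED_FAMILIES)
    for fam in families:
        if fam == "maccs":
            block = [f"MACCS_{i + 1:03d}" for i in range(166)]
        elif fam == "morgan":
            block = [f"MORGAN_{i:04d}" for i in range(morgan_bits)]
        elif fam == "pathfp":
            block = [f"PATHFP_{i:04d}" for i in range(pathfp_bits)]
        elif fam == "d2d":
            block = list(DESCRIPTOR_2D_NAMES)
        elif fam in THREED_FAMILIES:
            block = [f"{fam.upper()}_{i:03d}" for i in range(FAMILY_SIZES[fam])]
        else:
            raise DescriptorError(f"unknown family {fam!r}")
        col_names += block
        tags.update({c: fam for c in block})
    for spec in grid_specs:
        block = voxel_names(spec)
        col_names += block
        tags.update({c: "voxel" for c in block})

    rows = []
    threed_index = {f: i for i, f in enumerate(THREED_FAMILIES)}
    for rec in records:
        parts: list[np.ndarray] = []
        full_3d: np.ndarray | None = None
        for fam in families:
            if fam == "maccs":
                parts.append(compute_maccs(rec.smiles))
            elif fam == "morgan":
                parts.append(compute_morgan(rec.smiles, morgan_bits, morgan_radius))
            elif fam == "pathfp":
                parts.append(compute_path_fp(rec.smiles, pathfp_bits))
            elif fam == "d2d":
                parts.append(compute_2d(rec.smiles))
            else:  # 3D family: compute all four once, slice what is requested
                if full_3d is None:
                    full_3d = compute_3d(conformers[rec.id])
                start = sum(FAMILY_SIZES[f] for f in THREED_FAMILIES
                            if threed_index[f] < threed_index[fam])
                parts.append(full_3d[start:start + FAMILY_SIZES[fam]])
        for spec in grid_specs:
            parts.append(compute_voxel_grid(conformers[rec.id], spec))
        rows.append(np.concatenate([np.asarray(p, dtype=np.float64)
                                    for p in parts]))
    values = np.vstack(rows)
    return DescriptorMatrix([r.id for r in records], col_names, values, tags)
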