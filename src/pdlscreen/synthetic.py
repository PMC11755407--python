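"""Synthetic SMILES datasets with a planted structure–activity rule.

The generator emulates the shape of a curated bioactivity collection: a
desk-scale library that is heavily imbalanced (default 1.4% actives, the
ratio of a few hundred actives to tens of thousands of inactives) in which
activity is *structurally determined* — a molecule is truly active iff it
contains a biphenyl moiety together with an amide group or a 1,3-oxazole
ring, motifs repeatedly associated with the active class of PD-1/PD-L1 axis
inhibitors.  Observed labels optionally carry symmetric flip noise; the
noiseless truth is kept in a sidecar so recovery can be measured.

Molecules are assembled from a combinatorial grammar (ring cores × linkers ×
substituents).  Every generated structure is verified post hoc against the
planted SMARTS rule, so actives provably match and inactives provably do
not; the inactive pool deliberately contains biphenyl-only and amide-only
decoys to make the conjunctive rule non-trivial.  A separate bank of
scaffolds absent from the grammar (steroids, long aliphatics, crown ethers,
sugars) provides library molecules guaranteed to be structurally unrelated
(max Tanimoto < 0.15 to pool exemplars) for exercising the applicability-
domain filter.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from rdkit import Chem

from .clustering import pairwise_tanimoto
from .curation import MoleculeRecord
from .descriptors import compute_morgan

logger = logging.getLogger(__name__)


class SyntheticError(ValueError):
    pass


#: planted rule: biphenyl AND (amide OR 1,3-oxazole)
RULE_BIPHENYL = Chem.MolFromSmarts("c1ccc(-c2ccccc2)cc1")
RULE_AMIDE = Chem.MolFromSmarts("[NX3][CX3]=[OX1]")
RULE_OXAZOLE = Chem.MolFromSmarts("c1ocnc1")


def matches_planted_rule(smiles: str) -> bool:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return False
    return bool(mol.HasSubstructMatch(RULE_BIPHENYL)
                and (mol.HasSubstructMatch(RULE_AMIDE)
                     or mol.HasSubstructMatch(RULE_OXAZOLE)))


@dataclass
class SyntheticSpec:
    """Study conditions for one synthetic dataset."""

    n_total: int = 3000
    active_fraction: float = 0.014
    label_noise: float = 0.01
    seed: int = 0
    scaffold_pool_size: int = 10

    def __post_init__(self) -> None:
        if not 0 < self.active_fraction < 0.5:
            raise SyntheticError("active_fraction must be in (0, 0.5)")
        if not 0 <= self.label_noise < 0.1:
            raise SyntheticError("label_noise must be in [0, 0.1)")
        if self.n_total < 10:
            raise SyntheticError("n_total too small")


@dataclass
class SyntheticDataset:
    records: list[MoleculeRecord]
    truth: dict[str, str]  # id -> noiseless label
    manifest: SyntheticSpec
    sidecar: dict = field(default_factory=dict)

    def truth_labels(self) -> list[str]:
        return [self.truth[r.id] for r in self.records]

    def observed_labels(self) -> list[str]:
        return [r.label for r in self.records]

    def write(self, out_dir: str | Path, stem: str = "synthetic") -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        lines = ["id,smiles,label"]
        lines += [f"{r.id},{r.smiles},{r.label}" for r in self.records]
        (out_dir / f"{stem}.csv").write_text("\n".join(lines) + "\n")
        (out_dir / f"{stem}.smi").write_text(
            "".join(f"{r.smiles} {r.id}\n" for r in self.records))
        payload = {"spec": self.manifest.__dict__, "truth": self.truth,
                   **self.sidecar}
        (out_dir / f"{stem}.truth.json").write_text(json.dumps(payload, indent=1))


# ---------------------------------------------------------------------------
# fragment grammar

NEUTRAL_SUBS = (
    "F", "Cl", "Br", "I", "C", "CC", "CCC", "C(C)C", "OC", "OCC", "O", "N",
    "NC", "C#N", "C(F)(F)F", "SC", "C=C", "CCO", "CCCC", "[N+](=O)[O-]",
    "N(C)C", "OC(C)C", "CC(C)(C)C", "C(=O)O", "C(=O)OC", "C(=O)C",
    "OC(=O)C", "S(C)(=O)=O", "COC", "CSC",
)
AMIDE_N_SUBS = ("C", "CC", "CCC", "C(C)C", "C1CCCC1", "CCO")

# Active grammar: biphenyl with the amide or 1,3-oxazole attached ortho or
# meta to the ring junction.  The proximity matters: it guarantees that some
# radius-2 circular environments span both the junction and the second motif,
# so the conjunctive rule is expressible as fingerprint bits and fingerprint
# models can in principle classify perfectly.
ACTIVE_TEMPLATES = (
    "O=C(N{r})c1cc({s})ccc1-c1ccc({t})cc1",
    "O=C(N{r})c1cccc({s})c1-c1ccc({t})cc1",
    "{s}c1ccc(-c2ccccc2C(=O)N{r})cc1",
    "{s}c1ccc(-c2cccc(C(=O)N{r})c2)cc1",
    "{s}c1ccc(-c2ccccc2-c2occn2)cc1",
    "{s}c1ccc(-c2cccc(-c3occn3)c2)cc1",
    "{s}c1cc(NC(C)=O)ccc1-c1ccc({t})cc1",
)

# Inactive grammar: mono/bicyclic cores plus deliberate hard negatives —
# biphenyl-only and amide-only decoys — so the planted rule is a genuine
# conjunction rather than a single-motif lookup.
INACTIVE_TEMPLATES = (
    "{s}c1ccc({t})cc1",
    "{s}c1ccc({t})cn1",
    "{s}c1ccc({t})nc1",
    "{s}c1ncc({t})cn1",
    "{s}c1ccc({t})s1",
    "{s}c1ccc({t})o1",
    "{s}c1ccc2ccccc2c1",
    "{s}C1CCC({t})CC1",
    "{s}c1ccc(C{t})cc1",
    "{s}c1ccc(O{t})cc1",
    "{s}c1cc({t})cc({u})c1",
    "{s}c1ccc(-c2ccc({t})s2)cc1",
    "{s}c1ccc(S(=O)(=O)C{t})cc1",
    "{s}c1ccc(-c2ccc({t})cc2)cc1",    # biphenyl decoys (no amide/oxazole)
    "{s}c1cc({t})ccc1-c1ccccc1",
    "O=C(N{r})c1ccc({s})cc1",          # amide decoys (no biphenyl)
    "O=C(N{r})c1cccc({s})c1",
    "O=C(N{r})Cc1ccc({s})cc1",
    "{s}c1ccc(NC(C)=O)cc1",
    "O=C(N{r})C{s2}",
)


def _fill(template: str, rng: np.random.Generator) -> str:
    out = template
    if "{s}" in out:
        out = out.replace("{s}", rng.choice(NEUTRAL_SUBS))
    if "{t}" in out:
        out = out.replace("{t}", rng.choice(NEUTRAL_SUBS))
    if "{u}" in out:
        out = out.replace("{u}", rng.choice(NEUTRAL_SUBS))
    if "{r}" in out:
        out = out.replace("{r}", rng.choice(AMIDE_N_SUBS))
    if "{s2}" in out:
        out = out.replace("{s2}", rng.choice(("C", "CC", "CCC", "CCCC", "CCCCC")))
    return out


def _generate_bucket(templates: tuple[str, ...], want_active: bool, n: int,
                     rng: np.random.Generator, taken: set[str]) -> list[str]:
    """Draw distinct canonical SMILES from a grammar until the quota is met.

    Every candidate is verified against the planted rule; candidates landing
    in the wrong class (or unparseable) are discarded.
    """
    out: list[str] = []
    attempts = 0
    limit = 500 * n + 1000
    while len(out) < n:
        attempts += 1
        if attempts > limit:
            raise SyntheticError(
                f"cannot generate {n} distinct "
                f"{'active' if want_active else 'inactive'} molecules")
        raw = _fill(templates[int(rng.integers(len(templates)))], rng)
        mol = Chem.MolFromSmiles(raw)
        if mol is None:
            continue
        can = Chem.MolToSmiles(mol)
        if can in taken or matches_planted_rule(can) != want_active:
            continue
        taken.add(can)
        out.append(can)
    return out


def generate(spec: SyntheticSpec) -> SyntheticDataset:
    """Generate an imbalanced labelled dataset under the planted rule.

    Deterministic per seed.  Truth labels follow the rule exactly; observed
    labels are truth with independent flips at probability ``label_noise``.
    """
    rng = np.random.default_rng(spec.seed)
    n_active = max(2, round(spec.n_total * spec.active_fraction))
    n_inactive = spec.n_total - n_active
    taken: set[str] = set()
    actives = _generate_bucket(ACTIVE_TEMPLATES, True, n_active, rng, taken)
    inactives = _generate_bucket(INACTIVE_TEMPLATES, False, n_inactive, rng, taken)

    smiles_all = actives + inactives
    truth_all = ["active"] * n_active + ["inactive"] * n_inactive
    order = rng.permutation(len(smiles_all))

    records: list[MoleculeRecord] = []
    truth: dict[str, str] = {}
    n_flipped = 0
    for row, j in enumerate(order):
        mid = f"SYN-{row:06d}"
        t = truth_all[j]
        obs = t
        if spec.label_noise > 0 and rng.random() < spec.label_noise:
            obs = "inactive" if t == "active" else "active"
            n_flipped += 1
        records.append(MoleculeRecord(id=mid, smiles=smiles_all[j], label=obs,
                                      source="synthetic"))
        truth[mid] = t
    logger.info("synthetic set: %d molecules, %d true actives, %d labels flipped",
                spec.n_total, n_active, n_flipped)
    return SyntheticDataset(records=records, truth=truth, manifest=spec,
                            sidecar={"n_flipped": n_flipped})


# ---------------------------------------------------------------------------
# screening library with planted hits and an AD-unrelated block

_UNRELATED_BANK = tuple(
    # steroid-like fused polycycles
    ["CC12CCC3C(CCC4CCCCC43C)C1CCC2O",
     "CC12CCC3C(CCC4CC(=O)CCC43C)C1CCC2O",
     "CC(C)CCCC(C)C1CCC2C1(C)CCC1C2CCC2CCCCC21C",
     "CC12CCC(=O)CC1CCC1C2CCC2(C)C(O)CCC12",
     "CC12CCC3C(CCC4CC(O)CCC43C)C1CCC2=O",
     "CC12CCC3C(CCC4CC(F)CCC43C)C1CCC2O",
     "OC1CCC2(C)C(CCC3C2CCC2(C)C3CCC2O)C1",
     "CC12CCC3C(CCC4COCCC43C)C1CCC2O"]
    # crown ethers / cyclic and acyclic polyethers / ketals
    + ["C1COCCO1", "C1COCCOCCO1", "C1COCCOCCOCCO1", "C1COCCOCCOCCOCCO1",
       "C1COCCOCCOCCOCCOCCO1", "COCCOCCOCCOCCOC", "COCCOCCOCCOC",
       "C1CCC2(CC1)OCCO2", "C1CC2(CCO1)OCCC2", "C1OC2COC1CO2"]
    # cage and fused saturated hydrocarbons
    + ["C1C2CC3CC1CC(C2)C3", "C1CC2CCC1C2", "C1CC2CCC1CC2",
       "C1CCC2(CC1)CCCCC2", "C12C3C4C1C1C2C3C41",
       "CC1(C)C2CCC1(C)CC2"]
    # sugars and open-chain polyols
    + ["OCC1OC(O)C(O)C(O)C1O", "OCC1OC(OC2OC(CO)C(O)C(O)C2O)C(O)C(O)C1O",
       "OCC1OC(O)C(O)C1O", "OCC(O)C(O)C(O)C(O)CO", "OCC(O)C(O)C(O)CO",
       "OCC(O)CO", "OC1COC(O)C(O)C1O"]
    # perfluorinated chains
    + ["FC(F)(F)C(F)(F)C(F)(F)C(F)(F)F",
       "FC(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)F",
       "FC(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)F",
       "OC(=O)C(F)(F)C(F)(F)C(F)(F)C(F)(F)F",
       "OCC(F)(F)C(F)(F)C(F)(F)C(F)(F)F"]
    # terpenoid-like saturated bicyclics with gem-dimethyl bridges
    + ["CC1(C)C2CCC1(C)C(O)C2", "CC1(C)C2CCC1(C)C(=O)C2",
       "CC12CCC(CC1O)C2(C)C", "OC1CC2CCC1(C)C2(C)C"]
)


def pool_exemplars(n: int = 30, seed: int = 12345) -> list[str]:
    """Representative molecules from both grammar classes.

    Used as the reference set when asserting that the unrelated block really
    is unrelated (max Tanimoto < 0.15).
    """
    rng = np.random.default_rng(seed)
    taken: set[str] = set()
    half = n // 2
    return (_generate_bucket(ACTIVE_TEMPLATES, True, half, rng, taken)
            + _generate_bucket(INACTIVE_TEMPLATES, False, n - half, rng, taken))


def unrelated_block(n: int, seed: int = 0,
                    max_similarity: float = 0.15) -> list[str]:
    """``n`` molecules structurally unrelated to the generator's grammar.

    Unrelatedness is asserted at generation time: every returned molecule has
    max Morgan-Tanimoto below ``max_similarity`` to the pool exemplars.
    """
    exemplar_fps = np.vstack([compute_morgan(s) for s in pool_exemplars()])
    rng = np.random.default_rng(seed)
    candidates = list(_UNRELATED_BANK)
    rng.shuffle(candidates)
    out: list[str] = []
    for smi in candidates:
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            continue
        can = Chem.MolToSmiles(mol)
        sims = pairwise_tanimoto(compute_morgan(can)[None, :], exemplar_fps)[0]
        if sims.max() < max_similarity:
            out.append(can)
        if len(out) == n:
            return out
    raise SyntheticError(
        f"only {len(out)} unrelated molecules available (need {n})")


def generate_screen_library(spec: SyntheticSpec, n_hits_planted: int = 2,
                            n_unrelated: int = 30) -> SyntheticDataset:
    """A screening library with unknown labels plus a truth sidecar.

    Contains ``n_hits_planted`` molecules satisfying the planted rule, an
    ``n_unrelated`` block outside the generator's chemistry (to exercise the
    applicability-domain filter) and rule-negative filler for the rest.
    """
    if n_hits_planted * 10 > spec.n_total:
        raise SyntheticError("n_hits_planted must be small vs n_total")
    rng = np.random.default_rng(spec.seed)
    n_filler = spec.n_total - n_hits_planted - n_unrelated
    if n_filler < 0:
        raise SyntheticError("library too small for requested blocks")
    taken: set[str] = set()
    hits = _generate_bucket(ACTIVE_TEMPLATES, True, n_hits_planted, rng, taken)
    filler = _generate_bucket(INACTIVE_TEMPLATES, False, n_filler, rng, taken)
    unrelated = unrelated_block(n_unrelated, seed=spec.seed)

    smiles_all = hits + filler + unrelated
    roles = (["hit"] * len(hits) + ["filler"] * len(filler)
             + ["unrelated"] * len(unrelated))
    order = rng.permutation(len(smiles_all))
    records, truth = [], {}
    hit_ids, unrelated_ids = [], []
    for row, j in enumerate(order):
        mid = f"LIB-{row:06d}"
        records.append(MoleculeRecord(id=mid, smiles=smiles_all[j],
                                      label="unknown", source="library"))
        truth[mid] = "active" if roles[j] == "hit" else "inactive"
        if roles[j] == "hit":
            hit_ids.append(mid)
        elif roles[j] == "unrelated":
            unrelated_ids.append(mid)
    return SyntheticDataset(
        records=records, truth=truth, manifest=spec,
        sidecar={"planted_hits": sorted(hit_ids),
                 "unrelated": sorted(unrelated_ids)})
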