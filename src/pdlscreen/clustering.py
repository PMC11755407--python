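"""Fingerprint clustering, centroids, X-category pruning and the AD rule.

The training set is grouped by a deterministic leader (sphere-exclusion)
algorithm on Tanimoto distance; the largest clusters are labelled A, B, C, D
in decreasing size.  Each cluster's centroid is the member with the highest
mean Tanimoto similarity to the rest of the cluster.  Members whose
similarity to their own centroid falls below a threshold (default 0.195) are
moved to a residual category X, which gets its own centroid.  A molecule is
inside the model's applicability domain (AD) iff its maximum Tanimoto
similarity over the five centroids is at least the threshold — similarity
exactly at the threshold is in-domain.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem.Scaffolds import MurckoScaffold

from .curation import MoleculeRecord

logger = logging.getLogger(__name__)

DEFAULT_AD_THRESHOLD = 0.195
CLUSTER_NAMES = tuple("ABCDEFGHIJKLMNOPQRSTUVWX"[:23])


class ClusteringError(ValueError):
    pass


def tanimoto(fp_a: np.ndarray, fp_b: np.ndarray) -> float:
    """Tanimoto similarity |a∧b| / |a∨b| of two equal-length bit vectors.

    Two all-zero vectors have undefined similarity; it is returned as 0.0
    with a warning.
    """
    a = np.asarray(fp_a, dtype=bool)
    b = np.asarray(fp_b, dtype=bool)
    if a.shape != b.shape:
        raise ClusteringError("fingerprint length mismatch")
    union = np.count_nonzero(a | b)
    if union == 0:
        warnings.warn("Tanimoto of two all-zero fingerprints; returning 0")
        return 0.0
    return np.count_nonzero(a & b) / union


def pairwise_tanimoto(fps_a: np.ndarray, fps_b: np.ndarray) -> np.ndarray:
    """Dense Tanimoto matrix between two stacks of bit vectors (rows)."""
    a = np.asarray(fps_a, dtype=np.float32)
    b = np.asarray(fps_b, dtype=np.float32)
    inter = a @ b.T
    pa = a.sum(axis=1)[:, None]
    pb = b.sum(axis=1)[None, :]
    union = pa + pb - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(union > 0, inter / union, 0.0)
    return sim


@dataclass
class ClusterModel:
    """Cluster assignments, centroids and the applicability-domain threshold."""

    cluster_labels: dict[str, str]
    centroids: dict[str, tuple[str, np.ndarray]]  # cluster -> (member id, fp)
    similarity_fp_family: str = "morgan"
    ad_threshold: float = DEFAULT_AD_THRESHOLD

    def __post_init__(self) -> None:
        if not 0 < self.ad_threshold < 1:
            raise ClusteringError("ad_threshold must be in (0,1)")

    def to_json(self, path: str | Path,
                smiles: dict[str, str] | None = None) -> None:
        payload = {
            "similarity_fp_family": self.similarity_fp_family,
            "ad_threshold": self.ad_threshold,
            "cluster_labels": self.cluster_labels,
            "centroids": {
                c: {"id": mid, "fp_bits": np.flatnonzero(fp).tolist(),
                    "n_bits": int(len(fp)),
                    "smiles": (smiles or {}).get(mid, "")}
                for c, (mid, fp) in self.centroids.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "ClusterModel":
        data = json.loads(Path(path).read_text())
        centroids = {}
        for c, entry in data["centroids"].items():
            fp = np.zeros(entry["n_bits"], dtype=np.uint8)
            fp[entry["fp_bits"]] = 1
            centroids[c] = (entry["id"], fp)
        return cls(cluster_labels=data["cluster_labels"], centroids=centroids,
                   similarity_fp_family=data["similarity_fp_family"],
                   ad_threshold=data["ad_threshold"])


def _sorted_ids(fps: dict[str, np.ndarray]) -> list[str]:
    # canonical processing order: densest fingerprints first, then bit
    # pattern, then id — independent of insertion order
    return sorted(fps, key=lambda i: (-int(np.count_nonzero(fps[i])),
                                      fps[i].tobytes(), i))


def cluster_dataset(fps: dict[str, np.ndarray], n_target_clusters: int = 4,
                    similarity_cutoff: float = 0.25,
                    fp_family: str = "morgan",
                    ad_threshold: float = DEFAULT_AD_THRESHOLD) -> ClusterModel:
    """Leader (sphere-exclusion) clustering on Tanimoto similarity.

    Molecules are visited in a canonical order; a molecule joins the most
    similar existing leader if that similarity is at least
    ``similarity_cutoff``, otherwise it opens a new cluster.  The
    ``n_target_clusters`` largest clusters are kept and labelled A, B, C, …
    by decreasing size; members of any smaller cluster are reassigned to
    their most similar kept leader.  Fully deterministic and independent of
    input ordering (up to relabelling).
    """
    if len(fps) < n_target_clusters:
        raise ClusteringError(
            f"{len(fps)} molecules < {n_target_clusters} clusters")
    order = _sorted_ids(fps)
    leaders: list[str] = []
    leader_fps: list[np.ndarray] = []
    members: dict[str, list[str]] = {}
    for mid in order:
        fp = fps[mid]
        if leaders:
            sims = pairwise_tanimoto(fp[None, :], np.vstack(leader_fps))[0]
            best = int(np.argmax(sims))
            if sims[best] >= similarity_cutoff:
                members[leaders[best]].append(mid)
                continue
        leaders.append(mid)
        leader_fps.append(fp)
        members[mid] = [mid]

    ranked = sorted(members, key=lambda l: (-len(members[l]), l))
    kept = ranked[:n_target_clusters]
    kept_fps = np.vstack([fps[l] for l in kept])
    labels: dict[str, str] = {}
    for rank, leader in enumerate(kept):
        for mid in members[leader]:
            labels[mid] = CLUSTER_NAMES[rank]
    for leader in ranked[n_target_clusters:]:
        for mid in members[leader]:
            sims = pairwise_tanimoto(fps[mid][None, :], kept_fps)[0]
            labels[mid] = CLUSTER_NAMES[int(np.argmax(sims))]

    model = ClusterModel(cluster_labels=labels, centroids={},
                         similarity_fp_family=fp_family,
                         ad_threshold=ad_threshold)
    model.centroids = _compute_centroids(model, fps)
    return model


def find_centroid(cluster_fps: dict[str, np.ndarray],
                  smiles: dict[str, str] | None = None) -> str:
    """The cluster member maximizing mean Tanimoto to all other members.

    Ties are broken by canonical SMILES order when available, then by id.
    A singleton cluster is its own centroid.
    """
    if not cluster_fps:
        raise ClusteringError("empty cluster")
    ids = sorted(cluster_fps)
    if len(ids) == 1:
        return ids[0]
    mat = np.vstack([cluster_fps[i] for i in ids])
    sims = pairwise_tanimoto(mat, mat)
    np.fill_diagonal(sims, 0.0)
    mean_sim = sims.sum(axis=1) / (len(ids) - 1)
    best = np.max(mean_sim)
    candidates = [ids[i] for i in np.flatnonzero(mean_sim >= best - 1e-12)]
    if smiles:
        candidates.sort(key=lambda i: (smiles.get(i, ""), i))
    else:
        candidates.sort()
    return candidates[0]


def _compute_centroids(model: ClusterModel, fps: dict[str, np.ndarray],
                       smiles: dict[str, str] | None = None,
                       ) -> dict[str, tuple[str, np.ndarray]]:
    clusters: dict[str, dict[str, np.ndarray]] = {}
    for mid, lab in model.cluster_labels.items():
        clusters.setdefault(lab, {})[mid] = fps[mid]
    out = {}
    for lab in sorted(clusters):
        cid = find_centroid(clusters[lab], smiles)
        out[lab] = (cid, fps[cid])
    return out


def prune_to_x(cluster_model: ClusterModel, fps: dict[str, np.ndarray],
               threshold: float = DEFAULT_AD_THRESHOLD,
               smiles: dict[str, str] | None = None) -> ClusterModel:
    """Move low-similarity members of every cluster to the residual category X.

    A member whose Tanimoto similarity to its own cluster centroid is below
    ``threshold`` is relabelled X.  Centroids of the surviving clusters are
    recomputed once (a single pass; membership is not re-evaluated after the
    recompute) and X receives its own centroid when nonempty.
    """
    if not 0 < threshold < 1:
        raise ClusteringError("threshold outside (0,1)")
    if not cluster_model.centroids:
        raise ClusteringError("centroids not computed")
    labels = dict(cluster_model.cluster_labels)
    for mid, lab in cluster_model.cluster_labels.items():
        _, cfp = cluster_model.centroids[lab]
        if tanimoto(fps[mid], cfp) < threshold:
            labels[mid] = "X"
    pruned = ClusterModel(cluster_labels=labels, centroids={},
                          similarity_fp_family=cluster_model.similarity_fp_family,
                          ad_threshold=threshold)
    pruned.centroids = _compute_centroids(pruned, fps, smiles)
    return pruned


def in_applicability_domain(fp: np.ndarray, cluster_model: ClusterModel,
                            ) -> tuple[bool, float, str | None]:
    """AD membership: max Tanimoto over the cluster centroids ≥ threshold.

    Returns ``(in_domain, max_similarity, nearest_cluster)``.  The rule is
    inclusive at the threshold (only strictly smaller similarity excludes).
    If the residual category X is empty the decision falls back to the
    available centroids and a note is logged.
    """
    if not cluster_model.centroids:
        raise ClusteringError("cluster model has no centroids")
    if "X" not in cluster_model.centroids:
        logger.info("AD evaluated without an X centroid (X empty)")
    best_sim, nearest = -1.0, None
    for lab in sorted(cluster_model.centroids):
        _, cfp = cluster_model.centroids[lab]
        s = tanimoto(fp, cfp)
        if s > best_sim:
            best_sim, nearest = s, lab
    if best_sim <= 0.0:
        return False, max(best_sim, 0.0), None
    return best_sim >= cluster_model.ad_threshold, best_sim, nearest


# ---------------------------------------------------------------------------
# Murcko scaffold analysis

def murcko_scaffold(smiles: str) -> str:
    """Canonical Murcko framework (ring systems + linkers, side chains off).

    Acyclic molecules have an empty framework and are counted in their own
    scaffold bin.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ClusteringError(f"unparseable SMILES {smiles!r}")
    return MurckoScaffold.MurckoScaffoldSmiles(mol=mol)


def murcko_summary(records: list[MoleculeRecord],
                   cluster_model: ClusterModel) -> pd.DataFrame:
    """Per-cluster molecule count, distinct Murcko scaffold count and %."""
    scaffolds: dict[str, set[str]] = {}
    counts: dict[str, int] = {}
    for rec in records:
        lab = cluster_model.cluster_labels.get(rec.id)
        if lab is None:
            continue
        counts[lab] = counts.get(lab, 0) + 1
        scaffolds.setdefault(lab, set()).add(murcko_scaffold(rec.smiles))
    rows = []
    for lab in sorted(counts):
        n, ns = counts[lab], len(scaffolds[lab])
        rows.append({"cluster": lab, "n_molecules": n, "n_scaffolds": ns,
                     "scaffold_pct": 100.0 * ns / n})
    return pd.DataFrame(rows)
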