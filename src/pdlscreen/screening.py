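"""Virtual screening: model probability + applicability domain + docking data.

A library molecule is a hit when its predicted probability of activity
reaches the probability threshold (default 0.64, the random-forest vote
fraction) *and* it lies inside the applicability domain (Tanimoto ≥ 0.195 to
at least one cluster centroid).  Externally computed docking affinities
(kcal/mol) can be ingested from a TSV and, optionally, applied as a third
filter; by default they are carried as annotation only.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .clustering import ClusterModel, in_applicability_domain
from .descriptors import DescriptorMatrix
from .models import TrainedModel, predict_proba

logger = logging.getLogger(__name__)


class ScreeningError(ValueError):
    pass


@dataclass
class ScreeningConfig:
    """Thresholds applied during the screen."""

    p_threshold: float = 0.64
    ad_threshold: float = 0.195
    dock_dg_cutoff: float | None = None  # kcal/mol; off unless docking given

    def __post_init__(self) -> None:
        if not 0 <= self.p_threshold <= 1:
            raise ScreeningError("p_threshold outside [0,1]")
        if not 0 < self.ad_threshold < 1:
            raise ScreeningError("ad_threshold outside (0,1)")


@dataclass
class ScreeningHit:
    """One library molecule with its screening verdict."""

    id: str
    smiles: str
    p_active: float
    in_ad: bool
    nearest_cluster: str | None
    max_centroid_similarity: float
    dock_dg: float | None = None
    passed: bool = False


def screen_library(model: TrainedModel, library_matrix: DescriptorMatrix,
                   cluster_model: ClusterModel,
                   config: ScreeningConfig | None = None,
                   docking: dict[str, float] | None = None,
                   smiles: dict[str, str] | None = None) -> list[ScreeningHit]:
    """Score and filter every library molecule.

    The AD similarity uses the fingerprint family recorded in the cluster
    model, which must be one of the library matrix's descriptor families.
    Hits are sorted by (passed, p_active desc, ΔG asc, centroid similarity
    desc, id) so the ranking is fully deterministic.
    """
    if not library_matrix.row_ids:
        raise ScreeningError("empty library")
    config = config or ScreeningConfig()
    cluster_model.ad_threshold = config.ad_threshold
    probs = predict_proba(model, library_matrix)

    fp_cols = library_matrix.family_columns(cluster_model.similarity_fp_family)
    if not fp_cols:
        raise ScreeningError(
            f"library matrix lacks the {cluster_model.similarity_fp_family!r} "
            "fingerprint family needed for the AD rule")
    fp_block = library_matrix.subset_columns(fp_cols).values

    hits: list[ScreeningHit] = []
    for i, mid in enumerate(library_matrix.row_ids):
        ok, sim, nearest = in_applicability_domain(
            fp_block[i].astype(np.uint8), cluster_model)
        dg = (docking or {}).get(mid)
        if dg is not None and dg >= 0:
            logger.warning("%s: non-negative docking affinity %.2f", mid, dg)
        passed = bool(probs[i] >= config.p_threshold and ok)
        if passed and config.dock_dg_cutoff is not None and dg is not None:
            passed = dg <= config.dock_dg_cutoff
        hits.append(ScreeningHit(
            id=mid, smiles=(smiles or {}).get(mid, ""),
            p_active=float(probs[i]), in_ad=ok, nearest_cluster=nearest,
            max_centroid_similarity=float(sim), dock_dg=dg, passed=passed))
    hits.sort(key=lambda h: (not h.passed, -h.p_active,
                             h.dock_dg if h.dock_dg is not None else 0.0,
                             -h.max_centroid_similarity, h.id))
    return hits


def ingest_docking_scores(tsv_path: str | Path,
                          ) -> tuple[dict[str, float], list[tuple[int, str]]]:
    """Read a TSV of (id, ΔG kcal/mol); keep the most negative duplicate.

    Returns the id → ΔG map and a list of (line number, reason) rejects for
    malformed rows.  A header line naming the columns is permitted.
    """
    path = Path(tsv_path)
    if not path.exists():
        raise ScreeningError(f"no such file: {path}")
    scores: dict[str, float] = {}
    rejects: list[tuple[int, str]] = []
    for line_no, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) < 2:
            rejects.append((line_no, "fewer than two columns"))
            continue
        mid, raw = parts[0].strip(), parts[1].strip()
        try:
            dg = float(raw)
        except ValueError:
            if line_no == 1:
                continue  # header
            rejects.append((line_no, f"non-numeric affinity {raw!r}"))
            continue
        if mid in scores:
            logger.info("duplicate docking id %s: keeping most negative", mid)
            dg = min(dg, scores[mid])
        scores[mid] = dg
    return scores, rejects


def write_report(hits: list[ScreeningHit], out_dir: str | Path) -> dict:
    """Write the full per-molecule CSV plus a JSON/text summary.

    The summary counts molecules passing each criterion and breaks down the
    out-of-AD molecules by their nearest cluster.
    """
    if not hits:
        raise ScreeningError("no hits to report")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    frame = pd.DataFrame([h.__dict__ for h in hits])
    frame.to_csv(out_dir / "screening_hits.csv", index=False)

    outside = [h for h in hits if not h.in_ad]
    by_cluster: dict[str, int] = {}
    for h in outside:
        key = h.nearest_cluster or "-"
        by_cluster[key] = by_cluster.get(key, 0) + 1
    summary = {
        "n_library": len(hits),
        "n_in_ad": int(sum(h.in_ad for h in hits)),
        "n_outside_ad": len(outside),
        "outside_ad_by_nearest_cluster": dict(sorted(by_cluster.items())),
        "n_above_probability": int(sum(h.p_active >= 0.64 for h in hits)),
        "n_passed": int(sum(h.passed for h in hits)),
        "passed_ids": [h.id for h in hits if h.passed],
    }
    (out_dir / "screening_summary.json").write_text(json.dumps(summary, indent=1))
    lines = [f"library molecules      : {summary['n_library']}",
             f"inside AD              : {summary['n_in_ad']}",
             f"outside AD             : {summary['n_outside_ad']}"]
    for cl, cnt in summary["outside_ad_by_nearest_cluster"].items():
        lines.append(f"  nearest cluster {cl}: {cnt}")
    lines.append(f"passing all criteria   : {summary['n_passed']}")
    (out_dir / "screening_summary.txt").write_text("\n".join(lines) + "\n")
    return summary
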