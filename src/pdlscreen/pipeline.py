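"""Pipeline orchestration: configured, seeded, logged end-to-end runs.

A run executes curate → featurize → cluster/AD → train/validate →
(optionally) screen, writing every stage artifact plus a provenance manifest
into the run directory.  One global seed is fanned out deterministically to
each stage (salted by the stage name), so any stage can be re-run in
isolation with the same randomness.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import curation, screening, synthetic
from .clustering import cluster_dataset, murcko_summary, prune_to_x
from .descriptors import (FAMILY_SIZES, FINGERPRINT_FAMILIES, GridSpec,
                          assemble_matrix, embed_conformer)
from .models import ModelConfig, TRAINERS, cross_validate, oob_metrics
from .screening import ScreeningConfig
from .synthetic import SyntheticSpec

logger = logging.getLogger(__name__)

STAGES = ("curate", "featurize", "cluster", "train", "screen")


class ConfigError(ValueError):
    pass


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: global seed XOR CRC32 of the stage name."""
    return (int(global_seed) ^ zlib.crc32(stage.encode())) % (2 ** 31)


@dataclass
class RunConfig:
    """Everything a pipeline run needs, loadable from YAML."""

    out_dir: str = "run"
    seed: int = 0
    log_level: str = "INFO"
    # input: either a curated CSV or a synthetic generation block
    input_csv: str | None = None
    synth: dict | None = None          # SyntheticSpec fields
    # descriptors
    families: tuple[str, ...] = ("morgan",)
    grid_specs: tuple[dict, ...] = ()
    # clustering / AD
    n_clusters: int = 4
    similarity_cutoff: float = 0.25
    ad_threshold: float = 0.195
    # modelling
    model: dict = field(default_factory=dict)   # ModelConfig fields
    # screening
    screening_enabled: bool = False
    library_csv: str | None = None
    synth_library: dict | None = None  # n_total / n_hits / n_unrelated
    p_threshold: float = 0.64
    docking_tsv: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ConfigError("config YAML must be a mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config fields: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.families = tuple(cfg.families)
        cfg.grid_specs = tuple(cfg.grid_specs)
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["families"] = list(self.families)
        data["grid_specs"] = [dict(g) for g in self.grid_specs]
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def validate_config(config: RunConfig) -> list[str]:
    """Static pre-flight checks; an empty list means the config is runnable."""
    issues: list[str] = []
    if config.seed < 0:
        issues.append("seed: must be non-negative")
    if not 0 < config.ad_threshold < 1:
        issues.append("ad_threshold: outside (0,1)")
    if not 0 <= config.p_threshold <= 1:
        issues.append("p_threshold: outside [0,1]")
    if config.input_csv is None and config.synth is None:
        issues.append("input: either input_csv or synth block required")
    if config.input_csv and not Path(config.input_csv).exists():
        issues.append(f"input_csv: no such file {config.input_csv}")
    for fam in config.families:
        if fam not in FAMILY_SIZES:
            issues.append(f"families: unknown family {fam!r}")
    for g in config.grid_specs:
        try:
            GridSpec(**g)
        except Exception as exc:
            issues.append(f"grid_specs: {exc}")
    if config.model:
        try:
            ModelConfig(**config.model)
        except Exception as exc:
            issues.append(f"model: {exc}")
    if config.screening_enabled:
        if config.library_csv is None and config.synth_library is None:
            issues.append("screening: library_csv or synth_library required")
        if config.library_csv and not Path(config.library_csv).exists():
            issues.append(f"library_csv: no such file {config.library_csv}")
    if config.docking_tsv and not Path(config.docking_tsv).exists():
        issues.append(f"docking_tsv: no such file {config.docking_tsv}")
    return issues


def _setup_logging(out_dir: Path, level: str) -> None:
    handler = logging.FileHandler(out_dir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    root = logging.getLogger("pdlscreen")
    root.setLevel(getattr(logging, level.upper(), logging.INFO))
    root.addHandler(handler)


def run_pipeline(config: RunConfig) -> Path:
    """Execute all configured stages; returns the run directory.

    Re-running with an identical config and seed reproduces the forest's OOB
    confusion matrix exactly.  Any stage failure propagates after its
    predecessors' artifacts are on disk.
    """
    issues = validate_config(config)
    if issues:
        raise ConfigError("; ".join(issues))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _setup_logging(out, config.log_level)
    manifest: dict = {"seed": config.seed,
                      "stage_seeds": {s: stage_seed(config.seed, s)
                                      for s in STAGES},
                      "artifacts": {}, "metrics": {}}
    config.to_yaml(out / "config.yaml")
    manifest["config_sha256"] = hashlib.sha256(
        (out / "config.yaml").read_bytes()).hexdigest()

    # --- curate ---------------------------------------------------------
    if config.synth is not None:
        spec = SyntheticSpec(seed=stage_seed(config.seed, "curate"),
                             **config.synth)
        dataset = synthetic.generate(spec)
        records = dataset.records
        dataset.write(out, stem="training")
        manifest["artifacts"]["training"] = "training.csv"
    else:
        parsed, rejects = curation.parse_molecule_table(config.input_csv)
        records = []
        for rec in parsed:
            try:
                records.append(curation.standardize(rec))
            except curation.CurationError as exc:
                rejects.append(curation.Reject(-1, rec.id, str(exc)))
        records, conflicts = curation.deduplicate(records)
        records += curation.resolve_conflicts(conflicts, "drop")
        records = [r for r in records if r.label in ("active", "inactive")]
        curation.write_curated(records, out / "training.csv")
        curation.write_rejects(rejects, out / "rejects.csv")
        manifest["artifacts"]["training"] = "training.csv"
        manifest["artifacts"]["rejects"] = "rejects.csv"
    labels = [r.label for r in records]
    manifest["metrics"]["n_molecules"] = len(records)
    manifest["metrics"]["n_active"] = labels.count("active")
    logger.info("curate: %d molecules (%d active)", len(records),
                labels.count("active"))

    # --- featurize ------------------------------------------------------
    grid_specs = tuple(GridSpec(**g) for g in config.grid_specs)
    conformers = None
    if grid_specs or any(f in ("autocorr3d", "morse", "rdf", "whim")
                         for f in config.families):
        emb_seed = stage_seed(config.seed, "featurize")
        conformers = {r.id: embed_conformer(r, seed=emb_seed) for r in records}
    matrix = assemble_matrix(records, conformers, config.families, grid_specs)
    matrix.to_csv(out / "descriptors.csv")
    manifest["artifacts"]["descriptors"] = "descriptors.csv"
    logger.info("featurize: %d x %d matrix", *matrix.values.shape)

    # --- cluster / AD ---------------------------------------------------
    fp_family = next((f for f in config.families if f in FINGERPRINT_FAMILIES),
                     None)
    if fp_family is None:
        raise ConfigError("AD clustering needs a fingerprint family")
    fp_cols = matrix.family_columns(fp_family)
    fp_block = matrix.subset_columns(fp_cols).values.astype(np.uint8)
    fps = {mid: fp_block[i] for i, mid in enumerate(matrix.row_ids)}
    cmodel = cluster_dataset(fps, n_target_clusters=config.n_clusters,
                             similarity_cutoff=config.similarity_cutoff,
                             fp_family=fp_family,
                             ad_threshold=config.ad_threshold)
    cmodel = prune_to_x(cmodel, fps, threshold=config.ad_threshold,
                        smiles={r.id: r.smiles for r in records})
    cmodel.to_json(out / "clusters.json", smiles={r.id: r.smiles for r in records})
    murcko_summary(records, cmodel).to_csv(out / "scaffolds.csv", index=False)
    manifest["artifacts"]["clusters"] = "clusters.json"
    manifest["artifacts"]["scaffolds"] = "scaffolds.csv"

    # --- train ----------------------------------------------------------
    mconf = ModelConfig(seed=stage_seed(config.seed, "train"),
                        **{k: v for k, v in (config.model or {}).items()
                           if k != "seed"})
    model = TRAINERS[mconf.family](matrix, labels, mconf)
    if mconf.family == "rf":
        metrics = oob_metrics(model)
        manifest["metrics"]["oob"] = metrics.as_dict()
        logger.info("train: OOB MCC %.3f", metrics.mcc)
    else:
        metrics = cross_validate(mconf, matrix, labels, folds=10,
                                 seed=stage_seed(config.seed, "train"))
        manifest["metrics"]["cv10"] = metrics.as_dict()
    (out / "model_metrics.json").write_text(json.dumps(
        {"config": asdict(mconf), "columns": len(model.column_manifest),
         "metrics": metrics.as_dict()}, indent=1))
    manifest["artifacts"]["model_metrics"] = "model_metrics.json"

    # --- screen ---------------------------------------------------------
    if config.screening_enabled:
        if config.synth_library is not None:
            lib_spec = SyntheticSpec(
                n_total=config.synth_library.get("n_total", 200),
                seed=stage_seed(config.seed, "screen"))
            library = synthetic.generate_screen_library(
                lib_spec, config.synth_library.get("n_hits", 2),
                config.synth_library.get("n_unrelated", 30))
            lib_records = library.records
            library.write(out, stem="library")
        else:
            lib_records, _ = curation.parse_molecule_table(
                config.library_csv, source="library")
        lib_matrix = assemble_matrix(lib_records, None, config.families, ())
        docking = None
        if config.docking_tsv:
            docking, dock_rejects = screening.ingest_docking_scores(
                config.docking_tsv)
            if dock_rejects:
                logger.warning("docking table: %d malformed rows", len(dock_rejects))
        hits = screening.screen_library(
            model, lib_matrix, cmodel,
            ScreeningConfig(p_threshold=config.p_threshold,
                            ad_threshold=config.ad_threshold),
            docking=docking,
            smiles={r.id: r.smiles for r in lib_records})
        summary = screening.write_report(hits, out)
        manifest["metrics"]["screening"] = summary
        manifest["artifacts"]["screening"] = "screening_hits.csv"

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out
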