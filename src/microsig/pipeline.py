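"""Pipeline orchestration: YAML config, staged execution, hashed manifest.

The configuration schema is versioned and strict — unknown keys are
errors, not warnings — and every run writes a ``manifest.json`` recording
the package version, config hash, seed and a SHA-256 per output file, so
a rerun with the same config is verifiably bit-identical.
"""
from __future__ import annotations

import hashlib
import logging
from pathlib import Path

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, ValidationError

from . import __version__
from ._rng import substream
from .diffexpr import differential_expression, rank_metric
from .enrichment import enrich_collection
from .io import (
    read_ct_table,
    read_gmt,
    read_matrix,
    read_rank,
    sha256_of,
    write_ct_table,
    write_gmt,
    write_json,
    write_matrix,
    write_newick,
    write_rank,
)
from .qpcr import collapse_replicates, ddct_fold_change
from .signatures import (
    classical_mds,
    correlation_long_format,
    correlation_matrix,
    distance_matrix,
    hierarchical_cluster,
)
from .simulate import (
    DEFAULT_ARRAY_FOLDS,
    QpcrSimConfig,
    SignatureSimConfig,
    StudySimConfig,
    make_gene_sets,
    simulate_expression_study,
    simulate_qpcr_plate,
    simulate_signature_collection,
)
from .io import FLOAT_FORMAT

log = logging.getLogger(__name__)

SCHEMA_VERSION = 1


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


class StageToggles(BaseModel):
    model_config = ConfigDict(extra="forbid")
    simulate: bool = True
    de: bool = True
    enrich: bool = True
    compare: bool = True
    qpcr: bool = True


class StudyStageConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_genes: int = 2000
    n_samples_per_condition: int = 3
    noise_sd_log2: float = 0.25
    baseline_log2_mean: float = 7.0
    baseline_log2_sd: float = 1.5
    n_background_up: int = 150
    n_background_down: int = 40
    background_up_fold_max: float = 8.0
    background_down_fold_min: float = 0.125


class SignatureStageConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_genes: int = 500
    within_block_cosine: float = 0.9
    between_block_cosine: float = 0.2
    noise_sd: float = 0.1


class QpcrStageConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_animals_per_group: int = 6
    n_technical_replicates: int = 3
    ct_noise_sd: float = 0.3


class EnrichStageConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_permutations: int = 199
    weight_exponent: float = 1.0
    n_random_sets: int = 10
    random_set_size: int = 50


class AnalysisConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    schema_version: int = SCHEMA_VERSION
    seed: int = 0
    out_dir: str = "results/run"
    reference_label: str = "WT"
    test_label: str = "KO"
    q_threshold: float = 0.05
    fc_threshold: float = 1.5
    mds_k: int = 2
    reference_gene: str = "Rn18s"
    stages: StageToggles = StageToggles()
    study: StudyStageConfig = StudyStageConfig()
    signatures: SignatureStageConfig = SignatureStageConfig()
    qpcr: QpcrStageConfig = QpcrStageConfig()
    enrichment: EnrichStageConfig = EnrichStageConfig()

    def config_hash(self) -> str:
        payload = self.model_dump_json().encode("utf8")
        return hashlib.sha256(payload).hexdigest()


def load_config(path: str | Path) -> AnalysisConfig:
    """Load a YAML config; unknown keys or a wrong schema version are errors."""
    with open(Path(path)) as fh:
        data = yaml.safe_load(fh) or {}
    try:
        cfg = AnalysisConfig(**data)
    except ValidationError as exc:
        raise ValueError(f"invalid config {path}: {exc}") from exc
    if cfg.schema_version != SCHEMA_VERSION:
        raise ValueError(f"unsupported schema_version {cfg.schema_version} (expected {SCHEMA_VERSION})")
    return cfg


def planted_study_config(cfg: AnalysisConfig) -> StudySimConfig:
    """Expand the stage config into an explicit planted-gene study config.

    The marker genes carry their default planted folds; background
    up/down genes get folds drawn log-uniformly from the configured
    ranges (lower bound 1.5-fold, mirroring the filter scale).
    """
    rng = substream(cfg.seed, "background-folds")
    s = cfg.study
    up = dict(DEFAULT_ARRAY_FOLDS)
    folds_up = np.exp2(
        rng.uniform(np.log2(1.6), np.log2(s.background_up_fold_max), s.n_background_up)
    )
    up.update({f"Up{i:04d}": float(f) for i, f in enumerate(folds_up)})
    folds_down = np.exp2(
        rng.uniform(np.log2(s.background_down_fold_min), np.log2(1 / 1.6), s.n_background_down)
    )
    down = {f"Down{i:04d}": float(f) for i, f in enumerate(folds_down)}
    return StudySimConfig(
        n_genes=s.n_genes,
        n_samples_per_condition=s.n_samples_per_condition,
        planted_up=up,
        planted_down=down,
        baseline_log2_mean=s.baseline_log2_mean,
        baseline_log2_sd=s.baseline_log2_sd,
        noise_sd_log2=s.noise_sd_log2,
        reference_label=cfg.reference_label,
        test_label=cfg.test_label,
        seed=cfg.seed,
    )


def write_fixture_bundle(cfg: AnalysisConfig, out: Path) -> dict[str, Path]:
    """Emit the complete synthetic input bundle into ``out``."""
    out.mkdir(parents=True, exist_ok=True)
    study_cfg = planted_study_config(cfg)
    mat = simulate_expression_study(study_cfg)
    sig = simulate_signature_collection(
        SignatureSimConfig(
            n_genes=cfg.signatures.n_genes,
            within_block_cosine=cfg.signatures.within_block_cosine,
            between_block_cosine=cfg.signatures.between_block_cosine,
            noise_sd=cfg.signatures.noise_sd,
            seed=cfg.seed,
        )
    )
    plate = simulate_qpcr_plate(
        QpcrSimConfig(
            n_animals_per_group=cfg.qpcr.n_animals_per_group,
            n_technical_replicates=cfg.qpcr.n_technical_replicates,
            ct_noise_sd=cfg.qpcr.ct_noise_sd,
            calibrator_group=cfg.reference_label,
            test_group=cfg.test_label,
            seed=cfg.seed,
        )
    )
    planted = list(study_cfg.planted_up)[: cfg.enrichment.random_set_size]
    sets = make_gene_sets(
        planted,
        universe=list(mat.genes),
        n_random_sets=cfg.enrichment.n_random_sets,
        random_set_size=cfg.enrichment.random_set_size,
        seed=cfg.seed,
    )
    paths = {
        "expression": out / "expression.tsv",
        "signatures": out / "signatures.tsv",
        "ct_plate": out / "ct_plate.csv",
        "gene_sets": out / "gene_sets.gmt",
        "config": out / "config.yaml",
    }
    write_matrix(mat, paths["expression"])
    write_matrix(sig, paths["signatures"])
    write_ct_table(plate, paths["ct_plate"])
    write_gmt(sets, paths["gene_sets"])
    paths["config"].write_text(yaml.safe_dump(cfg.model_dump(), sort_keys=True))
    return paths


def run_pipeline(cfg: AnalysisConfig) -> dict:
    """Run the enabled stages and return the output manifest."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    data_dir = out / "data"
    log.info("microsig %s | seed=%d | config=%s", __version__, cfg.seed, cfg.config_hash())
    manifest: dict = {
        "package_version": __version__,
        "schema_version": cfg.schema_version,
        "seed": cfg.seed,
        "config_sha256": cfg.config_hash(),
        "stages": {},
    }

    def record(stage: str, outputs: dict[str, Path]) -> None:
        manifest["stages"][stage] = {
            "outputs": {name: {"path": str(p), "sha256": sha256_of(p)} for name, p in outputs.items()}
        }

    def run_stage(name, fn):
        try:
            fn()
        except Exception as exc:
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc

    if cfg.stages.simulate:
        run_stage("simulate", lambda: record("simulate", write_fixture_bundle(cfg, data_dir)))

    deg = None
    if cfg.stages.de:
        def _de():
            nonlocal deg
            mat = read_matrix(data_dir / "expression.tsv", kind="expression")
            deg_, summary = differential_expression(
                mat,
                reference=cfg.reference_label,
                test=cfg.test_label,
                q_threshold=cfg.q_threshold,
                fc_threshold=cfg.fc_threshold,
            )
            deg = deg_
            deg_path = out / "deg.tsv"
            deg_.to_csv(deg_path, sep="\t", float_format=FLOAT_FORMAT, index_label="gene")
            summary_path = out / "de_summary.json"
            write_json(
                {"n_total": summary.n_total, "n_up": summary.n_up, "n_down": summary.n_down},
                summary_path,
            )
            record("de", {"deg": deg_path, "summary": summary_path})
        run_stage("de", _de)

    if cfg.stages.enrich:
        def _enrich():
            if deg is None:
                raise RuntimeError("enrich stage needs the de stage")
            scores = rank_metric(deg)
            rank_path = out / "rank.tsv"
            write_rank(scores, rank_path)
            sets = read_gmt(data_dir / "gene_sets.gmt")
            res = enrich_collection(
                read_rank(rank_path),
                sets,
                n_permutations=cfg.enrichment.n_permutations,
                seed=cfg.seed,
                weight_exponent=cfg.enrichment.weight_exponent,
            )
            res_path = out / "enrichment.tsv"
            res.to_csv(res_path, sep="\t", float_format=FLOAT_FORMAT, index=False)
            record("enrich", {"rank": rank_path, "results": res_path})
        run_stage("enrich", _enrich)

    if cfg.stages.compare:
        def _compare():
            sig = read_matrix(data_dir / "signatures.tsv", kind="signature")
            dm = distance_matrix(sig)
            cm = correlation_matrix(sig)
            emb = classical_mds(dm, k=cfg.mds_k)
            dend = hierarchical_cluster(dm)
            paths = {
                "distance": out / "distance_matrix.csv",
                "correlation": out / "correlation_matrix.csv",
                "embedding": out / "mds_embedding.tsv",
                "dendrogram": out / "dendrogram.nwk",
                "heatmap_long": out / "correlation_long.csv",
            }
            dm.to_frame().to_csv(paths["distance"], float_format=FLOAT_FORMAT, index_label="population")
            cm.to_frame().to_csv(paths["correlation"], float_format=FLOAT_FORMAT, index_label="population")
            import pandas as pd

            emb_frame = pd.DataFrame(
                emb.coordinates,
                index=emb.labels,
                columns=[f"dim{i + 1}" for i in range(emb.coordinates.shape[1])],
            )
            emb_frame["stress"] = emb.stress
            emb_frame.to_csv(paths["embedding"], sep="\t", float_format=FLOAT_FORMAT, index_label="population")
            write_newick(dend, paths["dendrogram"])
            correlation_long_format(cm).to_csv(paths["heatmap_long"], float_format=FLOAT_FORMAT, index=False)
            record("compare", paths)
        run_stage("compare", _compare)

    if cfg.stages.qpcr:
        def _qpcr():
            plate = read_ct_table(data_dir / "ct_plate.csv")
            res = ddct_fold_change(
                collapse_replicates(plate),
                reference_gene=cfg.reference_gene,
                calibrator_group=cfg.reference_label,
                test_group=cfg.test_label,
            )
            path = out / "qpcr_results.tsv"
            res.per_gene.to_csv(path, sep="\t", float_format=FLOAT_FORMAT)
            record("qpcr", {"results": path})
        run_stage("qpcr", _qpcr)

    manifest_path = out / "manifest.json"
    write_json(manifest, manifest_path)
    return manifest
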