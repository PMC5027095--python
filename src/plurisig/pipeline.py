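"""End-to-end orchestration: simulate/load -> features -> select -> classify
-> evaluate, from a single config, with per-stage seeds and an output
manifest carrying content hashes.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import feature_extraction, peak_io, synthetic_data
from .ensemble_classification import (
    EnsembleResult,
    compare_scopes,
    run_ensemble,
    write_ensemble_outputs,
)
from .evaluation import compare_expression, feature_correlations
from .signature_selection import (
    SCOPES,
    Signature,
    make_resample_plan,
    select_signature,
    write_signature,
    _derive_seed,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Configuration for one pipeline run.

    Exactly one input mode: either ``generator`` (a
    :class:`~plurisig.synthetic_data.GeneratorConfig`) or ``paths`` (a
    mapping with keys ``manifest``, ``annotation``, ``positives`` and
    optionally ``expression``).
    """

    generator: synthetic_data.GeneratorConfig | None = None
    paths: dict[str, str] | None = None
    scopes: tuple[str, ...] = ("combined",)
    n_resamples: int = 100
    n_folds: int = 10
    frequency_threshold: float = 0.5
    prob_threshold: float = 0.5
    call_threshold: float = 0.9
    use_expression: bool = False
    master_seed: int = 0
    out_dir: str = "plurisig_run"

    def __post_init__(self) -> None:
        if (self.generator is None) == (self.paths is None):
            raise ValueError(
                "exactly one of 'generator' and 'paths' must be given"
            )
        for scope in self.scopes:
            if scope not in SCOPES:
                raise ValueError(f"unknown scope {scope!r}")
        for name, v in (("frequency_threshold", self.frequency_threshold),
                        ("prob_threshold", self.prob_threshold),
                        ("call_threshold", self.call_threshold)):
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.paths is not None:
            missing = {"manifest", "annotation", "positives"} - set(self.paths)
            if missing:
                raise ValueError(f"paths missing required keys {sorted(missing)}")


def config_from_yaml(path) -> PipelineConfig:
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    gen = raw.pop("generator", None)
    if gen is not None:
        gen = synthetic_data.GeneratorConfig(**gen)
    scopes = tuple(raw.pop("scopes", ("combined",)))
    return PipelineConfig(generator=gen, scopes=scopes, **raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    files: dict[str, str] = field(default_factory=dict)     # name -> path
    hashes: dict[str, str] = field(default_factory=dict)    # name -> sha256
    metrics: dict[str, float] = field(default_factory=dict)
    timings: dict[str, float] = field(default_factory=dict)

    def record(self, name: str, path: Path) -> None:
        self.files[name] = str(path)
        self.hashes[name] = _sha256(path)

    def write(self, path: Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"files": self.files, "hashes": self.hashes,
                 "metrics": self.metrics, "timings": self.timings},
                fh, indent=2, sort_keys=True,
            )
            fh.write("\n")


def _load_inputs(config: PipelineConfig, out_dir: Path, manifest: RunManifest):
    if config.generator is not None:
        study = synthetic_data.generate_study(config.generator)
        study_dir = out_dir / "study"
        paths = synthetic_data.write_study(study, study_dir)
        for name, p in paths.items():
            manifest.record(f"study:{name}", p)
        return (study.annotation, study.manifest, study.peaks,
                study.expression, study.positives)
    paths = config.paths
    annotation = peak_io.read_gene_annotation(paths["annotation"])
    datasets = peak_io.read_manifest(paths["manifest"])
    base = Path(paths["manifest"]).parent
    peaks = {}
    for d in datasets:
        p = Path(d.path)
        if not p.is_absolute():
            p = base / p
        peaks[d.dataset_id] = peak_io.read_peak_file(p, d.dialect)
    expression = (peak_io.read_expression_table(paths["expression"])
                  if "expression" in paths else [])
    positives = peak_io.read_gene_list(paths["positives"])
    gene_ids = {g.gene_id for g in annotation}
    unknown = positives - gene_ids
    if unknown:
        logger.warning("%d positive genes absent from the annotation; dropped",
                       len(unknown))
        positives = positives & gene_ids
    return annotation, datasets, peaks, expression, positives


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute every stage for each requested scope; returns the manifest."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest()
    t0 = time.perf_counter()

    annotation, datasets, peaks, expression, positives = _load_inputs(
        config, out_dir, manifest
    )
    manifest.timings["inputs"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    per_dataset = {
        d.dataset_id: feature_extraction.extract_dataset_features(
            peaks[d.dataset_id], annotation
        )
        for d in datasets
    }
    needs_expression = config.use_expression or any(
        s == "combined_expression" for s in config.scopes
    )
    raw = feature_extraction.build_feature_matrix(
        per_dataset, datasets, annotation,
        expression=expression if (needs_expression and expression) else None,
    )
    matrix = feature_extraction.zscore_normalize(raw)
    features_path = out_dir / "features.tsv"
    peak_io.write_feature_matrix(raw, features_path)
    manifest.record("features", features_path)
    manifest.timings["features"] = time.perf_counter() - t0

    universe = {g.gene_id for g in annotation}
    plan = make_resample_plan(
        positives, universe, n_resamples=config.n_resamples,
        master_seed=_derive_seed(config.master_seed, "plan"),
    )

    results: dict[str, EnsembleResult] = {}
    for scope in config.scopes:
        t0 = time.perf_counter()
        signature = select_signature(
            matrix, plan, scope=scope,
            frequency_threshold=config.frequency_threshold,
        )
        sig_path = out_dir / f"signature_{scope}.tsv"
        write_signature(signature, sig_path)
        manifest.record(f"signature:{scope}", sig_path)
        manifest.timings[f"select:{scope}"] = time.perf_counter() - t0

        t0 = time.perf_counter()
        scoped = matrix.select_columns(matrix.scope_mask(scope))
        if signature.entries:
            model_matrix = scoped.select_columns(signature.column_mask(scoped))
        else:
            # nothing survives the frequency threshold (e.g. null data):
            # fall back to all scope columns so the ensemble is still assessed
            logger.warning(
                "scope %s: empty signature, running ensemble on all %d "
                "scope columns", scope, scoped.n_columns,
            )
            model_matrix = scoped
        result = run_ensemble(
            model_matrix, plan, scope=scope, n_folds=config.n_folds,
            prob_threshold=config.prob_threshold,
            call_threshold=config.call_threshold,
        )
        results[scope] = result
        for name, p in write_ensemble_outputs(result, out_dir, set(positives)).items():
            manifest.record(f"ensemble:{scope}:{name}", Path(p))
        manifest.metrics[f"mean_auc:{scope}"] = result.mean_auc
        manifest.metrics[f"n_candidates:{scope}"] = len(result.candidates)
        manifest.timings[f"classify:{scope}"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    corr = feature_correlations(raw)
    corr_path = out_dir / "count_breadth_correlation.tsv"
    with open(corr_path, "w") as fh:
        fh.write("dataset_id\tfeature_a\tfeature_b\tspearman_rho\tn\n")
        for p in corr.pairs:
            fh.write(f"{p.dataset_id}\t{p.feature_a}\t{p.feature_b}"
                     f"\t{p.spearman_rho:.6g}\t{p.n}\n")
    manifest.record("correlations", corr_path)
    manifest.metrics["mean_count_breadth_rho"] = corr.mean_rho

    if expression:
        for scope, result in results.items():
            if result.candidates:
                try:
                    cmp = compare_expression(result.candidates, expression)
                except ValueError as exc:
                    logger.warning("scope %s: expression comparison skipped (%s)",
                                   scope, exc)
                    continue
                manifest.metrics[f"expression_p:{scope}"] = cmp.p_value

    if len(results) >= 2:
        ranking = compare_scopes(results)
        rank_path = out_dir / "scope_ranking.tsv"
        ranking.to_csv(rank_path, sep="\t", index=False)
        manifest.record("scope_ranking", rank_path)
    manifest.timings["evaluate"] = time.perf_counter() - t0

    manifest.write(out_dir / "run_manifest.json")
    return manifest
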