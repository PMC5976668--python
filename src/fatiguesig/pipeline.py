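"""End-to-end orchestration: phenotype -> preprocess -> score -> band-select
-> minimal signature -> network sampler, with a reproducible run manifest.

A single global seed is fanned out to per-stage child seeds through a fixed
``numpy.random.SeedSequence`` derivation, so any seeded stage can be re-run
in isolation and reproduce the pipeline's output.  The manifest records
inputs, outputs, the parameter echo, the seed, and content checksums; two
runs with identical config and inputs produce identical checksums.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io
from .errors import ConfigError, StageError
from .fisher import BandFilter, DEFAULT_BAND_FILTER, score_genes, select_band
from .phenotype import labels_from_assessments
from .preprocess import (
    differential_expression,
    log2_transform,
    quantile_normalize,
    remove_batch_effects,
)
from .sampler import SamplerConfig, frequency_report, sample_networks
from .signature import minimal_signature

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "derive_seed"]

_STAGE_NAMES = ("phenotype", "preprocess", "score", "select", "signature", "sampler")


def derive_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage child seed below 2**31."""
    digest = hashlib.sha256(f"{int(global_seed)}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class PipelineConfig:
    """Everything one reproducible run needs."""

    matrix_path: str
    subjects_path: str | None = None  # FACT-F table; classified at run time
    labels_path: str | None = None  # or precomputed labels
    batches_path: str | None = None
    out_dir: str = "fatiguesig_run"
    # preprocessing switches
    apply_log2: bool = False  # input is usually already log2
    apply_quantile: bool = True
    apply_batch_removal: bool = True
    # feature selection
    band: BandFilter = field(default_factory=lambda: DEFAULT_BAND_FILTER)
    band_enabled: bool = True
    top_k_fallback: int = 100  # ranked pool size when the band is disabled
    # classifier
    knn: int = 1
    metric: str = "euclidean"
    zscore: bool = False
    # sampler
    sampler_draws: int = 10_000
    sampler_size_min: int = 2
    sampler_size_max: int = 20
    sampler_retention: float | None = None  # default: signature accuracy - 1/n
    seed: int = 0
    verbosity: int = 1

    def __post_init__(self) -> None:
        if self.subjects_path is None and self.labels_path is None:
            raise ConfigError("one of subjects_path or labels_path is required")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        """Load a flat key-value config file (``section.key`` prefixes allowed)."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        flat = {}
        for key, value in raw.items():
            if isinstance(value, dict):
                for sub, v in value.items():
                    flat[f"{key}.{sub}"] = v
            else:
                flat[key] = value
        kwargs = {}
        band_kwargs = {}
        for key, value in flat.items():
            name = key.split(".")[-1]
            if name in ("fr_min", "fr_max", "fc_bands"):
                band_kwargs[name] = value
            else:
                kwargs[name.replace("-", "_")] = value
        if band_kwargs:
            kwargs["band"] = BandFilter.from_string(
                band_kwargs.get("fr_min", DEFAULT_BAND_FILTER.fr_min),
                band_kwargs.get("fr_max", DEFAULT_BAND_FILTER.fr_max),
                band_kwargs.get("fc_bands", "-0.92:-0.15,0.09:1.13"),
            )
        unknown = set(kwargs) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**kwargs)

    _UNHASHED = ("matrix_path", "subjects_path", "labels_path", "batches_path", "out_dir", "verbosity")

    def config_hash(self) -> str:
        # hash only analysis parameters, so identical analyses of the same
        # inputs reproduce checksums regardless of where files live
        payload = {
            k: (v if not isinstance(v, BandFilter) else [v.fr_min, v.fr_max, list(v.fc_bands)])
            for k, v in self.__dict__.items()
            if k not in self._UNHASHED
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage in flow order and write artifacts plus a manifest.

    Raises :class:`~fatiguesig.errors.StageError` naming the first failing
    stage; in that case a manifest marking the run partial is still written
    when the output directory could be created.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    manifest: dict = {
        "complete": False,
        "seed": int(config.seed),
        "config_hash": chash,
        "stages": [],
        "outputs": {},
        "config": json.loads(json.dumps(config.__dict__, default=str)),
    }

    def finish_stage(stage: str, *artifacts: Path):
        manifest["stages"].append(stage)
        for art in artifacts:
            manifest["outputs"][art.name] = io.sha256_of(art)

    try:
        stage = "phenotype"
        if config.labels_path is not None:
            labels = io.read_labels(config.labels_path)
        else:
            subjects = io.read_subjects(config.subjects_path)
            labels = labels_from_assessments(subjects)
        labels_file = out_dir / "labels.csv"
        io.write_labels(labels, labels_file, seed=config.seed)
        finish_stage(stage, labels_file)

        stage = "preprocess"
        matrix = io.read_expression_matrix(config.matrix_path)
        matrix = matrix[labels.index.tolist()]  # align and validate sample ids
        if config.apply_log2:
            matrix = log2_transform(matrix)
        if config.apply_quantile:
            matrix = quantile_normalize(matrix)
        if config.apply_batch_removal and config.batches_path is not None:
            batches = io.read_csv(config.batches_path).set_index("sample_id")["batch"]
            matrix = remove_batch_effects(matrix, batches)
        de = differential_expression(matrix, labels)
        matrix_file = out_dir / "matrix.preprocessed.tsv"
        de_file = out_dir / "differential_expression.csv"
        io.write_expression_matrix(matrix, matrix_file, seed=config.seed, config_hash=chash)
        io.write_csv(de, de_file, seed=config.seed, config_hash=chash)
        finish_stage(stage, matrix_file, de_file)

        stage = "score"
        scores = score_genes(matrix, labels)
        scores_file = out_dir / "gene_scores.csv"
        io.write_csv(scores, scores_file, seed=config.seed, config_hash=chash)
        finish_stage(stage, scores_file)

        stage = "select"
        if config.band_enabled:
            selected = select_band(scores, config.band)
            if len(selected) == 0:
                raise StageError(stage, "band filter selected no genes; widen the bands or disable band selection")
        else:
            selected = scores.head(config.top_k_fallback)
        selected_file = out_dir / "selected_genes.csv"
        io.write_csv(selected, selected_file, seed=config.seed, config_hash=chash)
        finish_stage(stage, selected_file)

        stage = "signature"
        sig = minimal_signature(
            matrix,
            labels,
            selected.index.tolist(),
            k=config.knn,
            metric=config.metric,
            zscore=config.zscore,
        )
        sig_file = out_dir / "signature.json"
        curve_file = out_dir / "accuracy_curve.csv"
        io.write_signature_json(
            sig,
            sig_file,
            params={"knn": config.knn, "metric": config.metric, "zscore": config.zscore},
            seed=config.seed,
        )
        io.write_csv(
            pd.DataFrame(sig.accuracy_curve, columns=["subset_size", "loocv_accuracy"]),
            curve_file,
            seed=config.seed,
            config_hash=chash,
            index=False,
        )
        finish_stage(stage, sig_file, curve_file)

        stage = "sampler"
        n = len(labels)
        retention = (
            config.sampler_retention
            if config.sampler_retention is not None
            else sig.loocv_accuracy - 1.0 / n
        )
        pool = selected.index.tolist()
        sampler_config = SamplerConfig(
            pool=tuple(pool),
            n_draws=config.sampler_draws,
            size_min=min(config.sampler_size_min, len(pool)),
            size_max=min(config.sampler_size_max, len(pool)),
            retention_accuracy=retention,
            seed=derive_seed(config.seed, "sampler"),
        )
        result = sample_networks(matrix, labels, sampler_config)
        sampler_file = out_dir / "sampler.json"
        freq_file = out_dir / "posterior_frequencies.csv"
        io.write_sampler_json(result, sampler_file, seed=config.seed)
        io.write_csv(frequency_report(result), freq_file, seed=config.seed, config_hash=chash)
        finish_stage(stage, sampler_file, freq_file)

        manifest["complete"] = True
        manifest["signature"] = {
            "genes": list(sig.gene_ids),
            "size": sig.size,
            "loocv_accuracy": sig.loocv_accuracy,
        }
        manifest["sampler"] = {"n_retained": result.n_retained, "retention": retention}
    except StageError:
        _write_manifest(out_dir, manifest)
        raise
    except Exception as exc:  # noqa: BLE001 - annotate with the failing stage
        _write_manifest(out_dir, manifest)
        raise StageError(stage, str(exc)) from exc

    _write_manifest(out_dir, manifest)
    return manifest


def _write_manifest(out_dir: Path, manifest: dict) -> None:
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
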