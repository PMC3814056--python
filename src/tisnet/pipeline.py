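"""End-to-end workflow: evidence -> core sets -> extraction -> analyses.

A single YAML config drives the whole pipeline; every stage writes its
intermediates under the output directory and a manifest records parameters,
seeds and stage tallies, so identical config + seed reproduces identical
outputs byte for byte.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .biomarkers import (
    DEFAULT_CURRENCY,
    biomarker_distributions,
    disorder_union_view,
    predict_biomarkers,
)
from .comparison import deg_perturbation_profile, degree_distribution, enrich, pair_different_genes
from .flux_analysis import single_gene_deletion
from .mba import find_blocked_reactions, mba_extract
from .model_core import read_sbml, write_sbml
from .omics import (
    CoreSets,
    build_core_sets,
    filter_low_expression,
    integrate_evidence,
    protein_active_genes,
)
from .synthetic import PRESETS, generate_dataset

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Raised when a pipeline configuration is invalid."""


@dataclass
class PipelineConfig:
    """Validated configuration for :func:`run_pipeline`.

    Inputs come either from a synthetic preset (``synthetic_preset``) or from
    explicit file paths.  All stochastic stages derive their randomness from
    ``seed``.
    """

    out_dir: str
    seed: int
    synthetic_preset: str | None = None
    model_path: str | None = None
    protein_path: str | None = None
    expression_path: str | None = None
    replicate_groups: dict = field(default_factory=dict)
    validation_path: str | None = None
    validation_groups: dict = field(default_factory=dict)
    disorders_path: str | None = None
    annotation_path: str | None = None
    degs_path: str | None = None
    mba_n_runs: int = 50
    mba_inclusion_threshold: float = 0.5
    mba_eps_w: float = 0.5
    fva_fraction: float = 0.0
    expression_percentile: float = 10.0
    lethal_threshold: float = 1e-3
    reduced_threshold: float = 0.95
    currency: list[str] = field(default_factory=lambda: sorted(DEFAULT_CURRENCY))
    enrichment_alpha: float = 0.01

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        try:
            config = cls(**raw)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc
        config.validate()
        return config

    def validate(self) -> None:
        if self.seed is None:
            raise ConfigError("seed is mandatory")
        if self.synthetic_preset is not None:
            if self.synthetic_preset not in PRESETS:
                raise ConfigError(
                    f"unknown synthetic preset {self.synthetic_preset!r}"
                )
            return
        required = {
            "model_path": self.model_path,
            "protein_path": self.protein_path,
            "expression_path": self.expression_path,
            "validation_path": self.validation_path,
            "disorders_path": self.disorders_path,
            "annotation_path": self.annotation_path,
            "degs_path": self.degs_path,
        }
        missing = [k for k, v in required.items() if v is None]
        if missing:
            raise ConfigError(f"missing input paths: {missing}")
        absent = [k for k, v in required.items() if not Path(v).exists()]
        if absent:
            raise ConfigError(
                f"input files do not exist: {[required[k] for k in absent]}"
            )


class StageFailure(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def _write_tsv(frame: pd.DataFrame, path: Path, **kwargs) -> None:
    frame.to_csv(path, sep="\t", index=kwargs.pop("index", False), **kwargs)


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the full workflow; returns the artifact directory.

    Stages: inputs, evidence, core_sets, extraction, essentiality,
    biomarkers, comparison, deg_profiles.  Any stage failure aborts with the
    stage name; a manifest.json summarises parameters and per-stage tallies.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tisnet_version": __version__,
        "seed": config.seed,
        "parameters": {
            "mba_n_runs": config.mba_n_runs,
            "mba_inclusion_threshold": config.mba_inclusion_threshold,
            "mba_eps_w": config.mba_eps_w,
            "fva_fraction": config.fva_fraction,
            "expression_percentile": config.expression_percentile,
            "lethal_threshold": config.lethal_threshold,
            "reduced_threshold": config.reduced_threshold,
            "enrichment_alpha": config.enrichment_alpha,
            "synthetic_preset": config.synthetic_preset,
        },
        "stages": [],
    }
    timings: dict[str, float] = {}

    def stage(name):
        class _Ctx:
            def __enter__(self):
                logger.info("stage %s: start", name)
                self.t0 = time.perf_counter()
                return self

            def __exit__(self, exc_type, exc, tb):
                timings[name] = round(time.perf_counter() - self.t0, 3)
                if exc is not None:
                    raise StageFailure(name, exc) from exc
                manifest["stages"].append(name)
                logger.info("stage %s: done (%.2fs)", name, timings[name])

        return _Ctx()

    with stage("inputs"):
        if config.synthetic_preset is not None:
            dataset = generate_dataset(config.synthetic_preset, seed=config.seed)
            model = dataset.model
            protein = dataset.omics.protein
            expression = dataset.omics.expression
            replicate_groups = dataset.omics.replicate_groups
            validation = dataset.omics.validation
            validation_groups = dataset.omics.validation_groups
            disorders = dataset.disorders
            annotation = dataset.annotation
            degs = dataset.degs
            inputs_dir = out / "inputs"
            inputs_dir.mkdir(exist_ok=True)
            write_sbml(model, inputs_dir / "generic_model.xml")
            _write_tsv(protein, inputs_dir / "protein_evidence.tsv")
            expression.to_csv(inputs_dir / "expression.tsv", sep="\t")
            validation.to_csv(inputs_dir / "validation.tsv", sep="\t")
            _write_tsv(disorders, inputs_dir / "disorders.tsv")
            _write_tsv(annotation, inputs_dir / "annotation.tsv")
            _write_tsv(degs, inputs_dir / "degs.tsv")
            dataset.truth.save(inputs_dir / "truth.json")
        else:
            model = read_sbml(config.model_path)
            protein = pd.read_csv(config.protein_path, sep="\t")
            expression = pd.read_csv(config.expression_path, sep="\t", index_col=0)
            replicate_groups = config.replicate_groups or None
            validation = pd.read_csv(config.validation_path, sep="\t", index_col=0)
            validation_groups = config.validation_groups or None
            disorders = pd.read_csv(config.disorders_path, sep="\t")
            annotation = pd.read_csv(config.annotation_path, sep="\t")
            degs = pd.read_csv(config.degs_path, sep="\t")
        manifest["model"] = {
            "id": model.id,
            "n_reactions": len(model.reactions),
            "n_metabolites": len(model.metabolites),
            "n_genes": len(model.genes),
        }

    with stage("evidence"):
        protein_genes = protein_active_genes(protein)
        transcript_genes = filter_low_expression(
            expression, config.expression_percentile, replicate_groups
        )
        validated_genes = filter_low_expression(
            validation, config.expression_percentile, validation_groups
        )
        calls = integrate_evidence(protein_genes, transcript_genes, validated_genes)
        calls.to_tsv(out / "activity_calls.tsv")
        manifest["evidence"] = {
            "protein_active": len(protein_genes & set(model.genes)),
            "transcript_active": len(transcript_genes & set(model.genes)),
            "final_active": len(calls.active_genes & set(model.genes)),
        }

    with stage("core_sets"):
        core = build_core_sets(calls, model)
        with open(out / "core_sets.json", "w") as fh:
            json.dump(core.to_json_dict(), fh, indent=1)
            fh.write("\n")
        manifest["core_sets"] = {"CH": len(core.CH), "CM": len(core.CM)}

    with stage("extraction"):
        extraction = mba_extract(
            model,
            core,
            n_runs=config.mba_n_runs,
            inclusion_threshold=config.mba_inclusion_threshold,
            seed=config.seed,
            eps_w=config.mba_eps_w,
        )
        tissue = extraction.final_model
        write_sbml(tissue, out / "tissue_model.xml")
        freq = pd.DataFrame(
            sorted(extraction.inclusion_frequency.items()),
            columns=["reaction", "inclusion_frequency"],
        )
        freq["kept"] = freq["reaction"].isin(set(tissue.reaction_ids))
        _write_tsv(freq, out / "inclusion_frequency.tsv")
        blocked = find_blocked_reactions(tissue)
        if blocked:
            raise RuntimeError(f"extracted model has blocked reactions: {sorted(blocked)}")
        manifest["extraction"] = {
            "n_reactions_kept": len(tissue.reactions),
            "n_reactions_pruned": len(model.reactions) - len(tissue.reactions),
            "n_runs": config.mba_n_runs,
        }

    with stage("essentiality"):
        tables = []
        for method in ("FBA", "MOMA"):
            tables.append(
                single_gene_deletion(
                    tissue,
                    method=method,
                    lethal_threshold=config.lethal_threshold,
                    reduced_threshold=config.reduced_threshold,
                )
            )
        deletions = pd.concat(tables, ignore_index=True)
        _write_tsv(deletions, out / "gene_deletions.tsv")
        manifest["essentiality"] = {
            "n_genes": int(deletions["gene"].nunique()),
            "n_lethal_fba": int(
                ((deletions["method"] == "FBA") & (deletions["verdict"] == "lethal")).sum()
            ),
        }

    with stage("biomarkers"):
        predictions = predict_biomarkers(
            tissue,
            disorders,
            currency_ids=frozenset(config.currency),
            fraction=config.fva_fraction,
        )
        _write_tsv(predictions, out / "biomarkers.tsv")
        _write_tsv(disorder_union_view(predictions), out / "biomarkers_by_disorder.tsv")
        dists = biomarker_distributions(predictions)
        _write_tsv(dists["counts"], out / "biomarker_counts.tsv")
        _write_tsv(dists["patterns"], out / "biomarker_patterns.tsv")
        manifest["biomarkers"] = {
            "n_predictions": int((~predictions["infeasible"]).sum()),
            "n_metabolites": int(
                predictions.loc[~predictions["infeasible"], "metabolite"].nunique()
            ),
        }

    with stage("comparison"):
        generic_only, tissue_only = pair_different_genes(model, tissue)
        with open(out / "pair_different_genes.json", "w") as fh:
            json.dump(
                {"generic_only": sorted(generic_only), "tissue_only": sorted(tissue_only)},
                fh, indent=1,
            )
            fh.write("\n")
        enrichment = enrich(
            set(tissue.genes), annotation, set(model.genes), alpha=config.enrichment_alpha
        )
        _write_tsv(enrichment, out / "enrichment.tsv")
        topology = degree_distribution(tissue)
        with open(out / "degree_distribution.json", "w") as fh:
            json.dump(
                {
                    "histogram": {str(k): v for k, v in topology["histogram"].items()},
                    "slope": None if pd.isna(topology["slope"]) else topology["slope"],
                },
                fh, indent=1,
            )
            fh.write("\n")
        manifest["comparison"] = {
            "pdg_generic_only": len(generic_only),
            "pdg_tissue_only": len(tissue_only),
            "n_enriched_terms": int(enrichment["enriched"].sum()),
        }

    with stage("deg_profiles"):
        deg_result = deg_perturbation_profile(tissue, degs, fraction=config.fva_fraction)
        _write_tsv(deg_result["summary"], out / "deg_profiles.tsv")
        with open(out / "deg_unmapped.json", "w") as fh:
            json.dump(deg_result["unmapped"], fh)
            fh.write("\n")
        manifest["deg_profiles"] = {
            "n_mapped": len(deg_result["profiles"]),
            "n_unmapped": len(deg_result["unmapped"]),
        }

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    logger.info("pipeline complete: %s (timings: %s)", out, timings)
    return out
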