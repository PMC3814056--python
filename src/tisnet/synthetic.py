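"""Synthetic benchmark data with planted ground truth.

Generates flux-consistent toy "generic" networks that contain a planted
tissue subnetwork (core pathways from a substrate exchange to a biomass
reaction) plus decoy pathways that can be pruned without blocking the core,
together with matching omics evidence tables, annotation tables, disorder
maps and DEG tables.  Every artifact is reproducible bit-for-bit from
(parameters, seed), and every planted property (flux consistency, biomarker
directions, enrichment) is verified with the package's own oracles at
generation time.

Decoy pathways branch off core intermediates and drain to their own
exchanges, so removing them can never starve the core of mass balance —
the extraction target provably exists.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .biomarkers import DISORDER_COLUMNS, exchange_interval_shifts, is_currency
from .flux_analysis import fba
from .mba import find_blocked_reactions
from .model_core import (
    DEFAULT_BOUND,
    GprRule,
    Metabolite,
    MetabolicModel,
    ModelError,
    Reaction,
)


def _rng(seed: int, stream: str) -> np.random.Generator:
    """Named substream of the master seed (independent, reproducible)."""
    tag = int.from_bytes(stream.encode()[:4].ljust(4, b"\0"), "little")
    return np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), tag]))


@dataclass
class SyntheticTruth:
    """Ground truth planted into a generated dataset."""

    planted_reactions: set[str] = field(default_factory=set)
    planted_genes: set[str] = field(default_factory=set)
    decoy_genes: set[str] = field(default_factory=set)
    all_genes: set[str] = field(default_factory=set)
    planted_biomarkers: list[dict] = field(default_factory=list)
    planted_enriched_term: str | None = None
    noise_rates: dict = field(default_factory=dict)
    seed: int = 0

    def to_json_dict(self) -> dict:
        data = asdict(self)
        for key in ("planted_reactions", "planted_genes", "decoy_genes", "all_genes"):
            data[key] = sorted(data[key])
        return data

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json_dict(), fh, indent=1, sort_keys=True)
            fh.write("\n")


# ---------------------------------------------------------------------------
# Network generation
# ---------------------------------------------------------------------------


def generate_network(
    n_core_paths: int = 3,
    n_decoy_paths: int = 2,
    genes_per_reaction: tuple[int, int] = (1, 2),
    chain_length: tuple[int, int] = (2, 4),
    seed: int = 0,
) -> tuple[MetabolicModel, SyntheticTruth]:
    """Generate a generic model with a planted tissue subnetwork.

    Core paths run from the substrate exchange ``EX_S`` through linear chains
    to a biomass precursor consumed by the objective reaction; decoy paths
    branch off core metabolites and drain through their own exchanges.
    Internal reactions carry AND/OR GPRs over fresh genes drawn uniformly
    from ``genes_per_reaction``.  Both the generic and the planted models
    are verified flux-consistent and biomass-feasible before returning.
    """
    if n_core_paths < 1 or n_decoy_paths < 0:
        raise ValueError("need n_core_paths >= 1 and n_decoy_paths >= 0")
    lo, hi = genes_per_reaction
    if lo < 1 or hi < lo:
        raise ValueError("genes_per_reaction must be a (min, max) range with min >= 1")
    rng = _rng(seed, "net")

    metabolites = [Metabolite("S"), Metabolite("bm")]
    reactions = [Reaction("EX_S", {"S": -1.0}, -10.0, DEFAULT_BOUND)]
    gene_counter = 0
    core_genes: set[str] = set()
    decoy_genes: set[str] = set()

    def fresh_gpr(pool: set[str]) -> GprRule:
        nonlocal gene_counter
        k = int(rng.integers(lo, hi + 1))
        genes = []
        for _ in range(k):
            gene_counter += 1
            genes.append(f"g{gene_counter:04d}")
        pool.update(genes)
        if k == 1:
            return GprRule(genes[0])
        joiner = " and " if rng.random() < 0.5 else " or "
        return GprRule(joiner.join(genes))

    core_intermediates = ["S"]
    core_rxn_ids = ["EX_S"]
    for p in range(1, n_core_paths + 1):
        length = int(rng.integers(chain_length[0], chain_length[1] + 1))
        prev = "S"
        for step in range(1, length + 1):
            product = "bm" if step == length else f"c{p}_{step}"
            if product != "bm":
                metabolites.append(Metabolite(product))
                core_intermediates.append(product)
            rid = f"CORE{p}_{step}"
            reactions.append(
                Reaction(rid, {prev: -1.0, product: 1.0}, 0.0, DEFAULT_BOUND,
                         fresh_gpr(core_genes), subsystem="core")
            )
            core_rxn_ids.append(rid)
            prev = product
    reactions.append(Reaction("BIOMASS", {"bm": -1.0}, 0.0, DEFAULT_BOUND))
    core_rxn_ids.append("BIOMASS")

    for q in range(1, n_decoy_paths + 1):
        source = core_intermediates[int(rng.integers(len(core_intermediates)))]
        length = int(rng.integers(1, 4))
        prev = source
        for step in range(1, length + 1):
            product = f"d{q}_{step}"
            metabolites.append(Metabolite(product))
            reactions.append(
                Reaction(f"DECOY{q}_{step}", {prev: -1.0, product: 1.0}, 0.0,
                         DEFAULT_BOUND, fresh_gpr(decoy_genes), subsystem="decoy")
            )
            prev = product
        reactions.append(Reaction(f"EX_d{q}", {prev: -1.0}, 0.0, DEFAULT_BOUND))

    model = MetabolicModel(metabolites, reactions, "BIOMASS", id=f"synthetic_{seed}")
    model.validate()

    planted = model.restrict(core_rxn_ids, model_id="planted")
    for candidate, label in ((model, "generic"), (planted, "planted")):
        sol = fba(candidate)
        if not sol.ok or sol.objective_value <= 0:
            raise ModelError(f"generated {label} model cannot produce biomass")
        blocked = find_blocked_reactions(candidate)
        if blocked:
            raise ModelError(f"generated {label} model has blocked reactions: {sorted(blocked)}")

    truth = SyntheticTruth(
        planted_reactions=set(core_rxn_ids),
        planted_genes=core_genes,
        decoy_genes=decoy_genes,
        all_genes=set(model.genes),
        seed=int(seed),
    )
    return model, truth


# ---------------------------------------------------------------------------
# Omics evidence
# ---------------------------------------------------------------------------


@dataclass
class OmicsTables:
    """Synthetic evidence bundle: protein calls plus two expression datasets."""

    protein: pd.DataFrame
    expression: pd.DataFrame
    replicate_groups: dict
    validation: pd.DataFrame
    validation_groups: dict


def generate_omics(
    truth: SyntheticTruth,
    false_negative_rate: float = 0.0,
    false_positive_rate: float = 0.0,
    seed: int = 0,
) -> OmicsTables:
    """Evidence tables whose activity calls mark the planted genes.

    Protein evidence covers planted genes (positive IHC) minus a
    false-negative fraction that is demoted to transcript-only evidence;
    decoy genes appear only as negative rows unless promoted by the
    false-positive rate.  Both expression datasets report planted genes at
    high signal over a low-signal background of filler genes (decoy genes
    are not probed), so at zero noise the evidence pipeline recovers exactly
    the planted genes.
    """
    for rate in (false_negative_rate, false_positive_rate):
        if not 0.0 <= rate < 1.0:
            raise ValueError("noise rates must be in [0, 1)")
    planted = sorted(truth.planted_genes)
    decoys = sorted(truth.decoy_genes)
    rng_p = _rng(seed, "prot")
    rng_e = _rng(seed, "expr")
    rng_v = _rng(seed, "vali")

    demoted = {g for g in planted if rng_p.random() < false_negative_rate}
    promoted = {g for g in decoys if rng_p.random() < false_positive_rate}

    rows = []
    for gene in planted + decoys:
        protein_positive = (gene in planted and gene not in demoted) or gene in promoted
        for cell_type in ("glomeruli", "tubules"):
            if protein_positive:
                ihc = str(rng_p.choice(["weak", "moderate", "strong"]))
                summary = str(rng_p.choice(["low", "medium", "high"]))
            else:
                ihc, summary = "negative", "none"
            rows.append((gene, cell_type, ihc, summary))
    protein = pd.DataFrame(rows, columns=["gene", "cell_type", "ihc", "summary"])

    def expression_matrix(rng, columns, bg_prefix):
        n_bg = max(3 * len(truth.all_genes), 20)
        genes = planted + [f"{bg_prefix}{i:05d}" for i in range(n_bg)]
        means = np.concatenate(
            [rng.uniform(200.0, 1000.0, len(planted)), rng.uniform(1.0, 10.0, n_bg)]
        )
        data = {
            col: np.round(means * rng.uniform(0.95, 1.05, len(genes)), 3)
            for col in columns
        }
        return pd.DataFrame(data, index=pd.Index(genes, name="gene"))

    # The two datasets emulate different array platforms: each has its own
    # low-signal background probe set, so a background gene detected in one
    # is never confirmed by the other.
    expression = expression_matrix(rng_e, ["kidney_rep1", "kidney_rep2"], "bg")
    validation = expression_matrix(rng_v, ["validation_rep1", "validation_rep2"], "vbg")

    truth.noise_rates = {
        "false_negative_rate": false_negative_rate,
        "false_positive_rate": false_positive_rate,
    }
    return OmicsTables(
        protein=protein,
        expression=expression,
        replicate_groups={"kidney": ["kidney_rep1", "kidney_rep2"]},
        validation=validation,
        validation_groups={"validation": ["validation_rep1", "validation_rep2"]},
    )


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------


def generate_annotation(
    model: MetabolicModel,
    truth: SyntheticTruth,
    n_terms: int = 8,
    seed: int = 0,
) -> pd.DataFrame:
    """Random gene-term annotations plus one term planted on the core genes.

    The planted term covers 90% of the planted genes and almost nothing
    else, so enrichment of the planted gene set flags it.
    """
    genes = sorted(model.genes)
    if not genes:
        raise ModelError("model has no genes to annotate")
    if n_terms < 1:
        raise ValueError("n_terms must be >= 1")
    rng = _rng(seed, "anno")
    terms = [f"T{i:03d}" for i in range(1, n_terms + 1)]
    rows = []
    for gene in genes:
        for term in rng.choice(terms, size=min(2, n_terms), replace=False):
            rows.append((gene, str(term), f"process {term}"))

    planted = sorted(truth.planted_genes)
    n_cover = max(1, math.ceil(0.9 * len(planted)))
    covered = [planted[i] for i in rng.choice(len(planted), size=n_cover, replace=False)]
    for gene in covered:
        rows.append((gene, "T_planted", "planted process"))
    truth.planted_enriched_term = "T_planted"

    frame = pd.DataFrame(rows, columns=["gene", "term", "term_name"])
    return (
        frame.drop_duplicates(subset=["gene", "term"])
        .sort_values(["gene", "term"], kind="stable")
        .reset_index(drop=True)
    )


# ---------------------------------------------------------------------------
# Disorders with analytically known biomarkers
# ---------------------------------------------------------------------------


def generate_disorders(
    model: MetabolicModel,
    truth: SyntheticTruth,
    n_disorders: int = 2,
    seed: int = 0,
    currency_ids=frozenset(),
) -> pd.DataFrame:
    """Disorder-gene map for genes with verified exchange-interval shifts.

    Candidate genes are screened with the FVA interval-shift oracle at
    generation time; only genes whose knockout shifts at least one
    non-currency exchange interval are eligible, and the shifted metabolites
    with their directions are recorded in ``truth.planted_biomarkers``.
    """
    if n_disorders < 1:
        raise ValueError("n_disorders must be >= 1")
    rng = _rng(seed, "diso")
    eligible: list[tuple[str, list[tuple[str, str]]]] = []
    for gene in sorted(model.genes):
        shifts = exchange_interval_shifts(model, {gene})
        if shifts is None:
            continue
        markers = [
            (s.metabolite, s.direction)
            for s in shifts.itertuples(index=False)
            if s.direction != "unchanged" and not is_currency(s.metabolite, currency_ids)
        ]
        if markers:
            eligible.append((gene, markers))
    if n_disorders > len(eligible):
        raise ValueError(
            f"requested {n_disorders} disorders but only {len(eligible)} genes "
            "shift an exchange interval"
        )
    chosen = sorted(rng.choice(len(eligible), size=n_disorders, replace=False))
    rows = []
    truth.planted_biomarkers = []
    for i, idx in enumerate(chosen, start=1):
        gene, markers = eligible[idx]
        disorder_id = f"DIS{i:03d}"
        rows.append((disorder_id, f"synthetic disorder {i}", gene))
        for metabolite, direction in markers:
            truth.planted_biomarkers.append(
                {"disorder_id": disorder_id, "gene": gene,
                 "metabolite": metabolite, "direction": direction}
            )
    return pd.DataFrame(rows, columns=DISORDER_COLUMNS)


# ---------------------------------------------------------------------------
# DEG tables
# ---------------------------------------------------------------------------


def generate_degs(
    model: MetabolicModel,
    n_degs: int = 4,
    seed: int = 0,
    n_unmapped: int = 1,
) -> pd.DataFrame:
    """DEG table: model genes with fold changes beyond 1.5, plus a few
    unmapped gene ids (as real DEG lists contain genes outside the model)."""
    genes = sorted(model.genes)
    if n_degs > len(genes):
        raise ValueError("n_degs exceeds the number of model genes")
    rng = _rng(seed, "degs")
    chosen = [genes[i] for i in sorted(rng.choice(len(genes), size=n_degs, replace=False))]
    chosen += [f"offmodel{i}" for i in range(1, n_unmapped + 1)]
    rows = []
    for gene in chosen:
        sign = -1.0 if rng.random() < 0.5 else 1.0
        fc_g = sign * float(np.round(rng.uniform(1.6, 9.5), 3))
        fc_t = sign * float(np.round(rng.uniform(1.6, 9.5), 3))
        rows.append((gene, fc_g, fc_t))
    return pd.DataFrame(rows, columns=["gene", "fc_glomeruli", "fc_tubuli"])


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

PRESETS = {
    "small": dict(n_core_paths=3, n_decoy_paths=2, genes_per_reaction=(1, 2),
                  chain_length=(2, 3), n_terms=6, n_disorders=2, n_degs=3),
    "medium": dict(n_core_paths=12, n_decoy_paths=5, genes_per_reaction=(1, 2),
                   chain_length=(3, 4), n_terms=12, n_disorders=4, n_degs=6),
}


@dataclass
class SyntheticDataset:
    model: MetabolicModel
    truth: SyntheticTruth
    omics: OmicsTables
    annotation: pd.DataFrame
    disorders: pd.DataFrame
    degs: pd.DataFrame


def generate_dataset(
    preset: str = "small",
    seed: int = 0,
    false_negative_rate: float = 0.0,
    false_positive_rate: float = 0.0,
) -> SyntheticDataset:
    """Generate a full benchmark dataset from a named preset."""
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
    params = PRESETS[preset]
    model, truth = generate_network(
        n_core_paths=params["n_core_paths"],
        n_decoy_paths=params["n_decoy_paths"],
        genes_per_reaction=params["genes_per_reaction"],
        chain_length=params["chain_length"],
        seed=seed,
    )
    omics = generate_omics(
        truth, false_negative_rate=false_negative_rate,
        false_positive_rate=false_positive_rate, seed=seed,
    )
    annotation = generate_annotation(model, truth, n_terms=params["n_terms"], seed=seed)
    disorders = generate_disorders(model, truth, n_disorders=params["n_disorders"], seed=seed)
    degs = generate_degs(model, n_degs=params["n_degs"], seed=seed)
    return SyntheticDataset(model, truth, omics, annotation, disorders, degs)
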