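"""Omics evidence integration: per-gene activity calls and core reaction sets.

The evidence hierarchy mirrors a proteome-first tissue workflow:

1. Protein evidence (immunohistochemistry per cell type plus an evidence
   summary score) is the primary signal — a positive IHC stain (weak,
   moderate or strong) or any non-"none" summary score marks the gene active.
2. Transcript evidence (microarray signal intensities, replicates averaged)
   supplies genes the proteome missed; genes below the 10th percentile of
   averaged signal are filtered out.
3. Transcript-only genes must be confirmed in an independent validation
   expression dataset, otherwise they are discarded.

The resulting activity calls drive two core reaction sets for tissue-model
extraction: CH (high confidence — GPR satisfiable with protein-supported
genes only, plus the biomass objective) and CM (moderate — satisfiable with
all finally-active genes but not in CH).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model_core import MetabolicModel

logger = logging.getLogger(__name__)

IHC_CATEGORIES = ("negative", "weak", "moderate", "strong")
POSITIVE_IHC = ("weak", "moderate", "strong")
SUMMARY_CATEGORIES = ("none", "low", "medium", "high")
POSITIVE_SUMMARY = ("low", "medium", "high")

PROTEIN_COLUMNS = ["gene", "cell_type", "ihc", "summary"]


def call_protein_active(ihc: str, summary: str) -> bool:
    """Protein-level activity call for one (gene, cell type) observation.

    Active iff the IHC signal is positive (weak/moderate/strong) or the
    evidence summary score is low/medium/high.
    """
    if ihc not in IHC_CATEGORIES:
        raise ValueError(f"unknown IHC category {ihc!r}; expected one of {IHC_CATEGORIES}")
    if summary not in SUMMARY_CATEGORIES:
        raise ValueError(
            f"unknown summary category {summary!r}; expected one of {SUMMARY_CATEGORIES}"
        )
    return ihc in POSITIVE_IHC or summary in POSITIVE_SUMMARY


def protein_active_genes(table: pd.DataFrame) -> set[str]:
    """Genes protein-active in ANY cell type (cell types are pooled)."""
    missing = set(PROTEIN_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"protein evidence table missing columns: {sorted(missing)}")
    dup = table.duplicated(subset=["gene", "cell_type"])
    if dup.any():
        raise ValueError("duplicate (gene, cell_type) rows in protein evidence table")
    active = set()
    for row in table.itertuples(index=False):
        if call_protein_active(row.ihc, row.summary):
            active.add(row.gene)
    return active


def average_replicates(matrix: pd.DataFrame, replicate_groups=None) -> pd.DataFrame:
    """Average sample columns within each replicate group.

    ``replicate_groups`` maps a group name to its sample columns; ungrouped
    columns pass through as their own group.  Without a map, all columns form
    one group.
    """
    if matrix.isna().any().any():
        raise ValueError("expression matrix contains missing values")
    if matrix.shape[1] < 1:
        raise ValueError("expression matrix has no samples")
    if replicate_groups is None:
        replicate_groups = {"all": list(matrix.columns)}
    out = {}
    grouped = set()
    for group, cols in replicate_groups.items():
        missing = set(cols) - set(matrix.columns)
        if missing:
            raise ValueError(f"replicate group {group!r} references unknown samples {sorted(missing)}")
        out[group] = matrix[list(cols)].mean(axis=1)
        grouped.update(cols)
    for col in matrix.columns:
        if col not in grouped:
            out[col] = matrix[col]
    return pd.DataFrame(out, index=matrix.index)


def filter_low_expression(
    matrix: pd.DataFrame, percentile: float = 10.0, replicate_groups=None
) -> set[str]:
    """Transcript-active genes after the low-expression percentile filter.

    Replicates are averaged per group first; the threshold is the given
    empirical percentile (linear interpolation) of all averaged values; a
    gene is active if any averaged value reaches the threshold (boundary
    values are kept).
    """
    if not 0.0 <= percentile < 100.0:
        raise ValueError("percentile must be in [0, 100)")
    if matrix.empty:
        raise ValueError("expression matrix is empty")
    averaged = average_replicates(matrix, replicate_groups)
    threshold = float(np.percentile(averaged.to_numpy().ravel(), percentile))
    active = averaged.ge(threshold).any(axis=1)
    return set(averaged.index[active])


@dataclass
class ActivityCalls:
    """Per-gene evidence verdicts; ``frame`` has one row per gene with
    protein_active / transcript_active / validated / final_status columns."""

    frame: pd.DataFrame

    @property
    def active_genes(self) -> set[str]:
        return set(self.frame.index[self.frame["final_status"] == "active"])

    @property
    def protein_supported(self) -> set[str]:
        return set(self.frame.index[self.frame["protein_active"]])

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index_label="gene")


def integrate_evidence(protein, transcript, validation) -> ActivityCalls:
    """Combine the three evidence channels into final activity calls.

    Each argument is a set of gene ids (or a gene -> bool map); genes missing
    from a channel count as false.  A gene is active if protein-supported, or
    transcript-supported and confirmed in the validation dataset; otherwise
    it is discarded.
    """

    def as_set(x):
        if isinstance(x, dict):
            return {g for g, v in x.items() if v}
        return set(x)

    protein, transcript, validation = map(as_set, (protein, transcript, validation))
    universe = sorted(protein | transcript | validation)
    rows = []
    for gene in universe:
        p, t, v = gene in protein, gene in transcript, gene in validation
        status = "active" if (p or (t and v)) else "discarded"
        rows.append((gene, p, t, v, status))
    frame = pd.DataFrame(
        rows, columns=["gene", "protein_active", "transcript_active", "validated", "final_status"]
    ).set_index("gene")
    return ActivityCalls(frame)


# ---------------------------------------------------------------------------
# Core sets
# ---------------------------------------------------------------------------


@dataclass
class CoreSets:
    """High-confidence (CH) and moderate (CM) core reaction sets for
    tissue-model extraction.  CH must be retained; CM should be."""

    CH: set[str] = field(default_factory=set)
    CM: set[str] = field(default_factory=set)

    def validate(self, model: MetabolicModel) -> None:
        if self.CH & self.CM:
            raise ValueError("CH and CM overlap")
        rxns = set(model.reaction_ids)
        if not self.CH <= rxns or not self.CM <= rxns:
            raise ValueError("core sets reference reactions outside the model")
        if model.objective_reaction_id not in self.CH:
            raise ValueError("objective reaction must be in CH")

    def to_json_dict(self) -> dict:
        return {"CH": sorted(self.CH), "CM": sorted(self.CM)}

    @classmethod
    def from_json_dict(cls, data: dict) -> "CoreSets":
        return cls(CH=set(data["CH"]), CM=set(data["CM"]))


def build_core_sets(calls: ActivityCalls, model: MetabolicModel) -> CoreSets:
    """Derive CH/CM from activity calls by GPR evaluation.

    CH: reactions whose GPR is satisfied using protein-supported genes only,
    plus the objective.  CM: remaining reactions satisfied with all active
    genes.  Empty-GPR reactions (except the objective) join neither set and
    are free to prune.
    """
    model_genes = set(model.genes)
    protein = calls.protein_supported & model_genes
    active = calls.active_genes & model_genes
    outside = (calls.protein_supported | calls.active_genes) - model_genes
    if outside:
        logger.info("%d evidence genes not in the model (ignored)", len(outside))

    CH, CM = set(), set()
    for rxn in model.reactions:
        if rxn.gpr.is_empty:
            continue
        rule_genes = rxn.gpr.genes
        if rxn.gpr.evaluate(rule_genes - protein):
            CH.add(rxn.id)
        elif rxn.gpr.evaluate(rule_genes - active):
            CM.add(rxn.id)
    CH.add(model.objective_reaction_id)
    CM.discard(model.objective_reaction_id)
    core = CoreSets(CH=CH, CM=CM)
    core.validate(model)
    return core
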