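"""Model comparison, degree statistics, enrichment, DEG profiling, targets.

Tools for contrasting two tissue models (pair-different genes, PDG),
characterising a model's gene-reaction bipartite topology, testing a gene
set for annotation-term enrichment (hypergeometric upper tail with
Benjamini-Hochberg correction), profiling differentially expressed genes by
knockout FVA, and ranking genes whose knockouts alter fluxes like a
reference gene's (drug-target search).
"""

from __future__ import annotations

import logging

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .flux_analysis import FvaResult, InfeasibleProblemError, fva, flux_span_ratio
from .model_core import MetabolicModel, apply_knockout

logger = logging.getLogger(__name__)

ANNOTATION_COLUMNS = ["gene", "term", "term_name"]
DEG_COLUMNS = ["gene", "fc_glomeruli", "fc_tubuli"]


# ---------------------------------------------------------------------------
# Model comparison and topology
# ---------------------------------------------------------------------------


def pair_different_genes(model_a: MetabolicModel, model_b: MetabolicModel):
    """Genes present in exactly one of two models: ``(a_only, b_only)``."""
    genes_a, genes_b = set(model_a.genes), set(model_b.genes)
    return genes_a - genes_b, genes_b - genes_a


def gene_reaction_graph(model: MetabolicModel) -> nx.Graph:
    """Bipartite gene-reaction graph: an edge when the gene appears in the
    reaction's GPR."""
    graph = nx.Graph()
    for gene in sorted(model.genes):
        graph.add_node(gene, bipartite="gene")
    for rxn in model.reactions:
        if rxn.gpr.is_empty:
            continue
        graph.add_node(rxn.id, bipartite="reaction")
        for gene in sorted(rxn.gpr.genes):
            graph.add_edge(gene, rxn.id)
    return graph


def degree_distribution(model: MetabolicModel) -> dict:
    """Per-gene degrees, degree histogram, and log-log OLS slope.

    The slope is fit by least squares on ``log(count)`` vs ``log(degree)``
    over degrees with nonzero count — the usual quick check that a network's
    degree distribution is power-law-like (slope ≈ -gamma).  With fewer than
    two distinct degrees the slope is undefined (NaN).
    """
    graph = gene_reaction_graph(model)
    degrees = {
        g: graph.degree(g) if g in graph else 0 for g in sorted(model.genes)
    }
    histogram: dict[int, int] = {}
    for d in degrees.values():
        if d > 0:
            histogram[d] = histogram.get(d, 0) + 1
    slope = degree_histogram_slope(histogram)
    return {"degrees": degrees, "histogram": dict(sorted(histogram.items())), "slope": slope}


def degree_histogram_slope(histogram: dict[int, int]) -> float:
    """OLS slope of log(count) vs log(degree) for a degree histogram."""
    pts = [(d, c) for d, c in histogram.items() if d > 0 and c > 0]
    if len(pts) < 2:
        return float("nan")
    x = np.log([d for d, _ in pts])
    y = np.log([c for _, c in pts])
    slope, _ = np.polyfit(x, y, 1)
    return float(slope)


# ---------------------------------------------------------------------------
# Enrichment
# ---------------------------------------------------------------------------


def hypergeometric_tail(N: int, K: int, n: int, k: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    if not 0 <= K <= N or not 0 <= n <= N:
        raise ValueError("require 0 <= K, n <= N")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (step-up, monotone)."""
    pvalues = np.asarray(pvalues, dtype=float)
    if pvalues.size == 0:
        return pvalues
    return multipletests(pvalues, method="fdr_bh")[1]


def enrich(
    query,
    annotation: pd.DataFrame,
    universe,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Hypergeometric term enrichment of a gene set with BH correction.

    For each term with at least one annotated gene in the universe:
    ``k`` = annotated query genes, ``K`` = annotated universe genes,
    ``n`` = query size, ``N`` = universe size; p is the upper-tail
    hypergeometric probability and q its BH adjustment across all tested
    terms.  A term is enriched iff ``q < alpha``.
    """
    missing = set(ANNOTATION_COLUMNS) - set(annotation.columns)
    if missing:
        raise ValueError(f"annotation table missing columns: {sorted(missing)}")
    universe = set(universe)
    if not universe:
        raise ValueError("empty gene universe")
    query = set(query)
    if not query <= universe:
        raise ValueError("query genes must be a subset of the universe")

    ann = annotation[annotation["gene"].isin(universe)]
    if ann.duplicated(subset=["gene", "term"]).any():
        ann = ann.drop_duplicates(subset=["gene", "term"])
    N, n = len(universe), len(query)
    rows = []
    for term, sub in ann.groupby("term", sort=True):
        genes = set(sub["gene"])
        K = len(genes)
        k = len(genes & query)
        p = hypergeometric_tail(N, K, n, k)
        rows.append((term, sub["term_name"].iloc[0], k, K, n, N, p))
    frame = pd.DataFrame(rows, columns=["term", "term_name", "k", "K", "n", "N", "p"])
    frame["q"] = bh_adjust(frame["p"].to_numpy())
    frame["enriched"] = frame["q"] < alpha
    return frame.sort_values(["p", "term"], kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# DEG knockout profiling
# ---------------------------------------------------------------------------


def deg_perturbation_profile(
    model: MetabolicModel,
    degs: pd.DataFrame,
    fraction: float = 0.0,
    wt_fva: FvaResult | None = None,
) -> dict:
    """Knockout FVA profiles for differentially expressed genes.

    Every DEG present in the model is knocked out (up- and down-regulated
    alike) and its per-reaction span-ratio profile computed against the
    wild-type FVA; class counts tally type I (r > 2), type II (0 < r < 0.5)
    and type III (span drops to zero) reactions.  Returns ``profiles``
    (gene -> span-ratio DataFrame), ``summary`` (one row per mapped gene)
    and ``unmapped`` (genes absent from the model).
    """
    missing = set(DEG_COLUMNS) - set(degs.columns)
    if missing:
        raise ValueError(f"DEG table missing columns: {sorted(missing)}")
    if (degs[["fc_glomeruli", "fc_tubuli"]] == 0).any().any():
        raise ValueError("fold changes must be non-zero")
    model_genes = set(model.genes)
    if wt_fva is None:
        wt_fva = fva(model, fraction=fraction)

    profiles: dict[str, pd.DataFrame] = {}
    summary_rows = []
    unmapped = []
    for rec in degs.itertuples(index=False):
        if rec.gene not in model_genes:
            unmapped.append(rec.gene)
            continue
        ko = apply_knockout(model, {rec.gene})
        try:
            ko_fva = fva(ko, fraction=fraction)
        except InfeasibleProblemError:
            logger.warning("knockout of DEG %r is infeasible; skipped", rec.gene)
            unmapped.append(rec.gene)
            continue
        profile = flux_span_ratio(wt_fva, ko_fva)
        profiles[rec.gene] = profile
        cls = profile["alteration_class"]
        summary_rows.append(
            (
                rec.gene,
                rec.fc_glomeruli,
                rec.fc_tubuli,
                "up" if rec.fc_glomeruli > 0 else "down",
                int((cls == "type_I").sum()),
                int((cls == "type_II").sum()),
                int((cls == "type_III").sum()),
                int((cls == "unchanged").sum()),
            )
        )
    summary = pd.DataFrame(
        summary_rows,
        columns=["gene", "fc_glomeruli", "fc_tubuli", "direction",
                 "n_type_I", "n_type_II", "n_type_III", "n_unchanged"],
    )
    return {"profiles": profiles, "summary": summary, "unmapped": sorted(unmapped)}


# ---------------------------------------------------------------------------
# Flux-alteration-similar target search
# ---------------------------------------------------------------------------


def _class_vector(model, gene, wt_fva, fraction):
    ko = apply_knockout(model, {gene})
    try:
        ko_fva = fva(ko, fraction=fraction)
    except InfeasibleProblemError:
        return None
    profile = flux_span_ratio(wt_fva, ko_fva)
    return tuple(profile["alteration_class"])


def similar_flux_targets(
    model: MetabolicModel,
    reference_gene: str,
    fraction: float = 0.0,
) -> pd.DataFrame:
    """Rank genes by how closely their knockout mimics a reference knockout.

    Similarity is the fraction of reactions whose span-ratio alteration class
    (type I/II/III/unchanged/novel) matches the reference gene's knockout
    profile; identical profiles score 1.0.  Candidates whose knockout is
    infeasible score 0.  Ties break lexicographically.
    """
    if reference_gene not in model.genes:
        raise KeyError(f"reference gene {reference_gene!r} not in model")
    wt_fva = fva(model, fraction=fraction)
    ref_vec = _class_vector(model, reference_gene, wt_fva, fraction)
    if ref_vec is None:
        raise InfeasibleProblemError(
            f"knockout of reference gene {reference_gene!r} is infeasible"
        )
    rows = []
    for gene in sorted(model.genes):
        if gene == reference_gene:
            continue
        vec = _class_vector(model, gene, wt_fva, fraction)
        if vec is None:
            score = 0.0
        else:
            score = float(np.mean([a == b for a, b in zip(ref_vec, vec)]))
        rows.append((gene, score))
    frame = pd.DataFrame(rows, columns=["gene", "similarity"])
    frame = frame.sort_values(
        ["similarity", "gene"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    frame["rank"] = np.arange(1, len(frame) + 1)
    return frame
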