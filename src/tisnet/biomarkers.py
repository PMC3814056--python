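"""Exchange-metabolite biomarker prediction for disorder-gene knockouts.

A gene defect changes which boundary metabolites the network can take up or
secrete.  Comparing each exchange reaction's attainable flux interval
(by FVA, uptake negative / secretion positive) between wild type and the
knockout classifies the metabolite's expected concentration change:

* elevated — both interval endpoints shift upward (more secretion / less
  uptake is forced or enabled);
* reduced — both endpoints shift downward;
* unchanged — no shift beyond tolerance, or an ambiguous widening.

Ubiquitous currency metabolites (water, protons, inorganic ions, ...) are
excluded: they are unusable as clinical biomarkers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .flux_analysis import FvaResult, InfeasibleProblemError, LpData, fva
from .model_core import MetabolicModel, apply_knockout

logger = logging.getLogger(__name__)

#: Default currency metabolite base ids (compartment suffixes are stripped
#: before matching, so "h2o_c" matches "h2o").
DEFAULT_CURRENCY = frozenset(
    {"h", "h2o", "o2", "co2", "co", "pi", "ppi", "nh4", "na1", "k", "cl",
     "so4", "hco3", "fe2", "fe3"}
)

DISORDER_COLUMNS = ["disorder_id", "disorder_name", "gene"]
PREDICTION_COLUMNS = [
    "disorder_id", "disorder_name", "gene", "exchange_reaction", "metabolite",
    "direction", "wt_min", "wt_max", "ko_min", "ko_max", "infeasible",
]


def classify_interval_shift(wt, ko, tol: float = 1e-6) -> str:
    """Classify a knockout's shift of one exchange-flux interval.

    ``wt``/``ko`` are ``(low, high)`` intervals.  Elevated if both endpoints
    move up (beyond ``tol``), reduced if both move down, otherwise unchanged
    (including ambiguous widenings where the endpoints move apart).
    """
    l_w, u_w = wt
    l_k, u_k = ko
    if l_w > u_w or l_k > u_k:
        raise ValueError("malformed interval: lower end exceeds upper end")
    if l_k >= l_w - tol and u_k >= u_w - tol and max(l_k - l_w, u_k - u_w) > tol:
        return "elevated"
    if l_k <= l_w + tol and u_k <= u_w + tol and max(l_w - l_k, u_w - u_k) > tol:
        return "reduced"
    return "unchanged"


def _base_met_id(met_id: str) -> str:
    """Strip a trailing compartment tag: 'glc_D_e' -> 'glc_D', 'h2o[c]' -> 'h2o'."""
    if met_id.endswith("]") and "[" in met_id:
        return met_id[: met_id.rindex("[")]
    if "_" in met_id and len(met_id.rsplit("_", 1)[1]) <= 2:
        return met_id.rsplit("_", 1)[0]
    return met_id


def is_currency(metabolite_id: str, currency_ids=DEFAULT_CURRENCY) -> bool:
    return metabolite_id in currency_ids or _base_met_id(metabolite_id) in currency_ids


def exchange_interval_shifts(
    model: MetabolicModel,
    genes,
    wt_fva: FvaResult | None = None,
    fraction: float = 0.0,
    tol: float = 1e-6,
) -> pd.DataFrame | None:
    """Wild-type vs knockout exchange-flux intervals for a gene knockout.

    Returns a DataFrame (exchange_reaction, metabolite, direction, intervals)
    covering every exchange reaction, or ``None`` if the knockout model has
    no feasible flux state.
    """
    exchange_ids = [r.id for r in model.exchange_reactions]
    if wt_fva is None:
        wt_fva = fva(model, fraction=fraction, reactions=exchange_ids)
    ko_model = apply_knockout(model, genes)
    try:
        ko_fva = fva(ko_model, fraction=fraction, reactions=exchange_ids)
    except InfeasibleProblemError:
        return None
    rows = []
    for rid in exchange_ids:
        met = next(iter(model.reaction(rid).stoichiometry))
        direction = classify_interval_shift(wt_fva.intervals[rid], ko_fva.intervals[rid], tol)
        rows.append(
            (rid, met, direction, *wt_fva.intervals[rid], *ko_fva.intervals[rid])
        )
    return pd.DataFrame(
        rows,
        columns=["exchange_reaction", "metabolite", "direction",
                 "wt_min", "wt_max", "ko_min", "ko_max"],
    )


def predict_biomarkers(
    model: MetabolicModel,
    disorders: pd.DataFrame,
    currency_ids=DEFAULT_CURRENCY,
    fraction: float = 0.0,
    tol: float = 1e-6,
) -> pd.DataFrame:
    """Predict elevated/reduced boundary metabolites per disorder gene.

    ``disorders`` has columns (disorder_id, disorder_name, gene).  Disorder
    genes absent from the model are logged and skipped.  Exchange FVA uses
    ``fraction = 0`` by default so secretion potential is not masked by
    growth coupling.  Unchanged exchanges and currency metabolites are
    dropped; a gene whose knockout model is infeasible yields a single
    flagged row with no direction.
    """
    missing = set(DISORDER_COLUMNS) - set(disorders.columns)
    if missing:
        raise ValueError(f"disorder table missing columns: {sorted(missing)}")
    if disorders.duplicated(subset=["disorder_id", "gene"]).any():
        raise ValueError("duplicate (disorder, gene) rows in disorder table")
    currency_ids = frozenset(currency_ids)
    model_genes = set(model.genes)
    exchange_ids = [r.id for r in model.exchange_reactions]
    wt_fva = fva(model, fraction=fraction, reactions=exchange_ids)

    rows = []
    shift_cache: dict[str, pd.DataFrame | None] = {}
    for rec in disorders.itertuples(index=False):
        if rec.gene not in model_genes:
            logger.info("disorder gene %r not in model; skipped", rec.gene)
            continue
        if rec.gene not in shift_cache:
            shift_cache[rec.gene] = exchange_interval_shifts(
                model, {rec.gene}, wt_fva=wt_fva, fraction=fraction, tol=tol
            )
        shifts = shift_cache[rec.gene]
        if shifts is None:
            rows.append(
                (rec.disorder_id, rec.disorder_name, rec.gene, "", "", "",
                 float("nan"), float("nan"), float("nan"), float("nan"), True)
            )
            continue
        for s in shifts.itertuples(index=False):
            if s.direction == "unchanged" or is_currency(s.metabolite, currency_ids):
                continue
            rows.append(
                (rec.disorder_id, rec.disorder_name, rec.gene, s.exchange_reaction,
                 s.metabolite, s.direction, s.wt_min, s.wt_max, s.ko_min, s.ko_max, False)
            )
    return pd.DataFrame(rows, columns=PREDICTION_COLUMNS)


def disorder_union_view(predictions: pd.DataFrame) -> pd.DataFrame:
    """Disorder-level union of per-gene predictions (one row per disorder,
    metabolite, direction)."""
    ok = predictions[~predictions["infeasible"]]
    if ok.empty:
        return pd.DataFrame(columns=["disorder_id", "disorder_name", "metabolite", "direction"])
    return (
        ok[["disorder_id", "disorder_name", "metabolite", "direction"]]
        .drop_duplicates()
        .sort_values(["disorder_id", "metabolite"], kind="stable")
        .reset_index(drop=True)
    )


def biomarker_distributions(predictions: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Distribution summaries of predictions across disorders.

    Returns ``counts`` (per-disorder biomarker count with the cumulative
    fraction of disorders having <= k biomarkers) and ``patterns`` (groups of
    disorders sharing an identical (metabolite, direction) set).
    """
    union = disorder_union_view(predictions)
    if union.empty:
        return {
            "counts": pd.DataFrame(columns=["disorder_id", "n_biomarkers", "cumulative_fraction"]),
            "patterns": pd.DataFrame(columns=["pattern", "n_disorders", "disorders"]),
        }
    counts = (
        union.groupby("disorder_id").size().rename("n_biomarkers").reset_index()
    )
    counts = counts.sort_values(["n_biomarkers", "disorder_id"], kind="stable").reset_index(drop=True)
    total = len(counts)
    counts["cumulative_fraction"] = [
        (counts["n_biomarkers"] <= k).mean() for k in counts["n_biomarkers"]
    ]

    patterns = (
        union.assign(item=union["metabolite"] + ":" + union["direction"])
        .groupby("disorder_id")["item"]
        .apply(lambda items: "|".join(sorted(items)))
        .rename("pattern")
        .reset_index()
    )
    grouped = (
        patterns.groupby("pattern")["disorder_id"]
        .apply(lambda ids: ",".join(sorted(ids)))
        .rename("disorders")
        .reset_index()
    )
    grouped["n_disorders"] = grouped["disorders"].str.count(",") + 1
    grouped = grouped.sort_values(
        ["n_disorders", "pattern"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    return {"counts": counts, "patterns": grouped[["pattern", "n_disorders", "disorders"]]}


def fraction_with_at_most(counts: pd.DataFrame, k: int) -> float:
    """Fraction of disorders with at most ``k`` predicted biomarkers."""
    if counts.empty:
        return float("nan")
    return float((counts["n_biomarkers"] <= k).mean())
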