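"""LP-based flux analyses: FBA, FVA, linear MOMA, gene deletion, flux spans.

All analyses solve linear programs over the steady-state flux cone
``{v : S v = 0, lb <= v <= ub}`` with scipy's HiGHS backend.

* FBA maximizes the biomass objective flux.
* FVA minimizes/maximizes each reaction flux, optionally constraining the
  objective to a fraction of its FBA optimum.
* Linear MOMA predicts the post-knockout flux state as the L1-closest feasible
  flux to a wild-type distribution.
* Flux spans ``f_i = |v_max,i - v_min,i|`` and knockout/wild-type span ratios
  ``r_i = f_ko / f_wt`` classify the flexibility change of each reaction after
  a perturbation (type I: r > 2; type II: 0 < r < 0.5; type III: span drops
  to zero).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .model_core import MetabolicModel, apply_knockout

logger = logging.getLogger(__name__)

#: Fluxes with magnitude below this are reported as exactly zero.
ZERO_CLIP = 1e-9
#: Default tolerance for treating a flux (or span) as nonzero.
FLUX_EPS = 1e-6


class InfeasibleProblemError(RuntimeError):
    """Raised when a base LP required by an analysis has no feasible point."""


# ---------------------------------------------------------------------------
# LP workspace
# ---------------------------------------------------------------------------


class LpData:
    """Dense arrays (S, bounds, objective index) backing the LP solves."""

    def __init__(self, model: MetabolicModel):
        self.reaction_ids = list(model.reaction_ids)
        self.index = {rid: i for i, rid in enumerate(self.reaction_ids)}
        n = len(self.reaction_ids)
        m = len(model.metabolites)
        met_index = {mid: i for i, mid in enumerate(model.metabolite_ids)}
        S = np.zeros((m, n))
        for j, rxn in enumerate(model.reactions):
            for met_id, coeff in rxn.stoichiometry.items():
                S[met_index[met_id], j] = coeff
        self.S = S
        self.lb = np.array([r.lower_bound for r in model.reactions], dtype=float)
        self.ub = np.array([r.upper_bound for r in model.reactions], dtype=float)
        self.objective_index = self.index[model.objective_reaction_id]

    def solve(self, c, extra_A_ub=None, extra_b_ub=None, lb=None, ub=None):
        """Minimize ``c @ v`` over the flux cone; returns the scipy result."""
        lb = self.lb if lb is None else lb
        ub = self.ub if ub is None else ub
        return linprog(
            c,
            A_ub=extra_A_ub,
            b_ub=extra_b_ub,
            A_eq=self.S,
            b_eq=np.zeros(self.S.shape[0]),
            bounds=np.column_stack([lb, ub]),
            method="highs",
        )


_STATUS = {0: "optimal", 1: "iteration_limit", 2: "infeasible", 3: "unbounded", 4: "numerical"}


def _clip(values):
    out = np.asarray(values, dtype=float).copy()
    out[np.abs(out) < ZERO_CLIP] = 0.0
    return out


# ---------------------------------------------------------------------------
# Results
# ---------------------------------------------------------------------------


@dataclass
class FbaResult:
    status: str
    objective_value: float | None
    fluxes: dict | None

    @property
    def ok(self) -> bool:
        return self.status == "optimal"


@dataclass
class MomaResult(FbaResult):
    """Linear-MOMA solution: ``objective_value`` is the knockout growth and
    ``distance`` the minimal L1 distance to the wild-type flux."""

    distance: float | None = None


@dataclass
class FvaResult:
    """Per-reaction flux intervals ``[v_min, v_max]`` at a given optimality
    fraction (0 = unconstrained objective)."""

    intervals: dict[str, tuple[float, float]]
    fraction: float = 0.0

    def minimum(self, rxn_id: str) -> float:
        return self.intervals[rxn_id][0]

    def maximum(self, rxn_id: str) -> float:
        return self.intervals[rxn_id][1]

    def span(self, rxn_id: str) -> float:
        lo, hi = self.intervals[rxn_id]
        return abs(hi - lo)

    def to_frame(self) -> pd.DataFrame:
        rows = [(rid, lo, hi, abs(hi - lo)) for rid, (lo, hi) in self.intervals.items()]
        return pd.DataFrame(rows, columns=["reaction", "v_min", "v_max", "span"])


# ---------------------------------------------------------------------------
# Analyses
# ---------------------------------------------------------------------------


def fba(model: MetabolicModel, lp: LpData | None = None) -> FbaResult:
    """Maximize the objective flux subject to ``S v = 0`` and bounds."""
    lp = lp or LpData(model)
    c = np.zeros(len(lp.reaction_ids))
    c[lp.objective_index] = -1.0
    res = lp.solve(c)
    status = _STATUS.get(res.status, "failed")
    if status != "optimal":
        return FbaResult(status=status, objective_value=None, fluxes=None)
    fluxes = dict(zip(lp.reaction_ids, _clip(res.x)))
    return FbaResult("optimal", float(_clip([-res.fun])[0]), fluxes)


def fva(
    model: MetabolicModel,
    fraction: float = 0.0,
    reactions=None,
    lp: LpData | None = None,
) -> FvaResult:
    """Flux variability analysis at an optimality fraction in [0, 1].

    With ``fraction > 0`` the objective flux is constrained to at least
    ``fraction`` times the FBA optimum; ``fraction = 0`` explores the whole
    bounded flux cone.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    lp = lp or LpData(model)
    n = len(lp.reaction_ids)
    A_ub = b_ub = None
    if fraction > 0.0:
        base = fba(model, lp=lp)
        if not base.ok:
            raise InfeasibleProblemError(f"base FBA problem is {base.status}")
        row = np.zeros((1, n))
        row[0, lp.objective_index] = -1.0
        A_ub, b_ub = row, np.array([-fraction * base.objective_value])
    targets = list(reactions) if reactions is not None else list(lp.reaction_ids)

    intervals = {}
    c = np.zeros(n)
    for rid in targets:
        j = lp.index[rid]
        bounds_pair = []
        for sign in (1.0, -1.0):
            c[:] = 0.0
            c[j] = sign
            res = lp.solve(c, extra_A_ub=A_ub, extra_b_ub=b_ub)
            status = _STATUS.get(res.status, "failed")
            if status != "optimal":
                raise InfeasibleProblemError(
                    f"FVA subproblem for {rid!r} is {status}"
                )
            bounds_pair.append(float(_clip([res.x[j]])[0]))
        vmin, vmax = bounds_pair
        if vmin > vmax:  # solver jitter on a point interval
            vmin = vmax = 0.5 * (vmin + vmax)
        intervals[rid] = (vmin, vmax)
    return FvaResult(intervals=intervals, fraction=fraction)


def linear_moma(model_ko: MetabolicModel, wt_flux: dict) -> MomaResult:
    """Linear (L1) minimization of metabolic adjustment.

    Finds ``v*`` minimizing ``sum_i |v_i - wt_i|`` subject to the knockout
    model's constraints, via auxiliary variables ``d_i >= |v_i - wt_i|``.
    Growth is the objective-reaction flux at ``v*``.
    """
    lp = LpData(model_ko)
    missing = set(lp.reaction_ids) - set(wt_flux)
    if missing:
        raise ValueError(f"wt_flux missing reactions: {sorted(missing)}")
    n = len(lp.reaction_ids)
    wt = np.array([wt_flux[rid] for rid in lp.reaction_ids], dtype=float)

    # Variables [v (n), d (n)]; minimize sum(d) s.t. S v = 0, |v - wt| <= d.
    c = np.concatenate([np.zeros(n), np.ones(n)])
    A_eq = np.hstack([lp.S, np.zeros_like(lp.S)])
    eye = np.eye(n)
    A_ub = np.vstack(
        [np.hstack([eye, -eye]), np.hstack([-eye, -eye])]
    )
    b_ub = np.concatenate([wt, -wt])
    bounds = np.vstack(
        [
            np.column_stack([lp.lb, lp.ub]),
            np.column_stack([np.zeros(n), np.full(n, np.inf)]),
        ]
    )
    res = linprog(
        c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=np.zeros(A_eq.shape[0]),
        bounds=bounds, method="highs",
    )
    status = _STATUS.get(res.status, "failed")
    if status != "optimal":
        return MomaResult(status=status, objective_value=None, fluxes=None, distance=None)
    v = _clip(res.x[:n])
    fluxes = dict(zip(lp.reaction_ids, v))
    growth = fluxes[model_ko.objective_reaction_id]
    return MomaResult("optimal", float(growth), fluxes, distance=float(_clip([res.fun])[0]))


def single_gene_deletion(
    model: MetabolicModel,
    genes=None,
    method: str = "FBA",
    lethal_threshold: float = 1e-3,
    reduced_threshold: float = 0.95,
) -> pd.DataFrame:
    """Single-gene knockout screen with growth-ratio verdicts.

    Returns a DataFrame (gene, method, growth_wt, growth_ko, ratio, verdict)
    where verdict is ``lethal`` (ratio <= lethal_threshold), ``reduced``
    (< reduced_threshold) or ``nonlethal``.  Growth is evaluated by FBA or by
    linear MOMA against the wild-type FBA flux distribution.
    """
    if method not in ("FBA", "MOMA"):
        raise ValueError("method must be 'FBA' or 'MOMA'")
    columns = ["gene", "method", "growth_wt", "growth_ko", "ratio", "verdict"]
    genes = list(model.genes) if genes is None else list(genes)
    if not genes:
        return pd.DataFrame(columns=columns)
    wt = fba(model)
    if not wt.ok:
        raise InfeasibleProblemError(f"wild-type FBA is {wt.status}")
    wt_growth = wt.objective_value
    model_genes = set(model.genes)

    rows = []
    for gene in genes:
        if gene not in model_genes:
            logger.warning("gene %r not in model; reported with ratio 1", gene)
            rows.append((gene, method, wt_growth, wt_growth, 1.0, "nonlethal"))
            continue
        ko = apply_knockout(model, {gene})
        if method == "FBA":
            sol = fba(ko)
        else:
            sol = linear_moma(ko, wt.fluxes)
        growth_ko = sol.objective_value if sol.ok else 0.0
        ratio = 0.0 if wt_growth == 0 else max(growth_ko / wt_growth, 0.0)
        if ratio <= lethal_threshold:
            verdict = "lethal"
        elif ratio < reduced_threshold:
            verdict = "reduced"
        else:
            verdict = "nonlethal"
        rows.append((gene, method, wt_growth, growth_ko, ratio, verdict))
    return pd.DataFrame(rows, columns=columns)


# ---------------------------------------------------------------------------
# Flux spans (knockout vs wild type)
# ---------------------------------------------------------------------------

SPAN_CLASSES = ("type_I", "type_II", "type_III", "unchanged", "novel")


def flux_span_ratio(
    fva_wt: FvaResult, fva_ko: FvaResult, tol: float = ZERO_CLIP
) -> pd.DataFrame:
    """Per-reaction flux spans and knockout/wild-type span ratios.

    Computes ``f = |v_max - v_min|`` for each condition and ``r = f_ko/f_wt``.
    Classes: ``type_I`` (r > 2), ``type_II`` (0 < r < 0.5), ``type_III``
    (span collapses to zero: f_ko = 0 < f_wt), ``novel`` (f_wt = 0 < f_ko,
    r undefined), else ``unchanged``.
    """
    wt_set, ko_set = set(fva_wt.intervals), set(fva_ko.intervals)
    if wt_set != ko_set:
        raise ValueError("wild-type and knockout FVA cover different reactions")
    rows = []
    for rid in fva_wt.intervals:
        f_wt = fva_wt.span(rid)
        f_ko = fva_ko.span(rid)
        f_wt = 0.0 if f_wt < tol else f_wt
        f_ko = 0.0 if f_ko < tol else f_ko
        if f_wt == 0.0:
            if f_ko == 0.0:
                ratio, cls = 1.0, "unchanged"
            else:
                ratio, cls = np.nan, "novel"
        else:
            ratio = f_ko / f_wt
            if f_ko == 0.0:
                cls = "type_III"
            elif ratio > 2.0:
                cls = "type_I"
            elif ratio < 0.5:
                cls = "type_II"
            else:
                cls = "unchanged"
        rows.append((rid, f_wt, f_ko, ratio, cls))
    return pd.DataFrame(
        rows, columns=["reaction", "f_wt", "f_ko", "ratio", "alteration_class"]
    )


# ---------------------------------------------------------------------------
# Blocked reactions (flux consistency)
# ---------------------------------------------------------------------------


def blocked_reactions(
    model: MetabolicModel,
    eps: float = FLUX_EPS,
    lp: LpData | None = None,
    disabled=(),
) -> set[str]:
    """Reactions that cannot carry flux of magnitude >= eps at steady state.

    ``disabled`` reactions are forced to zero and excluded from the report.
    Uses witness reuse: any optimal flux vector certifies every reaction it
    moves, so typically far fewer than 2n LPs are solved.
    """
    lp = lp or LpData(model)
    n = len(lp.reaction_ids)
    disabled_idx = {lp.index[r] for r in disabled}
    lb, ub = lp.lb.copy(), lp.ub.copy()
    for j in disabled_idx:
        lb[j] = ub[j] = 0.0

    unresolved = [j for j in range(n) if j not in disabled_idx]
    certified = np.zeros(n, dtype=bool)
    blocked: set[str] = set()
    c = np.zeros(n)
    for j in unresolved:
        if certified[j]:
            continue
        is_blocked = True
        for sign in (-1.0, 1.0):  # maximize then minimize v_j
            c[:] = 0.0
            c[j] = sign
            res = lp.solve(c, lb=lb, ub=ub)
            if res.status != 0:
                raise InfeasibleProblemError(
                    "flux-consistency LP is "
                    + _STATUS.get(res.status, "failed")
                )
            if abs(res.x[j]) >= eps:
                certified[np.abs(res.x) >= eps] = True
                is_blocked = False
                break
        if is_blocked:
            blocked.add(lp.reaction_ids[j])
    return blocked
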