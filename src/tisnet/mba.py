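"""Tissue-model extraction by iterative random-order pruning (MBA style).

Starting from a generic stoichiometric model and core reaction sets (CH:
must-keep, CM: should-keep), a scan visits the non-core reactions in a random
order and tentatively removes each one.  A removal is accepted only if it
keeps biomass production feasible, blocks no CH reaction, and blocks at most
``eps_w`` moderately-supported (CM) reactions per unsupported reaction it
blocks; accepted removals also delete every reaction they newly block.

Many scans with different random orders are aggregated into per-reaction
inclusion frequencies; the final model keeps CH plus every reaction retained
in at least ``inclusion_threshold`` of the scans, rescued/trimmed to a
flux-consistent, biomass-feasible submodel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .flux_analysis import FLUX_EPS, InfeasibleProblemError, LpData, blocked_reactions
from .model_core import MetabolicModel
from .omics import CoreSets

logger = logging.getLogger(__name__)


def find_blocked_reactions(model: MetabolicModel, eps: float = FLUX_EPS) -> set[str]:
    """Reactions whose flux is zero over the whole steady-state cone."""
    return blocked_reactions(model, eps=eps)


@dataclass
class PruneResult:
    kept_reactions: set[str]
    removal_order_seed: int
    n_scanned: int


@dataclass
class ExtractionResult:
    final_model: MetabolicModel
    inclusion_frequency: dict[str, float]
    n_runs: int
    seed: int


# ---------------------------------------------------------------------------
# Witness-accelerated feasibility/blockedness under a removal set
# ---------------------------------------------------------------------------


class _ScanState:
    """LP workspace for one scan, caching optimal flux vectors as witnesses.

    A cached flux vector whose support avoids every removed reaction proves
    all reactions in its support unblocked without solving an LP.
    """

    MAX_WITNESSES = 80

    def __init__(self, lp: LpData, eps: float):
        self.lp = lp
        self.eps = eps
        self.n = len(lp.reaction_ids)
        self._supports: list[np.ndarray] = []  # boolean support masks

    def add_witness(self, x: np.ndarray) -> None:
        support = np.abs(x) >= self.eps
        if support.any():
            self._supports.append(support)
            if len(self._supports) > self.MAX_WITNESSES:
                del self._supports[0]

    def covered(self, removed_mask: np.ndarray) -> np.ndarray:
        """Union of supports of witnesses still valid under the removal set."""
        out = np.zeros(self.n, dtype=bool)
        for support in self._supports:
            if not (support & removed_mask).any():
                out |= support
        return out

    def _bounds(self, removed_mask):
        lb, ub = self.lp.lb.copy(), self.lp.ub.copy()
        lb[removed_mask] = 0.0
        ub[removed_mask] = 0.0
        return lb, ub

    def biomass_optimum(self, removed_mask: np.ndarray) -> float:
        c = np.zeros(self.n)
        c[self.lp.objective_index] = -1.0
        lb, ub = self._bounds(removed_mask)
        res = self.lp.solve(c, lb=lb, ub=ub)
        if res.status == 2:
            return -np.inf
        if res.status != 0:
            raise InfeasibleProblemError(f"biomass LP failed with status {res.status}")
        self.add_witness(res.x)
        return -res.fun

    def newly_blocked(self, removed_mask: np.ndarray) -> set[int]:
        """Indices of non-removed reactions blocked under the removal set."""
        covered = self.covered(removed_mask)
        lb, ub = self._bounds(removed_mask)
        blocked: set[int] = set()
        c = np.zeros(self.n)
        for j in range(self.n):
            if removed_mask[j] or covered[j]:
                continue
            is_blocked = True
            for sign in (-1.0, 1.0):
                c[:] = 0.0
                c[j] = sign
                res = self.lp.solve(c, lb=lb, ub=ub)
                if res.status != 0:
                    raise InfeasibleProblemError(
                        f"blockedness LP failed with status {res.status}"
                    )
                if abs(res.x[j]) >= self.eps:
                    self.add_witness(res.x)
                    covered |= np.abs(res.x) >= self.eps
                    is_blocked = False
                    break
            if is_blocked:
                blocked.add(j)
        return blocked


# ---------------------------------------------------------------------------
# Pruning
# ---------------------------------------------------------------------------


def prune_scan(
    model: MetabolicModel,
    core: CoreSets,
    seed: int,
    eps_w: float = 0.5,
    biomass_eps: float = 1e-6,
    eps: float = FLUX_EPS,
    _lp: LpData | None = None,
) -> PruneResult:
    """One random-order pruning scan over the non-CH reactions.

    For each candidate reaction ``r`` (in a seed-determined permutation), let
    ``B`` be ``{r}`` plus the reactions newly blocked by its removal.  The
    removal is rolled back if B touches CH, biomass drops below
    ``biomass_eps``, or ``|B ∩ CM| > eps_w * |B \\ (CH ∪ CM)|``; otherwise all
    of B is removed.
    """
    core.validate(model)
    lp = _lp or LpData(model)
    state = _ScanState(lp, eps)
    n = state.n
    removed = np.zeros(n, dtype=bool)

    if state.biomass_optimum(removed) < biomass_eps:
        raise InfeasibleProblemError("input model cannot produce biomass")

    ch_idx = {lp.index[r] for r in core.CH}
    cm_idx = {lp.index[r] for r in core.CM}
    candidates = [j for j in range(n) if j not in ch_idx]
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), 911]))
    order = rng.permutation(len(candidates))

    for pos in order:
        j = candidates[pos]
        if removed[j]:
            continue
        trial = removed.copy()
        trial[j] = True
        if state.biomass_optimum(trial) < biomass_eps:
            continue
        B = state.newly_blocked(trial) | {j}
        if B & ch_idx:
            continue
        n_cm = len(B & cm_idx)
        n_plain = len(B - ch_idx - cm_idx)
        if n_cm > eps_w * n_plain:
            continue
        for b in B:
            removed[b] = True

    kept = {lp.reaction_ids[j] for j in range(n) if not removed[j]}
    return PruneResult(kept_reactions=kept, removal_order_seed=int(seed), n_scanned=len(candidates))


def mba_extract(
    model: MetabolicModel,
    core: CoreSets,
    n_runs: int = 1000,
    inclusion_threshold: float = 0.5,
    seed: int = 0,
    eps_w: float = 0.5,
    biomass_eps: float = 1e-6,
    eps: float = FLUX_EPS,
) -> ExtractionResult:
    """Aggregate ``n_runs`` pruning scans into a tissue-specific model.

    Inclusion frequency of a reaction is the fraction of scans retaining it.
    The final reaction set is CH plus reactions at or above the threshold;
    if biomass is infeasible, reactions are added back in descending
    frequency until it is, and any still-blocked non-core reactions are then
    trimmed so the output is flux-consistent.  Deterministic given ``seed``.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    core.validate(model)
    lp = LpData(model)
    counts = {rid: 0 for rid in model.reaction_ids}
    for run in range(n_runs):
        sub_seed = int(
            np.random.SeedSequence([int(seed) % (2**31), run]).generate_state(1)[0] % (2**31)
        )
        result = prune_scan(
            model, core, seed=sub_seed, eps_w=eps_w, biomass_eps=biomass_eps, eps=eps, _lp=lp
        )
        for rid in result.kept_reactions:
            counts[rid] += 1
    freq = {rid: counts[rid] / n_runs for rid in model.reaction_ids}

    keep = set(core.CH) | {rid for rid, f in freq.items() if f >= inclusion_threshold}
    # Rescue: add back highest-frequency leftovers until biomass is feasible.
    leftovers = sorted(
        (rid for rid in model.reaction_ids if rid not in keep and freq[rid] > 0),
        key=lambda rid: (-freq[rid], rid),
    )
    state = _ScanState(lp, eps)
    removed_mask = np.array([rid not in keep for rid in lp.reaction_ids])
    while state.biomass_optimum(removed_mask) < biomass_eps:
        if not leftovers:
            raise InfeasibleProblemError(
                "no frequency-supported reaction set yields a biomass-feasible model"
            )
        rid = leftovers.pop(0)
        keep.add(rid)
        removed_mask[lp.index[rid]] = False

    # Trim blocked non-core reactions (removing blocked reactions cannot
    # change the flux cone, so one pass suffices).
    blocked = {
        lp.reaction_ids[j] for j in state.newly_blocked(removed_mask)
    }
    bad_core = blocked & core.CH
    if bad_core:
        raise InfeasibleProblemError(
            f"CH reactions blocked in the extracted model: {sorted(bad_core)}"
        )
    keep -= blocked

    final = model.restrict(keep, model_id=f"{model.id}_tissue")
    return ExtractionResult(
        final_model=final, inclusion_frequency=freq, n_runs=n_runs, seed=int(seed)
    )


def jaccard(a, b) -> float:
    """Jaccard similarity of two id sets (1.0 for two empty sets)."""
    a, b = set(a), set(b)
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)
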