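"""Shared fixtures: the toy model and random network generators."""

from __future__ import annotations

import numpy as np
import pytest

from tisnet.model_core import (
    DEFAULT_BOUND,
    GprRule,
    Metabolite,
    MetabolicModel,
    Reaction,
    toy9,
)


@pytest.fixture
def toy():
    return toy9()


@pytest.fixture
def toy_wt_flux():
    """The wild-type optimum routing all substrate to biomass."""
    return {
        "EX_A": -10.0, "R1": 10.0, "R2": 10.0, "BIOMASS": 10.0,
        "R3": 0.0, "EX_D": 0.0, "R5": 0.0, "EX_E": 0.0,
    }


def random_model(
    seed: int,
    max_reactions: int = 10,
    with_gprs: bool = False,
    allow_forced_bounds: bool = False,
) -> MetabolicModel:
    """Small random stoichiometric model with finite bounds.

    Always includes a substrate uptake; internal reactions connect random
    metabolite pairs.  With ``allow_forced_bounds`` one exchange may get a
    fixed nonzero flux, so the model can be infeasible.
    """
    rng = np.random.default_rng(seed)
    n_mets = int(rng.integers(3, 7))
    mets = [Metabolite(f"M{i}") for i in range(n_mets)]
    reactions = [Reaction("EX_M0", {"M0": -1.0}, -10.0, DEFAULT_BOUND)]
    gene_pool = [f"g{i}" for i in range(1, 7)]

    def random_gpr():
        if not with_gprs:
            return GprRule("")
        k = int(rng.integers(1, 3))
        genes = list(rng.choice(gene_pool, size=k, replace=False))
        if k == 1:
            return GprRule(genes[0])
        return GprRule(f"{genes[0]} {'and' if rng.random() < 0.5 else 'or'} {genes[1]}")

    n_internal = int(rng.integers(2, max(3, max_reactions - 3)))
    for r in range(n_internal):
        i, j = rng.choice(n_mets, size=2, replace=False)
        coeff_out = float(rng.integers(1, 3))
        lb = 0.0 if rng.random() < 0.7 else -DEFAULT_BOUND
        reactions.append(
            Reaction(
                f"R{r}", {f"M{i}": -1.0, f"M{j}": coeff_out}, lb, DEFAULT_BOUND,
                gpr=random_gpr(),
            )
        )
    for i in range(1, n_mets):
        if rng.random() < 0.6 and len(reactions) < max_reactions:
            reactions.append(Reaction(f"EX_M{i}", {f"M{i}": -1.0}, 0.0, DEFAULT_BOUND))
    if allow_forced_bounds and rng.random() < 0.3:
        forced = reactions[0]
        value = float(rng.uniform(-3.0, 3.0))
        forced.lower_bound = forced.upper_bound = value
    objective = reactions[int(rng.integers(1, len(reactions)))].id
    model = MetabolicModel(mets, reactions[:max_reactions], objective, id=f"rand{seed}")
    model.validate()
    return model


def to_cobra(model: MetabolicModel):
    """Build the equivalent cobrapy model (reference LP oracle)."""
    import cobra

    cm = cobra.Model(model.id)
    mets = {
        m.id: cobra.Metabolite(m.id, compartment=m.compartment)
        for m in model.metabolites
    }
    for r in model.reactions:
        cr = cobra.Reaction(r.id)
        cr.lower_bound = r.lower_bound
        cr.upper_bound = r.upper_bound
        cm.add_reactions([cr])
        cr.add_metabolites({mets[k]: v for k, v in r.stoichiometry.items()})
        rule = r.gpr.to_string()
        if rule:
            cr.gene_reaction_rule = rule
    cm.objective = model.objective_reaction_id
    return cm
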