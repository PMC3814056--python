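"""Data model for constraint-based metabolic networks.

A :class:`MetabolicModel` is the in-memory representation of a stoichiometric
model: metabolites, reactions with flux bounds and gene-protein-reaction (GPR)
rules, and a biomass objective.  It implies the stoichiometric matrix ``S``
(one row per metabolite, one column per reaction) used by flux balance
analysis, where steady state means ``S v = 0`` for the flux vector ``v``.

I/O supports SBML Level 3 with the FBC v2 extension (bounds, objective, gene
associations), a JSON dialect for fixtures, and TSV tables.
"""

from __future__ import annotations

import copy as _copy
import json
import logging
import math
import re
from dataclasses import dataclass, field

import pandas as pd

logger = logging.getLogger(__name__)

#: Default magnitude used for "unconstrained" flux bounds (mmol gDW^-1 h^-1).
DEFAULT_BOUND = 1000.0

_SID_RE = re.compile(r"^[A-Za-z_][A-Za-z0-9_]*$")


class ModelError(ValueError):
    """Raised for invalid models or unparsable model files."""


# ---------------------------------------------------------------------------
# GPR rules
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(r"\(|\)|[^\s()]+")


def _parse_gpr(text):
    """Parse a boolean GPR expression into a nested tuple tree.

    Grammar: ``expr := term ("or" term)* ; term := factor ("and" factor)* ;
    factor := gene | "(" expr ")"``.  "and"/"or" are case-insensitive.
    Returns ``None`` for an empty rule.
    """
    tokens = _TOKEN_RE.findall(text)
    if not tokens:
        return None
    pos = 0

    def peek():
        return tokens[pos] if pos < len(tokens) else None

    def take():
        nonlocal pos
        tok = tokens[pos]
        pos += 1
        return tok

    def combine(op, parts):
        # n-ary canonical form: nested same-operator nodes are flattened
        # (AND/OR are associative), so render -> parse is idempotent.
        if len(parts) == 1:
            return parts[0]
        flat = []
        for part in parts:
            if part[0] == op:
                flat.extend(part[1])
            else:
                flat.append(part)
        return (op, tuple(flat))

    def parse_expr():
        parts = [parse_term()]
        while peek() is not None and peek().lower() == "or":
            take()
            parts.append(parse_term())
        return combine("or", parts)

    def parse_term():
        parts = [parse_factor()]
        while peek() is not None and peek().lower() == "and":
            take()
            parts.append(parse_factor())
        return combine("and", parts)

    def parse_factor():
        tok = peek()
        if tok is None:
            raise ModelError(f"malformed GPR expression: {text!r} (unexpected end)")
        if tok == "(":
            take()
            node = parse_expr()
            if peek() != ")":
                raise ModelError(f"malformed GPR expression: {text!r} (missing ')')")
            take()
            return node
        if tok == ")" or tok.lower() in ("and", "or"):
            raise ModelError(f"malformed GPR expression: {text!r} (unexpected {tok!r})")
        return ("gene", take())

    tree = parse_expr()
    if pos != len(tokens):
        raise ModelError(f"malformed GPR expression: {text!r} (trailing tokens)")
    return tree


@dataclass(frozen=True)
class GprRule:
    """Boolean gene requirement of a reaction.

    AND joins subunits of an obligate complex, OR joins isozymes.  An empty
    rule means the reaction has no gene requirement.
    """

    text: str = ""

    def __post_init__(self):
        object.__setattr__(self, "_tree", _parse_gpr(self.text))

    @property
    def tree(self):
        return self._tree

    @property
    def is_empty(self) -> bool:
        return self._tree is None

    @property
    def genes(self) -> frozenset[str]:
        out = set()

        def walk(node):
            if node[0] == "gene":
                out.add(node[1])
            else:
                for child in node[1]:
                    walk(child)

        if self._tree is not None:
            walk(self._tree)
        return frozenset(out)

    def evaluate(self, inactive_genes=()) -> bool:
        """True iff the rule holds with ``inactive_genes`` set false.

        All genes not listed are treated as present; an empty rule is true.
        """
        inactive = set(inactive_genes)

        def walk(node):
            kind, payload = node
            if kind == "gene":
                return payload not in inactive
            if kind == "and":
                return all(walk(c) for c in payload)
            return any(walk(c) for c in payload)

        return True if self._tree is None else walk(self._tree)

    def to_string(self) -> str:
        def walk(node, parent=None):
            kind, payload = node
            if kind == "gene":
                return payload
            joiner = f" {kind} "
            inner = joiner.join(walk(c, kind) for c in payload)
            if parent is not None and parent != kind:
                return f"({inner})"
            return inner

        return "" if self._tree is None else walk(self._tree)


def evaluate_gpr(rule: GprRule | str, inactive_genes=()) -> bool:
    """Evaluate a GPR rule with the given genes knocked out."""
    if isinstance(rule, str):
        rule = GprRule(rule)
    return rule.evaluate(inactive_genes)


# ---------------------------------------------------------------------------
# Model components
# ---------------------------------------------------------------------------


@dataclass
class Metabolite:
    id: str
    name: str = ""
    compartment: str = "c"
    is_currency: bool = False


@dataclass
class Reaction:
    """A reaction with signed stoichiometry, flux bounds, and a GPR rule.

    Stoichiometry maps metabolite ids to signed coefficients (negative =
    consumed).  Bounds are fluxes in mmol gDW^-1 h^-1 by convention; for an
    exchange reaction negative flux is uptake.
    """

    id: str
    stoichiometry: dict[str, float]
    lower_bound: float = 0.0
    upper_bound: float = DEFAULT_BOUND
    gpr: GprRule = field(default_factory=GprRule)
    subsystem: str = ""
    name: str = ""

    @property
    def is_exchange(self) -> bool:
        """Structural test: a single-metabolite boundary reaction."""
        return len(self.stoichiometry) == 1

    @property
    def genes(self) -> frozenset[str]:
        return self.gpr.genes


@dataclass
class MetabolicModel:
    """A genome-scale (or toy) stoichiometric model."""

    metabolites: list[Metabolite]
    reactions: list[Reaction]
    objective_reaction_id: str
    id: str = "model"

    # -- lookups ------------------------------------------------------------

    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def metabolite(self, met_id: str) -> Metabolite:
        for m in self.metabolites:
            if m.id == met_id:
                return m
        raise KeyError(met_id)

    def reaction(self, rxn_id: str) -> Reaction:
        for r in self.reactions:
            if r.id == rxn_id:
                return r
        raise KeyError(rxn_id)

    @property
    def genes(self) -> frozenset[str]:
        out: set[str] = set()
        for r in self.reactions:
            out |= r.gpr.genes
        return frozenset(out)

    @property
    def exchange_reactions(self) -> list[Reaction]:
        return [r for r in self.reactions if r.is_exchange]

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        """Check the structural invariants; raise :class:`ModelError` if violated."""
        met_ids = self.metabolite_ids
        if len(set(met_ids)) != len(met_ids):
            raise ModelError("duplicate metabolite ids")
        rxn_ids = self.reaction_ids
        if len(set(rxn_ids)) != len(rxn_ids):
            raise ModelError("duplicate reaction ids")
        if self.objective_reaction_id not in rxn_ids:
            raise ModelError(
                f"objective reaction {self.objective_reaction_id!r} not in model"
            )
        met_set = set(met_ids)
        for m in self.metabolites:
            if not m.compartment:
                raise ModelError(f"metabolite {m.id!r} has empty compartment")
        for r in self.reactions:
            if not r.stoichiometry:
                raise ModelError(f"reaction {r.id!r} has empty stoichiometry")
            if r.lower_bound > r.upper_bound:
                raise ModelError(f"reaction {r.id!r} has lower_bound > upper_bound")
            for met_id, coeff in r.stoichiometry.items():
                if met_id not in met_set:
                    raise ModelError(
                        f"reaction {r.id!r} references unknown metabolite {met_id!r}"
                    )
                if coeff == 0 or not math.isfinite(coeff):
                    raise ModelError(f"reaction {r.id!r} has invalid coefficient for {met_id!r}")

    # -- manipulation -------------------------------------------------------

    def copy(self) -> "MetabolicModel":
        return _copy.deepcopy(self)

    def restrict(self, reaction_ids, model_id: str | None = None) -> "MetabolicModel":
        """Submodel with only the given reactions; orphan metabolites dropped.

        Preserves the original reaction order.  The objective reaction must be
        retained.
        """
        keep = set(reaction_ids)
        unknown = keep - set(self.reaction_ids)
        if unknown:
            raise KeyError(f"unknown reactions: {sorted(unknown)}")
        if self.objective_reaction_id not in keep:
            raise ModelError("cannot restrict away the objective reaction")
        reactions = [_copy.deepcopy(r) for r in self.reactions if r.id in keep]
        used = set()
        for r in reactions:
            used |= set(r.stoichiometry)
        metabolites = [_copy.deepcopy(m) for m in self.metabolites if m.id in used]
        return MetabolicModel(
            metabolites=metabolites,
            reactions=reactions,
            objective_reaction_id=self.objective_reaction_id,
            id=model_id or self.id,
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, MetabolicModel):
            return NotImplemented
        return model_to_dict(self) == model_to_dict(other)


#: A flux distribution: reaction id -> flux value.
FluxVector = dict


def apply_knockout(model: MetabolicModel, genes) -> MetabolicModel:
    """Return a copy with reactions disabled by the gene knockout.

    Every reaction whose GPR evaluates false with ``genes`` inactive gets
    bounds ``[0, 0]``; all other reactions are untouched.  Genes absent from
    the model are ignored with a warning.
    """
    genes = set(genes)
    unknown = genes - set(model.genes)
    if unknown:
        logger.warning("knockout genes not in model (ignored): %s", sorted(unknown))
    ko = model.copy()
    for r in ko.reactions:
        if not r.gpr.is_empty and not r.gpr.evaluate(genes):
            r.lower_bound = 0.0
            r.upper_bound = 0.0
    return ko


# ---------------------------------------------------------------------------
# SBML I/O (Level 3 + FBC v2)
# ---------------------------------------------------------------------------


def _fbc_association_to_tree(assoc, gp_labels):
    import libsbml

    if assoc is None:
        return None
    if isinstance(assoc, libsbml.GeneProductRef):
        ref = assoc.getGeneProduct()
        return ("gene", gp_labels.get(ref, ref))
    if isinstance(assoc, libsbml.FbcAnd):
        children = [
            _fbc_association_to_tree(assoc.getAssociation(i), gp_labels)
            for i in range(assoc.getNumAssociations())
        ]
        return ("and", tuple(children))
    if isinstance(assoc, libsbml.FbcOr):
        children = [
            _fbc_association_to_tree(assoc.getAssociation(i), gp_labels)
            for i in range(assoc.getNumAssociations())
        ]
        return ("or", tuple(children))
    raise ModelError(f"unsupported FBC association type: {type(assoc)}")


def _tree_to_text(tree):
    def walk(node, parent=None):
        kind, payload = node
        if kind == "gene":
            return payload
        inner = f" {kind} ".join(walk(c, kind) for c in payload)
        return f"({inner})" if parent is not None and parent != kind else inner

    return "" if tree is None else walk(tree)


def _notes_field(reaction, key):
    """Extract a 'KEY: value' entry from a reaction's notes (COBRA style)."""
    if not reaction.isSetNotes():
        return ""
    notes = reaction.getNotesString()
    m = re.search(rf"{key}:\s*([^<\n]*)", notes)
    return m.group(1).strip() if m else ""


def read_sbml(path) -> MetabolicModel:
    """Read an SBML L3+FBC model (bounds, objective, gene associations).

    Falls back to reaction notes for gene associations and to
    reversibility-based default bounds when FBC attributes are missing.
    """
    import libsbml
    import os

    path = str(path)
    if not os.path.exists(path):
        raise FileNotFoundError(f"SBML file not found: {path}")
    doc = libsbml.readSBMLFromFile(path)
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        first = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise ModelError(f"cannot parse SBML file {path}: {first.getMessage().strip()}")
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise ModelError(f"SBML file {path} contains no model")

    mplug = sbml_model.getPlugin("fbc")

    metabolites = []
    boundary = set()
    for i in range(sbml_model.getNumSpecies()):
        sp = sbml_model.getSpecies(i)
        if sp.getBoundaryCondition():
            boundary.add(sp.getId())
            continue
        metabolites.append(
            Metabolite(
                id=sp.getId(),
                name=sp.getName() or "",
                compartment=sp.getCompartment() or "c",
            )
        )

    gp_labels = {}
    if mplug is not None:
        for i in range(mplug.getNumGeneProducts()):
            gp = mplug.getGeneProduct(i)
            gp_labels[gp.getId()] = gp.getLabel() or gp.getId()

    def param_value(pid):
        p = sbml_model.getParameter(pid)
        if p is None:
            raise ModelError(f"SBML file {path}: missing flux-bound parameter {pid!r}")
        return p.getValue()

    reactions = []
    for i in range(sbml_model.getNumReactions()):
        rx = sbml_model.getReaction(i)
        stoich: dict[str, float] = {}
        for j in range(rx.getNumReactants()):
            sr = rx.getReactant(j)
            if sr.getSpecies() in boundary:
                continue
            stoich[sr.getSpecies()] = stoich.get(sr.getSpecies(), 0.0) - sr.getStoichiometry()
        for j in range(rx.getNumProducts()):
            sr = rx.getProduct(j)
            if sr.getSpecies() in boundary:
                continue
            stoich[sr.getSpecies()] = stoich.get(sr.getSpecies(), 0.0) + sr.getStoichiometry()
        stoich = {k: v for k, v in stoich.items() if v != 0}

        rplug = rx.getPlugin("fbc")
        if rplug is not None and rplug.isSetLowerFluxBound():
            lb = param_value(rplug.getLowerFluxBound())
            ub = param_value(rplug.getUpperFluxBound())
        else:
            lb = -DEFAULT_BOUND if rx.getReversible() else 0.0
            ub = DEFAULT_BOUND

        gpr_text = ""
        if rplug is not None and rplug.getGeneProductAssociation() is not None:
            tree = _fbc_association_to_tree(
                rplug.getGeneProductAssociation().getAssociation(), gp_labels
            )
            gpr_text = _tree_to_text(tree)
        else:
            gpr_text = _notes_field(rx, r"GENE[_ ]ASSOCIATION")

        reactions.append(
            Reaction(
                id=rx.getId(),
                stoichiometry=stoich,
                lower_bound=lb,
                upper_bound=ub,
                gpr=GprRule(gpr_text),
                subsystem=_notes_field(rx, "SUBSYSTEM"),
                name=rx.getName() or "",
            )
        )

    objective_id = None
    if mplug is not None:
        obj = mplug.getActiveObjective()
        if obj is None and mplug.getNumObjectives() > 0:
            obj = mplug.getObjective(0)
        if obj is not None and obj.getNumFluxObjectives() > 0:
            objective_id = obj.getFluxObjective(0).getReaction()
    if objective_id is None:
        raise ModelError(f"SBML file {path}: model declares no objective reaction")

    model = MetabolicModel(
        metabolites=metabolites,
        reactions=reactions,
        objective_reaction_id=objective_id,
        id=sbml_model.getId() or "model",
    )
    model.validate()
    return model


def write_sbml(model: MetabolicModel, path) -> None:
    """Write the model as SBML Level 3 Version 1 with FBC v2."""
    import libsbml

    if not model.reactions:
        raise ModelError("refusing to serialize a model with no reactions")
    model.validate()
    for ident in [model.id, *model.metabolite_ids, *model.reaction_ids, *sorted(model.genes)]:
        if not _SID_RE.match(ident):
            raise ModelError(f"id {ident!r} is not a valid SBML SId")

    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sm = doc.createModel()
    sm.setId(model.id)
    mplug = sm.getPlugin("fbc")
    mplug.setStrict(True)

    compartments = sorted({m.compartment for m in model.metabolites})
    for cid in compartments:
        comp = sm.createCompartment()
        comp.setId(cid)
        comp.setConstant(True)

    for m in model.metabolites:
        sp = sm.createSpecies()
        sp.setId(m.id)
        if m.name:
            sp.setName(m.name)
        sp.setCompartment(m.compartment)
        sp.setHasOnlySubstanceUnits(False)
        sp.setBoundaryCondition(False)
        sp.setConstant(False)

    bound_params: dict[float, str] = {}

    def bound_param(value: float) -> str:
        if value not in bound_params:
            pid = f"bnd_{len(bound_params)}"
            p = sm.createParameter()
            p.setId(pid)
            p.setValue(value)
            p.setConstant(True)
            bound_params[value] = pid
        return bound_params[value]

    for g in sorted(model.genes):
        gp = mplug.createGeneProduct()
        gp.setId(g)
        gp.setLabel(g)

    def build_association(parent, node):
        kind, payload = node
        if kind == "gene":
            ref = parent.createGeneProductRef()
            ref.setGeneProduct(payload)
        elif kind == "and":
            grp = parent.createAnd()
            for child in payload:
                build_association(grp, child)
        else:
            grp = parent.createOr()
            for child in payload:
                build_association(grp, child)

    for r in model.reactions:
        rx = sm.createReaction()
        rx.setId(r.id)
        if r.name:
            rx.setName(r.name)
        rx.setFast(False)
        rx.setReversible(r.lower_bound < 0)
        for met_id, coeff in r.stoichiometry.items():
            if coeff < 0:
                sr = rx.createReactant()
                sr.setStoichiometry(-coeff)
            else:
                sr = rx.createProduct()
                sr.setStoichiometry(coeff)
            sr.setSpecies(met_id)
            sr.setConstant(True)
        if r.subsystem:
            rx.setNotes(
                '<body xmlns="http://www.w3.org/1999/xhtml">'
                f"<p>SUBSYSTEM: {r.subsystem}</p></body>"
            )
        rplug = rx.getPlugin("fbc")
        rplug.setLowerFluxBound(bound_param(float(r.lower_bound)))
        rplug.setUpperFluxBound(bound_param(float(r.upper_bound)))
        if not r.gpr.is_empty:
            gpa = rplug.createGeneProductAssociation()
            build_association(gpa, r.gpr.tree)

    obj = mplug.createObjective()
    obj.setId("obj")
    obj.setType("maximize")
    fo = obj.createFluxObjective()
    fo.setReaction(model.objective_reaction_id)
    fo.setCoefficient(1.0)
    mplug.setActiveObjectiveId("obj")

    if libsbml.writeSBMLToFile(doc, str(path)) != 1:
        raise ModelError(f"cannot write SBML to {path}")


# ---------------------------------------------------------------------------
# JSON dialect and TSV tables
# ---------------------------------------------------------------------------


def model_to_dict(model: MetabolicModel) -> dict:
    return {
        "id": model.id,
        "objective": model.objective_reaction_id,
        "metabolites": [
            {
                "id": m.id,
                "name": m.name,
                "compartment": m.compartment,
                "is_currency": m.is_currency,
            }
            for m in model.metabolites
        ],
        "reactions": [
            {
                "id": r.id,
                "name": r.name,
                "stoichiometry": dict(sorted(r.stoichiometry.items())),
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "gpr": r.gpr.to_string(),
                "subsystem": r.subsystem,
            }
            for r in model.reactions
        ],
    }


def model_from_dict(data: dict) -> MetabolicModel:
    model = MetabolicModel(
        metabolites=[
            Metabolite(
                id=m["id"],
                name=m.get("name", ""),
                compartment=m.get("compartment", "c"),
                is_currency=m.get("is_currency", False),
            )
            for m in data["metabolites"]
        ],
        reactions=[
            Reaction(
                id=r["id"],
                stoichiometry={k: float(v) for k, v in r["stoichiometry"].items()},
                lower_bound=float(r.get("lower_bound", 0.0)),
                upper_bound=float(r.get("upper_bound", DEFAULT_BOUND)),
                gpr=GprRule(r.get("gpr", "")),
                subsystem=r.get("subsystem", ""),
                name=r.get("name", ""),
            )
            for r in data["reactions"]
        ],
        objective_reaction_id=data["objective"],
        id=data.get("id", "model"),
    )
    model.validate()
    return model


def read_json_model(path) -> MetabolicModel:
    with open(path) as fh:
        return model_from_dict(json.load(fh))


def write_json_model(model: MetabolicModel, path) -> None:
    with open(path, "w") as fh:
        json.dump(model_to_dict(model), fh, indent=1, sort_keys=True)
        fh.write("\n")


def reactions_table(model: MetabolicModel) -> pd.DataFrame:
    """Reaction summary as a DataFrame (one row per reaction)."""

    def equation(r: Reaction) -> str:
        lhs = " + ".join(
            f"{-c:g} {m}" if c != -1 else m
            for m, c in sorted(r.stoichiometry.items())
            if c < 0
        )
        rhs = " + ".join(
            f"{c:g} {m}" if c != 1 else m
            for m, c in sorted(r.stoichiometry.items())
            if c > 0
        )
        arrow = "<=>" if r.lower_bound < 0 else "-->"
        return f"{lhs} {arrow} {rhs}".strip()

    return pd.DataFrame(
        {
            "reaction": model.reaction_ids,
            "equation": [equation(r) for r in model.reactions],
            "lower_bound": [r.lower_bound for r in model.reactions],
            "upper_bound": [r.upper_bound for r in model.reactions],
            "gpr": [r.gpr.to_string() for r in model.reactions],
            "is_exchange": [r.is_exchange for r in model.reactions],
            "subsystem": [r.subsystem for r in model.reactions],
        }
    )


def metabolites_table(model: MetabolicModel) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "metabolite": model.metabolite_ids,
            "name": [m.name for m in model.metabolites],
            "compartment": [m.compartment for m in model.metabolites],
            "is_currency": [m.is_currency for m in model.metabolites],
        }
    )


def toy9() -> MetabolicModel:
    """The nine-component toy model used throughout the documentation.

    Five metabolites A..E; substrate uptake EX_A (bounds [-10, 1000], negative
    flux = uptake), a linear chain to biomass via C, a drain branch to D, and
    a side product E.  GPRs exercise single genes, an OR pair, and an AND pair.
    """
    mets = [Metabolite(id=x, compartment="c") for x in "ABCDE"]
    rxns = [
        Reaction("EX_A", {"A": -1.0}, -10.0, DEFAULT_BOUND),
        Reaction("R1", {"A": -1.0, "B": 1.0}, 0.0, DEFAULT_BOUND, GprRule("g1")),
        Reaction("R2", {"B": -1.0, "C": 1.0}, 0.0, DEFAULT_BOUND, GprRule("g2 or g3")),
        Reaction("R3", {"B": -1.0, "D": 1.0}, 0.0, DEFAULT_BOUND, GprRule("g4 and g5")),
        Reaction("BIOMASS", {"C": -1.0}, 0.0, DEFAULT_BOUND),
        Reaction("EX_D", {"D": -1.0}, 0.0, DEFAULT_BOUND),
        Reaction("R5", {"C": -1.0, "E": 1.0}, 0.0, DEFAULT_BOUND, GprRule("g6")),
        Reaction("EX_E", {"E": -1.0}, 0.0, DEFAULT_BOUND),
    ]
    model = MetabolicModel(mets, rxns, "BIOMASS", id="toy9")
    model.validate()
    return model
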