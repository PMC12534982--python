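"""Constraint-based metabolic network model: types, validation, I/O, curation.

A :class:`MetabolicModel` is a stoichiometric network with flux bounds, boolean
gene-protein-reaction (GPR) rules and a biomass objective.  Reversibility is
encoded purely through the lower bound (``lb < 0``); there is no separate flag.

Curation helpers implement the two standard pre-processing steps used before
condition-specific modeling: iterative removal of dead-end metabolites (those
that can only be produced or only consumed and therefore can never carry
steady-state flux) and insertion of sink reactions, i.e. reversible
pseudo-reactions that add or remove a single intracellular metabolite.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "Metabolite",
    "Reaction",
    "GprRule",
    "GprGene",
    "GprAnd",
    "GprOr",
    "MetabolicModel",
    "ModelFormatError",
    "ModelValidationError",
    "parse_gpr",
    "load_model",
    "write_model",
    "stoichiometric_matrix",
    "find_dead_end_metabolites",
    "prune_dead_ends",
    "add_sink_reaction",
]


class ModelFormatError(ValueError):
    """Raised when an input file cannot be parsed in the requested dialect."""


class ModelValidationError(ValueError):
    """Raised when a model violates a structural invariant."""


# ---------------------------------------------------------------------------
# GPR rules
# ---------------------------------------------------------------------------


class GprRule:
    """Base class for nodes of a boolean gene-association expression tree."""

    def genes(self) -> set[str]:
        raise NotImplementedError

    def evaluate(self, lookup) -> float:
        """Evaluate numerically; ``lookup`` maps gene id -> (value, and_op, or_op)."""
        raise NotImplementedError

    def evaluate_bool(self, active) -> bool:
        """Evaluate as boolean; ``active`` maps gene id -> bool."""
        raise NotImplementedError

    def to_string(self) -> str:
        raise NotImplementedError

    def __eq__(self, other):
        return isinstance(other, GprRule) and self.to_string() == other.to_string()

    def __repr__(self):
        return f"{type(self).__name__}({self.to_string()!r})"


@dataclass(frozen=True, eq=False, repr=False)
class GprGene(GprRule):
    gene: str

    def genes(self):
        return {self.gene}

    def evaluate(self, lookup):
        return lookup.value(self.gene)

    def evaluate_bool(self, active):
        return bool(active(self.gene))

    def to_string(self):
        return self.gene


@dataclass(frozen=True, eq=False, repr=False)
class GprAnd(GprRule):
    children: tuple[GprRule, ...]

    def __post_init__(self):
        if not self.children:
            raise ModelValidationError("AND node with no operands")

    def genes(self):
        return set().union(*(c.genes() for c in self.children))

    def evaluate(self, lookup):
        return lookup.and_op([c.evaluate(lookup) for c in self.children])

    def evaluate_bool(self, active):
        return all(c.evaluate_bool(active) for c in self.children)

    def to_string(self):
        return "(" + " and ".join(c.to_string() for c in self.children) + ")"


@dataclass(frozen=True, eq=False, repr=False)
class GprOr(GprRule):
    children: tuple[GprRule, ...]

    def __post_init__(self):
        if not self.children:
            raise ModelValidationError("OR node with no operands")

    def genes(self):
        return set().union(*(c.genes() for c in self.children))

    def evaluate(self, lookup):
        return lookup.or_op([c.evaluate(lookup) for c in self.children])

    def evaluate_bool(self, active):
        return any(c.evaluate_bool(active) for c in self.children)

    def to_string(self):
        return "(" + " or ".join(c.to_string() for c in self.children) + ")"


_GPR_TOKEN = re.compile(r"\(|\)|[^\s()]+")


def parse_gpr(text: str) -> GprRule | None:
    """Parse a GPR string (gene ids, parentheses, case-insensitive and/or).

    Returns ``None`` for an empty/blank rule.  ``and`` binds tighter than
    ``or``, the convention used by COBRA-style model files.
    """
    tokens = _GPR_TOKEN.findall(text or "")
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

    def parse_atom() -> GprRule:
        tok = peek()
        if tok is None:
            raise ModelFormatError(f"unexpected end of GPR rule: {text!r}")
        if tok == "(":
            take()
            node = parse_or()
            if peek() != ")":
                raise ModelFormatError(f"unbalanced parentheses in GPR rule: {text!r}")
            take()
            return node
        if tok == ")" or tok.lower() in ("and", "or"):
            raise ModelFormatError(f"misplaced token {tok!r} in GPR rule: {text!r}")
        return GprGene(take())

    def parse_and() -> GprRule:
        parts = [parse_atom()]
        while peek() is not None and peek().lower() == "and":
            take()
            parts.append(parse_atom())
        return parts[0] if len(parts) == 1 else GprAnd(tuple(parts))

    def parse_or() -> GprRule:
        parts = [parse_and()]
        while peek() is not None and peek().lower() == "or":
            take()
            parts.append(parse_and())
        return parts[0] if len(parts) == 1 else GprOr(tuple(parts))

    node = parse_or()
    if pos != len(tokens):
        raise ModelFormatError(f"trailing tokens in GPR rule: {text!r}")
    return node


# ---------------------------------------------------------------------------
# Core types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Metabolite:
    id: str
    name: str = ""
    compartment: str = "c"

    def __post_init__(self):
        if not self.id:
            raise ModelValidationError("metabolite id must be non-empty")
        if not self.compartment:
            raise ModelValidationError(f"metabolite {self.id!r}: compartment must be non-empty")


@dataclass(frozen=True)
class Reaction:
    """One reaction: signed stoichiometry, flux bounds (mmol/gDW/h), GPR."""

    id: str
    stoichiometry: Mapping[str, float]
    lb: float = 0.0
    ub: float = 1000.0
    gpr: GprRule | None = None
    is_sink: bool = False
    name: str = ""

    def __post_init__(self):
        if not self.id:
            raise ModelValidationError("reaction id must be non-empty")
        if not self.stoichiometry:
            raise ModelValidationError(f"reaction {self.id!r}: empty stoichiometry")
        for met, coef in self.stoichiometry.items():
            if not np.isfinite(coef) or coef == 0:
                raise ModelValidationError(
                    f"reaction {self.id!r}: coefficient for {met!r} must be finite and nonzero"
                )
        if self.lb > self.ub:
            raise ModelValidationError(f"reaction {self.id!r}: lb={self.lb} > ub={self.ub}")
        object.__setattr__(self, "stoichiometry", dict(self.stoichiometry))

    @property
    def reversible(self) -> bool:
        return self.lb < 0

    def genes(self) -> set[str]:
        return self.gpr.genes() if self.gpr is not None else set()


@dataclass
class MetabolicModel:
    """A stoichiometric model with bounds, GPRs and a biomass objective."""

    metabolites: list[Metabolite]
    reactions: list[Reaction]
    objective_reaction_id: str
    genes: set[str] = field(default_factory=set)
    id: str = "model"

    def __post_init__(self):
        self.genes = set(self.genes) | {g for r in self.reactions for g in r.genes()}
        self.validate()

    # -- lookups -----------------------------------------------------------
    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def reaction(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(rid)

    def metabolite(self, mid: str) -> Metabolite:
        for m in self.metabolites:
            if m.id == mid:
                return m
        raise KeyError(mid)

    def validate(self) -> None:
        mids = self.metabolite_ids
        if len(set(mids)) != len(mids):
            dupes = sorted({m for m in mids if mids.count(m) > 1})
            raise ModelValidationError(f"duplicate metabolite ids: {dupes}")
        rids = self.reaction_ids
        if len(set(rids)) != len(rids):
            dupes = sorted({r for r in rids if rids.count(r) > 1})
            raise ModelValidationError(f"duplicate reaction ids: {dupes}")
        if self.objective_reaction_id not in rids:
            raise ModelValidationError(
                f"objective reaction {self.objective_reaction_id!r} not in model"
            )
        known = set(mids)
        for r in self.reactions:
            missing = set(r.stoichiometry) - known
            if missing:
                raise ModelValidationError(
                    f"reaction {r.id!r} references unknown metabolites: {sorted(missing)}"
                )
        orphan = {g for r in self.reactions for g in r.genes()} - self.genes
        if orphan:
            raise ModelValidationError(f"GPR genes missing from gene list: {sorted(orphan)}")

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            metabolites=list(self.metabolites),
            reactions=list(self.reactions),
            objective_reaction_id=self.objective_reaction_id,
            genes=set(self.genes),
            id=self.id,
        )

    def with_bounds(self, bounds: Mapping[str, tuple[float, float]]) -> "MetabolicModel":
        """Return a copy with per-reaction (lb, ub) overridden by ``bounds``."""
        new = []
        for r in self.reactions:
            if r.id in bounds:
                lb, ub = bounds[r.id]
                new.append(replace(r, lb=lb, ub=ub))
            else:
                new.append(r)
        return MetabolicModel(self.metabolites, new, self.objective_reaction_id,
                              set(self.genes), self.id)


# ---------------------------------------------------------------------------
# I/O: COBRA-style JSON (read/write) and SBML Level-3 FBC (read-only)
# ---------------------------------------------------------------------------


def _model_to_dict(model: MetabolicModel) -> dict:
    return {
        "id": model.id,
        "metabolites": [
            {"id": m.id, "name": m.name, "compartment": m.compartment}
            for m in model.metabolites
        ],
        "reactions": [
            {
                "id": r.id,
                "name": r.name,
                "metabolites": dict(r.stoichiometry),
                "lower_bound": r.lb,
                "upper_bound": r.ub,
                "gene_reaction_rule": r.gpr.to_string() if r.gpr else "",
                "is_sink": r.is_sink,
                "objective_coefficient": 1.0 if r.id == model.objective_reaction_id else 0.0,
            }
            for r in model.reactions
        ],
        "genes": [{"id": g} for g in sorted(model.genes)],
    }


def write_model(model: MetabolicModel, path) -> None:
    """Write a model as COBRA-style JSON (the canonical hand-writable dialect)."""
    with open(path, "w") as fh:
        json.dump(_model_to_dict(model), fh, indent=1, sort_keys=False)
        fh.write("\n")


def _load_json(path) -> MetabolicModel:
    try:
        with open(path) as fh:
            data = json.load(fh)
    except json.JSONDecodeError as exc:
        raise ModelFormatError(f"{path}: not valid JSON ({exc})") from exc
    try:
        raw_mets = data["metabolites"]
        raw_rxns = data["reactions"]
    except KeyError as exc:
        raise ModelFormatError(f"{path}: missing top-level key {exc}") from exc
    mets = []
    for entry in raw_mets:
        if "id" not in entry:
            raise ModelFormatError(f"{path}: metabolite entry lacks 'id': {entry}")
        mets.append(Metabolite(entry["id"], entry.get("name", ""),
                               entry.get("compartment", "c")))
    objective = None
    rxns = []
    for entry in raw_rxns:
        rid = entry.get("id")
        if rid is None:
            raise ModelFormatError(f"{path}: reaction entry lacks 'id': {entry}")
        if "metabolites" not in entry:
            raise ModelFormatError(f"{path}: reaction {rid!r} lacks 'metabolites' stoichiometry")
        try:
            gpr = parse_gpr(entry.get("gene_reaction_rule", ""))
        except ModelFormatError as exc:
            raise ModelFormatError(f"{path}: reaction {rid!r}: {exc}") from exc
        rxns.append(
            Reaction(
                id=rid,
                stoichiometry={k: float(v) for k, v in entry["metabolites"].items()},
                lb=float(entry.get("lower_bound", 0.0)),
                ub=float(entry.get("upper_bound", 1000.0)),
                gpr=gpr,
                is_sink=bool(entry.get("is_sink", False)),
                name=entry.get("name", ""),
            )
        )
        if float(entry.get("objective_coefficient", 0.0)) != 0.0:
            objective = rid
    if objective is None and "objective" in data:
        objective = data["objective"]
    if objective is None:
        raise ModelFormatError(f"{path}: no objective reaction declared")
    declared = {g["id"] if isinstance(g, dict) else str(g) for g in data.get("genes", [])}
    used = {g for r in rxns for g in r.genes()}
    if declared and not used <= declared:
        raise ModelValidationError(
            f"{path}: GPR genes not declared in gene list: {sorted(used - declared)}"
        )
    return MetabolicModel(mets, rxns, objective, declared | used, id=data.get("id", "model"))


def _load_sbml(path) -> MetabolicModel:
    try:
        import libsbml
    except ImportError as exc:  # pragma: no cover - libsbml ships with the env
        raise ModelFormatError("SBML support requires python-libsbml") from exc
    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise ModelFormatError(f"{path}: SBML parse error: {err.getMessage() if err else 'unknown'}")
    sm = doc.getModel()
    if sm is None:
        raise ModelFormatError(f"{path}: SBML file contains no model")

    def _clip(sid: str, prefix: str) -> str:
        # SBML convention prefixes ids with R_/M_/G_; strip for COBRA-style ids
        return sid[len(prefix):] if sid.startswith(prefix) else sid

    mets = [
        Metabolite(_clip(sp.getId(), "M_"), sp.getName() or "", sp.getCompartment() or "c")
        for sp in sm.getListOfSpecies()
    ]
    params = {p.getId(): p.getValue() for p in sm.getListOfParameters()}

    def _assoc_to_rule(assoc) -> GprRule | None:
        if assoc is None:
            return None
        if assoc.isGeneProductRef():
            gp = sm.getPlugin("fbc").getGeneProduct(assoc.getGeneProduct())
            label = (gp.getLabel() or gp.getId()) if gp is not None else assoc.getGeneProduct()
            return GprGene(_clip(label, "G_"))
        children = [_assoc_to_rule(assoc.getAssociation(i))
                    for i in range(assoc.getNumAssociations())]
        children = [c for c in children if c is not None]
        if not children:
            return None
        if assoc.isFbcAnd():
            return children[0] if len(children) == 1 else GprAnd(tuple(children))
        return children[0] if len(children) == 1 else GprOr(tuple(children))

    objective = None
    mplug = sm.getPlugin("fbc")
    if mplug is not None and mplug.getNumObjectives() > 0:
        obj = mplug.getObjective(mplug.getActiveObjectiveId() or 0) or mplug.getObjective(0)
        if obj is not None and obj.getNumFluxObjectives() > 0:
            objective = _clip(obj.getFluxObjective(0).getReaction(), "R_")
    rxns = []
    for sr in sm.getListOfReactions():
        stoich: dict[str, float] = {}
        for i in range(sr.getNumReactants()):
            ref = sr.getReactant(i)
            mid = _clip(ref.getSpecies(), "M_")
            stoich[mid] = stoich.get(mid, 0.0) - ref.getStoichiometry()
        for i in range(sr.getNumProducts()):
            ref = sr.getProduct(i)
            mid = _clip(ref.getSpecies(), "M_")
            stoich[mid] = stoich.get(mid, 0.0) + ref.getStoichiometry()
        stoich = {k: v for k, v in stoich.items() if v != 0}
        rplug = sr.getPlugin("fbc")
        lb = params.get(rplug.getLowerFluxBound(), -1000.0) if rplug else -1000.0
        ub = params.get(rplug.getUpperFluxBound(), 1000.0) if rplug else 1000.0
        gpr = _assoc_to_rule(
            rplug.getGeneProductAssociation().getAssociation()
        ) if rplug and rplug.isSetGeneProductAssociation() else None
        rxns.append(Reaction(_clip(sr.getId(), "R_"), stoich, lb=lb, ub=ub, gpr=gpr,
                             name=sr.getName() or ""))
    if objective is None:
        raise ModelFormatError(f"{path}: SBML-FBC model declares no flux objective")
    return MetabolicModel(mets, rxns, objective, id=sm.getId() or "model")


def load_model(path, dialect: str = "cobra-json") -> MetabolicModel:
    """Load a model from ``path`` in the given dialect.

    Parameters
    ----------
    dialect : {"cobra-json", "sbml-fbc"}
        COBRA-style JSON is read/write; SBML Level-3 FBC is read-only.
    """
    if dialect == "cobra-json":
        return _load_json(path)
    if dialect == "sbml-fbc":
        return _load_sbml(path)
    raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# Structural analysis & curation
# ---------------------------------------------------------------------------


def stoichiometric_matrix(model: MetabolicModel) -> np.ndarray:
    """Dense S matrix (metabolites x reactions) in declaration order."""
    midx = {m: i for i, m in enumerate(model.metabolite_ids)}
    S = np.zeros((len(model.metabolites), len(model.reactions)))
    for j, r in enumerate(model.reactions):
        for met, coef in r.stoichiometry.items():
            S[midx[met], j] = coef
    return S


def find_dead_end_metabolites(model: MetabolicModel) -> set[str]:
    """Metabolites that cannot both be produced and consumed.

    A reversible reaction (lb < 0) counts as both producer and consumer of
    every participant; an irreversible one produces its products and consumes
    its reactants.  Metabolites failing either role are mass-balance blocked.
    """
    produced: set[str] = set()
    consumed: set[str] = set()
    for r in model.reactions:
        for met, coef in r.stoichiometry.items():
            forward_produces = coef > 0
            if r.reversible:
                produced.add(met)
                consumed.add(met)
            elif forward_produces:
                produced.add(met)
            else:
                consumed.add(met)
    return {m.id for m in model.metabolites if m.id not in produced or m.id not in consumed}


def prune_dead_ends(model: MetabolicModel) -> tuple[MetabolicModel, list[str]]:
    """Iteratively remove dead-end metabolites and the reactions touching them.

    Removal cascades to fixpoint (a removal can orphan upstream metabolites).
    Returns the pruned model and an ordered log of removed ids (metabolites
    and reactions interleaved, in removal order).  Idempotent; errors out if
    the objective reaction itself would be removed.
    """
    current = model
    log: list[str] = []
    while True:
        dead = find_dead_end_metabolites(current)
        if not dead:
            return current, log
        doomed_rxns = [r.id for r in current.reactions
                       if any(m in dead for m in r.stoichiometry)]
        if current.objective_reaction_id in doomed_rxns:
            raise ModelValidationError(
                "pruning dead ends would remove the objective reaction "
                f"{current.objective_reaction_id!r}; model is irreparable without sinks"
            )
        log.extend(sorted(dead))
        log.extend(doomed_rxns)
        current = MetabolicModel(
            metabolites=[m for m in current.metabolites if m.id not in dead],
            reactions=[r for r in current.reactions if r.id not in doomed_rxns],
            objective_reaction_id=current.objective_reaction_id,
            genes=set(current.genes),
            id=current.id,
        )


def add_sink_reaction(
    model: MetabolicModel,
    metabolite_id: str,
    lb: float = -1000.0,
    ub: float = 1000.0,
) -> MetabolicModel:
    """Append a sink reaction (stoichiometry ``{metabolite: -1}``) for one metabolite.

    Sinks default to reversible bounds so they can either drain or supply the
    metabolite.  Adding a second sink for the same metabolite is an error.
    """
    if metabolite_id not in model.metabolite_ids:
        raise ModelValidationError(f"cannot add sink: unknown metabolite {metabolite_id!r}")
    for r in model.reactions:
        if r.is_sink and set(r.stoichiometry) == {metabolite_id}:
            raise ModelValidationError(f"duplicate sink for metabolite {metabolite_id!r}")
    sink = Reaction(
        id=f"sink_{metabolite_id}",
        stoichiometry={metabolite_id: -1.0},
        lb=lb,
        ub=ub,
        is_sink=True,
        name=f"sink for {metabolite_id}",
    )
    if sink.id in model.reaction_ids:
        raise ModelValidationError(f"reaction id {sink.id!r} already present")
    return MetabolicModel(
        metabolites=list(model.metabolites),
        reactions=list(model.reactions) + [sink],
        objective_reaction_id=model.objective_reaction_id,
        genes=set(model.genes),
        id=model.id,
    )
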