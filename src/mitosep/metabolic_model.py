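"""Constraint-based metabolic models: container, I/O and flux balance analysis.

A model is a stoichiometric matrix with per-reaction flux bounds, an ATP
production objective reaction, optional gene-protein-reaction (GPR) boolean
rules, and named lactate/succinate export reactions used by the blockage
screen.  Models round-trip through SBML Level 3 (FBC v2, via libsbml) and an
equivalent JSON dialect::

    {"id": ..., "metabolites": [...],
     "reactions": [{"id", "metabolites": {met: coeff}, "lower_bound",
                    "upper_bound", "gpr"}, ...],
     "objective_id": ..., "lactate_export_id": ..., "succinate_export_id": ...}

Fluxes are unitless (nominally mmol/gDW/h); only relative comparisons matter
for the screen.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.optimize import linprog


@dataclass
class Reaction:
    id: str
    metabolites: dict[str, float]        # metabolite id -> stoichiometric coeff
    lower_bound: float = 0.0
    upper_bound: float = 1000.0
    gpr: str = ""                        # boolean expression over gene ids

    def __post_init__(self):
        if self.lower_bound > self.upper_bound:
            raise ValueError(f"reaction {self.id}: lower bound exceeds upper bound")


@dataclass
class MetabolicModel:
    id: str
    metabolites: list[str]
    reactions: list[Reaction]
    objective_id: str
    lactate_export_id: Optional[str] = None
    succinate_export_id: Optional[str] = None

    def __post_init__(self):
        self.validate()

    # -- structure ---------------------------------------------------------
    def validate(self) -> None:
        rids = [r.id for r in self.reactions]
        if len(set(rids)) != len(rids):
            raise ValueError("duplicate reaction ids")
        known = set(self.metabolites)
        for r in self.reactions:
            missing = set(r.metabolites) - known
            if missing:
                raise ValueError(f"reaction {r.id} uses unknown metabolites {missing}")
        for name, rid in (("objective", self.objective_id),
                          ("lactate export", self.lactate_export_id),
                          ("succinate export", self.succinate_export_id)):
            if rid is not None and rid not in set(rids):
                raise ValueError(f"{name} reaction id {rid!r} not in model")

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def reaction(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(rid)

    def stoichiometric_matrix(self) -> np.ndarray:
        """Dense metabolites x reactions matrix."""
        midx = {m: i for i, m in enumerate(self.metabolites)}
        S = np.zeros((len(self.metabolites), len(self.reactions)))
        for j, r in enumerate(self.reactions):
            for m, c in r.metabolites.items():
                S[midx[m], j] = c
        return S

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lb = np.array([r.lower_bound for r in self.reactions], dtype=float)
        ub = np.array([r.upper_bound for r in self.reactions], dtype=float)
        return lb, ub

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            id=self.id,
            metabolites=list(self.metabolites),
            reactions=[replace(r, metabolites=dict(r.metabolites))
                       for r in self.reactions],
            objective_id=self.objective_id,
            lactate_export_id=self.lactate_export_id,
            succinate_export_id=self.succinate_export_id,
        )

    def genes(self) -> list[str]:
        out: set[str] = set()
        for r in self.reactions:
            out |= set(genes_in_gpr(r.gpr))
        return sorted(out)

    # -- JSON dialect ------------------------------------------------------
    def to_json(self) -> str:
        return json.dumps({
            "id": self.id,
            "metabolites": self.metabolites,
            "reactions": [{
                "id": r.id, "metabolites": r.metabolites,
                "lower_bound": r.lower_bound, "upper_bound": r.upper_bound,
                "gpr": r.gpr,
            } for r in self.reactions],
            "objective_id": self.objective_id,
            "lactate_export_id": self.lactate_export_id,
            "succinate_export_id": self.succinate_export_id,
        }, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "MetabolicModel":
        d = json.loads(text)
        return cls(
            id=d["id"], metabolites=list(d["metabolites"]),
            reactions=[Reaction(r["id"], {k: float(v) for k, v in
                                          r["metabolites"].items()},
                                float(r["lower_bound"]), float(r["upper_bound"]),
                                r.get("gpr", ""))
                       for r in d["reactions"]],
            objective_id=d["objective_id"],
            lactate_export_id=d.get("lactate_export_id"),
            succinate_export_id=d.get("succinate_export_id"),
        )


# ---------------------------------------------------------------------------
# GPR boolean rules
# ---------------------------------------------------------------------------

_GPR_TOKEN = re.compile(r"\(|\)|\band\b|\bor\b|[A-Za-z0-9_.:-]+")


def genes_in_gpr(expr: str) -> list[str]:
    if not expr.strip():
        return []
    return [t for t in _GPR_TOKEN.findall(expr)
            if t not in ("and", "or", "(", ")")]


def evaluate_gpr(expr: str, knocked_out: Iterable[str]) -> bool:
    """Evaluate a GPR boolean expression with the given genes deleted.

    A gene evaluates True when present (not knocked out).  An empty rule means
    the reaction has no gene requirement and stays active.
    """
    if not expr.strip():
        return True
    ko = set(knocked_out)
    tokens = _GPR_TOKEN.findall(expr)
    pos = 0

    def parse_or():
        nonlocal pos
        val = parse_and()
        while pos < len(tokens) and tokens[pos] == "or":
            pos += 1
            val = parse_and() or val
        return val

    def parse_and():
        nonlocal pos
        val = parse_atom()
        while pos < len(tokens) and tokens[pos] == "and":
            pos += 1
            val = parse_atom() and val
        return val

    def parse_atom():
        nonlocal pos
        tok = tokens[pos]
        pos += 1
        if tok == "(":
            val = parse_or()
            if pos >= len(tokens) or tokens[pos] != ")":
                raise ValueError(f"unbalanced parentheses in GPR {expr!r}")
            pos += 1
            return val
        if tok in (")", "and", "or"):
            raise ValueError(f"malformed GPR {expr!r}")
        return tok not in ko

    result = parse_or()
    if pos != len(tokens):
        raise ValueError(f"trailing tokens in GPR {expr!r}")
    return result


# ---------------------------------------------------------------------------
# Flux balance analysis
# ---------------------------------------------------------------------------

@dataclass
class FBAResult:
    status: str                      # "optimal" | "infeasible"
    objective_value: Optional[float] = None
    fluxes: Optional[dict[str, float]] = None


def fba_max(model: MetabolicModel, objective_id: Optional[str] = None
            ) -> FBAResult:
    """Maximize one reaction's flux subject to S v = 0 and the bounds.

    Infeasible models are reported as such (status ``"infeasible"``), never as
    a zero optimum.
    """
    objective_id = objective_id or model.objective_id
    rids = model.reaction_ids
    if objective_id not in rids:
        raise KeyError(f"objective reaction {objective_id!r} not in model")
    S = model.stoichiometric_matrix()
    lb, ub = model.bounds()
    c = np.zeros(len(rids))
    c[rids.index(objective_id)] = -1.0
    res = linprog(c, A_eq=S, b_eq=np.zeros(S.shape[0]),
                  bounds=list(zip(lb, ub)), method="highs")
    if not res.success:
        return FBAResult("infeasible")
    fluxes = dict(zip(rids, res.x))
    return FBAResult("optimal", float(-res.fun), fluxes)


# ---------------------------------------------------------------------------
# SBML Level 3 + FBC v2 I/O (libsbml)
# ---------------------------------------------------------------------------

def write_sbml(model: MetabolicModel, path: str) -> None:
    import libsbml

    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sbml_model = doc.createModel()
    sbml_model.setId(model.id)
    mplug = sbml_model.getPlugin("fbc")
    mplug.setStrict(True)

    comp = sbml_model.createCompartment()
    comp.setId("c")
    comp.setConstant(True)
    comp.setSize(1.0)

    for m in model.metabolites:
        sp = sbml_model.createSpecies()
        sp.setId("M_" + m)
        sp.setCompartment("c")
        sp.setConstant(False)
        sp.setBoundaryCondition(False)
        sp.setHasOnlySubstanceUnits(False)
        sp.setInitialConcentration(0.0)

    for g in model.genes():
        gp = mplug.createGeneProduct()
        gp.setId("G_" + g)
        gp.setLabel(g)

    bound_params: dict[float, str] = {}

    def bound_param(value: float) -> str:
        if value not in bound_params:
            pid = f"fb_{len(bound_params)}"
            p = sbml_model.createParameter()
            p.setId(pid)
            p.setValue(float(value))
            p.setConstant(True)
            bound_params[value] = pid
        return bound_params[value]

    for r in model.reactions:
        rx = sbml_model.createReaction()
        rx.setId("R_" + r.id)
        rx.setReversible(r.lower_bound < 0)
        rx.setFast(False)
        rplug = rx.getPlugin("fbc")
        rplug.setLowerFluxBound(bound_param(r.lower_bound))
        rplug.setUpperFluxBound(bound_param(r.upper_bound))
        for m, coeff in r.metabolites.items():
            ref = rx.createReactant() if coeff < 0 else rx.createProduct()
            ref.setSpecies("M_" + m)
            ref.setStoichiometry(abs(float(coeff)))
            ref.setConstant(True)
        if r.gpr.strip():
            gpa = rplug.createGeneProductAssociation()
            infix = re.sub(r"([A-Za-z0-9_.:-]+)",
                           lambda m: ("G_" + m.group(1))
                           if m.group(1) not in ("and", "or") else m.group(1),
                           r.gpr)
            gpa.setAssociation(infix)

    obj = mplug.createObjective()
    obj.setId("obj")
    obj.setType("maximize")
    fo = obj.createFluxObjective()
    fo.setReaction("R_" + model.objective_id)
    fo.setCoefficient(1.0)
    mplug.setActiveObjectiveId("obj")

    if not libsbml.writeSBMLToFile(doc, path):
        raise IOError(f"could not write SBML to {path}")


def read_sbml(path: str, objective_id: Optional[str] = None,
              lactate_export_id: Optional[str] = None,
              succinate_export_id: Optional[str] = None) -> MetabolicModel:
    """Load an SBML Level 3 FBC model.

    The ``R_``/``M_``/``G_`` SBML id prefixes are stripped.  The objective is
    taken from the active FBC objective unless overridden.
    """
    import libsbml

    doc = libsbml.readSBMLFromFile(path)
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        raise IOError(f"SBML parse errors in {path}: "
                      f"{doc.getErrorLog().toString()}")
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise IOError(f"no model element in {path}")
    mplug = sbml_model.getPlugin("fbc")

    def strip(sid: str, prefix: str) -> str:
        return sid[len(prefix):] if sid.startswith(prefix) else sid

    mets = [strip(sbml_model.getSpecies(i).getId(), "M_")
            for i in range(sbml_model.getNumSpecies())]
    params = {sbml_model.getParameter(i).getId(): sbml_model.getParameter(i).getValue()
              for i in range(sbml_model.getNumParameters())}

    reactions = []
    for i in range(sbml_model.getNumReactions()):
        rx = sbml_model.getReaction(i)
        stoich: dict[str, float] = {}
        for j in range(rx.getNumReactants()):
            ref = rx.getReactant(j)
            m = strip(ref.getSpecies(), "M_")
            stoich[m] = stoich.get(m, 0.0) - ref.getStoichiometry()
        for j in range(rx.getNumProducts()):
            ref = rx.getProduct(j)
            m = strip(ref.getSpecies(), "M_")
            stoich[m] = stoich.get(m, 0.0) + ref.getStoichiometry()
        rplug = rx.getPlugin("fbc")
        lb = params.get(rplug.getLowerFluxBound(), -1000.0) \
            if rplug is not None and rplug.isSetLowerFluxBound() \
            else (-1000.0 if rx.getReversible() else 0.0)
        ub = params.get(rplug.getUpperFluxBound(), 1000.0) \
            if rplug is not None and rplug.isSetUpperFluxBound() else 1000.0
        gpr = ""
        if rplug is not None and rplug.isSetGeneProductAssociation():
            assoc = rplug.getGeneProductAssociation().getAssociation()
            gpr = re.sub(r"\bG_", "", assoc.toInfix()) if assoc is not None else ""
        reactions.append(Reaction(strip(rx.getId(), "R_"), stoich,
                                  float(lb), float(ub), gpr))

    if objective_id is None and mplug is not None:
        obj = mplug.getActiveObjective()
        if obj is not None and obj.getNumFluxObjectives() > 0:
            objective_id = strip(obj.getFluxObjective(0).getReaction(), "R_")
    if objective_id is None:
        raise ValueError(f"no objective reaction found in {path}; pass objective_id")

    return MetabolicModel(
        id=sbml_model.getId() or "model",
        metabolites=mets, reactions=reactions, objective_id=objective_id,
        lactate_export_id=lactate_export_id,
        succinate_export_id=succinate_export_id,
    )
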