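"""Domain types and I/O for reaction-list metabolic models.

A model is a set of metabolites and reactions with flux bounds and one
objective reaction (typically a biomass drain).  Metabolites marked
*external* are boundary species: they are excluded from the steady-state
balance, so reactions touching them act as exchange reactions across the
system boundary.

Two serialisations are supported:

* a line-oriented reaction-list dialect in the OptGene/BioOpt tradition
  (sections ``-REACTIONS``, ``-CONSTRAINTS``, ``-EXTERNAL METABOLITES``,
  ``-OBJ``), and
* SBML (export and import via libsbml), with boundary species flagged by
  ``boundaryCondition`` and flux bounds carried as kinetic-law parameters
  in the widespread COBRA convention.

Stoichiometric coefficients are parsed and stored as exact
:class:`fractions.Fraction` values and only converted to floating point
when a numeric matrix is assembled, which keeps elemental-balance audits
exact.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Dict, Iterable, List, Optional, Tuple

import libsbml

logger = logging.getLogger("photogem")

#: Magnitude used for "effectively unbounded" fluxes, mmol gDW^-1 h^-1.
#: Any optimal flux that reaches this value is worth flagging in logs.
DEFAULT_BOUND = 1000.0

#: Conventional suffix marking external (boundary) metabolites in the
#: text dialect.  The explicit ``-EXTERNAL METABOLITES`` section is
#: authoritative; the suffix is a convention layered on top of it.
EXTERNAL_SUFFIX = "_ext"


class ModelError(ValueError):
    """Invalid model structure (invariant violation)."""


class ModelFormatError(ModelError):
    """Malformed model file.  Carries the offending line number."""

    def __init__(self, message: str, line: Optional[int] = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class Metabolite:
    """A chemical species.

    Parameters
    ----------
    id:
        Short unique token (case-sensitive).
    name:
        Free-text description.
    external:
        True for boundary species excluded from the steady-state balance.
    formula:
        Optional elemental composition, element symbol -> positive count.
    charge:
        Optional formal charge.
    """

    id: str
    name: str = ""
    external: bool = False
    formula: Optional[Dict[str, int]] = None
    charge: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ModelError("metabolite id must be non-empty")
        if self.formula is not None:
            for elem, count in self.formula.items():
                if count <= 0:
                    raise ModelError(
                        f"metabolite {self.id!r}: formula count for {elem} "
                        f"must be strictly positive, got {count}"
                    )


@dataclass
class Reaction:
    """A stoichiometric conversion with flux bounds.

    ``stoichiometry`` maps metabolite id to a signed rational
    coefficient: negative = consumed, positive = produced.  Fluxes are in
    mmol gDW^-1 h^-1 (photon fluxes in mE gDW^-1 h^-1, numerically
    interchangeable since 1 mE = 1 mmol photons).
    """

    id: str
    stoichiometry: Dict[str, Fraction]
    reversible: bool = False
    lower_bound: float = 0.0
    upper_bound: float = DEFAULT_BOUND
    name: str = ""
    genes: List[str] = field(default_factory=list)
    ec_number: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ModelError("reaction id must be non-empty")
        if not self.stoichiometry:
            raise ModelError(f"reaction {self.id!r}: stoichiometry is empty")
        self.stoichiometry = {m: Fraction(c) for m, c in self.stoichiometry.items()}
        if any(c == 0 for c in self.stoichiometry.values()):
            raise ModelError(f"reaction {self.id!r}: zero stoichiometric coefficient")
        if self.lower_bound > self.upper_bound:
            raise ModelError(
                f"reaction {self.id!r}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}"
            )
        if not self.reversible and self.lower_bound < 0:
            raise ModelError(
                f"reaction {self.id!r}: irreversible but lower bound "
                f"{self.lower_bound} < 0"
            )

    @property
    def substrates(self) -> Dict[str, Fraction]:
        return {m: -c for m, c in self.stoichiometry.items() if c < 0}

    @property
    def products(self) -> Dict[str, Fraction]:
        return {m: c for m, c in self.stoichiometry.items() if c > 0}


class MetabolicModel:
    """Metabolites + reactions + bounds + objective; the S-matrix source of truth.

    Insertion order of metabolites and reactions is preserved and defines
    row/column order of the stoichiometric matrix.
    """

    def __init__(
        self,
        metabolites: Iterable[Metabolite] = (),
        reactions: Iterable[Reaction] = (),
        objective_id: Optional[str] = None,
        id: str = "model",
    ):
        self.id = id
        self.metabolites: Dict[str, Metabolite] = {}
        self.reactions: Dict[str, Reaction] = {}
        self.objective_id = objective_id
        for met in metabolites:
            self.add_metabolite(met)
        for rxn in reactions:
            self.add_reaction(rxn)

    # -- construction ------------------------------------------------------

    def add_metabolite(self, met: Metabolite) -> None:
        if met.id in self.metabolites:
            raise ModelError(f"duplicate metabolite id {met.id!r}")
        self.metabolites[met.id] = met

    def add_reaction(self, rxn: Reaction) -> None:
        if rxn.id in self.reactions:
            raise ModelError(f"duplicate reaction id {rxn.id!r}")
        for met_id in rxn.stoichiometry:
            if met_id not in self.metabolites:
                raise ModelError(
                    f"reaction {rxn.id!r} references unknown metabolite {met_id!r}"
                )
        self.reactions[rxn.id] = rxn

    # -- queries -----------------------------------------------------------

    @property
    def internal_metabolites(self) -> List[str]:
        return [m for m, met in self.metabolites.items() if not met.external]

    @property
    def external_metabolites(self) -> List[str]:
        return [m for m, met in self.metabolites.items() if met.external]

    def exchange_reactions(self) -> List[str]:
        """Reactions crossing the boundary: they touch an external
        metabolite, or they have a single participant (implicit boundary)."""
        out = []
        for rid, rxn in self.reactions.items():
            if len(rxn.stoichiometry) == 1 or any(
                self.metabolites[m].external for m in rxn.stoichiometry
            ):
                out.append(rid)
        return out

    def validate(self) -> None:
        """Re-check all structural invariants; raise ModelError on violation."""
        seen = set()
        for rid, rxn in self.reactions.items():
            if rid in seen:
                raise ModelError(f"duplicate reaction id {rid!r}")
            seen.add(rid)
            Reaction(**{k: getattr(rxn, k) for k in (
                "id", "stoichiometry", "reversible", "lower_bound",
                "upper_bound", "name", "genes", "ec_number")})
            for met_id in rxn.stoichiometry:
                if met_id not in self.metabolites:
                    raise ModelError(
                        f"reaction {rid!r} references unknown metabolite {met_id!r}"
                    )
        if self.objective_id is not None and self.objective_id not in self.reactions:
            raise ModelError(f"objective {self.objective_id!r} is not a reaction")

    def equivalent(self, other: "MetabolicModel") -> bool:
        """Structural equality up to ordering."""
        if set(self.metabolites) != set(other.metabolites):
            return False
        for mid, met in self.metabolites.items():
            o = other.metabolites[mid]
            if (met.external, met.formula, met.charge) != (o.external, o.formula, o.charge):
                return False
        if set(self.reactions) != set(other.reactions):
            return False
        for rid, rxn in self.reactions.items():
            o = other.reactions[rid]
            if rxn.stoichiometry != o.stoichiometry:
                return False
            if (rxn.reversible, rxn.lower_bound, rxn.upper_bound) != (
                o.reversible, o.lower_bound, o.upper_bound
            ):
                return False
        return self.objective_id == other.objective_id

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            metabolites=[Metabolite(id=m.id, name=m.name, external=m.external,
                                    formula=dict(m.formula) if m.formula else None,
                                    charge=m.charge)
                         for m in self.metabolites.values()],
            reactions=[Reaction(id=r.id, stoichiometry=dict(r.stoichiometry),
                                reversible=r.reversible, lower_bound=r.lower_bound,
                                upper_bound=r.upper_bound, name=r.name,
                                genes=list(r.genes), ec_number=r.ec_number)
                       for r in self.reactions.values()],
            objective_id=self.objective_id, id=self.id)

    def __repr__(self) -> str:  # pragma: no cover
        return (f"<MetabolicModel {self.id}: {len(self.reactions)} reactions, "
                f"{len(self.metabolites)} metabolites>")


# ---------------------------------------------------------------------------
# Reaction-list dialect
# ---------------------------------------------------------------------------

_ARROWS = ("<->", "<=>", "->", "=>")
_COMMENT = re.compile(r"[%#].*$")


def _parse_coefficient(token: str, lineno: int) -> Fraction:
    try:
        return Fraction(token)
    except (ValueError, ZeroDivisionError):
        raise ModelFormatError(f"malformed stoichiometric coefficient {token!r}", lineno)


def _looks_numeric(token: str) -> bool:
    try:
        Fraction(token)
        return True
    except (ValueError, ZeroDivisionError):
        return False


def _parse_side(text: str, lineno: int) -> List[Tuple[Fraction, str]]:
    terms: List[Tuple[Fraction, str]] = []
    text = text.strip()
    if not text:
        return terms
    for term in re.split(r"\s\+\s", text):
        parts = term.strip().split()
        if not parts:
            raise ModelFormatError("empty term in reaction equation", lineno)
        if len(parts) == 2:
            coeff = _parse_coefficient(parts[0], lineno)
            met = parts[1]
        elif len(parts) == 1:
            coeff, met = Fraction(1), parts[0]
        else:
            raise ModelFormatError(f"cannot parse reaction term {term.strip()!r}", lineno)
        if coeff <= 0:
            raise ModelFormatError(
                f"stoichiometric coefficient must be positive, got {coeff}", lineno)
        if _looks_numeric(met):
            raise ModelFormatError(f"metabolite token {met!r} looks like a number", lineno)
        terms.append((coeff, met))
    return terms


def parse_model(text: str) -> MetabolicModel:
    """Parse the reaction-list dialect into a :class:`MetabolicModel`.

    Reactions written with ``<->`` are reversible with default bounds
    [-1000, 1000]; ``->`` gives [0, 1000].  Lines in ``-CONSTRAINTS``
    (``id [lb, ub]``) override defaults.  Metabolites listed under
    ``-EXTERNAL METABOLITES`` or carrying the ``_ext`` suffix are
    boundary species.  Comments start with ``%`` or ``#``.
    """
    section = "-REACTIONS"
    raw_reactions: List[Tuple[int, str, List[Tuple[Fraction, str]],
                              List[Tuple[Fraction, str]], bool]] = []
    constraints: List[Tuple[int, str, float, float]] = []
    externals: List[str] = []
    objective: Optional[str] = None

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = _COMMENT.sub("", raw).strip()
        if not line:
            continue
        if line.startswith("-"):
            header = line.upper()
            if header.startswith("-REA"):
                section = "-REACTIONS"
            elif header.startswith("-CON"):
                section = "-CONSTRAINTS"
            elif header.startswith("-EXT"):
                section = "-EXTERNAL"
            elif header.startswith("-OBJ"):
                section = "-OBJ"
            else:
                raise ModelFormatError(f"unknown section header {line!r}", lineno)
            continue

        if section == "-REACTIONS":
            if ":" not in line:
                raise ModelFormatError("reaction line lacks 'id:' prefix", lineno)
            rid, _, equation = line.partition(":")
            rid = rid.strip()
            if not rid:
                raise ModelFormatError("empty reaction id", lineno)
            arrow = next((a for a in _ARROWS if a in equation), None)
            if arrow is None:
                raise ModelFormatError("reaction equation lacks an arrow", lineno)
            reversible = arrow in ("<->", "<=>")
            lhs_text, rhs_text = equation.split(arrow, 1)
            lhs = _parse_side(lhs_text, lineno)
            rhs = _parse_side(rhs_text, lineno)
            if not lhs and not rhs:
                raise ModelFormatError("reaction has no participants", lineno)
            raw_reactions.append((lineno, rid, lhs, rhs, reversible))
        elif section == "-CONSTRAINTS":
            m = re.match(r"^(\S+)\s*\[\s*([^\s,\]]+)\s*,\s*([^\s,\]]+)\s*\]$", line)
            if not m:
                raise ModelFormatError(f"malformed constraint line {line!r}", lineno)
            try:
                lb, ub = float(m.group(2)), float(m.group(3))
            except ValueError:
                raise ModelFormatError(f"malformed bound in {line!r}", lineno)
            constraints.append((lineno, m.group(1), lb, ub))
        elif section == "-EXTERNAL":
            externals.extend(line.split())
        elif section == "-OBJ":
            parts = line.split()
            objective = parts[0]

    external_set = set(externals)
    model = MetabolicModel(id="model")

    def ensure_metabolite(met_id: str) -> None:
        if met_id not in model.metabolites:
            ext = met_id in external_set or met_id.endswith(EXTERNAL_SUFFIX)
            model.add_metabolite(Metabolite(id=met_id, external=ext))

    for lineno, rid, lhs, rhs, reversible in raw_reactions:
        stoich: Dict[str, Fraction] = {}
        for coeff, met in lhs:
            stoich[met] = stoich.get(met, Fraction(0)) - coeff
        for coeff, met in rhs:
            stoich[met] = stoich.get(met, Fraction(0)) + coeff
        stoich = {m: c for m, c in stoich.items() if c != 0}
        if not stoich:
            raise ModelFormatError(
                f"reaction {rid!r} cancels to an empty stoichiometry", lineno)
        for met in stoich:
            ensure_metabolite(met)
        if rid in model.reactions:
            raise ModelFormatError(f"duplicate reaction id {rid!r}", lineno)
        lb, ub = (-DEFAULT_BOUND, DEFAULT_BOUND) if reversible else (0.0, DEFAULT_BOUND)
        model.add_reaction(Reaction(id=rid, stoichiometry=stoich,
                                    reversible=reversible,
                                    lower_bound=lb, upper_bound=ub))

    for met_id in externals:
        if met_id not in model.metabolites:
            model.add_metabolite(Metabolite(id=met_id, external=True))

    for lineno, rid, lb, ub in constraints:
        if rid not in model.reactions:
            raise ModelFormatError(
                f"constraint references unknown reaction {rid!r}", lineno)
        rxn = model.reactions[rid]
        if lb > ub:
            raise ModelFormatError(f"constraint on {rid!r}: lb {lb} > ub {ub}", lineno)
        if not rxn.reversible and lb < 0:
            logger.info("constraint makes %s reversible (lb %g < 0)", rid, lb)
            rxn.reversible = True
        rxn.lower_bound, rxn.upper_bound = lb, ub

    if objective is not None:
        if objective not in model.reactions:
            raise ModelFormatError(f"objective references unknown reaction {objective!r}")
        model.objective_id = objective

    model.validate()
    return model


def _format_coefficient(c: Fraction) -> str:
    if c.denominator == 1:
        return str(c.numerator)
    f = float(c)
    if Fraction(repr(f)) == c:  # exact decimal representation
        return repr(f)
    return f"{c.numerator}/{c.denominator}"


def _format_side(terms: Dict[str, Fraction]) -> str:
    parts = []
    for met, coeff in terms.items():
        parts.append(met if coeff == 1 else f"{_format_coefficient(coeff)} {met}")
    return " + ".join(parts)


def write_model(model: MetabolicModel) -> str:
    """Serialise to the reaction-list dialect (round-trips with parse_model)."""
    if not model.reactions:
        raise ModelError("cannot serialise a model with no reactions")
    lines = ["-REACTIONS"]
    for rxn in model.reactions.values():
        arrow = "<->" if rxn.reversible else "->"
        lines.append(f"{rxn.id}: {_format_side(rxn.substrates)} {arrow} "
                     f"{_format_side(rxn.products)}".replace("  ", " ").rstrip())
    constraint_lines = []
    for rxn in model.reactions.values():
        default = (-DEFAULT_BOUND, DEFAULT_BOUND) if rxn.reversible else (0.0, DEFAULT_BOUND)
        if (rxn.lower_bound, rxn.upper_bound) != default:
            constraint_lines.append(f"{rxn.id} [{rxn.lower_bound:g}, {rxn.upper_bound:g}]")
    if constraint_lines:
        lines.append("-CONSTRAINTS")
        lines.extend(constraint_lines)
    externals = sorted(model.external_metabolites)
    if externals:
        lines.append("-EXTERNAL METABOLITES")
        lines.extend(externals)
    if model.objective_id:
        lines.append("-OBJ")
        lines.append(f"{model.objective_id} 1")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# SBML export / import
# ---------------------------------------------------------------------------

_SID_RE = re.compile(r"^[A-Za-z_][A-Za-z0-9_]*$")


def _sanitize_sid(raw: str, prefix: str, taken: set) -> str:
    sid = re.sub(r"[^A-Za-z0-9_]", "_", raw)
    if not _SID_RE.match(sid):
        sid = prefix + sid
    base, k = sid, 2
    while sid in taken:
        sid = f"{base}_{k}"
        k += 1
    taken.add(sid)
    return sid


def export_sbml(model: MetabolicModel) -> Tuple[str, Dict[str, str]]:
    """Export to SBML Level 2 Version 4 with COBRA-style bound parameters.

    External metabolites get ``boundaryCondition='true'``; bounds travel
    as ``LOWER_BOUND``/``UPPER_BOUND`` kinetic-law parameters and the
    objective as ``OBJECTIVE_COEFFICIENT``.  Returns the document text
    and the mapping original-id -> sanitized SBML SId.
    """
    if not model.reactions:
        raise ModelError("cannot export a model with no reactions")
    doc = libsbml.SBMLDocument(2, 4)
    sm = doc.createModel()
    sm.setId(_sanitize_sid(model.id, "M_", set()))
    comp = sm.createCompartment()
    comp.setId("cell")
    comp.setSize(1.0)

    taken: set = {"cell"}
    mapping: Dict[str, str] = {}
    for met in model.metabolites.values():
        sid = _sanitize_sid(met.id, "M_", taken)
        mapping[met.id] = sid
        sp = sm.createSpecies()
        sp.setId(sid)
        sp.setName(met.name or met.id)
        sp.setCompartment("cell")
        sp.setBoundaryCondition(met.external)
        sp.setInitialAmount(0.0)
        if met.charge is not None:
            sp.setCharge(met.charge)
    for rxn in model.reactions.values():
        sid = _sanitize_sid(rxn.id, "R_", taken)
        mapping[rxn.id] = sid
        sr = sm.createReaction()
        sr.setId(sid)
        sr.setName(rxn.name or rxn.id)
        sr.setReversible(rxn.reversible)
        for met_id, coeff in rxn.stoichiometry.items():
            ref = sr.createProduct() if coeff > 0 else sr.createReactant()
            ref.setSpecies(mapping[met_id])
            ref.setStoichiometry(abs(float(coeff)))
        kl = sr.createKineticLaw()
        kl.setMath(libsbml.parseFormula("FLUX_VALUE"))
        for pname, val in (
            ("LOWER_BOUND", rxn.lower_bound),
            ("UPPER_BOUND", rxn.upper_bound),
            ("FLUX_VALUE", 0.0),
            ("OBJECTIVE_COEFFICIENT", 1.0 if rxn.id == model.objective_id else 0.0),
        ):
            par = kl.createParameter()
            par.setId(pname)
            par.setValue(val)
    return libsbml.writeSBMLToString(doc), mapping


def import_sbml(text: str) -> MetabolicModel:
    """Read an SBML document into a :class:`MetabolicModel`.

    Recognises ``boundaryCondition`` species as external and picks up
    COBRA-convention bound/objective parameters when present.
    """
    doc = libsbml.readSBMLFromString(text)
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise ModelFormatError(f"SBML parse error: {err.getMessage() if err else 'unknown'}")
    sm = doc.getModel()
    if sm is None:
        raise ModelFormatError("SBML document contains no model")
    model = MetabolicModel(id=sm.getId() or "model")
    for i in range(sm.getNumSpecies()):
        sp = sm.getSpecies(i)
        model.add_metabolite(Metabolite(
            id=sp.getId(), name=sp.getName() or "",
            external=bool(sp.getBoundaryCondition()),
            charge=sp.getCharge() if sp.isSetCharge() else None))
    objective = None
    for i in range(sm.getNumReactions()):
        sr = sm.getReaction(i)
        stoich: Dict[str, Fraction] = {}
        for j in range(sr.getNumReactants()):
            ref = sr.getReactant(j)
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), Fraction(0)) - \
                Fraction(repr(ref.getStoichiometry()))
        for j in range(sr.getNumProducts()):
            ref = sr.getProduct(j)
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), Fraction(0)) + \
                Fraction(repr(ref.getStoichiometry()))
        stoich = {m: c for m, c in stoich.items() if c != 0}
        reversible = bool(sr.getReversible())
        lb, ub = (-DEFAULT_BOUND, DEFAULT_BOUND) if reversible else (0.0, DEFAULT_BOUND)
        kl = sr.getKineticLaw()
        if kl is not None:
            for k in range(kl.getNumParameters()):
                par = kl.getParameter(k)
                if par.getId() == "LOWER_BOUND":
                    lb = par.getValue()
                elif par.getId() == "UPPER_BOUND":
                    ub = par.getValue()
                elif par.getId() == "OBJECTIVE_COEFFICIENT" and par.getValue():
                    objective = sr.getId()
        model.add_reaction(Reaction(
            id=sr.getId(), stoichiometry=stoich, reversible=reversible or lb < 0,
            lower_bound=lb, upper_bound=ub, name=sr.getName() or ""))
    model.objective_id = objective
    model.validate()
    return model


def load_model(text: str) -> MetabolicModel:
    """Dispatch on content: SBML/XML documents vs the reaction-list dialect."""
    head = text.lstrip()[:200]
    if head.startswith("<?xml") or head.startswith("<sbml"):
        return import_sbml(text)
    return parse_model(text)
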