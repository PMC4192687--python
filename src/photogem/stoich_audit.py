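"""Stoichiometric matrix assembly and curation audits.

The stoichiometric matrix S has one row per *internal* (balanced)
metabolite and one column per reaction; external boundary species
contribute no row, so exchange reactions appear as single-entry columns.

The audits mirror the manual curation steps used when building a
genome-scale model: per-reaction element/charge balancing against a
supplied formula dictionary, and detection of duplicated reactions
(identical stoichiometry, or mirror-image stoichiometry when both copies
are reversible).  Audits only report; nothing is auto-corrected, because
apparent duplicates may be intentional isoenzymes and completion with
H+/H2O is a curator's call.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np
from scipy import sparse

from .model_core import MetabolicModel, Reaction


@dataclass
class StoichiometricMatrix:
    """Sparse S with its row (internal metabolite) and column (reaction) labels."""

    rows: List[str]
    cols: List[str]
    matrix: sparse.csc_matrix

    @property
    def shape(self) -> Tuple[int, int]:
        return self.matrix.shape

    def to_dense(self) -> np.ndarray:
        return self.matrix.toarray()

    def column(self, reaction_id: str) -> np.ndarray:
        return self.matrix[:, self.cols.index(reaction_id)].toarray().ravel()


def build_matrix(model: MetabolicModel) -> StoichiometricMatrix:
    """Assemble S from a model.  External metabolites contribute no row."""
    rows = model.internal_metabolites
    cols = list(model.reactions)
    row_index = {m: i for i, m in enumerate(rows)}
    data, ri, ci = [], [], []
    for j, rid in enumerate(cols):
        for met_id, coeff in model.reactions[rid].stoichiometry.items():
            i = row_index.get(met_id)
            if i is not None:
                data.append(float(coeff))
                ri.append(i)
                ci.append(j)
    matrix = sparse.csc_matrix(
        (data, (ri, ci)), shape=(len(rows), len(cols)))
    return StoichiometricMatrix(rows=rows, cols=cols, matrix=matrix)


# ---------------------------------------------------------------------------
# Element / charge balance
# ---------------------------------------------------------------------------

#: Audit statuses.
BALANCED = "balanced"
UNBALANCED = "unbalanced"
UNKNOWABLE = "unknowable"


@dataclass
class ImbalanceReport:
    """Net products-minus-substrates difference per element for one reaction.

    ``element_diff`` is empty and status is ``balanced`` iff the reaction
    conserves every element checked.  When any participant lacks a
    formula the status is ``unknowable`` (not unbalanced).  ``suggestion``
    carries a human-readable completion hint (e.g. missing water) and is
    never applied automatically.
    """

    reaction_id: str
    status: str
    element_diff: Dict[str, Fraction] = field(default_factory=dict)
    charge_diff: Optional[Fraction] = None
    missing_formulas: List[str] = field(default_factory=list)
    suggestion: Optional[str] = None

    @property
    def balanced(self) -> bool:
        return self.status == BALANCED


def _completion_hint(diff: Dict[str, Fraction], charge: Optional[Fraction]) -> Optional[str]:
    elems = set(diff)
    if elems == {"H", "O"} and diff["H"] == 2 * diff["O"]:
        n = -diff["O"]
        side = "product" if n > 0 else "substrate"
        return f"adding {abs(n)} H2O on the {side} side would close the balance"
    if elems == {"H"} and (charge is None or charge == diff["H"]):
        n = -diff["H"]
        side = "product" if n > 0 else "substrate"
        return f"adding {abs(n)} H+ on the {side} side would close the balance"
    return None


def check_element_balance(
    reaction: Reaction,
    formulas: Dict[str, Dict[str, int]],
    charges: Optional[Dict[str, int]] = None,
) -> ImbalanceReport:
    """Net per-element difference (products minus substrates) for one reaction.

    Coefficients are exact rationals, so the audit is exact.  Charge is
    compared only when every participant carries a charge in ``charges``;
    otherwise it is skipped.
    """
    missing = [m for m in reaction.stoichiometry if m not in formulas]
    if missing:
        return ImbalanceReport(reaction_id=reaction.id, status=UNKNOWABLE,
                               missing_formulas=sorted(missing))
    diff: Dict[str, Fraction] = {}
    for met_id, coeff in reaction.stoichiometry.items():
        for elem, count in formulas[met_id].items():
            diff[elem] = diff.get(elem, Fraction(0)) + coeff * count
    diff = {e: d for e, d in diff.items() if d != 0}

    charge_diff: Optional[Fraction] = None
    if charges is not None and all(m in charges for m in reaction.stoichiometry):
        charge_diff = sum(
            (coeff * charges[m] for m, coeff in reaction.stoichiometry.items()),
            Fraction(0))
        if charge_diff == 0:
            charge_diff = Fraction(0)
    status = BALANCED if not diff and not charge_diff else UNBALANCED
    report = ImbalanceReport(reaction_id=reaction.id, status=status,
                             element_diff=diff, charge_diff=charge_diff)
    if status == UNBALANCED:
        report.suggestion = _completion_hint(diff, charge_diff)
    return report


def audit_balance(
    model: MetabolicModel,
    formulas: Optional[Dict[str, Dict[str, int]]] = None,
    charges: Optional[Dict[str, int]] = None,
) -> List[ImbalanceReport]:
    """Run the element-balance audit over every reaction.

    Formulas default to those attached to the model's metabolites.
    """
    if formulas is None:
        formulas = {m.id: m.formula for m in model.metabolites.values()
                    if m.formula is not None}
    if charges is None:
        attached = {m.id: m.charge for m in model.metabolites.values()
                    if m.charge is not None}
        charges = attached or None
    return [check_element_balance(rxn, formulas, charges)
            for rxn in model.reactions.values()]


# ---------------------------------------------------------------------------
# Duplicate reactions
# ---------------------------------------------------------------------------

def _canonical_keys(rxn: Reaction) -> Tuple[tuple, Optional[tuple]]:
    fwd = tuple(sorted(rxn.stoichiometry.items()))
    rev = tuple(sorted((m, -c) for m, c in rxn.stoichiometry.items())) \
        if rxn.reversible else None
    return fwd, rev


def find_duplicate_reactions(model: MetabolicModel) -> List[List[str]]:
    """Group reactions with identical stoichiometry.

    Two reactions are duplicates iff their stoichiometry maps are equal,
    or equal after negating one when *both* are reversible.  Returns a
    partition of the flagged reactions; each group is sorted by insertion
    order and groups are ordered by their first member.
    """
    ids = list(model.reactions)
    parent = {rid: rid for rid in ids}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: str, b: str) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    by_fwd: Dict[tuple, List[str]] = {}
    for rid in ids:
        fwd, _ = _canonical_keys(model.reactions[rid])
        by_fwd.setdefault(fwd, []).append(rid)
    for group in by_fwd.values():
        for other in group[1:]:
            union(group[0], other)
    # mirror-image pairs among reversibles
    rev_index: Dict[tuple, List[str]] = {}
    for rid in ids:
        rxn = model.reactions[rid]
        if rxn.reversible:
            fwd, _ = _canonical_keys(rxn)
            rev_index.setdefault(fwd, []).append(rid)
    for rid in ids:
        rxn = model.reactions[rid]
        if not rxn.reversible:
            continue
        _, rev = _canonical_keys(rxn)
        for other in rev_index.get(rev, []):
            if other != rid:
                union(rid, other)

    groups: Dict[str, List[str]] = {}
    for rid in ids:
        groups.setdefault(find(rid), []).append(rid)
    order = {rid: i for i, rid in enumerate(ids)}
    return sorted((sorted(g, key=order.get) for g in groups.values() if len(g) > 1),
                  key=lambda g: order[g[0]])


# ---------------------------------------------------------------------------
# Report serialisation
# ---------------------------------------------------------------------------

def balance_report_tsv(reports: Iterable[ImbalanceReport]) -> str:
    lines = ["reaction\tstatus\telement_diffs\tcharge_diff\tsuggestion"]
    for rep in reports:
        diffs = ";".join(f"{e}:{d}" for e, d in sorted(rep.element_diff.items()))
        lines.append("\t".join([
            rep.reaction_id, rep.status, diffs or "-",
            str(rep.charge_diff) if rep.charge_diff is not None else "-",
            rep.suggestion or "-"]))
    return "\n".join(lines) + "\n"


def balance_report_json(reports: Iterable[ImbalanceReport]) -> str:
    return json.dumps([
        {"reaction": r.reaction_id, "status": r.status,
         "element_diff": {e: str(d) for e, d in sorted(r.element_diff.items())},
         "charge_diff": str(r.charge_diff) if r.charge_diff is not None else None,
         "missing_formulas": r.missing_formulas,
         "suggestion": r.suggestion}
        for r in reports], indent=2)
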