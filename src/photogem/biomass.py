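"""Biomass drain construction.

Growth is represented as a pseudo-reaction draining precursor
metabolites in fixed mmol per gram dry weight (gDW) proportions into one
unit of a virtual biomass species.  Because the coefficients are in
mmol/gDW and fluxes in mmol gDW^-1 h^-1, the flux through the drain is
the specific growth rate in h^-1.

The default composition shipped here is the experimentally grounded
precursor table for *Synechococcus elongatus* PCC7942: an aggregate
protein pool, glycogen as the carbohydrate store, antenna chromophores,
deoxy- and ribonucleotides, and five lipid classes.  The protein entry
is a drain of one aggregate pool metabolite whose synthesis from amino
acids must exist in the host model.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from fractions import Fraction
from typing import List, Optional, Tuple

import pandas as pd

from .model_core import MetabolicModel, Metabolite, ModelError, Reaction

#: Virtual product species of the drain; external so that the drain
#: closes the steady-state balance.
BIOMASS_METABOLITE = "biomass"


@dataclass
class CompositionEntry:
    metabolite_id: str
    coefficient: Fraction  # mmol per gDW
    category: Optional[str] = None


class BiomassComposition:
    """A list of (metabolite, mmol/gDW) precursor coefficients."""

    def __init__(self, entries: List[Tuple[str, object, Optional[str]]] | List[CompositionEntry]):
        self.entries: List[CompositionEntry] = []
        seen = set()
        for entry in entries:
            if not isinstance(entry, CompositionEntry):
                met, coeff, *rest = entry
                entry = CompositionEntry(met, Fraction(str(coeff)),
                                         rest[0] if rest else None)
            if entry.coefficient <= 0:
                raise ModelError(
                    f"biomass coefficient for {entry.metabolite_id!r} must be "
                    f"strictly positive, got {entry.coefficient}")
            if entry.metabolite_id in seen:
                raise ModelError(
                    f"duplicate metabolite {entry.metabolite_id!r} in composition")
            seen.add(entry.metabolite_id)
            self.entries.append(entry)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def coefficient(self, metabolite_id: str) -> Fraction:
        for e in self.entries:
            if e.metabolite_id == metabolite_id:
                return e.coefficient
        raise KeyError(metabolite_id)

    @classmethod
    def from_tsv(cls, text_or_path) -> "BiomassComposition":
        """Read a TSV with columns metabolite, mmol_per_gDW[, category]."""
        if isinstance(text_or_path, str) and "\t" in text_or_path:
            buf = io.StringIO(text_or_path)
        else:
            buf = text_or_path
        df = pd.read_csv(buf, sep="\t", dtype=str)
        cols = {c.lower(): c for c in df.columns}
        met_col = cols.get("metabolite", df.columns[0])
        coeff_col = cols.get("mmol_per_gdw", df.columns[1])
        cat_col = cols.get("category")
        return cls([
            (row[met_col], row[coeff_col],
             row[cat_col] if cat_col and pd.notna(row[cat_col]) else None)
            for _, row in df.iterrows()])

    def to_tsv(self) -> str:
        lines = ["metabolite\tmmol_per_gDW\tcategory"]
        for e in self.entries:
            lines.append(f"{e.metabolite_id}\t{float(e.coefficient):.9g}\t"
                         f"{e.category or '-'}")
        return "\n".join(lines) + "\n"


#: Precursor composition for S. elongatus PCC7942, mmol/gDW.
SYNECHOCOCCUS_COMPOSITION = BiomassComposition([
    ("protein_pool", "0.000459", "proteins"),
    ("glycogen", "0.53439", "carbohydrates"),
    ("zeaxanthin", "0.00079", "chromophores"),
    ("beta_carotene", "0.000875", "chromophores"),
    ("trans_lycopene", "0.00820225", "chromophores"),
    ("chlorophyll_a", "0.0057", "chromophores"),
    ("phycocyanobilin", "0.0285", "chromophores"),
    ("dATP", "0.0201156", "deoxyribonucleotides"),
    ("dTTP", "0.0201156", "deoxyribonucleotides"),
    ("dGTP", "0.02538445", "deoxyribonucleotides"),
    ("dCTP", "0.02538445", "deoxyribonucleotides"),
    ("AMP", "0.140389293", "ribonucleotides"),
    ("UMP", "0.140389293", "ribonucleotides"),
    ("GMP", "0.123745851", "ribonucleotides"),
    ("CMP", "0.123745851", "ribonucleotides"),
    ("lipid_14C", "0.028", "lipids"),
    ("lipid_16C", "0.0042", "lipids"),
    ("lipid_18C", "0.00448", "lipids"),
    ("lipid_16C_9Z", "0.0066", "lipids"),
    ("lipid_18C_9Z", "0.00625", "lipids"),
])


def build_biomass_reaction(
    composition: BiomassComposition,
    id: str = "biomass_drain",
    product_id: str = BIOMASS_METABOLITE,
) -> Reaction:
    """Build the irreversible drain reaction from a composition table.

    Each precursor is consumed with its mmol/gDW coefficient and one
    unit of the virtual biomass species is produced.
    """
    if len(composition) == 0:
        raise ModelError("biomass composition is empty")
    stoich = {e.metabolite_id: -e.coefficient for e in composition}
    stoich[product_id] = Fraction(1)
    return Reaction(id=id, stoichiometry=stoich, reversible=False,
                    lower_bound=0.0, name="biomass drain")


def attach_biomass_reaction(
    model: MetabolicModel,
    composition: BiomassComposition,
    id: str = "biomass_drain",
    set_objective: bool = True,
) -> Reaction:
    """Attach the drain to a model, adding the external biomass species.

    Raises :class:`ModelError` if any precursor metabolite is missing
    from the model.
    """
    for e in composition:
        if e.metabolite_id not in model.metabolites:
            raise ModelError(
                f"biomass precursor {e.metabolite_id!r} not in model")
    if BIOMASS_METABOLITE not in model.metabolites:
        model.add_metabolite(Metabolite(id=BIOMASS_METABOLITE, external=True,
                                        name="virtual biomass"))
    rxn = build_biomass_reaction(composition, id=id)
    model.add_reaction(rxn)
    if set_objective:
        model.objective_id = rxn.id
    return rxn
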