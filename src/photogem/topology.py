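"""Metabolite connectivity and the Pareto power-law fit.

Genome-scale metabolic networks are scale-free: a handful of currency
metabolites (water, ATP, phosphate, ...) participate in hundreds of
reactions while most species touch one or two.  Connectivity is
summarised as a degree per metabolite and the tail behaviour as a
power-law exponent gamma estimated from the complementary cumulative
distribution ("Pareto") fit

    P(K > k) ~ k^(-gamma + 1)

by ordinary least squares on log-log axes.  Fitting the CCDF rather
than a binned log-log histogram smooths the tail so no data are
obscured by binning.

Two degree conventions are offered: *reaction participation* (how many
reactions contain the metabolite — directly readable off the S-matrix
and the default) and *metabolite adjacency* (how many distinct other
metabolites co-occur with it in at least one reaction).  Currency
metabolites are deliberately not excluded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Tuple, Union

import numpy as np
from scipy import stats

from .model_core import MetabolicModel, ModelError

PARTICIPATION = "participation"
ADJACENCY = "adjacency"


@dataclass
class ConnectivityTable:
    """Degree k per metabolite under one of the two counting modes."""

    degree: Dict[str, int]
    mode: str

    def degrees(self) -> List[int]:
        return list(self.degree.values())

    def to_tsv(self) -> str:
        lines = ["metabolite\tdegree"]
        for met, k in sorted(self.degree.items(), key=lambda kv: (-kv[1], kv[0])):
            lines.append(f"{met}\t{k}")
        return "\n".join(lines) + "\n"


@dataclass
class PowerLawFit:
    """OLS fit of log10 CCDF against log10 k; gamma = 1 - slope."""

    gamma: float
    k_min: int
    n_points: int
    r_squared: float


def degree_distribution(
    model: MetabolicModel,
    mode: str = PARTICIPATION,
    include_external: bool = False,
) -> ConnectivityTable:
    """Count metabolite connectivity.

    In participation mode the degree of a metabolite is the number of
    reactions whose stoichiometry contains it; summed over metabolites
    this equals the total number of (metabolite, reaction) incidences.
    In adjacency mode it is the number of distinct *other* metabolites
    sharing at least one reaction.  External metabolites are excluded by
    default.
    """
    if mode not in (PARTICIPATION, ADJACENCY):
        raise ModelError(f"unknown degree mode {mode!r}")
    keep = [m for m, met in model.metabolites.items()
            if include_external or not met.external]
    keep_set = set(keep)
    if mode == PARTICIPATION:
        degree = {m: 0 for m in keep}
        for rxn in model.reactions.values():
            for met_id in rxn.stoichiometry:
                if met_id in keep_set:
                    degree[met_id] += 1
    else:
        neighbours: Dict[str, set] = {m: set() for m in keep}
        for rxn in model.reactions.values():
            participants = [m for m in rxn.stoichiometry if m in keep_set]
            for m in participants:
                neighbours[m].update(p for p in participants if p != m)
        degree = {m: len(s) for m, s in neighbours.items()}
    return ConnectivityTable(degree=degree, mode=mode)


def hub_table(table: ConnectivityTable, n: int) -> List[Tuple[str, int]]:
    """Top-n metabolites by degree; ties broken lexicographically by id."""
    if n < 1:
        raise ModelError(f"n must be >= 1, got {n}")
    ranked = sorted(table.degree.items(), key=lambda kv: (-kv[1], kv[0]))
    return ranked[:n]


def empirical_ccdf(degrees: Sequence[int], k_min: int = 1) -> Tuple[np.ndarray, np.ndarray]:
    """Strictly-greater empirical CCDF P(K > k) at each observed degree >= k_min.

    The CCDF is non-increasing in k and starts <= 1; the largest degree
    has CCDF 0 and is dropped by the fit.
    """
    d = np.asarray(degrees, dtype=float)
    d = d[d >= k_min]
    if d.size == 0:
        raise ModelError("no degrees at or above k_min")
    ks = np.unique(d)
    ccdf = np.array([(d > k).sum() for k in ks], dtype=float) / d.size
    return ks, ccdf


def fit_pareto(
    table: Union[ConnectivityTable, Sequence[int], Iterable[int]],
    k_min: int = 1,
) -> PowerLawFit:
    """Estimate the power-law exponent from the cumulative distribution.

    Ordinary least squares of log10 P(K > k) on log10 k over all
    observed degrees with k >= k_min and CCDF > 0; the slope m gives
    gamma = 1 - m.  Raises on fewer than 3 distinct positive degrees or
    a degenerate (no-spread) distribution.
    """
    degrees = table.degrees() if isinstance(table, ConnectivityTable) else list(table)
    positive = [k for k in degrees if k >= max(k_min, 1)]
    distinct = set(positive)
    if len(distinct) < 3:
        raise ModelError(
            f"power-law fit needs >= 3 distinct degrees >= k_min, got {len(distinct)}")
    ks, ccdf = empirical_ccdf(positive, k_min=max(k_min, 1))
    mask = ccdf > 0
    ks, ccdf = ks[mask], ccdf[mask]
    if len(ks) < 2:
        raise ModelError("degenerate degree distribution: no CCDF spread")
    res = stats.linregress(np.log10(ks), np.log10(ccdf))
    return PowerLawFit(gamma=float(1.0 - res.slope), k_min=max(k_min, 1),
                       n_points=int(len(ks)), r_squared=float(res.rvalue ** 2))
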