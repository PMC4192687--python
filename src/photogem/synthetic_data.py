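"""Deterministic generators for synthetic test systems.

Everything the test-suite exercises on is generated here with explicit
seeds and construction-time bookkeeping, so every expected value is an
oracle independent of the LP engine:

* toy phototroph models (photon capture -> ATP -> carbon fixation ->
  biomass drain) whose optimal growth and minimal photon demand follow
  from stoichiometric accounting at construction;
* random small flux models for cross-checking the LP solver against
  brute-force vertex enumeration;
* integer degree samples from a discrete (zeta-normalised) power law
  for exponent-recovery tests of the Pareto fit;
* deliberately broken models, each with exactly one planted defect
  (element imbalance, duplicated reaction, or internal loop) for the
  curation audits.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.special import zeta

from .model_core import DEFAULT_BOUND, MetabolicModel, Metabolite, ModelError, Reaction


# ---------------------------------------------------------------------------
# Toy phototrophs
# ---------------------------------------------------------------------------

@dataclass
class PhototrophSpec:
    """Parameters of the generated toy phototroph.

    n_intermediates: length of the carbon-fixation chain.
    photons_per_atp: photons consumed per ATP produced.
    atp_per_fixation: ATP consumed per carbon fixed.
    carbon_bound: upper bound of the carbon exchange, mmol gDW^-1 h^-1.
    split_photosystems: model light capture as a two-photosystem
        Z-scheme (each ATP then needs photons_per_atp photons on *each*
        photosystem) instead of one lumped light reaction.
    """

    n_intermediates: int = 1
    photons_per_atp: int = 1
    atp_per_fixation: int = 3
    carbon_bound: float = 2.0
    seed: int = 0
    split_photosystems: bool = False

    def __post_init__(self) -> None:
        if min(self.n_intermediates, self.photons_per_atp, self.atp_per_fixation) < 1:
            raise ModelError("all counts must be >= 1")
        if self.carbon_bound <= 0:
            raise ModelError("carbon_bound must be positive")


#: Reaction ids of the generated phototroph, fixed by contract.
PHOTON_EXCHANGE = "EX_photon"
PHOTON_EXCHANGE_PSII = "EX_photon_psII"
PHOTON_EXCHANGE_PSI = "EX_photon_psI"
CARBON_EXCHANGE = "EX_carbon"
BIOMASS_DRAIN = "growth"


def make_toy_phototroph(spec: PhototrophSpec) -> Tuple[MetabolicModel, float, float]:
    """Generate a minimal phototroph and its closed-form optima.

    Returns ``(model, expected_growth, expected_min_photons)``.  Every
    fixed carbon traverses the intermediate chain into one biomass unit,
    so expected_growth = carbon_bound; each fixation burns
    atp_per_fixation ATP at photons_per_atp photons apiece (times two
    photosystems in split mode), so expected_min_photons =
    carbon_bound * atp_per_fixation * photons_per_atp * (2 if split).
    Both numbers come from this construction-time accounting, not from
    any solver.  The seed only shuffles reaction insertion order.
    """
    p = Fraction(spec.photons_per_atp)
    a = Fraction(spec.atp_per_fixation)

    mets = [Metabolite("photon_ext", external=True),
            Metabolite("co2_ext", external=True),
            Metabolite("biomass_ext", external=True),
            Metabolite("co2"), Metabolite("atp")]
    rxns: List[Reaction] = []

    if spec.split_photosystems:
        mets += [Metabolite("photon_psII"), Metabolite("photon_psI"),
                 Metabolite("plastoquinol")]
        rxns += [
            Reaction(PHOTON_EXCHANGE_PSII,
                     {"photon_ext": Fraction(-1), "photon_psII": Fraction(1)}),
            Reaction(PHOTON_EXCHANGE_PSI,
                     {"photon_ext": Fraction(-1), "photon_psI": Fraction(1)}),
            Reaction("PSII", {"photon_psII": -p, "plastoquinol": Fraction(1)}),
            Reaction("PSI", {"photon_psI": -p, "plastoquinol": Fraction(-1),
                             "atp": Fraction(1)}),
        ]
        photons_per_atp_total = 2 * p
    else:
        mets.append(Metabolite("photon"))
        rxns += [
            Reaction(PHOTON_EXCHANGE,
                     {"photon_ext": Fraction(-1), "photon": Fraction(1)}),
            Reaction("light_atp", {"photon": -p, "atp": Fraction(1)}),
        ]
        photons_per_atp_total = p

    rxns.append(Reaction(CARBON_EXCHANGE,
                         {"co2_ext": Fraction(-1), "co2": Fraction(1)},
                         upper_bound=spec.carbon_bound))
    chain = [f"C{i}" for i in range(1, spec.n_intermediates + 1)]
    for name in chain:
        mets.append(Metabolite(name))
    rxns.append(Reaction("fixation", {"co2": Fraction(-1), "atp": -a,
                                      chain[0]: Fraction(1)}))
    for i in range(len(chain) - 1):
        rxns.append(Reaction(f"chain_{i + 1}",
                             {chain[i]: Fraction(-1), chain[i + 1]: Fraction(1)}))
    rxns.append(Reaction(BIOMASS_DRAIN,
                         {chain[-1]: Fraction(-1), "biomass_ext": Fraction(1)}))

    rng = np.random.default_rng(spec.seed)
    order = rng.permutation(len(rxns))
    model = MetabolicModel(metabolites=mets, reactions=[rxns[i] for i in order],
                           objective_id=BIOMASS_DRAIN, id="toy_phototroph")
    model.validate()
    expected_growth = float(spec.carbon_bound)
    expected_min_photons = float(
        Fraction(str(spec.carbon_bound)) * a * photons_per_atp_total)
    return model, expected_growth, expected_min_photons


def photon_reactions_of(model: MetabolicModel) -> List[str]:
    """Photon exchange reaction ids of a generated phototroph."""
    return [rid for rid in (PHOTON_EXCHANGE, PHOTON_EXCHANGE_PSII,
                            PHOTON_EXCHANGE_PSI) if rid in model.reactions]


# ---------------------------------------------------------------------------
# Random small flux models for the LP oracle
# ---------------------------------------------------------------------------

def make_random_lp_model(
    seed: int,
    max_reactions: int = 8,
    max_metabolites: int = 5,
) -> MetabolicModel:
    """A small random stoichiometric model with finite bounds.

    Coefficients are small integers, all bounds are finite (so the flux
    polytope is bounded and vertex enumeration terminates) and most
    bounds straddle zero so that v = 0 is usually feasible; occasionally
    a strictly positive lower bound is planted to exercise infeasible
    instances.
    """
    rng = np.random.default_rng(seed)
    n_rxn = int(rng.integers(2, max_reactions + 1))
    n_met = int(rng.integers(2, max_metabolites + 1))
    met_ids = [f"M{i}" for i in range(n_met)]
    mets = [Metabolite(m, external=(i == 0 and rng.random() < 0.3))
            for i, m in enumerate(met_ids)]
    rxns = []
    for j in range(n_rxn):
        k = int(rng.integers(1, min(3, n_met) + 1))
        chosen = rng.choice(n_met, size=k, replace=False)
        stoich = {}
        for m in chosen:
            c = int(rng.integers(-3, 4))
            if c != 0:
                stoich[met_ids[m]] = Fraction(c)
        if not stoich:
            stoich = {met_ids[int(chosen[0])]: Fraction(1)}
        if rng.random() < 0.1:
            lb = float(rng.integers(1, 3))
            ub = lb + float(rng.integers(0, 5))
        else:
            lb = -float(rng.integers(0, 8))
            ub = float(rng.integers(0, 8))
        rxns.append(Reaction(f"R{j}", stoich, reversible=lb < 0,
                             lower_bound=lb, upper_bound=ub))
    objective = f"R{int(rng.integers(0, n_rxn))}"
    return MetabolicModel(metabolites=mets, reactions=rxns,
                          objective_id=objective, id=f"random_{seed}")


# ---------------------------------------------------------------------------
# Discrete power-law sampler
# ---------------------------------------------------------------------------

def sample_powerlaw_degrees(
    gamma: float, k_min: int, n: int, seed: int
) -> np.ndarray:
    """Draw n integers >= k_min from a discrete power law P(k) ~ k^-gamma.

    Inverse-CDF sampling on the zeta-normalised mass function
    P(k) = k^-gamma / zeta(gamma, k_min); CDF values are tabulated up to
    k = 1e5 and the (astronomically rare) deeper tail is resolved by
    bisection on the Hurwitz-zeta CCDF.  Deterministic for a fixed seed.
    """
    if gamma <= 1:
        raise ModelError("gamma must exceed 1")
    if k_min < 1 or n < 1:
        raise ModelError("k_min and n must be >= 1")
    rng = np.random.default_rng(seed)
    u = rng.random(n)
    k_max = 100_000
    ks = np.arange(k_min, k_max + 1)
    norm = zeta(gamma, k_min)
    cdf = 1.0 - zeta(gamma, ks + 1) / norm
    idx = np.searchsorted(cdf, u, side="left")
    out = ks[np.minimum(idx, len(ks) - 1)].astype(np.int64)
    deep = u > cdf[-1]
    for i in np.flatnonzero(deep):
        lo, hi = k_max, k_max
        while 1.0 - zeta(gamma, hi + 1) / norm < u[i]:
            lo, hi = hi, hi * 4
        while lo < hi:
            mid = (lo + hi) // 2
            if 1.0 - zeta(gamma, mid + 1) / norm >= u[i]:
                hi = mid
            else:
                lo = mid + 1
        out[i] = lo
    return out


def powerlaw_mean(gamma: float, k_min: int = 1) -> float:
    """Analytic mean zeta(gamma-1, k_min) / zeta(gamma, k_min) (gamma > 2)."""
    if gamma <= 2:
        raise ModelError("mean finite only for gamma > 2")
    return float(zeta(gamma - 1, k_min) / zeta(gamma, k_min))


# ---------------------------------------------------------------------------
# Broken models with planted defects
# ---------------------------------------------------------------------------

UNBALANCED = "unbalanced"
DUPLICATE = "duplicate"
LOOPED = "looped"


def _clean_chain(rng: np.random.Generator) -> Tuple[List[Metabolite], List[Reaction]]:
    """A defect-free linear pathway with uptake and secretion exchanges.

    All metabolites share the formula CH2O, every chain step is 1:1, so
    every reaction is balanced; closed exchanges force zero flux
    everywhere (no loops); all stoichiometries are distinct.
    """
    n = int(rng.integers(4, 9))
    formula = {"C": 1, "H": 2, "O": 1}
    mets = [Metabolite("S_ext", external=True, formula=dict(formula)),
            Metabolite("P_ext", external=True, formula=dict(formula))]
    chain = [f"M{i}" for i in range(n)]
    mets += [Metabolite(m, formula=dict(formula)) for m in chain]
    rxns = [Reaction("uptake", {"S_ext": Fraction(-1), chain[0]: Fraction(1)})]
    for i in range(n - 1):
        rxns.append(Reaction(f"step{i}", {chain[i]: Fraction(-1),
                                          chain[i + 1]: Fraction(1)}))
    rxns.append(Reaction("secretion", {chain[-1]: Fraction(-1),
                                       "P_ext": Fraction(1)}))
    return mets, rxns


def make_broken_model(kind: str, seed: int = 0) -> Tuple[MetabolicModel, Dict[str, object]]:
    """A model with exactly one planted defect of the named kind.

    Returns the model and a defect descriptor: for ``unbalanced`` the
    offending reaction id, for ``duplicate`` the planted id pair, for
    ``looped`` the ids of the planted cycle.
    """
    rng = np.random.default_rng(seed)
    mets, rxns = _clean_chain(rng)
    info: Dict[str, object]

    if kind == UNBALANCED:
        mets += [Metabolite("U", formula={"C": 2, "H": 4, "O": 2}),
                 Metabolite("V", formula={"C": 1, "H": 2, "O": 1}),
                 Metabolite("U_ext", external=True, formula={"C": 2, "H": 4, "O": 2}),
                 Metabolite("V_ext", external=True, formula={"C": 1, "H": 2, "O": 1})]
        # U -> V silently loses CH2O: imbalance C -1, H -2, O -1
        rxns.insert(int(rng.integers(0, len(rxns) + 1)),
                    Reaction("lossy", {"U": Fraction(-1), "V": Fraction(1)}))
        rxns.append(Reaction("EX_U", {"U_ext": Fraction(-1), "U": Fraction(1)}))
        rxns.append(Reaction("EX_V", {"V": Fraction(-1), "V_ext": Fraction(1)}))
        info = {"reaction": "lossy",
                "imbalance": {"C": Fraction(-1), "H": Fraction(-2), "O": Fraction(-1)}}
    elif kind == DUPLICATE:
        victim = rxns[int(rng.integers(1, len(rxns) - 1))]
        dup = Reaction("shadow", dict(victim.stoichiometry))
        rxns.insert(int(rng.integers(0, len(rxns) + 1)), dup)
        info = {"pair": (victim.id, "shadow")}
    elif kind == LOOPED:
        cycle_mets = ["L0", "L1", "L2"]
        formula = {"C": 1, "H": 2, "O": 1}
        mets += [Metabolite(m, formula=dict(formula)) for m in cycle_mets]
        cycle_ids = []
        for i in range(3):
            rid = f"cycle{i}"
            cycle_ids.append(rid)
            rxns.insert(int(rng.integers(0, len(rxns) + 1)), Reaction(
                rid, {cycle_mets[i]: Fraction(-1),
                      cycle_mets[(i + 1) % 3]: Fraction(1)},
                reversible=True, lower_bound=-DEFAULT_BOUND))
        # tether the cycle so its members are reachable, without new loops
        rxns.append(Reaction("tether", {"M0": Fraction(-1), "L0": Fraction(1)}))
        rxns.append(Reaction("EX_L", {"L2": Fraction(-1)}))
        info = {"cycle": tuple(cycle_ids)}
    else:
        raise ModelError(f"unknown defect kind {kind!r}")

    model = MetabolicModel(metabolites=mets, reactions=rxns, id=f"broken_{kind}_{seed}")
    model.validate()
    return model, info
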