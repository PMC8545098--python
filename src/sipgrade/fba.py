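"""Critical-reaction auxotrophy calling by flux balance analysis.

A compound's biosynthesis is probed by counting its *critical*
reactions: reactions that (i) are not part of central carbon metabolism,
(ii) are essential under the minimal medium but not under the rich
medium (the rich medium supplies every biomass precursor by exchange, so
biosynthetic routes only matter when the compound must be made), and
(iii) are flux-coupled to the compound's production.  A genome is
auxotrophic for a compound when its critical-reaction count falls below
a compound-specific threshold θ, or when the number of gap-filled
critical reactions exceeds a threshold γ.

FBA itself is an ordinary steady-state LP (maximize biomass flux subject
to S·v = 0 and flux bounds), solved with HiGHS via scipy.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog

logger = logging.getLogger(__name__)

COUPLING_TOL = 1e-6
DEFAULT_GROWTH_CUTOFF = 0.01
DEFAULT_DEMAND = 0.1


class ModelError(ValueError):
    pass


@dataclass
class ToyMetabolicModel:
    """Stoichiometric model with media, gap-fill and central-carbon flags."""

    id: str
    compound_ids: list[str]
    reaction_ids: list[str]
    stoichiometry: np.ndarray  # compounds x reactions
    lower_bounds: np.ndarray
    upper_bounds: np.ndarray
    gapfilled: dict[str, bool]
    central_carbon: dict[str, bool]
    biomass_reaction: str
    exchange_reactions: list[str]
    media: dict[str, dict[str, tuple[float, float]]]
    target_compounds: list[str]

    _rxn_index: dict[str, int] = field(default_factory=dict, repr=False)
    _cpd_index: dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._rxn_index = {r: i for i, r in enumerate(self.reaction_ids)}
        self._cpd_index = {c: i for i, c in enumerate(self.compound_ids)}
        if self.biomass_reaction not in self._rxn_index:
            raise ModelError(f"biomass reaction '{self.biomass_reaction}' not in model")
        for name in ("rich", "minimal"):
            if name not in self.media:
                raise ModelError(f"medium '{name}' not defined")
        if np.any(self.lower_bounds > self.upper_bounds):
            raise ModelError("lower bound exceeds upper bound")

    @classmethod
    def from_dict(cls, d: dict) -> "ToyMetabolicModel":
        compounds = [c["id"] for c in d["compounds"]]
        cidx = {c: i for i, c in enumerate(compounds)}
        reactions = d["reactions"]
        rids = [r["id"] for r in reactions]
        s = np.zeros((len(compounds), len(reactions)))
        lb = np.zeros(len(reactions))
        ub = np.zeros(len(reactions))
        gap, central = {}, {}
        for j, r in enumerate(reactions):
            for cpd, coeff in r["stoichiometry"].items():
                if cpd not in cidx:
                    raise ModelError(f"reaction {r['id']} references unknown compound {cpd}")
                s[cidx[cpd], j] = coeff
            lb[j] = r.get("lower_bound", 0)
            ub[j] = r.get("upper_bound", 1000)
            gap[r["id"]] = bool(r.get("gapfilled", False))
            central[r["id"]] = bool(r.get("central_carbon", False))
        media = {
            name: {rx: (b[0], b[1]) for rx, b in med.items()}
            for name, med in d["media"].items()
        }
        return cls(
            id=d.get("id", "model"),
            compound_ids=compounds,
            reaction_ids=rids,
            stoichiometry=s,
            lower_bounds=lb,
            upper_bounds=ub,
            gapfilled=gap,
            central_carbon=central,
            biomass_reaction=d["biomass_reaction"],
            exchange_reactions=list(d.get("exchange_reactions", [])),
            media=media,
            target_compounds=list(d.get("target_compounds", [])),
        )

    @classmethod
    def from_json(cls, path) -> "ToyMetabolicModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def bounds_for(self, medium: str) -> tuple[np.ndarray, np.ndarray]:
        if medium not in self.media:
            raise ModelError(f"unknown medium '{medium}'")
        lb = self.lower_bounds.copy()
        ub = self.upper_bounds.copy()
        for rx, (lo, hi) in self.media[medium].items():
            j = self._rxn_index[rx]
            lb[j], ub[j] = lo, hi
        return lb, ub


@dataclass
class FbaResult:
    feasible: bool
    objective: float | None
    fluxes: np.ndarray | None


def _solve(
    s: np.ndarray, lb: np.ndarray, ub: np.ndarray, c: np.ndarray, maximize: bool
) -> FbaResult:
    res = linprog(
        -c if maximize else c,
        A_eq=s,
        b_eq=np.zeros(s.shape[0]),
        bounds=list(zip(lb, ub)),
        method="highs",
    )
    if not res.success:
        return FbaResult(feasible=False, objective=None, fluxes=None)
    obj = -res.fun if maximize else res.fun
    return FbaResult(feasible=True, objective=float(obj), fluxes=res.x)


def fba(
    model: ToyMetabolicModel,
    medium: str,
    objective: str | None = None,
    fixed: dict[str, tuple[float, float]] | None = None,
) -> FbaResult:
    """Maximize the objective reaction's flux at steady state.

    Infeasibility is reported in the result, not raised.  ``fixed``
    overrides individual reaction bounds (used for knockouts).
    """
    objective = objective or model.biomass_reaction
    lb, ub = model.bounds_for(medium)
    if fixed:
        for rx, (lo, hi) in fixed.items():
            j = model._rxn_index[rx]
            lb[j], ub[j] = lo, hi
    c = np.zeros(len(model.reaction_ids))
    c[model._rxn_index[objective]] = 1.0
    return _solve(model.stoichiometry, lb, ub, c, maximize=True)


def essential_reactions(
    model: ToyMetabolicModel,
    medium: str,
    growth_cutoff: float = DEFAULT_GROWTH_CUTOFF,
) -> set[str]:
    """Reactions whose knockout drops growth below growth_cutoff × wild type."""
    wt = fba(model, medium)
    if not wt.feasible or wt.objective is None or wt.objective <= 0:
        raise ModelError(f"no wild-type growth under medium '{medium}'")
    threshold = growth_cutoff * wt.objective
    essential = set()
    for rx in model.reaction_ids:
        ko = fba(model, medium, fixed={rx: (0.0, 0.0)})
        if not ko.feasible or ko.objective < threshold:
            essential.add(rx)
    return essential


def coupled_to_compound(
    model: ToyMetabolicModel,
    reaction: str,
    compound: str,
    medium: str = "minimal",
    demand: float = DEFAULT_DEMAND,
    tol: float = COUPLING_TOL,
) -> bool:
    """Is the reaction's flux coupled to production of the compound?

    With the biomass objective disabled (its flux fixed to 0) and a
    demand flux for the compound fixed at ≥ ``demand``, the reaction is
    coupled iff the feasible flux interval [min v, max v] excludes 0
    beyond tolerance (two LPs).  An infeasible demand means the compound
    is unproducible; that is logged and reported as not coupled.
    """
    if compound not in model._cpd_index:
        raise ModelError(f"unknown compound '{compound}'")
    lb, ub = model.bounds_for(medium)
    jb = model._rxn_index[model.biomass_reaction]
    lb[jb], ub[jb] = 0.0, 0.0
    # append a demand reaction consuming the compound
    dcol = np.zeros((len(model.compound_ids), 1))
    dcol[model._cpd_index[compound], 0] = -1.0
    s = np.hstack([model.stoichiometry, dcol])
    lb = np.append(lb, demand)
    ub = np.append(ub, np.inf)
    c = np.zeros(s.shape[1])
    c[model._rxn_index[reaction]] = 1.0
    lo = _solve(s, lb, ub, c, maximize=False)
    if not lo.feasible:
        logger.info("demand for %s infeasible in %s; not coupled", compound, model.id)
        return False
    hi = _solve(s, lb, ub, c, maximize=True)
    return lo.objective > tol or hi.objective < -tol


def critical_reactions(
    model: ToyMetabolicModel,
    compound: str,
    growth_cutoff: float = DEFAULT_GROWTH_CUTOFF,
    demand: float = DEFAULT_DEMAND,
    _essential_minimal: set[str] | None = None,
    _essential_rich: set[str] | None = None,
) -> set[str]:
    """Critical reactions for a compound's biosynthesis.

    r is critical iff it is not central-carbon, essential under the
    minimal medium only (not under rich), and flux-coupled to the
    compound's production.  Precomputed essential sets may be passed to
    avoid repeating knockouts across compounds.
    """
    ess_min = (
        _essential_minimal
        if _essential_minimal is not None
        else essential_reactions(model, "minimal", growth_cutoff)
    )
    ess_rich = (
        _essential_rich
        if _essential_rich is not None
        else essential_reactions(model, "rich", growth_cutoff)
    )
    candidates = {
        r for r in ess_min - ess_rich if not model.central_carbon.get(r, False)
    }
    return {
        r for r in candidates if coupled_to_compound(model, r, compound, demand=demand)
    }


@dataclass
class AuxotrophyProfile:
    """Per-compound critical-reaction counts and auxotrophy calls."""

    model_id: str
    n_critical: dict[str, int]
    n_gapfilled_critical: dict[str, int]
    auxotrophic: dict[str, bool]

    @property
    def prototrophy_count(self) -> int:
        return sum(not a for a in self.auxotrophic.values())

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "compound": list(self.auxotrophic),
                "n_critical": [self.n_critical[c] for c in self.auxotrophic],
                "n_gapfilled": [self.n_gapfilled_critical[c] for c in self.auxotrophic],
                "auxotrophic": list(self.auxotrophic.values()),
            }
        )


def call_auxotrophy(
    model: ToyMetabolicModel,
    theta: dict[str, int] | int = 1,
    gamma: dict[str, int] | int = 0,
    growth_cutoff: float = DEFAULT_GROWTH_CUTOFF,
    demand: float = DEFAULT_DEMAND,
) -> AuxotrophyProfile:
    """Auxotrophy profile over the model's target compounds.

    auxotrophic(c) iff n_critical(c) < θ(c) or n_gapfilled_critical(c) > γ(c).
    θ and γ may be single defaults or per-compound mappings.
    """
    def thr(val, cpd, default):
        if isinstance(val, dict):
            return val.get(cpd, default)
        return val

    ess_min = essential_reactions(model, "minimal", growth_cutoff)
    ess_rich = essential_reactions(model, "rich", growth_cutoff)
    n_crit, n_gap, calls = {}, {}, {}
    for cpd in model.target_compounds:
        crit = critical_reactions(
            model, cpd, growth_cutoff, demand,
            _essential_minimal=ess_min, _essential_rich=ess_rich,
        )
        n_crit[cpd] = len(crit)
        n_gap[cpd] = sum(model.gapfilled.get(r, False) for r in crit)
        t = thr(theta, cpd, 1)
        g = thr(gamma, cpd, 0)
        calls[cpd] = n_crit[cpd] < t or n_gap[cpd] > g
    return AuxotrophyProfile(
        model_id=model.id, n_critical=n_crit, n_gapfilled_critical=n_gap, auxotrophic=calls
    )


def prototrophy_count(profile: AuxotrophyProfile) -> int:
    """Number of pathways detected, out of the evaluated targets (≤ 32)."""
    return profile.prototrophy_count
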