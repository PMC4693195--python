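"""Stoichiometric model containers, readers/writers and flux balance analysis.

The in-memory representation is intentionally small: metabolites, reactions
with signed stoichiometry and flux bounds, and two named reaction roles —
the growth (biomass) reaction and the target (product-forming) reaction.
Flux balance analysis is posed as the linear program

    opt  v_obj   s.t.   S v = 0,   lb <= v <= ub

over the stoichiometric matrix S (metabolites x reactions), solved through
the backend in :mod:`lycoscreen.lp`.

Sign convention: exchange (boundary) reactions are written ``metabolite → ∅``,
so a negative flux means uptake from the medium and a positive flux means
secretion.

Model files are read and written in two formats: SBML Level 3 (delegated to
cobrapy, which handles the fbc flux-bound semantics) and a small documented
JSON dialect that additionally carries the growth/target reaction roles.
"""

from __future__ import annotations

import copy as _copy
import json
import math
from dataclasses import dataclass

import numpy as np

from . import formula as _formula
from .errors import (
    BoundError,
    FormatError,
    IntegrityError,
    RoleError,
)
from .lp import LPResult, solve_lp

#: default bounds when a file omits them
DEFAULT_BOUND = 1000.0

#: |flux| below this is reported as zero in outputs — magnitudes of that
#: order are solver rounding noise, not biology
NUMERICAL_ZERO = 1e-9


@dataclass
class Metabolite:
    id: str
    name: str = ""
    compartment: str = ""
    formula: dict[str, int] | None = None


@dataclass
class Reaction:
    id: str
    stoichiometry: dict[str, float]
    name: str = ""
    lower_bound: float = -DEFAULT_BOUND
    upper_bound: float = DEFAULT_BOUND

    def __post_init__(self) -> None:
        if not self.stoichiometry:
            raise IntegrityError(f"reaction {self.id!r} has empty stoichiometry")
        if self.lower_bound > self.upper_bound:
            raise BoundError(
                f"reaction {self.id!r}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}"
            )

    @property
    def is_exchange(self) -> bool:
        """True iff exactly one metabolite participates (boundary reaction)."""
        return sum(1 for c in self.stoichiometry.values() if c != 0) == 1


@dataclass
class MetabolicModel:
    metabolites: list[Metabolite]
    reactions: list[Reaction]
    growth_reaction_id: str
    target_reaction_id: str
    name: str = ""

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        met_ids = [m.id for m in self.metabolites]
        if len(set(met_ids)) != len(met_ids):
            raise IntegrityError(f"duplicate metabolite ids in model {self.name!r}")
        rxn_ids = [r.id for r in self.reactions]
        if len(set(rxn_ids)) != len(rxn_ids):
            raise IntegrityError(f"duplicate reaction ids in model {self.name!r}")
        known = set(met_ids)
        for r in self.reactions:
            missing = set(r.stoichiometry) - known
            if missing:
                raise IntegrityError(
                    f"reaction {r.id!r} references unknown metabolites: "
                    f"{sorted(missing)}"
                )
        for role, rid in (
            ("growth", self.growth_reaction_id),
            ("target", self.target_reaction_id),
        ):
            if rid not in set(rxn_ids):
                raise IntegrityError(
                    f"{role} reaction {rid!r} not present in model {self.name!r}"
                )

    def reaction(self, reaction_id: str) -> Reaction:
        for r in self.reactions:
            if r.id == reaction_id:
                return r
        raise IntegrityError(f"no reaction {reaction_id!r} in model {self.name!r}")

    def metabolite(self, metabolite_id: str) -> Metabolite:
        for m in self.metabolites:
            if m.id == metabolite_id:
                return m
        raise IntegrityError(f"no metabolite {metabolite_id!r} in model {self.name!r}")

    def stoichiometric_matrix(self) -> tuple[np.ndarray, list[str], list[str]]:
        """Dense S plus its row (metabolite) and column (reaction) id orders."""
        met_ids = [m.id for m in self.metabolites]
        rxn_ids = [r.id for r in self.reactions]
        row = {mid: i for i, mid in enumerate(met_ids)}
        s = np.zeros((len(met_ids), len(rxn_ids)))
        for j, r in enumerate(self.reactions):
            for mid, coeff in r.stoichiometry.items():
                s[row[mid], j] = coeff
        return s, met_ids, rxn_ids

    def copy(self) -> "MetabolicModel":
        return _copy.deepcopy(self)


@dataclass
class FBASolution:
    status: str                        # "optimal" | "infeasible" | "unbounded"
    objective_value: float | None
    fluxes: dict[str, float]           # empty unless optimal
    objective_reaction_id: str
    direction: str                     # "maximize" | "minimize"


def find_exchange_reactions(model: MetabolicModel) -> list[str]:
    """Ids of all boundary reactions (single participating metabolite), sorted."""
    return sorted(r.id for r in model.reactions if r.is_exchange)


def fba(
    model: MetabolicModel,
    objective_reaction_id: str | None = None,
    direction: str = "maximize",
) -> FBASolution:
    """Flux balance analysis: optimize one reaction flux at steady state.

    Defaults to maximizing the model's growth reaction. Fluxes smaller in
    magnitude than NUMERICAL_ZERO are reported as exactly zero. Alternate
    optima are possible; only the objective value is unique.
    """
    if objective_reaction_id is None:
        objective_reaction_id = model.growth_reaction_id
    if direction not in ("maximize", "minimize"):
        raise ValueError(f"direction must be maximize|minimize, got {direction!r}")
    model.reaction(objective_reaction_id)  # raises IntegrityError if absent

    s, _, rxn_ids = model.stoichiometric_matrix()
    n = len(rxn_ids)
    c = np.zeros(n)
    c[rxn_ids.index(objective_reaction_id)] = 1.0
    bounds = [(r.lower_bound, r.upper_bound) for r in model.reactions]
    res: LPResult = solve_lp(
        c, s, np.zeros(s.shape[0]), bounds,
        sense="max" if direction == "maximize" else "min",
    )
    if res.status != "optimal":
        return FBASolution(res.status, None, {}, objective_reaction_id, direction)
    fluxes = {
        rid: (0.0 if abs(v) < NUMERICAL_ZERO else float(v))
        for rid, v in zip(rxn_ids, res.x)
    }
    return FBASolution(
        "optimal",
        fluxes[objective_reaction_id],
        fluxes,
        objective_reaction_id,
        direction,
    )


def set_exchange_bound(
    model: MetabolicModel, reaction_id: str, lower_bound: float
) -> MetabolicModel:
    """Return a copy of ``model`` with the exchange's lower bound replaced.

    The input model is never mutated — screening loops relax one exchange at
    a time against a shared base model.
    """
    rxn = model.reaction(reaction_id)
    if not rxn.is_exchange:
        raise RoleError(f"reaction {reaction_id!r} is not an exchange reaction")
    if lower_bound > rxn.upper_bound:
        raise BoundError(
            f"new lower bound {lower_bound} exceeds upper bound "
            f"{rxn.upper_bound} on {reaction_id!r}"
        )
    new = model.copy()
    new.reaction(reaction_id).lower_bound = float(lower_bound)
    return new


def flux_variability(
    model: MetabolicModel,
    reaction_ids: list[str] | None = None,
    objective_fraction: float = 1.0,
) -> dict[str, tuple[float, float]]:
    """Optional cross-check: flux ranges with growth held at a fraction of max.

    Not part of the screening procedure itself; useful for inspecting
    alternate optima.
    """
    base = fba(model)
    if base.status != "optimal":
        raise IntegrityError("model is infeasible; cannot run variability analysis")
    fixed = objective_fraction * base.objective_value
    pinned = model.copy()
    g = pinned.reaction(model.growth_reaction_id)
    g.lower_bound = g.upper_bound = fixed
    out: dict[str, tuple[float, float]] = {}
    for rid in reaction_ids or [r.id for r in model.reactions]:
        lo = fba(pinned, rid, "minimize")
        hi = fba(pinned, rid, "maximize")
        out[rid] = (lo.objective_value, hi.objective_value)
    return out


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_model(
    path: str,
    fmt: str | None = None,
    growth_reaction_id: str | None = None,
    target_reaction_id: str | None = None,
) -> MetabolicModel:
    """Read a model from ``path`` in ``fmt`` ("sbml" or "json").

    The format is inferred from the suffix when not given. The JSON dialect
    carries the growth/target roles in the file; for SBML they must be passed
    as arguments (the growth reaction falls back to the file's fbc objective
    when one is declared).
    """
    if fmt is None:
        fmt = "json" if str(path).endswith(".json") else "sbml"
    if fmt == "json":
        return _read_json(path, growth_reaction_id, target_reaction_id)
    if fmt == "sbml":
        return _read_sbml(path, growth_reaction_id, target_reaction_id)
    raise FormatError(f"unknown model format {fmt!r}")


def write_model(model: MetabolicModel, path: str, fmt: str | None = None) -> None:
    if fmt is None:
        fmt = "json" if str(path).endswith(".json") else "sbml"
    if fmt == "json":
        _write_json(model, path)
    elif fmt == "sbml":
        _write_sbml(model, path)
    else:
        raise FormatError(f"unknown model format {fmt!r}")


def _read_json(
    path: str, growth_id: str | None, target_id: str | None
) -> MetabolicModel:
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise FormatError(f"{path}: not valid JSON ({exc})") from exc
    try:
        mets = [
            Metabolite(
                id=m["id"],
                name=m.get("name", ""),
                compartment=m.get("compartment", ""),
                formula=(
                    _formula.parse_formula(m["formula"])
                    if isinstance(m.get("formula"), str)
                    else m.get("formula")
                ),
            )
            for m in doc["metabolites"]
        ]
        rxns = []
        for r in doc["reactions"]:
            reversible = r.get("reversible", True)
            lb = r.get("lower_bound", -DEFAULT_BOUND if reversible else 0.0)
            ub = r.get("upper_bound", DEFAULT_BOUND)
            rxns.append(
                Reaction(
                    id=r["id"],
                    name=r.get("name", ""),
                    stoichiometry={k: float(v) for k, v in r["metabolites"].items()},
                    lower_bound=float(lb),
                    upper_bound=float(ub),
                )
            )
    except KeyError as exc:
        raise FormatError(f"{path}: missing required element {exc}") from exc
    return MetabolicModel(
        metabolites=mets,
        reactions=rxns,
        growth_reaction_id=growth_id or doc.get("growth_reaction", ""),
        target_reaction_id=target_id or doc.get("target_reaction", ""),
        name=doc.get("name", ""),
    )


def _write_json(model: MetabolicModel, path: str) -> None:
    doc = {
        "name": model.name,
        "growth_reaction": model.growth_reaction_id,
        "target_reaction": model.target_reaction_id,
        "metabolites": [
            {
                "id": m.id,
                "name": m.name,
                "compartment": m.compartment,
                "formula": _formula.format_formula(m.formula) if m.formula else None,
            }
            for m in model.metabolites
        ],
        "reactions": [
            {
                "id": r.id,
                "name": r.name,
                "metabolites": r.stoichiometry,
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
            }
            for r in model.reactions
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=False)
        fh.write("\n")


def _read_sbml(
    path: str, growth_id: str | None, target_id: str | None
) -> MetabolicModel:
    import cobra.io

    try:
        cm = cobra.io.read_sbml_model(str(path))
    except Exception as exc:  # cobra raises a mix of types on bad files
        raise FormatError(f"{path}: SBML parse failure ({exc})") from exc
    mets = [
        Metabolite(
            id=m.id,
            name=m.name or "",
            compartment=m.compartment or "",
            formula=_formula.parse_formula(m.formula) if m.formula else None,
        )
        for m in cm.metabolites
    ]
    rxns = [
        Reaction(
            id=r.id,
            name=r.name or "",
            stoichiometry={m.id: float(c) for m, c in r.metabolites.items()},
            lower_bound=float(r.lower_bound),
            upper_bound=float(r.upper_bound),
        )
        for r in cm.reactions
    ]
    if growth_id is None:
        # fall back to the fbc objective when the file declares one
        obj = [v.name for v in cm.objective.variables]
        growth_id = obj[0] if obj else ""
    return MetabolicModel(
        metabolites=mets,
        reactions=rxns,
        growth_reaction_id=growth_id,
        target_reaction_id=target_id or "",
        name=cm.id or "",
    )


def _write_sbml(model: MetabolicModel, path: str) -> None:
    import cobra

    cm = cobra.Model(model.name or "model")
    cmets = {
        m.id: cobra.Metabolite(
            m.id,
            name=m.name,
            compartment=m.compartment or "c",
            formula=_formula.format_formula(m.formula) if m.formula else None,
        )
        for m in model.metabolites
    }
    crxns = []
    for r in model.reactions:
        cr = cobra.Reaction(r.id, name=r.name)
        cr.add_metabolites({cmets[mid]: c for mid, c in r.stoichiometry.items()})
        cr.bounds = (r.lower_bound, r.upper_bound)
        crxns.append(cr)
    cm.add_reactions(crxns)
    if model.growth_reaction_id:
        cm.objective = model.growth_reaction_id
    cobra.io.write_sbml_model(cm, str(path))


def write_flux_report(
    solution: FBASolution, model: MetabolicModel, path: str
) -> None:
    """Tab-separated flux report: reaction_id, name, flux, lower/upper bound."""
    with open(path, "w") as fh:
        fh.write("reaction_id\tname\tflux\tlower_bound\tupper_bound\n")
        for r in model.reactions:
            v = solution.fluxes.get(r.id, math.nan)
            if abs(v) < NUMERICAL_ZERO:
                v = 0.0
            fh.write(f"{r.id}\t{r.name}\t{v:.10g}\t{r.lower_bound:g}\t{r.upper_bound:g}\n")


def models_equal(a: MetabolicModel, b: MetabolicModel) -> bool:
    """Stoichiometric identity: same reactions, bounds, roles and formulas."""
    if a.growth_reaction_id != b.growth_reaction_id:
        return False
    if a.target_reaction_id != b.target_reaction_id:
        return False
    if sorted(m.id for m in a.metabolites) != sorted(m.id for m in b.metabolites):
        return False
    ra = {r.id: r for r in a.reactions}
    rb = {r.id: r for r in b.reactions}
    if set(ra) != set(rb):
        return False
    for rid, r1 in ra.items():
        r2 = rb[rid]
        if r1.stoichiometry != r2.stoichiometry:
            return False
        if (r1.lower_bound, r1.upper_bound) != (r2.lower_bound, r2.upper_bound):
            return False
    return True
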