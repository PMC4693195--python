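"""FBA-guided supplement screening for a production target at fixed growth.

The procedure mirrors how constraint-based models are used to design culture
media for a growth-coupled product: first maximize the specific growth rate
on the base medium, then pin growth at a fraction of that maximum (an
equality on both bounds) and maximize the target flux. Candidate medium
supplements are evaluated one at a time by relaxing the lower bound of their
exchange reaction — amino acids to one uptake allowance, other factors to
another — and recording the gain in the optimized target flux. Finally,
candidates are flagged by whether adding them to the base medium keeps the
medium's molar carbon-to-nitrogen ratio above a threshold, since
nitrogen-rich supplements can push an oleaginous process out of the
lipid/terpenoid accumulation regime.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field

from . import formula as _formula
from .errors import (
    DataError,
    InfeasibleProblemError,
    MappingError,
    StateError,
)
from .gsmn import (
    FBASolution,
    MetabolicModel,
    fba,
    set_exchange_bound,
)

CATEGORIES = (
    "carbon_source",
    "nitrogen_source",
    "amino_acid",
    "cofactor",
    "salt",
    "other",
)


@dataclass
class MediumComponent:
    name: str
    exchange_reaction_id: str
    concentration: float = 0.0            # g/L
    molar_mass: float | None = None       # g/mol; derived from formula if absent
    formula: dict[str, int] | None = None
    category: str = "other"

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise DataError(f"component {self.name!r}: negative concentration")
        if self.category not in CATEGORIES:
            raise DataError(
                f"component {self.name!r}: unknown category {self.category!r}"
            )
        if isinstance(self.formula, str):
            self.formula = _formula.parse_formula(self.formula)
        if self.molar_mass is None and self.formula:
            self.molar_mass = _formula.molar_mass(self.formula)


@dataclass
class ScreenSettings:
    growth_fraction: float = 0.9          # growth pinned at this fraction of max
    amino_acid_bound: float = -2.0        # mmol/gDCW/h uptake allowance
    factor_bound: float = -1.0            # mmol/gDCW/h for non-amino-acid factors
    zero_tolerance: float = 1e-9          # |flux| below this is solver noise
    cn_threshold: float = 10.0            # required molar C/N of the medium

    def __post_init__(self) -> None:
        if not 0 < self.growth_fraction <= 1:
            raise DataError("growth_fraction must be in (0, 1]")
        if self.amino_acid_bound > 0 or self.factor_bound > 0:
            raise DataError("relaxation bounds are uptake bounds and must be <= 0")
        if self.cn_threshold <= 0:
            raise DataError("cn_threshold must be positive")


@dataclass
class SupplementScanResult:
    exchange_reaction_id: str
    reaction_name: str
    bound_used: float
    growth_fixed_at: float
    baseline_target_flux: float
    relaxed_target_flux: float
    delta: float
    supplement_flux: float                # candidate uptake at the target optimum
    passes_cn_filter: bool | None = None  # set by cn_filter


def max_growth(model: MetabolicModel) -> float:
    """Maximum flux through the growth reaction on the current medium (h^-1)."""
    sol = fba(model, model.growth_reaction_id, "maximize")
    if sol.status != "optimal":
        raise InfeasibleProblemError(
            f"growth optimization {sol.status} for model {model.name!r}; "
            "check the medium's exchange bounds"
        )
    return sol.objective_value


def target_flux_at_growth(
    model: MetabolicModel,
    settings: ScreenSettings,
    growth_rate: float | None = None,
) -> FBASolution:
    """Maximize the target flux with growth fixed at fraction x max growth.

    Growth is pinned with an equality (both bounds), so the target optimum is
    conditional on exactly that growth rate. ``growth_rate`` overrides the
    pinned value — the supplement scan passes the *base* model's rate so all
    rows share one growth rate and relaxation gains show up in the target,
    not in biomass.
    """
    mu = (
        settings.growth_fraction * max_growth(model)
        if growth_rate is None
        else growth_rate
    )
    pinned = model.copy()
    g = pinned.reaction(model.growth_reaction_id)
    g.lower_bound = g.upper_bound = mu
    sol = fba(pinned, model.target_reaction_id, "maximize")
    if sol.status != "optimal":
        raise InfeasibleProblemError(
            f"target optimization {sol.status} with growth fixed at {mu:.6g} h^-1"
        )
    return sol


def negative_flux_exchanges(
    solution: FBASolution, model: MetabolicModel, settings: ScreenSettings
) -> list[tuple[str, float]]:
    """Exchange reactions consumed at the optimum, most negative first.

    Values in [-zero_tolerance, 0) are excluded: magnitudes that small are
    rounding errors of the LP solver, not genuine uptake.
    """
    if solution.status != "optimal":
        raise StateError("negative_flux_exchanges requires an optimal solution")
    out = [
        (r.id, solution.fluxes[r.id])
        for r in model.reactions
        if r.is_exchange and solution.fluxes.get(r.id, 0.0) < -settings.zero_tolerance
    ]
    return sorted(out, key=lambda t: (t[1], t[0]))


def supplement_scan(
    model: MetabolicModel,
    candidates: list[MediumComponent],
    settings: ScreenSettings,
) -> list[SupplementScanResult]:
    """Relax each candidate's exchange independently and record the target gain.

    The relaxation never tightens: the new lower bound is the minimum of the
    existing bound and the requested allowance, so a candidate whose exchange
    is already open yields delta = 0. Results are sorted by descending delta
    (ties by reaction id); evaluation is stateless and order-independent.
    """
    unmapped = [
        c.name
        for c in candidates
        if not any(r.id == c.exchange_reaction_id and r.is_exchange
                   for r in model.reactions)
    ]
    if unmapped:
        raise MappingError(
            f"candidates with no exchange reaction in the model: {unmapped}"
        )
    baseline = target_flux_at_growth(model, settings)
    mu = baseline.fluxes[model.growth_reaction_id]
    results = []
    for cand in candidates:
        requested = (
            settings.amino_acid_bound
            if cand.category == "amino_acid"
            else settings.factor_bound
        )
        rxn = model.reaction(cand.exchange_reaction_id)
        bound = min(rxn.lower_bound, requested)
        relaxed_model = set_exchange_bound(model, cand.exchange_reaction_id, bound)
        relaxed = target_flux_at_growth(relaxed_model, settings, growth_rate=mu)
        results.append(
            SupplementScanResult(
                exchange_reaction_id=cand.exchange_reaction_id,
                reaction_name=rxn.name or cand.name,
                bound_used=bound,
                growth_fixed_at=mu,
                baseline_target_flux=baseline.objective_value,
                relaxed_target_flux=relaxed.objective_value,
                delta=relaxed.objective_value - baseline.objective_value,
                supplement_flux=relaxed.fluxes[cand.exchange_reaction_id],
            )
        )
    return sorted(results, key=lambda r: (-r.delta, r.exchange_reaction_id))


def medium_cn_ratio(components: list[MediumComponent]) -> float:
    """Molar carbon-to-nitrogen ratio of a medium; +inf when it has no nitrogen.

    Each C- or N-containing component at nonzero concentration must carry an
    elemental formula (the molar mass is derived from it when not given).
    """
    mol_c = mol_n = 0.0
    for comp in components:
        if comp.concentration == 0:
            continue
        if comp.formula is None:
            # a component without formula is assumed C- and N-free (salts);
            # named components of unknown composition should carry formulas
            continue
        n_c = comp.formula.get("C", 0)
        n_n = comp.formula.get("N", 0)
        if n_c == 0 and n_n == 0:
            continue
        if not comp.molar_mass:
            raise DataError(
                f"component {comp.name!r} contains C or N but has no molar mass"
            )
        moles = comp.concentration / comp.molar_mass
        mol_c += moles * n_c
        mol_n += moles * n_n
    if mol_n == 0:
        return math.inf
    return mol_c / mol_n


def supplement_dose_g_per_l(
    candidate: MediumComponent,
    result: SupplementScanResult,
    override: float | None = None,
) -> float:
    """Convert a scan uptake flux into a medium dose (g/L).

    |flux| (mmol/gDCW/h) is read as a mmol/L dose on a nominal 1 gDCW·h
    basis; an explicit per-candidate override (g/L) takes precedence. This
    convention is declared, not derived — see the methods note.
    """
    if override is not None:
        return override
    if candidate.molar_mass is None:
        raise DataError(
            f"candidate {candidate.name!r}: no molar mass to convert uptake "
            "flux to a dose"
        )
    return abs(result.supplement_flux) / 1000.0 * candidate.molar_mass


def cn_filter(
    results: list[SupplementScanResult],
    base_medium: list[MediumComponent],
    candidates: list[MediumComponent],
    settings: ScreenSettings,
    dose_overrides: dict[str, float] | None = None,
) -> list[SupplementScanResult]:
    """Flag each scan result by the C/N ratio of base medium + candidate dose.

    ``passes_cn_filter`` is True iff the augmented medium keeps the molar C/N
    ratio above ``settings.cn_threshold``. All results are returned with the
    flag set; none are dropped.
    """
    by_rxn = {c.exchange_reaction_id: c for c in candidates}
    overrides = dose_overrides or {}
    out = []
    for res in results:
        cand = by_rxn.get(res.exchange_reaction_id)
        if cand is None:
            raise MappingError(
                f"scan result {res.exchange_reaction_id!r} has no matching candidate"
            )
        dose = supplement_dose_g_per_l(
            cand, res, overrides.get(cand.name)
        ) if (cand.formula and (cand.formula.get("C") or cand.formula.get("N"))) else 0.0
        dosed = MediumComponent(
            name=cand.name,
            exchange_reaction_id=cand.exchange_reaction_id,
            concentration=dose,
            molar_mass=cand.molar_mass,
            formula=dict(cand.formula) if cand.formula else None,
            category=cand.category,
        )
        ratio = medium_cn_ratio(list(base_medium) + [dosed])
        res.passes_cn_filter = ratio > settings.cn_threshold
        out.append(res)
    return out


# ---------------------------------------------------------------------------
# medium file I/O
# ---------------------------------------------------------------------------

MEDIUM_COLUMNS = [
    "name",
    "exchange_reaction_id",
    "concentration_g_per_L",
    "molar_mass",
    "formula",
    "category",
]


def read_medium(path: str) -> list[MediumComponent]:
    """Read a tab-separated medium definition file."""
    comps = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = set(MEDIUM_COLUMNS) - set(reader.fieldnames or [])
        if missing:
            raise DataError(f"{path}: missing medium columns {sorted(missing)}")
        for row in reader:
            comps.append(
                MediumComponent(
                    name=row["name"],
                    exchange_reaction_id=row["exchange_reaction_id"],
                    concentration=float(row["concentration_g_per_L"] or 0),
                    molar_mass=float(row["molar_mass"]) if row["molar_mass"] else None,
                    formula=(
                        _formula.parse_formula(row["formula"])
                        if row["formula"]
                        else None
                    ),
                    category=row["category"] or "other",
                )
            )
    return comps


def write_scan_report(results: list[SupplementScanResult], path: str) -> None:
    """Scan report mirroring the growth/target/uptake table layout."""
    with open(path, "w") as fh:
        fh.write(
            "exchange_reaction_id\treaction_name\tgrowth\ttarget_flux\t"
            "supplement_flux\tdelta\tbound_used\tpasses_cn_filter\n"
        )
        for r in results:
            flag = "" if r.passes_cn_filter is None else str(r.passes_cn_filter)
            fh.write(
                f"{r.exchange_reaction_id}\t{r.reaction_name}\t"
                f"{r.growth_fixed_at:.4f}\t{r.relaxed_target_flux:.4f}\t"
                f"{r.supplement_flux:.4f}\t{r.delta:.4f}\t{r.bound_used:g}\t{flag}\n"
            )
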