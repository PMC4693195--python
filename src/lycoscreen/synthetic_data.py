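"""Synthetic stand-ins with analytically known answers.

Two generators back the test-beds of the pipeline:

* :func:`make_toy_model` emits a small terpenoid-pathway metabolic model —
  substrate uptake, lumped catabolism, a biomass reaction, a single
  FPP-producing reaction (the declared target) and optional amino-acid
  exchanges — wired so that the maximum growth rate, the target optimum at
  any fixed growth fraction, and the gain from relaxing each amino-acid
  exchange all have closed forms, returned alongside the model.

* :func:`simulate_pb_responses` draws screening-design responses from a
  known coded-effects model ``y = link_inv(b0 + X beta + eps)`` so that the
  effect-estimation stage has a planted ground truth to recover.

Both are deterministic under a seed and never touch global random state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DataError
from .gsmn import Metabolite, MetabolicModel, Reaction
from .media_screen import MediumComponent
from .pb_design import PBDesign

#: elemental formulas for the amino acids the default toy model knows about
AMINO_ACID_FORMULAS = {
    "l-isoleucine": "C6H13NO2",
    "l-leucine": "C6H13NO2",
    "l-valine": "C5H11NO2",
    "l-asparagine": "C4H8N2O3",
    "l-histidine": "C6H9N3O2",
    "l-methionine": "C5H11NO2S",
    "l-lysine": "C6H14N2O2",
    "l-tryptophan": "C11H12N2O2",
    "glycine": "C2H5NO2",
}


def _default_boosts() -> dict[str, tuple[float, float]]:
    # uptake bound (mmol/gDCW/h) and FPP gain per unit uptake; gains sized
    # like the small per-amino-acid target improvements seen in genome-scale
    # screens (deltas of order 1e-3 at a -2 uptake allowance)
    return {
        "l-isoleucine": (-2.0, 0.0005),
        "l-leucine": (-2.0, 0.0010),
        "l-valine": (-2.0, 0.0009),
    }


@dataclass
class ToyModelSpec:
    substrate_uptake_max: float = -10.0     # mmol/gDCW/h, uptake is negative
    biomass_yield: float = 0.1              # gDCW per mmol substrate
    fpp_yield: float = 0.05                 # mmol FPP per mmol substrate
    amino_acid_boosts: dict[str, tuple[float, float]] = field(
        default_factory=_default_boosts
    )
    include_oxygen: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.substrate_uptake_max > 0:
            raise DataError("substrate_uptake_max is an uptake bound; must be <= 0")
        if self.biomass_yield <= 0:
            raise DataError("biomass_yield must be positive")
        if self.fpp_yield < 0:
            raise DataError("fpp_yield must be >= 0")
        for name, (bound, gain) in self.amino_acid_boosts.items():
            if bound > 0:
                raise DataError(f"boost {name!r}: uptake bound must be <= 0")
            if gain < 0:
                raise DataError(f"boost {name!r}: gain must be >= 0")


@dataclass
class ToyModelGuarantees:
    """Closed-form optima the generated network is constructed to satisfy."""

    max_growth: float
    fpp_yield: float
    substrate_capacity: float               # |uptake bound|, mmol/gDCW/h
    biomass_yield: float
    boosts: dict[str, tuple[float, float]]

    def target_at_fraction(self, growth_fraction: float) -> float:
        """Max FPP flux with growth pinned at fraction x max growth."""
        spare = self.substrate_capacity * (1.0 - growth_fraction)
        return self.fpp_yield * spare

    def boost_delta(self, name: str, bound: float | None = None) -> float:
        """Target-flux gain from relaxing one amino-acid exchange to `bound`."""
        declared_bound, gain = self.boosts[name]
        b = declared_bound if bound is None else bound
        return gain * abs(b)


def make_toy_model(spec: ToyModelSpec) -> tuple[MetabolicModel, ToyModelGuarantees]:
    """Emit the toy terpenoid network and its guaranteed optima.

    Structure (uptake negative, secretion positive):

        EX_substrate <-> substrate_e
        CATAB:   substrate_e (+ 2 o2_e) -> precursor_c
        GROWTH:  (1/biomass_yield) precursor_c -> biomass_c
        FPP_SYNTH: (1/fpp_yield) precursor_c -> fpp_c      [target]
        EX_fpp, EX_biomass: sinks
        per amino acid: EX_aa (closed) and aa_e -> (gain/fpp_yield) precursor_c

    With substrate the only limiting resource, max growth equals
    biomass_yield x substrate capacity, and at a pinned growth fraction f the
    target optimum is fpp_yield x capacity x (1 - f). Relaxing an amino-acid
    exchange to bound b adds gain x |b| to that optimum. A zero fpp_yield
    emits the synthesis reaction with a zero upper bound (pathway absent), so
    the baseline target optimum is 0.
    """
    mets = [
        Metabolite("substrate_e", "substrate (glucose equivalent)", "e",
                   {"C": 6, "H": 12, "O": 6}),
        Metabolite("precursor_c", "lumped catabolic precursor", "c"),
        Metabolite("fpp_c", "farnesyl diphosphate", "c",
                   {"C": 15, "H": 28, "O": 7, "P": 2}),
        Metabolite("biomass_c", "biomass", "c"),
    ]
    catab = {"substrate_e": -1.0, "precursor_c": 1.0}
    rxns = [
        Reaction("EX_substrate", {"substrate_e": -1.0}, "substrate exchange",
                 spec.substrate_uptake_max, 0.0),
    ]
    if spec.include_oxygen:
        mets.append(Metabolite("o2_e", "oxygen", "e", {"O": 2}))
        rxns.append(Reaction("EX_o2", {"o2_e": -1.0}, "oxygen exchange",
                             -1000.0, 0.0))
        catab["o2_e"] = -2.0
    rxns.append(Reaction("CATAB", catab, "lumped catabolism", 0.0, 1000.0))
    rxns.append(
        Reaction("GROWTH", {"precursor_c": -1.0 / spec.biomass_yield,
                            "biomass_c": 1.0},
                 "biomass formation", 0.0, 1000.0)
    )
    rxns.append(Reaction("EX_biomass", {"biomass_c": -1.0}, "biomass sink",
                         0.0, 1000.0))
    if spec.fpp_yield > 0:
        synth = Reaction(
            "FPP_SYNTH",
            {"precursor_c": -1.0 / spec.fpp_yield, "fpp_c": 1.0},
            "FPP synthesis", 0.0, 1000.0,
        )
    else:
        synth = Reaction("FPP_SYNTH", {"precursor_c": -1.0, "fpp_c": 1.0},
                         "FPP synthesis (disabled)", 0.0, 0.0)
    rxns.append(synth)
    rxns.append(Reaction("EX_fpp", {"fpp_c": -1.0}, "FPP sink", 0.0, 1000.0))

    for name, (bound, gain) in spec.amino_acid_boosts.items():
        aa_id = name.replace("-", "_").replace(" ", "_")
        mets.append(Metabolite(f"{aa_id}_e", name, "e"))
        rxns.append(Reaction(f"EX_{aa_id}", {f"{aa_id}_e": -1.0},
                             f"{name} exchange", 0.0, 0.0))
        conv_coeff = (gain / spec.fpp_yield) if spec.fpp_yield > 0 else gain
        rxns.append(
            Reaction(f"CONV_{aa_id}",
                     {f"{aa_id}_e": -1.0, "precursor_c": conv_coeff},
                     f"{name} assimilation", 0.0, 1000.0)
        )

    model = MetabolicModel(
        metabolites=mets,
        reactions=rxns,
        growth_reaction_id="GROWTH",
        target_reaction_id="FPP_SYNTH",
        name="toy terpenoid network",
    )
    capacity = abs(spec.substrate_uptake_max)
    guarantees = ToyModelGuarantees(
        max_growth=spec.biomass_yield * capacity,
        fpp_yield=spec.fpp_yield,
        substrate_capacity=capacity,
        biomass_yield=spec.biomass_yield,
        boosts=dict(spec.amino_acid_boosts),
    )
    return model, guarantees


def toy_candidates(spec: ToyModelSpec) -> list[MediumComponent]:
    """Medium candidates matching the toy model's amino-acid exchanges."""
    out = []
    for name in spec.amino_acid_boosts:
        aa_id = name.replace("-", "_").replace(" ", "_")
        out.append(
            MediumComponent(
                name=name,
                exchange_reaction_id=f"EX_{aa_id}",
                concentration=0.0,
                formula=AMINO_ACID_FORMULAS.get(name),
                category="amino_acid",
            )
        )
    return out


# ---------------------------------------------------------------------------
# screening-design response simulation
# ---------------------------------------------------------------------------

LINKS = ("identity", "sqrt_inverse", "log10_inverse")


@dataclass
class ResponseSimSpec:
    true_intercept: float
    true_coefficients: dict[str, float]     # coded units
    noise_sd: float = 0.0
    n_replicates: int = 1
    seed: int = 0
    link: str = "identity"

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise DataError("noise_sd must be >= 0")
        if self.n_replicates < 1:
            raise DataError("n_replicates must be >= 1")
        if self.link not in LINKS:
            raise DataError(f"unknown link {self.link!r}; choose from {LINKS}")


def simulate_pb_responses(
    design: PBDesign, spec: ResponseSimSpec
) -> tuple[np.ndarray, int]:
    """Draw responses ``y = link_inv(b0 + X beta + eps)`` for each replicate.

    Returns an (n_runs, n_replicates) array and the count of values clipped
    at zero (responses are concentrations; how zeros interact with the
    sqrt/log10 transformation rule is itself under test downstream). The
    noise is Gaussian on the linear-predictor scale, i.i.d. across runs and
    replicates, from a generator seeded with ``spec.seed``.
    """
    unknown = set(spec.true_coefficients) - set(design.factor_labels)
    if unknown:
        raise DataError(f"unknown factor labels in simulation spec: {sorted(unknown)}")
    rng = np.random.default_rng(spec.seed)
    n = design.n_runs
    lin = np.full(n, spec.true_intercept, dtype=float)
    for label, beta in spec.true_coefficients.items():
        lin = lin + beta * design.column(label)
    cols = []
    clipped = 0
    for _ in range(spec.n_replicates):
        eps = rng.normal(0.0, spec.noise_sd, size=n) if spec.noise_sd > 0 else 0.0
        pred = lin + eps
        if spec.link == "sqrt_inverse":
            y = pred ** 2
        elif spec.link == "log10_inverse":
            y = 10.0 ** pred
        else:
            y = pred.copy() if isinstance(pred, np.ndarray) else np.full(n, pred)
        below = y < 0
        clipped += int(below.sum())
        y[below] = 0.0
        cols.append(y)
    return np.column_stack(cols), clipped


def attach_simulated_response(
    design: PBDesign, spec: ResponseSimSpec, name: str = "simulated"
) -> tuple[PBDesign, int]:
    """Simulate and attach responses as columns ``name``, ``name_rep2``, ..."""
    ys, clipped = simulate_pb_responses(design, spec)
    for i in range(ys.shape[1]):
        key = name if i == 0 else f"{name}_rep{i + 1}"
        design.responses[key] = ys[:, i]
    return design, clipped
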