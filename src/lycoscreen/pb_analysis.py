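"""Effect estimation and significance screening for saturated two-level designs.

The analysis follows standard screening-design practice:

* the response is transformed when its max/min ratio exceeds 10 (log10 when
  all values are positive, square root when zeros are present);
* for each factor the *effect* is the mean response at the high level minus
  the mean at the low level, and the coded-unit *coefficient* is half the
  effect — by orthogonality these equal the least-squares estimates of the
  first-order model;
* a saturated design leaves no residual degrees of freedom, so significance
  requires pooling: the columns not retained in the reduced model (plus any
  dummy columns) form the error estimate. Effects are then compared to two
  t-quantile limits — the individual t-value limit and the family-wise
  Bonferroni limit. Effects above the Bonferroni limit are certainly
  significant, effects between the two limits possibly significant, and the
  rest likely insignificant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .errors import AnalysisError, DataError, SaturationError
from .pb_design import PBDesign

TRANSFORM_KINDS = ("identity", "sqrt", "log10")

#: max/min ratio above which the response is transformed
RATIO_LIMIT = 10.0


@dataclass
class Transformation:
    kind: str
    rationale: str = ""

    def __post_init__(self) -> None:
        if self.kind not in TRANSFORM_KINDS:
            raise DataError(f"unknown transformation {self.kind!r}")

    def apply(self, y: np.ndarray) -> np.ndarray:
        y = np.asarray(y, dtype=float)
        if self.kind == "identity":
            return y
        if self.kind == "sqrt":
            if (y < 0).any():
                raise DataError("sqrt transformation requires y >= 0")
            return np.sqrt(y)
        if (y <= 0).any():
            raise DataError("log10 transformation requires y > 0")
        return np.log10(y)

    def label(self, response_name: str) -> str:
        if self.kind == "identity":
            return response_name
        if self.kind == "sqrt":
            return f"Sqrt({response_name})"
        return f"Log10({response_name})"


@dataclass
class EffectAnalysis:
    response_name: str
    transformation: Transformation
    intercept: float
    coefficients: dict[str, float]          # coded units; coefficient = effect/2
    effects: dict[str, float]
    t_values: dict[str, float] = field(default_factory=dict)
    t_limit: float | None = None
    bonferroni_limit: float | None = None
    classification: dict[str, str] = field(default_factory=dict)
    selected_terms: list[str] = field(default_factory=list)
    residual_df: int | None = None
    alpha: float = 0.05


def choose_transformation(
    y: np.ndarray, override: Transformation | str | None = None
) -> Transformation:
    """Pick a variance-stabilizing transformation from the max/min ratio rule.

    Ratio <= 10 (over the strictly positive values): identity. Ratio > 10:
    log10 when every value is positive, square root when zeros occur (a zero
    always counts as ratio > 10). Responses are concentrations, so negative
    values are a domain error.
    """
    y = np.asarray(y, dtype=float)
    if y.size == 0 or not np.isfinite(y).all():
        raise DataError("response vector must be non-empty and finite")
    if (y < 0).any():
        raise DataError("negative response values are not transformable")
    if override is not None:
        t = Transformation(override) if isinstance(override, str) else override
        t.apply(y)  # validates domain, e.g. log10 with zeros
        return t
    has_zero = (y == 0).any()
    pos = y[y > 0]
    ratio = math.inf if (has_zero or pos.size == 0) else pos.max() / pos.min()
    if ratio <= RATIO_LIMIT:
        return Transformation("identity", f"max/min = {ratio:.3g} <= {RATIO_LIMIT:g}")
    if has_zero:
        return Transformation("sqrt", "zeros present with max/min > 10")
    return Transformation("log10", f"max/min = {ratio:.3g} > {RATIO_LIMIT:g}")


def estimate_effects(
    design: PBDesign, response_name: str, transformation: Transformation
) -> EffectAnalysis:
    """Half-effect contrasts of the transformed response for every factor.

    Requires balanced columns; on an orthogonal design these contrasts equal
    the least-squares coefficients of the first-order model.
    """
    y = transformation.apply(design.response(response_name))
    effects: dict[str, float] = {}
    for fac in design.factors:
        col = design.column(fac.label)
        if col.sum() != 0:
            raise AnalysisError(
                f"column {fac.label!r} is unbalanced; effects are not contrasts"
            )
        effects[fac.label] = float(y[col == 1].mean() - y[col == -1].mean())
    return EffectAnalysis(
        response_name=response_name,
        transformation=transformation,
        intercept=float(y.mean()),
        coefficients={k: v / 2 for k, v in effects.items()},
        effects=effects,
    )


def significance_limits(
    analysis: EffectAnalysis,
    design: PBDesign,
    selected_terms: list[str] | None = None,
    auto_k: int | None = None,
    alpha: float = 0.05,
) -> EffectAnalysis:
    """Pool unselected columns into error and compute both t limits.

    ``selected_terms`` names the factors kept in the reduced model;
    alternatively ``auto_k`` drops the k smallest-|effect| factors into the
    error pool. Dummy (unassigned) columns are always pooled. The residual
    mean square comes from the least-squares fit of the reduced model; the
    coefficient standard error is sqrt(MSE/n) (orthogonal +/-1 columns), and
    the two limits are the upper alpha/2 and alpha/(2m) t-quantiles at the
    residual degrees of freedom, with m the number of candidate effects.
    """
    labels = list(analysis.coefficients)
    if selected_terms is not None and auto_k is not None:
        raise AnalysisError("give either selected_terms or auto_k, not both")
    if selected_terms is None:
        if auto_k is None:
            auto_k = 0
        by_size = sorted(labels, key=lambda l: (abs(analysis.effects[l]), l))
        dropped = set(by_size[:auto_k])
        selected = [l for l in labels if l not in dropped]
    else:
        unknown = set(selected_terms) - set(labels)
        if unknown:
            raise AnalysisError(f"selected terms not in the design: {sorted(unknown)}")
        selected = [l for l in labels if l in set(selected_terms)]

    n = design.n_runs
    df = n - 1 - len(selected)
    if df < 1:
        raise SaturationError(
            "no residual degrees of freedom: drop terms (selected_terms or "
            "auto_k) so that runs - 1 - |selected| >= 1"
        )
    y = analysis.transformation.apply(design.response(analysis.response_name))
    x = np.column_stack(
        [np.ones(n)] + [design.column(l).astype(float) for l in selected]
    )
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    sse = float(((y - x @ beta) ** 2).sum())
    if sse < 1e-18 * max(1.0, float((y**2).sum())):
        sse = 0.0  # response exactly spanned by the reduced model
    mse = sse / df
    se = math.sqrt(mse / n)

    m = len(labels)
    t_limit = float(stats.t.ppf(1 - alpha / 2, df))
    bonferroni_limit = float(stats.t.ppf(1 - alpha / (2 * m), df))
    t_values: dict[str, float] = {}
    classification: dict[str, str] = {}
    for l in labels:
        coef = analysis.coefficients[l]
        if se == 0:
            t = math.inf if coef != 0 else 0.0
        else:
            t = abs(coef) / se
        t_values[l] = t
        if t >= bonferroni_limit:
            classification[l] = "certain"
        elif t >= t_limit:
            classification[l] = "possible"
        else:
            classification[l] = "insignificant"
    return replace(
        analysis,
        t_values=t_values,
        t_limit=t_limit,
        bonferroni_limit=bonferroni_limit,
        classification=classification,
        selected_terms=selected,
        residual_df=df,
        alpha=alpha,
    )


def format_coefficient(c: float) -> str:
    """2 decimals for |c| >= 0.01, mantissa.e-exponent notation below."""
    if c == 0:
        return "0.00"
    if abs(c) >= 0.01:
        return f"{abs(c):.2f}"
    mantissa, exp = f"{abs(c):.3e}".split("e")
    return f"{mantissa}e{int(exp):+04d}"


def coded_equation(analysis: EffectAnalysis) -> str:
    """Render the reduced model in coded units, e.g.

    ``Sqrt(Biomass) = 2.24 - 0.38 × A + 0.29 × D ...``

    Terms appear in design order; an intercept-only model renders as
    ``<name> = <grand mean>``.
    """
    lhs = analysis.transformation.label(analysis.response_name)
    parts = [f"{lhs} = {analysis.intercept:.2f}"]
    terms = analysis.selected_terms or []
    for label in terms:
        c = analysis.coefficients[label]
        sign = "-" if c < 0 else "+"
        parts.append(f"{sign} {format_coefficient(c)} × {label}")
    return " ".join(parts)


def pareto_data(
    analysis: EffectAnalysis,
) -> list[tuple[str, float, str]]:
    """(factor, t-value, class) triples ranked for a Pareto chart.

    Descending by t-value; ties broken by design column order (the order of
    ``analysis.coefficients``).
    """
    if analysis.t_limit is None:
        raise AnalysisError("significance limits not computed yet")
    order = {l: i for i, l in enumerate(analysis.coefficients)}
    ranked = sorted(
        analysis.t_values.items(), key=lambda kv: (-kv[1], order[kv[0]])
    )
    return [(l, t, analysis.classification[l]) for l, t in ranked]


def plot_pareto(analysis: EffectAnalysis, path: str) -> None:
    """Render the ranked t-values with both limits (SVG/PNG by suffix)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    data = pareto_data(analysis)
    labels = [d[0] for d in data]
    ts = [min(d[1], 1e6) for d in data]
    colors = {"certain": "#b2182b", "possible": "#ef8a62", "insignificant": "#999999"}
    fig, ax = plt.subplots(figsize=(max(6, 0.35 * len(labels)), 4))
    ax.bar(range(len(labels)), ts, color=[colors[d[2]] for d in data])
    ax.axhline(analysis.t_limit, ls="--", color="k", label="t-value limit")
    ax.axhline(analysis.bonferroni_limit, ls="-", color="k", label="Bonferroni limit")
    ax.set_xticks(range(len(labels)), labels)
    ax.set_ylabel("|t|")
    ax.set_title(analysis.transformation.label(analysis.response_name))
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
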