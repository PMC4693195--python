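"""Bioprocess summary statistics over screening-run records.

Content metrics (product per unit dry cell weight), max/min range ratios
(the quantity that drives the transformation rule), and Pearson correlation
with a two-tailed t test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError
from .pb_design import PBDesign
from .pb_analysis import choose_transformation


@dataclass
class RunRecord:
    run: int
    biomass: float                      # g/L
    lycopene: float                     # mg/L
    lipid: float | None = None          # g/L
    lycopene_content: float | None = None   # mg/g DCW (derived)
    lipid_content: float | None = None      # % of DCW (derived)


@dataclass
class CorrelationResult:
    r: float
    p_two_tailed: float
    n: int


def derive_contents(records: list[RunRecord]) -> list[RunRecord]:
    """Fill per-gram contents: lycopene/biomass (mg/g) and 100*lipid/biomass (%).

    Contents are computed from the unrounded inputs; rounding is a display
    concern only.
    """
    out = []
    for rec in records:
        if rec.biomass <= 0:
            raise DataError(f"run {rec.run}: biomass must be positive, got {rec.biomass}")
        out.append(
            replace(
                rec,
                lycopene_content=rec.lycopene / rec.biomass,
                lipid_content=(
                    100.0 * rec.lipid / rec.biomass if rec.lipid is not None else None
                ),
            )
        )
    return out


def range_ratio(y: np.ndarray) -> float:
    """max/min of a response; +inf when any value is zero (flagged upstream)."""
    y = np.asarray(y, dtype=float)
    if y.size == 0:
        raise DataError("range_ratio of an empty vector")
    if (y < 0).any():
        raise DataError("range_ratio requires non-negative values")
    if (y == 0).any():
        return math.inf
    return float(y.max() / y.min())


def pearson(x: np.ndarray, y: np.ndarray) -> CorrelationResult:
    """Sample Pearson correlation with the two-tailed t test on n-2 df."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DataError("pearson requires two equal-length vectors")
    if x.size < 3:
        raise DataError("pearson requires n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise DataError("pearson is undefined for a zero-variance input")
    res = stats.pearsonr(x, y)
    return CorrelationResult(
        r=float(res.statistic), p_two_tailed=float(res.pvalue), n=int(x.size)
    )


def records_from_design(design: PBDesign) -> list[RunRecord]:
    """Build run records from a design's Biomass/Lycopene(/Lipid) responses."""
    needed = {"Biomass", "Lycopene"}
    if not needed <= set(design.responses):
        raise DataError(f"design responses must include {sorted(needed)}")
    lipid = design.responses.get("Lipid")
    return [
        RunRecord(
            run=i + 1,
            biomass=float(design.responses["Biomass"][i]),
            lycopene=float(design.responses["Lycopene"][i]),
            lipid=float(lipid[i]) if lipid is not None else None,
        )
        for i in range(design.n_runs)
    ]


def summarize_responses(design: PBDesign) -> pd.DataFrame:
    """Per-response min/max/ratio table with the transformation each implies."""
    rows = []
    for name, y in design.responses.items():
        y = np.asarray(y, dtype=float)
        ratio = range_ratio(y)
        rows.append(
            {
                "response": name,
                "min": float(y.min()),
                "max": float(y.max()),
                "max_min_ratio": ratio,
                "contains_zero": bool((y == 0).any()),
                "transformation": choose_transformation(y).kind,
            }
        )
    return pd.DataFrame(rows).set_index("response")
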