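"""Two-level Plackett-Burman screening designs.

A Plackett-Burman design studies up to N-1 factors in N runs (N a multiple
of 4) at two coded levels, -1 (low) and +1 (high). Every column is balanced
(equal counts of each level) and any two columns are orthogonal, which makes
the half-effect contrasts equal to least-squares coefficients of the
first-order model.

Designs can be generated from the published cyclic generator rows, or
ingested from a printed concentration-valued table plus a declaration of
each factor's low/high level (the decoding path used for the packaged
design-table fixtures).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import CapabilityError, DataError, DecodingError, FormatError

#: first rows of the cyclic Plackett-Burman constructions; the remaining
#: rows are cyclic shifts, plus a final all-minus run. Correctness is
#: asserted by the balance/orthogonality validator, not by string identity.
GENERATOR_ROWS: dict[int, str] = {
    8: "+++-+--",
    12: "++-+++---+-",
    16: "++++-+-++--+---",
    20: "++--++++-+-+----++-",
    24: "+++++-+-++--++--+-+----",
}

#: design-letter sequence; "I" is skipped by DOE convention
LETTERS = [c for c in "ABCDEFGHJKLMNOPQRSTUVWXYZ"]


@dataclass
class Factor:
    label: str
    name: str = ""
    low_level: float = -1.0
    high_level: float = 1.0
    units: str = ""

    def __post_init__(self) -> None:
        if self.low_level == self.high_level:
            raise DataError(f"factor {self.label!r}: identical low/high levels")


@dataclass
class PBDesign:
    factors: list[Factor]
    coded_matrix: np.ndarray              # runs x columns, entries in {-1, +1}
    std_order: list[int]
    run_order: list[int]
    responses: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        labels = [f.label for f in self.factors]
        if len(set(labels)) != len(labels):
            raise DataError(f"duplicate factor labels: {labels}")
        self.coded_matrix = np.asarray(self.coded_matrix, dtype=int)
        if len(self.factors) > self.coded_matrix.shape[1]:
            raise DataError("more factors than design columns")

    @property
    def n_runs(self) -> int:
        return self.coded_matrix.shape[0]

    @property
    def n_columns(self) -> int:
        return self.coded_matrix.shape[1]

    @property
    def factor_labels(self) -> list[str]:
        return [f.label for f in self.factors]

    def column(self, label: str) -> np.ndarray:
        """Coded column of an assigned factor."""
        idx = self.factor_labels.index(label)
        return self.coded_matrix[:, idx]

    def dummy_columns(self) -> np.ndarray:
        """Unassigned (dummy) columns, used for error pooling."""
        return self.coded_matrix[:, len(self.factors):]

    def response(self, name: str) -> np.ndarray:
        if name not in self.responses:
            raise DataError(
                f"no response {name!r}; available: {sorted(self.responses)}"
            )
        return np.asarray(self.responses[name], dtype=float)


def pb_matrix(n_runs: int) -> np.ndarray:
    """Coded (n_runs x n_runs-1) Plackett-Burman matrix from the cyclic rows."""
    if n_runs not in GENERATOR_ROWS:
        raise CapabilityError(
            f"unsupported run count {n_runs}; supported: "
            f"{sorted(GENERATOR_ROWS)}"
        )
    first = np.array([1 if c == "+" else -1 for c in GENERATOR_ROWS[n_runs]])
    rows = [np.roll(first, i) for i in range(n_runs - 1)]
    rows.append(-np.ones(n_runs - 1, dtype=int))
    matrix = np.array(rows)
    problems = validate_matrix(matrix)
    if problems:  # embedded generator rows are pre-validated; belt and braces
        raise CapabilityError(f"generator for {n_runs} runs failed: {problems}")
    return matrix


def validate_matrix(matrix: np.ndarray) -> list[str]:
    """Balance/orthogonality violations of a coded matrix (empty = valid)."""
    problems = []
    m = np.asarray(matrix)
    if not np.isin(m, (-1, 1)).all():
        problems.append("entries outside {-1, +1}")
        return problems
    sums = m.sum(axis=0)
    for j, s in enumerate(sums):
        if s != 0:
            problems.append(f"column {j} unbalanced (sum {s})")
    gram = m.T @ m
    n_cols = m.shape[1]
    for i in range(n_cols):
        for j in range(i + 1, n_cols):
            if gram[i, j] != 0:
                problems.append(f"columns {i},{j} not orthogonal (dot {gram[i, j]})")
    return problems


def validate_design(design: PBDesign) -> list[str]:
    """Run the matrix validator plus design-level bookkeeping checks."""
    problems = validate_matrix(design.coded_matrix)
    n = design.n_runs
    if n % 4 != 0:
        problems.append(f"{n} runs is not a multiple of 4")
    for attr in ("std_order", "run_order"):
        order = getattr(design, attr)
        if sorted(order) != list(range(1, n + 1)):
            problems.append(f"{attr} is not a permutation of 1..{n}")
    for name, y in design.responses.items():
        if len(y) != n:
            problems.append(f"response {name!r} has {len(y)} values for {n} runs")
    return problems


def assign_factors(
    matrix: np.ndarray, factors: list[Factor], seed: int
) -> PBDesign:
    """Attach factors to the first columns and draw a randomized run order.

    Unused columns are retained as unnamed dummy columns. The run order is a
    seed-determined permutation, so a fixed seed reproduces the design
    exactly.
    """
    matrix = np.asarray(matrix, dtype=int)
    n_runs, n_cols = matrix.shape
    if len(factors) > n_cols:
        raise CapabilityError(
            f"{len(factors)} factors exceed the {n_cols} columns available"
        )
    rng = np.random.default_rng(seed)
    run_order = list(rng.permutation(n_runs) + 1)
    return PBDesign(
        factors=list(factors),
        coded_matrix=matrix,
        std_order=list(range(1, n_runs + 1)),
        run_order=[int(r) for r in run_order],
    )


def decode_design(
    table: pd.DataFrame,
    factors: list[Factor],
    responses: dict[str, np.ndarray] | None = None,
    std_order: list[int] | None = None,
    level_tolerance: float = 1e-9,
) -> tuple[PBDesign, list[str]]:
    """Decode a concentration-valued run table into a coded design.

    ``table`` has one column per factor label, rows in run order. Each cell
    must match the factor's low or high level to within ``level_tolerance``;
    +1 codes the high level. Balance/orthogonality violations are returned
    as warnings (second element), not raised — printed tables are ingested
    as they are.
    """
    n_runs = len(table)
    coded = np.zeros((n_runs, len(factors)), dtype=int)
    for j, fac in enumerate(factors):
        if fac.label not in table.columns:
            raise DataError(f"table has no column for factor {fac.label!r}")
        col = table[fac.label].to_numpy(dtype=float)
        for i, val in enumerate(col):
            if abs(val - fac.high_level) <= level_tolerance:
                coded[i, j] = 1
            elif abs(val - fac.low_level) <= level_tolerance:
                coded[i, j] = -1
            else:
                raise DecodingError(
                    f"run {i + 1}, factor {fac.label}: value {val!r} matches "
                    f"neither level {fac.low_level} nor {fac.high_level}"
                )
    design = PBDesign(
        factors=list(factors),
        coded_matrix=coded,
        std_order=list(std_order) if std_order else list(range(1, n_runs + 1)),
        run_order=list(range(1, n_runs + 1)),
        responses={k: np.asarray(v, dtype=float) for k, v in (responses or {}).items()},
    )
    return design, validate_design(design)


def encode_design(design: PBDesign) -> pd.DataFrame:
    """Inverse of decode_design: map coded levels back to concentrations."""
    data = {}
    for j, fac in enumerate(design.factors):
        col = design.coded_matrix[:, j]
        data[fac.label] = np.where(col == 1, fac.high_level, fac.low_level)
    return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# design file I/O: TSV run table + YAML sidecar with levels and responses
# ---------------------------------------------------------------------------

def read_design(table_path: str | Path, sidecar_path: str | Path | None = None
                ) -> tuple[PBDesign, list[str]]:
    """Read a design from a TSV table and its YAML sidecar.

    The sidecar declares factor labels, names, units and low/high levels,
    plus the names/units of the response columns. When ``sidecar_path`` is
    omitted, ``<table>.yaml`` next to the table is used.
    """
    table_path = Path(table_path)
    if sidecar_path is None:
        sidecar_path = table_path.with_suffix(".yaml")
    with open(sidecar_path) as fh:
        meta = yaml.safe_load(fh)
    try:
        factors = [
            Factor(
                label=f["label"],
                name=f.get("name", ""),
                low_level=float(f["low"]),
                high_level=float(f["high"]),
                units=f.get("units", ""),
            )
            for f in meta["factors"]
        ]
        response_names = [r["name"] for r in meta.get("responses", [])]
    except (KeyError, TypeError) as exc:
        raise FormatError(f"{sidecar_path}: malformed design sidecar ({exc})") from exc
    df = pd.read_csv(table_path, sep="\t")
    responses = {}
    for name in response_names:
        if name not in df.columns:
            raise DataError(f"{table_path}: missing response column {name!r}")
        responses[name] = df[name].to_numpy(dtype=float)
    std = df["Std"].astype(int).tolist() if "Std" in df.columns else None
    return decode_design(df, factors, responses=responses, std_order=std)


def write_design(
    design: PBDesign,
    table_path: str | Path,
    sidecar_path: str | Path | None = None,
) -> None:
    """Write a design (and responses) in the TSV + YAML sidecar format."""
    table_path = Path(table_path)
    if sidecar_path is None:
        sidecar_path = table_path.with_suffix(".yaml")
    df = encode_design(design)
    df.insert(0, "Std", design.std_order)
    df.insert(1, "Run", design.run_order)
    for name, y in design.responses.items():
        df[name] = y
    df.to_csv(table_path, sep="\t", index=False)
    meta = {
        "factors": [
            {
                "label": f.label,
                "name": f.name,
                "units": f.units,
                "low": float(f.low_level),
                "high": float(f.high_level),
            }
            for f in design.factors
        ],
        "responses": [{"name": n} for n in design.responses],
    }
    with open(sidecar_path, "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)
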