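"""Stage drivers tying the modules into the two screening workflows.

``run_screen`` is the constraint-based path: maximize growth, pin it at a
fraction, maximize the target flux, scan candidate exchange relaxations and
flag them by the medium C/N ratio. ``run_doe`` is the statistical path:
decode a two-level screening design, transform responses, estimate effects,
compute significance limits, and emit equations, Pareto rankings, summary
ratios and requested correlations. ``run_synth`` materializes the synthetic
model/response fixtures.

Each run writes a ``manifest.json`` (inputs, config hash, seed, package
version) so deterministic stages can be reproduced bit for bit. The numbered
scripts under ``analysis/`` are thin command-line drivers over these
functions and are the package's command-line surface.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .bioprocess_stats import pearson, records_from_design, derive_contents, summarize_responses
from .errors import ConfigurationError
from .gsmn import read_model, write_flux_report, write_model
from .media_screen import (
    ScreenSettings,
    cn_filter,
    max_growth,
    negative_flux_exchanges,
    read_medium,
    supplement_scan,
    target_flux_at_growth,
    write_scan_report,
)
from .pb_analysis import (
    choose_transformation,
    coded_equation,
    estimate_effects,
    pareto_data,
    plot_pareto,
    significance_limits,
)
from .pb_design import read_design, write_design, assign_factors, pb_matrix
from .synthetic_data import (
    ResponseSimSpec,
    ToyModelSpec,
    attach_simulated_response,
    make_toy_model,
    toy_candidates,
)

log = logging.getLogger("lycoscreen")

# exit codes for script drivers: configuration, data, numerical
EXIT_CONFIG, EXIT_DATA, EXIT_NUMERICAL = 2, 3, 4


def packaged_design(which: str) -> tuple[Path, Path]:
    """Paths of a packaged design fixture: 'fba_independent' or 'fba_predicted'."""
    names = {"fba_independent": "table1", "fba_predicted": "table4"}
    if which not in names:
        raise ConfigurationError(f"unknown packaged design {which!r}")
    base = resources.files("lycoscreen") / "data"
    return Path(str(base / f"{names[which]}.tsv")), Path(str(base / f"{names[which]}.yaml"))


@dataclass
class PipelineConfig:
    output_dir: str | Path
    model_path: str | Path | None = None
    medium_path: str | Path | None = None
    candidates_path: str | Path | None = None
    design_path: str | Path | None = None
    design_sidecar_path: str | Path | None = None
    settings: ScreenSettings = field(default_factory=ScreenSettings)
    analysis: dict[str, dict] = field(default_factory=dict)  # per-response config
    correlations: list[tuple[str, str]] = field(default_factory=list)
    seed: int = 0
    make_plots: bool = False


def _write_manifest(config: PipelineConfig, outdir: Path, stage: str,
                    inputs: dict[str, str]) -> None:
    blob = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    manifest = {
        "stage": stage,
        "package_version": __version__,
        "seed": config.seed,
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
        "inputs": inputs,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
        fh.write("\n")


def run_screen(config: PipelineConfig) -> dict:
    """FBA-assisted screening: growth, pinned-growth target optimum, scan, C/N.

    Writes a baseline flux report, a scan report in the growth/target/uptake
    table layout, and a ranked candidate list. Returns the key numbers.
    """
    if config.model_path is None:
        raise ConfigurationError("run_screen requires model_path")
    if config.medium_path is None:
        raise ConfigurationError("run_screen requires medium_path")
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    model = read_model(str(config.model_path))
    base_medium = read_medium(str(config.medium_path))
    candidates = (
        read_medium(str(config.candidates_path)) if config.candidates_path else []
    )
    settings = config.settings

    log.info("stage screen: maximizing growth")
    mu_max = max_growth(model)
    baseline = target_flux_at_growth(model, settings)
    consumed = negative_flux_exchanges(baseline, model, settings)
    write_flux_report(baseline, model, str(outdir / "baseline_fluxes.tsv"))

    results = supplement_scan(model, candidates, settings)
    results = cn_filter(results, base_medium, candidates, settings) if candidates else results
    write_scan_report(results, str(outdir / "supplement_scan.tsv"))
    with open(outdir / "ranked_candidates.tsv", "w") as fh:
        fh.write("rank\texchange_reaction_id\tdelta\tpasses_cn_filter\n")
        for i, r in enumerate(results, 1):
            fh.write(f"{i}\t{r.exchange_reaction_id}\t{r.delta:.6g}\t{r.passes_cn_filter}\n")

    summary = {
        "max_growth": mu_max,
        "growth_fixed_at": settings.growth_fraction * mu_max,
        "baseline_target_flux": baseline.objective_value,
        "consumed_exchanges": consumed,
        "n_candidates": len(results),
        "best_candidate": results[0].exchange_reaction_id if results else None,
        "best_delta": results[0].delta if results else None,
    }
    _write_manifest(config, outdir, "screen", {
        "model": str(config.model_path), "medium": str(config.medium_path),
        "candidates": str(config.candidates_path or ""),
    })
    return summary


def run_doe(config: PipelineConfig) -> dict:
    """Design-of-experiments analysis of a two-level screening table.

    Per response: transformation (auto unless configured), effect estimates,
    significance limits over the configured term set (or auto_k pooling),
    coded-unit equation and Pareto ranking. Also writes the response summary
    (min/max/ratio) and any configured content-column correlations.
    """
    if config.design_path is None:
        raise ConfigurationError("run_doe requires design_path")
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    design, warnings = read_design(config.design_path, config.design_sidecar_path)
    for w in warnings:
        log.warning("design: %s", w)

    report: dict = {"responses": {}, "design_warnings": warnings}
    for name in design.responses:
        cfg = config.analysis.get(name, {})
        if cfg.get("skip"):
            continue
        y = design.response(name)
        override = cfg.get("transform")
        transformation = choose_transformation(
            y, None if override in (None, "auto") else override
        )
        analysis = estimate_effects(design, name, transformation)
        terms = cfg.get("included_terms")
        auto_k = cfg.get("auto_k", 2 if terms is None else None)
        analysis = significance_limits(
            analysis, design,
            selected_terms=terms, auto_k=auto_k,
            alpha=cfg.get("alpha", 0.05),
        )
        equation = coded_equation(analysis)
        ranked = pareto_data(analysis)
        report["responses"][name] = {
            "transformation": transformation.kind,
            "intercept": analysis.intercept,
            "coefficients": analysis.coefficients,
            "t_values": analysis.t_values,
            "t_limit": analysis.t_limit,
            "bonferroni_limit": analysis.bonferroni_limit,
            "classification": analysis.classification,
            "residual_df": analysis.residual_df,
            "equation": equation,
            "pareto": ranked,
        }
        if config.make_plots:
            plot_pareto(analysis, str(outdir / f"pareto_{name}.svg"))

    summary = summarize_responses(design)
    summary.to_csv(outdir / "response_summary.tsv", sep="\t")
    report["response_summary"] = summary.to_dict(orient="index")

    if config.correlations:
        records = derive_contents(records_from_design(design))
        derived = {
            "Lycopene_content": np.array([r.lycopene_content for r in records]),
            "Lipid_content": np.array([r.lipid_content for r in records]),
        }
        report["correlations"] = {}
        for a, b in config.correlations:
            xa = derived.get(a, design.responses.get(a))
            xb = derived.get(b, design.responses.get(b))
            res = pearson(np.asarray(xa, float), np.asarray(xb, float))
            report["correlations"][f"{a}~{b}"] = {
                "r": res.r, "p_two_tailed": res.p_two_tailed, "n": res.n,
            }

    with open(outdir / "doe_report.json", "w") as fh:
        json.dump(report, fh, indent=1, default=float)
        fh.write("\n")
    with open(outdir / "equations.txt", "w") as fh:
        for name, r in report["responses"].items():
            fh.write(r["equation"] + "\n")
    _write_manifest(config, outdir, "doe", {"design": str(config.design_path)})
    return report


def run_synth(
    config: PipelineConfig,
    toy_spec: ToyModelSpec | None = None,
    sim_spec: ResponseSimSpec | None = None,
    n_runs: int = 12,
) -> dict:
    """Materialize synthetic fixtures: toy model JSON and a simulated design."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict = {}

    toy_spec = toy_spec or ToyModelSpec(seed=config.seed)
    model, guarantees = make_toy_model(toy_spec)
    model_path = outdir / "toy_model.json"
    write_model(model, str(model_path))
    written["model"] = str(model_path)
    written["guaranteed_max_growth"] = guarantees.max_growth

    if sim_spec is not None:
        from .pb_design import Factor, LETTERS

        matrix = pb_matrix(n_runs)
        factors = [
            Factor(label=l, name=f"factor {l}", low_level=0.0, high_level=1.0)
            for l in LETTERS[: n_runs - 1]
        ]
        design = assign_factors(matrix, factors, seed=config.seed)
        design, clipped = attach_simulated_response(design, sim_spec)
        design_path = outdir / "simulated_design.tsv"
        write_design(design, design_path)
        written["design"] = str(design_path)
        written["clipped"] = clipped

    _write_manifest(config, outdir, "synth", {})
    return written


def toy_screen_inputs(outdir: Path, spec: ToyModelSpec | None = None):
    """Write the toy model plus matching medium/candidate files; return paths.

    Convenience for drivers and tests: the base medium is the glucose
    minimal medium (glucose 20 g/L, ammonium sulfate 3 g/L, KH2PO4 2 g/L)
    mapped onto the toy model's substrate exchange.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spec = spec or ToyModelSpec()
    model, guarantees = make_toy_model(spec)
    model_path = outdir / "toy_model.json"
    write_model(model, str(model_path))

    medium_rows = [
        ("glucose", "EX_substrate", 20.0, "", "C6H12O6", "carbon_source"),
        ("ammonium sulfate", "", 3.0, "", "(NH4)2SO4", "nitrogen_source"),
        ("KH2PO4", "", 2.0, "", "KH2PO4", "salt"),
    ]
    medium_path = outdir / "minimal_medium.tsv"
    header = "name\texchange_reaction_id\tconcentration_g_per_L\tmolar_mass\tformula\tcategory\n"
    with open(medium_path, "w") as fh:
        fh.write(header)
        for row in medium_rows:
            fh.write("\t".join(str(x) for x in row) + "\n")

    cands = toy_candidates(spec)
    cand_path = outdir / "candidates.tsv"
    with open(cand_path, "w") as fh:
        fh.write(header)
        for c in cands:
            from .formula import format_formula
            fh.write(
                f"{c.name}\t{c.exchange_reaction_id}\t0\t\t"
                f"{format_formula(c.formula) if c.formula else ''}\t{c.category}\n"
            )
    return model_path, medium_path, cand_path, guarantees
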