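#!/usr/bin/env python
"""Effect analysis of the FBA-predicted medium screen, plus bioprocess stats.

Decodes the packaged 24-run design of model-predicted components, analyses
log10(lycopene) over the published term set, summarizes the max/min range
ratios that drive the transformation rule (23.29 lycopene, 3.91 biomass,
3.23 lipid), derives per-gram contents and computes the Pearson correlation
between lipid content and lycopene content (published r = 0.49, two-tailed).
Writes results/doe_fba_predicted/.
"""

import sys
from pathlib import Path

import yaml

from lycoscreen.errors import ConfigurationError, DataError, LycoscreenError
from lycoscreen.pipeline import (
    EXIT_CONFIG,
    EXIT_DATA,
    EXIT_NUMERICAL,
    PipelineConfig,
    packaged_design,
    run_doe,
)

ROOT = Path(__file__).resolve().parents[1]


def main() -> int:
    table, sidecar = packaged_design("fba_predicted")
    analysis = yaml.safe_load(sidecar.read_text())["analysis"]
    outdir = ROOT / "results" / "doe_fba_predicted"
    report = run_doe(
        PipelineConfig(
            output_dir=outdir,
            design_path=table,
            design_sidecar_path=sidecar,
            analysis=analysis,
            correlations=[("Lipid_content", "Lycopene_content")],
            make_plots=True,
        )
    )
    lyc = report["responses"]["Lycopene"]
    certain = [l for l, c in lyc["classification"].items() if c == "certain"]
    print(f"Lycopene: {lyc['equation']}")
    print(f"  grand mean {lyc['intercept']:.4f}, certain factors: "
          f"{', '.join(certain)}")
    for name in ("Lycopene", "Biomass", "Lipid"):
        s = report["response_summary"][name]
        print(f"{name}: max/min = {s['max_min_ratio']:.2f} "
              f"-> {s['transformation']}")
    corr = report["correlations"]["Lipid_content~Lycopene_content"]
    print(f"lipid content ~ lycopene content: r = {corr['r']:.2f}, "
          f"p = {corr['p_two_tailed']:.3f} (n = {corr['n']})")
    print(f"reports written to: {outdir}")
    return 0


if __name__ == "__main__":
    try:
        sys.exit(main())
    except ConfigurationError as exc:
        print(f"configuration error: {exc}", file=sys.stderr)
        sys.exit(EXIT_CONFIG)
    except DataError as exc:
        print(f"data error: {exc}", file=sys.stderr)
        sys.exit(EXIT_DATA)
    except LycoscreenError as exc:
        print(f"numerical error: {exc}", file=sys.stderr)
        sys.exit(EXIT_NUMERICAL)
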