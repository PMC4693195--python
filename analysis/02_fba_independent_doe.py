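#!/usr/bin/env python
"""Effect analysis of the literature-selected (FBA-independent) medium screen.

Decodes the packaged 24-run, 23-factor design, applies the square-root
transformation declared for both responses, estimates half-effect
coefficients, computes t-value and Bonferroni limits over the published term
sets and prints the coded equations alongside the published grand means
(2.24 for sqrt biomass, 0.75 for sqrt lycopene). Writes results/doe_fba_independent/.
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
    table, sidecar = packaged_design("fba_independent")
    analysis = yaml.safe_load(sidecar.read_text())["analysis"]
    outdir = ROOT / "results" / "doe_fba_independent"
    report = run_doe(
        PipelineConfig(
            output_dir=outdir,
            design_path=table,
            design_sidecar_path=sidecar,
            analysis=analysis,
            make_plots=True,
        )
    )
    for name in ("Biomass", "Lycopene"):
        r = report["responses"][name]
        certain = [l for l, c in r["classification"].items() if c == "certain"]
        print(f"{name}: {r['equation']}")
        print(f"  grand mean {r['intercept']:.4f}, residual df {r['residual_df']}, "
              f"certain factors: {', '.join(certain) or 'none'}")
    ratio = report["response_summary"]["Biomass"]["max_min_ratio"]
    print(f"biomass max/min ratio: {ratio:.2f}")
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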