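# FBA-predicted medium screening design: 23 components, 24 runs.
# Levels in g/L; +1 codes the high level.
factors:
  - {label: A, name: Thiamine pyrophosphate, units: g/L, low: 0.0006, high: 0.006}
  - {label: B, name: Pyridoxine hydrochloride, units: g/L, low: 0.0006, high: 0.006}
  - {label: C, name: Succinate, units: g/L, low: 1, high: 5}
  - {label: D, name: (R)-Pantothenate, units: g/L, low: 1, high: 5}
  - {label: E, name: 4-Aminobutyric acid, units: g/L, low: 1, high: 5}
  - {label: F, name: KH2PO4, units: g/L, low: 6, high: 12}
  - {label: G, name: (NH4)2SO4, units: g/L, low: 0.5, high: 2}
  - {label: H, name: Urea, units: g/L, low: 0.5, high: 2}
  - {label: J, name: Na2SO3, units: g/L, low: 0.1, high: 2}
  - {label: K, name: Ergosterol, units: g/L, low: 0.01, high: 0.1}
  - {label: L, name: Ethanolamine, units: g/L, low: 0.05, high: 0.3}
  - {label: M, name: Hypoxanthine, units: g/L, low: 1, high: 5}
  - {label: N, name: Guanine, units: g/L, low: 1, high: 5}
  - {label: O, name: l-histidine, units: g/L, low: 1, high: 5}
  - {label: P, name: l-methionine, units: g/L, low: 1, high: 5}
  - {label: Q, name: l-lysine, units: g/L, low: 1, high: 5}
  - {label: R, name: l-tryptophan, units: g/L, low: 1, high: 5}
  - {label: S, name: l-valine, units: g/L, low: 1, high: 5}
  - {label: T, name: l-asparagine, units: g/L, low: 1, high: 10}
  - {label: U, name: l-isoleucine, units: g/L, low: 1, high: 10}
  - {label: V, name: l-leucine, units: g/L, low: 1, high: 10}
  - {label: W, name: d-glucose, units: g/L, low: 20, high: 60}
  - {label: X, name: d-fructose, units: g/L, low: 20, high: 60}
responses:
  - {name: Lycopene, units: mg/L}
  - {name: Biomass, units: g/L}
  - {name: Lycopene_content, units: mg/g}
  - {name: Lipid, units: g/L}
  - {name: Lipid_content, units: "%"}
# Term set of the published log10(lycopene) model (read off the printed
# coded equation; C, H and O were not retained there).
analysis:
  Lycopene:
    transform: log10
    included_terms: [A, B, D, E, F, G, J, K, L, M, N, P, Q, R, S, T, U, V, W, X]
  Biomass:
    transform: identity
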