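# FBA-independent medium screening design: 23 components, 24 runs.
# Levels in g/L; +1 codes the high level.
factors:
  - {label: A, name: CuCl2.2H2O, units: g/L, low: 0.03, high: 0.3}
  - {label: B, name: NiSO4.6H2O, units: g/L, low: 1, high: 3}
  - {label: C, name: CoCl2.6H2O, units: g/L, low: 0.02, high: 0.4}
  - {label: D, name: MgSO4.7H2O, units: g/L, low: 1.5, high: 15}
  - {label: E, name: NiCl2.6H2O, units: g/L, low: 0.05, high: 0.1}
  - {label: F, name: H3BO3, units: g/L, low: 0.01, high: 0.1}
  - {label: G, name: ZnCl2, units: g/L, low: 0.01, high: 0.15}
  - {label: H, name: MnSO4.7H2O, units: g/L, low: 0.02, high: 0.4}
  - {label: J, name: KI, units: g/L, low: 0.01, high: 0.1}
  - {label: K, name: MnCl2.4H2O, units: g/L, low: 0.01, high: 0.2}
  - {label: L, name: FeSO4.7H2O, units: g/L, low: 0.1, high: 2.5}
  - {label: M, name: Na2MoO4.2H2O, units: g/L, low: 0.01, high: 0.1}
  - {label: N, name: FeCl3.6H2O, units: g/L, low: 0.02, high: 3}
  - {label: O, name: KNO3, units: g/L, low: 0.01, high: 0.2}
  - {label: P, name: NaCl, units: g/L, low: 0.01, high: 1}
  - {label: Q, name: Glucose, units: g/L, low: 10, high: 20}
  - {label: R, name: Fructose, units: g/L, low: 0, high: 20}
  - {label: S, name: Yeast extract, units: g/L, low: 0.5, high: 10}
  - {label: T, name: (NH4)2SO4, units: g/L, low: 0.5, high: 10}
  - {label: U, name: KH2PO4, units: g/L, low: 0.01, high: 10}
  - {label: V, name: K2HPO4, units: g/L, low: 0, high: 3.5}
  - {label: W, name: Vitamin B1, units: g/L, low: 0, high: 0.01}
  - {label: X, name: BaCl2.2H2O, units: g/L, low: 0.01, high: 1}
responses:
  - {name: Biomass, units: g/L}
  - {name: Lycopene, units: mg/L}
  - {name: Lycopene_content, units: mg/g}
# Term sets of the published first-order models (read off the printed coded
# equations); used by the reproduction analyses for error pooling.
analysis:
  Biomass:
    transform: sqrt
    included_terms: [A, B, C, D, E, G, H, J, K, L, M, N, O, Q, R, S, T, U, V, W, X]
  Lycopene:
    transform: sqrt
    included_terms: [A, B, C, D, E, G, H, J, K, L, M, N, O, P, Q, R, T, U, V, W, X]
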