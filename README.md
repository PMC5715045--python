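# cnmfa — steady-state ¹³C metabolic flux analysis for *Cupriavidus necator* H16

*Cupriavidus necator* H16 is a facultatively lithoautotrophic "Knallgas"
bacterium: it grows on organic substrates, but can also fix CO₂ through the
Calvin–Benson–Bassham (CBB) cycle with hydrogen as the energy source.  A
central question for engineering this organism is how much carbon actually
flows through the CBB cycle, the Entner–Doudoroff (ED) route, the TCA cycle
and the glyoxylate shunt under heterotrophic growth (on [1-¹³C]fructose or
[1,2-¹³C]glycerol) versus mixotrophic growth ([1,2-¹³C]glycerol + CO₂).

`cnmfa` implements the complete steady-state ¹³C-MFA workflow for this
system, for modellers and fluxomics practitioners:

* **Atom-transition network model** — a packaged 72-reaction central-carbon
  model of *C. necator* (ED pathway, non-oxidative PPP, CBB carboxylation,
  TCA + glyoxylate shunt, anaplerosis, PHB drain, amino acid synthesis)
  with per-carbon atom mappings, flux classes and steady-state
  parameterization (free fluxes + null-space-determined dependent fluxes).
* **EMU labelling simulator** — predicts mass isotopomer distributions
  (MIDs) of proteinogenic amino acid fragments from a flux vector by
  elementary-metabolite-unit decomposition, with a brute-force
  positional-isotopomer oracle for verification.
* **GC-MS natural-abundance correction** — converts raw isotopologue
  envelopes of TBDMS-derivatized amino acid [M-57]/[M-85] fragments into
  tracer-only MIDs (correction matrix from elemental formulas, IUPAC
  isotope abundances, 99 atom% tracer purity; non-negative least squares).
* **Labelling statistics** — summed fractional labelling
  SFL = Σᵢ i·Mᵢ (the average number of ¹³C atoms in a fragment) and the
  mixotrophic R-value, the glycerol-to-CO₂ flux ratio obtained by inverting
  the two-source mixing model

      (0.99·n·V_gly + 0.01·V_CO₂)/(m·V_gly + V_CO₂) = SFL/C,
      n = 2, m = 3  ⇒  R = V_gly/V_CO₂,

  plus specific growth rates μ, doubling times ln2/μ and biomass-specific
  substrate uptake rates from OD₆₀₀/concentration time series.
* **Flux estimation** — variance-weighted least squares on corrected MIDs
  with Latin-hypercube multi-start local optimization (100 restarts by
  default) and profile-likelihood 95% confidence intervals
  (Δ SSR = 3.84 with re-optimization).
* **Synthetic data with known ground truth** — generators for all three
  study conditions (labelling vectors, admissible flux vectors, noisy MID
  tables forward-convolved through the correction matrices, growth series),
  so every estimator claim is testable by parameter recovery.

## Worked example

```python
import cnmfa

model = cnmfa.load_default_model()          # 72 reactions, atom-mapped
truth = cnmfa.demo_truth(model, "mixo_glycerol_co2")

# synthetic mixotrophic GC-MS dataset (SD 0.01 mole fraction, seeded)
scenario = cnmfa.ScenarioConfig("mixo_glycerol_co2", seed=7, noise_sd=0.01)
measurements, raw, gt = cnmfa.simulate_dataset(model, truth, scenario)

# labelling statistics for one fragment
ala = next(m for m in measurements
           if m.amino_acid == "Ala" and m.fragment_kind == "M-57")
print("Ala [M-57] SFL:", round(float(cnmfa.sfl(ala.mid).value), 3))
print("Ala [M-57] R:  ", round(float(cnmfa.r_value_from_mid(ala.mid)), 3))

# flux estimation with 95% profile CIs for the CBB flux
measured, demands = cnmfa.condition_setup(model, "mixo_glycerol_co2")
labs = cnmfa.make_labeling("mixo_glycerol_co2")
result = cnmfa.fit(model, measurements, labs, measured, overrides=demands,
                   n_starts=20, seed=1, clip_sd=scenario.noise_sd)
ci = cnmfa.confidence_interval_95(result, "rbc")
print(f"RuBisCO flux: {result.best_fluxes['rbc']:.3f} "
      f"[{ci.lower:.3f}, {ci.upper:.3f}] mmol/g DW/h "
      f"(truth {truth['rbc']})")
```

Output:

```
Ala [M-57] SFL: 1.342
Ala [M-57] R:   0.686
RuBisCO flux: 2.200 [2.148, 2.254] mmol/g DW/h (truth 2.2)
```

The Ala SFL of ~1.34 of a possible 3 reflects the dilution of the
[1,2-¹³C]glycerol label by unlabelled CO₂ fixed through the CBB cycle; the
R-value ≈ 0.7 says glycerol contributes roughly 0.7 units of carbon flux
per unit from CO₂; the fitted RuBisCO flux recovers the generating value
2.2 mmol/g DW/h inside its 95% interval.

The same pipeline is scriptable from the shell:

```bash
cnmfa simulate --seed 3 --out run      # synthetic MID + growth tables
cnmfa stats    --out run               # SFL/R and growth-rate tables
cnmfa fit      --out run               # per-condition flux estimates + CIs
cnmfa report   --out run               # merged summary (run/report.md)
```

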