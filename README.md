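# nsip

DNA stable-isotope-probing (SIP) density-shift detection and ¹⁵N tracer
uptake budgets for marine nitrogen-cycling studies.

## The problem

Bulk ¹⁵N tracer incubations tell you *how much* ammonium, nitrate, urea
or N₂ a plankton community takes up, but not *who* is doing it. DNA-SIP
closes that gap: organisms that assimilate a ¹⁵N-labeled substrate build
the heavy isotope into their DNA, which raises its buoyant density in an
isopycnic CsCl gradient. After ultracentrifugation the gradient is
collected from the bottom as ~50 fractions of ~100 µl, each fraction's
density and bulk DNA mass are measured, and 16S amplicon sequencing of
each fraction locates every OTU's DNA band along the density axis.

`nsip` implements the full reduction from those fraction tables to
per-taxon enrichment calls, together with the tracer-rate arithmetic
that turns IRMS atom-percent measurements into a depth-integrated
new-vs-regenerated production budget. A seeded synthetic-data generator
emulates the whole experiment (Gaussian DNA bands, multinomial read
sampling, quantification and refractometer noise), so every stage is
testable without any sequencing data.

## The method

For one OTU in one gradient, read counts are converted to relative
abundance within each fraction, multiplied by the fraction's bulk DNA to
give ng DNA per fraction, trimmed to a common density window across all
of that OTU's gradients, and renormalized. The band's location is its
weighted mean buoyant density

    WMD = Σᵢ ρᵢ wᵢ / Σᵢ wᵢ ,

with weights wᵢ the OTU's DNA mass in fraction i, together with the
weighted variance s² = Σ wᵢ(ρᵢ − WMD)²/Σ wᵢ and Kish's effective sample
size n_eff = (Σwᵢ)²/Σwᵢ². Unlabeled controls cannot shift density, so
all control bands of an OTU are pooled across treatments into one
estimate. Each labeled band is compared to its pooled control with
Welch's t-test,

    t = (WMD_L − WMD_C) / √(s²_L/n_L + s²_C/n_C) ,

one-sided for a positive shift, with Welch–Satterthwaite degrees of
freedom. P-values across all OTU × treatment tests are corrected by
Benjamini–Hochberg at FDR 0.1, and a positive call additionally requires
the shift to amount to ≥ 30 % of the full-label density gain
(Δρ_max = 0.016 g ml⁻¹), reported as percent enrichment
100·shift/Δρ_max.

Tracer uptake rates follow the standard ¹⁵N mass balance

    ρ = (A_PN(t_f) − A_PN(t₀)) / (A_dis − A_PN(t₀)) · PN / t ,

where A_dis is the post-spike dissolved-pool atom% (mixing of ambient
substrate at natural abundance, 0.366 atom%, with the >98 atom% spike).
Rates at the three light depths (5, 17, 35 m) are trapezoid-integrated
over the euphotic zone, converted to carbon with the Redfield ratio
(106:16), and summarized by the f-ratio
(ρNO₃ + ρN₂) / (ρNO₃ + ρN₂ + ρNH₄ + ρurea).

## Worked example

```python
from nsip.config import SimConfig, AnalysisConfig
from nsip.io import Treatment
from nsip.synth import simulate_community, simulate_experiment, otu_ids
from nsip.enrich import run_enrichment
from nsip.uptake import build_budget

sim = SimConfig(seed=7)
labeled = Treatment("NH4", "15N", "50")
controls = [Treatment(s, "14N_control", "50") for s in ("NH4", "NO3", "urea")]
assimilators = otu_ids(100)[:10]          # ground truth: 10 of 100 OTUs
community = simulate_community(100, sim, {labeled: assimilators},
                               atom_fraction=0.5)
gradients, counts, otus, truth = simulate_experiment(
    community, [labeled] + controls, sim)
results = run_enrichment(gradients, counts, AnalysisConfig())
print(results[results["enriched"]]
      [["otu_id", "shift", "q_value", "percent_enrichment"]].head(4))
```

prints

```
otu_id    shift  q_value  percent_enrichment
OTU001 0.007003 0.054076           43.768088
OTU002 0.006267 0.054076           39.171578
OTU003 0.006457 0.054076           40.357573
OTU004 0.006508 0.054076           40.674523
```

All 10 calls on this seed are the 10 simulated assimilators and none of
the 90 unlabeled OTUs is called. The shift of ~0.007 g ml⁻¹ reflects the
simulated half-label gain (0.5 × 0.016 = 0.008 g ml⁻¹) minus the small
attenuation introduced by trimming the band tails to a common window;
percent enrichment ~40 % clears the 30 % floor, and q ≈ 0.054 clears
FDR 0.1.

For the budget side, profiles integrating to the study's published
per-substrate euphotic-zone totals (urea 3.4, NO₃⁻ 3.1, NH₄⁺ 2.4, N₂
0.19 mmol N m⁻² d⁻¹):

```python
profiles = {s: ([5.0, 17.0, 35.0], [v / 35.0] * 3) for s, v in
            {"urea": 3.4, "NO3": 3.1, "NH4": 2.4, "N2": 0.19}.items()}
budget = build_budget(profiles)
print(f"total N = {budget.total_n:.2f} mmol m-2 d-1, "
      f"total C = {budget.total_c:.1f}, f-ratio = {budget.f_ratio:.3f}")
```

prints `total N = 9.09 mmol m-2 d-1, total C = 60.2, f-ratio = 0.362`
— i.e. ~9 mmol N m⁻² d⁻¹ of total uptake supporting ~60 mmol C m⁻² d⁻¹,
roughly a third of it new production.

A command-line interface wraps the same pipeline:
`nsip simulate`, `nsip enrich`, `nsip uptake`, `nsip budget`.

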