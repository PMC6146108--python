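# Methods

This note records the models, parameter choices and numerical decisions
behind `nsip`, in the order the pipeline runs.

## Synthetic gradient model

The generator emulates one CsCl ultracentrifugation run per incubation.
Fractions are collected densest-first: the density axis
[`density_min`, `density_max`] = [1.66, 1.77] g ml⁻¹ is split into
`n_fractions` = 50 equal intervals, fraction 1 covering the densest
interval. Measured fraction densities are the interval midpoints plus
Gaussian refractometer noise (`refractometer_sd`, default 1 × 10⁻⁴
g ml⁻¹, the resolution class of a handheld digital refractometer).

Each OTU's DNA is a Gaussian band in density with standard deviation
`band_sd` = 0.006 g ml⁻¹ (a literature-typical equilibrium width) whose
center is

    ρ₀ = 1.660 + 0.098 · GC + Δρ_max · a ,

the classic linear GC–density relation plus a linear gain of
`delta_rho_max` = 0.016 g ml⁻¹ at full ¹⁵N labeling, scaled by the atom
fraction a actually incorporated. GC fractions are uniform on
[0.35, 0.65], so unlabeled bands sit between ~1.694 and ~1.724 g ml⁻¹,
well inside the gradient. Relative abundances are lognormal with
σ = 0.8, normalized — a skewed species-abundance distribution in which
a typical community member holds roughly half the mean share and the
largest few percent of taxa dominate.

The OTU's expected mass in a fraction is its abundance times the
Gaussian mass falling in that fraction's density interval (difference
of normal CDFs — the band is integrated, not sampled at the midpoint).
Bulk DNA per fraction is total community mass × `dna_total_ng` (2000 ng
loaded per tube) with multiplicative lognormal noise of CV `qubit_cv`
(5 %, a typical fluorometric quantification error; the lognormal is
mean-1 so noise conserves mass in expectation). Reads are multinomial
per fraction over the community's mass proportions at
`reads_per_fraction` = 50 000 — the per-library depth implied by
spreading one MiSeq run across the ~420 sequenced fraction libraries of
the emulated design (30 fractions kept per gradient, 14 gradients).
Fractions holding less than `seq_min_mass_share` (10⁻⁶) of the
gradient's DNA yield no library, mirroring the practice of sequencing
only the fractions that contain essentially all the bulk DNA.

All randomness flows from a single seed; each gradient's generator is
split deterministically from the seed and a CRC of the gradient id, so
adding or reordering gradients never changes another gradient's draws.

What the generator does *not* emulate: PCR/primer bias, sequencing
error, chimeras, multi-modal bands from mixed populations, isotope
fractionation chemistry, or between-gradient density-axis calibration
offsets. Passing recovery tests therefore show that the statistical
chain behaves correctly under the stated band model and noise sources —
not that real amplicon artifacts are handled.

## Band isolation and weighted mean density

Within each gradient, fractions with fewer than `min_fraction_reads`
(100) total reads are dropped, counts become within-fraction relative
abundances, and abundances are converted to ng DNA per OTU per fraction
using the measured bulk-DNA distribution. Comparisons are strictly
within-OTU, which cancels organism-level offsets such as GC content.

Band tails are trimmed to a common window per OTU: in each gradient the
contiguous run of fractions around the OTU's peak with mass ≥
`band_tail_pct` (2 %) of the peak is retained, and the windows of all
gradients carrying that OTU (every control and every labeled treatment)
are intersected, so the pooled control and all labeled bands are
evaluated over the same densities. Within the window, masses are
renormalized to percent of the OTU's DNA. Bands with fewer than
`min_band_fractions` (3) positive-mass fractions, or an empty window
intersection, are excluded with a logged reason.

Two numerical choices matter here:

* **Boundary smoothing.** The 2 % run boundary is located on a
  binomial-smoothed ([1, 2, 1]/4, edge-renormalized) copy of the mass
  profile; the raw masses are untouched and remain the density weights.
  Per-fraction quantification noise otherwise jitters the tail cut-offs,
  and because the final window is an *intersection* over several
  gradients, boundary jitter is systematically biased narrow (an
  extreme-value effect), which clips band cores and attenuates measured
  shifts.
* **Interval-aware window edges.** A retained run's window extends half
  a fraction's density width beyond its outer fraction midpoints, since
  each fraction covers an interval of density, not a point. Without
  this, boundary fractions of other gradients whose midpoints sit just
  outside the run are spuriously trimmed.

Even with both, a residual attenuation is intrinsic to trimming: a
labeled band shifted by δ against its controls has its top tail clipped
at the controls' upper edge (and vice versa), so a true half-label shift
of 0.008 g ml⁻¹ is measured as ~0.0065–0.0072 (percent enrichment ~40
instead of 50). This is a property of the window policy, shared by any
"trim to common densities" scheme, and is why the 30 % positive-call
floor should not be raised without revisiting the policy.

The band location is the weighted mean density with the OTU's DNA mass
as weight; dispersion is the weighted variance, and the sample-size
notion required by Welch's test is Kish's effective n, (Σw)²/Σw². The
normalized percent column serves as the weight — identical to ng for a
single band (the estimator is scale-invariant) and it makes pooled
bands weight each contributing gradient equally. A single-fraction band
gets variance 0 and n_eff 1: flagged low-information, not an error.

## Enrichment decisions

Unlabeled N cannot change buoyant density, so every control band of an
OTU — across all substrates and depths — is pooled by concatenating the
normalized fractions and recomputing one weighted estimate. Each
labeled band is tested against the pooled control with Welch's t-test
on (WMD, s²/n_eff) pairs, one-sided for a positive shift by default
(¹⁵N can only add mass; a two-sided option exists). Degenerate
zero-variance pairs return p = 1 (equal means) or p = 0 with a
degeneracy flag (differing means) and are reported, never dropped.

Bands with fewer than `min_otu_reads` (500) summed reads on either side
are excluded before correction — a handful of reads can move a weighted
mean drastically — as are estimates with n_eff below `min_effective_n`
(2). The surviving p-values form a single Benjamini–Hochberg family per
analysis run (all OTU × treatment tests), delegated to
`statsmodels.stats.multitest` at FDR 0.1. A call requires q ≤ 0.1, a
positive shift, and percent enrichment (100·shift/Δρ_max) ≥
`min_percent` (30, following the precedent of earlier ¹⁵N-SIP work;
set 0 for a pure-FDR mode). The FDR decision and the percent floor are
combined as a conjunction.

Activity summaries count enriched OTUs per substrate × light level,
split prokaryote vs chloroplast-derived eukaryote signal, and report
per-OTU multi-treatment activity (the number of treatments in which an
OTU is labeled) and its mean by domain.

## Tracer rates and the budget

The dissolved pool after the spike mixes ambient substrate at natural
abundance (0.366 atom% ¹⁵N) with the tracer (>98 atom%), weighted by
concentration. The uptake rate is the atom-percent-excess transfer into
particulate N scaled by PN concentration over the incubation (24 h
incubations are treated as net daily rates). Negative apparent rates —
t_f below t₀ within instrument noise — are floored at zero with a
warning. N₂ fixation uses the same form with the measured aqueous ¹⁵N₂
enrichment supplied directly as the dissolved-pool atom%;
bubble-equilibration modeling is out of scope. IRMS size-effect/drift
correction is a linear standards-based form (coefficients fit by least
squares from reference standards); without a calibration it is the
identity, with a warning.

Depth integration is trapezoidal over the measured depths, with the
shallowest rate extended to the surface (standard oceanographic
boundary treatment) and the bottom at the deepest sampled depth (35 m,
the 1 % light level); both boundaries are configurable, and a bottom
between measurements is handled by linear interpolation. The carbon
equivalent uses the Redfield ratio fixed at 106/16 = 6.625; published
budget tables rounded from per-substrate values are not exactly
self-consistent under this ratio (nor is a printed total always equal
to its printed components' sum), so reproduction checks compare at
print rounding rather than chasing the discrepancy. The f-ratio is new
production (nitrate uptake + N₂ fixation) over total production.

## Problem sizes in the standard checks

The statistical operating characteristics are measured on communities
of 200 OTUs across four gradients (one labeled + three pooled
controls): the null false-positive check at 5 000 reads per fraction
with the percent floor disabled, and the recovery check (50 assimilators
at atom fraction 0.5 among 150 nulls) at the generator's default depth.
Both complete in a few seconds on one CPU; typical results are a 0 %
false-positive rate (the band-variance-based Welch test is conservative
under the null), ~98 % detection, and a median percent enrichment of
~40 (see the attenuation discussion above).

## Known limitations

* Percent enrichment is a linear proxy (shift over Δρ_max); no per-OTU
  atom-fraction or growth-rate inference is attempted.
* The window policy assumes unimodal bands; multi-modal bands (e.g.
  partial labeling of a population) would be mis-trimmed.
* The Welch test treats the weighted band variance over Kish's n as the
  variance of the mean; this is conservative when read depth is high,
  because multinomial noise on the mean is far smaller than band width.
* Fraction indices must be contiguous from 1 with fraction 1 densest;
  gradients collected top-first must be reindexed upstream.
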