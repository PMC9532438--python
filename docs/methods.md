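# Methods

This note documents the models behind each ploidyscope module, the
parameters that matter, what the synthetic generators do and do not
emulate, and the numerical choices made where the design was open.

## FUCCI flow-cytometry model and gating

**Event model.** A singlet event is characterised by its DNA content in
C-units (diploid G1 = 2C) and its reporter state.  The DNA-stain intensity
is `gain · C · ε`, with ε a unit-mean lognormal factor of coefficient of
variation `dna_cv` (default 0.06, a typical DAPI histogram width;
multiplicative noise is the natural model for stain/illumination
variation).  Reporter channels are two-level — an expressed level
(default 1000 a.u.) and an autofluorescence background (10 a.u.), each
lognormal with CV 0.25 — so positivity is separable by threshold without
spectral modelling.  Class semantics: G1 cells are mCherry⁺, S/G2/M cells
mVenus⁺, the G1/S boundary double-positive.  Dying cells carry sub-2C DNA
(uniform over 0.5–1.8C, so the <2C gate is exercised across its range)
with S/G2/M-type reporters, reflecting death out of G1.  Cycling diploids
split evenly between the double-positive boundary at 2C and mVenus-only S
phase with DNA uniform in (2C, 4C).  Doublets (probability
`doublet_rate`) are sums of two independent singlets: summed DNA, summed
pulse width, union of reporter states.  Non-induced cells (probability
1 − `induction_rate`) show background in both reporter channels.

The day-2 composition preset places 39.8% of cells in the cycling class
(5.2% dead, 50% diploid G1, 5% polyploid), the day-3 preset 8.8% cycling
with 17% polyploid and 19.6% dead, and the healthy preset 94% diploid G1 —
the summary fractions the generators are meant to reproduce.  What the
generator does **not** emulate: spectral spillover and compensation,
instrument drift, debris other than sub-2C dying cells, aggregates larger
than two cells, and S-phase DNA between 4C and 8C in polyploid cyclers.
Passing tests therefore demonstrate correctness of the gating logic under
idealised, well-separated populations — not robustness to compensation
artefacts on a real cytometer.

**Gating.**  Auto-derived parameters, all overridable:

* *Reporter thresholds* — 5× the channel background median.  The
  background population is located by an Otsu split of the log₁₀
  intensity histogram (expressed reporter sits ~2 decades above
  autofluorescence); a channel whose upper mode is less than a decade
  above the lower is treated as all-background.
* *2C anchor* — mode of the DNA histogram of mCherry⁺-only events (the G1
  population, dominated by diploids), refined as the median within the
  modal bin neighbourhood of a 256-bin log₂ histogram; requires ≥100 such
  events.  4C and 8C peaks are 2× and 4× the anchor.
* *DNA bins* — nearest C-peak on the log₂ axis (window half-width
  `bin_tolerance`, default 0.25 log₂ units; out-of-window values go to the
  nearest peak).  The sub-2C (dying) boundary is placed
  `min(bin_tolerance, 3σ̂)` log₂ units below the anchor, where σ̂ is the
  MAD-based width of the calibrated G1 peak: on noise-free data the dead
  gate closes at the peak itself (exact recovery), on noisy data it
  reduces to the window edge at 1.68C.  With CV 0.06 about 9% of the dead
  band (1.68–1.8C) falls into the 2C bin; this mis-assignment is ~0.5
  percentage points of the sample and is the dominant residual error.
* *Doublet cut* — 1.45× the median pulse width, the valley between the
  singlet population and doublets at ~2× singlet width.  A percentile rule
  on the singlet pool was rejected because it excludes a fixed fraction of
  singlets by construction.

Fractions are reported over induced singlets (doublet-excluded and
reporter-negative events removed from the denominator), matching
normalisation to per-animal induction.  The redistribution of the day-2
cycling pool takes the newly polyploid and newly dead fractions as
caller-supplied inputs (new polyploid = day-3 polyploid minus healthy
baseline, since pre-existing polyploids were not day-2 cyclers), divides
by the day-2 cycling fraction, clips at zero and renormalises to 1.
Computed from cohort *group means* (39.8% cycling, 17% newly polyploid,
19.6% newly dead) the shares are 42.7% / 49.2% / 8.0%; per-animal
averaging (mean of per-mouse shares) gives different numbers, and both
conventions are available — neither is asserted as canonical.

## Confetti recombination model

Each recombination event fixes one colour from (RFP, YFP, CFP, GFP) with
probabilities `colour_probs`; diploid cells draw once, 4C polyploid cells
twice independently.  With equiprobable scored colours the discordance
probability is (n−1)/n — 2/3 for three colours — so
`p̂ = b_obs/(2/3) = (3/2)·b_obs`, clipped to [0, 1].  GFP recombines
rarely (default probability 0.01; no published number exists beyond
"extremely rare") and GFP-containing cells are excluded from numerator
and denominator alike.  Cells with more than two recombination events
(≥8C) are not modelled.

Two summary conventions are emitted side by side, labelled distinctly:
the efficiency-normalised bi-coloured percentage `b/e` (the published
arithmetic: 13.3/0.847 → 15.7%), and the combinatorial inversion
`(3/2)·b`.  They answer different questions and neither is converted into
the other.  The 95% interval on p̂ is a percentile bootstrap (default
2,000 resamples) over the scored cells, resampling the bi-coloured
indicator as a binomial; an optional plug-in mode replaces the 2/3 by the
discordance implied by supplied colour frequencies, guarding against
unequal recombination probabilities.

## PicoGreen ploidy quantification

Per-nucleus fold over diploid is `(I − background)/reference_mean`, where
the reference mean is the average background-subtracted intensity of ≥20
flagged diploid control nuclei (a healthy biopsy imaged at identical
settings).  2C ≡ fold 1.0; a C-value scale (×2) is available.  Background
is subtracted per nucleus from the supplied local average; a
global-background mode exists.  Negative folds are clipped to zero with a
warning; nuclei at the detector maximum can be flagged saturated and
excluded.  An optional trimmed-mean calibration guards against >2C nuclei
mislabelled as reference; the plain mean is the default.  Group
comparisons use the two-sided Mann-Whitney test (scipy implementation).
The generator draws C-classes (2C/4C/8C) from a mix that can differ by
marker status, with intensity `background + gain · C · ε` (ε lognormal,
CV 0.06); it does not emulate segmentation error, out-of-focus nuclei or
chromatin-state-dependent staining.

## GFR and ChIP closed forms

FITC-sinistrin kinetics follow a two-compartment model: amplitude
fractions `1 − w` and `w` (default w = 0.25) decaying with the
elimination half-life and a fast distribution half-life (default 2 min),
plus additive Gaussian noise (default SD 0.003 of the initial amplitude).
The published device formula gives
`GFR [µl/min] = 14616.8/t½ · bw/100`; the generator embeds the
elimination half-life by inverting it, so parameter recovery is checkable
end to end.  The two-compartment parameter defaults are this package's
own choice — no published values exist for them — set so the distribution
phase is clearly resolved at 0.5-min sampling over 90 min.  The default
fit discards the first 10 min and regresses log-fluorescence on time with
weights proportional to fluorescence (approximating least squares on the
raw scale and suppressing the noisy tail); residual contamination by the
distribution phase biases t½ by well under the 5% recovery tolerance.  A
full bi-exponential fit (scipy `curve_fit`, slow-phase half-life
reported) is the alternative mode.  Sham normalisation divides each
animal's baseline ratio by the sham-group *mean* ratio at the same time
point (mean vs median is unstated in the source; mean chosen).

ChIP enrichment is pure Ct arithmetic:
`ΔCt = Ct(bound) − [Ct(input) − log₂(dilution)]`,
`FR = 2^−(ΔCt_specific − ΔCt_IgG)`.  When both samples share the dilution
factor the log₂ terms cancel, so FR is dilution-invariant — asserted as a
property test.

## Pipeline and reproducibility

A run's global seed fans out as `seed + stage_index` so each stage is
independently reproducible; manifests record per-stage seeds and SHA-256
checksums of every output, and identical config + seed reproduce
byte-identical files.  CLI exit codes: 0 success, 2 bad configuration, 3
data error.  Percentages in the anchor report are printed to one decimal;
the cortical fold increase is printed to two decimals because the ratio
of the one-decimal means (13.3/5.9 = 2.25) sits exactly between
one-decimal roundings.

**Problem sizes.**  The test suite and the acceptance script use 10⁴
events per gating sample (the binomial error on a 39.8% fraction is then
~0.5%, well inside the ±1.5-point recovery bar), 3×10⁴ cells for the
recombination-probability simulation, 5×10⁴ cells per Confetti recovery
replicate (100 replicates per true fraction for interval coverage), 400
nuclei + 50 reference for imaging, and 181-point decay curves.  FCS
binary ingestion is not implemented; event tables are consumed as CSV
with the documented columns.

## Known limitations

* Gating assumes well-separated lognormal populations; heavily
  overlapping DNA peaks (CV ≳ 0.12) would erode the 4C/8C separation the
  nearest-peak rule relies on.
* The Confetti estimator treats every polyploid cell as exactly 4C; ≥8C
  cells with a third recombination would bias p̂ upward.
* The dead gate is DNA-defined (<2C); apoptotic cells that have not yet
  lost DNA are not separable in this model.
* Redistribution shares from group means and from per-animal means differ
  (42.7/49.2/8.0 vs 38.8/44.4 published per-mouse); the package computes
  either from the inputs it is given but cannot reconstruct per-animal
  values from group summaries.
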