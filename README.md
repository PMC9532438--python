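# ploidyscope

Quantification toolkit for tubular-cell (TC) polyploidy in the injured
kidney.  After acute kidney injury, surviving proximal tubule cells either
keep cycling, die, or endoreplicate into polyploid (≥4C) cells; this
package implements the measurement machinery used to quantify that
process, with seeded synthetic-data generators so every stage is testable
end to end without instrument exports:

* **FUCCI2aR flow-cytometry gating** (`ploidyscope.fucci`) — classify
  events by reporter state (mCherry-hCdt1 = G1, mVenus-hGem = S/G2/M) and
  DNA content into dead (<2C), diploid G1, cycling, and cycling /
  non-cycling polyploid classes; summarise per-sample fractions over
  induced singlets; redistribute the day-2 cycling pool over its day-3
  fates.
* **Confetti recombination model** (`ploidyscope.confetti`) — a diploid
  cell fixes one stochastic reporter colour, a 4C cell two; with three
  equiprobable scored colours a polyploid cell is bi-coloured with
  probability (n−1)/n = 2/3.  The module provides the closed-form outcome
  expectations, the recombination-efficiency normalisation
  b/e, and the model inversion p̂ = (3/2)·b with a percentile-bootstrap CI.
* **PicoGreen ploidy imaging** (`ploidyscope.imaging`) — per-nucleus DNA
  content as fold over a diploid internal control
  ((I − background)/reference mean; 2C ≡ 1.0), with two-sided
  Mann-Whitney marker-group comparison (e.g. YAP1⁺ vs YAP1⁻ nuclei).
* **Physiology closed forms** (`ploidyscope.physio`) — transcutaneous GFR
  from the FITC-sinistrin elimination half-life,
  GFR [µl/min] = 14616.8/t½ · bw/100, with log-linear or bi-exponential
  half-life fitting; ChIP-qPCR enrichment
  ΔCt = Ct(bound) − [Ct(input) − log₂(dilution)],
  FR = 2^−(ΔCt_ab − ΔCt_IgG).
* **Synthetic data** (`ploidyscope.synthetic`) — seeded generators for all
  of the above with ground-truth labels, including day-2/day-3/healthy
  event-composition presets.
* **Pipeline & CLI** (`ploidyscope.pipeline`, `ploidyscope` command) —
  seeded multi-stage runs with checksummed manifests and a report.

## Worked example

```python
from ploidyscope import synthetic, fucci
from ploidyscope.confetti import tally_confetti, estimate_polyploid_fraction

# day-2 post-injury composition: 39.8% cycling truth, 6% DNA CV, 5% doublets
cfg = synthetic.FucciSimConfig(
    n_cells=10_000, class_probs=synthetic.DAY2_PRESET.class_probs,
    dna_cv=0.06, doublet_rate=0.05, induction_rate=0.9, seed=202)
events = synthetic.simulate_fucci_events(cfg)
s = fucci.summarize_sample(fucci.classify_events(events))
print(f"cycling {100*s.cycling:.1f}%  polyploid {100*s.polyploid_total:.1f}%")

cells = synthetic.simulate_confetti(synthetic.ConfettiSimConfig(
    n_cells=50_000, polyploid_fraction=0.30, induction_efficiency=0.847, seed=5))
est = estimate_polyploid_fraction(tally_confetti(cells), seed=5)
print(f"bi-coloured {100*est.b_obs:.1f}%  p_hat {est.p_hat:.3f} "
      f"[{est.ci_low:.3f}, {est.ci_high:.3f}]")
```

prints

```
cycling 39.7%  polyploid 5.4%
bi-coloured 20.1%  p_hat 0.301 [0.295, 0.307]
```

— the gate recovers the simulated 39.8% day-2 cycling fraction within
binomial error, and inverting the 2/3 bi-coloured probability recovers the
simulated 30% polyploid fraction.

The same stages are available from the shell
(`ploidyscope simulate fucci --seed 3 --out events.csv`,
`ploidyscope gate --events events.csv --out calls.csv --summary summary.csv`,
`ploidyscope run --seed 5 --outdir run/`), and the numbered scripts under
`analysis/` chain them into a narrative cohort analysis
(01 simulate → 02 gate → 03 confetti → 04 biopsy ploidy → 05 GFR/ChIP),
writing summary tables under `results/`.

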