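#!/usr/bin/env python
"""Generate the synthetic study cohorts every later step consumes.

Simulates, with known ground truth: FUCCI2aR flow-event tables for healthy,
day-2 and day-3 post-injury compositions (6 animals each), a Confetti
colour table, a PicoGreen nuclei table with a YAP1+-enriched mix, a
two-compartment FITC-sinistrin decay cohort (sham and injured), and a
ChIP-qPCR Ct table.  Event-level tables go to scratch/data/ (bulky);
per-animal metadata to results/.
"""

import argparse
from pathlib import Path

import pandas as pd

from ploidyscope import synthetic

ROOT = Path(__file__).resolve().parents[1]

PRESETS = {
    "healthy": synthetic.HEALTHY_PRESET,
    "day2": synthetic.DAY2_PRESET,
    "day3": synthetic.DAY3_PRESET,
}


def main(seed: int) -> None:
    data = ROOT / "scratch" / "data"
    results = ROOT / "results"
    data.mkdir(parents=True, exist_ok=True)
    results.mkdir(exist_ok=True)

    import dataclasses

    n_mice = 6
    manifest = []
    for t, (label, preset) in enumerate(PRESETS.items()):
        for mouse in range(n_mice):
            cfg = dataclasses.replace(
                preset, n_cells=10_000, doublet_rate=0.05, induction_rate=0.9,
                seed=seed + 100 * t + mouse)
            ev = synthetic.simulate_fucci_events(cfg)
            path = data / f"fucci_{label}_m{mouse}.csv"
            ev.to_csv(path, index=False)
            manifest.append({"timepoint": label, "mouse": mouse,
                             "seed": cfg.seed, "path": str(path.relative_to(ROOT))})
    pd.DataFrame(manifest).to_csv(results / "fucci_cohort_manifest.csv", index=False)

    cells = synthetic.simulate_confetti(synthetic.ConfettiSimConfig(
        n_cells=50_000, polyploid_fraction=0.30, induction_efficiency=0.847,
        seed=seed + 1000))
    cells.to_csv(data / "confetti_cells.csv", index=False)

    nuclei = synthetic.simulate_nuclei(synthetic.NucleiSimConfig(
        n_nuclei=400, ploidy_mix=(0.9, 0.1, 0.0),
        marker_positive_mix=(0.45, 0.45, 0.10), n_reference=50,
        seed=seed + 2000))
    nuclei.to_csv(data / "nuclei.csv", index=False)

    rows = []
    for i in range(4):
        for group, gfr in (("sham", 250.0), ("iri", 150.0)):
            cfg = synthetic.DecaySimConfig(gfr_true=gfr, body_weight=25.0,
                                           seed=seed + 3000 + 10 * i + (group == "iri"))
            curve = synthetic.simulate_decay(cfg)
            df = pd.DataFrame({"time_min": curve.time,
                               "fluorescence": curve.fluorescence})
            df["animal_id"] = f"{group}{i}"
            df["group"] = group
            df["body_weight_g"] = cfg.body_weight
            df["gfr_true"] = gfr
            rows.append(df)
    pd.concat(rows).to_csv(data / "decay_cohort.csv", index=False)

    synthetic.simulate_chip(synthetic.ChipSimConfig(
        true_fr=4.0, noise_sd=0.15, seed=seed + 4000)).to_csv(
        data / "chip_ct.csv", index=False)

    print(f"wrote {3 * n_mice} FUCCI tables, confetti, nuclei, decay and ChIP "
          f"tables under {data.relative_to(ROOT)}/")


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    main(ap.parse_args().seed)
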