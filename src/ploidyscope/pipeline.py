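"""Reproducible multi-stage runs: configuration, manifest, report.

A run executes a subset of the pipeline stages on synthetic inputs with a
single global seed that fans out deterministically to stage-local seeds
(``seed + stage index``), writes every table as CSV into the run directory
and records a manifest (seeds, outputs, SHA-256 checksums).  Identical
config + seed therefore reproduce byte-identical outputs.

The ``paper_numbers`` stage recomputes the headline closed-form quantities
of the analysis (recombination combinatorics, efficiency-normalised
bi-coloured percentage, cortex fold increase, GFR formula unit check,
ChIP fold-enrichment example) from their defining arithmetic.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd

from . import confetti as cf
from . import fucci, imaging, physio, synthetic
from .errors import ConfigError, DataError

__all__ = ["RunConfig", "run_pipeline", "report", "STAGES"]

log = logging.getLogger("ploidyscope")

STAGES = ("fucci", "confetti", "nuclei", "gfr", "chip", "paper_numbers")


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one pipeline run.

    ``stage_params`` holds per-stage keyword overrides for the generator
    configs (e.g. ``{"fucci": {"n_cells": 5000}}``); unknown stages are
    rejected.  ``events_csv`` optionally points the fucci stage at an
    existing event table instead of simulating one.
    """

    stages: tuple = STAGES
    seed: int = 0
    outdir: str = "run"
    stage_params: dict = field(default_factory=dict)
    events_csv: str | None = None

    def __post_init__(self):
        for s in self.stages:
            if s not in STAGES:
                raise ConfigError(f"unknown stage {s!r}; valid stages: {STAGES}")
        for s in self.stage_params:
            if s not in STAGES:
                raise ConfigError(f"stage_params for unknown stage {s!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError("run config must be a YAML mapping")
        known = {"stages", "seed", "outdir", "stage_params", "events_csv"}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.10g")


def _stage_seed(cfg: RunConfig, stage: str) -> int:
    return cfg.seed + STAGES.index(stage)


def _run_fucci(cfg: RunConfig, outdir: Path) -> list[Path]:
    params = dict(cfg.stage_params.get("fucci", {}))
    if cfg.events_csv is not None:
        path = Path(cfg.events_csv)
        if not path.exists():
            raise DataError(f"events CSV not found: {path}")
        events = pd.read_csv(path)
    else:
        preset = params.pop("preset", "day2")
        base = {"day2": synthetic.DAY2_PRESET, "day3": synthetic.DAY3_PRESET,
                "healthy": synthetic.HEALTHY_PRESET}.get(preset)
        if base is None:
            raise ConfigError(f"unknown fucci preset {preset!r}")
        if "class_probs" in params:
            params["class_probs"] = tuple(params["class_probs"])
        sim = replace(base, seed=_stage_seed(cfg, "fucci"), **params)
        events = synthetic.simulate_fucci_events(sim)
    calls = fucci.classify_events(events)
    summary = fucci.summarize_sample(calls)
    events_path, calls_path, summary_path = (
        outdir / "fucci_events.csv", outdir / "fucci_calls.csv", outdir / "fucci_summary.csv",
    )
    _write(events, events_path)
    _write(pd.concat([events[["event_id"]], calls.reset_index(drop=True)], axis=1), calls_path)
    _write(pd.DataFrame([summary.as_dict()]), summary_path)
    log.info("fucci: %d induced singlets, cycling %.1f%%, polyploid %.1f%%",
             summary.n_events, 100 * summary.cycling, 100 * summary.polyploid_total)
    return [events_path, calls_path, summary_path]


def _run_confetti(cfg: RunConfig, outdir: Path) -> list[Path]:
    params = dict(cfg.stage_params.get("confetti", {}))
    n_bootstrap = params.pop("n_bootstrap", 2000)
    if "colour_probs" in params:
        params["colour_probs"] = tuple(params["colour_probs"])
    seed = _stage_seed(cfg, "confetti")
    sim = synthetic.ConfettiSimConfig(seed=seed, **params)
    cells = synthetic.simulate_confetti(sim)
    tally = cf.tally_confetti(cells, region="simulated")
    est = cf.estimate_polyploid_fraction(tally, n_bootstrap=n_bootstrap, seed=seed)
    cells_path, est_path = outdir / "confetti_cells.csv", outdir / "confetti_estimate.csv"
    _write(cells, cells_path)
    _write(pd.DataFrame([{
        "region": tally.region,
        "n_total_tc": tally.n_total_tc,
        "n_coloured": tally.n_coloured,
        "n_bicoloured": tally.n_bicoloured,
        "n_gfp_excluded": tally.n_gfp_excluded,
        "b_obs_pct": 100 * est.b_obs,
        "efficiency_pct": 100 * est.efficiency,
        "b_corrected_pct": est.b_corrected,
        "p_hat": est.p_hat,
        "ci_low": est.ci_low,
        "ci_high": est.ci_high,
    }]), est_path)
    log.info("confetti: b_obs %.1f%%, p_hat %.3f [%.3f, %.3f]",
             100 * est.b_obs, est.p_hat, est.ci_low, est.ci_high)
    return [cells_path, est_path]


def _run_nuclei(cfg: RunConfig, outdir: Path) -> list[Path]:
    params = dict(cfg.stage_params.get("nuclei", {}))
    for key in ("ploidy_mix", "marker_positive_mix"):
        if params.get(key) is not None:
            params[key] = tuple(params[key])
    sim = synthetic.NucleiSimConfig(seed=_stage_seed(cfg, "nuclei"), **params)
    nuclei = synthetic.simulate_nuclei(sim)
    ref = imaging.calibrate_diploid_reference(nuclei)
    folds = imaging.ploidy_fold(nuclei, ref)
    body = folds[~folds["reference_diploid"].astype(bool)]
    comparison = imaging.compare_marker_groups(body["fold"], body["marker_positive"])
    nuclei_path, folds_path, cmp_path = (
        outdir / "nuclei.csv", outdir / "nuclei_folds.csv", outdir / "marker_comparison.csv",
    )
    _write(nuclei, nuclei_path)
    _write(folds, folds_path)
    _write(pd.DataFrame([comparison.__dict__]), cmp_path)
    log.info("nuclei: reference mean %.2f, marker medians %.2f vs %.2f (p=%.3g)",
             ref, comparison.median_positive, comparison.median_negative, comparison.p_value)
    return [nuclei_path, folds_path, cmp_path]


def _run_gfr(cfg: RunConfig, outdir: Path) -> list[Path]:
    params = dict(cfg.stage_params.get("gfr", {}))
    sim = synthetic.DecaySimConfig(seed=_stage_seed(cfg, "gfr"), **params)
    curve = synthetic.simulate_decay(sim)
    t_half = physio.fit_halflife(curve)
    gfr = physio.gfr_from_halflife(t_half, curve.body_weight)
    curve_path, fit_path = outdir / "gfr_curve.csv", outdir / "gfr_fit.csv"
    _write(pd.DataFrame({"time_min": curve.time, "fluorescence": curve.fluorescence,
                         "body_weight_g": curve.body_weight}), curve_path)
    _write(pd.DataFrame([{
        "t_half_min": t_half,
        "body_weight_g": curve.body_weight,
        "gfr_ul_min": gfr,
        "gfr_true_ul_min": sim.gfr_true,
    }]), fit_path)
    log.info("gfr: fitted t_half %.2f min -> GFR %.1f ul/min (true %.1f)",
             t_half, gfr, sim.gfr_true)
    return [curve_path, fit_path]


def _run_chip(cfg: RunConfig, outdir: Path) -> list[Path]:
    params = dict(cfg.stage_params.get("chip", {}))
    sim = synthetic.ChipSimConfig(seed=_stage_seed(cfg, "chip"), **params)
    table = synthetic.simulate_chip(sim)

    def _mean_sample(antibody: str) -> physio.ChipSample:
        rows = table[table["antibody"] == antibody]
        return physio.ChipSample(
            ct_bound=float(rows["ct_bound"].mean()),
            ct_input=float(rows["ct_input"].mean()),
            input_dilution_factor=float(rows["dilution_factor"].iloc[0]),
            antibody=antibody,
        )

    fr = physio.chip_fold_enrichment(_mean_sample("specific"), _mean_sample("IgG"))
    ct_path, fr_path = outdir / "chip_ct.csv", outdir / "chip_enrichment.csv"
    _write(table, ct_path)
    _write(pd.DataFrame([{"locus": sim.locus, "fold_enrichment": fr,
                          "true_fr": sim.true_fr}]), fr_path)
    log.info("chip: fold enrichment %.2f (true %.2f)", fr, sim.true_fr)
    return [ct_path, fr_path]


def _run_paper_numbers(cfg: RunConfig, outdir: Path) -> list[Path]:
    params = dict(cfg.stage_params.get("paper_numbers", {}))
    b_obs_pct = params.pop("b_obs_pct", 13.3)
    efficiency = params.pop("efficiency", 0.847)
    sham_pct = params.pop("sham_pct", 5.9)
    c2, p3_new, d3 = params.pop("redistribution", (0.398, 0.17, 0.196))
    shares = fucci.redistribute_cycling(c2, p3_new, d3)
    fr_example = physio.chip_fold_enrichment(
        physio.ChipSample(25.0, 20.0, 10.0, "specific"),
        physio.ChipSample(27.0, 20.0, 10.0, "IgG"),
    )
    rows = [
        {"quantity": "bicoloured_probability_polyploid",
         "value": round(cf.p_bicoloured(3), 4)},
        {"quantity": "duplicate_probability_polyploid",
         "value": round(1 - cf.p_bicoloured(3), 4)},
        {"quantity": "bicoloured_pct_efficiency_corrected",
         "value": round(cf.correct_for_efficiency(b_obs_pct, efficiency), 1)},
        {"quantity": "cortex_bicoloured_fold_increase",
         "value": round(b_obs_pct / sham_pct, 2)},
        {"quantity": "day2_cycling_became_polyploid_pct",
         "value": round(100 * shares["became_polyploid"], 1)},
        {"quantity": "day2_cycling_died_pct",
         "value": round(100 * shares["died"], 1)},
        {"quantity": "day2_cycling_still_cycling_pct",
         "value": round(100 * shares["still_cycling"], 1)},
        {"quantity": "gfr_formula_unit_check_ul_min",
         "value": round(physio.gfr_from_halflife(synthetic.GFR_CONVERSION_UL, 100.0), 4)},
        {"quantity": "chip_fold_enrichment_example",
         "value": round(fr_example, 4)},
    ]
    path = outdir / "paper_numbers.csv"
    _write(pd.DataFrame(rows), path)
    return [path]


_RUNNERS = {
    "fucci": _run_fucci,
    "confetti": _run_confetti,
    "nuclei": _run_nuclei,
    "gfr": _run_gfr,
    "chip": _run_chip,
    "paper_numbers": _run_paper_numbers,
}


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the requested stages and write a run manifest.

    Stages run in canonical order regardless of how they are listed.
    Returns the manifest dict (also written to ``<outdir>/manifest.json``),
    mapping each stage to its seed and output checksums.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    import ploidyscope

    manifest: dict = {
        "seed": cfg.seed,
        "version": ploidyscope.__version__,
        "stages": {},
    }
    for stage in STAGES:
        if stage not in cfg.stages:
            continue
        log.info("running stage %s (seed %d)", stage, _stage_seed(cfg, stage))
        outputs = _RUNNERS[stage](cfg, outdir)
        manifest["stages"][stage] = {
            "seed": _stage_seed(cfg, stage),
            "outputs": {p.name: _sha256(p) for p in outputs},
        }
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


def report(manifest: dict, outdir: str | Path | None = None) -> pd.DataFrame:
    """Render a human-readable summary of a completed run.

    Collects the per-stage result tables referenced by the manifest into a
    single long-format frame (section, quantity, value), verifies that the
    FUCCI fractions sum to 100%, and writes ``report.csv`` next to the run
    outputs.  Raises :class:`DataError` on an empty or incomplete manifest.
    """
    if not manifest.get("stages"):
        raise DataError("manifest contains no completed stages")
    outdir = Path(outdir) if outdir is not None else Path(".")
    rows: list[dict] = []

    def _need(stage: str, name: str) -> Path:
        entry = manifest["stages"][stage]["outputs"]
        if name not in entry:
            raise DataError(f"manifest stage {stage!r} lacks output {name!r}")
        path = outdir / name
        if not path.exists():
            raise DataError(f"output file missing: {path}")
        return path

    stages = manifest["stages"]
    if "fucci" in stages:
        s = pd.read_csv(_need("fucci", "fucci_summary.csv")).iloc[0]
        total = s["dead"] + s["diploid_G1"] + s["cycling"] + s["polyploid_total"]
        if abs(100 * total - 100.0) > 0.01:
            raise DataError(f"FUCCI fractions sum to {100 * total:.3f}%, not 100%")
        for key in ("dead", "diploid_G1", "cycling", "polyploid_total",
                    "polyploid_cycling", "polyploid_noncycling"):
            rows.append({"section": "fucci", "quantity": f"{key}_pct",
                         "value": round(100 * s[key], 1)})
    if "confetti" in stages:
        e = pd.read_csv(_need("confetti", "confetti_estimate.csv")).iloc[0]
        rows += [
            {"section": "confetti", "quantity": "bicoloured_obs_pct",
             "value": round(e["b_obs_pct"], 1)},
            {"section": "confetti", "quantity": "bicoloured_over_efficiency_pct",
             "value": round(e["b_corrected_pct"], 1)},
            {"section": "confetti", "quantity": "polyploid_fraction_3_2_b",
             "value": round(e["p_hat"], 3)},
        ]
    if "nuclei" in stages:
        c = pd.read_csv(_need("nuclei", "marker_comparison.csv")).iloc[0]
        rows += [
            {"section": "imaging", "quantity": "median_fold_marker_positive",
             "value": round(c["median_positive"], 3)},
            {"section": "imaging", "quantity": "median_fold_marker_negative",
             "value": round(c["median_negative"], 3)},
            {"section": "imaging", "quantity": "mannwhitney_p", "value": c["p_value"]},
        ]
    if "gfr" in stages:
        g = pd.read_csv(_need("gfr", "gfr_fit.csv")).iloc[0]
        rows += [
            {"section": "gfr", "quantity": "t_half_min", "value": round(g["t_half_min"], 2)},
            {"section": "gfr", "quantity": "gfr_ul_min", "value": round(g["gfr_ul_min"], 1)},
        ]
    if "chip" in stages:
        c = pd.read_csv(_need("chip", "chip_enrichment.csv")).iloc[0]
        rows.append({"section": "chip", "quantity": "fold_enrichment",
                     "value": round(c["fold_enrichment"], 2)})
    if "paper_numbers" in stages:
        for _, r in pd.read_csv(_need("paper_numbers", "paper_numbers.csv")).iterrows():
            rows.append({"section": "anchors", "quantity": r["quantity"],
                         "value": r["value"]})

    out = pd.DataFrame(rows)
    out.to_csv(outdir / "report.csv", index=False)
    return out
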