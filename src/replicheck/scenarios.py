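"""End-to-end scenario runs: simulation -> pipeline -> analysis tables.

Two packaged scenarios mirror the study designs the package targets:

* ``g1-release`` — an S-phase-release time course under configurable
  checkpoint arms (G1/S transcription delay; probabilistic origin-firing
  block), analysed into per-origin replication amounts, trep-quintile
  summaries and quintile t-tests.

* ``g2-rerep`` — a G2/M re-replication induction run over strain-like
  variants (licensing control intact; licensing mutant; licensing mutant
  with the checkpoint brake on re-initiation relieved), analysed into gain
  segments, per-chromosome re-replication indices and marker-origin peak
  heights, plus a simulated RRIGA plating experiment.

Runs are deterministic given the seed: re-running a scenario with the same
seed reproduces byte-identical TSV outputs.  The seed and the full effective
configuration are echoed into every output for provenance.
"""

from __future__ import annotations

import importlib.resources
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .genome_model import (GenomeSpec, Origin, default_genome, default_origins,
                           load_genome, load_origins)
from .origin_analysis import (compare_quintiles, origin_replication,
                              quintile_summary)
from .profile_pipeline import (CopyProfile, calibrate_baseline, flat_profile,
                               normalize_ratio, smooth, write_bedgraph)
from .rerep_analysis import (chromosome_rerep_index, gain_segments,
                             peak_height, segments_frame)
from .rriga_stats import compare_strains, percent_leu, results_frame
from .simulate import (CheckpointConfig, RerepConfig, SimConfig, sample_reads,
                       simulate_g2_rereplication, simulate_rriga_counts,
                       simulate_sphase)

__all__ = [
    "ScenarioConfigError",
    "load_scenario_config",
    "packaged_scenario_path",
    "run_scenario",
]

SCENARIOS = ("g1-release", "g2-rerep")

DEFAULTS: dict = {
    "scenario": None,
    "seed": 1,
    "genome": None,   # path to a genome TSV; None = packaged toy genome
    "origins": None,  # path to an origin TSV; None = packaged registry
    "sim": {"fork_speed": 1.5, "n_cells": 500, "read_depth": 100.0,
            "bin_width": 1000},
    "checkpoint": {"transcription_delay": 0.0, "firing_block_prob": 0.0,
                   "release_time": 60.0, "block_scope": "all"},
    "timepoints": [10.0, 20.0, 30.0],
    "rerep": {
        "fork_extent_mean": 10.0,
        "induction_time": 240.0,
        "variants": [
            {"name": "licensing-control", "licensing_enabled": False,
             "rate_scale": 1.0},
            {"name": "licensing-mutant", "licensing_enabled": True,
             "rate_scale": 1.0},
            {"name": "licensing-mutant checkpoint-relieved",
             "licensing_enabled": True, "rate_scale": 3.0},
        ],
    },
    "pipeline": {"smooth_window": 15, "min_ref_count": 10.0},
    "analysis": {"halfwidth": 5000, "gain_threshold": 0.2, "min_bins": 5,
                 "peak_origin": "ARS317"},
    "rriga": {
        "enabled": True,
        "n_viable_per_ml": 1.0e7,
        "pre_induction_p_amp": 1.0e-6,
        "n_replicates": 3,
        "strains": [
            {"name": "licensing-mutant", "p_amp": 0.001},
            {"name": "licensing-mutant checkpoint-relieved", "p_amp": 0.002},
        ],
        "compare": ["licensing-mutant", "licensing-mutant checkpoint-relieved"],
    },
}


class ScenarioConfigError(ValueError):
    """A scenario configuration violated the schema; message carries the field path."""


def _merge(base: dict, override: dict, path: str = "") -> dict:
    out = dict(base)
    for key, val in override.items():
        here = f"{path}.{key}" if path else key
        if key not in base:
            raise ScenarioConfigError(f"{here}: unknown configuration field")
        if isinstance(base[key], dict) and isinstance(val, dict):
            out[key] = _merge(base[key], val, here)
        else:
            out[key] = val
    return out


def _coerce_numbers(cfg: dict) -> None:
    # YAML 1.1 reads exponent forms like 1.0e7 as strings; coerce in place
    def as_float(d, key, path):
        try:
            d[key] = float(d[key])
        except (TypeError, ValueError):
            raise ScenarioConfigError(f"{path}: expected a number, got {d[key]!r}")

    for key in ("fork_speed", "read_depth"):
        as_float(cfg["sim"], key, f"sim.{key}")
    for key in ("transcription_delay", "firing_block_prob", "release_time"):
        as_float(cfg["checkpoint"], key, f"checkpoint.{key}")
    cfg["timepoints"] = [float(t) for t in cfg["timepoints"]]
    for key in ("fork_extent_mean", "induction_time"):
        as_float(cfg["rerep"], key, f"rerep.{key}")
    for i, var in enumerate(cfg["rerep"]["variants"]):
        if "rate_scale" in var:
            as_float(var, "rate_scale", f"rerep.variants[{i}].rate_scale")
    as_float(cfg["pipeline"], "min_ref_count", "pipeline.min_ref_count")
    as_float(cfg["analysis"], "gain_threshold", "analysis.gain_threshold")
    for key in ("n_viable_per_ml", "pre_induction_p_amp"):
        as_float(cfg["rriga"], key, f"rriga.{key}")
    for i, s in enumerate(cfg["rriga"]["strains"]):
        if "p_amp" in s:
            as_float(s, "p_amp", f"rriga.strains[{i}].p_amp")


def _require(cond: bool, path: str, message: str) -> None:
    if not cond:
        raise ScenarioConfigError(f"{path}: {message}")


def validate_config(config: dict) -> dict:
    """Apply defaults and validate; returns the full effective configuration."""
    if not isinstance(config, dict):
        raise ScenarioConfigError("top level: expected a mapping")
    cfg = _merge(DEFAULTS, config)
    _coerce_numbers(cfg)
    _require(cfg["scenario"] in SCENARIOS, "scenario",
             f"must be one of {SCENARIOS}")
    _require(isinstance(cfg["seed"], int) and cfg["seed"] >= 0, "seed",
             "must be a non-negative integer")
    sim = cfg["sim"]
    _require(sim["fork_speed"] > 0, "sim.fork_speed", "must be > 0")
    _require(int(sim["n_cells"]) > 0, "sim.n_cells", "must be > 0")
    _require(sim["read_depth"] > 0, "sim.read_depth", "must be > 0")
    _require(int(sim["bin_width"]) > 0, "sim.bin_width", "must be > 0")
    chk = cfg["checkpoint"]
    _require(0 <= chk["firing_block_prob"] <= 1, "checkpoint.firing_block_prob",
             "must be in [0, 1]")
    _require(chk["transcription_delay"] >= 0, "checkpoint.transcription_delay",
             "must be >= 0")
    _require(chk["block_scope"] in ("all", "early", "late"),
             "checkpoint.block_scope", "must be 'all', 'early' or 'late'")
    _require(len(cfg["timepoints"]) >= 1 and all(t >= 0 for t in cfg["timepoints"]),
             "timepoints", "must be a non-empty list of minutes >= 0")
    rr = cfg["rerep"]
    _require(rr["fork_extent_mean"] > 0, "rerep.fork_extent_mean", "must be > 0")
    _require(len(rr["variants"]) >= 1, "rerep.variants", "need at least one variant")
    for i, var in enumerate(rr["variants"]):
        _require("name" in var, f"rerep.variants[{i}].name", "is required")
        _require(var.get("rate_scale", 1.0) >= 0,
                 f"rerep.variants[{i}].rate_scale", "must be >= 0")
    pl = cfg["pipeline"]
    _require(pl["smooth_window"] >= 1 and pl["smooth_window"] % 2 == 1,
             "pipeline.smooth_window", "must be odd and >= 1")
    _require(pl["min_ref_count"] >= 0, "pipeline.min_ref_count", "must be >= 0")
    an = cfg["analysis"]
    _require(an["halfwidth"] > 0, "analysis.halfwidth", "must be > 0")
    _require(an["gain_threshold"] >= 0, "analysis.gain_threshold", "must be >= 0")
    _require(an["min_bins"] >= 1, "analysis.min_bins", "must be >= 1")
    rg = cfg["rriga"]
    _require(rg["n_viable_per_ml"] >= 0, "rriga.n_viable_per_ml", "must be >= 0")
    for i, s in enumerate(rg["strains"]):
        _require("name" in s and "p_amp" in s, f"rriga.strains[{i}]",
                 "needs name and p_amp")
        _require(0 <= s["p_amp"] <= 1, f"rriga.strains[{i}].p_amp",
                 "must be in [0, 1]")
    _require(0 <= rg["pre_induction_p_amp"] <= 1, "rriga.pre_induction_p_amp",
             "must be in [0, 1]")
    return cfg


def load_scenario_config(path) -> dict:
    """Load and validate a scenario YAML file."""
    try:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    except yaml.YAMLError as exc:
        raise ScenarioConfigError(f"invalid YAML: {exc}") from exc
    return validate_config(raw or {})


def packaged_scenario_path(name: str):
    """Path to a packaged scenario config ('g1-release' or 'g2-rerep')."""
    fname = {"g1-release": "g1_release.yaml", "g2-rerep": "g2_rerep.yaml"}[name]
    return importlib.resources.files("replicheck.data.scenarios").joinpath(fname)


def load_packaged_scenario(name: str) -> dict:
    with importlib.resources.as_file(packaged_scenario_path(name)) as p:
        return load_scenario_config(p)


def _subseed(seed: int, *tags: int) -> list[int]:
    return [int(seed), *map(int, tags)]


def _header(cfg: dict, extra: list[str] | None = None) -> list[str]:
    lines = [
        f"replicheck {__version__}",
        f"scenario: {cfg['scenario']}",
        f"seed: {cfg['seed']}",
        "config: " + json.dumps(cfg, sort_keys=True, default=str),
    ]
    return lines + (extra or [])


def _write_table(df: pd.DataFrame, path: Path, header_lines: list[str]) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def _load_world(cfg: dict) -> tuple[GenomeSpec, list[Origin]]:
    genome = load_genome(cfg["genome"]) if cfg["genome"] else default_genome()
    origins = (load_origins(cfg["origins"], genome) if cfg["origins"]
               else default_origins(genome))
    return genome, origins


def _run_pipeline(sample_cov, reference_cov, baseline: int, cfg: dict) -> CopyProfile:
    ratio = normalize_ratio(sample_cov, reference_cov,
                            min_ref_count=cfg["pipeline"]["min_ref_count"])
    window = cfg["pipeline"]["smooth_window"]
    calibrated = calibrate_baseline(ratio, baseline, presmooth_window=window)
    return smooth(calibrated, window=window)


def _run_g1_release(cfg: dict, out: Path) -> dict:
    genome, origins = _load_world(cfg)
    seed = cfg["seed"]
    sim = SimConfig(fork_speed=cfg["sim"]["fork_speed"],
                    n_cells=int(cfg["sim"]["n_cells"]),
                    read_depth=cfg["sim"]["read_depth"], seed=seed,
                    bin_width=int(cfg["sim"]["bin_width"]))
    chk = CheckpointConfig(**cfg["checkpoint"])
    header = _header(cfg)
    all_reps = []
    summaries = []
    comparisons = []
    for ti, t in enumerate(cfg["timepoints"]):
        truth = simulate_sphase(genome, origins, t, sim, chk)
        sample_cov = sample_reads(truth, sim, seed=_subseed(seed, 1, ti),
                                  sample=f"t{t:g}")
        reference_cov = sample_reads(flat_profile(genome, sim.bin_width, 1.0),
                                     sim, seed=_subseed(seed, 2, ti),
                                     sample="G1-reference")
        profile = _run_pipeline(sample_cov, reference_cov, baseline=1, cfg=cfg)
        profile.write_tsv(out / f"profile_t{t:g}.tsv",
                          header_lines=header + [f"timepoint_min: {t:g}"])
        reps = origin_replication(profile, origins, timepoint=t,
                                  halfwidth=int(cfg["analysis"]["halfwidth"]))
        all_reps.extend(reps)
        summ = quintile_summary(reps).assign(timepoint=t)
        summaries.append(summ)
        by_q = {q: [r for r in reps if r.quintile == q] for q in range(1, 6)}
        for qa, qb in [(1, 2), (2, 3), (3, 4), (4, 5), (1, 5)]:
            if len(by_q[qa]) >= 2 and len(by_q[qb]) >= 2:
                c = compare_quintiles(by_q[qa], by_q[qb],
                                      labels=(f"Q{qa}", f"Q{qb}"))
                comparisons.append({"timepoint": t, "group_a": f"Q{qa}",
                                    "group_b": f"Q{qb}", "n_a": c.n[0],
                                    "n_b": c.n[1], "mean_a": c.means[0],
                                    "mean_b": c.means[1], "t": c.t, "p": c.p})
    reps_df = pd.DataFrame([r.__dict__ for r in all_reps])
    _write_table(reps_df, out / "origin_replication.tsv", header)
    summary_df = pd.concat(summaries, ignore_index=True)
    _write_table(summary_df, out / "quintile_summary.tsv", header)
    comp_df = pd.DataFrame(comparisons)
    _write_table(comp_df, out / "quintile_comparisons.tsv", header)
    _write_summary_text(out, cfg, [
        ("Per-quintile replication amounts", summary_df),
        ("Quintile t-tests", comp_df),
    ])
    return {"origin_replication": reps_df, "quintile_summary": summary_df,
            "quintile_comparisons": comp_df}


def _run_g2_rerep(cfg: dict, out: Path) -> dict:
    genome, origins = _load_world(cfg)
    seed = cfg["seed"]
    sim = SimConfig(fork_speed=cfg["sim"]["fork_speed"],
                    n_cells=int(cfg["sim"]["n_cells"]),
                    read_depth=cfg["sim"]["read_depth"], seed=seed,
                    bin_width=int(cfg["sim"]["bin_width"]))
    header = _header(cfg)
    origin_by_name = {o.name: o for o in origins}
    peak_origin = origin_by_name.get(cfg["analysis"]["peak_origin"])
    index_rows = []
    seg_frames = []
    peak_rows = []
    for vi, var in enumerate(cfg["rerep"]["variants"]):
        rr = RerepConfig(induction_time=cfg["rerep"]["induction_time"],
                         fork_extent_mean=cfg["rerep"]["fork_extent_mean"],
                         licensing_enabled=bool(var.get("licensing_enabled", True)),
                         rate_scale=float(var.get("rate_scale", 1.0)))
        truth = simulate_g2_rereplication(genome, origins, sim, rr)
        sample_cov = sample_reads(truth, sim, seed=_subseed(seed, 3, vi),
                                  sample=var["name"])
        reference_cov = sample_reads(flat_profile(genome, sim.bin_width, 2.0),
                                     sim, seed=_subseed(seed, 4, vi),
                                     sample="0hr-reference")
        profile = _run_pipeline(sample_cov, reference_cov, baseline=2, cfg=cfg)
        safe = var["name"].replace(" ", "_")
        profile.write_tsv(out / f"profile_{safe}.tsv",
                          header_lines=header + [f"variant: {var['name']}"])
        segs = gain_segments(profile,
                             threshold=cfg["analysis"]["gain_threshold"],
                             min_bins=int(cfg["analysis"]["min_bins"]))
        seg_frames.append(segments_frame(segs).assign(variant=var["name"]))
        idx = chromosome_rerep_index(profile)
        for chrom, value in idx.items():
            index_rows.append({"variant": var["name"], "chrom": chrom,
                               "rerep_index": value})
        if peak_origin is not None:
            pk = peak_height(profile, peak_origin,
                             halfwidth=int(cfg["analysis"]["halfwidth"]))
            peak_rows.append({"variant": var["name"],
                              "origin": peak_origin.name,
                              "peak_copy": pk})
    index_df = pd.DataFrame(index_rows)
    index_df["rank"] = index_df.groupby("variant")["rerep_index"].rank(
        ascending=False, method="first").astype(int)
    nonempty = [f for f in seg_frames if not f.empty]
    seg_df = (pd.concat(nonempty, ignore_index=True) if nonempty
              else seg_frames[0])
    peak_df = pd.DataFrame(peak_rows)
    _write_table(index_df, out / "rerep_index.tsv", header)
    _write_table(seg_df, out / "gain_segments.tsv", header)
    _write_table(peak_df, out / "origin_peaks.tsv", header)

    tables = [("Per-chromosome re-replication index", index_df),
              ("Gain segments", seg_df),
              ("Marker-origin peak heights", peak_df)]
    results = {"rerep_index": index_df, "gain_segments": seg_df,
               "origin_peaks": peak_df}

    if cfg["rriga"]["enabled"]:
        rg = cfg["rriga"]
        counts_frames = []
        rriga_results = []
        for si, strain in enumerate(rg["strains"]):
            for pi, (tp, p_amp) in enumerate(
                [("pre-induction", rg["pre_induction_p_amp"]),
                 ("induced", strain["p_amp"])]
            ):
                counts = simulate_rriga_counts(
                    p_amp=p_amp, n_viable_per_ml=rg["n_viable_per_ml"],
                    seed=int(np.random.default_rng(
                        _subseed(seed, 5, si, pi)).integers(2**31)),
                    strain=strain["name"], timepoint=tp,
                    n_replicates=int(rg["n_replicates"]))
                counts_frames.append(counts)
                rriga_results.append(percent_leu(counts))
        counts_df = pd.concat(counts_frames, ignore_index=True)
        res_df = results_frame(rriga_results)
        _write_table(counts_df, out / "rriga_counts.tsv", header)
        _write_table(res_df, out / "rriga_results.tsv", header)
        comp_rows = []
        if rg["compare"]:
            a_name, b_name = rg["compare"]
            induced = {r.strain: r for r in rriga_results
                       if r.timepoint == "induced"}
            c = compare_strains(induced[a_name], induced[b_name])
            comp_rows.append({"strain_a": a_name, "strain_b": b_name,
                              "mean_a": c.means[0], "mean_b": c.means[1],
                              "t": c.t, "p": c.p, "test": c.flavour})
        comp_df = pd.DataFrame(comp_rows)
        _write_table(comp_df, out / "rriga_comparison.tsv", header)
        tables += [("RRIGA %Leu+ per strain", res_df),
                   ("RRIGA strain comparison", comp_df)]
        results.update({"rriga_results": res_df, "rriga_comparison": comp_df,
                        "rriga_counts": counts_df})

    _write_summary_text(out, cfg, tables)
    return results


def _write_summary_text(out: Path, cfg: dict,
                        tables: list[tuple[str, pd.DataFrame]]) -> None:
    with open(out / "summary.txt", "w") as fh:
        for line in _header(cfg):
            fh.write(f"# {line}\n")
        for title, df in tables:
            fh.write(f"\n== {title} ==\n")
            if df.empty:
                fh.write("(empty)\n")
            else:
                fh.write(df.to_string(index=False, float_format="%.4g"))
                fh.write("\n")


def run_scenario(config: dict | str, out_dir, seed: int | None = None) -> dict:
    """Run a scenario end to end and write its output bundle.

    ``config`` is a validated config dict, a path to a YAML file, or the name
    of a packaged scenario.  ``seed`` overrides the config seed.  Returns the
    result tables keyed by name.
    """
    if isinstance(config, str):
        if config in SCENARIOS:
            cfg = load_packaged_scenario(config)
        else:
            cfg = load_scenario_config(config)
    else:
        cfg = validate_config(config)
    if seed is not None:
        cfg["seed"] = int(seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if cfg["scenario"] == "g1-release":
        return _run_g1_release(cfg, out)
    return _run_g2_rerep(cfg, out)
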