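"""End-to-end orchestration: simulate/read -> filter -> polarize -> analyse.

A run is driven by a :class:`RunConfig` (usually loaded from YAML): exactly
one of a simulation block or a VCF input block, plus filter thresholds, ROH
parameters and output location.  Every stage writes its TSV next to a
``manifest.json`` that echoes the configuration, the seed, library versions
and a per-stage site/sample count ledger, so a run is reproducible and its
filter provenance auditable.  Identical (config, seed) produces identical
outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .callset import (CohortCallset, FilterSpec, annotate_sites, apply_site_filters,
                      load_annotations, polarize_to_ancestral, read_vcf,
                      restrict_complete_cases, write_tsv)
from .diversity import het_per_kb, pairwise_group_test, pi_windows
from .load import GerpBins, load_summary
from .roh import PRESETS, ROHParams, detect_roh_all, froh_table
from .rxy import FreqTable, rxy_jackknife, rxy_point, sharing_summary
from .simulate import SimulationConfig, simulate_cohort, write_cohort

log = logging.getLogger("bottleload")

ALL_STAGES = ("diversity", "roh", "load", "rxy")


class PipelineError(ValueError):
    pass


@dataclass
class RunConfig:
    outdir: str
    seed: int = 0
    simulate: dict | None = None          # SimulationConfig fields
    input: dict | None = None             # vcf, populations, [gerp, impact, ancestral]
    filters: dict | None = None           # FilterSpec fields; None = skip filtering
    roh: dict = field(default_factory=lambda: {"preset": "desk"})
    gerp_bins: dict | None = None
    genome_bp: float | None = None
    stages: tuple = ALL_STAGES
    rxy_categories: tuple = ("MODERATE", "HIGH")

    def __post_init__(self) -> None:
        if (self.simulate is None) == (self.input is None):
            raise PipelineError("exactly one of 'simulate' and 'input' must be set")
        if self.input is not None:
            for key in ("vcf", "populations"):
                if key not in self.input:
                    raise PipelineError(f"input.{key} is required")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text())
        try:
            return cls(**raw)
        except TypeError as e:
            raise PipelineError(f"malformed config {path}: {e}") from None


def _roh_params(spec: dict) -> ROHParams:
    spec = dict(spec or {})
    spec.pop("min_lengths_bp", None)
    preset = spec.pop("preset", None)
    if preset is not None:
        if spec:
            raise PipelineError("give either roh.preset or explicit parameters, not both")
        try:
            return PRESETS[preset]
        except KeyError:
            raise PipelineError(f"unknown ROH preset {preset!r}; "
                                f"choose from {sorted(PRESETS)}") from None
    return ROHParams(**spec)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in dependency order; returns the manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}
    manifest: dict = {
        "tool": "bottleload",
        "version": __version__,
        "seed": config.seed,
        "versions": {"numpy": np.__version__, "pandas": pd.__version__},
        "stages": list(config.stages),
        "counts": counts,
    }

    # --- acquire callset and annotations -----------------------------------
    if config.simulate is not None:
        sim_cfg = SimulationConfig.from_dict({**config.simulate, "seed": config.seed})
        callset, ann_table, truth = simulate_cohort(sim_cfg)
        write_cohort(callset, ann_table, truth, sim_cfg, outdir / "sim")
        annotations = load_annotations(
            gerp_source=ann_table[["chrom", "pos", "gerp"]],
            impact_source=ann_table[["chrom", "pos", "impact"]])
        genome_bp = float(config.genome_bp or sim_cfg.genome_bp)
        manifest["simulate"] = sim_cfg.to_dict()
    else:
        inp = config.input
        callset = read_vcf(inp["vcf"], inp["populations"])
        annotations = None
        if inp.get("gerp") or inp.get("impact"):
            annotations = load_annotations(gerp_source=inp.get("gerp"),
                                           impact_source=inp.get("impact"))
        if config.genome_bp is None:
            raise PipelineError("genome_bp is required for VCF input")
        genome_bp = float(config.genome_bp)
        manifest["input"] = {k: str(v) for k, v in inp.items()}
        if config.filters is not None:
            callset = apply_site_filters(callset, FilterSpec(**config.filters))
        anc = inp.get("ancestral", "AA")
        callset = polarize_to_ancestral(callset, anc)
    counts["sites_loaded"] = callset.n_sites
    counts["samples"] = callset.n_samples

    callset = restrict_complete_cases(callset)
    counts["sites_complete_case"] = callset.n_sites
    counts.update({k: v for k, v in callset.provenance.items() if isinstance(v, int)})

    pops = [callset.populations[s] for s in callset.samples]
    pop_sizes = pd.Series(pops).value_counts()
    testable = (len(pop_sizes) >= 2) and (pop_sizes.min() >= 2)

    # --- diversity ----------------------------------------------------------
    if "diversity" in config.stages:
        het = het_per_kb(callset)
        het_df = pd.DataFrame({"sample": het.index, "population": pops,
                               "het_per_kb": het.to_numpy()})
        write_tsv(het_df, outdir / "het.tsv")
        write_tsv(pi_windows(callset), outdir / "pi_windows.tsv")
        if testable:
            write_tsv(pairwise_group_test(het_df["het_per_kb"], het_df["population"]),
                      outdir / "tukey_het.tsv")
        counts["diversity_samples"] = len(het_df)

    # --- ROH ----------------------------------------------------------------
    if "roh" in config.stages:
        params = _roh_params(config.roh)
        min_lengths = tuple(config.roh.get("min_lengths_bp", (100_000.0, 2_000_000.0))) \
            if config.roh else (100_000.0, 2_000_000.0)
        segments = detect_roh_all(callset, params)
        write_tsv(segments, outdir / "roh_segments.tsv")
        froh = froh_table(callset, params, genome_bp, min_lengths)
        write_tsv(froh, outdir / "froh.tsv")
        froh_col = froh.columns[3]
        if testable:
            write_tsv(pairwise_group_test(froh[froh_col], froh["population"]),
                      outdir / "tukey_froh.tsv")
        counts["roh_segments"] = len(segments)

    # --- load ---------------------------------------------------------------
    need_ann = {"load", "rxy"} & set(config.stages)
    aligned = None
    if need_ann:
        if annotations is None:
            raise PipelineError("load/rxy stages need gerp/impact annotations")
        aligned = annotate_sites(callset, annotations)
    if "load" in config.stages:
        bins = GerpBins(**config.gerp_bins) if config.gerp_bins else GerpBins()
        summary = load_summary(callset, aligned, bins)
        write_tsv(summary, outdir / "load_summary.tsv")
        counts["load_rows"] = len(summary)

    # --- rxy / sharing ------------------------------------------------------
    if "rxy" in config.stages:
        freqs = FreqTable.from_callset(callset, aligned["impact"].to_numpy())
        rxy_rows, pseudo_rows, sharing_rows = [], [], []
        # orient each pair as (later population, earlier population) so that
        # rxy < 1 reads as a frequency reduction in the descendant cohort
        for pop_y, pop_x in combinations(callset.pop_names(), 2):
            for cat in config.rxy_categories:
                try:
                    s = rxy_jackknife(freqs, pop_x, pop_y, cat)
                except ValueError:
                    s = rxy_point(freqs, pop_x, pop_y, cat)
                rxy_rows.append({
                    "pop_x": pop_x, "pop_y": pop_y, "category": cat,
                    "n_sites": s.n_sites, "freq_x": s.freq_x, "freq_y": s.freq_y,
                    "rxy": s.rxy, "jackknife_mean": s.jackknife_mean,
                    "jackknife_se": s.jackknife_se,
                })
                if s.loo is not None:
                    for c, lv, pv in zip(s.chromosomes, s.loo, s.pseudo):
                        pseudo_rows.append({"pop_x": pop_x, "pop_y": pop_y,
                                            "category": cat, "chrom": c,
                                            "leave_one_out": lv, "pseudo_value": pv})
                sharing_rows.append({"pop_a": pop_x, "pop_b": pop_y, "category": cat,
                                     **sharing_summary(freqs, pop_x, pop_y, cat)})
        write_tsv(pd.DataFrame(rxy_rows), outdir / "rxy.tsv")
        write_tsv(pd.DataFrame(pseudo_rows), outdir / "rxy_pseudovalues.tsv")
        write_tsv(pd.DataFrame(sharing_rows), outdir / "sharing.tsv")
        counts["rxy_rows"] = len(rxy_rows)

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
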