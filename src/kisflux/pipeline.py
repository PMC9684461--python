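"""End-to-end driver: simulate -> GRO inference -> Kis analysis -> report.

One global seed spawns named substreams per stage so every output is
reproducible; the report collects the quantities of interest
(affected-gene counts, overlap p, median ratios, buffering medians/p,
correlations) in a machine-readable dict also written as JSON.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from kisflux import gro, io, kis, simulate

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Validated configuration for a full pipeline run."""

    preset: str = "headline"
    n_genes: int = 5000
    conditions: tuple[str, ...] = ("WT", "dNLS12")
    mutant: str = "dNLS12"
    n_replicates: int = 3
    sigma_noise: float = 0.2
    beta: float = 1.0
    cell_volumes: dict = field(default_factory=dict)
    n_bins: int = 6
    threshold: float = 2.0
    outdir: str = "kisflux_run"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.preset not in simulate.PRESETS:
            raise ValueError(f"unknown preset {self.preset!r}")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        unknown = set(self.conditions) - set(simulate.CONDITION_ETA)
        if unknown:
            raise ValueError(f"unknown conditions: {sorted(unknown)}")
        if "WT" not in self.conditions:
            raise ValueError("conditions must include WT")
        if self.mutant not in self.conditions or self.mutant == "WT":
            raise ValueError("mutant must be a non-WT member of conditions")
        if not (1 <= self.n_bins <= self.n_genes):
            raise ValueError("n_bins out of range")
        if self.threshold <= 1:
            raise ValueError("threshold must be > 1")
        if self.n_replicates < 1 or self.sigma_noise < 0:
            raise ValueError("invalid measurement settings")
        if not (0.0 <= self.beta <= 1.0):
            raise ValueError("beta must lie in [0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "conditions" in raw:
            raw["conditions"] = tuple(raw["conditions"])
        return cls(**raw)


def _stage_seeds(seed: int, n: int) -> list[int]:
    """Deterministic per-stage child seeds below 2**31."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


def run_pipeline(config: RunConfig) -> dict:
    """Run the whole chain and write all tables plus report.json.

    Stages: truth generation, per-condition GRO simulation, kinetic
    inference (TR, RA, HL), Kis scoring against WT, classification at
    the fold threshold, equal-size binning, per-bin medians, buffering
    rank-sum test, and the HL/TR log-ratio correlation.
    """
    outdir = io.ensure_dir(config.outdir)
    seeds = _stage_seeds(config.seed, 1 + len(config.conditions))

    truth = simulate.generate_truth(config.n_genes, config.preset, seeds[0])
    io.write_tsv(truth, outdir / "truth.tsv", io.TRUTH_COLUMNS)
    logger.info("generated truth: %d genes, preset=%s", len(truth), config.preset)

    kinetics = {}
    gro_frames = []
    for cond_name, cond_seed in zip(config.conditions, seeds[1:]):
        cond = simulate.ConditionSpec.from_name(cond_name, beta=config.beta)
        profile = simulate.apply_condition(truth, cond)
        volume = config.cell_volumes.get(cond_name, 1.0)
        mc = simulate.MeasurementConfig(
            n_replicates=config.n_replicates,
            sigma_noise=config.sigma_noise,
            cell_volume=volume,
            seed=cond_seed,
        )
        sample = simulate.simulate_gro(profile, mc)
        sample.insert(1, "strain", cond_name)
        gro_frames.append(sample)
        kinetics[cond_name] = gro.build_kinetics_table(
            sample.drop(columns="strain"), cond_name, volume
        )
    io.write_tsv(pd.concat(gro_frames, ignore_index=True), outdir / "gro.tsv", io.GRO_COLUMNS)
    io.write_tsv(
        pd.concat(kinetics.values(), ignore_index=True),
        outdir / "kinetics.tsv",
        io.KINETICS_COLUMNS,
    )

    wt, mut = kinetics["WT"], kinetics[config.mutant]
    kis_table = kis.compute_kis_values(wt, mut)
    classification = kis.classify_kis(kis_table, config.threshold)
    kis_table = kis.assign_bins(kis_table, config.n_bins)
    io.write_tsv(kis_table, outdir / "kis_table.tsv", io.KIS_COLUMNS)

    hl_summary = kis.bin_summary(np.log2(kis_table["hl_ratio"]), kis_table["bin"])
    tr_summary = kis.bin_summary(np.log2(kis_table["tr_ratio_inv"]), kis_table["bin"])
    hl_summary.insert(0, "metric", "log2_hl_ratio")
    tr_summary.insert(0, "metric", "log2_tr_ratio_inv")
    io.write_tsv(pd.concat([hl_summary, tr_summary], ignore_index=True), outdir / "bin_summary.tsv")

    merged = wt.merge(mut, on="gene_id", suffixes=("_wt", "_mut"))
    buffering = kis.buffering_test(merged["RA_wt"], merged["RA_mut"])
    overlap_p = kis.overlap_significance(
        classification.hl_affected, classification.tr_affected, len(kis_table)
    )
    corr = kis.correlate_log_ratios(kis_table["hl_ratio"], kis_table["tr_ratio_inv"])

    report = {
        "preset": config.preset,
        "n_genes": int(config.n_genes),
        "mutant": config.mutant,
        "seed": int(config.seed),
        "n_scored": int(len(kis_table)),
        **classification.counts,
        "overlap_p": overlap_p,
        "median_hl_ratio": float(kis_table["hl_ratio"].median()),
        "median_tr_ratio_inv": float(kis_table["tr_ratio_inv"].median()),
        "median_kis_value": float(kis_table["kis_value"].median()),
        "buffering_median_ra_wt": buffering.median_wt,
        "buffering_median_ra_mut": buffering.median_mut,
        "buffering_p": buffering.pvalue,
        "hl_tr_log_ratio_pearson_r": corr if np.isfinite(corr) else None,
        "total_polii_tr_wt": gro.total_polii_tr(wt["TR"].dropna()),
        "total_polii_tr_mut": gro.total_polii_tr(mut["TR"].dropna()),
    }
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    logger.info(
        "pipeline done: %d Kis genes of %d scored, overlap p=%.3g",
        report["n_kis"], report["n_scored"], overlap_p,
    )
    return report
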