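"""End-to-end pipeline: simulate/load -> filter -> DE x3 -> categorize ->
temporal -> conserve, with file outputs and a JSON run manifest.

Stages communicate through TSV files under the output directory so each
one can be inspected or re-run independently; the manifest records the
seed, thresholds and per-stage gene counts.  Reruns with the same config
and inputs are byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .core import (
    CountMatrix,
    Thresholds,
    ValidationError,
    filter_low_counts,
    read_counts,
    size_factors,
    write_tsv,
)
from .simdata import SimulationConfig, simulate_experiment, simulate_circadian_replicate
from .de import run_analysis1, run_analysis2, run_analysis3, estimate_dispersions
from .categorize import refined_categorize, standard_categorize, summarize_categories
from .temporal import select_temporal_genes, cluster_temporal
from .conserve import response_correlation

logger = logging.getLogger("dielgate")

STAGES = ("simulate", "filter", "de", "categorize", "temporal", "conserve")


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    out_dir: str
    seed: int = 0
    counts_path: str | None = None
    samplesheet_path: str | None = None
    circadian_counts_path: str | None = None
    circadian_samplesheet_path: str | None = None
    thresholds: Thresholds = field(default_factory=Thresholds)
    sim: SimulationConfig | None = None
    stages: tuple[str, ...] = STAGES

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValidationError(f"unknown stage name(s): {sorted(unknown)}")
        if "simulate" not in self.stages and self.counts_path is None:
            raise ValidationError("either enable the simulate stage or give counts_path")

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = json.load(fh)
        if "thresholds" in raw:
            raw["thresholds"] = Thresholds(**raw["thresholds"])
        if "sim" in raw and raw["sim"] is not None:
            raw["sim"] = SimulationConfig.from_dict(raw["sim"])
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)


def run_pipeline(config: RunConfig) -> dict:
    """Run the enabled stages and return the manifest (also written to
    ``manifest.json`` in the output directory)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    th = config.thresholds
    meta = {"tool": f"dielgate {__version__}", "seed": config.seed}
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "thresholds": th.to_dict(),
        "stages": [],
        "counts": {},
    }

    truth = None
    if "simulate" in config.stages:
        sim = config.sim or SimulationConfig()
        sim = SimulationConfig.from_dict({**sim.to_dict(), "seed": config.seed})
        cm, truth = simulate_experiment(sim)
        cm.write(out / "counts.tsv", out / "samples.csv")
        write_tsv(truth.reset_index(), out / "truth.tsv", meta)
        manifest["stages"].append("simulate")
        manifest["counts"]["simulated_genes"] = cm.n_genes
        logger.info("simulated %d genes x %d samples", cm.n_genes, cm.n_samples)
    else:
        cm = read_counts(config.counts_path, config.samplesheet_path)

    if "filter" in config.stages:
        cm = filter_low_counts(cm, th.min_count)
        manifest["stages"].append("filter")
        manifest["counts"]["filtered_genes"] = cm.n_genes
        logger.info("%d genes pass the count filter", cm.n_genes)

    factors = size_factors(cm)
    dispersions = estimate_dispersions(cm, factors)

    de1 = de2 = de3 = None
    if "de" in config.stages:
        de1 = run_analysis1(cm, th, factors=factors, dispersions=dispersions)
        de2 = run_analysis2(cm, th, factors=factors, dispersions=dispersions)
        de3 = run_analysis3(cm, th, factors=factors, dispersions=dispersions)
        for time, res in de1.items():
            res.write(out / f"de_analysis1_{time}.tsv", meta)
        for cname, res in de2.items():
            res.write(out / f"de_analysis2_{cname}.tsv", meta)
        de3.write(out / "de_analysis3_interaction.tsv", meta)
        manifest["stages"].append("de")

    if "categorize" in config.stages:
        if de1 is None or de2 is None:
            raise ValidationError("categorize stage requires the de stage")
        std = standard_categorize(de1["AM"], de1["PM"], th)
        manifest["counts"]["standard"] = std.totals()
        rc = refined_categorize(de2, th)
        write_tsv(
            rc.reset_index().rename(columns={"index": "gene"}),
            out / "refined_categories.tsv",
            meta,
        )
        summary = summarize_categories(rc, th)
        write_tsv(
            summary.per_category.reset_index(), out / "category_summary.tsv", meta
        )
        write_tsv(summary.unions.reset_index(), out / "category_unions.tsv", meta)
        manifest["stages"].append("categorize")
        manifest["counts"]["heat_responsive"] = summary.total_categorized
        manifest["counts"]["discordant"] = summary.n_discordant

    if "temporal" in config.stages:
        if de3 is None:
            raise ValidationError("temporal stage requires the de stage")
        tg = select_temporal_genes(de3, th)
        manifest["stages"].append("temporal")
        manifest["counts"]["temporal_genes"] = len(tg)
        if len(tg) >= th.n_clusters:
            ca = cluster_temporal(tg, cm, th)
            write_tsv(
                ca.labels.rename_axis("gene").reset_index(),
                out / "temporal_clusters.tsv",
                meta,
            )
            write_tsv(
                ca.profiles.reset_index(), out / "temporal_profiles.tsv", meta
            )
            manifest["counts"]["cluster_sizes"] = {
                str(k): int(v) for k, v in ca.sizes.items()
            }
        else:
            logger.warning("too few temporal genes to cluster (%d)", len(tg))

    if "conserve" in config.stages:
        circ = None
        if config.circadian_counts_path is not None:
            circ = read_counts(
                config.circadian_counts_path, config.circadian_samplesheet_path
            )
        elif truth is not None:
            sim = config.sim or SimulationConfig()
            sim = SimulationConfig.from_dict({**sim.to_dict(), "seed": config.seed})
            flags = pd.Series(True, index=truth.index)
            circ = simulate_circadian_replicate(truth, flags, sim)
        if circ is not None:
            cc = response_correlation(cm, circ, thresholds=th)
            write_tsv(
                cc.table.reset_index(), out / "conservation.tsv", meta
            )
            manifest["stages"].append("conserve")
            manifest["counts"]["conserved"] = int((cc.table["cls"] == "conserved").sum())

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
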