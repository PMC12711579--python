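"""End-to-end orchestration: simulate (optional) -> call -> cis-DCO ->
CoC -> landscape, with provenance-stamped TSV/JSON outputs.

Every run consumes child streams of a single global seed, so a rerun with
the same configuration and seed is bit-identical.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, io
from .calling import call_population, per_individual_counts
from .genome import GenomeMap
from .interference import (
    AnalysisParams,
    bin_distances,
    coc_distance_histogram,
    coc_interval_pairs,
    expected_distance_sample,
    extract_cis_dcos,
    independent_dco_rate,
    short_dco_position_test,
)
from .landscape import arm_scaled_profile, region_counts, window_co_frequency
from .simulate import PRESETS, SimulationConfig, generate_population

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    genome: GenomeMap
    input_path: str | None = None          # genotype table, or ...
    simulation: SimulationConfig | None = None  # ... a simulation; exactly one
    params: AnalysisParams = field(default_factory=AnalysisParams)
    min_support: int = 3
    window_bp: int = 300_000
    coc_mode: str = "distance_histogram"
    outdir: str = "meicos_out"
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.simulation is None):
            raise ValueError("exactly one of input_path / simulation must be set")


def _provenance(config: PipelineConfig) -> dict:
    prov = {
        "meicos_version": __version__,
        "seed": config.seed,
        "min_support": config.min_support,
        "window_bp": config.window_bp,
        "coc_mode": config.coc_mode,
        "params": dataclasses.asdict(config.params),
        "input": None,
    }
    if config.input_path is not None:
        prov["input"] = {
            "path": str(config.input_path),
            "sha256": io.file_checksum(config.input_path),
        }
    else:
        sim = dataclasses.asdict(config.simulation)
        sim.pop("genome")
        prov["simulation"] = sim
    return prov


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and write the output bundle to ``config.outdir``.

    Returns the JSON stats report (also written as ``stats.json``).
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = np.random.SeedSequence(config.seed).spawn(3)
    rng_expected = np.random.default_rng(seeds[1])
    rng_perm = np.random.default_rng(seeds[2])

    # ---- stage: input ------------------------------------------------------
    if config.simulation is not None:
        sim = dataclasses.replace(
            config.simulation, genome=config.genome,
            seed=int(np.random.default_rng(seeds[0]).integers(2**31 - 1)),
        )
        pop = generate_population(sim)
        genotypes = pop.genotypes
        individuals = pop.individuals
        io.write_genotype_table(genotypes, out / "genotypes.tsv")
        io.write_truth(pop.truth, out / "truth.tsv")
    else:
        genotypes = io.read_genotype_table(config.input_path)
        individuals = list(dict.fromkeys(genotypes["individual"]))

    # ---- stage: CO calling -------------------------------------------------
    segments, events = call_population(genotypes, min_support=config.min_support)
    io.write_events(events, out / "co_events.tsv")
    counts = per_individual_counts(events, individuals, config.genome)
    counts.to_csv(out / "co_counts.tsv", sep="\t")

    # ---- stage: cis-DCO ----------------------------------------------------
    dcos = extract_cis_dcos(segments, config.genome)
    dcos.to_csv(out / "cis_dco.tsv", sep="\t", index=False)

    report: dict = {
        "n_individuals": len(individuals),
        "n_events": int(len(events)),
        "n_cis_dcos": int(len(dcos)),
        "mean_cos_per_individual": float(counts["total"].mean()),
        "provenance": _provenance(config),
    }

    # ---- stage: distances + CoC -------------------------------------------
    if len(dcos):
        mids_by_chrom = {
            str(c): sub["midpoint"].to_numpy()
            for c, sub in events.groupby("chrom", observed=True)
        }
        expected = expected_distance_sample(mids_by_chrom, config.params, rng_expected)
        dist = bin_distances(dcos["distance"].to_numpy(), expected, config.params)
        dist.to_frame().to_csv(out / "distance_distribution.tsv", sep="\t", index=False)
        obs_rate = len(dcos) / len(individuals)
        exp_rate = independent_dco_rate(counts)
        if config.coc_mode == "interval_pairs":
            coc = coc_interval_pairs(events, config.genome, individuals, config.params)
        else:
            coc = coc_distance_histogram(dist, obs_rate, exp_rate)
        coc.to_frame().to_csv(out / "coc.tsv", sep="\t", index=False)
        report["distance"] = {
            "observed_median": dist.observed_median,
            "expected_median": dist.expected_median,
            "observed_gamma": dataclasses.asdict(dist.observed_fit) if dist.observed_fit else None,
            "expected_gamma": dataclasses.asdict(dist.expected_fit) if dist.expected_fit else None,
            "observed_dco_rate": obs_rate,
            "independent_dco_rate": exp_rate,
        }
        try:
            pos = short_dco_position_test(dcos, config.genome, config.params, rng_perm)
            report["short_dco_position_test"] = dataclasses.asdict(pos)
        except ValueError as err:
            logger.warning("position test skipped: %s", err)
            report["short_dco_position_test"] = None
    else:
        logger.warning("no cis-DCOs found; distance/CoC stages skipped")

    # ---- stage: landscape --------------------------------------------------
    land = window_co_frequency(events, config.genome, len(individuals), config.window_bp)
    land.to_csv(out / "landscape.tsv", sep="\t", index=False)
    arm_scaled_profile(land, config.genome).to_csv(
        out / "landscape_scaled.tsv", sep="\t", index=False
    )
    region_counts(events, config.genome, individuals).to_csv(
        out / "region_counts.tsv", sep="\t", index=False
    )

    io.write_json(report, out / "stats.json")
    return report


def simulation_from_spec(genome: GenomeMap, spec: dict | str) -> SimulationConfig:
    """Build a SimulationConfig from a preset name or a config mapping."""
    if isinstance(spec, str):
        if spec not in PRESETS:
            raise ValueError(f"unknown preset {spec!r}; have {sorted(PRESETS)}")
        return PRESETS[spec](genome=genome)
    return SimulationConfig(genome=genome, **spec)
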