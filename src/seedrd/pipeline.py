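"""End-to-end pipeline: simulate/load -> depth -> filter -> RD -> classify -> report.

One config (YAML or dict) drives every stage; all randomness flows from a
single seed, so two runs of the same config are byte-identical.  Inputs are
either a simulator block (synthetic cohorts) or real per-base depth
(samtools-depth TSV or SAM alignments) plus the reference FASTA and a sample
sheet naming the cohorts and the reference ("young") cohort.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

from . import degradation, depth as depth_mod, filtering
from .degradation import DEFAULT_BOUNDS, RegionBounds
from .errors import ConfigurationError
from .simulate import (
    CohortDesign,
    FragmentationModel,
    ercc_like_spikeins,
    random_transcriptome,
    simulate_library,
    write_fasta,
    write_ground_truth,
)

__all__ = ["PipelineConfig", "PipelineResult", "design_from_dict", "run_pipeline"]


def design_from_dict(sheet: Mapping[str, Any]) -> CohortDesign:
    """Build a :class:`CohortDesign` from a sample-sheet mapping.

    Expected keys: ``cohorts`` (cohort id -> list of sample ids) and
    ``reference`` (the young cohort's id).
    """
    if not sheet or "cohorts" not in sheet:
        raise ConfigurationError("sample sheet must define 'cohorts'")
    cohorts = tuple(
        (str(c), tuple(str(s) for s in ss)) for c, ss in sheet["cohorts"].items()
    )
    if not any(ss for _, ss in cohorts):
        raise ConfigurationError("sample sheet defines no samples")
    ref = sheet.get("reference")
    if ref is None:
        raise ConfigurationError("sample sheet must name the reference cohort")
    return CohortDesign(cohorts=cohorts, reference_cohort=str(ref))


@dataclass
class PipelineConfig:
    """Everything one run needs; see ``from_yaml`` for the file layout."""

    sample_sheet: Mapping[str, Any]
    seed: int = 0
    simulate: Mapping[str, Any] | None = None
    depth_tsv: str | None = None
    fasta: str | None = None
    spike_ins: tuple[str, ...] = ()
    coverage_threshold: float = 0.75
    min_max_depth: int = 20
    coverage_mode: str = "mean"
    depth_mode: str = "per_sample"
    window: tuple[float, float] = (0.25, 0.75)
    bounds: str | Mapping[str, Any] = "default"
    plots: tuple[str, ...] = ()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        filters = raw.get("filters", {})
        return cls(
            sample_sheet=raw.get("sample_sheet", {}),
            seed=int(raw.get("seed", 0)),
            simulate=raw.get("simulate"),
            depth_tsv=raw.get("depth_tsv"),
            fasta=raw.get("fasta"),
            spike_ins=tuple(raw.get("spike_ins", ())),
            coverage_threshold=float(filters.get("coverage_threshold", 0.75)),
            min_max_depth=int(filters.get("min_max_depth", 20)),
            coverage_mode=str(filters.get("coverage_mode", "mean")),
            depth_mode=str(filters.get("depth_mode", "per_sample")),
            window=tuple(raw.get("window", (0.25, 0.75))),
            bounds=raw.get("bounds", "default"),
            plots=tuple(raw.get("plots", ())),
        )


@dataclass
class PipelineResult:
    design: CohortDesign
    cascade: filtering.CascadeResult
    rd_table: pd.DataFrame
    summary: pd.DataFrame
    bounds: RegionBounds
    paths: dict[str, Path] = field(default_factory=dict)


def _resolve_bounds(
    spec: str | Mapping[str, Any], rd_table: pd.DataFrame
) -> RegionBounds:
    if spec == "default":
        return DEFAULT_BOUNDS
    if spec == "spike_in":
        spikes = rd_table[rd_table["is_spike_in"]]
        return degradation.derive_spikein_bounds(spikes)
    if isinstance(spec, Mapping):
        kwargs = {k: tuple(v) for k, v in spec.items()}
        return RegionBounds(**kwargs)
    raise ConfigurationError(f"unknown bounds specification {spec!r}")


def _simulate_inputs(config: PipelineConfig, outdir: Path):
    sim = dict(config.simulate or {})
    design = design_from_dict(config.sample_sheet)
    rng = np.random.default_rng([int(config.seed) % 2**31, 101])
    transcripts = random_transcriptome(
        int(sim.get("n_transcripts", 50)),
        rng,
        length_range=tuple(sim.get("length_range", (300, 7000))),
    )
    spikes = ercc_like_spikeins(int(sim.get("n_spike_ins", 4)), rng)
    all_tx = transcripts + spikes
    model = FragmentationModel(
        lambda_early=float(sim.get("lambda_early", 2e-4)),
        lambda_aging=float(sim.get("lambda_aging", 1.5e-3)),
        priming=str(sim.get("priming", "oligo_dT")),
        selection=str(sim.get("selection", "polyA")),
        reads_per_sample=int(sim.get("reads_per_sample", 5000)),
        depth_noise=str(sim.get("depth_noise", "none")),
        seed=int(config.seed),
    )
    library = simulate_library(all_tx, model, design)
    matrices = library.depth_matrices()
    fasta_path = write_fasta(all_tx, outdir / "reference.fa", seed=config.seed)
    depth_mod.write_depth_tsv(matrices, outdir / "depth.tsv")
    write_ground_truth(library, outdir / "ground_truth.tsv")
    sequences = {
        rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")
    }
    spike_ids = tuple(t.id for t in spikes)
    return matrices, design, sequences, spike_ids


def _load_inputs(config: PipelineConfig):
    design = design_from_dict(config.sample_sheet)
    if config.fasta is None or config.depth_tsv is None:
        raise ConfigurationError(
            "without a simulate block the config must provide 'fasta' and "
            "'depth_tsv'"
        )
    sequences = {
        rec.id: str(rec.seq) for rec in SeqIO.parse(str(config.fasta), "fasta")
    }
    lengths = {tid: len(s) for tid, s in sequences.items()}
    matrices = depth_mod.load_depth_tsv(
        config.depth_tsv, lengths, samples=design.samples
    )
    return matrices, design, sequences, tuple(config.spike_ins)


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> PipelineResult:
    """Run every stage in order and write the tabular outputs to ``outdir``.

    Outputs: ``filter_report.tsv``, ``rd_table.tsv``, ``region_summary.tsv``,
    ``run_log.json`` (parameters and per-stage counts; no timestamps, so
    repeated runs are byte-identical), plus simulator artifacts when
    simulating.  Spike-in transcripts that pass the presence filter are kept
    in the RD table as controls even if they fail later stages.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if config.simulate is not None:
        matrices, design, sequences, spike_ids = _simulate_inputs(config, outdir)
    else:
        matrices, design, sequences, spike_ids = _load_inputs(config)

    cascade = filtering.run_cascade(
        matrices,
        design,
        coverage_threshold=config.coverage_threshold,
        min_max_depth=config.min_max_depth,
        coverage_mode=config.coverage_mode,
        depth_mode=config.depth_mode,
    )
    survivors = cascade.survivors
    presence_ok = set(cascade.reports[0].survivors)
    keep = list(survivors) + [
        t for t in spike_ids if t in presence_ok and t not in set(survivors)
    ]

    rd_table = degradation.compute_rd_table(
        matrices,
        design,
        transcripts=keep,
        window_fracs=config.window,
        sequences=sequences,
        spike_ins=spike_ids,
    )
    bounds = _resolve_bounds(config.bounds, rd_table)
    if bounds != DEFAULT_BOUNDS:
        regions = [
            degradation.classify_region(r, d, bounds)
            for r, d in zip(rd_table["rd_ref"], rd_table["rd_delta"])
        ]
        rd_table["region"] = [p for p, _ in regions]
        rd_table["region_flags"] = [";".join(sorted(f)) for _, f in regions]
    summary = degradation.region_summary(rd_table)

    paths = {
        "filter_report": filtering.write_filter_reports(
            cascade, outdir / "filter_report.tsv"
        ),
        "rd_table": degradation.write_rd_table(rd_table, outdir / "rd_table.tsv"),
    }
    summary.to_csv(
        outdir / "region_summary.tsv", sep="\t", index=False, float_format="%.10g"
    )
    paths["region_summary"] = outdir / "region_summary.tsv"

    if config.plots:
        from .depth import cohort_mean_profiles
        from .plotting import render_profile_plot

        aged = design.aged_cohorts[0]
        for tid in config.plots:
            profiles = cohort_mean_profiles(matrices[tid], design)
            paths[f"plot:{tid}"] = render_profile_plot(
                tid,
                profiles,
                design.reference_cohort,
                aged,
                outdir / f"profile_{tid}.png",
                window_fracs=config.window,
            )

    log = {
        "seed": config.seed,
        "samples": list(design.samples),
        "reference_cohort": design.reference_cohort,
        "filters": {
            "coverage_threshold": config.coverage_threshold,
            "min_max_depth": config.min_max_depth,
            "coverage_mode": config.coverage_mode,
            "depth_mode": config.depth_mode,
        },
        "window": list(config.window),
        "stages": [
            {"stage": r.stage, "n_input": r.n_input, "n_output": r.n_output}
            for r in cascade.reports
        ],
        "rd_rows": int(len(rd_table)),
        "bounds": {
            "a_box": list(bounds.a_box),
            "a_prime": list(bounds.a_prime),
            "b": list(bounds.b),
            "c": list(bounds.c),
            "d": list(bounds.d),
        },
    }
    with open(outdir / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2, sort_keys=True)
        fh.write("\n")
    paths["run_log"] = outdir / "run_log.json"

    return PipelineResult(
        design=design,
        cascade=cascade,
        rd_table=rd_table,
        summary=summary,
        bounds=bounds,
        paths=paths,
    )
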