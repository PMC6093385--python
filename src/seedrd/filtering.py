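"""Transcript curation cascade.

Cohort comparison of coverage profiles only makes sense for transcripts that
are observed everywhere and sequenced deeply enough; three stages select
them, applied strictly in order:

1. **presence** — at least one aligned read in every sample;
2. **coverage** — reference-cohort coverage fraction above a threshold
   (default: mean across reference replicates > 0.75);
3. **depth** — at least one base with raw depth >= 20 (default: required in
   every sample).

Each stage emits a :class:`FilterReport` with per-transcript pass/fail and a
reason, and the survivor sets are nested by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .depth import DepthMatrix
from .errors import ParameterError
from .simulate import CohortDesign

__all__ = [
    "FilterReport",
    "CascadeResult",
    "presence_filter",
    "coverage_fraction",
    "coverage_filter",
    "depth_filter",
    "observed_length",
    "cohort_observed_length",
    "run_cascade",
    "write_filter_reports",
]


@dataclass
class FilterReport:
    """Outcome of one cascade stage: per-transcript verdicts with reasons."""

    stage: str
    results: dict[str, tuple[bool, str]]

    @property
    def n_input(self) -> int:
        return len(self.results)

    @property
    def n_output(self) -> int:
        return sum(1 for ok, _ in self.results.values() if ok)

    @property
    def survivors(self) -> list[str]:
        return [t for t, (ok, _) in self.results.items() if ok]

    @property
    def failed(self) -> list[str]:
        return [t for t, (ok, _) in self.results.items() if not ok]


@dataclass
class CascadeResult:
    reports: list[FilterReport]

    @property
    def survivors(self) -> list[str]:
        return self.reports[-1].survivors if self.reports else []


def presence_filter(
    matrices: Mapping[str, DepthMatrix],
    design: CohortDesign,
    subset: Sequence[str] | None = None,
) -> tuple[list[str], FilterReport]:
    """Keep transcripts with at least one aligned read in every sample."""
    results: dict[str, tuple[bool, str]] = {}
    for tid in subset if subset is not None else matrices:
        mat = matrices[tid]
        absent = [s for s in design.samples if mat.sample_depth(s).max(initial=0) < 1]
        if absent:
            results[tid] = (False, "absent in: " + ",".join(absent))
        else:
            results[tid] = (True, "present in all samples")
    report = FilterReport("presence", results)
    return report.survivors, report


def coverage_fraction(depth: np.ndarray) -> float:
    """Fraction of positions 1..L with depth >= 1."""
    d = np.asarray(depth)
    if d.size == 0:
        raise ParameterError("empty depth vector")
    return float((d >= 1).sum() / d.size)


def coverage_filter(
    matrices: Mapping[str, DepthMatrix],
    design: CohortDesign,
    subset: Sequence[str] | None = None,
    threshold: float = 0.75,
    cohort: str | None = None,
    mode: str = "mean",
) -> tuple[list[str], FilterReport]:
    """Keep transcripts whose reference-cohort coverage exceeds ``threshold``.

    ``mode='mean'`` compares the mean coverage fraction across the cohort's
    replicates (the coverage of the cohort treated as one per-transcript
    quantity); ``mode='every'`` requires every replicate to exceed it.  The
    inequality is strict, matching a ">75%" criterion exactly at the boundary.
    """
    if not 0.0 < threshold <= 1.0:
        raise ParameterError(f"coverage threshold must be in (0, 1], got {threshold}")
    if mode not in ("mean", "every"):
        raise ParameterError(f"unknown coverage mode {mode!r}")
    cohort = cohort or design.reference_cohort
    reps = design.replicates(cohort)
    results: dict[str, tuple[bool, str]] = {}
    for tid in subset if subset is not None else matrices:
        mat = matrices[tid]
        covs = [coverage_fraction(mat.sample_depth(s)) for s in reps]
        stat = float(np.mean(covs)) if mode == "mean" else float(np.min(covs))
        ok = stat > threshold
        results[tid] = (ok, f"{mode} {cohort} coverage {stat:.4f}")
    report = FilterReport("coverage", results)
    return report.survivors, report


def depth_filter(
    matrices: Mapping[str, DepthMatrix],
    design: CohortDesign,
    subset: Sequence[str] | None = None,
    min_max_depth: int = 20,
    mode: str = "per_sample",
) -> tuple[list[str], FilterReport]:
    """Keep deeply sequenced transcripts: some base reaches raw depth ``min_max_depth``.

    ``mode='per_sample'`` requires the criterion in every sample (strictest
    reading, guaranteeing both cohorts are comparable); ``mode='pooled'``
    applies it to depth summed over samples.
    """
    if min_max_depth < 1:
        raise ParameterError(f"min_max_depth must be >= 1, got {min_max_depth}")
    if mode not in ("per_sample", "pooled"):
        raise ParameterError(f"unknown depth mode {mode!r}")
    results: dict[str, tuple[bool, str]] = {}
    for tid in subset if subset is not None else matrices:
        mat = matrices[tid]
        if mode == "per_sample":
            maxima = {s: int(mat.sample_depth(s).max(initial=0)) for s in design.samples}
            shallow = [s for s, m in maxima.items() if m < min_max_depth]
            ok = not shallow
            reason = (
                "max depth >= threshold in all samples"
                if ok
                else "max depth < threshold in: " + ",".join(shallow)
            )
        else:
            pooled = int(mat.depth.sum(axis=0).max(initial=0))
            ok = pooled >= min_max_depth
            reason = f"pooled max depth {pooled}"
        results[tid] = (ok, reason)
    report = FilterReport("depth", results)
    return report.survivors, report


def observed_length(depth: np.ndarray) -> int:
    """Covered span: number of positions with depth >= 1 (sequenced length proxy)."""
    d = np.asarray(depth)
    return int((d >= 1).sum())


def cohort_observed_length(
    matrix: DepthMatrix, design: CohortDesign, cohort: str | None = None
) -> float:
    """Mean observed length across a cohort's replicates."""
    cohort = cohort or design.reference_cohort
    reps = design.replicates(cohort)
    return float(np.mean([observed_length(matrix.sample_depth(s)) for s in reps]))


def run_cascade(
    matrices: Mapping[str, DepthMatrix],
    design: CohortDesign,
    coverage_threshold: float = 0.75,
    min_max_depth: int = 20,
    coverage_mode: str = "mean",
    depth_mode: str = "per_sample",
    coverage_cohort: str | None = None,
) -> CascadeResult:
    """Apply presence -> coverage -> depth in order; survivor sets are nested."""
    s1, r1 = presence_filter(matrices, design)
    s2, r2 = coverage_filter(
        matrices,
        design,
        subset=s1,
        threshold=coverage_threshold,
        cohort=coverage_cohort,
        mode=coverage_mode,
    )
    s3, r3 = depth_filter(
        matrices, design, subset=s2, min_max_depth=min_max_depth, mode=depth_mode
    )
    return CascadeResult(reports=[r1, r2, r3])


def write_filter_reports(
    result: CascadeResult, path: str | Path
) -> Path:
    """TSV with one row per (stage, transcript): verdict and reason."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("stage\ttranscript_id\tpassed\treason\n")
        for rep in result.reports:
            for tid, (ok, why) in rep.results.items():
                fh.write(f"{rep.stage}\t{tid}\t{int(ok)}\t{why}\n")
    return path
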