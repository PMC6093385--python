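"""Per-base read depth: containers, parsers, normalization, cohort averaging.

Depth is the number of aligned cDNA reads covering each base of a reference
transcript.  Coordinates are 1-based and intervals fully closed throughout
the package (the samtools convention).  Each sample's profile is scaled so
that its maximum over the full transcript is 100, replicate profiles are
averaged within a cohort, and a centered moving window is available for
display smoothing only — the RD statistics are always computed from the
unsmoothed cohort means.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pysam
from Bio import SeqIO

from .errors import (
    ConfigurationError,
    FormatError,
    ParameterError,
    UndefinedProfileError,
)

__all__ = [
    "DepthMatrix",
    "NormalizedProfile",
    "read_fasta_lengths",
    "load_depth_tsv",
    "write_depth_tsv",
    "depth_from_alignments",
    "normalize_profile",
    "average_cohort",
    "cohort_mean_profiles",
    "smooth_moving_window",
    "write_profiles_tsv",
]


@dataclass
class DepthMatrix:
    """Raw read depth for one transcript: one integer row per sample.

    ``depth`` has shape ``(n_samples, L)``; column ``b-1`` is position ``b``
    (1-based).  Every position 1..L is represented; absent rows in sparse
    inputs are imputed as zero by the loaders.
    """

    transcript_id: str
    samples: tuple[str, ...]
    depth: np.ndarray

    def __post_init__(self) -> None:
        self.samples = tuple(self.samples)
        self.depth = np.asarray(self.depth)
        if self.depth.ndim != 2:
            raise ParameterError("depth must be a 2-D (samples x positions) array")
        if self.depth.shape[0] != len(self.samples):
            raise ParameterError(
                f"{self.transcript_id}: {len(self.samples)} sample ids for "
                f"{self.depth.shape[0]} depth rows"
            )
        if self.depth.size and self.depth.min() < 0:
            raise ParameterError(f"{self.transcript_id}: negative depth")

    @property
    def L(self) -> int:
        return self.depth.shape[1]

    def sample_depth(self, sample_id: str) -> np.ndarray:
        try:
            i = self.samples.index(sample_id)
        except ValueError:
            raise ConfigurationError(
                f"sample {sample_id!r} not present in depth matrix for "
                f"{self.transcript_id}"
            ) from None
        return self.depth[i]


@dataclass
class NormalizedProfile:
    """Cohort-averaged, 0–100-normalized depth profile for one transcript."""

    transcript_id: str
    cohort_id: str
    values: np.ndarray
    n_replicates: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ParameterError("profile values must be 1-D")


def read_fasta_lengths(path: str | Path) -> dict[str, int]:
    """Transcript id -> length from a reference transcriptome FASTA."""
    return {rec.id: len(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def _parse_header(line: str) -> list[str] | None:
    if line.startswith("#"):
        return line.lstrip("#").rstrip("\n").split("\t")[2:]
    return None


def load_depth_tsv(
    path: str | Path,
    lengths: Mapping[str, int],
    samples: Sequence[str] | None = None,
) -> dict[str, DepthMatrix]:
    """Load a samtools-depth-style TSV into one :class:`DepthMatrix` per transcript.

    Columns are transcript id, 1-based position, then one depth column per
    sample.  A leading ``#``-prefixed header line names the sample columns;
    without one, ``samples`` must be given.  Every transcript in ``lengths``
    receives a matrix; positions missing from the file are zero-filled, so an
    empty file yields all-zero matrices.
    """
    path = Path(path)
    header_samples: list[str] | None = None
    with open(path) as fh:
        first = fh.readline()
    if first:
        header_samples = _parse_header(first)

    if header_samples is not None:
        if samples is not None:
            unknown = [s for s in header_samples if s not in set(samples)]
            if unknown:
                raise ConfigurationError(
                    f"depth TSV columns not in sample sheet: {', '.join(unknown)}"
                )
        cols = header_samples
    else:
        if samples is None:
            raise ConfigurationError(
                f"{path}: no header line and no sample list supplied"
            )
        cols = list(samples)

    n_s = len(cols)
    mats = {
        tid: np.zeros((n_s, L), dtype=np.int64) for tid, L in lengths.items()
    }
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 2 + n_s:
                raise FormatError(
                    f"{path}:{ln}: expected {2 + n_s} columns, got {len(parts)}"
                )
            tid, pos_s = parts[0], parts[1]
            if tid not in mats:
                raise FormatError(f"{path}:{ln}: unknown transcript {tid!r}")
            pos = int(pos_s)
            L = lengths[tid]
            if not 1 <= pos <= L:
                raise FormatError(
                    f"{path}:{ln}: position {pos} outside 1..{L} for {tid}"
                )
            mats[tid][:, pos - 1] = [int(v) for v in parts[2:]]
    return {
        tid: DepthMatrix(tid, tuple(cols), arr) for tid, arr in mats.items()
    }


def write_depth_tsv(
    matrices: Mapping[str, DepthMatrix],
    path: str | Path,
    header: bool = True,
    sparse: bool = False,
) -> Path:
    """Write matrices as a samtools-depth-style TSV (one row per position).

    With ``sparse=True`` all-zero rows are omitted, as samtools does without
    ``-a``; the loader restores them.
    """
    path = Path(path)
    with open(path, "w") as fh:
        first = True
        for tid, mat in matrices.items():
            if first and header:
                fh.write("#transcript_id\tpos\t" + "\t".join(mat.samples) + "\n")
            first = False
            keep = (
                np.flatnonzero(mat.depth.any(axis=0)) if sparse else range(mat.L)
            )
            for j in keep:
                row = "\t".join(str(int(v)) for v in mat.depth[:, j])
                fh.write(f"{tid}\t{j + 1}\t{row}\n")
    return path


def depth_from_alignments(
    sam_path: str | Path,
    lengths: Mapping[str, int],
    default_sample: str = "sample1",
) -> dict[str, DepthMatrix]:
    """Compute per-base depth from a SAM/BAM of transcriptome alignments.

    Depth at position b counts primary alignments whose span covers b;
    secondary and supplementary records are ignored (one molecule, one read).
    Reads are assigned to samples by their ``RG`` tag, falling back to
    ``default_sample``.  Reference names in the header must match ``lengths``.
    """
    sam_path = Path(sam_path)
    with pysam.AlignmentFile(str(sam_path), check_sq=False) as af:
        offenders = [
            (name, ln)
            for name, ln in zip(af.references, af.lengths)
            if name not in lengths or lengths[name] != ln
        ]
        if offenders:
            listing = ", ".join(f"{n} (L={l})" for n, l in offenders)
            raise FormatError(
                f"{sam_path}: references absent from or inconsistent with the "
                f"reference transcriptome: {listing}"
            )
        # diff arrays per (transcript, sample): +1 at start, -1 past the end
        diffs: dict[str, dict[str, np.ndarray]] = {}
        sample_order: list[str] = []
        for rec in af:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            sample = rec.get_tag("RG") if rec.has_tag("RG") else default_sample
            if sample not in sample_order:
                sample_order.append(sample)
            tid = rec.reference_name
            L = lengths[tid]
            d = diffs.setdefault(tid, {}).setdefault(
                sample, np.zeros(L + 1, dtype=np.int64)
            )
            d[rec.reference_start] += 1
            d[rec.reference_end] -= 1

    samples = tuple(sorted(sample_order)) or (default_sample,)
    out: dict[str, DepthMatrix] = {}
    for tid, L in lengths.items():
        arr = np.zeros((len(samples), L), dtype=np.int64)
        for i, s in enumerate(samples):
            d = diffs.get(tid, {}).get(s)
            if d is not None:
                arr[i] = np.cumsum(d[:-1])
        out[tid] = DepthMatrix(tid, samples, arr)
    return out


def normalize_profile(depth: np.ndarray) -> np.ndarray:
    """Scale a depth vector so its maximum over the full transcript is 100.

    Raises :class:`UndefinedProfileError` on an all-zero vector — such a
    transcript has no profile and must have been excluded by the presence
    filter.
    """
    d = np.asarray(depth, dtype=float)
    m = d.max(initial=0.0)
    if m <= 0:
        raise UndefinedProfileError("all-zero depth vector has no profile")
    return 100.0 * d / m


def average_cohort(profiles: Sequence[np.ndarray]) -> np.ndarray:
    """Unweighted per-position mean of replicate profiles (equal lengths)."""
    if len(profiles) == 0:
        raise ParameterError("no replicate profiles to average")
    arrs = [np.asarray(p, dtype=float) for p in profiles]
    n = arrs[0].shape[0]
    if any(a.shape != (n,) for a in arrs):
        raise ParameterError("replicate profiles differ in length")
    return np.mean(arrs, axis=0)


def cohort_mean_profiles(
    matrix: DepthMatrix, design: "CohortDesign"
) -> dict[str, NormalizedProfile]:
    """Normalize each replicate, then average within each cohort of ``design``."""
    out: dict[str, NormalizedProfile] = {}
    for cohort_id, sample_ids in design.cohorts:
        reps = [normalize_profile(matrix.sample_depth(s)) for s in sample_ids]
        out[cohort_id] = NormalizedProfile(
            matrix.transcript_id, cohort_id, average_cohort(reps), len(reps)
        )
    return out


def smooth_moving_window(values: np.ndarray, w: int = 100) -> np.ndarray:
    """Centered moving average with the window truncated at transcript ends.

    Display smoothing only; never feeds the RD computation.  For even ``w``
    the window extends one position further 3' than 5'.
    """
    if w < 1:
        raise ParameterError(f"window width must be >= 1, got {w}")
    v = np.asarray(values, dtype=float)
    n = v.shape[0]
    if n == 0 or w == 1:
        return v.copy()
    c = np.concatenate(([0.0], np.cumsum(v)))
    i = np.arange(n)
    lo = np.maximum(i - (w - 1) // 2, 0)
    hi = np.minimum(i + w // 2, n - 1)
    return (c[hi + 1] - c[lo]) / (hi - lo + 1)


def write_profiles_tsv(
    profiles: Iterable[NormalizedProfile], path: str | Path
) -> Path:
    """Write normalized cohort profiles as TSV (transcript, cohort, pos, value)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("transcript_id\tcohort_id\tpos\tvalue\n")
        for p in profiles:
            for j, val in enumerate(p.values, start=1):
                fh.write(f"{p.transcript_id}\t{p.cohort_id}\t{j}\t{val:.6f}\n")
    return path
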