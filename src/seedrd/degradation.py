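"""Relative-degradation (RD) statistics and region classification.

For each transcript, coverage deficits over the central analysis window
(positions ceil(0.25L)..floor(0.75L); the ends are excluded because depth
there is unreliable) are summed and scaled by the profile of a perfectly
intact transcript, L x 100:

    RD_ref   = sum_b (100 - dbar_ref(b))          / (L * 100)
    RD_delta = sum_b (dbar_ref(b) - dbar_aged(b)) / (L * 100)

where dbar is the cohort-mean 0-100-normalized depth.  RD_ref measures
degradation of the reference ("young") cohort against an intact transcript;
RD_delta measures the additional degradation of the aged cohort.  Because
the denominator spans the full length while the sum spans ~half of it, the
attainable maximum is ~0.5.

Each (RD_delta, RD_ref) point falls into rectangular regions of the RD
plane (strict inequalities throughout):

    A   : intact in both cohorts — box calibrated on intact spike-in controls
    A'  : RD_delta < 0.1  and RD_ref < 0.2   (intact-ish superset of A)
    B   : RD_delta > 0.15 and RD_ref < 0.2   (degraded only during storage)
    C   : RD_delta > 0.15 and RD_ref > 0.4   (early + progressive degradation)
    D   : RD_delta < 0.1  and RD_ref > 0.4   (early degradation, then stable)

A', B, C and D are mutually exclusive; A is a subset of A' and takes
precedence as the primary label; the gaps between regions are "unclassified".
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .depth import DepthMatrix, cohort_mean_profiles
from .errors import ConfigurationError, ParameterError
from .simulate import CohortDesign

__all__ = [
    "AnalysisWindow",
    "analysis_window",
    "RDRecord",
    "RegionBounds",
    "DEFAULT_BOUNDS",
    "rd_ref",
    "rd_delta",
    "classify_region",
    "derive_spikein_bounds",
    "zero_intercept_regression",
    "rd_length_correlation",
    "gc_percent",
    "compute_rd_table",
    "region_summary",
]


@dataclass(frozen=True)
class AnalysisWindow:
    """Central 25-75% window of a transcript, 1-based inclusive."""

    transcript_id: str
    L: int
    start: int
    end: int


def analysis_window(
    L: int, lo: float = 0.25, hi: float = 0.75, transcript_id: str = ""
) -> AnalysisWindow:
    """Window [ceil(lo*L), floor(hi*L)], ties at exact fractions kept on the boundary."""
    if not 0.0 < lo < hi <= 1.0:
        raise ParameterError(f"window fractions must satisfy 0 < lo < hi <= 1")
    if L < 1:
        raise ParameterError("L must be >= 1")
    start = max(1, math.ceil(lo * L))
    end = math.floor(hi * L)
    if start > end:
        raise ParameterError(f"transcript of length {L} too short for RD window")
    return AnalysisWindow(transcript_id, L, start, end)


@dataclass(frozen=True)
class RegionBounds:
    """Rectangular region boundaries in the (RD_delta, RD_ref) plane.

    ``a_box`` is (delta_min, delta_max, ref_min, ref_max); the other entries
    are the single cut each region uses on each axis.  Defaults are the
    spike-in-calibrated A box and the published A'/B/C/D cuts.
    """

    a_box: tuple[float, float, float, float] = (-0.028, 0.02, 0.06, 0.12)
    a_prime: tuple[float, float] = (0.1, 0.2)  # delta_max, ref_max
    b: tuple[float, float] = (0.15, 0.2)  # delta_min, ref_max
    c: tuple[float, float] = (0.15, 0.4)  # delta_min, ref_min
    d: tuple[float, float] = (0.1, 0.4)  # delta_max, ref_min


DEFAULT_BOUNDS = RegionBounds()


@dataclass(frozen=True)
class RDRecord:
    """Per-transcript RD statistics and region assignment."""

    transcript_id: str
    L: int
    rd_ref: float
    rd_delta: float
    region: str
    region_flags: frozenset[str]
    gc_percent: float | None = None
    is_spike_in: bool = False


def _check_window(values: np.ndarray, window: AnalysisWindow) -> None:
    if window.end > values.shape[0] or window.start < 1:
        raise ParameterError(
            f"window {window.start}..{window.end} outside profile of length "
            f"{values.shape[0]}"
        )


def rd_ref(
    mean_ref: np.ndarray, window: AnalysisWindow, L: int | None = None
) -> float:
    """Reference-cohort degradation vs a perfectly intact transcript.

    Sums (100 - profile) over the window and divides by L*100; 0 for an
    intact profile, ~0.5 for a fully degraded window.
    """
    v = np.asarray(mean_ref, dtype=float)
    _check_window(v, window)
    L = window.L if L is None else L
    seg = v[window.start - 1 : window.end]
    return float(np.sum(100.0 - seg) / (L * 100.0))


def rd_delta(
    mean_ref: np.ndarray,
    mean_aged: np.ndarray,
    window: AnalysisWindow,
    L: int | None = None,
) -> float:
    """Additional degradation of the aged cohort relative to the reference.

    Antisymmetric: swapping the cohorts flips the sign; may be slightly
    negative when the aged profile sits above the reference.
    """
    a = np.asarray(mean_ref, dtype=float)
    b = np.asarray(mean_aged, dtype=float)
    if a.shape != b.shape:
        raise ParameterError("cohort profiles differ in length")
    _check_window(a, window)
    L = window.L if L is None else L
    seg = a[window.start - 1 : window.end] - b[window.start - 1 : window.end]
    return float(np.sum(seg) / (L * 100.0))


def classify_region(
    rd_ref_value: float,
    rd_delta_value: float,
    bounds: RegionBounds = DEFAULT_BOUNDS,
) -> tuple[str, frozenset[str]]:
    """All satisfied region predicates plus the primary label.

    All inequalities are strict.  A takes precedence over A'; A', B, C and D
    are pairwise disjoint under any bounds with b/c delta cuts above the
    a_prime/d cut; a point satisfying nothing is "unclassified".
    """
    r, d = float(rd_ref_value), float(rd_delta_value)
    if not (np.isfinite(r) and np.isfinite(d)):
        raise ParameterError("RD values must be finite")
    flags = set()
    dmin, dmax, rmin, rmax = bounds.a_box
    if dmin < d < dmax and rmin < r < rmax:
        flags.add("A")
    if d < bounds.a_prime[0] and r < bounds.a_prime[1]:
        flags.add("A'")
    if d > bounds.b[0] and r < bounds.b[1]:
        flags.add("B")
    if d > bounds.c[0] and r > bounds.c[1]:
        flags.add("C")
    if d < bounds.d[0] and r > bounds.d[1]:
        flags.add("D")
    if "A" in flags:
        primary = "A"
    else:
        rest = flags - {"A"}
        primary = next(iter(rest)) if len(rest) == 1 else "unclassified"
    return primary, frozenset(flags)


def derive_spikein_bounds(
    records: "pd.DataFrame | Iterable[RDRecord]",
    base: RegionBounds = DEFAULT_BOUNDS,
    pad: float = 1e-9,
) -> RegionBounds:
    """Calibrate the A box from intact spike-in control transcripts.

    The box is the min/max of the controls' RD values, widened by ``pad`` on
    each side so the defining controls themselves satisfy the strict
    inequalities (pad=0 gives the literal min/max box, which excludes its own
    extremes).  Requires at least two spike-in records.
    """
    if isinstance(records, pd.DataFrame):
        deltas = records["rd_delta"].to_numpy(dtype=float)
        refs = records["rd_ref"].to_numpy(dtype=float)
    else:
        recs = list(records)
        deltas = np.array([r.rd_delta for r in recs], dtype=float)
        refs = np.array([r.rd_ref for r in recs], dtype=float)
    if deltas.size < 2:
        raise ParameterError(
            f"need >= 2 spike-in records to derive bounds, got {deltas.size}"
        )
    if pad < 0:
        raise ParameterError("pad must be >= 0")
    box = (
        float(deltas.min() - pad),
        float(deltas.max() + pad),
        float(refs.min() - pad),
        float(refs.max() + pad),
    )
    return replace(base, a_box=box)


def zero_intercept_regression(
    x: Sequence[float], y: Sequence[float], centered_r2: bool = True
) -> tuple[float, float]:
    """Least-squares fit of y = m*x through the origin.

    slope = sum(xy)/sum(x^2).  R^2 defaults to 1 - SSres/SStot with the
    *centered* total sum of squares (spreadsheet convention for a forced
    intercept; may be negative), or the uncentered version with
    ``centered_r2=False``.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.size < 2:
        raise ParameterError("need >= 2 (x, y) points of equal length")
    sxx = float(np.sum(xa * xa))
    if sxx == 0.0:
        raise ParameterError("all x values are zero")
    slope = float(np.sum(xa * ya)) / sxx
    resid = ya - slope * xa
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((ya - ya.mean()) ** 2)) if centered_r2 else float(
        np.sum(ya**2)
    )
    if ss_tot == 0.0:
        r2 = 1.0 if ss_res < 1e-300 else float("nan")
    else:
        r2 = 1.0 - ss_res / ss_tot
    return slope, r2


@dataclass(frozen=True)
class LinearFit:
    slope: float
    intercept: float
    r_squared: float
    p_value: float


def rd_length_correlation(table: pd.DataFrame) -> dict[str, LinearFit]:
    """OLS (with intercept) of rd_ref and rd_delta on transcript length."""
    if len(table) < 3:
        raise ParameterError("need >= 3 RD records")
    L = table["length"].to_numpy(dtype=float)
    if np.allclose(L, L[0]):
        raise ParameterError("degenerate length variance")
    out = {}
    for col in ("rd_ref", "rd_delta"):
        res = stats.linregress(L, table[col].to_numpy(dtype=float))
        out[col] = LinearFit(
            float(res.slope),
            float(res.intercept),
            float(res.rvalue**2),
            float(res.pvalue),
        )
    return out


_GAPS = set("-.")


def gc_percent(sequence: str) -> float:
    """GC content of a nucleotide sequence, in percent.

    G/C (case-insensitive) count in the numerator; every non-gap character —
    including IUPAC ambiguity codes — counts in the denominator.
    """
    chars = [c for c in sequence if c not in _GAPS]
    if not chars:
        raise ParameterError("empty sequence")
    gc = sum(1 for c in chars if c in "GCgc")
    return 100.0 * gc / len(chars)


def compute_rd_table(
    matrices: Mapping[str, DepthMatrix],
    design: CohortDesign,
    transcripts: Sequence[str] | None = None,
    aged_cohort: str | None = None,
    window_fracs: tuple[float, float] = (0.25, 0.75),
    bounds: RegionBounds = DEFAULT_BOUNDS,
    sequences: Mapping[str, str] | None = None,
    spike_ins: Iterable[str] = (),
) -> pd.DataFrame:
    """Per-transcript RD table: length, RD_ref, RD_delta, region, flags, GC.

    Uses independently normalized cohort-mean profiles of the reference
    cohort and ``aged_cohort`` (defaulting to the single non-reference
    cohort).  ``transcripts`` restricts to filter survivors; all listed
    transcripts must have a defined profile in every sample.
    """
    if aged_cohort is None:
        aged = design.aged_cohorts
        if len(aged) != 1:
            raise ConfigurationError(
                f"aged cohort is ambiguous ({aged}); pass aged_cohort explicitly"
            )
        aged_cohort = aged[0]
    spike_set = set(spike_ins)
    rows = []
    for tid in transcripts if transcripts is not None else matrices:
        mat = matrices[tid]
        profiles = cohort_mean_profiles(mat, design)
        win = analysis_window(mat.L, *window_fracs, transcript_id=tid)
        r = rd_ref(profiles[design.reference_cohort].values, win)
        d = rd_delta(
            profiles[design.reference_cohort].values,
            profiles[aged_cohort].values,
            win,
        )
        region, flags = classify_region(r, d, bounds)
        gc = (
            gc_percent(sequences[tid])
            if sequences is not None and tid in sequences
            else float("nan")
        )
        rows.append(
            {
                "transcript_id": tid,
                "length": mat.L,
                "gc_percent": gc,
                "rd_ref": r,
                "rd_delta": d,
                "region": region,
                "region_flags": ";".join(sorted(flags)),
                "is_spike_in": tid in spike_set,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "transcript_id",
            "length",
            "gc_percent",
            "rd_ref",
            "rd_delta",
            "region",
            "region_flags",
            "is_spike_in",
        ],
    )


def region_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Counts and mean length/GC/RD per primary region."""
    if len(table) == 0:
        return pd.DataFrame(
            columns=["region", "n", "mean_length", "mean_gc", "mean_rd_ref", "mean_rd_delta"]
        )
    g = table.groupby("region", sort=True)
    out = g.agg(
        n=("transcript_id", "size"),
        mean_length=("length", "mean"),
        mean_gc=("gc_percent", "mean"),
        mean_rd_ref=("rd_ref", "mean"),
        mean_rd_delta=("rd_delta", "mean"),
    ).reset_index()
    return out


def write_rd_table(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    table.to_csv(path, sep="\t", index=False, float_format="%.10g")
    return path
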