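"""qPCR transcript-integrity assay: ΔCt, primer efficiency, and the closed-form
link to the strand-fission model.

Transcript integrity is read out as ΔCt = Ct(3' amplicon) − Ct(5' amplicon)
for a pair of amplicons near the two ends of the same transcript.  In a
3'-anchored cDNA library (poly(A) selection and/or oligo(dT) priming) a
fragmented template loses its 5' end first, so the 5' amplicon template is
rarer, its Ct higher, and ΔCt negative.  In a random-hexamer total-RNA
library any fragment can prime, template abundance depends only on the
amplicon staying unbroken, and the two cohorts give similar ΔCt — the
signature separating fragmentation from, e.g., base oxidation.

Under the fission model with per-bond rate λ and amplification factor E per
cycle, a 3'-anchored library gives exactly

    ΔCt = (s3 − s5) · ln(1 − λ) / ln E   (≤ 0)

where s5, s3 are the amplicon start positions; the random-hexamer model
depends only on amplicon lengths, so equal-length amplicons give a cohort
difference of zero.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, ParameterError, QCWarning
from .simulate import (
    CohortDesign,
    _sample_3prime_starts,
    capture_fragment,
    simulate_breakpoints,
)

__all__ = [
    "LIBRARY_TYPES",
    "AmpliconAssay",
    "delta_ct",
    "efficiency_from_dilution",
    "EfficiencyResult",
    "expected_delta_ct",
    "simulate_ct",
    "monte_carlo_delta_ct",
    "simulate_ct_table",
    "summarize_ct_table",
]

LIBRARY_TYPES = ("polyA_oligodT", "polyA_hexamer", "total_oligodT", "total_hexamer")
# Libraries whose cDNA is anchored at the poly(A) tail: either the selection
# keeps only tail-bearing fragments or the priming converts only them.
_THREE_PRIME_ANCHORED = {"polyA_oligodT", "polyA_hexamer", "total_oligodT"}


@dataclass(frozen=True)
class AmpliconAssay:
    """A 5'/3' amplicon pair on one transcript, with primer efficiency E."""

    transcript_id: str
    amplicon_5p: tuple[int, int]
    amplicon_3p: tuple[int, int]
    efficiency: float = 2.0

    def __post_init__(self) -> None:
        for name, (s, e) in (("5p", self.amplicon_5p), ("3p", self.amplicon_3p)):
            if not 1 <= s <= e:
                raise ParameterError(f"invalid {name} amplicon ({s}, {e})")
        if self.amplicon_5p[1] >= self.amplicon_3p[0]:
            raise ParameterError("5' amplicon must end before the 3' amplicon starts")
        if not 1.0 < self.efficiency <= 2.2:
            raise ParameterError(
                f"efficiency must be in (1, 2.2], got {self.efficiency}"
            )

    def check_within(self, L: int) -> None:
        if self.amplicon_3p[1] > L:
            raise ParameterError(
                f"amplicons exceed transcript length {L} for {self.transcript_id}"
            )


def delta_ct(ct_3p, ct_5p):
    """ΔCt = Ct(3') − Ct(5'); negative when the 5' end is less abundant."""
    out = np.asarray(ct_3p, dtype=float) - np.asarray(ct_5p, dtype=float)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class EfficiencyResult:
    slope: float
    efficiency: float
    r_squared: float
    passes_qc: bool


def efficiency_from_dilution(
    ct_values: Sequence[float],
    log2_input: Sequence[float] | None = None,
    band: tuple[float, float] = (1.93, 2.13),
    monotone_tol: float = 0.5,
) -> EfficiencyResult:
    """Primer efficiency from a 2-fold dilution-series standard curve.

    Regresses Ct on log2(relative input); with slope m, E = 2^(−1/m).  A
    perfect doubling assay rises one cycle per dilution (m = −1, E = 2).
    ``passes_qc`` flags whether E lies in the acceptance band (default
    1.93–2.13).  A Ct trend that *decreases* with dilution by more than
    ``monotone_tol`` cycles triggers a :class:`QCWarning`.
    """
    ct = np.asarray(ct_values, dtype=float)
    if ct.size < 3:
        raise ParameterError("need >= 3 dilution points")
    if log2_input is None:
        x = -np.arange(ct.size, dtype=float)  # undiluted first, then 2x steps
    else:
        x = np.asarray(log2_input, dtype=float)
        if x.shape != ct.shape:
            raise ParameterError("ct and log2_input lengths differ")
    order = np.argsort(x)[::-1]  # decreasing input
    steps = np.diff(ct[order])
    if np.any(steps < -monotone_tol):
        warnings.warn(
            "Ct decreases with dilution beyond tolerance; standard curve suspect",
            QCWarning,
            stacklevel=2,
        )
    res = stats.linregress(x, ct)
    m = float(res.slope)
    if m == 0.0:
        raise ParameterError("flat standard curve; efficiency undefined")
    eff = 2.0 ** (-1.0 / m)
    return EfficiencyResult(
        slope=m,
        efficiency=float(eff),
        r_squared=float(res.rvalue**2),
        passes_qc=bool(band[0] <= eff <= band[1]),
    )


def _log_template_3prime(start: int, L: int, lam: float) -> float:
    # P(no break in bonds start..L-1) = (1-lam)^(L-start)
    return (L - start) * math.log1p(-lam)


def _log_template_unbroken(length: int, lam: float) -> float:
    # P(no break inside an amplicon of `length` bases) = (1-lam)^(length-1)
    return (length - 1) * math.log1p(-lam)


def expected_delta_ct(
    assay: AmpliconAssay, L: int, lam: float, library: str
) -> float:
    """Closed-form ΔCt under the fission model for one library type.

    3'-anchored libraries: template for an amplicon starting at s is
    (1−λ)^(L−s), giving ΔCt = (s3 − s5)·ln(1−λ)/ln E.  total_hexamer:
    template ∝ P(amplicon unbroken), so ΔCt depends only on amplicon
    lengths and equals zero for equal-length amplicons.
    """
    if library not in LIBRARY_TYPES:
        raise ConfigurationError(f"unknown library type {library!r}")
    if not 0.0 <= lam < 1.0:
        raise ParameterError(f"lam must be in [0, 1), got {lam}")
    assay.check_within(L)
    lnE = math.log(assay.efficiency)
    if library in _THREE_PRIME_ANCHORED:
        lt5 = _log_template_3prime(assay.amplicon_5p[0], L, lam)
        lt3 = _log_template_3prime(assay.amplicon_3p[0], L, lam)
    else:
        len5 = assay.amplicon_5p[1] - assay.amplicon_5p[0] + 1
        len3 = assay.amplicon_3p[1] - assay.amplicon_3p[0] + 1
        lt5 = _log_template_unbroken(len5, lam)
        lt3 = _log_template_unbroken(len3, lam)
    # ct = intercept - ln(T)/ln(E); the intercept cancels in the difference
    return (lt5 - lt3) / lnE


def simulate_ct(
    template_fraction: float,
    E: float,
    ct_intercept: float,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> float:
    """Standard exponential qPCR model: ct = intercept − ln(template)/ln(E)."""
    if not 0.0 < template_fraction <= 1.0:
        raise ParameterError(
            f"template fraction must be in (0, 1], got {template_fraction}"
        )
    if E <= 1.0:
        raise ParameterError(f"efficiency must be > 1, got {E}")
    ct = ct_intercept - math.log(template_fraction) / math.log(E)
    if noise_sd > 0.0:
        if rng is None:
            raise ParameterError("technical noise requires an rng")
        ct += float(rng.normal(0.0, noise_sd))
    return float(ct)


def _template_fractions_mc(
    assay: AmpliconAssay,
    L: int,
    lam: float,
    library: str,
    n_molecules: int,
    rng: np.random.Generator,
) -> tuple[float, float]:
    """Monte-Carlo amplifiable fractions for the 5' and 3' amplicons.

    A cDNA amplifies an amplicon iff its span covers the whole amplicon.
    """
    assay.check_within(L)
    s5, e5 = assay.amplicon_5p
    s3, e3 = assay.amplicon_3p
    if library in _THREE_PRIME_ANCHORED:
        lam_v = np.full(n_molecules, lam)
        L_v = np.full(n_molecules, L, dtype=np.int64)
        starts = _sample_3prime_starts(lam_v, L_v, rng)
        t5 = float(np.mean(starts <= s5))
        t3 = float(np.mean(starts <= s3))
    elif library == "total_hexamer":
        c5 = c3 = 0
        for _ in range(n_molecules):
            br = simulate_breakpoints(L, lam, rng)
            fs, fe = capture_fragment(br, L, "random_hexamer", "total", rng)
            c5 += fs <= s5 and fe >= e5
            c3 += fs <= s3 and fe >= e3
        t5 = c5 / n_molecules
        t3 = c3 / n_molecules
    else:
        raise ConfigurationError(f"unknown library type {library!r}")
    return t5, t3


def monte_carlo_delta_ct(
    assay: AmpliconAssay,
    L: int,
    lam: float,
    library: str,
    n_molecules: int,
    rng: np.random.Generator,
    ct_intercept: float = 20.0,
) -> float:
    """ΔCt from simulated molecules (fission + capture + exponential qPCR)."""
    t5, t3 = _template_fractions_mc(assay, L, lam, library, n_molecules, rng)
    if t5 == 0.0 or t3 == 0.0:
        raise ParameterError(
            "no amplifiable template in the Monte-Carlo sample; increase "
            "n_molecules or lower lam"
        )
    ct5 = simulate_ct(t5, assay.efficiency, ct_intercept)
    ct3 = simulate_ct(t3, assay.efficiency, ct_intercept)
    return delta_ct(ct3, ct5)


def simulate_ct_table(
    assays: Sequence[AmpliconAssay],
    lengths: Mapping[str, int],
    design: CohortDesign,
    lam_by_cohort: Mapping[str, float],
    libraries: Sequence[str] = LIBRARY_TYPES,
    n_molecules: int = 20_000,
    technical_replicates: int = 3,
    noise_sd: float = 0.05,
    ct_intercept: float = 20.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a full Ct table: biological replicates x libraries x amplicon ends.

    Each biological replicate gets its own Monte-Carlo template draw
    (biological variation) and ``technical_replicates`` Gaussian-noise Ct
    readings (technical variation).
    """
    rows = []
    for li, library in enumerate(libraries):
        if library not in LIBRARY_TYPES:
            raise ConfigurationError(f"unknown library type {library!r}")
        for ai, assay in enumerate(assays):
            L = lengths[assay.transcript_id]
            for si, sample in enumerate(design.samples):
                cohort = design.cohort_of(sample)
                lam = lam_by_cohort[cohort]
                rng = np.random.default_rng([int(seed) % 2**31, li, ai, si])
                t5, t3 = _template_fractions_mc(
                    assay, L, lam, library, n_molecules, rng
                )
                for end, tf in (("5p", t5), ("3p", t3)):
                    for tr in range(1, technical_replicates + 1):
                        ct = simulate_ct(
                            tf, assay.efficiency, ct_intercept, noise_sd, rng
                        )
                        rows.append(
                            {
                                "sample_id": sample,
                                "cohort_id": cohort,
                                "library": library,
                                "transcript_id": assay.transcript_id,
                                "amplicon_end": end,
                                "technical_replicate": tr,
                                "ct": ct,
                            }
                        )
    return pd.DataFrame(rows)


def summarize_ct_table(
    table: pd.DataFrame, design: CohortDesign | None = None
) -> pd.DataFrame:
    """Per (library, transcript, cohort) ΔCt mean ± SD with a cohort comparison.

    Technical replicates are averaged first within (sample, amplicon end);
    ΔCt is then formed per biological replicate, and mean/SD taken across
    replicates.  The two-sample comparison is Welch's t-test between the
    reference and the other cohort when exactly two cohorts are present.
    """
    required = {
        "sample_id",
        "cohort_id",
        "library",
        "transcript_id",
        "amplicon_end",
        "ct",
    }
    missing = required - set(table.columns)
    if missing:
        raise ParameterError(f"Ct table missing columns: {sorted(missing)}")
    if (table["ct"] <= 0).any():
        raise ParameterError("Ct values must be positive")
    tech = (
        table.groupby(
            ["library", "transcript_id", "cohort_id", "sample_id", "amplicon_end"],
            sort=True,
        )["ct"]
        .mean()
        .unstack("amplicon_end")
    )
    if not {"5p", "3p"} <= set(tech.columns):
        raise ParameterError("Ct table must contain both 5p and 3p amplicon ends")
    tech = tech.reset_index()
    tech["delta_ct"] = tech["3p"] - tech["5p"]

    rows = []
    for (library, tid), grp in tech.groupby(["library", "transcript_id"], sort=True):
        cohorts = sorted(grp["cohort_id"].unique())
        per_cohort = {
            c: grp.loc[grp["cohort_id"] == c, "delta_ct"].to_numpy() for c in cohorts
        }
        t_stat = p_val = float("nan")
        if len(cohorts) == 2:
            a, b = cohorts
            if design is not None and design.reference_cohort in cohorts:
                a = design.reference_cohort
                b = next(c for c in cohorts if c != a)
            if len(per_cohort[a]) >= 2 and len(per_cohort[b]) >= 2:
                res = stats.ttest_ind(per_cohort[a], per_cohort[b], equal_var=False)
                t_stat, p_val = float(res.statistic), float(res.pvalue)
        for c in cohorts:
            vals = per_cohort[c]
            rows.append(
                {
                    "library": library,
                    "transcript_id": tid,
                    "cohort_id": c,
                    "n": len(vals),
                    "delta_ct_mean": float(np.mean(vals)),
                    "delta_ct_sd": float(np.std(vals, ddof=1))
                    if len(vals) > 1
                    else float("nan"),
                    "t_statistic": t_stat,
                    "p_value": p_val,
                }
            )
    return pd.DataFrame(rows)
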