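"""Random strand-fission simulator for whole-molecule cDNA libraries.

Aged, dry-stored mRNA is modeled as breaking by independent fission events:
each of the L−1 backbone bonds of a transcript of length L breaks with a
small per-bond probability λ.  Library chemistry then decides which fragment
of a broken molecule is observed:

* **oligo(dT) priming of poly(A)-selected RNA** — only the fragment that
  retains the poly(A) tail is reverse-transcribed, so each molecule yields at
  most the unique 3'-terminal fragment.  Coverage therefore rises 5'→3', and
  the probability that a captured molecule still covers position x has the
  closed form (1−λ)^(L−x) (no break in the bonds between x and the 3' end).
* **random-hexamer priming of total RNA** — one fragment is captured with
  probability proportional to its length (priming-site abundance), covering
  that fragment's full extent; coverage is near-uniform.

Two cohorts are simulated: the reference ("young") cohort breaks at
``lambda_early`` and the aged cohort at ``lambda_early + lambda_aging``.
ERCC-like spike-in transcripts are intact by construction (λ=0) and calibrate
the no-degradation region of the RD plane downstream.

Everything is deterministic under a fixed seed, including the optional
Poisson/homopolymer-dip depth noise and the FASTA/SAM/TSV writers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from .depth import DepthMatrix
from .errors import ConfigurationError, ParameterError

__all__ = [
    "TranscriptModel",
    "FragmentationModel",
    "ReadInterval",
    "CohortDesign",
    "simulate_breakpoints",
    "capture_fragment",
    "expected_coverage",
    "simulate_library",
    "LibraryResult",
    "random_transcriptome",
    "ercc_like_spikeins",
    "write_fasta",
    "write_sam",
    "write_ground_truth",
]

_PRIMING = ("oligo_dT", "random_hexamer")
_SELECTION = ("polyA", "total")
_NOISE = ("none", "poisson", "poisson_with_homopolymer_dips")


@dataclass(frozen=True)
class TranscriptModel:
    """A reference transcript: length, GC, relative molecule count, spike-in flag."""

    id: str
    length: int
    gc_fraction: float = 0.42
    abundance: float = 1.0
    is_spike_in: bool = False

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ParameterError(f"{self.id}: length must be >= 1")
        if self.abundance <= 0:
            raise ParameterError(f"{self.id}: abundance must be > 0")
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise ParameterError(f"{self.id}: gc_fraction must be in [0, 1]")


@dataclass(frozen=True)
class FragmentationModel:
    """Break rates, capture chemistry and noise for one simulated experiment.

    ``lambda_early`` is the per-bond break probability shared by all cohorts
    (fission accrued early, before the cohorts diverge); ``lambda_aging`` is
    the additional probability applied only to the aged cohort(s).  Units are
    breaks per bond (dimensionless probabilities, both << 1 in practice).
    """

    lambda_early: float
    lambda_aging: float
    priming: str = "oligo_dT"
    selection: str = "polyA"
    reads_per_sample: int = 10_000
    depth_noise: str = "none"
    dip_fraction: float = 0.01
    dip_depth_multiplier: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lambda_early < 0 or self.lambda_aging < 0:
            raise ParameterError("break rates must be non-negative")
        if self.reads_per_sample < 0:
            raise ParameterError("reads_per_sample must be >= 0")
        if self.priming not in _PRIMING:
            raise ConfigurationError(f"unknown priming {self.priming!r}")
        if self.selection not in _SELECTION:
            raise ConfigurationError(f"unknown selection {self.selection!r}")
        if self.depth_noise not in _NOISE:
            raise ConfigurationError(f"unknown depth_noise {self.depth_noise!r}")
        _validate_chemistry(self.priming, self.selection)
        if not 0.0 <= self.dip_fraction <= 1.0:
            raise ParameterError("dip_fraction must be in [0, 1]")
        if self.dip_depth_multiplier < 0:
            raise ParameterError("dip_depth_multiplier must be >= 0")


@dataclass(frozen=True)
class ReadInterval:
    """One sequenced cDNA molecule as a closed 1-based interval on its transcript."""

    transcript_id: str
    start: int
    end: int
    sample_id: str

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ParameterError(
                f"invalid interval [{self.start}, {self.end}] on {self.transcript_id}"
            )


@dataclass(frozen=True)
class CohortDesign:
    """Cohorts with replicate sample ids; one cohort is the reference."""

    cohorts: tuple[tuple[str, tuple[str, ...]], ...]
    reference_cohort: str

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "cohorts",
            tuple((c, tuple(s)) for c, s in self.cohorts),
        )
        ids = [c for c, _ in self.cohorts]
        if self.reference_cohort not in ids:
            raise ConfigurationError(
                f"reference cohort {self.reference_cohort!r} not among {ids}"
            )
        all_samples = [s for _, ss in self.cohorts for s in ss]
        if len(all_samples) != len(set(all_samples)):
            raise ConfigurationError("sample ids must be globally unique")
        if not all_samples:
            raise ConfigurationError("cohort design contains no samples")

    @property
    def samples(self) -> tuple[str, ...]:
        return tuple(s for _, ss in self.cohorts for s in ss)

    def cohort_of(self, sample_id: str) -> str:
        for c, ss in self.cohorts:
            if sample_id in ss:
                return c
        raise ConfigurationError(f"unknown sample {sample_id!r}")

    def replicates(self, cohort_id: str) -> tuple[str, ...]:
        for c, ss in self.cohorts:
            if c == cohort_id:
                return ss
        raise ConfigurationError(f"unknown cohort {cohort_id!r}")

    @property
    def aged_cohorts(self) -> tuple[str, ...]:
        return tuple(c for c, _ in self.cohorts if c != self.reference_cohort)


def _validate_chemistry(priming: str, selection: str) -> None:
    ok = (priming, selection) in {("oligo_dT", "polyA"), ("random_hexamer", "total")}
    if not ok:
        raise ConfigurationError(
            f"unsupported priming/selection combination {priming}+{selection}; "
            "supported: oligo_dT+polyA, random_hexamer+total"
        )


def simulate_breakpoints(
    L: int, lam: float, rng: np.random.Generator
) -> np.ndarray:
    """Break each of the L−1 bonds independently with probability min(λ, 1).

    Returns strictly increasing bond indices in 1..L−1 (bond b sits between
    bases b and b+1).  Sampling draws the break count from Binomial(L−1, λ)
    and places it uniformly without replacement, which is distributionally
    identical to per-bond Bernoulli trials.
    """
    if L < 1:
        raise ParameterError(f"L must be >= 1, got {L}")
    if lam < 0:
        raise ParameterError(f"break rate must be non-negative, got {lam}")
    p = min(lam, 1.0)
    if L == 1 or p == 0.0:
        return np.empty(0, dtype=np.int64)
    n = int(rng.binomial(L - 1, p))
    if n == 0:
        return np.empty(0, dtype=np.int64)
    pos = rng.choice(np.arange(1, L, dtype=np.int64), size=n, replace=False)
    return np.sort(pos)


def capture_fragment(
    breaks: np.ndarray | Sequence[int],
    L: int,
    priming: str = "oligo_dT",
    selection: str = "polyA",
    rng: np.random.Generator | None = None,
) -> tuple[int, int]:
    """Which fragment of a broken molecule becomes a cDNA read.

    oligo(dT)+poly(A): the unique 3'-terminal fragment ``[b_last+1, L]``
    (the whole molecule if unbroken) — 5' fragments lack the tail and are
    never captured.  random-hexamer+total: one fragment chosen with
    probability proportional to its length, covered over its full extent.
    """
    _validate_chemistry(priming, selection)
    br = np.asarray(breaks, dtype=np.int64)
    if br.size and not (1 <= br.min() and br.max() <= L - 1):
        raise ParameterError("break positions must lie in 1..L-1")
    if priming == "oligo_dT":
        start = int(br[-1]) + 1 if br.size else 1
        return (start, L)
    if rng is None:
        raise ParameterError("random_hexamer capture requires an rng")
    edges = np.concatenate(([0], br, [L]))
    lens = np.diff(edges)
    i = int(rng.choice(lens.size, p=lens / L))
    return (int(edges[i]) + 1, int(edges[i + 1]))


def expected_coverage(
    x: int | np.ndarray, L: int, lam: float
) -> float | np.ndarray:
    """P(a captured oligo(dT)/poly(A) molecule covers position x) = (1−λ)^(L−x).

    The closed form behind the 5'→3' coverage rise: a captured (3'-anchored)
    read covers x iff none of the bonds x..L−1 broke.  Common capture
    normalization aside, this is the expected normalized coverage profile.
    """
    if lam < 0:
        raise ParameterError(f"break rate must be non-negative, got {lam}")
    xs = np.asarray(x)
    if np.any(xs < 1) or np.any(xs > L):
        raise ParameterError(f"position out of range 1..{L}")
    out = (1.0 - min(lam, 1.0)) ** (L - xs.astype(float))
    return float(out) if np.isscalar(x) else out


def _sample_3prime_starts(
    lam: np.ndarray, L: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Sample the start of the 3'-terminal fragment for each read.

    Scanning bonds from the 3' end, the first broken bond is geometrically
    distributed; ``start = L − G + 1`` clipped to 1 when no bond broke.
    Exactly matches the per-bond Bernoulli model.
    """
    lam = np.asarray(lam, dtype=float)
    L = np.asarray(L, dtype=np.int64)
    starts = np.ones(lam.shape, dtype=np.int64)
    mask = lam > 0
    if mask.any():
        g = rng.geometric(np.minimum(lam[mask], 1.0))
        s = L[mask] - g + 1
        starts[mask] = np.maximum(s, 1)
    return starts


def _breaks_given_start(
    starts: np.ndarray, lam: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Total break count of the source molecule, conditional on the read start.

    If the read starts at s > 1, bond s−1 broke and the s−2 bonds 5' of it
    remain unconditioned Bernoulli(λ); if s == 1 the molecule was intact.
    """
    nb = np.zeros(starts.shape, dtype=np.int64)
    broken = starts > 1
    if broken.any():
        extra = rng.binomial(
            np.maximum(starts[broken] - 2, 0), np.minimum(lam[broken], 1.0)
        )
        nb[broken] = 1 + extra
    return nb


@dataclass
class LibraryResult:
    """Simulated reads for every sample plus per-(sample, transcript) ground truth."""

    transcripts: tuple[TranscriptModel, ...]
    model: FragmentationModel
    design: CohortDesign
    _reads: dict[str, dict[str, np.ndarray]] = field(repr=False)
    ground_truth: pd.DataFrame = field(repr=False)

    def read_table(self, sample_id: str) -> pd.DataFrame:
        r = self._reads[sample_id]
        ids = np.array([t.id for t in self.transcripts])
        return pd.DataFrame(
            {
                "transcript_id": ids[r["tx"]],
                "start": r["start"],
                "end": r["end"],
                "n_breaks": r["n_breaks"],
            }
        )

    def intervals(self, sample_id: str) -> Iterator[ReadInterval]:
        r = self._reads[sample_id]
        for ti, s, e in zip(r["tx"], r["start"], r["end"]):
            yield ReadInterval(self.transcripts[ti].id, int(s), int(e), sample_id)

    def depth_matrices(self) -> dict[str, DepthMatrix]:
        """Per-transcript depth, with the configured depth noise applied.

        Noise uses its own stream derived from the model seed, so raw read
        sets and noisy depth are each reproducible independently.
        """
        samples = self.design.samples
        nt = len(self.transcripts)
        raw = {
            t.id: np.zeros((len(samples), t.length), dtype=np.int64)
            for t in self.transcripts
        }
        for si, sample in enumerate(samples):
            r = self._reads[sample]
            for ti in np.unique(r["tx"]):
                t = self.transcripts[ti]
                sel = r["tx"] == ti
                d = np.zeros(t.length + 1, dtype=np.int64)
                np.add.at(d, r["start"][sel] - 1, 1)
                np.add.at(d, r["end"][sel], -1)
                raw[t.id][si] = np.cumsum(d[:-1])

        if self.model.depth_noise != "none":
            rng = np.random.default_rng(
                [int(self.model.seed) % 2**31, 915_233]
            )
            for ti, t in enumerate(self.transcripts):
                expect = raw[t.id].astype(float)
                if self.model.depth_noise == "poisson_with_homopolymer_dips":
                    n_dip = int(round(self.model.dip_fraction * t.length))
                    if n_dip:
                        dips = rng.choice(t.length, size=n_dip, replace=False)
                        expect[:, dips] *= self.model.dip_depth_multiplier
                raw[t.id] = rng.poisson(expect)

        return {
            t.id: DepthMatrix(t.id, tuple(samples), raw[t.id])
            for t in self.transcripts
        }


def simulate_library(
    transcripts: Sequence[TranscriptModel],
    model: FragmentationModel,
    design: CohortDesign,
) -> LibraryResult:
    """Draw ``reads_per_sample`` reads per sample under the fission model.

    Transcripts are chosen proportional to abundance.  The aged cohort(s) use
    per-bond rate ``lambda_early + lambda_aging``; the reference cohort uses
    ``lambda_early``; spike-in transcripts are never fragmented (λ=0).
    Deterministic under ``model.seed``.
    """
    transcripts = tuple(transcripts)
    if not transcripts:
        raise ParameterError("empty transcript set")
    ids = [t.id for t in transcripts]
    if len(ids) != len(set(ids)):
        raise ParameterError("duplicate transcript ids")
    ab = np.array([t.abundance for t in transcripts], dtype=float)
    p = ab / ab.sum()
    L_vec = np.array([t.length for t in transcripts], dtype=np.int64)
    spike = np.array([t.is_spike_in for t in transcripts], dtype=bool)

    reads: dict[str, dict[str, np.ndarray]] = {}
    gt_rows = []
    for si, sample in enumerate(design.samples):
        cohort = design.cohort_of(sample)
        lam_cohort = model.lambda_early + (
            model.lambda_aging if cohort != design.reference_cohort else 0.0
        )
        lam_vec = np.where(spike, 0.0, lam_cohort)
        rng = np.random.default_rng([int(model.seed) % 2**31, si])
        R = model.reads_per_sample
        tx = rng.choice(len(transcripts), size=R, p=p) if R else np.empty(0, np.int64)
        tx = tx.astype(np.int64)
        lam_read = lam_vec[tx]
        L_read = L_vec[tx]
        if model.priming == "oligo_dT":
            starts = _sample_3prime_starts(lam_read, L_read, rng)
            ends = L_read.copy()
            n_breaks = _breaks_given_start(starts, lam_read, rng)
        else:
            starts = np.empty(R, dtype=np.int64)
            ends = np.empty(R, dtype=np.int64)
            n_breaks = np.empty(R, dtype=np.int64)
            for i in range(R):
                br = simulate_breakpoints(int(L_read[i]), float(lam_read[i]), rng)
                s, e = capture_fragment(
                    br, int(L_read[i]), model.priming, model.selection, rng
                )
                starts[i], ends[i], n_breaks[i] = s, e, br.size
        reads[sample] = {"tx": tx, "start": starts, "end": ends, "n_breaks": n_breaks}
        counts = np.bincount(tx, minlength=len(transcripts))
        for ti, t in enumerate(transcripts):
            gt_rows.append(
                {
                    "sample_id": sample,
                    "cohort_id": cohort,
                    "transcript_id": t.id,
                    "true_lambda": float(lam_vec[ti]),
                    "n_reads": int(counts[ti]),
                }
            )
    return LibraryResult(
        transcripts=transcripts,
        model=model,
        design=design,
        _reads=reads,
        ground_truth=pd.DataFrame(gt_rows),
    )


def random_transcriptome(
    n: int,
    rng: np.random.Generator,
    length_range: tuple[int, int] = (300, 7000),
    gc_mean: float = 0.42,
    gc_sd: float = 0.03,
    abundance_decades: float = 2.0,
) -> list[TranscriptModel]:
    """Random transcript set: log-uniform lengths and abundances, Gaussian GC.

    Lengths are log-uniform over ``length_range`` (mRNA length distributions
    are right-skewed); abundances log-uniform over ``abundance_decades``
    decades; GC around the soybean transcriptome's ~42%.
    """
    if n < 1:
        raise ParameterError("need at least one transcript")
    lo, hi = length_range
    lens = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n)).astype(int)
    gcs = np.clip(rng.normal(gc_mean, gc_sd, size=n), 0.2, 0.8)
    abund = 10.0 ** rng.uniform(0.0, abundance_decades, size=n)
    return [
        TranscriptModel(f"tx{i + 1:04d}", int(lens[i]), float(gcs[i]), float(abund[i]))
        for i in range(n)
    ]


def ercc_like_spikeins(
    n: int = 8,
    rng: np.random.Generator | None = None,
    length_range: tuple[int, int] = (250, 2000),
    abundance: float = 30.0,
) -> list[TranscriptModel]:
    """Intact synthetic control transcripts (never fragmented by the simulator)."""
    rng = rng or np.random.default_rng(7)
    lo, hi = length_range
    lens = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n)).astype(int)
    return [
        TranscriptModel(
            f"SPIKE-{i + 1:03d}", int(lens[i]), 0.5, abundance, is_spike_in=True
        )
        for i in range(n)
    ]


def estimate_lambda(
    depth: np.ndarray, window: tuple[int, int] | None = None
) -> float:
    """Recover the per-bond break rate from an oligo(dT)/poly(A) depth profile.

    Under the fission model, mean depth follows d(x) ∝ (1−λ)^(L−x), so a
    log-linear regression of depth on (L−x) over the central window has
    slope ln(1−λ).  Positions with zero depth are excluded.
    """
    d = np.asarray(depth, dtype=float)
    L = d.shape[0]
    if window is None:
        import math as _math

        window = (max(1, _math.ceil(0.25 * L)), _math.floor(0.75 * L))
    lo, hi = window
    if not 1 <= lo <= hi <= L:
        raise ParameterError(f"window {window} outside 1..{L}")
    xs = np.arange(lo, hi + 1)
    vals = d[xs - 1]
    ok = vals > 0
    if ok.sum() < 2:
        raise ParameterError("not enough covered positions to fit")
    slope = np.polyfit((L - xs[ok]).astype(float), np.log(vals[ok]), 1)[0]
    return float(1.0 - np.exp(slope))


_BASES = np.array(list("ACGT"))


def write_fasta(
    transcripts: Sequence[TranscriptModel], path: str | Path, seed: int = 0
) -> Path:
    """Write synthetic reference sequences honouring each transcript's GC fraction."""
    path = Path(path)
    with open(path, "w") as fh:
        for i, t in enumerate(transcripts):
            rng = np.random.default_rng([int(seed) % 2**31, 55_001, i])
            g = t.gc_fraction / 2.0
            a = (1.0 - t.gc_fraction) / 2.0
            seq = rng.choice(_BASES, size=t.length, p=[a, g, g, a])
            fh.write(f">{t.id}\n")
            s = "".join(seq)
            for j in range(0, t.length, 60):
                fh.write(s[j : j + 60] + "\n")
    return path


def write_sam(library: LibraryResult, path: str | Path) -> Path:
    """Minimal SAM: ungapped alignments, one line per read, RG = sample id."""
    path = Path(path)
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": t.id, "LN": t.length} for t in library.transcripts],
        "RG": [{"ID": s, "SM": s} for s in library.design.samples],
    }
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for sample in library.design.samples:
            r = library._reads[sample]
            for k, (ti, s, e) in enumerate(zip(r["tx"], r["start"], r["end"])):
                a = pysam.AlignedSegment(out.header)
                a.query_name = f"{sample}_read{k + 1}"
                a.flag = 0
                a.reference_id = int(ti)
                a.reference_start = int(s) - 1
                a.mapping_quality = 60
                a.cigarstring = f"{int(e) - int(s) + 1}M"
                a.query_sequence = None
                a.set_tag("RG", sample)
                out.write(a)
    return path


def write_ground_truth(library: LibraryResult, path: str | Path) -> Path:
    path = Path(path)
    library.ground_truth.to_csv(path, sep="\t", index=False)
    return path
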