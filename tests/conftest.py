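import numpy as np
import pytest

from seedrd import CohortDesign, DepthMatrix


@pytest.fixture
def two_cohort_design() -> CohortDesign:
    return CohortDesign(
        cohorts=(
            ("young", ("y1", "y2", "y3", "y4", "y5")),
            ("aged", ("a1", "a2", "a3", "a4", "a5")),
        ),
        reference_cohort="young",
    )


def random_depth_matrix(
    rng: np.random.Generator,
    design: CohortDesign,
    tid: str = "tx",
    L: int | None = None,
    max_depth: int = 50,
) -> DepthMatrix:
    """Random matrix with every sample guaranteed at least one covered base."""
    L = L if L is not None else int(rng.integers(8, 201))
    depth = rng.integers(0, max_depth + 1, size=(len(design.samples), L))
    for i in range(depth.shape[0]):
        if depth[i].max() == 0:
            depth[i, rng.integers(0, L)] = 1
    return DepthMatrix(tid, design.samples, depth)


def brute_force_rd(
    mat: DepthMatrix, design: CohortDesign, aged_cohort: str = "aged"
) -> tuple[float, float]:
    """Independent per-position reimplementation of RD_ref / RD_delta.

    Pure-Python loops: normalize each replicate by its own full-length
    maximum, average per cohort, then sum deficits over the
    ceil(0.25L)..floor(0.75L) window and divide by L*100.
    """
    import math

    L = mat.L

    def cohort_mean(cohort: str) -> list[float]:
        reps = design.replicates(cohort)
        profiles = []
        for s in reps:
            d = [float(v) for v in mat.sample_depth(s)]
            m = max(d)
            profiles.append([100.0 * v / m for v in d])
        return [
            sum(p[b] for p in profiles) / len(profiles) for b in range(L)
        ]

    ref = cohort_mean(design.reference_cohort)
    aged = cohort_mean(aged_cohort)
    start, end = math.ceil(0.25 * L), math.floor(0.75 * L)
    rd_ref = sum(100.0 - ref[b - 1] for b in range(start, end + 1)) / (L * 100.0)
    rd_delta = sum(ref[b - 1] - aged[b - 1] for b in range(start, end + 1)) / (
        L * 100.0
    )
    return rd_ref, rd_delta
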