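"""Small constructed datasets with known-by-design outcomes.

These are synthetic demonstration inputs built in code (no files shipped);
the curation fixture's survivor sets at each cascade stage are fixed by
construction, which makes it a convenient oracle for the filter cascade and
a runnable example for the README.
"""

from __future__ import annotations

import numpy as np

from .depth import DepthMatrix
from .simulate import CohortDesign

__all__ = ["curation_fixture", "curation_design"]


def curation_design() -> CohortDesign:
    """Two cohorts x five replicates; 'young' is the reference."""
    return CohortDesign(
        cohorts=(
            ("young", tuple(f"y{i}" for i in range(1, 6))),
            ("aged", tuple(f"a{i}" for i in range(1, 6))),
        ),
        reference_cohort="young",
    )


def curation_fixture() -> tuple[dict[str, DepthMatrix], CohortDesign, dict[str, set[str]]]:
    """Six transcripts (L=100) built so the cascade goes 6 -> 4 -> 3 -> 2.

    * ``tx_full_a``, ``tx_full_b`` — depth 30 everywhere: survive everything.
    * ``tx_shallow`` — full coverage but max depth 19 in sample y3: falls at
      the depth stage.
    * ``tx_gappy`` — depth 30 on positions 1..60 only (60% coverage): falls
      at the coverage stage.
    * ``tx_missing1`` — zero depth in sample a5: falls at presence.
    * ``tx_missing2`` — zero depth in samples y1 and y2: falls at presence.

    Returns the matrices, the design, and the expected survivor set after
    each stage.
    """
    design = curation_design()
    samples = design.samples
    n_s, L = len(samples), 100

    def mat(tid: str, depth: np.ndarray) -> DepthMatrix:
        return DepthMatrix(tid, samples, depth)

    full = np.full((n_s, L), 30, dtype=np.int64)

    shallow = full.copy()
    shallow[samples.index("y3")] = 19

    gappy = np.zeros((n_s, L), dtype=np.int64)
    gappy[:, :60] = 30

    missing1 = full.copy()
    missing1[samples.index("a5")] = 0

    missing2 = full.copy()
    missing2[samples.index("y1")] = 0
    missing2[samples.index("y2")] = 0

    matrices = {
        "tx_full_a": mat("tx_full_a", full.copy()),
        "tx_full_b": mat("tx_full_b", full.copy()),
        "tx_shallow": mat("tx_shallow", shallow),
        "tx_gappy": mat("tx_gappy", gappy),
        "tx_missing1": mat("tx_missing1", missing1),
        "tx_missing2": mat("tx_missing2", missing2),
    }
    expected = {
        "presence": {"tx_full_a", "tx_full_b", "tx_shallow", "tx_gappy"},
        "coverage": {"tx_full_a", "tx_full_b", "tx_shallow"},
        "depth": {"tx_full_a", "tx_full_b"},
    }
    return matrices, design, expected
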