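"""RD statistics, region classification, regressions, GC."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from seedrd import (
    CohortDesign,
    DEFAULT_BOUNDS,
    FragmentationModel,
    ParameterError,
    analysis_window,
    classify_region,
    compute_rd_table,
    derive_spikein_bounds,
    ercc_like_spikeins,
    gc_percent,
    random_transcriptome,
    rd_delta,
    rd_length_correlation,
    rd_ref,
    simulate_library,
    zero_intercept_regression,
)

from conftest import brute_force_rd, random_depth_matrix


class TestWindow:
    @pytest.mark.parametrize(
        "L,start,end",
        [(10, 3, 7), (100, 25, 75), (101, 26, 75), (4, 1, 3), (7, 2, 5)],
    )
    def test_ceil_floor_convention(self, L, start, end):
        w = analysis_window(L)
        assert (w.start, w.end) == (start, end)

    def test_too_short_transcript(self):
        with pytest.raises(ParameterError):
            analysis_window(1)

    def test_bad_fractions(self):
        with pytest.raises(ParameterError):
            analysis_window(100, 0.75, 0.25)


class TestRDValues:
    def test_intact_transcript_is_zero(self):
        prof = np.full(10, 100.0)
        assert rd_ref(prof, analysis_window(10)) == 0.0

    def test_hand_summation(self):
        # window 3..7 of L=10 with depths [100,80,60,40,20]
        prof = np.full(10, 100.0)
        prof[2:7] = [100, 80, 60, 40, 20]
        assert rd_ref(prof, analysis_window(10)) == pytest.approx(0.20, abs=1e-15)

    def test_fully_degraded_window_reaches_half(self):
        prof = np.full(10, 100.0)
        prof[2:7] = 0.0
        assert rd_ref(prof, analysis_window(10)) == pytest.approx(0.5)

    def test_rd_delta_identical_profiles(self):
        prof = np.linspace(0, 100, 20)
        assert rd_delta(prof, prof, analysis_window(20)) == 0.0

    def test_rd_delta_hand_summation_and_antisymmetry(self):
        ref = np.full(10, 100.0)
        aged = np.full(10, 100.0)
        aged[2:7] = [100, 80, 60, 40, 20]
        w = analysis_window(10)
        assert rd_delta(ref, aged, w) == pytest.approx(0.20, abs=1e-15)
        assert rd_delta(aged, ref, w) == pytest.approx(-0.20, abs=1e-15)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ParameterError):
            rd_delta(np.ones(10), np.ones(11), analysis_window(10))

    def test_window_outside_profile_rejected(self):
        with pytest.raises(ParameterError):
            rd_ref(np.ones(5), analysis_window(10))

    def test_matches_brute_force_oracle(self, two_cohort_design):
        rng = np.random.default_rng(23)
        for i in range(25):
            mat = random_depth_matrix(rng, two_cohort_design, tid=f"t{i}")
            table = compute_rd_table({f"t{i}": mat}, two_cohort_design)
            bf_ref, bf_delta = brute_force_rd(mat, two_cohort_design)
            assert table.loc[0, "rd_ref"] == pytest.approx(bf_ref, abs=1e-12)
            assert table.loc[0, "rd_delta"] == pytest.approx(bf_delta, abs=1e-12)

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(st.integers(8, 200), st.integers(0, 2**31 - 1))
    def test_bounds_and_scale_invariance(self, L, seed):
        design = CohortDesign(
            (
                ("young", ("y1", "y2", "y3", "y4", "y5")),
                ("aged", ("a1", "a2", "a3", "a4", "a5")),
            ),
            "young",
        )
        rng = np.random.default_rng(seed)
        mat = random_depth_matrix(rng, design, L=L)
        table = compute_rd_table({"tx": mat}, design)
        r, d = table.loc[0, "rd_ref"], table.loc[0, "rd_delta"]
        bound = 0.5 + 1.0 / L
        assert 0.0 <= r <= bound
        assert abs(d) <= bound
        # multiplying one sample's raw depths by a constant changes nothing
        scaled = mat.depth.copy()
        scaled[3] *= 13
        mat2 = type(mat)(mat.transcript_id, mat.samples, scaled)
        table2 = compute_rd_table({"tx": mat2}, design)
        assert table2.loc[0, "rd_ref"] == pytest.approx(r, abs=1e-14)
        assert table2.loc[0, "rd_delta"] == pytest.approx(d, abs=1e-14)


class TestClassifier:
    @pytest.mark.parametrize(
        "rd_ref_v,rd_delta_v,primary,flags",
        [
            (0.10, 0.0, "A", {"A", "A'"}),
            (0.10, 0.20, "B", {"B"}),
            (0.30, 0.12, "unclassified", set()),
            (0.45, 0.20, "C", {"C"}),
            (0.45, 0.05, "D", {"D"}),
            (0.15, 0.05, "A'", {"A'"}),
        ],
    )
    def test_printed_examples(self, rd_ref_v, rd_delta_v, primary, flags):
        p, f = classify_region(rd_ref_v, rd_delta_v)
        assert p == primary and set(f) == flags

    def test_boundaries_are_strict(self):
        assert classify_region(0.2, 0.05)[0] == "unclassified"  # ref == A' cut
        assert classify_region(0.1, 0.15)[0] == "unclassified"  # delta == B cut
        assert classify_region(0.12, 0.0)[1] == frozenset({"A'"})  # ref == A box max

    def test_non_finite_rejected(self):
        with pytest.raises(ParameterError):
            classify_region(float("nan"), 0.0)


class TestSpikeInBounds:
    def test_exact_min_max_box(self):
        import pandas as pd

        records = pd.DataFrame(
            {"rd_delta": [-0.01, 0.01], "rd_ref": [0.07, 0.11]}
        )
        b = derive_spikein_bounds(records, pad=0.0)
        assert b.a_box == (-0.01, 0.01, 0.07, 0.11)

    def test_single_record_rejected(self):
        import pandas as pd

        with pytest.raises(ParameterError):
            derive_spikein_bounds(
                pd.DataFrame({"rd_delta": [0.0], "rd_ref": [0.1]})
            )

    def test_noisy_spikeins_match_min_max_oracle(self):
        import pandas as pd

        rng = np.random.default_rng(3)
        d = rng.normal(0, 0.01, 10)
        r = rng.normal(0.09, 0.02, 10)
        b = derive_spikein_bounds(
            pd.DataFrame({"rd_delta": d, "rd_ref": r}), pad=0.0
        )
        assert b.a_box == (d.min(), d.max(), r.min(), r.max())

    def test_pad_keeps_extremes_inside(self):
        import pandas as pd

        records = pd.DataFrame({"rd_delta": [0.0, 0.0], "rd_ref": [0.0, 0.0]})
        b = derive_spikein_bounds(records)  # default infinitesimal pad
        assert classify_region(0.0, 0.0, b)[0] == "A"


class TestRegressions:
    def test_zero_intercept_identity(self):
        slope, r2 = zero_intercept_regression([1, 2, 3], [1, 2, 3])
        assert slope == pytest.approx(1.0) and r2 == pytest.approx(1.0)

    def test_zero_intercept_closed_form(self):
        slope, r2 = zero_intercept_regression([2, 4], [1, 2])
        assert slope == pytest.approx(0.5) and r2 == pytest.approx(1.0)

    def test_zero_intercept_consistency_with_noise(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(1, 10, 500)
        y = 0.8 * x + rng.normal(0, 1e-6, 500)
        slope, _ = zero_intercept_regression(x, y)
        assert slope == pytest.approx(0.8, abs=1e-5)

    def test_all_zero_x_rejected(self):
        with pytest.raises(ParameterError):
            zero_intercept_regression([0, 0], [1, 2])

    def test_rd_length_constant_rd_gives_zero_slope(self):
        import pandas as pd

        table = pd.DataFrame(
            {"length": [100, 200, 300], "rd_ref": [0.1] * 3, "rd_delta": [0.2] * 3}
        )
        fits = rd_length_correlation(table)
        assert fits["rd_ref"].slope == pytest.approx(0.0)
        assert fits["rd_delta"].slope == pytest.approx(0.0)

    def test_collinear_gives_r2_one(self):
        import pandas as pd

        L = np.array([100.0, 500.0, 2000.0, 4000.0])
        table = pd.DataFrame(
            {"length": L, "rd_ref": 1e-5 * L, "rd_delta": 5e-5 * L + 0.01}
        )
        fits = rd_length_correlation(table)
        assert fits["rd_ref"].r_squared == pytest.approx(1.0)
        assert fits["rd_delta"].r_squared == pytest.approx(1.0)

    def test_degenerate_length_variance_rejected(self):
        import pandas as pd

        table = pd.DataFrame(
            {"length": [100] * 3, "rd_ref": [0.1, 0.2, 0.3], "rd_delta": [0] * 3}
        )
        with pytest.raises(ParameterError):
            rd_length_correlation(table)

    def test_simulated_cohorts_rd_delta_increases_with_length(
        self, two_cohort_design
    ):
        # aging-driven fission: length significantly predicts extra degradation
        # of the aged cohort.  (With a single shared early break rate, RD_ref
        # is a near-deterministic function of length, so no claim is made
        # about the relative R^2 of the two fits.)
        for seed in (0, 1, 2):
            rng = np.random.default_rng([seed, 31])
            tx = random_transcriptome(60, rng, length_range=(300, 5000))
            model = FragmentationModel(
                2e-4, 1.5e-3, reads_per_sample=6000, seed=seed
            )
            lib = simulate_library(tx, model, two_cohort_design)
            mats = lib.depth_matrices()
            from seedrd import presence_filter

            keep, _ = presence_filter(mats, two_cohort_design)
            table = compute_rd_table(mats, two_cohort_design, transcripts=keep)
            fits = rd_length_correlation(table)
            assert fits["rd_delta"].slope > 0
            assert fits["rd_delta"].p_value < 1e-3
            assert fits["rd_ref"].slope > 0


class TestGC:
    @pytest.mark.parametrize(
        "seq,expect",
        [("ATAT", 0.0), ("ATGC", 50.0), ("GGCCN", 80.0), ("gcat", 50.0)],
    )
    def test_values(self, seq, expect):
        assert gc_percent(seq) == pytest.approx(expect)

    def test_gaps_excluded_entirely(self):
        assert gc_percent("GC--AT") == pytest.approx(50.0)

    def test_empty_rejected(self):
        with pytest.raises(ParameterError):
            gc_percent("---")
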