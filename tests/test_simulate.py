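"""Strand-fission simulator: break process, capture chemistry, closed forms."""

import numpy as np
import pytest

from seedrd import (
    CohortDesign,
    ConfigurationError,
    FragmentationModel,
    ParameterError,
    TranscriptModel,
    capture_fragment,
    ercc_like_spikeins,
    expected_coverage,
    simulate_breakpoints,
    simulate_library,
    write_depth_tsv,
    write_sam,
)
from seedrd.simulate import estimate_lambda


class TestBreakpoints:
    def test_zero_rate_never_breaks(self):
        rng = np.random.default_rng(0)
        assert simulate_breakpoints(1000, 0.0, rng).size == 0

    def test_rate_one_breaks_every_bond(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            assert simulate_breakpoints(2, 1.0, rng).tolist() == [1]
        assert simulate_breakpoints(5, 1.0, rng).tolist() == [1, 2, 3, 4]

    def test_negative_rate_rejected(self):
        with pytest.raises(ParameterError):
            simulate_breakpoints(100, -0.1, np.random.default_rng(0))

    def test_positions_strictly_increasing_and_in_range(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            br = simulate_breakpoints(200, 0.05, rng)
            assert np.all(np.diff(br) > 0)
            if br.size:
                assert 1 <= br.min() and br.max() <= 199

    def test_mean_break_count_matches_binomial(self):
        # oracle: break count ~ Binomial(L-1, lam), mean (L-1)*lam
        rng = np.random.default_rng(42)
        L, lam, reps = 10_000, 1e-3, 10_000
        counts = [simulate_breakpoints(L, lam, rng).size for _ in range(reps)]
        mean_expected = (L - 1) * lam
        se = np.sqrt((L - 1) * lam * (1 - lam) / reps)
        assert abs(np.mean(counts) - mean_expected) < 3 * se


class TestCapture:
    def test_intact_molecule_spans_everything(self):
        assert capture_fragment([], 500) == (1, 500)

    def test_three_prime_anchoring(self):
        assert capture_fragment([200], 500) == (201, 500)
        assert capture_fragment([10, 200, 450], 500) == (451, 500)

    def test_hexamer_fragment_chosen_by_length(self):
        # fragment [1,200] of a 500-bp molecule is drawn w.p. 200/500
        rng = np.random.default_rng(5)
        n = 20_000
        hits = sum(
            capture_fragment([200], 500, "random_hexamer", "total", rng)
            == (1, 200)
            for _ in range(n)
        )
        p = 200 / 500
        assert abs(hits / n - p) < 3 * np.sqrt(p * (1 - p) / n)

    def test_unsupported_chemistry_rejected(self):
        with pytest.raises(ConfigurationError):
            capture_fragment([], 100, "oligo_dT", "total")
        with pytest.raises(ConfigurationError):
            capture_fragment([], 100, "random_hexamer", "polyA")


class TestExpectedCoverage:
    def test_intact_and_terminus(self):
        assert expected_coverage(17, 1000, 0.0) == 1.0
        assert expected_coverage(1000, 1000, 0.005) == 1.0

    def test_closed_form_value(self):
        assert expected_coverage(1501, 3001, 1e-3) == pytest.approx(
            0.999**1500, abs=1e-12
        )
        assert expected_coverage(1501, 3001, 1e-3) == pytest.approx(0.2231, abs=5e-4)

    def test_out_of_range_position(self):
        with pytest.raises(ParameterError):
            expected_coverage(0, 100, 0.01)
        with pytest.raises(ParameterError):
            expected_coverage(101, 100, 0.01)


def _single_sample_design() -> CohortDesign:
    return CohortDesign((("young", ("s1",)),), "young")


class TestLibrary:
    def test_empty_transcript_set_rejected(self):
        model = FragmentationModel(1e-3, 0.0, reads_per_sample=10)
        with pytest.raises(ParameterError):
            simulate_library([], model, _single_sample_design())

    def test_zero_reads_keeps_ground_truth(self):
        model = FragmentationModel(1e-3, 0.0, reads_per_sample=0)
        lib = simulate_library(
            [TranscriptModel("t1", 500)], model, _single_sample_design()
        )
        assert len(lib.read_table("s1")) == 0
        assert len(lib.ground_truth) == 1
        assert lib.ground_truth.loc[0, "true_lambda"] == pytest.approx(1e-3)

    def test_spike_ins_never_fragmented(self):
        model = FragmentationModel(0.05, 0.05, reads_per_sample=500, seed=2)
        design = CohortDesign(
            (("young", ("s1",)), ("aged", ("s2",))), "young"
        )
        spike = TranscriptModel("spike", 800, is_spike_in=True)
        lib = simulate_library([spike], model, design)
        for sample in ("s1", "s2"):
            tab = lib.read_table(sample)
            assert (tab["start"] == 1).all() and (tab["end"] == 800).all()
            assert (tab["n_breaks"] == 0).all()

    def test_aged_cohort_uses_summed_rate(self):
        model = FragmentationModel(2e-4, 1.5e-3, reads_per_sample=0)
        design = CohortDesign(
            (("young", ("s1",)), ("aged", ("s2",))), "young"
        )
        lib = simulate_library([TranscriptModel("t1", 100)], model, design)
        gt = lib.ground_truth.set_index("sample_id")["true_lambda"]
        assert gt["s1"] == pytest.approx(2e-4)
        assert gt["s2"] == pytest.approx(1.7e-3)

    def test_empirical_coverage_matches_closed_form(self):
        lam, L, n = 1e-3, 2000, 10_000
        model = FragmentationModel(lam, 0.0, reads_per_sample=n, seed=11)
        lib = simulate_library(
            [TranscriptModel("t1", L)], model, _single_sample_design()
        )
        depth = lib.depth_matrices()["t1"].sample_depth("s1")
        x = 1000
        p = expected_coverage(x, L, lam)
        assert abs(depth[x - 1] / n - p) <= 3 * np.sqrt(p * (1 - p) / n)

    def test_coverage_monotone_after_smoothing(self):
        from seedrd import smooth_moving_window

        model = FragmentationModel(1e-3, 0.0, reads_per_sample=20_000, seed=4)
        lib = simulate_library(
            [TranscriptModel("t1", 2000)], model, _single_sample_design()
        )
        depth = lib.depth_matrices()["t1"].sample_depth("s1").astype(float)
        sm = smooth_moving_window(depth, 100)
        violations = np.mean(np.diff(sm) < 0)
        assert violations < 0.01

    def test_lambda_recovery_from_profile(self):
        for lam in (5e-4, 1e-3, 2e-3):
            model = FragmentationModel(lam, 0.0, reads_per_sample=10_000, seed=9)
            lib = simulate_library(
                [TranscriptModel("t1", 2000)], model, _single_sample_design()
            )
            depth = lib.depth_matrices()["t1"].sample_depth("s1")
            lam_hat = estimate_lambda(depth)
            assert abs(lam_hat - lam) / lam < 0.10

    def test_depth_noise_is_deterministic_and_perturbs(self):
        kwargs = dict(reads_per_sample=2000, seed=13)
        clean = FragmentationModel(1e-3, 0.0, depth_noise="none", **kwargs)
        noisy = FragmentationModel(1e-3, 0.0, depth_noise="poisson", **kwargs)
        tx = [TranscriptModel("t1", 400)]
        design = _single_sample_design()
        d_clean = simulate_library(tx, clean, design).depth_matrices()["t1"].depth
        d_noisy1 = simulate_library(tx, noisy, design).depth_matrices()["t1"].depth
        d_noisy2 = simulate_library(tx, noisy, design).depth_matrices()["t1"].depth
        assert np.array_equal(d_noisy1, d_noisy2)
        assert not np.array_equal(d_clean, d_noisy1)

    def test_identical_seeds_give_byte_identical_outputs(self, tmp_path):
        design = CohortDesign(
            (("young", ("s1", "s2")), ("aged", ("s3", "s4"))), "young"
        )
        tx = [TranscriptModel("t1", 300), TranscriptModel("t2", 700)]
        for run in ("r1", "r2"):
            model = FragmentationModel(5e-4, 1e-3, reads_per_sample=500, seed=21)
            lib = simulate_library(tx, model, design)
            write_depth_tsv(lib.depth_matrices(), tmp_path / f"{run}.tsv")
            write_sam(lib, tmp_path / f"{run}.sam")
        assert (tmp_path / "r1.tsv").read_bytes() == (tmp_path / "r2.tsv").read_bytes()
        assert (tmp_path / "r1.sam").read_bytes() == (tmp_path / "r2.sam").read_bytes()


def test_spikein_factory_marks_controls():
    spikes = ercc_like_spikeins(5)
    assert len(spikes) == 5
    assert all(s.is_spike_in for s in spikes)
    assert len({s.id for s in spikes}) == 5
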