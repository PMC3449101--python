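import numpy as np
import pandas as pd
import pytest

from swatcna import (
    PlantedEvent,
    RunConfig,
    SimSpec,
    classify_segments,
    collapse_direction,
    compute_all_tracks,
    consensus_merge,
    figure1_fixture,
    naive_segment,
    perturb_segments,
    simulate_cohort,
)
from swatcna.regions import detect_regions
from swatcna.synthetic_data import GAIN_LOG2

from conftest import make_probe_matrix


class TestFigure1Fixture:
    def test_printed_window_scores(self, figure1):
        from swatcna import compute_pws

        pm, calls = figure1
        track = compute_pws(collapse_direction(calls), pm, "1", 3, "gain")
        assert track.scores[0] == 0.0
        assert track.scores[1] == 50.0
        gainers = calls.calls.iloc[1:4]  # probes 2-4
        samples = [s for s in calls.sample_ids if (gainers[s] == 1).all()]
        assert samples == ["A", "D", "E"]

    def test_nonzero_windows_union_to_both_cris(self, figure1):
        from swatcna import compute_pws

        pm, calls = figure1
        track = compute_pws(collapse_direction(calls), pm, "1", 3, "gain")
        covered = np.zeros(20, dtype=bool)
        for s in np.flatnonzero(track.scores > 0):
            covered[s : s + 3] = True
        expected = np.zeros(20, dtype=bool)
        expected[1:10] = True  # probes 2-10
        expected[11:19] = True  # probes 12-19
        np.testing.assert_array_equal(covered, expected)

    def test_log2_values_consistent_with_calls(self, figure1):
        pm, calls = figure1
        np.testing.assert_allclose(
            pm.log2.to_numpy(), calls.calls.to_numpy() * GAIN_LOG2
        )

    def test_regeneration_is_deterministic(self, figure1):
        pm2, calls2 = figure1_fixture()
        pd.testing.assert_frame_equal(pm2.log2, figure1[0].log2)
        pd.testing.assert_frame_equal(calls2.calls, figure1[1].calls)


class TestSimulateCohort:
    def test_zero_events_pure_noise(self):
        spec = SimSpec(n_samples=4, n_probes=50, n_chromosomes=1, noise_sd=0.1, seed=2)
        pm, truth = simulate_cohort(spec)
        assert truth.empty
        assert abs(pm.log2.to_numpy().mean()) < 0.05

    def test_same_seed_identical(self):
        spec = dict(n_samples=6, n_probes=80, n_chromosomes=2,
                    events=[PlantedEvent("1", 10, 20, "gain", prevalence=0.5)],
                    noise_sd=0.1, seed=9)
        a, _ = simulate_cohort(SimSpec(**spec))
        b, _ = simulate_cohort(SimSpec(**spec))
        pd.testing.assert_frame_equal(a.log2, b.log2)

    def test_carriers_reported_and_signal_planted(self):
        spec = SimSpec(
            n_samples=38, n_probes=100, n_chromosomes=1,
            events=[PlantedEvent("1", 40, 60, "gain", amplitude=0.8, prevalence=0.5)],
            noise_sd=0.01, seed=3,
        )
        pm, truth = simulate_cohort(spec)
        carriers = truth.loc[0, "carriers"].split(",")
        assert truth.loc[0, "n_carriers"] == len(carriers)
        assert 8 <= len(carriers) <= 30  # binomial(38, 0.5) plausible range
        block = pm.log2.loc[40:60, carriers].to_numpy()
        assert block.mean() == pytest.approx(0.8, abs=0.01)

    def test_overlapping_events_sum_and_flagged(self):
        spec = SimSpec(
            n_samples=4, n_probes=50, n_chromosomes=1,
            events=[
                PlantedEvent("1", 10, 30, "gain", amplitude=0.5, prevalence=1.0),
                PlantedEvent("1", 20, 25, "gain", amplitude=0.5, prevalence=1.0),
            ],
            noise_sd=0.001, seed=1,
        )
        pm, truth = simulate_cohort(spec)
        assert truth["overlaps_other_event"].iloc[1]
        assert pm.log2.loc[22].mean() == pytest.approx(1.0, abs=0.01)

    def test_event_outside_chromosome_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            SimSpec(n_probes=50, events=[PlantedEvent("1", 40, 60, "gain")])


class TestNaiveSegment:
    def test_step_function_breakpoints_recovered(self):
        rng = np.random.default_rng(6)
        x = rng.normal(0, 0.05, size=(150, 2))
        x[50:81] += 0.8
        pm = make_probe_matrix(x)
        segset = naive_segment(pm, min_seg=3, alpha=1e-4)
        for sample in pm.sample_ids:
            segs = segset.df[segset.df["sample"] == sample].sort_values("start_bp")
            assert len(segs) == 3
            starts = (segs["start_bp"].to_numpy() // 100_000)
            assert abs(starts[1] - 50) <= 2 and abs(starts[2] - 81) <= 2

    def test_constant_signal_single_segment(self):
        pm = make_probe_matrix(np.full((60, 2), 0.3))
        segset = naive_segment(pm)
        assert (segset.df.groupby("sample").size() == 1).all()

    def test_tiny_alpha_never_splits(self):
        rng = np.random.default_rng(6)
        x = rng.normal(0, 0.05, size=(150, 2))
        x[50:81] += 0.8
        pm = make_probe_matrix(x)
        segset = naive_segment(pm, alpha=0.0)
        assert (segset.df.groupby("sample").size() == 1).all()

    def test_segments_tile_chromosome_without_gaps(self):
        rng = np.random.default_rng(8)
        x = rng.normal(0, 0.1, size=(100, 3))
        x[30:60, :] += 0.7
        pm = make_probe_matrix(x)
        segset = naive_segment(pm)
        for sample, grp in segset.df.groupby("sample"):
            grp = grp.sort_values("start_bp")
            assert (grp["start_bp"].to_numpy()[1:] == grp["end_bp"].to_numpy()[:-1]).all()


class TestPerturbSegments:
    def _base(self):
        rng = np.random.default_rng(10)
        x = rng.normal(0, 0.05, size=(120, 3))
        x[40:71] += 0.8
        pm = make_probe_matrix(x)
        return pm, naive_segment(pm, method="m1")

    def test_zero_jitter_is_identity_up_to_means(self):
        pm, base = self._base()
        out = perturb_segments(base, 0, seed=1, probes=pm, method="m1")
        pd.testing.assert_frame_equal(
            out.df[["sample", "chromosome", "start_bp", "end_bp"]],
            base.df[["sample", "chromosome", "start_bp", "end_bp"]],
        )

    def test_jittered_methods_still_reach_consensus(self):
        pm, base = self._base()
        config = RunConfig(window_sizes=(3,), n_permutations=200)
        per_method = {}
        for k, segs in enumerate(
            [base,
             perturb_segments(base, 2, seed=21, probes=pm, method="m2"),
             perturb_segments(base, 2, seed=22, probes=pm, method="m3")]
        ):
            calls = classify_segments(segs, pm, config)
            tracks = compute_all_tracks(collapse_direction(calls), pm, config)
            analysis = detect_regions(tracks, pm, config, 3)
            per_method[f"m{k + 1}"] = analysis.mris
        merged = consensus_merge(per_method, min_methods=2)
        gains = [r for r in merged if r.direction == "gain"]
        assert len(gains) == 1
        assert gains[0].start_bp <= 40 * 100_000 < 71 * 100_000 <= gains[0].end_bp + 300_000

    def test_excessive_jitter_drops_degenerate_segments(self, caplog):
        pm, base = self._base()
        import logging

        with caplog.at_level(logging.WARNING, logger="swatcna"):
            perturb_segments(base, 200, seed=0, probes=pm, method="m2")
        # with jitter far beyond segment widths some breakpoints collide
        assert any("degenerate" in r.message for r in caplog.records)
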