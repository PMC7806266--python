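"""Binning, ratio normalisation, baseline calibration, smoothing."""

import hypothesis.strategies as st
import numpy as np
import pytest
from hypothesis import given, settings

from replicheck import (BinnedCoverage, GenomeSpec, RerepConfig, SimConfig,
                        calibrate_baseline, default_genome, default_origins,
                        flat_profile, normalize_ratio, read_bedgraph,
                        read_profile_tsv, sample_reads,
                        simulate_g2_rereplication, smooth, write_bedgraph)
from tests.conftest import make_profile


@pytest.fixture
def grid_genome():
    return GenomeSpec((("chr1", 5000),))


def cov(genome, counts, bin_width=1000):
    return BinnedCoverage(genome, bin_width,
                          {c: np.asarray(v, float) for c, v in counts.items()})


class TestReadBedgraph:
    def test_grid_aligned_intervals_copied_through(self, grid_genome, tmp_path):
        p = tmp_path / "a.bedgraph"
        p.write_text("chr1\t0\t1000\t7\nchr1\t1000\t2000\t3\nchr1\t4000\t5000\t2\n")
        c = read_bedgraph(p, grid_genome)
        np.testing.assert_allclose(c.counts["chr1"], [7, 3, 0, 0, 2])

    def test_overlap_proportional_split(self, grid_genome, tmp_path):
        # 600 bp in bin 0, 400 bp in bin 1 -> 60%/40% of the count
        p = tmp_path / "a.bedgraph"
        p.write_text("chr1\t400\t1400\t10\n")
        c = read_bedgraph(p, grid_genome)
        np.testing.assert_allclose(c.counts["chr1"], [6.0, 4.0, 0, 0, 0])

    def test_empty_file_all_zero(self, grid_genome, tmp_path):
        p = tmp_path / "a.bedgraph"
        p.write_text("")
        assert read_bedgraph(p, grid_genome).total() == 0.0

    def test_unknown_chromosome_named(self, grid_genome, tmp_path):
        p = tmp_path / "a.bedgraph"
        p.write_text("chrX\t0\t100\t1\n")
        with pytest.raises(ValueError, match="chrX"):
            read_bedgraph(p, grid_genome)

    def test_negative_count_rejected(self, grid_genome, tmp_path):
        p = tmp_path / "a.bedgraph"
        p.write_text("chr1\t0\t100\t-1\n")
        with pytest.raises(ValueError, match="negative"):
            read_bedgraph(p, grid_genome)

    def test_interval_beyond_chromosome_end(self, grid_genome, tmp_path):
        p = tmp_path / "a.bedgraph"
        p.write_text("chr1\t4000\t6000\t1\n")
        with pytest.raises(ValueError, match="invalid interval"):
            read_bedgraph(p, grid_genome)

    def test_roundtrip_with_writer(self, grid_genome, tmp_path):
        c = cov(grid_genome, {"chr1": [1, 2, 3, 4, 5]})
        p = tmp_path / "out.bedgraph"
        write_bedgraph(c, p)
        back = read_bedgraph(p, grid_genome)
        np.testing.assert_allclose(back.counts["chr1"], c.counts["chr1"])


class TestNormalizeRatio:
    def test_identity(self, grid_genome):
        a = cov(grid_genome, {"chr1": [50, 60, 70, 80, 90]})
        prof = normalize_ratio(a, a)
        np.testing.assert_allclose(prof.unmasked_values(), 1.0)

    def test_hand_arithmetic(self):
        g = GenomeSpec((("chr1", 2000),))
        prof = normalize_ratio(cov(g, {"chr1": [20, 10]}), cov(g, {"chr1": [10, 10]}))
        # S = 30, R = 20: (20/30)/(10/20) = 4/3; (10/30)/(10/20) = 2/3
        np.testing.assert_allclose(prof.values["chr1"], [4 / 3, 2 / 3])

    def test_zero_reference_bin_masked_others_unaffected(self):
        g = GenomeSpec((("chr1", 3000),))
        prof = normalize_ratio(cov(g, {"chr1": [10, 10, 10]}),
                               cov(g, {"chr1": [20, 0, 20]}))
        assert list(prof.masked["chr1"]) == [False, True, False]
        np.testing.assert_allclose(prof.values["chr1"][[0, 2]], [1.0, 1.0])

    def test_low_reference_bins_masked_by_threshold(self):
        g = GenomeSpec((("chr1", 2000),))
        prof = normalize_ratio(cov(g, {"chr1": [10, 10]}), cov(g, {"chr1": [9, 50]}),
                               min_ref_count=10)
        assert list(prof.masked["chr1"]) == [True, False]

    def test_grid_mismatch(self, grid_genome):
        a = cov(grid_genome, {"chr1": [1, 1, 1, 1, 1]})
        b = BinnedCoverage(grid_genome, 2500, {"chr1": np.array([1.0, 1.0])})
        with pytest.raises(ValueError, match="bin width"):
            normalize_ratio(a, b)

    def test_all_reference_below_threshold(self, grid_genome):
        a = cov(grid_genome, {"chr1": [1, 1, 1, 1, 1]})
        b = cov(grid_genome, {"chr1": [1, 1, 1, 1, 1]})
        with pytest.raises(ValueError, match="min_ref_count"):
            normalize_ratio(a, b, min_ref_count=10)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.floats(min_value=0.1, max_value=100.0))
    def test_scale_invariance(self, factor):
        g = GenomeSpec((("chr1", 4000),))
        s = [12, 30, 18, 25]
        r = [20, 20, 25, 15]
        base = normalize_ratio(cov(g, {"chr1": s}), cov(g, {"chr1": r}))
        scaled = normalize_ratio(cov(g, {"chr1": [x * factor for x in s]}),
                                 cov(g, {"chr1": r}))
        np.testing.assert_allclose(scaled.values["chr1"], base.values["chr1"])


class TestCalibrateBaseline:
    def test_constant_profile_to_baseline_two(self):
        prof = make_profile({"chr1": np.ones(100)})
        cal = calibrate_baseline(prof, 2)
        np.testing.assert_allclose(cal.unmasked_values(), 2.0)
        assert cal.baseline == 2

    def test_minor_high_component_does_not_shift_mode(self):
        # 90% of bins at 1.0, 10% at 1.5: mode is the majority level
        vals = np.concatenate([np.ones(180), np.full(20, 1.5)])
        cal = calibrate_baseline(make_profile({"chr1": vals}), 2)
        got = cal.unmasked_values()
        np.testing.assert_allclose(np.sort(np.unique(got)), [2.0, 3.0])

    def test_too_few_bins(self):
        with pytest.raises(ValueError, match="unmasked bins"):
            calibrate_baseline(make_profile({"chr1": np.ones(30)}), 2)

    def test_invalid_baseline(self):
        with pytest.raises(ValueError, match="baseline"):
            calibrate_baseline(make_profile({"chr1": np.ones(100)}), 3)

    def test_g2_simulation_baseline_recovered(self):
        """Licensing-intact control pushed through ratio + calibration sits at 2."""
        genome = default_genome()
        origins = default_origins(genome)
        cfg = SimConfig(seed=5)
        truth = simulate_g2_rereplication(genome, origins, cfg,
                                          RerepConfig(licensing_enabled=False))
        s = sample_reads(truth, cfg, seed=[5, 1])
        r = sample_reads(flat_profile(genome, cfg.bin_width, 2.0), cfg, seed=[5, 2])
        cal = calibrate_baseline(normalize_ratio(s, r), 2)
        assert abs(np.median(cal.unmasked_values()) - 2.0) < 0.02


class TestSmooth:
    def test_window_one_identity(self):
        prof = make_profile({"chr1": [1.0, 5.0, 2.0, 8.0, 3.0] * 2})
        out = smooth(prof, 1)
        np.testing.assert_allclose(out.values["chr1"], prof.values["chr1"])
        assert not out.smoothed

    def test_truncated_edges_hand_computed(self):
        prof = make_profile({"chr1": [1.0, 2.0, 3.0, 4.0, 5.0]})
        out = smooth(prof, 3)
        np.testing.assert_allclose(out.values["chr1"], [1.5, 2.0, 3.0, 4.0, 4.5])

    def test_even_window_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            smooth(make_profile({"chr1": np.ones(5)}), 4)

    def test_all_masked_chromosome_unchanged(self):
        masked = {"chr1": np.ones(5, dtype=bool)}
        prof = make_profile({"chr1": np.ones(5)}, masked=masked)
        out = smooth(prof, 3)
        assert out.masked["chr1"].all()
        assert np.isnan(out.values["chr1"]).all()

    def test_masked_bins_excluded_from_average(self):
        masked = {"chr1": np.array([False, True, False, False, False])}
        prof = make_profile({"chr1": [1.0, 100.0, 3.0, 4.0, 5.0]}, masked=masked)
        out = smooth(prof, 3)
        # bin 2's window is (masked, 3, 4) -> mean of 3 and 4
        assert out.values["chr1"][2] == pytest.approx(3.5)
        assert out.masked["chr1"][1]

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=10.0), min_size=3, max_size=40),
           st.sampled_from([3, 5, 7]))
    def test_never_widens_range_and_preserves_constant(self, vals, window):
        prof = make_profile({"chr1": vals})
        out = smooth(prof, window)
        got = out.unmasked_values()
        assert got.min() >= min(vals) - 1e-12
        assert got.max() <= max(vals) + 1e-12
        const = smooth(make_profile({"chr1": [4.2] * len(vals)}), window)
        np.testing.assert_allclose(const.unmasked_values(), 4.2)


class TestPipelineProperties:
    def test_masks_only_grow(self):
        """No pipeline step may un-mask a bin."""
        g = GenomeSpec((("chr1", 100_000),))
        rng = np.random.default_rng(0)
        s = cov(g, {"chr1": rng.poisson(100, 100).astype(float)})
        ref_counts = rng.poisson(100, 100).astype(float)
        ref_counts[7] = 0.0
        r = cov(g, {"chr1": ref_counts})
        prof = normalize_ratio(s, r)
        m0 = prof.masked["chr1"].copy()
        cal = calibrate_baseline(prof, 1)
        assert np.all(m0 <= cal.masked["chr1"])
        sm = smooth(cal, 5)
        assert np.all(cal.masked["chr1"] <= sm.masked["chr1"])

    def test_end_to_end_error_bounded_on_simulation(self):
        """Calibrated + smoothed estimate tracks the simulator truth to
        within 0.1 copy units (MAE) at read depth 100."""
        genome = default_genome()
        origins = default_origins(genome)
        cfg = SimConfig(seed=17)
        truth = simulate_g2_rereplication(genome, origins, cfg, RerepConfig())
        s = sample_reads(truth, cfg, seed=[17, 1])
        r = sample_reads(flat_profile(genome, cfg.bin_width, 2.0), cfg, seed=[17, 2])
        est = smooth(calibrate_baseline(normalize_ratio(s, r), 2), 15)
        errs = []
        for c in genome.names:
            ok = ~est.masked[c]
            errs.append(np.abs(est.values[c][ok] - truth.values[c][ok]))
        mae = np.concatenate(errs).mean()
        assert mae <= 0.1

    def test_profile_tsv_roundtrip(self, tmp_path):
        prof = make_profile({"chr1": [1.0, 1.5, 2.0, 1.0, 1.25]})
        path = tmp_path / "prof.tsv"
        prof.write_tsv(path, header_lines=["seed: 1"])
        back = read_profile_tsv(path, prof.genome)
        np.testing.assert_allclose(back.values["chr1"], prof.values["chr1"])
        np.testing.assert_array_equal(back.masked["chr1"], prof.masked["chr1"])
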