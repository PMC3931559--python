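import numpy as np
import pytest

import rdna_chromatin as rc
from rdna_chromatin.signal import (
    AlignedFragment,
    FragmentSet,
    background_stats,
    call_peaks,
    dedup,
    fragment_centers,
    kde_track,
    subtract_input,
)

from .oracles import direct_gaussian_sum


def _frags(centers, chrom="chr1", frag_size=200, read_length=36):
    """Build '+' strand fragments whose kernel centers are exactly ``centers``."""
    half = frag_size // 2
    return FragmentSet(
        [AlignedFragment(chrom, int(c) - half, "+", read_length) for c in centers],
        frag_size=frag_size,
        dedup_applied=True,
    )


class TestDedup:
    def test_one_fragment_per_position_strand(self):
        reads = [
            AlignedFragment("chr1", 10, "+"),
            AlignedFragment("chr1", 10, "+"),
            AlignedFragment("chr1", 10, "+"),
            AlignedFragment("chr1", 10, "-"),
        ]
        assert len(dedup(reads)) == 2

    def test_empty_input(self):
        assert len(dedup([])) == 0

    def test_order_independent(self):
        rng = np.random.default_rng(0)
        reads = [
            AlignedFragment("chr1", int(s), "+" if b else "-")
            for s, b in zip(rng.integers(0, 500, 1000), rng.integers(0, 2, 1000))
        ]
        shuffled = list(reads)
        rng.shuffle(shuffled)
        assert dedup(reads).fragments == dedup(shuffled).fragments

    def test_retained_count_equals_distinct_pairs(self):
        rng = np.random.default_rng(1)
        reads = [
            AlignedFragment("chr1", int(s), "+") for s in rng.integers(0, 300, 1000)
        ]
        expected = len({(r.chrom, r.start, r.strand) for r in reads})
        assert len(dedup(reads)) == expected


class TestKdeTrack:
    def test_single_fragment_peaks_at_center(self):
        track = kde_track(_frags([100]), ("chr1", 0, 1000), 50.0)
        assert int(np.argmax(track.values)) == 100

    def test_minus_strand_center(self):
        # '-' read at start s: center = s + read_length - frag_size/2
        frag = AlignedFragment("chr1", 164, "-", 36)
        fs = FragmentSet([frag], frag_size=200)
        assert fragment_centers(fs)[0] == 100.0

    def test_linearity(self):
        one = kde_track(_frags([300]), ("chr1", 0, 600), 50.0)
        two = kde_track(_frags([300, 300]), ("chr1", 0, 600), 50.0)
        np.testing.assert_allclose(two.values, 2 * one.values, rtol=1e-12)

    def test_matches_direct_gaussian_sum(self):
        rng = np.random.default_rng(11)
        centers = rng.integers(100, 9_900, size=500)
        track = kde_track(_frags(centers), ("chr1", 0, 10_000), 50.0)
        exact = direct_gaussian_sum(centers, 10_000, 50.0)
        np.testing.assert_allclose(track.values, exact, rtol=1e-6)

    def test_mass_conservation(self):
        rng = np.random.default_rng(12)
        centers = rng.integers(2_000, 8_000, size=300)  # kernels fully inside
        track = kde_track(_frags(centers), ("chr1", 0, 10_000), 50.0)
        assert track.values.sum() == pytest.approx(300, rel=1e-4)

    def test_shift_equivariance(self):
        centers = [500, 700, 900]
        d = 137
        base = kde_track(_frags(centers), ("chr1", 0, 2_000), 50.0)
        shifted = kde_track(
            _frags([c + d for c in centers]), ("chr1", d, 2_000 + d), 50.0
        )
        np.testing.assert_allclose(shifted.values, base.values, rtol=1e-12)
        p0 = call_peaks(base, threshold_sd=4.0)
        p1 = call_peaks(shifted, threshold_sd=4.0)
        assert [(p.start + d, p.end + d, p.summit + d) for p in p0] == [
            (p.start, p.end, p.summit) for p in p1
        ]

    def test_rejects_nonpositive_bandwidth(self):
        with pytest.raises(ValueError):
            kde_track(_frags([10]), ("chr1", 0, 100), 0.0)


class TestSubtractInput:
    def test_self_subtraction_is_zero(self):
        track = kde_track(_frags([100, 300]), ("chr1", 0, 500), 50.0)
        residual = subtract_input(track, track)
        np.testing.assert_array_equal(residual.values, np.zeros(500))
        assert residual.total_fragments == track.total_fragments

    def test_zero_input_fragments_rejected(self):
        chip = kde_track(_frags([100]), ("chr1", 0, 500), 50.0)
        empty = kde_track(_frags([]), ("chr1", 0, 500), 50.0)
        with pytest.raises(ValueError):
            subtract_input(chip, empty)

    def test_library_size_scaling(self):
        # chip = 2 copies of every input fragment: after scaling by the
        # fragment-count ratio (2) the libraries cancel exactly
        centers = [100, 200, 300]
        chip = kde_track(_frags(centers + centers), ("chr1", 0, 500), 50.0)
        inp = kde_track(_frags(centers), ("chr1", 0, 500), 50.0)
        residual = subtract_input(chip, inp)
        np.testing.assert_allclose(residual.values, np.zeros(500), atol=1e-15)

    def test_scaling_formula(self):
        chip = kde_track(_frags([100, 150, 300, 320]), ("chr1", 0, 500), 50.0)
        inp = kde_track(_frags([110, 290]), ("chr1", 0, 500), 50.0)
        residual = subtract_input(chip, inp)
        np.testing.assert_allclose(
            residual.values, chip.values - 2.0 * inp.values, rtol=1e-12
        )

    def test_length_mismatch_rejected(self):
        chip = kde_track(_frags([100]), ("chr1", 0, 500), 50.0)
        inp = kde_track(_frags([100]), ("chr1", 0, 400), 50.0)
        with pytest.raises(ValueError):
            subtract_input(chip, inp)

    def test_negative_residuals_retained(self):
        chip = kde_track(_frags([100]), ("chr1", 0, 500), 50.0)
        inp = kde_track(_frags([300]), ("chr1", 0, 500), 50.0)
        residual = subtract_input(chip, inp)
        assert residual.values.min() < 0


class TestCallPeaks:
    def test_flat_zero_track_has_no_peaks(self):
        track = kde_track(_frags([]), ("chr1", 0, 1_000), 50.0)
        assert call_peaks(track) == []

    def test_isolated_stack_gives_single_peak_at_center(self):
        track = kde_track(_frags([5_000] * 100), ("chr1", 0, 10_000), 50.0)
        peaks = call_peaks(track, threshold_sd=4.0)
        assert len(peaks) == 1
        assert peaks[0].summit == 5_000
        assert peaks[0].intensity == track.values.max()
        assert peaks[0].start <= peaks[0].summit < peaks[0].end

    def test_summit_tie_breaks_leftmost(self):
        from rdna_chromatin.signal import SignalTrack

        values = np.array([0.0, 0.0, 5.0, 5.0, 0.0])
        track = SignalTrack("chr1", 0, values, total_fragments=0, bandwidth=50.0)
        (peak,) = call_peaks(track, threshold_sd=0.0)
        assert peak.summit == 2

    def test_montecarlo_threshold_close_to_analytic(self):
        mu_a, sd_a = background_stats(10_000, 100_000, 50.0, "analytic")
        mu_m, sd_m = background_stats(10_000, 100_000, 50.0, "montecarlo", seed=5)
        t_a = mu_a + 4 * sd_a
        t_m = mu_m + 4 * sd_m
        assert abs(t_m - t_a) / t_a < 0.10

    def test_negative_threshold_sd_rejected(self):
        track = kde_track(_frags([100]), ("chr1", 0, 500), 50.0)
        with pytest.raises(ValueError):
            call_peaks(track, threshold_sd=-1.0)


class TestPeakRecoveryOnSimulation:
    @pytest.mark.parametrize("seed", [101, 102, 103])
    def test_designed_sites_recovered(self, seed):
        build, _ = rc.simulate_genome(
            rc.SyntheticGenomeSpec(
                host_length=40_000, repeat_length=10_000, n_pseudogenes=0, seed=seed
            )
        )
        ins = build.insertion
        region = (ins.chrom, 0, len(build.sequences[ins.chrom]))
        sites = rc.standard_sites(build.repeat_length)
        spec = rc.SyntheticReadSpec(
            n_reads=5_000,
            enrichment_sites=sites,
            enriched_fraction=0.3,
            dup_rate=0.1,
            seed=seed,
        )
        res = rc.simulate_reads(build, spec, mode="chip")
        track = kde_track(dedup(res.reads), region, 50.0)
        peaks = call_peaks(track, threshold_sd=4.0)
        for center in res.site_centers_build:
            covering = [p for p in peaks if p.start <= center < p.end]
            assert covering, f"site at {center} not covered by any peak"
            assert abs(covering[0].summit - center) <= track.bandwidth
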