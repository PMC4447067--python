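import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from sigchip.formats_io import GenomicInterval
from sigchip.peaks import (
    PeakCallParams,
    call_peaks,
    cross_correlation,
    locus_enrichment_ratio,
    window_poisson_test,
    window_scan,
)
from sigchip.synthetic import (
    SimulationParams,
    generate_genome,
    simulate_libraries,
    site_interval,
)
from sigchip.tracks import CoverageTrack, FragmentSet, coverage_from_fragments


def poisson_upper_tail_oracle(k: int, lam: float) -> float:
    """Direct term-by-term pmf summation of P(X >= k)."""
    if k <= 0:
        return 1.0
    total = 0.0
    for i in range(k, k + 2500):
        total += math.exp(i * math.log(lam) - lam - math.lgamma(i + 1))
    return total


class TestWindowPoissonTest:
    def test_zero_ip_count_returns_one(self):
        assert window_poisson_test(0, 50, 1.0) == 1.0
        assert window_poisson_test(0, 0, 2.0) == 1.0

    def test_matches_direct_summation(self):
        # ip=5, input=2, size_factor=1 -> sum_{i>=5} e^-2 2^i / i!
        assert window_poisson_test(5, 2, 1.0) == pytest.approx(
            poisson_upper_tail_oracle(5, 2.0), abs=1e-12
        )

    def test_strong_enrichment_is_tiny(self):
        assert window_poisson_test(50, 2, 1.0) < 1e-6

    def test_size_factor_must_be_positive(self):
        with pytest.raises(ValueError):
            window_poisson_test(5, 2, 0.0)

    @given(
        ip=st.integers(min_value=1, max_value=200),
        lam=st.floats(min_value=0.3, max_value=80),
    )
    def test_monotone_in_ip_count_and_lambda(self, ip, lam):
        p = window_poisson_test(ip, lam, 1.0)
        assert window_poisson_test(ip + 1, lam, 1.0) <= p
        assert window_poisson_test(ip, lam * 1.5, 1.0) >= p


class TestCallPeaks:
    def test_identical_tracks_give_no_peaks(self):
        p = SimulationParams(n_sites=0, depth=20_000, seed=3)
        seq, _, truth = generate_genome(p)
        ip, _ = simulate_libraries(seq, truth.sites, p)
        track = coverage_from_fragments(ip)
        assert call_peaks(track, track) == []

    def test_empty_tracks_rejected(self):
        empty = CoverageTrack("c", np.zeros(1000), 0)
        with pytest.raises(ValueError):
            call_peaks(empty, empty)

    def test_single_site_yields_one_covering_peak(self):
        """Each planted site is covered by exactly one peak, never split."""
        for seed in range(7, 18):
            p = SimulationParams(n_sites=1, depth=200_000, seed=seed, divergent_fraction=0.0)
            seq, _, truth = generate_genome(p)
            ip, inp = simulate_libraries(seq, truth.sites, p)
            peaks = call_peaks(coverage_from_fragments(ip), coverage_from_fragments(inp))
            site = truth.sites[0]
            covering = [pk for pk in peaks if pk.interval.contains(site.position)]
            assert len(covering) == 1
            assert covering[0].p_value <= 0.01
            assert covering[0].enrichment > 2

    def test_two_distant_sites_never_merge(self):
        from sigchip.synthetic import PlantedSite

        sites = tuple(
            PlantedSite(
                position=pos,
                promoter_class="sigmaS",
                promoter_sequence="A" * 21,
                enrichment_fold=10.0,
                tss=pos + 15,
                strand="+",
                gene_ids=(),
                layout="unequivocal",
            )
            for pos in (50_000, 60_000)
        )
        for seed in range(5):
            p = SimulationParams(n_sites=0, depth=200_000, seed=seed)
            ip, inp = simulate_libraries(200_000, sites, p)
            peaks = call_peaks(coverage_from_fragments(ip), coverage_from_fragments(inp))
            hits = [
                pk for pk in peaks if any(pk.interval.contains(s.position) for s in sites)
            ]
            assert len(hits) == 2
            assert not any(
                pk.interval.contains(sites[0].position)
                and pk.interval.contains(sites[1].position)
                for pk in peaks
            )

    def test_peak_widths_concentrate_below_twice_fragment_length(self):
        p = SimulationParams(n_sites=10, depth=200_000, seed=5)
        seq, _, truth = generate_genome(p)
        ip, inp = simulate_libraries(seq, truth.sites, p)
        peaks = call_peaks(coverage_from_fragments(ip), coverage_from_fragments(inp))
        site_peaks = [
            pk
            for pk in peaks
            if any(pk.interval.contains(s.position) for s in truth.sites)
        ]
        widths = [pk.interval.width for pk in site_peaks]
        assert np.median(widths) <= 2 * 400

    def test_null_calibration_is_conservative(self):
        """Window discovery fraction under fold=1 stays at/below nominal alpha."""
        fracs_01, fracs_05 = [], []
        for seed in range(10):
            p = SimulationParams(n_sites=0, depth=50_000, seed=seed)
            seq, _, truth = generate_genome(p)
            ip, inp = simulate_libraries(seq, truth.sites, p)
            _, pvals = window_scan(
                coverage_from_fragments(ip), coverage_from_fragments(inp)
            )
            fracs_01.append((pvals <= 0.01).mean())
            fracs_05.append((pvals <= 0.05).mean())
        n = 10 * len(pvals)
        for alpha, fracs in ((0.01, fracs_01), (0.05, fracs_05)):
            se = math.sqrt(alpha * (1 - alpha) / n)
            assert np.mean(fracs) <= alpha + 2 * se

    def test_summit_lies_inside_peak(self, small_simulation):
        peaks = call_peaks(small_simulation["ip_cov"], small_simulation["input_cov"])
        for pk in peaks:
            assert pk.interval.start <= pk.summit <= pk.interval.end


class TestCrossCorrelation:
    @staticmethod
    def _point_source_fragments(rng, frag_len=250, n=300, L=200_000):
        pos = rng.integers(1000, L - 1000, n)
        starts = np.concatenate([pos, pos])
        lengths = np.full(2 * n, frag_len)
        strands = np.array(["+"] * n + ["-"] * n)
        return FragmentSet("c", L, starts, lengths, strands)

    def test_estimate_equals_constructed_length(self, rng):
        frags = self._point_source_fragments(rng)
        _, estimate = cross_correlation(frags, max_shift=500)
        assert abs(estimate - 250) <= 1

    def test_strand_swap_gives_identical_profile(self, rng):
        frags = self._point_source_fragments(rng)
        swapped = FragmentSet(
            frags.chrom,
            frags.genome_length,
            frags.start,
            frags.length,
            np.where(frags.strand == "+", "-", "+"),
        )
        a, _ = cross_correlation(frags, max_shift=400)
        b, _ = cross_correlation(swapped, max_shift=400)
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_profile_bounded_by_one(self, rng):
        frags = self._point_source_fragments(rng, frag_len=180)
        profile, _ = cross_correlation(frags, max_shift=500)
        assert profile.min() >= -1 - 1e-12
        assert profile.max() <= 1 + 1e-12

    def test_single_strand_data_rejected(self):
        frags = FragmentSet(
            "c", 1000, np.array([10, 50]), np.array([100, 100]), np.array(["+", "+"])
        )
        with pytest.raises(ValueError, match="strand"):
            cross_correlation(frags, max_shift=300)


class TestLocusEnrichmentRatio:
    def test_uniform_coverage_gives_unity(self):
        track = CoverageTrack("c", np.full(1000, 5.0), 100)
        target = GenomicInterval("c", 100, 199)
        refs = [GenomicInterval("c", 400, 499), GenomicInterval("c", 700, 799)]
        assert locus_enrichment_ratio(track, track, target, refs) == (1.0, 1.0)

    def test_target_equal_to_reference_is_exactly_one(self, small_simulation):
        iv = GenomicInterval("synchrom", 10_000, 10_499)
        r_ip, r_in = locus_enrichment_ratio(
            small_simulation["ip_cov"], small_simulation["input_cov"], iv, [iv]
        )
        assert (r_ip, r_in) == (1.0, 1.0)

    def test_zero_reference_coverage_rejected(self):
        depth = np.zeros(1000)
        depth[100:200] = 4
        track = CoverageTrack("c", depth, 10)
        with pytest.raises(ValueError, match="reference"):
            locus_enrichment_ratio(
                track, track, GenomicInterval("c", 101, 200), [GenomicInterval("c", 500, 599)]
            )


class TestPeakCallParams:
    @pytest.mark.parametrize("kwargs", [{"step": 0}, {"step": 300}, {"p_threshold": 0.0}])
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            PeakCallParams(**kwargs)
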