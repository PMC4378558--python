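import numpy as np
import pytest
from conftest import make_match, match_from_pattern
from hypothesis import given, settings
from hypothesis import strategies as st

from envdeconv.constants import H2O_MASS, ISOTOPE_SPACING, PROTON_MASS
from envdeconv.detect import (
    annotate_support,
    estimate_noise_level,
    generate_candidates,
    match_peaks,
    passes_filters,
    scale_theoretical,
)
from envdeconv.isotope import TheoreticalDistribution, averagine_distribution, align_to_base_peak
from envdeconv.msio import Spectrum
from envdeconv.simulate import SimulationConfig, simulate_spectrum


def _dist(mz, prob, z=1, mono=None):
    mz = np.asarray(mz, dtype=float)
    if mono is None:
        mono = (mz[0] - PROTON_MASS) * z
    return TheoreticalDistribution(z=z, mz=mz, prob=np.asarray(prob, float), monoisotopic_mass=mono)


class TestNoiseLevel:
    def test_noise_floor_dominates(self):
        mz = np.arange(100, 205, 1.0)
        intensity = np.concatenate([np.full(100, 1.0), np.full(5, 100.0)])
        level = estimate_noise_level(Spectrum(mz[:105], intensity))
        assert level < 100.0
        assert level >= 1.0  # the populated bin contains the noise peaks

    def test_all_identical_intensity(self):
        s = Spectrum(np.array([100.0, 200.0, 300.0]), np.array([5.0, 5.0, 5.0]))
        level = estimate_noise_level(s)
        assert level >= 5.0  # zero signal peaks remain
        assert (s.intensity > level).sum() == 0

    def test_single_peak(self):
        s = Spectrum(np.array([100.0]), np.array([42.0]))
        assert estimate_noise_level(s) >= 42.0

    def test_empty_spectrum_rejected(self):
        with pytest.raises(ValueError):
            estimate_noise_level(Spectrum(np.empty(0), np.empty(0)))

    def test_scales_with_intensity(self):
        rng = np.random.default_rng(0)
        mz = np.sort(rng.uniform(100, 1000, 300))
        intensity = rng.uniform(1, 100, 300)
        a = estimate_noise_level(Spectrum(mz, intensity))
        b = estimate_noise_level(Spectrum(mz, intensity * 137.0))
        assert b == pytest.approx(a * 137.0, rel=1e-9)


class TestMatchPeaks:
    def test_exact_positions(self):
        dist = _dist([100.0, 101.0, 102.0], [0.2, 0.5, 0.3])
        spec = Spectrum(np.array([100.0, 101.0, 102.0]), np.array([2.0, 5.0, 3.0]))
        env = match_peaks(dist, spec, tol=0.02)
        assert not env.placeholder.any()
        assert np.allclose(env.mz, dist.mz)

    def test_all_placeholders(self):
        dist = _dist([100.0, 101.0], [0.5, 0.5])
        spec = Spectrum(np.array([500.0]), np.array([1.0]))
        env = match_peaks(dist, spec, tol=0.02)
        assert env.placeholder.all()
        assert np.all(env.intensity == 0)
        assert np.allclose(env.mz, dist.mz)

    def test_nearest_wins(self):
        dist = _dist([100.0], [1.0])
        spec = Spectrum(np.array([99.994, 100.004]), np.array([10.0, 1.0]))
        env = match_peaks(dist, spec, tol=0.01)
        assert env.mz[0] == pytest.approx(100.004)

    def test_placeholder_outside_tolerance(self):
        dist = _dist([100.0], [1.0])
        spec = Spectrum(np.array([100.05]), np.array([1.0]))
        env = match_peaks(dist, spec, tol=0.02)
        assert env.placeholder[0]


class TestScaleTheoretical:
    def test_ratio_from_top_three(self):
        dist = _dist([100.0, 101.0, 102.0], [0.5, 0.3, 0.2])
        spec = Spectrum(np.array([100.0, 101.0, 102.0]), np.array([50.0, 30.0, 20.0]))
        env = match_peaks(dist, spec, tol=0.01)
        theo, exp = scale_theoretical(dist, env, noise=0.0)
        assert np.allclose(theo.intensity, [50.0, 30.0, 20.0])
        assert theo.k == 3

    def test_sub_noise_peaks_pruned_in_lockstep(self):
        dist = _dist([100.0, 101.0, 102.0], [0.5, 0.3, 0.2])
        spec = Spectrum(np.array([100.0, 101.0, 102.0]), np.array([50.0, 30.0, 20.0]))
        env = match_peaks(dist, spec, tol=0.01)
        theo, exp = scale_theoretical(dist, env, noise=25.0)
        assert theo.k == 2
        assert len(exp) == 2
        assert np.allclose(theo.intensity, [50.0, 30.0])

    def test_fewer_than_three_peaks_uses_all(self):
        dist = _dist([100.0, 101.0], [0.6, 0.4])
        spec = Spectrum(np.array([100.0, 101.0]), np.array([30.0, 20.0]))
        env = match_peaks(dist, spec, tol=0.01)
        theo, _ = scale_theoretical(dist, env, noise=0.0)
        assert np.allclose(theo.intensity, [30.0, 20.0])

    def test_all_top_placeholders_rejected(self):
        dist = _dist([100.0, 101.0, 102.0], [0.5, 0.3, 0.2])
        spec = Spectrum(np.array([500.0]), np.array([1.0]))
        env = match_peaks(dist, spec, tol=0.01)
        assert scale_theoretical(dist, env, noise=0.0) is None


class TestFilters:
    @pytest.mark.parametrize(
        "pattern,expected",
        [
            ("mm", True),
            ("m.", False),       # 2 theoretical peaks, 1 missing
            ("mm.", True),
            ("m..", False),      # 3 theoretical peaks, 2 missing
            ("m.m.mm", False),   # longest run 2 < k - 3 = 3
            ("mmm.mm", True),
            ("mm...", False),    # >= 3 missing
        ],
    )
    def test_quoted_clauses(self, pattern, expected):
        assert passes_filters(match_from_pattern(pattern)) is expected

    @settings(max_examples=200, deadline=None)
    @given(st.lists(st.booleans(), min_size=2, max_size=12))
    def test_agrees_with_independent_clause_check(self, matched):
        pattern = "".join("m" if m else "." for m in matched)
        k = len(matched)
        missing = matched.count(False)
        longest = run = 0
        for m in matched:
            run = run + 1 if m else 0
            longest = max(longest, run)
        expected = not (
            missing >= 3
            or (k == 3 and missing == 2)
            or (k == 2 and missing == 1)
            or longest < k - 3
        )
        assert passes_filters(match_from_pattern(pattern)) is expected


class TestGenerateCandidates:
    def test_clean_envelope_recovered(self):
        cfg = SimulationConfig(
            n_ions=1, seed=11, charge_range=(3, 3), mass_range=(3000.0, 3000.0),
            noise_sigma=0.0, jitter_ppm=0.0, dropout=0.0, n_noise_peaks=0,
        )
        spec, gt = simulate_spectrum(cfg)
        candidates = generate_candidates(spec, max_charge=5, noise=0.0)
        truth = gt.ions[0].monoisotopic_mass
        hits = [
            c for c in candidates
            if c.charge == 3
            and min(abs(c.monoisotopic_mass - truth),
                    abs(abs(c.monoisotopic_mass - truth) - ISOTOPE_SPACING))
            <= 15e-6 * truth
        ]
        assert hits

    def test_pure_subthreshold_noise_empty(self):
        rng = np.random.default_rng(3)
        spec = Spectrum(np.sort(rng.uniform(300, 800, 50)), np.full(50, 10.0))
        # all peaks at/below the declared noise level -> no signal peaks
        assert generate_candidates(spec, max_charge=5, noise=10.0) == []

    def test_noiseless_multi_envelope_full_recovery(self):
        cfg = SimulationConfig(
            n_ions=5, seed=4, charge_range=(1, 6), mass_range=(1000.0, 4000.0),
            noise_sigma=0.0, jitter_ppm=0.0, dropout=0.0, n_noise_peaks=0,
        )
        spec, gt = simulate_spectrum(cfg)
        candidates = generate_candidates(spec, max_charge=8, noise=0.0)
        for ion in gt.ions:
            truth = ion.monoisotopic_mass
            assert any(
                c.charge == ion.charge
                and min(abs(c.monoisotopic_mass - truth),
                        abs(abs(c.monoisotopic_mass - truth) - ISOTOPE_SPACING))
                <= 15e-6 * truth
                for c in candidates
            ), f"planted ion {truth:.2f} z={ion.charge} not recovered"

    def test_filters_hold_on_all_candidates(self):
        cfg = SimulationConfig(n_ions=6, seed=9)
        spec, _ = simulate_spectrum(cfg)
        for cand in generate_candidates(spec, max_charge=10):
            assert passes_filters(cand)
            assert cand.k >= 2


class TestAnnotateSupport:
    def _candidate(self, mass, z):
        dist = averagine_distribution(mass, z)
        base = float(dist.mz[dist.index_of_most_abundant])
        aligned = align_to_base_peak(dist, base)
        theo_int = aligned.prob * 1000.0
        return make_match(aligned.mz, theo_int, z=z, mono=aligned.monoisotopic_mass)

    def test_mutual_support_different_charges(self):
        a = self._candidate(2000.0, 2)
        b = self._candidate(2000.0, 3)
        b.theoretical.monoisotopic_mass = a.theoretical.monoisotopic_mass
        annotate_support([a, b])
        assert a.supporting_count == 1
        assert b.supporting_count == 1

    def test_same_charge_not_supporting(self):
        a = self._candidate(2000.0, 2)
        b = self._candidate(2000.0, 2)
        annotate_support([a, b])
        assert a.supporting_count == 0

    def test_neutral_loss_detected(self):
        a = self._candidate(2000.0, 2)
        b = self._candidate(2000.0, 3)
        b.theoretical.monoisotopic_mass = a.theoretical.monoisotopic_mass - H2O_MASS
        annotate_support([a, b])
        assert a.neutral_loss_count == 1
        assert b.neutral_loss_count == 0

    def test_singleton(self):
        a = self._candidate(1500.0, 1)
        annotate_support([a])
        assert a.supporting_count == 0
        assert a.neutral_loss_count == 0

    def test_counts_match_pairwise_oracle_and_are_symmetric(self):
        rng = np.random.default_rng(2)
        cands = [
            self._candidate(float(rng.uniform(1000, 3000)), int(z))
            for z in rng.integers(1, 6, 12)
        ]
        # force a few coincidences
        cands[1].theoretical.monoisotopic_mass = cands[0].monoisotopic_mass
        cands[3].theoretical.monoisotopic_mass = cands[0].monoisotopic_mass + ISOTOPE_SPACING
        annotate_support(cands)

        def supports(a, b):
            tol = 15e-6 * a.monoisotopic_mass
            diff = abs(a.monoisotopic_mass - b.monoisotopic_mass)
            return min(diff, abs(diff - ISOTOPE_SPACING)) <= tol and a.charge != b.charge

        for a in cands:
            expected = sum(supports(a, b) for b in cands if b is not a)
            assert a.supporting_count == expected
        for a in cands:
            for b in cands:
                if a is not b:
                    assert supports(a, b) == supports(b, a)
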