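"""Genotype coding, haplotype construction and closed-form moments."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import gembayes as gb
from gembayes.genotype import (
    EnumerationCapError,
    InvalidLDError,
    MissingGenotypeError,
    _delta_bounds,
    estimate_panel,
    genotype_states,
    sample_genotypes,
)


class TestCodes:
    @pytest.mark.parametrize("g, expected", [(2, 1.0), (1, 0.0), (0, -1.0)])
    def test_additive_code(self, g, expected):
        assert gb.encode_additive(np.array([g]))[0] == expected

    @pytest.mark.parametrize(
        "g, p, expected",
        [(2, 0.25, -0.5625), (1, 0.25, 0.1875), (0, 0.5, -0.25)],
    )
    def test_dominance_code(self, g, p, expected):
        panel = gb.MarkerPanel([p])
        assert gb.encode_dominance(np.array([g]), panel)[0] == pytest.approx(expected)

    def test_missing_entries_rejected(self):
        with pytest.raises(MissingGenotypeError):
            gb.encode_additive(np.array([1, gb.MISSING]))
        with pytest.raises(MissingGenotypeError):
            gb.encode_dominance(np.array([np.nan, 1.0]), gb.MarkerPanel([0.3, 0.3]))

    @given(st.lists(st.integers(0, 2), min_size=1, max_size=6))
    def test_codes_pure_and_total(self, g):
        g = np.array(g)
        a1, a2 = gb.encode_additive(g), gb.encode_additive(g)
        assert np.array_equal(a1, a2)
        assert set(np.unique(a1)) <= {-1.0, 0.0, 1.0}

    def test_dominance_zero_mean_under_hwe(self):
        panel = gb.MarkerPanel([0.3])
        states, probs = gb.joint_genotype_distribution(panel)
        b = gb.encode_dominance(states, panel)[:, 0]
        assert probs @ b == pytest.approx(0.0, abs=1e-12)


class TestHaplotypes:
    def test_independence_product(self):
        panel = gb.MarkerPanel([0.25, 0.25])
        patterns, freqs = gb.haplotype_frequencies(panel)
        mm = np.all(patterns == 1, axis=1)
        assert freqs[mm][0] == pytest.approx(0.0625)

    def test_pairwise_ld_shifts_double_m(self):
        panel = gb.MarkerPanel([0.25, 0.25], [[0, 0.03], [0.03, 0]])
        patterns, freqs = gb.haplotype_frequencies(panel)
        mm = np.all(patterns == 1, axis=1)
        assert freqs[mm][0] == pytest.approx(0.0925)

    def test_infeasible_ld_raises(self):
        with pytest.raises(InvalidLDError):
            gb.MarkerPanel([0.25, 0.25], [[0, 0.2], [0.2, 0]])

    def test_margins_and_covariance_match_parameters(self, three_marker_panel):
        patterns, freqs = gb.haplotype_frequencies(three_marker_panel)
        assert freqs.sum() == pytest.approx(1.0)
        marg = freqs @ patterns
        np.testing.assert_allclose(marg, three_marker_panel.p_m, atol=1e-12)
        for i, j in itertools.combinations(range(3), 2):
            cov = freqs @ (patterns[:, i] * patterns[:, j]) - marg[i] * marg[j]
            assert cov == pytest.approx(0.03, abs=1e-12)

    @given(
        p1=st.floats(0.05, 0.95),
        p2=st.floats(0.05, 0.95),
        frac=st.floats(0.0, 0.99),
    )
    @settings(max_examples=50, deadline=None)
    def test_any_in_bounds_delta_gives_valid_table(self, p1, p2, frac):
        lo, hi = _delta_bounds(p1, p2)
        delta = lo + frac * (hi - lo)
        panel = gb.MarkerPanel([p1, p2], [[0, delta], [delta, 0]])
        _, freqs = gb.haplotype_frequencies(panel)
        assert np.all(freqs >= 0)
        assert freqs.sum() == pytest.approx(1.0)


class TestGenotypeDistribution:
    def test_single_marker_hwe(self):
        states, probs = gb.joint_genotype_distribution(gb.MarkerPanel([0.25]))
        lookup = dict(zip(states[:, 0].tolist(), probs))
        assert lookup[2] == pytest.approx(0.0625)
        assert lookup[1] == pytest.approx(0.375)
        assert lookup[0] == pytest.approx(0.5625)

    def test_normalization(self, three_marker_panel):
        _, probs = gb.joint_genotype_distribution(three_marker_panel)
        assert probs.sum() == pytest.approx(1.0, abs=1e-12)

    def test_marginals_are_hwe_despite_ld(self):
        """Enumerate the two-marker table; each margin stays HWE at 0.25."""
        panel = gb.MarkerPanel([0.25, 0.25], [[0, 0.03], [0.03, 0]])
        states, probs = gb.joint_genotype_distribution(panel)
        hwe = {2: 0.0625, 1: 0.375, 0: 0.5625}
        for m in (0, 1):
            for gval, expected in hwe.items():
                assert probs[states[:, m] == gval].sum() == pytest.approx(expected)

    def test_equilibrium_factorizes(self, three_marker_panel):
        panel0 = three_marker_panel.with_delta_zero()
        states, probs = gb.joint_genotype_distribution(panel0)
        _, per = gb.joint_genotype_distribution(gb.MarkerPanel([0.25]))
        product = np.prod(per[states], axis=1)
        np.testing.assert_allclose(probs, product, atol=1e-14)

    def test_enumeration_cap(self):
        with pytest.raises(EnumerationCapError):
            genotype_states(11)


class TestMoments:
    def test_closed_forms(self, three_marker_panel):
        mom = gb.coding_moments(three_marker_panel)
        np.testing.assert_allclose(mom["E_A"], -0.5)
        np.testing.assert_allclose(mom["E_B"], 0.0)
        assert mom["V_A"][0, 0] == pytest.approx(0.375)
        assert mom["V_A"][0, 1] == pytest.approx(0.06)
        assert mom["V_D"][0, 0] == pytest.approx(0.25**2 * 0.75**2)
        assert mom["V_D"][0, 1] == pytest.approx(0.0009)

    def test_exact_moments_from_enumeration(self, three_marker_panel):
        """The printed closed forms agree with full enumeration of the
        genotype distribution (exact, not Monte Carlo)."""
        panel = three_marker_panel
        states, probs = gb.joint_genotype_distribution(panel)
        a = gb.encode_additive(states)
        b = gb.encode_dominance(states, panel)
        mom = gb.coding_moments(panel)
        np.testing.assert_allclose(probs @ a, mom["E_A"], atol=1e-12)
        np.testing.assert_allclose(probs @ b, mom["E_B"], atol=1e-12)
        cov_a = (a * probs[:, None]).T @ a - np.outer(probs @ a, probs @ a)
        np.testing.assert_allclose(cov_a, mom["V_A"], atol=1e-12)
        cov_b = (b * probs[:, None]).T @ b - np.outer(probs @ b, probs @ b)
        np.testing.assert_allclose(cov_b, mom["V_D"], atol=1e-12)
        cross = (a * probs[:, None]).T @ b
        np.testing.assert_allclose(cross, 0.0, atol=1e-12)

    def test_monte_carlo_moments(self, three_marker_panel):
        """10^5 sampled genotypes reproduce the closed-form moments to 3 SE."""
        rng = np.random.default_rng(2024)
        n = 100_000
        g = sample_genotypes(three_marker_panel, n, rng)
        a = gb.encode_additive(g)
        mom = gb.coding_moments(three_marker_panel)
        se_mean = np.sqrt(np.diag(mom["V_A"]) / n)
        np.testing.assert_array_less(np.abs(a.mean(0) - mom["E_A"]), 3 * se_mean)
        emp_cov = np.cov(a.T)
        # SE of a covariance entry is approx sqrt((v_ii v_jj + v_ij^2)/n)
        v = mom["V_A"]
        se_cov = np.sqrt((np.outer(np.diag(v), np.diag(v)) + v**2) / n)
        assert np.all(np.abs(emp_cov - v) < 3 * se_cov + 1e-12)


class TestEstimatePanel:
    def test_recovers_parameters_from_large_sample(self, three_marker_panel):
        rng = np.random.default_rng(7)
        g = sample_genotypes(three_marker_panel, 60_000, rng)
        panel = estimate_panel(g)
        np.testing.assert_allclose(panel.p_m, 0.25, atol=0.01)
        np.testing.assert_allclose(panel.delta[0, 1], 0.03, atol=0.01)

    def test_handles_missing(self, three_marker_panel):
        rng = np.random.default_rng(8)
        g = sample_genotypes(three_marker_panel, 5000, rng).astype(float)
        g[rng.random(g.shape) < 0.3] = gb.MISSING
        panel = estimate_panel(g)
        assert np.all((panel.p_m > 0.15) & (panel.p_m < 0.35))
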