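import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from invcline import clinefit
from invcline.clinefit import (
    ClineParams,
    cline_frequency,
    fis_by_bins,
    fis_by_bins_multiallelic,
    fit_frequency_cline,
    fit_size_cline,
    map_legacy_sites,
    project_to_path,
    scan_snp_clines,
    selection_from_width,
)


def _sigmoid_fit(params):
    """Wrap known parameters as a ClineFit for the F_IS machinery."""
    m = clinefit.ModelFit(params.shape, None, params, 0.0, 0.0, 4, True)
    return clinefit.ClineFit(models={params.shape: m}, selected=params.shape)


class TestClineFrequency:
    def test_center_symmetry(self):
        p = ClineParams(center=85, width=65, pmin=0, pmax=1)
        assert cline_frequency(85.0, p) == pytest.approx(0.5)

    def test_limits(self):
        p = ClineParams(center=85, width=65, pmin=0.03, pmax=0.97)
        assert cline_frequency(1e6, p) == pytest.approx(0.97)
        assert cline_frequency(-1e6, p) == pytest.approx(0.03)

    def test_high_precision_point(self):
        """Half a width right of center the sigmoid is 1/(1+e^-2)."""
        p = ClineParams(center=100, width=65, pmin=0, pmax=1)
        assert cline_frequency(132.5, p) == pytest.approx(1 / (1 + np.exp(-2)),
                                                          abs=1e-12)

    @given(st.floats(-50, 250), st.floats(-50, 250),
           st.floats(1, 50), st.floats(1, 50),
           st.floats(0.05, 1), st.floats(0.05, 1))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_monotone_and_continuous_with_tails(self, x1, x2, dl, dr, tl, tr):
        p = ClineParams(shape="sigmoid_indep", center=85, width=65,
                        pmin=0.0, pmax=1.0, delta_l=dl, tau_l=tl,
                        delta_r=dr, tau_r=tr)
        lo, hi = sorted([x1, x2])
        assert cline_frequency(lo, p) <= cline_frequency(hi, p) + 1e-12

    @pytest.mark.parametrize("delta", [10.0, 30.0])
    def test_continuity_at_junctions(self, delta):
        p = ClineParams(shape="sigmoid_both", center=85, width=65,
                        pmin=0, pmax=1, delta_l=delta, tau_l=0.5,
                        delta_r=delta, tau_r=0.5)
        for xj in (85 - delta, 85 + delta):
            below = cline_frequency(xj - 1e-9, p)
            above = cline_frequency(xj + 1e-9, p)
            assert below == pytest.approx(above, abs=1e-6)

    def test_c1_at_junctions_when_tau_one(self):
        """With tau = 1 the tails attach with a continuous derivative."""
        p = ClineParams(shape="sigmoid_both", center=85, width=65,
                        pmin=0, pmax=1, delta_l=20, tau_l=1.0,
                        delta_r=20, tau_r=1.0)
        h = 1e-5
        for xj in (65.0, 105.0):
            d_below = (cline_frequency(xj - h, p)
                       - cline_frequency(xj - 3 * h, p)) / (2 * h)
            d_above = (cline_frequency(xj + 3 * h, p)
                       - cline_frequency(xj + h, p)) / (2 * h)
            assert d_below == pytest.approx(d_above, rel=1e-3)


class TestFrequencyClineFit:
    def test_monomorphic_returns_constant_with_note(self):
        x = np.linspace(0, 175, 40)
        fit = fit_frequency_cline(x, np.zeros(40), 2)
        assert fit.selected == "constant"
        assert "monomorphic" in fit.note
        assert fit.params.pmin == pytest.approx(0.0, abs=1e-4)

    def test_tail_models_never_lose_likelihood(self):
        """Nesting: each tail extension reaches at least the plain sigmoid
        likelihood (tails pushed outside the data reproduce it exactly)."""
        rng = np.random.default_rng(3)
        p = ClineParams(center=85, width=65, pmin=0.03, pmax=0.97)
        x = rng.uniform(0, 175, 120)
        g = rng.binomial(2, cline_frequency(x, p))
        fit = fit_frequency_cline(x, g, 2, compute_ci=False)
        base = fit.models["sigmoid"].loglik
        for shape in ("sigmoid_left", "sigmoid_right", "sigmoid_both",
                      "sigmoid_indep"):
            assert fit.models[shape].loglik >= base - 1e-6

    def test_recovers_center_within_ci(self):
        rng = np.random.default_rng(11)
        p = ClineParams(center=85, width=65, pmin=0.03, pmax=0.97)
        x = rng.uniform(0, 175, 200)
        g = rng.binomial(2, cline_frequency(x, p))
        fit = fit_frequency_cline(x, g, 2,
                                  shapes=("constant", "linear", "sigmoid"))
        lo, hi = fit.ci["c"]
        assert lo < 85 < hi
        assert fit.gof > 0.4

    def test_requires_two_positions(self):
        with pytest.raises(ValueError, match="distinct positions"):
            fit_frequency_cline([5.0, 5.0], [0, 1], 2)


class TestSizeCline:
    def test_recovers_size_ratio(self):
        """Simulated 1.5x dimorphism: fitted end-mean ratio in [1.3, 1.7]."""
        rng = np.random.default_rng(5)
        x = rng.uniform(0, 175, 200)
        frac = cline_frequency(x, ClineParams(center=85, width=65,
                                              pmin=0, pmax=1))
        mu = 9.0 - 3.0 * frac  # large ecotype at x=0
        y = rng.normal(mu, 0.8)
        fit = fit_size_cline(x, y)
        p = fit.params
        ratio = max(p.mu_min, p.mu_max) / min(p.mu_min, p.mu_max)
        assert 1.3 <= ratio <= 1.7
        assert fit.ci["c"][0] < 85 < fit.ci["c"][1]

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError, match="variance"):
            fit_size_cline(np.linspace(0, 100, 20), np.full(20, 7.0))

    def test_flat_profile_flagged(self):
        rng = np.random.default_rng(0)
        x = np.linspace(0, 175, 60)
        y = 7.0 + rng.normal(0, 1e-3, 60)
        fit = fit_size_cline(x, y)
        assert "unidentifiable" in fit.note


class TestFisBins:
    def test_hobs_equals_hexp_gives_zero(self):
        params = ClineParams(shape="constant", pmin=0.5, pmax=0.5)
        x = np.linspace(0, 100, 40)
        # 50% heterozygotes exactly matches 2pq = 0.5
        g = np.tile([0, 1, 1, 2], 10)
        res = fis_by_bins(g, x, _sigmoid_fit(params), nbins=1, n_boot=200,
                          seed=0)
        assert res.table["fis"].iloc[0] == pytest.approx(0.0)

    def test_complete_wahlund_gives_one(self):
        params = ClineParams(shape="constant", pmin=0.5, pmax=0.5)
        x = np.concatenate([np.full(10, 5.0), np.full(10, 95.0)])
        g = np.concatenate([np.zeros(10, int), np.full(10, 2, int)])
        res = fis_by_bins(g, x, _sigmoid_fit(params), nbins=1, n_boot=200,
                          seed=0)
        assert res.table["fis"].iloc[0] == 1.0
        assert res.table["h_obs"].iloc[0] == 0.0

    def test_empty_bin_missing(self):
        params = ClineParams(shape="constant", pmin=0.5, pmax=0.5)
        x = np.concatenate([np.full(10, 0.0), np.full(10, 70.0)])
        g = np.tile([0, 1], 10)
        res = fis_by_bins(g, x, _sigmoid_fit(params), nbins=7, n_boot=100,
                          seed=0)
        assert res.table["fis"].isna().sum() == 5

    def test_multiallelic_null_near_zero(self):
        """Three-allele genotypes drawn from renormalized per-allele clines
        under HWE give mean F_IS near zero."""
        rng = np.random.default_rng(4)
        x = rng.uniform(0, 175, 600)
        p120 = cline_frequency(x, ClineParams(center=85, width=65,
                                              pmin=0.02, pmax=0.95))
        p80 = (1 - p120) * 0.19
        p100 = (1 - p120) * 0.81
        P = np.stack([p80, p100, p120], axis=1)
        pairs = np.stack([
            np.array([rng.choice(3, p=row) for row in P]),
            np.array([rng.choice(3, p=row) for row in P]),
        ], axis=1)
        fits = [
            _sigmoid_fit(ClineParams(center=85, width=65, pmin=0.19 * 0.98,
                                     pmax=0.19 * 0.05)),
            _sigmoid_fit(ClineParams(center=85, width=65, pmin=0.81 * 0.98,
                                     pmax=0.81 * 0.05)),
            _sigmoid_fit(ClineParams(center=85, width=65, pmin=0.02,
                                     pmax=0.95)),
        ]
        res = fis_by_bins_multiallelic(pairs, x, fits, n_boot=400, seed=0)
        assert abs(np.nanmean(res.table["fis"])) < 0.08


class TestGeometry:
    def test_point_on_path(self):
        wp = [(0, 0), (10, 0), (10, 10)]
        pos = project_to_path([(4, 0), (10, 3)], wp)
        np.testing.assert_allclose(pos, [4.0, 13.0])

    def test_right_angle_oracle(self):
        """Foot of the perpendicular onto the first segment; arc length from
        elementary geometry."""
        wp = [(0, 0), (10, 0), (10, 10)]
        pos = project_to_path([(3, 4)], wp)
        assert pos[0] == pytest.approx(3.0)

    def test_tie_resolves_to_lower_arc_length(self):
        wp = [(0, 0), (10, 0), (10, 10)]
        # equidistant from both segments (diagonal of the corner)
        pos = project_to_path([(8, 2)], wp)
        assert pos[0] == pytest.approx(8.0)

    def test_degenerate_waypoints_raise(self):
        with pytest.raises(ValueError, match="degenerate"):
            project_to_path([(0, 0)], [(1, 1), (1, 1)])

    def test_legacy_site_coincident_snail(self):
        snails = np.array([[0, 0, 0], [5, 5, 0], [9, 1, 1]], float)
        pos = np.array([2.0, 7.0, 11.0])
        out = map_legacy_sites([[5, 5, 0]], snails, pos)
        assert out[0] == 7.0

    def test_legacy_tie_takes_smaller_position(self):
        snails = np.array([[0, 0], [2, 0]], float)
        out = map_legacy_sites([[1, 0]], snails, [4.0, 9.0])
        assert out[0] == 4.0

    def test_legacy_brute_force_oracle(self):
        rng = np.random.default_rng(8)
        snails = rng.normal(size=(20, 3))
        pos = rng.uniform(0, 175, 20)
        sites = rng.normal(size=(7, 3))
        out = map_legacy_sites(sites, snails, pos)
        for i, s in enumerate(sites):
            d = np.linalg.norm(snails - s, axis=1)
            assert out[i] == pos[np.argmin(d)]

    def test_empty_snail_set_raises(self):
        with pytest.raises(ValueError, match="empty"):
            map_legacy_sites([[0, 0]], np.empty((0, 2)), [])


class TestSelectionFromWidth:
    def test_unit_case(self):
        assert selection_from_width(1.732 * 10, 10).s_star == pytest.approx(1.0)

    def test_direct_arithmetic(self):
        assert selection_from_width(100, 10).s_star == pytest.approx(0.03,
                                                                     abs=1e-4)

    def test_scale_invariance(self):
        a = selection_from_width(65, 10).s_star
        b = selection_from_width(130, 20).s_star
        assert a == pytest.approx(b)

    def test_nonpositive_inputs_raise(self):
        with pytest.raises(ValueError):
            selection_from_width(-1, 10)
        with pytest.raises(ValueError):
            selection_from_width(65, 0)


class TestScan:
    def test_weak_end_difference_skipped(self, small_bundle):
        """A SNP whose terminal-window frequency difference is below 10% is
        absent from the scan table."""
        scan = scan_snp_clines(small_bundle.genotypes, small_bundle.samples,
                               n_restarts=2)
        assert (scan["end_diff"] >= 0.10).all()
        # outside-inversion SNPs mostly lack clines, so some must be skipped
        assert scan["site"].nunique() < small_bundle.genotypes.n_sites
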