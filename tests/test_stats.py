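"""FDR, pairwise contrasts, variance tests and the variance attribution."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from pftc.stats import (
    bh_fdr,
    class_average_profile,
    pairwise_timepoint_tests,
    pairwise_variance_tests,
    profile,
    response_table,
    signal_vs_control_variance,
    variance_f_test,
    welch_t_test,
)


def brute_force_bh(p):
    """Step-up definition applied literally."""
    n = len(p)
    order = sorted(range(n), key=lambda i: p[i])
    adj = [None] * n
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * n / rank)
        adj[i] = running
    return adj


class TestBhFdr:
    def test_hand_example(self):
        assert bh_fdr([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_single_and_tied_inputs(self):
        assert bh_fdr([0.2]) == pytest.approx([0.2])
        assert bh_fdr([0.1, 0.1, 0.1]) == pytest.approx([0.1, 0.1, 0.1])

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.1, np.nan])

    @settings(derandomize=True, max_examples=60)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    def test_matches_brute_force_definition(self, p):
        got = bh_fdr(p)
        assert got == pytest.approx(brute_force_bh(p))
        # adjusted never below raw, never above 1, order-preserving in rank
        assert np.all(got >= np.asarray(p) - 1e-15) and np.all(got <= 1)
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(got[order]) >= -1e-15)

    def test_agrees_with_statsmodels(self):
        sm = pytest.importorskip("statsmodels.stats.multitest")
        rng = np.random.default_rng(0)
        p = rng.uniform(size=200)
        assert bh_fdr(p) == pytest.approx(
            sm.multipletests(p, method="fdr_bh")[1]
        )


class TestWelch:
    def test_identical_groups(self):
        t, p = welch_t_test([3, 3, 4, 4], [4, 3, 4, 3])
        assert p == pytest.approx(1.0) and t == pytest.approx(0.0)

    def test_degenerate_zero_variance(self):
        assert welch_t_test([2, 2, 2], [2, 2, 2]) == (0.0, 1.0)
        t, p = welch_t_test([2, 2, 2], [3, 3, 3])
        assert p == 0.0 and np.isinf(t)

    def test_strong_separation_matches_closed_form(self):
        """Zeros vs ~40: the Welch statistic computed by hand."""
        a = np.zeros(6)
        b = np.array([39.0, 41.0, 40.5, 39.5, 40.2, 39.8])
        t, p = welch_t_test(b, a)
        se = np.sqrt(b.var(ddof=1) / 6 + a.var(ddof=1) / 6)
        t_hand = (b.mean() - a.mean()) / se
        df_hand = 5.0  # a has zero variance: Welch df collapses to n_b - 1
        assert t == pytest.approx(t_hand)
        assert p == pytest.approx(2 * sps.t.sf(t_hand, df_hand), rel=1e-6)
        assert p < 1e-6


class TestVarianceFTest:
    def test_equal_variances(self):
        f, p, dfa, dfb = variance_f_test([1, 2, 3, 4], [5, 6, 7, 8])
        assert f == pytest.approx(1.0) and p == pytest.approx(1.0)
        assert (dfa, dfb) == (3, 3)

    def test_nine_to_one_matches_null_monte_carlo(self):
        """Two-sided analytic p vs a 100k-draw null simulation oracle."""
        a = np.array([0, 3, 6, 9, 12, 15.0])  # sample variance 31.5
        b = a / 3.0  # variance ratio exactly 9
        f, p, *_ = variance_f_test(a, b)
        assert f == pytest.approx(9.0)
        p_analytic = 2 * min(sps.f.cdf(9, 5, 5), sps.f.sf(9, 5, 5))
        assert p == pytest.approx(p_analytic)
        rng = np.random.default_rng(1)
        n = 100_000
        x = rng.standard_normal((n, 6)).var(axis=1, ddof=1)
        y = rng.standard_normal((n, 6)).var(axis=1, ddof=1)
        r = x / y
        p_mc = np.mean((r >= 9.0) | (r <= 1 / 9.0))
        mc_se = np.sqrt(p_mc * (1 - p_mc) / n)
        assert abs(p - p_mc) < 3 * mc_se

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            variance_f_test([1, 1, 1], [1, 2, 3])


class TestPairwiseContrasts:
    def test_zero_min_contrasts_dominate_class_a(self, binding_seed1):
        """Across class-A sites: 0-min contrasts respond, others rarely.

        Aggregated over 100 sites because single-site FDR families admit
        occasional false discoveries by design (~5% of the discoveries)."""
        sites = [
            s for s in binding_seed1.values.index if s.startswith("ER_A_")
        ][:100]
        zero_sig, other_sig = [], []
        for s in sites:
            tt = pairwise_timepoint_tests(binding_seed1, s)
            zero = tt["time_a"] == 0
            zero_sig.append(tt.loc[zero, "significant"].mean())
            other_sig.append(tt.loc[~zero, "significant"].sum())
        assert np.mean(zero_sig) > 0.85
        assert np.mean(other_sig) < 1.5  # of 36 null pairs per site

    def test_identical_replicate_values_give_p_one(self):
        from tests.conftest import make_binding

        same = make_binding(np.tile([4.0, 6.0, 5.0], 2).reshape(1, 6), [0, 10], 3)
        tt = pairwise_timepoint_tests(same, "site_0")
        assert tt["p_value"].iloc[0] == pytest.approx(1.0)
        assert tt["statistic"].iloc[0] == pytest.approx(0.0)

    def test_post_activation_variances_homogeneous(self, binding_seed1):
        """Post-stimulation variance is flat for class-A sites; the 0-min
        point has genuinely lower variance under multiplicative noise."""
        sites = [
            s for s in binding_seed1.values.index if s.startswith("ER_A_")
        ][:100]
        post_frac = []
        zero_var_lower = 0
        for s in sites:
            vt = pairwise_variance_tests(binding_seed1, s)
            post = vt["time_a"] >= 10
            post_frac.append(vt.loc[post, "significant"].mean())
            by_time = binding_seed1.site_values_by_time(s)
            v0 = by_time[0.0].var(ddof=1)
            vpost = np.mean([by_time[t].var(ddof=1) for t in by_time if t >= 10])
            zero_var_lower += v0 < vpost
        assert np.mean(post_frac) < 0.05
        assert zero_var_lower / len(sites) > 0.95

    def test_variance_zero_replicates_rejected(self):
        from tests.conftest import make_binding

        b = make_binding(np.tile([3.0], (1, 12)).reshape(1, 12), [0, 10], 6)
        with pytest.raises(ValueError, match="zero replicate variance"):
            pairwise_variance_tests(b, "site_0")


class TestVarianceAttribution:
    def test_identical_sites_give_f_one(self, binding):
        sid = binding.values.index[0]
        vc = signal_vs_control_variance(binding, sid, sid)
        assert vc.F == pytest.approx(1.0) and vc.p_value == pytest.approx(1.0)

    def test_df_bookkeeping(self, binding):
        """9 post-stimulation time points x 6 replicates -> df 54 - 9 = 45."""
        a = next(s for s in binding.values.index if s.startswith("ER_A_"))
        c = next(s for s in binding.values.index if s.startswith("CTCF_"))
        vc = signal_vs_control_variance(binding, a, c, min_time=10)
        assert vc.df_signal == vc.df_control == 45

    def test_signal_variance_exceeds_control(self, response, binding):
        """Biological noise on the responder inflates replicate scatter far
        beyond the technical scatter of a mean-matched control site."""
        top = response["amplitude"].idxmax()
        prof = binding.replicate_mean_profiles()
        post = [c for c in prof.columns if c >= 10]
        target = prof.loc[top, post].mean()
        ctl = binding.sites.index[binding.sites["role"] == "control"]
        matched = (prof.loc[ctl, post].mean(axis=1) - target).abs().idxmin()
        vc = signal_vs_control_variance(binding, top, matched)
        assert vc.F > 2.5
        assert vc.p_value < 1e-4
        assert vc.cv_signal > vc.cv_control

    def test_zero_control_residual_rejected(self):
        from tests.conftest import make_binding

        vals = np.vstack([np.arange(12, dtype=float), np.repeat([3.0, 4.0], 6)])
        b = make_binding(vals, [10, 20], 6)
        with pytest.raises(ValueError, match="zero residual"):
            signal_vs_control_variance(b, "site_0", "site_1", min_time=10)


class TestProfiles:
    def test_constant_profile_tie_resolves_to_first_time(self):
        from tests.conftest import make_binding

        b = make_binding(np.full((1, 20), 7.0), list(range(0, 100, 10)), 2)
        p = profile(b, "site_0")
        assert p.time_of_max == 0.0
        assert (p.table["sd"] == 0).all()

    def test_monotone_site_peaks_last(self, binding):
        a = next(s for s in binding.values.index if s.startswith("ER_A_"))
        assert profile(binding, a).time_of_max >= 10.0

    def test_class_average_is_linear(self, binding):
        ids = list(binding.values.index[:2])
        pa = profile(binding, ids[0]).mean
        pb = profile(binding, ids[1]).mean
        avg = class_average_profile(binding, ids).mean
        assert np.allclose(avg, (pa + pb) / 2)

    def test_unknown_site_rejected(self, binding):
        with pytest.raises(KeyError):
            profile(binding, "no_such_site")
        with pytest.raises(KeyError):
            class_average_profile(binding, ["no_such_site"])
        with pytest.raises(ValueError):
            class_average_profile(binding, [])


class TestTypeIError:
    def test_null_sites_hold_nominal_level(self, null_site_pvalues):
        """0-vs-10 Welch rejections on null sites within binomial 99% bounds
        of the nominal 0.05."""
        p = null_site_pvalues
        n = p.size
        assert n >= 2000
        rate = (p < 0.05).mean()
        half_width = 2.576 * np.sqrt(0.05 * 0.95 / n)
        assert abs(rate - 0.05) < half_width


class TestResponseTable:
    def test_power_on_class_a_sites(self, response, truth_labels):
        """>= 99% of class-A sites respond at genome-wide FDR < 0.05."""
        a_sites = truth_labels.index[truth_labels == "A"]
        assert response.loc[a_sites, "significant"].mean() >= 0.99

    def test_amplitude_sign_matches_truth(self, response, truth_labels):
        resp_sites = truth_labels.index[truth_labels.isin(["A", "C"])]
        flat_sites = truth_labels.index[truth_labels == "B"]
        assert (response.loc[resp_sites, "amplitude"] > 0).mean() > 0.99
        assert abs(response.loc[flat_sites, "amplitude"].mean()) < 2.0
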