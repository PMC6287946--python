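"""Consensus peaks, control-derived factors, and max-normalizations."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize_scalar

from pftc.containers import CountMatrix
from pftc.normalize import (
    apply_factors,
    consensus_sites,
    derive_factors,
    normalize_rows_to_max,
    normalize_series_to_max,
)
from pftc.simulate import expected_count_matrix


def _interval_df(intervals):
    return pd.DataFrame(intervals, columns=["chrom", "start", "end"])


def brute_force_consensus(per_sample, min_fraction):
    """Connected-component reference implementation of merge + support.

    Two half-open intervals are connected iff they share at least one base;
    a merged interval is the hull of a connected component and its support
    is the number of distinct samples contributing to the component.
    """
    n = len(per_sample)
    items = [
        (r["chrom"], int(r["start"]), int(r["end"]), k)
        for k, df in enumerate(per_sample)
        for _, r in df.iterrows()
    ]
    parent = list(range(len(items)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(items)):
        for j in range(i + 1, len(items)):
            ci, si, ei, _ = items[i]
            cj, sj, ej, _ = items[j]
            if ci == cj and si < ej and sj < ei:
                parent[find(i)] = find(j)
    comps = {}
    for i, (c, s, e, k) in enumerate(items):
        comps.setdefault(find(i), []).append((c, s, e, k))
    out = []
    for members in comps.values():
        chrom = members[0][0]
        start = min(m[1] for m in members)
        end = max(m[2] for m in members)
        support = {m[3] for m in members}
        if len(support) > min_fraction * n:
            out.append((chrom, start, end))
    return sorted(out)


class TestConsensusSites:
    def test_unanimous_interval_kept(self):
        sets = [_interval_df([("chr1", 100, 200)])] * 6
        out = consensus_sites(sets, 0.5)
        assert out[["chrom", "start", "end"]].values.tolist() == [
            ["chr1", 100, 200]
        ]

    def test_exactly_half_is_excluded(self):
        """'over 50%' is strict: 3 of 6 samples is not enough."""
        present = _interval_df([("chr1", 100, 200)])
        absent = _interval_df([])
        out = consensus_sites([present] * 3 + [absent] * 3, 0.5)
        assert len(out) == 0
        out4 = consensus_sites([present] * 4 + [absent] * 2, 0.5)
        assert len(out4) == 1

    def test_single_bp_overlap_merges(self):
        left = _interval_df([("chr1", 100, 201)])
        right = _interval_df([("chr1", 200, 300)])
        out = consensus_sites([left, right, left, right], 0.5)
        assert out[["start", "end"]].values.tolist() == [[100, 300]]
        # abutting half-open intervals (no shared bp) stay separate
        out2 = consensus_sites(
            [_interval_df([("chr1", 100, 200), ("chr1", 200, 300)])] * 2, 0.5
        )
        assert len(out2) == 2

    def test_empty_input_warns_not_raises(self):
        with pytest.warns(UserWarning):
            out = consensus_sites([_interval_df([])] * 3, 0.5)
        assert out.empty

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(
        data=st.lists(
            st.lists(
                st.tuples(st.integers(0, 60), st.integers(1, 15)),
                min_size=0, max_size=4,
            ),
            min_size=1, max_size=5,
        ),
        min_fraction=st.sampled_from([0.3, 0.5, 0.8]),
    )
    def test_matches_per_bp_oracle(self, data, min_fraction):
        sets = [
            _interval_df([("chr1", s, s + w) for s, w in sample])
            for sample in data
        ]
        got = consensus_sites(sets, min_fraction)
        expected = brute_force_consensus(sets, min_fraction)
        assert (
            [tuple(r) for r in got[["chrom", "start", "end"]].values.tolist()]
            == expected
        )


def _count_matrix(arr, sample_ids=None, role="control"):
    arr = np.asarray(arr)
    n_sites, n_samples = arr.shape
    sample_ids = sample_ids or [f"s{i}" for i in range(n_samples)]
    manifest = pd.DataFrame(
        {
            "time_min": [float(10 * i) for i in range(n_samples)],
            "replicate": 1,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    sites = pd.DataFrame(
        {
            "chrom": "chr1",
            "start": np.arange(n_sites) * 500,
            "end": np.arange(n_sites) * 500 + 100,
            "role": role,
        },
        index=pd.Index([f"c{j}" for j in range(n_sites)], name="site_id"),
    )
    counts = pd.DataFrame(arr, index=sites.index, columns=manifest.index)
    return CountMatrix(counts=counts, sites=sites, manifest=manifest)


class TestDeriveFactors:
    def test_identical_samples_give_unit_factors(self):
        cm = _count_matrix(np.tile([[10], [50], [200]], (1, 4)))
        f = derive_factors(cm, min_control_sites=3)
        assert np.allclose(f.factors, 1.0)

    def test_doubled_sample_gets_half_factor(self):
        base = np.array([[10], [50], [200]])
        cm = _count_matrix(np.hstack([base, 2 * base]))
        f = derive_factors(cm, min_control_sites=3)
        assert f.factors.iloc[1] / f.factors.iloc[0] == pytest.approx(0.5)
        norm = apply_factors(cm, f).values
        assert np.allclose(norm.iloc[:, 0], norm.iloc[:, 1])

    def test_noiseless_fixture_recovers_confounders_exactly(self, default_dataset):
        exact = expected_count_matrix(default_dataset)
        f = derive_factors(exact)
        target = 1.0 / default_dataset.truth.confounder()
        target /= np.exp(np.mean(np.log(target)))
        assert np.abs(f.factors - target).max() < 1e-9

    def test_matches_grid_minimization_oracle(self):
        """Each factor minimizes sum_j (mean_j - f * x_ij)^2 (checked
        independently by 1-D numeric minimization on a 5x5 matrix)."""
        rng = np.random.default_rng(2)
        arr = rng.integers(5, 500, size=(5, 5))
        cm = _count_matrix(arr)
        f = derive_factors(cm, min_control_sites=5)
        mean_profile = arr.mean(axis=1)
        raw = []
        for i in range(5):
            obj = lambda g: float(((mean_profile - g * arr[:, i]) ** 2).sum())
            grid = np.linspace(1e-3, 10, 20001)
            g0 = grid[np.argmin([obj(g) for g in grid])]
            res = minimize_scalar(obj, bounds=(g0 - 1e-3, g0 + 1e-3),
                                  method="bounded",
                                  options={"xatol": 1e-12})
            raw.append(res.x)
        raw = np.array(raw)
        raw /= np.exp(np.mean(np.log(raw)))
        assert np.allclose(f.factors, raw, atol=1e-6)

    def test_scale_equivariance_up_to_global_rescale(self, default_dataset):
        """Rescaling one sample's raw counts by c rescales its factor by ~1/c.

        Exact only in the large-n limit (the rescaled column also moves the
        arithmetic-mean reference profile by (c-1)/n), hence the 2% band and
        the comparison up to one global scalar."""
        cm = default_dataset.counts
        f0 = derive_factors(cm)
        scaled = cm.counts.copy()
        k = scaled.columns[3]
        scaled[k] = scaled[k] * 2
        cm2 = CountMatrix(counts=scaled, sites=cm.sites, manifest=cm.manifest)
        f1 = derive_factors(cm2)
        drift = np.exp(
            np.mean(np.log(f1.factors.drop(k) / f0.factors.drop(k)))
        )
        assert f1.factors[k] / f0.factors[k] == pytest.approx(
            0.5 * drift, rel=0.02
        )
        b0 = apply_factors(cm, f0).values
        b1 = apply_factors(cm2, f1).values
        ratio = (b1.to_numpy() + 1) / (b0.to_numpy() * drift + 1)
        assert np.quantile(np.abs(ratio - 1), 0.99) < 0.02

    def test_median_ratio_agrees_within_5_percent(self, default_dataset):
        f_reg = derive_factors(default_dataset.counts)
        f_med = derive_factors(default_dataset.counts, method="median-ratio")
        assert np.abs(f_med.factors / f_reg.factors - 1).max() < 0.05

    def test_all_zero_sample_is_named_in_error(self):
        arr = np.tile([[10], [50], [200]], (1, 3))
        arr[:, 1] = 0
        cm = _count_matrix(arr, sample_ids=["ok1", "dead", "ok2"])
        with pytest.raises(ValueError, match="dead"):
            derive_factors(cm, min_control_sites=3)

    def test_too_few_control_sites_rejected(self):
        cm = _count_matrix(np.tile([[10], [50]], (1, 3)))
        with pytest.raises(ValueError, match="control sites"):
            derive_factors(cm, min_control_sites=10)


class TestApplyFactors:
    def test_unit_factors_are_identity(self, default_dataset):
        cm = default_dataset.counts
        f = derive_factors(cm)
        f.factors[:] = 1.0
        out = apply_factors(cm, f)
        assert np.array_equal(out.values.to_numpy(), cm.counts.to_numpy())

    def test_factor_scaling_is_columnwise(self, default_dataset):
        cm = default_dataset.counts
        f = derive_factors(cm)
        b0 = apply_factors(cm, f).values
        f.factors.iloc[0] *= 2
        b1 = apply_factors(cm, f).values
        assert np.allclose(b1.iloc[:, 0], 2 * b0.iloc[:, 0])
        assert np.array_equal(b1.iloc[:, 1:].to_numpy(), b0.iloc[:, 1:].to_numpy())

    def test_normalization_flattens_control_column_means(
        self, default_dataset, binding
    ):
        raw = default_dataset.counts.restrict("control").counts.mean(axis=0)
        norm = binding.restrict("control").values.mean(axis=0)
        cv = lambda s: s.std(ddof=1) / s.mean()
        assert cv(norm) < 0.05
        assert cv(norm) < cv(raw)

    def test_sample_mismatch_is_reported(self, default_dataset):
        cm = default_dataset.counts
        f = derive_factors(cm)
        f.factors = f.factors.iloc[:-1]
        with pytest.raises(ValueError, match=cm.manifest.index[-1]):
            apply_factors(cm, f)


class TestRowMaxNormalization:
    def test_hand_example(self):
        from tests.conftest import make_binding

        b = make_binding(np.array([[2.0, 4.0, 8.0]]), [0, 10, 20], 1)
        out = normalize_rows_to_max(b).matrix
        assert out.iloc[0].tolist() == [0.25, 0.5, 1.0]

    def test_constant_and_monotone_rows(self):
        from tests.conftest import make_binding

        b = make_binding(
            np.array([[5.0] * 10, np.linspace(1, 30, 10)]),
            list(range(0, 100, 10)), 1,
        )
        out = normalize_rows_to_max(b).matrix
        assert (out.iloc[0] == 1.0).all()
        assert out.iloc[1, -1] == 1.0
        assert out.to_numpy().max() == 1.0 and out.to_numpy().min() >= 0.0

    def test_idempotent_and_maxima_exactly_one(self, binding):
        first = normalize_rows_to_max(binding)
        assert (first.matrix.max(axis=1) == 1.0).all()
        # re-normalizing the already row-relative matrix changes nothing
        again = first.matrix.div(first.matrix.max(axis=1), axis=0)
        pd.testing.assert_frame_equal(again, first.matrix)

    def test_all_zero_row_excluded_with_report(self):
        from tests.conftest import make_binding

        vals = np.vstack([[0.0] * 6, [1, 2, 3, 4, 5, 6.0]])
        b = make_binding(vals, [0, 10, 20, 30, 40, 50], 1)
        with pytest.warns(UserWarning, match="excluded 1"):
            out = normalize_rows_to_max(b)
        assert out.excluded == ["site_0"]
        assert list(out.matrix.index) == ["site_1"]


class TestSeriesToMax:
    def test_hand_examples(self):
        assert normalize_series_to_max([1, 3, 2]).tolist() == [
            pytest.approx(1 / 3), 1.0, pytest.approx(2 / 3)
        ]
        assert normalize_series_to_max([5]).tolist() == [1.0]

    def test_idempotent(self):
        once = normalize_series_to_max([0.2, 1.0, 0.7])
        assert np.array_equal(normalize_series_to_max(once), once)

    def test_non_positive_max_rejected(self):
        with pytest.raises(ValueError):
            normalize_series_to_max([-1.0, 0.0])
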