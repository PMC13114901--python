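"""Rank correlation, tertiles, the DMP scan and BH-FDR vs independent oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from epiperform.association import (
    bh_fdr,
    chronological_tertiles,
    dmp_scan,
    spearman,
    stratified_correlation,
    tertile_split,
)
from epiperform.datasets import example_clock_ages


# ---------------------------------------------------------------- oracles
def rho_oracle(x, y):
    """Brute-force rank-Pearson: explicit mid-ranks, explicit Pearson."""
    def midrank(v):
        v = list(v)
        out = []
        for vi in v:
            less = sum(1 for vj in v if vj < vi)
            equal = sum(1 for vj in v if vj == vi)
            out.append(less + (equal + 1) / 2.0)
        return out

    rx, ry = midrank(x), midrank(y)
    n = len(rx)
    mx, my = sum(rx) / n, sum(ry) / n
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = (sum((a - mx) ** 2 for a in rx)
           * sum((b - my) ** 2 for b in ry)) ** 0.5
    return num / den


def bh_oracle(p):
    """Classic step-up: walk ranks from the largest p downward."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [None] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        q[i] = running
    return q


# --------------------------------------------------------------- spearman
class TestSpearman:
    def test_perfect_monotone(self):
        res = spearman([1, 2, 3, 4], [10, 20, 30, 40])
        assert res.rho == pytest.approx(1.0)
        assert res.method == "permutation"  # degenerate |rho| = 1

    def test_perfect_reversal(self):
        res = spearman([1, 2, 3, 4], [40, 30, 20, 10])
        assert res.rho == pytest.approx(-1.0)

    def test_matches_bruteforce_oracle_with_ties(self, rng):
        for _ in range(200):
            n = int(rng.integers(4, 31))
            x = rng.integers(0, 8, n).astype(float)  # heavy ties
            y = rng.integers(0, 8, n).astype(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            res = spearman(x, y)
            assert res.rho == pytest.approx(rho_oracle(x, y), abs=1e-12)

    def test_t_approx_p_matches_scipy(self, rng):
        x = rng.normal(size=40)
        y = x + rng.normal(size=40)
        res = spearman(x, y)
        ref_rho, ref_p = stats.spearmanr(x, y)
        assert res.method == "t_approx"
        assert res.rho == pytest.approx(ref_rho, abs=1e-12)
        assert res.p_value == pytest.approx(ref_p, rel=1e-6)

    def test_exact_permutation_p_small_n(self):
        # n = 4, rho = 1: 1 of 24 orderings ties the observed statistic in
        # each direction -> two-sided exact p = 2/24
        res = spearman([1, 2, 3, 4], [10, 20, 30, 40])
        assert res.p_value == pytest.approx(2 / 24)

    def test_constant_vector_is_an_error(self):
        with pytest.raises(ValueError, match="constant"):
            spearman([1.0, 1.0, 1.0, 1.0], [1, 2, 3, 4])

    @settings(derandomize=True, max_examples=30)
    @given(st.lists(st.integers(0, 100), min_size=10, max_size=25,
                    unique=True))
    def test_invariant_to_monotone_transforms(self, xs):
        rng = np.random.default_rng(hash(tuple(xs)) % 2**31)
        y = rng.normal(size=len(xs))
        if np.ptp(y) == 0:
            return
        x = np.array(xs, dtype=float)
        base = spearman(x, y).rho
        assert spearman(np.exp(x / 50.0), y).rho == pytest.approx(base)
        assert spearman(3.0 * x - 7.0, y).rho == pytest.approx(base)
        assert spearman(x, np.exp(y)).rho == pytest.approx(base)


# --------------------------------------------------------------- tertiles
class TestTertiles:
    def test_no_ties_gives_balanced_groups(self):
        split = tertile_split(np.arange(1, 10))
        assert split.sizes == (3, 3, 3)

    def test_example_cohort_ranked_split(self):
        """Ranked tertiles of the bundled Hannum ages give sizes (6, 8, 7)."""
        table = example_clock_ages()
        split = tertile_split(table["DNAmAgeHannum"], ids=table.index,
                              basis="DNAmAgeHannum")
        assert split.sizes == (6, 8, 7)
        # a tie never straddles a boundary
        vals = table["DNAmAgeHannum"]
        for g in (1, 2):
            upper = vals[split.labels[split.labels == g].index].max()
            lower = vals[split.labels[split.labels == g + 1].index].min()
            assert upper < lower

    def test_all_tied_values_collapse_to_group_three(self):
        with pytest.warns(UserWarning, match="tied"):
            split = tertile_split([5.0] * 7)
        assert split.sizes == (0, 0, 7)

    def test_sizes_differ_by_at_most_one_without_ties(self, rng):
        for n in range(3, 30):
            values = rng.permutation(n) + rng.uniform(0, 0.1, n)
            sizes = tertile_split(values).sizes
            assert max(sizes) - min(sizes) <= 1
            assert sum(sizes) == n

    def test_groups_ordered_by_value(self, rng):
        values = rng.normal(size=30)
        split = tertile_split(values)
        ranges = split.value_ranges(pd.Series(values))
        assert ranges[1][1] <= ranges[2][0] and ranges[2][1] <= ranges[3][0]

    def test_chronological_fixed_boundaries(self):
        """Ages 55 and 56 land either side of the first boundary; 64/65 of
        the second; the bundled cohort splits (10, 6, 5)."""
        split = chronological_tertiles([55.0, 56.0, 64.0, 65.0])
        assert list(split.labels) == [1, 2, 2, 3]
        table = example_clock_ages()
        cohort_split = chronological_tertiles(table["chronological_age"],
                                              ids=table.index)
        assert cohort_split.sizes == (10, 6, 5)

    def test_chronological_allows_empty_groups(self):
        split = chronological_tertiles([40.0, 45.0, 50.0])
        assert split.sizes == (3, 0, 0)


class TestStratifiedCorrelation:
    def test_global_reversal_in_every_group(self, rng):
        x = rng.normal(size=30)
        split = tertile_split(x)
        out = stratified_correlation(x, -x, split)
        for g in (1, 2, 3):
            assert out[g].rho == pytest.approx(-1.0)

    def test_tiny_group_reported_undefined(self):
        labels = pd.Series([1, 1, 1, 2, 2, 3, 3, 3],
                           index=range(8))
        from epiperform.association import TertileSplit
        split = TertileSplit(labels=labels, basis="x")
        out = stratified_correlation(np.arange(8.0),
                                     np.arange(8.0)[::-1] + 0.0, split)
        assert out[2] is None
        assert out[1] is not None

    def test_signal_confined_to_middle_tertile(self):
        """Slope present only in the middle third shows up only there."""
        rng = np.random.default_rng(42)
        n = 300
        x = np.sort(rng.uniform(0, 30, n))
        y = rng.normal(0, 1.0, n)
        mid = (x > 10) & (x < 20)
        y[mid] += -0.8 * x[mid]
        split = tertile_split(x)
        out = stratified_correlation(x, y, split)
        assert abs(out[2].rho) > abs(out[1].rho)
        assert abs(out[2].rho) > abs(out[3].rho)


# ------------------------------------------------------------------ FDR
class TestBhFdr:
    def test_single_p_is_unchanged(self):
        assert bh_fdr([0.037])[0] == pytest.approx(0.037)

    def test_stepup_arithmetic(self):
        q = bh_fdr([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_all_ones(self):
        np.testing.assert_allclose(bh_fdr([1.0, 1.0, 1.0]), 1.0)

    def test_matches_stepup_oracle_on_random_inputs(self, rng):
        for _ in range(50):
            m = int(rng.integers(1, 40))
            p = np.round(rng.uniform(0, 1, m), 3)
            np.testing.assert_allclose(bh_fdr(p), bh_oracle(list(p)),
                                       atol=1e-12)

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests
        p = rng.uniform(0, 1, 200)
        _, q_ref, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(bh_fdr(p), q_ref, atol=1e-12)

    def test_rejection_set_equals_classic_stepup(self, rng):
        alpha = 0.05
        p = rng.uniform(0, 0.2, 30)
        rejected_q = set(np.flatnonzero(bh_fdr(p) <= alpha))
        # classic: largest k with p_(k) <= k*alpha/m
        order = np.argsort(p)
        m = len(p)
        k = 0
        for i, idx in enumerate(order, start=1):
            if p[idx] <= i * alpha / m:
                k = i
        rejected_classic = set(order[:k])
        assert rejected_q == rejected_classic

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])


# ------------------------------------------------------------------ DMP
class TestDmpScan:
    def _frame(self, values, samples=None):
        values = np.atleast_2d(np.asarray(values, dtype=float))
        samples = samples or [f"S{j}" for j in range(values.shape[1])]
        return pd.DataFrame(values, columns=samples,
                            index=[f"cg{i}" for i in range(values.shape[0])])

    def test_noiseless_linear_cpg_recovered(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        m = self._frame(2.5 * x - 1.0)
        out = dmp_scan(m, x)
        assert out["slope"].iloc[0] == pytest.approx(2.5, abs=1e-9)
        assert out["p_value"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_t_stats_match_scipy_linregress(self, rng):
        """Three-CpG example cross-checked against an independent OLS."""
        x = np.array([20.0, 35.0, 50.0, 65.0, 80.0, 95.0])
        m = self._frame(rng.normal(0, 1, (3, 6)))
        out = dmp_scan(m, x)
        for i in range(3):
            ref = stats.linregress(x, m.iloc[i].to_numpy())
            assert out["slope"].iloc[i] == pytest.approx(ref.slope, abs=1e-9)
            t_ref = ref.slope / ref.stderr
            assert out["t_stat"].iloc[i] == pytest.approx(t_ref, abs=1e-9)
            assert out["p_value"].iloc[i] == pytest.approx(ref.pvalue,
                                                           rel=1e-9)

    def test_q_values_are_bh_of_p(self, rng):
        m = self._frame(rng.normal(0, 1, (50, 10)))
        x = rng.normal(size=10)
        out = dmp_scan(m, x)
        np.testing.assert_allclose(out["q_value"],
                                   bh_fdr(out["p_value"].to_numpy()))
        assert (out["significant"] == (out["q_value"] < 0.01)).all()

    def test_null_scan_rarely_discovers(self, rng):
        """FDR control: independent CpGs yield (almost) no q < 0.01 calls."""
        discoveries = []
        for _ in range(20):
            m = self._frame(rng.normal(0, 1, (500, 24)))
            x = rng.normal(size=24)
            discoveries.append(int(dmp_scan(m, x)["significant"].sum()))
        assert np.mean(discoveries) < 1

    def test_zero_variance_phenotype_rejected(self):
        m = self._frame(np.random.default_rng(0).normal(0, 1, (3, 6)))
        with pytest.raises(ValueError, match="variance"):
            dmp_scan(m, np.ones(6))
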