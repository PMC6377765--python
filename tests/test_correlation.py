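import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from plaidoh import correlation
from plaidoh.types import LCP, Transcript


def _lcp(lnc_name, gene_name, x, y, chrom="chr1"):
    lnc = Transcript(chrom, 0, 1000, lnc_name, "lncRNA", x)
    gene = Transcript(chrom, 5000, 6000, gene_name, "protein_coding", y)
    return LCP(lnc=lnc, gene=gene, distance=4000)


class TestSpearman:
    def test_identity_and_antitone(self):
        x = [3.0, 1.0, 4.0, 1.5, 5.0]
        assert correlation.spearman_lcp(x, x)[0] == pytest.approx(1.0)
        assert correlation.spearman_lcp(x, [-v for v in x])[0] == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        # d^2 = 1+1+1+1+0 = 4 -> rho = 1 - 6*4/(5*24) = 0.8
        rho, p = correlation.spearman_lcp([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
        assert rho == pytest.approx(0.8)
        assert 0 < p < 1

    def test_degenerate_inputs_flagged_missing(self):
        assert np.isnan(correlation.spearman_lcp([1, 2], [2, 1])[0])
        assert np.isnan(correlation.spearman_lcp([1.0] * 5, [1, 2, 3, 4, 5])[0])

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_equals_pearson_on_midranks(self, seed):
        """Spearman with ties is Pearson on midranks: independent oracle."""
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 5, 20).astype(float)  # heavy ties
        y = rng.integers(0, 5, 20).astype(float)
        if np.all(x == x[0]) or np.all(y == y[0]):
            return
        rho, _ = correlation.spearman_lcp(x, y)
        oracle = stats.pearsonr(stats.rankdata(x), stats.rankdata(y))[0]
        assert rho == pytest.approx(oracle, abs=1e-12)


def bh_bruteforce(p):
    """Step-up oracle: adj_i = min over j>=i of p_(j)*m/j, capped at 1."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = np.inf
    for pos in range(m - 1, -1, -1):
        i = order[pos]
        running = min(running, p[i] * m / (pos + 1))
        adj[i] = min(running, 1.0)
    return adj


class TestBH:
    def test_single_p_unchanged(self):
        assert correlation.adjust_bh([0.04])[0] == pytest.approx(0.04)

    def test_stepup_hand_example(self):
        assert correlation.adjust_bh([0.01, 0.02, 0.03, 0.04]) == pytest.approx(
            [0.04, 0.04, 0.04, 0.04]
        )

    def test_all_equal_stay_equal(self):
        adj = correlation.adjust_bh([0.2] * 6)
        assert np.allclose(adj, adj[0])

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            correlation.adjust_bh([0.5, 1.5])

    def test_nan_excluded_then_restored(self):
        adj = correlation.adjust_bh([0.01, np.nan, 0.04])
        assert np.isnan(adj[1]) and np.isfinite(adj[0]) and np.isfinite(adj[2])

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2**31 - 1), st.integers(1, 1000))
    def test_matches_bruteforce_stepup(self, seed, n):
        p = np.random.default_rng(seed).random(n)
        assert correlation.adjust_bh(p) == pytest.approx(bh_bruteforce(p))

    def test_adjusted_at_least_raw_and_monotone(self):
        p = np.random.default_rng(0).random(200)
        adj = correlation.adjust_bh(p)
        assert np.all(adj >= p - 1e-12)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)


class TestZscore:
    def test_hand_example_flags_outlier(self):
        # mean 0.4, sample sd sqrt(0.19): z(0.9) = 0.5/sqrt(0.19) ~ 1.147
        z, flags = correlation.zscore_per_lncrna([0.9, 0.1, 0.2])
        assert z[0] == pytest.approx(0.5 / np.sqrt(0.19))
        assert list(flags) == [True, False, False]

    def test_equal_rhos_no_flags(self):
        z, flags = correlation.zscore_per_lncrna([0.5, 0.5])
        assert np.all(np.isnan(z)) and not flags.any()

    def test_standardization_identity(self):
        rng = np.random.default_rng(1)
        r = rng.uniform(-1, 1, 15)
        z, _ = correlation.zscore_per_lncrna(r)
        assert np.mean(z) == pytest.approx(0, abs=1e-12)
        assert np.std(z, ddof=1) == pytest.approx(1)


class TestFrequencyMatrix:
    def _lcps(self, plan):
        """plan: lnc_name -> list of adj_p (one per paired gene)."""
        lcps = []
        for lnc, adjs in plan.items():
            for j, a in enumerate(adjs):
                lcp = _lcp(lnc, f"{lnc}_G{j}", [1, 2, 3], [1, 2, 3])
                lcp.adj_p = a
                lcps.append(lcp)
        return lcps

    def test_single_cell(self):
        plan = {f"L{i}": [0.5] * 5 for i in range(3)}
        fm = correlation.frequency_matrix(self._lcps(plan))
        assert fm.cells == {(5, 0): 3}

    def test_planted_poly_correlated_cell(self):
        plan = {"POLY": [0.001] * 8 + [0.9] * 2, "MONO": [0.001] + [0.9] * 9}
        fm = correlation.frequency_matrix(self._lcps(plan))
        assert fm.cells[(10, 8)] == 1 and fm.cells[(10, 1)] == 1

    def test_frequencies_sum_to_lncrna_count(self):
        rng = np.random.default_rng(5)
        plan = {f"L{i}": list(rng.random(rng.integers(1, 8))) for i in range(25)}
        fm = correlation.frequency_matrix(self._lcps(plan))
        assert sum(fm.cells.values()) == 25
        df = fm.to_dataframe()
        assert np.allclose(df["LOG10_FREQUENCY"], np.log10(df["FREQUENCY"]))


class TestCrossDataset:
    def _table(self, entries):
        return pd.DataFrame(
            entries, columns=["LNC_NAME", "GENE_NAME", "ADJUSTED_SPEARMAN", "SPEARMAN_RHO"]
        )

    def test_patterns_and_sign_split(self):
        ds = {
            "A": self._table([("L1", "G1", 0.001, 0.8), ("L2", "G2", 0.01, -0.5)]),
            "B": self._table([("L1", "G1", 0.002, 0.7), ("L2", "G2", 0.9, -0.1)]),
            "C": self._table([("L1", "G1", 0.01, 0.9), ("L3", "G3", 0.5, 0.2)]),
        }
        matrix, patterns, signs = correlation.cross_dataset_conservation(ds)
        assert matrix.loc[("L1", "G1")].tolist() == [1, 1, 1]
        assert matrix.loc[("L2", "G2")].tolist() == [1, 0, 0]
        assert ("L3", "G3") not in matrix.index  # significant nowhere
        assert patterns == {3: 1, 1: 1}
        assert signs["positive"] == {3: 1} and signs["negative"] == {1: 1}

    def test_requires_two_datasets(self):
        with pytest.raises(ValueError):
            correlation.cross_dataset_conservation({"A": self._table([])})


class TestAnnotateCorrelations:
    def test_fills_stats_and_outliers(self):
        rng = np.random.default_rng(11)
        x = rng.random(30)
        lcps = [
            _lcp("L1", "G1", x, x + rng.normal(0, 0.01, 30)),  # near-perfect
            _lcp("L1", "G2", x, rng.random(30)),
            _lcp("L1", "G3", x, rng.random(30)),
            _lcp("L2", "G4", np.ones(30), rng.random(30)),  # constant -> missing
        ]
        correlation.annotate_correlations(lcps)
        assert lcps[0].rho == pytest.approx(1.0, abs=0.05)
        assert lcps[0].adj_p is not None and lcps[0].adj_p < 0.05
        assert lcps[3].rho is None and lcps[3].adj_p is None
        assert lcps[0].zscore is not None  # three defined rhos for L1
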