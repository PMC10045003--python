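"""Prognostic index, risk groups, concordance, and Cox screening."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar

from cgsurv import (
    CensoredSample,
    GeneSignature,
    chen_signature,
    concordance_index,
    emura_chen_signature,
    median_cutoff,
    prognostic_index,
    split_groups,
    toy_sample,
    univariate_cox_screen,
)


class TestPrognosticIndex:
    def test_signature_fixtures(self):
        ec = emura_chen_signature()
        assert len(ec) == 16
        assert ec.genes[0] == "MMP16" and ec.weights[0] == 0.51
        ch = chen_signature()
        assert len(ch) == 16
        assert ch.genes[0] == "ANXA5" and ch.weights[0] == -1.09

    def test_all_ones_expression(self):
        sig = emura_chen_signature()
        expr = pd.DataFrame(np.ones((3, 16)), columns=list(sig.genes))
        np.testing.assert_allclose(prognostic_index(expr, sig), 5.06, atol=1e-12)

    def test_linearity_in_expression(self):
        sig = emura_chen_signature()
        expr = pd.DataFrame(np.full((2, 16), 4.0), columns=list(sig.genes))
        np.testing.assert_allclose(prognostic_index(expr, sig), 4 * 5.06, atol=1e-12)

    def test_zero_weights(self):
        sig = GeneSignature(genes=("a", "b"), weights=[0.0, 0.0])
        expr = pd.DataFrame({"a": [1.0, 2.0], "b": [3.0, 4.0]})
        np.testing.assert_array_equal(prognostic_index(expr, sig), [0.0, 0.0])

    def test_column_order_invariance_and_scaling(self, rng):
        sig = GeneSignature(genes=("a", "b", "c"), weights=[1.0, -2.0, 0.5])
        expr = pd.DataFrame(rng.normal(size=(5, 3)), columns=["c", "a", "b"])
        pi = prognostic_index(expr, sig)
        scaled = GeneSignature(genes=sig.genes, weights=3.0 * sig.weights)
        np.testing.assert_allclose(prognostic_index(expr, scaled), 3.0 * pi)

    def test_missing_gene_listed(self):
        sig = GeneSignature(genes=("a", "zz"), weights=[1.0, 1.0])
        expr = pd.DataFrame({"a": [1.0]})
        with pytest.raises(KeyError, match="zz"):
            prognostic_index(expr, sig)


class TestCutoffAndSplit:
    @pytest.mark.parametrize(
        "values,expected", [([1, 2, 3], 2.0), ([1, 2, 3, 4], 2.5), ([7, 7, 7], 7.0)]
    )
    def test_median(self, values, expected):
        assert median_cutoff(values) == expected

    def test_median_empty_rejected(self):
        with pytest.raises(ValueError):
            median_cutoff([])

    def test_quantile_cutoff(self):
        from cgsurv import quantile_cutoff

        assert quantile_cutoff([1, 2, 3, 4], 0.5) == median_cutoff([1, 2, 3, 4])
        assert quantile_cutoff([0, 1, 2, 3, 4], 0.25) == 1.0
        with pytest.raises(ValueError):
            quantile_cutoff([1.0], 1.5)

    def test_toy_split_is_half_and_half(self):
        s = toy_sample()
        split = split_groups(s, 4.5)
        assert split.n_good == 4 and split.n_poor == 4
        np.testing.assert_array_equal(np.sort(s.pi[split.good_idx]), [1, 2, 3, 4])

    def test_tie_at_cutoff_goes_good(self):
        s = CensoredSample(time=[1.0, 2.0], status=[1, 1], pi=[4.5, 5.0])
        split = split_groups(s, 4.5)
        assert split.good_idx.tolist() == [0]

    def test_empty_group_flagged(self):
        s = CensoredSample(time=[1.0, 2.0], status=[1, 1], pi=[1.0, 2.0])
        with pytest.warns(UserWarning, match="empty risk group"):
            split = split_groups(s, 10.0)
        assert not split.testable

    def test_partition_property(self, rng):
        for _ in range(30):
            n = int(rng.integers(2, 40))
            s = CensoredSample(
                time=rng.exponential(size=n) + 0.1,
                status=rng.integers(0, 2, size=n),
                pi=rng.normal(size=n),
            )
            cut = float(rng.normal())
            split = split_groups(s, cut)
            both = np.concatenate([split.good_idx, split.poor_idx])
            np.testing.assert_array_equal(np.sort(both), np.arange(n))


def _cindex_brute_force(pis, time, status):
    conc = ties = usable = 0
    for i, j in itertools.combinations(range(len(pis)), 2):
        if time[i] == time[j]:
            if status[i] == status[j]:
                continue
            short, long_ = (i, j) if status[i] == 1 else (j, i)
        elif time[i] < time[j]:
            short, long_ = i, j
        else:
            short, long_ = j, i
        if status[short] != 1:
            continue
        usable += 1
        if pis[short] > pis[long_]:
            conc += 1
        elif pis[short] == pis[long_]:
            ties += 1
    return (conc + 0.5 * ties) / usable


class TestConcordance:
    def test_perfect_reverse_order(self):
        s = CensoredSample(time=[1.0, 2.0, 3.0], status=[1, 1, 1])
        assert concordance_index([3.0, 2.0, 1.0], s) == 1.0

    def test_all_ties_half(self):
        s = CensoredSample(time=[1.0, 2.0, 3.0], status=[1, 1, 1])
        assert concordance_index([1.0, 1.0, 1.0], s) == 0.5

    def test_matches_exhaustive_enumeration(self, rng):
        for _ in range(10):
            n = 20
            time = np.round(rng.exponential(size=n) + 0.05, 1)
            status = rng.integers(0, 2, size=n)
            status[0] = 1
            pis = np.round(rng.normal(size=n), 1)
            s = CensoredSample(time=time, status=status)
            assert concordance_index(pis, s) == pytest.approx(
                _cindex_brute_force(pis, time, status), abs=1e-15
            )

    def test_complement_symmetry_without_ties(self, rng):
        n = 15
        s = CensoredSample(
            time=rng.exponential(size=n) + 0.05, status=np.ones(n, dtype=int)
        )
        pis = rng.normal(size=n)
        assert concordance_index(pis, s) + concordance_index(-pis, s) == pytest.approx(
            1.0, abs=1e-12
        )

    def test_no_usable_pairs_rejected(self):
        s = CensoredSample(time=[1.0, 2.0], status=[0, 0])
        with pytest.raises(ValueError, match="usable"):
            concordance_index([1.0, 2.0], s)


def _breslow_loglik(beta, time, status, x):
    """Independent partial-likelihood oracle (Breslow tie handling)."""
    order = np.argsort(time)
    time, status, x = time[order], status[order], x[order]
    ll = 0.0
    for i in range(len(time)):
        if status[i] != 1:
            continue
        risk = time >= time[i]
        ll += beta * x[i] - np.log(np.sum(np.exp(beta * x[risk])))
    return ll


class TestCoxScreen:
    def test_small_case_matches_brute_force_optimum(self):
        time = np.array([2.0, 4.0, 3.0, 5.0])
        status = np.array([1, 1, 1, 0])
        x = np.array([1.0, 0.0, 2.0, 0.0])
        s = CensoredSample(time=time, status=status)
        expr = pd.DataFrame({"g": x})
        sig = univariate_cox_screen(expr, s, p_threshold=0.999)
        res = minimize_scalar(
            lambda b: -_breslow_loglik(b, time, status, x), bounds=(-5, 5),
            method="bounded", options={"xatol": 1e-10},
        )
        assert sig.weights[0] == pytest.approx(res.x, abs=1e-6)

    def test_threshold_presets_accepted(self, rng):
        n = 80
        x = rng.integers(1, 5, size=n).astype(float)
        t = rng.exponential(np.exp(-1.5 * x))
        s = CensoredSample(time=t + 1e-9, status=np.ones(n, dtype=int))
        expr = pd.DataFrame({"g": x})
        for thr in (0.05, 0.01, 0.001):
            sig = univariate_cox_screen(expr, s, p_threshold=thr)
            assert sig.genes == ("g",)

    def test_invalid_threshold(self):
        s = CensoredSample(time=[1.0], status=[1])
        with pytest.raises(ValueError):
            univariate_cox_screen(pd.DataFrame({"g": [1.0]}), s, p_threshold=1.5)

    def test_null_type_one_error_rate(self, rng):
        # gene independent of survival: selection rate at 0.05 should sit
        # within 3 binomial SEs of 0.05
        reps, n, hits = 1000, 200, 0
        for _ in range(reps):
            x = rng.integers(1, 5, size=n).astype(float)
            t = rng.exponential(size=n)
            d = (rng.uniform(size=n) < 0.8).astype(int)
            if d.sum() == 0:
                d[0] = 1
            s = CensoredSample(time=t + 1e-9, status=d)
            try:
                univariate_cox_screen(pd.DataFrame({"g": x}), s, p_threshold=0.05)
                hits += 1
            except ValueError:
                pass
        rate = hits / reps
        se = np.sqrt(0.05 * 0.95 / reps)
        assert abs(rate - 0.05) < 3 * se
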