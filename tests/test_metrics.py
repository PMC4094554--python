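"""Binned MI, OLS linear regression, DPI pruning, regulator-vs-all scoring."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from are_regnet.metrics import (
    compute_lr,
    compute_mi,
    default_bins,
    dpi_prune,
    score_regulator,
)
from are_regnet.mic import MicParams


class TestMutualInformation:
    def test_identity_reaches_log_bins(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(1000)
        assert compute_mi(x, x, n_bins=10) == pytest.approx(math.log(10), abs=1e-12)

    def test_independent_pairs_near_zero(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(1000)
        y = rng.permutation(x)
        assert compute_mi(x, y, n_bins=10) < 0.05

    def test_symmetry_and_nonnegativity(self):
        rng = np.random.default_rng(2)
        x, y = rng.standard_normal(100), rng.standard_normal(100)
        mi = compute_mi(x, y)
        assert mi >= 0.0
        assert compute_mi(y, x) == pytest.approx(mi, abs=1e-12)

    def test_bin_validation(self):
        x = np.arange(10.0)
        with pytest.raises(ValueError, match="n_bins"):
            compute_mi(x, x, n_bins=1)
        with pytest.raises(ValueError, match="n >= n_bins"):
            compute_mi(x, x, n_bins=11)
        assert default_bins(1000) == 10


class TestLinearRegression:
    def test_exact_line(self):
        x = np.arange(10.0)
        fit = compute_lr(x, -2.0 * x)
        assert fit["slope"] == pytest.approx(-2.0, abs=1e-12)
        assert fit["r"] == pytest.approx(-1.0, abs=1e-12)

    def test_five_point_closed_form_oracle(self):
        # independent arithmetic: slope = (n*Sxy - Sx*Sy) / (n*Sxx - Sx^2)
        x = np.array([1.0, 2.0, 4.0, 7.0, 11.0])
        y = np.array([2.0, 1.0, 5.0, 3.0, 9.0])
        n, sx, sy = 5, x.sum(), y.sum()
        sxx, sxy = (x * x).sum(), (x * y).sum()
        syy = (y * y).sum()
        slope = (n * sxy - sx * sy) / (n * sxx - sx**2)
        r = (n * sxy - sx * sy) / math.sqrt((n * sxx - sx**2) * (n * syy - sy**2))
        fit = compute_lr(x, y)
        assert fit["slope"] == pytest.approx(slope, rel=1e-14)
        assert fit["r"] == pytest.approx(r, rel=1e-14)
        assert math.copysign(1, fit["slope"]) == math.copysign(1, fit["r"])

    def test_independent_r_small(self):
        rng = np.random.default_rng(3)
        x, y = rng.standard_normal(1000), rng.standard_normal(1000)
        assert abs(compute_lr(x, y)["r"]) < 0.1

    def test_constant_x_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            compute_lr(np.ones(10), np.arange(10.0))


class TestDpiPrune:
    def test_strict_dpi_breaks_markov_chain(self):
        # X -> Y -> Z: the indirect X-Z edge carries the least information
        edges = [("X", "Y", 1.0), ("Y", "Z", 0.8), ("X", "Z", 0.3)]
        kept = dpi_prune(edges, tolerance=0.0)
        assert ("X", "Z", 0.3) not in kept
        assert len(kept) == 2

    def test_tolerance_one_is_identity(self):
        rng = np.random.default_rng(4)
        nodes = list("ABCDE")
        edges = [
            (a, b, float(rng.uniform(0, 2)))
            for a, b in itertools.combinations(nodes, 2)
        ]
        assert dpi_prune(edges, tolerance=1.0) == edges

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_triangle_scan(self, seed):
        rng = np.random.default_rng(seed)
        nodes = list("ABCDE")
        mi = {
            frozenset(p): float(rng.uniform(0, 1))
            for p in itertools.combinations(nodes, 2)
        }
        edges = [(a, b, mi[frozenset((a, b))]) for a, b in itertools.combinations(nodes, 2)]
        tol = 0.15
        doomed = set()
        for a, b, c in itertools.combinations(nodes, 3):
            for (u, v), (p1, p2) in [
                ((a, c), ((a, b), (b, c))),
                ((a, b), ((a, c), (b, c))),
                ((b, c), ((a, b), (a, c))),
            ]:
                if mi[frozenset((u, v))] < (1 - tol) * min(
                    mi[frozenset(p1)], mi[frozenset(p2)]
                ):
                    doomed.add(frozenset((u, v)))
        expected = [e for e in edges if frozenset(e[:2]) not in doomed]
        assert dpi_prune(edges, tolerance=tol) == expected

    def test_tolerance_validation(self):
        with pytest.raises(ValueError, match="tolerance"):
            dpi_prune([], tolerance=1.2)


class TestScoreRegulator:
    def test_planted_noiseless_targets_top_ranked(self, small_matrix):
        dep = score_regulator(small_matrix, "REG")
        top2 = dep.scores["mic"].nlargest(2).index
        assert set(top2) == {"T1", "T2"}

    def test_regulator_excluded_from_result(self, small_matrix):
        dep = score_regulator(small_matrix, "REG")
        assert "REG" not in dep.scores.index
        assert len(dep.scores) == len(small_matrix) - 1

    def test_unknown_regulator(self, small_matrix):
        with pytest.raises(KeyError, match="NOPE"):
            score_regulator(small_matrix, "NOPE")

    def test_parabolic_target_found_by_mic_not_lr(self):
        # noiseless even dependency on a regulator symmetric about 0:
        # top MIC rank, bottom-half |r| rank (the sample covariance of x and
        # x^2 vanishes identically under exact sign symmetry)
        rng = np.random.default_rng(5)
        half = rng.standard_normal(100)
        reg = np.concatenate([half, -half])
        rows = {"REG": reg, "PARAB": reg**2 - 1.0}
        for i in range(498):
            rows[f"BG{i:03d}"] = rng.standard_normal(200)
        m = pd.DataFrame(rows).T
        dep = score_regulator(m, "REG", mic_params=MicParams())
        mic_rank = dep.scores["mic"].rank(ascending=False)["PARAB"]
        r_rank = dep.scores["lr_r"].abs().rank(ascending=False)["PARAB"]
        assert mic_rank <= 3
        assert r_rank > len(dep.scores) / 2

    def test_lr_columns_match_pairwise_fit(self, small_matrix):
        dep = score_regulator(small_matrix, "REG")
        x = small_matrix.loc["REG"].to_numpy()
        for gene in ("T1", "BG0"):
            fit = compute_lr(x, small_matrix.loc[gene].to_numpy())
            assert dep.scores.loc[gene, "lr_slope"] == pytest.approx(fit["slope"], rel=1e-10)
            assert dep.scores.loc[gene, "lr_r"] == pytest.approx(fit["r"], rel=1e-10)
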