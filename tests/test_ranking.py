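"""geNorm, NormFinder, BestKeeper, comparative delta-Ct and the composite
rank, validated against brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

from refstab.ranking import (
    bestkeeper,
    composite_rank,
    delta_ct_score,
    genorm,
    normfinder,
    rank_candidates,
)


def _log2_matrix(seed=0, genes=5, samples=8):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        rng.normal(10, 1, size=(genes, samples)),
        index=[f"G{i}" for i in range(genes)],
        columns=[f"s{j}" for j in range(samples)],
    )


def _brute_force_m(matrix: pd.DataFrame) -> pd.Series:
    """All-pairs mean-SD oracle, written as the plainest possible loops."""
    out = {}
    for g in matrix.index:
        sds = []
        for k in matrix.index:
            if k == g:
                continue
            ratio = matrix.loc[g] - matrix.loc[k]
            mean = ratio.mean()
            sds.append(float(np.sqrt(((ratio - mean) ** 2).sum() / (len(ratio) - 1))))
        out[g] = sum(sds) / len(sds)
    return pd.Series(out)


class TestGenorm:
    def test_constant_ratio_pair_has_zero_pairwise_term(self):
        m = _log2_matrix(1, genes=3)
        m.loc["G1"] = m.loc["G0"] + 2.0  # x_j = c * x_k in linear space
        sd = (m.loc["G0"] - m.loc["G1"]).std(ddof=1)
        assert sd == pytest.approx(0.0, abs=1e-12)

    def test_scale_invariance_per_gene(self):
        m = _log2_matrix(2, genes=4)
        shifted = m.copy()
        shifted.loc["G2"] += np.log2(37.0)  # multiply linear values by 37
        np.testing.assert_allclose(genorm(m).m, genorm(shifted).m, rtol=1e-12)

    def test_m_matches_brute_force_oracle(self):
        m = _log2_matrix(3, genes=4, samples=6)
        result = genorm(m)
        oracle = _brute_force_m(m)
        np.testing.assert_allclose(result.m, oracle.reindex(result.m.index), atol=1e-10)

    def test_fewer_than_three_genes_rejected(self):
        with pytest.raises(ValueError):
            genorm(_log2_matrix(0, genes=2))

    def test_stepwise_removes_least_stable_first(self):
        m = _log2_matrix(4, genes=5)
        m.loc["G4"] += np.random.default_rng(9).normal(0, 3, size=m.shape[1])
        result = genorm(m)
        assert result.ranking[-1] == "G4"
        assert result.ranks["G4"] == 5

    def test_pairwise_variation_nonnegative_and_sized(self):
        m = _log2_matrix(5, genes=6)
        result = genorm(m)
        assert len(result.pairwise_variation) == 4  # V2/3 .. V5/6
        assert (result.pairwise_variation >= 0).all()

    def test_ranks_are_permutation(self):
        result = genorm(_log2_matrix(6, genes=7))
        assert sorted(result.ranks) == list(range(1, 8))


class TestDeltaCt:
    def test_equals_initial_genorm_m(self):
        m = _log2_matrix(7, genes=5)
        np.testing.assert_allclose(delta_ct_score(m), genorm(m).m, atol=1e-10)

    def test_matches_brute_force_oracle_on_random_matrix(self):
        m = _log2_matrix(8, genes=5, samples=8)
        np.testing.assert_allclose(delta_ct_score(m), _brute_force_m(m), atol=1e-10)


class TestNormFinder:
    def test_identical_genes_equal_minimal_rho(self):
        m = pd.DataFrame(
            np.tile(np.linspace(8, 12, 6), (4, 1)),
            index=list("ABCD"), columns=[f"s{j}" for j in range(6)],
        )
        rho = normfinder(m, groups=["g1"] * 3 + ["g2"] * 3)
        assert rho.nunique() == 1
        assert rho.iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_planted_group_shift_ranks_worst(self):
        m = _log2_matrix(10, genes=5, samples=8) * 0.01  # nearly flat genes
        groups = ["g1"] * 4 + ["g2"] * 4
        m.loc["G3", m.columns[4:]] += 2.0  # strong intergroup shift
        rho = normfinder(m, groups)
        assert rho.idxmax() == "G3"

    def test_single_sample_group_rejected(self):
        m = _log2_matrix(11, genes=3, samples=4)
        with pytest.raises(ValueError):
            normfinder(m, groups=["a", "b", "b", "b"])

    def test_matches_variance_decomposition_oracle(self):
        m = _log2_matrix(12, genes=5, samples=8)
        groups = ["g1"] * 4 + ["g2"] * 4
        rho = normfinder(m, groups)
        # oracle: recompute d and sigma by definition with explicit loops
        x = m.to_numpy()
        z = x - x.mean(axis=1, keepdims=True) - x.mean(axis=0, keepdims=True) + x.mean()
        expected = []
        for i in range(5):
            acc = 0.0
            for cols in (range(0, 4), range(4, 8)):
                vals = [z[i, j] for j in cols]
                d = sum(vals) / len(vals)
                mean = d
                s2 = sum((v - mean) ** 2 for v in vals) / (len(vals) - 1)
                acc += np.sqrt(d**2 + s2 / len(vals))
            expected.append(acc / 2)
        np.testing.assert_allclose(rho, expected, rtol=1e-10)
        # ordering agrees with the oracle's
        assert list(rho.sort_values().index) == list(
            pd.Series(expected, index=m.index).sort_values().index
        )


class TestBestKeeper:
    def test_gene_equal_to_index_has_r_one(self):
        rng = np.random.default_rng(13)
        g1 = rng.normal(10, 1, 6)
        g2 = rng.normal(8, 1, 6)
        g3 = (g1 + g2) / 2  # equals the 3-gene index (g1+g2+g3)/3
        m = pd.DataFrame([g1, g2, g3], index=["A", "B", "C"],
                         columns=[f"s{j}" for j in range(6)])
        out = bestkeeper(m)
        assert out.loc["C", "pearson_r"] == pytest.approx(1.0, abs=1e-10)

    def test_constant_gene_zero_sd_and_undefined_r(self):
        m = _log2_matrix(14, genes=3)
        m.loc["G0"] = 5.0
        out = bestkeeper(m)
        assert out.loc["G0", "sd_log2"] == 0.0
        assert np.isnan(out.loc["G0", "pearson_r"])

    def test_r_matches_hand_pearson_formula(self):
        m = _log2_matrix(15, genes=3, samples=7)
        out = bestkeeper(m)
        index = m.mean(axis=0)
        for g in m.index:
            x, y = m.loc[g].to_numpy(), index.to_numpy()
            xc, yc = x - x.mean(), y - y.mean()
            r = (xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum())
            assert out.loc[g, "pearson_r"] == pytest.approx(r, rel=1e-10)

    def test_cv_is_scale_sensitive_but_sd_is_not(self):
        m = _log2_matrix(16, genes=3)
        shifted = m + 3.0
        a, b = bestkeeper(m), bestkeeper(shifted)
        np.testing.assert_allclose(a["sd_log2"], b["sd_log2"], rtol=1e-12)
        assert not np.allclose(a["cv_percent"], b["cv_percent"])


class TestComposite:
    def test_all_methods_agree(self):
        ranks = pd.Series([1, 2, 3], index=list("ABC"))
        out = composite_rank({"m1": ranks, "m2": ranks, "m3": ranks, "m4": ranks})
        assert list(out.index) == list("ABC")
        np.testing.assert_allclose(out["geomean_rank"], [1, 2, 3])

    def test_single_method_identity(self):
        ranks = pd.Series([2, 1, 3], index=list("ABC"))
        out = composite_rank({"only": ranks})
        assert list(out.index) == ["B", "A", "C"]

    def test_tie_broken_lexicographically(self):
        out = composite_rank(
            {
                "m1": pd.Series({"ZZ": 1, "AA": 2}),
                "m2": pd.Series({"ZZ": 2, "AA": 1}),
            }
        )
        assert out.loc["AA", "geomean_rank"] == out.loc["ZZ", "geomean_rank"]
        assert out.loc["AA", "composite_rank"] == 1
        assert out.loc["ZZ", "composite_rank"] == 2

    def test_mismatched_gene_sets_rejected(self):
        with pytest.raises(ValueError):
            composite_rank(
                {
                    "m1": pd.Series({"A": 1, "B": 2}),
                    "m2": pd.Series({"A": 1, "C": 2}),
                }
            )


class TestRankCandidates:
    def test_all_scores_scale_invariant_except_bestkeeper_cv(self):
        m = _log2_matrix(17, genes=5)
        shifted = m.copy()
        for i, g in enumerate(m.index):
            shifted.loc[g] += float(i)  # per-gene multiplicative rescale
        groups = ["g1"] * 4 + ["g2"] * 4
        a = rank_candidates(m, groups)
        b = rank_candidates(shifted, groups)
        for col in ("genorm_m", "normfinder_rho", "bestkeeper_sd", "delta_ct_score"):
            np.testing.assert_allclose(
                a[col].sort_index(), b[col].sort_index(), rtol=1e-9, atol=1e-12
            )

    def test_stable_genes_outrank_planted_sensitive(self):
        """A strongly g-sensitive gene lands last on every method."""
        rng = np.random.default_rng(18)
        m = pd.DataFrame(
            rng.normal(10, 0.05, size=(5, 8)),
            index=[f"G{i}" for i in range(5)],
            columns=[f"s{j}" for j in range(8)],
        )
        groups = ["a"] * 4 + ["b"] * 4
        m.loc["G2", m.columns[4:]] += 1.0
        out = rank_candidates(m, groups)
        for col in ("genorm", "normfinder", "bestkeeper", "delta_ct"):
            assert out.loc["G2", col] == 5
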