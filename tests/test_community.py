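import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.spatial import procrustes

from qasd_mediate import (
    bray_curtis, dbrda_univariate, envfit, forward_select, pcoa, permanova,
    permanova_mediation, redundancy_filter,
)


@pytest.fixture
def random_abundances():
    rng = np.random.default_rng(0)
    return pd.DataFrame(rng.random((24, 10)),
                        index=[f"s{i}" for i in range(24)])


class TestBrayCurtis:
    def test_identical_and_disjoint_rows(self):
        ab = pd.DataFrame([[1, 1, 0], [1, 1, 0], [0, 0, 2]],
                          index=list("abc"), dtype=float)
        d = bray_curtis(ab)
        assert d.loc["a", "b"] == 0.0
        assert d.loc["a", "c"] == 1.0

    def test_hand_example(self):
        ab = pd.DataFrame([[1, 1, 0], [0, 1, 1]], dtype=float)
        assert bray_curtis(ab).iloc[0, 1] == pytest.approx(0.5)

    def test_double_loop_oracle(self):
        rng = np.random.default_rng(1)
        ab = pd.DataFrame(rng.random((5, 4)))
        d = bray_curtis(ab)
        A = ab.to_numpy()
        for i in range(5):
            for j in range(5):
                expected = np.abs(A[i] - A[j]).sum() / (A[i] + A[j]).sum()
                assert abs(d.iloc[i, j] - expected) < 1e-12

    def test_symmetric_bounded_zero_diag(self, random_abundances):
        d = bray_curtis(random_abundances)
        D = d.to_numpy()
        assert np.allclose(D, D.T)
        assert np.allclose(np.diag(D), 0.0)
        assert (D >= 0).all() and (D <= 1).all()

    def test_all_zero_row_rejected(self):
        ab = pd.DataFrame([[1.0, 1], [0, 0]], index=["ok", "empty"])
        with pytest.raises(ValueError, match="empty"):
            bray_curtis(ab)


class TestPcoa:
    def test_euclidean_round_trip(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(15, 2))
        d = pd.DataFrame(
            np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1)))
        ordn = pcoa(d)
        coords = ordn.coordinates.to_numpy()[:, :2]
        _, _, disparity = procrustes(X - X.mean(0), coords)
        assert disparity < 1e-8
        assert len(ordn.negative_eigenvalues) == 0

    def test_three_equidistant_points(self):
        d = pd.DataFrame(1.0 - np.eye(3))
        ordn = pcoa(d)
        assert len(ordn.eigenvalues) == 2
        assert ordn.eigenvalues[0] == pytest.approx(ordn.eigenvalues[1])

    def test_duplicate_samples_coincide(self):
        ab = pd.DataFrame([[1, 2, 0], [1, 2, 0], [4, 0, 1], [0, 3, 3.0]])
        ordn = pcoa(bray_curtis(ab))
        c = ordn.coordinates.to_numpy()
        assert np.allclose(c[0], c[1], atol=1e-8)

    def test_coordinates_centered_and_axes_ordered(self, random_abundances):
        ordn = pcoa(bray_curtis(random_abundances))
        assert np.allclose(ordn.coordinates.mean(axis=0), 0.0, atol=1e-9)
        assert (np.diff(ordn.eigenvalues) <= 1e-12).all()
        assert ordn.relative_eigenvalues.sum() == pytest.approx(1.0)

    def test_asymmetric_input_rejected(self):
        d = pd.DataFrame([[0.0, 1.0], [0.5, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            pcoa(d)

    def test_matches_skbio_on_fixture(self, random_abundances):
        skbio = pytest.importorskip("skbio")
        d = bray_curtis(random_abundances)
        ours = pcoa(d)
        theirs = skbio.stats.ordination.pcoa(
            skbio.DistanceMatrix(d.to_numpy()))
        k = len(ours.eigenvalues)
        ref = np.sort(theirs.eigvals.to_numpy())[::-1][:k]
        assert np.allclose(ours.eigenvalues, ref, atol=1e-8)


class TestPermanova:
    def test_r2_partition_sums_to_one(self, random_abundances):
        rng = np.random.default_rng(3)
        d = bray_curtis(random_abundances)
        design = pd.DataFrame({
            "g": rng.choice(["a", "b"], len(d)),
            "z": rng.normal(size=len(d)),
        }, index=d.index)
        out = permanova(d, design, permutations=49, seed=0)
        assert out["R2"].sum() == pytest.approx(1.0)

    def test_separated_clusters_significant(self):
        rng = np.random.default_rng(4)
        a = rng.normal(0, 0.05, size=(12, 4)) + 1.0
        b = rng.normal(0, 0.05, size=(12, 4)) + 3.0
        ab = pd.DataFrame(np.vstack([a, b]))
        labels = pd.DataFrame({"g": ["a"] * 12 + ["b"] * 12})
        out = permanova(bray_curtis(ab), labels, permutations=199, seed=1)
        assert out.loc["g", "p"] == pytest.approx(1 / 200)

    def test_matches_skbio_pseudo_f(self, random_abundances):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(5)
        d = bray_curtis(random_abundances)
        labels = rng.choice(["a", "b", "c"], len(d))
        ours = permanova(d, pd.DataFrame({"g": labels}, index=d.index),
                         permutations=9, seed=0)
        ref = skbio.stats.distance.permanova(
            skbio.DistanceMatrix(d.to_numpy()), labels, permutations=9)
        assert ours.loc["g", "F"] == pytest.approx(ref["test statistic"],
                                                   abs=1e-8)

    def test_single_level_term_rejected(self, random_abundances):
        d = bray_curtis(random_abundances)
        with pytest.raises(ValueError, match="single level"):
            permanova(d, pd.DataFrame({"g": ["a"] * len(d)}, index=d.index),
                      permutations=9)

    def test_null_pvalues_uniform(self):
        rng = np.random.default_rng(6)
        pvals = []
        for _ in range(60):
            ab = pd.DataFrame(rng.random((16, 6)))
            design = pd.DataFrame({"g": rng.choice(["x", "y"], 16)})
            out = permanova(bray_curtis(ab), design, permutations=99,
                            seed=int(rng.integers(2**31)))
            pvals.append(out.loc["g", "p"])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestPermanovaMediation:
    def _chain(self, effect, seed=0, n=40):
        # exposure shifts composition; composition drives the outcome
        rng = np.random.default_rng(seed)
        x = rng.choice([0.0, 1.0], n)
        comp = rng.random((n, 6)) + effect * x[:, None] * np.array(
            [1.0, 0.5, 0, 0, 0, 0])
        ab = pd.DataFrame(comp, index=[f"s{i}" for i in range(n)])
        axis = pcoa(bray_curtis(ab)).coordinates.iloc[:, 0]
        outcome = pd.Series(
            effect * axis + 0.2 * rng.standard_normal(n), index=ab.index)
        return bray_curtis(ab), pd.Series(
            np.where(x == 1, "high", "low"), index=ab.index), outcome

    def test_planted_chain_detected(self):
        d, expo, outcome = self._chain(effect=2.0, seed=7)
        res = permanova_mediation(d, expo, outcome, permutations=199,
                                  seed=0, n_axes=2)
        assert res["mediation_p"] < 0.05
        assert res["f_exposure_composition"] > 1

    def test_joint_significance_bound(self):
        d, expo, outcome = self._chain(effect=0.0, seed=8)
        res = permanova_mediation(d, expo, outcome, permutations=99,
                                  seed=1, n_axes=2)
        assert res["mediation_p"] >= res["p_exposure_composition"]
        assert res["mediation_p"] >= res["p_composition_outcome"]

    def test_noise_outcome_not_significant(self):
        d, expo, _ = self._chain(effect=2.0, seed=9)
        rng = np.random.default_rng(10)
        noise = pd.Series(rng.standard_normal(len(d)), index=d.index)
        res = permanova_mediation(d, expo, noise, permutations=99, seed=2,
                                  n_axes=2)
        assert res["mediation_p"] > 0.05


class TestDbrda:
    def test_first_axis_self_fit(self, random_abundances):
        d = bray_curtis(random_abundances)
        ordn = pcoa(d)
        out = dbrda_univariate(d, ordn.coordinates["PCo1"], permutations=49,
                               seed=0)
        assert out["r2"] == pytest.approx(ordn.relative_eigenvalues[0],
                                          abs=1e-10)
        assert out["adj_r2"] <= out["r2"]

    def test_permuted_covariate_null(self, random_abundances):
        rng = np.random.default_rng(11)
        d = bray_curtis(random_abundances)
        out = dbrda_univariate(
            d, pd.Series(rng.normal(size=len(d)), index=d.index),
            permutations=99, seed=1)
        assert out["adj_r2"] < 0.1
        assert out["p"] > 0.05

    def test_constant_covariate_rejected(self, random_abundances):
        d = bray_curtis(random_abundances)
        with pytest.raises(ValueError, match="constant"):
            dbrda_univariate(d, pd.Series(1.0, index=d.index))


class TestForwardSelect:
    def test_single_informative_candidate(self, random_abundances):
        rng = np.random.default_rng(12)
        d = bray_curtis(random_abundances)
        axis = pcoa(d).coordinates["PCo1"]
        cands = pd.DataFrame({
            "signal": axis + 0.05 * rng.standard_normal(len(d)),
            "n1": rng.standard_normal(len(d)),
            "n2": rng.standard_normal(len(d)),
        }, index=d.index)
        out = forward_select(d, cands, alpha=0.01, permutations=199, seed=0)
        assert list(out["variable"]) == ["signal"]

    def test_collinear_pair_yields_one_pick(self, random_abundances):
        rng = np.random.default_rng(13)
        d = bray_curtis(random_abundances)
        axis = pcoa(d).coordinates["PCo1"]
        cands = pd.DataFrame({
            "sig_a": axis + 0.05 * rng.standard_normal(len(d)),
        }, index=d.index)
        cands["sig_b"] = cands["sig_a"] + 0.01 * rng.standard_normal(len(d))
        out = forward_select(d, cands, permutations=99, seed=1)
        assert len(out) == 1

    def test_all_noise_usually_empty(self):
        rng = np.random.default_rng(14)
        empties = 0
        for seed in range(20):
            ab = pd.DataFrame(rng.random((18, 6)))
            d = bray_curtis(ab)
            cands = pd.DataFrame(rng.standard_normal((18, 4)), index=d.index,
                                 columns=list("wxyz"))
            out = forward_select(d, cands, permutations=99, seed=seed)
            empties += int(out.empty)
        assert empties >= 15

    def test_cumulative_adj_r2_nondecreasing(self, random_abundances):
        rng = np.random.default_rng(15)
        d = bray_curtis(random_abundances)
        coords = pcoa(d).coordinates
        cands = pd.DataFrame({
            "a": coords["PCo1"] + 0.05 * rng.standard_normal(len(d)),
            "b": coords["PCo2"] + 0.05 * rng.standard_normal(len(d)),
            "c": rng.standard_normal(len(d)),
        }, index=d.index)
        out = forward_select(d, cands, permutations=99, seed=2)
        assert (out["cum_adj_r2"].diff().dropna() > 0).all()


class TestEnvfit:
    def test_axis_covariate_recovered(self, random_abundances):
        ordn = pcoa(bray_curtis(random_abundances))
        out = envfit(ordn, ordn.coordinates["PCo2"], k=2, permutations=49,
                     seed=0)
        assert out["r2"] == pytest.approx(1.0)
        assert abs(out["arrow"][1]) == pytest.approx(1.0)
        assert abs(out["arrow"][0]) < 1e-8

    def test_noise_covariate_null(self, random_abundances):
        rng = np.random.default_rng(16)
        ordn = pcoa(bray_curtis(random_abundances))
        out = envfit(ordn, pd.Series(rng.normal(size=24)), k=2,
                     permutations=99, seed=1)
        assert out["p"] > 0.05

    def test_matches_vegan_style_r2(self, random_abundances):
        # oracle: envfit R2 equals OLS R2 of covariate on the axes
        rng = np.random.default_rng(17)
        ordn = pcoa(bray_curtis(random_abundances))
        cov = pd.Series(ordn.coordinates["PCo1"].to_numpy()
                        + 0.3 * rng.normal(size=24))
        out = envfit(ordn, cov, k=3, permutations=9, seed=2)
        X = np.column_stack([np.ones(24),
                             ordn.coordinates.iloc[:, :3].to_numpy()])
        beta, *_ = np.linalg.lstsq(X, cov.to_numpy(), rcond=None)
        resid = cov.to_numpy() - X @ beta
        r2 = 1 - resid @ resid / ((cov - cov.mean()) ** 2).sum()
        assert out["r2"] == pytest.approx(r2, abs=1e-10)


class TestRedundancyFilter:
    def test_identical_columns_deduplicated(self):
        rng = np.random.default_rng(18)
        a = rng.normal(size=30)
        cov = pd.DataFrame({"a": a, "b": a.copy(),
                            "c": rng.normal(size=30)})
        kept = redundancy_filter(cov)
        assert "c" in kept
        assert len([k for k in kept if k in ("a", "b")]) == 1

    def test_uncorrelated_set_untouched(self):
        rng = np.random.default_rng(19)
        cov = pd.DataFrame(rng.normal(size=(50, 4)), columns=list("wxyz"))
        assert redundancy_filter(cov) == list("wxyz")

    def test_chain_leaves_no_pair_over_threshold(self):
        rng = np.random.default_rng(20)
        base = rng.normal(size=100)
        cov = pd.DataFrame({
            "a": base,
            "b": base + 0.1 * rng.normal(size=100),
            "c": base + 0.15 * rng.normal(size=100),
            "d": rng.normal(size=100),
        })
        kept = redundancy_filter(cov, threshold=0.9)
        assert len(kept) >= 1
        corr = cov[kept].corr(method="spearman").abs().to_numpy()
        np.fill_diagonal(corr, 0.0)
        assert corr.max() <= 0.9
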