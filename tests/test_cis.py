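import numpy as np
import pytest
from scipy import stats

from qtlcurator import cis
from qtlcurator.containers import TranscriptModel
from qtlcurator.simulate import simulate_genotypes, simulate_trait_group
from tests.conftest import make_dosage_matrix


def gene(start, end, strand="+"):
    return TranscriptModel("tx", "g", "chr1", strand, [(start, end)])


class TestCisWindow:
    def test_plus_strand_window(self):
        w = cis.define_cis_window(gene(5_000_000, 5_050_000))
        assert (w.start, w.end, w.anchor) == (4_000_000, 6_000_000, 5_000_000)

    def test_minus_strand_anchored_at_rightmost(self):
        w = cis.define_cis_window(gene(5_000_000, 5_050_000, "-"))
        assert w.anchor == 5_049_999
        assert w.start == 4_049_999 and w.end == 6_049_999

    def test_clamped_at_origin(self):
        w = cis.define_cis_window(gene(200_000, 250_000))
        assert w.start == 0 and w.end == 1_200_000


class TestComputePcs:
    def test_collinear_data_one_component(self, rng):
        t = rng.standard_normal(50)
        X = np.outer(t, [1.0, -2.0, 0.5]) + 1e-9 * rng.standard_normal((50, 3))
        scores = cis.compute_pcs(X, k=2)
        var = scores.var(axis=0, ddof=1)
        assert var[0] / var.sum() > 0.999

    def test_matches_eigendecomposition_oracle(self, rng):
        X = rng.standard_normal((10, 6))
        Z = (X - X.mean(0)) / X.std(0, ddof=1)
        evals, evecs = np.linalg.eigh(Z.T @ Z)
        order = np.argsort(evals)[::-1]
        oracle = Z @ evecs[:, order[:3]]
        scores = cis.compute_pcs(X, k=3)
        for j in range(3):
            assert np.allclose(scores[:, j], oracle[:, j], atol=1e-8) or np.allclose(
                scores[:, j], -oracle[:, j], atol=1e-8
            )

    def test_rotation_invariance_up_to_sign(self, rng):
        X = rng.standard_normal((30, 5))
        q, _ = np.linalg.qr(rng.standard_normal((5, 5)))
        # covariance-based scores describe the sample geometry, which an
        # orthogonal rotation of the feature axes leaves unchanged
        s1 = cis.compute_pcs(X, k=3, scale=False)
        s2 = cis.compute_pcs(X @ q, k=3, scale=False)
        np.testing.assert_allclose(np.abs(s1), np.abs(s2), atol=1e-8)

    def test_k_too_large_rejected(self, rng):
        with pytest.raises(cis.ScanError):
            cis.compute_pcs(rng.standard_normal((5, 3)), k=3)


def closed_form_ols(y, g, C):
    """Textbook (X'X)^-1 X'y with full covariate matrix; the oracle."""
    X = np.column_stack([np.ones_like(y), g, C]) if C is not None else \
        np.column_stack([np.ones_like(y), g])
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ y
    resid = y - X @ beta
    df = len(y) - X.shape[1]
    sigma2 = resid @ resid / df
    se = np.sqrt(sigma2 * np.diag(XtX_inv))
    t = beta[1] / se[1]
    return beta[1], se[1], 2 * stats.t.sf(abs(t), df)


class TestNominalScan:
    def test_matches_closed_form_oracle(self, rng):
        dos = simulate_genotypes(20, 8, maf=0.4, seed=5)
        y = rng.standard_normal(20)
        C = rng.standard_normal((20, 2))
        ss = cis.nominal_scan(y, dos, covariates=C)
        for j in range(8):
            b, s, p = closed_form_ols(y, dos.dosage[:, j], C)
            assert ss["beta"][j] == pytest.approx(b, abs=1e-10)
            assert ss["se"][j] == pytest.approx(s, abs=1e-10)
            assert ss["pvalue"][j] == pytest.approx(p, abs=1e-10)

    def test_trait_equal_to_dosage(self, small_genotypes):
        y = small_genotypes.dosage[:, 3].copy()
        ss = cis.nominal_scan(y, small_genotypes)
        assert ss["beta"][3] == pytest.approx(1.0)
        assert ss["pvalue"][3] < 1e-100

    def test_null_pvalues_roughly_uniform(self):
        rng = np.random.default_rng(99)
        dos = simulate_genotypes(1000, 40, maf=0.3, seed=100)
        y = rng.standard_normal(1000)
        ss = cis.nominal_scan(y, dos)
        ks = stats.kstest(ss["pvalue"], "uniform")
        assert ks.pvalue > 0.01

    def test_fewer_than_five_variants_rejected(self, rng):
        dos = simulate_genotypes(30, 4, maf=0.3, seed=1)
        with pytest.raises(cis.ScanError, match="minimum 5"):
            cis.nominal_scan(rng.standard_normal(30), dos)

    def test_zero_variance_trait_rejected(self, small_genotypes):
        with pytest.raises(cis.ScanError, match="zero variance"):
            cis.nominal_scan(np.ones(80), small_genotypes)

    def test_monomorphic_dosage_flagged_not_fatal(self, rng):
        d = rng.integers(0, 3, size=(40, 5)).astype(float)
        d[:, 2] = 1.0
        dm = make_dosage_matrix(d)
        ss = cis.nominal_scan(rng.standard_normal(40), dm)
        assert np.isnan(ss["beta"][2]) and ss["note"][2] == "zero_variance_dosage"
        assert np.isfinite(ss["beta"][[0, 1, 3, 4]]).all()

    def test_missing_dosage_dropped_pairwise(self, rng):
        d = rng.integers(0, 3, size=(50, 6)).astype(float)
        d[:10, 1] = np.nan
        dm = make_dosage_matrix(d)
        y = rng.standard_normal(50)
        ss = cis.nominal_scan(y, dm)
        b, s, p = closed_form_ols(y[10:], d[10:, 1], None)
        assert ss["beta"][1] == pytest.approx(b, abs=1e-10)
        assert ss["an"][1] == 80

    def test_residualised_equals_covariate_adjusted(self, rng):
        # Frisch-Waugh: scanning residualised trait/dosage without covariates
        # reproduces the covariate-adjusted slope
        dos = simulate_genotypes(60, 6, maf=0.3, seed=2)
        y = rng.standard_normal(60)
        C = rng.standard_normal((60, 4))
        ss_cov = cis.nominal_scan(y, dos, covariates=C)
        Cw = np.column_stack([np.ones(60), C])
        ry = cis.residualise(y[:, None], Cw)[:, 0]
        rG = cis.residualise(dos.dosage, Cw)
        beta_fw = (rG.T @ ry) / np.einsum("ij,ij->j", rG, rG)
        np.testing.assert_allclose(ss_cov["beta"], beta_fw, atol=1e-8)


class TestGroupPermutation:
    def test_planted_effect_hits_estimator_floor(self):
        dos = simulate_genotypes(200, 10, maf=0.3, seed=7)
        tm, _ = simulate_trait_group(dos, 4, n_traits=3, lead_effect=2.0, seed=8)
        res = cis.group_permutation(
            tm.values, list(tm.traits["trait_id"]), dos, n_perm=1000, seed=1
        )
        assert res.empirical_p == pytest.approx(1 / 1001)

    def test_single_trait_group_reduces_to_single_pass(self):
        dos = simulate_genotypes(100, 8, maf=0.3, seed=3)
        rng = np.random.default_rng(5)
        y = rng.standard_normal(100)
        r1 = cis.group_permutation(y[:, None], ["t"], dos, n_perm=200, seed=11)
        r2 = cis.group_permutation(y[:, None], ["t"], dos, n_perm=200, seed=11)
        assert r1.empirical_p == r2.empirical_p
        assert r1.lead_trait == "t"

    def test_invariant_to_trait_relabelling(self):
        dos = simulate_genotypes(80, 6, maf=0.3, seed=4)
        rng = np.random.default_rng(6)
        Y = rng.standard_normal((80, 3))
        r1 = cis.group_permutation(Y, ["a", "b", "c"], dos, n_perm=300, seed=2)
        r2 = cis.group_permutation(
            Y[:, ::-1], ["c", "b", "a"], dos, n_perm=300, seed=2
        )
        assert r1.empirical_p == r2.empirical_p

    def test_low_n_perm_warns(self):
        dos = simulate_genotypes(50, 6, maf=0.3, seed=9)
        y = np.random.default_rng(0).standard_normal(50)
        with pytest.warns(UserWarning, match="coarse"):
            cis.group_permutation(y[:, None], ["t"], dos, n_perm=50, seed=0)


class TestDatasetFdr:
    def test_all_null(self):
        res = cis.dataset_fdr({f"g{i}": 1.0 for i in range(20)})
        assert not res["significant"].any()

    def test_single_strong_signal(self):
        p = {f"g{i}": 1.0 for i in range(100)}
        p["hit"] = 1e-10
        res = cis.dataset_fdr(p)
        sig = set(res.loc[res["significant"], "group_id"])
        assert sig == {"hit"}

    def test_matches_bh_definition_oracle(self, rng):
        pvals = rng.uniform(0, 1, 50) ** 3
        res = cis.dataset_fdr({f"g{i}": p for i, p in enumerate(pvals)}, level=0.05)
        m = len(pvals)
        order = np.sort(pvals)
        ks = np.flatnonzero(order <= (np.arange(1, m + 1) * 0.05 / m))
        thresh = order[ks.max()] if ks.size else -1.0
        expected = pvals <= thresh
        np.testing.assert_array_equal(res["significant"].to_numpy(), expected)


class TestExonEffectProfile:
    def test_exon_equal_to_dosage_flagged(self, small_genotypes, rng):
        g = small_genotypes.dosage[:, 0]
        E = np.column_stack([g, rng.standard_normal(80)])
        prof = cis.exon_effect_profile(g, E, ["hit", "noise"])
        hit = prof.set_index("exon_id").loc["hit"]
        assert hit["beta"] == pytest.approx(1.0)
        assert hit["ci_low"] > 0 and bool(hit["significant"])

    def test_null_exons_unflagged(self, small_genotypes, rng):
        g = small_genotypes.dosage[:, 0]
        E = rng.standard_normal((80, 6))
        prof = cis.exon_effect_profile(g, E, [f"e{i}" for i in range(6)])
        assert not prof["significant"].any()

    def test_zero_variance_exon_noted(self, small_genotypes, rng):
        g = small_genotypes.dosage[:, 0]
        E = np.column_stack([rng.standard_normal(80), np.ones(80)])
        prof = cis.exon_effect_profile(g, E, ["ok", "flat"])
        assert prof.loc[1, "note"] == "zero_variance"
        assert np.isnan(prof.loc[1, "beta"])

    def test_ci_covers_null_about_95_percent(self):
        # coverage of the 95% interval on null exons, across seeds
        hits = 0
        total = 0
        for seed in range(40):
            rng = np.random.default_rng(seed)
            dos = simulate_genotypes(100, 6, maf=0.3, seed=seed + 1000)
            g = dos.dosage[:, 0]
            E = rng.standard_normal((100, 5))
            prof = cis.exon_effect_profile(g, E, [f"e{i}" for i in range(5)])
            covered = (prof["ci_low"] <= 0) & (0 <= prof["ci_high"])
            hits += int(covered.sum())
            total += len(prof)
        assert 0.90 <= hits / total <= 0.99
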