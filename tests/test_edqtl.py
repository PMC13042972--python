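"""cis-edQTL machinery: transforms, scan vs normal-equation oracle,
permutation empirical p, FDR, conditional signals, LD and sharing."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import expit, logit

from editome_kit import edqtl


class TestTransforms:
    def test_int_closed_form_blom(self):
        levels = np.array([0.1, 0.2, 0.4, 0.8])
        y = edqtl.transform_levels(levels)
        n = 4
        expected = stats.norm.ppf((np.arange(1, 5) - 3 / 8) / (n + 1 - 3 / 4))
        assert np.allclose(np.sort(y), expected)
        # monotone input preserves ranks
        assert np.array_equal(np.argsort(y), np.argsort(levels))

    def test_output_standardized(self, rng):
        y = edqtl.transform_levels(rng.uniform(0.01, 0.99, 200))
        assert abs(y.mean()) < 0.05
        assert abs(y.std() - 1) < 0.1

    def test_constant_vector_errors(self):
        with pytest.raises(ValueError):
            edqtl.transform_levels(np.full(10, 0.3))

    def test_pc_residualization_removes_covariate(self, rng):
        pc = rng.normal(0, 1, 100)
        levels = expit(0.5 + 2.0 * pc + rng.normal(0, 0.05, 100))
        y = edqtl.transform_levels(levels, pcs=pc[:, None], inverse_normal=False)
        assert abs(np.corrcoef(y, pc)[0, 1]) < 0.15


class TestCisScan:
    def test_perfect_fit(self):
        g = np.array([0.0, 1.0, 2.0, 0.0, 1.0, 2.0])
        y = 0.5 * g
        res = edqtl.cis_scan(y, g[None, :])
        assert res.slope[0] == pytest.approx(0.5)
        assert res.nominal_p[0] < 1e-10

    def test_matches_normal_equation_oracle(self, rng):
        n, m = 150, 30
        G = rng.binomial(2, 0.3, size=(m, n)).astype(float)
        y = rng.normal(0, 1, n)
        res = edqtl.cis_scan(y, G)
        X = np.column_stack([np.ones(n), np.zeros(n)])
        for j in range(m):
            X[:, 1] = G[j]
            XtX_inv = np.linalg.inv(X.T @ X)
            beta = XtX_inv @ X.T @ y
            resid = y - X @ beta
            s2 = resid @ resid / (n - 2)
            se = np.sqrt(s2 * XtX_inv[1, 1])
            assert abs(res.slope[j] - beta[1]) < 1e-10
            assert abs(res.slope_se[j] - se) < 1e-10
            p = 2 * stats.t.sf(abs(beta[1] / se), n - 2)
            assert abs(res.nominal_p[j] - p) < 1e-10

    def test_null_nominal_p_uniform(self, rng):
        n = 120
        g = rng.binomial(2, 0.4, n).astype(float)
        ps = []
        for _ in range(500):
            y = rng.normal(0, 1, n)
            ps.append(edqtl.cis_scan(y, g[None, :]).nominal_p[0])
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestSelectPCs:
    def test_pure_noise_gives_zero_pcs(self, rng):
        level = pd.DataFrame(rng.uniform(0.1, 0.9, size=(50, 40)))
        pcs = edqtl.select_pcs(level, seed=5)
        assert pcs.shape[1] == 0

    def test_batch_factor_detected(self, rng):
        batch = np.repeat([0.0, 1.0], 20)
        base = rng.uniform(0.2, 0.6, 50)
        level = expit(logit(base)[:, None] + 1.5 * batch[None, :]
                      + rng.normal(0, 0.2, size=(50, 40)))
        pcs = edqtl.select_pcs(pd.DataFrame(level), seed=5)
        assert pcs.shape[1] >= 1
        assert abs(np.corrcoef(pcs[:, 0], batch)[0, 1]) > 0.9

    def test_deterministic_given_seed(self, rng):
        level = pd.DataFrame(rng.uniform(0.1, 0.9, size=(30, 20)))
        a = edqtl.select_pcs(level, seed=3)
        b = edqtl.select_pcs(level, seed=3)
        assert np.array_equal(a, b)


class TestPermutationPass:
    def test_planted_effect_low_empirical_p(self, rng):
        n = 200
        G = rng.binomial(2, 0.3, size=(15, n)).astype(float)
        y = 0.8 * G[4] + rng.normal(0, 1, n)
        res = edqtl.permutation_pass(y, G, n_perm=500, seed=1)
        assert res["empirical_p"] < 1e-3
        assert res["lead_index"] == 4

    def test_null_empirical_p_not_extreme(self, rng):
        n = 200
        G = rng.binomial(2, 0.3, size=(15, n)).astype(float)
        ps = [edqtl.permutation_pass(rng.normal(0, 1, n), G, n_perm=300,
                                     seed=k)["empirical_p"]
              for k in range(40)]
        # under the null, empirical p should look uniform-ish
        assert min(ps) > 1e-4
        assert stats.kstest(ps, "uniform").pvalue > 0.005

    def test_beta_close_to_rank_estimate(self, rng):
        n = 150
        G = rng.binomial(2, 0.3, size=(10, n)).astype(float)
        y = 0.25 * G[0] + rng.normal(0, 1, n)
        res = edqtl.permutation_pass(y, G, n_perm=2000, seed=2)
        assert res["beta_ok"]
        assert abs(res["empirical_p"] - res["rank_p"]) < 0.05


class TestFDR:
    def test_bh_arithmetic(self):
        q, sig = edqtl.fdr_control(np.array([0.001, 0.02, 0.9]))
        assert np.allclose(q, [0.003, 0.03, 0.9])
        assert list(sig) == [True, True, False]

    def test_all_ones_none_significant(self):
        q, sig = edqtl.fdr_control(np.ones(10))
        assert not sig.any()

    def test_empty(self):
        q, sig = edqtl.fdr_control(np.array([]))
        assert len(q) == 0

    def test_null_fdp_controlled(self, rng):
        # mixed truth: 100 signal p-values ~ tiny, 900 null uniform
        fdps = []
        for _ in range(200):
            p = np.concatenate([rng.uniform(0, 1e-6, 100), rng.uniform(0, 1, 900)])
            truth = np.arange(1000) < 100
            _, sig = edqtl.fdr_control(p)
            r = sig.sum()
            fdps.append((sig & ~truth).sum() / max(r, 1))
        assert np.mean(fdps) <= 0.07


class TestConditionalSignals:
    def _site(self, rng, slopes, n=300, m=40):
        G = rng.binomial(2, rng.uniform(0.2, 0.5, m)[:, None], size=(m, n)).astype(float)
        y = rng.normal(0, 1, n)
        causal = []
        for i, s in enumerate(slopes):
            j = (i + 1) * 10
            y = y + s * G[j]
            causal.append(j)
        ids = np.array([f"s{i}" for i in range(m)])
        return y, G, ids, causal

    def test_two_independent_causal_snps(self, rng):
        y, G, ids, causal = self._site(rng, [0.7, 0.7])
        pp = edqtl.permutation_pass(y, G, n_perm=500, seed=3)
        out = edqtl.conditional_signals(y, G, ids, pp["beta_a"], pp["beta_b"])
        assert len(out) == 2
        found = set(out.snp)
        for c in causal:
            tags = {f"s{i}" for i in range(len(ids))
                    if edqtl.ld_r2(G[c], G[i]) is not np.nan
                    and edqtl.ld_r2(G[c], G[i]) > 0.8}
            assert found & tags

    def test_single_causal_usually_one_signal(self, rng):
        counts = []
        for _ in range(10):
            y, G, ids, _ = self._site(rng, [0.8])
            pp = edqtl.permutation_pass(y, G, n_perm=300, seed=4)
            out = edqtl.conditional_signals(y, G, ids, pp["beta_a"], pp["beta_b"])
            counts.append(len(out))
        assert np.mean([c == 1 for c in counts]) >= 0.8

    def test_null_site_no_signal(self, rng):
        y, G, ids, _ = self._site(rng, [])
        pp = edqtl.permutation_pass(y, G, n_perm=300, seed=5)
        out = edqtl.conditional_signals(y, G, ids, pp["beta_a"], pp["beta_b"])
        assert len(out) == 0


class TestLD:
    def test_identical_and_anticorrelated(self):
        a = np.array([0, 1, 2, 0, 1, 2], dtype=float)
        b = np.array([2, 1, 0, 2, 1, 0], dtype=float)
        assert edqtl.ld_r2(a, a) == pytest.approx(1.0)
        assert edqtl.ld_r2(a, b) == pytest.approx(1.0)

    def test_monomorphic_nan(self):
        assert np.isnan(edqtl.ld_r2(np.zeros(10), np.arange(10.0)))

    def test_independent_snps_small_r2(self, rng):
        a = rng.binomial(2, 0.3, 10_000).astype(float)
        b = rng.binomial(2, 0.3, 10_000).astype(float)
        assert edqtl.ld_r2(a, b) < 0.01


class TestTypeSpecific:
    def test_identical_snp_excluded_and_unlinked_retained(self, rng):
        n = 100
        variants = pd.DataFrame({
            "chrom": ["c"] * 3, "pos0": [100, 200, 50_000],
            "id": ["a", "b", "far"], "ref": ["A"] * 3, "alt": ["G"] * 3,
            "maf": [0.3] * 3,
        })
        g1 = rng.binomial(2, 0.3, n).astype(float)
        g3 = rng.binomial(2, 0.3, n).astype(float)
        D = np.stack([g1, g1, g3])
        ed = pd.DataFrame({"snp": ["a", "far"]})
        other = pd.DataFrame({"snp": ["b"]})
        out = edqtl.type_specific_filter(ed, other, variants, D).set_index("snp")
        assert not out.loc["a", "type_specific"]
        assert out.loc["far", "type_specific"]


class TestPositionalDensity:
    def test_snps_at_anchor_centers(self):
        anchors = pd.DataFrame({"chrom": ["c"] * 3, "pos0": [5000, 9000, 20_000]})
        qtl = pd.DataFrame({"chrom": ["c"] * 3, "pos0": [5000, 9000, 20_000]})
        dens = edqtl.positional_density(qtl, anchors)
        # 2 kb window / 40 bins -> 50 bp bins; anchors sit in bin 20
        assert len(dens) == 40
        assert np.nansum(dens[20]) > 0
        mass = np.nansum(dens)
        assert dens[20] == pytest.approx(mass)

    def test_uniform_snps_flat(self, rng):
        anchors = pd.DataFrame({"chrom": ["c"], "pos0": [50_000]})
        pos = rng.integers(49_000, 51_000, 4000)
        qtl = pd.DataFrame({"chrom": ["c"] * len(pos), "pos0": pos})
        dens = edqtl.positional_density(qtl, anchors)
        counts = dens * 50  # uniform coverage: density * width = counts
        chi2 = ((counts - counts.mean()) ** 2 / counts.mean()).sum()
        assert stats.chi2.sf(chi2, len(counts) - 1) > 0.01


class TestTissueSharing:
    def _table(self, slopes, sig=True):
        return pd.DataFrame({
            "site": [f"x{i}" for i in range(len(slopes))],
            "snp": [f"s{i}" for i in range(len(slopes))],
            "slope": slopes, "significant": sig,
        })

    def test_identical_tables_rho_one(self, rng):
        slopes = rng.normal(0, 1, 30)
        ts = edqtl.tissue_sharing({"t1": self._table(slopes), "t2": self._table(slopes)})
        assert ts.loc["t1", "t2"] == pytest.approx(1.0)
        assert ts.loc["t1", "t1"] == 1.0

    def test_sign_flip_rho_minus_one(self, rng):
        slopes = rng.normal(0, 1, 30)
        ts = edqtl.tissue_sharing({"t1": self._table(slopes), "t2": self._table(-slopes)})
        assert ts.loc["t1", "t2"] == pytest.approx(-1.0)

    def test_shared_effect_model_high_rho(self, rng):
        base = rng.normal(0, 1, 100)
        tabs = {}
        for t in range(3):
            # ~90% of effects shared pairwise: each tissue resamples 5%
            eff = np.where(rng.random(100) < 0.95, base, rng.normal(0, 1, 100)) \
                + rng.normal(0, 0.1, 100)
            tabs[f"t{t}"] = self._table(eff)
        ts = edqtl.tissue_sharing(tabs)
        off = [ts.iloc[i, j] for i in range(3) for j in range(3) if i != j]
        assert np.mean(off) > 0.75
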