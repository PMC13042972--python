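"""GWAS integration: LD scores, matched-control enrichment, clumping vs a
brute-force oracle, ABF colocalization and REML heritability."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from editome_kit import traitint


def _variants(n, chrom="c", spacing=1000):
    return pd.DataFrame({
        "chrom": [chrom] * n, "pos0": np.arange(n) * spacing,
        "id": [f"s{i}" for i in range(n)], "ref": ["A"] * n,
        "alt": ["G"] * n, "maf": np.full(n, 0.3),
    })


class TestLDScore:
    def test_isolated_snp_scores_one(self, rng):
        v = _variants(2)
        v.loc[1, "pos0"] = 5_000_000  # out of window
        D = rng.binomial(2, 0.3, size=(2, 500)).astype(float)
        s = traitint.ld_scores(v, D)
        assert s[0] == pytest.approx(1.0, abs=0.05)

    def test_duplicated_snp_scores_two(self, rng):
        v = _variants(2)
        g = rng.binomial(2, 0.3, 200).astype(float)
        D = np.stack([g, g])
        s = traitint.ld_scores(v, D)
        assert s[0] == pytest.approx(2.0)

    def test_independent_panel_bias_term(self, rng):
        m, n = 40, 400
        v = _variants(m, spacing=10)
        D = rng.binomial(2, 0.3, size=(m, n)).astype(float)
        s = traitint.ld_scores(v, D)
        expected = 1 + (m - 1) / n  # E[sample r^2] ~ 1/n under independence
        assert abs(np.nanmean(s) - expected) < 0.05


class TestMatchedControls:
    def _pool(self, rng, n=200):
        return pd.DataFrame({
            "snp": [f"s{i}" for i in range(n)], "chrom": "c",
            "maf": rng.uniform(0.05, 0.5, n),
            "ldscore": rng.uniform(1, 5, n),
        })

    def test_pool_equals_focal_all_matched(self, rng):
        pool = self._pool(rng)
        # duplicate each focal so a distinct-but-identical control exists
        twin = pool.copy()
        twin["snp"] = twin.snp + "_twin"
        both = pd.concat([pool, twin], ignore_index=True)
        mc = traitint.match_controls(list(pool.snp[:50]), both, seed=1)
        assert len(mc.unmatched) == 0
        assert (np.abs(mc.mapping.d_maf) <= 0.02).all()

    def test_no_tolerance_match_flagged(self, rng):
        pool = self._pool(rng, 5)
        pool.loc[0, "maf"] = 0.05
        pool.loc[1:, "maf"] = 0.5
        mc = traitint.match_controls(["s0"], pool, seed=1)
        assert mc.unmatched == ["s0"]

    def test_seeded_repeatability(self, rng):
        pool = self._pool(rng)
        a = traitint.match_controls(list(pool.snp[:30]), pool, seed=9)
        b = traitint.match_controls(list(pool.snp[:30]), pool, seed=9)
        pd.testing.assert_frame_equal(a.mapping, b.mapping)

    def test_empty_pool_errors(self):
        with pytest.raises(ValueError):
            traitint.match_controls(["s0"], pd.DataFrame(columns=["snp", "chrom", "maf", "ldscore"]))


class TestZ2Enrichment:
    def _setup(self, rng, focal_scale=1.0, n=600):
        pool = pd.DataFrame({
            "snp": [f"s{i}" for i in range(n)], "chrom": "c",
            "maf": rng.uniform(0.1, 0.4, n), "ldscore": rng.uniform(1, 2, n),
        })
        z = rng.normal(0, 1, n)
        focal = [f"s{i}" for i in range(100)]
        z[:100] = rng.normal(0, focal_scale, 100)
        gwas = pd.DataFrame({"snp": pool.snp, "z": z})
        return focal, gwas, pool

    def test_inflated_focal_detected(self, rng):
        focal, gwas, pool = self._setup(rng, focal_scale=1.5)
        res = traitint.z2_enrichment(focal, gwas, pool, n_perm=300, seed=2)
        assert res["ratio"] > 1.5
        assert res["empirical_p"] < 0.05
        assert res["wilcoxon_p"] < 0.05

    def test_null_ratio_near_one(self, rng):
        focal, gwas, pool = self._setup(rng, focal_scale=1.0)
        res = traitint.z2_enrichment(focal, gwas, pool, n_perm=300, seed=3)
        assert 0.6 < res["ratio"] < 1.6
        assert res["empirical_p"] > 0.05


class TestClump:
    def _brute_force(self, df, variants, D, r2, kb):
        # independent re-implementation of greedy clumping
        meta = variants.set_index("id")
        rows = {s: i for i, s in enumerate(variants.id)}
        work = df.copy()
        work["pos0"] = meta.pos0.reindex(work.snp).to_numpy()
        work["chrom"] = meta.chrom.reindex(work.snp).to_numpy()
        work["alt"] = meta.alt.reindex(work.snp).to_numpy()
        work = work.sort_values(["p", "pos0", "alt"], kind="stable")
        taken, leads = set(), []
        for r in work.itertuples(index=False):
            if r.snp in taken:
                continue
            leads.append(r.snp)
            taken.add(r.snp)
            for o in work.itertuples(index=False):
                if o.snp in taken or o.chrom != r.chrom:
                    continue
                if abs(o.pos0 - r.pos0) > kb * 1000:
                    continue
                g1, g2 = D[rows[r.snp]], D[rows[o.snp]]
                if g1.std() and g2.std() and np.corrcoef(g1, g2)[0, 1] ** 2 >= r2:
                    taken.add(o.snp)
        return leads

    def test_two_linked_nearby_snps_one_clump(self, rng):
        v = _variants(2, spacing=10_000)
        g = rng.binomial(2, 0.3, 200).astype(float)
        D = np.stack([g, g])
        snps = pd.DataFrame({"snp": ["s0", "s1"], "p": [1e-8, 1e-4]})
        out = traitint.clump(snps, v, D)
        assert list(out.snp) == ["s0"]

    def test_distant_snps_two_clumps(self, rng):
        v = _variants(2, spacing=300_000)
        g = rng.binomial(2, 0.3, 200).astype(float)
        D = np.stack([g, g])
        snps = pd.DataFrame({"snp": ["s0", "s1"], "p": [1e-8, 1e-4]})
        out = traitint.clump(snps, v, D)
        assert len(out) == 2

    def test_matches_brute_force_oracle(self, rng):
        for seed in range(5):
            local = np.random.default_rng(seed)
            m = 40
            v = _variants(m, spacing=int(local.integers(5_000, 100_000)))
            blocks = local.integers(0, 8, m)
            anchors = local.binomial(2, 0.3, size=(8, 300)).astype(float)
            D = anchors[blocks] + local.binomial(1, 0.05, size=(m, 300))
            snps = pd.DataFrame({"snp": v.id, "p": local.uniform(0, 1, m)})
            ours = list(traitint.clump(snps, v, D).snp)
            oracle = self._brute_force(snps, v, D, 0.4, 250)
            assert ours == oracle


class TestColoc:
    def _frames(self, rng, m=201, se=0.1):
        snp = [f"s{i}" for i in range(m)]
        qtl = pd.DataFrame({"snp": snp, "z": rng.normal(0, 1, m), "se": se})
        gwas = pd.DataFrame({"snp": snp, "z": rng.normal(0, 1, m), "se": se})
        return qtl, gwas

    def test_flat_signals_pp0(self, rng):
        qtl, gwas = self._frames(rng)
        qtl["z"] = rng.uniform(-0.5, 0.5, len(qtl))
        gwas["z"] = rng.uniform(-0.5, 0.5, len(gwas))
        res = traitint.coloc_abf(qtl, gwas, enforce_region_p=False)
        assert res["PP0"] > 0.9

    def test_shared_causal_pp4(self, rng):
        qtl, gwas = self._frames(rng)
        qtl.loc[0, "z"] = 8.0
        gwas.loc[0, "z"] = 8.0
        res = traitint.coloc_abf(qtl, gwas)
        assert res["eligible"]
        assert res["PP4"] > 0.9
        total = sum(res[f"PP{i}"] for i in range(5))
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_distinct_causals_pp3(self, rng):
        qtl, gwas = self._frames(rng)
        qtl.loc[0, "z"] = 8.0
        gwas.loc[10, "z"] = 8.0
        res = traitint.coloc_abf(qtl, gwas)
        assert res["PP3"] == max(res[f"PP{i}"] for i in range(5))

    def test_region_p_gate(self, rng):
        qtl, gwas = self._frames(rng)
        gwas["z"] = rng.uniform(-1, 1, len(gwas))
        res = traitint.coloc_abf(qtl, gwas)
        assert not res["eligible"]

    def test_pp4_monotone_in_shared_z(self, rng):
        pps = []
        for zz in (4.0, 6.0, 8.0):
            qtl, gwas = self._frames(rng)
            qtl.loc[0, "z"] = zz
            gwas.loc[0, "z"] = zz
            pps.append(traitint.coloc_abf(qtl, gwas, enforce_region_p=False)["PP4"])
        assert pps[0] < pps[1] < pps[2]

    def test_no_shared_snps_errors(self):
        qtl = pd.DataFrame({"snp": ["a"], "z": [1.0], "se": [0.1]})
        gwas = pd.DataFrame({"snp": ["b"], "z": [1.0], "se": [0.1]})
        with pytest.raises(ValueError):
            traitint.coloc_abf(qtl, gwas)


class TestREML:
    def _simulate(self, rng, n=400, m=150, h2=0.5):
        G = rng.binomial(2, rng.uniform(0.1, 0.5, m)[:, None], size=(m, n)).astype(float)
        K = traitint._grm(G)
        L = np.linalg.cholesky(K + 1e-8 * np.eye(n))
        g = L @ rng.normal(0, 1, n)
        g = g / g.std() * np.sqrt(h2)
        y = g + rng.normal(0, np.sqrt(1 - h2), n)
        return y, K

    def test_single_component_recovery(self, rng):
        errs = []
        for _ in range(5):
            y, K = self._simulate(rng)
            res = traitint.reml_h2(y, [K])
            errs.append(abs(res["h2_total"] - 0.5))
        assert np.median(errs) < 0.1

    def test_null_heritability_small(self, rng):
        ests = []
        for _ in range(5):
            y, K = self._simulate(rng, h2=0.0)
            ests.append(traitint.reml_h2(y, [K])["h2_total"])
        assert np.median(ests) <= 0.1

    def test_two_category_enrichment(self, rng):
        n, m = 400, 200
        G = rng.binomial(2, rng.uniform(0.1, 0.5, m)[:, None], size=(m, n)).astype(float)
        Z = (G - G.mean(axis=1, keepdims=True))
        Z = Z / Z.std(axis=1, keepdims=True)
        # category 0 (first 50 SNPs) carries 3x per-SNP heritability share
        b = np.concatenate([rng.normal(0, np.sqrt(3.0), 50), rng.normal(0, 1.0, 150)])
        g = Z.T @ b
        g = g / g.std() * np.sqrt(0.6)
        y = g + rng.normal(0, np.sqrt(0.4), n)
        K1 = traitint._grm(G[:50])
        K2 = traitint._grm(G[50:])
        res = traitint.reml_h2(y, [K1, K2], m_snps=[50, 150])
        assert res["enrichment"][0] > 1.3
        assert res["enrichment"][0] / res["enrichment"][1] > 1.5


class TestHypergeom:
    def test_closed_form_example(self):
        # overlap 4 of query 4 against a 5-gene set in a 10-gene background:
        # C(5,4)*C(5,0)/C(10,4) = 5/210
        bg = set(range(10))
        gs = set(range(5))
        q = {0, 1, 2, 3}
        assert traitint.hypergeom_enrichment(q, gs, bg) == pytest.approx(5 / 210)

    def test_zero_overlap_p_one(self):
        bg = set(range(10))
        assert traitint.hypergeom_enrichment({5, 6}, {0, 1}, bg) == pytest.approx(1.0)

    def test_query_equals_background(self):
        bg = set(range(6))
        assert traitint.hypergeom_enrichment(bg, bg, bg) == pytest.approx(1.0)

    def test_query_outside_background_errors(self):
        with pytest.raises(ValueError):
            traitint.hypergeom_enrichment({99}, {1}, {1, 2})
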