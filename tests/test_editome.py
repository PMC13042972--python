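"""Level arithmetic, entropy, annotation and module detection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from editome_kit import editome


class TestLevels:
    def test_editing_level_examples(self):
        assert editome.editing_level(0, 10) == 0.0
        assert editome.editing_level(10, 10) == 1.0
        assert editome.editing_level(3, 12) == pytest.approx(0.25)

    def test_zero_coverage_errors(self):
        with pytest.raises(ValueError):
            editome.editing_level(0, 0)

    def test_overall_level_is_ratio_of_totals(self):
        assert editome.sample_overall_level([2, 8], [10, 10]) == pytest.approx(0.5)
        assert editome.sample_overall_level([3], [12]) == pytest.approx(0.25)
        assert editome.sample_overall_level([0, 0], [5, 9]) == 0.0

    def test_overall_level_no_coverage_errors(self):
        with pytest.raises(ValueError):
            editome.sample_overall_level([0], [0])

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_overall_level_order_invariant_and_not_mean_of_ratios(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 30))
        cov = rng.integers(1, 100, n)
        ed = rng.binomial(cov, rng.uniform(0, 1, n))
        v = editome.sample_overall_level(ed, cov)
        perm = rng.permutation(n)
        assert v == pytest.approx(editome.sample_overall_level(ed[perm], cov[perm]))
        assert v == pytest.approx(ed.sum() / cov.sum())


class TestEntropy:
    def test_single_support_zero_bits(self):
        assert editome.shannon_entropy([0.4, 0, 0, 0]) == pytest.approx(0.0)

    def test_uniform_two_bits(self):
        assert editome.shannon_entropy([0.25] * 4) == pytest.approx(2.0)

    def test_closed_form_example(self):
        # normalized (0.5, 0.3, 0.1, 0.1): -sum p log2 p = 1.6855
        assert editome.shannon_entropy([0.5, 0.3, 0.1, 0.1]) == pytest.approx(1.6855, abs=5e-5)

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=50, deadline=None)
    def test_matches_direct_oracle(self, seed):
        rng = np.random.default_rng(seed)
        v = rng.uniform(0, 1, int(rng.integers(2, 12)))
        p = v / v.sum()
        oracle = -sum(x * np.log2(x) for x in p if x > 0)
        assert abs(editome.shannon_entropy(v) - oracle) < 1e-12


class TestSpecificity:
    def _profile(self, rows, tissues=("t1", "t2", "t3", "t4")):
        return pd.DataFrame(rows, columns=tissues)

    def test_concentrated_profile_specific(self):
        prof = self._profile([[0.4, 0.0, 0.0, 0.0]], )
        prof.index = ["s1"]
        n = pd.DataFrame([[40, 40, 40, 40]], index=["s1"], columns=prof.columns)
        out = editome.tissue_specificity(prof, n, min_samples=30)
        assert out.is_specific.iloc[0]
        assert out.entropy.iloc[0] == pytest.approx(0.0)
        assert out.top_tissue.iloc[0] == "t1"

    def test_uniform_profile_not_specific(self):
        prof = self._profile([[0.25, 0.25, 0.25, 0.25]])
        prof.index = ["s1"]
        n = pd.DataFrame([[40] * 4], index=["s1"], columns=prof.columns)
        out = editome.tissue_specificity(prof, n, min_samples=30)
        assert not out.is_specific.iloc[0]
        assert out.entropy.iloc[0] == pytest.approx(2.0)

    def test_all_zero_profile_undefined_entropy(self):
        prof = self._profile([[0.0, 0.0, 0.0, 0.0]])
        prof.index = ["s1"]
        n = pd.DataFrame([[40] * 4], index=["s1"], columns=prof.columns)
        out = editome.tissue_specificity(prof, n, min_samples=30)
        assert np.isnan(out.entropy.iloc[0])
        assert not out.is_specific.iloc[0]

    def test_eligibility_excludes_thin_sites(self):
        prof = self._profile([[0.4, 0, 0, 0]])
        prof.index = ["s1"]
        n = pd.DataFrame([[5] * 4], index=["s1"], columns=prof.columns)
        out = editome.tissue_specificity(prof, n, min_samples=30)
        assert len(out) == 0


class TestAnnotation:
    def _toy_gene(self, strand="+"):
        # chrom layout: exon1 [100,200) with CDS [150,200), intron, exon2
        # [300,400) all CDS, intron, exon3 [500,600) CDS [500,549)+stop
        rows = [
            ("c", "gene", 100, 600, strand, ".", "g1", "g1.1"),
            ("c", "transcript", 100, 600, strand, ".", "g1", "g1.1"),
            ("c", "exon", 100, 200, strand, ".", "g1", "g1.1"),
            ("c", "exon", 300, 400, strand, ".", "g1", "g1.1"),
            ("c", "exon", 500, 600, strand, ".", "g1", "g1.1"),
            ("c", "CDS", 150, 200, strand, 0, "g1", "g1.1"),
            ("c", "CDS", 300, 400, strand, 0, "g1", "g1.1"),
            ("c", "CDS", 500, 549, strand, 0, "g1", "g1.1"),
            ("c", "five_prime_utr", 100, 150, strand, ".", "g1", "g1.1"),
            ("c", "three_prime_utr", 549, 600, strand, ".", "g1", "g1.1"),
        ]
        return pd.DataFrame(rows, columns=[
            "chrom", "feature", "start", "end", "strand", "frame",
            "gene_id", "transcript_id"])

    repeats = pd.DataFrame(columns=["chrom", "start", "end"])

    def test_intronic(self):
        genes = self._toy_gene()
        seq = {"c": "A" * 700}
        out = editome.annotate_site("c", 250, "A", "G", genes, self.repeats, seq)
        assert out["region"] == "intronic"

    def test_exonic_precedence_over_intron(self):
        # second transcript with an intron over the same position
        genes = pd.concat([self._toy_gene(), pd.DataFrame([
            ("c", "gene", 100, 600, "+", ".", "g2", "g2.1"),
            ("c", "exon", 100, 120, "+", ".", "g2", "g2.1"),
            ("c", "exon", 580, 600, "+", ".", "g2", "g2.1"),
        ], columns=self._toy_gene().columns)], ignore_index=True)
        seq = {"c": "A" * 700}
        out = editome.annotate_site("c", 160, "A", "G", genes, self.repeats, seq)
        assert out["region"] == "exonic"

    def test_nonsynonymous_codon_change(self):
        # CDS starts at 150 with AAA...; editing the middle A of the first
        # codon gives AGA: K -> R, nonsynonymous
        seq = {"c": "C" * 150 + "AAA" + "C" * 547}
        genes = self._toy_gene()
        out = editome.annotate_site("c", 151, "A", "G", genes, self.repeats, seq)
        assert out["region"] == "exonic"
        assert out["consequence"] == "nonsynonymous"

    def test_synonymous_third_position(self):
        # AAA -> AAG is K -> K
        seq = {"c": "C" * 150 + "AAA" + "C" * 547}
        genes = self._toy_gene()
        out = editome.annotate_site("c", 152, "A", "G", genes, self.repeats, seq)
        assert out["consequence"] == "synonymous"

    def test_utr_and_intergenic(self):
        genes = self._toy_gene()
        seq = {"c": "A" * 700}
        assert editome.annotate_site("c", 120, "A", "G", genes, self.repeats, seq)["region"] == "UTR5"
        assert editome.annotate_site("c", 560, "A", "G", genes, self.repeats, seq)["region"] == "UTR3"
        out = editome.annotate_site("c", 650, "A", "G", genes, self.repeats, seq)
        assert out["region"] in ("downstream", "upstream")


class TestModules:
    def _block_profile(self, rng, n_noise=120, block=40, n_tissues=20, r=0.9):
        rows = []
        labels = []
        for b in range(2):
            f = rng.normal(0, 1, n_tissues)
            for _ in range(block):
                x = np.sqrt(r) * f + np.sqrt(1 - r) * rng.normal(0, 1, n_tissues)
                rows.append(x + 10)   # shift positive, like editing levels
                labels.append(b)
        for _ in range(n_noise):
            rows.append(rng.normal(10, 1, n_tissues))
            labels.append(2)
        prof = pd.DataFrame(rows, index=[f"s{i}" for i in range(len(rows))],
                            columns=[f"t{j}" for j in range(n_tissues)])
        return prof, np.array(labels)

    def test_planted_blocks_recovered(self, rng):
        prof, labels = self._block_profile(rng)
        mods = editome.coedit_modules(prof, cv_min=0.0, missing_site_max=100,
                                      min_tissues=5)
        named = [m for m in mods if m.module_id != "grey"]
        assert len(named) == 2
        # membership recovery >= 90% per block
        for b in range(2):
            truth = set(prof.index[labels == b])
            best = max(named, key=lambda m: len(set(m.members) & truth))
            overlap = len(set(best.members) & truth) / len(truth)
            assert overlap >= 0.9
        # adjusted Rand on non-grey truth labels
        from sklearn.metrics import adjusted_rand_score
        pred = {}
        for m in mods:
            for s in m.members:
                pred[s] = m.module_id
        idx = [i for i, s in enumerate(prof.index) if s in pred]
        ari = adjusted_rand_score(labels[idx], [pred[prof.index[i]] for i in idx])
        assert ari >= 0.8

    def test_independent_sites_all_grey(self, rng):
        prof = pd.DataFrame(rng.normal(0, 1, (60, 20)),
                            index=[f"s{i}" for i in range(60)],
                            columns=[f"t{j}" for j in range(20)])
        mods = editome.coedit_modules(prof, cv_min=0.0, missing_site_max=100,
                                      min_tissues=5)
        assert all(m.module_id == "grey" for m in mods)

    def test_too_few_sites_single_grey(self, rng):
        prof = pd.DataFrame(rng.normal(0, 1, (10, 20)),
                            index=[f"s{i}" for i in range(10)],
                            columns=[f"t{j}" for j in range(20)])
        mods = editome.coedit_modules(prof, cv_min=0.0, missing_site_max=100,
                                      min_tissues=5)
        assert len(mods) == 1 and mods[0].module_id == "grey"

    def test_module_tissue_correlation_for_loading_block(self, rng):
        # block of sites high in tissue 0 only
        n_tissues = 12
        rows = []
        for _ in range(40):
            x = rng.normal(0, 0.05, n_tissues)
            x[0] += 1.0
            rows.append(x)
        for _ in range(60):
            rows.append(rng.normal(0, 1, n_tissues))
        prof = pd.DataFrame(rows, index=[f"s{i}" for i in range(100)],
                            columns=[f"t{j}" for j in range(n_tissues)])
        mods = editome.coedit_modules(prof, cv_min=0.0, missing_site_max=100,
                                      min_tissues=5)
        named = [m for m in mods if m.module_id != "grey"]
        assert named
        m = max(named, key=lambda m: len(m.members))
        assert abs(m.tissue_correlation["t0"]) > 0.8

    def test_hubs_subset_of_members(self, rng):
        prof, _ = self._block_profile(rng, n_noise=40)
        mods = editome.coedit_modules(prof, cv_min=0.0, missing_site_max=100,
                                      min_tissues=5)
        for m in mods:
            assert set(m.hubs) <= set(m.members)


class TestSoftThreshold:
    def test_scale_free_synthetic_high_r2(self, rng):
        # hub-structured profiles: site i loads on factor with weight ~ 1/i
        n_tissues = 30
        f = rng.normal(0, 1, n_tissues)
        rows = []
        for i in range(1, 101):
            w = 1.0 / np.sqrt(i)
            rows.append(w * f + np.sqrt(max(1 - w ** 2, 0.05)) * rng.normal(0, 1, n_tissues))
        prof = pd.DataFrame(rows, columns=[f"t{j}" for j in range(n_tissues)])
        fit = editome.soft_threshold_fit(prof, powers=(4, 6))
        assert fit.scale_free_r2.max() > 0.5

    def test_constant_matrix_missing_not_crash(self):
        prof = pd.DataFrame(np.ones((20, 10)))
        fit = editome.soft_threshold_fit(prof, powers=(1, 4))
        assert fit.scale_free_r2.isna().all()
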