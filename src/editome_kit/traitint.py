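"""Trait integration: GWAS enrichment, clumping, colocalization and
heritability partitioning.

Z^2 enrichment compares squared GWAS z-scores of focal (edQTL) SNPs with
MAF- and LD-score-matched controls from the same chromosome (one-sided
Wilcoxon rank-sum plus a permutation p over re-matched control draws).
Colocalization follows the approximate-Bayes-factor framework: per-SNP
Wakefield log-ABFs combined into posteriors for the five hypotheses
H0 (no signal) .. H4 (one shared causal variant).  Heritability is
partitioned across SNP categories with average-information REML on
category-specific genomic relationship matrices (standardized genotypes,
no MAF weighting), with an EM fallback on non-convergence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

log = logging.getLogger(__name__)


# -------------------------------------------------------------- LD score

def ld_scores(variants: pd.DataFrame, dosages: np.ndarray,
              window: int = 1_000_000) -> np.ndarray:
    """l(i) = 1 + sum of r^2 with neighbors within the window (same chrom).
    Monomorphic SNPs get NaN."""
    n = len(variants)
    out = np.full(n, np.nan)
    chroms = variants.chrom.to_numpy()
    pos = variants.pos0.to_numpy()
    D = dosages - dosages.mean(axis=1, keepdims=True)
    sd = D.std(axis=1)
    for chrom in np.unique(chroms):
        idx = np.flatnonzero(chroms == chrom)
        order = idx[np.argsort(pos[idx])]
        p = pos[order]
        Z = D[order]
        s = sd[order]
        nloc = len(order)
        # full correlation within chromosome (desk-scale panels)
        with np.errstate(invalid="ignore", divide="ignore"):
            C = (Z @ Z.T) / Z.shape[1] / np.outer(s, s)
        r2 = C ** 2
        for i in range(nloc):
            if s[i] == 0:
                continue
            m = (np.abs(p - p[i]) <= window) & (np.arange(nloc) != i) & (s > 0)
            out[order[i]] = 1.0 + float(r2[i, m].sum())
    return out


# -------------------------------------------------------- matched controls

@dataclass
class MatchedControls:
    mapping: pd.DataFrame      # focal, control, d_maf, d_ldscore
    unmatched: list


def match_controls(focal_ids: list, pool: pd.DataFrame,
                   maf_tol: float = 0.02, ld_tol_sd: float = 0.1,
                   seed: int = 0) -> MatchedControls:
    """One same-chromosome control per focal SNP, matched on MAF (+-tol)
    and LD score (+- ld_tol_sd * SD), sampled without replacement where
    possible; unmatched focal SNPs are flagged and excluded."""
    if len(pool) == 0:
        raise ValueError("empty control pool")
    rng = np.random.default_rng(seed)
    ld_sd = float(np.nanstd(pool.ldscore))
    tol_ld = ld_tol_sd * ld_sd
    pool_idx = pool.set_index("snp")
    used = set()
    rows, unmatched = [], []
    for f in focal_ids:
        if f not in pool_idx.index:
            unmatched.append(f)
            continue
        frow = pool_idx.loc[f]
        cand = pool[
            (pool.chrom == frow.chrom)
            & (pool.snp != f)
            & (np.abs(pool.maf - frow.maf) <= maf_tol)
            & (np.abs(pool.ldscore - frow.ldscore) <= tol_ld)
        ]
        fresh = cand[~cand.snp.isin(used)]
        pick_from = fresh if len(fresh) else cand
        if len(pick_from) == 0:
            unmatched.append(f)
            continue
        pick = pick_from.iloc[int(rng.integers(len(pick_from)))]
        used.add(pick.snp)
        rows.append({
            "focal": f, "control": pick.snp,
            "d_maf": float(pick.maf - frow.maf),
            "d_ldscore": float(pick.ldscore - frow.ldscore),
        })
    if unmatched:
        log.info("%d focal SNPs had no matched control", len(unmatched))
    return MatchedControls(pd.DataFrame(rows, columns=["focal", "control", "d_maf", "d_ldscore"]),
                           unmatched)


def z2_enrichment(focal_ids: list, gwas: pd.DataFrame, pool: pd.DataFrame,
                  n_perm: int = 1000, seed: int = 0,
                  maf_tol: float = 0.02, ld_tol_sd: float = 0.1) -> dict:
    """Ratio of mean Z^2 (focal / matched controls), one-sided Wilcoxon
    rank-sum, and an empirical p over re-matched control draws."""
    z2 = gwas.set_index("snp").z ** 2
    rng = np.random.default_rng(seed)
    mc = match_controls(focal_ids, pool, maf_tol, ld_tol_sd, seed=int(rng.integers(2 ** 31)))
    matched = mc.mapping
    if len(matched) < 10:
        log.warning("only %d matched pairs: enrichment underpowered", len(matched))
    focal_z2 = z2.reindex(matched.focal).to_numpy()
    ctrl_z2 = z2.reindex(matched.control).to_numpy()
    ok = np.isfinite(focal_z2) & np.isfinite(ctrl_z2)
    focal_z2, ctrl_z2 = focal_z2[ok], ctrl_z2[ok]
    ratio = float(focal_z2.mean() / ctrl_z2.mean()) if len(ctrl_z2) else np.nan
    if len(focal_z2) and len(ctrl_z2):
        wilcox_p = float(stats.mannwhitneyu(focal_z2, ctrl_z2, alternative="greater").pvalue)
    else:
        wilcox_p = np.nan
    # permutation null: per focal SNP, precompute its matched-candidate set
    # once, then draw one control per focal per permutation
    pool_idx = pool.set_index("snp")
    ld_sd = float(np.nanstd(pool.ldscore))
    cand_z2 = []
    for f in matched.focal:
        frow = pool_idx.loc[f]
        cand = pool[
            (pool.chrom == frow.chrom) & (pool.snp != f)
            & (np.abs(pool.maf - frow.maf) <= maf_tol)
            & (np.abs(pool.ldscore - frow.ldscore) <= ld_tol_sd * ld_sd)
        ]
        cz = z2.reindex(cand.snp).to_numpy()
        cand_z2.append(cz[np.isfinite(cz)])
    # each draw's mean Z^2 is one realization of the matched background;
    # the focal mean is enriched when it beats these draws
    null_means = np.empty(n_perm)
    for b in range(n_perm):
        draw = np.array([c[rng.integers(len(c))] for c in cand_z2 if len(c)])
        null_means[b] = draw.mean() if len(draw) else np.nan
    valid = np.isfinite(null_means)
    emp_p = float((1 + np.sum(null_means[valid] >= focal_z2.mean())) / (valid.sum() + 1)) \
        if valid.any() and len(focal_z2) else np.nan
    return {
        "ratio": ratio, "wilcoxon_p": wilcox_p, "empirical_p": emp_p,
        "n_pairs": int(len(focal_z2)), "underpowered": len(matched) < 10,
    }


# ---------------------------------------------------------------- clump

def clump(snps: pd.DataFrame, variants: pd.DataFrame, dosages: np.ndarray,
          r2: float = 0.4, kb: float = 250.0) -> pd.DataFrame:
    """Greedy p-value clumping: best remaining SNP claims all SNPs within
    ``kb`` kilobases at r^2 >= threshold.  Ties break by position, then
    allele order."""
    if len(snps) == 0:
        return snps.copy()
    meta = variants.set_index("id")
    df = snps.copy()
    df["pos0"] = meta.pos0.reindex(df.snp).to_numpy()
    df["chrom"] = meta.chrom.reindex(df.snp).to_numpy()
    df["alt"] = meta.alt.reindex(df.snp).to_numpy()
    row = {sid: i for i, sid in enumerate(variants.id)}
    df = df.sort_values(["p", "pos0", "alt"], kind="stable").reset_index(drop=True)
    alive = np.ones(len(df), dtype=bool)
    leads = []
    for i in range(len(df)):
        if not alive[i]:
            continue
        lead = df.iloc[i]
        leads.append(lead)
        alive[i] = False
        for j in np.flatnonzero(alive):
            other = df.iloc[j]
            if other.chrom != lead.chrom or abs(other.pos0 - lead.pos0) > kb * 1000:
                continue
            g1, g2 = dosages[row[lead.snp]], dosages[row[other.snp]]
            if g1.std() == 0 or g2.std() == 0:
                continue
            if np.corrcoef(g1, g2)[0, 1] ** 2 >= r2:
                alive[j] = False
    return pd.DataFrame(leads).reset_index(drop=True)


# ----------------------------------------------------------------- coloc

@dataclass
class ColocPriors:
    p1: float = 1e-4
    p2: float = 1e-4
    p12: float = 1e-5
    W_qtl: float = 0.15 ** 2
    W_gwas: float = 0.15 ** 2


def wakefield_labf(z: np.ndarray, se: np.ndarray, W: float) -> np.ndarray:
    """log approximate Bayes factor: 0.5 [log(1 - r) + r z^2], r = W/(W+se^2)."""
    se = np.asarray(se, dtype=float)
    z = np.asarray(z, dtype=float)
    if np.any(se <= 0):
        raise ValueError("non-positive standard error")
    r = W / (W + se ** 2)
    return 0.5 * (np.log(1 - r) + r * z ** 2)


def coloc_abf(qtl: pd.DataFrame, gwas: pd.DataFrame,
              priors: ColocPriors | None = None,
              gwas_p_min: float = 1e-5, enforce_region_p: bool = True) -> dict:
    """Posterior probabilities PP0..PP4 for one region.

    Inputs are summary frames with snp/z/se joined on shared SNPs; the
    region is eligible only if the minimum GWAS p is below ``gwas_p_min``.
    """
    priors = priors or ColocPriors()
    merged = qtl.merge(gwas, on="snp", suffixes=("_qtl", "_gwas"))
    if len(merged) == 0:
        raise ValueError("no shared SNPs between QTL and GWAS summaries")
    merged = merged[(merged.se_qtl > 0) & (merged.se_gwas > 0)]
    gwas_min_p = float(2 * stats.norm.sf(np.abs(merged.z_gwas)).min())
    eligible = gwas_min_p < gwas_p_min
    if enforce_region_p and not eligible:
        return {"eligible": False, "gwas_min_p": gwas_min_p, "n_snps": len(merged)}

    l1 = wakefield_labf(merged.z_qtl.to_numpy(), merged.se_qtl.to_numpy(), priors.W_qtl)
    l2 = wakefield_labf(merged.z_gwas.to_numpy(), merged.se_gwas.to_numpy(), priors.W_gwas)
    lsum = l1 + l2
    lH0 = 0.0
    lH1 = np.log(priors.p1) + logsumexp(l1)
    lH2 = np.log(priors.p2) + logsumexp(l2)
    # H3: different causal SNPs = sum over pairs i != j
    s1, s2, s12 = logsumexp(l1), logsumexp(l2), logsumexp(lsum)
    # sum over i != j of BF1_i BF2_j, via log(exp(s1+s2) - exp(s12))
    lH3 = np.log(priors.p1) + np.log(priors.p2) + _log_diff(s1 + s2, s12)
    lH4 = np.log(priors.p12) + s12
    ls = np.array([lH0, lH1, lH2, lH3, lH4])
    pp = np.exp(ls - logsumexp(ls))
    lead_qtl = merged.snp.iloc[int(np.argmax(l1))]
    lead_gwas = merged.snp.iloc[int(np.argmax(l2))]
    return {
        "eligible": True, "gwas_min_p": gwas_min_p, "n_snps": int(len(merged)),
        "PP0": pp[0], "PP1": pp[1], "PP2": pp[2], "PP3": pp[3], "PP4": pp[4],
        "lead_qtl_snp": lead_qtl, "lead_gwas_snp": lead_gwas,
    }


def _log_diff(a: float, b: float) -> float:
    """log(exp(a) - exp(b)) for a > b, stable."""
    if b >= a:
        return -np.inf
    return a + np.log1p(-np.exp(b - a))


# ------------------------------------------------------------------ REML

def _grm(G: np.ndarray) -> np.ndarray:
    """Genomic relationship matrix from an (m, n) dosage block:
    standardize per SNP, K = Z'Z / m (no MAF-dependent weighting)."""
    Z = G - G.mean(axis=1, keepdims=True)
    sd = Z.std(axis=1)
    keep = sd > 0
    Z = Z[keep] / sd[keep][:, None]
    return (Z.T @ Z) / keep.sum()


def reml_h2(y: np.ndarray, grms: list[np.ndarray], m_snps: list[int] | None = None,
            max_iter: int = 100, tol: float = 1e-6) -> dict:
    """Average-information REML for variance components over K GRMs.

    Returns per-component variances, total h2, per-category h2 shares and
    enrichment (h2 share / SNP share) when SNP counts are given.  Falls
    back to EM steps when the AI update proposes an invalid state; a
    ``converged`` flag reports the outcome.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    X = np.ones((n, 1))
    Ks = [np.asarray(K) for K in grms] + [np.eye(n)]
    k = len(Ks)
    vy = float(y.var())
    theta = np.full(k, vy / k)
    floor = 1e-6 * vy
    converged = False
    for it in range(max_iter):
        V = sum(t * K for t, K in zip(theta, Ks))
        try:
            Vinv = np.linalg.inv(V)
        except np.linalg.LinAlgError:
            break
        XtVX = X.T @ Vinv @ X
        P = Vinv - Vinv @ X @ np.linalg.solve(XtVX, X.T @ Vinv)
        Py = P @ y
        KPy = [K @ Py for K in Ks]
        # trace(P K) = sum(P * K) for symmetric K
        trPK = [float((P * K).sum()) for K in Ks]
        score = np.array([
            -0.5 * (tr - Py @ KPy_i) for tr, KPy_i in zip(trPK, KPy)
        ])
        PKPy = [P @ v for v in KPy]
        AI = 0.5 * np.array([[KPy[i] @ PKPy[j] for j in range(k)] for i in range(k)])
        try:
            delta = np.linalg.solve(AI, score)
        except np.linalg.LinAlgError:
            delta = None
        new = theta + delta if delta is not None else None
        if new is None or np.any(~np.isfinite(new)) or np.any(new < -vy):
            # EM fallback step
            new = np.array([
                t + (t ** 2) * float(Py @ KPy_i - tr) / n
                for t, tr, KPy_i in zip(theta, trPK, KPy)
            ])
        new = np.maximum(new, floor)
        if np.max(np.abs(new - theta)) < tol * max(vy, 1e-12):
            theta = new
            converged = True
            break
        theta = new
    if not converged:
        log.warning("REML did not converge in %d iterations; EM estimate returned", max_iter)
    total = float(theta.sum())
    h2 = {f"component_{i}": float(t / total) for i, t in enumerate(theta[:-1])}
    out = {
        "variances": theta,
        "h2_total": float(theta[:-1].sum() / total),
        "h2_components": np.array([t / total for t in theta[:-1]]),
        "converged": converged,
        **h2,
    }
    if m_snps is not None:
        M = float(sum(m_snps))
        h2g = theta[:-1].sum()
        enr = []
        for t, m in zip(theta[:-1], m_snps):
            share_h2 = t / h2g if h2g > 0 else np.nan
            share_m = m / M
            enr.append(share_h2 / share_m if share_m > 0 else np.nan)
        out["enrichment"] = np.array(enr)
    return out


# ------------------------------------------------------------ gene sets

def hypergeom_enrichment(query: set, gene_set: set, background: set) -> float:
    """Upper-tail hypergeometric P(X >= k) for query/set overlap."""
    if not query <= background:
        raise ValueError("query genes must be a subset of the background")
    N = len(background)
    K = len(gene_set & background)
    nq = len(query)
    k = len(query & gene_set)
    return float(stats.hypergeom.sf(k - 1, N, K, nq))
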