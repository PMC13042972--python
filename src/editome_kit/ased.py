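"""Allele-specific editing (ASED).

For each (editing site, heterozygous SNP) group, individuals contribute a
matched pair of per-allele edited/total read counts.  The test models the
edited counts of allele a in individual i as
BetaBinomial(total_ia, mu_a, phi) with a shared overdispersion phi that
absorbs between-individual variation, and compares H0: mu_ref = mu_alt
against H1 by a 1-df likelihood-ratio test.  The effect is
delta = logit(mu_alt) - logit(mu_ref).  When the ML fit fails, a
coverage-weighted paired t-test on pseudo-count logit levels is used and
flagged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit, gammaln, logit

from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

PHI_MIN = 1e-6
PHI_MAX = 10.0


def pair_alleles(allelic: pd.DataFrame, min_individuals: int = 5) -> pd.DataFrame:
    """Retain het individuals with non-zero total on both alleles and
    (site, snp) groups with enough paired individuals."""
    wide = allelic.pivot_table(
        index=["site", "snp", "individual"], columns="allele",
        values=["edited", "total"], aggfunc="first",
    )
    need = [("edited", "ref"), ("edited", "alt"), ("total", "ref"), ("total", "alt")]
    for c in need:
        if c not in wide.columns:
            return pd.DataFrame(columns=["site", "snp", "individual",
                                         "edited_ref", "total_ref", "edited_alt", "total_alt"])
    wide = wide.dropna(subset=need)
    wide = wide[(wide[("total", "ref")] > 0) & (wide[("total", "alt")] > 0)]
    out = pd.DataFrame({
        "site": wide.index.get_level_values("site"),
        "snp": wide.index.get_level_values("snp"),
        "individual": wide.index.get_level_values("individual"),
        "edited_ref": wide[("edited", "ref")].to_numpy(dtype=int),
        "total_ref": wide[("total", "ref")].to_numpy(dtype=int),
        "edited_alt": wide[("edited", "alt")].to_numpy(dtype=int),
        "total_alt": wide[("total", "alt")].to_numpy(dtype=int),
    }).reset_index(drop=True)
    sizes = out.groupby(["site", "snp"]).individual.transform("nunique")
    dropped = (sizes < min_individuals).sum()
    if dropped:
        log.info("dropped %d rows in groups below %d individuals", dropped, min_individuals)
    return out[sizes >= min_individuals].reset_index(drop=True)


def _bb_loglik(k, n, mu, phi):
    """Beta-binomial log-likelihood with mean mu and overdispersion phi
    (phi -> 0 recovers the binomial).  Written out via gammaln for speed."""
    s = 1.0 / max(phi, PHI_MIN)
    a = mu * s
    b = (1.0 - mu) * s
    ll = (gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
          + gammaln(k + a) + gammaln(n - k + b) - gammaln(n + a + b)
          - gammaln(a) - gammaln(b) + gammaln(a + b))
    return float(ll.sum())


def _fit_bb(k_ref, n_ref, k_alt, n_alt, shared_mu: bool):
    """ML fit; parameters on (logit mu, log phi) scale for stability."""
    p_ref = (k_ref.sum() + 0.5) / (n_ref.sum() + 1.0)
    p_alt = (k_alt.sum() + 0.5) / (n_alt.sum() + 1.0)
    p_all = (k_ref.sum() + k_alt.sum() + 0.5) / (n_ref.sum() + n_alt.sum() + 1.0)

    if shared_mu:
        def nll(theta):
            mu = expit(theta[0])
            phi = np.exp(theta[1])
            if not (PHI_MIN <= phi <= PHI_MAX):
                return 1e12
            return -(_bb_loglik(k_ref, n_ref, mu, phi)
                     + _bb_loglik(k_alt, n_alt, mu, phi))
        x0 = np.array([logit(np.clip(p_all, 1e-4, 1 - 1e-4)), np.log(0.01)])
    else:
        def nll(theta):
            mu_r = expit(theta[0])
            mu_a = expit(theta[1])
            phi = np.exp(theta[2])
            if not (PHI_MIN <= phi <= PHI_MAX):
                return 1e12
            return -(_bb_loglik(k_ref, n_ref, mu_r, phi)
                     + _bb_loglik(k_alt, n_alt, mu_a, phi))
        x0 = np.array([logit(np.clip(p_ref, 1e-4, 1 - 1e-4)),
                       logit(np.clip(p_alt, 1e-4, 1 - 1e-4)), np.log(0.01)])
    res = optimize.minimize(nll, x0, method="Nelder-Mead",
                            options={"maxiter": 600, "xatol": 1e-6, "fatol": 1e-8})
    return res


def _weighted_paired_t(k_ref, n_ref, k_alt, n_alt):
    """Coverage-weighted paired t on pseudo-count logit levels (fallback)."""
    lr = logit((k_ref + 0.5) / (n_ref + 1.0))
    la = logit((k_alt + 0.5) / (n_alt + 1.0))
    d = la - lr
    w = (n_ref + n_alt).astype(float)
    w = w / w.sum()
    m = float((w * d).sum())
    v = float((w * (d - m) ** 2).sum() / (1 - (w ** 2).sum())) if len(d) > 1 else np.nan
    se = np.sqrt(v / len(d)) if np.isfinite(v) else np.nan
    if not np.isfinite(se) or se == 0:
        return m, 1.0
    t = m / se
    return m, float(2 * stats.t.sf(abs(t), df=len(d) - 1))


def paired_ased_test(group: pd.DataFrame) -> dict:
    """Beta-binomial paired LRT for one (site, snp) group.

    ``group`` carries edited_ref/total_ref/edited_alt/total_alt per
    individual.  Returns delta (logit scale), p, per-allele means and a
    flag for the fallback path.
    """
    k_ref = group.edited_ref.to_numpy(dtype=float)
    n_ref = group.total_ref.to_numpy(dtype=float)
    k_alt = group.edited_alt.to_numpy(dtype=float)
    n_alt = group.total_alt.to_numpy(dtype=float)
    mean_ref = float(k_ref.sum() / n_ref.sum())
    mean_alt = float(k_alt.sum() / n_alt.sum())
    base = {
        "n_individuals": int(len(group)),
        "mean_level_ref": mean_ref, "mean_level_alt": mean_alt,
        "direction": "alt>ref" if mean_alt > mean_ref else "ref>alt",
        "fallback": False, "degenerate": False,
    }
    # degenerate: all counts at a boundary on both alleles
    if ((k_ref.sum() == 0 and k_alt.sum() == 0)
            or ((k_ref == n_ref).all() and (k_alt == n_alt).all())):
        return {**base, "delta": 0.0, "p": 1.0, "degenerate": True}
    r1 = _fit_bb(k_ref, n_ref, k_alt, n_alt, shared_mu=False)
    r0 = _fit_bb(k_ref, n_ref, k_alt, n_alt, shared_mu=True)
    if r1.success and r0.success and np.isfinite(r1.fun) and np.isfinite(r0.fun):
        lrt = max(2.0 * (r0.fun - r1.fun), 0.0)
        p = float(stats.chi2.sf(lrt, df=1))
        delta = float(r1.x[1] - r1.x[0])
        return {**base, "delta": delta, "p": p}
    delta, p = _weighted_paired_t(k_ref, n_ref, k_alt, n_alt)
    return {**base, "delta": float(delta), "p": p, "fallback": True}


def run_ased(allelic: pd.DataFrame, min_individuals: int = 5,
             fdr: float = 0.05) -> pd.DataFrame:
    """Pair alleles, test every (site, snp) group, BH-correct at 5%."""
    paired = pair_alleles(allelic, min_individuals)
    rows = []
    for (site, snp), grp in paired.groupby(["site", "snp"]):
        res = paired_ased_test(grp)
        rows.append({"site": site, "snp": snp, **res})
    out = pd.DataFrame(rows)
    if len(out):
        _, q, _, _ = multipletests(out.p.to_numpy(), method="fdr_bh")
        out["q"] = q
        out["significant"] = q < fdr
    return out


def ased_report(results: pd.DataFrame,
                tissue_of_result: pd.Series | None = None) -> dict:
    """Per-allele ratio table for significant pairs plus cross-tissue
    occurrence tallies (by exact (site, snp) identity)."""
    if len(results) == 0:
        return {"table": pd.DataFrame(), "occurrence": pd.DataFrame()}
    sig = results[results.get("significant", False) == True]  # noqa: E712
    table = sig[["site", "snp", "n_individuals",
                 "mean_level_ref", "mean_level_alt", "delta", "p", "q", "direction"]].copy()
    if tissue_of_result is not None and len(sig):
        occ = (sig.assign(tissue=tissue_of_result.reindex(sig.index))
               .groupby(["site", "snp"]).tissue.nunique()
               .rename("n_tissues").reset_index())
        occ["tissue_specific"] = occ.n_tissues == 1
    else:
        occ = pd.DataFrame(columns=["site", "snp", "n_tissues", "tissue_specific"])
    return {"table": table, "occurrence": occ}
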