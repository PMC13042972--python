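"""Cis-edQTL mapping.

Editing levels are logit-transformed (with a (k + 0.5)/(n + 1) pseudo-count
shrink at the boundaries), residualized on significant sample PCs, and
rank-inverse-normal transformed.  Each site is tested against every common
SNP within +-1 Mb by simple linear regression on dosage; the site-level
empirical p-value comes from a phenotype-permutation null of the minimum
nominal p, smoothed by a maximum-likelihood Beta fit.  BH across sites at
FDR < 5% defines significant edSites; forward-backward conditional
selection yields independent signals per site.

PC significance uses a permutation (parallel-analysis style) criterion:
keep leading PCs whose explained variance exceeds the 95th percentile of
the column-permutation null.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logit
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)


# ------------------------------------------------------------ covariates

def select_pcs(level: pd.DataFrame, n_perm: int = 100, alpha: float = 0.05,
               max_pcs: int = 10, seed: int = 0) -> np.ndarray:
    """Sample-space PCs retained by a permutation null on explained variance.

    ``level`` is site x sample; missing levels are imputed to site means.
    Returns a (n_samples, n_selected) matrix (possibly zero columns).
    """
    X = level.to_numpy(dtype=float).T  # samples x sites
    n, m = X.shape
    if n < 3:
        raise ValueError("need at least 3 samples for PC selection")
    col_mean = np.nanmean(X, axis=0)
    col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
    inds = np.where(np.isnan(X))
    X[inds] = np.take(col_mean, inds[1])
    Xc = X - X.mean(axis=0)
    sd = Xc.std(axis=0)
    sd[sd == 0] = 1.0
    Xc = Xc / sd
    u, s, vt = np.linalg.svd(Xc, full_matrices=False)
    ev = s ** 2
    k_max = min(max_pcs, len(ev))

    rng = np.random.default_rng(seed)
    null_ev = np.empty((n_perm, k_max))
    Xp = Xc.copy()
    for b in range(n_perm):
        for j in range(m):
            rng.shuffle(Xp[:, j])
        sv = np.linalg.svd(Xp, compute_uv=False)
        null_ev[b] = sv[:k_max] ** 2
    crit = np.quantile(null_ev, 1 - alpha, axis=0)
    keep = 0
    for k in range(k_max):
        if ev[k] > crit[k]:
            keep += 1
        else:
            break
    return u[:, :keep] * s[:keep]


# ---------------------------------------------------------- transforms

def logit_levels(edited: np.ndarray, coverage: np.ndarray) -> np.ndarray:
    """Pseudo-count logit: logit((k + 0.5) / (n + 1))."""
    edited = np.asarray(edited, dtype=float)
    coverage = np.asarray(coverage, dtype=float)
    return logit((edited + 0.5) / (coverage + 1.0))


def inverse_normal_transform(x: np.ndarray, c: float = 3.0 / 8.0) -> np.ndarray:
    """Rank-based INT with Blom offset; ties get average ranks."""
    x = np.asarray(x, dtype=float)
    ranks = stats.rankdata(x, method="average")
    n = len(x)
    return stats.norm.ppf((ranks - c) / (n - 2 * c + 1))


def transform_levels(levels: np.ndarray, pcs: np.ndarray | None = None,
                     coverage: np.ndarray | None = None,
                     inverse_normal: bool = True) -> np.ndarray:
    """logit -> OLS residual on PCs -> rank inverse-normal.

    ``levels`` may be raw proportions (boundaries shrunk by a pseudo-count
    using ``coverage`` when available, else a fixed epsilon).
    """
    x = np.asarray(levels, dtype=float)
    if np.nanmax(x) - np.nanmin(x) == 0:
        raise ValueError("constant phenotype: untestable site")
    if coverage is not None:
        y = logit_levels(x * np.asarray(coverage), coverage)
    else:
        eps = 1e-3
        y = logit(np.clip(x, eps, 1 - eps))
    if pcs is not None and pcs.size:
        Z = np.column_stack([np.ones(len(y)), pcs])
        beta, *_ = np.linalg.lstsq(Z, y, rcond=None)
        y = y - Z @ beta
    if inverse_normal:
        y = inverse_normal_transform(y)
    return y


# ------------------------------------------------------------- cis scan

@dataclass
class CisWindowGenotypes:
    """Dosage matrix restricted to a site's cis window, MAF-filtered."""

    dosages: np.ndarray      # (n_snps, n_samples)
    snp_ids: np.ndarray
    positions: np.ndarray


def cis_window(variants: pd.DataFrame, dosages: np.ndarray, chrom: str,
               pos0: int, window: int = 1_000_000, maf_min: float = 0.05
               ) -> CisWindowGenotypes:
    m = (variants.chrom.to_numpy() == chrom) \
        & (np.abs(variants.pos0.to_numpy() - pos0) <= window)
    D = dosages[m]
    freqs = D.mean(axis=1) / 2.0
    maf = np.minimum(freqs, 1 - freqs)
    ok = (maf >= maf_min) & (D.std(axis=1) > 0)
    return CisWindowGenotypes(
        dosages=D[ok],
        snp_ids=variants.id.to_numpy()[m][ok],
        positions=variants.pos0.to_numpy()[m][ok],
    )


def cis_scan(phenotype: np.ndarray, genotypes: np.ndarray) -> pd.DataFrame:
    """Per-SNP simple linear regression of phenotype on dosage.

    Returns slope, slope_se, t statistic and two-sided nominal p per SNP.
    """
    y = np.asarray(phenotype, dtype=float)
    G = np.atleast_2d(np.asarray(genotypes, dtype=float))
    n = len(y)
    yc = y - y.mean()
    Gc = G - G.mean(axis=1, keepdims=True)
    ss_g = (Gc ** 2).sum(axis=1)
    ss_y = (yc ** 2).sum()
    with np.errstate(invalid="ignore", divide="ignore"):
        slope = (Gc @ yc) / ss_g
        rss = ss_y - slope ** 2 * ss_g
        se = np.sqrt(np.maximum(rss, 0.0) / (n - 2) / ss_g)
        t = slope / se
    p = 2 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.isnan(t), np.nan, p)
    return pd.DataFrame({"slope": slope, "slope_se": se, "t": t, "nominal_p": p})


def _min_p_null(y: np.ndarray, G: np.ndarray, n_perm: int, rng) -> np.ndarray:
    """Minimum nominal p over SNPs for each phenotype permutation,
    computed through the correlation-to-t identity (vectorized)."""
    n = len(y)
    yc = (y - y.mean())
    ys = yc / np.sqrt((yc ** 2).sum())
    Gc = G - G.mean(axis=1, keepdims=True)
    gn = np.sqrt((Gc ** 2).sum(axis=1))
    gn[gn == 0] = np.inf
    Gs = Gc / gn[:, None]
    perms = np.empty((n_perm, n))
    for b in range(n_perm):
        perms[b] = rng.permutation(ys)
    R = perms @ Gs.T                       # (n_perm, n_snps) correlations
    R = np.clip(R, -0.999999999, 0.999999999)
    t = R * np.sqrt((n - 2) / (1 - R ** 2))
    pmin = 2 * stats.t.sf(np.abs(t).max(axis=1), df=n - 2)
    return pmin


def permutation_pass(phenotype: np.ndarray, genotypes: np.ndarray,
                     n_perm: int = 1000, seed: int = 0) -> dict:
    """Site-level empirical p for the best cis association.

    Fits Beta(a, b) by ML to the permutation null of minimum nominal p;
    the adjusted p is the Beta CDF at the observed minimum.  The direct
    rank-based estimate (1 + #{null <= obs}) / (n_perm + 1) is always
    reported; it is also the fallback when the Beta fit fails.
    """
    if n_perm < 100:
        log.warning("n_perm=%d is small; empirical p will be coarse", n_perm)
    rng = np.random.default_rng(seed)
    scan = cis_scan(phenotype, genotypes)
    i_best = int(np.nanargmin(scan.nominal_p.to_numpy()))
    p_obs = float(scan.nominal_p.iloc[i_best])
    null = _min_p_null(np.asarray(phenotype, float),
                       np.atleast_2d(np.asarray(genotypes, float)),
                       n_perm, rng)
    rank_p = (1.0 + np.sum(null <= p_obs)) / (n_perm + 1.0)
    try:
        eps = 1e-12
        a, b, _, _ = stats.beta.fit(np.clip(null, eps, 1 - eps), floc=0, fscale=1)
        beta_p = float(stats.beta.cdf(p_obs, a, b))
        ok = np.isfinite(beta_p) and 0 <= beta_p <= 1
    except Exception:
        ok = False
        a = b = np.nan
        beta_p = np.nan
    return {
        "lead_index": i_best,
        "nominal_p": p_obs,
        "empirical_p": beta_p if ok else rank_p,
        "rank_p": rank_p,
        "beta_a": a, "beta_b": b, "beta_ok": ok,
        "slope": float(scan.slope.iloc[i_best]),
        "slope_se": float(scan.slope_se.iloc[i_best]),
    }


def fdr_control(empirical_p: np.ndarray, alpha: float = 0.05):
    """BH q-values across sites; significant = q < alpha."""
    p = np.asarray(empirical_p, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q, q < alpha


def map_cis_edqtl(level: pd.DataFrame, coverage: pd.DataFrame,
                  site_coords: pd.DataFrame, variants: pd.DataFrame,
                  dosages: np.ndarray, pcs: np.ndarray | None = None,
                  window: int = 1_000_000, maf_min: float = 0.05,
                  n_perm: int = 1000, seed: int = 0,
                  fdr: float = 0.05) -> pd.DataFrame:
    """Site-level cis scan over a level matrix.

    ``site_coords`` carries site (index-aligned with ``level``), chrom,
    pos0.  Returns one row per testable site with the lead SNP, slope,
    nominal/empirical p, BH q and significance flag.
    """
    rows = []
    rng = np.random.default_rng(seed)
    for i, site in enumerate(level.index):
        chrom = site_coords.chrom.iloc[i]
        pos0 = int(site_coords.pos0.iloc[i])
        lv = level.loc[site].to_numpy(dtype=float)
        cov = coverage.loc[site].to_numpy(dtype=float)
        m = ~np.isnan(lv) & (cov > 0)
        if m.sum() < 10:
            continue
        cw = cis_window(variants, dosages, chrom, pos0, window, maf_min)
        if len(cw.snp_ids) == 0:
            continue
        G = cw.dosages[:, m]
        poly = G.std(axis=1) > 0
        if not poly.any():
            continue
        G = G[poly]
        try:
            y = transform_levels(lv[m], pcs[m] if pcs is not None else None,
                                 coverage=cov[m])
        except ValueError:
            continue
        res = permutation_pass(y, G, n_perm=n_perm, seed=int(rng.integers(2 ** 31)))
        rows.append({
            "site": site, "chrom": chrom, "pos0": pos0,
            "snp": cw.snp_ids[poly][res["lead_index"]],
            "snp_pos0": int(cw.positions[poly][res["lead_index"]]),
            "slope": res["slope"], "slope_se": res["slope_se"],
            "nominal_p": res["nominal_p"], "empirical_p": res["empirical_p"],
            "rank_p": res["rank_p"], "beta_a": res["beta_a"], "beta_b": res["beta_b"],
            "n_samples": int(m.sum()),
        })
    out = pd.DataFrame(rows)
    if len(out):
        q, sig = fdr_control(out.empirical_p.to_numpy(), fdr)
        out["q_value"] = q
        out["significant"] = sig
    return out


# ------------------------------------------------- conditional signals

def conditional_signals(phenotype: np.ndarray, genotypes: np.ndarray,
                        snp_ids: np.ndarray, beta_a: float, beta_b: float,
                        alpha: float = 0.05, max_signals: int = 5) -> pd.DataFrame:
    """Forward-backward stepwise selection of independent cis signals.

    The nominal-p threshold is the Beta-null quantile at ``alpha`` from the
    site's permutation pass; forward steps add the best remaining SNP while
    it clears the threshold conditioning on those selected, and a backward
    sweep drops signals that lose significance.  Collinear SNPs are skipped.
    """
    y = np.asarray(phenotype, dtype=float)
    G = np.atleast_2d(np.asarray(genotypes, dtype=float))
    if np.isfinite(beta_a) and np.isfinite(beta_b) and beta_a > 0:
        p_thresh = float(stats.beta.ppf(alpha, beta_a, beta_b))
    else:
        p_thresh = alpha / max(G.shape[0], 1)   # Bonferroni fallback
    selected: list[int] = []

    def conditional_p(idx_candidates, conditioning):
        if conditioning:
            Z = np.column_stack([np.ones(len(y))] + [G[i] for i in conditioning])
            H, *_ = np.linalg.lstsq(Z, y, rcond=None)
            yr = y - Z @ H
            Gr = G[idx_candidates].T
            B, *_ = np.linalg.lstsq(Z, Gr, rcond=None)
            Gr = (Gr - Z @ B).T
        else:
            yr = y
            Gr = G[idx_candidates]
        keep = Gr.std(axis=1) > 1e-10
        res = cis_scan(yr, Gr)
        # degrees of freedom lost to conditioning: recompute p with proper df
        n = len(y)
        dof = n - 2 - len(conditioning)
        t = res.t.to_numpy()
        p = 2 * stats.t.sf(np.abs(t), df=max(dof, 1))
        p[~keep] = np.nan
        return p

    remaining = list(range(G.shape[0]))
    while len(selected) < max_signals:
        cand = [i for i in remaining if i not in selected]
        if not cand:
            break
        p = conditional_p(cand, selected)
        if np.all(np.isnan(p)):
            break
        j = int(np.nanargmin(p))
        if p[j] >= p_thresh:
            break
        selected.append(cand[j])
        # backward check
        drop = []
        for s in selected[:-1]:
            others = [x for x in selected if x != s]
            ps = conditional_p([s], others)[0]
            if not np.isfinite(ps) or ps >= p_thresh:
                drop.append(s)
        for s in drop:
            selected.remove(s)
            log.info("backward elimination dropped %s", snp_ids[s])

    rows = []
    for rank, s in enumerate(selected, start=1):
        others = [x for x in selected if x != s]
        p = conditional_p([s], others)[0]
        rows.append({"rank": rank, "snp": snp_ids[s], "conditional_p": float(p)})
    return pd.DataFrame(rows, columns=["rank", "snp", "conditional_p"])


# ------------------------------------------------------------------- LD

def ld_r2(a: np.ndarray, b: np.ndarray) -> float:
    """Squared Pearson correlation of dosages; NaN for monomorphic input."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.std() == 0 or b.std() == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1] ** 2)


def type_specific_filter(edqtl_snps: pd.DataFrame, other_snps: pd.DataFrame,
                         variants: pd.DataFrame, dosages: np.ndarray,
                         r2_thresh: float = 0.8, window: int = 1_000_000,
                         other_nominal_p: pd.Series | None = None) -> pd.DataFrame:
    """edQTLs not in LD (max r2 < r2_thresh) with any eQTL/sQTL SNP nearby.

    ``edqtl_snps`` and ``other_snps`` carry snp ids; positions are looked
    up in ``variants``.  When nominal eQTL p-values for the retained SNPs
    are supplied, the fraction with p > 0.05 is reported as a robustness
    attribute on the result frame.
    """
    pos = dict(zip(variants.id, zip(variants.chrom, variants.pos0)))
    row = {sid: i for i, sid in enumerate(variants.id)}
    rows = []
    others = [(s, *pos[s]) for s in other_snps.snp.unique() if s in pos]
    for s in edqtl_snps.snp.unique():
        if s not in pos:
            continue
        chrom, p0 = pos[s]
        max_r2 = 0.0
        for o, oc, op in others:
            if oc != chrom or abs(op - p0) > window:
                continue
            r2 = ld_r2(dosages[row[s]], dosages[row[o]])
            if np.isfinite(r2):
                max_r2 = max(max_r2, r2)
        rows.append({"snp": s, "max_r2": max_r2, "type_specific": max_r2 < r2_thresh})
    out = pd.DataFrame(rows, columns=["snp", "max_r2", "type_specific"])
    if other_nominal_p is not None and len(out):
        retained = out[out.type_specific].snp
        ps = other_nominal_p.reindex(retained).dropna()
        out.attrs["fraction_other_p_gt_05"] = float((ps > 0.05).mean()) if len(ps) else np.nan
    return out


def positional_density(qtl_positions: pd.DataFrame, anchors: pd.DataFrame,
                       flank: int = 1000, bins: int = 40,
                       contig_sizes: dict | None = None) -> np.ndarray:
    """QTL-SNP density around anchors, per half-open bin, normalized per
    anchor by the covered bin width."""
    width = 2 * flank / bins
    counts = np.zeros(bins)
    norm = np.zeros(bins)
    qtl_by_chrom = {c: np.sort(g.pos0.to_numpy()) for c, g in qtl_positions.groupby("chrom")}
    for a in anchors.itertuples(index=False):
        lo = a.pos0 - flank
        edges = lo + width * np.arange(bins + 1)
        cmax = contig_sizes.get(a.chrom) if contig_sizes else None
        covered = np.minimum(edges[1:], cmax if cmax is not None else np.inf) \
            - np.maximum(edges[:-1], 0)
        covered = np.clip(covered, 0, width)
        pos = qtl_by_chrom.get(a.chrom)
        if pos is not None:
            idx = np.clip(((pos - lo) // width).astype(int), -1, bins)
            for b in idx[(idx >= 0) & (idx < bins)]:
                counts[b] += 1
        norm += covered
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(norm > 0, counts / norm, np.nan)


# ------------------------------------------------------- tissue sharing

def tissue_sharing(effect_tables: dict[str, pd.DataFrame],
                   min_shared: int = 10) -> pd.DataFrame:
    """Spearman rho of effects on (site, snp) pairs significant in at
    least one tissue of each pair; diagonal 1, symmetric."""
    tissues = list(effect_tables)
    out = pd.DataFrame(np.eye(len(tissues)), index=tissues, columns=tissues)
    for i, t1 in enumerate(tissues):
        for t2 in tissues[i + 1:]:
            a, b = effect_tables[t1], effect_tables[t2]
            sig = set(map(tuple, a.loc[a.significant, ["site", "snp"]].to_numpy())) \
                | set(map(tuple, b.loc[b.significant, ["site", "snp"]].to_numpy()))
            am = a.set_index(["site", "snp"]).slope
            bm = b.set_index(["site", "snp"]).slope
            shared = [k for k in sig if k in am.index and k in bm.index]
            if len(shared) == 0:
                rho = np.nan
            else:
                rho = stats.spearmanr([am[k] for k in shared], [bm[k] for k in shared]).statistic
                if len(shared) < min_shared:
                    log.info("%s-%s: only %d shared records (low confidence)", t1, t2, len(shared))
            out.loc[t1, t2] = out.loc[t2, t1] = rho
    return out
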