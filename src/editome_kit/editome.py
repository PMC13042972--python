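"""Editome characterization: level matrices, annotation, tissue specificity
and correlation-based co-editing modules.

Editing level is edited reads / covering reads per site and sample; a
sample's overall level is the ratio of summed edited reads to summed
coverage over its catalog sites (coverage-weighted, not a mean of ratios).
Tissue specificity uses Shannon entropy (bits) of the tissue-mean profile
normalized to a probability vector, combined with the max-min level range.
Co-editing modules come from average-linkage clustering of 1 - |r|^power
with a fixed-height cut; modules below the minimum size fall into "grey".
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform

from .io import IntervalIndex
from .simgen import COMPLEMENT

log = logging.getLogger(__name__)

CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L", "CTT": "L", "CTC": "L",
    "CTA": "L", "CTG": "L", "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V", "TCT": "S", "TCC": "S",
    "TCA": "S", "TCG": "S", "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T", "GCT": "A", "GCC": "A",
    "GCA": "A", "GCG": "A", "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q", "AAT": "N", "AAC": "N",
    "AAA": "K", "AAG": "K", "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W", "CGT": "R", "CGC": "R",
    "CGA": "R", "CGG": "R", "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


# ----------------------------------------------------------- level math

def editing_level(edited, coverage):
    edited = np.asarray(edited, dtype=float)
    coverage = np.asarray(coverage, dtype=float)
    if np.any(coverage <= 0):
        raise ValueError("editing level undefined at zero coverage")
    return edited / coverage


def sample_overall_level(edited, coverage) -> float:
    """Sum(edited)/Sum(coverage) over a sample's covered catalog sites."""
    edited = np.asarray(edited, dtype=float)
    coverage = np.asarray(coverage, dtype=float)
    m = coverage > 0
    if not m.any():
        raise ValueError("no covered sites for this sample")
    return float(edited[m].sum() / coverage[m].sum())


def build_editing_matrix(pileups: dict[str, pd.DataFrame], catalog: pd.DataFrame,
                         sample_tissue: pd.Series):
    """Site x sample level and coverage matrices for the catalog sites.

    The edited count at each site is the count of the catalog's (genomic)
    alt allele; missing (uncovered) cells hold NaN level / 0 coverage.
    """
    sites = catalog.drop_duplicates(["chrom", "pos0"]).reset_index(drop=True)
    site_ids = [f"{c}:{p}" for c, p in zip(sites.chrom, sites.pos0)]
    idx = {sid: i for i, sid in enumerate(site_ids)}
    samples = list(pileups)
    level = np.full((len(sites), len(samples)), np.nan)
    cover = np.zeros((len(sites), len(samples)))
    alt_codes = pd.Categorical(sites.alt, categories=list("ACGT")).codes
    for j, s in enumerate(samples):
        df = pileups[s]
        sid = (df.chrom.astype(str) + ":" + (df.pos - 1).astype(str)).to_numpy()
        m = np.array([x in idx for x in sid])
        if not m.any():
            continue
        sub = df[m]
        rows = np.array([idx[x] for x in sid[m]])
        counts = sub[["A", "C", "G", "T"]].to_numpy(dtype=float)
        cov = counts.sum(axis=1)
        ed = counts[np.arange(len(sub)), alt_codes[rows]]
        ok = cov > 0
        cover[rows[ok], j] = cov[ok]
        level[rows[ok], j] = ed[ok] / cov[ok]
    level_df = pd.DataFrame(level, index=site_ids, columns=samples)
    cover_df = pd.DataFrame(cover, index=site_ids, columns=samples)
    tissues = sample_tissue.loc[samples]
    return level_df, cover_df, tissues


def tissue_profile(level: pd.DataFrame, coverage: pd.DataFrame,
                   tissues: pd.Series):
    """Per-site tissue means (over samples covering the site) and the
    count of contributing samples."""
    means, ns = {}, {}
    for t in tissues.unique():
        cols = tissues.index[tissues == t]
        sub = level[cols]
        means[t] = sub.mean(axis=1, skipna=True)
        ns[t] = sub.notna().sum(axis=1)
    return pd.DataFrame(means), pd.DataFrame(ns)


# ----------------------------------------------------------- annotation

def _site_consequence(site_pos, ref, alt, cds_rows, sequences) -> str:
    """Synonymous/nonsynonymous call by codon substitution on the coding
    frame reconstructed from the transcript's CDS intervals."""
    strand = cds_rows.strand.iloc[0]
    chrom = cds_rows.chrom.iloc[0]
    pieces = cds_rows.sort_values("start")
    coding_pos = []  # genomic positions in transcription order
    for r in pieces.itertuples(index=False):
        coding_pos.extend(range(r.start, r.end))
    if strand == "-":
        coding_pos = coding_pos[::-1]
    try:
        i = coding_pos.index(site_pos)
    except ValueError:
        return "unknown"
    seq = sequences[chrom]
    codon_i = i // 3
    codon_pos = coding_pos[codon_i * 3: codon_i * 3 + 3]
    if len(codon_pos) < 3:
        return "unknown"

    def base_at(p, sub=None):
        b = seq[p] if sub is None or p != site_pos else sub
        return b if strand == "+" else COMPLEMENT[b]

    codon_ref = "".join(base_at(p) for p in codon_pos)
    codon_alt = "".join(base_at(p, alt) for p in codon_pos)
    aa_ref = CODON_TABLE.get(codon_ref)
    aa_alt = CODON_TABLE.get(codon_alt)
    if aa_ref is None or aa_alt is None:
        return "unknown"
    return "synonymous" if aa_ref == aa_alt else "nonsynonymous"


def annotate_site(chrom: str, pos0: int, ref: str, alt: str,
                  genes: pd.DataFrame, repeats: pd.DataFrame,
                  sequences: dict[str, str] | None = None,
                  flank: int = 1000) -> dict:
    """Region class with precedence exonic > UTR > intronic >
    up/downstream > intergenic, plus coding consequence and repeat overlap."""
    g = genes[genes.chrom == chrom]
    inside = lambda rows: ((rows.start <= pos0) & (pos0 < rows.end)).any()
    region = "intergenic"
    consequence = ""
    exon = g[(g.feature == "exon")]
    utr = g[g.feature.isin(["five_prime_utr", "three_prime_utr"])]
    cds = g[g.feature == "CDS"]
    gene_rows = g[g.feature == "gene"]
    if inside(exon):
        in_cds = (cds.start <= pos0) & (pos0 < cds.end)
        if in_cds.any():
            region = "exonic"
            if sequences is not None:
                tx = cds[in_cds].transcript_id.iloc[0]
                consequence = _site_consequence(
                    pos0, ref, alt, cds[cds.transcript_id == tx], sequences)
            else:
                consequence = "unknown"
        else:
            hit5 = ((utr.feature == "five_prime_utr") & (utr.start <= pos0) & (pos0 < utr.end)).any()
            region = "UTR5" if hit5 else ("UTR3" if inside(utr) else "exonic")
            if region == "exonic":
                consequence = "unknown"  # exonic but no CDS annotation
    elif inside(gene_rows):
        region = "intronic"
    else:
        near = gene_rows[((gene_rows.start - flank) <= pos0) & (pos0 < (gene_rows.end + flank))]
        if len(near):
            r = near.iloc[0]
            before = pos0 < r.start
            upstream = (before and r.strand == "+") or (not before and r.strand == "-")
            region = "upstream" if upstream else "downstream"
    in_repeat = bool(IntervalIndex(repeats).contains(chrom, [pos0])[0])
    return {"region": region, "consequence": consequence, "in_repeat": in_repeat}


# ------------------------------------------------------- specificity

def shannon_entropy(values: np.ndarray) -> float:
    """Entropy in bits of a nonnegative profile normalized to sum 1."""
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    s = v.sum()
    if s <= 0:
        return np.nan
    p = v / s
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def tissue_specificity(profile: pd.DataFrame, n_samples: pd.DataFrame,
                       coverage_sum: pd.DataFrame | None = None,
                       min_reads: int = 50, min_samples: int = 30,
                       range_min: float = 0.10, entropy_max: float = 0.4) -> pd.DataFrame:
    """Specificity calls on eligible sites.

    Eligibility requires >= min_reads summed coverage and >= min_samples
    covered samples in at least one tissue (both configurable); a site is
    specific iff entropy < entropy_max (bits) and tissue-mean range >
    range_min.
    """
    elig = (n_samples >= min_samples)
    if coverage_sum is not None:
        elig &= (coverage_sum >= min_reads)
    eligible_sites = elig.any(axis=1)
    rows = []
    for site in profile.index[eligible_sites]:
        means = profile.loc[site].to_numpy(dtype=float)
        valid = ~np.isnan(means)
        if valid.sum() == 0:
            continue
        ent = shannon_entropy(means)
        rng = float(np.nanmax(means) - np.nanmin(means))
        specific = bool(not np.isnan(ent) and ent < entropy_max and rng > range_min)
        rows.append({
            "site": site,
            "entropy": ent,
            "level_range": rng,
            "is_specific": specific,
            "top_tissue": profile.columns[np.nanargmax(means)],
        })
    return pd.DataFrame(rows, columns=["site", "entropy", "level_range", "is_specific", "top_tissue"])


# ---------------------------------------------------------- co-editing

@dataclass
class CoEditModule:
    module_id: str
    members: list
    hubs: list
    eigenprofile: np.ndarray
    tissue_correlation: pd.Series


def _module_eigenprofile(X: np.ndarray) -> np.ndarray:
    """First principal component of the standardized member profiles,
    oriented to correlate positively with the mean profile."""
    Z = (X - X.mean(axis=1, keepdims=True))
    sd = X.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    Z = Z / sd
    u, s, vt = np.linalg.svd(Z, full_matrices=False)
    e = vt[0]
    if np.corrcoef(e, Z.mean(axis=0))[0, 1] < 0:
        e = -e
    return e


def coedit_modules(profile: pd.DataFrame,
                   missing_site_max: int = 4, tissue_missing_max: float = 0.5,
                   cv_min: float = 0.8, min_tissues: int = 10,
                   power: float = 4.0, min_module: int = 30,
                   cut_height: float = 0.9, hub_kme: float = 0.8) -> list[CoEditModule]:
    """Correlation-module detection on the site x tissue mean-level matrix.

    Preprocessing drops sites missing in >= missing_site_max tissues,
    tissues missing >= tissue_missing_max of sites, sites with CV < cv_min
    and sites observed in < min_tissues tissues.  Adjacency |r|^power,
    average-linkage clustering of 1 - adjacency with a fixed-height cut;
    modules below min_module merge into grey.  Hubs are members whose
    profile correlates with the module eigenprofile at >= hub_kme.
    """
    X = profile.copy()
    X = X[X.isna().sum(axis=1) < missing_site_max]
    keep_t = X.isna().mean(axis=0) < tissue_missing_max
    X = X.loc[:, keep_t]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        cv = X.std(axis=1) / X.mean(axis=1).abs()  # levels are nonnegative in practice
    X = X[(cv >= cv_min) & (X.notna().sum(axis=1) >= min_tissues)]
    X = X.apply(lambda row: row.fillna(row.mean()), axis=1)
    sites = list(X.index)
    if len(sites) < min_module:
        log.warning("only %d sites after preprocessing; all grey", len(sites))
        return [_grey_module(X)] if len(sites) else []

    M = X.to_numpy(dtype=float)
    sd = M.std(axis=1)
    usable = sd > 0
    M = M[usable]
    sites = [s for s, u in zip(sites, usable) if u]
    R = np.corrcoef(M)
    A = np.abs(R) ** power
    D = 1.0 - A
    np.fill_diagonal(D, 0.0)
    D = (D + D.T) / 2
    link = average(squareform(D, checks=False))
    labels = fcluster(link, t=cut_height, criterion="distance")

    modules = []
    grey_members = []
    color_names = ["turquoise", "blue", "brown", "yellow", "green", "red",
                   "black", "pink", "magenta", "purple"]
    next_color = 0
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        if len(idx) < min_module:
            grey_members.extend(idx)
            continue
        e = _module_eigenprofile(M[idx])
        kme = np.array([np.corrcoef(M[i], e)[0, 1] for i in idx])
        name = color_names[next_color] if next_color < len(color_names) else f"module{next_color + 1}"
        next_color += 1
        tiss_corr = _tissue_correlation(e, list(X.columns))
        modules.append(CoEditModule(
            module_id=name,
            members=[sites[i] for i in idx],
            hubs=[sites[i] for i, k in zip(idx, kme) if k >= hub_kme],
            eigenprofile=e,
            tissue_correlation=tiss_corr,
        ))
    if grey_members:
        idx = np.asarray(grey_members)
        e = _module_eigenprofile(M[idx]) if len(idx) > 1 else M[idx[0]]
        modules.append(CoEditModule(
            module_id="grey",
            members=[sites[i] for i in idx],
            hubs=[],
            eigenprofile=np.asarray(e, dtype=float),
            tissue_correlation=_tissue_correlation(np.asarray(e, dtype=float), list(X.columns)),
        ))
    return modules


def _grey_module(X: pd.DataFrame) -> CoEditModule:
    M = X.to_numpy(dtype=float)
    e = _module_eigenprofile(M) if len(M) > 1 else M[0]
    return CoEditModule("grey", list(X.index), [], np.asarray(e, dtype=float),
                        _tissue_correlation(np.asarray(e, dtype=float), list(X.columns)))


def _tissue_correlation(eigenprofile: np.ndarray, tissue_names: list) -> pd.Series:
    """Pearson r between the module eigenprofile and each tissue indicator."""
    out = {}
    n = len(tissue_names)
    for i, t in enumerate(tissue_names):
        ind = np.zeros(n)
        ind[i] = 1.0
        if eigenprofile.std() == 0:
            out[t] = np.nan
        else:
            out[t] = float(np.corrcoef(eigenprofile, ind)[0, 1])
    return pd.Series(out)


def soft_threshold_fit(profile: pd.DataFrame, powers=(1, 2, 3, 4, 5, 6, 8, 10),
                       n_bins: int = 10) -> pd.DataFrame:
    """Scale-free topology fit R^2 per candidate soft-threshold power.

    Connectivity k_i = sum_j |r_ij|^power; R^2 of the log10 p(k) vs
    log10 k regression over connectivity bins, with the slope's sign
    reported alongside.  Degenerate connectivity yields a missing R^2.
    """
    M = profile.dropna(axis=0, how="any").to_numpy(dtype=float)
    sd = M.std(axis=1)
    M = M[sd > 0]
    if M.shape[0] < 3:
        return pd.DataFrame([
            {"power": p, "scale_free_r2": np.nan, "slope": np.nan} for p in powers
        ])
    R = np.corrcoef(M)
    np.fill_diagonal(R, 0.0)
    rows = []
    for power in powers:
        A = np.abs(R) ** power
        k = A.sum(axis=1)
        if k.max() <= 0 or np.isclose(k.max(), k.min()):
            rows.append({"power": power, "scale_free_r2": np.nan, "slope": np.nan})
            continue
        edges = np.linspace(k.min(), k.max() + 1e-9, n_bins + 1)
        which = np.digitize(k, edges) - 1
        xs, ys = [], []
        for b in range(n_bins):
            m = which == b
            if m.sum() == 0:
                continue
            xs.append(np.log10(k[m].mean() + 1e-12))
            ys.append(np.log10(m.mean() + 1e-12))
        if len(xs) < 3:
            rows.append({"power": power, "scale_free_r2": np.nan, "slope": np.nan})
            continue
        xs, ys = np.asarray(xs), np.asarray(ys)
        r = np.corrcoef(xs, ys)[0, 1]
        slope = r * ys.std() / xs.std() if xs.std() > 0 else np.nan
        rows.append({"power": power, "scale_free_r2": float(r ** 2), "slope": float(slope)})
    return pd.DataFrame(rows)
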