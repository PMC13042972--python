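"""RNA editing site calling: the DNA-free filter cascade.

Per-sample pileups are reduced to mismatch candidates and then passed
through a fixed sequence of filters:

    call -> read-position -> homopolymer -> known-SNP -> similarity
         -> region-stratified -> presence

Quality gates (base/mapping quality, coverage, edited-read support) are
applied at calling time.  Mismatches supported only by read starts, sites
in or adjacent to homopolymer runs, known genomic SNPs, and mismatches in
self-similar (alignment-artifact prone) regions outside annotated repeats
are removed.  Non-repeat candidates face stricter support thresholds than
repeat candidates, and a site must recur in a minimum number and fraction
of a tissue's samples to enter the catalog.  Re-running any filter on its
own output is a no-op.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import IntervalIndex
from .selfsim import SimilarityMask
from .simgen import COMPLEMENT, _encode, _scan_homopolymers

log = logging.getLogger(__name__)

CANDIDATE_COLUMNS = [
    "chrom", "pos0", "ref", "alt", "edited", "coverage", "level",
    "sample", "meanBQ", "meanMQ", "n_mismatch_in_first6",
]


@dataclass
class CallParams:
    min_bq: float = 25.0
    min_mq: float = 20.0
    min_coverage: int = 10
    min_edited: int = 2


@dataclass
class RegionParams:
    """Support thresholds, stratified by repeat overlap (non-repeat stricter)."""

    nonrepeat_min_edited: int = 3
    nonrepeat_min_level: float = 0.10
    repeat_min_edited: int = 2
    repeat_min_level: float = 0.05


def call_candidates(pileup: pd.DataFrame, sample: str,
                    params: CallParams | None = None) -> pd.DataFrame:
    """One candidate per (site, sample): the highest-count non-reference
    allele, ties broken alphabetically; reference-only sites emit nothing."""
    params = params or CallParams()
    counts = pileup[["A", "C", "G", "T"]].to_numpy(dtype=np.int64)
    coverage = counts.sum(axis=1)
    n_zero = int((coverage == 0).sum())
    if n_zero:
        log.info("%s: skipped %d zero-coverage pileup rows", sample, n_zero)

    ref_idx = pd.Categorical(pileup["ref"], categories=list("ACGT")).codes
    alt_counts = counts.copy()
    alt_counts[np.arange(len(pileup)), ref_idx] = -1
    alt_idx = alt_counts.argmax(axis=1)  # argmax takes the first (alphabetical) max
    edited = counts[np.arange(len(pileup)), alt_idx]

    keep = (
        (coverage >= params.min_coverage)
        & (edited >= params.min_edited)
        & (pileup["meanBQ"].to_numpy() >= params.min_bq)
        & (pileup["meanMQ"].to_numpy() >= params.min_mq)
    )
    out = pd.DataFrame({
        "chrom": pileup["chrom"].to_numpy()[keep],
        "pos0": pileup["pos"].to_numpy()[keep] - 1,
        "ref": pileup["ref"].to_numpy()[keep],
        "alt": np.array(list("ACGT"))[alt_idx[keep]],
        "edited": edited[keep],
        "coverage": coverage[keep],
        "sample": sample,
        "meanBQ": pileup["meanBQ"].to_numpy()[keep],
        "meanMQ": pileup["meanMQ"].to_numpy()[keep],
        "n_mismatch_in_first6": pileup["n_mismatch_in_first6"].to_numpy()[keep],
    })
    out["level"] = out.edited / out.coverage
    return out[CANDIDATE_COLUMNS]


def filter_read_position(candidates: pd.DataFrame,
                         min_edited: int = 2) -> pd.DataFrame:
    """Discount mismatching reads whose mismatch lies in the first 6 read
    bases; drop candidates whose support falls below ``min_edited``."""
    out = candidates.copy()
    out["edited"] = (out["edited"] - out["n_mismatch_in_first6"]).clip(lower=0)
    out["n_mismatch_in_first6"] = 0
    out = out[out.edited >= min_edited].copy()
    out["level"] = out.edited / out.coverage
    return out.reset_index(drop=True)


def homopolymer_intervals(sequences: dict[str, str], run_length: int = 5,
                          pad: int = 1) -> pd.DataFrame:
    rows = []
    for chrom, seq in sequences.items():
        for s, e in _scan_homopolymers(_encode(seq), run_length):
            rows.append((chrom, max(int(s) - pad, 0), int(e) + pad))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def filter_homopolymer(candidates: pd.DataFrame, sequences: dict[str, str],
                       run_length: int = 5) -> pd.DataFrame:
    """Remove candidates within +-1 bp of a reference run of >= run_length
    identical bases (runs read inclusively: a site inside the run counts)."""
    iv = IntervalIndex(homopolymer_intervals(sequences, run_length))
    bad = iv.contains_df(candidates)
    return candidates[~bad].reset_index(drop=True)


def filter_known_snps(candidates: pd.DataFrame, panels: list[pd.DataFrame],
                      allele_aware: bool = True) -> pd.DataFrame:
    """Drop candidates present in any known-SNP panel.

    ``allele_aware`` removes only candidates whose mismatch allele equals
    the panel ALT; positional mode removes any candidate at a panel site.
    """
    if not panels:
        return candidates.reset_index(drop=True)
    panel = pd.concat(panels, ignore_index=True)
    if allele_aware:
        known = set(zip(panel.chrom, panel.pos0, panel.alt))
        bad = [
            (c, p, a) in known
            for c, p, a in zip(candidates.chrom, candidates.pos0, candidates.alt)
        ]
    else:
        known = set(zip(panel.chrom, panel.pos0))
        bad = [(c, p) in known for c, p in zip(candidates.chrom, candidates.pos0)]
    return candidates[~np.asarray(bad)].reset_index(drop=True)


def filter_similarity(candidates: pd.DataFrame, mask: SimilarityMask,
                      repeats: pd.DataFrame) -> pd.DataFrame:
    """Remove non-repeat candidates inside the self-similarity mask;
    candidates inside annotated repeats are exempt."""
    rep_idx = IntervalIndex(repeats)
    in_rep = rep_idx.contains_df(candidates)
    in_mask = mask._index.contains_df(candidates)
    return candidates[~(in_mask & ~in_rep)].reset_index(drop=True)


def region_stratified_filter(candidates: pd.DataFrame, repeats: pd.DataFrame,
                             params: RegionParams | None = None) -> pd.DataFrame:
    params = params or RegionParams()
    rep_idx = IntervalIndex(repeats)
    in_rep = rep_idx.contains_df(candidates)
    ed = candidates.edited.to_numpy()
    lv = candidates.level.to_numpy()
    ok = np.where(
        in_rep,
        (ed >= params.repeat_min_edited) & (lv >= params.repeat_min_level),
        (ed >= params.nonrepeat_min_edited) & (lv >= params.nonrepeat_min_level),
    )
    return candidates[ok].reset_index(drop=True)


def presence_filter(candidates: pd.DataFrame, sample_tissue: pd.Series,
                    min_samples: int = 20, min_fraction: float = 0.10) -> pd.DataFrame:
    """Per-tissue site catalog: a site is kept iff present in
    >= min_samples samples AND >= min_fraction of that tissue's samples."""
    cand = candidates.copy()
    cand["tissue"] = cand["sample"].map(sample_tissue)
    if len(cand) and cand["tissue"].isna().any():
        raise ValueError("candidate sample without a tissue assignment")
    n_per_tissue = sample_tissue.value_counts()
    if len(cand) and ((n_per_tissue == 0).any() or len(n_per_tissue) == 0):
        raise ValueError("tissue with zero samples")
    rows = []
    for (tissue, chrom, pos0), grp in cand.groupby(["tissue", "chrom", "pos0"]):
        n_tissue = int(n_per_tissue[tissue])
        n_present = grp["sample"].nunique()
        if n_present >= min_samples and n_present / n_tissue >= min_fraction:
            top = grp.groupby("alt").edited.sum().sort_index()
            alt = top.idxmax()
            rows.append({
                "tissue": tissue, "chrom": chrom, "pos0": pos0,
                "ref": grp.ref.iloc[0], "alt": alt,
                "n_samples_present": n_present, "n_tissue_samples": n_tissue,
                "mean_level": grp.level.mean(),
            })
    return pd.DataFrame(rows, columns=[
        "tissue", "chrom", "pos0", "ref", "alt",
        "n_samples_present", "n_tissue_samples", "mean_level"])


def correct_strand(sites: pd.DataFrame, genes: pd.DataFrame) -> pd.DataFrame:
    """Resolve substitution types onto the transcribed strand.

    Sites in a minus-strand gene get complemented types (T>C becomes A>G);
    sites in no gene, or in genes on both strands, keep their genomic type
    and carry ``strand_ambiguous``.
    """
    gene_rows = genes[genes.feature == "gene"] if "feature" in genes else genes
    plus = IntervalIndex(gene_rows[gene_rows.strand == "+"])
    minus = IntervalIndex(gene_rows[gene_rows.strand == "-"])
    on_plus = plus.contains_df(sites)
    on_minus = minus.contains_df(sites)
    out = sites.copy()
    sub, amb = [], []
    for r, a, pl, mi in zip(out.ref, out.alt, on_plus, on_minus):
        if pl and not mi:
            sub.append(f"{r}>{a}")
            amb.append(False)
        elif mi and not pl:
            sub.append(f"{COMPLEMENT[r]}>{COMPLEMENT[a]}")
            amb.append(False)
        else:
            sub.append(f"{r}>{a}")
            amb.append(True)
    out["sub_type"] = sub
    out["strand_ambiguous"] = amb
    return out


def mutation_spectrum(sites: pd.DataFrame) -> pd.Series:
    """Fractions of the 12 substitution types over a strand-resolved catalog."""
    if len(sites) == 0:
        raise ValueError("empty site catalog")
    frac = sites.sub_type.value_counts(normalize=True)
    return frac


def calibrate_presence_threshold(candidates: pd.DataFrame, sample_tissue: pd.Series,
                                 genes: pd.DataFrame,
                                 thresholds: list[int]) -> pd.DataFrame:
    """Presence-threshold calibration curve: retained-site count and
    strand-corrected A-to-G fraction at each minimum-sample threshold."""
    if len(candidates) == 0:
        return pd.DataFrame(columns=["threshold", "n_retained", "a2g_fraction"])
    cand = candidates.copy()
    cand["tissue"] = cand["sample"].map(sample_tissue)
    pres = (cand.groupby(["tissue", "chrom", "pos0"])
            .agg(n=("sample", "nunique"), ref=("ref", "first"), alt=("alt", "first"))
            .reset_index())
    rows = []
    for thr in thresholds:
        kept = pres[pres.n >= thr]
        sites = kept.drop_duplicates(["chrom", "pos0"]).reset_index(drop=True)
        if len(sites) == 0:
            rows.append({"threshold": thr, "n_retained": 0, "a2g_fraction": np.nan})
            continue
        sc = correct_strand(sites, genes)
        rows.append({
            "threshold": thr,
            "n_retained": len(sites),
            "a2g_fraction": float((sc.sub_type == "A>G").mean()),
        })
    return pd.DataFrame(rows)


def run_filter_cascade(
    pileups: dict[str, pd.DataFrame],
    sample_tissue: pd.Series,
    sequences: dict[str, str],
    genes: pd.DataFrame,
    repeats: pd.DataFrame,
    mask: SimilarityMask,
    snp_panels: list[pd.DataFrame],
    call_params: CallParams | None = None,
    region_params: RegionParams | None = None,
    min_samples: int = 20,
    min_fraction: float = 0.10,
):
    """Full cascade in the documented, fixed order.

    Returns (per-tissue catalog with strand-corrected types, per-stage
    candidate counts, post-filter per-sample candidates).
    """
    call_params = call_params or CallParams()
    stages = {}
    cands = pd.concat(
        [call_candidates(df, s, call_params) for s, df in pileups.items()],
        ignore_index=True,
    )
    stages["called"] = len(cands)
    cands = filter_read_position(cands, call_params.min_edited)
    stages["read_position"] = len(cands)
    cands = filter_homopolymer(cands, sequences)
    stages["homopolymer"] = len(cands)
    cands = filter_known_snps(cands, snp_panels)
    stages["known_snp"] = len(cands)
    cands = filter_similarity(cands, mask, repeats)
    stages["similarity"] = len(cands)
    cands = region_stratified_filter(cands, repeats, region_params)
    stages["region_stratified"] = len(cands)
    catalog = presence_filter(cands, sample_tissue, min_samples, min_fraction)
    stages["presence_sites"] = len(catalog)
    catalog = correct_strand(catalog, genes)
    rep_idx = IntervalIndex(repeats)
    if len(catalog):
        catalog["in_repeat"] = rep_idx.contains_df(catalog)
    return catalog, stages, cands
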