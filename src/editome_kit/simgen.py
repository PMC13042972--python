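"""Synthetic multi-tissue RNA-editome generator with planted ground truth.

Every input the downstream pipeline consumes is generated here: a repeat-rich
genome with near-exact duplicated segments and homopolymer runs, gene models
on both strands, a biallelic SNP panel with blockwise LD, per-sample pileup
tables in which true A-to-I editing, alignment artifacts (confined to the
duplicated segments), leaked genomic SNPs and uniform base errors are all
planted, per-allele count tables for heterozygous individuals, and GWAS
summary statistics whose causal set overlaps the planted edQTLs.

The generator emulates the observation layer of an editing-detection
pipeline (site-level base counts), not reads: read alignment and read-level
allele splitting are deliberately outside its scope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from . import io as ekio

BASES = np.array(["A", "C", "G", "T"])
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass
class SimConfig:
    """All knobs of the synthetic study, with the default study conditions.

    Defaults describe a desk-scale editome: 3 tissues x 60 samples, 2,000
    true editing sites, 500 alignment-artifact sites inside duplicated
    segments and 500 genomic-SNP leak sites.
    """

    seed: int = 0
    # genome
    genome_length: int = 600_000
    n_chromosomes: int = 3
    repeat_fraction: float = 0.25
    repeat_divergence: float = 0.15   # per-copy mutation rate from consensus
    n_duplicated_segments: int = 12
    duplicated_segment_length: int = 400
    duplication_identity: float = 1.0
    homopolymer_rate: float = 0.15    # runs per kb
    n_genes: int = 60
    # editome
    n_tissues: int = 3
    samples_per_tissue: tuple = (60, 60, 60)
    n_edit_sites: int = 2000
    edit_level_alpha: float = 2.0
    edit_level_beta: float = 4.0
    edit_level_min: float = 0.08
    edit_level_max: float = 0.95
    tissue_level_sd: float = 0.4      # per-tissue logit jitter
    sample_level_sd: float = 0.2      # per-sample logit jitter
    a2g_fraction: float = 0.75
    repeat_site_fraction: float = 0.75
    tissue_specific_fraction: float = 0.05
    n_artifact_sites: int = 500
    n_snp_leak_sites: int = 500
    # genotypes
    n_snps: int = 3000
    maf_min: float = 0.05
    maf_max: float = 0.5
    ld_block_size: int = 5
    ld_block_flip: float = 0.01       # per-SNP allele flip vs block anchor
    # edQTL
    n_edqtl: int = 300
    edqtl_slope_mean: float = 0.8     # logit scale, random sign
    edqtl_slope_sd: float = 0.2
    # sequencing
    coverage_mean: float = 60.0
    coverage_dispersion: float = 5.0  # NB size parameter
    base_error_rate: float = 1e-3
    errors_per_sample: float = 30.0   # Poisson mean of error-only pileup rows
    # GWAS
    n_gwas_samples: int = 2000
    n_gwas_causal: int = 20
    gwas_causal_overlap: float = 0.5  # fraction of causal SNPs that are planted edQTLs
    gwas_effect_sd: float = 0.25      # per-causal effect, phenotype SD units

    def validate(self) -> None:
        for name in ("genome_length", "n_chromosomes", "n_genes", "n_tissues",
                     "n_edit_sites", "n_artifact_sites", "n_snp_leak_sites",
                     "n_snps", "n_edqtl", "n_duplicated_segments",
                     "n_gwas_samples", "n_gwas_causal"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("repeat_fraction", "a2g_fraction", "repeat_site_fraction",
                     "tissue_specific_fraction", "gwas_causal_overlap",
                     "duplication_identity"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.genome_length < 10_000:
            raise ValueError("genome_length must be >= 10 kb")
        if len(self.samples_per_tissue) != self.n_tissues:
            raise ValueError("samples_per_tissue length must equal n_tissues")
        if self.n_edqtl > self.n_edit_sites:
            raise ValueError("n_edqtl cannot exceed n_edit_sites")


@dataclass
class Genome:
    sequences: dict[str, str]
    repeats: pd.DataFrame           # chrom, start, end
    duplications: pd.DataFrame      # chrom, start, end, pair_id
    homopolymers: pd.DataFrame      # chrom, start, end (runs >= 5 in final sequence)
    genes: pd.DataFrame             # GTF-style feature table, 0-based half-open
    gene_table: pd.DataFrame        # gene_id, chrom, start, end, strand


@dataclass
class Genotypes:
    variants: pd.DataFrame          # chrom, pos0, id, ref, alt, maf, block
    dosages: np.ndarray             # (n_snps, n_individuals)
    sample_names: list[str]
    sample_tissue: pd.Series        # tissue label per individual


@dataclass
class TruthSet:
    true_sites: pd.DataFrame        # chrom, pos0, ref, alt, strand, sub_type, in_repeat
    tissue_levels: np.ndarray       # (n_true_sites, n_tissues) mean editing level
    artifact_sites: pd.DataFrame    # chrom, pos0, ref, alt, level
    snp_leak_sites: pd.DataFrame    # chrom, pos0, ref, alt, snp_id
    edqtl: pd.DataFrame             # site_id, snp_id, slope
    tissue_specific_sites: pd.DataFrame  # site_id, top_tissue
    gwas_causal: pd.DataFrame       # snp_id, effect, is_edqtl

    def check_disjoint(self) -> None:
        sets = [
            set(zip(self.true_sites.chrom, self.true_sites.pos0)),
            set(zip(self.artifact_sites.chrom, self.artifact_sites.pos0)),
            set(zip(self.snp_leak_sites.chrom, self.snp_leak_sites.pos0)),
        ]
        for i in range(3):
            for j in range(i + 1, 3):
                if sets[i] & sets[j]:
                    raise AssertionError("truth site categories are not disjoint")


@dataclass
class SimBundle:
    config: SimConfig
    genome: Genome
    genotypes: Genotypes
    truth: TruthSet
    pileups: dict[str, pd.DataFrame]
    allelic_counts: pd.DataFrame
    gwas: pd.DataFrame


# ------------------------------------------------------------ placement

def _place_intervals(rng, occupied: np.ndarray, n: int, length, max_tries: int = 2000):
    """Greedily place n non-overlapping intervals into a boolean occupancy
    track, marking them occupied.  Raises on infeasible packing."""
    L = occupied.shape[0]
    out = []
    lengths = np.full(n, length) if np.isscalar(length) else np.asarray(length)
    for m in lengths:
        m = int(m)
        if m > L:
            raise ValueError("requested feature longer than chromosome")
        for _ in range(max_tries):
            s = int(rng.integers(0, L - m + 1))
            if not occupied[s:s + m].any():
                occupied[s:s + m] = True
                out.append((s, s + m))
                break
        else:
            raise ValueError("infeasible packing: could not place requested features")
    return out


def _scan_homopolymers(seq: np.ndarray, min_run: int = 5) -> np.ndarray:
    """All maximal runs of >= min_run identical bases, as (start, end) pairs."""
    if len(seq) == 0:
        return np.empty((0, 2), dtype=np.int64)
    change = np.flatnonzero(seq[1:] != seq[:-1])
    starts = np.concatenate([[0], change + 1])
    ends = np.concatenate([change + 1, [len(seq)]])
    keep = (ends - starts) >= min_run
    return np.stack([starts[keep], ends[keep]], axis=1)


def _encode(seq: str) -> np.ndarray:
    lut = np.full(256, -1, dtype=np.int8)
    for i, b in enumerate("ACGT"):
        lut[ord(b)] = i
    return lut[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _decode(codes: np.ndarray) -> str:
    return "".join(BASES[codes])


# ------------------------------------------------------------- genome

def simulate_genome(config: SimConfig, rng: np.random.Generator | None = None) -> Genome:
    """Build the genomic substrate: sequence, repeats, duplications,
    homopolymer runs and gene models."""
    config.validate()
    rng = rng or np.random.default_rng(config.seed)
    chrom_len = config.genome_length // config.n_chromosomes
    chroms = [f"chr{i + 1}" for i in range(config.n_chromosomes)]

    consensus = rng.integers(0, 4, size=280)  # PRE-like SINE consensus
    seqs: dict[str, np.ndarray] = {}
    repeat_rows, dup_rows, gene_rows, gene_feat_rows = [], [], [], []

    dup_per_chrom = np.zeros(config.n_chromosomes, dtype=int)
    for i in range(config.n_duplicated_segments):
        dup_per_chrom[i % config.n_chromosomes] += 1
    genes_per_chrom = np.zeros(config.n_chromosomes, dtype=int)
    for i in range(config.n_genes):
        genes_per_chrom[i % config.n_chromosomes] += 1

    pair_id = 0
    for ci, chrom in enumerate(chroms):
        seq = rng.integers(0, 4, size=chrom_len).astype(np.int8)
        occupied = np.zeros(chrom_len, dtype=bool)

        # repeats: mutated truncated copies of the consensus
        target = config.repeat_fraction * chrom_len
        covered = 0
        while covered < target:
            m = int(rng.integers(180, 281))
            try:
                (s, e), = _place_intervals(rng, occupied, 1, m)
            except ValueError:
                break
            copy = consensus[:m].copy()
            mut = rng.random(m) < config.repeat_divergence
            copy[mut] = (copy[mut] + rng.integers(1, 4, size=mut.sum())) % 4
            seq[s:e] = copy
            repeat_rows.append((chrom, s, e))
            covered += m

        # homopolymer runs overwrite sequence outside repeats/duplications
        n_runs = rng.poisson(config.homopolymer_rate * chrom_len / 1000)
        run_lens = rng.integers(5, 13, size=n_runs)
        try:
            placed = _place_intervals(rng, occupied, n_runs, run_lens)
        except ValueError:
            placed = []
        for s, e in placed:
            seq[s:e] = rng.integers(0, 4)

        # duplicated segments: copy source to target after all other edits
        m = config.duplicated_segment_length
        for _ in range(dup_per_chrom[ci]):
            (s1, e1), (s2, e2) = _place_intervals(rng, occupied, 2, m)
            copy = seq[s1:e1].copy()
            if config.duplication_identity < 1.0:
                mut = rng.random(m) < (1.0 - config.duplication_identity)
                copy[mut] = (copy[mut] + rng.integers(1, 4, size=mut.sum())) % 4
            seq[s2:e2] = copy
            dup_rows.append((chrom, s1, e1, pair_id))
            dup_rows.append((chrom, s2, e2, pair_id))
            pair_id += 1

        # gene models: 3 exons, UTRs at the transcript ends, CDS in frame
        gene_occ = np.zeros(chrom_len, dtype=bool)
        exon_len, intron_len, utr_len = 300, 500, 100
        gene_len = 3 * exon_len + 2 * intron_len
        placed = _place_intervals(rng, gene_occ, genes_per_chrom[ci], gene_len)
        for gi, (gs, ge) in enumerate(placed):
            gene_id = f"G{ci + 1}_{gi + 1}"
            tx_id = gene_id + ".1"
            strand = "+" if rng.random() < 0.5 else "-"
            exons = [(gs, gs + exon_len),
                     (gs + exon_len + intron_len, gs + 2 * exon_len + intron_len),
                     (ge - exon_len, ge)]
            # coding region excludes one UTR at each transcript end
            if strand == "+":
                cds = [(exons[0][0] + utr_len, exons[0][1]),
                       exons[1],
                       (exons[2][0], exons[2][1] - utr_len - 1)]
                utr5, utr3 = (exons[0][0], exons[0][0] + utr_len), (exons[2][1] - utr_len - 1, exons[2][1])
            else:
                cds = [(exons[0][0] + utr_len + 1, exons[0][1]),
                       exons[1],
                       (exons[2][0], exons[2][1] - utr_len)]
                utr3, utr5 = (exons[0][0], exons[0][0] + utr_len + 1), (exons[2][1] - utr_len, exons[2][1])
            gene_rows.append((gene_id, chrom, gs, ge, strand))
            gene_feat_rows.append((chrom, "gene", gs, ge, strand, ".", gene_id, tx_id))
            gene_feat_rows.append((chrom, "transcript", gs, ge, strand, ".", gene_id, tx_id))
            for s, e in exons:
                gene_feat_rows.append((chrom, "exon", s, e, strand, ".", gene_id, tx_id))
            cds_tx_order = cds if strand == "+" else cds[::-1]
            cum = 0
            frames = {}
            for s, e in cds_tx_order:
                frames[(s, e)] = (3 - cum % 3) % 3
                cum += e - s
            for s, e in cds:
                gene_feat_rows.append((chrom, "CDS", s, e, strand, frames[(s, e)], gene_id, tx_id))
            gene_feat_rows.append((chrom, "five_prime_utr", *utr5, strand, ".", gene_id, tx_id))
            gene_feat_rows.append((chrom, "three_prime_utr", *utr3, strand, ".", gene_id, tx_id))

        seqs[chrom] = seq

    homo_rows = []
    for chrom in chroms:
        for s, e in _scan_homopolymers(seqs[chrom]):
            homo_rows.append((chrom, int(s), int(e)))

    return Genome(
        sequences={c: _decode(s) for c, s in seqs.items()},
        repeats=pd.DataFrame(repeat_rows, columns=["chrom", "start", "end"]),
        duplications=pd.DataFrame(dup_rows, columns=["chrom", "start", "end", "pair_id"]),
        homopolymers=pd.DataFrame(homo_rows, columns=["chrom", "start", "end"]),
        genes=pd.DataFrame(
            gene_feat_rows,
            columns=["chrom", "feature", "start", "end", "strand", "frame", "gene_id", "transcript_id"],
        ),
        gene_table=pd.DataFrame(gene_rows, columns=["gene_id", "chrom", "start", "end", "strand"]),
    )


# ----------------------------------------------------------- genotypes

def _haplotypes(rng, anchor_freqs, blocks, n_hap, flip):
    """Blockwise haplotype sampler: SNPs in a block copy the block anchor
    haplotype with a small per-SNP flip probability (creates high LD)."""
    n_snps = len(blocks)
    H = np.zeros((n_snps, n_hap), dtype=np.int8)
    for b in np.unique(blocks):
        idx = np.flatnonzero(blocks == b)
        anchor = (rng.random(n_hap) < anchor_freqs[idx[0]]).astype(np.int8)
        for i in idx:
            flips = rng.random(n_hap) < flip
            H[i] = np.where(flips, 1 - anchor, anchor)
    return H


def simulate_genotypes(config: SimConfig, genome: Genome,
                       rng: np.random.Generator | None = None) -> Genotypes:
    """Biallelic SNP panel with blockwise LD and per-individual dosages."""
    rng = rng or np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    chroms = list(genome.sequences)
    chrom_len = len(genome.sequences[chroms[0]])
    per_chrom = np.full(len(chroms), config.n_snps // len(chroms))
    per_chrom[: config.n_snps % len(chroms)] += 1

    rows = []
    blocks_all = []
    block_id = 0
    for chrom, n in zip(chroms, per_chrom):
        pos = np.sort(rng.choice(chrom_len, size=n, replace=False))
        codes = _encode(genome.sequences[chrom])
        for j, p in enumerate(pos):
            ref = BASES[codes[p]] if codes[p] >= 0 else "A"
            alt = str(rng.choice([b for b in BASES if b != ref]))
            if j % config.ld_block_size == 0:
                block_id += 1
            rows.append((chrom, int(p), f"snp_{chrom}_{p}", ref, alt, block_id))
            blocks_all.append(block_id)
    variants = pd.DataFrame(rows, columns=["chrom", "pos0", "id", "ref", "alt", "block"])
    blocks = np.asarray(blocks_all)

    anchor_freqs = np.empty(len(variants))
    for b in np.unique(blocks):
        idx = np.flatnonzero(blocks == b)
        anchor_freqs[idx] = rng.uniform(config.maf_min, config.maf_max)
    variants["maf"] = anchor_freqs

    n_ind = int(sum(config.samples_per_tissue))
    H = _haplotypes(rng, anchor_freqs, blocks, 2 * n_ind, config.ld_block_flip)
    dosages = (H[:, ::2] + H[:, 1::2]).astype(np.float64)

    sample_names, tissues = [], []
    for t, n in enumerate(config.samples_per_tissue):
        for j in range(n):
            sample_names.append(f"T{t + 1}_S{j + 1:03d}")
            tissues.append(f"tissue{t + 1}")
    return Genotypes(
        variants=variants,
        dosages=dosages,
        sample_names=sample_names,
        sample_tissue=pd.Series(tissues, index=sample_names, name="tissue"),
    )


# --------------------------------------------------------------- truth

def simulate_truth(config: SimConfig, genome: Genome, genotypes: Genotypes,
                   rng: np.random.Generator | None = None) -> TruthSet:
    """Plant true editing sites, artifact sites and SNP-leak sites.

    True sites sit inside gene bodies, preferentially in repeats, away from
    homopolymer runs, duplicated segments and SNPs; ~``a2g_fraction`` are
    canonical A-to-G on the annotated strand.  Artifact sites sit inside
    duplicated segments outside repeats.  Leak sites are common SNPs of the
    panel re-emitted as RNA mismatches.
    """
    rng = rng or np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    repeat_idx = ekio.IntervalIndex(genome.repeats)
    dup_idx = ekio.IntervalIndex(genome.duplications)
    homo = genome.homopolymers.copy()
    homo["start"] -= 1
    homo["end"] += 1
    homo_idx = ekio.IntervalIndex(homo)
    snp_pos = set(zip(genotypes.variants.chrom, genotypes.variants.pos0))

    # candidate genic positions, annotated with strand
    frames = []
    for g in genome.gene_table.itertuples(index=False):
        codes = _encode(genome.sequences[g.chrom])
        pos = np.arange(g.start, g.end)
        ok = (~homo_idx.contains(g.chrom, pos)) & (~dup_idx.contains(g.chrom, pos))
        pos = pos[ok]
        frames.append(pd.DataFrame({
            "chrom": g.chrom,
            "pos0": pos,
            "ref": BASES[codes[pos]],
            "strand": g.strand,
            "in_repeat": repeat_idx.contains(g.chrom, pos),
        }))
    cand = pd.concat(frames, ignore_index=True)
    cand = cand[~pd.Series(list(zip(cand.chrom, cand.pos0))).isin(snp_pos).to_numpy()]
    cand = cand.drop_duplicates(["chrom", "pos0"])

    n_canon = int(round(config.a2g_fraction * config.n_edit_sites))
    canon_pool = cand[((cand.strand == "+") & (cand.ref == "A"))
                      | ((cand.strand == "-") & (cand.ref == "T"))]
    canon_rep = canon_pool[canon_pool.in_repeat]
    canon_non = canon_pool[~canon_pool.in_repeat]
    n_rep = int(round(config.repeat_site_fraction * n_canon))
    if len(canon_rep) < n_rep or len(canon_non) < n_canon - n_rep:
        raise ValueError("n_edit_sites exceeds available candidate positions")
    pick = pd.concat([
        canon_rep.sample(n=n_rep, random_state=np.random.RandomState(rng.integers(2**31))),
        canon_non.sample(n=n_canon - n_rep, random_state=np.random.RandomState(rng.integers(2**31))),
    ])
    pick = pick.copy()
    pick["alt"] = np.where(pick.ref == "A", "G", "C")   # A>G on +, T>C on -
    pick["sub_type"] = "A>G"

    n_noncanon = config.n_edit_sites - n_canon
    rest = cand.loc[~cand.index.isin(pick.index)]
    if len(rest) < n_noncanon:
        raise ValueError("n_edit_sites exceeds available candidate positions")
    nc = rest.sample(n=n_noncanon, random_state=np.random.RandomState(rng.integers(2**31))).copy()
    alts = []
    subs = []
    for ref, strand in zip(nc.ref, nc.strand):
        choices = [b for b in BASES if b != ref]
        alt = str(rng.choice(choices))
        # avoid accidentally canonical picks so the planted fraction is exact
        sr = ref if strand == "+" else COMPLEMENT[ref]
        sa = alt if strand == "+" else COMPLEMENT[alt]
        if sr == "A" and sa == "G":
            alt = [b for b in choices if b != alt][0]
            sa = alt if strand == "+" else COMPLEMENT[alt]
        alts.append(alt)
        subs.append(f"{sr}>{sa}")
    nc["alt"] = alts
    nc["sub_type"] = subs
    true_sites = pd.concat([pick, nc], ignore_index=True)
    true_sites = true_sites.sort_values(["chrom", "pos0"]).reset_index(drop=True)
    true_sites["site_id"] = [f"site_{c}_{p}" for c, p in zip(true_sites.chrom, true_sites.pos0)]

    n_sites = len(true_sites)
    base = rng.beta(config.edit_level_alpha, config.edit_level_beta, size=n_sites)
    base = np.clip(base, config.edit_level_min, config.edit_level_max)
    shifts = rng.normal(0.0, config.tissue_level_sd, size=(n_sites, config.n_tissues))
    levels = expit(logit(base)[:, None] + shifts)

    n_spec = int(round(config.tissue_specific_fraction * n_sites))
    spec_idx = rng.choice(n_sites, size=n_spec, replace=False)
    top = rng.integers(0, config.n_tissues, size=n_spec)
    for i, t in zip(spec_idx, top):
        lv = max(levels[i].max(), 0.2)
        levels[i, :] = 0.005
        levels[i, t] = lv
    tissue_specific = pd.DataFrame({
        "site_id": true_sites.site_id.to_numpy()[spec_idx],
        "top_tissue": [f"tissue{t + 1}" for t in top],
    })

    # artifact sites: inside duplicated segments, outside repeats
    art_rows = []
    dup_iter = genome.duplications.sample(frac=1.0, random_state=np.random.RandomState(rng.integers(2**31)))
    need = config.n_artifact_sites
    used = set()
    stall = 0
    while need > 0:
        placed_this_round = 0
        for d in dup_iter.itertuples(index=False):
            if need <= 0:
                break
            codes = _encode(genome.sequences[d.chrom])
            for _ in range(10):
                p = int(rng.integers(d.start, d.end))
                key = (d.chrom, p)
                if key in used or key in snp_pos:
                    continue
                ref = BASES[codes[p]]
                alt = str(rng.choice([b for b in BASES if b != ref]))
                art_rows.append((d.chrom, p, ref, alt, float(rng.uniform(0.08, 0.35))))
                used.add(key)
                need -= 1
                placed_this_round += 1
                break
        stall = stall + 1 if placed_this_round == 0 else 0
        if need > 0 and stall > 50:
            raise ValueError("cannot place artifact sites inside duplicated segments")
    artifact_sites = pd.DataFrame(art_rows, columns=["chrom", "pos0", "ref", "alt", "level"])

    # SNP-leak sites: common panel SNPs emitted as RNA mismatches
    v = genotypes.variants
    eligible = v[(v.maf >= 0.25)
                 & ~dup_idx.contains_df(v)
                 & ~homo_idx.contains_df(v)]
    if len(eligible) < config.n_snp_leak_sites:
        raise ValueError("not enough common SNPs for the requested leak sites")
    leak = eligible.sample(n=config.n_snp_leak_sites,
                           random_state=np.random.RandomState(rng.integers(2**31)))
    snp_leak_sites = leak[["chrom", "pos0", "ref", "alt"]].copy()
    snp_leak_sites["snp_id"] = leak["id"].to_numpy()

    # edQTL assignments: causal SNP within 1 Mb, slope on the logit scale
    leak_ids = set(snp_leak_sites.snp_id)
    edqtl_rows = []
    qtl_sites = rng.choice(n_sites, size=config.n_edqtl, replace=False)
    for i in qtl_sites:
        chrom = true_sites.chrom.iloc[i]
        p = true_sites.pos0.iloc[i]
        nearby = v[(v.chrom == chrom) & (np.abs(v.pos0 - p) <= 1_000_000)
                   & (v.maf >= 0.1) & ~v.id.isin(leak_ids)]
        if len(nearby) == 0:
            continue
        snp = nearby.sample(n=1, random_state=np.random.RandomState(rng.integers(2**31)))
        slope = rng.normal(config.edqtl_slope_mean, config.edqtl_slope_sd)
        slope *= rng.choice([-1.0, 1.0])
        edqtl_rows.append((true_sites.site_id.iloc[i], snp.id.iloc[0], float(slope)))
    edqtl = pd.DataFrame(edqtl_rows, columns=["site_id", "snp_id", "slope"])

    # GWAS causal set overlaps planted edQTL SNPs
    n_from_qtl = int(round(config.gwas_causal_overlap * config.n_gwas_causal))
    n_from_qtl = min(n_from_qtl, len(edqtl))
    qtl_snps = (rng.choice(edqtl.snp_id.to_numpy(), size=n_from_qtl, replace=False)
                if n_from_qtl else np.array([], dtype=object))
    pool = v[~v.id.isin(set(qtl_snps))]
    extra = pool.sample(n=config.n_gwas_causal - n_from_qtl,
                        random_state=np.random.RandomState(rng.integers(2**31)))["id"].to_numpy()
    causal_ids = np.concatenate([qtl_snps, extra])
    effects = rng.normal(0.0, config.gwas_effect_sd, size=len(causal_ids))
    # keep effects away from zero so the causal label is meaningful
    effects = np.sign(effects) * np.maximum(np.abs(effects), 0.15)
    gwas_causal = pd.DataFrame({
        "snp_id": causal_ids,
        "effect": effects,
        "is_edqtl": [s in set(qtl_snps) for s in causal_ids],
    })

    truth = TruthSet(
        true_sites=true_sites,
        tissue_levels=levels,
        artifact_sites=artifact_sites,
        snp_leak_sites=snp_leak_sites,
        edqtl=edqtl,
        tissue_specific_sites=tissue_specific,
        gwas_causal=gwas_causal,
    )
    truth.check_disjoint()
    return truth


# -------------------------------------------------------------- pileups

def _nb_coverage(rng, mean, k, size):
    return rng.negative_binomial(k, k / (k + mean), size=size)


def simulate_pileups(config: SimConfig, genome: Genome, genotypes: Genotypes,
                     truth: TruthSet, rng: np.random.Generator | None = None):
    """Per-sample pileup tables plus per-allele counts for het individuals.

    Edited read counts are Binomial(coverage, level) with
    level = invlogit(base + slope * dosage) at edQTL sites; artifact
    mismatches appear in every sample at their planted level; het genomic
    SNPs leak as ~50% mismatches; uniform base errors produce sporadic
    low-count rows.
    """
    rng = rng or np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    tissues = [f"tissue{t + 1}" for t in range(config.n_tissues)]
    tissue_of = genotypes.sample_tissue
    samples = genotypes.sample_names

    ts = truth.true_sites
    n_sites = len(ts)
    site_tissue_logit = logit(np.clip(truth.tissue_levels, 1e-4, 1 - 1e-4))

    # map edQTL slope/dosage onto sites
    slope = np.zeros(n_sites)
    dosage_row = np.zeros((n_sites, len(samples)))
    snp_index = {sid: i for i, sid in enumerate(genotypes.variants.id)}
    site_index = {sid: i for i, sid in enumerate(ts.site_id)}
    for q in truth.edqtl.itertuples(index=False):
        i = site_index[q.site_id]
        slope[i] = q.slope
        dosage_row[i] = genotypes.dosages[snp_index[q.snp_id]]

    leak = truth.snp_leak_sites
    leak_dos = np.stack([genotypes.dosages[snp_index[s]] for s in leak.snp_id]) \
        if len(leak) else np.zeros((0, len(samples)))
    art = truth.artifact_sites

    chrom_codes = {c: _encode(s) for c, s in genome.sequences.items()}
    chrom_len = {c: len(s) for c, s in genome.sequences.items()}

    pileups: dict[str, pd.DataFrame] = {}
    allelic_rows = []

    # precompute allelic metadata for edQTL (site, snp) groups
    het_info = []
    for q in truth.edqtl.itertuples(index=False):
        i = site_index[q.site_id]
        d = genotypes.dosages[snp_index[q.snp_id]]
        het_info.append((q.site_id, q.snp_id, i, q.slope, d))

    for j, sample in enumerate(samples):
        t = tissues.index(tissue_of[sample])
        rows = []

        # true sites
        cov = _nb_coverage(rng, config.coverage_mean, config.coverage_dispersion, n_sites)
        lg = site_tissue_logit[:, t] + slope * dosage_row[:, j] \
            + rng.normal(0.0, config.sample_level_sd, size=n_sites)
        level = expit(lg)
        edited = rng.binomial(cov, level)
        rows.append(pd.DataFrame({
            "chrom": ts.chrom, "pos0": ts.pos0, "ref": ts.ref, "alt": ts.alt,
            "coverage": cov, "edited": edited,
        }))

        # artifact sites
        if len(art):
            cov_a = _nb_coverage(rng, config.coverage_mean, config.coverage_dispersion, len(art))
            ed_a = rng.binomial(cov_a, art.level.to_numpy())
            rows.append(pd.DataFrame({
                "chrom": art.chrom, "pos0": art.pos0, "ref": art.ref, "alt": art.alt,
                "coverage": cov_a, "edited": ed_a,
            }))

        # SNP-leak sites
        if len(leak):
            cov_l = _nb_coverage(rng, config.coverage_mean, config.coverage_dispersion, len(leak))
            d = leak_dos[:, j]
            p_alt = np.select([d == 0, d == 1, d == 2], [config.base_error_rate, 0.5, 1.0])
            ed_l = rng.binomial(cov_l, p_alt)
            rows.append(pd.DataFrame({
                "chrom": leak.chrom, "pos0": leak.pos0, "ref": leak.ref, "alt": leak.alt,
                "coverage": cov_l, "edited": ed_l,
            }))

        # sporadic base-error rows at random positions
        n_err = rng.poisson(config.errors_per_sample)
        err_rows = []
        for _ in range(n_err):
            chrom = f"chr{int(rng.integers(1, config.n_chromosomes + 1))}"
            p = int(rng.integers(0, chrom_len[chrom]))
            code = chrom_codes[chrom][p]
            ref = BASES[code] if code >= 0 else "A"
            alt = str(rng.choice([b for b in BASES if b != ref]))
            c = int(_nb_coverage(rng, config.coverage_mean, config.coverage_dispersion, 1)[0])
            e = 1 + int(rng.binomial(max(c - 1, 0), config.base_error_rate))
            err_rows.append((chrom, p, ref, alt, c, e))
        if err_rows:
            rows.append(pd.DataFrame(err_rows, columns=["chrom", "pos0", "ref", "alt", "coverage", "edited"]))

        df = pd.concat(rows, ignore_index=True)
        df = df.drop_duplicates(["chrom", "pos0"], keep="first")
        df = df[df.coverage > 0].reset_index(drop=True)
        n = len(df)
        counts = {b: np.zeros(n, dtype=np.int64) for b in BASES}
        ref_arr = df.ref.to_numpy()
        alt_arr = df.alt.to_numpy()
        cov_arr = df.coverage.to_numpy()
        ed_arr = np.minimum(df.edited.to_numpy(), cov_arr)
        for b in BASES:
            counts[b] += np.where(ref_arr == b, cov_arr - ed_arr, 0)
            counts[b] += np.where(alt_arr == b, ed_arr, 0)
        out = pd.DataFrame({
            "chrom": df.chrom,
            "pos": df.pos0 + 1,  # pileup tables are 1-based
            "ref": df.ref,
            "A": counts["A"], "C": counts["C"], "G": counts["G"], "T": counts["T"],
            "meanBQ": np.round(np.clip(rng.normal(32, 1.5, n), 20, 40), 2),
            "meanMQ": np.round(np.clip(rng.normal(45, 3, n), 20, 60), 2),
            "n_mismatch_in_first6": rng.binomial(ed_arr, 6 / 76.0),
        })
        pileups[sample] = out

        # per-allele counts at edQTL sites for het individuals
        for site_id, snp_id, i, s, d in het_info:
            if d[j] != 1:
                continue
            c = int(_nb_coverage(rng, config.coverage_mean, config.coverage_dispersion, 1)[0])
            c_ref = int(rng.binomial(c, 0.5))
            c_alt = c - c_ref
            b = site_tissue_logit[i, t]
            e_ref = int(rng.binomial(c_ref, expit(b)))
            e_alt = int(rng.binomial(c_alt, expit(b + 2 * s)))
            allelic_rows.append((sample, snp_id, site_id, "ref", e_ref, c_ref))
            allelic_rows.append((sample, snp_id, site_id, "alt", e_alt, c_alt))

    allelic = pd.DataFrame(
        allelic_rows,
        columns=["individual", "snp", "site", "allele", "edited", "total"],
    )
    return pileups, allelic


# ----------------------------------------------------------------- GWAS

def simulate_gwas(config: SimConfig, genotypes: Genotypes, truth: TruthSet,
                  rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Marginal single-SNP summary statistics for a quantitative trait
    whose causal set overlaps the planted edQTLs."""
    rng = rng or np.random.default_rng(np.random.SeedSequence([config.seed, 4]))
    v = genotypes.variants
    n = config.n_gwas_samples
    H = _haplotypes(rng, v.maf.to_numpy(), v.block.to_numpy(), 2 * n, config.ld_block_flip)
    G = (H[:, ::2] + H[:, 1::2]).astype(np.float64)   # (m, n)

    y = rng.normal(0.0, 1.0, size=n)
    snp_index = {sid: i for i, sid in enumerate(v.id)}
    for c in truth.gwas_causal.itertuples(index=False):
        g = G[snp_index[c.snp_id]]
        sd = g.std()
        if sd > 0:
            y += c.effect * (g - g.mean()) / sd

    Gc = G - G.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    ss_g = (Gc ** 2).sum(axis=1)
    ok = ss_g > 0
    beta = np.full(len(v), np.nan)
    se = np.full(len(v), np.nan)
    beta[ok] = (Gc[ok] @ yc) / ss_g[ok]
    rss = (yc ** 2).sum() - beta[ok] ** 2 * ss_g[ok]
    se[ok] = np.sqrt(np.maximum(rss, 1e-12) / (n - 2) / ss_g[ok])
    z = beta / se
    from scipy.stats import t as t_dist
    p = 2 * t_dist.sf(np.abs(z), df=n - 2)
    return pd.DataFrame({
        "snp": v.id, "beta": beta, "se": se, "z": z,
        "p": np.clip(p, np.finfo(float).tiny, 1.0), "n": n,
    })


# ------------------------------------------------------------ assembly

def simulate_all(config: SimConfig) -> SimBundle:
    """Run every generator stage under one master seed."""
    config.validate()
    genome = simulate_genome(config)
    genotypes = simulate_genotypes(config, genome)
    truth = simulate_truth(config, genome, genotypes)
    pileups, allelic = simulate_pileups(config, genome, genotypes, truth)
    gwas = simulate_gwas(config, genotypes, truth)
    return SimBundle(config, genome, genotypes, truth, pileups, allelic, gwas)


def write_bundle(bundle: SimBundle, outdir: str) -> None:
    """Write the bundle to the pipeline's flat-file interfaces."""
    import os

    os.makedirs(outdir, exist_ok=True)
    g = bundle.genome
    ekio.write_fasta(g.sequences, os.path.join(outdir, "genome.fa"))
    ekio.write_bed(g.repeats, os.path.join(outdir, "repeats.bed"))
    ekio.write_bed(g.duplications, os.path.join(outdir, "duplications.bed"))
    ekio.write_bed(g.homopolymers, os.path.join(outdir, "homopolymers.bed"))
    ekio.write_gtf(g.genes, os.path.join(outdir, "genes.gtf"))
    gt = bundle.genotypes
    ekio.write_vcf(os.path.join(outdir, "genotypes.vcf"), gt.variants,
                   gt.dosages.astype(int), gt.sample_names)
    ekio.write_vcf(os.path.join(outdir, "known_snps.vcf"), gt.variants)
    ts = bundle.truth.true_sites.copy()
    for t in range(bundle.config.n_tissues):
        ts[f"level_tissue{t + 1}"] = bundle.truth.tissue_levels[:, t]
    ts.to_csv(os.path.join(outdir, "truth_sites.tsv"), sep="\t", index=False)
    bundle.truth.artifact_sites.to_csv(os.path.join(outdir, "truth_artifacts.tsv"), sep="\t", index=False)
    bundle.truth.snp_leak_sites.to_csv(os.path.join(outdir, "truth_snp_leaks.tsv"), sep="\t", index=False)
    bundle.truth.edqtl.to_csv(os.path.join(outdir, "truth_edqtl.tsv"), sep="\t", index=False)
    pdir = os.path.join(outdir, "pileups")
    os.makedirs(pdir, exist_ok=True)
    for sample, df in bundle.pileups.items():
        ekio.write_pileup(df, os.path.join(pdir, f"{sample}.pileup.tsv"))
    bundle.allelic_counts.to_csv(os.path.join(outdir, "allelic_counts.tsv"), sep="\t", index=False)
    ekio.write_gwas(bundle.gwas, os.path.join(outdir, "gwas.tsv"))
    bundle.genotypes.sample_tissue.rename_axis("sample").reset_index().to_csv(
        os.path.join(outdir, "samples.tsv"), sep="\t", index=False)
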