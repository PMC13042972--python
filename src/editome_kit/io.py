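"""Readers and writers for the flat-file formats the pipeline consumes.

All genomic intervals are handled as 0-based half-open internally; the
1-based conventions of VCF/GTF/pileup tables are converted at the boundary.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

PILEUP_COLUMNS = [
    "chrom", "pos", "ref", "A", "C", "G", "T",
    "meanBQ", "meanMQ", "n_mismatch_in_first6",
]

GWAS_COLUMNS = ["snp", "beta", "se", "z", "p", "n"]


# ---------------------------------------------------------------- FASTA

def write_fasta(sequences: Mapping[str, str], path: str) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, path, "fasta")


def read_fasta(path: str) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


# ------------------------------------------------------------------ BED

def write_bed(df: pd.DataFrame, path: str) -> None:
    """Write a BED file from a frame with chrom/start/end (+ extra cols)."""
    cols = ["chrom", "start", "end"] + [c for c in df.columns if c not in ("chrom", "start", "end")]
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def read_bed(path: str, extra_cols: Iterable[str] = ()) -> pd.DataFrame:
    names = ["chrom", "start", "end"] + list(extra_cols)
    if os.path.getsize(path) == 0:
        return pd.DataFrame(columns=names)
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.iloc[:, : len(names)]
    df.columns = names[: df.shape[1]]
    return df


# ------------------------------------------------------------------ GTF

def write_gtf(features: pd.DataFrame, path: str) -> None:
    """Write gene/transcript/exon/CDS features.

    ``features`` uses internal 0-based half-open ``start``/``end`` plus
    chrom, feature, strand, frame, gene_id, transcript_id.
    """
    with open(path, "w") as fh:
        for row in features.itertuples(index=False):
            attrs = f'gene_id "{row.gene_id}"; transcript_id "{row.transcript_id}";'
            frame = str(getattr(row, "frame", "."))
            fh.write(
                "\t".join(
                    [
                        row.chrom, "simgen", row.feature,
                        str(int(row.start) + 1), str(int(row.end)),  # GTF is 1-based closed
                        ".", row.strand, frame, attrs,
                    ]
                )
                + "\n"
            )


def read_gtf(path: str) -> pd.DataFrame:
    """Read a GTF into a frame with 0-based half-open coordinates."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            attrs = dict(
                item.strip().split(" ", 1)
                for item in f[8].strip().strip(";").split(";")
                if item.strip()
            )
            rows.append(
                {
                    "chrom": f[0],
                    "feature": f[2],
                    "start": int(f[3]) - 1,
                    "end": int(f[4]),
                    "strand": f[6],
                    "frame": f[7],
                    "gene_id": attrs.get("gene_id", "").strip('"'),
                    "transcript_id": attrs.get("transcript_id", "").strip('"'),
                }
            )
    return pd.DataFrame(rows)


# ------------------------------------------------------------------ VCF

def write_vcf(
    path: str,
    variants: pd.DataFrame,
    genotypes: np.ndarray | None = None,
    sample_names: list[str] | None = None,
) -> None:
    """Write biallelic SNPs (frame: chrom, pos0, id, ref, alt, maf).

    ``genotypes`` is an (n_variants, n_samples) dosage matrix of 0/1/2.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=AF,Number=A,Type=Float,Description="Allele frequency">\n')
        if genotypes is not None:
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO"]
        if genotypes is not None:
            header += ["FORMAT"] + list(sample_names)
        fh.write("\t".join(header) + "\n")
        gt_str = {0: "0/0", 1: "0/1", 2: "1/1"}
        for i, row in enumerate(variants.itertuples(index=False)):
            fields = [
                row.chrom, str(int(row.pos0) + 1), row.id, row.ref, row.alt,
                ".", "PASS", f"AF={row.maf:.4f}",
            ]
            if genotypes is not None:
                fields.append("GT")
                fields.extend(gt_str[int(g)] for g in genotypes[i])
            fh.write("\t".join(fields) + "\n")


def read_vcf(path: str, with_genotypes: bool = True):
    """Read biallelic SNPs via cyvcf2.

    Returns (variants frame with 0-based pos0, dosage matrix or None,
    sample names). Malformed rows raise with the 1-based line context
    from cyvcf2.
    """
    from cyvcf2 import VCF

    vcf = VCF(path)
    samples = list(vcf.samples)
    rows, dosages = [], []
    for var in vcf:
        rows.append(
            {
                "chrom": var.CHROM,
                "pos0": var.start,
                "id": var.ID or f"{var.CHROM}:{var.POS}",
                "ref": var.REF,
                "alt": var.ALT[0] if var.ALT else ".",
                "maf": float(var.INFO.get("AF", np.nan)),
            }
        )
        if with_genotypes and samples:
            gts = var.gt_types.astype(float)  # 0=hom ref,1=het,2=unknown,3=hom alt
            dosages.append(np.select([gts == 0, gts == 1, gts == 3], [0.0, 1.0, 2.0], np.nan))
    variants = pd.DataFrame(rows)
    G = np.asarray(dosages) if (with_genotypes and samples and dosages) else None
    return variants, G, samples


# ---------------------------------------------------------------- pileup

def write_pileup(df: pd.DataFrame, path: str) -> None:
    """Write a per-sample pileup table (``pos`` 1-based in the file)."""
    out = df[PILEUP_COLUMNS].copy()
    out.to_csv(path, sep="\t", index=False)


def read_pileup(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(PILEUP_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"pileup table {path} lacks columns: {sorted(missing)}")
    return df


# ------------------------------------------------------------------ GWAS

def write_gwas(df: pd.DataFrame, path: str) -> None:
    df[GWAS_COLUMNS].to_csv(path, sep="\t", index=False)


def read_gwas(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(GWAS_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"GWAS table {path} lacks columns: {sorted(missing)}")
    return df


# ------------------------------------------------- interval utilities

def merge_intervals(intervals: np.ndarray) -> np.ndarray:
    """Merge 0-based half-open [start, end) intervals; returns sorted array."""
    if len(intervals) == 0:
        return np.empty((0, 2), dtype=np.int64)
    iv = np.asarray(intervals, dtype=np.int64)
    iv = iv[np.argsort(iv[:, 0], kind="stable")]
    merged = [list(iv[0])]
    for s, e in iv[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return np.asarray(merged, dtype=np.int64)


class IntervalIndex:
    """Membership queries against merged per-chromosome interval sets."""

    def __init__(self, df: pd.DataFrame):
        self._by_chrom: dict[str, np.ndarray] = {}
        if len(df):
            for chrom, sub in df.groupby("chrom"):
                self._by_chrom[str(chrom)] = merge_intervals(
                    sub[["start", "end"]].to_numpy()
                )

    def contains(self, chrom, pos) -> np.ndarray:
        """Vectorised half-open membership for positions on one chromosome."""
        pos = np.atleast_1d(np.asarray(pos, dtype=np.int64))
        iv = self._by_chrom.get(str(chrom))
        if iv is None or len(iv) == 0:
            return np.zeros(pos.shape, dtype=bool)
        idx = np.searchsorted(iv[:, 0], pos, side="right") - 1
        ok = idx >= 0
        out = np.zeros(pos.shape, dtype=bool)
        out[ok] = pos[ok] < iv[idx[ok], 1]
        return out

    def contains_df(self, df: pd.DataFrame, pos_col: str = "pos0") -> np.ndarray:
        out = np.zeros(len(df), dtype=bool)
        chroms = df["chrom"].to_numpy()
        positions = df[pos_col].to_numpy()
        for chrom in np.unique(chroms):
            m = chroms == chrom
            out[m] = self.contains(chrom, positions[m])
        return out
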