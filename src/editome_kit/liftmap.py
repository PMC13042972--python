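"""Cross-species coordinate lifting and conservation analysis.

Implements the UCSC chain format: each chain aligns an interval of the
source assembly to an interval of the target assembly through ungapped
blocks separated by source/target gaps.  Positions are lifted through the
block arithmetic (strand-aware: '-' strand chains use reverse-complement
coordinates); positions falling in a gap fail with reason "unmapped".
Interval lifting additionally requires a minimum fraction of bases inside
aligned blocks.  Downstream: conservation-score filtering (strictly
greater than threshold), exact-position catalog overlap, permutation
enrichment against random genomic positions, and level correlation at
conserved sites.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)


@dataclass
class ChainBlock:
    size: int
    dt: int  # gap in the source genome after this block
    dq: int  # gap in the target genome after this block


@dataclass
class ChainAlignment:
    score: float
    chain_id: str
    s_name: str
    s_size: int
    s_strand: str
    s_start: int
    s_end: int
    t_name: str
    t_size: int
    t_strand: str
    t_start: int
    t_end: int
    blocks: list[ChainBlock] = field(default_factory=list)

    def validate(self) -> None:
        s_span = sum(b.size + b.dt for b in self.blocks[:-1]) + self.blocks[-1].size
        t_span = sum(b.size + b.dq for b in self.blocks[:-1]) + self.blocks[-1].size
        if s_span != self.s_end - self.s_start:
            raise ValueError(f"chain {self.chain_id}: source block arithmetic inconsistent")
        if t_span != self.t_end - self.t_start:
            raise ValueError(f"chain {self.chain_id}: target block arithmetic inconsistent")
        if any(b.size <= 0 for b in self.blocks):
            raise ValueError(f"chain {self.chain_id}: non-positive block size")


@dataclass
class LiftResult:
    success: bool
    chrom: str | None = None
    pos: int | None = None
    strand: str | None = None
    reason: str | None = None
    matched_fraction: float | None = None
    start: int | None = None
    end: int | None = None


def parse_chain(path: str) -> list[ChainAlignment]:
    chains: list[ChainAlignment] = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        if not line.startswith("chain"):
            raise ValueError(f"expected chain header at line {i + 1}")
        f = line.split()
        if len(f) < 12:
            raise ValueError(f"truncated chain header at line {i + 1}")
        ch = ChainAlignment(
            score=float(f[1]),
            s_name=f[2], s_size=int(f[3]), s_strand=f[4],
            s_start=int(f[5]), s_end=int(f[6]),
            t_name=f[7], t_size=int(f[8]), t_strand=f[9],
            t_start=int(f[10]), t_end=int(f[11]),
            chain_id=f[12] if len(f) > 12 else str(len(chains) + 1),
        )
        i += 1
        done = False
        while i < len(lines):
            row = lines[i].strip()
            i += 1
            if not row:
                continue
            parts = row.split()
            if len(parts) == 3:
                ch.blocks.append(ChainBlock(int(parts[0]), int(parts[1]), int(parts[2])))
            elif len(parts) == 1:
                ch.blocks.append(ChainBlock(int(parts[0]), 0, 0))
                done = True
                break
            else:
                raise ValueError(f"malformed block line {i} in chain {ch.chain_id}")
        if not done:
            raise ValueError(f"truncated chain {ch.chain_id}: missing final block")
        ch.validate()
        chains.append(ch)
    return chains


def _lift_in_chain(pos: int, ch: ChainAlignment) -> int | None:
    """Map a source-forward position through one chain; None if in a gap."""
    if ch.s_strand == "-":
        p = ch.s_size - 1 - pos
    else:
        p = pos
    if not (ch.s_start <= p < ch.s_end):
        return None
    s_cur, t_cur = ch.s_start, ch.t_start
    for b in ch.blocks:
        if s_cur <= p < s_cur + b.size:
            t = t_cur + (p - s_cur)
            if ch.t_strand == "-":
                return ch.t_size - 1 - t
            return t
        s_cur += b.size + b.dt
        t_cur += b.size + b.dq
    return None


def lift_position(chrom: str, pos: int, chains: list[ChainAlignment]) -> LiftResult:
    """Lift one position; overlapping chains resolve by highest score."""
    cands = [c for c in chains if c.s_name == chrom]
    cands.sort(key=lambda c: -c.score)
    covered = False
    for ch in cands:
        p = ch.s_size - 1 - pos if ch.s_strand == "-" else pos
        if not (ch.s_start <= p < ch.s_end):
            continue
        covered = True
        t = _lift_in_chain(pos, ch)
        if t is not None:
            strand = "+" if ch.s_strand == ch.t_strand else "-"
            return LiftResult(True, ch.t_name, int(t), strand)
        break  # the best covering chain decides; a gap means unmapped
    return LiftResult(False, reason="unmapped" if covered else "no_chain")


def lift_interval(chrom: str, start: int, end: int,
                  chains: list[ChainAlignment], min_match: float = 0.5) -> LiftResult:
    """Lift an interval; requires >= min_match of its bases inside aligned
    blocks of the selected (highest-score covering) chain."""
    cands = sorted((c for c in chains if c.s_name == chrom), key=lambda c: -c.score)
    for ch in cands:
        if ch.s_strand == "-":
            lo, hi = ch.s_size - end, ch.s_size - start
        else:
            lo, hi = start, end
        if hi <= ch.s_start or lo >= ch.s_end:
            continue
        mapped = [_lift_in_chain(p, ch) for p in range(start, end)]
        ok = [t for t in mapped if t is not None]
        frac = len(ok) / (end - start)
        if frac < min_match:
            return LiftResult(False, reason="below_min_match", matched_fraction=frac)
        strand = "+" if ch.s_strand == ch.t_strand else "-"
        return LiftResult(True, ch.t_name, None, strand,
                          matched_fraction=frac, start=min(ok), end=max(ok) + 1)
    return LiftResult(False, reason="no_chain")


def invert_chain(ch: ChainAlignment) -> ChainAlignment:
    """Swap source and target roles (valid for lifting back)."""
    inv = ChainAlignment(
        score=ch.score, chain_id=ch.chain_id + "_inv",
        s_name=ch.t_name, s_size=ch.t_size, s_strand=ch.t_strand,
        s_start=ch.t_start, s_end=ch.t_end,
        t_name=ch.s_name, t_size=ch.s_size, t_strand=ch.s_strand,
        t_start=ch.s_start, t_end=ch.s_end,
        blocks=[ChainBlock(b.size, b.dq, b.dt) for b in ch.blocks],
    )
    inv.validate()
    return inv


def lift_sites(sites: pd.DataFrame, chains: list[ChainAlignment]) -> pd.DataFrame:
    """Lift a frame of single-base sites (chrom, pos0); min_match does not
    apply to single positions."""
    rows = []
    for s in sites.itertuples(index=False):
        r = lift_position(s.chrom, int(s.pos0), chains)
        rows.append({
            "chrom": s.chrom, "pos0": int(s.pos0),
            "lifted": r.success,
            "t_chrom": r.chrom, "t_pos0": r.pos, "t_strand": r.strand,
            "reason": r.reason,
        })
    return pd.DataFrame(rows)


# ------------------------------------------------------- conservation

def read_bedgraph(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "start", "end", "score"])
    return df


def score_at(track: pd.DataFrame, chrom: str, pos: int) -> float:
    sub = track[(track.chrom == chrom) & (track.start <= pos) & (pos < track.end)]
    return float(sub.score.iloc[0]) if len(sub) else np.nan


def conservation_filter(lifted: pd.DataFrame, track: pd.DataFrame,
                        threshold: float = 0.5) -> pd.DataFrame:
    """Keep lifted sites with conservation score strictly > threshold;
    sites without track coverage are dropped and counted."""
    ok_rows = []
    n_missing = 0
    for r in lifted.itertuples(index=False):
        if not r.lifted:
            continue
        s = score_at(track, r.t_chrom, r.t_pos0)
        if np.isnan(s):
            n_missing += 1
            continue
        if s > threshold:
            ok_rows.append({**r._asdict(), "phastcons": s})
    if n_missing:
        log.info("conservation filter: %d lifted sites without track coverage", n_missing)
    return pd.DataFrame(ok_rows)


def overlap_catalog(lifted: pd.DataFrame, catalog: pd.DataFrame) -> pd.DataFrame:
    """Exact-position, strand-agnostic membership in the target-species
    editing catalog (BED-style frame chrom/start)."""
    cat = set(zip(catalog.chrom, catalog.start))
    out = lifted.copy()
    out["in_catalog"] = [
        (c, p) in cat for c, p in zip(out.t_chrom, out.t_pos0)
    ]
    return out


def permutation_enrichment(n_query: int, observed_overlap: int,
                           genome_sizes: dict[str, int], catalog: pd.DataFrame,
                           n_perm: int = 1000, seed: int = 0) -> dict:
    """Fold enrichment of catalog overlap vs random genomic positions.

    fold = observed / mean(null); empirical p = (1 + #{null >= obs}) / (n_perm + 1).
    """
    rng = np.random.default_rng(seed)
    chroms = list(genome_sizes)
    sizes = np.array([genome_sizes[c] for c in chroms], dtype=float)
    probs = sizes / sizes.sum()
    cat_pos = {c: np.unique(g.start.to_numpy()) for c, g in catalog.groupby("chrom")}
    null = np.empty(n_perm)
    for b in range(n_perm):
        ci = rng.choice(len(chroms), size=n_query, p=probs)
        pos = (rng.random(n_query) * sizes[ci]).astype(np.int64)
        hits = 0
        for c in np.unique(ci):
            cp = cat_pos.get(chroms[c])
            if cp is not None:
                hits += int(np.isin(pos[ci == c], cp).sum())
        null[b] = hits
    mean_null = float(null.mean())
    fold = observed_overlap / mean_null if mean_null > 0 else np.inf
    emp_p = float((1 + np.sum(null >= observed_overlap)) / (n_perm + 1))
    return {
        "fold": float(fold), "empirical_p": emp_p,
        "mean_null_overlap": mean_null,
        "infinite_fold": mean_null == 0,
    }


def level_correlation(source_levels: np.ndarray, target_levels: np.ndarray) -> dict:
    """Pearson r and r^2 of editing levels at conserved sites."""
    x = np.asarray(source_levels, dtype=float)
    y = np.asarray(target_levels, dtype=float)
    m = np.isfinite(x) & np.isfinite(y)
    if m.sum() < 3:
        raise ValueError("need at least 3 paired levels")
    r = float(stats.pearsonr(x[m], y[m]).statistic)
    return {"r": r, "r2": r ** 2, "n": int(m.sum())}
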