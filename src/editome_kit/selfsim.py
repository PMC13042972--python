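"""Genome self-similarity mask for alignment-artifact filtering.

The reference genome is tiled into fixed-length windows (default 76 bp,
step 19 bp) which are re-aligned against the whole genome by exact k-mer
seeding followed by ungapped evaluation on both strands.  Windows with an
off-locus ungapped alignment of >= 61 aligned bases at >= 94% identity mark
both the window and the hit locus as "self-similar"; mismatches falling in
such regions outside annotated repeats are treated as alignment artifacts
downstream.

The aligner is deliberately ungapped: the masking decision is a pure
length + identity threshold, so a gapped alignment engine adds nothing at
the scales this package targets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import IntervalIndex, merge_intervals
from .simgen import _encode


@dataclass
class WindowSpec:
    window_length: int = 76
    step: int = 19

    def __post_init__(self):
        if self.window_length <= 0:
            raise ValueError("window_length must be > 0")
        if not 0 < self.step <= self.window_length:
            raise ValueError("step must be in (0, window_length]")


@dataclass
class SimilarityThresholds:
    min_aligned_length: int = 61
    min_identity: float = 0.94
    seed_kmer: int = 16
    seed_stride: int = 8
    mismatch_penalty: float = 3.0  # ungapped extension scoring: match +1


@dataclass
class SimilarityMask:
    """Merged self-similar intervals, 0-based half-open, per chromosome."""

    intervals: pd.DataFrame  # chrom, start, end

    def __post_init__(self):
        self._index = IntervalIndex(self.intervals)

    def is_masked(self, chrom: str, pos) -> np.ndarray:
        return self._index.contains(chrom, pos)

    def total_bases(self) -> int:
        return int((self.intervals.end - self.intervals.start).sum()) if len(self.intervals) else 0


def tile_genome(sequences: dict[str, str], spec: WindowSpec | None = None) -> pd.DataFrame:
    """Pure sliding windows; no tail window beyond the last full one."""
    spec = spec or WindowSpec()
    rows = []
    for chrom, seq in sequences.items():
        L = len(seq)
        if L < spec.window_length:
            continue
        n = (L - spec.window_length) // spec.step + 1
        starts = np.arange(n) * spec.step
        rows.append(pd.DataFrame({
            "chrom": chrom, "start": starts, "end": starts + spec.window_length,
        }))
    if not rows:
        return pd.DataFrame(columns=["chrom", "start", "end"])
    return pd.concat(rows, ignore_index=True)


class _KmerIndex:
    """Sorted-array exact k-mer lookup over the concatenated genome."""

    def __init__(self, sequences: dict[str, str], k: int):
        self.k = k
        self.chroms = list(sequences)
        codes = []
        offsets = {}
        off = 0
        gap = np.full(k, -1, dtype=np.int8)  # separator prevents cross-chrom k-mers
        for c in self.chroms:
            offsets[c] = off
            arr = _encode(sequences[c])
            codes.append(arr)
            codes.append(gap)
            off += len(arr) + k
        self.offsets = offsets
        self.codes = np.concatenate(codes)
        self.bounds = {c: (offsets[c], offsets[c] + len(sequences[c])) for c in self.chroms}
        keys = _kmer_keys(self.codes, k)
        valid = keys >= 0
        self.positions = np.flatnonzero(valid)
        self.keys = keys[valid]
        order = np.argsort(self.keys, kind="stable")
        self.keys = self.keys[order]
        self.positions = self.positions[order]

    def lookup(self, query_keys: np.ndarray):
        """For each query key, return (start, stop) slice into .positions."""
        lo = np.searchsorted(self.keys, query_keys, side="left")
        hi = np.searchsorted(self.keys, query_keys, side="right")
        return lo, hi

    def to_chrom(self, gpos: np.ndarray):
        chroms = np.empty(len(gpos), dtype=object)
        local = np.empty(len(gpos), dtype=np.int64)
        for c in self.chroms:
            s, e = self.bounds[c]
            m = (gpos >= s) & (gpos < e)
            chroms[m] = c
            local[m] = gpos[m] - s
        return chroms, local


def _kmer_keys(codes: np.ndarray, k: int) -> np.ndarray:
    """2-bit packed k-mer keys; -1 where the window contains a non-ACGT code."""
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    c = codes.astype(np.int64)
    keys = np.zeros(n, dtype=np.int64)
    bad = np.zeros(n, dtype=bool)
    for i in range(k):
        keys = (keys << 2) | (c[i:i + n] & 3)
        bad |= c[i:i + n] < 0
    keys[bad] = -1
    return keys


def _revcomp_keys(keys: np.ndarray, k: int) -> np.ndarray:
    """Reverse-complement of 2-bit packed keys (complement = 3 - code)."""
    out = np.zeros_like(keys)
    tmp = keys.copy()
    for _ in range(k):
        out = (out << 2) | (3 - (tmp & 3))
        tmp >>= 2
    out[keys < 0] = -1
    return out


def _best_span(match: np.ndarray, thresholds: SimilarityThresholds):
    """Maximal-scoring ungapped segment per row of a (N, W) match matrix.

    Scoring is match +1 / mismatch -penalty (the ungapped analogue of a
    local aligner), so extension never chains through mismatch-dense
    flanks.  Returns per row: aligned_length, identity, span start; the
    segment always begins and ends on a match.
    """
    N, W = match.shape
    step = np.where(match, 1.0, -thresholds.mismatch_penalty)
    cur = np.zeros(N)
    cur_start = np.zeros(N, dtype=np.int32)
    best = np.zeros(N)
    best_start = np.zeros(N, dtype=np.int32)
    best_end = np.zeros(N, dtype=np.int32)
    for j in range(W):
        reset = cur <= 0
        cur_start = np.where(reset, j, cur_start)
        cur = np.where(reset, 0.0, cur) + step[:, j]
        better = cur > best
        best = np.where(better, cur, best)
        best_start = np.where(better, cur_start, best_start)
        best_end[better] = j + 1
    aligned_length = np.where(best > 0, best_end - best_start, 0).astype(np.int32)
    csum = np.zeros((N, W + 1), dtype=np.int32)
    np.cumsum(match, axis=1, out=csum[:, 1:])
    n_match = csum[np.arange(N), best_end] - csum[np.arange(N), best_start]
    with np.errstate(invalid="ignore", divide="ignore"):
        identity = np.where(aligned_length > 0, n_match / np.maximum(aligned_length, 1), 0.0)
    return aligned_length, identity, best_start


def align_windows(
    sequences: dict[str, str],
    windows: pd.DataFrame,
    thresholds: SimilarityThresholds | None = None,
    index: _KmerIndex | None = None,
) -> pd.DataFrame:
    """Seed-and-extend all windows against the genome on both strands.

    Returns one row per (window, locus) candidate with columns:
    window_idx, chrom, start, end (query), t_chrom, t_start, t_end (hit),
    strand, aligned_length, identity, is_source_locus.
    """
    thresholds = thresholds or SimilarityThresholds()
    k = thresholds.seed_kmer
    index = index or _KmerIndex(sequences, k)
    if len(windows) == 0:
        return pd.DataFrame(columns=[
            "window_idx", "chrom", "start", "end", "t_chrom", "t_start",
            "t_end", "strand", "aligned_length", "identity", "is_source_locus"])
    W = int((windows.end - windows.start).iloc[0])

    # global coordinates of windows in the concatenated code array
    gstart = windows.start.to_numpy() + np.array([index.offsets[c] for c in windows.chrom])

    # sample seed k-mers at a fixed stride within each window
    seed_off = np.arange(0, W - k + 1, thresholds.seed_stride)
    if seed_off[-1] != W - k:
        seed_off = np.append(seed_off, W - k)
    all_keys = _kmer_keys(index.codes, k)

    cand = {}  # (window_idx, strand, diagonal) -> None, insertion-ordered
    q_keys = np.concatenate([all_keys[gstart + off] for off in seed_off])
    q_rc = _revcomp_keys(q_keys, k)
    n_win = len(windows)
    win_ids = np.tile(np.arange(n_win), len(seed_off))
    offs = np.repeat(seed_off, n_win)

    for strand, keys in (("+", q_keys), ("-", q_rc)):
        lo, hi = index.lookup(keys)
        counts = hi - lo
        has = counts > 0
        for w, j, l, h in zip(win_ids[has], offs[has], lo[has], hi[has]):
            for t in index.positions[l:h]:
                if strand == "+":
                    diag = int(t) - int(gstart[w]) - int(j)
                else:
                    # window base at offset j+k-1 pairs with genome base t
                    diag = int(t) + k - 1 + int(j)   # anchor a: g(w_off) = a - w_off
                cand.setdefault((int(w), strand, diag), None)

    if not cand:
        return pd.DataFrame(columns=[
            "window_idx", "chrom", "start", "end", "t_chrom", "t_start",
            "t_end", "strand", "aligned_length", "identity", "is_source_locus"])

    wv_all = np.array([c[0] for c in cand], dtype=np.int64)
    sv_all = np.array([c[1] for c in cand])
    dv_all = np.array([c[2] for c in cand], dtype=np.int64)

    # padded code array so off-end targets compare as mismatches
    pad = W
    padded = np.full(len(index.codes) + 2 * pad, -9, dtype=np.int8)
    padded[pad:pad + len(index.codes)] = index.codes
    col = np.arange(W)

    chunks = []
    chunk_size = 100_000
    for c0 in range(0, len(wv_all), chunk_size):
        wv = wv_all[c0:c0 + chunk_size]
        sv = sv_all[c0:c0 + chunk_size]
        dv = dv_all[c0:c0 + chunk_size]
        fwd = sv == "+"
        qmat = index.codes[gstart[wv][:, None] + col[None, :]]
        tidx = np.empty((len(wv), W), dtype=np.int64)
        tidx[fwd] = (gstart[wv[fwd]] + dv[fwd])[:, None] + col[None, :]
        tidx[~fwd] = dv[~fwd][:, None] - col[None, :]
        tmat = padded[tidx + pad]
        match = np.where(
            fwd[:, None], qmat == tmat, (qmat >= 0) & (qmat == (3 - tmat))
        )

        aligned_length, identity, span_start = _best_span(match, thresholds)

        # hit interval in concatenated coordinates
        t_lo = np.where(fwd,
                        gstart[wv] + dv + span_start,
                        dv - (span_start + aligned_length) + 1)
        # assign chromosome by span midpoint; clamp spans that poke off-end
        mid = t_lo + aligned_length // 2
        t_chrom, _ = index.to_chrom(mid.astype(np.int64))
        chrom_off = np.array([index.offsets.get(c, 0) if c is not None else 0 for c in t_chrom])
        chrom_size = np.array([len(sequences[c]) if c is not None else 0 for c in t_chrom])
        t_start = np.clip(t_lo - chrom_off, 0, chrom_size)
        t_end = np.clip(t_lo + aligned_length - chrom_off, 0, chrom_size)

        q_chrom = windows.chrom.to_numpy()[wv]
        q_start = windows.start.to_numpy()[wv]
        q_end = windows.end.to_numpy()[wv]
        is_source = (sv == "+") & (t_chrom == q_chrom) & (t_start < q_end) & (t_end > q_start)

        chunks.append(pd.DataFrame({
            "window_idx": wv,
            "chrom": q_chrom, "start": q_start, "end": q_end,
            "t_chrom": t_chrom, "t_start": t_start, "t_end": t_end,
            "strand": sv,
            "aligned_length": aligned_length, "identity": identity,
            "is_source_locus": is_source,
        }))
    out = pd.concat(chunks, ignore_index=True)
    # drop degenerate hits that ran entirely off-chromosome
    return out[(out.aligned_length > 0) & out.t_chrom.notna()].reset_index(drop=True)


def align_window(sequences: dict[str, str], chrom: str, start: int,
                 spec: WindowSpec | None = None,
                 thresholds: SimilarityThresholds | None = None) -> pd.DataFrame:
    """Align a single window (convenience wrapper over align_windows)."""
    spec = spec or WindowSpec()
    win = pd.DataFrame({"chrom": [chrom], "start": [start], "end": [start + spec.window_length]})
    return align_windows(sequences, win, thresholds)


def build_similarity_mask(
    sequences: dict[str, str],
    spec: WindowSpec | None = None,
    thresholds: SimilarityThresholds | None = None,
) -> SimilarityMask:
    """Mask every window with a qualifying off-locus hit plus the hit locus
    itself (symmetric by construction)."""
    spec = spec or WindowSpec()
    thresholds = thresholds or SimilarityThresholds()
    windows = tile_genome(sequences, spec)
    hits = align_windows(sequences, windows, thresholds)
    q = hits[
        (~hits.is_source_locus)
        & (hits.aligned_length >= thresholds.min_aligned_length)
        & (hits.identity >= thresholds.min_identity)
    ]
    rows = []
    for chrom, sub in q.groupby("chrom"):
        for s, e in merge_intervals(sub[["start", "end"]].to_numpy()):
            rows.append((chrom, int(s), int(e)))
    for chrom, sub in q.groupby("t_chrom"):
        for s, e in merge_intervals(sub[["t_start", "t_end"]].to_numpy()):
            rows.append((chrom, int(s), int(e)))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    merged_rows = []
    for chrom, sub in df.groupby("chrom"):
        for s, e in merge_intervals(sub[["start", "end"]].to_numpy()):
            merged_rows.append((chrom, int(s), int(e)))
    return SimilarityMask(pd.DataFrame(merged_rows, columns=["chrom", "start", "end"]))


def is_masked(chrom: str, pos: int, mask: SimilarityMask) -> bool:
    return bool(mask.is_masked(chrom, [pos])[0])
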