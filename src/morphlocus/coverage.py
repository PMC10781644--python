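"""Window read depth, background standardization and content genotyping.

Reads are placed on an assembly by exact unique-k-mer seed voting: every
k-mer that occurs exactly once in the assembly (on either strand) is an
anchor; each read's seed hits vote for an implied (start, orientation) and
the read is placed at the majority vote.  Reads with no unique seeds or a
tied top vote are discarded, which suppresses placements inside repeats the
same way a mapping-quality filter does in a full aligner.

Depth is then averaged over fixed non-overlapping windows (default 500 bp),
windows with more than 10% repeat-annotated content are excluded, and each
sample's window means are divided by that sample's mean depth over a large
neutral background region.  Standardized depth sits near 1 for content on
both haplotypes, near 0.5 for heterozygous content and near 0 for content
the sample lacks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import _seq, cli_io
from .synthio import ReadSet

log = logging.getLogger("morphlocus")


@dataclass
class SeedIndex:
    """Unique exact k-mer anchors of an assembly."""

    assembly_id: str
    k: int
    length: int
    codes: np.ndarray  # sorted canonical codes occurring exactly once
    pos: np.ndarray  # 0-based start of each anchor on the assembly
    is_fwd: np.ndarray  # assembly forward orientation == canonical


def build_seed_index(assembly: np.ndarray, k: int = 31, assembly_id: str = "assembly") -> SeedIndex:
    asm = np.asarray(assembly, dtype=np.uint8)
    codes, is_fwd = _seq.canonical_codes(asm, k)
    valid = _seq.valid_windows(asm, k)
    pos = np.flatnonzero(valid)
    codes, is_fwd = codes[pos], is_fwd[pos]
    order = np.argsort(codes, kind="stable")
    codes, is_fwd, pos = codes[order], is_fwd[order], pos[order]
    uniq, start, counts = np.unique(codes, return_index=True, return_counts=True)
    once = counts == 1
    sel = start[once]
    return SeedIndex(assembly_id, k, len(asm), codes[sel], pos[sel], is_fwd[sel])


@dataclass
class MappingStats:
    n_reads: int
    n_placed: int
    n_no_seed: int
    n_ambiguous: int

    @property
    def placed_fraction(self) -> float:
        return self.n_placed / self.n_reads if self.n_reads else 0.0


def map_reads_light(
    reads: ReadSet | np.ndarray | str | Path,
    index: SeedIndex,
    stride: int = 7,
    return_placements: bool = False,
):
    """Per-base depth from unique-seed majority-vote placement.

    Returns ``(depth, stats)`` or ``(depth, stats, placements)`` where
    placements is an int64 array of read start positions (-1 for discarded
    reads).  An empty read set yields an all-zero depth array.
    """
    if isinstance(reads, (str, Path)):
        _names, seqs = cli_io.read_fastq(reads)
        if not seqs:
            mat = np.zeros((0, index.k), dtype=np.uint8)
        else:
            mat = np.vstack(seqs)
    elif isinstance(reads, ReadSet):
        mat = reads.matrix
    else:
        mat = np.asarray(reads, dtype=np.uint8)

    depth = np.zeros(index.length, dtype=np.int64)
    n_reads = len(mat)
    if n_reads == 0:
        stats = MappingStats(0, 0, 0, 0)
        return (depth, stats, np.array([], dtype=np.int64)) if return_placements else (depth, stats)

    L = mat.shape[1]
    k = index.k
    if L < k:
        raise ValueError("reads shorter than the seed k")
    offsets = np.arange(0, L - k + 1, stride)
    if offsets[-1] != L - k:
        offsets = np.append(offsets, L - k)

    placements = np.full(n_reads, -1, dtype=np.int64)
    if len(index.codes) == 0:
        stats = MappingStats(n_reads, 0, n_reads, 0)
        return (depth, stats, placements) if return_placements else (depth, stats)
    chunk = max(1, (1 << 23) // L)
    for c0 in range(0, n_reads, chunk):
        sub = mat[c0 : c0 + chunk]
        # seed codes only at the sampled offsets (not every window)
        fwd = np.zeros((len(sub), len(offsets)), dtype=np.uint64)
        two = np.uint64(2)
        for j in range(k):
            np.left_shift(fwd, two, out=fwd)
            np.bitwise_or(fwd, (sub[:, offsets + j] & np.uint8(3)).astype(np.uint64), out=fwd)
        rc = _seq.rc_from_codes(fwd, k)
        read_fwd = fwd <= rc
        codes = np.minimum(fwd, rc)
        if (sub > 3).any():
            valid = _seq.valid_windows(sub, k)[:, offsets]
        else:
            valid = np.ones_like(read_fwd, dtype=bool)
        idx = np.searchsorted(index.codes, codes)
        idx_c = np.minimum(idx, len(index.codes) - 1)
        hit = valid & (index.codes[idx_c] == codes)
        rid, jcol = np.nonzero(hit)
        if len(rid) == 0:
            continue
        anchor = idx_c[rid, jcol]
        p = index.pos[anchor]
        same = index.is_fwd[anchor] == read_fwd[rid, jcol]
        j = offsets[jcol]
        start = np.where(same, p - j, p + k + j - L)
        ok = (start >= 0) & (start <= index.length - L)
        rid, start, same = rid[ok], start[ok], same[ok]
        if len(rid) == 0:
            continue
        key = start * 2 + same.astype(np.int64)
        group = rid.astype(np.int64) * (2 * index.length + 2) + key
        g_sorted = np.sort(group)
        g_uniq, g_counts = np.unique(g_sorted, return_counts=True)
        g_rid = (g_uniq // (2 * index.length + 2)).astype(np.int64)
        # per read: max vote count and whether it is unique
        maxc = np.zeros(len(sub), dtype=np.int64)
        np.maximum.at(maxc, g_rid, g_counts)
        n_at_max = np.zeros(len(sub), dtype=np.int64)
        np.add.at(n_at_max, g_rid, (g_counts == maxc[g_rid]).astype(np.int64))
        winner = (g_counts == maxc[g_rid]) & (n_at_max[g_rid] == 1)
        wr = g_rid[winner]
        wstart = (g_uniq[winner] % (2 * index.length + 2)) // 2
        placements[c0 + wr] = wstart

    placed = placements >= 0
    starts = placements[placed]
    ends = np.minimum(starts + L, index.length)
    delta = np.zeros(index.length + 1, dtype=np.int64)
    np.add.at(delta, starts, 1)
    np.add.at(delta, ends, -1)
    depth = np.cumsum(delta)[:-1]

    n_placed = int(placed.sum())
    n_discard = n_reads - n_placed  # no unique seed, or tied top vote
    stats = MappingStats(n_reads, n_placed, 0, n_discard)
    log.info(
        "event=map_reads assembly=%s reads=%d placed=%d discarded=%d",
        index.assembly_id, n_reads, n_placed, n_discard,
    )
    if return_placements:
        return depth, stats, placements
    return depth, stats


# ---------------------------------------------------------------------------
# windows
# ---------------------------------------------------------------------------

def window_depth(
    depth: np.ndarray,
    width: int = 500,
    repeat_intervals: np.ndarray | None = None,
    max_repeat_fraction: float = 0.10,
    assembly_id: str = "assembly",
    sample_id: str = "sample",
) -> pd.DataFrame:
    """Mean depth over non-overlapping windows; the final partial window is
    dropped.  Windows with more than ``max_repeat_fraction`` repeat-annotated
    content are flagged ``excluded``."""
    if width < 100:
        raise ValueError("window width must be >= 100")
    n = len(depth)
    n_win = n // width
    if n_win == 0:
        raise ValueError("window width exceeds the sequence length")
    means = depth[: n_win * width].reshape(n_win, width).mean(axis=1)
    starts = np.arange(n_win, dtype=np.int64) * width
    win = np.column_stack([starts, starts + width])
    if repeat_intervals is not None and len(repeat_intervals):
        rep = cli_io.interval_coverage(win, repeat_intervals)
    else:
        rep = np.zeros(n_win)
    return pd.DataFrame(
        {
            "assembly": assembly_id,
            "start": starts,
            "end": starts + width,
            "sample": sample_id,
            "raw": means,
            "repeat_fraction": rep,
            "excluded": rep > max_repeat_fraction,
        }
    )


@dataclass
class BackgroundSpec:
    """A large neutral region used to normalize per-sample coverage."""

    assembly_id: str
    interval: tuple[int, int]
    min_windows: int = 100


def background_mean(profile: pd.DataFrame, background: BackgroundSpec) -> float:
    """Mean raw depth over the non-repetitive windows of the background
    region (requires at least ``min_windows`` usable windows)."""
    s, e = background.interval
    sel = profile[(profile["start"] >= s) & (profile["end"] <= e) & (~profile["excluded"])]
    if len(sel) < background.min_windows:
        raise ValueError(
            f"background region has {len(sel)} non-repetitive windows; "
            f"need >= {background.min_windows}"
        )
    return float(sel["raw"].mean())


def standardize(profile: pd.DataFrame, background: BackgroundSpec) -> pd.DataFrame:
    """Divide each sample's window means by that sample's background mean.

    Samples with background mean 0 are dropped with a warning.
    """
    out = []
    for sample, sub in profile.groupby("sample", sort=False):
        bg = background_mean(sub, background)
        if bg <= 0:
            log.warning("event=zero_background sample=%s excluded", sample)
            continue
        sub = sub.copy()
        sub["standardized"] = sub["raw"] / bg
        sub["background_mean"] = bg
        out.append(sub)
    if not out:
        raise ValueError("no sample has positive background depth")
    return pd.concat(out, ignore_index=True)


def call_content(
    profile: pd.DataFrame, thresholds: tuple[float, float] = (0.25, 0.75)
) -> pd.DataFrame:
    """Genotype each (window, sample) from standardized depth.

    absent < lo <= heterozygous < hi <= homozygous-present; midpoints
    between the expected 0 / 0.5 / 1.0 by default.  Excluded (repetitive)
    windows are skipped.
    """
    lo, hi = thresholds
    if not 0 < lo < hi:
        raise ValueError("thresholds must satisfy 0 < lo < hi")
    out = profile[~profile["excluded"]].copy()
    sd = out["standardized"].to_numpy()
    call = np.where(sd < lo, "absent", np.where(sd < hi, "heterozygous", "homozygous-present"))
    out["call"] = call
    return out


def pool_contrast(
    profile_pool_1: pd.DataFrame,
    profile_pool_2: pd.DataFrame,
    candidate_interval: tuple[int, int],
    flag_percentile: float = 99.0,
) -> dict:
    """Per-window standardized-depth difference between two pools.

    delta = pool2 - pool1 per window; the genome-wide distribution of delta
    outside the candidate interval calibrates how extreme the candidate is.
    The locus is flagged when the median candidate delta exceeds the given
    genome-wide percentile.
    """
    m = pd.merge(
        profile_pool_1[~profile_pool_1["excluded"]][["start", "end", "standardized"]],
        profile_pool_2[~profile_pool_2["excluded"]][["start", "end", "standardized"]],
        on=["start", "end"],
        suffixes=("_1", "_2"),
    )
    m["delta"] = m["standardized_2"] - m["standardized_1"]
    s, e = candidate_interval
    in_cand = (m["start"] >= s) & (m["end"] <= e)
    cand = m[in_cand]
    if len(cand) == 0:
        raise ValueError("candidate interval empty after repeat filtering")
    bg = m[~in_cand]["delta"].to_numpy()
    cutoff = float(np.percentile(bg, flag_percentile)) if len(bg) else float("nan")
    med = float(cand["delta"].median())
    cand = cand.copy()
    if len(bg):
        cand["background_quantile"] = np.searchsorted(np.sort(bg), cand["delta"]) / len(bg)
    return {
        "windows": cand,
        "median_candidate_delta": med,
        "background_cutoff": cutoff,
        "flagged": bool(len(bg)) and med > cutoff,
    }
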