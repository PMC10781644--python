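"""Reference-free k-mer presence/absence association.

The pipeline mirrors the reference-free GWAS idea: count canonical k-mers per
sample (presence, not abundance), filter by minor allele count and by the
fraction of containing samples that saw the k-mer in both orientations
("canonized"), test each k-mer's 2x2 presence x phenotype table with a 1-df
Pearson chi-square, and control the family-wise error rate with a
max-statistic phenotype-permutation threshold.  Significant k-mers are then
mapped exactly (full length, 100% identity, either strand) to morph
assemblies to tell novel genomic *content* apart from *sequence* divergence.

The default k is 31; only odd k (no self-palindromes) is accepted.  k <= 31
uses the packed uint64 fast path.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import _seq
from .synthio import ReadSet

log = logging.getLogger("morphlocus")


def _check_k(k: int) -> None:
    if k % 2 == 0:
        raise ValueError("k must be odd (self-palindromic k-mers are ambiguous)")
    if not 15 <= k <= 63:
        raise ValueError("k must be in [15, 63]")
    if k > 31:
        raise NotImplementedError(
            "k > 31 exceeds the packed 2-bit uint64 representation"
        )


@dataclass
class SampleKmerSet:
    """Canonical k-mers present (>= min_count occurrences) in one sample.

    ``both_orientations`` marks k-mers whose forward and reverse-complement
    orientations were both observed in the sample's reads.
    """

    sample_id: str
    k: int
    kmers: np.ndarray  # sorted uint64 canonical codes
    both_orientations: np.ndarray
    n_reads_skipped: int = 0


def count_kmers(
    reads: ReadSet | list[np.ndarray] | list[str] | str | Path,
    k: int = 31,
    sample_id: str | None = None,
    min_count: int = 1,
) -> SampleKmerSet:
    """Canonical k-mer presence set for one sample's reads.

    ``reads`` may be a ReadSet, a FASTQ path, or a list of sequences
    (strings or encoded arrays).  Reads shorter than k are skipped and
    counted.  ``min_count`` (default 1 = plain presence) optionally requires
    a k-mer to occur that many times before it counts as present.
    """
    _check_k(k)
    if isinstance(reads, (str, Path)):
        from . import cli_io

        sample_id = sample_id or Path(reads).stem
        _names, seqs = cli_io.read_fastq(reads)
        arrays = seqs
    elif isinstance(reads, ReadSet):
        sample_id = sample_id or reads.sample_id
        arrays = reads.matrix
    else:
        sample_id = sample_id or "sample"
        arrays = [_seq.encode(r) if isinstance(r, str) else np.asarray(r, dtype=np.uint8) for r in reads]

    skipped = 0
    chunks_keys: list[np.ndarray] = []

    def eat(mat: np.ndarray) -> None:
        codes, is_fwd = _seq.canonical_codes(mat, k)
        # orientation goes into the low bit of a widened key so a single
        # sorted pass yields, per canonical k-mer, which orientations occurred
        key = (codes << np.uint64(1)) | is_fwd
        if (mat > 3).any():
            key = key[_seq.valid_windows(mat, k)]
        chunks_keys.append(key.ravel())

    if isinstance(arrays, np.ndarray) and arrays.ndim == 2:
        step = max(1, (1 << 24) // max(arrays.shape[1], 1))
        for i in range(0, len(arrays), step):
            eat(arrays[i : i + step])
    else:
        # group variable-length reads by length so each batch is a matrix
        by_len: dict[int, list[np.ndarray]] = {}
        for a in arrays:
            if len(a) < k:
                skipped += 1
                continue
            by_len.setdefault(len(a), []).append(a)
        for L, group in sorted(by_len.items()):
            eat(np.vstack(group))
    if skipped:
        log.info("event=reads_shorter_than_k sample=%s skipped=%d", sample_id, skipped)

    if not chunks_keys or sum(len(c) for c in chunks_keys) == 0:
        empty = np.array([], dtype=np.uint64)
        return SampleKmerSet(sample_id, k, empty, np.array([], dtype=bool), skipped)

    keys = np.concatenate(chunks_keys) if len(chunks_keys) > 1 else chunks_keys[0]
    uk, kcount = np.unique(keys, return_counts=True)
    codes_u = uk >> np.uint64(1)
    # segment per canonical code: 1 or 2 adjacent rows (one per orientation)
    first = np.ones(len(uk), dtype=bool)
    first[1:] = codes_u[1:] != codes_u[:-1]
    starts = np.flatnonzero(first)
    totals = np.add.reduceat(kcount, starts) if len(starts) else np.array([], dtype=np.int64)
    seg_len = np.diff(np.append(starts, len(uk)))
    kmers = codes_u[starts]
    both = seg_len == 2
    if min_count > 1:
        keep = totals >= min_count
        kmers, both = kmers[keep], both[keep]
    return SampleKmerSet(sample_id, k, kmers, both, skipped)


@dataclass
class KmerTable:
    """Canonical k-mer presence matrix across samples, with filter tallies."""

    k: int
    samples: list[str]
    kmers: np.ndarray  # sorted uint64 canonical codes, shape (m,)
    presence: np.ndarray  # bool, shape (m, n_samples)
    canonized_fraction: np.ndarray  # shape (m,)
    filter_log: dict = field(default_factory=dict)

    @property
    def n_kmers(self) -> int:
        return len(self.kmers)

    def kmer_strings(self) -> list[str]:
        return [_seq.code_to_kmer(c, self.k) for c in self.kmers]


def build_table(
    sample_sets: list[SampleKmerSet],
    min_allele_count: int = 5,
    min_canonized: float = 0.20,
) -> KmerTable:
    """Union presence table with the listing-stage filters applied.

    Drops k-mers present in fewer than ``min_allele_count`` samples and
    k-mers whose canonized fraction (share of containing samples that saw
    both orientations) is below ``min_canonized``.
    """
    if not sample_sets:
        raise ValueError("no samples")
    k = sample_sets[0].k
    if any(s.k != k for s in sample_sets):
        raise ValueError("mixed k across samples")
    if len(sample_sets) < min_allele_count:
        raise ValueError("fewer samples than min_allele_count")

    all_codes = np.concatenate([s.kmers for s in sample_sets])
    uniq, counts = np.unique(all_codes, return_counts=True)
    n_listed = len(uniq)
    keep = counts >= min_allele_count
    uniq = uniq[keep]
    n_after_mac = len(uniq)

    m, n = len(uniq), len(sample_sets)
    presence = np.zeros((m, n), dtype=bool)
    both = np.zeros((m, n), dtype=bool)
    for j, s in enumerate(sample_sets):
        idx = np.searchsorted(uniq, s.kmers)
        ok = (idx < m) & (uniq[np.minimum(idx, m - 1)] == s.kmers)
        presence[idx[ok], j] = True
        both[idx[ok], j] = s.both_orientations[ok]

    containing = presence.sum(axis=1)
    canonized = both.sum(axis=1) / np.maximum(containing, 1)
    keep = canonized >= min_canonized
    tally = {
        "n_listed": int(n_listed),
        "n_failed_mac": int(n_listed - n_after_mac),
        "n_failed_canonized": int((~keep).sum()),
        "n_kept": int(keep.sum()),
    }
    if tally["n_kept"] == 0:
        log.warning("event=empty_kmer_table %s", tally)
    log.info("event=kmer_table %s", tally)
    return KmerTable(
        k,
        [s.sample_id for s in sample_sets],
        uniq[keep],
        presence[keep],
        canonized[keep],
        tally,
    )


# ---------------------------------------------------------------------------
# association
# ---------------------------------------------------------------------------

def _chi2_2x2(a, b, c, d):
    """Vectorized Pearson chi-square (1 df, no continuity correction) for a
    2x2 table [[a, b], [c, d]]; zero-margin tables give 0."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    c = np.asarray(c, dtype=np.float64)
    d = np.asarray(d, dtype=np.float64)
    n = a + b + c + d
    den = (a + b) * (c + d) * (a + c) * (b + d)
    num = n * (a * d - b * c) ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(den > 0, num / den, 0.0)
    return out


@dataclass
class AssociationResult:
    """Per-k-mer chi-square association on the MAF-filtered table."""

    k: int
    kmers: np.ndarray
    case_present: np.ndarray
    case_absent: np.ndarray
    control_present: np.ndarray
    control_absent: np.ndarray
    statistic: np.ndarray
    p_value: np.ndarray
    kept_mask: np.ndarray  # mask into the parent table's k-mers

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "kmer": [_seq.code_to_kmer(c, self.k) for c in self.kmers],
                "case_present": self.case_present,
                "case_absent": self.case_absent,
                "control_present": self.control_present,
                "control_absent": self.control_absent,
                "chi2": self.statistic,
                "p": self.p_value,
            }
        )


def _maf_mask(table: KmerTable, maf: float, mac: int) -> np.ndarray:
    n = len(table.samples)
    present = table.presence.sum(axis=1)
    minor = np.minimum(present, n - present)
    return (minor / n >= maf) & (n - present >= mac) & (present >= mac)


def test_association(
    table: KmerTable,
    phenotypes: np.ndarray,
    maf: float = 0.05,
    mac: int = 5,
) -> AssociationResult:
    """1-df chi-square on presence/absence x case/control for every k-mer
    passing the minor-allele-frequency filter.

    ``phenotypes`` is a boolean case vector aligned with the table's samples;
    any of the morph contrasts (A vs O, A vs I, A+I vs O) is expressed by the
    labels alone.
    """
    labels = np.asarray(phenotypes, dtype=bool)
    if labels.shape != (len(table.samples),):
        raise ValueError("phenotype vector does not match the table's samples")
    if labels.all() or not labels.any():
        raise ValueError("phenotypes must contain two classes")
    if labels.sum() < 2 or (~labels).sum() < 2:
        raise ValueError("each phenotype class needs at least 2 samples")

    keep = _maf_mask(table, maf, mac)
    pres = table.presence[keep]
    n_case = int(labels.sum())
    n_ctrl = int((~labels).sum())
    a = pres[:, labels].sum(axis=1)
    c = pres.sum(axis=1) - a
    b = n_case - a
    d = n_ctrl - c
    stat = _chi2_2x2(a, b, c, d)
    p = stats.chi2.sf(stat, df=1)
    return AssociationResult(table.k, table.kmers[keep], a, b, c, d, stat, p, keep)


@dataclass
class PermutationNull:
    """Max-statistic permutation null for family-wise error control.

    The chi-square has discrete support, so the observed maximum often *ties*
    the threshold order statistic; a strict-inequality rule would then be
    badly conservative.  ``significant`` therefore applies the standard
    randomized exact tie rule: with U drawn once per analysis (seeded), the
    permutation p-value (1 + #{perm > M} + U * #{perm == M}) / (m + 1) is
    exactly Uniform(0,1) under exchangeability, so rejecting at p <= fwer
    attains the nominal family-wise level exactly and never exceeds it.
    """

    n_permutations: int
    max_statistics: np.ndarray
    threshold_5pct: float
    fwer: float
    seed: int
    tie_u: float = 0.5

    def significant(self, statistics: np.ndarray) -> np.ndarray:
        stats = np.asarray(statistics)
        if stats.size == 0:
            return np.zeros(0, dtype=bool)
        m_obs = float(stats.max())
        g = int((self.max_statistics > m_obs).sum())
        e = int((self.max_statistics == m_obs).sum())
        p_rand = (1.0 + g + self.tie_u * e) / (self.n_permutations + 1)
        if p_rand > self.fwer:
            return np.zeros(stats.shape, dtype=bool)
        if m_obs > self.threshold_5pct:
            return stats > self.threshold_5pct
        # rejection decided at a tie with the threshold: the top ties stand
        return stats >= m_obs


def permutation_threshold(
    table: KmerTable,
    phenotypes: np.ndarray,
    n_permutations: int = 100,
    fwer: float = 0.05,
    seed: int = 0,
    maf: float = 0.05,
    mac: int = 5,
) -> PermutationNull:
    """Family-wise threshold from phenotype permutations.

    Each permutation shuffles the case labels (class sizes preserved) and
    records the maximum chi-square over all MAF-passing k-mers.  The
    threshold is the ceil((1-fwer)(m+1))-th smallest maximum -- the
    exchangeability-exact quantile, guaranteeing FWER <= fwer for the rule
    "observed statistic strictly greater than the threshold".
    """
    if n_permutations < 20:
        raise ValueError("n_permutations < 20 makes the quantile unstable")
    labels = np.asarray(phenotypes, dtype=bool)
    keep = _maf_mask(table, maf, mac)
    pres = table.presence[keep].astype(np.float32)
    n = len(table.samples)
    n_case = int(labels.sum())
    n_ctrl = n - n_case
    rng = np.random.default_rng(seed)
    # permuted case indicator matrix (n_samples x n_permutations)
    perm = np.empty((n, n_permutations), dtype=np.float32)
    for p_i in range(n_permutations):
        perm[:, p_i] = rng.permutation(labels).astype(np.float32)
    r = pres.sum(axis=1, keepdims=True)
    maxima = np.zeros(n_permutations)
    # chunk permutations to bound the chi-square temporaries
    chunk = max(1, int(5e6 // max(len(pres), 1)))
    for lo_i in range(0, n_permutations, chunk):
        a = pres @ perm[:, lo_i : lo_i + chunk]
        c = r - a
        b = n_case - a
        d = n_ctrl - c
        stat = _chi2_2x2(a, b, c, d)
        if stat.size:
            maxima[lo_i : lo_i + chunk] = stat.max(axis=0)
    idx = int(np.ceil((1.0 - fwer) * (n_permutations + 1)))
    srt = np.sort(maxima)
    threshold = float(srt[idx - 1]) if idx <= n_permutations else float("inf")
    tie_u = float(rng.random())  # randomized exact tie rule (see PermutationNull)
    return PermutationNull(n_permutations, maxima, threshold, fwer, seed, tie_u)


# ---------------------------------------------------------------------------
# exact mapping to assemblies
# ---------------------------------------------------------------------------

def map_kmers(
    kmers: np.ndarray,
    assembly: np.ndarray,
    k: int,
    assembly_id: str = "assembly",
) -> pd.DataFrame:
    """Exact full-length matches of canonical k-mers to an assembly.

    Returns one row per hit (kmer code, assembly, 0-based position, strand);
    k-mers with no hit are absent from the frame (an empty hit list is
    valid).  Only 100%-identity full-length matches exist by construction.
    """
    _check_k(k)
    kq = np.asarray(kmers, dtype=np.uint64)
    asm_codes, asm_is_fwd = _seq.canonical_codes(np.asarray(assembly, dtype=np.uint8), k)
    valid = _seq.valid_windows(np.asarray(assembly, dtype=np.uint8), k)
    pos_all = np.flatnonzero(valid)
    codes = asm_codes[pos_all]
    fwd = asm_is_fwd[pos_all]
    order = np.argsort(codes, kind="stable")
    codes, fwd, pos_all = codes[order], fwd[order], pos_all[order]
    lo = np.searchsorted(codes, kq, side="left")
    hi = np.searchsorted(codes, kq, side="right")
    rows_kmer, rows_pos, rows_strand = [], [], []
    n_hits = hi - lo
    for i in np.flatnonzero(n_hits):
        sl = slice(lo[i], hi[i])
        rows_kmer.append(np.full(hi[i] - lo[i], kq[i], dtype=np.uint64))
        rows_pos.append(pos_all[sl])
        rows_strand.append(np.where(fwd[sl], "+", "-"))
    if rows_kmer:
        df = pd.DataFrame(
            {
                "kmer": np.concatenate(rows_kmer),
                "assembly": assembly_id,
                "pos": np.concatenate(rows_pos),
                "strand": np.concatenate(rows_strand),
            }
        )
    else:
        df = pd.DataFrame(columns=["kmer", "assembly", "pos", "strand"])
    return df


def mapping_summary(kmers: np.ndarray, hits: pd.DataFrame) -> dict:
    mapped = hits["kmer"].nunique() if len(hits) else 0
    return {
        "n_kmers": int(len(kmers)),
        "n_mapped": int(mapped),
        "mapped_fraction": float(mapped / len(kmers)) if len(kmers) else 0.0,
    }


# ---------------------------------------------------------------------------
# content vs sequence verdict
# ---------------------------------------------------------------------------

def classify_divergence(
    kmers: np.ndarray,
    hits_by_assembly: dict[str, pd.DataFrame],
    majority: float = 0.90,
) -> dict:
    """Classify a significant-k-mer set as content vs sequence divergence.

    Novel *content* puts the vast majority of significant k-mers in exactly
    one assembly; *sequence* divergence produces morph-specific k-mers
    exclusive to each of the two assemblies.  Reports per-assembly exclusive
    / both / unmapped fractions, a positional span containing 95% of hits
    per assembly, and the verdict.
    """
    if len(hits_by_assembly) < 2:
        raise ValueError("need hits against at least 2 assemblies")
    kq = np.asarray(kmers, dtype=np.uint64)
    if len(kq) == 0:
        return {"verdict": "none", "n_kmers": 0}
    names = list(hits_by_assembly)
    mapped = {}
    for name, df in hits_by_assembly.items():
        mapped[name] = np.isin(kq, df["kmer"].to_numpy(dtype=np.uint64) if len(df) else np.array([], dtype=np.uint64))
    any_mapped = np.logical_or.reduce([mapped[n] for n in names])
    n_total = len(kq)
    report: dict = {"n_kmers": int(n_total), "unmapped_fraction": float((~any_mapped).mean())}
    n_mapped = int(any_mapped.sum())
    shares = {}
    both_mask = np.logical_and.reduce([mapped[n] for n in names])
    for name in names:
        excl = mapped[name] & ~np.logical_or.reduce([mapped[o] for o in names if o != name])
        shares[name] = float(excl.sum() / n_mapped) if n_mapped else 0.0
        df = hits_by_assembly[name]
        if len(df):
            pos = df["pos"].to_numpy()
            span = (float(np.percentile(pos, 2.5)), float(np.percentile(pos, 97.5)))
        else:
            span = (float("nan"), float("nan"))
        report[f"exclusive_{name}"] = shares[name]
        report[f"span95_{name}"] = span
    report["both_fraction"] = float(both_mask.sum() / n_mapped) if n_mapped else 0.0

    if n_mapped == 0:
        report["verdict"] = "none"
    elif max(shares.values()) >= majority:
        report["verdict"] = "content"
    elif min(shares.values()) >= 1.0 - majority:
        report["verdict"] = "sequence"
    else:
        report["verdict"] = "mixed"
    return report
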