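"""Windowed population-genetic statistics, LD decay and SNP association.

Statistics are missing-data aware and denominator-honest: pi is a ratio of
sums over callable sites (invariant sites count toward comparable pairs, so
adding invariant callable sites dilutes pi), Hudson's FST is the
ratio-of-sums estimator (sum of per-site numerators over sum of per-site
denominators; invariant sites contribute zero to both), and Tajima's D uses
the canonical constants for the window's effective haplotype count.
Windows are coordinate-tiled; the final partial window is kept, with its
true callable extent, unlike the fixed-width depth windows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import cli_io
from .synthio import BACKBONE, Cohort, _rng, lift_positions

log = logging.getLogger("morphlocus")


@dataclass
class VariantTable:
    """Biallelic SNP genotypes plus callability for invariant sites.

    ``gt`` holds per-sample diploid calls with -1 for a missing haplotype
    allele.  ``callable_intervals`` (one interval array per haplotype, in
    sample order, two per sample) says where each haplotype copy carries the
    reference content at all; ``None`` means everything is callable.
    """

    pos: np.ndarray  # (m,) 0-based positions on the reference assembly
    gt: np.ndarray  # (m, n_samples, 2) int8 in {-1, 0, 1}
    samples: list[str]
    seq_length: int
    mq: np.ndarray = None  # mapping-quality proxy per site
    gq: np.ndarray = None  # genotype-quality proxy per site
    depth: np.ndarray = None  # combined depth across samples per site
    repeat: np.ndarray = None  # site overlaps repeat annotation
    callable_intervals: list[np.ndarray] | None = None

    def __post_init__(self):
        m = len(self.pos)
        if self.mq is None:
            self.mq = np.full(m, 60.0)
        if self.gq is None:
            self.gq = np.full(m, 99.0)
        if self.depth is None:
            self.depth = np.full(m, np.nan)
        if self.repeat is None:
            self.repeat = np.zeros(m, dtype=bool)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_indices(self, names: list[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        return np.array([lookup[n] for n in names], dtype=np.int64)


def make_windows(seq_length: int, width: int) -> np.ndarray:
    """Coordinate-tiled half-open windows; the final partial window is kept."""
    starts = np.arange(0, seq_length, width, dtype=np.int64)
    ends = np.minimum(starts + width, seq_length)
    return np.column_stack([starts, ends])


# ---------------------------------------------------------------------------
# per-site counts
# ---------------------------------------------------------------------------

def _site_counts(gt: np.ndarray, idx: np.ndarray):
    """Called haplotypes and derived-allele counts per site for a sample
    subset; returns (n_called, n_alt)."""
    sub = gt[:, idx, :]
    called = sub >= 0
    n = called.sum(axis=(1, 2))
    alt = (sub == 1).sum(axis=(1, 2))
    return n, alt


def _hap_callable_counts(
    vt: VariantTable, idx: np.ndarray, positions: np.ndarray
) -> np.ndarray:
    """Interval-based callable haplotype count at given positions."""
    if vt.callable_intervals is None:
        return np.full(len(positions), 2 * len(idx), dtype=np.int64)
    out = np.zeros(len(positions), dtype=np.int64)
    for s in idx:
        for h in (0, 1):
            iv = vt.callable_intervals[2 * s + h]
            if len(iv) == 0:
                continue
            i = np.searchsorted(iv[:, 0], positions, side="right") - 1
            ok = (i >= 0) & (positions < iv[np.maximum(i, 0), 1])
            out += ok
    return out


def _callable_pair_bp(vt: VariantTable, idx: np.ndarray, window: tuple[int, int]) -> float:
    """Sum over window positions of C(n_callable, 2) from the interval
    callability (piecewise-constant sweep)."""
    s, e = window
    if vt.callable_intervals is None:
        n = 2 * len(idx)
        return (e - s) * n * (n - 1) / 2.0
    events = []
    for smp in idx:
        for h in (0, 1):
            for a, b in vt.callable_intervals[2 * smp + h]:
                a, b = max(a, s), min(b, e)
                if a < b:
                    events.append((a, 1))
                    events.append((b, -1))
    if not events:
        return 0.0
    ev = sorted(events)
    total = 0.0
    cur = s
    n = 0
    for x, d in ev:
        if x > cur and n >= 2:
            total += (x - cur) * n * (n - 1) / 2.0
        cur = max(cur, x)
        n += d
    return total


# ---------------------------------------------------------------------------
# pi
# ---------------------------------------------------------------------------

def pairwise_pi(
    vt: VariantTable,
    samples: list[str] | np.ndarray,
    width: int = 3000,
) -> pd.DataFrame:
    """Nucleotide diversity per window as a ratio of sums.

    pi = sum over sites of differing pairs / sum over callable sites of
    comparable pairs, with invariant callable sites contributing pairs to
    the denominator only.  Windows with no comparable pairs are missing.
    """
    idx = vt.sample_indices(list(samples)) if isinstance(samples[0], str) else np.asarray(samples)
    windows = make_windows(vt.seq_length, width)
    n_called, n_alt = _site_counts(vt.gt, idx)
    diffs = n_alt * (n_called - n_alt)
    pairs_gt = n_called * (n_called - 1) / 2.0
    rows = []
    for s, e in windows:
        in_w = (vt.pos >= s) & (vt.pos < e)
        total_pairs = _callable_pair_bp(vt, idx, (s, e))
        # replace the interval-based pair count at variant positions with the
        # genotype-based one (they agree when genotype missingness mirrors
        # interval callability, but genotypes are authoritative)
        n_iv = _hap_callable_counts(vt, idx, vt.pos[in_w])
        total_pairs += float((pairs_gt[in_w] - n_iv * (n_iv - 1) / 2.0).sum())
        d = float(diffs[in_w].sum())
        rows.append(
            {
                "start": s, "end": e, "statistic": "pi",
                "value": d / total_pairs if total_pairs > 0 else np.nan,
                "n_callable": total_pairs,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Hudson FST
# ---------------------------------------------------------------------------

def hudson_fst(
    vt: VariantTable,
    pop1: list[str] | np.ndarray,
    pop2: list[str] | np.ndarray,
    width: int = 3000,
) -> pd.DataFrame:
    """Hudson's FST per window, ratio of sums over sites.

    Per site: dxy is the mean between-population pairwise difference and
    pi_w the mean of the two unbiased within-population diversities;
    numerator = dxy - pi_w, denominator = dxy.  Sites need >= 2 called
    haplotypes in each population.  The raw value is kept; ``value_plotted``
    clamps negatives to zero (a plotting convention only).
    """
    i1 = vt.sample_indices(list(pop1)) if isinstance(pop1[0], str) else np.asarray(pop1)
    i2 = vt.sample_indices(list(pop2)) if isinstance(pop2[0], str) else np.asarray(pop2)
    n1, a1 = _site_counts(vt.gt, i1)
    n2, a2 = _site_counts(vt.gt, i2)
    usable = (n1 >= 2) & (n2 >= 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        pi1 = 2.0 * a1 * (n1 - a1) / (n1 * (n1 - 1.0))
        pi2 = 2.0 * a2 * (n2 - a2) / (n2 * (n2 - 1.0))
        dxy = (a1 * (n2 - a2) + (n1 - a1) * a2) / (n1 * n2 * 1.0)
    num = np.where(usable, dxy - 0.5 * (pi1 + pi2), 0.0)
    den = np.where(usable, dxy, 0.0)
    windows = make_windows(vt.seq_length, width)
    rows = []
    for s, e in windows:
        in_w = (vt.pos >= s) & (vt.pos < e) & usable
        ds = float(den[in_w].sum())
        val = float(num[in_w].sum()) / ds if ds > 0 else np.nan
        rows.append(
            {
                "start": s, "end": e, "statistic": "fst",
                "value": val,
                "value_plotted": max(val, 0.0) if np.isfinite(val) else np.nan,
                "n_callable": int(in_w.sum()),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Tajima's D
# ---------------------------------------------------------------------------

def tajima_constants(n: int) -> dict[str, float]:
    """The canonical a1, a2, b1, b2, c1, c2, e1, e2 for sample size n."""
    if n < 4:
        raise ValueError("Tajima's D needs at least 4 haplotypes")
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def tajimas_d(
    vt: VariantTable,
    samples: list[str] | np.ndarray,
    width: int = 3000,
    min_completeness: float = 0.5,
) -> pd.DataFrame:
    """Tajima's D per window: (pi_hat - S/a1) / sqrt(e1*S + e2*S*(S-1)).

    Sites with fewer than ``min_completeness`` of the subset's haplotypes
    called are dropped; the effective n is the minimum per-site called count
    over the window's retained segregating sites.  Windows with S = 0 are
    missing, not zero.
    """
    idx = vt.sample_indices(list(samples)) if isinstance(samples[0], str) else np.asarray(samples)
    n_called, n_alt = _site_counts(vt.gt, idx)
    n_max = 2 * len(idx)
    retained = n_called >= min_completeness * n_max
    seg = retained & (n_alt > 0) & (n_alt < n_called)
    with np.errstate(divide="ignore", invalid="ignore"):
        k_site = 2.0 * n_alt * (n_called - n_alt) / (n_called * (n_called - 1.0))
    windows = make_windows(vt.seq_length, width)
    rows = []
    for s, e in windows:
        in_w = (vt.pos >= s) & (vt.pos < e) & seg
        S = int(in_w.sum())
        if S == 0:
            rows.append({"start": s, "end": e, "statistic": "tajimas_d",
                         "value": np.nan, "n_callable": 0})
            continue
        n_eff = int(n_called[in_w].min())
        if n_eff < 4:
            rows.append({"start": s, "end": e, "statistic": "tajimas_d",
                         "value": np.nan, "n_callable": S})
            continue
        c = tajima_constants(n_eff)
        pi_hat = float(k_site[in_w].sum())
        var = c["e1"] * S + c["e2"] * S * (S - 1)
        d = (pi_hat - S / c["a1"]) / np.sqrt(var) if var > 0 else np.nan
        rows.append({"start": s, "end": e, "statistic": "tajimas_d",
                     "value": d, "n_callable": S})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# envelopes
# ---------------------------------------------------------------------------

def percentile_envelope(
    window_stats: pd.DataFrame,
    statistic: str,
    bounds: tuple[float, float] = (5.0, 95.0),
) -> dict:
    """Genome-wide percentile envelope (linear interpolation).

    For FST only the non-zero plotted values enter the upper percentile,
    matching the convention of marking the 95th percentile of non-zero
    genome-wide values.
    """
    df = window_stats[window_stats["statistic"] == statistic] if "statistic" in window_stats else window_stats
    if statistic == "fst":
        col = "value_plotted" if "value_plotted" in df else "value"
        vals = df[col].to_numpy(dtype=float)
        vals = vals[np.isfinite(vals) & (vals > 0)]
    else:
        vals = df["value"].to_numpy(dtype=float)
        vals = vals[np.isfinite(vals)]
    if len(vals) < 100:
        log.warning("event=envelope_few_windows statistic=%s n=%d", statistic, len(vals))
    if len(vals) == 0:
        return {"statistic": statistic, "lower": np.nan, "upper": np.nan, "n": 0}
    lo, hi = bounds
    return {
        "statistic": statistic,
        "lower": float(np.percentile(vals, lo)),
        "upper": float(np.percentile(vals, hi)),
        "n": int(len(vals)),
    }


# ---------------------------------------------------------------------------
# linkage disequilibrium
# ---------------------------------------------------------------------------

def ld_scan(
    vt: VariantTable,
    downsample_every: int = 100,
    r2_floor: float = 0.05,
    max_distance: int = 1_500_000,
    max_between: int = 10_000,
) -> pd.DataFrame:
    """Composite (genotype-dosage) r-squared for downsampled variant pairs.

    Variants are thinned to every ``downsample_every``-th site; a pair is
    examined when it is within ``max_distance`` bp or has at most
    ``max_between`` retained variants between its members, and recorded when
    r2 exceeds ``r2_floor``.  Monomorphic sites are skipped.  r2 is the
    squared Pearson correlation of allele dosages (no phasing assumed);
    missing dosages are mean-imputed per site.
    """
    order = np.argsort(vt.pos, kind="stable")
    sel = order[::downsample_every]
    pos = vt.pos[sel]
    g = vt.gt[sel].astype(np.float64)
    dose = np.where(g >= 0, g, np.nan).sum(axis=2)  # nan if any allele missing
    with np.errstate(invalid="ignore"):
        mu = np.nanmean(dose, axis=1)
    filled = np.where(np.isnan(dose), mu[:, None], dose)
    sd = filled.std(axis=1)
    poly = sd > 0
    pos, filled, sd = pos[poly], filled[poly], sd[poly]
    m = len(pos)
    if m < 2:
        return pd.DataFrame(columns=["pos1", "pos2", "distance", "r2"])
    z = (filled - filled.mean(axis=1, keepdims=True)) / sd[:, None]
    r = (z @ z.T) / filled.shape[1]
    r2 = r**2
    i, j = np.triu_indices(m, k=1)
    dist = pos[j] - pos[i]
    within = (dist <= max_distance) | ((j - i - 1) <= max_between)
    keep = within & (r2[i, j] > r2_floor)
    return pd.DataFrame(
        {"pos1": pos[i[keep]], "pos2": pos[j[keep]],
         "distance": dist[keep], "r2": r2[i[keep], j[keep]]}
    )


def ld_decay(records: pd.DataFrame, bin_width: int = 10_000) -> pd.DataFrame:
    """Mean r2 per distance bin."""
    if len(records) == 0:
        return pd.DataFrame(columns=["bin_start", "bin_end", "mean_r2", "n_pairs"])
    b = (records["distance"] // bin_width).astype(int)
    g = records.groupby(b)["r2"]
    return pd.DataFrame(
        {
            "bin_start": g.mean().index * bin_width,
            "bin_end": (g.mean().index + 1) * bin_width,
            "mean_r2": g.mean().to_numpy(),
            "n_pairs": g.size().to_numpy(),
        }
    )


# ---------------------------------------------------------------------------
# SNP GWAS
# ---------------------------------------------------------------------------

def default_depth_cap(n_samples: int, mean_coverage: float) -> float:
    """Combined-depth cap: all samples at ~50% above average coverage."""
    return 1.5 * n_samples * mean_coverage


def snp_gwas(
    vt: VariantTable,
    phenotypes: np.ndarray,
    min_mq: float = 20.0,
    min_gq: float = 30.0,
    min_maf: float = 0.02,
    depth_cap: float | None = None,
    exclude_repeats: bool = True,
    genotypic: bool = False,
) -> pd.DataFrame:
    """Per-site association between a binary phenotype and SNP genotypes.

    Sites failing mapping quality (> min_mq), genotype quality (> min_gq),
    minor allele frequency (> min_maf), repeat overlap, or the combined-depth
    cap are excluded.  The default test is the allelic 1-df chi-square on the
    2x2 allele-count table; ``genotypic=True`` switches to the 2x3
    genotype-count table (2 df).
    """
    labels = np.asarray(phenotypes, dtype=bool)
    if labels.all() or not labels.any():
        raise ValueError("phenotypes must contain two classes")
    n_called, n_alt = _site_counts(vt.gt, np.arange(vt.n_samples))
    with np.errstate(divide="ignore", invalid="ignore"):
        af = n_alt / np.maximum(n_called, 1)
    maf = np.minimum(af, 1 - af)
    keep = (vt.mq > min_mq) & (vt.gq > min_gq) & (maf > min_maf) & (n_called > 0)
    if exclude_repeats:
        keep &= ~vt.repeat
    if depth_cap is not None:
        keep &= ~(vt.depth > depth_cap)
    if not keep.any():
        log.warning("event=gwas_all_sites_filtered")
        return pd.DataFrame(columns=["pos", "chi2", "p", "minus_log10_p"])

    case = np.flatnonzero(labels)
    ctrl = np.flatnonzero(~labels)
    nc, ac = _site_counts(vt.gt[keep], case)
    nk, ak = _site_counts(vt.gt[keep], ctrl)
    if genotypic:
        stat = np.zeros(int(keep.sum()))
        gsub = vt.gt[keep]
        dose = np.where(gsub >= 0, gsub, 0).sum(axis=2)
        ok = (gsub >= 0).all(axis=2)
        for s in range(len(stat)):
            tab = np.zeros((2, 3))
            for grp, rows in ((0, case), (1, ctrl)):
                d = dose[s, rows][ok[s, rows]]
                for g in (0, 1, 2):
                    tab[grp, g] = (d == g).sum()
            tab = tab[:, tab.sum(axis=0) > 0]
            if tab.shape[1] < 2 or (tab.sum(axis=1) == 0).any():
                stat[s] = 0.0
            else:
                stat[s] = sps.chi2_contingency(tab, correction=False)[0]
        df_dof = 2
    else:
        from .kmer_assoc import _chi2_2x2

        stat = _chi2_2x2(ac, nc - ac, ak, nk - ak)
        df_dof = 1
    p = sps.chi2.sf(stat, df=df_dof)
    with np.errstate(divide="ignore"):
        mlp = -np.log10(p)
    return pd.DataFrame(
        {"pos": vt.pos[keep], "chi2": stat, "p": p, "minus_log10_p": mlp}
    )


# ---------------------------------------------------------------------------
# TE / repeat windowing
# ---------------------------------------------------------------------------

def te_window_fraction(
    repeats: pd.DataFrame,
    seq_length: int,
    width: int = 150_000,
    family_column: str = "name",
) -> pd.DataFrame:
    """Proportion of each window covered by each repeat family.

    Overlapping annotations within a family are merged before coverage is
    computed.
    """
    windows = make_windows(seq_length, width)
    rows = []
    families = repeats[family_column].unique() if len(repeats) else []
    for fam in families:
        iv = repeats.loc[repeats[family_column] == fam, ["start", "end"]].to_numpy(dtype=np.int64)
        cov = cli_io.interval_coverage(windows, iv)
        for (s, e), c in zip(windows, cov):
            rows.append({"start": int(s), "end": int(e), "family": fam,
                         "statistic": "te_fraction", "value": float(c)})
    return pd.DataFrame(rows, columns=["start", "end", "family", "statistic", "value"])


# ---------------------------------------------------------------------------
# VCF input dialect
# ---------------------------------------------------------------------------

def read_vcf(path, seq_length: int, region: str | None = None) -> VariantTable:
    """Optional VCF input dialect for the variant table.

    Biallelic SNPs only; MQ and site QUAL map onto the mapping-quality and
    genotype-quality proxies, INFO/DP onto combined depth.  Invariant-site
    callability cannot be conveyed by plain VCF, so ``callable_intervals``
    is left as all-callable; the native interchange (genotype TSV plus a
    callable-sites BED) is preferred when invariant-site denominators matter.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    pos, gts, mq, gq, depth = [], [], [], [], []
    it = vcf(region) if region else vcf
    for rec in it:
        if not rec.is_snp or len(rec.ALT) != 1:
            continue
        pos.append(rec.POS - 1)  # VCF is 1-based
        g = rec.genotype.array()[:, :2]
        gts.append(np.where(g < 0, -1, np.minimum(g, 1)).astype(np.int8))
        mq.append(rec.INFO.get("MQ", 60.0))
        gq.append(rec.QUAL if rec.QUAL is not None else 99.0)
        depth.append(rec.INFO.get("DP", np.nan))
    m = len(pos)
    gt = (np.stack(gts) if m else np.zeros((0, len(samples), 2), dtype=np.int8))
    return VariantTable(
        pos=np.asarray(pos, dtype=np.int64),
        gt=gt,
        samples=samples,
        seq_length=seq_length,
        mq=np.asarray(mq, dtype=float),
        gq=np.asarray(gq, dtype=float),
        depth=np.asarray(depth, dtype=float),
    )


# ---------------------------------------------------------------------------
# truth-derived variant tables (simulator cohorts)
# ---------------------------------------------------------------------------

def truth_variants(cohort: Cohort, reference: str = "A") -> VariantTable:
    """Genotypes on the reference assembly straight from simulator truth,
    with simulated mapping-quality / genotype-quality / depth annotations.

    This stands in for the mapping + variant-calling steps: genotypes are
    exact, callability reflects which content each haplotype copy carries,
    and the annotations are drawn so that the standard site filters have
    something to act on (repeat-overlapping sites get low MQ and inflated
    depth; a small fraction of sites get low GQ).
    """
    ref = cohort.alleles[reference]
    carried = {
        sym: {s.content_id for s in al.segments}
        for sym, al in cohort.alleles.items()
    }
    n = len(cohort.individuals)

    # sites: class-divergent backbone positions plus every within-population
    # polymorphic site whose content the reference carries
    blocks = []  # (ref_pos, gt_block) per source
    div_pos = cohort.alleles["A"].class_snp_pos
    if len(div_pos):
        rp = lift_positions(ref.segments, BACKBONE, div_pos)
        ok = rp >= 0
        gt_b = np.full((int(ok.sum()), n, 2), -1, dtype=np.int8)
        for si, ind in enumerate(cohort.individuals):
            for h, copy in enumerate(ind.copies):
                gt_b[:, si, h] = 1 if copy.allele == "A" else 0
        blocks.append((rp[ok], gt_b))

    for cid, tab in cohort.variation.items():
        rp = lift_positions(ref.segments, cid, tab.pos)
        ok = rp >= 0
        if not ok.any():
            continue
        m_c = int(ok.sum())
        gt_b = np.full((m_c, n, 2), -1, dtype=np.int8)
        col_of = {ci: j for j, ci in enumerate(tab.copy_ids)}
        for si, ind in enumerate(cohort.individuals):
            for h, copy in enumerate(ind.copies):
                j = col_of.get((si, h))
                if j is None:
                    continue  # this copy's class lacks the content: missing
                gt_b[:, si, h] = tab.carriers[ok, j].astype(np.int8)
        blocks.append((rp[ok], gt_b))

    if blocks:
        ref_pos = np.concatenate([b[0] for b in blocks])
        gt = np.concatenate([b[1] for b in blocks], axis=0)
        order = np.argsort(ref_pos, kind="stable")
        ref_pos, gt = ref_pos[order], gt[order]
    else:
        ref_pos = np.array([], dtype=np.int64)
        gt = np.zeros((0, n, 2), dtype=np.int8)
    m = len(ref_pos)

    # callability intervals per haplotype copy on the reference
    callable_iv: list[np.ndarray] = []
    for ind in cohort.individuals:
        for copy in ind.copies:
            ivs = [
                (s.start, s.end)
                for s in ref.segments
                if s.content_id in carried[copy.allele] and s.end > s.start
            ]
            callable_iv.append(cli_io.merge_intervals(np.array(ivs, dtype=np.int64).reshape(-1, 2)))

    # simulated site annotations
    rng = _rng(cohort.config.seed, 5)
    rep_iv = ref.repeat_intervals
    in_rep = np.zeros(m, dtype=bool)
    if len(rep_iv):
        i = np.searchsorted(rep_iv[:, 0], ref_pos, side="right") - 1
        in_rep = (i >= 0) & (ref_pos < rep_iv[np.maximum(i, 0), 1])
    mq = np.where(in_rep, rng.uniform(2, 20, m), rng.uniform(40, 60, m))
    gq = rng.uniform(50, 99, m)
    low_gq = rng.random(m) < 0.02
    gq[low_gq] = rng.uniform(5, 29, int(low_gq.sum()))
    n_call_haps = (gt >= 0).sum(axis=(1, 2))
    lam = cohort.config.coverage / 2.0 * n_call_haps * np.where(in_rep, 3.0, 1.0)
    depth = rng.poisson(lam).astype(float)

    return VariantTable(
        pos=ref_pos,
        gt=gt,
        samples=cohort.samples,
        seq_length=len(ref),
        mq=mq,
        gq=gq,
        depth=depth,
        repeat=in_rep,
        callable_intervals=callable_iv,
    )
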