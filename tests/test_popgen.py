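"""pi / Hudson FST / Tajima's D / r2 / allelic chi-square against
independent brute-force oracles, plus filter and envelope behaviour."""

import numpy as np
import pandas as pd
import pytest

from morphlocus import popgen, synthio
from morphlocus.popgen import (
    VariantTable, hudson_fst, ld_scan, pairwise_pi, percentile_envelope,
    snp_gwas, tajima_constants, tajimas_d, te_window_fraction, truth_variants,
)

# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def haplotype_matrix(vt: VariantTable, idx) -> np.ndarray:
    """(n_sites, n_haplotypes) allele matrix for a sample subset."""
    return vt.gt[:, idx, :].reshape(len(vt.pos), -1)


def brute_pi(haps: np.ndarray, n_invariant: int) -> float:
    """All-pairs per-site difference count over callable sites."""
    m, n = haps.shape
    diffs = pairs = 0
    for s in range(m):
        called = haps[s][haps[s] >= 0]
        for i in range(len(called)):
            for j in range(i + 1, len(called)):
                pairs += 1
                diffs += int(called[i] != called[j])
    pairs += n_invariant * n * (n - 1) // 2
    return diffs / pairs


def brute_hudson(h1: np.ndarray, h2: np.ndarray) -> float:
    num = den = 0.0
    for s in range(h1.shape[0]):
        a, b = h1[s], h2[s]
        a, b = a[a >= 0], b[b >= 0]
        if len(a) < 2 or len(b) < 2:
            continue
        pi1 = np.mean([x != y for i, x in enumerate(a) for y in a[i + 1 :]]) if len(a) > 1 else 0
        pi2 = np.mean([x != y for i, x in enumerate(b) for y in b[i + 1 :]]) if len(b) > 1 else 0
        dxy = np.mean([x != y for x in a for y in b])
        num += dxy - (pi1 + pi2) / 2
        den += dxy
    return num / den


def brute_tajima(haps: np.ndarray) -> float:
    """Textbook D from the constants, computed independently here."""
    m, n = haps.shape
    seg = [s for s in range(m) if 0 < (haps[s] == 1).sum() < n]
    S = len(seg)
    pi = 0.0
    for s in seg:
        c = (haps[s] == 1).sum()
        pi += c * (n - c) / (n * (n - 1) / 2)
    a1 = sum(1 / i for i in range(1, n))
    a2 = sum(1 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return (pi - S / a1) / np.sqrt(e1 * S + e2 * S * (S - 1))


def make_vt(haps: np.ndarray, seq_length: int, positions=None) -> VariantTable:
    """VariantTable from a (n_sites, 2N) haplotype matrix (even 2N)."""
    m, two_n = haps.shape
    gt = haps.reshape(m, two_n // 2, 2).astype(np.int8)
    pos = np.arange(m, dtype=np.int64) if positions is None else np.asarray(positions)
    return VariantTable(pos, gt, [f"s{i}" for i in range(two_n // 2)], seq_length)


# ---------------------------------------------------------------------------
# pi
# ---------------------------------------------------------------------------

class TestPi:
    def test_two_haplotypes_one_difference_in_ten_sites(self):
        haps = np.array([[0, 1]])
        vt = make_vt(haps, 10)
        out = pairwise_pi(vt, vt.samples, width=10)
        assert out["value"][0] == pytest.approx(0.1)

    def test_all_invariant_window_is_zero(self):
        vt = make_vt(np.zeros((0, 4), dtype=np.int8).reshape(0, 4), 100)
        out = pairwise_pi(vt, vt.samples, width=100)
        assert out["value"][0] == pytest.approx(0.0)

    def test_six_haplotypes_matches_brute_force(self, rng):
        haps = (rng.random((12, 6)) < 0.4).astype(np.int8)
        vt = make_vt(haps, 50)
        out = pairwise_pi(vt, vt.samples, width=50)
        assert out["value"][0] == pytest.approx(brute_pi(haps, 50 - 12))

    def test_adding_invariant_sites_dilutes_pi(self):
        haps = np.array([[0, 1], [1, 0]])
        short = pairwise_pi(make_vt(haps, 10), ["s0"], width=10)["value"][0]
        long = pairwise_pi(make_vt(haps, 100), ["s0"], width=100)["value"][0]
        assert long < short

    def test_missing_genotypes_shrink_comparable_pairs(self):
        haps = np.array([[0, 1, -1, -1]])
        vt = make_vt(haps, 1)
        out = pairwise_pi(vt, vt.samples, width=1)
        assert out["value"][0] == pytest.approx(1.0)  # 1 diff / 1 comparable pair


# ---------------------------------------------------------------------------
# Hudson FST
# ---------------------------------------------------------------------------

class TestHudsonFst:
    def test_fixed_difference_is_one(self):
        h = np.array([[0, 0, 0, 0, 1, 1, 1, 1]])
        vt = make_vt(h, 10)
        out = hudson_fst(vt, ["s0", "s1"], ["s2", "s3"], width=10)
        assert out["value"][0] == pytest.approx(1.0)

    def test_identical_frequencies_nonpositive_raw_zero_plotted(self):
        h = np.array([[0, 1, 0, 1, 0, 1, 0, 1]])
        vt = make_vt(h, 10)
        out = hudson_fst(vt, ["s0", "s1"], ["s2", "s3"], width=10)
        assert out["value"][0] <= 0
        assert out["value_plotted"][0] == 0.0

    def test_matches_brute_force_on_random_pops(self, rng):
        h1 = (rng.random((30, 8)) < 0.3).astype(np.int8)
        h2 = (rng.random((30, 8)) < 0.7).astype(np.int8)
        haps = np.concatenate([h1, h2], axis=1)
        vt = make_vt(haps, 30)
        p1 = [f"s{i}" for i in range(4)]
        p2 = [f"s{i}" for i in range(4, 8)]
        out = hudson_fst(vt, p1, p2, width=30)
        assert out["value"][0] == pytest.approx(brute_hudson(h1, h2))

    def test_invariant_sites_do_not_move_fst(self):
        h = np.array([[0, 0, 1, 1]])
        a = hudson_fst(make_vt(h, 5), ["s0"], ["s1"], width=5)["value"][0]
        b = hudson_fst(make_vt(h, 500), ["s0"], ["s1"], width=500)["value"][0]
        assert a == pytest.approx(b)

    def test_never_exceeds_one(self, rng):
        for _ in range(10):
            haps = (rng.random((15, 12)) < rng.random()).astype(np.int8)
            vt = make_vt(haps, 20)
            out = hudson_fst(vt, [f"s{i}" for i in range(3)],
                             [f"s{i}" for i in range(3, 6)], width=20)
            v = out["value"][0]
            assert np.isnan(v) or v <= 1.0


# ---------------------------------------------------------------------------
# Tajima's D
# ---------------------------------------------------------------------------

class TestTajimasD:
    def test_toy_window_matches_independent_constants(self, rng):
        haps = (rng.random((3, 4)) < 0.5).astype(np.int8)
        while not ((haps.sum(axis=1) > 0) & (haps.sum(axis=1) < 4)).all():
            haps = (rng.random((3, 4)) < 0.5).astype(np.int8)
        vt = make_vt(haps, 100)
        out = tajimas_d(vt, vt.samples, width=100)
        assert out["value"][0] == pytest.approx(brute_tajima(haps))

    def test_random_bigger_window_matches_oracle(self, rng):
        haps = (rng.random((25, 10)) < 0.3).astype(np.int8)
        seg = (haps.sum(axis=1) > 0) & (haps.sum(axis=1) < 10)
        vt = make_vt(haps[seg], 1000)
        out = tajimas_d(vt, vt.samples, width=1000)
        assert out["value"][0] == pytest.approx(brute_tajima(haps[seg]))

    def test_all_singletons_negative(self):
        haps = np.zeros((8, 16), dtype=np.int8)
        for s in range(8):
            haps[s, s] = 1
        vt = make_vt(haps, 100)
        assert tajimas_d(vt, vt.samples, width=100)["value"][0] < 0

    def test_intermediate_frequency_positive(self):
        haps = np.zeros((8, 16), dtype=np.int8)
        haps[:, :8] = 1
        vt = make_vt(haps, 100)
        assert tajimas_d(vt, vt.samples, width=100)["value"][0] > 0

    def test_no_segregating_sites_missing_not_zero(self):
        vt = make_vt(np.zeros((2, 8), dtype=np.int8), 100)
        assert np.isnan(tajimas_d(vt, vt.samples, width=100)["value"][0])

    def test_constants_reject_tiny_samples(self):
        with pytest.raises(ValueError):
            tajima_constants(3)


# ---------------------------------------------------------------------------
# envelopes
# ---------------------------------------------------------------------------

class TestEnvelope:
    def _frame(self, values, stat="pi"):
        return pd.DataFrame({"statistic": stat, "value": values})

    def test_constant_statistic_collapses(self):
        env = percentile_envelope(self._frame(np.full(150, 0.7)), "pi")
        assert env["lower"] == env["upper"] == pytest.approx(0.7)

    def test_uniform_sampling_recovers_bounds(self, rng):
        env = percentile_envelope(self._frame(rng.random(10_000)), "pi")
        assert env["lower"] == pytest.approx(0.05, abs=0.01)
        assert env["upper"] == pytest.approx(0.95, abs=0.01)

    def test_fst_zeros_excluded_from_upper_percentile(self):
        vals = np.concatenate([np.zeros(900), np.full(100, 0.5)])
        df = pd.DataFrame({"statistic": "fst", "value": vals, "value_plotted": vals})
        env = percentile_envelope(df, "fst")
        assert env["upper"] == pytest.approx(0.5)
        assert env["n"] == 100


# ---------------------------------------------------------------------------
# LD
# ---------------------------------------------------------------------------

class TestLD:
    def test_perfect_linkage_r2_one(self):
        haps = np.tile(np.array([[0, 0, 1, 1, 0, 1, 1, 1]]), (2, 1))
        vt = make_vt(haps, 100)
        out = ld_scan(vt, downsample_every=1)
        assert len(out) == 1 and out["r2"][0] == pytest.approx(1.0)

    def test_independent_sites_below_recording_floor(self, rng):
        n = 400
        haps = (rng.random((2, 2 * n)) < 0.5).astype(np.int8)
        vt = make_vt(haps, 100)
        out = ld_scan(vt, downsample_every=1)
        assert len(out) == 0  # r2 ~ 1/n, under the 0.05 floor

    def test_hand_built_pair_matches_phased_formula(self):
        # 8 haplotypes doubled into homozygous diploids so the genotype
        # (composite) r2 equals the phased D^2/(p1 q1 p2 q2)
        h1 = np.array([1, 1, 1, 0, 0, 0, 1, 0])
        h2 = np.array([1, 1, 0, 0, 0, 1, 1, 0])
        haps = np.stack([np.repeat(h1, 2), np.repeat(h2, 2)]).astype(np.int8)
        vt = make_vt(haps, 100)
        out = ld_scan(vt, downsample_every=1)
        p1, p2 = h1.mean(), h2.mean()
        d = (h1 & h2).mean() - p1 * p2
        expected = d**2 / (p1 * (1 - p1) * p2 * (1 - p2))
        assert out["r2"][0] == pytest.approx(expected)

    def test_recording_rules_keep_everything_the_oracle_keeps(self, rng):
        m, n = 30, 20
        haps = (rng.random((m, 2 * n)) < rng.uniform(0.2, 0.8, (m, 1))).astype(np.int8)
        pos = np.sort(rng.choice(100_000, m, replace=False))
        vt = make_vt(haps, 100_000, positions=pos)
        out = ld_scan(vt, downsample_every=1, max_distance=100_000)
        got = {(int(a), int(b)) for a, b in zip(out["pos1"], out["pos2"])}
        dose = haps.reshape(m, n, 2).sum(axis=2)
        for i in range(m):
            for j in range(i + 1, m):
                if dose[i].std() == 0 or dose[j].std() == 0:
                    continue
                r2 = np.corrcoef(dose[i], dose[j])[0, 1] ** 2
                if r2 > 0.05:
                    assert (int(pos[i]), int(pos[j])) in got

    def test_decay_summary_bins_pairs(self):
        rec = pd.DataFrame({"pos1": [0, 0, 0], "pos2": [5_000, 15_000, 18_000],
                            "distance": [5_000, 15_000, 18_000],
                            "r2": [0.9, 0.5, 0.3]})
        dec = popgen.ld_decay(rec, bin_width=10_000)
        assert dec["mean_r2"].tolist() == [0.9, 0.4]
        assert dec["n_pairs"].tolist() == [1, 2]

    def test_downsampling_thins_sites(self, rng):
        haps = np.tile((rng.random((1, 16)) < 0.5).astype(np.int8), (200, 1))
        vt = make_vt(haps, 10_000, positions=np.arange(200) * 50)
        full = ld_scan(vt, downsample_every=1)
        thin = ld_scan(vt, downsample_every=100)
        assert len(thin) < len(full)


# ---------------------------------------------------------------------------
# SNP GWAS
# ---------------------------------------------------------------------------

class TestSnpGwas:
    def _vt(self, haps, **kw):
        vt = make_vt(np.asarray(haps, dtype=np.int8), 1000)
        for k, v in kw.items():
            setattr(vt, k, np.asarray(v))
        return vt

    def test_complete_separation_chi2_equals_allele_count(self):
        haps = np.array([[1] * 38 + [0] * 38])
        vt = self._vt(haps)
        labels = np.array([True] * 19 + [False] * 19)
        out = snp_gwas(vt, labels)
        assert out["chi2"][0] == pytest.approx(76.0)

    def test_low_maf_site_excluded(self):
        haps = np.zeros((1, 100), dtype=np.int8)
        haps[0, 0] = 1  # MAF 0.01
        out = snp_gwas(self._vt(haps), np.array([True] * 25 + [False] * 25))
        assert len(out) == 0

    def test_quality_and_depth_filters(self):
        haps = np.array([[1] * 10 + [0] * 10] * 4)
        labels = np.array([True] * 5 + [False] * 5)
        vt = self._vt(haps, mq=[60, 10, 60, 60], gq=[90, 90, 20, 90],
                      depth=[100, 100, 100, 10_000], repeat=[False] * 4)
        out = snp_gwas(vt, labels, depth_cap=1000)
        assert out["pos"].tolist() == [0]

    def test_repeat_sites_excluded(self):
        haps = np.array([[1] * 10 + [0] * 10] * 2)
        vt = self._vt(haps, repeat=[True, False])
        out = snp_gwas(vt, np.array([True] * 5 + [False] * 5))
        assert out["pos"].tolist() == [1]

    def test_matches_scipy_allelic_chi2(self, rng):
        from scipy import stats as sps

        haps = (rng.random((1, 40)) < 0.4).astype(np.int8)
        labels = np.array([True] * 10 + [False] * 10)
        out = snp_gwas(self._vt(haps), labels)
        h = haps[0]
        case_alt = h.reshape(20, 2)[labels].sum()
        ctrl_alt = h.reshape(20, 2)[~labels].sum()
        tab = [[case_alt, 20 - case_alt], [ctrl_alt, 20 - ctrl_alt]]
        expected = sps.chi2_contingency(tab, correction=False)[0]
        assert out["chi2"][0] == pytest.approx(expected)


# ---------------------------------------------------------------------------
# TE windowing
# ---------------------------------------------------------------------------

class TestTeFraction:
    def test_full_and_partial_coverage(self):
        rep = pd.DataFrame({"start": [0, 1200], "end": [1000, 1600],
                            "name": ["famA", "famB"]})
        out = te_window_fraction(rep, 2000, width=1000)
        a = out[(out["family"] == "famA")]
        assert a["value"].tolist() == [1.0, 0.0]
        b = out[(out["family"] == "famB")]
        assert b["value"].tolist() == [0.0, 0.4]

    def test_overlapping_annotations_merged(self):
        rep = pd.DataFrame({"start": [0, 100, 200], "end": [300, 400, 500],
                            "name": ["f", "f", "f"]})
        out = te_window_fraction(rep, 1000, width=1000)
        assert out["value"][0] == pytest.approx(0.5)  # union is [0, 500)


# ---------------------------------------------------------------------------
# simulator-facing behaviour
# ---------------------------------------------------------------------------

def test_vcf_dialect_biallelic_snps_only(tmp_path):
    text = (
        "##fileformat=VCFv4.2\n"
        '##INFO=<ID=DP,Number=1,Type=Integer,Description="d">\n'
        '##INFO=<ID=MQ,Number=1,Type=Float,Description="m">\n'
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="g">\n'
        "##contig=<ID=chr1,length=1000>\n"
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\n"
        "chr1\t11\t.\tA\tG\t90\t.\tDP=40;MQ=55\tGT\t0/1\t1/1\n"
        "chr1\t21\t.\tC\tT\t80\t.\tDP=35;MQ=58\tGT\t0/0\t./.\n"
        "chr1\t31\t.\tG\tGA\t70\t.\tDP=30;MQ=50\tGT\t0/0\t0/1\n"  # indel: skipped
    )
    p = tmp_path / "toy.vcf"
    p.write_text(text)
    vt = popgen.read_vcf(p, 1000)
    assert vt.pos.tolist() == [10, 20]  # 0-based, indel dropped
    assert vt.samples == ["s1", "s2"]
    assert vt.gt[0, 0].tolist() == [0, 1]
    assert vt.gt[1, 1].tolist() == [-1, -1]
    assert vt.mq.tolist() == [55.0, 58.0]


class TestTruthVariants:
    def test_pi_tracks_theta_genome_wide(self, tiny_cohort, tiny_config):
        vt = truth_variants(tiny_cohort)
        s, e = tiny_cohort.arch.background_region
        win = e - s
        out = pairwise_pi(vt, tiny_cohort.samples, width=win)
        bg = out[(out["start"] >= s)]["value"].dropna()
        assert bg.mean() == pytest.approx(tiny_config.theta_within, rel=0.3)

    def test_gwas_top_sites_in_divergent_region(self, tiny_cohort):
        vt = truth_variants(tiny_cohort)
        phen = tiny_cohort.phenotype_labels()
        labels = np.array([phen[s] == "A" for s in tiny_cohort.samples])
        out = snp_gwas(vt, labels)
        top = out.nlargest(10, "chi2")
        a = tiny_cohort.alleles["A"]
        ds, de = tiny_cohort.arch.divergent_region
        lo, hi = synthio.lift_positions(a.segments, synthio.BACKBONE,
                                        np.array([ds, de - 1]))
        assert (((top["pos"] >= lo) & (top["pos"] <= hi)).mean()) == 1.0

    def test_fst_missing_in_a_unique_windows(self, tiny_cohort):
        vt = truth_variants(tiny_cohort)
        phen = tiny_cohort.phenotype_labels()
        by = {m: [s for s in tiny_cohort.samples if phen[s] == m] for m in "AO"}
        a = tiny_cohort.alleles["A"]
        seg = next(s for s in a.segments if s.content_id == synthio.A_UNIQUE_1)
        out = hudson_fst(vt, by["A"], by["O"], width=500)
        inside = out[(out["start"] >= seg.start) & (out["end"] <= seg.end)]
        assert inside["value"].isna().all()
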