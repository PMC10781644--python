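"""End-to-end orchestration: simulate -> kmer -> depth -> popgen -> architecture.

Each stage hashes its own parameters together with its upstream stages'
hashes; a stage is skipped when its hash matches the recorded state and its
outputs are still present with matching checksums, so re-runs recompute
nothing and a parameter change invalidates exactly the stages downstream of
it.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from contextlib import contextmanager
from pathlib import Path

import numpy as np
import pandas as pd

from . import architecture as arch_mod
from . import cli_io, coverage, kmer_assoc, popgen, synthio
from .cli_io import Manifest, RunConfig

log = logging.getLogger("morphlocus")

CONTRASTS = {
    "A_vs_O": (("A",), ("O",)),
    "A_vs_I": (("A",), ("I",)),
    "AI_vs_O": (("A", "I"), ("O",)),
}


def _hash(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()[:16]


class StageFailure(RuntimeError):
    """A pipeline stage failed; partial outputs were quarantined."""


@contextmanager
def _guard(stage: str, outputs):
    """Halt on stage failure, naming the stage and renaming partial outputs
    to '<name>.partial' so a re-run cannot mistake them for complete."""
    try:
        yield
    except Exception as exc:
        for p in outputs:
            p = Path(p)
            if p.exists():
                p.rename(p.with_name(p.name + ".partial"))
        raise StageFailure(f"stage '{stage}' failed: {exc}") from exc


class _State:
    def __init__(self, outdir: Path):
        self.path = outdir / "state.json"
        self.data = json.loads(self.path.read_text()) if self.path.exists() else {}

    def fresh(self, stage: str, h: str, outputs: list[Path]) -> bool:
        rec = self.data.get(stage)
        if rec is None or rec["hash"] != h:
            return False
        for p in outputs:
            if not Path(p).exists():
                return False
        return True

    def record(self, stage: str, h: str, outputs: list[Path]) -> None:
        self.data[stage] = {"hash": h, "outputs": [str(p) for p in outputs]}
        self.path.write_text(json.dumps(self.data, indent=2))


def _contrast_labels(cohort: synthio.Cohort, case: tuple[str, ...], control: tuple[str, ...]):
    phen = cohort.phenotype_labels()
    samples = [s for s in cohort.samples if phen[s] in case + control]
    labels = np.array([phen[s] in case for s in samples])
    return samples, labels


def run_pipeline(cfg: RunConfig, outdir: str | Path) -> Manifest:
    """Run the configured stages; returns a manifest of all outputs.

    The in-memory cohort is rebuilt deterministically on every call (cheap);
    only file-producing work is skipped on re-runs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cli_io.save_config(outdir / "config.yaml", cfg)
    manifest = Manifest(seed=cfg.seed)
    manifest.add(outdir / "config.yaml", "config", {})
    state = _State(outdir)
    timings: dict[str, float] = {}

    arch = synthio.default_architecture(cfg.scale_factor)
    cohort = synthio.simulate_population(cfg, arch)
    a_allele = cohort.alleles["A"]
    locus = synthio.locus_interval(a_allele)
    bg_backbone = np.array([arch.background_region], dtype=np.int64)
    bg_iv = synthio.lift_intervals(a_allele.segments, synthio.BACKBONE, bg_backbone)
    background = coverage.BackgroundSpec("A", (int(bg_iv[0, 0]), int(bg_iv[0, 1])))

    sim_params = {k: v for k, v in cfg.to_dict().items()
                  if k in ("seed", "scale_factor", "n_per_morph", "coverage",
                           "read_length", "error_rate", "theta_within",
                           "d_between", "allele_freqs")}
    h_sim = _hash(sim_params)
    stages = set(cfg.stages)
    recomputed: list[str] = []

    # ---- simulate ---------------------------------------------------------
    fastqs = {s: outdir / f"{s}.fastq" for s in cohort.samples}
    sim_outputs = [outdir / f"assembly_{m}.fasta" for m in "AIo"] + list(fastqs.values())
    if "simulate" in stages:
        t0 = time.time()
        if state.fresh("simulate", h_sim, sim_outputs):
            log.info("event=stage_skipped stage=simulate")
        else:
            with _guard("simulate", sim_outputs):
                synthio.write_cohort(cohort, outdir)
                state.record("simulate", h_sim, sim_outputs)
                recomputed.append("simulate")
        timings["simulate"] = time.time() - t0
        for pattern in ("assembly_*.fasta", "truth_*.bed", "repeats_*.bed",
                        "*.fastq", "*.truth.tsv"):
            for p in sorted(outdir.glob(pattern)):
                manifest.add(p, "simulate", sim_params)
        manifest.add(outdir / "samples.tsv", "simulate", sim_params)

    # ---- k-mer association -------------------------------------------------
    h_kmer = _hash([h_sim, cfg.k, cfg.mac, cfg.maf, cfg.n_permutations, cfg.fwer])
    kmer_outputs = [outdir / f"assoc_{c}.tsv" for c in CONTRASTS] + [
        outdir / "kmer_hits.tsv", outdir / "kmer_report.json"
    ]
    if "kmer" in stages:
        t0 = time.time()
        if state.fresh("kmer", h_kmer, kmer_outputs):
            log.info("event=stage_skipped stage=kmer")
        else:
            with _guard("kmer", kmer_outputs):
                reads = synthio.cohort_reads(cohort)
                sets = {s: kmer_assoc.count_kmers(reads[s], k=cfg.k) for s in cohort.samples}
                report = {}
                all_hits = []
                for cname, (case, control) in CONTRASTS.items():
                    samples, labels = _contrast_labels(cohort, case, control)
                    table = kmer_assoc.build_table([sets[s] for s in samples], cfg.mac)
                    assoc = kmer_assoc.test_association(table, labels, cfg.maf, cfg.mac)
                    null = kmer_assoc.permutation_threshold(
                        table, labels, cfg.n_permutations, cfg.fwer, cfg.seed, cfg.maf, cfg.mac
                    )
                    sig = null.significant(assoc.statistic)
                    sig_kmers = assoc.kmers[sig]
                    df = assoc.to_frame()
                    df["significant"] = sig
                    cli_io.write_tsv(outdir / f"assoc_{cname}.tsv", df, seed=cfg.seed)
                    hits = {
                        m: kmer_assoc.map_kmers(sig_kmers, cohort.alleles[m].seq, cfg.k, m)
                        for m in ("A", "I", "o")
                    }
                    for m, hdf in hits.items():
                        hdf = hdf.copy()
                        hdf["contrast"] = cname
                        all_hits.append(hdf)
                    pair = {"A_vs_O": ("A", "o"), "A_vs_I": ("A", "I"), "AI_vs_O": ("A", "o")}[cname]
                    verdict = (
                        kmer_assoc.classify_divergence(
                            sig_kmers, {m: hits[m] for m in pair}
                        )
                        if len(sig_kmers)
                        else {"verdict": "none", "n_kmers": 0}
                    )
                    report[cname] = {
                        "n_significant": int(sig.sum()),
                        "threshold": null.threshold_5pct,
                        "filters": table.filter_log,
                        "divergence": {k: v for k, v in verdict.items() if not isinstance(v, tuple)},
                    }
                pd.concat(all_hits, ignore_index=True).pipe(
                    lambda d: cli_io.write_tsv(outdir / "kmer_hits.tsv", d, seed=cfg.seed)
                )
                (outdir / "kmer_report.json").write_text(json.dumps(report, indent=2))
                state.record("kmer", h_kmer, kmer_outputs)
                recomputed.append("kmer")
        timings["kmer"] = time.time() - t0
        for p in kmer_outputs:
            manifest.add(p, "kmer", {"k": cfg.k})

    # ---- depth -------------------------------------------------------------
    h_depth = _hash([h_sim, cfg.depth_window, cfg.repeat_threshold, cfg.call_thresholds])
    depth_out = outdir / "depth_calls.tsv"
    if "depth" in stages:
        t0 = time.time()
        if state.fresh("depth", h_depth, [depth_out]):
            log.info("event=stage_skipped stage=depth")
        else:
            with _guard("depth", [depth_out]):
                reads = synthio.cohort_reads(cohort)
                index = coverage.build_seed_index(a_allele.seq, cfg.k, "A")
                frames = []
                for s in cohort.samples:
                    d, _stats = coverage.map_reads_light(reads[s], index)
                    prof = coverage.window_depth(
                        d, cfg.depth_window, a_allele.repeat_intervals,
                        cfg.repeat_threshold, "A", s,
                    )
                    frames.append(prof)
                profile = pd.concat(frames, ignore_index=True)
                std = coverage.standardize(profile, background)
                calls = coverage.call_content(std, cfg.call_thresholds)
                cli_io.write_tsv(depth_out, calls, seed=cfg.seed)
                state.record("depth", h_depth, [depth_out])
                recomputed.append("depth")
        timings["depth"] = time.time() - t0
        manifest.add(depth_out, "depth", {"window": cfg.depth_window})

    # ---- popgen ------------------------------------------------------------
    h_pop = _hash([h_sim, cfg.popgen_window])
    pop_out = [outdir / "window_stats.tsv", outdir / "gwas_A_vs_O.tsv", outdir / "ld.tsv"]
    if "popgen" in stages:
        t0 = time.time()
        if state.fresh("popgen", h_pop, pop_out):
            log.info("event=stage_skipped stage=popgen")
        else:
            with _guard("popgen", pop_out):
                vt = popgen.truth_variants(cohort)
                phen = cohort.phenotype_labels()
                by = {m: [s for s in cohort.samples if phen[s] == m] for m in "AIO"}
                stats_frames = [
                    popgen.pairwise_pi(vt, cohort.samples, cfg.popgen_window),
                    popgen.tajimas_d(vt, cohort.samples, cfg.popgen_window),
                ]
                fst = popgen.hudson_fst(vt, by["A"], by["O"], cfg.popgen_window)
                stats_frames.append(fst)
                ws = pd.concat(stats_frames, ignore_index=True)
                cli_io.write_tsv(outdir / "window_stats.tsv", ws, seed=cfg.seed)
                labels = np.array([phen[s] == "A" for s in cohort.samples])
                cap = popgen.default_depth_cap(len(cohort.samples), cfg.coverage)
                gw = popgen.snp_gwas(vt, labels, depth_cap=cap)
                cli_io.write_tsv(outdir / "gwas_A_vs_O.tsv", gw, seed=cfg.seed)
                ld = popgen.ld_scan(vt, downsample_every=100)
                cli_io.write_tsv(outdir / "ld.tsv", ld, seed=cfg.seed)
                state.record("popgen", h_pop, pop_out)
                recomputed.append("popgen")
        timings["popgen"] = time.time() - t0
        for p in pop_out:
            manifest.add(p, "popgen", {"window": cfg.popgen_window})

    # ---- architecture ------------------------------------------------------
    h_arch = _hash([h_kmer, h_depth, h_pop, cfg.majority])
    arch_out = [outdir / "class_map.tsv", outdir / "locus_report.txt"]
    if "architecture" in stages:
        t0 = time.time()
        if state.fresh("architecture", h_arch, arch_out):
            log.info("event=stage_skipped stage=architecture")
        else:
            with _guard("architecture", arch_out):
                calls = cli_io.read_tsv(depth_out)
                phen = cohort.phenotype_labels()
                margin = 10 * cfg.depth_window
                cand = (max(0, locus[0] - margin), locus[1] + margin)
                cmap = arch_mod.classify_windows(calls, phen, cfg.majority, cand)
                cli_io.write_tsv(outdir / "class_map.tsv", cmap, seed=cfg.seed)
                hits = cli_io.read_tsv(outdir / "kmer_hits.tsv")
                shared = hits[hits["contrast"] == "AI_vs_O"]
                trans = None
                try:
                    ha = shared[shared["assembly"] == "A"].assign(kmer=lambda d: d["kmer"].astype(np.uint64))
                    hi = shared[shared["assembly"] == "I"].assign(kmer=lambda d: d["kmer"].astype(np.uint64))
                    trans = arch_mod.estimate_translocation(ha, hi)
                except (ValueError, arch_mod.AmbiguousTranslocationError) as exc:
                    log.warning("event=translocation_unavailable reason=%s", exc)
                ws = cli_io.read_tsv(outdir / "window_stats.tsv") if (outdir / "window_stats.tsv").exists() else None
                env = popgen.percentile_envelope(ws, "tajimas_d") if ws is not None else None
                intervals, text = arch_mod.locus_report(cmap, trans, ws, env)
                cli_io.write_tsv(outdir / "class_intervals.tsv", intervals, seed=cfg.seed)
                (outdir / "locus_report.txt").write_text(text)
                state.record("architecture", h_arch, arch_out)
                recomputed.append("architecture")
        timings["architecture"] = time.time() - t0
        for p in arch_out + [outdir / "class_intervals.tsv"]:
            manifest.add(p, "architecture", {"majority": cfg.majority})

    for stage, dt in timings.items():
        log.info("event=stage_timing stage=%s seconds=%.1f", stage, dt)
    manifest.save(outdir / "manifest.json")
    manifest.recomputed_stages = recomputed  # type: ignore[attr-defined]
    return manifest
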