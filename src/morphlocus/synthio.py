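"""Ground-truthed synthetic genomes, populations and short reads.

The simulator forges the three-haplotype architecture behind a female-limited
colour polymorphism: an ancestral backbone (the o allele), a derived A
haplotype carrying a tandem inverted duplication, two windows of novel
A-unique content and a block of novel content shared with the I haplotype,
and an I haplotype carrying only that shared block -- translocated several
megabases downstream of where it sits in the A arrangement.  A region of the
backbone shared by all morphs carries deep divergence between the A haplotype
class and everything else, emulating the footprint of long-term balancing
selection at intermediate allele frequencies.

Sizes default to the emulated system's full-scale physical sizes divided by
``scale_factor`` (A-unique ~400 kb and ~500 kb, shared ~150 kb, translocation
~3.5 mb, inverted duplication ~20 kb at full scale).

Coordinates are 0-based half-open everywhere.  Every stochastic step draws
from a named child stream of the master seed, so identical configs produce
byte-identical FASTA/FASTQ/BED output.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import _seq, cli_io
from .cli_io import RunConfig

# content-class labels used in truth files
BACKBONE = "backbone"
INVDUP = "inverted-dup"
A_UNIQUE_1 = "a-unique-1"
A_UNIQUE_2 = "a-unique-2"
AI_SHARED = "ai-shared"

CONTENT_CLASSES = (BACKBONE, INVDUP, A_UNIQUE_1, A_UNIQUE_2, AI_SHARED)

# full-scale layout (bp), divided by scale_factor in default_architecture
_FULL = {
    "o_length": 20_000_000,
    "dup_source": (280_000, 300_000),  # ~20 kb tandem inverted duplication
    "shared_insert_at": 500_000,
    "shared_length": 150_000,  # ~150 kb shared by A and I, absent in O
    "a1_insert_at": 510_000,
    "a1_length": 400_000,  # first window of A-unique content (~400 kb)
    "divergent_region": (510_000, 910_000),  # backbone shared by all morphs
    "a2_insert_at": 910_000,
    "a2_length": 500_000,  # second window of A-unique content (~500 kb)
    "translocation_offset": 3_500_000,  # ~3.5 mb shift of the shared block in I
    "background_region": (10_000_000, 20_000_000),
    "repeat_tract_length": 20_000,
}


class ConfigError(ValueError):
    """Invalid simulation configuration."""


class ArchitectureError(ValueError):
    """Inconsistent haplotype architecture (overlaps, out-of-range offsets)."""


class SimulationError(RuntimeError):
    """Unreachable sampling target (e.g. phenotype quota at frequency 0)."""


@dataclass(frozen=True)
class Segment:
    """A block of haplotype content.

    ``source_interval`` is a 0-based half-open interval on the ancestral
    backbone for duplicated content, or ``None`` for novel sequence.
    """

    id: str
    length: int
    source_interval: tuple[int, int] | None = None
    orientation: str = "forward"
    repeat_fraction: float = 0.0

    def __post_init__(self):
        # zero length is allowed (degenerate architectures with no novel content)
        if self.length < 0:
            raise ArchitectureError(f"segment {self.id}: negative length")
        if self.source_interval is not None:
            s, e = self.source_interval
            if s >= e:
                raise ArchitectureError(f"segment {self.id}: interval start >= end")
        if not 0.0 <= self.repeat_fraction <= 1.0:
            raise ArchitectureError(f"segment {self.id}: repeat_fraction outside [0,1]")
        if self.orientation not in ("forward", "reverse-complement"):
            raise ArchitectureError(f"segment {self.id}: bad orientation")


@dataclass
class HaplotypeArchitecture:
    """Ground-truth layout of the three morph haplotypes (scaled bp)."""

    scale_factor: float
    o_length: int
    dup: Segment  # tandem inverted duplication, inserted at dup.source_interval[1]
    shared: Segment
    a_unique_1: Segment
    a_unique_2: Segment
    shared_insert_at: int
    a1_insert_at: int
    a2_insert_at: int
    divergent_region: tuple[int, int]
    translocation_offset: int
    background_region: tuple[int, int]
    repeat_fraction: float = 0.10
    repeat_tract_length: int = 2_000
    repeat_unit_length: int = 100

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if self.translocation_offset <= self.shared.length:
            raise ArchitectureError(
                "translocation_offset must exceed the shared segment length"
            )
        pts = [self.dup.source_interval[1], self.shared_insert_at,
               self.a1_insert_at, self.a2_insert_at]
        if any(p < 0 or p > self.o_length for p in pts):
            raise ArchitectureError("insertion point outside the backbone")
        if sorted(pts) != pts or len(set(pts)) != len(pts):
            raise ArchitectureError("insertion points must be strictly increasing")
        ds, de = self.divergent_region
        if not (self.a1_insert_at <= ds < de <= self.a2_insert_at):
            raise ArchitectureError(
                "divergent region must lie between the two A-unique insertions"
            )
        bs, be = self.background_region
        if bs >= be or be > self.o_length:
            raise ArchitectureError("background region outside the backbone")
        if bs < self.a2_insert_at:
            raise ArchitectureError("background region overlaps the candidate locus")

    @property
    def a_unique_total(self) -> int:
        return self.a_unique_1.length + self.a_unique_2.length


def default_architecture(scale_factor: float = 10.0) -> HaplotypeArchitecture:
    """The full-scale architecture scaled down by ``scale_factor``."""
    if scale_factor <= 0:
        raise ConfigError("scale_factor must be positive")

    def s(v: int) -> int:
        return int(round(v / scale_factor))

    dup_src = (_FULL["dup_source"][0], _FULL["dup_source"][1])
    return HaplotypeArchitecture(
        scale_factor=scale_factor,
        o_length=s(_FULL["o_length"]),
        dup=Segment(
            INVDUP,
            s(dup_src[1] - dup_src[0]),
            source_interval=(s(dup_src[0]), s(dup_src[1])),
            orientation="reverse-complement",
        ),
        shared=Segment(AI_SHARED, s(_FULL["shared_length"])),
        a_unique_1=Segment(A_UNIQUE_1, s(_FULL["a1_length"])),
        a_unique_2=Segment(A_UNIQUE_2, s(_FULL["a2_length"])),
        shared_insert_at=s(_FULL["shared_insert_at"]),
        a1_insert_at=s(_FULL["a1_insert_at"]),
        a2_insert_at=s(_FULL["a2_insert_at"]),
        divergent_region=(s(_FULL["divergent_region"][0]), s(_FULL["divergent_region"][1])),
        translocation_offset=s(_FULL["translocation_offset"]),
        background_region=(s(_FULL["background_region"][0]), s(_FULL["background_region"][1])),
        repeat_tract_length=s(_FULL["repeat_tract_length"]),
    )


# ---------------------------------------------------------------------------
# placed segments: a haplotype as a partition into content blocks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlacedSegment:
    """haplotype[start:end] == contents[content_id][offset : offset+end-start]"""

    start: int
    end: int
    content_id: str
    offset: int = 0


def place_insertions(
    o_length: int, insertions: list[tuple[int, str, int]]
) -> list[PlacedSegment]:
    """Insert content blocks into the backbone at given backbone points.

    ``insertions`` is a list of (backbone_point, content_id, length); points
    must be non-decreasing is an error -- strictly increasing and in range.
    Returns placed segments that partition [0, o_length + sum(lengths)).
    """
    segs: list[PlacedSegment] = []
    cur_bb = 0
    hap = 0
    last_pt = -1
    for pt, cid, ln in sorted(insertions, key=lambda t: t[0]):
        if pt <= last_pt:
            raise ArchitectureError("overlapping insertion coordinates")
        if pt < cur_bb or pt > o_length:
            raise ArchitectureError(f"insertion point {pt} out of range")
        last_pt = pt
        if pt > cur_bb:
            segs.append(PlacedSegment(hap, hap + pt - cur_bb, BACKBONE, cur_bb))
            hap += pt - cur_bb
            cur_bb = pt
        segs.append(PlacedSegment(hap, hap + ln, cid, 0))
        hap += ln
    if cur_bb < o_length:
        segs.append(PlacedSegment(hap, hap + o_length - cur_bb, BACKBONE, cur_bb))
    return segs


def lift_positions(
    segments: list[PlacedSegment], content_id: str, pos: np.ndarray
) -> np.ndarray:
    """Map content-space positions to haplotype coordinates (-1 if absent)."""
    pos = np.asarray(pos, dtype=np.int64)
    out = np.full(pos.shape, -1, dtype=np.int64)
    for seg in segments:
        if seg.content_id != content_id:
            continue
        m = (pos >= seg.offset) & (pos < seg.offset + (seg.end - seg.start))
        out[m] = seg.start + pos[m] - seg.offset
    return out


def lift_intervals(
    segments: list[PlacedSegment], content_id: str, intervals: np.ndarray
) -> np.ndarray:
    """Map content-space intervals to haplotype intervals (clipped per block)."""
    iv = np.asarray(intervals, dtype=np.int64).reshape(-1, 2)
    out = []
    for seg in segments:
        if seg.content_id != content_id:
            continue
        lo, hi = seg.offset, seg.offset + (seg.end - seg.start)
        for s, e in iv:
            cs, ce = max(s, lo), min(e, hi)
            if cs < ce:
                out.append((seg.start + cs - lo, seg.start + ce - lo))
    return cli_io.merge_intervals(np.array(out, dtype=np.int64).reshape(-1, 2))


def content_intervals(segments: list[PlacedSegment]) -> pd.DataFrame:
    """Truth table of haplotype intervals per content class."""
    return pd.DataFrame(
        [(s.start, s.end, s.content_id) for s in segments],
        columns=["start", "end", "content"],
    )


# ---------------------------------------------------------------------------
# morph alleles
# ---------------------------------------------------------------------------

@dataclass
class MorphAllele:
    """One morph haplotype class: consensus sequence plus truth bookkeeping."""

    symbol: str
    seq: np.ndarray
    segments: list[PlacedSegment]
    # class-level divergence from the ancestral consensus: backbone positions
    # and alternative base codes (empty for o and I)
    class_snp_pos: np.ndarray = field(default_factory=lambda: np.array([], dtype=np.int64))
    class_snp_alt: np.ndarray = field(default_factory=lambda: np.array([], dtype=np.uint8))
    repeat_intervals: np.ndarray = field(default_factory=lambda: np.zeros((0, 2), dtype=np.int64))

    def __len__(self) -> int:
        return len(self.seq)


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=tuple(key)))


def _plant_repeats(
    backbone: np.ndarray, arch: HaplotypeArchitecture, rng: np.random.Generator
) -> np.ndarray:
    """Overwrite ~repeat_fraction of the backbone with tandem-repeat tracts.

    Each tract is one random unit tiled end to end, so reads drawn from a
    tract genuinely have ambiguous placements.  The inverted-duplication
    source is left untouched so its truth bookkeeping stays exact.
    """
    n = len(backbone)
    tract = max(arch.repeat_tract_length, 2 * arch.repeat_unit_length)
    n_tracts = int(round(arch.repeat_fraction * n / tract))
    if n_tracts == 0:
        return np.zeros((0, 2), dtype=np.int64)
    forbidden = (max(0, arch.dup.source_interval[0] - tract), arch.dup.source_interval[1] + tract)
    grid = np.arange(0, n - tract, 2 * tract)
    grid = grid[(grid + tract <= forbidden[0]) | (grid >= forbidden[1])]
    starts = np.sort(rng.choice(grid, size=min(n_tracts, len(grid)), replace=False))
    iv = []
    for s in starts:
        unit = _seq.random_seq(rng, arch.repeat_unit_length)
        reps = int(np.ceil(tract / arch.repeat_unit_length))
        backbone[s : s + tract] = np.tile(unit, reps)[:tract]
        iv.append((int(s), int(s + tract)))
    return np.array(iv, dtype=np.int64)


def build_ancestral_o(
    config: RunConfig, arch: HaplotypeArchitecture | None = None
) -> MorphAllele:
    """Random uniform-base ancestral backbone with planted repeat tracts.

    Deterministic given the config seed; errors if the backbone is shorter
    than 10 read lengths (no meaningful coverage simulation possible).
    """
    if arch is None:
        arch = default_architecture(config.scale_factor)
    if arch.o_length < 10 * config.read_length:
        raise ConfigError("o_length must be at least 10 x read_length")
    backbone = _seq.random_seq(_rng(config.seed, 0), arch.o_length)
    repeats = _plant_repeats(backbone, arch, _rng(config.seed, 1))
    segs = [PlacedSegment(0, arch.o_length, BACKBONE, 0)]
    return MorphAllele("o", backbone, segs, repeat_intervals=repeats)


def _novel_contents(
    arch: HaplotypeArchitecture, backbone: np.ndarray, seed: int
) -> dict[str, np.ndarray]:
    rng = _rng(seed, 2)
    s, e = arch.dup.source_interval
    contents = {
        BACKBONE: backbone,
        INVDUP: _seq.revcomp(backbone[s:e]),
        AI_SHARED: _seq.random_seq(rng, arch.shared.length),
        A_UNIQUE_1: _seq.random_seq(rng, arch.a_unique_1.length),
        A_UNIQUE_2: _seq.random_seq(rng, arch.a_unique_2.length),
    }
    return contents


def _realize(contents: dict[str, np.ndarray], segments: list[PlacedSegment]) -> np.ndarray:
    total = segments[-1].end
    out = np.empty(total, dtype=np.uint8)
    for seg in segments:
        out[seg.start : seg.end] = contents[seg.content_id][
            seg.offset : seg.offset + (seg.end - seg.start)
        ]
    return out


def derive_a_haplotype(
    o: MorphAllele,
    arch: HaplotypeArchitecture,
    config: RunConfig,
    contents: dict[str, np.ndarray] | None = None,
) -> MorphAllele:
    """A = backbone + tandem inverted duplication + shared block + two
    windows of novel A-unique content, with deep class divergence planted in
    the divergent backbone region."""
    if contents is None:
        contents = _novel_contents(arch, o.seq, config.seed)
    insertions = [
        (arch.dup.source_interval[1], INVDUP, arch.dup.length),
        (arch.shared_insert_at, AI_SHARED, arch.shared.length),
        (arch.a1_insert_at, A_UNIQUE_1, arch.a_unique_1.length),
        (arch.a2_insert_at, A_UNIQUE_2, arch.a_unique_2.length),
    ]
    segs = place_insertions(arch.o_length, insertions)
    # class-divergent sites on the backbone inside the divergent region
    rng = _rng(config.seed, 3)
    ds, de = arch.divergent_region
    hit = np.flatnonzero(rng.random(de - ds) < config.d_between) + ds
    alts = ((o.seq[hit] + rng.integers(1, 4, size=len(hit))) % 4).astype(np.uint8)
    seq = _realize(contents, segs)
    hap_pos = lift_positions(segs, BACKBONE, hit)
    seq[hap_pos] = alts
    rep = lift_intervals(segs, BACKBONE, o.repeat_intervals) if len(o.repeat_intervals) else np.zeros((0, 2), dtype=np.int64)
    return MorphAllele("A", seq, segs, class_snp_pos=hit, class_snp_alt=alts,
                       repeat_intervals=rep)


def derive_i_haplotype(
    o: MorphAllele,
    a: MorphAllele,
    arch: HaplotypeArchitecture,
    config: RunConfig,
    contents: dict[str, np.ndarray] | None = None,
) -> MorphAllele:
    """I = backbone + a copy of the shared block, translocated so that its
    I-assembly coordinate sits exactly ``translocation_offset`` downstream of
    its coordinate in the A arrangement."""
    if contents is None:
        contents = _novel_contents(arch, o.seq, config.seed)
    shared_in_a = next(s for s in a.segments if s.content_id == AI_SHARED)
    insert_at = shared_in_a.start + arch.translocation_offset
    if insert_at > arch.o_length:
        raise ArchitectureError(
            f"translocation point {insert_at} exceeds backbone length {arch.o_length}"
        )
    segs = place_insertions(arch.o_length, [(insert_at, AI_SHARED, arch.shared.length)])
    seq = _realize(contents, segs)
    rep = lift_intervals(segs, BACKBONE, o.repeat_intervals) if len(o.repeat_intervals) else np.zeros((0, 2), dtype=np.int64)
    return MorphAllele("I", seq, segs, repeat_intervals=rep)


def locus_interval(a: MorphAllele) -> tuple[int, int]:
    """Truth morph-locus span on the A assembly: from the inverted
    duplication through the end of the second A-unique window."""
    by_content = {s.content_id: s for s in a.segments}
    return (by_content[INVDUP].start, by_content[A_UNIQUE_2].end)


# ---------------------------------------------------------------------------
# population
# ---------------------------------------------------------------------------

PHENOTYPE_OF = {
    ("A", "A"): "A", ("A", "I"): "A", ("A", "o"): "A",
    ("I", "I"): "I", ("I", "o"): "I",
    ("o", "o"): "O",
}


def assign_phenotype(genotype: tuple[str, str]) -> str:
    """Dominance hierarchy A > I > o: one A allele -> morph A, else one I
    allele -> morph I, else morph O."""
    key = tuple(sorted(genotype))
    if key not in PHENOTYPE_OF:
        raise ValueError(f"unknown allele symbols in genotype {genotype}")
    return PHENOTYPE_OF[key]


@dataclass
class HaplotypeCopy:
    allele: str  # A / I / o


@dataclass
class DiploidIndividual:
    sample_id: str
    genotype: tuple[str, str]
    phenotype: str
    copies: list[HaplotypeCopy]
    sex: str = "female"


@dataclass
class SiteTable:
    """Within-population polymorphic sites on one content space.

    ``carriers[s, c]`` says whether carrying copy c (column order given by
    ``copy_ids``) holds the derived allele at site s.  Sites are drawn at
    Watterson density theta * a1(n) with derived-allele counts following the
    neutral frequency spectrum (P(i) proportional to 1/i), so expected
    pairwise diversity per site equals theta and windowed Tajima's D is
    centred near zero away from the planted divergent region.
    """

    pos: np.ndarray
    alt: np.ndarray
    carriers: np.ndarray  # bool, (n_sites, n_carrying_copies)
    copy_ids: list[tuple[int, int]]  # (individual index, haplotype index)


@dataclass
class Cohort:
    config: RunConfig
    arch: HaplotypeArchitecture
    alleles: dict[str, MorphAllele]
    individuals: list[DiploidIndividual]
    variation: dict[str, SiteTable] = field(default_factory=dict)

    @property
    def samples(self) -> list[str]:
        return [ind.sample_id for ind in self.individuals]

    def phenotype_labels(self) -> dict[str, str]:
        return {ind.sample_id: ind.phenotype for ind in self.individuals}

    def realize_haplotype(self, ind_idx_or_ind, which: int) -> np.ndarray:
        if isinstance(ind_idx_or_ind, DiploidIndividual):
            ind_idx = self.individuals.index(ind_idx_or_ind)
        else:
            ind_idx = int(ind_idx_or_ind)
        ind = self.individuals[ind_idx]
        copy = ind.copies[which]
        allele = self.alleles[copy.allele]
        seq = allele.seq.copy()
        for cid, tab in self.variation.items():
            try:
                col = tab.copy_ids.index((ind_idx, which))
            except ValueError:
                continue
            mask = tab.carriers[:, col]
            if not mask.any():
                continue
            hap = lift_positions(allele.segments, cid, tab.pos[mask])
            ok = hap >= 0
            seq[hap[ok]] = tab.alt[mask][ok]
        return seq

    def sample_sheet(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.samples,
                "phenotype": [i.phenotype for i in self.individuals],
                "genotype": ["".join(sorted(i.genotype)) for i in self.individuals],
            }
        )


def _watterson_a1(n: int) -> float:
    return float(np.sum(1.0 / np.arange(1, n))) if n >= 2 else 0.0


def _draw_within_variation(
    contents: dict[str, np.ndarray],
    carried_by: dict[str, set[str]],
    individuals: list[DiploidIndividual],
    theta_within: float,
    rng: np.random.Generator,
    forbidden_backbone: np.ndarray,
) -> dict[str, SiteTable]:
    """Unlinked neutral polymorphisms per content space across the copies
    that carry it (see :class:`SiteTable`)."""
    out: dict[str, SiteTable] = {}
    for cid, seq in contents.items():
        copy_ids = [
            (ii, h)
            for ii, ind in enumerate(individuals)
            for h, copy in enumerate(ind.copies)
            if cid in carried_by[copy.allele]
        ]
        n = len(copy_ids)
        if n < 2:
            continue
        L = len(seq)
        m = rng.binomial(L, min(1.0, theta_within * _watterson_a1(n)))
        if m == 0:
            continue
        pos = np.sort(rng.choice(L, size=m, replace=False).astype(np.int64))
        if cid == BACKBONE and len(forbidden_backbone):
            pos = np.setdiff1d(pos, forbidden_backbone)
        m = len(pos)
        if m == 0:
            continue
        alt = ((seq[pos] + rng.integers(1, 4, size=m)) % 4).astype(np.uint8)
        # derived-allele counts from the neutral SFS: P(i) ~ 1/i, i in 1..n-1
        i_vals = np.arange(1, n)
        p = (1.0 / i_vals) / (1.0 / i_vals).sum()
        counts = rng.choice(i_vals, size=m, p=p)
        ranks = rng.random((m, n)).argsort(axis=1)
        carriers = ranks < counts[:, None]
        out[cid] = SiteTable(pos, alt, carriers, copy_ids)
    return out


def simulate_population(
    config: RunConfig,
    arch: HaplotypeArchitecture | None = None,
) -> Cohort:
    """Draw diploid females until ``n_per_morph`` of each phenotype exist.

    Genotypes are Hardy-Weinberg draws at the configured (A, I, o) allele
    frequencies; phenotypes follow the A > I > o dominance hierarchy.
    """
    if arch is None:
        arch = default_architecture(config.scale_factor)
    freqs = np.asarray(config.allele_freqs, dtype=float)
    if freqs.min() < 0 or abs(freqs.sum() - 1.0) > 1e-9:
        raise ConfigError("allele_freqs must be non-negative and sum to 1")
    pA, pI, po = freqs
    if (pA == 0) or (pI == 0 and pA == 0) or (po == 0):
        # each phenotype needs positive probability: A needs pA>0, I needs
        # pI>0 with some non-A partner, O needs po>0
        raise SimulationError("phenotype quota unreachable at these allele frequencies")
    if pI == 0:
        raise SimulationError("phenotype quota unreachable: I frequency is 0")

    o = build_ancestral_o(config, arch)
    contents = _novel_contents(arch, o.seq, config.seed)
    a = derive_a_haplotype(o, arch, config, contents)
    i = derive_i_haplotype(o, a, arch, config, contents)
    alleles = {"o": o, "A": a, "I": i}

    rng = _rng(config.seed, 4)
    need = {"A": config.n_per_morph, "I": config.n_per_morph, "O": config.n_per_morph}
    counts = {"A": 0, "I": 0, "O": 0}
    individuals: list[DiploidIndividual] = []
    symbols = np.array(["A", "I", "o"])
    max_draws = 10_000 * 3 * config.n_per_morph
    draws = 0
    while any(counts[m] < need[m] for m in need):
        draws += 1
        if draws > max_draws:
            raise SimulationError("phenotype quotas not reached; check allele_freqs")
        g = tuple(sorted(rng.choice(symbols, size=2, p=freqs)))
        phen = assign_phenotype(g)
        if counts[phen] >= need[phen]:
            continue
        counts[phen] += 1
        sid = f"{phen}{counts[phen]:02d}"
        individuals.append(
            DiploidIndividual(sid, g, phen, [HaplotypeCopy(sym) for sym in g])
        )
    individuals.sort(key=lambda ind: ind.sample_id)
    carried_by = {
        sym: {s.content_id for s in al.segments} for sym, al in alleles.items()
    }
    variation = _draw_within_variation(
        contents, carried_by, individuals, config.theta_within,
        _rng(config.seed, 6), alleles["A"].class_snp_pos,
    )
    return Cohort(config, arch, alleles, individuals, variation)


# ---------------------------------------------------------------------------
# reads
# ---------------------------------------------------------------------------

@dataclass
class ReadSet:
    """Single-end reads from one diploid individual.

    ``matrix`` is (n_reads, read_length) encoded bases; truth arrays give the
    haplotype index, 0-based start on that haplotype and strand of each read.
    Truth is written only to a side-channel file, never into FASTQ.
    """

    sample_id: str
    matrix: np.ndarray
    hap_index: np.ndarray
    start: np.ndarray
    strand: np.ndarray  # True = reverse-complemented

    @property
    def n_reads(self) -> int:
        return len(self.matrix)

    @property
    def read_length(self) -> int:
        return self.matrix.shape[1]

    def names(self) -> list[str]:
        return [f"{self.sample_id}:{i}" for i in range(self.n_reads)]

    def write_fastq(self, path: str | Path) -> None:
        cli_io.write_fastq(path, self.names(), self.matrix)

    def write_truth(self, path: str | Path, seed: int | None = None) -> None:
        df = pd.DataFrame(
            {
                "read": self.names(),
                "hap": self.hap_index,
                "start": self.start,
                "end": self.start + self.read_length,
                "strand": np.where(self.strand, "-", "+"),
            }
        )
        cli_io.write_tsv(path, df, seed=seed)


def simulate_reads(
    haplotypes: tuple[np.ndarray, np.ndarray],
    config: RunConfig,
    rng: np.random.Generator,
    sample_id: str = "sample",
) -> ReadSet:
    """Uniform single-end reads from both haplotypes with substitution errors.

    Each haplotype contributes round(coverage x length / (2 x read_length))
    reads, so expected depth at a position present on both copies equals
    ``coverage``.
    """
    if config.coverage <= 0:
        raise ConfigError("coverage must be positive")
    rl = config.read_length
    mats, haps, starts, strands = [], [], [], []
    for hi, hap in enumerate(haplotypes):
        if len(hap) < rl:
            raise ConfigError("haplotype shorter than read_length")
        n = int(round(config.coverage * len(hap) / (2 * rl)))
        st = rng.integers(0, len(hap) - rl + 1, size=n)
        mat = hap[st[:, None] + np.arange(rl)[None, :]]
        rev = rng.random(n) < 0.5
        mat[rev] = 3 - mat[rev][:, ::-1]
        if config.error_rate > 0:
            err = rng.random(mat.shape) < config.error_rate
            shift = rng.integers(1, 4, size=int(err.sum()), dtype=np.uint8)
            mat[err] = (mat[err] + shift) % 4
        mats.append(mat)
        haps.append(np.full(n, hi, dtype=np.int8))
        starts.append(st)
        strands.append(rev)
    return ReadSet(
        sample_id,
        np.concatenate(mats),
        np.concatenate(haps),
        np.concatenate(starts).astype(np.int64),
        np.concatenate(strands),
    )


def cohort_reads(cohort: Cohort) -> dict[str, ReadSet]:
    """Deterministic per-individual read sets (child stream per sample)."""
    out = {}
    for idx, ind in enumerate(cohort.individuals):
        h1 = cohort.realize_haplotype(idx, 0)
        h2 = cohort.realize_haplotype(idx, 1)
        rng = _rng(cohort.config.seed, 100, idx)
        out[ind.sample_id] = simulate_reads((h1, h2), cohort.config, rng, ind.sample_id)
    return out


# ---------------------------------------------------------------------------
# null cohorts (permutation calibration)
# ---------------------------------------------------------------------------

def simulate_null_cohort(
    seed: int,
    n_samples: int = 20,
    genome_length: int = 50_000,
    snp_spacing: int = 200,
    coverage: float = 8.0,
    read_length: int = 100,
) -> tuple[list[ReadSet], np.ndarray]:
    """A cohort with population SNP variation and phenotypes independent of
    the genome, for family-wise error calibration.

    SNP sites sit every ``snp_spacing`` bp with allele frequencies drawn
    uniformly on (0.1, 0.9); haplotypes sample alleles independently per site
    (linkage equilibrium).  Labels are a fixed half/half split, so phenotype
    carries no genetic signal by construction.
    """
    rng = _rng(seed, 7)
    backbone = _seq.random_seq(rng, genome_length)
    sites = np.arange(snp_spacing // 2, genome_length, snp_spacing)
    freqs = rng.uniform(0.1, 0.9, size=len(sites))
    alts = ((backbone[sites] + rng.integers(1, 4, size=len(sites))) % 4).astype(np.uint8)
    cfg = RunConfig(seed=seed, coverage=coverage, read_length=read_length, error_rate=0.0)
    reads = []
    for s in range(n_samples):
        haps = []
        for _h in range(2):
            hap = backbone.copy()
            carry = rng.random(len(sites)) < freqs
            hap[sites[carry]] = alts[carry]
            haps.append(hap)
        reads.append(simulate_reads((haps[0], haps[1]), cfg, rng, f"S{s:02d}"))
    labels = np.zeros(n_samples, dtype=bool)
    labels[: n_samples // 2] = True
    return reads, labels


# ---------------------------------------------------------------------------
# output writers
# ---------------------------------------------------------------------------

def truth_bed(allele: MorphAllele) -> pd.DataFrame:
    df = content_intervals(allele.segments)
    df.insert(0, "chrom", allele.symbol)
    return df


def repeat_bed(allele: MorphAllele) -> pd.DataFrame:
    iv = allele.repeat_intervals
    return pd.DataFrame(
        {
            "chrom": allele.symbol,
            "start": iv[:, 0] if len(iv) else [],
            "end": iv[:, 1] if len(iv) else [],
            "name": "tandem-repeat",
        }
    )


def write_cohort(cohort: Cohort, outdir: str | Path) -> list[Path]:
    """Write assemblies, repeat/truth BEDs, sample sheet and per-sample FASTQ
    plus truth side-channels; returns the written paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = cohort.config.seed
    written = []
    for sym, allele in cohort.alleles.items():
        p = outdir / f"assembly_{sym}.fasta"
        cli_io.write_fasta(p, {sym: allele.seq}, seed=seed)
        written.append(p)
        p = outdir / f"truth_{sym}.bed"
        cli_io.write_bed(p, truth_bed(allele), seed=seed)
        written.append(p)
        p = outdir / f"repeats_{sym}.bed"
        cli_io.write_bed(p, repeat_bed(allele), seed=seed)
        written.append(p)
    p = outdir / "samples.tsv"
    cli_io.write_tsv(p, cohort.sample_sheet(), seed=seed)
    written.append(p)
    for sid, rs in cohort_reads(cohort).items():
        p = outdir / f"{sid}.fastq"
        rs.write_fastq(p)
        written.append(p)
        p = outdir / f"{sid}.truth.tsv"
        rs.write_truth(p, seed=seed)
        written.append(p)
    return written
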