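"""Morph-locus architecture from content calls and k-mer hit positions.

Integrates per-window read-depth genotype calls across morphs into content
classes (A-unique, AI-shared, all-shared, O-only), merges them into
intervals, estimates the translocation offset of the shared block from the
positions of shared-class k-mer hits on two assemblies, and renders a
single locus report.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger("morphlocus")

CLASSES = ("A-unique", "AI-shared", "all-shared", "O-only", "background", "ambiguous")


class AmbiguousTranslocationError(RuntimeError):
    """Shared-content hits do not form one dominant cluster per assembly."""


# ---------------------------------------------------------------------------
# window classification
# ---------------------------------------------------------------------------

def classify_windows(
    calls: pd.DataFrame,
    sample_morphs: dict[str, str],
    majority: float = 0.8,
    candidate_interval: tuple[int, int] | None = None,
) -> pd.DataFrame:
    """Per-window content class from per-morph majority genotype calls.

    ``calls`` needs columns (start, end, sample, call).  A window is
    "present" for a morph when >= ``majority`` of its samples are called
    heterozygous or homozygous-present, and "absent" when >= ``majority``
    are called absent -- so a single discordant individual (e.g. one O
    sample carrying the shared block) does not flip the class.  Windows
    outside ``candidate_interval`` are labelled background; windows meeting
    no rule are labelled ambiguous, never dropped.
    """
    morphs = sorted(set(sample_morphs.values()))
    per_morph_n = {m: sum(1 for v in sample_morphs.values() if v == m) for m in morphs}
    for mph, cnt in per_morph_n.items():
        if cnt < 3:
            raise ValueError(f"morph {mph} has {cnt} samples; need >= 3 to classify")

    df = calls.copy()
    df["morph"] = df["sample"].map(sample_morphs)
    df["present"] = df["call"].isin(["heterozygous", "homozygous-present"])
    grp = df.groupby(["start", "end", "morph"])["present"].mean().unstack("morph")

    def morph_state(row, mph):
        frac = row.get(mph, np.nan)
        if not np.isfinite(frac):
            return "unknown"
        if frac >= majority:
            return "present"
        if 1.0 - frac >= majority:
            return "absent"
        return "mixed"

    rows = []
    for (s, e), row in grp.iterrows():
        st = {mph: morph_state(row, mph) for mph in ("A", "I", "O")}
        if candidate_interval is not None and not (
            s >= candidate_interval[0] and e <= candidate_interval[1]
        ):
            cls = "background"
        elif st["A"] == "present" and st["I"] == "absent" and st["O"] == "absent":
            cls = "A-unique"
        elif st["A"] == "present" and st["I"] == "present" and st["O"] == "absent":
            cls = "AI-shared"
        elif st["A"] == "present" and st["I"] == "present" and st["O"] == "present":
            cls = "all-shared"
        elif st["A"] == "absent" and st["I"] == "absent" and st["O"] == "present":
            cls = "O-only"
        else:
            cls = "ambiguous"
        out = {"start": int(s), "end": int(e), "class": cls}
        for mph in ("A", "I", "O"):
            out[f"frac_present_{mph}"] = float(row.get(mph, np.nan))
        rows.append(out)
    return pd.DataFrame(rows).sort_values("start").reset_index(drop=True)


def merge_class_intervals(class_map: pd.DataFrame) -> pd.DataFrame:
    """Merge runs of adjacent same-class windows into intervals with spans."""
    out = []
    cur = None
    for _, row in class_map.sort_values("start").iterrows():
        if cur is not None and row["class"] == cur["class"] and row["start"] == cur["end"]:
            cur["end"] = row["end"]
        else:
            if cur is not None:
                out.append(cur)
            cur = {"start": row["start"], "end": row["end"], "class": row["class"]}
    if cur is not None:
        out.append(cur)
    df = pd.DataFrame(out)
    df["span"] = df["end"] - df["start"]
    return df


def class_totals(class_map: pd.DataFrame) -> dict[str, int]:
    """Total bp per content class across the classified windows."""
    widths = class_map["end"] - class_map["start"]
    return {
        cls: int(widths[class_map["class"] == cls].sum()) for cls in CLASSES
    }


# ---------------------------------------------------------------------------
# translocation
# ---------------------------------------------------------------------------

@dataclass
class TranslocationEstimate:
    centroid_a: float
    centroid_b: float
    offset: float
    span_a: tuple[int, int]
    span_b: tuple[int, int]
    n_kmers_a: int
    n_kmers_b: int


def _main_cluster(positions: np.ndarray, gap: int, min_fraction: float):
    pos = np.sort(np.asarray(positions))
    if len(pos) == 0:
        raise AmbiguousTranslocationError("no hit positions")
    breaks = np.flatnonzero(np.diff(pos) > gap)
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks + 1, [len(pos)]])
    sizes = ends - starts
    top = int(np.argmax(sizes))
    if sizes[top] < min_fraction * len(pos):
        diag = [(int(pos[s]), int(pos[e - 1]), int(e - s)) for s, e in zip(starts, ends)]
        raise AmbiguousTranslocationError(
            f"no cluster holds >= {min_fraction:.0%} of hits; clusters (start, end, n): {diag}"
        )
    cl = pos[starts[top] : ends[top]]
    return float(cl.mean()), (int(cl[0]), int(cl[-1])), len(cl)


def estimate_translocation(
    hits_a: pd.DataFrame,
    hits_b: pd.DataFrame,
    gap: int = 10_000,
    min_kmers: int = 100,
    min_cluster_fraction: float = 0.9,
) -> TranslocationEstimate:
    """Offset between the shared-content cluster on two assemblies.

    Hit positions on each assembly are clustered 1-D (split at gaps larger
    than ``gap``); each assembly's main cluster must hold at least
    ``min_cluster_fraction`` of its hits, otherwise the translocation is
    ambiguous.  The offset is the absolute difference of cluster centroids.
    """
    shared = np.intersect1d(
        hits_a["kmer"].to_numpy(dtype=np.uint64),
        hits_b["kmer"].to_numpy(dtype=np.uint64),
    )
    if len(shared) < min_kmers:
        raise ValueError(
            f"only {len(shared)} k-mers hit both assemblies; need >= {min_kmers}"
        )
    pa = hits_a[hits_a["kmer"].isin(shared)]["pos"].to_numpy()
    pb = hits_b[hits_b["kmer"].isin(shared)]["pos"].to_numpy()
    ca, span_a, na = _main_cluster(pa, gap, min_cluster_fraction)
    cb, span_b, nb = _main_cluster(pb, gap, min_cluster_fraction)
    return TranslocationEstimate(ca, cb, abs(cb - ca), span_a, span_b, na, nb)


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------

def locus_report(
    class_map: pd.DataFrame,
    translocation: TranslocationEstimate | None,
    window_stats: pd.DataFrame | None = None,
    envelope: dict | None = None,
) -> tuple[pd.DataFrame, str]:
    """Render the locus summary: class intervals, spans, translocation and
    which windows exceed the Tajima's D upper envelope.

    Returns (interval table, human-readable text).  Deterministic given its
    inputs, so regenerating from saved intermediates is byte-identical.
    """
    lines = []
    informative = class_map[~class_map["class"].isin(["background", "all-shared", "ambiguous"])]
    if len(informative) == 0:
        intervals = pd.DataFrame(columns=["start", "end", "class", "span"])
        lines.append("no morph-associated content")
        return intervals, "\n".join(lines) + "\n"

    intervals = merge_class_intervals(class_map)
    totals = class_totals(class_map)
    locus = informative
    lines.append(
        f"morph locus span: {int(locus['start'].min())}-{int(locus['end'].max())} "
        f"({int(locus['end'].max() - locus['start'].min())} bp)"
    )
    for cls in ("A-unique", "AI-shared", "all-shared", "O-only"):
        lines.append(f"total {cls}: {totals.get(cls, 0)} bp")
    if translocation is not None:
        lines.append(
            "shared-content translocation: "
            f"centroids {translocation.centroid_a:.0f} vs {translocation.centroid_b:.0f}, "
            f"offset {translocation.offset:.0f} bp"
        )
    if window_stats is not None and envelope is not None and np.isfinite(envelope.get("upper", np.nan)):
        d = window_stats[window_stats["statistic"] == "tajimas_d"]
        hot = d[d["value"] > envelope["upper"]]
        lines.append(
            f"windows above Tajima's D 95th percentile ({envelope['upper']:.3f}): {len(hot)}"
        )
        for _, row in hot.iterrows():
            lines.append(f"  {int(row['start'])}-{int(row['end'])} D={row['value']:.3f}")
    return intervals, "\n".join(lines) + "\n"
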