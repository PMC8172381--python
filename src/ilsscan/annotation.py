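"""Intersection of ILS segments with annotation tracks and content profiling.

Sweep-line (two-pointer) interval intersection over sorted tracks gives ILS
exon sets, gene-level counts, and the content columns of the summary table
(GC%, feature coverage %, intergenic-to-intragenic ratio).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .clustering import ILSSegmentSet


class AnnotationError(ValueError):
    pass


@dataclass
class FeatureTrack:
    """Sorted intervals (chrom, start, end, name) for one annotation class."""

    label: str
    intervals: pd.DataFrame

    def __post_init__(self) -> None:
        req = {"chrom", "start", "end"}
        if not req.issubset(self.intervals.columns):
            raise AnnotationError(f"track {self.label}: missing columns {req}")
        if "name" not in self.intervals.columns:
            self.intervals = self.intervals.assign(name=".")
        self.validate()

    @classmethod
    def from_bed(cls, label: str, path: str) -> "FeatureTrack":
        from .msa import read_bed

        recs = read_bed(path)
        df = pd.DataFrame(recs, columns=["chrom", "start", "end", "name"])
        return cls(label=label, intervals=df)

    def validate(self) -> None:
        for chrom, grp in self.intervals.groupby("chrom", sort=False):
            if not grp["start"].is_monotonic_increasing:
                raise AnnotationError(f"track {self.label}: unsorted on {chrom}")

    def merged(self) -> dict[str, np.ndarray]:
        """Per-chromosome merged (start, end) arrays (overlaps unioned)."""
        out: dict[str, np.ndarray] = {}
        for chrom, grp in self.intervals.groupby("chrom", sort=False):
            ivs = grp[["start", "end"]].to_numpy()
            merged: list[list[int]] = []
            for s, e in ivs:
                if merged and s <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            out[chrom] = np.array(merged, dtype=np.int64).reshape(-1, 2)
        return out


def sweep_intersect(a: pd.DataFrame, b: pd.DataFrame) -> list[tuple[int, int, int]]:
    """All overlapping pairs between two chromosome-sorted interval frames.

    Returns (index into a, index into b, overlap bp); deterministic two-pointer
    sweep per chromosome.
    """
    out: list[tuple[int, int, int]] = []
    a_idx = {c: g for c, g in a.groupby("chrom", sort=False)}
    b_idx = {c: g for c, g in b.groupby("chrom", sort=False)}
    for chrom in a_idx:
        if chrom not in b_idx:
            continue
        ga, gb = a_idx[chrom], b_idx[chrom]
        astarts = ga["start"].to_numpy()
        aends = ga["end"].to_numpy()
        bstarts = gb["start"].to_numpy()
        bends = gb["end"].to_numpy()
        ai = ga.index.to_numpy()
        bi = gb.index.to_numpy()
        if np.any(astarts[1:] < astarts[:-1]) or np.any(bstarts[1:] < bstarts[:-1]):
            raise AnnotationError(f"unsorted intervals on {chrom}")
        j0 = 0
        for k in range(len(astarts)):
            while j0 < len(bstarts) and bends[j0] <= astarts[k]:
                j0 += 1
            j = j0
            while j < len(bstarts) and bstarts[j] < aends[k]:
                ov = min(aends[k], bends[j]) - max(astarts[k], bstarts[j])
                if ov > 0:
                    out.append((int(ai[k]), int(bi[j]), int(ov)))
                j += 1
    return out


@dataclass
class ILSExonSet:
    """Exons overlapping ILS windows, tagged with every overlapping class."""

    exons: pd.DataFrame  # chrom, start, end, name, classes (frozenset), max_overlap
    min_overlap: int


def intersect_exons(
    segset: ILSSegmentSet, exon_track: FeatureTrack, min_overlap: int = 1
) -> ILSExonSet:
    """Exons with >= min_overlap bp overlap with at least one ILS window.

    An exon inherits the topology class of every overlapping window, so it can
    be tagged both HB_ILS and HC_ILS.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    exons = exon_track.intervals.reset_index(drop=True)
    ils = segset.ils.reset_index(drop=True)
    hits = sweep_intersect(exons, ils)
    classes: dict[int, set[str]] = {}
    best: dict[int, int] = {}
    for ei, wi, ov in hits:
        if ov < min_overlap:
            continue
        classes.setdefault(ei, set()).add(ils.loc[wi, "label"])
        best[ei] = max(best.get(ei, 0), ov)
    keep = sorted(classes)
    df = exons.loc[keep].copy()
    df["classes"] = [frozenset(classes[i]) for i in keep]
    df["max_overlap"] = [best[i] for i in keep]
    return ILSExonSet(exons=df.reset_index(drop=True), min_overlap=min_overlap)


def genes_with_k_ils_exons(
    ils_exons: ILSExonSet, exon_to_gene: dict[str, str], k: int = 2
) -> pd.DataFrame:
    """Genes with >= k distinct ILS exons, sorted by count desc then name.

    Exons without a gene mapping are counted under the sentinel '_unassigned'
    with a warning.
    """
    counts: dict[str, set[str]] = {}
    unmapped = 0
    for name in ils_exons.exons["name"]:
        gene = exon_to_gene.get(name)
        if gene is None:
            gene = "_unassigned"
            unmapped += 1
        counts.setdefault(gene, set()).add(name)
    if unmapped:
        warnings.warn(f"{unmapped} ILS exons without gene mapping")
    rows = [(g, len(ex)) for g, ex in counts.items() if len(ex) >= k]
    rows.sort(key=lambda r: (-r[1], r[0]))
    return pd.DataFrame(rows, columns=["gene", "n_ils_exons"])


def _coverage_in_windows(windows: pd.DataFrame, merged: dict[str, np.ndarray]) -> int:
    total = 0
    for chrom, grp in windows.groupby("chrom", sort=False):
        ivs = merged.get(chrom)
        if ivs is None or not len(ivs):
            continue
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        j = 0
        for s, e in zip(starts, ends):
            while j < len(ivs) and ivs[j, 1] <= s:
                j += 1
            jj = j
            while jj < len(ivs) and ivs[jj, 0] < e:
                total += min(e, ivs[jj, 1]) - max(s, ivs[jj, 0])
                jj += 1
    return int(total)


def _gc_in_windows(windows: pd.DataFrame, ref) -> tuple[int, int]:
    """(gc bases, called bases) over the windows; ref maps chrom -> sequence."""
    gc = called = 0
    for chrom, grp in windows.groupby("chrom", sort=False):
        try:
            seq = ref[chrom]
        except (KeyError, IndexError) as exc:
            raise AnnotationError(f"reference sequence missing for {chrom}") from exc
        arr = np.frombuffer(str(seq).upper().encode(), dtype=np.uint8)
        for s, e in zip(grp["start"].to_numpy(), grp["end"].to_numpy()):
            sub = arr[s:e]
            is_base = np.isin(sub, np.frombuffer(b"ACGT", dtype=np.uint8))
            called += int(is_base.sum())
            gc += int(np.isin(sub, np.frombuffer(b"GC", dtype=np.uint8)).sum())
    return gc, called


@dataclass
class ContentSummary:
    """GC / feature content of ILS windows and of all analyzable windows."""

    rows: pd.DataFrame = field(default_factory=pd.DataFrame)


def content_summary(
    segset: ILSSegmentSet,
    tracks: dict[str, FeatureTrack],
    ref,
    intragenic_label: str = "gene",
) -> ContentSummary:
    """Content columns for ILS windows plus the genome-average analogue.

    feature% = covered bp within the window set / total window bp * 100;
    GC% is over called bases only; the intergenic/intragenic ratio uses the
    ``intragenic_label`` track as the gene-body union.
    """
    merged = {lab: tr.merged() for lab, tr in tracks.items()}
    rows = []
    for set_label, windows in (("ILS", segset.ils), ("genome_average", segset.analyzable)):
        total_bp = int((windows["end"] - windows["start"]).sum())
        row: dict[str, object] = {"set": set_label, "total_bp": total_bp}
        if total_bp == 0:
            rows.append(row)
            continue
        gc, called = _gc_in_windows(windows, ref)
        row["gc_pct"] = 100.0 * gc / called if called else float("nan")
        for lab in tracks:
            cov = _coverage_in_windows(windows, merged[lab])
            row[f"{lab}_pct"] = 100.0 * cov / total_bp
        if intragenic_label in tracks:
            intra = _coverage_in_windows(windows, merged[intragenic_label])
            inter = total_bp - intra
            row["intragenic_bp"] = intra
            row["intergenic_bp"] = inter
            row["inter_intra_ratio"] = inter / intra if intra else float("inf")
        rows.append(row)
    return ContentSummary(rows=pd.DataFrame(rows))
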