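"""Spatial clustering of ILS segments against a random-placement null.

Observed inter-segment gaps (end-to-start, within chromosome) are compared to
a null in which, per replicate and chromosome, the observed number of ILS
windows is placed uniformly without replacement among that chromosome's
analyzable windows — so holes in alignability are never ILS-eligible and
cannot masquerade as clustering.  A two-sample Wilcoxon rank-sum test compares
the pooled distributions, and segments are partitioned into clustered /
non-clustered by thresholding each segment's nearest-neighbour gap at a null
quantile.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class ILSSegmentSet:
    """Sorted ILS windows plus the analyzable-window geometry, one window size."""

    window_size: int
    ils: pd.DataFrame  # chrom, start, end, label
    analyzable: pd.DataFrame  # chrom, start, end

    @classmethod
    def from_calls(cls, calls: pd.DataFrame, window_size: int,
                   ils_labels=("HB_ILS", "HC_ILS")) -> "ILSSegmentSet":
        calls = calls.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
        ils = calls[calls["label"].isin(ils_labels)][
            ["chrom", "start", "end", "label"]
        ].reset_index(drop=True)
        return cls(window_size=window_size, ils=ils,
                   analyzable=calls[["chrom", "start", "end"]].copy())

    def validate(self) -> None:
        for chrom, grp in self.ils.groupby("chrom", sort=False):
            starts = grp["start"].to_numpy()
            ends = grp["end"].to_numpy()
            if np.any(starts[1:] < ends[:-1]):
                raise ValueError(f"overlapping ILS windows on {chrom}")

    def chrom_geometry(self):
        """(chrom, analyzable starts, analyzable ends, n_ils) per chromosome."""
        out = []
        ils_counts = self.ils.groupby("chrom").size()
        for chrom, grp in self.analyzable.groupby("chrom", sort=False):
            out.append(
                (chrom, grp["start"].to_numpy(), grp["end"].to_numpy(),
                 int(ils_counts.get(chrom, 0)))
            )
        return out


@dataclass
class InterDistances:
    per_chrom: dict[str, np.ndarray]
    pooled: np.ndarray


def inter_ils_distances(segset: ILSSegmentSet) -> InterDistances:
    """Gaps (bp) between consecutive ILS windows, within chromosome only."""
    segset.validate()
    per_chrom: dict[str, np.ndarray] = {}
    pooled = []
    for chrom, grp in segset.ils.groupby("chrom", sort=False):
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        if len(starts) < 2:
            continue
        gaps = starts[1:] - ends[:-1]
        per_chrom[chrom] = gaps
        pooled.append(gaps)
    pooled_arr = np.concatenate(pooled) if pooled else np.array([], dtype=int)
    return InterDistances(per_chrom=per_chrom, pooled=pooled_arr)


def _nearest_neighbour_gaps(starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
    """Per-segment min of flanking gaps; chromosome ends use the single flank."""
    n = len(starts)
    if n < 2:
        return np.array([], dtype=int)
    gaps = starts[1:] - ends[:-1]
    left = np.concatenate(([np.iinfo(np.int64).max], gaps))
    right = np.concatenate((gaps, [np.iinfo(np.int64).max]))
    return np.minimum(left, right)


@dataclass
class NullModel:
    """Pooled null gap distributions stored as value/count tables."""

    window_size: int
    n_sims: int
    seed: int
    gap_values: np.ndarray
    gap_counts: np.ndarray
    nn_values: np.ndarray
    nn_counts: np.ndarray
    per_chrom_n: dict[str, int] = field(default_factory=dict)

    @property
    def n_gaps(self) -> int:
        return int(self.gap_counts.sum())

    def mean_gap(self) -> float:
        return float(np.average(self.gap_values, weights=self.gap_counts))

    def _quantile(self, values, counts, q) -> float:
        """Smallest support value whose CDF reaches q (inverted CDF)."""
        cdf = np.cumsum(counts) / counts.sum()
        idx = int(np.searchsorted(cdf, q, side="left"))
        return float(values[min(idx, len(values) - 1)])

    def gap_quantile(self, q: float) -> float:
        return self._quantile(self.gap_values, self.gap_counts, q)

    def nn_quantile(self, q: float) -> float:
        return self._quantile(self.nn_values, self.nn_counts, q)

    def sample_gaps(self, max_n: int = 500_000) -> np.ndarray:
        """The pooled null gaps, or a deterministic quantile-grid thinning."""
        total = self.n_gaps
        if total <= max_n:
            return np.repeat(self.gap_values, self.gap_counts)
        cdf = np.cumsum(self.gap_counts) / total
        probs = (np.arange(max_n) + 0.5) / max_n
        idx = np.searchsorted(cdf, probs, side="left")
        return self.gap_values[np.minimum(idx, len(self.gap_values) - 1)]


def simulate_null(
    segset: ILSSegmentSet, n_sims: int, seed: int, batch: int = 200
) -> NullModel:
    """Random placement null preserving per-chromosome counts and geometry."""
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    gap_acc: dict[int, int] = {}
    nn_acc: dict[int, int] = {}
    rng = np.random.default_rng(seed)
    per_chrom_n: dict[str, int] = {}
    for chrom, starts, ends, n in segset.chrom_geometry():
        per_chrom_n[chrom] = n
        N = len(starts)
        if n > N:
            raise ValueError(f"{chrom}: observed ILS count {n} exceeds analyzable {N}")
        if n < 2:
            continue
        done = 0
        while done < n_sims:
            m = min(batch, n_sims - done)
            keys = rng.random((m, N))
            idx = np.sort(np.argpartition(keys, n - 1, axis=1)[:, :n], axis=1)
            gaps = starts[idx[:, 1:]] - ends[idx[:, :-1]]
            nn = np.minimum(
                np.concatenate((np.full((m, 1), np.iinfo(np.int64).max), gaps), axis=1),
                np.concatenate((gaps, np.full((m, 1), np.iinfo(np.int64).max)), axis=1),
            )
            for acc, arr in ((gap_acc, gaps), (nn_acc, nn)):
                vals, cnts = np.unique(arr, return_counts=True)
                for v, c in zip(vals.tolist(), cnts.tolist()):
                    acc[v] = acc.get(v, 0) + c
            done += m
    if not gap_acc:
        raise ValueError("no chromosome with >= 2 ILS windows; null undefined")
    gv = np.array(sorted(gap_acc))
    nv = np.array(sorted(nn_acc))
    return NullModel(
        window_size=segset.window_size, n_sims=n_sims, seed=seed,
        gap_values=gv, gap_counts=np.array([gap_acc[v] for v in gv]),
        nn_values=nv, nn_counts=np.array([nn_acc[v] for v in nv]),
        per_chrom_n=per_chrom_n,
    )


@dataclass
class RankSumResult:
    statistic: float
    pvalue: float
    n_obs: int
    n_null: int


def compare_distributions(obs: InterDistances, null: NullModel,
                          max_null: int = 500_000) -> RankSumResult:
    """Two-sided two-sample Wilcoxon rank-sum of observed vs null gaps.

    Uses the exact distribution for tiny tie-free samples and the
    tie-corrected normal approximation otherwise.
    """
    x = np.asarray(obs.pooled, dtype=float)
    y = null.sample_gaps(max_null).astype(float)
    if x.size == 0 or y.size == 0:
        raise ValueError("empty sample")
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="auto")
    return RankSumResult(statistic=float(res.statistic), pvalue=float(res.pvalue),
                         n_obs=int(x.size), n_null=int(y.size))


@dataclass
class ClusterPartition:
    clustered: pd.DataFrame
    non_clustered: pd.DataFrame
    threshold_bp: float
    clustered_fraction: float


def partition_clustered(
    segset: ILSSegmentSet, null: NullModel, q: float = 0.05
) -> ClusterPartition:
    """Split ILS segments at the null q-quantile of nearest-neighbour gaps.

    A segment is clustered iff its nearest-neighbour gap (min of flanking
    gaps; single flank at chromosome ends) is <= the q-quantile of the null
    nearest-neighbour distribution.  Segments that are alone on their
    chromosome have no neighbour and are non-clustered.
    """
    if not 0.0 < q < 1.0:
        raise ValueError("q must be in (0, 1)")
    threshold = null.nn_quantile(q)
    flags = []
    for chrom, grp in segset.ils.groupby("chrom", sort=False):
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        if len(starts) < 2:
            flags.append(np.zeros(len(starts), dtype=bool))
            continue
        nn = _nearest_neighbour_gaps(starts, ends)
        flags.append(nn <= threshold)
    mask = np.concatenate(flags) if flags else np.array([], dtype=bool)
    ils = segset.ils.reset_index(drop=True)
    clustered = ils[mask].reset_index(drop=True)
    non_clustered = ils[~mask].reset_index(drop=True)
    frac = float(mask.mean()) if len(mask) else float("nan")
    return ClusterPartition(clustered=clustered, non_clustered=non_clustered,
                            threshold_bp=float(threshold), clustered_fraction=frac)
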