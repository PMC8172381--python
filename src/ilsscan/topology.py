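"""Per-window genealogy classification for the hominid quartet and quintet.

Four-taxon core: each window over {human, chimpanzee, bonobo} + gorilla
outgroup is classified by outgroup-polarized site-pattern counting.  A column
is informative when all four species carry a called base, the column shows a
clean derived pair — exactly two ingroup taxa share a state absent from the
outgroup while the third ingroup taxon matches the outgroup — and the pair
identity (BC / BH / CH) votes for one rooted topology.  The window label is
the strict argmax of the three counts; SPECIES for the bonobo+chimpanzee pair,
HB_ILS / HC_ILS for the two discordant genealogies, UNRESOLVED when the
window has too few informative sites, too small a margin, or a tie.

Five-taxon extension: with orangutan as outgroup, a Jukes-Cantor corrected
neighbor-joining tree is rooted on orangutan and the rooted ingroup shape over
{H, C, B, G} is mapped to SPECIES / PAN_ILS / OH_ILS / OGH_ILS / OTHER.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .msa import AlignmentWindow

LABELS_4 = ("SPECIES", "HB_ILS", "HC_ILS", "UNRESOLVED")
ILS_LABELS = ("HB_ILS", "HC_ILS")

_BASE_LUT = np.zeros(256, dtype=bool)
for _b in b"ACGT":
    _BASE_LUT[_b] = True


@dataclass(frozen=True)
class SpeciesRoles:
    """Which alignment row plays which part in the quartet/quintet."""

    human: str = "human"
    chimpanzee: str = "chimpanzee"
    bonobo: str = "bonobo"
    outgroup: str = "gorilla"
    outgroup2: str = "orangutan"


@dataclass(frozen=True)
class SitePatternCounts:
    """Outgroup-polarized derived-pair counts for one window."""

    n_bc: int
    n_bh: int
    n_ch: int
    n_other: int

    @property
    def n_informative(self) -> int:
        return self.n_bc + self.n_bh + self.n_ch


@dataclass(frozen=True)
class TopologyCall:
    chrom: str
    start: int
    end: int
    label: str
    counts: SitePatternCounts
    margin: int


@dataclass(frozen=True)
class FiveTaxonCall:
    chrom: str
    start: int
    end: int
    topology: str  # canonical rooted ingroup shape, "" when unresolved
    ils_class: str  # SPECIES | PAN_ILS | OH_ILS | OGH_ILS | OTHER | UNRESOLVED


def _seq_array(window: AlignmentWindow, species: str) -> np.ndarray:
    try:
        s = window.seqs[species]
    except KeyError:
        raise KeyError(f"window {window.chrom}:{window.start} missing species {species!r}")
    return np.frombuffer(s.encode(), dtype=np.uint8)


def count_site_patterns(
    window: AlignmentWindow, roles: SpeciesRoles = SpeciesRoles()
) -> SitePatternCounts:
    """Count clean derived-pair columns, polarized by the outgroup.

    BC pattern: bonobo==chimp, human==outgroup, pair state != outgroup state
    (and symmetrically for BH and CH).  Any other all-called variable column
    counts toward ``n_other``.
    """
    h = _seq_array(window, roles.human)
    c = _seq_array(window, roles.chimpanzee)
    b = _seq_array(window, roles.bonobo)
    g = _seq_array(window, roles.outgroup)
    valid = _BASE_LUT[h] & _BASE_LUT[c] & _BASE_LUT[b] & _BASE_LUT[g]
    bc = valid & (b == c) & (h == g) & (b != g)
    bh = valid & (b == h) & (c == g) & (b != g)
    ch = valid & (c == h) & (b == g) & (c != g)
    variable = valid & ~((h == c) & (c == b) & (b == g))
    other = variable & ~bc & ~bh & ~ch
    return SitePatternCounts(
        n_bc=int(bc.sum()), n_bh=int(bh.sum()), n_ch=int(ch.sum()),
        n_other=int(other.sum()),
    )


def call_topology(
    counts: SitePatternCounts,
    min_informative: int = 3,
    min_margin: int = 1,
    chrom: str = ".",
    start: int = 0,
    end: int = 0,
) -> TopologyCall:
    """Strict-argmax topology call with an informative-site floor and margin.

    Ties and under-supported windows are UNRESOLVED, never randomly assigned.
    """
    if min_informative < 0 or min_margin < 0:
        raise ValueError("thresholds must be non-negative")
    triple = (counts.n_bc, counts.n_bh, counts.n_ch)
    order = sorted(triple, reverse=True)
    margin = order[0] - order[1]
    if (
        counts.n_informative < min_informative
        or margin < min_margin
        or triple.count(order[0]) > 1
    ):
        label = "UNRESOLVED"
    else:
        label = ("SPECIES", "HB_ILS", "HC_ILS")[int(np.argmax(triple))]
    return TopologyCall(chrom=chrom, start=start, end=end, label=label,
                        counts=counts, margin=margin)


def classify_windows(
    windows: list[AlignmentWindow],
    roles: SpeciesRoles = SpeciesRoles(),
    min_informative: int = 3,
    min_margin: int = 1,
) -> pd.DataFrame:
    """Classify every window; returns the per-window call table.

    Columns: chrom, start, end, n_BC, n_BH, n_CH, n_other, label, margin.
    """
    rows = []
    for w in windows:
        counts = count_site_patterns(w, roles)
        call = call_topology(counts, min_informative, min_margin,
                             chrom=w.chrom, start=w.start, end=w.end)
        rows.append(
            dict(chrom=w.chrom, start=w.start, end=w.end,
                 n_BC=counts.n_bc, n_BH=counts.n_bh, n_CH=counts.n_ch,
                 n_other=counts.n_other, label=call.label, margin=call.margin)
        )
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "n_BC", "n_BH", "n_CH",
                       "n_other", "label", "margin"],
    )


# ---------------------------------------------------------------------------
# five-taxon calls
# ---------------------------------------------------------------------------

def jc_distance(a: np.ndarray, b: np.ndarray, saturated: float = 5.0) -> float:
    """Jukes-Cantor distance between two byte arrays over jointly called sites."""
    valid = _BASE_LUT[a] & _BASE_LUT[b]
    n = int(valid.sum())
    if n == 0:
        return saturated
    p = float((a[valid] != b[valid]).mean())
    if p >= 0.75:
        return saturated
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def _nj_tree(names: list[str], dmat: np.ndarray):
    from Bio.Phylo.TreeConstruction import DistanceMatrix, DistanceTreeConstructor

    lower = [[float(dmat[i, j]) for j in range(i + 1)] for i in range(len(names))]
    dm = DistanceMatrix(names, lower)
    return DistanceTreeConstructor().nj(dm)


def _classify_ingroup_splits(splits: set[frozenset], roles: SpeciesRoles) -> str:
    H, C, B, G = roles.human, roles.chimpanzee, roles.bonobo, roles.outgroup
    if frozenset({B, C}) in splits and frozenset({B, C, H}) in splits:
        return "SPECIES"
    if frozenset({H, B}) in splits or frozenset({H, C}) in splits:
        return "PAN_ILS"
    if frozenset({G, H}) in splits:
        return "OGH_ILS"
    if frozenset({B, C, G}) in splits:
        return "OH_ILS"
    return "OTHER"


def _canonical_newick(clade) -> str:
    if clade.is_terminal():
        return clade.name
    parts = sorted(_canonical_newick(ch) for ch in clade.clades)
    return "(" + ",".join(parts) + ")"


def call_topology_5taxa(
    window: AlignmentWindow,
    roles: SpeciesRoles = SpeciesRoles(),
    min_informative: int = 3,
    zero_branch_tol: float = 1e-9,
) -> FiveTaxonCall:
    """NJ + outgroup rooting over {H, C, B, G} with orangutan outgroup.

    The rooted ingroup shape is canonicalized and mapped to the deep-phylogeny
    discordance classes; windows whose NJ tree has an internal branch shorter
    than ``zero_branch_tol`` (substitutions/site), or with too few variable
    all-called columns, are UNRESOLVED.
    """
    order = [roles.human, roles.chimpanzee, roles.bonobo, roles.outgroup,
             roles.outgroup2]
    arrs = []
    for sp in order:
        if sp not in window.seqs:
            raise KeyError(f"window {window.chrom}:{window.start} missing species {sp!r}")
        arrs.append(_seq_array(window, sp))
    valid = np.ones(len(arrs[0]), dtype=bool)
    for a in arrs:
        valid &= _BASE_LUT[a]
    stacked = np.vstack(arrs)[:, valid]
    n_var = int((stacked != stacked[0]).any(axis=0).sum()) if stacked.size else 0
    unresolved = FiveTaxonCall(chrom=window.chrom, start=window.start,
                               end=window.end, topology="", ils_class="UNRESOLVED")
    if n_var < min_informative:
        return unresolved

    n = len(order)
    dmat = np.zeros((n, n))
    for i in range(n):
        for j in range(i):
            dmat[i, j] = dmat[j, i] = jc_distance(arrs[i], arrs[j])
    tree = _nj_tree(order, dmat)
    tree.root_with_outgroup(roles.outgroup2)

    ingroup_root = next(
        cl for cl in tree.root.clades
        if roles.outgroup2 not in {t.name for t in cl.get_terminals()}
    )
    internal_branches = [
        cl.branch_length or 0.0
        for cl in ingroup_root.find_clades()
        if not cl.is_terminal() and cl is not ingroup_root
    ]
    if any(bl < zero_branch_tol for bl in internal_branches):
        return unresolved
    splits = {
        frozenset(t.name for t in cl.get_terminals())
        for cl in ingroup_root.find_clades()
        if not cl.is_terminal() and cl is not ingroup_root
    }
    ils_class = _classify_ingroup_splits(splits, roles)
    return FiveTaxonCall(
        chrom=window.chrom, start=window.start, end=window.end,
        topology=_canonical_newick(ingroup_root), ils_class=ils_class,
    )


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

@dataclass
class ILSSummary:
    """Per-window-size class counts and percentages (Table-1-shaped row).

    ``pct`` holds percentages over all analyzable windows (these sum to 100
    including UNRESOLVED); ``total_ils_pct`` is HB+HC on the same denominator.
    ``ils_fraction_informative`` is HB+HC over resolved windows only — the
    estimator of the underlying genomic ILS fraction, since windows without
    informative sites carry no genealogy signal.
    """

    window_size: int
    n_windows: int
    counts: dict[str, int]
    pct: dict[str, float]
    total_ils_pct: float
    n_resolved: int
    ils_fraction_informative: float


@dataclass
class ILSFractionEstimate:
    """Detection-corrected estimate of the genomic ILS fraction.

    At hominid-like divergence a 500-bp window carries on the order of one
    informative site, so whether a window is called at all depends on its true
    class: the species-tree internal branch is longer than the discordant
    internal branch, concordant windows resolve more often, and the raw
    resolved-window fraction underestimates ILS.  Modelling each class's
    support count as Poisson, the counts observed among called windows follow
    a zero-truncated Poisson; fitting its rate per class gives each class a
    detection probability, and inverse-weighting the called counts corrects
    the bias (detection-probability correction, as in occupancy estimation).
    """

    ils_fraction: float
    raw_fraction: float
    corrected_counts: dict[str, float]
    detection_prob: dict[str, float]
    n_called: dict[str, int]


def _fit_truncated_poisson(x: np.ndarray) -> float:
    """MLE rate of a zero-truncated Poisson from counts >= 1 (moment solve)."""
    from scipy.optimize import brentq

    xbar = float(x.mean())
    if xbar <= 1.0 + 1e-9:
        return max(xbar - 1.0, 1e-6) if xbar > 1.0 else 1e-6
    return brentq(lambda lam: lam / -math.expm1(-lam) - xbar, 1e-9, max(10 * xbar, 1.0))


def estimate_ils_fraction(
    windows: list[AlignmentWindow], roles: SpeciesRoles = SpeciesRoles()
) -> ILSFractionEstimate:
    """Estimate the fraction of the genome under ILS from window calls.

    Classifies windows with an informative-site floor of 1 (the truncated-
    Poisson detection model needs the full support-count distribution) and
    applies the per-class detection-probability correction.
    """
    calls = classify_windows(windows, roles, min_informative=1, min_margin=1)
    support_col = {"SPECIES": "n_BC", "HB_ILS": "n_BH", "HC_ILS": "n_CH"}
    corrected: dict[str, float] = {}
    det: dict[str, float] = {}
    n_called: dict[str, int] = {}
    for lab, col in support_col.items():
        x = calls.loc[calls["label"] == lab, col].to_numpy()
        n_called[lab] = len(x)
        if len(x) == 0:
            corrected[lab] = 0.0
            det[lab] = float("nan")
            continue
        lam = _fit_truncated_poisson(x)
        p_det = float(-math.expm1(-lam))
        det[lab] = p_det
        corrected[lab] = len(x) / p_det
    total = sum(corrected.values())
    n_res = sum(n_called.values())
    raw = (n_called["HB_ILS"] + n_called["HC_ILS"]) / n_res if n_res else float("nan")
    ils = (
        (corrected["HB_ILS"] + corrected["HC_ILS"]) / total if total else float("nan")
    )
    return ILSFractionEstimate(
        ils_fraction=ils, raw_fraction=raw, corrected_counts=corrected,
        detection_prob=det, n_called=n_called,
    )


def summarize_ils(calls: pd.DataFrame, window_size: int) -> ILSSummary:
    """Aggregate per-window calls for one window size."""
    if not calls.empty:
        sizes = (calls["end"] - calls["start"]).unique()
        if len(sizes) > 1 or (len(sizes) == 1 and sizes[0] != window_size):
            raise ValueError(f"mixed or mismatched window sizes: {sorted(sizes)}")
    n = len(calls)
    counts = {lab: int((calls["label"] == lab).sum()) if n else 0 for lab in LABELS_4}
    if n == 0:
        pct = {lab: float("nan") for lab in LABELS_4}
        return ILSSummary(window_size, 0, counts, pct, float("nan"), 0, float("nan"))
    pct = {lab: 100.0 * counts[lab] / n for lab in LABELS_4}
    total_ils = pct["HB_ILS"] + pct["HC_ILS"]
    n_res = counts["SPECIES"] + counts["HB_ILS"] + counts["HC_ILS"]
    frac_inf = (
        (counts["HB_ILS"] + counts["HC_ILS"]) / n_res if n_res else float("nan")
    )
    return ILSSummary(window_size, n, counts, pct, total_ils, n_res, frac_inf)
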