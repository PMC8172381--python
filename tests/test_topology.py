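"""Site-pattern counting, quartet/quintet topology calls, and ILS summaries."""

import math

import numpy as np
import pandas as pd
import pytest

from ilsscan.simulate import DemographyModel, simulate_dataset, window_truth_labels
from ilsscan.msa import AlignmentWindow, WindowFilterConfig, extract_windows
from ilsscan.topology import (
    SitePatternCounts,
    SpeciesRoles,
    call_topology,
    call_topology_5taxa,
    classify_windows,
    count_site_patterns,
    summarize_ils,
)
from conftest import SPECIES4, SPECIES5, make_window

ROLES = SpeciesRoles()


class TestSitePatterns:
    def test_identical_sequences_give_zero_counts(self):
        w = make_window([("A", "A", "A", "A")] * 30)
        c = count_site_patterns(w)
        assert (c.n_bc, c.n_bh, c.n_ch, c.n_other) == (0, 0, 0, 0)

    def test_hand_enumerated_six_column_toy(self):
        # columns ordered (human, chimp, bonobo, gorilla)
        cols = [
            ("A", "G", "G", "A"),  # derived pair B+C
            ("A", "G", "G", "A"),  # derived pair B+C
            ("T", "C", "C", "T"),  # derived pair B+C
            ("A", "A", "G", "A"),  # derived singleton -> other
            ("C", "C", "C", "C"),  # invariant -> nothing
            ("A", "G", "C", "A"),  # three states -> other
        ]
        c = count_site_patterns(make_window(cols))
        assert (c.n_bc, c.n_bh, c.n_ch, c.n_other) == (3, 0, 0, 2)
        assert c.n_informative == 3

    def test_human_bonobo_derived_pair(self):
        cols = [("G", "A", "G", "A"), ("T", "C", "T", "C"), ("A", "A", "A", "A")]
        c = count_site_patterns(make_window(cols))
        assert (c.n_bc, c.n_bh, c.n_ch, c.n_other) == (0, 2, 0, 0)

    def test_missing_data_excluded(self):
        cols = [("A", "G", "G", "-"), ("A", "G", "G", "N"), ("A", "G", "G", "A")]
        c = count_site_patterns(make_window(cols))
        assert c.n_bc == 1

    def test_missing_species_raises(self):
        w = make_window([("A", "A", "A", "A")])
        del w.seqs["gorilla"]
        with pytest.raises(KeyError, match="gorilla"):
            count_site_patterns(w)

    def test_symmetry_under_chimp_bonobo_swap(self, rng):
        """Swapping the chimpanzee and bonobo rows maps BH<->CH and fixes BC."""
        for _ in range(50):
            cols = [tuple(rng.choice(list("ACGT-"), size=4)) for _ in range(60)]
            w = make_window(cols)
            sw = AlignmentWindow(
                chrom=w.chrom, start=w.start, end=w.end,
                seqs={**w.seqs, "chimpanzee": w.seqs["bonobo"],
                      "bonobo": w.seqs["chimpanzee"]},
                n_aligned_cols=w.n_aligned_cols,
            )
            a, b = count_site_patterns(w), count_site_patterns(sw)
            assert (a.n_bc, a.n_bh, a.n_ch, a.n_other) == (
                b.n_bc, b.n_ch, b.n_bh, b.n_other)


class TestCallTopology:
    @pytest.mark.parametrize(
        "triple,expected,margin",
        [((3, 1, 0), "SPECIES", 2), ((2, 2, 0), "UNRESOLVED", 0),
         ((0, 4, 1), "HB_ILS", 3), ((1, 1, 5), "HC_ILS", 4),
         ((1, 0, 0), "UNRESOLVED", 1)],  # below min_informative
    )
    def test_argmax_and_tie_rules(self, triple, expected, margin):
        c = SitePatternCounts(n_bc=triple[0], n_bh=triple[1], n_ch=triple[2], n_other=0)
        call = call_topology(c, min_informative=3, min_margin=1)
        assert call.label == expected
        assert call.margin == margin

    def test_negative_thresholds_rejected(self):
        c = SitePatternCounts(1, 1, 1, 0)
        with pytest.raises(ValueError):
            call_topology(c, min_informative=-1)

    def test_margin_threshold(self):
        c = SitePatternCounts(n_bc=5, n_bh=4, n_ch=0, n_other=0)
        assert call_topology(c, min_margin=2).label == "UNRESOLVED"
        assert call_topology(c, min_margin=1).label == "SPECIES"


def _evolve_tree(tree, branch, length, mu, rng):
    """Evolve ACGT sequences down a nested tuple tree; used as an
    implementation-independent sequence construction for the NJ caller."""
    seqs = {}

    def jc(seq, d):
        p = 0.75 * (1 - math.exp(-4 * d / 3))
        out = seq.copy()
        hit = rng.random(len(seq)) < p
        out[hit] = (out[hit] + rng.integers(1, 4, int(hit.sum()))) % 4
        return out

    def walk(node, seq):
        if isinstance(node, str):
            seqs[node] = jc(seq, branch[node] * mu)
            return
        for child in node:
            key = child if isinstance(child, str) else str(child)
            walk(child, jc(seq, branch.get(key, 0.0) * mu))

    walk(tree, rng.integers(0, 4, length))
    return {
        name: "".join("ACGT"[b] for b in arr) for name, arr in seqs.items()
    }


def _window_from_tree(tree, branch, rng, length=2000, mu=1.0, species=SPECIES5):
    seqs = _evolve_tree(tree, branch, length, mu, rng)
    return AlignmentWindow(chrom="sim", start=0, end=length,
                          seqs={sp: seqs[sp] for sp in species},
                          n_aligned_cols=length)


class TestFiveTaxon:
    def test_species_tree_recovered(self, rng):
        tree = (((("bonobo", "chimpanzee"), "human"), "gorilla"), "orangutan")
        branch = {"bonobo": 0.01, "chimpanzee": 0.01, "human": 0.02,
                  "gorilla": 0.03, "orangutan": 0.05,
                  str(("bonobo", "chimpanzee")): 0.01,
                  str((("bonobo", "chimpanzee"), "human")): 0.01,
                  str(((("bonobo", "chimpanzee"), "human"), "gorilla")): 0.01}
        call = call_topology_5taxa(_window_from_tree(tree, branch, rng))
        assert call.ils_class == "SPECIES"

    def test_gorilla_human_clade_is_ogh(self, rng):
        tree = ((("human", "gorilla"), ("bonobo", "chimpanzee")), "orangutan")
        branch = {"bonobo": 0.01, "chimpanzee": 0.01, "human": 0.02,
                  "gorilla": 0.02, "orangutan": 0.05,
                  str(("human", "gorilla")): 0.015,
                  str(("bonobo", "chimpanzee")): 0.015,
                  str((("human", "gorilla"), ("bonobo", "chimpanzee"))): 0.01}
        call = call_topology_5taxa(_window_from_tree(tree, branch, rng))
        assert call.ils_class == "OGH_ILS"

    def test_human_with_bonobo_is_pan_ils(self, rng):
        tree = (((("bonobo", "human"), "chimpanzee"), "gorilla"), "orangutan")
        branch = {"bonobo": 0.01, "human": 0.01, "chimpanzee": 0.02,
                  "gorilla": 0.03, "orangutan": 0.05,
                  str(("bonobo", "human")): 0.01,
                  str((("bonobo", "human"), "chimpanzee")): 0.01,
                  str(((("bonobo", "human"), "chimpanzee"), "gorilla")): 0.01}
        call = call_topology_5taxa(_window_from_tree(tree, branch, rng))
        assert call.ils_class == "PAN_ILS"

    def test_basal_human_is_oh(self, rng):
        tree = (((("bonobo", "chimpanzee"), "gorilla"), "human"), "orangutan")
        branch = {"bonobo": 0.01, "chimpanzee": 0.01, "gorilla": 0.02,
                  "human": 0.03, "orangutan": 0.05,
                  str(("bonobo", "chimpanzee")): 0.01,
                  str((("bonobo", "chimpanzee"), "gorilla")): 0.01,
                  str(((("bonobo", "chimpanzee"), "gorilla"), "human")): 0.01}
        call = call_topology_5taxa(_window_from_tree(tree, branch, rng))
        assert call.ils_class == "OH_ILS"

    def test_identical_sequences_unresolved(self):
        w = make_window([("A",) * 5] * 50, species=SPECIES5)
        assert call_topology_5taxa(w).ils_class == "UNRESOLVED"

    def test_missing_species_raises(self):
        w = make_window([("A",) * 4] * 50, species=SPECIES4)
        with pytest.raises(KeyError):
            call_topology_5taxa(w)


def _nj_quartet_call(window, roles=ROLES):
    """Independent four-taxon call: NJ on JC distances, rooted on gorilla."""
    from ilsscan.topology import _nj_tree, jc_distance, _seq_array

    order = [roles.human, roles.chimpanzee, roles.bonobo, roles.outgroup]
    arrs = [_seq_array(window, sp) for sp in order]
    n = len(order)
    dmat = np.zeros((n, n))
    for i in range(n):
        for j in range(i):
            dmat[i, j] = dmat[j, i] = jc_distance(arrs[i], arrs[j])
    tree = _nj_tree(order, dmat)
    tree.root_with_outgroup(roles.outgroup)
    ingroup = next(
        cl for cl in tree.root.clades
        if roles.outgroup not in {t.name for t in cl.get_terminals()}
    )
    cherries = [
        frozenset(t.name for t in cl.get_terminals())
        for cl in ingroup.find_clades()
        if not cl.is_terminal() and cl is not ingroup
    ]
    pair = cherries[0] if cherries else None
    mapping = {
        frozenset({roles.bonobo, roles.chimpanzee}): "SPECIES",
        frozenset({roles.bonobo, roles.human}): "HB_ILS",
        frozenset({roles.chimpanzee, roles.human}): "HC_ILS",
    }
    return mapping.get(pair, "UNRESOLVED")


def test_site_pattern_and_nj_calls_agree_at_margin_three():
    """On a simulated window suite, the argmax call matches an NJ-based call
    on every window with margin >= 3."""
    dem = DemographyModel(mu=5e-8, rec=2e-10).with_discordance(0.3)
    ds = simulate_dataset(dem, 1_000_000, seed=123)
    filt = WindowFilterConfig(required_species=tuple(SPECIES4))
    wins = extract_windows(ds.alignment, 1000, filt)
    assert len(wins) == 1000
    calls = classify_windows(wins, ROLES, min_informative=1)
    checked = 0
    for w, (_, row) in zip(wins, calls.iterrows()):
        if row["margin"] >= 3 and row["label"] != "UNRESOLVED":
            assert _nj_quartet_call(w) == row["label"], (w.start, row)
            checked += 1
    assert checked > 300


class TestSummarize:
    def test_percentages(self):
        labels = ["SPECIES"] * 90 + ["HB_ILS"] * 5 + ["HC_ILS"] * 5
        calls = pd.DataFrame(
            dict(chrom="chr1", start=np.arange(100) * 500,
                 end=(np.arange(100) + 1) * 500, label=labels)
        )
        s = summarize_ils(calls, 500)
        assert s.total_ils_pct == pytest.approx(10.0)
        assert s.counts["SPECIES"] == 90
        assert sum(s.pct.values()) == pytest.approx(100.0)
        assert s.ils_fraction_informative == pytest.approx(0.1)

    def test_empty_is_flagged(self):
        calls = pd.DataFrame(columns=["chrom", "start", "end", "label"])
        s = summarize_ils(calls, 500)
        assert s.n_windows == 0
        assert math.isnan(s.total_ils_pct)

    def test_mixed_window_sizes_rejected(self):
        calls = pd.DataFrame(
            dict(chrom=["chr1", "chr1"], start=[0, 500], end=[500, 1200],
                 label=["SPECIES", "SPECIES"])
        )
        with pytest.raises(ValueError):
            summarize_ils(calls, 500)

    def test_conservation_over_classes(self, rng):
        labels = rng.choice(["SPECIES", "HB_ILS", "HC_ILS", "UNRESOLVED"], size=200)
        calls = pd.DataFrame(
            dict(chrom="chr1", start=np.arange(200) * 500,
                 end=(np.arange(200) + 1) * 500, label=labels)
        )
        s = summarize_ils(calls, 500)
        assert sum(s.counts.values()) == s.n_windows == 200


def test_pure_tract_truth_labels_match_classifier():
    """High-information windows inside pure tracts are labelled correctly."""
    dem = DemographyModel(mu=4e-8, rec=2e-10).with_discordance(0.3)
    ds = simulate_dataset(dem, 1_000_000, seed=5)
    filt = WindowFilterConfig(required_species=tuple(SPECIES4))
    W = 2000
    wins = extract_windows(ds.alignment, W, filt)
    truth = window_truth_labels(ds.tracts, W)
    calls = classify_windows(wins, ROLES, min_informative=1)
    # restrict to windows fully inside one tract
    pure = {}
    for t in ds.tracts:
        first = -(-t.start // W)
        last = t.end // W
        for i in range(first, last):
            pure[i] = t.label
    good = total = 0
    for i, (_, row) in enumerate(calls.iterrows()):
        if i in pure and row["n_BC"] + row["n_BH"] + row["n_CH"] >= 20:
            total += 1
            good += row["label"] == pure[i]
    assert total > 100
    assert good / total >= 0.95
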