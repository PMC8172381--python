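"""Pairwise dN/dS by Nei-Gojobori (1986) counting with Jukes-Cantor correction.

Per codon, synonymous site counts are the fraction of the three single-base
changes at each position that preserve the amino acid (changes to stop codons
count as nonsynonymous); observed differences between two codons are
classified along mutational pathways, averaging over pathway orders and
skipping orders that pass through a stop codon.  Proportions pN = Nd/N and
pS = Sd/S are corrected with d = -(3/4) ln(1 - (4/3) p), and omega = dN/dS.

ILS exon sets are tested for excess amino-acid replacement with a one-sample
t-test of their omegas against the mean of a genome-wide null set.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from Bio.Data import CodonTable
from scipy import stats

_TABLE = CodonTable.unambiguous_dna_by_name["Standard"]
_AA = dict(_TABLE.forward_table)
_STOPS = frozenset(_TABLE.stop_codons)
_BASES = "ACGT"
SATURATION_P = 0.75


class DnDsError(ValueError):
    pass


@dataclass
class CodonAlignment:
    """One codon-aligned exon pair (equal lengths, multiple of 3, in frame)."""

    exon_id: str
    species: tuple[str, str]
    seq_a: str
    seq_b: str

    def __post_init__(self) -> None:
        if len(self.seq_a) != len(self.seq_b):
            raise DnDsError(f"{self.exon_id}: unequal sequence lengths")
        if len(self.seq_a) % 3 != 0:
            raise DnDsError(f"{self.exon_id}: length not a multiple of 3")

    def codons(self):
        a, b = self.seq_a.upper(), self.seq_b.upper()
        for i in range(0, len(a), 3):
            yield a[i:i + 3], b[i:i + 3]

    def has_internal_stop(self) -> bool:
        n = len(self.seq_a) // 3
        for i, (ca, cb) in enumerate(self.codons()):
            if i == n - 1:
                break  # terminal stop is legitimate
            if ca in _STOPS or cb in _STOPS:
                return True
        return False


@dataclass
class DnDsRecord:
    exon_id: str
    n_sites: float  # nonsynonymous sites N
    s_sites: float  # synonymous sites S
    nd: float
    sd: float
    pn: float
    ps: float
    dn: float
    ds: float
    omega: float  # nan when undefined (dS == 0) or saturated
    n_codons: int
    undefined: bool
    saturated: bool


@lru_cache(maxsize=None)
def ng86_sites(codon: str) -> tuple[float, float]:
    """(nonsynonymous, synonymous) site counts for one sense codon.

    Per position, the synonymous contribution is (# synonymous single-base
    changes)/3; changes to stop codons are nonsynonymous.  n + s == 3.
    """
    codon = codon.upper()
    if codon in _STOPS:
        raise DnDsError(f"stop codon {codon}")
    if codon not in _AA:
        raise DnDsError(f"ambiguous or invalid codon {codon!r}")
    s = 0.0
    for pos in range(3):
        for base in _BASES:
            if base == codon[pos]:
                continue
            mut = codon[:pos] + base + codon[pos + 1:]
            if mut not in _STOPS and _AA[mut] == _AA[codon]:
                s += 1.0 / 3.0
    return 3.0 - s, s


def _classify_step(c1: str, c2: str) -> tuple[float, float]:
    """(nd, sd) for a single-base step c1 -> c2 (both sense codons)."""
    if _AA[c1] == _AA[c2]:
        return 0.0, 1.0
    return 1.0, 0.0


@lru_cache(maxsize=None)
def ng86_diffs(codon_a: str, codon_b: str) -> tuple[float, float]:
    """(nd, sd) differences between two sense codons, pathway-averaged.

    Multi-hit codons average over all substitution orders whose intermediate
    codons avoid stops; when every order passes through a stop, all orders are
    averaged.  nd + sd equals the number of differing positions.
    """
    a, b = codon_a.upper(), codon_b.upper()
    if len(a) != 3 or len(b) != 3:
        raise DnDsError("codons must have length 3")
    for c in (a, b):
        if c in _STOPS:
            raise DnDsError(f"stop codon {c}")
        if c not in _AA:
            raise DnDsError(f"invalid codon {c!r}")
    diff_pos = [i for i in range(3) if a[i] != b[i]]
    if not diff_pos:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(diff_pos):
        cur = a
        nd = sd = 0.0
        ok = True
        for step, pos in enumerate(order):
            nxt = cur[:pos] + b[pos] + cur[pos + 1:]
            if nxt in _STOPS:
                ok = False
                break
            dn_, ds_ = _classify_step(cur, nxt)
            nd += dn_
            sd += ds_
            cur = nxt
        paths.append((ok, nd, sd))
    valid = [(nd, sd) for ok, nd, sd in paths if ok]
    if not valid:
        # all orders hit a stop: average over all complete stop-free prefixes
        # is ill-defined, so average over all orders ignoring the stop rule
        valid = []
        for order in itertools.permutations(diff_pos):
            cur = a
            nd = sd = 0.0
            for pos in order:
                nxt = cur[:pos] + b[pos] + cur[pos + 1:]
                if nxt in _STOPS or cur in _STOPS:
                    # count the step by amino-acid change where defined,
                    # else as nonsynonymous
                    nd += 1.0
                else:
                    dn_, ds_ = _classify_step(cur, nxt)
                    nd += dn_
                    sd += ds_
                cur = nxt
            valid.append((nd, sd))
    nd = sum(v[0] for v in valid) / len(valid)
    sd = sum(v[1] for v in valid) / len(valid)
    return nd, sd


def _jc(p: float) -> float:
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def dnds_pair(aln: CodonAlignment) -> DnDsRecord:
    """NG86 dN/dS for one codon-aligned pair.

    Codons containing gaps, ambiguity, or stops in either species are
    skipped; site counts N and S are averaged over the two sequences.
    """
    n_a = s_a = n_b = s_b = 0.0
    nd = sd = 0.0
    n_codons = 0
    skipped_stop = 0
    for ca, cb in aln.codons():
        if any(ch not in _BASES for ch in ca + cb):
            continue
        if ca in _STOPS or cb in _STOPS:
            skipped_stop += 1
            continue
        na_, sa_ = ng86_sites(ca)
        nb_, sb_ = ng86_sites(cb)
        n_a += na_
        s_a += sa_
        n_b += nb_
        s_b += sb_
        d_n, d_s = ng86_diffs(ca, cb)
        nd += d_n
        sd += d_s
        n_codons += 1
    if skipped_stop:
        warnings.warn(
            f"{aln.exon_id}: skipped {skipped_stop} stop-containing codon columns"
        )
    if n_codons == 0:
        raise DnDsError(f"{aln.exon_id}: zero countable codons")
    N = (n_a + n_b) / 2.0
    S = (s_a + s_b) / 2.0
    pn = nd / N if N > 0 else 0.0
    ps = sd / S if S > 0 else 0.0
    saturated = pn >= SATURATION_P or ps >= SATURATION_P
    dn = _jc(pn) if not saturated else float("nan")
    ds = _jc(ps) if not saturated else float("nan")
    undefined = (not saturated) and ds == 0.0
    omega = dn / ds if not saturated and ds > 0.0 else float("nan")
    return DnDsRecord(
        exon_id=aln.exon_id, n_sites=N, s_sites=S, nd=nd, sd=sd, pn=pn, ps=ps,
        dn=dn, ds=ds, omega=omega, n_codons=n_codons,
        undefined=undefined, saturated=saturated,
    )


def dnds_table(alignments: list[CodonAlignment],
               drop_internal_stops: bool = True) -> pd.DataFrame:
    """Per-exon dN/dS table; records with internal stops are flagged and dropped."""
    rows = []
    for aln in alignments:
        if drop_internal_stops and aln.has_internal_stop():
            warnings.warn(f"{aln.exon_id}: internal stop codon; excluded")
            continue
        rec = dnds_pair(aln)
        rows.append(vars(rec))
    return pd.DataFrame(rows)


@dataclass
class ExcessTestResult:
    label: str
    n: int
    mean_omega: float
    null_mean: float
    statistic: float
    pvalue: float


def excess_test(omegas_set, omegas_null, label: str = "set") -> ExcessTestResult:
    """One-sample two-sided t-test of a set's omegas against the null mean.

    Non-finite omegas (undefined / saturated) must be excluded upstream;
    they are rejected here.
    """
    x = np.asarray(omegas_set, dtype=float)
    null = np.asarray(omegas_null, dtype=float)
    if x.size < 2:
        raise DnDsError("need at least 2 omegas in the test set")
    if null.size == 0:
        raise DnDsError("empty null set")
    if not (np.isfinite(x).all() and np.isfinite(null).all()):
        raise DnDsError("non-finite omega in input; filter undefined records first")
    mu0 = float(null.mean())
    res = stats.ttest_1samp(x, popmean=mu0, alternative="two-sided")
    return ExcessTestResult(label=label, n=int(x.size), mean_omega=float(x.mean()),
                            null_mean=mu0, statistic=float(res.statistic),
                            pvalue=float(res.pvalue))


def read_codon_pairs_fasta(path: str) -> list[CodonAlignment]:
    """Read exon pairs from FASTA with ids '<exon>|<species>' (pairs consecutive)."""
    from Bio import SeqIO

    recs = list(SeqIO.parse(path, "fasta"))
    if len(recs) % 2 != 0:
        raise DnDsError(f"{path}: odd number of records")
    out = []
    for i in range(0, len(recs), 2):
        ra, rb = recs[i], recs[i + 1]
        ea, sa = (ra.id.split("|", 1) + ["a"])[:2]
        eb, sb = (rb.id.split("|", 1) + ["b"])[:2]
        if ea != eb:
            raise DnDsError(f"{path}: unpaired records {ra.id} / {rb.id}")
        out.append(CodonAlignment(exon_id=ea, species=(sa, sb),
                                  seq_a=str(ra.seq), seq_b=str(rb.seq)))
    return out
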