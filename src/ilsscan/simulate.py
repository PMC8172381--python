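"""Ground-truth generator: coalescent genealogy tracts, sequences, codon pairs.

The generator emulates the structure the detection pipeline assumes: a
chromosome is a tiling of genealogy tracts produced by an exponential renewal
process (tract scale 1/(r * 2N_A), the classical scale at which recombination
re-draws the local genealogy), each tract carrying the species topology or one
of the two discordant (ILS) topologies with the multispecies-coalescent
discordance probability p = (2/3) exp(-Delta / (2 N_A)), Delta = T_HP - T_BC
(generations in the ancestral Pan population of effective size N_A).  Sequences
evolve down each tract's genealogy under Jukes-Cantor; branch lengths use the
expected coalescent times conditional on the tract label (a sampled-times mode
is available for realism).  A separate generator produces codon-alignment
pairs with a specified dN/dS for the selection module.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict, replace

import numpy as np

from .msa import AlignmentBlock, GenomeAlignment

_BASE_CHARS = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class DemographyModel:
    """Split times (generations), ancestral size, and per-generation rates.

    Defaults correspond to 1.7 / 6 / 9 / 15 Myr splits at a 25-year generation
    time, N_A = 50,000, mu = 1.25e-8 /bp/gen, r = 1e-9 /bp/gen.  These are
    module defaults chosen to give hominid-like divergence (~0.4-1.6%
    pairwise) and ~10-kb genealogy tracts; they are tunable, not estimates.
    """

    t_bc: float = 1.7e6 / 25.0
    t_hp: float = 6.0e6 / 25.0
    t_g: float = 9.0e6 / 25.0
    t_o: float = 15.0e6 / 25.0
    n_anc: float = 5.0e4
    mu: float = 1.25e-8
    rec: float = 1.0e-9
    generation_time: float = 25.0

    def __post_init__(self) -> None:
        if not (0 < self.t_bc < self.t_hp < self.t_g < self.t_o):
            raise ValueError("require 0 < T_BC < T_HP < T_G < T_O")
        for name in ("n_anc", "mu", "rec", "generation_time"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def internal_branch(self) -> float:
        """Delta = T_HP - T_BC, the branch on which lineage sorting resolves."""
        return self.t_hp - self.t_bc

    def with_discordance(self, p: float) -> "DemographyModel":
        """Demography with ancestral size solved so that discordance equals p.

        Split times are kept; N_A = Delta / (2 ln(2 / 3p)).
        """
        if not 0.0 < p < 2.0 / 3.0:
            raise ValueError("p must be in (0, 2/3)")
        n_anc = self.internal_branch / (2.0 * math.log(2.0 / (3.0 * p)))
        return replace(self, n_anc=n_anc)


def discordance_probability(dem: DemographyModel) -> float:
    """P(gene tree discordant with the species tree) for the hominid quartet.

    p = (2/3) exp(-Delta / (2 N_A)); the two discordant classes (human+bonobo,
    human+chimpanzee) each occur with probability p/2.
    """
    delta = dem.internal_branch
    if delta <= 0 or dem.n_anc <= 0:
        raise ValueError("require positive internal branch and ancestral size")
    return (2.0 / 3.0) * math.exp(-delta / (2.0 * dem.n_anc))


@dataclass(frozen=True)
class TruthTract:
    chrom: str
    start: int
    end: int
    label: str  # SPECIES | HB_ILS | HC_ILS

    @property
    def length(self) -> int:
        return self.end - self.start


def _in_intervals(pos: float, intervals) -> bool:
    return any(s <= pos < e for s, e in intervals)


def simulate_tracts(
    dem: DemographyModel,
    length: int,
    seed: int | np.random.Generator,
    hotspots: list[tuple[int, int]] | None = None,
    hotspot_factor: float = 1.0,
    chrom: str = "sim1",
) -> list[TruthTract]:
    """Tile [0, length) with genealogy tracts.

    Tract lengths are exponential with mean 1/(r * 2 N_A) (rounded, >= 1 bp);
    labels are drawn {SPECIES: 1-p, HB_ILS: p/2, HC_ILS: p/2}.  Inside declared
    hotspot intervals p is multiplied by ``hotspot_factor`` (capped at 2/3 with
    a warning).  Deterministic given the seed.
    """
    if length <= 0:
        raise ValueError("length must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p0 = discordance_probability(dem)
    mean_len = 1.0 / (dem.rec * 2.0 * dem.n_anc)
    tracts: list[TruthTract] = []
    pos = 0
    capped = False
    while pos < length:
        tlen = max(1, int(round(rng.exponential(mean_len))))
        end = min(pos + tlen, length)
        p = p0
        if hotspots and hotspot_factor != 1.0 and _in_intervals((pos + end) / 2, hotspots):
            p = p0 * hotspot_factor
            if p > 2.0 / 3.0:
                p, capped = 2.0 / 3.0, True
        u = rng.random()
        if u < 1.0 - p:
            label = "SPECIES"
        elif u < 1.0 - p / 2.0:
            label = "HB_ILS"
        else:
            label = "HC_ILS"
        tracts.append(TruthTract(chrom=chrom, start=pos, end=end, label=label))
        pos = end
    if capped:
        import warnings

        warnings.warn("hotspot_factor pushed discordance above 2/3; capped")
    return tracts


# ---------------------------------------------------------------------------
# sequence layer
# ---------------------------------------------------------------------------

def _expected_times(dem: DemographyModel, label: str) -> dict[str, float]:
    """Node times (generations) for the tract genealogy, expected-time mode."""
    two_n = 2.0 * dem.n_anc
    delta = dem.internal_branch
    q = math.exp(-delta / two_n)
    times = {"g_join": dem.t_g + two_n, "o_join": dem.t_o + two_n}
    if label == "SPECIES":
        # pair coalescence conditional on landing within the internal branch
        e_c = two_n - delta * q / (1.0 - q)
        times["t1"] = dem.t_bc + e_c
        times["t2"] = dem.t_hp + two_n
    else:
        # three lineages enter the ancestral population; first coalescence
        # at rate 3/(2N), then the last pair at rate 1/(2N)
        times["t1"] = dem.t_hp + two_n / 3.0
        times["t2"] = times["t1"] + two_n
    return times


def _sampled_times(dem: DemographyModel, label: str, rng: np.random.Generator) -> dict[str, float]:
    two_n = 2.0 * dem.n_anc
    delta = dem.internal_branch
    times = {}
    if label == "SPECIES":
        # truncated exponential within the internal branch (inverse CDF)
        u = rng.random()
        e_c = -two_n * math.log1p(-u * (1.0 - math.exp(-delta / two_n)))
        times["t1"] = dem.t_bc + e_c
        times["t2"] = dem.t_hp + rng.exponential(two_n)
    else:
        times["t1"] = dem.t_hp + rng.exponential(two_n / 3.0)
        times["t2"] = times["t1"] + rng.exponential(two_n)
    times["g_join"] = max(dem.t_g + rng.exponential(two_n), times["t2"] + 1.0)
    times["o_join"] = max(dem.t_o + rng.exponential(two_n), times["g_join"] + 1.0)
    return times


def _evolve_branch(seq: np.ndarray, d_subs: float, rng: np.random.Generator) -> np.ndarray:
    """Jukes-Cantor evolution of a 0..3 integer sequence along d substitutions/site."""
    if d_subs <= 0:
        return seq.copy()
    p_diff = 0.75 * (1.0 - math.exp(-4.0 * d_subs / 3.0))
    out = seq.copy()
    hit = rng.random(seq.size) < p_diff
    k = int(hit.sum())
    if k:
        out[hit] = (out[hit] + rng.integers(1, 4, size=k)) % 4
    return out


def _tract_tree(label: str, times: dict[str, float], include_orangutan: bool):
    """Nested (time, children|leaf) genealogy for one tract."""
    if label == "SPECIES":
        pair = (times["t1"], ("bonobo", "chimpanzee"))
        trio = (times["t2"], (pair, "human"))
    elif label == "HB_ILS":
        pair = (times["t1"], ("bonobo", "human"))
        trio = (times["t2"], (pair, "chimpanzee"))
    elif label == "HC_ILS":
        pair = (times["t1"], ("human", "chimpanzee"))
        trio = (times["t2"], (pair, "bonobo"))
    else:
        raise ValueError(f"unknown tract label {label!r}")
    tree = (times["g_join"], (trio, "gorilla"))
    if include_orangutan:
        tree = (times["o_join"], (tree, "orangutan"))
    return tree


@dataclass
class SyntheticDataset:
    alignment: GenomeAlignment
    tracts: list[TruthTract]
    hotspots: list[tuple[int, int]] = field(default_factory=list)
    manifest: dict = field(default_factory=dict)

    def truth_intervals(self) -> list[tuple[str, int, int, str]]:
        return [(t.chrom, t.start, t.end, t.label) for t in self.tracts]

    def write_manifest(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")


def evolve_alignment(
    tracts: list[TruthTract],
    dem: DemographyModel,
    seed: int | np.random.Generator,
    include_orangutan: bool = False,
    sampled_times: bool = False,
) -> SyntheticDataset:
    """Evolve a gap-free alignment down each tract's genealogy.

    An ancestral uniform-random sequence at the root is propagated along each
    branch under Jukes-Cantor at rate mu; species rows are concatenated across
    tracts into a single alignment block on simulated reference coordinates.
    """
    if not tracts:
        raise ValueError("empty tract list")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    species = ["human", "chimpanzee", "bonobo", "gorilla"]
    if include_orangutan:
        species.append("orangutan")
    length = tracts[-1].end
    out = {sp: np.empty(length, dtype=np.uint8) for sp in species}

    def descend(node, seq, node_time):
        if isinstance(node, str):
            leaf_seq = _evolve_branch(seq, dem.mu * node_time, rng)
            out[node][tract.start:tract.end] = _BASE_CHARS[leaf_seq]
            return
        child_time, children = node
        child_seq = _evolve_branch(seq, dem.mu * (node_time - child_time), rng)
        for ch in children:
            descend(ch, child_seq, child_time)

    for tract in tracts:
        times = (
            _sampled_times(dem, tract.label, rng)
            if sampled_times
            else _expected_times(dem, tract.label)
        )
        root_time, children = _tract_tree(tract.label, times, include_orangutan)
        root_seq = rng.integers(0, 4, size=tract.length).astype(np.int64)
        for ch in children:
            descend(ch, root_seq, root_time)

    block = AlignmentBlock(
        chrom=tracts[0].chrom, ref_start=0,
        seqs={sp: out[sp].tobytes().decode() for sp in species},
    )
    ga = GenomeAlignment(species_ids=species, blocks=[block])
    return SyntheticDataset(alignment=ga, tracts=list(tracts))


def simulate_dataset(
    dem: DemographyModel,
    length: int,
    seed: int,
    hotspots: list[tuple[int, int]] | None = None,
    hotspot_factor: float = 1.0,
    include_orangutan: bool = False,
    sampled_times: bool = False,
    chrom: str = "sim1",
) -> SyntheticDataset:
    """Tracts + sequences + manifest from a single seed (bit-reproducible)."""
    rng = np.random.default_rng(seed)
    tracts = simulate_tracts(dem, length, rng, hotspots=hotspots,
                             hotspot_factor=hotspot_factor, chrom=chrom)
    ds = evolve_alignment(tracts, dem, rng, include_orangutan=include_orangutan,
                          sampled_times=sampled_times)
    ds.hotspots = list(hotspots or [])
    ds.manifest = dict(
        demography=asdict(dem), length=length, seed=seed, chrom=chrom,
        hotspots=[list(h) for h in ds.hotspots], hotspot_factor=hotspot_factor,
        include_orangutan=include_orangutan, sampled_times=sampled_times,
        discordance_probability=discordance_probability(dem),
    )
    return ds


def ils_bp_fraction(tracts: list[TruthTract]) -> float:
    """Fraction of simulated bp lying in ILS-labelled tracts."""
    total = sum(t.length for t in tracts)
    ils = sum(t.length for t in tracts if t.label != "SPECIES")
    return ils / total if total else float("nan")


def window_truth_labels(tracts: list[TruthTract], window_size: int) -> list[str]:
    """Majority-bp tract label for each full window tiling the simulated chromosome."""
    length = tracts[-1].end
    n_win = length // window_size
    labels = []
    ti = 0
    for i in range(n_win):
        start, end = i * window_size, (i + 1) * window_size
        cover: dict[str, int] = {}
        while ti < len(tracts) and tracts[ti].end <= start:
            ti += 1
        j = ti
        while j < len(tracts) and tracts[j].start < end:
            ov = min(end, tracts[j].end) - max(start, tracts[j].start)
            cover[tracts[j].label] = cover.get(tracts[j].label, 0) + ov
            j += 1
        labels.append(max(sorted(cover), key=lambda k: cover[k]))
    return labels


# ---------------------------------------------------------------------------
# codon alignments with known dN/dS
# ---------------------------------------------------------------------------

def _codon_tables():
    from Bio.Data import CodonTable

    table = CodonTable.unambiguous_dna_by_name["Standard"]
    aa = dict(table.forward_table)
    stops = set(table.stop_codons)
    sense = sorted(aa)
    return aa, stops, sense


def simulate_codon_exons(
    omega_true: float,
    n_exons: int,
    codons_per_exon: int,
    t: float,
    seed: int,
    pair: tuple[str, str] = ("human", "bonobo"),
):
    """Codon-alignment pairs evolved at a specified dN/dS.

    Each exon starts from a random stop-free codon sequence; candidate
    single-base changes arrive at ``t/2`` proposals per site on each of the two
    branches, are rejected if they create a stop, accepted if synonymous, and
    accepted with probability ``omega_true`` if nonsynonymous (so the
    nonsynonymous-to-synonymous rate ratio is omega by construction;
    ``omega_true = 0`` yields strictly synonymous evolution).

    Returns (alignments, manifest) where alignments is a list of
    (exon_id, seq_a, seq_b) tuples.
    """
    if omega_true < 0:
        raise ValueError("omega_true must be non-negative")
    if t <= 0:
        raise ValueError("t must be positive")
    aa, stops, sense = _codon_tables()
    rng = np.random.default_rng(seed)
    bases = "ACGT"

    def evolve(codons: list[str], branch_t: float) -> list[str]:
        out = list(codons)
        n_sites = 3 * len(out)
        n_events = rng.poisson(branch_t * n_sites)
        for _ in range(n_events):
            site = int(rng.integers(n_sites))
            ci, p = divmod(site, 3)
            old = out[ci]
            new_base = bases[(bases.index(old[p]) + int(rng.integers(1, 4))) % 4]
            new = old[:p] + new_base + old[p + 1:]
            if new in stops:
                continue
            # accept so that the nonsyn:syn rate ratio is omega for any
            # omega > 0: thin nonsynonymous events below omega = 1, thin
            # synonymous events above it
            if aa[new] == aa[old]:
                accept = omega_true <= 1.0 or rng.random() < 1.0 / omega_true
            else:
                accept = omega_true >= 1.0 or rng.random() < omega_true
            if accept:
                out[ci] = new
        return out

    alignments = []
    for i in range(n_exons):
        root = [sense[int(k)] for k in rng.integers(0, len(sense), size=codons_per_exon)]
        a = evolve(root, t / 2.0)
        b = evolve(root, t / 2.0)
        alignments.append((f"exon{i:04d}", "".join(a), "".join(b)))
    manifest = dict(omega_true=omega_true, n_exons=n_exons,
                    codons_per_exon=codons_per_exon, t=t, seed=seed,
                    pair=list(pair))
    return alignments, manifest


def write_codon_pairs_fasta(alignments, path: str,
                            pair: tuple[str, str] = ("human", "bonobo")) -> None:
    """Write exon pairs as FASTA with ids '<exon>|<species>' (pairs consecutive)."""
    with open(path, "w") as fh:
        for exon_id, a, b in alignments:
            fh.write(f">{exon_id}|{pair[0]}\n{a}\n>{exon_id}|{pair[1]}\n{b}\n")
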