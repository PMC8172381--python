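# Methods

## Window-based genealogy classification

The unit of analysis is a fixed-size window on the reference genome
(coordinates 0-based half-open, BED-compatible). Windows are anchored at
multiples of the window size W from chromosome start; the partial terminal
window is discarded, so the analyzable total is always (number of windows)·W.
A window is analyzable when alignment blocks cover at least `min_window_cov`
of it (default 0.5) and every required species has a called base in at least
`1 − max_missing_frac` of its columns (default 0.5). Blocks containing more
than one alignment row for a species (paralogous alignments) disqualify the
windows they touch, because the classifier assumes one sequence per species.
These thresholds are conventions, not estimates; they are recorded in the
persisted run config.

**Four-taxon calls.** For the quartet {human H, chimpanzee C, bonobo B} with
gorilla G as outgroup, a column votes when all four species have a called
base and it shows a clean outgroup-polarized derived pair: exactly two
ingroup taxa share a state absent from the outgroup while the third ingroup
taxon matches the outgroup. The pair identity increments n_BC, n_BH, or n_CH;
any other all-called variable column (derived singletons, outgroup
singletons, three-state columns) counts to n_other and carries no topology
signal. The window label is the strict argmax of (n_BC, n_BH, n_CH) —
SPECIES, HB_ILS, or HC_ILS — and UNRESOLVED when the informative total is
below `min_informative` (default 3), the winning margin is below `min_margin`
(default 1), or the maximum is tied. Ties are never broken randomly. By
construction the counting is exactly symmetric under exchanging the
chimpanzee and bonobo rows (HB↔HC). For quartets this argmax is equivalent to
choosing the parsimony/NJ tree; an NJ-based call agrees with it on every
window with margin ≥ 3 in the test suite.

**Five-taxon calls.** With orangutan as outgroup, pairwise Jukes–Cantor
distances over jointly called sites feed neighbor-joining
(Bio.Phylo); the tree is rooted on orangutan and the rooted ingroup shape
over {H,C,B,G} is mapped to classes: the species shape (((B,C),H),G) →
SPECIES; a human–bonobo or human–chimpanzee cherry → PAN_ILS; a
gorilla–human cherry → OGH_ILS; human basal (sister to the B,C,G clade,
i.e. pulled toward the orangutan root) → OH_ILS; anything else → OTHER.
Windows with fewer variable all-called columns than `min_informative`, or
whose NJ tree has an internal branch shorter than 1e−9 substitutions/site,
are UNRESOLVED.

**Summaries and the detection-corrected ILS fraction.** `summarize_ils`
reports per-class counts and percentages over all analyzable windows (these
sum to 100% including UNRESOLVED; "total ILS" = HB% + HC% on that
denominator, the convention of window-sweep summary tables), plus the HB+HC
share of resolved windows. Neither is an unbiased estimate of the genomic
ILS fraction at small W: at hominid-like divergence (~1%) a 500-bp window
carries on the order of one informative site, and the expected support
differs by class — the concordant (B,C) internal branch spans the conditional
pair-coalescence time plus the full stem to the human join, roughly 1.45×
the discordant internal branch (one ancestral coalescent interval, 2N_A
generations) at p = 0.3. Concordant windows therefore resolve more often and
the resolved-window share underestimates ILS. `estimate_ils_fraction`
removes this bias with a detection-probability correction borrowed from
occupancy estimation: windows are called with an informative-site floor of 1,
the support counts among windows called for class k are modelled as a
zero-truncated Poisson, its rate λ_k is solved from the truncated mean, the
class detection probability is 1 − e^(−λ_k), and called counts are
inverse-weighted before forming the fraction. On 10-Mb synthetic datasets at
p_true = 0.30 the corrected estimate tracks the realized truth fraction to
within ~0.005 (the raw resolved-window share is ~0.26).

## Spatial clustering of ILS segments

An ILS "segment" is an ILS-classified window; windows are not merged into
runs, so adjacent ILS windows have inter-segment distance 0. Distances are
end-to-start gaps between consecutive ILS windows within a chromosome.

The null model preserves the geometry of analyzability: per replicate and
chromosome, the observed number of ILS windows is drawn uniformly without
replacement from that chromosome's analyzable windows, and gaps are computed
on the real window coordinates, so holes in alignability can never manufacture
apparent clustering. For a contiguous tiling the null mean gap has the closed
form W·(N−n)/(n+1), which the simulation reproduces to <1% at 10,000
replicates; the default replicate count for production runs is 400,000. Null
distributions are stored as value/count tables, so memory is independent of
the replicate count. The observed and null pooled gap distributions are
compared with a two-sided two-sample Wilcoxon rank-sum test
(`scipy.stats.mannwhitneyu`: exact for tiny tie-free samples, tie-corrected
normal approximation otherwise; the null side is thinned to a deterministic
quantile grid above 500,000 values).

Clustered vs non-clustered segments: each segment's nearest-neighbour gap
(minimum of its flanking gaps; single flank at chromosome ends; a segment
alone on its chromosome has no neighbour and is non-clustered) is compared
with the q-quantile of the null nearest-neighbour distribution (default
q = 0.05), taken as the smallest support value whose null CDF reaches q.
That convention makes the degenerate cases exact — an all-adjacent run is
entirely clustered, segments beyond the null maximum never are — and is
calibrated (clustered fraction ≈ q on null-drawn data) whenever the null
mass per lattice point (gaps are multiples of W on contiguous tilings) is
small at the quantile; the calibration test uses n = 100 segments among
N = 20,000 windows for that reason. On tract-structured data the threshold
typically lands at 0 bp: the biological signal of clustering at window
resolution is runs of adjacent ILS windows.

## Annotation content

Interval work uses a deterministic two-pointer sweep over chromosome-sorted
intervals (verified against brute-force all-pairs overlap on random
fixtures). An exon belongs to the ILS exon set when it overlaps at least one
ILS window by ≥ `min_overlap` bp (default 1); it inherits every overlapping
window's topology class, so an exon can be counted in both the HB and HC
sets, matching per-topology accounting that can double-count. Gene-level
counts require k distinct exons (not k windows on one exon). Content columns:
GC% uses called bases only (Ns excluded from the denominator); feature
percentages are covered bp within the window set over total window bp, with
overlapping track intervals unioned first; "intragenic" is the union of gene
bodies and the intergenic/intragenic ratio is the complementary bp ratio
within the window set, so intragenic + intergenic = total exactly. The same
quantities over all analyzable windows give the genome-average row.

## dN/dS and the excess-replacement test

Sites and differences follow Nei–Gojobori (1986). Per codon position the
synonymous site contribution is the fraction of the three single-base changes
that preserve the amino acid, with changes to stop codons counted as
nonsynonymous, so n + s = 3 per codon. Differences between codons at 2–3
positions are averaged over substitution orders whose intermediates avoid
stop codons (all orders when none do, counting undefined steps as
nonsynonymous). Codons containing gaps, ambiguity codes, or stops in either
sequence are skipped; alignments with internal stops are excluded. N and S
are averaged over the two sequences; pN = Nd/N and pS = Sd/S are corrected
with the Jukes–Cantor transform d = −(3/4)·ln(1 − (4/3)p); ω = dN/dS.
Records with dS = 0 (ω undefined) or p ≥ 3/4 (saturated) are flagged and
excluded from testing, with counts logged. Excess amino-acid replacement in
an exon set is a two-sided one-sample t-test of the set's ω values against
the mean of the genome-wide null set (exons not overlapping any ILS window,
same species pair and filters). The species pair is configurable; the
convention is human–bonobo pairs for HB_ILS exons and human–chimpanzee for
HC_ILS.

## Synthetic data generator

The generator produces the structures the pipeline assumes, with known truth:

- **Demography.** Split times default to 1.7 / 6 / 9 / 15 Myr
  (chimpanzee–bonobo, human–Pan, gorilla, orangutan) at a 25-year generation
  time, ancestral effective size N_A = 50,000, mutation rate
  μ = 1.25e−8 /bp/generation. These give hominid-like pairwise divergences
  (H–C ≈ 1.0%, H–G ≈ 1.3% at defaults) and quartet discordance
  p = (2/3)·exp(−Δ/2N_A) ≈ 0.12 with Δ = T_HP − T_BC. They are conventional
  literature-scale values, stated as defaults and tunable;
  `with_discordance(p)` solves N_A for a target discordance with split times
  held fixed.
- **Tracts.** Genealogy tracts form an exponential renewal process with mean
  length 1/(r·2N_A); labels are drawn {SPECIES: 1−p, HB: p/2, HC: p/2}.
  The default recombination rate r = 1e−9 /bp/generation puts tracts at
  ~10 kb for the default demography so that tracts span multiple 500-bp
  windows — the regime in which window classification is well-posed; a
  shorter-tract regime is a parameter change away. Hotspot intervals multiply
  p by a declared factor (capped at 2/3 with a warning) and are emitted in
  the truth manifest as the clustering positive control.
- **Sequences.** Each tract's genealogy gets branch lengths from expected
  coalescent times conditional on its label: concordant pairs coalesce at the
  truncated-exponential mean within the internal branch; discordant
  genealogies enter the ancestral population unpaired, first coalescence at
  rate 3/2N_A, the remainder one coalescent interval later; outgroups join
  at their split time plus 2N_A. (The SPECIES label also covers
  deep-coalescing concordant genealogies; expected-time mode ignores their
  small extra depth.) A sampled-times mode draws the times instead for
  realism. Sequences evolve from a uniform-random ancestral sequence under
  Jukes–Cantor; the output is a gap-free alignment, so synthetic runs
  exercise classification, clustering, annotation, and dN/dS but not the
  missing-data filters, strand handling, or alignment-error robustness that
  real MAFs require — passing tests bound estimator behaviour under the
  model, not alignment quality on real data.
- **Codon pairs.** Exon pairs evolve from a random stop-free codon sequence
  along two branches of t/2 proposed changes per site each; proposals
  creating stops are rejected, and thinning (nonsynonymous by ω below 1,
  synonymous by 1/ω above 1) fixes the nonsynonymous:synonymous rate ratio at
  ω for any ω ≥ 0.

Every run consumes one named NumPy generator seeded from the manifest; the
manifest regenerates all outputs byte-identically.

## Determinism and numeric conventions

A pipeline re-run with the same config and seed writes byte-identical stage
outputs; the only timestamped artifact is the run log. Reports serialize
percentages to 2 decimals and other floats to 6 significant digits; the
config hash covers scientific parameters (not the output directory). Window
sizes used by the bundled verification runs — 10 Mb at W = 500 for ILS
recovery, 2 Mb at W = 2000 with elevated μ for classifier accuracy
(windows conditioned on ≥ 20 informative sites), 10,000-replicate nulls —
were chosen as the smallest sizes at which Monte-Carlo error is comfortably
below the quantities' tolerances.

## Known limitations

- The window classifier has no power below ~1 informative site per window;
  the corrected estimator fixes the aggregate fraction, not per-window calls.
- The truncated-Poisson detection model assumes homogeneous support rates
  within a class; windows straddling tract boundaries violate it mildly.
- The clustering threshold lives on a W-lattice; calibration at q degrades
  when the null nearest-neighbour mass at single support points is large
  relative to q (dense ILS, small N/n).
- NG86 is a counting estimator: it ignores transition/transversion and codon
  frequency biases and saturates at high divergence; it is used for
  determinism and desk-verifiability, not as a replacement for ML codon
  models.
- The five-taxon class map collapses the 15 rooted ingroup shapes into five
  classes; alternative groupings are one function away
  (`FiveTaxonCall.topology` keeps the canonical shape string).
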