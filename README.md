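# ilsscan

Window-based detection and characterization of **incomplete lineage sorting
(ILS)** in great-ape genome alignments.

When ancestral polymorphism sorts across speciation events, parts of the human
genome are genetically closer to bonobo or to chimpanzee than bonobo and
chimpanzee are to each other. Given a multi-species alignment over
{human, chimpanzee, bonobo, gorilla} (optionally orangutan), `ilsscan`:

1. tiles the reference into fixed-size windows and filters them for
   analyzability (`ilsscan.msa`);
2. classifies each window's local genealogy against the species tree
   (((B,C),H),G) by outgroup-polarized site-pattern counting — the two
   discordant classes are (G,((B,H),C)) ("HB_ILS") and (G,((H,C),B))
   ("HC_ILS") — with a neighbor-joining caller for the five-taxon extension
   (`ilsscan.topology`);
3. tests whether ILS segments are spatially clustered by comparing inter-ILS
   distances with a random-placement null (Wilcoxon rank-sum) and partitions
   segments into clustered / non-clustered at a null quantile of
   nearest-neighbour gaps (`ilsscan.clustering`);
4. profiles ILS segment content (GC%, repeat and exon coverage,
   intergenic/intragenic ratio) and identifies ILS exons and genes with
   multiple ILS exons (`ilsscan.annotation`);
5. computes per-exon pairwise dN/dS by Nei–Gojobori (1986) counting with
   Jukes–Cantor correction, dN = −(3/4)·ln(1 − (4/3)·pN), and tests ILS exon
   sets for excess amino-acid replacement with a one-sample t-test against a
   genome-wide null (`ilsscan.dnds`);
6. generates ground-truth synthetic data under a multispecies-coalescent
   model — genealogy tracts with discordance probability
   p = (2/3)·exp(−Δ/2N<sub>A</sub>), Jukes–Cantor sequences, codon pairs at a
   specified ω (`ilsscan.simulate`).

Because short windows at hominid divergence (~1%) carry on the order of one
informative site, the package also provides a detection-corrected estimator of
the genomic ILS fraction (`estimate_ils_fraction`): per-class zero-truncated
Poisson fits of the informative-site support give each topology class a
detection probability, and inverse-weighting the called windows removes the
resolution bias. See `docs/methods.md`.

## Worked example

Simulate a 1-Mb four-way alignment with 30% of the genome in ILS tracts, then
scan it at 500-bp resolution:

```sh
ils-scan simulate --length 1000000 --p-ils 0.30 --seed 7 --out-dir sim/
ils-scan classify --maf sim/alignment.maf \
    --species human,chimpanzee,bonobo,gorilla \
    --window-size 500 --out calls.tsv
ils-scan cluster --calls calls.tsv --window-size 500 \
    --n-sims 10000 --seed 17 --q 0.05 --out-prefix clus
```

Output printed by the three commands:

```
simulated 1000000 bp, p = 0.3000
total ILS 4.85% over 2000 windows (0.1980 of resolved)
clustered fraction 0.186 (threshold 0 bp, p = 5.027e-07)
```

Reading: at the default call thresholds (≥3 informative sites) only a small
fraction of 500-bp windows resolve, so the Table-style "total ILS" (4.85% of
all windows) is far below the simulated tract fraction — exactly the
behaviour seen when window size shrinks on real alignments. The
resolved-window fraction (0.198) is closer, and `estimate_ils_fraction`
(reported as `ils_fraction_corrected` in pipeline reports) recovers
≈0.29–0.30 at 10 Mb. The clustering stage still rejects random placement
(rank-sum p ≈ 5e−7): called ILS windows inherit their multi-window genealogy
tracts, so 18.6% of them sit directly adjacent to another ILS window
(nearest-neighbour gap 0), far more than uniform placement predicts.

The same stages run end-to-end from a YAML config with
`ils-scan run --config run.yaml`, which persists per-stage TSV/BED/JSON plus
a summary table (one row per window size: per-topology segment counts and
percentages, total ILS%, and content columns, with a genome-average row).

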