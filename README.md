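# orthoflow

Flow-cytometric genome size estimation with an internal standard, dual-dye
GC content, comparative statistics, and Brownian-motion ancestral state
reconstruction — built for genome-size surveys of insects (Orthoptera in
particular, whose grasshoppers carry the largest insect genomes known), but
generic over any internally standardized flow-cytometry campaign.

## What it computes

**Genome size.** Nuclei of a specimen are co-stained and co-run with an
internal standard of known DNA content (the default is the garden pea
*Pisum sativum* 'Ctirad', 2C = 9.09 pg, GC = 38.50 %). Each run yields a
fluorescence histogram with two G0/G1 peaks; `orthoflow` fits Gaussians to
both and estimates

> 2C_sample = 2C_standard · (sample peak mean / standard peak mean),

which cancels instrument gain. 1C = 2C/2 for every specimen regardless of
sex, and masses convert to base pairs via 1 pg = 0.978 Gbp. Peak CVs and
particle counts drive QC flags.

**GC content.** An intercalating dye (propidium iodide) reports genome size
alone; an AT-selective dye (DAPI) needs n consecutive AT base pairs per
binding site, so its signal scales with genome size × (AT fraction)^n.
Measuring the same specimen with both dyes against a standard of known
composition gives the sample AT fraction

> p_s = p_st · (r_AT / r_int)^(1/n),   GC% = 100 · (1 − p_s),

with n = 4 by default (the conventional DAPI binding length; configurable).

**Comparative statistics.** Species-level aggregation (per-sex 1C means),
female-minus-male differences (the X chromosome's DNA content under XX/X0
sex determination), Kruskal–Wallis and Bonferroni-corrected pairwise
Mann–Whitney tests of genome size across chromosome-number groups, Pearson
correlation, and one-way ANOVA plus pairwise contrasts of GC across
families.

**Ancestral states.** Under Brownian motion the tip values x are jointly
normal with mean a·1 and covariance σ²C, C_ij the shared root-to-MRCA path
length. The ML root state is the GLS mean â = (1ᵀC⁻¹1)⁻¹1ᵀC⁻¹x, the ML rate
is σ̂² = (x−â1)ᵀC⁻¹(x−â1)/N, and every internal node's estimate equals the
GLS mean of the tree re-rooted there — computed here in two linear-time
message-passing sweeps, with per-node variances and 95 % intervals.
Non-ultrametric trees and polytomies are handled natively.

The package also bundles the species-level results of a 50-species
orthopteran survey (four families; record holder *Bryodemella tuberculata*,
1C = 21.96 pg ≈ 21.48 Gbp) and a synthetic-data module that generates
histograms, dye pairs, pure-birth trees with Brownian traits, and grouped
species tables with the statistical structure the analyses assume.

## Worked example

```python
from orthoflow import (HistogramSimConfig, PISUM_CTIRAD, simulate_histogram,
                       measure_histogram, read_newick, bm_asr)

cfg = HistogramSimConfig(standard_channel=100, true_ratio=4.832,
                         cv_sample=2.31, cv_standard=2.31,
                         n_sample=2000, n_standard=2000, seed=7)
hist = simulate_histogram(cfg, dye="PI")
m = measure_histogram(hist, PISUM_CTIRAD, standard_window=(90, 110))
print(f"2C = {m.genome_size_2C_pg:.2f} pg, "
      f"1C = {m.genome_size_1C_pg:.2f} pg ({m.genome_size_1C_gbp:.2f} Gbp)")
```

prints

```
2C = 43.98 pg, 1C = 21.99 pg (21.51 Gbp)
```

— a simulated run at the record operating point (true ratio 4.832 ×
9.09 pg / 2 = 21.96 pg 1C) recovered within 0.2 %, with CVs ≈ 2.3 % and an
empty QC flag set. Continuing with a small phylogeny:

```python
phy = read_newick("((Bryodemella_tuberculata:0.12,Stethophyma_grossum:0.12)"
                  ":0.3,(Chorthippus_dorsatus:0.2,"
                  "Pseudochorthippus_parallelus:0.2):0.22);")
res = bm_asr(phy, {"Bryodemella_tuberculata": 21.92,
                   "Stethophyma_grossum": 18.51,
                   "Chorthippus_dorsatus": 12.66,
                   "Pseudochorthippus_parallelus": 12.98})
print(res.summary())
```

```
Brownian-motion ancestral state reconstruction (ML)
  tips: 4   internal nodes: 3
  sigma2_hat: 32.2818   root: 16.3   logL: -10.3725
node_id  estimate  variance   ci_lo   ci_hi
     n0   16.3000    5.4689 11.7165 20.8835
     n1   19.5625    1.7660 16.9579 22.1671
     n2   13.9075    2.7534 10.6552 17.1598
```

Node `n0` is the root: 16.30 pg, the GLS-weighted compromise between the
large-genome and small-genome clades, with its 95 % interval.

A command-line interface wraps the same machinery
(`orthoflow measure | gc | stats | asr | simulate | run`); `orthoflow run
--config cfg.yaml` executes the whole pipeline and writes a JSON run report
with a content hash per output.

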