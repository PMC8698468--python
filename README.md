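# evcirc

Profiling of circular and linear RNA cargo in plasma extracellular
vesicles (EVs), built around pooled RNA-seq count data from multiple
sclerosis patients (relapsing-remitting RR-MS, secondary-progressive
SP-MS) and healthy controls (HC). The package is aimed at transcriptomics
researchers who have detector-level circRNA call tables and gene-level
count matrices and want a reproducible, testable path from those tables to
biological summaries.

## What it computes

* **Consensus circRNA catalog** — a back-splice junction (BSJ) is a
  *bona fide* circRNA when found by both detectors (a find_circ-style BED
  table and a CIRI2-style TSV) and supported by ≥ 2 BSJ reads in at least
  one pool of the quantifying detector. Junctions are normalized to a
  common coordinate convention, assigned to same-strand host genes, and
  summarized by abundance bins and circRNAs-per-gene multiplicity.
* **Group comparisons** — for any pair of groups, transcripts partition
  into exclusive-to-A / exclusive-to-B / shared (detected = ≥ 1 read in
  ≥ 1 pool), with percentages over the union.
* **Twelve-type biotyping** — read totals per RNA category (protein
  coding, lncRNA, pre-miRNA, misc RNA, snRNA, snoRNA, scaRNA, rRNA, tRNA,
  circRNA, other RNA, nondefined), overall and restricted to non-coding
  reads, compared between groups with a Pearson chi-squared test.
* **Differential expression** — an NB-Wald engine with design
  `~ status + sex`: median-of-ratios size factors, gene-wise
  method-of-moments dispersion (floor 0.01), NB log-link GLM, Wald test on
  the contrast coefficient, Benjamini-Hochberg adjustment. Calls use
  |FC| > 1.5 and p < 0.05, with adjusted-p counts reported alongside, and
  a Table-style candidate ranking (best shared transcripts by adjusted p
  plus the strongest group-exclusive transcripts).
* **miRNA-sponge scoring** — per circRNA, the maximum binding-site (BS)
  count for any single miRNA; super-sponge flag (> 20 BS); and the
  binding-site density max BS / spliced length, anchored by CiRS-7
  (70 miR-7 sites / 1485 nt = 0.05); plus the length-vs-BS Pearson
  correlation and length-set comparisons.
* **Secondary-structure classes** — length-normalized minimum folding
  free energy −ΔG/nt: highly structured (> 0.25), poorly structured
  (< 0.2), undetermined in between. Energies come either from an external
  TSV (e.g. a thermodynamic folding tool) or from the built-in
  Nussinov-style pair-maximization engine.

A synthetic-data module generates detector calls, count matrices,
annotation, spliced sequences and miRNA-site tables with known ground
truth, emulating the 12-pool study design (4 pools per group, sex
balanced), so the entire pipeline is exercised end-to-end without any
download. See `docs/methods.md` for the statistical details.

## Worked example

```bash
evcirc run-all --outdir demo --seed 3
```

runs simulation, catalog construction, biotyping, the three disease
contrasts, sponge and structure scoring, and writes `demo/summary.json`
and a human-readable `demo/report.txt`. With 300 simulated circRNAs and
600 genes (seed 3) the report reads:

```
bona fide circRNAs: 246 (7 intergenic, 186 host genes, max 4 circRNAs/gene)

RR-MS_vs_HC (circ): exclusive 10 (4.3%) / 11 (4.7%), shared 213 (91.0%)
SP-MS_vs_HC (circ): exclusive 12 (5.1%) / 11 (4.7%), shared 213 (90.3%)
SP-MS_vs_RR-MS (circ): exclusive 12 (5.1%) / 10 (4.3%), shared 213 (90.6%)

RR-MS_vs_HC (circ DE): 15 up / 12 down (9/10 at adjusted p)
SP-MS_vs_HC (circ DE): 0 up / 3 down (0/0 at adjusted p)
SP-MS_vs_RR-MS (circ DE): 14 up / 14 down (5/7 at adjusted p)

sponge: 0 super-sponges, density classes {'<0.01': 199, '[0.01,0.05)': 101, '>=0.05': 0}
structure: {'highly structured': 22.67, 'poorly structured': 32.0, 'undetermined': 45.33}
```

Reading this: 246 of the simulated junctions survive the two-detector
consensus and ≥ 2-reads filter; the planted fold changes surface in the
RR-MS vs HC contrast (the generator plants effects in RR-MS), while SP-MS
vs HC is essentially null; no short EV-like circRNA reaches the
super-sponge bar, and the structure mixture reproduces the EV-mode
generator fractions. Each stage is also available separately
(`evcirc catalog`, `evcirc venn`, `evcirc diffexp`, `evcirc sponge`,
`evcirc structure`, `evcirc biotype`) on files in the documented formats,
or as plain library calls.

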