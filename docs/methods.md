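# Methods

## Study design being modelled

The package targets pooled bulk RNA-seq of plasma-EV RNA: twelve pools —
four RR-MS, four SP-MS, four HC — each pool a mixture of same-status,
same-sex donors, so sex is a pool-level covariate. Circular RNAs are
evidenced only by reads spanning their back-splice junction (BSJ);
detector outputs are therefore tables of junctions with per-pool BSJ read
counts, and linear RNAs are gene-level count matrices. All downstream
statistics operate on these tables; alignment and junction detection are
upstream of the package.

## Consensus catalog

Two detector tables are normalized to 0-based half-open coordinates
(BED-style input is already half-open; CIRI2-style 1-based inclusive
input is shifted). Junction identity is an exact (contig, start, end,
strand) match — no fuzz window, since no tolerance is defined for the
detectors being emulated and an exact rule is the only reproducible
default. A junction is *bona fide* when present in both tables and its
**maximum per-pool** count in the quantifying detector (the CIRI2-role
table, which also supplies the catalog counts) is ≥ `min_reads` (default
2). The support phrase "at least two reads in a given pool" admits a
summed-support reading; the per-pool maximum is implemented because it is
the literal reading, and `min_reads` is configurable.

Host genes: a circRNA is assigned to a gene when its junction interval
lies entirely within the gene body on the same strand (back-splicing is
intragenic and strand-specific). Nested containments resolve to the
larger reciprocal overlap — i.e. the smallest containing gene — then
lexicographic gene id. Unassigned junctions are `intergenic` and are
excluded from the circRNAs-per-gene denominators.

Abundance bins use per-transcript means across pools with closed lower
edges: [0,10), [10,50), [50,500), [500,∞) reads/sample.

Group comparisons: "detected in a group" means ≥ 1 read in ≥ 1 of the
group's pools (no higher floor, since detection is defined by presence).
Exclusive/shared sets partition the union of transcripts detected in
either group, and percentages are taken over that union.

## Differential expression

The engine is a deliberately specified NB-Wald procedure rather than a
re-implementation of any particular DE tool:

1. **Size factors** — median-of-ratios against the geometric-mean
   reference over transcripts positive in all pools; if none exists,
   library-size ratios with a warning (pools with empty libraries get a
   neutral factor of 1).
2. **Dispersion** — per transcript, method of moments on normalized
   counts within each status group: α̂ = (s² − m)/m², pooled across
   groups weighted by degrees of freedom and clipped to [0.01, 20]. The
   floor guards against the variance estimate collapsing at n = 4
   pools/group; the ceiling prevents degenerate fits on near-empty rows.
3. **GLM** — NB log-link GLM with intercept, status indicator
   (numerator level of the contrast) and sex dummies, offset log size
   factors, fit by IRLS (statsmodels).
4. **Wald test** — the status coefficient over its standard error,
   referred to a t distribution with the residual degrees of freedom
   (n − p). With eight pools and three parameters the normal reference is
   anti-conservative; the t reference keeps the null type-I error inside
   [0.03, 0.07] at nominal 0.05 in the package's calibration suite
   (500-transcript null, 4+4 pools).
5. **Multiplicity** — Benjamini-Hochberg across tested transcripts.

Calls: up/down require |log2FC| > log2(1.5) **and raw p < 0.05** (the
headline definition); counts at adjusted p < 0.05 are reported alongside.
There is no fold-change shrinkage, no independent filtering and no
outlier replacement — omissions chosen to keep every step inspectable at
desk scale.

Transcripts not detected in both contrast groups never enter the GLM.
Those detected in exactly one group are *group-exclusive*; because a
group of structural zeros has no finite NB maximum-likelihood fold
change, exclusives carry a **moderated descriptive** log2 fold change
(pseudocount 0.5 on group means of normalized counts) and no p-value or
adjusted p-value. Candidate ranking lists the k best shared transcripts
by ascending adjusted p (ties: ascending |log2FC|, then id) followed by
exclusives in descending base-mean order.

## Biotyping

Twelve categories; consensus circRNAs are category `circRNA` by
definition, annotation biotype strings map through a shipped editable
TSV covering standard annotation vocabularies, and unmapped strings are
`nondefined`. Distributions are **read** distributions: per category, the
sum of per-pool mean raw counts within a group. Group comparisons use a
Pearson chi-squared on the 2 × k table of rounded totals, dropping
categories empty in both groups, with no continuity correction (the
table is k × 2 with k up to 12); raw rounded totals are used rather than
rescaled counts.

## Sponge scoring

For each circRNA the score is the **maximum per-miRNA** binding-site
count (ties to the lexicographically first miRNA id). Super-sponge means
strictly more than 20 sites. Binding-site density is max BS divided by
**spliced length** (the sequence actually available for binding, not the
genomic span). Density classes < 0.01, [0.01, 0.05), ≥ 0.05 are computed
on the exact ratio; the 2-decimal half-up rounding (CiRS-7: 70/1485 =
0.047 → displayed 0.05) is display-only, so CiRS-7 itself classifies as
[0.01, 0.05). Length sets are compared by Welch t-test on log lengths
(raw lengths are heavy-tailed) with a Mann-Whitney alternative reported
alongside.

## Structure classification

−ΔG/nt = −ΔG / spliced length; > 0.25 highly structured, < 0.2 poorly
structured, the closed band [0.2, 0.25] undetermined (both published
thresholds are strict inequalities, so boundary values fall in the band).
Energies are pluggable:

* **external** — a TSV of (circ_id, ΔG) from any thermodynamic folding
  tool is passed through unchanged;
* **built-in** — a Nussinov-style maximizer of nested Watson-Crick + GU
  pairs with minimum hairpin loop 3 and no pseudoknots, scoring −1
  kcal/mol per pair. It is non-thermodynamic by construction and exists
  so the repository is self-testable; its output equals exhaustive
  enumeration of nested pairings on all short test sequences. The engine
  identity is recorded per record. Sequences are folded as linear
  molecules (T mapped to U); no circular-topology correction is applied.

## Synthetic data generator

The generator's role is to produce inputs whose *statistical structure*
matches what the analyses assume, with exact ground truth:

* **Counts** — negative binomial with per-transcript baseline means
  drawn log-uniformly (default 10^0.5 to 10^2.5 reads/pool) and a shared
  dispersion α = 0.1, typical of bulk RNA-seq of pooled samples. DE
  transcripts (default 10%) carry a ±2 log2 fold change planted in the
  first group; exclusive transcripts (default 5% per group) are
  **structural zeros** in all other groups' pools, so exclusive calling
  has an exact truth set, unlike low-sampling zeros.
* **Design** — 4 pools per group, sex alternating M/F within groups so
  `~ status + sex` stays estimable.
* **Geometry** — genes tile a toy multi-contig genome with gaps;
  circRNAs are placed inside host genes (spliced length ≤ genomic span ≤
  gene length) or in gaps (3% intergenic). Host-gene truth is therefore
  known, and a gene can be forced to carry a fixed number of circRNAs
  for multiplicity tests.
* **Lengths** — lognormal, median 386 bp (EV mode) or 476 bp (leukocyte
  mode), σ = 0.5, matching the observation that most bona fide circRNAs
  fall between ~250 and ~800 bp. Lengths are capped by the host gene's
  span.
* **Detector calls** — each true junction enters each detector
  independently with probability 1 − miss rate, so consensus recall has
  the closed form (1−a)(1−b).
* **Sites** — the dominant miRNA of each circRNA gets Poisson(bs_per_kb ×
  L/1000) sites (default 8/kb, keeping the mean density below 0.01);
  other miRNAs get a 15% background rate. An optional CiRS-7 spike adds
  the 1485-nt, 70-site reference record.
* **Sequences** — each circRNA's target structure class is realized
  exactly: a G/C hairpin stem of size round(target × L) over a 3-nt loop
  with adenine filler has maximum pairing exactly equal to the stem, so
  the built-in engine recovers the intended −ΔG/nt. EV mode draws
  classes at (22% HS, 34% PS, 44% undetermined); cell mode shifts toward
  highly structured (35%/25%/40%).

What the generator does **not** emulate: detector false positives beyond
independent misses, sequencing-depth variation between pools beyond NB
noise, realistic miRNA seed-match placement (site counts are abstract),
thermodynamic folding energies, or the empirical fact that no real EV
circRNA reaches density 0.01 (Poisson tails put a minority of synthetic
records above it). Passing tests therefore demonstrate correctness of
the algorithms and calibration of the statistics under the declared
model, not recovery of any dataset-dependent published count.

## Problem sizes and determinism

Default analyses run at a few hundred circRNAs / genes and 12 pools; the
calibration suites use 400–500 transcripts and two groups; correlation
properties use 1000 circRNAs with the wide (reference-catalog-like,
median ~8.7 kb) length range on which the published length/BS
correlation was computed, since the short EV length range intrinsically
attenuates the Poisson-noised correlation to ~0.75. The built-in folder
is O(L³) and is capped in the pipeline at a configurable number of
sequences (default 150). Every stochastic step flows from a single seed
through independent per-stage substreams; pipeline reruns with the same
configuration are byte-identical.

## Known limitations

* The built-in folding engine ranks pairing capacity, not free energy;
  absolute −ΔG/nt values are comparable only within an engine, and
  production classification should ingest external thermodynamic
  energies.
* Exclusive-transcript fold changes are descriptive; their magnitudes
  are not comparable to published tool-internal pseudo-estimates.
* The NB engine's dispersion is gene-wise with a floor — no shrinkage
  toward a mean-dispersion trend — which is adequate at the calibration
  sizes tested but noisier than shrinkage estimators at n = 4.
* Host-gene assignment requires strand agreement; annotations lacking
  reliable strand will over-report intergenic circRNAs.
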