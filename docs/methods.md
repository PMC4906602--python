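# Methods

## Scope and data model

`paracns` analyzes WGD-derived paralog pairs for concurrent purifying
selection on coding and non-coding sequence. Its inputs are gene-level
tables: an annotation (chromosome, strand, protein-coding span, in-CDS
introns, protein length), a genes × tissues expression matrix on an
RMA-style log2 scale, a paralog-pair list, up to three CNS tracks in
BED, an ortholog table with dN/dS, cross-species expression Z scores, a
TF binding-site table, and an mRNA half-life table. Probe-level
processing (normalization, probe-to-gene mapping), dN/dS estimation and
CNS discovery are upstream of the package; their outputs are consumed
as files.

Coordinates are 0-based half-open everywhere in memory. BED is read
and written natively in that convention; annotation tables are declared
1-based inclusive on disk and converted on read, so containment tests
and BED tracks compose without off-by-one adjustments.

## Expression profiles and τ

Replicate samples are averaged per tissue (arithmetic mean, declared
tissue order). A gene's overall expression is the mean over its tissue
profile, and tissue specificity is

τ = Σᵢ (1 − xᵢ/max(x)) / (N − 1),

computed directly on the stored log2-scale values (no de-logging — the
index is applied to the same scale the expression estimates arrive on).
All-zero profiles leave τ undefined (division by max = 0) and are
excluded from τ analyses rather than assigned 0. By default τ uses the
averaged tissue matrix (e.g. 15 tissues) rather than raw replicate
columns; since `tissue_specificity_tau` takes any vector, either choice
is available.

## Pair classification

Pairs are dropped (with a logged reason) when a gene lacks annotation,
is absent from the expression data, or the protein lengths differ by
more than 5 % of the longer protein. The pair ratio is
max(mean)/min(mean) ≥ 1. The boundary conventions are exact: strict
`<` for similar (default threshold 1.25), inclusive `≥` for
differential (default 7); the remainder is *intermediate* and excluded
from group contrasts. Whether the thresholds are meant on the log2
scale or after de-logging is genuinely ambiguous for microarray-style
data; the package's default applies them to the stored (log2-scale)
values, and because every correlation downstream is rank-based, that
choice affects group membership only, not the sign or magnitude of
rank correlations given a membership. One gene of every similar pair is
sampled uniformly (seeded) for contrasts against the higher/lower
groups.

## Divergence statistics

* **Best ortholog**: maximal percent identity, ties resolved by lowest
  dS, residual ties by smallest ortholog id (deterministic).
* **Retention**: a 2×2 table (rows lower/higher role, columns ortholog
  present/absent) tested with the two-sided Fisher exact test under the
  probability-mass rule (sum of hypergeometric probabilities of all
  tables with the observed margins no more probable than the observed
  one). This matches the common implementations; the alternative
  "doubling" definition is not used.
* **dN/dS**: entries with dS = 0 have no defined rate ratio and are
  excluded with a logged count. The omnibus test is Kruskal–Wallis
  with tie correction; post-hoc contrasts are Dunn's pairwise z-tests
  on pooled mean ranks with tie-corrected variance and a
  Bonferroni-type adjustment over the three comparisons (the adjustment
  family is switchable; medians and means are both reported since
  central-tendency conventions differ between sources).
* **Expression conservation**: Spearman ρ between own and ortholog
  expression Z scores per group. For the similar group, one gene per
  pair is selected at random and ρ recomputed, 10,000 times; the
  summary is the empirical median and the central 95 % interval
  (2.5th/97.5th percentiles, no smoothing). Two correlation
  coefficients are compared by Fisher's z transformation,
  z = (atanh r₁ − atanh r₂)/√(1/(n₁−3) + 1/(n₂−3)).

## Gene-associated regions and CNS assignment

For a gene whose start codon sits at position s (strand-aware), the
promoter windows are [s−W, s−100) for W ∈ {500, 1000, 1500} — the 100 bp
immediately upstream are treated as a 5′ UTR proxy to avoid biasing
toward genes with well-annotated UTRs. Downstream of the stop codon e,
the 3′ UTR proxy is [e, e+200) and the downstream window [e+300,
e+1000); both mirrored for − strand genes. Introns are those inside
the protein-coding span. Upstream/downstream regions are clipped to the
free space between the nearest annotated gene spans on either side
(strand ignored — any annotated neighbor shortens the region) and to the
chromosome ends; fully covered regions become empty.

A CNS counts for a region only when contained entirely within it;
intervals straddling a boundary count for neither side, and a gene
without any CNS in a region scores an explicit 0 (it stays in the
correlation, it is not missing data). Counts and base sums (summed CNS
lengths) are both reported; by construction promoter counts are
monotone in the window size.

Correlations between pair expression ratio and per-gene CNS measures
use Kendall τ-b, which corrects for the heavy ties in small counts; the
p-value is the tie-corrected normal approximation. Since τ-b is
invariant under monotone transforms of either variable, the ratio can
enter on its stored scale. Genes with zero introns contribute intron
count 0 rather than being skipped. No multiple-testing correction is
applied across region classes/datasets/roles — each correlation is
reported with its own p — and this is deliberate: the output table is a
survey, not a family of confirmatory tests.

## Resampling tests

Group means (CNS length, GC content) are compared to the genome-wide
promoter-CNS pool by drawing same-size subsets without replacement,
1000 iterations by default. The two-sided empirical p doubles the
smaller tail with a +1 correction, p = min(1, 2·min(P≥, P≤)) with
P≥ = (1 + #{resampled mean ≥ observed})/(iterations + 1), so p is never
0 and the test is valid at its nominal level (its type-I error at 0.01
is verified to sit in [0.003, 0.03] by the calibration suite).

TF binding sites are filtered to conservation score ≥ 0.5 (inclusive).
A site is inside a CNS when it starts at most 2 bases upstream of the
CNS start or overlaps it by at least 4 bases; the 2-base rule is
applied in genomic coordinates relative to the CNS's lower coordinate
(strand-agnostic — the site table carries strand, but the assignment
rule does not use it; a strand-relative variant would only relabel
which end counts as "upstream" for − strand sites). Family-level
enrichment compares observed motif counts in group CNSs to counts in
resampled same-size CNS sets from the pool (one shared draw sequence
across families), fold = observed/resampled mean. Families with no
motif in the group despite motifs in the pool are reported *absent*
(distinct from depleted), mirroring how sparse motif catalogues behave.
Counts are raw (not per-base normalized); group size is matched by the
resampling itself.

## mRNA half-life contrast

Pairs qualify when exactly one gene has zero 3′ UTR CNSs and the other
at least one, and half-lives are known for both. Selection runs over
all filtered pairs, not only the differential group — the contrast is
about CNS presence, not expression class, and restricting it to one
expression group is available via configuration. Differences
(with-CNS − without-CNS) are tested with the Wilcoxon signed-rank test:
zero differences are dropped (Wilcoxon's original treatment;
implementations differ here, so it is stated explicitly), the exact
two-sided p is computed for n ≤ 25 by dynamic programming over doubled
midranks (ties produce half-integer midranks, so doubling gives an
integer-valued convolution), and larger n uses the normal approximation
with tie-corrected variance. No transformation is applied to the
half-lives: the rank statistic is invariant to monotone transforms.

## Synthetic data generator

The generator is first-class, tested code: it emulates the schemas and
the statistical couplings the analyses assume, under one global seed
that drives named substreams (`numpy` `SeedSequence` spawn keys), so
adding a table never perturbs earlier draws and a bundle is
byte-reproducible. No distributional choice below is estimated from
real data; all are documented stand-ins.

* **Groups and ratios.** The requested fractions of pairs are made
  similar (ratio uniform in [1, 1.25)) and differential (ratio =
  7 + Exponential(mean 2.5), capped at +15); the rest are intermediate.
  Tissue profiles are gamma-weighted around the target means (gene-wise
  concentration log-uniform in [2, 30], giving a realistic spread of
  τ), rescaled so the computed overall means reproduce the injected
  ratios exactly.
* **Gene layout.** Genes are placed in order on 5 chromosomes with
  mixed intergenic gaps (30 % short, 150–1200 bp) so neighbor
  shortening of promoters and downstream windows is actually exercised,
  0–4 introns per CDS, and protein lengths that always pass the 5 %
  filter.
* **CNS counts.** Per region class and dataset, counts are Poisson —
  the minimal count model, chosen because nothing stronger is implied
  by the analyses. The base rate (default 2 per promoter, scaled down
  for the other classes and for datasets 2–3) applies to every gene
  except the lower-expressed member of a differential pair, whose rate
  is base·exp(−β·(ratio − 7)): CNS loss accumulates with expression
  divergence *beyond the differential threshold*. At the threshold the
  lower gene matches the higher gene's rate, and β = 0 recovers the
  exact null. The driver is the excess over the threshold rather than
  the raw ratio because the raw ratio of a differential pair is ≥ 7 by
  construction, which would suppress every lower-gene count to
  essentially zero for any loss strength near 1 and make the injected
  effect unrecoverable in principle; the excess form keeps the marginal
  count scale realistic while placing the full gradient inside the
  differential group, which is where the correlation is measured.
  CNSs are placed fully inside the (already neighbor-shortened)
  regions, with short random sequences of Beta-distributed GC, plus a
  sparse background of unassociated CNSs.
* **Orthologs.** Presence is Bernoulli(1 − loss probability) per group
  role (defaults 0.006 higher / 0.08 lower, matching the observed
  155/156 vs 144/156 retention; 0.04 for similar and intermediate
  genes as an intermediate regime). dN/dS is Gamma(shape 6) around the
  group location (defaults 0.17/0.13/0.24), dS uniform in [0.08, 0.35],
  dN their product. Z scores are bivariate normal with per-group
  correlation (defaults 0.64/0.54/0.49).
* **TFBS.** 30 plant TF family labels, ~2 factors each (a scaled-down
  stand-in for a genome-wide catalogue of hundreds of factors). Sites
  are placed inside promoter CNSs so that the in-CNS rule holds, with
  density tilted by exp(tfbs_enrichment) toward CNSs of higher-group
  genes (0 = null), plus scattered background sites; conservation
  scores are uniform in [0.25, 1].
* **Half-lives.** Log-normal around 240 min (σ = 0.6 on the log
  scale), multiplied by exp(halflife_effect) for genes with a 3′ UTR
  CNS; ~8 % of genes lack half-life data to exercise the availability
  filter.

What passing tests on these bundles does and does not show: the
generator reproduces the couplings the pipeline is designed to detect
(group-shifted dN/dS, differential ortholog loss, divergence-coupled
CNS loss, enrichment tilts), so recovery tests demonstrate that the
statistics detect what they claim to detect at realistic sizes, and
calibration tests demonstrate their nominal error rates under the
corresponding nulls. They do not validate the biological distributions
of real annotation or expression data — real CNS counts need not be
Poisson, real expression is not gamma-weighted, and real intergenic
structure is richer than the layout here.

## Study sizes and calibration designs

The default `SimulationConfig` mirrors the reference study scale: 1312
pairs, 15 tissues, similar/differential fractions 245/1312 and
156/1312, thresholds 1.25 and 7. The injected-effect recovery and
null-calibration checks instead use a differential-focused design,
`recovery_config` (300 pairs, 30 % similar / 50 % differential, i.e.
~150 differential pairs), fixed by a prior power analysis of the CNS
count model: with the default fractions only ~36 of 300 pairs are
differential, a size at which the expected |τ-b| under the null alone
is ≈ 0.09, so neither the ≥95 % recovery rate nor a tight higher-gene
null bound is achievable by any method at that size. The calibration
suite verifies, per seed: negative significant (α = 0.01) promoter τ-b
for lower-expressed genes with β = 1; non-significant τ-b for
higher-expressed genes; ≤ 10 % false positives at β = 0; resampling
type-I error at nominal 0.01 within [0.003, 0.03]; half-life
signed-rank rejection ≈ 5 % at α = 0.05 under a zero effect.

## Numerical choices

* Fisher exact, Kendall τ-b, Spearman ρ and Kruskal–Wallis are
  delegated to `scipy.stats`; the test suite verifies each against an
  independent brute-force oracle (exact-rational table enumeration,
  O(n²) pair counting with ties, 2ⁿ sign-flip enumeration, base-by-base
  containment).
* Dunn's post-hoc and the Wilcoxon signed-rank test are implemented in
  the package (the exact signed-rank distribution with ties is not
  available upstream).
* Permutation and resampling seeds are derived from the pipeline seed
  through fixed named spawn keys; reports embed the seed and a SHA-256
  config hash, so a results directory identifies the run that produced
  it.
* Empty regions, zero CNS counts, all-tied vectors, dS = 0, zero
  differences and absent motif families all have explicit, documented
  behavior (count 0, error, exclusion with logging, p = 1 with warning,
  or *absent*), never silent NaN propagation; the pipeline records
  skipped entities in its filter log.

## Known limitations

* The generator draws one ortholog candidate per gene; multi-candidate
  selection (max identity, min dS) is exercised by unit tests rather
  than by synthetic bundles.
* TFBS placement guarantees rule-satisfying sites; near-miss geometries
  (e.g. 3-base overlaps) appear only in unit fixtures.
* No sequence-level evolution is simulated: CNS sequences exist only to
  carry GC content, and dN/dS values are drawn, not computed from
  alignments.
* The pipeline's file-input mode consumes a bundle directory written by
  `write_bundle`; assembling a bundle from arbitrary external files is
  done in code via `paracns.io` readers.
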