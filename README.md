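# paracns

Concurrent purifying selection on the coding **and** non-coding sequence
of paralog pairs retained after whole-genome duplication (WGD).

After a WGD event (such as the α event in *Arabidopsis thaliana*), every
gene is duplicated and most duplicates are subsequently lost
(fractionation). The pairs that survive fall into two contrasting
regimes: pairs whose two members keep **similar** expression levels
(consistent with dosage-balance retention) and pairs whose members have
**diverged** in expression, where the lower-expressed copy tends to show
relaxed purifying selection — fewer retained orthologs, higher dN/dS,
more tissue-specific expression, and fewer conserved non-coding
sequences (CNSs, presumed *cis*-regulatory elements) in its promoter,
introns and 3′ UTR. `paracns` implements the full analysis pipeline
that quantifies these contrasts, for researchers in comparative genomics
and molecular evolution who want to run it on their own annotation /
expression / CNS tables or study its statistical behavior on synthetic
data with known effect sizes.

## What it computes

* **Expression profiles** — replicate averaging to a genes × tissues
  matrix, overall mean expression, and the tissue-specificity index

  τ = Σᵢ (1 − xᵢ / max(x)) / (N − 1),  τ ∈ [0, 1]

  (0 = uniformly expressed over the N tissues, 1 = single-tissue).
* **Pair classification** — protein-length (≤ 5 % difference) and
  expression filters; the per-pair ratio of overall means (larger /
  smaller, on the stored log2-scale values) classifies pairs as
  *similar* (ratio < 1.25), *differential* (ratio ≥ 7) or
  *intermediate*; differential pairs get higher/lower roles, and one
  gene per similar pair is sampled for group contrasts.
* **Sequence divergence** — best-ortholog selection (max % identity,
  ties to lowest dS), a 2×2 ortholog-retention table with a two-sided
  Fisher exact test, Kruskal–Wallis + Dunn post-hoc on group dN/dS,
  Spearman correlations of cross-species expression Z scores, the
  10,000-iteration permutation distribution of ρ over random
  one-gene-per-pair selections, and Fisher z comparison of correlation
  coefficients.
* **CNS mapping** — strand-aware gene-associated regions (promoters of
  1500/1000/500 bp upstream of the start codon minus the first 100 bp,
  a 100 bp 5′ UTR proxy, in-CDS introns, a 200 bp 3′ UTR proxy, and a
  300–1000 bp downstream window), shortened where a neighboring gene
  intrudes; CNSs assigned by strict containment; Kendall τ-b (tie
  corrected) between pair expression ratio and per-gene CNS counts or
  base sums.
* **CNS properties** — GC content and length of group CNSs versus the
  genome-wide promoter-CNS pool, and TF binding-site family enrichment
  (sites with conservation score ≥ 50 %, counted inside a CNS when they
  start ≤ 2 bp upstream of it or overlap it by ≥ 4 bp), both judged by
  resampling without replacement (1000 iterations).
* **mRNA half-life contrast** — Wilcoxon signed-rank test (exact for
  n ≤ 25, tie-corrected normal approximation above) on pairs where
  exactly one gene carries a 3′ UTR CNS.
* **Synthetic data** — a seeded generator that emulates every input
  schema with injectable effect sizes (group fractions, CNS-loss
  strength, dN/dS locations, ortholog-loss probabilities, TFBS
  enrichment, half-life shifts), so the whole pipeline is testable
  end-to-end without any external downloads.

## Worked example

```python
from paracns import PipelineConfig, SimulationConfig, run_pipeline

config = PipelineConfig(
    simulate=SimulationConfig(n_pairs=300, frac_similar=0.3,
                              frac_differential=0.5, seed=3),
    permutation_iterations=2000,
    seed=3,
)
results = run_pipeline(config)

d = results.divergence
print(d["retention_table"], round(d["retention_fisher_p"], 6))
print({k: round(v, 3) for k, v in d["dnds"]["medians"].items()})
promoter = results.cns_correlations.query(
    "dataset == 1 and region_class == 'promoter_1500' and measure == 'count'")
print(promoter[["role", "tau_b", "p_value"]])
```

prints

```
[[134, 16], [148, 2]] 0.000946
{'similar': 0.181, 'higher': 0.116, 'lower': 0.234}
     role     tau_b       p_value
0  higher -0.016391  7.830164e-01
2   lower -0.309669  6.265352e-07
```

Reading: of the 150 differentially expressed pairs, the lower-expressed
members retained 134 orthologs versus 148 for the higher-expressed
members (Fisher p ≈ 9×10⁻⁴ — a retention deficit); group dN/dS medians
order lower > similar > higher (relaxed constraint on the lower copy);
and promoter CNS counts of the lower-expressed genes fall with
increasing expression divergence (τ-b = −0.31, p < 10⁻⁶) while the
higher-expressed genes show no trend — exactly the injected effect
structure of this simulation.

The same run is available from the shell:

```sh
paracns simulate --n-pairs 300 --seed 3 --out bundle/
paracns run --config config.yaml --out results/
paracns cns --config config.yaml --out results/   # single section
```

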