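# famturnover

Gene-family turnover analysis on dated species trees: who gained, duplicated
and lost genes, on which branches, how fast, and whether any of it is faster
than chance.

The package targets comparative-genomics studies in which each gene family
(for example a hierarchical orthologous group) is summarized as a copy-count
profile over the sampled species, and the species tree is a chronogram with
branch lengths in million years (My). It was built around an 18-taxon
laurasiatherian mammal study design — eight bats (three Old World fruit bats,
five yangochiropterans) plus carnivore, perissodactyl and cetartiodactyl
outgroups on an 80-My-deep tree, which ships as the default fixture — but all
stages accept any binary ultrametric Newick tree and matching TSV tables.

## What it computes

**Event mapping** (`event_mapping`). Each family's origin is the MRCA of the
species that carry it; ancestral copy numbers inside that subtree are
reconstructed by Wagner parsimony (minimum total |copy-number change|, all
per-copy events weighted equally) via Sankoff dynamic programming, yielding
per-branch tallies of families gained, families lost, duplication events and
loss events.

**Birth–death likelihood** (`bd_likelihood`). Family sizes evolve as a linear
birth–death process: each copy duplicates at rate λ and is lost at rate μ
(per gene per My), size 0 absorbing. With e = exp((λ−μ)t),

    α = μ(e−1)/(λe−μ),   β = λ(e−1)/(λe−μ)        (α = β = λt/(1+λt) if λ = μ)

and P(c|s) is the classical survivor-sum over j surviving lineages. The tree
likelihood of a profile is computed by post-order pruning over ancestral
sizes 0..S under a uniform root prior on 1..S. Models assign λ, μ per branch
class — one global class, a separate bat class, or separate Old World fruit
bat / Yangochiroptera classes — with gain and loss either tied (λ = μ) or
free, fitted by Nelder–Mead restarts in log-rate space. Observed tip counts
may differ from the truth through a ±1 annotation-error channel with
per-species rate ε, estimated by a caferror-style profile-likelihood search
(global or per species).

**Significance** (`significance`). Per-family Monte-Carlo p-values rank each
family's likelihood among profiles simulated from the fitted model;
per-branch p-values are exact probability-ordered tail tests on single
transitions given maximum-likelihood ancestral states; nested rate models
are compared against a null distribution of 2ΔlnL built entirely by
simulate-and-refit (no asymptotic χ²). Bonferroni/Holm/Sidak/BH corrections
included.

**Enrichment** (`enrichment`). One-sided hypergeometric over-representation
tests of terms among expanding or contracting family sets, with the
population defined as all families present at the parent node of the tested
branch.

**Comparative** (`comparative`). Spearman correlation (seeded permutation p)
and Felsenstein's phylogenetic independent contrasts (correlation through
the origin, t-test on n−1 df) between per-tip turnover statistics and a
species trait such as genome size, with genus-average C-value imputation.

**Synthetic data** (`synthetic_data`). Exact event-time simulation of the
birth–death process along the tree with a full ground-truth event log,
error-channel corruption, planted term enrichment among truly contracting
families, and Brownian-motion traits — so every stage above is testable
end to end without any external data.

## Worked example

```python
from famturnover import (StudyConfig, generate_study, fit_model, RateModel,
                         family_pvalues, adjust_pvalues, fisher_enrichment)

study = generate_study(StudyConfig(n_families=1000, eps=0.0), seed=42)
tree, table = study.tree, study.observed_table

fit = fit_model(table, tree, RateModel.single(tree), n_restarts=3, seed=1)
print(f"tied turnover rate: {fit.model.lams[0]:.6f} changes/gene/My "
      f"(-lnL {fit.neg_log_likelihood:.1f}, AIC {fit.aic:.1f})")

p = family_pvalues(table, tree, fit, n_mc=500, seed=2)
bh = adjust_pvalues(p.to_numpy(), "bh")
print(f"families with BH-adjusted p < 0.01: {(bh < 0.01).sum()}")
```

prints

```
tied turnover rate: 0.000815 changes/gene/My (-lnL 12375.4, AIC 24752.9)
families with BH-adjusted p < 0.01: 0
```

The study was generated with a tied turnover rate of 0.0008, so the refit
recovers the truth to about 2%, and — because every family actually evolved
under the fitted model — no family is flagged as accelerated after FDR
control. Testing the planted "OR-like" term among families that truly
contracted on the bat stem branch recovers it decisively:

```
top term among contracting families: OR-like (k=15/21, K=113/1000,
p_raw=7.92e-11, p_bonferroni=1.66e-09)
```

i.e. 15 of the 21 contracting families carry the term versus 113 of 1,000 in
the population.

The same analysis runs from the shell:

```bash
famturnover run --config config.yaml     # simulate/load -> events -> fit ->
                                         # significance -> enrichment -> PIC
famturnover fit --counts counts.tsv --free --clade owf --clade yango \
    --out fit.json                       # three-class gain/loss model
```

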