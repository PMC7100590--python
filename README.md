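# metatracker

Bayesian microbial source tracking for shotgun metagenomes.

Given a taxa × samples read-count table (e.g. from a k-mer taxonomic
classifier) and a mapping file that labels each sample with an
environment and a source/sink role, `metatracker` estimates, for every
sink sample, the proportion of its reads contributed by each candidate
source environment — plus a latent **Unknown** source that absorbs reads
no provided source explains. It is aimed at studies of contamination and
microbial dispersal (coastal waters receiving freshwater runoff, built
environments seeded by human skin and soil, and the like) where sinks
are mixtures of several communities.

Beyond the estimator itself the package provides the surrounding
workflow: parsing classifier reports (name-keyed or full-lineage
dialects), splitting tables by taxonomic domain (Bacteria, Archaea,
Eukaryota, Viruses) so each domain can be tracked separately,
depth-filtering and rarefaction, cross-chain convergence diagnostics,
random-forest environment classification, and a synthetic-study
generator with known mixing truth for validation.

## The model

Each sink read carries a taxon *t* and a latent source assignment
*z ∈ {1..V, Unknown}*. Known sources are the per-environment sums of the
source samples' (rarefied) counts *m₍tv₎*, smoothed by a Dirichlet prior;
the Unknown source's taxon distribution is learned from the sink reads
currently assigned to it; and a symmetric Dirichlet(β) prior sits on the
mixing proportions. Collapsing the proportions and the Unknown's
distribution, a read of taxon *t* (removed from all tallies) is
reassigned with probability

```
q(v) ∝ P(t | v) · (n_v + β)

P(t | v)       = (m_tv + α₁) / (M_v + T·α₁)          known source v
P(t | Unknown) = (n_tu + α₂) / (n_unknown + T·α₂)     self-updating urn
```

where *n_v* counts sink reads currently assigned to source *v*, *T* is
the taxon universe size, and α₁ = 0.001, α₂ = 0.1, β = 10 by default.
A **chain** is an independently initialized Gibbs run; a **draw** is one
recorded sweep; a chain's estimate is the cumulative mean of its per-draw
assignment fractions, and the reported proportions average the final
cumulative means of 5 chains × 100 draws (after 100 burn-in sweeps).
The per-(sink, environment) **spread** — max − min of the chains' final
estimates — is the convergence diagnostic, flagged when above 5%.
`exact_posterior` enumerates the same collapsed joint exactly on tiny
instances and serves as the sampler's correctness oracle in the tests.

## Worked example

```python
from metatracker.gibbs import GibbsConfig, run_all
from metatracker.synthdata import generate_study

study = generate_study("coastal-small", seed=7)   # 5 envs, 209 sources, 14 sinks
config = GibbsConfig(seed=7)                      # 5 chains, 100 draws, depth 1000
estimates, traces, proportions = run_all(study.table, study.metadata, config)
print(proportions.head(3).round(3))
```

prints

```
         coastal_marine  freshwater    gut   sand   soil  Unknown
sink_id
sink01            0.165       0.089  0.147  0.026  0.542    0.031
sink02            0.620       0.132  0.064  0.098  0.061    0.026
sink03            0.122       0.143  0.249  0.033  0.427    0.025
```

Each row sums to 1: sink01 is estimated to draw 54.2% of its reads from
soil sources and 16.5% from coastal-marine sources, with 3.1% left to
the Unknown source. Against the generator's truth these estimates are
accurate to about one percentage point per environment (mean absolute
error 0.005–0.013 for the known environments, 0.034 for Unknown in this
run). The same workflow is available from the shell:

```bash
metatracker simulate --preset coastal-small --seed 7 -o study/
metatracker gibbs -i study/table.tsv -m study/mapping.tsv -o out/ --diagnostics
metatracker diagnose --traces out/chains --plots -o diag/
metatracker classify -i study/table.tsv -m study/mapping.tsv --target-env gut -o clf/
```

The `examples/` directory holds one short script per capability
(simulation, source tracking, chain diagnostics, domain splitting,
environment classification), each printing its numbers with a line on
what they mean.

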