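# Methods

## The mixture model

A sink sample is a vector of taxon read counts of depth *N* (after
rarefaction). Each read *i* carries a taxon *tᵢ* and a latent source
assignment *zᵢ ∈ {1..V, U}*, where the V known sources are environments
and U is a latent Unknown source. The model:

* **Known sources** have fixed taxon distributions estimated from
  training counts: each source environment's samples are rarefied to a
  common depth, summed ("collapsed"), and Dirichlet-smoothed, giving
  P(t|v) = (m₍tv₎ + α₁) / (M_v + T·α₁). Training counts never update
  during sampling — sinks do not inform sources.
* **The Unknown source** has no training data; its distribution is the
  Pólya-urn implied by a Dirichlet(α₂) prior over the taxon universe,
  updated by the sink reads currently assigned to it:
  P(t|U) = (n₍tU₎ + α₂) / (n_U + T·α₂).
* **Mixing proportions** get a symmetric Dirichlet(β) prior, collapsed
  into the assignment conditional as the (n_v + β) factor.

The collapsed Gibbs conditional for read *i* (leave-one-out tallies) is
q(v) ∝ P(tᵢ|v)·(n_v + β). One pass resamples every read once in a fixed
systematic scan. Because the joint is exchangeable in the reads, the
full joint over an assignment vector factorizes into (a) the product of
known-source read probabilities, (b) a Pólya-urn product over the
Unknown's reads, and (c) the Dirichlet-multinomial mixing term
∏_v Γ(n_v + β)/Γ(β). `exact_posterior` enumerates this joint over all
(V+1)^N assignments on tiny instances; the test suite checks the sampler
against it to 0.02 at 10⁴ recorded draws, which pins down both the
formula transcription and the sweep's bookkeeping.

### Estimates, chains, and the convergence diagnostic

A *chain* starts from a uniform-random assignment, discards `burnin`
passes, then records `draws` proportion vectors (assignment counts / N)
every `delay` passes. The chain's running estimate is the cumulative
mean of its per-draw vectors; the sink's estimate averages the final
cumulative means across chains. For every (sink, environment) the
*spread* is the max − min of the chains' final estimates; pairs with
spread strictly greater than the threshold (default 5%) are flagged and,
on request, exported as one line graph per pair with each chain's final
estimate in the legend. The flag is strict at the boundary (spread
exactly equal to the threshold is not flagged); both sides are tested.
The Unknown column participates in flagging like any environment.

### Parameters

| parameter | default | meaning |
|---|---|---|
| α₁ | 0.001 | Dirichlet smoothing of known-source taxon distributions (pseudo-reads per taxon) |
| α₂ | 0.1 | prior mass per taxon for the Unknown source's urn |
| β | 10 | Dirichlet prior mass per source on the mixing proportions |
| chains | 5 | independent Gibbs restarts compared for convergence |
| draws | 100 | recorded sweeps per chain |
| burnin | 100 | discarded initial sweeps |
| delay | 1 | sweeps between recorded draws |
| rarefaction_depth | 1000 | common per-sample depth (reads) |
| threshold | 0.05 | chain-spread flag level (printed as percent) |

α₂·T is the effective resistance of the Unknown source: a read whose
taxon the sources explain well is unlikely to seed the urn, because the
urn's denominator carries the full T·α₂ mass. Consequently recovery of
known sources requires a reasonably large taxon universe; with toy
universes (T of a few) the Unknown can mimic any source — the test suite
documents this regime explicitly. Note also that the Unknown's
first-read probability is α₂/(T·α₂) = 1/T independent of α₂, so small
α₂ makes the urn sticky rather than suppressing it.

### Seeding and determinism

Every chain's RNG seed derives from `blake2b(base_seed : sink_id :
chain_index)` (reduced below 2³¹), so results are invariant to sink
processing order and chain scheduling. Rarefaction uses an analogous
per-sample substream keyed on (seed, sample_id), making it invariant to
column order. The sweep kernel consumes pre-generated uniform variates
from the chain's `numpy` Generator and is numba-jitted when numba is
importable, falling back to the identical pure-Python function
otherwise; both paths therefore produce bit-identical chains. Full
reruns with the same configuration are byte-identical, including the
written TSV outputs (fixed 4-decimal formatting, lexicographic
environment order with Unknown always last).

## Table plumbing

Classifier reports are two-column (taxon key, count) TSVs in either a
name-keyed or a full-lineage-keyed dialect; the dialect is sniffed from
the first data line (a key containing `rank:` tokens is a lineage) and
logged, since column layouts vary across classifier versions. Lineage
strings follow `sk:...;p:...;...;g:...`; whitespace around names is
stripped. A taxon is *unresolved* when its lineage lacks a parseable
`sk:` token, contains a malformed token, or is absent from the offline
name→lineage map — unresolved rows go to a separate bucket excluded
from per-domain analyses (the live taxonomy-service lookup of the
original workflow is replaced by the offline map for reproducibility;
misses are data, not errors). Merging, domain splitting and environment
collapsing conserve grand totals exactly and are asserted to in the
tests. Rarefaction is sampling without replacement
(`multivariate_hypergeometric`); samples below the requested depth must
be removed first (`filter_min_depth`, default 1,000), and the removal
list is returned so related per-domain tables can be synchronized.
Sources are rarefied per sample and then collapsed per environment, so
every source sample carries equal weight regardless of its sequencing
depth; collapse order is configurable in principle but rarefy-then-
collapse is the only mode exposed.

BIOM 2.1 (HDF5) interchange is implemented directly on h5py (ids plus
CSR/CSC matrix groups, empty metadata groups); TSV and BIOM round-trips
are identities on (taxon ids, sample ids, counts).

## Random-forest classification

One environment is tested against all others pooled as "other" (or all
environments at once in multiclass mode) on the same rarefied tables
used for source tracking, with no further normalization. The forest
uses 500 trees, a fixed random state, and out-of-bag scoring; the
train/test split is ~3:1 (test size = round(n/4)), stratified whenever
every class has at least two members — without stratification the
smallest environments (sand, n=6) can vanish from test sets. Feature
importance is mean impurity decrease by default, with permutation
importance as an option. Classes with fewer than two samples are
rejected with advice to merge or add data.

## The synthetic-study generator

The generator stands in for real multi-study source/sink collections:
it draws per-environment taxon profiles, multinomial source samples
around them, and sink samples from known environment mixtures, recording
the truth.

* **Profiles.** Each environment's support is a shared block plus a
  private block; `overlap` is the shared fraction of each support, so
  under the symmetric Dirichlet it equals the expected probability mass
  an environment shares with all others, independent of the number of
  environments (overlap 0 = disjoint supports, 1 = common support). One
  extra private block feeds the withheld *unknown* profile, modelling
  organisms absent from every source collection. Profiles are
  Dirichlet(0.5) over their support — a concentration below 1 gives the
  skewed rank-abundance curves real communities show.
* **Source samples** perturb the profile by a per-sample Dirichlet draw
  with precision 1/noise (default noise 0.02) and sample multinomially
  at the target depth, emulating biological replicate variation.
* **Sinks** draw each read's origin environment from the truth mixing
  vector, then a taxon from that origin's profile.
* **Default preset** (`coastal-small`): five environments named for a
  coastal study (coastal_marine, freshwater, gut, sand, soil) with
  source sample counts following that study design (96/30/13/6/64), 14
  sinks at depth 1,000 — twelve with Dirichlet(1) mixtures over the
  known environments and two drawn entirely from the withheld profile —
  and a 300-taxon universe tagged with domains at realistic shotgun
  frequencies (88.8% Bacteria, 9.0% Eukaryota, 1.9% Archaea, 0.3%
  Viruses). Preset depth equals the rarefaction limit, so rarefaction is
  an identity on preset data; its mechanics are exercised by dedicated
  tests and the `mini` preset. A `mini` preset (2 envs, 60 taxa, depth
  200) serves fast pipeline smoke tests.

What the generator does **not** emulate: classifier misassignment and
database incompleteness (taxon labels are exact), compositional
correlations between taxa beyond the Dirichlet, varying library sizes,
within-environment population structure, and cross-study batch effects.
Passing recovery tests therefore show the estimator is correct under
its own model assumptions and honest sampling noise — not that real
classifier output is this clean.

## Problem sizes and observed behavior

The validation suite uses: four enumeration instances with state spaces
up to 6⁴ = 1296 at 10⁴ recorded draws (observed max deviation ≈ 0.005);
recovery over ten seeded default-preset studies (observed
per-environment mean absolute error ≈ 0.01–0.04, withheld-sink Unknown
mass ≥ 0.98); convergence over 28 sinks at 10 vs 100 draws (mean spread
≈ 0.8% → 0.3%); and per-environment one-vs-other forests at 500 trees
(accuracy 1.0, OOB error 0.0 — the synthetic environments are
well-separated by design, so this probes the expected high-accuracy
regime rather than any real dataset's exact figures). A 20-repeat label-permutation null checks that shuffled
labels drop accuracy to chance. `scripts/acceptance.py` recomputes all
of these quantities at run time for any seed.

## Known limitations

* No formal MCMC diagnostics (Gelman–Rubin R̂, effective sample size);
  the cross-chain spread is deliberately the simple, interpretable
  statistic practitioners can read off the trace plots.
* The Unknown proportion is sensitive to source training depth: thinly
  sampled source environments inflate Unknown mass because rare taxa go
  unobserved in training. This is a property of the model, not a bug;
  deeper or more numerous source samples reduce it.
* Leave-one-out source-vs-source validation, alternative inference
  (variational, MAP), and read-level simulation are out of scope.
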