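"""Bayesian source tracking by collapsed Gibbs sampling.

Each sink sample (a vector of taxon read counts) is modelled as a mixture
of V known source environments plus one latent "Unknown" source.  Known
sources contribute fixed, Dirichlet-smoothed taxon distributions estimated
from their collapsed training counts; the Unknown source's taxon
distribution is learned from the sink reads currently assigned to it.  A
symmetric Dirichlet(beta) prior sits on the mixing proportions.

With read i carrying taxon t removed from all tallies, the full
conditional for its source assignment is

    q(v) ∝ P(t | v) * (n_v + beta)

where for a known source v

    P(t | v) = (m_tv + alpha1) / (M_v + T * alpha1)

and for the Unknown source

    P(t | Unknown) = (n_tu + alpha2) / (n_unknown + T * alpha2),

with m_tv the training count of taxon t in source v, M_v its total, T the
taxon universe size, n_v the number of sink reads currently assigned to v,
and n_tu / n_unknown the Unknown source's current taxon/total tallies.
This is the full conditional of an exchangeable joint that
:func:`exact_posterior` enumerates exactly on tiny instances, which is the
sampler's correctness oracle.

A "draw" is one recorded Gibbs sample of the full assignment vector; a
"chain" is one independently initialized run.  Per-draw source proportions
are assignment counts divided by the sink depth N, and each chain's
running estimate is the cumulative mean of its per-draw proportions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from hashlib import blake2b
from itertools import product
from math import lgamma, log
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import MetatrackerError
from .tables_io import FeatureTable, collapse_by_env, filter_min_depth, rarefy

logger = logging.getLogger(__name__)

UNKNOWN = "Unknown"


@dataclass(frozen=True)
class GibbsConfig:
    """Sampler configuration.

    alpha1: Dirichlet smoothing of known-source taxon distributions.
    alpha2: smoothing of the Unknown source's self-updating distribution.
    beta: Dirichlet prior mass on the mixing proportions.
    chains/draws/burnin/delay: chain count, recorded draws per chain,
        discarded initial passes, and passes between recorded draws.
    rarefaction_depth: common per-sample depth enforced before sampling.
    seed: base seed; per-chain seeds derive from (seed, sink_id, chain).
    """

    alpha1: float = 0.001
    alpha2: float = 0.1
    beta: float = 10.0
    chains: int = 5
    draws: int = 100
    burnin: int = 100
    delay: int = 1
    rarefaction_depth: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.alpha1, self.alpha2, self.beta) <= 0:
            raise MetatrackerError("alpha1, alpha2 and beta must be > 0")
        if self.chains < 1 or self.draws < 1 or self.burnin < 0 or self.delay < 1:
            raise MetatrackerError(
                "need chains >= 1, draws >= 1, burnin >= 0, delay >= 1"
            )


@dataclass
class SamplerState:
    """Mutable tallies of one Gibbs chain.

    z: per-read source index (V = Unknown); n_v: reads per source;
    n_tu: Unknown-source per-taxon counts; m: fixed training counts
    (T x V); M_v: training totals per source.
    """

    taxa: np.ndarray
    z: np.ndarray
    n_v: np.ndarray
    n_tu: np.ndarray
    m: np.ndarray
    M_v: np.ndarray

    @classmethod
    def from_assignments(
        cls, taxa: np.ndarray, z: np.ndarray, m: np.ndarray
    ) -> "SamplerState":
        V = m.shape[1]
        n_v = np.bincount(z, minlength=V + 1).astype(np.int64)
        n_tu = np.bincount(taxa[z == V], minlength=m.shape[0]).astype(np.int64)
        return cls(taxa=taxa.astype(np.int64), z=z.astype(np.int64), n_v=n_v,
                   n_tu=n_tu, m=m.astype(np.float64),
                   M_v=m.sum(axis=0).astype(np.float64))

    @property
    def n_sources(self) -> int:
        return self.m.shape[1]

    @property
    def n_taxa(self) -> int:
        return self.m.shape[0]


def known_source_probs(m: np.ndarray, alpha1: float) -> np.ndarray:
    """Dirichlet-smoothed taxon distributions P(t|v), one column per source."""
    m = np.asarray(m, dtype=np.float64)
    T = m.shape[0]
    if T == 0:
        raise MetatrackerError("empty taxon universe")
    return (m + alpha1) / (m.sum(axis=0) + T * alpha1)


def conditional_probs(state: SamplerState, t: int, config: GibbsConfig) -> np.ndarray:
    """Normalized assignment probabilities for a read of taxon ``t``.

    Pre-condition: the read has already been removed from the state's
    tallies (leave-one-out).
    """
    T, V = state.n_taxa, state.n_sources
    if T == 0:
        raise MetatrackerError("empty taxon universe")
    p = np.empty(V + 1)
    p[:V] = known_source_probs(state.m, config.alpha1)[t]
    n_unk = state.n_v[V]
    p[V] = (state.n_tu[t] + config.alpha2) / (n_unk + T * config.alpha2)
    q = p * (state.n_v + config.beta)
    return q / q.sum()


# ---------------------------------------------------------------------------
# The sweep kernel (numba-jitted when available)
# ---------------------------------------------------------------------------

def _sweep_kernel(taxa, z, n_v, n_tu, p_known, alpha2, beta, uniforms):
    """One systematic-scan pass: resample every read once, in place."""
    N = taxa.shape[0]
    T = p_known.shape[0]
    V = p_known.shape[1]
    for i in range(N):
        t = taxa[i]
        v_old = z[i]
        n_v[v_old] -= 1
        if v_old == V:
            n_tu[t] -= 1
        total = 0.0
        for v in range(V):
            total += p_known[t, v] * (n_v[v] + beta)
        p_unk = (n_tu[t] + alpha2) / (n_v[V] + T * alpha2)
        total += p_unk * (n_v[V] + beta)
        u = uniforms[i] * total
        acc = 0.0
        v_new = V
        for v in range(V):
            acc += p_known[t, v] * (n_v[v] + beta)
            if u < acc:
                v_new = v
                break
        z[i] = v_new
        n_v[v_new] += 1
        if v_new == V:
            n_tu[t] += 1


try:  # pragma: no cover - exercised implicitly by every sampler test
    from numba import njit

    _sweep = njit(cache=False)(_sweep_kernel)
except Exception:  # pragma: no cover
    logger.warning("numba unavailable; Gibbs sweep runs in pure Python")
    _sweep = _sweep_kernel


def gibbs_pass(state: SamplerState, rng: np.random.Generator,
               config: GibbsConfig) -> SamplerState:
    """Resample every sink read once from its full conditional."""
    N = state.taxa.shape[0]
    if N == 0:
        return state
    p_known = known_source_probs(state.m, config.alpha1)
    uniforms = rng.random(N)
    _sweep(state.taxa, state.z, state.n_v, state.n_tu, p_known,
           config.alpha2, config.beta, uniforms)
    return state


# ---------------------------------------------------------------------------
# Chains and estimates
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChainTrace:
    """Per-draw and cumulative-mean proportion traces of one chain."""

    sink_id: str
    chain_index: int
    envs: tuple[str, ...]  # known environments + "Unknown", in output order
    draws: np.ndarray      # (n_draws, n_envs) per-draw proportions
    cum_mean: np.ndarray   # running mean of `draws` along axis 0

    @property
    def final(self) -> np.ndarray:
        """The chain's estimate: final cumulative mean over all draws."""
        return self.cum_mean[-1]


@dataclass(frozen=True)
class MixingEstimate:
    """Per-sink source proportions with cross-chain agreement."""

    sink_id: str
    envs: tuple[str, ...]
    proportions: np.ndarray  # mean of per-chain finals; sums to 1
    per_chain: np.ndarray    # (chains, n_envs) final cumulative means
    spread: np.ndarray       # max - min over chains, per environment


def chain_seed(base_seed: int, sink_id: str, chain_index: int) -> int:
    """Stable seed for one chain, independent of sink order and scheduling."""
    h = blake2b(f"{base_seed}:{sink_id}:{chain_index}".encode(),
                digest_size=8).digest()
    return int.from_bytes(h, "big") % (2**31)


def run_chain(
    sink_counts: np.ndarray,
    source_counts: np.ndarray,
    config: GibbsConfig,
    seed: int,
    sink_id: str = "sink",
    chain_index: int = 0,
    envs: Sequence[str] | None = None,
) -> ChainTrace:
    """Run one Gibbs chain on one sink.

    ``sink_counts`` is the sink's taxon count vector (length T);
    ``source_counts`` the taxa x sources training-count matrix (T x V).
    Assignments start uniform over V+1 sources, ``burnin`` passes are
    discarded, then ``draws`` proportion vectors are recorded every
    ``delay`` passes, with the cumulative-mean trace attached.
    """
    sink_counts = np.asarray(sink_counts)
    m = np.asarray(source_counts, dtype=np.float64)
    T, V = m.shape
    if sink_counts.shape[0] != T:
        raise MetatrackerError("sink and source taxon universes differ")
    N = int(sink_counts.sum())
    if N == 0:
        raise MetatrackerError(f"sink {sink_id!r} has depth 0")
    if envs is None:
        envs = tuple(f"source_{v}" for v in range(V)) + (UNKNOWN,)
    envs = tuple(envs)
    if len(envs) != V + 1:
        raise MetatrackerError("envs must list V known sources plus Unknown")

    taxa = np.repeat(np.arange(T, dtype=np.int64), sink_counts.astype(np.int64))
    rng = np.random.default_rng(seed)
    z = rng.integers(0, V + 1, size=N, dtype=np.int64)
    state = SamplerState.from_assignments(taxa, z, m)
    p_known = known_source_probs(m, config.alpha1)

    for _ in range(config.burnin):
        _sweep(state.taxa, state.z, state.n_v, state.n_tu, p_known,
               config.alpha2, config.beta, rng.random(N))
    recorded = np.empty((config.draws, V + 1))
    for d in range(config.draws):
        for _ in range(config.delay):
            _sweep(state.taxa, state.z, state.n_v, state.n_tu, p_known,
                   config.alpha2, config.beta, rng.random(N))
        recorded[d] = state.n_v / N
    cum = np.cumsum(recorded, axis=0) / np.arange(1, config.draws + 1)[:, None]
    return ChainTrace(sink_id=sink_id, chain_index=chain_index, envs=envs,
                      draws=recorded, cum_mean=cum)


def estimate_sink(
    sink_counts: np.ndarray,
    source_counts: np.ndarray,
    config: GibbsConfig,
    sink_id: str = "sink",
    envs: Sequence[str] | None = None,
) -> tuple[MixingEstimate, list[ChainTrace]]:
    """Estimate one sink's mixing proportions from ``config.chains`` chains.

    The estimate is the mean of the chains' final cumulative-mean
    proportions; the per-environment max-min spread across chains is the
    convergence signal consumed by the diagnostics module.
    """
    traces = [
        run_chain(sink_counts, source_counts, config,
                  seed=chain_seed(config.seed, sink_id, c),
                  sink_id=sink_id, chain_index=c, envs=envs)
        for c in range(config.chains)
    ]
    per_chain = np.vstack([t.final for t in traces])
    est = MixingEstimate(
        sink_id=sink_id,
        envs=traces[0].envs,
        proportions=per_chain.mean(axis=0),
        per_chain=per_chain,
        spread=per_chain.max(axis=0) - per_chain.min(axis=0),
    )
    return est, traces


def run_all(
    table: FeatureTable,
    metadata: pd.DataFrame,
    config: GibbsConfig,
) -> tuple[list[MixingEstimate], dict[str, list[ChainTrace]], pd.DataFrame]:
    """Full source-tracking run on a feature table plus mapping metadata.

    Samples below the rarefaction depth are removed, the rest rarefied to
    that depth (per-sample RNG substreams), sources collapsed into
    per-environment profiles, and every sink estimated independently.
    Returns the estimates, the per-sink chain traces, and a sinks x
    (environments + Unknown) proportion table.
    """
    from .tables_io import align_mapping

    metadata, _missing = align_mapping(table, metadata)
    table, removed = filter_min_depth(table, config.rarefaction_depth)
    metadata = metadata.loc[[s for s in metadata.index if s not in removed]]
    table = rarefy(table, config.rarefaction_depth, seed=config.seed)

    sources_meta = metadata[metadata["role"] == "source"]
    if sources_meta.empty:
        raise MetatrackerError("no source samples after filtering")
    profiles = collapse_by_env(table, metadata)  # taxa x envs, lexicographic
    envs = tuple(profiles.columns) + (UNKNOWN,)

    sink_ids = sorted(metadata.index[metadata["role"] == "sink"])
    estimates: list[MixingEstimate] = []
    traces: dict[str, list[ChainTrace]] = {}
    for sink_id in sink_ids:
        sink_counts = table.data[sink_id].to_numpy()
        est, sink_traces = estimate_sink(
            sink_counts, profiles.to_numpy(), config, sink_id=sink_id, envs=envs
        )
        estimates.append(est)
        traces[sink_id] = sink_traces
        logger.info("sink %s: %s", sink_id,
                    dict(zip(est.envs, np.round(est.proportions, 4))))
    table_out = mixing_table(estimates, envs)
    return estimates, traces, table_out


def mixing_table(
    estimates: Iterable[MixingEstimate], envs: Sequence[str] | None = None
) -> pd.DataFrame:
    """Sinks x (environments + Unknown) proportion DataFrame."""
    estimates = list(estimates)
    if not estimates:
        return pd.DataFrame(columns=list(envs) if envs else [])
    envs = envs or estimates[0].envs
    df = pd.DataFrame(
        [e.proportions for e in estimates],
        index=[e.sink_id for e in estimates],
        columns=list(envs),
    )
    df.index.name = "sink_id"
    return df


# ---------------------------------------------------------------------------
# Exact enumeration oracle
# ---------------------------------------------------------------------------

def exact_posterior(
    sink_counts: np.ndarray,
    source_counts: np.ndarray,
    config: GibbsConfig,
    max_states: int = 10**6,
) -> np.ndarray:
    """Exact expected assignment fractions by enumerating every z.

    Enumerates all (V+1)^N assignment vectors of the N sink reads and
    weights each by the exchangeable collapsed joint: known-source reads
    contribute their fixed smoothed probabilities, Unknown-source reads a
    Polya-urn product over alpha2, and the mixing term is
    prod_v Gamma(n_v + beta) / Gamma(beta).  Serves as the independent
    correctness oracle for the Gibbs sampler on tiny instances.
    """
    sink_counts = np.asarray(sink_counts)
    m = np.asarray(source_counts, dtype=np.float64)
    T, V = m.shape
    N = int(sink_counts.sum())
    if (V + 1) ** N > max_states:
        raise MetatrackerError(
            f"enumeration over {(V + 1) ** N} states exceeds max_states={max_states}"
        )
    taxa = np.repeat(np.arange(T), sink_counts.astype(np.int64))
    logp = np.log(known_source_probs(m, config.alpha1))
    a2, b = config.alpha2, config.beta
    lg_beta = lgamma(b)

    total_w = 0.0
    expected = np.zeros(V + 1)
    for z in product(range(V + 1), repeat=N):
        lw = 0.0
        n_v = [0] * (V + 1)
        c_t: dict[int, int] = {}
        n_u = 0
        for i, v in enumerate(z):
            t = int(taxa[i])
            if v < V:
                lw += logp[t, v]
            else:
                c = c_t.get(t, 0)
                lw += log(c + a2) - log(n_u + T * a2)
                c_t[t] = c + 1
                n_u += 1
            n_v[v] += 1
        for v in range(V + 1):
            lw += lgamma(n_v[v] + b) - lg_beta
        w = np.exp(lw)
        total_w += w
        expected += w * np.asarray(n_v) / N
    return expected / total_w


# ---------------------------------------------------------------------------
# Trace persistence (consumed by the diagnostics module)
# ---------------------------------------------------------------------------

def write_traces(traces: Mapping[str, list[ChainTrace]], outdir: str | Path) -> None:
    """Persist per-sink chain traces as ``<outdir>/<sink>.tsv``.

    Columns: chain, draw, env, proportion, cum_mean — one row per
    (chain, draw, environment).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for sink_id, chain_traces in traces.items():
        rows = []
        for tr in chain_traces:
            for d in range(tr.draws.shape[0]):
                for e, env in enumerate(tr.envs):
                    rows.append((tr.chain_index, d + 1, env,
                                 tr.draws[d, e], tr.cum_mean[d, e]))
        df = pd.DataFrame(rows, columns=["chain", "draw", "env",
                                         "proportion", "cum_mean"])
        df.to_csv(outdir / f"{sink_id}.tsv", sep="\t", index=False,
                  float_format="%.6f")


def read_traces(tracedir: str | Path) -> dict[str, list[ChainTrace]]:
    """Load traces written by :func:`write_traces`."""
    tracedir = Path(tracedir)
    if not tracedir.is_dir():
        raise MetatrackerError(f"trace directory not found: {tracedir}")
    out: dict[str, list[ChainTrace]] = {}
    for path in sorted(tracedir.glob("*.tsv")):
        sink_id = path.stem
        df = pd.read_csv(path, sep="\t")
        envs = tuple(df["env"].drop_duplicates())
        chain_traces = []
        for chain_idx in sorted(df["chain"].unique()):
            sub = df[df["chain"] == chain_idx]
            draws = sub.pivot(index="draw", columns="env", values="proportion")
            cum = sub.pivot(index="draw", columns="env", values="cum_mean")
            draws = draws.loc[sorted(draws.index), list(envs)]
            cum = cum.loc[sorted(cum.index), list(envs)]
            chain_traces.append(
                ChainTrace(sink_id=sink_id, chain_index=int(chain_idx),
                           envs=envs, draws=draws.to_numpy(),
                           cum_mean=cum.to_numpy())
            )
        out[sink_id] = chain_traces
    return out
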