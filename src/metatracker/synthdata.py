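"""Synthetic multi-environment metagenome studies with known mixing truth.

Generates environment taxon profiles (Dirichlet over a taxon pool with a
tunable fraction of shared vs environment-private taxa), multinomial
source samples with per-sample Dirichlet noise, and sink samples whose
reads are drawn from a known mixture of environment profiles plus a
withheld "unknown" profile.  The generator's manifest (profiles, per-sink
truth vectors, seed) makes every downstream module testable without any
external downloads.

The default ``coastal-small`` preset mirrors the shape of a coastal-marine
source-tracking study — five environments (coastal marine, freshwater,
gut, sand, soil) with sample counts scaled down roughly fourfold from the
original 110/30/13/6/64, fourteen sinks, and 1,000-read depth — with
domain tags drawn at realistic shotgun-metagenome frequencies (88.8%
Bacteria, 9.0% Eukaryota, 1.9% Archaea, 0.3% Viruses).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import MetatrackerError
from .gibbs import UNKNOWN
from .tables_io import (
    FeatureTable,
    merge_counts,
    write_feature_table,
    write_lineage_map,
    write_mapping,
)

DOMAIN_FREQS = {
    "Bacteria": 0.888,
    "Eukaryota": 0.090,
    "Archaea": 0.019,
    "Viruses": 0.003,
}


@dataclass(frozen=True)
class SyntheticStudy:
    """A generated study: tables, metadata, and the generator manifest."""

    table: FeatureTable            # sources + sinks, taxa x samples
    metadata: pd.DataFrame         # sample_id -> env, role
    truth: pd.DataFrame            # sinks x (envs + Unknown) true mixing
    env_profiles: pd.DataFrame     # taxa x envs probability vectors
    unknown_profile: pd.Series     # withheld environment's profile
    lineage_map: dict[str, str]    # taxon -> lineage string (domain tags)
    seed: int
    preset: str


def generate_profiles(
    n_envs: int,
    n_taxa: int,
    concentration: float = 0.5,
    overlap: float = 0.2,
    seed: int = 0,
    env_names: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Draw per-environment taxon probability profiles plus a withheld one.

    Every environment's support is a shared block plus a private block,
    sized so that the shared block makes up fraction ``overlap`` of each
    support — i.e. under a symmetric Dirichlet, ``overlap`` is the
    expected probability mass an environment places on taxa it shares
    with every other environment, independent of how many environments
    there are.  One extra private block feeds the withheld "unknown"
    profile.  Each profile is Dirichlet(``concentration``) over its own
    support, so small concentrations give realistically skewed
    rank-abundance curves.  overlap=0 yields disjoint supports; overlap=1
    a fully common support.
    """
    if not 0 <= overlap <= 1:
        raise MetatrackerError("overlap must be in [0, 1]")
    if env_names is None:
        env_names = [f"env{k + 1}" for k in range(n_envs)]
    if len(env_names) != n_envs:
        raise MetatrackerError("env_names length must equal n_envs")
    rng = np.random.default_rng(seed)
    taxa = [f"taxon{i + 1:04d}" for i in range(n_taxa)]
    n_groups = n_envs + 1  # environments + withheld unknown
    # support size S with shared block c = overlap*S and private p = S-c,
    # filling the pool: c + n_groups*p = n_taxa
    support_size = n_taxa / (n_groups - (n_groups - 1) * overlap)
    n_shared = int(round(overlap * support_size))
    n_private = (n_taxa - n_shared) // n_groups
    if n_private < 1 and overlap < 1:
        raise MetatrackerError("too few taxa for private support blocks")
    shared = np.arange(n_shared)
    blocks = np.array_split(np.arange(n_shared, n_taxa), n_groups)

    def draw(support: np.ndarray) -> np.ndarray:
        p = np.zeros(n_taxa)
        p[support] = rng.dirichlet(np.full(support.shape[0], concentration))
        return p

    cols = {}
    for k, env in enumerate(env_names):
        support = np.concatenate([shared, blocks[k]]) if overlap < 1 else shared
        cols[env] = draw(support.astype(np.int64))
    unk_support = np.concatenate([shared, blocks[-1]]) if overlap < 1 else shared
    unknown = draw(unk_support.astype(np.int64))
    profiles = pd.DataFrame(cols, index=taxa)
    profiles.index.name = "taxon_id"
    return profiles, pd.Series(unknown, index=taxa, name=UNKNOWN)


def generate_source_samples(
    profiles: pd.DataFrame,
    n_per_env: int | Mapping[str, int],
    depth: int = 1000,
    noise: float = 0.02,
    seed: int = 0,
) -> tuple[FeatureTable, pd.DataFrame]:
    """Multinomial source samples around each environment profile.

    Each sample's composition is the environment profile perturbed by a
    per-sample Dirichlet draw with precision ``1/noise`` (noise=0 means no
    perturbation), then sampled multinomially at ``depth`` reads.
    """
    rng = np.random.default_rng(seed)
    records: list[tuple[str, str, int]] = []
    meta_rows = []
    taxa = list(profiles.index)
    for env in profiles.columns:
        base = profiles[env].to_numpy()
        n = n_per_env[env] if isinstance(n_per_env, Mapping) else n_per_env
        for i in range(n):
            sample_id = f"{env}_src{i + 1:02d}"
            p = base
            if noise > 0:
                support = base > 0
                p = np.zeros_like(base)
                p[support] = rng.dirichlet(base[support] / noise)
            counts = rng.multinomial(depth, p)
            records.extend(
                (sample_id, taxa[t], int(c)) for t, c in enumerate(counts) if c
            )
            meta_rows.append((sample_id, env, "source"))
    if not meta_rows:
        table = FeatureTable(pd.DataFrame(index=pd.Index(taxa, name="taxon_id")))
        meta = pd.DataFrame(columns=["env", "role"])
        meta.index.name = "sample_id"
        return table, meta
    table = merge_counts(records)
    # fix full taxon universe and a deterministic row order
    table = FeatureTable(table.data.reindex(index=taxa, fill_value=0))
    meta = pd.DataFrame(
        [(env, role) for _, env, role in meta_rows],
        index=[sid for sid, _, _ in meta_rows],
        columns=["env", "role"],
    )
    meta.index.name = "sample_id"
    return table, meta


def generate_sink(
    profiles: pd.DataFrame,
    unknown_profile: pd.Series,
    mixing_vector: Sequence[float],
    depth: int = 1000,
    seed: int = 0,
    sink_id: str = "sink",
) -> tuple[pd.Series, pd.Series]:
    """One sink sample drawn from a known environment mixture.

    ``mixing_vector`` lists proportions over the profile environments with
    the unknown profile last; each read first draws its origin environment,
    then a taxon from that origin's profile.  Returns the sink's count
    vector and the truth record (the mixing vector, environments +
    Unknown).
    """
    envs = list(profiles.columns)
    mix = np.asarray(mixing_vector, dtype=np.float64)
    if mix.shape[0] != len(envs) + 1:
        raise MetatrackerError(
            f"mixing vector needs {len(envs) + 1} entries (envs + unknown)"
        )
    if (mix < 0).any() or abs(mix.sum() - 1) > 1e-9:
        raise MetatrackerError("mixing vector must be a probability vector")
    rng = np.random.default_rng(seed)
    origin_counts = rng.multinomial(depth, mix)
    counts = np.zeros(profiles.shape[0], dtype=np.int64)
    all_profiles = [profiles[e].to_numpy() for e in envs] + [
        unknown_profile.to_numpy()
    ]
    for o, n_reads in enumerate(origin_counts):
        if n_reads:
            counts += rng.multinomial(int(n_reads), all_profiles[o])
    sink = pd.Series(counts, index=profiles.index, name=sink_id)
    truth = pd.Series(mix, index=envs + [UNKNOWN], name=sink_id)
    return sink, truth


def assign_domains(
    taxon_ids: Sequence[str],
    seed: int = 0,
    freqs: Mapping[str, float] = DOMAIN_FREQS,
) -> dict[str, str]:
    """Tag taxa with domains at the given frequencies; returns a lineage map.

    Each taxon gets a minimal ``sk:<Domain>;g:<name>`` lineage string so
    per-domain table splitting can be exercised realistically.
    """
    rng = np.random.default_rng(seed)
    domains = list(freqs)
    p = np.asarray([freqs[d] for d in domains], dtype=np.float64)
    p = p / p.sum()
    picks = rng.choice(len(domains), size=len(taxon_ids), p=p)
    return {
        t: f"sk:{domains[k]};g:{t}" for t, k in zip(taxon_ids, picks)
    }


PRESETS: dict[str, dict] = {
    # Analogue of a 5-environment coastal study: source sample counts follow
    # the study design (96 marine sources after withholding 14 sinks, 30
    # freshwater, 13 gut, 6 sand, 64 soil); the taxon universe is scaled
    # down (300 vs thousands), hence "small".
    "coastal-small": dict(
        env_names=["coastal_marine", "freshwater", "gut", "sand", "soil"],
        n_per_env={"coastal_marine": 96, "freshwater": 30, "gut": 13,
                   "sand": 6, "soil": 64},
        n_taxa=300,
        concentration=0.5,
        overlap=0.2,
        depth=1000,
        noise=0.02,
        n_sinks=14,
        n_unknown_sinks=2,
    ),
    # Tiny preset for fast smoke tests of the full pipeline.
    "mini": dict(
        env_names=["freshwater", "soil"],
        n_per_env={"freshwater": 3, "soil": 3},
        n_taxa=60,
        concentration=0.5,
        overlap=0.2,
        depth=200,
        noise=0.02,
        n_sinks=3,
        n_unknown_sinks=1,
    ),
}


def generate_study(
    preset: str = "coastal-small",
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> SyntheticStudy:
    """Generate a full study (sources + sinks + truth), optionally on disk.

    The last ``n_unknown_sinks`` sinks draw all reads from the withheld
    unknown profile; the rest mix the known environments with Dirichlet(1)
    truth vectors.  With ``out_dir`` set, writes ``table.tsv``,
    ``mapping.tsv``, ``truth.tsv``, ``lineage_map.tsv`` and
    ``env_profiles.tsv`` — byte-identical for identical (preset, seed).
    """
    if preset not in PRESETS:
        raise MetatrackerError(
            f"unknown preset {preset!r}; available: {sorted(PRESETS)}"
        )
    cfg = PRESETS[preset]
    rng = np.random.default_rng(seed)
    profiles, unknown_profile = generate_profiles(
        n_envs=len(cfg["env_names"]),
        n_taxa=cfg["n_taxa"],
        concentration=cfg["concentration"],
        overlap=cfg["overlap"],
        seed=int(rng.integers(2**31)),
        env_names=cfg["env_names"],
    )
    table, metadata = generate_source_samples(
        profiles, cfg["n_per_env"], depth=cfg["depth"], noise=cfg["noise"],
        seed=int(rng.integers(2**31)),
    )
    n_envs = len(cfg["env_names"])
    sink_cols = {}
    truth_rows = []
    for s in range(cfg["n_sinks"]):
        sink_id = f"sink{s + 1:02d}"
        if s >= cfg["n_sinks"] - cfg["n_unknown_sinks"]:
            mix = np.zeros(n_envs + 1)
            mix[-1] = 1.0
        else:
            mix = np.concatenate([rng.dirichlet(np.ones(n_envs)), [0.0]])
        sink, truth = generate_sink(
            profiles, unknown_profile, mix, depth=cfg["depth"],
            seed=int(rng.integers(2**31)), sink_id=sink_id,
        )
        sink_cols[sink_id] = sink
        truth_rows.append(truth)
    sinks_df = pd.DataFrame(sink_cols, index=profiles.index)
    combined = FeatureTable(pd.concat([table.data, sinks_df], axis=1))
    sink_meta = pd.DataFrame(
        {"env": "mixed", "role": "sink"}, index=list(sink_cols)
    )
    sink_meta.index.name = "sample_id"
    metadata = pd.concat([metadata, sink_meta])
    truth = pd.DataFrame(truth_rows)
    truth.index.name = "sink_id"
    lineage_map = assign_domains(list(profiles.index), seed=int(rng.integers(2**31)))
    study = SyntheticStudy(
        table=combined, metadata=metadata, truth=truth,
        env_profiles=profiles, unknown_profile=unknown_profile,
        lineage_map=lineage_map, seed=seed, preset=preset,
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_feature_table(combined, out_dir / "table.tsv")
        write_mapping(metadata, out_dir / "mapping.tsv")
        truth.to_csv(out_dir / "truth.tsv", sep="\t", float_format="%.6f")
        write_lineage_map(lineage_map, out_dir / "lineage_map.tsv")
        profiles.to_csv(out_dir / "env_profiles.tsv", sep="\t",
                        float_format="%.8e")
    return study
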