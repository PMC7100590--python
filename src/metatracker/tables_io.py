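"""Feature-table plumbing for shotgun-metagenome source tracking.

Reads per-sample taxonomic classifier reports (Kaiju-style TSV, either
name-keyed or full-lineage-keyed), resolves taxon lineages against an
offline name->lineage map, and builds taxa x samples count tables that can
be split by taxonomic domain, depth-filtered, rarefied, and collapsed into
per-environment source profiles.  Tables round-trip through TSV and BIOM
2.1 (HDF5).

Lineage strings follow the ``sk:...;p:...;...;g:...`` convention, e.g.::

    sk:Bacteria;p:Proteobacteria;c:Gammaproteobacteria;o:Enterobacterales;f:Enterobacteriaceae;g:Salmonella

A taxon whose lineage lacks a parseable ``sk:`` token, or contains any
malformed token, is treated as unresolved: its counts are kept in a
separate bucket and excluded from per-domain analyses.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from hashlib import blake2b
from pathlib import Path
from typing import IO, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import MetatrackerError, ParseError

logger = logging.getLogger(__name__)

#: Recognized rank codes, outermost first.
RANK_CODES = ("sk", "p", "c", "o", "f", "g", "s")

DEFAULT_MIN_DEPTH = 1000
DEFAULT_RAREFACTION_DEPTH = 1000


class Domain(enum.Enum):
    """Taxonomic domain (superkingdom) of a taxon."""

    BACTERIA = "Bacteria"
    ARCHAEA = "Archaea"
    EUKARYOTA = "Eukaryota"
    VIRUSES = "Viruses"
    UNRESOLVED = "Unresolved"


#: Domains that participate in analysis (everything except UNRESOLVED).
ANALYSIS_DOMAINS = (
    Domain.BACTERIA,
    Domain.ARCHAEA,
    Domain.EUKARYOTA,
    Domain.VIRUSES,
)

_SK_TO_DOMAIN = {
    "bacteria": Domain.BACTERIA,
    "archaea": Domain.ARCHAEA,
    "eukaryota": Domain.EUKARYOTA,
    "viruses": Domain.VIRUSES,
    "viroids": Domain.VIRUSES,
}


@dataclass(frozen=True)
class LineageRecord:
    """Parsed taxonomic lineage for one classifier taxon key."""

    query_name: str
    ranks: tuple[tuple[str, str], ...]
    domain: Domain
    incomplete: bool = False

    def rank(self, code: str) -> str | None:
        for c, name in self.ranks:
            if c == code:
                return name
        return None


@dataclass(frozen=True)
class FeatureTable:
    """Taxa x samples matrix of non-negative integer read counts.

    Thin wrapper over a pandas DataFrame (index = taxon ids, columns =
    sample ids) that enforces unique identifiers and integral counts.
    """

    data: pd.DataFrame = field()

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise MetatrackerError(f"duplicate taxon ids: {dups}")
        if df.columns.has_duplicates:
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise MetatrackerError(f"duplicate sample ids: {dups}")
        values = df.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.integer):
            if not np.allclose(values, np.round(values)):
                raise MetatrackerError("feature table counts must be integral")
        if values.size and (values < 0).any():
            raise MetatrackerError("feature table counts must be non-negative")
        clean = df.astype(np.int64)
        clean.index = clean.index.astype(str)
        clean.columns = clean.columns.astype(str)
        clean.index.name = "taxon_id"
        object.__setattr__(self, "data", clean)

    # -- convenience accessors -------------------------------------------
    @property
    def taxon_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def counts(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_taxa(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def sample_sums(self) -> pd.Series:
        """Per-sample total counts (sequencing depth after classification)."""
        return self.data.sum(axis=0)

    def total(self) -> int:
        return int(self.data.to_numpy().sum())

    def select_samples(self, sample_ids: Sequence[str]) -> "FeatureTable":
        missing = [s for s in sample_ids if s not in self.data.columns]
        if missing:
            raise MetatrackerError(f"samples not in table: {missing}")
        return FeatureTable(self.data.loc[:, list(sample_ids)])


# ---------------------------------------------------------------------------
# Classifier report parsing
# ---------------------------------------------------------------------------

def sniff_dialect(taxon_keys: Iterable[str]) -> str:
    """Guess the report dialect from taxon keys.

    ``"lineage"`` if keys look like semicolon-delimited ``rank:name``
    strings, otherwise ``"name"``.
    """
    for key in taxon_keys:
        if ":" in key and (";" in key or key.split(":", 1)[0] in RANK_CODES):
            return "lineage"
        return "name"
    return "name"


def parse_classifier_report(
    stream: IO[str] | Iterable[str],
    sample_id: str,
    dialect: str = "auto",
    sep: str = "\t",
) -> list[tuple[str, str, int]]:
    """Parse a per-sample classifier report into (sample, taxon_key, count).

    Two dialects are supported: ``"name"`` (taxon name + count) and
    ``"lineage"`` (full semicolon-delimited lineage string + count).  With
    ``dialect="auto"`` the dialect is sniffed from the first data line and
    logged.  Zero-count records are dropped.  Lines with the wrong column
    count or a non-integer count raise :class:`ParseError` naming the line.
    """
    if dialect not in ("auto", "name", "lineage"):
        raise ParseError(f"unknown classifier-report dialect: {dialect!r}")
    records: list[tuple[str, str, int]] = []
    sniffed: str | None = None if dialect == "auto" else dialect
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split(sep)
        if len(parts) != 2:
            raise ParseError(
                f"line {lineno}: expected 2 columns (taxon, count), got {len(parts)}"
            )
        key, count_str = parts[0].strip(), parts[1].strip()
        try:
            count = int(count_str)
        except ValueError:
            raise ParseError(
                f"line {lineno}: count {count_str!r} is not an integer"
            ) from None
        if count < 0:
            raise ParseError(f"line {lineno}: negative count {count}")
        if sniffed is None:
            sniffed = sniff_dialect([key])
            logger.info("report dialect sniffed as %r for sample %s", sniffed, sample_id)
        if count == 0:
            continue
        records.append((sample_id, key, count))
    return records


def write_classifier_report(
    records: Iterable[tuple[str, str, int]], stream: IO[str], sep: str = "\t"
) -> None:
    """Serialize (sample, taxon_key, count) records back to report lines."""
    for _sample, key, count in records:
        stream.write(f"{key}{sep}{count}\n")


# ---------------------------------------------------------------------------
# Lineage handling
# ---------------------------------------------------------------------------

def parse_lineage_string(s: str) -> LineageRecord:
    """Parse a ``sk:...;p:...;...`` lineage string.

    The domain comes from the ``sk:`` token; an empty string, a missing or
    unrecognized superkingdom yields :attr:`Domain.UNRESOLVED`.  Tokens
    without a ``:`` (or with an unknown rank code) flag the record as
    incomplete without discarding the parseable ranks.
    """
    s = s.strip()
    if not s:
        return LineageRecord(query_name=s, ranks=(), domain=Domain.UNRESOLVED,
                             incomplete=True)
    ranks: list[tuple[str, str]] = []
    incomplete = False
    for token in s.split(";"):
        token = token.strip()
        if not token:
            continue
        if ":" not in token:
            incomplete = True
            continue
        code, name = token.split(":", 1)
        code, name = code.strip(), name.strip()
        if code not in RANK_CODES or not name:
            incomplete = True
            continue
        ranks.append((code, name))
    sk = next((name for code, name in ranks if code == "sk"), None)
    domain = _SK_TO_DOMAIN.get(sk.lower(), Domain.UNRESOLVED) if sk else Domain.UNRESOLVED
    return LineageRecord(query_name=s, ranks=tuple(ranks), domain=domain,
                         incomplete=incomplete)


def looks_like_lineage(taxon_key: str) -> bool:
    return ":" in taxon_key and (
        ";" in taxon_key or taxon_key.split(":", 1)[0].strip() in RANK_CODES
    )


def resolve_domain(taxon_key: str, lineage_map: Mapping[str, str]) -> Domain:
    """Resolve the taxonomic domain of a classifier taxon key.

    Keys that are themselves lineage strings are parsed directly; bare
    names are looked up in the offline name->lineage map.  Map misses and
    incomplete lineages resolve to UNRESOLVED — they are data, not errors.
    """
    if looks_like_lineage(taxon_key):
        rec = parse_lineage_string(taxon_key)
    else:
        lineage = lineage_map.get(taxon_key)
        if lineage is None:
            return Domain.UNRESOLVED
        rec = parse_lineage_string(lineage)
    if rec.incomplete:
        return Domain.UNRESOLVED
    return rec.domain


def read_lineage_map(path: str | Path) -> dict[str, str]:
    """Read a two-column (name, lineage string) TSV into a dict."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ParseError(
                    f"{path}: line {lineno}: expected 2 columns, got {len(parts)}"
                )
            out[parts[0].strip()] = parts[1].strip()
    return out


def write_lineage_map(lineage_map: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in lineage_map:
            fh.write(f"{name}\t{lineage_map[name]}\n")


# ---------------------------------------------------------------------------
# Table construction and algebra
# ---------------------------------------------------------------------------

def merge_counts(records: Iterable[tuple[str, str, int]]) -> FeatureTable:
    """Merge (sample, taxon_key, count) records into one feature table.

    One column per sample, one row per distinct taxon key; absent
    combinations are zero.  Duplicate (sample, taxon) records are summed
    with a log message — classifier reports can repeat a name across rank
    collapses.  The grand total of the table equals the record total.
    """
    cells: dict[tuple[str, str], int] = {}
    sample_order: list[str] = []
    taxon_order: list[str] = []
    n_dups = 0
    for sample_id, taxon_key, count in records:
        key = (taxon_key, sample_id)
        if key in cells:
            n_dups += 1
            cells[key] += int(count)
        else:
            cells[key] = int(count)
            if sample_id not in sample_order:
                sample_order.append(sample_id)
            if taxon_key not in taxon_order:
                taxon_order.append(taxon_key)
    if n_dups:
        logger.warning("merge_counts: summed %d duplicate (sample, taxon) records", n_dups)
    # preserve first-seen sample order; deterministic taxon row order
    data = np.zeros((len(taxon_order), len(sample_order)), dtype=np.int64)
    t_idx = {t: i for i, t in enumerate(taxon_order)}
    s_idx = {s: j for j, s in enumerate(sample_order)}
    for (taxon, sample), count in cells.items():
        data[t_idx[taxon], s_idx[sample]] = count
    return FeatureTable(pd.DataFrame(data, index=taxon_order, columns=sample_order))


def split_by_domain(
    table: FeatureTable, lineage_map: Mapping[str, str]
) -> dict[Domain, FeatureTable]:
    """Partition taxon rows into per-domain tables plus an unresolved bucket.

    Every row lands in exactly one bucket, so per-sample counts summed
    across all buckets reproduce the combined table.  The unresolved bucket
    holds incomplete/unknown lineages and is excluded from analysis.
    """
    assignment = {
        taxon: resolve_domain(taxon, lineage_map) for taxon in table.taxon_ids
    }
    out: dict[Domain, FeatureTable] = {}
    for domain in Domain:
        rows = [t for t in table.taxon_ids if assignment[t] is domain]
        out[domain] = FeatureTable(table.data.loc[rows])
    return out


def filter_min_depth(
    table: FeatureTable, depth: int = DEFAULT_MIN_DEPTH
) -> tuple[FeatureTable, list[str]]:
    """Drop samples whose total count is below ``depth``.

    Returns the filtered table and the removed sample ids so the caller can
    synchronize removals across related (e.g. per-domain) tables.
    """
    sums = table.sample_sums()
    removed = [s for s in table.sample_ids if sums[s] < depth]
    kept = [s for s in table.sample_ids if sums[s] >= depth]
    if removed:
        logger.info("filter_min_depth: removed %d samples below depth %d: %s",
                    len(removed), depth, removed)
    return FeatureTable(table.data.loc[:, kept]), removed


def _substream_seed(seed: int, label: str) -> int:
    """Stable per-label RNG substream seed (independent of sample order)."""
    h = blake2b(f"{seed}:{label}".encode(), digest_size=8).digest()
    return int.from_bytes(h, "big") % (2**31)


def rarefy(
    table: FeatureTable,
    depth: int = DEFAULT_RAREFACTION_DEPTH,
    seed: int = 0,
) -> FeatureTable:
    """Subsample every sample to exactly ``depth`` reads without replacement.

    Each sample uses its own RNG substream derived from (seed, sample_id),
    so results do not depend on column order.  Samples below ``depth``
    raise an error — run :func:`filter_min_depth` first.
    """
    data = table.data.copy()
    for sample in table.sample_ids:
        col = data[sample].to_numpy()
        total = int(col.sum())
        if total < depth:
            raise MetatrackerError(
                f"sample {sample!r} has depth {total} < rarefaction depth {depth}"
            )
        if total == depth:
            continue
        rng = np.random.default_rng(_substream_seed(seed, sample))
        data[sample] = rng.multivariate_hypergeometric(col, depth)
    return FeatureTable(data)


def collapse_by_env(table: FeatureTable, metadata: pd.DataFrame) -> pd.DataFrame:
    """Sum source samples of the same environment into source profiles.

    Returns a taxa x environments DataFrame of counts.  Sink samples are
    excluded; environment columns are ordered lexicographically.
    """
    sources = metadata[metadata["role"] == "source"]
    envs = sorted(sources["env"].unique())
    cols = {}
    for env in envs:
        sample_ids = [s for s in sources.index[sources["env"] == env]
                      if s in table.data.columns]
        cols[env] = table.data.loc[:, sample_ids].sum(axis=1)
    out = pd.DataFrame(cols, index=table.data.index, dtype=np.int64)
    out.index.name = "taxon_id"
    return out


# ---------------------------------------------------------------------------
# File I/O: mapping files and feature tables
# ---------------------------------------------------------------------------

def read_mapping(path: str | Path) -> pd.DataFrame:
    """Read a sample-metadata mapping TSV (SampleID, Env, SourceSink).

    Returns a DataFrame indexed by sample id with columns ``env`` and
    ``role`` (``"source"``/``"sink"``, parsed case-insensitively).  Any
    other SourceSink value is an error.
    """
    path = Path(path)
    if not path.exists():
        raise MetatrackerError(f"mapping file not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str, comment=None)
    cols = {c.lower().lstrip("#"): c for c in df.columns}
    required = {"sampleid": "SampleID", "env": "Env", "sourcesink": "SourceSink"}
    missing = [orig for key, orig in required.items() if key not in cols]
    if missing:
        raise ParseError(f"{path}: missing mapping columns: {missing}")
    out = pd.DataFrame(
        {
            "env": df[cols["env"]].str.strip().to_numpy(),
            "role": df[cols["sourcesink"]].str.strip().str.lower().to_numpy(),
        },
        index=pd.Index(df[cols["sampleid"]].str.strip().to_numpy()),
    )
    out.index.name = "sample_id"
    if out.index.has_duplicates:
        dups = out.index[out.index.duplicated()].unique().tolist()
        raise ParseError(f"{path}: duplicate sample ids: {dups}")
    bad = out.loc[~out["role"].isin(["source", "sink"]), "role"]
    if len(bad):
        raise ParseError(
            f"{path}: invalid SourceSink value(s) {sorted(bad.unique())}; "
            "expected 'source' or 'sink'"
        )
    return out


def write_mapping(metadata: pd.DataFrame, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "SampleID": metadata.index,
            "Env": metadata["env"].to_numpy(),
            "SourceSink": metadata["role"].to_numpy(),
        }
    )
    df.to_csv(path, sep="\t", index=False)


def align_mapping(
    table: FeatureTable, metadata: pd.DataFrame
) -> tuple[pd.DataFrame, list[str]]:
    """Restrict metadata to samples present in the table.

    Mapping samples absent from the table are returned (and logged) rather
    than raised — the caller decides whether that is fatal.
    """
    missing = [s for s in metadata.index if s not in table.data.columns]
    if missing:
        logger.warning("mapping samples absent from table: %s", missing)
    kept = metadata.loc[[s for s in metadata.index if s in table.data.columns]]
    return kept, missing


def read_feature_table(path: str | Path, format: str | None = None) -> FeatureTable:
    """Read a feature table from TSV or BIOM 2.1 HDF5 (by extension)."""
    path = Path(path)
    if not path.exists():
        raise MetatrackerError(f"feature table not found: {path}")
    fmt = format or ("biom" if path.suffix == ".biom" else "tsv")
    if fmt == "biom":
        from ._biom import read_biom

        return read_biom(path)
    if fmt == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return FeatureTable(df)
    raise MetatrackerError(f"unknown feature-table format: {fmt!r}")


def write_feature_table(
    table: FeatureTable, path: str | Path, format: str | None = None
) -> None:
    """Write a feature table as TSV (taxa rows x sample columns) or BIOM."""
    path = Path(path)
    fmt = format or ("biom" if path.suffix == ".biom" else "tsv")
    if fmt == "biom":
        from ._biom import write_biom

        write_biom(table, path)
    elif fmt == "tsv":
        table.data.to_csv(path, sep="\t")
    else:
        raise MetatrackerError(f"unknown feature-table format: {fmt!r}")
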