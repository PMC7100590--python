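"""Cross-chain convergence diagnostics for source-proportion estimates.

Each Gibbs chain yields a moving average (cumulative mean) of its per-draw
source proportions.  For every (sink, environment) pair this module
computes the spread — the absolute difference between the chains with the
maximum and minimum final moving averages — and flags pairs whose spread
exceeds a threshold (default 5%).  Flagged pairs can be exported as line
graphs with one line per chain and the chains' final estimates in the
legend; a text table of all spreads is always produced.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import MetatrackerError
from .gibbs import ChainTrace

DEFAULT_THRESHOLD = 0.05


def moving_average(per_draw_values: np.ndarray) -> np.ndarray:
    """Cumulative mean: out[d] = mean(values[:d+1]); same length as input."""
    x = np.asarray(per_draw_values, dtype=np.float64)
    n = np.arange(1, x.shape[0] + 1)
    if x.ndim == 1:
        return np.cumsum(x) / n
    return np.cumsum(x, axis=0) / n[:, None]


def chain_spread(final_values_per_chain: np.ndarray) -> np.ndarray:
    """Max - min of the chains' final moving averages, per environment."""
    x = np.atleast_2d(np.asarray(final_values_per_chain, dtype=np.float64))
    return x.max(axis=0) - x.min(axis=0)


@dataclass(frozen=True)
class DiagnosticsReport:
    """Spread table over all (sink, environment) pairs.

    ``table`` has one row per pair with per-chain final proportions,
    the spread, and the flag (spread strictly greater than ``threshold``).
    """

    table: pd.DataFrame
    threshold: float
    plot_paths: tuple[Path, ...] = ()

    @property
    def n_flagged(self) -> int:
        return int(self.table["flagged"].sum())

    def to_tsv(self, path: str | Path) -> None:
        """Write the text table; spread printed as percent, 4 decimals."""
        out = self.table.copy()
        out["spread_percent"] = (out.pop("spread") * 100).map(lambda v: f"{v:.4f}")
        out.to_csv(path, sep="\t", index=False, float_format="%.6f")


def diagnose(
    traces: Mapping[str, Sequence[ChainTrace]],
    threshold: float = DEFAULT_THRESHOLD,
    plot_dir: str | Path | None = None,
) -> DiagnosticsReport:
    """Build the spread report (and optionally plots) from chain traces.

    ``traces`` maps sink id -> list of chains for that sink.  Chains of a
    sink must have equal recorded lengths (anything else indicates a
    misconfigured run).  When ``plot_dir`` is given, every flagged
    (sink, env) pair gets one line graph with each chain's moving-average
    trace and the final estimates in the legend.
    """
    if threshold < 0:
        raise MetatrackerError("threshold must be >= 0")
    rows = []
    flagged_pairs: list[tuple[str, str]] = []
    trace_lookup: dict[tuple[str, str], list[tuple[int, np.ndarray]]] = {}
    for sink_id in traces:
        chain_traces = list(traces[sink_id])
        if not chain_traces:
            continue
        lengths = {t.draws.shape[0] for t in chain_traces}
        if len(lengths) != 1:
            raise MetatrackerError(
                f"sink {sink_id!r}: chains have unequal recorded lengths {sorted(lengths)}"
            )
        envs = chain_traces[0].envs
        if any(t.envs != envs for t in chain_traces):
            raise MetatrackerError(f"sink {sink_id!r}: chains disagree on environments")
        finals = np.vstack([t.final for t in chain_traces])
        spreads = chain_spread(finals)
        for e, env in enumerate(envs):
            flagged = bool(spreads[e] > threshold)
            row = {"sink_id": sink_id, "env": env}
            # chain columns in trace order regardless of chain_index labels
            for k, t in enumerate(chain_traces):
                row[f"chain_{k + 1}"] = finals[k, e]
            row["spread"] = spreads[e]
            row["flagged"] = flagged
            rows.append(row)
            if flagged:
                flagged_pairs.append((sink_id, env))
                trace_lookup[(sink_id, env)] = [
                    (k, t.cum_mean[:, e]) for k, t in enumerate(chain_traces)
                ]
    table = pd.DataFrame(rows)
    plot_paths: list[Path] = []
    if plot_dir is not None:
        plot_dir = Path(plot_dir)
        plot_dir.mkdir(parents=True, exist_ok=True)
        for sink_id, env in flagged_pairs:
            plot_paths.append(
                _plot_pair(sink_id, env, trace_lookup[(sink_id, env)], plot_dir)
            )
    return DiagnosticsReport(table=table, threshold=threshold,
                             plot_paths=tuple(plot_paths))


def _plot_pair(
    sink_id: str, env: str,
    chain_curves: Sequence[tuple[int, np.ndarray]],
    plot_dir: Path,
) -> Path:
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for k, curve in chain_curves:
        ax.plot(np.arange(1, curve.shape[0] + 1), curve,
                label=f"chain {k + 1}: {curve[-1]:.4f}")
    ax.set_xlabel("draw")
    ax.set_ylabel("moving-average proportion")
    ax.set_title(f"{sink_id} / {env}")
    ax.legend(title="final estimate", fontsize=8)
    path = plot_dir / f"{sink_id}__{env}.png"
    fig.savefig(path, dpi=100)
    plt.close(fig)
    return path
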