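"""Check Markov-chain convergence: 10 draws vs 100 draws.

Each chain's estimate is the cumulative mean of its per-draw
proportions; the diagnostic is the max-min spread of the five chains'
final estimates per (sink, environment), flagged when above 5%.
"""

import numpy as np

from metatracker.diagnostics import diagnose
from metatracker.gibbs import GibbsConfig, run_all
from metatracker.synthdata import generate_study

study = generate_study("coastal-small", seed=7)

for draws in (10, 100):
    config = GibbsConfig(draws=draws, seed=7)
    _, traces, _ = run_all(study.table, study.metadata, config)
    report = diagnose(traces, threshold=0.05, plot_dir="scratch/diag_plots"
                      if draws == 10 else None)
    spread = report.table["spread"]
    print(f"draws={draws:>3}: mean spread {spread.mean() * 100:.2f}%, "
          f"max {spread.max() * 100:.2f}%, "
          f"{report.n_flagged}/{len(report.table)} pairs flagged (>5%)")

print("\nIncreasing draws from 10 to 100 shrinks the disagreement between "
      "independently initialized chains - the moving averages converge. "
      "Flagged pairs (if any) get one line-graph per (sink, environment) "
      "with each chain's final estimate in the legend.")
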