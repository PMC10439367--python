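#!/usr/bin/env python
"""Posterior parameter estimation under the winning ghost scenario.

Reuses the pseudo-observed dataset of 02_model_selection.py and the
single-scenario slice of the ghost reference table; tunes the forest on
a small grid, then estimates every free parameter with quantile
regression forests.  Writes results/posterior_estimates.csv with the
columns (parameter, mean, median, q2.5, q97.5, nmae).
"""

import json
from pathlib import Path

from ghostflow import (ReferenceTable, SampleConfig, ScenarioParams,
                       compute_sumstats, estimate_parameters, simulate_snps,
                       tune_forest)

RESULTS = Path(__file__).resolve().parent.parent / "results"

GHGEA_MEDIANS = dict(
    N_A=2228, N_B=2505, N_aA=10318, N_aB=11436, N_anc=2.62, N_ghost=10318,
    m_A=1.03e-3, m_B=1.12e-3, m_G=4.6e-4, m_AG=2.4e-4,
    T_m=4252, T_div=301_759, T_divG=411_780, T_G=8249)


def main():
    choice = json.loads((RESULTS / "model_choice.json").read_text())
    best = choice["ghost"]["best"]
    print(f"estimating parameters under the winning scenario: {best}")
    ref = ReferenceTable.load(RESULTS / "ref_ghost.csv").subset_scenario(best)

    params = ScenarioParams(scenario="GhGeA", **GHGEA_MEDIANS)
    gm = simulate_snps(params, SampleConfig(), seed=777, design="ddrad")
    observed = compute_sumstats(gm, "TaiA", "TaiB")

    node_size, mtry = tune_forest(ref, [5, 20, 50], [4, 7], n_trees=100,
                                  seed=3, parameter="T_divG")
    print(f"tuned forest: node_size={node_size}, mtry={mtry}")
    est = estimate_parameters(ref, observed, n_trees=500,
                              node_size=node_size, mtry=mtry, seed=3)
    est.table.to_csv(RESULTS / "posterior_estimates.csv")
    print(est.table.round(4).to_string())
    print(f"wrote {RESULTS / 'posterior_estimates.csv'}")


if __name__ == "__main__":
    main()
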