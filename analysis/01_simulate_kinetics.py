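#!/usr/bin/env python
"""Simulate a wild-type-style stopped-flow titration and extract k_obs.

Generates fluorescence traces for 1 uM probe titrated with 1-12 uM partner
(true k_on = 21.3 uM^-1 s^-1, k_off = 2.2 s^-1, 1% amplitude noise), fits
each trace to a single exponential, and writes the observed-rate table to
results/kobs_table.csv.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

import tsphi as T

ap = argparse.ArgumentParser()
ap.add_argument("--seed", type=int, default=1)
args = ap.parse_args()

scn = T.KineticsScenario(kon=21.3, koff=2.2, noise_sigma=0.01, seed=args.seed)
traces, truth = T.gen_traces(scn)

rows = []
for tr in traces:
    fit = T.fit_trace(tr, n_phases=1)
    rows.append({"conc_uM": tr.meta["conc_uM"],
                 "kobs": fit.kobs,
                 "kobs_err": fit.rate_errors[0],
                 "kobs_true": tr.meta["kobs_true"],
                 "converged": fit.converged})
df = pd.DataFrame(rows)

out = Path(__file__).resolve().parents[1] / "results"
out.mkdir(exist_ok=True)
df.to_csv(out / "kobs_table.csv", index=False)

err = np.abs(df.kobs - df.kobs_true) / df.kobs_true
print(f"fitted {len(df)} traces (true k_on {scn.kon}, k_off {scn.koff}); "
      f"max |k_obs error| {100 * err.max():.2f}% -> results/kobs_table.csv")
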