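#!/usr/bin/env python
"""Fit the k_obs-vs-concentration curve for k_on and k_off.

Reads results/kobs_table.csv (from 01_simulate_kinetics.py) and fits the
reversible bimolecular binding expression; writes results/rate_fits.json.
"""

import json
from pathlib import Path

import pandas as pd

import tsphi as T

root = Path(__file__).resolve().parents[1]
df = pd.read_csv(root / "results" / "kobs_table.csv")

obs = T.ObservedRates(df.conc_uM.values, df.kobs.values, df.kobs_err.values)
kon, koff, se_on, se_off = T.fit_binding_curve(obs, probe_uM=1.0)

result = {"kon_uM_s": kon, "kon_se": se_on,
          "koff_s": koff, "koff_se": se_off,
          "kd_nM": T.kd_nM(kon, koff)}
(root / "results" / "rate_fits.json").write_text(json.dumps(result, indent=2))
print(f"k_on = {kon:.2f} +- {se_on:.2f} uM^-1 s^-1, "
      f"k_off = {koff:.2f} +- {se_off:.2f} s^-1, "
      f"K_d = {T.kd_nM(kon, koff):.0f} nM -> results/rate_fits.json")
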