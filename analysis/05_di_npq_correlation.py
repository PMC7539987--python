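#!/usr/bin/env python
"""Correlation of NPQ components with xanthophyll-cycle activation.

Sweeps actinic irradiance from 200 to 2500 µmol m⁻² s⁻¹ with the
continuous NPQ protocol, tabulates end-of-light DI, zeaxanthin, NPQ and
its qE / qI(qZ) split, and fits the saturating exponential
y = y_max (1 − e^(−rate·DI)) per component.  Writes
results/di_npq_sweep.tsv and results/di_npq_fits.tsv.
"""

from pathlib import Path

import pandas as pd

from xcquench import correlate, io, kinetics

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

model = kinetics.default_model("chlorella", "in_vivo")
table = correlate.sweep_irradiance(model)
io.write_table(table, OUT / "di_npq_sweep.tsv",
               {"protocol": "25 min light / 10 min dark", "x": "end-of-light DI"})
print(table.to_string(index=False, float_format=lambda v: f"{v:.3f}"))

fits = correlate.fit_components(table)
fit_table = pd.DataFrame([
    {"component": k, "y_max": f.y_max, "rate_per_di": f.rate, "rmse": f.rmse}
    for k, f in fits.items()])
io.write_table(fit_table, OUT / "di_npq_fits.tsv",
               {"model": "y = y_max * (1 - exp(-rate * DI))"})
for k, f in fits.items():
    print(f"{k}: y_max = {f.y_max:.2f}, rate = {f.rate:.2f} per DI unit")
assert fits["qE"].rate > fits["NPQ"].rate > fits["qI/qZ"].rate
print("qE saturates at the lowest DI (highest rate); the slow component "
      "tracks zeaxanthin almost linearly (lowest rate).")
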