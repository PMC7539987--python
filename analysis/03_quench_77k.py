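#!/usr/bin/env python
"""Photosystem-resolved quenching from 77 K emission spectra.

Generates dark-adapted and high-light-treated spectra (GFP internal
standard, PSII bands at 686/698 nm, PSI at 720 nm) for control and
DTT-treated samples — light-treated band areas are attenuated according to
the in-vivo simulation of a 6-min 2000 µmol m⁻² s⁻¹ exposure — then
deconvolves and computes (A_dark − A_light)/A_light per photosystem.
Writes results/quench77k.tsv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from xcquench import io, kinetics, spectra77k, synthetic
from xcquench.types import LightSchedule, NoiseSpec, PigmentProfile, Segment

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

DARK_AREAS = {"standard": 1.0, "psii_686": 2.0, "psii_698": 1.5,
              "psi_720": 2.5, "vibronic": 0.8}
# PSI quenching engages more weakly than PSII quenching per unit NPQ
PSI_COUPLING = 0.45

model = kinetics.default_model("chlorella", "in_vivo")
rows = []
for dtt in (False, True):
    sched = LightSchedule(segments=(Segment(60.0, 0.0, dtt), Segment(360.0, 2000.0, dtt)))
    sim = kinetics.simulate_in_vivo(model, sched, PigmentProfile(vio=3.0, ant=0, zea=0))
    npq_end = float(sim.npq_total[-1])
    light_areas = dict(
        DARK_AREAS,
        psii_686=DARK_AREAS["psii_686"] / (1 + npq_end),
        psii_698=DARK_AREAS["psii_698"] / (1 + npq_end),
        psi_720=DARK_AREAS["psi_720"] / (1 + PSI_COUPLING * npq_end),
    )
    fits = {}
    for cond, areas, seed in (("dark", DARK_AREAS, 1), ("light", light_areas, 2)):
        s = synthetic.gen_spectrum77k(areas, NoiseSpec(seed=seed),
                                      condition=f"{cond}/{'dtt' if dtt else 'no_dtt'}")
        fits[cond] = spectra77k.fit_gaussians(spectra77k.normalize_to_standard(s))
    q = spectra77k.ps_quenching(fits["dark"], fits["light"])
    rows.append({"condition": "dtt" if dtt else "control",
                 "npq_after_6min": npq_end, "psii_q": q.psii_q, "psi_q": q.psi_q})
    print(f"{'DTT' if dtt else 'control'}: 6-min NPQ = {npq_end:.2f} -> "
          f"PSII quenching = {q.psii_q:.2f}, PSI quenching = {q.psi_q:.2f}")

table = pd.DataFrame(rows)
io.write_table(table, OUT / "quench77k.tsv",
               {"formula": "(A_dark - A_light)/A_light", "exposure": "6 min @ 2000"})
assert table.loc[1, "psii_q"] < table.loc[0, "psii_q"]
assert table.loc[1, "psi_q"] < table.loc[0, "psi_q"]
print("VDE inhibition weakens quenching of both photosystems.")
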