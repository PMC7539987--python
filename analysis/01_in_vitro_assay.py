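#!/usr/bin/env python
"""In-vitro violaxanthin de-epoxidase characterization.

Tabulates the normalized pH-activity profiles of the A. thaliana and
C. vulgaris enzymes, runs the 60-min reconstituted assay (0.33 µM
violaxanthin, pH 5.1) with and without the inhibitor DTT, and derives the
normalized A505−A540 absorption readout from the simulated kinetics.
Writes results/in_vitro_*.tsv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from xcquench import io, kinetics, pigments, synthetic
from xcquench.types import NoiseSpec

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

grid = np.round(np.arange(4.0, 7.5 + 1e-9, 0.1), 10)
profiles = {"arabidopsis": kinetics.ARABIDOPSIS_PH, "chlorella": kinetics.CHLORELLA_PH}
ph_table = pd.DataFrame({"ph": grid})
for name, prof in profiles.items():
    ph_table[f"activity_{name}"] = kinetics.ph_activity(grid, prof)
io.write_table(ph_table, OUT / "in_vitro_ph_activity.tsv",
               {"note": "normalized VDE activity, 1.0 at the optimum"})
for name in profiles:
    act = ph_table[f"activity_{name}"].to_numpy()
    print(f"{name}: pH optimum {grid[np.argmax(act)]:.1f}, "
          f"activity at pH 7.0 = {act[np.searchsorted(grid, 7.0)]:.2f}")

rows = []
for species in ("arabidopsis", "chlorella"):
    model = kinetics.default_model(species, "in_vitro")
    for dtt in (False, True):
        sim = kinetics.simulate_in_vitro(model, ph=5.1, vio0=0.33, t_end=60.0, dtt=dtt)
        rows.append({"species": species, "dtt": dtt,
                     "conversion_pct": 100.0 * sim.conversion,
                     "di_end": float(sim.di[-1]) if not dtt else 0.0})
        print(f"{species} (DTT={dtt}): {100 * sim.conversion:.1f}% of violaxanthin "
              f"converted after 60 min at pH 5.1")
io.write_table(pd.DataFrame(rows), OUT / "in_vitro_conversion.tsv",
               {"assay": "0.33 uM violaxanthin, 60 min, pH 5.1"})

# spectrophotometric readout of the C. vulgaris assay
sim = kinetics.simulate_in_vitro(kinetics.default_model("chlorella"), 5.1, 0.33, 60.0)
t, wl, ab = synthetic.gen_assay_series(sim, NoiseSpec(seed=0))
ak = pigments.assay_readout(t, wl, ab)
io.write_table(pd.DataFrame({"time_min": ak.time, "a505": ak.a505, "a540": ak.a540,
                             "delta_norm": ak.delta_norm}),
               OUT / "in_vitro_assay_readout.tsv",
               {"note": "(A505 - A540) normalized to its maximum"})
print(f"A505-A540 readout rises to 1.0 by t = {ak.time[np.argmax(ak.delta_norm)]:.0f} min, "
      f"tracking zeaxanthin formation")
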