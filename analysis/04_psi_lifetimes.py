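#!/usr/bin/env python
"""Fluorescence lifetimes of PSI with and without bound zeaxanthin.

Generates streak-camera-style decays (Gaussian IRF, FWHM 30 ps, 10⁴ peak
counts, Poisson noise) from the two shipped PSI parameter sets, fits each
with a two-exponential reconvolution model, and reports amplitude- and
intensity-weighted average lifetimes.  Writes results/psi_lifetimes.tsv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from xcquench import decay, io, synthetic
from xcquench.types import NoiseSpec

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)
N_SEEDS = 50

rows = []
for name, params in (("psi_zea_free", decay.PSI_ZEA_FREE),
                     ("psi_zea_bound", decay.PSI_ZEA_BOUND)):
    amp, inten = [], []
    for seed in range(N_SEEDS):
        trace = synthetic.gen_decay(params["lifetimes"], params["amplitudes"],
                                    noise=NoiseSpec(seed=seed))
        fit = decay.fit_decay(trace, 2)
        amp.append(fit.tau_avg)
        inten.append(fit.tau_avg_intensity)
    rows.append({"sample": name,
                 "tau_true_ps": float(np.dot(params["lifetimes"], params["amplitudes"])),
                 "tau_amp_median_ps": float(np.median(amp)),
                 "tau_amp_iqr_ps": float(np.subtract(*np.percentile(amp, [75, 25]))),
                 "tau_intensity_median_ps": float(np.median(inten)),
                 "n_seeds": N_SEEDS})
    print(f"{name}: median amplitude-weighted lifetime "
          f"{np.median(amp):.1f} ps (truth {rows[-1]['tau_true_ps']:.0f} ps), "
          f"intensity-weighted {np.median(inten):.1f} ps")

table = pd.DataFrame(rows)
io.write_table(table, OUT / "psi_lifetimes.tsv",
               {"irf_fwhm_ps": decay.IRF_FWHM_STREAK, "peak_counts": 10000})
drop = 1 - table.loc[1, "tau_amp_median_ps"] / table.loc[0, "tau_amp_median_ps"]
print(f"Zeaxanthin binding shortens the PSI lifetime by {100 * drop:.0f}%.")
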