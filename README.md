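# xcquench

Xanthophyll-cycle kinetics and photoprotective-quenching analysis for green
algae.

Photosynthetic organisms in excess light dissipate absorbed energy as heat
(non-photochemical quenching, NPQ). A central actor is the xanthophyll
cycle: at low lumen pH the enzyme violaxanthin de-epoxidase (VDE) converts
violaxanthin (Vio) to zeaxanthin (Zea) via antheraxanthin (Ant); zeaxanthin
in turn enables the fast (qE) and slowly relaxing (qZ) quenching
components. In the green alga *Chlorella vulgaris* this cycle is driven by
a plant-type, DTT-inhibitable VDE with a sharper alkaline pH cutoff than
the *Arabidopsis thaliana* enzyme, and zeaxanthin quenches both
photosystem II and photosystem I. `xcquench` packages that analysis as a
tested pipeline for people working on algal photoprotection: a mechanistic
ODE simulator of the cycle and its quenching couplings, analysis stages
for the four instrument modalities involved, and seeded synthetic
generators so every stage can be exercised end-to-end without instrument
data.

The core quantities, in the field's standard notation:

* de-epoxidation index DI = ([Zea] + ½[Ant]) / ([Zea] + [Ant] + [Vio])
* NPQ = (Fm − Fm′)/Fm′ from saturating-pulse (PAM) fluorometry, with
  Fv/Fm = (Fm − Fo)/Fm and the relaxation split into qE and qI/qZ
* 77 K photosystem quenching = (A_dark − A_light)/A_light over the PSII
  (686 + 698 nm) and PSI (720 nm) Gaussian band areas
* amplitude-weighted average lifetime τ_avg = Σ aᵢτᵢ from IRF-convolved
  multi-exponential decay fits
* the asymptotic correlation y = y_max(1 − e^(−rate·DI)) linking NPQ
  components to xanthophyll-cycle activation

See `docs/methods.md` for the model equations, default parameters and
their calibration.

## Layout

* `src/xcquench/` — the library: `kinetics` (cycle + quenching simulator),
  `pigments` (HPLC and the A505−A540 assay readout), `pam`, `spectra77k`,
  `decay`, `correlate`, `synthetic` (seeded generators), `io`, `cli`.
* `analysis/01_…05_….py` — numbered drivers reproducing the study's
  analyses on synthetic data; each writes tables under `results/`.
* `scripts/acceptance.py` — recomputes the headline calibration numbers.

## Worked example

Simulate the continuous high-light protocol (25 min at 2000 µmol m⁻² s⁻¹,
10 min dark recovery), synthesize a PAM trace from it, and analyze it back:

```python
import numpy as np
from xcquench import correlate, kinetics, pam, synthetic
from xcquench.types import NoiseSpec, PigmentProfile

model = kinetics.default_model("chlorella", "in_vivo")
schedule = correlate.npq_schedule(2000.0)
sim = kinetics.simulate_in_vivo(model, schedule, PigmentProfile(vio=3.0, ant=0, zea=0))

trace = synthetic.gen_pam_trace(sim, schedule, noise=NoiseSpec(seed=42))
res = pam.analyze_trace(trace)
i_end = np.searchsorted(sim.time, schedule.boundaries()[-2]) - 1
print(f"Fv/Fm = {res.fv_fm:.2f}, end-of-light DI = {sim.di[i_end]:.2f}, "
      f"NPQ = {res.npq[res.pulse_times < schedule.boundaries()[-2]][-1]:.2f}, "
      f"qE = {res.q_e:.2f}, qI/qZ = {res.q_islow:.2f}")
```

prints

```
Fv/Fm = 0.80, end-of-light DI = 0.49, NPQ = 3.88, qE = 2.36, qI/qZ = 1.52
```

i.e. dark-adapted cells with a healthy PSII yield (0.80) de-epoxidate about
half their violaxanthin pool in 25 min of strong light and build an NPQ of
~3.9, of which ~2.4 relaxes within the 10-min dark recovery (qE) and ~1.5
persists (qI/qZ). Running the same protocol with the VDE inhibitor DTT
(`correlate.npq_schedule(2000.0, inhibitor=True)`) yields no zeaxanthin and
an end-of-light NPQ of only 0.58 — the quenching is zeaxanthin-dependent.
The same pipeline is available from the shell:

```sh
xcquench generate --modality pam --seed 42 --out pam.tsv
xcquench npq pam.tsv pam.schedule.yaml --out npq.tsv
```

The numbered drivers cover the remaining analyses; for instance
`python analysis/04_psi_lifetimes.py` fits synthetic PSI decays and prints

```
psi_zea_free:  median amplitude-weighted lifetime 71.8 ps (truth 72 ps) ...
psi_zea_bound: median amplitude-weighted lifetime 48.9 ps (truth 49 ps) ...
Zeaxanthin binding shortens the PSI lifetime by 32%.
```

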