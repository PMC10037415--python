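# giet — graphene-induced energy transfer analysis

Graphene quenches a nearby fluorophore with a steep distance dependence:
within ~25 nm of a graphene sheet, near-field energy transfer shortens the
dye's fluorescence lifetime from its bulk value essentially to zero at
contact. Measuring a lifetime and inverting it through a calculated
lifetime-vs-distance calibration curve therefore localizes the dye along
the optical axis with sub-nanometre accuracy — GIET (graphene-induced
energy transfer) spectroscopy.

This package implements the complete GIET analysis chain used to measure
the thickness of supported lipid bilayers (SLBs) assembled on a
glass / graphene / 10 nm SiO₂ substrate, with both leaflets carrying a few
head-group-labelled lipids (Atto655):

* **`giet.optics`** — the electrodynamic forward model. The dye is treated
  as an ideal oscillating electric dipole at height *z* above the layered
  substrate; its normalized total decay rate is the classical
  wavevector-resolved reflection integral (CPS theory)

  $$S(z) = 1 + C_{\mathrm{ori}}\,\mathrm{Re}\!\int_0^\infty
  f_{\mathrm{ori}}(q)\; r(q)\, e^{2 i k z \sqrt{1-q^2}}\,\mathrm{d}q ,$$

  evaluated per wavelength, averaged over the emission spectrum, and
  converted to a lifetime via the dye's free-space photophysics,
  τ(z) = τ₀ / (1 − φ + φ·S̄(z)) with τ₀ = 2.6 ns and φ = 0.36 for Atto655.
* **`giet.calibration`** — calibration curves for dyes above / below an SLB
  slab (n = 1.46), monotone-branch inversion of lifetimes into heights, and
  the iterative solution of the implicit equation
  z_bottom = g_bottom(τ_short, d) with d = z_top − z_bottom.
* **`giet.tcspc`** — TCSPC decay histograms, splitting photon streams into
  bunches of 10⁶ photons, and Poisson maximum-likelihood biexponential fits
  (Gaussian IRF, constant background): τ_short ↔ bottom leaflet,
  τ_long ↔ top leaflet.
* **`giet.synthetic`** — ground-truth-tagged synthetic photon streams drawn
  from the forward model (the raw study data are not deposited), including
  a 3-lipid × 4-cholesterol-level scenario panel.
* **`giet.pipeline`** — per-bunch analysis, mean ± SD aggregation
  (bunch-to-bunch spread is the measurement error), result tables, and
  descriptive thickness-vs-cholesterol parabola fits.

Heights are measured from the graphene top surface; the water-accessible
range starts at the SiO₂ spacer surface, 10 nm above it.

## Worked example

```python
import numpy as np
from giet import (ScenarioDesign, StackSpec, ThicknessInverter, atto655,
                  IRFModel, simulate_measurement, bunch_photons, analyze_measurement)

emitter = atto655()                      # tau0 = 2.6 ns, phi = 0.36, horizontal dipole
stack = StackSpec()                      # glass / graphene / 10 nm SiO2 / water
irf = IRFModel(sigma_ns=0.1, shift_ns=2.0)

# a DOPC-like bilayer: bottom leaflet 11 nm above the graphene, 5.4 nm thick
design = ScenarioDesign(lipid_label="DOPC", true_z_bottom_nm=11.0,
                        true_thickness_nm=5.4, photons_per_bunch=1_000_000,
                        n_bunches=5, seed=7)
times, truth = simulate_measurement(design, emitter, irf, stack)
print(f"forward-model lifetimes: tau_short = {truth.tau_short_ns:.3f} ns, "
      f"tau_long = {truth.tau_long_ns:.3f} ns")

inverter = ThicknessInverter(emitter, stack)
est = analyze_measurement(bunch_photons(times, design.photons_per_bunch),
                          emitter, irf, inverter)
print(f"recovered thickness: {est.mean_d_nm:.2f} +/- {est.sd_d_nm:.2f} nm "
      f"over {est.n_bunches} bunches (truth: {design.true_thickness_nm} nm)")
```

prints

```
forward-model lifetimes: tau_short = 0.975 ns, tau_long = 1.817 ns
recovered thickness: 5.44 +/- 0.09 nm over 5 bunches (truth: 5.4 nm)
```

The two lifetimes are what a biexponential fit of the mixed decay must
disentangle: 0.975 ns for the strongly quenched bottom leaflet, 1.817 ns
for the top leaflet 5.4 nm further from the graphene. Each 10⁶-photon
bunch is fitted and inverted independently; the spread of the per-bunch
thicknesses (here 0.09 nm) is the measurement uncertainty.

A `giet` console command exposes the same stages
(`giet calibrate`, `giet fit`, `giet bunch`, `giet simulate`,
`giet thickness`, `giet trend`); see `giet --help`.

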