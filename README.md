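# beamtune

Computer-driven beam-model tuning for scanned proton and carbon-ion
delivery systems.

Commissioning a pencil-beam-scanning (PBS) beam line for dose calculation
means determining, per nominal accelerator energy, the parameters of the
treatment-planning source model: the mean beam energy *E*, the Gaussian
energy spread *σ<sub>E</sub>*, and for each transverse plane the phase-space
triple of beam width *σ* [mm], divergence *θ* [mrad] and emittance *ε*
[mm·mrad] (with *ε = π σ θ* at the beam waist).  Doing this by hand is slow
and expert-dependent.  `beamtune` automates it: a derivative-free simplex
optimizer iteratively matches forward-simulated observables to
commissioning measurements —

* **energy**: minimize (R80<sub>meas</sub> − R80<sub>sim</sub>(E))², where
  R80 is the distal 80 %-of-peak depth of a laterally integrated depth-dose
  curve (IDC) in water;
* **energy spread**: minimize (BPW80<sub>meas</sub> −
  BPW80<sub>sim</sub>(σ<sub>E</sub>))², the Bragg-peak width at 80 % of the
  maximum;
* **beam optics**: minimize Σ<sub>i</sub> (FWHM<sub>meas,i</sub> −
  FWHM<sub>sim,i</sub>(σ, θ, ε))² over spot sizes in air at several
  isocenter distances, plus a regularization term
  λ·[(σ<sub>j</sub>−σ<sub>j−1</sub>)² + (θ<sub>j</sub>−θ<sub>j−1</sub>)² +
  (ε<sub>j</sub>−ε<sub>j−1</sub>)²] (λ = 0.1) tying each energy to the
  preceding one; the lowest energy is not regularized.

The tuned parameters are then compiled into an energy-parametrized beam
model (4th–6th order polynomials in nominal energy per parameter, plus a
dose-scaling calibration factor) and evaluated against measurements in
terms of R80, BPW50/BPW80 and FWHM.

Instead of Monte Carlo particle transport, `beamtune` uses fast analytic
forward engines — a Bragg–Kleeman / Bortfeld-style pristine Bragg curve
with range straggling for the depth dose, and Fermi–Eyges moment transport
with Highland multiple-Coulomb-scattering in air for the lateral beam size
— so the whole pipeline runs in seconds and every stage can be validated by
parameter-recovery experiments on synthetic machines with known ground
truth.  The `beamtune.synthetic` module generates exactly the tables a
commissioning campaign produces (per-energy IDCs, spot-size records at
0/±100/±200 mm) from hidden smooth parameter curves, with configurable
measurement noise.

## Worked example

```python
from beamtune.synthetic import make_machine_truth, generate_measurements, NoiseConfig
from beamtune.tuning import tune_all, TuningConfig
from beamtune.model import build_beam_model, evaluate_model

truth = make_machine_truth("synchrotron-20", seed=1)          # 20 energies, 62-253 MeV
measurements = generate_measurements(truth, NoiseConfig(rng_seed=1001))
result = tune_all(measurements, TuningConfig())               # energy, spread, optics
model = build_beam_model(result, measurements.particle)       # polynomial beam model
report = evaluate_model(model, measurements, n_energies=5)
print(report.to_text())
```

prints

```
Beam model evaluation (simulation - measurement)
energies: 62.0, 112.3, 162.5, 202.7, 253.0 MeV

metric         avg       min       max       RMS     avg%     min%     max%
R80         0.0131    0.0023    0.0304    0.0169    0.009    0.001    0.012
BPW50      -0.0085   -0.1753    0.1198    0.1134   -0.090   -1.046    0.708
BPW80       0.0067   -0.0132    0.0271    0.0179   -0.130   -0.960    0.353
FWHM        0.0064   -0.1048    0.0803    0.0429    0.046   -0.923    0.612
```

Each row aggregates signed differences (simulation − measurement) at the
five evaluation energies: the compiled model reproduces the synthetic
measured ranges to ~0.01 mm on average and spot sizes to well under a
percent, despite 0.5 % dose noise per IDC bin and 0.05 mm noise per FWHM
record in the input.  Per-energy diagnostics are available too, e.g. the
lowest-energy spectrum fit here converges to E\* = 62.405 MeV with
|ΔR80| = 0.0009 mm.

The same pipeline is available from the shell:

```
beamtune run-all --preset synchrotron-20 --seed 1 --out run/
beamtune synth --preset cyclotron-27 --seed 3 --out ms/      # stage by stage
beamtune tune-energy --measurements ms/ --out run2/
...
```

Every run writes a reproducibility record (config, seeds, version); stages
enforce their order (energy before spread before optics before model
generation).

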