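# lpica — Linear Poisson ICA for MALDI-ToF mixture quantification

Quantifying how much of each of two biological materials (milk from two
species, two tissue types, …) is present in a mixed sample from its
MALDI-ToF mass spectrum is hard: spectra vary with matrix chemistry, laser
conditions and ionisation efficiency, and the classical approach — tracking
one informative peak normalised to a reference peak — discards most of the
signal. `lpica` implements an alternative built for counting data: the
spectrum histogram is modelled as a non-negative mixture of probability
mass functions under Poisson noise,

```
m_i = Σ_k Q_k · P(i|k),        h_i ~ Poisson(m_i)
```

where `P(i|k)` is the sub-spectrum (PMF over peak bins) of component `k`
and `Q_k` the ion events attributed to it. Components are learned from a
corpus of spectra by expectation–maximisation (a Poisson-compatible form of
ICA), the model order is chosen from the χ²/dof plateau, linear degeneracy
among components is removed by **MAX SEP** (maximal pairwise subtraction
keeping all probabilities non-negative), components are mapped to the two
classes and calibrated against known mixture proportions with per-component
efficiency weights, and every per-spectrum proportion estimate comes with a
propagated error from the observed Fisher information. Bland–Altman
diagnostics (residual variance vs expected intensity, fitted as
`Var = a·x^b`) verify the Poisson noise assumption — `b = 1` is the Poisson
signature and `a` the detector gain — and pull distributions
(`(estimate − truth)/predicted error`, ideally mean 0 and width 1) validate
the error theory. A peak-ratio benchmark is included for comparison.

Because the mixture studies this method targets are not publicly deposited,
the package ships a first-class synthetic-data module that emulates the
study design (11 proportions from 0 % to 100 % in 10 % steps, 8 replicate
depositions each, uncontrolled per-spectrum signal, contamination,
class-dependent detection efficiency, gain-scaled Poisson noise), so every
stage is testable end to end.

## Worked example

```python
from lpica import run_pipeline
summary = run_pipeline({"seed": 1, "restarts": 5}, "demo_out")
```

This simulates the default binary-mixture corpus (88 spectra, class B
detected at half the efficiency of class A, 5 % contamination), selects the
model order, applies MAX SEP, calibrates against the known proportions and
validates the noise model. The summary it printed:

```
K               2          # selected model order (χ²/dof 76.2 → 0.930 from K=1 to 2)
precision       0.0058     # 1σ of calibrated predictions vs truth (≈ ±0.6 %)
power_law       a=1.32, b=0.921 ± 0.017   # noise grows ∝ expected intensity: Poisson
pull            mean −0.022, std 0.881 (n=88)  # unbiased, errors honestly sized
best_peak_ratio precision 0.166           # best single peak: ±16.6 %
```

Reading it: the mixture model measures proportions to about ±0.6 % on this
corpus while the best single-peak calibration manages ±16.6 %; the
Bland–Altman exponent near 1 confirms Poisson-style noise; and the pull
width near 1 means the per-spectrum predicted errors match the deviations
actually observed against ground truth.

The same stages are available on the command line
(`lpica simulate | preprocess | train | maxsep | calibrate | predict |
peakratio | validate | run`) operating on plain CSV/JSON artefacts; raw
profile spectra can be read from mzML or two-column CSV and taken through
alignment, baseline correction, peak-bin detection and integration first.

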