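# plaquetime

Timestamping amyloid plaques from ¹⁵N isotopologue signatures in MALDI
mass spectrometry imaging, and linking plaque age to single-plaque gene
expression, amyloid structural maturity and radial synapse/dystrophy
profiles.

## The problem

In amyloidosis mouse models fed a ¹⁵N diet for a defined pulse (with an
optional unlabeled chase), the Aβ1-42 deposited in a plaque carries the
body-pool ¹⁵N enrichment prevailing while it grew. Each nitrogen atom of
the peptide (n_N = 55) is ¹⁵N with probability *q*, so the isotopologue
envelope of the [M+H]⁺ ion at m/z 4512.3 right-shifts by
Δm ≈ 55 · (q − q_nat) · 0.9970 Da and broadens with the binomial variance
55 · q(1 − q). Reading that signature off per-plaque ROI spectra yields a
**nitrogen index** — a relative plaque age — which can then be correlated
with anything else measured on the same plaque: spatial-transcriptomic
counts, luminescent conjugated oligothiophene (LCO) maturity ratios, or
radial immunostain profiles.

Two instrument modes, two estimators:

- **LP (linear positive, m/Δm = 1000)** — the envelope collapses into one
  broad peak. The index is the full width at half maximum of an
  asymmetric Gaussian, FWHM = √(2 ln 2)(σ_L + σ_R), fitted by bounded
  nonlinear least squares after asymmetric-least-squares (ALS) baseline
  correction; fits with R² ≤ 0.90 fail QC.
- **RP (reflector positive, m/Δm = 15000)** — the 1-Da isotopologue
  ladder is resolved. The index is the area ratio of the 4th to the 3rd
  isotopologue peak (1-based from the monoisotopic peak), integrated
  between local baseline intersections. The exact-convolution isotope
  model provides the theoretical ratio for any enrichment.

A first-class synthetic-data generator produces every pipeline input with
known ground truth: labeled spectrum cohorts under pulse-only /
pulse-chase designs, plaque-age-correlated negative-binomial count
matrices with planted genes, 32-channel hyperspectral LCO images, and
radial immunostain images.

## Worked example

```python
import numpy as np
from plaquetime.isotopes import (ABETA42_SEQUENCE, EnrichmentParams,
                                 composition_from_sequence, isotopologue_pattern,
                                 monoisotopic_mz, theoretical_peak_ratio)
from plaquetime.simulate import render_pattern_spectrum
from plaquetime.spectral import nitrogen_index_lp, nitrogen_index_rp
from plaquetime.stats import PowerSpec, min_n_power

comp = composition_from_sequence(ABETA42_SEQUENCE)
print(f"[M+H]+ monoisotopic m/z: {monoisotopic_mz(comp, 1):.1f}")
for q in (0.00364, 0.10, 0.20):
    pat = isotopologue_pattern(comp, EnrichmentParams(q=q), charge=1)
    lp = nitrogen_index_lp(render_pattern_spectrum(pat, "LP", snr=20.0, seed=0))
    rp = nitrogen_index_rp(render_pattern_spectrum(pat, "RP", snr=np.inf, seed=0))
    print(f"q={q:.3f}  LP FWHM={lp.value:.2f} Da  RP 4/3 ratio={rp.value:.3f}"
          f" (theory {theoretical_peak_ratio(pat, 4, 3):.3f})")
print("min n (d=2.5):", min_n_power(PowerSpec(2.5)),
      "  min n (d=1.5):", min_n_power(PowerSpec(1.5)))
```

prints

```
[M+H]+ monoisotopic m/z: 4512.3
q=0.004  LP FWHM=5.08 Da  RP 4/3 ratio=0.902 (theory 0.901)
q=0.100  LP FWHM=6.41 Da  RP 4/3 ratio=2.757 (theory 2.763)
q=0.200  LP FWHM=7.22 Da  RP 4/3 ratio=5.182 (theory 5.208)
min n (d=2.5): 3   min n (d=1.5): 5
```

The LP FWHM and the RP area ratio both increase with enrichment — more
¹⁵N, broader envelope, heavier isotopologue ladder. The noiseless RP
ratios track the exact-convolution theory to well under a percent, and
the power-analysis minima are the sample sizes needed to detect
standardized effects of 2.5 and 1.5 at α = 0.05 and power 0.8 with a
one-sample one-sided t test.

Downstream, `PlaqueAgeExpressionModel(counts, indices, design).fit()`
quantile-normalizes an AOI count matrix and correlates every gene with
the age axis (inverting the axis for pulse-only labeling, where older
plaques carry *less* label), `plaquetime.unmixing` classifies plaques
into Aβ+h+q+ / Aβ+h+q− / Aβ+h−q− from non-negative unmixing of the two
LCO reference spectra, and `plaquetime.rings` quantifies marker
intensities in 10-µm concentric shells with contested pixels between
neighbouring plaques removed.

The whole workflow is scriptable through the `plaquetime` CLI
(`simulate | nitrogen-index | correlate | unmix | classify | rings |
power | run`).

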