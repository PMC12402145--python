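# Methods

## Isotopologue model

A peptide's elemental composition is the residue-formula sum plus one
water for free termini; for Aβ1-42 (42 residues,
DAEFRHDSGYEVHHQKLVFFAEDVGSNKGAIIGLMVGGVVIA) this is C₂₀₃H₃₁₁N₅₅O₆₀S₁ with
55 nitrogens and a protonated monoisotopic m/z of 4512.28. Under
metabolic ¹⁵N labeling each nitrogen is ¹⁵N with probability *q*
(independently), while C, H, O and S stay at natural abundance
(¹³C 0.0107, ²H 0.000115, ¹⁷O 0.00038, ¹⁸O 0.00205, ³³S 0.0075,
³⁴S 0.0429, ³⁶S 0.0001; ¹⁵N natural 0.00364).

The theoretical pattern is computed exactly by convolving per-element
isotope distributions over all atoms (binary exponentiation of the
single-atom polynomial), tracking per-bin probability and mean exact
mass. Bins are **nominal-mass aggregates**: the ¹³C/¹⁵N fine structure is
0.0063 Da apart — unresolvable at m/Δm = 15000 — so substitutions with
the same nominal shift share a bin whose centroid is the
abundance-weighted mean mass. Atomic masses: ¹⁴N 14.0030740,
¹⁵N 15.0001089, proton 1.007276; IUPAC monoisotopic masses elsewhere.
Bins below 10⁻¹⁰ relative abundance are pruned and the rest renormalized
(configurable). An exhaustive multinomial enumerator
(`enumerate_pattern_bruteforce`) serves as an independent oracle on small
molecules; the two agree bin-by-bin to < 10⁻¹⁰.

Isotopologue indices are **1-based from the monoisotopic bin**. The
alternative convention (counting from the first detectable peak in noisy
data) was considered and rejected as the default because it makes the
measured ratio incomparable with the theoretical `theoretical_peak_ratio`
at unknown enrichment; the ladder anchor in the RP estimator tolerates a
missing monoisotopic peak regardless (see below).

## LP nitrogen index

Pipeline: TIC normalization → ALS baseline → local-maxima peak picking
(strict neighbour comparison; plateau ties to the lowest index) → main
peak by maximum intensity (ties to lowest m/z) → symmetric fitting window
(default half-width 3× the instrument FWHM, m/RP at the peak) → bounded
NLS fit of a two-sided Gaussian (common amplitude A and center c,
independent σ_L/σ_R; starts from the data's half-window second moments;
bounds A ∈ (0, 2·max], c in-window, σ ∈ (0, window width]). The index is
the analytic FWHM = √(2 ln 2)(σ_L + σ_R); QC requires convergence and
R² > 0.90.

**ALS baseline.** Iteratively reweighted penalized least squares:
minimize Σ wᵢ(yᵢ − zᵢ)² + λ‖Δ²z‖² with wᵢ = p where yᵢ > zᵢ else 1 − p;
defaults p = 0.025, maxit = 100, convergence when no weight flips. The
smoothness penalty is conventionally quoted on a log₁₀ scale; the
package's default is λ = 10⁵ (i.e. log₁₀ λ = 5). A literal λ of order 1
makes the baseline track the analyte envelope itself and erases the FWHM
signal entirely (measured: FWHM pinned near 2.8 Da independent of
enrichment), which is why the log-scale reading is adopted. RP spectra
use λ = 10³: their baseline must relax inside the sub-Da valleys between
resolved isotopologues, whereas the LP envelope spans tens of Da.

## RP nitrogen index

After baseline correction the 1-Da isotopologue ladder is anchored by the
most intense apex: its offset from the nearest predicted ladder position
(monoisotopic m/z + k·1.00335) absorbs small calibration shifts, and the
3rd/4th peak positions are snapped to detected apexes within ±0.3 Da.
This deliberately avoids requiring the monoisotopic apex itself, which
becomes invisible above q ≈ 0.2. Peak areas are trapezoids on the
corrected trace between the first samples at or below zero flanking each
apex, capped at ±0.5 Da (half the ladder spacing). QC additionally
requires both peaks to exceed 3× the noise floor, estimated from second
differences of the residual (Var = 6σ² for white noise) over the
signal-free margin below the monoisotopic position — second differences
reject smooth baseline error, the margin rejects the envelope. Without
this check the ratio silently integrates noise at high enrichment, where
the 3rd/4th isotopologue abundances fall below 10⁻⁵.

Noiseless accuracy against the exact-convolution theory is ≤ 0.6% across
q ∈ [0, 0.25]; at SNR 10 and natural abundance the median bias over 100
seeds is ~2.5%.

## Synthetic-data generator

The generator defines the study conditions; its defaults are fixed, not
fitting knobs.

**Labeling kinetics.** Body-pool enrichment e(t) follows first-order
kinetics: e(t) = e_max(1 − e^(−k_in(t − t_pulse_start))) during the pulse
and exponential washout e(t_pulse_end)·e^(−k_out(t − t_pulse_end))
during the chase. Defaults: pulse 6–10 months, e_max = 0.25,
k_in = 3 /month, k_out = 1 /month, deposition onset at 9 months; the two
study arms are pulse-only with cull at 10 months and pulse-chase with
cull at 18 months. The kinetic form and rate constants are the
generator's own model — chosen as a plausible protein-pool turnover —
since no kinetic equations are prescribed by the data being emulated.

**Plaques.** A plaque born at time b deposits Aβ uniformly over
[b, cull]; its spectrum is the deposition-weighted mixture of
isotopologue patterns at q(t) = e(t) + q_nat (12-point midpoint
quadrature, patterns cached on a rounded-q grid). The *center* sub-ROI
draws from the earliest third of the window and the *periphery* from the
latest third — a discretization of the growth-ring picture in which the
plaque center holds the first-deposited material. Spectra are rendered by
convolving the stick pattern with a Gaussian instrument response
(FWHM = m/RP; RP 1000 in LP mode, 15000 in RP mode), sampled at 0.1 Da
(LP) / 0.04 Da (RP) over m/z 4470–4600 / 4505–4545 — mid-range of
realistic TOF digitization at this m/z — plus a smooth exponential
chemical baseline (5% of peak, 80-Da decay) and white Gaussian noise with
σ = peak/SNR. Every simulator is a pure function of (parameters, seed).

**Expression.** Counts are negative-binomial (gamma–Poisson) with a
log-link latent Gaussian: planted genes have latent correlation ±ρ with
plaque age, nulls 0; per-AOI size factors are log-normal (σ = 0.2), base
mean 100 counts, NB size 20 (mild overdispersion, typical of
probe-counted spatial transcriptomics at plaque-sized AOIs).

**Hyperspectral / IHC.** LCO references are Gaussians (σ = 30 nm) peaking
at 500/580 nm on a 32-channel 450–700 nm grid; measured references can be
substituted via CSV. In age mode the core q-fraction rises linearly with
plaque age; in class mode per-class (a_q, a_h) amplitudes are planted for
classification recovery. IHC images plant piecewise-constant ring
intensities on Euclidean-distance shells from the plaque mask — the same
geometry the analyzer measures, making noiseless recovery exact — with a
LAMP1-like profile decreasing outward and a HOMER1-like profile dipping
at the plaque.

**What the generator does not emulate:** pixel-level MSI rasters,
isotope-pattern interference from co-deposited species, detector
saturation, spatial autocorrelation of expression between neighbouring
AOIs, optical point-spread blur and channel crosstalk. Passing recovery
tests therefore demonstrates correctness of the estimators under the
stated noise model, not robustness to every artifact of real acquisitions.

## Transcriptomics link

Genes with per-AOI geometric-mean count < 1 are dropped (configurable
floor), then quantile normalization forces all AOI columns onto the mean
empirical distribution (ties receive the mean of their spanned rank
values). Gene-wise Pearson r against the age axis uses the exact t
reference (t = r√((n−2)/(1−r²)), n−2 df); under pulse-only labeling the
index axis is inverted before reporting so that "positive" always means
up with age — flipping the design negates every r exactly. The volcano
split uses uncorrected p < 0.05 by convention. Over-representation is a
one-sided Fisher's exact test per gene set against the measured
background with Benjamini–Hochberg q across sets (p < 0.05 and q < 0.05
to report). AOI exclusion (Grubbs, low counts) happens before
normalization. The iterative two-sided Grubbs test uses the t-based
critical value G = ((n−1)/√n)·√(t²_{α/(2n), n−2}/(n−2+t²)) at α = 0.01.

## Hyperspectral and rings

Per-pixel NNLS onto the two references uses the closed-form two-component
active-set solution (exact; cross-checked against `scipy.optimize.nnls`).
The 500/580 ratio uses the nearest detector channel (no interpolation, as
the detector bins are discrete); the core ratio averages a 2-px-radius
disc at the most 500-shifted in-mask pixel; z-planes are selected by
maximum in-mask ratio. Segmentation is Otsu (or fixed) threshold +
8-connected components + area filter; touching plaques merge (documented).
Class thresholds default to Otsu on pooled per-object mean abundances
since no fixed positivity cutoffs are prescribed; h−q+ combinations are
flagged anomalous rather than classified, because q-FTAA binds only
material that is already h-FTAA-positive under the maturation ordering.

Rings are Euclidean-distance-transform shells at 10-µm increments to
30 µm (exact at any pixel size; pixel size must be supplied). Overlap
removal is pixel-level and symmetric: any pixel claimed by ≥ 2 plaques'
ring systems (including other plaques' cores) is dropped from all rings.
Aggregation averages plaques within (class, image), then images within
(class, animal); per-group values > 2 SD from the group mean are excluded
(toggleable). Ring means are measured on the standard-deviation z-projection.

## Power analysis

Exact power via the noncentral t: for a one-sample test, noncentrality
δ = d√n, df = n − 1, critical value from the central t at α; the minimum
n is found by increment from n = 2. The one-sample one-sided family is
the default because it is the unique standard configuration whose minima
at α = 0.05, power 0.8 are n = 3 for d = 2.5 and n = 5 for d = 1.5;
two-sided and two-sample variants are available through `PowerSpec.test`.

## Known limitations

- The LP FWHM index saturates for strongly bimodal deposition mixtures
  (old pulse-chase plaques): a single asymmetric Gaussian under-measures
  a labeled hump riding ~13 Da above a dominant unlabeled peak, and its
  R² sits near the 0.9 QC floor. Under the default washout rate the
  enrichment of plaques born > 3 months after the pulse is also nearly
  flat, so age ranks within that subgroup are unrecoverable at SNR 20
  regardless of estimator (the FWHM spread there is below the Cramér–Rao
  bound of the fit). Cohort-level age recovery is correspondingly partial
  at SNR 20 (median Spearman ≈ 0.7; ≈ 0.98 noiseless).
- The RP 4/3 ratio (counted from the monoisotopic bin) is measurable only
  while those bins clear the noise floor — up to q ≈ 0.1 at SNR 20; QC
  rejects spectra beyond that rather than returning noise.
- Quantile normalization's "identical sorted columns" and idempotence
  properties hold exactly only for tie-free data; the tie policy breaks
  them by design.
- Plaque identity across modalities is a user-supplied mapping; no image
  registration is attempted.
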