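"""Synthetic data with known ground truth for every pipeline branch.

The generator emulates a metabolic 15N pulse(-chase) labeling study in an
amyloidosis mouse model:

* a first-order body-pool enrichment curve e(t) — label rises toward a
  plateau during the pulse diet and washes out during the chase;
* plaques that deposit Abeta1-42 continuously from a birth time until
  cull, so a plaque's isotopologue signature is the deposition-weighted
  mixture of patterns at the enrichment prevailing while it grew (the
  center holds the earliest material, the periphery the latest);
* instrument rendering at linear-mode (m/dm = 1000 at m/z 4515) or
  reflector-mode (m/dm = 15000 at m/z 4512.3) resolution with a smooth
  exponential chemical baseline and additive Gaussian noise;
* plaque-age-correlated negative-binomial count matrices with planted
  positive/negative genes (latent-Gaussian copula);
* 32-channel hyperspectral images mixing q-FTAA-like (500 nm) and
  h-FTAA-like (580 nm) reference emission spectra, with core q-fraction
  increasing with plaque age;
* radial immunostain images with piecewise-constant ring profiles per
  plaque class (LAMP1-like decreasing outward, HOMER1-like dipping at the
  plaque).

Every simulator is a pure function of its parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .isotopes import (
    ABETA42_SEQUENCE,
    N15_NATURAL,
    EnrichmentParams,
    IsotopologuePattern,
    composition_from_sequence,
    isotopologue_pattern,
    monoisotopic_mz,
)
from .spectral import Spectrum

__all__ = [
    "LabelingDesign",
    "SimPlaque",
    "SimTruth",
    "PULSE_ONLY_10M",
    "PULSE_CHASE_18M",
    "body_enrichment",
    "mixture_pattern",
    "simulate_plaque_spectrum",
    "render_pattern_spectrum",
    "simulate_cohort",
    "simulate_expression",
    "gaussian_reference_spectra",
    "simulate_hyperspectral",
    "simulate_ihc",
]

#: Deposition is first reliably detectable at this age (months).
PATHOLOGY_ONSET_MONTHS = 9.0


@dataclass(frozen=True)
class LabelingDesign:
    """Pulse(-chase) 15N diet design with first-order body-pool kinetics.

    ``e_max`` is the plateau enrichment of the free Abeta pool; ``k_in``
    and ``k_out`` are the first-order rise and washout rates (1/month).
    The kinetic form is the generator's own model — rise
    ``e_max*(1-exp(-k_in*(t-pulse_start)))`` during the pulse, exponential
    decay after ``pulse_end``.
    """

    kind: str  # pulse_only | pulse_chase
    pulse_start: float = 6.0
    pulse_end: float = 10.0
    cull_time: float = 10.0
    e_max: float = 0.25
    k_in: float = 3.0
    k_out: float = 1.0

    def __post_init__(self):
        if self.kind not in ("pulse_only", "pulse_chase"):
            raise ValueError("kind must be pulse_only or pulse_chase")
        if not self.pulse_start < self.pulse_end <= self.cull_time:
            raise ValueError("require pulse_start < pulse_end <= cull_time")
        if not 0 < self.e_max <= 1:
            raise ValueError("e_max must be in (0, 1]")


#: The two study arms: pulse 6-10 months with cull at 10 months, or the
#: same pulse followed by an 8-month chase to 18 months.
PULSE_ONLY_10M = LabelingDesign(kind="pulse_only", cull_time=10.0)
PULSE_CHASE_18M = LabelingDesign(kind="pulse_chase", cull_time=18.0)


@dataclass(frozen=True)
class SimPlaque:
    """One simulated plaque: born at ``birth_time``, grows until cull."""

    birth_time: float
    design: LabelingDesign
    region: str = "cortex"
    subregion: str = "whole"  # whole | center | periphery
    plaque_id: str = ""

    def __post_init__(self):
        if not (PATHOLOGY_ONSET_MONTHS - 1e-9 <= self.birth_time
                <= self.design.cull_time + 1e-9):
            raise ValueError("birth_time must lie in [onset, cull_time]")

    @property
    def age(self) -> float:
        return self.design.cull_time - self.birth_time


@dataclass
class SimTruth:
    """Ground truth for recovery tests; one entry per simulated observable."""

    plaque_q: dict = field(default_factory=dict)
    plaque_age: dict = field(default_factory=dict)
    gene_rho: dict = field(default_factory=dict)
    pixel_mixing: np.ndarray | None = None
    ring_means: dict = field(default_factory=dict)
    plaque_class: dict = field(default_factory=dict)
    extras: dict = field(default_factory=dict)


def body_enrichment(t, design: LabelingDesign):
    """Body-pool 15N fraction e(t) (above-natural label probability).

    Natural abundance before the pulse; saturating rise during the pulse;
    exponential washout during the chase.  Vectorized over ``t``.
    """
    t = np.asarray(t, float)
    e_end = design.e_max * (1.0 - np.exp(-design.k_in * (design.pulse_end - design.pulse_start)))
    rise = design.e_max * (1.0 - np.exp(-design.k_in * (t - design.pulse_start)))
    decay = e_end * np.exp(-design.k_out * (t - design.pulse_end))
    e = np.where(t < design.pulse_start, 0.0,
                 np.where(t <= design.pulse_end, rise, decay))
    out = np.maximum(e, 0.0) + N15_NATURAL * 0  # label on top of natural handled in q
    return out if out.ndim else float(out)


def _deposition_window(plaque: SimPlaque):
    """Time window contributing material to the sampled sub-ROI."""
    t0, t1 = plaque.birth_time, plaque.design.cull_time
    if plaque.subregion == "center":
        return t0, t0 + (t1 - t0) / 3.0
    if plaque.subregion == "periphery":
        return t1 - (t1 - t0) / 3.0, t1
    return t0, t1


_PATTERN_CACHE: dict = {}


def _cached_pattern(q: float, sequence: str, charge: int) -> IsotopologuePattern:
    key = (round(q, 4), sequence, charge)
    if key not in _PATTERN_CACHE:
        comp = composition_from_sequence(sequence)
        _PATTERN_CACHE[key] = isotopologue_pattern(
            comp, EnrichmentParams(q=round(q, 4)), charge=charge)
    return _PATTERN_CACHE[key]


def mixture_pattern(plaque: SimPlaque, n_quad: int = 12,
                    sequence: str = ABETA42_SEQUENCE,
                    charge: int = 1) -> tuple[IsotopologuePattern, float]:
    """Deposition-weighted isotopologue mixture over the plaque's window.

    Uniform deposition rate over the window (midpoint quadrature).  Returns
    the aggregated pattern and the true mean enrichment q-bar (total 15N
    fraction including natural).
    """
    t0, t1 = _deposition_window(plaque)
    ts = t0 + (np.arange(n_quad) + 0.5) / n_quad * (t1 - t0)
    qs = np.clip(body_enrichment(ts, plaque.design) + N15_NATURAL, 0.0, 1.0)
    comp = composition_from_sequence(sequence)
    mono_ref = monoisotopic_mz(comp, charge) if charge else None
    if mono_ref is None:
        from .isotopes import monoisotopic_mass
        mono_ref = monoisotopic_mass(comp)
    acc: dict = {}
    w = 1.0 / n_quad
    spacing = 1.00335 / max(charge, 1)
    for q in qs:
        pat = _cached_pattern(float(q), sequence, charge)
        for m, a in zip(pat.masses, pat.abundances):
            # anchor bins on the monoisotopic m/z so patterns align exactly
            k = int(round((m - mono_ref) / spacing))
            cell = acc.setdefault(k, [0.0, 0.0])
            cell[0] += w * a
            cell[1] += w * a * m
    ks = sorted(acc)
    ab = np.array([acc[k][0] for k in ks])
    masses = np.array([acc[k][1] for k in ks]) / ab
    ab = ab / ab.sum()
    q_bar = float(np.mean(qs))
    return IsotopologuePattern(masses=masses, abundances=ab,
                               enrichment_q=q_bar), q_bar


def _render_spectrum(pattern: IsotopologuePattern, mz_grid: np.ndarray,
                     resolving_power: float) -> np.ndarray:
    """Convolve stick pattern with the Gaussian instrument response."""
    out = np.zeros_like(mz_grid)
    for m, a in zip(pattern.masses, pattern.abundances):
        fwhm = m / resolving_power
        sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        out += a * np.exp(-((mz_grid - m) ** 2) / (2.0 * sigma ** 2))
    return out


def simulate_plaque_spectrum(plaque: SimPlaque, mode: str = "LP",
                             snr: float = 20.0, seed: int = 0,
                             baseline_amplitude: float = 0.05,
                             sequence: str = ABETA42_SEQUENCE) -> tuple[Spectrum, float]:
    """Render one plaque-ROI spectrum; returns (spectrum, true mean q).

    ``snr = numpy.inf`` gives a noiseless trace (the smooth exponential
    baseline is still added; the processing pipeline removes it).
    """
    if not snr > 0:
        raise ValueError("snr must be positive")
    pat, q_bar = mixture_pattern(plaque, sequence=sequence)
    sp = render_pattern_spectrum(pat, mode=mode, snr=snr, seed=seed,
                                 baseline_amplitude=baseline_amplitude)
    sp.roi_id = plaque.plaque_id
    sp.region = plaque.region
    sp.subregion = plaque.subregion
    return sp, q_bar


def render_pattern_spectrum(pattern: IsotopologuePattern, mode: str = "LP",
                            snr: float = 20.0, seed: int = 0,
                            baseline_amplitude: float = 0.05) -> Spectrum:
    """Render any stick pattern at instrument resolution with baseline/noise.

    Sampling: 0.1 Da in LP (m/dm = 1000), 0.04 Da in RP (m/dm = 15000) —
    typical of exported linear- and reflector-mode TOF traces at m/z 4500.
    """
    if not snr > 0:
        raise ValueError("snr must be positive")
    rng = np.random.default_rng(seed)
    if mode == "LP":
        rp, step = 1000.0, 0.1
        lo, hi = 4470.0, 4600.0
    elif mode == "RP":
        rp, step = 15000.0, 0.04
        lo, hi = 4505.0, 4545.0
    else:
        raise ValueError("mode must be LP or RP")
    mz = np.arange(lo, hi, step)
    signal = _render_spectrum(pattern, mz, rp)
    peak = signal.max()
    baseline = baseline_amplitude * peak * np.exp(-(mz - mz[0]) / 80.0)
    noise = 0.0 if np.isinf(snr) else rng.normal(0.0, peak / snr, mz.size)
    intensity = np.clip(signal + baseline + noise, 0.0, None)
    return Spectrum(mz, intensity, mode=mode, resolving_power=rp)


def simulate_cohort(n_plaques: int, design: LabelingDesign, mode: str = "LP",
                    snr: float = 20.0, seed: int = 0) -> tuple[list[Spectrum], SimTruth]:
    """A cohort of whole-plaque spectra with birth times uniform on
    [pathology onset, cull]."""
    if n_plaques < 2:
        raise ValueError("need at least 2 plaques")
    rng = np.random.default_rng(seed)
    births = rng.uniform(PATHOLOGY_ONSET_MONTHS, design.cull_time, n_plaques)
    truth = SimTruth()
    spectra = []
    for i, b in enumerate(np.sort(births)):
        pid = f"plaque_{i:03d}"
        pl = SimPlaque(birth_time=float(b), design=design, plaque_id=pid)
        sp, q_bar = simulate_plaque_spectrum(
            pl, mode=mode, snr=snr, seed=int(rng.integers(2 ** 31)))
        spectra.append(sp)
        truth.plaque_q[pid] = q_bar
        truth.plaque_age[pid] = pl.age
    return spectra, truth


def simulate_expression(n_genes: int, plaque_ages: np.ndarray,
                        n_planted_pos: int = 0, n_planted_neg: int = 0,
                        rho: float = 0.8, dispersion: float = 20.0,
                        mean_count: float = 100.0,
                        seed: int = 0) -> tuple[np.ndarray, list[str], SimTruth]:
    """Plaque-age-correlated negative-binomial count matrix.

    Planted genes have latent Gaussian correlation ±rho with plaque age;
    nulls have 0.  The latent value is passed through a monotone log-link
    to NB means with per-AOI size factors.  ``dispersion`` is the NB size
    parameter (larger = closer to Poisson).

    Returns (genes x AOIs counts, gene ids, truth).
    """
    ages = np.asarray(plaque_ages, float)
    n_aoi = ages.size
    if abs(rho) >= 1:
        raise ValueError("|rho| must be < 1")
    if n_planted_pos + n_planted_neg > n_genes:
        raise ValueError("planted genes exceed n_genes")
    rng = np.random.default_rng(seed)
    z_age = (ages - ages.mean()) / (ages.std() if ages.std() > 0 else 1.0)
    signs = np.zeros(n_genes)
    signs[:n_planted_pos] = 1.0
    signs[n_planted_pos:n_planted_pos + n_planted_neg] = -1.0
    size_factors = np.exp(rng.normal(0.0, 0.2, n_aoi))
    counts = np.empty((n_genes, n_aoi))
    truth = SimTruth()
    gene_ids = [f"gene_{g:04d}" for g in range(n_genes)]
    for g in range(n_genes):
        r = signs[g] * rho
        latent = r * z_age + np.sqrt(1.0 - r ** 2) * rng.standard_normal(n_aoi)
        mu = mean_count * size_factors * np.exp(0.5 * latent)
        # NB via gamma-Poisson mixture
        lam = rng.gamma(dispersion, mu / dispersion)
        counts[g] = rng.poisson(lam)
        truth.gene_rho[gene_ids[g]] = r
    truth.extras["size_factors"] = size_factors
    return counts, gene_ids, truth


def gaussian_reference_spectra(n_channels: int = 32,
                               wl_min: float = 450.0, wl_max: float = 700.0,
                               q_peak: float = 500.0, h_peak: float = 580.0,
                               width: float = 30.0):
    """Gaussian stand-ins for the q-FTAA / h-FTAA emission references.

    Synthetic references on an evenly spaced detector grid; measured
    spectra may be substituted via CSV.  Returns (wavelengths, ref_q, ref_h).
    """
    wl = np.linspace(wl_min, wl_max, n_channels)
    ref_q = np.exp(-((wl - q_peak) ** 2) / (2 * width ** 2))
    ref_h = np.exp(-((wl - h_peak) ** 2) / (2 * width ** 2))
    return wl, ref_q, ref_h


#: Planted (a_q, a_h) amplitudes per LCO plaque class.
CLASS_MIXING = {
    "Abeta+h+q+": (0.8, 0.8),
    "Abeta+h+q-": (0.03, 0.8),
    "Abeta+h-q-": (0.03, 0.06),
}


def simulate_hyperspectral(n_plaques: int, plaque_ages: np.ndarray | None = None,
                           image_size: int = 160, pixel_size: float = 1.0,
                           noise: float = 0.02, seed: int = 0,
                           refs=None, plaque_classes: list[str] | None = None,
                           radii_px: np.ndarray | None = None):
    """32-channel image of radial plaque blobs mixing the two LCO references.

    Two planting modes:

    * age mode (default) — the core q-FTAA mixing fraction increases with
      plaque age (structural maturation), the h-FTAA component dominates
      the body of the blob;
    * class mode (``plaque_classes`` given) — each plaque gets the
      per-class (a_q, a_h) amplitudes from :data:`CLASS_MIXING`, for
      classification recovery experiments; ``radii_px`` optionally plants
      the per-plaque sizes (and hence the class area fractions).

    Returns ``(image HxWxC, wavelengths, truth)``; truth carries per-pixel
    mixing coefficients, per-plaque masks, an LCO-independent ``abeta``
    channel for segmentation, centers, radii and ages/classes.
    """
    rng = np.random.default_rng(seed)
    if refs is None:
        wl, ref_q, ref_h = gaussian_reference_spectra()
    else:
        wl, ref_q, ref_h = refs
    if plaque_ages is None:
        plaque_ages = rng.uniform(0.0, 9.0, n_plaques)
    plaque_ages = np.asarray(plaque_ages, float)
    if plaque_classes is not None and len(plaque_classes) != n_plaques:
        raise ValueError("one class per plaque required")
    H = W = image_size
    a_q = np.zeros((H, W))
    a_h = np.zeros((H, W))
    abeta = np.zeros((H, W))
    truth = SimTruth()
    yy, xx = np.mgrid[0:H, 0:W]
    centers, radii, masks = [], [], []
    n_side = int(np.ceil(np.sqrt(n_plaques)))
    pitch = image_size / (n_side + 0.0)
    for i in range(n_plaques):
        cy = pitch * (i // n_side + 0.5)
        cx = pitch * (i % n_side + 0.5)
        if radii_px is not None:
            radius = float(radii_px[i])
        else:
            radius = 0.22 * pitch * (1.0 + 0.3 * rng.random())
        d = np.hypot(yy - cy, xx - cx)
        blob = np.exp(-(d ** 2) / (2 * (radius / 1.5) ** 2))
        blob[d > 2.5 * radius] = 0.0
        pid = f"plaque_{i:03d}"
        if plaque_classes is None:
            age_frac = plaque_ages[i] / max(plaque_ages.max(), 1e-9)
            core = np.exp(-(d ** 2) / (2 * (radius / 3.0) ** 2))
            q_weight = 0.15 + 0.75 * age_frac
            a_q += q_weight * core * blob
            a_h += (1.0 - 0.5 * q_weight) * blob
            truth.plaque_age[pid] = float(plaque_ages[i])
        else:
            cls = plaque_classes[i]
            if cls not in CLASS_MIXING:
                raise ValueError(f"unknown plaque class {cls!r}")
            wq, wh = CLASS_MIXING[cls]
            a_q += wq * blob
            a_h += wh * blob
            truth.plaque_class[pid] = cls
        abeta += blob
        centers.append((cy, cx))
        radii.append(radius)
        masks.append(d <= radius)
    img = a_q[..., None] * ref_q[None, None, :] + a_h[..., None] * ref_h[None, None, :]
    img = np.clip(img + rng.normal(0.0, noise, img.shape), 0.0, None)
    truth.pixel_mixing = np.stack([a_q, a_h], axis=-1)
    truth.extras.update({"centers": centers, "radii": radii, "masks": masks,
                         "abeta": abeta, "wavelengths": wl,
                         "pixel_size": pixel_size})
    return img, wl, truth


#: Planted per-class ring means (ring 0..3) for the two marker channels.
#: LAMP1-like dystrophy decreases with distance and with plaque immaturity;
#: HOMER1-like synaptic signal dips at the plaque and recovers outward.
DEFAULT_RING_PROFILES = {
    "Abeta+h+q+": {"lamp1": (100.0, 70.0, 40.0, 20.0),
                   "homer1": (10.0, 25.0, 45.0, 60.0)},
    "Abeta+h+q-": {"lamp1": (70.0, 50.0, 30.0, 18.0),
                   "homer1": (20.0, 35.0, 50.0, 60.0)},
    "Abeta+h-q-": {"lamp1": (40.0, 30.0, 22.0, 16.0),
                   "homer1": (35.0, 45.0, 55.0, 60.0)},
}


def simulate_ihc(plaque_classes: list[str], pixel_size: float = 1.0,
                 image_size: int = 220, plaque_radius_um: float = 12.0,
                 ring_increment_um: float = 10.0, noise: float = 0.0,
                 profiles: dict | None = None, seed: int = 0):
    """Marker-channel images with piecewise-constant radial ring intensities.

    Each plaque is a disc; pixel intensity in ring k (distance bands of
    ``ring_increment_um``) is the planted class profile value plus noise.
    Returns ``(channels dict, masks list, truth)``.
    """
    rng = np.random.default_rng(seed)
    profiles = profiles or DEFAULT_RING_PROFILES
    H = W = image_size
    yy, xx = np.mgrid[0:H, 0:W]
    n = len(plaque_classes)
    n_side = int(np.ceil(np.sqrt(n)))
    pitch = image_size / n_side
    masks = []
    channels = {ch: np.zeros((H, W)) for ch in next(iter(profiles.values()))}
    truth = SimTruth()
    bg = {ch: profiles[plaque_classes[0]][ch][-1] for ch in channels}
    for ch in channels:
        channels[ch] += bg[ch]
    from scipy.ndimage import distance_transform_edt

    for i, cls in enumerate(plaque_classes):
        cy = pitch * (i // n_side + 0.5)
        cx = pitch * (i % n_side + 0.5)
        d_um = np.hypot(yy - cy, xx - cx) * pixel_size
        mask = d_um <= plaque_radius_um
        masks.append(mask)
        pid = f"plaque_{i:03d}"
        truth.plaque_class[pid] = cls
        truth.ring_means[pid] = {ch: profiles[cls][ch] for ch in channels}
        # plant on Euclidean-distance shells measured from the mask, the
        # same geometry the ring analyzer uses
        edt = distance_transform_edt(~mask, sampling=pixel_size)
        for ch in channels:
            vals = profiles[cls][ch]
            for k in range(len(vals)):
                if k == 0:
                    ring = mask
                else:
                    ring = ((edt > (k - 1) * ring_increment_um)
                            & (edt <= k * ring_increment_um))
                channels[ch][ring] = vals[k]
    if noise > 0:
        for ch in channels:
            channels[ch] = np.clip(
                channels[ch] + rng.normal(0.0, noise, (H, W)), 0.0, None)
    truth.extras["pixel_size"] = pixel_size
    return channels, masks, truth
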