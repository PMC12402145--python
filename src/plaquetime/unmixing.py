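"""Hyperspectral LCO analysis: unmixing, maturity ratios, plaque classes.

Two structure-sensitive amyloid dyes with distinct emission maxima —
q-FTAA (mature, compact fibrils, ~500 nm) and h-FTAA (less compact
aggregates, ~580 nm) — are imaged on a 32-channel spectral detector.
Per-pixel non-negative least squares against the two reference spectra
yields abundance maps; the 500/580 nm intensity ratio indexes structural
maturity; thresholding the per-object mean abundances classifies plaques
into Abeta+h+q+, Abeta+h+q- and Abeta+h-q- populations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ReferencePair",
    "PlaqueObject",
    "linear_unmix",
    "ratio_500_580",
    "core_ratio",
    "segment_plaques",
    "classify_plaques",
    "class_area_fractions",
    "select_plane",
]

PLAQUE_CLASSES = ("Abeta+h+q+", "Abeta+h+q-", "Abeta+h-q-")


@dataclass(frozen=True)
class ReferencePair:
    """Reference emission spectra of the two LCO dyes on the detector grid."""

    wavelengths: np.ndarray
    ref_q: np.ndarray
    ref_h: np.ndarray

    def __post_init__(self):
        wl = np.asarray(self.wavelengths, float)
        rq = np.asarray(self.ref_q, float)
        rh = np.asarray(self.ref_h, float)
        if not (wl.size == rq.size == rh.size):
            raise ValueError("wavelengths and references must share length")
        if np.any(np.diff(wl) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if np.any(rq < 0) or np.any(rh < 0):
            raise ValueError("reference spectra must be non-negative")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "ref_q", rq)
        object.__setattr__(self, "ref_h", rh)

    @classmethod
    def from_csv(cls, path) -> "ReferencePair":
        df = pd.read_csv(path)
        return cls(df.iloc[:, 0].to_numpy(), df.iloc[:, 1].to_numpy(),
                   df.iloc[:, 2].to_numpy())


@dataclass
class PlaqueObject:
    """One segmented Abeta-positive object."""

    label: int
    mask: np.ndarray
    centroid_um: tuple
    area_um2: float
    plaque_class: str = ""
    core_ratio_500_580: float = float("nan")
    anomalous: bool = False
    extras: dict = field(default_factory=dict)


def linear_unmix(image: np.ndarray, refs: ReferencePair):
    """Per-pixel NNLS of the spectrum onto the two references.

    For two components the NNLS solution has a closed form: solve the
    unconstrained 2x2 normal equations; if a coefficient goes negative,
    clamp it to zero and re-solve for the other alone (clamped at zero).
    Returns ``(a_q, a_h, residual_norm)`` maps.
    """
    img = np.asarray(image, float)
    if img.ndim != 3:
        raise ValueError("image must be H x W x C")
    rq, rh = refs.ref_q, refs.ref_h
    gqq = rq @ rq
    ghh = rh @ rh
    gqh = rq @ rh
    det = gqq * ghh - gqh ** 2
    if det <= 1e-12 * gqq * ghh:
        raise ValueError("reference spectra are collinear")
    bq = img @ rq
    bh = img @ rh
    a_q = (ghh * bq - gqh * bh) / det
    a_h = (gqq * bh - gqh * bq) / det
    # active-set fixups: exact for the two-component case
    neg_q = a_q < 0
    a_q = np.where(neg_q, 0.0, a_q)
    a_h = np.where(neg_q, np.maximum(bh / ghh, 0.0), a_h)
    neg_h = a_h < 0
    a_h = np.where(neg_h, 0.0, a_h)
    a_q = np.where(neg_h & ~neg_q, np.maximum(bq / gqq, 0.0), a_q)
    model = a_q[..., None] * rq + a_h[..., None] * rh
    residual = np.linalg.norm(img - model, axis=-1)
    return a_q, a_h, residual


def _nearest_channel(wavelengths: np.ndarray, target: float) -> int:
    return int(np.argmin(np.abs(np.asarray(wavelengths, float) - target)))


def ratio_500_580(data: np.ndarray, wavelengths: np.ndarray):
    """Intensity at the channel nearest 500 nm over the one nearest 580 nm.

    Works on a single spectrum (C,) or an image (..., C).  Zero
    denominators yield NaN (flagged undefined), not an error.
    """
    wl = np.asarray(wavelengths, float)
    if wl.min() > 500 or wl.max() < 580:
        raise ValueError("wavelength grid must cover 500 and 580 nm")
    i500 = _nearest_channel(wl, 500.0)
    i580 = _nearest_channel(wl, 580.0)
    num = np.asarray(data, float)[..., i500]
    den = np.asarray(data, float)[..., i580]
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
    return out if out.ndim else float(out)


def core_ratio(mask: np.ndarray, image: np.ndarray, wavelengths: np.ndarray,
               disc_radius_px: int = 2) -> float:
    """Mean 500/580 ratio over a small disc at the most 500-shifted pixel.

    Mirrors placing a small circle on the area of the plaque with the
    highest 500 nm shift; the disc is clipped at image bounds and at the
    plaque mask.
    """
    mask = np.asarray(mask, bool)
    if mask.sum() == 0:
        raise ValueError("empty plaque mask")
    ratios = ratio_500_580(image, wavelengths)
    masked = np.where(mask, ratios, np.nan)
    if np.all(np.isnan(masked)):
        return float("nan")
    hot = np.unravel_index(np.nanargmax(masked), masked.shape)
    yy, xx = np.mgrid[0:mask.shape[0], 0:mask.shape[1]]
    disc = (yy - hot[0]) ** 2 + (xx - hot[1]) ** 2 <= disc_radius_px ** 2
    sel = disc & ~np.isnan(ratios)
    return float(np.nanmean(ratios[sel]))


def select_plane(stack: np.ndarray, masks, wavelengths: np.ndarray) -> int:
    """Pick the z-plane with the most pronounced 500-nm shift.

    ``stack`` is Z x H x W x C; the chosen plane maximizes the in-mask
    maximum 500/580 ratio over all provided masks.
    """
    best, best_val = 0, -np.inf
    union = np.zeros(stack.shape[1:3], bool)
    for m in masks:
        union |= np.asarray(m, bool)
    for z in range(stack.shape[0]):
        r = ratio_500_580(stack[z], wavelengths)
        val = np.nanmax(np.where(union, r, np.nan)) if union.any() else np.nanmax(r)
        if val > best_val:
            best, best_val = z, float(val)
    return best


def segment_plaques(abeta: np.ndarray, pixel_size: float,
                    threshold: float | str = "otsu",
                    min_area_um2: float = 0.0) -> list[PlaqueObject]:
    """Threshold + 8-connected components + area filter on the Abeta channel."""
    from skimage.filters import threshold_otsu
    from skimage.measure import label as cc_label, regionprops

    img = np.asarray(abeta, float)
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    if img.max() == img.min():
        return []
    thr = threshold_otsu(img) if threshold == "otsu" else float(threshold)
    binary = img > thr
    labels = cc_label(binary, connectivity=2)
    objects = []
    px_area = pixel_size ** 2
    for rp in regionprops(labels):
        area = rp.area * px_area
        if area < min_area_um2:
            continue
        objects.append(PlaqueObject(
            label=int(rp.label), mask=labels == rp.label,
            centroid_um=tuple(float(c) * pixel_size for c in rp.centroid),
            area_um2=float(area)))
    return objects


def _otsu_1d(values: np.ndarray) -> float:
    from skimage.filters import threshold_otsu
    v = np.asarray(values, float)
    if v.max() == v.min():
        return v.min()
    return float(threshold_otsu(v))


def classify_plaques(objects: list[PlaqueObject], a_q: np.ndarray,
                     a_h: np.ndarray, q_thresh: float | None = None,
                     h_thresh: float | None = None) -> list[PlaqueObject]:
    """Label objects by mean-abundance positivity for each dye.

    Thresholds default to Otsu on the pooled per-object mean abundances.
    The combination h-q+ contradicts the maturation ordering (q-FTAA binds
    only once h-FTAA-positive material has compacted) and is flagged
    anomalous instead of being assigned a class.
    """
    if not objects:
        return []
    mean_q = np.array([a_q[o.mask].mean() for o in objects])
    mean_h = np.array([a_h[o.mask].mean() for o in objects])
    qt = _otsu_1d(mean_q) if q_thresh is None else float(q_thresh)
    ht = _otsu_1d(mean_h) if h_thresh is None else float(h_thresh)
    if (q_thresh is not None and q_thresh < 0) or \
       (h_thresh is not None and h_thresh < 0):
        raise ValueError("thresholds must be non-negative")
    for o, mq, mh in zip(objects, mean_q, mean_h):
        q_pos = mq > qt
        h_pos = mh > ht
        if q_pos and not h_pos:
            o.plaque_class = ""
            o.anomalous = True
        elif q_pos and h_pos:
            o.plaque_class = "Abeta+h+q+"
        elif h_pos:
            o.plaque_class = "Abeta+h+q-"
        else:
            o.plaque_class = "Abeta+h-q-"
        o.extras.update({"mean_a_q": float(mq), "mean_a_h": float(mh)})
    return objects


def class_area_fractions(objects: list[PlaqueObject]) -> pd.DataFrame:
    """Per-class fractions of total Abeta-positive area and of object count."""
    if not objects:
        raise ValueError("no objects")
    classed = [o for o in objects if o.plaque_class]
    total_area = sum(o.area_um2 for o in classed)
    rows = []
    for cls in PLAQUE_CLASSES:
        members = [o for o in classed if o.plaque_class == cls]
        rows.append({
            "class": cls,
            "n": len(members),
            "area_um2": sum(o.area_um2 for o in members),
            "area_fraction": (sum(o.area_um2 for o in members) / total_area
                              if total_area else 0.0),
            "count_fraction": len(members) / len(classed) if classed else 0.0,
        })
    return pd.DataFrame(rows)
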