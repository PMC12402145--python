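"""Radial intensity profiles around classified plaques.

Concentric rings at fixed micrometre increments (default 10 um out to
30 um) are built around each plaque mask from the Euclidean distance
transform, contested pixels shared by two plaques' ring systems are
dropped symmetrically, and mean marker intensities per ring are
aggregated plaque -> image -> animal.  LAMP1-type dystrophy markers fall
off with distance from the plaque; HOMER1-type synaptic markers dip at
the plaque and recover outward.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .stats import pearson

__all__ = [
    "RingSet",
    "RingProfile",
    "project_zstack",
    "build_rings",
    "remove_overlaps",
    "ring_means",
    "aggregate_profiles",
    "homer_vs_maturity",
]


@dataclass
class RingSet:
    """Ring 0 is the plaque mask itself; ring k the (k-1..k)*increment shell."""

    plaque_id: str
    rings: list  # list of boolean masks, ring 0 first
    increment_um: float
    clipped: bool = False
    excluded: np.ndarray | None = None


@dataclass
class RingProfile:
    plaque_id: str
    plaque_class: str
    image: str
    animal: str
    means: list
    pixel_counts: list


def project_zstack(stack: np.ndarray, method: str = "std") -> np.ndarray:
    """Project a z-stack to one plane; per-pixel population SD by default."""
    stack = np.asarray(stack, float)
    if stack.ndim != 3:
        raise ValueError("stack must be Z x H x W")
    if stack.shape[0] < 2:
        import warnings
        warnings.warn("single-plane stack: projection is the identity")
        return stack[0].copy()
    if method != "std":
        raise ValueError(f"unknown projection method {method!r}")
    return stack.std(axis=0, ddof=0)


def build_rings(mask: np.ndarray, pixel_size: float,
                increment_um: float = 10.0, max_um: float = 30.0,
                plaque_id: str = "") -> RingSet:
    """Distance-transform shells around a plaque mask.

    Ring k (k >= 1) contains pixels whose Euclidean distance from the
    mask lies in ((k-1)*increment, k*increment]; exact at any pixel size
    via the EDT with physical sampling.  A mask touching the image border
    yields clipped rings, flagged on the result.
    """
    mask = np.asarray(mask, bool)
    if mask.sum() == 0:
        raise ValueError("empty plaque mask")
    if pixel_size <= 0 or increment_um <= 0:
        raise ValueError("pixel_size and increment must be positive")
    n_shells = int(round(max_um / increment_um))
    if abs(n_shells * increment_um - max_um) > 1e-9:
        raise ValueError("max_um must be a multiple of increment_um")
    dist = ndimage.distance_transform_edt(~mask, sampling=pixel_size)
    rings = [mask.copy()]
    for k in range(1, n_shells + 1):
        rings.append((dist > (k - 1) * increment_um) & (dist <= k * increment_um))
    # shells reaching the image border are geometrically incomplete
    clipped = bool(_touches_border(mask) or _touches_border(rings[-1]))
    return RingSet(plaque_id=plaque_id, rings=rings,
                   increment_um=increment_um, clipped=clipped)


def _touches_border(ring: np.ndarray) -> bool:
    return bool(ring[0].any() or ring[-1].any()
                or ring[:, 0].any() or ring[:, -1].any())


def remove_overlaps(ring_sets: list[RingSet]) -> list[RingSet]:
    """Drop every pixel claimed by two or more plaques' ring systems.

    Removal is symmetric — neither plaque keeps a contested pixel — and
    counts other plaques' ring-0 masks as claims.
    """
    if not ring_sets:
        raise ValueError("need at least one ring set")
    shape = ring_sets[0].rings[0].shape
    multiplicity = np.zeros(shape, dtype=int)
    for rs in ring_sets:
        system = np.zeros(shape, bool)
        for ring in rs.rings:
            system |= ring
        multiplicity += system
    contested = multiplicity >= 2
    out = []
    for rs in ring_sets:
        rings = [ring & ~contested for ring in rs.rings]
        out.append(RingSet(plaque_id=rs.plaque_id, rings=rings,
                           increment_um=rs.increment_um, clipped=rs.clipped,
                           excluded=contested))
    return out


def ring_means(image: np.ndarray, ring_sets: list[RingSet],
               classes: dict | None = None, image_id: str = "",
               animal: str = "") -> list[RingProfile]:
    """Arithmetic mean intensity per surviving ring; empty rings give NaN."""
    img = np.asarray(image, float)
    profiles = []
    for rs in ring_sets:
        if rs.rings[0].shape != img.shape:
            raise ValueError("image and ring masks must share shape")
        means, counts = [], []
        for ring in rs.rings:
            n = int(ring.sum())
            counts.append(n)
            means.append(float(img[ring].mean()) if n else float("nan"))
        profiles.append(RingProfile(
            plaque_id=rs.plaque_id,
            plaque_class=(classes or {}).get(rs.plaque_id, ""),
            image=image_id, animal=animal,
            means=means, pixel_counts=counts))
    return profiles


def profiles_to_frame(profiles: list[RingProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        for k, (m, n) in enumerate(zip(p.means, p.pixel_counts)):
            rows.append({"animal": p.animal, "image": p.image,
                         "plaque": p.plaque_id, "class": p.plaque_class,
                         "ring": k, "mean": m, "n_pixels": n})
    return pd.DataFrame(rows)


def aggregate_profiles(profiles: list[RingProfile],
                       exclude_sd: float | None = 2.0) -> pd.DataFrame:
    """Two-stage aggregation: plaques within (class, image, ring), then
    images within (class, animal, ring).

    ``exclude_sd`` drops per-plaque values more than that many group SDs
    from the (class, image, ring) group mean before averaging; pass None
    to keep everything.  Empty rings (NaN means) never contribute.
    """
    df = profiles_to_frame(profiles)
    if df.empty:
        raise ValueError("no profiles to aggregate")
    if df["class"].eq("").any() or df["image"].eq("").any() \
            or df["animal"].eq("").any():
        raise ValueError("profiles must carry class, image and animal labels")
    df = df.dropna(subset=["mean"])
    if exclude_sd is not None:
        def keep(g):
            if len(g) < 3:
                return g
            mu, sd = g["mean"].mean(), g["mean"].std(ddof=1)
            if sd == 0:
                return g
            return g[(g["mean"] - mu).abs() <= exclude_sd * sd]
        df = pd.concat([keep(g) for _, g in df.groupby(["class", "image", "ring"])],
                       ignore_index=True)
    per_image = (df.groupby(["class", "animal", "image", "ring"])
                   .agg(mean=("mean", "mean"), n_plaques=("mean", "size"))
                   .reset_index())
    per_animal = (per_image.groupby(["class", "animal", "ring"])
                  .agg(mean=("mean", "mean"), n_images=("mean", "size"),
                       n_plaques=("n_plaques", "sum"))
                  .reset_index())
    return per_animal


def homer_vs_maturity(intensities, core_ratios,
                      animals=None) -> pd.DataFrame:
    """Pearson r/p of per-plaque marker intensity vs core 500/580 ratio.

    Reported pooled and, when ``animals`` labels are given, per animal
    (groups with n < 4 or zero variance are flagged undefined).
    """
    x = np.asarray(core_ratios, float)
    y = np.asarray(intensities, float)
    if x.size != y.size or x.size < 4:
        raise ValueError("need n >= 4 matched plaques")
    rows = []

    def _row(scope, xi, yi):
        if xi.size < 4 or np.std(xi) == 0 or np.std(yi) == 0:
            rows.append({"scope": scope, "r": float("nan"), "p": float("nan"),
                         "n": int(xi.size), "flag": "undefined"})
        else:
            r, p = pearson(xi, yi)
            rows.append({"scope": scope, "r": r, "p": p, "n": int(xi.size),
                         "flag": ""})

    _row("pooled", x, y)
    if animals is not None:
        animals = np.asarray(animals)
        for a in pd.unique(animals):
            sel = animals == a
            _row(str(a), x[sel], y[sel])
    return pd.DataFrame(rows)
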