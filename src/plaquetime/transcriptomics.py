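"""Linking plaque age (nitrogen index) to single-plaque gene expression.

AOI-level count matrices from plaque-centered spatial transcriptomics are
quantile-normalized and correlated gene-by-gene against the nitrogen
index of the matched plaque.  Because the labeling design determines
whether a high index marks an old or a young plaque, the reported
correlation sign is oriented to *age*: direct under pulse-chase, inverted
under pulse-only.  Significant genes split into positive/negative lists
(uncorrected p < 0.05 by convention) and feed a Fisher over-representation
analysis against user-supplied GMT gene sets with Benjamini-Hochberg
control.  Covariate checks (AOI area, cell count, GFAP area fraction)
guard against confounding, and an iterative Grubbs test flags outlier
probes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .stats import bh_adjust, fisher_exact_greater, pearson

__all__ = [
    "AoiMetadata",
    "GeneAgeResult",
    "quantile_normalize",
    "PlaqueAgeExpressionModel",
    "correlate_gene_age",
    "volcano_split",
    "read_gmt",
    "ora_fisher",
    "covariate_check",
    "gfap_area_fraction",
    "grubbs_outlier",
    "geometric_mean_filter",
]


@dataclass(frozen=True)
class AoiMetadata:
    """Per-AOI annotations for covariate checks."""

    aoi_id: str
    roi_id: str = ""
    aoi_area: float = float("nan")
    cell_count: float = float("nan")
    gfap_area_fraction: float = float("nan")
    animal: str = ""
    age_group: str = ""

    def __post_init__(self):
        if not np.isnan(self.aoi_area) and self.aoi_area <= 0:
            raise ValueError("aoi_area must be positive")
        g = self.gfap_area_fraction
        if not np.isnan(g) and not 0 <= g <= 1:
            raise ValueError("gfap_area_fraction must be in [0, 1]")


@dataclass(frozen=True)
class GeneAgeResult:
    gene: str
    pearson_r: float
    p_two_sided: float
    direction: str  # positive | negative | ns
    flag: str = ""


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force every AOI column onto the shared mean empirical distribution.

    Each column's rank-r value is replaced by the mean of the rank-r
    values across columns; ties receive the mean of their spanned rank
    values (mean-of-ranks tie policy).  Idempotent.
    """
    if matrix.shape[1] < 2:
        import warnings
        warnings.warn("single-column matrix: quantile normalization is identity")
        return matrix.copy()
    values = matrix.to_numpy(float)
    ref = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        col = values[:, j]
        first = sstats.rankdata(col, method="ordinal") - 1
        assigned = ref[first]
        # ties get the mean of the reference values their ranks span
        tied = pd.Series(assigned).groupby(pd.Series(col)).transform("mean")
        out[:, j] = tied.to_numpy()
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def correlate_gene_age(matrix: pd.DataFrame, indices,
                       design_kind: str = "pulse_chase") -> list[GeneAgeResult]:
    """Per-gene Pearson correlation of expression with plaque age.

    ``indices`` are the per-AOI nitrogen-index values (QC-passed only).
    Under ``pulse_chase`` a higher index means an older plaque, so the
    index is used directly as the age axis; under ``pulse_only`` older
    plaques carry *less* label and the axis is inverted before reporting,
    so that "positive" always means up with age.
    """
    idx = np.asarray(indices, float)
    if idx.size != matrix.shape[1]:
        raise ValueError("one index per AOI column required")
    if idx.size < 4:
        raise ValueError("need at least 4 AOIs")
    if design_kind not in ("pulse_only", "pulse_chase"):
        raise ValueError("design_kind must be pulse_only or pulse_chase")
    age_axis = idx if design_kind == "pulse_chase" else -idx
    results = []
    for gene, row in zip(matrix.index, matrix.to_numpy(float)):
        if np.std(row) == 0:
            results.append(GeneAgeResult(str(gene), float("nan"), float("nan"),
                                         "ns", flag="zero variance"))
            continue
        r, p = pearson(age_axis, row)
        results.append(GeneAgeResult(str(gene), r, p, "ns"))
    return results


def volcano_split(results: list[GeneAgeResult], p_cut: float = 0.05):
    """Partition results at p < p_cut into positive/negative gene lists."""
    if not 0 < p_cut < 1:
        raise ValueError("p_cut must be in (0, 1)")
    pos, neg = [], []
    for res in results:
        if np.isnan(res.p_two_sided) or res.p_two_sided >= p_cut:
            continue
        (pos if res.pearson_r > 0 else neg).append(res.gene)
    return pos, neg


class PlaqueAgeExpressionModel:
    """Gene-expression-versus-plaque-age analysis for one labeling arm.

    Statsmodels-flavored front end: construct from the raw count matrix
    (genes x AOIs) and the per-AOI nitrogen indices, then ``fit()``
    quantile-normalizes, correlates each gene with the age axis and
    returns a results object with the per-gene table, volcano split and
    an ``ora()`` method for gene-set over-representation.
    """

    def __init__(self, counts: pd.DataFrame, indices,
                 design_kind: str = "pulse_chase",
                 count_floor: float = 1.0):
        self.counts = counts
        self.indices = np.asarray(indices, float)
        self.design_kind = design_kind
        self.count_floor = count_floor

    @classmethod
    def from_files(cls, counts_tsv, indices, **kw) -> "PlaqueAgeExpressionModel":
        counts = pd.read_csv(counts_tsv, sep="\t", index_col=0)
        return cls(counts, indices, **kw)

    def fit(self, p_cut: float = 0.05) -> "PlaqueAgeExpressionResults":
        kept = geometric_mean_filter(self.counts, self.count_floor)
        norm = quantile_normalize(kept)
        results = correlate_gene_age(norm, self.indices, self.design_kind)
        return PlaqueAgeExpressionResults(self, norm, results, p_cut)


class PlaqueAgeExpressionResults:
    def __init__(self, model, normalized, results, p_cut):
        self.model = model
        self.normalized = normalized
        self.results = results
        self.p_cut = p_cut
        self.positive, self.negative = volcano_split(results, p_cut)

    @property
    def table(self) -> pd.DataFrame:
        df = pd.DataFrame([vars(r) for r in self.results]).set_index("gene")
        sig = df["p_two_sided"] < self.p_cut
        df.loc[sig & (df["pearson_r"] > 0), "direction"] = "positive"
        df.loc[sig & (df["pearson_r"] < 0), "direction"] = "negative"
        return df

    def ora(self, gene_sets: dict, which: str = "positive",
            p_cut: float = 0.05, q_cut: float = 0.05) -> pd.DataFrame:
        gene_list = self.positive if which == "positive" else self.negative
        background = [str(g) for g in self.normalized.index]
        return ora_fisher(gene_list, gene_sets, background, p_cut, q_cut)

    def summary(self) -> str:
        t = self.table
        lines = [
            "Plaque-age expression correlation",
            "=" * 44,
            f"design:            {self.model.design_kind}",
            f"AOIs:              {self.normalized.shape[1]}",
            f"genes tested:      {self.normalized.shape[0]}",
            f"positive (p<{self.p_cut:g}): {len(self.positive)}",
            f"negative (p<{self.p_cut:g}): {len(self.negative)}",
            f"median |r|:        {t['pearson_r'].abs().median():.3f}",
        ]
        return "\n".join(lines)


def geometric_mean_filter(counts: pd.DataFrame, floor: float = 1.0) -> pd.DataFrame:
    """Drop genes whose per-AOI geometric mean count falls below ``floor``."""
    vals = counts.to_numpy(float)
    gm = np.exp(np.log1p(vals).mean(axis=1)) - 1.0
    return counts.loc[gm >= floor]


def read_gmt(path) -> dict:
    """GMT gene-set file: name <tab> description <tab> genes..."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                sets[parts[0]] = set(parts[2:])
    return sets


def ora_fisher(gene_list, gene_sets: dict, background,
               p_cut: float = 0.05, q_cut: float = 0.05) -> pd.DataFrame:
    """Over-representation of ``gene_list`` in each set vs the background.

    One-sided Fisher's exact test on the 2x2 (in-list x in-set) table over
    the measured background, Benjamini-Hochberg q across all tested sets;
    rows flagged significant when p < p_cut and q < q_cut.
    """
    background = set(map(str, background))
    listed = set(map(str, gene_list))
    if not listed <= background:
        raise ValueError("gene_list must be a subset of the background")
    rows = []
    for name, members in gene_sets.items():
        members = set(map(str, members)) & background
        if not members:
            continue  # no overlap with the measured background
        a = len(listed & members)
        b = len(listed - members)
        c = len(members - listed)
        d = len(background) - a - b - c
        p = fisher_exact_greater(a, b, c, d)
        rows.append({"set": name, "overlap": a, "set_size": len(members),
                     "list_size": len(listed), "background": len(background),
                     "p": p})
    if not rows:
        return pd.DataFrame(columns=["set", "overlap", "set_size", "list_size",
                                     "background", "p", "q", "significant"])
    df = pd.DataFrame(rows)
    df["q"] = bh_adjust(df["p"].to_numpy())
    df["significant"] = (df["p"] < p_cut) & (df["q"] < q_cut)
    return df.sort_values("p").reset_index(drop=True)


def covariate_check(metadata: list[AoiMetadata], indices) -> pd.DataFrame:
    """Pearson r/p of the nitrogen index against AOI-level covariates."""
    idx = np.asarray(indices, float)
    if idx.size != len(metadata) or idx.size < 4:
        raise ValueError("need one index per AOI and n >= 4")
    covs = {
        "aoi_area": np.array([m.aoi_area for m in metadata]),
        "cell_count": np.array([m.cell_count for m in metadata]),
        "gfap_area_fraction": np.array([m.gfap_area_fraction for m in metadata]),
    }
    rows = []
    for name, v in covs.items():
        if np.all(np.isnan(v)):
            raise ValueError(f"covariate {name} missing for all AOIs")
        ok = ~np.isnan(v)
        if np.std(v[ok]) == 0:
            rows.append({"covariate": name, "r": float("nan"),
                         "p": float("nan"), "n": int(ok.sum()),
                         "flag": "constant"})
            continue
        r, p = pearson(idx[ok], v[ok])
        rows.append({"covariate": name, "r": r, "p": p, "n": int(ok.sum()),
                     "flag": ""})
    return pd.DataFrame(rows)


def gfap_area_fraction(image: np.ndarray, mask: np.ndarray,
                       threshold: float | str = "otsu") -> float:
    """Thresholded-positive pixel fraction of an immunostain inside a mask.

    The same threshold rule should be applied uniformly across all images
    of a batch; pass a fixed value to enforce that.
    """
    mask = np.asarray(mask, bool)
    if mask.sum() == 0:
        raise ValueError("empty AOI mask")
    vals = np.asarray(image, float)[mask]
    if threshold == "otsu":
        from skimage.filters import threshold_otsu
        thr = threshold_otsu(vals)
    else:
        thr = float(threshold)
    return float((vals > thr).sum() / vals.size)


def _grubbs_critical(n: int, alpha: float) -> float:
    t = sstats.t.ppf(1 - alpha / (2 * n), n - 2)
    return (n - 1) / np.sqrt(n) * np.sqrt(t ** 2 / (n - 2 + t ** 2))


def grubbs_outlier(values, alpha: float = 0.01) -> list[int]:
    """Iterative two-sided Grubbs test; returns indices of flagged outliers.

    At each step the most extreme value is removed while its studentized
    deviation G = max|x - mean| / sd exceeds the t-based critical value.
    """
    x = np.asarray(values, float)
    if x.size < 3:
        raise ValueError("Grubbs test needs n >= 3")
    active = list(range(x.size))
    flagged: list[int] = []
    while len(active) >= 3:
        sub = x[active]
        s = sub.std(ddof=1)
        if s == 0:
            break
        dev = np.abs(sub - sub.mean())
        i_ext = int(np.argmax(dev))
        G = dev[i_ext] / s
        if G > _grubbs_critical(len(active), alpha):
            flagged.append(active.pop(i_ext))
        else:
            break
    return sorted(flagged)
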