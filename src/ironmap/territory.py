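"""ROI-level statistics over coronary territories.

Implements the two summary statistics of the quantification chain:

* the in vivo pre/post contrast difference of territory-mean R2* (delta R2*),
  the per-region proxy for the amount of bound iron-oxide contrast;
* the ex vivo high-R2* pixel-count ratio: a Gaussian is fitted to the
  histogram of R2* over the whole LV myocardium, pixels strictly above
  mu + 2*sigma are counted per region, normalized by region area, and the
  lesion/reference ratio of these normalized counts is reported.

Group-comparison reporting (Mann-Whitney U, t-test, one-way ANOVA with
Bonferroni-corrected pairwise tests) delegates to scipy.stats.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .phantom import TERRITORY_CODES
from .relaxometry import ParameterMap

__all__ = [
    "RoiStat",
    "TerritoryReport",
    "CountRatioResult",
    "GaussianFitError",
    "roi_mean",
    "delta_r2star",
    "fit_gaussian_to_histogram",
    "exvivo_count_ratio",
    "compare_groups",
]


@dataclass(frozen=True)
class RoiStat:
    mean: float
    n: int
    std: float


@dataclass
class TerritoryReport:
    """Per-territory pre/post means and their difference (delta = post - pre)."""

    territories: dict[str, dict[str, float]]
    slice_ids: tuple[int, ...] = ()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame.from_dict(self.territories, orient="index")

    def to_dict(self) -> dict:
        return {"territories": self.territories, "slice_ids": list(self.slice_ids)}


@dataclass
class CountRatioResult:
    """Provenance-complete result of the ex vivo count-ratio statistic."""

    mu: float
    sigma: float
    threshold: float
    count_lesion: int
    count_reference: int
    area_lesion: int
    area_reference: int
    normalized_lesion: float
    normalized_reference: float
    ratio: float
    bin_edges: np.ndarray = field(default_factory=lambda: np.array([]))
    bin_counts: np.ndarray = field(default_factory=lambda: np.array([]))

    def to_dict(self) -> dict:
        return {
            "mu": self.mu,
            "sigma": self.sigma,
            "threshold": self.threshold,
            "count_lesion": self.count_lesion,
            "count_reference": self.count_reference,
            "area_lesion": self.area_lesion,
            "area_reference": self.area_reference,
            "normalized_lesion": self.normalized_lesion,
            "normalized_reference": self.normalized_reference,
            "ratio": self.ratio,
            "bin_edges": [float(v) for v in self.bin_edges],
            "bin_counts": [int(v) for v in self.bin_counts],
        }


class GaussianFitError(RuntimeError):
    """Raised when the histogram Gaussian fit fails; carries the histogram."""

    def __init__(self, message: str, bin_edges: np.ndarray, bin_counts: np.ndarray):
        super().__init__(message)
        self.bin_edges = bin_edges
        self.bin_counts = bin_counts


def _territory_code(territory: int | str) -> int:
    if isinstance(territory, str):
        return TERRITORY_CODES[territory]
    return int(territory)


def roi_mean(pmap: ParameterMap, labels: np.ndarray, territory: int | str) -> RoiStat:
    """Mean parameter value over the valid pixels of one territory."""
    code = _territory_code(territory)
    if labels.shape != pmap.values.shape:
        raise ValueError("labels shape does not match map")
    if not np.any(labels == code):
        raise ValueError(f"territory {territory!r} not present in labels")
    sel = (labels == code) & pmap.valid_mask
    if not sel.any():
        raise ValueError(f"territory {territory!r} has no valid pixels")
    vals = pmap.values[sel]
    return RoiStat(mean=float(vals.mean()), n=int(sel.sum()), std=float(vals.std()))


def delta_r2star(
    pre: ParameterMap | Sequence[ParameterMap],
    post: ParameterMap | Sequence[ParameterMap],
    labels: np.ndarray | Sequence[np.ndarray],
    territories: Sequence[str] = ("LCX", "LAD", "RCA"),
) -> TerritoryReport:
    """Per-territory difference of mean R2* after vs before contrast.

    Means are taken over the intersection of the pre and post validity masks
    (the maps are assumed co-registered).  Multiple short-axis slices may be
    passed as sequences; their pixels are pooled per territory before
    averaging.  delta = post_mean - pre_mean, an exact identity of the
    returned numbers.
    """
    pres = [pre] if isinstance(pre, ParameterMap) else list(pre)
    posts = [post] if isinstance(post, ParameterMap) else list(post)
    labs = [labels] if isinstance(labels, np.ndarray) else list(labels)
    if not (len(pres) == len(posts) == len(labs)):
        raise ValueError("pre, post and labels must have matching slice counts")
    for a, b, l in zip(pres, posts, labs):
        if a.values.shape != b.values.shape or a.values.shape != l.shape:
            raise ValueError("pre/post/label geometries do not match")
        if a.kind != "R2star" or b.kind != "R2star":
            raise ValueError("delta_r2star requires R2star maps")

    report: dict[str, dict[str, float]] = {}
    for name in territories:
        code = _territory_code(name)
        pre_vals, post_vals = [], []
        for a, b, l in zip(pres, posts, labs):
            sel = (l == code) & a.valid_mask & b.valid_mask
            pre_vals.append(a.values[sel])
            post_vals.append(b.values[sel])
        pv = np.concatenate(pre_vals)
        qv = np.concatenate(post_vals)
        if pv.size == 0:
            raise ValueError(f"territory {name!r} has no jointly valid pixels")
        pre_mean = float(pv.mean())
        post_mean = float(qv.mean())
        report[name] = {
            "pre": pre_mean,
            "post": post_mean,
            "delta": post_mean - pre_mean,
            "n": int(pv.size),
        }
    return TerritoryReport(territories=report,
                           slice_ids=tuple(range(len(pres))))


def fit_gaussian_to_histogram(
    values: np.ndarray, bins: int | str = "fd"
) -> tuple[float, float, np.ndarray, np.ndarray]:
    """Fit amp*exp(-(x-mu)^2 / (2 sigma^2)) to histogram bin counts.

    The fit is a nonlinear least-squares fit to the (bin center, count)
    pairs, initialized at the sample moments.  Freedman-Diaconis binning by
    default; pass an int for a fixed bin count.  Returns
    (mu, sigma, bin_edges, bin_counts).

    A degenerate sample with zero spread short-circuits to mu = the common
    value and sigma = 0 (no histogram exists to fit).
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 values to fit a histogram")
    if np.ptp(values) == 0.0:
        v = float(values[0])
        return v, 0.0, np.array([v, v]), np.array([values.size])

    counts, edges = np.histogram(values, bins=bins)
    centers = 0.5 * (edges[:-1] + edges[1:])

    def model(x, amp, mu, sigma):
        return amp * np.exp(-((x - mu) ** 2) / (2.0 * sigma**2))

    # initialize at the dominant mode (robust when a lesion adds a second,
    # smaller mode to the whole-myocardium histogram), falling back to the
    # sample moments
    mad_sigma = 1.4826 * float(np.median(np.abs(values - np.median(values))))
    inits = [
        (float(counts.max()), float(centers[np.argmax(counts)]),
         mad_sigma if mad_sigma > 0 else float(values.std())),
        (float(counts.max()), float(values.mean()), float(values.std())),
    ]
    popt, last_exc = None, None
    for p0 in inits:
        try:
            popt, _ = optimize.curve_fit(model, centers, counts.astype(float),
                                         p0=p0, maxfev=10000)
            break
        except (RuntimeError, TypeError, optimize.OptimizeWarning) as exc:
            last_exc = exc
    if popt is None:
        raise GaussianFitError(f"Gaussian histogram fit failed: {last_exc}",
                               edges, counts) from last_exc
    mu, sigma = float(popt[1]), float(abs(popt[2]))
    if not (np.isfinite(mu) and np.isfinite(sigma)):
        raise GaussianFitError("Gaussian histogram fit diverged", edges, counts)
    return mu, sigma, edges, counts


def exvivo_count_ratio(
    pmap: ParameterMap,
    myocardium_mask: np.ndarray,
    lesion_mask: np.ndarray,
    reference_mask: np.ndarray,
    bins: int | str = "fd",
) -> CountRatioResult:
    """High-R2* pixel-count ratio between a lesion and a reference region.

    A normal distribution is fitted to the histogram of valid R2* values
    over the whole myocardium; pixels with R2* strictly greater than
    mu + 2*sigma are counted in the lesion and reference regions, each count
    is normalized by the region's valid-pixel area, and the ratio
    lesion/reference of the normalized counts is returned.
    """
    for m in (myocardium_mask, lesion_mask, reference_mask):
        if m.shape != pmap.values.shape:
            raise ValueError("mask shape does not match map")
    valid = pmap.valid_mask & myocardium_mask
    if valid.sum() < 100:
        raise ValueError("need >= 100 valid myocardial pixels for the histogram")
    vals = pmap.values[valid]

    mu, sigma, edges, counts = fit_gaussian_to_histogram(vals, bins=bins)
    threshold = mu + 2.0 * sigma

    les_valid = pmap.valid_mask & lesion_mask
    ref_valid = pmap.valid_mask & reference_mask
    area_les = int(les_valid.sum())
    area_ref = int(ref_valid.sum())
    if area_les == 0 or area_ref == 0:
        raise ValueError("lesion/reference region has no valid pixels")
    count_les = int((pmap.values[les_valid] > threshold).sum())
    count_ref = int((pmap.values[ref_valid] > threshold).sum())
    norm_les = count_les / area_les
    norm_ref = count_ref / area_ref
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = norm_les / norm_ref if norm_ref > 0 else float("inf")

    return CountRatioResult(
        mu=mu, sigma=sigma, threshold=threshold,
        count_lesion=count_les, count_reference=count_ref,
        area_lesion=area_les, area_reference=area_ref,
        normalized_lesion=norm_les, normalized_reference=norm_ref,
        ratio=float(ratio), bin_edges=edges, bin_counts=counts,
    )


def _bonferroni(p: float, n_comparisons: int) -> float:
    return min(1.0, p * n_comparisons)


def compare_groups(
    groups: Mapping[str, Sequence[float]],
    test: str = "mannwhitney",
) -> pd.DataFrame:
    """Group-comparison table using standard statistical routines.

    For two groups, ``test`` selects "mannwhitney" (asymptotic normal
    approximation with tie correction, no continuity correction, so
    identical samples give p = 1) or "ttest" (Welch).  For more than two
    groups, ``test="anova"`` runs a one-way ANOVA followed by pairwise
    Welch t-tests with Bonferroni correction (p multiplied by the number of
    comparisons, capped at 1).

    Returns a DataFrame with columns comparison, test, statistic, pvalue,
    pvalue_adjusted.
    """
    names = list(groups)
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for k, v in arrays.items():
        if v.size < 2:
            raise ValueError(f"group {k!r} needs >= 2 observations")
    rows = []
    if test in ("mannwhitney", "ttest"):
        if len(names) != 2:
            raise ValueError(f"{test} requires exactly 2 groups")
        a, b = arrays[names[0]], arrays[names[1]]
        if test == "mannwhitney":
            res = stats.mannwhitneyu(a, b, alternative="two-sided",
                                     method="asymptotic", use_continuity=False)
        else:
            res = stats.ttest_ind(a, b, equal_var=False)
        rows.append({
            "comparison": f"{names[0]} vs {names[1]}", "test": test,
            "statistic": float(res.statistic), "pvalue": float(res.pvalue),
            "pvalue_adjusted": float(res.pvalue),
        })
    elif test == "anova":
        if len(names) < 3:
            raise ValueError("anova requires >= 3 groups")
        res = stats.f_oneway(*[arrays[k] for k in names])
        rows.append({
            "comparison": "overall", "test": "anova",
            "statistic": float(res.statistic), "pvalue": float(res.pvalue),
            "pvalue_adjusted": float(res.pvalue),
        })
        pairs = [(i, j) for i in range(len(names)) for j in range(i + 1, len(names))]
        for i, j in pairs:
            t = stats.ttest_ind(arrays[names[i]], arrays[names[j]], equal_var=False)
            rows.append({
                "comparison": f"{names[i]} vs {names[j]}",
                "test": "ttest_bonferroni",
                "statistic": float(t.statistic), "pvalue": float(t.pvalue),
                "pvalue_adjusted": _bonferroni(float(t.pvalue), len(pairs)),
            })
    else:
        raise ValueError(f"unknown test {test!r}")
    return pd.DataFrame(rows)
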