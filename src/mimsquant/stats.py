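"""Pixel-population statistics: regressions, robust dispersion, percentile subsets.

Each NanoSIMS pixel carries parallel, perfectly colocalized measurements of
several tracers, so intranuclear organization is interrogated with
pixel-population statistics: ordinary least-squares regressions of RNA
enrichment on DNA density (per nucleus), robust dispersion of the pixel
enrichment distribution (median absolute deviation; coefficient of
variation), top-percentile DNA-density subsets, and tidy pulse-chase /
condition summary tables ready for external inference.

Notes on conventions: MAD is the raw median absolute deviation without the
1.4826 normal-consistency constant (it is used comparatively between
distributions, where the constant cancels); COV uses the sample (n-1)
standard deviation; percentile cutoffs use nearest-rank with ties included.
Pixels are treated as independent observations, as is conventional for these
per-nucleus dot plots and regressions; no spatial-autocorrelation correction
is applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .ratios import EnrichmentImage, MassImageStack, RatioDefinition, pooled_roi_ratio, ratio_to_scaled
from .rois import ROI

__all__ = [
    "RegressionResult",
    "DispersionStats",
    "DegenerateDesignError",
    "TopPercentileResult",
    "pixel_regression",
    "dispersion",
    "top_percentile_subset",
    "pulse_chase_table",
    "condition_contrast",
]


class DegenerateDesignError(ValueError):
    """The regressor is constant; a slope cannot be estimated."""


@dataclass
class RegressionResult:
    """OLS fit of y on x over jointly valid masked pixels."""

    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int
    stderr: float
    cell_id: str | None = None

    def slope_ci(self, level: float = 0.95) -> tuple:
        """Two-sided confidence interval for the slope."""
        t = sps.t.ppf(0.5 + level / 2.0, self.n - 2)
        return (self.slope - t * self.stderr, self.slope + t * self.stderr)


@dataclass
class DispersionStats:
    median: float
    mad: float          # raw median absolute deviation (no consistency constant)
    mean: float
    sd: float           # sample SD (n-1); NaN for n = 1
    cov: float | None   # sd/mean; None when mean <= 0 or sd undefined
    n: int


def _values_and_mask(image):
    if isinstance(image, EnrichmentImage):
        return image.values, image.valid_mask
    arr = np.asarray(image, dtype=float)
    return arr, np.isfinite(arr)


def pixel_regression(x, y, mask=None, cell_id: str | None = None) -> RegressionResult:
    """Per-nucleus OLS of tracer y on density proxy x over masked valid pixels.

    ``x`` and ``y`` are EnrichmentImages or plain grids (e.g. a P/S proxy or
    raw Br counts); only pixels valid in both and inside ``mask`` enter the
    fit.  Raises :class:`DegenerateDesignError` when x is constant rather
    than silently reporting a zero slope.
    """
    xv, xm = _values_and_mask(x)
    yv, ym = _values_and_mask(y)
    joint = xm & ym
    if mask is not None:
        joint &= np.asarray(getattr(mask, "mask", mask), dtype=bool)
    xs, ys = xv[joint], yv[joint]
    n = xs.size
    if n < 3:
        raise ValueError(f"need >= 3 jointly valid pixels, have {n}")
    if np.ptp(xs) == 0:
        raise DegenerateDesignError("regressor is constant over the masked pixels")
    if np.ptp(ys) == 0:
        # flat response: slope 0 with no explained variance
        return RegressionResult(
            slope=0.0, intercept=float(ys[0]), r_squared=0.0, p_value=1.0,
            n=int(n), stderr=0.0, cell_id=cell_id,
        )
    fit = sps.linregress(xs, ys)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        p_value=float(fit.pvalue),
        n=int(n),
        stderr=float(fit.stderr),
        cell_id=cell_id,
    )


def dispersion(values, require_cov: bool = False) -> DispersionStats:
    """Robust and classical dispersion of a pixel-enrichment population.

    mad = median(|v - median(v)|), reported raw.  COV = sample SD / mean and
    is defined only for a positive mean; with ``require_cov`` a non-positive
    mean raises instead of yielding ``cov=None``.
    """
    v = np.asarray(values, dtype=float).ravel()
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise ValueError("no finite values")
    med = float(np.median(v))
    mad = float(np.median(np.abs(v - med)))
    mean = float(v.mean())
    sd = float(v.std(ddof=1)) if v.size > 1 else math.nan
    if mean > 0 and v.size > 1:
        cov = sd / mean
    else:
        if require_cov:
            raise ValueError(f"COV undefined: mean = {mean:.4g}, n = {v.size}")
        cov = None
    return DispersionStats(median=med, mad=mad, mean=mean, sd=sd, cov=cov, n=int(v.size))


@dataclass
class TopPercentileResult:
    """Densest-pixel subset and the companion tracer's labeling within it."""

    roi: ROI
    cutoff: float                       # density value at the nearest-rank cutoff
    pct: float
    n_subset: int
    companion_pooled_enrichment_pct: float | None
    companion_pixel_mean_enrichment_pct: float | None
    background_reference_scaled: float  # natural background in the x1e4 convention


def top_percentile_subset(
    density,
    mask,
    pct: float = 5.0,
    stack: MassImageStack | None = None,
    companion_rd: RatioDefinition | None = None,
    min_subset_px: int = 3,
) -> TopPercentileResult:
    """Select the top ``pct`` percent densest masked pixels (nearest rank).

    The cutoff is the k-th largest density with k = ceil(pct * n / 100); all
    pixels tied at the cutoff are included, so the subset may exceed pct * n.
    When a stack and companion ratio definition are supplied, the companion
    tracer's pooled and per-pixel-mean enrichments within the subset are
    reported, along with the companion's natural background on the x10^4
    scale as the reference-line value.
    """
    if not 0 < pct < 100:
        raise ValueError("pct must be in (0, 100)")
    dv, dm = _values_and_mask(density)
    m = dm & np.asarray(getattr(mask, "mask", mask), dtype=bool)
    if not m.any():
        raise ValueError("mask selects no valid pixels")
    vals = dv[m]
    k = math.ceil(pct * vals.size / 100.0)
    cutoff = float(np.partition(vals, vals.size - k)[vals.size - k])
    subset_mask = m & (dv >= cutoff)
    n_subset = int(subset_mask.sum())
    if n_subset < min_subset_px:
        raise ValueError(f"top-percentile subset has only {n_subset} px (< {min_subset_px})")
    roi = ROI(subset_mask, label=f"top_{pct:g}pct_density", kind="custom",
              provenance=f"density >= {cutoff:.4g} (nearest-rank top {pct:g}%)")

    pooled_pct = pixmean_pct = None
    ref = math.nan
    if stack is not None and companion_rd is not None:
        pooled = pooled_roi_ratio(stack, roi, companion_rd)
        pooled_pct = pooled.enrichment_pct
        pixmean_pct = pooled.pixel_mean_enrichment_pct
        ref = ratio_to_scaled(companion_rd.r0)
    return TopPercentileResult(
        roi=roi,
        cutoff=cutoff,
        pct=pct,
        n_subset=n_subset,
        companion_pooled_enrichment_pct=pooled_pct,
        companion_pixel_mean_enrichment_pct=pixmean_pct,
        background_reference_scaled=ref,
    )


def pulse_chase_table(records) -> pd.DataFrame:
    """Summarize per-cell pooled enrichments by timepoint and compartment.

    ``records`` is an iterable of ``(cell_id, timepoint, compartment,
    enrichment_pct)`` tuples (or dicts with those keys).  Returns a tidy
    long-format table with n, mean, sd, se per timepoint x compartment; sd/se
    are NaN for single-cell groups (flagged via n = 1).
    """
    recs = list(records)
    if not recs:
        raise ValueError("no records")
    if not isinstance(recs[0], dict):
        recs = [
            {"cell_id": r[0], "timepoint": r[1], "compartment": r[2], "enrichment_pct": r[3]}
            for r in recs
        ]
    df = pd.DataFrame(recs)
    grouped = (
        df.groupby(["timepoint", "compartment"], sort=True)["enrichment_pct"]
        .agg(n="count", mean="mean", sd=lambda v: v.std(ddof=1))
        .reset_index()
    )
    grouped["se"] = grouped["sd"] / np.sqrt(grouped["n"])
    return grouped


def condition_contrast(groups: dict, reference: str, ci_level: float = 0.95) -> pd.DataFrame:
    """Descriptive per-condition contrast of per-cell mean enrichments.

    Returns each group's n, mean, t-based confidence interval, and percent
    change versus the named reference group.  Inferential testing (ANOVA,
    post-hoc adjustment) is deliberately left to standard external routines
    operating on the exported per-cell tables.
    """
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    if reference not in groups:
        raise KeyError(f"reference group {reference!r} not among {sorted(groups)}")
    ref_mean = float(np.mean(groups[reference]))
    rows = []
    for name, vals in groups.items():
        v = np.asarray(vals, dtype=float)
        if v.size == 0:
            raise ValueError(f"group {name!r} is empty")
        mean = float(v.mean())
        if v.size > 1:
            half = sps.t.ppf(0.5 + ci_level / 2.0, v.size - 1) * v.std(ddof=1) / math.sqrt(v.size)
        else:
            half = math.nan
        rows.append(
            {
                "condition": name,
                "n": int(v.size),
                "mean": mean,
                "ci_low": mean - half,
                "ci_high": mean + half,
                "pct_change_vs_ref": 100.0 * (mean - ref_mean) / ref_mean if ref_mean != 0 else math.nan,
                "reference": reference,
            }
        )
    return pd.DataFrame(rows)
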