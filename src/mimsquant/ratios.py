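"""Isotope-ratio and enrichment arithmetic for ion-count image stacks.

NanoSIMS rasters a focused Cs+ beam over a sample and counts several secondary
ion species in parallel at every pixel.  Incorporation of a stable-isotope
tracer (e.g. 15N-uridine into new RNA) raises the relevant isotope ratio above
its natural background R0, and labeling is conventionally expressed as percent
above that background:

    enrichment(%) = 100 * (R / R0 - 1),      R = numerator / denominator counts

so 0% means natural abundance and 100% means a doubled ratio.  For 15N/14N the
natural background is 0.0037; a ratio of 0.0074 is 100% above background and,
in the "x10^4" display convention used for raw ratios, is written 74.

This module owns the ratio/enrichment transforms, per-pixel ratio images with
low-count masking, pooled region-of-interest ratios with Poisson counting
errors, and the hue-scale (HSI) rendering of enrichment images.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from matplotlib.colors import hsv_to_rgb

__all__ = [
    "R0_15N14N",
    "R0_13C12C_DIMER",
    "R0_2H1H",
    "DEFAULT_MIN_DENOMINATOR",
    "TRACERS",
    "MassImageStack",
    "RatioDefinition",
    "EnrichmentImage",
    "HSIRenderSpec",
    "PooledRatio",
    "MissingSpeciesError",
    "compute_ratio_image",
    "enrichment_from_ratio",
    "ratio_from_enrichment",
    "ratio_to_scaled",
    "enrichment_image",
    "pooled_roi_ratio",
    "ps_ratio_definition",
    "render_hsi",
]

# Natural-abundance background ratios.
R0_15N14N = 0.0037          # 12C15N- / 12C14N-
R0_13C12C_DIMER = 0.0224    # 13C12C- / 12C2-  (two 13C sites in the dimer)
R0_2H1H = 1.56e-4           # 12C2-2H- / 12C2-1H-  (single H site)

#: Pixels whose denominator falls below this count are masked invalid; at 20
#: counts the single-pixel ratio relative SE is already ~22%, and lower
#: denominators let the ratio blow up toward infinity.
DEFAULT_MIN_DENOMINATOR = 20


class MissingSpeciesError(KeyError):
    """A ratio definition references an ion species absent from the stack."""


@dataclass
class MassImageStack:
    """Aligned per-species ion-count grids from one NanoSIMS acquisition.

    Parameters
    ----------
    channels
        Mapping from species name (e.g. ``"12C14N"``) to a 2D grid of
        non-negative integer counts.  All grids must share one shape.
    pixel_size_nm
        Lateral pixel size in nanometres.
    metadata
        Free-form provenance (instrument, seed, scene echo, ...).
    """

    channels: dict
    pixel_size_nm: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("stack must contain at least one channel")
        shapes = {np.asarray(g).shape for g in self.channels.values()}
        if len(shapes) != 1:
            raise ValueError(f"channel grids have differing shapes: {shapes}")
        for name, grid in self.channels.items():
            arr = np.asarray(grid)
            if arr.ndim != 2:
                raise ValueError(f"channel {name!r} is not a 2D grid")
            if not np.issubdtype(arr.dtype, np.integer):
                if not np.all(np.mod(arr, 1) == 0):
                    raise ValueError(f"channel {name!r} has non-integer counts")
                arr = arr.astype(np.int64)
            if (arr < 0).any():
                raise ValueError(f"channel {name!r} has negative counts")
            self.channels[name] = arr
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be positive")

    @property
    def shape(self) -> tuple:
        return next(iter(self.channels.values())).shape

    @property
    def species(self) -> list:
        return list(self.channels)

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.channels[name]
        except KeyError:
            raise MissingSpeciesError(
                f"species {name!r} not in stack (have: {sorted(self.channels)})"
            ) from None


@dataclass(frozen=True)
class RatioDefinition:
    """An isotope pair with its natural background ratio.

    ``r0`` is the ratio of unlabeled material; enrichment is expressed as
    percent above it.  For proxy ratios with no natural background (P/S), r0
    is a within-image reference such as the cytoplasmic median.
    """

    numerator: str
    denominator: str
    r0: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.r0 <= 0:
            raise ValueError(f"natural background r0 must be > 0, got {self.r0}")


#: Canonical tracer definitions used throughout the pipeline.
TRACERS: Mapping[str, RatioDefinition] = {
    "15N_RNA": RatioDefinition("12C15N", "12C14N", R0_15N14N, "15N_RNA"),
    "13C_DNA": RatioDefinition("13C12C", "12C2", R0_13C12C_DIMER, "13C_DNA"),
    "2H_DNA": RatioDefinition("12C2-2H", "12C2-1H", R0_2H1H, "2H_DNA"),
}


@dataclass
class EnrichmentImage:
    """Per-pixel percent-above-background field with a validity mask.

    ``values`` holds 0.0 at invalid pixels; the mask, not the sentinel, is
    authoritative and every downstream statistic excludes invalid pixels.
    """

    values: np.ndarray
    valid_mask: np.ndarray
    ratio_def: RatioDefinition
    min_denominator: int

    @property
    def shape(self) -> tuple:
        return self.values.shape

    def valid_values(self, mask: np.ndarray | None = None) -> np.ndarray:
        """Flat array of valid enrichments, optionally restricted to a mask."""
        m = self.valid_mask if mask is None else (self.valid_mask & np.asarray(mask, bool))
        return self.values[m]


@dataclass(frozen=True)
class HSIRenderSpec:
    """Hue-scale bounds for rendering an enrichment image.

    Hue runs linearly from blue at ``lower_pct`` to red at ``upper_pct``;
    out-of-range values are clamped.  Changing bounds rescales the display
    only — underlying enrichment values are never modified.
    """

    lower_pct: float = 0.0
    upper_pct: float = 100.0

    def __post_init__(self) -> None:
        if self.upper_pct <= self.lower_pct:
            raise ValueError(
                f"upper bound ({self.upper_pct}) must exceed lower ({self.lower_pct})"
            )


def enrichment_from_ratio(ratio, r0: float):
    """Percent above natural background: ``100 * (ratio / r0 - 1)``."""
    if r0 <= 0:
        raise ValueError(f"natural background r0 must be > 0, got {r0}")
    return 100.0 * (np.asarray(ratio, dtype=float) / r0 - 1.0) if np.ndim(ratio) else 100.0 * (ratio / r0 - 1.0)


def ratio_from_enrichment(percent, r0: float):
    """Inverse of :func:`enrichment_from_ratio`: ``r0 * (1 + percent / 100)``."""
    if r0 <= 0:
        raise ValueError(f"natural background r0 must be > 0, got {r0}")
    return r0 * (1.0 + np.asarray(percent, dtype=float) / 100.0) if np.ndim(percent) else r0 * (1.0 + percent / 100.0)


def ratio_to_scaled(ratio):
    """Raw-ratio display convention: ratio x 10^4 (0.0037 is written 37)."""
    return np.asarray(ratio, dtype=float) * 1e4 if np.ndim(ratio) else ratio * 1e4


def compute_ratio_image(
    stack: MassImageStack,
    rd: RatioDefinition,
    min_denominator: int = DEFAULT_MIN_DENOMINATOR,
):
    """Per-pixel numerator/denominator ratio with a low-count validity mask.

    Returns ``(ratio, valid_mask)``.  Pixels whose denominator count falls
    below ``min_denominator`` are invalid and carry 0.0 in the ratio grid;
    no NaN or inf values escape.
    """
    if min_denominator < 1:
        raise ValueError("min_denominator must be >= 1")
    num = stack.channel(rd.numerator).astype(float)
    den = stack.channel(rd.denominator).astype(float)
    valid = den >= min_denominator
    ratio = np.zeros_like(den, dtype=float)
    np.divide(num, den, out=ratio, where=valid)
    return ratio, valid


def enrichment_image(
    stack: MassImageStack,
    rd: RatioDefinition,
    min_denominator: int = DEFAULT_MIN_DENOMINATOR,
) -> EnrichmentImage:
    """Percent-above-background image for one tracer (masked invalid at low counts)."""
    ratio, valid = compute_ratio_image(stack, rd, min_denominator)
    values = np.zeros_like(ratio)
    values[valid] = enrichment_from_ratio(ratio[valid], rd.r0)
    return EnrichmentImage(values, valid, rd, min_denominator)


@dataclass
class PooledRatio:
    """Pooled ROI isotope ratio with Poisson counting error.

    The primary statistic is the ratio of summed counts over the ROI, which is
    robust at low per-pixel counts; the mean of per-pixel ratios is reported
    alongside because pixel-level distributions are also analyzed.  The two
    coincide when the denominator is uniform across the ROI.
    """

    ratio: float
    se: float
    enrichment_pct: float
    enrichment_se_pct: float
    pixel_mean_ratio: float
    pixel_mean_enrichment_pct: float
    n_pixels: int
    num_sum: float
    den_sum: float


def pooled_roi_ratio(
    stack: MassImageStack,
    roi,
    rd: RatioDefinition,
    min_denominator: int = DEFAULT_MIN_DENOMINATOR,
) -> PooledRatio:
    """Ratio of summed counts over an ROI, with its Poisson standard error.

    ``roi`` may be a boolean mask or any object with a boolean ``mask``
    attribute.  SE of the ratio of two independent Poisson sums N/D is
    ``ratio * sqrt(1/N + 1/D)``.
    """
    mask = np.asarray(getattr(roi, "mask", roi), dtype=bool)
    if mask.shape != stack.shape:
        raise ValueError("ROI mask shape does not match stack shape")
    if not mask.any():
        raise ValueError("ROI is empty")
    num = stack.channel(rd.numerator).astype(float)
    den = stack.channel(rd.denominator).astype(float)
    num_sum = float(num[mask].sum())
    den_sum = float(den[mask].sum())
    if den_sum <= 0:
        raise ValueError("ROI denominator counts sum to zero; ratio undefined")
    ratio = num_sum / den_sum
    if num_sum > 0:
        se = ratio * np.sqrt(1.0 / num_sum + 1.0 / den_sum)
    else:
        se = np.nan
    # per-pixel-ratio variant over valid pixels only
    valid = mask & (den >= min_denominator)
    if valid.any():
        pix = num[valid] / den[valid]
        pixel_mean_ratio = float(pix.mean())
    else:
        pixel_mean_ratio = np.nan
    return PooledRatio(
        ratio=ratio,
        se=se,
        enrichment_pct=enrichment_from_ratio(ratio, rd.r0),
        enrichment_se_pct=100.0 * se / rd.r0 if np.isfinite(se) else np.nan,
        pixel_mean_ratio=pixel_mean_ratio,
        pixel_mean_enrichment_pct=(
            enrichment_from_ratio(pixel_mean_ratio, rd.r0)
            if np.isfinite(pixel_mean_ratio)
            else np.nan
        ),
        n_pixels=int(mask.sum()),
        num_sum=num_sum,
        den_sum=den_sum,
    )


def ps_ratio_definition(
    stack: MassImageStack,
    cytoplasm_mask,
    min_denominator: int = DEFAULT_MIN_DENOMINATOR,
) -> RatioDefinition:
    """P/S DNA-density proxy anchored to the cytoplasmic median.

    Chromatin is phosphorus-rich and sulfur-poor, so the 31P/32S ratio tracks
    DNA density; it has no natural-abundance background, so the per-image
    cytoplasmic median P/S serves as the 0% reference and the proxy is used
    ordinally within an image.
    """
    mask = np.asarray(getattr(cytoplasm_mask, "mask", cytoplasm_mask), dtype=bool)
    p = stack.channel("31P").astype(float)
    s = stack.channel("32S").astype(float)
    valid = mask & (s >= min_denominator)
    if not valid.any():
        raise ValueError("no valid cytoplasmic pixels to anchor the P/S reference")
    r0 = float(np.median(p[valid] / s[valid]))
    if r0 <= 0:
        raise ValueError("cytoplasmic median P/S is not positive")
    return RatioDefinition("31P", "32S", r0, "PS_density")


def render_hsi(
    enr: EnrichmentImage,
    spec: HSIRenderSpec,
    intensity: np.ndarray | None = None,
) -> np.ndarray:
    """Render an enrichment image on the blue-to-red hue scale.

    Hue varies linearly from blue at/below the lower bound to red at/above the
    upper bound (values clamp; they are never modified).  Invalid pixels are
    black.  ``intensity``, if given (typically the denominator count image),
    modulates brightness after normalization to its 98th percentile.

    Returns an (H, W, 3) float RGB array in [0, 1].
    """
    t = (enr.values - spec.lower_pct) / (spec.upper_pct - spec.lower_pct)
    t = np.clip(t, 0.0, 1.0)
    hsv = np.zeros(enr.shape + (3,), dtype=float)
    hsv[..., 0] = (1.0 - t) * (240.0 / 360.0)  # blue -> red
    hsv[..., 1] = 1.0
    if intensity is not None:
        scale = np.percentile(intensity, 98)
        if scale <= 0:
            warnings.warn("intensity image is all zero; rendering at full brightness")
            hsv[..., 2] = 1.0
        else:
            hsv[..., 2] = np.clip(np.asarray(intensity, float) / scale, 0.0, 1.0)
    else:
        hsv[..., 2] = 1.0
    rgb = hsv_to_rgb(hsv)
    rgb[~enr.valid_mask] = 0.0
    return rgb
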