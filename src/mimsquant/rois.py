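"""Nuclear compartment segmentation, line profiles, and laminar silencing metrics.

Structural ion channels (32S marks cell material, 31P is chromatin-rich, CN-
emission is intense in nucleic-acid-dense regions) guide the delineation of
the nucleus and cytoplasm; enrichment images locate nucleoli and trace
label-guided nuclear borders.  The laminar silencing metric compares the
nuclear area traced from the DNA label with the area traced from the RNA
label:

    area (% unlabeled) = 100 * (DNA area - RNA area) / DNA area

a positive value meaning an RNA-silent rim inside the DNA-defined border.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as sk_label, regionprops

from .ratios import EnrichmentImage, MassImageStack

__all__ = [
    "ROI",
    "LineProfile",
    "SegmentationError",
    "SEGMENTATION_CHANNELS",
    "segment_nucleus",
    "segment_nuclei",
    "cytoplasm_roi",
    "roi_from_enrichment_threshold",
    "line_profile",
    "unlabeled_margin_fraction",
    "nucleolus_detect",
    "fold_enrichment",
]

ROI_KINDS = {"nucleus", "cytoplasm", "nucleolus", "lamina_margin", "hotspot", "custom"}


class SegmentationError(RuntimeError):
    """No acceptable structure could be segmented from the channel."""


@dataclass
class ROI:
    """A labeled pixel set on the acquisition grid."""

    mask: np.ndarray
    label: str
    kind: str = "custom"
    provenance: str = ""

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.kind not in ROI_KINDS:
            raise ValueError(f"kind must be one of {sorted(ROI_KINDS)}, got {self.kind!r}")
        if not self.mask.any():
            raise ValueError(f"ROI {self.label!r} is empty")

    @property
    def area_px(self) -> int:
        return int(self.mask.sum())

    def area_um2(self, pixel_size_nm: float) -> float:
        return self.area_px * (pixel_size_nm / 1000.0) ** 2


@dataclass
class LineProfile:
    """Per-position channel values sampled along a polyline."""

    positions_px: np.ndarray          # distance along the path, 1 px steps
    samples: dict                     # channel name -> value array (NaN where no valid pixel)
    width_px: int
    spacing_nm: float
    polyline: list = field(default_factory=list)


#: Channel used by each nucleus-segmentation strategy.
SEGMENTATION_CHANNELS = {
    "P_threshold": "31P",
    "S_contour": "32S",
    "CN_contour": "12C14N",
}


def _bright_components(channel: np.ndarray, smooth_sigma: float):
    """Otsu split of a (smoothed) channel into bright connected components."""
    img = ndimage.gaussian_filter(np.asarray(channel, dtype=float), smooth_sigma)
    if img.max() <= img.min():
        raise SegmentationError("channel is constant; nothing to segment")
    thr = threshold_otsu(img)
    binary = ndimage.binary_fill_holes(img > thr)
    return sk_label(binary, connectivity=2)


def segment_nucleus(
    stack: MassImageStack,
    strategy: str = "P_threshold",
    min_area_px: int = 50,
    smooth_sigma: float = 1.0,
) -> ROI:
    """Segment the (largest) nucleus from a structural channel.

    The strategy names the guiding channel (31P, 32S, or CN); the threshold is
    an automatic bimodal (Otsu) split, so segmentation is invariant to
    multiplying the channel by a positive constant.  Holes are filled and the
    largest connected component at least ``min_area_px`` is returned.

    Note the 32S strategy outlines whatever is brightest in sulfur — often the
    whole cell rather than the nucleus alone; 31P or CN are the reliable
    nuclear guides on phosphorus-rich nuclei.
    """
    rois = segment_nuclei(stack, strategy, min_area_px, smooth_sigma, max_instances=1)
    return rois[0]


def segment_nuclei(
    stack: MassImageStack,
    strategy: str = "P_threshold",
    min_area_px: int = 50,
    smooth_sigma: float = 1.0,
    max_instances: int | None = None,
) -> list:
    """Multi-instance variant: all sufficiently large bright components, largest first."""
    if strategy not in SEGMENTATION_CHANNELS:
        raise ValueError(f"unknown strategy {strategy!r}; choose from {sorted(SEGMENTATION_CHANNELS)}")
    channel = stack.channel(SEGMENTATION_CHANNELS[strategy])
    try:
        labels = _bright_components(channel, smooth_sigma)
    except SegmentationError:
        raise SegmentationError(f"segmentation failed on channel {SEGMENTATION_CHANNELS[strategy]!r}")
    sizes = np.bincount(labels.ravel())
    order = [i for i in np.argsort(sizes)[::-1] if i != 0 and sizes[i] >= min_area_px]
    if not order:
        raise SegmentationError(
            f"no component >= {min_area_px} px on channel {SEGMENTATION_CHANNELS[strategy]!r}"
        )
    if max_instances is not None:
        order = order[:max_instances]
    return [
        ROI(
            mask=labels == idx,
            label=f"nucleus_{rank}",
            kind="nucleus",
            provenance=f"{strategy} on {SEGMENTATION_CHANNELS[strategy]} (otsu, sigma={smooth_sigma})",
        )
        for rank, idx in enumerate(order, start=1)
    ]


def cytoplasm_roi(cell: ROI, nucleus: ROI, label: str = "cytoplasm") -> ROI:
    """Cell-minus-nucleus ROI."""
    mask = cell.mask & ~nucleus.mask
    return ROI(mask, label, kind="cytoplasm", provenance=f"{cell.label} minus {nucleus.label}")


def roi_from_enrichment_threshold(
    enr: EnrichmentImage,
    level_pct: float = 30.0,
    smooth_sigma: float = 1.5,
    min_area_px: int = 50,
    label: str = "labeled_area",
    kind: str = "custom",
) -> ROI:
    """Label-guided border: the largest region above a fixed enrichment level.

    Emulates tracing a nuclear border guided by one tracer's labeling: the
    enrichment image is smoothed (mask-aware, so invalid pixels neither leak
    in nor bias the average), thresholded at ``level_pct`` percent above
    background, hole-filled, and the largest component returned.
    """
    values = np.where(enr.valid_mask, enr.values, 0.0)
    weight = enr.valid_mask.astype(float)
    if smooth_sigma > 0:
        num = ndimage.gaussian_filter(values, smooth_sigma)
        den = ndimage.gaussian_filter(weight, smooth_sigma)
        with np.errstate(invalid="ignore"):
            smoothed = np.where(den > 1e-9, num / np.maximum(den, 1e-9), 0.0)
    else:
        smoothed = values
    binary = ndimage.binary_fill_holes(smoothed >= level_pct)
    labels = sk_label(binary, connectivity=2)
    sizes = np.bincount(labels.ravel())
    order = [i for i in np.argsort(sizes)[::-1] if i != 0 and sizes[i] >= min_area_px]
    if not order:
        raise SegmentationError(f"no region >= {min_area_px} px above {level_pct}% enrichment")
    return ROI(
        labels == order[0],
        label,
        kind=kind,
        provenance=f"{enr.ratio_def.label} >= {level_pct}% (sigma={smooth_sigma})",
    )


def _as_grid_and_mask(image):
    if isinstance(image, EnrichmentImage):
        return image.values, image.valid_mask
    arr = np.asarray(image, dtype=float)
    return arr, np.ones(arr.shape, dtype=bool)


def line_profile(
    images: dict,
    polyline,
    width_px: int = 1,
    pixel_size_nm: float = 1.0,
) -> LineProfile:
    """Sample channels along a polyline, averaging over a perpendicular width.

    ``images`` maps channel names to EnrichmentImages or plain grids.
    Positions step at 1 px along the path; each sample is the mean over
    ``width_px`` nearest pixels perpendicular to the local direction, using
    valid pixels only (a sample with no valid pixel is NaN).  The polyline
    must stay inside the image.
    """
    if width_px < 1:
        raise ValueError("width_px must be >= 1")
    pts = np.asarray(polyline, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2 or pts.shape[1] != 2:
        raise ValueError("polyline must be a sequence of >= 2 (row, col) points")
    grids = {name: _as_grid_and_mask(img) for name, img in images.items()}
    shape = next(iter(grids.values()))[0].shape
    if (pts < -0.5).any() or (pts[:, 0] > shape[0] - 0.5).any() or (pts[:, 1] > shape[1] - 0.5).any():
        raise ValueError("polyline exits the image")

    # resample the path at 1 px arc-length steps
    seg = np.diff(pts, axis=0)
    seg_len = np.hypot(seg[:, 0], seg[:, 1])
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    total = cum[-1]
    if total <= 0:
        raise ValueError("polyline has zero length")
    positions = np.arange(0.0, total + 1e-9, 1.0)
    centers = np.empty((len(positions), 2))
    directions = np.empty((len(positions), 2))
    for i, s in enumerate(positions):
        j = min(np.searchsorted(cum, s, side="right") - 1, len(seg) - 1)
        frac = (s - cum[j]) / seg_len[j] if seg_len[j] > 0 else 0.0
        centers[i] = pts[j] + frac * seg[j]
        directions[i] = seg[j] / seg_len[j] if seg_len[j] > 0 else (1.0, 0.0)

    normals = np.stack([-directions[:, 1], directions[:, 0]], axis=1)
    offsets = np.arange(width_px, dtype=float) - (width_px - 1) / 2.0

    samples = {name: np.full(len(positions), np.nan) for name in grids}
    for i in range(len(positions)):
        px = np.rint(centers[i] + offsets[:, None] * normals[i]).astype(int)
        px[:, 0] = np.clip(px[:, 0], 0, shape[0] - 1)
        px[:, 1] = np.clip(px[:, 1], 0, shape[1] - 1)
        for name, (grid, mask) in grids.items():
            ok = mask[px[:, 0], px[:, 1]]
            if ok.any():
                samples[name][i] = grid[px[ok, 0], px[ok, 1]].mean()

    return LineProfile(
        positions_px=positions,
        samples=samples,
        width_px=width_px,
        spacing_nm=pixel_size_nm,
        polyline=[tuple(p) for p in pts],
    )


def unlabeled_margin_fraction(dna_roi: ROI, rna_roi: ROI) -> float:
    """Laminar silencing metric: 100 * (DNA area - RNA area) / DNA area.

    Negative values (RNA-guided area exceeding the DNA-guided area) are
    reported as-is with a warning, never clamped.
    """
    if dna_roi.mask.shape != rna_roi.mask.shape:
        raise ValueError("ROIs live on different grids")
    dna_area = dna_roi.area_px
    if dna_area == 0:
        raise ValueError("DNA-guided ROI is empty")
    pct = 100.0 * (dna_area - rna_roi.area_px) / dna_area
    if pct < 0:
        warnings.warn(
            f"RNA-guided area ({rna_roi.area_px} px) exceeds DNA-guided area "
            f"({dna_area} px): unlabeled margin fraction is negative ({pct:.2f}%)"
        )
    return pct


def nucleolus_detect(
    rna_enr: EnrichmentImage,
    nucleus: ROI,
    pixel_size_nm: float,
    min_diameter_um: float = 1.0,
    max_diameter_um: float = 3.0,
    fold_threshold: float = 2.0,
    smooth_sigma: float = 1.0,
) -> list:
    """Find putative nucleoli: bright compact RNA-label bodies inside the nucleus.

    Candidate pixels exceed ``fold_threshold`` times the mean nuclear
    enrichment (on a lightly smoothed image); connected components whose
    equivalent diameter falls in the 1-3 um nucleolar range are returned as
    disjoint ROIs strictly inside the nucleus.  An empty list is a valid
    outcome.  The union of the returned masks is the nucleolar exclusion mask
    used by non-nucleolar hotspot and regression analyses.
    """
    nuc = nucleus.mask
    valid = rna_enr.valid_mask & nuc
    if not valid.any():
        return []
    nuclear_mean = rna_enr.values[valid].mean()
    if nuclear_mean <= 0:
        return []

    values = np.where(rna_enr.valid_mask, rna_enr.values, 0.0)
    if smooth_sigma > 0:
        w = rna_enr.valid_mask.astype(float)
        num = ndimage.gaussian_filter(values, smooth_sigma)
        den = np.maximum(ndimage.gaussian_filter(w, smooth_sigma), 1e-9)
        values = num / den

    candidate = (values >= fold_threshold * nuclear_mean) & nuc & rna_enr.valid_mask
    labels = sk_label(candidate, connectivity=2)
    px_um = pixel_size_nm / 1000.0
    out = []
    for prop in regionprops(labels):
        diam_um = prop.equivalent_diameter_area * px_um
        if min_diameter_um <= diam_um <= max_diameter_um:
            mask = labels == prop.label
            out.append(
                ROI(
                    mask,
                    label=f"nucleolus_{len(out) + 1}",
                    kind="nucleolus",
                    provenance=(
                        f">= {fold_threshold}x nuclear mean "
                        f"({nuclear_mean:.1f}%), diameter {diam_um:.2f} um"
                    ),
                )
            )
    return out


def fold_enrichment(target: ROI, reference: ROI, enr: EnrichmentImage) -> float:
    """Mean valid-pixel enrichment of target divided by that of reference.

    Reported only when the reference enrichment is positive (a non-positive
    reference mean makes the fold undefined and raises).
    """
    t_vals = enr.valid_values(target.mask)
    r_vals = enr.valid_values(reference.mask)
    if t_vals.size == 0 or r_vals.size == 0:
        raise ValueError("target or reference ROI has no valid pixels")
    ref_mean = r_vals.mean()
    if ref_mean <= 0:
        raise ValueError(f"reference mean enrichment is not positive ({ref_mean:.3f}%)")
    return float(t_vals.mean() / ref_mean)
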