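"""Lossless on-disk formats: TIFF stacks with JSON sidecars, masks, tables.

A mass-image stack is stored as a multi-page 32-bit integer TIFF (one page
per species) plus a ``<stem>.json`` sidecar carrying species names (in page
order), pixel size and provenance.  Compartment maps and ROI masks are 8-bit
label TIFFs with JSON legends.  Enrichment images are 32-bit float TIFFs with
a companion mask TIFF.  All round-trips are exact.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .ratios import EnrichmentImage, MassImageStack, RatioDefinition
from .rois import ROI

__all__ = [
    "FormatError",
    "save_stack",
    "load_stack",
    "save_compartment_map",
    "load_compartment_map",
    "save_enrichment",
    "load_enrichment",
    "save_roi",
    "load_roi",
]


class FormatError(ValueError):
    """An on-disk stack or sidecar violates the format contract."""


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def save_stack(stack: MassImageStack, path) -> Path:
    """Write a stack as multi-page int32 TIFF + JSON sidecar; returns the TIFF path."""
    path = Path(path)
    species = list(stack.channels)
    pages = np.stack([stack.channels[sp] for sp in species]).astype(np.int32)
    tifffile.imwrite(path, pages, photometric="minisblack")
    meta = {
        "species": species,
        "pixel_size_nm": stack.pixel_size_nm,
        "metadata": stack.metadata,
    }
    _sidecar(path).write_text(json.dumps(meta, indent=1, default=str))
    return path


def load_stack(path) -> MassImageStack:
    """Read a stack written by :func:`save_stack`, validating the format contract."""
    path = Path(path)
    side = _sidecar(path)
    if not side.exists():
        raise FormatError(f"missing JSON sidecar {side}")
    meta = json.loads(side.read_text())
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    species = meta.get("species")
    if not species:
        raise FormatError(f"sidecar {side} lists no species")
    if len(species) != pages.shape[0]:
        raise FormatError(
            f"sidecar lists {len(species)} species but TIFF has {pages.shape[0]} pages"
        )
    if not np.issubdtype(pages.dtype, np.integer):
        if not np.all(np.mod(pages, 1) == 0):
            raise FormatError("TIFF pages contain non-integer counts")
        pages = pages.astype(np.int64)
    if (pages < 0).any():
        raise FormatError("TIFF pages contain negative counts")
    return MassImageStack(
        channels={sp: pages[i] for i, sp in enumerate(species)},
        pixel_size_nm=float(meta["pixel_size_nm"]),
        metadata=meta.get("metadata", {}),
    )


def save_compartment_map(cmap: np.ndarray, legend: dict, path) -> Path:
    """8-bit label TIFF + JSON legend (name -> code)."""
    path = Path(path)
    tifffile.imwrite(path, np.asarray(cmap, dtype=np.uint8))
    _sidecar(path).write_text(json.dumps({"legend": legend}, indent=1))
    return path


def load_compartment_map(path):
    path = Path(path)
    side = _sidecar(path)
    if not side.exists():
        raise FormatError(f"missing JSON legend {side}")
    legend = json.loads(side.read_text())["legend"]
    return tifffile.imread(path), legend


def save_enrichment(enr: EnrichmentImage, path) -> Path:
    """32-bit float value TIFF + mask TIFF + JSON (ratio definition, threshold)."""
    path = Path(path)
    tifffile.imwrite(path, enr.values.astype(np.float32))
    mask_path = path.with_name(path.stem + "_mask" + path.suffix)
    tifffile.imwrite(mask_path, enr.valid_mask.astype(np.uint8))
    meta = {
        "numerator": enr.ratio_def.numerator,
        "denominator": enr.ratio_def.denominator,
        "r0": enr.ratio_def.r0,
        "label": enr.ratio_def.label,
        "min_denominator": enr.min_denominator,
    }
    _sidecar(path).write_text(json.dumps(meta, indent=1))
    return path


def load_enrichment(path) -> EnrichmentImage:
    path = Path(path)
    meta = json.loads(_sidecar(path).read_text())
    values = tifffile.imread(path).astype(float)
    mask = tifffile.imread(path.with_name(path.stem + "_mask" + path.suffix)).astype(bool)
    rd = RatioDefinition(meta["numerator"], meta["denominator"], meta["r0"], meta["label"])
    return EnrichmentImage(values, mask, rd, int(meta["min_denominator"]))


def save_roi(roi: ROI, path) -> Path:
    path = Path(path)
    tifffile.imwrite(path, roi.mask.astype(np.uint8))
    meta = {"label": roi.label, "kind": roi.kind, "provenance": roi.provenance}
    _sidecar(path).write_text(json.dumps(meta, indent=1))
    return path


def load_roi(path) -> ROI:
    path = Path(path)
    side = _sidecar(path)
    if not side.exists():
        raise FormatError(f"missing JSON metadata {side}")
    meta = json.loads(side.read_text())
    mask = tifffile.imread(path).astype(bool)
    return ROI(mask, meta["label"], meta["kind"], meta.get("provenance", ""))
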