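"""Automated top-N square-window hotspot detection ranked by isotope ratio.

A hotspot is a small square window (default 4x4 px) ranked among the top N by
the pooled isotope ratio of the ion counts it contains.  Because the mass
channels are acquired in parallel from the same sputtered nanovolumes, the
complementary tracer's ratio over the identical window pixels is perfectly
colocalized and can be extracted directly for every hotspot.

Candidate windows must lie wholly inside the search region (e.g. the nucleus)
and must not touch the exclusion region (e.g. putative nucleoli).  Under the
default ``disjoint`` overlap policy, windows are selected greedily by
descending score, skipping any window overlapping an already accepted one —
otherwise the top N would be N near-copies of the single global maximum.
Ties break toward the higher total denominator count, then row-major origin
order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ratios import MassImageStack, RatioDefinition, enrichment_from_ratio

__all__ = ["Hotspot", "detect_hotspots", "colocalize_hotspots", "hotspot_overlay", "hotspot_table"]


@dataclass
class Hotspot:
    """One ranked square window."""

    origin: tuple            # (row, col) of the window's top-left pixel
    size: int                # lateral dimension in px
    rank: int                # 1-based, dense
    window_ratio: float      # pooled ratio of summed counts in the window
    window_enrichment_pct: float
    num_sum: float
    den_sum: float
    complementary_ratio: float | None = None
    complementary_enrichment_pct: float | None = None

    def window_mask(self, shape: tuple) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        r, c = self.origin
        m[r : r + self.size, c : c + self.size] = True
        return m


def _window_sums(grid: np.ndarray, w: int) -> np.ndarray:
    """Sum of every w x w window (via an integral image); shape (H-w+1, W-w+1)."""
    ii = np.zeros((grid.shape[0] + 1, grid.shape[1] + 1), dtype=float)
    ii[1:, 1:] = np.cumsum(np.cumsum(np.asarray(grid, dtype=float), axis=0), axis=1)
    return ii[w:, w:] - ii[:-w, w:] - ii[w:, :-w] + ii[:-w, :-w]


def detect_hotspots(
    stack: MassImageStack,
    rd: RatioDefinition,
    window: int = 4,
    top_n: int = 20,
    search_mask=None,
    exclusion_mask=None,
    overlap_policy: str = "disjoint",
) -> list:
    """Top-N square windows ranked by pooled isotope ratio.

    Parameters
    ----------
    search_mask
        Boolean mask (or ROI); candidate windows must lie wholly inside it.
        Defaults to the full image.
    exclusion_mask
        Optional mask (or ROI); candidates intersecting it are discarded.
    overlap_policy
        ``"disjoint"`` (default): greedy selection by descending score,
        skipping windows that overlap an accepted one.  ``"free"``: the N
        best-scoring windows regardless of overlap.

    Returns up to ``top_n`` hotspots with dense ranks 1..N; fewer if the
    geometry admits fewer windows.  Windows with zero denominator counts are
    not rankable and are dropped.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    if overlap_policy not in ("disjoint", "free"):
        raise ValueError(f"unknown overlap_policy {overlap_policy!r}")

    num = stack.channel(rd.numerator)
    den = stack.channel(rd.denominator)
    shape = num.shape
    if search_mask is None:
        search = np.ones(shape, dtype=bool)
    else:
        search = np.asarray(getattr(search_mask, "mask", search_mask), dtype=bool)
    if not search.any():
        raise ValueError("search mask is empty")
    rows = np.where(search.any(axis=1))[0]
    cols = np.where(search.any(axis=0))[0]
    if rows[-1] - rows[0] + 1 < window or cols[-1] - cols[0] + 1 < window:
        raise ValueError(f"window ({window} px) larger than the search-mask extent")

    num_s = _window_sums(num, window)
    den_s = _window_sums(den, window)
    inside = _window_sums(search, window) >= window * window - 0.5
    if exclusion_mask is not None:
        excl = np.asarray(getattr(exclusion_mask, "mask", exclusion_mask), dtype=bool)
        inside &= _window_sums(excl, window) < 0.5
    candidate = inside & (den_s > 0)
    if not candidate.any():
        return []

    cr, cc = np.nonzero(candidate)
    score = num_s[cr, cc] / den_s[cr, cc]
    # descending score, then descending denominator sum, then row-major origin
    order = np.lexsort((cc, cr, -den_s[cr, cc], -score))

    selected = []
    if overlap_policy == "free":
        chosen = order[:top_n]
    else:
        occupied = np.zeros(shape, dtype=bool)
        chosen = []
        for idx in order:
            r, c = int(cr[idx]), int(cc[idx])
            if occupied[r : r + window, c : c + window].any():
                continue
            occupied[r : r + window, c : c + window] = True
            chosen.append(idx)
            if len(chosen) == top_n:
                break
    for rank, idx in enumerate(chosen, start=1):
        r, c = int(cr[idx]), int(cc[idx])
        ratio = float(score[idx])
        selected.append(
            Hotspot(
                origin=(r, c),
                size=window,
                rank=rank,
                window_ratio=ratio,
                window_enrichment_pct=enrichment_from_ratio(ratio, rd.r0),
                num_sum=float(num_s[r, c]),
                den_sum=float(den_s[r, c]),
            )
        )
    return selected


def colocalize_hotspots(
    hotspots: list,
    other_rd: RatioDefinition,
    stack: MassImageStack,
    nucleus_mask=None,
) -> tuple:
    """Fill each hotspot's complementary-tracer enrichment over its own pixels.

    The complementary ratio is pooled over exactly the window pixels (the two
    tracers are measured in parallel from the same nanovolumes, so the
    colocalization is exact by construction).  Returns ``(hotspots,
    nuclear_mean_enrichment)`` where the nuclear mean (the red reference line
    of the figure convention) is the pooled complementary enrichment over
    ``nucleus_mask``, or None when no mask is given.
    """
    num = stack.channel(other_rd.numerator).astype(float)
    den = stack.channel(other_rd.denominator).astype(float)
    for h in hotspots:
        r, c = h.origin
        n = num[r : r + h.size, c : c + h.size].sum()
        d = den[r : r + h.size, c : c + h.size].sum()
        if d <= 0:
            h.complementary_ratio = np.nan
            h.complementary_enrichment_pct = np.nan
        else:
            h.complementary_ratio = float(n / d)
            h.complementary_enrichment_pct = enrichment_from_ratio(n / d, other_rd.r0)
    nuclear_mean = None
    if nucleus_mask is not None:
        mask = np.asarray(getattr(nucleus_mask, "mask", nucleus_mask), dtype=bool)
        n, d = num[mask].sum(), den[mask].sum()
        if d > 0:
            nuclear_mean = enrichment_from_ratio(n / d, other_rd.r0)
    return hotspots, nuclear_mean


def hotspot_overlay(
    hotspots: list,
    base_image: np.ndarray,
    color=(0.0, 1.0, 0.0),
) -> np.ndarray:
    """Draw 1-px square outlines at hotspot positions on an RGB image (pure view)."""
    rgb = np.asarray(base_image, dtype=float)
    if rgb.ndim == 2:
        rgb = np.stack([rgb] * 3, axis=-1)
    out = rgb.copy()
    for h in hotspots:
        r, c = h.origin
        r2, c2 = r + h.size - 1, c + h.size - 1
        out[r, c : c2 + 1] = color
        out[r2, c : c2 + 1] = color
        out[r : r2 + 1, c] = color
        out[r : r2 + 1, c2] = color
    return out


def hotspot_table(hotspots: list, nuclear_mean_pct: float | None = None) -> pd.DataFrame:
    """Tidy export: one row per hotspot with both tracers' enrichments."""
    rows = [
        {
            "rank": h.rank,
            "origin_row": h.origin[0],
            "origin_col": h.origin[1],
            "size_px": h.size,
            "primary_ratio": h.window_ratio,
            "primary_enrichment_pct": h.window_enrichment_pct,
            "complementary_enrichment_pct": h.complementary_enrichment_pct,
            "nuclear_mean_pct": nuclear_mean_pct,
        }
        for h in hotspots
    ]
    return pd.DataFrame(rows)
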