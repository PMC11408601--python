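"""Hotspot detection against a brute-force enumeration oracle, plus colocalization."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mimsquant import (
    RatioDefinition,
    TRACERS,
    colocalize_hotspots,
    detect_hotspots,
    hotspot_overlay,
)

from conftest import make_stack

RD = TRACERS["15N_RNA"]


def brute_force_hotspots(num, den, window, top_n, search, exclusion=None, policy="disjoint"):
    """Independent oracle: enumerate every window, filter, sort, greedily select.

    Returns a list of (origin, ratio) in rank order.
    """
    h, w = num.shape
    candidates = []
    for r in range(h - window + 1):
        for c in range(w - window + 1):
            block = np.s_[r : r + window, c : c + window]
            if not search[block].all():
                continue
            if exclusion is not None and exclusion[block].any():
                continue
            d = den[block].sum()
            if d <= 0:
                continue
            n = num[block].sum()
            candidates.append((r, c, n / d, d))
    candidates.sort(key=lambda t: (-t[2], -t[3], t[0], t[1]))
    if policy == "free":
        chosen = candidates[:top_n]
    else:
        chosen = []
        for r, c, ratio, d in candidates:
            if any(abs(r - r2) < window and abs(c - c2) < window for r2, c2, *_ in chosen):
                continue
            chosen.append((r, c, ratio, d))
            if len(chosen) == top_n:
                break
    return [((r, c), ratio) for r, c, ratio, _ in chosen]


def _random_instance(seed, shape=(32, 32)):
    rng = np.random.default_rng(seed)
    den = rng.poisson(100, size=shape)
    num = rng.poisson(2.0, size=shape)
    search = np.ones(shape, bool)
    # random rectangular search region and a random exclusion blob
    r0, c0 = rng.integers(0, 8, 2)
    r1, c1 = rng.integers(24, 32, 2)
    search[:r0], search[r1:] = False, False
    search[:, :c0], search[:, c1:] = False, False
    excl = np.zeros(shape, bool)
    er, ec = rng.integers(8, 20, 2)
    excl[er : er + 4, ec : ec + 4] = True
    return num, den, search, excl


class TestDetectHotspots:
    def test_single_bright_block_found(self):
        """8x8 field with one 4x4 block at ratio 0.40 over 0.01 background."""
        num = np.ones((8, 8), int)
        den = np.full((8, 8), 100, int)
        num[2:6, 3:7] = 40
        stack = make_stack({"12C15N": num, "12C14N": den})
        spots = detect_hotspots(stack, RD, window=4, top_n=1)
        assert spots[0].origin == (2, 3)
        assert spots[0].window_ratio == pytest.approx(0.40)
        # cross-check against the exhaustive oracle over all 25 windows
        oracle = brute_force_hotspots(num, den, 4, 1, np.ones((8, 8), bool))
        assert oracle[0] == ((2, 3), pytest.approx(0.40))

    def test_uniform_ties_break_row_major(self):
        num = np.full((10, 10), 5, int)
        den = np.full((10, 10), 100, int)
        stack = make_stack({"12C15N": num, "12C14N": den})
        spots = detect_hotspots(stack, RD, window=4, top_n=3)
        assert spots[0].origin == (0, 0)
        # disjoint greedy then skips overlapping windows in row-major order
        assert spots[1].origin == (0, 4)

    @pytest.mark.parametrize("policy", ["disjoint", "free"])
    def test_matches_brute_force_oracle(self, policy):
        for seed in range(30):
            num, den, search, excl = _random_instance(seed)
            stack = make_stack({"12C15N": num, "12C14N": den})
            got = detect_hotspots(
                stack, RD, window=4, top_n=5, search_mask=search,
                exclusion_mask=excl, overlap_policy=policy,
            )
            expected = brute_force_hotspots(num, den, 4, 5, search, excl, policy)
            assert [h.origin for h in got] == [o for o, _ in expected]
            for h, (_, ratio) in zip(got, expected):
                assert h.window_ratio == pytest.approx(ratio)

    def test_prefix_stability(self):
        num, den, search, excl = _random_instance(99)
        stack = make_stack({"12C15N": num, "12C14N": den})
        top3 = detect_hotspots(stack, RD, window=4, top_n=3, search_mask=search)
        top8 = detect_hotspots(stack, RD, window=4, top_n=8, search_mask=search)
        assert [h.origin for h in top3] == [h.origin for h in top8[:3]]

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_exclusion_and_disjointness_properties(self, seed):
        num, den, search, excl = _random_instance(seed)
        stack = make_stack({"12C15N": num, "12C14N": den})
        spots = detect_hotspots(
            stack, RD, window=4, top_n=10, search_mask=search, exclusion_mask=excl
        )
        shape = num.shape
        ranks = [h.rank for h in spots]
        assert ranks == list(range(1, len(spots) + 1))
        occupancy = np.zeros(shape, int)
        for h in spots:
            m = h.window_mask(shape)
            assert not (m & excl).any()          # exclusion correctness
            assert (m <= search).all()           # wholly inside search mask
            occupancy += m
        assert occupancy.max() <= 1              # pairwise disjoint

    def test_window_larger_than_mask_extent(self):
        num = np.ones((10, 10), int)
        den = np.full((10, 10), 100, int)
        stack = make_stack({"12C15N": num, "12C14N": den})
        mask = np.zeros((10, 10), bool)
        mask[4:6, 4:6] = True
        with pytest.raises(ValueError, match="larger than"):
            detect_hotspots(stack, RD, window=4, top_n=1, search_mask=mask)


class TestColocalize:
    def test_background_complementary_is_zero(self):
        rng = np.random.default_rng(0)
        num = rng.poisson(5, size=(16, 16))
        den = np.full((16, 16), 1000, int)
        # complementary channel exactly at natural background everywhere
        c_den = np.full((16, 16), 10_000, int)
        c_num = np.full((16, 16), 37, int)
        stack = make_stack(
            {"12C15N": num, "12C14N": den, "13C12C": c_num, "12C2": c_den}
        )
        rd2 = RatioDefinition("13C12C", "12C2", 37 / 10_000, "13C_DNA")
        spots = detect_hotspots(stack, RD, window=4, top_n=5)
        spots, nuclear_mean = colocalize_hotspots(spots, rd2, stack, np.ones((16, 16), bool))
        for h in spots:
            assert h.complementary_enrichment_pct == pytest.approx(0.0, abs=1e-9)
        assert nuclear_mean == pytest.approx(0.0, abs=1e-9)

    def test_lamina_window_complementary_enrichment(self, flat_truth, flat_stack):
        """A hotspot restricted to the silent laminar rim shows ~200% DNA and ~0% RNA."""
        lamina = flat_truth.compartment_mask("lamina")
        spots = detect_hotspots(
            flat_stack, TRACERS["13C_DNA"], window=2, top_n=1, search_mask=lamina
        )
        spots, _ = colocalize_hotspots(spots, TRACERS["15N_RNA"], flat_stack)
        assert spots[0].window_enrichment_pct == pytest.approx(200.0, abs=80.0)
        assert spots[0].complementary_enrichment_pct == pytest.approx(0.0, abs=40.0)

    def test_symmetric_analysis_both_directions(self, flat_truth, flat_stack):
        nucleus = flat_truth.nucleus_mask
        for primary, other in [("15N_RNA", "13C_DNA"), ("13C_DNA", "15N_RNA")]:
            spots = detect_hotspots(
                flat_stack, TRACERS[primary], window=4, top_n=10, search_mask=nucleus
            )
            spots, nuclear_mean = colocalize_hotspots(spots, TRACERS[other], flat_stack, nucleus)
            assert len(spots) == 10
            assert np.isfinite(nuclear_mean)
            assert all(np.isfinite(h.complementary_enrichment_pct) for h in spots)


class TestOverlay:
    def test_no_hotspots_image_unchanged(self):
        base = np.random.default_rng(0).random((8, 8, 3))
        out = hotspot_overlay([], base)
        np.testing.assert_array_equal(out, base)

    def test_outline_positions(self):
        num = np.ones((8, 8), int)
        den = np.full((8, 8), 100, int)
        num[0:4, 0:4] = 50
        stack = make_stack({"12C15N": num, "12C14N": den})
        spots = detect_hotspots(stack, RD, window=4, top_n=1)
        assert spots[0].origin == (0, 0)
        out = hotspot_overlay(spots, np.zeros((8, 8, 3)), color=(0, 1, 0))
        green = np.all(out == [0, 1, 0], axis=-1)
        # outline occupies the border of rows/cols 0..3
        assert green[0, 0:4].all() and green[3, 0:4].all()
        assert green[0:4, 0].all() and green[0:4, 3].all()
        assert not green[1:3, 1:3].any()
        assert not green[4:, :].any() and not green[:, 4:].any()
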