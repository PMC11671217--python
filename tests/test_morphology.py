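"""Morphological refinement against set-definition and flood-fill oracles."""

import numpy as np
import pytest

from pleuraseg import morphology as mo
from pleuraseg.errors import ParameterError


# --- independent oracles ----------------------------------------------------


def oracle_dilate(mask, element):
    """Union of element translates centred on foreground (background padding)."""
    h, w = mask.shape
    k = element.shape[0]
    m = k // 2
    out = np.zeros_like(mask, dtype=bool)
    for y, x in np.argwhere(mask):
        for dy in range(-m, m + 1):
            for dx in range(-m, m + 1):
                if element[dy + m, dx + m] and 0 <= y + dy < h and 0 <= x + dx < w:
                    out[y + dy, x + dx] = True
    return out


def oracle_erode_dual(mask, element):
    """Erosion as the dual of background-padded dilation of the complement."""
    return ~oracle_dilate(~mask, element)


def oracle_close(mask, element):
    return oracle_erode_dual(oracle_dilate(mask, element), element)


def flood_fill_components(mask, connectivity=8):
    """BFS flood fill; returns list of pixel-index sets."""
    offsets = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    if connectivity == 8:
        offsets += [(-1, -1), (-1, 1), (1, -1), (1, 1)]
    seen = np.zeros_like(mask, dtype=bool)
    comps = []
    h, w = mask.shape
    for y0 in range(h):
        for x0 in range(w):
            if mask[y0, x0] and not seen[y0, x0]:
                stack = [(y0, x0)]
                seen[y0, x0] = True
                comp = set()
                while stack:
                    y, x = stack.pop()
                    comp.add((y, x))
                    for dy, dx in offsets:
                        ny, nx = y + dy, x + dx
                        if 0 <= ny < h and 0 <= nx < w and mask[ny, nx] and not seen[ny, nx]:
                            seen[ny, nx] = True
                            stack.append((ny, nx))
                comps.append(comp)
    return comps


def oracle_top_k(mask, k, connectivity=8):
    comps = flood_fill_components(mask, connectivity)
    comps.sort(key=lambda c: (-len(c), min(y * mask.shape[1] + x for y, x in c)))
    out = np.zeros_like(mask, dtype=bool)
    for comp in comps[:k]:
        for y, x in comp:
            out[y, x] = True
    return out


# --- tests ------------------------------------------------------------------


class TestEllipseElement:
    def test_size_one(self):
        assert np.array_equal(mo.ellipse_element(1), np.ones((1, 1), bool))

    def test_size_three_is_plus(self):
        elem = mo.ellipse_element(3)
        assert elem.sum() == 5
        assert np.array_equal(elem, np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], bool))

    def test_symmetry(self):
        for size in (3, 5, 9, 15, 19):
            e = mo.ellipse_element(size)
            assert np.array_equal(e, e.T)
            assert np.array_equal(e, e[::-1])
            assert np.array_equal(e, e[:, ::-1])

    def test_even_size_rejected(self):
        with pytest.raises(ParameterError):
            mo.ellipse_element(4)


class TestTopK:
    def test_single_blob_unchanged(self):
        m = np.zeros((10, 10), bool)
        m[2:5, 2:5] = True
        assert np.array_equal(mo.top_k_components(m, 2), m)

    def test_empty_mask(self):
        m = np.zeros((6, 6), bool)
        assert not mo.top_k_components(m, 2).any()

    def test_three_blobs_keep_two(self):
        m = np.zeros((12, 12), bool)
        m[0:3, 0:4] = True  # 12 px
        m[5:12, 0:1] = True  # 7 px
        m[10:12, 10:11] = True  # 2 px
        out = mo.top_k_components(m, 2)
        assert np.array_equal(out, oracle_top_k(m, 2))
        assert out.sum() == 19

    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_matches_flood_fill_oracle(self, rng, connectivity):
        for _ in range(40):
            m = rng.random((20, 20)) < 0.35
            for k in (1, 2, 3):
                assert np.array_equal(
                    mo.top_k_components(m, k, connectivity),
                    oracle_top_k(m, k, connectivity),
                )

    def test_never_increases_foreground(self, rng):
        for _ in range(20):
            m = rng.random((16, 16)) < 0.4
            out = mo.top_k_components(m, 2)
            assert not (out & ~m).any()


class TestDilateClose:
    def test_single_pixel_dilation_is_footprint(self):
        for size in (3, 5, 7):
            m = np.zeros((15, 15), bool)
            m[7, 7] = True
            elem = mo.ellipse_element(size)
            out = mo.dilate(m, elem)
            r = size // 2
            assert np.array_equal(out[7 - r : 7 + r + 1, 7 - r : 7 + r + 1], elem)
            assert out.sum() == elem.sum()

    def test_close_fills_hole_keeps_boundary(self):
        m = np.zeros((12, 12), bool)
        m[3:8, 3:8] = True
        m[5, 5] = False  # 1-px interior hole
        elem = mo.ellipse_element(3)
        out = mo.close(m, elem)
        assert np.array_equal(out, oracle_close(m, elem))
        assert out[5, 5]
        assert np.array_equal(out, m | (out & ~m))  # extensive

    @pytest.mark.parametrize("size", [3, 5])
    def test_matches_set_definition_oracles(self, rng, size):
        elem = mo.ellipse_element(size)
        for _ in range(30):
            m = rng.random((24, 24)) < 0.3
            assert np.array_equal(mo.dilate(m, elem), oracle_dilate(m, elem))
            assert np.array_equal(mo.close(m, elem), oracle_close(m, elem))

    def test_extensivity(self, rng):
        elem = mo.ellipse_element(5)
        for _ in range(100):
            m = rng.random((20, 20)) < 0.3
            assert not (m & ~mo.dilate(m, elem)).any()
            assert not (m & ~mo.close(m, elem)).any()

    def test_closing_idempotent(self, rng):
        elem = mo.ellipse_element(5)
        for _ in range(20):
            m = rng.random((24, 24)) < 0.35
            once = mo.close(m, elem)
            assert np.array_equal(mo.close(once, elem), once)


class TestRefine:
    def test_empty_input_empty_constraint(self):
        out = mo.refine(np.zeros((32, 32), bool))
        assert not out.any()

    def test_speckle_removed(self, rng):
        m = np.zeros((32, 32), bool)
        m[4:18, 4:10] = True
        m[4:18, 20:26] = True
        m[28:30, 28:30] = True  # speckle island
        out = mo.top_k_components(m, 2)
        assert not out[28:30, 28:30].any()
        assert out.sum() == m.sum() - 4

    def test_covers_true_lungspace_on_phantom(self, small_config):
        from pleuraseg.phantom import generate_phantom

        sample = generate_phantom(small_config, 0)
        cfg = mo.MorphConfig(closing_size=9, dilation_size=2 * small_config.pleural_rim_px + 1)
        refined = mo.refine(sample.lung_mask, cfg)
        assert not (sample.lungspace_mask & ~refined).any()

    def test_monotone_in_dilation_size(self, rng):
        m = rng.random((32, 32)) < 0.2
        small = mo.refine(m, mo.MorphConfig(closing_size=5, dilation_size=5))
        large = mo.refine(m, mo.MorphConfig(closing_size=5, dilation_size=9))
        assert not (small & ~large).any()

    def test_even_sizes_rejected(self):
        with pytest.raises(ParameterError):
            mo.MorphConfig(closing_size=18)
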