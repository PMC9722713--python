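"""Packaged bitmap glyph faces for lead-name rendering.

Only the twelve characters appearing in lead names are needed
(``I a v r l f 1 2 3 4 5 6``).  Two faces are hand-authored as bitmaps
("block", a slab face with bars on the capital I, and "sans", a lighter
face with different letterforms); a third ("round") is derived from "sans"
by morphological thickening at render time.  Keeping several faces lets the
fixture font and the recogniser's template fonts be varied independently,
so recognition tests are not self-fulfilling.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

_BLOCK = {
    "I": [
        "#####",
        "..#..",
        "..#..",
        "..#..",
        "..#..",
        "..#..",
        "#####",
    ],
    "a": [
        ".....",
        ".....",
        ".###.",
        "....#",
        ".####",
        "#...#",
        ".####",
    ],
    "v": [
        ".....",
        ".....",
        "#...#",
        "#...#",
        "#...#",
        ".#.#.",
        "..#..",
    ],
    "r": [
        ".....",
        ".....",
        "#.##.",
        "##..#",
        "#....",
        "#....",
        "#....",
    ],
    "l": [
        ".#...",
        ".#...",
        ".#...",
        ".#...",
        ".#...",
        ".#...",
        "..##.",
    ],
    "f": [
        "..##.",
        ".#...",
        ".#...",
        "####.",
        ".#...",
        ".#...",
        ".#...",
    ],
    "1": [
        "..#..",
        ".##..",
        "..#..",
        "..#..",
        "..#..",
        "..#..",
        ".###.",
    ],
    "2": [
        ".###.",
        "#...#",
        "....#",
        "...#.",
        "..#..",
        ".#...",
        "#####",
    ],
    "3": [
        "####.",
        "....#",
        "....#",
        ".###.",
        "....#",
        "....#",
        "####.",
    ],
    "4": [
        "...#.",
        "..##.",
        ".#.#.",
        "#..#.",
        "#####",
        "...#.",
        "...#.",
    ],
    "5": [
        "#####",
        "#....",
        "####.",
        "....#",
        "....#",
        "#...#",
        ".###.",
    ],
    "6": [
        ".###.",
        "#....",
        "#....",
        "####.",
        "#...#",
        "#...#",
        ".###.",
    ],
}

_SANS = {
    "I": [
        "##",
        "##",
        "##",
        "##",
        "##",
        "##",
        "##",
    ],
    "a": [
        "....",
        "....",
        "###.",
        "...#",
        "####",
        "#..#",
        ".###",
    ],
    "v": [
        ".....",
        ".....",
        "#...#",
        ".#.#.",
        ".#.#.",
        ".#.#.",
        "..#..",
    ],
    "r": [
        "....",
        "....",
        "#.##",
        "##..",
        "#...",
        "#...",
        "#...",
    ],
    "l": [
        "#.",
        "#.",
        "#.",
        "#.",
        "#.",
        "#.",
        "##",
    ],
    "f": [
        ".###",
        ".#..",
        "####",
        ".#..",
        ".#..",
        ".#..",
        ".#..",
    ],
    "1": [
        ".#.",
        "##.",
        ".#.",
        ".#.",
        ".#.",
        ".#.",
        ".#.",
    ],
    "2": [
        ".##.",
        "#..#",
        "...#",
        "..#.",
        ".#..",
        "#...",
        "####",
    ],
    "3": [
        "###.",
        "...#",
        "..#.",
        "...#",
        "...#",
        "#..#",
        ".##.",
    ],
    "4": [
        "..#..",
        ".##..",
        "#.#..",
        "#####",
        "..#..",
        "..#..",
        "..#..",
    ],
    "5": [
        "####",
        "#...",
        "###.",
        "...#",
        "...#",
        "#..#",
        ".##.",
    ],
    "6": [
        ".##.",
        "#...",
        "###.",
        "#..#",
        "#..#",
        "#..#",
        ".##.",
    ],
}

#: face name -> (base bitmaps, post-scale dilation structuring element or None)
FACES: dict[str, tuple[dict[str, list[str]], np.ndarray | None]] = {
    "block": (_BLOCK, None),
    "sans": (_SANS, None),
    # "round": sans letterforms thickened with a cross element after scaling.
    "round": (_SANS, ndimage.generate_binary_structure(2, 1)),
}

#: The 12-string lead-name vocabulary.
LEAD_VOCABULARY = ("I", "II", "III", "avr", "avl", "avf", "v1", "v2", "v3", "v4", "v5", "v6")


def _bitmap(rows: list[str]) -> np.ndarray:
    return np.array([[c == "#" for c in row] for row in rows], dtype=bool)


def render_glyph(char: str, face: str = "block", scale: int = 4) -> np.ndarray:
    """Render one character as a boolean array at integer pixel scale."""
    bitmaps, dilate = FACES[face]
    if char not in bitmaps:
        raise KeyError(f"face {face!r} has no glyph for {char!r}")
    arr = np.kron(_bitmap(bitmaps[char]), np.ones((scale, scale), dtype=bool))
    if dilate is not None:
        arr = ndimage.binary_dilation(arr, structure=dilate)
    return arr


def render_label(label: str, face: str = "block", scale: int = 4, gap_px: int = 2) -> np.ndarray:
    """Render a lead-name string; glyphs are separated by ``gap_px`` columns.

    The small gap keeps the whole label a single connected component after a
    3x3 dilation-then-erosion pass, which is what the object detector does.
    """
    glyphs = []
    for c in label:
        g = render_glyph(c, face, scale)
        used = np.nonzero(g.any(axis=0))[0]  # trim empty margin columns
        glyphs.append(g[:, used.min(): used.max() + 1])
    height = max(g.shape[0] for g in glyphs)
    cols = []
    for i, g in enumerate(glyphs):
        pad = height - g.shape[0]
        g = np.pad(g, ((pad, 0), (0, 0)))  # align glyph baselines at the bottom
        cols.append(g)
        if i < len(glyphs) - 1:
            cols.append(np.zeros((height, gap_px), dtype=bool))
    return np.hstack(cols)
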