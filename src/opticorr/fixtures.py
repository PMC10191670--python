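"""Synthetic fixtures: structured test images and bundled data files.

The package builds and tests with zero downloads: display spectra and cone
fundamentals come from :mod:`opticorr.spectra`'s generators, and the test
images here are designed to mix the high- and low-frequency content that
exercises a deblurring method — a slanted-edge chart, a text-like
high-frequency glyph pattern, and a smooth colour gradient.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .exceptions import ValidationError
from .spectra import (
    DisplaySpectra,
    ConeFundamentals,
    builtin_cone_fundamentals,
    synth_display_spectra,
    write_cone_fundamentals_csv,
    write_display_spectra_csv,
)

__all__ = [
    "edge_chart",
    "text_pattern",
    "smooth_gradient",
    "fixture_images",
    "default_display_and_cones",
    "make_fixtures",
]


def default_display_and_cones(grid=None) -> tuple[DisplaySpectra, ConeFundamentals]:
    """The default synthetic display (620/530/460 nm Gaussian primaries)
    and built-in cone fundamentals, on a shared wavelength grid."""
    return synth_display_spectra(grid=grid), builtin_cone_fundamentals(grid=grid)


def edge_chart(size: int = 256) -> np.ndarray:
    """Slanted-edge and bar chart: strong step edges at several angles."""
    if size < 16:
        raise ValidationError("size must be >= 16")
    y, x = np.mgrid[0:size, 0:size] / size
    img = np.zeros((size, size, 3))
    # quadrant slanted edges
    img[:, :, 0] = (x + 0.35 * y > 0.55).astype(float)
    img[:, :, 1] = (y - 0.2 * x > 0.45).astype(float)
    # vertical bar grating of increasing frequency in the lower-right
    freq = 4 + 28 * x
    bars = 0.5 * (1 + np.sign(np.sin(2 * np.pi * freq * x)))
    region = (x > 0.5) & (y > 0.5)
    for c in range(3):
        img[:, :, c] = np.where(region, bars, img[:, :, c])
    # a mid-gray patch so the chart is not purely binary
    img[size // 8 : size // 4, size // 8 : size // 4, :] = 0.5
    return np.clip(img, 0.0, 1.0)


def text_pattern(size: int = 256, seed: int = 0) -> np.ndarray:
    """Text-like pattern: rows of short dark strokes on a light background.

    Seeded pseudo-glyphs — random-width vertical/horizontal strokes arranged
    in lines — reproduce the high-frequency, high-contrast statistics of
    rendered text without shipping a font.
    """
    if size < 16:
        raise ValidationError("size must be >= 16")
    rng = np.random.default_rng(seed)
    img = np.ones((size, size))
    line_h = max(6, size // 24)
    gap = max(3, line_h // 2)
    y = gap
    while y + line_h < size - gap:
        x = gap
        while x < size - gap:
            glyph_w = int(rng.integers(2, max(3, line_h // 2) + 2))
            if rng.random() < 0.8:  # stroke
                img[y : y + line_h, x : x + glyph_w] = rng.uniform(0.0, 0.15)
                if rng.random() < 0.5:  # crossbar
                    cy = y + int(rng.integers(0, line_h - 1))
                    img[cy : cy + 2, x : x + 2 * glyph_w] = rng.uniform(0.0, 0.15)
            x += glyph_w + int(rng.integers(1, 4))
        y += line_h + gap
    return np.stack([img] * 3, axis=-1)


def smooth_gradient(size: int = 256) -> np.ndarray:
    """Smooth low-frequency colour field: crossed linear and radial ramps."""
    if size < 16:
        raise ValidationError("size must be >= 16")
    y, x = np.mgrid[0:size, 0:size] / (size - 1)
    r = np.hypot(x - 0.5, y - 0.5) / np.sqrt(0.5)
    img = np.stack([x, 0.5 + 0.5 * np.cos(np.pi * r), 1.0 - y], axis=-1)
    return np.clip(img, 0.0, 1.0)


def fixture_images(size: int = 256, seed: int = 0) -> dict[str, np.ndarray]:
    """The three structured test images used throughout the test-bench."""
    return {
        "edge_chart": edge_chart(size),
        "text_pattern": text_pattern(size, seed=seed),
        "smooth_gradient": smooth_gradient(size),
    }


def make_fixtures(seed: int = 0, outdir: str | Path = "fixtures", size: int = 256) -> dict:
    """Write the full fixture bundle to ``outdir``.

    Produces the synthetic display spectra CSV, cone fundamentals CSV, the
    three test images as PNGs, and a manifest recording the seed.  Returns
    a dict of the written paths.
    """
    from .retina import save_image

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    display, cones = default_display_and_cones()
    paths = {
        "display_spectra": outdir / "display_spectra.csv",
        "cone_fundamentals": outdir / "cone_fundamentals.csv",
        "manifest": outdir / "fixtures_manifest.json",
    }
    write_display_spectra_csv(display, paths["display_spectra"])
    write_cone_fundamentals_csv(cones, paths["cone_fundamentals"])
    for name, img in fixture_images(size=size, seed=seed).items():
        p = outdir / f"{name}.png"
        save_image(img, p)
        paths[name] = p
    manifest = {"seed": seed, "size": size, "files": {k: str(v) for k, v in paths.items() if k != "manifest"}}
    paths["manifest"].write_text(json.dumps(manifest, indent=2))
    return paths
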