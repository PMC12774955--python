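"""Deterministic virtual staining of mass maps and the contrast metric.

Two render modes, both pure functions of the recovered mass maps:

* Virtual fluorescence — dark background, each species adds emission along
  a colour vector (nucleic acid → blue, protein → purple) with a saturating
  map ``1 − exp(−m / scale)``, monotone in mass.
* H&E-like — optical-density colour mixing, ``RGB = 10^−(m_nuc·v_nuc +
  m_pro·v_pro)`` per channel with stain vectors in the classic
  hematoxylin/eosin directions, plus a constant green background term; zero
  mass renders white, nucleic acid pulls toward hematoxylin blue-violet and
  protein toward eosin pink, and every channel is non-increasing in every
  mass before the background term.

The comparison contrast metric is Michelson contrast, ``(max − min) /
(max + min)``, on a percentile-clipped region of interest — a declared
convention of this package (gain-invariant and bounded in [0, 1]).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import tifffile
import yaml

from .errors import ValidationError
from .spectra import MassMaps

__all__ = [
    "StainPalette",
    "default_palette",
    "render_fluorescence",
    "render_he",
    "contrast_metric",
    "save_palette",
    "load_palette",
    "export_rgb",
]


@dataclass(frozen=True)
class StainPalette:
    """Colour vectors and scales for the two render modes.

    he_*_od: per-channel optical-density vectors (non-negative; the classic
    Ruifrok–Johnston hematoxylin/eosin directions by default).  fluor_*_rgb:
    emission colours in [0, 1].  *_scale: mass value (fg/px) mapped to unit
    stain OD / to the 1/e point of the fluorescence saturation; ``None``
    auto-scales to the 95th percentile of the nonzero masses (still a pure
    function of the input).  green_background adds the constant green of an
    H&E scan background.
    """

    he_nuc_od: tuple = (0.650, 0.704, 0.286)
    he_pro_od: tuple = (0.072, 0.990, 0.105)
    fluor_nuc_rgb: tuple = (0.15, 0.35, 1.0)
    fluor_pro_rgb: tuple = (0.60, 0.20, 0.95)
    he_nuc_scale: float | None = None
    he_pro_scale: float | None = None
    fluor_nuc_scale: float | None = None
    fluor_pro_scale: float | None = None
    he_strength: float = 1.6
    green_background: float = 0.06
    gamma: float = 1.0

    def __post_init__(self) -> None:
        for name in ("he_nuc_od", "he_pro_od", "fluor_nuc_rgb", "fluor_pro_rgb"):
            vec = np.asarray(getattr(self, name), dtype=float)
            if vec.shape != (3,) or np.any(vec < 0):
                raise ValidationError(f"{name} must be a non-negative RGB triple")
        if self.he_strength < 0 or self.green_background < 0 or self.gamma <= 0:
            raise ValidationError("strengths and gamma must be non-negative / positive")


def default_palette() -> StainPalette:
    return StainPalette()


def _auto_scale(mass: np.ndarray, given: float | None) -> float:
    if given is not None:
        if given <= 0:
            raise ValidationError("palette scales must be positive")
        return given
    nz = mass[mass > 0]
    if nz.size == 0:
        return 1.0
    return float(np.percentile(nz, 95.0))


def _check_masses(mass: MassMaps) -> tuple[np.ndarray, np.ndarray]:
    m_nuc = np.asarray(mass.m_nuc, dtype=float)
    m_pro = np.asarray(mass.m_pro, dtype=float)
    if m_nuc.min() < 0 or m_pro.min() < 0:
        raise ValidationError("mass maps must be non-negative")
    return m_nuc, m_pro


def render_fluorescence(mass: MassMaps, palette: StainPalette | None = None) -> np.ndarray:
    """Virtual-fluorescence RGB render (float in [0, 1], dark background)."""
    pal = palette or default_palette()
    m_nuc, m_pro = _check_masses(mass)
    s_nuc = _auto_scale(m_nuc, pal.fluor_nuc_scale)
    s_pro = _auto_scale(m_pro, pal.fluor_pro_scale)
    v_nuc = 1.0 - np.exp(-m_nuc / s_nuc)
    v_pro = 1.0 - np.exp(-m_pro / s_pro)
    rgb = (
        v_nuc[..., None] * np.asarray(pal.fluor_nuc_rgb)
        + v_pro[..., None] * np.asarray(pal.fluor_pro_rgb)
    )
    rgb = np.clip(rgb, 0.0, 1.0)
    if pal.gamma != 1.0:
        rgb = rgb ** (1.0 / pal.gamma)
    return rgb


def render_he(mass: MassMaps, palette: StainPalette | None = None) -> np.ndarray:
    """H&E-like RGB render via optical-density colour mixing."""
    pal = palette or default_palette()
    m_nuc, m_pro = _check_masses(mass)
    s_nuc = _auto_scale(m_nuc, pal.he_nuc_scale)
    s_pro = _auto_scale(m_pro, pal.he_pro_scale)
    od = (
        (pal.he_strength * m_nuc / s_nuc)[..., None] * np.asarray(pal.he_nuc_od)
        + (pal.he_strength * m_pro / s_pro)[..., None] * np.asarray(pal.he_pro_od)
    )
    rgb = np.power(10.0, -od)
    rgb[..., 1] = rgb[..., 1] + pal.green_background
    rgb = np.clip(rgb, 0.0, 1.0)
    if pal.gamma != 1.0:
        rgb = rgb ** (1.0 / pal.gamma)
    return rgb


def contrast_metric(image: np.ndarray, roi: tuple | None = None,
                    clip_percentiles: tuple[float, float] = (1.0, 99.0)) -> float:
    """Michelson contrast on a percentile-clipped region of interest.

    ``roi`` is a ``(slice, slice)`` pair (None = whole image) and must span
    at least 16 px per side.  Returns ``(max − min) / (max + min)`` of the
    clipped ROI, in [0, 1]; a constant ROI scores 0.  Invariant to
    multiplicative gain.
    """
    img = np.asarray(image, dtype=float)
    sub = img[roi] if roi is not None else img
    if sub.ndim != 2 or min(sub.shape) < 16:
        raise ValidationError("ROI must be 2-D and at least 16 px per side")
    lo, hi = np.percentile(sub, clip_percentiles)
    clipped = np.clip(sub, lo, hi)
    mx, mn = float(clipped.max()), float(clipped.min())
    if mx + mn == 0 or mx == mn:
        return 0.0
    return (mx - mn) / (mx + mn)


def save_palette(path, palette: StainPalette) -> None:
    data = {
        k: (list(v) if isinstance(v, tuple) else v)
        for k, v in palette.__dict__.items()
    }
    with open(path, "w") as f:
        yaml.safe_dump(data, f)


def load_palette(path) -> StainPalette:
    with open(path) as f:
        data = yaml.safe_load(f)
    for k in ("he_nuc_od", "he_pro_od", "fluor_nuc_rgb", "fluor_pro_rgb"):
        if k in data and data[k] is not None:
            data[k] = tuple(data[k])
    return StainPalette(**data)


def export_rgb(path, rgb: np.ndarray, palette: StainPalette | None = None) -> None:
    """8-bit RGB export (PNG or TIFF by extension) with the palette recorded."""
    img8 = np.clip(np.asarray(rgb) * 255.0 + 0.5, 0, 255).astype(np.uint8)
    path = str(path)
    if path.lower().endswith((".tif", ".tiff")):
        meta = {"palette": repr(palette or default_palette())}
        tifffile.imwrite(path, img8, photometric="rgb", metadata=meta)
    else:
        from PIL import Image

        Image.fromarray(img8).save(path)

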