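"""Classification overlay: the cumulative green/pink site map.

Each sampled site is drawn on the video as a filled circle whose colour
interpolates linearly in RGB from pure green (normal, p_tumor = 0) to pink
(tumor, p_tumor = 1).  Markers persist on all subsequent frames, building
up a map of every sampled location as scanning proceeds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError

GREEN = np.array([0, 255, 0], dtype=float)  # normal endpoint
PINK = np.array([255, 105, 180], dtype=float)  # tumor endpoint


@dataclass
class ClassifiedSite:
    """One sampled location with its tumor probability."""

    frame_index: int
    x: float
    y: float
    p_tumor: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_tumor <= 1.0):
            raise ConfigError(f"p_tumor {self.p_tumor} outside [0, 1]")

    @property
    def hard_label(self) -> str:
        return "tumor" if self.p_tumor >= 0.5 else "normal"


def colorize(p_tumor: float) -> np.ndarray:
    """uint8 RGB between green (p=0) and pink (p=1), linear per channel."""
    if not (0.0 <= p_tumor <= 1.0):
        raise ConfigError(f"p_tumor {p_tumor} outside [0, 1]")
    return np.round((1.0 - p_tumor) * GREEN + p_tumor * PINK).astype(np.uint8)


def _disc_mask(h: int, w: int, cx: float, cy: float, radius: float) -> np.ndarray:
    yy, xx = np.mgrid[0:h, 0:w]
    return (xx - cx) ** 2 + (yy - cy) ** 2 <= radius**2


def render_overlay(
    frames: Iterable[np.ndarray],
    sites: Sequence[ClassifiedSite],
    radius: float = 6.0,
    opacity: float = 0.7,
) -> Iterator[np.ndarray]:
    """Yield frames with the cumulative classification map painted on.

    A site appears from its own frame index onward (alpha-blended filled
    circle).  Sites outside the frame bounds are skipped with a warning.
    Rendering is deterministic: identical inputs give identical bytes.
    """
    if not (0.0 < opacity <= 1.0):
        raise ConfigError("opacity must be in (0, 1]")
    ordered = sorted(sites, key=lambda s: (s.frame_index,))
    pending = list(ordered)
    active: list[ClassifiedSite] = []
    for i, frame in enumerate(frames):
        frame = np.asarray(frame)
        out = frame.astype(float).copy()
        h, w = out.shape[:2]
        while pending and pending[0].frame_index <= i:
            site = pending.pop(0)
            if not (0 <= site.x < w and 0 <= site.y < h):
                warnings.warn(
                    f"site at ({site.x}, {site.y}) outside frame bounds; skipped",
                    stacklevel=2,
                )
                continue
            active.append(site)
        for site in active:
            mask = _disc_mask(h, w, site.x, site.y, radius)
            color = colorize(site.p_tumor).astype(float)
            if frame.dtype != np.uint8 and out.max() <= 1.0:
                color = color / 255.0
            out[mask] = (1.0 - opacity) * out[mask] + opacity * color
        if frame.dtype == np.uint8:
            yield np.clip(np.round(out), 0, 255).astype(np.uint8)
        else:
            yield out


def sites_to_csv(sites: Sequence[ClassifiedSite], path) -> None:
    pd.DataFrame(
        {
            "frame": [s.frame_index for s in sites],
            "x": [s.x for s in sites],
            "y": [s.y for s in sites],
            "p_tumor": [s.p_tumor for s in sites],
            "label": [s.hard_label for s in sites],
        }
    ).to_csv(path, index=False)


def sites_from_csv(path) -> list[ClassifiedSite]:
    frame = pd.read_csv(path)
    return [
        ClassifiedSite(int(r["frame"]), float(r["x"]), float(r["y"]), float(r["p_tumor"]))
        for _, r in frame.iterrows()
    ]
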