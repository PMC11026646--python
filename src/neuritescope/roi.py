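"""Tunnel regions of interest.

A microfluidic axon tunnel is analysed inside a rectangular ROI aligned with
the tunnel axis (here always the column axis).  The ROI also declares which
end of the tunnel faces the somata: ``anterograde_sign = +1`` means that
transport away from the cell bodies corresponds to increasing column index.
ROIs are stored as a plain JSON list so they can be drawn once and reused
across timepoints.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .images import CalibratedImage, ImageSeries


@dataclass(frozen=True)
class TunnelROI:
    tunnel_id: str
    row_start: int
    row_stop: int
    col_start: int
    col_stop: int
    anterograde_sign: int = 1

    def __post_init__(self) -> None:
        if self.row_stop <= self.row_start or self.col_stop <= self.col_start:
            raise ValueError(f"{self.tunnel_id}: empty ROI")
        if self.anterograde_sign not in (-1, 1):
            raise ValueError("anterograde_sign must be +1 or -1")

    @property
    def width_px(self) -> int:
        return self.row_stop - self.row_start

    @property
    def length_px(self) -> int:
        return self.col_stop - self.col_start

    def check_inside(self, shape: tuple[int, int]) -> None:
        if self.row_start < 0 or self.col_start < 0 or self.row_stop > shape[0] or self.col_stop > shape[1]:
            raise ValueError(f"{self.tunnel_id}: ROI {self} outside image of shape {shape}")

    def extract(self, pixels: np.ndarray) -> np.ndarray:
        self.check_inside(pixels.shape[-2:])
        return pixels[..., self.row_start : self.row_stop, self.col_start : self.col_stop]

    def crop_image(self, image: CalibratedImage) -> CalibratedImage:
        return CalibratedImage(self.extract(image.pixels), image.pixel_size)

    def crop_series(self, series: ImageSeries) -> ImageSeries:
        return ImageSeries(self.extract(series.frames), series.pixel_size, series.frame_interval)


def save_rois(path, rois: list[TunnelROI]) -> None:
    with open(path, "w") as fh:
        json.dump([asdict(r) for r in rois], fh, indent=2)


def load_rois(path) -> list[TunnelROI]:
    with open(path) as fh:
        return [TunnelROI(**d) for d in json.load(fh)]
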