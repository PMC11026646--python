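"""Simulation parameters.

One dataclass drives all synthetic scenes.  The defaults encode the
acquisition the pipelines assume: 0.2 um/px confocal sampling, one frame per
second for a minute, 145-um tunnel segments, and 7-minute MEA recordings at
10 kHz.  A single integer seed fixes every random draw; independent
sub-streams are derived per scene/tunnel/channel so partial regeneration is
reproducible.
"""

from __future__ import annotations

import zlib
from dataclasses import asdict, dataclass, replace

import numpy as np
import yaml

from ..roi import TunnelROI


@dataclass(frozen=True)
class SimParams:
    # --- imaging calibration -------------------------------------------------
    pixel_size: float = 0.2          # um per pixel
    frame_interval: float = 1.0      # s between frames
    n_frames: int = 60               # frames per motility series
    psf_sigma_px: float = 1.2        # isotropic Gaussian blob sigma, px
    background: float = 200.0        # flat background level, counts
    background_ramp: float = 40.0    # peak-to-peak linear ramp across columns
    noise_sigma: float = 100.0       # additive Gaussian noise sigma, counts
    amplitude: float = 500.0         # puncta peak amplitude above background

    # --- tunnel geometry -----------------------------------------------------
    n_tunnels: int = 4               # kymographs per series, one per tunnel
    tunnel_length_um: float = 145.0  # analysed segment length
    tunnel_width_px: int = 12        # ROI width across the axon bundle
    tunnel_gap_px: int = 8           # blank rows between tunnel ROIs
    tunnel_margin_px: int = 10       # blank columns at either tunnel end

    # --- mitochondria scene --------------------------------------------------
    n_stationary: int = 31           # per tunnel
    n_motile: int = 2                # per tunnel
    speed_range: tuple[float, float] = (0.3, 1.8)   # |speed| draw, um/s
    speeds: tuple[float, ...] | None = None          # explicit signed speeds
    anterograde_prob: float = 0.5
    placement: str = "uniform_x"     # 'uniform_x' (motility) or 'grid' (dense)
    min_separation_px: float = 8.0
    injected_patch_areas_um2: tuple[float, ...] = ()  # sharp calibration discs

    # --- neurite / bouton scene ---------------------------------------------
    image_shape: tuple[int, int] = (512, 512)
    n_neurites: int = 5
    n_termini: int | None = None     # default: 2 per neurite (no branching)
    neurite_snr: float = 10.0
    bouton_gain: float = 1.7         # bouton amplitude relative to neurite

    # --- two-channel synapse scene ------------------------------------------
    n_puncta: int = 15               # unpaired puncta per channel
    punctum_diameter_um: float = 0.8
    overlap_diameters_um: tuple[float, ...] = (1.0, 1.0, 1.0, 1.0)

    # --- z-stack scene -------------------------------------------------------
    stack_shape: tuple[int, int] = (128, 128)
    n_slices: int = 40
    z_step: float = 1.0              # um per slice
    signal_slices: tuple[int, int] = (10, 20)  # inclusive slice range
    n_stack_puncta: int = 40

    # --- MEA recording -------------------------------------------------------
    n_channels: int = 12
    sampling_rate: float = 10_000.0  # Hz
    duration: float = 420.0          # s (7 min)
    spike_amplitude_uv: float = 60.0
    mea_noise_sigma_uv: float = 5.0
    firing_rate_hz: float | tuple[float, ...] = 1.0
    refractory_ms: float = 2.0
    coupled_pairs: tuple[tuple[int, int, float, float], ...] = ()
    # each coupled pair: (source channel, target channel, lag ms, co-spike prob)

    seed: int = 0

    def __post_init__(self) -> None:
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be positive")
        if not self.frame_interval > 0:
            raise ValueError("frame_interval must be positive")
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be positive")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if min(self.n_stationary, self.n_motile, self.n_puncta) < 0:
            raise ValueError("object counts must be non-negative")
        for (_, _, lag, prob) in self.coupled_pairs:
            if abs(lag) > 100:
                raise ValueError("coupling lag must lie within [-100, 100] ms")
            if not 0 <= prob <= 1:
                raise ValueError("co-spike probability must be in [0, 1]")

    # -- derived tunnel-frame geometry ---------------------------------------
    @property
    def tunnel_length_px(self) -> int:
        return int(round(self.tunnel_length_um / self.pixel_size))

    @property
    def frame_shape(self) -> tuple[int, int]:
        rows = self.n_tunnels * self.tunnel_width_px + (self.n_tunnels + 1) * self.tunnel_gap_px
        cols = self.tunnel_length_px + 2 * self.tunnel_margin_px
        return rows, cols

    def tunnel_rois(self) -> list[TunnelROI]:
        rois = []
        for i in range(self.n_tunnels):
            r0 = self.tunnel_gap_px + i * (self.tunnel_width_px + self.tunnel_gap_px)
            rois.append(
                TunnelROI(
                    tunnel_id=f"tunnel{i:02d}",
                    row_start=r0,
                    row_stop=r0 + self.tunnel_width_px,
                    col_start=self.tunnel_margin_px,
                    col_stop=self.tunnel_margin_px + self.tunnel_length_px,
                )
            )
        return rois

    def rng_for(self, *stream) -> np.random.Generator:
        """Deterministic sub-stream keyed by (seed, stream labels).

        Labels are reduced with CRC32 (not Python ``hash``, which is salted
        per process) so the same parameters always give the same stream.
        """
        key = [int(self.seed)] + [zlib.crc32(str(s).encode()) for s in stream]
        return np.random.default_rng(key)

    def replace(self, **kwargs) -> "SimParams":
        return replace(self, **kwargs)

    # -- YAML round trip ------------------------------------------------------
    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(_plain(asdict(self)), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimParams":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    @classmethod
    def from_dict(cls, d: dict) -> "SimParams":
        d = dict(d)
        for key in ("speed_range", "speeds", "overlap_diameters_um",
                    "injected_patch_areas_um2", "signal_slices", "image_shape",
                    "stack_shape"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        if isinstance(d.get("firing_rate_hz"), list):
            d["firing_rate_hz"] = tuple(d["firing_rate_hz"])
        if "coupled_pairs" in d:
            d["coupled_pairs"] = tuple(tuple(p) for p in d["coupled_pairs"])
        return cls(**d)


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj
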