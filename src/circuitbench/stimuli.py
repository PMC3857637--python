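"""Visual stimuli: regularly sampled 2D luminance frame streams.

Stimuli live in a planar visual space sampled at pixel centres on a
half-open grid.  A drifting sinusoidal grating with orientation ``theta``
(direction of the spatial-frequency vector, counter-clockwise from the
positive x axis; stripes run perpendicular to it), spatial frequency ``SF``
(cycles/deg), temporal frequency ``TF`` (Hz) and Michelson contrast ``C``
(percent about the background luminance ``bg``) has luminance

    L(x, y, t) = bg * (1 + (C/100) * sin(2*pi*SF*(x*cos th + y*sin th)
                                         - 2*pi*TF*t/1000))

with ``x, y`` in degrees relative to the field centre and ``t`` in ms.
Initial spatial phase is zero.  The disk variant sets pixels farther than
``size/2`` degrees from the field centre back to background.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from .identities import Identity, ParamDecl, make_identity

__all__ = [
    "VisualSpaceSpec",
    "StimulusDescriptor",
    "FrameStream",
    "frame_count",
    "grating_frame",
    "apply_disk_aperture",
    "null_frames",
    "frames_for_stimulus",
]

NULL = "Null"
FULLFIELD_GRATING = "FullfieldDriftingSinusoidalGrating"
GRATING_DISK = "DriftingSinusoidalGratingDisk"


@dataclass(frozen=True)
class VisualSpaceSpec:
    """Geometry and sampling of the visual input space."""

    update_interval: float = 7.0          # ms between frames
    background_luminance: float = 50.0    # cd/m^2
    centre: tuple[float, float] = (0.0, 0.0)   # deg
    size: tuple[float, float] = (6.8, 6.8)     # deg (width, height)
    resolution: float = 10.0              # pixels per degree

    def __post_init__(self) -> None:
        if self.update_interval <= 0:
            raise ValueError("update_interval must be > 0")
        if self.resolution <= 0:
            raise ValueError("resolution must be > 0")
        if self.size[0] <= 0 or self.size[1] <= 0:
            raise ValueError("field size must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        """(rows, cols) = (ny, nx)."""
        return (
            int(round(self.size[1] * self.resolution)),
            int(round(self.size[0] * self.resolution)),
        )

    def pixel_coords(self) -> tuple[np.ndarray, np.ndarray]:
        """Pixel-centre coordinates (deg, relative to field centre).

        Returns broadcastable ``(x[1, nx], y[ny, 1])`` on a half-open grid.
        """
        ny, nx = self.shape
        dx = 1.0 / self.resolution
        x = (np.arange(nx) + 0.5) * dx - self.size[0] / 2.0
        y = (np.arange(ny) + 0.5) * dx - self.size[1] / 2.0
        return x[np.newaxis, :], y[:, np.newaxis]


_COMMON_DECLS = (
    ParamDecl("duration", float, "ms", doc="presentation length"),
    ParamDecl("trial", int, doc="trial index"),
)
_GRATING_DECLS = (
    ParamDecl("orientation", float, "rad", period=math.pi),
    ParamDecl("spatial_frequency", float, "cycles/deg"),
    ParamDecl("temporal_frequency", float, "Hz"),
    ParamDecl("contrast", float, "%"),
)

_DECLS_BY_KIND: dict[str, tuple[ParamDecl, ...]] = {
    NULL: _COMMON_DECLS,
    FULLFIELD_GRATING: _COMMON_DECLS + _GRATING_DECLS,
    GRATING_DISK: _COMMON_DECLS + _GRATING_DECLS + (ParamDecl("size", float, "deg"),),
}


@dataclass(frozen=True)
class StimulusDescriptor:
    """One stimulus presentation's full parameterization.

    Declared parameters make every descriptor convertible to an
    :class:`~circuitbench.identities.Identity` (and hence queryable).
    """

    kind: str
    duration: float
    trial: int = 0
    orientation: float = 0.0
    spatial_frequency: float = 0.8
    temporal_frequency: float = 2.0
    contrast: float = 100.0
    size: float = 1.0  # disk aperture diameter, deg

    def __post_init__(self) -> None:
        if self.kind not in _DECLS_BY_KIND:
            raise ValueError(f"unknown stimulus kind {self.kind!r}")
        if self.duration < 0:
            raise ValueError("duration must be >= 0")
        if not 0.0 <= self.contrast <= 100.0:
            raise ValueError("contrast must be in [0, 100]")

    def identity(self) -> Identity:
        decls = _DECLS_BY_KIND[self.kind]
        values = {d.name: getattr(self, d.name) for d in decls}
        return make_identity(self.kind, decls, values)


@dataclass
class FrameStream:
    """Ordered luminance frames (cd/m^2) at a fixed frame period (ms)."""

    frames: list[np.ndarray] = field(default_factory=list)
    frame_period: float = 7.0

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self) -> Iterator[np.ndarray]:
        return iter(self.frames)

    def __getitem__(self, i: int) -> np.ndarray:
        return self.frames[i]


def frame_count(stim: StimulusDescriptor, space: VisualSpaceSpec) -> int:
    """Number of frames: ceil(duration / update_interval)."""
    return int(math.ceil(stim.duration / space.update_interval - 1e-12)) if stim.duration > 0 else 0


def grating_frame(stim: StimulusDescriptor, space: VisualSpaceSpec, t: float) -> np.ndarray:
    """One grating frame at time ``t`` (ms); the module formula above."""
    if stim.kind not in (FULLFIELD_GRATING, GRATING_DISK):
        raise ValueError(f"{stim.kind} is not a grating stimulus")
    bg = space.background_luminance
    x, y = space.pixel_coords()
    th = stim.orientation
    phase = (
        2.0 * math.pi * stim.spatial_frequency * (x * math.cos(th) + y * math.sin(th))
        - 2.0 * math.pi * stim.temporal_frequency * t / 1000.0
    )
    return bg * (1.0 + (stim.contrast / 100.0) * np.sin(phase))


def apply_disk_aperture(stim: StimulusDescriptor, space: VisualSpaceSpec,
                        frame: np.ndarray) -> np.ndarray:
    """Mask a frame to a circular aperture of diameter ``stim.size`` deg."""
    if stim.kind != GRATING_DISK:
        raise ValueError("aperture applies to DriftingSinusoidalGratingDisk only")
    x, y = space.pixel_coords()
    r2 = x * x + y * y
    out = frame.copy()
    out[r2 > (stim.size / 2.0) ** 2] = space.background_luminance
    return out


def null_frames(duration: float, space: VisualSpaceSpec) -> FrameStream:
    """Uniform background frames covering ``duration`` ms."""
    if duration < 0:
        raise ValueError("duration must be >= 0")
    n = frame_count(StimulusDescriptor(NULL, duration), space)
    frame = np.full(space.shape, space.background_luminance)
    return FrameStream([frame.copy() for _ in range(n)], space.update_interval)


def frames_for_stimulus(stim: StimulusDescriptor, space: VisualSpaceSpec) -> FrameStream:
    """Render the full frame stream for any supported stimulus kind."""
    if stim.kind == NULL:
        return null_frames(stim.duration, space)
    n = frame_count(stim, space)
    frames = []
    for i in range(n):
        t = i * space.update_interval
        frame = grating_frame(stim, space, t)
        if stim.kind == GRATING_DISK:
            frame = apply_disk_aperture(stim, space, frame)
        frames.append(frame)
    return FrameStream(frames, space.update_interval)
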