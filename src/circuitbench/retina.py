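"""Simplified retina/LGN sensory front-end.

The whole retino-thalamic pathway is abstracted into two mirrored mosaics
of relay cells, ON and OFF, sharing the same positions.  Each cell applies
a spatial difference-of-Gaussians (centre sigma_c, surround sigma_s,
amplitudes normalized so each lobe integrates to A_c / A_s over the pixel
grid) to the contrast image ``(L - bg)/bg``, followed by a first-order
exponential temporal low-pass with time constant ``tau_lgn`` across frames.
The resulting linear drive is rectified into a firing rate

    r = clip(r0 + gain * s * drive, 0, r_max),   s = +1 (ON), -1 (OFF)

and spikes are emitted as an inhomogeneous Poisson process with the rate
held constant over each frame interval.  ON and OFF drives are exact
negatives of each other, so wherever neither is clipped,
``r_ON + r_OFF = 2 r0``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .sheets import Sheet, SheetSpec, RecorderSpec, BackgroundNoiseSpec
from .stimuli import FrameStream, VisualSpaceSpec

__all__ = [
    "RetinaLGNSpec",
    "LGNDrive",
    "build_lgn_mosaic",
    "linear_drive",
    "rates_from_drive",
    "poisson_spikes",
    "lgn_spike_trains",
]


@dataclass(frozen=True)
class RetinaLGNSpec:
    sigma_c: float = 0.2        # deg, centre Gaussian
    sigma_s: float = 0.6        # deg, surround Gaussian
    A_c: float = 1.0            # centre amplitude (integral of centre lobe)
    A_s: float = 1.0            # surround amplitude; A_c == A_s -> balanced
    tau_lgn: float = 10.0       # ms, temporal low-pass
    r0: float = 10.0            # spikes/s baseline
    gain: float = 100.0         # spikes/s per unit drive
    r_max: float = 200.0        # spikes/s ceiling
    density: float = 20.0       # cells/deg^2 per polarity
    recorders: dict[str, RecorderSpec] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.sigma_s > self.sigma_c > 0:
            raise ValueError("need sigma_s > sigma_c > 0")
        if not self.r_max >= self.r0 >= 0:
            raise ValueError("need r_max >= r0 >= 0")


@dataclass
class LGNDrive:
    """Per-cell, per-frame linear drive (dimensionless contrast units)."""

    drive: np.ndarray           # (n_cells, n_frames)
    frame_period: float         # ms


def build_lgn_mosaic(spec: RetinaLGNSpec, space: VisualSpaceSpec,
                     polarity: str, margin: float = 0.5) -> Sheet:
    """A square mosaic sheet (``X_ON`` or ``X_OFF``) covering the visual
    field minus ``margin`` degrees on each side (so every DoG support stays
    inside the field).  ON and OFF mosaics share identical positions."""
    if polarity not in ("ON", "OFF"):
        raise ValueError("polarity must be 'ON' or 'OFF'")
    w = max(space.size[0] - 2 * margin, 0.0)
    h = max(space.size[1] - 2 * margin, 0.0)
    spacing = 1.0 / np.sqrt(spec.density)
    nx = max(int(np.floor(w / spacing)) + 1, 1)
    ny = max(int(np.floor(h / spacing)) + 1, 1)
    xs = (np.arange(nx) - (nx - 1) / 2.0) * spacing
    ys = (np.arange(ny) - (ny - 1) / 2.0) * spacing
    gx, gy = np.meshgrid(xs, ys)
    positions_deg = np.column_stack([gx.ravel(), gy.ravel()])
    mf = 1000.0  # nominal um/deg, only used for the linear retinotopy
    sheet_spec = SheetSpec(
        name=f"X_{polarity}",
        sx=max(w, spacing) * mf, sy=max(h, spacing) * mf,
        density=0.0, magnification_factor=mf,
        cell_model="SpikeSource",
        background_noise=BackgroundNoiseSpec(),
        recorders=dict(spec.recorders),
    )
    return Sheet(sheet_spec, positions_deg * mf)


def _dog_kernel(spec: RetinaLGNSpec, space: VisualSpaceSpec,
                position_deg: np.ndarray) -> np.ndarray:
    """Discrete DoG weights on the pixel grid, each lobe normalized to unit
    discrete sum (so a uniform frame yields exactly A_c - A_s)."""
    x, y = space.pixel_coords()
    dx = x - position_deg[0]
    dy = y - position_deg[1]
    r2 = dx * dx + dy * dy
    centre = np.exp(-r2 / (2.0 * spec.sigma_c ** 2))
    surround = np.exp(-r2 / (2.0 * spec.sigma_s ** 2))
    return spec.A_c * centre / centre.sum() - spec.A_s * surround / surround.sum()


def linear_drive(frames: FrameStream, spec: RetinaLGNSpec, space: VisualSpaceSpec,
                 positions_deg: np.ndarray) -> LGNDrive:
    """DoG inner product per frame, then exponential low-pass across frames
    (initial state 0).  ``positions_deg``: (n_cells, 2) in visual degrees."""
    positions_deg = np.atleast_2d(positions_deg)
    half_w, half_h = space.size[0] / 2.0, space.size[1] / 2.0
    if np.any(np.abs(positions_deg[:, 0]) > half_w + 1e-9) \
            or np.any(np.abs(positions_deg[:, 1]) > half_h + 1e-9):
        raise ValueError("LGN cell position outside the visual field")
    n_cells = positions_deg.shape[0]
    n_frames = len(frames)
    kernels = np.stack([
        _dog_kernel(spec, space, positions_deg[i]).ravel() for i in range(n_cells)
    ]) if n_cells else np.empty((0, int(np.prod(space.shape))))
    bg = space.background_luminance
    raw = np.empty((n_cells, n_frames))
    for j, frame in enumerate(frames):
        contrast = (frame.ravel() - bg) / bg
        raw[:, j] = kernels @ contrast
    # first-order low-pass: y_k = a y_{k-1} + (1 - a) x_k, y_{-1} = 0
    a = np.exp(-frames.frame_period / spec.tau_lgn)
    out = np.empty_like(raw)
    prev = np.zeros(n_cells)
    for j in range(n_frames):
        prev = a * prev + (1.0 - a) * raw[:, j]
        out[:, j] = prev
    return LGNDrive(out, frames.frame_period)


def rates_from_drive(drive: LGNDrive, spec: RetinaLGNSpec, polarity: str) -> np.ndarray:
    """Rectified firing rates (spikes/s), shape (n_cells, n_frames)."""
    sign = {"ON": 1.0, "OFF": -1.0}[polarity]
    return np.clip(spec.r0 + spec.gain * sign * drive.drive, 0.0, spec.r_max)


def poisson_spikes(rates: np.ndarray, frame_period: float, duration: float,
                   rng: np.random.Generator) -> list[np.ndarray]:
    """Piecewise-constant-rate Poisson spike trains.

    ``rates``: (n_cells, n_frames) in spikes/s; returns per-cell sorted
    spike-time arrays (ms) within [0, duration).
    """
    rates = np.atleast_2d(rates)
    if np.any(rates < 0):
        raise ValueError("rates must be >= 0")
    n_cells, n_frames = rates.shape
    trains: list[np.ndarray] = []
    for i in range(n_cells):
        times: list[np.ndarray] = []
        for j in range(n_frames):
            t0 = j * frame_period
            t1 = min(t0 + frame_period, duration)
            if t1 <= t0:
                break
            lam = rates[i, j] * (t1 - t0) / 1000.0
            count = rng.poisson(lam) if lam > 0 else 0
            if count:
                times.append(rng.uniform(t0, t1, size=count))
        if times:
            train = np.sort(np.concatenate(times))
            train = train[np.concatenate(([True], np.diff(train) > 0))]
            trains.append(train)
        else:
            trains.append(np.empty(0))
    return trains


def lgn_spike_trains(frames: FrameStream, spec: RetinaLGNSpec, space: VisualSpaceSpec,
                     mosaic: Sheet, polarity: str, duration: float,
                     rng: np.random.Generator) -> list[np.ndarray]:
    """Frames -> drive -> rates -> Poisson spikes for one polarity mosaic."""
    drive = linear_drive(frames, spec, space, mosaic.visual_positions())
    rates = rates_from_drive(drive, spec, polarity)
    return poisson_spikes(rates, frames.frame_period, duration, rng)
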