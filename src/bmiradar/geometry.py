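"""Scan and reconstruction geometry for a monostatic circular breast scan.

The imaging plane is the 2-D coronal plane of the scan, in meters, with the
origin at the rotation axis of the chamber.  Antenna position ``m`` (of ``M``)
sits on a circle of radius ``trajectory_radius`` at angle ``2*pi*m/M``,
counter-clockwise from the +x axis.  The breast is modelled as a disc of
radius ``breast_radius`` centred on the rotation axis, with relative
permittivity ``eps_breast`` inside and ``eps_bg`` (air) outside.

The reconstruction grid is a square of ``image_size`` pixels per side spanning
``image_extent`` metres, centred on the rotation axis.  Pixels are indexed
row-major with pixel (0, 0) at the top-left: +x right, +y up, so row index
increases as y decreases.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .exceptions import InvalidArgumentError, InvalidConfigError

C_VACUUM = 299_792_458.0  # speed of light in vacuum, m/s

__all__ = [
    "C_VACUUM",
    "ScanConfig",
    "Image",
    "DelayTensor",
    "estimate_propagation_speed",
    "time_of_flight",
    "delay_tensor_for_points",
]


def _check_uniform(grid: np.ndarray, name: str, rtol: float = 1e-6) -> None:
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size < 2:
        raise InvalidConfigError(f"{name} must be a 1-D grid with >= 2 points")
    steps = np.diff(grid)
    if np.any(steps <= 0):
        raise InvalidConfigError(f"{name} must be strictly increasing")
    if not np.allclose(steps, steps[0], rtol=rtol, atol=0.0):
        raise InvalidConfigError(f"{name} must be uniformly spaced")


@dataclass(frozen=True)
class ScanConfig:
    """Acquisition and reconstruction geometry of one monostatic scan.

    Parameters
    ----------
    n_positions
        Number of equally spaced antenna positions on the circular trajectory.
    trajectory_radius
        Radius of the antenna path, metres.
    freq_grid
        Stepped-frequency grid of the VNA sweep, Hz, uniformly spaced.
    time_grid
        Output time grid of the inverse chirp z-transform, seconds, uniform.
    breast_radius
        Radius of the assumed circular breast, metres (< trajectory_radius).
    eps_breast
        Relative permittivity assumed inside the breast (default 6.4, the
        adipose-mimicking value at the central scan frequency).
    eps_bg
        Relative permittivity of the surround (air, 1.0).
    image_extent
        Side length of the square field of view, metres, centred on the axis.
    image_size
        Pixels per image side.
    """

    n_positions: int
    trajectory_radius: float
    freq_grid: np.ndarray
    time_grid: np.ndarray
    breast_radius: float
    eps_breast: float = 6.4
    eps_bg: float = 1.0
    image_extent: float = 0.15
    image_size: int = 100

    def __post_init__(self) -> None:
        object.__setattr__(self, "freq_grid", np.asarray(self.freq_grid, dtype=float))
        object.__setattr__(self, "time_grid", np.asarray(self.time_grid, dtype=float))
        if self.n_positions < 1:
            raise InvalidConfigError("n_positions must be >= 1")
        if self.trajectory_radius <= 0 or self.breast_radius <= 0:
            raise InvalidConfigError("radii must be positive")
        if self.breast_radius >= self.trajectory_radius:
            raise InvalidConfigError("breast_radius must be < trajectory_radius")
        if self.eps_breast < 1.0 or self.eps_bg < 1.0:
            raise InvalidConfigError("relative permittivities must be >= 1")
        if self.image_extent < 2.0 * self.breast_radius:
            raise InvalidConfigError("image_extent must cover the breast disc")
        if self.image_size < 1:
            raise InvalidConfigError("image_size must be >= 1")
        _check_uniform(self.freq_grid, "freq_grid")
        _check_uniform(self.time_grid, "time_grid")

    # ------------------------------------------------------------------ grids
    @property
    def antenna_positions(self) -> np.ndarray:
        """(M, 2) antenna coordinates; antenna 0 on the +x axis, CCW order."""
        ang = 2.0 * np.pi * np.arange(self.n_positions) / self.n_positions
        return self.trajectory_radius * np.stack([np.cos(ang), np.sin(ang)], axis=1)

    @property
    def pixel_size(self) -> float:
        return self.image_extent / self.image_size

    @property
    def n_pixels(self) -> int:
        return self.image_size * self.image_size

    def pixel_coords(self) -> np.ndarray:
        """(n_pixels, 2) pixel-centre coordinates, row-major, row 0 at +y top."""
        n, p = self.image_size, self.pixel_size
        xs = -0.5 * self.image_extent + (np.arange(n) + 0.5) * p
        ys = 0.5 * self.image_extent - (np.arange(n) + 0.5) * p
        X, Y = np.meshgrid(xs, ys)  # Y constant along rows
        return np.stack([X.ravel(), Y.ravel()], axis=1)

    # ------------------------------------------------------------ constructors
    @classmethod
    def clinical(cls, **overrides) -> "ScanConfig":
        """72 positions, 1-8 GHz x 1001 points, 0-6 ns x 700, 500x500 grid."""
        kw = dict(
            n_positions=72,
            trajectory_radius=0.15,
            freq_grid=np.linspace(1e9, 8e9, 1001),
            time_grid=np.linspace(0.0, 6e-9, 700),
            breast_radius=0.055,
            eps_breast=6.4,
            eps_bg=1.0,
            image_extent=0.15,
            image_size=500,
        )
        kw.update(overrides)
        return cls(**kw)

    @classmethod
    def reduced(cls, **overrides) -> "ScanConfig":
        """Desk-scale config for tests: 24 positions, 128 time bins, 100^2 grid."""
        kw = dict(
            n_positions=24,
            trajectory_radius=0.15,
            freq_grid=np.linspace(1e9, 8e9, 257),
            time_grid=np.linspace(0.0, 6e-9, 128),
            breast_radius=0.055,
            eps_breast=6.4,
            eps_bg=1.0,
            image_extent=0.15,
            image_size=100,
        )
        kw.update(overrides)
        return cls(**kw)

    def with_(self, **overrides) -> "ScanConfig":
        return replace(self, **overrides)

    # ------------------------------------------------------------ serialization
    def to_dict(self) -> dict:
        def grid_spec(g: np.ndarray) -> dict:
            return {"start": float(g[0]), "stop": float(g[-1]), "num": int(g.size)}

        return {
            "n_positions": int(self.n_positions),
            "trajectory_radius": float(self.trajectory_radius),
            "freq_grid": grid_spec(self.freq_grid),
            "time_grid": grid_spec(self.time_grid),
            "breast_radius": float(self.breast_radius),
            "eps_breast": float(self.eps_breast),
            "eps_bg": float(self.eps_bg),
            "image_extent": float(self.image_extent),
            "image_size": int(self.image_size),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScanConfig":
        def grid(spec) -> np.ndarray:
            if isinstance(spec, dict):
                return np.linspace(spec["start"], spec["stop"], spec["num"])
            return np.asarray(spec, dtype=float)

        kw = dict(d)
        kw["freq_grid"] = grid(kw["freq_grid"])
        kw["time_grid"] = grid(kw["time_grid"])
        return cls(**kw)


@dataclass
class Image:
    """Non-negative reflectivity map on the square reconstruction grid.

    ``values`` has shape (image_size, image_size), row-major with row 0 at the
    top (+y); ``extent`` is the physical side length in metres.
    """

    values: np.ndarray
    extent: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise InvalidConfigError("image grid must be square")

    @property
    def size(self) -> int:
        return self.values.shape[0]

    @property
    def pixel_size(self) -> float:
        return self.extent / self.size

    def display_map(self) -> np.ndarray:
        """Squared intensity map, the presentation convention for all images."""
        return self.values**2


@dataclass
class DelayTensor:
    """Two-way times of flight and derived nearest-bin sampling indices.

    ``delays[m, i]`` is the round-trip time from antenna ``m`` to pixel ``i``
    (flattened row-major).  ``bin_index`` holds the nearest index into the
    time grid and ``valid`` marks delays that fall inside the time window;
    out-of-window delays contribute nothing to either projector.
    """

    delays: np.ndarray  # (M, n_pixels), seconds
    bin_index: np.ndarray  # (M, n_pixels), int
    valid: np.ndarray  # (M, n_pixels), bool
    n_times: int
    dt: float
    t0: float
    image_shape: tuple | None = None  # (size, size) when built from a config
    image_extent: float | None = None

    @property
    def n_positions(self) -> int:
        return self.delays.shape[0]

    @property
    def n_pixels(self) -> int:
        return self.delays.shape[1]


def estimate_propagation_speed(config: ScanConfig) -> float:
    """Average propagation speed in the scan region, assuming a circular breast.

    The permittivity is averaged by area over the disc bounded by the antenna
    trajectory::

        eps_avg = (eps_breast * A_breast + eps_bg * (A_scan - A_breast)) / A_scan

    and the speed is ``c / sqrt(eps_avg)``.
    """
    a_scan = np.pi * config.trajectory_radius**2
    a_breast = np.pi * config.breast_radius**2
    eps_avg = (config.eps_breast * a_breast + config.eps_bg * (a_scan - a_breast)) / a_scan
    return C_VACUUM / np.sqrt(eps_avg)


def delay_tensor_for_points(
    antenna_positions: np.ndarray,
    points: np.ndarray,
    speed: float,
    time_grid: np.ndarray,
    image_shape: tuple | None = None,
    image_extent: float | None = None,
) -> DelayTensor:
    """Round-trip delays ``2 |r_i - r_m| / v`` for arbitrary target points."""
    if speed <= 0:
        raise InvalidArgumentError("propagation speed must be positive")
    antenna_positions = np.asarray(antenna_positions, dtype=float)
    points = np.asarray(points, dtype=float)
    time_grid = np.asarray(time_grid, dtype=float)
    t0 = float(time_grid[0])
    dt = float(time_grid[1] - time_grid[0])
    n_times = int(time_grid.size)

    m = antenna_positions.shape[0]
    n = points.shape[0]
    delays = np.empty((m, n), dtype=float)
    for k in range(m):  # looped to bound peak memory on large grids
        diff = points - antenna_positions[k]
        delays[k] = 2.0 * np.hypot(diff[:, 0], diff[:, 1]) / speed
    idx = np.rint((delays - t0) / dt).astype(np.int64)
    valid = (idx >= 0) & (idx < n_times)
    return DelayTensor(
        delays=delays,
        bin_index=idx,
        valid=valid,
        n_times=n_times,
        dt=dt,
        t0=t0,
        image_shape=image_shape,
        image_extent=image_extent,
    )


def time_of_flight(config: ScanConfig, speed: float) -> DelayTensor:
    """Delay tensor between every antenna position and every image pixel."""
    return delay_tensor_for_points(
        config.antenna_positions,
        config.pixel_coords(),
        speed,
        config.time_grid,
        image_shape=(config.image_size, config.image_size),
        image_extent=config.image_extent,
    )
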