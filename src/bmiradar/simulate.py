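"""Synthetic monostatic scans of parametric phantoms.

The simulator emulates the two-scan protocol of a stepped-frequency circular
scan: each point scatterer of reflectivity ``sigma`` at position ``p``
contributes ``sigma * exp(-j 2 pi f_n t_m(p))`` to the S11 spectrum at
antenna ``m`` (round-trip delay ``t_m`` at the configured average speed),
plus additive complex Gaussian noise.  The paired reference scan contains
the same scatterers minus the tumor, with an independent noise realization —
so ideal reference subtraction isolates the tumor response plus sqrt(2)-
inflated noise, exactly as in the real calibration protocol.

The simulator deliberately shares the single-speed straight-ray delay model
with the reconstructor: its job is algorithmic correctness of the chain, not
electromagnetic fidelity.  ``eps_true`` lets callers simulate at a different
breast permittivity than the reconstruction assumes, to probe robustness to
speed mismatch.

Spherical scatterers (radius > 0) are rasterized as discs of uniformly
spaced point reflectors at the image pixel pitch, sharing the scatterer's
total reflectivity; point targets (radius 0) are the default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import InvalidPhantomError
from .geometry import ScanConfig, estimate_propagation_speed
from .signal import FrequencySinogram

__all__ = ["Scatterer", "PhantomSpec", "simulate_scan", "standard_fixtures", "SimFixture"]

# Clutter presets grading phantom difficulty like the four mammographic
# density classes: denser breasts -> more and stronger clutter scatterers.
DENSITY_CLASS_PRESETS = {
    "I": {"n_clutter": 2, "amplitude": 0.25},
    "II": {"n_clutter": 4, "amplitude": 0.40},
    "III": {"n_clutter": 6, "amplitude": 0.55},
    "IV": {"n_clutter": 8, "amplitude": 0.75},
}


@dataclass
class Scatterer:
    """One reflector: centre position (m), total reflectivity, radius (m)."""

    position: tuple
    reflectivity: float
    radius: float = 0.0


@dataclass
class PhantomSpec:
    """Parametric phantom: a tumor plus optional clutter scatterers."""

    scatterers: list
    breast_radius: float
    tumor_index: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.tumor_index < len(self.scatterers):
            raise InvalidPhantomError("tumor_index must select one scatterer")
        for k, s in enumerate(self.scatterers):
            if s.reflectivity <= 0:
                raise InvalidPhantomError(f"scatterer {k} has non-positive reflectivity")
            r = float(np.hypot(*s.position))
            if r + s.radius > self.breast_radius:
                raise InvalidPhantomError(
                    f"scatterer {k} at radius {r:.4f} m (+{s.radius:.4f} m) lies "
                    f"outside the breast disc (radius {self.breast_radius:.4f} m)"
                )

    @property
    def tumor(self) -> Scatterer:
        return self.scatterers[self.tumor_index]

    @classmethod
    def from_density_class(
        cls,
        density_class: str,
        breast_radius: float = 0.055,
        tumor_position: tuple = (0.02, 0.01),
        tumor_reflectivity: float = 1.0,
        tumor_radius: float = 0.0,
        rng: np.random.Generator | None = None,
    ) -> "PhantomSpec":
        """Tumor plus preset clutter emulating one of the four density classes."""
        if density_class not in DENSITY_CLASS_PRESETS:
            raise InvalidPhantomError(f"unknown density class {density_class!r}")
        preset = DENSITY_CLASS_PRESETS[density_class]
        rng = np.random.default_rng(0) if rng is None else rng
        scatterers = [Scatterer(tumor_position, tumor_reflectivity, tumor_radius)]
        for _ in range(preset["n_clutter"]):
            # rejection-free draw inside 0.85 * breast disc, away from the tumor
            while True:
                p = rng.uniform(-0.85 * breast_radius, 0.85 * breast_radius, size=2)
                if np.hypot(*p) > 0.85 * breast_radius:
                    continue
                if np.hypot(p[0] - tumor_position[0], p[1] - tumor_position[1]) < 0.015:
                    continue
                break
            amp = preset["amplitude"] * rng.uniform(0.7, 1.3)
            scatterers.append(Scatterer(tuple(p), amp, 0.0))
        return cls(scatterers=scatterers, breast_radius=breast_radius, tumor_index=0)


def _rasterize(s: Scatterer, pitch: float) -> tuple:
    """Point set and per-point amplitudes for one scatterer."""
    if s.radius <= 0:
        return np.asarray([s.position], dtype=float), np.asarray([s.reflectivity])
    n = int(np.ceil(2 * s.radius / pitch)) + 1
    ax = np.linspace(-s.radius, s.radius, n)
    X, Y = np.meshgrid(ax, ax)
    inside = X**2 + Y**2 <= s.radius**2
    pts = np.stack([X[inside] + s.position[0], Y[inside] + s.position[1]], axis=1)
    amps = np.full(len(pts), s.reflectivity / len(pts))
    return pts, amps


def _spectrum(
    points: np.ndarray,
    amps: np.ndarray,
    config: ScanConfig,
    speed: float,
) -> np.ndarray:
    ants = config.antenna_positions
    f = config.freq_grid
    out = np.zeros((config.n_positions, f.size), dtype=complex)
    for m in range(config.n_positions):
        d = points - ants[m]
        tau = 2.0 * np.hypot(d[:, 0], d[:, 1]) / speed  # round-trip delay per point
        out[m] = (amps[:, None] * np.exp(-2j * np.pi * tau[:, None] * f[None, :])).sum(0)
    return out


def simulate_scan(
    phantom: PhantomSpec,
    config: ScanConfig,
    noise_sigma: float = 0.0,
    seed: int | np.random.Generator | None = None,
    eps_true: float | None = None,
    reference_mode: str = "tumor-free",
) -> tuple:
    """Simulate the two-scan protocol; returns (full, reference) sinograms.

    ``noise_sigma`` is the standard deviation of the complex noise modulus
    (components drawn as N(0, sigma/sqrt(2)) each); full and reference scans
    receive independent realizations.  ``eps_true`` overrides the breast
    permittivity used to generate (not reconstruct) the data.

    ``reference_mode`` selects what the paired reference scan contains:

    * ``"tumor-free"`` (default) — every scatterer except the tumor, so the
      calibrated difference isolates the tumor response plus noise.
    * ``"adipose-only"`` — no scatterers at all, emulating the experimental
      protocol in which *all* inner tissue components are removed for the
      reference scan; the calibrated difference then retains the clutter
      scatterers, which is what makes the density-class presets graded.
    """
    if noise_sigma < 0:
        raise InvalidPhantomError("noise_sigma must be >= 0")
    if reference_mode not in ("tumor-free", "adipose-only"):
        raise InvalidPhantomError(f"unknown reference_mode {reference_mode!r}")
    if phantom.breast_radius > config.trajectory_radius:
        raise InvalidPhantomError("phantom does not fit inside the antenna trajectory")
    sim_config = config if eps_true is None else config.with_(eps_breast=eps_true)
    speed = estimate_propagation_speed(sim_config)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    shape = (config.n_positions, config.freq_grid.size)
    full = np.zeros(shape, dtype=complex)
    reference = np.zeros(shape, dtype=complex)
    for k, s in enumerate(phantom.scatterers):
        pts, amps = _rasterize(s, config.pixel_size)
        spec = _spectrum(pts, amps, config, speed)
        full += spec
        if k != phantom.tumor_index and reference_mode == "tumor-free":
            reference += spec

    def noise() -> np.ndarray:
        if noise_sigma == 0:
            return np.zeros(shape, dtype=complex)
        scale = noise_sigma / np.sqrt(2.0)
        return rng.normal(0.0, scale, shape) + 1j * rng.normal(0.0, scale, shape)

    return (
        FrequencySinogram(values=full + noise(), freq_grid=config.freq_grid),
        FrequencySinogram(values=reference + noise(), freq_grid=config.freq_grid),
    )


@dataclass
class SimFixture:
    """A named phantom with matched desk-scale and full-scale configs."""

    name: str
    phantom: PhantomSpec
    config: ScanConfig  # reduced, used throughout the test suite
    full_config: ScanConfig  # the clinical-scale 72 x 1001 x 700 x 500^2 setup
    seed: int


def standard_fixtures(seed: int = 0) -> dict:
    """Reproducible regression phantoms used across the test suite.

    * ``point-tumor-clean`` — one point tumor, no clutter.
    * ``three-scatterer`` — tumor plus two weaker clutter reflectors.
    * ``class-I`` ... ``class-IV`` — density-class clutter presets.

    All share the reduced config (24 positions, 128 time bins, 100^2 grid);
    the clinical-scale config is attached for full-size runs.
    """
    reduced = ScanConfig.reduced()
    full = ScanConfig.clinical()
    breast = reduced.breast_radius

    fixtures = {}

    def add(name: str, phantom: PhantomSpec, sub: int) -> None:
        fixtures[name] = SimFixture(
            name=name, phantom=phantom, config=reduced, full_config=full,
            seed=int(seed) + sub,
        )

    add(
        "point-tumor-clean",
        PhantomSpec(
            scatterers=[Scatterer((0.020, 0.010), 1.0, 0.0)],
            breast_radius=breast,
        ),
        1,
    )
    add(
        "three-scatterer",
        PhantomSpec(
            scatterers=[
                Scatterer((0.022, 0.008), 1.0, 0.0),  # tumor
                Scatterer((-0.025, 0.015), 0.40, 0.0),
                Scatterer((0.000, -0.030), 0.40, 0.0),
            ],
            breast_radius=breast,
        ),
        2,
    )
    for i, cls_name in enumerate(("I", "II", "III", "IV")):
        rng = np.random.default_rng(int(seed) + 100 + i)
        add(
            f"class-{cls_name}",
            PhantomSpec.from_density_class(cls_name, breast_radius=breast, rng=rng),
            10 + i,
        )
    return fixtures
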