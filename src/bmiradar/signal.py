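"""Frequency-to-time conversion and calibration of monostatic S11 sinograms.

The VNA records complex S11 reflection coefficients on a uniform stepped
frequency grid at each antenna position.  The inverse chirp z-transform (ICZT)
evaluates the inverse transform on an arbitrary uniform time grid::

    s_m(t_k) = (1/N_f) * sum_n S11[m, n] * exp(+j 2 pi f_n t_k)

which is what the chirp z factorization computes in O(N log N).  Beamforming
operates on the envelope (pointwise modulus) of these complex time signals:
the multiplicative iterative update requires non-negative data, and applying
the same envelope uniformly to DAS/DMAS/itDAS/itDMAS keeps the four methods
comparable.  A coherent "complex" mode for the non-iterative beamformers is
available through :func:`bmiradar.iterative.reconstruct`.

Skin/interface suppression is ideal: a matched target-free reference scan is
subtracted elementwise in the frequency domain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.signal

from .exceptions import IncompatibleScanError, UnsupportedGridError

__all__ = [
    "FrequencySinogram",
    "TimeSinogram",
    "iczt",
    "envelope",
    "ideal_skin_subtract",
    "to_time_domain",
]


@dataclass
class FrequencySinogram:
    """Complex S11 measurements, one row per antenna position.

    ``values``: complex, shape (n_positions, n_frequencies); ``freq_grid``: Hz.
    """

    values: np.ndarray
    freq_grid: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=complex)
        self.freq_grid = np.asarray(self.freq_grid, dtype=float)
        if self.values.ndim != 2:
            raise IncompatibleScanError("sinogram must be 2-D (positions x frequencies)")
        if self.values.shape[1] != self.freq_grid.size:
            raise IncompatibleScanError(
                f"sinogram has {self.values.shape[1]} frequency columns but the "
                f"grid has {self.freq_grid.size} points"
            )
        if not np.all(np.isfinite(self.values)):
            raise IncompatibleScanError("sinogram contains non-finite entries")

    @property
    def n_positions(self) -> int:
        return self.values.shape[0]


@dataclass
class TimeSinogram:
    """Non-negative envelope signals, one row per antenna position.

    ``values``: real >= 0, shape (n_positions, n_times); ``time_grid``: s.
    This is the data domain of the iterative update.
    """

    values: np.ndarray
    time_grid: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.time_grid = np.asarray(self.time_grid, dtype=float)
        if self.values.ndim != 2:
            raise IncompatibleScanError("sinogram must be 2-D (positions x times)")
        if self.values.shape[1] != self.time_grid.size:
            raise IncompatibleScanError(
                f"sinogram has {self.values.shape[1]} time columns but the grid "
                f"has {self.time_grid.size} points"
            )
        if np.any(self.values < 0):
            raise IncompatibleScanError("envelope sinogram must be non-negative")

    @property
    def n_positions(self) -> int:
        return self.values.shape[0]


def _uniform_step(grid: np.ndarray, name: str) -> float:
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size < 2:
        raise UnsupportedGridError(f"{name} must be 1-D with >= 2 points")
    steps = np.diff(grid)
    if np.any(steps <= 0) or not np.allclose(steps, steps[0], rtol=1e-6, atol=0.0):
        raise UnsupportedGridError(f"{name} must be strictly increasing and uniform")
    return float(steps[0])


def iczt(
    freq_sino: FrequencySinogram,
    time_grid: np.ndarray,
    method: str = "czt",
) -> np.ndarray:
    """Inverse chirp z-transform of a frequency sinogram onto a uniform time grid.

    Returns the complex time signals, shape (n_positions, n_times).  The fast
    path factors the double sum through scipy's Bluestein chirp z-transform;
    ``method="direct"`` evaluates the O(N^2) sum and is exact by construction.
    """
    f = np.asarray(freq_sino.freq_grid, dtype=float)
    t = np.asarray(time_grid, dtype=float)
    df = _uniform_step(f, "freq_grid")
    dt = _uniform_step(t, "time_grid")
    x = freq_sino.values
    nf = f.size

    if method == "direct":
        kernel = np.exp(2j * np.pi * np.outer(f, t))
        return (x @ kernel) / nf
    if method != "czt":
        raise ValueError(f"unknown ICZT method {method!r}")

    # s(t_k) = e^{2j pi f0 t_k}/Nf * sum_n x[n] e^{2j pi n df t0} e^{2j pi n k df dt}
    f0, t0 = f[0], t[0]
    w = np.exp(2j * np.pi * df * dt)  # czt: z_k^{-n} = a^{-n} w^{k n}
    a = np.exp(-2j * np.pi * df * t0)
    out = scipy.signal.czt(x, m=t.size, w=w, a=a, axis=-1)
    out *= np.exp(2j * np.pi * f0 * t)[None, :]
    out /= nf
    return out


def envelope(complex_signals: np.ndarray, time_grid: np.ndarray) -> TimeSinogram:
    """Pointwise modulus of complex time signals, packaged as a TimeSinogram."""
    return TimeSinogram(values=np.abs(np.asarray(complex_signals)), time_grid=time_grid)


def ideal_skin_subtract(
    full_scan: FrequencySinogram, reference_scan: FrequencySinogram
) -> FrequencySinogram:
    """Subtract a matched target-free reference scan (ideal skin suppression)."""
    if full_scan.values.shape != reference_scan.values.shape:
        raise IncompatibleScanError(
            f"scan shapes differ: {full_scan.values.shape} vs "
            f"{reference_scan.values.shape}"
        )
    if not np.array_equal(full_scan.freq_grid, reference_scan.freq_grid):
        raise IncompatibleScanError("scans were measured on different frequency grids")
    return FrequencySinogram(
        values=full_scan.values - reference_scan.values,
        freq_grid=full_scan.freq_grid,
    )


def to_time_domain(
    full_scan: FrequencySinogram,
    reference_scan: FrequencySinogram | None,
    time_grid: np.ndarray,
    mode: str = "envelope",
):
    """Calibrate (optional) and convert a scan to the time domain.

    ``mode="envelope"`` returns a :class:`TimeSinogram`; ``mode="complex"``
    returns the raw complex signals for coherent beamforming.
    """
    calibrated = (
        ideal_skin_subtract(full_scan, reference_scan)
        if reference_scan is not None
        else full_scan
    )
    signals = iczt(calibrated, time_grid)
    if mode == "envelope":
        return envelope(signals, time_grid)
    if mode == "complex":
        return signals
    raise ValueError(f"unknown signal mode {mode!r}")
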