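"""Delay-and-sum (DAS) and delay-multiply-and-sum (DMAS) back-projectors.

Both beamformers sample each antenna's time signal at the round-trip delay of
each pixel and combine the samples across the ``M`` antenna positions:

* DAS:   ``I(r) = sum_m s_m(t_m(r))``
* DMAS:  ``I(r) = sum_{m<n} s_m(t_m(r)) * s_n(t_n(r))``

DMAS is computed through the algebraic identity
``sum_{m<n} a_m a_n = (S^2 - Q) / 2`` with ``S = sum a_m``, ``Q = sum a_m^2``,
avoiding the explicit O(M^2) pair loop.

Sampling is nearest-bin (``round(delay / dt)``) by default, which makes DAS
the exact matrix adjoint of the nearest-bin forward projector — the pairing
the multiplicative iterative update relies on.  Linear-interpolation sampling
is available but breaks exact adjointness.  Delays outside the recorded time
window contribute zero.

Images are stored un-squared; squaring is a display/metric convention.
"""

from __future__ import annotations

import warnings

import numpy as np

from .exceptions import InvalidInputError
from .geometry import DelayTensor, Image
from .signal import TimeSinogram

__all__ = ["sample_at_delay", "das", "dmas"]


def _check(sino: TimeSinogram | np.ndarray, delays: DelayTensor) -> np.ndarray:
    values = sino.values if isinstance(sino, TimeSinogram) else np.asarray(sino)
    if values.size == 0:
        raise InvalidInputError("empty sinogram")
    if values.shape != (delays.n_positions, delays.n_times):
        raise InvalidInputError(
            f"sinogram shape {values.shape} does not match delay tensor "
            f"({delays.n_positions} positions x {delays.n_times} time bins)"
        )
    return values


def sample_at_delay(
    sino: TimeSinogram | np.ndarray,
    delays: DelayTensor,
    interpolation: str = "nearest",
) -> np.ndarray:
    """Per-position, per-pixel signal samples ``s_m(t_m(r_i))``.

    Returns shape (n_positions, n_pixels).  Out-of-window delays sample 0.
    """
    values = _check(sino, delays)
    if interpolation == "nearest":
        idx = np.where(delays.valid, delays.bin_index, 0)
        out = np.take_along_axis(values, idx, axis=1)
        out = np.where(delays.valid, out, 0.0)
        return out
    if interpolation == "linear":
        pos = (delays.delays - delays.t0) / delays.dt
        lo = np.floor(pos).astype(np.int64)
        frac = pos - lo
        lo_ok = (lo >= 0) & (lo < delays.n_times)
        hi_ok = (lo + 1 >= 0) & (lo + 1 < delays.n_times)
        s_lo = np.take_along_axis(values, np.where(lo_ok, lo, 0), axis=1)
        s_hi = np.take_along_axis(values, np.where(hi_ok, lo + 1, 0), axis=1)
        return np.where(lo_ok, (1.0 - frac) * s_lo, 0.0) + np.where(
            hi_ok, frac * s_hi, 0.0
        )
    raise ValueError(f"unknown interpolation {interpolation!r}")


def _as_image(flat: np.ndarray, delays: DelayTensor) -> Image | np.ndarray:
    if delays.image_shape is None:
        return flat
    return Image(
        values=flat.reshape(delays.image_shape), extent=float(delays.image_extent)
    )


def das(
    sino: TimeSinogram | np.ndarray,
    delays: DelayTensor,
    interpolation: str = "nearest",
) -> Image | np.ndarray:
    """Delay-and-sum beamformer: sum the delay-compensated samples over antennas."""
    values = _check(sino, delays)
    acc = np.zeros(delays.n_pixels, dtype=float)
    for m in range(delays.n_positions):  # per-antenna pass keeps memory flat
        row = sample_at_delay(
            values[m : m + 1],
            _row_view(delays, m),
            interpolation=interpolation,
        )[0]
        acc += row
    return _as_image(acc, delays)


def dmas(
    sino: TimeSinogram | np.ndarray,
    delays: DelayTensor,
    interpolation: str = "nearest",
) -> Image | np.ndarray:
    """Delay-multiply-and-sum beamformer: sum of pairwise sample products.

    Uses the (S^2 - Q)/2 identity; with a single antenna there are no pairs
    and the result is identically zero (a warning is emitted).
    """
    values = _check(sino, delays)
    if delays.n_positions < 2:
        warnings.warn("DMAS with fewer than 2 antenna positions is identically zero")
        return _as_image(np.zeros(delays.n_pixels), delays)
    s = np.zeros(delays.n_pixels, dtype=float)
    q = np.zeros(delays.n_pixels, dtype=float)
    for m in range(delays.n_positions):
        row = sample_at_delay(
            values[m : m + 1],
            _row_view(delays, m),
            interpolation=interpolation,
        )[0]
        s += row
        q += row * row
    return _as_image(0.5 * (s * s - q), delays)


def _row_view(delays: DelayTensor, m: int) -> DelayTensor:
    """Single-antenna view of a delay tensor (no copies of the big arrays)."""
    return DelayTensor(
        delays=delays.delays[m : m + 1],
        bin_index=delays.bin_index[m : m + 1],
        valid=delays.valid[m : m + 1],
        n_times=delays.n_times,
        dt=delays.dt,
        t0=delays.t0,
        image_shape=None,
        image_extent=None,
    )
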