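"""Radar forward model: reflectivity image -> time-domain sinogram.

Each pixel of reflectivity ``sigma_i`` produces an ideal impulse at its
round-trip delay in every antenna's signal::

    s_m(t) = sum_i sigma_i * delta(t - t_m(r_i))

discretized by depositing ``sigma_i`` into the single nearest time bin
(matching the nearest-bin sampler, so DAS is the exact adjoint of this
operator).  Pixels whose delay falls outside the recorded window deposit
nothing.  No amplitude decay, antenna pattern or attenuation is modelled;
an optional per-position per-bin weight map is accepted so such corrections
can be slotted in without changing the interface.
"""

from __future__ import annotations

import numpy as np

from .beamform import das
from .exceptions import InvalidImageError
from .geometry import DelayTensor, Image
from .signal import TimeSinogram

__all__ = ["forward_project", "forward_unity", "backproject_unity"]


def _time_grid(delays: DelayTensor) -> np.ndarray:
    return delays.t0 + delays.dt * np.arange(delays.n_times)


def forward_project(
    image: Image | np.ndarray,
    delays: DelayTensor,
    weights: np.ndarray | None = None,
) -> TimeSinogram:
    """Project an image into the data domain by nearest-bin deposition.

    ``weights``, if given, multiplies the sinogram elementwise (shape
    (n_positions, n_times)) — a hook for future path-dependent corrections.
    """
    flat = (image.values if isinstance(image, Image) else np.asarray(image)).ravel()
    if flat.size != delays.n_pixels:
        raise InvalidImageError(
            f"image has {flat.size} pixels but delay tensor expects {delays.n_pixels}"
        )
    if np.any(flat < 0):
        raise InvalidImageError("forward model requires a non-negative image")
    out = np.zeros((delays.n_positions, delays.n_times), dtype=float)
    for m in range(delays.n_positions):
        v = delays.valid[m]
        out[m] = np.bincount(
            delays.bin_index[m][v], weights=flat[v], minlength=delays.n_times
        )
    if weights is not None:
        out *= weights
    return TimeSinogram(values=out, time_grid=_time_grid(delays))


def forward_unity(delays: DelayTensor) -> TimeSinogram:
    """Forward projection of the all-ones image.

    Entry [m, k] counts the pixels whose delay at antenna m rounds to bin k —
    the data-domain normalizer of the iterative update.
    """
    return forward_project(np.ones(delays.n_pixels), delays)


def backproject_unity(delays: DelayTensor) -> Image | np.ndarray:
    """DAS back-projection of the all-ones sinogram (sensitivity map).

    Equals the number of antennas with an in-window delay at each pixel
    (= M for interior pixels).
    """
    ones = np.ones((delays.n_positions, delays.n_times), dtype=float)
    return das(ones, delays)
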