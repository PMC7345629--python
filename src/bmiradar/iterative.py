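"""Multiplicative iterative reconstruction (itDAS / itDMAS).

The update has the functional form of the MLEM algorithm from emission
tomography, with an additional data-domain normalizer F[U] multiplying the
measured dataset D::

    I_{n+1} = ( I_n / B[U] ) * B[ (D * F[U]) / F[I_n] ]

where F is the radar forward projector, B is the chosen beamformer (DAS for
itDAS, DMAS for itDMAS), U denotes the all-ones image (in F[U]) or sinogram
(in B[U]), and all products/ratios are elementwise.  The initial estimate is
a homogeneous map of ones; the default stopping iteration is 6, the balance
of contrast and noise adopted here (no automatic stopping rule — the full
trace is returned so callers can apply their own).

Numerical guards: a small ``epsilon`` (default ``1e-12 * max(F[U])``) is
added to the denominator; bins where the denominator is zero contribute
ratio 0, and pixels where B[U] = 0 are frozen at 0.

Operation counts are tracked per the complexity model in which each forward
or back projection costs ``Ns`` signal summations (Ns = number of antenna
signals): a run of N iterations performs 2(N+1) projections — two to
initialize F[U] and B[U], plus one forward and one back projection per
iteration — i.e. 2(N+1)*Ns signal summations in total.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .beamform import das, dmas
from .exceptions import InvalidArgumentError, InvalidDataError
from .forward import backproject_unity, forward_project, forward_unity
from .geometry import DelayTensor, Image, ScanConfig, estimate_propagation_speed, time_of_flight
from .signal import FrequencySinogram, TimeSinogram, to_time_domain

logger = logging.getLogger(__name__)

__all__ = ["IterationTrace", "iterate", "itdas", "itdmas", "reconstruct"]

_BACKPROJECTORS = {"das": das, "dmas": dmas}


@dataclass
class IterationTrace:
    """Full history of one iterative reconstruction.

    ``images`` holds I_0 ... I_N; ``projections`` holds F[I_n] for
    n = 0 ... N-1 (the forward projections compared against the data at each
    step, for measured-vs-projected diagnostics).  ``op_counts`` records the
    projection bookkeeping of the complexity model.
    """

    images: list
    projections: list
    n_iterations: int
    backprojector: str
    max_ratio: list = field(default_factory=list)
    op_counts: dict = field(default_factory=dict)

    @property
    def final(self) -> Image:
        return self.images[-1]


def iterate(
    data: TimeSinogram,
    config: ScanConfig,
    backprojector: str = "das",
    n_iterations: int = 6,
    epsilon: float | None = None,
    delays: DelayTensor | None = None,
    keep_trace: bool = True,
) -> IterationTrace:
    """Run the multiplicative iterative update from a homogeneous start.

    Parameters
    ----------
    data
        Calibrated non-negative envelope sinogram (the dataset D).
    config
        Scan geometry; the delay tensor is derived from it unless ``delays``
        is supplied (e.g. precomputed and shared across methods).
    backprojector
        ``"das"`` (itDAS) or ``"dmas"`` (itDMAS).
    n_iterations
        Number of multiplicative updates (>= 1); default 6.
    epsilon
        Denominator guard; ``None`` selects ``1e-12 * max(F[U])``.  With
        ``epsilon=0`` zero-denominator bins contribute ratio 0 exactly.
    """
    if n_iterations < 1:
        raise InvalidArgumentError("n_iterations must be >= 1")
    if np.any(data.values < 0):
        raise InvalidDataError("iterative update requires non-negative data")
    if backprojector not in _BACKPROJECTORS:
        raise InvalidArgumentError(
            f"unknown backprojector {backprojector!r}; expected 'das' or 'dmas'"
        )
    back = _BACKPROJECTORS[backprojector]

    if delays is None:
        speed = estimate_propagation_speed(config)
        delays = time_of_flight(config, speed)

    m = delays.n_positions
    ops = {"n_forward": 0, "n_backward": 0, "signal_sums": 0}

    def count(kind: str) -> None:
        ops[kind] += 1
        ops["signal_sums"] += m

    # Normalizers: F[U] over images, B[U] over sinograms.
    fu = forward_unity(delays)
    count("n_forward")
    if backprojector == "das":
        bu = backproject_unity(delays)
    else:
        bu = dmas(np.ones((m, delays.n_times)), delays)
    count("n_backward")
    bu_flat = (bu.values if isinstance(bu, Image) else bu).ravel()
    live = bu_flat > 0  # pixels with no antenna coverage stay at 0

    if epsilon is None:
        epsilon = 1e-12 * float(fu.values.max())

    img = np.ones(delays.n_pixels, dtype=float)
    images = [img.copy()]
    projections = []
    max_ratio = []

    d_weighted = data.values * fu.values
    for n in range(n_iterations):
        fi = forward_project(img, delays)
        count("n_forward")
        denom = fi.values + epsilon
        ratio = np.divide(
            d_weighted,
            denom,
            out=np.zeros_like(d_weighted),
            where=denom > 0,
        )
        bratio = back(ratio, delays)
        count("n_backward")
        b_flat = (bratio.values if isinstance(bratio, Image) else bratio).ravel()
        img = np.where(live, img * b_flat / np.where(live, bu_flat, 1.0), 0.0)
        max_ratio.append(float(ratio.max()))
        logger.debug(
            "iteration %d: max ratio %.4g, image max %.4g", n + 1, max_ratio[-1], img.max()
        )
        if keep_trace:
            projections.append(fi)
            images.append(img.copy())

    if not keep_trace:
        images.append(img.copy())

    shape = delays.image_shape or (delays.n_pixels,)
    extent = delays.image_extent if delays.image_extent is not None else 1.0

    def wrap(flat: np.ndarray):
        if delays.image_shape is None:
            return flat
        return Image(values=flat.reshape(shape), extent=extent)

    return IterationTrace(
        images=[wrap(x) for x in images],
        projections=projections,
        n_iterations=n_iterations,
        backprojector=backprojector,
        max_ratio=max_ratio,
        op_counts=ops,
    )


def itdas(
    data: TimeSinogram,
    config: ScanConfig,
    n_iterations: int = 6,
    **kw,
) -> Image:
    """Iterative DAS: final image of :func:`iterate` with the DAS back-projector."""
    return iterate(data, config, "das", n_iterations, **kw).final


def itdmas(
    data: TimeSinogram,
    config: ScanConfig,
    n_iterations: int = 6,
    **kw,
) -> Image:
    """Iterative DMAS: final image of :func:`iterate` with the DMAS back-projector."""
    return iterate(data, config, "dmas", n_iterations, **kw).final


def reconstruct(
    full_scan: FrequencySinogram,
    reference_scan: FrequencySinogram | None,
    config: ScanConfig,
    method: str = "das",
    n_iterations: int = 6,
    signal_mode: str = "envelope",
    delays: DelayTensor | None = None,
    interpolation: str = "nearest",
) -> Image:
    """End-to-end reconstruction from frequency-domain S11 scans.

    Calibrates (reference subtraction), converts to the time domain via the
    ICZT, and applies the selected method: ``das``, ``dmas``, ``itdas`` or
    ``itdmas``.  ``signal_mode="complex"`` performs coherent DAS/DMAS on the
    complex signals and takes the modulus at the end (squaring then being the
    display step); the iterative methods require envelope mode.
    """
    if method not in ("das", "dmas", "itdas", "itdmas"):
        raise InvalidArgumentError(f"unknown reconstruction method {method!r}")
    if delays is None:
        delays = time_of_flight(config, estimate_propagation_speed(config))

    if signal_mode == "complex":
        if method in ("itdas", "itdmas"):
            raise InvalidArgumentError(
                "complex signal mode applies to the non-iterative beamformers only"
            )
        signals = to_time_domain(full_scan, reference_scan, config.time_grid, "complex")
        beam = das if method == "das" else dmas
        re = _signed_beamform(np.ascontiguousarray(signals.real), delays, beam, interpolation)
        im = _signed_beamform(np.ascontiguousarray(signals.imag), delays, beam, interpolation)
        out = np.hypot(re, im)
        return Image(values=out.reshape(delays.image_shape), extent=delays.image_extent)

    sino = to_time_domain(full_scan, reference_scan, config.time_grid, "envelope")
    if method == "das":
        return das(sino, delays, interpolation=interpolation)
    if method == "dmas":
        return dmas(sino, delays, interpolation=interpolation)
    back = "das" if method == "itdas" else "dmas"
    return iterate(sino, config, back, n_iterations, delays=delays).final


def _signed_beamform(values: np.ndarray, delays: DelayTensor, beam, interpolation: str):
    """Apply a beamformer to signed signals by splitting positive/negative parts.

    DAS is linear so pos-neg recombination is exact; for DMAS the split is a
    documented approximation of the coherent pair product's real part.
    """
    if beam is das:
        pos = das(np.clip(values, 0, None), delays, interpolation=interpolation)
        neg = das(np.clip(-values, 0, None), delays, interpolation=interpolation)
        p = pos.values if isinstance(pos, Image) else pos
        q = neg.values if isinstance(neg, Image) else neg
        return (p - q).ravel()
    # DMAS on signed data: use the (S^2 - Q)/2 identity directly, which is
    # sign-correct without any non-negativity requirement.
    from .beamform import sample_at_delay

    s = np.zeros(delays.n_pixels)
    q = np.zeros(delays.n_pixels)
    for m in range(delays.n_positions):
        row_delays = _single_row(delays, m)
        row = sample_at_delay(values[m : m + 1], row_delays, interpolation)[0]
        s += row
        q += row * row
    return 0.5 * (s * s - q)


def _single_row(delays: DelayTensor, m: int) -> DelayTensor:
    return DelayTensor(
        delays=delays.delays[m : m + 1],
        bin_index=delays.bin_index[m : m + 1],
        valid=delays.valid[m : m + 1],
        n_times=delays.n_times,
        dt=delays.dt,
        t0=delays.t0,
    )
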