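"""File formats: sinograms (CSV/HDF5), images (PNG/CSV/HDF5), YAML configs.

CSV sinogram dialect: a header row of frequencies in Hz followed by one row
per antenna position, cells written as ``re+imj`` complex literals that
Python's ``complex()`` parses; doubles are printed with 17 significant
digits so the round-trip is bit-exact.  HDF5 files store ``/s11`` (complex),
``/freqs`` and the scan geometry as root attributes.

PNG rendering follows the presentation convention: the squared intensity map
normalized to its maximum, with optional overlay circles for the antenna
trajectory (black), the breast boundary (white) and the known tumor (green).
Physics coordinates are +x right / +y up with image row 0 at the top, so no
row flip is needed at render time — pixel (0, 0) is the top-left corner.
PNG is visualization-only; CSV/HDF5 store the raw un-squared values.
"""

from __future__ import annotations

import numpy as np
import yaml
from PIL import Image as PILImage

from .exceptions import FormatError, IncompatibleScanError
from .geometry import Image, ScanConfig
from .signal import FrequencySinogram, TimeSinogram
from .simulate import PhantomSpec, Scatterer

__all__ = [
    "write_frequency_sinogram",
    "read_frequency_sinogram",
    "write_time_sinogram",
    "read_time_sinogram",
    "write_image",
    "read_image",
    "save_config",
    "load_config",
    "save_phantom",
    "load_phantom",
]


def _fmt_float(x: float) -> str:
    return f"{x:.17g}"


def _fmt_complex(z: complex) -> str:
    return f"{z.real:.17g}{z.imag:+.17g}j"


def _infer_format(path: str, fmt: str | None, choices: tuple) -> str:
    if fmt is not None:
        if fmt not in choices:
            raise FormatError(f"unsupported format {fmt!r}; expected one of {choices}")
        return fmt
    p = str(path).lower()
    for c in choices:
        ext = ".h5" if c == "hdf5" else f".{c}"
        if p.endswith(ext) or p.endswith(f".{c}"):
            return c
    raise FormatError(f"cannot infer format of {path!r}; pass format= explicitly")


# --------------------------------------------------------------- sinograms
def write_frequency_sinogram(
    sino: FrequencySinogram, path: str, format: str | None = None
) -> None:
    fmt = _infer_format(path, format, ("csv", "hdf5"))
    if fmt == "csv":
        with open(path, "w") as fh:
            fh.write(",".join(_fmt_float(f) for f in sino.freq_grid) + "\n")
            for row in sino.values:
                fh.write(",".join(_fmt_complex(z) for z in row) + "\n")
        return
    import h5py

    with h5py.File(path, "w") as fh:
        fh.create_dataset("s11", data=sino.values)
        fh.create_dataset("freqs", data=sino.freq_grid)


def read_frequency_sinogram(
    path: str, format: str | None = None, config: ScanConfig | None = None
) -> FrequencySinogram:
    fmt = _infer_format(path, format, ("csv", "hdf5"))
    if fmt == "csv":
        with open(path) as fh:
            lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
        if not lines:
            raise FormatError(f"{path}: empty file")
        try:
            freqs = np.array([float(c) for c in lines[0].split(",")])
        except ValueError as e:
            raise FormatError(f"{path}: unparseable frequency header: {e}") from e
        rows = []
        for r, ln in enumerate(lines[1:], start=1):
            cells = ln.split(",")
            if len(cells) != freqs.size:
                raise FormatError(
                    f"{path}: row {r} has {len(cells)} cells, expected {freqs.size}"
                )
            try:
                rows.append([complex(c) for c in cells])
            except ValueError as e:
                bad = next(
                    (c + 1 for c, cell in enumerate(cells) if _unparseable(cell)), "?"
                )
                raise FormatError(
                    f"{path}: unparseable complex literal at row {r}, column {bad}"
                ) from e
        sino = FrequencySinogram(values=np.array(rows, dtype=complex), freq_grid=freqs)
    else:
        import h5py

        with h5py.File(path, "r") as fh:
            sino = FrequencySinogram(
                values=fh["s11"][...], freq_grid=fh["freqs"][...]
            )
    if config is not None:
        if sino.values.shape[0] != config.n_positions or not np.allclose(
            sino.freq_grid, config.freq_grid
        ):
            raise IncompatibleScanError(
                f"{path}: sinogram axes do not match the supplied scan config"
            )
    return sino


def _unparseable(cell: str) -> bool:
    try:
        complex(cell)
        return False
    except ValueError:
        return True


def write_time_sinogram(sino: TimeSinogram, path: str, format: str | None = None) -> None:
    fmt = _infer_format(path, format, ("csv", "hdf5"))
    if fmt == "csv":
        with open(path, "w") as fh:
            fh.write(",".join(_fmt_float(t) for t in sino.time_grid) + "\n")
            for row in sino.values:
                fh.write(",".join(_fmt_float(v) for v in row) + "\n")
        return
    import h5py

    with h5py.File(path, "w") as fh:
        fh.create_dataset("signals", data=sino.values)
        fh.create_dataset("times", data=sino.time_grid)


def read_time_sinogram(path: str, format: str | None = None) -> TimeSinogram:
    fmt = _infer_format(path, format, ("csv", "hdf5"))
    if fmt == "csv":
        data = np.loadtxt(path, delimiter=",")
        return TimeSinogram(values=data[1:], time_grid=data[0])
    import h5py

    with h5py.File(path, "r") as fh:
        return TimeSinogram(values=fh["signals"][...], time_grid=fh["times"][...])


# ------------------------------------------------------------------- images
def _ring_mask(coords: np.ndarray, radius: float, width: float) -> np.ndarray:
    d = np.hypot(coords[:, 0], coords[:, 1])
    return np.abs(d - radius) <= width


def write_image(
    image: Image,
    path: str,
    format: str | None = None,
    config: ScanConfig | None = None,
    tumor_center: tuple | None = None,
    tumor_radius: float | None = None,
) -> None:
    """Write a reconstruction; PNG renders, CSV/HDF5 store losslessly.

    PNG overlays (drawn when ``config`` / tumor info are given): antenna
    trajectory in black, breast boundary in white, tumor circle in green.
    """
    if not np.all(np.isfinite(image.values)):
        raise FormatError("refusing to write an image with non-finite values")
    fmt = _infer_format(path, format, ("png", "csv", "hdf5"))
    if fmt == "csv":
        np.savetxt(path, image.values, delimiter=",", fmt="%.17g")
        return
    if fmt == "hdf5":
        import h5py

        with h5py.File(path, "w") as fh:
            ds = fh.create_dataset("image", data=image.values)
            ds.attrs["extent_m"] = image.extent
        return

    disp = image.display_map()
    peak = disp.max()
    norm = disp / peak if peak > 0 else disp
    gray = (255.0 * norm).astype(np.uint8)
    rgb = np.stack([gray, gray, gray], axis=-1)

    n = image.size
    pix = image.pixel_size
    xs = -0.5 * image.extent + (np.arange(n) + 0.5) * pix
    ys = 0.5 * image.extent - (np.arange(n) + 0.5) * pix
    X, Y = np.meshgrid(xs, ys)
    coords = np.stack([X.ravel(), Y.ravel()], axis=1)
    width = 0.75 * pix

    def paint(radius: float, color: tuple, center=(0.0, 0.0)) -> None:
        c = np.stack([coords[:, 0] - center[0], coords[:, 1] - center[1]], axis=1)
        mask = _ring_mask(c, radius, width).reshape(n, n)
        rgb[mask] = color

    if config is not None:
        if config.trajectory_radius <= 0.5 * image.extent * np.sqrt(2):
            paint(config.trajectory_radius, (0, 0, 0))
        paint(config.breast_radius, (255, 255, 255))
    if tumor_center is not None and tumor_radius is not None:
        paint(tumor_radius, (0, 255, 0), center=tumor_center)

    PILImage.fromarray(rgb, mode="RGB").save(path)


def read_image(path: str, format: str | None = None, extent: float | None = None) -> Image:
    fmt = _infer_format(path, format, ("csv", "hdf5"))
    if fmt == "csv":
        vals = np.loadtxt(path, delimiter=",")
        if extent is None:
            raise FormatError("reading a CSV image requires extent=")
        return Image(values=vals, extent=extent)
    import h5py

    with h5py.File(path, "r") as fh:
        ds = fh["image"]
        return Image(values=ds[...], extent=float(ds.attrs["extent_m"]))


# ------------------------------------------------------------------ configs
def save_config(config: ScanConfig, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


def load_config(path: str) -> ScanConfig:
    with open(path) as fh:
        return ScanConfig.from_dict(yaml.safe_load(fh))


def save_phantom(phantom: PhantomSpec, path: str) -> None:
    d = {
        "breast_radius": float(phantom.breast_radius),
        "tumor_index": int(phantom.tumor_index),
        "scatterers": [
            {
                "position": [float(s.position[0]), float(s.position[1])],
                "reflectivity": float(s.reflectivity),
                "radius": float(s.radius),
            }
            for s in phantom.scatterers
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)


def load_phantom(path: str) -> PhantomSpec:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    return PhantomSpec(
        scatterers=[
            Scatterer(tuple(s["position"]), s["reflectivity"], s.get("radius", 0.0))
            for s in d["scatterers"]
        ],
        breast_radius=d["breast_radius"],
        tumor_index=d.get("tumor_index", 0),
    )
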